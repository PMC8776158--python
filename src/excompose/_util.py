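"""Small shared helpers: reporting-grade rounding and key-value text files."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .errors import FormatError

__all__ = ["round_half_away", "read_keyvalues", "write_keyvalues"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of the report tables).

    ``round_half_away(0.125, 2) == 0.13`` whereas builtin ``round`` gives 0.12.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def read_keyvalues(path) -> dict[str, str]:
    """Parse a ``key = value`` text file; '#' starts a comment, blanks ignored."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_keyvalues(mapping: dict, path) -> None:
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")
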