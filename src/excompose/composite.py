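"""Term decomposition and composite assembly of 0-0 excitation energies.

A ZPVE-corrected 0-0 energy splits into three additive terms,

    e_00 = e_vert + (e_ad - e_vert) + (e_00 - e_ad)
         = e_vert +    dd_ad        +    dd_00

where the relaxation term ``dd_ad`` and the ZPVE-difference term ``dd_00``
are much less method-sensitive than the vertical term. A composite protocol
takes each term from a (possibly different) method:

* P1: vertical from the wavefunction reference, relaxation and ZPVE
  difference from DFT/TD-DFT;
* P2: vertical and relaxation from the wavefunction reference, ZPVE
  difference from DFT/TD-DFT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

from ._util import read_keyvalues, write_keyvalues
from .dataio import ConformerRecord, EnergyTerms
from .errors import MissingTermError

__all__ = [
    "ProtocolSpec",
    "CompositeResult",
    "P1",
    "P2",
    "delta_delta_ad",
    "delta_delta_00",
    "assemble_composite",
    "read_protocol",
    "write_protocol",
    "load_bundled_protocol",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Per-term method assignment defining a composite protocol."""

    name: str
    source_e_vert: str
    source_dd_ad: str
    source_dd_00: str


# Bundled defaults use the selected DFT/TD-DFT functional as the low-level source.
P1 = ProtocolSpec("P1", source_e_vert="CC2", source_dd_ad="wB97X-D", source_dd_00="wB97X-D")
P2 = ProtocolSpec("P2", source_e_vert="CC2", source_dd_ad="CC2", source_dd_00="wB97X-D")


@dataclass(frozen=True)
class CompositeResult:
    """An assembled 0-0 energy with its per-term audit trail.

    ``terms`` maps term name -> (source method, value eV); ``e_00`` is their
    exact sum.
    """

    conformer: Optional[ConformerRecord]
    protocol: ProtocolSpec
    e_00: float
    terms: dict[str, tuple[str, float]]


def _require(value: Optional[float], what: str, context: str = "") -> float:
    if value is None or not math.isfinite(value):
        suffix = f" ({context})" if context else ""
        raise MissingTermError(f"missing {what}{suffix}")
    return value


def delta_delta_ad(e_ad: Optional[float], e_vert: Optional[float]) -> float:
    """Excited-state relaxation term e_ad - e_vert (typically negative)."""
    return _require(e_ad, "e_ad") - _require(e_vert, "e_vert")


def delta_delta_00(e_00: Optional[float], e_ad: Optional[float]) -> float:
    """S1-S0 ZPVE difference term e_00 - e_ad."""
    return _require(e_00, "e_00") - _require(e_ad, "e_ad")


def assemble_composite(
    protocol: ProtocolSpec,
    terms_by_method: Mapping[str, EnergyTerms],
    conformer: Optional[ConformerRecord] = None,
) -> CompositeResult:
    """Assemble one conformer's composite 0-0 energy from per-method terms.

    ``terms_by_method`` maps method name -> that method's EnergyTerms for the
    conformer. A missing field raises MissingTermError naming the term and
    method; no silent substitution is allowed (a composite energy with a
    substituted term is a different protocol).
    """
    if conformer is None:
        for rec in terms_by_method.values():
            conformer = rec.conformer
            break
    ctx = f"conformer {conformer.system} {conformer.conformer}" if conformer else ""

    def get(method: str) -> EnergyTerms:
        try:
            return terms_by_method[method]
        except KeyError:
            raise MissingTermError(
                f"no energy record for method {method!r}" + (f" ({ctx})" if ctx else "")
            ) from None

    src1 = get(protocol.source_e_vert)
    e_vert = _require(src1.e_vert, f"e_vert from {protocol.source_e_vert}", ctx)

    src2 = get(protocol.source_dd_ad)
    dd_ad = _require(src2.e_ad, f"e_ad from {protocol.source_dd_ad}", ctx) - _require(
        src2.e_vert, f"e_vert from {protocol.source_dd_ad}", ctx
    )

    src3 = get(protocol.source_dd_00)
    dd_00 = _require(src3.e_00, f"e_00 from {protocol.source_dd_00}", ctx) - _require(
        src3.e_ad, f"e_ad from {protocol.source_dd_00}", ctx
    )

    terms = {
        "e_vert": (protocol.source_e_vert, e_vert),
        "dd_ad": (protocol.source_dd_ad, dd_ad),
        "dd_00": (protocol.source_dd_00, dd_00),
    }
    return CompositeResult(
        conformer=conformer,
        protocol=protocol,
        e_00=e_vert + dd_ad + dd_00,
        terms=terms,
    )


def read_protocol(path) -> ProtocolSpec:
    kv = read_keyvalues(path)
    return ProtocolSpec(
        name=kv["name"],
        source_e_vert=kv["e_vert_source"],
        source_dd_ad=kv["dd_ad_source"],
        source_dd_00=kv["dd_00_source"],
    )


def write_protocol(spec: ProtocolSpec, path) -> None:
    write_keyvalues(
        {
            "name": spec.name,
            "e_vert_source": spec.source_e_vert,
            "dd_ad_source": spec.source_dd_ad,
            "dd_00_source": spec.source_dd_00,
        },
        path,
    )


def load_bundled_protocol(name: str) -> ProtocolSpec:
    """Load one of the packaged protocol definitions ('P1' or 'P2')."""
    with resources.as_file(
        resources.files("excompose.data").joinpath(f"protocols/{name}.txt")
    ) as p:
        return read_protocol(p)
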