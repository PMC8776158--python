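"""Mode-dependent linear scaling of N-H stretch frequencies and S1-S0 shifts.

Calculated harmonic frequencies in the amide-A window carry systematic
method/basis errors plus anharmonicity; a per-mode-class linear map
``nu_corrected = a * nu_harmonic + b`` fitted against experimental band
positions absorbs them. Corrected excited-minus-ground shifts are obtained
by scaling the absolute S1 and S0 frequencies with their state-specific
functions and differencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

import numpy as np

from ._util import read_keyvalues, round_half_away, write_keyvalues
from .errors import EmptyComparisonError, FitError, UsageError, ValidationError

__all__ = [
    "MODE_CLASSES",
    "STATES",
    "ScalingFunction",
    "ShiftRecord",
    "RmsdResult",
    "fit_scaling",
    "apply_scaling",
    "compute_shift",
    "shift_rmsd",
    "read_scaling",
    "write_scaling",
]

MODE_CLASSES = ("NH", "NH2sym", "NH2anti")
STATES = ("S0", "S1")


@dataclass(frozen=True)
class ScalingFunction:
    """Linear map nu_exp = a * nu_theo + b for one mode class in one state."""

    mode_class: str
    state: str
    a: float
    b: float
    n_points: int
    rmse: float
    method: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode_class not in MODE_CLASSES:
            raise ValidationError(
                f"mode_class {self.mode_class!r} not in {MODE_CLASSES}"
            )
        if self.state not in STATES:
            raise ValidationError(f"state {self.state!r} not in {STATES}")
        if self.n_points < 2:
            raise ValidationError("a scaling function needs n_points >= 2")
        if self.a <= 0:
            warnings.warn(
                f"scaling slope a={self.a:g} <= 0 is not physically meaningful",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ShiftRecord:
    """S1 - S0 frequency shift at one N-H site (integers, red-shift negative)."""

    system: str
    conformer: str
    method: str
    site_label: str
    mode_class: str
    harmonic_shift: int
    corrected_shift: Optional[int] = None
    experimental_shift: Optional[int] = None
    coupled: bool = False


class RmsdResult(NamedTuple):
    value: float
    rounded: int


def fit_scaling(
    pairs: Iterable[tuple[float, float]],
    mode_class: str,
    state: str,
    method: Optional[str] = None,
) -> ScalingFunction:
    """Ordinary least-squares fit of nu_exp = a * nu_theo + b.

    Parameters
    ----------
    pairs
        Iterable of ``(nu_theo, nu_exp)`` in cm^-1.

    Raises
    ------
    FitError
        Fewer than two points, or all ``nu_theo`` identical.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise FitError("fit_scaling needs at least 2 (nu_theo, nu_exp) pairs")
    theo, exp = arr[:, 0], arr[:, 1]
    if np.ptp(theo) == 0:
        raise FitError("all nu_theo values identical; slope undetermined")
    a, b = np.polyfit(theo, exp, 1)
    resid = exp - (a * theo + b)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return ScalingFunction(
        mode_class=mode_class,
        state=state,
        a=float(a),
        b=float(b),
        n_points=int(arr.shape[0]),
        rmse=rmse,
        method=method,
    )


def apply_scaling(
    f: ScalingFunction, nu: float, mode_class: Optional[str] = None
) -> float:
    """Return a * nu + b, unrounded. ``nu`` must be positive.

    If ``mode_class`` is given (the class of the record being corrected) it
    must match the function's class.
    """
    if nu <= 0:
        raise ValidationError(f"frequency must be positive, got {nu}")
    if mode_class is not None and mode_class != f.mode_class:
        raise UsageError(
            f"scaling function is for {f.mode_class}, record is {mode_class}"
        )
    return f.a * nu + f.b


def compute_shift(
    nu_s1: float,
    nu_s0: float,
    f_s1: Optional[ScalingFunction] = None,
    f_s0: Optional[ScalingFunction] = None,
    *,
    system: str = "",
    conformer: str = "",
    method: str = "",
    site_label: str = "",
    mode_class: str = "NH",
    experimental_shift: Optional[int] = None,
    coupled: bool = False,
) -> ShiftRecord:
    """Harmonic (and, with scaling functions, corrected) S1 - S0 shift.

    Scaling functions must be given for both states or neither; shifts are
    rounded half-away-from-zero to integer cm^-1 for reporting.
    """
    if nu_s1 <= 0 or nu_s0 <= 0:
        raise ValidationError("frequencies must be positive")
    if (f_s1 is None) != (f_s0 is None):
        raise UsageError("give scaling functions for both states or neither")
    harmonic = int(round_half_away(nu_s1 - nu_s0))
    corrected = None
    if f_s1 is not None and f_s0 is not None:
        corrected = int(
            round_half_away(
                apply_scaling(f_s1, nu_s1, mode_class)
                - apply_scaling(f_s0, nu_s0, mode_class)
            )
        )
    return ShiftRecord(
        system=system,
        conformer=conformer,
        method=method,
        site_label=site_label,
        mode_class=mode_class,
        harmonic_shift=harmonic,
        corrected_shift=corrected,
        experimental_shift=experimental_shift,
        coupled=coupled,
    )


def shift_rmsd(predicted: Iterable[float], observed: Iterable[float]) -> RmsdResult:
    """Root-mean-square deviation between predicted and observed shifts.

    Pairs with a missing observed value must be excluded upstream; the two
    collections must already be aligned and of equal length.
    """
    pred = np.asarray(list(predicted), dtype=float)
    obs = np.asarray(list(observed), dtype=float)
    if pred.shape != obs.shape:
        raise UsageError(
            f"length mismatch: {pred.shape[0]} predicted vs {obs.shape[0]} observed"
        )
    if pred.size == 0:
        raise EmptyComparisonError("no shift pairs to compare")
    value = float(np.sqrt(np.mean((pred - obs) ** 2)))
    return RmsdResult(value=value, rounded=int(round_half_away(value)))


def write_scaling(f: ScalingFunction, path) -> None:
    mapping = {
        "mode_class": f.mode_class,
        "state": f.state,
        "a": repr(f.a),
        "b": repr(f.b),
        "n_points": f.n_points,
        "rmse": repr(f.rmse),
    }
    if f.method is not None:
        mapping["method"] = f.method
    write_keyvalues(mapping, path)


def read_scaling(path) -> ScalingFunction:
    kv = read_keyvalues(path)
    return ScalingFunction(
        mode_class=kv["mode_class"],
        state=kv["state"],
        a=float(kv["a"]),
        b=float(kv["b"]),
        n_points=int(kv["n_points"]),
        rmse=float(kv["rmse"]),
        method=kv.get("method"),
    )
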