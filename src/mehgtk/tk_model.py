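"""One-compartment steady-state toxicokinetics of methylmercury.

At steady state the daily absorbed dose equals the daily first-order
elimination, which ties the blood concentration to the dietary intake:

    C_blood = d * t_half * Abs * frac_b * w / (ln2 * V_b)

where ``d`` is the daily dietary intake (ug/kg bw/day), ``t_half`` the
biological half-life (days), ``Abs`` the gastrointestinal absorption
fraction, ``frac_b`` the fraction of the absorbed body burden residing in
blood, ``w`` the body weight (kg) and ``V_b`` the blood volume (L).  The
divisor is the natural logarithm of 2, i.e. the first-order elimination
constant is ``k = ln2 / t_half``.

Canonical units are fixed throughout the package: concentrations in ug/L,
intakes in ug/kg bw/day, half-lives in days.  There is no unit-conversion
layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LN2",
    "TKParams",
    "Subject",
    "steady_state_blood",
    "invert_half_life",
    "elimination_constant",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class TKParams:
    """Shared kinetic nuisance parameters.

    Attributes
    ----------
    abs_fraction : float
        Gastrointestinal absorption fraction, in (0, 1].
    frac_blood : float
        Fraction of the body burden residing in blood, in (0, 1).
    blood_volume : float
        Blood volume V_b in litres, > 0.
    """

    abs_fraction: float
    frac_blood: float
    blood_volume: float

    def __post_init__(self) -> None:
        if not (0.0 < self.abs_fraction <= 1.0):
            raise ValueError(f"abs_fraction must be in (0, 1], got {self.abs_fraction}")
        if not (0.0 < self.frac_blood < 1.0):
            raise ValueError(f"frac_blood must be in (0, 1), got {self.frac_blood}")
        if not self.blood_volume > 0.0:
            raise ValueError(f"blood_volume must be > 0, got {self.blood_volume}")


@dataclass(frozen=True)
class Subject:
    """One observed study participant.

    ``blood_mehg`` is the measured blood methylmercury concentration (ug/L)
    and ``intake`` the daily dietary methylmercury intake (ug/kg bw/day).
    """

    id: str
    sex: str
    age: float
    weight: float
    blood_mehg: float
    intake: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.weight > 0.0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        if self.blood_mehg < 0.0:
            raise ValueError(f"blood_mehg must be >= 0, got {self.blood_mehg}")
        if self.intake < 0.0:
            raise ValueError(f"intake must be >= 0, got {self.intake}")


def _check_nonnegative(**kwargs: object) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"{name} must be nonnegative")


def steady_state_blood(d, t_half, w, tk: TKParams):
    """Steady-state blood methylmercury concentration (ug/L).

    Linear in each of ``d`` (intake, ug/kg bw/day), ``t_half`` (days) and
    ``w`` (body weight, kg); accepts scalars or broadcastable arrays.
    """
    _check_nonnegative(d=d, t_half=t_half, w=w)
    return np.multiply(d, t_half) * (tk.abs_fraction * tk.frac_blood / (LN2 * tk.blood_volume)) * w


def invert_half_life(y, d, w, tk: TKParams):
    """Half-life (days) implied by a steady-state blood concentration.

    Algebraic inversion of :func:`steady_state_blood`; requires strictly
    positive intake and weight (the half-life is unidentifiable at d = 0).
    """
    _check_nonnegative(y=y)
    if np.any(np.asarray(d) <= 0):
        raise ValueError("d must be > 0 to invert the steady-state relation")
    if np.any(np.asarray(w) <= 0):
        raise ValueError("w must be > 0 to invert the steady-state relation")
    return np.asarray(y) * LN2 * tk.blood_volume / (np.multiply(d, w) * tk.abs_fraction * tk.frac_blood)


def elimination_constant(t_half):
    """First-order elimination rate constant k = ln2 / t_half (per day)."""
    if np.any(np.asarray(t_half) <= 0):
        raise ValueError("t_half must be > 0")
    return LN2 / np.asarray(t_half)
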