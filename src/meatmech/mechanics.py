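"""Closed-form kinematics and constitutive evaluation for incompressible,
isotropic hyperelasticity under uniaxial and simple-shear loading.

The material model is an eight-term invariant-based free-energy library

    psi(I1, I2) = w1 [I1-3] + w2 [exp(w2* [I1-3]) - 1]
                + w3 [I1-3]^2 + w4 [exp(w4* [I1-3]^2) - 1]
                + w5 [I2-3] + w6 [exp(w6* [I2-3]) - 1]
                + w7 [I2-3]^2 + w8 [exp(w8* [I2-3]^2) - 1]

with non-negative linear weights ``w1..w8`` (kPa) and non-negative
dimensionless exponents ``w2*, w4*, w6*, w8*``. Non-negativity makes every
term polyconvex, so any admissible weight vector yields a stable material.

Deformations are parameterized directly by the stretch ``lam`` (uniaxial)
or the engineering shear strain ``gam`` (simple shear); the deformation
gradient, the incompressibility multiplier (pressure) and the third
invariant are eliminated analytically through the zero-lateral-stress and
plane-shear boundary conditions, so only I1, I2 and their derivatives with
respect to the control variable ever appear.

Stress derivatives are the *exact* partial derivatives of psi, including
the chain-rule exponent factors on the exponential terms (so e.g. the
Demiray term contributes ``w2 w2* exp(w2*[I1-3])`` to dpsi/dI1). All
stresses and weights are in kPa; stretches and strains are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Invariants",
    "ModelWeights",
    "Modulus",
    "TERM_NAMES",
    "EXP_ARG_MAX",
    "OverflowFlag",
    "invariants_uniaxial",
    "invariants_shear",
    "free_energy",
    "dpsi_dI1",
    "dpsi_dI2",
    "piola_stress_uniaxial",
    "piola_stress_shear",
    "small_strain_shear_modulus",
]

#: Human-readable names of the eight library terms, indexed 1..8.
TERM_NAMES = {
    1: "I1 linear (neo-Hooke)",
    2: "I1 exponential linear (Demiray)",
    3: "I1 quadratic",
    4: "I1 exponential quadratic",
    5: "I2 linear (Blatz-Ko)",
    6: "I2 exponential linear",
    7: "I2 quadratic",
    8: "I2 exponential quadratic",
}

#: Terms whose stress contribution is linear in the weight with no exponent.
LINEAR_TERMS = (1, 3, 5, 7)
#: Terms carrying a paired exponent (index into ``wexp``: 2->0, 4->1, 6->2, 8->3).
EXP_TERMS = (2, 4, 6, 8)

#: Exponent-argument clip used during optimization trial steps. A clipped
#: evaluation signals a divergent candidate rather than silently saturating.
EXP_ARG_MAX = 50.0


class OverflowFlag(FloatingPointError):
    """Raised when an exponential term's argument exceeds ``EXP_ARG_MAX``."""


@dataclass(frozen=True)
class Invariants:
    """First and second principal invariants and their derivatives with
    respect to the loading control variable (lambda or gamma)."""

    I1: np.ndarray
    I2: np.ndarray
    dI1: np.ndarray
    dI2: np.ndarray


@dataclass
class ModelWeights:
    """Weights of the eight-term free-energy library.

    Parameters
    ----------
    w : array-like of length 8
        Linear weights w1..w8 in kPa.
    wexp : array-like of length 4, optional
        Dimensionless exponents (w2*, w4*, w6*, w8*), paired with terms
        2, 4, 6 and 8. Defaults to zeros (exponents are irrelevant when the
        paired linear weight is zero).
    """

    w: np.ndarray
    wexp: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (8,):
            raise ValueError(f"w must have length 8, got shape {w.shape}")
        wexp = self.wexp
        wexp = np.zeros(4) if wexp is None else np.asarray(wexp, dtype=float)
        if wexp.shape != (4,):
            raise ValueError(f"wexp must have length 4, got shape {wexp.shape}")
        if np.any(w < 0) or np.any(wexp < 0):
            raise ValueError("all weights and exponents must be non-negative")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "wexp", wexp)

    @classmethod
    def from_terms(cls, terms: dict[int, float], exponents: dict[int, float] | None = None) -> "ModelWeights":
        """Build weights from sparse ``{term index: weight}`` mappings.

        ``exponents`` maps the exponential term index (2, 4, 6 or 8) to its
        paired exponent value.
        """
        w = np.zeros(8)
        for k, v in terms.items():
            if not 1 <= k <= 8:
                raise ValueError(f"term index {k} out of range 1..8")
            w[k - 1] = v
        wexp = np.zeros(4)
        for k, v in (exponents or {}).items():
            if k not in EXP_TERMS:
                raise ValueError(f"term {k} carries no exponent")
            wexp[EXP_TERMS.index(k)] = v
        return cls(w=w, wexp=wexp)

    def active_terms(self) -> tuple[int, ...]:
        return tuple(k for k in range(1, 9) if self.w[k - 1] > 0)


@dataclass(frozen=True)
class Modulus:
    """Small-strain stiffness pair for an incompressible solid (nu = 0.5)."""

    mu: float
    nu: float = 0.5

    @property
    def E(self) -> float:
        return 2.0 * (1.0 + self.nu) * self.mu


def invariants_uniaxial(lam):
    """Invariants for incompressible uniaxial stretch ``lam``.

    The lateral stretches are 1/sqrt(lam), hence
    I1 = lam^2 + 2/lam, I2 = 2 lam + 1/lam^2,
    dI1/dlam = 2 lam - 2/lam^2, dI2/dlam = 2 - 2/lam^3.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    I1 = lam**2 + 2.0 / lam
    I2 = 2.0 * lam + 1.0 / lam**2
    dI1 = 2.0 * lam - 2.0 / lam**2
    dI2 = 2.0 - 2.0 / lam**3
    return Invariants(I1=I1, I2=I2, dI1=dI1, dI2=dI2)


def invariants_shear(gam):
    """Invariants for simple shear with engineering strain ``gam``:
    I1 = I2 = 3 + gam^2, with derivatives 2 gam."""
    gam = np.asarray(gam, dtype=float)
    if np.any(gam < 0):
        raise ValueError("shear strain must be non-negative")
    I = 3.0 + gam**2
    dI = 2.0 * gam
    return Invariants(I1=I, I2=I.copy(), dI1=dI, dI2=dI.copy())


def _checked_exp(arg, clip: bool):
    arg = np.asarray(arg, dtype=float)
    if np.any(arg > EXP_ARG_MAX):
        if clip:
            arg = np.minimum(arg, EXP_ARG_MAX)
        else:
            raise OverflowFlag(
                f"exponential argument exceeds {EXP_ARG_MAX}; candidate flagged divergent"
            )
    return np.exp(arg)


def free_energy(weights: ModelWeights, inv: Invariants, *, clip: bool = False):
    """Free-energy density psi (kPa) at the given invariant state.

    psi vanishes at the reference state I1 = I2 = 3. With ``clip`` the
    exponential arguments are saturated at ``EXP_ARG_MAX`` (optimizer trial
    steps); otherwise an overshoot raises :class:`OverflowFlag`.
    """
    w, e = weights.w, weights.wexp
    x1 = np.asarray(inv.I1, dtype=float) - 3.0
    x2 = np.asarray(inv.I2, dtype=float) - 3.0
    psi = w[0] * x1 + w[2] * x1**2 + w[4] * x2 + w[6] * x2**2
    if w[1]:
        psi = psi + w[1] * (_checked_exp(e[0] * x1, clip) - 1.0)
    if w[3]:
        psi = psi + w[3] * (_checked_exp(e[1] * x1**2, clip) - 1.0)
    if w[5]:
        psi = psi + w[5] * (_checked_exp(e[2] * x2, clip) - 1.0)
    if w[7]:
        psi = psi + w[7] * (_checked_exp(e[3] * x2**2, clip) - 1.0)
    return psi


def dpsi_dI1(weights: ModelWeights, inv: Invariants, *, clip: bool = False):
    """Exact partial derivative of psi with respect to I1 (kPa).

    dpsi/dI1 = w1 + w2 w2* exp(w2*[I1-3])
             + 2 [I1-3] (w3 + w4 w4* exp(w4* [I1-3]^2)).
    """
    w, e = weights.w, weights.wexp
    x1 = np.asarray(inv.I1, dtype=float) - 3.0
    out = w[0] + 2.0 * x1 * w[2]
    if w[1]:
        out = out + w[1] * e[0] * _checked_exp(e[0] * x1, clip)
    if w[3]:
        out = out + 2.0 * x1 * w[3] * e[1] * _checked_exp(e[1] * x1**2, clip)
    return out + np.zeros_like(x1)


def dpsi_dI2(weights: ModelWeights, inv: Invariants, *, clip: bool = False):
    """Exact partial derivative of psi with respect to I2 (kPa); mirrors
    :func:`dpsi_dI1` with terms 5-8."""
    w, e = weights.w, weights.wexp
    x2 = np.asarray(inv.I2, dtype=float) - 3.0
    out = w[4] + 2.0 * x2 * w[6]
    if w[5]:
        out = out + w[5] * e[2] * _checked_exp(e[2] * x2, clip)
    if w[7]:
        out = out + 2.0 * x2 * w[7] * e[3] * _checked_exp(e[3] * x2**2, clip)
    return out + np.zeros_like(x2)


def piola_stress_uniaxial(weights: ModelWeights, lam, *, clip: bool = False):
    """Nominal uniaxial stress P11 (kPa) at stretch ``lam``.

    Derived from the zero lateral stress condition P22 = P33 = 0:

        P11 = 2 [lam - 1/lam^2] dpsi/dI1 + 2 [1 - 1/lam^3] dpsi/dI2.
    """
    lam = np.asarray(lam, dtype=float)
    inv = invariants_uniaxial(lam)
    return (
        2.0 * (lam - 1.0 / lam**2) * dpsi_dI1(weights, inv, clip=clip)
        + 2.0 * (1.0 - 1.0 / lam**3) * dpsi_dI2(weights, inv, clip=clip)
    )


def piola_stress_shear(weights: ModelWeights, gam, *, clip: bool = False):
    """Nominal shear stress P12 (kPa) at shear strain ``gam``:
    P12 = 2 [dpsi/dI1 + dpsi/dI2] gam."""
    gam = np.asarray(gam, dtype=float)
    inv = invariants_shear(gam)
    return 2.0 * gam * (dpsi_dI1(weights, inv, clip=clip) + dpsi_dI2(weights, inv, clip=clip))


def small_strain_shear_modulus(weights: ModelWeights) -> Modulus:
    """Shear modulus implied by the weights in the small-strain limit.

    mu = 2 (dpsi/dI1 + dpsi/dI2) at the reference state
       = 2 (w1 + w2 w2* + w5 + w6 w6*),

    which reduces to the classical mu = 2 w1 + 2 w5 for Mooney-Rivlin-type
    weight vectors. Young's modulus follows as E = 3 mu for nu = 0.5.
    """
    w, e = weights.w, weights.wexp
    mu = 2.0 * (w[0] + w[1] * e[0] + w[4] + w[5] * e[2])
    return Modulus(mu=float(mu))
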