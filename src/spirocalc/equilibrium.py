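"""Four-species acid-base/spirocyclization speciation model.

Hydroxymethyl rhodamine (HMR) dyes interconvert between four ground-state
species: the fluorescent ring-opened form and the dark spirocyclic
ring-closed form, each in an acidic and a basic protonation state
(``O_A``, ``O_B``, ``C_A``, ``C_B``).  Three constants fix the whole
speciation diagram:

* ``ka_oh`` -- acid dissociation constant of the benzylic nucleophile in
  the open form (the benzyl-alcohol-like OH, or 0 for an aminomethyl
  nucleophile that is never deprotonated in water),
* ``ka_nh`` -- acid dissociation constant of the protonated xanthene
  aniline in the closed form,
* ``k_closure`` -- the open->closed equilibrium constant under acidic
  conditions, ``[C_A]/[O_A]``.

pK_cycl is the pH at which open and closed populations are equal (equivalently,
where the open-form signal is half-maximal); it has the closed form

    pK_cycl = -log10[(k_closure * ka_nh - ka_oh) / (1 - k_closure)]

whenever ``ka_oh/ka_nh < k_closure < 1``.  Outside that window one of the
two forms dominates at every pH and no finite pK_cycl exists; such regimes
are reported as typed flags, never as infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy.optimize import bisect

from .errors import InputError

__all__ = [
    "KA_OH_BENZYL",
    "KA_NH_PRIMARY",
    "KA_NH_ALKYL",
    "Definition",
    "EquilibriumConstants",
    "PkcyclResult",
    "Regime",
    "SpeciationProfile",
    "classify_regime",
    "closure_constant_from_pkcycl",
    "fraction_open",
    "pkcycl_closed_form",
    "pkcycl_numeric",
    "speciation_profile",
    "species_fractions",
]

#: Literature acid dissociation constants substituted into the model:
#: benzyl alcohol for the open-form OH, aniline / N-alkylaniline for the
#: closed-form anilinium.
KA_OH_BENZYL = 10.0 ** -15.4
KA_NH_PRIMARY = 10.0 ** -4.6  # both amines NH2
KA_NH_ALKYL = 10.0 ** -4.9  # mono- or dialkylated amines

_BRACKET = (-5.0, 25.0)
_XTOL = 1e-8


class Regime(str, Enum):
    """Qualitative behaviour of the open/closed balance over all pH."""

    CROSSING = "crossing"
    OPEN_EVERYWHERE = "open-dominant-everywhere"
    CLOSED_EVERYWHERE = "closed-dominant-everywhere"


class Definition(str, Enum):
    """Operational definition used to extract pK_cycl.

    ``CONCENTRATION_EQUALITY`` is the pH where open and closed populations
    are equal (the closed-form equation above).  ``HALF_OF_PLATEAU`` is the
    pH where the open fraction falls to half its acidic-plateau value
    ``1/(1 + k_closure)`` -- the literal "half of maximal signal" reading of a
    titration curve.  The two agree when ``k_closure << 1``.
    """

    CONCENTRATION_EQUALITY = "concentration-equality"
    HALF_OF_PLATEAU = "half-of-plateau"


@dataclass(frozen=True)
class EquilibriumConstants:
    """The three equilibrium constants of the four-species model.

    Parameters
    ----------
    ka_oh : float
        Acid dissociation constant (molar) of the benzylic nucleophile in
        the open form.  ``0`` encodes an aminomethyl nucleophile whose
        deprotonated open form is negligible in water.
    ka_nh : float
        Acid dissociation constant (molar) of the closed-form anilinium.
    k_closure : float
        Open->closed equilibrium constant ``[C_A]/[O_A]`` under acidic
        conditions (dimensionless).
    temperature : float, default 298.15
        Kelvin; carried for free-energy conversions.
    """

    ka_oh: float
    ka_nh: float
    k_closure: float
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("ka_oh", "ka_nh", "k_closure", "temperature"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InputError(f"{name} must be finite, got {v!r}")
        if self.ka_oh < 0:
            raise InputError(f"ka_oh must be >= 0, got {self.ka_oh}")
        if self.ka_nh <= 0:
            raise InputError(f"ka_nh must be > 0, got {self.ka_nh}")
        if self.k_closure < 0:
            raise InputError(f"k_closure must be >= 0, got {self.k_closure}")
        if self.temperature <= 0:
            raise InputError(f"temperature must be > 0 K, got {self.temperature}")

    @classmethod
    def for_hmr(
        cls,
        k_closure: float,
        *,
        primary_amines: bool = False,
        temperature: float = 298.15,
    ) -> "EquilibriumConstants":
        """Constants for a hydroxymethyl (OH-nucleophile) dye using the
        literature acid constants; ``primary_amines=True`` selects the
        NH2-amine anilinium pKa (4.6), otherwise the alkylated one (4.9)."""
        ka_nh = KA_NH_PRIMARY if primary_amines else KA_NH_ALKYL
        return cls(KA_OH_BENZYL, ka_nh, k_closure, temperature)

    @classmethod
    def for_amr(
        cls,
        k_closure: float,
        *,
        primary_amines: bool = False,
        temperature: float = 298.15,
    ) -> "EquilibriumConstants":
        """Constants for an aminomethyl dye: the benzylic amine is not
        deprotonated in water, so ``ka_oh = 0``."""
        ka_nh = KA_NH_PRIMARY if primary_amines else KA_NH_ALKYL
        return cls(0.0, ka_nh, k_closure, temperature)


@dataclass(frozen=True)
class PkcyclResult:
    """Outcome of a pK_cycl evaluation.

    ``value`` is finite exactly when ``regime == Regime.CROSSING``; in the
    dominant-everywhere regimes it is ``None``.
    """

    value: Optional[float]
    regime: Regime
    definition: Definition = Definition.CONCENTRATION_EQUALITY

    @property
    def is_finite(self) -> bool:
        return self.value is not None


def _check_ph(ph) -> np.ndarray:
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise InputError("pH values must be finite")
    return ph


def species_fractions(ph, constants: EquilibriumConstants) -> np.ndarray:
    """Equilibrium mole fractions ``(f_OA, f_OB, f_CA, f_CB)`` at ``ph``.

    Relative abundances follow from the three constants: taking ``O_A`` as
    reference, ``O_B`` scales as ``ka_oh/[H+]``, ``C_A`` as ``k_closure`` and
    ``C_B`` as ``k_closure*ka_nh/[H+]``.  Weights are multiplied through by
    ``[H+]`` before normalising so that strongly basic pH cannot overflow.

    Returns an array of shape ``ph.shape + (4,)`` summing to 1 along the
    last axis.
    """
    ph = _check_ph(ph)
    h = np.power(10.0, -ph)
    k = constants.k_closure
    w = np.stack(
        np.broadcast_arrays(
            h, np.full_like(h, constants.ka_oh), k * h, np.full_like(h, k * constants.ka_nh)
        ),
        axis=-1,
    )
    return w / w.sum(axis=-1, keepdims=True)


def fraction_open(ph, constants: EquilibriumConstants) -> np.ndarray:
    """Total open-form fraction ``f_OA + f_OB`` (the fluorescent population)."""
    ph = _check_ph(ph)
    h = np.power(10.0, -ph)
    open_w = h + constants.ka_oh
    closed_w = constants.k_closure * (h + constants.ka_nh)
    return open_w / (open_w + closed_w)


@dataclass(frozen=True)
class SpeciationProfile:
    """Species fractions tabulated on a pH grid."""

    ph: np.ndarray
    fractions: np.ndarray  # shape (n, 4): O_A, O_B, C_A, C_B
    constants: Optional[EquilibriumConstants] = field(default=None, compare=False)

    SPECIES = ("O_A", "O_B", "C_A", "C_B")

    @property
    def open_fraction(self) -> np.ndarray:
        return self.fractions[:, 0] + self.fractions[:, 1]

    def plot(self, ax=None):
        """Speciation diagram (fractions vs pH); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, name in enumerate(self.SPECIES):
            ax.plot(self.ph, self.fractions[:, i], label=name)
        ax.plot(self.ph, self.open_fraction, "k--", label="open total")
        ax.set_xlabel("pH")
        ax.set_ylabel("fraction")
        ax.legend()
        return ax


def speciation_profile(ph_grid, constants: EquilibriumConstants) -> SpeciationProfile:
    ph = _check_ph(ph_grid)
    return SpeciationProfile(ph, species_fractions(ph, constants), constants)


def classify_regime(constants: EquilibriumConstants) -> Regime:
    """Case analysis of the closed-form equation's positivity.

    A finite open/closed crossing exists iff
    ``ka_oh/ka_nh < k_closure < 1``; the boundaries belong to the
    dominant-everywhere regimes.
    """
    k = constants.k_closure
    if k >= 1.0:
        return Regime.CLOSED_EVERYWHERE
    if k * constants.ka_nh <= constants.ka_oh:
        return Regime.OPEN_EVERYWHERE
    return Regime.CROSSING


def pkcycl_closed_form(constants: EquilibriumConstants) -> PkcyclResult:
    """pK_cycl from the closed-form solution of open == closed.

    Solves ``[H+] + ka_oh = k_closure * ([H+] + ka_nh)`` for ``[H+]``:

        pK_cycl = -log10[(k_closure*ka_nh - ka_oh) / (1 - k_closure)]

    Degenerate regimes (no crossing) are returned as flags, not errors.
    """
    regime = classify_regime(constants)
    if regime is not Regime.CROSSING:
        return PkcyclResult(None, regime)
    h = (constants.k_closure * constants.ka_nh - constants.ka_oh) / (
        1.0 - constants.k_closure
    )
    return PkcyclResult(-math.log10(h), regime)


def pkcycl_numeric(
    constants: EquilibriumConstants,
    definition: Definition = Definition.CONCENTRATION_EQUALITY,
    bracket: tuple[float, float] = _BRACKET,
    xtol: float = _XTOL,
) -> PkcyclResult:
    """pK_cycl by bisection on the open-fraction curve.

    ``CONCENTRATION_EQUALITY`` finds the root of ``fraction_open = 1/2``;
    ``HALF_OF_PLATEAU`` finds where the open fraction drops to half of its
    acidic plateau ``1/(1 + k_closure)``.  ``fraction_open`` is monotone
    non-increasing in pH (for ``ka_nh > ka_oh``), so bisection on the
    default bracket of pH -5..25 is safe whenever a crossing exists.
    """
    definition = Definition(definition)
    if definition is Definition.CONCENTRATION_EQUALITY:
        target = 0.5
    else:
        target = 0.5 / (1.0 + constants.k_closure)

    lo, hi = bracket

    def g(ph: float) -> float:
        return float(fraction_open(ph, constants)) - target

    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        return PkcyclResult(lo, Regime.CROSSING, definition)
    if glo < 0.0:
        # open fraction already below target at the acidic end of the bracket
        return PkcyclResult(None, Regime.CLOSED_EVERYWHERE, definition)
    if ghi > 0.0:
        return PkcyclResult(None, Regime.OPEN_EVERYWHERE, definition)
    root = bisect(g, lo, hi, xtol=xtol)
    return PkcyclResult(float(root), Regime.CROSSING, definition)


def closure_constant_from_pkcycl(pkcycl: float, ka_oh: float, ka_nh: float) -> float:
    """Invert the closed-form pK_cycl equation for the closure constant.

    ``k_closure = ([H+] + ka_oh) / ([H+] + ka_nh)`` at ``[H+] = 10**-pkcycl``.
    The result lies in ``(ka_oh/ka_nh, 1)`` by construction, so feeding it
    back into :func:`pkcycl_closed_form` recovers ``pkcycl``.
    """
    if not math.isfinite(pkcycl):
        raise InputError(f"pkcycl must be finite, got {pkcycl!r}")
    if ka_nh <= 0:
        raise InputError(f"ka_nh must be > 0, got {ka_nh}")
    if ka_oh < 0:
        raise InputError(f"ka_oh must be >= 0, got {ka_oh}")
    h = 10.0 ** (-pkcycl)
    return (h + ka_oh) / (h + ka_nh)
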