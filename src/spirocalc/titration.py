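"""pH-titration simulation and fitting.

A titration of an HMR dye records a fluorescence (or absorbance) signal
proportional to the open-form population as the pH is stepped.  This module
simulates such curves, fits them with either the mechanistic four-species
speciation model (closure constant free, literature acid constants fixed)
or a generic Hill sigmoid, and extracts pK_cycl operationally as the pH at
which the fitted open-form signal is half of its maximum.  Uncertainty
comes from a residual-resampling bootstrap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .equilibrium import (
    Definition,
    EquilibriumConstants,
    Regime,
    fraction_open,
    pkcycl_numeric,
)
from .errors import FitError, InputError

__all__ = [
    "TitrationCurve",
    "FitResult",
    "TitrationModel",
    "simulate_titration",
    "fit_pkcycl",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class TitrationCurve:
    """Paired pH / normalized-signal arrays.

    ``noise_sigma`` records the Gaussian noise level used in simulation
    (0 for measured data); ``seed`` the simulation seed, if any.
    """

    ph: np.ndarray
    signal: np.ndarray
    noise_sigma: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "signal", signal)
        if ph.ndim != 1 or signal.ndim != 1 or len(ph) != len(signal):
            raise InputError("pH and signal must be 1-D arrays of equal length")
        if len(ph) < 6:
            raise InputError(f"need at least 6 titration points, got {len(ph)}")
        if not np.all(np.diff(ph) > 0):
            raise InputError("pH values must be strictly increasing")
        if self.noise_sigma < 0:
            raise InputError("noise_sigma must be >= 0")

    @classmethod
    def from_csv(cls, source: Union[str, Path, IO[str]]) -> "TitrationCurve":
        df = pd.read_csv(source)
        cols = {c.lower(): c for c in df.columns}
        if "ph" not in cols or "signal" not in cols:
            raise InputError("titration CSV needs 'pH' and 'signal' columns")
        return cls(df[cols["ph"]].to_numpy(float), df[cols["signal"]].to_numpy(float))

    def to_csv(self, target: Union[str, Path, IO[str]]) -> None:
        pd.DataFrame({"pH": self.ph, "signal": self.signal}).to_csv(target, index=False)

    def plot(self, ax=None, fit: Optional["FitResult"] = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ph, self.signal, "o", label="data")
        if fit is not None:
            grid = np.linspace(self.ph[0], self.ph[-1], 200)
            ax.plot(grid, fit.predict(grid), "-", label=f"{fit.model} fit")
            if fit.pkcycl_hat is not None:
                ax.axvline(fit.pkcycl_hat, ls=":", color="gray")
        ax.set_xlabel("pH")
        ax.set_ylabel("normalized signal")
        ax.legend()
        return ax


def _hill(ph, pkcycl, slope, amplitude, baseline):
    return baseline + amplitude / (1.0 + np.power(10.0, slope * (ph - pkcycl)))


def simulate_titration(
    params,
    ph,
    noise_sigma: float = 0.0,
    seed: Optional[int] = None,
    model: str = "speciation",
    slope: float = 1.0,
) -> TitrationCurve:
    """Generate a titration curve.

    ``model="speciation"``: ``params`` is an :class:`EquilibriumConstants`
    and the noiseless signal is the open-form fraction.
    ``model="hill"``: ``params`` is the midpoint pK_cycl (with ``slope``)
    and the signal is ``1/(1 + 10**(slope*(pH - pkcycl)))``.
    Gaussian noise of sd ``noise_sigma`` is added i.i.d.; a fixed ``seed``
    reproduces the curve exactly.
    """
    ph = np.asarray(ph, dtype=float)
    if noise_sigma < 0:
        raise InputError("noise_sigma must be >= 0")
    if model == "speciation":
        if not isinstance(params, EquilibriumConstants):
            raise InputError("speciation model requires EquilibriumConstants")
        clean = fraction_open(ph, params)
    elif model == "hill":
        clean = _hill(ph, float(params), slope, 1.0, 0.0)
    else:
        raise InputError(f"unknown titration model {model!r}")
    noise = 0.0
    if noise_sigma > 0:
        noise = np.random.default_rng(seed).normal(0.0, noise_sigma, size=ph.shape)
    return TitrationCurve(ph, clean + noise, noise_sigma=noise_sigma, seed=seed)


@dataclass(frozen=True)
class FitResult:
    """Titration fit: point estimates, optional bootstrap CI, diagnostics.

    ``pkcycl_hat`` is extracted from the fitted curve as the pH where the
    open-form signal (above baseline) is half of its maximum, found by
    root-finding on the fitted model rather than read off a raw parameter.
    For the speciation model ``k_closure_hat`` is the fitted closure
    constant; for the Hill model ``slope_hat`` is the Hill slope.
    """

    model: str
    pkcycl_hat: Optional[float]
    amplitude_hat: float
    baseline_hat: float
    converged: bool
    k_closure_hat: Optional[float] = None
    slope_hat: Optional[float] = None
    constants: Optional[EquilibriumConstants] = None
    ci: Optional[Tuple[float, float]] = None
    regime: Regime = Regime.CROSSING
    residual_sd: float = math.nan
    n_points: int = 0

    def predict(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        if self.model == "speciation":
            return self.baseline_hat + self.amplitude_hat * fraction_open(ph, self.constants)
        return _hill(ph, self.pkcycl_hat, self.slope_hat, self.amplitude_hat, self.baseline_hat)

    def summary(self) -> str:
        lines = [
            f"Titration fit ({self.model} model, n={self.n_points})",
            "-" * 44,
            f"pKcycl          {self.pkcycl_hat:.4f}" if self.pkcycl_hat is not None
            else f"pKcycl          none ({self.regime.value})",
        ]
        if self.ci is not None:
            lines.append(f"95% bootstrap CI [{self.ci[0]:.4f}, {self.ci[1]:.4f}]")
        if self.k_closure_hat is not None:
            lines.append(f"K(open->closed) {self.k_closure_hat:.4e}")
        if self.slope_hat is not None:
            lines.append(f"Hill slope      {self.slope_hat:.4f}")
        lines += [
            f"amplitude       {self.amplitude_hat:.4f}",
            f"baseline        {self.baseline_hat:.4f}",
            f"residual sd     {self.residual_sd:.4g}",
            f"converged       {self.converged}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "pkcycl_hat": self.pkcycl_hat,
            "ci95": list(self.ci) if self.ci is not None else None,
            "k_closure_hat": self.k_closure_hat,
            "slope_hat": self.slope_hat,
            "amplitude_hat": self.amplitude_hat,
            "baseline_hat": self.baseline_hat,
            "regime": self.regime.value,
            "residual_sd": None if math.isnan(self.residual_sd) else self.residual_sd,
            "converged": self.converged,
            "n_points": self.n_points,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _halfway_start(ph: np.ndarray, signal: np.ndarray) -> float:
    """pH at the half-range crossing of the raw signal (linear interpolation);
    the optimizer's starting midpoint."""
    half = 0.5 * (signal.max() + signal.min())
    below = np.nonzero(signal <= half)[0]
    above = np.nonzero(signal >= half)[0]
    if len(below) == 0 or len(above) == 0:
        return float(ph[len(ph) // 2])
    # signal decreases with pH: first index at/below the half level
    i = below[0]
    if i == 0:
        return float(ph[0])
    x0, x1 = ph[i - 1], ph[i]
    y0, y1 = signal[i - 1], signal[i]
    if y0 == y1:
        return float(x1)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


class TitrationModel:
    """Statsmodels-style front end: build from a curve, ``fit()`` returns a
    :class:`FitResult`.

    Parameters
    ----------
    curve : TitrationCurve
    model : {"speciation", "hill"}
        Mechanistic four-species model (closure constant free, acid
        constants fixed) or generic Hill sigmoid.
    ka_oh, ka_nh : float
        Fixed acid dissociation constants for the speciation model.
    """

    def __init__(
        self,
        curve: TitrationCurve,
        model: str = "speciation",
        ka_oh: float = 10.0 ** -15.4,
        ka_nh: float = 10.0 ** -4.9,
        temperature: float = 298.15,
    ) -> None:
        if model not in ("speciation", "hill"):
            raise InputError(f"unknown titration model {model!r}")
        self.curve = curve
        self.model = model
        self.ka_oh = ka_oh
        self.ka_nh = ka_nh
        self.temperature = temperature

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TitrationModel":
        cols = {c.lower(): c for c in df.columns}
        return cls(
            TitrationCurve(df[cols["ph"]].to_numpy(float), df[cols["signal"]].to_numpy(float)),
            **kwargs,
        )

    # -- internals -------------------------------------------------------

    def _fit_arrays(self, ph: np.ndarray, signal: np.ndarray) -> FitResult:
        n_params = 3 if self.model == "speciation" else 4
        if len(ph) <= n_params:
            raise FitError(f"{len(ph)} points cannot constrain {n_params} parameters")
        amp0 = float(signal.max() - signal.min()) or 1.0
        base0 = float(signal.min())
        pk0 = _halfway_start(ph, signal)
        converged = True
        try:
            if self.model == "speciation":
                k0 = (10.0 ** -pk0 + self.ka_oh) / (10.0 ** -pk0 + self.ka_nh)

                def f(x, log10_k, amplitude, baseline):
                    c = EquilibriumConstants(
                        self.ka_oh, self.ka_nh, 10.0 ** log10_k, self.temperature
                    )
                    return baseline + amplitude * fraction_open(x, c)

                popt, _ = curve_fit(
                    f, ph, signal, p0=[math.log10(k0), amp0, base0], maxfev=20000
                )
                log10_k, amplitude, baseline = popt
                constants = EquilibriumConstants(
                    self.ka_oh, self.ka_nh, 10.0 ** log10_k, self.temperature
                )
                half = pkcycl_numeric(constants, Definition.HALF_OF_PLATEAU)
                result = FitResult(
                    model="speciation",
                    pkcycl_hat=half.value,
                    amplitude_hat=float(amplitude),
                    baseline_hat=float(baseline),
                    converged=converged,
                    k_closure_hat=float(10.0 ** log10_k),
                    constants=constants,
                    regime=half.regime,
                    n_points=len(ph),
                )
            else:

                popt, _ = curve_fit(
                    _hill, ph, signal, p0=[pk0, 1.0, amp0, base0], maxfev=20000
                )
                pk, slope, amplitude, baseline = popt
                # half-of-maximum root of the fitted sigmoid; analytically the
                # midpoint parameter, recovered here from the curve itself
                from scipy.optimize import brentq

                pk_half = brentq(
                    lambda x: _hill(x, pk, slope, 1.0, 0.0) - 0.5, pk - 12, pk + 12
                )
                result = FitResult(
                    model="hill",
                    pkcycl_hat=float(pk_half),
                    amplitude_hat=float(amplitude),
                    baseline_hat=float(baseline),
                    converged=converged,
                    slope_hat=float(slope),
                    n_points=len(ph),
                )
        except RuntimeError as exc:  # curve_fit non-convergence
            raise FitError(f"titration fit did not converge: {exc}") from exc
        resid = signal - result.predict(ph)
        return replace(result, residual_sd=float(np.std(resid, ddof=min(n_params, len(ph) - 1))))

    def fit(self) -> FitResult:
        return self._fit_arrays(self.curve.ph, self.curve.signal)

    def fit_bootstrap(
        self, n_boot: int = 1000, seed: Optional[int] = None
    ) -> FitResult:
        """Fit, then attach a residual-resampling 95% percentile interval."""
        base = self.fit()
        ci = bootstrap_ci(self.curve, model=self.model, n_boot=n_boot, seed=seed,
                          ka_oh=self.ka_oh, ka_nh=self.ka_nh, _base=base)
        lo = min(ci[0], base.pkcycl_hat)
        hi = max(ci[1], base.pkcycl_hat)
        return replace(base, ci=(lo, hi))


def fit_pkcycl(
    curve: TitrationCurve,
    model: str = "speciation",
    ka_oh: float = 10.0 ** -15.4,
    ka_nh: float = 10.0 ** -4.9,
    temperature: float = 298.15,
) -> FitResult:
    """Nonlinear least-squares fit of a titration curve (functional
    wrapper around :class:`TitrationModel`)."""
    return TitrationModel(curve, model=model, ka_oh=ka_oh, ka_nh=ka_nh,
                          temperature=temperature).fit()


def bootstrap_ci(
    curve: TitrationCurve,
    model: str = "speciation",
    n_boot: int = 1000,
    seed: Optional[int] = None,
    ka_oh: float = 10.0 ** -15.4,
    ka_nh: float = 10.0 ** -4.9,
    temperature: float = 298.15,
    _base: Optional[FitResult] = None,
) -> Tuple[float, float]:
    """Residual-resampling bootstrap 95% percentile interval for pK_cycl.

    Residuals of the point fit are resampled with replacement, added back
    to the fitted curve and refitted ``n_boot`` times.  Replicates whose
    fits diverge are dropped; more than 20% divergent replicates is an
    error.
    """
    m = TitrationModel(curve, model=model, ka_oh=ka_oh, ka_nh=ka_nh,
                       temperature=temperature)
    base = _base if _base is not None else m.fit()
    if base.pkcycl_hat is None:
        raise FitError(f"no finite pKcycl to bootstrap (regime {base.regime.value})")
    fitted = base.predict(curve.ph)
    resid = curve.signal - fitted
    rng = np.random.default_rng(seed)
    estimates = []
    failures = 0
    for _ in range(n_boot):
        sample = fitted + rng.choice(resid, size=len(resid), replace=True)
        try:
            rep = m._fit_arrays(curve.ph, sample)
            if rep.pkcycl_hat is None:
                raise FitError("replicate lost the crossing regime")
            estimates.append(rep.pkcycl_hat)
        except FitError:
            failures += 1
    if failures > 0.2 * n_boot:
        raise FitError(
            f"{failures}/{n_boot} bootstrap replicates failed to converge"
        )
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)
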