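"""Benchmark comparison, probe-design screening, and the end-to-end
pK_cycl prediction pipeline (free energies -> closure constant -> pH
crossing)."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .equilibrium import (
    Definition,
    EquilibriumConstants,
    Regime,
    pkcycl_numeric,
)
from .errors import InputError
from .qcio import BenchmarkEntry
from .thermo import (
    EnsembleMode,
    FreeEnergyDifference,
    SpeciesRecord,
    assemble_delta_g,
    closure_constant_from_delta_g,
)

__all__ = [
    "ComparisonReport",
    "ComparisonRow",
    "DesignCandidate",
    "PredictionReport",
    "compare_benchmark",
    "predict_from_delta_g",
    "predict_pipeline",
    "screen_candidates",
]

#: Probe-design window: a useful fluorogenic scaffold is dark at
#: physiological pH while protected (pK_cycl < 5.5) and bright once the
#: enzyme removes the protecting group (pK_cycl > 8.5).
FREE_THRESHOLD = 8.5
PROTECTED_THRESHOLD = 5.5


@dataclass(frozen=True)
class ComparisonRow:
    name: str
    measured: float
    calculated: float
    abs_error: float  # always recomputed |measured - calculated|


@dataclass(frozen=True)
class ComparisonReport:
    """Measured-vs-calculated comparison with recomputed error statistics."""

    rows: List[ComparisonRow]
    n_skipped: int = 0

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def mean_abs_error(self) -> float:
        return float(np.mean([r.abs_error for r in self.rows]))

    @property
    def max_abs_error(self) -> float:
        return float(np.max([r.abs_error for r in self.rows]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.rows],
                "measured": [r.measured for r in self.rows],
                "calculated": [r.calculated for r in self.rows],
                "abs_error": [r.abs_error for r in self.rows],
            }
        )

    def summary(self) -> str:
        lines = [f"{'dye':<12}{'measured':>9}{'calc':>7}{'|err|':>7}"]
        for r in self.rows:
            lines.append(
                f"{r.name:<12}{r.measured:>9.1f}{r.calculated:>7.1f}{round(r.abs_error, 1):>7.1f}"
            )
        lines.append(
            f"n={self.n}  MAE={self.mean_abs_error:.2f}  max|err|={self.max_abs_error:.2f}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "rows": [
                {
                    "name": r.name,
                    "measured": r.measured,
                    "calculated": r.calculated,
                    "abs_error": r.abs_error,
                }
                for r in self.rows
            ],
            "summary": {
                "n": self.n,
                "mean_abs_error": self.mean_abs_error,
                "max_abs_error": self.max_abs_error,
            },
            "n_skipped": self.n_skipped,
        }


def compare_benchmark(entries: Sequence[BenchmarkEntry]) -> ComparisonReport:
    """Compare measured against calculated pK_cycl across dyes.

    Absolute errors are recomputed from the two value columns — the
    published error column is never copied.  Entries lacking either value
    (e.g. substituent-grid positions that were only calculated) are
    skipped and counted in ``n_skipped``.
    """
    if not entries:
        raise InputError("compare_benchmark requires at least one entry")
    rows, skipped = [], 0
    for e in entries:
        if e.measured_pkcycl is None or e.calculated_pkcycl is None:
            skipped += 1
            continue
        rows.append(
            ComparisonRow(
                e.name,
                e.measured_pkcycl,
                e.calculated_pkcycl,
                abs(e.measured_pkcycl - e.calculated_pkcycl),
            )
        )
    if not rows:
        raise InputError("no entries carry both a measured and a calculated value")
    return ComparisonReport(rows, n_skipped=skipped)


@dataclass(frozen=True)
class DesignCandidate:
    """A candidate fluorophore judged against the probe-design window.

    ``pkcycl_free`` is the value after enzymatic hydrolysis (the bright
    product must stay open at physiological pH); ``pkcycl_protected`` the
    value with the amino-acid or acetyl cap (the probe must stay closed and
    dark)."""

    name: str
    pkcycl_free: float
    pkcycl_protected: float
    passes: Optional[bool] = None


def screen_candidates(
    candidates: Sequence[DesignCandidate],
    free_threshold: float = FREE_THRESHOLD,
    protected_threshold: float = PROTECTED_THRESHOLD,
) -> List[DesignCandidate]:
    """Apply the design window with strict inequalities:
    pass iff ``pkcycl_free > free_threshold`` and
    ``pkcycl_protected < protected_threshold``."""
    out = []
    for c in candidates:
        if not (math.isfinite(c.pkcycl_free) and math.isfinite(c.pkcycl_protected)):
            raise InputError(f"candidate {c.name!r} has non-finite pKcycl values")
        out.append(
            replace(
                c,
                passes=(c.pkcycl_free > free_threshold)
                and (c.pkcycl_protected < protected_threshold),
            )
        )
    return out


@dataclass(frozen=True)
class PredictionReport:
    """Everything a pK_cycl prediction run produced, with provenance."""

    delta_g: FreeEnergyDifference
    k_closure: float
    constants: EquilibriumConstants
    regime: Regime
    pkcycl_equality: Optional[float]
    pkcycl_half_plateau: Optional[float]
    provenance: dict

    @property
    def pkcycl(self) -> Optional[float]:
        """Default reading: the concentration-equality crossing."""
        return self.pkcycl_equality

    def to_dict(self) -> dict:
        return {
            "delta_g_kj_per_mol": self.delta_g.delta_g,
            "temperature_K": self.delta_g.temperature,
            "n_waters": self.delta_g.n_waters,
            "sign_convention": "delta_g = G(closed_acidic) - G(open_acidic)",
            "k_closure": self.k_closure,
            "ka_oh": self.constants.ka_oh,
            "ka_nh": self.constants.ka_nh,
            "regime": self.regime.value,
            "pkcycl": self.pkcycl_equality,
            "pkcycl_half_of_plateau": self.pkcycl_half_plateau,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def summary(self) -> str:
        pk = "none" if self.pkcycl_equality is None else f"{self.pkcycl_equality:.2f}"
        return (
            f"dG(closed-open) = {self.delta_g.delta_g:.3f} kJ/mol @ "
            f"{self.delta_g.temperature:.2f} K\n"
            f"K(open->closed) = {self.k_closure:.4e}\n"
            f"regime          = {self.regime.value}\n"
            f"pKcycl          = {pk}"
        )


def predict_from_delta_g(
    delta_g: FreeEnergyDifference,
    ka_oh: float,
    ka_nh: float,
    provenance: Optional[dict] = None,
) -> PredictionReport:
    """Free-energy difference -> closure constant -> pK_cycl (both
    operational definitions), with regime classification."""
    k = closure_constant_from_delta_g(delta_g)
    constants = EquilibriumConstants(ka_oh, ka_nh, k, delta_g.temperature)
    eq = pkcycl_numeric(constants, Definition.CONCENTRATION_EQUALITY)
    half = pkcycl_numeric(constants, Definition.HALF_OF_PLATEAU)
    return PredictionReport(
        delta_g=delta_g,
        k_closure=k,
        constants=constants,
        regime=eq.regime,
        pkcycl_equality=eq.value,
        pkcycl_half_plateau=half.value,
        provenance=provenance or {},
    )


def predict_pipeline(
    species: Sequence[SpeciesRecord],
    ka_oh: float = 10.0 ** -15.4,
    ka_nh: float = 10.0 ** -4.9,
    ensemble_mode: str = "min",
    temperature: float = 298.15,
    provenance: Optional[dict] = None,
) -> PredictionReport:
    """End-to-end prediction from computed structures.

    Splits the records into open-acidic and closed-acidic ensembles (an
    optional lone-water record provides the balancing reference when the
    two carry different explicit-water counts), assembles
    dG = G(closed) - G(open), and converts it to a pK_cycl prediction.
    """
    species = list(species)
    open_records = [r for r in species if r.form.value == "open_acidic"]
    closed_records = [r for r in species if r.form.value == "closed_acidic"]
    waters = [r for r in species if r.form.value == "water"]
    if not open_records or not closed_records:
        raise InputError(
            f"need at least one open_acidic and one closed_acidic record "
            f"(got {len(open_records)} open, {len(closed_records)} closed)"
        )
    water_reference = waters[0] if waters else None
    dg = assemble_delta_g(
        open_records,
        closed_records,
        mode=EnsembleMode(ensemble_mode),
        water_reference=water_reference,
        temperature=temperature,
    )
    prov = dict(provenance or {})
    prov.update(
        {
            "ensemble_mode": EnsembleMode(ensemble_mode).value,
            "n_open_structures": len(open_records),
            "n_closed_structures": len(closed_records),
            "water_reference": water_reference.label if water_reference else None,
            "open_waters": open_records[0].n_waters,
            "closed_waters": closed_records[0].n_waters,
        }
    )
    return predict_from_delta_g(dg, ka_oh, ka_nh, provenance=prov)
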