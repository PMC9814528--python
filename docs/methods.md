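# Methods

## The four-species equilibrium

The model assumes exactly four species: open and closed forms, each in an
acidic and basic protonation state. Relative abundances at proton
activity h = 10^−pH, taking the acidic open form O_A as reference, are

    w(O_A) = 1,  w(O_B) = K_aOH/h,  w(C_A) = K_A,  w(C_B) = K_A·K_aNH/h.

Internally the weights are multiplied through by h before normalising, so
strongly basic pH cannot overflow. Further protonation states (e.g. a
xanthene dication in strong acid) are deliberately outside the model.

Setting open = closed gives h·(1 − K_A) = K_A·K_aNH − K_aOH, hence the
closed-form pK_cycl above, finite iff K_aOH/K_aNH < K_A < 1. Boundary
cases are assigned to the dominant-everywhere regimes, and degenerate
regimes are returned as typed flags (`Regime`) rather than ±inf so report
code can never silently propagate non-finite numbers.

Because the open fraction

    f_open(pH) = (h + K_aOH) / [(h + K_aOH) + K_A·(h + K_aNH)]

has derivative proportional to K_A·(K_aNH − K_aOH) ≥ 0 in h, it is
monotone non-increasing in pH whenever the anilinium is more acidic than
the benzylic OH — which holds for every chemically sensible parameter set
— so bisection on a pH ∈ [−5, 25] bracket (absolute tolerance 1e−8) is a
safe, independent route to the same crossing. The package carries both
routes and the test suite holds them to 1e−6 agreement over random
constants.

### Two operational definitions

`CONCENTRATION_EQUALITY` (default) is the crossing of open and closed
populations — the closed-form equation. `HALF_OF_PLATEAU` is the pH where
f_open falls to half its acidic-plateau value 1/(1+K_A) — the literal
"half of the maximal signal" reading of a titration curve. They coincide
for K_A ≪ 1 (all benchmark dyes; difference ~1e−5 pH at K_A = 2.5e−5)
but diverge when K_A approaches 1, where the half-of-plateau value is
strictly larger. Both are computed and reported; keeping the discrepancy
visible was preferred to hiding it behind a single number.

## Constants and units

Literature substitutions: K_aOH = 10^−15.4 (benzyl alcohol),
K_aNH = 10^−4.6 for NH₂ amines and 10^−4.9 for mono- or dialkylated
amines (aniline / N,N-dimethylaniline). For asymmetric dyes with one H
and one alkyl substituent the alkylated constant is used; the benchmark
fixture records the per-dye assumption. For aminomethyl (AMR) dyes the
benzylic amine is essentially never deprotonated in water, encoded as
K_aOH = 0 exactly.

Physical constants are pinned for bit-stable arithmetic:
R = 8.314462618 J mol⁻¹ K⁻¹, k_B = 1.380649e−23 J K⁻¹,
h = 6.62607015e−34 J s, 1 hartree = 2625.4996 kJ/mol. The ΔG sign
convention is fixed package-wide as closed − open (acidic forms), so
K_A = exp(−ΔG/RT), and every prediction report states it. Default
temperature 298.15 K.

## Free-energy assembly

Candidate hydration structures of one form (same explicit-water count)
are reduced to an effective G either by taking the minimum (default —
the most-stable-structure practice) or Boltzmann weighting
−RT·ln Σ exp(−G_i/RT), which is always ≤ the minimum. Mixing forms or
water counts inside one ensemble is a stoichiometry error. When open and
closed complexes carry different explicit-water counts, the deficient
side is topped up with (difference) × G(water) from a supplied lone-water
record; without one, the mismatch is an error naming both counts. Species
tables serialize energies with 6 decimal places in hartree (≈2.6 J/mol),
far below the ≈0.57 kJ/mol that moves pK_cycl by 0.1 unit.

The QM-log reader extracts one number per structure — the value after the
last `Sum of electronic and thermal Free Energies=` line (the last wins
so re-optimized logs report the final structure). Structure role and
water count are metadata the caller supplies (species table or CLI
flags); they are never guessed from filenames. Full electronic-structure
parsing is out of scope: the thermodynamic model needs only G.

The Eyring helper uses transmission coefficient 1; at 298.15 K the
prefactor k_BT/h is 6.212e12 s⁻¹, and a 28.7 kJ/mol ring-opening barrier
maps to ~5.8e7 s⁻¹ — the quantitative content behind "ring opening is
spontaneous at room temperature".

## Titration simulation and fitting

The simulator draws signal = f_open(pH) (speciation model) or a Hill
sigmoid 1/(1 + 10^{slope·(pH−pK)}), plus i.i.d. homoscedastic Gaussian
noise (default σ chosen as 0.02, a typical residual scatter for
normalized plate-reader titrations); curves are reproducible under a
fixed seed. Heteroscedastic noise is out of scope. The generator emulates
an idealized single-dye titration — it does not model inner-filter
effects, absorbance/fluorescence differences, pH-electrode error, or
replicate structure — so recovery tests show estimator correctness under
the stated noise model, not robustness to those real-data effects.

Fitting is nonlinear least squares (scipy `curve_fit`). Two model
families: the mechanistic speciation model with acid constants fixed to
their literature values and (log₁₀K_A, amplitude, baseline) free — the
log parameterization keeps the optimizer well-conditioned — and a generic
4-parameter Hill sigmoid for data of unknown mechanism (the benchmark's
measured values were published without a stated fit family, so the Hill
default there is this package's decision). Amplitude and baseline are
free nuisance parameters because raw fluorescence is not normalized a
priori. Starting values: midpoint from the half-range crossing of the raw
signal by linear interpolation, slope 1, amplitude/baseline from the
signal range. The reported pK_cycl is extracted from the *fitted curve*
as the pH at half of the fitted maximum (for the speciation model, the
half-of-plateau root of the fitted constants), not read off a raw
parameter. Non-convergence raises a typed error, never a silent result.

Uncertainty: residual-resampling bootstrap (default 1000 replicates,
seeded), 95% percentile interval, with >20% divergent replicates treated
as failure; the interval is widened to include the point estimate if a
finite-sample percentile excludes it.

Monte-Carlo sizes used in the test suite — 200 replicates for recovery
and coverage with 300 bootstrap resamples each, 33-point pH 4–12 grids —
were chosen as the package's own benchmark of estimator quality; at these
sizes the mean absolute recovery error at σ = 0.02 is comfortably below
0.05 pH units and bootstrap coverage is ≥ 90%.

## Benchmark fixtures

Three packaged CSVs transcribe the published comparison tables digit for
digit: the 17-dye main benchmark, the benzene-ring substituent grid
(F/Me/CF₃ at positions 3′–6′, measured values existing only at 3′ and,
for Me, 5′), and the two designed fluorophores (HMRR measured 8.4 vs
predicted 8.6; HMRY 9.2 vs 9.0). For the NH₂-amine dyes HMRG and AMRG
the prediction column stores the 5-explicit-water values (7.9, 6.2) that
the method needs for N–H-bearing amines, with the plain 3-water-bridge
values (11.3, 10.1) kept in an auxiliary column. Comparison reports
always recompute |measured − calculated| — the published error column is
retained for provenance only. One published row (HMJSiR: 6.6 / 7.1 /
error 0.4) is internally inconsistent, since |6.6 − 7.1| = 0.5; the
fixture transcribes it verbatim and flags it in its footnote, and the
corresponding strict reproduction test is left failing rather than
widened.

## Design screening

The probe-design window — pK_cycl > 8.5 for the free (hydrolysed)
fluorophore and < 5.5 for the amino-acid/acetyl-protected form — uses
strict inequalities and configurable thresholds (`--free-min`,
`--protected-max`). It guarantees a dark probe and bright product at
physiological pH; the relation between the pK_cycl gap and fold
activation is not modelled.

## Known limitations

- Only the four species of the scheme; multiprotic extensions and
  ring-opening/closing kinetics (beyond the single Eyring evaluation) are
  out of scope.
- Predictions are only as good as the supplied free energies; the package
  performs no electronic-structure computation and no generation of
  hydrated geometries.
- The half-of-plateau and concentration-equality definitions diverge for
  K_A ≳ 0.1; users comparing to absorbance titrations of strongly
  closed dyes should state which definition they report.
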