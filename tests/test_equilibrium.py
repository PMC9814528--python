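"""Four-species speciation model: fractions, regimes, and the two pK_cycl
routes (closed form vs independent bisection oracle)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spirocalc import (
    Definition,
    EquilibriumConstants,
    InputError,
    Regime,
    classify_regime,
    closure_constant_from_pkcycl,
    fraction_open,
    pkcycl_closed_form,
    pkcycl_numeric,
    speciation_profile,
    species_fractions,
)

KA_OH = 10.0 ** -15.4
KA_NH_PRIMARY = 10.0 ** -4.6
KA_NH_ALKYL = 10.0 ** -4.9


def brute_fraction_open(ph: float, ka_oh: float, ka_nh: float, k: float) -> float:
    """Independent oracle: species weights written out from the scheme
    (O_A reference), no shared code with the implementation."""
    h = 10.0 ** -ph
    w_oa = 1.0
    w_ob = ka_oh / h
    w_ca = k
    w_cb = k * ka_nh / h
    return (w_oa + w_ob) / (w_oa + w_ob + w_ca + w_cb)


def brute_pkcycl(ka_oh: float, ka_nh: float, k: float, tol: float = 1e-12) -> float:
    """Plain bisection of brute_fraction_open == 1/2 on pH in [-5, 25]."""
    lo, hi = -5.0, 25.0
    flo = brute_fraction_open(lo, ka_oh, ka_nh, k) - 0.5
    fhi = brute_fraction_open(hi, ka_oh, ka_nh, k) - 0.5
    assert flo > 0 > fhi, "no crossing in bracket"
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if brute_fraction_open(mid, ka_oh, ka_nh, k) - 0.5 > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------- fractions


def test_acidic_limit_partitions_between_the_two_acidic_forms():
    c = EquilibriumConstants(KA_OH, KA_NH_ALKYL, 0.3)
    f = species_fractions(-10.0, c)
    assert f[0] == pytest.approx(1 / 1.3, abs=1e-12)
    assert f[2] == pytest.approx(0.3 / 1.3, abs=1e-12)
    assert f[1] == pytest.approx(0.0, abs=1e-12)
    assert f[3] == pytest.approx(0.0, abs=1e-12)


def test_fractions_sum_to_one_on_a_grid(hmtmr_constants):
    ph = np.linspace(-5, 25, 301)
    f = species_fractions(ph, hmtmr_constants)
    assert f.shape == (301, 4)
    np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-12)


@settings(deadline=None, max_examples=100)
@given(
    ph=st.floats(-5, 25),
    pk_oh=st.floats(10, 16),
    pk_nh=st.floats(3, 6),
    log_k=st.floats(-8, 1),
)
def test_fractions_sum_to_one_for_random_constants(ph, pk_oh, pk_nh, log_k):
    c = EquilibriumConstants(10.0 ** -pk_oh, 10.0 ** -pk_nh, 10.0 ** log_k)
    f = species_fractions(ph, c)
    assert np.all(f >= 0)
    assert f.sum() == pytest.approx(1.0, abs=1e-12)


def test_open_fraction_half_at_measured_crossing(hmtmr_constants):
    """With the closure constant inverted from the measured crossing pH
    of 9.5, the open fraction is exactly one half there."""
    f = species_fractions(9.5, hmtmr_constants)
    assert f[0] + f[1] == pytest.approx(0.5, abs=1e-9)
    assert fraction_open(9.5, hmtmr_constants) == pytest.approx(0.5, abs=1e-9)


def test_fraction_open_matches_sum_of_open_fractions(hmtmr_constants):
    ph = np.linspace(0, 14, 57)
    f = species_fractions(ph, hmtmr_constants)
    np.testing.assert_allclose(
        fraction_open(ph, hmtmr_constants), f[:, 0] + f[:, 1], atol=1e-14
    )


def test_fraction_open_is_one_without_closed_form():
    c = EquilibriumConstants(KA_OH, KA_NH_ALKYL, 0.0)
    assert float(fraction_open(7.0, c)) == 1.0


def test_basic_limit_favors_closed_form():
    c = EquilibriumConstants(KA_OH, KA_NH_ALKYL, 1e-3)
    assert float(fraction_open(25.0, c)) < 0.5


@settings(deadline=None, max_examples=50)
@given(
    pk_oh=st.floats(10, 16),
    pk_nh=st.floats(3, 6),
    log_k=st.floats(-8, 1),
)
def test_fraction_open_monotone_nonincreasing(pk_oh, pk_nh, log_k):
    """Whenever the anilinium is more acidic than the benzylic OH, raising
    the pH can only shift population toward the closed forms."""
    c = EquilibriumConstants(10.0 ** -pk_oh, 10.0 ** -pk_nh, 10.0 ** log_k)
    ph = np.linspace(0, 14, 561)
    f = fraction_open(ph, c)
    assert np.all(np.diff(f) <= 1e-15)


def test_nonfinite_ph_rejected(hmtmr_constants):
    with pytest.raises(InputError):
        fraction_open(float("nan"), hmtmr_constants)
    with pytest.raises(InputError):
        species_fractions(float("inf"), hmtmr_constants)


def test_invalid_constants_rejected():
    with pytest.raises(InputError):
        EquilibriumConstants(-1e-16, KA_NH_ALKYL, 0.1)
    with pytest.raises(InputError):
        EquilibriumConstants(KA_OH, 0.0, 0.1)
    with pytest.raises(InputError):
        EquilibriumConstants(KA_OH, KA_NH_ALKYL, -0.1)
    with pytest.raises(InputError):
        EquilibriumConstants(KA_OH, KA_NH_ALKYL, 0.1, temperature=0.0)


# ---------------------------------------------------------------- regimes


@pytest.mark.parametrize(
    "k,expected",
    [
        (0.0, Regime.OPEN_EVERYWHERE),
        (2.0, Regime.CLOSED_EVERYWHERE),
        (1.0, Regime.CLOSED_EVERYWHERE),  # boundary to the dominant class
        (10.0 ** -4.6, Regime.CROSSING),
        (KA_OH / KA_NH_ALKYL, Regime.OPEN_EVERYWHERE),  # boundary
    ],
)
def test_classify_regime(k, expected):
    c = EquilibriumConstants(KA_OH, KA_NH_ALKYL, k)
    assert classify_regime(c) is expected


def test_degenerate_regimes_have_no_value():
    for k, regime in [(0.0, Regime.OPEN_EVERYWHERE), (5.0, Regime.CLOSED_EVERYWHERE)]:
        c = EquilibriumConstants(KA_OH, KA_NH_ALKYL, k)
        res = pkcycl_closed_form(c)
        assert res.value is None and not res.is_finite
        assert res.regime is regime
        num = pkcycl_numeric(c)
        assert num.value is None
        assert num.regime is regime


# ---------------------------------------------------------------- pK_cycl


def test_closed_form_recovers_tetramethyl_anchor():
    """Inverting at the measured 9.5 crossing and re-solving lands back on
    9.5 (closed form and brute-force oracle)."""
    k = closure_constant_from_pkcycl(9.5, KA_OH, KA_NH_ALKYL)
    assert k == pytest.approx(2.512e-5, rel=1e-3)
    c = EquilibriumConstants(KA_OH, KA_NH_ALKYL, k)
    assert pkcycl_closed_form(c).value == pytest.approx(9.5, abs=1e-9)
    assert brute_pkcycl(KA_OH, KA_NH_ALKYL, k) == pytest.approx(9.5, abs=1e-6)


def test_closed_form_recovers_aminomethyl_anchor():
    """Aminomethyl assumption ka_oh = 0; measured crossing at pH 6.2."""
    k = closure_constant_from_pkcycl(6.2, 0.0, KA_NH_PRIMARY)
    assert k == pytest.approx(0.02450, rel=1e-3)
    c = EquilibriumConstants(0.0, KA_NH_PRIMARY, k)
    assert pkcycl_closed_form(c).value == pytest.approx(6.2, abs=1e-9)
    assert brute_pkcycl(0.0, KA_NH_PRIMARY, k) == pytest.approx(6.2, abs=1e-6)


def test_inversion_acid_limit_approaches_unity():
    # at very acidic crossing pH, [H+] dominates both numerator and denominator
    assert closure_constant_from_pkcycl(-10.0, 0.0, KA_NH_PRIMARY) == pytest.approx(
        1.0, rel=1e-5
    )


def test_inversion_round_trip_across_ph_scale():
    for p in np.linspace(0, 14, 29):
        k = closure_constant_from_pkcycl(p, KA_OH, KA_NH_ALKYL)
        assert KA_OH / KA_NH_ALKYL < k < 1
        assert pkcycl_closed_form(
            EquilibriumConstants(KA_OH, KA_NH_ALKYL, k)
        ).value == pytest.approx(p, abs=1e-9)


def test_numeric_agrees_with_closed_form_random_sweep():
    """Closed form vs the package's bisection route over random valid
    constants (the dual-route consistency at the heart of the model)."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        pk_oh = rng.uniform(10, 16)
        pk_nh = rng.uniform(3, 6)
        lo = -pk_oh + pk_nh  # log10 of ka_oh/ka_nh
        log_k = rng.uniform(lo * 0.999, 0.0)
        c = EquilibriumConstants(10.0 ** -pk_oh, 10.0 ** -pk_nh, 10.0 ** log_k)
        if classify_regime(c) is not Regime.CROSSING:
            continue
        a = pkcycl_closed_form(c)
        b = pkcycl_numeric(c)
        assert b.value == pytest.approx(a.value, abs=1e-6)


def test_half_plateau_definition_matches_equality_for_small_closure():
    k = 1e-9
    c = EquilibriumConstants(KA_OH, KA_NH_ALKYL, k)
    eqv = pkcycl_numeric(c, Definition.CONCENTRATION_EQUALITY).value
    hp = pkcycl_numeric(c, Definition.HALF_OF_PLATEAU).value
    assert abs(eqv - hp) < 1e-6


def test_half_plateau_definition_larger_for_large_closure():
    """With half the population already closed in acid (k=0.5), half of
    the plateau (1/3) lies below 1/2 on a decreasing curve, so the
    half-of-maximum reading sits at higher pH."""
    c = EquilibriumConstants(KA_OH, KA_NH_ALKYL, 0.5)
    eqv = pkcycl_numeric(c, Definition.CONCENTRATION_EQUALITY).value
    hp = pkcycl_numeric(c, Definition.HALF_OF_PLATEAU).value
    assert hp > eqv


def test_speciation_profile_container(hmtmr_constants):
    prof = speciation_profile(np.linspace(4, 12, 33), hmtmr_constants)
    np.testing.assert_allclose(prof.fractions.sum(axis=1), 1.0, atol=1e-12)
    assert prof.open_fraction[0] > 0.99
    ax = prof.plot()
    assert ax is not None
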