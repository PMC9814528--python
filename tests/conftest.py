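import matplotlib
import pytest

matplotlib.use("Agg")

from spirocalc import EquilibriumConstants, closure_constant_from_pkcycl

KA_OH = 10.0 ** -15.4
KA_NH_PRIMARY = 10.0 ** -4.6
KA_NH_ALKYL = 10.0 ** -4.9


@pytest.fixture
def hmtmr_constants() -> EquilibriumConstants:
    """Constants of the tetramethyl dye whose measured open/closed crossing
    sits at pH 9.5: closure constant obtained by inverting the closed-form
    equation at that value."""
    k = closure_constant_from_pkcycl(9.5, KA_OH, KA_NH_ALKYL)
    return EquilibriumConstants(KA_OH, KA_NH_ALKYL, k)


@pytest.fixture
def amrg_constants() -> EquilibriumConstants:
    """Aminomethyl dye: the benzylic amine is never deprotonated (ka_oh=0);
    crossing at the measured pH 6.2."""
    k = closure_constant_from_pkcycl(6.2, 0.0, KA_NH_PRIMARY)
    return EquilibriumConstants(0.0, KA_NH_PRIMARY, k)
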