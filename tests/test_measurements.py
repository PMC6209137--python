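"""Measurement groups, device templates and error models."""

import numpy as np
import pytest

from fluxdesign import (
    ConfigurationError,
    DegeneracyError,
    ErrorModel,
    MeasurementGroup,
    MeasurementSetup,
    build_cumomer_cascade,
    evaluate_error_model,
    expand_flux_state,
    make_device_templates,
    predict_measurements,
    solve_labeling,
)
from fluxdesign.measurements import replicate_scaling_factor

from .conftest import pure_mixture


@pytest.fixture
def branch_state(branch):
    system = build_cumomer_cascade(branch.network)
    state = expand_flux_state(branch.param, [0.7])
    return solve_labeling(system, state, pure_mixture(branch, "1-13C"))


def test_ms_mid_is_m1_for_single_label_any_split(branch, branch_state):
    group = make_device_templates("P", 2)["ms"]
    setup = MeasurementSetup(groups=[group], n_rep=[1])
    mvec = predict_measurements(branch_state, setup)
    np.testing.assert_allclose(mvec.values, [0.0, 1.0, 0.0], atol=1e-12)


def test_positional_row_reads_split_ratio(branch, branch_state):
    group = make_device_templates("P", 2)["nmr13c"]
    setup = MeasurementSetup(groups=[group], n_rep=[1])
    mvec = predict_measurements(branch_state, setup)
    np.testing.assert_allclose(mvec.values, [0.7, 0.3], atol=1e-12)


def test_normalization_scales_group_to_unit_sum():
    group = MeasurementGroup(
        device="ms",
        name="g",
        rows=[{"P": np.array([1.0, 0, 0, 0])}, {"P": np.array([0, 1.0, 0, 0])}],
        normalize=True,
    )

    class FakeState:
        def isotopomer_fractions(self, pool):
            return np.array([0.2, 0.2, 0.0, 0.0])

    np.testing.assert_allclose(group.evaluate(FakeState()), [0.5, 0.5])


def test_zero_mass_normalized_group_is_degenerate():
    group = MeasurementGroup(
        device="ms", name="g", rows=[{"P": np.array([0, 0, 1.0, 0])}], normalize=True
    )

    class FakeState:
        def isotopomer_fractions(self, pool):
            return np.array([1.0, 0.0, 0.0, 0.0])

    with pytest.raises(DegeneracyError, match="g"):
        group.evaluate(FakeState())


def test_groups_with_zero_replicates_are_excluded(branch_state):
    tpl = make_device_templates("P", 2)
    setup = MeasurementSetup(groups=[tpl["ms"], tpl["nmr13c"]], n_rep=[0, 1])
    mvec = predict_measurements(branch_state, setup)
    assert mvec.values.size == 2  # only the positional rows


# -- device templates --------------------------------------------------------


def test_template_row_counts_for_c3_pool():
    tpl = make_device_templates("X", 3, fragment=(1, 2))
    assert tpl["ms"].n_rows == 4  # M+0..M+3
    assert tpl["nmr13c"].n_rows == 3
    assert tpl["irms"].n_rows == 1
    # feasible (precursor, fragment) mass pairs for a C2-C3 fragment:
    # j <= k <= j + 1 with k in 0..3, j in 0..2
    labels = tpl["msms"].row_labels
    assert len(labels) == 6
    assert "X:M+1/m+0" in labels and "X:M+2/m+2" in labels


def test_tandem_ms_separates_positional_isomers():
    """Precursor/fragment pairs distinguish [1-13C] from [3-13C]."""
    tpl = make_device_templates("X", 3, fragment=(1, 2))
    msms = tpl["msms"]

    class LabeledAt:
        def __init__(self, mask):
            self.iso = np.zeros(8)
            self.iso[mask] = 1.0

        def isotopomer_fractions(self, pool):
            return self.iso

    v1 = msms.evaluate(LabeledAt(0b001))  # C1 labeled: fragment unlabeled
    v3 = msms.evaluate(LabeledAt(0b100))  # C3 labeled: fragment labeled
    assert not np.allclose(v1, v3)
    ms = tpl["ms"]
    np.testing.assert_allclose(
        ms.evaluate(LabeledAt(0b001)), ms.evaluate(LabeledAt(0b100))
    )


def test_noncontiguous_fragment_declared_contiguous_raises():
    with pytest.raises(ConfigurationError, match="contiguous"):
        make_device_templates("X", 3, fragment=(0, 2), contiguous=True)


# -- error models ------------------------------------------------------------


def test_constant_error_model_gives_04_mol_percent():
    model = ErrorModel(device="gcms", b1=0.0, b2=0.004, scaling="none")
    eta = np.array([0.0, 0.3, 0.9])
    sigma, cov = evaluate_error_model(eta, model, 1)
    np.testing.assert_allclose(sigma, 0.004)  # 0.4 mol% on percentage scale
    np.testing.assert_allclose(cov, 0.004**2)


def test_linear_error_model_evaluation():
    model = ErrorModel(device="d", b1=0.004, b2=0.002, scaling="none")
    sigma, _ = evaluate_error_model(np.array([0.5]), model, 1)
    assert sigma[0] == pytest.approx(0.004)


def test_replicate_factor_tends_to_one():
    assert replicate_scaling_factor(1) == 2.0
    assert replicate_scaling_factor(2) == pytest.approx(np.sqrt(2.0))
    assert replicate_scaling_factor(1000) == pytest.approx(1.0, abs=1e-3)


def test_sigma_positive_and_monotone_in_replicates():
    model = ErrorModel(device="d", b1=0.01, b2=0.003)
    eta = np.array([0.4])
    sigmas = [model.sigma(eta, n)[0] for n in range(1, 11)]
    assert all(s > 0 for s in sigmas)
    assert all(a >= b for a, b in zip(sigmas, sigmas[1:]))


def test_negative_coefficients_rejected():
    with pytest.raises(ConfigurationError):
        ErrorModel(device="d", b1=-0.1, b2=0.01)
    with pytest.raises(ConfigurationError):
        ErrorModel(device="d", b1=0.1, b2=0.0)


def test_normalized_group_jacobian_differentiates_normalized_values(branch):
    """Sensitivities are taken of the normalized group prediction."""
    from fluxdesign import labeling_jacobian

    system = build_cumomer_cascade(branch.network)
    # a partial MID group (2 of 3 mass rows) where normalization matters
    group = MeasurementGroup(
        device="ms",
        name="partial",
        rows=[
            {"P": np.array([1.0, 0, 0, 0])},
            {"P": np.array([0, 1.0, 1.0, 0])},
        ],
        normalize=True,
    )
    setup = MeasurementSetup(groups=[group], n_rep=[1])
    mix = pure_mixture(branch, "1-13C")

    def measure(lab):
        return predict_measurements(lab, setup).values

    J = labeling_jacobian(system, branch.param, branch.reference_free, mix, measure)

    h = 1e-6

    def norm_eval(r1):
        state = expand_flux_state(branch.param, [r1])
        lab = solve_labeling(system, state, mix)
        return predict_measurements(lab, setup).values

    fd = (norm_eval(0.7 + h) - norm_eval(0.7 - h)) / (2 * h)
    np.testing.assert_allclose(J[:, 0], fd, atol=1e-6)
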