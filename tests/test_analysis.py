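"""Archive post-processing: clustering, robustness sampling, table exports."""

import numpy as np
import pytest

from fluxdesign import (
    ParetoArchive,
    cluster_mixtures,
    evaluate_design,
    export_results,
    front_table,
    repair_and_decode,
    robustness_sample,
)
from fluxdesign.criteria import iterative_freeze
from fluxdesign.errors import ConfigurationError
from fluxdesign.labeling import labeling_jacobian
from fluxdesign.measurements import attach_sigmas, predict_measurements


def _archive_from_designs(ctx, raws, capacity=100):
    archive = ParetoArchive(capacity=capacity)
    for raw in raws:
        design = repair_and_decode(np.asarray(raw, float), ctx)
        res = evaluate_design(design, ctx)
        archive.entries.append((res.values, res))  # keep all, dominated or not
    return archive


@pytest.fixture(scope="module")
def branch_ctx():
    from fluxdesign import make_fixture

    return make_fixture("branch").context("nmr")


@pytest.fixture(scope="module")
def branch_fim(branch_ctx):
    ctx = branch_ctx
    mix = ctx.mixture([0, 1, 0, 0])
    setup = ctx.setup_template.with_replicates([1])
    state = ctx.reference_state()
    from fluxdesign import solve_labeling

    lab = solve_labeling(ctx.system, state, mix)
    mvec = attach_sigmas(predict_measurements(lab, setup), setup)
    J = labeling_jacobian(
        ctx.system,
        ctx.param,
        ctx.reference_free,
        mix,
        lambda s: predict_measurements(s, setup).values,
    )
    return iterative_freeze(J, mvec.sigmas, ctx.param.free_flux_names)


# -- clustering --------------------------------------------------------------


def test_two_separated_compositions_cluster_cleanly(branch_ctx):
    raws = [
        [0.9, 0.1, 0, 0, 1],
        [0.88, 0.12, 0, 0, 1],
        [0, 0, 0.1, 0.9, 1],
        [0, 0, 0.12, 0.88, 1],
    ]
    archive = _archive_from_designs(branch_ctx, raws)
    clusters, merges = cluster_mixtures(archive, branch_ctx, k=2)
    assert len(clusters) == 2
    for c in clusters:
        comp = np.array(
            [c.mean_composition[s.name] for s in branch_ctx.species]
        )
        members = np.vstack(
            [archive.entries[i][1].design.fractions[0] for i in c.members]
        )
        np.testing.assert_allclose(comp, members.mean(axis=0), atol=1e-12)
        assert comp.sum() == pytest.approx(1.0)
    assert len(merges) == 3  # n-1 merges


def test_identical_designs_merge_at_distance_zero(branch_ctx):
    archive = _archive_from_designs(branch_ctx, [[0.5, 0.5, 0, 0, 2]] * 3)
    clusters, merges = cluster_mixtures(archive, branch_ctx, k=1)
    assert len(clusters) == 1
    assert clusters[0].frequency == 1.0
    assert np.allclose(merges["distance"], 0.0)


def test_single_cluster_is_grand_mean_on_simplex(branch_ctx):
    raws = [[0.2, 0.8, 0, 0, 1], [0.6, 0.4, 0, 0, 3], [0.4, 0.6, 0, 0, 5]]
    archive = _archive_from_designs(branch_ctx, raws)
    clusters, _ = cluster_mixtures(archive, branch_ctx, k=1)
    comp = np.array(
        [clusters[0].mean_composition[s.name] for s in branch_ctx.species]
    )
    assert comp.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(comp[:2], [0.4, 0.6], atol=1e-12)


def test_empty_archive_clusters_to_nothing(branch_ctx):
    clusters, merges = cluster_mixtures(ParetoArchive(), branch_ctx, k=2)
    assert clusters == [] and len(merges) == 0


def test_clustering_invariant_to_archive_order(branch_ctx):
    raws = [
        [0.9, 0.1, 0, 0, 1],
        [0, 0, 0.1, 0.9, 1],
        [0.85, 0.15, 0, 0, 2],
        [0, 0, 0.2, 0.8, 2],
    ]
    a1 = _archive_from_designs(branch_ctx, raws)
    a2 = _archive_from_designs(branch_ctx, raws[::-1])
    c1, _ = cluster_mixtures(a1, branch_ctx, k=2)
    c2, _ = cluster_mixtures(a2, branch_ctx, k=2)
    comps1 = sorted(
        tuple(round(v, 9) for v in c.mean_composition.values()) for c in c1
    )
    comps2 = sorted(
        tuple(round(v, 9) for v in c.mean_composition.values()) for c in c2
    )
    assert comps1 == comps2


# -- robustness --------------------------------------------------------------


def test_robustness_is_reproducible_under_seed(branch_ctx, branch_fim):
    design = repair_and_decode(np.array([0, 1, 0, 0, 1.0]), branch_ctx)
    r1 = robustness_sample(design, branch_fim, branch_ctx, n=100, seed=5)
    r2 = robustness_sample(design, branch_fim, branch_ctx, n=100, seed=5)
    np.testing.assert_array_equal(r1.phi_d, r2.phi_d)
    assert r1.quantiles == r2.quantiles


def test_robustness_zero_covariance_collapses_to_reference(branch_ctx, branch_fim):
    import dataclasses

    tight = dataclasses.replace(branch_fim)
    tight.cov = branch_fim.cov * 0.0
    design = repair_and_decode(np.array([0, 1, 0, 0, 1.0]), branch_ctx)
    rep = robustness_sample(design, tight, branch_ctx, n=50, seed=1)
    np.testing.assert_allclose(rep.phi_d, rep.reference_phi_d)


def test_robustness_requires_samples_and_identifiability(branch_ctx, branch_fim):
    design = repair_and_decode(np.array([0, 1, 0, 0, 1.0]), branch_ctx)
    with pytest.raises(ConfigurationError):
        robustness_sample(design, branch_fim, branch_ctx, n=0, seed=1)


def test_robustness_monte_carlo_self_consistency(branch):
    """Mean criterion of a small run agrees with a 10x larger run.

    Uses a signal-dependent error model (b1 > 0) so the criterion actually
    varies across the sampled flux space.
    """
    from fluxdesign import CriteriaConfig, ErrorModel, MeasurementSetup
    from fluxdesign.design import DesignContext

    groups, _ = branch.devices["nmr_full"]
    setup = MeasurementSetup(
        groups=list(groups),
        n_rep=[1] * len(groups),
        error_models={"nmr13c": ErrorModel("nmr13c", b1=0.05, b2=0.005, scaling="none")},
        n_max=10,
    )
    ctx = DesignContext(
        param=branch.param,
        reference_free=branch.reference_free,
        species=branch.species,
        setup_template=setup,
        cost_params=branch.cost_params,
    )
    design = repair_and_decode(np.array([0, 1, 0, 0, 1.0]), ctx)
    res = evaluate_design(design, ctx)
    assert res.p == 1
    from fluxdesign import solve_labeling

    mix = ctx.mixture([0, 1, 0, 0])
    lab = solve_labeling(ctx.system, ctx.reference_state(), mix)
    mvec = attach_sigmas(predict_measurements(lab, setup), setup)
    J = labeling_jacobian(
        ctx.system,
        ctx.param,
        ctx.reference_free,
        mix,
        lambda s: predict_measurements(s, setup).values,
    )
    fim = iterative_freeze(J, mvec.sigmas, ctx.param.free_flux_names)
    small = robustness_sample(design, fim, ctx, n=1000, seed=11)
    large = robustness_sample(design, fim, ctx, n=10000, seed=12)
    assert small.phi_d.std() > 0
    se = small.phi_d.std() / np.sqrt(small.n)
    assert abs(small.mean_phi_d - large.mean_phi_d) < 3 * se


# -- exports -----------------------------------------------------------------


def test_chord_table_one_row_per_design_species_pair(branch_ctx):
    raws = [[0.25, 0.25, 0.25, 0.25, r] for r in (1, 3, 5, 7, 9, 2, 4, 6, 8, 10)]
    archive = _archive_from_designs(branch_ctx, raws)
    tables = export_results(archive, branch_ctx)
    assert len(tables["chord_links"]) == 40  # 10 designs x 4 species >= 1%


def test_trace_species_below_one_percent_omitted(branch_ctx):
    raws = [[0.005, 0.995, 0, 0, 1]]
    archive = _archive_from_designs(branch_ctx, raws)
    tables = export_results(archive, branch_ctx)
    assert set(tables["chord_links"]["species"]) == {"1-13C"}


def test_front_table_round_trips_objectives(branch_ctx, tmp_path):
    from fluxdesign.io import read_archive, write_archive

    raws = [[0, 1, 0, 0, 1], [1, 0, 0, 0, 2], [0.5, 0.5, 0, 0, 3]]
    archive = _archive_from_designs(branch_ctx, raws)
    path = tmp_path / "archive.csv"
    write_archive(archive, branch_ctx, path, metadata={"seed": 1})
    back, meta = read_archive(path, branch_ctx)
    np.testing.assert_array_equal(back.objectives, archive.objectives)
    assert meta["seed"] == "1"
    df = front_table(back, branch_ctx)
    np.testing.assert_allclose(
        df["cost_total"], [e[1].cost.total for e in archive.entries]
    )


def test_scaled_objective_coordinates_within_0_100(branch_ctx):
    raws = [[0, 1, 0, 0, r] for r in (1, 5, 10)] + [[1, 0, 0, 0, 2]]
    archive = _archive_from_designs(branch_ctx, raws)
    tables = export_results(archive, branch_ctx)
    cols = [c for c in tables["chord_links"].columns if c.endswith("_pct")]
    vals = tables["chord_links"][cols].to_numpy()
    assert vals.min() >= 0.0 and vals.max() <= 100.0


def test_ternary_export_needs_exactly_three_active_species(branch_ctx):
    # four active species -> skipped
    archive4 = _archive_from_designs(branch_ctx, [[0.25, 0.25, 0.25, 0.25, 1]])
    assert export_results(archive4, branch_ctx)["ternary"] is None
    # three active -> coordinates on the simplex
    archive3 = _archive_from_designs(
        branch_ctx, [[0.5, 0.3, 0.2, 0, 1], [0.2, 0.4, 0.4, 0, 2]]
    )
    tern = export_results(archive3, branch_ctx)["ternary"]
    assert tern is not None and len(tern) == 2
    sums = tern.drop(columns="design_id").sum(axis=1)
    np.testing.assert_allclose(sums, 1.0)


def test_replicate_histogram_counts_designs(branch_ctx):
    raws = [[0, 1, 0, 0, 2], [0, 1, 0, 0, 2], [0, 1, 0, 0, 7]]
    archive = _archive_from_designs(branch_ctx, raws)
    hist = export_results(archive, branch_ctx)["replicate_histogram"]
    at2 = hist[(hist["n_rep"] == 2)]["count"].sum()
    at7 = hist[(hist["n_rep"] == 7)]["count"].sum()
    assert at2 == 2 and at7 == 1


def test_mixture_histogram_uses_five_percent_bins(branch_ctx):
    raws = [[0.52, 0.48, 0, 0, 1], [0.54, 0.46, 0, 0, 2]]
    archive = _archive_from_designs(branch_ctx, raws)
    hist = export_results(archive, branch_ctx)["mixture_histogram"]
    row = hist[(hist["species"] == "unlabeled") & (hist["count"] == 2)]
    assert len(row) == 1
    assert row.iloc[0]["bin_low"] == pytest.approx(0.50)
    assert row.iloc[0]["bin_high"] == pytest.approx(0.55)
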