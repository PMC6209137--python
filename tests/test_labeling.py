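"""Cumomer cascade: structure, solutions, oracle equivalence, sensitivities."""

import numpy as np
import pytest

from fluxdesign import (
    ConfigurationError,
    DegeneracyError,
    TracerMixture,
    build_cumomer_cascade,
    expand_flux_state,
    labeling_jacobian,
    load_network,
    solve_labeling,
)
from fluxdesign.labeling import _cumomers_to_isotopomers, _isotopomers_to_cumomers

from .conftest import pure_mixture
from .oracles import brute_force_labeling, mixture_isotopomers


def test_branch_cascade_level_sizes(branch):
    system = build_cumomer_cascade(branch.network)
    # two 2-carbon balanced pools: 2x2 weight-1 cumomers, 2x1 weight-2
    assert system.level_sizes == {1: 4, 2: 2}


def test_chain_cascade_excludes_input_pool(chain):
    system = build_cumomer_cascade(chain.network)
    pools = {p for lvl in system.unknowns.values() for p, _ in lvl}
    assert "S_ext" not in pools
    assert system.input_pools == ["S_ext"]
    assert sorted(system.unknowns) == [1, 2]


def test_carbon_free_cofactor_contributes_no_cumomers():
    doc = {
        "metabolites": [
            {"name": "S", "carbons": 1, "balanced": False},
            {"name": "A", "carbons": 1, "balanced": True},
            {"name": "ATP", "carbons": 0, "balanced": False},
            {"name": "P", "carbons": 1, "balanced": False},
        ],
        "reactions": [
            {"name": "in", "equation": "S#a -> A#a"},
            {"name": "out", "equation": "A#a + ATP -> P#a"},
        ],
    }
    system = build_cumomer_cascade(load_network(doc))
    assert system.level_sizes == {1: 1}


def test_missing_atom_map_raises():
    doc = {
        "metabolites": [
            {"name": "S", "carbons": 1, "balanced": False},
            {"name": "A", "carbons": 1, "balanced": True},
            {"name": "P", "carbons": 1, "balanced": False},
        ],
        "reactions": [
            {"name": "in", "equation": "S#a -> A#a"},
            {"name": "out", "equation": "A -> P"},
        ],
    }
    with pytest.raises(ConfigurationError, match="out"):
        build_cumomer_cascade(load_network(doc))


def test_chain_propagates_positional_label_unchanged(chain):
    system = build_cumomer_cascade(chain.network)
    state = expand_flux_state(chain.param, [1.0])
    lab = solve_labeling(system, state, pure_mixture(chain, "1-13C"))
    for pool in ("A", "B", "C"):
        iso = lab.isotopomer_fractions(pool)
        assert iso[0b01] == pytest.approx(1.0, abs=1e-12)


def test_branch_split_ratio_appears_in_positional_enrichment(branch):
    system = build_cumomer_cascade(branch.network)
    state = expand_flux_state(branch.param, [0.7])
    lab = solve_labeling(system, state, pure_mixture(branch, "1-13C"))
    assert lab.positional_enrichment("P", 0) == pytest.approx(0.7, abs=1e-12)
    assert lab.positional_enrichment("P", 1) == pytest.approx(0.3, abs=1e-12)


def test_half_uniform_mixture_gives_half_enrichment(chain):
    system = build_cumomer_cascade(chain.network)
    state = expand_flux_state(chain.param, [1.0])
    mix = TracerMixture(chain.species, [0.5, 0.0, 0.0, 0.5], pool="S_ext")
    lab = solve_labeling(system, state, mix)
    for pool in ("A", "B", "C"):
        for pos in (0, 1):
            assert lab.positional_enrichment(pool, pos) == pytest.approx(0.5)


def test_dead_pool_raises_degeneracy_error():
    doc = {
        "metabolites": [
            {"name": "S", "carbons": 1, "balanced": False},
            {"name": "A", "carbons": 1, "balanced": True},
            {"name": "P", "carbons": 1, "balanced": False},
        ],
        "reactions": [
            {"name": "in", "equation": "S#a -> A#a"},
            {"name": "out", "equation": "A#a -> P#a"},
        ],
    }
    net = load_network(doc)
    system = build_cumomer_cascade(net)
    from fluxdesign.network import FluxState

    with pytest.raises(DegeneracyError, match="A"):
        solve_labeling(system, FluxState(net={"in": 0.0, "out": 0.0}, exchange={}),
                       pure_mixture_for(net))


def pure_mixture_for(net):
    from fluxdesign import TracerSpecies

    sp = TracerSpecies("t", (1,), purity=1.0)
    return TracerMixture([sp], [1.0], pool="S")


@pytest.mark.parametrize("fixture_name", ["chain", "branch", "cycle"])
@pytest.mark.parametrize(
    "fractions", [(0.0, 1.0, 0.0, 0.0), (0.2, 0.3, 0.1, 0.4), (0.0, 0.0, 0.0, 1.0)]
)
def test_cumomer_solution_matches_brute_force_enumeration(
    all_bundles, fixture_name, fractions
):
    """The cascade agrees with the independent full-isotopomer solver."""
    bundle = all_bundles[fixture_name]
    system = build_cumomer_cascade(bundle.network)
    state = bundle.context(
        "ms"
    ).reference_state()  # nominal fluxes incl. exchanges
    mix = TracerMixture(bundle.species, list(fractions), pool="S_ext")
    lab = solve_labeling(system, state, mix)
    oracle = brute_force_labeling(
        bundle.network,
        state,
        {"S_ext": mixture_isotopomers(bundle.species, fractions)},
    )
    for pool, iso_expected in oracle.items():
        np.testing.assert_allclose(
            lab.isotopomer_fractions(pool), iso_expected, atol=1e-8
        )


def test_mixture_labeling_is_fraction_weighted_pure_runs(branch, rng):
    """Steady-state labeling is linear in the input mixture at fixed fluxes."""
    system = build_cumomer_cascade(branch.network)
    state = expand_flux_state(branch.param, [0.55])
    fracs = rng.dirichlet(np.ones(len(branch.species)))
    mixed = solve_labeling(
        system, state, TracerMixture(branch.species, fracs, pool="S_ext")
    )
    weighted = np.zeros(4)
    for f, sp in zip(fracs, branch.species):
        pure = solve_labeling(system, state, pure_mixture(branch, sp.name))
        weighted += f * pure.isotopomer_fractions("P")
    np.testing.assert_allclose(mixed.isotopomer_fractions("P"), weighted, atol=1e-10)


def test_isotopomer_fractions_form_a_distribution(all_bundles, rng):
    for bundle in all_bundles.values():
        system = build_cumomer_cascade(bundle.network)
        state = bundle.context("ms").reference_state()
        fracs = rng.dirichlet(np.ones(len(bundle.species)))
        lab = solve_labeling(
            system, state, TracerMixture(bundle.species, fracs, pool="S_ext")
        )
        for pool in lab.cumomers:
            iso = lab.isotopomer_fractions(pool)
            assert np.all(iso >= -1e-9) and np.all(iso <= 1 + 1e-9)
            assert iso.sum() == pytest.approx(1.0, abs=1e-9)
            assert lab.cumomers[pool][0] == pytest.approx(1.0)


def test_moebius_transforms_are_inverse(rng):
    iso = rng.dirichlet(np.ones(8))
    cum = _isotopomers_to_cumomers(iso)
    np.testing.assert_allclose(_cumomers_to_isotopomers(cum), iso, atol=1e-14)


# -- sensitivities -----------------------------------------------------------


def test_branch_positional_derivative_is_one(branch):
    system = build_cumomer_cascade(branch.network)
    mix = pure_mixture(branch, "1-13C")

    def measure(lab):
        return np.array([lab.positional_enrichment("P", 0)])

    J = labeling_jacobian(system, branch.param, branch.reference_free, mix, measure)
    assert J.shape == (1, 1)
    assert J[0, 0] == pytest.approx(1.0, abs=1e-8)


def test_chain_labeling_is_flux_insensitive(chain):
    system = build_cumomer_cascade(chain.network)
    mix = pure_mixture(chain, "1-13C")

    def measure(lab):
        return np.array(
            [lab.positional_enrichment("C", 0), lab.positional_enrichment("C", 1)]
        )

    J = labeling_jacobian(system, chain.param, np.array([2.0]), mix, measure)
    np.testing.assert_allclose(J, 0.0, atol=1e-8)


def test_finite_difference_richardson_consistency(branch):
    """Halving the step changes the derivative by < 1e-6 relative."""
    system = build_cumomer_cascade(branch.network)
    mix = TracerMixture(branch.species, [0.1, 0.6, 0.0, 0.3], pool="S_ext")

    def measure(lab):
        return lab.isotopomer_fractions("P")

    J1 = labeling_jacobian(
        system, branch.param, branch.reference_free, mix, measure, step=1e-5
    )
    J2 = labeling_jacobian(
        system, branch.param, branch.reference_free, mix, measure, step=5e-6
    )
    scale = max(1.0, np.abs(J1).max())
    assert np.abs(J1 - J2).max() / scale < 1e-6


def test_cycle_exchange_sensitivity_present_for_positional_tracer(cycle):
    system = build_cumomer_cascade(cycle.network)

    def measure(lab):
        return np.array([lab.positional_enrichment("A", 0)])

    J_pos = labeling_jacobian(
        system, cycle.param, cycle.reference_free, pure_mixture(cycle, "1-13C"), measure
    )
    assert abs(J_pos[0, 0]) > 1e-3
    J_uni = labeling_jacobian(
        system, cycle.param, cycle.reference_free, pure_mixture(cycle, "U-13C"), measure
    )
    assert abs(J_uni[0, 0]) < 1e-8
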