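"""Self-contained toy systems for testing and demonstration.

Three deterministic desk-scale networks cover the qualitatively distinct
identifiability situations of labeling-based flux analysis:

* ``chain`` — a linear pathway; every steady-state labeling pattern simply
  propagates downstream, so measurements carry no flux information at all.
* ``branch`` — two parallel routes from a two-carbon substrate to the same
  product, one preserving carbon order and one swapping C1/C2. Positional
  (NMR-type) data read the split ratio directly, while the mass isotopomer
  distribution is flux-blind because both routes conserve the number of
  labeled carbons — the classic positional-vs-mass contrast.
* ``cycle`` — a pathway with a reversible carbon-scrambling step whose
  exchange flux shows up only in positional contrast generated by an
  asymmetric tracer; with uniformly labeled substrate (or mass-only data)
  it is unidentifiable.

Each bundle carries an ``expected`` ledger of hand-derived quantities that
the test suite re-verifies against the live implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .costs import CostParameters
from .criteria import CriteriaConfig
from .design import DesignContext
from .errors import ConfigurationError
from .labeling import TracerSpecies
from .measurements import ErrorModel, MeasurementGroup, MeasurementSetup, make_device_templates
from .network import MetabolicNetwork, load_network, stoichiometric_analysis

__all__ = ["FixtureBundle", "make_fixture", "make_cost_params", "fixture_names"]

FIXTURE_NAMES = ("chain", "branch", "cycle")


def fixture_names():
    return list(FIXTURE_NAMES)


@dataclass
class FixtureBundle:
    """A toy network with everything needed to run the full pipeline."""

    name: str
    network: MetabolicNetwork
    param: object
    reference_free: np.ndarray  # net frees then exchanges
    species: list
    devices: dict  # device name -> (groups, ErrorModel)
    cost_params: CostParameters
    expected: dict = field(default_factory=dict)  # hand-derived values + notes

    def context(self, device: str, objectives: str = "3D", n_cle: int = 1,
                criteria_config: CriteriaConfig | None = None) -> DesignContext:
        groups, model = self.devices[device]
        setup = MeasurementSetup(
            groups=list(groups),
            n_rep=[1] * len(groups),
            error_models={model.device: model},
            n_max=self.cost_params.n_samples,
        )
        return DesignContext(
            param=self.param,
            reference_free=self.reference_free,
            species=list(self.species),
            setup_template=setup,
            cost_params=self.cost_params,
            n_cle=n_cle,
            criteria_config=criteria_config or CriteriaConfig(),
            objectives=objectives,
        )


# toy tracer palette for a two-carbon substrate; purities are exactly 1 so
# the hand-derived labeling values are exact (the glucose price profile
# below uses the realistic 99%/98% purities instead)
def _toy_species():
    return [
        TracerSpecies("unlabeled", (0, 0), purity=1.0, price=0.30),
        TracerSpecies("1-13C", (1, 0), purity=1.0, price=100.0),
        TracerSpecies("2-13C", (0, 1), purity=1.0, price=700.0),
        TracerSpecies("U-13C", (1, 1), purity=1.0, price=200.0),
    ]


def make_cost_params(profile: str = "glucose", **overrides) -> CostParameters:
    """Cost parameter sets.

    ``glucose`` — the ten commercial glucose species with the printed price
    bounds (0.30 EUR/g unlabeled, 1293.00 EUR/g [5-13C]); intermediate
    prices are plausible market values and freely overridable. ``toy`` —
    prices of the two-carbon fixture palette.
    """
    if profile == "glucose":
        params = CostParameters(
            tracer_prices={
                "unlabeled": 0.30,
                "1-13C": 85.0,
                "2-13C": 700.0,
                "3-13C": 950.0,
                "4-13C": 1100.0,
                "5-13C": 1293.00,
                "6-13C": 250.0,
                "1,2-13C": 450.0,
                "1,6-13C": 900.0,
                "U-13C": 180.0,
            },
            substrate_mass=5.0,
            c_exp=500.0,
            c_work=30.0,
            t_work_exp=8.0,
            c_sample=50.0,
            n_samples=10,
            t_work_ana=0.05,
        )
    elif profile == "toy":
        params = CostParameters(
            tracer_prices={s.name: s.price for s in _toy_species()},
            substrate_mass=5.0,
            c_exp=100.0,
            c_work=30.0,
            t_work_exp=2.0,
            c_sample=50.0,
            n_samples=10,
            t_work_ana=0.05,
        )
    else:
        raise ConfigurationError(
            f"unknown cost profile {profile!r}; options: glucose, toy"
        )
    return params.override(**overrides) if overrides else params


_CHAIN_DOC = {
    "name": "chain",
    "metabolites": [
        {"name": "S_ext", "carbons": 2, "balanced": False},
        {"name": "A", "carbons": 2, "balanced": True},
        {"name": "B", "carbons": 2, "balanced": True},
        {"name": "C", "carbons": 2, "balanced": True},
        {"name": "P_ext", "carbons": 2, "balanced": False},
    ],
    "reactions": [
        {"name": "upt", "equation": "S_ext#ab -> A#ab"},
        {"name": "r1", "equation": "A#ab -> B#ab"},
        {"name": "r2", "equation": "B#ab -> C#ab"},
        {"name": "out", "equation": "C#ab -> P_ext#ab"},
    ],
}

_BRANCH_DOC = {
    "name": "branch",
    "metabolites": [
        {"name": "S_ext", "carbons": 2, "balanced": False},
        {"name": "A", "carbons": 2, "balanced": True},
        {"name": "P", "carbons": 2, "balanced": True},
        {"name": "P_ext", "carbons": 2, "balanced": False},
    ],
    "reactions": [
        {"name": "upt", "equation": "S_ext#ab -> A#ab"},
        {"name": "r1", "equation": "A#ab -> P#ab"},
        {"name": "r2", "equation": "A#ab -> P#ba"},
        {"name": "out", "equation": "P#ab -> P_ext#ab"},
    ],
    "rates": {"upt": 1.0},
}

_CYCLE_DOC = {
    "name": "cycle",
    "metabolites": [
        {"name": "S_ext", "carbons": 2, "balanced": False},
        {"name": "A", "carbons": 2, "balanced": True},
        {"name": "P_ext", "carbons": 2, "balanced": False},
    ],
    "reactions": [
        {"name": "upt", "equation": "S_ext#ab -> A#ab"},
        {"name": "scr", "equation": "A#ab -> A#ba", "reversible": True},
        {"name": "out", "equation": "A#ab -> P_ext#ab"},
    ],
    "rates": {"upt": 1.0, "scr": 0.0},
}


def make_fixture(name: str) -> FixtureBundle:
    """Build one of the named fixtures with devices, tracers and costs."""
    if name not in FIXTURE_NAMES:
        raise ConfigurationError(
            f"unknown fixture {name!r}; options: {', '.join(FIXTURE_NAMES)}"
        )
    species = _toy_species()
    cost_params = make_cost_params("toy")

    if name == "chain":
        network = load_network(_CHAIN_DOC)
        param = stoichiometric_analysis(network)
        reference = np.array([1.0])  # throughput
        measured_pool = "C"
        expected = {
            "dof": (1, "4 reactions, 3 independent balances"),
            "jacobian_zero": (True, "labeling on a chain is flux-independent"),
        }
    elif name == "branch":
        network = load_network(_BRANCH_DOC)
        param = stoichiometric_analysis(network, preferred=["r1"])
        reference = np.array([0.7])  # r1; r2 = 1 - r1 by the A balance
        measured_pool = "P"
        expected = {
            "dof": (1, "uptake pinned to 1; split ratio r1 remains"),
            "dof_without_rates": (2, "4 reactions, 2 balances"),
            "c1_enrichment_at_r1_0.7": (
                0.7,
                "pure [1-13C] feed: order-preserving route r1 puts the label "
                "on product C1, the swapping route r2 on C2",
            ),
            "c2_enrichment_at_r1_0.7": (0.3, "complement of the split ratio"),
            "nmr_c1_derivative": (1.0, "eta = r1 exactly, so d(eta)/d(r1) = 1"),
            "nmr_flux_sd": (
                0.01,
                "single C1 row, sigma = 0.01 (b1=0, b2=0.01, a=1): "
                "FIM = 1/sigma^2, sd = sigma",
            ),
            "ms_mid_pure_1_13C": (
                (0.0, 1.0, 0.0),
                "exactly one labeled carbon survives on both routes",
            ),
        }
    else:  # cycle
        network = load_network(_CYCLE_DOC)
        param = stoichiometric_analysis(network)
        # all net fluxes pinned by the rate equalities; the scrambling
        # exchange is the single remaining free flux
        reference = np.array([0.5])
        measured_pool = "A"
        expected = {
            "dof": (0, "net fluxes fully determined; one free exchange"),
            "c1_enrichment_pure_1_13C": (
                2.0 / 3.0,
                "throughput 1, scramble fwd+bwd = 2*xch = 1: "
                "a1 = (1+e)/(1+2e) with e = 1",
            ),
            "c2_enrichment_pure_1_13C": (1.0 / 3.0, "a2 = e/(1+2e), e = 1"),
        }

    templates = make_device_templates(measured_pool, 2, fragment=(1,))
    # toy devices reuse the printed 0.4 mol% MS precision; replicate scaling
    # is off so the hand-derived sd values are exact
    devices = {
        "nmr": (
            [
                MeasurementGroup(
                    device="nmr13c",
                    name=f"{measured_pool}_c1",
                    rows=[templates["nmr13c"].rows[0]],
                    row_labels=[f"{measured_pool}:C1"],
                    normalize=False,
                )
            ],
            ErrorModel(device="nmr13c", b1=0.0, b2=0.01, scaling="none"),
        ),
        "nmr_full": (
            [templates["nmr13c"]],
            ErrorModel(device="nmr13c", b1=0.0, b2=0.01, scaling="none"),
        ),
        "ms": (
            [templates["ms"]],
            ErrorModel(device="ms", b1=0.0, b2=0.004, scaling="none"),
        ),
        "msms": (
            [templates["msms"]],
            ErrorModel(device="msms", b1=0.0, b2=0.004, scaling="none"),
        ),
    }
    return FixtureBundle(
        name=name,
        network=network,
        param=param,
        reference_free=reference,
        species=species,
        devices=devices,
        cost_params=cost_params,
        expected=expected,
    )
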