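"""Experimental and analytical cost model of carbon labeling experiments.

One experiment's cost splits into an experimental part

    C_CLE = substrate_mass * (x_inp . prices) + C_exp + t_work_exp * C_work

(tracer purchase for the fed substrate mass, technical setup, and wage for
running the cultivation) and an analytical part

    C_ANA = n_samples * C_sample
          + (sum over groups of n_rep * n_peaks) * t_work_ana * C_work

(sample acquisition at the instrument's per-sample rate — instrument
depreciation folded in — plus manual peak evaluation, linear in replicates
and peaks). Groups with zero replicates contribute nothing to the peak
term. The total design cost sums both parts over the parallel experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigurationError, ConstraintError
from .labeling import TracerMixture
from .measurements import MeasurementSetup

__all__ = ["CostParameters", "CostBreakdown", "cle_cost", "analytical_cost", "total_cost"]


@dataclass(frozen=True)
class CostParameters:
    """All monetary and effort constants of one experimental scenario.

    Units: EUR, grams, hours. ``substrate_mass`` is the fed substrate per
    experiment (culture volume x concentration); ``n_samples`` is the fixed
    number of samples drawn per experiment and bounds the replicate counts.
    """

    tracer_prices: dict = field(default_factory=dict)  # EUR / g per species
    substrate_mass: float = 5.0  # g per CLE (250 mL x 20 g/L)
    c_exp: float = 0.0  # EUR fixed setup cost
    c_work: float = 30.0  # EUR / h
    t_work_exp: float = 0.0  # h to set up and run the experiment
    c_sample: float = 50.0  # EUR per acquired sample
    n_samples: int = 10  # samples per CLE (max replicates)
    t_work_ana: float = 0.05  # h per peak evaluation

    def __post_init__(self):
        for name in (
            "substrate_mass",
            "c_exp",
            "c_work",
            "t_work_exp",
            "c_sample",
            "t_work_ana",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"cost parameter {name} must be >= 0")
        if self.n_samples < 0:
            raise ConfigurationError("n_samples must be >= 0")
        if any(p < 0 for p in self.tracer_prices.values()):
            raise ConfigurationError("tracer prices must be >= 0")

    def override(self, **kwargs) -> "CostParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CostBreakdown:
    experimental: float
    analytical: float

    @property
    def total(self) -> float:
        return self.experimental + self.analytical


def cle_cost(mixture: TracerMixture, params: CostParameters) -> float:
    """Experimental cost of one labeling experiment."""
    substrate = 0.0
    for sp, frac in zip(mixture.species, mixture.fractions):
        if sp.name not in params.tracer_prices:
            raise ConfigurationError(
                f"no price for tracer species {sp.name!r} in cost parameters"
            )
        substrate += float(frac) * params.tracer_prices[sp.name]
    return (
        params.substrate_mass * substrate
        + params.c_exp
        + params.t_work_exp * params.c_work
    )


def analytical_cost(setup: MeasurementSetup, params: CostParameters) -> float:
    """Acquisition plus peak-evaluation cost of one experiment's analytics."""
    for g, n in zip(setup.groups, setup.n_rep):
        if n > params.n_samples:
            raise ConstraintError(
                f"group {g.name!r}: {n} replicates exceed the {params.n_samples} "
                "samples available",
                [g.name],
            )
    acquisition = params.n_samples * params.c_sample
    peaks = sum(n * g.n_peaks for g, n in zip(setup.groups, setup.n_rep))
    return acquisition + peaks * params.t_work_ana * params.c_work


def total_cost(experiments, params: CostParameters) -> CostBreakdown:
    """Summed cost over parallel experiments.

    ``experiments`` is a sequence of (mixture, setup) pairs, one per CLE.
    """
    experiments = list(experiments)
    if not experiments:
        raise ConfigurationError("at least one experiment required")
    exp = sum(cle_cost(mix, params) for mix, _ in experiments)
    ana = sum(analytical_cost(setup, params) for _, setup in experiments)
    return CostBreakdown(experimental=float(exp), analytical=float(ana))
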