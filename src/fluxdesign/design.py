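"""Design vectors and the design-to-objectives evaluation pipeline.

A candidate experiment series is encoded, per parallel labeling experiment,
as the tracer mixture fractions (a point on the unit simplex) followed by
per-measurement-group replicate counts. The search operates on a relaxed
continuous vector; :func:`repair_and_decode` projects it back to a feasible
*executable* protocol (fractions normalized, replicates rounded to
integers), and :func:`evaluate_design` scores that rounded protocol:

    solve labeling -> predict measurements -> error models -> Jacobian
    -> iterative freezing -> D/A/E/DoF criteria + total cost

Objectives are reported in all-maximize orientation: the degrees of
freedom, the reciprocal dispersion criteria (information values), and the
negated cost.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .costs import CostBreakdown, CostParameters, total_cost
from .criteria import CriteriaConfig, CriteriaValues, FimResult, evaluate_criteria, iterative_freeze
from .errors import ConfigurationError, ConstraintError, DegeneracyError
from .labeling import (
    CumomerSystem,
    TracerMixture,
    TracerSpecies,
    build_cumomer_cascade,
    labeling_jacobian,
    solve_labeling,
)
from .measurements import MeasurementSetup, attach_sigmas, predict_measurements
from .network import FluxParametrization, expand_flux_state

logger = logging.getLogger(__name__)

__all__ = ["DesignContext", "DesignVector", "ObjectiveVector", "repair_and_decode", "evaluate_design"]


@dataclass
class DesignContext:
    """Everything held constant while designs are scored.

    ``reference_free`` is the nominal free flux vector (net frees followed
    by exchanges, order of ``param.free_flux_names``) around which the
    Fisher information is linearized.
    """

    param: FluxParametrization
    reference_free: np.ndarray
    species: list  # TracerSpecies of the substrate pool
    setup_template: MeasurementSetup  # groups + error models; n_rep ignored
    cost_params: CostParameters
    substrate_pool: str | None = None
    n_cle: int = 1
    criteria_config: CriteriaConfig = field(default_factory=CriteriaConfig)
    objectives: str = "3D"  # "3D" or "5D"
    system: CumomerSystem | None = None

    def __post_init__(self):
        self.reference_free = np.asarray(self.reference_free, float)
        if self.reference_free.shape != (self.param.n_free,):
            raise ConfigurationError(
                f"reference_free must cover the {self.param.n_free} free fluxes"
            )
        if self.objectives not in ("3D", "5D"):
            raise ConfigurationError("objectives must be '3D' or '5D'")
        if self.n_cle < 1:
            raise ConfigurationError("n_cle must be >= 1")
        if self.system is None:
            self.system = build_cumomer_cascade(self.param.network)
        if self.substrate_pool is None:
            if len(self.system.input_pools) != 1:
                raise ConfigurationError(
                    "substrate_pool must be named when the network has "
                    f"multiple input pools {self.system.input_pools}"
                )
            self.substrate_pool = self.system.input_pools[0]
        # reference point must be feasible
        self.reference_state()

    # -- conveniences ----------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_groups(self) -> int:
        return len(self.setup_template.groups)

    @property
    def n_max(self) -> int:
        return self.setup_template.n_max

    @property
    def n_vars(self) -> int:
        return self.n_cle * (self.n_species + self.n_groups)

    @property
    def lower(self) -> np.ndarray:
        return np.zeros(self.n_vars)

    @property
    def upper(self) -> np.ndarray:
        per_cle = np.concatenate(
            [np.ones(self.n_species), np.full(self.n_groups, float(self.n_max))]
        )
        return np.tile(per_cle, self.n_cle)

    @property
    def objective_names(self) -> list:
        if self.objectives == "3D":
            return ["dof", "info_d", "neg_cost"]
        return ["dof", "info_d", "info_a", "info_e", "neg_cost"]

    def reference_state(self):
        net = self.reference_free[: self.param.dof]
        xch = {
            nm: float(self.reference_free[self.param.dof + i])
            for i, nm in enumerate(self.param.free_exchange_names)
        }
        return expand_flux_state(self.param, net, exchanges=xch, check=True)

    def mixture(self, fractions) -> TracerMixture:
        return TracerMixture(
            species=list(self.species),
            fractions=np.asarray(fractions, float),
            pool=self.substrate_pool,
        )


@dataclass
class DesignVector:
    """A feasible, executable protocol: one (mixture, replicates) block per CLE."""

    fractions: np.ndarray  # (n_cle, n_species), rows on the simplex
    replicates: np.ndarray  # (n_cle, n_groups), integers in [0, n_max]

    @property
    def n_cle(self) -> int:
        return self.fractions.shape[0]

    def flat(self) -> np.ndarray:
        return np.concatenate(
            [
                np.concatenate([self.fractions[c], self.replicates[c].astype(float)])
                for c in range(self.n_cle)
            ]
        )

    def to_json(self, context: DesignContext | None = None) -> str:
        if context is not None:
            payload = [
                {
                    "mixture": {
                        sp.name: float(f)
                        for sp, f in zip(context.species, self.fractions[c])
                    },
                    "replicates": {
                        g.name: int(n)
                        for g, n in zip(
                            context.setup_template.groups, self.replicates[c]
                        )
                    },
                }
                for c in range(self.n_cle)
            ]
        else:
            payload = [
                {
                    "mixture": [float(f) for f in self.fractions[c]],
                    "replicates": [int(n) for n in self.replicates[c]],
                }
                for c in range(self.n_cle)
            ]
        return json.dumps(payload)

    @staticmethod
    def from_json(text: str, context: DesignContext) -> "DesignVector":
        payload = json.loads(text)
        fracs, reps = [], []
        for block in payload:
            mix = block["mixture"]
            rep = block["replicates"]
            if isinstance(mix, dict):
                fracs.append([mix.get(sp.name, 0.0) for sp in context.species])
                reps.append(
                    [rep.get(g.name, 0) for g in context.setup_template.groups]
                )
            else:
                fracs.append(mix)
                reps.append(rep)
        return DesignVector(
            fractions=np.asarray(fracs, float), replicates=np.asarray(reps)
        )


@dataclass
class ObjectiveVector:
    """Named objective values (all-maximize) plus evaluation metadata."""

    names: list
    values: np.ndarray
    p: int
    criteria: CriteriaValues | None = None
    cost: CostBreakdown | None = None
    frozen: list = field(default_factory=list)
    design: DesignVector | None = None

    def as_dict(self) -> dict:
        return dict(zip(self.names, (float(v) for v in self.values)))


def repair_and_decode(raw, context: DesignContext) -> DesignVector:
    """Project a relaxed continuous vector onto the feasible design space.

    Fraction blocks are made nonnegative and normalized to the simplex —
    proportions are preserved, so (2, 1, 1) becomes (0.5, 0.25, 0.25); an
    all-zero block is repaired to the uniform mixture and logged.
    Replicate values are clipped to [0, n_max] and rounded half-up to
    integers. Deterministic.
    """
    x = np.asarray(raw, float)
    if x.shape != (context.n_vars,):
        raise ValueError(f"expected design vector of length {context.n_vars}")
    ns, ng = context.n_species, context.n_groups
    fracs, reps = [], []
    for c in range(context.n_cle):
        off = c * (ns + ng)
        f = np.maximum(x[off : off + ns], 0.0)
        total = f.sum()
        if total <= 0.0:
            logger.info("all-zero mixture block in CLE %d repaired to uniform", c)
            f = np.full(ns, 1.0 / ns)
        else:
            f = f / total
        r = np.floor(np.clip(x[off + ns : off + ns + ng], 0.0, context.n_max) + 0.5)
        r = r.astype(int)
        fracs.append(f)
        reps.append(np.clip(r, 0, context.n_max))
    return DesignVector(fractions=np.asarray(fracs), replicates=np.asarray(reps))


def evaluate_design(design: DesignVector, context: DesignContext) -> ObjectiveVector:
    """Score one executable protocol; deterministic given (design, context).

    Measurement blocks of all parallel experiments are concatenated before
    the identifiability analysis. A degenerate simulation (dead pool, zero
    group mass, no evaluated measurements) is not an error: the design is
    scored with p = 0 information and its actual cost, so the swarm keeps
    it and dominance removes it naturally.
    """
    if design.fractions.shape != (context.n_cle, context.n_species):
        raise ConfigurationError("design/context species blocks disagree")
    if design.replicates.shape != (context.n_cle, context.n_groups):
        raise ConfigurationError("design/context group blocks disagree")

    experiments = []
    for c in range(context.n_cle):
        mixture = context.mixture(design.fractions[c])
        setup = context.setup_template.with_replicates(design.replicates[c])
        experiments.append((mixture, setup))
    cost = total_cost(experiments, context.cost_params)

    jac_blocks, sig_blocks = [], []
    degenerate = False
    try:
        for mixture, setup in experiments:
            if not setup.active():
                continue
            state = solve_labeling(
                context.system, context.reference_state(), mixture
            )
            mvec = attach_sigmas(predict_measurements(state, setup), setup)

            def predict(lab_state, _setup=setup):
                return predict_measurements(lab_state, _setup).values

            J = labeling_jacobian(
                context.system,
                context.param,
                context.reference_free,
                mixture,
                predict,
            )
            jac_blocks.append(J)
            sig_blocks.append(mvec.sigmas)
    except (DegeneracyError, ConstraintError) as exc:
        logger.debug("design scored degenerate: %s", exc)
        degenerate = True

    if degenerate or not jac_blocks:
        fim_result = FimResult(
            fim=np.empty((0, 0)),
            cov=np.empty((0, 0)),
            p=0,
            retained=[],
            frozen=list(context.param.free_flux_names),
        )
    else:
        J = np.vstack(jac_blocks)
        sigma = np.concatenate(sig_blocks)
        fim_result = iterative_freeze(
            J, sigma, context.param.free_flux_names, context.criteria_config
        )
    crit = evaluate_criteria(fim_result)

    if context.objectives == "3D":
        values = np.array([float(crit.dof), crit.info_d, -cost.total])
    else:
        values = np.array(
            [float(crit.dof), crit.info_d, crit.info_a, crit.info_e, -cost.total]
        )
    return ObjectiveVector(
        names=context.objective_names,
        values=values,
        p=crit.dof,
        criteria=crit,
        cost=cost,
        frozen=list(fim_result.frozen),
        design=design,
    )
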