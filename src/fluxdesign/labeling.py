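"""Steady-state labeling simulation via the cumomer cascade.

At isotopic steady state the labeling state of every balanced pool is
determined by the flux distribution and the labeled substrate mixture. In
cumomer coordinates (a weight-``w`` cumomer of a pool is the joint
probability that a given set of ``w`` carbon positions is labeled) the
balance equations decompose into a cascade of *linear* systems, one per
weight level: the level-``w`` system only involves products of cumomers
whose weights sum to ``w``, hence at most one factor of weight ``w`` per
term — everything else is known from lower levels or from the input
patterns.

Isotopomer fractions are recovered from cumomers by Moebius inversion over
the subset lattice of carbon positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConstraintError, DegeneracyError
from .network import FluxParametrization, FluxState, MetabolicNetwork, expand_flux_state

__all__ = [
    "TracerSpecies",
    "TracerMixture",
    "CumomerSystem",
    "LabelingState",
    "build_cumomer_cascade",
    "solve_labeling",
    "labeling_jacobian",
    "input_isotopomer_distribution",
]


@dataclass(frozen=True)
class TracerSpecies:
    """A commercially available labeled form of the input metabolite.

    ``pattern`` marks the designed-to-be-labeled carbon positions;
    ``purity`` is the probability that such a position actually carries the
    heavy isotope (independently per position). Natural abundance at
    unlabeled positions is not modelled.
    """

    name: str
    pattern: tuple
    purity: float = 1.0
    price: float = 0.0

    def __post_init__(self):
        if not all(b in (0, 1) for b in self.pattern):
            raise ConfigurationError(
                f"tracer {self.name!r}: pattern entries must be 0/1"
            )
        if not 0.0 <= self.purity <= 1.0:
            raise ConfigurationError(
                f"tracer {self.name!r}: purity {self.purity} outside [0, 1]"
            )
        if self.price < 0:
            raise ConfigurationError(f"tracer {self.name!r}: negative price")

    @property
    def n_carbons(self) -> int:
        return len(self.pattern)

    def cumomer_vector(self) -> np.ndarray:
        """Cumomer values of the pure species over all 2^n position masks."""
        n = self.n_carbons
        probs = np.array([self.purity if b else 0.0 for b in self.pattern])
        out = np.empty(1 << n)
        for mask in range(1 << n):
            val = 1.0
            for i in range(n):
                if (mask >> i) & 1:
                    val *= probs[i]
            out[mask] = val
        return out

    def isotopomer_vector(self) -> np.ndarray:
        return _cumomers_to_isotopomers(self.cumomer_vector())


@dataclass
class TracerMixture:
    """Proportions of tracer species fed as the substrate of one pool.

    Fractions must lie on the unit simplex: sum to 1, each in [0, 1].
    """

    species: list[TracerSpecies]
    fractions: np.ndarray
    pool: str | None = None

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, float)
        if len(self.species) != self.fractions.size:
            raise ConfigurationError("one fraction per tracer species required")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise ConfigurationError("mixture fractions must lie in [0, 1]")
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ConfigurationError(
                f"mixture fractions sum to {self.fractions.sum():.6g}, expected 1"
            )
        ncs = {s.n_carbons for s in self.species}
        if len(ncs) > 1:
            raise ConfigurationError("tracer species differ in carbon count")

    @property
    def n_carbons(self) -> int:
        return self.species[0].n_carbons

    def cumomer_vector(self) -> np.ndarray:
        out = np.zeros(1 << self.n_carbons)
        for frac, sp in zip(self.fractions, self.species):
            if frac != 0.0:
                out += frac * sp.cumomer_vector()
        return out

    def as_dict(self) -> dict[str, float]:
        return {s.name: float(f) for s, f in zip(self.species, self.fractions)}


def input_isotopomer_distribution(mixture: TracerMixture) -> np.ndarray:
    """Isotopomer distribution of the mixed substrate."""
    return _cumomers_to_isotopomers(mixture.cumomer_vector())


def _cumomers_to_isotopomers(cum: np.ndarray) -> np.ndarray:
    """Moebius inversion: cum[m] = sum over isotopomers i >= m of iso[i]."""
    iso = cum.copy()
    n = int(np.log2(iso.size))
    for b in range(n):
        bit = 1 << b
        for m in range(iso.size):
            if not m & bit:
                iso[m] -= iso[m | bit]
    return iso


def _isotopomers_to_cumomers(iso: np.ndarray) -> np.ndarray:
    cum = iso.copy()
    n = int(np.log2(cum.size))
    for b in range(n):
        bit = 1 << b
        for m in range(cum.size):
            if not m & bit:
                cum[m] += cum[m | bit]
    return cum


# ---------------------------------------------------------------------------
# cascade construction
# ---------------------------------------------------------------------------


@dataclass
class _Term:
    """One production term: flux(reaction direction) x product of factors."""

    rxn_index: int  # index into directed reaction list
    same_level: int | None  # unknown index within the level, or None
    known_factors: tuple  # ((pool, mask), ...) resolved at solve time


@dataclass
class CumomerSystem:
    """Prebuilt cumomer cascade of one atom-mapped network.

    ``unknowns[w]`` lists the (pool, mask) pairs of weight-``w`` cumomers of
    balanced pools; ``terms[w][i]`` holds the production terms feeding
    unknown ``i`` of level ``w``. Directed reactions (forward plus, for
    reversible steps, backward) are shared across levels.
    """

    network: MetabolicNetwork
    directed: list  # (reaction, direction) with direction in {+1, -1}
    input_pools: list[str]
    unknowns: dict[int, list]  # weight -> [(pool, mask)]
    terms: dict[int, list]  # weight -> per-unknown [_Term, ...]
    consumption: dict[str, list] = field(default_factory=dict)  # pool -> [(rxn_idx, count)]
    max_weight: int = 0

    @property
    def level_sizes(self) -> dict[int, int]:
        return {w: len(u) for w, u in self.unknowns.items()}

    def directed_fluxes(self, fluxes: FluxState) -> np.ndarray:
        vals = np.empty(len(self.directed))
        for k, (rxn, direction) in enumerate(self.directed):
            vals[k] = (
                fluxes.forward(rxn.name) if direction > 0 else fluxes.backward(rxn.name)
            )
        return vals


def build_cumomer_cascade(network: MetabolicNetwork) -> CumomerSystem:
    """Assemble the level-by-level cumomer balance structure.

    Raises :class:`ConfigurationError` if a carbon-carrying reaction lacks
    atom transitions.
    """
    mets = network.metabolite_index
    balanced_carbon = [m for m in network.balanced_pools() if m.n_carbons > 0]

    for r in network.reactions:
        carbon_mets = [
            met
            for met, _ in (r.educts + r.products)
            if mets[met].n_carbons > 0
        ]
        mapped = {met for met, _ in (r.educt_instances + r.product_instances)}
        missing = [m for m in carbon_mets if m not in mapped]
        if missing:
            raise ConfigurationError(
                f"reaction {r.name!r}: no atom map for carbon-carrying "
                f"metabolite(s) {sorted(set(missing))}"
            )

    directed = []
    for r in network.reactions:
        directed.append((r, +1))
        if r.reversible:
            directed.append((r, -1))

    balanced_names = {m.name for m in balanced_carbon}
    input_pools = sorted(
        {
            met
            for r, d in directed
            for met, _ in (r.educt_instances if d > 0 else r.product_instances)
            if met not in balanced_names and not mets[met].balanced
        }
    )

    # consumption bookkeeping: how often each directed reaction consumes a pool
    consumption: dict[str, list] = {m.name: [] for m in balanced_carbon}
    for k, (r, d) in enumerate(directed):
        educt_side = r.educt_instances if d > 0 else r.product_instances
        counts: dict[str, int] = {}
        for met, _ in educt_side:
            counts[met] = counts.get(met, 0) + 1
        for met, c in counts.items():
            if met in consumption:
                consumption[met].append((k, c))

    max_weight = max((m.n_carbons for m in balanced_carbon), default=0)
    unknowns: dict[int, list] = {w: [] for w in range(1, max_weight + 1)}
    index: dict[tuple, tuple] = {}
    for m in balanced_carbon:
        for mask in range(1, 1 << m.n_carbons):
            w = bin(mask).count("1")
            index[(m.name, mask)] = (w, len(unknowns[w]))
            unknowns[w].append((m.name, mask))

    terms: dict[int, list] = {w: [[] for _ in unknowns[w]] for w in unknowns}
    for k, (r, d) in enumerate(directed):
        educt_side = r.educt_instances if d > 0 else r.product_instances
        product_side = r.product_instances if d > 0 else r.educt_instances
        amap = r.atom_map()
        if d > 0:
            origin = amap  # (prod_inst, pos) -> (educt_inst, pos)
        else:
            origin = {v: kk for kk, v in amap.items()}
        for pi, (pmet, _) in enumerate(product_side):
            if pmet not in balanced_names:
                continue
            npc = mets[pmet].n_carbons
            for mask in range(1, 1 << npc):
                w = bin(mask).count("1")
                # split the preimage of `mask` across educt instances
                sub: dict[int, int] = {}
                for pos in range(npc):
                    if (mask >> pos) & 1:
                        ei, epos = origin[(pi, pos)]
                        sub[ei] = sub.get(ei, 0) | (1 << epos)
                same_level = None
                known = []
                for ei, emask in sorted(sub.items()):
                    emet = educt_side[ei][0]
                    ew = bin(emask).count("1")
                    if ew == w and emet in balanced_names:
                        same_level = index[(emet, emask)][1]
                    else:
                        known.append((emet, emask))
                widx = index[(pmet, mask)][1]
                terms[w][widx].append(
                    _Term(rxn_index=k, same_level=same_level, known_factors=tuple(known))
                )

    return CumomerSystem(
        network=network,
        directed=directed,
        input_pools=input_pools,
        unknowns=unknowns,
        terms=terms,
        consumption=consumption,
        max_weight=max_weight,
    )


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


@dataclass
class LabelingState:
    """Per-pool cumomer and isotopomer fractions at isotopic steady state."""

    cumomers: dict[str, np.ndarray]
    network: MetabolicNetwork

    @property
    def isotopomers(self) -> dict[str, np.ndarray]:
        return {p: _cumomers_to_isotopomers(c) for p, c in self.cumomers.items()}

    def isotopomer_fractions(self, pool: str) -> np.ndarray:
        return _cumomers_to_isotopomers(self.cumomers[pool])

    def positional_enrichment(self, pool: str, position: int) -> float:
        """Fraction labeled at carbon `position` (0-based)."""
        return float(self.cumomers[pool][1 << position])

    def to_table(self) -> pd.DataFrame:
        rows = []
        mets = self.network.metabolite_index
        for pool, cum in sorted(self.cumomers.items()):
            n = mets[pool].n_carbons
            iso = _cumomers_to_isotopomers(cum)
            for mask in range(1 << n):
                bits = "".join("1" if (mask >> i) & 1 else "0" for i in range(n))
                rows.append(
                    {"pool": pool, "isotopomer": bits, "fraction": float(iso[mask])}
                )
        return pd.DataFrame(rows, columns=["pool", "isotopomer", "fraction"])


def _input_cumomers(system: CumomerSystem, mixture) -> dict[str, np.ndarray]:
    mets = system.network.metabolite_index
    per_pool: dict[str, TracerMixture] = {}
    if isinstance(mixture, TracerMixture):
        if len(system.input_pools) != 1 and mixture.pool is None:
            raise ConfigurationError(
                f"network has input pools {system.input_pools}; "
                "the mixture must name its pool"
            )
        pool = mixture.pool or system.input_pools[0]
        per_pool[pool] = mixture
    else:
        per_pool = dict(mixture)
    out = {}
    for pool in system.input_pools:
        n = mets[pool].n_carbons
        if pool in per_pool:
            mix = per_pool[pool]
            if mix.n_carbons != n:
                raise ConfigurationError(
                    f"mixture for pool {pool!r} has {mix.n_carbons} carbons, "
                    f"pool has {n}"
                )
            out[pool] = mix.cumomer_vector()
        else:
            vec = np.zeros(1 << n)
            vec[0] = 1.0  # unlabeled
            out[pool] = vec
    unknown = set(per_pool) - set(system.input_pools)
    if unknown:
        raise ConfigurationError(
            f"mixtures given for non-input pools: {sorted(unknown)}"
        )
    return out


def solve_labeling(
    system: CumomerSystem,
    fluxes: FluxState,
    mixture,
    residual_tol: float = 1e-10,
) -> LabelingState:
    """Solve the cascade bottom-up; deterministic direct solves per level.

    Requires every balanced pool to have strictly positive total outflux;
    a dead pool makes its level system singular and raises
    :class:`DegeneracyError` naming the pool.
    """
    flux_vals = system.directed_fluxes(fluxes)
    mets = system.network.metabolite_index

    outflux = {}
    for pool, consumers in system.consumption.items():
        total = sum(flux_vals[k] * c for k, c in consumers)
        if total <= 1e-12:
            raise DegeneracyError(
                f"pool {pool!r} has no outflux at this flux state (dead pool)"
            )
        outflux[pool] = total

    values: dict[str, np.ndarray] = {}
    for pool, cum in _input_cumomers(system, mixture).items():
        values[pool] = cum
    for pool in system.consumption:
        values[pool] = np.empty(1 << mets[pool].n_carbons)
        values[pool][0] = 1.0  # weight-0 cumomer

    for w in range(1, system.max_weight + 1):
        unknowns = system.unknowns[w]
        if not unknowns:
            continue
        nw = len(unknowns)
        A = np.zeros((nw, nw))
        rhs = np.zeros(nw)
        for i, (pool, _mask) in enumerate(unknowns):
            A[i, i] = outflux[pool]
            for term in system.terms[w][i]:
                f = flux_vals[term.rxn_index]
                if f == 0.0:
                    continue
                prod = f
                for kpool, kmask in term.known_factors:
                    prod *= values[kpool][kmask]
                if term.same_level is not None:
                    A[i, term.same_level] -= prod
                else:
                    rhs[i] += prod
        try:
            x = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise DegeneracyError(f"singular level-{w} cumomer system") from exc
        resid = np.max(np.abs(A @ x - rhs), initial=0.0)
        if resid > residual_tol * max(1.0, np.max(np.abs(rhs), initial=0.0)):
            raise DegeneracyError(
                f"level-{w} cumomer system ill-conditioned (residual {resid:.3g})"
            )
        for (pool, mask), xi in zip(unknowns, x):
            values[pool][mask] = xi

    cums = {p: values[p] for p in system.consumption}
    return LabelingState(cumomers=cums, network=system.network)


# ---------------------------------------------------------------------------
# sensitivities
# ---------------------------------------------------------------------------


def labeling_jacobian(
    system: CumomerSystem,
    param: FluxParametrization,
    free_values,
    mixture,
    measurement_map,
    step: float = 1e-6,
):
    """Finite-difference sensitivities d(eta)/d(v_free).

    ``free_values`` covers the full free set of ``param`` — net free fluxes
    followed by one exchange per reversible reaction (order of
    ``param.free_flux_names``). ``measurement_map`` maps a LabelingState to
    a 1-D measurement vector; central differences with per-coordinate step
    ``step * max(1, |v_i|)``, falling back to one-sided differencing with a
    warning when a perturbed point violates constraints.
    """
    theta = np.asarray(free_values, float)
    if theta.shape != (param.n_free,):
        raise ValueError(
            f"expected {param.n_free} free flux values "
            f"({param.free_flux_names}), got shape {theta.shape}"
        )

    def evaluate(vec):
        net = vec[: param.dof]
        xch = {
            nm: vec[param.dof + i]
            for i, nm in enumerate(param.free_exchange_names)
        }
        state = expand_flux_state(param, net, exchanges=xch, check=True)
        lab = solve_labeling(system, state, mixture)
        return np.asarray(measurement_map(lab), float)

    eta0 = evaluate(theta)
    J = np.zeros((eta0.size, theta.size))
    for i in range(theta.size):
        h = step * max(1.0, abs(theta[i]))
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        try:
            eta_up = evaluate(up)
            ok_up = True
        except (ConstraintError, DegeneracyError):
            ok_up = False
        try:
            eta_dn = evaluate(dn)
            ok_dn = True
        except (ConstraintError, DegeneracyError):
            ok_dn = False
        if ok_up and ok_dn:
            J[:, i] = (eta_up - eta_dn) / (2 * h)
        elif ok_up:
            warnings.warn(
                f"one-sided differencing for {param.free_flux_names[i]!r} "
                "(design point on a constraint boundary)"
            )
            J[:, i] = (eta_up - eta0) / h
        elif ok_dn:
            warnings.warn(
                f"one-sided differencing for {param.free_flux_names[i]!r} "
                "(design point on a constraint boundary)"
            )
            J[:, i] = (eta0 - eta_dn) / h
        else:
            raise ConstraintError(
                f"cannot perturb free flux {param.free_flux_names[i]!r} in "
                "either direction"
            )
    return J

# default exchange treatment: zero-exchange reversible steps behave as
# irreversible at the design point (backward flux identically zero).
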