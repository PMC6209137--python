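"""Atom-mapped metabolic networks and free-flux parametrization.

A network couples a stoichiometric model ``S·v = b`` (balances of the
intracellular pools plus measured extracellular rates) with per-reaction
carbon atom transitions written in the compact ``A#ab + B#c -> C#abc``
notation: each lower-case letter names one carbon atom, letters on the educt
side must reappear exactly once on the product side, so the atom map is a
bijection between educt and product carbons.

Reversible reactions carry a (net, exchange) flux pair; the unidirectional
rates follow the standard convention::

    forward  = exchange + max(net, 0)
    backward = exchange + max(-net, 0)

Because ``S`` is rank deficient on realistic networks, the steady-state flux
space is parametrized by a deterministic choice of *free* net fluxes (the
kernel coordinates of the constrained system) plus one exchange flux per
reversible reaction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConstraintError, InfeasibleError, NetworkValidationError

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "FluxParametrization",
    "FluxState",
    "load_network",
    "save_network",
    "stoichiometric_analysis",
    "expand_flux_state",
]

#: singular values below RANK_TOL x largest are treated as zero
RANK_TOL = 1e-10


@dataclass(frozen=True)
class Metabolite:
    name: str
    n_carbons: int
    balanced: bool = True

    def __post_init__(self):
        if self.n_carbons < 0:
            raise NetworkValidationError(
                f"metabolite {self.name!r}: n_carbons must be >= 0"
            )


_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?([A-Za-z_][\w.-]*)(?:#([a-zA-Z]+))?$")


def _parse_side(side: str, rxn: str):
    """Parse one side of an equation into [(name, coeff, atoms-or-None), ...]."""
    terms = []
    for raw in side.split("+"):
        raw = raw.strip()
        if not raw:
            raise NetworkValidationError(f"reaction {rxn!r}: empty term in equation")
        m = _TERM_RE.match(raw)
        if m is None:
            raise NetworkValidationError(
                f"reaction {rxn!r}: cannot parse term {raw!r}"
            )
        coeff = float(m.group(1)) if m.group(1) else 1.0
        if coeff <= 0:
            raise NetworkValidationError(
                f"reaction {rxn!r}: nonpositive coefficient in term {raw!r}"
            )
        terms.append((m.group(2), coeff, m.group(3)))
    return terms


@dataclass(frozen=True)
class Reaction:
    """One reaction step with its carbon atom transitions.

    ``educt_instances`` / ``product_instances`` are ``(metabolite, atoms)``
    pairs, one per occurrence of a carbon-carrying metabolite in the
    equation (``atoms`` is the per-instance letter string, ``None`` for
    carbon-free species). ``educts`` / ``products`` aggregate instances into
    ``(name, coefficient)`` pairs.
    """

    name: str
    equation: str
    reversible: bool = False
    educt_instances: tuple = ()
    product_instances: tuple = ()

    @staticmethod
    def parse(name: str, equation: str, reversible: bool = False) -> "Reaction":
        if "->" not in equation:
            raise NetworkValidationError(f"reaction {name!r}: missing '->'")
        lhs, rhs = equation.split("->", 1)
        edu, pro = [], []
        for side, out in ((lhs, edu), (rhs, pro)):
            for met, coeff, atoms in _parse_side(side, name):
                if atoms is not None:
                    # expand integral coefficients into explicit instances
                    n = int(round(coeff))
                    if abs(coeff - n) > 1e-12:
                        raise NetworkValidationError(
                            f"reaction {name!r}: fractional coefficient on "
                            f"carbon-mapped species {met!r}"
                        )
                    out.extend([(met, atoms)] * n)
                else:
                    out.append((met, coeff))
        educt_instances = tuple((m, a) for m, a in edu if isinstance(a, str))
        product_instances = tuple((m, a) for m, a in pro if isinstance(a, str))
        return Reaction(
            name=name,
            equation=equation,
            reversible=bool(reversible),
            educt_instances=educt_instances,
            product_instances=product_instances,
        )

    def _side_terms(self, side_index):
        lhs, rhs = self.equation.split("->", 1)
        return _parse_side((lhs, rhs)[side_index], self.name)

    @property
    def educts(self):
        return self._aggregate(0)

    @property
    def products(self):
        return self._aggregate(1)

    def _aggregate(self, side_index):
        agg: dict[str, float] = {}
        for met, coeff, _ in self._side_terms(side_index):
            agg[met] = agg.get(met, 0.0) + coeff
        return list(agg.items())

    def atom_letters(self):
        """(educt letters joined, product letters joined)."""
        e = "".join(a for _, a in self.educt_instances)
        p = "".join(a for _, a in self.product_instances)
        return e, p

    def atom_map(self):
        """Map (product_instance, product_pos) -> (educt_instance, educt_pos)."""
        origin = {}
        for ei, (_, atoms) in enumerate(self.educt_instances):
            for pos, letter in enumerate(atoms):
                if letter in origin:
                    raise NetworkValidationError(
                        f"reaction {self.name!r}: atom letter {letter!r} used "
                        "twice on the educt side"
                    )
                origin[letter] = (ei, pos)
        amap = {}
        seen = set()
        for pi, (_, atoms) in enumerate(self.product_instances):
            for pos, letter in enumerate(atoms):
                if letter not in origin:
                    raise NetworkValidationError(
                        f"reaction {self.name!r}: product atom {letter!r} has "
                        "no educt origin"
                    )
                if letter in seen:
                    raise NetworkValidationError(
                        f"reaction {self.name!r}: atom letter {letter!r} used "
                        "twice on the product side"
                    )
                seen.add(letter)
                amap[(pi, pos)] = origin[letter]
        if seen != set(origin):
            missing = sorted(set(origin) - seen)
            raise NetworkValidationError(
                f"reaction {self.name!r}: educt atoms {missing} do not appear "
                "on the product side (atom map must be a bijection)"
            )
        return amap


@dataclass
class MetabolicNetwork:
    """Validated network: metabolites, reactions, rates and constraints."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    extracellular_rates: dict[str, float] = field(default_factory=dict)
    inequality_constraints: tuple | None = None  # (C_ieq, c_ieq) over reaction order
    flux_bounds: dict[str, tuple] = field(default_factory=dict)
    name: str = "network"

    def __post_init__(self):
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_index(self) -> dict[str, Metabolite]:
        return {m.name: m for m in self.metabolites}

    @property
    def reaction_names(self) -> list[str]:
        return [r.name for r in self.reactions]

    def balanced_pools(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.balanced]

    def validate(self):
        seen = set()
        for m in self.metabolites:
            if m.name in seen:
                raise NetworkValidationError(f"duplicate metabolite name {m.name!r}")
            seen.add(m.name)
        mets = self.metabolite_index
        rseen = set()
        used = set()
        for r in self.reactions:
            if r.name in rseen:
                raise NetworkValidationError(f"duplicate reaction name {r.name!r}")
            rseen.add(r.name)
            for side in (r.educts, r.products):
                for met, _ in side:
                    if met not in mets:
                        raise NetworkValidationError(
                            f"reaction {r.name!r}: undeclared metabolite {met!r}"
                        )
                    used.add(met)
            for met, atoms in r.educt_instances + r.product_instances:
                if met not in mets:
                    raise NetworkValidationError(
                        f"reaction {r.name!r}: undeclared metabolite {met!r}"
                    )
                if len(atoms) != mets[met].n_carbons:
                    raise NetworkValidationError(
                        f"reaction {r.name!r}: atom string {atoms!r} assigns "
                        f"{len(atoms)} carbons to metabolite {met!r} which has "
                        f"{mets[met].n_carbons}"
                    )
            r.atom_map()  # raises on non-bijective transitions
        for rate_name in self.extracellular_rates:
            if rate_name not in rseen:
                raise NetworkValidationError(
                    f"extracellular rate references unknown reaction {rate_name!r}"
                )
        for bname in self.flux_bounds:
            if bname not in rseen:
                raise NetworkValidationError(
                    f"flux bound references unknown reaction {bname!r}"
                )
        for m in self.balanced_pools():
            if m.name not in used:
                raise NetworkValidationError(
                    f"balanced metabolite {m.name!r} appears in no reaction"
                )

    def stoichiometric_matrix(self):
        """(S, pools): net stoichiometry of balanced pools x reactions."""
        pools = self.balanced_pools()
        pidx = {m.name: i for i, m in enumerate(pools)}
        S = np.zeros((len(pools), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coeff in r.educts:
                if met in pidx:
                    S[pidx[met], j] -= coeff
            for met, coeff in r.products:
                if met in pidx:
                    S[pidx[met], j] += coeff
        return S, pools

    def default_bounds(self):
        """Per-reaction (lo, hi) net-flux bounds.

        Irreversible reactions default to [0, inf); reversible ones are
        unbounded. Explicit ``flux_bounds`` override.
        """
        out = {}
        for r in self.reactions:
            lo, hi = (0.0, np.inf) if not r.reversible else (-np.inf, np.inf)
            if r.name in self.flux_bounds:
                lo, hi = self.flux_bounds[r.name]
                lo = -np.inf if lo is None else float(lo)
                hi = np.inf if hi is None else float(hi)
            out[r.name] = (lo, hi)
        return out

    def without_rates(self) -> "MetabolicNetwork":
        """Copy with measured extracellular rates dropped (unconstrained)."""
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            extracellular_rates={},
            inequality_constraints=self.inequality_constraints,
            flux_bounds=dict(self.flux_bounds),
            name=self.name,
        )


# ---------------------------------------------------------------------------
# schema i/o
# ---------------------------------------------------------------------------


def load_network(document) -> MetabolicNetwork:
    """Read a network from its YAML document (path, text, or mapping)."""
    if isinstance(document, dict):
        doc = document
    else:
        text = document
        try:
            import os

            if os.path.exists(str(document)):
                with open(document) as fh:
                    text = fh.read()
        except (OSError, ValueError):
            pass
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise NetworkValidationError("network document must be a mapping")
    mets = []
    for rec in doc.get("metabolites", []):
        mets.append(
            Metabolite(
                name=str(rec["name"]),
                n_carbons=int(rec.get("carbons", 0)),
                balanced=bool(rec.get("balanced", True)),
            )
        )
    rxns = []
    for rec in doc.get("reactions", []):
        rxns.append(
            Reaction.parse(
                str(rec["name"]), str(rec["equation"]), bool(rec.get("reversible", False))
            )
        )
    ieq = None
    if doc.get("inequalities"):
        rnames = [r.name for r in rxns]
        rows, rhs = [], []
        for rec in doc["inequalities"]:
            row = np.zeros(len(rnames))
            for met, coef in rec["coeffs"].items():
                if met not in rnames:
                    raise NetworkValidationError(
                        f"inequality references unknown reaction {met!r}"
                    )
                row[rnames.index(met)] = float(coef)
            rows.append(row)
            rhs.append(float(rec["rhs"]))
        ieq = (np.asarray(rows), np.asarray(rhs))
    bounds = {
        str(k): (v[0], v[1]) for k, v in (doc.get("bounds") or {}).items()
    }
    rates = {str(k): float(v) for k, v in (doc.get("rates") or {}).items()}
    return MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        extracellular_rates=rates,
        inequality_constraints=ieq,
        flux_bounds=bounds,
        name=str(doc.get("name", "network")),
    )


def save_network(network: MetabolicNetwork, path=None) -> str:
    """Serialize to the YAML schema; round-trip stable with load_network."""
    doc = {
        "name": network.name,
        "metabolites": [
            {"name": m.name, "carbons": m.n_carbons, "balanced": m.balanced}
            for m in network.metabolites
        ],
        "reactions": [
            {"name": r.name, "equation": r.equation, "reversible": r.reversible}
            for r in network.reactions
        ],
    }
    if network.extracellular_rates:
        doc["rates"] = dict(network.extracellular_rates)
    if network.flux_bounds:
        doc["bounds"] = {k: list(v) for k, v in network.flux_bounds.items()}
    if network.inequality_constraints is not None:
        C, c = network.inequality_constraints
        rnames = network.reaction_names
        doc["inequalities"] = [
            {
                "coeffs": {
                    rnames[j]: float(C[i, j])
                    for j in range(C.shape[1])
                    if C[i, j] != 0.0
                },
                "rhs": float(c[i]),
            }
            for i in range(C.shape[0])
        ]
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# free-flux parametrization
# ---------------------------------------------------------------------------


@dataclass
class FluxParametrization:
    """Deterministic free-flux parametrization of the constrained flux space.

    ``v_net = particular_solution + kernel_basis @ free_values`` reproduces
    every steady-state net flux vector; ``free_values`` are the net fluxes of
    the reactions in ``free_net_names`` themselves (the basis is pivoted so
    that the free coordinates read through unchanged).
    """

    network: MetabolicNetwork
    free_net_names: list[str]
    free_exchange_names: list[str]
    particular_solution: np.ndarray
    kernel_basis: np.ndarray  # (n_reactions, dof)
    dof: int

    @property
    def free_flux_names(self) -> list[str]:
        return list(self.free_net_names) + [
            f"{n}.xch" for n in self.free_exchange_names
        ]

    @property
    def n_free(self) -> int:
        return self.dof + len(self.free_exchange_names)

    def net_vector(self, free_values) -> np.ndarray:
        w = np.asarray(free_values, float)
        if w.shape != (self.dof,):
            raise ValueError(
                f"expected {self.dof} free net flux values, got {w.shape}"
            )
        return self.particular_solution + self.kernel_basis @ w

    def extract_free(self, net: dict[str, float]) -> np.ndarray:
        return np.array([net[n] for n in self.free_net_names])


def _rank(a, tol_rel=RANK_TOL):
    if a.size == 0:
        return 0
    s = np.linalg.svd(a, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > tol_rel * s[0]))


def stoichiometric_analysis(
    network: MetabolicNetwork, preferred=None
) -> FluxParametrization:
    """Build the free-flux parametrization of ``S·v = b``.

    Measured extracellular rates enter as equality rows appended to the
    balance system. The free net fluxes are chosen greedily: candidate
    reactions in ``preferred`` order first, then declaration order, keeping
    a reaction whenever it enlarges the rank of the selected kernel rows —
    a deterministic column-pivoted choice.
    """
    S, _ = network.stoichiometric_matrix()
    n_rx = len(network.reactions)
    rnames = network.reaction_names
    rows = [S]
    rhs = [np.zeros(S.shape[0])]
    for rate_name, value in network.extracellular_rates.items():
        e = np.zeros(n_rx)
        e[rnames.index(rate_name)] = 1.0
        rows.append(e[None, :])
        rhs.append(np.array([value]))
    A = np.vstack(rows)
    b = np.concatenate(rhs)

    rank = _rank(A)
    dof = n_rx - rank
    particular, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = A @ particular - b
    if np.max(np.abs(resid), initial=0.0) > 1e-8 * max(1.0, np.max(np.abs(b), initial=0.0)):
        raise InfeasibleError(
            f"equality system of network {network.name!r} has no solution "
            f"(residual {np.max(np.abs(resid)):.3g})"
        )

    # nullspace of A
    if dof > 0:
        _, s, vt = np.linalg.svd(A)
        null = vt[rank:, :].T  # (n_rx, dof)
    else:
        null = np.zeros((n_rx, 0))

    order = []
    if preferred:
        for nm in preferred:
            if nm in rnames and nm not in order:
                order.append(nm)
    for nm in rnames:
        if nm not in order:
            order.append(nm)

    selected: list[int] = []
    for nm in order:
        if len(selected) == dof:
            break
        idx = rnames.index(nm)
        trial = null[selected + [idx], :]
        if _rank(trial) > _rank(null[selected, :]):
            selected.append(idx)
    if len(selected) != dof:
        raise InfeasibleError(
            f"could not select {dof} independent free fluxes for {network.name!r}"
        )

    if dof > 0:
        NF = null[selected, :]  # (dof, dof), invertible by construction
        T = null @ np.linalg.inv(NF)  # (n_rx, dof)
        v0 = particular - T @ particular[selected]
    else:
        T = np.zeros((n_rx, 0))
        v0 = particular
    free_net = [rnames[i] for i in selected]
    free_xch = [r.name for r in network.reactions if r.reversible]
    return FluxParametrization(
        network=network,
        free_net_names=free_net,
        free_exchange_names=free_xch,
        particular_solution=v0,
        kernel_basis=T,
        dof=dof,
    )


@dataclass
class FluxState:
    """Full flux state: signed net rates plus nonnegative exchange rates."""

    net: dict[str, float]
    exchange: dict[str, float]

    def forward(self, name: str) -> float:
        return self.exchange.get(name, 0.0) + max(self.net[name], 0.0)

    def backward(self, name: str) -> float:
        return self.exchange.get(name, 0.0) + max(-self.net[name], 0.0)


def expand_flux_state(
    param: FluxParametrization,
    free_values,
    exchanges=None,
    check: bool = True,
    tol: float = 1e-9,
) -> FluxState:
    """Expand free net fluxes (and optional exchanges) to a full FluxState.

    ``exchanges`` maps reversible reaction names to nonnegative exchange
    rates (missing entries default to zero). With ``check``, bound and
    inequality violations raise :class:`ConstraintError` listing the rows.
    """
    w = np.asarray(free_values, float)
    if not np.all(np.isfinite(w)):
        raise ValueError("free flux values must be finite")
    v = param.net_vector(w)
    network = param.network
    net = dict(zip(network.reaction_names, v))
    xch = {}
    exchanges = exchanges or {}
    for nm in param.free_exchange_names:
        val = float(exchanges.get(nm, 0.0))
        if val < 0:
            raise ConstraintError(
                f"exchange flux of {nm!r} must be nonnegative", [nm]
            )
        xch[nm] = val
    unknown = set(exchanges) - set(param.free_exchange_names)
    if unknown:
        raise ConstraintError(
            f"exchange values given for irreversible reactions: {sorted(unknown)}",
            sorted(unknown),
        )

    if check:
        violations = []
        for nm, (lo, hi) in network.default_bounds().items():
            val = net[nm]
            if val < lo - tol or val > hi + tol:
                violations.append(f"bound {nm}: {val:.6g} not in [{lo:.6g}, {hi:.6g}]")
        if network.inequality_constraints is not None:
            C, c = network.inequality_constraints
            g = C @ v - c
            for i, gi in enumerate(g):
                if gi > tol:
                    violations.append(f"inequality row {i}: excess {gi:.6g}")
        if violations:
            raise ConstraintError(
                "flux state violates constraints:\n  " + "\n  ".join(violations),
                violations,
            )
    return FluxState(net=net, exchange=xch)
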