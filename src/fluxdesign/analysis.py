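"""Post-processing of Pareto archives: clustering, robustness, exports.

The archive of trade-off designs is condensed for decision making:
mixtures are hierarchically clustered (composition + information + cost,
each min-max scaled, Euclidean distance, average linkage), the local
information criteria are stress-tested by re-evaluating the design at flux
vectors sampled in the bounding box of the confidence ellipsoid, and flat
tables are exported for external plotting tools — front scatter data,
chord-diagram link tables (Circos-style), per-group replicate histograms
and ternary mixture coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .criteria import FimResult, compute_fim
from .design import DesignContext, DesignVector, ObjectiveVector
from .errors import ConfigurationError, ConstraintError, DegeneracyError
from .labeling import labeling_jacobian, solve_labeling
from .measurements import attach_sigmas, predict_measurements
from .moo import ParetoArchive
from .network import expand_flux_state

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureCluster",
    "RobustnessReport",
    "archive_entries",
    "front_table",
    "cluster_mixtures",
    "robustness_sample",
    "export_results",
]

#: species below this mixture fraction are suppressed in displays
DISPLAY_FRACTION_FLOOR = 0.01


def archive_entries(archive: ParetoArchive):
    """Yield (objectives, ObjectiveVector) regardless of payload wrapping."""
    out = []
    for obj, payload in archive.entries:
        result = payload
        if isinstance(payload, dict) and "payload" in payload:
            result = payload["payload"]
        if not isinstance(result, ObjectiveVector):
            raise ConfigurationError(
                "archive entries must carry design evaluation payloads"
            )
        out.append((obj, result))
    return out


def front_table(archive: ParetoArchive, context: DesignContext) -> pd.DataFrame:
    """One row per archive design: objectives, criteria, itemized costs."""
    rows = []
    for i, (obj, res) in enumerate(archive_entries(archive)):
        row = {"design_id": i}
        row.update({name: float(v) for name, v in zip(res.names, obj)})
        row.update(
            p=res.p,
            phi_d=res.criteria.phi_d,
            phi_a=res.criteria.phi_a,
            phi_e=res.criteria.phi_e,
            cost_experimental=res.cost.experimental,
            cost_analytical=res.cost.analytical,
            cost_total=res.cost.total,
            frozen=";".join(res.frozen),
            design=res.design.to_json(context),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _mixture_matrix(entries, context: DesignContext) -> np.ndarray:
    """Per-design mean mixture composition across parallel experiments."""
    return np.vstack(
        [res.design.fractions.mean(axis=0) for _, res in entries]
    )


@dataclass
class MixtureCluster:
    """One cluster of similar Pareto-optimal mixtures."""

    label: int
    members: list  # design ids
    mean_composition: dict  # species -> mean fraction (simplex)
    info_range: tuple
    cost_range: tuple
    frequency: float

    def display_composition(self) -> dict:
        """Mean composition with components below 1% suppressed."""
        return {
            k: v
            for k, v in self.mean_composition.items()
            if v >= DISPLAY_FRACTION_FLOOR
        }


def _minmax(col: np.ndarray) -> np.ndarray:
    span = col.max() - col.min()
    if span <= 0:
        return np.zeros_like(col)
    return (col - col.min()) / span


def cluster_mixtures(
    archive: ParetoArchive,
    context: DesignContext,
    k: int | None = None,
    distance_threshold: float | None = None,
    p: int | None = None,
):
    """Hierarchical clustering of the archive's mixture designs.

    Feature vector per design: mixture fractions, information value and
    total cost, each min-max scaled to [0, 1]; Euclidean distance, average
    linkage. Cut either at ``k`` clusters or at a ``distance_threshold``.
    ``p`` filters the archive to one model dimensionality first (mixed-p
    archives are not directly comparable).

    Returns ``(clusters, merges)`` where ``merges`` is the dendrogram merge
    table (scipy linkage rows: left, right, distance, size).
    """
    entries = archive_entries(archive)
    if p is not None:
        entries = [(o, r) for o, r in entries if r.p == p]
    if not entries:
        return [], pd.DataFrame(columns=["left", "right", "distance", "size"])
    comp = _mixture_matrix(entries, context)
    info = np.array([r.criteria.info_d for _, r in entries])
    cost = np.array([r.cost.total for _, r in entries])
    feats = np.column_stack(
        [np.apply_along_axis(_minmax, 0, comp), _minmax(info), _minmax(cost)]
    )
    species_names = [s.name for s in context.species]

    if len(entries) == 1:
        labels = np.array([1])
        merges = pd.DataFrame(columns=["left", "right", "distance", "size"])
    else:
        Z = hierarchy.linkage(feats, method="average", metric="euclidean")
        merges = pd.DataFrame(Z, columns=["left", "right", "distance", "size"])
        if k is not None:
            labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        elif distance_threshold is not None:
            labels = hierarchy.fcluster(Z, t=distance_threshold, criterion="distance")
        else:
            labels = hierarchy.fcluster(Z, t=min(4, len(entries)), criterion="maxclust")

    clusters = []
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        mean_comp = comp[idx].mean(axis=0)
        mean_comp = mean_comp / mean_comp.sum()
        clusters.append(
            MixtureCluster(
                label=int(lab),
                members=idx,
                mean_composition=dict(zip(species_names, mean_comp)),
                info_range=(float(info[idx].min()), float(info[idx].max())),
                cost_range=(float(cost[idx].min()), float(cost[idx].max())),
                frequency=len(idx) / len(entries),
            )
        )
    return clusters, merges


# ---------------------------------------------------------------------------
# robustness of the local information criteria
# ---------------------------------------------------------------------------


@dataclass
class RobustnessReport:
    """Information-criterion values at flux vectors around the design point."""

    n: int
    seed: int
    phi_d: np.ndarray  # dispersion values, one per sample
    reference_phi_d: float
    quantiles: dict = field(default_factory=dict)
    fraction_top_tercile: float = 0.0
    n_rejected: int = 0

    @property
    def info_values(self) -> np.ndarray:
        return 1.0 / self.phi_d

    @property
    def mean_phi_d(self) -> float:
        return float(np.mean(self.phi_d))


def robustness_sample(
    design: DesignVector,
    fim_result: FimResult,
    context: DesignContext,
    n: int,
    seed: int,
    z: float = 1.96,
) -> RobustnessReport:
    """Re-evaluate the D-criterion at fluxes sampled around the reference.

    Samples are drawn uniformly in the axis-aligned bounding box of the
    confidence ellipsoid — half-widths ``z * sqrt(diag(Cov))`` on the
    retained free fluxes, frozen fluxes staying at nominal. Infeasible
    draws (constraint violations, dead pools) are rejected and redrawn.
    The FIM at each sample is evaluated on the same retained flux set as
    the reference result so the criterion dimension stays fixed.
    """
    if n <= 0:
        raise ConfigurationError("robustness sampling needs n >= 1")
    if fim_result.p < 1:
        raise ConfigurationError("robustness sampling needs p >= 1")
    rng = np.random.default_rng(seed)

    names = context.param.free_flux_names
    retained_idx = [names.index(nm) for nm in fim_result.retained]
    half = z * np.sqrt(np.diag(fim_result.cov))
    ref = context.reference_free

    experiments = []
    for c in range(context.n_cle):
        mixture = context.mixture(design.fractions[c])
        setup = context.setup_template.with_replicates(design.replicates[c])
        if setup.active():
            experiments.append((mixture, setup))
    if not experiments:
        raise ConfigurationError("design evaluates no measurement groups")

    def phi_d_at(free_vec) -> float:
        jac_blocks, sig_blocks = [], []
        for mixture, setup in experiments:
            net = free_vec[: context.param.dof]
            xch = {
                nm: float(free_vec[context.param.dof + i])
                for i, nm in enumerate(context.param.free_exchange_names)
            }
            state = expand_flux_state(context.param, net, exchanges=xch)
            lab = solve_labeling(context.system, state, mixture)
            mvec = attach_sigmas(predict_measurements(lab, setup), setup)

            def predict(ls, _setup=setup):
                return predict_measurements(ls, _setup).values

            J = labeling_jacobian(
                context.system, context.param, free_vec, mixture, predict
            )
            jac_blocks.append(J[:, retained_idx])
            sig_blocks.append(mvec.sigmas)
        fim = compute_fim(np.vstack(jac_blocks), np.concatenate(sig_blocks))
        sign, logdet = np.linalg.slogdet(fim)
        if sign <= 0:
            raise DegeneracyError("information matrix singular at sample")
        # det(Cov) = 1/det(FIM)
        return float(np.exp(-logdet / (2 * fim_result.p)))

    reference_phi = phi_d_at(ref)

    degenerate_box = bool(np.all(half < 1e-12))
    values = np.empty(n)
    rejected = 0
    max_attempts = 100 * n + 100
    attempts = 0
    filled = 0
    while filled < n:
        if attempts > max_attempts:
            raise DegeneracyError(
                "robustness sampling rejected too many infeasible draws"
            )
        attempts += 1
        if degenerate_box:
            values[filled] = reference_phi
            filled += 1
            continue
        sample = ref.copy()
        offsets = rng.uniform(-1.0, 1.0, size=len(retained_idx))
        for j, idx in enumerate(retained_idx):
            sample[idx] += offsets[j] * half[j]
        # exchanges must stay nonnegative
        if np.any(sample[context.param.dof :] < 0):
            rejected += 1
            continue
        try:
            values[filled] = phi_d_at(sample)
        except (ConstraintError, DegeneracyError):
            rejected += 1
            continue
        filled += 1

    qs = {q: float(np.quantile(values, q / 100)) for q in (5, 25, 50, 75, 95)}
    info = 1.0 / values
    lo, hi = info.min(), info.max()
    if hi > lo:
        frac_top = float(np.mean(info >= lo + 2.0 / 3.0 * (hi - lo)))
    else:
        frac_top = 1.0
    return RobustnessReport(
        n=n,
        seed=seed,
        phi_d=values,
        reference_phi_d=reference_phi,
        quantiles=qs,
        fraction_top_tercile=frac_top,
        n_rejected=rejected,
    )


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def export_results(archive: ParetoArchive, context: DesignContext) -> dict:
    """Flat tables for external plotting.

    Returns a dict with keys ``front`` (objectives + cost breakdown),
    ``chord_links`` (one row per design x species at >= 1%, with all
    objectives min-max scaled to 0–100), ``mixture_histogram`` (5%-wide
    bins of proposed fractions per species), ``replicate_histogram``
    (per-group replicate frequencies) and ``ternary`` (three-species
    coordinates, or None unless exactly three species are active).
    """
    entries = archive_entries(archive)
    if not entries:
        raise ConfigurationError("cannot export an empty archive")
    front = front_table(archive, context)

    objs = np.vstack([o for o, _ in entries])
    scaled = np.column_stack(
        [100.0 * _minmax(objs[:, k]) for k in range(objs.shape[1])]
    )
    names = entries[0][1].names
    species_names = [s.name for s in context.species]
    comp = _mixture_matrix(entries, context)

    link_rows = []
    for i, (_, res) in enumerate(entries):
        for j, sp in enumerate(species_names):
            frac = comp[i, j]
            if frac < DISPLAY_FRACTION_FLOOR:
                continue
            row = {"design_id": i, "species": sp, "fraction": float(frac)}
            row.update(
                {f"{nm}_pct": float(scaled[i, k]) for k, nm in enumerate(names)}
            )
            link_rows.append(row)
    chord_links = pd.DataFrame(link_rows)

    hist_rows = []
    edges = np.arange(0.0, 1.0 + 1e-9, 0.05)
    for j, sp in enumerate(species_names):
        counts, _ = np.histogram(comp[:, j], bins=edges)
        for b, cnt in enumerate(counts):
            if cnt == 0:
                continue
            hist_rows.append(
                {
                    "species": sp,
                    "bin_low": float(edges[b]),
                    "bin_high": float(edges[b + 1]),
                    "count": int(cnt),
                    "frequency": cnt / len(entries),
                }
            )
    mixture_histogram = pd.DataFrame(hist_rows)

    rep_rows = []
    groups = context.setup_template.groups
    reps = np.stack(
        [res.design.replicates.mean(axis=0) for _, res in entries]
    )
    for g_idx, g in enumerate(groups):
        vals, counts = np.unique(reps[:, g_idx].astype(int), return_counts=True)
        for v, cnt in zip(vals, counts):
            rep_rows.append(
                {
                    "group": g.name,
                    "n_rep": int(v),
                    "count": int(cnt),
                    "frequency": cnt / len(entries),
                }
            )
    replicate_histogram = pd.DataFrame(rep_rows)

    active = [
        j
        for j in range(len(species_names))
        if np.any(comp[:, j] >= DISPLAY_FRACTION_FLOOR)
    ]
    ternary = None
    if len(active) == 3:
        tern_rows = []
        for i in range(len(entries)):
            tri = comp[i, active]
            total = tri.sum()
            if total <= 0:
                continue
            tri = tri / total
            tern_rows.append(
                {
                    "design_id": i,
                    species_names[active[0]]: float(tri[0]),
                    species_names[active[1]]: float(tri[1]),
                    species_names[active[2]]: float(tri[2]),
                }
            )
        ternary = pd.DataFrame(tern_rows)
    else:
        logger.info(
            "ternary export skipped: %d active species (needs exactly 3)",
            len(active),
        )

    return {
        "front": front,
        "chord_links": chord_links,
        "mixture_histogram": mixture_histogram,
        "replicate_histogram": replicate_histogram,
        "ternary": ternary,
    }
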