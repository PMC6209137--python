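"""Measurement groups, device observations and linear error models.

A *measurement group* is the set of jointly acquired observations of one
analyte on one device — a mass isotopomer distribution, a set of positional
enrichments, joint precursor/fragment mass pairs of a tandem-MS scan, or a
single total-enrichment value. Each row is a nonnegative linear functional
over isotopomer space; normalized groups are rescaled to sum to one before
they are compared with (percentage-scale) data, and all downstream
sensitivities are taken of the normalized prediction.

Expected standard deviations come from device-specific linear error models
``sigma = a(n_rep) * (b1 * eta + b2)`` where the replicate factor ``a``
shrinks towards 1 as the number of technical replicates grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegeneracyError
from .labeling import LabelingState

__all__ = [
    "MeasurementGroup",
    "ErrorModel",
    "MeasurementSetup",
    "MeasurementVector",
    "predict_measurements",
    "evaluate_error_model",
    "replicate_scaling_factor",
    "make_device_templates",
]


@dataclass
class MeasurementGroup:
    """A block of the measurement matrix for one analyte on one device.

    ``rows`` is a list of mappings ``pool -> coefficient vector`` over that
    pool's 2^n isotopomer coordinates (most groups touch a single pool).
    ``n_peaks`` is the number of spectral peaks evaluated per replicate,
    used by the cost model; it defaults to the number of rows.
    """

    device: str
    name: str
    rows: list
    row_labels: list | None = None
    n_peaks: int = 0
    normalize: bool = False

    def __post_init__(self):
        if not self.rows:
            raise ConfigurationError(f"group {self.name!r}: no rows")
        for r, row in enumerate(self.rows):
            for pool, coefs in row.items():
                coefs = np.asarray(coefs, float)
                if np.any(coefs < 0):
                    raise ConfigurationError(
                        f"group {self.name!r} row {r}: negative coefficient "
                        f"for pool {pool!r}"
                    )
                row[pool] = coefs
        if self.n_peaks <= 0:
            self.n_peaks = len(self.rows)
        if self.row_labels is None:
            self.row_labels = [f"{self.name}[{i}]" for i in range(len(self.rows))]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def pools(self) -> list:
        seen = []
        for row in self.rows:
            for pool in row:
                if pool not in seen:
                    seen.append(pool)
        return seen

    def evaluate(self, state: LabelingState) -> np.ndarray:
        iso = {p: state.isotopomer_fractions(p) for p in self.pools}
        raw = np.empty(self.n_rows)
        for i, row in enumerate(self.rows):
            val = 0.0
            for pool, coefs in row.items():
                vec = iso[pool]
                if coefs.size != vec.size:
                    raise ConfigurationError(
                        f"group {self.name!r}: row length {coefs.size} does not "
                        f"match pool {pool!r} isotopomer space {vec.size}"
                    )
                val += float(coefs @ vec)
            raw[i] = val
        if self.normalize:
            total = raw.sum()
            if total <= 1e-12:
                raise DegeneracyError(
                    f"group {self.name!r}: zero total mass, cannot normalize"
                )
            raw = raw / total
        return raw


def replicate_scaling_factor(n_rep: int, scheme="jackknife") -> float:
    """Replicate factor a(n): >= 1, non-increasing, -> 1 for many repeats.

    Default "jackknife" scheme: sqrt(n/(n-1)) for n >= 2, capped at 2 for a
    single replicate. "none" disables replicate scaling (a == 1).
    """
    if callable(scheme):
        return float(scheme(n_rep))
    if n_rep < 1:
        raise ConfigurationError("replicate scaling needs n_rep >= 1")
    if scheme == "none":
        return 1.0
    if scheme == "jackknife":
        if n_rep == 1:
            return 2.0
        return float(np.sqrt(n_rep / (n_rep - 1)))
    raise ConfigurationError(f"unknown replicate scaling scheme {scheme!r}")


@dataclass(frozen=True)
class ErrorModel:
    """Linear error model of one device: sigma = a(n) * (b1 * eta + b2)."""

    device: str
    b1: float
    b2: float
    scaling: object = "jackknife"

    def __post_init__(self):
        if self.b1 < 0:
            raise ConfigurationError(f"error model {self.device!r}: b1 must be >= 0")
        if self.b2 <= 0:
            raise ConfigurationError(f"error model {self.device!r}: b2 must be > 0")

    def sigma(self, eta: np.ndarray, n_rep: int) -> np.ndarray:
        a = replicate_scaling_factor(n_rep, self.scaling)
        return a * (self.b1 * np.asarray(eta, float) + self.b2)


def evaluate_error_model(values, model: ErrorModel, n_rep: int):
    """Elementwise sigma and the diagonal covariance sigma^2."""
    if n_rep < 1:
        raise ConfigurationError("groups with n_rep = 0 are excluded upstream")
    eta = values.values if isinstance(values, MeasurementVector) else values
    sigma = model.sigma(eta, n_rep)
    return sigma, sigma**2


@dataclass
class MeasurementSetup:
    """Ordered groups with per-group replicate counts and device error models.

    ``n_rep[i] = 0`` means group ``i`` is acquired but not evaluated: it
    contributes neither measurements nor analytical peak-evaluation cost.
    """

    groups: list
    n_rep: list
    error_models: dict = field(default_factory=dict)
    n_max: int = 10

    def __post_init__(self):
        if len(self.groups) != len(self.n_rep):
            raise ConfigurationError("one replicate count per group required")
        for g, n in zip(self.groups, self.n_rep):
            if int(n) != n or n < 0 or n > self.n_max:
                raise ConfigurationError(
                    f"group {g.name!r}: replicate count {n} not an integer "
                    f"in [0, {self.n_max}]"
                )
        self.n_rep = [int(n) for n in self.n_rep]

    def active(self):
        return [
            (g, n) for g, n in zip(self.groups, self.n_rep) if n >= 1
        ]

    def with_replicates(self, n_rep) -> "MeasurementSetup":
        return MeasurementSetup(
            groups=list(self.groups),
            n_rep=list(n_rep),
            error_models=dict(self.error_models),
            n_max=self.n_max,
        )


@dataclass
class MeasurementVector:
    """Stacked predicted observations with optional standard deviations."""

    values: np.ndarray
    labels: list
    group_slices: list  # [(group, n_rep, slice), ...]
    sigmas: np.ndarray | None = None

    @property
    def covariance_diagonal(self) -> np.ndarray:
        if self.sigmas is None:
            raise ConfigurationError("error models not yet evaluated")
        return self.sigmas**2


def predict_measurements(state: LabelingState, setup: MeasurementSetup) -> MeasurementVector:
    """Simulated device observations eta of all evaluated groups."""
    chunks, labels, slices = [], [], []
    offset = 0
    for group, n in setup.active():
        vals = group.evaluate(state)
        chunks.append(vals)
        labels.extend(f"{group.device}:{lbl}" for lbl in group.row_labels)
        slices.append((group, n, slice(offset, offset + vals.size)))
        offset += vals.size
    values = np.concatenate(chunks) if chunks else np.empty(0)
    return MeasurementVector(values=values, labels=labels, group_slices=slices)


def attach_sigmas(mvec: MeasurementVector, setup: MeasurementSetup) -> MeasurementVector:
    """Fill standard deviations from each group's device error model."""
    sigmas = np.empty_like(mvec.values)
    for group, n, sl in mvec.group_slices:
        if group.device not in setup.error_models:
            raise ConfigurationError(
                f"no error model for device {group.device!r}"
            )
        model = setup.error_models[group.device]
        sigmas[sl], _ = evaluate_error_model(mvec.values[sl], model, n)
    mvec.sigmas = sigmas
    return mvec


# ---------------------------------------------------------------------------
# device templates
# ---------------------------------------------------------------------------


def make_device_templates(
    pool: str, n_carbons: int, fragment=None, protonated=None, contiguous=True
):
    """Archetypal measurement groups of one pool per analytical platform.

    MS — full mass isotopomer distribution (n+1 rows); MS/MS — joint
    (precursor mass, fragment mass) indicator rows for the carbon subset
    ``fragment`` (0-based positions, default: all but the first carbon);
    13C-NMR — per-position enrichments; 1H-NMR — enrichments of the
    ``protonated`` positions (default: all); IRMS — one row holding the
    mean enrichment over all positions.
    """
    if n_carbons < 1:
        raise ConfigurationError("device templates need n_carbons >= 1")
    size = 1 << n_carbons
    masses = np.array([bin(m).count("1") for m in range(size)])

    def indicator(cond):
        return {pool: cond.astype(float)}

    ms_rows = [indicator(masses == k) for k in range(n_carbons + 1)]
    ms = MeasurementGroup(
        device="ms",
        name=f"{pool}_mid",
        rows=ms_rows,
        row_labels=[f"{pool}:M+{k}" for k in range(n_carbons + 1)],
        normalize=True,
    )

    if fragment is None:
        fragment = tuple(range(1, n_carbons)) if n_carbons > 1 else (0,)
    fragment = tuple(sorted(fragment))
    if contiguous and fragment != tuple(
        range(fragment[0], fragment[0] + len(fragment))
    ):
        raise ConfigurationError(
            f"fragment {fragment} of pool {pool!r} declared contiguous but is not"
        )
    frag_mask = 0
    for p in fragment:
        if not 0 <= p < n_carbons:
            raise ConfigurationError(
                f"fragment position {p} outside pool {pool!r} carbons"
            )
        frag_mask |= 1 << p
    frag_size = bin(frag_mask).count("1")
    frag_masses = np.array(
        [bin(m & frag_mask).count("1") for m in range(size)]
    )
    msms_rows, msms_labels = [], []
    for k in range(n_carbons + 1):
        for j in range(frag_size + 1):
            if j <= k <= j + (n_carbons - frag_size):
                cond = (masses == k) & (frag_masses == j)
                msms_rows.append(indicator(cond))
                msms_labels.append(f"{pool}:M+{k}/m+{j}")
    msms = MeasurementGroup(
        device="msms",
        name=f"{pool}_tandem",
        rows=msms_rows,
        row_labels=msms_labels,
        normalize=True,
    )

    def positional(pos):
        cond = np.array([(m >> pos) & 1 for m in range(size)], dtype=bool)
        return indicator(cond)

    nmr13c = MeasurementGroup(
        device="nmr13c",
        name=f"{pool}_pos",
        rows=[positional(p) for p in range(n_carbons)],
        row_labels=[f"{pool}:C{p + 1}" for p in range(n_carbons)],
        normalize=False,
    )

    if protonated is None:
        protonated = tuple(range(n_carbons))
    nmr1h = MeasurementGroup(
        device="nmr1h",
        name=f"{pool}_hpos",
        rows=[positional(p) for p in protonated],
        row_labels=[f"{pool}:H-C{p + 1}" for p in protonated],
        normalize=False,
    )

    irms = MeasurementGroup(
        device="irms",
        name=f"{pool}_enrichment",
        rows=[{pool: masses / n_carbons}],
        row_labels=[f"{pool}:total"],
        normalize=False,
    )

    return {"ms": ms, "msms": msms, "nmr13c": nmr13c, "nmr1h": nmr1h, "irms": irms}
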