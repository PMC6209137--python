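"""Fisher information, statistical identifiability and design criteria.

The Fisher information matrix of a planned labeling experiment is

    FIM = J^T diag(sigma^-2) J,      J = d(eta)/d(v_free)

and its inverse approximates the free-flux covariance at the design point.
The FIM is accepted only if its smallest eigenvalue clears a threshold and
its condition number stays bounded; otherwise the worst-determined free
flux is frozen at its nominal value and the test repeats — the greedy
one-at-a-time elimination that yields the effective dimension ``p``.

Scalar design criteria condense the covariance:

* D — det(Cov)^(1/(2p)), the geometric mean of the flux standard
  deviations (2p-th root so the value is on standard-deviation scale);
* A — trace(Cov)/p, the mean flux variance;
* E — lambda_max/lambda_min of Cov, the conditioning of the confidence
  ellipsoid;
* DoF — p itself.

D/A/E are dispersions (smaller is better); the *information* orientation
reports their reciprocals so that larger means more informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegeneracyError

__all__ = [
    "CriteriaConfig",
    "FimResult",
    "CriteriaValues",
    "compute_fim",
    "assess_identifiability",
    "iterative_freeze",
    "evaluate_criteria",
]


@dataclass(frozen=True)
class CriteriaConfig:
    """Invertibility thresholds and reporting orientation.

    ``tau1`` scales with the spectrum: the FIM passes if
    lambda_min > tau1 * max(lambda_max, 1), i.e. relative on well-scaled
    systems with an absolute floor so that a matrix of pure numerical noise
    (where lambda_min == lambda_max can hold) is still rejected.
    """

    tau1: float = 1e-9
    tau2: float = 1e12
    orientation: str = "dispersion"  # or "information"

    def __post_init__(self):
        if self.tau1 <= 0:
            raise ConfigurationError("tau1 must be > 0")
        if not np.isfinite(self.tau2):
            raise ConfigurationError("tau2 must be finite")


def compute_fim(jacobian, sigma) -> np.ndarray:
    """FIM = J^T diag(sigma^-2) J (symmetric positive semidefinite)."""
    J = np.atleast_2d(np.asarray(jacobian, float))
    s = np.asarray(sigma, float)
    if s.ndim != 1 or s.size != J.shape[0]:
        raise ValueError("sigma must be one value per measurement row")
    if np.any(s <= 0):
        raise DegeneracyError("zero or negative sigma entry (singular weights)")
    W = J / s[:, None]
    fim = W.T @ W
    return 0.5 * (fim + fim.T)


def assess_identifiability(fim, config: CriteriaConfig | None = None):
    """(passes, diagnostics) for the two invertibility conditions."""
    config = config or CriteriaConfig()
    fim = np.asarray(fim, float)
    if fim.size == 0:
        return False, {"lambda_min": 0.0, "lambda_max": 0.0, "cond": np.inf}
    if not np.allclose(fim, fim.T, atol=1e-10 * max(1.0, np.abs(fim).max())):
        raise ValueError("FIM must be symmetric")
    eig = np.linalg.eigvalsh(fim)
    lam_min, lam_max = float(eig[0]), float(eig[-1])
    cond = np.inf if lam_min <= 0 else lam_max / lam_min
    ok = (
        lam_max > 0
        and lam_min > config.tau1 * max(lam_max, 1.0)
        and cond < config.tau2
    )
    return bool(ok), {"lambda_min": lam_min, "lambda_max": lam_max, "cond": cond}


@dataclass
class FimResult:
    """Outcome of the identifiability analysis at one design point."""

    fim: np.ndarray
    cov: np.ndarray
    p: int
    retained: list = field(default_factory=list)
    frozen: list = field(default_factory=list)
    lambda_min: float = 0.0
    cond: float = np.inf


def iterative_freeze(jacobian, sigma, free_names, config: CriteriaConfig | None = None) -> FimResult:
    """Greedy one-at-a-time elimination of non-identifiable free fluxes.

    Starting from the full free set, while the FIM fails the invertibility
    conditions the *worst determined* flux — the one with the largest
    diagonal entry of the FIM pseudo-inverse, i.e. the largest variance — is
    constrained to its nominal value and removed. ``p = 0`` (nothing
    identifiable) is a valid result. Deterministic, and invariant to the
    ordering of measurement rows (the FIM is a sum over rows).
    """
    config = config or CriteriaConfig()
    J = np.atleast_2d(np.asarray(jacobian, float))
    free_names = list(free_names)
    if J.shape[1] != len(free_names):
        raise ValueError("one Jacobian column per free flux required")

    retained = list(range(len(free_names)))
    frozen: list[str] = []
    while retained:
        fim = compute_fim(J[:, retained], sigma)
        ok, diag = assess_identifiability(fim, config)
        if ok:
            cov = np.linalg.inv(fim)
            cov = 0.5 * (cov + cov.T)
            return FimResult(
                fim=fim,
                cov=cov,
                p=len(retained),
                retained=[free_names[i] for i in retained],
                frozen=frozen,
                lambda_min=diag["lambda_min"],
                cond=diag["cond"],
            )
        # "worst determined" = largest variance. Near-null FIM directions
        # carry effectively infinite variance but vanish from the plain
        # pseudo-inverse diagonal, so fluxes participating in the near-null
        # eigenspace are ranked first; otherwise the variance diagonal rules.
        eigval, eigvec = np.linalg.eigh(fim)
        lam_max = eigval[-1]
        null = eigval <= config.tau1 * max(lam_max, 1.0)
        if np.any(null) or lam_max <= 0:
            scores = (eigvec[:, null] ** 2).sum(axis=1)
        else:
            scores = np.diag(np.linalg.pinv(fim))
        worst = int(np.argmax(scores))
        frozen.append(free_names[retained[worst]])
        del retained[worst]
    return FimResult(
        fim=np.empty((0, 0)),
        cov=np.empty((0, 0)),
        p=0,
        retained=[],
        frozen=frozen,
        lambda_min=0.0,
        cond=np.inf,
    )


@dataclass(frozen=True)
class CriteriaValues:
    """D/A/E/DoF criterion values of one identifiability result."""

    dof: int
    phi_d: float = np.nan
    phi_a: float = np.nan
    phi_e: float = np.nan

    @property
    def info_d(self) -> float:
        return 0.0 if self.dof == 0 else 1.0 / self.phi_d

    @property
    def info_a(self) -> float:
        return 0.0 if self.dof == 0 else 1.0 / self.phi_a

    @property
    def info_e(self) -> float:
        return 0.0 if self.dof == 0 else 1.0 / self.phi_e

    def as_dict(self, orientation: str = "dispersion") -> dict:
        out = {"dof": self.dof}
        if orientation == "information":
            out.update(info_d=self.info_d, info_a=self.info_a, info_e=self.info_e)
        else:
            out.update(phi_d=self.phi_d, phi_a=self.phi_a, phi_e=self.phi_e)
        return out


def evaluate_criteria(result: FimResult) -> CriteriaValues:
    """D/A/E/DoF values from a (possibly reduced) covariance matrix."""
    p = result.p
    if p == 0:
        return CriteriaValues(dof=0)
    cov = np.asarray(result.cov, float)
    eig = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if eig[0] <= 0:
        raise DegeneracyError("covariance matrix is not positive definite")
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise DegeneracyError("covariance determinant is not positive")
    phi_d = float(np.exp(logdet / (2 * p)))
    phi_a = float(np.trace(cov) / p)
    phi_e = float(eig[-1] / eig[0])
    return CriteriaValues(dof=p, phi_d=phi_d, phi_a=phi_a, phi_e=phi_e)
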