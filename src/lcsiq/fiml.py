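"""Full-information maximum likelihood for the trivariate (BF, IQ_M, IQ_C) moments.

Each dyad record observes an arbitrary non-empty subset of the three
variables. Under a joint-normal working model the observed-data
log-likelihood is the sum over records of the log marginal normal density of
the record's observed sub-vector; its maximizer is the FIML estimate of the
mean vector and covariance matrix. Because every downstream latent change
score model is saturated, these nine moments are the complete sufficient
summary of a dataset: all model coefficients are closed-form functions of a
:class:`MomentSet`.

The maximization uses the classical EM algorithm for multivariate normal
data with missing values: the E-step imputes conditional expectations (and
conditional covariances) of the missing entries pattern by pattern, the
M-step recomputes moments from the completed sufficient statistics.
The binary breastfeeding indicator is carried as a plain numeric variable in
the joint likelihood — the standard structural-equation treatment of an
exogenous binary covariate under FIML, and the treatment under which the
published estimates are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.stats import multivariate_normal

from .data import DyadDataset

__all__ = [
    "MomentSet",
    "ConvergenceReport",
    "fiml_moments",
    "observed_data_loglik",
    "numerical_information",
    "pack_params",
    "unpack_params",
]

VAR_NAMES = ("bf", "iq_mother", "iq_child")
_PSD_TOL = 1e-10

# vech index pairs for a 3x3 symmetric matrix, lower triangle column-major:
# (0,0),(1,0),(1,1),(2,0),(2,1),(2,2)
_VECH_IDX = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]


@dataclass
class MomentSet:
    """FIML mean vector and covariance matrix of (BF, IQ_mother, IQ_child).

    ``mean`` is ordered (BF, IQ_mother, IQ_child); ``cov`` is the 3x3
    ML-convention (divisor n) covariance. ``pattern_counts`` maps each
    missingness pattern — a tuple of three booleans, True = observed — to its
    record count.
    """

    mean: np.ndarray
    cov: np.ndarray
    n_total: int
    loglik: float = float("nan")
    pattern_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.cov = np.asarray(self.cov, dtype=float).reshape(3, 3)
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance matrix is not symmetric")
        eigmin = np.linalg.eigvalsh(self.cov).min()
        if eigmin < -_PSD_TOL * max(1.0, np.trace(self.cov)):
            raise ValueError(f"covariance matrix is not PSD (min eigenvalue {eigmin:g})")
        if self.pattern_counts:
            total = sum(self.pattern_counts.values())
            if total != self.n_total:
                raise ValueError("pattern counts do not sum to n_total")

    def to_dict(self) -> dict:
        return {
            "variables": list(VAR_NAMES),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "n_total": self.n_total,
            "loglik": self.loglik,
            "pattern_counts": {"".join("1" if o else "0" for o in k): v
                               for k, v in self.pattern_counts.items()},
        }


@dataclass
class ConvergenceReport:
    iterations: int
    final_loglik: float
    loglik_trace: np.ndarray
    converged: bool
    tol: float

    def __post_init__(self) -> None:
        self.loglik_trace = np.asarray(self.loglik_trace, dtype=float)


def pack_params(mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Stack (mean, vech(cov)) into the 9-parameter vector."""
    theta = np.empty(9)
    theta[:3] = mean
    for k, (i, j) in enumerate(_VECH_IDX):
        theta[3 + k] = cov[i, j]
    return theta


def unpack_params(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = np.asarray(theta[:3], dtype=float)
    cov = np.empty((3, 3))
    for k, (i, j) in enumerate(_VECH_IDX):
        cov[i, j] = cov[j, i] = theta[3 + k]
    return mean, cov


def _pattern_groups(values: np.ndarray) -> dict[tuple[bool, bool, bool], np.ndarray]:
    """Group record indices by missingness pattern (True = observed)."""
    obs = ~np.isnan(values)
    groups: dict[tuple[bool, bool, bool], list[int]] = {}
    keys = obs @ np.array([4, 2, 1])
    for key in np.unique(keys):
        idx = np.nonzero(keys == key)[0]
        pattern = tuple(bool(b) for b in obs[idx[0]])
        groups[pattern] = idx
    return groups


def _as_values(data: Union[DyadDataset, np.ndarray]) -> np.ndarray:
    if isinstance(data, DyadDataset):
        return data.values
    return np.asarray(data, dtype=float)


def observed_data_loglik(
    data: Union[DyadDataset, np.ndarray],
    mean: np.ndarray,
    cov: np.ndarray,
) -> float:
    """Exact observed-data log-likelihood at the given moments.

    Sum over records of the log density of the record's observed sub-vector
    under N(mean_O, cov_OO). Raises on a singular observed sub-block.
    """
    x = _as_values(data)
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    total = 0.0
    for pattern, idx in _pattern_groups(x).items():
        o = np.array(pattern)
        sub = cov[np.ix_(o, o)]
        if np.linalg.det(sub) <= 0:
            raise np.linalg.LinAlgError(
                f"singular observed sub-block for pattern {pattern}"
            )
        total += float(
            multivariate_normal(mean[o], sub, allow_singular=False)
            .logpdf(x[np.ix_(idx, np.nonzero(o)[0])])
            .sum()
        )
    return total


def _pairwise_start(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-available-case start values, ridge-repaired to PD."""
    p = x.shape[1]
    mean = np.nanmean(x, axis=0)
    cov = np.empty((p, p))
    for i in range(p):
        for j in range(i + 1):
            both = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            if both.sum() >= 2:
                xi = x[both, i] - x[both, i].mean()
                xj = x[both, j] - x[both, j].mean()
                cov[i, j] = cov[j, i] = (xi * xj).mean()
            else:
                cov[i, j] = cov[j, i] = 0.0
    # ridge repair: ensure strictly PD start
    scale = max(np.trace(cov) / p, 1.0)
    for i in range(p):
        if cov[i, i] <= 0:
            cov[i, i] = scale
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < 1e-6 * scale:
        cov += (1e-6 * scale - eigmin) * np.eye(p)
    return mean, cov


def fiml_moments(
    data: Union[DyadDataset, np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> tuple[MomentSet, ConvergenceReport]:
    """FIML estimate of the trivariate moments by EM.

    Iterates until the maximum absolute change across the nine parameters
    falls below ``tol``. The log-likelihood trace is recorded each iteration
    and is guaranteed non-decreasing by EM; a decrease beyond numerical
    round-off raises.

    With complete data the E-step is vacuous and the algorithm lands on the
    sample ML moments (divisor n) after one effective iteration.

    Raises
    ------
    ValueError
        If a record misses all variables, a variable is never observed, or a
        variable has fewer than two distinct observed values.
    RuntimeError
        On non-convergence within ``max_iter``.
    """
    x = _as_values(data)
    n, p = x.shape
    if p != 3:
        raise ValueError("expected three variables (bf, iq_mother, iq_child)")
    obs = ~np.isnan(x)
    if (~obs).all(axis=1).any():
        raise ValueError("records with all variables missing must be removed before FIML")
    for j in range(p):
        vals = np.unique(x[obs[:, j], j])
        if vals.size < 2:
            raise ValueError(
                f"variable {VAR_NAMES[j]!r} needs >=2 distinct observed values, has {vals.size}"
            )

    groups = _pattern_groups(x)
    pattern_counts = {k: int(len(v)) for k, v in groups.items()}

    mean, cov = _pairwise_start(x)
    theta = pack_params(mean, cov)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll = observed_data_loglik(x, mean, cov)
        if trace and ll < trace[-1] - 1e-7 * max(1.0, abs(trace[-1])):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {trace[-1]} -> {ll}"
            )
        trace.append(ll)

        # E-step: completed sufficient statistics
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for pattern, idx in groups.items():
            o = np.array(pattern)
            m = ~o
            xo = x[np.ix_(idx, np.nonzero(o)[0])]
            filled = np.empty((len(idx), p))
            filled[:, o] = xo
            add = np.zeros((p, p))
            if m.any():
                soo = cov[np.ix_(o, o)]
                smo = cov[np.ix_(m, o)]
                smm = cov[np.ix_(m, m)]
                beta = np.linalg.solve(soo, smo.T).T          # (n_m, n_o)
                cond_mean = mean[m] + (xo - mean[o]) @ beta.T
                filled[:, m] = cond_mean
                cond_cov = smm - beta @ smo.T
                add[np.ix_(m, m)] = len(idx) * cond_cov
            s1 += filled.sum(axis=0)
            s2 += filled.T @ filled + add

        # M-step
        new_mean = s1 / n
        new_cov = s2 / n - np.outer(new_mean, new_mean)
        new_cov = (new_cov + new_cov.T) / 2
        new_theta = pack_params(new_mean, new_cov)
        delta = np.max(np.abs(new_theta - theta))
        mean, cov, theta = new_mean, new_cov, new_theta
        if delta < tol:
            converged = True
            break

    final_ll = observed_data_loglik(x, mean, cov)
    trace.append(final_ll)
    report = ConvergenceReport(
        iterations=it, final_loglik=final_ll, loglik_trace=np.array(trace),
        converged=converged, tol=tol,
    )
    if not converged:
        raise RuntimeError(
            f"EM did not converge within {max_iter} iterations "
            f"(last parameter change above {tol:g})"
        )
    moments = MomentSet(
        mean=mean, cov=cov, n_total=n, loglik=final_ll, pattern_counts=pattern_counts
    )
    return moments, report


def numerical_information(
    data: Union[DyadDataset, np.ndarray],
    moments: MomentSet,
    rel_step: float = 1e-5,
) -> np.ndarray:
    """Observed information: negative Hessian of the log-likelihood.

    Central finite differences on the 9-parameter vector
    (mu_BF, mu_M, mu_C, vech Sigma), evaluated at ``moments`` (which should
    be the FIML solution). The result is symmetrized. At an interior maximum
    it is positive definite; an indefinite result raises, flagging a boundary
    or non-maximum point.
    """
    x = _as_values(data)
    theta0 = pack_params(moments.mean, moments.cov)

    def f(theta: np.ndarray) -> float:
        mean, cov = unpack_params(theta)
        return observed_data_loglik(x, mean, cov)

    k = theta0.size
    h = rel_step * np.maximum(np.abs(theta0), 1.0)
    hess = np.empty((k, k))
    f0 = f(theta0)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        hess[i, i] = (f(theta0 + ei) - 2 * f0 + f(theta0 - ei)) / h[i] ** 2
    for i in range(k):
        for j in range(i):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            hij = (
                f(theta0 + ei + ej) - f(theta0 + ei - ej)
                - f(theta0 - ei + ej) + f(theta0 - ei - ej)
            ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = hij
    info = -(hess + hess.T) / 2
    eigmin = np.linalg.eigvalsh(info).min()
    if eigmin <= 0:
        raise np.linalg.LinAlgError(
            f"observed information is not positive definite (min eigenvalue {eigmin:g}); "
            "the supplied moments may not be an interior maximum"
        )
    return info
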