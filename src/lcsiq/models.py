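"""Latent change score (LCS) parameterizations and the total-effect decomposition.

Three saturated LCS parameterizations of the trivariate system
(BF, IQ_M, IQ_C), where the change score is the latent intergenerational
difference with both loadings fixed to one:

``forward_adj``
    Child IQ = maternal IQ + Delta (unit loadings); Delta regressed on
    maternal IQ and the breastfeeding indicator; BF and maternal IQ covary
    freely. The Delta equation conditions on the baseline, so the BF effect
    is exposed to regression to the mean through unreliable maternal IQ.
``backward_adj``
    Mother and child change places: Delta' = IQ_M - IQ_C regressed on child
    IQ and BF. Comparing its BF effect with the forward one diagnoses
    regression-to-the-mean artefacts: a true causal effect cannot be
    positive in both directions.
``forward_noadj``
    Delta regressed on BF only; the baseline-to-change regression is
    replaced by a free covariance, which removes the conditioning and with
    it the regression-to-the-mean pathway.

All three models are saturated (zero degrees of freedom), so their ML
estimates are exact closed-form functions of the FIML :class:`~lcsiq.fiml.MomentSet`;
the FIML engine carries the entire missing-data burden. Because the models
are moment maps, the classical omitted-variable identity holds exactly:

    total = direct + (BF-group mean difference in the conditioning IQ) x (IQ slope)

and the forward-adjusted total equals the unadjusted BF effect computed from
the same moments, while the backward-adjusted total equals its negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .data import DyadDataset
from .fiml import (
    MomentSet,
    fiml_moments,
    numerical_information,
    pack_params,
    unpack_params,
)

__all__ = [
    "MODELS",
    "LCSFit",
    "DecompositionResult",
    "coefficients_from_moments",
    "fit_lcs",
    "total_effect",
    "decompose_fit",
    "implied_moments",
]

MODELS = ("forward_adj", "backward_adj", "forward_noadj")
_B, _M, _C = 0, 1, 2  # canonical variable order (bf, iq_mother, iq_child)
_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass
class LCSFit:
    """One fitted LCS parameterization.

    ``bf_effect`` is the effect of breastfeeding on the latent change score
    in IQ points; ``iq_effect`` the unit-free slope of the change score on
    the conditioning IQ (None for ``forward_noadj``); ``cov_term`` is the
    free covariance of the model: Cov(BF, conditioning IQ) for the adjusted
    models, Cov(IQ_M, Delta) for the unadjusted one. ``se`` and ``ci`` map
    coefficient names to standard errors and 95% Wald intervals.
    """

    model: str
    bf_effect: float
    iq_effect: Optional[float]
    intercept: float
    var_delta: float
    cov_term: float
    mean_bf: float
    var_bf: float
    mean_iq: float
    var_iq: float
    cov_bf_iq: float = float("nan")
    n_total: Optional[int] = None
    loglik: Optional[float] = None
    se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "bf_effect": self.bf_effect,
            "iq_effect": self.iq_effect,
            "intercept": self.intercept,
            "var_delta": self.var_delta,
            "cov_term": self.cov_term,
            "n_total": self.n_total,
            "loglik": self.loglik,
            "se": dict(self.se),
            "ci": {k: list(v) for k, v in self.ci.items()},
        }
        return d


@dataclass
class DecompositionResult:
    """Total-effect decomposition of an adjusted LCS fit.

    total = direct + group_mean_diff * conditioning_coef, exactly.
    """

    direct: float
    conditioning_coef: float
    group_mean_diff: float
    total: float


def _coef_vector(moments_mean: np.ndarray, moments_cov: np.ndarray, model: str) -> np.ndarray:
    """(bf_effect, iq_effect, intercept) for adjusted models;
    (bf_effect, intercept) for forward_noadj. Shared by fitting and the
    delta-method Jacobian."""
    m, s = moments_mean, moments_cov
    if model == "forward_adj":
        cond = _M
        d_mean = m[_C] - m[_M]
        cov_d_cond = s[_C, cond] - s[_M, cond]
        cov_d_b = s[_C, _B] - s[_M, _B]
    elif model == "backward_adj":
        cond = _C
        d_mean = m[_M] - m[_C]
        cov_d_cond = s[_M, cond] - s[_C, cond]
        cov_d_b = s[_M, _B] - s[_C, _B]
    elif model == "forward_noadj":
        d_mean = m[_C] - m[_M]
        cov_d_b = s[_C, _B] - s[_M, _B]
        if s[_B, _B] <= 0:
            raise ValueError("Var(BF) must be positive (need both groups present)")
        beta = cov_d_b / s[_B, _B]
        return np.array([beta, d_mean - beta * m[_B]])
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")

    if s[_B, _B] <= 0:
        raise ValueError("Var(BF) must be positive (need both groups present)")
    if s[cond, cond] <= 0:
        raise ValueError("conditioning IQ variance must be positive")
    pred_cov = np.array([[s[cond, cond], s[cond, _B]], [s[cond, _B], s[_B, _B]]])
    if np.linalg.det(pred_cov) <= 0:
        raise np.linalg.LinAlgError("singular predictor covariance (BF, conditioning IQ)")
    slopes = np.linalg.solve(pred_cov, np.array([cov_d_cond, cov_d_b]))
    iq_effect, bf_effect = slopes
    intercept = d_mean - iq_effect * m[cond] - bf_effect * m[_B]
    return np.array([bf_effect, iq_effect, intercept])


def coefficients_from_moments(moments: MomentSet, model: str) -> LCSFit:
    """Exact ML point estimates of one LCS parameterization from moments.

    All coefficients are moment algebra on the saturated system; on complete
    data they coincide with ordinary least squares on the observed
    difference score.
    """
    m, s = moments.mean, moments.cov
    coefs = _coef_vector(m, s, model)

    if model == "forward_noadj":
        bf_effect, intercept = coefs
        iq_effect = None
        var_d = s[_C, _C] + s[_M, _M] - 2 * s[_C, _M]
        var_delta = var_d - bf_effect**2 * s[_B, _B]
        cov_term = s[_C, _M] - s[_M, _M]  # Cov(IQ_M, Delta), the freed covariance path
        cond = _M
    else:
        bf_effect, iq_effect, intercept = coefs
        cond = _M if model == "forward_adj" else _C
        other = _C if model == "forward_adj" else _M
        var_d = s[_C, _C] + s[_M, _M] - 2 * s[_C, _M]
        cov_d_cond = s[other, cond] - s[cond, cond]
        cov_d_b = s[other, _B] - s[cond, _B]
        var_delta = var_d - (iq_effect * cov_d_cond + bf_effect * cov_d_b)
        cov_term = s[cond, _B]  # Cov(conditioning IQ, BF)

    return LCSFit(
        model=model,
        bf_effect=float(bf_effect),
        iq_effect=None if iq_effect is None else float(iq_effect),
        intercept=float(intercept),
        var_delta=float(var_delta),
        cov_term=float(cov_term),
        mean_bf=float(m[_B]),
        var_bf=float(s[_B, _B]),
        mean_iq=float(m[cond]),
        var_iq=float(s[cond, cond]),
        cov_bf_iq=float(s[cond, _B]),
        n_total=moments.n_total,
        loglik=moments.loglik,
    )


def implied_moments(fit: LCSFit) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the trivariate (mean, cov) implied by a fit.

    The models are saturated, so this must reproduce the input MomentSet
    exactly; it is the zero-degrees-of-freedom consistency check.
    """
    mean = np.empty(3)
    cov = np.empty((3, 3))
    mean[_B] = fit.mean_bf
    cov[_B, _B] = fit.var_bf
    if fit.model == "forward_noadj":
        # free parameters: Delta equation on BF, the Cov(M, Delta) path in
        # cov_term, and the free BF/baseline covariance in cov_bf_iq.
        cond, other = _M, _C
        mean[cond] = fit.mean_iq
        cov[cond, cond] = fit.var_iq
        cov[cond, _B] = cov[_B, cond] = fit.cov_bf_iq
        cov_d_b = fit.bf_effect * fit.var_bf
        var_d = fit.bf_effect**2 * fit.var_bf + fit.var_delta
        cov_m_d = fit.cov_term
        d_mean = fit.intercept + fit.bf_effect * fit.mean_bf
        mean[other] = mean[cond] + d_mean
        cov[other, cond] = cov[cond, other] = cov[cond, cond] + cov_m_d
        cov[other, other] = cov[cond, cond] + 2 * cov_m_d + var_d
        cov[other, _B] = cov[_B, other] = fit.cov_bf_iq + cov_d_b
        return mean, cov
    cond = _M if fit.model == "forward_adj" else _C
    other = _C if fit.model == "forward_adj" else _M
    mean[cond] = fit.mean_iq
    cov[cond, cond] = fit.var_iq
    cov[cond, _B] = cov[_B, cond] = fit.cov_term
    d_mean = fit.intercept + fit.iq_effect * mean[cond] + fit.bf_effect * mean[_B]
    cov_d_cond = fit.iq_effect * cov[cond, cond] + fit.bf_effect * cov[cond, _B]
    cov_d_b = fit.iq_effect * cov[cond, _B] + fit.bf_effect * cov[_B, _B]
    var_d = (
        fit.iq_effect * cov_d_cond + fit.bf_effect * cov_d_b + fit.var_delta
    )
    mean[other] = mean[cond] + d_mean
    cov[other, cond] = cov[cond, other] = cov[cond, cond] + cov_d_cond
    cov[other, _B] = cov[_B, other] = cov[cond, _B] + cov_d_b
    cov[other, other] = cov[cond, cond] + 2 * cov_d_cond + var_d
    return mean, cov


def _coef_names(model: str) -> list[str]:
    if model == "forward_noadj":
        return ["bf_effect", "intercept"]
    return ["bf_effect", "iq_effect", "intercept"]


def _delta_method_se(
    data, moments: MomentSet, model: str, rel_step: float = 1e-6
) -> dict[str, float]:
    """SEs by propagating the inverse observed information through the
    moment-to-coefficient map's finite-difference Jacobian."""
    info = numerical_information(data, moments)
    vcov_theta = np.linalg.inv(info)
    theta0 = pack_params(moments.mean, moments.cov)

    def g(theta: np.ndarray) -> np.ndarray:
        mean, cov = unpack_params(theta)
        return _coef_vector(mean, cov, model)

    k = theta0.size
    g0 = g(theta0)
    jac = np.empty((g0.size, k))
    h = rel_step * np.maximum(np.abs(theta0), 1.0)
    for i in range(k):
        e = np.zeros(k); e[i] = h[i]
        jac[:, i] = (g(theta0 + e) - g(theta0 - e)) / (2 * h[i])
    vcov_coef = jac @ vcov_theta @ jac.T
    ses = np.sqrt(np.clip(np.diag(vcov_coef), 0.0, None))
    return dict(zip(_coef_names(model), ses))


def _bootstrap_se(
    dataset: DyadDataset, model: str, n_boot: int, seed: int
) -> dict[str, float]:
    """Nonparametric (case-resampling) bootstrap SEs.

    Complete data uses a vectorized sample-moment fast path; with missing
    values each replicate is re-estimated by EM.
    """
    x = dataset.values
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    names = _coef_names(model)
    out = np.empty((n_boot, len(names)))
    complete = not np.isnan(x).any()
    for b in range(n_boot):
        xb = x[rng.integers(0, n, size=n)]
        if complete:
            mean = xb.mean(axis=0)
            cov = np.cov(xb, rowvar=False, bias=True)
        else:
            ms, _ = fiml_moments(xb, tol=1e-7)
            mean, cov = ms.mean, ms.cov
        out[b] = _coef_vector(mean, cov, model)
    return dict(zip(names, out.std(axis=0, ddof=1)))


def fit_lcs(
    dataset: DyadDataset,
    model: str,
    se: Optional[str] = "delta",
    tol: float = 1e-8,
    max_iter: int = 5000,
    n_boot: int = 2000,
    seed: int = 0,
) -> LCSFit:
    """Fit one LCS parameterization to a dyad dataset.

    Runs FIML moment estimation then the closed-form coefficient map.
    ``se``: ``"delta"`` (default) for observed-information delta-method
    standard errors, ``"bootstrap"`` for case-resampling, ``None`` for point
    estimates only. 95% intervals are Wald: estimate +- 1.96 * SE.
    """
    moments, _ = fiml_moments(dataset, tol=tol, max_iter=max_iter)
    fit = coefficients_from_moments(moments, model)
    if se == "delta":
        fit.se = _delta_method_se(dataset, moments, model)
    elif se == "bootstrap":
        fit.se = _bootstrap_se(dataset, model, n_boot=n_boot, seed=seed)
    elif se is not None:
        raise ValueError(f"se must be 'delta', 'bootstrap' or None, got {se!r}")
    if fit.se:
        est = {"bf_effect": fit.bf_effect, "iq_effect": fit.iq_effect,
               "intercept": fit.intercept}
        fit.ci = {
            name: (est[name] - _Z95 * s, est[name] + _Z95 * s)
            for name, s in fit.se.items()
        }
    return fit


def total_effect(direct: float, conditioning_coef: float, group_mean_diff: float) -> float:
    """Assemble a total effect from an adjusted fit's pieces.

    total = direct + group_mean_diff * conditioning_coef. This is the
    omitted-variable identity: adding back the pathway through the
    conditioning IQ (whose BF-group means differ by ``group_mean_diff`` and
    which carries slope ``conditioning_coef`` into the change score) turns
    the adjusted (direct) BF effect into the total effect that the
    unadjusted model estimates.
    """
    return direct + group_mean_diff * conditioning_coef


def decompose_fit(adj_fit: LCSFit, moments: MomentSet) -> DecompositionResult:
    """Decompose an adjusted fit's BF effect into direct and total.

    The BF-group mean difference in the conditioning IQ equals
    Cov(IQ_cond, BF) / Var(BF) because BF is binary. The assembled total
    equals the unadjusted BF effect computed from the same moments (with a
    sign flip for the backward model, since its change score is the negated
    forward one).
    """
    if adj_fit.model not in ("forward_adj", "backward_adj"):
        raise ValueError("decomposition applies to the adjusted models only")
    cond = _M if adj_fit.model == "forward_adj" else _C
    if moments.cov[_B, _B] <= 0:
        raise ValueError("Var(BF) must be positive")
    gmd = float(moments.cov[cond, _B] / moments.cov[_B, _B])
    tot = total_effect(adj_fit.bf_effect, adj_fit.iq_effect, gmd)
    return DecompositionResult(
        direct=adj_fit.bf_effect,
        conditioning_coef=adj_fit.iq_effect,
        group_mean_diff=gmd,
        total=tot,
    )
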