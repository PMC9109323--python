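"""Virtual intergenerational cohorts and their closed-form moment oracle.

The generative process builds mother-child dyads in which breastfeeding has,
by construction, no effect on child IQ beyond maternal IQ and heritability:

1. Two groups of virtual mothers (breastfeeding / non-breastfeeding) receive
   true IQ scores from normal distributions with group-specific means and
   SDs.
2. Each mother gets one child whose true IQ correlates ``rho_h`` with hers:
   the child's true z-score (taken against the pooled maternal true
   distribution) is ``rho_h * z_mother + sqrt(1 - rho_h^2) * noise``.
3. Observed IQ correlates ``rho_r`` with true IQ the same way, for mothers
   and children alike, and the observed scores are affinely rescaled to the
   configured observed-scale targets (default: mothers M=100/SD=15,
   children M=102.8/SD=11.3, mirroring the empirical cohort).

Any breastfeeding "effect" recovered from such data is therefore an
artefact of confounding by maternal IQ combined with measurement
unreliability — the regression-to-the-mean mechanism the models probe.

``moment_matched`` mode makes the relevant *sample* moments equal the
configured values exactly (group true means/SDs, both 0.8 correlations, the
observed-scale means/SDs, and with them the full covariance of
(BF, IQ_M, IQ_C)), by orthogonalizing each noise vector against everything
built before it. Stochastic mode matches moments in expectation only and is
kept for parameter-recovery and consistency testing.

``population_moments`` is the analytic companion: the exact population mean
vector and covariance matrix of (BF, observed maternal IQ, observed child
IQ) implied by the generative equations, from which the expected model
coefficients follow through the same moment maps the fitted models use.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .data import SUBSTANTIVE_COLUMNS, DyadDataset
from .fiml import MomentSet
from .models import LCSFit, coefficients_from_moments

__all__ = [
    "DGPConfig",
    "PopulationMoments",
    "generate_cohort",
    "population_moments",
    "expected_model_coefficients",
    "emulate_empirical_missingness",
    "table_matched_dataset",
]


@dataclass
class DGPConfig:
    """Full parameterization of the intergenerational simulation.

    Defaults reproduce the study conditions: group sizes and true-score
    moments equal those of the breastfeeding / non-breastfeeding mothers of
    firstborn children in the empirical cohort, heritability-like and
    reliability-like correlations both 0.8, and observed scales 100/15
    (mothers) and 102.8/11.3 (children).
    """

    n_bf: int = 1801
    n_nobf: int = 2763
    mu_true_bf: float = 103.3
    mu_true_nobf: float = 91.5
    sd_true_bf: float = 15.1
    sd_true_nobf: float = 12.4
    rho_h: float = 0.8           # corr(child true, mother true), pooled
    rho_r: float = 0.8           # corr(observed, true), mothers and children
    obs_mother_mean: float = 100.0
    obs_mother_sd: float = 15.0
    obs_child_mean: float = 102.8
    obs_child_sd: float = 11.3
    #: child true-score location/scale before the observed-scale rescale;
    #: None = pooled maternal true mean/SD. Immaterial for every observed
    #: quantity (affine invariance), exposed to make that testable.
    child_true_mean: Optional[float] = None
    child_true_sd: Optional[float] = None
    seed: int = 0
    moment_matched: bool = True

    def validate(self) -> None:
        if self.n_bf <= 0 or self.n_nobf <= 0:
            raise ValueError("group sizes must be positive")
        if self.sd_true_bf <= 0 or self.sd_true_nobf <= 0:
            raise ValueError("true-score SDs must be positive")
        for name in ("rho_h", "rho_r"):
            r = getattr(self, name)
            if not 0 < r <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {r}")
        if self.obs_mother_sd <= 0 or self.obs_child_sd <= 0:
            raise ValueError("observed-scale SDs must be positive")
        if self.moment_matched and min(self.n_bf, self.n_nobf) < 3:
            raise ValueError(
                "moment matching needs >=3 records per group to fix mean, SD "
                "and correlation simultaneously"
            )

    @property
    def n_total(self) -> int:
        return self.n_bf + self.n_nobf

    @property
    def p_bf(self) -> float:
        return self.n_bf / self.n_total

    def pooled_true_mean(self) -> float:
        p = self.p_bf
        return p * self.mu_true_bf + (1 - p) * self.mu_true_nobf

    def pooled_true_var(self) -> float:
        p = self.p_bf
        return (
            p * self.sd_true_bf**2
            + (1 - p) * self.sd_true_nobf**2
            + p * (1 - p) * (self.mu_true_bf - self.mu_true_nobf) ** 2
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str) -> "DGPConfig":
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


@dataclass
class PopulationMoments:
    """Exact population moments of (BF, observed maternal IQ, observed child IQ)."""

    mean: np.ndarray
    cov: np.ndarray
    p_bf: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.cov = np.asarray(self.cov, dtype=float).reshape(3, 3)
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("population covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-10 * np.trace(self.cov):
            raise ValueError("population covariance must be PSD")

    def as_moment_set(self, n_total: int) -> MomentSet:
        return MomentSet(mean=self.mean, cov=self.cov, n_total=n_total)


def population_moments(config: DGPConfig) -> PopulationMoments:
    """Closed-form moments of (BF, M_obs, C_obs) under the generative equations.

    Maternal true IQ is a two-component normal mixture; all z-scores are
    taken against the pooled true distribution, so Cov(BF, z_M) =
    p(1-p)(mu_bf - mu_nobf) / sigma_pooled, and the heritability and
    reliability steps each scale covariances with BF by their rho while the
    affine observed-scale maps set the final units.
    """
    config.validate()
    p = config.p_bf
    dmu = config.mu_true_bf - config.mu_true_nobf
    sigma = np.sqrt(config.pooled_true_var())
    cov_b_zm = p * (1 - p) * dmu / sigma

    sm, sc = config.obs_mother_sd, config.obs_child_sd
    rh, rr = config.rho_h, config.rho_r
    mean = np.array([p, config.obs_mother_mean, config.obs_child_mean])
    cov = np.array([
        [p * (1 - p),          sm * rr * cov_b_zm,   sc * rr * rh * cov_b_zm],
        [sm * rr * cov_b_zm,   sm**2,                sm * sc * rr**2 * rh],
        [sc * rr * rh * cov_b_zm, sm * sc * rr**2 * rh, sc**2],
    ])
    return PopulationMoments(mean=mean, cov=cov, p_bf=p)


def expected_model_coefficients(config: DGPConfig, model: str) -> LCSFit:
    """Population (expected) coefficients of one LCS parameterization.

    Applies the identical moment-to-coefficient map the fitted models use to
    the exact population moments, so a moment-matched cohort's fit must
    agree with this to numerical tolerance.
    """
    pm = population_moments(config)
    if pm.cov[0, 0] <= 0:
        raise ValueError("Var(BF) is zero: a single group cannot identify a BF effect")
    return coefficients_from_moments(pm.as_moment_set(config.n_total), model)


def _standardized(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if not s > 0:
        raise ValueError("degenerate draw: zero spread")
    return (x - x.mean()) / s


def _orthonormal_noise(rng: np.random.Generator, n: int, basis: list[np.ndarray]) -> np.ndarray:
    """A standardized noise vector with exactly zero sample covariance with
    every basis vector (moment-matched construction)."""
    if n <= len(basis) + 1:
        raise ValueError(
            f"moment matching needs n > {len(basis) + 1} records for this noise term"
        )
    v = rng.standard_normal(n)
    x = np.column_stack(basis)
    coef, *_ = np.linalg.lstsq(x, v, rcond=None)
    resid = v - x @ coef
    return _standardized(resid)


def generate_cohort(
    config: DGPConfig,
    return_latent: bool = False,
) -> Union[DyadDataset, tuple[DyadDataset, pd.DataFrame]]:
    """Generate one virtual cohort of ``n_bf + n_nobf`` complete dyads.

    Deterministic given ``config.seed``. With ``moment_matched`` on, the
    sample moments equal the configured targets exactly; off, they match in
    expectation only. With ``return_latent`` the latent true scores and
    pooled z-scores are returned alongside for diagnostics.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n1, n0 = config.n_bf, config.n_nobf
    n = n1 + n0
    bf = np.concatenate([np.ones(n1), np.zeros(n0)])

    # step 1: group-wise maternal true scores
    w1 = rng.standard_normal(n1)
    w0 = rng.standard_normal(n0)
    if config.moment_matched:
        w1, w0 = _standardized(w1), _standardized(w0)
    true_m = np.concatenate([
        config.mu_true_bf + config.sd_true_bf * w1,
        config.mu_true_nobf + config.sd_true_nobf * w0,
    ])

    # pooled maternal true z-scores
    if config.moment_matched:
        z_m = _standardized(true_m)
    else:
        z_m = (true_m - config.pooled_true_mean()) / np.sqrt(config.pooled_true_var())

    ones = np.ones(n)
    basis = [ones, bf, z_m]

    # step 2: child true scores, correlated rho_h with maternal true scores
    rh = config.rho_h
    if rh < 1:
        eps = (_orthonormal_noise(rng, n, basis) if config.moment_matched
               else rng.standard_normal(n))
        z_c = rh * z_m + np.sqrt(1 - rh**2) * eps
        basis = basis + [eps]
    else:
        z_c = z_m.copy()
    child_mu = config.child_true_mean if config.child_true_mean is not None else config.pooled_true_mean()
    child_sd = config.child_true_sd if config.child_true_sd is not None else np.sqrt(config.pooled_true_var())
    true_c = child_mu + child_sd * z_c

    # step 3: observed scores, correlated rho_r with true scores
    rr = config.rho_r
    if rr < 1:
        eta_m = (_orthonormal_noise(rng, n, basis) if config.moment_matched
                 else rng.standard_normal(n))
        z_obs_m = rr * z_m + np.sqrt(1 - rr**2) * eta_m
        basis = basis + [eta_m]
        eta_c = (_orthonormal_noise(rng, n, basis) if config.moment_matched
                 else rng.standard_normal(n))
        z_obs_c = rr * z_c + np.sqrt(1 - rr**2) * eta_c
    else:
        z_obs_m, z_obs_c = z_m.copy(), z_c.copy()

    iq_mother = config.obs_mother_mean + config.obs_mother_sd * z_obs_m
    iq_child = config.obs_child_mean + config.obs_child_sd * z_obs_c

    df = pd.DataFrame({
        "dyad_id": np.arange(1, n + 1),
        "bf": bf,
        "iq_mother": iq_mother,
        "iq_child": iq_child,
    })
    dataset = DyadDataset(df, child_index=1, provenance="synthetic")
    if not return_latent:
        return dataset
    latent = pd.DataFrame({
        "true_mother": true_m, "true_child": true_c,
        "z_mother": z_m, "z_child": z_c,
    })
    return dataset, latent


def emulate_empirical_missingness(
    dataset: DyadDataset,
    target_counts: Mapping[str, int],
    seed: int,
) -> DyadDataset:
    """MCAR-mask a complete dataset down to per-variable observed counts.

    For each substantive variable, ``n_total - target`` records are masked
    uniformly at random; any record left with all three fields missing is
    repaired by moving one of its masks to a fully observed record, so the
    counts are hit exactly and the load-filter invariant holds.
    """
    n = dataset.n_total
    rng = np.random.default_rng(seed)
    values = dataset.values.copy()
    for j, var in enumerate(SUBSTANTIVE_COLUMNS):
        target = int(target_counts.get(var, n))
        if not 0 <= target <= n:
            raise ValueError(f"target count for {var!r} must be in [0, {n}], got {target}")
        observed_now = int((~np.isnan(values[:, j])).sum())
        if target > observed_now:
            raise ValueError(
                f"infeasible target for {var!r}: {target} > {observed_now} observed"
            )
        n_mask = observed_now - target
        candidates = np.nonzero(~np.isnan(values[:, j]))[0]
        mask_idx = rng.choice(candidates, size=n_mask, replace=False)
        values[mask_idx, j] = np.nan

    # repair all-missing records without disturbing per-variable counts
    for _ in range(10 * n):
        all_missing = np.nonzero(np.isnan(values).all(axis=1))[0]
        if all_missing.size == 0:
            break
        r = all_missing[0]
        j = int(rng.integers(0, 3))
        donors = np.nonzero(
            ~np.isnan(values[:, j]) & ((~np.isnan(values)).sum(axis=1) >= 2)
        )[0]
        if donors.size == 0:
            raise ValueError("cannot repair all-missing records under these targets")
        d = int(rng.choice(donors))
        values[r, j] = dataset.values[r, j]
        values[d, j] = np.nan
    else:
        raise RuntimeError("mask repair did not terminate")

    return dataset.with_values(values, provenance=dataset.provenance + "+mcar")


def table_matched_dataset(
    n: int,
    p_bf: float,
    mean_mother: float,
    sd_mother: float,
    mean_child: float,
    sd_child: float,
    r_mother_child: float,
    r_mother_bf: float,
    r_child_bf: float,
    seed: int = 0,
    provenance: str = "synthetic-table-matched",
) -> DyadDataset:
    """Synthetic complete cohort whose sample moments match a descriptive table.

    Builds a binary BF column with round(n * p_bf) ones and IQ columns whose
    sample means, SDs and pairwise correlations (divisor-n convention) equal
    the requested values exactly, via an orthonormal-noise construction and a
    Cholesky recoloring. Useful as a stand-in for an empirical extract of
    which only the descriptive moments are known.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    n1 = int(round(n * p_bf))
    if not 0 < n1 < n:
        raise ValueError("p_bf must leave both groups non-empty")
    p = n1 / n
    rng = np.random.default_rng(seed)
    bf = np.concatenate([np.ones(n1), np.zeros(n - n1)])
    z1 = _standardized(bf)
    e2 = _orthonormal_noise(rng, n, [np.ones(n), z1])
    e3 = _orthonormal_noise(rng, n, [np.ones(n), z1, e2])

    sd_b = np.sqrt(p * (1 - p))
    mean = np.array([p, mean_mother, mean_child])
    cov = np.array([
        [sd_b**2, r_mother_bf * sd_b * sd_mother, r_child_bf * sd_b * sd_child],
        [r_mother_bf * sd_b * sd_mother, sd_mother**2, r_mother_child * sd_mother * sd_child],
        [r_child_bf * sd_b * sd_child, r_mother_child * sd_mother * sd_child, sd_child**2],
    ])
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("requested moments are not positive definite") from exc
    z = np.column_stack([z1, e2, e3])
    x = mean + z @ chol.T
    # column 0 is mu_B + sd_B * z1, which reproduces the binary bf exactly
    df = pd.DataFrame({
        "dyad_id": np.arange(1, n + 1),
        "bf": np.round(x[:, 0]).astype(float),
        "iq_mother": x[:, 1],
        "iq_child": x[:, 2],
    })
    if not np.array_equal(df["bf"].to_numpy(), bf):
        raise AssertionError("binary BF reconstruction failed")
    return DyadDataset(df, child_index=1, provenance=provenance)
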