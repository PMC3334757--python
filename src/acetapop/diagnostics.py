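"""Model evaluation: normalized prediction distribution errors (NPDE),
calibration tests and goodness-of-fit predictions.

NPDE is a simulation-based residual: K full-model Monte-Carlo replicates of
each subject's observation vector are drawn at the observed design, the
observed and simulated vectors are decorrelated with the simulation mean
and covariance (symmetric matrix square-root), and the normalized error is
the standard-normal quantile of the rank of the decorrelated observation
among its decorrelated simulations.  Under a correct model the NPDE are
iid standard normal, so their mean, variance and normality are testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._engine import ProfileEngine
from .covariates import PopulationParameters, typical_bicar0, typical_kout
from .datasets import StudyDataset

logger = logging.getLogger(__name__)

__all__ = ["NPDEResult", "compute_npde", "npde_tests", "gof_predictions"]


@dataclass
class NPDEResult:
    """Per-observation NPDE with the calibration test p-values."""

    table: pd.DataFrame  # columns ID, TIME, DV, PRED, NPDE
    K: int
    p_mean: float       # Wilcoxon signed-rank vs 0
    p_variance: float   # chi-squared variance-vs-1 test
    p_normality: float  # Shapiro-Wilk
    degenerate: bool = False

    @property
    def npde(self) -> np.ndarray:
        return self.table["NPDE"].to_numpy()


def compute_npde(
    ds: StudyDataset,
    theta: PopulationParameters,
    K: int = 500,
    rng: np.random.Generator | None = None,
    decorrelate: bool = True,
    ridge_threshold: float = 1e-10,
) -> NPDEResult:
    """NPDE of a dataset under population parameters via K simulations.

    ``decorrelate=False`` skips the whitening step (plain prediction
    distribution errors), kept for comparing within-subject correlation.
    Deterministic under a fixed generator; invariant to subject order
    because each subject consumes an independent stream drawn in ID order.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    subjects = ds.subjects()
    engine = ProfileEngine(subjects, k_elim=theta.k_elim, e_max=theta.e_max,
                           a50=theta.a50)
    rows = []
    clip = 1.0 / (2.0 * K)
    for i, subj in enumerate(subjects):
        m = len(subj.obs_times)
        sub_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
        eta = np.empty((K, 2))
        eta[:, 0] = sub_rng.normal(0.0, theta.omega_bicar0, size=K)
        eta[:, 1] = sub_rng.normal(0.0, theta.omega_kout, size=K)
        tb = typical_bicar0(theta, subj.covariates)
        tk = typical_kout(theta, subj.covariates)
        f_sim = engine.eval_subject(i, tb * np.exp(eta[:, 0]), tk * np.exp(eta[:, 1]))
        y_sim = f_sim * (1.0 + theta.sigma_prop * sub_rng.normal(size=(K, m)))
        if theta.sigma_add > 0:
            y_sim = y_sim + theta.sigma_add * sub_rng.normal(size=(K, m))
        y_obs = subj.obs_values
        mean = y_sim.mean(axis=0)
        if decorrelate and m > 0:
            S = np.cov(y_sim, rowvar=False).reshape(m, m)
            lam, V = np.linalg.eigh(S)
            floor = ridge_threshold * max(lam.max(), 1.0)
            if np.any(lam < floor):
                logger.warning("NPDE: near-singular simulation covariance for "
                               "subject %s; ridge-stabilized", subj.id)
                lam = np.maximum(lam, floor)
            W = V @ np.diag(1.0 / np.sqrt(lam)) @ V.T  # symmetric inverse sqrt
            d_obs = W @ (y_obs - mean)
            d_sim = (y_sim - mean) @ W.T
        else:
            sd = y_sim.std(axis=0, ddof=1)
            sd = np.maximum(sd, ridge_threshold)
            d_obs = (y_obs - mean) / sd
            d_sim = (y_sim - mean) / sd
        below = (d_sim < d_obs).sum(axis=0)
        ties = (d_sim == d_obs).sum(axis=0)
        p = np.clip((below + 0.5 * ties) / K, clip, 1.0 - clip)
        npde = stats.norm.ppf(p)
        for j in range(m):
            rows.append(dict(ID=subj.id, TIME=subj.obs_times[j],
                             DV=y_obs[j], PRED=mean[j], NPDE=npde[j]))
    table = pd.DataFrame(rows, columns=["ID", "TIME", "DV", "PRED", "NPDE"])
    p_mean, p_var, p_norm, degen = _tests(table["NPDE"].to_numpy())
    return NPDEResult(table=table, K=K, p_mean=p_mean, p_variance=p_var,
                      p_normality=p_norm, degenerate=degen)


def _tests(values: np.ndarray):
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("at least 3 NPDE values are required for the tests")
    if np.std(values) == 0:
        logger.warning("NPDE vector is constant; calibration tests are degenerate")
        return np.nan, np.nan, np.nan, True
    p_mean = float(stats.wilcoxon(values).pvalue)
    n = values.size
    var_stat = (n - 1) * np.var(values, ddof=1)  # ~ chi2(n-1) if var = 1
    p_var = float(2.0 * min(stats.chi2.cdf(var_stat, n - 1),
                            stats.chi2.sf(var_stat, n - 1)))
    p_var = min(p_var, 1.0)
    p_norm = float(stats.shapiro(values).pvalue)
    return p_mean, p_var, p_norm, False


def npde_tests(res_or_values) -> tuple[float, float, float]:
    """(mean-zero, variance-one, normality) p-values for NPDE values.

    Wilcoxon signed-rank against 0; a two-sided chi-squared test of the
    sample variance against 1 on n-1 degrees of freedom; Shapiro-Wilk.
    A constant vector is degenerate and yields NaNs with a warning.
    """
    values = res_or_values.npde if isinstance(res_or_values, NPDEResult) \
        else np.asarray(res_or_values, dtype=float)
    p_mean, p_var, p_norm, _ = _tests(values)
    return p_mean, p_var, p_norm


def gof_predictions(fit, ds: StudyDataset | None = None) -> pd.DataFrame:
    """Population (eta = 0) and individual (conditional-mode eta)
    predictions for every observation; columns ID, TIME, DV, PRED, IPRED."""
    if ds is None:
        ds = fit.dataset
    theta = fit.params
    subjects = ds.subjects()
    engine = ProfileEngine(subjects, k_elim=theta.k_elim, e_max=theta.e_max,
                           a50=theta.a50)
    tb = np.array([typical_bicar0(theta, s.covariates) for s in subjects])
    tk = np.array([typical_kout(theta, s.covariates) for s in subjects])
    pred = engine.eval(tb, tk)
    etas = np.asarray(fit.etas)
    ipred = engine.eval(tb * np.exp(etas[:, 0]), tk * np.exp(etas[:, 1]))
    rows = []
    for i, subj in enumerate(subjects):
        for j in range(len(subj.obs_times)):
            rows.append(dict(ID=subj.id, TIME=subj.obs_times[j],
                             DV=subj.obs_values[j],
                             PRED=pred[i, j], IPRED=ipred[i, j]))
    return pd.DataFrame(rows, columns=["ID", "TIME", "DV", "PRED", "IPRED"])
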