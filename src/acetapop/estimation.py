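"""Nonlinear mixed-effects estimation of the population model.

The observation model for subject i at time t_ij is

    y_ij = f(t_ij; Bicar0_i, kout_i) * (1 + eps_ij),   eps ~ N(0, sigma_prop^2)

(plus an optional additive component), with individual parameters obtained
from the covariate submodel and log-normal between-subject variability.
The marginal likelihood integrates the two random effects per subject over
their Normal(0, Omega) distribution.  The integral is evaluated by adaptive
Gauss-Hermite quadrature: the conditional mode of each subject's joint
density is located by a damped Newton iteration run for all subjects
simultaneously with analytic gradients (the trajectory is linear in Bicar0
and smooth in kout, so the chain rule is exact), the quadrature grid is
centred and scaled there, and one node per dimension reduces exactly to the
Laplace approximation.

Fixed effects, variance components and the residual SD are maximised
jointly with L-BFGS-B on a log-transformed scale (power-law exponents stay
untransformed).  Emax and the drug elimination rate are held fixed.
Standard errors come from the numerically differentiated observed
information at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, roots_hermite
from scipy.stats import chi2

from ._engine import ProfileEngine
from .covariates import PopulationParameters
from .datasets import StudyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FitSettings",
    "FitResult",
    "LRTResult",
    "log_marginal_likelihood",
    "fit_nlme",
    "information_criteria",
    "likelihood_ratio_test",
    "shrinkage",
    "forward_covariate_scan",
]

#: parameters estimated in the final published model, in reporting order
DEFAULT_FREE = (
    "tv_bicar0", "beta_saps", "beta_chloride", "theta_cort",
    "tv_kout", "fur50", "a50",
    "omega_bicar0", "omega_kout", "sigma_prop",
)
_LOG_SCALE = frozenset({
    "tv_bicar0", "theta_cort", "tv_kout", "fur50", "a50",
    "omega_bicar0", "omega_kout", "sigma_prop", "sigma_add",
})
#: values at which a covariate effect is absent (used by the covariate scan)
NULL_VALUES = {"beta_saps": 0.0, "beta_chloride": 0.0, "theta_cort": 1.0,
               "fur50": 1e12}
_LOG_2PI = float(np.log(2.0 * np.pi))
_ETA_CLIP = 40.0  # |eta| beyond this is prior-impossible; keeps exp() finite


@dataclass(frozen=True)
class FitSettings:
    """Estimation settings.

    ``algorithm`` selects 'laplace' (one-node) or 'agh' (adaptive
    Gauss-Hermite with ``n_agh`` nodes per random-effect dimension).
    ``free`` lists the parameters to estimate; everything else (notably
    e_max and k_elim, fixed in the final model) is held at its value in
    ``initial``.
    """

    algorithm: str = "agh"
    n_agh: int = 5
    free: tuple[str, ...] = DEFAULT_FREE
    initial: PopulationParameters | None = None  # None -> data-driven
    maxiter: int = 300
    gtol: float = 2e-2
    inner_gtol: float = 1e-8
    inner_maxiter: int = 60
    nodes_per_segment: int = 10
    compute_se: bool = True
    seed: int | None = None  # reserved for stochastic refinements

    def __post_init__(self) -> None:
        if self.algorithm not in ("laplace", "agh"):
            raise NotImplementedError(
                f"algorithm {self.algorithm!r} not available; use 'laplace' or 'agh'")
        if self.n_agh < 1 or self.maxiter < 1 or self.inner_maxiter < 1:
            raise ValueError("iteration budgets and node counts must be >= 1")
        bad = [p for p in self.free if p in ("e_max", "k_elim")]
        if bad:
            raise ValueError(f"{bad} are fixed in this model and cannot be freed")
        unknown = [p for p in self.free
                   if p not in {f.name for f in dc_fields(PopulationParameters)}]
        if unknown:
            raise ValueError(f"unknown parameters in free list: {unknown}")


# ---------------------------------------------------------------------------


class _NLMEProblem:
    """Dataset unpacked into padded arrays plus the trajectory engine."""

    def __init__(self, ds: StudyDataset, k_elim: float, e_max: float,
                 nodes_per_segment: int = 10):
        subjects = ds.subjects()
        self.n = len(subjects)
        self.engine = ProfileEngine(subjects, k_elim=k_elim, e_max=e_max,
                                    nodes_per_segment=nodes_per_segment)
        M = self.engine.M
        self.y = np.zeros((self.n, M))
        self.mask = self.engine.obs_mask
        for i, s in enumerate(subjects):
            self.y[i, :len(s.obs_values)] = s.obs_values
        self.saps = np.array([s.covariates.saps2 for s in subjects])
        self.chl = np.array([s.covariates.chloride for s in subjects])
        self.cort = np.array([s.covariates.corticosteroids for s in subjects])
        self.furo = np.array([s.covariates.furosemide_dose for s in subjects])
        self.n_obs_total = int(self.mask.sum())
        # mean pre-dose observation, for data-driven initial values
        pre = [s.obs_values[s.obs_times <= s.dose_times.min() + 1e-9]
               for s in subjects]
        pre_vals = np.concatenate([p for p in pre if p.size]) if any(
            p.size for p in pre) else np.concatenate(
                [s.obs_values for s in subjects])
        self.mean_predose = float(np.mean(pre_vals))
        amts = np.concatenate([s.dose_amounts for s in subjects])
        self.median_dose = float(np.median(amts[amts > 0])) if (amts > 0).any() else 500.0
        self.median_furo = float(np.median(self.furo[self.furo > 0])) if (
            self.furo > 0).any() else 100.0

    def structurals(self, theta: PopulationParameters):
        """Typical bicar0 and kout per subject (vectorised covariate model)."""
        tb = (theta.tv_bicar0
              * (self.saps / 50.0) ** theta.beta_saps
              * (self.chl / 100.0) ** theta.beta_chloride
              * np.where(self.cort, theta.theta_cort, 1.0))
        tk = theta.tv_kout * (1.0 - self.furo / (self.furo + theta.fur50))
        return tb, tk

    def cond_loglik(self, theta: PopulationParameters, typ_b0, typ_kout, etas):
        """Conditional log-likelihood per subject for eta array (..., n, 2)."""
        if theta.sigma_prop <= 0 and theta.sigma_add <= 0:
            raise ValueError("zero residual variance: conditional likelihood undefined")
        etas = np.asarray(etas, dtype=float)
        b0 = typ_b0 * np.exp(np.clip(etas[..., 0], -_ETA_CLIP, _ETA_CLIP))
        kout = typ_kout * np.exp(np.clip(etas[..., 1], -_ETA_CLIP, _ETA_CLIP))
        f = self.engine.eval(b0, kout)
        var = theta.sigma_add ** 2 + (theta.sigma_prop * np.maximum(f, 1e-12)) ** 2
        ll = -0.5 * ((self.y - f) ** 2 / var + np.log(var) + _LOG_2PI)
        return np.where(self.mask, ll, 0.0).sum(axis=-1)


class _MarginalLikelihood:
    """Per-theta marginal log-likelihood.

    One instance per (dataset, settings); calling it with a parameter set
    returns the per-subject log marginal likelihoods.  The conditional
    modes are located from scratch every call (grid scan + Newton), so the
    value is a deterministic pure function of theta.
    """

    def __init__(self, problem: _NLMEProblem, settings: FitSettings):
        self.prob = problem
        self.settings = settings
        self.modes = np.zeros((problem.n, 2))

    # -- residual log-density and its derivatives in f ---------------------
    def _ll_terms(self, f, deriv: int = 0):
        """Masked per-observation log-density sums and d/df derivatives."""
        y, mask = self.prob.y, self.prob.mask
        a, b = self._var_add, self._var_prop
        fv = np.maximum(f, 1e-12)
        v = a + b * fv * fv
        r = y - f
        l0 = np.where(mask, -0.5 * (r * r / v + np.log(v) + _LOG_2PI), 0.0)
        if deriv == 0:
            return l0.sum(axis=-1)
        vp = 2.0 * b * fv
        vpp = 2.0 * b
        l1 = r / v + 0.5 * r * r * vp / v ** 2 - 0.5 * vp / v
        l2 = (-1.0 / v - 2.0 * r * vp / v ** 2 + 0.5 * r * r * vpp / v ** 2
              - r * r * vp * vp / v ** 3 - 0.5 * vpp / v + 0.5 * vp * vp / v ** 2)
        return l0.sum(axis=-1), np.where(mask, l1, 0.0), np.where(mask, l2, 0.0)

    def _prior(self, eta1, eta2):
        out = 0.0
        if self._active[0]:
            out = out - 0.5 * (eta1 / self._om[0]) ** 2 \
                - np.log(self._om[0]) - 0.5 * _LOG_2PI
        if self._active[1]:
            out = out - 0.5 * (eta2 / self._om[1]) ** 2 \
                - np.log(self._om[1]) - 0.5 * _LOG_2PI
        return out

    def _h_value(self, eta):
        """h(eta) = conditional log-lik + log prior, eta of shape (n, 2)."""
        k = self._tk * np.exp(np.clip(eta[:, 1], -_ETA_CLIP, _ETA_CLIP))
        b0 = self._tb * np.exp(np.clip(eta[:, 0], -_ETA_CLIP, _ETA_CLIP))
        g = self.prob.engine.eval_g(k)
        return self._ll_terms(b0[:, None] * g) + self._prior(eta[:, 0], eta[:, 1])

    def _grad_hess(self, eta):
        """h, gradient (n, 2) and Hessian (n, 2, 2) at eta, analytically."""
        tb, tk, om = self._tb, self._tk, self._om
        b0 = tb * np.exp(np.clip(eta[:, 0], -_ETA_CLIP, _ETA_CLIP))
        k = tk * np.exp(np.clip(eta[:, 1], -_ETA_CLIP, _ETA_CLIP))
        g, dg, d2g = self.prob.engine.eval_g(k, deriv=2)
        f = b0[:, None] * g
        fk = b0[:, None] * dg * k[:, None]          # df/deta2
        fkk = fk + b0[:, None] * d2g * k[:, None] ** 2
        lsum, l1, l2 = self._ll_terms(f, deriv=2)
        h = lsum + self._prior(eta[:, 0], eta[:, 1])
        n = eta.shape[0]
        grad = np.zeros((n, 2))
        H = np.zeros((n, 2, 2))
        grad[:, 0] = (l1 * f).sum(-1)
        grad[:, 1] = (l1 * fk).sum(-1)
        H[:, 0, 0] = (l2 * f * f + l1 * f).sum(-1)
        H[:, 1, 1] = (l2 * fk * fk + l1 * fkk).sum(-1)
        H[:, 0, 1] = H[:, 1, 0] = (l2 * f * fk + l1 * fk).sum(-1)
        for d in range(2):
            if self._active[d]:
                grad[:, d] -= eta[:, d] / om[d] ** 2
                H[:, d, d] -= 1.0 / om[d] ** 2
        return h, grad, H

    # -- conditional modes --------------------------------------------------
    def _grid_scan(self):
        """Deterministic coarse scan of h over the eta plane.

        The subject-conditional surface can be multimodal in eta_kout, so
        the Newton polish is started from the argmax of a fixed grid
        spanning +-4.5 prior SDs; this makes the marginal likelihood a pure
        function of theta (no dependence on evaluation history), which the
        outer finite-difference optimiser requires.
        """
        tb, tk, om = self._tb, self._tk, self._om
        n = self.prob.n
        w1 = min(4.5 * om[1], _ETA_CLIP)
        w0 = min(4.5 * om[0], _ETA_CLIP)
        e2_grid = np.linspace(-w1, w1, 25) if self._active[1] else np.array([0.0])
        e1_grid = np.linspace(-w0, w0, 9) if self._active[0] else np.array([0.0])
        best_h = np.full(n, -np.inf)
        best = np.zeros((n, 2))
        b0_grid = tb[None, :] * np.exp(e1_grid)[:, None]        # (E1, n)
        for e2 in e2_grid:
            k = tk * np.exp(e2)
            g = self.prob.engine.eval_g(k)
            f = b0_grid[:, :, None] * g[None, :, :]
            h = self._ll_terms(f) + self._prior(e1_grid[:, None], e2)
            i1 = np.argmax(h, axis=0)
            h_e2 = h[i1, np.arange(n)]
            upd = h_e2 > best_h
            best_h[upd] = h_e2[upd]
            best[upd, 0] = e1_grid[i1[upd]]
            best[upd, 1] = e2
        return best

    def _find_modes(self):
        st = self.settings
        active_idx = [d for d in range(2) if self._active[d]]
        n = self.prob.n
        if not active_idx:
            eta = np.zeros((n, 2))
            h = self._h_value(eta)
            return eta, np.zeros((n, 2)), np.zeros((n, 2, 2)), h
        eta = self._grid_scan()
        h, grad, H = self._grad_hess(eta)
        for _ in range(st.inner_maxiter):
            ga = grad[:, active_idx]
            if np.max(np.abs(ga)) < st.inner_gtol:
                break
            step = np.zeros_like(eta)
            if len(active_idx) == 1:
                d = active_idx[0]
                curv = H[:, d, d]
                ok = curv < -1e-12
                step[:, d] = np.where(ok, -grad[:, d] / np.where(ok, curv, -1.0),
                                      np.sign(grad[:, d]))
            else:
                a, b, c = H[:, 0, 0], H[:, 0, 1], H[:, 1, 1]
                det = a * c - b * b
                ok = (a < -1e-12) & (det > 1e-16)
                dets = np.where(ok, det, 1.0)
                step[:, 0] = np.where(ok, -(c * grad[:, 0] - b * grad[:, 1]) / dets,
                                      grad[:, 0])
                step[:, 1] = np.where(ok, -(a * grad[:, 1] - b * grad[:, 0]) / dets,
                                      grad[:, 1])
            norm = np.linalg.norm(step, axis=1, keepdims=True)
            step *= np.minimum(1.0, 3.0 / np.maximum(norm, 1e-300))
            alpha = np.ones((len(eta), 1))
            accepted = eta
            for _bt in range(12):
                cand = eta + alpha * step
                h_new = self._h_value(cand)
                bad = ~(h_new >= h - 1e-12)  # NaN counts as bad
                if not bad.any():
                    accepted = cand
                    break
                alpha[bad] *= 0.5
            else:
                improved = h_new >= h
                accepted = np.where(improved[:, None], cand, eta)
            if accepted is eta:  # no subject moved; stuck
                break
            eta = accepted
            h, grad, H = self._grad_hess(eta)
        return eta, grad, H, h

    # -- adaptive Gauss-Hermite ---------------------------------------------
    def _agh(self, modes, H, n_nodes: int):
        """log Int exp(h) d eta per subject, grid centred at the modes.

        The grid is parameterised so that the kout random effect varies only
        with the outer node index: the expensive kout-dependent trajectory
        factor is computed once per outer node and shared across the inner
        (Bicar0) nodes, which enter linearly.
        """
        tb, tk, om = self._tb, self._tk, self._om
        active_idx = [d for d in range(2) if self._active[d]]
        da = len(active_idx)
        n = modes.shape[0]
        if da == 0:
            return self._h_value(modes)
        z, w = roots_hermite(n_nodes)
        logw = np.log(w)
        sqrt2 = np.sqrt(2.0)
        eng = self.prob.engine

        if da == 1:
            d = active_idx[0]
            # floor curvature at a fraction of the prior precision so a flat
            # or saddle Hessian still yields a usable quadrature scale
            p = np.maximum(-H[:, d, d], 0.25 / om[d] ** 2)
            sig = 1.0 / np.sqrt(p)
            terms = np.empty((n_nodes, n))
            if d == 0:  # Bicar0 effect only; kout fixed at typical
                g = eng.eval_g(tk)
                eta1 = modes[None, :, 0] + sqrt2 * sig[None, :] * z[:, None]
                b0 = tb * np.exp(np.clip(eta1, -_ETA_CLIP, _ETA_CLIP))
                for i in range(n_nodes):
                    terms[i] = (self._ll_terms(b0[i][:, None] * g)
                                + self._prior(eta1[i], 0.0)
                                + z[i] ** 2 + logw[i])
            else:
                b0 = tb  # eta1 fixed at 0
                for i in range(n_nodes):
                    eta2 = modes[:, 1] + sqrt2 * sig * z[i]
                    k = tk * np.exp(np.clip(eta2, -_ETA_CLIP, _ETA_CLIP))
                    g = eng.eval_g(k)
                    terms[i] = (self._ll_terms(b0[:, None] * g)
                                + self._prior(0.0, eta2)
                                + z[i] ** 2 + logw[i])
            return logsumexp(terms, axis=0) + 0.5 * np.log(2.0) + np.log(sig)

        # da == 2: C = (-H)^{-1}; Cholesky in (eta_kout, eta_bicar0) order so
        # eta_kout depends on the outer node only.  Curvatures are floored at
        # a fraction of the prior precision (usable scale even off a proper
        # mode), and the cross term is dropped if it breaks definiteness.
        a = np.maximum(-H[:, 0, 0], 0.25 / om[0] ** 2)
        b = -H[:, 0, 1]
        c = np.maximum(-H[:, 1, 1], 0.25 / om[1] ** 2)
        b = np.where(a * c - b * b > 1e-3 * a * c, b, 0.0)
        det = np.maximum(a * c - b * b, 1e-18)
        C00, C01, C11 = c / det, -b / det, a / det
        l00 = np.sqrt(C11)
        l10 = C01 / l00
        l11 = np.sqrt(np.maximum(C00 - l10 ** 2, 1e-18))
        logdetL = np.log(l00) + np.log(l11)
        terms = np.empty((n_nodes * n_nodes, n))
        for ia in range(n_nodes):
            eta2 = modes[:, 1] + sqrt2 * l00 * z[ia]
            k = tk * np.exp(np.clip(eta2, -_ETA_CLIP, _ETA_CLIP))
            g = eng.eval_g(k)
            eta1 = (modes[None, :, 0]
                    + sqrt2 * (l10[None, :] * z[ia] + l11[None, :] * z[:, None]))
            b0 = tb * np.exp(np.clip(eta1, -_ETA_CLIP, _ETA_CLIP))
            f = b0[:, :, None] * g[None, :, :]
            ll = self._ll_terms(f)
            pr = self._prior(eta1, eta2[None, :])
            terms[ia * n_nodes:(ia + 1) * n_nodes] = (
                ll + pr + z[ia] ** 2 + z[:, None] ** 2
                + logw[ia] + logw[:, None])
        return logsumexp(terms, axis=0) + np.log(2.0) + logdetL

    # -----------------------------------------------------------------------
    def __call__(self, theta: PopulationParameters, return_modes: bool = False):
        if theta.sigma_prop <= 0 and theta.sigma_add <= 0:
            raise ValueError("zero residual variance: marginal likelihood undefined")
        prob, st = self.prob, self.settings
        prob.engine.update_effect(theta.a50)
        self._tb, self._tk = prob.structurals(theta)
        self._om = np.array([theta.omega_bicar0, theta.omega_kout])
        self._active = self._om > 0
        self._var_add = theta.sigma_add ** 2
        self._var_prop = theta.sigma_prop ** 2

        modes, grad, H, h = self._find_modes()
        self.modes = modes
        n_nodes = 1 if st.algorithm == "laplace" else st.n_agh
        per_subject = self._agh(modes, H, n_nodes)
        if return_modes:
            return per_subject, modes
        return per_subject


def log_marginal_likelihood(
    ds: StudyDataset,
    theta: PopulationParameters,
    settings: FitSettings | None = None,
    by_subject: bool = False,
):
    """Marginal log-likelihood of a dataset under population parameters.

    Random effects are integrated out by adaptive Gauss-Hermite quadrature
    (default 20 nodes per dimension here, where accuracy matters more than
    speed).  Deterministic; invariant to subject relabelling.
    """
    if settings is None:
        settings = FitSettings(n_agh=20)
    prob = _NLMEProblem(ds, k_elim=theta.k_elim, e_max=theta.e_max,
                        nodes_per_segment=settings.nodes_per_segment)
    per_subject = _MarginalLikelihood(prob, settings)(theta)
    return per_subject if by_subject else float(per_subject.sum())


# ---------------------------------------------------------------------------


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics of a mixed-effects fit."""

    params: PopulationParameters
    free: tuple[str, ...]
    se: dict
    llf: float
    n_obs: int
    n_subjects: int
    etas: np.ndarray              # conditional modes (n_subjects, 2)
    converged: bool
    message: str
    cov: np.ndarray | None = None
    cov_ok: bool = True
    settings: FitSettings | None = None
    dataset: StudyDataset | None = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.free)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.n_params * np.log(self.n_obs)

    @property
    def rse_percent(self) -> dict:
        out = {}
        for name, s in self.se.items():
            est = getattr(self.params, name)
            out[name] = 100.0 * s / abs(est) if (np.isfinite(s) and est != 0) else np.nan
        return out

    @property
    def shrinkage(self) -> dict:
        return shrinkage(self)

    def predict(self, ds: StudyDataset | None = None):
        from .diagnostics import gof_predictions
        return gof_predictions(self, ds if ds is not None else self.dataset)

    def compute_npde(self, K: int = 500, rng=None, ds: StudyDataset | None = None):
        from .diagnostics import compute_npde
        return compute_npde(ds if ds is not None else self.dataset,
                            self.params, K=K, rng=rng)

    def summary(self) -> str:
        p = self.params
        rse = self.rse_percent
        shr = self.shrinkage
        lines = [
            "Population pharmacodynamic model of bicarbonate response",
            f"  subjects: {self.n_subjects}   observations: {self.n_obs}",
            f"  log-likelihood: {self.llf:.2f}   AIC: {self.aic:.1f}   BIC: {self.bic:.1f}",
            f"  converged: {self.converged}",
            "",
            f"{'Parameter':<34}{'Estimate':>12}{'(%rse)':>10}",
            f"{'Half-life, day':<34}{p.half_life:>12.4g}{'(fixed)':>10}",
        ]

        def row(label, name):
            est = getattr(p, name)
            r = rse.get(name)
            tag = f"({r:.0f})" if name in self.se and np.isfinite(rse.get(name, np.nan)) else \
                ("" if name in self.se else "(fixed)")
            lines.append(f"{label:<34}{est:>12.4g}{tag:>10}")

        row("Bicar0, mmol/L", "tv_bicar0")
        row("  x SAPS II effect (SAPS II/50)^b", "beta_saps")
        row("  x corticosteroid effect", "theta_cort")
        row("  x chloride effect (Cl/100)^b", "beta_chloride")
        row("kout, 1/day", "tv_kout")
        row("Fur50, mg/day", "fur50")
        row("A50, mg", "a50")
        row("Emax", "e_max")
        row("Residual (proportional SD)", "sigma_prop")
        lines.append("")
        lines.append(f"{'BSV (SD of log eta)':<34}{'Estimate':>12}{'(%rse)':>10}{'[shrinkage]':>14}")
        for label, name in (("omega Bicar0", "omega_bicar0"), ("omega kout", "omega_kout")):
            est = getattr(p, name)
            r = rse.get(name)
            tag = f"({r:.0f})" if name in self.se and np.isfinite(rse.get(name, np.nan)) else ""
            s = shr.get(name)
            stag = f"[{s:.2f}]" if s is not None and np.isfinite(s) else "[--]"
            lines.append(f"{label:<34}{est:>12.4g}{tag:>10}{stag:>14}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return dict(
            estimates={f.name: getattr(self.params, f.name)
                       for f in dc_fields(self.params)},
            free=list(self.free),
            se={k: float(v) for k, v in self.se.items()},
            rse_percent={k: float(v) for k, v in self.rse_percent.items()},
            llf=self.llf, aic=self.aic, bic=self.bic,
            n_obs=self.n_obs, n_subjects=self.n_subjects,
            shrinkage={k: float(v) for k, v in self.shrinkage.items()},
            converged=self.converged, message=self.message,
        )


def _default_initial(prob: _NLMEProblem) -> PopulationParameters:
    """Data-driven, scale-free initial values."""
    return PopulationParameters(
        tv_bicar0=prob.mean_predose,
        beta_saps=0.0, beta_chloride=0.0, theta_cort=1.0,
        tv_kout=0.5, fur50=prob.median_furo, a50=0.5 * prob.median_dose,
        omega_bicar0=0.1, omega_kout=0.1, sigma_prop=0.1,
    )


def _pack(theta: PopulationParameters, free) -> np.ndarray:
    x = []
    for name in free:
        v = getattr(theta, name)
        x.append(np.log(v) if name in _LOG_SCALE else v)
    return np.asarray(x)


def _unpack(x: np.ndarray, free, base: PopulationParameters) -> PopulationParameters:
    upd = {}
    for name, v in zip(free, x):
        upd[name] = float(np.exp(v)) if name in _LOG_SCALE else float(v)
    return base.replace(**upd)


def fit_nlme(ds: StudyDataset, settings: FitSettings | None = None) -> FitResult:
    """Maximum-likelihood fit of the population model to a study dataset.

    Free parameters are optimised with L-BFGS-B under a log transform for
    positivity; e_max and the drug elimination rate stay fixed, as in the
    final model.  The returned result carries estimates, standard errors,
    the marginal log-likelihood and information criteria, the per-subject
    conditional modes (empirical random effects) and their shrinkage.
    """
    if settings is None:
        settings = FitSettings()
    if ds.n_subjects < 2:
        raise ValueError("fit_nlme requires at least 2 subjects")
    base = settings.initial
    prob = _NLMEProblem(
        ds,
        k_elim=(base.k_elim if base is not None else PopulationParameters().k_elim),
        e_max=(base.e_max if base is not None else 1.0),
        nodes_per_segment=settings.nodes_per_segment,
    )
    if base is None:
        base = _default_initial(prob)
    marg = _MarginalLikelihood(prob, settings)
    free = tuple(settings.free)

    neval = [0]

    def objective(x):
        neval[0] += 1
        try:
            theta = _unpack(x, free, base)
            return -float(marg(theta).sum())
        except (ValueError, FloatingPointError):
            return 1e12  # out-of-domain excursion; finite penalty

    x0 = _pack(base, free)
    # generous box bounds on the transformed scale keep the line search away
    # from under/overflowing parameter values
    bounds = [(np.log(1e-8), np.log(1e8)) if name in _LOG_SCALE else (-50.0, 50.0)
              for name in free]
    f0 = objective(x0)
    res = minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options=dict(maxiter=settings.maxiter, ftol=1e-11,
                     gtol=settings.gtol, eps=1e-6),
    )
    converged = bool(res.success)
    message = str(res.message)
    x_hat, f_hat = res.x, float(res.fun)
    if f_hat > f0:  # never return a point worse than the start
        x_hat, f_hat = x0, f0
        converged = False
        message += " (optimizer did not improve on the initial point; kept start)"
    theta_hat = _unpack(x_hat, free, base)
    per_subject, modes = marg(theta_hat, return_modes=True)
    llf = float(per_subject.sum())

    se: dict = {name: np.nan for name in free}
    cov = None
    cov_ok = False
    if settings.compute_se:
        cov, cov_ok = _observed_information_cov(marg, theta_hat, free)
        if cov is not None:
            d = np.sqrt(np.maximum(np.diag(cov), 0.0))
            se = {name: float(d[j]) for j, name in enumerate(free)}
        if not cov_ok:
            logger.warning("observed information is not positive definite; "
                           "standard errors are approximate or missing")

    logger.info("fit_nlme: %d objective evaluations, llf=%.3f, converged=%s",
                neval[0], llf, converged)
    return FitResult(
        params=theta_hat, free=free, se=se, llf=llf,
        n_obs=prob.n_obs_total, n_subjects=prob.n,
        etas=modes, converged=converged, message=message,
        cov=cov, cov_ok=cov_ok, settings=settings, dataset=ds,
    )


def _observed_information_cov(marg, theta_hat, free, rel_step: float = 1e-3):
    """Covariance of the estimates from the FD observed information matrix."""
    p = len(free)

    def nll_at(values):
        theta = theta_hat.replace(**{name: float(v) for name, v in zip(free, values)})
        return -float(marg(theta).sum())

    v0 = np.array([getattr(theta_hat, name) for name in free], dtype=float)
    h = rel_step * np.maximum(np.abs(v0), 1e-3)
    Hm = np.zeros((p, p))
    f0 = nll_at(v0)
    for i in range(p):
        for j in range(i, p):
            if i == j:
                vp, vm = v0.copy(), v0.copy()
                vp[i] += h[i]
                vm[i] -= h[i]
                Hm[i, i] = (nll_at(vp) - 2 * f0 + nll_at(vm)) / h[i] ** 2
            else:
                vpp, vpm, vmp, vmm = v0.copy(), v0.copy(), v0.copy(), v0.copy()
                vpp[[i, j]] += [h[i], h[j]]
                vpm[i] += h[i]; vpm[j] -= h[j]
                vmp[i] -= h[i]; vmp[j] += h[j]
                vmm[[i, j]] -= [h[i], h[j]]
                Hm[i, j] = Hm[j, i] = (
                    nll_at(vpp) - nll_at(vpm) - nll_at(vmp) + nll_at(vmm)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(Hm)
        ok = bool(np.all(np.diag(cov) > 0))
        if not ok:
            cov = np.linalg.pinv(Hm)
        return cov, ok
    except np.linalg.LinAlgError:
        return np.linalg.pinv(Hm), False


def information_criteria(fit: FitResult, ds: StudyDataset | None = None):
    """(AIC, BIC) with p = number of estimated parameters and the BIC
    sample size taken as the number of observations."""
    n_ref = ds.n_obs if ds is not None else fit.n_obs
    p = fit.n_params
    return (-2.0 * fit.llf + 2.0 * p, -2.0 * fit.llf + p * np.log(n_ref))


def likelihood_ratio_test(fit_full: FitResult, fit_reduced: FitResult) -> LRTResult:
    """Chi-squared LRT of nested fits (reduced free set strictly inside full)."""
    full, red = set(fit_full.free), set(fit_reduced.free)
    if not (red < full):
        raise ValueError("models are not nested: reduced free parameters must "
                         "be a strict subset of the full model's")
    df = len(full) - len(red)
    stat = max(0.0, 2.0 * (fit_full.llf - fit_reduced.llf))
    return LRTResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def shrinkage(fit: FitResult) -> dict:
    """Per-omega eta shrinkage, 1 - sd(empirical eta)/omega (NaN if omega=0)."""
    out = {}
    for j, name in enumerate(("omega_bicar0", "omega_kout")):
        om = getattr(fit.params, name)
        if om > 0 and fit.etas.shape[0] > 1:
            out[name] = float(1.0 - np.std(fit.etas[:, j], ddof=1) / om)
        else:
            out[name] = np.nan
    return out


def forward_covariate_scan(
    ds: StudyDataset,
    base_free: tuple[str, ...] = ("tv_bicar0", "tv_kout", "a50",
                                  "omega_bicar0", "omega_kout", "sigma_prop"),
    candidates: tuple[str, ...] = ("beta_saps", "beta_chloride", "theta_cort", "fur50"),
    alpha: float = 0.05,
    settings: FitSettings | None = None,
):
    """Forward inclusion of covariate effects by likelihood ratio testing.

    Starting from a model with all candidate effects fixed at their null
    values, repeatedly frees the candidate with the smallest LRT p-value
    below ``alpha``. Returns (included candidates, final fit).
    """
    if settings is None:
        settings = FitSettings()
    base_init = settings.initial or PopulationParameters()
    null_init = base_init.replace(**{c: NULL_VALUES[c] for c in candidates})
    current = fit_nlme(ds, replace(settings, free=base_free, initial=null_init,
                                   compute_se=False))
    included: list[str] = []
    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:
            init = current.params.replace(
                **{c: NULL_VALUES[c] for c in remaining if c != cand})
            if cand == "fur50":
                init = init.replace(fur50=base_init.fur50)
            trial = fit_nlme(ds, replace(
                settings, free=tuple(current.free) + (cand,), initial=init,
                compute_se=False))
            lrt = likelihood_ratio_test(trial, current)
            if best is None or lrt.p_value < best[1].p_value:
                best = (cand, lrt, trial)
        cand, lrt, trial = best
        if lrt.p_value >= alpha:
            break
        included.append(cand)
        remaining.remove(cand)
        current = trial
    return included, current
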