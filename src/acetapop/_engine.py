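"""Vectorised bicarbonate-trajectory evaluator.

The turnover ODE dB/dt = k_in - E(t) k_out B is linear, so

    B(t) = bicar0 * ( e^{-kout*H1(t)} + kout * Int_0^t e^{kout*(H1(s)-H1(t))} ds ),
    H1(t) = Int_0^t E(s) ds,

where the inner integral H1 is available in closed form piecewise between iv
doses (see `pkpd`).  The outer integral is evaluated with a fixed composite
Gauss-Legendre rule per inter-dose segment, which makes B a smooth,
deterministic function of (bicar0, kout, a50) — exactly what the marginal
likelihood optimiser and the Monte-Carlo simulation loops need.  Node
positions and the drug amounts at them depend only on the regimen and
k_elim, so they are precomputed once; changing A50 only requires cheap
re-evaluation of logarithms.

Trajectories are linear in bicar0 and the exponents kout*(H1(s)-H1(t)) are
non-positive, so evaluation is overflow-safe for arbitrarily large kout.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = ["ProfileEngine"]


class ProfileEngine:
    """Batched trajectory evaluation for a fixed set of subjects.

    Parameters
    ----------
    subjects
        Iterable of objects with ``dose_times``, ``dose_amounts`` and
        ``obs_times`` array attributes (times in days, amounts in mg; iv
        boluses).
    k_elim, e_max
        Fixed PK/effect constants.
    a50
        Initial half-maximal amount; may be changed later with
        :meth:`update_effect`.
    nodes_per_segment
        Gauss-Legendre order used on each inter-dose segment.
    """

    def __init__(self, subjects, k_elim: float, e_max: float = 1.0,
                 a50: float | None = None, nodes_per_segment: int = 10):
        subjects = list(subjects)
        self.n = len(subjects)
        self.k_elim = float(k_elim)
        self.e_max = float(e_max)
        self._c = self.e_max / self.k_elim
        gl_x, gl_w = leggauss(nodes_per_segment)

        n_obs = np.array([len(s.obs_times) for s in subjects], dtype=int)
        self.n_obs = n_obs
        M = max(1, int(n_obs.max()) if self.n else 1)
        # max number of inter-dose segments over all (subject, obs) pairs
        S = 1
        for s in subjects:
            dt = np.asarray(s.dose_times, dtype=float)
            for t in s.obs_times:
                S = max(S, int(np.sum((dt > 0) & (dt < t))) + 1)
        Q = S * nodes_per_segment
        self.M, self.S, self.Q = M, S, Q

        self.t_obs = np.zeros((self.n, M))
        self.obs_mask = np.zeros((self.n, M), dtype=bool)
        self._A_start = np.zeros((self.n, M, S))
        self._A_end = np.zeros((self.n, M, S))
        self._s_node = np.zeros((self.n, M, Q))
        self._w_node = np.zeros((self.n, M, Q))
        self._A_node = np.zeros((self.n, M, Q))
        self._seg_idx = np.zeros((self.n, M, Q), dtype=np.intp)

        k = self.k_elim
        for i, subj in enumerate(subjects):
            dtimes = np.asarray(subj.dose_times, dtype=float)
            damts = np.asarray(subj.dose_amounts, dtype=float)
            order = np.argsort(dtimes, kind="stable")
            dtimes, damts = dtimes[order], damts[order]
            for j, t in enumerate(np.asarray(subj.obs_times, dtype=float)):
                self.t_obs[i, j] = t
                self.obs_mask[i, j] = True
                if t <= 0:
                    continue
                inner = dtimes[(dtimes > 0) & (dtimes < t)]
                bounds = np.concatenate([[0.0], inner, [t]])
                for g, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
                    # amount just after the segment start (dose at a included)
                    past = dtimes <= a
                    a_start = float(np.sum(damts[past] * np.exp(-k * (a - dtimes[past]))))
                    self._A_start[i, j, g] = a_start
                    self._A_end[i, j, g] = a_start * np.exp(-k * (b - a))
                    sl = slice(g * nodes_per_segment, (g + 1) * nodes_per_segment)
                    s_nodes = 0.5 * (a + b) + 0.5 * (b - a) * gl_x
                    self._s_node[i, j, sl] = s_nodes
                    self._w_node[i, j, sl] = 0.5 * (b - a) * gl_w
                    self._A_node[i, j, sl] = a_start * np.exp(-k * (s_nodes - a))
                    self._seg_idx[i, j, sl] = g

        self.a50: float | None = None
        if a50 is not None:
            self.update_effect(a50)

    # ------------------------------------------------------------------
    def update_effect(self, a50: float) -> None:
        """Recompute the effect integral H1 for a new half-maximal amount."""
        if a50 <= 0:
            raise ValueError("a50 must be > 0")
        ln_seg = np.log(self._A_start + a50) - np.log(self._A_end + a50)
        self._h1_t = self.t_obs + self._c * ln_seg.sum(axis=-1)
        cum_excl = np.cumsum(ln_seg, axis=-1) - ln_seg
        cum_g = np.take_along_axis(cum_excl, self._seg_idx, axis=-1)
        a_start_g = np.take_along_axis(self._A_start, self._seg_idx, axis=-1)
        h1_node = self._s_node + self._c * (
            cum_g + np.log(a_start_g + a50) - np.log(self._A_node + a50)
        )
        # H1 is increasing, so H1(node) <= H1(t) up to rounding; clip to keep
        # the exponents non-positive and padded entries inert.
        d = h1_node - self._h1_t[..., None]
        self._Dh1 = np.where(self._w_node > 0.0, np.minimum(d, 0.0), 0.0)
        self._wD = self._w_node * self._Dh1
        self._wD2 = self._wD * self._Dh1
        self.a50 = float(a50)

    # ------------------------------------------------------------------
    def eval_g(self, kout: np.ndarray, deriv: int = 0):
        """kout-dependent trajectory factor g with B = bicar0 * g.

        ``kout`` has shape (n,).  Returns g of shape (n, M), optionally with
        dg/dkout and d2g/dkout2 (used by the Newton conditional-mode search
        and by quadrature loops that reuse g across bicar0 values).
        """
        if self.a50 is None:
            raise RuntimeError("call update_effect(a50) before eval_g()")
        kq = kout[:, None, None]
        E = np.exp(kq * self._Dh1)
        I0 = np.einsum("nmq,nmq->nm", self._w_node, E)
        k2 = kout[:, None]
        e0 = np.exp(-k2 * self._h1_t)
        g = e0 + k2 * I0
        if deriv == 0:
            return g
        I1 = np.einsum("nmq,nmq->nm", self._wD, E)
        dg = -self._h1_t * e0 + I0 + k2 * I1
        if deriv == 1:
            return g, dg
        I2 = np.einsum("nmq,nmq->nm", self._wD2, E)
        d2g = self._h1_t ** 2 * e0 + 2.0 * I1 + k2 * I2
        return g, dg, d2g

    def _eval_flat(self, bicar0: np.ndarray, kout: np.ndarray) -> np.ndarray:
        """bicar0, kout of shape (n,) -> trajectories (n, M)."""
        kq = kout[:, None, None]
        integral = np.einsum("nmq,nmq->nm", self._w_node, np.exp(kq * self._Dh1))
        return bicar0[:, None] * (np.exp(-kout[:, None] * self._h1_t)
                                  + kout[:, None] * integral)

    def eval(self, bicar0, kout) -> np.ndarray:
        """Trajectories at the stored observation times.

        ``bicar0`` and ``kout`` broadcast against each other with trailing
        axis = subjects; output has shape ``(..., n_subjects, max_obs)``
        (padded entries equal bicar0; apply :attr:`obs_mask`).
        """
        if self.a50 is None:
            raise RuntimeError("call update_effect(a50) before eval()")
        b0, ko = np.broadcast_arrays(np.asarray(bicar0, float), np.asarray(kout, float))
        if b0.ndim == 1:
            return self._eval_flat(b0, ko)
        lead = b0.shape[:-1]
        B = int(np.prod(lead))
        b2 = b0.reshape(B, self.n)
        k2 = ko.reshape(B, self.n)
        out = np.empty((B, self.n, self.M))
        for r in range(B):  # chunked to bound peak memory
            out[r] = self._eval_flat(b2[r], k2[r])
        return out.reshape(*lead, self.n, self.M)

    def eval_subject(self, i: int, bicar0, kout, chunk: int = 256) -> np.ndarray:
        """Trajectories of subject ``i`` for K parameter draws -> (K, n_obs_i)."""
        if self.a50 is None:
            raise RuntimeError("call update_effect(a50) before eval_subject()")
        b0 = np.atleast_1d(np.asarray(bicar0, float))
        ko = np.atleast_1d(np.asarray(kout, float))
        m = int(self.n_obs[i])
        D = self._Dh1[i, :m]
        w = self._w_node[i, :m]
        h1t = self._h1_t[i, :m]
        K = len(ko)
        out = np.empty((K, m))
        for s in range(0, K, chunk):
            kk = ko[s:s + chunk]
            integral = np.einsum("mq,kmq->km", w, np.exp(kk[:, None, None] * D))
            out[s:s + chunk] = b0[s:s + chunk, None] * (
                np.exp(-kk[:, None] * h1t) + kk[:, None] * integral
            )
        return out
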