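"""Structural PK/PD model: drug amount under a dosing regimen and the
bicarbonate turnover trajectory it drives.

Acetazolamide kinetics follow a one-compartment model with first-order
elimination (iv bolus) and an optional first-order absorption variant
(oral/enteral route).  Amounts are tracked in mg of dose; no volume of
distribution is introduced because the half-maximal parameter A50 is
expressed in mg.

Serum bicarbonate B(t) (mmol/L) follows an indirect-response turnover model
in which the drug stimulates the loss term:

    dB/dt = k_in - E(t) * k_out * B(t),
    E(t)  = 1 + Emax * A(t) / (A(t) + A50),

with equilibrium baseline Bicar0 = k_in / k_out.  Because the ODE is linear
(non-autonomous), an integrating-factor solution exists:

    B(t) = e^{-kout*H(t)} * (Bicar0 + k_in * Int_0^t e^{kout*H(s)} ds),
    H(t) = Int_0^t E(s) ds,

and H(t) is available in closed form piecewise between iv doses, since
Int A/(A+A50) dt = -(1/k_elim) * ln(A + A50) for exponentially decaying A.
`solve_bicarbonate` integrates the ODE numerically (LSODA with dose times as
breakpoints); `oracle_bicarbonate` evaluates the integrating-factor form with
adaptive quadrature and serves as an independent check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import quad, solve_ivp

logger = logging.getLogger(__name__)

__all__ = [
    "PKConstants",
    "DoseEvent",
    "EffectParameters",
    "TurnoverState",
    "amount_iv",
    "amount_oral",
    "amount_in_body",
    "effect_multiplier",
    "solve_bicarbonate",
    "oracle_bicarbonate",
]

#: default elimination rate, 1/day (half-life fixed at 0.25 day = six hours)
DEFAULT_K_ELIM = float(np.log(2) / 0.25)


@dataclass(frozen=True)
class PKConstants:
    """First-order rate constants of the acetazolamide kinetic model."""

    k_elim: float = DEFAULT_K_ELIM  # 1/day
    k_a: float | None = None        # 1/day, absorption rate (oral variant)

    def __post_init__(self) -> None:
        if self.k_elim <= 0:
            raise ValueError("k_elim must be > 0")
        if self.k_a is not None and self.k_a <= 0:
            raise ValueError("k_a must be > 0 when present")

    @property
    def half_life(self) -> float:
        """Elimination half-life, days."""
        return float(np.log(2) / self.k_elim)


@dataclass(frozen=True)
class DoseEvent:
    """One administration: time (days since first dose), amount (mg), route."""

    time: float
    amount: float
    route: str = "iv"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")
        if self.route not in ("iv", "oral"):
            raise ValueError(f"unknown route {self.route!r}")


@dataclass(frozen=True)
class EffectParameters:
    """Emax stimulation of bicarbonate elimination by the drug amount."""

    e_max: float = 1.0   # dimensionless; fixed to 1 in the final model
    a50: float = 117.0   # mg producing half-maximal stimulation

    def __post_init__(self) -> None:
        if self.a50 <= 0:
            raise ValueError("a50 must be > 0")
        if self.e_max < 0:
            raise ValueError("e_max must be >= 0")


@dataclass(frozen=True)
class TurnoverState:
    """Bicarbonate turnover parameters at equilibrium (Bicar0 = k_in/k_out)."""

    bicar0: float  # mmol/L
    k_out: float   # 1/day

    def __post_init__(self) -> None:
        if self.bicar0 <= 0 or self.k_out <= 0:
            raise ValueError("bicar0 and k_out must be > 0")

    @property
    def k_in(self) -> float:
        """Formation rate, mmol/L/day."""
        return self.bicar0 * self.k_out

    @property
    def bicar(self) -> float:
        """Bicarbonate at t = 0 (equilibrium assumption)."""
        return self.bicar0


def _regimen_arrays(regimen: Iterable[DoseEvent]):
    doses = sorted(regimen, key=lambda d: d.time)
    times = np.array([d.time for d in doses], dtype=float)
    amounts = np.array([d.amount for d in doses], dtype=float)
    routes = [d.route for d in doses]
    return times, amounts, routes


def amount_iv(regimen: Sequence[DoseEvent], t, pk: PKConstants):
    """Drug amount in the body at time t for an iv-bolus regimen.

    Superposition of exponentially decaying boluses; a dose at exactly t is
    included (instantaneous bolus). Accepts scalar or array t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("evaluation times must be >= 0")
    times, amounts, routes = _regimen_arrays(regimen)
    if any(r != "iv" for r in routes):
        raise ValueError("amount_iv requires an all-iv regimen")
    tt = np.atleast_1d(t)
    dt = tt[:, None] - times[None, :]
    contrib = np.where(
        dt >= 0, amounts[None, :] * np.exp(-pk.k_elim * np.maximum(dt, 0.0)), 0.0
    )
    out = contrib.sum(axis=1)
    return out if t.ndim else float(out[0])


def amount_oral(regimen: Sequence[DoseEvent], t, pk: PKConstants):
    """Drug amount in the central compartment under first-order absorption.

    Bateman superposition; the degenerate case k_a == k_elim uses the
    analytic limit D * k * tau * exp(-k*tau) rather than failing.
    """
    if pk.k_a is None:
        raise ValueError("amount_oral requires k_a")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("evaluation times must be >= 0")
    times, amounts, _ = _regimen_arrays(regimen)
    ka, ke = pk.k_a, pk.k_elim
    tt = np.atleast_1d(t)
    tau = tt[:, None] - times[None, :]
    mask = tau > 0
    tau = np.where(mask, tau, 0.0)
    if np.isclose(ka, ke, rtol=1e-12, atol=0.0):
        logger.info("amount_oral: k_a == k_elim, using the t*exp(-k t) limit form")
        term = ke * tau * np.exp(-ke * tau)
    else:
        term = ka / (ka - ke) * (np.exp(-ke * tau) - np.exp(-ka * tau))
    out = np.where(mask, amounts[None, :] * term, 0.0).sum(axis=1)
    return out if t.ndim else float(out[0])


def amount_in_body(regimen: Sequence[DoseEvent], t, pk: PKConstants):
    """Total drug amount, dispatching each dose by its route."""
    iv = [d for d in regimen if d.route == "iv"]
    oral = [d for d in regimen if d.route == "oral"]
    total = 0.0
    if iv:
        total = total + amount_iv(iv, t, pk)
    if oral:
        total = total + amount_oral(oral, t, pk)
    if not iv and not oral:
        total = np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0
    return total


def effect_multiplier(amount, eff: EffectParameters):
    """E = 1 + Emax * A / (A + A50); in [1, 1 + Emax], increasing in A."""
    amount = np.asarray(amount, dtype=float)
    if np.any(amount < 0):
        raise ValueError("drug amount must be >= 0")
    out = 1.0 + eff.e_max * amount / (amount + eff.a50)
    return out if out.ndim else float(out)


def solve_bicarbonate(
    state0: TurnoverState,
    eff: EffectParameters,
    regimen: Sequence[DoseEvent],
    pk: PKConstants,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Bicarbonate trajectory at the requested times (days).

    Numeric solution of dB/dt = k_in - E(t) k_out B with A(t) from the
    regimen. Dose times are inserted as integration breakpoints so the
    discontinuities in A(t) are never smoothed over. The subject starts at
    equilibrium (B(0) = bicar0).
    """
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(np.diff(times) < 0) or np.any(times < 0)):
        raise ValueError("times must be sorted and non-negative")
    dose_times, _, _ = _regimen_arrays(regimen)

    def rhs(t, y):
        a = amount_in_body(regimen, t, pk)
        e = effect_multiplier(a, eff)
        return [state0.k_in - e * state0.k_out * y[0]]

    t_end = float(times[-1]) if times.size else 0.0
    breaks = np.unique(np.concatenate([[0.0], dose_times[dose_times < t_end], [t_end]]))
    out = np.empty_like(times)
    out[times == 0.0] = state0.bicar0
    y0 = [state0.bicar0]
    for a, b in zip(breaks[:-1], breaks[1:]):
        t_eval = times[(times > a) & (times <= b)]
        sol = solve_ivp(
            rhs, (a, b), y0, method="LSODA", rtol=rtol, atol=atol,
            t_eval=np.unique(np.concatenate([t_eval, [b]])), dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"bicarbonate ODE solve failed on [{a}, {b}]: {sol.message}"
            )
        if t_eval.size:
            out[(times > a) & (times <= b)] = np.interp(t_eval, sol.t, sol.y[0])
        y0 = [sol.y[0, -1]]
    return out


# ---------------------------------------------------------------------------
# Independent integrating-factor oracle (iv regimens only).

def _h1_factory(regimen: Sequence[DoseEvent], eff: EffectParameters, pk: PKConstants):
    """Closed-form H1(t) = Int_0^t E(s) ds for an iv regimen.

    Between doses, A decays exponentially and
    Int_a^b A/(A+A50) ds = (1/k) ln((A(a)+A50)/(A(b)+A50)).
    """
    dose_times, _, routes = _regimen_arrays(regimen)
    if any(r != "iv" for r in routes):
        raise ValueError("the integrating-factor oracle supports iv regimens only")
    k, a50, emax = pk.k_elim, eff.a50, eff.e_max

    def h1(t: float) -> float:
        if t <= 0:
            return 0.0
        bounds = np.concatenate([[0.0], dose_times[(dose_times > 0) & (dose_times < t)], [t]])
        acc = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            a_start = amount_iv(regimen, a, pk)
            a_end = a_start * np.exp(-k * (b - a))
            acc += np.log((a_start + a50) / (a_end + a50))
        return t + emax / k * acc

    return h1


def oracle_bicarbonate(
    state0: TurnoverState,
    eff: EffectParameters,
    regimen: Sequence[DoseEvent],
    pk: PKConstants,
    times,
    quad_tol: float = 1e-10,
) -> np.ndarray:
    """Integrating-factor solution evaluated with adaptive quadrature.

    B(t) = bicar0 * (e^{-kout H(t)} + kout * Int_0^t e^{kout (H1(s)-H1(t))} ds)
    with H1 in closed form piecewise; independent of the ODE solver path.
    """
    times = np.asarray(times, dtype=float)
    h1 = _h1_factory(regimen, eff, pk)
    dose_times, _, _ = _regimen_arrays(regimen)
    kout, b0 = state0.k_out, state0.bicar0
    out = np.empty_like(times)
    for i, t in enumerate(times):
        if t <= 0:
            out[i] = b0
            continue
        h1_t = h1(float(t))
        bounds = np.concatenate([[0.0], dose_times[(dose_times > 0) & (dose_times < t)], [t]])
        integral = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            val, err = quad(
                lambda s: np.exp(kout * (h1(s) - h1_t)), a, b,
                epsabs=quad_tol, epsrel=quad_tol, limit=200,
            )
            if not np.isfinite(val):
                raise RuntimeError(f"quadrature failure on [{a}, {b}] at t={t}")
            integral += val
        out[i] = b0 * (np.exp(-kout * h1_t) + kout * integral)
    return out
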