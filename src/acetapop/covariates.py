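"""Covariate submodel: population fixed effects -> individual turnover parameters.

The final population model expresses the bicarbonate baseline and elimination
rate of subject *i* as

    Bicar0_i = TV(Bicar0) * (SAPSII_i/50)^beta_saps * (Cl_i/100)^beta_cl
               * theta_cort^[steroids_i] * exp(eta_Bicar0,i)
    kout_i   = TV(kout) * (1 - Furo_i / (Furo_i + Fur50)) * exp(eta_kout,i)
    kin_i    = Bicar0_i * kout_i          (turnover equilibrium)

with eta ~ Normal(0, omega^2) on the log scale (exponential between-subject
variability) and a proportional residual error on the observations.
SAPS II is centred at 50 points and chloride at 100 mmol/L, so the typical
values are the parameters of a reference ICU patient.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np

__all__ = [
    "PopulationParameters",
    "SubjectCovariates",
    "RandomEffects",
    "IndividualParameters",
    "REFERENCE_COVARIATES",
    "typical_bicar0",
    "typical_kout",
    "individual_params",
    "sample_etas",
    "read_params",
    "write_params",
]


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, variance components and constants of the final model.

    Defaults are the published estimates of the final acetazolamide
    population model (reference: SAPS II 50, chloride 100 mmol/L, no
    steroids, no furosemide).
    """

    tv_bicar0: float = 35.5       # mmol/L, typical baseline bicarbonate
    beta_saps: float = -0.112     # exponent on (SAPS II / 50)
    beta_chloride: float = -1.18  # exponent on (chloride / 100)
    theta_cort: float = 1.092     # baseline multiplier under glucocorticoids
    tv_kout: float = 0.395        # 1/day, typical bicarbonate elimination rate
    fur50: float = 187.0          # mg/day furosemide halving kout
    a50: float = 117.0            # mg acetazolamide giving half-maximal effect
    e_max: float = 1.0            # maximal fractional stimulation (fixed)
    k_elim: float = float(np.log(2) / 0.25)  # 1/day; half-life fixed at 0.25 d
    omega_bicar0: float = 0.101   # SD of log-scale BSV on Bicar0
    omega_kout: float = 0.792     # SD of log-scale BSV on kout
    sigma_prop: float = 0.04      # proportional residual SD (4% CV)
    sigma_add: float = 0.0        # additive residual SD (mmol/L), off by default

    def __post_init__(self) -> None:
        for name in ("tv_bicar0", "tv_kout", "fur50", "a50", "theta_cort"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.omega_bicar0 < 0 or self.omega_kout < 0:
            raise ValueError("omega values must be >= 0")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual SDs must be >= 0")
        if self.k_elim <= 0:
            raise ValueError("k_elim must be > 0")

    @property
    def half_life(self) -> float:
        """Acetazolamide elimination half-life in days."""
        return float(np.log(2) / self.k_elim)

    def replace(self, **kwargs) -> "PopulationParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SubjectCovariates:
    """Covariates entering the final model for one subject."""

    saps2: float = 50.0            # SAPS II at ICU admission, points
    chloride: float = 100.0        # serum chloride, mmol/L
    corticosteroids: bool = False  # concomitant glucocorticoid administration
    furosemide_dose: float = 0.0   # mg/day

    def __post_init__(self) -> None:
        if self.saps2 <= 0:
            raise ValueError(f"saps2 must be > 0, got {self.saps2}")
        if self.chloride <= 0:
            raise ValueError(f"chloride must be > 0, got {self.chloride}")
        if self.furosemide_dose < 0:
            raise ValueError("furosemide_dose must be >= 0")


REFERENCE_COVARIATES = SubjectCovariates()


@dataclass(frozen=True)
class RandomEffects:
    """Log-scale deviations of one subject from the typical parameters."""

    eta_bicar0: float = 0.0
    eta_kout: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eta_bicar0) and np.isfinite(self.eta_kout)):
            raise ValueError("etas must be finite")


@dataclass(frozen=True)
class IndividualParameters:
    """Realized turnover parameters of one subject."""

    bicar0: float  # mmol/L
    kout: float    # 1/day

    @property
    def kin(self) -> float:
        """Bicarbonate formation rate (mmol/L/day), from equilibrium."""
        return self.bicar0 * self.kout


def typical_bicar0(theta: PopulationParameters, cov: SubjectCovariates) -> float:
    """Typical (eta = 0) baseline bicarbonate for a subject's covariates."""
    return float(
        theta.tv_bicar0
        * (cov.saps2 / 50.0) ** theta.beta_saps
        * (cov.chloride / 100.0) ** theta.beta_chloride
        * (theta.theta_cort if cov.corticosteroids else 1.0)
    )


def typical_kout(theta: PopulationParameters, cov: SubjectCovariates) -> float:
    """Typical bicarbonate elimination rate; furosemide attenuates it (Imax form)."""
    frac = cov.furosemide_dose / (cov.furosemide_dose + theta.fur50)
    return float(theta.tv_kout * (1.0 - frac))


def individual_params(
    theta: PopulationParameters,
    cov: SubjectCovariates,
    eta: RandomEffects = RandomEffects(),
) -> IndividualParameters:
    """Apply exponential between-subject variability to the typical values."""
    return IndividualParameters(
        bicar0=typical_bicar0(theta, cov) * float(np.exp(eta.eta_bicar0)),
        kout=typical_kout(theta, cov) * float(np.exp(eta.eta_kout)),
    )


def sample_etas(
    theta: PopulationParameters, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n pairs (eta_bicar0, eta_kout), independent Normal(0, omega^2).

    Returns an array of shape (n, 2). Reproducible under a fixed generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty((n, 2))
    out[:, 0] = rng.normal(0.0, theta.omega_bicar0, size=n)
    out[:, 1] = rng.normal(0.0, theta.omega_kout, size=n)
    return out


# ---------------------------------------------------------------------------
# Flat key = value parameter files (one parameter per line, '#' comments).

def write_params(theta: PopulationParameters, path: str | Path) -> None:
    lines = ["# acetazolamide population model parameters"]
    for f in fields(theta):
        lines.append(f"{f.name} = {getattr(theta, f.name)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path: str | Path) -> PopulationParameters:
    known = {f.name for f in fields(PopulationParameters)}
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'name = value', got {raw!r}")
        name, value = (part.strip() for part in line.split("=", 1))
        if name not in known:
            raise ValueError(f"{path}:{lineno}: unknown parameter {name!r}")
        values[name] = float(value)
    return PopulationParameters(**values)
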