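"""Synthetic study generation and the NONMEM-like dataset dialect.

The generator emulates the design of a retrospective ICU study of invasively
ventilated COPD patients treated with acetazolamide during weaning: 250 or
500 mg boluses twice daily, arterial bicarbonate sampled before the first
dose and up to 24 h after a dose, a median of three observations per patient
(range 1 to 6), and covariates (SAPS II, serum chloride, glucocorticoid and
furosemide co-prescription) drawn to match the published population
characteristics (medians and ranges; the distribution shapes themselves are
modelling choices, see docs/methods.md).

Datasets are long-format CSV with columns
``ID, TIME, EVID, AMT, DV, MDV, SAPS2, CHLORIDE, CORT, FURO``
(EVID 1 = dose, 0 = observation; TIME in days; AMT in mg; DV in mmol/L).
Simulated datasets additionally carry the realized individual parameters
(``TRUE_BICAR0``, ``TRUE_KOUT``, ``ETA_BICAR0``, ``ETA_KOUT``) so recovery
experiments can compare estimates against the generating truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._engine import ProfileEngine
from .covariates import (
    PopulationParameters,
    SubjectCovariates,
    typical_bicar0,
    typical_kout,
    sample_etas,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "Subject",
    "StudyDataset",
    "generate_study",
    "read_dataset",
    "write_dataset",
    "delta_24h_summary",
]

REQUIRED_COLUMNS = (
    "ID", "TIME", "EVID", "AMT", "DV", "MDV", "SAPS2", "CHLORIDE", "CORT", "FURO",
)
TRUTH_COLUMNS = ("TRUE_BICAR0", "TRUE_KOUT", "ETA_BICAR0", "ETA_KOUT")


@dataclass(frozen=True)
class StudyDesign:
    """Study-design settings matched to the published population."""

    n_subjects: int = 68
    saps2_median: float = 47.0
    saps2_log_sd: float = 0.30
    saps2_bounds: tuple[float, float] = (20.0, 95.0)
    chloride_mean: float = 96.0
    chloride_sd: float = 7.0
    chloride_bounds: tuple[float, float] = (69.0, 108.0)
    p_corticosteroids: float = 0.147
    p_furosemide: float = 0.471
    furosemide_range: tuple[float, float] = (20.0, 160.0)
    dose_menu: tuple[float, ...] = (250.0, 500.0)  # mg per administration
    doses_per_day: int = 2
    duration_days: float = 3.0
    #: P(number of observations = 1..6); median 3, range 1-6
    obs_count_probs: tuple[float, ...] = (0.12, 0.22, 0.28, 0.18, 0.12, 0.08)
    obs_window_days: float = 1.0  # observations up to 24 h after a dose

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for p in (self.p_corticosteroids, self.p_furosemide):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.obs_count_probs) - 1.0) > 1e-9:
            raise ValueError("obs_count_probs must sum to 1")
        if min(self.dose_menu) < 0:
            raise ValueError("doses must be >= 0")
        if self.duration_days <= 0 or self.doses_per_day < 1:
            raise ValueError("invalid regimen settings")


@dataclass
class Subject:
    """One subject's covariates, dosing history and observations."""

    id: int
    covariates: SubjectCovariates
    dose_times: np.ndarray
    dose_amounts: np.ndarray
    obs_times: np.ndarray
    obs_values: np.ndarray
    truth: dict | None = None  # simulation provenance, if any


class StudyDataset:
    """Long-format dosing/observation table with per-subject accessors."""

    def __init__(self, df: pd.DataFrame):
        self._df = self._validate(df)
        self._subjects: list[Subject] | None = None

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing mandatory columns: {missing}")
        df = df.reset_index(drop=True)
        if (df["AMT"].fillna(0) < 0).any():
            row = int(df.index[df["AMT"].fillna(0) < 0][0])
            raise ValueError(f"row {row}: negative dose amount")
        if (df["TIME"] < 0).any():
            row = int(df.index[df["TIME"] < 0][0])
            raise ValueError(f"row {row}: negative time")
        for sid, grp in df.groupby("ID", sort=False):
            t = grp["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                row = int(grp.index[1:][np.diff(t) < 0][0])
                raise ValueError(f"row {row}: non-monotone times within subject {sid}")
            if not (grp["EVID"] == 1).any():
                raise ValueError(f"subject {sid} has no dose record")
            if not (grp["EVID"] == 0).any():
                raise ValueError(f"subject {sid} has no observation record")
        return df

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def has_truth(self) -> bool:
        return all(c in self._df.columns for c in TRUTH_COLUMNS)

    @property
    def n_subjects(self) -> int:
        return self._df["ID"].nunique()

    @property
    def n_obs(self) -> int:
        return int((self._df["EVID"] == 0).sum())

    def subjects(self) -> list[Subject]:
        if self._subjects is None:
            out = []
            for sid, grp in self._df.groupby("ID", sort=False):
                doses = grp[grp["EVID"] == 1]
                obs = grp[grp["EVID"] == 0]
                first = grp.iloc[0]
                cov = SubjectCovariates(
                    saps2=float(first["SAPS2"]),
                    chloride=float(first["CHLORIDE"]),
                    corticosteroids=bool(first["CORT"]),
                    furosemide_dose=float(first["FURO"]),
                )
                truth = None
                if all(c in grp.columns for c in TRUTH_COLUMNS):
                    truth = {c.lower(): float(first[c]) for c in TRUTH_COLUMNS}
                out.append(Subject(
                    id=int(sid),
                    covariates=cov,
                    dose_times=doses["TIME"].to_numpy(dtype=float),
                    dose_amounts=doses["AMT"].to_numpy(dtype=float),
                    obs_times=obs["TIME"].to_numpy(dtype=float),
                    obs_values=obs["DV"].to_numpy(dtype=float),
                    truth=truth,
                ))
            self._subjects = out
        return self._subjects

    def observations(self) -> pd.DataFrame:
        """Observation rows only (EVID == 0)."""
        return self._df[self._df["EVID"] == 0].copy()


def _truncated(draw, lo: float, hi: float, rng: np.random.Generator,
               max_tries: int = 1000) -> float:
    for _ in range(max_tries):
        x = draw(rng)
        if lo <= x <= hi:
            return float(x)
    raise ValueError(f"truncated sampling failed to hit [{lo}, {hi}]")


def generate_study(
    design: StudyDesign,
    theta: PopulationParameters,
    rng: np.random.Generator,
) -> StudyDataset:
    """Simulate a study dataset under the population model.

    For each subject: draw covariates, draw random effects, build the
    regimen, solve the bicarbonate trajectory at the sampled observation
    times and emit y = f * (1 + eps) with proportional (plus optional
    additive) residual noise.  The realized individual parameters are stored
    as provenance columns.
    """
    n = design.n_subjects
    mu_saps = np.log(design.saps2_median)

    covs: list[SubjectCovariates] = []
    for _ in range(n):
        saps = _truncated(
            lambda r: np.exp(r.normal(mu_saps, design.saps2_log_sd)),
            *design.saps2_bounds, rng)
        chl = _truncated(
            lambda r: r.normal(design.chloride_mean, design.chloride_sd),
            *design.chloride_bounds, rng)
        cort = bool(rng.random() < design.p_corticosteroids)
        if rng.random() < design.p_furosemide:
            furo = float(rng.uniform(*design.furosemide_range))
        else:
            furo = 0.0
        covs.append(SubjectCovariates(saps, chl, cort, furo))

    etas = sample_etas(theta, n, rng)
    n_dose = int(np.ceil(design.duration_days * design.doses_per_day))
    interval = 1.0 / design.doses_per_day
    counts = rng.choice(np.arange(1, len(design.obs_count_probs) + 1), size=n,
                        p=np.asarray(design.obs_count_probs))
    dose_amounts_pick = rng.choice(np.asarray(design.dose_menu), size=n)

    subjects: list[Subject] = []
    for i in range(n):
        dose_times = np.arange(n_dose) * interval
        dose_amts = np.full(n_dose, dose_amounts_pick[i])
        extra = int(counts[i]) - 1
        obs = [0.0]  # pre-dose sample of the equilibrium baseline
        for _ in range(extra):
            j = int(rng.integers(0, n_dose))
            offset = rng.uniform(0.0, design.obs_window_days)
            obs.append(dose_times[j] + max(offset, 1e-6))
        obs_times = np.sort(np.asarray(obs))
        subjects.append(Subject(
            id=i + 1, covariates=covs[i],
            dose_times=dose_times, dose_amounts=dose_amts,
            obs_times=obs_times, obs_values=np.empty(0),
        ))

    engine = ProfileEngine(subjects, k_elim=theta.k_elim, e_max=theta.e_max,
                           a50=theta.a50)
    b0 = np.array([typical_bicar0(theta, c) for c in covs]) * np.exp(etas[:, 0])
    kout = np.array([typical_kout(theta, c) for c in covs]) * np.exp(etas[:, 1])
    if np.any(kout <= 0) or np.any(b0 <= 0):
        raise ValueError("design yields non-positive individual parameters")
    f = engine.eval(b0, kout)  # (n, max_obs)

    rows = []
    for i, subj in enumerate(subjects):
        m = len(subj.obs_times)
        eps = rng.normal(0.0, 1.0, size=m)
        y = f[i, :m] * (1.0 + theta.sigma_prop * eps)
        if theta.sigma_add > 0:
            y = y + rng.normal(0.0, theta.sigma_add, size=m)
        subj.obs_values = y
        c = subj.covariates
        common = dict(
            ID=subj.id, SAPS2=c.saps2, CHLORIDE=c.chloride,
            CORT=int(c.corticosteroids), FURO=c.furosemide_dose,
            TRUE_BICAR0=b0[i], TRUE_KOUT=kout[i],
            ETA_BICAR0=etas[i, 0], ETA_KOUT=etas[i, 1],
        )
        events = (
            [dict(TIME=t, EVID=0, AMT=0.0, DV=v, MDV=0, **common)
             for t, v in zip(subj.obs_times, y)]
            + [dict(TIME=t, EVID=1, AMT=a, DV=np.nan, MDV=1, **common)
               for t, a in zip(subj.dose_times, subj.dose_amounts)]
        )
        # stable sort by time; pre-dose observations precede same-time doses
        events.sort(key=lambda e: (e["TIME"], e["EVID"]))
        rows.extend(events)

    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(TRUTH_COLUMNS))
    return StudyDataset(df)


def write_dataset(ds: StudyDataset, path: str | Path) -> None:
    ds.df.to_csv(path, index=False)


def read_dataset(path: str | Path) -> StudyDataset:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise ValueError(f"could not parse dataset {path}: {exc}") from exc
    return StudyDataset(df)


def delta_24h_summary(ds: StudyDataset, window: float = 0.25) -> pd.DataFrame:
    """Intrapatient 24 h bicarbonate change, summarised by total daily dose.

    For each subject with both a pre-dose observation and an observation
    within ``window`` days of t = 1 day, compute (bicarbonate at ~24 h -
    pre-dose bicarbonate); group subjects by the total dose administered in
    the first day and report median, quartiles and 10th/90th percentiles.
    Subjects lacking either anchor are excluded; the count is logged and
    stored in ``result.attrs['n_excluded']``.
    """
    records = []
    n_excluded = 0
    for subj in ds.subjects():
        first_dose_t = subj.dose_times.min() if len(subj.dose_times) else np.inf
        pre_mask = subj.obs_times <= first_dose_t + 1e-9
        day_mask = np.abs(subj.obs_times - 1.0) <= window
        if not pre_mask.any() or not day_mask.any():
            n_excluded += 1
            continue
        pre = subj.obs_values[pre_mask][0]
        idx = np.argmin(np.abs(subj.obs_times[day_mask] - 1.0))
        at24 = subj.obs_values[day_mask][idx]
        total_dose = float(subj.dose_amounts[subj.dose_times < 1.0].sum())
        records.append((total_dose, at24 - pre))
    if n_excluded:
        logger.warning("delta_24h_summary: excluded %d subject(s) lacking "
                       "pre-dose or ~24 h observations", n_excluded)
    out_rows = []
    by_dose: dict[float, list[float]] = {}
    for dose, diff in records:
        by_dose.setdefault(dose, []).append(diff)
    for dose in sorted(by_dose):
        d = np.asarray(by_dose[dose])
        out_rows.append(dict(
            total_dose=dose, n=len(d), median=np.median(d),
            q25=np.percentile(d, 25), q75=np.percentile(d, 75),
            p10=np.percentile(d, 10), p90=np.percentile(d, 90),
        ))
    table = pd.DataFrame(out_rows,
                         columns=["total_dose", "n", "median", "q25", "q75", "p10", "p90"])
    table.attrs["n_excluded"] = n_excluded
    return table
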