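"""Model/Results front end in the style of statistical modelling packages.

``BicarbonateTurnoverModel`` is built from a study dataset (long-format
dosing/observation table); ``fit()`` returns a
``BicarbonateTurnoverResults`` (= :class:`~acetapop.estimation.FitResult`)
carrying estimates, standard errors, information criteria, empirical random
effects and shrinkage, with ``summary()``, ``predict()`` and
``compute_npde()`` hanging off it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .covariates import PopulationParameters
from .datasets import StudyDataset, read_dataset
from .estimation import FitResult, FitSettings, fit_nlme, log_marginal_likelihood

__all__ = ["BicarbonateTurnoverModel", "BicarbonateTurnoverResults"]

BicarbonateTurnoverResults = FitResult


class BicarbonateTurnoverModel:
    """Population turnover model of serum bicarbonate under acetazolamide.

    Parameters
    ----------
    dataset
        A :class:`~acetapop.datasets.StudyDataset` (long-format dosing and
        observation records with covariates).
    settings
        Default :class:`~acetapop.estimation.FitSettings`; individual
        keywords to :meth:`fit` override these.

    Examples
    --------
    >>> model = BicarbonateTurnoverModel.from_csv("data.csv")  # doctest: +SKIP
    >>> results = model.fit()                                  # doctest: +SKIP
    >>> print(results.summary())                               # doctest: +SKIP
    """

    def __init__(self, dataset: StudyDataset, settings: FitSettings | None = None):
        self.dataset = dataset
        self.settings = settings or FitSettings()

    @classmethod
    def from_csv(cls, path: str | Path, settings: FitSettings | None = None):
        return cls(read_dataset(path), settings=settings)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, settings: FitSettings | None = None):
        return cls(StudyDataset(df), settings=settings)

    @property
    def n_subjects(self) -> int:
        return self.dataset.n_subjects

    @property
    def n_obs(self) -> int:
        return self.dataset.n_obs

    def loglike(self, theta: PopulationParameters,
                settings: FitSettings | None = None) -> float:
        """Marginal log-likelihood of the data under ``theta``."""
        return log_marginal_likelihood(self.dataset, theta, settings=settings)

    def fit(self, settings: FitSettings | None = None, **kwargs) -> FitResult:
        """Maximum-likelihood estimation; returns a results object."""
        st = settings or self.settings
        if kwargs:
            from dataclasses import replace
            st = replace(st, **kwargs)
        return fit_nlme(self.dataset, st)
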