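"""Model/Results object surface.

``SizeCoxModel`` is constructed from a cohort table plus a model
definition; ``fit()`` returns a ``SizeCoxResults`` carrying the
estimates, their uncertainties and diagnostics, with a ``summary()``
table.  ``ResamplingStudy`` plays the same role for the bootstrap
experiment.  Both are thin, stateful wrappers over the functional core
(:mod:`gbmsize.cox`, :mod:`gbmsize.resampling`).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cox import ADJUSTMENT_VARIABLES, CoxFit, ModelSpec, fit_cox
from .resampling import (
    KSResult,
    ResamplingConfig,
    ResamplingResult,
    compare_extremes,
    run_resampling,
)
from .spline import SplineCurve, fit_penalized_spline

__all__ = ["SizeCoxModel", "SizeCoxResults", "ResamplingStudy", "ResamplingResults"]


class SizeCoxModel:
    """Cox model of one tumour-size variable, built from a cohort table.

    Parameters
    ----------
    data
        Cohort table with the standard columns (``age``, ``sex``,
        ``surgery``, ``oncology``, ``mgmt``, ``diameter_cm``,
        ``cv_cm3``, ``wv_cm3``, ``time_months``, ``event``).
    size
        ``'diameter'``, ``'cv'`` or ``'wv'``.
    transform
        ``'identity'`` or ``'log'``.
    adjust
        Clinical covariates to adjust for, in order; ``'all'`` expands
        to age + sex + surgery + oncology + mgmt.

    Examples
    --------
    >>> model = SizeCoxModel(cohort, size="wv", transform="log",
    ...                      adjust=["surgery"])           # doctest: +SKIP
    >>> res = model.fit()                                  # doctest: +SKIP
    >>> res.summary()                                      # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, size: str, transform: str = "identity", adjust=()):
        if adjust == "all":
            adjust = ADJUSTMENT_VARIABLES
        elif isinstance(adjust, str):
            adjust = (adjust,)
        self.data = data
        self.spec = ModelSpec(size, transform, tuple(adjust))

    @classmethod
    def from_spec(cls, data: pd.DataFrame, spec: ModelSpec) -> "SizeCoxModel":
        obj = cls.__new__(cls)
        obj.data = data
        obj.spec = spec
        return obj

    def fit(self) -> "SizeCoxResults":
        return SizeCoxResults(self, fit_cox(self.data, self.spec))

    def fit_spline(self, **kwargs) -> SplineCurve:
        """Penalised-spline check of nonlinearity in the size variable."""
        return fit_penalized_spline(
            self.data, self.spec.size_variable, transform=self.spec.transform, **kwargs
        )


class SizeCoxResults:
    """Estimates and diagnostics from a fitted :class:`SizeCoxModel`."""

    def __init__(self, model: SizeCoxModel, fit: CoxFit):
        self.model = model
        self.fit_ = fit

    # statsmodels-flavoured accessors
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit_.beta, index=self.fit_.terms, name="coef")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.fit_.se, index=self.fit_.terms, name="se")

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self.fit_.wald_pvalues, index=self.fit_.terms, name="p")

    @property
    def hazard_ratios(self) -> pd.Series:
        return pd.Series(self.fit_.hr, index=self.fit_.terms, name="hr")

    @property
    def concordance(self) -> float:
        return self.fit_.concordance

    @property
    def size_p(self) -> float:
        return self.fit_.size_p

    @property
    def converged(self) -> bool:
        return self.fit_.converged

    def conf_int(self) -> pd.DataFrame:
        ci = self.fit_.ci95
        return pd.DataFrame(ci, index=self.fit_.terms, columns=["hr_ci_lo", "hr_ci_hi"])

    def summary(self) -> pd.DataFrame:
        """Per-term table: coef, se, HR with 95% CI, Wald p."""
        frame = self.fit_.to_frame().set_index("term")
        frame.attrs.update(
            {
                "model": self.fit_.spec.label,
                "n_used": self.fit_.n_used,
                "n_events": self.fit_.n_events,
                "concordance": self.fit_.concordance,
                "overall_wald_p": self.fit_.overall_wald_p,
                "converged": self.fit_.converged,
                "dropped_terms": list(self.fit_.dropped_terms),
            }
        )
        return frame

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        f = self.fit_
        return (
            f"<SizeCoxResults {f.spec.label!r} n={f.n_used} events={f.n_events} "
            f"C={f.concordance:.3f} size_p={f.size_p:.4f}>"
        )


class ResamplingStudy:
    """Bootstrap power study of tumour-size models on one cohort."""

    def __init__(self, data: pd.DataFrame, config: ResamplingConfig | None = None, **kwargs):
        if config is None:
            config = ResamplingConfig(**kwargs)
        elif kwargs:
            config = replace(config, **kwargs)
        self.data = data
        self.config = config

    def fit(self, progress=None) -> "ResamplingResults":
        return ResamplingResults(run_resampling(self.data, self.config, progress=progress))


class ResamplingResults:
    """Percent-significant tables and KS comparisons for a finished study."""

    def __init__(self, result: ResamplingResult):
        self.result = result

    def percent_table(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.result.percent_table(alpha)

    def summary(self) -> pd.DataFrame:
        return self.percent_table(0.05)

    def pvalues(self, spec: ModelSpec, sample_size: int) -> np.ndarray:
        cell = self.result.cell(spec, sample_size)
        if cell.pvalues is None:
            raise ValueError("p-values were not stored; enable store_pvalues")
        return cell.pvalues

    def ks_extremes(self, spec: ModelSpec) -> KSResult:
        return compare_extremes(self.result, spec)

    def long_frame(self) -> pd.DataFrame:
        return self.result.long_frame()
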