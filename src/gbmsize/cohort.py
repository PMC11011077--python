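"""Synthetic glioblastoma survival cohorts.

Generates patient tables with the joint structure the downstream Cox
analysis assumes: correlated tumour-size variables (maximum diameter,
core volume CV, whole volume WV) drawn through a Gaussian copula with
quartile-matched marginals, clinical covariates (age, sex, extent of
surgery, adjuvant oncology, MGMT promoter methylation with missingness),
a Weibull proportional-hazards outcome model on a centred linear
predictor, and uniform potential censoring.

The outcome model is exactly the model the analysis fits: the hazard for
patient *i* is ``h0(t) * exp(lp_i)`` with a Weibull baseline ``h0``, so
parameter-recovery and calibration checks have a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .config import (
    CohortConfig,
    MGMT_LEVELS,
    ONCOLOGY_LEVELS,
    SURGERY_LEVELS,
)

__all__ = [
    "SizeDistribution",
    "lognormal_from_quartiles",
    "truncnorm_from_quartiles",
    "sample_covariates",
    "linear_predictor",
    "sample_survival_times",
    "apply_censoring",
    "generate_cohort",
    "summarize_cohort",
]

_Z75 = 0.6744897501960817  # Phi^{-1}(0.75)

#: Column order of the cohort CSV interface.
COHORT_COLUMNS = [
    "age",
    "sex",
    "surgery",
    "oncology",
    "mgmt",
    "diameter_cm",
    "cv_cm3",
    "wv_cm3",
    "time_months",
    "event",
]


@dataclass(frozen=True)
class SizeDistribution:
    """A quartile-matched marginal for one size variable.

    ``lognormal``: ln(X) ~ N(mu, sigma^2).  ``truncated-normal``:
    X ~ N(mu, sigma^2) truncated to [lo, hi].  ``degenerate`` marks the
    zero-spread point mass obtained when all three quartiles coincide.
    """

    family: str
    mu: float
    sigma: float
    lo: float = -np.inf
    hi: float = np.inf

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.degenerate:
            centre = np.exp(self.mu) if self.family == "lognormal" else self.mu
            return np.full_like(u, centre)
        if self.family == "lognormal":
            return np.exp(self.mu + self.sigma * special.ndtri(u))
        a = (self.lo - self.mu) / self.sigma
        b = (self.hi - self.mu) / self.sigma
        return stats.truncnorm.ppf(u, a, b, loc=self.mu, scale=self.sigma)

    def quantile(self, q: float) -> float:
        return float(self.ppf(np.array([q]))[0])


def lognormal_from_quartiles(median: float, q1: float, q3: float) -> SizeDistribution:
    """Lognormal with the given theoretical median and quartiles.

    mu = ln(median), sigma = (ln q3 - ln q1) / (2 * z_0.75); the returned
    distribution's median and IQR reproduce the inputs exactly.
    """
    if median <= 0 or q1 <= 0 or q3 <= 0:
        raise ValueError("quartiles must be positive")
    if q1 == median == q3:
        return SizeDistribution("lognormal", float(np.log(median)), 0.0)
    if not q1 < median < q3:
        raise ValueError("need q1 < median < q3")
    mu = float(np.log(median))
    sigma = float((np.log(q3) - np.log(q1)) / (2.0 * _Z75))
    return SizeDistribution("lognormal", mu, sigma)


def truncnorm_from_quartiles(
    median: float,
    q1: float,
    q3: float,
    lo: float = -np.inf,
    hi: float = np.inf,
) -> SizeDistribution:
    """Truncated normal whose *truncated* quartiles match the inputs.

    (mu, sigma) are solved numerically so that the quantile conditions
    hold after truncation to [lo, hi]; with infinite bounds this reduces
    to mu = median, sigma = IQR / (2 * z_0.75).
    """
    if q1 == median == q3:
        return SizeDistribution("truncated-normal", float(median), 0.0, lo, hi)
    if not q1 < median < q3:
        raise ValueError("need q1 < median < q3")
    if not (lo < q1 and q3 < hi):
        raise ValueError("quartiles must lie strictly inside [lo, hi]")
    mu, sigma = _solve_truncnorm(float(median), float(q1), float(q3), float(lo), float(hi))
    return SizeDistribution("truncated-normal", mu, sigma, lo, hi)


@lru_cache(maxsize=256)
def _solve_truncnorm(median, q1, q3, lo, hi):
    sigma0 = (q3 - q1) / (2.0 * _Z75)

    def equations(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        med = stats.truncnorm.ppf(0.5, a, b, loc=mu, scale=sigma)
        iqr = stats.truncnorm.ppf(0.75, a, b, loc=mu, scale=sigma) - stats.truncnorm.ppf(
            0.25, a, b, loc=mu, scale=sigma
        )
        return [med - median, iqr - (q3 - q1)]

    sol = optimize.root(equations, x0=[median, np.log(sigma0)], method="hybr")
    if not sol.success or max(abs(v) for v in equations(sol.x)) > 1e-6:
        # e.g. an IQR at or beyond the uniform-limit of the truncation window
        raise ValueError(
            "truncated-normal quartile matching failed: the requested "
            f"median/IQR are not achievable inside [{lo}, {hi}]"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


# ----------------------------------------------------------------------
# covariates


def _sample_sizes(config: CohortConfig, n: int, rng: np.random.Generator):
    """Correlated (diameter, CV, WV) via a Gaussian copula.

    Returns the three size vectors plus the standardised WV latent score
    (used by the surgery proportional-odds association).
    """
    d_diam = truncnorm_from_quartiles(
        config.diameter_median, config.diameter_q1, config.diameter_q3, lo=0.5
    )
    d_cv = lognormal_from_quartiles(config.cv_median, config.cv_q1, config.cv_q3)
    d_wv = lognormal_from_quartiles(config.wv_median, config.wv_q1, config.wv_q3)
    chol = np.linalg.cholesky(config.copula_matrix)

    def draw(m: int):
        z = rng.standard_normal((m, 3)) @ chol.T
        u = special.ndtr(z)
        return z, d_diam.ppf(u[:, 0]), d_cv.ppf(u[:, 1]), d_wv.ppf(u[:, 2])

    z, diam, cv, wv = draw(n)
    if config.enforce_nesting:
        for _ in range(100):
            bad = wv <= cv
            if not bad.any():
                break
            zb, db, cb, wb = draw(int(bad.sum()))
            z[bad], diam[bad], cv[bad], wv[bad] = zb, db, cb, wb
    return diam, cv, wv, z[:, 2]


def _sample_surgery(
    config: CohortConfig, z_size: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Proportional-odds draw of the 4-level surgery category.

    Categories are ordered by completeness of resection
    (biopsy < <90% < >=90% < 100%); intercepts reproduce
    ``surgery_probs`` at mean tumour size and a positive
    ``surgery_size_assoc`` shifts larger tumours toward the
    less-complete end.
    """
    p_biopsy, p_100, p_ge90, p_lt90 = config.surgery_probs
    # cumulative probabilities along the completeness ordering
    cum = np.array([p_biopsy, p_biopsy + p_lt90, p_biopsy + p_lt90 + p_ge90])
    theta = special.logit(cum)
    cdf = special.expit(theta[None, :] + config.surgery_size_assoc * z_size[:, None])
    u = rng.random(len(z_size))
    idx = (u[:, None] > cdf).sum(axis=1)  # 0..3 along completeness ordering
    order = np.array(["biopsy", "resection_lt90", "resection_ge90", "resection_100"])
    return order[idx]


def sample_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the covariate block of a cohort (no survival outcome yet).

    The returned frame carries one private column,
    ``_mgmt_methylated_true``: the generative methylation status before
    the missingness mask is applied, which the hazard model uses.
    """
    n = config.n_patients
    # Age: location pinned at the printed median with IQR-matched spread,
    # then hard-truncated to the printed range.  The asymmetric bounds
    # produce the slight left skew real cohorts show (mean below median).
    age_dist = SizeDistribution(
        "truncated-normal",
        float(config.age_median),
        (config.age_q3 - config.age_q1) / (2.0 * _Z75),
        config.age_min,
        config.age_max,
    )
    age = age_dist.ppf(rng.random(n))
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    diam, cv, wv, z_size = _sample_sizes(config, n, rng)
    surgery = _sample_surgery(config, z_size, rng)
    oncology = rng.choice(ONCOLOGY_LEVELS, size=n, p=config.oncology_probs)
    mgmt_true = rng.random(n) < config.p_mgmt_methylated_given_known
    missing = rng.random(n) < config.p_mgmt_missing
    mgmt = np.where(missing, "unknown", np.where(mgmt_true, "methylated", "unmethylated"))
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "surgery": surgery,
            "oncology": oncology,
            "mgmt": mgmt,
            "diameter_cm": diam,
            "cv_cm3": cv,
            "wv_cm3": wv,
            "_mgmt_methylated_true": mgmt_true,
        }
    )


def linear_predictor(config: CohortConfig, covariates: pd.DataFrame) -> np.ndarray:
    """Centred log-hazard linear predictor implied by ``config.betas``.

    Each covariate enters on its analysis scale minus a fixed centre
    (config medians for continuous terms, marginal category
    probabilities for dummies), so the population-average linear
    predictor is ~0 and ``baseline_scale`` keeps its interpretation as
    the near-marginal time scale regardless of which betas are active.
    """
    n = len(covariates)
    lp = np.zeros(n)
    if not config.betas:
        return lp
    if "_mgmt_methylated_true" in covariates:
        mgmt_meth = covariates["_mgmt_methylated_true"].to_numpy(dtype=float)
    else:
        mgmt_meth = (covariates["mgmt"] == "methylated").to_numpy(dtype=float)
    p_b, p_100, p_ge90, p_lt90 = config.surgery_probs
    p_ns, p_fs, p_ps = config.oncology_probs
    centred = {
        "age": covariates["age"].to_numpy() - config.age_median,
        "female": (covariates["sex"] == "female").to_numpy(dtype=float) - config.p_female,
        "surgery_resection_100": (covariates["surgery"] == "resection_100").to_numpy(dtype=float) - p_100,
        "surgery_resection_ge90": (covariates["surgery"] == "resection_ge90").to_numpy(dtype=float) - p_ge90,
        "surgery_resection_lt90": (covariates["surgery"] == "resection_lt90").to_numpy(dtype=float) - p_lt90,
        "oncology_full_stupp": (covariates["oncology"] == "full_stupp").to_numpy(dtype=float) - p_fs,
        "oncology_partial_stupp": (covariates["oncology"] == "partial_stupp").to_numpy(dtype=float) - p_ps,
        "mgmt_methylated": mgmt_meth - config.p_mgmt_methylated_given_known,
        "diameter": covariates["diameter_cm"].to_numpy() - config.diameter_median,
        "log_diameter": np.log(covariates["diameter_cm"].to_numpy()) - np.log(config.diameter_median),
        "cv": covariates["cv_cm3"].to_numpy() - config.cv_median,
        "log_cv": np.log(covariates["cv_cm3"].to_numpy()) - np.log(config.cv_median),
        "wv": covariates["wv_cm3"].to_numpy() - config.wv_median,
        "log_wv": np.log(covariates["wv_cm3"].to_numpy()) - np.log(config.wv_median),
    }
    for name, beta in config.betas.items():
        lp += beta * centred[name]
    return lp


# ----------------------------------------------------------------------
# outcome


def sample_survival_times(
    linear_predictor: np.ndarray,
    baseline_shape: float,
    baseline_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Event times from a Weibull proportional-hazards model.

    Inverse-transform sampling: ``T = scale * (-ln U / exp(lp))**(1/shape)``;
    at lp = 0 the median time is ``scale * (ln 2)**(1/shape)`` months.
    """
    if baseline_shape <= 0 or baseline_scale <= 0:
        raise ValueError("baseline parameters must be positive")
    lp = np.asarray(linear_predictor, dtype=float)
    u = rng.random(lp.shape[0])
    return baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / baseline_shape)


def apply_censoring(
    event_times: np.ndarray,
    censor_lo: float,
    censor_hi: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform potential censoring: observe min(T, C), C ~ U(lo, hi)."""
    if censor_lo < 0 or censor_lo >= censor_hi:
        raise ValueError("need 0 <= censor_lo < censor_hi")
    t = np.asarray(event_times, dtype=float)
    c = rng.uniform(censor_lo, censor_hi, size=t.shape[0])
    time = np.minimum(t, c)
    event = (t <= c).astype(np.int64)
    return time, event


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a full cohort table from a validated config.

    The master seed is split into named substreams (covariates,
    survival, censoring), so e.g. changing only the censoring window
    re-uses identical covariates and latent event times.
    """
    ss = np.random.SeedSequence(config.seed)
    cov_ss, surv_ss, cens_ss = ss.spawn(3)
    cov = sample_covariates(config, np.random.default_rng(cov_ss))
    lp = linear_predictor(config, cov)
    t = sample_survival_times(
        lp, config.baseline_shape, config.baseline_scale, np.random.default_rng(surv_ss)
    )
    time, event = apply_censoring(
        t, config.censor_lo, config.censor_hi, np.random.default_rng(cens_ss)
    )
    out = cov.drop(columns=["_mgmt_methylated_true"]).copy()
    out["time_months"] = time
    out["event"] = event
    return out[COHORT_COLUMNS]


# ----------------------------------------------------------------------
# summaries


def _median_iqr(x: pd.Series) -> dict:
    return {
        "median": float(x.median()),
        "q1": float(x.quantile(0.25)),
        "q3": float(x.quantile(0.75)),
    }


def _counts(x: pd.Series, levels) -> dict:
    n = len(x)
    return {
        lev: {"count": int((x == lev).sum()), "pct": 100.0 * float((x == lev).mean())}
        for lev in levels
    }


def summarize_cohort(table: pd.DataFrame) -> dict:
    """Demographics-table style summary of a cohort.

    Medians/IQRs for age and the size variables, category counts and
    percentages, deaths, Kaplan-Meier median OS with 95% CI, and
    reverse-Kaplan-Meier median follow-up.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    if len(table) == 0:
        raise ValueError("cannot summarise an empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(table["time_months"], table["event"])
    km_median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    km_lo, km_hi = (float(v) for v in np.asarray(ci).ravel()[:2])
    rkmf = KaplanMeierFitter()
    rkmf.fit(table["time_months"], 1 - table["event"])
    return {
        "n": int(len(table)),
        "n_events": int(table["event"].sum()),
        "age": _median_iqr(table["age"]),
        "diameter_cm": _median_iqr(table["diameter_cm"]),
        "cv_cm3": _median_iqr(table["cv_cm3"]),
        "wv_cm3": _median_iqr(table["wv_cm3"]),
        "sex": _counts(table["sex"], ("female", "male")),
        "surgery": _counts(table["surgery"], SURGERY_LEVELS),
        "oncology": _counts(table["oncology"], ONCOLOGY_LEVELS),
        "mgmt": _counts(table["mgmt"], MGMT_LEVELS),
        "km_median_os_months": km_median,
        "km_median_os_ci95": (km_lo, km_hi),
        "median_followup_months": float(rkmf.median_survival_time_),
        "max_followup_months": float(table["time_months"].max()),
    }
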