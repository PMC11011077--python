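"""Cox proportional-hazards models of tumour size.

The prognostic question is always phrased the same way: one tumour size
variable (maximum diameter, core volume, or whole volume), optionally
log-transformed, entered alone or adjusted for clinical covariates
(age, sex, extent of surgery, adjuvant oncology protocol, MGMT
methylation).  :func:`fit_cox` fits one such model; :func:`build_model_suite`
fits the full grid of 6 univariable + 36 multivariable models.

Dummy coding uses fixed reference levels: male, biopsy, no-Stupp,
unmethylated.  Models adjusted for MGMT first exclude patients whose
methylation status is unknown.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._engine import efron_loglik_grad_info, newton_cox

__all__ = [
    "ModelSpec",
    "CoxFit",
    "fit_cox",
    "partial_log_likelihood",
    "wald_p",
    "concordance_index",
    "build_model_suite",
    "design_matrix",
    "ADJUSTMENT_VARIABLES",
]

SIZE_COLUMNS = {"diameter": "diameter_cm", "cv": "cv_cm3", "wv": "wv_cm3"}
ADJUSTMENT_VARIABLES = ("age", "sex", "surgery", "oncology", "mgmt")

#: dummy columns per adjustment variable (reference level omitted)
_DUMMIES = {
    "age": [("age", None)],
    "sex": [("sex_female", ("sex", "female"))],
    "surgery": [
        ("surgery_resection_100", ("surgery", "resection_100")),
        ("surgery_resection_ge90", ("surgery", "resection_ge90")),
        ("surgery_resection_lt90", ("surgery", "resection_lt90")),
    ],
    "oncology": [
        ("oncology_full_stupp", ("oncology", "full_stupp")),
        ("oncology_partial_stupp", ("oncology", "partial_stupp")),
    ],
    "mgmt": [("mgmt_methylated", ("mgmt", "methylated"))],
}


@dataclass(frozen=True)
class ModelSpec:
    """One Cox model: a size variable, its transform, and adjustments."""

    size_variable: str
    transform: str = "identity"
    adjustment: tuple[str, ...] = ()

    def __post_init__(self):
        if self.size_variable not in SIZE_COLUMNS:
            raise ValueError(f"size_variable must be one of {sorted(SIZE_COLUMNS)}")
        if self.transform not in ("identity", "log"):
            raise ValueError("transform must be 'identity' or 'log'")
        object.__setattr__(self, "adjustment", tuple(self.adjustment))
        if len(set(self.adjustment)) != len(self.adjustment):
            raise ValueError("adjustment entries must be unique")
        for a in self.adjustment:
            if a not in ADJUSTMENT_VARIABLES:
                raise ValueError(f"unknown adjustment variable {a!r}")

    @property
    def size_term(self) -> str:
        name = self.size_variable
        return f"log({name})" if self.transform == "log" else name

    @property
    def label(self) -> str:
        if not self.adjustment:
            return self.size_term
        return f"{self.size_term} + " + " + ".join(self.adjustment)

    @property
    def univariable(self) -> bool:
        return not self.adjustment


@dataclass
class CoxFit:
    """Fitted Cox model: per-term estimates plus model-level diagnostics."""

    spec: ModelSpec
    terms: list
    beta: np.ndarray
    se: np.ndarray
    concordance: float
    overall_wald_p: float
    n_used: int
    n_events: int
    converged: bool
    loglik: float
    dropped_terms: list = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - 1.959963984540054 * self.se)
        hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return np.column_stack([lo, hi])

    @property
    def wald_pvalues(self) -> np.ndarray:
        return np.array([wald_p(b, s) for b, s in zip(self.beta, self.se)])

    def term_index(self, term: str) -> int:
        return self.terms.index(term)

    @property
    def size_p(self) -> float:
        """Wald p-value for the size variable's coefficient."""
        return float(self.wald_pvalues[self.term_index(self.spec.size_term)])

    @property
    def size_hr(self) -> float:
        return float(self.hr[self.term_index(self.spec.size_term)])

    def to_frame(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.beta,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_lo": ci[:, 0],
                "hr_ci_hi": ci[:, 1],
                "p": self.wald_pvalues,
            }
        )


# ----------------------------------------------------------------------


def design_matrix(table: pd.DataFrame, spec: ModelSpec):
    """Design matrix (size term first, then adjustment dummies).

    Returns ``(X, names, filtered_table)``; rows with unknown MGMT are
    removed when the spec adjusts for MGMT.
    """
    df = table
    if "mgmt" in spec.adjustment:
        df = df[df["mgmt"] != "unknown"]
    cols = [np.asarray(df[SIZE_COLUMNS[spec.size_variable]], dtype=float)]
    if spec.transform == "log":
        if np.any(cols[0] <= 0):
            raise ValueError("log transform requires positive sizes")
        cols[0] = np.log(cols[0])
    names = [spec.size_term]
    for adj in spec.adjustment:
        for name, coding in _DUMMIES[adj]:
            if coding is None:
                cols.append(np.asarray(df[name], dtype=float))
            else:
                col, level = coding
                cols.append((df[col] == level).to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names, df


def fit_cox(table: pd.DataFrame, spec: ModelSpec) -> CoxFit:
    """Fit one Cox model by maximising the Efron partial likelihood.

    Constant design columns are dropped and reported in
    ``dropped_terms``; a constant size variable or an all-constant
    design is an error.  Non-convergence is flagged, never silently
    returned.
    """
    X, names, df = design_matrix(table, spec)
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events, got {n_events}")
    keep = np.ptp(X, axis=0) > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if spec.size_term in dropped:
        raise ValueError("size variable is constant; no prognostic information")
    if not keep.any():
        raise ValueError("design matrix is all-constant")
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]

    res = newton_cox(df["time_months"].to_numpy(), df["event"].to_numpy(), X)
    risk = X @ res.beta
    c = concordance_index(df, risk)
    chi2 = float(res.beta @ res.info @ res.beta)
    overall_p = float(stats.chi2.sf(chi2, df=len(names)))
    return CoxFit(
        spec=spec,
        terms=names,
        beta=res.beta,
        se=res.se,
        concordance=c,
        overall_wald_p=overall_p,
        n_used=int(len(df)),
        n_events=n_events,
        converged=res.converged,
        loglik=res.loglik,
        dropped_terms=dropped,
    )


def partial_log_likelihood(
    beta, table: pd.DataFrame, spec: ModelSpec, ties: str = "efron"
) -> float:
    """Exact Cox log partial likelihood at ``beta`` (reference version).

    Deliberately naive (explicit loops over event times) and independent
    of the Newton engine, so it can serve as a brute-force oracle for
    :func:`fit_cox`.  With no tied event times, Efron and Breslow agree.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    X, names, df = design_matrix(table, spec)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.shape[0] != X.shape[1]:
        raise ValueError(f"beta has {beta.shape[0]} entries, design has {X.shape[1]} columns")
    time = df["time_months"].to_numpy(dtype=float)
    event = df["event"].to_numpy().astype(bool)
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event]):
        tied = event & (time == t)
        at_risk = time >= t
        d = int(tied.sum())
        s_risk = w[at_risk].sum()
        s_tied = w[tied].sum()
        ll += eta[tied].sum()
        for el in range(d):
            if ties == "efron":
                ll -= math.log(s_risk - (el / d) * s_tied)
            else:
                ll -= math.log(s_risk)
    return float(ll)


def wald_p(coefficient: float, se: float) -> float:
    """Two-sided Wald p-value, 2 * (1 - Phi(|beta| / se))."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = abs(coefficient) / se
    # erfc form of 2*(1 - Phi(z)); scipy.special agrees but costs more per call
    return float(math.erfc(z / math.sqrt(2.0)))


def concordance_index(table: pd.DataFrame, risk_scores) -> float:
    """Harrell's C over usable pairs; higher risk should mean shorter survival."""
    from lifelines.utils import concordance_index as _ci

    risk = np.asarray(risk_scores, dtype=float)
    return float(
        _ci(table["time_months"], -risk, event_observed=table["event"])
    )


def build_model_suite(table: pd.DataFrame) -> dict[ModelSpec, CoxFit]:
    """The full model grid for one cohort.

    6 univariable fits (3 size variables x identity/log) and, for each,
    5 single-adjustment fits plus the all-adjusted fit: 42 in total.
    """
    fits: dict[ModelSpec, CoxFit] = {}
    for size, transform in itertools.product(SIZE_COLUMNS, ("identity", "log")):
        specs = [ModelSpec(size, transform)]
        specs += [ModelSpec(size, transform, (adj,)) for adj in ADJUSTMENT_VARIABLES]
        specs += [ModelSpec(size, transform, ADJUSTMENT_VARIABLES)]
        for spec in specs:
            fits[spec] = fit_cox(table, spec)
    return fits
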