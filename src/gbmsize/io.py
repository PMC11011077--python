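"""Cohort CSV schema and result exports.

The cohort interchange format is a plain UTF-8, LF-terminated CSV with
columns ``age,sex,surgery,oncology,mgmt,diameter_cm,cv_cm3,wv_cm3,
time_months,event``; ``mgmt`` uses the literal ``unknown`` for missing
results.  Floats are written with 12 significant digits so a
write/read round trip reproduces the in-memory table exactly.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS
from .config import MGMT_LEVELS, ONCOLOGY_LEVELS, SURGERY_LEVELS
from .cox import CoxFit, ModelSpec, concordance_index, design_matrix

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "SchemaError",
    "univariable_table",
    "adjusted_table",
    "write_manifest",
]

_FLOAT_COLS = ("age", "diameter_cm", "cv_cm3", "wv_cm3", "time_months")
_LEVELS = {
    "sex": ("female", "male"),
    "surgery": SURGERY_LEVELS,
    "oncology": ONCOLOGY_LEVELS,
    "mgmt": MGMT_LEVELS,
}


class SchemaError(ValueError):
    """A cohort CSV violates the interface schema."""


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    table = table[COHORT_COLUMNS]
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        table.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises :class:`SchemaError` listing problems."""
    df = pd.read_csv(path)
    problems = []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    for col, levels in _LEVELS.items():
        bad = df.loc[~df[col].isin(levels), col]
        if len(bad):
            problems.append(
                f"column {col!r}: invalid value {bad.iloc[0]!r} at row {bad.index[0]}"
            )
    if not df["event"].isin((0, 1)).all():
        row = df.index[~df["event"].isin((0, 1))][0]
        problems.append(f"column 'event': value at row {row} is not 0/1")
    for col in ("time_months", "diameter_cm", "cv_cm3", "wv_cm3"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            bad = df.index[vals.isna() | (vals <= 0)][0]
            problems.append(f"column {col!r}: non-positive or non-numeric at row {bad}")
    if problems:
        raise SchemaError("; ".join(problems))
    df["event"] = df["event"].astype(np.int64)
    return df[COHORT_COLUMNS]


# ----------------------------------------------------------------------
# result tables


def _fmt_ci(lo: float, hi: float) -> str:
    return f"({lo:.3g}-{hi:.3g})"


def _concordance_ci(table: pd.DataFrame, fit: CoxFit, n_boot: int = 200) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI for Harrell's C at the fitted risk score."""
    X_all, names, df = design_matrix(table, fit.spec)
    cols = [names.index(t) for t in fit.terms]
    risk = X_all[:, cols] @ fit.beta
    rng = np.random.default_rng(0)
    n = len(df)
    cs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = df.iloc[idx]
        if sub["event"].sum() == 0:
            continue
        cs.append(concordance_index(sub, risk[idx]))
    lo, hi = np.percentile(cs, [2.5, 97.5])
    return float(lo), float(hi)


def univariable_table(
    fits: dict[ModelSpec, CoxFit], table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Univariable summary: one row per size/transform model.

    If the cohort ``table`` is supplied, a bootstrap 95% CI for the
    concordance index is added.
    """
    rows = []
    for spec, fit in fits.items():
        if not spec.univariable:
            continue
        i = fit.term_index(spec.size_term)
        ci = fit.ci95[i]
        row = {
            "model": spec.size_term,
            "C": round(fit.concordance, 3),
            "C_ci": "",
            "HR": fit.hr[i],
            "HR_ci": _fmt_ci(ci[0], ci[1]),
            "p": fit.wald_pvalues[i],
            "n": fit.n_used,
        }
        if table is not None:
            row["C_ci"] = _fmt_ci(*_concordance_ci(table, fit))
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


def adjusted_table(fits: dict[ModelSpec, CoxFit]) -> pd.DataFrame:
    """Adjusted summary: rows = adjustment sets, columns per size model.

    Cells report the HR (95% CI) and Wald p of the *size* coefficient,
    not of the adjustment variable.
    """
    rows: dict[str, dict] = {}
    for spec, fit in fits.items():
        if spec.univariable:
            continue
        adj = "+".join(spec.adjustment) if len(spec.adjustment) > 1 else spec.adjustment[0]
        i = fit.term_index(spec.size_term)
        ci = fit.ci95[i]
        rows.setdefault(adj, {})[f"{spec.size_term} HR (95% CI)"] = (
            f"{fit.hr[i]:.3g} {_fmt_ci(ci[0], ci[1])}"
        )
        rows[adj][f"{spec.size_term} p"] = round(float(fit.wald_pvalues[i]), 4)
        rows[adj][f"{spec.size_term} n"] = fit.n_used
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "adjustment"
    return frame


# ----------------------------------------------------------------------
# manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    *,
    command: str,
    seed: int | None,
    config_snapshot: dict | None,
    counts: dict | None = None,
) -> Path:
    """Write ``manifest.json`` listing every output file with a checksum."""
    from . import __version__

    out_dir = Path(out_dir)
    files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "tool": "gbmsize",
        "version": __version__,
        "command": command,
        "seed": seed,
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": config_snapshot,
        "counts": counts or {},
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
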