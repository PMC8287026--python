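"""Cohort statistics: group comparisons, correlations, agreement, reports.

Thin, policy-carrying wrappers around scipy.stats — two-sided throughout,
listwise deletion per statistic, exact Mann-Whitney for small tie-free
samples and the tie/continuity-corrected normal approximation otherwise —
plus assembly of the two standard report tables: per-variable group
mean +/- sd with Mann-Whitney p, and correlations of ocular rigidity with
every characteristic for the combined cohort and the control stratum.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import CohortTable, StatResult

__all__ = [
    "pearson_corr",
    "mann_whitney_u",
    "shapiro_wilk",
    "paired_t",
    "bland_altman",
    "build_report",
    "REPORT_VARIABLES",
]


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired inputs must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def pearson_corr(x, y) -> StatResult:
    """Pearson correlation with two-sided p from the t-transform (n-2 df)."""
    x, y = _clean_pairs(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return StatResult(
        test_name="pearson",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        estimate=float(res.statistic),
        n=(x.size,),
    )


def mann_whitney_u(x, y, exact_threshold: int = 8) -> StatResult:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) group comparison.

    The p-value is exact (full enumeration of rank arrangements) when both
    samples have at most ``exact_threshold`` observations and there are no
    ties; otherwise the normal approximation with tie correction and
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size <= exact_threshold and y.size <= exact_threshold and not has_ties)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return StatResult(
        test_name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        estimate=float(res.statistic),
        n=(x.size, y.size),
        extra={"method": "exact" if exact else "asymptotic"},
    )


def shapiro_wilk(x) -> StatResult:
    """Shapiro-Wilk normality test, 3 <= n <= 2000."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if not (3 <= x.size <= 2000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 2000")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for constant input")
    res = sps.shapiro(x)
    return StatResult(
        test_name="shapiro_wilk",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(x.size,),
    )


def paired_t(x, y) -> StatResult:
    """Two-sided paired t-test on n-1 degrees of freedom."""
    x, y = _clean_pairs(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 complete pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise ValueError("paired differences have zero variance")
    res = sps.ttest_rel(x, y)
    return StatResult(
        test_name="paired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        estimate=float(np.mean(d)),
        n=(x.size,),
    )


def bland_altman(x, y) -> StatResult:
    """Bland-Altman agreement: bias and 95% limits of agreement.

    bias = mean(x - y); limits = bias +/- 1.96 * sd(x - y) (sample sd).
    The per-pair means and differences are returned for plotting.
    """
    x, y = _clean_pairs(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    d = x - y
    m = (x + y) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    return StatResult(
        test_name="bland_altman",
        statistic=bias,
        p_value=np.nan,
        estimate=bias,
        n=(x.size,),
        ci=(lo, hi),
        extra={"means": m, "differences": d, "sd": sd},
    )


# variable -> (column, pretty name, units) for the report tables
REPORT_VARIABLES = [
    ("age_years", "Age", "years"),
    ("cct_um", "Central corneal thickness", "um"),
    ("corneal_radius_mm", "Radius of corneal curvature", "mm"),
    ("al_mm", "Axial length", "mm"),
    ("acv_ul", "Anterior chamber volume", "uL"),
    ("iop_mmhg", "Intraocular pressure", "mmHg"),
    ("opa_mmhg", "Ocular pulse amplitude", "mmHg"),
    ("dv_ul", "Ocular volume change", "uL"),
    ("k_per_ul", "Ocular rigidity", "1/uL"),
    ("sp_a1", "SP-A1", ""),
    ("sp_hc", "SP-HC", ""),
]

_CORR_VARS = [v for v in REPORT_VARIABLES if v[0] not in ("k_per_ul",)] + [
    ("pv_ratio_mmhg_per_ul", "P/V ratio", "mmHg/uL")
]


def build_report(
    table: CohortTable,
    alpha: float = 0.05,
    exact_threshold: int = 8,
    holm_adjust: bool = False,
) -> dict[str, pd.DataFrame]:
    """Assemble the group-comparison and rigidity-correlation tables.

    Returns ``{"group_comparison": ..., "correlations": ...}``.  The group
    table gives per-variable mean +/- sd per group with the Mann-Whitney p
    and per-cell n (listwise deletion per variable).  The correlation
    table relates ocular rigidity k to each characteristic for the
    combined cohort and the control-only stratum.  Significance is flagged
    at ``alpha`` (optionally Holm-adjusted).  With a single group the
    comparison columns are omitted and correlations are still produced.
    """
    if len(table) == 0:
        raise ValueError("empty cohort")
    df = table.to_dataframe()
    if df["k_per_ul"].isna().all():
        raise ValueError(
            "no subject carries a derived rigidity k; run compute_subject first"
        )
    groups_present = [g for g in ("control", "glaucoma") if (df["group"] == g).any()]

    rows = []
    pvals = []
    for col, name, units in REPORT_VARIABLES:
        if col not in df or df[col].isna().all():
            continue
        row: dict = {"variable": name, "units": units}
        for g in groups_present:
            vals = df.loc[df["group"] == g, col].dropna()
            row[f"{g}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{g}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{g}_n"] = len(vals)
        if len(groups_present) == 2:
            a = df.loc[df["group"] == groups_present[0], col].dropna()
            b = df.loc[df["group"] == groups_present[1], col].dropna()
            if len(a) and len(b):
                res = mann_whitney_u(a, b, exact_threshold=exact_threshold)
                row["p_value"] = res.p_value
                pvals.append(res.p_value)
            else:
                row["p_value"] = np.nan
        rows.append(row)
    group_tab = pd.DataFrame(rows)
    if "p_value" in group_tab:
        group_tab["significant"] = _flag(group_tab["p_value"].to_numpy(), alpha, holm_adjust)

    corr_rows = []
    strata = [("combined", df)]
    if "control" in groups_present:
        strata.append(("control", df[df["group"] == "control"]))
    for col, name, units in _CORR_VARS:
        if col not in df or df[col].isna().all():
            continue
        row = {"variable": name, "units": units}
        for label, sub in strata:
            pair = sub[["k_per_ul", col]].dropna()
            if len(pair) >= 3 and pair[col].std() > 0 and pair["k_per_ul"].std() > 0:
                res = pearson_corr(pair["k_per_ul"], pair[col])
                row[f"R_{label}"] = res.estimate
                row[f"p_{label}"] = res.p_value
                row[f"n_{label}"] = len(pair)
            else:
                row[f"R_{label}"] = np.nan
                row[f"p_{label}"] = np.nan
                row[f"n_{label}"] = len(pair)
        corr_rows.append(row)
    corr_tab = pd.DataFrame(corr_rows)
    for label, _ in strata:
        if f"p_{label}" in corr_tab:
            corr_tab[f"significant_{label}"] = _flag(
                corr_tab[f"p_{label}"].to_numpy(), alpha, holm_adjust
            )
    return {"group_comparison": group_tab, "correlations": corr_tab}


def _flag(p: np.ndarray, alpha: float, holm: bool) -> np.ndarray:
    """Significance flags, optionally Holm step-down adjusted."""
    p = np.asarray(p, dtype=float)
    if not holm:
        return p < alpha
    flags = np.zeros(p.size, dtype=bool)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    order = np.argsort(np.where(ok, p, np.inf))
    for rank, idx in enumerate(order[:m]):
        if p[idx] < alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags


def report_to_markdown(report: dict[str, pd.DataFrame]) -> str:
    """Render the report tables as a Markdown document."""
    parts = []
    titles = {
        "group_comparison": "Group comparison (mean +/- sd, Mann-Whitney U)",
        "correlations": "Correlation of ocular rigidity with characteristics",
    }
    for key, df in report.items():
        parts.append(f"## {titles.get(key, key)}\n")
        cells = df.copy()
        for col in cells.columns:
            if cells[col].dtype.kind == "f":
                cells[col] = cells[col].map(lambda v: f"{v:.4g}")
        header = "| " + " | ".join(map(str, cells.columns)) + " |"
        sep = "|" + "|".join(["---"] * len(cells.columns)) + "|"
        rows = ["| " + " | ".join(map(str, row)) + " |" for row in cells.to_numpy()]
        parts.extend([header, sep, *rows, ""])
    return "\n".join(parts)
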