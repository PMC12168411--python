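"""Exploratory univariate screen of microbial/clinical indices against plaque.

For every index x visit x stratum (overall / placebo / antibiotic) cell, an
ordinary least-squares regression of the index on the O'Leary plaque value is
fit, reported both as the raw-scale slope and as the standardized coefficient
(z-scored predictor and response — identical to the Pearson correlation in
simple regression), with Benjamini-Hochberg FDR adjustment applied within a
configurable family (default: all indices of one visit x stratum cell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("plaquetopics")

STRATA = ("overall", "placebo", "antibiotic")

#: Index columns screened by default when present in the joined table.
DEFAULT_INDEX_COLUMNS = (
    "richness",
    "shannon",
    "inverse_simpson",
    "mean_bray_curtis",
    "smdi",
    "dysbiosis_covariate",
    "topic_share",
    "bop_pct",
    "ppd5_pct",
    "psal_pct",
)


@dataclass
class UnivariateResult:
    index_name: str
    visit: str
    stratum: str
    estimate: float  # raw-scale slope of index on O'Leary
    std_estimate: float  # slope after z-scoring both variables (= Pearson r)
    p_value: float
    n: int
    degenerate: bool = False
    adj_p: float = float("nan")  # filled in by the screen's FDR step


def fit_univariate(
    y: np.ndarray,
    x: np.ndarray,
    index_name: str = "",
    visit: str = "",
    stratum: str = "overall",
) -> UnivariateResult:
    """OLS of index ``y`` on O'Leary ``x`` with pairwise-complete cases.

    A constant predictor or fewer than 3 complete pairs yields a degenerate
    result (NaN estimates, excluded from the FDR family by the screen).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning(
            "degenerate univariate fit for %s/%s/%s (n=%d)", index_name, visit, stratum, n
        )
        return UnivariateResult(
            index_name, visit, stratum, float("nan"), float("nan"), float("nan"), n, True
        )
    res = stats.linregress(x, y)
    return UnivariateResult(
        index_name=index_name,
        visit=visit,
        stratum=stratum,
        estimate=float(res.slope),
        std_estimate=float(res.rvalue),
        p_value=float(res.pvalue),
        n=n,
    )


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (tail-monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_stars(adj_p: float) -> str:
    if not np.isfinite(adj_p):
        return ""
    if adj_p < 0.001:
        return "***"
    if adj_p < 0.01:
        return "**"
    if adj_p < 0.05:
        return "*"
    return ""


def association_screen(
    data: pd.DataFrame,
    index_columns: list[str] | tuple[str, ...] | None = None,
    strata: tuple[str, ...] = STRATA,
    fdr_family: str = "per-visit",
    predictor: str = "oleary_pct",
) -> pd.DataFrame:
    """Run the full index x visit x stratum screen and FDR-adjust it.

    ``data`` is the metadata table joined with any per-sample index columns
    (diversity profiles, topic shares). ``fdr_family`` is "per-visit"
    (adjust within each visit x stratum cell) or "global" (one family per
    stratum across all visits and indices). Degenerate fits are kept in the
    output but excluded from the FDR family; empty strata are omitted with a
    warning. A ``stars`` column marks adj_p < 0.05 / 0.01 / 0.001.
    """
    if index_columns is None:
        index_columns = [c for c in DEFAULT_INDEX_COLUMNS if c in data.columns]
    if not index_columns:
        raise ValueError("no index columns to screen")
    if fdr_family not in ("per-visit", "global"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")

    results: list[UnivariateResult] = []
    for stratum in strata:
        sub = data if stratum == "overall" else data[data["arm"] == stratum]
        if sub.empty:
            logger.warning("association_screen: empty stratum %r omitted", stratum)
            continue
        for visit in pd.unique(sub["visit"]):
            cell = sub[sub["visit"] == visit]
            for index_name in index_columns:
                results.append(
                    fit_univariate(
                        cell[index_name].to_numpy(),
                        cell[predictor].to_numpy(),
                        index_name=index_name,
                        visit=str(visit),
                        stratum=stratum,
                    )
                )

    table = pd.DataFrame([r.__dict__ for r in results])
    table["adj_p"] = np.nan
    family_cols = ["visit", "stratum"] if fdr_family == "per-visit" else ["stratum"]
    valid = ~table["degenerate"]
    for _, idx in table[valid].groupby(family_cols, sort=False).groups.items():
        table.loc[idx, "adj_p"] = fdr_adjust(table.loc[idx, "p_value"].to_numpy())
    table["stars"] = [significance_stars(a) for a in table["adj_p"]]
    return table
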