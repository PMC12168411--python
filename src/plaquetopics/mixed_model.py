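"""Confounder-adjusted mixed-effects logistic model for the plaque effect.

The candidate topic's per-sample share is dichotomized at the pooled median
(above vs. below), and a mixed-effects logistic regression quantifies how the
odds of the high-share state change per 10-point increment of the O'Leary
plaque index, adjusted for age band, sex, smoking, visit, pre-treatment
count, a dysbiosis covariate, %BOP, %PPD>=5mm and %PSAL, with random
intercepts for subject nested in study center. Reported as odds ratios with
Wald 95% intervals, overall and stratified by treatment arm.

Estimation is delegated to lme4::glmer (Laplace approximation) through
Rscript; data and results cross the boundary as TSV and JSON. Grouping
factors with fewer than two levels are dropped from the random-effects
structure, so single-center or single-observation data degrade gracefully to
the corresponding simpler model.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("plaquetopics")

STRATA = ("overall", "antibiotic", "placebo")

#: Adjustment set of the association model (arm is added in the overall fit).
DEFAULT_CONFOUNDERS: tuple[str, ...] = (
    "age_band",
    "sex",
    "smoking",
    "visit",
    "pretreatment_count",
    "dysbiosis_covariate",
    "bop10",
    "ppd10",
    "psal10",
)

_FACTOR_COLUMNS = ("age_band", "sex", "smoking", "visit", "arm", "subject_id", "center_id")

_GLMER_SCRIPT = r"""
suppressMessages({library(lme4); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
d <- read.delim(args[1], stringsAsFactors = FALSE)
spec <- fromJSON(args[2])
d$outcome <- as.integer(d$outcome)
for (f in spec$factors) if (f %in% names(d)) d[[f]] <- factor(d[[f]])
form <- as.formula(spec$formula)
msgs <- character(0)
fit <- withCallingHandlers(
  tryCatch(
    glmer(form, data = d, family = binomial,
          control = glmerControl(check.conv.singular = "ignore")),
    error = function(e) e
  ),
  warning = function(w) { msgs <<- c(msgs, conditionMessage(w)); invokeRestart("muffleWarning") },
  message = function(m) { msgs <<- c(msgs, conditionMessage(m)); invokeRestart("muffleMessage") }
)
if (inherits(fit, "error")) {
  out <- list(ok = FALSE, error = conditionMessage(fit))
} else {
  fe <- fixef(fit)
  se <- sqrt(diag(as.matrix(vcov(fit))))
  vc <- as.data.frame(VarCorr(fit))
  conv_opt <- fit@optinfo$conv$opt
  lme4_msgs <- unlist(fit@optinfo$conv$lme4$messages)
  out <- list(
    ok = TRUE,
    names = names(fe), coef = unname(fe), se = unname(se),
    vc_grp = as.character(vc$grp), vc_var = vc$vcov,
    converged = (conv_opt == 0) && is.null(lme4_msgs),
    messages = c(msgs, lme4_msgs),
    n = nrow(model.frame(fit))
  )
}
writeLines(toJSON(out, digits = 15, auto_unbox = TRUE, null = "null"), args[3])
"""


class MixedModelError(RuntimeError):
    """The mixed-model backend failed."""


@dataclass
class MixedModelResult:
    stratum: str
    or_oleary: float  # odds ratio per 10 O'Leary points
    ci_low: float
    ci_high: float
    coefficients: pd.DataFrame  # term, estimate, se
    re_variances: dict[str, float]
    n_samples: int
    n_subjects: int
    converged: bool
    messages: list[str] = field(default_factory=list)
    method: str = "lme4::glmer (Laplace), Wald 95% CI"

    def validate(self) -> "MixedModelResult":
        if not (self.ci_low <= self.or_oleary <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")
        if self.or_oleary <= 0:
            raise ValueError("odds ratios must be positive")
        if any(v < 0 for v in self.re_variances.values()):
            raise ValueError("random-effect variances must be non-negative")
        return self


def dichotomize_share(
    shares: np.ndarray | pd.Series,
    visits: np.ndarray | pd.Series | None = None,
    per_visit: bool = False,
) -> np.ndarray:
    """Binary high/low topic state: 1 where share strictly exceeds the median.

    The median is pooled over all samples and visits by default; with
    ``per_visit=True`` it is computed within each visit. A degenerate
    (constant) share vector is an error.
    """
    x = np.asarray(shares, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all shares identical; dichotomization is degenerate")
    if per_visit:
        if visits is None:
            raise ValueError("per_visit dichotomization requires visit labels")
        visits = np.asarray(visits)
        out = np.zeros(x.size, dtype=int)
        for v in pd.unique(visits):
            m = visits == v
            out[m] = (x[m] > np.median(x[m])).astype(int)
        return out
    return (x > np.median(x)).astype(int)


def association_frame(
    shares: pd.Series, metadata: pd.DataFrame, per_visit: bool = False, increment: float = 10.0
) -> pd.DataFrame:
    """Join topic shares onto metadata and derive the model covariates.

    Adds ``outcome`` (median-dichotomized share), ``oleary10`` (O'Leary per
    ``increment`` points), the three age bands, and /10-scaled clinical
    percentages. Incomplete records are dropped (complete-case) and logged.
    """
    df = metadata.merge(
        shares.rename("topic_share"), left_on="sample_id", right_index=True, how="inner"
    )
    if df.empty:
        raise ValueError("no overlap between shares and metadata sample ids")
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("association_frame: dropped %d incomplete record(s)", n0 - len(df))
    df = df.copy()
    df["outcome"] = dichotomize_share(df["topic_share"], df["visit"], per_visit=per_visit)
    df["oleary10"] = df["oleary_pct"] / increment
    df["age_band"] = pd.cut(
        df["age_years"], [-np.inf, 44.5, 54.5, np.inf], labels=["lt45", "45to54", "ge55"]
    ).astype(str)
    df["bop10"] = df["bop_pct"] / 10.0
    df["ppd10"] = df["ppd5_pct"] / 10.0
    df["psal10"] = df["psal_pct"] / 10.0
    return df


def _rscript() -> str:
    path = shutil.which("Rscript")
    if path is None:
        raise MixedModelError(
            "Rscript not found on PATH; the mixed-model backend requires R with lme4"
        )
    return path


def _run_glmer(df: pd.DataFrame, formula: str, factors: list[str]) -> dict:
    with tempfile.TemporaryDirectory(prefix="plaquetopics_glmer_") as tmp:
        tmp = Path(tmp)
        (tmp / "fit.R").write_text(_GLMER_SCRIPT)
        df.to_csv(tmp / "data.tsv", sep="\t", index=False)
        (tmp / "spec.json").write_text(json.dumps({"formula": formula, "factors": factors}))
        proc = subprocess.run(
            [_rscript(), "--vanilla", str(tmp / "fit.R"), str(tmp / "data.tsv"),
             str(tmp / "spec.json"), str(tmp / "out.json")],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or not (tmp / "out.json").exists():
            raise MixedModelError(f"glmer backend failed: {proc.stderr[-2000:]}")
        out = json.loads((tmp / "out.json").read_text())
    if not out.get("ok", False):
        raise MixedModelError(f"glmer fit failed: {out.get('error')}")
    return out


def fit_mixed_logistic(
    data: pd.DataFrame,
    stratum: str = "overall",
    confounders: tuple[str, ...] | list[str] = DEFAULT_CONFOUNDERS,
    include_arm: bool | None = None,
) -> MixedModelResult:
    """Fit the adjusted mixed logistic model in one stratum.

    ``data`` is an :func:`association_frame` (needs columns outcome,
    oleary10, subject_id, center_id plus the confounders). Fixed-effect
    terms that are constant within the stratum are dropped, as are random
    grouping factors with fewer than two levels. Non-convergence is reported
    through ``converged``/``messages`` with the backend's diagnostics; very
    large coefficients trigger a separation warning.
    """
    if stratum != "overall":
        data = data[data["arm"] == stratum]
        if data.empty:
            raise ValueError(f"stratum {stratum!r} has no samples")
    data = data.copy()
    y = data["outcome"].to_numpy()
    if y.min() == y.max():
        raise ValueError(f"outcome is degenerate (all {y[0]}) in stratum {stratum!r}")

    if include_arm is None:
        include_arm = stratum == "overall"
    terms = ["oleary10"] + [c for c in confounders if c in data.columns]
    if include_arm and data["arm"].nunique() > 1:
        terms.append("arm")
    terms = [t for t in terms if data[t].nunique() > 1 or t == "oleary10"]

    re_terms = []
    if data["center_id"].nunique() > 1:
        re_terms.append("(1 | center_id/subject_id)")
    else:
        re_terms.append("(1 | subject_id)")
    formula = "outcome ~ " + " + ".join(terms + re_terms)
    factors = [c for c in _FACTOR_COLUMNS if c in data.columns]

    cols = ["outcome", "subject_id", "center_id"] + [t for t in terms if t != "arm"]
    if "arm" in data.columns:
        cols.append("arm")
    out = _run_glmer(data.loc[:, sorted(set(cols))], formula, factors)

    def aslist(v):  # jsonlite auto_unbox collapses length-1 vectors
        return v if isinstance(v, list) else [v]

    names = aslist(out["names"])
    coefs = pd.DataFrame(
        {"term": names, "estimate": aslist(out["coef"]), "se": aslist(out["se"])}
    )
    if (coefs["estimate"].abs() > 15).any():
        logger.warning(
            "very large coefficient(s) in stratum %r — possible separation: %s",
            stratum,
            list(coefs.loc[coefs["estimate"].abs() > 15, "term"]),
        )
    b = float(coefs.loc[coefs["term"] == "oleary10", "estimate"].iloc[0])
    se = float(coefs.loc[coefs["term"] == "oleary10", "se"].iloc[0])
    re_var = {
        g: float(v)
        for g, v in zip(aslist(out.get("vc_grp", [])), aslist(out.get("vc_var", [])))
    }
    msgs = out.get("messages") or []
    if isinstance(msgs, str):
        msgs = [msgs]
    result = MixedModelResult(
        stratum=stratum,
        or_oleary=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.96 * se)),
        ci_high=float(np.exp(b + 1.96 * se)),
        coefficients=coefs,
        re_variances=re_var,
        n_samples=int(out["n"]),
        n_subjects=int(data["subject_id"].nunique()),
        converged=bool(out["converged"]),
        messages=list(msgs),
    ).validate()
    if not result.converged:
        logger.warning("glmer reported convergence issues in %r: %s", stratum, msgs)
    return result


def stratified_analysis(
    data: pd.DataFrame,
    confounders: tuple[str, ...] | list[str] = DEFAULT_CONFOUNDERS,
) -> dict[str, MixedModelResult | None]:
    """Overall fit plus per-arm stratified fits (arm term dropped in strata).

    Requires both arms to be present. A failing stratum is reported as None
    (with the error logged) without aborting the other fits.
    """
    arms = set(data["arm"].unique())
    missing = {"placebo", "antibiotic"} - arms
    if missing:
        raise ValueError(f"stratified analysis requires both arms; missing: {sorted(missing)}")
    results: dict[str, MixedModelResult | None] = {}
    for stratum in STRATA:
        try:
            results[stratum] = fit_mixed_logistic(data, stratum, confounders)
        except (MixedModelError, ValueError) as exc:
            logger.error("stratum %r failed: %s", stratum, exc)
            results[stratum] = None
    return results


def mixed_results_table(results: dict[str, MixedModelResult | None]) -> pd.DataFrame:
    """Tidy per-stratum OR table (stratum, OR, CI bounds, sizes)."""
    rows = []
    for stratum, res in results.items():
        if res is None:
            rows.append({"stratum": stratum, "or_oleary": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "n_samples": 0, "n_subjects": 0,
                         "converged": False})
        else:
            rows.append(
                {
                    "stratum": stratum,
                    "or_oleary": res.or_oleary,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n_samples": res.n_samples,
                    "n_subjects": res.n_subjects,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)
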