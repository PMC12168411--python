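"""Cross-validated LDA + random-forest discovery of plaque-associated topics.

The method treats each subgingival sample as a mixture of latent microbial
sub-communities ("topics", probability distributions over genera). Topic
proportions are engineered *inside* the cross-validation loop: for every
fold, LDA is fit on the training samples only and held-out samples are
folded in with the topic-genus matrix phi held fixed, so no information
leaks from the held-out fold into the features. A random-forest regression
of the O'Leary plaque value on the topic proportions is tuned jointly with
the topic count over a hyperparameter grid by 5-fold CV (RMSE); the winning
configuration is refit on all baseline samples, and the topic with the
highest impurity-based importance becomes the candidate plaque-associated
topic. Follow-up visits receive topic shares by folding into the
baseline-trained model (no refit), keeping the topic definitions unbiased
by treatment.

LDA inference is batch variational EM (deterministic given a seed); the
fold-in solver is a fixed-point EM with phi frozen.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import psi
from sklearn.ensemble import RandomForestRegressor

from .io_core import GenusCountTable, StudyDataset

logger = logging.getLogger("plaquetopics")

# paper-stated hyperparameter ranges (warned about, not enforced, for custom grids)
_PAPER_RANGES = {"trees": (500, 2000), "mtry": (5, 15), "min_node": (1, 15), "K": (5, 30)}


def _derive_seed(*parts: int) -> int:
    """Stable 31-bit seed from a tuple of integers."""
    h = 0
    for p in parts:
        h = (h * 1000003 + int(p) + 0x9E3779B9) % (2**31)
    return h


# ---------------------------------------------------------------------------
# LDA: batch variational EM + fold-in
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Fitted topic model: phi rows are topic-genus distributions."""

    K: int
    phi: np.ndarray  # (K, G), rows sum to 1
    alpha_prior: float
    eta_prior: float
    genus_ids: list[str]
    rng_seed: int
    method: str = "batch-vem"
    max_iter: int = 80
    tol: float = 5e-5
    n_iter: int = 0
    converged: bool = True

    def validate(self) -> "LDAModel":
        if self.K < 2 and self.method != "pooled":
            pass
        if np.abs(self.phi.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("phi rows must sum to 1 within 1e-8")
        return self


def fit_lda(
    counts: GenusCountTable | np.ndarray,
    K: int,
    alpha: float | None = None,
    eta: float = 0.01,
    max_iter: int = 80,
    tol: float = 5e-5,
    seed: int = 0,
    genus_ids: list[str] | None = None,
) -> LDAModel:
    """Fit LDA by batch variational EM.

    Priors default to the sparse-topic setting alpha = 1/K, eta = 0.01.
    Randomness enters only through the seeded topic-genus initialization, so
    a fixed seed yields a bit-identical phi regardless of any other data.
    Non-convergence at max_iter logs a warning with the last parameter change.
    """
    if isinstance(counts, GenusCountTable):
        X = counts.counts.astype(float)
        genus_ids = list(counts.genus_ids)
    else:
        X = np.asarray(counts, dtype=float)
        genus_ids = list(genus_ids) if genus_ids is not None else [
            f"g{i + 1:03d}" for i in range(X.shape[1])
        ]
    n, G = X.shape
    if K > G:
        raise ValueError(f"K={K} exceeds the number of genera ({G})")
    if n < K:
        raise ValueError(f"need at least K={K} samples, got {n}")
    if alpha is None:
        alpha = 1.0 / K

    rng = np.random.default_rng(seed)
    lam = rng.gamma(100.0, 1.0 / 100.0, size=(K, G))
    delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        exp_elog_beta = np.exp(psi(lam) - psi(lam.sum(axis=1, keepdims=True)))
        # E-step, vectorized over all samples; the variational doc-topic
        # parameters are re-initialized randomly every EM sweep, which keeps
        # the optimizer out of diluted symmetric optima at small priors
        gamma = rng.gamma(100.0, 1.0 / 100.0, size=(n, K))
        for _ in range(100):
            exp_elog_theta = np.exp(psi(gamma) - psi(gamma.sum(axis=1, keepdims=True)))
            phinorm = exp_elog_theta @ exp_elog_beta + 1e-100
            gamma_new = alpha + exp_elog_theta * ((X / phinorm) @ exp_elog_beta.T)
            change = np.abs(gamma_new - gamma).mean()
            gamma = gamma_new
            if change < 1e-3 * max(1.0, gamma.mean()):
                break
        # M-step
        exp_elog_theta = np.exp(psi(gamma) - psi(gamma.sum(axis=1, keepdims=True)))
        phinorm = exp_elog_theta @ exp_elog_beta + 1e-100
        sstats = exp_elog_beta * (exp_elog_theta.T @ (X / phinorm))
        lam_new = eta + sstats
        # convergence is judged on the normalized topic-genus rows; the raw
        # variational parameters keep a noise floor from the per-sweep re-init
        delta = np.abs(
            lam_new / lam_new.sum(axis=1, keepdims=True)
            - lam / lam.sum(axis=1, keepdims=True)
        ).mean()
        lam = lam_new
        if delta < tol:
            break
    converged = delta < tol
    if not converged:
        logger.warning(
            "LDA did not converge in %d iterations (relative change %.2e)", max_iter, delta
        )
    phi = lam / lam.sum(axis=1, keepdims=True)
    return LDAModel(
        K=K,
        phi=phi,
        alpha_prior=alpha,
        eta_prior=eta,
        genus_ids=genus_ids,
        rng_seed=seed,
        max_iter=max_iter,
        tol=tol,
        n_iter=it,
        converged=converged,
    ).validate()


def infer_theta(
    model: LDAModel,
    counts: GenusCountTable | np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> np.ndarray:
    """Fold in samples: per-sample topic proportions with phi held fixed.

    Deterministic fixed-point EM on the posterior pseudo-counts
    gamma_k = alpha + sum_g n_g * r_gk with responsibilities
    r_gk ∝ theta_k phi_kg; phi is never updated (leakage-safe). An all-zero
    sample returns the prior mean alpha / sum(alpha).
    """
    if isinstance(counts, GenusCountTable):
        if list(counts.genus_ids) != list(model.genus_ids):
            missing = set(model.genus_ids) - set(counts.genus_ids)
            extra = set(counts.genus_ids) - set(model.genus_ids)
            raise ValueError(
                f"genus set mismatch with model: missing={sorted(missing)[:5]}, "
                f"extra={sorted(extra)[:5]}"
            )
        X = counts.counts.astype(float)
    else:
        X = np.asarray(counts, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    n, K = X.shape[0], model.K
    phi = model.phi
    alpha = model.alpha_prior
    theta = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        denom = theta @ phi + 1e-300
        gamma = alpha + theta * ((X / denom) @ phi.T)
        theta_new = gamma / gamma.sum(axis=1, keepdims=True)
        if np.abs(theta_new - theta).max() < tol:
            theta = theta_new
            break
        theta = theta_new
    return theta


# ---------------------------------------------------------------------------
# Random forest on topic features
# ---------------------------------------------------------------------------

def fit_rf(
    theta: np.ndarray,
    y: np.ndarray,
    trees: int = 500,
    mtry: int = 5,
    min_node: int = 5,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> tuple[RandomForestRegressor, np.ndarray]:
    """Regression forest on topic proportions with impurity importances.

    mtry is clamped to the number of topic features (clamping logged). When
    ``sample_ids`` are given, rows are put into canonical id order before
    fitting so the seeded bootstrap — and hence the importances — are
    invariant to the order samples arrive in.
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    if theta.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit a forest")
    if sample_ids is not None:
        order = np.argsort(np.asarray(sample_ids))
        theta, y = theta[order], y[order]
    mtry_eff = min(mtry, theta.shape[1])
    if mtry_eff != mtry:
        logger.info("mtry clamped from %d to %d (K=%d features)", mtry, mtry_eff, theta.shape[1])
    forest = RandomForestRegressor(
        n_estimators=trees,
        max_features=mtry_eff,
        min_samples_leaf=min_node,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(theta, y)
    return forest, forest.feature_importances_


# ---------------------------------------------------------------------------
# Hyperparameter grid and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class HyperGrid:
    """Joint grid over forest hyperparameters and the LDA topic count."""

    trees: tuple[int, ...] = (500, 1000, 1500, 2000)
    mtry: tuple[int, ...] = (5, 10, 15)
    min_node: tuple[int, ...] = (1, 5, 10, 15)
    K: tuple[int, ...] = (5, 10, 15, 20, 25, 30)

    def validate(self) -> "HyperGrid":
        for name in ("trees", "mtry", "min_node", "K"):
            vals = getattr(self, name)
            if not vals:
                raise ValueError(f"grid dimension {name} is empty")
            if any(int(v) < 1 for v in vals):
                raise ValueError(f"grid dimension {name} has non-positive values")
            lo, hi = _PAPER_RANGES[name]
            if any(not (lo <= v <= hi) for v in vals):
                logger.warning("grid %s=%s outside default range [%d, %d]", name, vals, lo, hi)
        logger.info("hyperparameter grid: %d combination(s)", self.n_combinations)
        return self

    @property
    def n_combinations(self) -> int:
        return len(self.trees) * len(self.mtry) * len(self.min_node) * len(self.K)

    def combinations(self) -> list[dict[str, int]]:
        return [
            {"K": k, "trees": t, "mtry": m, "min_node": n}
            for k in self.K
            for t in self.trees
            for m in self.mtry
            for n in self.min_node
        ]

    @classmethod
    def reduced(cls) -> "HyperGrid":
        """Small grid for desk-scale recovery runs."""
        return cls(trees=(500,), mtry=(3, 5), min_node=(5,), K=(5, 8, 12))


@dataclass
class CVSpec:
    n_folds: int = 5
    seed: int = 0
    metric: str = "rmse"

    def validate(self) -> "CVSpec":
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.metric != "rmse":
            raise ValueError(f"unsupported metric {self.metric!r}")
        return self


@dataclass
class CandidateTopic:
    """The topic most predictive of the plaque value in the final forest."""

    topic_index: int
    genus_contributions: np.ndarray  # phi row over genus_ids
    genus_ids: list[str]
    importance: float
    hyperparameters: dict[str, int]
    rng_seed: int

    def ranked_contributions(self) -> pd.DataFrame:
        order = np.argsort(self.genus_contributions)[::-1]
        return pd.DataFrame(
            {
                "genus": [self.genus_ids[i] for i in order],
                "contribution": self.genus_contributions[order],
            }
        )

    def top_genera(self, n: int = 2) -> list[str]:
        return list(self.ranked_contributions()["genus"].head(n))

    def to_json(self, path: str) -> None:
        obj = {
            "topic_index": int(self.topic_index),
            "importance": float(self.importance),
            "hyperparameters": {k: int(v) for k, v in self.hyperparameters.items()},
            "rng_seed": int(self.rng_seed),
            "contributions": [
                {"genus": g, "contribution": float(c)}
                for g, c in self.ranked_contributions().itertuples(index=False)
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1)


def _subject_folds(
    subjects: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded subject-level fold assignment; returns sample-index arrays."""
    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)
    rng.shuffle(uniq)
    fold_subjects = np.array_split(uniq, n_folds)
    folds = []
    for fs in fold_subjects:
        idx = np.flatnonzero(np.isin(subjects, fs))
        if idx.size < 2:
            raise ValueError(f"fold with fewer than 2 samples (got {idx.size})")
        folds.append(idx)
    return folds


def cv_evaluate(
    counts: GenusCountTable,
    y: np.ndarray,
    subjects: np.ndarray,
    grid: HyperGrid,
    cv: CVSpec = CVSpec(),
    lda_max_iter: int = 80,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Mean cross-validated RMSE for every grid combination.

    For each fold and each topic count K, LDA is fit on the training fold
    only; topic proportions for *both* folds are obtained by fold-in with the
    training phi fixed, and every forest configuration is evaluated on the
    held-out predictions. One LDA fit is shared by all forest configurations
    at the same (fold, K), matching the workflow's factorized grid.
    """
    grid.validate()
    cv.validate()
    y = np.asarray(y, dtype=float)
    folds = _subject_folds(np.asarray(subjects), cv.n_folds, cv.seed)
    combos = grid.combinations()
    sq_err = {i: [] for i in range(len(combos))}

    all_idx = np.arange(counts.n_samples)
    sample_ids = np.asarray(counts.sample_ids)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_counts = counts.counts[train_idx].astype(float)
        test_counts = counts.counts[test_idx].astype(float)
        for K in grid.K:
            model = fit_lda(
                train_counts,
                K,
                max_iter=lda_max_iter,
                seed=_derive_seed(base_seed, f, K),
                genus_ids=counts.genus_ids,
            )
            theta_tr = infer_theta(model, train_counts)
            theta_te = infer_theta(model, test_counts)
            for ci, combo in enumerate(combos):
                if combo["K"] != K:
                    continue
                forest, _ = fit_rf(
                    theta_tr,
                    y[train_idx],
                    trees=combo["trees"],
                    mtry=combo["mtry"],
                    min_node=combo["min_node"],
                    seed=_derive_seed(base_seed, f, K, ci),
                    sample_ids=list(sample_ids[train_idx]),
                )
                pred = forest.predict(theta_te)
                sq_err[ci].append(float(np.sqrt(np.mean((pred - y[test_idx]) ** 2))))

    rows = []
    for ci, combo in enumerate(combos):
        rows.append({**combo, "mean_cv_rmse": float(np.mean(sq_err[ci]))})
    result = pd.DataFrame(rows)
    logger.info(
        "cv_evaluate: best mean RMSE %.4f over %d combination(s)",
        result["mean_cv_rmse"].min(),
        len(result),
    )
    return result


def select_best(cv_results: pd.DataFrame) -> dict[str, int]:
    """Combination minimizing mean CV RMSE; ties go to smaller K, then fewer
    trees, then smaller mtry and min_node."""
    if cv_results.empty:
        raise ValueError("empty CV results")
    ranked = cv_results.sort_values(
        ["mean_cv_rmse", "K", "trees", "mtry", "min_node"], kind="mergesort"
    )
    row = ranked.iloc[0]
    return {k: int(row[k]) for k in ("K", "trees", "mtry", "min_node")}


def extract_candidate_topic(
    counts: GenusCountTable,
    y: np.ndarray,
    chosen: dict[str, int],
    seed: int = 0,
    lda_max_iter: int = 80,
) -> tuple[CandidateTopic, LDAModel]:
    """Refit on all baseline samples and pick the most important topic.

    LDA is refit with the chosen K on the full baseline table, the forest is
    refit on the full-baseline topic proportions, and the topic with maximal
    impurity importance is returned (ties broken deterministically toward the
    lowest topic index, with a warning).
    """
    model = fit_lda(
        counts, chosen["K"], max_iter=lda_max_iter, seed=_derive_seed(seed, 9001, chosen["K"])
    )
    theta = infer_theta(model, counts)
    _, importances = fit_rf(
        theta,
        np.asarray(y, dtype=float),
        trees=chosen["trees"],
        mtry=chosen["mtry"],
        min_node=chosen["min_node"],
        seed=_derive_seed(seed, 9002),
        sample_ids=list(counts.sample_ids),
    )
    best = int(np.argmax(importances))
    if (importances == importances[best]).sum() > 1:
        warnings.warn("importance tie across topics; selecting the lowest topic index")
    candidate = CandidateTopic(
        topic_index=best,
        genus_contributions=model.phi[best],
        genus_ids=list(model.genus_ids),
        importance=float(importances[best]),
        hyperparameters=dict(chosen),
        rng_seed=seed,
    )
    logger.info(
        "candidate topic %d (importance %.4f), top genera: %s",
        best,
        candidate.importance,
        candidate.top_genera(5),
    )
    return candidate, model


def topic_share_all_visits(
    model: LDAModel, dataset: StudyDataset, topic_index: int
) -> pd.Series:
    """Fold every sample (all visits) into the baseline-trained model and
    extract the candidate topic's share."""
    theta = infer_theta(model, dataset.counts)
    return pd.Series(
        theta[:, topic_index], index=dataset.counts.sample_ids, name="topic_share"
    )
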