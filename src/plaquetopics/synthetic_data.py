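"""Synthetic multi-center longitudinal cohorts with planted topic structure.

Generates cohorts shaped like a two-arm (placebo vs. adjunctive antibiotic),
eight-center periodontitis trial observed at five visits (baseline V2 and
2/8/14/26 months after therapy), where subgingival genus counts arise from a
latent-topic (Dirichlet-multinomial) mixture. One planted topic, dominated by
two genera at ~40% each, has a per-sample share whose odds of exceeding the
population median increase by a configurable factor per 10 points of the
O'Leary supragingival plaque index. Clinical couplings are planted too:
O'Leary drives %BOP at baseline, centers differ in pre-treatment frequency
which shifts baseline plaque, the antibiotic arm's %BOP is suppressed from
V4 on, and %PPD>=5mm / %PSAL are generated independent of plaque.

Every latent quantity is returned in a :class:`GroundTruth` so downstream
stages (diversity screen, topic pipeline, mixed model) can be validated
against known truth.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_core import ARMS, METADATA_COLUMNS, VISITS, GenusCountTable, StudyDataset

logger = logging.getLogger("plaquetopics")

# fixed sub-stream tags so each operation is independently reproducible
_TAG_TOPICS, _TAG_METADATA, _TAG_COUNTS, _TAG_CALIB = 11, 12, 13, 14


class ConfigError(ValueError):
    """A simulation configuration is infeasible."""


class CalibrationError(RuntimeError):
    """The tilt calibration failed to bracket or converge."""


def _default_center_map() -> dict[str, int]:
    # one heavily pre-treated center, one untreated, the rest at two sessions
    # (mirrors the observed center -> pre-treatment -> baseline-plaque gradient)
    return {
        "center_1": 5,
        "center_2": 2,
        "center_3": 2,
        "center_4": 2,
        "center_5": 2,
        "center_6": 2,
        "center_7": 2,
        "center_8": 0,
    }


def _default_bop_visit_factors() -> dict[str, float]:
    # gradual post-treatment BOP decline in the placebo arm
    return {"V2": 1.0, "V4": 0.9, "V6": 0.8, "V8": 0.65, "V12": 0.55}


def _default_oleary_visit_factors() -> dict[str, float]:
    # hygiene instructions lower plaque after baseline, with partial relapse
    return {"V2": 1.0, "V4": 0.85, "V6": 0.9, "V8": 0.95, "V12": 1.0}


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with study-shaped defaults."""

    n_subjects: int = 163
    n_centers: int = 8
    visits: tuple[str, ...] = VISITS
    n_placebo: int | None = None  # default: 82/163 of n_subjects; rest antibiotic
    n_genera: int = 120
    k_true: int = 8
    planted_topic_index: int = 0
    dominant_genus_indices: tuple[int, int] = (0, 1)
    dominant_share: float = 0.40
    dominant_jitter: float = 0.04
    topic_concentration: float = 0.1  # eta: Dirichlet over genera per topic
    theta_concentration: float = 0.3  # alpha: Dirichlet over topics per sample
    library_size_median: float = 2.0e4
    library_size_sigma: float = 0.5  # log-normal sigma
    beta_plaque: float = math.log(1.2)  # log-odds of high planted share per 10 O'Leary pts
    beta_plaque_by_arm: dict[str, float] | None = None
    beta_bop: float = 0.45  # %BOP per %O'Leary at baseline
    bop_intercept: float = 18.0
    bop_noise_sd: float = 8.0
    bop_visit_factors: dict[str, float] = field(default_factory=_default_bop_visit_factors)
    ab_bop_suppression: float = 0.35  # multiplier on %BOP in the antibiotic arm from V4
    center_pretreatment_map: dict[str, int] = field(default_factory=_default_center_map)
    oleary_base: float = 52.0
    oleary_per_pretreatment: float = 6.5  # baseline O'Leary drop per pre-treatment session
    oleary_center_sd: float = 6.0
    oleary_subject_sd: float = 16.0
    oleary_visit_factors: dict[str, float] = field(default_factory=_default_oleary_visit_factors)
    oleary_noise_sd: float = 6.0
    ppd5_baseline_mean: float = 32.0
    ppd5_baseline_sd: float = 10.0
    ppd5_visit_factors: dict[str, float] = field(
        default_factory=lambda: {"V2": 1.0, "V4": 0.55, "V6": 0.5, "V8": 0.5, "V12": 0.55}
    )
    psal_baseline_mean: float = 12.0
    psal_baseline_sd: float = 6.0
    clinical_noise_sd: float = 4.0
    age_band_probs: tuple[float, float, float] = (36 / 163, 65 / 163, 62 / 163)
    p_female: float = 83 / 163
    p_smoker: float = 0.5
    topic_visit_drift: dict[str, dict[str, float]] | None = None  # arm -> visit -> factor
    rng_seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.k_true < 2:
            raise ConfigError("k_true must be >= 2")
        if not (0 <= self.planted_topic_index < self.k_true):
            raise ConfigError("planted_topic_index must be < k_true")
        if len(set(self.dominant_genus_indices)) != 2 or any(
            not (0 <= g < self.n_genera) for g in self.dominant_genus_indices
        ):
            raise ConfigError("dominant_genus_indices must be two distinct genus indices")
        hi = self.dominant_share + self.dominant_jitter
        if 2 * hi >= 1.0:
            raise ConfigError(
                f"two dominant genera at up to {hi:.2f} each exceed the simplex"
            )
        if self.topic_concentration <= 0 or self.theta_concentration <= 0:
            raise ConfigError("Dirichlet concentrations must be > 0")
        for p in (self.p_female, self.p_smoker, *self.age_band_probs):
            if not (0 <= p <= 1):
                raise ConfigError("probabilities must lie in [0, 1]")
        if len(self.center_pretreatment_map) != self.n_centers:
            raise ConfigError("center_pretreatment_map must list every center")
        if not (0 <= self.effective_n_placebo <= self.n_subjects):
            raise ConfigError("n_placebo must be within [0, n_subjects]")
        return self

    @property
    def effective_n_placebo(self) -> int:
        if self.n_placebo is None:
            return int(round(self.n_subjects * 82 / 163))
        return self.n_placebo

    def genus_ids(self) -> list[str]:
        return [f"g{i + 1:03d}" for i in range(self.n_genera)]

    def arm_betas(self) -> dict[str, float]:
        if self.beta_plaque_by_arm is not None:
            return dict(self.beta_plaque_by_arm)
        return {arm: self.beta_plaque for arm in ARMS}


@dataclass
class GroundTruth:
    """Generative latents recorded for downstream validation."""

    phi_true: np.ndarray  # (k_true, n_genera), rows on the simplex
    theta_true: np.ndarray  # (n_samples, k_true), rows on the simplex
    sample_ids: list[str]
    genus_ids: list[str]
    planted_topic_index: int
    beta_plaque_by_arm: dict[str, float]
    tilt_by_arm: dict[str, float]
    share_threshold: float  # pooled median used to define the latent state
    high_state: np.ndarray  # per-sample planted-share-above-median indicator
    library_sizes: np.ndarray

    def validate(self) -> "GroundTruth":
        for name, mat in (("phi_true", self.phi_true), ("theta_true", self.theta_true)):
            if np.abs(mat.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"{name} rows must sum to 1 within 1e-9")
        return self

    def to_json(self, path: str) -> None:
        obj = {
            "planted_topic_index": int(self.planted_topic_index),
            "beta_plaque_by_arm": self.beta_plaque_by_arm,
            "tilt_by_arm": self.tilt_by_arm,
            "share_threshold": float(self.share_threshold),
            "sample_ids": self.sample_ids,
            "genus_ids": self.genus_ids,
            "phi_true": self.phi_true.tolist(),
            "theta_true": self.theta_true.tolist(),
            "high_state": self.high_state.astype(int).tolist(),
            "library_sizes": self.library_sizes.astype(int).tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)


# ---------------------------------------------------------------------------
# Topic-genus distributions
# ---------------------------------------------------------------------------

def simulate_topics(config: SimulationConfig) -> np.ndarray:
    """Draw the true topic-genus matrix phi (k_true x n_genera).

    The planted row gives each of the two dominant genera a share of
    ~``dominant_share`` (within ±jitter) and spreads the remainder
    Dirichlet-randomly over the other genera; all other rows are symmetric
    Dirichlet(eta) draws over the full genus set.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, _TAG_TOPICS])
    K, G = config.k_true, config.n_genera
    eta = config.topic_concentration
    phi = rng.dirichlet(np.full(G, eta), size=K)
    d1, d2 = config.dominant_genus_indices
    shares = rng.uniform(
        config.dominant_share - config.dominant_jitter,
        config.dominant_share + config.dominant_jitter,
        size=2,
    )
    rest = np.setdiff1d(np.arange(G), list(config.dominant_genus_indices))
    row = np.zeros(G)
    row[[d1, d2]] = shares
    row[rest] = (1.0 - shares.sum()) * rng.dirichlet(np.full(rest.size, eta))
    phi[config.planted_topic_index] = row
    return phi


# ---------------------------------------------------------------------------
# Clinical metadata
# ---------------------------------------------------------------------------

def simulate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the per-sample clinical/design covariates for the cohort.

    Couplings: center pre-treatment frequency lowers baseline O'Leary; %BOP
    at every visit follows ``bop_intercept + beta_bop * O'Leary`` scaled by a
    per-visit decay, additionally multiplied by ``ab_bop_suppression`` in the
    antibiotic arm from V4 on; %PPD>=5mm and %PSAL are independent of plaque.
    Coupled variables are generated from the *realized* (truncated) O'Leary
    values, so planted slopes are exactly recoverable.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, _TAG_METADATA])
    n = config.n_subjects
    centers = list(config.center_pretreatment_map)

    n_pl = config.effective_n_placebo
    arm = np.array(["placebo"] * n_pl + ["antibiotic"] * (n - n_pl))
    rng.shuffle(arm)
    center = rng.choice(centers, size=n)
    center_shift = {c: rng.normal(0.0, config.oleary_center_sd) for c in centers}
    subj_eff = rng.normal(0.0, config.oleary_subject_sd, size=n)

    band = rng.choice(3, size=n, p=np.asarray(config.age_band_probs) / sum(config.age_band_probs))
    lo = np.array([25, 45, 55])[band]
    hi = np.array([44, 54, 75])[band]
    age = rng.integers(lo, hi + 1)
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    smoking = (rng.random(n) < config.p_smoker).astype(int)

    ppd_base = rng.normal(config.ppd5_baseline_mean, config.ppd5_baseline_sd, size=n)
    psal_base = rng.normal(config.psal_baseline_mean, config.psal_baseline_sd, size=n)

    rows = []
    for i in range(n):
        subject_id = f"S{i + 1:04d}"
        pretreat = config.center_pretreatment_map[center[i]]
        mu = config.oleary_base - config.oleary_per_pretreatment * pretreat
        mu = mu + center_shift[center[i]] + subj_eff[i]
        for visit in config.visits:
            oleary = mu * config.oleary_visit_factors.get(visit, 1.0)
            oleary = np.clip(oleary + rng.normal(0.0, config.oleary_noise_sd), 0.0, 100.0)
            bop = config.bop_intercept + config.beta_bop * oleary
            bop *= config.bop_visit_factors.get(visit, 1.0)
            if arm[i] == "antibiotic" and visit != "V2":
                bop *= config.ab_bop_suppression
            bop = np.clip(bop + rng.normal(0.0, config.bop_noise_sd), 0.0, 100.0)
            ppd = ppd_base[i] * config.ppd5_visit_factors.get(visit, 1.0)
            ppd = np.clip(ppd + rng.normal(0.0, config.clinical_noise_sd), 0.0, 100.0)
            psal = np.clip(
                psal_base[i] + rng.normal(0.0, config.clinical_noise_sd), 0.0, 100.0
            )
            rows.append(
                {
                    "sample_id": f"{subject_id}_{visit}",
                    "subject_id": subject_id,
                    "center_id": center[i],
                    "visit": visit,
                    "arm": arm[i],
                    "age_years": int(age[i]),
                    "sex": sex[i],
                    "smoking": int(smoking[i]),
                    "pretreatment_count": int(pretreat),
                    "oleary_pct": float(oleary),
                    "bop_pct": float(bop),
                    "ppd5_pct": float(ppd),
                    "psal_pct": float(psal),
                    "dysbiosis_covariate": float(rng.normal()),
                }
            )
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


# ---------------------------------------------------------------------------
# Tilt calibration (plaque -> planted-topic link)
# ---------------------------------------------------------------------------

def _draw_planted_share(
    alpha: float, k: int, shape_planted: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    gp = rng.gamma(shape_planted)
    go = rng.gamma(alpha, size=(shape_planted.size, k - 1)).sum(axis=1)
    return gp / (gp + go)


def _logistic_slope(y: np.ndarray, x10: np.ndarray) -> float:
    model = sm.Logit(y, sm.add_constant(x10))
    return float(model.fit(disp=0, maxiter=200).params[1])


def calibrate_tilt(
    config: SimulationConfig,
    oleary_by_arm: dict[str, np.ndarray],
    n_mc: int = 40000,
    tol: float = 0.005,
    c_max: float = 512.0,
) -> tuple[dict[str, float], float]:
    """Calibrate the per-arm tilt coefficient c by bisection.

    The planted component of the per-sample Dirichlet concentration is
    ``alpha + c * oleary/10``. c is chosen so that a logistic regression of
    (planted share > pooled median) on oleary/10 recovers the target
    log-odds slope ``beta_plaque`` in each arm. Because the pooled median
    itself depends on c, a second pass re-bisections against the threshold
    implied by the first-pass solution.

    Returns (c per arm, pooled share threshold). Raises
    :class:`CalibrationError` with the bracketing interval on failure.
    """
    alpha, K = config.theta_concentration, config.k_true
    betas = config.arm_betas()
    seed = [config.rng_seed, _TAG_CALIB]

    def slope(c: float, x10: np.ndarray, threshold: float | None) -> tuple[float, np.ndarray]:
        rng = np.random.default_rng(seed)  # common random numbers across c values
        share = _draw_planted_share(alpha, K, alpha + c * x10, rng)
        t = float(np.median(share)) if threshold is None else threshold
        return _logistic_slope((share > t).astype(int), x10), share

    def bisect(beta: float, x10: np.ndarray, threshold: float | None) -> float:
        if beta == 0.0:
            return 0.0
        lo, hi = 0.0, 1.0
        while slope(hi, x10, threshold)[0] < beta:
            hi *= 2.0
            if hi > c_max:
                raise CalibrationError(
                    f"tilt calibration failed to bracket beta={beta:.4f} in c ∈ [0, {c_max}]"
                )
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            s, _ = slope(mid, x10, threshold)
            if abs(s - beta) < tol:
                return mid
            if s < beta:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-4 * max(1.0, hi):
                break
        return 0.5 * (lo + hi)

    def beta_for(group: str) -> float:
        return betas.get(group, next(iter(betas.values())))

    arms = [a for a in oleary_by_arm if oleary_by_arm[a].size > 0]
    if len({beta_for(a) for a in arms}) == 1 and len(arms) > 1:
        # one shared target: calibrate once on the pooled O'Leary distribution
        pooled_x = np.concatenate([oleary_by_arm[a] for a in arms])
        cs, threshold = calibrate_tilt(
            config, {"pooled": pooled_x}, n_mc=n_mc, tol=tol, c_max=c_max
        )
        return {a: cs["pooled"] for a in arms}, threshold
    rng0 = np.random.default_rng(seed)
    x_by_arm = {
        a: rng0.choice(np.asarray(oleary_by_arm[a], dtype=float), size=n_mc) / 10.0
        for a in arms
    }
    # pass 1: per-arm medians as provisional thresholds
    cs = {a: bisect(beta_for(a), x_by_arm[a], None) for a in arms}
    # pooled threshold implied by pass-1 tilts, weighted by true arm sizes
    weights = np.array([oleary_by_arm[a].size for a in arms], dtype=float)
    pooled = []
    for a in arms:
        _, share = slope(cs[a], x_by_arm[a], 0.5)
        k = int(round(n_mc * weights[arms.index(a)] / weights.sum()))
        pooled.append(share[: max(k, 1)])
    threshold = float(np.median(np.concatenate(pooled)))
    # pass 2: re-calibrate against the fixed pooled threshold
    cs = {a: bisect(beta_for(a), x_by_arm[a], threshold) for a in arms}
    logger.info("tilt calibration: c=%s, pooled threshold=%.4f", cs, threshold)
    return cs, threshold


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SimulationConfig, phi_true: np.ndarray, metadata: pd.DataFrame
) -> tuple[StudyDataset, GroundTruth]:
    """Draw per-sample topic mixtures and multinomial genus counts.

    theta is Dirichlet with the planted component tilted by the calibrated
    c * oleary/10; counts are Multinomial(library_size, theta @ phi). The
    returned GroundTruth records every latent, including the pooled-median
    high/low planted-share state the association model targets.
    """
    config.validate()
    if phi_true.shape != (config.k_true, config.n_genera):
        raise ConfigError("phi_true shape does not match config")
    rng = np.random.default_rng([config.rng_seed, _TAG_COUNTS])
    n = len(metadata)
    K = config.k_true
    alpha = config.theta_concentration
    oleary = metadata["oleary_pct"].to_numpy(dtype=float)
    arm = metadata["arm"].to_numpy()

    oleary_by_arm = {a: oleary[arm == a] for a in pd.unique(arm)}
    cs, _ = calibrate_tilt(config, oleary_by_arm)

    alpha_mat = np.full((n, K), alpha, dtype=float)
    tilt = np.array([cs[a] for a in arm]) * oleary / 10.0
    alpha_mat[:, config.planted_topic_index] += tilt
    if config.topic_visit_drift is not None:
        visit = metadata["visit"].to_numpy()
        drift = np.array(
            [config.topic_visit_drift.get(a, {}).get(v, 1.0) for a, v in zip(arm, visit)]
        )
        alpha_mat[:, config.planted_topic_index] *= drift

    gam = rng.gamma(alpha_mat)
    theta = gam / gam.sum(axis=1, keepdims=True)

    lib = rng.lognormal(math.log(config.library_size_median), config.library_size_sigma, n)
    lib = np.maximum(lib.astype(np.int64), 100)
    probs = theta @ phi_true
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.empty((n, config.n_genera), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(lib[i], probs[i])

    sample_ids = list(metadata["sample_id"])
    table = GenusCountTable(sample_ids, config.genus_ids(), counts).validate(
        drop_zero_rows=False
    )
    dataset = StudyDataset(table, metadata.reset_index(drop=True))

    shares = theta[:, config.planted_topic_index]
    threshold = float(np.median(shares))
    truth = GroundTruth(
        phi_true=phi_true,
        theta_true=theta,
        sample_ids=sample_ids,
        genus_ids=config.genus_ids(),
        planted_topic_index=config.planted_topic_index,
        beta_plaque_by_arm=config.arm_betas(),
        tilt_by_arm={a: float(c) for a, c in cs.items()},
        share_threshold=threshold,
        high_state=shares > threshold,
        library_sizes=lib,
    ).validate()
    return dataset, truth


def simulate_cohort(config: SimulationConfig) -> tuple[StudyDataset, GroundTruth]:
    """Convenience wrapper: topics + metadata + counts in one call."""
    phi = simulate_topics(config)
    meta = simulate_metadata(config)
    return simulate_counts(config, phi, meta)
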