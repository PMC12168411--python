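"""Alpha diversity, Bray-Curtis beta diversity, and the dysbiosis log-ratio.

Per sample: richness (genera present), Shannon entropy in nats, inverse
Simpson (effective number of genera), mean Bray-Curtis dissimilarity to the
other samples of the same visit, and a subgingival microbial dysbiosis index
(SMDI) — log10 of the disease-associated over health-associated genus count
sums, with a pseudocount. No rarefaction is applied; an optional seeded
subsampling flag is available for library-size sensitivity checks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_core import StudyDataset, ValidationError

logger = logging.getLogger("plaquetopics")

#: Default SMDI genus lists. The dysbiosis index is defined relative to
#: externally curated disease- and health-associated taxa; these defaults use
#: canonical periodontitis-associated and health-associated oral genera and
#: are meant to be replaced by a study-specific configuration (YAML) whenever
#: the analyzed table contains the curated taxa.
DEFAULT_SMDI_DISEASE = (
    "Porphyromonas",
    "Treponema",
    "Tannerella",
    "Filifactor",
    "Fretibacterium",
)
DEFAULT_SMDI_HEALTH = (
    "Rothia",
    "Streptococcus",
    "Haemophilus",
    "Neisseria",
    "Actinomyces",
)


def richness(row: np.ndarray) -> int:
    """Number of genera with count > 0."""
    return int(np.count_nonzero(np.asarray(row)))


def shannon(row: np.ndarray) -> float:
    """Shannon entropy H = -sum p ln p (nats) over genera with p > 0."""
    row = np.asarray(row, dtype=float)
    tot = row.sum()
    if tot < 1:
        raise ValidationError("shannon requires row total >= 1")
    p = row[row > 0] / tot
    return float(-(p * np.log(p)).sum())


def inverse_simpson(row: np.ndarray) -> float:
    """Inverse Simpson concentration 1 / sum p^2 (effective genera)."""
    row = np.asarray(row, dtype=float)
    tot = row.sum()
    if tot < 1:
        raise ValidationError("inverse_simpson requires row total >= 1")
    p = row / tot
    return float(1.0 / (p @ p))


def bray_curtis(row_i: np.ndarray, row_j: np.ndarray) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum min(x, y) / (sum x + sum y)."""
    x = np.asarray(row_i, dtype=float)
    y = np.asarray(row_j, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("bray_curtis requires rows over identical genus sets")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValidationError("bray_curtis undefined for two all-zero rows")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def mean_bray_curtis(
    counts: np.ndarray, groups: np.ndarray | pd.Series | None = None
) -> np.ndarray:
    """Mean Bray-Curtis dissimilarity of each sample to its group comparators.

    ``groups`` assigns every row a comparison set (default: one global group).
    Samples whose group is a singleton have no comparator; their value is NaN
    and a warning is logged.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    if groups is None:
        groups = np.zeros(n)
    groups = np.asarray(groups)
    out = np.full(n, np.nan)
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size == 1:
            logger.warning("mean_bray_curtis: singleton group %r -> missing value", g)
            continue
        dm = squareform(pdist(counts[idx], metric="braycurtis"))
        out[idx] = dm.sum(axis=1) / (idx.size - 1)
    return out


def smdi(
    row: np.ndarray,
    genus_ids: list[str],
    disease_genera: list[str] | tuple[str, ...] = DEFAULT_SMDI_DISEASE,
    health_genera: list[str] | tuple[str, ...] = DEFAULT_SMDI_HEALTH,
    pseudocount: float = 1.0,
) -> float:
    """Dysbiosis index: log10((disease counts + pc) / (health counts + pc)).

    Genus names absent from the table contribute zero; overlapping or empty
    lists are configuration errors.
    """
    disease = set(disease_genera)
    health = set(health_genera)
    if not disease or not health:
        raise ValidationError("SMDI genus lists must be non-empty")
    if disease & health:
        raise ValidationError(f"SMDI genus lists overlap: {sorted(disease & health)}")
    row = np.asarray(row, dtype=float)
    pos = {g: i for i, g in enumerate(genus_ids)}
    d = sum(row[pos[g]] for g in disease if g in pos)
    h = sum(row[pos[g]] for g in health if g in pos)
    return float(np.log10((d + pseudocount) / (h + pseudocount)))


def subsample_counts(
    counts: np.ndarray, depth: int, seed: int = 0
) -> np.ndarray:
    """Optional seeded subsampling (without replacement) to a common depth."""
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts)
    out = np.zeros_like(counts)
    for i, row in enumerate(counts):
        tot = int(row.sum())
        if tot <= depth:
            out[i] = row
            continue
        drawn = rng.multivariate_hypergeometric(row.astype(np.int64), depth)
        out[i] = drawn
    return out


def diversity_profiles(
    dataset: StudyDataset,
    disease_genera: list[str] | tuple[str, ...] = DEFAULT_SMDI_DISEASE,
    health_genera: list[str] | tuple[str, ...] = DEFAULT_SMDI_HEALTH,
    pseudocount: float = 1.0,
    group_by: str | None = "visit",
) -> pd.DataFrame:
    """Per-sample diversity/dysbiosis profile table.

    Beta diversity is the mean Bray-Curtis dissimilarity to all other samples
    of the same ``group_by`` level (default: same visit, matching per-visit
    reporting); ``group_by=None`` compares against the whole dataset.
    """
    counts = dataset.counts.counts
    genus_ids = dataset.counts.genus_ids
    groups = dataset.metadata[group_by].to_numpy() if group_by else None
    prof = pd.DataFrame(
        {
            "sample_id": dataset.counts.sample_ids,
            "richness": [richness(r) for r in counts],
            "shannon": [shannon(r) for r in counts],
            "inverse_simpson": [inverse_simpson(r) for r in counts],
            "mean_bray_curtis": mean_bray_curtis(counts, groups),
            "smdi": [
                smdi(r, genus_ids, disease_genera, health_genera, pseudocount)
                for r in counts
            ],
        }
    )
    return prof
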