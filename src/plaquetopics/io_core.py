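"""Reading, validation, and alignment of genus count tables and clinical metadata.

The analyzable unit is a :class:`StudyDataset`: an integer sample x genus
count matrix (:class:`GenusCountTable`) paired row-for-row with per-sample
clinical covariates from a multi-center longitudinal periodontitis cohort
(subject, center, visit, treatment arm, O'Leary plaque index, %BOP, %PPD>=5mm,
%PSAL, demographics, and a dysbiosis covariate).

Count tables are accepted as TSV (samples in rows, genera in columns, first
column the sample id) or as BIOM v1 JSON (observations = genera in rows,
samples in columns). Genus names are opaque case-sensitive strings; taxonomy
normalization is out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("plaquetopics")

#: The five scheduled visits: baseline and 2, 8, 14, 26 months after therapy.
VISITS: tuple[str, ...] = ("V2", "V4", "V6", "V8", "V12")
BASELINE_VISIT = "V2"
ARMS: tuple[str, ...] = ("placebo", "antibiotic")

#: Required metadata columns, in canonical order.
METADATA_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "subject_id",
    "center_id",
    "visit",
    "arm",
    "age_years",
    "sex",
    "smoking",
    "pretreatment_count",
    "oleary_pct",
    "bop_pct",
    "ppd5_pct",
    "psal_pct",
    "dysbiosis_covariate",
)

PERCENT_COLUMNS = ("oleary_pct", "bop_pct", "ppd5_pct", "psal_pct")


class ValidationError(ValueError):
    """An input violates a structural invariant."""


class ParseError(ValueError):
    """An input file could not be parsed."""


@dataclass
class GenusCountTable:
    """Integer sample x genus abundance matrix.

    Invariants (enforced by :meth:`validate`): no negative entries, unique
    sample and genus identifiers, and every retained row has total count >= 1.
    """

    sample_ids: list[str]
    genus_ids: list[str]
    counts: np.ndarray  # (n_samples, n_genera), integer

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genera(self) -> int:
        return len(self.genus_ids)

    def validate(self, drop_zero_rows: bool = False) -> "GenusCountTable":
        """Check invariants, optionally dropping zero-total samples.

        Zero-total samples carry no compositional information; at read time
        they are dropped with a warning rather than imputed.
        """
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.genus_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.genus_ids)} genera"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, genus {self.genus_ids[j]!r}"
            )
        for name, ids in (("sample", self.sample_ids), ("genus", self.genus_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
                raise ValidationError(f"duplicated {name} id: {dup!r}")
        row_tot = counts.sum(axis=1)
        if (row_tot == 0).any():
            zero_ids = [s for s, t in zip(self.sample_ids, row_tot) if t == 0]
            if not drop_zero_rows:
                raise ValidationError(f"zero-total samples present: {zero_ids}")
            logger.warning("dropping %d zero-total sample(s): %s", len(zero_ids), zero_ids)
            keep = row_tot > 0
            return GenusCountTable(
                [s for s, k in zip(self.sample_ids, keep) if k],
                list(self.genus_ids),
                counts[keep],
            )
        return GenusCountTable(list(self.sample_ids), list(self.genus_ids), counts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.genus_ids)

    def subset(self, sample_ids: list[str]) -> "GenusCountTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenusCountTable(list(sample_ids), list(self.genus_ids), self.counts[idx])


@dataclass
class StudyDataset:
    """Counts and metadata in one-to-one row correspondence."""

    counts: GenusCountTable
    metadata: pd.DataFrame  # one row per counts row, same order

    def baseline(self) -> "StudyDataset":
        """Subset to the baseline visit (V2)."""
        meta = self.metadata[self.metadata["visit"] == BASELINE_VISIT]
        if meta.empty:
            raise ValidationError("no baseline (V2) samples in dataset")
        return StudyDataset(
            self.counts.subset(list(meta["sample_id"])), meta.reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# Count-table readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str, format_tag: str = "tsv") -> GenusCountTable:
    """Read and validate a genus count table.

    format_tag "tsv": tab-separated UTF-8 with a mandatory header row; first
    column holds sample ids, remaining columns one genus each.
    format_tag "biom-json": BIOM v1 JSON with rows = observations (genera)
    and columns = samples; both sparse and dense matrix_type are accepted.

    Zero-total samples are dropped with a logged warning.
    """
    if format_tag == "tsv":
        table = _read_tsv_counts(path)
    elif format_tag == "biom-json":
        table = _read_biom_json(path)
    else:
        raise ValueError(f"unknown count-table format: {format_tag!r}")
    return table.validate(drop_zero_rows=True)


def _read_tsv_counts(path: str) -> GenusCountTable:
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse TSV count table {path}: {exc}") from exc
    try:
        mat = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in {path}: {exc}") from exc
    if np.isnan(mat).any():
        i, j = np.argwhere(np.isnan(mat))[0]
        raise ValidationError(
            f"missing/non-numeric count at line {i + 2}, column {df.columns[j]!r}"
        )
    if not np.all(np.equal(np.mod(mat, 1), 0)):
        i, j = np.argwhere(np.mod(mat, 1) != 0)[0]
        raise ValidationError(f"non-integer count at line {i + 2}, column {df.columns[j]!r}")
    return GenusCountTable(
        [str(s) for s in df.index], [str(g) for g in df.columns], mat.astype(np.int64)
    )


def _read_biom_json(path: str) -> GenusCountTable:
    with open(path, encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON in {path}: {exc}") from exc
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in obj:
            raise ParseError(f"BIOM table {path} missing key {key!r}")
    genus_ids = [str(r["id"]) for r in obj["rows"]]
    sample_ids = [str(c["id"]) for c in obj["columns"]]
    n_obs, n_samp = obj["shape"]
    if (n_obs, n_samp) != (len(genus_ids), len(sample_ids)):
        raise ParseError(f"BIOM shape {obj['shape']} inconsistent with rows/columns lists")
    mat = np.zeros((n_obs, n_samp), dtype=np.float64)
    if obj["matrix_type"] == "sparse":
        for entry in obj["data"]:
            i, j, v = entry
            mat[int(i), int(j)] = v
    elif obj["matrix_type"] == "dense":
        mat[:] = np.asarray(obj["data"], dtype=np.float64)
    else:
        raise ParseError(f"unsupported BIOM matrix_type {obj['matrix_type']!r}")
    if not np.all(np.equal(np.mod(mat, 1), 0)):
        raise ValidationError(f"non-integer count in BIOM table {path}")
    # BIOM stores observations x samples; the in-memory convention is samples x genera.
    return GenusCountTable(sample_ids, genus_ids, mat.T.astype(np.int64))


def write_count_table(table: GenusCountTable, path: str, format_tag: str = "tsv") -> None:
    """Write a count table in either supported format (round-trip exact)."""
    if format_tag == "tsv":
        table.to_dataframe().rename_axis("sample_id").to_csv(path, sep="\t")
    elif format_tag == "biom-json":
        obj = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "plaquetopics",
            "date": "",
            "rows": [{"id": g, "metadata": None} for g in table.genus_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [table.n_genera, table.n_samples],
            "data": [
                [int(j), int(i), int(table.counts[i, j])]
                for i in range(table.n_samples)
                for j in range(table.n_genera)
                if table.counts[i, j] != 0
            ],
        }
        # sparse entries sorted by observation index, as BIOM writers emit them
        obj["data"].sort(key=lambda t: (t[0], t[1]))
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)
    else:
        raise ValueError(f"unknown count-table format: {format_tag!r}")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame, drop_incomplete: bool = True) -> pd.DataFrame:
    """Validate a per-sample metadata table.

    Checks column presence, percentage bounds, the visit schedule, and that
    every subject keeps a single arm and a single center across visits.
    Records with missing covariates are excluded (complete-case) and logged.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s): {missing}")
    meta = meta.loc[:, list(METADATA_COLUMNS)].copy()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicated sample id in metadata: {dup!r}")
    incomplete = meta.isna().any(axis=1)
    if incomplete.any():
        if not drop_incomplete:
            raise ValidationError(f"{int(incomplete.sum())} metadata record(s) incomplete")
        logger.warning(
            "excluding %d metadata record(s) with missing covariates: %s",
            int(incomplete.sum()),
            list(meta.loc[incomplete, "sample_id"].head(10)),
        )
        meta = meta[~incomplete]
    bad_visit = ~meta["visit"].isin(VISITS)
    if bad_visit.any():
        raise ValidationError(
            f"unknown visit label(s): {sorted(meta.loc[bad_visit, 'visit'].unique())}"
        )
    bad_arm = ~meta["arm"].isin(ARMS)
    if bad_arm.any():
        raise ValidationError(f"unknown arm label(s): {sorted(meta.loc[bad_arm, 'arm'].unique())}")
    for col in PERCENT_COLUMNS:
        vals = pd.to_numeric(meta[col], errors="raise")
        if ((vals < 0) | (vals > 100)).any():
            raise ValidationError(f"{col} outside [0, 100]")
        meta[col] = vals.astype(float)
    if (pd.to_numeric(meta["pretreatment_count"]) < 0).any():
        raise ValidationError("pretreatment_count must be non-negative")
    for col, what in (("arm", "arm"), ("center_id", "center")):
        per_subject = meta.groupby("subject_id")[col].nunique()
        switchers = per_subject[per_subject > 1]
        if not switchers.empty:
            raise ValidationError(
                f"subject(s) with more than one {what} across visits: "
                f"{list(switchers.index[:5])}"
            )
    return meta.reset_index(drop=True)


def read_metadata(path: str) -> pd.DataFrame:
    """Read and validate a metadata TSV with the canonical column names."""
    try:
        meta = pd.read_csv(path, sep="\t", header=0, comment="#")
    except Exception as exc:
        raise ParseError(f"cannot parse metadata TSV {path}: {exc}") from exc
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment and transforms
# ---------------------------------------------------------------------------

def align_dataset(counts: GenusCountTable, metadata: pd.DataFrame) -> StudyDataset:
    """Intersect counts and metadata on sample id, in count-table order.

    Idempotent: aligning an already aligned dataset changes nothing. An empty
    intersection is fatal.
    """
    meta_ids = set(metadata["sample_id"])
    keep = [s for s in counts.sample_ids if s in meta_ids]
    if not keep:
        raise ValidationError("no sample ids shared between counts and metadata")
    dropped_counts = counts.n_samples - len(keep)
    dropped_meta = len(meta_ids) - len(keep)
    if dropped_counts or dropped_meta:
        logger.info(
            "align_dataset: dropped %d count-table sample(s) and %d metadata record(s)",
            dropped_counts,
            dropped_meta,
        )
    sub_counts = counts.subset(keep)
    meta = metadata.set_index("sample_id").loc[keep].reset_index()
    return StudyDataset(sub_counts, meta.loc[:, list(METADATA_COLUMNS)])


def to_relative_abundance(counts: GenusCountTable | np.ndarray) -> np.ndarray:
    """Row-normalize counts to proportions (each row sums to 1)."""
    mat = counts.counts if isinstance(counts, GenusCountTable) else np.asarray(counts)
    tot = mat.sum(axis=1, keepdims=True)
    if (tot == 0).any():
        raise ValidationError("zero-total row; drop empty samples before normalizing")
    return mat / tot
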