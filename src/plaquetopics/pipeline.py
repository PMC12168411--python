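"""One-command orchestration: simulate -> diversity -> screen -> topics -> associate.

A :class:`RunConfig` (usually loaded from YAML) fixes every stage's
parameters and a single global seed; each stage draws its own substream seed
from it, so stage-local reruns stay reproducible. Every run writes a
manifest with the config hash, per-stage seeds, input hashes and timings;
all tabular outputs carry the config hash in a leading comment line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import DEFAULT_SMDI_DISEASE, DEFAULT_SMDI_HEALTH, diversity_profiles
from .io_core import StudyDataset, align_dataset, read_count_table, read_metadata
from .mixed_model import association_frame, mixed_results_table, stratified_analysis
from .synthetic_data import SimulationConfig, simulate_cohort
from .topics import (
    CVSpec,
    HyperGrid,
    cv_evaluate,
    extract_candidate_topic,
    select_best,
    topic_share_all_visits,
)
from .univariate import association_screen

logger = logging.getLogger("plaquetopics")

STAGES = ("simulate", "diversity", "screen", "topics", "associate")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    counts_path: str | None = None
    counts_format: str = "tsv"
    metadata_path: str | None = None
    smdi_disease: tuple[str, ...] = DEFAULT_SMDI_DISEASE
    smdi_health: tuple[str, ...] = DEFAULT_SMDI_HEALTH
    smdi_pseudocount: float = 1.0
    fdr_family: str = "per-visit"
    grid: dict = field(default_factory=dict)  # HyperGrid overrides
    cv_folds: int = 5
    lda_max_iter: int = 80
    per_visit_median: bool = False
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if not self.simulate:
            for name, path in (("counts_path", self.counts_path),
                               ("metadata_path", self.metadata_path)):
                if path is None:
                    raise ValueError(f"{name} is required when simulate is disabled")
                if not Path(path).exists():
                    raise ValueError(f"{name} does not resolve: {path}")
        if self.fdr_family not in ("per-visit", "global"):
            raise ValueError(f"unknown fdr_family {self.fdr_family!r}")
        return self

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["smdi_disease"] = list(self.smdi_disease)
        d["smdi_health"] = list(self.smdi_health)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # the output location is not part of the analysis
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Named substream seed (< 2**31) for one pipeline stage."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] % 2**31)


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def _hash_file(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order; returns the run directory.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    artifacts of completed stages remain on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = f"# plaquetopics v{__version__} config={chash} seed={config.seed}\n"
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages_completed": [],
        "timings_s": {},
        "input_hashes": {},
    }

    def finish(stage: str, t0: float) -> None:
        manifest["stages_completed"].append(stage)
        manifest["timings_s"][stage] = round(time.time() - t0, 3)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)

    # --- stage: simulate (or load) ------------------------------------------
    t0 = time.time()
    try:
        if config.simulate:
            sim_cfg = SimulationConfig(
                **{**config.simulation, "rng_seed": stage_seed(config.seed, "simulate")}
            )
            dataset, truth = simulate_cohort(sim_cfg)
            _write_tsv(
                dataset.counts.to_dataframe().rename_axis("sample_id"),
                out / "counts.tsv",
                stamp,
                index=True,
            )
            _write_tsv(dataset.metadata, out / "metadata.tsv", stamp)
            truth.to_json(str(out / "ground_truth.json"))
        else:
            counts = read_count_table(config.counts_path, config.counts_format)
            metadata = read_metadata(config.metadata_path)
            dataset = align_dataset(counts, metadata)
            manifest["input_hashes"] = {
                "counts": _hash_file(config.counts_path),
                "metadata": _hash_file(config.metadata_path),
            }
    except Exception as exc:
        raise PipelineStageError("simulate", exc) from exc
    finish("simulate", t0)

    # --- stage: diversity ----------------------------------------------------
    t0 = time.time()
    try:
        profiles = diversity_profiles(
            dataset,
            disease_genera=config.smdi_disease,
            health_genera=config.smdi_health,
            pseudocount=config.smdi_pseudocount,
        )
        _write_tsv(profiles, out / "profiles.tsv", stamp)
    except Exception as exc:
        raise PipelineStageError("diversity", exc) from exc
    finish("diversity", t0)

    # --- stage: screen -------------------------------------------------------
    t0 = time.time()
    try:
        joined = dataset.metadata.merge(profiles, on="sample_id")
        screen = association_screen(joined, fdr_family=config.fdr_family)
        _write_tsv(screen, out / "screen.tsv", stamp)
    except Exception as exc:
        raise PipelineStageError("screen", exc) from exc
    finish("screen", t0)

    # --- stage: topics -------------------------------------------------------
    t0 = time.time()
    try:
        tseed = stage_seed(config.seed, "topics")
        baseline = dataset.baseline()
        grid = HyperGrid(**{k: tuple(v) for k, v in config.grid.items()}) if config.grid \
            else HyperGrid()
        y = baseline.metadata["oleary_pct"].to_numpy(dtype=float)
        cv_results = cv_evaluate(
            baseline.counts,
            y,
            baseline.metadata["subject_id"].to_numpy(),
            grid,
            CVSpec(n_folds=config.cv_folds, seed=tseed),
            lda_max_iter=config.lda_max_iter,
            base_seed=tseed,
        )
        _write_tsv(cv_results, out / "cv_results.tsv", stamp)
        chosen = select_best(cv_results)
        candidate, model = extract_candidate_topic(
            baseline.counts, y, chosen, seed=tseed, lda_max_iter=config.lda_max_iter
        )
        _write_tsv(
            pd.DataFrame(model.phi, columns=model.genus_ids).rename_axis("topic"),
            out / "phi.tsv",
            stamp,
            index=True,
        )
        shares = topic_share_all_visits(model, dataset, candidate.topic_index)
        _write_tsv(
            shares.rename_axis("sample_id").reset_index(), out / "topic_shares.tsv", stamp
        )
        cand_obj = {
            "config_hash": chash,
            "seed": config.seed,
            "topic_index": candidate.topic_index,
            "importance": candidate.importance,
            "hyperparameters": candidate.hyperparameters,
            "contributions": [
                {"genus": g, "contribution": float(c)}
                for g, c in candidate.ranked_contributions().itertuples(index=False)
            ],
        }
        with open(out / "candidate_topic.json", "w", encoding="utf-8") as fh:
            json.dump(cand_obj, fh, indent=1)
    except Exception as exc:
        raise PipelineStageError("topics", exc) from exc
    finish("topics", t0)

    # --- stage: associate ----------------------------------------------------
    t0 = time.time()
    try:
        frame = association_frame(
            shares, dataset.metadata, per_visit=config.per_visit_median
        )
        results = stratified_analysis(frame)
        _write_tsv(mixed_results_table(results), out / "association.tsv", stamp)
        coef_tables = []
        for stratum, res in results.items():
            if res is not None:
                ct = res.coefficients.copy()
                ct.insert(0, "stratum", stratum)
                coef_tables.append(ct)
        if coef_tables:
            _write_tsv(pd.concat(coef_tables), out / "coefficients.tsv", stamp)
    except Exception as exc:
        raise PipelineStageError("associate", exc) from exc
    finish("associate", t0)
    logger.info("pipeline complete: %s", out)
    return out
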