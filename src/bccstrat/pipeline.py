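"""End-to-end orchestration of the seven-step analysis.

Steps: (1) TICI text-mined outcome labels, (2) univariate sex screen with
FDR control, (3) collinearity clustering with sex-concordance model
selection, (4) pooled sPLS-DA with repeated CV, (5) sex-stratified models
with stability selection, (6) etiology rerun and consistency mapping,
(7) covariate-adjusted logistic models.  A manifest records the config,
seed, row counts at every filter and SHA-256 hashes of every output so a
run can be regenerated and verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjusted import DEFAULT_COVARIATES, adjusted_effects_table
from .clustering import make_representatives, partition_to_frame, select_k
from .config import ConfigError
from .consistency import (
    build_consistency_map,
    consistency_report,
    etiology_stability,
)
from .screen import screen_cohort
from .simulate import read_cohort_csv, read_reports_jsonl
from .tici import extract_corpus
from .validation import DEFAULT_KEEPX_GRID, stratified_comparison

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort_csv: str
    outdir: str
    seed: int
    reports_jsonl: str | None = None
    labels_csv: str | None = None
    folds: int = 5
    repeats: int = 100
    threshold: float = 0.9
    k_grid: tuple[int, int] = (40, 70)
    keepX_grid: tuple[int, ...] = DEFAULT_KEEPX_GRID
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    etiology_mode: str = "binary"
    steps: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6, 7])

    def validate(self) -> None:
        if not Path(self.cohort_csv).exists():
            raise ConfigError(f"cohort file not found: {self.cohort_csv}")
        for p in (self.reports_jsonl, self.labels_csv):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        if self.seed is None:
            raise ConfigError("a seed is required")
        if self.etiology_mode not in ("binary", "three_class"):
            raise ConfigError(f"unknown etiology mode {self.etiology_mode!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "k_grid" in raw:
            raw["k_grid"] = tuple(raw["k_grid"])
        if "keepX_grid" in raw:
            raw["keepX_grid"] = tuple(raw["keepX_grid"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    """Named substream: derive a stage seed from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def eligibility_filter(
    records: pd.DataFrame, window_minutes: int = 60
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study's eligibility rules to an intake table.

    Expects columns ``evt_performed`` (0/1), ``arrival_time``, ``bcc_time``,
    ``evt_start_time`` (parseable timestamps).  Excludes, in order: EVT not
    performed; unparseable timestamps; blood panel drawn at or after EVT
    start; no panel within ``window_minutes`` of arrival (inclusive bound).
    Returns the retained rows and a tally per exclusion reason; tallies plus
    retained rows always sum to the input row count.
    """
    reasons = {"evt_not_performed": 0, "bad_timestamp": 0, "post_evt_sample": 0,
               "no_bcc_60min": 0}
    keep = np.ones(len(records), dtype=bool)
    arr = pd.to_datetime(records["arrival_time"], errors="coerce")
    bcc = pd.to_datetime(records["bcc_time"], errors="coerce")
    evt = pd.to_datetime(records["evt_start_time"], errors="coerce")
    for i in range(len(records)):
        if not bool(records["evt_performed"].iloc[i]):
            reasons["evt_not_performed"] += 1
            keep[i] = False
        elif pd.isna(arr.iloc[i]) or pd.isna(bcc.iloc[i]) or pd.isna(evt.iloc[i]):
            reasons["bad_timestamp"] += 1
            keep[i] = False
            logger.warning("row %d excluded: unparseable timestamp", i)
        elif bcc.iloc[i] >= evt.iloc[i]:
            reasons["post_evt_sample"] += 1
            keep[i] = False
        else:
            delta = (bcc.iloc[i] - arr.iloc[i]).total_seconds() / 60.0
            if delta < 0 or delta > window_minutes:
                reasons["no_bcc_60min"] += 1
                keep[i] = False
    return records.loc[keep].reset_index(drop=True), reasons


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured steps and write all artifacts plus a manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort_csv(config.cohort_csv)
    bcc_cols = [c for c in cohort.columns if c.startswith("bcc_")]
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_input_rows": int(len(cohort)),
        "n_bcc": len(bcc_cols),
        "outputs": {},
        "row_counts": {},
    }
    steps = set(config.steps)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    # Step 1: outcome labels from report text
    if 1 in steps and config.reports_jsonl is not None:
        labels = extract_corpus(read_reports_jsonl(config.reports_jsonl))
        save(labels, "tici_labels.csv")
        auto = labels[labels["outcome"] != "needs_manual"][["patient_id", "outcome"]]
        cohort = cohort.merge(
            auto.rename(columns={"outcome": "_mined"}), on="patient_id", how="left"
        )
        if "recanalization" in cohort.columns:
            # mined labels take precedence; needs_manual rows keep the
            # existing (manually adjudicated) label
            cohort["recanalization"] = cohort["_mined"].fillna(cohort["recanalization"])
        else:
            cohort["recanalization"] = cohort["_mined"]
        n0 = len(cohort)
        cohort = cohort.dropna(subset=["recanalization"]).reset_index(drop=True)
        manifest["row_counts"]["dropped_unlabeled"] = n0 - len(cohort)
        cohort = cohort.drop(columns=["_mined"])
    if "recanalization" not in cohort.columns:
        raise ConfigError("no recanalization labels available (provide reports or a labeled cohort)")
    manifest["row_counts"]["analyzed"] = int(len(cohort))

    # Step 2: univariate sex screen
    if 2 in steps:
        screen = screen_cohort(cohort, bcc_cols)
        save(screen, "sex_screen.csv")
        manifest["n_sex_different"] = int(screen["significant"].sum())

    # Step 3: collinearity clustering
    if steps & {3, 4, 5, 6, 7}:
        X = cohort[bcc_cols]
        lo, hi = config.k_grid
        model = select_k(X, cohort["sex"].to_numpy(), range(lo, hi + 1))
        save(partition_to_frame(model.partition), "clusters.csv")
        save(model.representatives, "representatives.csv")
        manifest["k_chosen"] = model.k
        manifest["cluster_concordance_rand"] = model.concordance
        manifest["cluster_concordance_ari"] = model.concordance_adjusted

    # Steps 4-5: pooled + stratified sPLS-DA with stability selection
    if steps & {4, 5, 6, 7}:
        comp = stratified_comparison(
            X,
            cohort["recanalization"].to_numpy(),
            cohort["sex"].to_numpy(),
            partition=model.partition,
            K=config.folds,
            R=config.repeats,
            seed=_stage_seed(config.seed, "cv"),
            keepX_grid=config.keepX_grid,
            threshold=config.threshold,
        )
        err = pd.DataFrame(
            {name: res.error_rates for name, res in comp.results.items()}
        )
        save(err, "cv_error_rates.csv")
        freq_rows = []
        for name, res in comp.results.items():
            for cl, fq in res.selection_frequency.items():
                freq_rows.append({"model": name, "cluster": cl, "frequency": fq})
        save(pd.DataFrame(freq_rows), "selection_frequencies.csv")
        manifest["cv"] = {
            name: {"mean_error": res.mean_error, "sd_error": res.sd_error,
                   "stable_set": sorted(res.stable_set)}
            for name, res in comp.results.items()
        }
        manifest["welch"] = {k: list(v) for k, v in comp.welch.items()}

    # Step 6: etiology rerun + consistency map
    if 6 in steps:
        if "etiology" not in cohort.columns:
            raise ConfigError("step 6 requires an etiology column")
        recan_stable = {s: comp.results[s].stable_set for s in ("F", "M")}
        et_results = etiology_stability(
            X,
            cohort["etiology"].to_numpy(),
            cohort["sex"].to_numpy(),
            model.partition,
            recan_stable,
            mode=config.etiology_mode,
            K=config.folds,
            R=config.repeats,
            seed=_stage_seed(config.seed, "etiology"),
            keepX_grid=config.keepX_grid,
            threshold=config.threshold,
        )
        reps_by_sex = {
            s: model.representatives.loc[(cohort["sex"] == s).to_numpy()]
            for s in ("F", "M")
        }
        cmap = build_consistency_map(
            {s: comp.results[s] for s in ("F", "M")},
            et_results,
            reps_by_sex=reps_by_sex,
            recan_labels={
                s: cohort.loc[cohort["sex"] == s, "recanalization"].to_numpy()
                for s in ("F", "M")
            },
            etiology_labels={
                s: cohort.loc[cohort["sex"] == s, "etiology"].to_numpy()
                for s in ("F", "M")
            },
        )
        cpath = outdir / "consistency.json"
        cpath.write_text(
            json.dumps(
                {
                    "recan_stable": {s: sorted(v) for s, v in cmap.recan_stable.items()},
                    "etiology_stable": {s: sorted(v) for s, v in cmap.etiology_stable.items()},
                    "both_stable": {s: sorted(v) for s, v in cmap.both_stable.items()},
                    "shared_across_sexes": {s: sorted(v) for s, v in cmap.shared_across_sexes.items()},
                    "direction": cmap.direction,
                },
                indent=1,
            )
        )
        written.append(cpath)
        rpath = outdir / "consistency_report.md"
        rpath.write_text(consistency_report(cmap))
        written.append(rpath)

    # Step 7: covariate-adjusted models per sex
    if 7 in steps:
        for s in ("F", "M"):
            stable = comp.results[s].stable_set
            if not stable:
                continue
            mask = (cohort["sex"] == s).to_numpy()
            reps_s, _, _ = make_representatives(
                cohort.loc[mask, bcc_cols], model.partition
            )
            covs = [c for c in config.covariates if c in cohort.columns]
            table = adjusted_effects_table(
                cohort.loc[mask].reset_index(drop=True),
                reps_s.reset_index(drop=True),
                stable,
                covariates=covs,
            )
            save(table, f"adjusted_effects_{s}.csv")

    for path in written:
        manifest["outputs"][path.name] = _sha256(path)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
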