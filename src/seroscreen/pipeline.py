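"""End-to-end orchestration: simulate -> screen -> normalize -> call ->
profile -> associate -> sensitivity, with a manifest for exact re-runs.

All stage hand-offs are plain files (CSV/JSON) under the output directory;
every random draw derives from the single config seed, so the same config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import SelectionCriteria, records_frame, select_associations, \
    characterize_positives
from .counts import (count_distribution, characterize_strata, cluster_profiles,
                     dendrogram_json, stratify_counts)
from .cutoffs import call_seropositive, detect_cutoffs
from .normalize import score_matrix
from .planar import select_antigens
from .sensitivity import BaselineRun, run_sensitivity
from .synthetic import CYTOKINES, CLINICAL_VARS, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "results/run"
    seed: int = 0
    simulate: bool = True
    #: used when simulate is False
    mfi_path: str | None = None
    clinical_path: str | None = None
    #: optional planar pools CSV (pools x antigens); screened if present
    planar_path: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    low_pct: float = 5.0
    high_pct: float = 95.0
    strata_variables: list[str] = field(
        default_factory=lambda: list(CLINICAL_VARS) + list(CYTOKINES))
    scaled_mad: bool = True
    run_sensitivity: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        criteria = SelectionCriteria(**raw.pop("criteria", {}))
        return cls(cohort=cohort, criteria=criteria, **raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Stage failures propagate with the failing stage named; outputs of the
    stages already completed remain on disk.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": _params(config), "stages": {}}
    stage = "input"
    try:
        if config.simulate:
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            cohort = generate_cohort(cohort_cfg)
            cohort.write(out / "simulated")
            mfi, clinical = cohort.mfi, cohort.clinical
            symptoms = cohort.symptom_columns
            manifest["stages"]["simulate"] = {
                "n_individuals": int(mfi.shape[0]),
                "n_antigens": int(mfi.shape[1]),
                "planted_pairs": [[a, s] for a, s in cohort.planted_pairs]}
        else:
            for p, what in ((config.mfi_path, "MFI"),
                            (config.clinical_path, "clinical")):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{what} file not found: {p}")
            mfi = pd.read_csv(config.mfi_path, index_col=0)
            clinical = pd.read_csv(config.clinical_path, index_col=0)
            symptoms = [c for c in clinical.columns if c.startswith("sym_")]

        if config.planar_path is not None:
            stage = "planar_screen"
            pools = pd.read_csv(config.planar_path, index_col=0)
            screen = select_antigens(pools)
            screen.to_frame().to_csv(out / "planar_panel.csv", index=False)
            manifest["stages"]["planar_screen"] = {
                "n_selected": len(screen.union),
                "unique_fraction": screen.unique_fraction}

        stage = "normalize"
        sm = score_matrix(mfi, scaled_mad=config.scaled_mad)
        sm.xmad.to_csv(out / "xmad.csv")
        sm.scores.to_csv(out / "scores.csv")

        stage = "call"
        cutoffs = detect_cutoffs(sm)
        calls = call_seropositive(sm, cutoffs)
        calls.cutoff_frame().to_csv(out / "cutoffs.csv", index=False)
        calls.calls.to_csv(out / "calls.csv")
        manifest["stages"]["call"] = {
            "n_detected": int(len(calls.detected)),
            "sparsity_detected": calls.sparsity_detected()}

        stage = "profile"
        summary = count_distribution(calls)
        calls.counts.rename("count").to_csv(out / "counts.csv")
        strata = stratify_counts(calls.counts, config.low_pct, config.high_pct)
        pd.DataFrame({"individual_id": strata.low_ids + strata.high_ids,
                      "stratum": (["low"] * len(strata.low_ids) +
                                  ["high"] * len(strata.high_ids))}
                     ).to_csv(out / "strata.csv", index=False)
        strata_tests = characterize_strata(
            strata, clinical, [v for v in config.strata_variables
                               if v in clinical.columns])
        for name, frame in strata_tests.items():
            frame.to_csv(out / f"strata_{name}_tests.csv", index=False)
        if calls.calls.shape[0] >= 2:
            Z, order = cluster_profiles(calls.calls)
            (out / "dendrogram.json").write_text(
                json.dumps(dendrogram_json(Z, list(calls.calls.index))))
        manifest["stages"]["profile"] = {
            "count_summary": summary.per_individual,
            "antigen_summary": summary.per_antigen,
            "low_threshold": strata.low_threshold,
            "high_threshold": strata.high_threshold,
            "n_low": len(strata.low_ids), "n_high": len(strata.high_ids)}

        stage = "associate"
        records = select_associations(calls, clinical, symptoms,
                                      config.criteria)
        records_frame(records).to_csv(out / "associations.csv", index=False)
        targeted = [v for v in config.strata_variables if v in clinical.columns]
        for r in records:
            characterize_positives(r, calls, clinical, targeted).to_csv(
                out / f"characterize_{r.antigen_id}.csv", index=False)
        manifest["stages"]["associate"] = {
            "n_selected": len(records),
            "pairs": [[str(r.antigen_id), str(r.symptom_id)] for r in records]}

        if config.run_sensitivity:
            stage = "sensitivity"
            baseline = BaselineRun(score_matrix=sm, cutoffs=cutoffs,
                                   calls=calls, clinical=clinical,
                                   symptoms=symptoms, criteria=config.criteria,
                                   low_pct=config.low_pct,
                                   high_pct=config.high_pct,
                                   strata_variables=targeted, records=records)
            report = run_sensitivity(baseline)
            report.table.to_csv(out / "sensitivity.csv", index=False)
            (out / "sensitivity_summary.json").write_text(
                json.dumps(report.summary()))
            manifest["stages"]["sensitivity"] = report.summary()
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def _params(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))
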