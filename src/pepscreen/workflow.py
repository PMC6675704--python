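"""Configuration-driven orchestration of the full screening pipeline.

Stages run in order: tiling (panel table), signal (cohort SNR + QC),
serostats (cut-offs, calls, case-control comparison, coverage and
trajectories), association (serology vs IHC), and survival (KM, log-rank,
univariable and forward-selected Cox).  Every output table is a TSV
re-parseable by the package's own readers, and a JSON run manifest records
every parameter, the seed and per-stage counts.  A failing stage aborts the
run with the stage name; an ``_INCOMPLETE`` marker is left in the output
directory so partial output is never mistaken for a finished run.
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

from . import array_signal, association, serostats, survival, synthetic_data, tiling
from .panels import mgmt_panel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

CONFIG_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults mirror the module defaults."""

    out_dir: str = "pepscreen_out"
    seed: int = 0
    # input study (layout.tsv, manifest.csv, arrays/, optional clinical.csv);
    # alternatively simulate a study first
    data_dir: str | None = None
    simulate: str | None = None  # "default" | "study_shape"
    # tiling
    antigen_fasta: str | None = None
    antigen_id: str | None = None
    tile_length: int = 20
    offset: int = 10
    # signal QC
    min_pos_snr: float = 2.0
    max_neg_snr: float = 1.0
    # serostats
    case_group: str = "glioma"
    control_group: str = "healthy"
    cutoff_mode: str = "observed"  # or "grid"
    grid_step: float = 0.1
    min_cutoff: float | None = 2.0  # candidate floor for the cut-off search
    bonferroni_m: int | None = None
    top_alpha: float = 0.05
    top_k: int = 5
    # survival
    tie_method: str = "breslow"
    entry_p: float = 0.05
    schema_version: int = CONFIG_SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc

        return wrapper

    return decorate


@_stage("tiling")
def _run_tiling(config: PipelineConfig, out: Path, counts: dict) -> list[str]:
    if config.antigen_fasta:
        protein = tiling.read_fasta(config.antigen_fasta, config.antigen_id)
        tiles = tiling.tile_protein(protein, config.tile_length, config.offset)
    else:
        tiles = mgmt_panel()
    tiling.write_tiles_tsv(tiles, out / "panel.tsv")
    counts["tiles"] = len(tiles)
    return [t.name for t in tiles]


@_stage("signal")
def _run_signal(config: PipelineConfig, out: Path, data_dir: Path, counts: dict):
    layout = array_signal.parse_layout(data_dir / "layout.tsv")
    profiles, qc_report = array_signal.load_cohort(
        data_dir / "manifest.csv",
        layout,
        data_dir=data_dir / "arrays",
        min_pos_snr=config.min_pos_snr,
        max_neg_snr=config.max_neg_snr,
    )
    long = array_signal.profiles_to_long(profiles)
    long.to_csv(out / "snr_long.tsv", sep="\t", index=False)
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    counts["arrays"] = len(qc_report)
    counts["arrays_failed_qc"] = int((~qc_report["pass"]).sum()) if len(qc_report) else 0
    counts["profiles"] = len(profiles)
    counts["profiles_missing"] = sum(p.missing for p in profiles)
    return profiles


@_stage("serostats")
def _run_serostats(config: PipelineConfig, out: Path, profiles, counts: dict):
    long = array_signal.profiles_to_long(profiles)
    pre = long.loc[long["timepoint"] == "preoperative"]
    cutoffs = serostats.optimize_cutoffs(
        pre,
        case_group=config.case_group,
        control_group=config.control_group,
        grid_step=config.grid_step if config.cutoff_mode == "grid" else None,
        min_cutoff=config.min_cutoff,
    )
    pd.DataFrame(
        [
            {
                "peptide": c.peptide,
                "cutoff": c.cutoff,
                "max_difference": c.max_difference,
                "candidates_evaluated": c.candidates_evaluated,
            }
            for c in cutoffs.values()
        ]
    ).to_csv(out / "cutoffs.tsv", sep="\t", index=False)
    calls = serostats.classify_cohort(profiles, cutoffs)
    calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    pre_calls = calls.loc[calls["timepoint"] == "preoperative"]
    comparison = serostats.compare_groups(
        pre_calls,
        case_group=config.case_group,
        control_group=config.control_group,
        m=config.bonferroni_m,
        cutoffs=cutoffs,
    )
    comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
    serostats.render_comparison(comparison).to_csv(
        out / "comparison_rendered.tsv", sep="\t", index=False
    )
    cov, traj = serostats.longitudinal_coverage(calls)
    cov.to_csv(out / "coverage_by_timepoint.tsv", sep="\t", index=False)
    traj.to_csv(out / "trajectories.tsv", sep="\t", index=False)
    top = serostats.select_top_peptides(comparison, config.top_alpha, config.top_k)
    counts["sera_classified"] = int(calls["serum_id"].nunique())
    counts["peptides_compared"] = len(comparison)
    counts["top_peptides"] = top
    return cutoffs, calls, comparison, top


@_stage("association")
def _run_association(out: Path, calls: pd.DataFrame, clinical: pd.DataFrame, top: list[str], counts: dict):
    ihc = clinical.dropna(subset=["mgmt_ihc_pct"])
    if len(ihc) < 3:
        counts["association"] = "skipped (fewer than 3 IHC subjects)"
        return None
    pre = calls.loc[
        (calls["timepoint"] == "preoperative") & (calls["peptide"].isin(top))
    ]
    sero_any = pre.groupby("serum_id")["positive"].any()
    merged = ihc.assign(
        seropositive=ihc["subject_id"].map(sero_any).astype("boolean")
    ).dropna(subset=["seropositive"])
    if len(merged) < 3:
        counts["association"] = "skipped (fewer than 3 subjects with both assays)"
        return None
    expression = np.array(
        [
            association.ihc_call(p, "MGMT") == "positive"
            for p in merged["mgmt_ihc_pct"]
        ],
        dtype=float,
    )
    seropos = merged["seropositive"].to_numpy(dtype=float)
    try:
        result = association.spearman_association(seropos, expression)
    except ValueError as exc:
        counts["association"] = f"skipped ({exc})"
        return None
    payload = {
        "r": result.r,
        "p_value": result.p_value,
        "n": result.n,
        "table_a_b_c_d": list(result.table) if result.table else None,
        "p_method": result.p_method,
        "peptides_pooled": top,
    }
    (out / "association.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    counts["association_n"] = result.n
    return result


@_stage("survival")
def _run_survival(
    config: PipelineConfig,
    out: Path,
    calls: pd.DataFrame,
    clinical: pd.DataFrame,
    top: list[str],
    counts: dict,
):
    if "rfs_days" not in clinical.columns:
        counts["survival"] = "skipped (no RFS columns in clinical table)"
        return None
    peptide = top[0] if top else sorted(calls["peptide"].unique())[0]
    pre = calls.loc[
        (calls["timepoint"] == "preoperative") & (calls["peptide"] == peptide)
    ].set_index("serum_id")
    frame = clinical.dropna(subset=["rfs_days"]).copy()
    frame["time"] = frame["rfs_days"].astype(float)
    frame["event"] = frame["event"].astype(int)
    frame["serostatus"] = frame["subject_id"].map(pre["positive"]).astype("boolean")
    frame = frame.dropna(subset=["serostatus"])
    frame["serostatus"] = frame["serostatus"].astype(float)
    frame["age_65"] = (frame["age_group"] == ">=65").astype(float)
    frame["male"] = (frame["sex"] == "male").astype(float)
    frame["high_grade"] = (frame["grade_group"] == "high").astype(float)
    frame["ki67_high"] = np.array(
        [association.ihc_call(p, "Ki67") == "high" for p in frame["ki67_pct"]],
        dtype=float,
    )
    pos = frame.loc[frame["serostatus"] == 1.0]
    neg = frame.loc[frame["serostatus"] == 0.0]
    for label, sub in (("seropositive", pos), ("seronegative", neg)):
        if sub.empty:
            continue
        curve = survival.km_estimate(sub)
        pd.DataFrame(
            {
                "time": curve.times,
                "survival": curve.survival,
                "n_at_risk": curve.n_at_risk,
                "n_events": curve.n_events,
            }
        ).to_csv(out / f"km_{label}.tsv", sep="\t", index=False)
    payload: dict = {"peptide": peptide, "n": len(frame), "n_events": int(frame["event"].sum())}
    if not pos.empty and not neg.empty:
        stat, p = survival.logrank_test(pos, neg)
        payload["logrank"] = {"statistic": stat, "p_value": p}
    candidates = ["serostatus", "age_65", "male", "high_grade", "ki67_high"]
    usable = [c for c in candidates if frame[c].nunique() > 1]
    uni_rows = []
    for name in usable:
        fit = survival.cox_fit(frame, [name], tie_method=config.tie_method)
        uni_rows.append(fit.summary().iloc[0])
    if uni_rows:
        pd.DataFrame(uni_rows).to_csv(out / "survival_univariable.tsv", sep="\t", index=False)
    selected, final = survival.forward_selection(
        frame, usable, entry_p=config.entry_p, tie_method=config.tie_method
    )
    payload["forward_selected"] = selected
    if final is not None:
        final.summary().to_csv(out / "survival_multivariable.tsv", sep="\t", index=False)
        payload["multivariable"] = {
            "loglik": final.loglik,
            "converged": final.converged,
            "covariates": final.covariates,
        }
    (out / "survival.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    counts["survival_n"] = len(frame)
    counts["survival_selected"] = selected
    return payload


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "_INCOMPLETE"
    marker.write_text("run in progress\n")
    counts: dict = {}
    manifest = {
        "config": {
            **dataclasses.asdict(config),
        },
        "stages": counts,
    }
    if config.simulate is not None:
        presets = {
            "default": synthetic_data.default_config,
            "study_shape": synthetic_data.study_shape_config,
        }
        if config.simulate not in presets:
            raise PipelineError(
                f"stage 'simulate': unknown preset {config.simulate!r}; "
                f"expected one of {sorted(presets)}"
            )
        cohort = synthetic_data.generate_study(presets[config.simulate](seed=config.seed))
        data_dir = out / "data"
        cohort.write(data_dir)
        counts["simulated_arrays"] = len(cohort.arrays)
    else:
        if config.data_dir is None:
            raise PipelineError("stage 'inputs': neither data_dir nor simulate given")
        data_dir = Path(config.data_dir)
    for name in ("layout.tsv", "manifest.csv"):
        if not (data_dir / name).exists():
            raise PipelineError(f"stage 'inputs': missing input file {data_dir / name}")

    _run_tiling(config, out, counts)
    profiles = _run_signal(config, out, data_dir, counts)
    cutoffs, calls, comparison, top = _run_serostats(config, out, profiles, counts)
    clinical_path = data_dir / "clinical.csv"
    if clinical_path.exists():
        clinical = pd.read_csv(clinical_path)
        if "mgmt_ihc_pct" in clinical.columns:
            _run_association(out, calls, clinical, top, counts)
        _run_survival(config, out, calls, clinical, top, counts)
    else:
        counts["association"] = "skipped (no clinical table)"
        counts["survival"] = "skipped (no clinical table)"
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    marker.unlink()
    logger.info("pipeline complete: %s", out)
    return manifest
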