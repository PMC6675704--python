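"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a case-control serological screen: each serum has a
latent true serostatus per panel peptide (Bernoulli with group-specific
prevalence), a latent SNR drawn from a status-specific log-normal mixture
(seronegative median 0.5, seropositive median 6 by default — SNR is a
positive-skewed ratio), and two replicate arrays whose spot intensities are

    intensity = background * (1 + SNR) * (1 + noise),

with per-block background and multiplicative spot noise; blank spots carry
background * (1 + noise), positive controls a high fixed SNR, and the
negative control an SNR of ~0.  Default per-peptide prevalences follow the
published glioma/healthy positive-response rates of the MGMT screen; the
default cohort is 100 cases vs 300 controls, with a ``study_shape`` preset
at the study's 67 vs 311 (52 post-operative, 11 recurrence sera).

Longitudinal extension: day-30 post-operative latent SNR is the
preoperative level times a decay factor (< 1, antigen removed with the
tumor); at recurrence, preoperatively seropositive patients rebound to
about the preoperative level while seronegative patients stay low.

Survival extension: recurrence times are exponential with hazard
``baseline * exp(logHR * serostatus)`` for a designated peptide, with
independent uniform censoring tuned to a target censoring rate, plus
clinical covariates (age group, sex, WHO grade, Ki-67) from configured
marginals and IHC percentages correlated with true serostatus.

Everything is reproducible from the config seed, and all emitted files
parse through the pipeline's own readers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .array_signal import ArrayLayout, default_layout
from .panels import MGMT_PANEL_NAMES, MGMT_TOP_PEPTIDES

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "default_config",
    "study_shape_config",
    "generate_cohort",
    "generate_longitudinal",
    "generate_survival",
    "generate_study",
]

# default per-peptide seropositivity prevalences: the published positive
# response rates of the 20-peptide MGMT screen (glioma / healthy)
DEFAULT_PREVALENCE_CASE: dict[str, float] = {
    "MGMT-01": 0.12, "MGMT-02": 0.45, "MGMT-03": 0.15, "MGMT-04": 0.27,
    "MGMT-05": 0.13, "MGMT-06": 0.04, "MGMT-07": 0.21, "MGMT-08": 0.13,
    "MGMT-09": 0.04, "MGMT-10": 0.13, "MGMT-11": 0.01, "MGMT-12": 0.01,
    "MGMT-13": 0.06, "MGMT-14": 0.03, "MGMT-15": 0.01, "MGMT-16": 0.09,
    "MGMT-17": 0.04, "MGMT-18": 0.24, "MGMT-19": 0.07, "MGMT-20": 0.10,
}
DEFAULT_PREVALENCE_CONTROL: dict[str, float] = {
    "MGMT-01": 0.02, "MGMT-02": 0.06, "MGMT-03": 0.04, "MGMT-04": 0.05,
    "MGMT-05": 0.06, "MGMT-06": 0.00, "MGMT-07": 0.02, "MGMT-08": 0.07,
    "MGMT-09": 0.01, "MGMT-10": 0.01, "MGMT-11": 0.01, "MGMT-12": 0.01,
    "MGMT-13": 0.02, "MGMT-14": 0.01, "MGMT-15": 0.01, "MGMT-16": 0.01,
    "MGMT-17": 0.01, "MGMT-18": 0.05, "MGMT-19": 0.01, "MGMT-20": 0.02,
}

TIMEPOINTS = ("preoperative", "postop_day30", "recurrence")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_case: int = 100
    n_control: int = 300
    panel: tuple[str, ...] = MGMT_PANEL_NAMES
    prevalence_case: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_CASE)
    )
    prevalence_control: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_CONTROL)
    )
    # log-normal SNR mixture (dimensionless)
    snr_neg_median: float = 0.5
    snr_neg_sigma: float = 0.6
    snr_pos_median: float = 6.0
    snr_pos_sigma: float = 0.4
    # spot model (arbitrary intensity units)
    background_mean: float = 100.0
    background_cv: float = 0.10
    spot_cv: float = 0.08
    replicates_per_serum: int = 2
    positive_control_snr: float = 8.0
    negative_control_snr: float = 0.0
    # longitudinal dynamics
    postop_decay: float = 0.3
    recurrence_rebound: float = 1.0
    n_postop: int | None = None  # None -> all cases resampled at day 30
    n_recurrence: int | None = None  # None -> all recurring cases resampled
    # survival model
    baseline_hazard: float = 1.0 / 400.0  # per day
    log_hr_seropositive: float = float(np.log(2.0))
    censoring_rate: float = 0.30
    survival_peptide: str = "MGMT-02"
    # clinical marginals
    n_ihc: int = 21
    p_expression_given_seropositive: float = 4 / 7
    p_expression_given_seronegative: float = 1 / 14

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("cohort sizes must be >= 1")
        for name, prev in (
            ("prevalence_case", self.prevalence_case),
            ("prevalence_control", self.prevalence_control),
        ):
            for pep in self.panel:
                p = prev.get(pep, 0.0)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{pep}] = {p} outside [0, 1]")
        for name in ("snr_neg_sigma", "snr_pos_sigma", "background_mean", "spot_cv"):
            if getattr(self, name) <= 0 and name != "spot_cv":
                raise ValueError(f"{name} must be > 0")
        if self.snr_pos_median <= self.snr_neg_median:
            raise ValueError(
                "seropositive SNR median must exceed the seronegative median "
                "(separable mixture assumed by thresholding)"
            )
        if self.postop_decay <= 0 or self.recurrence_rebound <= 0:
            raise ValueError("longitudinal factors must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must lie in [0, 1]")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default well-separated preset (100 cases vs 300 controls)."""
    return dataclasses.replace(SimulationConfig(seed=seed), **overrides)


def study_shape_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Stylized emulation of the published study shape: 67 glioma vs 311
    healthy sera, 52 post-operative and 11 recurrence samples."""
    cfg = SimulationConfig(seed=seed, n_case=67, n_control=311, n_postop=52, n_recurrence=11)
    return dataclasses.replace(cfg, **overrides)


@dataclass
class SyntheticCohort:
    """Generated study: truth tables plus pipeline-ready tables."""

    config: SimulationConfig
    layout: ArrayLayout
    truth: pd.DataFrame  # serum_id, group, timepoint, peptide, true_status, latent_snr
    arrays: dict[str, pd.DataFrame]  # array_file -> intensity table
    manifest: pd.DataFrame
    clinical: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "arrays").mkdir(parents=True, exist_ok=True)
        self.layout.to_tsv(out / "layout.tsv")
        for name, frame in sorted(self.arrays.items()):
            frame.to_csv(out / "arrays" / name, sep="\t", index=False)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        if self.clinical is not None:
            self.clinical.to_csv(out / "clinical.csv", index=False)
        params = dataclasses.asdict(self.config)
        params["panel"] = list(params["panel"])
        (out / "simulation.json").write_text(
            json.dumps(params, indent=2, sort_keys=True) + "\n"
        )


def _latent_snr(rng: np.random.Generator, status: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    mu = np.where(status, np.log(cfg.snr_pos_median), np.log(cfg.snr_neg_median))
    sigma = np.where(status, cfg.snr_pos_sigma, cfg.snr_neg_sigma)
    return np.exp(rng.normal(mu, sigma))


def _array_table(
    rng: np.random.Generator,
    layout: ArrayLayout,
    snr_by_peptide: dict[str, float],
    cfg: SimulationConfig,
) -> pd.DataFrame:
    spots = layout.spots
    rows = []
    for block, sub in spots.groupby("Block"):
        background = max(
            1e-6, rng.normal(cfg.background_mean, cfg.background_cv * cfg.background_mean)
        )
        for _, spot in sub.iterrows():
            st = spot["SpotType"]
            if st == "peptide":
                snr = snr_by_peptide[spot["ID"]]
            elif st == "positive_control":
                snr = cfg.positive_control_snr
            elif st == "negative_control":
                snr = cfg.negative_control_snr
            else:
                snr = 0.0
            noise = rng.normal(0.0, cfg.spot_cv)
            intensity = max(0.0, background * (1.0 + snr) * (1.0 + noise))
            rows.append(
                {
                    "Block": spot["Block"],
                    "Row": spot["Row"],
                    "Column": spot["Column"],
                    "ID": spot["ID"],
                    "MedianIntensity": round(intensity, 4),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw the preoperative case-control screen (truth + arrays + manifest)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = default_layout(list(config.panel))
    panel = list(config.panel)
    truth_rows = []
    arrays: dict[str, pd.DataFrame] = {}
    manifest_rows = []
    subjects = [(f"case_{i+1:04d}", "glioma") for i in range(config.n_case)] + [
        (f"ctrl_{i+1:04d}", "healthy") for i in range(config.n_control)
    ]
    for serum_id, group in subjects:
        prev = config.prevalence_case if group == "glioma" else config.prevalence_control
        status = np.array([rng.random() < prev.get(p, 0.0) for p in panel])
        latent = _latent_snr(rng, status, config)
        for pep, st, snr in zip(panel, status, latent):
            truth_rows.append(
                {
                    "serum_id": serum_id,
                    "group": group,
                    "timepoint": "preoperative",
                    "peptide": pep,
                    "true_status": bool(st),
                    "latent_snr": snr,
                }
            )
        snr_map = dict(zip(panel, latent))
        for rep in range(1, config.replicates_per_serum + 1):
            fname = f"{serum_id}_preoperative_r{rep}.tsv"
            arrays[fname] = _array_table(rng, layout, snr_map, config)
            manifest_rows.append(
                {
                    "array_file": fname,
                    "serum_id": serum_id,
                    "replicate": rep,
                    "group": group,
                    "timepoint": "preoperative",
                }
            )
    return SyntheticCohort(
        config=config,
        layout=layout,
        truth=pd.DataFrame(truth_rows),
        arrays=arrays,
        manifest=pd.DataFrame(manifest_rows),
    )


def generate_longitudinal(cohort: SyntheticCohort, config: SimulationConfig | None = None) -> SyntheticCohort:
    """Extend a cohort with day-30 post-operative and recurrence samples.

    Day-30 latent SNR = preoperative SNR x ``postop_decay``; at recurrence,
    preoperatively seropositive patients return to ``recurrence_rebound`` x
    the preoperative level while seronegative patients keep the decayed
    level.  Only case sera are resampled.
    """
    cfg = config or cohort.config
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    panel = list(cfg.panel)
    pre = cohort.truth.loc[
        (cohort.truth["timepoint"] == "preoperative") & (cohort.truth["group"] == "glioma")
    ]
    if pre.empty:
        raise ValueError("cohort has no preoperative case sera to extend")
    case_ids = sorted(pre["serum_id"].unique())
    n_postop = len(case_ids) if cfg.n_postop is None else min(cfg.n_postop, len(case_ids))
    postop_ids = list(rng.choice(case_ids, size=n_postop, replace=False))
    n_rec = n_postop if cfg.n_recurrence is None else min(cfg.n_recurrence, n_postop)
    recurrence_ids = list(rng.choice(sorted(postop_ids), size=n_rec, replace=False))

    pre_snr = pre.set_index(["serum_id", "peptide"])
    truth_rows = []
    arrays = dict(cohort.arrays)
    manifest_rows = []

    def _emit(serum_id: str, timepoint: str, latent: np.ndarray, status: np.ndarray) -> None:
        for pep, st, snr in zip(panel, status, latent):
            truth_rows.append(
                {
                    "serum_id": serum_id,
                    "group": "glioma",
                    "timepoint": timepoint,
                    "peptide": pep,
                    "true_status": bool(st),
                    "latent_snr": snr,
                }
            )
        snr_map = dict(zip(panel, latent))
        for rep in range(1, cfg.replicates_per_serum + 1):
            fname = f"{serum_id}_{timepoint}_r{rep}.tsv"
            arrays[fname] = _array_table(rng, cohort.layout, snr_map, cfg)
            manifest_rows.append(
                {
                    "array_file": fname,
                    "serum_id": serum_id,
                    "replicate": rep,
                    "group": "glioma",
                    "timepoint": timepoint,
                }
            )

    for serum_id in postop_ids:
        base = pre_snr.loc[serum_id].reindex(panel)
        status = base["true_status"].to_numpy(dtype=bool)
        latent30 = base["latent_snr"].to_numpy(dtype=float) * cfg.postop_decay
        _emit(serum_id, "postop_day30", latent30, status)
        if serum_id in recurrence_ids:
            pre_latent = base["latent_snr"].to_numpy(dtype=float)
            latent_rec = np.where(
                status, pre_latent * cfg.recurrence_rebound, pre_latent * cfg.postop_decay
            )
            _emit(serum_id, "recurrence", latent_rec, status)

    truth = pd.concat([cohort.truth, pd.DataFrame(truth_rows)], ignore_index=True)
    manifest = pd.concat([cohort.manifest, pd.DataFrame(manifest_rows)], ignore_index=True)
    return SyntheticCohort(
        config=cfg,
        layout=cohort.layout,
        truth=truth,
        arrays=arrays,
        manifest=manifest,
        clinical=cohort.clinical,
    )


def _censoring_horizon(hazards: np.ndarray, target_rate: float) -> float:
    """Horizon m of Uniform(0, m) censoring giving the target censoring rate.

    For T ~ Exp(h) and C ~ U(0, m) independently,
    P(censored) = P(T > C) = mean over subjects of (1 - exp(-h m)) / (h m).
    """
    if target_rate <= 0.0:
        return float("inf")

    def rate(m: float) -> float:
        hm = hazards * m
        return float(np.mean((1.0 - np.exp(-hm)) / hm))

    lo, hi = 1e-6, 1e8
    return float(optimize.brentq(lambda m: rate(m) - target_rate, lo, hi))


def generate_survival(
    cohort: SyntheticCohort, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Attach RFS outcomes and clinical covariates to the case sera.

    Event times are exponential with hazard
    ``baseline_hazard * exp(log_hr_seropositive * serostatus)`` where
    serostatus is the true preoperative status for ``survival_peptide``;
    censoring is independent Uniform(0, m) with m tuned to the target
    censoring rate.  With ``censoring_rate == 1`` every record is censored.
    The resulting clinical table is stored on the cohort and returned.
    """
    cfg = config or cohort.config
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    pre = cohort.truth.loc[
        (cohort.truth["timepoint"] == "preoperative")
        & (cohort.truth["group"] == "glioma")
        & (cohort.truth["peptide"] == cfg.survival_peptide)
    ]
    if pre.empty:
        raise ValueError(f"no preoperative truth for peptide {cfg.survival_peptide!r}")
    top = [p for p in MGMT_TOP_PEPTIDES if p in cfg.panel] or list(cfg.panel[:1])
    any_top = (
        cohort.truth.loc[
            (cohort.truth["timepoint"] == "preoperative")
            & (cohort.truth["group"] == "glioma")
            & (cohort.truth["peptide"].isin(top))
        ]
        .groupby("serum_id")["true_status"]
        .any()
    )
    sero = pre.set_index("serum_id")["true_status"].astype(int)
    ids = sorted(sero.index)
    n = len(ids)
    hazards = cfg.baseline_hazard * np.exp(
        cfg.log_hr_seropositive * sero.loc[ids].to_numpy(dtype=float)
    )
    event_time = rng.exponential(1.0 / hazards)
    if cfg.censoring_rate >= 1.0:
        time = np.maximum(1.0, np.round(rng.uniform(30.0, 720.0, size=n)))
        event = np.zeros(n, dtype=int)
    elif cfg.censoring_rate <= 0.0:
        time = np.maximum(1.0, np.round(event_time))
        event = np.ones(n, dtype=int)
    else:
        m = _censoring_horizon(hazards, cfg.censoring_rate)
        censor_time = rng.uniform(0.0, m, size=n)
        time = np.maximum(1.0, np.round(np.minimum(event_time, censor_time)))
        event = (event_time <= censor_time).astype(int)

    age = np.clip(np.round(rng.normal(52.0, 10.0, size=n)), 19, 80)
    sex = rng.choice(["male", "female"], size=n, p=[0.55, 0.45])
    grade = rng.choice(["II", "III", "IV"], size=n, p=[0.24, 0.49, 0.27])
    ki67 = np.clip(np.round(rng.uniform(0.0, 60.0, size=n), 1), 0.0, 100.0)
    # IHC MGMT expression correlated with pooled (any-of-top-peptide) serostatus
    sero_any = any_top.reindex(ids).fillna(False).to_numpy(dtype=bool)
    p_expr = np.where(
        sero_any, cfg.p_expression_given_seropositive, cfg.p_expression_given_seronegative
    )
    expressed = rng.random(n) < p_expr
    mgmt_pct = np.where(
        expressed,
        np.round(rng.uniform(15.0, 80.0, size=n), 1),
        np.round(rng.uniform(0.0, 10.0, size=n), 1),
    )
    has_ihc = np.zeros(n, dtype=bool)
    has_ihc[: min(cfg.n_ihc, n)] = True
    has_ihc = rng.permutation(has_ihc)

    surgery = pd.Timestamp("2012-01-01") + pd.to_timedelta(
        rng.integers(0, 365 * 4, size=n), unit="D"
    )
    end = surgery + pd.to_timedelta(time.astype(int), unit="D")
    clinical = pd.DataFrame(
        {
            "subject_id": ids,
            "group": "glioma",
            "age": age.astype(int),
            "age_group": np.where(age >= 65, ">=65", "<65"),
            "sex": sex,
            "who_grade": grade,
            "grade_group": np.where(np.isin(grade, ["III", "IV"]), "high", "low"),
            "ki67_pct": ki67,
            "mgmt_ihc_pct": np.where(has_ihc, mgmt_pct, np.nan),
            "surgery_date": surgery.strftime("%Y-%m-%d"),
            "recurrence_date": np.where(event == 1, end.strftime("%Y-%m-%d"), ""),
            "last_followup_date": end.strftime("%Y-%m-%d"),
            "rfs_days": time.astype(int),
            "event": event,
        }
    )
    cohort.clinical = clinical
    return clinical


def generate_study(config: SimulationConfig) -> SyntheticCohort:
    """Full study: preoperative screen + longitudinal sampling + RFS outcomes."""
    cohort = generate_cohort(config)
    cohort = generate_longitudinal(cohort, config)
    generate_survival(cohort, config)
    return cohort
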