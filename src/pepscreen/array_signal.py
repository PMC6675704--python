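"""Microarray layout, spot intensities, SNR computation and replicate aggregation.

The screening arrays are printed as square subarray blocks (9x9 by default)
containing one spot per panel peptide plus four positive-control spots
(human IgG), one negative-control spot (printing buffer) and eight blank
spots.  Spot quantification software reports a median chemiluminescence
intensity per spot; this module converts intensities into per-spot
signal-to-noise ratios

    SNR = (signal - background) / background,

where the background is the mean intensity of the blank spots (computed per
block, since blanks are printed within each block), applies control-based QC,
and averages the two replicate arrays per serum into a reactivity profile.

Negative SNR values (signal below background) are retained unclipped so that
downstream thresholding sees the full distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPOT_TYPES = frozenset({"peptide", "positive_control", "negative_control", "blank"})

LAYOUT_COLUMNS = ["Block", "Row", "Column", "ID", "SpotType"]
INTENSITY_COLUMNS = ["Block", "Row", "Column", "ID", "MedianIntensity"]

EXPECTED_BLANKS_PER_BLOCK = 8

__all__ = [
    "SPOT_TYPES",
    "ArrayLayout",
    "ArrayQC",
    "SampleReactivityProfile",
    "parse_layout",
    "default_layout",
    "read_intensities",
    "compute_background",
    "compute_snr",
    "qc_array",
    "quantify_array",
    "aggregate_replicates",
    "load_cohort",
    "profiles_to_long",
]


@dataclass(frozen=True)
class ArrayLayout:
    """Validated spot layout: one row per printed spot.

    ``spots`` has columns Block, Row, Column, ID, SpotType and a unique
    (Block, Row, Column) index.
    """

    spots: pd.DataFrame
    n_rows: int = 9
    n_cols: int = 9

    @property
    def peptides(self) -> list[str]:
        mask = self.spots["SpotType"] == "peptide"
        return sorted(self.spots.loc[mask, "ID"].unique())

    def counts_by_type(self) -> pd.DataFrame:
        """Per-block spot counts of each spot type."""
        return (
            self.spots.groupby(["Block", "SpotType"], observed=True)
            .size()
            .unstack(fill_value=0)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.spots.to_csv(path, sep="\t", index=False)


@dataclass
class ArrayQC:
    """Control-based quality assessment of a single array."""

    array_id: str
    background: float
    positive_control_snr: list[float]
    negative_control_snr: float
    pass_flag: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class SampleReactivityProfile:
    """Per-serum aggregated SNR across QC-passing replicate arrays."""

    serum_id: str
    group: str
    timepoint: str
    snr: dict[str, float]
    n_replicates: int

    @property
    def missing(self) -> bool:
        return self.n_replicates == 0


def _validate_layout_frame(frame: pd.DataFrame, source: str = "layout") -> pd.DataFrame:
    missing = set(LAYOUT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{source}: missing columns {sorted(missing)}")
    if frame.empty:
        raise ValueError(f"{source}: no spots defined")
    bad = frame.loc[~frame["SpotType"].isin(SPOT_TYPES)]
    if not bad.empty:
        row = bad.index[0]
        raise ValueError(
            f"{source}: unknown SpotType {bad['SpotType'].iloc[0]!r} at row {row + 2}"
        )
    dup = frame.duplicated(subset=["Block", "Row", "Column"], keep=False)
    if dup.any():
        b, r, c = frame.loc[dup.idxmax(), ["Block", "Row", "Column"]]
        raise ValueError(f"{source}: duplicate spot coordinate (block {b}, row {r}, col {c})")
    return frame[LAYOUT_COLUMNS].copy()


def parse_layout(
    source: str | Path | pd.DataFrame,
    panel: Sequence[str] | None = None,
    n_rows: int = 9,
    n_cols: int = 9,
) -> ArrayLayout:
    """Read and validate a GAL-like layout TSV (Block, Row, Column, ID, SpotType).

    ``panel``, when given, is the list of valid peptide probe IDs; any peptide
    spot with an ID outside the panel is rejected with its row number.
    """
    if isinstance(source, pd.DataFrame):
        frame, name = source, "layout"
    else:
        frame = pd.read_csv(source, sep="\t")
        name = str(source)
    frame = _validate_layout_frame(frame, name)
    for block, sub in frame.groupby("Block"):
        if len(sub) > n_rows * n_cols:
            raise ValueError(
                f"{name}: block {block} has {len(sub)} spots, more than "
                f"the {n_rows}x{n_cols} grid holds"
            )
        if (sub["Row"].max() > n_rows) or (sub["Column"].max() > n_cols):
            raise ValueError(f"{name}: block {block} has coordinates outside the grid")
    if panel is not None:
        pep = frame.loc[frame["SpotType"] == "peptide"]
        unknown = pep.loc[~pep["ID"].isin(set(panel))]
        if not unknown.empty:
            row = unknown.index[0]
            raise ValueError(
                f"{name}: peptide probe {unknown['ID'].iloc[0]!r} at row "
                f"{row + 2} is not in the panel"
            )
    layout = ArrayLayout(spots=frame.reset_index(drop=True), n_rows=n_rows, n_cols=n_cols)
    logger.info("layout: %d spots in %d block(s)", len(frame), frame["Block"].nunique())
    return layout


def default_layout(
    panel: Sequence[str],
    n_pos_controls: int = 4,
    n_neg_controls: int = 1,
    n_blanks: int = EXPECTED_BLANKS_PER_BLOCK,
    n_rows: int = 9,
    n_cols: int = 9,
    peptide_replicates: int = 1,
) -> ArrayLayout:
    """Build the default single-block template layout.

    Spots are laid out row-major: panel peptides (optionally replicated
    within the block), then positive controls, one negative control, and
    blanks.
    """
    ids = (
        [p for p in panel for _ in range(peptide_replicates)]
        + ["H-IgG"] * n_pos_controls
        + ["buffer"] * n_neg_controls
        + ["blank"] * n_blanks
    )
    types = (
        ["peptide"] * len(panel) * peptide_replicates
        + ["positive_control"] * n_pos_controls
        + ["negative_control"] * n_neg_controls
        + ["blank"] * n_blanks
    )
    if len(ids) > n_rows * n_cols:
        raise ValueError(
            f"{len(ids)} spots do not fit in a {n_rows}x{n_cols} block"
        )
    rows = [1 + i // n_cols for i in range(len(ids))]
    cols = [1 + i % n_cols for i in range(len(ids))]
    frame = pd.DataFrame(
        {"Block": 1, "Row": rows, "Column": cols, "ID": ids, "SpotType": types}
    )
    return ArrayLayout(spots=frame, n_rows=n_rows, n_cols=n_cols)


def read_intensities(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read a GPR-like spot intensity TSV (Block, Row, Column, ID, MedianIntensity)."""
    if isinstance(source, pd.DataFrame):
        frame, name = source.copy(), "intensities"
    else:
        frame = pd.read_csv(source, sep="\t")
        name = str(source)
    missing = set(INTENSITY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{name}: missing columns {sorted(missing)}")
    if (frame["MedianIntensity"] < 0).any():
        raise ValueError(f"{name}: negative intensities present")
    return frame[INTENSITY_COLUMNS]


def compute_background(
    blank_intensities: Sequence[float] | np.ndarray,
    expected_blanks: int = EXPECTED_BLANKS_PER_BLOCK,
) -> float:
    """Mean intensity of the blank spots.

    Logs a warning when the blank count differs from the printed design
    (eight per block); rejects zero blanks and a zero mean, either of which
    would make the SNR undefined.
    """
    values = np.asarray(blank_intensities, dtype=float)
    if values.size == 0:
        raise ValueError("no blank spots: background undefined")
    if values.size != expected_blanks:
        logger.warning(
            "background computed from %d blank spots (design has %d)",
            values.size,
            expected_blanks,
        )
    background = float(values.mean())
    if background <= 0.0:
        raise ValueError(f"background mean is {background}; SNR would be undefined")
    return background


def compute_snr(signal, background):
    """Signal-to-noise ratio: (signal - background) / background.

    Accepts scalars or arrays; the background must be positive.  Values below
    background yield negative SNR and are not clipped.
    """
    bg = np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background must be > 0")
    sig = np.asarray(signal, dtype=float)
    if np.any(sig < 0):
        raise ValueError("signal intensities must be >= 0")
    out = (sig - bg) / bg
    return float(out) if out.ndim == 0 else out


def _merge_spots(layout: ArrayLayout, spots: pd.DataFrame) -> pd.DataFrame:
    merged = layout.spots.merge(
        spots[["Block", "Row", "Column", "MedianIntensity"]],
        on=["Block", "Row", "Column"],
        how="left",
    )
    return merged


def _per_block_background(merged: pd.DataFrame) -> dict[int, float | None]:
    backgrounds: dict[int, float | None] = {}
    for block, sub in merged.groupby("Block"):
        blanks = sub.loc[sub["SpotType"] == "blank", "MedianIntensity"].dropna()
        try:
            backgrounds[block] = compute_background(blanks.to_numpy())
        except ValueError:
            backgrounds[block] = None
    return backgrounds


def qc_array(
    layout: ArrayLayout,
    spots: pd.DataFrame,
    min_pos_snr: float = 2.0,
    max_neg_snr: float = 1.0,
    array_id: str = "",
) -> ArrayQC:
    """Control-based QC: positive controls must reach ``min_pos_snr``, the
    negative control must stay at or below ``max_neg_snr``.

    Missing control or blank spots produce a failing :class:`ArrayQC` with an
    explanatory reason rather than an exception.
    """
    merged = _merge_spots(layout, spots)
    reasons: list[str] = []
    backgrounds = _per_block_background(merged)
    valid_bg = [b for b in backgrounds.values() if b is not None]
    for block, bg in backgrounds.items():
        if bg is None:
            reasons.append(f"block {block}: no usable blank spots for background")
    background = float(np.mean(valid_bg)) if valid_bg else float("nan")

    def _control_snr(spot_type: str) -> list[float]:
        out = []
        sub = merged.loc[merged["SpotType"] == spot_type]
        for _, row in sub.iterrows():
            bg = backgrounds.get(row["Block"])
            if bg is None or pd.isna(row["MedianIntensity"]):
                continue
            out.append(compute_snr(row["MedianIntensity"], bg))
        return out

    pos_snr = _control_snr("positive_control")
    neg_snr = _control_snr("negative_control")
    n_pos_expected = int((layout.spots["SpotType"] == "positive_control").sum())
    n_neg_expected = int((layout.spots["SpotType"] == "negative_control").sum())
    if len(pos_snr) < n_pos_expected:
        reasons.append(
            f"missing control: {n_pos_expected - len(pos_snr)} positive-control spot(s)"
        )
    if len(neg_snr) < n_neg_expected:
        reasons.append("missing control: negative-control spot(s)")
    low = [s for s in pos_snr if s < min_pos_snr]
    if low:
        reasons.append(
            f"positive control SNR below {min_pos_snr}: "
            + ", ".join(f"{s:.3g}" for s in low)
        )
    high = [s for s in neg_snr if s > max_neg_snr]
    if high:
        reasons.append(
            f"negative control SNR above {max_neg_snr}: "
            + ", ".join(f"{s:.3g}" for s in high)
        )
    qc = ArrayQC(
        array_id=array_id,
        background=background,
        positive_control_snr=pos_snr,
        negative_control_snr=neg_snr[0] if neg_snr else float("nan"),
        pass_flag=not reasons,
        reasons=reasons,
    )
    if reasons:
        logger.info("array %s failed QC: %s", array_id or "<unnamed>", "; ".join(reasons))
    return qc


def quantify_array(
    layout: ArrayLayout,
    spots: pd.DataFrame,
    min_pos_snr: float = 2.0,
    max_neg_snr: float = 1.0,
    array_id: str = "",
) -> tuple[pd.Series, ArrayQC]:
    """Per-peptide SNR for one array (mean over that peptide's spots), plus QC.

    The background is local: each spot is corrected with its own block's mean
    blank intensity.
    """
    qc = qc_array(layout, spots, min_pos_snr, max_neg_snr, array_id=array_id)
    merged = _merge_spots(layout, spots)
    backgrounds = _per_block_background(merged)
    pep = merged.loc[merged["SpotType"] == "peptide"].copy()
    bg = pep["Block"].map(backgrounds)
    with np.errstate(invalid="ignore"):
        pep["snr"] = np.where(
            bg.notna() & pep["MedianIntensity"].notna(),
            (pep["MedianIntensity"] - bg) / bg,
            np.nan,
        )
    snr = pep.groupby("ID")["snr"].mean()
    snr.name = array_id or None
    return snr, qc


def aggregate_replicates(
    replicate_snr: Sequence[Mapping[str, float] | pd.Series],
    serum_id: str,
    group: str,
    timepoint: str = "preoperative",
    panel: Sequence[str] | None = None,
) -> SampleReactivityProfile:
    """Average QC-passing replicate arrays into one reactivity profile.

    Each element of ``replicate_snr`` is a per-peptide SNR mapping from one
    passing replicate; the aggregate is the arithmetic mean per peptide over
    the replicates where it was measured.  An empty replicate list yields a
    profile flagged missing (``n_replicates == 0``).
    """
    series = [pd.Series(r, dtype=float) for r in replicate_snr]
    if not series:
        logger.info("serum %s: no QC-passing replicates; profile marked missing", serum_id)
        return SampleReactivityProfile(serum_id, group, timepoint, {}, 0)
    table = pd.concat(series, axis=1)
    if panel is not None:
        table = table.reindex(list(panel))
    agg = table.mean(axis=1, skipna=True)
    return SampleReactivityProfile(
        serum_id=serum_id,
        group=group,
        timepoint=timepoint,
        snr={k: float(v) for k, v in agg.items()},
        n_replicates=len(series),
    )


def load_cohort(
    manifest: str | Path | pd.DataFrame,
    layout: ArrayLayout,
    data_dir: str | Path | None = None,
    arrays: Mapping[str, pd.DataFrame] | None = None,
    min_pos_snr: float = 2.0,
    max_neg_snr: float = 1.0,
) -> tuple[list[SampleReactivityProfile], pd.DataFrame]:
    """Quantify and aggregate a whole cohort of arrays.

    The manifest (CSV or DataFrame) has one row per array with columns
    array_file, serum_id, replicate, group, timepoint.  Intensity tables are
    read from ``data_dir/array_file`` unless supplied in-memory via
    ``arrays`` (keyed by array_file).  Returns the aggregated profiles and a
    per-array QC report.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = {"array_file", "serum_id", "replicate", "group", "timepoint"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest: missing columns {sorted(missing)}")
    profiles: list[SampleReactivityProfile] = []
    qc_rows = []
    n_fail = 0
    for (serum_id, timepoint), sub in manifest.groupby(
        ["serum_id", "timepoint"], sort=True
    ):
        passing: list[pd.Series] = []
        group = str(sub["group"].iloc[0])
        for _, row in sub.sort_values("replicate").iterrows():
            key = str(row["array_file"])
            if arrays is not None and key in arrays:
                spots = read_intensities(arrays[key])
            else:
                if data_dir is None:
                    raise ValueError("data_dir required when arrays are not in-memory")
                path = Path(data_dir) / key
                if not path.exists():
                    raise FileNotFoundError(f"intensity file not found: {path}")
                spots = read_intensities(path)
            snr, qc = quantify_array(
                layout, spots, min_pos_snr, max_neg_snr, array_id=key
            )
            qc_rows.append(
                {
                    "array_file": key,
                    "serum_id": serum_id,
                    "timepoint": timepoint,
                    "background": qc.background,
                    "pass": qc.pass_flag,
                    "reasons": "; ".join(qc.reasons),
                }
            )
            if qc.pass_flag:
                passing.append(snr)
            else:
                n_fail += 1
        profiles.append(
            aggregate_replicates(
                passing,
                serum_id=str(serum_id),
                group=group,
                timepoint=str(timepoint),
                panel=layout.peptides,
            )
        )
    logger.info(
        "cohort: %d arrays quantified, %d failed QC, %d profiles",
        len(qc_rows),
        n_fail,
        len(profiles),
    )
    return profiles, pd.DataFrame(qc_rows)


def profiles_to_long(profiles: Iterable[SampleReactivityProfile]) -> pd.DataFrame:
    """Long-format table: serum_id, group, timepoint, peptide, snr, n_replicates."""
    rows = []
    for p in profiles:
        for peptide, snr in sorted(p.snr.items()):
            rows.append(
                {
                    "serum_id": p.serum_id,
                    "group": p.group,
                    "timepoint": p.timepoint,
                    "peptide": peptide,
                    "snr": snr,
                    "n_replicates": p.n_replicates,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["serum_id", "group", "timepoint", "peptide", "snr", "n_replicates"],
    )
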