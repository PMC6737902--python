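"""Readers and writers for the package's table and image formats.

Tables are comma-separated UTF-8 with a mandatory header row and '.' decimal
separator; undefined probabilities are serialized as ``NA``. Writers are
deterministic given identical inputs (stable row ordering, fixed float
formatting). Image stacks are multi-frame TIFFs with a JSON sidecar carrying
the physical calibration (``pixel_size_um``, ``frame_interval_s``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import LABEL_ALPHABETS, CellTrack, ImageStack, VesselSequenceSet

__all__ = [
    "read_sequences",
    "write_sequences",
    "read_tracks",
    "write_tracks",
    "read_annotations",
    "write_annotations",
    "read_stack",
    "write_stack",
    "write_table",
    "write_run_config",
    "file_checksum",
]

_SEQ_COLUMNS = ["embryo_id", "flank", "position", "label", "tags"]
_TRACK_COLUMNS = [
    "cell_id", "isv_id", "fate", "time_min", "distance_from_da_um",
    "golgi_dx_um", "golgi_dy_um", "phase",
]
_FLOAT_FMT = "%.6f"


class SchemaError(ValueError):
    """A file violates the expected table schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# vessel sequences
# ---------------------------------------------------------------------------

def read_sequences(path: str | Path) -> VesselSequenceSet:
    """Read a vessel sequence CSV (embryo_id, flank, position, label[, tags])."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"tags": str}, keep_default_na=False)
    _require_columns(df, _SEQ_COLUMNS[:4], path)
    allowed = set().union(*LABEL_ALPHABETS)
    bad = df.loc[~df["label"].astype(str).isin(allowed)]
    if len(bad):
        raise SchemaError(
            f"{path}: label {bad.iloc[0]['label']!r} outside {sorted(allowed)} "
            f"at row {bad.index[0] + 2}"  # +2: header + 1-based
        )
    dup = df.duplicated(subset=["embryo_id", "flank", "position"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate (embryo, flank, position) = "
            f"({row['embryo_id']!r}, {row['flank']!r}, {row['position']})"
        )
    try:
        return VesselSequenceSet(df)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_sequences(seqs: VesselSequenceSet, path: str | Path) -> None:
    df = seqs.data.sort_values(
        ["embryo_id", "flank", "position"], kind="stable"
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cell tracks
# ---------------------------------------------------------------------------

def write_tracks(tracks: list[CellTrack], path: str | Path) -> None:
    """Write tracks as long-format CSV, one row per (cell, timepoint)."""
    rows = []
    for tr in tracks:
        for i, t in enumerate(tr.time_min):
            phase = ""
            for ph, (t0, t1) in tr.phase_intervals.items():
                if t0 <= t <= t1:
                    phase = ph
                    break
            rows.append(
                (tr.cell_id, tr.isv_id, tr.fate, t, tr.distance_um[i],
                 tr.golgi_um[i, 0], tr.golgi_um[i, 1], phase)
            )
    pd.DataFrame(rows, columns=_TRACK_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_tracks(path: str | Path) -> list[CellTrack]:
    """Read tracks from CSV; phase intervals are recovered from the per-row
    phase labels as (first, last) sample time of each phase."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(df, _TRACK_COLUMNS, path)
    tracks = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_min")
        spans = []  # (first, last, phase) ordered by first appearance
        for ph, sub in grp.groupby("phase", sort=False):
            if ph == "":
                continue
            spans.append((float(sub["time_min"].min()),
                          float(sub["time_min"].max()), str(ph)))
        spans.sort()
        intervals = {}
        for i, (t0, t1, ph) in enumerate(spans):
            # a boundary sample is written with the earlier phase's label;
            # extend each phase back to the previous phase's last sample so
            # shared boundary timepoints are recovered
            start = spans[i - 1][1] if i > 0 else t0
            intervals[ph] = (start, t1)
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                isv_id=str(grp["isv_id"].iloc[0]),
                fate=str(grp["fate"].iloc[0]),
                time_min=grp["time_min"].to_numpy(float),
                distance_um=grp["distance_from_da_um"].to_numpy(float),
                golgi_um=grp[["golgi_dx_um", "golgi_dy_um"]].to_numpy(float),
                phase_intervals=intervals,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

ANNOTATION_VOCABS: dict[str, set[str]] = {
    "perfused": {"yes", "no"},
    "lumenised": {"yes", "no"},
    "junction": {"unicellular", "multicellular"},
    "regression_category": {
        "full_disconnection", "thin_membrane", "lumen_collapse_reconnect",
        "cell_death", "none",
    },
    "tp1": {"positive", "negative", "high"},
}


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a vessel-level annotation CSV, validating closed vocabularies."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    for col, vocab in ANNOTATION_VOCABS.items():
        if col in df.columns:
            bad = df.loc[~df[col].astype(str).isin(vocab | {""})]
            if len(bad):
                raise SchemaError(
                    f"{path}: {col}={bad.iloc[0][col]!r} outside {sorted(vocab)} "
                    f"at row {bad.index[0] + 2}"
                )
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a multi-frame TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    # frames are time points, not colour channels
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "pixel_size_um": stack.pixel_size_um,
                "frame_interval_s": stack.frame_interval_s,
            },
            indent=2,
        )
    )


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"calibration sidecar {sidecar} not found; write a JSON file with "
            'keys "pixel_size_um" and "frame_interval_s" next to the TIFF'
        )
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(path)
    return ImageStack(
        np.asarray(frames), float(meta["pixel_size_um"]),
        float(meta["frame_interval_s"]),
    )


# ---------------------------------------------------------------------------
# generic outputs, config, logging support
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with NA for undefined values."""
    pd.DataFrame(df).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT
    )


def write_run_config(config: dict, out_dir: str | Path) -> Path:
    """Record the fully resolved run configuration (incl. seed) as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_config.json"
    path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str))
    return path


def file_checksum(path: str | Path) -> str:
    """SHA-256 checksum of a file, for run logs."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
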