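"""Endothelial polarity, per-phase migration speed and annotation summaries.

Polarity is scored from the Golgi-minus-nucleus offset vector expressed in
the local ISV frame (first component along the ISV axis pointing dorsally):
the angle between the offset and the dorsal direction classifies the cell as
dorsal (< 90 - band), ventral (> 90 + band) or unpolarised (within the band
about the perpendicular). The default band half-width of 30 degrees splits
the circle into three equal 120-degree sectors.

Upward speed of a cell within a remodelling phase is (final - initial
nucleus distance from the aorta) / duration, computed in um/min and
reported x1440 as um/day; positive speeds point away from the aorta
(toward the DLAV).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import CellTrack

__all__ = [
    "PolarityCall",
    "classify_polarity",
    "summarize_polarity",
    "upward_speed",
    "summarize_speeds",
    "summarize_fraction",
]

POLARITY_CLASSES = ("dorsal", "ventral", "unpolarised")
MIN_PER_DAY = 1440.0


@dataclass
class PolarityCall:
    cls: str  # 'dorsal' | 'ventral' | 'unpolarised'
    angle_deg: float  # angle to the dorsal axis, in [0, 180]


def classify_polarity(
    golgi_offset: Sequence[float], band_deg: float = 30.0
) -> PolarityCall:
    """Classify a Golgi offset vector against the local dorsal axis.

    ``golgi_offset`` is (dorsal_component, orthogonal_component) in um. A
    zero offset is unpolarised by convention (degenerate input).
    """
    d, o = float(golgi_offset[0]), float(golgi_offset[1])
    norm = np.hypot(d, o)
    if norm == 0.0:
        return PolarityCall("unpolarised", 90.0)
    angle = float(np.degrees(np.arccos(np.clip(d / norm, -1.0, 1.0))))
    if angle < 90.0 - band_deg:
        cls = "dorsal"
    elif angle > 90.0 + band_deg:
        cls = "ventral"
    else:
        cls = "unpolarised"
    return PolarityCall(cls, angle)


def _counts_frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(
        rows, columns=["fate", "phase", "n_dorsal", "n_ventral", "n_unpolarised"]
    )
    df["n_total"] = df[["n_dorsal", "n_ventral", "n_unpolarised"]].sum(axis=1)
    for cls in POLARITY_CLASSES:
        with np.errstate(invalid="ignore"):
            df[f"pct_{cls}"] = 100.0 * df[f"n_{cls}"] / df["n_total"].where(df["n_total"] > 0)
    return df


def summarize_polarity(
    tracks: Iterable[CellTrack] | None = None,
    counts: pd.DataFrame | None = None,
    band_deg: float = 30.0,
    per_cell: bool = False,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Polarity class counts and percentages per (fate, phase).

    Either score ``tracks`` (one call per cell per timepoint within each
    phase, summed over timepoints as in the manual scoring workflow; with
    ``per_cell=True`` a single call per cell per phase from its mean offset
    vector), or pass pre-tabulated ``counts`` with columns
    ``fate, phase, n_dorsal, n_ventral, n_unpolarised`` so published count
    tables are directly summarisable. ``decimals`` optionally rounds the
    percentage columns to the precision used for display; raw counts are
    always retained.
    """
    if (tracks is None) == (counts is None):
        raise ValueError("pass exactly one of tracks or counts")
    if counts is not None:
        rows = [
            (r["fate"], r["phase"], int(r["n_dorsal"]), int(r["n_ventral"]),
             int(r["n_unpolarised"]))
            for _, r in pd.DataFrame(counts).iterrows()
        ]
    else:
        tally: dict[tuple[str, str], list[int]] = {}
        for tr in tracks:  # type: ignore[union-attr]
            for phase in tr.phase_intervals:
                mask = tr.in_phase(phase)
                if not mask.any():
                    continue
                key = (tr.fate, phase)
                cnt = tally.setdefault(key, [0, 0, 0])
                if per_cell:
                    mean_vec = tr.golgi_um[mask].mean(axis=0)
                    calls = [classify_polarity(mean_vec, band_deg)]
                else:
                    calls = [
                        classify_polarity(v, band_deg) for v in tr.golgi_um[mask]
                    ]
                for call in calls:
                    cnt[POLARITY_CLASSES.index(call.cls)] += 1
        rows = [(f, p, *c) for (f, p), c in sorted(tally.items())]
    df = _counts_frame(rows)
    if decimals is not None:
        for cls in POLARITY_CLASSES:
            df[f"pct_{cls}"] = df[f"pct_{cls}"].round(decimals)
    return df


def upward_speed(track: CellTrack, phase: str) -> float:
    """Net upward speed (um/day) of one cell within one remodelling phase."""
    mask = track.in_phase(phase)
    if mask.sum() < 2:
        raise ValueError(
            f"track {track.cell_id}: fewer than 2 samples in phase {phase}"
        )
    t = track.time_min[mask]
    d = track.distance_um[mask]
    return float((d[-1] - d[0]) / (t[-1] - t[0]) * MIN_PER_DAY)


def summarize_speeds(
    tracks: Iterable[CellTrack],
    by: tuple[str, ...] = ("fate", "phase"),
) -> pd.DataFrame:
    """Group mean +/- sem upward speed (um/day) over cells.

    ``by`` selects grouping attributes among ``fate``, ``condition`` and
    ``phase``. Cells with fewer than two in-phase samples are skipped.
    Single-cell groups report NaN sem (undefined).
    """
    rows = []
    for tr in tracks:
        for phase in tr.phase_intervals:
            if tr.in_phase(phase).sum() < 2:
                continue
            attrs = {"fate": tr.fate, "condition": tr.condition, "phase": phase}
            rows.append(tuple(attrs[k] for k in by) + (upward_speed(tr, phase),))
    if not rows:
        raise ValueError("no scorable (group, phase) combinations")
    df = pd.DataFrame(rows, columns=list(by) + ["speed_um_day"])
    out = (
        df.groupby(list(by))["speed_um_day"]
        .agg(mean_um_day="mean", sem_um_day="sem", n_cells="count")
        .reset_index()
    )
    return out


def summarize_fraction(
    annotations: pd.DataFrame,
    predicate: Callable[[pd.DataFrame], pd.Series] | tuple[str, object],
    group_by: str | Sequence[str] | None = None,
    per_embryo: bool = False,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Fraction of records satisfying a predicate, per group.

    ``predicate`` is either ``(column, value)`` or a callable returning a
    boolean Series. Pooled mode (default) returns numerator, denominator and
    pooled percentage (= 100 x sum(num)/sum(den)); ``per_embryo=True``
    instead returns mean +/- sem of embryo-level percentages (requires an
    ``embryo_id`` column), the form used for regression-behaviour summaries.
    ``decimals`` rounds the reported percentage; the raw fraction column is
    always exact.
    """
    df = pd.DataFrame(annotations)
    if df.empty:
        raise ValueError("empty annotation selection")
    if callable(predicate):
        hit = predicate(df).astype(bool)
    else:
        col, val = predicate
        hit = df[col] == val
    if group_by is None:
        keys = pd.Series("all", index=df.index, name="group")
        group_cols = ["group"]
    else:
        group_cols = [group_by] if isinstance(group_by, str) else list(group_by)
        keys = df[group_cols]
    if per_embryo:
        if "embryo_id" not in df.columns:
            raise ValueError("per_embryo mode requires an embryo_id column")
        per = hit.groupby(
            [df["embryo_id"]] + ([keys] if group_by is None else [df[c] for c in group_cols]),
            sort=False,
        ).mean() * 100.0
        per = per.rename("pct").reset_index()
        out = (
            per.groupby(group_cols)["pct"]
            .agg(mean_pct="mean", sem_pct="sem", n_embryos="count")
            .reset_index()
        )
        if decimals is not None:
            out["mean_pct"] = out["mean_pct"].round(decimals)
        return out
    grp = hit.groupby(keys if group_by is None else [df[c] for c in group_cols], sort=False)
    out = grp.agg(n_hit="sum", n_total="count").reset_index()
    out["fraction"] = out["n_hit"] / out["n_total"]
    out["pct"] = 100.0 * out["fraction"]
    if decimals is not None:
        out["pct"] = out["pct"].round(decimals)
    return out
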