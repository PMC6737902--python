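"""Core data containers shared across the package.

The containers are thin, validated wrappers around numpy arrays and pandas
DataFrames: a :class:`VesselSequenceSet` holds per-embryo, per-flank ordered
artery/vein (or Notch-reporter) labels; a :class:`CellTrack` holds one
endothelial cell's nucleus trajectory and Golgi offsets; an
:class:`ImageStack` holds a calibrated time-lapse movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABEL_ALPHABETS",
    "VesselSequenceSet",
    "CellTrack",
    "ImageStack",
    "GroundTruth",
]

#: Recognised binary label alphabets: arterial/venous identity, and the
#: tp1 Notch-activity reporter status.
LABEL_ALPHABETS: tuple[frozenset[str], ...] = (
    frozenset({"A", "V"}),
    frozenset({"tp1+", "tp1-"}),
)

_SEQ_COLUMNS = ["embryo_id", "flank", "position", "label", "tags"]


class VesselSequenceSet:
    """Ordered vessel labels on both flanks of a scored trunk segment.

    One row per intersegmental vessel: ``embryo_id``, ``flank`` (``L``/``R``),
    ``position`` (1-based, contiguous within a flank), ``label`` (one binary
    alphabet per set, e.g. ``A``/``V``), and optional ``tags`` (semicolon-
    separated strings such as ``NICD_clamped``).
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        df = data.copy()
        if "tags" not in df.columns:
            df["tags"] = ""
        df["tags"] = df["tags"].fillna("").astype(str)
        missing = [c for c in _SEQ_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"sequence table missing columns: {missing}")
        df = df[_SEQ_COLUMNS].reset_index(drop=True)
        df["position"] = df["position"].astype(int)
        df["flank"] = df["flank"].astype(str)
        df["label"] = df["label"].astype(str)
        self.data = df
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.data
        bad_flank = df.loc[~df["flank"].isin(["L", "R"])]
        if len(bad_flank):
            raise ValueError(
                f"flank must be 'L' or 'R'; offending row index {bad_flank.index[0]}"
            )
        labels = set(df["label"].unique())
        if not any(labels <= alpha for alpha in LABEL_ALPHABETS):
            allowed = [sorted(a) for a in LABEL_ALPHABETS]
            raise ValueError(
                f"labels {sorted(labels)} not within a single alphabet {allowed}"
            )
        dup = df.duplicated(subset=["embryo_id", "flank", "position"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise ValueError(
                "duplicate (embryo, flank, position): "
                f"({row.embryo_id!r}, {row.flank!r}, {row.position})"
            )
        for (emb, flank), grp in df.groupby(["embryo_id", "flank"], sort=False):
            pos = np.sort(grp["position"].to_numpy())
            if pos[0] != 1 or not np.array_equal(pos, np.arange(1, len(pos) + 1)):
                raise ValueError(
                    f"positions of embryo {emb!r} flank {flank!r} are not "
                    f"contiguous from 1: {pos.tolist()}"
                )

    # -- basic introspection -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_vessels(self) -> int:
        return len(self.data)

    @property
    def embryos(self) -> list:
        return list(pd.unique(self.data["embryo_id"]))

    @property
    def alphabet(self) -> tuple[str, str]:
        """The (sorted) binary label alphabet this set lives in."""
        labels = set(self.data["label"].unique())
        for alpha in LABEL_ALPHABETS:
            if labels <= alpha:
                return tuple(sorted(alpha))  # type: ignore[return-value]
        raise ValueError("labels outside known alphabets")  # pragma: no cover

    # -- iteration helpers ---------------------------------------------------
    def flank_sequences(self) -> Iterator[tuple[Any, str, np.ndarray, np.ndarray]]:
        """Yield ``(embryo_id, flank, labels, tags)`` ordered by position."""
        for (emb, flank), grp in self.data.groupby(
            ["embryo_id", "flank"], sort=False
        ):
            grp = grp.sort_values("position")
            yield emb, flank, grp["label"].to_numpy(), grp["tags"].to_numpy()

    def paired_flanks(self) -> Iterator[tuple[Any, np.ndarray, np.ndarray]]:
        """Yield ``(embryo_id, labels_L, labels_R)`` for contralateral analyses.

        Raises ``ValueError`` if an embryo lacks one flank or the flanks have
        unequal lengths.
        """
        for emb, grp in self.data.groupby("embryo_id", sort=False):
            sides = {}
            for flank, sub in grp.groupby("flank", sort=False):
                sides[flank] = sub.sort_values("position")["label"].to_numpy()
            if set(sides) != {"L", "R"}:
                raise ValueError(f"embryo {emb!r} lacks a paired flank")
            if len(sides["L"]) != len(sides["R"]):
                raise ValueError(
                    f"embryo {emb!r} flanks have unequal lengths "
                    f"({len(sides['L'])} vs {len(sides['R'])})"
                )
            yield emb, sides["L"], sides["R"]

    # -- construction / subsetting -------------------------------------------
    @classmethod
    def from_strings(
        cls, flanks: Mapping[tuple[Any, str], str], tags: str = ""
    ) -> "VesselSequenceSet":
        """Build a set from ``{(embryo_id, flank): "AVAV..."}`` label strings."""
        rows = []
        for (emb, flank), seq in flanks.items():
            for i, ch in enumerate(seq, start=1):
                rows.append((emb, flank, i, ch, tags))
        return cls(pd.DataFrame(rows, columns=_SEQ_COLUMNS))

    def subset_rows(self, mask: pd.Series | np.ndarray) -> "VesselSequenceSet":
        """Row subset (no validation of contiguity: used for tag filters)."""
        out = VesselSequenceSet.__new__(VesselSequenceSet)
        out.data = self.data.loc[np.asarray(mask)].reset_index(drop=True)
        return out

    def has_tag(self, tag: str) -> pd.Series:
        return self.data["tags"].str.split(";").apply(lambda ts: tag in ts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VesselSequenceSet):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class CellTrack:
    """Nucleus trajectory and Golgi offsets of one endothelial cell.

    ``distance_um`` is the nucleus distance from the dorsal aorta (µm,
    non-negative); ``golgi_um`` holds the Golgi-minus-nucleus offset vectors
    in the (along-ISV-dorsal, orthogonal) frame; ``phase_intervals`` maps the
    remodelling phase (``I``/``II``/``III``) to its ``(t_start, t_end)`` in
    minutes.
    """

    cell_id: str
    isv_id: str
    fate: str  # 'aISV' or 'vISV' (or a condition label such as 'NICD_OE')
    time_min: np.ndarray
    distance_um: np.ndarray
    golgi_um: np.ndarray  # shape (n, 2)
    phase_intervals: dict[str, tuple[float, float]]
    condition: str = "wild_type"

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        self.golgi_um = np.asarray(self.golgi_um, dtype=float)
        n = len(self.time_min)
        if self.distance_um.shape != (n,) or self.golgi_um.shape != (n, 2):
            raise ValueError("sample arrays have inconsistent shapes")
        if n >= 2 and not np.all(np.diff(self.time_min) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.distance_um < 0):
            raise ValueError("distance_from_da must be non-negative")
        bounds = sorted(self.phase_intervals.values())
        for (a0, a1), (b0, b1) in zip(bounds, bounds[1:]):
            if a1 > b0:
                raise ValueError("phase intervals overlap")
        for t0, t1 in bounds:
            if t1 <= t0:
                raise ValueError("phase interval has non-positive duration")

    def in_phase(self, phase: str) -> np.ndarray:
        """Boolean sample mask for one remodelling phase (inclusive bounds)."""
        t0, t1 = self.phase_intervals[phase]
        return (self.time_min >= t0) & (self.time_min <= t1)


@dataclass
class ImageStack:
    """Calibrated time-lapse movie: ``frames`` is (n_frames, height, width)."""

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (n_frames >= 2, height, width)")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]


@dataclass
class GroundTruth:
    """Known truth attached to every synthetic object (generator plumbing)."""

    true_params: Any = None
    true_displacements: np.ndarray | None = None  # (n_frames-1, 2) px, (dx, dy)
    true_velocity: np.ndarray | None = None  # µm/s per frame pair
    true_heart_rate: float | None = None  # beats per minute
    true_fates: Sequence[str] | None = None
    extra: dict = field(default_factory=dict)
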