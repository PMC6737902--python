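"""Synthetic stand-ins for the study's live-imaging inputs, with ground truth.

Four generators emulate, respectively: (a) per-embryo artery/vein label
sequences over a 10-somite trunk segment on both flanks, with an ipsilateral
alternation bias and weak contralateral coupling; (b) endothelial cell tracks
(nucleus distance from the dorsal aorta over time plus Golgi offset vectors)
across the three remodelling phases; (c) time-lapse movies of advected
particles in a vessel with a known per-frame displacement; (d) periodic
heartbeat intensity traces of known rate.

Every generator returns the synthetic object together with a
:class:`~isvbalance.datatypes.GroundTruth` recording what was simulated, so
downstream estimators can be tested by parameter recovery. All randomness
flows from one seeded generator per call; per-embryo/per-track sub-streams
are spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .datatypes import CellTrack, GroundTruth, ImageStack, VesselSequenceSet

__all__ = [
    "SequenceGenParams",
    "TrackGenParams",
    "FlowMovieParams",
    "generate_sequences",
    "generate_tracks",
    "generate_flow_movie",
    "generate_heartbeat_trace",
    "DEFAULT_SPEEDS_UM_DAY",
    "DEFAULT_POLARITY_PROBS",
    "DEFAULT_PHASE_DURATIONS_MIN",
]

FATES = ("aISV", "vISV")
PHASES = ("I", "II", "III")

MIN_PER_DAY = 1440.0


# ---------------------------------------------------------------------------
# vessel label sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceGenParams:
    """Parameters of the two-state Markov model for flank label sequences.

    ``alternation`` interpolates between independent draws (0) and strict
    ipsilateral alternation (1); ``contralateral_coupling`` in [-1, 1] is the
    probability of copying (positive) or anti-copying (negative) the
    opposing flank's same-position label instead of drawing ipsilaterally.
    """

    n_embryos: int
    flank_length: int = 10
    p_artery: float = 0.5
    alternation: float = 0.0
    contralateral_coupling: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_embryos < 1 or self.flank_length < 1:
            raise ValueError("n_embryos and flank_length must be >= 1")
        if not 0.0 <= self.p_artery <= 1.0:
            raise ValueError("p_artery must be a probability")
        if not 0.0 <= self.alternation <= 1.0:
            raise ValueError("alternation must be in [0, 1]")
        if not -1.0 <= self.contralateral_coupling <= 1.0:
            raise ValueError("contralateral_coupling must be in [-1, 1]")


def _chain_draw(rng: np.random.Generator, prev: str | None, p: SequenceGenParams) -> str:
    """One ipsilateral draw: mix independent Bernoulli with strict alternation."""
    if prev is not None and rng.random() < p.alternation:
        return "V" if prev == "A" else "A"
    return "A" if rng.random() < p.p_artery else "V"


def generate_sequences(
    params: SequenceGenParams,
) -> tuple[VesselSequenceSet, GroundTruth]:
    """Generate per-embryo two-flank vessel label sequences.

    The left flank follows the alternation-mixing Markov chain; the right
    flank additionally mixes in the left flank's same-position label with
    probability ``|contralateral_coupling|`` (copied if positive, inverted if
    negative). Reproducible under a fixed seed.
    """
    master = np.random.SeedSequence(params.seed)
    rows = []
    for emb_idx, child in enumerate(master.spawn(params.n_embryos)):
        rng = np.random.default_rng(child)
        left: list[str] = []
        prev = None
        for _ in range(params.flank_length):
            lab = _chain_draw(rng, prev, params)
            left.append(lab)
            prev = lab
        right: list[str] = []
        prev = None
        c = params.contralateral_coupling
        for i in range(params.flank_length):
            if c != 0.0 and rng.random() < abs(c):
                lab = left[i] if c > 0 else ("V" if left[i] == "A" else "A")
            else:
                lab = _chain_draw(rng, prev, params)
            right.append(lab)
            prev = lab
        emb = f"emb{emb_idx + 1:04d}"
        for flank, seq in (("L", left), ("R", right)):
            for pos, lab in enumerate(seq, start=1):
                rows.append((emb, flank, pos, lab, ""))
    seqs = VesselSequenceSet(
        pd.DataFrame(rows, columns=["embryo_id", "flank", "position", "label", "tags"])
    )
    return seqs, GroundTruth(true_params=params)


# ---------------------------------------------------------------------------
# endothelial cell tracks
# ---------------------------------------------------------------------------

#: Default mean upward speed (µm/day) per (fate, phase). Positive = dorsal
#: movement away from the aorta. Future vISV cells migrate dorsally from
#: phase I on; future aISV cells stay put or drift slightly ventrally.
DEFAULT_SPEEDS_UM_DAY: dict[tuple[str, str], float] = {
    ("aISV", "I"): -30.0,
    ("aISV", "II"): -50.0,
    ("aISV", "III"): -30.0,
    ("vISV", "I"): 150.0,
    ("vISV", "II"): 200.0,
    ("vISV", "III"): 100.0,
}

#: Default (dorsal, ventral, unpolarised) class probabilities per
#: (fate, phase). Biases strengthen toward phase III: ~60% ventral in aISVs
#: and ~52% dorsal in vISVs after resolution, weaker but same-signed in
#: phase I (the pre-patterned heterogeneity).
DEFAULT_POLARITY_PROBS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("aISV", "I"): (0.25, 0.45, 0.30),
    ("aISV", "II"): (0.22, 0.52, 0.26),
    ("aISV", "III"): (0.20, 0.60, 0.20),
    ("vISV", "I"): (0.42, 0.28, 0.30),
    ("vISV", "II"): (0.48, 0.26, 0.26),
    ("vISV", "III"): (0.52, 0.26, 0.22),
}

#: Default phase durations (minutes): ~2.5 h before connection, ~3 h of
#: three-way connection, ~2.5 h after resolution.
DEFAULT_PHASE_DURATIONS_MIN: dict[str, float] = {"I": 150.0, "II": 180.0, "III": 150.0}


@dataclass
class TrackGenParams:
    """Parameters for the piecewise-linear endothelial track generator."""

    n_isvs_per_fate: int = 10
    cells_per_isv: int = 3
    mean_speed_um_day: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SPEEDS_UM_DAY)
    )
    polarity_probs: Mapping[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_POLARITY_PROBS)
    )
    phase_durations_min: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_DURATIONS_MIN)
    )
    position_noise_sd_um: float = 0.5
    sample_interval_min: float = 15.0
    start_distance_um: float = 40.0
    golgi_magnitude_um: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for ph, d in self.phase_durations_min.items():
            if d <= 0:
                raise ValueError(f"phase {ph} duration must be positive")
        for key, triple in self.polarity_probs.items():
            if abs(sum(triple) - 1.0) > 1e-9 or any(p < 0 for p in triple):
                raise ValueError(f"polarity probabilities for {key} must sum to 1")
        if self.sample_interval_min <= 0:
            raise ValueError("sample_interval_min must be positive")
        if self.position_noise_sd_um < 0:
            raise ValueError("position_noise_sd_um must be non-negative")


# angular sectors (degrees from the dorsal axis) used to draw Golgi offsets
# for each polarity class; kept 5 deg clear of the 60/120 deg class
# boundaries of the default 30 deg band so the draw is classified exactly.
_CLASS_SECTORS = {"dorsal": (5.0, 55.0), "unpolarised": (65.0, 115.0),
                  "ventral": (125.0, 175.0)}


def generate_tracks(
    params: TrackGenParams,
) -> tuple[list[CellTrack], GroundTruth]:
    """Generate endothelial cell tracks with fate/phase-dependent behaviour.

    Nucleus distance from the aorta evolves piecewise linearly at the
    fate/phase mean speed plus iid Gaussian position noise; Golgi offset
    class is drawn per timepoint from the fate/phase class probabilities and
    rendered as a vector in the (dorsal, orthogonal) frame.
    """
    master = np.random.SeedSequence(params.seed)
    durations = [params.phase_durations_min[ph] for ph in PHASES]
    bounds = np.concatenate([[0.0], np.cumsum(durations)])
    phase_intervals = {
        ph: (float(bounds[i]), float(bounds[i + 1])) for i, ph in enumerate(PHASES)
    }
    t = np.arange(0.0, bounds[-1] + 1e-9, params.sample_interval_min)
    # phase membership: per-sample (boundary samples belong to the earlier
    # phase; `CellTrack.in_phase` uses inclusive bounds) and per-interval
    # (by midpoint, so intervals flanking a boundary get the right speed)
    phase_of_t = np.searchsorted(bounds[1:-1], t, side="left")
    mids = 0.5 * (t[:-1] + t[1:])
    phase_of_interval = np.searchsorted(bounds[1:-1], mids, side="left")
    speeds_min = np.empty((2, 3))
    for fi, fate in enumerate(FATES):
        for pi, ph in enumerate(PHASES):
            speeds_min[fi, pi] = params.mean_speed_um_day[(fate, ph)] / MIN_PER_DAY

    tracks: list[CellTrack] = []
    fates: list[str] = []
    n_tracks = 2 * params.n_isvs_per_fate * params.cells_per_isv
    children = iter(master.spawn(n_tracks))
    for fi, fate in enumerate(FATES):
        for isv in range(params.n_isvs_per_fate):
            isv_id = f"{fate}_{isv + 1:03d}"
            for cell in range(params.cells_per_isv):
                rng = np.random.default_rng(next(children))
                # integrate the phase-wise speed over the sample grid
                v = speeds_min[fi, phase_of_interval]
                dist = params.start_distance_um + np.concatenate(
                    [[0.0], np.cumsum(v * np.diff(t))]
                )
                dist = dist + rng.normal(0.0, params.position_noise_sd_um, len(t))
                dist = np.clip(dist, 0.0, None)
                # Golgi offsets: class per timepoint, vector within its sector
                golgi = np.empty((len(t), 2))
                for i in range(len(t)):
                    ph = PHASES[phase_of_t[i]]
                    probs = params.polarity_probs[(fate, ph)]
                    cls = ("dorsal", "ventral", "unpolarised")[
                        rng.choice(3, p=[probs[0], probs[1], probs[2]])
                    ]
                    lo, hi = _CLASS_SECTORS[cls]
                    ang = np.deg2rad(rng.uniform(lo, hi))
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    golgi[i] = params.golgi_magnitude_um * np.array(
                        [np.cos(ang), sign * np.sin(ang)]
                    )
                tracks.append(
                    CellTrack(
                        cell_id=f"{isv_id}_c{cell + 1}",
                        isv_id=isv_id,
                        fate=fate,
                        time_min=t.copy(),
                        distance_um=dist,
                        golgi_um=golgi,
                        phase_intervals=dict(phase_intervals),
                    )
                )
                fates.append(fate)
    return tracks, GroundTruth(true_params=params, true_fates=fates)


# ---------------------------------------------------------------------------
# particle flow movies
# ---------------------------------------------------------------------------

@dataclass
class FlowMovieParams:
    """Parameters for the advected-particle movie generator.

    ``velocity_um_s`` is the axial flow speed profile: a constant (µm/s), a
    ``(mean, amplitude, frequency_hz)`` triple for a sinusoidal pulsatile
    profile, or a callable of time (s).
    """

    n_frames: int = 50
    height: int = 64
    width: int = 64
    pixel_size_um: float = 0.5
    frame_interval_s: float = 0.01
    velocity_um_s: float | tuple[float, float, float] | Callable[[np.ndarray], np.ndarray] = 150.0
    particle_density: float = 30.0  # particles per frame
    particle_radius_px: float = 1.5  # Gaussian sigma of a rendered particle
    noise_sd: float = 0.0
    periodic: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_interval_s and pixel_size_um must be positive")
        if self.particle_density <= 0:
            raise ValueError("particle_density must be positive (nothing to track)")


def _displacements_um(params: FlowMovieParams) -> np.ndarray:
    """Per-frame-pair axial displacement (µm) = integral of v over interval."""
    dt = params.frame_interval_s
    v = params.velocity_um_s
    if callable(v):
        # trapezoidal integration on a fine sub-grid per interval
        out = np.empty(params.n_frames - 1)
        for i in range(params.n_frames - 1):
            ts = np.linspace(i * dt, (i + 1) * dt, 33)
            out[i] = np.trapezoid(np.asarray(v(ts), dtype=float), ts)
        return out
    if isinstance(v, tuple):
        mean, amp, freq = v
        t0 = np.arange(params.n_frames - 1) * dt
        t1 = t0 + dt
        if freq == 0:
            return (mean + amp) * dt * np.ones_like(t0)
        w = 2.0 * np.pi * freq
        return mean * dt - amp / w * (np.cos(w * t1) - np.cos(w * t0))
    return float(v) * dt * np.ones(params.n_frames - 1)


def _render_frame(
    x: np.ndarray, y: np.ndarray, params: FlowMovieParams
) -> np.ndarray:
    """Render particles as (wrapped) Gaussian blobs on the pixel grid."""
    H, W = params.height, params.width
    sig = params.particle_radius_px
    xs = np.arange(W)[None, :]
    ys = np.arange(H)[None, :]
    if params.periodic:
        dx = (xs - x[:, None] + W / 2.0) % W - W / 2.0
        dy = (ys - y[:, None] + H / 2.0) % H - H / 2.0
    else:
        dx = xs - x[:, None]
        dy = ys - y[:, None]
    gx = np.exp(-(dx ** 2) / (2.0 * sig ** 2))  # (n, W)
    gy = np.exp(-(dy ** 2) / (2.0 * sig ** 2))  # (n, H)
    return np.einsum("ph,pw->hw", gy, gx)


def generate_flow_movie(
    params: FlowMovieParams,
) -> tuple[ImageStack, GroundTruth]:
    """Generate a movie of particles advected along +x by the flow profile.

    With ``periodic=True`` (default) particles wrap around the field of view,
    so an integer per-frame pixel shift produces frames that are exact
    circular translations of each other — the construction oracle for the
    phase-correlation estimator. Ground truth records per-pair pixel
    displacements and the µm/s velocity trace.
    """
    rng = np.random.default_rng(params.seed)
    n_part = max(1, int(round(params.particle_density)))
    x0 = rng.uniform(0, params.width, n_part)
    y0 = rng.uniform(0, params.height, n_part)
    disp_um = _displacements_um(params)
    disp_px = disp_um / params.pixel_size_um
    cum_px = np.concatenate([[0.0], np.cumsum(disp_px)])
    frames = np.empty((params.n_frames, params.height, params.width))
    for i in range(params.n_frames):
        frames[i] = _render_frame(x0 + cum_px[i], y0, params)
    if params.noise_sd > 0:
        frames += rng.normal(0.0, params.noise_sd, frames.shape)
    stack = ImageStack(frames, params.pixel_size_um, params.frame_interval_s)
    truth = GroundTruth(
        true_params=params,
        true_displacements=np.column_stack([disp_px, np.zeros_like(disp_px)]),
        true_velocity=np.abs(disp_um) / params.frame_interval_s,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# heartbeat traces
# ---------------------------------------------------------------------------

def generate_heartbeat_trace(
    rate_bpm: float,
    duration_s: float = 8.0,
    sample_interval_s: float = 0.01,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Generate a periodic heartbeat intensity trace of known rate.

    The trace is a unit-amplitude train of Gaussian pulses at the beat
    period (width 10% of the period), with the first beat centred half a
    period in so that every beat peak is an interior sample, plus optional
    additive Gaussian noise.
    """
    if rate_bpm <= 0:
        raise ValueError("rate_bpm must be positive")
    period = 60.0 / rate_bpm
    if duration_s < period:
        raise ValueError("duration shorter than one beat period")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, sample_interval_s)
    beat_times = np.arange(period / 2.0, duration_s, period)
    sig = 0.1 * period
    trace = np.zeros_like(t)
    for bt in beat_times:
        trace += np.exp(-((t - bt) ** 2) / (2.0 * sig ** 2))
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, len(t))
    truth = GroundTruth(
        true_heart_rate=float(rate_bpm),
        extra={"beat_times_s": beat_times, "sample_interval_s": sample_interval_s},
    )
    return trace, truth
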