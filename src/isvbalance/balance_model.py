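"""Stochastic simulator of the dual artery-vein balancing mechanism.

The model formalises two stacked processes observed in the zebrafish trunk:

1. **Notch pre-patterning.** Each flank's primary ISVs draw a Notch activity
   level sequentially with a lateral-inhibition penalty: the level is an
   AR(1) sequence with negative coefficient (a high-Notch vessel pushes its
   next neighbour low), producing the alternation-biased salt-and-pepper
   pattern of the tp1 reporter. Vessels above a threshold are pre-specified
   arterial; the threshold defaults to the 40th percentile of the stationary
   level distribution, so the pre-pattern is ~60% arterial / 40% venous.

2. **Flow-mediated fine-tuning.** Nearly all vessels transiently form a
   three-way connection with a secondary sprout (probability ``p_connect``,
   default 0.775, the observed lower bound). When flow is on, the cohort's
   arterial excess over the 50:50 target is relaxed by flipping eligible
   vessels (connected, unclamped, pre-arterial) to venous, lowest Notch
   level first, each with probability ``compensation_gain x (current
   arterial fraction - target)``, until the target is reached. Without flow
   (tricaine) no flips occur and the final pattern equals the pre-pattern.

NICD mosaic overexpression is modelled by clamping a random fraction of
vessels arterial; clamped vessels never flip, so the compensation burden
falls on wild-type vessels — reproducing the elevated venous fraction among
unclamped vessels and the flattening of the ipsilateral neighbourhood
pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import pattern_stats
from .datatypes import VesselSequenceSet

__all__ = [
    "ModelParams",
    "SimulatedCohort",
    "simulate_prepattern",
    "resolve_three_way",
    "run_experiment",
    "SCENARIOS",
]


@dataclass
class ModelParams:
    """Parameters of the dual-mechanism balance model.

    ``notch_mean``/``notch_sd`` set the per-vessel Notch level draw;
    ``lateral_inhibition`` in [0, 1) is the magnitude of the negative AR(1)
    coefficient coupling neighbouring levels. ``prearterial_fraction`` fixes
    the marginal probability that a vessel's level exceeds the arterial
    threshold (the threshold may instead be given explicitly via
    ``artery_threshold``). ``high_notch_quantile`` labels the top fraction
    of levels as 'high' (tp1-high analogue).
    """

    n_embryos: int = 100
    flank_length: int = 10
    notch_mean: float = 1.0
    notch_sd: float = 0.3
    lateral_inhibition: float = 0.4
    prearterial_fraction: float = 0.6
    artery_threshold: float | None = None
    high_notch_quantile: float = 0.1
    p_connect: float = 0.775
    flow_on: bool = True
    compensation_gain: float = 2.0
    target_fraction: float = 0.5
    clamp_fraction: float = 0.0
    tolerance: float = 0.005
    max_iterations: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("prearterial_fraction", "high_notch_quantile", "p_connect",
                     "target_fraction", "clamp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not 0.0 <= self.lateral_inhibition < 1.0:
            raise ValueError("lateral_inhibition must be in [0, 1)")
        if self.notch_sd <= 0:
            raise ValueError("notch_sd must be positive")
        if self.n_embryos < 1 or self.flank_length < 1:
            raise ValueError("n_embryos and flank_length must be >= 1")

    @property
    def stationary_sd(self) -> float:
        """SD of the stationary AR(1) Notch level distribution."""
        return self.notch_sd / np.sqrt(1.0 - self.lateral_inhibition ** 2)

    def resolved_threshold(self) -> float:
        """Arterial threshold: explicit, or the (1 - prearterial) quantile."""
        if self.artery_threshold is not None:
            return self.artery_threshold
        return float(
            sps.norm.ppf(
                1.0 - self.prearterial_fraction, self.notch_mean, self.stationary_sd
            )
        )


@dataclass
class SimulatedCohort:
    """Per-vessel simulation state (one row per ISV)."""

    data: pd.DataFrame
    params: ModelParams
    converged: bool = True
    notch_high_cut: float = field(default=np.nan)

    def arterial_fraction(self, which: str = "final_identity") -> float:
        return float((self.data[which] == "A").mean())

    def to_sequence_set(self, which: str = "final_identity") -> VesselSequenceSet:
        df = self.data[["embryo_id", "flank", "position"]].copy()
        df["label"] = self.data[which]
        df["tags"] = np.where(self.data["clamped"], "NICD_clamped", "")
        return VesselSequenceSet(df)


def simulate_prepattern(params: ModelParams) -> SimulatedCohort:
    """Draw Notch levels and pre-identities for every vessel.

    Levels follow a stationary AR(1) with coefficient
    ``-lateral_inhibition`` per flank (the first vessel is drawn from the
    stationary distribution), so the marginal level distribution — and
    hence the pre-arterial fraction — is identical at every position and
    every inhibition strength. Clamped vessels are pre-arterial regardless
    of their level.
    """
    rng = np.random.default_rng(params.seed)
    n_emb, L = params.n_embryos, params.flank_length
    lam, mu = params.lateral_inhibition, params.notch_mean
    s_stat = params.stationary_sd
    n_flanks = n_emb * 2
    # vectorised AR(1) across all flanks
    levels = np.empty((n_flanks, L))
    levels[:, 0] = rng.normal(mu, s_stat, n_flanks)
    for j in range(1, L):
        levels[:, j] = (
            mu
            - lam * (levels[:, j - 1] - mu)
            + rng.normal(0.0, params.notch_sd, n_flanks)
        )
    flat = levels.reshape(-1)
    thr = params.resolved_threshold()
    clamped = rng.random(flat.size) < params.clamp_fraction
    pre_a = (flat > thr) | clamped
    high_cut = float(
        sps.norm.ppf(1.0 - params.high_notch_quantile, mu, s_stat)
    )
    notch_class = np.where(
        flat > high_cut, "high", np.where(flat > thr, "positive", "negative")
    )
    emb_ids = np.repeat([f"emb{i + 1:04d}" for i in range(n_emb)], 2 * L)
    flanks = np.tile(np.repeat(["L", "R"], L), n_emb)
    positions = np.tile(np.arange(1, L + 1), n_flanks)
    df = pd.DataFrame(
        {
            "embryo_id": emb_ids,
            "flank": flanks,
            "position": positions,
            "notch_level": flat,
            "notch_class": notch_class,
            "clamped": clamped,
            "connected": False,
            "pre_identity": np.where(pre_a, "A", "V"),
            "final_identity": np.where(pre_a, "A", "V"),
            "flip_iteration": -1,
        }
    )
    return SimulatedCohort(df, params, notch_high_cut=high_cut)


def resolve_three_way(cohort: SimulatedCohort, params: ModelParams | None = None) -> SimulatedCohort:
    """Form transient connections and apply flow-mediated compensation.

    Each vessel independently forms a transient three-way connection with
    probability ``p_connect``. With flow on, while the cohort's arterial
    fraction exceeds the target, eligible vessels (connected, unclamped,
    currently arterial) are visited in ascending Notch order and flip to
    venous with probability ``gain x (fraction - target)``; passes repeat
    until convergence or ``max_iterations``. Non-convergence is flagged on
    the result, not raised. With flow off no flips occur, so the final
    identities equal the pre-pattern exactly.
    """
    if params is None:
        params = cohort.params
    df = cohort.data.copy()
    rng = np.random.default_rng(
        None if params.seed is None else params.seed + 1
    )
    n = len(df)
    df["connected"] = rng.random(n) < params.p_connect
    df["final_identity"] = df["pre_identity"].to_numpy(copy=True)
    df["flip_iteration"] = -1
    converged = True
    if params.flow_on:
        target_count = params.target_fraction * n
        eligible = (
            df["connected"].to_numpy()
            & ~df["clamped"].to_numpy()
            & (df["pre_identity"].to_numpy() == "A")
        )
        # ascending Notch level: lowest-Notch vessels are the most plastic;
        # RNG jitter breaks exact ties
        order = np.argsort(
            df["notch_level"].to_numpy() + rng.normal(0, 1e-12, n), kind="stable"
        )
        order = order[eligible[order]]
        final = df["final_identity"].to_numpy(copy=True)
        flip_iter = df["flip_iteration"].to_numpy(copy=True)
        n_a = int((final == "A").sum())
        tol_count = params.tolerance * n
        it = 0
        while n_a - target_count > tol_count and it < params.max_iterations:
            it += 1
            p_flip = params.compensation_gain * (n_a / n - params.target_fraction)
            if p_flip <= 0:
                break
            remaining = order[final[order] == "A"]
            if len(remaining) == 0:
                break
            # only the `deficit` lowest-Notch eligible vessels are candidates
            # this pass: compensation recruits the most plastic vessels and
            # never overshoots below the target
            deficit = int(np.ceil(n_a - target_count))
            candidates = remaining[:deficit]
            flips = candidates[rng.random(len(candidates)) < p_flip]
            final[flips] = "V"
            flip_iter[flips] = it
            n_a -= len(flips)
        converged = n_a - target_count <= tol_count
        df["final_identity"] = final
        df["flip_iteration"] = flip_iter
    return SimulatedCohort(df, params, converged=converged,
                           notch_high_cut=cohort.notch_high_cut)


#: Named experimental scenarios (parameter overrides on the defaults).
SCENARIOS: dict[str, dict] = {
    "wild_type": {},
    "tricaine": {"flow_on": False},
    "nicd_mosaic": {"clamp_fraction": 0.3},
    "nicd_mosaic_tricaine": {"clamp_fraction": 0.3, "flow_on": False},
}


@dataclass
class ExperimentResult:
    scenario: str
    cohort: SimulatedCohort
    sequences: VesselSequenceSet
    balance: pattern_stats.BalanceSummary
    ipsilateral: pd.DataFrame
    contralateral: pd.DataFrame


def run_experiment(
    scenario: str,
    n_embryos: int = 100,
    seed: int | None = None,
    **overrides,
) -> ExperimentResult:
    """Simulate a named scenario and run the neighbourhood analyses on it.

    Scenarios: ``wild_type`` (flow on, no clamping), ``tricaine`` (flow
    off), ``nicd_mosaic`` (30% of vessels clamped arterial, flow on) and
    ``nicd_mosaic_tricaine``. Extra keyword overrides are applied on top.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}"
        )
    params = ModelParams(n_embryos=n_embryos, seed=seed)
    params = replace(params, **{**SCENARIOS[scenario], **overrides})
    cohort = resolve_three_way(simulate_prepattern(params))
    seqs = cohort.to_sequence_set()
    return ExperimentResult(
        scenario=scenario,
        cohort=cohort,
        sequences=seqs,
        balance=pattern_stats.global_balance(seqs, positive_label="A"),
        ipsilateral=pattern_stats.neighbourhood(seqs, (-1, 1), positive_label="A"),
        contralateral=pattern_stats.contralateral(seqs, positive_label="A"),
    )
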