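"""Global artery-vein balance and neighbourhood conditional probabilities.

Given per-embryo, per-flank ordered vessel labels, these routines compute:

* the global balance (pooled and per-embryo arterial fraction),
* ipsilateral neighbourhood tables — the conditional probability of a vessel
  carrying the positive label (e.g. arterial) given how many of its
  neighbours at the requested offsets do,
* the contralateral table — the same probability conditioned on the label of
  the opposing-flank vessel at the same somite position,
* embryo-level bootstrap confidence intervals for any scalar statistic.

Boundary vessels lacking a required neighbour offset are excluded from
eligibility, so with offsets {-1, +1} a flank of length L contributes L - 2
eligible vessels (74 embryos x 2 flanks x 10 somites -> 1184 eligible).
Conditions with no eligible vessels are reported with an undefined (NaN)
probability, never as 0. The same construction applies unchanged to the tp1
Notch-reporter alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .datatypes import VesselSequenceSet

__all__ = [
    "BalanceSummary",
    "global_balance",
    "neighbourhood",
    "contralateral",
    "bootstrap_ci",
    "lag1_correlation",
]


@dataclass
class BalanceSummary:
    """Pooled and per-embryo fraction of the positive label."""

    positive_label: str
    n_total: int
    n_positive: int
    per_embryo: pd.Series  # embryo_id -> fraction

    @property
    def fraction(self) -> float:
        return self.n_positive / self.n_total

    @property
    def mean(self) -> float:
        """Mean of embryo-level fractions."""
        return float(self.per_embryo.mean())

    @property
    def sem(self) -> float:
        """Standard error of the mean across embryos."""
        return float(self.per_embryo.sem())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BalanceSummary({self.positive_label}: {self.n_positive}/{self.n_total}"
            f" = {self.fraction:.3f}; embryo mean {self.mean:.3f} +/- {self.sem:.3f})"
        )


def _positive(seqs: VesselSequenceSet, positive_label: str | None) -> str:
    if positive_label is None:
        return seqs.alphabet[0]  # 'A' sorts before 'V'; 'tp1+' before 'tp1-'
    return positive_label


def global_balance(
    seqs: VesselSequenceSet,
    positive_label: str | None = None,
    tag: str | None = None,
    exclude_tag: str | None = None,
) -> BalanceSummary:
    """Pooled and per-embryo fraction of ``positive_label`` vessels.

    ``tag`` / ``exclude_tag`` select vessel subsets by annotation tag (the
    mosaic analyses: overall / clamped / wild-type vessels).
    """
    df = seqs.data
    mask = pd.Series(True, index=df.index)
    if tag is not None:
        mask &= seqs.has_tag(tag)
    if exclude_tag is not None:
        mask &= ~seqs.has_tag(exclude_tag)
    sel = df.loc[mask]
    if sel.empty:
        raise ValueError("no vessels left after tag filtering")
    pos = _positive(seqs, positive_label)
    is_pos = sel["label"] == pos
    per_embryo = is_pos.groupby(sel["embryo_id"], sort=False).mean()
    return BalanceSummary(
        positive_label=pos,
        n_total=len(sel),
        n_positive=int(is_pos.sum()),
        per_embryo=per_embryo,
    )


def _condition_table(
    conditions: Iterable[str],
    cond: np.ndarray,
    is_pos: np.ndarray,
) -> pd.DataFrame:
    rows = []
    cond = np.asarray(cond)
    is_pos = np.asarray(is_pos, dtype=bool)
    for c in conditions:
        sel = cond == c
        n = int(sel.sum())
        k = int(is_pos[sel].sum())
        rows.append((c, n, k, k / n if n > 0 else np.nan))
    return pd.DataFrame(rows, columns=["condition", "n_eligible", "n_positive", "p_positive"])


def neighbourhood(
    seqs: VesselSequenceSet,
    offsets: Iterable[int] = (-1, 1),
    positive_label: str | None = None,
) -> pd.DataFrame:
    """Ipsilateral neighbourhood table.

    A vessel is eligible iff all ``offsets`` positions fall inside its
    flank's scored segment; its condition is the count of positive-labelled
    vessels among those positions (0..len(offsets)). Returns one row per
    condition with ``n_eligible``, ``n_positive`` and ``p_positive``
    (NaN where no vessel realises the condition).
    """
    offsets = sorted(set(int(o) for o in offsets))
    if not offsets:
        raise ValueError("offsets must be non-empty")
    if 0 in offsets:
        raise ValueError("offsets must exclude 0 (the vessel itself)")
    pos_label = _positive(seqs, positive_label)
    conds: list[int] = []
    is_pos: list[bool] = []
    for _, _, labels, _ in seqs.flank_sequences():
        L = len(labels)
        lab_pos = labels == pos_label
        for i in range(L):
            idx = [i + o for o in offsets]
            if any(j < 0 or j >= L for j in idx):
                continue
            conds.append(int(sum(lab_pos[j] for j in idx)))
            is_pos.append(bool(lab_pos[i]))
    table = _condition_table(range(len(offsets) + 1), np.array(conds, dtype=object), np.array(is_pos, dtype=bool))
    table["condition"] = table["condition"].astype(int)
    return table


def contralateral(
    seqs: VesselSequenceSet,
    positive_label: str | None = None,
) -> pd.DataFrame:
    """Contralateral table: condition = label of the same-position opposing vessel.

    All vessels are eligible; requires both flanks of each embryo present
    with equal lengths.
    """
    pos_label = _positive(seqs, positive_label)
    alphabet = seqs.alphabet
    conds: list[str] = []
    is_pos: list[bool] = []
    for _, left, right in seqs.paired_flanks():
        for own, opp in ((left, right), (right, left)):
            conds.extend(opp.tolist())
            is_pos.extend((own == pos_label).tolist())
    return _condition_table(alphabet, np.array(conds, dtype=object), np.array(is_pos))


def bootstrap_ci(
    statistic: Callable[[VesselSequenceSet], float],
    seqs: VesselSequenceSet,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap interval, resampling embryos with replacement.

    The embryo is the independent experimental unit, so resampling happens
    at embryo level (a hierarchical bootstrap with the embryo as the only
    random level). Deterministic under a fixed seed.
    """
    embryos = seqs.embryos
    if len(embryos) < 2:
        raise ValueError("bootstrap requires at least 2 embryos")
    rng = np.random.default_rng(seed)
    groups = {e: g for e, g in seqs.data.groupby("embryo_id", sort=False)}
    stats = np.empty(n_boot)
    for b in range(n_boot):
        picks = rng.choice(len(embryos), size=len(embryos), replace=True)
        frames = []
        for k, p in enumerate(picks):
            g = groups[embryos[p]].copy()
            g["embryo_id"] = f"bs{k}"  # keep resampled embryos distinct
            frames.append(g)
        resampled = VesselSequenceSet(pd.concat(frames, ignore_index=True), validate=False)
        stats[b] = statistic(resampled)
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def lag1_correlation(
    seqs: VesselSequenceSet, positive_label: str | None = None
) -> float:
    """Pearson correlation between adjacent same-flank labels (+/-1 coded).

    Negative values indicate alternation-biased patterning; used to check
    that the generator's alternation parameter is recovered in direction.
    """
    pos_label = _positive(seqs, positive_label)
    a: list[float] = []
    b: list[float] = []
    for _, _, labels, _ in seqs.flank_sequences():
        x = np.where(labels == pos_label, 1.0, -1.0)
        a.extend(x[:-1])
        b.extend(x[1:])
    if len(a) < 2:
        raise ValueError("need at least one flank of length >= 2")
    return float(np.corrcoef(a, b)[0, 1])
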