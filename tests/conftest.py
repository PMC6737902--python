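"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isvbalance.datatypes import VesselSequenceSet


def brute_force_neighbourhood(
    seqs: VesselSequenceSet, offsets: tuple[int, ...], positive: str = "A"
) -> pd.DataFrame:
    """Exhaustive per-vessel recount, independent of the package's vectorised
    bookkeeping: plain nested loops over rows of the raw table."""
    rows = []
    df = seqs.data
    for (emb, flank), grp in df.groupby(["embryo_id", "flank"]):
        grp = grp.sort_values("position")
        labels = list(grp["label"])
        L = len(labels)
        for i in range(L):
            neigh = [i + o for o in offsets]
            if all(0 <= j < L for j in neigh):
                cond = sum(labels[j] == positive for j in neigh)
                rows.append((cond, labels[i] == positive))
    out = []
    for c in range(len(offsets) + 1):
        sel = [p for cc, p in rows if cc == c]
        n = len(sel)
        out.append((c, n, sum(sel), sum(sel) / n if n else np.nan))
    return pd.DataFrame(
        out, columns=["condition", "n_eligible", "n_positive", "p_positive"]
    )


@pytest.fixture
def alternating_flank() -> VesselSequenceSet:
    return VesselSequenceSet.from_strings({("e1", "L"): "AVAVAVAVAV"})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
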