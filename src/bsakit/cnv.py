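"""Copy-number detection from windowed read depth.

Depth is compared between an evolved clone, its ancestor, and the
selected spore pool on a shared window grid.  After median
normalization (which removes library-size differences) a clone/ancestor
ratio near 2 marks a duplication and a ratio well below 1 a deletion.
Causality is then read from the pool: an event that segregates
neutrally through the backcross is carried by half the selected spores,
so its pool ratio sits midway between ancestor and clone (1.5 for a
2.0x duplication), while an event retained by selection keeps the
clone's ratio in the pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from bsakit.errors import DataIntegrityError, InvalidInputError

GAIN_THRESHOLD = 1.5
LOSS_THRESHOLD = 0.75
MIN_WINDOWS = 3

NON_CAUSAL = "non_causal"
POSSIBLY_CAUSAL = "possibly_causal"


@dataclass
class DepthProfile:
    """Mean read depth per genomic window (BED-style 0-based half-open)."""

    windows: pd.DataFrame  # columns: chrom, start, end, depth
    window_bp: int

    def __post_init__(self):
        required = {"chrom", "start", "end", "depth"}
        if not required.issubset(self.windows.columns):
            raise InvalidInputError(f"depth profile needs columns {sorted(required)}")
        if (self.windows["depth"] < 0).any():
            raise InvalidInputError("depths must be non-negative")

    def median_depth(self) -> float:
        return float(self.windows["depth"].median())

    def grid(self) -> pd.DataFrame:
        return self.windows[["chrom", "start", "end"]]


@dataclass
class CNVCall:
    """One contiguous copy-number event with its clone/pool evidence."""

    chromosome: str
    start: int  # bp, 0-based half-open
    end: int
    clone_ratio: float
    call: str  # duplication | deletion
    n_windows: int
    pool_ratio: Optional[float] = None
    causality: Optional[str] = None


def depth_ratio(test: DepthProfile, reference: DepthProfile) -> pd.DataFrame:
    """Per-window ratio of median-normalized depths (test / reference).

    Profiles must share the window grid exactly.  Reference windows
    with zero depth yield NaN.
    """
    if test.window_bp != reference.window_bp or not test.grid().equals(reference.grid()):
        raise DataIntegrityError("depth profiles are on different window grids")
    t = test.windows["depth"].to_numpy(dtype=float) / test.median_depth()
    r = reference.windows["depth"].to_numpy(dtype=float) / reference.median_depth()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(r > 0, t / r, np.nan)
    out = test.grid().copy()
    out["ratio"] = ratio
    return out


def segment_cnv(
    ratio_track: pd.DataFrame,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    min_windows: int = MIN_WINDOWS,
) -> list[CNVCall]:
    """Merge maximal runs of threshold-crossing windows into CNV calls.

    A run of at least ``min_windows`` consecutive windows with ratio
    >= ``gain_threshold`` becomes a duplication call (<= ``loss_threshold``
    a deletion); boundaries sit at the first and last qualifying window.
    Missing (NaN) windows break runs.
    """
    calls: list[CNVCall] = []
    for chrom, sub in ratio_track.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        ratios = sub["ratio"].to_numpy(dtype=float)
        state = np.zeros(len(ratios), dtype=int)
        with np.errstate(invalid="ignore"):
            state[ratios >= gain_threshold] = 1
            state[ratios <= loss_threshold] = -1
        state[np.isnan(ratios)] = 0
        i = 0
        while i < len(state):
            if state[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(state) and state[j + 1] == state[i]:
                j += 1
            if j - i + 1 >= min_windows:
                calls.append(CNVCall(
                    chromosome=chrom,
                    start=int(sub["start"].iloc[i]),
                    end=int(sub["end"].iloc[j]),
                    clone_ratio=float(np.mean(ratios[i : j + 1])),
                    call="duplication" if state[i] == 1 else "deletion",
                    n_windows=j - i + 1,
                ))
            i = j + 1
    return calls


def assess_causality(call: CNVCall, pool_ratio_track: pd.DataFrame) -> str:
    """Decide whether a CNV was under selection from its pool depth ratio.

    For an event of clone ratio ``c`` the neutral-segregation
    expectation in the pool is ``(c + 1) / 2`` (half the selected spores
    carry it) and the causal expectation is ``c`` (all of them do).  The
    call is assigned to whichever expectation its mean pool ratio is
    closer to.
    """
    if abs(call.clone_ratio - 1.0) < 1e-9:
        raise InvalidInputError("clone ratio 1.0 is not a copy-number event")
    sub = pool_ratio_track[
        (pool_ratio_track["chrom"] == call.chromosome)
        & (pool_ratio_track["start"] < call.end)
        & (pool_ratio_track["end"] > call.start)
    ]
    if sub.empty:
        raise DataIntegrityError("pool ratio track does not cover the CNV call")
    pool = float(np.nanmean(sub["ratio"].to_numpy(dtype=float)))
    call.pool_ratio = pool
    neutral_expect = (call.clone_ratio + 1.0) / 2.0
    causal_expect = call.clone_ratio
    call.causality = (
        NON_CAUSAL if abs(pool - neutral_expect) <= abs(pool - causal_expect) else POSSIBLY_CAUSAL
    )
    return call.causality
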