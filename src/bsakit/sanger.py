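"""Allele frequencies from Sanger trace peak heights.

Commercial Sanger chromatograms report a peak height for each base at a
polymorphic position.  The mutant allele fraction is estimated as
``h_mut / (h_mut + h_anc)``.  In time-course mode, values below the ~5%
trace background are clamped to 0 and values above 95% to 1; in
segregation mode the raw, unclamped value is reported.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from bsakit.errors import InvalidInputError, MissingDataError

BACKGROUND_LEVEL = 0.05


def peak_fraction(h_mut: float, h_anc: float, clamp: bool = False) -> float:
    """Mutant allele fraction from a pair of peak heights.

    ``clamp=True`` applies the time-course background rule: fractions
    strictly below 0.05 become 0 and strictly above 0.95 become 1
    (exactly 0.05 / 0.95 are left as-is).  Both heights zero is
    uncallable.
    """
    if h_mut < 0 or h_anc < 0:
        raise InvalidInputError("peak heights must be non-negative")
    if h_mut + h_anc == 0:
        raise MissingDataError("both peak heights are zero; fraction uncallable")
    f = h_mut / (h_mut + h_anc)
    if clamp:
        if f < BACKGROUND_LEVEL:
            return 0.0
        if f > 1.0 - BACKGROUND_LEVEL:
            return 1.0
    return f


def build_timecourse(series: pd.DataFrame, clamp: bool = True) -> pd.DataFrame:
    """Per-allele frequency estimates across evolution time points.

    ``series`` is a tidy frame with columns allele, time_point, h_mut,
    h_anc.  Frequencies are computed with :func:`peak_fraction` (clamp
    mode by default); rows with missing heights are emitted with NaN
    frequency, never interpolated, and no smoothing is applied.
    """
    required = {"allele", "time_point", "h_mut", "h_anc"}
    if not required.issubset(series.columns):
        raise InvalidInputError(f"trace series needs columns {sorted(required)}")
    freqs = []
    for _, row in series.iterrows():
        if any(pd.isna(row[c]) for c in ("h_mut", "h_anc")):
            freqs.append(math.nan)
            continue
        freqs.append(peak_fraction(float(row["h_mut"]), float(row["h_anc"]), clamp=clamp))
    out = series[["allele", "time_point"]].copy()
    out["frequency"] = np.asarray(freqs)
    return out.sort_values(["allele", "time_point"]).reset_index(drop=True)
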