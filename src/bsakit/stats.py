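"""Small quantitative procedures used around the main pipeline.

Adjusted-Wald (Agresti-Coull-style) binomial confidence intervals for
small-n growth assays, the delta-delta-Ct method for relative qPCR
expression, serial-dilution-to-generations arithmetic, and the
qualitative competition scoring used in head-to-head fitness assays.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import norm

from bsakit.errors import InvalidInputError

logger = logging.getLogger(__name__)

MAJORITY_FRACTION = 0.75
ELIMINATION_SYMBOLS = {  # rounded mean elimination cycle -> magnitude
    1: 4, 2: 4,  # eliminated in 1-2 growth cycles
    3: 3, 4: 3,  # 3-4 cycles
    5: 2, 6: 2,  # 5-6 cycles
}


def adjusted_wald_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Adjusted-Wald binomial confidence interval, clipped to [0, 1].

    Adds two successes and two failures before applying the normal
    approximation: ``p~ = (x + 2) / (n + 4)`` with half-width
    ``z * sqrt(p~ (1 - p~) / (n + 4))``.  At 95% confidence ``z`` is
    fixed at 1.96; other levels use the exact normal quantile.
    """
    if trials <= 0:
        raise InvalidInputError("trials must be positive")
    if not 0 <= successes <= trials:
        raise InvalidInputError("successes must lie in [0, trials]")
    z = 1.96 if confidence == 0.95 else float(norm.ppf(1 - (1 - confidence) / 2))
    p = (successes + 2) / (trials + 4)
    half = z * math.sqrt(p * (1 - p) / (trials + 4))
    return max(0.0, p - half), min(1.0, p + half)


def ddct_fold_change(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the delta-delta-Ct method: ``2 ** -ddCt``."""
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def generations_from_dilutions(dilution_factors: Sequence[float]) -> tuple[float, int]:
    """Total generations implied by serial dilutions back to saturation.

    Each growth cycle that returns an ``f``-fold diluted culture to
    saturation takes ``log2(f)`` doublings.  Returns ``(total,
    rounded)``; e.g. one 100:1 plus three 500:1 dilutions give ~34
    generations and six 200:1 passages give 46.
    """
    if not dilution_factors:
        raise InvalidInputError("need at least one dilution factor")
    if any(f <= 1 for f in dilution_factors):
        raise InvalidInputError("dilution factors must exceed 1")
    total = sum(math.log2(f) for f in dilution_factors)
    return total, math.floor(total + 0.5)


@dataclass(frozen=True)
class CompetitionOutcome:
    """One replicate of a two-strain competition.

    Exactly one of ``cycles_to_elimination`` (with ``winner`` 1 or 2)
    or ``final_majority_fraction`` (strain 1's share after six growth
    cycles) is set.  Elimination means zero cells of one strain while
    more than 30 cells of the other are counted.
    """

    cycles_to_elimination: Optional[int] = None
    winner: Optional[int] = None
    final_majority_fraction: Optional[float] = None

    def __post_init__(self):
        eliminated = self.cycles_to_elimination is not None
        if eliminated == (self.final_majority_fraction is not None):
            raise InvalidInputError("set exactly one of elimination or final fraction")
        if eliminated:
            if self.winner not in (1, 2):
                raise InvalidInputError("elimination replicate needs winner 1 or 2")
            if not 1 <= self.cycles_to_elimination <= 6:
                raise InvalidInputError("cycles_to_elimination must be 1-6")
        elif not 0 <= self.final_majority_fraction <= 1:
            raise InvalidInputError("final fraction must be in [0, 1]")


def _symbol(magnitude: int, sign: int) -> str:
    if magnitude == 0:
        return "0"
    return ("+" if sign > 0 else "-") * magnitude


def score_competition(outcomes: Sequence[CompetitionOutcome]) -> str:
    """Map replicate competition outcomes to the qualitative fitness symbol.

    Elimination replicates dominate: the mean elimination cycle
    (rounded half-up over the majority winner's replicates) maps to
    ++++ (1-2 cycles), +++ (3-4), or ++ (5-6), signed by who won.
    Without eliminations, "+" ("-") requires strain 1 (2) to hold >75%
    of the population in at least two of three replicates; otherwise
    "0".  Replicates with eliminations in both directions trigger a
    warning and majority rule.
    """
    if not outcomes:
        raise InvalidInputError("need at least one replicate")
    elim = [o for o in outcomes if o.cycles_to_elimination is not None]
    if elim:
        wins1 = [o for o in elim if o.winner == 1]
        wins2 = [o for o in elim if o.winner == 2]
        if wins1 and wins2:
            logger.warning("eliminations in both directions; applying majority rule")
        if len(wins1) == len(wins2):
            return "0"
        winners = wins1 if len(wins1) > len(wins2) else wins2
        mean_cycle = sum(o.cycles_to_elimination for o in winners) / len(winners)
        rounded = min(6, max(1, math.floor(mean_cycle + 0.5)))
        return _symbol(ELIMINATION_SYMBOLS[rounded], +1 if winners is wins1 else -1)
    n = len(outcomes)
    needed = 2 if n == 3 else n // 2 + 1
    won1 = sum(1 for o in outcomes if o.final_majority_fraction > MAJORITY_FRACTION)
    won2 = sum(1 for o in outcomes if o.final_majority_fraction < 1 - MAJORITY_FRACTION)
    if won1 >= needed and won1 > won2:
        return "+"
    if won2 >= needed and won2 > won1:
        return "-"
    return "0"
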