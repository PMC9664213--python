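"""Modified-Delphi consensus statistics and round bookkeeping.

Panelists rate each proposition on a 5-point Likert scale (1 = completely
disagree, 5 = completely agree).  Predefined thresholds classify each
proposition:

* accept:  lower quartile >= 4, mean > 4, CV < 0.20
* reject:  upper quartile <= 2, mean < 2, CV < 0.20
* otherwise no consensus (revise and carry to the next round).

The CV is the coefficient of variation sd/mean; sd defaults to the sample
standard deviation (n-1 denominator) and quartiles default to linear
interpolation between order statistics — the common spreadsheet behavior —
but both conventions are switchable and recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

CV_THRESHOLD = 0.20


@dataclass(frozen=True)
class RatingSet:
    proposition_id: str
    round: int
    ratings: tuple[int, ...]

    def __post_init__(self):
        if not self.ratings:
            raise ValueError("ratings must be nonempty")
        bad = [r for r in self.ratings if not (isinstance(r, int) and 1 <= r <= 5)]
        if bad:
            raise ValueError(f"ratings outside the 1-5 Likert scale: {bad}")
        if self.round < 1:
            raise ValueError("round must be >= 1")


@dataclass(frozen=True)
class ConsensusStats:
    mean: float
    sd: float
    cv: float
    median: float
    q1: float
    q3: float
    iqr: float
    full_score_rate: float
    n: int
    sd_ddof: int = 1
    quartile_method: str = "linear"


ConsensusStatus = Literal["accept", "reject", "no_consensus"]


def compute_stats(r: RatingSet, sd_ddof: int = 1,
                  quartile_method: str = "linear") -> ConsensusStats:
    """Per-proposition descriptive statistics of one rating round."""
    x = np.asarray(r.ratings, dtype=float)
    mean = float(x.mean())
    sd = float(x.std(ddof=sd_ddof)) if len(x) > sd_ddof else 0.0
    q1, med, q3 = (float(v) for v in
                   np.percentile(x, [25, 50, 75], method=quartile_method))
    return ConsensusStats(
        mean=mean, sd=sd, cv=sd / mean, median=med, q1=q1, q3=q3,
        iqr=q3 - q1, full_score_rate=float((x == 5).mean()), n=len(x),
        sd_ddof=sd_ddof, quartile_method=quartile_method,
    )


def classify_consensus(s: ConsensusStats) -> ConsensusStatus:
    """Apply the predefined acceptance/rejection thresholds (CV strictly
    below 0.20 in both directions)."""
    if s.q3 <= 2 and s.mean < 2 and s.cv < CV_THRESHOLD:
        return "reject"
    if s.q1 >= 4 and s.mean > 4 and s.cv < CV_THRESHOLD:
        return "accept"
    return "no_consensus"


@dataclass(frozen=True)
class RoundResult:
    """Outcome of one survey round, after any human adjudication.

    ``carried`` propositions are revised and re-rated next round together
    with ``new_next_round`` newly proposed ones.  In a final round the
    non-consensus propositions are retained or deleted by human review;
    ``adjudicated_retained`` is that round's total retained count.
    """

    entered: int
    accepted: int = 0
    rejected: int = 0
    carried: int = 0
    new_next_round: int = 0
    adjudicated_retained: Optional[int] = None


@dataclass
class RoundLedger:
    rounds: list[RoundResult] = field(default_factory=list)
    final_retained: int = 0


class ConservationError(ValueError):
    """Round arithmetic does not balance."""


def tally_rounds(rounds: Sequence[RoundResult]) -> RoundLedger:
    """Check conservation and accumulate the final retained count.

    Each non-final round must satisfy entered = accepted + rejected +
    carried, and the next round must enter carried + new propositions.  The
    final retained count is the sum of accepted counts plus the last
    round's adjudicated retention.
    """
    if not rounds:
        raise ConservationError("no rounds supplied")
    total = 0
    for i, r in enumerate(rounds):
        is_final = i == len(rounds) - 1
        if is_final and r.adjudicated_retained is not None:
            if r.adjudicated_retained > r.entered:
                raise ConservationError(
                    f"round {i + 1}: retained {r.adjudicated_retained} exceeds "
                    f"entered {r.entered}")
            total += r.adjudicated_retained
            continue
        if r.accepted + r.rejected + r.carried != r.entered:
            raise ConservationError(
                f"round {i + 1}: entered {r.entered} != accepted {r.accepted} "
                f"+ rejected {r.rejected} + carried {r.carried}")
        total += r.accepted
        if not is_final:
            expected_next = r.carried + r.new_next_round
            if rounds[i + 1].entered != expected_next:
                raise ConservationError(
                    f"round {i + 2}: entered {rounds[i + 1].entered} != carried "
                    f"{r.carried} + new {r.new_next_round}")
    return RoundLedger(rounds=list(rounds), final_retained=total)


def preliminary_count(unique_propositions: int, excluded_without_evidence: int) -> int:
    """Preliminary criteria size: deduplicated propositions minus those
    lacking pediatric evidence."""
    n = unique_propositions - excluded_without_evidence
    if n < 0:
        raise ValueError("excluded exceeds unique propositions")
    return n


def panel_share_percent(k: int, n: int) -> int:
    """Share of panelists with an attribute, as a rounded whole percent."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    return round(100 * k / n)


def read_ratings(path) -> list[RatingSet]:
    """Load a ratings CSV (proposition_id, round, panelist_id, rating)."""
    df = pd.read_csv(path)
    needed = {"proposition_id", "round", "panelist_id", "rating"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"ratings file missing columns: {sorted(missing)}")
    out: list[RatingSet] = []
    for (pid, rnd), grp in df.groupby(["proposition_id", "round"], sort=True):
        ratings = []
        for i, v in zip(grp.index, grp["rating"]):
            iv = int(v)
            if iv != v or not 1 <= iv <= 5:
                raise ValueError(f"row {i}: rating {v!r} outside 1-5")
            ratings.append(iv)
        out.append(RatingSet(str(pid), int(rnd), tuple(ratings)))
    return out


def stats_table(rating_sets: Sequence[RatingSet], sd_ddof: int = 1,
                quartile_method: str = "linear") -> pd.DataFrame:
    """One output row per proposition per round, with stats and status."""
    rows = []
    for rs in rating_sets:
        s = compute_stats(rs, sd_ddof=sd_ddof, quartile_method=quartile_method)
        rows.append({
            "proposition_id": rs.proposition_id, "round": rs.round,
            "n": s.n, "mean": s.mean, "sd": s.sd, "cv": s.cv,
            "median": s.median, "q1": s.q1, "q3": s.q3, "iqr": s.iqr,
            "full_score_rate": s.full_score_rate,
            "status": classify_consensus(s),
            "quartile_method": s.quartile_method, "sd_ddof": s.sd_ddof,
        })
    return pd.DataFrame(rows)
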