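"""Behavioral tap-timing synchrony between a leader and a follower.

The leader's tap train is the rhythm baseline; each follower tap is matched to
its nearest leader tap and the signed difference (follower minus leader, so a
late follower is positive) summarizes how closely the follower tracks the
leader.  Before matching, trains are cleaned of double taps (inter-tap gaps
below 0.2 s) and extreme outliers (taps terminating a gap above 2 s), the two
exclusion rules applied to the study task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyResultError

__all__ = [
    "TapTrain",
    "CleanCounts",
    "MatchResult",
    "SyncSummary",
    "clean_taps",
    "match_taps",
    "synchronicity",
    "DOUBLE_TAP_GAP",
    "OUTLIER_GAP",
]

#: Inter-tap gaps below this many seconds mark the later tap as a double tap.
DOUBLE_TAP_GAP = 0.2
#: Inter-tap gaps above this many seconds mark the following tap as an outlier.
OUTLIER_GAP = 2.0


@dataclass
class TapTrain:
    """A strictly increasing train of tap times in seconds."""

    times: np.ndarray
    person: str = ""
    task: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size and not np.isfinite(self.times).all():
            raise ValueError("tap times must be finite")
        if self.times.size and self.times[0] < 0:
            raise ValueError("tap times must be non-negative")
        if self.times.size > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("tap times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class CleanCounts:
    n_double: int
    n_outlier: int


@dataclass
class MatchResult:
    """Follower-to-leader tap assignment.

    ``pairs`` holds (leader index, follower index) into the cleaned trains;
    ``diffs`` the signed follower-minus-leader differences in the same order.
    """

    pairs: list[tuple[int, int]]
    diffs: np.ndarray
    n_unmatched_leader: int
    n_unmatched_follower: int


@dataclass
class SyncSummary:
    """Relative tap synchronicity of a follower against the leader baseline."""

    mean_diff: float
    sd_diff: float
    n_matched: int
    n_excluded_double: int
    n_excluded_outlier: int
    n_unmatched: int
    person: str = ""
    task: str = ""

    def to_row(self) -> dict:
        return {
            "person": self.person,
            "task": self.task,
            "mean_diff_s": self.mean_diff,
            "sd_diff_s": self.sd_diff,
            "n_matched": self.n_matched,
            "n_excluded_double": self.n_excluded_double,
            "n_excluded_outlier": self.n_excluded_outlier,
            "n_unmatched": self.n_unmatched,
        }


def clean_taps(
    train: TapTrain,
    *,
    double_gap: float = DOUBLE_TAP_GAP,
    outlier_gap: float = OUTLIER_GAP,
) -> tuple[TapTrain, CleanCounts]:
    """Remove double taps and extreme-outlier taps from a train.

    Double taps: scanning left to right over the running cleaned train, any tap
    closer than ``double_gap`` to the previously kept tap is removed (the
    earlier tap of the pair is kept).  Outliers: on the resulting train, every
    tap terminating an inter-tap gap longer than ``outlier_gap`` is removed in
    one pass (removal does not cascade, so a legitimate tap after a removed one
    is kept).  The operation is idempotent.
    """
    times = train.times
    kept: list[float] = []
    n_double = 0
    for t in times:
        if kept and t - kept[-1] < double_gap:
            n_double += 1
            continue
        kept.append(t)
    arr = np.asarray(kept)
    if arr.size > 1:
        long_gap = np.diff(arr) > outlier_gap
        keep_mask = np.ones(arr.size, dtype=bool)
        keep_mask[1:] = ~long_gap
        n_outlier = int((~keep_mask).sum())
        arr = arr[keep_mask]
    else:
        n_outlier = 0
    cleaned = TapTrain(arr, person=train.person, task=train.task)
    return cleaned, CleanCounts(n_double=n_double, n_outlier=n_outlier)


def match_taps(leader: TapTrain, follower: TapTrain, *, window: float = 1.0) -> MatchResult:
    """Match follower taps to leader taps within ``+-window`` seconds.

    Candidate (leader, follower) pairs within the window are accepted greedily
    in ascending order of absolute time difference, each tap used at most once,
    so conflicts resolve toward the smallest total absolute difference.  Ties
    break on the earlier leader, then earlier follower, tap.
    """
    if len(leader) == 0 or len(follower) == 0:
        raise EmptyResultError("both trains must contain at least one tap")
    lt, ft = leader.times, follower.times
    candidates = []
    for fi, t in enumerate(ft):
        lo = np.searchsorted(lt, t - window, side="left")
        hi = np.searchsorted(lt, t + window, side="right")
        for li in range(lo, hi):
            candidates.append((abs(t - lt[li]), li, fi))
    candidates.sort()
    used_l = np.zeros(len(lt), dtype=bool)
    used_f = np.zeros(len(ft), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _, li, fi in candidates:
        if used_l[li] or used_f[fi]:
            continue
        used_l[li] = used_f[fi] = True
        pairs.append((li, fi))
    pairs.sort()
    diffs = np.asarray([ft[fi] - lt[li] for li, fi in pairs])
    return MatchResult(
        pairs=pairs,
        diffs=diffs,
        n_unmatched_leader=int((~used_l).sum()),
        n_unmatched_follower=int((~used_f).sum()),
    )


def synchronicity(
    leader: TapTrain,
    follower: TapTrain,
    *,
    window: float = 1.0,
    double_gap: float = DOUBLE_TAP_GAP,
    outlier_gap: float = OUTLIER_GAP,
) -> SyncSummary:
    """Clean both trains, match, and summarize signed follower-leader timing.

    Raises
    ------
    EmptyResultError
        If no follower tap could be matched to a leader tap.
    """
    lc, lcnt = clean_taps(leader, double_gap=double_gap, outlier_gap=outlier_gap)
    fc, fcnt = clean_taps(follower, double_gap=double_gap, outlier_gap=outlier_gap)
    if len(lc) == 0 or len(fc) == 0:
        raise EmptyResultError("no taps remain after cleaning")
    match = match_taps(lc, fc, window=window)
    if not match.pairs:
        raise EmptyResultError("no follower tap matched a leader tap")
    diffs = match.diffs
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    return SyncSummary(
        mean_diff=float(np.mean(diffs)),
        sd_diff=sd,
        n_matched=len(match.pairs),
        n_excluded_double=lcnt.n_double + fcnt.n_double,
        n_excluded_outlier=lcnt.n_outlier + fcnt.n_outlier,
        n_unmatched=match.n_unmatched_leader + match.n_unmatched_follower,
        person=follower.person,
        task=follower.task or leader.task,
    )
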