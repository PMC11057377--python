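"""Dyad-level classification and summaries of discovered causal graphs.

Links are partitioned into four classes by where their endpoints live:
within the leader's triad (``intra_leader``), within the follower's triad
(``intra_follower``), or across brains in either direction
(``leader_to_follower``, ``follower_to_leader``).  Magnitude summaries use
|MCI|; per node pair the significant lags are listed strongest first (ties
toward the smaller lag), the convention of the study's process graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pcmci import CausalGraph
from .series import MultichannelSeries

__all__ = ["DyadSystem", "DyadSummary", "classify_links", "summarize", "aggregate_pairs", "LINK_CLASSES"]

LINK_CLASSES = ("intra_leader", "intra_follower", "leader_to_follower", "follower_to_leader")

_PERSON_PREFIX = {"L": "leader", "F": "follower"}


@dataclass
class DyadSystem:
    """Role and channel metadata of a six-variable leader/follower system.

    Variable labels follow the ``L_``/``F_`` prefix convention (e.g. ``L_Fz``
    is the leader's midline prefrontal channel).
    """

    labels: list[str]
    person_of: dict[str, str]
    channel_of: dict[str, str]
    pair_id: str = ""
    task: str = ""
    series: MultichannelSeries | None = None

    @classmethod
    def from_labels(cls, labels, *, pair_id: str = "", task: str = "",
                    series: MultichannelSeries | None = None) -> "DyadSystem":
        person_of, channel_of = {}, {}
        for lab in labels:
            try:
                prefix, chan = lab.split("_", 1)
                person_of[lab] = _PERSON_PREFIX[prefix]
            except (ValueError, KeyError):
                raise ValueError(
                    f"label {lab!r} does not follow the L_/F_ channel convention"
                ) from None
            channel_of[lab] = chan
        for person in ("leader", "follower"):
            n = sum(1 for p in person_of.values() if p == person)
            if n != 3:
                raise ValueError(f"expected 3 channels for {person}, found {n}")
        return cls(labels=list(labels), person_of=person_of, channel_of=channel_of,
                   pair_id=pair_id, task=task, series=series)


@dataclass
class DyadSummary:
    """Per-class counts and |MCI| statistics of one dyad-task graph."""

    pair_id: str
    task: str
    n_significant: int
    counts: dict[str, int]
    abs_mci: dict[str, dict[str, float]]  # class -> {mean, sd, min, max}
    lag_lists: dict[tuple[str, str], list[int]]

    @property
    def n_intra_leader(self) -> int:
        return self.counts["intra_leader"]

    @property
    def n_intra_follower(self) -> int:
        return self.counts["intra_follower"]

    @property
    def n_leader_to_follower(self) -> int:
        return self.counts["leader_to_follower"]

    @property
    def n_follower_to_leader(self) -> int:
        return self.counts["follower_to_leader"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in LINK_CLASSES:
            stats = self.abs_mci.get(cls, {})
            rows.append(
                {
                    "pair_id": self.pair_id,
                    "task": self.task,
                    "link_class": cls,
                    "n_significant": self.counts[cls],
                    "abs_mci_mean": stats.get("mean", np.nan),
                    "abs_mci_sd": stats.get("sd", np.nan),
                    "abs_mci_min": stats.get("min", np.nan),
                    "abs_mci_max": stats.get("max", np.nan),
                }
            )
        return pd.DataFrame(rows)


def classify_links(graph: CausalGraph, system: DyadSystem) -> CausalGraph:
    """Annotate every link with its intra/inter-brain class."""
    unknown = set(graph.labels) - set(system.labels)
    if unknown:
        raise ValueError(f"graph variables {sorted(unknown)} not in the dyad system")
    new_links = []
    for link in graph.links:
        src_p = system.person_of[link.source]
        tgt_p = system.person_of[link.target]
        if src_p == tgt_p:
            cls = f"intra_{src_p}"
        elif src_p == "leader":
            cls = "leader_to_follower"
        else:
            cls = "follower_to_leader"
        new_links.append(replace(link, link_class=cls))
    return replace(graph, links=new_links)


def summarize(graph: CausalGraph, *, pair_id: str = "", task: str = "") -> DyadSummary:
    """Counts, |MCI| statistics per class and Figure-style lag lists.

    Only significant links enter counts, statistics and lag lists; classes
    with no significant link report zero counts and no statistics.
    """
    sig = graph.significant_links()
    if any(l.link_class is None for l in sig):
        raise ValueError("graph must be classified first (classify_links)")
    counts = {cls: 0 for cls in LINK_CLASSES}
    values: dict[str, list[float]] = {cls: [] for cls in LINK_CLASSES}
    by_pair: dict[tuple[str, str], list] = {}
    for link in sig:
        counts[link.link_class] += 1
        values[link.link_class].append(abs(link.mci))
        by_pair.setdefault((link.source, link.target), []).append(link)
    abs_mci = {}
    for cls, vals in values.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        abs_mci[cls] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    lag_lists = {
        pair: [l.lag for l in sorted(links, key=lambda l: (-abs(l.mci), l.lag))]
        for pair, links in sorted(by_pair.items())
    }
    return DyadSummary(
        pair_id=pair_id,
        task=task,
        n_significant=len(sig),
        counts=counts,
        abs_mci=abs_mci,
        lag_lists=lag_lists,
    )


def aggregate_pairs(summaries: list[DyadSummary]) -> pd.DataFrame:
    """Cohort table: per-class totals and per-summary mean/SD of link counts.

    Each summary is one dyad-task analysis whose leading person contributes
    that analysis's directed counts, so the per-class mean is the mean count
    per person-in-role across the cohort.
    """
    if not summaries:
        raise ValueError("need at least one summary to aggregate")
    rows = []
    for cls in LINK_CLASSES:
        counts = np.asarray([s.counts[cls] for s in summaries], dtype=float)
        rows.append(
            {
                "link_class": cls,
                "total": int(counts.sum()),
                "mean": float(counts.mean()),
                "sd": float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
                "n_analyses": len(summaries),
            }
        )
    return pd.DataFrame(rows)
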