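"""Two-step lag-resolved causal discovery: PC condition selection + MCI tests.

For an N-variable system observed at T time points, every pair (source
variable i at lag l, target variable j) with l in 1..tau_max is a candidate
causal link; contemporaneous (lag-0) links are excluded.  Discovery runs in
two steps:

1. **PC** — for each target, iteratively prune the full candidate-parent set
   by ParCorr tests conditioned on the q strongest surviving parents
   (q = 0, 1, 2, ... up to ``max_conds_dim``), removing candidates whose
   p-value exceeds ``pc_alpha``.  When ``pc_alpha`` is a list, the value
   minimizing the summed Gaussian least-squares AIC of the per-target parent
   regressions is chosen (ties to the smaller alpha, i.e. the sparser model).
2. **MCI** — every candidate link is re-tested conditioned on the target's
   selected parents (minus the link itself) plus the source's parents shifted
   back by the link lag.  This momentary-conditional-independence construction
   screens out indirect paths and common drivers, including the false lagged
   associations that plain correlation or Granger-style screening reports.

All MCI p-values form one family corrected by Benjamini-Hochberg FDR;
significance is ``qvalue <= fdr_alpha``.  Self-links (autodependencies) are
tested, reported and included in the FDR family, but flagged separately.

The estimator follows the scikit-learn protocol: ``PCMCI(...).fit(X)`` leaves
``parents_``, ``links_`` (a tidy DataFrame) and ``graph_`` (a
:class:`CausalGraph`) on the instance.  ``run_pcmci`` is the functional
wrapper.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .citest import CITestResult, parcorr_test
from .exceptions import DegenerateDataError
from .series import MultichannelSeries

__all__ = [
    "PCMCIConfig",
    "CausalLink",
    "CausalGraph",
    "ParentSet",
    "PCMCI",
    "pc_select",
    "select_alpha_by_aic",
    "mci_link_test",
    "run_pcmci",
    "bh_fdr",
]

#: Default alpha grid scanned when pc_alpha is requested as "aic".
DEFAULT_ALPHA_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class PCMCIConfig:
    """Tuning parameters of the two-step discovery."""

    tau_max: int = 5
    pc_alpha: float | tuple[float, ...] = 0.05
    fdr_alpha: float = 0.05
    max_conds_dim: int | None = 3
    max_parents_per_iter: int | None = None
    include_source_parents: bool = True

    def __post_init__(self):
        if self.tau_max < 1:
            raise ValueError("tau_max must be >= 1")
        alphas = self.alpha_list()
        if not alphas:
            raise ValueError("pc_alpha list must be non-empty")
        for a in alphas + [self.fdr_alpha]:
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha {a} outside (0, 1)")

    def alpha_list(self) -> list[float]:
        if np.isscalar(self.pc_alpha):
            return [float(self.pc_alpha)]
        return [float(a) for a in self.pc_alpha]


@dataclass
class ParentSet:
    """Selected lagged parents per target, ordered by |selection statistic|."""

    parents: dict[int, list[tuple[int, int]]]  # target -> [(source, lag), ...]
    stats: dict[int, dict[tuple[int, int], float]]


@dataclass
class CausalLink:
    """One lag-resolved directed link with its MCI test outcome."""

    source: str
    lag: int
    target: str
    mci: float
    pvalue: float
    qvalue: float
    significant: bool
    is_self: bool
    link_class: str | None = None


@dataclass
class CausalGraph:
    """All tested links of one system, with config echo."""

    labels: list[str]
    links: list[CausalLink]
    tau_max: int
    n_eff: int
    pc_alpha: float
    fdr_alpha: float
    params: dict = field(default_factory=dict)

    def significant_links(self) -> list[CausalLink]:
        return [l for l in self.links if l.significant]

    def to_frame(self) -> pd.DataFrame:
        cols = ["source", "lag", "target", "mci", "pvalue", "qvalue", "significant", "is_self", "link_class"]
        return pd.DataFrame([asdict(l) for l in self.links], columns=cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_json(self) -> str:
        payload = {
            "variables": self.labels,
            "tau_max": self.tau_max,
            "n_eff": self.n_eff,
            "pc_alpha": self.pc_alpha,
            "fdr_alpha": self.fdr_alpha,
            "links": [asdict(l) for l in self.links],
        }
        return json.dumps(payload, indent=2)

    def to_dot(self, *, significant_only: bool = True) -> str:
        """Graphviz DOT process graph: one edge per node pair, lag list as label.

        Lags are listed strongest |MCI| first (ties toward the smaller lag),
        the ordering convention of the study's process-graph figures.
        """
        colors = {
            "intra_leader": "steelblue",
            "intra_follower": "darkorange",
            "leader_to_follower": "forestgreen",
            "follower_to_leader": "firebrick",
            None: "gray30",
        }
        pairs: dict[tuple[str, str], list[CausalLink]] = {}
        for l in self.links:
            if significant_only and not l.significant:
                continue
            pairs.setdefault((l.source, l.target), []).append(l)
        lines = ["digraph causal {", "  rankdir=LR;"]
        for lab in self.labels:
            lines.append(f'  "{lab}";')
        for (src, tgt), ls in sorted(pairs.items()):
            ordered = sorted(ls, key=lambda l: (-abs(l.mci), l.lag))
            lags = ",".join(str(l.lag) for l in ordered)
            color = colors.get(ordered[0].link_class, "gray30")
            lines.append(f'  "{src}" -> "{tgt}" [label="{lags}", color={color}];')
        lines.append("}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# helpers


def _coerce(system) -> tuple[np.ndarray, list[str]]:
    if isinstance(system, MultichannelSeries):
        return np.asarray(system.values, dtype=float), list(system.labels)
    X = np.asarray(system, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a (T, N) array or MultichannelSeries")
    return X, [f"X{i}" for i in range(X.shape[1])]


def _standardize_system(X: np.ndarray, labels: list[str]) -> np.ndarray:
    sd = X.std(axis=0)
    if (sd < 1e-15).any():
        bad = labels[int(np.argmin(sd))]
        raise DegenerateDataError(f"channel {bad!r} has zero variance")
    return (X - X.mean(axis=0)) / sd


def _lagged(X: np.ndarray, var: int, lag: int, t0: int) -> np.ndarray:
    """Column of variable ``var`` lagged by ``lag``, aligned to targets at t0..T-1."""
    T = X.shape[0]
    return X[t0 - lag : T - lag, var]


def _check_stationarity(X: np.ndarray, labels: list[str], threshold: float = 0.5) -> None:
    """Warn if the two series halves differ in mean or variance.

    The absolute standardized difference of half-means (in units of the full
    SD) and of half-variances (relative to the full variance) must stay below
    ``threshold``; violations warn rather than abort, mirroring analyses that
    rely on visual stationarity checks.
    """
    T = X.shape[0]
    a, b = X[: T // 2], X[T // 2 :]
    sd = X.std(axis=0)
    var = sd**2
    d_mean = np.abs(a.mean(axis=0) - b.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    d_var = np.abs(a.var(axis=0) - b.var(axis=0)) / np.where(var > 0, var, 1.0)
    for k in np.nonzero((d_mean > threshold) | (d_var > threshold))[0]:
        warnings.warn(
            f"channel {labels[k]!r} may be nonstationary: half-split mean shift "
            f"{d_mean[k]:.2f} SD, variance shift {d_var[k]:.2f}",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# PC condition selection


def _pc_one_target(
    X: np.ndarray, j: int, cfg: PCMCIConfig, alpha: float
) -> tuple[list[tuple[int, int]], dict[tuple[int, int], float]]:
    T, N = X.shape
    tau = cfg.tau_max
    t0 = tau
    n_eff = T - tau
    y = X[t0:, j]
    cols = {(i, l): _lagged(X, i, l, t0) for i in range(N) for l in range(1, tau + 1)}

    stats: dict[tuple[int, int], float] = {}
    parents: list[tuple[int, int]] = []
    for cand, col in cols.items():
        res = parcorr_test(col, y, None, n_eff=n_eff)
        if res.pvalue <= alpha:
            stats[cand] = res.stat
            parents.append(cand)
    parents.sort(key=lambda c: (-abs(stats[c]), c))

    max_q = cfg.max_conds_dim if cfg.max_conds_dim is not None else N * tau
    for q in range(1, max_q + 1):
        if len(parents) - 1 < q:
            break
        order = list(parents)  # conditioning sets frozen at iteration start
        survivors = []
        for cand in order:
            others = [p for p in order if p != cand][:q]
            Z = np.column_stack([cols[o] for o in others])
            res = parcorr_test(cols[cand], y, Z, n_eff=n_eff)
            if res.pvalue <= alpha:
                stats[cand] = res.stat
                survivors.append(cand)
        survivors.sort(key=lambda c: (-abs(stats[c]), c))
        if cfg.max_parents_per_iter is not None:
            survivors = survivors[: cfg.max_parents_per_iter]
        parents = survivors
    return parents, {c: stats[c] for c in parents}


def pc_select(system, cfg: PCMCIConfig | None = None, *, alpha: float | None = None) -> ParentSet:
    """PC condition-selection step: candidate parents per target variable.

    Candidates start as all (variable, lag) pairs with lag in 1..tau_max and
    are pruned by iterated conditional tests; the surviving parents are
    returned ordered by |test statistic| descending.
    """
    cfg = cfg or PCMCIConfig()
    X, labels = _coerce(system)
    _validate_length(X, cfg.tau_max)
    X = _standardize_system(X, labels)
    a = float(alpha) if alpha is not None else cfg.alpha_list()[0]
    parents, stats = {}, {}
    for j in range(X.shape[1]):
        parents[j], stats[j] = _pc_one_target(X, j, cfg, a)
    return ParentSet(parents=parents, stats=stats)


def _validate_length(X: np.ndarray, tau_max: int) -> None:
    if X.shape[0] <= 10 * tau_max:
        raise ValueError(f"need T > 10 * tau_max = {10 * tau_max} samples, got {X.shape[0]}")


def _aic_of_parents(X: np.ndarray, parents: dict[int, list[tuple[int, int]]], tau_max: int) -> float:
    """Summed Gaussian least-squares AIC of the per-target parent regressions."""
    T = X.shape[0]
    t0 = tau_max
    n_eff = T - tau_max
    total = 0.0
    for j, pset in parents.items():
        y = X[t0:, j]
        design = [np.ones(n_eff)] + [_lagged(X, i, l, t0) for i, l in pset]
        D = np.column_stack(design)
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        rss = float(((y - D @ beta) ** 2).sum())
        k = len(pset) + 1  # parents + intercept
        total += n_eff * np.log(max(rss, 1e-300) / n_eff) + 2 * k
    return total


def select_alpha_by_aic(system, cfg: PCMCIConfig | None = None) -> tuple[float, ParentSet]:
    """Run PC per candidate alpha; keep the alpha minimizing the summed AIC.

    Ties break toward the smallest alpha (the sparser graph).
    """
    cfg = cfg or PCMCIConfig(pc_alpha=DEFAULT_ALPHA_GRID)
    alphas = cfg.alpha_list()
    X, labels = _coerce(system)
    _validate_length(X, cfg.tau_max)
    Xz = _standardize_system(X, labels)
    best: tuple[float, float, ParentSet] | None = None
    for a in sorted(alphas):
        parents, stats = {}, {}
        for j in range(Xz.shape[1]):
            parents[j], stats[j] = _pc_one_target(Xz, j, cfg, a)
        aic = _aic_of_parents(Xz, parents, cfg.tau_max)
        if best is None or aic < best[0] - 1e-12:
            best = (aic, a, ParentSet(parents=parents, stats=stats))
    return best[1], best[2]


# ---------------------------------------------------------------------------
# MCI


def _mci_condition_set(
    parents: ParentSet, source: tuple[int, int], target: int, include_source_parents: bool
) -> list[tuple[int, int]]:
    i, l = source
    conds = [p for p in parents.parents.get(target, []) if p != (i, l)]
    if include_source_parents:
        for k, m in parents.parents.get(i, []):
            shifted = (k, m + l)
            if shifted not in conds:
                conds.append(shifted)
    return conds


def _mci_one(
    X: np.ndarray,
    parents: ParentSet,
    source: tuple[int, int],
    target: int,
    cfg: PCMCIConfig,
) -> CITestResult:
    T = X.shape[0]
    i, l = source
    t0 = 2 * cfg.tau_max  # source parents shift back up to tau_max further
    n_eff = T - t0
    conds = _mci_condition_set(parents, source, target, cfg.include_source_parents)
    y = X[t0:, target]
    xs = _lagged(X, i, l, t0)
    Z = np.column_stack([_lagged(X, k, m, t0) for k, m in conds]) if conds else None
    return parcorr_test(xs, y, Z, n_eff=n_eff)


def mci_link_test(system, parents: ParentSet, source: tuple[int, int], target: int,
                  cfg: PCMCIConfig | None = None) -> CITestResult:
    """Momentary-conditional-independence test of one lagged link.

    The source X_i(t-l) is tested against the target X_j(t) conditioned on the
    target's parents (excluding the link itself) and the source's parents each
    shifted back by l.  With both parent sets empty this reduces to the plain
    lagged correlation test.
    """
    cfg = cfg or PCMCIConfig()
    X, labels = _coerce(system)
    _validate_length(X, cfg.tau_max)
    X = _standardize_system(X, labels)
    if not 1 <= source[1] <= cfg.tau_max:
        raise ValueError(f"lag {source[1]} outside 1..{cfg.tau_max}")
    return _mci_one(X, parents, source, target, cfg)


# ---------------------------------------------------------------------------
# FDR


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in the input order.

    ``q_(i) = min_{j >= i} (p_(j) * m / j)``, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# estimator


class PCMCI(BaseEstimator):
    """Scikit-learn style estimator for lag-resolved causal graph discovery.

    Parameters
    ----------
    tau_max : int
        Maximum lag considered as a candidate cause (lags 1..tau_max).
    pc_alpha : float, sequence of float, or "aic"
        Significance level of the PC pruning step.  A sequence (or "aic",
        meaning the default grid) triggers AIC-based selection.
    fdr_alpha : float
        FDR level of the Benjamini-Hochberg correction over all tested links.
    max_conds_dim : int or None
        Largest conditioning-set size in the PC step (None: unlimited).
    max_parents_per_iter : int or None
        Cap on parents retained after each PC iteration (None: unlimited).
    include_source_parents : bool
        Condition MCI tests on the source's shifted parents (standard MCI);
        False conditions on the target's parents only.
    check_stationarity : bool
        Warn when the two series halves differ in mean or variance.

    Attributes
    ----------
    labels_ : list of str
        Variable names.
    pc_alpha_ : float
        The alpha actually used (after AIC selection if requested).
    parents_ : ParentSet
        Selected condition sets per target.
    links_ : pandas.DataFrame
        One row per tested (source, lag, target) triple.
    graph_ : CausalGraph
        The same links as a graph object with exports.
    n_eff_ : int
        Effective sample count of the MCI tests.
    """

    def __init__(
        self,
        tau_max: int = 5,
        pc_alpha=0.05,
        fdr_alpha: float = 0.05,
        max_conds_dim: int | None = 3,
        max_parents_per_iter: int | None = None,
        include_source_parents: bool = True,
        check_stationarity: bool = True,
    ):
        self.tau_max = tau_max
        self.pc_alpha = pc_alpha
        self.fdr_alpha = fdr_alpha
        self.max_conds_dim = max_conds_dim
        self.max_parents_per_iter = max_parents_per_iter
        self.include_source_parents = include_source_parents
        self.check_stationarity = check_stationarity

    def _config(self) -> PCMCIConfig:
        pc_alpha = self.pc_alpha
        if isinstance(pc_alpha, str):
            if pc_alpha.lower() != "aic":
                raise ValueError("pc_alpha must be a float, a sequence, or 'aic'")
            pc_alpha = DEFAULT_ALPHA_GRID
        return PCMCIConfig(
            tau_max=self.tau_max,
            pc_alpha=pc_alpha,
            fdr_alpha=self.fdr_alpha,
            max_conds_dim=self.max_conds_dim,
            max_parents_per_iter=self.max_parents_per_iter,
            include_source_parents=self.include_source_parents,
        )

    def fit(self, X, y=None):
        """Discover the causal graph of a (T, N) system.

        ``X`` may be an array or a :class:`MultichannelSeries`; columns are
        standardized internally.  The fit is deterministic given the data.
        """
        cfg = self._config()
        Xv, labels = _coerce(X)
        _validate_length(Xv, cfg.tau_max)
        if not np.isfinite(Xv).all():
            raise ValueError("system contains non-finite values")
        if self.check_stationarity:
            _check_stationarity(Xv, labels)
        Xz = _standardize_system(Xv, labels)

        alphas = cfg.alpha_list()
        if len(alphas) > 1:
            chosen, parents = select_alpha_by_aic(Xz, cfg)
        else:
            chosen = alphas[0]
            ps, st = {}, {}
            for j in range(Xz.shape[1]):
                ps[j], st[j] = _pc_one_target(Xz, j, cfg, chosen)
            parents = ParentSet(parents=ps, stats=st)

        N = Xz.shape[1]
        records: list[tuple[int, int, int, CITestResult]] = []
        for j in range(N):
            for i in range(N):
                for l in range(1, cfg.tau_max + 1):
                    res = _mci_one(Xz, parents, (i, l), j, cfg)
                    records.append((i, l, j, res))
        qvals = bh_fdr([r.pvalue for *_, r in records])

        links = [
            CausalLink(
                source=labels[i],
                lag=l,
                target=labels[j],
                mci=res.stat,
                pvalue=res.pvalue,
                qvalue=float(q),
                significant=bool(q <= cfg.fdr_alpha),
                is_self=(i == j),
            )
            for (i, l, j, res), q in zip(records, qvals)
        ]
        self.labels_ = labels
        self.pc_alpha_ = float(chosen)
        self.parents_ = parents
        self.n_eff_ = Xv.shape[0] - 2 * cfg.tau_max
        self.graph_ = CausalGraph(
            labels=labels,
            links=links,
            tau_max=cfg.tau_max,
            n_eff=self.n_eff_,
            pc_alpha=self.pc_alpha_,
            fdr_alpha=cfg.fdr_alpha,
            params=self.get_params(),
        )
        self.links_ = self.graph_.to_frame()
        return self

    def significant_links_(self) -> pd.DataFrame:
        return self.links_[self.links_["significant"]]


def run_pcmci(system, cfg: PCMCIConfig | None = None, **kwargs) -> CausalGraph:
    """Functional wrapper: discover the causal graph of a system.

    Accepts a :class:`PCMCIConfig` or the estimator's keyword parameters.
    """
    if cfg is not None:
        kwargs = dict(
            tau_max=cfg.tau_max,
            pc_alpha=cfg.pc_alpha,
            fdr_alpha=cfg.fdr_alpha,
            max_conds_dim=cfg.max_conds_dim,
            max_parents_per_iter=cfg.max_parents_per_iter,
            include_source_parents=cfg.include_source_parents,
            **kwargs,
        )
    est = PCMCI(**kwargs)
    est.fit(system)
    return est.graph_
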