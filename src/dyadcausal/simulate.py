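"""Synthetic dyadic ground truth: stable VAR systems and leader/follower taps.

The generator realizes exactly the assumptions the causal analysis makes —
stationary, linear, Gaussian, no missing values — so every downstream stage can
be scored against planted structure.  A dyad is the six-variable system of two
persons' prefrontal triads (channels F3, Fz, F4), labelled ``L_F3 .. F_F4``
with ``L``/``F`` for leader/follower, coupled by lagged linear links at lags
1..5.

The coefficient tensor is indexed ``coeffs[lag-1][target][source]``: the VAR
recursion is ``x_t = sum_l A_l x_{t-l} + eps_t`` with independent Gaussian
innovations.  Stability (companion spectral radius < 1) is enforced; the
generator refuses unstable specifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import StabilityError
from .series import MultichannelSeries
from .tapping import TapTrain

__all__ = [
    "VARSpec",
    "TapGenConfig",
    "TapSimResult",
    "DYAD_LABELS",
    "simulate_var",
    "make_dyad_spec",
    "simulate_taps",
]

CHANNELS = ("F3", "Fz", "F4")
PERSONS = ("leader", "follower")
#: Variable order of a dyad system: leader triad then follower triad.
DYAD_LABELS = ("L_F3", "L_Fz", "L_F4", "F_F3", "F_Fz", "F_F4")


@dataclass
class VARSpec:
    """Ground-truth lagged coefficient tensor plus noise model.

    Attributes
    ----------
    coeffs : ndarray of shape (max_lag, n_vars, n_vars)
        ``coeffs[l-1, j, i]`` is the coefficient of variable ``i`` at lag ``l``
        in the equation of target ``j`` (dimensionless).
    noise_sd : ndarray of shape (n_vars,)
        Innovation standard deviations, all positive.
    labels : list of str
        Variable names.
    """

    coeffs: np.ndarray
    noise_sd: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (max_lag, n_vars, n_vars)")
        n = self.coeffs.shape[1]
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (n,)
        ).copy()
        if not (self.noise_sd > 0).all():
            raise ValueError("noise_sd must be positive for every variable")
        if not self.labels:
            self.labels = [f"X{i}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("one label per variable required")

    @property
    def n_vars(self) -> int:
        return self.coeffs.shape[1]

    @property
    def max_lag(self) -> int:
        return self.coeffs.shape[0]

    def companion_matrix(self) -> np.ndarray:
        """Companion form of the VAR: (n*L) x (n*L) block matrix."""
        n, L = self.n_vars, self.max_lag
        comp = np.zeros((n * L, n * L))
        comp[:n] = np.concatenate(list(self.coeffs), axis=1)
        if L > 1:
            comp[n:, : n * (L - 1)] = np.eye(n * (L - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion_matrix()))))

    def is_stable(self, tol: float = 1e-10) -> bool:
        return self.spectral_radius() < 1.0 - tol

    def check_stable(self) -> None:
        rho = self.spectral_radius()
        if not rho < 1.0 - 1e-10:
            raise StabilityError(rho)

    def links(self) -> list[tuple[str, int, str, float]]:
        """Nonzero couplings as (source_label, lag, target_label, coeff)."""
        out = []
        for l, j, i in zip(*np.nonzero(self.coeffs)):
            out.append((self.labels[i], int(l) + 1, self.labels[j], float(self.coeffs[l, j, i])))
        return out

    def to_config(self) -> dict:
        """Flat serializable form (nonzero coefficients listed individually)."""
        return {
            "n_vars": self.n_vars,
            "max_lag": self.max_lag,
            "labels": list(self.labels),
            "noise_sd": [float(s) for s in self.noise_sd],
            "coeffs": [
                {"source": s, "lag": l, "target": t, "value": v}
                for s, l, t, v in self.links()
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "VARSpec":
        n, L = int(cfg["n_vars"]), int(cfg["max_lag"])
        labels = [str(s) for s in cfg["labels"]]
        idx = {s: i for i, s in enumerate(labels)}
        coeffs = np.zeros((L, n, n))
        for entry in cfg.get("coeffs", []):
            coeffs[int(entry["lag"]) - 1, idx[entry["target"]], idx[entry["source"]]] = float(
                entry["value"]
            )
        return cls(coeffs=coeffs, noise_sd=np.asarray(cfg["noise_sd"], dtype=float), labels=labels)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VARSpec":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


def simulate_var(
    spec: VARSpec,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    burn_in: int = 1000,
) -> MultichannelSeries:
    """Draw a length-``n_samples`` realization of a stable VAR process.

    The recursion is initialized at zero and run for ``burn_in`` extra steps
    that are discarded, erasing initial-condition transients.  Reproducible
    under a fixed integer seed.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if n_samples < 10 * spec.max_lag:
        raise ValueError(f"n_samples must be at least 10 * max_lag = {10 * spec.max_lag}")
    if burn_in < 100:
        raise ValueError("burn_in must be at least 100")
    spec.check_stable()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, L = spec.n_vars, spec.max_lag
    total = n_samples + burn_in + L
    eps = rng.normal(0.0, spec.noise_sd, size=(total, n))
    x = np.zeros((total, n))
    A = spec.coeffs  # (L, n, n)
    for t in range(L, total):
        acc = eps[t]
        for l in range(L):
            acc = acc + A[l] @ x[t - l - 1]
        x[t] = acc
    return MultichannelSeries(values=x[L + burn_in :], labels=list(spec.labels), fs=100.0)


def make_dyad_spec(
    intra_links: list[tuple[str, str, str, int, float]] = (),
    inter_links: list[tuple[str, str, str, str, int, float]] = (),
    autocorr: float = 0.4,
    noise_sd: float = 1.0,
    max_lag: int = 5,
) -> VARSpec:
    """Build the six-variable leader/follower VAR specification.

    Parameters
    ----------
    intra_links : iterable of (person, source_chan, target_chan, lag, coeff)
        Within-brain couplings; person in {"leader", "follower"}, channels in
        {"F3", "Fz", "F4"}, lag in 1..max_lag.
    inter_links : iterable of (source_person, source_chan, target_person, target_chan, lag, coeff)
        Between-brain couplings.
    autocorr : float
        Lag-1 self-coupling applied to every variable's diagonal.
    """
    labels = list(DYAD_LABELS)
    prefix = {"leader": "L", "follower": "F"}

    def var_index(person: str, chan: str) -> int:
        if person not in PERSONS:
            raise ValueError(f"unknown person {person!r}; expected one of {PERSONS}")
        chan_norm = {c.lower(): c for c in CHANNELS}.get(str(chan).lower())
        if chan_norm is None:
            raise ValueError(f"unknown channel {chan!r}; expected one of {CHANNELS}")
        return labels.index(f"{prefix[person]}_{chan_norm}")

    coeffs = np.zeros((max_lag, len(labels), len(labels)))
    coeffs[0][np.diag_indices(len(labels))] = autocorr

    def check_lag(lag: int) -> int:
        lag = int(lag)
        if not 1 <= lag <= max_lag:
            raise ValueError(f"lag {lag} outside 1..{max_lag}")
        return lag

    for person, src_chan, tgt_chan, lag, coeff in intra_links:
        coeffs[check_lag(lag) - 1, var_index(person, tgt_chan), var_index(person, src_chan)] += coeff
    for sp, sc, tp, tc, lag, coeff in inter_links:
        coeffs[check_lag(lag) - 1, var_index(tp, tc), var_index(sp, sc)] += coeff

    spec = VARSpec(coeffs=coeffs, noise_sd=noise_sd, labels=labels)
    spec.check_stable()
    return spec


@dataclass
class TapGenConfig:
    """Configuration of the leader/follower tap simulator.

    The default rhythm is a seven-tap pattern within a 6 s cycle repeated five
    times, mirroring the study task; the follower echoes each leader tap after
    ``reaction_delay`` seconds plus Gaussian jitter.  Contamination: with
    probability ``double_tap_prob`` a spurious extra tap ``double_tap_gap``
    seconds after a follower tap (a double tap, gap < 0.2 s); with probability
    ``outlier_prob`` per genuine tap a stray tap preceded by an
    ``outlier_gap`` (> 2 s) silence appended after the train.
    """

    rhythm: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 2.5, 3.5, 4.5)
    cycle_len: float = 6.0
    n_cycles: int = 5
    start_time: float = 1.0  # first cycle onset; keeps anticipatory taps positive
    reaction_delay: float = 0.16
    jitter_sd: float = 0.02
    double_tap_prob: float = 0.0
    double_tap_gap: float = 0.1
    outlier_prob: float = 0.0
    outlier_gap: float = 2.5
    seed: int = 0

    def __post_init__(self):
        r = np.asarray(self.rhythm, dtype=float)
        if r.size == 0 or (np.diff(r) <= 0).any():
            raise ValueError("rhythm must be non-empty and strictly increasing")
        if r[0] < 0 or r[-1] >= self.cycle_len:
            raise ValueError("rhythm offsets must lie within [0, cycle_len)")
        for name in ("double_tap_prob", "outlier_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.double_tap_gap < 0.2:
            raise ValueError("double_tap_gap must be in (0, 0.2) s")
        if not self.outlier_gap > 2.0:
            raise ValueError("outlier_gap must exceed 2 s")
        if self.jitter_sd < 0 or self.reaction_delay < 0:
            raise ValueError("jitter_sd and reaction_delay must be non-negative")
        if self.start_time < 0:
            raise ValueError("start_time must be non-negative")


@dataclass
class TapSimResult:
    """Simulated trains plus the ground-truth leader/follower tap pairing.

    ``matches`` maps (leader index, follower index) into the returned trains
    for every genuine follower tap, so a matcher can be scored exactly.
    """

    leader: TapTrain
    follower: TapTrain
    matches: list[tuple[int, int]]
    n_doubles_planted: int
    n_outliers_planted: int


def simulate_taps(cfg: TapGenConfig) -> TapSimResult:
    """Generate a leader train and a contaminated follower train."""
    rng = np.random.default_rng(cfg.seed)
    rhythm = np.asarray(cfg.rhythm, dtype=float)
    leader_times = np.concatenate(
        [cfg.start_time + c * cfg.cycle_len + rhythm for c in range(cfg.n_cycles)]
    )
    jitter = rng.normal(0.0, cfg.jitter_sd, size=leader_times.size) if cfg.jitter_sd > 0 else 0.0
    genuine = leader_times + cfg.reaction_delay + jitter
    # (time, leader index or None) records, genuine first, then contamination
    records: list[tuple[float, int | None]] = [(t, i) for i, t in enumerate(genuine)]
    n_doubles = 0
    for t in genuine:
        if rng.random() < cfg.double_tap_prob:
            records.append((t + cfg.double_tap_gap, None))
            n_doubles += 1
    n_outliers = int((rng.random(genuine.size) < cfg.outlier_prob).sum())
    tail = max(leader_times[-1], max(t for t, _ in records))
    for k in range(n_outliers):
        records.append((tail + (k + 1) * (cfg.outlier_gap + 0.5), None))
    records.sort()
    follower_times = np.asarray([t for t, _ in records])
    if (np.diff(follower_times) <= 0).any():
        raise ValueError(
            "simulated follower taps collide; reduce jitter_sd relative to rhythm gaps"
        )
    matches = [(li, fi) for fi, (_, li) in enumerate(records) if li is not None]
    return TapSimResult(
        leader=TapTrain(leader_times, person="leader"),
        follower=TapTrain(follower_times, person="follower"),
        matches=matches,
        n_doubles_planted=n_doubles,
        n_outliers_planted=n_outliers,
    )
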