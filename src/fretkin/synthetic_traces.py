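"""Continuous-time Markov simulation of smFRET trajectories.

The generator replaces the microscope: it samples exact-event (Gillespie)
state paths from a first-order rate matrix, integrates them into camera
frames, and emits two-channel donor/acceptor intensities with Gaussian
noise, background, donor bleedthrough and optional photobleaching.

Kinetic states may be *degenerate*: several states can share one FRET
emission level and are then distinguishable only through their exit
kinetics.  The canonical example is a linear three-state binding scheme

    0 (unbound, zero FRET)  <->  1 (bound)  <->  2 (bound, ion-locked)

where states 1 and 2 both emit at the high-FRET level (~0.75).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RateModel",
    "EmissionModel",
    "StatePath",
    "FretTrace",
    "stationary_distribution",
    "sample_state_path",
    "bin_to_frames",
    "emit_intensities",
    "simulate_ensemble",
    "two_state_model",
    "three_state_model",
]

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class RateModel:
    """First-order kinetic scheme with per-state FRET emission levels.

    Parameters
    ----------
    state_labels : tuple of str
        Ordered state names, e.g. ``("0", "1", "2")``.
    K : ndarray, shape (n, n)
        Rate matrix in 1/s. Off-diagonal ``K[i, j]`` is the rate from state
        *i* to state *j*; each diagonal entry is minus its row sum, so every
        row sums to zero.
    emission_level : tuple of float
        Mean FRET efficiency emitted by each state.
    degenerate_groups : tuple of tuple of int
        Partition of state indices; states within one group share a single
        emission level.
    """

    state_labels: tuple
    K: np.ndarray
    emission_level: tuple
    degenerate_groups: tuple

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        object.__setattr__(self, "K", K)
        n = len(self.state_labels)
        if K.shape != (n, n):
            raise ValueError(f"K must be {n}x{n}, got {K.shape}")
        off = K - np.diag(np.diag(K))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.any(np.abs(K.sum(axis=1)) > 1e-9):
            raise ValueError("rows of K must sum to 0")
        seen = sorted(i for g in self.degenerate_groups for i in g)
        if seen != list(range(n)):
            raise ValueError("degenerate_groups must partition the state set")
        for g in self.degenerate_groups:
            levels = {self.emission_level[i] for i in g}
            if len(levels) != 1:
                raise ValueError(f"states {g} in one group have different levels")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def to_dict(self) -> dict:
        return {
            "state_labels": list(self.state_labels),
            "K": self.K.tolist(),
            "emission_level": list(self.emission_level),
            "degenerate_groups": [list(g) for g in self.degenerate_groups],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateModel":
        return cls(
            state_labels=tuple(d["state_labels"]),
            K=np.asarray(d["K"], dtype=float),
            emission_level=tuple(d["emission_level"]),
            degenerate_groups=tuple(tuple(g) for g in d["degenerate_groups"]),
        )


def two_state_model(k01: float, k10: float, level_high: float = 0.75) -> RateModel:
    """Reversible two-state binding scheme (0: unbound, 1: bound)."""
    K = np.array([[-k01, k01], [k10, -k10]])
    return RateModel(("0", "1"), K, (0.0, level_high), ((0,), (1,)))


def three_state_model(
    k01: float, k10: float, k12: float, k21: float, level_high: float = 0.75
) -> RateModel:
    """Linear three-state scheme with a twofold degenerate high-FRET level.

    State 0 is unbound (zero FRET); states 1 and 2 are bound and emit the
    same high-FRET level; 0<->2 transitions are forbidden. The (2, 1) entry
    carries the back-exchange rate ``k21`` so that the generator has a
    proper reversible structure (see methods note on the rate-matrix
    convention).
    """
    K = np.array(
        [
            [-k01, k01, 0.0],
            [k10, -(k10 + k12), k12],
            [0.0, k21, -k21],
        ]
    )
    return RateModel(("0", "1", "2"), K, (0.0, level_high, level_high), ((0,), (1, 2)))


@dataclass(frozen=True)
class EmissionModel:
    """Camera/detection model mapping FRET levels to channel intensities.

    ``fret_noise_sd`` is the standard deviation of the *apparent* FRET
    efficiency recomputed from the noisy channels; noise is applied as an
    anti-correlated perturbation of the two channels so this holds exactly.
    """

    total_intensity: float = 1000.0
    fret_noise_sd: float = 0.10
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    bleedthrough: float = 0.0
    bleach_rate: float | None = None

    def __post_init__(self):
        if min(self.total_intensity, self.fret_noise_sd, self.background_donor,
               self.background_acceptor, self.bleedthrough) < 0:
            raise ValueError("emission parameters must be non-negative")
        if self.bleedthrough >= 1:
            raise ValueError("bleedthrough must be < 1")
        if self.bleach_rate is not None and self.bleach_rate < 0:
            raise ValueError("bleach_rate must be non-negative")


@dataclass(frozen=True)
class StatePath:
    """Exact-event state path: segments tiling [0, duration]."""

    times: np.ndarray  # segment start times, strictly increasing, times[0] == 0
    states: np.ndarray  # state index per segment
    duration: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)
        if len(t) != len(s) or len(t) == 0:
            raise ValueError("times and states must be equal-length, non-empty")
        if t[0] != 0 or np.any(np.diff(t) <= 0) or (len(t) > 1 and t[-1] >= self.duration):
            raise ValueError("segment times must start at 0 and increase within duration")

    def segment_durations(self) -> np.ndarray:
        edges = np.append(self.times, self.duration)
        return np.diff(edges)


@dataclass
class FretTrace:
    """One molecule's per-frame intensities and derived FRET efficiency."""

    dt: float
    donor: np.ndarray
    acceptor: np.ndarray
    fret: np.ndarray | None = None
    truth_state: np.ndarray | None = None
    trace_id: str = "trace0"
    extras: dict = field(default_factory=dict)  # unknown file columns, preserved

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = len(self.donor)
        if len(self.acceptor) != n:
            raise ValueError("channel arrays must have equal length")
        if self.fret is not None and len(self.fret) != n:
            raise ValueError("fret array length mismatch")
        if self.truth_state is not None and len(self.truth_state) != n:
            raise ValueError("truth_state array length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.donor)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


def stationary_distribution(model: RateModel) -> np.ndarray:
    """Solve pi @ K = 0, sum(pi) = 1 for an irreducible generator.

    Raises ``ValueError`` naming the closed communicating classes if the
    chain is reducible with more than one closed class (the stationary
    distribution is then not unique).
    """
    K = model.K
    n = model.n_states
    closed = _closed_classes(K)
    if len(closed) > 1:
        names = [[model.state_labels[i] for i in c] for c in closed]
        raise ValueError(f"reducible chain with multiple closed classes: {names}")
    A = np.vstack([K.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _closed_classes(K: np.ndarray) -> list:
    """Closed communicating classes of the jump-chain digraph."""
    n = K.shape[0]
    adj = (K > 0) & ~np.eye(n, dtype=bool)
    # Tarjan-free approach: reachability closure, fine for the handful of states used here
    reach = adj | np.eye(n, dtype=bool)
    for _ in range(n):
        reach = reach | (reach @ reach)
    classes = []
    assigned = set()
    for i in range(n):
        if i in assigned:
            continue
        scc = {j for j in range(n) if reach[i, j] and reach[j, i]}
        assigned |= scc
        # closed iff nothing outside the class is reachable
        if all(not reach[i, j] or j in scc for j in range(n)):
            classes.append(sorted(scc))
    return classes


def sample_state_path(
    model: RateModel,
    duration: float,
    start: int | str = "stationary",
    seed: int | np.random.Generator | None = None,
) -> StatePath:
    """Gillespie-style exact simulation of the continuous-time chain.

    Dwell in state *i* is Exponential(-K_ii); the successor is drawn with
    probability proportional to ``K[i, j]``. A state with zero exit rate
    yields a single segment spanning the full duration.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if start == "stationary":
        pi = stationary_distribution(model)
        state = int(rng.choice(model.n_states, p=pi))
    else:
        state = int(start)
    K = model.K
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        exit_rate = -K[state, state]
        if exit_rate <= 0:
            break
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration:
            break
        probs = np.clip(K[state], 0.0, None)
        probs[state] = 0.0
        state = int(rng.choice(model.n_states, p=probs / probs.sum()))
        times.append(t)
        states.append(state)
    return StatePath(np.array(times), np.array(states), duration)


def bin_to_frames(
    path: StatePath, dt: float, emission_level: tuple | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a state path into camera frames of width ``dt``.

    Returns ``(levels, dominant)``: the occupancy-weighted mean emission
    level per frame (the camera integrates photons over the frame) and the
    index of the state occupying the largest share of each frame.
    The number of frames is ``floor(duration / dt)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_frames = int(np.floor(path.duration / dt))
    n_states = int(path.states.max()) + 1
    occ = np.zeros((n_frames, n_states))
    window_end = n_frames * dt
    starts = path.times
    ends = np.append(path.times[1:], path.duration)
    for t0, t1, s in zip(starts, ends, path.states):
        t1 = min(t1, window_end)
        if t1 <= t0:
            continue
        f0 = min(int(t0 / dt), n_frames - 1)
        f1 = min(int(np.ceil(t1 / dt)) - 1, n_frames - 1)
        if f0 == f1:
            occ[f0, s] += t1 - t0
            continue
        occ[f0, s] += (f0 + 1) * dt - t0
        if f1 > f0 + 1:
            occ[f0 + 1: f1, s] += dt
        occ[f1, s] += t1 - f1 * dt
    levels_per_state = np.asarray(emission_level, dtype=float)[:n_states]
    weights = occ / dt
    levels = weights @ levels_per_state
    dominant = occ.argmax(axis=1)
    return levels, dominant


def emit_intensities(
    levels: np.ndarray,
    emission: EmissionModel,
    seed: int | np.random.Generator | None = None,
    dt: float = 0.2,
    dominant: np.ndarray | None = None,
    trace_id: str = "trace0",
) -> FretTrace:
    """Turn ideal per-frame FRET levels into noisy two-channel intensities.

    Ideal intensities are ``I_A = E * I_total`` and ``I_D = (1 - E) *
    I_total``. An anti-correlated Gaussian perturbation with standard
    deviation ``fret_noise_sd * I_total`` is added to the acceptor and
    subtracted from the donor, so the recomputed apparent FRET has standard
    deviation ``fret_noise_sd`` exactly. Background counts are then added
    to both channels and a ``bleedthrough`` fraction of the donor signal
    leaks into the acceptor. An optional exponential photobleaching time
    truncates the signal to background-only. Negative counts are clipped
    at zero.
    """
    rng = np.random.default_rng(seed)
    E = np.asarray(levels, dtype=float)
    n = len(E)
    I_tot = emission.total_intensity
    I_A = E * I_tot
    I_D = (1.0 - E) * I_tot
    if emission.fret_noise_sd > 0:
        delta = rng.normal(0.0, emission.fret_noise_sd * I_tot, size=n)
        I_A = I_A + delta
        I_D = I_D - delta
    if emission.bleach_rate is not None and emission.bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / emission.bleach_rate)
        bleached = np.arange(n) * dt >= t_bleach
        I_A[bleached] = 0.0
        I_D[bleached] = 0.0
    I_A_obs = I_A + emission.background_acceptor + emission.bleedthrough * I_D
    I_D_obs = I_D + emission.background_donor
    np.clip(I_A_obs, 0.0, None, out=I_A_obs)
    np.clip(I_D_obs, 0.0, None, out=I_D_obs)
    total = I_A_obs + I_D_obs
    with np.errstate(invalid="ignore", divide="ignore"):
        fret = np.where(total > 0, I_A_obs / total, np.nan)
    return FretTrace(
        dt=dt,
        donor=I_D_obs,
        acceptor=I_A_obs,
        fret=fret,
        truth_state=dominant,
        trace_id=trace_id,
    )


def simulate_ensemble(
    model: RateModel,
    emission: EmissionModel,
    n_traces: int,
    duration: float,
    dt: float,
    seed: int | None = None,
    start: int | str = "stationary",
) -> tuple[list[FretTrace], list[StatePath]]:
    """Simulate an ensemble of independent traces with stored ground truth.

    Per-trace randomness is derived from one master seed through
    ``numpy.random.SeedSequence(seed).spawn(n_traces)`` (a documented
    counter scheme), so the ensemble is reproducible trace by trace.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_traces)
    traces, paths = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        path = sample_state_path(model, duration, start=start, seed=rng)
        levels, dominant = bin_to_frames(path, dt, model.emission_level)
        trace = emit_intensities(
            levels, emission, seed=rng, dt=dt, dominant=dominant,
            trace_id=f"trace{i:04d}",
        )
        traces.append(trace)
        paths.append(path)
    return traces, paths


def write_ground_truth_sidecar(path: str | Path, model: RateModel,
                               emission: EmissionModel, seed, dt: float,
                               duration: float) -> None:
    """JSON sidecar recording the generating model alongside a trace file."""
    payload = {
        "rate_model": model.to_dict(),
        "emission_model": {
            "total_intensity": emission.total_intensity,
            "fret_noise_sd": emission.fret_noise_sd,
            "background_donor": emission.background_donor,
            "background_acceptor": emission.background_acceptor,
            "bleedthrough": emission.bleedthrough,
            "bleach_rate": emission.bleach_rate,
        },
        "seed": seed,
        "dt": dt,
        "duration": duration,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
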