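"""Threshold discretization, dwell times, and per-molecule kinetic statistics.

A FRET trajectory is discretized into a two-level (zero/high) state
sequence by a threshold criterion; run lengths give dwell times. Dwells
touching the start or end of the observation window are truncated and
excluded from fits by default. Per-trace mean dwell times yield a
per-molecule dissociation constant K_d,n = c * <t_zero> / <t_high>, whose
cumulative distribution is fitted to a normalized logistic function

    P(K_d,n) = 1 / (1 + (K_d / K_d,n)^p),

the transition point K_d being the expected value of the distribution.
Pooled dwell survival curves are fitted with single-, bi- or stretched-
exponential decays to quantify kinetic heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans

__all__ = [
    "ZERO",
    "HIGH",
    "Dwell",
    "DwellSet",
    "DwellSummary",
    "LogisticFit",
    "SurvivalFit",
    "discretize_threshold",
    "extract_dwells",
    "summarize_trace",
    "cluster_center",
    "per_molecule_kd",
    "fit_logistic_cdf",
    "survival_curve",
    "fit_biexponential",
    "fit_stretched_exp",
]

ZERO, HIGH = 0, 1


@dataclass(frozen=True)
class Dwell:
    state: int  # ZERO or HIGH
    duration: float  # s
    truncated_start: bool = False
    truncated_end: bool = False
    trace_id: str = ""

    @property
    def truncated(self) -> bool:
        return self.truncated_start or self.truncated_end


@dataclass
class DwellSet:
    dwells: list

    def durations(self, state: int, include_truncated: bool = False) -> np.ndarray:
        return np.array(
            [
                d.duration
                for d in self.dwells
                if d.state == state and (include_truncated or not d.truncated)
            ]
        )

    def __len__(self) -> int:
        return len(self.dwells)

    def extend(self, other: "DwellSet") -> None:
        self.dwells.extend(other.dwells)


@dataclass
class DwellSummary:
    """Per-trace dwell statistics over non-truncated dwells.

    Means are NaN where no usable dwell exists in that state.
    """

    t_zero_mean: float
    t_high_mean: float
    dt_zero_range: float
    dt_high_range: float
    n_transitions: int
    trace_id: str = ""


@dataclass
class LogisticFit:
    kd: float  # transition point, same units as the input K_d,n values
    p: float  # steepness exponent
    kd_boot_mean: float = np.nan
    kd_boot_2sd: float = np.nan


@dataclass
class SurvivalFit:
    model: str  # "single" | "biexp" | "stretched"
    k_off_1: float = np.nan  # fast rate (1/s); for "stretched": 1/tau
    k_off_2: float = np.nan  # slow rate (1/s)
    weight_fast: float = np.nan
    weight_fast_sd: float = np.nan
    beta: float = np.nan
    tau: float = np.nan


def discretize_threshold(
    fret: np.ndarray, threshold: float = 0.375, min_dwell_frames: int = 1
) -> np.ndarray:
    """Two-level discretization: frame > threshold -> HIGH, else ZERO.

    Runs shorter than ``min_dwell_frames`` are merged into the preceding
    state (default 1 = no filtering). NaN frames inherit the previous
    state (leading NaNs the first finite state).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between the emission levels")
    fret = np.asarray(fret, dtype=float)
    finite = np.isfinite(fret)
    if not finite.any():
        raise ValueError("trace contains no finite FRET values")
    filled = fret.copy()
    # forward/backward fill NaNs so discretization is defined everywhere
    idx = np.where(finite, np.arange(len(fret)), -1)
    np.maximum.accumulate(idx, out=idx)
    first = np.argmax(finite)
    idx[idx < 0] = first
    filled = fret[idx]
    seq = (filled > threshold).astype(int)
    if min_dwell_frames > 1:
        seq = _merge_short_runs(seq, min_dwell_frames)
    return seq


def _merge_short_runs(seq: np.ndarray, min_len: int) -> np.ndarray:
    seq = seq.copy()
    changed = True
    while changed:
        changed = False
        starts, lengths, values = _runs(seq)
        for i in range(len(starts)):
            if lengths[i] < min_len and len(starts) > 1:
                s, l = starts[i], lengths[i]
                # absorb into the longer neighbour (prefer preceding)
                seq[s: s + l] = values[i - 1] if i > 0 else values[i + 1]
                changed = True
                break
    return seq


def _runs(seq: np.ndarray) -> tuple:
    change = np.flatnonzero(np.diff(seq) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(seq)]))
    return starts, ends - starts, seq[starts]


def extract_dwells(state_sequence: np.ndarray, dt: float, trace_id: str = "") -> DwellSet:
    """Run lengths times dt; first and last dwells are flagged truncated."""
    seq = np.asarray(state_sequence, dtype=int)
    if seq.size == 0:
        raise ValueError("empty state sequence")
    starts, lengths, values = _runs(seq)
    n = len(starts)
    dwells = [
        Dwell(
            state=int(values[i]),
            duration=float(lengths[i] * dt),
            truncated_start=(i == 0),
            truncated_end=(i == n - 1),
            trace_id=trace_id,
        )
        for i in range(n)
    ]
    return DwellSet(dwells)


def summarize_trace(dwell_set: DwellSet, trace_id: str = "",
                    include_truncated: bool = False) -> DwellSummary:
    """Per-state mean dwell time and range (max - min) over usable dwells."""
    out = {}
    for state, tag in ((ZERO, "zero"), (HIGH, "high")):
        d = dwell_set.durations(state, include_truncated=include_truncated)
        if d.size:
            out[f"t_{tag}_mean"] = float(d.mean())
            out[f"dt_{tag}_range"] = float(d.max() - d.min())
        else:
            out[f"t_{tag}_mean"] = np.nan
            out[f"dt_{tag}_range"] = np.nan
    n_trans = max(len(dwell_set) - 1, 0)
    return DwellSummary(n_transitions=n_trans, trace_id=trace_id, **out)


def cluster_center(
    summaries: list, k: int = 1, seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """k-means centroid(s) of the (<t_zero>, <t_high>) scatter.

    With the default k=1 this is the coordinate-wise mean of the cloud.
    Returns an array of shape (k, 2), rows sorted by the first coordinate.
    """
    pts = np.array(
        [
            (s.t_zero_mean, s.t_high_mean)
            for s in summaries
            if np.isfinite(s.t_zero_mean) and np.isfinite(s.t_high_mean)
        ]
    )
    if len(pts) < k:
        raise ValueError(f"need at least k={k} points, got {len(pts)}")
    if k == 1:
        return pts.mean(axis=0, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(pts)
    centers = km.cluster_centers_
    return centers[np.argsort(centers[:, 0])]


def per_molecule_kd(summary: DwellSummary, ligand_conc: float) -> float:
    """K_d,n = c * <t_zero> / <t_high> (from k_off = 1/<t_high>, k'_on = 1/<t_zero>).

    Returns NaN when either mean is undefined or non-positive.
    """
    if ligand_conc <= 0:
        raise ValueError("ligand_conc must be positive")
    tz, th = summary.t_zero_mean, summary.t_high_mean
    if not (np.isfinite(tz) and np.isfinite(th)) or tz <= 0 or th <= 0:
        return np.nan
    return ligand_conc * tz / th


def logistic_cdf(kd_n: np.ndarray, kd: float, p: float) -> np.ndarray:
    """Normalized logistic distribution function of per-molecule K_d,n."""
    kd_n = np.asarray(kd_n, dtype=float)
    return 1.0 / (1.0 + (kd / kd_n) ** p)


def fit_logistic_cdf(
    kd_values: np.ndarray, n_boot: int = 100, seed: int | None = None
) -> LogisticFit:
    """Fit the empirical cumulative K_d,n distribution to the logistic form.

    The transition point ``kd`` sits at the inflection (P = 1/2) and is the
    expected value of the distribution. Bootstrap resamples molecules.
    """
    vals = np.asarray(kd_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 10:
        raise ValueError("need >= 10 finite K_d,n values")
    if np.any(vals <= 0):
        raise ValueError("K_d,n values must be positive")
    if np.ptp(vals) < 1e-15 * vals[0]:
        raise ValueError("all K_d,n values identical; logistic fit undefined")

    def _fit(v: np.ndarray) -> tuple:
        x = np.sort(v)
        # empirical CDF at the sorted sample points (midpoint convention)
        ecdf = (np.arange(1, len(x) + 1) - 0.5) / len(x)
        p0 = (np.median(x), 1.5)
        popt, _ = curve_fit(
            logistic_cdf, x, ecdf, p0=p0,
            bounds=([1e-30, 0.05], [np.inf, 100.0]), maxfev=20000,
        )
        return popt

    kd, p = _fit(vals)
    boot = []
    if n_boot > 1:
        rng = np.random.default_rng(seed)
        for _ in range(n_boot):
            sample = rng.choice(vals, size=vals.size, replace=True)
            try:
                boot.append(_fit(sample)[0])
            except RuntimeError:
                continue
    boot = np.array(boot) if boot else np.array([kd])
    return LogisticFit(
        kd=float(kd),
        p=float(p),
        kd_boot_mean=float(boot.mean()),
        kd_boot_2sd=float(2 * boot.std(ddof=0)),
    )


def survival_curve(dwell_set: DwellSet, state: int,
                   include_truncated: bool = False) -> tuple:
    """Complementary cumulative dwell-time distribution (t, fraction >= t).

    Right-continuous step function evaluated at the sorted dwell times;
    S(0) = 1 by construction.
    """
    d = np.sort(dwell_set.durations(state, include_truncated=include_truncated))
    if d.size == 0:
        raise ValueError("no usable dwell in the requested state")
    t = np.concatenate(([0.0], d))
    frac = np.concatenate(([1.0], 1.0 - np.arange(1, d.size + 1) / d.size))
    return t, frac


def _survival_points(dwell_set_or_curve, state, dt_min):
    if isinstance(dwell_set_or_curve, DwellSet):
        t, s = survival_curve(dwell_set_or_curve, state)
    else:
        t, s = dwell_set_or_curve
        t, s = np.asarray(t, float), np.asarray(s, float)
    keep = t >= dt_min
    return t[keep], s[keep]


def _biexp_survival(t, w, k1, k2):
    return w * np.exp(-k1 * t) + (1 - w) * np.exp(-k2 * t)


def _fit_biexp_once(d: np.ndarray, dt_min: float, objective: str):
    from scipy.optimize import minimize

    k0 = 1.0 / max(d.mean(), 1e-12)
    if objective == "mle":
        # left-truncated mixture-of-exponentials likelihood: dwells below
        # dt_min are unobservable, so densities are conditioned on t >= dt_min
        def nll(p):
            w, lk1, lk2 = p
            k1, k2 = np.exp(lk1), np.exp(lk2)
            f = w * k1 * np.exp(-k1 * d) + (1 - w) * k2 * np.exp(-k2 * d)
            s_min = max(_biexp_survival(dt_min, w, k1, k2), 1e-300)
            return -np.sum(np.log(np.maximum(f, 1e-300))) + d.size * np.log(s_min)

        best = None
        for w0, f1, f2 in ((0.6, 5.0, 0.5), (0.9, 10.0, 0.2), (0.3, 2.0, 0.8)):
            res = minimize(
                nll, x0=[w0, np.log(f1 * k0), np.log(f2 * k0)],
                bounds=[(1e-6, 1 - 1e-6), (-30, 30), (-30, 30)],
                method="L-BFGS-B",
            )
            if best is None or res.fun < best.fun:
                best = res
        w, k1, k2 = best.x[0], np.exp(best.x[1]), np.exp(best.x[2])
    elif objective == "ls":
        ts = np.sort(d)
        t = np.concatenate(([0.0], ts))
        s = np.concatenate(([1.0], 1.0 - np.arange(1, ts.size + 1) / ts.size))
        keep = t >= dt_min
        popt, _ = curve_fit(
            _biexp_survival, t[keep], s[keep], p0=(0.6, 5 * k0, 0.5 * k0),
            bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]), maxfev=50000,
        )
        w, k1, k2 = popt
    else:
        raise ValueError(f"unknown objective {objective!r}")
    if k1 < k2:  # enforce the k1 >= k2 reporting convention
        k1, k2, w = k2, k1, 1.0 - w
    return float(w), float(k1), float(k2)


def fit_biexponential(
    dwell_set_or_curve, state: int = HIGH, dt_min: float = 0.0,
    n_boot: int = 100, seed: int | None = None, objective: str = "mle",
) -> SurvivalFit:
    """Fit S(t) = w exp(-k1 t) + (1-w) exp(-k2 t), with k1 >= k2, w in [0, 1].

    Default objective is the (left-truncated) maximum likelihood on the
    dwell sample; ``objective="ls"`` fits the empirical survival curve by
    nonlinear least squares instead. A fit collapsing to one component
    (rates within 5% or a vanishing weight) is reported with model tag
    "single". ``dt_min`` drops dwells below the resolvable timescale
    (dwells shorter than ~2 frames are biased by discretization).
    """
    if isinstance(dwell_set_or_curve, DwellSet):
        d = dwell_set_or_curve.durations(state)
        d = d[d >= dt_min]
        if d.size < 4:
            raise ValueError("too few usable dwells for a biexponential fit")
    else:
        if objective == "mle":
            raise ValueError("MLE objective needs the dwell sample; pass a "
                             "DwellSet or use objective='ls'")
        t, s = _survival_points(dwell_set_or_curve, state, dt_min)
        k0 = 1.0 / max(np.trapezoid(s, t), 1e-12)
        popt, _ = curve_fit(
            _biexp_survival, t, s, p0=(0.6, 5 * k0, 0.5 * k0),
            bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]), maxfev=50000,
        )
        w, k1, k2 = popt
        if k1 < k2:
            k1, k2, w = k2, k1, 1.0 - w
        single = (abs(k1 - k2) < 0.05 * k1) or w < 1e-3 or w > 1 - 1e-3
        return SurvivalFit(model="single" if single else "biexp",
                           k_off_1=float(k1), k_off_2=float(k2),
                           weight_fast=float(w))
    w, k1, k2 = _fit_biexp_once(d, dt_min, objective)
    # collapse test: likelihood ratio against the single-exponential MLE
    # (memorylessness makes the left-truncated MLE rate 1/(mean - dt_min))
    k_single = 1.0 / max(d.mean() - dt_min, 1e-12)
    ll_single = d.size * np.log(k_single) - k_single * np.sum(d - dt_min)
    f = w * k1 * np.exp(-k1 * d) + (1 - w) * k2 * np.exp(-k2 * d)
    s_min = _biexp_survival(dt_min, w, k1, k2)
    ll_biexp = np.sum(np.log(np.maximum(f, 1e-300))) - d.size * np.log(s_min)
    single = (abs(k1 - k2) < 0.05 * k1) or (2 * (ll_biexp - ll_single) < 5.99)
    w_sd = np.nan
    if n_boot > 1:
        rng = np.random.default_rng(seed)
        ws = []
        for _ in range(n_boot):
            sample = rng.choice(d, size=d.size, replace=True)
            try:
                wb, _, _ = _fit_biexp_once(sample, dt_min, objective)
                ws.append(wb)
            except (RuntimeError, ValueError):
                continue
        if ws:
            w_sd = float(np.std(ws, ddof=0))
    return SurvivalFit(
        model="single" if single else "biexp",
        k_off_1=k1, k_off_2=k2, weight_fast=w, weight_fast_sd=w_sd,
    )


def fit_stretched_exp(
    dwell_set_or_curve, state: int = HIGH, dt_min: float = 0.0,
    objective: str = "mle",
) -> SurvivalFit:
    """Fit S(t) = exp(-(t/tau)^beta), beta in (0, 1]; beta < 1 flags rate dispersion.

    Maximum likelihood on the dwell sample by default (left-truncated at
    ``dt_min``); ``objective="ls"`` fits the empirical survival instead.
    """
    if isinstance(dwell_set_or_curve, DwellSet) and objective == "mle":
        from scipy.optimize import minimize

        d = dwell_set_or_curve.durations(state)
        d = d[d >= max(dt_min, 0.0)]
        if d.size < 4:
            raise ValueError("too few usable dwells for a stretched fit")

        def nll(p):
            ltau, beta = p
            tau = np.exp(ltau)
            z = d / tau
            logf = np.log(beta / tau) + (beta - 1) * np.log(z) - z**beta
            trunc = (dt_min / tau) ** beta if dt_min > 0 else 0.0
            return -np.sum(logf) + d.size * trunc

        res = minimize(nll, x0=[np.log(d.mean()), 0.9],
                       bounds=[(-30, 30), (0.05, 1.0)], method="L-BFGS-B")
        tau, beta = float(np.exp(res.x[0])), float(res.x[1])
    else:
        t, s = _survival_points(dwell_set_or_curve, state, dt_min)
        tau0 = max(np.trapezoid(s, t), 1e-9)
        popt, _ = curve_fit(
            lambda t, tau, beta: np.exp(-((t / tau) ** beta)),
            t[t > 0], s[t > 0], p0=(tau0, 0.9),
            bounds=([1e-12, 0.05], [np.inf, 1.0]), maxfev=50000,
        )
        tau, beta = float(popt[0]), float(popt[1])
    return SurvivalFit(model="stretched", tau=tau, beta=beta,
                       k_off_1=1.0 / tau)
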