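"""Global hidden Markov modeling of smFRET ensembles with degenerate states.

Several hidden kinetic states may share one Gaussian FRET emission
component ("degenerate" states): they are indistinguishable by FRET level
and identifiable only through their exit kinetics. The workflow mirrors
common smFRET practice:

1. per-trace Baum-Welch fits determine the emission components;
2. the component means/widths are frozen (median over traces) and a single
   *global* transition matrix and start vector are optimized on the whole
   ensemble of dynamic traces;
3. candidate kinetic networks (e.g. two-state vs sequential three-state
   with a twofold degenerate bound level) are ranked by BIC;
4. per-frame transition probabilities are converted to first-order rate
   coefficients, state populations and a dissociation constant; parameter
   uncertainties come from profile-likelihood (likelihood-ratio) bounds.

The forward-backward recursions use the scaled (normalized) algorithm and
are vectorized across traces of equal length, so global fits on hundreds
of traces run in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import logm
from scipy.stats import chi2

from fretkin.synthetic_traces import FretTrace

__all__ = [
    "HmmSpec",
    "HmmParams",
    "two_state_spec",
    "degenerate_three_state_spec",
    "pooled_emissions",
    "train_trace_hmm",
    "train_global_hmm",
    "viterbi_path",
    "forward_loglik",
    "compute_bic",
    "select_model",
    "transition_to_rates",
    "state_population_kd",
    "likelihood_ratio_errors",
]

_MIN_SD = 1e-4
_B_FLOOR = 1e-300


@dataclass(frozen=True)
class HmmSpec:
    """Topology of a hidden kinetic network.

    ``adjacency[i, j]`` marks an allowed i -> j transition (diagonal is
    always allowed); ``emission_map[s]`` is the index of the Gaussian
    component state *s* emits from. Distinct states may map to the same
    component (degeneracy).
    """

    n_states: int
    adjacency: np.ndarray
    emission_map: tuple
    name: str = ""

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=bool).copy()
        np.fill_diagonal(adj, True)
        object.__setattr__(self, "adjacency", adj)
        if adj.shape != (self.n_states, self.n_states):
            raise ValueError("adjacency shape mismatch")
        if len(self.emission_map) != self.n_states:
            raise ValueError("emission_map must assign every state")

    @property
    def n_components(self) -> int:
        return int(max(self.emission_map)) + 1

    def n_free_parameters(self, emissions_fixed: bool = True) -> int:
        """Free transition entries (diagonal fixed by normalization) + free
        start entries (+ 2 per Gaussian component when emissions are learned)."""
        off = self.adjacency & ~np.eye(self.n_states, dtype=bool)
        n = int(off.sum()) + (self.n_states - 1)
        if not emissions_fixed:
            n += 2 * self.n_components
        return n


def two_state_spec(name: str = "two-state") -> HmmSpec:
    return HmmSpec(2, np.ones((2, 2), bool), (0, 1), name)


def degenerate_three_state_spec(name: str = "sequential-3-state-degenerate") -> HmmSpec:
    """Linear 0 <-> 1 <-> 2 with states 1 and 2 sharing the high-FRET level.

    The 0 <-> 2 link is forbidden: the unbound state connects to the bound
    level only through state 1, which canonicalizes the degenerate pair.
    """
    adj = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], bool)
    return HmmSpec(3, adj, (0, 1, 1), name)


@dataclass
class HmmParams:
    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray  # per emission component
    sds: np.ndarray
    spec: HmmSpec
    log_likelihood: float = np.nan
    n_free_parameters: int = 0
    n_observations: int = 0

    @property
    def bic(self) -> float:
        return compute_bic(self.log_likelihood, self.n_free_parameters,
                           self.n_observations)


# ---------------------------------------------------------------------------
# likelihood machinery (scaled forward-backward, batched over equal lengths)

def _as_obs(traces) -> list:
    """Extract finite FRET observation arrays from traces."""
    out = []
    for tr in traces:
        x = tr.fret if isinstance(tr, FretTrace) else np.asarray(tr, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValueError("trace has fewer than 2 finite frames")
        out.append(x)
    return out


def _emission_probs(x: np.ndarray, params: HmmParams) -> np.ndarray:
    """Gaussian emission densities, shape (..., n_states)."""
    mu = params.means[list(params.spec.emission_map)]
    sd = np.maximum(params.sds[list(params.spec.emission_map)], _MIN_SD)
    z = (x[..., None] - mu) / sd
    B = np.exp(-0.5 * z * z) / (np.sqrt(2 * np.pi) * sd)
    return np.maximum(B, _B_FLOOR)


def _forward_batch(B: np.ndarray, start: np.ndarray, A: np.ndarray):
    """Scaled forward pass. B: (N, T, S). Returns alpha_hat, scales, loglik."""
    N, T, S = B.shape
    alpha = np.empty((N, T, S))
    c = np.empty((N, T))
    a = start[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    return alpha, c, np.log(c).sum(axis=1)


def _backward_batch(B: np.ndarray, A: np.ndarray, c: np.ndarray) -> np.ndarray:
    N, T, S = B.shape
    beta = np.empty((N, T, S))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = (B[:, t + 1] * beta[:, t + 1]) @ A.T / c[:, t + 1, None]
    return beta


def _e_step(obs_groups, params: HmmParams):
    """Expected sufficient statistics summed over all traces.

    obs_groups: list of (N, T) observation matrices (traces grouped by
    equal length). Returns (loglik, start_counts, xi_sum, gamma0_by_comp
    weighted stats for emissions: (w_c, wx_c, wxx_c)).
    """
    A = params.transmat
    S = params.spec.n_states
    C = params.spec.n_components
    comp = np.asarray(params.spec.emission_map)
    loglik = 0.0
    start_counts = np.zeros(S)
    xi_sum = np.zeros((S, S))
    w = np.zeros(C)
    wx = np.zeros(C)
    wxx = np.zeros(C)
    for X in obs_groups:
        B = _emission_probs(X, params)  # (N, T, S)
        alpha, c, ll = _forward_batch(B, params.startprob, A)
        beta = _backward_batch(B, A, c)
        gamma = alpha * beta  # (N, T, S), rows sum to 1
        loglik += ll.sum()
        start_counts += gamma[:, 0].sum(axis=0)
        Bb = B[:, 1:] * beta[:, 1:]  # (N, T-1, S)
        # xi_t[i, j] = alpha[t-1, i] A[i, j] B[t, j] beta[t, j] / c[t]
        xi = np.einsum("nti,ntj->ij", alpha[:, :-1], Bb / c[:, 1:, None])
        xi_sum += xi * A
        g = gamma.reshape(-1, S)
        xflat = X.reshape(-1)
        for k in range(C):
            gk = g[:, comp == k].sum(axis=1)
            w[k] += gk.sum()
            wx[k] += (gk * xflat).sum()
            wxx[k] += (gk * xflat * xflat).sum()
    return loglik, start_counts, xi_sum, (w, wx, wxx)


def _m_step(params: HmmParams, start_counts, xi_sum, emis_stats,
            learn_emissions: bool, clamp: tuple | None = None) -> HmmParams:
    spec = params.spec
    start = start_counts / start_counts.sum()
    A = np.where(spec.adjacency, xi_sum, 0.0)
    rowsum = A.sum(axis=1, keepdims=True)
    # rows never visited keep their previous values
    stale = rowsum.ravel() <= 0
    A = np.where(stale[:, None], params.transmat, A / np.where(rowsum > 0, rowsum, 1.0))
    if clamp is not None:
        i, j, val = clamp
        A[i] = _clamp_row(A[i], j, val, spec.adjacency[i])
    means, sds = params.means, params.sds
    if learn_emissions:
        w, wx, wxx = emis_stats
        means = wx / np.maximum(w, 1e-12)
        var = wxx / np.maximum(w, 1e-12) - means**2
        sds = np.sqrt(np.maximum(var, _MIN_SD**2))
    return replace(params, startprob=start, transmat=A, means=means, sds=sds)


def _clamp_row(row: np.ndarray, j: int, val: float, allowed: np.ndarray) -> np.ndarray:
    """Fix row[j] = val and renormalize the other allowed entries to 1 - val."""
    out = np.where(allowed, row, 0.0)
    rest = out.sum() - out[j]
    out[j] = 0.0
    if rest <= 0:
        out[:] = np.where(allowed, (1.0 - val) / max(allowed.sum() - 1, 1), 0.0)
    else:
        out *= (1.0 - val) / rest
    out[j] = val
    return out


def _group_by_length(obs: list) -> list:
    groups = {}
    for x in obs:
        groups.setdefault(len(x), []).append(x)
    return [np.vstack(v) for v in groups.values()]


def _run_em(
    obs: list,
    params: HmmParams,
    learn_emissions: bool,
    tol: float,
    max_iter: int,
    clamp: tuple | None = None,
) -> HmmParams:
    groups = _group_by_length(obs)
    n_obs = sum(x.size for x in obs)
    prev = -np.inf
    for _ in range(max_iter):
        ll, sc, xi, emis = _e_step(groups, params)
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite log-likelihood during EM (previous {prev:.6g})"
            )
        params = _m_step(params, sc, xi, emis, learn_emissions, clamp)
        if ll - prev < tol * n_obs and np.isfinite(prev):
            prev = ll
            break
        prev = ll
    ll, *_ = _e_step(groups, params)
    params.log_likelihood = float(ll)
    params.n_observations = n_obs
    params.n_free_parameters = params.spec.n_free_parameters(
        emissions_fixed=not learn_emissions
    )
    return params


# ---------------------------------------------------------------------------
# initialization

def _dwell_based_transmat(obs, spec: HmmSpec, means, rng, jitter: float) -> np.ndarray:
    """Point estimate of A from threshold counts at the component level,
    distributed over degenerate states, with multiplicative log-normal
    jitter for restarts."""
    S = spec.n_states
    comp = np.asarray(spec.emission_map)
    thresh = float(np.mean(means))
    counts = np.full((spec.n_components, spec.n_components), 1.0)
    for x in obs:
        seq = (x > thresh).astype(int)
        if spec.n_components == 1:
            seq = np.zeros_like(seq)
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a, b] += 1
    A_comp = counts / counts.sum(axis=1, keepdims=True)
    A = np.zeros((S, S))
    exch0 = 0.02  # modest seed for exchange within a degenerate group
    for i in range(S):
        for j in range(S):
            if not spec.adjacency[i, j]:
                continue
            ci, cj = comp[i], comp[j]
            if ci == cj:
                # keep the self-transition dominant: within-group exchange
                # starts small, the remainder of the component mass stays
                # on the diagonal
                A[i, j] = exch0 if i != j else 0.0
            else:
                targets = [jj for jj in range(S)
                           if spec.adjacency[i, jj] and comp[jj] == cj]
                A[i, j] = A_comp[ci, cj] / len(targets)
    np.fill_diagonal(A, 0.0)
    resid = 1.0 - A.sum(axis=1)
    A += np.diag(np.maximum(resid, 0.05))
    if jitter > 0:
        off = ~np.eye(S, dtype=bool) & spec.adjacency
        A[off] *= np.exp(rng.normal(0.0, jitter, size=off.sum()))
    A = np.where(spec.adjacency, A, 0.0)
    return A / A.sum(axis=1, keepdims=True)


def _init_params(obs, spec: HmmSpec, means, sds, rng, jitter: float) -> HmmParams:
    start = np.full(spec.n_states, 1.0 / spec.n_states)
    A = _dwell_based_transmat(obs, spec, means, rng, jitter)
    return HmmParams(
        startprob=start, transmat=A,
        means=np.asarray(means, float), sds=np.asarray(sds, float), spec=spec,
    )


def _default_emissions(obs, spec: HmmSpec):
    pooled = np.concatenate(obs)
    if spec.n_components == 1:
        return np.array([pooled.mean()]), np.array([max(pooled.std(), _MIN_SD)])
    # simple quantile-split moment starts; EM refines them
    qs = np.quantile(pooled, np.linspace(0.1, 0.9, spec.n_components))
    return qs, np.full(spec.n_components, max(pooled.std() / 2, _MIN_SD))


def pooled_emissions(traces, n_components: int = 2, seed: int | None = None):
    """Median emission means/widths over per-trace two-state fits.

    Used as the "predetermined" emission components that are frozen before
    the global stage.
    """
    from sklearn.mixture import GaussianMixture

    obs = _as_obs(traces)
    rng = np.random.default_rng(seed)
    means_all, sds_all = [], []
    for x in obs:
        gm = GaussianMixture(
            n_components=n_components,
            random_state=int(rng.integers(2**31 - 1)),
            n_init=2, reg_covar=1e-6,
        ).fit(x.reshape(-1, 1))
        order = np.argsort(gm.means_.ravel())
        means_all.append(gm.means_.ravel()[order])
        sds_all.append(np.sqrt(gm.covariances_.ravel()[order]))
    return (
        np.median(np.vstack(means_all), axis=0),
        np.median(np.vstack(sds_all), axis=0),
    )


# ---------------------------------------------------------------------------
# public training interface

def train_trace_hmm(
    trace,
    spec: HmmSpec,
    init: HmmParams | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_restarts: int = 3,
    seed: int | None = None,
    learn_emissions: bool = True,
) -> HmmParams:
    """Baum-Welch fit of a single trace; best of ``n_restarts`` returned.

    ``tol`` is the convergence threshold on the log-likelihood increase
    *per frame*. The EM log-likelihood sequence is non-decreasing.
    """
    obs = _as_obs([trace])
    if len(obs[0]) < 10:
        raise ValueError("trace must have at least 10 frames")
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        if init is not None and r == 0:
            params = replace(init)
        else:
            means, sds = _default_emissions(obs, spec)
            params = _init_params(obs, spec, means, sds, rng,
                                  jitter=0.0 if r == 0 else 0.5)
        fitted = _run_em(obs, params, learn_emissions, tol, max_iter)
        if best is None or fitted.log_likelihood > best.log_likelihood:
            best = fitted
    return best


def train_global_hmm(
    traces,
    spec: HmmSpec,
    fixed_emissions: tuple,
    init: HmmParams | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_restarts: int = 3,
    seed: int | None = None,
) -> HmmParams:
    """Global fit: one shared transition matrix and start vector over the
    whole ensemble, with emission components held fixed.

    ``fixed_emissions`` is a ``(means, sds)`` pair indexed by emission
    component (see :func:`pooled_emissions`).
    """
    obs = _as_obs(traces)
    if len(obs) < 2:
        raise ValueError("global fit needs at least 2 traces")
    means, sds = (np.asarray(a, dtype=float) for a in fixed_emissions)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        if init is not None and r == 0:
            params = replace(init, means=means, sds=sds)
        else:
            params = _init_params(obs, spec, means, sds, rng,
                                  jitter=0.0 if r == 0 else 0.5)
        fitted = _run_em(obs, params, False, tol, max_iter)
        if best is None or fitted.log_likelihood > best.log_likelihood:
            best = fitted
    return best


def forward_loglik(trace, params: HmmParams) -> float:
    """Scaled-forward log-likelihood of one trace under fixed parameters."""
    x = _as_obs([trace])[0]
    B = _emission_probs(x[None, :], params)
    _, _, ll = _forward_batch(B, params.startprob, params.transmat)
    return float(ll[0])


def viterbi_path(trace, params: HmmParams) -> np.ndarray:
    """Most likely hidden state sequence; ties break toward lower index."""
    x = _as_obs([trace])[0]
    logB = np.log(_emission_probs(x[None, :], params)[0])  # (T, S)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transmat)
        logstart = np.log(params.startprob)
    T, S = logB.shape
    delta = np.empty((T, S))
    back = np.zeros((T, S), dtype=int)
    delta[0] = logstart + logB[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + logA  # (from, to)
        back[t] = cand.argmax(axis=0)  # argmax returns the lowest index on ties
        delta[t] = cand[back[t], np.arange(S)] + logB[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(delta[T - 1].argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# model selection and derived quantities

def compute_bic(logL: float, n_free_parameters: int, n_observations: int) -> float:
    """BIC = -2 logL + p ln(n); n is the total number of frames."""
    if n_observations < 0:
        raise ValueError("n_observations must be non-negative")
    penalty = n_free_parameters * np.log(n_observations) if n_observations else 0.0
    return -2.0 * logL + penalty


def select_model(
    traces,
    specs: list,
    fixed_emissions_by_spec: list | None = None,
    seed: int | None = None,
    **train_kwargs,
) -> list:
    """Train every candidate spec globally and rank by BIC (best first).

    Returns a list of dicts with keys spec, params, logL, bic, delta_bic,
    error (specs failing to converge are reported, not dropped).
    """
    if len(specs) < 1:
        raise ValueError("need at least one candidate spec")
    results = []
    for i, spec in enumerate(specs):
        if fixed_emissions_by_spec is not None:
            emis = fixed_emissions_by_spec[i]
        else:
            emis = pooled_emissions(traces, spec.n_components, seed=seed)
        try:
            params = train_global_hmm(traces, spec, emis, seed=seed, **train_kwargs)
            results.append(
                {"spec": spec, "params": params, "logL": params.log_likelihood,
                 "bic": params.bic, "error": None}
            )
        except (ValueError, FloatingPointError) as exc:  # reported, not dropped
            results.append(
                {"spec": spec, "params": None, "logL": np.nan,
                 "bic": np.inf, "error": str(exc)}
            )
    results.sort(key=lambda r: r["bic"])
    best = results[0]["bic"]
    for r in results:
        r["delta_bic"] = r["bic"] - best
    return results


def transition_to_rates(A: np.ndarray, dt: float, method: str = "linear") -> np.ndarray:
    """Per-frame transition probabilities -> first-order rate matrix (1/s).

    ``linear``: off-diagonal k_ij = A_ij / dt (first-order approximation;
    warns when any off-diagonal A_ij > 0.1, where the approximation
    degrades). ``logm``: matrix logarithm K = logm(A)/dt; raises when A is
    not embeddable (complex or negative off-diagonal generator).
    """
    A = np.asarray(A, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows of A must sum to 1")
    if method == "linear":
        off = A - np.diag(np.diag(A))
        if np.any(off > 0.1):
            warnings.warn(
                "transition probability > 0.1 per frame; the linear rate "
                "approximation k = A/dt is biased — consider method='logm'",
                stacklevel=2,
            )
        K = off / dt
        np.fill_diagonal(K, -K.sum(axis=1))
        return K
    if method == "logm":
        L = logm(A)
        if np.max(np.abs(np.imag(L))) > 1e-10:
            raise ValueError(
                "matrix logarithm is complex; A is not embeddable — "
                "use method='linear'"
            )
        K = np.real(L) / dt
        off = K - np.diag(np.diag(K))
        if np.min(off) < -1e-8:
            raise ValueError(
                "matrix logarithm has negative off-diagonal rates; A is not "
                "embeddable — use method='linear'"
            )
        return K
    raise ValueError(f"unknown method {method!r}")


def _stationary_of_transmat(A: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(A.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def state_population_kd(
    params: HmmParams,
    ligand_conc: float,
    bound_states: tuple | None = None,
    method: str = "stationary",
    traces=None,
) -> tuple[np.ndarray, float]:
    """State populations and K_d = S_unbound * c / S_bound.

    Populations come from the stationary distribution of the fitted
    transition matrix (default) or from Viterbi-decoded frame occupancy.
    Bound states default to every state whose emission mean exceeds the
    midpoint of the component means; degenerate bound states are
    aggregated. K_d is NaN when the bound population is zero.
    """
    if method == "stationary":
        pops = _stationary_of_transmat(params.transmat)
    elif method == "viterbi":
        if traces is None:
            raise ValueError("method='viterbi' requires traces")
        counts = np.zeros(params.spec.n_states)
        for tr in traces:
            path = viterbi_path(tr, params)
            counts += np.bincount(path, minlength=params.spec.n_states)
        pops = counts / counts.sum()
    else:
        raise ValueError(f"unknown method {method!r}")
    if bound_states is None:
        mid = params.means.mean()
        comp = np.asarray(params.spec.emission_map)
        bound_states = tuple(np.flatnonzero(params.means[comp] > mid))
    s_bound = pops[list(bound_states)].sum()
    s_unbound = 1.0 - s_bound
    kd = s_unbound * ligand_conc / s_bound if s_bound > 0 else np.nan
    return pops, kd


def likelihood_ratio_errors(
    traces,
    params: HmmParams,
    param_index: tuple,
    confidence: float = 0.6827,
    max_iter: int = 200,
    n_grid: int = 8,
) -> dict:
    """Profile-likelihood bounds for one transition-matrix entry.

    The entry ``A[i, j]`` is clamped on a bracket around its MLE while all
    remaining parameters are re-optimized (constrained EM); the bound is
    where twice the log-likelihood drop crosses the chi-square(1) quantile
    for the requested confidence (1-sigma default). A side whose profile
    never crosses within (0, 1) is flagged one-sided and reported as NaN.
    """
    from scipy.optimize import brentq

    i, j = param_index
    if not params.spec.adjacency[i, j] or i == j:
        raise ValueError("profiled entry must be an allowed off-diagonal transition")
    obs = _as_obs(traces)
    drop = chi2.ppf(confidence, df=1) / 2.0 if confidence > 0 else 0.0
    if drop == 0.0:
        v = float(params.transmat[i, j])
        return {"lower": v, "upper": v, "mle": v,
                "one_sided_lower": False, "one_sided_upper": False}
    # re-optimize on the supplied traces so the reference maximum is
    # consistent with the profiled likelihood (they may be a subset of the
    # ensemble the params were trained on)
    params = _run_em(obs, replace(params, transmat=params.transmat.copy()),
                     False, 1e-7, max_iter)
    mle_val = params.transmat[i, j]
    ll_max = params.log_likelihood

    def profile(v: float) -> float:
        p0 = replace(params, transmat=params.transmat.copy())
        p0.transmat[i] = _clamp_row(p0.transmat[i].copy(), j, v,
                                    params.spec.adjacency[i])
        fitted = _run_em(obs, p0, False, 1e-7, max_iter, clamp=(i, j, v))
        return fitted.log_likelihood

    def g(v: float) -> float:
        return profile(v) - (ll_max - drop)

    bounds = {}
    flags = {}
    for side, limit in (("lower", 1e-9), ("upper", 1.0 - 1e-9)):
        bracket = None
        v = mle_val
        for _ in range(n_grid):
            v = (v + limit) / 2.0 if side == "upper" else v / 2.0
            v = min(max(v, limit), 1.0 - 1e-9) if side == "upper" else max(v, limit)
            if g(v) < 0:
                bracket = v
                break
            if abs(v - limit) < 1e-12:
                break
        if bracket is None:
            bounds[side] = np.nan
            flags[side] = True
        else:
            lo, hi = (bracket, mle_val) if side == "lower" else (mle_val, bracket)
            bounds[side] = float(brentq(g, lo, hi, xtol=1e-8))
            flags[side] = False
    return {
        "lower": bounds["lower"], "upper": bounds["upper"], "mle": float(mle_val),
        "one_sided_lower": flags["lower"], "one_sided_upper": flags["upper"],
    }
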