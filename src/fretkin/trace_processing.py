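"""Raw-channel corrections, FRET efficiency, molecule classes, histogram fits.

The proximity ratio FRET = I_A / (I_A + I_D) is computed from background-
and bleedthrough-corrected intensities; no gamma/detection-efficiency
correction is applied. Ensemble FRET histograms of dynamic molecules are
fitted with a Gaussian mixture, and the bound fraction as a function of
Mg2+ is summarised by a Hill-form binding isotherm.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

__all__ = [
    "CorrectionParams",
    "MoleculeClass",
    "FretHistogramFit",
    "IsothermFit",
    "correct_intensities",
    "compute_fret",
    "classify_molecule",
    "fit_fret_histogram",
    "fit_binding_isotherm",
]


@dataclass(frozen=True)
class CorrectionParams:
    """Background counts per channel and donor->acceptor bleedthrough."""

    background_donor: float = 0.0
    background_acceptor: float = 0.0
    bleedthrough: float = 0.0

    def __post_init__(self):
        if not 0 <= self.bleedthrough < 1:
            raise ValueError("bleedthrough must be in [0, 1)")


class MoleculeClass(str, Enum):
    """Exhaustive interconversion-frequency classes for a discretized trace.

    static_zero: no binding event within the observation window;
    static_high: no unbinding event; one_transition: exactly one state
    change; dynamic: at least two transitions.
    """

    STATIC_ZERO = "static_zero"
    STATIC_HIGH = "static_high"
    ONE_TRANSITION = "one_transition"
    DYNAMIC = "dynamic"


@dataclass
class FretHistogramFit:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    fraction_bound: float
    fraction_bound_boot_mean: float
    fraction_bound_boot_2sd: float


@dataclass
class IsothermFit:
    midpoint: float  # ligand concentration at half saturation
    saturation: float  # plateau bound fraction
    hill_n: float
    midpoint_boot_2sd: float = 0.0


def correct_intensities(
    I_D_raw: np.ndarray, I_A_raw: np.ndarray, params: CorrectionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtract both channels, then remove donor bleedthrough.

    ``I_D = I_D_raw - bg_D`` and ``I_A = I_A_raw - bg_A - alpha * I_D``,
    with the bleedthrough correction using the background-corrected donor
    signal. Negative values are permitted (they flag over-correction).
    """
    I_D_raw = np.asarray(I_D_raw, dtype=float)
    I_A_raw = np.asarray(I_A_raw, dtype=float)
    if I_D_raw.shape != I_A_raw.shape:
        raise ValueError("channel arrays must have equal length")
    I_D = I_D_raw - params.background_donor
    I_A = I_A_raw - params.background_acceptor - params.bleedthrough * I_D
    return I_D, I_A


def compute_fret(I_D: np.ndarray, I_A: np.ndarray) -> np.ndarray:
    """Proximity ratio I_A / (I_A + I_D); NaN where the total signal is <= 0."""
    I_D = np.asarray(I_D, dtype=float)
    I_A = np.asarray(I_A, dtype=float)
    total = I_A + I_D
    with np.errstate(invalid="ignore", divide="ignore"):
        fret = np.where(total > 0, I_A / total, np.nan)
    if np.all(np.isnan(fret)):
        raise ValueError("no frame has positive total intensity")
    return fret


def classify_molecule(state_sequence: np.ndarray) -> MoleculeClass:
    """Classify a discretized two-level trace by its number of transitions."""
    seq = np.asarray(state_sequence)
    if seq.size == 0:
        raise ValueError("empty state sequence")
    n_trans = int(np.count_nonzero(np.diff(seq.astype(int)) != 0))
    if n_trans == 0:
        return MoleculeClass.STATIC_HIGH if seq[0] else MoleculeClass.STATIC_ZERO
    if n_trans == 1:
        return MoleculeClass.ONE_TRANSITION
    return MoleculeClass.DYNAMIC


def _bound_fraction(gmm: GaussianMixture, high_mean: float) -> tuple:
    means = gmm.means_.ravel()
    idx = int(np.argmin(np.abs(means - high_mean)))
    return float(gmm.weights_[idx]), means, np.sqrt(gmm.covariances_.ravel())


def fit_fret_histogram(
    fret_by_molecule: list,
    n_components: int = 2,
    n_boot: int = 100,
    seed: int | None = None,
    high_fret_mean: float = 0.75,
) -> FretHistogramFit:
    """Gaussian-mixture fit of pooled FRET frames from dynamic molecules.

    ``fraction_bound`` is the weight of the mixture component whose mean is
    nearest ``high_fret_mean``. The bootstrap resamples *molecules* (frames
    within a trace are correlated) and reports mean +/- 2 s.d. over
    ``n_boot`` replicates.
    """
    mols = [np.asarray(m, dtype=float) for m in fret_by_molecule]
    mols = [m[np.isfinite(m)] for m in mols if np.isfinite(m).any()]
    pooled = np.concatenate(mols)
    if pooled.size < 100:
        raise ValueError("need >= 100 pooled frames for a mixture fit")
    rng = np.random.default_rng(seed)

    def _fit(values: np.ndarray) -> GaussianMixture:
        gmm = GaussianMixture(
            n_components=n_components,
            random_state=int(rng.integers(2**31 - 1)),
            n_init=3,
        )
        gmm.fit(values.reshape(-1, 1))
        if not gmm.converged_:
            raise RuntimeError(
                f"mixture fit did not converge (lower bound {gmm.lower_bound_:.3g})"
            )
        return gmm

    gmm_full = _fit(pooled)
    frac, means, sds = _bound_fraction(gmm_full, high_fret_mean)
    order = np.argsort(means)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, len(mols), size=len(mols))
        sample = np.concatenate([mols[i] for i in pick])
        boot[b], _, _ = _bound_fraction(_fit(sample), high_fret_mean)
    weights = gmm_full.weights_[order]
    return FretHistogramFit(
        means=means[order],
        sds=sds[order],
        weights=weights,
        fraction_bound=frac,
        fraction_bound_boot_mean=float(boot.mean()),
        fraction_bound_boot_2sd=float(2 * boot.std(ddof=0)),
    )


def hill(conc: np.ndarray, saturation: float, midpoint: float, n: float) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    return saturation * conc**n / (conc**n + midpoint**n)


def fit_binding_isotherm(
    concentrations: np.ndarray,
    fractions_bound: np.ndarray,
    n_boot: int = 100,
    seed: int | None = None,
) -> IsothermFit:
    """Least-squares Hill fit f(c) = sat * c^n / (c^n + mid^n).

    Requires at least four concentration points and visible curvature
    (a strictly flat response is rejected rather than extrapolated).
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(fractions_bound, dtype=float)
    if c.size < 4:
        raise ValueError("need >= 4 concentration points")
    if np.ptp(f) < 1e-12:
        raise ValueError("no curvature in the binding data")
    pos = c > 0
    mid0 = np.median(c[pos])
    p0 = (max(f.max(), 1e-3), mid0, 1.0)
    bounds = ([1e-6, 1e-12, 0.05], [1.0, np.inf, 20.0])
    popt, _ = curve_fit(hill, c, f, p0=p0, bounds=bounds, maxfev=20000)
    boot_mid = []
    if n_boot > 1:
        rng = np.random.default_rng(seed)
        resid = f - hill(c, *popt)
        for _ in range(n_boot):
            fb = hill(c, *popt) + rng.choice(resid, size=len(resid), replace=True)
            try:
                pb, _ = curve_fit(hill, c, fb, p0=popt, bounds=bounds, maxfev=20000)
                boot_mid.append(pb[1])
            except RuntimeError:
                continue
    mid_2sd = float(2 * np.std(boot_mid)) if boot_mid else 0.0
    return IsothermFit(
        midpoint=float(popt[1]),
        saturation=float(popt[0]),
        hill_n=float(popt[2]),
        midpoint_boot_2sd=mid_2sd,
    )
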