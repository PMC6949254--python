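"""Sugar-ring pseudorotation analysis for nucleic-acid structures.

The conformation of a five-membered (deoxy)ribose ring is parameterized by
a pseudorotation phase P (degrees, [0, 360)) and a puckering amplitude.
Two definitions are implemented and cross-checked:

* the torsion-based formula of Altona and Sundaralingam,
      tan P = (nu4 + nu1 - nu3 - nu0) / (2 nu2 (sin 36 + sin 72)),
      nu_max = nu2 / cos P,
  on the five endocyclic torsions nu0..nu4; and
* a Cartesian definition from the out-of-plane displacements of the ring
  atoms (Cremer-Pople style), reported with a +90 degree offset so both
  phases agree on physical rings.

Phases are assigned to one of ten puckering modes (36-degree bins, with
C3'-endo centered at the canonical P = 18). A two-state North/South
reduction of a pucker time series gives repuckering rates and the
correlation time of the N/S indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "SugarRing",
    "PuckerState",
    "PuckerTrajectory",
    "RING_ATOMS",
    "PUCKER_MODES",
    "ring_torsions",
    "pseudorotation",
    "pseudorotation_from_torsions",
    "classify_pucker",
    "pucker_histogram",
    "circular_median",
    "repucker_correlation_time",
    "build_sugar_ring",
    "read_structure",
]

RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")

# ten 36-degree modes, C3'-endo covering [0, 36) so canonical P=18 is central
PUCKER_MODES = (
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
)

_AS_DENOM = 2.0 * (np.sin(np.deg2rad(36.0)) + np.sin(np.deg2rad(72.0)))
_AMP_TOL = 1.0  # deg; below this the ring is effectively planar


@dataclass(frozen=True)
class SugarRing:
    """Five ring atoms of one sugar, ordered O4', C1', C2', C3', C4' (Angstrom)."""

    coords: np.ndarray  # (5, 3)
    residue_id: int = 0
    chain_id: str = ""
    is_deoxy: bool = False

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", c)
        if c.shape != (5, 3):
            raise ValueError("coords must be (5, 3)")
        d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        if np.any(d[~np.eye(5, dtype=bool)] < 1e-6):
            raise ValueError("coincident ring atoms")


@dataclass(frozen=True)
class PuckerState:
    """Pseudorotation phase/amplitude with the one-of-ten mode label.

    ``phase``/``amplitude`` follow the torsion-based definition (degrees);
    ``phase_cartesian``/``amplitude_cartesian`` the displacement-based one
    (degrees / Angstrom). Phase is NaN for near-planar rings.
    """

    phase: float
    amplitude: float
    mode: str | None
    phase_cartesian: float = np.nan
    amplitude_cartesian: float = np.nan


@dataclass(frozen=True)
class PuckerTrajectory:
    """Uniformly sampled pucker time series for one residue."""

    dt_ps: float
    phases: np.ndarray
    residue_id: int = 0

    def __post_init__(self):
        if self.dt_ps <= 0:
            raise ValueError("time step must be positive")
        object.__setattr__(self, "phases", np.asarray(self.phases, dtype=float))


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees, (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear atom triple; dihedral undefined")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    return ang if ang != -180.0 else 180.0


def ring_torsions(ring: SugarRing) -> np.ndarray:
    """Endocyclic torsions nu0..nu4 in degrees.

    nu0: C4'-O4'-C1'-C2', nu1: O4'-C1'-C2'-C3', nu2: C1'-C2'-C3'-C4',
    nu3: C2'-C3'-C4'-O4', nu4: C3'-C4'-O4'-C1'.
    """
    # coords ordered O4'(0), C1'(1), C2'(2), C3'(3), C4'(4)
    c = ring.coords
    quads = [(4, 0, 1, 2), (0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 0), (3, 4, 0, 1)]
    return np.array([_dihedral(c[a], c[b], c[d], c[e]) for a, b, d, e in quads])


def pseudorotation_from_torsions(nu: np.ndarray) -> tuple[float, float]:
    """(phase, amplitude) in degrees from the five endocyclic torsions."""
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (5,):
        raise ValueError("need exactly five torsions")
    y = nu[4] + nu[1] - nu[3] - nu[0]
    x = nu[2] * _AS_DENOM
    # amplitude as hypot(nu2, y/denom) == nu2 / cos P, but stable at P ~ 90/270
    amplitude = np.sqrt(nu[2] ** 2 + (y / _AS_DENOM) ** 2)
    if amplitude < _AMP_TOL:
        return np.nan, float(amplitude)
    P = np.degrees(np.arctan2(y, x)) % 360.0
    if P >= 360.0 - 1e-9:
        P = 0.0
    return float(P), float(amplitude)


def _cartesian_pucker(coords: np.ndarray) -> tuple[float, float]:
    """Cremer-Pople-style (phase, amplitude_A) from out-of-plane displacements.

    The phase carries a +90 degree offset so that it matches the
    torsion-based P on physical sugar rings (agreement asserted within 2
    degrees for amplitudes above ~5 degrees).
    """
    r = coords - coords.mean(axis=0)
    j = np.arange(5)
    rp = (r * np.sin(2 * np.pi * j / 5)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / 5)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    n /= np.linalg.norm(n)
    z = r @ n
    qc = np.sqrt(2.0 / 5.0) * (z * np.cos(4 * np.pi * j / 5)).sum()
    qs = -np.sqrt(2.0 / 5.0) * (z * np.sin(4 * np.pi * j / 5)).sum()
    q = np.hypot(qc, qs)
    phi = np.degrees(np.arctan2(qs, qc))
    return (phi - 90.0) % 360.0, float(q)


def pseudorotation(ring_or_torsions) -> PuckerState:
    """PuckerState from a :class:`SugarRing` or a 5-vector of torsions.

    For rings, both the torsion-based and the Cartesian definitions are
    evaluated. Near-planar rings get a NaN phase and no mode label.
    """
    if isinstance(ring_or_torsions, SugarRing):
        nu = ring_torsions(ring_or_torsions)
        P, amp = pseudorotation_from_torsions(nu)
        Pc, qc = _cartesian_pucker(ring_or_torsions.coords)
        if not np.isfinite(P):
            Pc = np.nan
    else:
        P, amp = pseudorotation_from_torsions(ring_or_torsions)
        Pc, qc = np.nan, np.nan
    mode = classify_pucker(P) if np.isfinite(P) else None
    return PuckerState(phase=P, amplitude=amp, mode=mode,
                       phase_cartesian=Pc, amplitude_cartesian=qc)


def classify_pucker(P: float) -> str:
    """One-of-ten 36-degree mode label; C3'-endo covers [0, 36)."""
    if not np.isfinite(P):
        raise ValueError("phase undefined; cannot classify a planar ring")
    return PUCKER_MODES[int((P % 360.0) // 36.0)]


def circular_median(phases_deg: np.ndarray, max_candidates: int = 1024) -> float:
    """Phase (one of the samples) minimizing the summed circular arc distance.

    For large samples the candidate set is an evenly spaced subsample of
    the sorted phases (the cost of the full pairwise search is quadratic).
    """
    p = np.asarray(phases_deg, dtype=float) % 360.0
    if p.size == 0:
        raise ValueError("no phases")
    if p.size <= max_candidates:
        cand = p
    else:
        cand = np.sort(p)[:: max(p.size // max_candidates, 1)]
    diff = np.abs(cand[:, None] - p[None, :])
    arc = np.minimum(diff, 360.0 - diff)
    return float(cand[int(arc.sum(axis=1).argmin())])


def pucker_histogram(states, n_bins: int = 36) -> dict:
    """Circular histogram counts plus the circular median phase.

    ``states`` is an iterable of PuckerState (or raw phases in degrees);
    undefined phases are dropped.
    """
    phases = np.array(
        [s.phase if isinstance(s, PuckerState) else float(s) for s in states]
    )
    phases = phases[np.isfinite(phases)] % 360.0
    if phases.size == 0:
        raise ValueError("need at least one defined phase")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    return {"bin_edges": edges, "counts": counts, "median": circular_median(phases)}


def _north_south(phases: np.ndarray) -> np.ndarray:
    """1 = North (P in [270, 360) u [0, 90)), 0 = South (P in [90, 270))."""
    p = np.asarray(phases, dtype=float) % 360.0
    return ((p < 90.0) | (p >= 270.0)).astype(int)


def repucker_correlation_time(
    traj: PuckerTrajectory, max_lag_fraction: float = 0.25
) -> dict:
    """Repuckering kinetics from the two-state North/South reduction.

    Reports the mean dwell time on each side, the N<->S transition rates
    (1/mean dwell), and the exponential decay time of the autocorrelation
    of the N/S indicator (for a two-state telegraph process this equals
    1 / (k_NS + k_SN)). A trajectory with no transitions yields a
    one-sided report with a rate upper bound of 1/duration.
    """
    if len(traj.phases) < 100:
        raise ValueError("need at least 100 frames")
    ind = _north_south(traj.phases)
    dt = traj.dt_ps
    change = np.flatnonzero(np.diff(ind) != 0)
    result = {"n_transitions": int(len(change))}
    if len(change) == 0:
        side = "N" if ind[0] else "S"
        result.update(
            {"side": side, "mean_dwell_N_ps": np.nan, "mean_dwell_S_ps": np.nan,
             "rate_bound_per_ps": 1.0 / (len(ind) * dt),
             "correlation_time_ps": np.nan}
        )
        return result
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(ind)]))
    lengths = (ends - starts) * dt
    sides = ind[starts]
    # interior dwells only (first/last are truncated by the window)
    use = slice(1, -1) if len(lengths) > 2 else slice(None)
    ln, ls = lengths[use][sides[use] == 1], lengths[use][sides[use] == 0]
    result["mean_dwell_N_ps"] = float(ln.mean()) if ln.size else np.nan
    result["mean_dwell_S_ps"] = float(ls.mean()) if ls.size else np.nan
    result["k_NS_per_ps"] = 1.0 / result["mean_dwell_N_ps"] if ln.size else np.nan
    result["k_SN_per_ps"] = 1.0 / result["mean_dwell_S_ps"] if ls.size else np.nan
    x = ind - ind.mean()
    n = len(x)
    max_lag = max(int(n * max_lag_fraction), 10)
    # FFT autocorrelation (O(n log n); direct correlation is quadratic)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:max_lag]
    acf = acf / acf[0] if acf[0] > 0 else acf
    lags = np.arange(max_lag) * dt
    # fit only the initial decay, down to where the acf loses significance
    cut = np.argmax(acf < 0.05) or max_lag
    cut = max(cut, 5)
    try:
        popt, _ = curve_fit(
            lambda t, tau: np.exp(-t / tau), lags[:cut], acf[:cut],
            p0=(max(lags[cut - 1] / 2, dt),), maxfev=10000,
        )
        result["correlation_time_ps"] = float(popt[0])
    except RuntimeError:
        result["correlation_time_ps"] = np.nan
    return result


# ---------------------------------------------------------------------------
# ring construction (build/measure oracle) and PDB input

_PENTAGON_RADIUS = 1.26  # A; circumradius giving ~1.48 A ring bonds when planar
_Z_SCALE = 0.62 / 38.0  # A per degree of amplitude, rough starting guess


def _ring_from_qphi(q: float, phi_deg: float) -> np.ndarray:
    j = np.arange(5)
    ang = 2 * np.pi * j / 5
    xy = _PENTAGON_RADIUS * np.column_stack([np.cos(ang), np.sin(ang)])
    z = np.sqrt(2.0 / 5.0) * q * np.cos(np.deg2rad(phi_deg) + 4 * np.pi * j / 5)
    return np.column_stack([xy, z - z.mean()])


def build_sugar_ring(
    phase: float, amplitude: float, residue_id: int = 0, is_deoxy: bool = False
) -> SugarRing:
    """Construct ring coordinates realizing a requested (P, amplitude).

    A regular pentagon is puckered by out-of-plane displacements
    z_j = sqrt(2/5) q cos(phi + 4 pi j / 5); (q, phi) are then calibrated
    numerically so that the *measured* torsion-based phase and amplitude
    match the request to high precision. Serves as the independent
    build/measure oracle for the pseudorotation formulas.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude == 0:
        return SugarRing(_ring_from_qphi(0.0, 0.0), residue_id=residue_id,
                         is_deoxy=is_deoxy)

    def resid(v):
        q, phi = v
        ring = SugarRing(_ring_from_qphi(q, phi))
        P, amp = pseudorotation_from_torsions(ring_torsions(ring))
        if not np.isfinite(P):
            return [amp - amplitude, 1e3]
        dP = (P - phase + 180.0) % 360.0 - 180.0
        return [amp - amplitude, dP]

    sol = least_squares(
        resid, x0=[amplitude * _Z_SCALE, phase - 90.0],
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise RuntimeError(f"ring construction did not converge: {sol.fun}")
    return SugarRing(_ring_from_qphi(*sol.x), residue_id=residue_id,
                     is_deoxy=is_deoxy)


def read_structure(path, model: int | None = None) -> list:
    """Extract sugar rings from a PDB file, one ring list per model.

    Residues missing any of the five ring atoms (e.g. amino acids) are
    skipped with a warning. Returns a list over models, each a list of
    :class:`SugarRing`. With ``model`` given (1-based), only that model.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=model)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    models = []
    for arr in stack:
        rings = []
        for res_start in struc.get_residue_starts(arr):
            res_id = int(arr.res_id[res_start])
            chain = str(arr.chain_id[res_start])
            res_name = str(arr.res_name[res_start])
            mask = (arr.res_id == res_id) & (arr.chain_id == arr.chain_id[res_start])
            sub = arr[mask]
            coords = []
            ok = True
            for name in RING_ATOMS:
                hit = np.flatnonzero((sub.atom_name == name) |
                                     (sub.atom_name == name.replace("'", "*")))
                if hit.size == 0:
                    ok = False
                    break
                coords.append(sub.coord[hit[0]])
            if not ok:
                warnings.warn(
                    f"residue {res_name} {chain}{res_id}: missing ring atoms, skipped",
                    stacklevel=2,
                )
                continue
            is_deoxy = not np.any(sub.atom_name == "O2'")
            rings.append(SugarRing(np.array(coords), residue_id=res_id,
                                   chain_id=chain, is_deoxy=is_deoxy))
        models.append(rings)
    return models
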