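"""Trace file format, run configuration, and the end-to-end pipeline.

Traces travel as delimited text (CSV) with one row per frame and columns

    trace_id, frame_index, time_s, intensity_donor, intensity_acceptor
    [, fret][, truth_state]

frame_index is 0-based and contiguous per trace; time_s = frame_index * dt.
Unknown extra columns are preserved on round trip. Results are written as
JSON plus delimited tables into one results directory, together with a
machine-readable run log holding every seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from fretkin import dwell_analysis as dw
from fretkin import hmm_kinetics as hk
from fretkin import thermo
from fretkin import trace_processing as tp
from fretkin.synthetic_traces import FretTrace

__all__ = ["REQUIRED_COLUMNS", "RunConfig", "read_traces", "write_traces",
           "run_pipeline"]

REQUIRED_COLUMNS = (
    "trace_id", "frame_index", "time_s", "intensity_donor", "intensity_acceptor"
)


@dataclass
class RunConfig:
    """Analysis configuration; every stochastic step consumes a named seed."""

    trace_file: str = ""
    frame_rate_hz: float = 5.0
    threshold: float = 0.375
    ligand_conc_nm: float = 35.0
    temperature_k: float = 298.0
    n_boot: int = 100
    seed_bootstrap: int = 1
    seed_hmm: int = 2
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    bleedthrough: float = 0.0
    out_dir: str = "results"

    def __post_init__(self):
        for name in ("frame_rate_hz", "ligand_conc_nm", "temperature_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate_hz

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def write_traces(traces: list, path) -> None:
    """Write an ensemble to the delimited trace format (lossless round trip)."""
    rows = []
    for tr in traces:
        df = pd.DataFrame(
            {
                "trace_id": tr.trace_id,
                "frame_index": np.arange(tr.n_frames),
                "time_s": tr.time,
                "intensity_donor": tr.donor,
                "intensity_acceptor": tr.acceptor,
            }
        )
        if tr.fret is not None:
            df["fret"] = tr.fret
        if tr.truth_state is not None:
            df["truth_state"] = tr.truth_state
        for name, values in tr.extras.items():
            df[name] = values
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list:
    """Read a trace file; raises with line context on malformed input."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty trace file")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    traces = []
    for tid, g in df.groupby("trace_id", sort=False):
        g = g.reset_index()
        fi = g["frame_index"].to_numpy()
        if not np.array_equal(fi, np.arange(len(fi))):
            bad = int(np.argmax(fi != np.arange(len(fi))))
            raise ValueError(
                f"{path}: trace {tid!r} has non-contiguous frame_index near "
                f"input line {int(g.loc[bad, 'index']) + 2}"
            )
        t = g["time_s"].to_numpy()
        dt = t[1] - t[0] if len(t) > 1 else 1.0
        if np.max(np.abs(t - fi * dt)) > 1e-9 + 1e-9 * np.max(np.abs(t)):
            raise ValueError(f"{path}: trace {tid!r} time_s inconsistent with dt grid")
        known = set(REQUIRED_COLUMNS) | {"fret", "truth_state", "index"}
        extras = {c: g[c].to_numpy() for c in g.columns if c not in known}
        traces.append(
            FretTrace(
                dt=float(dt),
                donor=g["intensity_donor"].to_numpy(float),
                acceptor=g["intensity_acceptor"].to_numpy(float),
                fret=g["fret"].to_numpy(float) if "fret" in g else None,
                truth_state=(
                    g["truth_state"].to_numpy(int) if "truth_state" in g else None
                ),
                trace_id=str(tid),
                extras=extras,
            )
        )
    return traces


def _stage(log: dict, name: str):
    log["stages"].append(name)


def run_pipeline(config: RunConfig) -> dict:
    """classify -> dwell statistics -> survival fits -> global HMM with BIC
    ranking -> rate/population table -> thermodynamics.

    Writes one results directory and returns the results bundle as a dict.
    Any stage failure raises with the stage name; partial outputs written
    so far are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"config": asdict(config), "stages": []}
    bundle: dict = {}
    stage = "read"
    try:
        traces = read_traces(config.trace_file)
        _stage(log, stage)

        stage = "correct"
        corr = tp.CorrectionParams(
            background_donor=config.background_donor,
            background_acceptor=config.background_acceptor,
            bleedthrough=config.bleedthrough,
        )
        for tr in traces:
            I_D, I_A = tp.correct_intensities(tr.donor, tr.acceptor, corr)
            tr.fret = tp.compute_fret(I_D, I_A)
        _stage(log, stage)

        stage = "classify"
        classes = {}
        seqs = {}
        for tr in traces:
            seq = dw.discretize_threshold(tr.fret, config.threshold)
            seqs[tr.trace_id] = seq
            classes[tr.trace_id] = tp.classify_molecule(seq).value
        class_table = pd.DataFrame(
            {"trace_id": list(classes), "molecule_class": list(classes.values())}
        )
        class_table.to_csv(out / "classes.csv", index=False)
        bundle["classes"] = classes
        _stage(log, stage)

        stage = "dwell"
        dynamic = [tr for tr in traces
                   if classes[tr.trace_id] == tp.MoleculeClass.DYNAMIC.value]
        if not dynamic:
            raise ValueError("no dynamic molecules in the ensemble")
        pooled = dw.DwellSet([])
        summaries = []
        kd_values = []
        for tr in dynamic:
            ds = dw.extract_dwells(seqs[tr.trace_id], tr.dt, trace_id=tr.trace_id)
            pooled.extend(ds)
            s = dw.summarize_trace(ds, trace_id=tr.trace_id)
            summaries.append(s)
            kd_values.append(dw.per_molecule_kd(s, config.ligand_conc_nm))
        pd.DataFrame(
            [
                {"trace_id": s.trace_id, "t_zero_mean": s.t_zero_mean,
                 "t_high_mean": s.t_high_mean, "dt_zero_range": s.dt_zero_range,
                 "dt_high_range": s.dt_high_range,
                 "n_transitions": s.n_transitions}
                for s in summaries
            ]
        ).to_csv(out / "dwell_summaries.csv", index=False)
        bundle["cluster_center"] = dw.cluster_center(summaries, k=1)[0].tolist()
        kd_arr = np.array(kd_values)
        if np.isfinite(kd_arr).sum() >= 10:
            lf = dw.fit_logistic_cdf(kd_arr, n_boot=config.n_boot,
                                     seed=config.seed_bootstrap)
            bundle["logistic_kd_nM"] = {"kd": lf.kd, "p": lf.p,
                                        "kd_boot_2sd": lf.kd_boot_2sd}
        _stage(log, stage)

        stage = "survival"
        dt_min = 2.0 * config.dt
        surv = {}
        for state, tag in ((dw.HIGH, "high"), (dw.ZERO, "zero")):
            bi = dw.fit_biexponential(pooled, state=state, dt_min=dt_min,
                                      n_boot=config.n_boot,
                                      seed=config.seed_bootstrap)
            st = dw.fit_stretched_exp(pooled, state=state, dt_min=dt_min)
            surv[tag] = {
                "biexp": {"model": bi.model, "k_off_1": bi.k_off_1,
                          "k_off_2": bi.k_off_2, "weight_fast": bi.weight_fast,
                          "weight_fast_sd": bi.weight_fast_sd},
                "stretched": {"tau": st.tau, "beta": st.beta},
            }
        bundle["survival_fits"] = surv
        (out / "survival_fits.json").write_text(json.dumps(surv, indent=2))
        _stage(log, stage)

        stage = "hmm"
        specs = [hk.two_state_spec(), hk.degenerate_three_state_spec()]
        emis = hk.pooled_emissions(dynamic, 2, seed=config.seed_hmm)
        ranked = hk.select_model(
            dynamic, specs, fixed_emissions_by_spec=[emis, emis],
            seed=config.seed_hmm, n_restarts=2,
        )
        bic_table = [
            {"spec": r["spec"].name, "logL": r["logL"], "bic": r["bic"],
             "delta_bic": r["delta_bic"], "error": r["error"]}
            for r in ranked
        ]
        (out / "bic_ranking.json").write_text(json.dumps(bic_table, indent=2))
        best = ranked[0]["params"]
        dt = dynamic[0].dt
        K = hk.transition_to_rates(best.transmat, dt)
        pops, kd_nm = hk.state_population_kd(best, config.ligand_conc_nm)
        rates = {"spec": ranked[0]["spec"].name, "K_per_s": K.tolist(),
                 "populations": pops.tolist(), "kd_nM": kd_nm,
                 "emission_means": best.means.tolist(),
                 "emission_sds": best.sds.tolist()}
        bundle["hmm"] = rates
        bundle["bic_ranking"] = bic_table
        (out / "hmm_rates.json").write_text(json.dumps(rates, indent=2))
        _stage(log, stage)

        stage = "thermo"
        consts = thermo.ThermoConstants(T=config.temperature_k)
        c_molar = config.ligand_conc_nm * 1e-9
        k_on_pseudo = K[0, 1]
        k_on = thermo.kon_from_pseudo_first_order(k_on_pseudo, c_molar)
        th = {
            "k_on_pseudo_per_s": k_on_pseudo,
            "k_on_per_M_s": k_on,
            "k_off_per_s": K[1, 0],
            "kd_nM_population": kd_nm,
            "kd_nM_from_rates": thermo.kd_from_rates(k_on, K[1, 0]) * 1e9
            if k_on > 0 and K[1, 0] > 0 else np.nan,
            "delta_g_bind_kj_mol": thermo.delta_g_bind(kd_nm * 1e-9, consts)
            if np.isfinite(kd_nm) and kd_nm > 0 else np.nan,
            "delta_g_barrier_kj_mol": thermo.delta_g_barrier(k_on, consts)
            if k_on > 0 else np.nan,
        }
        bundle["thermo"] = th
        (out / "thermo.json").write_text(json.dumps(th, indent=2))
        _stage(log, stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log["n_traces"] = len(traces)
    log["n_dynamic"] = len(dynamic)
    import fretkin

    log["fretkin_version"] = fretkin.__version__
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    bundle["log"] = log
    return bundle
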