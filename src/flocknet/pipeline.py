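"""End-to-end orchestration: simulate -> curate -> dtw -> network -> couple.

One :class:`PipelineConfig` drives every stage; every stochastic stage
has an explicit seed and all parameters are serialized into the report,
so a rerun with the same config reproduces the report exactly.  Pens are
processed independently end-to-end; per-pen p-values combine via
Fisher's method at the final stage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling, curation, dtw, io, network
from .areas import default_gate_map
from .synthetic import SimConfig, simulate_flock

log = logging.getLogger("flocknet")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Parameters of one full pipeline run."""

    sim: SimConfig | None = None  # simulate when set...
    events_path: str | None = None  # ...otherwise read this CSV
    gate_map_path: str | None = None
    n_pens: int = 1  # independent replicate pens (simulation only)
    bin: int = 60
    cooccurrence_window: float = 5.0
    k_clusters: int | None = None  # None = silhouette-selected in 2..6
    cluster_method: str = "diana"
    n_perm_mantel: int = 10000
    n_perm_autocorr: int = 100
    n_perm_strength: int = 200
    autocorr_lags: int = 5
    timeshift_dyads: int = 200
    timeshift_seconds: float = 60.0
    seed: int = 0
    stages: tuple[str, ...] = ("curate", "dtw", "network", "couple")
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


def validate_inputs(events: pd.DataFrame, gate_map: dict | None = None) -> dict:
    """QC summary of a raw event log.

    Counts records, unknown antennas/hens (against the hens present),
    non-monotone per-hen-day streams, and the located-time fraction per
    hen (time not spanned by interpolated transition chains).
    """
    gate_map = gate_map or default_gate_map()
    qc: dict = {"n_records": int(len(events))}
    qc["n_unknown_antenna"] = int((~events.antenna_id.isin(gate_map.keys())).sum())
    known = events[events.antenna_id.isin(gate_map.keys())]
    nonmono = 0
    for _, grp in known.groupby(["hen_id", "day"], sort=False):
        if (np.diff(grp.time_s.to_numpy()) < 0).any():
            nonmono += 1
    qc["n_nonmonotone_hen_days"] = nonmono
    hens = sorted(events.hen_id.unique())
    qc["n_hens"] = len(hens)
    qc["n_days"] = int(events.day.nunique())
    if nonmono == 0 and len(known):
        trans = curation.pair_registrations(known.sort_values(["hen_id", "day", "time_s"]), hens, gate_map)
        day_len = float(events.time_s.max()) + 1
        located = {}
        for hen, grp in trans.groupby("hen_id"):
            unc = 0.0
            for _, g in grp.groupby("day"):
                t = g.time_s.to_numpy()
                interp = g.interpolated.to_numpy()
                # an interpolated run spans uncertainty from the previous
                # known time to the next known time
                prev_known = 0.0
                i = 0
                while i < len(t):
                    if interp[i]:
                        j = i
                        while j < len(t) and interp[j]:
                            j += 1
                        nxt = t[j] if j < len(t) else day_len
                        unc += nxt - prev_known
                        i = j
                    else:
                        prev_known = t[i]
                        i += 1
            located[hen] = 1.0 - unc / (day_len * max(grp.day.nunique(), 1))
        qc["located_fraction"] = located
        qc["mean_located_fraction"] = float(np.mean(list(located.values())))
    return qc


def _analyse_pen(
    pen: str,
    events: pd.DataFrame,
    hens: list[str],
    n_days: int,
    day_length: int,
    cfg: PipelineConfig,
    outdir: Path | None,
    rng: np.random.Generator,
) -> dict:
    t0 = time.time()
    report: dict = {"pen": pen, "n_hens": len(hens), "n_days": n_days}
    gate_map = default_gate_map()

    trans = curation.pair_registrations(events, hens, gate_map)
    sojourns = curation.extract_sojourns(events, hens, gate_map)
    series = curation.build_series_array(trans, hens, n_days, cfg.bin, day_length)
    summaries = curation.compute_hen_summary(trans, series, hens)
    report["curate"] = {
        "n_transitions": int(len(trans)),
        "n_interpolated": int(trans.interpolated.sum()),
        "n_sojourns": int(len(sojourns)),
        "qc": trans.attrs.get("qc", {}),
    }
    if outdir:
        trans.to_csv(outdir / f"{pen}_transitions.csv", index=False)
        sojourns.to_csv(outdir / f"{pen}_sojourns.csv", index=False)
        summaries.to_csv(outdir / f"{pen}_summaries.tsv", sep="\t", index=False)
    log.info("[%s] curation done in %.1fs", pen, time.time() - t0)
    if "dtw" not in cfg.stages:
        return report

    t0 = time.time()
    daily_mats = dtw.daily_distance_matrices(series)
    summed = dtw.summed_matrix_from_daily(daily_mats)
    trend = dtw.daily_dissimilarity_trend(daily_mats)
    clusters = dtw.cluster_hens(
        summed, k=cfg.k_clusters, hens=hens, method=cfg.cluster_method, summaries=summaries
    )
    report["dtw"] = {
        "daily_mean_dissimilarity": [float(m) for m in trend.daily_means],
        "trend": {"slope": trend.slope, "F": trend.F, "p": trend.p, "r2_adj": trend.r2_adj},
        "k_clusters": clusters.k,
        "cluster_method": clusters.method,
        "silhouette": clusters.silhouette,
    }
    if n_days >= 2:
        M4 = dtw.build_hypermatrix(series)
        wb = dtw.within_between_comparison(M4, hens)
        report["dtw"]["within_between"] = {
            "V": wb.V,
            "p": wb.p,
            "degenerate": wb.degenerate,
            "frac_within_smaller": float(
                (wb.per_hen.median_within < wb.per_hen.median_between).mean()
            ),
        }
        if outdir:
            io.write_hypermatrix(M4, hens, list(range(n_days)), outdir / f"{pen}_hypermatrix.npz")
    if outdir:
        io.write_matrix(summed, hens, outdir / f"{pen}_summed_dtw.tsv")
        pd.Series(clusters.labels, name="cluster").rename_axis("hen_id").to_csv(
            outdir / f"{pen}_clusters.tsv", sep="\t"
        )
    log.info("[%s] dtw done in %.1fs", pen, time.time() - t0)
    if "network" not in cfg.stages:
        return report

    t0 = time.time()
    counts = network.detect_cooccurrences(trans, hens, cfg.cooccurrence_window)
    ai = network.association_matrix(counts)
    daily_ai = network.daily_association_matrices(trans, hens, cfg.cooccurrence_window)
    comms = network.detect_communities(ai, hens)
    pr = network.pagerank_centrality(ai, hens)
    lags = range(1, min(cfg.autocorr_lags, n_days - 1) + 1)
    autoc = (
        network.network_autocorrelation(
            [daily_ai[d] for d in sorted(daily_ai)],
            lags,
            n_perm=cfg.n_perm_autocorr,
            seed=int(rng.integers(2**31)),
        )
        if n_days > 2
        else None
    )
    strength = network.strength_null_cdf(
        trans, hens, n_perm=cfg.n_perm_strength, window=cfg.cooccurrence_window,
        seed=int(rng.integers(2**31)),
    )
    report["network"] = {
        "mean_ai": float(coupling._upper_tri(ai).mean()),
        "density": float((coupling._upper_tri(ai) > 0).mean()),
        "n_communities": comms.n_communities,
        "modularity": comms.modularity,
        "assortativity": comms.assortativity,
        "pagerank_range": [float(pr.min()), float(pr.max())],
        "strength_cdf_ks_p": strength.p,
        "autocorrelation": autoc.to_dict(orient="list") if autoc is not None else None,
    }
    if outdir:
        io.write_matrix(ai, hens, outdir / f"{pen}_ai_pooled.tsv")
        io.write_network(ai, hens, outdir / f"{pen}_network.graphml", outdir / f"{pen}_edges.csv")
    log.info("[%s] network done in %.1fs", pen, time.time() - t0)
    if "couple" not in cfg.stages:
        return report

    t0 = time.time()
    mant = coupling.mantel_test(
        ai, summed, n_perm=cfg.n_perm_mantel, seed=int(rng.integers(2**31))
    )
    days_sorted = sorted(daily_ai)
    trend_c = coupling.daily_coupling_trend(
        [daily_ai[d] for d in days_sorted], [daily_mats[d] for d in days_sorted]
    )
    shift = coupling.timeshift_control(
        trans,
        hens,
        n_dyads=cfg.timeshift_dyads,
        shift=cfg.timeshift_seconds,
        bin=cfg.bin,
        day_length=day_length,
        window=cfg.cooccurrence_window,
        seed=int(rng.integers(2**31)),
    )
    gtab = pd.crosstab(
        pd.Series({h: clusters.labels[h] for h in hens}, name="cluster"),
        pd.Series({h: comms.labels[h] for h in hens}, name="community"),
    )
    try:
        G, gdf, gp = coupling.g_test(gtab.to_numpy())
    except ValueError:
        G, gdf, gp = np.nan, 0, np.nan
    report["couple"] = {
        "mantel": {
            "r": mant.r, "p": mant.p, "sigma": mant.sigma,
            "null_ci": [mant.null_low, mant.null_high], "n_perm": mant.n_perm,
        },
        "daily_trend": {
            "slope": trend_c.slope, "F": trend_c.F, "p": trend_c.p, "r2_adj": trend_c.r2_adj,
        },
        "timeshift": {
            "dtw_r": shift.dtw_r, "ai_r": shift.ai_r,
            "coupling_before": shift.coupling_before, "coupling_after": shift.coupling_after,
        },
        "g_test": {"G": G, "df": gdf, "p": gp},
    }
    log.info("[%s] coupling done in %.1fs", pen, time.time() - t0)

    if cfg.make_figures and outdir:
        _figures(pen, strength, autoc, trend_c, days_sorted, outdir)
    return report


def _figures(pen, strength, autoc, trend_c, days, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.plot(strength.grid, strength.observed_cdf, color="red", label="observed")
    ax.fill_between(strength.grid, strength.null_low, strength.null_high,
                    color="grey", alpha=0.5, label="null 95% envelope")
    ax.set_xlabel("dyadic association strength (AI)")
    ax.set_ylabel("CDF")
    ax.legend()
    fig.savefig(outdir / f"{pen}_strength_cdf.svg")
    plt.close(fig)

    if autoc is not None:
        fig, ax = plt.subplots()
        ax.plot(autoc.lag, autoc.r_mean, color="tab:blue", label="observed")
        ax.fill_between(autoc.lag, autoc.ci_low, autoc.ci_high, color="tab:blue", alpha=0.3)
        ax.plot(autoc.lag, autoc.null_mean, color="tab:orange", label="null")
        ax.fill_between(autoc.lag, autoc.null_low, autoc.null_high, color="tab:orange", alpha=0.3)
        ax.set_xlabel("lag (days)")
        ax.set_ylabel("network autocorrelation r")
        ax.legend()
        fig.savefig(outdir / f"{pen}_autocorrelation.svg")
        plt.close(fig)

    fig, ax = plt.subplots()
    ax.scatter(days, trend_c.daily_r, s=12, color="tab:blue")
    ax.set_xlabel("day")
    ax.set_ylabel("daily AI-DTW matrix correlation")
    fig.savefig(outdir / f"{pen}_daily_coupling.svg")
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig, outdir=None) -> dict:
    """Run all configured stages and return the consolidated report.

    With ``outdir`` set, stage outputs (CSV/TSV/GraphML/npz/SVG) and the
    report JSON are written under it.
    """
    outdir = Path(outdir) if outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    report: dict = {"config": _config_dict(cfg), "pens": []}

    pens: list[tuple[str, pd.DataFrame, list[str], int, int]] = []
    if cfg.sim is not None:
        for p in range(cfg.n_pens):
            sim_cfg = cfg.sim.with_(seed=cfg.sim.seed + p)
            events, truth = simulate_flock(sim_cfg)
            if outdir:
                io.write_events(events, outdir / f"pen{p + 1}_events.csv")
            pens.append(
                (f"pen{p + 1}", events, truth.hens, sim_cfg.n_days, sim_cfg.day_length)
            )
    elif cfg.events_path:
        events = io.read_events(cfg.events_path)
        hens = sorted(events.hen_id.unique())
        n_days = int(events.day.max()) + 1
        day_length = int(events.time_s.max()) + 1
        pens.append(("pen1", events, hens, n_days, day_length))
    else:
        raise ValueError("config must provide either a simulation or an event CSV path")

    for pen, events, hens, n_days, day_length in pens:
        report["pens"].append(
            _analyse_pen(pen, events, hens, n_days, day_length, cfg, outdir, rng)
        )

    if "couple" in cfg.stages and len(report["pens"]) > 1:
        trend_ps = [p["couple"]["daily_trend"]["p"] for p in report["pens"]]
        trend_ps = [max(min(p, 1.0), 1e-300) for p in trend_ps]
        X2, df, p = coupling.fisher_combined(trend_ps)
        report["combined"] = {"daily_trend_fisher": {"X2": X2, "df": df, "p": p}}

    if outdir:
        io.dump_json(report, outdir / "report.json")
    return report


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    if cfg.sim is not None:
        sim = asdict(cfg.sim)
        sim["types"] = [t.name for t in cfg.sim.types]
        d["sim"] = sim
    d["stages"] = list(cfg.stages)
    return d
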