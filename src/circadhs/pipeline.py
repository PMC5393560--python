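"""End-to-end orchestration: simulate -> peaks -> quantify -> rhythms ->
(optionally) motif activities, with one seed hierarchy and a hashed manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dhs_atlas, genomeio, motif_activity, rhythm_stats, simdata

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "peaks", "quantify", "rhythm", "activities")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage substream seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    outdir: str = "circadhs_run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "peaks", "quantify", "rhythm")
    sim: dict = field(default_factory=dict)           # SimConfig overrides
    peak_params: dict = field(default_factory=dict)   # PeakParams overrides
    fdr_sites: float = 0.05
    fdr_pairs: float = 0.1
    # between-time normalization of log2 signals per mark: "median" (robust
    # column centering), "quantile" (full distribution matching) or "none"
    normalization: str = "median"
    activity_radius: int = 50_000
    activity_alpha: float = 0.1
    activity_cv_folds: int = 10

    def __post_init__(self) -> None:
        for thr in (self.fdr_sites, self.fdr_pairs):
            if not 0 < thr < 1:
                raise ValueError("FDR thresholds must lie in (0, 1)")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.normalization not in ("median", "quantile", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data = {**data, "stages": tuple(data["stages"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest dict (also written to <outdir>/manifest.json) and
    keeps in-memory stage products under the "results" key.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    results: dict = {}
    times = None

    def finish_stage(name: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][name] = {"wall_time_s": round(time.time() - t0, 3),
                                    "seed": stage_seed(config.seed, name)}
        for f in files:
            manifest["files"][str(f.relative_to(outdir))] = _hash_file(f)
        logger.info("stage %s done (%.2fs)", name, time.time() - t0)

    # ---- simulate ---------------------------------------------------------
    t0 = time.time()
    sim_cfg = simdata.SimConfig(seed=stage_seed(config.seed, "simulate"), **config.sim)
    sim = simdata.simulate_study(sim_cfg)
    results["sim"] = sim
    times = sim.times
    tss_path = outdir / "active_tss.bed"
    genomeio.write_bed(tss_path, sim.tss_intervals())
    truth_path = outdir / "truth.json"
    sim.truth.to_json(truth_path)
    finish_stage("simulate", t0, [tss_path, truth_path])
    if "peaks" not in config.stages:
        _write_manifest(outdir, manifest)
        return {**manifest, "results": results}

    # ---- peaks ------------------------------------------------------------
    t0 = time.time()
    merged = genomeio.CutTrack.merge_all(list(sim.tracks["dnase"].values()))
    params = dhs_atlas.PeakParams(**config.peak_params)
    peaks = dhs_atlas.call_peaks(merged, params)
    active_tss = sim.genes[sim.genes["active"]][["gene_id", "chrom", "tss", "strand"]]
    peaks = dhs_atlas.annotate_to_tss(peaks, active_tss)
    results["peaks"] = peaks
    peaks_path = outdir / "peaks.bed"
    genomeio.write_bed(peaks_path, [p.interval for p in peaks])
    annot = pd.DataFrame([{"dhs_id": p.dhs_id, "gene": p.nearest_tss,
                           "distance": p.distance, "dclass": p.dclass} for p in peaks])
    annot_path = outdir / "peaks_annotation.tsv"
    annot.to_csv(annot_path, sep="\t", index=False)
    results["annotation"] = annot
    finish_stage("peaks", t0, [peaks_path, annot_path])
    if "quantify" not in config.stages:
        _write_manifest(outdir, manifest)
        return {**manifest, "results": results}

    # ---- quantify ---------------------------------------------------------
    t0 = time.time()
    sites = [p.interval for p in peaks]
    norm = {}
    for mark in simdata.MARKS:
        hw = simdata.MARK_HALFWIDTH[mark]
        raw = pd.DataFrame(
            {t: genomeio.quantify_signal(sim.tracks[mark][t], sites, hw) for t in times},
            index=[p.dhs_id for p in peaks])
        logged = genomeio.log2_transform(raw)
        if config.normalization == "quantile":
            norm[mark] = genomeio.quantile_normalize(logged)
        elif config.normalization == "median":
            norm[mark] = rhythm_stats.rhythm_adjusted_column_center(logged, times)
        else:
            norm[mark] = logged
    signal = pd.concat(norm, axis=1)
    signal.columns = pd.MultiIndex.from_tuples(
        [(m, t) for m, t in signal.columns], names=["mark", "time"])
    results["signal"] = signal
    sig_path = outdir / "signals.tsv"
    genomeio.write_signal_matrix(sig_path, signal)
    finish_stage("quantify", t0, [sig_path])
    if "rhythm" not in config.stages:
        _write_manifest(outdir, manifest)
        return {**manifest, "results": results}

    # ---- rhythm -----------------------------------------------------------
    t0 = time.time()
    fits = {}
    pmat = []
    for mark in simdata.MARKS:
        f = rhythm_stats.harmonic_fit_many(times, norm[mark])
        fits[mark] = f
        pmat.append(f["pvalue"].to_numpy())
    stat, combined_p = rhythm_stats.fisher_combine_matrix(np.column_stack(pmat))
    qvals = rhythm_stats.bh_fdr(combined_p)
    rhythm = pd.DataFrame({
        "dhs_id": [p.dhs_id for p in peaks],
        "fisher_stat": stat, "pvalue": combined_p, "qvalue": qvals,
        "phase_dnase": fits["dnase"]["phase"].to_numpy(),
        "amp_dnase": fits["dnase"]["amplitude"].to_numpy(),
        "phase_polii": fits["polii"]["phase"].to_numpy(),
        "cycling": qvals <= config.fdr_sites,
    })
    results["rhythm"] = rhythm
    results["fits"] = fits
    rhythm_path = outdir / "rhythms.tsv"
    rhythm.to_csv(rhythm_path, sep="\t", index=False)
    finish_stage("rhythm", t0, [rhythm_path])
    if "activities" not in config.stages:
        _write_manifest(outdir, manifest)
        return {**manifest, "results": results}

    # ---- activities -------------------------------------------------------
    t0 = time.time()
    pwms = [motif_activity.PWM.from_consensus(m.id, m.consensus)
            for m in sim.config.motif_library]
    dhs_table = pd.DataFrame({
        "dhs_id": [p.dhs_id for p in peaks],
        "chrom": [p.interval.chrom for p in peaks],
        "center": [p.center for p in peaks]})
    hits = motif_activity.scan_dhs_set(sim.sequences, dhs_table, pwms)
    active_genes = sim.genes[sim.genes["active"]]
    polii_tss = sim.log2_levels["polii"].loc[active_genes["gene_id"]]
    P = motif_activity.phase_vector(times, polii_tss)
    tss_table = active_genes[["gene_id", "chrom", "tss"]]
    N = motif_activity.build_motif_matrix(hits, dhs_table, tss_table,
                                          config.activity_radius)
    est = motif_activity.fit_activities(P, N, alpha=config.activity_alpha,
                                        cv_folds=config.activity_cv_folds,
                                        seed=stage_seed(config.seed, "activities"))
    results["activities"] = est
    act_path = outdir / "activities.tsv"
    est.activities.to_csv(act_path, sep="\t", index_label="motif")
    finish_stage("activities", t0, [act_path])

    _write_manifest(outdir, manifest)
    return {**manifest, "results": results}


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({k: v for k, v in manifest.items() if k != "results"}, fh, indent=1)


def evaluate_cycling_screen(rhythm: pd.DataFrame, match: pd.DataFrame,
                            dhs_truth: pd.DataFrame) -> dict:
    """Sensitivity and realized FDR of the cycling-site screen versus truth.

    Sensitivity counts recovered truly-rhythmic sites; a call is false only
    when it lands on a site with zero true amplitude (sub-threshold but
    nonzero oscillations are real signal, not false discoveries).
    """
    merged = rhythm.merge(match, left_on="dhs_id", right_on="peak_id")
    called = merged[merged["cycling"]]
    truth_cyc = set(dhs_truth.loc[dhs_truth["rhythmic"], "dhs_id"])
    recovered = set(called["true_dhs"].dropna()) & truth_cyc
    n_false = int((called["true_amplitude"] <= 1e-9).sum())
    return {
        "sensitivity": len(recovered) / len(truth_cyc) if truth_cyc else float("nan"),
        "realized_fdr": n_false / max(len(called), 1),
        "n_called": int(len(called)),
        "n_true_cycling": len(truth_cyc),
    }


def match_peaks_to_truth(peaks, sim, max_dist: int = 600) -> pd.DataFrame:
    """Associate called peaks with simulated DHSs by interval overlap.

    The default radius equals the peak width, i.e. the usual any-overlap rule
    for 600-bp intervals. Returns one row per called peak with the matched
    true DHS (or None), its rhythmicity flag and true amplitude.
    """
    truth = sim.dhs.merge(sim.truth.dhs_truth[["dhs_id", "rhythmic", "amplitude"]],
                          on="dhs_id")
    rows = []
    for p in peaks:
        sub = truth[truth["chrom"] == p.interval.chrom]
        d = (sub["center"] - p.center).abs()
        if len(d) and d.min() <= max_dist:
            hit = sub.loc[d.idxmin()]
            rows.append({"peak_id": p.dhs_id, "true_dhs": hit["dhs_id"],
                         "true_rhythmic": bool(hit["rhythmic"]),
                         "true_amplitude": float(hit["amplitude"])})
        else:
            rows.append({"peak_id": p.dhs_id, "true_dhs": None,
                         "true_rhythmic": False, "true_amplitude": 0.0})
    return pd.DataFrame(rows)
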