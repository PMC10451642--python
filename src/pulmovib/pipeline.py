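"""End-to-end orchestration of the two studies.

* ``run_six_state`` — six discrete resistance states: generate the
  recordings, segment each one on the servo pulse, extract the per-cycle
  burst features, and test every feature for pairwise group differences
  (Kruskal–Wallis omnibus + Dunn–Bonferroni pairs).  A trend summary
  reports the direction of each feature's group-median ladder.

* ``run_continuous`` — five continuous resistance-sweep runs: per-cycle
  features and pressure parameters, the feature/pressure correlation
  table, and leave-one-group-out regression (feature-based network and,
  optionally, the waveform deep model).

Both return plain dict bundles; ``save_bundle`` writes them out as
CSV/JSON.  Every random draw derives from the seeds recorded in the
manifest, so reruns are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pulmovib import features, regress, sigproc, stats, synth

__all__ = [
    "StudyConfig",
    "extract_cycle_table",
    "run_six_state",
    "run_continuous",
    "save_bundle",
]

#: feature columns whose group trend is summarised, with the direction the
#: rig exhibits as distal resistance rises
TREND_DIRECTIONS = {"Amp": +1, "Ener": +1, "MS": -1, "f": -1, "Pow": +1}


@dataclass
class StudyConfig:
    """Configuration of one study run."""

    study: str = "six_state"  # or "continuous"
    seed: int = 0
    duration: float | None = None  # None -> study default (300 s / 600 s)
    n_runs: int = 5
    alpha: float = 0.05
    with_deep: bool = True
    bpnn: regress.BPNNSpec = field(default_factory=regress.BPNNSpec)
    deep: regress.DeepSpec = field(default_factory=regress.DeepSpec)
    generator: synth.MCLConfig = field(default_factory=synth.MCLConfig)


def extract_cycle_table(rec: synth.Recording, keep_waveforms: bool = False):
    """Full per-recording processing chain.

    Low-pass the pressure, denoise the sounds, segment on servo edges,
    extract burst windows and assemble the per-cycle feature table.
    Returns (table, segments) or (table, segments, denoised sounds).
    """
    p = sigproc.lowpass_pressure(rec.p_pa, rec.fs)
    edges = sigproc.detect_edges(rec.servo, rec.fs)
    segs = sigproc.per_cycle_pressure_params(p, edges, rec.fs)
    snd_t = sigproc.denoise_vibration(rec.snd_tricuspid)
    snd_p = sigproc.denoise_vibration(rec.snd_pulmonary)
    wt = [
        sigproc.extract_valve_sound(
            snd_t, sigproc.tricuspid_search_window(s), rec.fs, "tricuspid")
        for s in segs
    ]
    wp = [
        sigproc.extract_valve_sound(
            snd_p, sigproc.pulmonary_search_window(s), rec.fs, "pulmonary")
        for s in segs
    ]
    table = features.feature_table(segs, wt, wp)
    if keep_waveforms:
        return table, segs, (snd_t, snd_p)
    return table, segs


def run_six_state(config: StudyConfig | None = None) -> dict:
    """Six-state group study: recordings -> features -> pairwise stats."""
    cfg = config or StudyConfig(study="six_state")
    duration = cfg.duration or 300.0
    recs = synth.generate_six_state_dataset(
        seed=cfg.seed, duration=duration, config=cfg.generator
    )
    tables = []
    for i, rec in enumerate(recs):
        tab, _ = extract_cycle_table(rec)
        tab = tab.assign(state=i + 1)
        tables.append(tab)
    pooled = pd.concat(tables, ignore_index=True)
    feature_cols = [
        f"{n}_{s}" for s in ("t", "p") for n in features.FEATURE_NAMES
    ]
    matrices = {
        col: stats.pairwise_significance(
            pooled[col], pooled["state"], alpha=cfg.alpha, feature=col)
        for col in feature_cols
    }
    trends = {}
    for col in feature_cols:
        base = col.rsplit("_", 1)[0]
        med = pooled.groupby("state")[col].median()
        rho = med.corr(pd.Series(med.index, index=med.index), method="spearman")
        trends[col] = {
            "median_by_state": med.to_dict(),
            "spearman_vs_state": float(rho),
            "expected_sign": TREND_DIRECTIONS.get(base),
            "matches": (
                None if base not in TREND_DIRECTIONS
                else bool(np.sign(rho) == TREND_DIRECTIONS[base])
            ),
        }
    manifest = {
        "study": "six_state",
        "seed": cfg.seed,
        "duration_s": duration,
        "n_states": len(recs),
        "alpha": cfg.alpha,
        "n_cycles": [int(t["cycle"].count()) for t in tables],
        "generator": {
            "fs": cfg.generator.fs,
            "cycle_period": cfg.generator.cycle_period,
            "noise_sd_pressure": cfg.generator.noise_sd_pressure,
            "noise_sd_sound": cfg.generator.noise_sd_sound,
        },
    }
    return {
        "tables": tables,
        "pooled": pooled,
        "pairwise": matrices,
        "trends": trends,
        "manifest": manifest,
    }


def run_continuous(config: StudyConfig | None = None) -> dict:
    """Continuous-sweep study: features -> correlations -> regression."""
    cfg = config or StudyConfig(study="continuous")
    duration = cfg.duration or 600.0
    recs = synth.generate_continuous_dataset(
        seed=cfg.seed, duration=duration, n_runs=cfg.n_runs,
        config=cfg.generator,
    )
    tables, seg_lists, denoised = [], [], []
    for i, rec in enumerate(recs):
        tab, segs, snds = extract_cycle_table(rec, keep_waveforms=True)
        tables.append(tab.assign(run=i + 1))
        seg_lists.append(segs)
        denoised.append(snds)
    pooled = pd.concat(tables, ignore_index=True)
    cc = stats.correlation_table(pooled.dropna())

    # feature-based regression, leave one run out
    cols = list(stats.TABLE_FEATURES)
    tcols = list(stats.PRESSURE_PARAMS)
    gX, gY = [], []
    for tab in tables:
        clean = tab.dropna(subset=cols + tcols)
        gX.append(clean[cols].to_numpy())
        gY.append(clean[tcols].to_numpy())
    bpnn_folds, bpnn_mae = regress.leave_one_group_out(
        gX, gY, lambda X, Y: regress.train_bpnn(X, Y, cfg.bpnn)
    )

    out = {
        "tables": tables,
        "correlations": cc,
        "bpnn": {"folds": bpnn_folds, "pooled_mae": bpnn_mae},
        "manifest": {
            "study": "continuous",
            "seed": cfg.seed,
            "duration_s": duration,
            "n_runs": cfg.n_runs,
            "n_cycles": [len(t) for t in tables],
            "with_deep": cfg.with_deep,
        },
    }

    if cfg.with_deep:
        wX, wY = [], []
        for rec, segs, snds in zip(recs, seg_lists, denoised):
            X, Y = regress.waveform_dataset(
                rec, segs, seq_len=cfg.deep.seq_len, denoised=snds
            )
            wX.append(X)
            wY.append(Y)
        deep_folds, deep_mae = regress.leave_one_group_out(
            wX, wY, lambda X, Y: regress.train_deep(X, Y, cfg.deep)
        )
        out["deep"] = {"folds": deep_folds, "pooled_mae": deep_mae}
    return out


def save_bundle(bundle: dict, outdir: str | Path) -> None:
    """Write a study bundle as CSV/JSON files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "pooled" in bundle:
        bundle["pooled"].to_csv(outdir / "features.csv", index=False)
    if "correlations" in bundle:
        bundle["correlations"].to_csv(outdir / "correlations.csv")
    if "pairwise" in bundle:
        mats = {
            name: {
                "groups": [int(g) for g in m.groups],
                "p_matrix": np.round(m.p_matrix, 6).tolist(),
                "sig_matrix": m.sig_matrix.tolist(),
                "H": m.H,
                "p_omnibus": m.p_omnibus,
            }
            for name, m in bundle["pairwise"].items()
        }
        (outdir / "pairwise.json").write_text(json.dumps(mats, indent=1))
    if "trends" in bundle:
        (outdir / "trends.json").write_text(
            json.dumps(bundle["trends"], indent=1, default=float))
    for key in ("bpnn", "deep"):
        if key in bundle:
            rows = []
            for fold in bundle[key]["folds"]:
                for (m_row, p_row) in zip(fold.measured, fold.predicted):
                    rows.append([fold.fold, *m_row, *p_row])
            pd.DataFrame(
                rows,
                columns=["fold", "PASP", "MRR", "MFR",
                         "PASP_pred", "MRR_pred", "MFR_pred"],
            ).to_csv(outdir / f"{key}_predictions.csv", index=False)
            (outdir / f"{key}_mae.json").write_text(
                json.dumps(bundle[key]["pooled_mae"], indent=1))
    if "manifest" in bundle:
        (outdir / "manifest.json").write_text(
            json.dumps(bundle["manifest"], indent=1, default=str))
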