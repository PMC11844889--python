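"""End-to-end experiment orchestration.

``run_experiment`` executes simulate → select windows → spectrograms →
decode → shuffled-label null → cross-nucleus comparison → autonomic
analysis, writing one artifact per stage under the configured output
directory.  Completed stages are skipped on re-run when their inputs
(the resolved configuration) are unchanged, checked by content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .autonomic import clean_ibi, interpolate_hr, rsa_strength
from .config import ExperimentConfig
from .decoding import (CNNSpec, TrainConfig, build_dataset, evaluate_repetitions,
                       make_cnn_factory, make_svm_factory, session_spectrograms)
from .nullmodel import bootstrap_null, compare_nuclei
from .protocol import StimulusTrainConfig, generate_protocol
from .session_io import export_events_csv, export_ibi_csv, load_session, save_session
from .simulate import EffectSpec, simulate_context_ibi, simulate_lfp_session
from .timefreq import CWTParams
from .windows import select_windows, windows_to_frame

logger = logging.getLogger(__name__)


def _config_hash(cfg: ExperimentConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _stage_done(out: Path, stage: str, cfg_hash: str, outputs: list) -> bool:
    manifest = out / f".{stage}.manifest.json"
    if not manifest.exists():
        return False
    try:
        recorded = json.loads(manifest.read_text())
    except json.JSONDecodeError:
        return False
    return recorded.get("config_hash") == cfg_hash and all(
        (out / p).exists() for p in outputs)


def _mark_stage(out: Path, stage: str, cfg_hash: str, outputs: list) -> None:
    _write_json(out / f".{stage}.manifest.json",
                {"config_hash": cfg_hash, "outputs": outputs})


def cwt_params(cfg: ExperimentConfig) -> CWTParams:
    freqs = np.arange(cfg.freq_lo, cfg.freq_hi + cfg.freq_step / 2, cfg.freq_step)
    return CWTParams(f0=cfg.cwt_f0, freqs=freqs, scale_rule=cfg.scale_rule)


def build_session(cfg: ExperimentConfig):
    airflow = StimulusTrainConfig(cfg.airflow_sequence_length, cfg.airflow_repetitions,
                                  cfg.stimulus_duration_s, cfg.stimulus_gap_s, 0.0)
    touch = StimulusTrainConfig(cfg.touch_sequence_length, cfg.touch_repetitions,
                                cfg.stimulus_duration_s, cfg.stimulus_gap_s,
                                cfg.touch_jitter_s)
    protocol = generate_protocol(airflow, touch, cfg.n_block_pairs,
                                 cfg.inter_block_gap_s, seed=cfg.seed)
    effect = EffectSpec(band_lo=cfg.band_lo, band_hi=cfg.band_hi,
                        power_ratio=cfg.power_ratio,
                        background_exponent=cfg.background_exponent,
                        noise_sd=cfg.noise_sd, shared_fraction=cfg.shared_fraction)
    session = simulate_lfp_session(protocol, cfg.channels_per_nucleus, effect,
                                   fs=cfg.fs, seed=cfg.seed)
    session.heartbeats = simulate_context_ibi(
        protocol, cfg.mean_hr_bpm, cfg.resp_freq_hz, cfg.resp_depth_touch,
        cfg.resp_depth_airflow, cfg.artifact_rate, seed=cfg.seed)
    return session


def _decode_nucleus(cfg: ExperimentConfig, session, windows, nucleus: str, seed: int):
    params = cwt_params(cfg)
    band = tuple(cfg.restrict_band) if cfg.restrict_band else None
    specs = session_spectrograms(session, windows, params, nucleus=nucleus,
                                 time_decim=cfg.time_decim, band=band)

    def dataset_builder(rng):
        return build_dataset(specs, rng)

    if cfg.classifier == "cnn":
        factory = make_cnn_factory(CNNSpec(), TrainConfig(
            batch_size=cfg.batch_size, epochs=cfg.epochs, lr=cfg.learning_rate))
    elif cfg.classifier == "svm":
        factory = make_svm_factory("rbf")
    else:
        raise ValueError(f"unknown classifier {cfg.classifier!r}")
    n_channels = len(session.channels_in(nucleus))
    result = evaluate_repetitions(dataset_builder, factory, cfg.n_repetitions,
                                  seed=seed,
                                  metadata={"nucleus": nucleus,
                                            "classifier": cfg.classifier,
                                            "n_channels": n_channels})
    null = bootstrap_null(dataset_builder, factory, cfg.n_shuffles, seed=seed + 1,
                          metadata={"nucleus": nucleus, "classifier": cfg.classifier})
    return result, null


def run_experiment(cfg: ExperimentConfig, out_dir=None) -> dict:
    """Run all stages; returns the experiment report (also written to disk)."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(cfg)
    cfg.save(out / "config.yaml")

    stage = "simulate"
    if not _stage_done(out, stage, cfg_hash, ["session.h5", "events.csv", "ibi.csv"]):
        logger.info("stage %s", stage)
        session = build_session(cfg)
        save_session(session, out / "session.h5")
        export_events_csv(session, out / "events.csv")
        export_ibi_csv(session.heartbeats, out / "ibi.csv")
        _mark_stage(out, stage, cfg_hash, ["session.h5", "events.csv", "ibi.csv"])
    session = load_session(out / "session.h5")

    stage = "windows"
    if not _stage_done(out, stage, cfg_hash, ["windows.csv"]):
        logger.info("stage %s", stage)
        windows, used = select_windows(session, cfg.window_length_s,
                                       cfg.fallback_length_s)
        df = windows_to_frame(windows)
        df.to_csv(out / "windows.csv", index=False)
        _mark_stage(out, stage, cfg_hash, ["windows.csv"])
    from .windows import SpontaneousWindow
    import pandas as pd

    wdf = pd.read_csv(out / "windows.csv")
    windows = [SpontaneousWindow(int(r.channel), float(r.start_s), float(r.length_s),
                                 str(r.label), int(r.trial_index))
               for r in wdf.itertuples()]

    stage = "decode"
    if not _stage_done(out, stage, cfg_hash, ["results.json", "null.json"]):
        logger.info("stage %s", stage)
        nuclei = [cfg.nucleus] if cfg.nucleus else session.nuclei
        results, nulls = {}, {}
        seed_base = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % (2 ** 30))
        for i, nucleus in enumerate(nuclei):
            res, null = _decode_nucleus(cfg, session, windows, nucleus,
                                        seed=seed_base + 101 * i)
            results[nucleus] = res.to_dict()
            nulls[nucleus] = null.to_dict()
        _write_json(out / "results.json", results)
        _write_json(out / "null.json", nulls)
        _mark_stage(out, stage, cfg_hash, ["results.json", "null.json"])
    results = json.loads((out / "results.json").read_text())
    nulls = json.loads((out / "null.json").read_text())

    stage = "compare"
    if not _stage_done(out, stage, cfg_hash, ["nucleus_comparison.json"]):
        logger.info("stage %s", stage)
        if len(results) >= 2:
            h, p = compare_nuclei({k: np.asarray(v["accuracies"])
                                   for k, v in results.items()})
            comp = {"H": h, "p": p, "groups": {k: len(v["accuracies"])
                                               for k, v in results.items()}}
        else:
            comp = {"H": None, "p": None,
                    "note": "fewer than 2 nuclei decoded; comparison skipped"}
        _write_json(out / "nucleus_comparison.json", comp)
        _mark_stage(out, stage, cfg_hash, ["nucleus_comparison.json"])

    stage = "autonomic"
    if not _stage_done(out, stage, cfg_hash, ["rsa.csv"]):
        logger.info("stage %s", stage)
        ibi = clean_ibi(session.heartbeats)
        t, hr = interpolate_hr(ibi)
        rsa = rsa_strength(t, hr, cfg.rsa_window_s, cfg.rsa_overlap_s,
                           protocol=session.protocol)
        rsa.to_frame().to_csv(out / "rsa.csv", index=False)
        _mark_stage(out, stage, cfg_hash, ["rsa.csv"])
    import pandas as pd

    rsa_df = pd.read_csv(out / "rsa.csv")

    # summary
    summary = {"version": __version__, "seed": cfg.seed, "config_hash": cfg_hash,
               "nuclei": {}}
    for nucleus, res in results.items():
        null = nulls[nucleus]
        med = float(np.median(res["accuracies"]))
        null_max = float(np.max(null["accuracies"]))
        summary["nuclei"][nucleus] = {
            "median_accuracy": med,
            "quantiles": res["quantiles"],
            "null_median": float(np.median(null["accuracies"])),
            "null_max": null_max,
            "separated_from_null": bool(med > null_max),
        }
    summary["context_effect_detected"] = any(
        v["separated_from_null"] for v in summary["nuclei"].values())
    touch_rsa = rsa_df.loc[rsa_df.block == "touch", "p_rsa_norm"]
    airflow_rsa = rsa_df.loc[rsa_df.block == "airflow", "p_rsa_norm"]
    summary["rsa"] = {
        "touch_mean": float(touch_rsa.mean()) if len(touch_rsa) else None,
        "airflow_mean": float(airflow_rsa.mean()) if len(airflow_rsa) else None,
    }
    _write_json(out / "summary.json", summary)
    lines = [f"spontlfp {__version__} experiment summary (seed {cfg.seed})"]
    for nucleus, s in summary["nuclei"].items():
        lines.append(
            f"  {nucleus}: median acc {s['median_accuracy']:.3f} "
            f"(q10 {s['quantiles']['q10']:.3f}, q90 {s['quantiles']['q90']:.3f}); "
            f"null median {s['null_median']:.3f}, max {s['null_max']:.3f}")
    lines.append("  context effect detected" if summary["context_effect_detected"]
                 else "  no context effect detected (median within null band)")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
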