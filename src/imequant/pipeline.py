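"""End-to-end orchestration: generate synthetic inputs, run all four stages.

One global seed fans out to per-stage child seeds by fixed offsets, so each
stage is reproducible on its own regardless of execution order:

    study  -> seed + 101
    ephys  -> seed + 211 (+ recording index)
    histo  -> seed + 307 (+ image index)
    chem   -> seed + 401

The report lists, per arm: phase active-electrode proportions and declines
with two-proportion z-tests, pooled unit SNR after outlier removal, the
normalized neuron-density profile, encapsulation efficiency, and cumulative
release at its anchor times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from imequant import ephys, histo, release, yield_stats
from imequant.synth import (
    chem as synth_chem,
    ihc as synth_ihc,
    recording as synth_rec,
    study as synth_study,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_end_to_end", "mean_phase_decline", "recover_batch_ee"]

SEED_OFFSETS = {"study": 101, "ephys": 211, "histo": 307, "chem": 401}

_KNOWN_KEYS = {
    "seed", "out_dir", "log_level", "n_recordings_per_cohort", "recording_duration_s",
    "n_ihc_images_per_arm", "ihc_image_size", "weeks", "q_rout",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | Path = "imequant_out"
    log_level: str = "INFO"
    n_recordings_per_cohort: int = 2
    recording_duration_s: float = 5.0
    n_ihc_images_per_arm: int = 3
    ihc_image_size: int = 2480
    weeks: int = 8
    q_rout: float = 5.0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    return (seed + SEED_OFFSETS[stage] + 7919 * index) % (2**31)


def mean_phase_decline(
    arms: list[synth_study.ArmSpec] | None = None,
    seeds: range | list[int] = range(1, 21),
    weeks: int = 8,
) -> pd.DataFrame:
    """Phase proportions and declines per arm, averaged over study replicates.

    Runs the full yield pipeline (generation, viable-channel exclusion,
    phase pooling) once per seed and averages; also reports the pooled
    z-test of phase 1 vs phase 2 from the last replicate's counts.
    """
    arms = arms if arms is not None else synth_study.DEFAULT_ARMS
    half = weeks // 2
    ph1_weeks = list(range(1, half + 1))
    ph2_weeks = list(range(half + 1, weeks + 1))
    acc: dict[str, dict[str, list[float]]] = {}
    last_counts: dict[str, tuple] = {}
    for s in seeds:
        table, _ = synth_study.gen_study(
            synth_study.StudyConfig(arms=list(arms), weeks=weeks, seed=int(s))
        )
        viable = yield_stats.viable_channels(table)
        p1 = {r.arm: r for r in yield_stats.phase_proportion(table, ph1_weeks, viable)}
        p2 = {r.arm: r for r in yield_stats.phase_proportion(table, ph2_weeks, viable)}
        for arm in p1:
            d = acc.setdefault(arm, {"p1": [], "p2": [], "decline": []})
            d["p1"].append(p1[arm].aey)
            d["p2"].append(p2[arm].aey)
            d["decline"].append(yield_stats.phase_decline(p1[arm].aey, p2[arm].aey))
            last_counts[arm] = (p1[arm].n_active, p1[arm].n_viable,
                                p2[arm].n_active, p2[arm].n_viable)
    rows = []
    for arm, d in acc.items():
        zt = yield_stats.two_prop_ztest(*last_counts[arm])
        rows.append(
            dict(arm=arm, p_active_w1_4=np.mean(d["p1"]), p_active_w5_8=np.mean(d["p2"]),
                 decline_percent=np.mean(d["decline"]), z_phase=zt.z, p_phase=zt.p)
        )
    return pd.DataFrame(rows)


def recover_batch_ee(config: synth_chem.HplcBatchConfig) -> pd.DataFrame:
    """Quantify every batch of a simulated campaign through the HPLC stage."""
    rows = []
    for batch in synth_chem.gen_hplc_batches(config):
        curve = release.fit_standard_curve(
            batch.standards["conc_ratio"], batch.standards["area_ratio"]
        )
        conc = release.quantify_unknown(
            batch.unknown_area_ratio, curve, config.internal_standard_conc
        )
        unencap_mg = conc * config.sample_volume_ml / 1000.0
        unencap_mg = min(unencap_mg, config.total_drug_mg)
        ee = release.encapsulation_efficiency(config.total_drug_mg, unencap_mg)
        rows.append(dict(batch=batch.batch_id, ee_percent=ee,
                         true_ee_percent=batch.true_ee_percent, r_squared=curve.r_squared))
    return pd.DataFrame(rows)


def snr_summary(
    n_recordings: int,
    duration_s: float,
    seed: int,
    cohorts: list[str] | None = None,
    q_rout: float = 5.0,
) -> pd.DataFrame:
    """Pooled validated-unit SNR per cohort through the full stage-1 chain."""
    cohorts = cohorts or [a.name for a in synth_study.DEFAULT_ARMS]
    rows = []
    for ci, cohort in enumerate(cohorts):
        snrs = []
        for ri in range(n_recordings):
            cfg = synth_rec.default_recording_config(
                seed=stage_seed(seed, "ephys", ci * 1000 + ri), duration=duration_s
            )
            block, _ = synth_rec.gen_recording(cfg)
            _, _, unit_table = ephys.process_recording(block, q_rout=q_rout)
            snrs.extend(unit_table.loc[~unit_table["rout_outlier"], "snr"].tolist())
        rows.append(dict(cohort=cohort, n_units=len(snrs),
                         snr_mean=float(np.mean(snrs)) if snrs else float("nan")))
    return pd.DataFrame(rows)


def ihc_density_summary(
    arm: str,
    n_images: int,
    seed: int,
    image_size: int = 2480,
) -> pd.DataFrame:
    """Normalized neuron-density profile for one arm, pooled across images.

    Counts and usable areas are summed across images before normalizing —
    the pooled estimator a multi-slice per-animal average converges to.
    """
    total_counts = np.zeros(histo.N_BINS)
    total_area = np.zeros(histo.N_BINS)
    for i in range(n_images):
        cfg = synth_ihc.default_ihc_config(
            arm=arm, seed=stage_seed(seed, "histo", i), image_size=image_size
        )
        image, _ = synth_ihc.gen_ihc_image(cfg)
        labels = histo.ring_labels(image.hole_mask, image.microns_per_pixel)
        centroids = histo.detect_centroids(image, soma_diameter_um=cfg.soma_diameter_um)
        prof = histo.density_profile(
            centroids, labels, image.microns_per_pixel, image.artifact_mask
        )
        total_counts += prof.counts
        total_area += prof.area_mm2
    density = total_counts / total_area
    normalized = density / density[histo.BACKGROUND_BIN]
    return pd.DataFrame(
        {
            "arm": arm,
            "bin_lo_um": np.arange(histo.N_BINS) * histo.RING_WIDTH_UM,
            "bin_hi_um": (np.arange(histo.N_BINS) + 1) * histo.RING_WIDTH_UM,
            "counts": total_counts.astype(int),
            "area_mm2": total_area,
            "density_per_mm2": density,
            "normalized": normalized,
        }
    )


def run_end_to_end(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage on freshly generated synthetic data; write CSV reports.

    Returns the report tables keyed by stage; all outputs are also written
    under ``config.out_dir``.  Fully deterministic given ``config.seed``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.weeks < 2:
        raise RuntimeError("[yield] study needs at least 2 weeks for phase statistics")
    reports: dict[str, pd.DataFrame] = {}

    try:
        reports["yield"] = mean_phase_decline(
            seeds=[stage_seed(config.seed, "study")], weeks=config.weeks
        )
    except Exception as exc:  # pragma: no cover - stage tagging only
        raise RuntimeError(f"[yield] {exc}") from exc

    try:
        reports["ephys"] = snr_summary(
            config.n_recordings_per_cohort, config.recording_duration_s,
            config.seed, q_rout=config.q_rout,
        )
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[ephys] {exc}") from exc

    try:
        frames = [
            ihc_density_summary(arm, config.n_ihc_images_per_arm, config.seed,
                                image_size=config.ihc_image_size)
            for arm in synth_ihc.DEFAULT_BIN0_RETENTION
        ]
        reports["histo"] = pd.concat(frames, ignore_index=True)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[histo] {exc}") from exc

    try:
        ee = recover_batch_ee(synth_chem.HplcBatchConfig(seed=stage_seed(config.seed, "chem")))
        truth = synth_chem.default_release_truth(seed=stage_seed(config.seed, "chem"))
        sim = synth_chem.gen_release(truth)
        curve = release.cumulative_release(
            sim.table["t_days"], sim.table["conc_ug_per_ml"], truth.loaded_mass,
            truth.bath_volume, truth.aliquot_volume,
        )
        reports["ee"] = ee
        reports["release"] = pd.DataFrame(
            {"t_days": curve.times, "cumulative_fraction": curve.cumulative_fraction}
        )
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[chem] {exc}") from exc

    for name, df in reports.items():
        df.to_csv(out / f"{name}.csv", index=False)
    _write_summary(out / "summary.txt", reports)
    return reports


def _write_summary(path: Path, reports: dict[str, pd.DataFrame]) -> None:
    lines = ["imequant end-to-end report", "=" * 30, ""]
    y = reports["yield"]
    for _, r in y.iterrows():
        lines.append(
            f"AEY {r['arm']:>10}: W1-4 {r['p_active_w1_4']:.3f}  "
            f"W5-8 {r['p_active_w5_8']:.3f}  decline {r['decline_percent']:.1f}%"
        )
    lines.append("")
    for _, r in reports["ephys"].iterrows():
        lines.append(f"SNR {r['cohort']:>10}: mean {r['snr_mean']:.2f} over {r['n_units']} units")
    lines.append("")
    h = reports["histo"]
    for arm, sub in h.groupby("arm"):
        lines.append(f"NeuN {arm}: normalized bin-0 density {sub['normalized'].iloc[0]:.3f}")
    lines.append("")
    lines.append(f"EE mean {reports['ee']['ee_percent'].mean():.1f}%")
    rel = reports["release"]
    for t in (1.0, 24.0):
        sel = rel[np.isclose(rel["t_days"], t)]
        if len(sel):
            lines.append(f"release at {t:g} d: {100 * sel['cumulative_fraction'].iloc[0]:.1f}%")
    path.write_text("\n".join(lines) + "\n")
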