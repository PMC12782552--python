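"""End-to-end pipeline: simulate -> sort -> rhythm -> phase -> intracell ->
behavior, with a manifest for reproducibility and a small figure exporter.

All stage outputs are plain CSV/JSON/HDF5; identical config + seed gives
byte-identical CSVs.
"""

from __future__ import annotations

import json
import hashlib
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import intracell, io, kinematics, phase, rhythm, spikesort, synth
from .config import RunConfig

__all__ = ["StageError", "run_pipeline", "export_figures"]

PACKAGE_VERSION = "0.1.0"


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured pipeline into ``out_dir``; returns the manifest.

    With ``config.simulate`` the inputs are generated first (synthetic
    nerve + NS traces and a behavioral bout at the generator defaults,
    seeded from ``config.seed``); otherwise existing files are expected in
    ``out_dir`` (``ephys.h5``, ``behavior.csv``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "config_diff": config.diff(),
        "package_version": PACKAGE_VERSION,
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "inputs": {},
    }
    t_all = time.perf_counter()

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_inner.t, 3),
                    "ok": exc is None,
                }
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
                if exc is not None:
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        with _stage("simulate"):
            if config.simulate:
                ep = synth.standard_episode(seed=config.seed)
                ns, ns_truth = synth.gen_ns_trace(
                    synth.NSSpec(), ep.cycles, seed=config.seed + 500_000
                )
                beh = synth.gen_behavior(
                    synth.KinematicSpec(fps=config.fps), seed=config.seed + 900_000
                )
                io.write_h5(
                    out / "ephys.h5",
                    traces={"DP": ep.trace, "NS": ns},
                    events={u: t for u, t in ep.spikes.items()},
                )
                beh.to_csv(out / "behavior.csv")
                beh.to_dlc_csv(out / "behavior_dlc.csv")
                ep.truth.merge(ns_truth).to_json(out / "ground_truth.json")
            for f in ("ephys.h5", "behavior.csv"):
                p = out / f
                if not p.exists():
                    raise FileNotFoundError(f"missing input {p}")
                manifest["inputs"][f] = _checksum(p)

        with _stage("sort"):
            trace = io.read_trace(out / "ephys.h5", "DP")
            result = spikesort.sort_trace(
                trace,
                threshold_k=config.threshold_k,
                window=config.detect_window,
                seed=config.embed_seed,
                min_cluster_size=config.min_cluster_size,
                max_embed=config.max_embed,
            )
            unit_spikes = {
                f"u{cid}": result.spike_times(cid) for cid in result.unit_ids()
            }
            io.write_spikes_csv(out / "units.csv", unit_spikes)
            io.write_templates_csv(
                out / "templates.csv",
                {f"u{cid}": result.clusters[cid].template for cid in result.unit_ids()},
            )
            io.write_curation_log(out / "curation.jsonl", result.log)

        with _stage("rhythm"):
            unit_spikes = io.read_spikes_csv(out / "units.csv")
            templates = io.read_templates_csv(out / "templates.csv")
            # DE-3 carries the largest spike in the DP nerve
            de3 = max(templates, key=lambda u: np.max(np.abs(templates[u])))
            bursts = rhythm.detect_bursts(
                unit_spikes[de3],
                max_isi=config.max_isi,
                min_spikes=config.min_spikes,
                min_mff=config.min_mff,
            )
            cycles = rhythm.segment_cycles(bursts, mode=config.cycle_mode)
            cycles = rhythm.assign_epochs(cycles, config.pulse)
            cycles.to_csv(out / "cycles.csv", index=False)
            manifest["de3_unit"] = de3

        with _stage("phase"):
            cycles = pd.read_csv(out / "cycles.csv")
            cycles.attrs["mode"] = config.cycle_mode
            period = float(cycles["period_s"].mean())
            de3_duty = float(cycles["duty"].mean())
            prof_rows, metric_rows = [], []
            for uid, st in unit_spikes.items():
                span = (float(cycles["start"].iloc[0]), float(cycles["end"].iloc[-1]))
                bff = rhythm.compute_bff(st, config.bff_bin_coarse, span)
                rr = phase.autocorr_rhythmicity(
                    bff,
                    period,
                    n_cycles=config.rhythm_cycles,
                    min_peaks=config.rhythm_min_peaks,
                    min_r=config.rhythm_min_r,
                    unit_id=uid,
                )
                if not rr.is_rhythmic:
                    continue
                prof = phase.phase_profile(
                    st,
                    cycles,
                    n_bins=config.n_phase_bins,
                    n_cycles=config.profile_cycles,
                    unit_id=uid,
                )
                label = phase.classify_unit(
                    prof,
                    de3_duty,
                    onset_tol=config.onset_tol,
                    onset_baseline_frac=config.onset_baseline_frac,
                )
                for p, v in zip(prof.phases, prof.mean_bff):
                    prof_rows.append(
                        {"unit": uid, "epoch": "all", "phase_bin": p, "mean_bff": v}
                    )
                metric_rows.append(
                    {
                        "unit": uid,
                        "epoch": "all",
                        "class": label,
                        "max_bff_hz": prof.max_bff,
                        "rel_hw": prof.rel_hw,
                        "onset_phase": prof.onset_phase,
                    }
                )
            pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)
            pd.DataFrame(metric_rows).to_csv(out / "unit_metrics.csv", index=False)

        with _stage("intracell"):
            vm = io.read_trace(out / "ephys.h5", "NS")
            de3_spikes = unit_spikes[de3]
            bursts = rhythm.detect_bursts(
                de3_spikes,
                max_isi=config.max_isi,
                min_spikes=config.min_spikes,
                min_mff=config.min_mff,
            )
            span = (0.0, vm.duration)
            bff = rhythm.compute_bff(de3_spikes, config.bff_bin_fine, span)
            bff_s = rhythm.smooth_gaussian(bff, config.bff_sigma)
            vm_rs = intracell.resample_trace(vm, bff_s)
            period = float(cycles["period_s"].mean())
            corr = intracell.cross_correlate(vm_rs, bff_s.as_timeseries(), period)
            pd.DataFrame(
                {"lag_s": corr.lags, "r": corr.coefficients}
            ).to_csv(out / "correlogram.csv", index=False)
            base = intracell.ns_baseline(vm, config.baseline_sigma)
            amps = intracell.hyp_amplitude(vm, base, bursts)
            feats = intracell.feature_table(amps, bursts)
            feats.to_csv(out / "ns_features.csv", index=False)
            manifest["ns_peak_r"] = corr.peak_coefficient
            manifest["ns_peak_lag_s"] = corr.peak_lag

        with _stage("behavior"):
            track = kinematics.load_pose(
                out / "behavior_dlc.csv"
                if (out / "behavior_dlc.csv").exists()
                else out / "behavior.csv",
                fps=config.fps,
                likelihood_floor=config.likelihood_floor,
            )
            sections, total = kinematics.section_lengths(
                track, sigma=config.kin_sigma, gap_limit=config.gap_limit
            )
            v_ant, v_post = kinematics.endpoint_speeds(track, sigma=config.kin_sigma)
            _, steps = kinematics.segment_steps(
                total,
                v_ant,
                v_post,
                track.fps,
                min_separation=config.min_step_separation,
                valid=track.valid,
            )
            table = kinematics.step_table(
                sections[:, 3], steps, track.fps, config.kneedle_sensitivity
            )
            table.to_csv(out / "steps.csv", index=False)

        manifest["warnings"] = [str(w.message) for w in wlist]
    manifest["seconds_total"] = round(time.perf_counter() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def export_figures(artifact_dir, out_dir=None) -> list[Path]:
    """Render summary panels from a pipeline artifact directory.

    Missing stage outputs skip their panel with a notice.  Returns the
    files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    src = Path(artifact_dir)
    out = Path(out_dir) if out_dir else src
    out.mkdir(parents=True, exist_ok=True)
    written = []

    prof_p = src / "profiles.csv"
    if prof_p.exists() and prof_p.stat().st_size > 1:
        prof = pd.read_csv(prof_p)
        if len(prof):
            units = sorted(prof["unit"].unique())
            mat = np.stack(
                [
                    prof[prof["unit"] == u].sort_values("phase_bin")["mean_bff"].to_numpy()
                    for u in units
                ]
            )
            fig, ax = plt.subplots(figsize=(6, 0.5 + 0.4 * len(units)))
            ax.imshow(mat, aspect="auto", cmap="gray_r", extent=[0, 1, len(units), 0])
            ax.set_yticks(np.arange(len(units)) + 0.5, units)
            ax.set_xlabel("cycle phase")
            fig.savefig(out / "raster.png", dpi=120)
            plt.close(fig)
            written.append(out / "raster.png")
    else:
        print("notice: profiles.csv missing; raster panel skipped")

    corr_p = src / "correlogram.csv"
    if corr_p.exists():
        c = pd.read_csv(corr_p)
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(c["lag_s"], c["r"], "k")
        ax.axhline(0, color="0.7", lw=0.5)
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("r")
        fig.tight_layout()
        fig.savefig(out / "correlogram.png", dpi=120)
        plt.close(fig)
        written.append(out / "correlogram.png")
    else:
        print("notice: correlogram.csv missing; panel skipped")

    steps_p = src / "steps.csv"
    beh_p = src / "behavior.csv"
    if steps_p.exists() and beh_p.exists():
        steps = pd.read_csv(steps_p)
        beh = pd.read_csv(beh_p)
        fig, ax = plt.subplots(figsize=(7, 3))
        ax.plot(beh["time_s"], beh["total_length_mm"], "k", lw=0.8)
        for _, s in steps[steps["qc"] == "ok"].iterrows():
            on = s["t_start"] + s["iso_pre_s"]
            mx = on + s["elong_s"]
            ax.axvspan(on, mx, color="red", alpha=0.15)
            ax.axvspan(mx, mx + s["contr_s"], color="blue", alpha=0.15)
            ax.axvline(s["t_start"], color="k", lw=0.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("total length (mm)")
        fig.tight_layout()
        fig.savefig(out / "steps.png", dpi=120)
        plt.close(fig)
        written.append(out / "steps.png")
    else:
        print("notice: steps/behavior outputs missing; step panel skipped")

    return written
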