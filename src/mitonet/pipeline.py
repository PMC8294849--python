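"""Configuration-driven end-to-end runs: simulate → quantify → summarize.

A RunConfig (YAML-loadable) holds the seed, the per-module parameters and
the output directory; run_pipeline executes every stage on synthetic data,
writes per-module CSV tables and a JSON run report echoing every effective
parameter, and is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, ephys, image_quant, morphometry, synthetic, trafficking
from .errors import InputError

#: parameters fixed by the source quantification rules
DEFAULT_PARAMS = {
    "trafficking": {
        "mobility_threshold_um": 2.0,
        "mobility_window_s": 300.0,
        "pause_exclusion_s": 10.0,
        "immobility_step_um": 0.1,
        "n_tracks": 100,
        "mobile_fraction": 0.23,
        "speed_um_s": 0.17,
        "duration_s": 500.0,
        "frame_dt_s": 5.0,
    },
    "morphometry": {
        "n_branch_axon": 5,
        "n_branch_dend": 5,
        "sholl_step_um": 1.0,
        "n_mito": 150,
        "voxel_size_um": 1.0,
        "psf_sigma_um": 0.4,
        "proximity_radius_um": 1.0,
    },
    "image_quant": {
        "soma_area_px": 10000,
        "mito_area_fraction": 0.39,
        "n_boutons": 100,
        "frac_with_mito": 0.74,
        "rolling_ball_trafficking": 50,
        "rolling_ball_synapse": 7,
        "max_filter_synapse": 1,
        "overlap_range": [0.33, 1.0],
    },
    "ephys": {
        "gamma_band_hz": [20.0, 80.0],
        "mains_exclusion_hz": [49.0, 51.0],
        "lfp_window_s": 300.0,
        "lfp_sample_rate_hz": 5000.0,
        "osc_frequency_hz": 31.0,
        "osc_amplitude_mv": 0.1,
        "lfp_noise_sd_mv": 0.05,
        "psc_init_threshold_pa": 3.0,
        "psc_noise_mult": 5.0,
        "psc_lp_cutoff_hz": 1000.0,
        "psc_rate_hz": 5.0,
        "psc_duration_s": 60.0,
    },
    "behavior": {
        "occupancy": {"closed": 0.76, "open": 0.18, "center": 0.06},
        "n_frames": 1000,
        "rotarod_start_rpm": 4.0,
        "rotarod_end_rpm": 40.0,
        "rotarod_trial_s": 300.0,
    },
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results/pipeline"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InputError("config must be a YAML mapping")
        unknown = set(raw) - {"seed", "out_dir", "params"}
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def effective_params(self) -> dict:
        merged = {k: dict(v) for k, v in DEFAULT_PARAMS.items()}
        for mod, over in (self.params or {}).items():
            if mod not in merged:
                raise InputError(f"unknown module {mod!r} in config")
            for key, val in over.items():
                if key not in merged[mod]:
                    raise InputError(f"unknown parameter {mod}.{key}")
                merged[mod][key] = val
        return merged


def iqr_fence_outliers(values, k: float = 1.5) -> np.ndarray:
    """Boolean outlier flags by Tukey's IQR fence.

    Provided as a simple, transparent alternative to regression-based
    outlier removal; flagged values are reported, never silently dropped.
    """
    values = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every analysis stage on synthetic inputs; return the report."""
    p = config.effective_params()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    report: dict = {
        "version": __version__,
        "seed": seed,
        "effective_parameters": p,
        "outputs": {},
    }

    # --- trafficking ------------------------------------------------------
    tp = p["trafficking"]
    tracks, truths = synthetic.gen_tracks(
        n=tp["n_tracks"], duration=tp["duration_s"], frame_dt=tp["frame_dt_s"],
        speed=tp["speed_um_s"], mobile_fraction=tp["mobile_fraction"],
        pause_spec=synthetic.PauseSpec(), seed=seed,
    )
    table = trafficking.stats_table(
        tracks,
        threshold=tp["mobility_threshold_um"], window=tp["mobility_window_s"],
        pause_exclusion=tp["pause_exclusion_s"],
        immobility_step=tp["immobility_step_um"],
    )
    table.to_csv(out / "track_stats.csv", index=False)
    mobile_pct = trafficking.movie_mobile_fraction(
        tracks, tp["n_tracks"],
        threshold=tp["mobility_threshold_um"], window=tp["mobility_window_s"],
    )
    report["outputs"]["trafficking"] = {
        "mobile_percent": mobile_pct,
        "median_velocity_um_s": float(np.nanmedian(table["velocity_um_s"])),
        "median_path_length_um": float(table["path_length_um"].median()),
    }

    # --- morphometry ------------------------------------------------------
    mp = p["morphometry"]
    morph = synthetic.gen_morphology(
        n_branch_axon=mp["n_branch_axon"], n_branch_dend=mp["n_branch_dend"], seed=seed,
    )
    morphometry.write_swc(morph, out / "morphology.swc")
    stack, truth = synthetic.gen_mito_stack(
        morph, n_mito=mp["n_mito"], voxel_size=mp["voxel_size_um"],
        psf_sigma=mp["psf_sigma_um"], seed=seed,
    )
    binary = morphometry.VoxelStack(
        stack.data > image_quant.threshold_value(stack.data, "otsu"),
        stack.voxel_size, stack.origin,
    )
    sholl = morphometry.sholl_intersections(morph, "all", mp["sholl_step_um"])
    pd.DataFrame({"radius_um": sholl.radii, "count": sholl.counts}).to_csv(
        out / "sholl.csv", index=False
    )
    bps = morphometry.branch_points(morph, "all")
    prox = morphometry.min_branch_mito_distance(bps, binary)
    pd.DataFrame(
        {
            "x_um": prox.branch_points[:, 0],
            "y_um": prox.branch_points[:, 1],
            "z_um": prox.branch_points[:, 2],
            "min_dist_um": prox.min_distances,
        }
    ).to_csv(out / "proximity.csv", index=False)
    report["outputs"]["morphometry"] = {
        "total_length_um": morphometry.total_length(morph, "all"),
        "n_branch_points": int(bps.shape[0]),
        "n_processes": morphometry.count_processes(morph),
        "p_within_radius": morphometry.prob_within_radius(
            prox, mp["proximity_radius_um"]
        ),
    }

    # --- image quantification --------------------------------------------
    ip = p["image_quant"]
    soma_mask, mito_mask, frac = synthetic.gen_soma_image(
        mito_area_fraction=ip["mito_area_fraction"],
        soma_area_px=ip["soma_area_px"], seed=seed,
    )
    bio, mito_img, flags = synthetic.gen_axon_boutons(
        n_boutons=ip["n_boutons"], frac_with_mito=ip["frac_with_mito"], seed=seed,
    )
    puncta = image_quant.detect_puncta(bio, pixel_size=0.1)
    pct_mito, _, _ = image_quant.bouton_mito_content(puncta, mito_img)
    report["outputs"]["image_quant"] = {
        "soma_mito_area_percent": image_quant.soma_mito_area_fraction(mito_mask, soma_mask),
        "n_boutons_detected": puncta.n,
        "bouton_mito_percent": pct_mito,
    }

    # --- ephys ------------------------------------------------------------
    ep = p["ephys"]
    lfp = synthetic.gen_lfp(
        synthetic.LFPGroundTruth(
            osc_frequency=ep["osc_frequency_hz"], osc_amplitude=ep["osc_amplitude_mv"],
            noise_sd=ep["lfp_noise_sd_mv"], duration=ep["lfp_window_s"],
            sample_rate=ep["lfp_sample_rate_hz"],
        ),
        seed=seed,
    )
    spec = ephys.power_spectrum(lfp, window=ep["lfp_window_s"],
                                mains_exclusion=tuple(ep["mains_exclusion_hz"]))
    gm = ephys.gamma_metrics(spec, tuple(ep["gamma_band_hz"]))
    pd.DataFrame({"freq_hz": spec.frequencies, "power": spec.power}).to_csv(
        out / "power_spectrum.csv", index=False
    )
    psc_truth = synthetic.gen_poisson_psc_truth(
        rate_hz=ep["psc_rate_hz"], duration=ep["psc_duration_s"], seed=seed,
    )
    trace, psc_truth = synthetic.gen_psc_trace(psc_truth, ep["psc_duration_s"], seed=seed)
    events = ephys.detect_pscs(
        trace, init_threshold=ep["psc_init_threshold_pa"],
        noise_mult=ep["psc_noise_mult"], lp_cutoff=ep["psc_lp_cutoff_hz"],
    )
    pd.DataFrame({"t_s": events.event_times, "amplitude_pA": events.amplitudes}).to_csv(
        out / "psc_events.csv", index=False
    )
    report["outputs"]["ephys"] = {
        "gamma_peak_hz": gm.peak_frequency,
        "gamma_peak_power": gm.peak_power,
        "gamma_power_area": gm.power_area,
        "width50_hz": ephys.spectrum_width50(spec, tuple(ep["gamma_band_hz"])),
        "n_psc_events": int(events.n),
        "psc_median_amplitude_pa": events.median_amplitude,
        "psc_median_iei_s": events.median_iei,
    }

    # --- behavior ---------------------------------------------------------
    bp_ = p["behavior"]
    zones = behavior.ZoneMap.elevated_plus_maze()
    traj = synthetic.gen_trajectory(zones, bp_["occupancy"],
                                    n_frames=bp_["n_frames"], seed=seed)
    behavior.write_trajectory_csv(out / "trajectory.csv", traj)
    occ = behavior.zone_occupancy(traj, zones)
    dist, vel = behavior.traj_kinematics(traj)
    report["outputs"]["behavior"] = {
        "zone_occupancy_percent": occ,
        "distance_cm": dist,
        "velocity_cm_s": vel,
        "rotarod_rpm_at_150s": behavior.rotarod_rpm(
            bp_["rotarod_start_rpm"], bp_["rotarod_end_rpm"], 150.0,
            bp_["rotarod_trial_s"],
        ),
    }

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
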