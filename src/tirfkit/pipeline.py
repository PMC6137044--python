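"""Reproducible end-to-end runs: configuration, seeding, manifests, tables.

A :class:`RunConfig` names a packaged preset, a global seed, and an output
directory.  :func:`run_pipeline` executes the preset's stages in dependency
order, writes every artifact plus a resolved copy of the configuration, and
returns a manifest mapping each written file to its SHA-256 hash — so two
runs with the same configuration and seed are verifiably identical.

The global seed is expanded into per-stage child seeds through a fixed
stage-id table (``numpy.random.SeedSequence([seed, stage_id])``), so adding
a stage never perturbs the random streams of existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import frap as frap_mod
from . import presets, spt, synthetic
from .io import read_stack, write_localizations, write_stack

#: Fixed stage identifiers of the seed-expansion scheme.  Append only.
STAGE_IDS = {
    "simulate": 0,
    "drift": 1,
    "track": 2,
    "cpdfit": 3,
    "eisodist": 4,
    "frap": 5,
}

_KNOWN_KEYS = {"preset", "seed", "out_dir", "n_particles", "n_steps", "noise_sd"}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    preset: str
    seed: int = 0
    out_dir: str = "tirfkit_run"
    n_particles: int = 40
    n_steps: int = 30
    noise_sd: float | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "preset" not in raw:
            raise ValueError("config must name a 'preset'")
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Child seed of one stage, independent of all other stages."""
    sid = STAGE_IDS[stage]
    return int(np.random.SeedSequence([global_seed, sid]).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, verbose: bool = False) -> dict:
    """Execute the preset's stages and return the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.time()

    if config.preset in presets.TRACKING_PRESETS:
        written += _run_tracking(config, out)
    elif config.preset in presets.FRAP_PRESETS:
        written += _run_frap(config, out)
    else:
        raise KeyError(
            f"unknown preset {config.preset!r}; available: "
            f"{sorted(presets.TRACKING_PRESETS) + sorted(presets.FRAP_PRESETS)}"
        )

    resolved = out / "config.resolved.json"
    # out_dir is a location, not a parameter: excluding it keeps the resolved
    # config (and hence the manifest) identical across relocated reruns
    cfg_dict = {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    resolved.write_text(json.dumps(cfg_dict, indent=1))
    written.append(resolved)
    manifest = {
        "preset": config.preset,
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 3) if verbose else None,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _run_tracking(config: RunConfig, out: Path) -> list[Path]:
    """simulate -> render -> track -> cpdfit for a yeast tracking preset."""
    preset = presets.get_tracking_preset(config.preset)
    params, lag_s = preset["params"], preset["lag_s"]
    sim_seed = stage_seed(config.seed, "simulate")
    side_um = 14.0
    trajs, gt = synthetic.simulate_trajectories(
        params,
        n_particles=config.n_particles,
        n_steps=config.n_steps,
        dt_s=lag_s,
        seed=sim_seed,
        start_box_um=(side_um - 4.0, side_um - 4.0),
    )
    # 2-um border margin keeps diffusing emitters inside the frame
    trajs = [
        spt.Trajectory(
            id=tr.id,
            localizations=[
                spt.Localization(p.frame_index, p.x_um + 2.0, p.y_um + 2.0, p.intensity)
                for p in tr.localizations
            ],
        )
        for tr in trajs
    ]
    n_px = int(np.ceil(side_um / 0.08))
    sim_cfg = synthetic.SimConfig(
        seed=sim_seed,
        pixel_size_nm=80.0,
        frame_interval_s=lag_s,
        n_frames=config.n_steps + 1,
        image_shape=(n_px, n_px),
        noise_sd=config.noise_sd if config.noise_sd is not None else 5.0,
    )
    stack = synthetic.render_particle_movie(trajs, sim_cfg)
    write_stack(stack, out / "stack.tif")
    gt.to_json(out / "ground_truth.json")

    locs = spt.detect_and_localize(stack, threshold=5.0)
    write_localizations(locs, out / "locs.csv")
    linked = spt.link_trajectories(locs, max_step_um=0.5)
    write_localizations(linked, out / "trajs.csv")
    steps = spt.step_sizes(linked, lag_frames=1, frame_interval_s=lag_s)
    cpd = spt.empirical_cpd(steps)
    fit = spt.fit_cpd_two_population(cpd, lag_s=lag_s, n_boot=50,
                                     random_state=stage_seed(config.seed, "cpdfit"))
    (out / "fit.json").write_text(json.dumps(dataclasses.asdict(fit), indent=1))
    _cpd_table(cpd, fit, lag_s).to_csv(out / "cpd.csv", index=False)
    return [
        out / "stack.tif",
        out / "stack.tif.json",
        out / "ground_truth.json",
        out / "locs.csv",
        out / "trajs.csv",
        out / "fit.json",
        out / "cpd.csv",
    ]


def _run_frap(config: RunConfig, out: Path) -> list[Path]:
    """simulate -> normalize -> fit for a FRAP preset."""
    preset = dict(presets.get_frap_preset(config.preset))
    noise = config.noise_sd if config.noise_sd is not None else 0.02
    trace, gt = synthetic.simulate_frap_trace(
        noise_sd=noise, seed=stage_seed(config.seed, "simulate"), **preset
    )
    gt.to_json(out / "ground_truth.json")
    pd.DataFrame({"time_s": trace.time_s, "intensity": trace.intensity}).to_csv(
        out / "trace.csv", index=False, float_format="%.6f"
    )
    norm = frap_mod.normalize_trace(trace)
    fit = frap_mod.fit_recovery(norm)
    (out / "fit.json").write_text(json.dumps(dataclasses.asdict(fit), indent=1))
    mask = norm.post_mask
    est = frap_mod.recovery_model(
        norm.time_s[mask], fit.f0, fit.f_inf - fit.f0, fit.t_half_s
    )
    df = pd.DataFrame({"time_s": norm.time_s, "intensity_norm": norm.intensity})
    df["fit"] = np.nan
    df.loc[mask, "fit"] = est
    df.to_csv(out / "trace_normalized.csv", index=False, float_format="%.6f")
    return [
        out / "ground_truth.json",
        out / "trace.csv",
        out / "fit.json",
        out / "trace_normalized.csv",
    ]


def _cpd_table(cpd: np.ndarray, fit: spt.CpdFit, lag_s: float) -> pd.DataFrame:
    est = spt.TwoPopulationCpd(lag_s=lag_s, n_boot=0)
    est.alpha_mobile_, est.d_mobile_, est.d_immobile_ = (
        fit.alpha_mobile,
        fit.d_mobile,
        fit.d_immobile,
    )
    return pd.DataFrame(
        {"r2_um2": cpd[:, 0], "p_empirical": cpd[:, 1], "p_fit": est.predict(cpd[:, 0])}
    )


def export_figure_tables(manifest: dict | str, out_dir: str | Path) -> list[Path]:
    """Re-export panel-ready tidy tables from a finished run.

    Emits one CSV per available panel type: per-pair movement, CPD points
    with the fitted curve, and the normalized FRAP trace with its fit.
    Raises when the upstream stage has not produced its artifact.
    """
    if isinstance(manifest, (str, Path)):
        manifest = json.loads(Path(manifest).read_text())
    out_dir = Path(out_dir)
    run_dir = out_dir
    files = manifest["files"]
    written: list[Path] = []
    if "fit.json" not in files:
        raise FileNotFoundError(
            "no fit.json in manifest: run the 'cpdfit' (tracking) or 'frap' stage first"
        )
    for name in ("cpd.csv", "trace_normalized.csv", "trace.csv"):
        if name in files and (run_dir / name).exists():
            df = pd.read_csv(run_dir / name)
            target = run_dir / f"table_{name}"
            df.to_csv(target, index=False)
            written.append(target)
    if "stack.tif" in files and (run_dir / "drift.csv").exists():
        written.append(run_dir / "drift.csv")
    return written


def drift_table(stack_path, roi=None) -> pd.DataFrame:
    """Movement table (pair_index, dx_px, dy_px) of a stack on disk."""
    from .drift import quantify_movement

    stack = read_stack(stack_path)
    trace = quantify_movement(stack, roi)
    return pd.DataFrame(
        {
            "pair_index": np.arange(trace.n_pairs),
            "dx_px": trace.shifts_px[:, 0],
            "dy_px": trace.shifts_px[:, 1],
        }
    )
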