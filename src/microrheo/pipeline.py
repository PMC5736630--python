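"""End-to-end orchestration: validated run configs, manifests, fixtures.

A run executes the Methods chain — simulate (or load), render, locate →
filter → link, drift-correct → MSD → fit → classify — writing every
intermediate artifact in a documented format plus a run manifest that echoes
all effective parameters, file checksums, per-stage counts and warnings.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from pathlib import Path

from . import __version__
from . import io as mio
from .analysis import analyze_ensemble, analyze_timecourse
from .errors import ConfigError, InputError
from .simulate import (SimConfig, build_aging_scenario, render_video,
                       simulate)
from .tracking import DEFAULT_TRACKING, track_stack

logger = logging.getLogger("microrheo.pipeline")

STAGES = ("simulate", "render", "track", "analyze", "timecourse")

_SECTION_KEYS = {
    "simulate": {"model", "n_particles", "n_frames", "fps", "seed", "box_size",
                 "boundary", "init", "localization_noise_sigma",
                 "drift_velocity", "model_params"},
    "render": {"psf_sigma", "peak_intensity", "background_level", "noise_sigma",
               "image_shape", "pixel_size", "spot_aspect"},
    "track": {"feature_diameter", "noise_length", "percentile_threshold",
              "min_mass", "size_min", "size_max", "max_ecc",
              "max_displacement", "memory"},
    "analyze": {"max_lag_frames", "min_traj_length", "window", "ref_lag",
                "elastic_max", "diffusive_band", "drift_correction",
                "min_traj_count"},
    "timecourse": {"scenario", "n_particles", "n_frames", "fps",
                   "localization_noise_sigma"},
}
_TOP_KEYS = {"stages", "seed", "out_dir", "verbosity", "input_tiff",
             "input_trajectories"} | set(_SECTION_KEYS)


def configure_logging(verbosity: str = "info") -> None:
    """Line-per-event structured logging: time | level | module | message."""
    level = getattr(logging, verbosity.upper(), logging.INFO)
    root = logging.getLogger("microrheo")
    root.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(
            "%(asctime)s | %(levelname)s | %(name)s | %(message)s"))
        root.addHandler(handler)


@dataclasses.dataclass
class RunConfig:
    """Validated, namespaced pipeline configuration. Unknown keys rejected."""

    stages: list[str]
    seed: int = 0
    out_dir: str = "."
    verbosity: str = "info"
    input_tiff: str | None = None
    input_trajectories: str | None = None
    simulate: dict = dataclasses.field(default_factory=dict)
    render: dict = dataclasses.field(default_factory=dict)
    track: dict = dataclasses.field(default_factory=dict)
    analyze: dict = dataclasses.field(default_factory=dict)
    timecourse: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _SECTION_KEYS.items():
            bad = set(d.get(section, {})) - allowed
            if bad:
                raise ConfigError(f"unknown keys in [{section}]: {sorted(bad)}")
        stages = list(d.get("stages", []))
        for s in stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}; choose from {STAGES}")
        if not stages:
            raise ConfigError("config must select at least one stage")
        return cls(stages=stages, seed=int(d.get("seed", 0)),
                   out_dir=str(d.get("out_dir", ".")),
                   verbosity=str(d.get("verbosity", "info")),
                   input_tiff=d.get("input_tiff"),
                   input_trajectories=d.get("input_trajectories"),
                   simulate=dict(d.get("simulate", {})),
                   render=dict(d.get("render", {})),
                   track=dict(d.get("track", {})),
                   analyze=dict(d.get("analyze", {})),
                   timecourse=dict(d.get("timecourse", {})))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the selected stages and return the written run manifest."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    configure_logging(config.verbosity)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"version": __version__, "config": config.to_dict(),
                      "counts": {}, "files": {}, "warnings": [], "timing_s": {},
                      "results": {}}
    files: list[Path] = []
    truth = None
    stack = None
    ensemble = None

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if "timecourse" in config.stages:
            t0 = time.perf_counter()
            tc_opts = dict(config.timecourse)
            scen_name = tc_opts.pop("scenario", "PAO1_like")
            scenario = build_aging_scenario(scen_name, seed=config.seed, **tc_opts)
            age_ens = [(age, ts.to_ensemble(surface_age=age))
                       for age, ts in scenario.simulate(seed=config.seed)]
            for age, ens in age_ens:
                p, m = mio.write_trajectories_csv(
                    ens, out_dir / f"age_{int(age)}s_trajectories.csv")
                files += [p, m]
            mio.write_scenario_json(scenario, out_dir / "scenario.json")
            files.append(out_dir / "scenario.json")
            result = analyze_timecourse(age_ens, **config.analyze)
            paths = mio.write_timecourse_outputs(result, out_dir)
            files += list(paths.values())
            manifest["counts"]["ages_analyzed"] = len(result.summaries)
            manifest["results"]["transition_age_s"] = result.transition_age
            manifest["results"]["subdiffusive_onset_age_s"] = \
                result.subdiffusive_onset_age
            manifest["results"]["regimes"] = [
                (s.surface_age, s.label.regime) for s in result.summaries]
            manifest["timing_s"]["timecourse"] = time.perf_counter() - t0

        if "simulate" in config.stages:
            t0 = time.perf_counter()
            sim_opts = dict(config.simulate)
            sim_opts.setdefault("seed", config.seed)
            if "drift_velocity" in sim_opts:
                sim_opts["drift_velocity"] = tuple(sim_opts["drift_velocity"])
            truth = simulate(SimConfig(**sim_opts))
            p, m = mio.write_trajectories_csv(
                truth.to_ensemble(), out_dir / "ground_truth_trajectories.csv")
            files += [p, m]
            manifest["counts"]["simulated_particles"] = truth.config.n_particles
            manifest["timing_s"]["simulate"] = time.perf_counter() - t0

        if "render" in config.stages:
            if truth is None:
                raise InputError("render stage requires the simulate stage")
            t0 = time.perf_counter()
            stack = render_video(truth, seed=config.seed, **config.render)
            p, m = mio.write_tiff_stack(stack, out_dir / "movie.tif")
            files += [p, m]
            manifest["counts"]["rendered_frames"] = stack.n_frames
            manifest["timing_s"]["render"] = time.perf_counter() - t0

        if "track" in config.stages:
            t0 = time.perf_counter()
            if stack is None:
                if not config.input_tiff:
                    raise InputError("track stage needs a rendered movie or "
                                     "input_tiff")
                stack = mio.read_tiff_stack(config.input_tiff)
            track_opts = {**DEFAULT_TRACKING, **config.track}
            features, ensemble = track_stack(stack, **track_opts)
            files.append(mio.write_features_csv(features, out_dir / "features.csv"))
            p, m = mio.write_trajectories_csv(
                ensemble, out_dir / "tracked_trajectories.csv")
            files += [p, m]
            manifest["counts"]["features_kept"] = int(len(features))
            manifest["counts"]["trajectories"] = ensemble.n_trajectories
            manifest["counts"]["feature_rejections"] = \
                ensemble.metadata.get("rejections", {})
            manifest["timing_s"]["track"] = time.perf_counter() - t0

        if "analyze" in config.stages:
            t0 = time.perf_counter()
            if ensemble is None:
                if config.input_trajectories:
                    ensemble = mio.read_trajectories_csv(config.input_trajectories)
                elif truth is not None:
                    ensemble = truth.to_ensemble()
                else:
                    raise InputError("analyze stage needs trajectories (tracked, "
                                     "simulated, or input_trajectories)")
            curve, fit, label = analyze_ensemble(ensemble, **config.analyze)
            files.append(mio.write_msd_csv(curve, out_dir / "msd.csv"))
            summary = {"n": fit.exponent, "prefactor": fit.prefactor,
                       "d_um": fit.d, "ref_lag_s": fit.ref_lag,
                       "r_squared": fit.r_squared, "regime": label.regime,
                       "elastic_max": label.elastic_max,
                       "diffusive_band": list(label.diffusive_band),
                       "n_trajectories": len(ensemble)}
            files.append(mio.write_json_atomic(summary, out_dir / "analysis.json"))
            manifest["results"]["analysis"] = summary
            manifest["counts"]["trajectories_analyzed"] = len(ensemble)
            manifest["timing_s"]["analyze"] = time.perf_counter() - t0

        manifest["warnings"] = [str(w.message) for w in caught]

    manifest["files"] = {str(p.relative_to(out_dir)): mio.sha256(p) for p in files}
    mio.write_json_atomic(manifest, out_dir / "manifest.json")
    logger.info("run complete: %d files, counts=%s", len(files), manifest["counts"])
    return manifest


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Generate the packaged test fixtures into ``out_dir``.

    Writes a Brownian movie and an arrested movie (16-bit TIFF + metadata),
    the two packaged aging scenarios as trajectory CSVs with manifest JSONs,
    expected-output JSONs from analyzing each fixture, and a checksum file
    over everything. Deterministic in ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    movie_specs = {
        "brownian_movie": SimConfig(
            model="brownian", n_particles=36, n_frames=180, fps=60.0,
            box_size=25.6, init="grid", seed=seed,
            model_params={"D": 0.15}),
        "arrested_movie": SimConfig(
            model="arrested", n_particles=36, n_frames=180, fps=60.0,
            box_size=25.6, init="grid", seed=seed + 1,
            model_params={"sigma_eq": 0.05, "tau_r": 0.01}),
    }
    expected: dict = {}
    for name, cfg in movie_specs.items():
        truth = simulate(cfg)
        stack = render_video(truth, psf_sigma=1.5, peak_intensity=6000,
                             background_level=800, noise_sigma=600,
                             image_shape=(256, 256), pixel_size=0.1,
                             seed=cfg.seed)
        p, m = mio.write_tiff_stack(stack, out_dir / f"{name}.tif")
        written += [p, m]
        p, m = mio.write_trajectories_csv(
            truth.to_ensemble(), out_dir / f"{name}_ground_truth.csv")
        written += [p, m]
        _, fit, label = analyze_ensemble(truth.to_ensemble(),
                                         max_lag_frames=100, min_traj_length=110)
        expected[name] = {"model": cfg.model, "n": fit.exponent, "d_um": fit.d,
                          "regime": label.regime}

    for scen_name in ("PAO1_like", "PA14_like"):
        scenario = build_aging_scenario(scen_name, seed=seed)
        mio.write_scenario_json(scenario, out_dir / f"{scen_name}_scenario.json")
        written.append(out_dir / f"{scen_name}_scenario.json")
        age_ens = []
        age_manifest = []
        for age, truth in scenario.simulate(seed=seed):
            ens = truth.to_ensemble(surface_age=age)
            age_ens.append((age, ens))
            fname = f"{scen_name}_age_{int(age)}s.csv"
            p, m = mio.write_trajectories_csv(ens, out_dir / fname)
            written += [p, m]
            age_manifest.append({"age_s": age, "trajectory_file": fname})
        mio.write_json_atomic(age_manifest, out_dir / f"{scen_name}_manifest.json")
        written.append(out_dir / f"{scen_name}_manifest.json")
        result = analyze_timecourse(age_ens)
        expected[scen_name] = {
            "transition_age_s": result.transition_age,
            "subdiffusive_onset_age_s": result.subdiffusive_onset_age,
            "regimes": {str(s.surface_age): s.label.regime
                        for s in result.summaries}}

    written.append(mio.write_json_atomic(expected, out_dir / "expected_outputs.json"))
    checksums = {p.name: mio.sha256(p) for p in written}
    mio.write_json_atomic(checksums, out_dir / "checksums.json")
    logger.info("wrote %d fixture files to %s", len(written) + 1, out_dir)
    return {"files": [str(p) for p in written], "checksums": checksums,
            "expected": expected}


# ---------------------------------------------------------------------------
# Format validation
# ---------------------------------------------------------------------------

def validate_formats(path) -> dict:
    """Check a file's readability and schema; report per-field problems."""
    path = Path(path)
    report = {"path": str(path), "ok": True, "errors": []}
    if not path.exists():
        report["ok"] = False
        report["errors"].append("file does not exist")
        return report
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            stack = mio.read_tiff_stack(path)
            report["n_frames"] = stack.n_frames
        elif path.suffix.lower() == ".csv":
            head = path.open().readline()
            if "x_um" in head:
                ens = mio.read_trajectories_csv(path)
                report["n_trajectories"] = ens.n_trajectories
                # round-trip check
                df1 = ens.to_dataframe()
                df2 = mio.read_trajectories_csv(path).to_dataframe()
                if not df1.equals(df2):
                    report["ok"] = False
                    report["errors"].append("round-trip mismatch")
            elif "x_px" in head:
                report["n_features"] = len(mio.read_features_csv(path))
            elif "msd_um2" in head:
                import pandas as pd
                df = pd.read_csv(path)
                for col in ("lag_s", "msd_um2", "n_traj"):
                    if col not in df.columns:
                        report["ok"] = False
                        report["errors"].append(f"missing column {col}")
            else:
                report["ok"] = False
                report["errors"].append("unrecognized CSV schema")
        elif path.suffix.lower() == ".json":
            json.loads(path.read_text())
        else:
            report["ok"] = False
            report["errors"].append(f"unrecognized extension {path.suffix}")
    except mio.CorruptFileError as exc:
        report["ok"] = False
        report["errors"].append(f"corrupt file: {exc}")
    except InputError as exc:
        report["ok"] = False
        report["errors"].append(str(exc))
    except json.JSONDecodeError as exc:
        report["ok"] = False
        report["errors"].append(f"invalid JSON: {exc}")
    return report
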