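"""End-to-end orchestration: simulate -> quantify -> ratio -> cohort.

Each stage of a run receives a deterministic child seed derived from
the master seed and the stage name, so two runs with the same config
are table-identical. ``run_pipeline`` writes every stage output plus a
machine-readable manifest (config hash, seeds, version, per-file
checksums) into the run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort_analysis, densitometry, ratio_stats
from .blot_synth import (
    BlotConfig,
    CohortConfig,
    StimulationParams,
    simulate_cohort,
    simulate_dilution_series,
    simulate_lane,
)
from .images import LaneProfile
from .presets import DilutionPreset, get_cohort_config, get_dilution_preset

__all__ = [
    "RunConfig",
    "run_pipeline",
    "simulate_cohort_lanes",
    "analyze_cohort",
    "dilution_detection_limit",
    "child_seed",
]

log = logging.getLogger("mmrscreen")

_STAGES = ("simulate", "quantify", "ratio", "cohort")
_STAGE_IDS = {name: i + 1 for i, name in enumerate(_STAGES)}


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    if stage not in _STAGE_IDS:
        raise ValueError(f"unknown stage {stage!r}; stages are {_STAGES}")
    ss = np.random.SeedSequence([int(master_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def simulate_cohort_lanes(
    cohort: CohortConfig,
    blot: BlotConfig,
    lane_seed: int,
    stim: StimulationParams | None = None,
) -> tuple[dict[str, LaneProfile], pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and one lane profile per subject.

    Subject identities come from ``cohort.seed``; lane measurement
    noise from per-subject children of ``lane_seed``. Returns
    (profiles by lane_id, manifest, ground truth).
    """
    stim = stim or StimulationParams()
    subjects, truth = simulate_cohort(cohort)
    profiles: dict[str, LaneProfile] = {}
    for i, subject in enumerate(subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(lane_seed), i]))
        profile, _ = simulate_lane(subject, stim, blot, rng=rng)
        profiles[subject.subject_id] = profile
    manifest = pd.DataFrame(
        {"sample_id": [s.subject_id for s in subjects],
         "lane_id": [s.subject_id for s in subjects]}
    )
    return profiles, manifest, truth


def analyze_cohort(
    cohort: CohortConfig,
    blot: BlotConfig | None = None,
    dens: densitometry.DensitometryConfig | None = None,
    lane_seed: int | None = None,
    fit_seed: int = 0,
) -> dict:
    """Full in-memory pipeline for one cohort.

    Returns a dict with the ground truth, band measurements, ratio
    table, bimodality verdict/evidence, mixture fit and cohort report.
    """
    blot = blot or BlotConfig()
    dens = dens or densitometry.DensitometryConfig.from_blot(blot)
    if lane_seed is None:
        lane_seed = child_seed(cohort.seed, "simulate")
    profiles, manifest, truth = simulate_cohort_lanes(cohort, blot, lane_seed)
    measurements = densitometry.quantify_sample(profiles, manifest, dens)
    results = ratio_stats.ratios_from_measurements(measurements)
    ratio_df = ratio_stats.ratios_to_frame(results)
    defined = ratio_df.dropna(subset=["ratio"])
    bimodal, evidence = cohort_analysis.bimodality_verdict(
        defined["ratio"].to_numpy(), seed=fit_seed
    )
    fit = evidence["fit_k2"]
    report = cohort_analysis.assign_and_report(
        defined["sample_id"].tolist(), defined["ratio"].to_numpy(), fit, bimodal
    )
    return {
        "truth": truth,
        "measurements": measurements,
        "ratios": ratio_df,
        "ratio_results": results,
        "bimodal": bimodal,
        "evidence": evidence,
        "fit": fit,
        "report": report,
    }


def dilution_detection_limit(preset: "DilutionPreset | str" = "figure1b") -> float:
    """Detection limit (ug) of a dilution-series preset: the smallest
    load whose lane has both bands detectable."""
    if isinstance(preset, str):
        preset = get_dilution_preset(preset)
    image, truth = simulate_dilution_series(
        preset.blot, preset.loads_ug, subject=preset.subject, stim=preset.stim
    )
    dens = densitometry.DensitometryConfig.from_blot(preset.blot, lod_abs=preset.lod_abs)
    manifest = pd.DataFrame(
        {"sample_id": list(image.lanes), "lane_id": list(image.lanes)}
    )
    measurements = densitometry.quantify_sample(image, manifest, dens)
    loads = dict(zip(truth["subject_id"], truth["load_ug"]))
    return densitometry.detection_limit(measurements, loads)


# ---------------------------------------------------------------------------
# File-based pipeline


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a file-based pipeline run."""

    out_dir: str
    seed: int = 0
    cohort_preset: str = "figure3"
    stages: tuple[str, ...] = _STAGES
    cohort: CohortConfig | None = None
    blot: BlotConfig = field(default_factory=BlotConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {_STAGES}")

    def resolved_cohort(self) -> CohortConfig:
        return self.cohort if self.cohort is not None else get_cohort_config(self.cohort_preset)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON; nested cohort/blot dicts map onto
        their config dataclasses."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        if "cohort" in data and isinstance(data["cohort"], dict):
            data["cohort"] = CohortConfig(**data["cohort"])
        if "blot" in data and isinstance(data["blot"], dict):
            data["blot"] = BlotConfig(**data["blot"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(path: Path, stage: str, produced_by: str) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs {path.name}, produced by stage {produced_by!r}; "
            "run that stage first"
        )


def _profiles_to_frame(profiles: Mapping[str, LaneProfile]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {"lane_id": lane_id, "position": p.positions, "intensity": p.intensities}
        )
        for lane_id, p in profiles.items()
    ]
    return pd.concat(frames, ignore_index=True)


def _profiles_from_frame(df: pd.DataFrame) -> dict[str, LaneProfile]:
    out = {}
    for lane_id, grp in df.groupby("lane_id", sort=False):
        grp = grp.sort_values("position")
        out[str(lane_id)] = LaneProfile(
            positions=grp["position"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
            lane_id=str(lane_id),
        )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write a manifest.

    Outputs (under ``config.out_dir``): ground_truth.csv, profiles.csv,
    lane_manifest.csv, measurements.csv, ratios.csv,
    cohort_report.json, assignments.csv, manifest.json, run.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level.upper())
    seeds = {stage: child_seed(config.seed, stage) for stage in _STAGES}
    written: list[Path] = []
    try:
        log.info("run start: config hash %s seed %d", _config_hash(config), config.seed)
        if "simulate" in config.stages:
            cohort = replace(config.resolved_cohort(), seed=seeds["simulate"])
            profiles, manifest, truth = simulate_cohort_lanes(
                cohort, config.blot, lane_seed=seeds["simulate"]
            )
            truth.to_csv(out / "ground_truth.csv", index=False)
            _profiles_to_frame(profiles).to_csv(out / "profiles.csv", index=False)
            manifest.to_csv(out / "lane_manifest.csv", index=False)
            written += [out / "ground_truth.csv", out / "profiles.csv", out / "lane_manifest.csv"]
            log.info("simulate: %d subjects", len(manifest))
        if "quantify" in config.stages:
            _require(out / "profiles.csv", "quantify", "simulate")
            _require(out / "lane_manifest.csv", "quantify", "simulate")
            profiles = _profiles_from_frame(pd.read_csv(out / "profiles.csv"))
            manifest = pd.read_csv(out / "lane_manifest.csv")
            dens = densitometry.DensitometryConfig.from_blot(config.blot)
            measurements = densitometry.quantify_sample(profiles, manifest, dens)
            measurements.to_csv(out / "measurements.csv", index=False)
            written.append(out / "measurements.csv")
            log.info("quantify: %d band measurements", len(measurements))
        if "ratio" in config.stages:
            _require(out / "measurements.csv", "ratio", "quantify")
            measurements = pd.read_csv(out / "measurements.csv")
            results = ratio_stats.ratios_from_measurements(measurements)
            ratio_stats.ratios_to_frame(results).to_csv(out / "ratios.csv", index=False)
            written.append(out / "ratios.csv")
            log.info("ratio: %d samples, %d defined",
                     len(results), sum(r.defined for r in results))
        if "cohort" in config.stages:
            _require(out / "ratios.csv", "cohort", "ratio")
            ratio_df = pd.read_csv(out / "ratios.csv").dropna(subset=["ratio"])
            bimodal, evidence = cohort_analysis.bimodality_verdict(
                ratio_df["ratio"].to_numpy(), seed=seeds["cohort"]
            )
            fit = evidence["fit_k2"]
            report = cohort_analysis.assign_and_report(
                ratio_df["sample_id"].tolist(), ratio_df["ratio"].to_numpy(), fit, bimodal
            )
            payload = {
                "bimodal": report.bimodal,
                "lower_mode_proportion": report.lower_mode_proportion,
                "fit_k2": _fit_to_dict(fit),
                "fit_k1": _fit_to_dict(evidence["fit_k1"]),
                "bic_k1": evidence["bic_k1"],
                "bic_k2": evidence["bic_k2"],
                "delta_bic": evidence["delta_bic"],
                "separation": evidence["separation"],
                "separation_threshold": evidence["separation_threshold"],
            }
            (out / "cohort_report.json").write_text(json.dumps(payload, indent=2))
            report.assignments.to_csv(out / "assignments.csv", index=False)
            written += [out / "cohort_report.json", out / "assignments.csv"]
            log.info("cohort: bimodal=%s lower_mode_proportion=%.3f",
                     report.bimodal, report.lower_mode_proportion)
        manifest_payload = {
            "version": __version__,
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "master_seed": config.seed,
            "stage_seeds": seeds,
            "outputs": {p.name: _sha256(p) for p in written},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest_payload, indent=2, default=str)
        )
        log.info("run complete: %d outputs", len(written))
        return manifest_payload
    finally:
        log.removeHandler(handler)
        handler.close()


def _fit_to_dict(fit: cohort_analysis.MixtureFit) -> dict:
    return {
        "k": fit.k,
        "means": list(fit.means),
        "sds": list(fit.sds),
        "weights": list(fit.weights),
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
    }
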