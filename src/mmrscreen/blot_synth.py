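"""Synthetic western-blot generator with known ground truth.

Simulates two-band lane profiles (MSH2 at ~100 kDa, MLH1 at ~80 kDa) on
a noisy film background, with band amplitude proportional to protein
abundance x protein load, mitogen (PHA) stimulation of fresh
lymphocytes, heterozygote gene-dosage reduction in carriers, replicate
measurement noise, and screening cohorts drawn from a two-component
ratio mixture.

Every stochastic operation takes an explicit seed; per-item child seeds
are derived with :class:`numpy.random.SeedSequence` so that adding
subjects or replicates never reshuffles earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .images import BlotImage, LaneProfile

__all__ = [
    "CellType",
    "CarrierStatus",
    "Protein",
    "SubjectSpec",
    "StimulationParams",
    "BlotConfig",
    "CohortConfig",
    "stimulation_multiplier",
    "simulate_lane",
    "simulate_blot_image",
    "simulate_dilution_series",
    "simulate_replicates",
    "simulate_cohort",
    "band_amplitudes",
]


class CellType(str, Enum):
    FRESH_LYMPHOCYTE = "fresh_lymphocyte"
    IMMORTALIZED_LYMPHOCYTE = "immortalized_lymphocyte"
    MONOCYTE = "monocyte"
    CELL_LINE = "cell_line"


class CarrierStatus(str, Enum):
    NON_CARRIER = "non_carrier"
    MLH1_CARRIER = "mlh1_carrier"
    MSH2_CARRIER = "msh2_carrier"


class Protein(str, Enum):
    MLH1 = "MLH1"
    MSH2 = "MSH2"


@dataclass(frozen=True)
class SubjectSpec:
    """One sample: cell type, carrier status and true protein abundances.

    ``dosage_factor`` multiplies the mutated protein's abundance for
    carriers (1.0 for non-carriers, enforced). Abundances are in
    arbitrary expression units; zero is allowed to model cell lines
    lacking a full-length protein (e.g. HCT116, LoVo).
    """

    subject_id: str
    cell_type: CellType = CellType.CELL_LINE
    carrier_status: CarrierStatus = CarrierStatus.NON_CARRIER
    base_abundance_mlh1: float = 1.0
    base_abundance_msh2: float = 1.0
    dosage_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.base_abundance_mlh1 < 0 or self.base_abundance_msh2 < 0:
            raise ValueError("base abundances must be non-negative")
        if not 0.0 < self.dosage_factor <= 1.0:
            raise ValueError("dosage_factor must be in (0, 1]")
        if (
            self.carrier_status is CarrierStatus.NON_CARRIER
            and self.dosage_factor != 1.0
        ):
            raise ValueError("dosage_factor must be 1 for non-carriers")

    @property
    def abundance_mlh1(self) -> float:
        """Effective MLH1 abundance after gene-dosage reduction."""
        f = self.dosage_factor if self.carrier_status is CarrierStatus.MLH1_CARRIER else 1.0
        return self.base_abundance_mlh1 * f

    @property
    def abundance_msh2(self) -> float:
        f = self.dosage_factor if self.carrier_status is CarrierStatus.MSH2_CARRIER else 1.0
        return self.base_abundance_msh2 * f

    @property
    def true_target_ratio(self) -> float:
        """min/max of the effective abundances; NaN when either is 0."""
        a, b = self.abundance_mlh1, self.abundance_msh2
        if a <= 0 or b <= 0:
            return float("nan")
        return min(a, b) / max(a, b)


@dataclass(frozen=True)
class StimulationParams:
    """PHA stimulation condition and response constants.

    The multiplier for fresh lymphocytes is
    ``E0_frac + (1 - E0_frac) * d/(d + K_d) * (1 - exp(-t/tau))``:
    a saturating hyperbola in dose times an exponential rise in time.
    Defaults (K_d = 5 ug, tau = 24 h, E0_frac = 0.05) put unstimulated
    fresh-lymphocyte bands below the default detection limit. These
    constants are placeholders for a qualitative dose/time response;
    no quantitative dose-response data exist to pin them down.
    """

    pha_dose_ug: float = 10.0
    time_hr: float = 48.0
    K_d: float = 5.0
    tau: float = 24.0
    E0_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.pha_dose_ug < 0 or self.time_hr < 0:
            raise ValueError("pha_dose_ug and time_hr must be non-negative")
        if self.K_d <= 0 or self.tau <= 0:
            raise ValueError("K_d and tau must be positive")
        if not 0.0 <= self.E0_frac < 1.0:
            raise ValueError("E0_frac must be in [0, 1)")


def stimulation_multiplier(params: StimulationParams, cell_type: CellType) -> float:
    """Expression multiplier in [E0_frac, 1] for a stimulation condition.

    Fresh lymphocytes respond to PHA dose- and time-dependently;
    immortalized lymphocytes and established cell lines express
    constitutively (multiplier 1 regardless of dose/time); monocytes do
    not respond (stuck at the unstimulated fraction).
    """
    cell_type = CellType(cell_type)
    if cell_type in (CellType.IMMORTALIZED_LYMPHOCYTE, CellType.CELL_LINE):
        return 1.0
    if cell_type is CellType.MONOCYTE:
        return params.E0_frac
    d, t = params.pha_dose_ug, params.time_hr
    rise = (d / (d + params.K_d)) * -np.expm1(-t / params.tau)
    return float(params.E0_frac + (1.0 - params.E0_frac) * rise)


@dataclass(frozen=True)
class BlotConfig:
    """Geometry, gain and noise of the simulated film scan.

    A band is a Gaussian on the migration axis with amplitude
    ``amplitude_per_unit * protein_load_ug * abundance * stimulation``;
    the per-position profile noise SD is ``noise_sd``. Band windows
    (center +- 3 sigma) must not overlap.
    """

    migration_axis_length: int = 600
    lane_width: int = 20
    band_center_msh2: int = 200  # 100 kDa: migrates less far
    band_center_mlh1: int = 400  # 80 kDa
    band_sigma: float = 4.0
    background_level: float = 10.0
    background_slope: float = 0.0
    noise_sd: float = 0.5
    amplitude_per_unit: float = 1.0
    protein_load_ug: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.migration_axis_length <= 0 or self.lane_width <= 0:
            raise ValueError("axis length and lane width must be positive")
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background_level must be non-negative")
        if self.amplitude_per_unit <= 0 or self.protein_load_ug <= 0:
            raise ValueError("amplitude_per_unit and protein_load_ug must be positive")
        for c in (self.band_center_msh2, self.band_center_mlh1):
            if not 0 <= c < self.migration_axis_length:
                raise ValueError("band centers must lie within the migration axis")
        lo1, hi1 = self.band_window(Protein.MSH2)
        lo2, hi2 = self.band_window(Protein.MLH1)
        if max(lo1, lo2) < min(hi1, hi2):
            raise ValueError("band windows (center +- 3 sigma) overlap")

    def band_center(self, protein: Protein) -> int:
        return self.band_center_msh2 if Protein(protein) is Protein.MSH2 else self.band_center_mlh1

    def band_window(self, protein: Protein) -> tuple[int, int]:
        """Half-open +-3 sigma pixel window around the nominal center."""
        c = self.band_center(protein)
        half = 3.0 * self.band_sigma
        return (int(round(c - half)), int(round(c + half)))


def band_amplitudes(
    subject: SubjectSpec, stim: StimulationParams, blot: BlotConfig
) -> dict[Protein, float]:
    """Peak height of each band for a subject under a stimulation condition."""
    m = stimulation_multiplier(stim, subject.cell_type)
    gain = blot.amplitude_per_unit * blot.protein_load_ug * m
    return {
        Protein.MLH1: gain * subject.abundance_mlh1,
        Protein.MSH2: gain * subject.abundance_msh2,
    }


def _clean_profile(subject, stim, blot) -> np.ndarray:
    x = np.arange(blot.migration_axis_length, dtype=np.float64)
    y = blot.background_level + blot.background_slope * x
    amps = band_amplitudes(subject, stim, blot)
    for protein, amp in amps.items():
        if amp > 0:
            mu = blot.band_center(protein)
            y += amp * np.exp(-((x - mu) ** 2) / (2.0 * blot.band_sigma**2))
    return y


def _ground_truth_row(subject, stim, blot) -> dict:
    amps = band_amplitudes(subject, stim, blot)
    return {
        "subject_id": subject.subject_id,
        "cell_type": subject.cell_type.value,
        "carrier_status": subject.carrier_status.value,
        "true_abundance_mlh1": subject.abundance_mlh1,
        "true_abundance_msh2": subject.abundance_msh2,
        "true_amplitude_mlh1": amps[Protein.MLH1],
        "true_amplitude_msh2": amps[Protein.MSH2],
        "stimulation_multiplier": stimulation_multiplier(stim, subject.cell_type),
        "protein_load_ug": blot.protein_load_ug,
        "true_target_ratio": subject.true_target_ratio,
    }


def simulate_lane(
    subject: SubjectSpec,
    stim: StimulationParams,
    blot: BlotConfig,
    rng: np.random.Generator | None = None,
) -> tuple[LaneProfile, dict]:
    """Simulate one lane's 1-D migration profile plus its ground-truth row.

    profile(x) = background_level + background_slope*x
                 + sum_b A_b * exp(-(x - mu_b)^2 / (2 sigma^2))
                 + N(0, noise_sd)
    with A_b = amplitude_per_unit * protein_load_ug * abundance_b *
    stimulation_multiplier.
    """
    if rng is None:
        rng = np.random.default_rng(blot.seed)
    y = _clean_profile(subject, stim, blot)
    if blot.noise_sd > 0:
        y = y + rng.normal(0.0, blot.noise_sd, size=y.shape)
    profile = LaneProfile(
        positions=np.arange(blot.migration_axis_length),
        intensities=y,
        lane_id=subject.subject_id,
    )
    return profile, _ground_truth_row(subject, stim, blot)


def simulate_blot_image(
    lanes: Sequence[tuple[SubjectSpec, StimulationParams]],
    blot: BlotConfig,
    gutter: int = 5,
) -> BlotImage:
    """Assemble per-lane profiles into a 2-D grayscale image.

    Each lane occupies ``lane_width`` columns; the lane's deterministic
    profile is spread evenly across its width and per-pixel noise has
    SD ``noise_sd / sqrt(lane_width)`` so that the column-sum over the
    lane reproduces the 1-D lane noise model. Gutters between lanes
    carry background only. Deterministic for a fixed ``blot.seed``.
    """
    if len(lanes) == 0:
        raise ValueError("at least one lane is required")
    rng = np.random.default_rng(blot.seed)
    L, w = blot.migration_axis_length, blot.lane_width
    ncol = len(lanes) * w + (len(lanes) + 1) * gutter
    x = np.arange(L, dtype=np.float64)
    bg = blot.background_level + blot.background_slope * x
    pixels = np.tile((bg / w)[:, None], (1, ncol))
    pixel_sd = blot.noise_sd / np.sqrt(w)
    if pixel_sd > 0:
        pixels += rng.normal(0.0, pixel_sd, size=pixels.shape)
    spans: dict[str, tuple[int, int]] = {}
    col = gutter
    truth_rows = []
    for subject, stim in lanes:
        clean = _clean_profile(subject, stim, blot)
        pixels[:, col : col + w] += ((clean - bg) / w)[:, None]
        spans[subject.subject_id] = (col, col + w)
        truth_rows.append(_ground_truth_row(subject, stim, blot))
        col += w + gutter
    return BlotImage(
        pixels=pixels,
        lanes=spans,
        meta={"gutter": gutter, "seed": blot.seed, "ground_truth": truth_rows},
    )


def simulate_dilution_series(
    blot: BlotConfig,
    loads_ug: Sequence[float],
    subject: SubjectSpec | None = None,
    stim: StimulationParams | None = None,
    gutter: int = 5,
) -> tuple[BlotImage, pd.DataFrame]:
    """One lane per protein load, same subject abundances throughout.

    Emulates a serial-dilution blot: net band signal scales linearly
    with load. Lane ids are ``load_<x>``. Returns the assembled image
    and a ground-truth table with one row per lane.
    """
    loads = [float(v) for v in loads_ug]
    if len(loads) == 0 or any(v <= 0 for v in loads):
        raise ValueError("loads_ug must be non-empty and strictly positive")
    if subject is None:
        subject = SubjectSpec(subject_id="SW480", cell_type=CellType.CELL_LINE)
    if stim is None:
        stim = StimulationParams()
    truth = []
    # Build one multi-lane image by varying protein_load_ug per lane:
    # assemble manually since BlotConfig is per-image.
    rng = np.random.default_rng(blot.seed)
    L, w = blot.migration_axis_length, blot.lane_width
    ncol = len(loads) * w + (len(loads) + 1) * gutter
    x = np.arange(L, dtype=np.float64)
    bg = blot.background_level + blot.background_slope * x
    pixels = np.tile((bg / w)[:, None], (1, ncol))
    pixel_sd = blot.noise_sd / np.sqrt(w)
    if pixel_sd > 0:
        pixels += rng.normal(0.0, pixel_sd, size=pixels.shape)
    spans: dict[str, tuple[int, int]] = {}
    col = gutter
    for load in loads:
        cfg = replace(blot, protein_load_ug=load)
        lane_id = f"load_{load:g}"
        lane_subject = replace(subject, subject_id=lane_id)
        clean = _clean_profile(lane_subject, stim, cfg)
        pixels[:, col : col + w] += ((clean - bg) / w)[:, None]
        spans[lane_id] = (col, col + w)
        row = _ground_truth_row(lane_subject, stim, cfg)
        row["load_ug"] = load
        truth.append(row)
        col += w + gutter
    image = BlotImage(pixels=pixels, lanes=spans, meta={"loads_ug": loads, "seed": blot.seed})
    return image, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Replicates


@dataclass(frozen=True)
class ReplicateNoisePreset:
    """Target distribution of the per-replicate abundance ratio.

    Each replicate draws an (unfolded) MLH1:MSH2 abundance ratio from
    N(ratio_mean, ratio_sd); draws above 1 simply mean MLH1 exceeded
    MSH2 in that preparation, and the min/max convention folds them
    back below 1 downstream. ``blot`` carries the measurement-noise
    settings used for the round-trip mode.
    """

    name: str
    ratio_mean: float
    ratio_sd: float
    blot: BlotConfig

    def __post_init__(self) -> None:
        if self.ratio_mean <= 0 or self.ratio_sd < 0:
            raise ValueError("ratio_mean must be positive and ratio_sd non-negative")


def _draw_replicate_ratios(preset: ReplicateNoisePreset, n: int, rng) -> np.ndarray:
    r = rng.normal(preset.ratio_mean, preset.ratio_sd, size=n)
    return np.clip(r, 1e-6, None)


def simulate_replicates(
    subject_id: str,
    n_reps: int,
    noise_preset: "ReplicateNoisePreset | str",
    seed: int,
    mode: str = "roundtrip",
) -> pd.DataFrame:
    """Simulate ``n_reps`` independent replicate measurements of one sample.

    mode="roundtrip" simulates a full lane per replicate and quantifies
    it through the densitometry and ratio stages; mode="direct" applies
    the min/max fold to the drawn abundance ratios without simulating
    pixels. Columns: replicate, true_abundance_ratio, mlh1_net,
    msh2_net, ratio, defined.
    """
    from . import densitometry, ratio_stats
    from .presets import get_replicate_preset

    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (replicate SD undefined otherwise)")
    if mode not in ("roundtrip", "direct"):
        raise ValueError(f"unknown mode {mode!r}")
    preset = (
        get_replicate_preset(noise_preset) if isinstance(noise_preset, str) else noise_preset
    )
    root = np.random.SeedSequence([int(seed), 0x5EED])
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    true_ratios = _draw_replicate_ratios(preset, n_reps, draw_rng)
    stim = StimulationParams()
    rows = []
    for i, r in enumerate(true_ratios):
        rec = {"replicate": i, "true_abundance_ratio": float(r)}
        if mode == "direct":
            folded = r if r <= 1.0 else 1.0 / r
            rec.update(
                mlh1_net=float("nan"), msh2_net=float("nan"), ratio=float(folded), defined=True
            )
        else:
            subject = SubjectSpec(
                subject_id=f"{subject_id}_rep{i}",
                cell_type=CellType.CELL_LINE,
                base_abundance_mlh1=float(r),
                base_abundance_msh2=1.0,
            )
            lane_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1, i]))
            profile, _ = simulate_lane(subject, stim, preset.blot, rng=lane_rng)
            cfg = densitometry.DensitometryConfig.from_blot(preset.blot)
            pair = densitometry.measure_band_pair(profile, cfg)
            res = ratio_stats.mmr_ratio(
                pair[Protein.MLH1].net_density,
                pair[Protein.MSH2].net_density,
                sample_id=subject.subject_id,
                mlh1_detectable=pair[Protein.MLH1].detectable,
                msh2_detectable=pair[Protein.MSH2].detectable,
            )
            rec.update(
                mlh1_net=pair[Protein.MLH1].net_density,
                msh2_net=pair[Protein.MSH2].net_density,
                ratio=res.ratio if res.ratio is not None else float("nan"),
                defined=res.ratio is not None,
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.insert(0, "sample_id", subject_id)
    return out


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortConfig:
    """Screening cohort: carrier mixture on the target-ratio scale.

    Carriers and non-carriers draw their true MLH1:MSH2 target ratio
    from truncated normals on [ratio_floor, 1]; the affected protein's
    abundance equals the unaffected one times the ratio.
    """

    n_subjects: int = 50
    carrier_prevalence: float = 0.25
    gene_split: float = 0.5  # fraction of carriers that are MLH1 carriers
    noncarrier_ratio_mean: float = 0.97
    noncarrier_ratio_sd: float = 0.02
    carrier_ratio_mean: float = 0.81
    carrier_ratio_sd: float = 0.08
    ratio_floor: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.carrier_prevalence <= 1.0:
            raise ValueError("carrier_prevalence must be in [0, 1]")
        if not 0.0 <= self.gene_split <= 1.0:
            raise ValueError("gene_split must be in [0, 1]")
        if not 0.0 < self.ratio_floor <= 1.0:
            raise ValueError("ratio_floor must be in (0, 1]")
        if self.carrier_ratio_mean >= self.noncarrier_ratio_mean:
            raise ValueError("carrier_ratio_mean must be below noncarrier_ratio_mean")


def _truncnorm_draw(mean: float, sd: float, lo: float, hi: float, rng) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_cohort(config: CohortConfig) -> tuple[list[SubjectSpec], pd.DataFrame]:
    """Draw a cohort of subjects with known carrier status and target ratios.

    Subject i uses the deterministic child seed (config.seed, i), so
    growing the cohort never reshuffles earlier subjects. Returns the
    subject specs (fresh lymphocytes throughout) and a ground-truth
    table with one row per subject.
    """
    subjects: list[SubjectSpec] = []
    rows = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), i]))
        is_carrier = rng.random() < config.carrier_prevalence
        if is_carrier:
            mlh1_mut = rng.random() < config.gene_split
            status = CarrierStatus.MLH1_CARRIER if mlh1_mut else CarrierStatus.MSH2_CARRIER
            ratio = _truncnorm_draw(
                config.carrier_ratio_mean, config.carrier_ratio_sd,
                config.ratio_floor, 1.0, rng,
            )
        else:
            status = CarrierStatus.NON_CARRIER
            mlh1_mut = rng.random() < 0.5  # which protein runs lower, by chance
            ratio = _truncnorm_draw(
                config.noncarrier_ratio_mean, config.noncarrier_ratio_sd,
                config.ratio_floor, 1.0, rng,
            )
        ab_mlh1, ab_msh2 = (ratio, 1.0) if mlh1_mut else (1.0, ratio)
        subject = SubjectSpec(
            subject_id=f"S{i:04d}",
            cell_type=CellType.FRESH_LYMPHOCYTE,
            carrier_status=status,
            base_abundance_mlh1=ab_mlh1,
            base_abundance_msh2=ab_msh2,
        )
        subjects.append(subject)
        rows.append(
            {
                "subject_id": subject.subject_id,
                "carrier_status": status.value,
                "true_abundance_mlh1": subject.abundance_mlh1,
                "true_abundance_msh2": subject.abundance_msh2,
                "true_target_ratio": subject.true_target_ratio,
                "lower_protein_true": "MLH1" if mlh1_mut else "MSH2",
            }
        )
    return subjects, pd.DataFrame(rows)
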