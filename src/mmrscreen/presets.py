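"""Named presets for reproducible experiment setups.

Registry names:

``figure1b``
    Dilution-series blot whose detection limit over the 2-fold load
    grid 1.25-40 ug is 10 ug of total protein.
``table2-sw480``, ``table2-wbc1`` .. ``table2-wbc4``
    Replicate-noise presets for the reproducibility panel
    (SW480 0.989 +- 0.006; WBC controls 0.980 +- 0.018,
    0.967 +- 0.031, 0.954 +- 0.059, 0.921 +- 0.074). ``table2-wbc``
    is an alias for ``table2-wbc1``.
``figure3``
    N=50 screening cohort, 25% carrier prevalence split evenly between
    MLH1 and MSH2, ratio components 0.97 +- 0.02 (non-carrier) and
    0.81 +- 0.08 (carrier), floor 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .blot_synth import (
    BlotConfig,
    CellType,
    CohortConfig,
    ReplicateNoisePreset,
    StimulationParams,
    SubjectSpec,
)

__all__ = [
    "DilutionPreset",
    "get_replicate_preset",
    "get_cohort_config",
    "get_dilution_preset",
    "replicate_preset_names",
    "TABLE2_PANEL",
]

# Measurement-noise blot used by the replicate presets: high signal and
# low pixel noise so the replicate spread is dominated by the preset's
# preparation-to-preparation ratio SD, as in the reproducibility panel.
_REPLICATE_BLOT = BlotConfig(
    noise_sd=0.25, amplitude_per_unit=2.0, protein_load_ug=40.0, seed=0
)

_REPLICATE_PRESETS: dict[str, ReplicateNoisePreset] = {
    name: ReplicateNoisePreset(name=name, ratio_mean=m, ratio_sd=s, blot=_REPLICATE_BLOT)
    for name, m, s in [
        ("table2-sw480", 0.989, 0.006),
        ("table2-wbc1", 0.980, 0.018),
        ("table2-wbc2", 0.967, 0.031),
        ("table2-wbc3", 0.954, 0.059),
        ("table2-wbc4", 0.921, 0.074),
    ]
}
_REPLICATE_PRESETS["table2-wbc"] = _REPLICATE_PRESETS["table2-wbc1"]

#: The full reproducibility panel (one SW480 + four WBC controls).
TABLE2_PANEL: tuple[str, ...] = (
    "table2-sw480", "table2-wbc1", "table2-wbc2", "table2-wbc3", "table2-wbc4",
)


def replicate_preset_names() -> list[str]:
    return sorted(_REPLICATE_PRESETS)


def get_replicate_preset(name: str) -> ReplicateNoisePreset:
    try:
        return _REPLICATE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown replicate preset {name!r}; available: {replicate_preset_names()}"
        ) from None


@dataclass(frozen=True)
class DilutionPreset:
    """Dilution-series setup: blot gain/noise, load grid and the
    detectability floor that fixes the detection limit."""

    name: str
    blot: BlotConfig
    loads_ug: tuple[float, ...]
    lod_abs: float
    subject: SubjectSpec
    stim: StimulationParams = field(default_factory=StimulationParams)


# amplitude_per_unit = 0.5 puts the net band integral at ~5 density
# units per ug of load (sigma=4 Gaussian), so the absolute floor of 35
# sits between the 5 ug (~25) and 10 ug (~50) lanes: the smallest load
# on the 2-fold grid with both bands detectable is 10 ug.
_FIGURE1B = DilutionPreset(
    name="figure1b",
    blot=BlotConfig(noise_sd=0.5, amplitude_per_unit=0.5, seed=101),
    loads_ug=(1.25, 2.5, 5.0, 10.0, 20.0, 40.0),
    lod_abs=35.0,
    subject=SubjectSpec(subject_id="SW480", cell_type=CellType.CELL_LINE),
)

_DILUTION_PRESETS = {"figure1b": _FIGURE1B}


def get_dilution_preset(name: str = "figure1b") -> DilutionPreset:
    try:
        return _DILUTION_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown dilution preset {name!r}; available: {sorted(_DILUTION_PRESETS)}"
        ) from None


_COHORT_PRESETS: dict[str, CohortConfig] = {
    "figure3": CohortConfig(
        n_subjects=50,
        carrier_prevalence=0.25,
        gene_split=0.5,
        noncarrier_ratio_mean=0.97,
        noncarrier_ratio_sd=0.02,
        carrier_ratio_mean=0.81,
        carrier_ratio_sd=0.08,
        ratio_floor=0.3,
        seed=0,
    )
}


def get_cohort_config(name: str = "figure3") -> CohortConfig:
    try:
        return _COHORT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown cohort preset {name!r}; available: {sorted(_COHORT_PRESETS)}"
        ) from None
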