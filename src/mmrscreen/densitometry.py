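"""Band quantification from blot images or lane profiles.

Implements the film-densitometry workflow: extract a lane's 1-D
migration profile, locate each band, integrate pixel intensity over
the band window, subtract an equivalent-area background estimated from
flanking film regions, and call detectability.

Conventions: 0-based pixel indices, half-open windows ``[start, end)``.
Negative net densities are reported as-is (they force
``detectable=False``) — they are never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blot_synth import BlotConfig, Protein
from .images import BlotImage, LaneProfile

__all__ = [
    "BandWindow",
    "BandMeasurement",
    "DensitometryConfig",
    "extract_lane",
    "locate_band",
    "measure_band",
    "measure_band_pair",
    "quantify_sample",
    "detection_limit",
]


@dataclass(frozen=True)
class BandWindow:
    """Integration window plus localisation diagnostics."""

    start: int
    end: int
    center: float
    sigma_est: float
    flags: frozenset = frozenset()

    @property
    def width(self) -> int:
        return self.end - self.start

    def as_tuple(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class BandMeasurement:
    """Integrated density for one band, background-subtracted.

    ``net_density = raw_density - background_density`` exactly, where
    the background is the flank median intensity times the window
    width (an equivalent-area estimate from the same film).
    """

    protein: Protein
    window: tuple[int, int]
    raw_density: float
    background_density: float
    net_density: float
    detectable: bool
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not np.isclose(
            self.net_density, self.raw_density - self.background_density, atol=1e-9
        ):
            raise ValueError("net_density must equal raw_density - background_density")


@dataclass(frozen=True)
class DensitometryConfig:
    """Search windows, localisation and detectability settings.

    A band is detectable when its net density is positive, at least
    ``lod_abs``, and at least ``lod_snr`` times the flank noise scaled
    to the window (flank SD x sqrt(window width)).
    """

    search_window_msh2: tuple[int, int] = (150, 250)
    search_window_mlh1: tuple[int, int] = (350, 450)
    nominal_center_msh2: int = 200
    nominal_center_mlh1: int = 400
    nominal_sigma: float = 4.0
    k_sigma: float = 3.0  # integration half-width in sigmas
    lod_abs: float = 0.0
    lod_snr: float = 3.0
    flank_width: int | None = None  # per side; defaults to the window width
    flank_gap: int | None = None  # guard gap before flanks; defaults to width // 2
    saturation_level: float | None = None

    @classmethod
    def from_blot(cls, blot: BlotConfig, halfwidth: int = 50, **overrides) -> "DensitometryConfig":
        """Derive search windows from a synthetic blot's geometry."""
        hw = max(halfwidth, int(round(4 * blot.band_sigma)))
        L = blot.migration_axis_length
        mk = lambda c: (max(0, c - hw), min(L, c + hw))
        kw = dict(
            search_window_msh2=mk(blot.band_center_msh2),
            search_window_mlh1=mk(blot.band_center_mlh1),
            nominal_center_msh2=blot.band_center_msh2,
            nominal_center_mlh1=blot.band_center_mlh1,
            nominal_sigma=blot.band_sigma,
        )
        kw.update(overrides)
        return cls(**kw)

    def search_window(self, protein: Protein) -> tuple[int, int]:
        return (
            self.search_window_msh2
            if Protein(protein) is Protein.MSH2
            else self.search_window_mlh1
        )

    def nominal_center(self, protein: Protein) -> int:
        return (
            self.nominal_center_msh2
            if Protein(protein) is Protein.MSH2
            else self.nominal_center_mlh1
        )


def extract_lane(image: BlotImage, lane_id: str) -> LaneProfile:
    """Column-sum the lane's pixel columns into a 1-D migration profile."""
    if lane_id not in image.lanes:
        raise KeyError(f"unknown lane_id {lane_id!r}; have {sorted(image.lanes)}")
    a, b = image.lanes[lane_id]
    return LaneProfile(
        positions=np.arange(image.pixels.shape[0]),
        intensities=image.pixels[:, a:b].sum(axis=1),
        lane_id=lane_id,
    )


def _detrend(seg: np.ndarray) -> np.ndarray:
    """Remove a straight line anchored at the segment's two ends
    (median of the outer few pixels each side)."""
    n = len(seg)
    m = max(1, min(5, n // 4))
    left = float(np.median(seg[:m]))
    right = float(np.median(seg[-m:]))
    x = np.arange(n, dtype=np.float64)
    baseline = left + (right - left) * x / max(n - 1, 1)
    return seg - baseline


def locate_band(
    profile: LaneProfile,
    protein: Protein,
    search_window: tuple[int, int] | None = None,
    config: DensitometryConfig | None = None,
) -> BandWindow:
    """Find the integration window for a band inside a search window.

    The window is centred on the maximum of the background-detrended
    profile, with width ``round(2 * k_sigma * sigma_est)`` where
    ``sigma_est`` comes from the peak's full width at half maximum.
    If no local maximum rises above the detrended noise floor, the
    nominal window at the expected position is returned with a
    ``no_peak_found`` flag.
    """
    cfg = config or DensitometryConfig()
    protein = Protein(protein)
    if search_window is None:
        search_window = cfg.search_window(protein)
    s0, s1 = int(search_window[0]), int(search_window[1])
    n = len(profile)
    if not (0 <= s0 < s1 <= n):
        raise ValueError(f"search window ({s0}, {s1}) outside profile of length {n}")
    seg = profile.intensities[s0:s1]
    detr = _detrend(seg)
    mad = float(np.median(np.abs(detr - np.median(detr))))
    noise_floor = 3.0 * 1.4826 * mad
    peak_idx = int(np.argmax(detr))
    peak_val = float(detr[peak_idx])
    flags: set[str] = set()

    if peak_val <= max(noise_floor, 1e-9):
        center = float(cfg.nominal_center(protein))
        sigma_est = cfg.nominal_sigma
        flags.add("no_peak_found")
    else:
        center = float(s0 + peak_idx)
        sigma_est = _sigma_from_fwhm(detr, peak_idx, cfg.nominal_sigma)

    width = int(round(2.0 * cfg.k_sigma * sigma_est))
    width = max(width, 3)
    start = int(round(center)) - width // 2
    end = start + width
    start = max(start, 0)
    end = min(end, n)
    return BandWindow(start=start, end=end, center=center, sigma_est=sigma_est, flags=frozenset(flags))


def _sigma_from_fwhm(detr: np.ndarray, peak_idx: int, nominal_sigma: float) -> float:
    """Peak SD from the contiguous half-maximum region; clamped and
    falling back to the nominal value when the shape is degenerate."""
    half = detr[peak_idx] / 2.0
    lo = peak_idx
    while lo > 0 and detr[lo - 1] >= half:
        lo -= 1
    hi = peak_idx
    while hi < len(detr) - 1 and detr[hi + 1] >= half:
        hi += 1
    fwhm = hi - lo + 1
    sigma = fwhm / 2.3548
    if not np.isfinite(sigma) or sigma < 1.0:
        sigma = max(1.0, nominal_sigma)
    return float(min(sigma, 3.0 * nominal_sigma))


def _collect_flank(
    n: int,
    window: tuple[int, int],
    exclude: Sequence[tuple[int, int]],
    per_side: int,
    gap: int,
) -> np.ndarray:
    """Indices of eligible flank pixels, expanding outward from the
    window edges after a guard gap (which keeps the band's own tail
    out of the background) and skipping excluded (other-band) zones."""
    start, end = window
    blocked = np.zeros(n, dtype=bool)
    blocked[start:end] = True
    for a, b in exclude:
        blocked[max(0, a) : min(n, b)] = True
    left: list[int] = []
    i = start - 1 - gap
    while i >= 0 and len(left) < per_side:
        if not blocked[i]:
            left.append(i)
        i -= 1
    right: list[int] = []
    i = end + gap
    while i < n and len(right) < per_side:
        if not blocked[i]:
            right.append(i)
        i += 1
    return np.array(sorted(left + right), dtype=np.int64)


def measure_band(
    profile: LaneProfile,
    window: "BandWindow | tuple[int, int]",
    protein: Protein = Protein.MLH1,
    exclude: Sequence[tuple[int, int]] = (),
    config: DensitometryConfig | None = None,
) -> BandMeasurement:
    """Integrate a band and subtract the equivalent-area background.

    raw_density is the intensity sum over the window. The background
    estimate is the median intensity over flanking regions (combined
    width >= window width, other-band windows excluded) times the
    window width, mirroring a same-film equivalent-area reading.
    """
    cfg = config or DensitometryConfig()
    flags: set[str] = set()
    if isinstance(window, BandWindow):
        flags |= set(window.flags)
        window_t = window.as_tuple()
    else:
        window_t = (int(window[0]), int(window[1]))
    start, end = window_t
    n = len(profile)
    if not (0 <= start < end <= n):
        raise ValueError(f"window ({start}, {end}) outside profile of length {n}")
    for a, b in exclude:
        if max(start, a) < min(end, b):
            raise ValueError(
                f"integration window ({start}, {end}) overlaps exclusion zone ({a}, {b})"
            )
    w = end - start
    y = profile.intensities
    raw = float(y[start:end].sum())

    per_side = cfg.flank_width if cfg.flank_width is not None else w
    gap = cfg.flank_gap if cfg.flank_gap is not None else w // 2
    flank_idx = _collect_flank(n, window_t, exclude, per_side, gap)
    if len(flank_idx) < w:
        raise ValueError(
            f"only {len(flank_idx)} flank pixels available; need >= window width {w}"
        )
    flank = y[flank_idx]
    bg_per_px = float(np.median(flank))
    background = bg_per_px * w
    net = raw - background
    flank_sd = float(np.std(flank, ddof=1)) if len(flank) > 1 else 0.0

    detectable = (
        net > 0.0
        and net >= cfg.lod_abs
        and net >= cfg.lod_snr * flank_sd * np.sqrt(w)
    )
    if net <= 0:
        flags.add("nonpositive_net")
    if cfg.saturation_level is not None and np.any(y[start:end] >= cfg.saturation_level):
        flags.add("saturated")
    return BandMeasurement(
        protein=Protein(protein),
        window=window_t,
        raw_density=raw,
        background_density=background,
        net_density=net,
        detectable=bool(detectable),
        flags=frozenset(flags),
    )


def measure_band_pair(
    profile: LaneProfile, config: DensitometryConfig | None = None
) -> dict[Protein, BandMeasurement]:
    """Locate and measure both target bands in one lane, excluding each
    band's window from the other's background flanks."""
    cfg = config or DensitometryConfig()
    windows = {p: locate_band(profile, p, config=cfg) for p in Protein}
    out: dict[Protein, BandMeasurement] = {}
    for p in Protein:
        other = Protein.MSH2 if p is Protein.MLH1 else Protein.MLH1
        out[p] = measure_band(
            profile, windows[p], protein=p, exclude=[windows[other].as_tuple()], config=cfg
        )
    return out


def quantify_sample(
    source: "BlotImage | Mapping[str, LaneProfile]",
    manifest: pd.DataFrame,
    config: DensitometryConfig | None = None,
) -> pd.DataFrame:
    """Quantify both bands for every manifest entry.

    ``manifest`` needs columns ``sample_id`` and ``lane_id``. Returns a
    tidy table with one row per (sample, protein): sample_id, lane_id,
    protein, raw_density, background_density, net_density, detectable,
    flags.
    """
    cfg = config or DensitometryConfig()
    required = {"sample_id", "lane_id"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if isinstance(source, BlotImage):
        available = set(source.lanes)
        get = lambda lane_id: extract_lane(source, lane_id)
    else:
        available = set(source)
        get = lambda lane_id: source[lane_id]
    missing = [l for l in manifest["lane_id"] if l not in available]
    if missing:
        raise KeyError(f"manifest lanes missing from input: {missing}")
    rows = []
    for rec in manifest.itertuples(index=False):
        profile = get(rec.lane_id)
        pair = measure_band_pair(profile, cfg)
        for p in Protein:
            m = pair[p]
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "lane_id": rec.lane_id,
                    "protein": p.value,
                    "raw_density": m.raw_density,
                    "background_density": m.background_density,
                    "net_density": m.net_density,
                    "detectable": m.detectable,
                    "flags": ";".join(sorted(m.flags)),
                }
            )
    columns = [
        "sample_id", "lane_id", "protein", "raw_density",
        "background_density", "net_density", "detectable", "flags",
    ]
    return pd.DataFrame(rows, columns=columns)


def detection_limit(measurements: pd.DataFrame, loads: Mapping[str, float]) -> float:
    """Smallest protein load whose lane has *both* bands detectable.

    ``loads`` maps lane_id to load (ug). Returns NaN if no lane passes.
    """
    by_lane = measurements.groupby("lane_id")["detectable"].all()
    passing = [loads[lane] for lane, ok in by_lane.items() if ok and lane in loads]
    return float(min(passing)) if passing else float("nan")
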