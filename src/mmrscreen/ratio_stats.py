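"""The MMR ratio statistic and replicate reproducibility summaries.

The ratio always puts the smaller of the two net band densities (MLH1,
MSH2) in the numerator and the larger in the denominator, so a defined
ratio lies in (0, 1]: the further below 1, the greater the deficit of
the lower protein. Ratios are undefined when either net density is
non-positive or the band was not detectable; undefined ratios are
excluded from summaries, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RatioResult",
    "ReplicateSummary",
    "PooledSummary",
    "mmr_ratio",
    "summarize_replicates",
    "pool_overall",
    "ratios_from_measurements",
]


@dataclass(frozen=True)
class RatioResult:
    sample_id: str
    ratio: float | None
    lower_protein: str  # "MLH1" | "MSH2" | "tie" | "undefined"
    mlh1_net: float
    msh2_net: float
    qc_flags: frozenset = frozenset()

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def mmr_ratio(
    mlh1_net: float,
    msh2_net: float,
    sample_id: str = "",
    mlh1_detectable: bool = True,
    msh2_detectable: bool = True,
) -> RatioResult:
    """min(MLH1, MSH2) / max(MLH1, MSH2) with the lower protein named.

    Handles any real inputs: a non-positive or non-detectable density
    yields an undefined ratio with a ``nondetectable_band`` qc flag
    rather than an error.
    """
    mlh1_net = float(mlh1_net)
    msh2_net = float(msh2_net)
    flags: set[str] = set()
    usable = (
        np.isfinite(mlh1_net)
        and np.isfinite(msh2_net)
        and mlh1_net > 0.0
        and msh2_net > 0.0
        and mlh1_detectable
        and msh2_detectable
    )
    if not usable:
        flags.add("nondetectable_band")
        return RatioResult(
            sample_id=sample_id,
            ratio=None,
            lower_protein="undefined",
            mlh1_net=mlh1_net,
            msh2_net=msh2_net,
            qc_flags=frozenset(flags),
        )
    if mlh1_net == msh2_net:
        lower = "tie"
        ratio = 1.0
    elif mlh1_net < msh2_net:
        lower = "MLH1"
        ratio = mlh1_net / msh2_net
    else:
        lower = "MSH2"
        ratio = msh2_net / mlh1_net
    return RatioResult(
        sample_id=sample_id,
        ratio=ratio,
        lower_protein=lower,
        mlh1_net=mlh1_net,
        msh2_net=msh2_net,
        qc_flags=frozenset(flags),
    )


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +- SD of one sample's defined replicate ratios.

    ``sde_ratio`` is the sample standard deviation (n-1 denominator);
    the defined ratios themselves are retained so that panels can be
    pooled over the concatenated raw values.
    """

    sample_id: str
    n_reps: int
    mean_ratio: float
    sde_ratio: float
    ratios: tuple[float, ...]


def summarize_replicates(results: Sequence[RatioResult]) -> ReplicateSummary:
    """Aggregate replicate measurements of a single sample."""
    vals = [r.ratio for r in results if r.ratio is not None]
    if len(vals) < 2:
        raise ValueError(
            f"need >= 2 defined replicate ratios, got {len(vals)} (SD undefined)"
        )
    ids = {r.sample_id for r in results}
    sample_id = ids.pop() if len(ids) == 1 else "|".join(sorted(map(str, ids)))
    arr = np.asarray(vals, dtype=np.float64)
    return ReplicateSummary(
        sample_id=sample_id,
        n_reps=len(vals),
        mean_ratio=float(arr.mean()),
        sde_ratio=float(arr.std(ddof=1)),
        ratios=tuple(float(v) for v in vals),
    )


@dataclass(frozen=True)
class PooledSummary:
    n_total: int
    mean_ratio: float
    sde_ratio: float


def pool_overall(summaries: Sequence[ReplicateSummary]) -> PooledSummary:
    """Overall mean +- SD over the concatenated defined ratios of all
    listed samples (not a mean of means)."""
    if len(summaries) == 0:
        raise ValueError("pool_overall requires at least one summary")
    pooled = np.concatenate([np.asarray(s.ratios, dtype=np.float64) for s in summaries])
    sde = float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0
    return PooledSummary(
        n_total=len(pooled), mean_ratio=float(pooled.mean()), sde_ratio=sde
    )


def ratios_from_measurements(measurements: pd.DataFrame) -> list[RatioResult]:
    """Pair up MLH1/MSH2 rows of a band-measurement table per
    (sample_id, lane_id) and compute the ratio for each pair."""
    required = {"sample_id", "lane_id", "protein", "net_density", "detectable"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")
    out: list[RatioResult] = []
    for (sample_id, _lane), grp in measurements.groupby(
        ["sample_id", "lane_id"], sort=False
    ):
        by_protein = {row.protein: row for row in grp.itertuples(index=False)}
        if set(by_protein) != {"MLH1", "MSH2"}:
            raise ValueError(
                f"sample {sample_id!r}: expected one MLH1 and one MSH2 row, "
                f"got {sorted(by_protein)}"
            )
        mlh1, msh2 = by_protein["MLH1"], by_protein["MSH2"]
        out.append(
            mmr_ratio(
                mlh1.net_density,
                msh2.net_density,
                sample_id=str(sample_id),
                mlh1_detectable=bool(mlh1.detectable),
                msh2_detectable=bool(msh2.detectable),
            )
        )
    return out


def ratios_to_frame(results: Sequence[RatioResult]) -> pd.DataFrame:
    """Tidy table of ratio results (ratio NaN when undefined)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "ratio": [r.ratio if r.ratio is not None else np.nan for r in results],
            "lower_protein": [r.lower_protein for r in results],
            "mlh1_net": [r.mlh1_net for r in results],
            "msh2_net": [r.msh2_net for r in results],
            "qc_flags": [";".join(sorted(r.qc_flags)) for r in results],
        }
    )
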