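"""Canned evaluation experiments used by the acceptance suite.

Each experiment regenerates its inputs from the named presets, runs the
relevant pipeline stages from scratch, and returns summary numbers.
All randomness is controlled by an explicit base seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import blot_synth as bs
from . import cohort_analysis as ca
from . import ratio_stats as rs
from . import workflow as wf
from .presets import TABLE2_PANEL, get_cohort_config

__all__ = [
    "figure3_experiment",
    "ratio_property_experiment",
    "table2_panel_experiment",
    "noncarrier_experiment",
    "bimodality_null_experiment",
    "bimodality_power_experiment",
]


def figure3_experiment(n_cohorts: int = 200, base_seed: int = 1) -> dict:
    """Simulate ``n_cohorts`` screening cohorts from the figure3 preset
    and push each through blot simulation, densitometry, the ratio
    statistic and the 2-component mixture fit with mode assignment.

    Returns means over cohorts of: fitted upper-mode mean, fitted
    lower-mode mean, lower-mode proportion, generator carrier
    fraction, and the bimodal verdict rate.
    """
    base = get_cohort_config("figure3")
    upper, lower, props, carrier, bimodal = [], [], [], [], []
    for i in range(n_cohorts):
        seed = base_seed + i
        res = wf.analyze_cohort(replace(base, seed=seed), fit_seed=seed)
        fit = res["fit"]
        upper.append(fit.means[0])
        lower.append(fit.means[1])
        props.append(res["report"].lower_mode_proportion)
        carrier.append((res["truth"]["carrier_status"] != "non_carrier").mean())
        bimodal.append(res["bimodal"])
    return {
        "n_cohorts": n_cohorts,
        "mean_upper_mode": float(np.mean(upper)),
        "mean_lower_mode": float(np.mean(lower)),
        "mean_lower_mode_proportion": float(np.mean(props)),
        "mean_carrier_fraction": float(np.mean(carrier)),
        "bimodal_rate": float(np.mean(bimodal)),
    }


def ratio_property_experiment(n_pairs: int = 100_000, seed: int = 0) -> dict:
    """Property sweep of the ratio statistic over random positive pairs:
    bound, symmetry and scale invariance, plus the equal-inputs case."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(1e-6, 1e4, n_pairs)
    b = rng.uniform(1e-6, 1e4, n_pairs)
    c = rng.uniform(1e-3, 1e3, n_pairs)
    ratios = np.empty(n_pairs)
    sym_ok = scale_ok = True
    for i in range(n_pairs):
        r = rs.mmr_ratio(a[i], b[i]).ratio
        ratios[i] = r
        sym_ok &= abs(rs.mmr_ratio(b[i], a[i]).ratio - r) <= 1e-12 * r
        scale_ok &= abs(rs.mmr_ratio(c[i] * a[i], c[i] * b[i]).ratio - r) <= 1e-9 * r
    return {
        "n_pairs": n_pairs,
        "max_ratio": float(ratios.max()),
        "min_ratio": float(ratios.min()),
        "all_in_bounds": bool((ratios > 0).all() and (ratios <= 1.0).all()),
        "symmetric": bool(sym_ok),
        "scale_invariant": bool(scale_ok),
        "equal_inputs_ratio": rs.mmr_ratio(5.0, 5.0).ratio,
    }


def _panel_summaries(n_seeds: int, n_reps: int, base_seed: int) -> list[rs.ReplicateSummary]:
    summaries = []
    for i in range(n_seeds):
        for name in TABLE2_PANEL:
            table = bs.simulate_replicates(name, n_reps, name, seed=base_seed + i)
            results = [
                rs.mmr_ratio(row.mlh1_net, row.msh2_net, sample_id=name)
                for row in table.itertuples(index=False)
            ]
            summaries.append(rs.summarize_replicates(results))
    return summaries


def table2_panel_experiment(n_seeds: int = 100, n_reps: int = 6, base_seed: int = 0) -> dict:
    """Round-trip reproducibility panel (SW480 + 4 WBC controls) pooled
    over all replicate ratios."""
    summaries = _panel_summaries(n_seeds, n_reps, base_seed)
    pooled = rs.pool_overall(summaries)
    return {
        "n_replicates": pooled.n_total,
        "pooled_mean": pooled.mean_ratio,
        "pooled_sde": pooled.sde_ratio,
    }


def noncarrier_experiment(n_subjects: int = 200, seed: int = 0) -> dict:
    """Simulated normal controls: non-carrier samples with the default
    WBC-control noise preset, quantified through the full round trip."""
    table = bs.simulate_replicates("controls", n_subjects, "table2-wbc", seed=seed)
    defined = table.loc[table["defined"], "ratio"]
    return {
        "n_subjects": n_subjects,
        "n_defined": int(len(defined)),
        "mean_ratio": float(defined.mean()),
        "sde_ratio": float(defined.std(ddof=1)),
    }


def bimodality_null_experiment(n_sims: int = 200, n: int = 100, seed: int = 0) -> dict:
    """Type-I control: verdict rate on unimodal N(0.97, 0.02^2) samples."""
    not_bimodal = 0
    for s in range(n_sims):
        rng = np.random.default_rng(seed + s)
        verdict, _ = ca.bimodality_verdict(rng.normal(0.97, 0.02, n), seed=seed + s)
        not_bimodal += (not verdict)
    return {"n_sims": n_sims, "not_bimodal_rate": not_bimodal / n_sims}


def bimodality_power_experiment(n_sims: int = 200, seed: int = 0) -> dict:
    """Power: verdict rate on figure3-preset cohort target ratios."""
    base = get_cohort_config("figure3")
    bimodal = 0
    for s in range(n_sims):
        _, truth = bs.simulate_cohort(replace(base, seed=seed + s))
        verdict, _ = ca.bimodality_verdict(
            truth["true_target_ratio"].to_numpy(), seed=seed + s
        )
        bimodal += verdict
    return {"n_sims": n_sims, "bimodal_rate": bimodal / n_sims}
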