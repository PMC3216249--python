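"""Cohort-level analysis of the ratio distribution.

Fits one- and two-component Gaussian mixtures to a cohort's MMR ratios
by expectation-maximisation, decides bimodality by BIC plus a
mode-separation rule, assigns each subject to a mode by posterior
probability, and reports the lower-mode proportion (the putative
carrier subpopulation).

Components are always reported sorted by mean descending, so component
0 is the upper (near-1) mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "MixtureFit",
    "CohortReport",
    "histogram",
    "fit_mixture",
    "bic",
    "bimodality_verdict",
    "assign_and_report",
    "plot_cohort",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class MixtureFit:
    """Gaussian mixture parameters on the ratio scale.

    means/sds/weights are index-aligned, sorted by mean descending.
    ``loglik_trace`` holds the EM log-likelihood path of the winning
    start (non-decreasing by construction).
    """

    k: int
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    loglik: float
    converged: bool
    n_obs: int
    n_iter: int = 0
    loglik_trace: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.k not in (1, 2):
            raise ValueError("k must be 1 or 2")
        if not (len(self.means) == len(self.sds) == len(self.weights) == self.k):
            raise ValueError("parameter lengths must equal k")
        if abs(sum(self.weights) - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("sds must be positive")
        if list(self.means) != sorted(self.means, reverse=True):
            raise ValueError("means must be sorted descending")

    @property
    def separation(self) -> float:
        return self.means[0] - self.means[-1]


def histogram(ratios: Sequence[float], bin_width: float = 0.05) -> pd.DataFrame:
    """Right-closed histogram bins covering (0, 1].

    Bin i is ``(i*w, (i+1)*w]``; counts sum to the number of defined
    (finite) ratios. Empty input gives an empty table.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = np.asarray([r for r in ratios if np.isfinite(r)], dtype=np.float64)
    if len(vals) == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    n_bins = int(math.ceil(1.0 / bin_width - 1e-12))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    # right-closed: value v lands in bin ceil(v/w) - 1
    idx = np.ceil(vals / bin_width - 1e-12).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def _log_density(x: np.ndarray, means, sds, weights) -> np.ndarray:
    """Per-observation log mixture density, shape (n, k) before reduction."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return np.log(weights)[None, :] - np.log(sds)[None, :] - 0.5 * (_LOG_2PI + z * z)


def _em_multistart(
    x: np.ndarray,
    means: np.ndarray,  # (S, k)
    sds: np.ndarray,
    weights: np.ndarray,
    sd_floor: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run EM for all starts simultaneously (vectorised over starts).

    Starts that have converged keep iterating harmlessly (EM ascent is
    monotone at a fixed point); their convergence iteration is
    recorded. Returns per-start parameters, log-likelihoods,
    convergence flags/iterations and the (iter, start) trace matrix.
    """
    n = len(x)
    S = means.shape[0]
    prev = np.full(S, -np.inf)
    conv_iter = np.zeros(S, dtype=int)
    converged = np.zeros(S, dtype=bool)
    traces = np.empty((0, S))
    rows = []
    loglik = prev
    for it in range(1, max_iter + 1):
        z = (x[None, :, None] - means[:, None, :]) / sds[:, None, :]
        log_comp = (
            np.log(weights)[:, None, :]
            - np.log(sds)[:, None, :]
            - 0.5 * (_LOG_2PI + z * z)
        )
        m = log_comp.max(axis=2)
        log_norm = m + np.log(np.exp(log_comp - m[:, :, None]).sum(axis=2))
        loglik = log_norm.sum(axis=1)
        rows.append(loglik.copy())
        if np.any(loglik + 1e-9 < prev):  # ascent guarantee; numerical guard
            raise RuntimeError("EM log-likelihood decreased")
        newly = (~converged) & (np.abs(loglik - prev) < tol)
        conv_iter[newly] = it
        converged |= newly
        if converged.all():
            break
        prev = loglik
        resp = np.exp(log_comp - log_norm[:, :, None])
        nk = np.maximum(resp.sum(axis=1), 1e-12)
        weights = nk / n
        means = (resp * x[None, :, None]).sum(axis=1) / nk
        var = (resp * (x[None, :, None] - means[:, None, :]) ** 2).sum(axis=1) / nk
        sds = np.maximum(np.sqrt(var), sd_floor)
    conv_iter[~converged] = max_iter
    traces = np.vstack(rows)
    return means, sds, weights, loglik, converged, conv_iter, traces


def fit_mixture(
    ratios: Sequence[float],
    k: int,
    seed: int = 0,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    sd_floor: float = 1e-3,
) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture on the ratio scale.

    Runs multi-start EM (quantile-based split plus random starts) and
    keeps the best log-likelihood. The SD floor prevents degenerate
    spikes. k=1 is the closed-form sample mean and ML (n-denominator)
    standard deviation.
    """
    x = np.asarray([r for r in ratios if np.isfinite(r)], dtype=np.float64)
    n = len(x)
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} observations for k={k}, got {n}")

    if k == 1:
        mean = float(x.mean())
        sd = max(float(x.std(ddof=0)), sd_floor)
        ll = float(
            logsumexp(
                _log_density(x, np.array([mean]), np.array([sd]), np.array([1.0])), axis=1
            ).sum()
        )
        return MixtureFit(
            k=1, means=(mean,), sds=(sd,), weights=(1.0,),
            loglik=ll, converged=True, n_obs=n, n_iter=0, loglik_trace=(ll,),
        )

    rng = np.random.default_rng(seed)
    overall_sd = max(float(x.std(ddof=0)), sd_floor)
    starts: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    # quantile-based: split at the median, each half supplies a component
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if len(lo) and len(hi):
        starts.append(
            (
                np.array([lo.mean(), hi.mean()]),
                np.maximum(np.array([lo.std(ddof=0), hi.std(ddof=0)]), sd_floor),
                np.array([0.5, 0.5]),
            )
        )
    # spread quantiles
    q = np.quantile(x, [0.25, 0.75])
    starts.append((q.copy(), np.full(2, overall_sd), np.array([0.5, 0.5])))
    while len(starts) < n_starts:
        mu = rng.choice(x, size=2, replace=len(x) < 2)
        starts.append((mu.astype(float), np.full(2, overall_sd), np.array([0.5, 0.5])))

    mu0 = np.stack([s[0] for s in starts])
    sd0 = np.stack([s[1] for s in starts])
    w0 = np.stack([s[2] for s in starts])
    degenerate = np.abs(mu0[:, 0] - mu0[:, 1]) < 1e-12
    mu0[degenerate] += np.array([-1e-6, 1e-6])
    means, sds, weights, lls, conv, conv_iter, traces = _em_multistart(
        x, mu0, sd0, w0, sd_floor, tol, max_iter
    )
    best = int(np.argmax(lls))
    order = np.argsort(-means[best])
    n_iter = int(conv_iter[best])
    return MixtureFit(
        k=2,
        means=tuple(float(v) for v in means[best][order]),
        sds=tuple(float(v) for v in sds[best][order]),
        weights=tuple(float(v) for v in weights[best][order]),
        loglik=float(lls[best]),
        converged=bool(conv[best]),
        n_obs=n,
        n_iter=n_iter,
        loglik_trace=tuple(float(v) for v in traces[:n_iter, best]),
    )


def bic(fit: MixtureFit) -> float:
    """Bayesian information criterion; k-component mixture has 3k-1
    free parameters."""
    p = 3 * fit.k - 1
    return -2.0 * fit.loglik + p * math.log(fit.n_obs)


def bimodality_verdict(
    ratios: Sequence[float],
    seed: int = 0,
    tol_sep: float = 0.05,
    sep_mult: float = 1.0,
    bic_margin: float = 2.0,
) -> tuple[bool, dict]:
    """Decide whether the ratio distribution is bimodal.

    Bimodal iff BIC(k=2) < BIC(k=1) - bic_margin AND the fitted modes
    are separated by more than
    ``max(tol_sep, 2 * sd_upper * sep_mult)``, where sd_upper is the
    SD of the upper (larger-mean) component. The separation guard
    blocks spurious two-component splits of a single mode. Evidence
    records both fits and the BIC difference.
    """
    fit1 = fit_mixture(ratios, k=1, seed=seed)
    fit2 = fit_mixture(ratios, k=2, seed=seed)
    bic1, bic2 = bic(fit1), bic(fit2)
    sep = fit2.separation
    threshold = max(tol_sep, 2.0 * fit2.sds[0] * sep_mult)
    bimodal = (bic2 < bic1 - bic_margin) and (sep > threshold)
    evidence = {
        "fit_k1": fit1,
        "fit_k2": fit2,
        "bic_k1": bic1,
        "bic_k2": bic2,
        "delta_bic": bic2 - bic1,
        "separation": sep,
        "separation_threshold": threshold,
    }
    return bool(bimodal), evidence


@dataclass(frozen=True)
class CohortReport:
    """Mixture fit, bimodality verdict and per-subject screening calls.

    ``assignments`` has columns subject_id, ratio, posterior_lower,
    assigned_mode, screen_positive. When the cohort is not bimodal all
    subjects screen negative and the lower-mode proportion is 0.
    """

    fit: MixtureFit
    bimodal: bool
    lower_mode_proportion: float
    assignments: pd.DataFrame = field(repr=False, default=None)


def assign_and_report(
    subject_ids: Sequence[str],
    ratios: Sequence[float],
    fit: MixtureFit,
    bimodal: bool = True,
) -> CohortReport:
    """Assign each subject to a mixture mode and summarise the screen.

    Assignment goes to the component with the higher posterior; an
    exact posterior tie goes to the lower mode (conservative: a
    borderline subject proceeds to genetic testing). screen_positive
    means assigned to the lower mode.
    """
    if len(subject_ids) != len(ratios):
        raise ValueError("subject_ids and ratios differ in length")
    x = np.asarray(ratios, dtype=np.float64)
    if bimodal and fit.k == 2:
        means = np.asarray(fit.means)
        sds = np.asarray(fit.sds)
        weights = np.asarray(fit.weights)
        log_comp = _log_density(x, means, sds, weights)
        post = np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])
        posterior_lower = post[:, 1]  # component 1 = lower mode (means sorted desc)
        screen_positive = posterior_lower >= 0.5 - 1e-9  # tie -> lower mode
    else:
        posterior_lower = np.full(len(x), np.nan)
        screen_positive = np.zeros(len(x), dtype=bool)
    assignments = pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "ratio": x,
            "posterior_lower": posterior_lower,
            "assigned_mode": np.where(screen_positive, "lower", "upper"),
            "screen_positive": screen_positive,
        }
    )
    prop = float(screen_positive.mean()) if len(x) else 0.0
    return CohortReport(
        fit=fit,
        bimodal=bool(bimodal and fit.k == 2),
        lower_mode_proportion=prop,
        assignments=assignments,
    )


def plot_cohort(
    report: CohortReport, path, bin_width: float = 0.05
) -> None:
    """Save a two-panel figure: per-subject ratio scatter (colored by
    assigned mode) and the pooled histogram with the fitted mixture
    density overlaid. Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    a = report.assignments
    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
    for mode, marker in [("upper", "D"), ("lower", "+")]:
        sel = a[a["assigned_mode"] == mode]
        ax0.scatter(range(len(sel)), sorted(sel["ratio"]), marker=marker, label=f"{mode} mode")
    ax0.set_xlabel("subject (sorted within mode)")
    ax0.set_ylabel("MMR ratio")
    ax0.set_ylim(0, 1.05)
    ax0.legend()

    h = histogram(a["ratio"], bin_width=bin_width)
    ax1.bar(h["bin_left"], h["count"], width=bin_width, align="edge",
            color="lightgray", edgecolor="black")
    fit = report.fit
    x = np.linspace(0, 1.05, 400)
    dens = sum(
        w * norm.pdf(x, m, s) for m, s, w in zip(fit.means, fit.sds, fit.weights)
    )
    ax1.plot(x, dens * len(a) * bin_width, color="C3")
    ax1.set_xlabel("MMR ratio")
    ax1.set_ylabel("count")
    fig.suptitle(
        f"bimodal={report.bimodal}, lower-mode proportion="
        f"{report.lower_mode_proportion:.0%}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
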