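"""Posterior summaries of the covariance chain.

Turns stored (G0, P0, R0) samples into the genetic parameters of interest
-- per-trait heritability h2 = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e)
and pairwise genetic / environmental / phenotypic correlations -- and
summarises each as posterior mean, SD, 95% equal-tail and highest-posterior
-density intervals, and the Monte Carlo standard error of the mean.

"Environmental" correlation is a convention, not a model quantity: by
default it is computed from the pooled non-genetic covariance (P0 + R0);
``env_mode="residual"`` switches to R0 alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import SampleStore
from .model import TRAITS

log = logging.getLogger(__name__)

_PAIRS = [(i, j) for i in range(len(TRAITS)) for j in range(i + 1, len(TRAITS))]


def parameter_names(env_mode: str = "pooled") -> list[str]:
    """All derived-parameter names, in report order."""
    names = [f"h2_{t}" for t in TRAITS]
    for prefix in ("rg", "re", "rp"):
        names += [f"{prefix}_{TRAITS[i]}_{TRAITS[j]}" for i, j in _PAIRS]
    return names


def derived_parameter_samples(
    store: SampleStore,
    definitions: list[str] | None = None,
    env_mode: str = "pooled",
) -> pd.DataFrame:
    """Per-sample heritabilities and correlations.

    Samples in which any trait has a nonpositive total, genetic or
    environmental variance are excluded (counted in ``df.attrs['n_excluded']``
    and logged).  ``definitions`` restricts the columns; default all.
    """
    if env_mode not in ("pooled", "residual"):
        raise ValueError("env_mode must be 'pooled' or 'residual'")
    if len(store) == 0:
        raise ValueError("empty sample store")
    valid = parameter_names(env_mode)
    definitions = definitions or valid
    unknown = [d for d in definitions if d not in valid]
    if unknown:
        raise ValueError(f"unknown parameter(s) {unknown}; valid: {valid}")

    rows = []
    kept_cycles = []
    n_excluded = 0
    for k in range(len(store)):
        G, P, R = store.matrices(k)
        E = P + R if env_mode == "pooled" else R
        T = G + P + R
        if min(np.diag(G).min(), np.diag(E).min(), np.diag(T).min()) <= 0:
            n_excluded += 1
            continue
        row = {}
        for t_i, t in enumerate(TRAITS):
            row[f"h2_{t}"] = G[t_i, t_i] / T[t_i, t_i]
        for i, j in _PAIRS:
            pair = f"{TRAITS[i]}_{TRAITS[j]}"
            row[f"rg_{pair}"] = G[i, j] / np.sqrt(G[i, i] * G[j, j])
            row[f"re_{pair}"] = E[i, j] / np.sqrt(E[i, i] * E[j, j])
            row[f"rp_{pair}"] = T[i, j] / np.sqrt(T[i, i] * T[j, j])
        rows.append(row)
        kept_cycles.append(store.cycles[k])
    if n_excluded:
        log.warning("excluded %d sample(s) with nonpositive variances", n_excluded)
    df = pd.DataFrame(rows, columns=parameter_names(env_mode))[definitions]
    df.insert(0, "cycle", kept_cycles)
    df.attrs["n_excluded"] = n_excluded
    return df


@dataclass
class PosteriorSummary:
    """Location and spread of one scalar parameter's posterior sample."""

    name: str
    mean: float
    sd: float
    equal_tail_95: tuple[float, float]
    hpd_95: tuple[float, float]
    mcse: float


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m])


def batch_means_mcse(samples: np.ndarray) -> float:
    """Monte Carlo SE of the mean by batch means with floor(sqrt(n)) batches."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    n_batches = int(np.floor(np.sqrt(n)))
    if n_batches < 2:
        return float("nan")
    size = n // n_batches
    means = x[: n_batches * size].reshape(n_batches, size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def summarize(samples, name: str = "") -> PosteriorSummary:
    """Posterior mean, SD, 95% equal-tail and HPD intervals, and MCSE."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to summarise")
    lo, hi = np.percentile(x, [2.5, 97.5])
    return PosteriorSummary(
        name=name,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        equal_tail_95=(float(lo), float(hi)),
        hpd_95=hpd_interval(x),
        mcse=batch_means_mcse(x),
    )


def summarize_store(store: SampleStore, env_mode: str = "pooled") -> pd.DataFrame:
    """Summary table over variance components and derived parameters.

    One row per parameter: posterior mean, SD, interval bounds, MCSE, and
    for correlations a flag recording whether the 95% HPD interval excludes
    zero (the usual significance convention).
    """
    derived = derived_parameter_samples(store, env_mode=env_mode)
    blocks = {name: store.samples[:, k] for k, name in enumerate(store.names)}
    blocks.update(
        {c: derived[c].to_numpy() for c in derived.columns if c != "cycle"}
    )
    rows = []
    for name, x in blocks.items():
        s = summarize(x, name)
        excl = ""
        if name.startswith(("rg_", "re_", "rp_")):
            excl = bool(s.hpd_95[0] > 0 or s.hpd_95[1] < 0)
        rows.append(
            {
                "parameter": name,
                "mean": s.mean,
                "sd": s.sd,
                "et_lo": s.equal_tail_95[0],
                "et_hi": s.equal_tail_95[1],
                "hpd_lo": s.hpd_95[0],
                "hpd_hi": s.hpd_95[1],
                "mcse": s.mcse,
                "excludes_zero": excl,
            }
        )
    return pd.DataFrame(rows)


def export_traces(
    store: SampleStore,
    which: list[str] | None = None,
    env_mode: str = "pooled",
    density_points: int = 256,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready trace and kernel-density tables for derived parameters.

    Returns ``(trace, density)``: the trace has one row per stored sample
    (columns: cycle + parameters), the density a Gaussian-KDE table
    (parameter, x, density) normalised so each curve integrates to one.
    """
    from scipy.stats import gaussian_kde

    which = which or parameter_names(env_mode)
    valid = parameter_names(env_mode)
    unknown = [w for w in which if w not in valid]
    if unknown:
        raise ValueError(f"unknown parameter(s) {unknown}; valid: {valid}")
    derived = derived_parameter_samples(store, definitions=which, env_mode=env_mode)
    dens_rows = []
    for name in which:
        x = derived[name].to_numpy()
        if np.ptp(x) == 0:  # degenerate: point mass
            continue
        kde = gaussian_kde(x)
        grid = np.linspace(x.min() - 3 * kde.factor * x.std(), x.max() + 3 * kde.factor * x.std(), density_points)
        d = kde(grid)
        d /= np.trapezoid(d, grid)
        for g, v in zip(grid, d):
            dens_rows.append({"parameter": name, "x": g, "density": v})
    return derived, pd.DataFrame(dens_rows, columns=["parameter", "x", "density"])


def geweke_z(samples, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain means.

    Offered as an optional diagnostic; trace inspection remains the primary
    convergence check.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    a = x[: int(first * n)]
    b = x[int((1 - last) * n):]
    va = batch_means_mcse(a) ** 2
    vb = batch_means_mcse(b) ** 2
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))
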