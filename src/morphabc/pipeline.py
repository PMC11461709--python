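"""Posterior summaries, predictive checking and data utilities."""

from __future__ import annotations

import math

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .growth import ModelParams, default_init, simulate_dataset
from .morphometrics import QOI_COLUMNS, dataset_qois
from .smc import ParticleEnsemble

__all__ = [
    "weighted_kde",
    "map_estimate",
    "PosteriorSummary",
    "posterior_summary",
    "predictive_check",
    "pair_neurons",
    "generate_fixture",
    "marginal_normality_check",
]


def _silverman_bandwidth(samples: np.ndarray, weights: np.ndarray) -> float:
    """Silverman's rule on the weighted sample (effective sample size)."""
    w = weights / weights.sum()
    mean = np.sum(w * samples)
    var = np.sum(w * (samples - mean) ** 2)
    neff = 1.0 / np.sum(w**2)
    bw = math.sqrt(max(var, 0.0)) * (4.0 / (3.0 * neff)) ** 0.2
    if bw <= 0.0:
        # single distinct sample: fall back to a scale-aware default
        bw = max(abs(mean) * 1e-3, 1e-6)
    return bw


def weighted_kde(samples, weights, grid) -> np.ndarray:
    """Weighted Gaussian KDE evaluated on ``grid`` (Silverman bandwidth)."""
    samples = np.asarray(samples, float).ravel()
    weights = np.asarray(weights, float).ravel()
    grid = np.asarray(grid, float).ravel()
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    w = weights / weights.sum()
    bw = _silverman_bandwidth(samples, w)
    z = (grid[:, None] - samples[None, :]) / bw
    dens = np.exp(-0.5 * z**2) @ w / (bw * math.sqrt(2.0 * math.pi))
    return dens


def _marginal_grid(samples: np.ndarray, weights: np.ndarray, n: int = 512):
    bw = _silverman_bandwidth(samples, weights / weights.sum())
    lo = samples.min() - 3.0 * bw
    hi = samples.max() + 3.0 * bw
    return np.linspace(lo, hi, n)


def map_estimate(ensemble: ParticleEnsemble, n_grid: int = 512) -> np.ndarray:
    """Marginal MAP: per-coordinate argmax of the weighted-KDE marginal.

    Ties break toward the smaller value (first maximum on the ascending
    grid).
    """
    thetas = ensemble.thetas
    out = np.empty(thetas.shape[1])
    for j in range(thetas.shape[1]):
        grid = _marginal_grid(thetas[:, j], ensemble.weights, n_grid)
        dens = weighted_kde(thetas[:, j], ensemble.weights, grid)
        # near-ties (within float tolerance of the maximum) break low
        peaks = np.flatnonzero(dens >= dens.max() * (1.0 - 1e-9))
        out[j] = grid[peaks[0]]
    return out


@dataclass
class PosteriorSummary:
    """Weighted-KDE marginals on per-parameter grids plus the MAP point."""

    names: tuple[str, ...]
    grids: list[np.ndarray]
    densities: list[np.ndarray]
    map_point: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "map": self.map_point,
                "mean": self.mean,
                "sd": self.sd,
            }
        )


def posterior_summary(ensemble: ParticleEnsemble, n_grid: int = 512) -> PosteriorSummary:
    w = ensemble.weights / ensemble.weights.sum()
    grids, densities = [], []
    for j in range(ensemble.thetas.shape[1]):
        x = ensemble.thetas[:, j]
        grid = _marginal_grid(x, w, n_grid)
        grids.append(grid)
        densities.append(weighted_kde(x, w, grid))
    mean = ensemble.thetas.T @ w
    sd = np.sqrt(np.maximum((ensemble.thetas.T**2) @ w - mean**2, 0.0))
    names = ensemble.names or tuple(
        f"theta_{i}" for i in range(ensemble.thetas.shape[1])
    )
    return PosteriorSummary(
        names=tuple(names),
        grids=grids,
        densities=densities,
        map_point=map_estimate(ensemble, n_grid),
        mean=mean,
        sd=sd,
    )


def predictive_check(
    ensemble: ParticleEnsemble,
    simulator,
    y_obs_qois,
    n_draws: int = 100,
    m_prime: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Posterior predictive comparison of QoI marginals.

    Draws ``n_draws`` parameters from the weighted ensemble, simulates
    ``m_prime`` neurons each, and returns (summary table with one row per
    QoI, pooled simulated QoI matrix).  The table lists mean, sd and
    quantiles of the data and the predictive marginals.
    """
    y_obs = np.asarray(y_obs_qois, float)
    rng = np.random.default_rng(seed)
    w = ensemble.weights / ensemble.weights.sum()
    idx = rng.choice(ensemble.thetas.shape[0], size=n_draws, p=w)
    sims = [
        np.asarray(simulator(ensemble.thetas[i], m_prime, int(rng.integers(2**32))))
        for i in idx
    ]
    y_sim = np.vstack(sims)
    cols = QOI_COLUMNS if y_obs.shape[1] == 4 else [
        f"qoi_{j}" for j in range(y_obs.shape[1])
    ]
    rows = []
    for j, col in enumerate(cols):
        d, s = y_obs[:, j], y_sim[:, j]
        rows.append(
            {
                "qoi": col,
                "data_mean": d.mean(),
                "data_sd": d.std(ddof=0),
                "data_q05": np.quantile(d, 0.05),
                "data_q95": np.quantile(d, 0.95),
                "sim_mean": s.mean(),
                "sim_sd": s.std(ddof=0),
                "sim_q05": np.quantile(s, 0.05),
                "sim_q95": np.quantile(s, 0.95),
            }
        )
    return pd.DataFrame(rows), y_sim


def pair_neurons(data_qois, sim_qois) -> pd.DataFrame:
    """Assign the nearest simulated neuron to each data neuron.

    Columns are normalised by the data marginals' standard deviation before
    the Euclidean nearest-neighbour search (with replacement).
    """
    data = np.asarray(data_qois, float)
    sim = np.asarray(sim_qois, float)
    if data.ndim != 2 or sim.ndim != 2 or data.shape[1] != sim.shape[1]:
        raise ValueError("QoI matrices must be 2-D with matching columns")
    if data.size == 0 or sim.size == 0:
        raise ValueError("QoI matrices must be non-empty")
    scale = data.std(axis=0)
    if np.any(scale <= 0):
        raise ValueError("zero-variance data column")
    dn = data / scale
    sn = sim / scale
    d2 = ((dn[:, None, :] - sn[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    return pd.DataFrame(
        {
            "data_index": np.arange(data.shape[0]),
            "sim_index": idx,
            "distance": np.sqrt(d2[np.arange(data.shape[0]), idx]),
        }
    )


def generate_fixture(
    model_id: int,
    params: ModelParams | None,
    m: int,
    seed: int,
    out_dir,
    selection: str = "all",
) -> pd.DataFrame:
    """Simulate ``m`` neurons, write SWC files plus ``qois.csv``.

    This is the synthetic-data generator standing in for observed datasets;
    fully reproducible from ``seed``.
    """
    from .swc import write_swc

    if params is None:
        params = ModelParams(model_id=model_id)
    elif params.model_id != model_id:
        raise ValueError("params.model_id does not match model_id")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trees = simulate_dataset(params, m=m, seed=seed)
    labels = []
    for k, tree in enumerate(trees):
        name = f"neuron_{k:04d}.swc"
        write_swc(tree, out / name)
        labels.append(name)
    qois = dataset_qois(trees, selection=selection, labels=labels)
    qois.to_csv(out / "qois.csv", index_label="neuron")
    return qois


def marginal_normality_check(qoi_matrix, level: float = 1.0) -> pd.DataFrame:
    """Anderson-Darling test of normality per QoI column.

    The null is the normal family with estimated location and scale.
    Returns, per column, the test statistic, its p-value, the rejection
    decision at ``level`` (percent) and the smallest significance level (%)
    at which the column still rejects; raises on constant columns.
    """
    x = (
        qoi_matrix.to_numpy(float)
        if isinstance(qoi_matrix, pd.DataFrame)
        else np.asarray(qoi_matrix, float)
    )
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 8:
        raise ValueError("need at least 8 rows")
    cols = (
        list(qoi_matrix.columns)
        if isinstance(qoi_matrix, pd.DataFrame)
        else [f"qoi_{j}" for j in range(x.shape[1])]
    )
    rows = []
    for j, col in enumerate(cols):
        v = x[:, j]
        if v.std() <= 0:
            raise ValueError(f"constant column {col!r}")
        try:
            res = stats.anderson(v, dist="norm", method="interpolate")
            pvalue = float(res.pvalue)
        except TypeError:  # older scipy without the method argument
            res = stats.anderson(v, dist="norm")
            levels = np.asarray(res.significance_level, float) / 100.0
            crits = np.asarray(res.critical_values, float)
            below = levels[res.statistic > crits]
            pvalue = float(below.min()) if below.size else float(levels.max())
        rows.append(
            {
                "qoi": col,
                "statistic": float(res.statistic),
                "pvalue": pvalue,
                "reject": bool(pvalue <= level / 100.0),
                "min_reject_level_pct": 100.0 * pvalue,
            }
        )
    return pd.DataFrame(rows)
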