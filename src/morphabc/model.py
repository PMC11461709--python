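"""Model/Results interface for likelihood-free calibration.

:class:`GrowthCalibration` couples an observed morphometric dataset to a
stochastic neuron growth simulator and a statistical distance;
:meth:`GrowthCalibration.fit` runs adaptive SMC-ABC and returns a
:class:`CalibrationResult` carrying the weighted particle ensemble, the
tolerance trace and posterior summaries.

Example
-------
>>> from morphabc import GrowthCalibration, ModelParams
>>> from morphabc._fast import fast_qoi_dataset
>>> y_obs = fast_qoi_dataset(ModelParams(model_id=2, n_steps=200), m=500, seed=7)
>>> model = GrowthCalibration(y_obs, model_id=2, n_steps=200)
>>> res = model.fit(seed=1)          # doctest: +SKIP
>>> print(res.summary())             # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from ._fast import make_qoi_simulator
from .growth import ModelParams
from .distances import make_distance
from .morphometrics import QOI_COLUMNS
from .pipeline import PosteriorSummary, posterior_summary, predictive_check
from .smc import Prior, SMCConfig, run_smcabc
from .sobol import DEFAULT_BOUNDS

__all__ = ["GrowthCalibration", "CalibrationResult"]


class GrowthCalibration:
    """Calibrate a resource-driven growth model against observed QoIs.

    Parameters
    ----------
    y_obs_qois
        Observed QoI matrix (n_neurons, 4): segment count, mean/std segment
        length, total dendritic length.  DataFrame or array.
    model_id
        1 (symmetric bifurcation, basal) or 2 (side-branching, apical).
    bounds
        Uniform prior box per free parameter; defaults to the standard
        domain over (p_bra, R, v).
    distance
        ``"wasserstein" | "sliced" | "kl" | "gamma"``.
    config
        :class:`morphabc.smc.SMCConfig`; defaults to the scaled-down desk
        profile (N=256, M'=25, budget 5e5 neuron simulations).
    **param_overrides
        Fixed (non-calibrated) entries of :class:`ModelParams`, e.g.
        ``n_steps=200``.
    """

    def __init__(
        self,
        y_obs_qois,
        model_id: int = 2,
        bounds: dict | None = None,
        distance: str = "wasserstein",
        config: SMCConfig | None = None,
        standardize_qois: bool = True,
        distance_kwargs: dict | None = None,
        **param_overrides,
    ):
        self.y_obs = (
            y_obs_qois.to_numpy(float)
            if isinstance(y_obs_qois, pd.DataFrame)
            else np.asarray(y_obs_qois, float)
        )
        if self.y_obs.ndim != 2:
            raise ValueError("y_obs_qois must be 2-D (neurons x QoIs)")
        bounds = dict(bounds or DEFAULT_BOUNDS)
        self.prior = Prior.from_bounds(bounds)
        self.param_names = tuple(bounds)
        self.base_params = ModelParams(model_id=model_id, **param_overrides)
        self.simulator = make_qoi_simulator(self.base_params, self.param_names)
        self.distance_name = distance
        self.config = config or SMCConfig()
        self.distance_fn = make_distance(
            distance,
            self.y_obs,
            standardize_qois=standardize_qois,
            **(distance_kwargs or {}),
        )

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_swc_dir(cls, path, selection: str = "all", **kwargs):
        """Build from a directory of SWC reconstructions."""
        from .morphometrics import dataset_qois

        files = sorted(Path(path).glob("*.swc"))
        if not files:
            raise FileNotFoundError(f"no SWC files under {path}")
        return cls(dataset_qois(files, selection=selection), **kwargs)

    @classmethod
    def from_qois_csv(cls, path, **kwargs):
        """Build from a pre-extracted QoI table (CSV with the QoI columns)."""
        df = pd.read_csv(path)
        return cls(df[QOI_COLUMNS], **kwargs)

    # -- estimation ------------------------------------------------------
    def fit(self, seed: int | None = None, callback=None) -> "CalibrationResult":
        config = self.config
        if seed is not None:
            config = dataclasses.replace(config, seed=seed)
        ensemble, trace = run_smcabc(
            self.y_obs,
            self.simulator,
            self.prior,
            config,
            distance_fn=self.distance_fn,
            callback=callback,
        )
        return CalibrationResult(self, ensemble, trace, config)


class CalibrationResult:
    """Weighted ABC posterior with summaries and predictive checking."""

    def __init__(self, model: GrowthCalibration, ensemble, trace, config):
        self.model = model
        self.ensemble = ensemble
        self.trace = trace
        self.config = config
        self._summary: PosteriorSummary | None = None

    @property
    def posterior(self) -> PosteriorSummary:
        if self._summary is None:
            self._summary = posterior_summary(self.ensemble)
        return self._summary

    @property
    def params(self) -> pd.Series:
        """Marginal MAP point (per-parameter weighted-KDE mode)."""
        return pd.Series(self.posterior.map_point, index=self.posterior.names)

    @property
    def epsilon(self) -> float:
        return float(self.trace.epsilons[-1])

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Weighted posterior quantile interval per parameter."""
        w = self.ensemble.weights / self.ensemble.weights.sum()
        rows = []
        for j, name in enumerate(self.posterior.names):
            x = self.ensemble.thetas[:, j]
            order = np.argsort(x)
            cdf = np.cumsum(w[order])
            lo = x[order][np.searchsorted(cdf, alpha / 2.0)]
            hi = x[order][min(np.searchsorted(cdf, 1.0 - alpha / 2.0), x.size - 1)]
            rows.append({"parameter": name, "lower": lo, "upper": hi})
        return pd.DataFrame(rows)

    def predictive_check(self, n_draws: int = 100, m_prime: int | None = None, seed: int = 0):
        return predictive_check(
            self.ensemble,
            self.model.simulator,
            self.model.y_obs,
            n_draws=n_draws,
            m_prime=m_prime or self.config.m_prime,
            seed=seed,
        )

    def summary(self) -> str:
        ps = self.posterior
        ci = self.conf_int()
        last = self.trace.records[-1]
        lines = [
            "            SMC-ABC Growth-Model Calibration",
            "=" * 64,
            f"Model:          resource-driven growth, model_id="
            f"{self.model.base_params.model_id}",
            f"Distance:       {self.model.distance_name}"
            f"   Observations: {self.model.y_obs.shape[0]} neurons",
            f"Particles:      {self.config.n_particles}"
            f"   M'={self.config.m_prime}   alpha={self.config.alpha}",
            f"Iterations:     {last['iteration']}"
            f"   final eps={last['epsilon']:.4g}"
            f"   simulations={last['neurons_used']}",
            "-" * 64,
            f"{'parameter':>10} {'MAP':>12} {'mean':>12} {'sd':>12} "
            f"{'[2.5%':>12} {'97.5%]':>12}",
        ]
        for j, name in enumerate(ps.names):
            lines.append(
                f"{name:>10} {ps.map_point[j]:>12.5g} {ps.mean[j]:>12.5g} "
                f"{ps.sd[j]:>12.5g} {ci['lower'][j]:>12.5g} {ci['upper'][j]:>12.5g}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_marginals(self, path=None, reference: dict | None = None):
        """Weighted-KDE posterior marginals; optionally saved to ``path``."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ps = self.posterior
        fig, axes = plt.subplots(1, len(ps.names), figsize=(4 * len(ps.names), 3))
        axes = np.atleast_1d(axes)
        for ax, name, grid, dens in zip(axes, ps.names, ps.grids, ps.densities):
            ax.plot(grid, dens)
            ax.set_xlabel(name)
            if reference and name in reference:
                ax.axvline(reference[name], color="k", ls="--")
        axes[0].set_ylabel("posterior density")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig
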