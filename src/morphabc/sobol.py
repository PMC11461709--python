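"""Global Sobol sensitivity analysis via Saltelli sampling.

The design draws a quasi-random base sample of ``n_base`` points for two
matrices A and B (Sobol' sequence) and forms the radial cross blocks
``A_B^(i)`` (A with column i replaced from B) and ``B_A^(i)``, giving
``K = n_base * (2 d + 2)`` model evaluations.  First-order indices use the
Saltelli-2010 estimator, total-effect indices the Jansen estimator; 95%
confidence intervals come from a bootstrap over the base-sample index.
The model output is the expected QoI vector, estimated by averaging
``m_replicates`` stochastic simulations per parameter point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = ["SAConfig", "SobolResult", "saltelli_sample", "expected_qois", "sobol_indices"]

DEFAULT_BOUNDS = {
    # parameter domain covering every operating point exercised in the
    # calibration studies (branching probability, resource consumption,
    # elongation speed; per-step units)
    "p_bra": (0.01, 0.10),
    "R": (2e-4, 1.4e-3),
    "v": (50.0, 150.0),
}


@dataclass
class SAConfig:
    bounds: dict = None
    n_base: int = 256
    m_replicates: int = 5
    n_bootstrap: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.bounds is None:
            self.bounds = dict(DEFAULT_BOUNDS)
        if self.m_replicates < 1:
            raise ValueError("m_replicates must be >= 1")


@dataclass
class SobolResult:
    """S1 / S_tot estimates with 95% CI half-widths per (parameter, output)."""

    s1: np.ndarray  # (d, n_outputs)
    s1_conf: np.ndarray
    s_tot: np.ndarray
    s_tot_conf: np.ndarray
    param_names: tuple[str, ...]
    output_names: tuple[str, ...]
    zero_variance: np.ndarray  # (n_outputs,) bool flag

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, out in enumerate(self.output_names):
            for i, p in enumerate(self.param_names):
                rows.append(
                    {
                        "output": out,
                        "parameter": p,
                        "S1": self.s1[i, j],
                        "S1_conf": self.s1_conf[i, j],
                        "ST": self.s_tot[i, j],
                        "ST_conf": self.s_tot_conf[i, j],
                        "zero_variance": bool(self.zero_variance[j]),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        return self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}")


def saltelli_sample(
    bounds: dict[str, tuple[float, float]], n_base: int, seed: int = 0
) -> np.ndarray:
    """Saltelli cross-sampling design: ``n_base * (2 d + 2)`` rows.

    Row layout: the A block, then the d blocks ``A_B^(i)``, then the d
    blocks ``B_A^(i)``, then the B block — each of length ``n_base``.
    """
    names = list(bounds)
    d = len(names)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    sampler = qmc.Sobol(2 * d, scramble=True, seed=seed)
    base = sampler.random(n_base)
    a = lo + (hi - lo) * base[:, :d]
    b = lo + (hi - lo) * base[:, d:]
    blocks = [a]
    for i in range(d):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    for i in range(d):
        ba = b.copy()
        ba[:, i] = a[:, i]
        blocks.append(ba)
    blocks.append(b)
    return np.vstack(blocks)


def expected_qois(
    simulator, param_matrix: np.ndarray, m_replicates: int, seed: int = 0
) -> np.ndarray:
    """Mean QoI vector per parameter row; deterministic given ``seed``.

    ``simulator(theta, m, seed) -> (m, n_qoi)`` as in the SMC module.
    """
    rows = np.asarray(param_matrix, float)
    seeds = np.random.SeedSequence(seed).generate_state(rows.shape[0])
    out = None
    for k, theta in enumerate(rows):
        q = np.asarray(simulator(theta, m_replicates, int(seeds[k])), float)
        if out is None:
            out = np.empty((rows.shape[0], q.shape[1]))
        out[k] = q.mean(axis=0)
    return out


def _indices_from_blocks(ya, yab, yb):
    """Saltelli-2010 S1 and Jansen S_tot for one output column."""
    var = np.var(np.concatenate([ya, yb]), ddof=0)
    if var <= 0:
        d = yab.shape[0]
        return np.zeros(d), np.zeros(d), True
    s1 = np.mean(yb[None, :] * (yab - ya[None, :]), axis=1) / var
    s_tot = 0.5 * np.mean((ya[None, :] - yab) ** 2, axis=1) / var
    return s1, s_tot, False


def sobol_indices(
    outputs: np.ndarray,
    d: int,
    n_bootstrap: int = 200,
    rng: np.random.Generator | int | None = 0,
    param_names: tuple[str, ...] | None = None,
    output_names: tuple[str, ...] | None = None,
) -> SobolResult:
    """Estimate S1/S_tot (with bootstrap CIs) from Saltelli block outputs.

    ``outputs`` has ``n_base * (2 d + 2)`` rows aligned with
    :func:`saltelli_sample` and one column per model output.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y = np.atleast_2d(np.asarray(outputs, float))
    if y.shape[0] % (2 * d + 2):
        raise ValueError("output rows do not match the Saltelli block structure")
    n = y.shape[0] // (2 * d + 2)
    n_out = y.shape[1]
    ya = y[:n]
    yab = np.stack([y[(1 + i) * n : (2 + i) * n] for i in range(d)])
    yb = y[-n:]

    s1 = np.empty((d, n_out))
    st = np.empty((d, n_out))
    s1c = np.zeros((d, n_out))
    stc = np.zeros((d, n_out))
    zero = np.zeros(n_out, bool)
    for j in range(n_out):
        s1[:, j], st[:, j], zero[j] = _indices_from_blocks(
            ya[:, j], yab[:, :, j], yb[:, j]
        )
        if zero[j] or n_bootstrap <= 0:
            continue
        bs1 = np.empty((n_bootstrap, d))
        bst = np.empty((n_bootstrap, d))
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            bs1[b], bst[b], _ = _indices_from_blocks(
                ya[idx, j], yab[:, idx, j], yb[idx, j]
            )
        s1c[:, j] = 1.96 * bs1.std(axis=0, ddof=1)
        stc[:, j] = 1.96 * bst.std(axis=0, ddof=1)

    pnames = param_names or tuple(f"x{i + 1}" for i in range(d))
    onames = output_names or tuple(f"y{j + 1}" for j in range(n_out))
    return SobolResult(
        s1=s1,
        s1_conf=s1c,
        s_tot=st,
        s_tot_conf=stc,
        param_names=tuple(pnames),
        output_names=tuple(onames),
        zero_variance=zero,
    )
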