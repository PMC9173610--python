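"""Convergence diagnostics: Gelman–Rubin R̂ and the Geweke z-score.

R̂ compares between- and within-chain variance of parallel chains; values
near 1 indicate the chains explore the same distribution.  The Geweke
statistic compares the mean of an early segment of a single chain with
the mean of a late segment, using spectral-density-at-zero standard
errors so that autocorrelation is accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Conventional convergence thresholds used for verdicts.
RHAT_LIMIT = 1.1
GEWEKE_LIMIT = 2.0


@dataclass(frozen=True)
class ChainSet:
    """Equal-length draws of one parameter from ≥ 2 parallel chains."""

    name: str
    draws: np.ndarray  # (chains, n)

    def __post_init__(self) -> None:
        arr = np.asarray(self.draws, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("draws must be (chains ≥ 2, n)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("draws must be finite")
        object.__setattr__(self, "draws", arr)


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor R̂.

    R̂ = √(((n−1)/n·W + B/n)/W) with W the mean within-chain variance and
    B = n · Var(chain means).  When the chains agree exactly (B = 0) the
    estimator equals √((n−1)/n), approaching 1 from below as n grows.
    """
    arr = chains.draws if isinstance(chains, ChainSet) else np.asarray(chains, float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need ≥ 2 chains")
    m, n = arr.shape
    if n < 10:
        raise ValueError("chains too short for R̂ (need length ≥ 10)")
    W = arr.var(axis=1, ddof=1).mean()
    B = n * arr.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0  # degenerate constant chains
    v_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(v_hat / W))


def _spectral_density_zero(x: np.ndarray) -> float:
    """S(0) via a Bartlett-windowed autocovariance sum, window √n."""
    n = len(x)
    xc = x - x.mean()
    K = int(np.sqrt(n))
    # biased autocovariances (divide by n), standard for spectral estimates
    gamma = np.array([np.dot(xc[: n - k], xc[k:]) / n for k in range(K + 1)])
    weights = 1.0 - np.arange(1, K + 1) / (K + 1)
    s0 = gamma[0] + 2.0 * np.sum(weights * gamma[1:])
    return float(max(s0, 0.0))


def geweke(chain, frac_a: float = 0.1, frac_b: float = 0.5) -> float:
    """z-score comparing the first ``frac_a`` and last ``frac_b`` of a chain."""
    x = np.asarray(chain, dtype=float).ravel()
    if len(x) < 100:
        raise ValueError("chain too short for Geweke (need length ≥ 100)")
    na = max(int(frac_a * len(x)), 10)
    nb = max(int(frac_b * len(x)), 10)
    a, b = x[:na], x[-nb:]
    var_a = _spectral_density_zero(a) / na
    var_b = _spectral_density_zero(b) / nb
    denom = np.sqrt(var_a + var_b)
    scale = max(1.0, abs(a.mean()), abs(b.mean()))
    if denom <= 1e-12 * scale:
        return 0.0  # both segments (numerically) constant: no drift signal
    return float((a.mean() - b.mean()) / denom)


def diagnose(
    parameters: dict[str, np.ndarray], model: str = "model"
) -> pd.DataFrame:
    """Diagnostic report for named parameters, each (chains × n) draws.

    Geweke is computed per chain and the largest |z| reported.  Verdict is
    "ok" when R̂ < 1.1 and max |z| < 2.
    """
    rows = []
    for name, arr in parameters.items():
        arr = np.asarray(arr, dtype=float)
        rhat = gelman_rubin(arr)
        if arr.shape[1] >= 100:
            z = max(abs(geweke(c)) for c in arr)
        else:
            z = np.nan  # chains too short for a stable spectral estimate
        verdict = "ok" if (rhat < RHAT_LIMIT
                           and not z >= GEWEKE_LIMIT) else "check"
        rows.append({"model": model, "parameter": name, "rhat": rhat,
                     "geweke_z": z, "verdict": verdict})
    return pd.DataFrame(rows, columns=["model", "parameter", "rhat",
                                       "geweke_z", "verdict"])
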