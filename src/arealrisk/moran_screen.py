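"""Global spatial autocorrelation screen with a Poisson parametric bootstrap.

Moran's I on the SIR surface is used as a cheap screen deciding which
outcomes warrant the expensive hierarchical smoothing step.  Because the
asymptotic normal null of Moran's I is unreliable for rate data with
heterogeneous denominators, the null distribution is built by a
parametric bootstrap: observed counts are re-drawn independently as
Poisson(E_i) and the statistic recomputed, which conditions the test on
the population structure.  One-tailed (positive autocorrelation) only;
Bonferroni control across the family of screened outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp


def morans_i(
    values: np.ndarray,
    weights: sp.spmatrix,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Moran's I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2.

    ``mask`` selects the areas entering the statistic (True = keep);
    masked areas contribute neither to the centring nor to the sums.
    Raises when fewer than 3 areas remain or the values are constant.
    """
    x = np.asarray(values, dtype=float)
    w = sp.csr_matrix(weights)
    if w.shape[0] != w.shape[1] or w.shape[0] != x.size:
        raise ValueError("weights must be square and conform to the value vector")
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)
        x = x[keep]
        w = w[keep][:, keep]
    n = x.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 areas")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I undefined: all values identical")
    s0 = float(w.sum())
    if s0 == 0.0:
        raise ValueError("weight matrix has no non-zero entries")
    num = float(z @ (w @ z))
    return (n / s0) * num / denom


@dataclass
class MoranResult:
    statistic: float
    b: int
    p_value: float
    seed: int
    replicates: Optional[np.ndarray] = None

    def __repr__(self) -> str:  # replicates elided
        return f"MoranResult(I={self.statistic:.4f}, B={self.b}, p={self.p_value:.4g})"


def parametric_bootstrap_p(
    observed: np.ndarray,
    expected: np.ndarray,
    weights: sp.spmatrix,
    b: int = 999,
    seed: int = 0,
    keep_replicates: bool = False,
) -> MoranResult:
    """One-tailed bootstrap p-value for Moran's I on the SIR surface.

    The observed statistic is computed on Y/E; each replicate redraws
    Y*_i ~ Poisson(E_i) independently and recomputes I on Y*/E.  The
    add-one Monte-Carlo convention p = (1 + #{I* >= I_obs}) / (B + 1)
    guarantees p in (0, 1].  Areas with E = 0 are masked out.  A
    degenerate replicate (all simulated SIRs equal, I undefined) is
    counted as non-exceeding.
    """
    if b < 1:
        raise ValueError("bootstrap replicate count B must be >= 1")
    y = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if (e < 0).any():
        raise ValueError("expected counts must be >= 0")
    keep = e > 0
    if not keep.any():
        raise ValueError("all expected counts are zero")
    w = sp.csr_matrix(weights)[keep][:, keep]
    e = e[keep]
    i_obs = morans_i(y[keep] / e, w)

    rng = np.random.default_rng(seed)
    n = e.size
    s0 = float(w.sum())
    sims = rng.poisson(e, size=(b, n)) / e  # B x n simulated SIR surfaces
    z = sims - sims.mean(axis=1, keepdims=True)
    denom = np.einsum("bi,bi->b", z, z)
    num = np.einsum("bi,bi->b", z @ w.T, z)
    with np.errstate(invalid="ignore", divide="ignore"):
        i_star = np.where(denom > 0, (n / s0) * num / denom, -np.inf)
    p = (1.0 + int(np.sum(i_star >= i_obs))) / (b + 1.0)
    return MoranResult(
        statistic=i_obs,
        b=b,
        p_value=p,
        seed=seed,
        replicates=i_star if keep_replicates else None,
    )


def bonferroni_screen(
    results: dict[str, MoranResult], alpha: float = 0.05, m: Optional[int] = None
) -> pd.DataFrame:
    """Family-wise screen: flag outcomes with p below alpha/m AND I > 0.

    ``m`` defaults to the number of outcomes tested but may be larger
    (e.g. a pre-registered family size when only some outcomes reach
    this stage).  Negative Moran's I never flags: the screen looks for
    positive spatial aggregation only.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = len(results) if m is None else m
    if m < len(results):
        raise ValueError("family size m cannot be smaller than the number of tests")
    threshold = alpha / m
    rows = [
        {
            "site": site,
            "moran_i": r.statistic,
            "b": r.b,
            "p_value": r.p_value,
            "family_size": m,
            "threshold": threshold,
            "flagged": (r.p_value < threshold) and (r.statistic > 0),
        }
        for site, r in results.items()
    ]
    return pd.DataFrame(rows)
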