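"""Besag-York-Mollié hierarchical smoothing of small-area relative risks.

Model, for areas i = 1..n with observed counts Y_i and expected counts
E_i > 0::

    Y_i | theta_i           ~ Poisson(E_i * theta_i)
    log theta_i             = alpha + u_i + v_i
    v_i | sigma_v           ~ Normal(0, sigma_v^2)   (unstructured)
    u   | sigma_u           ~ ICAR(W, sigma_u^2)     (structured)
    alpha                   ~ flat
    1/sigma_u^2, 1/sigma_v^2 ~ Gamma(0.5, 0.0005)

The intrinsic CAR density is the pairwise-difference form
exp(-(1/2 sigma_u^2) * sum_{i~j} (u_i - u_j)^2) over first-order
contiguity edges, improper in the constant direction; identifiability is
restored by a sum-to-zero constraint (one per connected component),
re-imposed after every sweep with the removed mean absorbed into alpha.
Areas with no neighbours (islands) have u_i fixed at 0 and carry their
risk entirely in v_i.

The sampler is a Metropolis-within-Gibbs scheme: vectorized single-site
random-walk Metropolis for v and for u (the latter scheduled by a proper
graph colouring, so same-colour areas are conditionally independent and
update as one vectorized block), random-walk Metropolis for alpha, and
conjugate Gamma draws for both precisions.  Proposal scales adapt toward
44% acceptance during burn-in and are frozen afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .adjacency import Adjacency


@dataclass
class MCMCConfig:
    """Sampler settings.

    Desk-scale defaults (2 chains x 20,000 kept iterations, burn-in
    5,000, thin 10) suit simulation studies; ``replica_protocol`` returns
    the heavyweight registry-analysis protocol of 3 chains x 1,000,000
    iterations after 100,000 burn-in, saving every 200th draw.
    """

    n_chains: int = 2
    burn_in: int = 5_000
    n_iter: int = 20_000
    thin: int = 10
    seed: int = 0
    prior_shape: float = 0.5
    prior_rate: float = 0.0005
    init_dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def saved_per_chain(self) -> int:
        return self.n_iter // self.thin

    @property
    def total_saved(self) -> int:
        return self.n_chains * self.saved_per_chain

    @property
    def total_post_burnin_iterations(self) -> int:
        return self.n_chains * self.n_iter


def replica_protocol(seed: int = 0) -> MCMCConfig:
    """The full-scale MCMC protocol used for registry analyses:
    3 chains, 100,000 burn-in, 1,000,000 further iterations each,
    every 200th sample saved (15,000 saved draws in total)."""
    return MCMCConfig(n_chains=3, burn_in=100_000, n_iter=1_000_000, thin=200, seed=seed)


@dataclass
class PosteriorSamples:
    """Saved MCMC draws, shape conventions: (chains, saved) or (chains, saved, areas)."""

    area_ids: list[str]
    alpha: np.ndarray
    u: np.ndarray
    v: np.ndarray
    sigma_u: np.ndarray
    sigma_v: np.ndarray
    island_mask: np.ndarray
    acceptance: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_saved(self) -> int:
        return self.alpha.shape[1]

    @property
    def theta(self) -> np.ndarray:
        return np.exp(self.alpha[:, :, None] + self.u + self.v)

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled over chains: (chains*saved, ...)."""
        arr = getattr(self, name if name != "theta" else "theta")
        return arr.reshape(-1, *arr.shape[2:])


def _project_sum_zero(u: np.ndarray, components: list[np.ndarray]) -> float:
    """Recenter u per connected component; return the overall active mean
    removed (to be absorbed into alpha)."""
    active = np.concatenate(components) if components else np.array([], dtype=int)
    m_all = float(u[active].mean()) if active.size else 0.0
    for comp in components:
        u[comp] -= u[comp].mean()
    return m_all


def fit_bym(
    observed: np.ndarray,
    expected: np.ndarray,
    adjacency: Adjacency,
    config: Optional[MCMCConfig] = None,
) -> PosteriorSamples:
    """Sample the BYM posterior by Metropolis-within-Gibbs MCMC.

    ``observed`` and ``expected`` align with ``adjacency.ids``; every
    modelled area needs E_i > 0 (zero-expectation areas are excluded
    upstream).  Computation is done in area-ID-sorted order, so a
    consistent relabelling of the study leaves per-area results
    bit-identical; outputs are returned in the input order.
    """
    config = config or MCMCConfig()
    y_in = np.asarray(observed, dtype=float)
    e_in = np.asarray(expected, dtype=float)
    if y_in.shape != e_in.shape or y_in.size != adjacency.n:
        raise ValueError("observed/expected must align with adjacency area list")
    if (e_in <= 0).any():
        bad = [adjacency.ids[i] for i in np.flatnonzero(e_in <= 0)]
        raise ValueError(f"non-positive expected counts for modelled areas: {bad}")

    # canonical order: sort by area ID (label invariance), map back at the end
    order = np.argsort(np.asarray(adjacency.ids, dtype=object))
    ids_sorted = [adjacency.ids[k] for k in order]
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    y = y_in[order]
    e = e_in[order]
    adj = Adjacency(ids_sorted, {a: set(adjacency.neighbors[a]) for a in ids_sorted})

    n = adj.n
    w = adj.to_sparse()
    deg = np.asarray(w.sum(axis=1)).ravel()
    island = deg == 0
    active = np.flatnonzero(~island)
    comps_ids = adj.subgraph([ids_sorted[i] for i in active]).components() if active.size else []
    idx_of = {a: i for i, a in enumerate(ids_sorted)}
    components = [np.array(sorted(idx_of[a] for a in comp)) for comp in comps_ids]
    if len(components) > 1:
        warnings.warn(
            f"adjacency has {len(components)} connected components; the intrinsic "
            "prior applies per component with one sum-to-zero constraint each"
        )
    colors = adj.greedy_coloring()
    color_classes = [
        np.intersect1d(np.flatnonzero(colors == c), active)
        for c in range(int(colors.max()) + 1 if n else 0)
    ]
    color_classes = [cc for cc in color_classes if cc.size]
    # precomputed per-colour slices (row slicing csr inside the sweep is costly)
    color_rows = [w[cc].tocsr() for cc in color_classes]
    color_y = [y[cc] for cc in color_classes]
    color_deg = [deg[cc] for cc in color_classes]

    a0, b0 = config.prior_shape, config.prior_rate
    n_active = int(active.size)
    n_comp = len(components)
    icar_df = max(n_active - n_comp, 0)
    alpha0 = float(np.log(max(y.sum(), 0.5) / e.sum()))
    y_tot = float(y.sum())

    saved = config.saved_per_chain
    out_alpha = np.empty((config.n_chains, saved))
    out_u = np.empty((config.n_chains, saved, n))
    out_v = np.empty((config.n_chains, saved, n))
    out_su = np.empty((config.n_chains, saved))
    out_sv = np.empty((config.n_chains, saved))
    acc_log: dict[str, list[float]] = {"v": [], "u": [], "alpha": []}

    chain_seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        disp = config.init_dispersion
        alpha = alpha0 + 0.5 * disp * rng.normal()
        u = 0.1 * disp * rng.normal(size=n)
        u[island] = 0.0
        _project_sum_zero(u, components)
        v = 0.1 * disp * rng.normal(size=n)
        tau_u = float(np.exp(rng.normal(np.log(20.0), 0.5 * disp)))
        tau_v = float(np.exp(rng.normal(np.log(20.0), 0.5 * disp)))
        ls_v, ls_u, ls_a = np.log(0.3), np.log(0.3), np.log(0.1)
        acc = {"v": 0.0, "u": 0.0, "alpha": 0.0}
        n_acc = 0

        total_iter = config.burn_in + config.n_iter
        k_saved = 0
        with np.errstate(over="ignore"):
            for t in range(total_iter):
                # --- v: vectorized single-site Metropolis (all areas) ---
                s_v = np.exp(ls_v)
                prop = v + s_v * rng.normal(size=n)
                e_au = e * np.exp(alpha + u)
                logr = y * (prop - v) - e_au * (np.exp(prop) - np.exp(v))
                logr -= 0.5 * tau_v * (prop**2 - v**2)
                ok = np.log(rng.uniform(size=n)) < logr
                v[ok] = prop[ok]
                rate_v = ok.mean()

                # --- u: Metropolis by colour class (islands fixed at 0) ---
                rate_u_num, rate_u_den = 0.0, 0
                if n_active:
                    s_u = np.exp(ls_u)
                    e_av = e * np.exp(alpha + v)
                    for cc, w_cc, y_cc, deg_cc in zip(
                        color_classes, color_rows, color_y, color_deg
                    ):
                        wu = w_cc @ u
                        cur = u[cc]
                        pu = cur + s_u * rng.normal(size=cc.size)
                        logr = y_cc * (pu - cur) - e_av[cc] * (np.exp(pu) - np.exp(cur))
                        logr -= 0.5 * tau_u * (deg_cc * (pu**2 - cur**2) - 2.0 * (pu - cur) * wu)
                        ok = np.log(rng.uniform(size=cc.size)) < logr
                        u[cc[ok]] = pu[ok]
                        rate_u_num += ok.sum()
                        rate_u_den += cc.size
                    alpha += _project_sum_zero(u, components)
                rate_u = rate_u_num / rate_u_den if rate_u_den else 1.0

                # --- alpha: random-walk Metropolis, flat prior ---
                s_a = np.exp(ls_a)
                pa = alpha + s_a * rng.normal()
                s_e = float(e @ np.exp(u + v))
                logr = y_tot * (pa - alpha) - s_e * (np.exp(pa) - np.exp(alpha))
                ok_a = np.log(rng.uniform()) < logr
                if ok_a:
                    alpha = pa

                # --- precisions: conjugate Gamma draws ---
                tau_v = rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * float(v @ v)))
                if icar_df > 0:
                    quad = float(u @ (deg * u) - u @ (w @ u))  # sum over edges (u_i-u_j)^2
                    tau_u = rng.gamma(a0 + icar_df / 2.0, 1.0 / (b0 + 0.5 * quad))
                else:
                    tau_u = rng.gamma(a0, 1.0 / b0)

                # --- adaptation during burn-in ---
                acc["v"] += rate_v
                acc["u"] += rate_u
                acc["alpha"] += float(ok_a)
                n_acc += 1
                if t < config.burn_in and n_acc == 50:
                    step = min(0.05, 5.0 / np.sqrt(t + 1.0))
                    ls_v += step if acc["v"] / n_acc > 0.44 else -step
                    ls_u += step if acc["u"] / n_acc > 0.44 else -step
                    ls_a += step if acc["alpha"] / n_acc > 0.44 else -step
                    acc = {"v": 0.0, "u": 0.0, "alpha": 0.0}
                    n_acc = 0
                if t == config.burn_in - 1:
                    acc = {"v": 0.0, "u": 0.0, "alpha": 0.0}
                    n_acc = 0

                # --- save ---
                tk = t - config.burn_in
                if tk >= 0 and (tk + 1) % config.thin == 0 and k_saved < saved:
                    out_alpha[c, k_saved] = alpha
                    out_u[c, k_saved] = u
                    out_v[c, k_saved] = v
                    out_su[c, k_saved] = tau_u**-0.5
                    out_sv[c, k_saved] = tau_v**-0.5
                    k_saved += 1
        for key in acc_log:
            acc_log[key].append(acc[key] / n_acc if n_acc else float("nan"))

    return PosteriorSamples(
        area_ids=list(adjacency.ids),
        alpha=out_alpha,
        u=out_u[:, :, inv],
        v=out_v[:, :, inv],
        sigma_u=out_su,
        sigma_v=out_sv,
        island_mask=island[inv],
        acceptance={k: np.array(vv) for k, vv in acc_log.items()},
    )


def gelman_rubin(samples: PosteriorSamples, parameter: str = "theta") -> np.ndarray | float:
    """Potential scale reduction factor R-hat from between/within chain
    variances of the saved draws.

    ``parameter`` is one of ``alpha``, ``sigma_u``, ``sigma_v`` (scalar
    returned), or ``theta``, ``u``, ``v`` (array over areas).  Degenerate
    chains (zero within-chain variance) yield NaN, not an exception.
    """
    if samples.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least 2 chains")
    if samples.n_saved < 10:
        raise ValueError("need at least 10 saved draws per chain")
    arr = getattr(samples, parameter)
    scalar = arr.ndim == 2
    if scalar:
        arr = arr[:, :, None]
    m, nd = arr.shape[0], arr.shape[1]
    means = arr.mean(axis=1)
    w_var = arr.var(axis=1, ddof=1).mean(axis=0)
    b_var = nd * means.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_hat = (nd - 1) / nd * w_var + b_var / nd
        rhat = np.where(w_var > 0, np.sqrt(v_hat / np.where(w_var > 0, w_var, 1.0)), np.nan)
    return float(rhat[0]) if scalar else rhat


def max_monitored_rhat(samples: PosteriorSamples) -> float:
    """Largest R-hat over the standard monitored set: alpha, both scale
    parameters, and every area's theta (NaNs from degenerate chains are
    ignored)."""
    vals = [
        gelman_rubin(samples, "alpha"),
        gelman_rubin(samples, "sigma_u"),
        gelman_rubin(samples, "sigma_v"),
    ]
    vals.extend(np.atleast_1d(gelman_rubin(samples, "theta")))
    return float(np.nanmax(vals))


def summarize_posterior(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-area posterior summaries of the relative risk: mean (the
    smoothed SIR), central 95% credible interval, and the exceedance
    probability P(theta_i > 1 | data)."""
    theta = samples.pooled("theta")
    if theta.shape[0] < 100:
        raise ValueError("need at least 100 pooled draws to summarize")
    return pd.DataFrame(
        {
            "area_id": samples.area_ids,
            "smoothed_sir": theta.mean(axis=0),
            "cri_low": np.quantile(theta, 0.025, axis=0),
            "cri_high": np.quantile(theta, 0.975, axis=0),
            "exceedance": (theta > 1.0).mean(axis=0),
        }
    )


def spatial_fraction(samples: PosteriorSamples, method: str = "variance") -> dict:
    """Posterior share of random-effect variation carried by the spatial
    component ("fracspatial").

    Per pooled draw the empirical across-area variances of u and v are
    formed and the fraction Var(u)/(Var(u)+Var(v)) computed (``method=
    'sd'`` uses standard deviations instead).  Draws with no variation at
    all are skipped with a warning.  Returns posterior mean and central
    95% interval.
    """
    if method not in ("variance", "sd"):
        raise ValueError("method must be 'variance' or 'sd'")
    u = samples.pooled("u")
    v = samples.pooled("v")
    if u.shape[0] < 100:
        raise ValueError("need at least 100 pooled draws")
    vu = u.var(axis=1)
    vv = v.var(axis=1)
    if method == "sd":
        vu, vv = np.sqrt(vu), np.sqrt(vv)
    tot = vu + vv
    keep = tot > 0
    if not keep.all():
        warnings.warn(f"skipping {int((~keep).sum())} degenerate draws with zero total variation")
    frac = vu[keep] / tot[keep]
    return {
        "mean": float(frac.mean()),
        "cri_low": float(np.quantile(frac, 0.025)),
        "cri_high": float(np.quantile(frac, 0.975)),
        "method": method,
    }
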