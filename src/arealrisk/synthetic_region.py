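"""Synthetic study regions for small-area disease mapping.

Real neighbourhood-level analyses run on census dissemination areas:
irregular polygons of roughly 400-700 residents, with age-sex population
strata, an areal income quintile, and case counts that are Poisson given
the area's expected count and relative risk.  This module generates
regions with exactly that statistical structure so every downstream
stage (standardization, Moran screening, BYM smoothing, scanning) can be
exercised and calibrated against known ground truth.

The true log-relative-risk surface follows the convolution decomposition
used by the BYM model itself: ``log theta = alpha + u + v`` with ``u`` an
intrinsic CAR (pairwise-difference) field over the contiguity graph and
``v`` independent Gaussian noise, plus an optional planted multiplicative
risk cluster for detection studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .adjacency import Adjacency, build_adjacency
from .geometry import PolygonLayer

# Fixed age pyramid used to split an area's total over age bands when the
# scenario uses the default five bands (fractions of total population,
# loosely shaped like a mature western age structure).  Sexes split evenly.
DEFAULT_AGE_BANDS = ("0-19", "20-39", "40-59", "60-74", "75+")
DEFAULT_AGE_PYRAMID = {
    "0-19": 0.25,
    "20-39": 0.27,
    "40-59": 0.28,
    "60-74": 0.13,
    "75+": 0.07,
}
DEFAULT_SEXES = ("F", "M")


@dataclass
class ClusterSpec:
    """Planted multiplicative risk cluster: all areas within ``radius``
    graph hops of ``seed_area`` have true risk multiplied by ``multiplier``."""

    seed_area: str
    radius: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("cluster risk multiplier must be > 0")


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study region."""

    n_areas: int = 331
    population_range: tuple[int, int] = (400, 700)
    age_bands: Sequence[str] = DEFAULT_AGE_BANDS
    sexes: Sequence[str] = DEFAULT_SEXES
    n_income_quintiles: int = 0
    alpha: float = 0.0
    sigma_u: float = 0.0
    sigma_v: float = 0.0
    cluster_spec: Optional[ClusterSpec] = None
    base_rate: float = 0.003
    age_rate_factor: float = 2.0
    income_gradient: float = 1.0
    income_spatial_correlation: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise ValueError("n_areas must be >= 1")
        lo, hi = self.population_range
        if lo < 1 or hi < lo:
            raise ValueError("population_range must satisfy 1 <= min <= max")
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise ValueError("sigma_u and sigma_v must be >= 0")
        if not self.age_bands or not self.sexes:
            raise ValueError("age_bands and sexes must be non-empty")

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["age_bands"] = list(self.age_bands)
        d["sexes"] = list(self.sexes)
        if self.cluster_spec is not None:
            d["cluster_spec"] = dict(self.cluster_spec.__dict__)
        return json.dumps(d, indent=2)


@dataclass
class SyntheticStudy:
    """One generated region: geometry, strata, ground truth, and provenance."""

    layer: PolygonLayer
    adjacency: Adjacency
    strata: pd.DataFrame  # area_id, age_band, sex, [income_quintile], population, cases
    truth: pd.DataFrame  # area_id, theta_true, u, v, cluster_member
    rates: pd.DataFrame  # stratum key columns + rate
    config: ScenarioConfig
    income: Optional[pd.DataFrame] = None  # area_id, income, income_quintile

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.layer.write_geojson(outdir / "areas.geojson")
        self.strata.to_csv(outdir / "strata.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        self.rates.to_csv(outdir / "reference_rates.csv", index=False)
        (outdir / "scenario.json").write_text(self.config.to_json())


def generate_geometry(n_areas: int, seed: int) -> PolygonLayer:
    """Irregular tessellation: Voronoi cells of uniform random points,
    clipped to the unit square.  IDs are ``A0000``, ``A0001``, ... in the
    order the seed points were drawn."""
    if n_areas < 1:
        raise ValueError("n_areas must be >= 1")
    window = box(0.0, 0.0, 1.0, 1.0)
    ids = [f"A{k:04d}" for k in range(n_areas)]
    if n_areas == 1:
        return PolygonLayer(ids, [window])
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, 1.0, size=(n_areas, 2))
    cells_raw = voronoi_diagram(MultiPoint([Point(p) for p in pts]), envelope=window)
    # voronoi_diagram does not preserve input order: match cells to seeds
    geoms: list = [None] * n_areas
    remaining = list(range(n_areas))
    for cell in cells_raw.geoms:
        clipped = cell.intersection(window)
        for pos, k in enumerate(remaining):
            if cell.covers(Point(pts[k])):
                geoms[k] = clipped
                remaining.pop(pos)
                break
    if any(g is None for g in geoms):
        raise RuntimeError("failed to match a Voronoi cell to its seed point")
    return PolygonLayer(ids, geoms)


def _age_pyramid(age_bands: Sequence[str]) -> np.ndarray:
    """Weights over age bands: the documented default pyramid when the
    default bands are used, otherwise a geometric decline (ratio 0.8)."""
    if tuple(age_bands) == DEFAULT_AGE_BANDS:
        w = np.array([DEFAULT_AGE_PYRAMID[b] for b in age_bands])
    else:
        w = 0.8 ** np.arange(len(age_bands))
    return w / w.sum()


def generate_population(
    layer: PolygonLayer, config: ScenarioConfig, seed: int
) -> pd.DataFrame:
    """Stratified population table (no cases yet).

    Each area's total is uniform on ``population_range`` inclusive, then
    allocated multinomially over age x sex cells using the fixed pyramid
    and an even sex split, so strata are non-negative integers summing
    exactly to the drawn total.
    """
    if not config.age_bands or not config.sexes:
        raise ValueError("age_bands and sexes must be non-empty")
    rng = np.random.default_rng(seed)
    lo, hi = config.population_range
    pyramid = _age_pyramid(config.age_bands)
    n_sex = len(config.sexes)
    cell_p = np.outer(pyramid, np.full(n_sex, 1.0 / n_sex)).ravel()
    rows = []
    for area_id in layer.ids:
        total = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(total, cell_p)
        k = 0
        for band in config.age_bands:
            for sex in config.sexes:
                rows.append((area_id, band, sex, int(counts[k])))
                k += 1
    return pd.DataFrame(rows, columns=["area_id", "age_band", "sex", "population"])


def generate_income(
    layer: PolygonLayer,
    adjacency: Adjacency,
    spatial_correlation: float,
    seed: int,
    n_quintiles: int = 5,
) -> pd.DataFrame:
    """Continuous area income with optional neighbour correlation, plus a
    rank-based quintile label (1 = lowest ... n_quintiles = highest).

    Correlation is induced by a one-step moving average over the
    contiguity graph: x_i = (1-rho) e_i + rho * mean(e_j, j ~ i).
    Quintile groups have near-equal counts; any remainder goes to the
    lower quintiles, ties broken by area ID order.
    """
    n = len(layer)
    if n < n_quintiles:
        raise ValueError(f"need at least {n_quintiles} areas for {n_quintiles} quintiles")
    rng = np.random.default_rng(seed)
    e = rng.normal(size=n)
    x = e.copy()
    if spatial_correlation > 0:
        for i, a in enumerate(layer.ids):
            nb = adjacency.neighbors[a]
            if nb:
                m = np.mean([e[layer.ids.index(b)] for b in nb])
                x[i] = (1 - spatial_correlation) * e[i] + spatial_correlation * m
    income = 50_000.0 * np.exp(0.35 * x)

    order = pd.DataFrame({"area_id": layer.ids, "income": income})
    order = order.sort_values(["income", "area_id"], kind="stable").reset_index(drop=True)
    sizes = np.full(n_quintiles, n // n_quintiles)
    sizes[: n % n_quintiles] += 1  # remainder to lower quintiles
    labels = np.repeat(np.arange(1, n_quintiles + 1), sizes)
    order["income_quintile"] = labels
    out = order.set_index("area_id").loc[layer.ids].reset_index()
    return out[["area_id", "income", "income_quintile"]]


def sample_icar(adjacency: Adjacency, sigma_u: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a structured field from the intrinsic CAR distribution.

    The graph Laplacian is eigendecomposed, the null (constant) direction
    dropped, a Gaussian drawn in the remaining eigenbasis with variance
    1/eigenvalue, the result centred to sum to zero, and finally rescaled
    so the empirical (across-area) standard deviation equals ``sigma_u``
    exactly.  The intrinsic prior fixes no scale of its own, so the
    generator must: the empirical-SD convention makes the realized
    spatial-vs-unstructured variance split exact by construction.
    """
    n = adjacency.n
    if sigma_u == 0.0:
        return np.zeros(n)
    comps = adjacency.components()
    if len(comps) > 1:
        raise ValueError(
            "ICAR field with sigma_u > 0 requires a connected adjacency; "
            f"found {len(comps)} components: {[sorted(c)[:3] for c in comps]}"
        )
    w = adjacency.to_sparse().toarray()
    lap = np.diag(w.sum(axis=1)) - w
    lam, vec = np.linalg.eigh(lap)
    keep = lam > 1e-9
    z = rng.normal(size=keep.sum())
    u = vec[:, keep] @ (z / np.sqrt(lam[keep]))
    u -= u.mean()
    sd = u.std()
    if sd > 0:
        u *= sigma_u / sd
    return u


def generate_risk_surface(
    adjacency: Adjacency, config: ScenarioConfig, seed: int
) -> pd.DataFrame:
    """True relative-risk surface theta = exp(alpha + u + v), with the
    optional planted cluster applied multiplicatively afterwards."""
    rng = np.random.default_rng(seed)
    u = sample_icar(adjacency, config.sigma_u, rng)
    v = rng.normal(scale=config.sigma_v, size=adjacency.n) if config.sigma_v > 0 else np.zeros(adjacency.n)
    theta = np.exp(config.alpha + u + v)
    member = np.zeros(adjacency.n, dtype=bool)
    if config.cluster_spec is not None:
        spec = config.cluster_spec
        ball = adjacency.graph_ball(spec.seed_area, spec.radius)
        member = np.array([a in ball for a in adjacency.ids])
        theta = np.where(member, theta * spec.multiplier, theta)
    return pd.DataFrame(
        {
            "area_id": adjacency.ids,
            "theta_true": theta,
            "u": u,
            "v": v,
            "cluster_member": member,
        }
    )


def make_reference_rates(
    age_bands: Sequence[str],
    sexes: Sequence[str],
    n_income_quintiles: int = 0,
    base_rate: float = 0.003,
    age_rate_factor: float = 2.0,
    income_gradient: float = 1.0,
    sex_factors: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Deterministic per-stratum reference rates (cases per person per
    study period).

    Rates rise geometrically with age band (factor ``age_rate_factor``
    per band) so they are monotone in age within each sex.  With income
    quintiles, quintile q is multiplied by
    ``income_gradient ** ((Q - q)/(Q - 1))`` — the lowest quintile's rate
    exceeds the highest's by exactly ``income_gradient`` — creating a
    deprivation gradient for confounding scenarios; gradient 1 is neutral.
    """
    if not age_bands or not sexes:
        raise ValueError("strata definition must be non-empty")
    sex_factors = sex_factors or {}
    rows = []
    for k, band in enumerate(age_bands):
        for sex in sexes:
            rate = base_rate * age_rate_factor**k * sex_factors.get(sex, 1.0)
            if n_income_quintiles > 0:
                for q in range(1, n_income_quintiles + 1):
                    mult = income_gradient ** ((n_income_quintiles - q) / (n_income_quintiles - 1))
                    rows.append((band, sex, q, rate * mult))
            else:
                rows.append((band, sex, rate))
    if n_income_quintiles > 0:
        return pd.DataFrame(rows, columns=["age_band", "sex", "income_quintile", "rate"])
    return pd.DataFrame(rows, columns=["age_band", "sex", "rate"])


def simulate_cases(
    population: pd.DataFrame,
    rates: pd.DataFrame,
    surface: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Draw stratum case counts: Poisson(persons x stratum rate x area theta)."""
    if (rates["rate"] < 0).any() or not np.isfinite(rates["rate"]).all():
        raise ValueError("reference rates must be finite and >= 0")
    keys = [c for c in ("age_band", "sex", "income_quintile") if c in rates.columns]
    df = population.merge(rates, on=keys, how="left", validate="many_to_one")
    if df["rate"].isna().any():
        missing = df[df["rate"].isna()][keys].drop_duplicates()
        raise KeyError(f"strata missing from rate vector: {missing.to_dict('records')}")
    df = df.merge(surface[["area_id", "theta_true"]], on="area_id", how="left")
    mean = df["population"].to_numpy() * df["rate"].to_numpy() * df["theta_true"].to_numpy()
    rng = np.random.default_rng(seed)
    df["cases"] = rng.poisson(mean)
    return df.drop(columns=["rate", "theta_true"])


def simulate_study(config: ScenarioConfig) -> SyntheticStudy:
    """End-to-end generation of one synthetic study region.

    The scenario seed is split into independent per-stage streams, so
    e.g. changing only the risk surface leaves geometry and populations
    untouched.
    """
    ss = np.random.SeedSequence(config.seed)
    s_geom, s_pop, s_inc, s_risk, s_case = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    layer = generate_geometry(config.n_areas, s_geom)
    adj = build_adjacency(layer, rule="queen")
    pop = generate_population(layer, config, s_pop)
    income = None
    if config.n_income_quintiles > 0:
        income = generate_income(
            layer, adj, config.income_spatial_correlation, s_inc, config.n_income_quintiles
        )
        pop = pop.merge(income[["area_id", "income_quintile"]], on="area_id")
        pop = pop[["area_id", "age_band", "sex", "income_quintile", "population"]]
    rates = make_reference_rates(
        config.age_bands,
        config.sexes,
        config.n_income_quintiles,
        config.base_rate,
        config.age_rate_factor,
        config.income_gradient,
    )
    surface = generate_risk_surface(adj, config, s_risk)
    strata = simulate_cases(pop, rates, surface, s_case)
    return SyntheticStudy(layer, adj, strata, surface, rates, config, income)
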