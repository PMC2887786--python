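"""Circular Poisson spatial scan statistic with Monte-Carlo inference.

A Kulldorff-style scan: candidate zones are grown around every area
centroid by ascending centroid distance, capped at a fraction of the
total expected count; each zone's Poisson likelihood ratio compares the
rate inside against outside, and the maximum over zones is referred to
a Monte-Carlo null in which the observed case total is redistributed
multinomially with probabilities proportional to the expected counts
(the scan conditioned on the total).  Only high-rate (hot-spot) zones
score; the analysis corroborates clusters suggested by the Bayesian
map.  Windows are circular; elliptical shapes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


@dataclass
class ScanZone:
    center: str
    members: list[str]
    observed: float
    expected: float  # conditioned scale: total expected = total observed


@dataclass
class ScanResult:
    zone: ScanZone
    llr: float
    p_value: float
    n_sim: int
    sir_inside: float
    sir_outside: float
    seed: int


def enumerate_zones(
    ids: list[str],
    centroids: np.ndarray,
    expected: np.ndarray,
    max_fraction: float = 0.5,
) -> list[list[int]]:
    """Candidate zones as index lists: for each centre, every prefix of
    the ascending-centroid-distance ordering whose expected count stays
    within ``max_fraction`` of the total; duplicate member sets removed.
    Ties in distance break by area index for determinism."""
    if not 0 < max_fraction <= 0.5:
        raise ValueError("max_fraction must be in (0, 0.5]")
    n = len(ids)
    if n == 0:
        raise ValueError("no areas to scan")
    pts = np.asarray(centroids, dtype=float)
    e = np.asarray(expected, dtype=float)
    cap = max_fraction * e.sum()
    zones: list[list[int]] = []
    seen: set[frozenset[int]] = set()
    for i in range(n):
        d = np.linalg.norm(pts - pts[i], axis=1)
        order = np.lexsort((np.arange(n), d))
        acc = 0.0
        members: list[int] = []
        for j in order:
            if acc + e[j] > cap:
                break
            acc += e[j]
            members.append(int(j))
            key = frozenset(members)
            if key not in seen:
                seen.add(key)
                zones.append(list(members))
    return zones


def poisson_llr(y_z: float, e_z: float, y_total: float, e_total: float) -> float:
    """Kulldorff's Poisson log-likelihood ratio for a high-rate zone.

    Assumes expectations conditioned so that e_total equals y_total.
    Zero-count terms contribute zero; zones whose inside rate does not
    exceed the outside rate score 0.
    """
    if e_z <= 0 or e_z >= e_total:
        raise ValueError("need 0 < E_z < E_total")
    y_out = y_total - y_z
    e_out = e_total - e_z
    if y_z / e_z <= y_out / e_out:
        return 0.0
    llr = 0.0
    if y_z > 0:
        llr += y_z * np.log(y_z / e_z)
    if y_out > 0:
        llr += y_out * np.log(y_out / e_out)
    return float(llr)


def _max_llr(y: np.ndarray, zmat: sp.csr_matrix, e_z: np.ndarray, y_total: float) -> tuple[float, int]:
    """Maximum LLR over zones for one count vector (vectorized)."""
    y_z = zmat @ y
    y_out = y_total - y_z
    e_out = y_total - e_z
    with np.errstate(invalid="ignore", divide="ignore"):
        hot = y_z * e_out > y_out * e_z
        t1 = np.where(y_z > 0, y_z * np.log(np.where(y_z > 0, y_z, 1.0) / e_z), 0.0)
        t2 = np.where(y_out > 0, y_out * np.log(np.where(y_out > 0, y_out, 1.0) / e_out), 0.0)
        llr = np.where(hot, t1 + t2, 0.0)
    k = int(np.argmax(llr))
    return float(llr[k]), k


def monte_carlo_scan(
    observed: np.ndarray,
    expected: np.ndarray,
    centroids: np.ndarray,
    ids: list[str],
    max_fraction: float = 0.5,
    n_sim: int = 999,
    seed: int = 0,
) -> ScanResult:
    """Most-likely high-rate zone and its Monte-Carlo p-value.

    p = (1 + #{max-LLR* >= max-LLR_obs}) / (n_sim + 1); with 999
    replicates the smallest attainable p is 0.001.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    y = np.asarray(observed, dtype=float)
    e_raw = np.asarray(expected, dtype=float)
    y_total = float(y.sum())
    if y_total <= 0:
        raise ValueError("no cases observed; nothing to scan")
    e = e_raw * (y_total / e_raw.sum())  # condition on the observed total

    zones = enumerate_zones(ids, centroids, e, max_fraction)
    rows = np.concatenate([[k] * len(m) for k, m in enumerate(zones)])
    cols = np.concatenate([np.asarray(m) for m in zones])
    zmat = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(len(zones), y.size)
    )
    e_z = zmat @ e

    llr_obs, k_obs = _max_llr(y, zmat, e_z, y_total)

    rng = np.random.default_rng(seed)
    sims = rng.multinomial(int(round(y_total)), e / e.sum(), size=n_sim).astype(float)
    exceed = 0
    e_out_all = y_total - e_z
    for lo in range(0, n_sim, 200):  # chunked to bound memory
        block = sims[lo : lo + 200]
        y_zb = (zmat @ block.T).T  # (chunk, zones)
        y_ob = y_total - y_zb
        with np.errstate(invalid="ignore", divide="ignore"):
            hot = y_zb * e_out_all > y_ob * e_z
            t1 = np.where(y_zb > 0, y_zb * np.log(np.where(y_zb > 0, y_zb, 1.0) / e_z), 0.0)
            t2 = np.where(y_ob > 0, y_ob * np.log(np.where(y_ob > 0, y_ob, 1.0) / e_out_all), 0.0)
            llr_b = np.where(hot, t1 + t2, 0.0).max(axis=1)
        exceed += int(np.sum(llr_b >= llr_obs))
    p = (1.0 + exceed) / (n_sim + 1.0)

    members = zones[k_obs]
    y_in = float(y[members].sum())
    e_in = float(e[members].sum())
    y_out = y_total - y_in
    e_out = y_total - e_in
    zone = ScanZone(
        center=ids[members[0]],
        members=[ids[j] for j in members],
        observed=y_in,
        expected=e_in,
    )
    return ScanResult(
        zone=zone,
        llr=llr_obs,
        p_value=p,
        n_sim=n_sim,
        sir_inside=y_in / e_in,
        sir_outside=y_out / e_out if e_out > 0 else float("nan"),
        seed=seed,
    )
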