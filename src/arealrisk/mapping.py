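"""Choropleth-ready outputs: class assignment, exceedance overlays,
shrinkage summaries, annotated map layers.

SIR maps use seven classes on a diverging scale with a natural class
containing 1.0 in its interior; significance is overlaid rather than
encoded in colour — on raw-SIR maps an area is flagged when its exact
interval excludes 1, on smoothed maps when the posterior exceedance
probability reaches the threshold (default 0.80).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import PolygonLayer

DEFAULT_BREAKS = (0.0, 0.5, 0.75, 0.95, 1.05, 1.33, 2.0, float("inf"))


@dataclass
class ClassScheme:
    """Seven ordered classes bounded by eight strictly increasing breaks,
    one class containing 1.0 in its interior."""

    breaks: Sequence[float] = DEFAULT_BREAKS
    labels: Sequence[str] = ()
    palette: str = "red-grey-diverging"

    def __post_init__(self) -> None:
        b = np.asarray(self.breaks, dtype=float)
        if b.size != 8:
            raise ValueError("need exactly 8 break points for 7 classes")
        if not (np.diff(b) > 0).all():
            raise ValueError("break points must be strictly increasing")
        interior = np.searchsorted(b, 1.0, side="right")
        if not (0 < interior < 8) or 1.0 in b:
            raise ValueError("one class must contain 1.0 in its interior")
        if not self.labels:
            self.labels = [
                f"[{b[k]:g}, {b[k + 1]:g})" for k in range(7)
            ]


def classify(values: np.ndarray, scheme: Optional[ClassScheme] = None) -> np.ndarray:
    """Class index 1..7 per value (half-open [b_k, b_k+1) intervals,
    clamped at both ends); NaN (undefined SIR) maps to 0 = unclassified."""
    scheme = scheme or ClassScheme()
    x = np.asarray(values, dtype=float)
    b = np.asarray(scheme.breaks, dtype=float)
    idx = np.searchsorted(b, x, side="right")
    idx = np.clip(idx, 1, 7)
    return np.where(np.isnan(x), 0, idx).astype(int)


def exceedance_flags(probabilities: np.ndarray, threshold: float = 0.80) -> np.ndarray:
    """Flag areas whose posterior exceedance probability reaches the
    threshold (inclusive: 0.80 flags at the default)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    p = np.asarray(probabilities, dtype=float)
    return p >= threshold


def shrinkage_summary(series: dict[str, np.ndarray]) -> pd.DataFrame:
    """Box-plot statistics per named series (raw vs smoothed SIRs):
    quartiles, mean, median, whiskers at Q1 - 1.5 IQR / Q3 + 1.5 IQR,
    and the count of points beyond the whiskers."""
    rows = []
    for name, vals in series.items():
        x = np.asarray(vals, dtype=float)
        x = x[~np.isnan(x)]
        if x.size == 0:
            raise ValueError(f"series {name!r} is empty")
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_w, hi_w = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        rows.append(
            {
                "series": name,
                "mean": x.mean(),
                "median": med,
                "q1": q1,
                "q3": q3,
                "iqr": iqr,
                "whisker_low": lo_w,
                "whisker_high": hi_w,
                "n_outliers": int(((x < lo_w) | (x > hi_w)).sum()),
                "n": x.size,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MapRecord:
    area_id: str
    value: float
    class_index: int
    significant: bool = False
    exceedance: bool = False
    extra: dict = field(default_factory=dict)


def build_map_records(
    risk: pd.DataFrame,
    value_col: str,
    scheme: Optional[ClassScheme] = None,
    significant: Optional[np.ndarray] = None,
    exceedance: Optional[np.ndarray] = None,
) -> list[MapRecord]:
    vals = risk[value_col].to_numpy(dtype=float)
    cls = classify(vals, scheme)
    sig = np.zeros(len(risk), dtype=bool) if significant is None else np.asarray(significant, bool)
    exc = np.zeros(len(risk), dtype=bool) if exceedance is None else np.asarray(exceedance, bool)
    return [
        MapRecord(a, float(v), int(c), bool(s), bool(x))
        for a, v, c, s, x in zip(risk["area_id"], vals, cls, sig, exc)
    ]


def write_map_layer(
    layer: PolygonLayer, records: list[MapRecord], path
) -> PolygonLayer:
    """Annotate the polygon layer with map attributes and write GeoJSON.

    Every record's area must exist in the layer; the annotated layer is
    returned (and round-trips losslessly through ``read_geojson``).
    """
    props = {
        r.area_id: {
            "value": None if np.isnan(r.value) else r.value,
            "class": r.class_index,
            "significant": r.significant,
            "exceedance": r.exceedance,
            **r.extra,
        }
        for r in records
    }
    annotated = layer.with_properties(props)
    annotated.write_geojson(path)
    return annotated


def plot_choropleth(layer: PolygonLayer, records: list[MapRecord], path=None, title: str = ""):
    """Simple matplotlib rendering of the classed map (hatching marks
    flagged areas).  Attribute assignment, not cartography."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("redgrey", ["#555555", "#ffffff", "#b2182b"])
    by_id = {r.area_id: r for r in records}
    fig, ax = plt.subplots(figsize=(6, 6))
    for area_id, geom in layer:
        r = by_id.get(area_id)
        color = "#dddddd" if r is None or r.class_index == 0 else cmap((r.class_index - 1) / 6)
        hatch = "///" if r is not None and (r.significant or r.exceedance) else None
        polys = getattr(geom, "geoms", [geom])
        for poly in polys:
            xs, ys = poly.exterior.xy
            ax.fill(xs, ys, facecolor=color, edgecolor="black", linewidth=0.3, hatch=hatch)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
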