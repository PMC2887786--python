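"""End-to-end orchestration: simulate (or load) -> standardize -> Moran
screen -> BYM smoothing of flagged outcomes -> scan corroboration -> maps.

The hierarchical smoothing step is expensive, so it is gated on the
Moran screen: only outcomes showing significant positive spatial
autocorrelation (family-wise controlled) are smoothed, mirroring the
screening logic of registry practice.  A master seed deterministically
spawns one sub-seed per stochastic stage, so a run is reproducible
bit-for-bit from its configuration.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import bym, mapping, moran_screen, scan, standardization
from .adjacency import build_adjacency, row_standardized_weights, validate_adjacency
from .synthetic_region import ScenarioConfig, SyntheticStudy, simulate_study


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    master_seed: int = 0
    reference: str = "generator"  # or "internal": pool the study itself
    screen_b: int = 999
    screen_alpha: float = 0.05
    screen_family_size: Optional[int] = None  # None -> number of outcomes
    mcmc: bym.MCMCConfig = field(default_factory=bym.MCMCConfig)
    scan_max_fraction: float = 0.5
    scan_n_sim: int = 999
    class_breaks: tuple = mapping.DEFAULT_BREAKS
    exceedance_threshold: float = 0.80
    rhat_gate: float = 1.1
    force_smooth: bool = False


@dataclass
class RunBundle:
    study: SyntheticStudy
    risk_table: pd.DataFrame
    screen_table: pd.DataFrame
    posterior: Optional[bym.PosteriorSamples]
    posterior_summary: Optional[pd.DataFrame]
    fracspatial: Optional[dict]
    scan_result: Optional[scan.ScanResult]
    report: dict


def run_pipeline(config: PipelineConfig, outdir: Optional[str | Path] = None) -> RunBundle:
    """Execute all stages in order; optionally write every stage output.

    Stage failures propagate with the stage named in the exception.
    """
    seeds = np.random.SeedSequence(config.master_seed).spawn(4)
    s_scen, s_screen, s_mcmc, s_scan = (int(s.generate_state(1)[0] % (2**31)) for s in seeds)
    report: dict = {"master_seed": config.master_seed, "stages": {}, "timings_s": {}}

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                report["timings_s"][name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Ctx()

    with _stage("simulate"):
        scen = ScenarioConfig(**{**config.scenario.__dict__, "seed": s_scen})
        study = simulate_study(scen)
        report["stages"]["simulate"] = {"n_areas": scen.n_areas, "seed": s_scen}

    with _stage("standardize"):
        if config.reference == "internal":
            rates = standardization.estimate_reference_rates(study.strata)
        else:
            rates = study.rates
        risk = standardization.compute_sir(study.strata, rates)
        report["stages"]["standardize"] = {
            "total_observed": int(risk["observed"].sum()),
            "total_expected": float(risk["expected"].sum()),
            "n_excluded": int(risk["excluded"].sum()),
            "reference": config.reference,
        }

    adj = study.adjacency
    adj_report = validate_adjacency(adj)
    report["adjacency"] = {
        "n_islands": len(adj_report.islands),
        "n_components": adj_report.n_components,
    }
    order = {a: k for k, a in enumerate(adj.ids)}
    risk = risk.sort_values("area_id", key=lambda s: s.map(order)).reset_index(drop=True)
    modelled = risk[~risk["excluded"]]

    with _stage("screen"):
        w_row = row_standardized_weights(adj)
        mres = moran_screen.parametric_bootstrap_p(
            risk["observed"].to_numpy(),
            risk["expected"].to_numpy(),
            w_row,
            b=config.screen_b,
            seed=s_screen,
        )
        screen_tab = moran_screen.bonferroni_screen(
            {"synthetic_outcome": mres},
            alpha=config.screen_alpha,
            m=config.screen_family_size,
        )
        flagged = bool(screen_tab["flagged"].iloc[0])
        report["stages"]["screen"] = {
            "moran_i": mres.statistic,
            "p_value": mres.p_value,
            "b": mres.b,
            "flagged": flagged,
            "seed": s_screen,
        }

    posterior = summary = frac = None
    if flagged or config.force_smooth:
        with _stage("smooth"):
            sub_adj = adj.subgraph(list(modelled["area_id"]))
            mcfg = bym.MCMCConfig(**{**config.mcmc.__dict__, "seed": s_mcmc})
            posterior = bym.fit_bym(
                modelled["observed"].to_numpy(),
                modelled["expected"].to_numpy(),
                sub_adj,
                mcfg,
            )
            summary = bym.summarize_posterior(posterior)
            frac = bym.spatial_fraction(posterior)
            rhat = bym.max_monitored_rhat(posterior)
            report["stages"]["smooth"] = {
                "max_rhat": rhat,
                "converged": bool(rhat < config.rhat_gate),
                "fracspatial": frac,
                "seed": s_mcmc,
            }
            if rhat >= config.rhat_gate:
                report["stages"]["smooth"]["warning"] = (
                    f"max monitored R-hat {rhat:.3f} >= gate {config.rhat_gate}"
                )

    scan_result = None
    if flagged or config.force_smooth:
        with _stage("scan"):
            cent = np.array(
                [study.layer.geom_of(a).centroid.coords[0] for a in modelled["area_id"]]
            )
            scan_result = scan.monte_carlo_scan(
                modelled["observed"].to_numpy(),
                modelled["expected"].to_numpy(),
                cent,
                list(modelled["area_id"]),
                max_fraction=config.scan_max_fraction,
                n_sim=config.scan_n_sim,
                seed=s_scan,
            )
            report["stages"]["scan"] = {
                "llr": scan_result.llr,
                "p_value": scan_result.p_value,
                "n_zone_areas": len(scan_result.zone.members),
                "sir_inside": scan_result.sir_inside,
                "sir_outside": scan_result.sir_outside,
                "seed": s_scan,
            }

    with _stage("map"):
        scheme = mapping.ClassScheme(breaks=config.class_breaks)
        sig_raw = (risk["ci_low"] > 1.0) | (risk["ci_high"] < 1.0)
        raw_records = mapping.build_map_records(
            risk, "sir", scheme, significant=sig_raw.to_numpy()
        )
        smooth_records = None
        if summary is not None:
            exc = mapping.exceedance_flags(
                summary["exceedance"].to_numpy(), config.exceedance_threshold
            )
            smooth_records = mapping.build_map_records(
                summary, "smoothed_sir", scheme, exceedance=exc
            )
            report["stages"]["map"] = {"n_exceedance_flags": int(exc.sum())}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        study.write(outdir)
        risk.to_csv(outdir / "sir.csv", index=False)
        screen_tab.to_csv(outdir / "screen.csv", index=False)
        mapping.write_map_layer(study.layer, raw_records, outdir / "map_raw.geojson")
        if summary is not None:
            summary.to_csv(outdir / "smoothed.csv", index=False)
            mapping.write_map_layer(study.layer, smooth_records, outdir / "map_smoothed.geojson")
        if scan_result is not None:
            (outdir / "scan.json").write_text(
                json.dumps(
                    {
                        "members": scan_result.zone.members,
                        "observed": scan_result.zone.observed,
                        "expected": scan_result.zone.expected,
                        "llr": scan_result.llr,
                        "p_value": scan_result.p_value,
                        "n_sim": scan_result.n_sim,
                        "sir_inside": scan_result.sir_inside,
                        "sir_outside": scan_result.sir_outside,
                        "seed": scan_result.seed,
                    },
                    indent=2,
                )
            )
        (outdir / "run_report.json").write_text(json.dumps(report, indent=2))

    return RunBundle(
        study=study,
        risk_table=risk,
        screen_table=screen_tab,
        posterior=posterior,
        posterior_summary=summary,
        fracspatial=frac,
        scan_result=scan_result,
        report=report,
    )
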