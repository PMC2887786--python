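"""Generator behaviour: geometry, populations, income, risk surfaces, cases."""

import numpy as np
import pandas as pd
import pytest

import arealrisk as ar
from arealrisk.moran_screen import morans_i
from arealrisk.adjacency import row_standardized_weights

from conftest import lattice_adjacency, grid_layer


class TestGeometry:
    def test_single_area_fills_window(self):
        layer = ar.generate_geometry(1, seed=0)
        assert len(layer) == 1
        assert layer.geoms[0].area == pytest.approx(1.0)

    def test_partition_conserves_area(self):
        layer = ar.generate_geometry(4, seed=42)
        assert sum(g.area for g in layer.geoms) == pytest.approx(1.0, abs=1e-9)

    def test_determinism_by_double_run(self):
        a = ar.generate_geometry(331, seed=5)
        b = ar.generate_geometry(331, seed=5)
        assert a.ids == b.ids
        for ga, gb in zip(a.geoms, b.geoms):
            assert ga.equals_exact(gb, 0.0)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            ar.generate_geometry(0, seed=1)


class TestPopulation:
    def test_totals_within_range(self):
        cfg = ar.ScenarioConfig(n_areas=50, population_range=(400, 700))
        layer = ar.generate_geometry(50, seed=1)
        pop = ar.generate_population(layer, cfg, seed=2)
        totals = pop.groupby("area_id")["population"].sum()
        assert totals.between(400, 700).all()
        assert (pop["population"] >= 0).all()
        assert pop["population"].dtype.kind == "i"

    def test_degenerate_range(self):
        cfg = ar.ScenarioConfig(n_areas=10, population_range=(10, 10))
        layer = ar.generate_geometry(10, seed=1)
        totals = ar.generate_population(layer, cfg, seed=3).groupby("area_id")["population"].sum()
        assert (totals == 10).all()

    def test_mean_total_matches_uniform_mean(self):
        # uniform on [400, 700]: mean 550, var (301^2 - 1)/12
        cfg = ar.ScenarioConfig(n_areas=1000, population_range=(400, 700))
        layer = ar.generate_geometry(1000, seed=4)
        totals = ar.generate_population(layer, cfg, seed=5).groupby("area_id")["population"].sum()
        se = np.sqrt((301**2 - 1) / 12 / 1000)
        assert abs(totals.mean() - 550) < 3 * se

    def test_determinism(self):
        cfg = ar.ScenarioConfig(n_areas=20)
        layer = ar.generate_geometry(20, seed=1)
        a = ar.generate_population(layer, cfg, seed=9)
        b = ar.generate_population(layer, cfg, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestIncome:
    def test_exact_quintile_split(self):
        layer = ar.generate_geometry(10, seed=1)
        adj = ar.build_adjacency(layer)
        inc = ar.generate_income(layer, adj, 0.5, seed=2)
        assert inc["income_quintile"].value_counts().eq(2).all()

    def test_near_equal_split_331(self):
        layer = ar.generate_geometry(331, seed=1)
        adj = ar.build_adjacency(layer)
        sizes = ar.generate_income(layer, adj, 0.0, seed=2)["income_quintile"].value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_spatial_correlation_gives_positive_moran(self):
        layer = grid_layer(10, 10)
        adj = lattice_adjacency(10, 10)
        w = row_standardized_weights(adj)
        hits = 0
        for rep in range(100):
            inc = ar.generate_income(layer, adj, spatial_correlation=0.6, seed=1000 + rep)
            if morans_i(inc["income"].to_numpy(), w) > 0:
                hits += 1
        assert hits >= 95

    def test_too_few_areas_rejected(self):
        layer = ar.generate_geometry(3, seed=1)
        adj = ar.build_adjacency(layer)
        with pytest.raises(ValueError):
            ar.generate_income(layer, adj, 0.0, seed=1)


class TestRiskSurface:
    def test_no_variation_limit(self):
        adj = lattice_adjacency(4, 4)
        cfg = ar.ScenarioConfig(n_areas=16, alpha=0.0, sigma_u=0.0, sigma_v=0.0)
        surf = ar.generate_risk_surface(adj, cfg, seed=1)
        assert np.allclose(surf["theta_true"], 1.0)

    def test_neutral_cluster_is_identity(self):
        adj = lattice_adjacency(4, 4)
        base = ar.ScenarioConfig(n_areas=16, sigma_u=0.2, sigma_v=0.1)
        withc = ar.ScenarioConfig(
            n_areas=16, sigma_u=0.2, sigma_v=0.1,
            cluster_spec=ar.ClusterSpec(adj.ids[5], 1, 1.0),
        )
        s0 = ar.generate_risk_surface(adj, base, seed=3)
        s1 = ar.generate_risk_surface(adj, withc, seed=3)
        assert np.allclose(s0["theta_true"], s1["theta_true"])

    def test_sum_to_zero_and_reconstruction(self):
        adj = lattice_adjacency(6, 6)
        cfg = ar.ScenarioConfig(n_areas=36, alpha=-0.2, sigma_u=0.4, sigma_v=0.2)
        surf = ar.generate_risk_surface(adj, cfg, seed=8)
        assert abs(surf["u"].sum()) < 1e-9
        recon = np.exp(cfg.alpha + surf["u"] + surf["v"])
        assert np.allclose(surf["theta_true"], recon)

    def test_variance_split_calibration(self):
        # generator target: Var(u)/(Var(u)+Var(v)) ~= 0.9 at sigma_u=.3, sigma_v=.1
        adj = lattice_adjacency(10, 10)
        cfg = ar.ScenarioConfig(n_areas=100, sigma_u=0.3, sigma_v=0.1)
        fracs = []
        for rep in range(200):
            s = ar.generate_risk_surface(adj, cfg, seed=2000 + rep)
            vu, vv = s["u"].var(ddof=0), s["v"].var(ddof=0)
            fracs.append(vu / (vu + vv))
        assert abs(np.mean(fracs) - 0.9) < 0.05

    def test_disconnected_with_spatial_effect_errors(self):
        adj = ar.Adjacency(list("abcd"), {"a": {"b"}, "b": {"a"}, "c": {"d"}, "d": {"c"}})
        cfg = ar.ScenarioConfig(n_areas=4, sigma_u=0.5)
        with pytest.raises(ValueError, match="components"):
            ar.generate_risk_surface(adj, cfg, seed=1)


class TestReferenceRates:
    def test_monotone_in_age_within_sex(self):
        rates = ar.make_reference_rates(["y", "o"], ["F", "M"])
        for sex in ("F", "M"):
            r = rates[rates["sex"] == sex].set_index("age_band")["rate"]
            assert r["o"] >= r["y"]

    def test_neutral_income_gradient(self):
        rates = ar.make_reference_rates(["y"], ["F"], n_income_quintiles=5, income_gradient=1.0)
        assert rates["rate"].nunique() == 1

    def test_gradient_ratio_exact(self):
        rates = ar.make_reference_rates(
            ["y", "o"], ["F", "M"], n_income_quintiles=5, income_gradient=2.0
        )
        for (_, _), grp in rates.groupby(["age_band", "sex"]):
            g = grp.set_index("income_quintile")["rate"]
            assert g[1] / g[5] == pytest.approx(2.0)


class TestSimulateCases:
    def _setup(self, n=36, **kw):
        cfg = ar.ScenarioConfig(n_areas=n, **kw)
        layer = ar.generate_geometry(n, seed=1)
        adj = ar.build_adjacency(layer)
        pop = ar.generate_population(layer, cfg, seed=2)
        rates = ar.make_reference_rates(cfg.age_bands, cfg.sexes, base_rate=cfg.base_rate)
        surf = ar.generate_risk_surface(adj, cfg, seed=3)
        return cfg, pop, rates, surf

    def test_zero_rates_give_zero_cases(self):
        cfg, pop, rates, surf = self._setup()
        rates = rates.assign(rate=0.0)
        cases = ar.simulate_cases(pop, rates, surf, seed=4)
        assert (cases["cases"] == 0).all()

    def test_negative_rate_rejected(self):
        cfg, pop, rates, surf = self._setup()
        with pytest.raises(ValueError):
            ar.simulate_cases(pop, rates.assign(rate=-1.0), surf, seed=4)

    def test_mean_total_matches_poisson_mean(self):
        cfg, pop, rates, surf = self._setup(sigma_u=0.3, sigma_v=0.1)
        from arealrisk.standardization import expected_counts

        e = expected_counts(pop, rates)
        target = float((e * surf.set_index("area_id").loc[e.index, "theta_true"]).sum())
        totals = [
            ar.simulate_cases(pop, rates, surf, seed=5000 + r)["cases"].sum()
            for r in range(1000)
        ]
        se = np.sqrt(target / 1000)  # Poisson variance of the grand total
        assert abs(np.mean(totals) - target) < 3 * se

    def test_doubling_risk_increases_totals(self):
        cfg, pop, rates, surf = self._setup()
        surf2 = surf.assign(theta_true=surf["theta_true"] * 2)
        wins = sum(
            ar.simulate_cases(pop, rates, surf2, seed=r)["cases"].sum()
            > ar.simulate_cases(pop, rates, surf, seed=r)["cases"].sum()
            for r in range(200)
        )
        from scipy import stats

        # sign test: doubled-risk totals stochastically larger
        assert stats.binomtest(wins, 200, 0.5, alternative="greater").pvalue < 0.01

    def test_generator_determinism_bit_identical(self):
        cfg = ar.ScenarioConfig(n_areas=25, sigma_u=0.2, sigma_v=0.1, seed=77)
        a = ar.simulate_study(cfg).strata
        b = ar.simulate_study(cfg).strata
        pd.testing.assert_frame_equal(a, b)


def test_planted_cluster_sir_ratio_converges_to_multiplier():
    """With large expected counts the mean SIR inside/outside a planted
    multiplier-2 cluster approaches 2."""
    adj = lattice_adjacency(10, 10)
    layer = grid_layer(10, 10)
    cfg = ar.ScenarioConfig(
        n_areas=100,
        population_range=(2000, 2000),
        base_rate=0.0062,  # E ~= 50 per area at this population
        cluster_spec=ar.ClusterSpec(adj.ids[44], 1, 2.0),
    )
    pop = ar.generate_population(layer, cfg, seed=1)
    rates = ar.make_reference_rates(cfg.age_bands, cfg.sexes, base_rate=cfg.base_rate)
    surf = ar.generate_risk_surface(adj, cfg, seed=2)
    from arealrisk.standardization import expected_counts

    e = expected_counts(pop, rates).loc[adj.ids].to_numpy()
    assert 40 < e.mean() < 60
    member = surf["cluster_member"].to_numpy()
    ratios = []
    for rep in range(100):
        cases = ar.simulate_cases(pop, rates, surf, seed=300 + rep)
        y = cases.groupby("area_id")["cases"].sum().loc[adj.ids].to_numpy()
        sir = y / e
        ratios.append(sir[member].mean() / sir[~member].mean())
    assert abs(np.mean(ratios) - 2.0) < 0.2
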