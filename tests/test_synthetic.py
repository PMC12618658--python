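"""The synthetic world: determinism, statistical structure, file roundtrips."""

import numpy as np
import pytest

from pncmap import (
    TruthParams,
    WorldConfig,
    gen_covariate_world,
    gen_station_records,
    gen_truth_pnc,
    harmonize_records,
    integrate_pnc,
)
from pncmap.fusion import CovariateStack, FEATURE_NAMES
from pncmap.stationio import (
    read_pnc_text,
    read_psd_netcdf,
    write_pnc_text,
    write_psd_netcdf,
)
from pncmap.synthetic import make_nonlinear_regression
from pncmap.ufp import fit_beta

SMALL = dict(nx=40, ny=40, n_stations=12, n_clusters=4, years=(2015,))


class TestCovariateWorld:
    def test_seeded_determinism(self):
        config = WorldConfig(seed=11, **SMALL)
        a = gen_covariate_world(config)
        b = gen_covariate_world(config)
        for name in FEATURE_NAMES:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])
        np.testing.assert_array_equal(a.sea_mask, b.sea_mask)

    def test_nonnegative_layers(self):
        stack = gen_covariate_world(WorldConfig(seed=2, **SMALL))
        for name in ("population", "built_up_volume", "road_network",
                     "bc_emission", "co_emission", "co2_emission", "nox_emission"):
            assert np.all(stack.layers[name] >= 0), name

    def test_population_correlates_with_no2(self):
        corrs = []
        for seed in range(10):
            config = WorldConfig(seed=seed, nx=200, ny=200, n_stations=10,
                                 n_clusters=5, coarse_factor=10, years=(2015,))
            stack = gen_covariate_world(config)
            corrs.append(
                np.corrcoef(
                    stack.layers["population"].ravel(), stack.layers["no2"].ravel()
                )[0, 1]
            )
        assert all(c > 0.3 for c in corrs), corrs

    def test_emissions_block_constant_before_downscaling(self):
        config = WorldConfig(seed=3, **SMALL)
        stack = gen_covariate_world(config)
        f = config.coarse_factor
        bc = stack.layers["bc_emission"]
        blocks = bc.reshape(bc.shape[0] // f, f, bc.shape[1] // f, f)
        assert np.all(blocks == blocks[:, :1, :, :1])

    def test_world_spans_both_population_thresholds(self):
        stack = gen_covariate_world(WorldConfig(seed=4, **SMALL))
        pop = stack.layers["population"][stack.land_mask]
        for limit in (250.0, 800.0):
            assert np.any(pop > limit) and np.any(pop < limit)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(nx=0, ny=40)
        with pytest.raises(ValueError):
            WorldConfig(nx=41, ny=40, coarse_factor=10)


class TestTruthSurface:
    def test_zero_slopes_give_constant_field(self):
        stack = gen_covariate_world(WorldConfig(seed=5, **SMALL))
        params = TruthParams(b0=8.0, b1=0, b2=0, b3=0, b4=0, b5=0)
        truth = gen_truth_pnc(stack, params)
        np.testing.assert_allclose(truth.pnc_true, np.exp(8.0))

    def test_monotone_in_built_up_volume(self):
        stack = gen_covariate_world(WorldConfig(seed=5, **SMALL))
        layers = {n: np.ones_like(stack.layers[n]) for n in FEATURE_NAMES}
        layers["built_up_volume"] = np.ones_like(layers["built_up_volume"])
        layers["built_up_volume"][0, 0] = 1000.0
        flat = CovariateStack(
            grid=stack.grid, layers=layers, sea_mask=np.zeros_like(stack.sea_mask),
            emissions_downscaled=True,
        )
        truth = gen_truth_pnc(flat, TruthParams(b1=0.3))
        assert truth.pnc_true[0, 0] > truth.pnc_true[1, 1]

    def test_populated_cells_have_higher_latent_pnc(self):
        ok = []
        for seed in range(10):
            config = WorldConfig(seed=seed, nx=60, ny=60, n_stations=10,
                                 n_clusters=5, years=(2015,))
            stack = gen_covariate_world(config)
            truth = gen_truth_pnc(stack)
            pop, land = stack.layers["population"], stack.land_mask
            hi = truth.pnc_true[(pop > 800) & land]
            lo = truth.pnc_true[(pop < 250) & land]
            ok.append(hi.mean() > lo.mean())
        assert all(ok)

    def test_non_finite_coefficient_rejected(self):
        stack = gen_covariate_world(WorldConfig(seed=5, **SMALL))
        with pytest.raises(ValueError):
            gen_truth_pnc(stack, TruthParams(b1=np.nan))


class TestStationRecords:
    def test_no_dropout_gives_full_years(self):
        config = WorldConfig(seed=6, flag_invalid_rate=0.0, day_dropout_rate=0.0,
                             nx=40, ny=40, n_stations=4, n_clusters=3,
                             years=(2015, 2016))
        stack = gen_covariate_world(config)
        truth = gen_truth_pnc(stack)
        records, registry, _ = gen_station_records(truth, stack, config)
        import pandas as pd

        df = pd.DataFrame(
            {"sid": [r.station_id for r in records],
             "day": [r.timestamp.floor("D") for r in records]}
        )
        df["year"] = [d.year for d in df["day"]]
        counts = df.groupby(["sid", "year"])["day"].nunique()
        assert set(counts.values) == {365, 366}  # 2016 is a leap year

    def test_generator_consistent_with_integrator(self, world):
        """Harmonized annual means recover the latent truth at station cells."""
        reg = world.registry.set_index("station_id")
        n_checked = 0
        for obs in world.observations:
            row = reg.loc[obs.station_id]
            base = world.truth.pnc_true[int(row["row"]), int(row["col"])]
            # lognormal day/year factors: s.e. of the annual mean plus the
            # station-year factor spread, on the log scale
            sigma = np.sqrt(
                world.config.year_sigma**2
                + world.config.day_sigma**2 / obs.n_unique_days
            )
            assert abs(np.log(obs.pnc_annual / base)) < 3.5 * sigma
            n_checked += 1
        assert n_checked >= 60

    def test_generated_fractions_recover_beta_parameters(self, world):
        assert world.fractions.size >= 5000
        model = fit_beta(world.fractions)
        assert abs(model.alpha - 18.75) / 18.75 < 0.10
        assert abs(model.beta - 1.89) / 1.89 < 0.10

    def test_fraction_mean_calibrated(self, world):
        assert world.fractions.size >= 2000
        expect = 18.75 / (18.75 + 1.89)
        assert abs(world.fractions.mean() - expect) < 0.02

    def test_psd_records_integrate_to_positive_totals(self, world):
        psd = next(r for r in world.records if r.kind == "PSD")
        assert integrate_pnc(psd.values, world.size_grid) > 0

    def test_empty_years_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(years=())


class TestStationFileDialects:
    def test_psd_netcdf_roundtrip(self, tmp_path, world):
        recs = [r for r in world.records if r.kind == "PSD"][:10]
        path = write_psd_netcdf(
            tmp_path / "st.nc", "ST900", 41.0, 11.0,
            [r.timestamp for r in recs], world.size_grid,
            np.vstack([r.values for r in recs]), [r.flag for r in recs],
        )
        back, grid, meta = read_psd_netcdf(path)
        assert meta == {"station_id": "ST900", "lat": 41.0, "lon": 11.0}
        np.testing.assert_allclose(grid.diameters, world.size_grid.diameters)
        assert len(back) == 10
        np.testing.assert_allclose(back[3].values, recs[3].values)
        assert back[3].timestamp == recs[3].timestamp
        assert back[3].flag == recs[3].flag

    def test_pnc_text_roundtrip(self, tmp_path):
        import pandas as pd

        times = pd.date_range("2015-03-01", periods=4, freq="D", tz="UTC")
        path = write_pnc_text(
            tmp_path / "st.nas", "ST901", 42.5, 12.5, times,
            [1000.0, 2000.0, 1500.0, 900.0], [0, 0, 9, 0],
        )
        back, meta = read_pnc_text(path)
        assert meta["station_id"] == "ST901"
        assert meta["lat"] == pytest.approx(42.5)
        assert [float(r.values[0]) for r in back] == [1000.0, 2000.0, 1500.0, 900.0]
        assert [r.flag for r in back] == [0.0, 0.0, 9.0, 0.0]

    def test_harmonizer_reads_generated_files(self, tmp_path, world):
        from pncmap.synthetic import write_station_files

        sub = world.registry.iloc[:4]
        recs = [r for r in world.records if r.station_id in set(sub["station_id"])]
        write_station_files(recs, sub, world.size_grid, tmp_path)
        collected, rows, grid = [], [], None
        for path in sorted(tmp_path.iterdir()):
            if path.suffix == ".nc":
                rr, grid, meta = read_psd_netcdf(path)
            else:
                rr, meta = read_pnc_text(path)
            collected.extend(rr)
            rows.append(meta)
        import pandas as pd

        obs, _, fr = harmonize_records(collected, pd.DataFrame(rows), grid)
        expect = {o.station_id for o in world.observations} & set(sub["station_id"])
        assert {o.station_id for o in obs} == expect


class TestNonlinearRegressionBenchmark:
    def test_seeded_and_shaped(self):
        X1, y1 = make_nonlinear_regression(100, seed=5)
        X2, y2 = make_nonlinear_regression(100, seed=5)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)
        assert X1.shape == (100, 5) and y1.shape == (100,)
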