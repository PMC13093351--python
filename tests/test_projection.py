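"""Raster projection, latitude regressions, binning, and the pipeline."""

import numpy as np
import pandas as pd
import pytest

from genoffset import synthetic as syn
from genoffset.climate_io import (Raster, RasterSet, bilinear_extract,
                                  fit_scaler)
from genoffset.offset_lfmm import genetic_gap
from genoffset.projection import (PipelineConfig, _tier, bin_offsets,
                                  project_offsets, regress_offset_latitude,
                                  run_pipeline)
from genoffset.synthetic import CLIMATE_VARS


@pytest.fixture(scope="module")
def projection_inputs(request):
    """Current + future raster sets, mask, scaler and a small B matrix."""
    design = syn.generate_design(n_pairs=3, latitude_range=(-50, -44), seed=0)
    cfg = syn.default_climate_config()
    trees, rs_cur, dem = syn.generate_climate(design, cfg, seed=0,
                                              n_per_site=10)
    scaler = fit_scaler(trees, variables=list(CLIMATE_VARS))
    rs_fut = syn.generate_future(rs_cur, "ssp370_mid", cfg, elevation=dem)
    mask = dem.copy_with((dem.data >= 200.0).astype(float))
    rng = np.random.default_rng(1)
    B = rng.normal(scale=0.1, size=(5, 20))
    return {"cur": rs_cur, "fut": rs_fut, "mask": mask, "dem": dem,
            "scaler": scaler, "B": B, "design": design, "cfg": cfg}


class TestProjectOffsets:
    def test_future_equals_current_gives_zero_raster(self, projection_inputs):
        pi = projection_inputs
        out = project_offsets(pi["cur"], pi["cur"], pi["mask"], pi["scaler"],
                              lfmm_B=pi["B"])
        vals = out["lfmm"].data
        inside = np.isfinite(vals)
        assert inside.any()
        assert np.allclose(vals[inside], 0.0)
        assert np.isnan(vals[pi["mask"].data == 0]).all()

    def test_cell_value_matches_direct_vector_computation(
            self, projection_inputs):
        pi = projection_inputs
        out = project_offsets(pi["cur"], pi["fut"], pi["mask"], pi["scaler"],
                              lfmm_B=pi["B"])
        i, j = np.argwhere(np.isfinite(out["lfmm"].data))[0]
        cur_tab = pd.DataFrame(
            {v: [pi["cur"][v].data[i, j]] for v in CLIMATE_VARS})
        fut_tab = pd.DataFrame(
            {v: [pi["fut"][v].data[i, j]] for v in CLIMATE_VARS})
        e0 = pi["scaler"].transform_table(cur_tab).to_numpy()[0]
        e1 = pi["scaler"].transform_table(fut_tab).to_numpy()[0]
        assert out["lfmm"].data[i, j] == pytest.approx(
            genetic_gap(pi["B"], e0, e1))

    def test_fully_masked_warns_all_nodata(self, projection_inputs):
        pi = projection_inputs
        empty = pi["mask"].copy_with(np.zeros(pi["mask"].shape))
        with pytest.warns(UserWarning, match="mask"):
            out = project_offsets(pi["cur"], pi["fut"], empty, pi["scaler"],
                                  lfmm_B=pi["B"])
        assert np.isnan(out["lfmm"].data).all()

    def test_misaligned_grids_rejected(self, projection_inputs):
        pi = projection_inputs
        t = pi["cur"].template()
        shifted = RasterSet({v: Raster(pi["fut"][v].data, t.west + 1.0,
                                       t.north, t.dx, t.dy)
                             for v in CLIMATE_VARS}, scenario="x")
        with pytest.raises(ValueError, match="aligned"):
            project_offsets(pi["cur"], shifted, pi["mask"], pi["scaler"],
                            lfmm_B=pi["B"])

    def test_novelty_flags_out_of_envelope_cells(self, projection_inputs):
        pi = projection_inputs
        out = project_offsets(pi["cur"], pi["fut"], pi["mask"], pi["scaler"],
                              lfmm_B=pi["B"])
        nov = out["novelty"].data
        finite = np.isfinite(nov)
        # future warming pushes some cells beyond the training envelope
        assert set(np.unique(nov[finite])) <= {0.0, 1.0}
        assert nov[finite].sum() > 0

    def test_elevation_dependent_warming_hits_high_cells_hardest(
            self, projection_inputs):
        """With elevation-dependent warming, the top elevation quartile of
        the range carries a larger mean projected offset than the bottom."""
        pi = projection_inputs
        out = project_offsets(pi["cur"], pi["fut"], pi["mask"], pi["scaler"],
                              lfmm_B=pi["B"])
        vals, dem = out["lfmm"].data, pi["dem"].data
        finite = np.isfinite(vals)
        q1, q3 = np.quantile(dem[finite], [0.25, 0.75])
        assert (vals[finite & (dem >= q3)].mean()
                > vals[finite & (dem <= q1)].mean())


class TestRegression:
    def test_perfectly_collinear_r2_one(self):
        design = syn.generate_design(n_pairs=3, latitude_range=(-50, -44),
                                     seed=0)
        sm = pd.DataFrame({
            "site_id": design.sites["site_id"],
            "mean_offset": 2.0 + 3.0 * design.sites["latitude"],
        })
        res = regress_offset_latitude(sm, design, group_by=None)
        assert res[0].r_squared == pytest.approx(1.0)
        assert res[0].slope == pytest.approx(3.0)

    def test_five_point_closed_form_oracle(self):
        design = syn.generate_design(n_pairs=3, latitude_range=(-50, -44),
                                     seed=1)
        lat = design.sites["latitude"].to_numpy()[:5]
        rng = np.random.default_rng(2)
        y = 1.0 - 0.5 * lat + rng.normal(0, 0.3, 5)
        sm = pd.DataFrame({"site_id": design.sites["site_id"].iloc[:5],
                           "mean_offset": y})
        sub = design.sites.iloc[:5]
        res = regress_offset_latitude(sm, syn.SamplingDesign(sub),
                                      group_by=None)[0]
        # normal-equation oracle
        X = np.column_stack([np.ones(5), lat])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        ss_res, ss_tot = (resid ** 2).sum(), ((y - y.mean()) ** 2).sum()
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_significance_tiers(self):
        assert _tier(0.04) == "solid"
        assert _tier(0.07) == "dashed"
        assert _tier(0.2) == "none"
        assert _tier(0.05) == "solid" and _tier(0.1) == "dashed"

    def test_small_group_rejected(self):
        design = syn.generate_design(n_pairs=1, latitude_range=(-48, -46),
                                     seed=0)
        sm = pd.DataFrame({"site_id": design.sites["site_id"],
                           "mean_offset": [1.0, 2.0]})
        with pytest.raises(ValueError, match="need >= 3"):
            regress_offset_latitude(sm, design, group_by=None)

    def test_constant_latitude_rejected(self):
        design = syn.generate_design(n_pairs=3, latitude_range=(-50, -44),
                                     seed=0)
        sites = design.sites.copy()
        sites["latitude"] = -45.0
        sm = pd.DataFrame({"site_id": sites["site_id"],
                           "mean_offset": np.arange(6.0)})
        bad = syn.SamplingDesign.__new__(syn.SamplingDesign)
        bad.sites = sites
        with pytest.raises(ValueError, match="constant"):
            regress_offset_latitude(sm, bad, group_by=None)


class TestBinOffsets:
    def make(self, values):
        a = np.asarray(values, dtype=float).reshape(1, -1)
        return Raster(a, west=0, north=1, dx=1, dy=1)

    def test_constant_raster_single_class(self):
        with pytest.warns(UserWarning, match="single bin"):
            classed, legend = bin_offsets(self.make([2.0] * 8), n_bins=4)
        assert np.unique(classed.data[np.isfinite(classed.data)]) == [1.0]
        assert len(legend) == 1

    def test_hand_equal_width_binning(self):
        classed, legend = bin_offsets(self.make([1, 2, 3, 4, 5, 6, 7, 8]),
                                      n_bins=4, scheme="equal")
        assert classed.data.ravel().tolist() == [1, 1, 2, 2, 3, 3, 4, 4]
        assert len(legend) == 4

    def test_monotone_class_assignment(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=64)
        classed, _ = bin_offsets(self.make(vals), n_bins=8)
        order = np.argsort(vals)
        classes = classed.data.ravel()[order]
        assert (np.diff(classes) >= 0).all()

    def test_nodata_preserved(self):
        vals = [1.0, np.nan, 3.0, 4.0]
        classed, _ = bin_offsets(self.make(vals), n_bins=2)
        assert np.isnan(classed.data.ravel()[1])


@pytest.fixture(scope="module")
def small_config(tmp_path_factory):
    return PipelineConfig(seed=42, n_neutral=400, n_adaptive=50,
                          gf_trees=30,
                          outdir=str(tmp_path_factory.mktemp("pipe")))


@pytest.fixture(scope="module")
def manifest(small_config):
    return run_pipeline(small_config)


class TestPipeline:
    def test_all_scenario_rasters_written(self, manifest):
        # 3 SSPs × 2 periods: offset raster pair per method + novelty
        for method in ("lfmm", "gf"):
            rasters = [k for k in manifest["checksums"]
                       if k.startswith(f"offset_{method}_")]
            assert len(rasters) == 6
        assert manifest["n_scenarios"] == 6

    def test_rerun_identical_checksums(self, small_config, manifest,
                                       tmp_path):
        import dataclasses
        cfg2 = dataclasses.replace(small_config, outdir=str(tmp_path))
        m2 = run_pipeline(cfg2)
        assert m2["checksums"] == manifest["checksums"]

    def test_site_table_and_regressions_exist(self, small_config, manifest):
        from pathlib import Path
        out = Path(small_config.outdir)
        site = pd.read_csv(out / "site_mean_offsets.tsv", sep="\t")
        assert set(site["method"]) == {"lfmm", "gf"}
        assert site["scenario"].nunique() == 6
        reg = pd.read_csv(out / "regressions.tsv", sep="\t")
        assert set(reg["tier"]) <= {"solid", "dashed", "none"}

    def test_config_missing_field_named(self):
        with pytest.raises(ValueError, match="n_pairs"):
            PipelineConfig.from_dict({"seed": 1, "n_per_site": 5,
                                      "n_neutral": 10, "n_adaptive": 1,
                                      "K": 3})

    def test_config_unknown_scenario_named(self):
        with pytest.raises(ValueError, match="scenarios"):
            PipelineConfig.from_dict({
                "seed": 1, "n_pairs": 3, "n_per_site": 5, "n_neutral": 10,
                "n_adaptive": 1, "K": 3, "scenarios": ["rcp85"]})


class TestSiteRasterConsistency:
    def test_projected_raster_agrees_with_tree_offsets_on_smooth_fields(self):
        """Extracting the projected offset raster at tree positions and
        averaging per site matches per-tree offsets computed from
        raster-extracted climate (smooth noiseless fields)."""
        design = syn.generate_design(n_pairs=3, latitude_range=(-50, -44),
                                     seed=4)
        cfg = syn.default_climate_config()
        for fld in cfg.fields.values():
            fld.noise_sd = 0.0
            fld.micro_sd = 0.0
            fld.elev_slope = 0.0  # decouple from the (rough) DEM surface
        trees, rs_cur, dem = syn.generate_climate(design, cfg, seed=4,
                                                  n_per_site=5)
        scaler = fit_scaler(trees, variables=list(CLIMATE_VARS))
        rs_fut = syn.generate_future(rs_cur, "ssp126_mid", cfg, elevation=dem)
        dem_at_trees = bilinear_extract(dem, trees["longitude"],
                                        trees["latitude"]).values
        fut_trees = syn.generate_future(trees, "ssp126_mid", cfg,
                                        elevation=dem_at_trees)
        rng = np.random.default_rng(5)
        B = rng.normal(scale=0.1, size=(5, 10))
        mask = dem.copy_with(np.ones(dem.shape))
        out = project_offsets(rs_cur, rs_fut, mask, scaler, lfmm_B=B)
        at_trees = bilinear_extract(out["lfmm"], trees["longitude"],
                                    trees["latitude"]).values
        E0 = scaler.transform_table(trees)[list(CLIMATE_VARS)].to_numpy()
        E1 = scaler.transform_table(fut_trees)[list(CLIMATE_VARS)].to_numpy()
        direct = genetic_gap(B, E0, E1)
        assert np.corrcoef(at_trees, direct)[0, 1] > 0.99
        np.testing.assert_allclose(at_trees, direct, rtol=0.15, atol=1e-4)
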