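"""Layer targets, splitting, covariate augmentation and the experiment grid."""

import numpy as np
import pandas as pd
import pytest

import salspec
from salspec.metrics import r_squared
from salspec.model import (
    RESULT_COLUMNS,
    GridConfig,
    SampleRecord,
    augment_with_covariates,
    compute_targets,
    layer_targets,
    run_experiment_grid,
    split_dataset,
)
from salspec.pls import fit_plsr
from salspec.preprocess import Spectrum
from salspec.selection import CARSParams, RFAParams, VIPParams


class TestLayerTargets:
    def test_uniform_profile_collapses_to_single_value(self):
        assert layer_targets((2.0, 2.0, 2.0)) == {"S1": 2.0, "S2": 2.0, "S3": 2.0}

    def test_cumulative_averages(self):
        out = layer_targets((2.89, 3.23, 3.10))
        assert out["S1"] == pytest.approx(2.89)
        assert out["S2"] == pytest.approx(3.06)
        assert out["S3"] == pytest.approx(3.0733, abs=1e-4)

    def test_partial_profile_serves_shallow_targets_only(self):
        assert layer_targets((2.44,), layers=("S1",)) == {"S1": 2.44}
        with pytest.raises(ValueError):
            layer_targets((2.44,), layers=("S2",))

    def test_frame_version_matches_scalar_version(self):
        df = pd.DataFrame({"ec_0_20": [2.89], "ec_20_40": [3.23], "ec_40_60": [3.10]})
        out = compute_targets(df)
        assert out.loc[0, "S2"] == pytest.approx(3.06)


class TestSampleRecord:
    @staticmethod
    def _spectrum():
        return Spectrum(np.arange(400.0, 500.0), np.full(100, 0.3))

    def test_valid_record_constructs(self):
        r = SampleRecord("a", "T1", 76, self._spectrum(), 50.0, 40.0, 0.8, (2.0, 2.1, 2.2))
        assert r.treatment == "T1"

    @pytest.mark.parametrize(
        "kw",
        [
            {"H": -1.0},
            {"AGB": -0.1},
            {"SWC": 1.2},
            {"ec_layers": (0.0, 2.0, 2.0)},
        ],
    )
    def test_invalid_fields_rejected(self, kw):
        base = dict(
            sample_id="a", treatment="T1", stage_das=76, spectrum=self._spectrum(),
            H=50.0, AGB=40.0, SWC=0.8, ec_layers=(2.0, 2.1, 2.2),
        )
        base.update(kw)
        with pytest.raises(ValueError):
            SampleRecord(**base)


class TestSplit:
    @staticmethod
    def _samples(n_per_stage=28):
        stages = np.repeat([76, 111, 124, 142, 162], n_per_stage)
        treatments = np.tile(np.repeat(["T1", "T2", "T3", "T4"], n_per_stage // 4), 5)
        return pd.DataFrame({"stage_das": stages, "treatment": treatments})

    def test_default_layout_gives_100_40(self):
        cal, val = split_dataset(self._samples(), 20, seed=0)
        assert cal.size == 100 and val.size == 40
        assert np.intersect1d(cal, val).size == 0
        assert np.union1d(cal, val).size == 140

    def test_per_stage_counts(self):
        s = self._samples()
        cal, _ = split_dataset(s, 20, seed=1)
        counts = s.iloc[cal].groupby("stage_das").size()
        assert (counts == 20).all()

    def test_reproducible_and_seed_sensitive(self):
        s = self._samples()
        a1, _ = split_dataset(s, 20, seed=5)
        a2, _ = split_dataset(s, 20, seed=5)
        b, _ = split_dataset(s, 20, seed=6)
        np.testing.assert_array_equal(a1, a2)
        assert not np.array_equal(a1, b)

    def test_insufficient_stage_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._samples(16), 20, seed=0)

    def test_validation_treatment_balance_over_draws(self):
        # each stage keeps 8 of 28 for validation; per treatment the expected
        # count is 2, and the average over 50 draws should sit near it
        s = self._samples()
        counts = []
        for seed in range(50):
            _, val = split_dataset(s, 20, seed=seed)
            counts.append(s.iloc[val].groupby("treatment").size() / 5.0)
        mean = pd.concat(counts, axis=1).mean(axis=1)
        assert ((mean > 1.5) & (mean < 2.5)).all()


class TestAugment:
    @staticmethod
    def _samples(n=30, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "H_cm": rng.uniform(30, 90, n),
                "AGB_g": rng.uniform(20, 120, n),
                "SWC_frac": rng.uniform(0.6, 0.85, n),
            }
        )

    def test_empty_covariates_is_identity(self):
        X = np.random.default_rng(0).random((30, 5))
        out, _ = augment_with_covariates(X, self._samples(), ())
        np.testing.assert_array_equal(out, X)

    def test_column_count_and_training_statistics(self):
        s = self._samples()
        X = np.zeros((30, 4))
        out, stats = augment_with_covariates(X, s, ("H", "SWC"))
        assert out.shape == (30, 6)
        np.testing.assert_allclose(out[:, 4].mean(), 0, atol=1e-12)
        np.testing.assert_allclose(out[:, 4].std(), 1, atol=1e-12)
        # transforming new rows with the training stats must reuse them
        out2, _ = augment_with_covariates(X[:5], s.iloc[:5], ("H", "SWC"), stats=stats)
        expected = (s["H_cm"].iloc[:5] - stats["mean"][0]) / stats["sd"][0]
        np.testing.assert_allclose(out2[:, 4], expected)

    def test_missing_covariate_rejected(self):
        with pytest.raises(KeyError):
            augment_with_covariates(np.zeros((30, 2)), self._samples(), ("LAI",))

    def test_leakage_probe_target_as_covariate(self):
        # a covariate equal to the response must produce near-perfect
        # validation accuracy — sanity check that covariates reach the model
        rng = np.random.default_rng(1)
        n = 60
        X = 0.01 * rng.standard_normal((n, 10))  # reflectance-scale distractors
        y = rng.uniform(2, 4, n)
        s = pd.DataFrame({"H_cm": y})
        Xa, stats = augment_with_covariates(X[:40], s.iloc[:40], ("H",))
        from salspec.pls import best_lv

        lv, _, _ = best_lv(Xa, y[:40], max_lv=8, folds=5, seed=0)
        m = fit_plsr(Xa, y[:40], lv)
        Xv, _ = augment_with_covariates(X[40:], s.iloc[40:], ("H",), stats=stats)
        assert r_squared(y[40:], m.predict(Xv)) >= 0.999


FAST_GRID = dict(
    cars=CARSParams(n_runs=10),
    rfa=RFAParams(n_chain_iters=60, burn_in=20, n_restarts=2),
    vip=VIPParams(),
    max_lv=6,
)


def _small_dataset(seed=0, n_reps=7):
    ds = salspec.generate_dataset(seed=seed)
    # thin the band axis to keep selector runs quick; grid spacing stays even
    return ds.samples, ds.wavelengths[::10], ds.reflectance[:, ::10]


class TestExperimentGrid:
    def test_single_cell_produces_one_finite_row(self):
        samples, wl, refl = _small_dataset()
        cfg = GridConfig(preprocessings=("R",), selectors=("full",),
                         covariate_sets=((),), layers=("S1",), **FAST_GRID)
        tab = run_experiment_grid(samples, wl, refl, cfg, seed=0)
        assert len(tab) == 1
        row = tab.iloc[0]
        for col in ("LV", "R2_C", "RMSE_C", "R2_V", "RMSE_V", "LCCC"):
            assert np.isfinite(row[col])

    def test_full_grid_has_96_cells_with_schema(self):
        samples, wl, refl = _small_dataset()
        cfg = GridConfig(**FAST_GRID)  # 2 x 4 x 4 x 3 defaults
        tab = run_experiment_grid(samples, wl, refl, cfg, seed=1)
        assert len(tab) == 96
        assert tab.columns.tolist()[: len(RESULT_COLUMNS)] == RESULT_COLUMNS
        assert not tab[["LV", "R2_C", "RMSE_C", "R2_V", "RMSE_V", "LCCC"]].isna().any().any()
        # selection reduces the band count in every selector cell
        sel_rows = tab[tab.selector != "full"]
        assert (sel_rows["n_spectral"] < refl[:, :].shape[1]).all()

    def test_deterministic_given_seed(self):
        samples, wl, refl = _small_dataset()
        cfg = GridConfig(preprocessings=("FDR",), selectors=("full", "CARS"),
                         covariate_sets=((), ("H",)), layers=("S2",), **FAST_GRID)
        t1 = run_experiment_grid(samples, wl, refl, cfg, seed=3)
        t2 = run_experiment_grid(samples, wl, refl, cfg, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_cell_spec_rejected(self):
        samples, wl, refl = _small_dataset()
        with pytest.raises(ValueError):
            run_experiment_grid(samples, wl, refl,
                                GridConfig(selectors=("GA",), **FAST_GRID), seed=0)
        with pytest.raises(ValueError):
            run_experiment_grid(samples, wl, refl,
                                GridConfig(layers=("S4",), **FAST_GRID), seed=0)

    def test_no_validation_leakage_into_calibration_metrics(self):
        # perturbing the validation rows' soil measurements must leave the
        # calibration metrics and the selected bands untouched
        samples, wl, refl = _small_dataset()
        cfg = GridConfig(preprocessings=("FDR",), selectors=("VIP",),
                         covariate_sets=((),), layers=("S2",), **FAST_GRID)
        base, sels = run_experiment_grid(samples, wl, refl, cfg, seed=7,
                                         return_selections=True)
        from salspec.model import _stage_seed
        _, val = split_dataset(compute_targets(samples), 20,
                               seed=_stage_seed(7, "split"))
        perturbed = samples.copy()
        rng = np.random.default_rng(0)
        for col in ("ec_0_20", "ec_20_40", "ec_40_60"):
            vals = perturbed[col].to_numpy().copy()
            vals[val] = rng.permutation(vals[val])
            perturbed[col] = vals
        out, sels2 = run_experiment_grid(perturbed, wl, refl, cfg, seed=7,
                                         return_selections=True)
        for col in ("LV", "R2_C", "RMSE_C"):
            assert out.iloc[0][col] == pytest.approx(base.iloc[0][col], abs=1e-12)
        k = ("FDR", "S2", "VIP")
        np.testing.assert_array_equal(sels[k].support, sels2[k].support)
        # validation metrics, by contrast, must move
        assert out.iloc[0]["R2_V"] != pytest.approx(base.iloc[0]["R2_V"], abs=1e-6)
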