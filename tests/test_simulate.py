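"""Synthetic cotton-field generator: structure, determinism, couplings."""

import numpy as np
import pandas as pd
import pytest

import salspec
from salspec.model import compute_targets, preprocess_matrix, GridConfig
from salspec.preprocess import bandwise_correlation
from salspec.simulate import (
    SyntheticConfig,
    generate_dataset,
    generate_growth,
    generate_salinity,
    generate_spectra,
    _baseline_curve,
)


class TestSalinity:
    def test_default_layout_is_140_records(self):
        ec = generate_salinity(SyntheticConfig(), seed=0)
        assert len(ec) == 140
        assert ec.groupby(["treatment", "stage_das"]).size().eq(7).all()

    def test_zero_scatter_reproduces_configured_means(self):
        cfg = SyntheticConfig(ec_sd=0.0)
        ec = generate_salinity(cfg, seed=1)
        for ti, trt in enumerate(cfg.treatments):
            for si, das in enumerate(cfg.stages_das):
                sub = ec[(ec.treatment == trt) & (ec.stage_das == das)]
                np.testing.assert_allclose(
                    sub[["ec_0_20", "ec_20_40", "ec_40_60"]].to_numpy(),
                    np.tile(cfg.ec_layer_means[ti, si], (len(sub), 1)),
                )

    def test_configured_trajectory_dips_at_124_das(self):
        # the layer-averaged stage trajectory has its minimum at 124 DAS for
        # every treatment and every cumulative layer
        cfg = SyntheticConfig()
        m = cfg.ec_layer_means
        s1 = m[:, :, 0]
        s2 = m[:, :, :2].mean(axis=2)
        s3 = m.mean(axis=2)
        i124 = cfg.stages_das.index(124)
        for surf in (s1, s2, s3):
            assert (surf.argmin(axis=1) == i124).all()

    def test_treatment_mean_ordering(self):
        cfg = SyntheticConfig()
        pooled_s2 = cfg.ec_layer_means[:, :, :2].mean(axis=2).mean(axis=1)
        order = [cfg.treatments[i] for i in np.argsort(pooled_s2)]
        assert order == ["T2", "T1", "T3", "T4"]

    def test_empirical_means_track_configuration(self):
        cfg = SyntheticConfig(n_reps=250)  # many replicates: tight means
        ec = generate_salinity(cfg, seed=3)
        got = (
            ec.groupby(["treatment", "stage_das"])["ec_0_20"].mean()
            .unstack().to_numpy()
        )
        se = cfg.ec_sd / np.sqrt(250)
        assert np.all(np.abs(got - cfg.ec_layer_means[:, :, 0]) < 4 * se)

    def test_positivity_floor(self):
        cfg = SyntheticConfig(ec_sd=5.0)
        with pytest.warns(UserWarning, match="resampled"):
            ec = generate_salinity(cfg, seed=4)
        assert (ec[["ec_0_20", "ec_20_40", "ec_40_60"]] > 0).all().all()


class TestGrowth:
    def test_noise_free_unattenuated_height_is_exactly_linear_in_s2(self):
        cfg = SyntheticConfig(h_noise_sd=0.0, attenuation=0.0)
        ec = generate_salinity(cfg, seed=0)
        g = compute_targets(generate_growth(cfg, ec, seed=0))
        for _, sub in g.groupby("stage_das"):
            r = np.corrcoef(sub["H_cm"], sub["S2"])[0, 1]
            assert r == pytest.approx(-1.0, abs=1e-10)

    def test_negative_correlations_each_stage(self):
        ds = generate_dataset(seed=42)
        s = compute_targets(ds.samples)
        for col in ("H_cm", "AGB_g", "SWC_frac"):
            for _, sub in s.groupby("stage_das"):
                assert np.corrcoef(sub[col], sub["S2"])[0, 1] < 0

    def test_salinity_coupling_attenuates_with_stage(self):
        ds = generate_dataset(seed=42)
        s = compute_targets(ds.samples)
        rs = [
            np.corrcoef(sub["H_cm"], sub["S2"])[0, 1]
            for _, sub in s.groupby("stage_das")
        ]
        assert rs[0] < rs[-1] < 0  # early coupling is the strongest

    def test_height_plateaus_after_142_das(self):
        # with noise and the salinity coupling off, only the logistic base
        # curve remains, and it is flat past 142 DAS by construction
        cfg = SyntheticConfig(h_noise_sd=0.0, h_sal_slope=0.0, ec_sd=0.0)
        ec = generate_salinity(cfg, seed=0)
        g = generate_growth(cfg, ec, seed=0)
        merged = g.groupby(["treatment", "stage_das"])["H_cm"].mean().unstack()
        np.testing.assert_allclose(merged[142], merged[162], rtol=1e-6)

    def test_swc_stays_a_fraction(self):
        for seed in (0, 1, 2):
            ds = generate_dataset(seed=seed)
            assert ds.samples["SWC_frac"].between(0, 1, inclusive="neither").all()


class TestSpectra:
    def test_grid_is_full_1nm_range(self):
        ds = generate_dataset(seed=0)
        assert ds.wavelengths[0] == 350 and ds.wavelengths[-1] == 2500
        assert ds.reflectance.shape == (140, 2151)
        assert np.all(ds.reflectance >= 0) and np.all(ds.reflectance <= 1.2)

    def test_no_response_no_noise_reduces_to_baseline(self):
        cfg = SyntheticConfig(
            vis_response_rel=0.0, lwir_response_rel=0.0,
            informative_bands=(), noise_components=(),
            canopy_salinity_sd=0.0,
        )
        ec = generate_salinity(cfg, seed=1)
        g = generate_growth(cfg, ec, seed=1)
        wl, refl, _ = generate_spectra(cfg, g, seed=1)
        stage_idx = np.searchsorted(np.asarray(cfg.stages_das), g["stage_das"].to_numpy())
        expected = _baseline_curve(
            wl,
            g["AGB_g"].to_numpy(),
            g["SWC_frac"].to_numpy(),
            np.asarray(cfg.vis_stage_factor)[stage_idx],
            np.asarray(cfg.lwir_stage_factor)[stage_idx],
            agb_ref=0.7 * cfg.agb_max,
        )
        np.testing.assert_allclose(refl, np.clip(expected, 0, 1.2), atol=1e-12)

    def test_treatment_mean_vis_up_lwir_down_with_salinity(self):
        # expectation-level check: treatment means averaged over seeds are
        # strictly ordered by root-zone salinity (T2 < T1 < T3 < T4)
        vis_m, lwir_m = [], []
        for seed in range(1, 9):
            ds = generate_dataset(seed=seed)
            s = compute_targets(ds.samples)
            wl = ds.wavelengths
            vis = (wl >= 400) & (wl <= 780)
            lwir = (wl >= 1100) & (wl <= 2400)
            vis_m.append([ds.reflectance[(s.treatment == t).to_numpy()][:, vis].mean()
                          for t in ("T2", "T1", "T3", "T4")])
            lwir_m.append([ds.reflectance[(s.treatment == t).to_numpy()][:, lwir].mean()
                           for t in ("T2", "T1", "T3", "T4")])
        assert np.all(np.diff(np.mean(vis_m, axis=0)) > 0)
        assert np.all(np.diff(np.mean(lwir_m, axis=0)) < 0)

    def test_fdr_correlation_peaks_near_informative_bands(self):
        cfg = SyntheticConfig()
        centres = np.array([c for c, _ in cfg.informative_bands])
        hits = 0
        for seed in range(1, 11):
            ds = generate_dataset(seed=seed)
            s = compute_targets(ds.samples)
            wl, mats = preprocess_matrix(ds.wavelengths, ds.reflectance, GridConfig())
            _, best, _ = bandwise_correlation(mats["FDR"], s["S2"].to_numpy())
            hits += np.min(np.abs(centres - wl[best])) <= 15.0
        assert hits >= 8

    def test_stronger_salinity_steepens_spectral_response(self):
        # doubling the visible response doubles the salinity-driven contrast
        lo = SyntheticConfig(vis_response_rel=0.05, noise_components=(),
                             canopy_salinity_sd=0.0)
        hi = SyntheticConfig(vis_response_rel=0.10, noise_components=(),
                             canopy_salinity_sd=0.0)
        ec = generate_salinity(SyntheticConfig(ec_sd=0.0), seed=0)
        g = generate_growth(SyntheticConfig(h_noise_sd=0.0), ec, seed=0)
        wl, r_lo, _ = generate_spectra(lo, g, seed=0)
        _, r_hi, _ = generate_spectra(hi, g, seed=0)
        vis = (wl >= 450) & (wl <= 700)
        t2 = (g.treatment == "T2").to_numpy()
        t4 = (g.treatment == "T4").to_numpy()
        gap_lo = r_lo[t4][:, vis].mean() - r_lo[t2][:, vis].mean()
        gap_hi = r_hi[t4][:, vis].mean() - r_hi[t2][:, vis].mean()
        assert gap_hi > 1.5 * gap_lo > 0


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        a = generate_dataset(seed=11)
        b = generate_dataset(seed=11)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in ("samples.csv", "spectra.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_dataset(seed=1)
        b = generate_dataset(seed=2)
        assert not np.array_equal(a.reflectance, b.reflectance)

    def test_write_read_round_trip(self, tmp_path):
        ds = generate_dataset(seed=5)
        ds.write(tmp_path / "d")
        back = salspec.Dataset.read(tmp_path / "d")
        np.testing.assert_array_equal(back.wavelengths, ds.wavelengths)
        np.testing.assert_allclose(back.reflectance, ds.reflectance, atol=1e-12)
        pd.testing.assert_frame_equal(
            back.samples.reset_index(drop=True), ds.samples.reset_index(drop=True),
            check_exact=False, atol=1e-12,
        )
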