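import numpy as np
import pytest

from cortexdyn import (
    PARAMETER_ORDER,
    SyntheticConfig,
    TimeseriesParams,
    dfa_hurst,
    fractional_gaussian_noise,
    make_bilateral_geometry,
    make_geometry,
    morans_i,
    simulate_cohort,
    simulate_parcel_timeseries,
    simulate_smooth_map,
    spearman_map_corr,
    spin_pvalue,
    spin_rotations,
)
from cortexdyn.synthetic import great_circle_distances


class TestMakeGeometry:
    def test_single_parcel_unit_norm(self):
        g = make_geometry(1, seed=3)
        assert g.n_parcels == 1
        assert np.linalg.norm(g.sphere_xyz[0]) == pytest.approx(1.0, abs=1e-9)

    def test_determinism(self):
        g1 = make_geometry(180, seed=1)
        g2 = make_geometry(180, seed=1)
        np.testing.assert_array_equal(g1.sphere_xyz, g2.sphere_xyz)
        np.testing.assert_array_equal(g1.anat_xyz, g2.anat_xyz)

    def test_seeds_differ(self):
        assert not np.allclose(
            make_geometry(50, seed=1).sphere_xyz, make_geometry(50, seed=2).sphere_xyz
        )

    def test_min_pairwise_distance_positive(self):
        # brute-force pairwise scan
        g = make_geometry(180, seed=1)
        d = great_circle_distances(g.sphere_xyz)
        off = d[~np.eye(180, dtype=bool)]
        assert off.min() > 0
        # quasi-uniform: min spacing should be a decent fraction of the
        # mean spacing sqrt(4 pi / n)
        assert off.min() > 0.3 * np.sqrt(4 * np.pi / 180)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            make_geometry(0)

    def test_medial_wall_flags(self):
        g = make_geometry(20, seed=0, medial_wall_fraction=0.2)
        assert g.medial_wall.sum() == 4

    def test_bilateral_pairing(self):
        g, pairs = make_bilateral_geometry(30, seed=2)
        assert g.n_parcels == 60
        assert sorted(pairs.ravel().tolist()) == list(range(60))
        # homotopic pairs mirror in x
        np.testing.assert_allclose(
            g.sphere_xyz[pairs[:, 0], 0], -g.sphere_xyz[pairs[:, 1], 0]
        )


class TestSmoothMap:
    def test_determinism(self, geom60):
        np.testing.assert_array_equal(
            simulate_smooth_map(geom60, 0.3, seed=5),
            simulate_smooth_map(geom60, 0.3, seed=5),
        )

    def test_large_length_scale_flattens(self, geom60):
        # across-parcel variance vanishes relative to field variance
        m = simulate_smooth_map(geom60, 50.0, seed=4)
        assert m.var() < 0.02

    def test_moran_monotone_in_length_scale(self, geom60):
        medians = []
        for ls in (0.05, 0.3, 1.0):
            vals = [
                morans_i(simulate_smooth_map(geom60, ls, seed=s), geom60).value
                for s in range(50)
            ]
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]

    def test_invalid_length_scale(self, geom60):
        with pytest.raises(ValueError):
            simulate_smooth_map(geom60, 0.0, seed=1)


class TestFractionalGaussianNoise:
    def test_white_limit(self):
        x = fractional_gaussian_noise(50000, 0.5, seed=3)
        assert abs(x.var() - 1.0) < 0.05
        assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.02

    def test_lag1_autocorrelation_matches_theory(self):
        h = 0.8
        x = fractional_gaussian_noise(100000, h, seed=4)
        rho1 = 2 ** (2 * h) / 2 - 1
        assert np.corrcoef(x[:-1], x[1:])[0, 1] == pytest.approx(rho1, abs=0.02)

    def test_invalid_hurst(self):
        with pytest.raises(ValueError):
            fractional_gaussian_noise(100, 1.0)


class TestSimulateTimeseries:
    def test_determinism(self):
        p = TimeseriesParams(alpha_amplitude=1.0, duration=30.0)
        np.testing.assert_array_equal(
            simulate_parcel_timeseries(p, seed=9), simulate_parcel_timeseries(p, seed=9)
        )

    def test_pure_powerlaw_slope(self):
        # b=0, k=0, chi=2, no alpha: periodogram log-log slope -2 +/- 0.15
        p = TimeseriesParams(offset=0.0, knee=0.0, exponent=2.0,
                             alpha_amplitude=0.0, fs=100.0, duration=300.0)
        ts = simulate_parcel_timeseries(p, seed=21)
        # least-squares oracle on the averaged periodogram
        nper = 1000
        segs = ts[: len(ts) // nper * nper].reshape(-1, nper)
        pxx = np.mean(np.abs(np.fft.rfft(segs, axis=1)) ** 2, axis=0)
        f = np.fft.rfftfreq(nper, 1 / 100.0)
        m = (f >= 1) & (f <= 40)
        slope = np.polyfit(np.log10(f[m]), np.log10(pxx[m]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.15)

    def test_no_alpha_no_peak(self):
        from cortexdyn import fit_spectral_model, welch_psd

        p = TimeseriesParams(offset=0.0, knee=20.0, exponent=2.0,
                             alpha_amplitude=0.0, fs=100.0, duration=300.0)
        ts = simulate_parcel_timeseries(p, seed=5)
        _, peaks = fit_spectral_model(welch_psd(ts, 100.0), fit_range=(1.0, 45.0))
        assert not any(7 <= pk.center_frequency <= 13 for pk in peaks)

    def test_envelope_hurst_white_target(self):
        # H_target = 0.5: DFA of the extracted alpha envelope in [0.43, 0.57]
        from cortexdyn import alpha_envelope

        ests = []
        for s in range(20):
            p = TimeseriesParams(offset=0.0, knee=10.0, exponent=2.0,
                                 alpha_amplitude=1.0, envelope_hurst=0.5,
                                 fs=100.0, duration=150.0)
            ts = simulate_parcel_timeseries(p, seed=s)
            env = alpha_envelope(ts, 100.0, trim_edges=True)
            ests.append(dfa_hurst(env, 100.0, fit_range=(3.0, 30.0)).hurst)
        assert 0.43 <= np.median(ests) <= 0.57

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            TimeseriesParams(exponent=0.0)
        with pytest.raises(ValueError):
            TimeseriesParams(knee=-1.0)


class TestSimulateCohort:
    @staticmethod
    def _config(beta, seed=0, n=10, n_parcels=40, **kw):
        geom = make_geometry(n_parcels, seed=seed)
        patterns = {p: simulate_smooth_map(geom, 0.4, seed=900 + i)
                    for i, p in enumerate(PARAMETER_ORDER)}
        return SyntheticConfig(
            seed=seed, n_parcels=n_parcels,
            group_sizes={"control": n, "clinical_A": n},
            signature_patterns={"clinical_A": patterns},
            signature_amplitude=beta, noise_sd=0.5,
            symptom_groups=("clinical_A",), **kw,
        ), patterns

    def test_bookkeeping(self):
        cfg, _ = self._config(beta=1.0)
        records, geom = simulate_cohort(cfg)
        by_group = {}
        for r in records:
            by_group.setdefault(r.group_label, []).append(r)
        assert len(by_group["control"]) == 10
        assert len(by_group["clinical_A"]) == 10
        assert all(r.symptoms is None for r in by_group["control"])
        assert all(r.symptoms is not None for r in by_group["clinical_A"])
        assert all(set(r.maps) == set(PARAMETER_ORDER) for r in records)

    def test_determinism(self):
        cfg, _ = self._config(beta=1.0, seed=3)
        r1, _ = simulate_cohort(cfg)
        r2, _ = simulate_cohort(cfg)
        for a, b in zip(r1, r2):
            assert a.subject_id == b.subject_id
            for p in PARAMETER_ORDER:
                np.testing.assert_array_equal(a.maps[p], b.maps[p])

    def test_beta_zero_null(self):
        # mean clinical-minus-control map not correlated with the pattern
        n_reject, n_seeds = 0, 20
        for s in range(n_seeds):
            cfg, patterns = self._config(beta=0.0, seed=s, n=8)
            records, geom = simulate_cohort(cfg)
            diff = self._group_diff(records, "exponent")
            assert abs(diff.mean()) < 0.5
            log = spin_rotations(geom, 99, seed=s)
            res = spin_pvalue(spearman_map_corr, diff, patterns["exponent"], log)
            n_reject += res.p_value <= 0.05
        assert n_reject <= 2  # >= 90% of seeds non-significant

    @staticmethod
    def _group_diff(records, param):
        clin = np.mean([r.maps[param] for r in records
                        if r.group_label == "clinical_A"], axis=0)
        ctrl = np.mean([r.maps[param] for r in records
                        if r.group_label == "control"], axis=0)
        return clin - ctrl

    def test_signature_recovery(self):
        cfg, patterns = self._config(beta=1.0, seed=1, n=40, n_parcels=60)
        records, _ = simulate_cohort(cfg)
        diff = self._group_diff(records, "exponent")
        assert spearman_map_corr(diff, patterns["exponent"]) > 0.8

    def test_missing_pattern_raises(self):
        cfg = SyntheticConfig(
            group_sizes={"control": 4, "clinical_A": 4},
            signature_amplitude=1.0,
            n_parcels=10,
        )
        with pytest.raises(ValueError):
            simulate_cohort(cfg)

    def test_paired_drug_design(self):
        geom = make_geometry(30, seed=0)
        pat = {"exponent": simulate_smooth_map(geom, 0.4, seed=9)}
        cfg = SyntheticConfig(
            seed=0, n_parcels=30,
            group_sizes={"placebo": 6, "drug_A": 6},
            signature_patterns={"drug_A": pat},
            signature_amplitude=1.0, noise_sd=0.5,
            paired_with={"drug_A": "placebo"},
        )
        records, _ = simulate_cohort(cfg)
        placebo_ids = {r.subject_id for r in records if r.group_label == "placebo"}
        drug_ids = {r.subject_id for r in records if r.group_label == "drug_A"}
        assert placebo_ids == drug_ids  # within-subject pairing

    def test_symptom_coupling(self):
        cfg, _ = self._config(beta=2.0, seed=4, n=40, n_parcels=20,
                              symptom_coupling=(1.0, 0.0), symptom_noise_sd=0.1)
        records, _ = simulate_cohort(cfg)
        pos = [r.symptoms[0] for r in records if r.group_label == "clinical_A"]
        # positive scores track beta_i (mean 2), negative stay near 0
        neg = [r.symptoms[1] for r in records if r.group_label == "clinical_A"]
        assert np.mean(pos) > 1.0
        assert abs(np.mean(neg)) < 0.3

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SyntheticConfig(group_sizes={"control": 1})
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sd=0.0)
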