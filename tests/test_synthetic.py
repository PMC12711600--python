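"""Generators: determinism, physical invariants, closed-form anchors."""

import numpy as np
import pytest

import hydrotraits as ht


class TestPVGenerator:
    def test_full_turgor_psi_is_zero(self, pv_params):
        curve, _ = ht.gen_pv_series(pv_params)
        _, psi = curve.arrays()
        assert psi[0] == pytest.approx(0.0, abs=1e-12)

    def test_truth_is_pi0_over_rwc(self, pv_params):
        _, truth = ht.gen_pv_series(pv_params)
        assert truth["psi_tlp"] == pytest.approx(-1.6 / 0.9)
        assert truth["psi_tlp"] == pytest.approx(-1.778, abs=1e-3)

    def test_masses_strictly_decreasing(self, pv_params):
        curve, _ = ht.gen_pv_series(pv_params)
        fresh, _ = curve.arrays()
        assert np.all(np.diff(fresh) < 0)

    def test_seeded_determinism(self):
        p = ht.PVGenParams(pi0=-1.6, rwc_tlp=0.9, sat_mass=1.0,
                           dry_mass=0.4, noise_sd_psi=0.1, seed=42)
        c1, _ = ht.gen_pv_series(p)
        c2, _ = ht.gen_pv_series(p)
        assert c1.observations == c2.observations

    def test_noisy_psi_stays_nonpositive(self):
        p = ht.PVGenParams(pi0=-1.0, rwc_tlp=0.95, sat_mass=1.0,
                           dry_mass=0.4, noise_sd_psi=0.5, seed=7)
        curve, _ = ht.gen_pv_series(p)
        _, psi = curve.arrays()
        assert np.all(psi <= 0)

    @pytest.mark.parametrize(
        "field,kwargs",
        [
            ("pi0", dict(pi0=0.5)),
            ("rwc_tlp", dict(rwc_tlp=1.2)),
            ("dry_mass", dict(dry_mass=1.5)),
            ("n_points", dict(n_points=4)),
        ],
    )
    def test_validation_names_field(self, field, kwargs):
        base = dict(pi0=-1.6, rwc_tlp=0.9, sat_mass=1.0, dry_mass=0.4)
        base.update(kwargs)
        with pytest.raises(ValueError, match=field):
            ht.PVGenParams(**base)


class TestVCGenerator:
    def test_plc_at_psi50_is_50(self):
        s, _ = ht.gen_vc_observations(
            ht.VCGenParams(psi50_true=-3.0, slope_a=2.0, n_branches=5,
                           psi_range=(-3.0 - 1e-12, 0.0), seed=0)
        )
        plc_at_mid = [r.plc for r in s.records if abs(r.psi_stem + 3.0) < 1e-9]
        assert plc_at_mid and plc_at_mid[0] == pytest.approx(50.0, abs=1e-6)

    def test_plc_near_zero_tension(self):
        # at psi = 0 the sigmoid with psi50 = -3, a = 2 gives 100/(1+e^6)
        s, _ = ht.gen_vc_observations(
            ht.VCGenParams(psi50_true=-3.0, slope_a=2.0, n_branches=10,
                           psi_range=(-6.0, 0.0), seed=0)
        )
        wettest = max(s.records, key=lambda r: r.psi_stem)
        assert wettest.psi_stem == 0.0
        assert wettest.plc == pytest.approx(100.0 / (1.0 + np.exp(6.0)))
        assert wettest.plc == pytest.approx(0.25, abs=0.005)

    def test_ki_kmax_consistency(self):
        s, _ = ht.gen_vc_observations(
            ht.VCGenParams(psi50_true=-2.0, slope_a=1.5, n_branches=15, seed=1)
        )
        for r in s.records:
            assert r.k_i / r.k_max == pytest.approx(1.0 - r.plc / 100.0)

    def test_noisy_plc_bounded(self):
        s, _ = ht.gen_vc_observations(
            ht.VCGenParams(psi50_true=-3.0, slope_a=2.0, n_branches=50,
                           noise_sd_plc=20.0, seed=2)
        )
        plc = np.array([r.plc for r in s.records])
        assert plc.min() >= 0 and plc.max() <= 100

    def test_range_not_bracketing_psi50_warns(self):
        with pytest.warns(UserWarning, match="poorly constrained"):
            s, _ = ht.gen_vc_observations(
                ht.VCGenParams(psi50_true=-8.0, slope_a=2.0, n_branches=10,
                               psi_range=(-3.0, -0.5), seed=0)
            )
        assert s.poorly_constrained

    def test_seeded_determinism(self):
        p = ht.VCGenParams(psi50_true=-3.0, slope_a=2.0, n_branches=12,
                           noise_sd_plc=5.0, seed=9)
        a, _ = ht.gen_vc_observations(p)
        b, _ = ht.gen_vc_observations(p)
        assert [r.plc for r in a.records] == [r.plc for r in b.records]


class TestDrydownGenerator:
    def test_strict_anisohydric_limit_on_identity_line(self):
        s, _ = ht.gen_drydown(
            ht.DrydownGenParams(sigma_true=1.0, intercept_true=0.0, seed=0)
        )
        obs = s.observations
        assert np.allclose(obs["psi_md"], obs["psi_pd"])

    def test_linear_construction(self):
        s, _ = ht.gen_drydown(
            ht.DrydownGenParams(sigma_true=0.6, intercept_true=-0.5, seed=0)
        )
        obs = s.observations
        assert np.allclose(obs["psi_md"], -0.5 + 0.6 * obs["psi_pd"])
        # spot value: psi_pd = -1.0 would map to -1.1
        assert -0.5 + 0.6 * -1.0 == pytest.approx(-1.1)

    def test_two_replicates_per_individual_date(self):
        s, _ = ht.gen_drydown(
            ht.DrydownGenParams(sigma_true=0.5, intercept_true=-0.3,
                                n_individuals=4, n_dates=6, seed=1)
        )
        counts = s.observations.groupby(["individual_id", "date"]).size()
        assert (counts == 2).all()
        assert len(counts) == 4 * 6

    def test_noise_free_exact_downstream_recovery(self):
        s, truth = ht.gen_drydown(
            ht.DrydownGenParams(sigma_true=0.42, intercept_true=-0.77, seed=3)
        )
        fit = ht.fit_sigma(s)
        assert fit.sigma == pytest.approx(truth["sigma"], abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError, match="n_dates"):
            ht.DrydownGenParams(sigma_true=0.5, intercept_true=-0.5, n_dates=2)
        with pytest.raises(ValueError, match="psi_pd_range"):
            ht.DrydownGenParams(sigma_true=0.5, intercept_true=-0.5,
                                psi_pd_range=(-2.0, 0.5))


class TestVesselGenerator:
    def test_unimodal_positive_diameters(self):
        v = ht.gen_vessels(
            ht.VesselGenParams(mode1_mean=30.0, mode1_sd=8.0,
                               n_vessels=500, seed=0)
        )
        assert v.diameters.size == 500
        assert (v.diameters > 0).all()

    def test_moments_approach_targets(self):
        v = ht.gen_vessels(
            ht.VesselGenParams(mode1_mean=30.0, mode1_sd=6.0,
                               n_vessels=20000, seed=1)
        )
        assert v.diameters.mean() == pytest.approx(30.0, rel=0.02)
        assert v.diameters.std() == pytest.approx(6.0, rel=0.05)

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError, match="n_vessels"):
            ht.VesselGenParams(mode1_mean=30.0, mode1_sd=8.0, n_vessels=0)

    def test_mix_weight_requires_mode2(self):
        with pytest.raises(ValueError, match="mix_weight"):
            ht.VesselGenParams(mode1_mean=30.0, mode1_sd=8.0,
                               n_vessels=10, mix_weight=0.5)

    def test_seeded_determinism(self):
        p = ht.VesselGenParams(mode1_mean=20.0, mode1_sd=4.0,
                               mode2_mean=60.0, mode2_sd=6.0,
                               mix_weight=0.4, n_vessels=100, seed=5)
        assert np.array_equal(
            ht.gen_vessels(p).diameters, ht.gen_vessels(p).diameters
        )


class TestLeafTraits:
    def test_lma_identity(self):
        df = ht.gen_leaf_traits(
            mean_area_cm2=40.0, sd_area_cm2=5.0,
            mean_lma_g_m2=90.0, sd_lma_g_m2=10.0, n=50, seed=0,
        )
        lma = df["dry_mass_g"] / (df["leaf_area_cm2"] * 1e-4)
        assert lma.mean() == pytest.approx(90.0, rel=0.1)
        assert len(df) == 50

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="mean_area_cm2"):
            ht.gen_leaf_traits(-1.0, 1.0, 90.0, 5.0)
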