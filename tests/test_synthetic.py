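"""Cohort generator, log-normal calibration, phantom rendering, GRE simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import lognorm

from nigra.core import VoxelGrid, wrap_phase
from nigra.synthetic import (
    MEASURES,
    CohortSpec,
    PhantomGeometry,
    cohort_frame,
    fit_lognormal_from_quartiles,
    generate_cohort,
    head_support,
    render_phantom,
    sample_measures,
    simulate_multiecho_gre,
)

SMALL_GRID = VoxelGrid(dims=(48, 48, 32), voxel_size=(0.5, 0.5, 1.0))
SMALL_GEOM = PhantomGeometry(sn_lateral_mm=5.0, sn_semiaxes_mm=(3.0, 4.5, 6.0),
                             rn_lateral_mm=3.5)


class TestLognormalFit:
    def test_symmetric_unit_case(self):
        mu, sigma = fit_lognormal_from_quartiles(1.0, np.exp(-0.674489), np.exp(0.674489))
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert sigma == pytest.approx(1.0, rel=1e-5)

    def test_published_pd_n1_row_against_quantile_oracle(self):
        # median 3.00, IQR 1.35-5.44: the fitted distribution must return the
        # median exactly and the quartile *ratio* exactly (log-IQR matching)
        mu, sigma = fit_lognormal_from_quartiles(3.00, 1.35, 5.44)
        assert mu == pytest.approx(np.log(3.0))
        assert sigma == pytest.approx(1.033, abs=2e-3)
        dist = lognorm(s=sigma, scale=np.exp(mu))
        q1, med, q3 = dist.ppf([0.25, 0.5, 0.75])
        assert med == pytest.approx(3.00, rel=1e-12)
        assert q3 / q1 == pytest.approx(5.44 / 1.35, rel=1e-12)

    def test_degenerate_point_mass_flagged(self):
        with pytest.warns(UserWarning, match="point-mass"):
            mu, sigma = fit_lognormal_from_quartiles(5.0, 5.0, 5.0)
        assert sigma == 0.0

    @pytest.mark.parametrize("args", [(0.0, 1.0, 2.0), (1.0, -1.0, 2.0), (1.0, 2.0, 0.5)])
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            fit_lognormal_from_quartiles(*args)


class TestCohort:
    def test_default_cohort_size_and_composition(self):
        cohort = generate_cohort(CohortSpec(seed=1))
        assert len(cohort) == 189
        assert sum(s.group == "PD" for s, _ in cohort) == 82

    def test_determinism_byte_for_byte(self):
        a = cohort_frame(generate_cohort(CohortSpec(seed=5)), with_latent=True)
        b = cohort_frame(generate_cohort(CohortSpec(seed=5)), with_latent=True)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_clinical_invariants(self):
        for subject, latent in generate_cohort(CohortSpec(n_pd=40, n_hc=40, seed=2)):
            if subject.group == "HC":
                assert subject.hy_stage == 0
                assert subject.ledd is None and subject.duration is None
            else:
                assert subject.hy_stage >= 1
                assert subject.ledd > 0 and subject.duration > 0
                assert subject.updrs3 >= 5

    def test_pd_updrs_median_near_calibration_target(self):
        df = cohort_frame(generate_cohort(CohortSpec(n_pd=400, n_hc=0, seed=3)))
        assert df.updrs3.median() == pytest.approx(31, rel=0.15)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_cohort(CohortSpec(n_pd=0, n_hc=0))


class TestMeasureSampler:
    def test_null_cohorts_show_no_group_separation(self):
        from nigra.stats import mann_whitney

        rejections = 0
        n_reps = 40
        for rep in range(n_reps):
            spec = CohortSpec(n_pd=30, n_hc=30, seed=5000 + rep, degeneration_scale=0.0)
            agg = sample_measures(spec).groupby(
                ["subject_id", "group"], as_index=False)[list(MEASURES)].mean()
            _, p = mann_whitney(agg.loc[agg.group == "PD", "qsm_based_volume"].to_numpy(),
                                agg.loc[agg.group == "HC", "qsm_based_volume"].to_numpy())
            rejections += p < 0.05
        assert rejections / n_reps <= 0.15

    def test_hemisphere_mean_matches_aggregate_marginal_exactly(self):
        spec = CohortSpec(n_pd=50, n_hc=50, seed=4)
        df = sample_measures(spec)
        # the L/R split is mean-preserving, so both sides are positive and
        # the contrast-range ratio stays near its physiologic band
        assert (df[list(MEASURES)] > 0).all().all()
        assert df.nms_contrast_range.between(1.0, 1.4).all()


class TestPhantom:
    def _latent(self, d):
        from nigra.synthetic import CohortSpec, _latent_state
        from scipy.stats import norm

        spec = CohortSpec(left_degeneration_offset=0.0)
        state = _latent_state("PD", 0.0, spec)
        for h in state.hemispheres.values():
            h.degeneration = d
            h.iron_elevation_ppb = 110.0 * d
            h.neuromelanin_level = 1.0 - 0.6 * d
        return state

    def test_intact_vs_complete_loss(self):
        chi0, _, masks0 = render_phantom(self._latent(0.0), SMALL_GRID, seed=0,
                                         geometry=SMALL_GEOM, chi_noise_ppb=0, nms_noise=0)
        chi1, _, _ = render_phantom(self._latent(1.0), SMALL_GRID, seed=0,
                                    geometry=SMALL_GEOM, chi_noise_ppb=0, nms_noise=0)
        for side in ("L", "R"):
            n1 = masks0[f"N1_{side}"]
            assert (chi0[n1] < 30).sum() > 0  # intact low-chi core
            assert (chi1[n1] < 30).sum() == 0  # complete loss

    def test_masks_well_formed(self):
        _, _, masks = render_phantom(self._latent(0.2), SMALL_GRID, seed=1,
                                     geometry=SMALL_GEOM)
        for side in ("L", "R"):
            assert masks[f"SN_{side}"].sum() > 0
            assert masks[f"RN_{side}"].sum() > 0
            assert not np.any(masks[f"N1_{side}"] & ~masks[f"SN_{side}"])
        assert not np.any(masks["SN_L"] & masks["SN_R"])

    def test_monotone_degeneration_response(self):
        # common random numbers: same seed; pointwise chi non-decreasing and
        # NMS non-increasing in degeneration
        prev_chi, prev_nms = None, None
        for d in (0.0, 0.3, 0.6, 1.0):
            chi, nms, masks = render_phantom(self._latent(d), SMALL_GRID, seed=7,
                                             geometry=SMALL_GEOM, chi_noise_ppb=0, nms_noise=0)
            if prev_chi is not None:
                sn = masks["SN_L"] | masks["SN_R"]
                assert np.all(chi[sn] >= prev_chi[sn] - 1e-9)
                assert np.all(nms[sn] <= prev_nms[sn] + 1e-9)
            prev_chi, prev_nms = chi, nms

    def test_grid_too_small_rejected(self):
        tiny = VoxelGrid(dims=(16, 16, 16), voxel_size=(0.5, 0.5, 1.0))
        with pytest.raises(ValueError, match="margin"):
            render_phantom(self._latent(0.0), tiny)

    def test_rendered_cohort_reproduces_group_ordering(self):
        # thresholded low-chi volume in the SN: HC median above PD median
        vols = {"PD": [], "HC": []}
        for group, n0 in (("PD", 0), ("HC", 100)):
            for i in range(15):
                from nigra.synthetic import _latent_state

                rng = np.random.default_rng(n0 + i)
                z = float(rng.standard_normal())
                state = _latent_state(group, z, CohortSpec())
                chi, _, masks = render_phantom(state, SMALL_GRID, seed=n0 + i,
                                               geometry=SMALL_GEOM)
                sn = masks["SN_L"] | masks["SN_R"]
                vols[group].append((chi[sn] < 40).sum())
        assert np.median(vols["HC"]) > np.median(vols["PD"])


class TestGreSimulation:
    def test_zero_chi_phase_is_wrapped_channel_offset(self):
        series = simulate_multiecho_gre(
            np.zeros(SMALL_GRID.dims), SMALL_GRID, n_channels=2, noise_sd=0.0,
            seed=3, background_gradient_hz=(0.0, 0.0, 0.0),
        )
        for c in range(2):
            vals = series.phase[c]
            assert np.ptp(vals) < 1e-12  # constant offset per channel

    def test_phase_wrap_invariant(self):
        chi = np.zeros(SMALL_GRID.dims)
        chi[20:28, 20:28, 10:20] = 200.0
        series = simulate_multiecho_gre(chi, SMALL_GRID, noise_sd=0.005, seed=9)
        assert series.phase.max() <= np.pi + 1e-12
        assert series.phase.min() > -np.pi - 1e-12

    def test_wrap_closure_of_stored_phase(self):
        # noiseless: the stored phase must equal wrap(true phase) exactly
        from nigra.qsm import dipole_field_hz

        chi = np.zeros(SMALL_GRID.dims)
        chi[22:26, 22:26, 14:18] = 300.0
        series = simulate_multiecho_gre(chi, SMALL_GRID, n_channels=1, noise_sd=0.0,
                                        seed=4, background_gradient_hz=(0.2, 0.0, 0.3))
        field = dipole_field_hz(chi, SMALL_GRID, series.b0_tesla)
        from nigra.synthetic import _mm_coords

        x, y, z = _mm_coords(SMALL_GRID)
        bg = 0.2 * x + 0.3 * z
        for e, te in enumerate(series.te_list_ms):
            true = 2 * np.pi * (field + bg) * te / 1000.0
            # solve the constant channel offset from one voxel, then compare all
            offset = np.angle(np.exp(1j * (series.phase[0, e] - true)))
            assert np.ptp(offset) < 1e-9
            np.testing.assert_allclose(wrap_phase(true + offset.flat[0]),
                                       series.phase[0, e], atol=1e-9)

    def test_bad_te_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_multiecho_gre(np.zeros(SMALL_GRID.dims), SMALL_GRID, te_list_ms=())
        with pytest.raises(ValueError):
            simulate_multiecho_gre(np.zeros(SMALL_GRID.dims), SMALL_GRID,
                                   te_list_ms=(39.0, 13.77))
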