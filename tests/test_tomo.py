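import dataclasses

import numpy as np
import pytest

from fltquant import synth, tomo
from fltquant.gating import GateSequence


class TestDiffusionGreen:
    def test_reciprocity(self, coarse_tomo):
        _, phantom, _, _ = coarse_tomo
        p1 = np.array([1.0, 2.0, 3.0])
        p2 = np.array([-4.0, 0.5, 12.0])
        assert tomo.diffusion_green(phantom, p1, p2) == pytest.approx(
            tomo.diffusion_green(phantom, p2, p1)
        )

    def test_infinite_medium_closed_form(self, coarse_tomo):
        _, phantom, _, _ = coarse_tomo
        mua, musp = phantom.mu_a, phantom.mu_s_prime
        D = 1.0 / (3.0 * (mua + musp))
        mu_eff = np.sqrt(3.0 * mua * (mua + musp))
        d = 10.0
        expect = np.exp(-mu_eff * d) / (4 * np.pi * D * d)
        got = tomo.diffusion_green(
            phantom, np.zeros(3), np.array([0.0, 0.0, d]), infinite=True
        )
        assert got == pytest.approx(expect, rel=1e-12)

    def test_monotone_in_distance(self, coarse_tomo):
        _, phantom, _, _ = coarse_tomo
        p = np.array([0.0, 0.0, 9.0])
        vals = [
            tomo.diffusion_green(phantom, p, np.array([0.0, 0.0, 9.0 + dz]))
            for dz in (1.0, 2.0, 4.0, 7.0)
        ]
        assert np.all(np.diff(vals) < 0)


class TestBuildJacobian:
    def test_adjoint_identity(self, coarse_tomo, rng):
        _, _, _, jac = coarse_tomo
        W = jac.W
        x = rng.normal(size=W.shape[1])
        y = rng.normal(size=W.shape[0])
        lhs = np.dot(W @ x, y)
        rhs = np.dot(x, W.T @ y)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_source_detector_swap(self):
        cfg = synth.TomoConfig(voxel_size=2.0, lateral=(16.0, 16.0),
                               source_grid=(1, 1), det_grid=(1, 1))
        phantom, geom = synth.generate_tomo_phantom(cfg)
        jac = tomo.build_jacobian(phantom, geom)
        # swap: source on the ventral face, detector on the dorsal face
        swapped = synth.SDGeometry(
            sources=geom.detectors.copy(),
            detectors=geom.sources.copy(),
            pairing=[(0, 0)],
        )
        jac2 = tomo.build_jacobian(phantom, swapped)
        assert np.allclose(jac.W, jac2.W, rtol=1e-9)

    def test_banana_on_axis_exceeds_off_axis(self, coarse_tomo):
        _, phantom, geom, jac = coarse_tomo
        si, di = geom.pairing[0]
        src, det = geom.sources[si], geom.detectors[di]
        mid = 0.5 * (src + det)
        vc = phantom.voxel_centers()
        on_axis = np.argmin(((vc - mid) ** 2).sum(axis=1))
        # off-axis voxel at the same distance from the midpoint
        d_on = np.linalg.norm(vc[on_axis] - mid)
        lateral = mid + np.array([6.0, 0.0, 0.0])
        off_axis = np.argmin(((vc - lateral) ** 2).sum(axis=1))
        row = jac.W[0]
        assert row[on_axis] > row[off_axis]

    def test_nonnegative_finite(self, coarse_tomo):
        _, _, _, jac = coarse_tomo
        assert np.isfinite(jac.W).all()
        assert (jac.W >= 0).all()

    def test_empty_grid_rejected(self, coarse_tomo):
        _, phantom, geom, _ = coarse_tomo
        bad = dataclasses.replace(
            phantom,
            shape=(0, 0, 0),
            etaT_true=np.zeros((0, 0, 0)),
            etaNS_true=np.zeros((0, 0, 0)),
            inclusion_mask=np.zeros((0, 0, 0), dtype=bool),
        )
        with pytest.raises(ValueError):
            tomo.build_jacobian(bad, geom)


class TestFitPairAmplitudes:
    def test_forward_consistency(self, coarse_tomo, coarse_traces, gates):
        _, phantom, geom, jac = coarse_tomo
        aT_true, aNS_true = synth.pair_amplitude_truth(phantom, jac)
        amps = tomo.fit_pair_amplitudes(coarse_traces, gates, 0.85, 0.60)
        ok = amps.ok & (aT_true > 0)
        rel = np.abs(amps.aT[ok] - aT_true[ok]) / aT_true[ok]
        assert rel.max() < 1e-6

    def test_no_nonspecific_limit(self, coarse_tomo, gates):
        _, phantom, geom, jac = coarse_tomo
        p0 = dataclasses.replace(
            phantom, etaNS_true=np.zeros_like(phantom.etaNS_true)
        )
        traces = synth.simulate_tomo_data(p0, geom, gates, jacobian=jac)
        amps = tomo.fit_pair_amplitudes(traces, gates, 0.85, 0.60)
        assert amps.aNS[amps.ok].max() <= 1e-9 * amps.aT[amps.ok].max()

    def test_source_power_linearity(self, coarse_tomo, gates):
        _, phantom, geom, jac = coarse_tomo
        t1 = synth.simulate_tomo_data(phantom, geom, gates, jacobian=jac)
        t5 = synth.simulate_tomo_data(
            phantom, geom, gates, jacobian=jac, source_power=5.0
        )
        a1 = tomo.fit_pair_amplitudes(t1, gates, 0.85, 0.60)
        a5 = tomo.fit_pair_amplitudes(t5, gates, 0.85, 0.60)
        ok = a1.ok & a5.ok
        assert np.allclose(a5.aT[ok], 5.0 * a1.aT[ok], rtol=1e-9)


class TestTikhonov:
    def test_identity_inversion(self):
        a = np.array([3.0, 1.0, 2.0])
        eta = tomo.tikhonov_invert(np.eye(3), a, lambda_rel=1e-12)
        assert np.allclose(eta, a, atol=1e-9)

    def test_2x2_closed_form(self):
        W = np.array([[2.0, 1.0], [0.5, 3.0]])
        a = np.array([1.0, 4.0])
        lam_rel = 0.1
        s1sq = np.linalg.svd(W, compute_uv=False)[0] ** 2
        lam = lam_rel * s1sq
        expect = np.linalg.solve(W.T @ W + lam * np.eye(2), W.T @ a)
        got = tomo.tikhonov_invert(W, a, lam_rel, clip_negative=False)
        assert np.allclose(got, expect, rtol=1e-8)

    def test_shrinkage_monotone(self, rng):
        W = rng.normal(size=(8, 12))
        a = rng.normal(size=8)
        norms = [
            np.linalg.norm(
                tomo.tikhonov_invert(W, a, lr, clip_negative=False)
            )
            for lr in (1e-4, 1e-3, 1e-2, 1e-1)
        ]
        assert np.all(np.diff(norms) < 1e-12)

    def test_residual_monotone_in_lambda(self, rng):
        W = np.abs(rng.normal(size=(6, 10)))
        a = np.abs(rng.normal(size=6))
        resids = []
        for lr in (1e-1, 1e-2, 1e-3, 1e-4):
            eta = tomo.tikhonov_invert(W, a, lr, clip_negative=False)
            resids.append(np.linalg.norm(W @ eta - a))
        assert np.all(np.diff(resids) <= 1e-12)

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError):
            tomo.tikhonov_invert(np.zeros((3, 3)), np.ones(3))

    def test_nnls_mode_nonnegative(self, rng):
        W = np.abs(rng.normal(size=(6, 4)))
        a = rng.normal(size=6)
        eta = tomo.tikhonov_invert(W, a, 1e-2, nonneg=True)
        assert (eta >= 0).all()


class TestThresholdYield:
    def test_eighty_percent_of_max(self):
        vol = np.arange(11.0)
        mask, mean = tomo.threshold_yield(vol, 0.8)
        assert set(np.nonzero(mask)[0]) == {8, 9, 10}

    def test_uniform_keeps_all(self):
        mask, mean = tomo.threshold_yield(np.full((3, 3, 3), 2.0), 0.8)
        assert mask.all()
        assert mean == pytest.approx(2.0)

    def test_loop_oracle(self, rng):
        vol = rng.uniform(0, 5, (4, 4, 4))
        mask, mean = tomo.threshold_yield(vol, 0.7)
        expect = vol >= 0.7 * vol.max()
        assert np.array_equal(mask, expect)
        assert mean == pytest.approx(vol[expect].mean())

    def test_percentile_mode(self, rng):
        vol = rng.uniform(0, 1, 1000)
        mask, _ = tomo.threshold_yield(vol, 0.8, mode="percentile")
        assert mask.sum() == pytest.approx(800, abs=2)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            tomo.threshold_yield(np.zeros((2, 2)), 0.8)


class TestYieldRatio:
    def test_proportional_fields(self):
        etaNS = np.random.default_rng(1).uniform(0.5, 1.5, (4, 4, 4))
        assert tomo.yield_ratio((2.0 * etaNS, etaNS)) == pytest.approx(2.0)

    def test_scale_invariance(self, rng):
        etaT = rng.uniform(0, 2, (4, 4, 4))
        etaNS = rng.uniform(0.1, 1, (4, 4, 4))
        r1 = tomo.yield_ratio((etaT, etaNS))
        r2 = tomo.yield_ratio((7.3 * etaT, 7.3 * etaNS))
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_toy_hand_computation(self):
        etaT = np.zeros((3, 3, 3))
        etaT[1, 1, 1] = 10.0
        etaT[1, 1, 0] = 9.0
        etaT[0, 0, 0] = 1.0
        etaNS = np.full((3, 3, 3), 2.0)
        etaNS[1, 1, 1] = 4.0
        # tumor mask: voxels >= 8 -> {(1,1,1), (1,1,0)}; mean_t = 9.5
        # etaNS in tumor = {4, 2}; top-80%-of-max (>= 3.2) -> {4}; mean 4
        assert tomo.yield_ratio((etaT, etaNS)) == pytest.approx(9.5 / 4.0)


class TestIntensityTomography:
    def test_single_lifetime_proportionality(self, coarse_tomo, gates):
        _, phantom, geom, jac = coarse_tomo
        p0 = dataclasses.replace(
            phantom, etaT_true=np.zeros_like(phantom.etaT_true)
        )
        traces = synth.simulate_tomo_data(p0, geom, gates, jacobian=jac)
        recon = tomo.reconstruct_yields(traces, gates, jac, p0, 0.85, 0.60)
        corr = np.corrcoef(recon.etaI.ravel(), recon.etaNS.ravel())[0, 1]
        assert corr > 0.999

    def test_zero_traces(self, coarse_tomo, gates):
        _, _, geom, jac = coarse_tomo
        arr = np.zeros((geom.n_pairs, gates.n_gates))
        vol = tomo.intensity_tomography(arr, gates, jac)
        assert np.all(vol == 0)

    def test_background_heavy_mask_volumes(self, gates):
        # broad nonspecific background -> intensity recovers a volume at
        # least as large as the specific (ATD) channel
        cfg = synth.TomoConfig(
            voxel_size=2.0, lateral=(20.0, 20.0),
            etaNS_liver=1.0, liver_radius=6.0,
        )
        phantom, geom = synth.generate_tomo_phantom(cfg)
        jac = tomo.build_jacobian(phantom, geom)
        traces = synth.simulate_tomo_data(phantom, geom, gates, jacobian=jac)
        recon = tomo.reconstruct_yields(traces, gates, jac, phantom, 0.85, 0.60)
        mask_i, _ = tomo.threshold_yield(recon.etaI, 0.8)
        assert mask_i.sum() >= recon.tumor_mask.sum()


class TestTumorDepth:
    def test_construction_example(self, coarse_tomo):
        _, phantom, _, _ = coarse_tomo
        eta = phantom.etaT_true
        mask = phantom.inclusion_mask
        depth = tomo.tumor_depth(
            eta, mask, phantom.voxel_centers(), phantom.surface_points()
        )
        assert depth == pytest.approx(6.3, abs=phantom.voxel_size[2])

    def test_surface_touching_mask(self, coarse_tomo):
        _, phantom, _, _ = coarse_tomo
        mask = np.zeros(phantom.shape, dtype=bool)
        mask[5, 5, 0] = True  # ventral-face voxel
        eta = mask.astype(float)
        depth = tomo.tumor_depth(
            eta, mask, phantom.voxel_centers(), phantom.surface_points()
        )
        assert depth <= phantom.voxel_size[2]

    def test_brute_force_oracle(self, coarse_tomo, rng):
        _, phantom, _, _ = coarse_tomo
        mask = np.zeros(phantom.shape, dtype=bool)
        mask[3:5, 4:6, 3:5] = True
        eta = rng.uniform(1, 2, phantom.shape)
        vc = phantom.voxel_centers()
        sp = phantom.surface_points()
        depth = tomo.tumor_depth(eta, mask, vc, sp)
        wts = eta[mask]
        com = (vc[mask.ravel()] * wts[:, None]).sum(0) / wts.sum()
        central = vc[np.argmin(((vc - com) ** 2).sum(1))]
        brute = min(np.linalg.norm(central - s) for s in sp)
        assert depth == pytest.approx(brute)

    def test_empty_mask_rejected(self, coarse_tomo):
        _, phantom, _, _ = coarse_tomo
        with pytest.raises(ValueError):
            tomo.tumor_depth(
                phantom.etaT_true,
                np.zeros(phantom.shape, bool),
                phantom.voxel_centers(),
                phantom.surface_points(),
            )


class TestEndToEnd:
    def test_localization_and_crosstalk(self, coarse_tomo, coarse_traces, gates):
        _, phantom, geom, jac = coarse_tomo
        recon = tomo.reconstruct_yields(
            coarse_traces, gates, jac, phantom, 0.85, 0.60
        )
        dice = (
            2.0 * np.sum(recon.tumor_mask & phantom.inclusion_mask)
            / (recon.tumor_mask.sum() + phantom.inclusion_mask.sum())
        )
        assert dice >= 0.3
        vc = phantom.voxel_centers()
        wts = recon.etaT[recon.tumor_mask]
        com = (vc[recon.tumor_mask.ravel()] * wts[:, None]).sum(0) / wts.sum()
        true_com = vc[phantom.inclusion_mask.ravel()].mean(axis=0)
        assert np.linalg.norm(com - true_com) <= 2.0 * max(phantom.voxel_size)

        # cross-talk bound: no specific yield -> reconstructed etaT over the
        # true inclusion is <= 5% of the matched-scale positive case
        p0 = dataclasses.replace(
            phantom, etaT_true=np.zeros_like(phantom.etaT_true)
        )
        tr0 = synth.simulate_tomo_data(p0, geom, gates, jacobian=jac)
        amps0 = tomo.fit_pair_amplitudes(tr0, gates, 0.85, 0.60)
        if amps0.aT.max() == 0:
            eta0_mean = 0.0
        else:
            eta0 = tomo.tikhonov_invert(
                jac, amps0.aT, "auto", keep=amps0.ok, sensitivity_scaled=True
            )
            eta0_mean = eta0[phantom.inclusion_mask].mean()
        assert eta0_mean <= 0.05 * recon.etaT[phantom.inclusion_mask].mean()

    def test_ratio_invariant_to_source_power(self, coarse_tomo, gates):
        _, phantom, geom, jac = coarse_tomo
        t1 = synth.simulate_tomo_data(phantom, geom, gates, jacobian=jac)
        t9 = synth.simulate_tomo_data(
            phantom, geom, gates, jacobian=jac, source_power=9.0
        )
        r1 = tomo.reconstruct_yields(t1, gates, jac, phantom, 0.85, 0.60,
                                     with_intensity=False)
        r9 = tomo.reconstruct_yields(t9, gates, jac, phantom, 0.85, 0.60,
                                     with_intensity=False)
        assert r9.ratio == pytest.approx(r1.ratio, rel=1e-6)
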