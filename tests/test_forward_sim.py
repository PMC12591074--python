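"""Forward simulator: projections, Fresnel propagation, detector model."""
import numpy as np
import pytest

import pbilung as P
from pbilung import forward_sim as fs, phantom as ph
from pbilung._constants import wavelength_m


class TestProjections:
    def test_all_air_phantom_projects_to_near_zero(self):
        p = ph.VoxelPhantom(np.zeros((2, 32, 32), dtype=np.uint8), voxel_size=0.5)
        phi, A = fs.project_line_integrals(p, [0.0], 70.0)
        assert np.all(A < 1e-3)  # air attenuation over 16 mm is ~3e-4

    def test_cylinder_chord_matches_analytic(self):
        """A(x) = 2 mu sqrt(r^2 - x^2), the closed-form chord length.

        0.1 mm voxels keep the staircase quantisation of the voxelised
        cylinder below the 1% comparison level.
        """
        cyl = ph.make_cylinder_phantom(10.0, P.SOFT_TISSUE, grid=(1, 256, 256), voxel_size=0.1)
        phi, A = fs.project_line_integrals(cyl, [0.0, 30.0], 70.0)
        mu = P.optical_constants(P.SOFT_TISSUE, 70.0).mu
        x = (np.arange(256) + 0.5) * 0.1 - 256 * 0.1 / 2
        chord = 2 * mu * np.sqrt(np.clip(10.0**2 - x**2, 0, None)) * 1e-3
        interior = np.abs(x) < 6.0  # away from the tangent rim
        for k in range(2):  # rotation invariance of a centred cylinder
            err = np.abs(A[k, 0, interior] - chord[interior])
            assert err.max() < 0.01 * chord.max()

    def test_opposing_angles_mirror(self, chest):
        phi, A = fs.project_line_integrals(chest, [30.0, 210.0], 60.0)
        assert np.allclose(A[0], A[1][:, ::-1], atol=1e-6 + 0.02 * A[0].max())

    def test_phase_sign_and_scale(self, soft_cylinder):
        phi, A = fs.project_line_integrals(soft_cylinder, [0.0], 70.0)
        oc = P.optical_constants(P.SOFT_TISSUE, 70.0)
        # centre ray: phase = -k * delta * chord
        k = 2 * np.pi / wavelength_m(70.0)
        expect = -k * oc.delta * 2 * 10.0e-3
        assert phi[0, 1].min() == pytest.approx(expect, rel=0.02)


class TestFresnel:
    def test_zero_distance_is_identity(self, rng):
        inten = rng.uniform(0.5, 1.5, (16, 64))
        phase = rng.uniform(-1, 1, (16, 64))
        out = fs.fresnel_propagate(inten, phase, 0.0, 70.0, 75.0)
        assert np.array_equal(out, inten)

    def test_plane_wave_stays_uniform(self):
        out = fs.fresnel_propagate(np.ones((16, 64)), np.full((16, 64), 0.3), 5.0, 60.0, 75.0)
        assert np.allclose(out, 1.0, atol=1e-9)

    def test_total_intensity_conserved(self, rng):
        """Free-space angular-spectrum propagation is unitary (Parseval)."""
        inten = rng.uniform(0.5, 1.5, (32, 64))
        phase = rng.uniform(-0.5, 0.5, (32, 64))
        out = fs.fresnel_propagate(inten, phase, 3.0, 70.0, 75.0, pad=False)
        assert out.mean() == pytest.approx(inten.mean(), rel=1e-9)

    def test_edge_fringe_position_matches_1d_fresnel_integral(self):
        """Independent oracle: direct quadrature of the Fresnel diffraction
        integral for a phase/absorption step edge, compared with the
        angular-spectrum propagator on the same 1-D profile."""
        from scipy.integrate import quad

        e_kev, z, dx_um = 70.0, 7.0, 5.0
        lam = wavelength_m(e_kev)
        n = 1024
        x = (np.arange(n) - n / 2) * dx_um * 1e-6
        a_step, phi_step = 0.05, 0.4
        amp = np.where(x > 0, np.exp(-a_step / 2), 1.0)
        phase = np.where(x > 0, -phi_step, 0.0)
        inten = fs.fresnel_propagate(np.tile(amp**2, (4, 1)), np.tile(phase, (4, 1)),
                                     z, e_kev, dx_um, pad=True)[0]

        def field_at(xd):
            # Fresnel integral with the step folded in analytically
            def re(xs):
                u = np.pi * (xd - xs) ** 2 / (lam * z)
                a = np.exp(-a_step / 2) if xs > 0 else 1.0
                p = -phi_step if xs > 0 else 0.0
                return a * np.cos(u + p)

            def im(xs):
                u = np.pi * (xd - xs) ** 2 / (lam * z)
                a = np.exp(-a_step / 2) if xs > 0 else 1.0
                p = -phi_step if xs > 0 else 0.0
                return a * np.sin(u + p)

            lim = 8 * np.sqrt(lam * z)
            rr = quad(re, xd - lim, xd + lim, limit=400)[0]
            ii = quad(im, xd - lim, xd + lim, limit=400)[0]
            return (rr**2 + ii**2) / (lam * z)

        probe = slice(n // 2 - 30, n // 2 + 30)
        oracle = np.array([field_at(xi) for xi in x[probe]])
        got = inten[probe]
        # fringe extremum positions within 1 px
        assert abs(int(np.argmax(oracle)) - int(np.argmax(got))) <= 1
        assert abs(int(np.argmin(oracle)) - int(np.argmin(got))) <= 1

    def test_fringe_contrast_grows_with_distance(self):
        """The PBI premise: edge contrast increases monotonically over 1-7 m."""
        n = 512
        x = np.arange(n) - n / 2
        amp = np.where(x > 0, 0.98, 1.0)
        phase = np.where(x > 0, -0.5, 0.0)
        contrasts = []
        for z in (1.0, 3.0, 5.0, 7.0):
            out = fs.fresnel_propagate(np.tile(amp**2, (2, 1)), np.tile(phase, (2, 1)),
                                       z, 70.0, 25.0)[0]
            contrasts.append(out.max() - out.min())
        assert all(a < b for a, b in zip(contrasts, contrasts[1:]))


class TestSourceBlurAndDetector:
    def test_blur_identity_at_zero_distance(self, rng):
        img = rng.uniform(size=(8, 64))
        assert np.array_equal(fs.apply_source_blur(img, 0.0, fs.BeamModel(), 75.0), img)

    def test_blur_preserves_mean(self, rng):
        img = rng.uniform(size=(8, 256))
        out = fs.apply_source_blur(img, 7.0, fs.BeamModel(), 75.0)
        assert out.mean() == pytest.approx(img.mean(), rel=1e-9)

    def test_penumbra_width_scales_with_geometry(self):
        """FWHM = source width * z / source distance: 800 um * 7 / 138.5
        ~ 40.4 um, i.e. sigma ~ 0.23 px at 75 um pixels."""
        beam = fs.BeamModel()
        step = np.zeros((2, 256))
        step[:, 128:] = 1.0
        out = fs.apply_source_blur(step, 7.0, beam, 75.0)
        sigma_px = 800.0 * 7.0 / 138.5 / 2.3548 / 75.0
        from scipy.special import erf

        x = np.arange(256) - 127.5
        expect = 0.5 * (1 + erf(x / (sigma_px * np.sqrt(2))))
        assert np.abs(out[0] - expect).max() < 0.02

    def test_zero_fluence_gives_zero_frame(self, rng):
        with pytest.raises(ValueError):
            fs.BeamModel(center_fluence=0.0)

    def test_poisson_counting_statistics(self, rng):
        """Sample variance ~ mean on a flat field (Poisson law)."""
        beam = fs.BeamModel(center_fluence=3e5, profile_peak_frac=0.5, profile_edge_ratio=1.0 - 1e-9)
        det = fs.DetectorModel(pixel_size=75.0)
        frame = fs.detect(np.ones((300, 334)), beam, det, rng).astype(float)
        assert frame.var() == pytest.approx(frame.mean(), rel=0.05)
        assert frame.mean() > 1000

    def test_hot_pixels_always_saturated(self, rng):
        det = fs.DetectorModel()
        hot = np.zeros((16, 16), dtype=bool)
        hot[3, 4] = True
        frame = fs.detect(np.ones((16, 16)), fs.BeamModel(), det, rng, hot_mask=hot)
        assert frame[3, 4] > 65000

    def test_gap_mask_geometry(self):
        det = fs.DetectorModel(chip_px=64, gap_h=10, gap_v=4)
        mask = det.gap_mask((128, 192))
        assert mask[:, 64 - 5 : 64 + 5].all() and mask[64 - 2 : 64 + 2, :].all()
        assert not mask[0, 0]

    def test_vertical_profile_peak_and_edge_ratio(self):
        beam = fs.BeamModel()
        prof = beam.vertical_profile(100)
        assert prof.max() == pytest.approx(1.0, abs=1e-3)  # peak between rows
        assert min(prof[0], prof[-1]) == pytest.approx(1 / 30, rel=0.05)


class TestScan:
    def test_scan_time_arithmetic(self):
        geo = fs.ScanGeometry(n_projections=3600, exposure=0.1)
        assert geo.scan_time_s == pytest.approx(360.0)  # 6 minutes

    def test_flat_corrected_air_scan_is_unity(self, rng):
        p = ph.VoxelPhantom(np.zeros((2, 48, 48), dtype=np.uint8), voxel_size=0.5)
        beam = fs.BeamModel(energy=60.0, center_fluence=2e5)
        geo = fs.ScanGeometry(n_projections=8, angular_range=180.0, n_flats=20)
        stack = fs.simulate_scan(p, beam, fs.DetectorModel(chip_px=100, gap_h=0, gap_v=0),
                                 geo, 1.0, seed=1, supersample=1)
        from pbilung.preprocess import flat_field_correct

        norm, valid = flat_field_correct(stack)
        assert norm[:, valid].mean() == pytest.approx(1.0, abs=0.01)

    def test_two_seeds_agree_in_mean(self, soft_cylinder):
        beam = fs.BeamModel(energy=60.0, center_fluence=2e5)
        geo = fs.ScanGeometry(n_projections=4, angular_range=180.0)
        det = fs.DetectorModel(chip_px=200, gap_h=0, gap_v=0)
        s1 = fs.simulate_scan(soft_cylinder, beam, det, geo, 1.0, seed=1, supersample=1)
        s2 = fs.simulate_scan(soft_cylinder, beam, det, geo, 1.0, seed=2, supersample=1)
        m1, m2 = s1.counts.mean(), s2.counts.mean()
        sem = np.sqrt(s1.counts.astype(float).var() / s1.counts.size)
        assert abs(m1 - m2) < 6 * sem

    def test_attenuation_only_equals_contact_up_to_blur(self, soft_cylinder):
        """With delta forced to 0 the propagated image is the contact image
        up to source blur."""
        phi, A = fs.project_line_integrals(soft_cylinder, [0.0], 70.0)
        beam = fs.BeamModel(energy=70.0)
        out = fs.simulate_projection(np.zeros_like(phi[0]), A[0], 7.0, 70.0, beam, 250.0, supersample=4)
        contact = fs._bin_columns(np.exp(-np.asarray(
            __import__("scipy.ndimage", fromlist=["zoom"]).zoom(A[0], (1.0, 4.0), order=3,
                                                                mode="nearest", grid_mode=True)
        )), 4)
        blurred = fs.apply_source_blur(contact, 7.0, beam, 250.0)
        assert np.abs(out - blurred).max() < 5e-3

    def test_stack_h5_round_trip(self, soft_cylinder, tmp_path):
        beam = fs.BeamModel(energy=60.0, center_fluence=1e5)
        geo = fs.ScanGeometry(n_projections=4, angular_range=180.0)
        stack = fs.simulate_scan(soft_cylinder, beam, fs.DetectorModel(), geo, 1.0, seed=3,
                                 supersample=1)
        f = tmp_path / "stack.h5"
        stack.save_h5(f)
        back = fs.ProjectionStack.load_h5(f)
        assert np.array_equal(back.counts, stack.counts)
        assert back.beam.energy == 60.0
        assert back.geometry.n_projections == 4
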