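import numpy as np
import pytest

from slamrecon.acquisition import KSpaceData, Protocol, build_aw_scheme, shift_fov, simulate_acquisition
from slamrecon.core import (
    ConsistencyError,
    IllConditionedError,
    SelectionError,
    UnderDeterminedError,
)
from slamrecon.phantom import (
    CompartmentMask,
    build_default_phantom,
    compartment_fid,
    rasterize_masks,
)
from slamrecon.recon import (
    build_slam_system,
    recon_ft,
    recon_slam,
    select_septal_voxel,
    septal_voxel_index,
    shift_mask,
)


def _true_fid(phantom, name, protocol, n_time=512, dwell=1.0 / 4000.0):
    from slamrecon.acquisition import effective_components

    t = np.arange(n_time) * dwell
    return compartment_fid(effective_components(phantom, name, protocol), t).data


def _kspace_from_voxels(voxel_fids, geometry, averages_grid=None):
    """Forward-encode an arbitrary voxel image exactly (full grid)."""
    n = geometry.matrix
    grid = np.fft.fftn(voxel_fids, axes=(0, 1, 2))
    k_index = geometry.k_indices()
    idx = k_index % np.array(n)
    samples = grid[idx[:, 0], idx[:, 1], idx[:, 2]]
    if averages_grid is None:
        averages = np.ones(k_index.shape[0], dtype=int)
    else:
        averages = averages_grid[idx[:, 0], idx[:, 1], idx[:, 2]]
        samples = samples * averages[:, None]
        keep = averages >= 1  # zero-average points are not acquired
        samples, k_index, averages = samples[keep], k_index[keep], averages[keep]
    return KSpaceData(samples=samples, k_index=k_index, averages=averages,
                      dwell_s=1.0 / 4000.0, geometry=geometry)


class TestReconFt:
    def test_forward_inverse_identity(self, clean_phantom):
        scheme = build_aw_scheme((8, 16, 8), max_averages=1, window="uniform")
        prot = Protocol(gated=True)
        ks = simulate_acquisition(clean_phantom, scheme, prot)
        grid = recon_ft(ks)
        mask = rasterize_masks(clean_phantom)
        scale = np.max(np.abs(grid.fids))
        for name, lab in (("heart", 1), ("chest_wall", 2), ("other", 0)):
            truth = _true_fid(clean_phantom, name, prot)
            for idx in np.argwhere(mask.labels == lab)[:5]:
                err = np.max(np.abs(grid.fids[tuple(idx)] - truth))
                assert err < 1e-10 * scale

    def test_impulse_object_gives_window_psf(self, default_geometry):
        # single-voxel object under Hann weighting: the reconstructed spatial
        # profile is the inverse DFT of the averages grid centred on the voxel
        n = default_geometry.matrix
        voxels = np.zeros((*n, 1), dtype=complex)
        r0 = (2, 5, 3)
        voxels[r0] = 1.0
        scheme = build_aw_scheme(n, max_averages=10, window="hann")
        full_grid = np.zeros(n, dtype=float)
        ki = scheme.k_index % np.array(n)
        full_grid[ki[:, 0], ki[:, 1], ki[:, 2]] = scheme.averages
        ks = _kspace_from_voxels(voxels, default_geometry,
                                 averages_grid=full_grid.astype(int))
        recon = recon_ft(ks).fids[..., 0]
        psf = np.fft.ifftn(full_grid)
        expected = np.roll(psf, r0, axis=(0, 1, 2))
        np.testing.assert_allclose(recon, expected, atol=1e-12)

    def test_empty_data_gives_zero_grid(self, default_geometry):
        ks = _kspace_from_voxels(
            np.zeros((*default_geometry.matrix, 4), dtype=complex),
            default_geometry)
        assert np.all(recon_ft(ks).fids == 0)

    def test_duplicate_k_indices_rejected(self, default_geometry):
        ks = _kspace_from_voxels(
            np.zeros((*default_geometry.matrix, 4), dtype=complex),
            default_geometry)
        with pytest.raises(ConsistencyError):
            KSpaceData(samples=ks.samples, k_index=np.zeros_like(ks.k_index),
                       averages=ks.averages, dwell_s=ks.dwell_s,
                       geometry=default_geometry)


class TestSeptalVoxelSelection:
    def test_single_heart_voxel_returned(self, default_geometry):
        labels = np.zeros(default_geometry.matrix, dtype=np.uint8)
        labels[3, 7, 4] = 1
        mask = CompartmentMask(labels, {0: "other", 1: "heart"},
                               default_geometry)
        assert septal_voxel_index(mask) == (3, 7, 4)

    def test_tie_breaks_on_lowest_linear_index(self, default_geometry):
        labels = np.zeros(default_geometry.matrix, dtype=np.uint8)
        labels[2, 6, 4] = 1
        labels[4, 6, 4] = 1  # symmetric about centroid (3, 6, 4)
        mask = CompartmentMask(labels, {0: "other", 1: "heart"},
                               default_geometry)
        assert septal_voxel_index(mask) == (2, 6, 4)

    def test_no_heart_voxels_raises(self, default_geometry):
        labels = np.zeros(default_geometry.matrix, dtype=np.uint8)
        mask = CompartmentMask(labels, {0: "other", 1: "heart"},
                               default_geometry)
        with pytest.raises(SelectionError):
            septal_voxel_index(mask)

    def test_default_phantom_selection_is_heart(self, default_phantom):
        mask = rasterize_masks(default_phantom)
        idx = septal_voxel_index(mask)
        assert mask.labels[idx] == 1
        # not face-adjacent to chest wall
        x, y, z = idx
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            nb = (x + dx, y + dy, z + dz)
            if all(0 <= n < s for n, s in zip(nb, mask.labels.shape)):
                assert mask.labels[nb] != 2

    def test_override_index(self, clean_kspace, clean_mask):
        grid = recon_ft(clean_kspace)
        fid = select_septal_voxel(grid, clean_mask, override_index=(1, 1, 1))
        np.testing.assert_array_equal(fid.data, grid.fids[1, 1, 1])


class TestBuildSlamSystem:
    def test_single_compartment_full_fov(self, default_geometry):
        labels = np.ones(default_geometry.matrix, dtype=np.uint8)
        mask = CompartmentMask(labels, {1: "tissue"}, default_geometry)
        ks = _kspace_from_voxels(
            np.zeros((*default_geometry.matrix, 4), dtype=complex),
            default_geometry)
        system = build_slam_system(mask, ks)
        dc = np.all(ks.k_index == 0, axis=1)
        nvox = default_geometry.n_voxels
        assert system.encoding[dc, 0] == pytest.approx(nvox)
        assert np.max(np.abs(system.encoding[~dc, 0])) < 1e-9 * nvox

    def test_default_mask_full_column_rank(self, clean_kspace, clean_mask):
        system = build_slam_system(clean_mask, clean_kspace)
        assert system.n_compartments == 3
        s = np.linalg.svd(system.weights[:, None] * system.encoding,
                          compute_uv=False)
        assert s[-1] > 0

    def test_under_determined_rejected(self, default_geometry):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, default_geometry.matrix).astype(np.uint8)
        mask = CompartmentMask(
            labels, {0: "other", 1: "a", 2: "b", 3: "c"}, default_geometry)
        ks = KSpaceData(
            samples=np.zeros((3, 256), dtype=complex),
            k_index=np.array([[0, 0, 0], [0, 1, 0], [1, 0, 0]]),
            averages=np.ones(3, dtype=int),
            dwell_s=1.0 / 4000.0, geometry=default_geometry)
        with pytest.raises(UnderDeterminedError):
            build_slam_system(mask, ks)


class TestReconSlam:
    def test_forward_then_solve_recovers_ground_truth(
            self, clean_phantom, clean_kspace, clean_mask):
        prot = Protocol(gated=True)
        spectra = recon_slam(clean_kspace, clean_mask)
        for name in ("heart", "chest_wall", "other"):
            truth = _true_fid(clean_phantom, name, prot)
            err = np.max(np.abs(spectra[name].data - truth))
            assert err < 1e-8 * np.max(np.abs(truth))

    def test_unitarity_slam_equals_ft_compartment_means(self, default_geometry):
        rng = np.random.default_rng(42)
        for _ in range(5):
            voxels = (rng.standard_normal((*default_geometry.matrix, 8))
                      + 1j * rng.standard_normal((*default_geometry.matrix, 8)))
            labels = rng.integers(0, 3, default_geometry.matrix).astype(np.uint8)
            mask = CompartmentMask(labels, {0: "other", 1: "heart", 2: "chest_wall"},
                                   default_geometry)
            ks = _kspace_from_voxels(voxels, default_geometry)
            spectra = recon_slam(ks, mask)
            grid = recon_ft(ks).fids
            for lab in mask.present_labels:
                name = mask.label_names[lab]
                mean_ft = grid[mask.labels == lab].mean(axis=0)
                err = np.max(np.abs(spectra[name].data - mean_ft))
                assert err <= 1e-10 * max(np.max(np.abs(mean_ft)), 1e-30)

    def test_full_truncation_raises_ill_conditioned(
            self, clean_kspace, clean_mask):
        with pytest.raises(IllConditionedError):
            recon_slam(clean_kspace, clean_mask, rcond=1.0)

    def test_conditioning_report_attached(self, clean_kspace, clean_mask):
        spectra = recon_slam(clean_kspace, clean_mask)
        rep = spectra.conditioning
        assert rep["effective_rank"] == 3
        assert len(rep["singular_values"]) == 3
        assert rep["condition_number"] >= 1.0

    def test_noise_propagation_matches_wls_covariance(self, small_geometry,
                                                      empty_phantom):
        # compartment noise variance vs analytic sigma^2 (Ew^H Ew)^-1
        scheme = build_aw_scheme((4, 4, 2), max_averages=4)
        labels = np.zeros((4, 4, 2), dtype=np.uint8)
        labels[:2] = 1
        mask = CompartmentMask(labels, {0: "other", 1: "heart"}, small_geometry)
        sigma = 1.0
        draws = []
        for seed in range(500):
            ks = simulate_acquisition(
                empty_phantom, scheme, Protocol(noise_sigma=sigma, seed=seed),
                n_time=256)
            spectra = recon_slam(ks, mask)
            draws.append([spectra["heart"].data[0], spectra["other"].data[0]])
        draws = np.asarray(draws)
        ks = simulate_acquisition(empty_phantom, scheme, Protocol(), n_time=256)
        system = build_slam_system(mask, ks)
        ew = system.weights[:, None] * system.encoding
        cov = np.linalg.inv(ew.conj().T @ ew)
        for i in range(2):
            analytic = sigma**2 * cov[i, i].real
            empirical = np.var(draws[:, i].real, ddof=1)
            assert empirical == pytest.approx(analytic, rel=0.10)


class TestFovShiftCompensation:
    @pytest.mark.parametrize("shift", [-1.0, -0.5, 0.5, 1.0])
    def test_compensated_ratio_within_one_percent(self, shift):
        from slamrecon.spectral import (
            apodize, default_cardiac_template, fit_amares)

        ph = build_default_phantom(motion_amplitude_mm=0.0)
        ks = simulate_acquisition(ph, build_aw_scheme(),
                                  Protocol(gated=True))
        mask = rasterize_masks(ph)

        def heart_ratio(kspace, m):
            fid = apodize(recon_slam(kspace, m)["heart"], 20.0)
            return fit_amares(fid, default_cardiac_template()).ratio()

        base = heart_ratio(ks, mask)
        delta = (0.0, shift, 0.0)
        comp = heart_ratio(shift_fov(ks, delta), shift_mask(mask, delta))
        assert comp == pytest.approx(base, rel=0.01)

    def test_monotone_contamination_toward_chest_wall(self, default_phantom):
        from slamrecon.spectral import (
            apodize, default_cardiac_template, fit_amares)

        ks = simulate_acquisition(default_phantom, build_aw_scheme(),
                                  Protocol(gated=True))
        mask = rasterize_masks(default_phantom)
        grid = recon_ft(ks)
        x, y, z = septal_voxel_index(mask)

        def ratio_at(idx):
            fid = apodize(grid.voxel_fid(idx), 20.0)
            return fit_amares(fid, default_cardiac_template()).ratio()

        # chest wall sits at lower y: stepping toward it raises PCr/ATP
        assert ratio_at((x, y - 1, z)) > ratio_at((x, y, z))


class TestShiftMask:
    def test_zero_delta_identity(self, clean_mask):
        out = shift_mask(clean_mask, (0.0, 0.0, 0.0))
        np.testing.assert_array_equal(out.labels, clean_mask.labels)

    def test_integer_delta_rolls(self, clean_mask):
        out = shift_mask(clean_mask, (0.0, 1.0, 0.0))
        np.testing.assert_array_equal(out.labels,
                                      np.roll(clean_mask.labels, 1, axis=1))

    def test_integer_roll_without_provenance(self, default_geometry):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, default_geometry.matrix).astype(np.uint8)
        mask = CompartmentMask(labels, {0: "other", 1: "heart", 2: "chest_wall"},
                               default_geometry)
        out = shift_mask(mask, (1.0, 0.0, 0.0))
        np.testing.assert_array_equal(out.labels, np.roll(labels, 1, axis=0))

    def test_fractional_without_provenance_unsupported(self, default_geometry):
        from slamrecon.core import UnsupportedOperationError

        labels = np.zeros(default_geometry.matrix, dtype=np.uint8)
        labels[2, 5, 3] = 1
        mask = CompartmentMask(labels, {0: "other", 1: "heart"},
                               default_geometry)
        with pytest.raises(UnsupportedOperationError):
            shift_mask(mask, (0.0, 0.5, 0.0))

    def test_half_voxel_matches_brute_force_rerasterization(self, default_phantom):
        out = shift_mask(rasterize_masks(default_phantom), (0.0, 0.5, 0.0))
        geom = default_phantom.geometry
        dy = 0.5 * geom.voxel_mm[1]
        points = geom.voxel_centers()
        delta = (0.0, dy, 0.0)
        heart = default_phantom.compartment("heart").contains(points, delta) \
            | default_phantom.compartment("blood").contains(points, delta)
        np.testing.assert_array_equal(out.labels == 1, heart)
        chest = default_phantom.compartment("chest_wall").contains(points, delta)
        np.testing.assert_array_equal(out.labels == 2, chest)
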