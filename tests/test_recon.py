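"""Gridding operator, subspace basis/projection, reconstruction, and PSF."""

import numpy as np
import pytest

from qti.epg import TissueParams, build_dictionary
from qti.gridding import GriddingOperator
from qti.recon import (CoefficientImages, compute_basis, estimate_coil_maps,
                       expand_kspace, project_kspace, psf_experiment,
                       reconstruct)
from qti.schedule import make_flip_schedule
from qti.trajectories import make_trajectory


# ---------------------------------------------------------------------------
# gridding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("shape", [(32, 32), (16, 16, 16)])
def test_gridding_adjoint_identity(shape):
    """<A x, y> == <x, A^H y> within 1e-6 relative on random inputs."""
    rng = np.random.default_rng(0)
    coords = rng.uniform(-0.5, 0.5, (400, len(shape)))
    op = GriddingOperator(shape, coords)
    x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    y = rng.standard_normal(400) + 1j * rng.standard_normal(400)
    lhs = np.vdot(op.forward(x), y)
    rhs = np.vdot(x, op.adjoint(y))
    assert abs(lhs - rhs) / abs(lhs) < 1e-6


def test_gridding_matches_explicit_dft():
    rng = np.random.default_rng(1)
    N = 24
    coords = rng.uniform(-0.5, 0.5, (200, 2))
    op = GriddingOperator((N, N), coords)
    x = rng.standard_normal((N, N)) + 1j * rng.standard_normal((N, N))
    idx = np.stack(np.meshgrid(*[np.arange(N) - N // 2] * 2, indexing="ij"), -1).reshape(-1, 2)
    ref = np.exp(-2j * np.pi * coords @ idx.T) @ x.ravel()
    err = np.linalg.norm(op.forward(x) - ref) / np.linalg.norm(ref)
    assert err < 0.02  # kernel approximation level


# ---------------------------------------------------------------------------
# basis
# ---------------------------------------------------------------------------

def test_basis_columns_orthonormal(small_basis):
    G = small_basis.basis.conj().T @ small_basis.basis
    assert np.allclose(G, np.eye(small_basis.R), atol=1e-9)


def test_basis_sign_convention_deterministic(small_dict):
    b1 = compute_basis(small_dict, 6).basis
    b2 = compute_basis(small_dict, 6).basis
    assert np.array_equal(b1, b2)
    for r in range(6):
        j = np.argmax(np.abs(b1[:, r]))
        assert b1[j, r].real > 0 and abs(b1[j, r].imag) < 1e-9


def test_full_rank_projection_lossless(sched_small):
    d = build_dictionary(sched_small, [300.0, 700.0, 1500.0], [40.0, 90.0, 250.0])
    basis = compute_basis(d, d.n_atoms)  # rank = n_atoms < n_reps, spans atoms
    proj = d.atoms @ basis.basis.conj()
    back = proj @ basis.basis.T
    err = np.linalg.norm(back - d.atoms) / np.linalg.norm(d.atoms)
    assert err < 1e-5  # atoms are stored in single precision


def test_rank10_retained_energy(small_dict, small_basis):
    total = np.linalg.norm(small_dict.atoms) ** 2
    kept = np.sum(small_basis.singular_values**2)
    assert kept / total >= 0.999


def test_rank_validation(small_dict):
    with pytest.raises(ValueError, match="rank"):
        compute_basis(small_dict, small_dict.n_reps + 1)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def test_project_single_location_matches_basis_product(small_dict, small_basis):
    """An atom's signal at one k-location projects to basis^H @ atom."""
    atom = small_dict.atoms[7]
    n_reps = small_dict.n_reps
    kdata = atom[None, :, None]  # (1 lead, n_reps, 1 sample), fully sampled
    coeff = project_kspace(kdata[0][None, ...][0], None, small_basis)
    expected = small_basis.basis.conj().T @ atom
    assert np.allclose(coeff[:, 0], expected, atol=1e-6)


def test_project_zero_gives_zero(small_basis):
    rep_map = np.arange(small_basis.n_reps)[None, :]
    z = np.zeros((small_basis.n_reps, 3))
    assert np.allclose(project_kspace(z, rep_map, small_basis), 0.0)


def test_project_expand_idempotent_on_subspace(small_basis):
    """expand -> project (summing over repetitions) is the identity on
    coefficient space, since the basis columns are orthonormal."""
    rng = np.random.default_rng(3)
    coeff = rng.standard_normal((small_basis.R, 4)) + 0j
    kdata = expand_kspace(coeff, None, small_basis)  # (n_reps, 4)
    coeff2 = project_kspace(kdata, None, small_basis)
    assert np.allclose(coeff2, coeff, atol=1e-10)


def test_project_shape_validation(small_basis):
    with pytest.raises(ValueError, match="rep_map|repetition"):
        project_kspace(np.zeros((7, 3)), np.arange(5)[None, :], small_basis)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def test_point_object_reconstruction_peak():
    traj = make_trajectory("radial2d", 101, matrix=32)
    coords = traj.flat_coords()
    # point source at center: unit k-space everywhere
    kdata = np.ones((1, coords.shape[0]), dtype=complex)
    imgs = reconstruct(kdata, traj, 32)
    mag = np.abs(imgs.images[0])
    assert np.unravel_index(np.argmax(mag), mag.shape) == (16, 16)
    assert mag[16, 16] / mag.max() == pytest.approx(1.0)
    # off-center voxels are far below the peak for dense radial sampling
    assert np.median(mag) < 0.05 * mag.max()


def test_coil_uniform_matches_single_coil():
    traj = make_trajectory("radial2d", 60, matrix=32)
    rng = np.random.default_rng(0)
    kdata = rng.standard_normal((2, traj.n_interleaves * traj.n_samples_per_interleave)) + 0j
    single = reconstruct(kdata, traj, 32)
    maps = np.ones((3, 32, 32), dtype=complex) / np.sqrt(3)
    multi = reconstruct(
        np.stack([kdata / np.sqrt(3)] * 3, axis=1), traj, 32, coil_maps=maps
    )
    assert np.allclose(multi.images, single.images, atol=1e-10)


def test_estimate_coil_maps_recovers_smooth_sensitivities():
    from qti.phantom import make_coil_maps

    maps = make_coil_maps(32, 4, seed=1, ndim=2)
    obj = np.zeros((32, 32))
    yy, xx = np.meshgrid(*[np.arange(32) - 16] * 2, indexing="ij")
    obj[np.hypot(yy, xx) < 12] = 1.0
    coil_imgs = maps * obj
    est = estimate_coil_maps(coil_imgs, smooth_sigma=1.0)
    inside = obj > 0
    # compare up to the common voxelwise phase reference
    ref = maps * np.exp(-1j * np.angle(maps[0]))
    err = np.abs(np.abs(est[:, inside]) - np.abs(ref[:, inside])).mean()
    assert err < 0.05


def test_reconstruct_sample_count_mismatch():
    traj = make_trajectory("radial2d", 10, matrix=32)
    with pytest.raises(ValueError, match="samples"):
        reconstruct(np.ones((2, 5), dtype=complex), traj, 32)


# ---------------------------------------------------------------------------
# PSF experiment
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def psf_setup():
    sched = make_flip_schedule(100)
    d = build_dictionary(sched, np.linspace(100, 2500, 12), np.linspace(20, 800, 10))
    basis = compute_basis(d, 6)
    traj = make_trajectory("radial2d", 100, matrix=32)
    return sched, basis, traj


def test_fully_sampled_psf_matches_dft_oracle(psf_setup):
    """The reference PSF equals an independently coded DFT sum within 1e-9."""
    sched, basis, traj = psf_setup
    from qti.epg import simulate_signal

    rep = psf_experiment(sched, traj, basis, TissueParams(600.0, 70.0))
    sig = simulate_signal(sched, TissueParams(600.0, 70.0))
    coeff = basis.basis.conj().T @ sig
    dcf = traj.flat_dcf()
    dcf = dcf / dcf.sum()
    kx = traj.flat_coords()[:, 0]
    for r in range(basis.R):
        oracle = np.array(
            [np.sum(coeff[r] * dcf * np.exp(2j * np.pi * kx * x)) for x in rep.positions]
        )
        assert np.max(np.abs(rep.profiles["full"][r] - oracle)) < 1e-9


def test_psf_reports_fwhm_and_sidelobes(psf_setup):
    sched, basis, traj = psf_setup
    rep = psf_experiment(sched, traj, basis)
    assert rep.fwhm["full"].shape == (basis.R,)
    assert np.all(np.isfinite(rep.fwhm["full"]))
    assert np.all(rep.max_sidelobe["full"] < 1.0)


def test_first_coefficient_psf_close_to_reference():
    """Undersampled first-coefficient PSFs approximate the fully sampled one."""
    sched = make_flip_schedule(80)
    d = build_dictionary(sched, np.linspace(100, 2500, 10), np.linspace(20, 800, 8))
    basis = compute_basis(d, 6)
    for kind, kwargs in [
        ("radial2d", dict(matrix=32)),
        ("spiral2d", dict(matrix=32)),
        ("radial3d", dict(n_segments=4, matrix=24, seed=2)),
        ("spiral3d", dict(n_segments=4, matrix=24, dcf_matrix=24)),
    ]:
        traj = make_trajectory(kind, 80, **kwargs)
        rep = psf_experiment(sched, traj, basis)
        ref = rep.max_sidelobe["full"][0]
        assert rep.max_sidelobe["zerofill"][0] <= 2.0 * max(ref, 1e-3), kind
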