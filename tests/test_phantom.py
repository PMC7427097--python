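"""Digital phantom, coil maps, and the exact class-cached forward model."""

import numpy as np
import pytest

from qti.epg import TissueParams, simulate_signal
from qti.gridding import GriddingOperator
from qti.phantom import (TISSUE_CLASSES, KSpaceData, forward_simulate,
                         make_coil_maps, make_phantom)
from qti.schedule import make_flip_schedule
from qti.trajectories import make_trajectory


def test_wm_class_values():
    assert TISSUE_CLASSES[1][1:3] == (600.0, 70.0)


def test_phantom_reproducible_and_jittered():
    a = make_phantom(64, seed=5, ndim=2)
    b = make_phantom(64, seed=5, ndim=2)
    c = make_phantom(64, seed=6, ndim=2)
    assert np.array_equal(a.labels, b.labels)
    assert not np.array_equal(a.labels, c.labels)


@pytest.mark.parametrize("ndim", [2, 3])
def test_phantom_covers_all_classes(ndim):
    ph = make_phantom(64, seed=0, ndim=ndim)
    assert set(np.unique(ph.labels)) == {0, 1, 2, 3, 4}
    assert np.all(ph.t2_ms <= ph.t1_ms)
    assert ph.pd.min() >= 0 and ph.pd.max() <= 1


def test_phantom_piecewise_constant():
    ph = make_phantom(48, seed=1, ndim=2)
    for lab in (1, 2, 3, 4):
        m = ph.labels == lab
        assert np.ptp(ph.t1_ms[m]) == 0.0
        assert np.ptp(ph.pd[m]) == 0.0


def test_phantom_rejects_small_matrix():
    with pytest.raises(ValueError, match="matrix"):
        make_phantom(16)


def test_single_coil_uniform():
    maps = make_coil_maps(32, 1, seed=0, ndim=2)
    assert np.allclose(maps, 1.0)


def test_coil_maps_sum_of_squares_unit():
    maps = make_coil_maps(48, 6, seed=2, ndim=2)
    sos = np.sum(np.abs(maps) ** 2, axis=0)
    assert np.all((sos > 0.95) & (sos < 1.05))
    assert np.array_equal(maps, make_coil_maps(48, 6, seed=2, ndim=2))


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fwd_setup():
    sched = make_flip_schedule(60)
    traj = make_trajectory("radial2d", 60, matrix=32)
    ph = make_phantom(32, seed=3, ndim=2)
    return sched, traj, ph


def test_forward_deterministic_noiseless(fwd_setup):
    sched, traj, ph = fwd_setup
    a = forward_simulate(ph, sched, traj)
    b = forward_simulate(ph, sched, traj)
    assert np.array_equal(a.kdata, b.kdata)
    assert a.kdata.shape == (1, traj.n_interleaves, traj.n_samples_per_interleave)


def test_forward_noise_reproducible_and_variance():
    """Noise is seeded and its variance matches the SNR definition within
    2% over >= 1e5 complex samples."""
    sched = make_flip_schedule(800)
    traj = make_trajectory("radial2d", 800, matrix=64)
    ph = make_phantom(64, seed=3, ndim=2)
    clean = forward_simulate(ph, sched, traj)
    n1 = forward_simulate(ph, sched, traj, snr_db=30.0, seed=42)
    n2 = forward_simulate(ph, sched, traj, snr_db=30.0, seed=42)
    assert np.array_equal(n1.kdata, n2.kdata)
    noise = n1.kdata - clean.kdata
    assert noise.size >= 1e5
    sigma_exp = np.sqrt(np.mean(np.abs(clean.kdata) ** 2)) * 10 ** (-30.0 / 20.0)
    sigma_obs = np.sqrt(np.mean(np.abs(noise) ** 2))
    assert sigma_obs == pytest.approx(sigma_exp, rel=0.02)


def test_point_object_spoke_magnitude(fwd_setup):
    """A single-voxel phantom yields constant |k-data| along each spoke."""
    sched, traj, _ = fwd_setup
    ph = make_phantom(32, seed=0, ndim=2)
    ph.labels[:] = 0
    ph.pd[:] = 0.0
    ph.t1_ms[:] = 0.0
    ph.t2_ms[:] = 0.0
    ph.labels[16, 16] = 1
    ph.pd[16, 16] = 1.0
    ph.t1_ms[16, 16], ph.t2_ms[16, 16] = 600.0, 70.0
    ks = forward_simulate(ph, sched, traj)
    sig = simulate_signal(sched, TissueParams(600.0, 70.0))
    rep_of_il = np.argsort(traj.rep_map[0])
    for il in (0, 13, 40):
        t = int(traj.rep_map[0][il] == il) * 0 + il  # radial2d: interleave == rep
        mags = np.abs(ks.kdata[0, il])
        assert np.allclose(mags, abs(sig[il]), rtol=2e-2)


def test_class_caching_matches_direct_nufft(fwd_setup):
    """Cached per-class synthesis equals the per-repetition forward NUFFT."""
    sched, traj, ph = fwd_setup
    ks = forward_simulate(ph, sched, traj)
    coords = traj.flat_coords().reshape(traj.n_interleaves, -1, 2)
    sigs = {
        lab: simulate_signal(sched, TissueParams(*TISSUE_CLASSES[lab][1:3]))
        for lab in (1, 2, 3, 4)
    }
    for rep in (0, 25):
        il = traj.rep_map[0, rep]
        img = np.zeros(ph.shape, dtype=complex)
        for lab, s in sigs.items():
            img += (ph.labels == lab) * ph.pd * s[rep]
        op = GriddingOperator(ph.shape, coords[il])
        ref = op.forward(img)
        assert np.allclose(ks.kdata[0, il], ref, rtol=1e-10, atol=1e-12)


def test_fully_sampled_layout(fwd_setup):
    sched, traj, ph = fwd_setup
    ks = forward_simulate(ph, sched, traj, fully_sampled=True)
    assert ks.kdata.shape == (
        1, sched.n_reps, traj.n_interleaves * traj.n_samples_per_interleave
    )


def test_kspace_h5_round_trip(tmp_path, fwd_setup):
    sched, traj, ph = fwd_setup
    ks = forward_simulate(ph, sched, traj, snr_db=40.0, seed=1)
    p = tmp_path / "k.h5"
    ks.save_h5(p, traj)
    loaded, traj2 = KSpaceData.load_h5(p)
    assert np.allclose(loaded.kdata, ks.kdata.astype(np.complex64))
    assert loaded.snr_db == 40.0
    assert np.allclose(traj2.coords, traj.coords)
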