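"""EPG operators, transient-state simulation, and dictionary construction.

The independent oracle for the full simulation is a brute-force isochromat
ensemble: many spins uniformly dephased across the voxel, rotated and
relaxed explicitly, and averaged.  With uniformly spaced spins this average
is exact for any integer number of dephasing cycles per TR.
"""

import numpy as np
import pytest

from qti.epg import (Dictionary, EPGState, TissueParams, apply_rf,
                     build_dictionary, default_t2_grid, evolve,
                     reduced_t1_grid, simulate_signal, simulate_signals_batch)
from qti.schedule import make_flip_schedule


def isochromat_signal(schedule, t1, t2, n_iter=2, n_spins=2000):
    """Brute-force ensemble average over uniformly dephased spins."""
    z_pos = (np.arange(n_spins) + 0.5) / n_spins - 0.5
    dphi = 2 * np.pi * schedule.dephasing_cycles * z_pos
    m = np.zeros(n_spins, dtype=complex)
    mz = np.ones(n_spins)
    sig = np.zeros(schedule.n_reps, dtype=complex)
    e1te, e2te = np.exp(-schedule.te_ms / t1), np.exp(-schedule.te_ms / t2)
    rem = schedule.tr_ms - schedule.te_ms
    e1rm, e2rm = np.exp(-rem / t1), np.exp(-rem / t2)
    for _ in range(n_iter):
        if schedule.inversion:
            m[:] = 0
            mz = -schedule.inversion_efficiency * mz
        for i in range(schedule.n_reps):
            a = np.deg2rad(schedule.flip_angles[i])
            p = np.deg2rad(schedule.rf_phases[i])
            eip = np.exp(1j * p)
            m_new = (
                np.cos(a / 2) ** 2 * m
                + np.sin(a / 2) ** 2 * eip**2 * np.conj(m)
                - 1j * eip * np.sin(a) * mz
            )
            mz = (-0.5j * (np.conj(eip) * m - eip * np.conj(m)) * np.sin(a)).real + np.cos(a) * mz
            m = m_new * e2te
            mz = mz * e1te + (1 - e1te)
            sig[i] = m.mean()
            m = m * e2rm * np.exp(1j * dphi)
            mz = mz * e1rm + (1 - e1rm)
    return sig


# ---------------------------------------------------------------------------
# elementary operators
# ---------------------------------------------------------------------------

def test_rf_inversion_flips_z():
    s = apply_rf(EPGState.equilibrium(4), 180.0, 0.0)
    assert s.z[0] == pytest.approx(-1.0)
    assert np.allclose(s.f_plus, 0.0, atol=1e-12)


@pytest.mark.parametrize("flip", [10.0, 35.0, 77.0])
def test_rf_rotation_z_component(flip):
    s = apply_rf(EPGState.equilibrium(4), flip, 0.0)
    assert abs(s.z[0]) == pytest.approx(abs(np.cos(np.deg2rad(flip))), abs=1e-12)


def test_rf_zero_flip_is_identity():
    s0 = EPGState.equilibrium(4)
    s0.f_plus[1] = 0.3 - 0.1j
    s0.f_minus[1] = np.conj(0.2j)
    s = apply_rf(s0, 0.0, 45.0)
    assert np.allclose(s.f_plus, s0.f_plus)
    assert np.allclose(s.z, s0.z)


def test_rf_is_unitary():
    """RF mixing conserves sum(|F+|^2/2 + |F-|^2/2 + |Z|^2); transverse
    energy therefore never exceeds the initial longitudinal store."""
    rng = np.random.default_rng(0)
    s = EPGState.equilibrium(6)

    def energy(st):
        return (
            0.5 * np.sum(np.abs(st.f_plus) ** 2)
            + 0.5 * np.sum(np.abs(st.f_minus) ** 2)
            + np.sum(np.abs(st.z) ** 2)
        )

    for _ in range(20):
        e_before = energy(s)
        s = apply_rf(s, rng.uniform(0, 90), rng.uniform(0, 360))
        assert energy(s) == pytest.approx(e_before, rel=1e-12)
        trans = 0.5 * (np.sum(np.abs(s.f_plus) ** 2) + np.sum(np.abs(s.f_minus) ** 2))
        assert trans <= 1.0 + 1e-9


def test_evolve_identity_and_recovery():
    s = apply_rf(EPGState.equilibrium(4), 30.0, 0.0)
    same = evolve(s, 0.0, 800.0, 80.0, 0)
    assert np.allclose(same.f_plus, s.f_plus)
    relaxed = evolve(s, 1e7, 800.0, 80.0, 0)
    assert relaxed.z[0] == pytest.approx(1.0)
    assert np.allclose(relaxed.f_plus, 0.0, atol=1e-12)


def test_evolve_z0_closed_form():
    s = apply_rf(EPGState.equilibrium(4), 40.0, 0.0)
    z0 = s.z[0]
    dt, t1 = 13.0, 700.0
    out = evolve(s, dt, t1, 90.0, 0)
    e1 = np.exp(-dt / t1)
    assert out.z[0] == pytest.approx(e1 * z0 + (1 - e1))


def test_evolve_negative_dt_rejected():
    with pytest.raises(ValueError, match="dt_ms"):
        evolve(EPGState.equilibrium(2), -1.0, 800.0, 80.0, 0)


def test_shift_round_trip():
    s = apply_rf(EPGState.equilibrium(6), 50.0, 20.0)
    s = evolve(s, 5.0, 800.0, 80.0, 1)
    back = evolve(s, 0.0, 800.0, 80.0, -1)
    fwd = evolve(back, 0.0, 800.0, 80.0, 1)
    assert np.allclose(fwd.f_plus, s.f_plus)
    assert np.allclose(fwd.f_minus, s.f_minus)


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------

def test_zero_flip_train_gives_zero_signal():
    sched = make_flip_schedule(20, ramp_peak_deg=1e-9, tail_deg=1e-9)
    sched = sched.with_(flip_angles=np.zeros(20))
    sig = simulate_signal(sched, TissueParams(800, 80))
    assert np.allclose(sig, 0.0, atol=1e-14)


def test_pd_linearity():
    sched = make_flip_schedule(60)
    s1 = simulate_signal(sched, TissueParams(600, 70, pd=1.0))
    s2 = simulate_signal(sched, TissueParams(600, 70, pd=2.0))
    assert np.allclose(s2, 2.0 * s1)


def test_epg_matches_isochromat_wm_voxel():
    """White-matter voxel (T1=600, T2=70 ms): EPG vs ensemble within 1e-6."""
    sched = make_flip_schedule(150)
    s_epg = simulate_signal(sched, TissueParams(600.0, 70.0), K=150)
    s_iso = isochromat_signal(sched, 600.0, 70.0)
    err = np.linalg.norm(s_epg - s_iso) / np.linalg.norm(s_iso)
    assert err < 1e-6


def test_two_iteration_stationarity():
    """The 2nd and 3rd segment signals agree within 1e-3 (steady transient state)."""
    sched = make_flip_schedule(880)
    # holds for the densely gridded T1 range (<= 2 s); tissues with much
    # longer T1 cannot finish recovering within one segment and keep
    # drifting by a few percent between iterations
    for t1, t2 in [(600, 70), (1200, 100), (2000, 300)]:
        s2 = simulate_signals_batch(sched, [t1], [t2], n_iterations=2)[0]
        s3 = simulate_signals_batch(sched, [t1], [t2], n_iterations=3)[0]
        assert np.linalg.norm(s3 - s2) / np.linalg.norm(s2) < 1e-3


def test_t2_monotonicity_at_large_flips():
    """More T2 never means less signal in the spin-echo (large-flip) portion."""
    sched = make_flip_schedule(200)
    peak_idx = int(np.argmax(sched.flip_angles))
    window = slice(peak_idx - 5, peak_idx + 5)
    prev = None
    for t2 in [40.0, 80.0, 160.0, 320.0]:
        sig = np.abs(simulate_signal(sched, TissueParams(1000.0, t2)))[window]
        if prev is not None:
            assert np.all(sig >= prev - 1e-12)
        prev = sig


def test_generic_and_batch_paths_agree():
    from qti.epg import _simulate_generic

    sched = make_flip_schedule(80)
    t = TissueParams(900.0, 110.0)
    fast = simulate_signal(sched, t, K=80)
    slow = _simulate_generic(sched, t, 2, 80)
    assert np.linalg.norm(fast - slow) / np.linalg.norm(slow) < 1e-12


# ---------------------------------------------------------------------------
# dictionary
# ---------------------------------------------------------------------------

def test_small_dictionary_count_and_norms():
    sched = make_flip_schedule(40)
    d = build_dictionary(sched, [300.0, 900.0], [50.0, 100.0, 200.0])
    assert d.n_atoms == 6
    assert np.allclose(np.linalg.norm(d.atoms, axis=1), 1.0, atol=1e-6)
    assert np.all(d.norms > 0)


def test_default_t2_grid_has_229_values():
    g = default_t2_grid()
    assert len(g) == 229
    assert np.sum((g >= 10) & (g <= 300)) == 59
    assert np.sum((g >= 310) & (g <= 2000)) == 170


def test_reduced_t1_grid_gives_52670_pairs():
    assert len(reduced_t1_grid()) * len(default_t2_grid()) == 52670


def test_t2_le_t1_constraint():
    sched = make_flip_schedule(30)
    d = build_dictionary(sched, [100.0, 500.0], [50.0, 200.0, 800.0],
                         constrain_t2_le_t1=True)
    assert np.all(d.t2_ms <= d.t1_ms)
    assert d.n_atoms == 1 + 2  # (100,50); (500,{50,200})


def test_dictionary_grid_validation():
    sched = make_flip_schedule(30)
    with pytest.raises(ValueError, match="increasing"):
        build_dictionary(sched, [500.0, 100.0], [50.0])
    with pytest.raises(ValueError, match="empty"):
        build_dictionary(sched, np.array([]), [50.0])


def test_dictionary_h5_round_trip(tmp_path, small_dict):
    p = tmp_path / "dict.h5"
    small_dict.save_h5(p)
    d2 = Dictionary.load_h5(p)
    assert np.allclose(d2.atoms, small_dict.atoms)
    assert np.allclose(d2.t1_ms, small_dict.t1_ms)
    assert d2.schedule_hash == small_dict.schedule_hash
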