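"""Extended Phase Graph (EPG) simulation of the transient-state sequence.

The EPG formalism tracks magnetization as complex configuration states at
discrete dephasing orders k: transverse states F(k) and longitudinal states
Z(k).  We store, per order k >= 0,

    ``f_plus[k]  = F(k)``,  ``f_minus[k] = conj(F(-k))``,  ``z[k] = Z(k)``,

so that a single 3x3 mixing matrix describes an RF pulse at every order.  An
unbalanced gradient per TR shifts all transverse orders by one; the recorded
echo is F(0) after the echo-time relaxation.

For the FISP-like sequence used here the RF phase is constant zero, in which
case all F states stay purely imaginary and all Z states real.  The batch
dictionary simulator exploits this to run entirely in real arithmetic (a
numba kernel), while the single-state API below implements the general
complex operators.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .schedule import AcquisitionSchedule

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "EPGState",
    "TissueParams",
    "Dictionary",
    "apply_rf",
    "evolve",
    "simulate_signal",
    "simulate_signals_batch",
    "build_dictionary",
    "default_t1_grid",
    "default_t2_grid",
    "reduced_t1_grid",
    "hann_sinc_profile",
]


# ---------------------------------------------------------------------------
# state and tissue containers
# ---------------------------------------------------------------------------

@dataclass
class EPGState:
    """EPG configuration-state vector up to maximum order ``K``."""

    f_plus: np.ndarray   # complex, orders 0..K, F(k)
    f_minus: np.ndarray  # complex, orders 0..K, conj(F(-k))
    z: np.ndarray        # complex, orders 0..K, Z(k)

    @property
    def K(self) -> int:
        return len(self.f_plus) - 1

    @classmethod
    def equilibrium(cls, K: int) -> "EPGState":
        """Unit equilibrium magnetization: Z(0) = 1, everything else 0."""
        fp = np.zeros(K + 1, dtype=complex)
        fm = np.zeros(K + 1, dtype=complex)
        z = np.zeros(K + 1, dtype=complex)
        z[0] = 1.0
        return cls(fp, fm, z)

    def copy(self) -> "EPGState":
        return EPGState(self.f_plus.copy(), self.f_minus.copy(), self.z.copy())


@dataclass
class TissueParams:
    """Relaxation times (ms) and relative proton density of one tissue."""

    t1_ms: float
    t2_ms: float
    pd: float = 1.0
    enforce_t2_le_t1: bool = True

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError(
                f"relaxation times must be positive, got T1={self.t1_ms}, T2={self.t2_ms}"
            )
        if self.pd < 0:
            raise ValueError(f"proton density must be >= 0, got {self.pd}")
        if self.enforce_t2_le_t1 and self.t2_ms > self.t1_ms:
            raise ValueError(
                f"T2={self.t2_ms} ms exceeds T1={self.t1_ms} ms; pass "
                "enforce_t2_le_t1=False for non-physical grid points"
            )


# ---------------------------------------------------------------------------
# elementary EPG operators (general complex form)
# ---------------------------------------------------------------------------

def apply_rf(state: EPGState, flip_deg: float, phase_deg: float = 0.0) -> EPGState:
    """Apply an RF rotation to every configuration order.

    Uses the standard unitary 3x3 mixing matrix acting on
    ``(F(k), conj(F(-k)), Z(k))`` jointly at each order k.
    """
    if not (np.isfinite(flip_deg) and np.isfinite(phase_deg)):
        raise ValueError("flip and phase must be finite")
    a = np.deg2rad(flip_deg)
    p = np.deg2rad(phase_deg)
    c2 = np.cos(a / 2) ** 2
    s2 = np.sin(a / 2) ** 2
    sa = np.sin(a)
    ca = np.cos(a)
    eip = np.exp(1j * p)
    T = np.array(
        [
            [c2, eip**2 * s2, -1j * eip * sa],
            [np.conj(eip) ** 2 * s2, c2, 1j * np.conj(eip) * sa],
            [-0.5j * np.conj(eip) * sa, 0.5j * eip * sa, ca],
        ]
    )
    stacked = np.vstack([state.f_plus, state.f_minus, state.z])
    fp, fm, z = T @ stacked
    return EPGState(fp, fm, z)


def evolve(
    state: EPGState,
    dt_ms: float,
    t1_ms: float,
    t2_ms: float,
    shift_orders: int = 0,
) -> EPGState:
    """Relax for ``dt_ms`` and shift transverse orders by ``shift_orders``.

    Transverse states decay with E2 = exp(-dt/T2), longitudinal with
    E1 = exp(-dt/T1) plus recovery (1 - E1) into Z(0).  A positive shift
    models a net dephasing gradient moment.
    """
    if dt_ms < 0:
        raise ValueError(f"dt_ms must be >= 0, got {dt_ms}")
    if shift_orders not in (0, 1, -1, 2, -2):
        raise ValueError(f"shift_orders must be in {{0, +-1, +-2}}, got {shift_orders}")
    e1 = np.exp(-dt_ms / t1_ms)
    e2 = np.exp(-dt_ms / t2_ms)
    fp = state.f_plus * e2
    fm = state.f_minus * e2
    z = state.z * e1
    z[0] += 1.0 - e1

    for _ in range(abs(shift_orders)):
        if shift_orders > 0:
            fp = np.roll(fp, 1)
            fp[0] = np.conj(fm[1]) if len(fm) > 1 else 0.0
            fm = np.roll(fm, -1)
            fm[-1] = 0.0
        else:
            fp = np.roll(fp, -1)
            fp[-1] = 0.0
            fm = np.roll(fm, 1)
            fm[0] = np.conj(fp[0])
    return EPGState(fp, fm, z)


def _invert(state: EPGState, efficiency: float) -> EPGState:
    """Adiabatic inversion followed by a crusher: Z -> -eff * Z, F spoiled."""
    out = state.copy()
    out.f_plus[:] = 0.0
    out.f_minus[:] = 0.0
    out.z *= -efficiency
    return out


# ---------------------------------------------------------------------------
# fast real-arithmetic batch kernel (RF phase identically zero)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _fisp_batch_kernel(flips_rad, tr_ms, te_ms, t1_ms, t2_ms, n_iter, K, do_inv, inv_eff):
    """Simulate a batch of (T1, T2) atoms through ``n_iter`` segments.

    With zero RF phase the F states are purely imaginary and Z real; this
    kernel propagates the imaginary parts ``fp, fm`` and real ``z``.  The
    physical echo is ``1j * sig``.
    """
    n_reps = flips_rad.size
    n_atoms = t1_ms.size
    sig = np.zeros((n_atoms, n_iter, n_reps), dtype=np.float64)

    c2 = np.empty(n_reps)
    s2 = np.empty(n_reps)
    sa = np.empty(n_reps)
    ca = np.empty(n_reps)
    for i in range(n_reps):
        a = flips_rad[i]
        c2[i] = np.cos(a / 2.0) ** 2
        s2[i] = np.sin(a / 2.0) ** 2
        sa[i] = np.sin(a)
        ca[i] = np.cos(a)

    for b in range(n_atoms):
        e1te = np.exp(-te_ms / t1_ms[b])
        e2te = np.exp(-te_ms / t2_ms[b])
        rem = tr_ms - te_ms
        e1rm = np.exp(-rem / t1_ms[b])
        e2rm = np.exp(-rem / t2_ms[b])

        fp = np.zeros(K + 1)
        fm = np.zeros(K + 1)
        z = np.zeros(K + 1)
        z[0] = 1.0
        kmax = 0  # highest populated order so far

        for it in range(n_iter):
            if do_inv:
                for k in range(kmax + 1):
                    fp[k] = 0.0
                    fm[k] = 0.0
                    z[k] = -inv_eff * z[k]
            for i in range(n_reps):
                # RF mixing at every populated order
                for k in range(kmax + 1):
                    a0 = fp[k]
                    m0 = fm[k]
                    z0 = z[k]
                    fp[k] = c2[i] * a0 + s2[i] * m0 - sa[i] * z0
                    fm[k] = s2[i] * a0 + c2[i] * m0 + sa[i] * z0
                    z[k] = 0.5 * sa[i] * (a0 - m0) + ca[i] * z0
                # relax to the echo and record F(0)
                for k in range(kmax + 1):
                    fp[k] *= e2te
                    fm[k] *= e2te
                    z[k] *= e1te
                z[0] += 1.0 - e1te
                sig[b, it, i] = fp[0]
                # relax for the remainder of TR
                for k in range(kmax + 1):
                    fp[k] *= e2rm
                    fm[k] *= e2rm
                    z[k] *= e1rm
                z[0] += 1.0 - e1rm
                # gradient shift by one order
                if kmax < K:
                    kmax += 1
                for k in range(kmax, 0, -1):
                    fp[k] = fp[k - 1]
                fp[0] = -fm[1] if kmax >= 1 else 0.0
                for k in range(kmax):
                    fm[k] = fm[k + 1]
                fm[kmax] = 0.0
                fm[0] = -fp[0]
    return sig


def _simulate_batch_zero_phase(schedule, t1_ms, t2_ms, n_iterations, K):
    flips = np.deg2rad(np.asarray(schedule.flip_angles, dtype=np.float64))
    sig = _fisp_batch_kernel(
        flips,
        float(schedule.tr_ms),
        float(schedule.te_ms),
        np.asarray(t1_ms, dtype=np.float64),
        np.asarray(t2_ms, dtype=np.float64),
        int(n_iterations),
        int(K),
        bool(schedule.inversion),
        float(schedule.inversion_efficiency),
    )
    return 1j * sig[:, -1, :]  # final iteration; F states are i * (real kernel value)


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------

def default_max_order(n_reps: int, K: int | None = None) -> int:
    """Default EPG truncation order: min(n_reps, 80) unless overridden."""
    return int(min(n_reps, 80)) if K is None else int(K)


def hann_sinc_profile(n_sub: int = 9, time_bandwidth: float = 4.0) -> np.ndarray:
    """Relative flip-angle scales across a slice for a Hann-windowed sinc pulse.

    The small-tip excitation profile is the Fourier transform of the RF
    envelope; we sample it at ``n_sub`` positions across the nominal slice
    width and normalize its peak to 1.  Used for 2D acquisitions, where the
    effective flip angle varies across the slice.
    """
    nt = 512
    t = np.linspace(-1, 1, nt)  # normalized pulse duration
    env = np.sinc(0.5 * time_bandwidth * t) * (0.5 + 0.5 * np.cos(np.pi * t))
    # profile across slice positions z in units of slice thickness
    z = np.linspace(-0.5, 0.5, n_sub)
    # FT of envelope at frequency f = z * TBW (cycles over the pulse)
    phase = np.exp(-2j * np.pi * np.outer(z * time_bandwidth, t / 2.0))
    prof = np.abs(phase @ env)
    return prof / prof.max()


def simulate_signal(
    schedule: AcquisitionSchedule,
    tissue: TissueParams,
    n_iterations: int = 2,
    slice_profile: np.ndarray | None = None,
    K: int | None = None,
) -> np.ndarray:
    """Simulate the complex transient-state signal for one tissue.

    Runs ``{inversion -> [RF -> echo at TE -> relax/shift over TR]}`` for
    ``n_iterations`` segments and returns the final segment's echo train
    scaled by the tissue's proton density.  With ``slice_profile`` (an array
    of relative flip-angle scales across the slice) the result is the mean
    of the sub-slice simulations.
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    schedule.validate()
    kmax = default_max_order(schedule.n_reps, K)

    scales = np.atleast_1d(np.asarray(slice_profile, dtype=float)) if slice_profile is not None else np.array([1.0])

    zero_phase = bool(np.all(np.asarray(schedule.rf_phases) == 0.0))
    acc = np.zeros(schedule.n_reps, dtype=complex)
    for s in scales:
        sub = schedule.with_(flip_angles=np.clip(schedule.flip_angles * s, 0.0, 90.0))
        if zero_phase:
            sig = _simulate_batch_zero_phase(
                sub, [tissue.t1_ms], [tissue.t2_ms], n_iterations, kmax
            )[0]
        else:
            sig = _simulate_generic(sub, tissue, n_iterations, kmax)
        acc += sig
    return tissue.pd * acc / len(scales)


def _simulate_generic(schedule, tissue, n_iterations, K):
    """Reference complex-state simulation via the elementary operators."""
    state = EPGState.equilibrium(K)
    sig = np.zeros(schedule.n_reps, dtype=complex)
    for _ in range(n_iterations):
        if schedule.inversion:
            state = _invert(state, schedule.inversion_efficiency)
        for i in range(schedule.n_reps):
            state = apply_rf(state, schedule.flip_angles[i], schedule.rf_phases[i])
            state = evolve(state, schedule.te_ms, tissue.t1_ms, tissue.t2_ms, 0)
            sig[i] = state.f_plus[0]
            state = evolve(
                state, schedule.tr_ms - schedule.te_ms, tissue.t1_ms, tissue.t2_ms, 1
            )
    return sig


def simulate_signals_batch(
    schedule: AcquisitionSchedule,
    t1_ms: np.ndarray,
    t2_ms: np.ndarray,
    n_iterations: int = 2,
    slice_profile: np.ndarray | None = None,
    K: int | None = None,
) -> np.ndarray:
    """Vectorized :func:`simulate_signal` over arrays of (T1, T2) pairs.

    Returns a complex array of shape ``(n_atoms, n_reps)`` with unit proton
    density.  Requires the zero-RF-phase fast path.
    """
    if not np.all(np.asarray(schedule.rf_phases) == 0.0):
        raise NotImplementedError("batch simulation requires zero RF phase")
    kmax = default_max_order(schedule.n_reps, K)
    scales = np.atleast_1d(np.asarray(slice_profile, dtype=float)) if slice_profile is not None else np.array([1.0])
    acc = np.zeros((len(t1_ms), schedule.n_reps), dtype=complex)
    for s in scales:
        sub = schedule.with_(flip_angles=np.clip(schedule.flip_angles * s, 0.0, 90.0))
        acc += _simulate_batch_zero_phase(sub, t1_ms, t2_ms, n_iterations, kmax)
    return acc / len(scales)


# ---------------------------------------------------------------------------
# dictionary
# ---------------------------------------------------------------------------

def default_t1_grid() -> np.ndarray:
    """T1 grid in ms: 10:1:2000 then 2100:100:5000."""
    return np.concatenate([np.arange(10, 2001, 1), np.arange(2100, 5001, 100)]).astype(float)


def reduced_t1_grid() -> np.ndarray:
    """Coarser T1 grid (10 ms steps below 2 s): 10:10:2000 then 2100:100:5000.

    Paired with the default T2 grid this yields 230 x 229 = 52,670 atoms.
    """
    return np.concatenate([np.arange(10, 2001, 10), np.arange(2100, 5001, 100)]).astype(float)


def default_t2_grid() -> np.ndarray:
    """T2 grid in ms: 10:5:300 then 310:10:2000 (229 values)."""
    return np.concatenate([np.arange(10, 301, 5), np.arange(310, 2001, 10)]).astype(float)


@dataclass
class Dictionary:
    """Unit-norm simulated signal atoms labelled with (T1, T2).

    ``norms`` holds each atom's pre-normalization 2-norm, the scaling factor
    that proxies proton density during inference.
    """

    atoms: np.ndarray    # complex, (n_atoms, n_reps), rows unit 2-norm
    norms: np.ndarray    # (n_atoms,), > 0
    t1_ms: np.ndarray    # (n_atoms,)
    t2_ms: np.ndarray    # (n_atoms,)
    schedule_hash: str = ""

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_reps(self) -> int:
        return self.atoms.shape[1]

    @property
    def params(self) -> np.ndarray:
        """(n_atoms, 2) array of (T1, T2) labels in ms."""
        return np.stack([self.t1_ms, self.t2_ms], axis=1)

    # -- persistence -------------------------------------------------------
    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("atoms", data=self.atoms)
            f.create_dataset("norms", data=self.norms)
            f.create_dataset("t1_ms", data=self.t1_ms)
            f.create_dataset("t2_ms", data=self.t2_ms)
            f.attrs["schedule_hash"] = self.schedule_hash

    @classmethod
    def load_h5(cls, path) -> "Dictionary":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                atoms=f["atoms"][:],
                norms=f["norms"][:],
                t1_ms=f["t1_ms"][:],
                t2_ms=f["t2_ms"][:],
                schedule_hash=str(f.attrs.get("schedule_hash", "")),
            )


def schedule_hash(schedule: AcquisitionSchedule) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(schedule.flip_angles, dtype=np.float64).tobytes())
    h.update(np.asarray(schedule.rf_phases, dtype=np.float64).tobytes())
    h.update(
        np.array(
            [schedule.tr_ms, schedule.te_ms, float(schedule.inversion),
             schedule.inversion_efficiency, schedule.dephasing_cycles],
            dtype=np.float64,
        ).tobytes()
    )
    return h.hexdigest()[:16]


def build_dictionary(
    schedule: AcquisitionSchedule,
    t1_grid: np.ndarray | None = None,
    t2_grid: np.ndarray | None = None,
    constrain_t2_le_t1: bool = False,
    n_iterations: int = 2,
    slice_profile: np.ndarray | None = None,
    K: int | None = None,
    chunk: int = 8192,
    dtype=np.complex64,
) -> Dictionary:
    """Simulate every retained (T1, T2) pair and return unit-norm atoms.

    The default grids are T1 = 10:1:2000 + 2100:100:5000 ms and
    T2 = 10:5:300 + 310:10:2000 ms.  With ``constrain_t2_le_t1`` pairs with
    T2 > T1 are dropped (off by default: the full rectangular range is
    simulated for dictionaries).
    """
    t1_grid = default_t1_grid() if t1_grid is None else np.asarray(t1_grid, dtype=float)
    t2_grid = default_t2_grid() if t2_grid is None else np.asarray(t2_grid, dtype=float)
    for name, g in (("t1_grid", t1_grid), ("t2_grid", t2_grid)):
        if g.size == 0:
            raise ValueError(f"{name} is empty")
        if np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
        if np.any(g <= 0):
            raise ValueError(f"{name} values must be positive")

    T1, T2 = np.meshgrid(t1_grid, t2_grid, indexing="ij")
    t1 = T1.ravel()
    t2 = T2.ravel()
    if constrain_t2_le_t1:
        keep = t2 <= t1
        t1, t2 = t1[keep], t2[keep]
    if t1.size == 0:
        raise ValueError("no (T1, T2) pairs remain after the T2 <= T1 constraint")

    n_reps = schedule.n_reps
    atoms = np.empty((t1.size, n_reps), dtype=dtype)
    norms = np.empty(t1.size, dtype=float)
    for lo in range(0, t1.size, chunk):
        hi = min(lo + chunk, t1.size)
        sig = simulate_signals_batch(
            schedule, t1[lo:hi], t2[lo:hi], n_iterations, slice_profile, K
        )
        nrm = np.linalg.norm(sig, axis=1)
        nrm = np.where(nrm > 0, nrm, 1.0)
        atoms[lo:hi] = (sig / nrm[:, None]).astype(dtype)
        norms[lo:hi] = nrm
    return Dictionary(
        atoms=atoms,
        norms=norms,
        t1_ms=t1,
        t2_ms=t2,
        schedule_hash=schedule_hash(schedule),
    )
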