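"""Digital brain-like phantoms and the multi-coil non-Cartesian forward model.

The phantom is piecewise constant over a handful of tissue classes (nested,
seeded-jittered ellipsoids: white matter, gray matter, CSF ventricles, and a
small lesion).  Piecewise constancy makes the forward model exact and fast:
the transient-state signal is simulated once per class and the k-space of
each (class mask x proton density x coil) image is computed once, so the
data of every repetition is a class-signal-weighted combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epg import TissueParams, simulate_signal
from .gridding import GriddingOperator
from .schedule import AcquisitionSchedule
from .trajectories import Trajectory

__all__ = [
    "PhantomVolume",
    "TISSUE_CLASSES",
    "make_phantom",
    "make_coil_maps",
    "forward_simulate",
    "KSpaceData",
]

#: Tissue classes: label -> (name, T1 ms, T2 ms, relative PD).  Values are
#: representative of brain tissue at 1.5-3 T (white matter ~600/70 ms).
TISSUE_CLASSES = {
    0: ("background", None, None, 0.0),
    1: ("wm", 600.0, 70.0, 0.77),
    2: ("gm", 1200.0, 100.0, 0.86),
    3: ("csf", 4000.0, 1800.0, 1.0),
    4: ("lesion", 1400.0, 250.0, 0.90),
}


@dataclass
class PhantomVolume:
    """Piecewise-constant parameter volumes plus the tissue-label volume."""

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    pd: np.ndarray
    labels: np.ndarray
    voxel_mm: float = 1.0

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def class_tissue(self, label: int) -> TissueParams:
        name, t1, t2, pd = TISSUE_CLASSES[label]
        return TissueParams(t1, t2, pd)

    def save_nifti(self, outdir, prefix: str = "phantom_") -> list:
        import os

        import nibabel as nib

        aff = np.diag([self.voxel_mm] * 3 + [1.0])[:4, :4]
        paths = []
        for name, vol in (
            ("t1_ms", self.t1_ms),
            ("t2_ms", self.t2_ms),
            ("pd", self.pd),
            ("labels", self.labels),
        ):
            arr = np.asarray(vol, dtype=np.float32)
            if arr.ndim == 2:
                arr = arr[:, :, None]
            p = os.path.join(outdir, f"{prefix}{name}.nii.gz")
            nib.save(nib.Nifti1Image(arr, aff), p)
            paths.append(p)
        return paths


def _ellipsoid_mask(shape, center, semiaxes):
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semiaxes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def make_phantom(
    matrix: int, seed: int = 0, ndim: int = 3, voxel_mm: float = 1.0
) -> PhantomVolume:
    """Nested-ellipsoid brain-like phantom with 5 tissue classes.

    The outer ellipsoid is gray matter, enclosing a white-matter ellipsoid
    that contains CSF "ventricles" and a small lesion.  Ellipsoid centers
    and semi-axes are jittered reproducibly by the seed.
    """
    if matrix < 32:
        raise ValueError(f"matrix must be >= 32, got {matrix}")
    if ndim not in (2, 3):
        raise ValueError("ndim must be 2 or 3")
    rng = np.random.default_rng(seed)
    shape = (matrix,) * ndim
    c0 = np.full(ndim, matrix / 2.0)

    def jitter(scale):
        return 1.0 + scale * (2 * rng.random(ndim) - 1)

    labels = np.zeros(shape, dtype=np.int16)
    # gray-matter head
    labels[_ellipsoid_mask(shape, c0 + 0.01 * matrix * (rng.random(ndim) - 0.5),
                           0.40 * matrix * jitter(0.04))] = 2
    # white-matter core
    labels_wm = _ellipsoid_mask(shape, c0, 0.30 * matrix * jitter(0.05))
    labels[labels_wm & (labels == 2)] = 1
    # CSF ventricles: two small ellipsoids offset left/right
    for sgn in (-1, 1):
        cv = c0.copy()
        cv[-1] += sgn * 0.10 * matrix
        vent = _ellipsoid_mask(shape, cv, np.array([0.10, 0.05, 0.06])[:ndim] * matrix * jitter(0.08))
        labels[vent & (labels == 1)] = 3
    # lesion in white matter
    cl = c0.copy()
    cl[0] += 0.14 * matrix
    lesion = _ellipsoid_mask(shape, cl, 0.045 * matrix * jitter(0.1))
    labels[lesion & (labels == 1)] = 4

    t1 = np.zeros(shape)
    t2 = np.zeros(shape)
    pd = np.zeros(shape)
    for lab, (_, c_t1, c_t2, c_pd) in TISSUE_CLASSES.items():
        if c_t1 is None:
            continue
        m = labels == lab
        t1[m], t2[m], pd[m] = c_t1, c_t2, c_pd
    return PhantomVolume(t1_ms=t1, t2_ms=t2, pd=pd, labels=labels, voxel_mm=voxel_mm)


def make_coil_maps(
    matrix: int, n_coils: int, seed: int = 0, ndim: int = 3
) -> np.ndarray:
    """Smooth complex coil sensitivities with unit sum-of-squares.

    Each coil is a broad Gaussian magnitude lobe centered outside the FOV
    with a low-order polynomial phase; maps are normalized voxelwise so the
    sum of squared magnitudes is exactly 1 (n_coils=1 returns uniform unit
    sensitivity).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    shape = (matrix,) * ndim
    if n_coils == 1:
        return np.ones((1,) + shape, dtype=complex)
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.linspace(-1, 1, matrix)] * ndim, indexing="ij")
    maps = np.empty((n_coils,) + shape, dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + 0.3 * rng.standard_normal()
        center = 1.3 * np.array(
            [np.cos(ang), np.sin(ang), 0.3 * rng.standard_normal()][:ndim]
        )
        r2 = sum((g - cc) ** 2 for g, cc in zip(grids, center))
        mag = np.exp(-r2 / (2 * (0.9 + 0.2 * rng.random()) ** 2))
        phase = sum(
            (0.5 * rng.standard_normal()) * g + (0.2 * rng.standard_normal()) * g**2
            for g in grids
        )
        maps[c] = mag * np.exp(1j * phase)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return maps / np.maximum(sos, 1e-30)


@dataclass
class KSpaceData:
    """Simulated multi-coil k-space in the package's HDF5 layout.

    ``kdata`` is ``(n_coils, n_interleaves, n_samples)`` for undersampled
    acquisitions or ``(n_coils, n_reps, n_samples_total)`` when fully
    sampled (every repetition sees the whole trajectory).
    """

    kdata: np.ndarray
    fully_sampled: bool
    schedule_hash: str = ""
    snr_db: float | None = None
    seed: int | None = None

    def save_h5(self, path, traj: Trajectory | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("kdata", data=self.kdata.astype(np.complex64))
            f.attrs["fully_sampled"] = self.fully_sampled
            f.attrs["schedule_hash"] = self.schedule_hash
            f.attrs["snr_db"] = -1.0 if self.snr_db is None else float(self.snr_db)
            f.attrs["seed"] = -1 if self.seed is None else int(self.seed)
            if traj is not None:
                f.create_dataset("traj/coords", data=traj.coords)
                f.create_dataset("traj/dcf", data=traj.dcf)
                f.create_dataset("traj/rep_map", data=traj.rep_map)
                f["traj"].attrs["kind"] = traj.kind

    @classmethod
    def load_h5(cls, path):
        import h5py

        with h5py.File(path, "r") as f:
            snr = float(f.attrs["snr_db"])
            seed = int(f.attrs["seed"])
            obj = cls(
                kdata=f["kdata"][:],
                fully_sampled=bool(f.attrs["fully_sampled"]),
                schedule_hash=str(f.attrs["schedule_hash"]),
                snr_db=None if snr < 0 else snr,
                seed=None if seed < 0 else seed,
            )
            traj = None
            if "traj" in f:
                traj = Trajectory(
                    coords=f["traj/coords"][:],
                    dcf=f["traj/dcf"][:],
                    rep_map=f["traj/rep_map"][:],
                    kind=str(f["traj"].attrs["kind"]),
                )
        return (obj, traj) if traj is not None else obj


def forward_simulate(
    phantom: PhantomVolume,
    schedule: AcquisitionSchedule,
    traj: Trajectory,
    coils: np.ndarray | None = None,
    snr_db: float | None = None,
    seed: int | None = None,
    fully_sampled: bool = False,
    n_iterations: int = 2,
    slice_profile: np.ndarray | None = None,
) -> KSpaceData:
    """Simulate multi-coil transient-state k-space data of a phantom.

    For each tissue class the temporal signal is simulated once; the
    k-space of each PD-weighted class-mask image (times each coil map) is
    computed once with the forward NUFFT; per-repetition data follow as
    class-signal-weighted sums.  This is exact for piecewise-constant
    phantoms.  Complex white Gaussian noise is added at ``snr_db`` relative
    to the RMS k-space signal amplitude (seeded).
    """
    if phantom.labels.ndim != traj.ndim:
        raise ValueError(
            f"phantom is {phantom.labels.ndim}-D but trajectory is {traj.ndim}-D"
        )
    matrix = phantom.shape[0]
    if coils is None:
        coils = np.ones((1,) + phantom.shape, dtype=complex)
    if coils.shape[1:] != phantom.shape:
        raise ValueError("coil maps do not match the phantom grid")

    present = [lab for lab in np.unique(phantom.labels) if TISSUE_CLASSES[lab][1]]
    coords = traj.flat_coords()
    op = GriddingOperator(phantom.shape, coords)

    # per-class temporal signals (unit PD; the PD weight lives in the image)
    sigs = np.stack(
        [
            simulate_signal(
                schedule,
                TissueParams(*TISSUE_CLASSES[lab][1:3]),
                n_iterations=n_iterations,
                slice_profile=slice_profile,
            )
            for lab in present
        ]
    )  # (n_class, n_reps)

    n_coils = coils.shape[0]
    F = np.empty((len(present), n_coils, coords.shape[0]), dtype=complex)
    for ci, lab in enumerate(present):
        base = (phantom.labels == lab) * phantom.pd
        for c in range(n_coils):
            F[ci, c] = op.forward(base * coils[c])

    n_il, n_samp = traj.n_interleaves, traj.n_samples_per_interleave
    if fully_sampled:
        kdata = np.einsum("ct,cks->kts", sigs, F)  # (coil, rep, n_total)
    else:
        rep_of_il = np.empty(n_il, dtype=np.int64)
        for s in range(traj.rep_map.shape[0]):
            rep_of_il[traj.rep_map[s]] = np.arange(traj.n_reps)
        Fr = F.reshape(len(present), n_coils, n_il, n_samp)
        w = sigs[:, rep_of_il]  # (n_class, n_il)
        kdata = np.einsum("ci,ckis->kis", w, Fr)

    if snr_db is not None:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.mean(np.abs(kdata) ** 2)) * 10.0 ** (-snr_db / 20.0)
        kdata = kdata + sigma / np.sqrt(2.0) * (
            rng.standard_normal(kdata.shape) + 1j * rng.standard_normal(kdata.shape)
        )
    return KSpaceData(
        kdata=kdata,
        fully_sampled=fully_sampled,
        snr_db=snr_db,
        seed=seed,
    )
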