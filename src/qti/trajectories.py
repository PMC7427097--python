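"""Non-Cartesian k-space sampling schedules.

All four readouts are rotations of a single fundamental interleave: a full
radial spoke or a variable-density spiral arm.  Coordinates are expressed in
cycles/voxel with every component in [-0.5, 0.5] (radial spokes extend to the
k-space cube boundary, max-norm 0.5; spirals stay inside the inscribed disc).

Orderings
---------
radial2d / spiral2d
    one interleave per repetition, rotated by the golden angle per TR
    (``n_segments`` must be 1).
radial3d
    spokes rotated about z (in-plane) and x (spherical); the readout order
    is a seeded random permutation of the orientation grid.
spiral3d
    spherical rotations advance by the golden angle from one repetition to
    the next, in-plane rotations linearly from one segment to the next, so
    ``n_reps x n_segments`` distinct orientations are acquired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GOLDEN_ANGLE_DEG = 180.0 * (np.sqrt(5.0) - 1.0) / 2.0  # ~111.2461 degrees
GAMMA_HZ_PER_T = 42.577478518e6  # proton gyromagnetic ratio / 2 pi

__all__ = [
    "Trajectory",
    "golden_angle_sequence",
    "make_trajectory",
    "sampling_density",
    "GOLDEN_ANGLE_DEG",
]


@dataclass
class Trajectory:
    """A set of k-space interleaves plus their acquisition ordering.

    Attributes
    ----------
    coords : (n_interleaves, n_samples, ndim) float array
        Sample positions in cycles/voxel, each component in [-0.5, 0.5].
    dcf : (n_interleaves, n_samples) float array
        Density-compensation weights, strictly positive.
    rep_map : (n_segments, n_reps) int array
        Interleave index acquired at each (segment, repetition).
    kind : str
        One of ``radial2d, spiral2d, radial3d, spiral3d``.
    """

    coords: np.ndarray
    dcf: np.ndarray
    rep_map: np.ndarray
    kind: str
    seed: int | None = None
    #: per-interleave (spherical_deg, inplane_deg) orientation labels for the
    #: 3D kinds (None for 2D kinds, whose single angle is the golden sequence)
    orientations: np.ndarray | None = None

    @property
    def ndim(self) -> int:
        return self.coords.shape[-1]

    @property
    def n_interleaves(self) -> int:
        return self.coords.shape[0]

    @property
    def n_samples_per_interleave(self) -> int:
        return self.coords.shape[1]

    @property
    def n_segments(self) -> int:
        return self.rep_map.shape[0]

    @property
    def n_reps(self) -> int:
        return self.rep_map.shape[1]

    def validate(self) -> None:
        if np.max(np.abs(self.coords)) > 0.5 + 1e-9:
            raise ValueError("coordinates exceed max-norm 0.5 cycles/voxel")
        if not np.all(np.isfinite(self.dcf)) or np.any(self.dcf <= 0):
            raise ValueError("dcf must be strictly positive and finite")
        idx = np.sort(self.rep_map.ravel())
        if len(np.unique(idx)) != idx.size:
            raise ValueError("rep_map assigns some interleave more than once")

    def flat_coords(self) -> np.ndarray:
        """All sample positions, flattened to (n_total, ndim)."""
        return self.coords.reshape(-1, self.ndim)

    def flat_dcf(self) -> np.ndarray:
        return self.dcf.reshape(-1)

    # -- persistence -------------------------------------------------------
    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("coords", data=self.coords)
            f.create_dataset("dcf", data=self.dcf)
            f.create_dataset("rep_map", data=self.rep_map)
            f.attrs["kind"] = self.kind
            f.attrs["seed"] = -1 if self.seed is None else int(self.seed)

    @classmethod
    def load_h5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            seed = int(f.attrs["seed"])
            return cls(
                coords=f["coords"][:],
                dcf=f["dcf"][:],
                rep_map=f["rep_map"][:],
                kind=str(f.attrs["kind"]),
                seed=None if seed < 0 else seed,
            )


def golden_angle_sequence(n: int) -> np.ndarray:
    """First ``n`` golden-angle increments in degrees, modulo 360."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return (np.arange(n) * GOLDEN_ANGLE_DEG) % 360.0


# ---------------------------------------------------------------------------
# fundamental interleaves
# ---------------------------------------------------------------------------

def _radial_spoke_template(n_samples: int) -> np.ndarray:
    """Full-spoke parameter in [-1, 1] with a sample exactly at the center."""
    if n_samples % 2 == 0:
        n_samples += 1
    return np.linspace(-1.0, 1.0, n_samples)


def _spoke_coords(directions: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Spokes through the origin scaled so endpoints sit at max-norm 0.5.

    ``directions``: (n, ndim) unit vectors.  Each spoke's half-length is
    0.5 / max|u_i|, i.e. spokes extend to the boundary of the k-space cube
    (diagonal spokes are longer than axis-aligned ones, covering the
    corners of k-space).
    """
    half_len = 0.5 / np.max(np.abs(directions), axis=1)  # (n,)
    return half_len[:, None, None] * t[None, :, None] * directions[:, None, :]


def _design_spiral_arm(
    matrix: int,
    n_inplane: int,
    gradient_limits: tuple[float, float],
    fov_mm: float = 192.0,
    dwell_us: float = 4.0,
    density_exponent: float = 1.0,
    max_samples: int = 8192,
) -> np.ndarray:
    """Variable-density spiral arm obeying gradient limits.

    The arm follows r(phi) = kmax * (phi / phi_max)^(1 / (2 - e)) with
    ``e = density_exponent``: after angular averaging over many rotated
    copies the areal sample density tapers as r^(-e), so the default e = 1
    (an Archimedean arm) oversamples the center like a radial readout.  The
    traversal speed along the arc is integrated greedily at the dwell time,
    limited by the gradient amplitude (max speed), slew rate (max tangential
    acceleration) and centripetal demand v^2 * curvature <= gamma * smax.

    Returns (n_samples, 2) coordinates in cycles/voxel.
    """
    if not (0 <= density_exponent < 2):
        raise ValueError("density_exponent must lie in [0, 2)")
    gmax_t_per_m, smax_t_per_m_s = gradient_limits[0] * 1e-3, gradient_limits[1]
    voxel_m = (fov_mm / matrix) * 1e-3
    # speeds in cycles/voxel per second
    vmax = GAMMA_HZ_PER_T * gmax_t_per_m * voxel_m
    amax = GAMMA_HZ_PER_T * smax_t_per_m_s * voxel_m
    dt = dwell_us * 1e-6

    kmax = 0.5
    n_turns = max(matrix / (2.0 * n_inplane), 0.5)
    phi_max = 2.0 * np.pi * n_turns
    p = 1.0 / (2.0 - density_exponent)

    def radius(phi):
        return kmax * (phi / phi_max) ** p

    pts = [np.zeros(2)]
    phi = 1e-4 * phi_max
    v = 0.0
    while phi < phi_max and len(pts) < max_samples:
        r = radius(phi)
        drdphi = kmax * p * (phi / phi_max) ** (p - 1.0) / phi_max
        ds_dphi = np.hypot(r, drdphi)  # arc length per unit phi
        # curvature of a near-Archimedean spiral
        kappa = (r * r + 2 * drdphi * drdphi) / max((r * r + drdphi * drdphi) ** 1.5, 1e-12)
        v_curv = np.sqrt(max(amax / max(kappa, 1e-9), 0.0))
        # split the slew budget between centripetal demand v^2*kappa and
        # tangential acceleration so their quadrature sum stays within amax
        a_cent = min(v * v * kappa, amax)
        a_tan = np.sqrt(max(amax**2 - a_cent**2, 0.0))
        v = min(vmax, v + a_tan * dt, v_curv)
        v = max(v, 1e-4 * vmax)
        phi_new = phi + v * dt / ds_dphi
        if phi_new >= phi_max:  # stop at the last in-limit point
            break
        phi = phi_new
        r = radius(phi)
        pts.append(np.array([r * np.cos(phi), r * np.sin(phi)]))
    return np.array(pts)


def _rot2(theta_deg: np.ndarray) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.stack([np.stack([c, -s], -1), np.stack([s, c], -1)], -2)


def _rotz(theta_deg):
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    o, z = np.ones_like(c), np.zeros_like(c)
    return np.stack(
        [np.stack([c, -s, z], -1), np.stack([s, c, z], -1), np.stack([z, z, o], -1)], -2
    )


def _rotx(theta_deg):
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    o, z = np.ones_like(c), np.zeros_like(c)
    return np.stack(
        [np.stack([o, z, z], -1), np.stack([z, c, -s], -1), np.stack([z, s, c], -1)], -2
    )


# ---------------------------------------------------------------------------
# density compensation
# ---------------------------------------------------------------------------

def _radial_dcf(coords: np.ndarray) -> np.ndarray:
    """Analytic |k|^(ndim-1) ramp with a finite value at the center sample."""
    r = np.linalg.norm(coords, axis=-1)
    n_samp = coords.shape[1]
    dr = 1.0 / n_samp  # approximate radial sample spacing
    w = np.maximum(r, 0.5 * dr) ** (coords.shape[-1] - 1)
    return w / w.max()

def _iterative_dcf(coords: np.ndarray, matrix: int, n_iter: int = 10) -> np.ndarray:
    """Gridding-based iterative density estimate (Pipe-Menon style).

    Repeatedly divides weights by their own gridded-and-resampled density so
    the weighted sampling approaches uniform coverage.  Dependency-free and
    adequate for adjoint reconstruction.
    """
    from .gridding import GriddingOperator

    shape = (matrix,) * coords.shape[-1]
    op = GriddingOperator(shape, coords.reshape(-1, coords.shape[-1]))
    w = np.ones(op.n_samples)
    for _ in range(n_iter):
        dens = np.abs(op.spread_resample(w.astype(complex)).real)
        w = w / np.maximum(dens, 1e-12)
    w = w / w.max()
    return w.reshape(coords.shape[:-1])


# ---------------------------------------------------------------------------
# trajectory factory
# ---------------------------------------------------------------------------

def make_trajectory(
    kind: str,
    n_reps: int,
    n_segments: int = 1,
    n_inplane: int | None = None,
    matrix: int = 200,
    gradient_limits: tuple[float, float] = (10.0, 90.0),
    seed: int | None = None,
    fov_mm: float = 192.0,
    n_samples: int | None = None,
    density_exponent: float = 1.0,
    dcf_matrix: int | None = None,
    compute_dcf: bool = True,
    dwell_us: float = 4.0,
) -> Trajectory:
    """Generate one of the four readout trajectories.

    Parameters
    ----------
    kind : {"radial2d", "spiral2d", "radial3d", "spiral3d"}
    n_reps : repetitions per segment (length of the flip-angle train).
    n_segments : segments; 2D kinds require 1.
    n_inplane : in-plane rotation count for 3D spirals (also sets the spiral
        arm's turn spacing); defaults to ``n_segments`` for spiral3d.
    matrix : nominal reconstruction matrix (sets spiral Nyquist spacing).
    gradient_limits : (amplitude mT/m, slew T/m/s) for the spiral design.
    seed : required for radial3d (pseudo-random spoke ordering).
    n_samples : samples per radial spoke (default ``2 * matrix + 1``).
    """
    if kind not in ("radial2d", "spiral2d", "radial3d", "spiral3d"):
        raise ValueError(f"unknown trajectory kind {kind!r}")
    if n_reps < 1 or n_segments < 1:
        raise ValueError("n_reps and n_segments must be positive")
    if kind in ("radial2d", "spiral2d") and n_segments != 1:
        raise ValueError(f"{kind} requires n_segments=1, got {n_segments}")

    orientations = None
    if kind == "radial2d":
        t = _radial_spoke_template(n_samples or 2 * matrix + 1)
        ang = golden_angle_sequence(n_reps)
        dirs = np.stack([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))], axis=1)
        coords = _spoke_coords(dirs, t)
        dcf = _radial_dcf(coords)
        rep_map = np.arange(n_reps, dtype=np.int64)[None, :]

    elif kind == "spiral2d":
        n_ip = n_inplane or max(int(np.ceil(matrix / 16)), 8)
        arm = _design_spiral_arm(matrix, n_ip, gradient_limits, fov_mm,
                                 dwell_us=dwell_us,
                                 density_exponent=density_exponent)
        ang = golden_angle_sequence(n_reps)
        R = _rot2(ang)  # (n_reps, 2, 2)
        coords = np.einsum("nij,sj->nsi", R, arm)
        dcf = (
            _iterative_dcf(coords, dcf_matrix or min(matrix, 128))
            if compute_dcf
            else np.ones(coords.shape[:-1])
        )
        rep_map = np.arange(n_reps, dtype=np.int64)[None, :]

    elif kind == "radial3d":
        if seed is None:
            raise ValueError("radial3d requires a seed for the pseudo-random ordering")
        t = _radial_spoke_template(n_samples or 2 * matrix + 1)
        n_total = n_reps * n_segments
        # orientation grid: n_segments in-plane rotations about z crossed
        # with n_reps spherical rotations about x
        inplane = np.repeat(np.arange(n_segments) * (180.0 / n_segments), n_reps)
        spherical = np.tile(golden_angle_sequence(n_reps), n_segments)
        base = np.array([1.0, 0.0, 0.0])
        dirs = np.einsum(
            "nij,njk,k->ni", _rotx(spherical), _rotz(inplane), base
        )
        coords = _spoke_coords(dirs, t)
        dcf = _radial_dcf(coords)
        orientations = np.stack([spherical, inplane], axis=1)
        rng = np.random.default_rng(seed)
        rep_map = rng.permutation(n_total).reshape(n_segments, n_reps).astype(np.int64)

    else:  # spiral3d
        n_ip = n_inplane or n_segments
        arm2 = _design_spiral_arm(matrix, n_ip, gradient_limits, fov_mm,
                                  dwell_us=dwell_us,
                                  density_exponent=density_exponent)
        arm = np.concatenate([arm2, np.zeros((len(arm2), 1))], axis=1)
        # orientation (segment s, repetition t): in-plane angle linear in s,
        # spherical angle golden in t; interleave index = t * n_segments + s
        inplane = np.tile(np.arange(n_segments) * (360.0 / max(n_ip, 1)), n_reps)
        spherical = np.repeat(golden_angle_sequence(n_reps), n_segments)
        R = np.einsum("nij,njk->nik", _rotx(spherical), _rotz(inplane))
        coords = np.einsum("nij,sj->nsi", R, arm)
        dcf = (
            _iterative_dcf(coords, dcf_matrix or 64)
            if compute_dcf
            else np.ones(coords.shape[:-1])
        )
        orientations = np.stack([spherical, inplane], axis=1)
        rep_map = (
            np.arange(n_reps)[:, None] * n_segments + np.arange(n_segments)[None, :]
        ).T.astype(np.int64)

    traj = Trajectory(coords=coords, dcf=dcf, rep_map=rep_map, kind=kind, seed=seed,
                      orientations=orientations)
    traj.validate()
    return traj


def sampling_density(
    traj: Trajectory, matrix: int, frames: np.ndarray | None = None
) -> np.ndarray:
    """Count-weighted k-grid occupancy, nearest-cell gridded, max-normalized.

    ``frames`` optionally restricts the count to a subset of repetition
    indices (all segments of those repetitions).
    """
    if matrix < 8:
        raise ValueError(f"matrix must be >= 8, got {matrix}")
    if frames is not None:
        frames = np.asarray(frames)
        if frames.size == 0:
            raise ValueError("frames subset is empty")
        interleaves = traj.rep_map[:, frames].ravel()
        coords = traj.coords[interleaves].reshape(-1, traj.ndim)
    else:
        coords = traj.flat_coords()
    cells = nearest_cells(coords, matrix)
    flat = np.ravel_multi_index(tuple(cells.T), (matrix,) * traj.ndim)
    counts = np.bincount(flat, minlength=matrix**traj.ndim).astype(float)
    counts = counts.reshape((matrix,) * traj.ndim)
    return counts / counts.max()


def nearest_cells(coords: np.ndarray, matrix: int) -> np.ndarray:
    """Nearest Cartesian k-grid cell per sample; DC maps to index matrix//2."""
    idx = np.rint(coords * matrix).astype(np.int64) + matrix // 2
    return np.clip(idx, 0, matrix - 1)
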