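"""k-space weighted view-sharing.

Transient-state acquisitions sample a different interleave every repetition,
so each temporal frame is massively undersampled away from the k-space
center.  View-sharing fills a frame's sparsely sampled k-space cells with
data acquired at neighboring repetitions: the lower the local sampling
density of a cell, the wider the temporal window over which its samples are
combined.  Densely sampled cells (the contrast-bearing center) are left
untouched.  Because the underlying transient-state signal varies smoothly
from repetition to repetition while the sampling pattern does not, this
trades a small temporal blur for a large reduction in aliasing energy.

The whole operation is linear in the data and acts on nearest k-grid cells,
so it is equivalent to one precomputed sparse weighting matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from .trajectories import Trajectory, nearest_cells, sampling_density

__all__ = ["ViewShareConfig", "kw_viewshare", "kw_viewshare_project"]


@dataclass
class ViewShareConfig:
    """Density-to-window mapping for view-sharing.

    Attributes
    ----------
    full_sample_threshold : float in (0, 1]
        Density level (fraction of the k-space maximum) above which a cell
        is considered fully sampled and no sharing occurs.
    max_window : int >= 0
        Maximum temporal half-width, in repetitions, applied where the
        density approaches zero.
    weight_shape : {"triangular", "uniform", "hann"}
        Taper family for the temporal weights.
    matrix : int
        Cartesian grid used to assess sampling density and associate
        samples to cells.
    """

    full_sample_threshold: float = 0.25
    max_window: int = 32
    weight_shape: str = "triangular"
    matrix: int = 64

    def __post_init__(self) -> None:
        if not (0 < self.full_sample_threshold <= 1):
            raise ValueError("full_sample_threshold must lie in (0, 1]")
        if self.max_window < 0:
            raise ValueError("max_window must be >= 0")
        if self.weight_shape not in ("triangular", "uniform", "hann"):
            raise ValueError(f"unknown weight_shape {self.weight_shape!r}")

    def window_halfwidth(self, density: np.ndarray) -> np.ndarray:
        """w(d) = round(max_window * (1 - min(d / threshold, 1))); non-increasing in d."""
        frac = np.minimum(np.asarray(density, dtype=float) / self.full_sample_threshold, 1.0)
        return np.rint(self.max_window * (1.0 - frac)).astype(np.int64)

    def taper(self, halfwidth: int) -> np.ndarray:
        """Symmetric temporal taper of length ``2 * halfwidth + 1``."""
        offs = np.arange(-halfwidth, halfwidth + 1)
        if self.weight_shape == "uniform":
            return np.ones(offs.size)
        if self.weight_shape == "hann":
            return 0.5 + 0.5 * np.cos(np.pi * offs / (halfwidth + 1))
        return 1.0 - np.abs(offs) / (halfwidth + 1.0)


def kw_viewshare(
    kdata: np.ndarray, traj: Trajectory, config: ViewShareConfig
) -> np.ndarray:
    """Apply density-weighted temporal sharing of k-space samples.

    ``kdata`` has shape ``(..., n_interleaves, n_samples)`` indexed
    consistently with ``traj.rep_map`` (leading axes, e.g. coils, are
    processed independently).  For every k-grid cell with local density d
    below the threshold, each sample's value is replaced by the normalized
    taper-weighted combination of that cell's per-repetition averages within
    a temporal half-width w(d); samples from different segments at the same
    repetition index share a frame (equivalent contrast).  Fully sampled
    cells are returned bit-identical.  The operation is linear.
    """
    kdata = np.asarray(kdata)
    if kdata.shape[-2:] != (traj.n_interleaves, traj.n_samples_per_interleave):
        raise ValueError(
            f"kdata trailing shape {kdata.shape[-2:]} does not match trajectory "
            f"({traj.n_interleaves}, {traj.n_samples_per_interleave})"
        )
    if config.max_window == 0:
        return kdata.copy()

    lead = kdata.shape[:-2]
    n_il, n_samp = kdata.shape[-2:]
    flat = kdata.reshape(-1, n_il, n_samp)
    n_reps = traj.n_reps
    m = config.matrix

    # repetition index of every interleave
    rep_of_il = np.empty(traj.n_interleaves, dtype=np.int64)
    for s in range(traj.n_segments):
        rep_of_il[traj.rep_map[s]] = np.arange(n_reps)

    density = sampling_density(traj, m)
    cells = nearest_cells(traj.flat_coords(), m)
    cell_flat = np.ravel_multi_index(tuple(cells.T), (m,) * traj.ndim)
    cell_flat = cell_flat.reshape(n_il, n_samp)
    d_cell_all = density.reshape(-1)
    w_cell_all = config.window_halfwidth(d_cell_all)

    w_sample = w_cell_all[cell_flat]          # (n_il, n_samp)
    shared = w_sample > 0
    if not np.any(shared):
        return kdata.copy()

    # compact index over the cells that actually need sharing, ordered by
    # window half-width so equal-w cells are contiguous for blockwise work
    shared_cells, inv = np.unique(cell_flat[shared], return_inverse=True)
    order = np.argsort(w_cell_all[shared_cells], kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    shared_cells = shared_cells[order]
    inv = rank[inv]
    n_cells = shared_cells.size
    w_of_cell = w_cell_all[shared_cells]

    rep_idx = np.broadcast_to(rep_of_il[:, None], (n_il, n_samp))
    rr = rep_idx[shared]
    cc = inv

    # working precision follows the input: single-precision k-space data is
    # filtered in single precision
    cplx = np.complex64 if flat.dtype == np.complex64 else np.complex128
    real = np.float32 if cplx == np.complex64 else np.float64

    # cells are independent, so process them in blocks that bound the
    # (n_reps x block) accumulation buffers to ~tens of MB
    block = max(int(32e6 // max(n_reps, 1)), 1024)
    out = flat.copy()
    sample_order = np.argsort(cc, kind="stable")
    cc_sorted = cc[sample_order]
    starts = np.searchsorted(cc_sorted, np.arange(0, n_cells + block, block))
    flat_shared_index = np.flatnonzero(shared.reshape(-1))

    for bi, (s0, s1) in enumerate(zip(starts[:-1], starts[1:])):
        if s0 == s1:
            continue
        c_lo = bi * block
        take = sample_order[s0:s1]
        cc_b = cc[take] - c_lo
        rr_b = rr[take]
        nc = min(block, n_cells - c_lo)
        lin = rr_b * nc + cc_b
        counts = np.bincount(lin, minlength=n_reps * nc).astype(np.int32)
        counts = counts.reshape(n_reps, nc)
        occ = counts > 0
        occ_f = occ.astype(real)

        for b in range(flat.shape[0]):
            vals = flat[b].reshape(-1)[flat_shared_index[take]]
            avg = np.zeros((n_reps, nc), dtype=cplx)
            avg.real.reshape(-1)[:] = np.bincount(
                lin, weights=vals.real, minlength=n_reps * nc
            )
            if np.iscomplexobj(flat):
                avg.imag.reshape(-1)[:] = np.bincount(
                    lin, weights=vals.imag, minlength=n_reps * nc
                )
            avg[occ] /= counts[occ].astype(real)

            shared_val = np.zeros_like(avg)
            for w in np.unique(w_of_cell[c_lo:c_lo + nc]):
                sel = w_of_cell[c_lo:c_lo + nc] == w
                kern = config.taper(int(w)).astype(real)
                num = convolve1d(avg[:, sel].real, kern, axis=0,
                                 mode="constant").astype(cplx)
                num += 1j * convolve1d(avg[:, sel].imag, kern, axis=0,
                                       mode="constant")
                den = convolve1d(occ_f[:, sel], kern, axis=0, mode="constant")
                good = den > 0
                num[good] /= den[good]
                num[~good] = 0.0
                shared_val[:, sel] = num
            out[b].reshape(-1)[flat_shared_index[take]] = shared_val[rr_b, cc_b]
    return out.reshape(*lead, n_il, n_samp)


def kw_viewshare_project(
    kdata: np.ndarray, traj: Trajectory, config: ViewShareConfig, basis,
    tikhonov: float | None = None,
) -> np.ndarray:
    """View-share into temporal frames, then fit the subspace per k-cell.

    Sharing "increases the number of samples per frame": for every k-grid
    cell, each temporal frame t within the density-dependent window of an
    acquisition receives that cell's taper-averaged value; densely sampled
    cells (w = 0) keep only their genuinely acquired frames.  By default
    the cell's coefficient vector is the projection of the basis onto the
    covered frames (uncovered frames contribute nothing instead of aliasing
    noise); where frame coverage is complete this equals the fully sampled
    projection exactly.  Passing a ``tikhonov`` damping level instead fits
    the basis to the covered frames by damped least squares
    (normal equations with ``tikhonov * trace/R`` on the diagonal), which
    removes the coverage-apodization of well-resolved components at the
    cost of amplifying noise in poorly resolved ones.  This is the operator
    the reconstruction pipeline applies between acquisition and gridding;
    :func:`kw_viewshare` exposes the plain data-domain sharing with
    unchanged layout.

    Returns coefficient k-space of shape ``(R, ..., n_il, n_samples)``.
    """
    kdata = np.asarray(kdata)
    if kdata.shape[-2:] != (traj.n_interleaves, traj.n_samples_per_interleave):
        raise ValueError(
            f"kdata trailing shape {kdata.shape[-2:]} does not match trajectory "
            f"({traj.n_interleaves}, {traj.n_samples_per_interleave})"
        )
    lead = kdata.shape[:-2]
    n_il, n_samp = kdata.shape[-2:]
    flat = kdata.reshape(-1, n_il, n_samp)
    n_reps = traj.n_reps
    m = config.matrix
    B = basis.basis  # (n_reps, R)
    R = B.shape[1]

    rep_of_il = np.empty(traj.n_interleaves, dtype=np.int64)
    for s in range(traj.n_segments):
        rep_of_il[traj.rep_map[s]] = np.arange(n_reps)

    density = sampling_density(traj, m)
    cells = nearest_cells(traj.flat_coords(), m)
    cell_flat = np.ravel_multi_index(tuple(cells.T), (m,) * traj.ndim)
    w_cell_all = config.window_halfwidth(density.reshape(-1))

    occupied_cells, inv = np.unique(cell_flat, return_inverse=True)
    order = np.argsort(w_cell_all[occupied_cells], kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    occupied_cells = occupied_cells[order]
    inv = rank[inv]
    n_cells = occupied_cells.size
    w_of_cell = w_cell_all[occupied_cells]

    rr = np.broadcast_to(rep_of_il[:, None], (n_il, n_samp)).reshape(-1)
    cc = inv

    cplx = np.complex64 if flat.dtype == np.complex64 else np.complex128
    real = np.float32 if cplx == np.complex64 else np.float64
    Bc = B.conj().astype(cplx)
    # pairwise products for assembling per-cell normal matrices by one gemm
    pair = (Bc[:, :, None] * B.astype(cplx)[:, None, :]).reshape(n_reps, R * R)

    out = np.zeros((R,) + flat.shape, dtype=cplx)
    block = max(int(32e6 // max(n_reps, 1)), 1024)
    sample_order = np.argsort(cc, kind="stable")
    cc_sorted = cc[sample_order]
    starts = np.searchsorted(cc_sorted, np.arange(0, n_cells + block, block))

    for bi, (s0, s1) in enumerate(zip(starts[:-1], starts[1:])):
        if s0 == s1:
            continue
        c_lo = bi * block
        take = sample_order[s0:s1]
        cc_b = cc[take] - c_lo
        rr_b = rr[take]
        nc = min(block, n_cells - c_lo)
        lin = rr_b * nc + cc_b
        counts = np.bincount(lin, minlength=n_reps * nc).astype(np.int32)
        counts = counts.reshape(n_reps, nc)
        occ = counts > 0
        occ_f = occ.astype(real)

        for b in range(flat.shape[0]):
            vals = flat[b].reshape(-1)[take]
            avg = np.zeros((n_reps, nc), dtype=cplx)
            avg.real.reshape(-1)[:] = np.bincount(
                lin, weights=vals.real, minlength=n_reps * nc
            )
            if np.iscomplexobj(flat):
                avg.imag.reshape(-1)[:] = np.bincount(
                    lin, weights=vals.imag, minlength=n_reps * nc
                )
            avg[occ] /= counts[occ].astype(real)

            coeff = np.empty((R, nc), dtype=cplx)
            for w in np.unique(w_of_cell[c_lo:c_lo + nc]):
                sel = w_of_cell[c_lo:c_lo + nc] == w
                if w == 0:
                    frames = avg[:, sel] * occ_f[:, sel]
                    cover = occ_f[:, sel]
                else:
                    kern = config.taper(int(w)).astype(real)
                    num = convolve1d(avg[:, sel].real, kern, axis=0,
                                     mode="constant").astype(cplx)
                    num += 1j * convolve1d(avg[:, sel].imag, kern, axis=0,
                                           mode="constant")
                    den = convolve1d(occ_f[:, sel], kern, axis=0, mode="constant")
                    good = den > 0
                    num[good] /= den[good]
                    num[~good] = 0.0
                    frames = num
                    cover = good.astype(real)
                    frames = frames * cover
                rhs = (Bc.T @ frames).T  # (ncs, R) masked projection
                if tikhonov is None:
                    coeff[:, sel] = rhs.T
                    continue
                # per-cell damped least squares of the basis to the frames
                ncs = int(sel.sum())
                G = (pair.T @ cover.astype(cplx)).T.reshape(ncs, R, R)
                lam = tikhonov * np.einsum("qrr->q", G).real / R
                G[:, np.arange(R), np.arange(R)] += np.maximum(lam, 1e-12)[:, None]
                sol = np.linalg.solve(
                    G.astype(np.complex128), rhs.astype(np.complex128)[..., None]
                )[..., 0]
                coeff[:, sel] = sol.T.astype(cplx)
            out[:, b].reshape(R, -1)[:, take] = coeff[:, cc_b]
    return out.reshape((R,) + lead + (n_il, n_samp))
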