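"""Parameter inference: dictionary matching, fast group matching, and
compact neural networks with integrated proton-density estimation.

All inference operates on subspace coefficient vectors x in C^R.  A phase
alignment removes the global phase and a normalization layer separates the
signal *shape* (which encodes T1 and T2) from its 2-norm (which carries the
proton-density scale).  Three network architectures map the aligned shape to
parameters:

* ``multipath`` — three independent 200-100-1 ReLU pathways, one per output
  (T1, T2, and the pre-normalization signal norm theta3 that proxies PD);
* ``fwd``       — a single 600-300 trunk with a 3-unit head (same total
  node count as the multipath net);
* ``fwd_bck``   — an encoder with two 200-100-1 pathways to a latent
  (T1, T2) plus a mirrored 100-200 decoder that re-synthesizes the signal,
  so PD can be computed exactly as in dictionary matching.

Relative proton density is recovered as rho = ||x||_2 / theta3 for the
first two architectures and rho = <x, x_dec> / ||x_dec||_2 for the
autoencoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epg import Dictionary
from .recon import CoefficientImages, SubspaceBasis

__all__ = [
    "AlignedSignal",
    "NNSpec",
    "TrainConfig",
    "ParameterMaps",
    "MatchResult",
    "phase_align",
    "phase_align_batch",
    "project_dictionary",
    "dict_match",
    "group_match",
    "mape_loss",
    "train_network",
    "TrainedModel",
    "infer_maps",
    "noise_std",
    "add_noise",
]


# ---------------------------------------------------------------------------
# phase alignment and normalization
# ---------------------------------------------------------------------------

@dataclass
class AlignedSignal:
    """Real-valued aligned coefficients plus the removed scale and phase."""

    coeffs: np.ndarray  # (R,) real, unit norm for nonzero input
    norm: float         # pre-normalization 2-norm
    phase: float        # removed global phase, radians


def phase_align(x: np.ndarray) -> AlignedSignal:
    """Remove the global phase and scale of one complex coefficient vector.

    The phase reference is the largest-magnitude coefficient (in practice
    the first SVD coefficient).  The real part of the rotated unit vector is
    retained; the result is invariant to multiplication of ``x`` by any unit
    phase.  A zero vector aligns to all-zero coefficients with norm 0.
    """
    x = np.asarray(x, dtype=complex)
    nrm = float(np.linalg.norm(x))
    if nrm == 0.0:
        return AlignedSignal(np.zeros(x.shape, dtype=float), 0.0, 0.0)
    j = int(np.argmax(np.abs(x)))
    ph = float(np.angle(x[j]))
    return AlignedSignal((x * np.exp(-1j * ph)).real / nrm, nrm, ph)


def phase_align_batch(x: np.ndarray):
    """Vectorized :func:`phase_align` over rows; returns (coeffs, norms, phases)."""
    x = np.asarray(x, dtype=complex)
    nrm = np.linalg.norm(x, axis=1)
    j = np.argmax(np.abs(x), axis=1)
    lead = x[np.arange(len(x)), j]
    ph = np.angle(np.where(lead == 0, 1.0, lead))
    safe = np.where(nrm == 0, 1.0, nrm)
    coeffs = (x * np.exp(-1j * ph)[:, None]).real / safe[:, None]
    coeffs[nrm == 0] = 0.0
    return coeffs, nrm, ph


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

def noise_std(signal_norm, snr_db, n_time: int):
    """Per-sample complex noise standard deviation for a stated SNR in dB.

    SNR is defined against the RMS signal amplitude over the ``n_time``
    temporal samples: sigma = ||x||_2 / sqrt(n_time) * 10^(-SNR/20).  White
    complex noise of this per-sample sigma has the same per-component sigma
    in any orthonormal temporal basis, so noise may equivalently be added to
    the R subspace coefficients directly.
    """
    return np.asarray(signal_norm) / np.sqrt(n_time) * 10.0 ** (-np.asarray(snr_db) / 20.0)


def add_noise(x: np.ndarray, snr_db, n_time: int, rng: np.random.Generator) -> np.ndarray:
    """Add complex white Gaussian noise at the stated SNR to rows of ``x``."""
    x = np.asarray(x, dtype=complex)
    sigma = np.broadcast_to(
        noise_std(np.linalg.norm(x, axis=-1, keepdims=True), snr_db, n_time), x.shape
    )
    noise = rng.standard_normal(x.shape) + 1j * rng.standard_normal(x.shape)
    return x + sigma / np.sqrt(2.0) * noise


# ---------------------------------------------------------------------------
# dictionary matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    pd: np.ndarray       # complex matched-filter projection <x, atom>
    atom_index: np.ndarray


def project_dictionary(dictionary: Dictionary, basis: SubspaceBasis) -> np.ndarray:
    """Unit-normalized subspace representation of every atom, (n_atoms, R)."""
    proj = dictionary.atoms @ basis.basis.conj()
    nrm = np.linalg.norm(proj, axis=1, keepdims=True)
    return proj / np.maximum(nrm, 1e-30)


def dict_match(
    signals: np.ndarray,
    dictionary: Dictionary,
    basis: SubspaceBasis,
    chunk: int = 512,
    atoms_proj: np.ndarray | None = None,
    candidate_idx: np.ndarray | None = None,
) -> MatchResult:
    """Exhaustive maximum-correlation search over the dictionary.

    Each complex signal (row of ``signals``, in the same subspace as the
    dictionary) is matched to the atom maximizing |<x, a>| over unit-norm
    projected atoms; ties resolve to the lowest atom index.  The returned
    per-signal PD is the matched-filter projection <x, a>.
    """
    if dictionary.n_atoms == 0:
        raise ValueError("dictionary is empty")
    signals = np.atleast_2d(np.asarray(signals, dtype=complex))
    A = project_dictionary(dictionary, basis) if atoms_proj is None else atoms_proj
    if candidate_idx is not None:
        A = A[candidate_idx]
    n = signals.shape[0]
    best = np.empty(n, dtype=np.int64)
    pd = np.empty(n, dtype=complex)
    # double precision keeps near-tied correlations ordered consistently
    # across chunkings and candidate subsets
    AH = A.conj().T.astype(np.complex128)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        scores = signals[lo:hi] @ AH  # (chunk, n_atoms)
        mag = np.abs(scores)
        idx = np.argmax(mag, axis=1)
        best[lo:hi] = idx
        pd[lo:hi] = scores[np.arange(hi - lo), idx]
    if candidate_idx is not None:
        best = np.asarray(candidate_idx)[best]
    return MatchResult(
        t1_ms=dictionary.t1_ms[best],
        t2_ms=dictionary.t2_ms[best],
        pd=pd,
        atom_index=best,
    )


def group_match(
    signals: np.ndarray,
    dictionary: Dictionary,
    basis: SubspaceBasis,
    n_groups: int = 80,
    n_probe: int = 2,
    seed: int = 0,
) -> MatchResult:
    """Fast group matching: cluster atoms, probe the best groups, then
    search exhaustively inside them.

    Atoms (phase-aligned, unit norm in the subspace) are clustered with
    k-means into ``n_groups`` groups under correlation distance; each signal
    is scored against the group representatives and the union of the best
    ``n_probe`` groups is searched exhaustively.  With ``n_groups`` equal to
    1 the search degenerates to :func:`dict_match`.
    """
    if n_groups < 1:
        raise ValueError(f"n_groups must be >= 1, got {n_groups}")
    n_groups = min(n_groups, dictionary.n_atoms)
    signals = np.atleast_2d(np.asarray(signals, dtype=complex))
    A = project_dictionary(dictionary, basis)
    if n_groups == 1:
        return dict_match(signals, dictionary, basis, atoms_proj=A)

    aligned, _, _ = phase_align_batch(A)
    if n_groups == dictionary.n_atoms:
        centroids = aligned
        assign = np.arange(dictionary.n_atoms)
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_groups, random_state=seed, n_init=2)
        km.fit(aligned.astype(np.float32))
        centroids = km.cluster_centers_.astype(float)
        centroids /= np.maximum(np.linalg.norm(centroids, axis=1, keepdims=True), 1e-30)
        # re-assign atoms by the same correlation score used at query time
        assign = np.argmax(np.abs(aligned @ centroids.T), axis=1)

    n_probe = min(n_probe, n_groups)
    scores = np.abs(signals @ centroids.T.astype(complex))  # (n, n_groups)
    top = np.argpartition(-scores, n_probe - 1, axis=1)[:, :n_probe]

    members = [np.where(assign == g)[0] for g in range(n_groups)]
    out_t1 = np.empty(signals.shape[0])
    out_t2 = np.empty(signals.shape[0])
    out_pd = np.empty(signals.shape[0], dtype=complex)
    out_idx = np.empty(signals.shape[0], dtype=np.int64)
    # group signals by their probed group set to batch the exhaustive stage
    keys = np.sort(top, axis=1)
    order = np.lexsort(keys.T[::-1])
    sorted_keys = keys[order]
    boundaries = np.flatnonzero(
        np.any(np.diff(sorted_keys, axis=0) != 0, axis=1)
    ) + 1
    for blk in np.split(order, boundaries):
        cand = np.concatenate([members[g] for g in keys[blk[0]]])
        cand = np.unique(cand)
        if cand.size == 0:
            cand = np.arange(dictionary.n_atoms)
        res = dict_match(signals[blk], dictionary, basis, atoms_proj=A,
                         candidate_idx=cand)
        out_t1[blk] = res.t1_ms
        out_t2[blk] = res.t2_ms
        out_pd[blk] = res.pd
        out_idx[blk] = res.atom_index
    return MatchResult(t1_ms=out_t1, t2_ms=out_t2, pd=out_pd, atom_index=out_idx)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def mape_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute percentage error J over samples and components."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    if np.any(truth == 0):
        raise ValueError("truth contains zero entries; MAPE undefined")
    return float(np.mean(np.abs(pred - truth) / np.abs(truth)))


# ---------------------------------------------------------------------------
# network specification and training
# ---------------------------------------------------------------------------

@dataclass
class NNSpec:
    """Architecture description for the compact inference networks."""

    architecture: str = "multipath"        # multipath | fwd | fwd_bck
    hidden_widths: tuple = (200, 100, 1)   # per pathway
    input_dim: int = 10

    def __post_init__(self) -> None:
        if self.architecture not in ("multipath", "fwd", "fwd_bck"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")


@dataclass
class TrainConfig:
    """Training protocol for the inference networks."""

    lr: float = 0.005
    batch: int = 100
    epochs: int = 500
    dropout: float = 0.9           # keep-probability by default
    dropout_is_keep_prob: bool = True
    noise_fraction: float = 0.8    # fraction of samples corrupted
    snr_range_db: tuple = (30.0, 70.0)
    split: float = 0.8             # train fraction (remainder validates)
    seed: int = 0
    loss_name: str = "mape"
    #: internal gradient scale pairing the relative-error loss with the
    #: stated learning rate; histories/returned losses stay fractional.
    loss_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch <= 0 or self.epochs <= 0:
            raise ValueError("lr, batch and epochs must be positive")
        if not (0 < self.split < 1):
            raise ValueError("split must lie in (0, 1)")
        if self.snr_range_db[0] > self.snr_range_db[1]:
            raise ValueError("snr_range_db must be ordered (low, high)")

    @property
    def keep_prob(self) -> float:
        return self.dropout if self.dropout_is_keep_prob else 1.0 - self.dropout


def _init_layers(dims, rng):
    """He-initialized dense layers [(W, b), ...]."""
    layers = []
    for din, dout in zip(dims[:-1], dims[1:]):
        W = rng.standard_normal((din, dout)) * np.sqrt(2.0 / din)
        layers.append([W, np.zeros(dout)])
    return layers


def _forward_stack(layers, x, keep_prob=1.0, rng=None, out_act="linear"):
    """Forward through a dense stack: ReLU hidden layers, configurable output.

    ``out_act="exp"`` makes the head predict in log-space (output is
    ``exp(z)``): for positive parameters spanning orders of magnitude this
    conditions the relative-error loss, whose gradient w.r.t. the
    pre-activation becomes ~ +-(pred/true), uniformly scaled across the
    range.  Returns the output and per-layer caches for backprop.
    """
    caches = []
    h = x
    n = len(layers)
    for i, (W, b) in enumerate(layers):
        z = h @ W + b
        last = i == n - 1
        if not last:
            a = np.maximum(z, 0.0)
        elif out_act == "exp":
            a = np.exp(np.minimum(z, 30.0))
        else:
            a = z
        mask = None
        if rng is not None and keep_prob < 1.0 and not last:
            mask = (rng.random(a.shape) < keep_prob) / keep_prob
            a = a * mask
        caches.append((h, z, mask, last))
        h = a
    return h, caches


def _backward_stack(layers, caches, grad_out, out_act="linear"):
    """Backprop; returns input gradient and accumulates per-layer grads."""
    grads = []
    g = grad_out
    for (W, b), (h, z, mask, last) in zip(reversed(layers), reversed(caches)):
        if mask is not None:
            g = g * mask
        if last and out_act == "exp":
            g = g * np.exp(np.minimum(z, 30.0))
        elif not last:
            g = g * (z > 0)
        grads.append((h.T @ g, g.sum(axis=0)))
        g = g @ W.T
    return g, list(reversed(grads))


def _sgd_step(layers, grads, lr, scale):
    for (W, b), (gW, gb) in zip(layers, grads):
        W -= lr * gW * scale
        b -= lr * gb * scale


@dataclass
class TrainedModel:
    """A trained inference network plus its target scaling."""

    spec: NNSpec
    pathways: list                 # list of layer stacks
    t1_scale: float
    t2_scale: float
    theta3_scale: float
    history: dict = field(default_factory=dict)

    def predict(self, aligned: np.ndarray):
        """Map aligned coefficient rows to (t1_ms, t2_ms, theta3[, decoded]).

        For ``fwd_bck`` the third return value is the decoded signal array
        instead of theta3.
        """
        aligned = np.atleast_2d(np.asarray(aligned, dtype=float))
        arch = self.spec.architecture
        if arch == "multipath":
            outs = [
                _forward_stack(p, aligned, out_act="exp")[0][:, 0]
                for p in self.pathways
            ]
            return (
                outs[0] * self.t1_scale,
                outs[1] * self.t2_scale,
                outs[2] * self.theta3_scale,
            )
        if arch == "fwd":
            out = _forward_stack(self.pathways[0], aligned, out_act="exp")[0]
            return (
                out[:, 0] * self.t1_scale,
                out[:, 1] * self.t2_scale,
                out[:, 2] * self.theta3_scale,
            )
        # fwd_bck: encoder pathways then decoder
        lat1 = _forward_stack(self.pathways[0], aligned, out_act="exp")[0][:, 0]
        lat2 = _forward_stack(self.pathways[1], aligned, out_act="exp")[0][:, 0]
        latent = np.stack([lat1, lat2], axis=1)
        decoded = _forward_stack(self.pathways[2], latent)[0]
        return lat1 * self.t1_scale, lat2 * self.t2_scale, decoded

    # -- persistence -------------------------------------------------------
    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["architecture"] = self.spec.architecture
            f.attrs["input_dim"] = self.spec.input_dim
            f.attrs["hidden_widths"] = list(self.spec.hidden_widths)
            f.attrs["scales"] = [self.t1_scale, self.t2_scale, self.theta3_scale]
            for p, stack in enumerate(self.pathways):
                for l, (W, b) in enumerate(stack):
                    f.create_dataset(f"p{p}/W{l}", data=W)
                    f.create_dataset(f"p{p}/b{l}", data=b)

    @classmethod
    def load_h5(cls, path) -> "TrainedModel":
        import h5py

        with h5py.File(path, "r") as f:
            spec = NNSpec(
                architecture=str(f.attrs["architecture"]),
                hidden_widths=tuple(int(w) for w in f.attrs["hidden_widths"]),
                input_dim=int(f.attrs["input_dim"]),
            )
            s = list(f.attrs["scales"])
            pathways = []
            for p in range(16):
                if f"p{p}" not in f:
                    break
                stack = []
                for l in range(16):
                    if f"W{l}" not in f[f"p{p}"]:
                        break
                    stack.append([f[f"p{p}/W{l}"][:], f[f"p{p}/b{l}"][:]])
                pathways.append(stack)
        return cls(spec=spec, pathways=pathways, t1_scale=s[0], t2_scale=s[1],
                   theta3_scale=s[2])


def _clone(pathways):
    return [[[W.copy(), b.copy()] for W, b in stack] for stack in pathways]


def train_network(
    spec: NNSpec,
    dictionary: Dictionary,
    basis: SubspaceBasis,
    cfg: TrainConfig,
) -> TrainedModel:
    """Train an inference network on the dictionary per the stated protocol.

    Atoms are projected to the subspace, phase-aligned and normalized; 80%
    of the samples are corrupted with complex white noise at an SNR drawn
    uniformly from ``snr_range_db``; plain SGD minimizes the mean absolute
    percentage error of the (grid-max normalized) targets; the model with
    the best validation loss across epochs is returned.  Bit-reproducible
    for a fixed seed.
    """
    if basis.R != spec.input_dim:
        raise ValueError(
            f"basis rank {basis.R} does not match network input dim {spec.input_dim}"
        )
    rng = np.random.default_rng(cfg.seed)
    proj = dictionary.atoms @ basis.basis.conj()  # (n_atoms, R), unnormalized

    n = proj.shape[0]
    perm = rng.permutation(n)
    n_train = int(round(cfg.split * n))
    tr_idx, va_idx = perm[:n_train], perm[n_train:]

    t1s = float(dictionary.t1_ms.max())
    t2s = float(dictionary.t2_ms.max())
    th3s = float(dictionary.norms.max())
    targets = np.stack(
        [dictionary.t1_ms / t1s, dictionary.t2_ms / t2s, dictionary.norms / th3s],
        axis=1,
    )

    def make_inputs(idx, corrupt):
        sig = proj[idx].copy()
        if corrupt:
            m = rng.random(len(idx)) < cfg.noise_fraction
            snr = rng.uniform(*cfg.snr_range_db, size=m.sum())
            sig[m] = add_noise(sig[m], snr[:, None], dictionary.n_reps, rng)
        aligned, _, _ = phase_align_batch(sig)
        return aligned

    x_tr = make_inputs(tr_idx, corrupt=True)
    y_tr = targets[tr_idx]
    x_va = make_inputs(va_idx, corrupt=True)
    y_va = targets[va_idx]
    clean_tr = phase_align_batch(proj[tr_idx])[0]  # decoder target for fwd_bck

    R = spec.input_dim
    w1, w2, w3 = spec.hidden_widths
    arch = spec.architecture
    if arch == "multipath":
        pathways = [_init_layers([R, w1, w2, w3], rng) for _ in range(3)]
    elif arch == "fwd":
        pathways = [_init_layers([R, 3 * w1, 3 * w2, 3 * w3], rng)]
    else:
        pathways = [
            _init_layers([R, w1, w2, w3], rng),
            _init_layers([R, w1, w2, w3], rng),
            _init_layers([2, w2, w1, R], rng),  # mirrored decoder
        ]
    # exp-output heads start near mid-range predictions (~0.3 of the scale)
    n_param_stacks = len(pathways) if arch != "fwd_bck" else 2
    for stack in pathways[:n_param_stacks]:
        stack[-1][1][:] = np.log(0.3)

    keep = cfg.keep_prob
    best_val = np.inf
    best_pathways = _clone(pathways)
    hist = {"train_loss": [], "val_loss": []}

    def val_loss():
        if arch == "multipath":
            pred = np.stack(
                [_forward_stack(p, x_va, out_act="exp")[0][:, 0] for p in pathways],
                axis=1,
            )
            return float(np.mean(np.abs(pred - y_va) / np.abs(y_va)))
        if arch == "fwd":
            pred = _forward_stack(pathways[0], x_va, out_act="exp")[0]
            return float(np.mean(np.abs(pred - y_va) / np.abs(y_va)))
        l1 = _forward_stack(pathways[0], x_va, out_act="exp")[0][:, 0]
        l2 = _forward_stack(pathways[1], x_va, out_act="exp")[0][:, 0]
        dec = _forward_stack(pathways[2], np.stack([l1, l2], 1))[0]
        pl = np.mean(np.abs(np.stack([l1, l2], 1) - y_va[:, :2]) / np.abs(y_va[:, :2]))
        rl = np.mean((dec - x_va) ** 2)
        return float(pl + rl)

    n_tr = len(tr_idx)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_tr)
        ep_loss = 0.0
        n_batches = 0
        for lo in range(0, n_tr, cfg.batch):
            bi = order[lo : lo + cfg.batch]
            xb, yb = x_tr[bi], y_tr[bi]
            bs = len(bi)
            if arch == "multipath":
                loss = 0.0
                for p, stack in enumerate(pathways):
                    out, caches = _forward_stack(stack, xb, keep, rng, out_act="exp")
                    diff = out[:, 0] - yb[:, p]
                    loss += np.mean(np.abs(diff) / np.abs(yb[:, p])) / 3.0
                    g = (np.sign(diff) / np.abs(yb[:, p]) / (3.0 * bs))[:, None]
                    _, grads = _backward_stack(stack, caches, g, out_act="exp")
                    _sgd_step(stack, grads, cfg.lr, cfg.loss_scale)
            elif arch == "fwd":
                out, caches = _forward_stack(pathways[0], xb, keep, rng, out_act="exp")
                diff = out - yb
                loss = np.mean(np.abs(diff) / np.abs(yb))
                g = np.sign(diff) / np.abs(yb) / (3.0 * bs)
                _, grads = _backward_stack(pathways[0], caches, g, out_act="exp")
                _sgd_step(pathways[0], grads, cfg.lr, cfg.loss_scale)
            else:  # fwd_bck
                out1, c1 = _forward_stack(pathways[0], xb, keep, rng, out_act="exp")
                out2, c2 = _forward_stack(pathways[1], xb, keep, rng, out_act="exp")
                latent = np.concatenate([out1, out2], axis=1)
                dec, c3 = _forward_stack(pathways[2], latent, keep, rng)
                diff_p = latent - yb[:, :2]
                diff_r = dec - clean_tr[bi]
                loss = float(
                    np.mean(np.abs(diff_p) / np.abs(yb[:, :2]))
                    + np.mean(diff_r**2)
                )
                g_dec = 2.0 * diff_r / diff_r.size
                g_lat, grads3 = _backward_stack(pathways[2], c3, g_dec)
                g_par = np.sign(diff_p) / np.abs(yb[:, :2]) / (2.0 * bs)
                g1 = (g_par[:, 0] + g_lat[:, 0])[:, None]
                g2 = (g_par[:, 1] + g_lat[:, 1])[:, None]
                _, grads1 = _backward_stack(pathways[0], c1, g1, out_act="exp")
                _, grads2 = _backward_stack(pathways[1], c2, g2, out_act="exp")
                _sgd_step(pathways[0], grads1, cfg.lr, cfg.loss_scale)
                _sgd_step(pathways[1], grads2, cfg.lr, cfg.loss_scale)
                _sgd_step(pathways[2], grads3, cfg.lr, cfg.loss_scale)
            ep_loss += loss
            n_batches += 1
        vl = val_loss()
        hist["train_loss"].append(ep_loss / max(n_batches, 1))
        hist["val_loss"].append(vl)
        if vl < best_val:
            best_val = vl
            best_pathways = _clone(pathways)

    return TrainedModel(
        spec=spec,
        pathways=best_pathways,
        t1_scale=t1s,
        t2_scale=t2s,
        theta3_scale=th3s,
        history=hist,
    )


# ---------------------------------------------------------------------------
# voxelwise map inference
# ---------------------------------------------------------------------------

@dataclass
class ParameterMaps:
    """Voxelwise T1, T2 (ms), relative PD, and the inference mask."""

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    pd: np.ndarray
    mask: np.ndarray

    def save_nifti(self, outdir, voxel_mm: float = 1.0, prefix: str = "") -> list:
        import os

        import nibabel as nib

        aff = np.diag([voxel_mm] * 3 + [1.0])[:4, :4]
        paths = []
        for name, vol in (
            ("t1_ms", self.t1_ms),
            ("t2_ms", self.t2_ms),
            ("pd", self.pd),
            ("mask", self.mask.astype(np.uint8)),
        ):
            arr = np.asarray(vol, dtype=np.float32)
            if arr.ndim == 2:
                arr = arr[:, :, None]
            img = nib.Nifti1Image(arr, aff)
            img.header["descrip"] = f"{name} (ms for relaxation times)".encode()[:80]
            p = os.path.join(outdir, f"{prefix}{name}.nii.gz".lstrip("_"))
            nib.save(img, p)
            paths.append(p)
        return paths


def infer_maps(
    model: TrainedModel,
    images: CoefficientImages,
    mask: np.ndarray | None = None,
    t1_range: tuple | None = None,
    t2_range: tuple | None = None,
) -> ParameterMaps:
    """Run the trained network voxelwise over coefficient images.

    Each voxel's coefficient vector is phase-aligned and normalized; the
    network infers (T1, T2) and either theta3 (PD via rho = ||x|| / theta3)
    or, for the autoencoder, a decoded signal (PD via the matched-filter
    projection rho = <x, x_dec> / ||x_dec||).  Zero-norm or non-finite
    voxels are masked out.  Estimates are clipped to the training range.
    """
    shape = images.shape
    X = images.voxel_signals()  # (n_voxels, R)
    finite = np.all(np.isfinite(X), axis=1)
    X = np.where(finite[:, None], X, 0.0)
    aligned, norms, _ = phase_align_batch(X)
    valid = (norms > 0) & finite
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool).reshape(-1)

    t1, t2, third = model.predict(aligned)
    if model.spec.architecture == "fwd_bck":
        num = np.einsum("ij,ij->i", X, np.conj(third.astype(complex)))
        den = np.linalg.norm(third, axis=1)
        pd = np.abs(num) / np.maximum(den, 1e-30)
    else:
        pd = norms / np.maximum(np.abs(third), 1e-30)

    lo1, hi1 = t1_range if t1_range else (1.0, model.t1_scale)
    lo2, hi2 = t2_range if t2_range else (1.0, model.t2_scale)
    t1 = np.clip(t1, lo1, hi1)
    t2 = np.clip(t2, lo2, hi2)
    for arr in (t1, t2, pd):
        arr[~valid] = 0.0
    return ParameterMaps(
        t1_ms=t1.reshape(shape),
        t2_ms=t2.reshape(shape),
        pd=pd.reshape(shape),
        mask=valid.reshape(shape),
    )
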