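"""Config-driven pipeline stages with a JSON manifest.

Each stage reads its inputs from the output directory, writes its products
there, and records provenance (config hash, seed, wall time) in
``manifest.json``.  Stages are idempotent: if their outputs already exist
they are skipped unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np

from . import epg, recon
from .config import PipelineConfig
from .epg import Dictionary, build_dictionary, reduced_t1_grid
from .inference import (NNSpec, TrainConfig, TrainedModel, dict_match,
                        group_match, infer_maps, phase_align_batch)
from .phantom import KSpaceData, forward_simulate, make_coil_maps, make_phantom
from .recon import SubspaceBasis, compute_basis, project_kspace, psf_experiment, reconstruct
from .schedule import AcquisitionSchedule, make_flip_schedule, timing_presets
from .synthesis import CONTRAST_PRESETS, synthesize
from .trajectories import make_trajectory
from .viewshare import ViewShareConfig, kw_viewshare

log = logging.getLogger("qti")

STAGES = ["schedule", "dict", "traj", "phantom", "forward", "recon", "train",
          "infer", "synth"]


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.model_dump(), sort_keys=True).encode()
    ).hexdigest()[:16]


class Pipeline:
    """Executes pipeline stages against one output directory."""

    def __init__(self, cfg: PipelineConfig, force: bool = False):
        self.cfg = cfg
        self.force = force
        self.outdir = cfg.io.outdir
        os.makedirs(self.outdir, exist_ok=True)
        self.manifest_path = os.path.join(self.outdir, "manifest.json")
        if os.path.exists(self.manifest_path):
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)
        else:
            self.manifest = {"stages": {}}
        self.manifest["config_hash"] = config_hash(cfg)
        self.manifest["seed"] = cfg.seed

    # -- helpers -----------------------------------------------------------
    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def _done(self, stage: str, outputs: list) -> bool:
        return (
            not self.force
            and all(os.path.exists(p) for p in outputs)
            and stage in self.manifest["stages"]
        )

    def _record(self, stage: str, outputs: list, t0: float) -> None:
        self.manifest["stages"][stage] = {
            "outputs": [os.path.relpath(p, self.outdir) for p in outputs],
            "wall_time_s": round(time.time() - t0, 3),
        }
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2)

    def run(self, stages: list | None = None) -> dict:
        for stage in stages or STAGES:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}; valid: {STAGES}")
            getattr(self, f"stage_{stage}")()
        return self.manifest

    # -- stages ------------------------------------------------------------
    def stage_schedule(self) -> AcquisitionSchedule:
        out = self.path("schedule.yaml")
        sc = self.cfg.schedule
        if self._done("schedule", [out]):
            return AcquisitionSchedule.from_yaml(out)
        t0 = time.time()
        tr, te = timing_presets(sc.field_strength, sc.readout_family)
        sched = make_flip_schedule(
            sc.n_reps, sc.ramp_peak_deg, sc.tail_deg, sc.ramp_up_frac,
            sc.ramp_down_frac, tr_ms=tr, te_ms=te, n_segments=sc.n_segments,
            inversion_efficiency=sc.inversion_efficiency,
            dephasing_cycles=sc.dephasing_cycles,
        )
        sched.to_yaml(out)
        log.info("schedule: %d repetitions, TR/TE %.2f/%.2f ms", sc.n_reps, tr, te)
        self._record("schedule", [out], t0)
        return sched

    def _grids(self):
        if self.cfg.subspace.t1_grid == "default":
            return epg.default_t1_grid(), epg.default_t2_grid()
        return reduced_t1_grid(), epg.default_t2_grid()

    def stage_dict(self) -> Dictionary:
        out = self.path("dictionary.h5")
        if self._done("dict", [out]):
            return Dictionary.load_h5(out)
        t0 = time.time()
        sched = self.stage_schedule()
        t1g, t2g = self._grids()
        d = build_dictionary(sched, t1g, t2g)
        d.save_h5(out)
        log.info("dictionary: %d atoms x %d repetitions", d.n_atoms, d.n_reps)
        self._record("dict", [out], t0)
        return d

    def stage_traj(self):
        out = self.path("trajectory.h5")
        if self._done("traj", [out]):
            from .trajectories import Trajectory

            return Trajectory.load_h5(out)
        t0 = time.time()
        tc, sc = self.cfg.trajectory, self.cfg.schedule
        traj = make_trajectory(
            tc.kind, sc.n_reps, sc.n_segments, tc.n_inplane,
            matrix=self.cfg.phantom.matrix,
            gradient_limits=(tc.gradient_amplitude_mt_m, tc.slew_rate_t_m_s),
            seed=self.cfg.seed, fov_mm=self.cfg.geometry.fov_mm,
            n_samples=tc.n_samples, density_exponent=tc.density_exponent,
        )
        traj.save_h5(out)
        log.info("trajectory: %s, %d interleaves", tc.kind, traj.n_interleaves)
        self._record("traj", [out], t0)
        return traj

    def stage_phantom(self):
        pc = self.cfg.phantom
        outs = [self.path(f"phantom_{n}.nii.gz") for n in ("t1_ms", "t2_ms", "pd", "labels")]
        npy = self.path("phantom_labels.npy")
        if self._done("phantom", outs + [npy]):
            ph = make_phantom(pc.matrix, self.cfg.seed, pc.ndim)
            return ph
        t0 = time.time()
        ph = make_phantom(pc.matrix, self.cfg.seed, pc.ndim)
        ph.save_nifti(self.outdir)
        np.save(npy, ph.labels)
        self._record("phantom", outs + [npy], t0)
        return ph

    def stage_forward(self) -> KSpaceData:
        out = self.path("kspace.h5")
        if self._done("forward", [out]):
            loaded = KSpaceData.load_h5(out)
            return loaded[0] if isinstance(loaded, tuple) else loaded
        t0 = time.time()
        pc = self.cfg.phantom
        ph = self.stage_phantom()
        sched = self.stage_schedule()
        traj = self.stage_traj()
        coils = make_coil_maps(pc.matrix, pc.n_coils, self.cfg.seed, pc.ndim)
        ks = forward_simulate(ph, sched, traj, coils, snr_db=pc.snr_db,
                              seed=self.cfg.seed)
        ks.save_h5(out, traj)
        log.info("forward: kdata shape %s", ks.kdata.shape)
        self._record("forward", [out], t0)
        return ks

    def stage_recon(self) -> recon.CoefficientImages:
        out = self.path("coeff_images.h5")
        if self._done("recon", [out]):
            import h5py

            with h5py.File(out) as f:
                return recon.CoefficientImages(images=f["images"][:])
        t0 = time.time()
        d = self.stage_dict()
        basis = compute_basis(d, self.cfg.subspace.rank)
        traj = self.stage_traj()
        ks = self.stage_forward()
        kdata = ks.kdata
        if self.cfg.viewshare.enabled and not ks.fully_sampled:
            from .viewshare import kw_viewshare_project

            vs = self.cfg.viewshare
            coeff = kw_viewshare_project(
                kdata, traj,
                ViewShareConfig(vs.full_sample_threshold, vs.max_window,
                                vs.weight_shape, matrix=self.cfg.phantom.matrix),
                basis,
            )
        else:
            rep_map = None if ks.fully_sampled else traj.rep_map
            coeff = project_kspace(kdata, rep_map, basis)
        coeff = coeff.reshape(basis.R, kdata.shape[0], -1)
        imgs = reconstruct(coeff, traj, self.cfg.phantom.matrix,
                           method=self.cfg.subspace.recon_method,
                           cg_iters=self.cfg.subspace.cg_iters)
        import h5py

        with h5py.File(out, "w") as f:
            f.create_dataset("images", data=imgs.images.astype(np.complex64))
        imgs.save_nifti(self.path("coeff_images.nii.gz"))
        self._record("recon", [out, self.path("coeff_images.nii.gz")], t0)
        return imgs

    def stage_train(self) -> TrainedModel:
        ic = self.cfg.inference
        if ic.pretrained_model:
            return TrainedModel.load_h5(ic.pretrained_model)
        out = self.path("model.h5")
        if self._done("train", [out]):
            return TrainedModel.load_h5(out)
        t0 = time.time()
        d = self.stage_dict()
        basis = compute_basis(d, self.cfg.subspace.rank)
        arch = ic.method if ic.method in ("multipath", "fwd", "fwd_bck") else "multipath"
        model = train_network(
            NNSpec(architecture=arch, input_dim=self.cfg.subspace.rank), d, basis,
            TrainConfig(lr=ic.lr, batch=ic.batch, epochs=ic.epochs,
                        dropout=ic.dropout,
                        dropout_is_keep_prob=ic.dropout_is_keep_prob,
                        seed=self.cfg.seed),
        )
        model.save_h5(out)
        log.info("train: best validation loss %.4f", min(model.history["val_loss"]))
        self._record("train", [out], t0)
        return model

    def stage_infer(self):
        outs = [self.path(f"{n}.nii.gz") for n in ("t1_ms", "t2_ms", "pd", "mask")]
        if self._done("infer", outs):
            return None
        t0 = time.time()
        imgs = self.stage_recon()
        ic = self.cfg.inference
        if ic.method in ("dict", "group"):
            d = self.stage_dict()
            basis = compute_basis(d, self.cfg.subspace.rank)
            X = imgs.voxel_signals()
            norms = np.linalg.norm(X, axis=1)
            matcher = dict_match if ic.method == "dict" else group_match
            res = matcher(X, d, basis)
            from .inference import ParameterMaps

            mask = norms > 0.05 * norms.max()
            maps = ParameterMaps(
                t1_ms=np.where(mask, res.t1_ms, 0).reshape(imgs.shape),
                t2_ms=np.where(mask, res.t2_ms, 0).reshape(imgs.shape),
                pd=np.where(mask, np.abs(res.pd), 0).reshape(imgs.shape),
                mask=mask.reshape(imgs.shape),
            )
        else:
            model = self.stage_train()
            X = imgs.voxel_signals()
            norms = np.linalg.norm(X, axis=1)
            maps = infer_maps(model, imgs, mask=norms > 0.05 * norms.max())
        maps.save_nifti(self.outdir, voxel_mm=self.cfg.geometry.voxel_mm)
        self._maps = maps
        self._record("infer", outs, t0)
        return maps

    def stage_synth(self):
        outs = [self.path(f"synth_{c}.nii.gz") for c in self.cfg.synthesis.contrasts]
        if self._done("synth", outs):
            return None
        t0 = time.time()
        maps = getattr(self, "_maps", None)
        if maps is None:
            maps = self.stage_infer()
        import nibabel as nib

        aff = np.diag([self.cfg.geometry.voxel_mm] * 3 + [1.0])[:4, :4]
        for c in self.cfg.synthesis.contrasts:
            img = synthesize(maps, CONTRAST_PRESETS[c])
            arr = np.asarray(img, dtype=np.float32)
            if arr.ndim == 2:
                arr = arr[:, :, None]
            nib.save(nib.Nifti1Image(arr, aff), self.path(f"synth_{c}.nii.gz"))
        self._record("synth", outs, t0)

    def stage_psf(self):
        out = self.path("psf_metrics.csv")
        if self._done("psf", [out]):
            return None
        t0 = time.time()
        sched = self.stage_schedule()
        d = self.stage_dict()
        basis = compute_basis(d, self.cfg.subspace.rank)
        traj = self.stage_traj()
        vs = self.cfg.viewshare
        rep = psf_experiment(
            sched, traj, basis, use_viewshare=vs.enabled,
            vs_config=ViewShareConfig(vs.full_sample_threshold, vs.max_window,
                                      vs.weight_shape,
                                      matrix=self.cfg.phantom.matrix),
        )
        rep.to_csv(out)
        self._record("psf", [out], t0)
        return rep
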