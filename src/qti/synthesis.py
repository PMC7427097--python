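"""Contrast-weighted image synthesis from quantitative parameter maps.

Once voxelwise T1, T2 and relative proton density are known, standard
clinical contrasts follow from the steady-state solutions of the Bloch
equations:

* SPGR (spoiled gradient echo):
  ``S = rho * sin(a) * (1 - exp(-TR/T1)) / (1 - cos(a) * exp(-TR/T1))``
* FSE (fast spin echo): ``S = rho * exp(-TE/T2)``
* FLAIR (fluid-attenuated inversion recovery):
  ``S = rho * exp(-TE/T2) * (1 - 2 * exp(-TI/T1))``

FLAIR nulls tissue with T1 = TI / ln 2 (the fluid-suppression condition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ContrastParams", "synthesize", "CONTRAST_PRESETS"]


@dataclass
class ContrastParams:
    """Sequence parameters of a synthesized contrast."""

    contrast: str                  # spgr | fse | flair
    tr_ms: float | None = None
    te_ms: float | None = None
    ti_ms: float | None = None
    flip_deg: float | None = None

    def __post_init__(self) -> None:
        required = {
            "spgr": ("tr_ms", "flip_deg"),
            "fse": ("te_ms",),
            "flair": ("te_ms", "ti_ms"),
        }
        if self.contrast not in required:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        for name in required[self.contrast]:
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValueError(
                    f"{self.contrast} synthesis requires positive {name}, got {v}"
                )


#: Presets exactly as used for the synthesized clinical contrasts.
CONTRAST_PRESETS = {
    "spgr": ContrastParams("spgr", tr_ms=5.83, flip_deg=13.0),
    "fse": ContrastParams("fse", te_ms=100.0),
    "flair": ContrastParams("flair", te_ms=84.812, ti_ms=2500.0),
}


def synthesize(maps, params: ContrastParams, signed: bool = False) -> np.ndarray:
    """Evaluate a contrast equation voxelwise over parameter maps.

    ``maps`` needs attributes ``t1_ms``, ``t2_ms``, ``pd`` and ``mask``
    (a :class:`~qti.inference.ParameterMaps`).  Masked-out voxels are 0;
    masked voxels with a vanishing relaxation time are dropped from the
    output with a warning.  By default the magnitude is returned; pass
    ``signed=True`` to keep the signed FLAIR value.
    """
    mask = np.asarray(maps.mask, dtype=bool)
    t1 = np.asarray(maps.t1_ms, dtype=float)
    t2 = np.asarray(maps.t2_ms, dtype=float)
    rho = np.asarray(maps.pd, dtype=float)

    bad = mask & ((t1 <= 0) | (t2 <= 0))
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} masked voxels have zero relaxation time; masking them out"
        )
        mask = mask & ~bad

    out = np.zeros_like(rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        if params.contrast == "spgr":
            a = np.deg2rad(params.flip_deg)
            e1 = np.exp(-params.tr_ms / np.where(mask, t1, 1.0))
            s = rho * np.sin(a) * (1 - e1) / (1 - np.cos(a) * e1)
        elif params.contrast == "fse":
            s = rho * np.exp(-params.te_ms / np.where(mask, t2, 1.0))
        else:  # flair
            s = (
                rho
                * np.exp(-params.te_ms / np.where(mask, t2, 1.0))
                * (1 - 2 * np.exp(-params.ti_ms / np.where(mask, t1, 1.0)))
            )
    out[mask] = s[mask] if signed else np.abs(s[mask])
    return out
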