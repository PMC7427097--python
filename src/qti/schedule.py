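"""Transient-state excitation schedules.

A transient-state acquisition drives the magnetization with a smoothly varying
flip-angle train: an inversion pulse, a ramp up to a peak angle that encodes T1
and T2, a ramp back down, and a constant low-angle tail that lets the
longitudinal magnetization recover before the next inversion.  The same train
("segment") is repeated to acquire different k-space interleaves at equivalent
contrast states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = ["AcquisitionSchedule", "make_flip_schedule", "timing_presets"]

#: Timing presets in ms, keyed by (field strength, readout family).
#: TR depends on field strength, TE on the readout family (spiral readouts
#: start at the k-space center and can use an ultra-short TE; full radial
#: spokes need to traverse half the readout first).
_TIMING_MS = {
    ("3T", "spiral"): (10.5, 0.46),
    ("1.5T", "spiral"): (12.0, 0.46),
    ("3T", "radial"): (10.5, 2.08),
    ("1.5T", "radial"): (12.0, 2.08),
}


@dataclass
class AcquisitionSchedule:
    """Flip-angle train plus timing for one transient-state segment.

    Parameters
    ----------
    flip_angles : (n_reps,) array, degrees
        Excitation flip angle for every repetition, in [0, 90].
    rf_phases : (n_reps,) array, degrees
        RF pulse phase per repetition (constant 0 for the unbalanced
        FISP-like sequence used here, which has no RF spoiling).
    tr_ms, te_ms : float
        Repetition and echo time in milliseconds, ``0 < te_ms <= tr_ms``.
    inversion : bool
        Whether an inversion pulse precedes the train.
    inversion_efficiency : float
        Fraction of longitudinal magnetization actually inverted, in [0, 1].
    n_segments : int
        Number of times the train is repeated (each segment acquires
        different k-space interleaves at the same contrast states).
    dephasing_cycles : float
        Net gradient dephasing per TR across the voxel, in cycles.  The
        default of 2 corresponds to 4*pi intra-voxel dephasing.
    """

    flip_angles: np.ndarray
    rf_phases: np.ndarray
    tr_ms: float
    te_ms: float
    inversion: bool = True
    inversion_efficiency: float = 1.0
    n_segments: int = 1
    dephasing_cycles: float = 2.0

    def __post_init__(self) -> None:
        self.flip_angles = np.asarray(self.flip_angles, dtype=float)
        self.rf_phases = np.asarray(self.rf_phases, dtype=float)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        if self.flip_angles.ndim != 1 or self.rf_phases.ndim != 1:
            raise ValueError("flip_angles and rf_phases must be 1-D")
        if len(self.flip_angles) != len(self.rf_phases):
            raise ValueError(
                "flip_angles and rf_phases must have equal length, got "
                f"{len(self.flip_angles)} and {len(self.rf_phases)}"
            )
        if np.any(self.flip_angles < 0) or np.any(self.flip_angles > 90):
            raise ValueError("flip_angles must lie in [0, 90] degrees")
        if not (0 < self.te_ms <= self.tr_ms):
            raise ValueError(
                f"need 0 < te_ms <= tr_ms, got te_ms={self.te_ms}, tr_ms={self.tr_ms}"
            )
        if not (0.0 <= self.inversion_efficiency <= 1.0):
            raise ValueError("inversion_efficiency must lie in [0, 1]")
        if self.n_segments < 1:
            raise ValueError("n_segments must be a positive integer")

    @property
    def n_reps(self) -> int:
        return len(self.flip_angles)

    def with_(self, **kwargs) -> "AcquisitionSchedule":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path=None) -> str:
        doc = {
            "flip_angles": [float(a) for a in self.flip_angles],
            "rf_phases": [float(p) for p in self.rf_phases],
            "tr_ms": float(self.tr_ms),
            "te_ms": float(self.te_ms),
            "inversion": bool(self.inversion),
            "inversion_efficiency": float(self.inversion_efficiency),
            "n_segments": int(self.n_segments),
            "dephasing_cycles": float(self.dephasing_cycles),
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "AcquisitionSchedule":
        """Load a schedule from a YAML string or file path."""
        import os

        if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(source)
        return cls(
            flip_angles=np.asarray(doc["flip_angles"], dtype=float),
            rf_phases=np.asarray(doc["rf_phases"], dtype=float),
            tr_ms=float(doc["tr_ms"]),
            te_ms=float(doc["te_ms"]),
            inversion=bool(doc.get("inversion", True)),
            inversion_efficiency=float(doc.get("inversion_efficiency", 1.0)),
            n_segments=int(doc.get("n_segments", 1)),
            dephasing_cycles=float(doc.get("dephasing_cycles", 2.0)),
        )


def make_flip_schedule(
    n_reps: int,
    ramp_peak_deg: float = 70.0,
    tail_deg: float = 5.0,
    ramp_up_frac: float = 0.4,
    ramp_down_frac: float = 0.3,
    *,
    tr_ms: float = 10.5,
    te_ms: float = 0.46,
    n_segments: int = 1,
    inversion_efficiency: float = 1.0,
    dephasing_cycles: float = 2.0,
) -> AcquisitionSchedule:
    """Build the canonical ramp-up / ramp-down / constant-tail flip train.

    The train rises linearly from ``tail_deg`` to ``ramp_peak_deg`` over the
    first ``ramp_up_frac * n_reps`` repetitions, descends linearly back to
    ``tail_deg`` over the next ``ramp_down_frac * n_reps``, and stays constant
    at ``tail_deg`` for the remainder.  An inversion pulse precedes the train.

    Raises
    ------
    ValueError
        If ``ramp_peak_deg < tail_deg``, fractions are negative or sum to
        more than 1, or ``n_reps < 3``.
    """
    if n_reps < 3:
        raise ValueError(f"n_reps must be >= 3, got {n_reps}")
    if not (0 < tail_deg <= ramp_peak_deg <= 90):
        raise ValueError(
            "need 0 < tail_deg <= ramp_peak_deg <= 90, got "
            f"tail_deg={tail_deg}, ramp_peak_deg={ramp_peak_deg}"
        )
    if ramp_up_frac < 0 or ramp_down_frac < 0:
        raise ValueError(
            f"ramp fractions must be nonnegative, got ramp_up_frac={ramp_up_frac}, "
            f"ramp_down_frac={ramp_down_frac}"
        )
    if ramp_up_frac + ramp_down_frac > 1:
        raise ValueError(
            "ramp_up_frac + ramp_down_frac must be <= 1, got "
            f"{ramp_up_frac} + {ramp_down_frac}"
        )

    n_up = int(round(ramp_up_frac * n_reps))
    n_down = int(round(ramp_down_frac * n_reps))
    n_tail = n_reps - n_up - n_down

    up = np.linspace(tail_deg, ramp_peak_deg, max(n_up, 0))
    # start the descent one step below the peak so the maximum is unique
    down = np.linspace(ramp_peak_deg, tail_deg, n_down + 1)[1:] if n_down else np.empty(0)
    tail = np.full(max(n_tail, 0), tail_deg)
    flips = np.concatenate([up, down, tail])[:n_reps]
    if len(flips) < n_reps:  # degenerate rounding at tiny n_reps
        flips = np.concatenate([flips, np.full(n_reps - len(flips), tail_deg)])

    return AcquisitionSchedule(
        flip_angles=flips,
        rf_phases=np.zeros(n_reps),
        tr_ms=tr_ms,
        te_ms=te_ms,
        inversion=True,
        inversion_efficiency=inversion_efficiency,
        n_segments=n_segments,
        dephasing_cycles=dephasing_cycles,
    )


def timing_presets(field_strength_label: str, readout_family: str) -> tuple:
    """Return ``(tr_ms, te_ms)`` for a field strength and readout family.

    ``field_strength_label`` is one of ``{"1.5T", "3T"}`` and
    ``readout_family`` one of ``{"spiral", "radial"}``.
    """
    key = (str(field_strength_label), str(readout_family))
    if key not in _TIMING_MS:
        raise ValueError(
            f"unknown timing preset {key!r}; field must be one of "
            "{'1.5T', '3T'} and readout one of {'spiral', 'radial'}"
        )
    return _TIMING_MS[key]
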