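"""Synthetic targets, decoys and emulated error predictors.

Stands in for a real benchmark set of homology models: targets are
compact self-avoiding CA traces; decoys add a chain-correlated
displacement field organised in segments (accurate cores, sloppy
loops, unreliable regions) so per-residue error is heterogeneous the
way homology-model error is; an emulated predictor degrades the true
per-residue errors with multiplicative log-normal noise, giving
"predicted" errors whose correlation with truth is tunable — a noisier
preset stands in for an older quality predictor, a tighter one for a
deep-learning successor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .quality import DEFAULT_CAP, ErrorProfile
from .structures import Structure
from .superpose import per_residue_deviation

ERROR_CLASSES = ("core", "loop", "unreliable")
DEFAULT_CLASS_RMS: Dict[str, float] = {"core": 0.5, "loop": 2.5, "unreliable": 6.0}

#: Emulated-predictor presets: log-sd of the multiplicative noise on true
#: error.  Calibrated to order fidelity only (the tighter preset tracks
#: truth better), not to reproduce any particular predictor's accuracy.
PREDICTOR_PRESETS: Dict[str, float] = {"proq2-like": 0.55, "proq3d-like": 0.35}

_BOND = 3.8
_BOND_JITTER = 0.04
_MIN_SEPARATION = 3.5
_RG_COEFF = 2.2
_RG_EXP = 0.38
_PULL = 1.4  # centroid-pull strength keeping the walk compact

__all__ = [
    "DecoySpec",
    "PredictorSpec",
    "GenerationError",
    "make_target",
    "make_decoy",
    "emulate_predictor",
    "random_segment_layout",
    "DEFAULT_CLASS_RMS",
    "PREDICTOR_PRESETS",
]


class GenerationError(RuntimeError):
    """Self-avoiding walk failed after bounded retries; try another seed."""


@dataclass(frozen=True)
class DecoySpec:
    """Recipe for one decoy: segment layout and per-class displacement RMS.

    `segment_layout` is a list of (length, error_class) tuples whose
    lengths sum to `n_residues`; `class_rms` maps each error class to
    the RMS displacement (Å) applied to its residues.
    """

    n_residues: int
    segment_layout: Tuple[Tuple[int, str], ...]
    class_rms: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_RMS))
    seed: int = 0

    def __post_init__(self):
        layout = tuple((int(l), str(c)) for l, c in self.segment_layout)
        object.__setattr__(self, "segment_layout", layout)
        total = sum(l for l, _ in layout)
        if total != self.n_residues:
            raise ValueError(
                f"segment lengths sum to {total}, expected n_residues={self.n_residues}"
            )
        for _, cls in layout:
            if cls not in ERROR_CLASSES:
                raise ValueError(f"unknown error class {cls!r}")
        if any(rms < 0 for rms in self.class_rms.values()):
            raise ValueError("class RMS values must be >= 0")

    @classmethod
    def random(
        cls,
        n_residues: int,
        seed: int,
        class_rms: Optional[Dict[str, float]] = None,
    ) -> "DecoySpec":
        """Random segment layout: mostly cores, some loops, occasional
        unreliable stretches — one draw per decoy."""
        rng = np.random.default_rng(seed)
        layout: List[Tuple[int, str]] = []
        remaining = n_residues
        while remaining > 0:
            u = rng.random()
            if u < 0.55:
                kind, length = "core", int(rng.integers(10, 31))
            elif u < 0.85:
                kind, length = "loop", int(rng.integers(4, 13))
            else:
                kind, length = "unreliable", int(rng.integers(4, 11))
            length = min(length, remaining)
            layout.append((length, kind))
            remaining -= length
        return cls(
            n_residues=n_residues,
            segment_layout=tuple(layout),
            class_rms=dict(class_rms or DEFAULT_CLASS_RMS),
            seed=seed,
        )


@dataclass(frozen=True)
class PredictorSpec:
    """Noise model for an emulated per-residue error predictor."""

    noise_sd_log: float = PREDICTOR_PRESETS["proq3d-like"]
    floor: float = 0.25  # minimum reported error, Å
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be >= 0")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "PredictorSpec":
        if name not in PREDICTOR_PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PREDICTOR_PRESETS)}")
        return cls(noise_sd_log=PREDICTOR_PRESETS[name], seed=seed)


def make_target(n_residues: int, seed: int) -> Structure:
    """Compact self-avoiding CA trace, deterministic in `seed`.

    Consecutive CA-CA distances are 3.8 +- 0.05 Å, non-consecutive CAs
    stay >= 3.5 Å apart, and a centroid pull keeps the radius of
    gyration near 2.2 * n^0.38 Å (globular scaling).
    """
    if n_residues < 20:
        raise ValueError("targets need at least 20 residues")
    rng = np.random.default_rng(seed)
    rg_target = _RG_COEFF * n_residues**_RG_EXP
    coords = [np.zeros(3)]
    failures = 0
    max_failures = 40 * n_residues
    while len(coords) < n_residues:
        pos = coords[-1]
        centroid = np.mean(coords, axis=0)
        placed = False
        for _ in range(120):
            direction = rng.normal(size=3)
            off = pos - centroid
            r = np.linalg.norm(off)
            if r > 0.9 * rg_target:
                direction -= _PULL * (r / rg_target) * off / r
            direction /= np.linalg.norm(direction)
            step = _BOND + rng.uniform(-_BOND_JITTER, _BOND_JITTER)
            cand = pos + step * direction
            if len(coords) > 1:
                prev = np.asarray(coords[:-1])
                if np.min(np.linalg.norm(prev - cand, axis=1)) < _MIN_SEPARATION:
                    continue
            coords.append(cand)
            placed = True
            break
        if not placed:
            failures += 120
            if failures > max_failures:
                raise GenerationError(
                    f"could not extend self-avoiding trace (seed {seed}); try another seed"
                )
            # back out of the dead end and retry
            del coords[-min(5, len(coords) - 1) :]
            if not coords:
                coords = [np.zeros(3)]
    xyz = np.asarray(coords)
    xyz -= xyz.mean(axis=0)
    return Structure.from_coords(xyz, identifier=f"target-{seed}")


def _segment_classes(spec: DecoySpec) -> List[Tuple[slice, str]]:
    out = []
    start = 0
    for length, cls in spec.segment_layout:
        out.append((slice(start, start + length), cls))
        start += length
    return out


def make_decoy(target: Structure, spec: DecoySpec) -> Tuple[Structure, ErrorProfile]:
    """Perturb `target` into a decoy with known heterogeneous error.

    A Gaussian displacement field is smoothed along the chain with a
    5-residue triangular kernel (so errors are spatially correlated:
    whole loops go bad together rather than single residues), then
    rescaled per segment so each segment's RMS displacement matches its
    class.  Returns the decoy and its realized (true, uncapped)
    per-residue deviations after superposition onto the target.
    """
    n = len(target)
    if spec.n_residues != n:
        raise ValueError(f"spec is for {spec.n_residues} residues, target has {n}")
    rng = np.random.default_rng(spec.seed)
    raw = rng.normal(size=(n, 3))
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    kernel /= kernel.sum()
    smooth = np.column_stack([np.convolve(raw[:, k], kernel, mode="same") for k in range(3)])
    disp = np.zeros_like(smooth)
    for seg, cls in _segment_classes(spec):
        want = spec.class_rms[cls]
        block = smooth[seg]
        have = np.sqrt(np.mean(np.sum(block**2, axis=1)))
        disp[seg] = block * (want / have) if have > 0 and want > 0 else 0.0
    decoy = target.with_coords(target.coords + disp)
    decoy = Structure.from_coords(decoy.coords, identifier=f"{target.identifier}-decoy{spec.seed}")
    return decoy, per_residue_deviation(decoy, target)


def emulate_predictor(true_profile: ErrorProfile, spec: PredictorSpec) -> ErrorProfile:
    """Emulated predicted errors: true d times log-normal noise.

    predicted d_i = clamp(floor, cap, d_i * exp(eps_i)),
    eps_i ~ Normal(0, noise_sd_log^2); qualities are recomputed from the
    predicted distances.  Deterministic given ``spec.seed``.
    """
    if len(true_profile) == 0:
        raise ValueError("true profile is empty")
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(scale=spec.noise_sd_log, size=len(true_profile)) if spec.noise_sd_log > 0 else 0.0
    d_pred = np.clip(true_profile.d * np.exp(eps), spec.floor, DEFAULT_CAP)
    return ErrorProfile.from_d(d_pred)


def random_segment_layout(n_residues: int, seed: int) -> Tuple[Tuple[int, str], ...]:
    """Convenience: layout of :meth:`DecoySpec.random` without the spec."""
    return DecoySpec.random(n_residues, seed).segment_layout
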