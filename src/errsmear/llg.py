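"""Desk-scale log-likelihood-gain (LLG) engine.

A deliberately small stand-in for a full molecular-replacement
likelihood: direct-summation structure factors from unit point
scatterers in a P1 orthorhombic cell, Debye-Waller attenuation from
per-atom B factors, shell-wise sigmaA estimated by correlation of
normalized amplitudes, and an acentric Rice likelihood scored against
the Wilson (random-atom) baseline:

    LLG = sum_h [ log Rice(E_obs | sigmaA, E_calc) - log Wilson(E_obs) ]

The mechanism of interest survives the simplification: smearing
unreliable atoms with large B factors suppresses their high-resolution
contribution, raises sigmaA, and therefore raises the LLG — the same
route by which coordinate-error estimates help a placed model explain
the data.  Absolute values are on this engine's own scale; only
comparisons between models on the same data are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import i0e

from .quality import ErrorProfile
from .structures import Structure, set_bfactors_from_errors

logger = logging.getLogger(__name__)

SIGMA_A_LIKELIHOOD_MAX = 0.999  # keeps the Rice log-likelihood finite

__all__ = [
    "ReflectionSet",
    "LLGResult",
    "make_reflections",
    "structure_factors",
    "simulate_observations",
    "estimate_sigma_a",
    "llg",
    "llg_with_errors",
    "cell_for",
]


@dataclass(frozen=True)
class ReflectionSet:
    """Unique reflections of a P1 orthorhombic cell (Friedel half-sphere).

    `inv_res_sq` holds s^2 = 1/d_hkl^2 per reflection (Å^-2); `f_obs`
    is None until observations are attached.
    """

    miller: np.ndarray  # (n, 3) int
    inv_res_sq: np.ndarray  # (n,) float
    cell: np.ndarray  # (3,) box lengths, Å
    f_obs: Optional[np.ndarray] = None

    def __post_init__(self):
        hkl = np.asarray(self.miller, dtype=int)
        s2 = np.asarray(self.inv_res_sq, dtype=float)
        cell = np.asarray(self.cell, dtype=float)
        if hkl.ndim != 2 or hkl.shape[1] != 3 or s2.shape != (hkl.shape[0],):
            raise ValueError("miller must be (n, 3) with matching inv_res_sq")
        if cell.shape != (3,) or np.any(cell <= 0):
            raise ValueError("cell must be three positive box lengths")
        if self.f_obs is not None:
            f = np.asarray(self.f_obs, dtype=float)
            if f.shape != s2.shape or np.any(f < 0):
                raise ValueError("f_obs must be non-negative, one per reflection")
            object.__setattr__(self, "f_obs", f)
        object.__setattr__(self, "miller", hkl)
        object.__setattr__(self, "inv_res_sq", s2)
        object.__setattr__(self, "cell", cell)

    def __len__(self) -> int:
        return self.miller.shape[0]

    def with_f_obs(self, f_obs: np.ndarray) -> "ReflectionSet":
        return replace(self, f_obs=np.asarray(f_obs, dtype=float))


@dataclass(frozen=True)
class LLGResult:
    """LLG of one model against one reflection set."""

    llg: float
    sigma_a_by_shell: np.ndarray
    n_reflections: int


def make_reflections(cell, d_min: float = 2.5, d_max: float = 20.0) -> ReflectionSet:
    """Enumerate unique reflections with d_min <= d_hkl <= d_max.

    Half-sphere convention (Friedel mates not duplicated):
    h > 0, or h = 0 and k > 0, or h = k = 0 and l > 0.
    """
    cell = np.asarray(cell, dtype=float)
    if d_min >= d_max:
        raise ValueError(f"d_min ({d_min}) must be smaller than d_max ({d_max})")
    hmax = np.floor(cell / d_min).astype(int)
    h = np.arange(-hmax[0], hmax[0] + 1)
    k = np.arange(-hmax[1], hmax[1] + 1)
    l = np.arange(-hmax[2], hmax[2] + 1)
    H, K, L = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.column_stack([H.ravel(), K.ravel(), L.ravel()])
    half = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | (
        (hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)
    )
    hkl = hkl[half]
    s2 = np.sum((hkl / cell) ** 2, axis=1)
    # relative epsilon keeps reflections sitting exactly on a resolution
    # limit (d_hkl == d_min or d_max) inside the set despite rounding
    keep = (s2 >= (1.0 - 1e-9) / d_max**2) & (s2 <= (1.0 + 1e-9) / d_min**2)
    hkl, s2 = hkl[keep], s2[keep]
    if len(hkl) == 0:
        raise ValueError(
            "no reflections in range; enlarge the cell or widen the resolution limits"
        )
    order = np.argsort(s2, kind="stable")
    return ReflectionSet(miller=hkl[order], inv_res_sq=s2[order], cell=cell)


def structure_factors(structure: Structure, reflections: ReflectionSet) -> np.ndarray:
    """Direct-summation complex structure factors with unit point scatterers.

    F(h) = sum_j exp(-B_j s^2 / 4) * exp(2 pi i h . x_frac,j)
    """
    cell = reflections.cell
    xyz = structure.coords
    if np.any(xyz < 0) or np.any(xyz >= cell):
        raise ValueError("atom outside the cell; shift the model into the box first")
    frac = xyz / cell
    phases = 2.0 * np.pi * (reflections.miller @ frac.T)  # (n_refl, n_atoms)
    dw = np.exp(-np.outer(reflections.inv_res_sq, structure.b_factors) / 4.0)
    return (dw * np.exp(1j * phases)).sum(axis=1)


def cell_for(*structures: Structure, padding: float = 10.0) -> Tuple[np.ndarray, np.ndarray]:
    """Orthorhombic box holding all structures with `padding` Å per side.

    Returns (cell lengths, translation to apply to coordinates).
    """
    all_xyz = np.vstack([s.coords for s in structures])
    lo = all_xyz.min(axis=0)
    hi = all_xyz.max(axis=0)
    cell = (hi - lo) + 2.0 * padding
    shift = padding - lo
    return cell, shift


def simulate_observations(
    target: Structure,
    reflections: ReflectionSet,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> ReflectionSet:
    """Attach synthetic amplitudes: |F(target)| with fractional Gaussian noise."""
    f = np.abs(structure_factors(target, reflections))
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f * (1.0 + noise_frac * rng.normal(size=len(f))), 0.0, None)
    return reflections.with_f_obs(f)


def _shell_slices(n: int, n_shells: int) -> List[np.ndarray]:
    """Split reflection indices (already sorted by s^2) into resolution
    shells of near-equal counts; shells below 5 reflections are merged."""
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    if n < 5 * n_shells:
        merged = max(1, n // 5)
        if merged != n_shells:
            logger.warning(
                "only %d reflections: merging %d shells into %d", n, n_shells, merged
            )
        n_shells = merged
    return np.array_split(np.arange(n), n_shells)


def estimate_sigma_a(
    f_calc: np.ndarray,
    f_obs: np.ndarray,
    inv_res_sq: np.ndarray,
    n_shells: int = 6,
) -> Tuple[np.ndarray, np.ndarray]:
    """Shell-wise sigmaA from correlation of normalized amplitudes.

    Per shell: sigmaA = clamp(0, 1, Pearson correlation of E_obs and
    E_calc), where E are amplitudes normalized to <E^2> = 1 within the
    shell.  The correlation is computed on mean-centred amplitudes:
    amplitudes are strictly positive, so an uncentred cosine similarity
    would sit near 0.8 even for unrelated structures and grossly
    overstate model quality; centring makes unrelated models score ~0.
    Returns (sigma_a per shell, shell index per reflection).
    """
    f_calc = np.abs(np.asarray(f_calc))
    f_obs = np.asarray(f_obs, dtype=float)
    s2 = np.asarray(inv_res_sq, dtype=float)
    if not (f_calc.shape == f_obs.shape == s2.shape):
        raise ValueError("f_calc, f_obs and inv_res_sq must be matched 1-D arrays")
    order = np.argsort(s2, kind="stable")
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    shells = _shell_slices(len(s2), n_shells)
    sigma = np.zeros(len(shells))
    shell_of = np.zeros(len(s2), dtype=int)
    for j, idx_sorted in enumerate(shells):
        idx = order[idx_sorted]
        shell_of[idx] = j
        eo = f_obs[idx] - f_obs[idx].mean()
        ec = f_calc[idx] - f_calc[idx].mean()
        denom = np.sqrt(np.sum(eo**2) * np.sum(ec**2))
        sigma[j] = 0.0 if denom == 0 else np.clip(np.sum(eo * ec) / denom, 0.0, 1.0)
    return sigma, shell_of


def _normalize(f: np.ndarray, shell_of: np.ndarray, n_shells: int) -> np.ndarray:
    e = np.empty_like(f, dtype=float)
    for j in range(n_shells):
        m = shell_of == j
        mean_sq = np.mean(f[m] ** 2)
        e[m] = f[m] / np.sqrt(mean_sq) if mean_sq > 0 else 0.0
    return e


def llg(
    model: Structure,
    observed: ReflectionSet,
    n_shells: int = 6,
    sigma_a: Optional[np.ndarray] = None,
) -> LLGResult:
    """Log-likelihood gain of `model` against observed amplitudes.

    Acentric Rice likelihood with shell-wise sigmaA versus the Wilson
    (sigmaA = 0) baseline; per-reflection terms cancel exactly when
    sigmaA = 0, so an uninformative model scores 0.  `sigma_a`
    optionally overrides the estimated per-shell values (same length as
    the number of shells actually formed).
    """
    if observed.f_obs is None:
        raise ValueError("reflection set has no observed amplitudes")
    f_calc = structure_factors(model, observed)
    est_sigma, shell_of = estimate_sigma_a(
        f_calc, observed.f_obs, observed.inv_res_sq, n_shells
    )
    n_formed = len(est_sigma)
    if sigma_a is not None:
        sigma_a = np.asarray(sigma_a, dtype=float)
        if sigma_a.shape != (n_formed,):
            raise ValueError(f"sigma_a override must have {n_formed} entries")
        if np.any(sigma_a < 0) or np.any(sigma_a > 1):
            raise ValueError("sigma_a values must lie in [0, 1]")
    else:
        sigma_a = est_sigma
    e_obs = _normalize(observed.f_obs, shell_of, n_formed)
    e_calc = _normalize(np.abs(f_calc), shell_of, n_formed)
    sa = np.minimum(sigma_a, SIGMA_A_LIKELIHOOD_MAX)[shell_of]
    one_m = 1.0 - sa**2
    x = 2.0 * sa * e_obs * e_calc / one_m
    # log I0 via the exponentially scaled Bessel function (overflow-safe)
    log_i0 = np.log(i0e(x)) + x
    terms = (
        -(e_obs**2 + sa**2 * e_calc**2) / one_m
        + e_obs**2
        - np.log(one_m)
        + log_i0
    )
    return LLGResult(
        llg=float(np.sum(terms)),
        sigma_a_by_shell=sigma_a,
        n_reflections=len(observed),
    )


def llg_with_errors(
    model: Structure,
    profile: ErrorProfile,
    observed: ReflectionSet,
    n_shells: int = 6,
) -> LLGResult:
    """LLG of `model` after encoding `profile` into its B factors."""
    return llg(set_bfactors_from_errors(model, profile), observed, n_shells=n_shells)
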