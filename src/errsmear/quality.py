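"""Local model-quality transforms.

The S score maps a per-residue distance deviation d (Å) to a bounded
quality in (0, 1]:

    S(d) = 1 / (1 + (d / d0)^2)

with d0 = 3.0 Å by default, which makes the transform most sensitive to
deviations around 3 Å: the 0-6 Å range maps to [0.2, 1] and everything
beyond 6 Å maps below 0.2.  The inverse transform recovers d from S,

    d(S) = d0 * sqrt(1/S - 1)

and any recovered deviation above a cap (15 Å by default) is clamped to
the cap, so very low qualities all collapse onto the same maximal error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_D0 = 3.0
DEFAULT_CAP = 15.0

__all__ = [
    "DEFAULT_D0",
    "DEFAULT_CAP",
    "ErrorProfile",
    "s_from_d",
    "d_from_s",
    "roundtrip_check",
    "global_quality",
]


def s_from_d(d, d0: float = DEFAULT_D0):
    """Quality S in (0, 1] from distance deviation d (Å).

    Strictly decreasing in d with S(0) = 1.  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any d is negative, non-finite, or d0 is not positive.
    """
    d = np.asarray(d, dtype=float)
    if d0 <= 0:
        raise ValueError(f"d0 must be positive, got {d0}")
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        raise ValueError("distance deviations must be finite and >= 0")
    out = 1.0 / (1.0 + (d / d0) ** 2)
    return float(out) if out.ndim == 0 else out


def d_from_s(s, d0: float = DEFAULT_D0, cap: float = DEFAULT_CAP):
    """Distance deviation d (Å) from quality S, capped at `cap`.

    Inverse of :func:`s_from_d` on [0, cap]; uncapped values above `cap`
    are replaced by `cap`.

    Raises
    ------
    ValueError
        If any s is outside (0, 1].
    """
    s = np.asarray(s, dtype=float)
    if d0 <= 0 or cap <= 0:
        raise ValueError("d0 and cap must be positive")
    if np.any(s <= 0) or np.any(s > 1) or not np.all(np.isfinite(s)):
        raise ValueError("quality scores must lie in (0, 1]")
    d = d0 * np.sqrt(1.0 / s - 1.0)
    d = np.minimum(d, cap)
    return float(d) if d.ndim == 0 else d


def roundtrip_check(d, d0: float = DEFAULT_D0, cap: float = DEFAULT_CAP):
    """d_from_s(s_from_d(d)): identity on [0, cap] to numerical precision."""
    return d_from_s(s_from_d(d, d0), d0, cap)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-residue error profile: deviations d (Å) and qualities s.

    `d` and `s` are parallel arrays, one entry per residue.  Built from
    either side of the transform via :meth:`from_d` / :meth:`from_s`.
    Pass ``cap=np.inf`` to :meth:`from_d` to keep raw (uncapped)
    deviations, e.g. for true superposition errors.
    """

    d: np.ndarray
    s: np.ndarray
    d0: float = DEFAULT_D0
    cap: float = DEFAULT_CAP

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        s = np.asarray(self.s, dtype=float)
        if d.shape != s.shape or d.ndim != 1:
            raise ValueError("d and s must be parallel 1-D arrays")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "s", s)

    def __len__(self) -> int:
        return self.d.shape[0]

    @classmethod
    def from_d(cls, d, d0: float = DEFAULT_D0, cap: float = DEFAULT_CAP) -> "ErrorProfile":
        d = np.minimum(np.asarray(d, dtype=float), cap)
        return cls(d=d, s=s_from_d(d, d0), d0=d0, cap=cap)

    @classmethod
    def from_s(cls, s, d0: float = DEFAULT_D0, cap: float = DEFAULT_CAP) -> "ErrorProfile":
        s = np.asarray(s, dtype=float)
        return cls(d=d_from_s(s, d0, cap), s=s, d0=d0, cap=cap)

    def capped(self, cap: float = DEFAULT_CAP) -> "ErrorProfile":
        """Profile with deviations clamped to `cap` (idempotent)."""
        return ErrorProfile.from_d(self.d, d0=self.d0, cap=cap)


def global_quality(profile: ErrorProfile) -> float:
    """Global model quality: unweighted mean of the per-residue S values."""
    if len(profile) == 0:
        raise ValueError("cannot compute global quality of an empty profile")
    return float(np.mean(profile.s))
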