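"""Minimal CA-level structure container and fixed-column PDB I/O.

Only the subset of the PDB format this pipeline needs: ATOM records,
one CA per residue by default, with the B-factor column (61-66) treated
as a first-class channel because estimated coordinate errors are
written into it before likelihood scoring.  Coordinates are stored at
full precision internally; files round-trip at PDB column precision
(3 decimals for coordinates, 2 for B factors).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional

import numpy as np

from .quality import ErrorProfile

logger = logging.getLogger(__name__)

PDB_B_MAX = 999.99  # widest value the fixed 6.2 column can hold

__all__ = [
    "AtomRecord",
    "Structure",
    "PDBParseError",
    "EmptyStructureError",
    "read_pdb",
    "write_pdb",
    "set_bfactors_from_errors",
    "bfactor_from_error",
    "read_error_tsv",
    "write_error_tsv",
]


class PDBParseError(ValueError):
    """Malformed ATOM record; message names the offending line number."""


class EmptyStructureError(ValueError):
    """No atoms (left) in a structure where at least one is required."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: 1-based residue index, name, position (Å), B factor (Å²)."""

    residue_index: int
    atom_name: str
    position: np.ndarray
    b_factor: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        if not math.isfinite(self.b_factor) or self.b_factor < 0:
            raise ValueError(f"b_factor must be finite and >= 0, got {self.b_factor}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class Structure:
    """Ordered CA-level chain: parallel arrays of indices, coords and Bs."""

    identifier: str
    residue_index: np.ndarray  # (n,) int, strictly increasing
    coords: np.ndarray  # (n, 3) float, Å
    b_factors: np.ndarray  # (n,) float, Å², >= 0
    atom_names: tuple = ()

    def __post_init__(self):
        idx = np.asarray(self.residue_index, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        b = np.asarray(self.b_factors, dtype=float)
        n = idx.shape[0]
        if xyz.shape != (n, 3) or b.shape != (n,):
            raise ValueError("residue_index, coords and b_factors lengths disagree")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        if np.any(b < 0) or not np.all(np.isfinite(b)):
            raise ValueError("B factors must be finite and >= 0")
        if n > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("residue_index must be strictly increasing")
        names = self.atom_names or tuple(["CA"] * n)
        if len(names) != n:
            raise ValueError("atom_names length disagrees with residue count")
        object.__setattr__(self, "residue_index", idx)
        object.__setattr__(self, "coords", xyz)
        object.__setattr__(self, "b_factors", b)
        object.__setattr__(self, "atom_names", tuple(names))

    def __len__(self) -> int:
        return self.residue_index.shape[0]

    def __iter__(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield AtomRecord(
                residue_index=int(self.residue_index[i]),
                atom_name=self.atom_names[i],
                position=self.coords[i],
                b_factor=float(self.b_factors[i]),
            )

    @classmethod
    def from_coords(
        cls,
        coords: np.ndarray,
        identifier: str = "model",
        b_factors: Optional[np.ndarray] = None,
    ) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
        if b_factors is None:
            b_factors = np.zeros(n)
        return cls(
            identifier=identifier,
            residue_index=np.arange(1, n + 1),
            coords=coords,
            b_factors=np.asarray(b_factors, dtype=float),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def with_bfactors(self, b_factors: np.ndarray) -> "Structure":
        return replace(self, b_factors=np.asarray(b_factors, dtype=float))


def _parse_field(raw: str, lineno: int, name: str, kind: type):
    try:
        return kind(raw)
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: could not parse {name} field {raw.strip()!r}"
        ) from exc


def read_pdb(path, atom_filter: Iterable[str] = ("CA",)) -> Structure:
    """Read ATOM records from a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path : path-like
        PDB file containing fixed-column ATOM records.
    atom_filter : iterable of str
        Atom names to keep (default: CA only).  Pass ``None`` to keep all.

    Raises
    ------
    PDBParseError
        On a malformed ATOM line (message names the line number).
    EmptyStructureError
        If no atoms survive the filter.
    """
    path = Path(path)
    keep = None if atom_filter is None else {a.strip().upper() for a in atom_filter}
    indices, names, coords, bs = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("ATOM"):
                continue
            if len(line.rstrip("\n")) < 66:
                raise PDBParseError(f"line {lineno}: ATOM record shorter than 66 columns")
            name = line[12:16].strip().upper()
            if keep is not None and name not in keep:
                continue
            resseq = _parse_field(line[22:26], lineno, "residue number", int)
            x = _parse_field(line[30:38], lineno, "x coordinate", float)
            y = _parse_field(line[38:46], lineno, "y coordinate", float)
            z = _parse_field(line[46:54], lineno, "z coordinate", float)
            b = _parse_field(line[60:66], lineno, "B factor", float)
            indices.append(resseq)
            names.append(name)
            coords.append((x, y, z))
            bs.append(b)
    if not indices:
        raise EmptyStructureError(f"no atoms in {path} after filtering to {sorted(keep) if keep else 'all'}")
    return Structure(
        identifier=path.stem,
        residue_index=np.asarray(indices),
        coords=np.asarray(coords),
        b_factors=np.asarray(bs),
        atom_names=tuple(names),
    )


def write_pdb(structure: Structure, path, on_overflow: str = "clamp") -> None:
    """Write a structure as fixed-column PDB ATOM records.

    B factors go into columns 61-66 with 2 decimals, occupancy is 1.00.
    Values above 999.99 overflow the field: with ``on_overflow="clamp"``
    (default) they are clamped to 999.99 with a logged warning — the
    in-memory pipeline keeps the numeric value, only file output is
    affected; with ``on_overflow="error"`` the write is refused.
    """
    if len(structure) == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    if on_overflow not in ("clamp", "error"):
        raise ValueError(f"on_overflow must be 'clamp' or 'error', got {on_overflow!r}")
    over = structure.b_factors > PDB_B_MAX
    if np.any(over):
        if on_overflow == "error":
            raise ValueError(
                f"{int(over.sum())} B factor(s) exceed the PDB field maximum {PDB_B_MAX}"
            )
        logger.warning(
            "clamping %d B factor(s) above %.2f to fit the PDB field",
            int(over.sum()),
            PDB_B_MAX,
        )
    lines = []
    for serial, atom in enumerate(structure, start=1):
        b = min(atom.b_factor, PDB_B_MAX)
        name = atom.atom_name
        # PDB convention: 1-3 char atom names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = atom.position
        lines.append(
            f"ATOM  {serial:5d} {name_field}{'':1s}ALA A{atom.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}          {'C':>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def bfactor_from_error(d) -> np.ndarray:
    """Default error→B policy: B = 8·pi²·d²/3 (Å²).

    The Debye-Waller convention for an isotropic total RMS coordinate
    error d, with per-axis mean-square displacement <u²> = d²/3.
    """
    d = np.asarray(d, dtype=float)
    return (8.0 * np.pi**2 / 3.0) * d**2


def set_bfactors_from_errors(
    structure: Structure,
    profile: ErrorProfile,
    mapping: Callable[[np.ndarray], np.ndarray] = bfactor_from_error,
) -> Structure:
    """Return a copy of `structure` with B factors encoding the error profile.

    Residue i gets B = mapping(d_i); the default policy is
    :func:`bfactor_from_error`.  The input structure is not modified.
    """
    if len(profile) != len(structure):
        raise ValueError(
            f"profile length {len(profile)} != structure residue count {len(structure)}"
        )
    return structure.with_bfactors(mapping(profile.d))


def read_error_tsv(path) -> ErrorProfile:
    """Two-column TSV (residue_index, d_i in Å) → capped error profile."""
    data = np.loadtxt(path, delimiter="\t", ndmin=2, comments="#")
    if data.shape[1] < 2:
        raise ValueError("error TSV needs two columns: residue_index and d")
    order = np.argsort(data[:, 0])
    return ErrorProfile.from_d(data[order, 1])


def write_error_tsv(profile: ErrorProfile, path) -> None:
    rows = np.column_stack([np.arange(1, len(profile) + 1), profile.d])
    np.savetxt(path, rows, delimiter="\t", fmt=("%d", "%.6f"), header="residue_index\td")
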