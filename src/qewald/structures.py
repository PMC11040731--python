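"""Atomic-structure containers, extended-XYZ I/O and reproducible splits.

Units are fixed package-wide: coordinates in angstrom, energies in
kcal/mol, charges in elementary-charge units.  The extended-XYZ dialect
supported here is the common comment-line ``key=value`` one::

    2
    charge=0 energy=-1.5 config_id=dimer
    H 0.0 0.0 0.0
    H 0.0 0.0 0.74

A missing ``charge`` key means a neutral system (Q=0), matching the
convention of data sets of neutral closed-shell complexes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomicStructure",
    "ConformerEnsemble",
    "DatasetSplit",
    "SYMBOL_TO_Z",
    "Z_TO_SYMBOL",
    "read_extxyz",
    "write_extxyz",
    "random_split",
    "group_into_ensembles",
]

# a modest periodic table is plenty for organometallic clusters
_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe"
).split()
SYMBOL_TO_Z = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}


class ExtXYZParseError(ValueError):
    """Malformed extended-XYZ content, reporting frame and line."""


@dataclass
class AtomicStructure:
    """One molecular geometry: elements, coordinates, total charge, label.

    Parameters
    ----------
    elements : sequence of int
        Atomic numbers Z_i, positive integers.
    coords : (N, 3) array
        Cartesian positions in angstrom.
    total_charge : int
        Total charge Q in elementary-charge units.
    energy : float, optional
        Reference total energy in kcal/mol.
    struct_id, config_id : str, optional
        Free-form identifier and configuration (bonding-topology) tag.
    """

    elements: np.ndarray
    coords: np.ndarray
    total_charge: int = 0
    energy: float | None = None
    struct_id: str | None = None
    config_id: str | None = None

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.elements.ndim != 1 or np.any(self.elements <= 0):
            raise ValueError("elements must be a 1-D sequence of positive integers")
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.total_charge != int(self.total_charge):
            raise ValueError("total_charge must be an integer")
        self.total_charge = int(self.total_charge)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "AtomicStructure":
        return AtomicStructure(
            self.elements.copy(),
            self.coords.copy(),
            self.total_charge,
            self.energy,
            self.struct_id,
            self.config_id,
        )


@dataclass
class ConformerEnsemble:
    """Conformers sharing one configuration (same atoms, same total charge)."""

    configuration_id: str
    members: list[AtomicStructure] = field(default_factory=list)

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("an ensemble needs at least one member")
        ref = self.members[0]
        for m in self.members[1:]:
            if not np.array_equal(m.elements, ref.elements):
                raise ValueError("ensemble members must share the element sequence")
            if m.total_charge != ref.total_charge:
                raise ValueError("ensemble members must share the total charge")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test index lists covering 0..n-1."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=np.int64)
        self.val_idx = np.asarray(self.val_idx, dtype=np.int64)
        self.test_idx = np.asarray(self.test_idx, dtype=np.int64)
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        n = len(all_idx)
        if len(np.unique(all_idx)) != n or (n and not np.array_equal(
            np.sort(all_idx), np.arange(n)
        )):
            raise ValueError("split indices must partition 0..n-1")


_KEYVAL_RE = re.compile(r'(\w+)=("(?:[^"]*)"|\S+)')


def _parse_comment(line: str) -> dict[str, str]:
    out = {}
    for key, val in _KEYVAL_RE.findall(line):
        out[key] = val.strip('"')
    return out


def read_extxyz(path: str | Path) -> list[AtomicStructure]:
    """Read every frame of an extended-XYZ file.

    Raises
    ------
    ExtXYZParseError
        On atom-count/line mismatches or unknown element symbols; the
        message names the offending frame and line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    structures: list[AtomicStructure] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ExtXYZParseError(
                f"frame {frame}, line {i + 1}: expected atom count, got "
                f"{lines[i]!r}"
            ) from exc
        if i + 2 + n > len(lines):
            raise ExtXYZParseError(
                f"frame {frame}, line {i + 1}: header declares {n} atoms but "
                f"file ends after {max(len(lines) - i - 2, 0)} atom lines"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        props = _parse_comment(comment)
        elements = []
        coords = []
        for j in range(n):
            ln = i + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ExtXYZParseError(
                    f"frame {frame}, line {ln + 1}: expected 'symbol x y z', "
                    f"got {lines[ln]!r}"
                )
            sym = parts[0]
            if sym not in SYMBOL_TO_Z:
                raise ExtXYZParseError(
                    f"frame {frame}, line {ln + 1}: unknown element symbol "
                    f"{sym!r}"
                )
            elements.append(SYMBOL_TO_Z[sym])
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError as exc:
                raise ExtXYZParseError(
                    f"frame {frame}, line {ln + 1}: non-numeric coordinate in "
                    f"{lines[ln]!r}"
                ) from exc
        structures.append(
            AtomicStructure(
                elements=np.array(elements, dtype=np.int64),
                coords=np.array(coords, dtype=np.float64).reshape(n, 3),
                total_charge=int(props["charge"]) if "charge" in props else 0,
                energy=float(props["energy"]) if "energy" in props else None,
                struct_id=props.get("id"),
                config_id=props.get("config_id"),
            )
        )
        i += 2 + n
        frame += 1
    return structures


def write_extxyz(structures: Iterable[AtomicStructure], path: str | Path) -> None:
    """Write structures as extended-XYZ; round-trips through read_extxyz."""
    path = Path(path)
    chunks: list[str] = []
    for s in structures:
        props = []
        if s.total_charge != 0:
            props.append(f"charge={s.total_charge}")
        if s.energy is not None:
            props.append(f"energy={s.energy!r}")
        if s.struct_id is not None:
            props.append(f'id="{s.struct_id}"')
        if s.config_id is not None:
            props.append(f'config_id="{s.config_id}"')
        chunks.append(str(s.n_atoms))
        chunks.append(" ".join(props))
        for z, (x, y, zc) in zip(s.elements, s.coords):
            chunks.append(f"{Z_TO_SYMBOL[int(z)]} {x:.14e} {y:.14e} {zc:.14e}")
    path.write_text("\n".join(chunks) + ("\n" if chunks else ""))


def random_split(
    n: int, fractions: Sequence[float], seed: int
) -> DatasetSplit:
    """Random disjoint train/val/test split of ``n`` items.

    Sizes are ``round(f * n)`` for the validation and test fractions, with
    the remainder assigned to train; identical seeds give identical splits.
    """
    if n < 3:
        raise ValueError("need n >= 3 to split three ways")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be 3 nonnegative reals")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("fractions leave no room for a training set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return DatasetSplit(
        train_idx=perm[:n_train],
        val_idx=perm[n_train : n_train + n_val],
        test_idx=perm[n_train + n_val :],
    )


def group_into_ensembles(structures: Iterable[AtomicStructure]) -> list[ConformerEnsemble]:
    """Group frames by their config_id tag, preserving first-seen order."""
    groups: dict[str, list[AtomicStructure]] = {}
    order: list[str] = []
    for k, s in enumerate(structures):
        cid = s.config_id if s.config_id is not None else f"__untagged_{k}"
        if cid not in groups:
            groups[cid] = []
            order.append(cid)
        groups[cid].append(s)
    return [ConformerEnsemble(cid, groups[cid]) for cid in order]
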