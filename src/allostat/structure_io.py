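"""Annotated structures, trajectory ensembles and atom selection.

Internal length unit is the nanometre throughout the package; PDB files
(which store Ångström) are converted on read and write.  Two on-disk
formats are supported:

* a fixed-width PDB subset (``ATOM``/``HETATM``/``MODEL``/``ENDMDL``,
  wwPDB v3.3 columns), parsed and written through :mod:`biotite`;
* a plain-text XYZ trajectory dialect — per frame: a line with the atom
  count, a line ``t=<time in ns>``, then one ``element x y z`` line per
  atom with coordinates in nm.

Residue ranges are 1-based and inclusive on both ends, matching
crystallographic numbering (e.g. an SRM-helix annotation covering
residues 143–153 selects eleven residues).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    AnnotationError,
    EmptyInputError,
    FormatError,
    ParseError,
    SelectionError,
)

ANGSTROM_PER_NM = 10.0

#: Backbone atom names excluded by the ``side_chain`` filter.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: Region roles the analysis layer knows about.
KNOWN_ROLES = ("srm_helix", "ezh2_loop", "ligand", "reader", "enzyme")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity labels plus a single-frame coordinate in nm."""

    atom_name: str
    element: str
    chain_id: str
    residue_number: int
    residue_name: str
    coordinates: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")


@dataclass(frozen=True)
class Region:
    """A named structural role: one chain and an inclusive residue range."""

    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(f"region start {self.start} > end {self.end}")


class AnnotatedStructure:
    """Ordered atoms plus named region annotations.

    Parameters
    ----------
    atoms:
        Atom records in file/build order.
    regions:
        Mapping from role (``srm_helix``, ``ezh2_loop``, ``ligand``,
        ``reader``, ``enzyme`` or user-defined) to :class:`Region`.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        regions: Mapping[str, Region] | None = None,
    ) -> None:
        self.atoms: list[AtomRecord] = list(atoms)
        if not self.atoms:
            raise EmptyInputError("structure has no atoms")
        keys = [(a.chain_id, a.residue_number, a.atom_name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise AnnotationError(f"duplicate atom key {dup} in structure")
        self._coords = np.array([a.coordinates for a in self.atoms], dtype=float)
        self.regions: dict[str, Region] = {}
        for role, region in (regions or {}).items():
            self.annotate(role, region)

    # -- basic container API -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in nm (a copy)."""
        return self._coords.copy()

    @property
    def chain_ids(self) -> np.ndarray:
        return np.array([a.chain_id for a in self.atoms])

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.array([a.residue_number for a in self.atoms], dtype=int)

    @property
    def residue_names(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms])

    @property
    def atom_names(self) -> np.ndarray:
        return np.array([a.atom_name for a in self.atoms])

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "AnnotatedStructure":
        """Copy of this structure with replaced coordinates (nm)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise FormatError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, coordinates=tuple(c)) for a, c in zip(self.atoms, coords)]
        return AnnotatedStructure(atoms, self.regions)

    # -- annotations ---------------------------------------------------------

    def annotate(self, role: str, region: Region) -> None:
        """Attach a named region; it must select at least one atom."""
        n = len(select_atoms(self, region.chain_id, (region.start, region.end), "all"))
        if n == 0:  # pragma: no cover - select_atoms raises first
            raise AnnotationError(f"region {role!r} selects no atoms")
        self.regions[role] = region

    def region_indices(self, role: str, atom_filter="all") -> np.ndarray:
        """Atom indices of an annotated region under an atom filter."""
        if role not in self.regions:
            raise AnnotationError(
                f"role {role!r} is not annotated (have {sorted(self.regions)})"
            )
        r = self.regions[role]
        return select_atoms(self, r.chain_id, (r.start, r.end), atom_filter)


@dataclass
class TrajectoryEnsemble:
    """Ordered frames sharing one topology.

    ``truth_labels`` is optional generator ground truth (per-frame
    ``bound`` / ``helix_folded`` flags and sampled distances) used only
    for validating analysis operations — real trajectories carry none.
    """

    topology: AnnotatedStructure
    frames: np.ndarray  # (n_frames, n_atoms, 3) nm
    times: np.ndarray  # (n_frames,) ns
    truth_labels: "object | None" = None  # pandas.DataFrame when present

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise FormatError(f"frames must be (n, atoms, 3); got {self.frames.shape}")
        if self.frames.shape[0] == 0:
            raise EmptyInputError("ensemble has zero frames")
        if self.frames.shape[1] != len(self.topology):
            raise FormatError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{len(self.topology)}"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise FormatError("times length does not match frame count")
        if self.frames.shape[0] > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> AnnotatedStructure:
        """Topology with the coordinates of frame ``i``."""
        return self.topology.with_coords(self.frames[i])

    def subset(self, keep: np.ndarray) -> "TrajectoryEnsemble":
        """Ensemble restricted to a boolean or index frame mask (order kept)."""
        keep = np.asarray(keep)
        labels = None
        if self.truth_labels is not None:
            labels = self.truth_labels.iloc[np.flatnonzero(keep) if keep.dtype == bool else keep]
            labels = labels.reset_index(drop=True)
        return TrajectoryEnsemble(self.topology, self.frames[keep], self.times[keep], labels)


# -- selection ----------------------------------------------------------------


def select_atoms(
    structure: AnnotatedStructure,
    chain: str,
    residues: tuple[int, int] | None = None,
    atom_filter="all",
) -> np.ndarray:
    """Deterministic, order-preserving atom index selection.

    Parameters
    ----------
    chain:
        Chain label; must exist in the structure.
    residues:
        Inclusive ``(start, end)`` residue-number range, or ``None`` for
        the whole chain.
    atom_filter:
        ``"all"``, ``"heavy"`` (element != H), ``"side_chain"`` (heavy
        atoms excluding backbone names N/CA/C/O), or an iterable of atom
        names to keep.
    """
    chains = structure.chain_ids
    if chain not in chains:
        raise SelectionError(f"chain {chain!r} not present (have {sorted(set(chains))})")
    mask = chains == chain
    if residues is not None:
        start, end = residues
        resnum = structure.residue_numbers
        mask &= (resnum >= start) & (resnum <= end)
    if isinstance(atom_filter, str):
        if atom_filter == "all":
            pass
        elif atom_filter == "heavy":
            mask &= structure.elements != "H"
        elif atom_filter == "side_chain":
            mask &= structure.elements != "H"
            mask &= ~np.isin(structure.atom_names, sorted(BACKBONE_NAMES))
        else:
            raise SelectionError(f"unknown atom filter {atom_filter!r}")
    else:
        mask &= np.isin(structure.atom_names, sorted(set(atom_filter)))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(
            f"empty selection: chain {chain!r}, residues {residues}, filter {atom_filter!r}"
        )
    return idx


# -- region config -------------------------------------------------------------


def load_regions(path: str | Path) -> dict[str, Region]:
    """Read a YAML/JSON mapping ``role -> {chain, start, end}``."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise AnnotationError(f"region file {path} must map roles to chain/start/end")
    out = {}
    for role, spec in data.items():
        try:
            out[role] = Region(str(spec["chain"]), int(spec["start"]), int(spec["end"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationError(f"bad region spec for role {role!r}: {spec!r}") from exc
    return out


# -- PDB I/O -------------------------------------------------------------------


def _prevalidate_pdb(path: Path) -> None:
    """Light line scan so parse errors carry a line number.

    Rejects insertion codes and blank chain identifiers up front; the
    heavy lifting (fixed-width fields, models) is done by biotite.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}, line {lineno}: truncated {rec} record")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise ParseError(
                    f"{path}, line {lineno}: malformed coordinate/residue fields"
                ) from exc
            if line[21].strip() == "":
                raise AnnotationError(f"{path}, line {lineno}: missing chain id")
            if line[26].strip():
                raise AnnotationError(
                    f"{path}, line {lineno}: insertion codes are not supported"
                )


def _atom_array_to_records(arr: struc.AtomArray) -> list[AtomRecord]:
    coords_nm = np.asarray(arr.coord, dtype=float) / ANGSTROM_PER_NM
    return [
        AtomRecord(
            atom_name=str(arr.atom_name[i]),
            element=str(arr.element[i]).capitalize(),
            chain_id=str(arr.chain_id[i]),
            residue_number=int(arr.res_id[i]),
            residue_name=str(arr.res_name[i]),
            coordinates=tuple(coords_nm[i]),
        )
        for i in range(arr.array_length())
    ]


def _records_to_atom_array(structure: AnnotatedStructure, coords_nm: np.ndarray) -> struc.AtomArray:
    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords_nm, dtype=float) * ANGSTROM_PER_NM
    arr.chain_id = structure.chain_ids
    arr.res_id = structure.residue_numbers
    arr.res_name = structure.residue_names
    arr.atom_name = structure.atom_names
    arr.element = np.char.upper(structure.elements)
    arr.hetero = np.array([a.residue_name not in _AMINO3 for a in structure.atoms])
    return arr


_AMINO3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".xyz", ".xyztraj"):
        return "xyz"
    raise FormatError(f"cannot infer format from suffix {suffix!r}; pass format explicitly")


def read_structure(path: str | Path, format: str | None = None) -> AnnotatedStructure:
    """Read a single-frame structure (first model/frame of a multi-frame file).

    PDB coordinates are converted Å → nm; region annotations are not
    stored in either format and must be attached afterwards (see
    :func:`load_regions` and :meth:`AnnotatedStructure.annotate`).
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        _prevalidate_pdb(path)
        try:
            arr = PDBFile.read(str(path)).get_structure(model=1, altloc="first")
        except Exception as exc:  # biotite raises assorted error types
            raise ParseError(f"{path}: {exc}") from exc
        return AnnotatedStructure(_atom_array_to_records(arr))
    if fmt == "xyz":
        ens = read_ensemble(path, format="xyz")
        return ens.frame_structure(0)
    raise FormatError(f"unknown structure format {fmt!r}")


def write_structure(path: str | Path, structure: AnnotatedStructure, format: str | None = None) -> None:
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        pdb = PDBFile()
        pdb.set_structure(_records_to_atom_array(structure, structure.coords))
        pdb.write(str(path))
    elif fmt == "xyz":
        ens = TrajectoryEnsemble(structure, structure.coords[None], np.array([0.0]))
        write_ensemble(path, ens, format="xyz")
    else:
        raise FormatError(f"unknown structure format {fmt!r}")


# -- ensemble I/O --------------------------------------------------------------


def read_ensemble(
    path: str | Path,
    format: str | None = None,
    topology: AnnotatedStructure | None = None,
    times: Sequence[float] | None = None,
) -> TrajectoryEnsemble:
    """Read a multi-model PDB or XYZ-dialect trajectory.

    Multi-model PDB carries no time stamps; frames are assigned 0, 1, 2,
    ... ns unless ``times`` is given.  For XYZ input, which records only
    elements, a ``topology`` read from a matching PDB restores full atom
    annotations (atom counts and elements must agree).
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        _prevalidate_pdb(path)
        try:
            stack = PDBFile.read(str(path)).get_structure(model=None, altloc="first")
        except Exception as exc:
            raise FormatError(f"{path}: {exc}") from exc
        if isinstance(stack, struc.AtomArray):  # single MODEL
            stack = struc.stack([stack])
        if stack.stack_depth() == 0:
            raise EmptyInputError(f"{path}: no frames")
        first = stack[0]
        topo = topology or AnnotatedStructure(_atom_array_to_records(first))
        if len(topo) != first.array_length():
            raise FormatError(
                f"{path}: topology atom count {len(topo)} != file atom count "
                f"{first.array_length()}"
            )
        frames = np.asarray(stack.coord, dtype=float) / ANGSTROM_PER_NM
        t = np.asarray(times, float) if times is not None else np.arange(len(frames), dtype=float)
        return TrajectoryEnsemble(topo, frames, t)
    if fmt == "xyz":
        return _read_xyz(path, topology)
    raise FormatError(f"unknown ensemble format {fmt!r}")


def _read_xyz(path: Path, topology: AnnotatedStructure | None) -> TrajectoryEnsemble:
    frames: list[np.ndarray] = []
    times: list[float] = []
    elements_first: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, lineno = 0, 0
    # skip leading blank lines
    while i < len(lines) and not lines[i].strip():
        i += 1
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}, line {i + 1}: expected atom count") from exc
        if i + 1 >= len(lines) or not lines[i + 1].strip().startswith("t="):
            raise ParseError(f"{path}, line {i + 2}: expected 't=<ns>' header")
        try:
            t = float(lines[i + 1].strip()[2:])
        except ValueError as exc:
            raise ParseError(f"{path}, line {i + 2}: bad time value") from exc
        coords = np.empty((natoms, 3))
        elems = []
        for j in range(natoms):
            k = i + 2 + j
            if k >= len(lines):
                raise FormatError(f"{path}: truncated frame at line {k + 1}")
            parts = lines[k].split()
            if len(parts) != 4:
                raise ParseError(f"{path}, line {k + 1}: expected 'element x y z'")
            elems.append(parts[0])
            try:
                coords[j] = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}, line {k + 1}: bad coordinate") from exc
        if frames and len(elems) != len(elements_first):
            raise FormatError(
                f"{path}: frame {len(frames)} has {len(elems)} atoms, "
                f"expected {len(elements_first)}"
            )
        if not frames:
            elements_first = elems
        frames.append(coords)
        times.append(t)
        i += 2 + natoms
    if not frames:
        raise EmptyInputError(f"{path}: no frames")
    if topology is not None:
        if len(topology) != len(elements_first):
            raise FormatError(
                f"{path}: topology atom count {len(topology)} != {len(elements_first)}"
            )
        topo = topology.with_coords(frames[0])
    else:
        atoms = [
            AtomRecord(f"{el}{j + 1}", el.capitalize(), "A", j + 1, "UNK", tuple(frames[0][j]))
            for j, el in enumerate(elements_first)
        ]
        topo = AnnotatedStructure(atoms)
    return TrajectoryEnsemble(topo, np.array(frames), np.array(times))


def write_ensemble(path: str | Path, ensemble: TrajectoryEnsemble, format: str | None = None) -> None:
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        arrays = [
            _records_to_atom_array(ensemble.topology, ensemble.frames[i])
            for i in range(ensemble.n_frames)
        ]
        pdb = PDBFile()
        pdb.set_structure(struc.stack(arrays))
        pdb.write(str(path))
    elif fmt == "xyz":
        elements = ensemble.topology.elements
        with open(path, "w") as fh:
            for i in range(ensemble.n_frames):
                fh.write(f"{len(elements)}\n")
                fh.write(f"t={ensemble.times[i]:.6f}\n")
                for el, (x, y, z) in zip(elements, ensemble.frames[i]):
                    fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
    else:
        raise FormatError(f"unknown ensemble format {fmt!r}")
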