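"""Per-frame geometry: superposition, region RMSD, contact maps, frame filtering.

The unbound-frame filter implements the trajectory pre-processing step
used throughout the mechanism analysis: a frame is discarded when the
ligand's RMSD from its reference (crystal-like) pose — after rigid
superposition of the receptor — is strictly greater than 0.8 nm.
Contact maps are frame-averaged minimum heavy-atom residue–residue
distances between two chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CorrespondenceError,
    EmptyInputError,
    SelectionError,
    SuperpositionError,
)
from .structure_io import (
    AnnotatedStructure,
    BACKBONE_NAMES,
    TrajectoryEnsemble,
    select_atoms,
)

DEFAULT_UNBOUND_THRESHOLD_NM = 0.8


# -- rigid superposition ------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping mobile coordinates onto a reference."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit (Kabsch) of ``mobile`` onto ``reference``.

    Returns the transform minimizing the RMSD between the transformed
    mobile coordinates and the reference.  Requires at least three
    non-collinear atom pairs in 1:1 correspondence.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise SuperpositionError(
            f"shape mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise SuperpositionError("superposition needs >= 3 atom pairs of shape (n, 3)")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, s, vt = np.linalg.svd(h)
    # collinear (rank < 2) point sets leave a rotation dof undetermined
    scale = max(s[0], np.linalg.norm(mobile - cm) ** 2, 1.0)
    if s[1] <= 1e-12 * scale:
        raise SuperpositionError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    return RigidTransform(rot, trans)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain root-mean-square deviation between paired coordinates (no fitting)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# -- region RMSD --------------------------------------------------------------


@dataclass
class RmsdSeries:
    """Per-frame RMSD (nm) of a measured region after fitting on another."""

    values: np.ndarray
    region_role: str
    fit_region_role: str
    times: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def mad(self) -> float:
        med = np.median(self.values)
        return float(np.median(np.abs(self.values - med)))


def _matched_indices(
    ensemble: TrajectoryEnsemble,
    reference: AnnotatedStructure,
    role: str,
    atom_filter,
) -> tuple[np.ndarray, np.ndarray]:
    idx_t = ensemble.topology.region_indices(role, atom_filter)
    idx_r = reference.region_indices(role, atom_filter)
    if idx_t.size != idx_r.size:
        raise CorrespondenceError(
            f"region {role!r}: ensemble selects {idx_t.size} atoms, "
            f"reference selects {idx_r.size}"
        )
    names_t = ensemble.topology.atom_names[idx_t]
    names_r = reference.atom_names[idx_r]
    if not np.array_equal(names_t, names_r):
        raise CorrespondenceError(f"region {role!r}: atom names differ between "
                                  "ensemble topology and reference")
    return idx_t, idx_r


def region_rmsd(
    ensemble: TrajectoryEnsemble,
    reference: AnnotatedStructure,
    fit_role: str,
    measure_role: str,
    atom_filter=("CA",),
    fit_filter=tuple(sorted(BACKBONE_NAMES)),
) -> RmsdSeries:
    """Per-frame region RMSD against a reference structure.

    Each frame is superposed onto the reference using the ``fit_role``
    atoms (backbone by default), then the RMSD is measured over the
    ``measure_role`` atoms without refitting.  The default measure
    filter is CA-only, the conventional choice for helix fold/unfold
    monitoring; pass ``"heavy"`` for all-heavy-atom RMSD.
    """
    if ensemble.n_frames == 0:
        raise EmptyInputError("ensemble has no frames")
    fit_t, fit_r = _matched_indices(ensemble, reference, fit_role, fit_filter)
    mea_t, mea_r = _matched_indices(ensemble, reference, measure_role, atom_filter)
    ref_fit = reference.coords[fit_r]
    ref_mea = reference.coords[mea_r]
    out = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        tf = superpose(ensemble.frames[i][fit_t], ref_fit)
        out[i] = rmsd(tf.apply(ensemble.frames[i][mea_t]), ref_mea)
    return RmsdSeries(out, measure_role, fit_role, ensemble.times.copy())


# -- unbound-frame filter -----------------------------------------------------


@dataclass
class FrameMask:
    """Kept/removed flags from the unbound-ligand filter."""

    kept: np.ndarray  # (n_frames,) bool
    threshold_nm: float
    reference_id: str
    ligand_rmsd_nm: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def n_removed(self) -> int:
        return int((~self.kept).sum())

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("frame_index,kept\n")
            for i, k in enumerate(self.kept):
                fh.write(f"{i},{int(k)}\n")


def _receptor_fit_indices(structure: AnnotatedStructure) -> np.ndarray:
    """Backbone atoms of the enzyme and reader regions, in topology order."""
    parts = []
    for role in ("enzyme", "reader"):
        if role in structure.regions:
            parts.append(structure.region_indices(role, tuple(sorted(BACKBONE_NAMES))))
    if not parts:
        raise SelectionError("filter requires 'enzyme' and/or 'reader' region annotations")
    return np.unique(np.concatenate(parts))


def ligand_rmsd_series(
    ensemble: TrajectoryEnsemble, reference: AnnotatedStructure
) -> np.ndarray:
    """Per-frame ligand heavy-atom RMSD from the reference pose.

    Frames are superposed on the receptor (enzyme + reader backbone)
    before measuring the ligand, so translation of the whole complex
    does not register as unbinding.
    """
    fit_t = _receptor_fit_indices(ensemble.topology)
    fit_r = _receptor_fit_indices(reference)
    if fit_t.size != fit_r.size:
        raise CorrespondenceError("receptor fit selections differ in size")
    lig_t = ensemble.topology.region_indices("ligand", "heavy")
    lig_r = reference.region_indices("ligand", "heavy")
    if lig_t.size != lig_r.size:
        raise CorrespondenceError("ligand selections differ in size")
    ref_fit = reference.coords[fit_r]
    ref_lig = reference.coords[lig_r]
    out = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        tf = superpose(ensemble.frames[i][fit_t], ref_fit)
        out[i] = rmsd(tf.apply(ensemble.frames[i][lig_t]), ref_lig)
    return out


def filter_unbound_frames(
    ensemble: TrajectoryEnsemble,
    reference: AnnotatedStructure,
    threshold_nm: float = DEFAULT_UNBOUND_THRESHOLD_NM,
    reference_id: str = "reference",
) -> tuple[TrajectoryEnsemble | None, FrameMask]:
    """Drop frames whose ligand RMSD exceeds ``threshold_nm`` (strictly).

    A frame at exactly the threshold is kept.  Returns the filtered
    ensemble (frame order and times preserved) and the frame mask.  If
    every frame is removed the ensemble slot is ``None`` and a warning
    is emitted; downstream operations reject it.
    """
    lig_rmsd = ligand_rmsd_series(ensemble, reference)
    kept = lig_rmsd <= threshold_nm
    mask = FrameMask(kept, threshold_nm, reference_id, lig_rmsd)
    if not kept.any():
        warnings.warn("all frames removed by the unbound-ligand filter", stacklevel=2)
        return None, mask
    return ensemble.subset(kept), mask


# -- distances and contact maps ----------------------------------------------


def min_residue_distance(frame: np.ndarray, atoms_a: np.ndarray, atoms_b: np.ndarray) -> float:
    """Minimum Euclidean distance over all cross pairs of two atom sets (nm)."""
    atoms_a = np.asarray(atoms_a, dtype=int)
    atoms_b = np.asarray(atoms_b, dtype=int)
    if atoms_a.size == 0 or atoms_b.size == 0:
        raise SelectionError("both atom sets must be non-empty")
    if np.intersect1d(atoms_a, atoms_b).size:
        raise SelectionError("atom sets overlap")
    diff = frame[atoms_a][:, None, :] - frame[atoms_b][None, :, :]
    return float(np.sqrt(np.min(np.sum(diff**2, axis=-1))))


@dataclass
class ContactMatrix:
    """Residues-of-A × residues-of-B grid of frame-averaged minimum distances (nm)."""

    rows: list[str]
    cols: list[str]
    values: np.ndarray
    n_frames_used: int

    def argmin(self) -> tuple[str, str]:
        i, j = np.unravel_index(np.argmin(self.values), self.values.shape)
        return self.rows[i], self.cols[j]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\t" + "\t".join(self.cols) + "\n")
            for label, row in zip(self.rows, self.values):
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    def plot(self, path: str | Path, title: str = "Average minimum residue-residue distance (nm)") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + 0.4 * len(self.cols), 1 + 0.4 * len(self.rows)))
        im = ax.imshow(self.values, cmap="viridis_r", aspect="auto")
        ax.set_xticks(range(len(self.cols)), self.cols, rotation=90, fontsize=7)
        ax.set_yticks(range(len(self.rows)), self.rows, fontsize=7)
        fig.colorbar(im, ax=ax, label="distance (nm)")
        ax.set_title(title, fontsize=9)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _residue_blocks(structure: AnnotatedStructure, chain: str, residues: tuple[int, int], atom_filter):
    """Per-residue atom index arrays and labels, in residue-number order."""
    idx = select_atoms(structure, chain, residues, atom_filter)
    resnum = structure.residue_numbers[idx]
    resname = structure.residue_names[idx]
    blocks, labels = [], []
    for rn in sorted(set(resnum.tolist())):
        sel = idx[resnum == rn]
        blocks.append(sel)
        labels.append(f"{resname[resnum == rn][0]}{rn}")
    return blocks, labels


def contact_map(
    ensemble: TrajectoryEnsemble,
    chain_a: str,
    range_a: tuple[int, int],
    chain_b: str,
    range_b: tuple[int, int],
    atom_filter="heavy",
) -> ContactMatrix:
    """Frame-averaged minimum residue–residue distance map between two chains.

    Entry (i, j) is the arithmetic mean over frames of the per-frame
    minimum heavy-atom distance between residue i of chain A and residue
    j of chain B.  Apply :func:`filter_unbound_frames` first when a
    ligand is annotated, so the average runs over bound frames only.
    """
    if ensemble is None or ensemble.n_frames == 0:
        raise EmptyInputError("contact_map requires a non-empty ensemble")
    topo = ensemble.topology
    blocks_a, labels_a = _residue_blocks(topo, chain_a, range_a, atom_filter)
    blocks_b, labels_b = _residue_blocks(topo, chain_b, range_b, atom_filter)
    idx_a = np.concatenate(blocks_a)
    idx_b = np.concatenate(blocks_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise SelectionError("chain selections overlap")
    # per-frame full cross-distance matrix, then block-wise minima
    sizes_a = [len(b) for b in blocks_a]
    sizes_b = [len(b) for b in blocks_b]
    ca = np.cumsum([0] + sizes_a)
    cb = np.cumsum([0] + sizes_b)
    acc = np.zeros((len(blocks_a), len(blocks_b)))
    for f in range(ensemble.n_frames):
        pa = ensemble.frames[f][idx_a]
        pb = ensemble.frames[f][idx_b]
        d2 = np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=-1)
        for i in range(len(blocks_a)):
            seg = d2[ca[i]:ca[i + 1]]
            for j in range(len(blocks_b)):
                acc[i, j] += np.sqrt(seg[:, cb[j]:cb[j + 1]].min())
    acc /= ensemble.n_frames
    return ContactMatrix(labels_a, labels_b, acc, ensemble.n_frames)
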