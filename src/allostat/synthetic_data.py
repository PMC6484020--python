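"""Synthetic inputs with known ground truth for every pipeline stage.

The generators stand in for inputs the analyses were designed around — a
three-chain reader/enzyme/ligand complex, multi-microsecond MD
trajectory ensembles, and plate-reader assay tables — at desk scale and
with controllable statistical structure:

* :func:`build_reference_complex` — a deterministic toy complex: a
  reader chain carrying the D362/M363/W364-like interaction markers, an
  enzyme chain with a flexible 136–142-like loop (two acidic side
  chains) and an ideal α-helix for residues 143–153 (the SRM analog),
  and a cationic ligand chain.
* :func:`simulate_trajectory` — frames mixing bound/unbound ligand
  poses and folded/partially-unfolded helix states with stated
  probabilities, plus three named interaction distances (d1, d2, d3)
  drawn from a correlated multivariate lognormal and realized exactly
  by marker-atom placement.
* :func:`simulate_assay` — SPA time courses, 4PL dose–response tables
  and FP saturation titrations with declared truths and multiplicative
  noise.

Distances are realized geometrically (marker atoms solved from the
sampled values) rather than by dynamics: the analyses need controllable
statistical structure, not physics.  All generators are pure functions
of (scenario, seed); sub-streams are split from the one seed via
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ScenarioError, ValidationError
from .structure_io import AnnotatedStructure, AtomRecord, Region, TrajectoryEnsemble

# -- reference complex ---------------------------------------------------------

_PYRROLIDINE = ("N1", "C2", "C3", "C4", "C5")
_TRP_RING = ("CG", "CD1", "NE1", "CE2", "CZ2")

# reference interaction geometry (nm): unit axes along which each
# receptor-side marker group is placed / re-placed per frame
_U1 = np.array([1.0, 0.0, 0.0])  # d1: D362 carboxylate direction
_U2 = np.array([0.0, 1.0, 0.0])  # d2: W364 ring direction
_U3 = np.array([0.0, 0.0, 1.0])  # d3: M363 sulfur direction
_D1_REF, _D2_REF, _D3_REF = 0.30, 0.45, 0.40
_OD2_OFFSET = np.array([0.12, 0.05, 0.0])  # keeps OD2 farther from the cation than OD1


def _backbone(ca: np.ndarray, resname: str) -> list[tuple[str, str, np.ndarray]]:
    """Toy backbone (+CB) atoms at fixed offsets from a CA position."""
    atoms = [
        ("N", "N", ca + (-0.10, 0.10, 0.0)),
        ("CA", "C", ca),
        ("C", "C", ca + (0.10, 0.10, 0.0)),
        ("O", "O", ca + (0.10, 0.22, 0.0)),
    ]
    if resname != "GLY":
        atoms.append(("CB", "C", ca + (0.0, -0.15, 0.0)))
    return atoms


def _ring(center: np.ndarray, names, elements, radius: float = 0.12) -> list:
    """Regular planar ring (xy-plane) whose centroid is exactly ``center``."""
    out = []
    for k, (nm, el) in enumerate(zip(names, elements)):
        ang = math.pi / 2 + 2 * math.pi * k / len(names)
        out.append((nm, el, center + radius * np.array([math.cos(ang), math.sin(ang), 0.0])))
    return out


def ideal_helix_ca(n: int, start: np.ndarray, radius: float = 0.23,
                   rise: float = 0.15, twist_deg: float = 100.0) -> np.ndarray:
    """CA positions of an ideal α-helix with axis along z."""
    out = np.empty((n, 3))
    for i in range(n):
        ang = math.radians(twist_deg) * i
        out[i] = start + np.array([radius * math.cos(ang), radius * math.sin(ang), rise * i])
    return out


def build_reference_complex() -> AnnotatedStructure:
    """Deterministic toy reader/enzyme/ligand complex with all regions annotated.

    Chain ``E`` (reader): two extended strands covering residues 355–370
    with side-chain interaction markers on ASP362 (carboxylate OD1/OD2),
    MET363 (sulfur SD) and TRP364 (5-atom aromatic ring).  Chain ``Z``
    (enzyme): strand 130–135, flexible loop 136–142 with acidic side
    chains at 136 and 140, ideal α-helix 143–153 (SRM analog).  Chain
    ``L``: one-residue cationic ligand (protonated pyrrolidine ring plus
    a lysine-mimic ammonium NZ engaging ASP140).
    """
    atoms: list[AtomRecord] = []

    def add(chain, resnum, resname, triples):
        for nm, el, xyz in triples:
            atoms.append(AtomRecord(nm, el, chain, resnum, resname,
                                    tuple(np.asarray(xyz, float))))

    # ligand chain L: pyrrolidine ring centered at the origin + lysine mimic
    pyr_center = np.zeros(3)
    lig = _ring(pyr_center, _PYRROLIDINE, ("N", "C", "C", "C", "C"))
    lig += [
        ("C6", "C", np.array([-0.15, -0.15, 0.0])),
        ("C7", "C", np.array([-0.30, -0.25, 0.0])),
        ("CE", "C", np.array([-0.45, -0.30, 0.0])),
        ("NZ", "N", np.array([-0.60, -0.35, 0.0])),
    ]
    add("L", 1, "LIG", lig)
    nz_ref = np.array([-0.60, -0.35, 0.0])

    # reader chain E: two antiparallel strands, well clear of the ligand site
    reader_res = {
        362: "ASP", 363: "MET", 364: "TRP", 365: "TYR",
    }
    for i, resnum in enumerate(range(355, 363)):
        ca = np.array([1.6 + 0.38 * i, 1.4, 0.9])
        add("E", resnum, reader_res.get(resnum, "GLY"), _backbone(ca, reader_res.get(resnum, "GLY")))
    for i, resnum in enumerate(range(363, 371)):
        ca = np.array([4.26 - 0.38 * i, 1.9, 0.9])
        add("E", resnum, reader_res.get(resnum, "GLY"), _backbone(ca, reader_res.get(resnum, "GLY")))
    # interaction markers (side chains reaching into the ligand site)
    n1_ref = np.array(lig[0][2])
    od1 = n1_ref + _D1_REF * _U1
    add("E", 362, "ASP", [("OD1", "O", od1), ("OD2", "O", od1 + _OD2_OFFSET)])
    add("E", 363, "MET", [("SD", "S", pyr_center + _D3_REF * _U3)])
    add("E", 364, "TRP", _ring(pyr_center + _D2_REF * _U2, _TRP_RING,
                               ("C", "C", "N", "C", "C")))

    # enzyme chain Z: strand 130-135, loop 136-142, SRM helix 143-153
    enzyme_res = {136: "ASP", 140: "ASP"}
    for i, resnum in enumerate(range(130, 143)):
        ca = np.array([-1.2 - 0.1 * i, -1.0 - 0.25 * i if resnum < 136 else -1.0 - 0.25 * 6 + 0.18 * (i - 6), -0.8])
        resname = enzyme_res.get(resnum, "ALA")
        add("Z", resnum, resname, _backbone(ca, resname))
    # acidic side chains reaching toward the ligand NZ
    od1_140 = nz_ref - 0.30 * np.array([1.0, 0.0, 0.0])
    add("Z", 140, "ASP", [("OD1", "O", od1_140),
                          ("OD2", "O", od1_140 - np.array([0.12, -0.05, 0.0]))])
    od1_136 = nz_ref - 0.55 * np.array([0.0, 1.0, 0.0])
    add("Z", 136, "ASP", [("OD1", "O", od1_136),
                          ("OD2", "O", od1_136 - np.array([0.0, 0.12, 0.05]))])
    helix_ca = ideal_helix_ca(11, np.array([0.9, -1.6, -0.9]))
    for i, resnum in enumerate(range(143, 154)):
        add("Z", resnum, "ALA", _backbone(helix_ca[i], "ALA"))

    regions = {
        "reader": Region("E", 355, 370),
        "enzyme": Region("Z", 130, 153),
        "ezh2_loop": Region("Z", 136, 142),
        "srm_helix": Region("Z", 143, 153),
        "ligand": Region("L", 1, 1),
    }
    return AnnotatedStructure(atoms, regions)


def default_interaction_groups(structure: AnnotatedStructure) -> dict:
    """Atom-group definitions for the named distances on the toy complex.

    d1 — salt bridge: ligand pyrrolidine nitrogen to the closer D362
    carboxylate oxygen (min mode); d2 — cation-π: pyrrolidine centroid
    to W364 ring centroid (centroid mode); d3 — M363 sulfur to
    pyrrolidine centroid (centroid mode).
    """
    names = structure.atom_names
    chains = structure.chain_ids
    resnums = structure.residue_numbers

    def pick(chain, resnum, wanted):
        mask = (chains == chain) & (resnums == resnum) & np.isin(names, list(wanted))
        return np.flatnonzero(mask)

    pyr = pick("L", 1, _PYRROLIDINE)
    return {
        "d1": (pick("L", 1, ("N1",)), pick("E", 362, ("OD1", "OD2")), "min"),
        "d2": (pyr, pick("E", 364, _TRP_RING), "centroid"),
        "d3": (pick("E", 363, ("SD",)), pyr, "centroid"),
    }


# -- trajectory scenario -------------------------------------------------------


def _default_corr() -> np.ndarray:
    # mutant-like coupling of the pyrrolidine contacts: d1-d3 0.75, d2-d3 0.61
    return np.array([[1.0, 0.50, 0.75], [0.50, 1.0, 0.61], [0.75, 0.61, 1.0]])


@dataclass
class TrajectoryScenario:
    """Generating parameters for a synthetic state-switching trajectory.

    Defaults correspond to the ``mutant_like`` preset: a mostly bound
    ligand, a mostly folded helix, a persistent salt bridge and strongly
    coupled (d1, d3) / (d2, d3) distances.
    """

    n_frames: int = 2500
    seed: int = 0
    bound_fraction: float = 0.8
    helix_unfold_prob: float = 0.10
    unbound_displacement_nm: float = 2.0
    coordinate_noise_nm: float = 0.005
    distance_correlation: np.ndarray = field(default_factory=_default_corr)
    distance_medians_nm: tuple[float, float, float] = (0.30, 0.45, 0.40)
    log_sigma: float = 0.18  # lognormal shape of the distance marginals
    loop_jitter_nm: float = 0.03  # mobility of the 136-142 loop side chains
    helix_disorder_nm: float = 0.35  # per-atom displacement of unfolded-helix frames
    dt_ns: float = 0.2

    def __post_init__(self) -> None:
        c = np.asarray(self.distance_correlation, dtype=float)
        if c.shape != (3, 3) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ScenarioError("distance_correlation must be symmetric 3x3 with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ScenarioError("distance_correlation is not positive semidefinite")
        for name in ("bound_fraction", "helix_unfold_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{name} must be in [0, 1], got {v}")
        self.distance_correlation = c


def wt_like(**overrides) -> TrajectoryScenario:
    """WT-complex preset: mobile loop, frequently unfolded helix, weak coupling."""
    base = dict(
        helix_unfold_prob=0.45,
        distance_correlation=np.array(
            [[1.0, 0.20, 0.30], [0.20, 1.0, 0.25], [0.30, 0.25, 1.0]]
        ),
        distance_medians_nm=(0.55, 0.50, 0.45),
        loop_jitter_nm=0.15,
    )
    base.update(overrides)
    return TrajectoryScenario(**base)


def mutant_like(**overrides) -> TrajectoryScenario:
    """Mutant-complex preset (the dataclass defaults): stable, coupled contacts."""
    return TrajectoryScenario(**overrides)


def simulate_trajectory(
    scenario: TrajectoryScenario, reference: AnnotatedStructure
) -> TrajectoryEnsemble:
    """Generate a labelled trajectory ensemble from a scenario.

    Per frame: draw a bound flag (unbound frames displace the whole
    ligand chain by ``unbound_displacement_nm`` in a random direction)
    and a helix-folded flag (unfolded frames disorder the SRM-helix
    atoms); sample (d1, d2, d3) from the correlated lognormal and place
    the D362/W364/M363 marker atoms so the realized distances equal the
    sampled values exactly; finally add isotropic Gaussian coordinate
    noise to every atom.  Ground truth is recorded in ``truth_labels``.
    """
    n = scenario.n_frames
    ss = np.random.SeedSequence(scenario.seed).spawn(5)
    rng_state, rng_dist, rng_dir, rng_helix, rng_noise = (
        np.random.default_rng(s) for s in ss
    )

    bound = rng_state.random(n) < scenario.bound_fraction
    folded = rng_state.random(n) >= scenario.helix_unfold_prob

    cov = scenario.distance_correlation
    z = rng_dist.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    medians = np.asarray(scenario.distance_medians_nm, dtype=float)
    dists = medians[None, :] * np.exp(scenario.log_sigma * z)

    ref_coords = reference.coords
    names = reference.atom_names
    chains = reference.chain_ids
    resnums = reference.residue_numbers

    def one(chain, resnum, name):
        idx = np.flatnonzero((chains == chain) & (resnums == resnum) & (names == name))
        return int(idx[0])

    i_n1 = one("L", 1, "N1")
    i_od1 = one("E", 362, "OD1")
    i_od2 = one("E", 362, "OD2")
    i_sd = one("E", 363, "SD")
    ring_idx = np.flatnonzero((chains == "E") & (resnums == 364) & np.isin(names, _TRP_RING))
    pyr_idx = np.flatnonzero((chains == "L") & np.isin(names, _PYRROLIDINE))
    lig_idx = np.flatnonzero(chains == "L")
    loop_side = np.flatnonzero(
        (chains == "Z") & (resnums >= 136) & (resnums <= 142)
        & ~np.isin(names, ("N", "CA", "C", "O"))
    )
    helix_idx = np.flatnonzero((chains == "Z") & (resnums >= 143) & (resnums <= 153))

    n1_ref = ref_coords[i_n1]
    pyr_center = ref_coords[pyr_idx].mean(axis=0)
    ring_ref = ref_coords[ring_idx]
    ring_centroid_ref = ring_ref.mean(axis=0)

    frames = np.empty((n, ref_coords.shape[0], 3))
    for f in range(n):
        c = ref_coords.copy()
        d1, d2, d3 = dists[f]
        od1 = n1_ref + d1 * _U1
        c[i_od1] = od1
        c[i_od2] = od1 + _OD2_OFFSET
        c[ring_idx] = ring_ref + (pyr_center + d2 * _U2 - ring_centroid_ref)
        c[i_sd] = pyr_center + d3 * _U3
        if scenario.loop_jitter_nm > 0:
            c[loop_side] += rng_helix.normal(0.0, scenario.loop_jitter_nm,
                                             (loop_side.size, 3))
        if not folded[f]:
            c[helix_idx] += rng_helix.normal(0.0, scenario.helix_disorder_nm,
                                             (helix_idx.size, 3))
        if not bound[f]:
            u = rng_dir.normal(size=3)
            u /= np.linalg.norm(u)
            c[lig_idx] += scenario.unbound_displacement_nm * u
        frames[f] = c
    if scenario.coordinate_noise_nm > 0:
        frames += rng_noise.normal(0.0, scenario.coordinate_noise_nm, frames.shape)

    labels = pd.DataFrame(
        {
            "bound": bound,
            "helix_folded": folded,
            "d1": dists[:, 0],
            "d2": dists[:, 1],
            "d3": dists[:, 2],
        }
    )
    times = scenario.dt_ns * np.arange(n, dtype=float)
    return TrajectoryEnsemble(reference, frames, times, labels)


# -- assay scenario ------------------------------------------------------------


@dataclass
class AssayScenario:
    """Generating truths and design of the synthetic plate assays.

    Truth defaults follow the characterized system: WT peptide turnover
    24 h⁻¹, activation EC50 2.3 µM, tracer Kd 156 nM at 40 nM tracer,
    triplicate wells.  The CPM conversion factor (counts per pmol of
    product) is a declared property of the generator, standing in for
    tritium specific activity times counting efficiency.
    """

    kcat_true: float = 24.0  # h^-1
    ec50_true: float = 2.3  # µM
    kd_true: float = 156.0  # nM
    noise_cv: float = 0.03
    n_replicates: int = 3
    seed: int = 0
    concentrations: tuple | None = None  # µM, dose-response only
    # design constants
    enzyme_conc_nM: float = 20.0
    substrate: str = "peptide"
    complex_id: str = "WT"
    compound_id: str = ""
    compound_conc_uM: float = 20.0
    times_h: tuple = (0.25, 0.5, 0.75, 1.0)
    counts_per_pmol: float = 100.0
    volume_uL: float = 10.0
    background_cpm: float = 50.0
    top: float = 240.0  # % activity plateau of an activator
    bottom: float = 100.0
    hill_true: float = 1.0
    tracer_nM: float = 40.0
    fp_min: float = 50.0
    fp_max: float = 250.0
    titration_top_nM: float = 2000.0
    n_titration: int = 12

    def __post_init__(self) -> None:
        for name in ("kcat_true", "ec50_true", "kd_true"):
            if getattr(self, name) <= 0:
                raise ScenarioError(f"{name} must be > 0")
        if self.noise_cv < 0:
            raise ScenarioError("noise_cv must be >= 0")


def _noisy(rng, values, cv):
    values = np.asarray(values, dtype=float)
    if cv == 0:
        return values.copy()
    return np.maximum(values * (1.0 + cv * rng.standard_normal(values.shape)), 0.0)


def simulate_assay(scenario: AssayScenario, kind: str,
                   include_controls: bool = True) -> pd.DataFrame:
    """Generate a tidy assay table of the requested kind.

    ``timecourse`` and ``dose_response`` return AssayWell rows (one row
    per well, CPM counts, with no-compound controls and no-enzyme
    backgrounds for the dataset); ``fp_titration`` returns FP rows
    (protein_conc_nM, polarization, tracer_conc_nM, replicate).
    Control emission cannot be disabled: the normalization stage
    requires both roles in every dataset.
    """
    if not include_controls:
        raise ValidationError("controls are required by the normalization stage")
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(1)[0])
    sc = scenario
    if kind == "timecourse":
        dataset = f"timecourse/{sc.complex_id}/{sc.compound_id or 'DMSO'}/{sc.substrate}"
        rows = []
        signal_cpm = lambda p_nM: p_nM * sc.volume_uL * sc.counts_per_pmol / 1000.0
        for t in sc.times_h:
            product = sc.kcat_true * sc.enzyme_conc_nM * t
            for rep in range(sc.n_replicates):
                cpm = sc.background_cpm + float(_noisy(rng, [signal_cpm(product)], sc.noise_cv)[0])
                rows.append((dataset, "sample", cpm, sc.compound_conc_uM if sc.compound_id else 0.0,
                             sc.enzyme_conc_nM, sc.substrate, t, rep))
        t_end = max(sc.times_h)
        ctrl_product = sc.kcat_true * sc.enzyme_conc_nM * t_end
        for rep in range(sc.n_replicates):
            cpm = sc.background_cpm + float(_noisy(rng, [signal_cpm(ctrl_product)], sc.noise_cv)[0])
            rows.append((dataset, "no_compound_control", cpm, 0.0,
                         sc.enzyme_conc_nM, sc.substrate, t_end, rep))
            bcpm = float(_noisy(rng, [sc.background_cpm], sc.noise_cv)[0])
            rows.append((dataset, "no_enzyme_background", bcpm, 0.0, 0.0,
                         sc.substrate, t_end, rep))
        return pd.DataFrame(rows, columns=list(
            ("dataset", "role", "cpm", "compound_conc_uM", "enzyme_conc_nM",
             "substrate", "time_h", "replicate")))
    if kind == "dose_response":
        from .enzymology import four_pl

        dataset = f"dose_response/{sc.complex_id}/{sc.compound_id or 'cmpd'}/{sc.substrate}"
        concs = sc.concentrations or tuple(np.geomspace(0.0316, 100.0, 8))
        control_cpm = 2000.0
        window = control_cpm - sc.background_cpm
        t_end = max(sc.times_h)
        rows = []
        for conc in concs:
            pct = float(four_pl(conc, sc.bottom, sc.top, sc.ec50_true, sc.hill_true))
            for rep in range(sc.n_replicates):
                signal = window * pct / 100.0
                cpm = sc.background_cpm + float(_noisy(rng, [signal], sc.noise_cv)[0])
                rows.append((dataset, "sample", cpm, conc, sc.enzyme_conc_nM,
                             sc.substrate, t_end, rep))
        for rep in range(sc.n_replicates):
            cpm = sc.background_cpm + float(_noisy(rng, [window], sc.noise_cv)[0])
            rows.append((dataset, "no_compound_control", cpm, 0.0, sc.enzyme_conc_nM,
                         sc.substrate, t_end, rep))
            bcpm = float(_noisy(rng, [sc.background_cpm], sc.noise_cv)[0])
            rows.append((dataset, "no_enzyme_background", bcpm, 0.0, 0.0,
                         sc.substrate, t_end, rep))
        return pd.DataFrame(rows, columns=list(
            ("dataset", "role", "cpm", "compound_conc_uM", "enzyme_conc_nM",
             "substrate", "time_h", "replicate")))
    if kind == "fp_titration":
        from .enzymology import bound_fraction

        dataset = f"fp/{sc.complex_id}"
        protein = sc.titration_top_nM / 2.0 ** np.arange(sc.n_titration)
        rows = []
        for p in protein:
            fb = float(bound_fraction(p, sc.tracer_nM, sc.kd_true))
            fp_true = sc.fp_min + (sc.fp_max - sc.fp_min) * fb
            for rep in range(sc.n_replicates):
                fp = float(_noisy(rng, [fp_true], sc.noise_cv)[0])
                rows.append((dataset, p, fp, sc.tracer_nM, rep))
        return pd.DataFrame(rows, columns=["dataset", "protein_conc_nM",
                                           "polarization", "tracer_conc_nM", "replicate"])
    raise ValueError(f"unknown assay kind {kind!r}")
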