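"""End-to-end runs: mechanism analysis and enzymology, driven by one config.

A run configuration is a plain mapping (usually loaded from YAML) with a
``seed``, an ``output_dir`` and a ``mechanism`` and/or ``enzymology``
block.  Inputs may be file paths (ensemble/reference/regions, assay
CSVs) or synthetic scenario blocks; all randomness flows from the single
seed.  Every output file carries the config hash in its header line or
JSON provenance, and headline numbers in the run report are recomputed
from the written outputs' source arrays — nothing is reported that does
not exist on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .structure_io import (
    AnnotatedStructure,
    TrajectoryEnsemble,
    load_regions,
    read_ensemble,
    read_structure,
)
from .traj_mechanics import contact_map, filter_unbound_frames, region_rmsd
from .interaction_stats import (
    CATION_PI_CUTOFF_NM,
    NamedDistanceSet,
    SALT_BRIDGE_CUTOFF_NM,
    distance_series,
    kde2d,
    occupancy,
    pearson_r,
    summarize,
)
from .enzymology import (
    cpm_to_product,
    fit_dose_response,
    fit_fp_binding,
    fit_kcat,
    fold_change,
    normalize_activity,
)
from .synthetic_data import (
    AssayScenario,
    TrajectoryScenario,
    build_reference_complex,
    default_interaction_groups,
    mutant_like,
    simulate_assay,
    simulate_trajectory,
    wt_like,
)

log = logging.getLogger("allostat")

_PRESETS = {"wt_like": wt_like, "mutant_like": mutant_like}


def config_hash(config: dict) -> str:
    """Stable short hash of a run configuration."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


@dataclass
class RunReport:
    """Provenance, output-file index and headline numbers of one run."""

    provenance: dict
    outputs: dict = field(default_factory=dict)
    headline: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float) + "\n")


def _resolve_mechanism_inputs(
    cfg: dict, seed: int
) -> tuple[TrajectoryEnsemble, AnnotatedStructure]:
    block = cfg.get("scenario")
    if block is not None:
        block = dict(block)
        preset = block.pop("preset", "mutant_like")
        if preset not in _PRESETS:
            raise ValidationError(f"unknown scenario preset {preset!r}")
        block.setdefault("seed", seed)
        scenario = _PRESETS[preset](**block)
        reference = build_reference_complex()
        return simulate_trajectory(scenario, reference), reference
    if "ensemble" not in cfg or "reference" not in cfg:
        raise ValidationError("mechanism block needs 'scenario' or 'ensemble'+'reference'")
    reference = read_structure(cfg["reference"])
    regions = load_regions(cfg["regions"]) if "regions" in cfg else {}
    for role, region in regions.items():
        reference.annotate(role, region)
    ensemble = read_ensemble(cfg["ensemble"], topology=reference)
    return ensemble, reference


def run_mechanism(config: dict, output_dir: str | Path | None = None) -> RunReport:
    """Filter → contact map → helix RMSD → d1/d2/d3 statistics → KDE.

    Writes the frame mask, contact matrix (TSV + PNG), helix RMSD
    series, distance series with summaries, and 2D density panels for
    (d1, d3) and (d2, d3); returns a report whose headline block holds
    the kept-frame fraction, occupancies, medians/MADs and r values.
    """
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "allostat_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    mech = config.get("mechanism", {})
    report = RunReport({"config_hash": chash, "seed": seed, "version": __version__})

    ensemble, reference = _resolve_mechanism_inputs(mech, seed)
    log.info("mechanism: %d frames, %d atoms", ensemble.n_frames, len(reference))

    threshold = float(mech.get("filter_threshold_nm", 0.8))
    filtered, mask = filter_unbound_frames(ensemble, reference, threshold)
    mask.to_csv(outdir / "frame_mask.csv")
    report.outputs["frame_mask"] = str(outdir / "frame_mask.csv")
    kept_fraction = mask.n_kept / len(mask.kept)
    report.headline["kept_frame_fraction"] = kept_fraction
    log.info("filter: kept %d / %d frames", mask.n_kept, len(mask.kept))
    if kept_fraction < 0.5:
        log.warning("fewer than half of the frames survive the unbound filter")
    if filtered is None:
        raise ValidationError("all frames removed by the unbound-ligand filter")

    cm_cfg = mech.get("contact_map", {})
    enzyme = reference.regions["enzyme"]
    ligand = reference.regions["ligand"]
    cm = contact_map(
        filtered,
        cm_cfg.get("chain_a", enzyme.chain_id),
        tuple(cm_cfg.get("range_a", (enzyme.start, enzyme.end))),
        cm_cfg.get("chain_b", ligand.chain_id),
        tuple(cm_cfg.get("range_b", (ligand.start, ligand.end))),
    )
    cm.to_tsv(outdir / "contact_map.tsv")
    cm.plot(outdir / "contact_map.png")
    report.outputs["contact_map"] = str(outdir / "contact_map.tsv")
    report.outputs["contact_map_png"] = str(outdir / "contact_map.png")
    report.headline["closest_contact"] = "-".join(cm.argmin())

    helix = region_rmsd(filtered, reference, "enzyme", "srm_helix")
    pd.DataFrame({"time_ns": helix.times, "rmsd_nm": helix.values}).to_csv(
        outdir / "helix_rmsd.csv", index=False
    )
    report.outputs["helix_rmsd"] = str(outdir / "helix_rmsd.csv")
    report.headline["helix_rmsd_median"] = helix.median
    report.headline["helix_rmsd_mad"] = helix.mad

    groups = default_interaction_groups(reference)
    series = {}
    for label, (ga, gb, mode) in groups.items():
        series[label] = distance_series(filtered, ga, gb, mode=mode, label=label)
    dset = NamedDistanceSet(series)
    dset.to_csv(outdir / "distances.csv")
    report.outputs["distances"] = str(outdir / "distances.csv")
    cutoffs = {
        "d1": float(mech.get("saltbridge_cutoff_nm", SALT_BRIDGE_CUTOFF_NM)),
        "d2": float(mech.get("cation_pi_cutoff_nm", CATION_PI_CUTOFF_NM)),
        "d3": float(mech.get("sulfur_contact_cutoff_nm", 0.6)),
    }
    for label, s in series.items():
        stats_ = summarize(s)
        report.headline[f"{label}_median"] = stats_["median"]
        report.headline[f"{label}_mad"] = stats_["mad"]
        report.headline[f"{label}_occupancy"] = occupancy(s, cutoffs[label])
    for a, b in (("d1", "d3"), ("d2", "d3")):
        r = pearson_r(series[a], series[b])
        report.headline[f"r_{a}_{b}"] = r
        dens = kde2d(series[a], series[b])
        dens.to_tsv(outdir / f"kde_{a}_{b}.tsv")
        dens.plot(outdir / f"kde_{a}_{b}.png",
                  xlabel=f"{a} (nm)", ylabel=f"{b} (nm)")
        report.outputs[f"kde_{a}_{b}"] = str(outdir / f"kde_{a}_{b}.tsv")

    report.to_json(outdir / "mechanism_report.json")
    report.outputs["report"] = str(outdir / "mechanism_report.json")
    return report


# -- enzymology ---------------------------------------------------------------


def _simulate_enzymology_tables(block: dict, seed: int):
    """Build the assay tables requested by a scenarios block."""
    tables, fp_tables = [], []
    scen = block.get("scenarios", {})
    sub = np.random.SeedSequence(seed).spawn(
        len(scen.get("timecourses", [])) + 2
    )
    k = 0
    for tc in scen.get("timecourses", []):
        sc = AssayScenario(seed=int(sub[k].generate_state(1)[0] % 2**31), **tc)
        tables.append(simulate_assay(sc, "timecourse"))
        k += 1
    if "dose_response" in scen:
        sc = AssayScenario(seed=int(sub[k].generate_state(1)[0] % 2**31),
                           **scen["dose_response"])
        tables.append(simulate_assay(sc, "dose_response"))
    k += 1
    if "fp_titration" in scen:
        sc = AssayScenario(seed=int(sub[k].generate_state(1)[0] % 2**31),
                           **scen["fp_titration"])
        fp_tables.append(simulate_assay(sc, "fp_titration"))
    wells = pd.concat(tables, ignore_index=True) if tables else None
    fp = pd.concat(fp_tables, ignore_index=True) if fp_tables else None
    return wells, fp


def _dataset_meta(name: str) -> dict:
    """Recover (kind, complex, compound, substrate) from a dataset name."""
    parts = name.split("/")
    if parts[0] in ("timecourse", "dose_response") and len(parts) == 4:
        return {"kind": parts[0], "complex_id": parts[1],
                "compound_id": parts[2], "substrate": parts[3]}
    return {"kind": parts[0], "complex_id": parts[-1], "compound_id": "",
            "substrate": ""}


def run_enzymology(config: dict, output_dir: str | Path | None = None) -> RunReport:
    """Normalize → kcat per condition → fold change vs DMSO → EC50 → FP Kd.

    Emits a turnover table shaped like a compound × complex kcat summary,
    a dose-response fit table and (when a titration is present) an FP
    binding fit, plus a JSON run report with the headline numbers.
    """
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "allostat_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    enz = config.get("enzymology", {})
    report = RunReport({"config_hash": chash, "seed": seed, "version": __version__})

    if "assay_csv" in enz:
        wells = pd.read_csv(enz["assay_csv"])
    elif "scenarios" in enz:
        wells, fp_table = _simulate_enzymology_tables(enz, seed)
    else:
        raise ValidationError("enzymology block needs 'assay_csv' or 'scenarios'")
    if "fp_csv" in enz:
        fp_table = pd.read_csv(enz["fp_csv"])
    elif "scenarios" not in enz:
        fp_table = None

    counts_per_pmol = float(enz.get("counts_per_pmol", 100.0))
    volume_uL = float(enz.get("volume_uL", 10.0))

    kin_rows, dr_rows = [], []
    if wells is not None:
        normalized, provenance = normalize_activity(wells)
        normalized.to_csv(outdir / "normalized_activity.csv", index=False)
        report.outputs["normalized_activity"] = str(outdir / "normalized_activity.csv")
        for name, grp in normalized.groupby("dataset"):
            meta = _dataset_meta(str(name))
            samples = grp[grp["role"] == "sample"]
            if samples.empty:
                log.info("dataset %s: no sample wells, skipped", name)
                continue
            if meta["kind"] == "timecourse":
                bkg = provenance[name][1]
                product = cpm_to_product(samples["cpm"] - bkg, counts_per_pmol, volume_uL)
                enzyme_conc = float(samples["enzyme_conc_nM"].iloc[0])
                res = fit_kcat(samples["time_h"].to_numpy(), product, enzyme_conc,
                               substrate=meta["substrate"], complex_id=meta["complex_id"],
                               compound_id=meta["compound_id"])
                kin_rows.append({**meta, "kcat_per_h": res.kcat, "sd": res.sd,
                                 "flag": res.flag, "_res": res})
                log.info("kcat %s: %.3g ± %.2g h^-1", name, res.kcat, res.sd)
            elif meta["kind"] == "dose_response":
                fit = fit_dose_response(samples["compound_conc_uM"].to_numpy(),
                                        samples["percent_activity"].to_numpy())
                if fit.flag:
                    log.warning("dose-response %s: %s", name, fit.flag)
                dr_rows.append({**meta, "ec50_uM": fit.ec50, "se_ec50_uM": fit.se_ec50,
                                "hill": fit.hill, "top": fit.top, "bottom": fit.bottom,
                                "direction": fit.direction, "flag": fit.flag})
            else:
                log.info("dataset %s: no dose-response or timecourse wells; skipped", name)

    if kin_rows:
        kin = pd.DataFrame([{k: v for k, v in r.items() if k != "_res"} for r in kin_rows])
        kin.to_csv(outdir / "kcat_table.csv", index=False)
        report.outputs["kcat_table"] = str(outdir / "kcat_table.csv")
        # fold changes of every treated condition against its DMSO control
        fold_rows = []
        by_key = {(r["complex_id"], r["substrate"], r["compound_id"]): r["_res"]
                  for r in kin_rows}
        for (cpx, sub, cmpd), res in by_key.items():
            ctrl = by_key.get((cpx, sub, "DMSO"))
            if ctrl is None or ctrl.kcat <= 0:
                continue
            fc = fold_change(res, ctrl)
            fold_rows.append({"complex_id": cpx, "substrate": sub, "compound_id": cmpd,
                              "fold_vs_DMSO": fc.ratio, "sd": fc.sd})
            report.headline[f"fold_{cpx}_{sub}_{cmpd}"] = fc.ratio
        if fold_rows:
            pd.DataFrame(fold_rows).to_csv(outdir / "fold_change.csv", index=False)
            report.outputs["fold_change"] = str(outdir / "fold_change.csv")
        for r in kin_rows:
            report.headline[
                f"kcat_{r['complex_id']}_{r['substrate']}_{r['compound_id']}"] = r["kcat_per_h"]

    if dr_rows:
        pd.DataFrame(dr_rows).to_csv(outdir / "dose_response.csv", index=False)
        report.outputs["dose_response"] = str(outdir / "dose_response.csv")
        for r in dr_rows:
            report.headline[f"ec50_{r['complex_id']}_{r['compound_id']}"] = r["ec50_uM"]

    if fp_table is not None and not fp_table.empty:
        fits = []
        for name, grp in fp_table.groupby("dataset"):
            fit = fit_fp_binding(grp["protein_conc_nM"].to_numpy(),
                                 grp["polarization"].to_numpy(),
                                 float(grp["tracer_conc_nM"].iloc[0]))
            if fit.flag:
                log.warning("fp %s: %s", name, fit.flag)
            fits.append({"dataset": name, "kd_nM": fit.kd, "se_kd_nM": fit.se_kd,
                         "fp_min": fit.fp_min, "fp_max": fit.fp_max, "flag": fit.flag})
            report.headline[f"kd_{name}"] = fit.kd
        pd.DataFrame(fits).to_csv(outdir / "fp_binding.csv", index=False)
        report.outputs["fp_binding"] = str(outdir / "fp_binding.csv")

    report.to_json(outdir / "enzymology_report.json")
    report.outputs["report"] = str(outdir / "enzymology_report.json")
    return report
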