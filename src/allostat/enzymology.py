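"""Biochemical quantification: activity normalization, kcat, EC50, FP Kd.

Implements the assay-side analysis chain for methyltransferase
scintillation-proximity (SPA) and fluorescence-polarization (FP) data:

* CPM normalization — within each dataset, the mean no-compound control
  defines 100% activity and the mean no-enzyme background defines 0%;
* turnover number kcat from the initial-rate slope of product vs time
  divided by enzyme concentration;
* activation/inhibition EC50 from a four-parameter logistic (4PL) fit
  of percent activity vs compound concentration;
* fold change of kcat between treated and control conditions with
  first-order error propagation;
* tracer dissociation constant Kd from an FP saturation titration using
  the exact (ligand-depletion) quadratic binding model — required here
  because the tracer concentration (40 nM) is comparable to Kd.

Assay tables are tidy pandas DataFrames, one row per well, with the
columns in :data:`WELL_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ComparisonError, DegenerateWindowError, ValidationError

#: Required columns of a tidy assay-well table.
WELL_COLUMNS = (
    "dataset",
    "role",  # sample | no_compound_control | no_enzyme_background
    "cpm",
    "compound_conc_uM",
    "enzyme_conc_nM",
    "substrate",  # peptide | nucleosome
    "time_h",
    "replicate",
)

ROLES = ("sample", "no_compound_control", "no_enzyme_background")


def validate_wells(wells: pd.DataFrame) -> None:
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValidationError(f"assay table lacks columns {missing}")
    bad_roles = set(wells["role"]) - set(ROLES)
    if bad_roles:
        raise ValidationError(f"unknown well roles {sorted(bad_roles)}")
    if (wells["cpm"] < 0).any():
        raise ValidationError("negative CPM counts")
    bg = wells[wells["role"] == "no_enzyme_background"]
    if (bg["enzyme_conc_nM"] != 0).any():
        raise ValidationError("no_enzyme_background wells must have enzyme_conc_nM = 0")


# -- normalization -------------------------------------------------------------


def normalize_activity(wells: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Convert CPM to percent activity per dataset.

    For each dataset, percent = 100 * (cpm - mean background) /
    (mean control - mean background), so control wells average to 100
    and background wells to 0 by construction.

    Returns the table with a ``percent_activity`` column added (all
    roles retained) and a provenance dict
    ``{dataset: (mean_control_cpm, mean_background_cpm)}``.
    """
    validate_wells(wells)
    out = wells.copy()
    out["percent_activity"] = np.nan
    provenance: dict = {}
    for name, grp in wells.groupby("dataset"):
        ctrl = grp.loc[grp["role"] == "no_compound_control", "cpm"]
        bkg = grp.loc[grp["role"] == "no_enzyme_background", "cpm"]
        if ctrl.empty or bkg.empty:
            raise ValidationError(
                f"dataset {name!r} lacks control and/or background wells"
            )
        c, b = float(ctrl.mean()), float(bkg.mean())
        if c <= b:
            raise DegenerateWindowError(
                f"dataset {name!r}: mean control CPM {c} <= mean background {b}"
            )
        sel = out["dataset"] == name
        out.loc[sel, "percent_activity"] = 100.0 * (out.loc[sel, "cpm"] - b) / (c - b)
        provenance[name] = (c, b)
    return out, provenance


# -- kinetics ------------------------------------------------------------------


def cpm_to_product(cpm, counts_per_pmol: float, volume_uL: float):
    """Linear CPM → product concentration (nM) conversion.

    ``counts_per_pmol`` bundles tritium specific activity and counting
    efficiency; product (nM) = cpm / counts_per_pmol / volume (µL) * 1000.
    """
    if counts_per_pmol <= 0:
        raise ValueError(f"counts_per_pmol must be > 0, got {counts_per_pmol}")
    if volume_uL <= 0:
        raise ValueError(f"volume_uL must be > 0, got {volume_uL}")
    return np.asarray(cpm, dtype=float) / counts_per_pmol / volume_uL * 1000.0


@dataclass
class KineticResult:
    """Turnover number with uncertainty, tagged by condition."""

    kcat: float  # h^-1
    sd: float  # h^-1
    substrate: str = "peptide"
    complex_id: str = ""
    compound_id: str = ""
    flag: str = ""  # "", "single_point", "non_positive_slope"


def fit_kcat(
    times_h: Sequence[float],
    product_nM: Sequence[float],
    enzyme_conc_nM: float,
    substrate: str = "peptide",
    complex_id: str = "",
    compound_id: str = "",
    through_origin: bool | None = None,
) -> KineticResult:
    """kcat from the linear initial-rate regime of product vs time.

    kcat = slope / [E].  With a single distinct time point (the endpoint
    design: fixed incubation, replicate wells) the line is forced
    through the origin; with a multi-point time course an intercept is
    fitted.  A non-positive slope is clipped to kcat = 0 and flagged.
    """
    t = np.asarray(times_h, dtype=float)
    p = np.asarray(product_nM, dtype=float)
    if t.shape != p.shape or t.size < 1:
        raise ValueError("times and product must be equal-length, non-empty")
    if enzyme_conc_nM <= 0:
        raise ValueError(f"enzyme_conc_nM must be > 0, got {enzyme_conc_nM}")
    if through_origin is None:
        through_origin = np.unique(t).size == 1
    flag = ""
    if through_origin:
        denom = float(np.sum(t**2))
        if denom == 0:
            raise ValueError("all time points are zero")
        slope = float(np.sum(t * p)) / denom
        resid = p - slope * t
        if t.size > 1:
            se = float(np.sqrt(np.sum(resid**2) / (t.size - 1) / denom))
        else:
            se = 0.0
            flag = "single_point"
    else:
        fit = stats.linregress(t, p)
        slope, se = float(fit.slope), float(fit.stderr)
    kcat = slope / enzyme_conc_nM
    sd = se / enzyme_conc_nM
    if kcat < 0:
        kcat = 0.0
        flag = "non_positive_slope"
    return KineticResult(kcat, sd, substrate, complex_id, compound_id, flag)


@dataclass
class FoldChange:
    ratio: float
    sd: float


def fold_change(treated: KineticResult, control: KineticResult) -> FoldChange:
    """kcat ratio treated/control with first-order error propagation.

    Both results must refer to the same substrate and complex; a ratio
    of a result against itself is exactly 1.
    """
    if treated.substrate != control.substrate or treated.complex_id != control.complex_id:
        raise ComparisonError(
            f"cannot compare ({treated.substrate}, {treated.complex_id}) "
            f"with ({control.substrate}, {control.complex_id})"
        )
    if control.kcat <= 0:
        raise ValueError("control kcat must be > 0")
    ratio = treated.kcat / control.kcat
    rel = 0.0
    if treated.kcat > 0:
        rel = (treated.sd / treated.kcat) ** 2
    rel += (control.sd / control.kcat) ** 2
    return FoldChange(ratio, ratio * np.sqrt(rel))


# -- dose response -------------------------------------------------------------


@dataclass
class DoseResponseFit:
    """Four-parameter logistic fit of percent activity vs concentration (µM)."""

    ec50: float
    hill: float
    top: float
    bottom: float
    se_ec50: float
    direction: str  # activation | inhibition
    flag: str = ""  # "wide_interval" when a plateau is poorly defined

    def predict(self, conc_uM) -> np.ndarray:
        return four_pl(np.asarray(conc_uM, float), self.bottom, self.top, self.ec50, self.hill)


def four_pl(conc, bottom, top, ec50, hill):
    """4PL response: bottom + (top - bottom) / (1 + (ec50/conc)^hill).

    ``bottom`` is the zero-concentration asymptote, ``top`` the
    saturating one; at conc = ec50 the response is their midpoint.
    """
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(conc > 0, ec50 / np.where(conc > 0, conc, 1.0), np.inf)
        return bottom + (top - bottom) / (1.0 + ratio**hill)


def fit_dose_response(
    conc_uM: Sequence[float],
    percent_activity: Sequence[float],
    hill_bounds: tuple[float, float] = (0.2, 5.0),
) -> DoseResponseFit:
    """Least-squares 4PL fit over all replicate points jointly.

    Replicates are fitted as individual points (not averaged), which
    weights concentrations by their replicate counts.  Zero
    concentrations pin the bottom plateau through the model limit and
    are retained.  Requires at least 5 distinct concentrations.
    """
    conc = np.asarray(conc_uM, dtype=float)
    pct = np.asarray(percent_activity, dtype=float)
    if conc.shape != pct.shape:
        raise ValueError("conc and percent arrays differ in shape")
    pos = conc > 0
    if np.unique(conc[pos]).size < 5:
        raise ValueError("need >= 5 distinct non-zero concentrations")
    lo_resp = float(pct[conc == conc[pos].min()].mean())
    hi_resp = float(pct[conc == conc.max()].mean())
    p0 = [lo_resp, hi_resp, float(np.exp(np.mean(np.log(conc[pos])))), 1.0]
    bounds = (
        [-np.inf, -np.inf, 1e-9, hill_bounds[0]],
        [np.inf, np.inf, 1e9, hill_bounds[1]],
    )
    popt, pcov = optimize.curve_fit(
        lambda c, bottom, top, ec50, hill: four_pl(c, bottom, top, ec50, hill),
        conc, pct, p0=p0, bounds=bounds, maxfev=20000,
    )
    bottom, top, ec50, hill = (float(v) for v in popt)
    se_ec50 = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    direction = "activation" if top > bottom else "inhibition"
    flag = "wide_interval" if not np.isfinite(se_ec50) or se_ec50 > ec50 else ""
    return DoseResponseFit(ec50, hill, top, bottom, se_ec50, direction, flag)


# -- FP binding ----------------------------------------------------------------


@dataclass
class BindingFit:
    """Quadratic (ligand-depletion) FP binding fit."""

    kd: float  # nM
    tracer_conc: float  # nM
    fp_min: float
    fp_max: float
    se_kd: float
    flag: str = ""  # "wide_interval" when saturation was not approached

    def predict(self, protein_nM) -> np.ndarray:
        fb = bound_fraction(np.asarray(protein_nM, float), self.tracer_conc, self.kd)
        return self.fp_min + (self.fp_max - self.fp_min) * fb


def bound_fraction(protein_nM, tracer_nM: float, kd_nM: float):
    """Exact bound tracer fraction for P + L ⇌ PL at total concentrations.

    Solves the mass-action quadratic; reduces to the hyperbola
    P/(P + Kd) in the limit of vanishing tracer.
    """
    p = np.asarray(protein_nM, dtype=float)
    s = p + tracer_nM + kd_nM
    disc = s**2 - 4.0 * p * tracer_nM
    pl = (s - np.sqrt(np.maximum(disc, 0.0))) / 2.0
    return pl / tracer_nM


def fit_fp_binding(
    protein_nM: Sequence[float],
    polarization: Sequence[float],
    tracer_conc_nM: float,
) -> BindingFit:
    """Fit Kd, fp_min and fp_max to an FP saturation titration.

    Uses the depletion-exact bound fraction, so the fit stays valid
    when the tracer concentration is within an order of magnitude of
    Kd.  Flags the result when the titration does not approach
    saturation (fitted bound fraction < 0.5 at the top concentration).
    """
    p = np.asarray(protein_nM, dtype=float)
    fp = np.asarray(polarization, dtype=float)
    if p.shape != fp.shape:
        raise ValueError("protein and polarization arrays differ in shape")
    if np.unique(p[p > 0]).size < 6:
        raise ValueError("need >= 6 distinct protein concentrations")
    if tracer_conc_nM <= 0:
        raise ValueError(f"tracer_conc_nM must be > 0, got {tracer_conc_nM}")

    def model(pp, kd, fp_min, fp_max):
        return fp_min + (fp_max - fp_min) * bound_fraction(pp, tracer_conc_nM, kd)

    p0 = [float(np.median(p[p > 0])), float(fp.min()), float(fp.max())]
    popt, pcov = optimize.curve_fit(
        model, p, fp, p0=p0,
        bounds=([1e-6, -np.inf, -np.inf], [1e9, np.inf, np.inf]), maxfev=20000,
    )
    kd, fp_min, fp_max = (float(v) for v in popt)
    se_kd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    top_fb = float(bound_fraction(p.max(), tracer_conc_nM, kd))
    flag = "wide_interval" if top_fb < 0.5 else ""
    return BindingFit(kd, tracer_conc_nM, fp_min, fp_max, se_kd, flag)
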