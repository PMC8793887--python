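"""Per-subject and cohort orchestration behind the command-line interface.

``run_subject`` chains preprocessing, geometry, and the hemodynamic maps
for one 4D-flow dataset and writes maps (NIfTI), projections (PNG), the
regional summary (CSV) and a provenance record (JSON). ``run_cohort``
stacks per-subject regional summaries into a subject-level table and runs
the statistics stage.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import PhysicalConstants, REGIONS
from .errors import AortaflowError, DataError, ParameterError
from .field import VelocityField4D, load_field, load_mask, save_mask
from . import geometry as geo
from . import hemodynamics as hd
from . import preprocess as pp
from .cohort_stats import compare_groups, correlate, multivariate_model

log = logging.getLogger(__name__)

#: default span fractions of the four region boundaries
DEFAULT_BOUNDARY_FRACTIONS = (0.10, 0.45, 0.60, 0.80)

HEMO_PARAMS = ("ff", "rf", "stasis", "ke", "peak_velocity")


@dataclass
class RunConfig:
    """Configuration of a single-subject run."""

    data_dir: str
    mask_path: str
    out_dir: str
    subject_id: str = "subject"
    cohort: str = "unknown"
    boundary_fractions: tuple = DEFAULT_BOUNDARY_FRACTIONS
    boundaries_mm: tuple | None = None  #: explicit arc lengths override fractions
    blood_density: float = 1060.0
    viscosity: float = 3.5e-3
    stasis_threshold: float = 0.1
    systole_threshold: float = 0.25
    noise_quantile: float = 0.3
    height_cm: float | None = None
    weight_kg: float | None = None
    seed: int = 0
    write_projections: bool = True

    def constants(self) -> PhysicalConstants:
        return PhysicalConstants(
            blood_density=self.blood_density,
            viscosity=self.viscosity,
            stasis_threshold=self.stasis_threshold,
        )

    def validate(self) -> None:
        for name in ("blood_density", "viscosity", "stasis_threshold", "systole_threshold"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 < self.noise_quantile < 1:
            raise ParameterError("noise_quantile must lie in (0, 1)")
        if not Path(self.data_dir).exists():
            raise DataError(f"input directory {self.data_dir} does not exist")
        if not Path(self.mask_path).exists():
            raise DataError(f"mask {self.mask_path} does not exist")


def run_subject(config: RunConfig) -> pd.DataFrame:
    """Execute preprocess -> geometry -> hemodynamics for one subject.

    Returns the regional summary frame; on error, partial outputs are
    removed before the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_subject_inner(config, out)
    except Exception:
        for p in out.glob("*"):
            if p.is_file():
                p.unlink()
        raise


def _run_subject_inner(config: RunConfig, out: Path) -> pd.DataFrame:
    import nibabel as nib

    constants = config.constants()
    fld = load_field(config.data_dir)
    mask = load_mask(config.mask_path)
    if mask.shape != fld.grid_shape:
        raise DataError("mask shape does not match the velocity grid")

    # preprocessing
    fld = pp.correct_maxwell(fld)
    fld = pp.unwrap_velocity(fld)
    fld = pp.correct_eddy(fld)
    keep = pp.noise_mask(fld, quantile=config.noise_quantile)
    pcmra = pp.compute_pcmra(fld)

    # isotropic analysis grid
    iso, mask_iso = hd.interpolate_isotropic(fld, mask & keep if (mask & keep).any() else mask)

    # geometry
    centerline = geo.extract_centerline(mask_iso, iso.spacing, origin=iso.origin)
    assignment = geo.assign_voxels(mask_iso, centerline, iso.spacing, origin=iso.origin)
    centerline, assignment, flipped = hd.ensure_downstream_orientation(
        iso, centerline, assignment
    )
    if config.boundaries_mm is not None:
        boundaries = np.asarray(config.boundaries_mm, float)
    else:
        boundaries = geo.region_boundaries_from_fractions(
            centerline, config.boundary_fractions
        )
    labels = geo.split_regions(centerline, assignment, boundaries)
    diam_stations = geo.station_diameters(mask_iso, centerline, iso.spacing, origin=iso.origin)
    diameters = geo.measure_diameters(mask_iso, centerline, labels, iso.spacing, origin=iso.origin)

    # hemodynamic maps
    systole = hd.detect_systole(iso, mask_iso, threshold=config.systole_threshold)
    ff, rf = hd.forward_reverse_flow(iso, assignment, centerline)
    maps = {
        "ff": ff,
        "rf": rf,
        "stasis": hd.stasis_map(iso, mask_iso, constants),
        "ke": hd.kinetic_energy_map(iso, mask_iso, constants),
        "peak_velocity": hd.peak_velocity_map(iso, systole, mask_iso),
    }
    georep = None
    if config.height_cm and config.weight_kg:
        georep = geo.geometry_report(diameters, config.height_cm, config.weight_kg)
    summary = hd.regional_summary(maps, labels, georep)
    if georep is None:
        summary["diameter"] = [diameters[r] for r in summary["region"]]
    reynolds = hd.reynolds_number(maps["peak_velocity"], assignment, diam_stations, constants)
    summary["reynolds_vena_contracta"] = reynolds
    summary.insert(0, "subject", config.subject_id)
    summary.insert(1, "cohort", config.cohort)

    # outputs
    aff = np.diag([*iso.spacing, 1.0])
    aff[:3, 3] = iso.origin
    for name, m in maps.items():
        nib.save(nib.Nifti1Image(np.nan_to_num(m, nan=0.0), aff), out / f"{name}.nii.gz")
    nib.save(nib.Nifti1Image(pcmra.data, np.diag([*fld.spacing, 1.0])), out / "pcmra.nii.gz")
    save_mask(mask_iso, iso.spacing, out / "mask_iso.nii.gz", origin=iso.origin)
    summary.to_csv(out / "regional_summary.csv", index=False, float_format="%.6g")

    if config.write_projections:
        _write_projections(maps, out)

    provenance = {
        "package_version": __version__,
        "config": asdict(config),
        "systole_frames": systole.tolist(),
        "centerline_span_mm": centerline.span,
        "centerline_flipped_to_net_flow": flipped,
        "region_boundaries_mm": boundaries.tolist(),
        "preprocess_meta": {
            k: v for k, v in fld.meta.items() if isinstance(v, (int, float, bool, str))
        },
        "reynolds_vena_contracta": reynolds,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return summary


def _write_projections(maps: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, m in maps.items():
        proj = hd.mip_projection(m, "y") if name == "peak_velocity" else hd.mean_projection(m, "y")
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(proj.T, origin="lower", cmap="viridis")
        fig.colorbar(im, ax=ax, label=name)
        ax.set_title(f"{name} ({'MIP' if name == 'peak_velocity' else 'mean'} projection)")
        fig.savefig(out / f"{name}_projection.png", dpi=100)
        plt.close(fig)


def cohort_table_from_summaries(summaries: list[pd.DataFrame], meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pivot per-subject regional summaries into one row per subject."""
    long = pd.concat(summaries, ignore_index=True)
    value_cols = [c for c in HEMO_PARAMS + ("diameter", "indexed_diameter") if c in long.columns]
    wide = long.pivot_table(index=["subject", "cohort"], columns="region", values=value_cols)
    wide.columns = [f"{region}_{param}" for param, region in wide.columns]
    wide = wide.reset_index().rename(columns={"subject": "subject_id"})
    if meta is not None:
        wide = wide.merge(meta, on="subject_id", how="left")
    return wide


def run_cohort(
    table: pd.DataFrame,
    out_dir: str | Path,
    grouping: str = "cohort",
    reference: str | None = "control",
    correlation_region: str = "AAo",
    dependent: str = "AAo_indexed_diameter",
) -> dict:
    """Run the statistics stage over a subject-level cohort table.

    Produces group comparisons per region and parameter, univariate
    correlations of the dependent variable against age and the regional
    hemodynamics, and the multivariate standardized-beta model. Results are
    written as CSV/JSON under ``out_dir`` and returned as a dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = [g for g in pd.unique(table[grouping].dropna())]
    report: dict = {"comparisons": [], "correlations": [], "regression": None}
    if len(groups) < 2:
        log.warning("single-group table: statistics skipped")
        table.to_csv(out / "cohort_table.csv", index=False)
        return report
    if reference not in groups:
        reference = groups[0]

    comp_rows = []
    for region in REGIONS:
        for param in HEMO_PARAMS + ("diameter", "indexed_diameter"):
            col = f"{region}_{param}"
            if col not in table.columns or table[col].dropna().empty:
                continue
            res = compare_groups(table, col, grouping, reference=reference)
            row = {
                "region": region,
                "parameter": param,
                "test": res.test,
                "p": res.p_value,
                "percent_change": res.percent_change,
            }
            for g in res.groups:
                row[f"mean_{g}"] = res.means[g]
                row[f"sd_{g}"] = res.sds[g]
                row[f"n_{g}"] = res.ns[g]
            comp_rows.append(row)
            report["comparisons"].append(row)
    pd.DataFrame(comp_rows).to_csv(out / "group_comparisons.csv", index=False)

    corr_rows = []
    if dependent in table.columns:
        patients = table[table[grouping] != reference]
        cands = ["age"] + [
            f"{correlation_region}_{p}"
            for p in HEMO_PARAMS
            if f"{correlation_region}_{p}" in table.columns
        ]
        cands = [c for c in cands if c in table.columns]
        for c in cands:
            try:
                res = correlate(patients, c, dependent)
            except (DataError, AortaflowError):
                continue
            corr_rows.append(
                {
                    "x": c,
                    "y": dependent,
                    "method": res.method,
                    "r": round(res.r, 3),
                    "p": res.p_value,
                    "significant": res.significant,
                }
            )
        report["correlations"] = corr_rows
        pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)

        hemo_cands = [c for c in cands if c != "age"]
        if len(patients) >= 10 and hemo_cands:
            reg = multivariate_model(patients, dependent, hemo_cands)
            report["regression"] = {
                "dependent": dependent,
                "overall_r": reg.overall_r,
                "std_beta": reg.std_beta,
                "p_values": reg.p_values,
                "dropped_univariate": reg.dropped_univariate,
                "dropped_collinear": reg.dropped_collinear,
            }
            reg.to_frame().to_csv(out / "regression.csv", index=False)

    table.to_csv(out / "cohort_table.csv", index=False)
    (out / "stats_report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
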