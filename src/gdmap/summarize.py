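"""Scalar endpoints per image volume: distribution volume, NA volume, mass.

Units fall out of the voxel geometry: with spacing in mm a voxel's volume in
mm^3 equals its volume in uL (1 mm^3 = 1 uL), so at 0.3 x 0.3 x 2 mm each
voxel is 0.18 uL.  Concentration in mM equals nmol/uL, so summing
concentration times voxel volume over defined voxels gives total contrast
mass in nmol directly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .concentration import ConcentrationMap
from .io_model import BinaryMask, T1Map
from .threshold_segment import ContrastRegion

__all__ = [
    "SummaryRecord",
    "region_volume",
    "total_mass",
    "na_region_volume",
    "implant_volume_from_weight",
    "summarize_run",
    "records_to_csv",
]


@dataclass(frozen=True)
class SummaryRecord:
    """One row of the per-(subject, time point, tissue, arm) summary table."""

    time_point_min: float
    contrast_volume_uL: float
    na_volume_uL: float
    implant_volume_uL: float | None
    adjusted_contrast_volume_uL: float | None
    adjusted_clamped: bool
    total_mass_nmol: float
    tissue: str = "muscle"
    arm: str = "experimental"
    subject: str = ""


def region_volume(mask: BinaryMask, spacing=None) -> float:
    """Volume of a mask in uL: voxel count times voxel volume (mm^3 = uL)."""
    spacing = mask.spacing if spacing is None else spacing
    dx, dy, dz = spacing
    return float(mask.n_voxels * dx * dy * dz)


def total_mass(conc: ConcentrationMap) -> float:
    """Total contrast mass in nmol over voxels with a defined concentration.

    NA voxels (cement, artifact) contribute nothing; mM times uL is nmol.
    """
    dx, dy, dz = conc.spacing
    vox_ul = dx * dy * dz
    defined = conc.defined()
    return float(np.nansum(conc.conc[defined]) * vox_ul)


def na_region_volume(t1_map: T1Map, region: ContrastRegion | None = None) -> float:
    """Volume (uL) of NA voxels, inside the segmented region if one is given.

    With ``region=None`` the whole volume is scanned — both variants are
    useful because an NA excess over the implant volume indicates
    superparamagnetic artifact from very high concentrations.
    """
    na = t1_map.na_mask
    if region is not None:
        na = na & region.mask.mask
    dx, dy, dz = t1_map.spacing
    return float(na.sum() * dx * dy * dz)


def implant_volume_from_weight(weight_g: float, density_g_per_mL: float) -> float:
    """Implant volume in uL from its weight and the cement density."""
    if weight_g < 0 or density_g_per_mL <= 0:
        raise ValueError("weight must be >= 0 and density > 0")
    return weight_g / density_g_per_mL * 1000.0


def summarize_run(
    region: ContrastRegion,
    t1_map: T1Map,
    conc: ConcentrationMap,
    time_point_min: float = 0.0,
    implant_volume_uL: float | None = None,
    tissue: str = "muscle",
    arm: str = "experimental",
    subject: str = "",
) -> SummaryRecord:
    """Assemble the scalar endpoints for one segmented time point.

    The adjusted contrast volume subtracts the implant volume from the
    segmented volume; a negative difference is clamped to zero and flagged.
    """
    cv = region_volume(region.mask)
    nav = na_region_volume(t1_map, region)
    adjusted = None
    clamped = False
    if implant_volume_uL is not None:
        adjusted = cv - implant_volume_uL
        if adjusted < 0:
            adjusted = 0.0
            clamped = True
    return SummaryRecord(
        time_point_min=time_point_min,
        contrast_volume_uL=cv,
        na_volume_uL=nav,
        implant_volume_uL=implant_volume_uL,
        adjusted_contrast_volume_uL=adjusted,
        adjusted_clamped=clamped,
        total_mass_nmol=total_mass(conc),
        tissue=tissue,
        arm=arm,
        subject=subject,
    )


def records_to_csv(records, path: str | Path) -> pd.DataFrame:
    """Write summary records as a tidy CSV (one row per record)."""
    df = pd.DataFrame([asdict(r) for r in records])
    df.to_csv(path, index=False)
    return df
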