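"""End-to-end analysis: label volume in, metric tables and comparisons out.

The sample unit follows the source study's convention: crista-level metrics
(lumen width, apex angle) are compared over pooled cristae, while
organelle-level metrics (diameter, cross-section area, MOM-IBM distance,
junction width, SA/V, cristae volume fraction, lamellarity) are compared
over mitochondria. Per-mitochondrion ids are kept on every crista row so a
nested analysis remains possible downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import volumetrics
from .crista import CristaMetrics, measure_crista, segment_crista_instances
from .geometry import central_crop
from .organelle import (MitoMetrics, cross_sectional_area, mim_mom_distance,
                        mitochondrial_diameter)
from .volume_io import LabelVolume

__all__ = [
    "analyze_volume",
    "cohort_tables",
    "compare_cohorts",
    "CRISTA_LEVEL_METRICS",
    "MITO_LEVEL_METRICS",
]

# metrics compared over pooled cristae vs over mitochondria
CRISTA_LEVEL_METRICS = ["width_mean_A", "apex_angle_deg"]
MITO_LEVEL_METRICS = [
    "diameter_nm", "cross_section_area_nm2", "mim_mom_distance_A",
    "mean_junction_width_A", "sa_to_icsvol_per_A", "cristae_volume_fraction_au",
    "mean_lamellarity_per_nm",
]


def analyze_volume(
    vol: LabelVolume,
    mito_id: str = "",
    crop_frac: float | None = None,
    exclude_boundary: bool = True,
) -> tuple[MitoMetrics, list[CristaMetrics]]:
    """All per-organelle and per-crista measurements for one volume.

    ``crop_frac`` applies a central z crop first; with ``exclude_boundary``
    (default) cristae touching the volume faces are dropped from the
    aggregated statistics (their rows are still returned, flagged).
    """
    if crop_frac is not None:
        vol = central_crop(vol, crop_frac)
    instances = segment_crista_instances(vol)
    crista_metrics = [m for m in (measure_crista(i) for i in instances) if m is not None]
    kept = [m for m in crista_metrics
            if not (exclude_boundary and m.touches_boundary)]
    quality = [m for m in kept if m.well_resolved]

    minor_nm, major_nm = mitochondrial_diameter(vol)
    area_nm2 = cross_sectional_area(vol)
    gap_mean, gap_sd, _ = mim_mom_distance(vol)
    # total membrane area / ICS volume over the well-resolved cristae, from
    # the per-instance meshes (the same attribution that feeds per-crista
    # lamellarity, so the organelle aggregate is consistent by construction)
    tot_area = float(np.sum([m.membrane_area_A2 for m in quality]))
    tot_vol = float(np.sum([m.lumen_volume_A3 for m in quality]))
    if tot_vol > 0:
        sa_per_A = tot_area / tot_vol
        sa_au = sa_per_A * vol.voxel_size_A
    else:
        sa_per_A = sa_au = float("nan")
    fraction = volumetrics.cristae_volume_fraction(vol)

    def _mean(vals):
        vals = [x for x in vals if np.isfinite(x)]
        return float(np.mean(vals)) if vals else float("nan")

    mito = MitoMetrics(
        mito_id=mito_id,
        diameter_nm=minor_nm,
        diameter_major_nm=major_nm,
        cross_section_area_nm2=area_nm2,
        mim_mom_distance_A=gap_mean,
        mim_mom_sd_A=gap_sd,
        shape_class="tubular" if major_nm / minor_nm >= 1.5 else "spheroid",
        n_cristae=len(kept),
        sa_to_icsvol_per_A=sa_per_A,
        sa_to_icsvol_au=sa_au,
        cristae_volume_fraction_au=fraction,
        mean_lamellarity_per_nm=_mean([m.lamellarity_per_nm for m in quality]),
        mean_lumen_width_A=_mean([m.width_mean_A for m in quality]),
        mean_apex_angle_deg=_mean([m.apex_angle_deg for m in quality]),
        mean_junction_width_A=_mean([m.junction_width_A for m in quality]),
    )
    return mito, crista_metrics


def cohort_tables(
    results: list[tuple[MitoMetrics, list[CristaMetrics]]],
    exclude_boundary: bool = True,
    well_resolved_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(mito_table, crista_table) with one row per unit.

    By default the crista table keeps only well-resolved, non-boundary
    cristae - the population entering crista-level group statistics.
    """
    mito_df = pd.DataFrame([asdict(m) for m, _ in results])
    rows = []
    for m, cristae in results:
        for c in cristae:
            if exclude_boundary and c.touches_boundary:
                continue
            if well_resolved_only and not c.well_resolved:
                continue
            row = asdict(c)
            row["mito_id"] = m.mito_id
            rows.append(row)
    crista_df = pd.DataFrame(rows)
    return mito_df, crista_df


def compare_cohorts(
    control: list[tuple[MitoMetrics, list[CristaMetrics]]],
    patient: list[tuple[MitoMetrics, list[CristaMetrics]]],
    alpha: float = 0.05,
    holm: bool = False,
) -> list:
    """GroupComparisons for the standard metric panel, at the study's units."""
    from .stats import compare_conditions

    c_mito, c_crista = cohort_tables(control)
    p_mito, p_crista = cohort_tables(patient)
    units = {m: "mitochondrion" for m in MITO_LEVEL_METRICS}
    units.update({m: "crista" for m in CRISTA_LEVEL_METRICS})
    comps = compare_conditions(c_crista, p_crista, metrics=CRISTA_LEVEL_METRICS,
                               units=units, alpha=alpha, holm=holm)
    comps += compare_conditions(c_mito, p_mito, metrics=MITO_LEVEL_METRICS,
                                units=units, alpha=alpha, holm=holm)
    return comps


def comparison_report(comparisons) -> dict:
    """JSON-serializable report mirroring the per-metric comparison panels."""
    out = {}
    for c in comparisons:
        out[c.metric] = {
            "unit": c.unit,
            "control": dataclasses.asdict(c.control),
            "patient": dataclasses.asdict(c.patient),
            "U": c.u_statistic,
            "p_value": c.p_value,
            "p_adjusted": c.p_adjusted,
            "significant": c.significant,
            "direction": c.direction,
        }
    return out
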