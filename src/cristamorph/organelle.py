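"""Whole-mitochondrion measurements.

These are the "standardized mitochondrial measurements": diameter and
cross-sectional area in the central z slice, and the MOM-to-IBM membrane
separation. The central slice mirrors the practice of restricting analyses
to the middle of the tomogram; "diameter" is the minor-axis Feret diameter
there, so tubular mitochondria report their width rather than their length
(the major axis is emitted alongside for transparency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import boundary_voxels
from .volume_io import Compartment, LabelVolume

__all__ = [
    "MitoMetrics",
    "mitochondrial_diameter",
    "cross_sectional_area",
    "mim_mom_distance",
]


@dataclass
class MitoMetrics:
    """Per-organelle measurement record.

    ``sa_to_icsvol_au`` and ``cristae_volume_fraction_au`` are the
    voxel-normalized dimensionless ratios; physical-unit twins are emitted
    alongside. ``mim_mom_*`` dispersion is the SD over boundary voxels, and
    every aggregated crista statistic reports the per-organelle mean over
    its (non-boundary-touching) cristae.
    """

    mito_id: str
    diameter_nm: float
    diameter_major_nm: float
    cross_section_area_nm2: float
    mim_mom_distance_A: float
    mim_mom_sd_A: float
    shape_class: str                      # "spheroid" | "tubular"
    n_cristae: int
    sa_to_icsvol_per_A: float
    sa_to_icsvol_au: float
    cristae_volume_fraction_au: float
    mean_lamellarity_per_nm: float
    mean_lumen_width_A: float
    mean_apex_angle_deg: float
    mean_junction_width_A: float


def _central_mom_slice(vol: LabelVolume) -> np.ndarray:
    mom = vol.mask(Compartment.MOM)
    if not mom.any():
        raise ValueError("no MOM (code 1) in volume")
    z = vol.shape[0] // 2
    sl = mom[z]
    if not sl.any():
        raise ValueError(f"central slice z={z} contains no MOM; crop or re-centre the volume")
    return sl


def _filled_contour(vol: LabelVolume) -> np.ndarray:
    sl = _central_mom_slice(vol)
    filled = ndimage.binary_fill_holes(sl)
    if not (filled & ~sl).any():
        raise ValueError(
            "open MOM contour in the central slice (no enclosed interior); "
            "consider repairing the wedge-eroded membrane or using central_crop"
        )
    return filled


def _min_max_feret_A(filled: np.ndarray, voxel_size_A: float) -> tuple[float, float]:
    """Minor/major Feret diameters of a filled 2D region via rotating calipers
    on the convex hull of its pixel centres (+1 px for pixel extent)."""
    pts = np.argwhere(filled).astype(float)
    if len(pts) < 3:
        ext = pts.max(axis=0) - pts.min(axis=0) + 1
        return float(min(ext) * voxel_size_A), float(max(ext) * voxel_size_A)
    from scipy.spatial import ConvexHull

    hull = pts[ConvexHull(pts).vertices]
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    norms = np.linalg.norm(edges, axis=1)
    dirs = edges[norms > 0] / norms[norms > 0, None]
    normals = np.stack([-dirs[:, 1], dirs[:, 0]], axis=1)
    proj = hull @ normals.T                       # (n_hull, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    minor = widths.min()
    # major Feret = max pairwise distance between hull points
    d2 = np.sum((hull[:, None, :] - hull[None, :, :]) ** 2, axis=2)
    major = np.sqrt(d2.max())
    return (float((minor + 1.0) * voxel_size_A), float((major + 1.0) * voxel_size_A))


def mitochondrial_diameter(vol: LabelVolume) -> tuple[float, float]:
    """(minor, major) Feret diameter in nm of the MOM-enclosed region in the
    central z slice."""
    filled = _filled_contour(vol)
    minor_A, major_A = _min_max_feret_A(filled, vol.voxel_size_A)
    return minor_A / 10.0, major_A / 10.0


def cross_sectional_area(vol: LabelVolume) -> float:
    """Area (nm^2) enclosed by the MOM contour in the central z slice."""
    filled = _filled_contour(vol)
    return float(np.count_nonzero(filled)) * (vol.voxel_size_A / 10.0) ** 2


def mim_mom_distance(vol: LabelVolume, max_sample: int = 10_000) -> tuple[float, float, int]:
    """Mean +- SD MOM-to-IBM membrane separation in Angstrom.

    For every IBM voxel facing the intermembrane gap, the nearest-MOM-voxel
    distance is taken and one voxel is subtracted to convert centre-to-centre
    into the surface-to-surface separation. Crista-junction openings
    contribute only their rim voxels, whose distances match the
    surrounding gap. Returns ``(mean, sd, n)``.
    """
    ibm = vol.mask(Compartment.IBM)
    mom = vol.mask(Compartment.MOM)
    if not ibm.any():
        raise ValueError("no IBM (code 2) in volume")
    if not mom.any():
        raise ValueError("no MOM (code 1) in volume")
    bg = vol.mask(Compartment.BACKGROUND)
    face = boundary_voxels(ibm) & ndimage.binary_dilation(
        bg, structure=ndimage.generate_binary_structure(3, 1))
    if not face.any():
        raise ValueError("IBM has no face toward the intermembrane gap")
    from scipy.spatial import cKDTree

    fpts = np.argwhere(face)
    if len(fpts) > max_sample:
        fpts = fpts[::int(np.ceil(len(fpts) / max_sample))]
    # nearest MOM voxel lies on the MOM's own boundary shell
    tree = cKDTree(np.argwhere(boundary_voxels(mom)))
    dist, _ = tree.query(fpts, k=1)
    d = np.maximum(dist * vol.voxel_size_A - vol.voxel_size_A, 0.0)
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return float(np.mean(d)), sd, int(d.size)
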