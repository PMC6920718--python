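"""Targeted 3D morphometry on percent-bone-length VOIs.

VOIs are defined on the percent grid (e.g. metaphyseal secondary
spongiosa 81–85%, epiphyseal 93–97%, diaphyseal cortex 58–62%) and cut
from the stack-level compartment masks.  Trabecular parameters: BV/TV,
direct (maximal-inscribed-sphere) Tb.Th and Tb.Sp, plate-model Tb.N,
bone pattern factor Tb.Pf, connectivity density Conn.D, surface-to-volume
ratio BS/BV and the un-plate index uPi = Tb.Th_direct / (2·BV/BS), which
is ≈1 for ideal plates and ≈2 for ideal rods.  Cortical parameters:
direct 3D Ct.Th plus slice-wise areas, J and Ecc averaged over the VOI.

Numerical conventions:

* bone surface = marching-cubes mesh area at the 0.5 iso-level of a
  σ = 1 px Gaussian-smoothed volume, *without* padding, so structures
  cut by a VOI face are left open rather than capped;
* direct thickness = distance-transform covering (descending radii);
* Euler characteristic χ = V − E + F − C of the cube complex of
  foreground voxels (26-connected foreground interpretation);
  Conn.D = (1 − χ) / VOI volume;
* Tb.Pf = (S1 − S2)/(V1 − V2) with surface/volume before and after one
  dilation by a 3×3×3 structuring element.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .axis_align import SpecimenFrame
from .compartments import CompartmentMasks
from .errors import ValidationError
from .slice_morph import eccentricity, polar_moment

_SURFACE_SIGMA = 1.0

#: VOI presets (percent bone length).  The metaphyseal trabecular window is
#: 81–85%; a 76–80% variant is also shipped for users who prefer a more
#: proximal metaphyseal sample.
PRESET_VOIS = {
    "trab_meta": ("trabecular", 81.0, 85.0),
    "trab_meta_proximal": ("trabecular", 76.0, 80.0),
    "trab_epi": ("trabecular", 93.0, 97.0),
    "cort_dia": ("cortical", 58.0, 62.0),
    "cort_meta": ("cortical", 81.0, 85.0),
}


@dataclass
class VOISpec:
    """A named percent-length window in one compartment."""

    name: str
    lo_percent: float
    hi_percent: float
    compartment: str  # "trabecular" | "cortical"

    def __post_init__(self) -> None:
        if not (40.0 <= self.lo_percent < self.hi_percent <= 100.0):
            raise ValidationError(
                f"VOI {self.name!r}: require 40 <= lo < hi <= 100, "
                f"got [{self.lo_percent}, {self.hi_percent}]"
            )
        if self.compartment not in ("trabecular", "cortical"):
            raise ValidationError(f"unknown compartment {self.compartment!r}")

    @classmethod
    def preset(cls, name: str) -> "VOISpec":
        comp, lo, hi = PRESET_VOIS[name]
        return cls(name, lo, hi, comp)


@dataclass
class VOI3DMetrics:
    """Averaged 3D morphometry of one VOI (mm-based units)."""

    bv_tv: float = 0.0
    tb_th: float = 0.0
    tb_n: float = 0.0
    tb_sp: float = 0.0
    tb_pf: float = 0.0
    conn_d: float = 0.0
    bs_bv: float = 0.0
    upi: float = 0.0
    ct_th: float = 0.0
    ct_ar: float = 0.0
    tt_ar: float = 0.0
    ma_ar: float = 0.0
    j: float = 0.0
    ecc: float = 0.0
    flags: str = ""

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls) if f.name != "flags"]


def extract_voi(
    masks: CompartmentMasks, frame: SpecimenFrame, spec: VOISpec
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the (bone, region) sub-volumes whose percent ∈ [lo, hi).

    Returns ``(bone, roi)``: trabecular bone within the trabecular ROI,
    or cortical bone within the periosteal region.
    """
    pct = frame.percent_array()
    sel = np.flatnonzero((pct >= spec.lo_percent) & (pct < spec.hi_percent))
    if sel.size == 0:
        lo, hi = pct.min(), pct.max()
        raise ValidationError(
            f"VOI {spec.name!r} [{spec.lo_percent}, {spec.hi_percent}) outside "
            f"covered percent range [{lo:.2f}, {hi:.2f}]"
        )
    sel = np.sort(sel)
    if spec.compartment == "trabecular":
        return masks.trabecular_bone[sel], masks.trabecular_roi[sel]
    return masks.cortical_mask[sel], masks.periosteal_region[sel]


def surface_area(volume: np.ndarray, *, sigma: float = _SURFACE_SIGMA) -> float:
    """Marching-cubes surface area (px²) of a 3D boolean volume."""
    volume = np.asarray(volume, dtype=bool)
    if not volume.any():
        return 0.0
    img = ndi.gaussian_filter(volume.astype(np.float32), sigma) if sigma else volume.astype(np.float32)
    if img.max() <= 0.5 or img.min() >= 0.5:
        # smoothing flattened the field (feature below resolvable size)
        img = volume.astype(np.float32)
        if img.max() <= 0.5 or img.min() >= 0.5:
            return 0.0
    verts, faces_, _, _ = measure.marching_cubes(img, 0.5)
    return float(measure.mesh_surface_area(verts, faces_))


def local_thickness_3d(volume: np.ndarray) -> np.ndarray:
    """Maximal-inscribed-sphere diameter map (px) of a 3D volume."""
    volume = np.asarray(volume, dtype=bool)
    lt = np.zeros(volume.shape, dtype=np.float32)
    if not volume.any():
        return lt
    dt = ndi.distance_transform_edt(volume)
    for r in np.unique(dt[volume])[::-1]:
        if r <= 0:
            break
        todo = volume & (lt == 0)
        if not todo.any():
            break
        seeds = dt >= r
        covered = ndi.distance_transform_edt(~seeds) <= r
        lt[covered & todo] = 2 * r
    return lt


def _maxpool(a: np.ndarray, axes) -> np.ndarray:
    for ax in axes:
        pad = [(1, 1) if i == ax else (0, 0) for i in range(a.ndim)]
        a = np.pad(a, pad)
        s1 = tuple(slice(1, None) if i == ax else slice(None) for i in range(a.ndim))
        s2 = tuple(slice(None, -1) if i == ax else slice(None) for i in range(a.ndim))
        a = a[s1] | a[s2]
    return a


def euler_characteristic(volume: np.ndarray) -> int:
    """χ = V − E + F − C of the cube complex of the foreground voxels.

    Counts the vertices, edges, faces and cubes of the union of closed
    unit cubes; equivalent to the 26-connected-foreground Euler number
    (solid ball 1, solid torus 0, hollow shell 2).
    """
    v = np.asarray(volume, dtype=bool)
    if not v.any():
        return 0
    cubes = int(np.count_nonzero(v))
    faces = sum(int(np.count_nonzero(_maxpool(v, [ax]))) for ax in range(3))
    edges = sum(
        int(np.count_nonzero(_maxpool(v, axes)))
        for axes in ([1, 2], [0, 2], [0, 1])
    )
    verts = int(np.count_nonzero(_maxpool(v, [0, 1, 2])))
    return verts - edges + faces - cubes


def trabecular_3d(
    bone: np.ndarray, roi: np.ndarray, voxel_size_mm: float
) -> VOI3DMetrics:
    """All trabecular 3D parameters of one VOI."""
    bone = np.asarray(bone, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    m = VOI3DMetrics()
    roi_vox = int(roi.sum())
    if roi_vox == 0:
        raise ValidationError("empty VOI roi")
    bone_vox = int(bone.sum())
    m.bv_tv = bone_vox / roi_vox
    a = voxel_size_mm
    if bone_vox == 0:
        m.flags = "no-bone"
        return m

    bs_px2 = surface_area(bone)
    bv_px3 = float(bone_vox)
    m.bs_bv = (bs_px2 / bv_px3) / a if bs_px2 > 0 else 0.0

    lt = local_thickness_3d(bone)
    m.tb_th = float(lt[bone].mean()) * a

    background = roi & ~bone
    if background.any():
        # separation: inscribed spheres in marrow, restricted to the roi
        lt_bg = local_thickness_3d(background)
        m.tb_sp = float(lt_bg[background].mean()) * a

    m.tb_n = m.bv_tv / m.tb_th if m.tb_th > 0 else 0.0

    if bs_px2 > 0:
        plate_th_px = 2.0 * bv_px3 / bs_px2
        m.upi = (m.tb_th / a) / plate_th_px

    dilated = ndi.binary_dilation(bone, structure=np.ones((3, 3, 3), bool))
    s1, v1 = bs_px2, bv_px3
    s2, v2 = surface_area(dilated), float(dilated.sum())
    if v2 > v1:
        m.tb_pf = ((s1 - s2) / (v1 - v2)) / a

    chi = euler_characteristic(bone)
    m.conn_d = (1.0 - chi) / (roi_vox * a**3)
    return m


def cortical_3d(
    cortical: np.ndarray, periosteal: np.ndarray, voxel_size_mm: float
) -> VOI3DMetrics:
    """Cortical 3D parameters: direct Ct.Th plus slice-averaged section values."""
    cortical = np.asarray(cortical, dtype=bool)
    periosteal = np.asarray(periosteal, dtype=bool)
    m = VOI3DMetrics()
    if not cortical.any():
        m.flags = "empty-cortex"
        return m
    a = voxel_size_mm
    lt = local_thickness_3d(cortical)
    m.ct_th = float(lt[cortical].mean()) * a

    ct_ar, tt_ar, ma_ar, j, ecc = [], [], [], [], []
    for i in range(cortical.shape[0]):
        if not cortical[i].any():
            continue
        ct_px = int(cortical[i].sum())
        tt_px = int(periosteal[i].sum())
        ct_ar.append(ct_px * a**2)
        tt_ar.append(tt_px * a**2)
        ma_ar.append((tt_px - ct_px) * a**2)
        j.append(polar_moment(cortical[i], a))
        ecc.append(eccentricity(periosteal[i]))
    m.ct_ar = float(np.mean(ct_ar))
    m.tt_ar = float(np.mean(tt_ar))
    m.ma_ar = float(np.mean(ma_ar))
    m.j = float(np.mean(j))
    m.ecc = float(np.mean(ecc))
    return m
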