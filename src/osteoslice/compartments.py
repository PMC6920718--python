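"""Per-slice separation of cortical bone, trabecular ROI and contours.

Each cross-section is decomposed into

* ``periosteal_region`` — the filled area enclosed by the periosteum,
  obtained by morphologically closing the largest connected bone
  component and filling its holes;
* ``cortical_mask`` — bone 8-connected to the periosteal boundary (the
  outer shell), with thin bone bridges to interior trabeculae detached
  by a configurable erosion depth ("bridge cut");
* ``trabecular_roi`` — the medullary region in which trabeculae are
  measured: periosteal region minus cortex minus a guard band so
  endocortical surface roughness is not counted as trabeculae;
* ``trabecular_bone`` — raw foreground inside the trabecular ROI.

The decomposition is 2D per slice, mirroring the slice-wise analysis
design; empty (gap) slices yield empty masks without error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

from .errors import SegmentationError
from .stack_io import BinaryStack

#: minimum residue-component area (px) reassigned from cortex to trabecular
#: bone by the bridge cut; smaller residues are rasterization jaggies
_MIN_TRABECULAR_RESIDUE_PX = 6


@dataclass
class SegmentationParams:
    """Tunable parameters of the compartment segmentation.

    closing_radius_px : radius of the morphological closing that seals
        small cortical breaches (vascular channels etc.) before hole
        filling; also the default guard-band width.
    min_cortex_area_px : slices whose detected cortex is smaller than
        this are QC-flagged.
    bridge_cut_px : erosion depth used to detach trabeculae that touch
        the cortex through thin connections; 0 disables the cut.
    guard_band_px : distance from the endocortical boundary excluded
        from the trabecular ROI (defaults to ``closing_radius_px``).
    """

    closing_radius_px: int = 3
    min_cortex_area_px: int = 64
    bridge_cut_px: int = 2
    guard_band_px: int | None = None

    @property
    def guard(self) -> int:
        return self.closing_radius_px if self.guard_band_px is None else self.guard_band_px


@dataclass
class SliceCompartments:
    """Compartment masks for a single slice (2D boolean arrays)."""

    cortical_mask: np.ndarray
    trabecular_roi: np.ndarray
    trabecular_bone: np.ndarray
    periosteal_region: np.ndarray
    flags: list = field(default_factory=list)


@dataclass
class CompartmentMasks:
    """Stack-level compartment masks (3D boolean arrays) plus per-slice QC."""

    cortical_mask: np.ndarray
    trabecular_roi: np.ndarray
    trabecular_bone: np.ndarray
    periosteal_region: np.ndarray
    qc: pd.DataFrame


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def _open_cortex_flag(closed: np.ndarray, filled: np.ndarray, fg: np.ndarray) -> bool:
    """Heuristic for a cortex the closing failed to seal into a ring.

    A closed ring encloses a cavity (hole filling adds area).  If no
    cavity was enclosed but the shape has a large convex deficiency, the
    section is an open "C" rather than a solid one.
    """
    enclosed = filled.sum() - closed.sum()
    if enclosed > 0:
        return False
    area = int(filled.sum())
    if area == 0:
        return False
    coords = np.argwhere(filled)
    from scipy.spatial import ConvexHull, QhullError

    if len(coords) < 4:
        return False
    try:
        hull_area = ConvexHull(coords).volume  # 2D hull "volume" is area
    except QhullError:
        return False
    return (hull_area - area) / max(hull_area, 1.0) > 0.10


def segment_slice(
    slice_mask: np.ndarray,
    closing_radius_px: int = 3,
    min_cortex_area_px: int = 64,
    bridge_cut_px: int = 2,
    guard_band_px: int | None = None,
) -> SliceCompartments:
    """Decompose one binarized cross-section into compartments.

    Empty slices return all-empty masks with no error.
    """
    fg = np.asarray(slice_mask, dtype=bool)
    empty = np.zeros_like(fg)
    if not fg.any():
        return SliceCompartments(empty, empty.copy(), empty.copy(), empty.copy(), ["empty"])

    guard = closing_radius_px if guard_band_px is None else guard_band_px
    flags: list = []

    largest = _largest_component(fg)
    # closing with explicit padding: scipy's closing erodes at the array
    # border for structuring elements larger than the margin
    pad = closing_radius_px + 1
    padded = np.pad(largest, pad)
    closed = ndi.binary_erosion(
        ndi.binary_dilation(padded, structure=disk(closing_radius_px)),
        structure=disk(closing_radius_px), border_value=1,
    )[pad:-pad, pad:-pad]
    periosteal = ndi.binary_fill_holes(closed)

    if _open_cortex_flag(closed, periosteal, fg):
        flags.append("open_cortex")

    # bone 8-connected to the periosteal boundary is cortical
    ring = periosteal & ~ndi.binary_erosion(periosteal, structure=disk(1))
    seed = fg & ndi.binary_dilation(ring, structure=disk(1))
    attached = ndi.binary_propagation(seed, mask=fg, structure=np.ones((3, 3), int))

    cortical = attached
    if bridge_cut_px > 0 and attached.any():
        eroded = ndi.binary_erosion(attached, structure=disk(bridge_cut_px))
        near_ring = ndi.binary_dilation(ring, structure=disk(bridge_cut_px + 1))
        core = ndi.binary_propagation(
            eroded & near_ring, mask=eroded, structure=np.ones((3, 3), int)
        )
        recovered = ndi.binary_dilation(core, structure=disk(bridge_cut_px)) & attached
        residue = attached & ~recovered
        labels, n = ndi.label(residue, structure=np.ones((3, 3), int))
        if n:
            sizes = np.bincount(labels.ravel())
            detach = np.isin(labels, np.flatnonzero(sizes > _MIN_TRABECULAR_RESIDUE_PX))
            detach &= labels > 0
            cortical = attached & ~detach

    if cortical.sum() < min_cortex_area_px:
        flags.append("small_cortex")

    # trabecular ROI: medullary area at least `guard` px from cortex/exterior
    excluded = cortical | ~periosteal
    if guard > 0:
        excluded = ndi.binary_dilation(excluded, structure=disk(guard))
    roi = periosteal & ~excluded & ~cortical
    trabecular = fg & roi
    return SliceCompartments(cortical, roi, trabecular, periosteal, flags)


def segment_stack(
    stack: BinaryStack,
    params: SegmentationParams | None = None,
    *,
    max_flagged_fraction: float = 0.20,
) -> CompartmentMasks:
    """Apply :func:`segment_slice` to every slice of an aligned stack.

    Raises
    ------
    SegmentationError
        If more than ``max_flagged_fraction`` of non-empty slices carry
        QC flags other than "empty".
    """
    params = params or SegmentationParams()
    shape = stack.shape
    cortical = np.zeros(shape, dtype=bool)
    roi = np.zeros(shape, dtype=bool)
    trab = np.zeros(shape, dtype=bool)
    perio = np.zeros(shape, dtype=bool)
    records = []
    for i in range(shape[0]):
        sc = segment_slice(
            stack.voxels[i],
            closing_radius_px=params.closing_radius_px,
            min_cortex_area_px=params.min_cortex_area_px,
            bridge_cut_px=params.bridge_cut_px,
            guard_band_px=params.guard_band_px,
        )
        cortical[i], roi[i], trab[i], perio[i] = (
            sc.cortical_mask, sc.trabecular_roi, sc.trabecular_bone, sc.periosteal_region,
        )
        records.append({"slice": i, "flags": ";".join(sc.flags)})
    qc = pd.DataFrame(records)

    in_range = qc[~qc["flags"].str.contains("empty")]
    flagged = in_range[in_range["flags"] != ""]
    if len(in_range) and len(flagged) / len(in_range) > max_flagged_fraction:
        raise SegmentationError(
            f"{len(flagged)}/{len(in_range)} slices flagged: "
            f"{flagged['slice'].tolist()[:20]}"
        )
    return CompartmentMasks(cortical, roi, trab, perio, qc)
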