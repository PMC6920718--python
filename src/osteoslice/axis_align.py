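"""Principal-axis alignment and the percent-bone-length coordinate frame.

A scanned long-bone segment must have its shaft centreline parallel to
the slice axis before slice-wise morphometry is meaningful.  Instead of
interactive rigid co-registration to a reference animal, each specimen is
aligned automatically to its own first principal axis of the foreground
voxel distribution; specimens are then compared on a shared
percent-bone-length grid, which is the quantity the statistics operate
on.  Axial spin about the shaft is left unconstrained.

Percent bone length is measured from the proximal end of the intact
bone, so the distal end of the scanned segment maps to 100% and percent
decreases by ``100 * voxel_size_mm / L`` per slice moving proximally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import AlignmentError, ConfigurationError
from .stack_io import BinaryStack, SpecimenMeta


def principal_axis(voxels: np.ndarray) -> np.ndarray:
    """Unit first principal axis of the foreground voxel cloud.

    Eigenvector of the largest eigenvalue of the coordinate covariance
    matrix, oriented to have a non-negative slice-axis component.
    """
    coords = np.argwhere(voxels)
    if len(coords) == 0:
        raise AlignmentError("empty foreground")
    cov = np.cov(coords.T.astype(float))
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    if axis[0] < 0:
        axis = -axis
    return axis


def axis_angle_deg(voxels: np.ndarray) -> float:
    """Angle (degrees) between the foreground principal axis and axis 0."""
    axis = principal_axis(voxels)
    return float(np.degrees(np.arccos(np.clip(abs(axis[0]), -1.0, 1.0))))


def _rotation_matrix_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix (Rodrigues) taking ``axis`` onto the slice axis e0."""
    e0 = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, e0)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, e0))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def align_to_principal_axis(
    stack: BinaryStack, *, max_iter: int = 3, tol_deg: float = 0.5
) -> BinaryStack:
    """Rigidly rotate a stack so the shaft centreline is the slice axis.

    Trilinear interpolation followed by re-binarization at 0.5 keeps the
    foreground volume conserved in expectation.  The volume is padded so
    no foreground is rotated out of frame.  Iterates (up to ``max_iter``)
    because interpolation can shift the measured axis slightly.

    Raises
    ------
    AlignmentError
        If the foreground is empty or confined to a single slice plane
        (no measurable long axis).
    """
    vox = stack.voxels
    occupied = np.flatnonzero(vox.any(axis=(1, 2)))
    if occupied.size == 0:
        raise AlignmentError("empty foreground")
    if occupied.size == 1:
        raise AlignmentError("foreground confined to a single slice plane")

    angle = axis_angle_deg(vox)
    if angle <= tol_deg:
        return BinaryStack(vox.copy(), stack.voxel_size_mm, stack.slice_axis_direction)

    # pad to a cube large enough to hold any rigid rotation of the content
    diag = int(np.ceil(np.linalg.norm(vox.shape))) + 2
    padded = np.zeros((diag,) * 3, dtype=bool)
    off = [(diag - s) // 2 for s in vox.shape]
    padded[off[0]:off[0] + vox.shape[0],
           off[1]:off[1] + vox.shape[1],
           off[2]:off[2] + vox.shape[2]] = vox

    out = padded.astype(np.float32)
    center = (np.array(out.shape) - 1) / 2.0
    for _ in range(max_iter):
        cur = out >= 0.5
        angle = axis_angle_deg(cur)
        if angle <= tol_deg:
            break
        rot = _rotation_matrix_to_z(principal_axis(cur))
        # affine_transform maps output coords through `matrix` to input coords
        inv = rot.T
        offset = center - inv @ center
        out = ndi.affine_transform(out, inv, offset=offset, order=1, prefilter=False)
    aligned = out >= 0.5

    # crop back to the foreground bounding box (with 1-voxel margin)
    coords = np.argwhere(aligned)
    lo = np.maximum(coords.min(axis=0) - 1, 0)
    hi = np.minimum(coords.max(axis=0) + 2, aligned.shape)
    aligned = aligned[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return BinaryStack(aligned, stack.voxel_size_mm, stack.slice_axis_direction)


@dataclass
class SpecimenFrame:
    """Affine mapping between slice index and percent bone length.

    ``distal_end_slice`` maps to exactly 100%; the per-slice step is
    ``100 * voxel_size_mm / bone_length_mm`` percent, decreasing moving
    proximally.
    """

    distal_end_slice: int
    bone_length_mm: float
    voxel_size_mm: float
    n_slices: int
    slice_axis_direction: str = "distal_increasing"

    @property
    def percent_per_slice(self) -> float:
        return 100.0 * self.voxel_size_mm / self.bone_length_mm

    def _signed_distal_distance(self, index) -> np.ndarray:
        """Distance in slices from `index` to the distal end (positive = proximal)."""
        index = np.asarray(index)
        if self.slice_axis_direction == "distal_increasing":
            return self.distal_end_slice - index
        return index - self.distal_end_slice

    def percent_of_slice(self, index):
        """Percent bone length of slice ``index`` (scalar or array)."""
        out = 100.0 - self._signed_distal_distance(index) * self.percent_per_slice
        return float(out) if np.isscalar(index) else out

    def slice_at_percent(self, percent):
        """Nearest slice index for a percent position (inverse mapping)."""
        dist = (100.0 - np.asarray(percent, dtype=float)) / self.percent_per_slice
        if self.slice_axis_direction == "distal_increasing":
            idx = np.round(self.distal_end_slice - dist)
        else:
            idx = np.round(self.distal_end_slice + dist)
        idx = np.clip(idx, 0, self.n_slices - 1).astype(int)
        return int(idx) if np.isscalar(percent) else idx

    def percent_array(self) -> np.ndarray:
        """Percent bone length for every slice index of the stack."""
        return self.percent_of_slice(np.arange(self.n_slices))

    def mm_per_percent(self) -> float:
        return self.bone_length_mm / 100.0


def build_frame(stack: BinaryStack, meta: SpecimenMeta) -> SpecimenFrame:
    """Construct the percent-length frame for one specimen.

    If the manifest does not set ``distal_end_slice``, the most distal
    foreground slice is used (only the distal portion of the bone is
    scanned, so the distal landmark is the available anchor).
    """
    distal = meta.distal_end_slice
    if distal is None:
        occupied = np.flatnonzero(stack.voxels.any(axis=(1, 2)))
        if occupied.size == 0:
            raise ConfigurationError(
                "distal_end_slice unset and stack has no foreground to infer it from"
            )
        distal = int(occupied[-1] if stack.slice_axis_direction == "distal_increasing"
                     else occupied[0])
    if meta.bone_length_mm is None or not meta.bone_length_mm > 0:
        raise ConfigurationError("bone_length_mm must be set and positive")
    return SpecimenFrame(
        distal_end_slice=int(distal),
        bone_length_mm=float(meta.bone_length_mm),
        voxel_size_mm=float(stack.voxel_size_mm),
        n_slices=stack.n_slices,
        slice_axis_direction=stack.slice_axis_direction,
    )
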