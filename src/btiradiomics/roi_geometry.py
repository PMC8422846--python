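"""Brain-tumor-interface ROI construction and volume metrics.

Nine regions of interest are built per subject from the tumor mask: four
interface bands (BTI) obtained by moving the tumor outline N mm inward and
N mm outward (N in {2, 3, 4, 5}, band full width 2N mm), four combined
regions (COM = tumor united with its band), and the whole tumor (WT).
Bands are intersected with the brain mask and skull-adjacent voxels are
removed, automating the manual skull-exclusion step of interface radiomics
workflows.

Signed distances are Euclidean in physical millimetres and honor
anisotropic spacing.  Two backends are provided:

``edt``
    distance from each voxel center to the nearest voxel center of the
    opposite class (exactly reproducible with a brute-force pairwise
    oracle); negative inside, positive outside.
``mesh``
    distance to the 0.5-level marching-cubes surface of the lightly
    smoothed mask, evaluated on a narrow band around the interface.  This
    sub-voxel surface makes band volumes on digital spheres agree with the
    analytic shell volume to within a few percent and is the default for
    geometry metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .grids import MaskVolume, VoxelGrid

__all__ = [
    "RoiSpec",
    "ALL_ROI_SPECS",
    "VolumeMetrics",
    "signed_distance",
    "make_roi",
    "build_region_set",
    "volume_metrics",
    "mesh_volume_ml",
]

_LEGAL_KINDS = ("BTI", "COM", "WT")
_LEGAL_N = (2, 3, 4, 5)


@dataclass(frozen=True)
class RoiSpec:
    """One of the nine legal ROI definitions."""

    kind: str
    half_width_mm: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _LEGAL_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "WT":
            if self.half_width_mm is not None:
                object.__setattr__(self, "half_width_mm", None)
        elif self.half_width_mm not in _LEGAL_N:
            raise ValueError(
                f"half width must be one of {_LEGAL_N} for {self.kind}, got {self.half_width_mm}"
            )

    @property
    def name(self) -> str:
        if self.kind == "WT":
            return "WT"
        return f"{self.kind}{self.half_width_mm}mm"


#: The nine ROI definitions of the interface analysis, in canonical order.
ALL_ROI_SPECS: tuple[RoiSpec, ...] = tuple(
    [RoiSpec("BTI", n) for n in _LEGAL_N]
    + [RoiSpec("COM", n) for n in _LEGAL_N]
    + [RoiSpec("WT")]
)


@dataclass
class VolumeMetrics:
    """Tumor volume (TV), peritumoral edema volume (PEV) and index (PEI)."""

    TV_ml: float
    PEV_ml: float
    PEI: float
    TV_mesh_ml: float | None = None


def _check_mask(mask: MaskVolume) -> None:
    n = mask.voxel_count
    if n == 0:
        raise ValueError("mask is empty")
    if n == mask.data.size:
        raise ValueError("mask covers the whole grid")


def signed_distance(mask: MaskVolume, method: str = "edt") -> np.ndarray:
    """Signed Euclidean distance (mm) to the mask surface.

    Negative inside the mask, positive outside.  ``method='edt'`` measures
    center-to-nearest-opposite-center; ``method='mesh'`` measures to the
    sub-voxel 0.5-level surface (narrow band of +-8 mm, beyond which the
    edt value is used).
    """
    _check_mask(mask)
    m = mask.data
    sp = mask.grid.spacing_mm
    d_out = ndimage.distance_transform_edt(~m, sampling=sp)
    d_in = ndimage.distance_transform_edt(m, sampling=sp)
    sd = np.where(m, -d_in, d_out)
    if method == "edt":
        return sd
    if method != "mesh":
        raise ValueError(f"unknown method {method!r}")
    return _mesh_refine(sd, m, sp)


def _surface_cloud(m: np.ndarray, sp: tuple[float, float, float], sigma_vox: float = 0.8):
    """Vertices + face centroids of the smoothed 0.5-level surface."""
    f = ndimage.gaussian_filter(m.astype(np.float32), sigma_vox)
    f = np.pad(f, 1)
    verts, faces, _, _ = measure.marching_cubes(f, level=0.5, spacing=sp)
    verts -= np.asarray(sp)
    cent = verts[faces].mean(axis=1)
    return np.vstack([verts, cent]), verts, faces


def _mesh_refine(sd: np.ndarray, m: np.ndarray, sp: tuple[float, float, float],
                 band_mm: float = 8.0) -> np.ndarray:
    cloud, _, _ = _surface_cloud(m, sp)
    tree = cKDTree(cloud)
    near = np.abs(sd) <= band_mm
    idx = np.argwhere(near)
    pts = idx * np.asarray(sp)
    d, _ = tree.query(pts, workers=-1)
    out = sd.copy()
    out[near] = np.where(m[near], -d, d)
    return out


def make_roi(
    tumor: MaskVolume,
    spec: RoiSpec,
    brain: MaskVolume | None = None,
    skull: MaskVolume | None = None,
    sd: np.ndarray | None = None,
    method: str = "mesh",
    subject: str = "",
) -> MaskVolume:
    """Realize one ROI mask from the tumor segmentation.

    BTI = voxels with signed distance in [-N, +N]; COM = tumor union BTI;
    WT = tumor.  The result is intersected with ``brain`` and voxels inside
    ``skull`` are removed (exclusion never adds voxels).  ``sd`` may be a
    precomputed signed-distance field to amortize cost across the nine ROIs.
    """
    for other in (brain, skull):
        if other is not None and not tumor.same_grid_as(other):
            raise ValueError("masks are not aligned to one grid")
    if spec.kind == "WT":
        roi = tumor.data.copy()
    else:
        if sd is None:
            sd = signed_distance(tumor, method=method)
        n = float(spec.half_width_mm)
        band = np.abs(sd) <= n
        if spec.kind == "COM":
            roi = band | tumor.data
        else:
            roi = band
    if brain is not None:
        roi &= brain.data
    if skull is not None:
        roi &= ~skull.data
    if not roi.any():
        raise ValueError(
            f"ROI {spec.name} is empty after brain/skull exclusion"
            + (f" for subject {subject}" if subject else "")
        )
    return MaskVolume(roi, tumor.grid)


def build_region_set(
    tumor: MaskVolume,
    brain: MaskVolume | None = None,
    skull: MaskVolume | None = None,
    specs: tuple[RoiSpec, ...] = ALL_ROI_SPECS,
    method: str = "mesh",
    subject: str = "",
) -> dict[str, MaskVolume]:
    """All requested ROIs from one signed-distance field."""
    sd = None
    if any(s.kind != "WT" for s in specs):
        sd = signed_distance(tumor, method=method)
    return {
        s.name: make_roi(tumor, s, brain, skull, sd=sd, method=method, subject=subject)
        for s in specs
    }


def mesh_volume_ml(mask: MaskVolume) -> float:
    """ROI volume from the triangle mesh of its 0.5-level surface (ml)."""
    _check_mask(mask)
    f = np.pad(mask.data.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(f, level=0.5, spacing=mask.grid.spacing_mm)
    tri = verts[faces]
    # divergence theorem: V = sum of signed tetrahedron volumes
    vol = np.abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)
    return float(vol / 1000.0)


def volume_metrics(
    tumor: MaskVolume,
    edema_outlined: MaskVolume,
    include_mesh: bool = False,
) -> VolumeMetrics:
    """TV, PEV = vol(outlined) - vol(tumor), and PEI = PEV / TV.

    The edema-outlined region (FLAIR) includes the tumor; voxels of the
    tumor outside it are clipped into the outlined region with a warning.
    Volumes are voxel-count based by default (``include_mesh`` adds the
    triangle-mesh tumor volume).
    """
    if not tumor.same_grid_as(edema_outlined):
        raise ValueError("tumor and edema-outlined masks are on different grids")
    _check_mask(tumor)
    outlined = edema_outlined.data
    stray = tumor.data & ~outlined
    if stray.any():
        import warnings

        warnings.warn(
            f"{int(stray.sum())} tumor voxels outside the edema-outlined region; clipping",
            stacklevel=2,
        )
        outlined = outlined | tumor.data
    vv = tumor.grid.voxel_volume_mm3 / 1000.0
    tv = tumor.voxel_count * vv
    pev = float(outlined.sum()) * vv - tv
    pei = pev / tv
    mesh = mesh_volume_ml(tumor) if include_mesh else None
    return VolumeMetrics(TV_ml=tv, PEV_ml=pev, PEI=pei, TV_mesh_ml=mesh)
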