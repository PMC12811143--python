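"""Serial-section morphometry on labelled heart reconstructions.

Quantities defined on per-slice anatomical label maps at known pixel size
and slice thickness: septal fill, attached-trabeculation fraction, apical
compact-layer thickness, septal-defect (VSD) detection by lumen contact,
closing-path defect areas, subtype assignment, and cell/nuclei morphometry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.graph import route_through_array
from skimage.morphology import medial_axis

from .exceptions import LabelingError, UndefinedRegionError

logger = logging.getLogger(__name__)

# Label codes (background must stay 0; empty space is explicit, not inferred).
BACKGROUND = 0
COMPACT_MYOCARDIUM = 1
TRABECULAE = 2
IVS = 3
AVCO = 4
ATRIA = 5
LV_LUMEN = 6
RV_LUMEN = 7
OTHER_TISSUE = 8

DEFAULT_LEGEND: dict[str, int] = {
    "background": BACKGROUND,
    "compact_myocardium": COMPACT_MYOCARDIUM,
    "trabeculae": TRABECULAE,
    "IVS": IVS,
    "AVco": AVCO,
    "atria": ATRIA,
    "LV_lumen": LV_LUMEN,
    "RV_lumen": RV_LUMEN,
    "other_tissue": OTHER_TISSUE,
}

TISSUE_CLASSES = frozenset(
    {COMPACT_MYOCARDIUM, TRABECULAE, IVS, AVCO, ATRIA, OTHER_TISSUE}
)
EMPTY_CLASSES = frozenset({BACKGROUND, LV_LUMEN, RV_LUMEN})
VENTRICULAR_CLASSES = frozenset(
    {COMPACT_MYOCARDIUM, TRABECULAE, IVS, LV_LUMEN, RV_LUMEN}
)


@dataclass
class SectionLabelStack:
    """Serial-section class labels with physical calibration.

    ``labels`` has shape (Z, Y, X): Z indexes 5 um (by default) sections,
    Y runs base -> apex, X runs anatomical right -> left.
    """

    labels: np.ndarray
    pixel_size_um: float
    slice_thickness_um: float = 5.0
    legend: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    side_map: np.ndarray | None = None  # -1 right, +1 left, 0 unassigned

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a (Z, Y, X) array")
        self.pixel_size_um = float(self.pixel_size_um)
        self.slice_thickness_um = float(self.slice_thickness_um)
        if self.pixel_size_um <= 0 or self.slice_thickness_um <= 0:
            raise ValueError("pixel size and slice thickness must be positive")
        if self.side_map is not None and self.side_map.shape != self.labels.shape:
            raise ValueError("side_map shape must match labels")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    def class_mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class VSDRecord:
    """One detected septal defect (connected lumen-contact component)."""

    component_id: int
    slice_range: tuple[int, int]  # inclusive
    voxel_count: int
    voxels: np.ndarray  # (N, 3) int indices (z, y, x)
    chords_um: dict[int, float] | None = None
    area_um2: float | None = None
    subtype: str = "unassigned"
    subtype_source: str = "auto"
    flags: list[str] = field(default_factory=list)


@dataclass
class CellShape:
    """Ellipse morphometry from a manually measured major/minor axis pair."""

    length_um: float
    width_um: float
    angle_deg: float = 0.0
    area_um2: float = field(init=False)
    eccentricity: float = field(init=False)
    diameter_um: float = field(init=False)

    def __post_init__(self) -> None:
        L, W = float(self.length_um), float(self.width_um)
        if L <= 0 or W <= 0:
            raise ValueError("axis lengths must be positive")
        if W > L:
            warnings.warn("width > length; swapping axes", stacklevel=2)
            L, W = W, L
        self.length_um, self.width_um = L, W
        self.area_um2 = np.pi * L * W / 4.0
        self.eccentricity = float(np.sqrt(1.0 - (W / L) ** 2))
        # "diameter" = diameter of the equal-area circle
        self.diameter_um = float(np.sqrt(L * W))


def cell_shape_from_axes(length_um: float, width_um: float, angle_deg: float = 0.0) -> CellShape:
    """Build a :class:`CellShape` from a length/width axis pair."""
    return CellShape(length_um, width_um, angle_deg)


def ivs_fill(
    stack,
    ivs_region: np.ndarray | None = None,
    darkness_threshold: float = 200.0,
):
    """Fraction of the septal region occupied by tissue.

    For a :class:`SectionLabelStack`, tissue = any tissue class and the
    septal region defaults to the hole-filled IVS mask per slice (so pores
    count against fill).  For an RGB section array of shape (..., 3) an
    explicit ``ivs_region`` mask is required and tissue pixels are those
    whose mean channel value is below ``darkness_threshold``.
    """
    if isinstance(stack, SectionLabelStack):
        labels = stack.labels
        if ivs_region is None:
            ivs = labels == IVS
            if not ivs.any():
                raise UndefinedRegionError("stack contains no IVS voxels")
            ivs_region = np.stack(
                [ndimage.binary_fill_holes(ivs[z]) for z in range(labels.shape[0])]
            )
        ivs_region = np.asarray(ivs_region, bool)
        if ivs_region.shape != labels.shape:
            raise ValueError("ivs_region shape must match labels")
        if not ivs_region.any():
            raise UndefinedRegionError("empty IVS region")
        tissue = np.isin(labels, list(TISSUE_CLASSES))
        return float(np.count_nonzero(tissue & ivs_region) / np.count_nonzero(ivs_region))

    rgb = np.asarray(stack, float)
    if rgb.shape[-1] != 3:
        raise ValueError("RGB input must have a trailing channel axis of size 3")
    if ivs_region is None:
        raise UndefinedRegionError("RGB input requires an explicit ivs_region mask")
    ivs_region = np.asarray(ivs_region, bool)
    if not ivs_region.any():
        raise UndefinedRegionError("empty IVS region")
    dark = rgb.mean(axis=-1) < darkness_threshold
    return float(np.count_nonzero(dark & ivs_region) / np.count_nonzero(ivs_region))


def trabeculation_fraction(stack: SectionLabelStack) -> float:
    """Attached-trabecula volume over attached-trabecula + IVS volume.

    A trabecular connected component (26-connectivity) counts as attached
    when any of its voxels neighbours the IVS class.
    """
    labels = stack.labels
    ivs = labels == IVS
    if not ivs.any():
        raise UndefinedRegionError("stack contains no IVS voxels")
    trab = labels == TRABECULAE
    v_ivs = int(np.count_nonzero(ivs))
    if not trab.any():
        return 0.0
    comp, n_comp = ndimage.label(trab, structure=np.ones((3, 3, 3), int))
    near_ivs = ndimage.binary_dilation(ivs, structure=np.ones((3, 3, 3), bool))
    touching = np.unique(comp[trab & near_ivs])
    touching = touching[touching > 0]
    if touching.size == 0:
        return 0.0
    v_att = int(np.count_nonzero(np.isin(comp, touching)))
    return v_att / (v_att + v_ivs)


def _ventricle_window(labels: np.ndarray, apex_fraction: float) -> tuple[int, int]:
    """Y-index range [y0, y1) of the apical ``apex_fraction`` of the ventricles."""
    vent = np.isin(labels, list(VENTRICULAR_CLASSES))
    rows = np.flatnonzero(vent.any(axis=(0, 2)))
    if rows.size == 0:
        raise UndefinedRegionError("no ventricular tissue in stack")
    y_min, y_max = int(rows[0]), int(rows[-1]) + 1
    extent = y_max - y_min
    y0 = y_max - max(1, int(round(apex_fraction * extent)))
    return y0, y_max


def compact_thickness(
    stack: SectionLabelStack,
    side: str,
    apex_fraction: float = 0.2,
) -> float:
    """Mean local thickness (um) of the apical compact myocardium on one side.

    Thickness is the diameter of the largest inscribed disk per slice
    (2*d - 1 pixels, d = Euclidean distance to the wall boundary, maximised
    over the region), restricted to the apical ``apex_fraction`` of the
    base->apex extent and to the requested side ("left" or "right"),
    then averaged across slices.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    labels = stack.labels
    y0, y1 = _ventricle_window(labels, apex_fraction)

    if stack.side_map is not None:
        side_sel = stack.side_map > 0 if side == "left" else stack.side_map < 0
    else:
        # X increases toward anatomical left; split at the septum centroid
        ivs = labels == IVS
        x_mid = (
            float(np.mean(np.nonzero(ivs)[2])) if ivs.any() else labels.shape[2] / 2.0
        )
        xs = np.arange(labels.shape[2])
        col_sel = xs >= x_mid if side == "left" else xs < x_mid
        side_sel = np.broadcast_to(col_sel, labels.shape)

    per_slice: list[float] = []
    for z in range(labels.shape[0]):
        compact = labels[z] == COMPACT_MYOCARDIUM
        if not compact.any():
            continue
        dist = ndimage.distance_transform_edt(compact)
        sel = compact.copy()
        sel[:y0] = False
        sel[y1:] = False
        sel &= side_sel[z]
        if sel.any():
            per_slice.append(2.0 * float(dist[sel].max()) - 1.0)
    if not per_slice:
        raise UndefinedRegionError(f"no apical compact myocardium on the {side} side")
    return float(np.mean(per_slice) * stack.pixel_size_um)


def _lumen_contact_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels of either lumen that are face-adjacent to the other lumen."""
    lv = labels == LV_LUMEN
    rv = labels == RV_LUMEN
    face = ndimage.generate_binary_structure(3, 1)
    lv_near_rv = lv & ndimage.binary_dilation(rv, structure=face)
    rv_near_lv = rv & ndimage.binary_dilation(lv, structure=face)
    return lv_near_rv | rv_near_lv


def detect_vsds(stack: SectionLabelStack) -> list[VSDRecord]:
    """Detect septal defects as connected components of LV/RV lumen contact.

    Contact is face adjacency (6-neighbourhood); contact voxels are grouped
    into defects with 26-connectivity across slices.
    """
    labels = stack.labels
    if not (labels == LV_LUMEN).any() or not (labels == RV_LUMEN).any():
        raise LabelingError("both LV_lumen and RV_lumen classes are required")
    contact = _lumen_contact_mask(labels)
    if not contact.any():
        return []
    comp, n_comp = ndimage.label(contact, structure=np.ones((3, 3, 3), int))
    records = []
    for cid in range(1, n_comp + 1):
        vox = np.argwhere(comp == cid)
        z0, z1 = int(vox[:, 0].min()), int(vox[:, 0].max())
        records.append(
            VSDRecord(
                component_id=cid,
                slice_range=(z0, z1),
                voxel_count=int(vox.shape[0]),
                voxels=vox,
            )
        )
    return records


def _rim_endpoints(labels_2d: np.ndarray, contact_2d: np.ndarray):
    """IVS pixels 8-adjacent to the contact region, as the farthest pair."""
    near = ndimage.binary_dilation(contact_2d, structure=np.ones((3, 3), bool))
    rim = (labels_2d == IVS) & near & ~contact_2d
    pts = np.argwhere(rim)
    if pts.shape[0] < 2:
        return None
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    if d2[i, j] == 0:
        return None
    return tuple(pts[i]), tuple(pts[j])


def vsd_area(
    stack: SectionLabelStack,
    record: VSDRecord,
    path: str = "geodesic",
) -> VSDRecord:
    """Measure the closing-path area of a detected defect.

    Per slice the closing chord c_k is the length of the minimal path joining
    the two septal rim endpoints across the aperture (geodesic through empty
    space by default, straight chord with ``path='chord'``); the defect area
    is sum(c_k) * slice_thickness.  Slices where rim endpoints cannot be
    identified fall back to the contact-region caliper width and are flagged.
    """
    if path not in ("geodesic", "chord"):
        raise ValueError("path must be 'geodesic' or 'chord'")
    labels = stack.labels
    px = stack.pixel_size_um
    chords: dict[int, float] = {}
    flags = list(record.flags)
    z0, z1 = record.slice_range
    for z in range(z0, z1 + 1):
        vox = record.voxels[record.voxels[:, 0] == z]
        if vox.shape[0] == 0:
            continue
        contact = np.zeros(labels.shape[1:], bool)
        contact[vox[:, 1], vox[:, 2]] = True
        endpoints = _rim_endpoints(labels[z], contact)
        if endpoints is None:
            pts = np.argwhere(contact)
            diff = pts[:, None, :] - pts[None, :, :]
            caliper = float(np.sqrt((diff**2).sum(axis=2).max()))
            chords[z] = (caliper + 1.0) * px
            flags.append(f"slice {z}: rim endpoints not identifiable; caliper fallback")
            continue
        a, b = endpoints
        if path == "chord":
            length_px = float(np.hypot(a[0] - b[0], a[1] - b[1]))
        else:
            passable = np.isin(labels[z], [LV_LUMEN, RV_LUMEN, BACKGROUND])
            passable[a] = True
            passable[b] = True
            costs = np.where(passable, 1.0, np.inf)
            try:
                route, _ = route_through_array(
                    costs, a, b, fully_connected=True, geometric=True
                )
            except ValueError:
                route = None
            if route is None:
                length_px = float(np.hypot(a[0] - b[0], a[1] - b[1]))
                flags.append(f"slice {z}: no geodesic; straight chord used")
            else:
                steps = np.diff(np.asarray(route, float), axis=0)
                length_px = float(np.sqrt((steps**2).sum(axis=1)).sum())
        # rim endpoint centres sit one pixel beyond the aperture on each side
        chords[z] = max(length_px - 1.0, 1.0) * px
    record.chords_um = chords
    record.area_um2 = float(sum(chords.values()) * stack.slice_thickness_um)
    record.flags = flags
    return record


def classify_vsd(
    stack: SectionLabelStack,
    record: VSDRecord,
    avco_distance_um: float = 50.0,
    override: str | None = None,
) -> str:
    """Assign a defect subtype: membranous if near the AV complex, else muscular.

    ``override`` accepts a manual call ("membranous" or "muscular"), which is
    stored with provenance ``subtype_source='manual'``.
    """
    if override is not None:
        if override not in ("membranous", "muscular"):
            raise ValueError("override must be 'membranous' or 'muscular'")
        record.subtype = override
        record.subtype_source = "manual"
        return record.subtype
    labels = stack.labels
    if not (labels == AVCO).any():
        record.subtype = "unassigned"
        logger.warning("no AVco class in stack; subtype left unassigned")
        return record.subtype
    dist = ndimage.distance_transform_edt(
        labels != AVCO,
        sampling=(stack.slice_thickness_um, stack.pixel_size_um, stack.pixel_size_um),
    )
    dmin = float(dist[record.voxels[:, 0], record.voxels[:, 1], record.voxels[:, 2]].min())
    record.subtype = "membranous" if dmin <= avco_distance_um else "muscular"
    record.subtype_source = "auto"
    return record.subtype


def detect_nuclei(
    image: np.ndarray,
    smoothing_sigma: float = 2.0,
    min_distance_um: float = 5.0,
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Detect nuclei as smoothed intensity peaks with non-maximum suppression.

    Returns an (N, 2) array of (row, col) coordinates.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.ptp(image) == 0:
        return np.empty((0, 2), int)
    smoothed = ndimage.gaussian_filter(image, smoothing_sigma)
    min_dist_px = max(1, int(round(min_distance_um / pixel_size_um)))
    thr = smoothed.min() + 0.1 * np.ptp(smoothed)
    return peak_local_max(smoothed, min_distance=min_dist_px, threshold_abs=thr)


def nuclei_density(
    coordinates: np.ndarray,
    roi_mask: np.ndarray,
    pixel_size_um: float,
) -> float:
    """Detections inside the ROI per square micrometre of ROI area."""
    roi_mask = np.asarray(roi_mask, bool)
    n_roi = int(np.count_nonzero(roi_mask))
    if n_roi == 0:
        raise UndefinedRegionError("zero-area ROI")
    coordinates = np.asarray(coordinates)
    if coordinates.size == 0:
        return 0.0
    rows = coordinates[:, 0].astype(int)
    cols = coordinates[:, 1].astype(int)
    inside = roi_mask[rows, cols]
    area_um2 = n_roi * pixel_size_um**2
    return float(np.count_nonzero(inside) / area_um2)
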