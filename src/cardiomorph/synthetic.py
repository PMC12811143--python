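"""Synthetic phantoms with stored ground truth.

Every generator is a pure function of its spec plus an explicit seed:
rerunning with the same arguments yields bit-identical output. Generated
objects emulate the input classes the analysis stages consume — two-lineage
reporter volumes with a parameterized right-left boundary, oriented 2-D
textures, serial heart-like label stacks with optional septal holes, ellipse
cell masks, and binomial incidence tables from an allele-dose log-odds
model — and each carries a JSON-serializable ground-truth record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit
from skimage.draw import ellipse as draw_ellipse

from . import morphometry as morpho
from .exceptions import InvalidSpecError, PlacementError
from .morphometry import SectionLabelStack
from .volume import MultiChannelVolume

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryPhantomSpec:
    """Two-reporter volume with a logistic lineage boundary along X.

    Channel "step" follows a logistic transition centred at
    ``boundary_center_um`` (0 = volume midline, positive = anatomical left)
    with length scale ``boundary_width_um``; channel "band" follows a
    Gaussian band of the same width at the same centre. With ``n_cells > 0``
    cells are rendered as Gaussian blobs whose density follows each
    channel's profile and are retained per labelling efficiency; with
    ``n_cells = 0`` the deterministic mean field itself is produced.
    """

    shape_px: tuple[int, int, int] = (8, 64, 256)  # (Z, Y, X)
    voxel_size_um: tuple[float, float, float] = (10.0, 2.0, 2.0)
    boundary_center_um: float = 0.0
    boundary_width_um: float = 20.0
    labeling_efficiency: tuple[float, float] = (1.0, 1.0)
    background_level: float = 0.0
    noise_sd: float = 0.0
    amplitude: float = 1.0
    n_cells: int = 0
    cell_sigma_um: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape_px) != 3 or any(int(s) <= 0 for s in self.shape_px):
            raise InvalidSpecError("shape_px must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size_um):
            raise InvalidSpecError("voxel sizes must be positive")
        if self.boundary_width_um <= 0:
            raise InvalidSpecError("boundary_width_um must be > 0")
        if any(not (0.0 <= e <= 1.0) for e in self.labeling_efficiency):
            raise InvalidSpecError("labeling efficiencies must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


@dataclass(frozen=True)
class HoleSpec:
    """A cylindrical septal perforation; axis along X (through the wall)."""

    z_center_um: float
    y_center_um: float
    radius_um: float
    membranous: bool = False


@dataclass(frozen=True)
class TrabeculaSpec:
    """A circular trabecular blob inside one lumen."""

    side: str  # "lv" or "rv"
    y_center_um: float
    radius_um: float
    attached: bool = True


@dataclass(frozen=True)
class HeartPhantomSpec:
    """Serial-section heart-like label stack, one identical layout per slice.

    Geometry (per slice, Y down = base->apex): an outer myocardial disc with
    two circular lumens (RV right/low X, LV left/high X) separated by a
    rectangular septal wall; an AV-complex band caps the septum at the base
    and everything above it inside the disc is atria.
    """

    lumen_radius_um: float = 250.0
    septal_thickness_um: float = 80.0
    compact_thickness_um: float = 60.0
    avco_height_um: float = 80.0
    pixel_size_um: float = 2.0
    slice_thickness_um: float = 5.0
    n_slices: int = 24
    hole_specs: tuple[HoleSpec, ...] = ()
    trabecula_specs: tuple[TrabeculaSpec, ...] = ()
    ivs_porosity: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.lumen_radius_um, self.septal_thickness_um,
               self.compact_thickness_um, self.pixel_size_um) <= 0:
            raise InvalidSpecError("geometric parameters must be positive")
        if self.slice_thickness_um <= 0:
            raise InvalidSpecError("slice_thickness_um must be > 0")
        if self.n_slices <= 0:
            raise InvalidSpecError("n_slices must be positive")
        if not (0.0 <= self.ivs_porosity < 1.0):
            raise InvalidSpecError("ivs_porosity must lie in [0, 1)")
        z_extent = self.n_slices * self.slice_thickness_um
        for h in self.hole_specs:
            if h.radius_um <= 0:
                raise InvalidSpecError("hole radius must be positive")
            if not (h.y_center_um - h.radius_um >= -self.lumen_radius_um
                    and h.y_center_um + h.radius_um <= self.lumen_radius_um):
                raise InvalidSpecError(
                    f"hole at y={h.y_center_um} um (r={h.radius_um}) lies outside "
                    "the septal wall"
                )
            if not (0 <= h.z_center_um - h.radius_um
                    and h.z_center_um + h.radius_um <= z_extent):
                raise InvalidSpecError("hole extends beyond the sectioned range")
        for t in self.trabecula_specs:
            if t.side not in ("lv", "rv"):
                raise InvalidSpecError("trabecula side must be 'lv' or 'rv'")
            if t.radius_um <= 0 or t.radius_um >= self.lumen_radius_um:
                raise InvalidSpecError("trabecula radius must fit inside the lumen")


@dataclass(frozen=True)
class AlleleDoseModel:
    """Log-odds model for incidence: beta0 + bt*tbx5 + bg*gene + bi*tbx5*gene."""

    beta0: float
    beta_tbx5: float
    beta_gene: float
    beta_int: float

    def validate(self) -> None:
        for v in (self.beta0, self.beta_tbx5, self.beta_gene, self.beta_int):
            if not np.isfinite(v):
                raise InvalidSpecError("all coefficients must be finite")

    def prob(self, tbx5_dose: float, gene_dose: float) -> float:
        eta = (self.beta0 + self.beta_tbx5 * tbx5_dose
               + self.beta_gene * gene_dose + self.beta_int * tbx5_dose * gene_dose)
        return float(expit(eta))


@dataclass
class GroundTruth:
    """Generating spec plus derived analytic values; JSON round-trippable."""

    generator: str
    spec: dict
    derived: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        return cls(**payload)


def _spec_dict(spec) -> dict:
    return json.loads(json.dumps(asdict(spec)))


# ---------------------------------------------------------------------------
# boundary volumes and profile sets
# ---------------------------------------------------------------------------

def _boundary_profiles_at(spec: BoundaryPhantomSpec, x_um: np.ndarray):
    step = expit((x_um - spec.boundary_center_um) / spec.boundary_width_um)
    band = np.exp(-0.5 * ((x_um - spec.boundary_center_um) / spec.boundary_width_um) ** 2)
    return step, band


def make_boundary_volume(spec: BoundaryPhantomSpec):
    """Generate a two-channel boundary phantom and its ground truth.

    Returns ``(MultiChannelVolume, GroundTruth)``. Channel "step" is the
    logistic lineage front, channel "band" the Gaussian boundary band.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = (int(s) for s in spec.shape_px)
    vx = spec.voxel_size_um[2]
    x_um = (np.arange(nx) - (nx - 1) / 2.0) * vx
    step, band = _boundary_profiles_at(spec, x_um)

    channels = []
    for c, profile in enumerate((step, band)):
        eff = spec.labeling_efficiency[c]
        if spec.n_cells > 0:
            img = np.zeros((nz, ny, nx), float)
            # candidate X positions by rejection sampling against the profile
            placed = 0
            p_max = profile.max() if profile.max() > 0 else 1.0
            while placed < spec.n_cells:
                ix = rng.integers(0, nx)
                if rng.random() * p_max > profile[ix]:
                    continue
                placed += 1
                if rng.random() > eff:  # cell not labelled
                    continue
                iz = rng.integers(0, nz)
                iy = rng.integers(0, ny)
                img[iz, iy, ix] += 1.0
            sigma = tuple(spec.cell_sigma_um / v for v in spec.voxel_size_um)
            img = ndimage.gaussian_filter(img, sigma)
            img *= spec.amplitude / max(img.max(), 1e-12)
            field3d = spec.background_level + img
        else:
            field3d = spec.background_level + spec.amplitude * eff * np.broadcast_to(
                profile, (nz, ny, nx)
            ).copy()
        if spec.noise_sd > 0:
            field3d = field3d + rng.normal(0.0, spec.noise_sd, size=(nz, ny, nx))
        channels.append(field3d)

    vol = MultiChannelVolume(
        data=np.stack(channels),
        voxel_size_um=spec.voxel_size_um,
        channel_names=("step", "band"),
    )
    truth = GroundTruth(
        generator="make_boundary_volume",
        spec=_spec_dict(spec),
        derived={
            "boundary_center_um": spec.boundary_center_um,
            "boundary_width_um": spec.boundary_width_um,
            "channel_profiles": {"step": "logistic", "band": "gaussian"},
        },
    )
    return vol, truth


def make_profile_set(
    spec: BoundaryPhantomSpec,
    n_profiles: int,
    seed: int | None = None,
):
    """Draw noisy boundary-band intensity profiles straight from the spec.

    A light-weight fixture for profile-level statistics: each profile is the
    channel-"band" Gaussian evaluated on the volume's X grid plus i.i.d.
    noise of sd ``spec.noise_sd``.  Returns (positions_um, matrix) with one
    row per profile.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nx = int(spec.shape_px[2])
    vx = spec.voxel_size_um[2]
    x_um = (np.arange(nx) - (nx - 1) / 2.0) * vx
    _, band = _boundary_profiles_at(spec, x_um)
    mat = spec.background_level + spec.amplitude * band[None, :]
    mat = np.repeat(mat, n_profiles, axis=0)
    if spec.noise_sd > 0:
        mat = mat + rng.normal(0.0, spec.noise_sd, size=mat.shape)
    return x_um, mat


# ---------------------------------------------------------------------------
# oriented textures
# ---------------------------------------------------------------------------

def wrap_axial_deg(angle_deg):
    """Wrap an angle to the axial range (-90, 90]."""
    a = (np.asarray(angle_deg, float) + 90.0) % 180.0 - 90.0
    return np.where(a == -90.0, 90.0, a)


def make_oriented_texture(
    angle_deg: float,
    coherency_level: float,
    shape_px: tuple[int, int] = (256, 256),
    seed: int = 0,
    period_px: float = 8.0,
) -> np.ndarray:
    """Sinusoidal stripes at ``angle_deg`` mixed with isotropic noise.

    ``coherency_level`` in [0, 1] sets the stripe/noise mixture so measured
    coherency increases monotonically with it. Angle convention: 0 deg along
    the image x axis (columns), counter-clockwise positive, axial period
    180 deg; out-of-range angles are wrapped with a logged warning.
    """
    if not (0.0 <= coherency_level <= 1.0):
        raise InvalidSpecError("coherency_level must lie in [0, 1]")
    if not (-90.0 < angle_deg <= 90.0):
        wrapped = float(wrap_axial_deg(angle_deg))
        logger.warning("angle %.1f outside (-90, 90]; wrapped to %.1f", angle_deg, wrapped)
        angle_deg = wrapped
    rng = np.random.default_rng(seed)
    ny, nx = (int(s) for s in shape_px)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    theta = np.deg2rad(angle_deg)
    # iso-intensity lines run along (cos t, sin t); phase varies orthogonally
    u = -xx * np.sin(theta) + yy * np.cos(theta)
    stripes = np.sin(2.0 * np.pi * u / period_px)
    noise = rng.standard_normal((ny, nx))
    stripes_n = stripes / max(stripes.std(), 1e-12)
    return coherency_level * stripes_n + (1.0 - coherency_level) * noise


# ---------------------------------------------------------------------------
# serial-section label stacks
# ---------------------------------------------------------------------------

def _base_slice(spec: HeartPhantomSpec):
    """Build the hole-free per-slice layout and return (labels2d, geometry)."""
    px = spec.pixel_size_um
    r_lum = spec.lumen_radius_um / px
    st = spec.septal_thickness_um / px
    compact = spec.compact_thickness_um / px
    avco_h = spec.avco_height_um / px
    atria_h = max(avco_h, 20.0 / px)
    margin = max(2.0, 4.0 / px)

    d = r_lum + st / 2.0  # lumen centre offset from septum midline
    disc_r = d + r_lum + compact
    cx = disc_r + margin
    cy = atria_h + avco_h + r_lum + margin
    height = int(np.ceil(cy + disc_r + margin))
    width = int(np.ceil(2 * (disc_r + margin)))

    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    labels = np.zeros((height, width), np.uint8)

    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= disc_r**2
    labels[disc] = morpho.COMPACT_MYOCARDIUM
    rv = (xx - (cx - d)) ** 2 + (yy - cy) ** 2 <= r_lum**2
    lv = (xx - (cx + d)) ** 2 + (yy - cy) ** 2 <= r_lum**2
    labels[rv] = morpho.RV_LUMEN
    labels[lv] = morpho.LV_LUMEN

    septum = (
        (np.abs(xx - cx) <= st / 2.0)
        & (yy >= cy - r_lum)
        & (yy <= cy + r_lum)
        & ~rv
        & ~lv
        & disc
    )
    labels[septum] = morpho.IVS

    avco = (
        (np.abs(xx - cx) <= st)
        & (yy >= cy - r_lum - avco_h)
        & (yy < cy - r_lum)
        & disc
    )
    labels[avco] = morpho.AVCO

    atria = disc & (yy < cy - r_lum - avco_h)
    labels[atria] = morpho.ATRIA

    for t in spec.trabecula_specs:
        r_t = t.radius_um / px
        lum_cx = cx + d if t.side == "lv" else cx - d
        sign = 1.0 if t.side == "lv" else -1.0
        if t.attached:
            # tangent to the septal face, overlapping it by one pixel
            tx = cx + sign * (st / 2.0 + r_t - 1.0)
        else:
            tx = lum_cx
        ty = cy + t.y_center_um / px
        blob = (xx - tx) ** 2 + (yy - ty) ** 2 <= r_t**2
        lum_code = morpho.LV_LUMEN if t.side == "lv" else morpho.RV_LUMEN
        labels[blob & (labels == lum_code)] = morpho.TRABECULAE

    geom = {"cx": cx, "cy": cy, "st_px": st, "r_lum_px": r_lum}
    return labels, geom


def make_section_stack(spec: HeartPhantomSpec):
    """Generate a serial-section label stack and its ground truth.

    Septal holes are cylinders through the wall (axis along X) whose
    cross-section lives in the sectioning (Z, Y) plane; hole voxels become
    lumen space joining LV to RV. Ground truth stores each hole's analytic
    in-plane area pi*r^2 and its slice range.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base, geom = _base_slice(spec)
    px = spec.pixel_size_um
    t = spec.slice_thickness_um
    cx, cy, st = geom["cx"], geom["cy"], geom["st_px"]

    labels = np.repeat(base[None, :, :], spec.n_slices, axis=0).copy()

    if spec.ivs_porosity > 0:
        ivs_idx = np.argwhere(labels == morpho.IVS)
        n_remove = int(round(spec.ivs_porosity * ivs_idx.shape[0]))
        pick = rng.choice(ivs_idx.shape[0], size=n_remove, replace=False)
        sel = ivs_idx[pick]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = morpho.BACKGROUND

    xs = np.arange(labels.shape[2], dtype=float)
    in_septum_x = np.abs(xs - cx) <= st / 2.0
    holes_truth = []
    for h in spec.hole_specs:
        z0 = int(np.floor((h.z_center_um - h.radius_um) / t))
        z1 = int(np.ceil((h.z_center_um + h.radius_um) / t))
        slice_range = []
        for z in range(max(z0, 0), min(z1 + 1, spec.n_slices)):
            zc = (z + 0.5) * t
            dz = zc - h.z_center_um
            if abs(dz) >= h.radius_um:
                continue
            half_chord = np.sqrt(h.radius_um**2 - dz**2) / px
            y_c = cy + h.y_center_um / px
            ys = np.arange(labels.shape[1], dtype=float)
            in_hole_y = np.abs(ys - y_c) <= half_chord
            region = np.outer(in_hole_y, in_septum_x) & (labels[z] == morpho.IVS)
            if not region.any():
                continue
            left_side = np.broadcast_to(xs > cx, region.shape)
            labels[z][region & left_side] = morpho.LV_LUMEN
            labels[z][region & ~left_side] = morpho.RV_LUMEN
            slice_range.append(z)
        if not slice_range:
            raise InvalidSpecError("hole produced no voxels (too small for the grid)")
        holes_truth.append(
            {
                "z_center_um": h.z_center_um,
                "y_center_um": h.y_center_um,
                "radius_um": h.radius_um,
                "membranous": h.membranous,
                "area_um2": float(np.pi * h.radius_um**2),
                "slice_range": [int(slice_range[0]), int(slice_range[-1])],
            }
        )

    stack = SectionLabelStack(
        labels=labels,
        pixel_size_um=px,
        slice_thickness_um=t,
    )
    truth = GroundTruth(
        generator="make_section_stack",
        spec=_spec_dict(spec),
        derived={"holes": holes_truth},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cell masks
# ---------------------------------------------------------------------------

def _as_sampler(dist) -> Callable[[np.random.Generator], float]:
    if callable(dist):
        return dist
    if np.isscalar(dist):
        return lambda rng, v=float(dist): v
    lo, hi = (float(v) for v in dist)
    return lambda rng: float(rng.uniform(lo, hi))


def make_cell_mask_set(
    n: int,
    length_dist,
    width_dist,
    seed: int = 0,
    canvas_px: tuple[int, int] = (512, 512),
    pixel_size_um: float = 1.0,
    max_tries_per_cell: int = 500,
):
    """Draw ``n`` non-overlapping ellipse cells; return (label mask, truth table).

    ``length_dist`` / ``width_dist`` may be a scalar (um), a (lo, hi) uniform
    range, or a callable taking a Generator. If a draw yields width > length
    the axes are swapped. The mask labels cells 1..n; the truth table has one
    row per cell (cell_id, length_um, width_um, angle_deg, row, col).
    """
    if n <= 0:
        raise InvalidSpecError("n must be positive")
    rng = np.random.default_rng(seed)
    sample_L = _as_sampler(length_dist)
    sample_W = _as_sampler(width_dist)
    ny, nx = (int(s) for s in canvas_px)
    mask = np.zeros((ny, nx), np.uint16)
    occupied = np.zeros((ny, nx), bool)
    rows = []
    for cid in range(1, n + 1):
        for _ in range(max_tries_per_cell):
            L = sample_L(rng)
            W = sample_W(rng)
            if L <= 0 or W <= 0:
                raise InvalidSpecError("axis distributions must yield positive values")
            if W > L:
                L, W = W, L
            angle = float(rng.uniform(-90.0, 90.0))
            a = L / 2.0 / pixel_size_um
            b = W / 2.0 / pixel_size_um
            r0 = rng.uniform(a + 2, ny - a - 2)
            c0 = rng.uniform(a + 2, nx - a - 2)
            rr, cc = draw_ellipse(r0, c0, b, a, rotation=np.deg2rad(angle), shape=(ny, nx))
            if rr.size == 0:
                continue
            # 1-px separation so components stay distinct
            pad = np.zeros((ny, nx), bool)
            pad[rr, cc] = True
            pad = ndimage.binary_dilation(pad, np.ones((3, 3), bool))
            if (pad & occupied).any():
                continue
            mask[rr, cc] = cid
            occupied |= pad
            rows.append(
                {
                    "cell_id": cid,
                    "length_um": L,
                    "width_um": W,
                    "angle_deg": angle,
                    "row": float(r0),
                    "col": float(c0),
                }
            )
            break
        else:
            raise PlacementError(
                f"could not place cell {cid}/{n} after {max_tries_per_cell} tries"
            )
    truth = pd.DataFrame(rows)
    return mask, truth


# ---------------------------------------------------------------------------
# incidence tables
# ---------------------------------------------------------------------------

def sample_incidence(
    model: AlleleDoseModel,
    group_sizes: Mapping[tuple[int, int], int] | Sequence[tuple[int, int, int]],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw binomial affected counts per genotype group under the dose model.

    ``group_sizes`` maps (tbx5_dose, gene_dose) -> total animals, or is a
    sequence of (tbx5_dose, gene_dose, total) triples. Returns a counts table
    with columns genotype_label, tbx5_dose, gene_dose, affected, total.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    if isinstance(group_sizes, Mapping):
        triples = [(t, g, n) for (t, g), n in group_sizes.items()]
    else:
        triples = [tuple(row) for row in group_sizes]
    rows = []
    for tbx5, gene, total in triples:
        if total < 0:
            raise InvalidSpecError("group sizes must be >= 0")
        p = model.prob(tbx5, gene)
        affected = int(rng.binomial(int(total), p)) if total > 0 else 0
        rows.append(
            {
                "genotype_label": f"tbx5_{tbx5}_gene_{gene}",
                "tbx5_dose": int(tbx5),
                "gene_dose": int(gene),
                "affected": affected,
                "total": int(total),
            }
        )
    return pd.DataFrame(rows)
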