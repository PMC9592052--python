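"""Ground-truthed synthetic two-channel fluorescence scenes.

Emulates fields of rod-shaped fission-yeast cells co-expressing an
F-actin reporter (channel ``factin``) and a tagged tropomyosin
(channel ``tpm``).  Each cell is a capsule (cylinder with hemispherical
caps) containing diffraction-limited cortical patches biased toward the
cell tips, thin cables running roughly parallel to the long axis, and —
in a configurable fraction of cells — a medial cytokinetic ring.

The key knob is the per-class *decoration ratio*: on every structure
pixel, the tropomyosin signal above cytoplasm equals
``decoration_ratio[class] x`` the F-actin signal above cytoplasm
(times a global channel-2 expression scale).  Rendering adds a Gaussian
PSF, Poisson shot noise and Gaussian read noise on top of per-cell
cytoplasmic and extracellular background, and returns the pre-blur
per-pixel class map as ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .classes import CABLE, CLASS_NAMES, CYTOPLASM, PATCH, RING, LabelImage
from .stack_io import ImageStack, write_stack


class SceneGeometryError(ValueError):
    """Raised when cells cannot be placed within the overlap budget."""


class StructureOutOfBoundsError(ValueError):
    """Raised when a structure falls outside the image field."""


# ---------------------------------------------------------------------------
# parametric scene description
# ---------------------------------------------------------------------------


@dataclass
class PatchSpec:
    center_um: tuple[float, float]  # (x, y)
    amplitude_ch1: float  # photons above cytoplasm
    radius_um: float
    decorated: bool = True  # carries tropomyosin signal
    z_um: float = 0.0  # offset from the cell mid-plane


@dataclass
class CableSpec:
    vertices_um: np.ndarray  # (K, 2) polyline, (x, y)
    width_um: float
    amplitude_ch1: float

    def __post_init__(self) -> None:
        self.vertices_um = np.asarray(self.vertices_um, dtype=float)


@dataclass
class RingSpec:
    axial_fraction: float  # position along the cell axis, 0..1
    thickness_um: float
    amplitude_ch1: float


@dataclass
class CellSpec:
    center_um: tuple[float, float]
    orientation: float  # radians, in [0, pi)
    length_um: float
    radius_um: float
    patches: list[PatchSpec] = field(default_factory=list)
    cables: list[CableSpec] = field(default_factory=list)
    ring: RingSpec | None = None
    in_clump: bool = False

    @property
    def half_axis_um(self) -> float:
        """Half-length of the cylinder's central segment."""
        return self.length_um / 2.0 - self.radius_um

    def endpoints_um(self) -> np.ndarray:
        d = np.array([np.cos(self.orientation), np.sin(self.orientation)])
        c = np.asarray(self.center_um)
        return np.stack([c - d * self.half_axis_um, c + d * self.half_axis_um])


@dataclass
class SceneGroundTruth:
    cells: list[CellSpec]
    decoration_ratio: dict[str, float]
    cytoplasm_level: dict[str, float]  # photons, per channel
    outside_level: dict[str, float]  # photons, per channel
    expression_scale_ch2: float
    field_um: tuple[float, float]  # (height, width)
    seed: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.decoration_ratio.values()):
            raise ValueError("decoration_ratio values must be >= 0")
        if self.cytoplasm_level["factin"] <= self.outside_level["factin"]:
            raise ValueError("cytoplasm level must exceed outside level in channel 1")

    def structure_ratio(self, cls: str, structure) -> float:
        r = self.decoration_ratio.get(cls, 0.0)
        if cls == "patch" and not structure.decorated:
            return 0.0
        return r

    def true_class_means(self, include_clumps: bool = False) -> dict[str, float]:
        """Mean per-structure true decoration ratio, per class.

        This is the quantity the quantification estimates: undecorated
        patches contribute a true ratio of 0, so the patch truth is
        below the nominal patch setting whenever the decorated fraction
        is below 1.
        """
        per_class: dict[str, list[float]] = {"patch": [], "cable": [], "ring": []}
        for cell in self.cells:
            if cell.in_clump and not include_clumps:
                continue
            for p in cell.patches:
                per_class["patch"].append(self.structure_ratio("patch", p))
            for c in cell.cables:
                per_class["cable"].append(self.structure_ratio("cable", c))
            if cell.ring is not None:
                per_class["ring"].append(self.structure_ratio("ring", cell.ring))
        return {k: float(np.mean(v)) for k, v in per_class.items() if v}


@dataclass
class OpticsNoiseModel:
    """Imaging and camera model used to render a scene."""

    pixel_size_nm: float = 69.0
    n_zplanes: int = 16
    z_step_um: float = 0.4
    # lateral sigma ~ 0.21*lambda/NA ~ 74 nm for 510 nm emission at NA 1.45,
    # i.e. ~1.1 px at 69 nm/px; axial FWHM ~ 0.5 um -> 0.55 planes at 0.4 um
    psf_sigma_xy: float = 1.1  # px
    psf_sigma_z: float = 0.55  # planes
    poisson_noise: bool = True
    read_noise_sd: float = 2.0  # counts
    camera_offset: float = 0.0  # counts
    photons_per_count: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.psf_sigma_xy < 0 or self.psf_sigma_z < 0:
            raise ValueError("psf sigmas must be >= 0")

    @classmethod
    def noiseless_2d(cls, pixel_size_nm: float = 69.0) -> "OpticsNoiseModel":
        """Single-plane, blur-free, noise-free model for exact tests."""
        return cls(
            pixel_size_nm=pixel_size_nm,
            n_zplanes=1,
            psf_sigma_xy=0.0,
            psf_sigma_z=0.0,
            poisson_noise=False,
            read_noise_sd=0.0,
        )


@dataclass
class SceneConfig:
    """Generator settings; the defaults define the study conditions."""

    field_size_px: tuple[int, int] = (512, 512)  # (ny, nx)
    pixel_size_nm: float = 69.0
    n_cells: int = 6
    n_clumps: int = 0
    clump_size_range: tuple[int, int] = (3, 5)  # cells per deliberate clump
    cell_radius_um: float = 1.75
    cell_length_range_um: tuple[float, float] = (7.0, 14.0)
    patches_per_cell: tuple[int, int] = (3, 8)
    patch_radius_um: float = 0.25
    patch_amplitude_range: tuple[float, float] = (400.0, 800.0)
    decorated_patch_fraction: float = 0.5
    cables_per_cell: tuple[int, int] = (1, 3)
    cable_width_um: float = 0.3
    cable_amplitude_range: tuple[float, float] = (150.0, 250.0)
    ring_fraction: float = 0.15
    ring_thickness_um: float = 0.3
    ring_amplitude_range: tuple[float, float] = (300.0, 500.0)
    decoration_ratio: dict[str, float] = field(
        default_factory=lambda: {"patch": 0.14, "cable": 0.97, "ring": 0.95}
    )
    # large diffuse reporter pools relative to structure contrast: the
    # regime in which the whole-cell expression normalisation is nearly
    # unbiased, as in the source images (fully decorated cables score ~1)
    cytoplasm_photons_ch1: float = 400.0  # above outside
    outside_photons: tuple[float, float] = (50.0, 50.0)  # (factin, tpm)
    expression_scale_ch2: float = 1.0
    placement_margin_um: float = 0.3
    intercell_gap_um: float = 0.2
    max_placement_tries: int = 800


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between segments p1-p2 and q1-q2 (2D)."""
    p1, p2, q1, q2 = (np.asarray(a, dtype=float) for a in (p1, p2, q1, q2))

    def pt_seg(pt, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else np.clip((pt - a) @ ab / denom, 0.0, 1.0)
        return float(np.hypot(*(pt - (a + t * ab))))

    d1, d2 = p2 - p1, q2 - q1
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(cross) > 1e-12:
        r = q1 - p1
        t = (r[0] * d2[1] - r[1] * d2[0]) / cross
        u = (r[0] * d1[1] - r[1] * d1[0]) / cross
        if 0 <= t <= 1 and 0 <= u <= 1:
            return 0.0
    return min(
        pt_seg(p1, q1, q2), pt_seg(p2, q1, q2), pt_seg(q1, p1, p2), pt_seg(q2, p1, p2)
    )


def _capsule_in_field(cell: CellSpec, field_um, margin: float) -> bool:
    ends = cell.endpoints_um()
    r = cell.radius_um + margin
    h, w = field_um
    return bool(
        np.all(ends[:, 0] - r >= 0)
        and np.all(ends[:, 0] + r <= w)
        and np.all(ends[:, 1] - r >= 0)
        and np.all(ends[:, 1] + r <= h)
    )


def _cells_overlap(a: CellSpec, b: CellSpec, gap: float) -> bool:
    ea, eb = a.endpoints_um(), b.endpoints_um()
    d = _segment_distance(ea[0], ea[1], eb[0], eb[1])
    return d < a.radius_um + b.radius_um + gap


# ---------------------------------------------------------------------------
# scene sampling
# ---------------------------------------------------------------------------


def _sample_cell_body(cfg: SceneConfig, rng, field_um) -> CellSpec:
    length = rng.uniform(*cfg.cell_length_range_um)
    orientation = rng.uniform(0.0, np.pi)
    h, w = field_um
    center = (rng.uniform(0.0, w), rng.uniform(0.0, h))
    return CellSpec(center, orientation, length, cfg.cell_radius_um)


def _populate_cell(cell: CellSpec, cfg: SceneConfig, rng) -> None:
    R, h = cell.radius_um, cell.half_axis_um
    d = np.array([np.cos(cell.orientation), np.sin(cell.orientation)])
    n = np.array([-d[1], d[0]])
    c = np.asarray(cell.center_um)

    n_patches = int(rng.integers(cfg.patches_per_cell[0], cfg.patches_per_cell[1] + 1))
    vmax_p = max(R - cfg.patch_radius_um - 0.1, 0.05)
    for _ in range(n_patches):
        u = float(rng.choice([-1.0, 1.0])) * h * float(rng.beta(2.5, 1.0))
        v = rng.uniform(-vmax_p, vmax_p)
        pos = c + u * d + v * n
        cell.patches.append(
            PatchSpec(
                center_um=(float(pos[0]), float(pos[1])),
                amplitude_ch1=float(rng.uniform(*cfg.patch_amplitude_range)),
                radius_um=cfg.patch_radius_um,
                decorated=bool(rng.random() < cfg.decorated_patch_fraction),
                z_um=float(rng.uniform(-0.5, 0.5) * R),
            )
        )

    n_cables = int(rng.integers(cfg.cables_per_cell[0], cfg.cables_per_cell[1] + 1))
    vmax_c = max(R - cfg.cable_width_um / 2 - 0.15, 0.05)
    for _ in range(n_cables):
        extent = rng.uniform(0.5, 0.9, size=2)
        us = np.linspace(-h * extent[0], h * extent[1], 8)
        vs = np.clip(
            rng.uniform(-vmax_c, vmax_c) * 0.6 + np.cumsum(rng.normal(0, 0.25, 8)),
            -vmax_c,
            vmax_c,
        )
        verts = c[None, :] + us[:, None] * d[None, :] + vs[:, None] * n[None, :]
        cell.cables.append(
            CableSpec(
                vertices_um=verts,
                width_um=cfg.cable_width_um,
                amplitude_ch1=float(rng.uniform(*cfg.cable_amplitude_range)),
            )
        )

    if rng.random() < cfg.ring_fraction:
        cell.ring = RingSpec(
            axial_fraction=float(np.clip(rng.normal(0.5, 0.02), 0.45, 0.55)),
            thickness_um=cfg.ring_thickness_um,
            amplitude_ch1=float(rng.uniform(*cfg.ring_amplitude_range)),
        )


def sample_scene(config: SceneConfig, seed: int) -> SceneGroundTruth:
    """Draw a full parametric scene from the generator settings.

    Isolated cells are placed by rejection sampling with a hard
    no-overlap constraint between groups; deliberate clumps (rows of
    touching cells) are placed as single groups so clump filtering is
    exercised downstream.
    """
    rng = np.random.default_rng(seed)
    ny, nx = config.field_size_px
    s = config.pixel_size_nm / 1000.0
    field_um = (ny * s, nx * s)

    groups: list[list[CellSpec]] = []
    # largest groups first: clumps need the most room
    plan = [
        int(rng.integers(config.clump_size_range[0], config.clump_size_range[1] + 1))
        for _ in range(config.n_clumps)
    ] + [1] * config.n_cells
    for gi, k in enumerate(plan):
        placed = None
        for _ in range(config.max_placement_tries):
            base = _sample_cell_body(config, rng, field_um)
            group = [base]
            for j in range(1, k):
                d = np.array([np.cos(base.orientation), np.sin(base.orientation)])
                nvec = np.array([-d[1], d[0]])
                off = nvec * 2.0 * config.cell_radius_um * 0.95 * j
                jitter = d * rng.uniform(-0.8, 0.8)
                mate = CellSpec(
                    tuple(np.asarray(base.center_um) + off + jitter),
                    base.orientation + rng.uniform(-0.05, 0.05),
                    rng.uniform(*config.cell_length_range_um),
                    config.cell_radius_um,
                    in_clump=True,
                )
                group.append(mate)
            if k > 1:
                for cell in group:
                    cell.in_clump = True
            if not all(
                _capsule_in_field(cell, field_um, config.placement_margin_um)
                for cell in group
            ):
                continue
            if any(
                _cells_overlap(cell, other, config.intercell_gap_um)
                for cell in group
                for g in groups
                for other in g
            ):
                continue
            placed = group
            break
        if placed is None:
            raise SceneGeometryError(
                f"could not place cell group {gi} ({k} cell(s)) within "
                f"{config.max_placement_tries} tries: field {field_um[1]:.1f}x"
                f"{field_um[0]:.1f} um cannot hold {sum(plan)} cells without "
                "violating the no-overlap constraint"
            )
        groups.append(placed)

    cells = [cell for g in groups for cell in g]
    for cell in cells:
        _populate_cell(cell, config, rng)

    out_f, out_t = config.outside_photons
    cyt_f = out_f + config.cytoplasm_photons_ch1
    cyt_t = out_t + config.cytoplasm_photons_ch1 * config.expression_scale_ch2
    return SceneGroundTruth(
        cells=cells,
        decoration_ratio=dict(config.decoration_ratio),
        cytoplasm_level={"factin": cyt_f, "tpm": cyt_t},
        outside_level={"factin": out_f, "tpm": out_t},
        expression_scale_ch2=config.expression_scale_ch2,
        field_um=field_um,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _cell_frame(cell: CellSpec, xs, ys):
    """Axis-aligned coordinates (u along, v across) for a pixel grid."""
    d = np.array([np.cos(cell.orientation), np.sin(cell.orientation)])
    dx = xs[None, :] - cell.center_um[0]
    dy = ys[:, None] - cell.center_um[1]
    u = dx * d[0] + dy * d[1]
    v = -dx * d[1] + dy * d[0]
    return u, v


def _capsule_dist(u, v, half_axis):
    return np.hypot(np.maximum(np.abs(u) - half_axis, 0.0), v)


def _polyline_dist(xs, ys, verts):
    """Distance from each grid point to a polyline (µm)."""
    px = xs[None, :]
    py = ys[:, None]
    dmin = np.full((ys.size, xs.size), np.inf)
    for a, b in zip(verts[:-1], verts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.hypot(px - a[0], py - a[1])
        else:
            t = np.clip(((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom, 0.0, 1.0)
            d = np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))
        dmin = np.minimum(dmin, d)
    return dmin


def render_scene(
    scene: SceneGroundTruth,
    optics: OpticsNoiseModel,
    seed: int | None = None,
) -> tuple[ImageStack, LabelImage]:
    """Render a scene through the optics/noise model.

    Returns a (1, 2, Z, Y, X) float stack — channel 0 is F-actin,
    channel 1 tropomyosin — and the 2D ground-truth class map defined
    by the pre-blur structure footprints.
    """
    s = optics.pixel_size_nm / 1000.0
    ny = int(round(scene.field_um[0] / s))
    nx = int(round(scene.field_um[1] / s))
    xs = (np.arange(nx) + 0.5) * s
    ys = (np.arange(ny) + 0.5) * s
    nz = optics.n_zplanes
    z_positions = (np.arange(nz) - (nz - 1) / 2.0) * optics.z_step_um

    for ci, cell in enumerate(scene.cells):
        if not _capsule_in_field(cell, scene.field_um, 0.0):
            raise StructureOutOfBoundsError(f"cell {ci} extends outside the field")
        for pi, p in enumerate(cell.patches):
            x, y = p.center_um
            if not (0 <= x <= scene.field_um[1] and 0 <= y <= scene.field_um[0]):
                raise StructureOutOfBoundsError(
                    f"patch {pi} of cell {ci} lies outside the field"
                )

    labels = np.zeros((ny, nx), dtype=np.uint8)
    # per-channel structure excess (photons above cytoplasm) and cell mask
    excess = {ch: np.zeros((ny, nx)) for ch in ("factin", "tpm")}
    cell_mask = np.zeros((ny, nx), dtype=bool)
    # weight maps per z-plane for the structure layer and cytoplasm layer
    s2 = scene.expression_scale_ch2
    struct_z = np.zeros((nz, ny, nx))  # per-pixel z-weight of winning structure
    struct_sigma_default = max(optics.z_step_um / 2.0, 1e-6)

    def paint(footprint, amp1, cls_code, cls_name, structure, z0=0.0, z_sigma=None):
        ratio = scene.structure_ratio(cls_name, structure)
        excess["factin"][footprint] = amp1
        excess["tpm"][footprint] = amp1 * ratio * s2
        labels[footprint] = cls_code
        if nz > 1:
            zs = z_sigma if z_sigma is not None else struct_sigma_default
            w = np.exp(-((z_positions - z0) ** 2) / (2.0 * zs**2))
            struct_z[:, footprint] = w[:, None]
        else:
            struct_z[:, footprint] = 1.0

    # paint in increasing precedence: cytoplasm < cable < patch < ring
    for cell in scene.cells:
        u, v = _cell_frame(cell, xs, ys)
        body = _capsule_dist(u, v, cell.half_axis_um) <= cell.radius_um
        cell_mask |= body
        labels[body & (labels == 0)] = CYTOPLASM

    for cell in scene.cells:
        u, v = _cell_frame(cell, xs, ys)
        for cable in cell.cables:
            fp = _polyline_dist(xs, ys, cable.vertices_um) <= cable.width_um / 2.0
            paint(
                fp, cable.amplitude_ch1, CABLE, "cable", cable,
                z_sigma=max(cable.width_um / 2.0, struct_sigma_default),
            )
    for cell in scene.cells:
        for p in cell.patches:
            px_, py_ = p.center_um
            fp = np.hypot(xs[None, :] - px_, ys[:, None] - py_) <= p.radius_um
            paint(
                fp, p.amplitude_ch1, PATCH, "patch", p,
                z0=p.z_um, z_sigma=max(p.radius_um, struct_sigma_default),
            )
    for cell in scene.cells:
        if cell.ring is None:
            continue
        u, v = _cell_frame(cell, xs, ys)
        body = _capsule_dist(u, v, cell.half_axis_um) <= cell.radius_um
        u_ring = (cell.ring.axial_fraction - 0.5) * cell.length_um
        fp = body & (np.abs(u - u_ring) <= cell.ring.thickness_um / 2.0)
        paint(
            fp, cell.ring.amplitude_ch1, RING, "ring", cell.ring,
            z_sigma=max(cell.ring.thickness_um / 2.0, struct_sigma_default),
        )

    # cytoplasm occupancy per plane: capsule cross-section shrinks with |dz|
    cyt_z = np.zeros((nz, ny, nx))
    if nz == 1:
        cyt_z[0] = cell_mask
    else:
        for cell in scene.cells:
            u, v = _cell_frame(cell, xs, ys)
            for iz, dz in enumerate(z_positions):
                if abs(dz) >= cell.radius_um:
                    continue
                r_eff = np.sqrt(cell.radius_um**2 - dz**2)
                sect = _capsule_dist(u, v, cell.half_axis_um) <= r_eff
                cyt_z[iz][sect] = 1.0

    data = np.zeros((1, 2, nz, ny, nx))
    for ci, ch in enumerate(("factin", "tpm")):
        base = scene.outside_level[ch]
        cyt_excess = scene.cytoplasm_level[ch] - base
        photons = base + cyt_excess * cyt_z + excess[ch][None, :, :] * struct_z
        if optics.psf_sigma_xy > 0:
            for iz in range(nz):
                photons[iz] = gaussian_filter(
                    photons[iz], optics.psf_sigma_xy, mode="nearest"
                )
        if nz > 1 and optics.psf_sigma_z > 0:
            photons = gaussian_filter1d(
                photons, optics.psf_sigma_z, axis=0, mode="nearest"
            )
        data[0, ci] = photons

    rng = np.random.default_rng(
        np.random.SeedSequence([scene.seed & 0x7FFFFFFF, 0xC0FFEE])
        if seed is None
        else seed
    )
    if optics.poisson_noise:
        data = rng.poisson(data).astype(float)
    data /= optics.photons_per_count
    if optics.read_noise_sd > 0:
        data = data + rng.normal(0.0, optics.read_noise_sd, size=data.shape)
    data = np.maximum(data + optics.camera_offset, 0.0)

    stack = ImageStack(
        data,
        pixel_size_nm=optics.pixel_size_nm,
        z_step_um=optics.z_step_um if nz > 1 else 0.0,
        channel_names=["factin", "tpm"],
    )
    provenance = {name: "ground_truth" for name in ("patch", "cable", "ring")}
    return stack, LabelImage(labels, provenance)


# ---------------------------------------------------------------------------
# dataset generation on disk
# ---------------------------------------------------------------------------


def _image_seed(seed: int, index: int, stream: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(index), int(stream)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_dataset(
    config: SceneConfig,
    optics: OpticsNoiseModel,
    n_images: int,
    out_dir: str | Path,
    seed: int,
) -> Path:
    """Write ``n_images`` rendered scene/label pairs plus a manifest.

    The manifest records every parameter and the seed; re-running
    :func:`generate_dataset_from_manifest` reproduces identical files.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i in range(n_images):
        scene = sample_scene(config, _image_seed(seed, i, 0))
        stack, gt = render_scene(scene, optics, seed=_image_seed(seed, i, 1))
        img_path = out_dir / f"image_{i:03d}.tif"
        data16 = np.clip(np.rint(stack.data), 0, 65535).astype(np.uint16)
        write_stack(dataclasses.replace(stack, data=data16), img_path)
        lbl_path = out_dir / f"labels_{i:03d}.tif"
        tifffile.imwrite(lbl_path, gt.labels)
        files.append({"image": img_path.name, "labels": lbl_path.name})
    manifest = {
        "config": dataclasses.asdict(config),
        "optics": dataclasses.asdict(optics),
        "n_images": int(n_images),
        "seed": int(seed),
        "class_palette": {str(k): v for k, v in CLASS_NAMES.items()},
        "files": files,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def generate_dataset_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> Path:
    """Reproduce a dataset byte-for-byte from its manifest."""
    m = json.loads(Path(manifest_path).read_text())
    cfg_d = dict(m["config"])
    for key in (
        "field_size_px", "clump_size_range", "cell_length_range_um",
        "patches_per_cell", "patch_amplitude_range", "cables_per_cell",
        "cable_amplitude_range", "ring_amplitude_range", "outside_photons",
    ):
        cfg_d[key] = tuple(cfg_d[key])
    config = SceneConfig(**cfg_d)
    optics = OpticsNoiseModel(**m["optics"])
    return generate_dataset(config, optics, m["n_images"], out_dir, m["seed"])
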