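"""Deterministic ball-and-stick rendering and multi-angle snapshot capture.

The featurization "photographs" each 3D conformer from a grid of rotation
angles about the x-, y- and z-axes, producing m^3 images per molecule for a
per-axis angle set {0, theta, 2*theta, ...} below 360 degrees.  Because the
images are the model's input features, the renderer must be bit-exact across
runs: it is a pure-numpy software rasterizer (orthographic camera, z-buffer,
Lambert-shaded sphere and cylinder impostors, one fixed directional light)
rather than a wrapper around an interactive viewer.

Conventions
-----------
* The molecule is centred on its centroid, rotated about the fixed lab x-,
  then y-, then z-axis, and orthographically projected onto the image plane.
* The projection scale fits the molecule's bounding sphere (including atom
  radii) with a 10% margin, so image corners always show the background.
* Atoms are coloured by the CPK scheme; bonds are drawn as two half-cylinders
  each taking its atom's colour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .molecule_prep import Conformer3D

# CPK colours (RGB 0-255)
CPK_COLORS: dict[str, tuple[int, int, int]] = {
    "H": (255, 255, 255),
    "C": (144, 144, 144),
    "N": (48, 80, 248),
    "O": (255, 13, 13),
    "F": (144, 224, 80),
    "Cl": (31, 240, 31),
    "Br": (166, 41, 41),
    "I": (148, 0, 148),
    "S": (255, 255, 48),
    "P": (255, 128, 0),
    "B": (255, 181, 181),
    "Si": (240, 200, 160),
    "Na": (171, 92, 242),
    "K": (143, 64, 212),
    "Ca": (61, 255, 0),
    "Fe": (224, 102, 51),
    "Zn": (125, 128, 176),
}
DEFAULT_COLOR = (255, 20, 147)  # anything exotic shows up loudly

# display radii in Angstrom (ball-and-stick balls are a fraction of vdW)
ELEMENT_RADII: dict[str, float] = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Cl": 1.75,
    "Br": 1.85, "I": 1.98, "S": 1.80, "P": 1.80, "B": 1.92, "Si": 2.10,
    "Na": 2.27, "K": 2.75, "Ca": 2.31, "Fe": 2.05, "Zn": 2.10,
}
DEFAULT_RADIUS = 1.75

_LIGHT = np.array([-0.35, -0.35, 0.87])
_LIGHT_DIR = _LIGHT / np.linalg.norm(_LIGHT)
_AMBIENT = 0.35
_MARGIN = 1.10  # 10% margin around the bounding sphere


@dataclass
class RenderStyle:
    """Visual parameters of the ball-and-stick depiction."""

    atom_colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(CPK_COLORS))
    atom_radius_scale: float = 0.30
    bond_radius: float = 0.12  # Angstrom
    background: tuple[int, int, int] = (0, 0, 0)
    image_size: int = 256

    def __post_init__(self) -> None:
        if self.atom_radius_scale <= 0 or self.bond_radius <= 0:
            raise ValueError("radii must be positive")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        for c in self.background:
            if not 0 <= c <= 255:
                raise ValueError("background RGB components must be in [0, 255]")


@dataclass(frozen=True)
class RotationTriple:
    rx: float
    ry: float
    rz: float

    def __post_init__(self) -> None:
        for a in (self.rx, self.ry, self.rz):
            if not 0 <= a < 360:
                raise ValueError("rotation angles must lie in [0, 360)")


@dataclass
class SnapshotSet:
    """All snapshot images of one molecule at one angle increment."""

    molecule_id: str
    increment: float
    items: list[tuple[RotationTriple, Path]]

    def __len__(self) -> int:
        return len(self.items)


def enumerate_angles(increment: float) -> list[RotationTriple]:
    """All rotation triples on the grid {0, theta, 2*theta, ...} < 360 per axis.

    The returned list is the full Cartesian product over the three axes in
    lexicographic order, of length m^3 where m is the number of multiples of
    ``increment`` in [0, 360).
    """
    if increment <= 0:
        raise ValueError(f"angle increment must be positive, got {increment}")
    values: list[float] = []
    k = 0
    while k * increment < 360:
        values.append(k * increment)
        k += 1
    return [RotationTriple(rx, ry, rz)
            for rx in values for ry in values for rz in values]


def _rotation_matrix(rot: RotationTriple) -> np.ndarray:
    ax, ay, az = (math.radians(a) for a in (rot.rx, rot.ry, rot.rz))
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    # rotate about x first, then y, then z (fixed lab axes)
    return rz @ ry @ rx


def _shade(color: np.ndarray, normals: np.ndarray) -> np.ndarray:
    lambert = np.clip(normals @ _LIGHT_DIR, 0.0, 1.0)
    intensity = _AMBIENT + (1.0 - _AMBIENT) * lambert
    return color[None, :] * intensity[:, None]


def render_snapshot(conf: Conformer3D, rot: RotationTriple,
                    style: RenderStyle | None = None) -> np.ndarray:
    """Rasterize one snapshot; returns an (S, S, 3) uint8 RGB array.

    Identical inputs produce bitwise-identical rasters.
    """
    style = style or RenderStyle()
    if conf.n_atoms == 0:
        raise ValueError("cannot render an empty conformer")

    coords = np.array([[x, y, z] for _, x, y, z in conf.atoms], dtype=np.float64)
    coords -= coords.mean(axis=0)
    coords = coords @ _rotation_matrix(rot).T

    radii = np.array([
        ELEMENT_RADII.get(el, DEFAULT_RADIUS) * style.atom_radius_scale
        for el, *_ in conf.atoms
    ])
    colors = np.array([
        style.atom_colors.get(el, DEFAULT_COLOR) for el, *_ in conf.atoms
    ], dtype=np.float64)

    size = style.image_size
    bound = float(np.max(np.linalg.norm(coords, axis=1) + radii))
    bound = max(bound, 1e-6)
    scale = (size / 2.0) / (bound * _MARGIN)  # px per Angstrom
    half = size / 2.0

    # pixel-centre coordinates; x right, y up (row 0 is the top of the image)
    img = np.empty((size, size, 3), dtype=np.float64)
    img[:, :] = np.asarray(style.background, dtype=np.float64)
    zbuf = np.full((size, size), -np.inf)

    def to_px(xy: np.ndarray) -> np.ndarray:
        # returns (col, row) float coordinates
        return np.stack([half + xy[..., 0] * scale,
                         half - xy[..., 1] * scale], axis=-1)

    def paint_sphere(center: np.ndarray, radius_a: float, color: np.ndarray) -> None:
        r_px = radius_a * scale
        c_col, c_row = to_px(center[:2])
        lo_r = max(int(math.floor(c_row - r_px)), 0)
        hi_r = min(int(math.ceil(c_row + r_px)) + 1, size)
        lo_c = max(int(math.floor(c_col - r_px)), 0)
        hi_c = min(int(math.ceil(c_col + r_px)) + 1, size)
        if lo_r >= hi_r or lo_c >= hi_c:
            return
        rows = np.arange(lo_r, hi_r)[:, None] + 0.5
        cols = np.arange(lo_c, hi_c)[None, :] + 0.5
        dx = (cols - c_col) / scale
        dy = -(rows - c_row) / scale
        d2 = dx * dx + dy * dy
        inside = d2 <= radius_a * radius_a
        if not inside.any():
            return
        dz = np.sqrt(np.maximum(radius_a * radius_a - d2, 0.0))
        z = center[2] + dz
        sel = inside & (z > zbuf[lo_r:hi_r, lo_c:hi_c])
        if not sel.any():
            return
        normals = np.stack([
            np.broadcast_to(dx, sel.shape)[sel],
            np.broadcast_to(dy, sel.shape)[sel],
            dz[sel],
        ], axis=-1) / radius_a
        shaded = _shade(color, normals)
        sub_img = img[lo_r:hi_r, lo_c:hi_c]
        sub_z = zbuf[lo_r:hi_r, lo_c:hi_c]
        sub_img[sel] = shaded
        sub_z[sel] = z[sel]

    def paint_cylinder(a: np.ndarray, b: np.ndarray, radius_a: float,
                       color: np.ndarray) -> None:
        # screen-space cylinder impostor between 3D endpoints a and b
        axis = b - a
        axis2d = axis[:2]
        seg_len2 = float(axis2d @ axis2d)
        r_px = radius_a * scale
        pa = to_px(a[:2])
        pb = to_px(b[:2])
        lo_r = max(int(math.floor(min(pa[1], pb[1]) - r_px)), 0)
        hi_r = min(int(math.ceil(max(pa[1], pb[1]) + r_px)) + 1, size)
        lo_c = max(int(math.floor(min(pa[0], pb[0]) - r_px)), 0)
        hi_c = min(int(math.ceil(max(pa[0], pb[0]) + r_px)) + 1, size)
        if lo_r >= hi_r or lo_c >= hi_c:
            return
        rows = np.arange(lo_r, hi_r)[:, None] + 0.5
        cols = np.arange(lo_c, hi_c)[None, :] + 0.5
        px = (cols - half) / scale          # Angstrom, x right
        py = (half - rows) / scale          # Angstrom, y up
        relx = px - a[0]
        rely = py - a[1]
        if seg_len2 < 1e-12:
            return
        t = (relx * axis2d[0] + rely * axis2d[1]) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dx = relx - t * axis2d[0]
        dy = rely - t * axis2d[1]
        d2 = dx * dx + dy * dy
        inside = d2 <= radius_a * radius_a
        if not inside.any():
            return
        dz = np.sqrt(np.maximum(radius_a * radius_a - d2, 0.0))
        z = a[2] + t * axis[2] + dz
        sel = inside & (z > zbuf[lo_r:hi_r, lo_c:hi_c])
        if not sel.any():
            return
        with np.errstate(invalid="ignore"):
            norm_d = np.sqrt(np.maximum(d2, 1e-12))
        normals = np.stack([
            np.broadcast_to(dx, sel.shape)[sel],
            np.broadcast_to(dy, sel.shape)[sel],
            dz[sel],
        ], axis=-1)
        normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)
        shaded = _shade(color, normals)
        sub_img = img[lo_r:hi_r, lo_c:hi_c]
        sub_z = zbuf[lo_r:hi_r, lo_c:hi_c]
        sub_img[sel] = shaded
        sub_z[sel] = z[sel]

    # bonds first or atoms first does not matter: the z-buffer arbitrates
    for i, j, _ in conf.bonds:
        a, b = coords[i], coords[j]
        mid = (a + b) / 2.0
        paint_cylinder(a, mid, style.bond_radius, colors[i])
        paint_cylinder(mid, b, style.bond_radius, colors[j])
    for idx in range(len(coords)):
        paint_sphere(coords[idx], radii[idx], colors[idx])

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _fmt_angle(a: float) -> str:
    return str(int(a)) if float(a).is_integer() else repr(float(a))


def snapshot_filename(mol_id: str, rot: RotationTriple) -> str:
    return f"{mol_id}_{_fmt_angle(rot.rx)}_{_fmt_angle(rot.ry)}_{_fmt_angle(rot.rz)}.png"


def snapshot_molecule(conf: Conformer3D, increment: float,
                      style: RenderStyle | None = None,
                      outdir: str | Path = ".") -> SnapshotSet:
    """Render and save one PNG per enumerated rotation; overwrites on re-run."""
    style = style or RenderStyle()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    items: list[tuple[RotationTriple, Path]] = []
    for rot in enumerate_angles(increment):
        raster = render_snapshot(conf, rot, style)
        path = outdir / snapshot_filename(conf.mol_id, rot)
        Image.fromarray(raster, mode="RGB").save(path, format="PNG")
        items.append((rot, path))
    return SnapshotSet(molecule_id=conf.mol_id, increment=increment, items=items)


def load_snapshot(path: str | Path) -> np.ndarray:
    """Read a snapshot PNG back as an (S, S, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
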