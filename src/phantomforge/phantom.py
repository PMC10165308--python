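"""Labelled voxel phantoms: loading, synthesis, label surgery, voxelization.

The source geometry for the printable phantom is a 3-D integer label
volume in the style of the reference adult voxel phantoms: one organ id
per voxel, 0 outside, together with the voxel spacing in mm and a table
mapping each id to an organ name and a *compartment role*.  The roles are
the fillable compartments of the physical phantom: liver, spleen, a
spherical tumour insert, left/right kidney cortex and medulla (medulla
here meaning the combined medulla + renal pelvis), and the elliptical
body housing that provides the background compartment.

World convention: voxel index (i, j, k) (0-based) has its **center** at
((i+0.5)·sx, (j+0.5)·sy, (k+0.5)·sz) mm.

Because the real reference anatomy cannot be redistributed, the module
also synthesises a deterministic stand-in phantom: an elliptical body
housing containing ellipsoidal organs at the design volumes of the
printed phantom (liver 1306.7 mL with an embedded 15.9 mL spherical
tumour, spleen 124.9 mL, and two kidneys each split into cortex and
medulla).  It is a geometric emulation, not a reproduction of real
anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .errors import (
    EmptyRegionError,
    FeasibilityError,
    ShapeMismatchError,
    ValidationError,
    WatertightError,
)

__all__ = [
    "ROLES",
    "Organ",
    "VoxelPhantom",
    "SyntheticSpec",
    "default_synthetic_spec",
    "two_organ_synthetic_spec",
    "load_voxel_phantom",
    "generate_synthetic_phantom",
    "merge_labels",
    "clean_label_region",
    "voxelize_mesh",
    "write_phantom",
    "read_phantom",
    "load_raw_labels",
]

#: Compartment roles of the printable phantom.
ROLES = (
    "liver",
    "spleen",
    "tumour",
    "cortex-L",
    "cortex-R",
    "medulla-L",
    "medulla-R",
    "body",
    "other",
)

# 6-connectivity structuring element for component analysis
_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class Organ:
    """Name and compartment role of one label id."""

    name: str
    role: str = "other"

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown compartment role {self.role!r}; expected one of {ROLES}"
            )


@dataclass
class VoxelPhantom:
    """A labelled voxel volume with spacing and an organ table."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    organ_table: dict[int, Organ]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    @property
    def voxel_volume_mL(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def label_for_role(self, role: str) -> int:
        hits = [lab for lab, org in self.organ_table.items() if org.role == role]
        if not hits:
            raise ValidationError(f"no label with role {role!r}")
        if len(hits) > 1:
            raise ValidationError(f"role {role!r} is ambiguous: labels {hits}")
        return hits[0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def volumes_mL(self) -> dict[str, float]:
        """Voxel-count volume per organ role (mL), keyed by role then name."""
        out = {}
        vv = self.voxel_volume_mL
        for lab, org in self.organ_table.items():
            key = org.role if org.role != "other" else org.name
            out[key] = self.voxel_count(lab) * vv
        return out

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(self.labels.copy(), tuple(self.spacing),
                            dict(self.organ_table))


def load_voxel_phantom(label_data, spacing, organ_table) -> VoxelPhantom:
    """Validate raw label data into a :class:`VoxelPhantom`.

    Parameters
    ----------
    label_data : array-like of int, 3-D
    spacing : 3-tuple of positive voxel edge lengths in mm
    organ_table : mapping id -> Organ (or (name, role) tuple)

    Raises
    ------
    ShapeMismatchError
        If ``label_data`` is not a 3-D integer volume.
    ValidationError
        If spacing is non-positive, the table is empty, or the volume
        contains ids absent from the table (all offenders are listed).
    """
    labels = np.asarray(label_data)
    if labels.ndim != 3:
        raise ShapeMismatchError(f"label volume must be 3-D, got shape {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ShapeMismatchError(f"label volume must be integer, got {labels.dtype}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be 3 positive lengths, got {spacing}")
    if not organ_table:
        raise ValidationError("organ table is empty")
    table = {}
    for lab, org in organ_table.items():
        if not isinstance(org, Organ):
            org = Organ(*org)
        table[int(lab)] = org
    present = set(np.unique(labels).tolist()) - {0}
    unknown = sorted(present - set(table))
    if unknown:
        raise ValidationError(
            f"labels present in the volume but absent from the organ table: {unknown}"
        )
    return VoxelPhantom(labels, spacing, table)


# ---------------------------------------------------------------------------
# synthetic phantom
# ---------------------------------------------------------------------------

#: Design volumes (mL) of the fillable compartments of the printed phantom.
DESIGN_VOLUMES_ML = {
    "liver": 1306.7,
    "spleen": 124.9,
    "tumour": 15.9,
    "cortex-L": 90.9,
    "medulla-L": 42.9,
    "cortex-R": 75.7,
    "medulla-R": 35.7,
}

#: Design volume (mL) of the elliptical background housing.
BACKGROUND_VOLUME_ML = 8297.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for the synthetic stand-in phantom.

    ``volumes_mL`` gives the target voxel volume per organ role; the body
    is an elliptical cylinder with the given internal semi-axes and
    height.  ``seed`` drives a small deterministic placement jitter.
    """

    volumes_mL: dict = field(default_factory=lambda: dict(DESIGN_VOLUMES_ML))
    body_semi_axes_mm: tuple[float, float] = (129.0, 99.0)
    body_height_mm: float = 268.0
    spacing_mm: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for role, v in self.volumes_mL.items():
            if v <= 0:
                raise ValidationError(f"volume for {role!r} must be positive, got {v}")
        if "tumour" in self.volumes_mL and "liver" in self.volumes_mL:
            if self.volumes_mL["tumour"] >= self.volumes_mL["liver"]:
                raise FeasibilityError(
                    "tumour volume must be smaller than liver volume "
                    f"({self.volumes_mL['tumour']} >= {self.volumes_mL['liver']} mL)"
                )
        if self.spacing_mm <= 0 or self.body_height_mm <= 0 \
                or any(a <= 0 for a in self.body_semi_axes_mm):
            raise ValidationError("body dimensions and spacing must be positive")


def default_synthetic_spec(spacing_mm: float = 2.0, seed: int = 0) -> SyntheticSpec:
    """Full seven-compartment phantom at the printed design volumes."""
    return SyntheticSpec(spacing_mm=spacing_mm, seed=seed)


def two_organ_synthetic_spec(spacing_mm: float = 2.0, seed: int = 0) -> SyntheticSpec:
    """Simplified spleen + right-kidney insert variant (for a cylindrical
    calibration housing); same production pipeline, fewer compartments."""
    keep = ("spleen", "cortex-R", "medulla-R")
    vols = {k: DESIGN_VOLUMES_ML[k] for k in keep}
    return SyntheticSpec(volumes_mL=vols, spacing_mm=spacing_mm, seed=seed)


# default label ids for the synthetic phantom
_SYNTH_LABELS = {
    "body": 1,
    "liver": 2,
    "tumour": 3,
    "spleen": 4,
    "cortex-L": 5,
    "medulla-L": 6,
    "cortex-R": 7,
    "medulla-R": 8,
}

# organ placement relative to the body-axis center (mm) and ellipsoid
# shape ratios; scaled to meet the target volume exactly in the continuum
_PLACEMENT = {
    "liver": {"center": (38.0, 12.0, 16.0), "ratios": (78.0, 55.0, 74.0)},
    "spleen": {"center": (-75.0, 15.0, 16.0), "ratios": (30.0, 25.0, 40.0)},
    "kidney-L": {"center": (-58.0, -42.0, -39.0), "ratios": (27.8, 22.7, 50.5)},
    "kidney-R": {"center": (64.0, -52.0, -64.0), "ratios": (26.2, 21.4, 47.6)},
    # tumour center is relative to the liver center
    "tumour": {"center": (25.0, -5.0, 20.0)},
}


def _ellipsoid_mask(shape, spacing, center, semi):
    """Boolean mask of voxel centers inside an axis-aligned ellipsoid."""
    s = spacing
    idx = [(np.arange(n) + 0.5) * s for n in shape]
    dx = (idx[0] - center[0]) / semi[0]
    dy = (idx[1] - center[1]) / semi[1]
    dz = (idx[2] - center[2]) / semi[2]
    return (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2) <= 1.0


def _semi_axes(volume_mL, ratios):
    """Scale shape ratios so that 4/3·pi·a·b·c equals the target volume."""
    prod = ratios[0] * ratios[1] * ratios[2]
    s = (volume_mL * 1000.0 * 3.0 / (4.0 * math.pi * prod)) ** (1.0 / 3.0)
    return tuple(r * s for r in ratios)


def generate_synthetic_phantom(spec: SyntheticSpec | None = None) -> VoxelPhantom:
    """Rasterize the synthetic phantom described by ``spec``.

    Deterministic for a fixed seed.  Each organ's voxel-count volume lands
    within a few percent of its target (exact in the continuum limit);
    the kidneys are nested cortex/medulla pairs sharing no voxels, the
    tumour sphere is carved out of the liver, and every organ lies inside
    the body ellipse.

    Raises
    ------
    FeasibilityError
        If the targets cannot be realised on the given grid (organ
        sticking out of the body, organs colliding, tumour >= liver).
    """
    if spec is None:
        spec = default_synthetic_spec()
    h = spec.spacing_mm
    ax, ay = spec.body_semi_axes_mm
    height = spec.body_height_mm
    margin = 2 * h
    nx = int(math.ceil((2 * ax + 2 * margin) / h))
    ny = int(math.ceil((2 * ay + 2 * margin) / h))
    nz = int(math.ceil((height + 2 * margin) / h))
    shape = (nx, ny, nz)
    center = (nx * h / 2.0, ny * h / 2.0, nz * h / 2.0)
    rng = np.random.default_rng(spec.seed)

    # body: elliptical cylinder
    ix = (np.arange(nx) + 0.5) * h
    iy = (np.arange(ny) + 0.5) * h
    iz = (np.arange(nz) + 0.5) * h
    ex = (ix - center[0]) / ax
    ey = (iy - center[1]) / ay
    in_ellipse = (ex[:, None] ** 2 + ey[None, :] ** 2) <= 1.0
    in_height = np.abs(iz - center[2]) <= height / 2.0
    body = in_ellipse[:, :, None] & in_height[None, None, :]

    labels = np.zeros(shape, dtype=np.uint8)
    labels[body] = _SYNTH_LABELS["body"]

    def jitter():
        return rng.uniform(-0.5, 0.5, size=3)

    def world(rel):
        return tuple(c + r for c, r in zip(center, rel))

    def place(mask, label, what):
        if not np.all(body[mask]):
            raise FeasibilityError(f"{what} does not fit inside the body ellipse")
        clash = mask & (labels != _SYNTH_LABELS["body"]) & (labels != 0)
        if clash.any():
            other = sorted(np.unique(labels[clash]).tolist())
            raise FeasibilityError(f"{what} collides with labels {other}")
        labels[mask] = label

    vols = spec.volumes_mL
    liver_mask = None
    if "liver" in vols:
        target = vols["liver"] + vols.get("tumour", 0.0)
        c = world(np.asarray(_PLACEMENT["liver"]["center"]) + jitter())
        semi = _semi_axes(target, _PLACEMENT["liver"]["ratios"])
        liver_mask = _ellipsoid_mask(shape, h, c, semi)
        place(liver_mask, _SYNTH_LABELS["liver"], "liver")
        if "tumour" in vols:
            r = (vols["tumour"] * 1000.0 * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
            tc = tuple(a + b for a, b in zip(c, _PLACEMENT["tumour"]["center"]))
            tmask = _ellipsoid_mask(shape, h, tc, (r, r, r))
            if not np.all(liver_mask[tmask]):
                raise FeasibilityError("tumour sphere does not fit inside the liver")
            labels[tmask] = _SYNTH_LABELS["tumour"]
    elif "tumour" in vols:
        raise FeasibilityError("a tumour compartment requires a liver to sit in")

    if "spleen" in vols:
        c = world(np.asarray(_PLACEMENT["spleen"]["center"]) + jitter())
        semi = _semi_axes(vols["spleen"], _PLACEMENT["spleen"]["ratios"])
        place(_ellipsoid_mask(shape, h, c, semi), _SYNTH_LABELS["spleen"], "spleen")

    for side in ("L", "R"):
        ck, mk = f"cortex-{side}", f"medulla-{side}"
        if ck not in vols:
            continue
        outer_vol = vols[ck] + vols.get(mk, 0.0)
        pl = _PLACEMENT[f"kidney-{side}"]
        c = world(np.asarray(pl["center"]) + jitter())
        semi = _semi_axes(outer_vol, pl["ratios"])
        outer = _ellipsoid_mask(shape, h, c, semi)
        place(outer, _SYNTH_LABELS[ck], f"kidney-{side}")
        if mk in vols:
            f = (vols[mk] / outer_vol) ** (1.0 / 3.0)
            inner = _ellipsoid_mask(shape, h, c, tuple(a * f for a in semi))
            labels[inner] = _SYNTH_LABELS[mk]

    table = {
        _SYNTH_LABELS["body"]: Organ("body housing", "body"),
    }
    names = {
        "liver": "liver", "tumour": "tumour insert", "spleen": "spleen",
        "cortex-L": "left kidney cortex", "medulla-L": "left kidney medulla",
        "cortex-R": "right kidney cortex", "medulla-R": "right kidney medulla",
    }
    for role in vols:
        table[_SYNTH_LABELS[role]] = Organ(names[role], role)

    phantom = load_voxel_phantom(labels, (h, h, h), table)

    # volume sanity: targets must be met to within 5 %
    achieved = phantom.volumes_mL()
    for role, target in vols.items():
        got = achieved.get(role, 0.0)
        if abs(got - target) / target > 0.05:
            raise FeasibilityError(
                f"{role} voxel volume {got:.1f} mL misses target {target} mL by "
                f"more than 5% at {h} mm spacing"
            )
    return phantom


# ---------------------------------------------------------------------------
# label surgery
# ---------------------------------------------------------------------------

def merge_labels(phantom: VoxelPhantom, mapping: dict[int, int]) -> VoxelPhantom:
    """Relabel voxels ``old -> new`` (e.g. renal pelvis into medulla).

    All old and new ids must exist in the organ table; merged-away ids are
    dropped from the table.  The total number of nonzero voxels is
    conserved.
    """
    unknown = sorted(set(mapping) - set(phantom.organ_table))
    if unknown:
        raise ValidationError(f"mapping references unknown labels: {unknown}")
    bad_targets = sorted(
        {new for new in mapping.values()
         if new not in phantom.organ_table and new != 0} | \
        {new for new in mapping.values() if new == 0}
    )
    if bad_targets:
        raise ValidationError(f"mapping targets invalid labels: {bad_targets}")
    labels = phantom.labels.copy()
    for old, new in mapping.items():
        if old != new:
            labels[phantom.labels == old] = new
    table = {lab: org for lab, org in phantom.organ_table.items()
             if lab not in mapping or mapping[lab] == lab}
    return VoxelPhantom(labels, tuple(phantom.spacing), table)


def clean_label_region(
    phantom: VoxelPhantom,
    label: int,
    reassign_to: int,
    cavity_threshold: int = 27,
    absorb_background: bool = False,
) -> tuple[VoxelPhantom, dict]:
    """Make a label region a single 6-connected component without small cavities.

    Detached components (everything but the largest 6-connected piece)
    are reassigned to ``reassign_to``.  Interior cavities of *other*
    labels smaller than ``cavity_threshold`` voxels are absorbed into
    ``label``; cavities of the background (0) are only absorbed when
    ``absorb_background`` is set, since that changes the total labelled
    voxel count.

    Returns the cleaned phantom and a change log
    ``{"detached_moved": n, "cavity_absorbed": n}``.
    """
    if label not in phantom.organ_table:
        raise ValidationError(f"label {label} not in organ table")
    if reassign_to != 0 and reassign_to not in phantom.organ_table:
        raise ValidationError(f"reassign target {reassign_to} not in organ table")
    mask = phantom.labels == label
    if not mask.any():
        raise EmptyRegionError(f"label {label} region is empty")

    labels = phantom.labels.copy()
    comp, ncomp = ndimage.label(mask, structure=_CONN6)
    moved = 0
    if ncomp > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, range(1, ncomp + 1))
        keep = int(np.argmax(sizes)) + 1
        detached = mask & (comp != keep)
        moved = int(detached.sum())
        labels[detached] = reassign_to
        mask = mask & (comp == keep)

    filled = ndimage.binary_fill_holes(mask, structure=_CONN6)
    holes = filled & ~mask
    absorbed = 0
    if holes.any():
        hcomp, nh = ndimage.label(holes, structure=_CONN6)
        sizes = ndimage.sum_labels(np.ones_like(hcomp), hcomp, range(1, nh + 1))
        for i in range(1, nh + 1):
            if sizes[i - 1] >= cavity_threshold:
                continue
            sel = hcomp == i
            if not absorb_background:
                sel = sel & (labels != 0)
            absorbed += int(sel.sum())
            labels[sel] = label
    out = VoxelPhantom(labels, tuple(phantom.spacing), dict(phantom.organ_table))
    return out, {"detached_moved": moved, "cavity_absorbed": absorbed}


# ---------------------------------------------------------------------------
# mesh -> voxel rasterization
# ---------------------------------------------------------------------------

def voxelize_mesh(mesh, spacing, shape, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Rasterize a closed mesh to a boolean mask: voxel center inside surface.

    Classification is by ray parity: for every grid column the z heights
    at which the surface crosses it are accumulated, and a voxel is
    inside iff an odd number of crossings lies below its center.  Voxel
    centers follow the (index+0.5)·spacing convention relative to
    ``origin``.

    Raises :class:`WatertightError` for an open mesh.
    """
    if not mesh.is_watertight:
        raise WatertightError("voxelize_mesh requires a watertight mesh")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    sx, sy, sz = spacing
    nx, ny, nz = (int(n) for n in shape)
    v = np.asarray(mesh.vertices, dtype=float) - np.asarray(origin, dtype=float)
    tv = v[np.asarray(mesh.faces)]          # (M, 3, 3)

    # nudge ray origins off exact edge/vertex alignments
    eps_x = 1e-6 * sx
    eps_y = 0.618e-6 * sy

    x = tv[:, :, 0]
    y = tv[:, :, 1]
    xmin = np.maximum(np.floor((x.min(axis=1) - eps_x) / sx - 0.5).astype(np.int64), 0)
    xmax = np.minimum(np.ceil((x.max(axis=1) - eps_x) / sx - 0.5).astype(np.int64), nx - 1)
    ymin = np.maximum(np.floor((y.min(axis=1) - eps_y) / sy - 0.5).astype(np.int64), 0)
    ymax = np.minimum(np.ceil((y.max(axis=1) - eps_y) / sy - 0.5).astype(np.int64), ny - 1)
    wx = np.maximum(xmax - xmin + 1, 0)
    wy = np.maximum(ymax - ymin + 1, 0)
    counts = wx * wy
    live = counts > 0
    if not live.any():
        return np.zeros((nx, ny, nz), dtype=bool)
    tv, xmin, ymin, wx, wy, counts = (
        a[live] for a in (tv, xmin, ymin, wx, wy, counts)
    )

    offsets = np.concatenate(([0], np.cumsum(counts)))
    total = int(offsets[-1])
    tri = np.repeat(np.arange(len(tv)), counts)
    li = np.arange(total) - offsets[tri]
    i = xmin[tri] + li // wy[tri]
    j = ymin[tri] + li % wy[tri]
    px = (i + 0.5) * sx + eps_x
    py = (j + 0.5) * sy + eps_y

    x0, y0, z0 = tv[tri, 0, 0], tv[tri, 0, 1], tv[tri, 0, 2]
    x1, y1, z1 = tv[tri, 1, 0], tv[tri, 1, 1], tv[tri, 1, 2]
    x2, y2, z2 = tv[tri, 2, 0], tv[tri, 2, 1], tv[tri, 2, 2]
    det = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
    ok = det != 0.0
    det = np.where(ok, det, 1.0)
    b1 = ((px - x0) * (y2 - y0) - (x2 - x0) * (py - y0)) / det
    b2 = ((x1 - x0) * (py - y0) - (px - x0) * (y1 - y0)) / det
    b0 = 1.0 - b1 - b2
    hit = ok & (b0 >= 0.0) & (b1 >= 0.0) & (b2 >= 0.0)
    if not hit.any():
        return np.zeros((nx, ny, nz), dtype=bool)
    zc = b0[hit] * z0[hit] + b1[hit] * z1[hit] + b2[hit] * z2[hit]
    # first cell whose center lies above the crossing
    ka = np.ceil(zc / sz - 0.5).astype(np.int64)
    ka = np.clip(ka, 0, nz)
    cross = np.zeros((nx, ny, nz + 1), dtype=np.int64)
    np.add.at(cross, (i[hit], j[hit], ka), 1)
    parity = np.cumsum(cross[:, :, :nz], axis=2) & 1
    return parity.astype(bool)


# ---------------------------------------------------------------------------
# raw-volume + sidecar I/O
# ---------------------------------------------------------------------------

_DTYPES = {"uint8": np.uint8, "uint16": np.uint16, "int16": np.int16,
           "int32": np.int32, "uint32": np.uint32}


def load_raw_labels(path, shape, dtype: str = "uint8") -> np.ndarray:
    """Read a raw little-endian label volume of the declared shape."""
    if dtype not in _DTYPES:
        raise ValidationError(f"unsupported raw dtype {dtype!r}")
    dt = np.dtype(_DTYPES[dtype]).newbyteorder("<")
    raw = Path(path).read_bytes()
    expected = int(np.prod(shape)) * dt.itemsize
    if len(raw) != expected:
        raise ShapeMismatchError(
            f"{path}: {len(raw)} bytes but shape {tuple(shape)} with dtype "
            f"{dtype} needs {expected}"
        )
    return np.frombuffer(raw, dtype=dt).reshape(shape).astype(_DTYPES[dtype])


def write_phantom(phantom: VoxelPhantom, directory) -> Path:
    """Write labels.raw (little-endian) plus a metadata sidecar YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dtype = "uint8" if phantom.labels.max() < 256 else "uint16"
    arr = phantom.labels.astype(np.dtype(_DTYPES[dtype]).newbyteorder("<"))
    (directory / "labels.raw").write_bytes(arr.tobytes(order="C"))
    meta = {
        "shape": list(phantom.shape),
        "spacing_mm": [float(s) for s in phantom.spacing],
        "dtype": dtype,
        "byte_order": "little",
        "voxel_center_convention": "(index + 0.5) * spacing",
        "organs": {
            int(lab): {"name": org.name, "role": org.role}
            for lab, org in phantom.organ_table.items()
        },
    }
    (directory / "phantom.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return directory


def read_phantom(directory) -> VoxelPhantom:
    """Read a phantom written by :func:`write_phantom`."""
    directory = Path(directory)
    meta = yaml.safe_load((directory / "phantom.yaml").read_text())
    labels = load_raw_labels(directory / "labels.raw", meta["shape"], meta["dtype"])
    table = {int(lab): Organ(d["name"], d["role"])
             for lab, d in meta["organs"].items()}
    return load_voxel_phantom(labels, meta["spacing_mm"], table)
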