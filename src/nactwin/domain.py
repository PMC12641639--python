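"""Voxelized region of interest (ROI) holding the tumor and drug fields.

The ROI Omega_0 is a regular 3-D voxel grid with isotropic spacing and a
boolean membership mask; its complement boundary is the closed surface
through which zero-flux conditions are enforced by the solver.  All volume
bookkeeping (seed placement, the lesion-volume functional) lives here, so
that the only clinically validated observable -- the integrated tumor
volume V* in cm^3 -- is exact by construction on the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MM3_PER_CM3 = 1000.0


class DomainError(ValueError):
    """Base class for ROI-construction failures."""


class EmptyMaskError(DomainError):
    """The imported or constructed mask contains no voxels."""


class OpenSurfaceError(DomainError):
    """An imported surface is not watertight and cannot be voxelized."""


class MaskReadError(DomainError):
    """The mask file could not be read."""


@dataclass(frozen=True)
class Domain:
    """A voxel grid with an embedded ROI mask.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis; each entry must be >= 3 so that interior stencils
        exist.
    spacing_mm : float
        Isotropic voxel edge length in millimetres.
    mask : numpy.ndarray of bool
        ROI membership per voxel (True inside Omega_0).
    """

    shape: tuple[int, int, int]
    spacing_mm: float
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise DomainError(f"spacing must be positive, got {self.spacing_mm}")
        if len(self.shape) != 3 or any(s < 3 for s in self.shape):
            raise DomainError(f"grid shape must be a triple with entries >= 3, got {self.shape}")
        if tuple(self.mask.shape) != tuple(self.shape):
            raise DomainError("mask shape does not match grid shape")
        if self.mask.dtype != np.bool_:
            object.__setattr__(self, "mask", self.mask.astype(bool))
        if not self.mask.any():
            raise EmptyMaskError("ROI mask is empty")
        self.mask.setflags(write=False)

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3, exactly (spacing/10)^3."""
        return (self.spacing_mm / 10.0) ** 3

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def roi_volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_cm3

    @property
    def center_index(self) -> tuple[int, int, int]:
        return tuple(s // 2 for s in self.shape)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape, dtype=float)

    def sidecar(self) -> dict:
        """JSON-serializable grid metadata (shape, spacing, origin)."""
        return {
            "shape": list(self.shape),
            "spacing_mm": self.spacing_mm,
            "origin": [0.0, 0.0, 0.0],
            "n_roi_voxels": self.n_voxels,
            "roi_volume_cm3": self.roi_volume_cm3,
        }


@dataclass(frozen=True)
class ScalarField:
    """One real value per voxel, tagged by physical role.

    ``kind="tumor"`` fields are dimensionless cell densities constrained to
    [0, K]; ``kind="drug"`` fields are non-negative dimensionless
    concentrations.  Values outside the ROI mask are identically zero.
    """

    values: np.ndarray = field(repr=False)
    kind: str = "tumor"

    def __post_init__(self) -> None:
        if self.kind not in ("tumor", "drug"):
            raise ValueError(f"unknown field kind {self.kind!r}")

    def validate(self, domain: Domain, k: float = 1.0) -> None:
        if tuple(self.values.shape) != tuple(domain.shape):
            raise DomainError("field shape does not match domain")
        if np.any(self.values[~domain.mask] != 0.0):
            raise DomainError("field is non-zero outside the ROI mask")
        if self.values.min() < 0:
            raise DomainError("field has negative values")
        if self.kind == "tumor" and self.values.max() > k * (1 + 1e-12):
            raise DomainError("tumor density exceeds carrying capacity")


def _center_coords_mm(shape: tuple[int, int, int], spacing_mm: float) -> tuple[np.ndarray, ...]:
    """Voxel-center coordinates (mm) relative to the grid center, per axis."""
    axes = [spacing_mm * (np.arange(s) - (s - 1) / 2.0) for s in shape]
    return tuple(np.meshgrid(*axes, indexing="ij"))


def build_ellipsoid_domain(
    semi_axes_mm: tuple[float, float, float],
    spacing_mm: float,
    padding_mm: float = 3.0,
) -> Domain:
    """Build a grid whose ROI is an axis-aligned ellipsoid.

    This is the synthetic stand-in for a segmented breast ROI: the mask
    marks voxels whose centers lie inside the ellipsoid, and the grid
    extends at least ``padding_mm`` beyond it on every axis.
    """
    a = np.asarray(semi_axes_mm, dtype=float)
    if a.shape != (3,) or np.any(a <= 0):
        raise DomainError(f"semi-axes must be three positive lengths, got {semi_axes_mm}")
    if spacing_mm <= 0:
        raise DomainError("spacing must be positive")
    if spacing_mm > a.min():
        raise DomainError(
            f"spacing {spacing_mm} mm exceeds smallest semi-axis {a.min()} mm: lesion unresolvable"
        )
    shape = tuple(
        max(3, int(2 * np.ceil((ax + padding_mm) / spacing_mm) + 1)) for ax in a
    )
    x, y, z = _center_coords_mm(shape, spacing_mm)
    mask = (x / a[0]) ** 2 + (y / a[1]) ** 2 + (z / a[2]) ** 2 <= 1.0
    return Domain(shape=shape, spacing_mm=spacing_mm, mask=mask)


def build_sphere_domain(radius_mm: float, spacing_mm: float, padding_mm: float = 3.0) -> Domain:
    return build_ellipsoid_domain((radius_mm, radius_mm, radius_mm), spacing_mm, padding_mm)


def place_seed(
    domain: Domain,
    center: tuple[int, int, int],
    seed_volume_cm3: float,
    phi_ci: float,
    k: float = 1.0,
) -> tuple[ScalarField, float]:
    """Deposit a uniform seed lesion and return (field, V_i*).

    A ball of voxels around ``center`` is set to ``phi_ci`` such that the
    seed-region volume matches ``seed_volume_cm3`` to within half a voxel:
    voxels are taken in order of distance from the center (ties broken
    lexicographically), so the realized region is the best ball-shaped
    approximation the grid allows.  The integrated initial field is
    V_i* = phi_ci * (seed-region volume).
    """
    if not (0 <= phi_ci < k):
        raise DomainError(f"phi_ci must lie in [0, K), got {phi_ci}")
    if seed_volume_cm3 < 0:
        raise DomainError("seed volume must be non-negative")
    if seed_volume_cm3 >= domain.roi_volume_cm3:
        raise DomainError(
            f"seed volume {seed_volume_cm3} cm^3 is not smaller than the "
            f"ROI volume {domain.roi_volume_cm3:.3f} cm^3"
        )
    n_seed = int(round(seed_volume_cm3 / domain.voxel_volume_cm3))
    values = domain.zeros()
    if n_seed == 0 or phi_ci == 0.0:
        field_ = ScalarField(values=values, kind="tumor")
        v_i_star = phi_ci * n_seed * domain.voxel_volume_cm3
        return field_, v_i_star

    idx = np.indices(domain.shape).reshape(3, -1).T
    d2 = ((idx - np.asarray(center)) ** 2).sum(axis=1)
    # stable lexicographic tie-break: argsort on (distance, i, j, k)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
    chosen = idx[order[:n_seed]]
    if not domain.mask[chosen[:, 0], chosen[:, 1], chosen[:, 2]].all():
        raise DomainError("seed region escapes the ROI mask")
    values[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = phi_ci
    v_i_star = phi_ci * n_seed * domain.voxel_volume_cm3
    return ScalarField(values=values, kind="tumor"), v_i_star


def integrate_field(domain: Domain, field_: ScalarField | np.ndarray) -> float:
    """Lesion-volume functional: sum of field values over the mask times
    the voxel volume, in cm^3."""
    values = field_.values if isinstance(field_, ScalarField) else field_
    if tuple(values.shape) != tuple(domain.shape):
        raise DomainError("field shape does not match domain")
    return float(values[domain.mask].sum()) * domain.voxel_volume_cm3


def save_mask(domain: Domain, path: str | Path) -> Path:
    """Export the ROI mask as a NIfTI volume (uint8, isotropic affine)."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([domain.spacing_mm, domain.spacing_mm, domain.spacing_mm, 1.0])
    img = nib.Nifti1Image(domain.mask.astype(np.uint8), affine)
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
    Path(str(sidecar) + ".json").write_text(json.dumps(domain.sidecar(), indent=2))
    return path


def load_mask(path: str | Path, spacing_mm: float | None = None) -> Domain:
    """Import an ROI from a NIfTI mask or a closed STL surface.

    NIfTI: non-zero voxels form the mask; spacing is taken from the header
    (must be isotropic).  STL: the closed surface is voxelized at
    ``spacing_mm`` by testing voxel centers for containment.
    """
    path = Path(path)
    if not path.exists():
        raise MaskReadError(f"no such file: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        return _load_nifti_mask(path)
    if suffixes.endswith(".stl"):
        if spacing_mm is None or spacing_mm <= 0:
            raise DomainError("a positive spacing is required to voxelize an STL surface")
        return _load_stl_mask(path, spacing_mm)
    raise MaskReadError(f"unsupported mask format: {path.name}")


def _load_nifti_mask(path: Path) -> Domain:
    import nibabel as nib

    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several types
        raise MaskReadError(f"could not read NIfTI file {path}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-6):
        raise DomainError(f"anisotropic NIfTI spacing {zooms} not supported")
    mask = data != 0
    if not mask.any():
        raise EmptyMaskError(f"NIfTI mask {path} contains no non-zero voxels")
    return Domain(shape=tuple(mask.shape), spacing_mm=float(zooms[0]), mask=mask)


def _load_stl_mask(path: Path, spacing_mm: float) -> Domain:
    import trimesh

    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as exc:
        raise MaskReadError(f"could not read STL file {path}: {exc}") from exc
    if mesh.is_empty or len(mesh.faces) == 0:
        raise MaskReadError(f"STL file {path} contains no geometry")
    if not mesh.is_watertight:
        raise OpenSurfaceError(f"STL surface {path} is open; cannot voxelize an open surface")
    lo, hi = mesh.bounds
    extent = hi - lo
    shape = tuple(max(3, int(np.ceil(e / spacing_mm)) + 3) for e in extent)
    centroid = (lo + hi) / 2.0
    axes = [
        centroid[i] + spacing_mm * (np.arange(shape[i]) - (shape[i] - 1) / 2.0)
        for i in range(3)
    ]
    inside = _parity_voxelize(
        np.asarray(mesh.triangles, dtype=float), axes[0], axes[1], axes[2]
    )
    if not inside.any():
        raise EmptyMaskError(f"voxelization of {path} at {spacing_mm} mm produced an empty mask")
    return Domain(shape=shape, spacing_mm=spacing_mm, mask=inside)


def _parity_voxelize(
    triangles: np.ndarray, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray
) -> np.ndarray:
    """Voxelize a closed triangle soup by ray-crossing parity.

    Casts one +x ray per (y, z) column of voxel centers, accumulates the
    x-coordinates where the ray pierces a triangle, and marks voxel
    centers behind an odd number of crossings as inside.  The column grid
    is jittered by a tiny irrational offset so rays never hit triangle
    edges or vertices exactly.
    """
    eps_y, eps_z = 1e-7 * np.sqrt(2), 1e-7 * np.sqrt(3)
    mask = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    yg, zg = np.meshgrid(ys + eps_y, zs + eps_z, indexing="ij")
    crossings: list[list[float]] = [[] for _ in range(yg.size)]
    yf, zf = yg.ravel(), zg.ravel()
    for v0, v1, v2 in triangles:
        ylo = min(v0[1], v1[1], v2[1])
        yhi = max(v0[1], v1[1], v2[1])
        zlo = min(v0[2], v1[2], v2[2])
        zhi = max(v0[2], v1[2], v2[2])
        cand = np.nonzero((yf >= ylo) & (yf <= yhi) & (zf >= zlo) & (zf <= zhi))[0]
        if not len(cand):
            continue
        # barycentric coordinates in the (y, z) projection
        d = (v1[1] - v0[1]) * (v2[2] - v0[2]) - (v2[1] - v0[1]) * (v1[2] - v0[2])
        if d == 0.0:
            continue  # triangle edge-on to the ray: adjacent faces cover it
        py, pz = yf[cand] - v0[1], zf[cand] - v0[2]
        a = (py * (v2[2] - v0[2]) - (v2[1] - v0[1]) * pz) / d
        b = ((v1[1] - v0[1]) * pz - py * (v1[2] - v0[2])) / d
        hit = (a >= 0) & (b >= 0) & (a + b <= 1)
        if not hit.any():
            continue
        x_hit = v0[0] + a[hit] * (v1[0] - v0[0]) + b[hit] * (v2[0] - v0[0])
        for idx, xh in zip(cand[hit], x_hit):
            crossings[idx].append(float(xh))
    ny, nz = len(ys), len(zs)
    for col, xcross in enumerate(crossings):
        if not xcross:
            continue
        iy, iz = divmod(col, nz)
        parity = (np.searchsorted(np.sort(xcross), xs, side="right") % 2).astype(bool)
        mask[:, iy, iz] = parity
    return mask
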