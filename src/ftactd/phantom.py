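"""Synthetic tensor fields and diffusion-weighted volumes with known geometry.

Three desk-scale phantom geometries with voxel-wise ground truth:

* ``straight`` — one cylindrical bundle along the x axis;
* ``curved``   — a quarter-circle arc bundle in the xy plane;
* ``crossing`` — two straight bundles intersecting at a chosen angle, with
  the overlap voxels holding the arithmetic mean of the two bundle tensors
  (a planar, disk-like tensor: the single-tensor signature of a fiber
  crossing).

In-bundle tensors are ``R diag(l1, l2, l3) R'`` oriented along the local
fiber tangent; the background is isotropic gray-matter-like diffusivity.
The forward signal model is ``S = S0 exp(-b g' D g)`` with optional Rician
noise (magnitude of a complex Gaussian perturbation).  The default
acquisition is one b=0 volume plus 32 directions at b = 1000 s/mm^2 on a
2 mm isotropic grid — a routine single-shell DTI protocol.

Each phantom also carries :class:`ConnectivityGroundTruth`: per bundle a
voxel mask, the two endpoint ROIs (end slabs extended one voxel past the
bundle tip, so streamlines terminating at the FA falloff still land inside),
and the world-mm centerline.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .dwi_model import TensorField, tensor_to_components
from .io import DWIVolume, GradientTable

__all__ = [
    "PhantomSpec",
    "Bundle",
    "ConnectivityGroundTruth",
    "DIRECTIONS_32",
    "default_gradient_table",
    "make_tensor_field",
    "make_phantom",
    "simulate_dwi",
    "uniform_tensor_field",
]

#: 32 unit gradient directions from electrostatic (antipodally symmetric)
#: repulsion on the sphere; fixed table, design-matrix condition number 1.58.
DIRECTIONS_32 = np.array([
    [-0.09348841, -0.64895790, 0.75505864],
    [-0.32223148, 0.55150895, 0.76941845],
    [0.36035170, -0.93005209, 0.07176187],
    [-0.67550915, 0.56001495, 0.47965680],
    [0.03281793, 0.82113450, 0.56979042],
    [0.13066437, -0.23816176, 0.96239586],
    [-0.95352999, -0.15014297, 0.26122338],
    [0.23879952, -0.84689808, 0.47511939],
    [-0.49320690, -0.67587925, 0.54766249],
    [0.79053098, 0.56128525, 0.24498907],
    [-0.82221796, 0.16188653, 0.54566508],
    [-0.51357633, 0.13830967, 0.84682335],
    [0.41519080, 0.12058550, 0.90170712],
    [0.53484370, 0.52776844, 0.65985051],
    [-0.94782457, 0.29962341, 0.10887792],
    [-0.16027224, -0.92949833, 0.33218318],
    [0.97434854, 0.15010057, 0.16767451],
    [-0.36078871, 0.85668201, 0.36868340],
    [-0.51306875, -0.85510222, 0.07456976],
    [0.37011155, -0.53486858, 0.75956109],
    [-0.80451294, -0.55302690, 0.21661067],
    [0.13770411, 0.49841010, 0.85593513],
    [-0.33217651, -0.29323165, 0.89647865],
    [0.42252227, 0.83282485, 0.35759991],
    [-0.72969566, 0.68254295, 0.04098015],
    [0.65865556, -0.63914664, 0.39706981],
    [0.65919110, -0.21993657, 0.71909318],
    [0.79708396, 0.18006226, 0.57639808],
    [0.90272401, -0.27138525, 0.33382542],
    [-0.09265706, 0.14389882, 0.98524505],
    [-0.70672735, -0.29060280, 0.64504764],
    [0.05310870, 0.99220869, 0.11270040],
])


def default_gradient_table(b_value: float = 1000.0, n_b0: int = 1) -> GradientTable:
    """Single-shell table: ``n_b0`` b=0 volumes plus 32 directions at ``b_value``."""
    n_dwi = len(DIRECTIONS_32)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dwi, b_value)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), DIRECTIONS_32])
    return GradientTable(bvals, bvecs)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and acquisition parameters of a synthetic phantom.

    Bundle eigenvalues default to white-matter-like (1.7, 0.3, 0.3)e-3
    mm^2/s (FA about 0.80); the background is isotropic at 0.7e-3 mm^2/s,
    typical of gray matter.
    """

    geometry: str = "straight"  # straight | curved | crossing
    grid_shape: tuple[int, int, int] = (30, 30, 30)
    voxel_size: float = 2.0  # mm, isotropic
    bundle_eigenvalues: tuple[float, float, float] = (1.7e-3, 0.3e-3, 0.3e-3)
    crossing_angle: float = 60.0  # degrees between the two bundle axes
    background_diffusivity: float = 0.7e-3  # mm^2/s
    bundle_radius: float = 4.0  # mm
    bundle_length: float = 40.0  # mm (straight); crossing uses 50 mm arms
    s0: float = 1000.0
    noise_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        l1, l2, l3 = self.bundle_eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("bundle eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if not 0 < self.crossing_angle <= 90:
            raise ValueError("crossing_angle must be in (0, 90] degrees")
        if self.geometry not in ("straight", "curved", "crossing"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass
class Bundle:
    """Ground truth for one fiber bundle."""

    mask: np.ndarray  # voxels the bundle occupies
    roi_a: np.ndarray  # endpoint region, start
    roi_b: np.ndarray  # endpoint region, end
    centerline: np.ndarray  # (n, 3) world mm, ordered a -> b


@dataclass
class ConnectivityGroundTruth:
    """Bundle masks, endpoint-ROI pairs and centerlines in one world frame."""

    bundles: list[Bundle]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def _prolate_tensor(direction: np.ndarray, evals) -> np.ndarray:
    """Axially symmetric tensor with principal axis ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    l1, l2, l3 = evals
    # l2 and l3 share the transverse plane; exact for l2 == l3, and for
    # l2 != l3 the secondary axis is the z-most transverse direction
    t1 = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(t1) < 1e-8:
        t1 = np.cross(d, [1.0, 0.0, 0.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(d, t1)
    return l1 * np.outer(d, d) + l3 * np.outer(t1, t1) + l2 * np.outer(t2, t2)


def _voxel_centers(shape, affine) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _tube_masks(centers, origin, axis, half_length, radius, voxel):
    """Bundle mask plus endpoint ROI slabs for a straight tube."""
    rel = centers - origin
    s = rel @ axis
    lat = np.linalg.norm(rel - s[..., None] * axis, axis=-1)
    in_rad = lat <= radius + 1e-9
    mask = in_rad & (np.abs(s) <= half_length + 1e-9)
    # end slabs: two voxel layers inside the tip plus one beyond it
    roi_a = in_rad & (s >= -half_length - voxel - 1e-9) & (s <= -half_length + 2 * voxel + 1e-9)
    roi_b = in_rad & (s <= half_length + voxel + 1e-9) & (s >= half_length - 2 * voxel - 1e-9)
    return mask, roi_a, roi_b, s


def uniform_tensor_field(
    shape=(20, 20, 20),
    voxel_size: float = 2.0,
    eigenvalues=(1.0e-3, 1.0e-3, 0.2e-3),
    axes: np.ndarray | None = None,
) -> tuple[TensorField, np.ndarray]:
    """Grid filled with one constant tensor (useful for limit-case studies).

    ``axes`` (3x3, rows = eigenvector directions) defaults to the identity,
    i.e. ``diag(eigenvalues)`` everywhere.  Returns the field and an
    all-ones mask.
    """
    if axes is None:
        axes = np.eye(3)
    axes = np.asarray(axes, dtype=float)
    D = axes.T @ np.diag(np.asarray(eigenvalues, dtype=float)) @ axes
    comp = np.broadcast_to(
        tensor_to_components(D), tuple(shape) + (6,)
    ).copy()
    affine = np.diag([voxel_size] * 3 + [1.0])
    return TensorField(comp, affine), np.ones(shape, dtype=bool)


def make_tensor_field(
    spec: PhantomSpec,
) -> tuple[TensorField, np.ndarray, ConnectivityGroundTruth]:
    """Construct the phantom tensor field, tracking mask and ground truth.

    The returned mask covers the whole grid (the "brain"); bundle membership
    lives in the ground truth.  Raises if the requested geometry does not
    fit the grid.
    """
    shape = tuple(spec.grid_shape)
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    centers = _voxel_centers(shape, affine)
    extent = (np.asarray(shape) - 1) * spec.voxel_size
    mid = extent / 2.0

    iso = spec.background_diffusivity * np.eye(3)
    tensors = np.broadcast_to(iso, shape + (3, 3)).copy()
    bundles: list[Bundle] = []
    vx = spec.voxel_size

    if spec.geometry == "straight":
        half = spec.bundle_length / 2.0
        if half + 2 * vx > mid[0] or spec.bundle_radius > min(mid[1], mid[2]):
            raise ValueError("straight bundle does not fit the grid")
        axis = np.array([1.0, 0.0, 0.0])
        mask, roi_a, roi_b, _ = _tube_masks(
            centers, mid, axis, half, spec.bundle_radius, vx
        )
        tensors[mask] = _prolate_tensor(axis, spec.bundle_eigenvalues)
        n_pts = int(round(spec.bundle_length)) + 1
        s = np.linspace(-half, half, n_pts)
        cl_pts = mid + s[:, None] * axis
        bundles.append(Bundle(mask, roi_a, roi_b, cl_pts))

    elif spec.geometry == "curved":
        # quarter-circle arc in the xy midplane, from angle 0 to 90 degrees
        radius = min(mid[0], mid[1]) - spec.bundle_radius - 2 * vx
        if radius <= 2 * spec.bundle_radius:
            raise ValueError("curved bundle does not fit the grid")
        cx = np.array([mid[0] - radius / 2, mid[1] - radius / 2, mid[2]])
        rel = centers - cx
        rho = np.linalg.norm(rel[..., :2], axis=-1)
        phi = np.arctan2(rel[..., 1], rel[..., 0])  # radians
        dist = np.sqrt((rho - radius) ** 2 + rel[..., 2] ** 2)
        in_rad = dist <= spec.bundle_radius + 1e-9
        # arc-length coordinate; one-voxel overhang at each end for the ROIs
        t = radius * phi
        d_ang = 2 * vx  # ROI depth along the arc
        mask = in_rad & (phi >= 0) & (phi <= np.pi / 2)
        roi_a = in_rad & (t >= -vx - 1e-9) & (t <= d_ang + 1e-9)
        t_end = radius * (np.pi / 2 - phi)
        roi_b = in_rad & (t_end >= -vx - 1e-9) & (t_end <= d_ang + 1e-9)
        sel = np.argwhere(mask)
        for i, j, k in sel:
            ph = phi[i, j, k]
            tangent = np.array([-np.sin(ph), np.cos(ph), 0.0])
            tensors[i, j, k] = _prolate_tensor(tangent, spec.bundle_eigenvalues)
        n_pts = int(round(radius * np.pi / 2)) + 1
        ph = np.linspace(0, np.pi / 2, n_pts)
        cl_pts = cx + radius * np.stack(
            [np.cos(ph), np.sin(ph), np.zeros_like(ph)], axis=-1
        )
        bundles.append(Bundle(mask, roi_a, roi_b, cl_pts))

    else:  # crossing
        half = 25.0  # mm arm length from the center
        theta = np.deg2rad(spec.crossing_angle) / 2.0
        axes = [
            np.array([np.cos(theta), np.sin(theta), 0.0]),
            np.array([np.cos(theta), -np.sin(theta), 0.0]),
        ]
        reach = half * max(np.cos(theta), np.sin(theta)) + 2 * vx
        if reach > min(mid[0], mid[1]) + vx:
            raise ValueError("crossing bundles do not fit the grid")
        parts = []
        for axis in axes:
            mask, roi_a, roi_b, _ = _tube_masks(
                centers, mid, axis, half, spec.bundle_radius, vx
            )
            D = _prolate_tensor(axis, spec.bundle_eigenvalues)
            n_pts = int(round(2 * half)) + 1
            s = np.linspace(-half, half, n_pts)
            cl_pts = mid + s[:, None] * axis
            parts.append((mask, roi_a, roi_b, cl_pts, D))
            bundles.append(Bundle(mask, roi_a, roi_b, cl_pts))
        m0, m1 = parts[0][0], parts[1][0]
        only0 = m0 & ~m1
        only1 = m1 & ~m0
        both = m0 & m1
        tensors[only0] = parts[0][4]
        tensors[only1] = parts[1][4]
        # Overlap voxels hold the oblate single-tensor equivalent of the
        # crossing: degenerate in the plane spanned by the two axes, with
        # the same trace as the arithmetic two-tensor mean (and equal to
        # that mean at 90 degrees).  DTI cannot resolve two populations in
        # one voxel; the disk-like tensor is the crossing's single-tensor
        # signature and leaves the principal eigenvector undefined in-plane.
        l1, l2, l3 = spec.bundle_eigenvalues
        normal = np.cross(axes[0], axes[1])
        normal /= np.linalg.norm(normal)
        m_in = 0.5 * (l1 + l2)
        D_cross = m_in * (np.eye(3) - np.outer(normal, normal)) + l3 * np.outer(
            normal, normal
        )
        tensors[both] = D_cross

    mask_all = np.ones(shape, dtype=bool)
    comp = tensor_to_components(tensors)
    return (
        TensorField(comp, affine),
        mask_all,
        ConnectivityGroundTruth(bundles, affine),
    )


def simulate_dwi(
    tensors: TensorField,
    gtab: GradientTable,
    s0: float = 1000.0,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> DWIVolume:
    """Forward-simulate the DWI signal ``S = S0 exp(-b g' D g)`` per volume.

    ``noise_sigma > 0`` applies Rician corruption
    ``S' = sqrt((S + n1)^2 + n2^2)`` with independent
    ``n1, n2 ~ Normal(0, sigma^2)``, seeded by ``rng_seed``.
    """
    D = tensors.as_matrices()
    g = gtab.bvecs
    b = gtab.bvals
    # quadratic form g' D g for every voxel and direction
    q = np.einsum("...ij,nj->...ni", D, g)
    gdg = np.einsum("...ni,ni->...n", q, g)
    signal = s0 * np.exp(-b * gdg)
    signal[..., gtab.b0_mask] = s0
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        n1 = rng.normal(0.0, noise_sigma, signal.shape)
        n2 = rng.normal(0.0, noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return DWIVolume(signal, tensors.affine)


def make_phantom(
    spec: PhantomSpec, gtab: GradientTable | None = None
) -> tuple[DWIVolume, GradientTable, np.ndarray, ConnectivityGroundTruth]:
    """Full phantom: simulated DWI, gradient table, mask and ground truth."""
    if gtab is None:
        gtab = default_gradient_table()
    tensors, mask, gt = make_tensor_field(spec)
    dwi = simulate_dwi(
        tensors, gtab, s0=spec.s0, noise_sigma=spec.noise_sigma, rng_seed=spec.rng_seed
    )
    return dwi, gtab, mask, gt


# ---------------------------------------------------------------------------
# ground-truth serialization (JSON manifest + NIfTI masks + TCK centerlines)

def save_ground_truth(gt: ConnectivityGroundTruth, prefix: str | os.PathLike) -> str:
    """Write ROI/bundle masks as NIfTI, centerlines as TCK, plus a JSON manifest.

    Returns the manifest path (``<prefix>_ground_truth.json``).
    """
    from .io import write_scalar_map, write_tractogram
    from .tracking import Streamline, Tractogram

    prefix = os.fspath(prefix)
    manifest = {"affine": np.asarray(gt.affine).tolist(), "bundles": []}
    shape = gt.bundles[0].mask.shape if gt.bundles else (1, 1, 1)
    for i, b in enumerate(gt.bundles):
        paths = {
            "mask": f"{prefix}_bundle{i}_mask.nii.gz",
            "roi_a": f"{prefix}_bundle{i}_roiA.nii.gz",
            "roi_b": f"{prefix}_bundle{i}_roiB.nii.gz",
            "centerline": f"{prefix}_bundle{i}_centerline.tck",
        }
        write_scalar_map(b.mask.astype(np.float32), gt.affine, paths["mask"])
        write_scalar_map(b.roi_a.astype(np.float32), gt.affine, paths["roi_a"])
        write_scalar_map(b.roi_b.astype(np.float32), gt.affine, paths["roi_b"])
        write_tractogram(
            Tractogram([Streamline(b.centerline)], gt.affine, shape),
            paths["centerline"],
        )
        manifest["bundles"].append(paths)
    out = f"{prefix}_ground_truth.json"
    with open(out, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def load_ground_truth(manifest_path: str | os.PathLike) -> ConnectivityGroundTruth:
    """Read a ground-truth manifest written by :func:`save_ground_truth`."""
    from .io import read_scalar_map, read_tractogram

    with open(manifest_path) as fh:
        manifest = json.load(fh)
    affine = np.asarray(manifest["affine"], dtype=float)
    bundles = []
    for entry in manifest["bundles"]:
        mask, _ = read_scalar_map(entry["mask"])
        roi_a, _ = read_scalar_map(entry["roi_a"])
        roi_b, _ = read_scalar_map(entry["roi_b"])
        centerline = read_tractogram(entry["centerline"])[0]
        bundles.append(
            Bundle(mask > 0.5, roi_a > 0.5, roi_b > 0.5, centerline)
        )
    return ConnectivityGroundTruth(bundles, affine)
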