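"""Diffusion-tensor estimation and scalar measures.

The single-tensor model describes the diffusion-attenuated signal along a
unit gradient ``g`` at weighting ``b`` as ``S = S0 * exp(-b * g' D g)`` with
``D`` a symmetric positive 3x3 tensor.  Taking logs linearizes the model, so
with one b=0 measurement and >=6 non-collinear weighted directions the six
unique components of ``D`` follow from an ordinary least-squares solve.

Derived per-voxel quantities:

* eigensystem ``lambda1 >= lambda2 >= lambda3`` with eigenvectors ``V1..V3``
  (axial: defined up to sign);
* fractional anisotropy
  ``FA = sqrt(3/2) * sqrt(sum (li - lbar)^2) / sqrt(sum li^2)``;
* Westin shape measures ``Cl = (l1 - l2)/l1``, ``Cp = (l2 - l3)/l1``,
  ``Cs = l3/l1``, which partition unity and classify the tensor as
  line-like, disk-like, or sphere-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DWIVolume, GradientTable

__all__ = [
    "TensorField",
    "TensorEigenSystem",
    "ScalarMaps",
    "compute_adc",
    "compute_fa",
    "compute_westin",
    "design_matrix",
    "eigendecompose",
    "fit_tensor",
    "tensor_from_components",
    "tensor_to_components",
]

#: component order of the 6-vector representation used throughout
COMPONENT_ORDER = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

#: signal floor relative to S0, applied before the log transform
SIGNAL_FLOOR = 1e-6

_IJ = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def tensor_from_components(comp: np.ndarray) -> np.ndarray:
    """(..., 6) component array -> (..., 3, 3) symmetric matrices."""
    comp = np.asarray(comp, dtype=float)
    out = np.empty(comp.shape[:-1] + (3, 3), dtype=float)
    for k, (i, j) in enumerate(_IJ):
        out[..., i, j] = comp[..., k]
        out[..., j, i] = comp[..., k]
    return out


def tensor_to_components(mat: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) component array."""
    mat = np.asarray(mat, dtype=float)
    return np.stack([mat[..., i, j] for i, j in _IJ], axis=-1)


@dataclass
class TensorField:
    """Per-voxel diffusion tensors on an image grid.

    ``components`` has shape (X, Y, Z, 6) in :data:`COMPONENT_ORDER`, units
    mm^2/s.  Voxels outside the fitting mask hold zero tensors.
    """

    components: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.components.ndim != 4 or self.components.shape[-1] != 6:
            raise ValueError(
                f"tensor components must be (X, Y, Z, 6), got {self.components.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    def as_matrices(self) -> np.ndarray:
        return tensor_from_components(self.components)


@dataclass
class TensorEigenSystem:
    """Sorted eigensystem of a tensor field.

    ``eigenvalues``: (X, Y, Z, 3) descending, clamped >= 0.
    ``eigenvectors``: (X, Y, Z, 3, 3); ``eigenvectors[..., i, :]`` is the unit
    eigenvector of ``eigenvalues[..., i]`` (sign arbitrary).
    ``n_clamped``: number of negative eigenvalues clamped to zero.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_clamped: int = 0

    @property
    def principal(self) -> np.ndarray:
        """Principal eigenvector map, shape (X, Y, Z, 3)."""
        return self.eigenvectors[..., 0, :]


@dataclass
class ScalarMaps:
    """FA and Westin shape maps derived from a tensor eigensystem."""

    fa: np.ndarray
    cl: np.ndarray
    cp: np.ndarray
    cs: np.ndarray


def compute_adc(
    signal: np.ndarray, s0: float | np.ndarray, b: float | np.ndarray
) -> np.ndarray:
    """Apparent diffusion coefficient per direction: ``-(1/b) ln(S/S0)``.

    ``signal`` is floored at ``SIGNAL_FLOOR * s0`` before the log so fully
    attenuated measurements stay finite.
    """
    signal = np.asarray(signal, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("s0 must be positive for ADC computation")
    if np.any(b <= 0):
        raise ValueError("b must be positive for ADC computation")
    clipped = np.maximum(signal, SIGNAL_FLOOR * s0)
    return -np.log(clipped / s0) / b


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """OLS design for the log-linear tensor fit, rows over b>0 volumes.

    Row i is ``b_i * [gx^2, 2 gx gy, 2 gx gz, gy^2, 2 gy gz, gz^2]`` so that
    ``A @ d = -ln(S/S0)`` for the 6-component tensor ``d``.
    """
    g = gtab.bvecs[gtab.dwi_mask]
    b = gtab.bvals[gtab.dwi_mask]
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    a = np.stack(
        [gx * gx, 2 * gx * gy, 2 * gx * gz, gy * gy, 2 * gy * gz, gz * gz], axis=1
    )
    return b[:, None] * a


def fit_tensor(
    dwi: DWIVolume, gtab: GradientTable, mask: np.ndarray | None = None
) -> TensorField:
    """Least-squares diffusion-tensor fit on log-signals.

    S0 is the mean of the b=0 volumes.  Voxels outside ``mask`` or with
    non-positive S0 get zero tensors.  With exactly six independent
    directions and noiseless data the solve is exact.
    """
    if len(gtab) != dwi.n_volumes:
        from .io import DWIFormatError

        raise DWIFormatError(
            f"gradient table has {len(gtab)} entries but image has "
            f"{dwi.n_volumes} volumes"
        )
    shape = dwi.data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match image grid")
    if not mask.any():
        raise ValueError("mask is empty")

    a = design_matrix(gtab)
    pinv = np.linalg.pinv(a)

    s0 = dwi.data[..., gtab.b0_mask].mean(axis=-1)
    usable = mask & (s0 > 0)
    sig = dwi.data[..., gtab.dwi_mask][usable]  # (nvox, ndir)
    s0v = s0[usable][:, None]
    sig = np.maximum(sig, SIGNAL_FLOOR * s0v)
    y = -np.log(sig / s0v)  # = A @ d
    comp = np.zeros(shape + (6,), dtype=float)
    comp[usable] = y @ pinv.T
    return TensorField(comp, dwi.affine)


def eigendecompose(tensors: TensorField | np.ndarray) -> TensorEigenSystem:
    """Eigendecompose symmetric tensors; sort descending; clamp negatives to 0."""
    if isinstance(tensors, TensorField):
        mats = tensors.as_matrices()
    else:
        mats = np.asarray(tensors, dtype=float)
        if mats.shape[-1] == 6:
            mats = tensor_from_components(mats)
    evals, evecs = np.linalg.eigh(mats)  # ascending, column eigenvectors
    evals = evals[..., ::-1]
    evecs = np.swapaxes(evecs[..., ::-1], -1, -2)  # rows are eigenvectors
    n_clamped = int((evals < 0).sum())
    evals = np.maximum(evals, 0.0)
    return TensorEigenSystem(np.ascontiguousarray(evals), np.ascontiguousarray(evecs), n_clamped)


def compute_fa(eigs: TensorEigenSystem | np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (clamped) eigenvalues; 0 where the tensor is 0."""
    evals = eigs.eigenvalues if isinstance(eigs, TensorEigenSystem) else np.asarray(eigs)
    mean = evals.mean(axis=-1, keepdims=True)
    num = ((evals - mean) ** 2).sum(axis=-1)
    den = (evals**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


def compute_westin(
    eigs: TensorEigenSystem | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Westin shape measures (Cl, Cp, Cs); all zero where lambda1 = 0."""
    evals = eigs.eigenvalues if isinstance(eigs, TensorEigenSystem) else np.asarray(eigs)
    l1 = evals[..., 0]
    l2 = evals[..., 1]
    l3 = evals[..., 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        cl = (l1 - l2) / l1
        cp = (l2 - l3) / l1
        cs = l3 / l1
    bad = ~(l1 > 0)
    for m in (cl, cp, cs):
        m[bad] = 0.0
    return cl, cp, cs


def scalar_maps(eigs: TensorEigenSystem) -> ScalarMaps:
    """Bundle FA and Westin maps for one eigensystem."""
    cl, cp, cs = compute_westin(eigs)
    return ScalarMaps(compute_fa(eigs), cl, cp, cs)
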