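"""Tissue conductivity assignment, including white-matter anisotropy.

Each element carries a symmetric positive-definite 3x3 conductivity tensor
in S/m. Non-white-matter tissue is isotropic. White matter may be made
anisotropic from a per-element eigensystem (principal fiber direction plus
eigenvalues), using either of the two conventions common in volume-conductor
modelling:

* ``normalized`` — volume-constraint scaling of measured diffusion
  eigenvalues: the eigenvalues are divided by their geometric mean and
  multiplied by the isotropic white-matter value, so the tensor determinant
  equals ``sigma_iso**3``.
* ``fixed_ratio`` — a prescribed longitudinal:transverse ratio ``r`` along
  the fiber, with the same volume constraint:
  ``sigma_long = r**(2/3) * sigma_iso``, ``sigma_trans = r**(-1/3) * sigma_iso``.

The degree of anisotropy of a tensor is summarized by the fractional
anisotropy (FA) of its eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import CSF, GM, WM, LabeledTetMesh

#: Default isotropic conductivities, S/m. WM, skull, scalp/body are the
#: values used by the stimulation model family this package implements;
#: GM and CSF are standard literature values (see docs/methods.md).
DEFAULT_SIGMA = {"WM": 0.126, "GM": 0.276, "CSF": 1.65, "skull": 0.01, "body": 0.465}

_REGION_KEY = {CSF: "CSF", GM: "GM", WM: "WM"}


@dataclass(frozen=True)
class IsotropicTable:
    """Isotropic conductivity per tissue, S/m."""

    WM: float = DEFAULT_SIGMA["WM"]
    GM: float = DEFAULT_SIGMA["GM"]
    CSF: float = DEFAULT_SIGMA["CSF"]
    skull: float = DEFAULT_SIGMA["skull"]
    body: float = DEFAULT_SIGMA["body"]

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"conductivity {name} must be positive")

    def for_region(self, code: int) -> float:
        return getattr(self, _REGION_KEY[code])


@dataclass(frozen=True)
class AnisotropyModel:
    """White-matter anisotropy convention.

    method:
        ``isotropic`` | ``normalized`` (volume-constraint scaling of raw
        diffusion eigenvalues) | ``fixed_ratio`` (prescribed ratio ``r``).
    r:
        longitudinal:transverse ratio coefficient (2, 5 or 10 in typical
        use); ignored unless method is ``fixed_ratio``.
    sigma_iso:
        isotropic white-matter conductivity preserved by the volume
        constraint, S/m.
    """

    method: str = "isotropic"
    r: float = 1.0
    sigma_iso: float = DEFAULT_SIGMA["WM"]

    def __post_init__(self) -> None:
        if self.method not in ("isotropic", "normalized", "fixed_ratio"):
            raise ValueError(f"unknown anisotropy method {self.method!r}")
        if self.r < 1.0:
            raise ValueError("ratio coefficient r must be >= 1")
        if self.sigma_iso <= 0.0:
            raise ValueError("sigma_iso must be positive")


@dataclass
class ConductivityField:
    """Per-element symmetric 3x3 conductivity tensors, S/m."""

    tensors: np.ndarray  # (M, 3, 3)
    model: Optional[AnisotropyModel] = None

    @property
    def num_elements(self) -> int:
        return self.tensors.shape[0]

    def is_spd(self) -> np.ndarray:
        """Sylvester-criterion SPD check per element (vectorized)."""
        t = self.tensors
        m1 = t[:, 0, 0]
        m2 = t[:, 0, 0] * t[:, 1, 1] - t[:, 0, 1] * t[:, 1, 0]
        m3 = np.linalg.det(t)
        return (m1 > 0) & (m2 > 0) & (m3 > 0)


def tensor_from_eigensystem(S: np.ndarray, eigenvalues: np.ndarray) -> np.ndarray:
    """Conductivity tensor(s) ``S @ diag(eigenvalues) @ S.T``.

    ``S`` holds orthonormal eigenvectors as columns (longitudinal first);
    accepts a single (3, 3) system or a stack (M, 3, 3) with eigenvalues
    (3,) or (M, 3).
    """
    S = np.asarray(S, dtype=float)
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    single = S.ndim == 2
    Sb = S[None] if single else S
    lb = np.broadcast_to(eigenvalues, (Sb.shape[0], 3)) if eigenvalues.ndim <= 1 else eigenvalues
    gram = np.einsum("mki,mkj->mij", Sb, Sb)
    if not np.allclose(gram, np.eye(3), atol=1e-10):
        raise ValueError("eigenvector matrix is not orthonormal (S^T S != I within 1e-10)")
    if np.any(lb < 0):
        raise ValueError("conductivity eigenvalues must be non-negative")
    t = np.einsum("mik,mk,mjk->mij", Sb, lb, Sb)
    return t[0] if single else t


def normalize_volume_constraint(
    diffusion_eigenvalues: np.ndarray, sigma_iso: float
) -> np.ndarray:
    """Volume-constraint normalization of diffusion-tensor eigenvalues.

    ``sigma_nor_i = sigma_iso * d_i / (d_1 d_2 d_3)**(1/3)``: the geometric
    mean of the output equals ``sigma_iso``, so the tensor determinant (the
    "volume" of the conductivity ellipsoid) matches the isotropic reference.
    """
    d = np.asarray(diffusion_eigenvalues, dtype=float)
    if np.any(d <= 0.0):
        raise ValueError("diffusion eigenvalues must be strictly positive")
    if sigma_iso <= 0.0:
        raise ValueError("sigma_iso must be positive")
    gm = np.prod(d, axis=-1, keepdims=True) ** (1.0 / 3.0)
    return sigma_iso * d / gm


def fixed_ratio_eigenvalues(sigma_iso: float, r: float) -> tuple[float, float]:
    """Longitudinal/transverse eigenvalues for a prescribed ratio ``r``.

    Jointly satisfies ``sigma_long / sigma_trans = r`` and the volume
    constraint ``sigma_long * sigma_trans**2 = sigma_iso**3``.
    """
    if r < 1.0:
        raise ValueError("ratio coefficient r must be >= 1")
    if sigma_iso <= 0.0:
        raise ValueError("sigma_iso must be positive")
    return r ** (2.0 / 3.0) * sigma_iso, r ** (-1.0 / 3.0) * sigma_iso


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of tensor eigenvalues, in [0, 1].

    ``FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l1-l3)^2)
    / sqrt(l1^2 + l2^2 + l3^2)``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0.0):
        raise ValueError("eigenvalues must be non-negative")
    sq = np.sum(lam**2, axis=-1)
    if np.any(sq == 0.0):
        raise ValueError("all-zero eigenvalue triple has undefined anisotropy")
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = np.sqrt(0.5) * np.sqrt((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2)
    return num / np.sqrt(sq)


def _orthonormal_frames(directions: np.ndarray) -> np.ndarray:
    """Orthonormal frames (columns) with the given unit vectors first.

    The two transverse eigenvalues are equal (axial symmetry), so any
    orthonormal completion is valid; a deterministic Gram-Schmidt against
    the least-aligned coordinate axis is used.
    """
    v1 = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    pick = np.argmin(np.abs(v1), axis=1)
    helper = np.eye(3)[pick]
    v2 = np.cross(v1, helper)
    v2 /= np.linalg.norm(v2, axis=1, keepdims=True)
    v3 = np.cross(v1, v2)
    return np.stack([v1, v2, v3], axis=2)  # columns


def build_conductivity_field(
    mesh: LabeledTetMesh,
    table: IsotropicTable | None = None,
    model: AnisotropyModel | None = None,
    fibers=None,
) -> ConductivityField:
    """Assign per-element tensors: isotropic everywhere, with optional
    white-matter anisotropy built from a fiber field.

    ``fibers`` is a :class:`~sucsim.synthetic.FiberField` (or any object
    with ``directions`` (W, 3) over the mesh's WM elements and optional
    ``diffusion_eigenvalues`` (W, 3)); required unless the model is
    isotropic.
    """
    table = table or IsotropicTable()
    model = model or AnisotropyModel()
    m = mesh.num_tets
    tensors = np.zeros((m, 3, 3))
    for code in (CSF, GM, WM):
        sel = mesh.region_labels == code
        tensors[sel] = table.for_region(code) * np.eye(3)

    if model.method != "isotropic":
        wm = np.flatnonzero(mesh.region_labels == WM)
        if fibers is None:
            raise ValueError("an anisotropic model requires a fiber field over white matter")
        directions = np.asarray(fibers.directions, dtype=float)
        if directions.shape[0] != wm.size:
            raise ValueError(
                f"fiber field covers {directions.shape[0]} elements but the mesh "
                f"has {wm.size} white-matter elements"
            )
        frames = _orthonormal_frames(directions)
        if model.method == "fixed_ratio":
            lo, tr = fixed_ratio_eigenvalues(model.sigma_iso, model.r)
            eig = np.array([lo, tr, tr])
        else:  # normalized
            d = getattr(fibers, "diffusion_eigenvalues", None)
            if d is None:
                raise ValueError(
                    "the normalized (volume-constraint) model requires raw "
                    "diffusion eigenvalues in the fiber field"
                )
            eig = normalize_volume_constraint(np.asarray(d, dtype=float), model.sigma_iso)
        tensors[wm] = tensor_from_eigensystem(frames, eig)

    return ConductivityField(tensors, model)


def fa_map(field: ConductivityField) -> np.ndarray:
    """Per-element fractional anisotropy of the conductivity tensors."""
    lam = np.linalg.eigvalsh(field.tensors)
    return fractional_anisotropy(lam[..., ::-1])


def fiber_field_from_tensor_volume(mesh: LabeledTetMesh, path: str):
    """Build a white-matter fiber field from a voxel tensor volume (NIfTI).

    The volume must be 4-D with 6 unique tensor components per voxel in the
    common diffusion-tensor order (xx, xy, xz, yy, yz, zz). Values are
    sampled at white-matter element centroids with nearest-voxel lookup
    through the NIfTI affine.
    """
    import nibabel as nib

    from .synthetic import FiberField

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 6:
        raise ValueError("expected a 4-D tensor volume with 6 components per voxel")
    wm = np.flatnonzero(mesh.region_labels == WM)
    cent = mesh.centroids()[wm]
    inv = np.linalg.inv(img.affine)
    vox = (inv[:3, :3] @ cent.T + inv[:3, 3:4]).T
    idx = np.rint(vox).astype(int)
    for a in range(3):
        idx[:, a] = np.clip(idx[:, a], 0, data.shape[a] - 1)
    comp = data[idx[:, 0], idx[:, 1], idx[:, 2], :]  # (W, 6)
    xx, xy, xz, yy, yz, zz = (comp[:, i] for i in range(6))
    tens = np.empty((wm.size, 3, 3))
    tens[:, 0, 0], tens[:, 1, 1], tens[:, 2, 2] = xx, yy, zz
    tens[:, 0, 1] = tens[:, 1, 0] = xy
    tens[:, 0, 2] = tens[:, 2, 0] = xz
    tens[:, 1, 2] = tens[:, 2, 1] = yz
    lam, vec = np.linalg.eigh(tens)
    lam = lam[:, ::-1]
    vec = vec[:, :, ::-1]
    if np.any(lam <= 0):
        raise ValueError("tensor volume contains non-positive-definite voxels over white matter")
    return FiberField(directions=vec[:, :, 0], diffusion_eigenvalues=lam, generator="nifti", seed=None)
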