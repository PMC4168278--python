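"""Synthetic inputs: white-matter fiber fields and analytic benchmarks.

The fiber generator stands in for what a diffusion-MRI pipeline would
provide: a per-element principal fiber direction (and optionally raw
diffusion eigenvalues) over white matter. The benchmark factory builds
small problems with closed-form impedances used to validate the solver:

* ``bar`` — homogeneous box driven across two opposite faces; series
  resistance ``R = L / (sigma A)``. P1 elements reproduce the linear
  potential exactly, so the solver must match to round-off.
* ``halfspace_disc`` — a disc contact at the centre of the top surface of
  a large grounded block; spreading resistance of a disc of radius ``a``
  on a half-space, ``R = 1 / (4 sigma a)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import fem
from .conductivity import ConductivityField
from .geometry import (
    WM,
    LabeledTetMesh,
    build_box_mesh,
    designate_reference,
    place_disc_electrode,
)

DEFAULT_SEED = 20140917

#: Synthetic raw diffusion eigenvalue shape (mm^2/s-like magnitudes). Only
#: the ratios matter after volume-constraint normalization; these are NOT
#: measured values.
SYNTHETIC_DIFFUSION_EIGENVALUES = (1.2e-3, 0.4e-3, 0.4e-3)


@dataclass
class FiberField:
    """Per-white-matter-element fiber eigensystem.

    directions:
        (W, 3) unit principal directions, ordered like the mesh's WM
        elements (``np.flatnonzero(region_labels == WM)``).
    diffusion_eigenvalues:
        optional (W, 3) raw eigenvalues (descending) for the
        volume-constraint (normalized) conductivity model.
    """

    directions: np.ndarray
    diffusion_eigenvalues: Optional[np.ndarray] = None
    generator: str = "unknown"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("fiber directions must be unit vectors (within 1e-10)")
        if self.diffusion_eigenvalues is not None:
            d = np.asarray(self.diffusion_eigenvalues, dtype=float)
            if d.shape != (self.directions.shape[0], 3):
                raise ValueError("diffusion eigenvalues must be (W, 3)")
            if np.any(d <= 0):
                raise ValueError("diffusion eigenvalues must be positive")


def generate_fiber_field(
    mesh: LabeledTetMesh,
    pattern: str = "u_fiber",
    seed: int = DEFAULT_SEED,
    direction=(1.0, 0.0, 0.0),
    spec=None,
) -> FiberField:
    """Deterministic synthetic fiber field over the mesh's WM elements.

    Patterns:

    * ``uniform`` — constant ``direction`` everywhere.
    * ``u_fiber`` — idealized corona-radiata fan in the x-z plane: the
      direction tilts by ``45 deg * sin(2 pi (x - x_crown) / period)``
      about the extrusion axis, i.e. vertical under the gyral crown and
      the sulcal floor, up to +/-45 degrees on the walls. ``spec`` (the
      SlabSpec the mesh was built from) supplies the fold period and crown
      position; without it a 15 mm period centred at the domain midline is
      assumed.
    * ``random_smooth`` — unit field from a few low-order random Fourier
      modes of the element centroid, spatially correlated and reproducible
      from the seed.

    Raw diffusion eigenvalues with the synthetic prolate shape
    ``SYNTHETIC_DIFFUSION_EIGENVALUES`` are attached for use by the
    normalized conductivity model.
    """
    wm = np.flatnonzero(mesh.region_labels == WM)
    if wm.size == 0:
        raise ValueError("mesh has no white-matter elements")
    cent = mesh.centroids()[wm]

    if pattern == "uniform":
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        dirs = np.tile(d, (wm.size, 1))
    elif pattern == "u_fiber":
        if spec is not None:
            period = spec.fold_period
            x0 = 0.5 * spec.extent_x
        else:
            period = 15.0
            x0 = 0.5 * (mesh.nodes[:, 0].min() + mesh.nodes[:, 0].max())
        theta = (np.pi / 4.0) * np.sin(2.0 * np.pi * (cent[:, 0] - x0) / period)
        dirs = np.stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)], axis=1)
    elif pattern == "random_smooth":
        rng = np.random.default_rng(seed)
        span = mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)
        span[span == 0] = 1.0
        u = 2.0 * np.pi * cent / span  # order-one spatial frequencies
        raw = np.zeros((wm.size, 3))
        for _ in range(4):
            k = rng.integers(1, 3, size=3)
            phase = rng.uniform(0, 2 * np.pi, size=3)
            amp = rng.normal(size=(3, 3))
            modes = np.cos(u * k + phase)  # (W, 3)
            raw += modes @ amp.T
        raw += rng.normal(size=3)  # constant bias keeps the field away from zero
        n = np.linalg.norm(raw, axis=1, keepdims=True)
        if np.any(n < 1e-12):
            raw[n[:, 0] < 1e-12] = (0.0, 0.0, 1.0)
            n = np.linalg.norm(raw, axis=1, keepdims=True)
        dirs = raw / n
    else:
        raise ValueError(f"unknown fiber pattern {pattern!r}")

    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    eig = np.tile(np.asarray(SYNTHETIC_DIFFUSION_EIGENVALUES), (wm.size, 1))
    return FiberField(dirs, eig, generator=pattern, seed=seed)


@dataclass(frozen=True)
class BenchmarkCase:
    """Closed-form solver validation case.

    bar: ``length`` (mm) along z, square cross-section ``width`` x ``width``
    (mm). halfspace_disc: disc of radius ``disc_radius`` (mm) on a block of
    half-width/depth ``block_size`` (mm); the block must be at least 10x the
    disc radius in every direction or the far-field assumption is broken.
    """

    name: str = "bar"
    sigma: float = 0.465
    length: float = 10.0
    width: float = 10.0
    disc_radius: float = 2.0
    block_size: float = 80.0

    def __post_init__(self) -> None:
        if self.name not in ("bar", "halfspace_disc"):
            raise ValueError(f"unknown benchmark {self.name!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.name == "halfspace_disc" and self.block_size < 10.0 * self.disc_radius:
            raise ValueError(
                "block must extend at least 10 disc radii in every direction "
                "(far-field assumption)"
            )

    @property
    def expected_impedance(self) -> float:
        """Closed-form impedance in ohms (lengths converted mm -> m)."""
        if self.name == "bar":
            return (self.length * 1e-3) / (self.sigma * self.width**2 * 1e-6)
        return 1.0 / (4.0 * self.sigma * self.disc_radius * 1e-3)


def _graded_axis(fine_extent: float, total_extent: float, h0: float, ratio: float = 1.3):
    """Grid coordinates 0..total: uniform ``h0`` out to ``fine_extent``,
    then geometrically stretched; last step snapped to land on total."""
    pts = list(np.arange(0.0, fine_extent + 0.5 * h0, h0))
    h = h0
    while pts[-1] < total_extent:
        h *= ratio
        pts.append(pts[-1] + h)
    pts[-1] = total_extent
    if pts[-1] - pts[-2] < 0.25 * h0:
        del pts[-2]
    return np.asarray(pts)


def make_benchmark(case: BenchmarkCase, resolution: float = 1.0):
    """Build (mesh, conductivity field, boundary conditions, expected R).

    The drive amplitude is 1 V; the measured impedance is
    ``1 / electrode_current`` at that drive.
    """
    if case.name == "bar":
        n_xy = max(2, round(case.width / resolution))
        n_z = max(2, round(case.length / resolution))
        xs = np.linspace(0.0, case.width, n_xy + 1)
        zs = np.linspace(0.0, case.length, n_z + 1)
        mesh = build_box_mesh(xs, xs, zs, label=WM)
        tensors = case.sigma * np.tile(np.eye(3), (mesh.num_tets, 1, 1))
        cfield = ConductivityField(tensors)
        top = np.unique(mesh.boundary_facets["top"])
        ref = designate_reference(mesh, ("bottom",))
        bc = fem.BoundaryConditions(drives=[(top, 1.0)], reference=ref)
        return mesh, cfield, bc, case.expected_impedance

    # halfspace_disc: fine uniform core under the disc, graded to the far field
    a, L = case.disc_radius, case.block_size
    h0 = min(resolution, a / 5.0)
    half = _graded_axis(2.0 * a, L, h0)
    xy = np.concatenate([-half[::-1], half[1:]])
    zs = -_graded_axis(2.0 * a, L, h0)[::-1]
    mesh = build_box_mesh(xy, xy, zs, label=WM)
    tensors = case.sigma * np.tile(np.eye(3), (mesh.num_tets, 1, 1))
    cfield = ConductivityField(tensors)
    patch = place_disc_electrode(mesh, (0.0, 0.0), 2.0 * a, tag="disc")
    ref = designate_reference(mesh, ("side", "bottom"))
    bc = fem.BoundaryConditions(drives=[(patch, 1.0)], reference=ref)
    return mesh, cfield, bc, case.expected_impedance
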