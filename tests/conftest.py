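"""Shared fixtures: a desk-scale slab small enough for fast solves.

Session-scoped fixtures cache the mesh and the 1 V solution so that the
metric and pipeline tests share one linear solve.
"""

import numpy as np
import pytest

from sucsim import (
    BoundaryConditions,
    ExperimentConfig,
    SlabSpec,
    assemble_system,
    build_conductivity_field,
    build_slab_mesh,
    designate_reference,
    place_disc_electrode,
    solve_potential,
)


@pytest.fixture(scope="session")
def small_spec() -> SlabSpec:
    # one gyral fold, segment lengths divisible by h for exact refinement checks
    return SlabSpec(
        extent_x=24.0,
        extent_y=16.0,
        extent_z=20.0,
        gyral_width=8.0,
        sulcal_width=3.0,
        sulcal_depth=8.0,
        gm_thickness=2.0,
        csf_thickness=2.0,
        resolution_h=1.0,
    )


@pytest.fixture(scope="session")
def small_mesh(small_spec):
    return build_slab_mesh(small_spec)


@pytest.fixture(scope="session")
def small_config(small_spec) -> ExperimentConfig:
    return ExperimentConfig(slab=small_spec, electrode_mode="single", contact_spacing=6.0)


@pytest.fixture(scope="session")
def small_solution(small_spec, small_mesh):
    """Single middle contact at 1 V on the small slab, isotropic tissue."""
    patch = place_disc_electrode(
        small_mesh, (0.5 * small_spec.extent_x, 0.5 * small_spec.extent_y), 4.0
    )
    field = build_conductivity_field(small_mesh)
    system = assemble_system(small_mesh, field)
    ref = designate_reference(small_mesh)
    bc = BoundaryConditions(drives=[(patch, 1.0)], reference=ref)
    sol = solve_potential(system, bc)
    return sol, patch


def regular_tet():
    nodes = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    tets = np.array([[0, 1, 2, 3]])
    return nodes, tets
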