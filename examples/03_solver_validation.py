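"""Validate the solver against closed-form impedances.

Two oracles: a homogeneous bar (series resistance L / (sigma A); linear
fields are exact for first-order elements, so the match is to round-off)
and a 4 mm disc on a large half-space block (spreading resistance
1 / (4 sigma a); accurate to a few percent at the default resolution).
"""

from sucsim import (
    BenchmarkCase,
    assemble_system,
    electrode_current,
    make_benchmark,
    solve_potential,
)

for case, res in [
    (BenchmarkCase("bar", sigma=0.465, length=10.0, width=10.0), 1.0),
    (BenchmarkCase("halfspace_disc", sigma=0.126, disc_radius=2.0), 0.4),
]:
    mesh, cfield, bc, expected = make_benchmark(case, resolution=res)
    sol = solve_potential(assemble_system(mesh, cfield), bc)
    current = electrode_current(sol, bc.drives[0][0])
    measured = 1.0 / current
    err = 100.0 * (measured / expected - 1.0)
    print(
        f"{case.name:15s} {mesh.num_tets:8d} tets: impedance {measured:8.2f} ohm, "
        f"closed form {expected:8.2f} ohm ({err:+.2f} %)"
    )
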