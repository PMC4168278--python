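"""Solve a stimulation experiment and sweep the amplitude grid.

One linear solve at 1 V yields the model impedance and, by linearity, the
full voltage sweep: the effective volume is the gray/white-matter volume
where |J| exceeds the 2.5 A/m^2 motor threshold, and the effective depth is
how far that region reaches below the contact centre.
"""

from sucsim import ExperimentConfig, SlabSpec, run_experiment

config = ExperimentConfig(
    slab=SlabSpec(resolution_h=1.2),  # coarse desk-scale mesh for a quick demo
    electrode_mode="single",
    stimulation_mode="voltage",
)
result = run_experiment(config)

print(f"single 4 mm contact on the slab: impedance {result.impedance:.1f} ohm, "
      f"output current {result.output_current_ma:.2f} mA at 1 V")
cols = ["amplitude", "effective_volume_cm3", "effective_depth_cm", "output_current_mA"]
print(result.table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("rows: stimulation voltage (V); columns: activated tissue volume (cm^3),")
print("penetration depth below the contact (cm), and delivered current (mA).")
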