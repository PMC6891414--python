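"""Simulate one six-sensor cyclic-voltammetry sample and inspect its shape.

A sample is a ternary benzodiazepine mixture; each of the six electrodes
records a 752-point current trace over the -1.5 -> +1.5 -> -1.5 V sweep, so
the raw fingerprint carries 6 x 752 = 4512 currents.
"""

import numpy as np

from voltet import NoiseModel, default_sensor_bank, make_grid, simulate_sample

grid = make_grid()  # -1.5 .. +1.5 V, 752 points/cycle
bank = default_sensor_bank()
rec = simulate_sample(
    [10.0, 5.0, 20.0],  # ppm of diazepam, flunitrazepam, lorazepam
    bank,
    grid,
    NoiseModel(sigma_rel=0.005, seed=1),
    sample_id="demo",
)

print(f"sweep: {grid.e_min:+.1f} -> {grid.e_max:+.1f} V, "
      f"{grid.n_points} points, step {grid.step * 1e3:.1f} mV")
print(f"sensors: {[v.sensor_id for v in rec.voltammograms]}")
print(f"raw fingerprint: {len(rec.raw_vector)} currents")
for vg in rec.voltammograms[:2]:
    i_peak = np.argmin(np.abs(grid.potentials - -1.1))
    print(f"  {vg.sensor_id:8s} current at -1.1 V (forward): "
          f"{vg.currents[i_peak]:7.2f} uA, trace range "
          f"[{vg.currents.min():.2f}, {vg.currents.max():.2f}] uA")
# The 4512-value fingerprint is what the wavelet stage compresses 31-fold.
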