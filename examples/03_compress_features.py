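"""Compress a raw 4512-value fingerprint to 144 wavelet coefficients.

Each sensor's 752-point trace is reduced to its depth-5 Daubechies-3
approximation (24 coefficients) under periodized boundaries; concatenating
the six sensors gives the 144-long feature vector fed to the neural model.
"""

from voltet import (
    NoiseModel,
    compress_sample,
    compression_percent,
    default_sensor_bank,
    make_grid,
    simulate_sample,
)

rec = simulate_sample(
    [10.0, 5.0, 20.0], default_sensor_bank(), make_grid(),
    NoiseModel(sigma_rel=0.005, seed=1), sample_id="demo",
)
fv = compress_sample(rec)
print(f"raw values per sample : {len(rec.raw_vector)}")
print(f"wavelet coefficients  : {len(fv.coefficients)} "
      f"({len(fv.coefficients) // 6} per sensor)")
print(f"compression           : "
      f"{compression_percent(len(rec.raw_vector), len(fv.coefficients)):.2f}%")
print(f"first sensor block    : {fv.coefficients[:4].round(2)} ...")
# The approximation branch keeps the low-frequency envelope (peaks +
# baseline) and discards fine-grained detail, mostly measurement noise.
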