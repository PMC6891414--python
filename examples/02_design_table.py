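"""Build the calibration design: tilted 3^3 factorial + random external test.

27 training standards come from a 3-level/3-factor full factorial over
0-30 ppm, rotated 45 degrees about each axis and refit into the domain cube;
9 independent test mixtures are drawn uniformly at random in the same domain.
"""

from voltet import DesignSpec, build_design

table = build_design(DesignSpec(seed=1))
print(table.frame.head(4).to_string(index=False))
print("...")
print(table.frame.tail(2).to_string(index=False))
print(f"\n{table.n_train} train + {table.n_test} test rows "
      f"({table.n_train / len(table.frame):.0%} training fraction)")
conc = table.concentrations()
print(f"all concentrations inside [{conc.min():.2f}, {conc.max():.2f}] ppm")
# The tilt spreads the factorial levels so no analyte repeats the same three
# values 9 times, which improves coverage of composition space.
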