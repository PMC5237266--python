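"""Convert between per-generation and time-domain substitution rates, and
estimate a genome-wide rate from singleton BSPs and base composition.
"""

import numpy as np

import trekkit as tk

# the crude human average: 12.85e-9 substitutions/site/generation, 20-yr span
crude = tk.convert_rate(12.85e-9, 20)
print(f"crude average rate: {crude:.4f} byr^-1")
print(f"expected substituted fraction over 20.4 myr: "
      f"{100 * tk.expected_fraction(crude, 0.0204):.2f}%")
print(f"repeated-hit underestimation at that horizon: "
      f"{tk.repeated_substitution_bias(crude, 0.0204):.2f}%")

# a genome-wide estimate: composition-weighted mean of the singleton BSPs
m = np.array([[0.0, 0.15, 0.55, 0.20],
              [0.50, 0.0, 0.15, 0.65],
              [0.65, 0.15, 0.0, 0.50],
              [0.20, 0.55, 0.15, 0.0]])
db = tk.TruthModel.singleton(m).to_database()
composition = (0.295, 0.205, 0.205, 0.295)  # A/C/G/T fractions
est = tk.genome_rate_estimate(composition, db, generation_years=20)
print(f"genome-wide estimate: {est.rate_byr:.3f} byr^-1 "
      f"= {est.rate_per_generation:.3e} per site per generation")
print("the per-generation value is rate_byr * generation_years / 1e9 exactly")
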