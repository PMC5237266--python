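"""Score 7-mer enrichment at mutation-linked sites against the background
genome, and fit the enrichment-ratio-versus-BSP slope below 1.3 byr^-1.

Sites are sampled in proportion to basal substitution propensity, so
low-BSP 7-mers should be depleted (ratio < 1) and the slope positive.
"""

import numpy as np

import trekkit as tk

db = tk.TruthModel.random(9, lo=0.05, hi=0.8, k=3).to_database()
# three-letter background: heptamers recur often and context BSPs below the
# 1.3 byr^-1 window are well represented
genome = "".join(np.random.default_rng(10).choice(list("ACT"), size=40_000))

table = tk.make_mutation_sites(genome, db, n=8000, weighting="bsp", seed=11,
                               snp_fraction=0.05, duplicate_fraction=0.037)
kept, report = tk.filter_mutation_sites(table)
print(f"sites: {report.n_input} in, {report.n_snp} SNP-flagged dropped, "
      f"{report.n_duplicate} duplicates dropped, {report.n_kept} kept")

records = tk.enrichment(kept, genome, db)
ratios = np.array([r.ratio for r in records])
print(f"7-mers observed at sites: {len(records)}; "
      f"mean enrichment ratio {ratios.mean():.3f}")

slope = tk.enrichment_slope(records, bsp_max=1.3)
print(f"ratio-vs-BSP slope below 1.3 byr^-1: {slope:.3f}")
print("a positive slope means 7-mers whose central base is intrinsically")
print("stable (low BSP) are under-represented among the mutation sites")
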