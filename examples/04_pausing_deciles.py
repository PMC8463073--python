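"""Pol II pausing index and its relation to promoter occupancy.

Simulates Pol II with a promoter-proximal peak plus a gene-body plateau
whose level rises with occupancy, computes per-gene pausing indices
(proximal mean over the mean 2000-4000 bp into the gene), and summarizes
them across TBP-occupancy deciles.
"""

import picarch as pc

archs = [
    pc.FactorArchitecture("TBP"),
    pc.FactorArchitecture("PolII", offset_bp=50.0, coupling=("TBP", 0.3)),
]
ds = pc.simulate_dataset(
    n_promoters=1000, architectures=archs, gene_length=6000,
    pause_spec=pc.PauseSpec("PolII", body_level_ratio=0.1,
                            occupancy_exponent=0.5),
    seed=4,
)

pauses = pc.pausing_table(ds.track("PolII"), ds.genes)
tab = pc.occupancy_table({"TBP": ds.track("TBP")}, ds.promoters)
dec = pc.decile_summary(tab, "TBP", pauses["pausing_index"])

print(pauses["status"].value_counts().to_string())
print("\npausing index by TBP-occupancy decile (1 = lowest TBP):")
for row in dec.itertuples(index=False):
    print(f"  decile {row.decile:2d}: median index {row.response_median:6.2f}"
          f"  (n={row.n})")
print("\nThe decreasing trend mirrors the planted coupling: promoters")
print("with more TBP initiate more and retain relatively less paused")
print("Pol II, so their pausing index is lower.")
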