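"""Summit-distance statistics with a replicate-based null.

Simulates two replicates of one factor (summit jitter SD 47 bp) and a
second factor offset 90 bp, calls one summit per promoter, and compares
the factor-pair distance distribution with the replicate null.
"""

import picarch as pc

archs = [
    pc.FactorArchitecture("Cdk7", jitter_sd_bp=47.0, n_replicates=2),
    pc.FactorArchitecture("PolII", offset_bp=90.0, jitter_sd_bp=47.0),
]
ds = pc.simulate_dataset(n_promoters=10_000, architectures=archs,
                         flank=600, gene_length=400, seed=2)

cdk7_r1 = pc.call_summits(ds.track("Cdk7", 0), ds.promoters)
cdk7_r2 = pc.call_summits(ds.track("Cdk7", 1), ds.promoters)
polii = pc.call_summits(ds.track("PolII", 0), ds.promoters)

null = pc.replicate_null(cdk7_r1, cdk7_r2)
pair = pc.summit_distances(cdk7_r1, polii)

print(f"replicate null median distance: {null.median:.0f} bp "
      f"(IQR {null.q25:.0f}-{null.q75:.0f}, n={null.n_pairs})")
print(f"Cdk7 - Pol II median distance:  {pair.median:.0f} bp "
      f"(IQR {pair.q25:.0f}-{pair.q75:.0f}, n={pair.n_pairs})")
print("The null (~45 bp) is pure summit-calling noise; a pair median")
print("well above it (~90 bp here) reflects a real positional offset —")
print("Pol II paused downstream of the TFIIH-marked PIC.")
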