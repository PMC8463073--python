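# picarch

Promoter-architecture analysis of ChIP-seq coverage tracks: where the
preinitiation complex (PIC), Mediator, TFIID, activators, and paused
RNA polymerase II sit relative to transcription start sites, and how
their occupancies co-vary across promoters.

## Who this is for

Groups comparing ChIP-seq occupancy of general transcription factors
(TBP, TFIIB, TFIIH), Mediator subunits, TAFs, sequence-specific
activators, and Pol II across many promoters or enhancers. The package
takes binned coverage tracks (bedGraph) plus gene/region annotations
(BED6/TSV) and produces the standard battery of promoter-architecture
statistics:

- **Metagene profiles** — strand-aware mean (or median) occupancy on an
  offset grid around TSSs or enhancer midpoints, and the signed offset
  between two factors' profile summits (e.g. paused Pol II ~+50 bp
  downstream of the GTFs at mammalian promoters, proximal activators
  ~−80 bp upstream, fly TAFs ~+60 bp downstream over the downstream
  promoter elements).
- **Summit pairing** — one summit per region per factor; the
  distribution of absolute inter-factor summit distances, interpreted
  against a replicate-vs-replicate null that quantifies pure
  experimental jitter (~45 bp median at 47 bp summit jitter).
- **Occupancy statistics** — per-region occupancy tables, activity
  ranking ("the 10,000 most active promoters by TBP"), log-scale Pearson
  correlations, median-centered occupancy-ratio classification of
  discordant gene groups (e.g. low Taf1:TBP promoters), decile
  summaries, Venn-style group overlap, and hypergeometric label
  enrichment with Benjamini–Hochberg adjustment.
- **Pausing index** — per gene, the mean Pol II signal in a
  promoter-proximal window divided by the mean 2000–4000 bp into the
  gene body (truncated at the TES for shorter genes).
- **Peak-shape classification** — at-TSS vs downstream vs bimodal calls
  per gene (the Taf7/Med26 downstream-peak phenomenon).
- **Synthetic data** — a generator that plants all of the above
  (summit offsets, jitter, log-scale occupancy coupling, discordant
  subsets, downstream peaks, gene-body plateaus, bidirectional enhancer
  PICs) with machine-readable ground truth, so every stage is testable
  without any external download.

## Core quantities

With $x_f(p)$ the CPM-normalized coverage of factor $f$ at position $p$:

- Metagene: $M_f(o) = \operatorname{mean}_{a \in A}\, x_f(a + s_a o)$
  over anchors $A$ with strand sign $s_a$; the inter-factor offset is
  $\arg\max M_g - \arg\max M_f$ after Gaussian smoothing (SD 25 bp).
- Summit distance: $d(r) = |s_f(r) - s_g(r)|$ per region $r$, summarized
  by median and quartiles; the replicate null is the same statistic for
  $f$ vs. its biological replicate.
- Ratio analysis: $\rho(r) = \frac{x_f(r)+c}{x_g(r)+c}$, normalized so
  the median over analyzed regions is exactly 1.0; regions with
  $|\log_2 \hat\rho| \ge 1$ form the high/low discordant groups.
- Pausing index: $\mathrm{PI} = \dfrac{\text{mean CPM in } [-50, +300)}
  {\text{mean CPM in } [+2000, +4000)}$ (body window truncated at the
  TES, status flagged).
- Occupancy coupling: with $\log_{10}$ occupancies coupled as
  $y = x + \varepsilon$, $\varepsilon \sim N(0, \sigma_n)$, the expected
  Pearson correlation is $1/\sqrt{1 + \sigma_n^2/\sigma_b^2}$ — the
  closed form used to validate the correlation stage.

## Worked example

```python
import picarch as pc

ds = pc.simulate_dataset(
    n_promoters=1000,
    architectures=pc.human_mode_architectures(),
    noise=pc.NoiseSpec(background_cpm=0.0),
    seed=1,
)
profiles = {f: pc.metagene(ds.track(f), ds.promoters)
            for f in ("TBP", "PolII", "SP1")}
print(pc.profile_offset(profiles["TBP"], profiles["PolII"]))   # 50.0
print(pc.profile_offset(profiles["SP1"], profiles["TBP"]))     # 80.0
```

The two numbers are summit offsets in base pairs on the transcription
orientation: Pol II peaks 50 bp downstream of the TBP/GTF profile (the
promoter-proximal pause), and the GTF profile peaks 80 bp downstream of
the SP1-class activator profile — the PIC marks the promoter, not the
activator-bound proximal elements. `examples/` contains five narrative
scripts covering metagene offsets, distance statistics, ratio
discordance, pausing deciles, and the one-shot pipeline; each prints
the numbers it computes and what they mean. The same pipeline is
scriptable from the shell:

```sh
picarch run --config run.yaml --outdir out/
```

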