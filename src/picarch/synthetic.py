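"""Synthetic multi-factor ChIP-seq coverage with planted ground truth.

The generator emulates the data regime of promoter-architecture ChIP-seq
studies: each transcription-associated factor occupies promoters (and
optionally enhancers) with a Gaussian-shaped coverage peak whose summit
sits at a characteristic signed offset from the TSS in transcription
orientation — general transcription factors at the TSS itself, paused
Pol II ~50 bp downstream in mammals (~60 bp in flies), proximal
sequence-specific activators ~60–80 bp upstream, and fly TAFs ~60 bp
downstream over the downstream promoter elements.

Occupancy levels are drawn log-normally; factors may be coupled on the
log10 scale (occupancy of A = occupancy of B plus log-scale noise), gene
subsets may carry a planted occupancy-ratio discordance, a named factor
may carry a second downstream peak component in a subset of genes
(bimodal shape), Pol II tracks may carry a gene-body plateau as substrate
for the pausing index, and enhancers receive bidirectional signal from
two divergent PICs. Every planted quantity is emitted as machine-readable
truth so each analysis stage can be tested without external data.

One RNG stream per (purpose, factor, replicate) is derived from the
master seed, so adding a factor or replicate never perturbs the draws of
the others, and a fixed seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .annotations import (
    GenomeLayout, RegionSet, ValidationError, write_gene_table, genes_to_bed6,
    GENE_TABLE_COLUMNS,
)
from .tracks import CoverageTrack, write_bedgraph

# Characteristic summit offsets (bp, transcription orientation) used by the
# preset architectures; positive is downstream of the TSS.
HUMAN_PAUSE_OFFSET = 50          # paused Pol II downstream of the PIC (human/mouse)
PROXIMAL_ACTIVATOR_OFFSET = -80  # SP1/NF-Y-class activators upstream of the PIC
FLY_PAUSE_OFFSET = 60            # paused Pol II in Drosophila
FLY_DOWNSTREAM_TAF_OFFSET = 60   # TAF1/TAF2 over the downstream promoter elements
FLY_ACTIVATOR_OFFSET = -60       # GAGA-class factors upstream of the fly PIC


@dataclass(frozen=True)
class FactorArchitecture:
    """Geometry and occupancy model of one factor's promoter binding.

    coupling=None draws occupancy independently from the dataset's
    occupancy model; coupling=(base_factor, log10_noise_sd) sets
    log10 occupancy = base factor's log10 occupancy + N(0, log10_noise_sd).
    """

    factor_name: str
    offset_bp: float = 0.0
    peak_sd_bp: float = 60.0
    jitter_sd_bp: float = 0.0
    coupling: tuple[str, float] | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.peak_sd_bp <= 0:
            raise ValidationError("peak_sd_bp must be > 0")
        if self.jitter_sd_bp < 0:
            raise ValidationError("jitter_sd_bp must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass(frozen=True)
class DiscordanceSpec:
    """Planted occupancy-ratio discordance in a random gene subset."""

    numerator: str
    denominator: str
    planted_fraction: float = 0.2
    log2_shift: float = -2.0
    planted_label: str = "discordant"

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValidationError("planted_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DownstreamPeakSpec:
    """Second peak component for one factor in a random gene subset.

    mode="bimodal" keeps the TSS peak and adds a minor downstream
    component at ``minor_to_major_height`` times the main height;
    mode="shifted" moves the whole peak to the downstream offset.
    """

    factor_name: str
    fraction: float = 0.25
    offset_bp: float = 150.0
    minor_to_major_height: float = 0.6
    mode: str = "bimodal"
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("bimodal", "shifted"):
            raise ValidationError("mode must be 'bimodal' or 'shifted'")

    @property
    def group_label(self) -> str:
        return self.label or f"{self.factor_name}_downstream"


@dataclass(frozen=True)
class PauseSpec:
    """Gene-body plateau for a Pol II-like factor (pausing-index substrate).

    The named factor's coverage gains a uniform plateau from TSS to TES at
    ``body_level_ratio`` times its promoter-proximal peak height.
    ``occupancy_exponent`` couples the plateau to occupancy: the per-gene
    ratio is scaled by (occupancy / median occupancy) ** exponent, so a
    positive exponent plants a decreasing pausing index with increasing
    occupancy.
    """

    factor_name: str
    proximal_offset_bp: float = HUMAN_PAUSE_OFFSET
    body_level_ratio: float = 0.1
    occupancy_exponent: float = 0.0


@dataclass(frozen=True)
class OccupancyModel:
    """Log-normal occupancy: log10(CPM peak height) ~ N(log10_mu, log10_sd)."""

    log10_mu: float = 1.5
    log10_sd: float = 1.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive uniform background (CPM) plus optional Poisson count noise
    applied to binned values before normalization."""

    background_cpm: float = 0.05
    poisson: bool = False
    counts_per_cpm: float = 1.0


@dataclass
class SyntheticTruth:
    """Planted ground truth: one summit row per region/factor/replicate,
    one occupancy row per region/factor, group labels per region, and the
    full parameter echo."""

    summits: pd.DataFrame
    occupancy: pd.DataFrame
    regions: pd.DataFrame
    seed: int
    params: dict

    def members(self, label: str) -> pd.Index:
        has = self.regions["labels"].str.split(";").apply(lambda ls: label in ls)
        return pd.Index(self.regions.loc[has, "region_id"])


@dataclass
class SimulatedDataset:
    layout: GenomeLayout
    genes: pd.DataFrame
    promoters: RegionSet
    enhancers: RegionSet
    tracks: dict[tuple[str, int], CoverageTrack]
    truth: SyntheticTruth
    bin_size: int

    def track(self, factor: str, replicate: int = 0) -> CoverageTrack:
        return self.tracks[(factor, replicate)]

    def write(self, outdir) -> list[str]:
        """Emit bedGraph per factor/replicate, gene table (TSV + BED6),
        region BEDs, truth TSVs, and a YAML parameter echo."""
        import os

        os.makedirs(outdir, exist_ok=True)
        written = []

        def _p(name):
            written.append(name)
            return os.path.join(outdir, name)

        write_gene_table(self.genes, _p("genes.tsv"))
        genes_to_bed6(self.genes, _p("genes.bed"))
        self.promoters.to_bed(_p("promoters.bed"))
        if len(self.enhancers):
            self.enhancers.to_bed(_p("enhancers.bed"))
        for (factor, rep), track in sorted(self.tracks.items()):
            write_bedgraph(track, _p(f"{factor}_rep{rep}.bedgraph"))
        truth_report(self.truth, outdir)
        written += ["truth_summits.tsv", "truth_occupancy.tsv",
                    "truth_regions.tsv", "params.yaml"]
        return written


def _stream(seed: int, *tags) -> np.random.Generator:
    """Independent, named RNG stream derived from the master seed."""
    keys = [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + keys))


def _paint_gaussian(arr, center, height, sd, bin_size, n_bins):
    lo = max(0, int((center - 4 * sd) // bin_size))
    hi = min(n_bins, int((center + 4 * sd) // bin_size) + 1)
    if hi <= lo:
        return
    pos = (np.arange(lo, hi) + 0.5) * bin_size
    arr[lo:hi] += height * np.exp(-0.5 * ((pos - center) / sd) ** 2)


def _paint_plateau(arr, lo_bp, hi_bp, level, bin_size, n_bins):
    lo = max(0, int(lo_bp // bin_size))
    hi = min(n_bins, int(-(-hi_bp // bin_size)))
    if hi > lo:
        arr[lo:hi] += level


def simulate_dataset(
    *,
    n_promoters: int,
    architectures: list[FactorArchitecture],
    n_enhancers: int = 0,
    discordance: list[DiscordanceSpec] = (),
    downstream_peak: DownstreamPeakSpec | None = None,
    pause_spec: PauseSpec | None = None,
    occupancy: OccupancyModel = OccupancyModel(),
    noise: NoiseSpec = NoiseSpec(),
    seed: int,
    layout: GenomeLayout | None = None,
    bin_size: int = 5,
    flank: int = 1000,
    gene_length: int = 2000,
    enhancer_spacing: int = 200,
    enhancer_asymmetry_log2_sd: float = 1.0,
    regions_per_chrom: int = 2500,
) -> SimulatedDataset:
    """Generate a fully specified synthetic dataset with ground truth.

    Regions are laid out on evenly spaced, non-overlapping slots (spacing
    at least gene_length + 2*flank) across as many chromosomes as needed.
    Anchors are placed off the bin grid (at bin centers) so that planted
    summits are recoverable exactly in the noise-free limit.
    """
    names = [a.factor_name for a in architectures]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate factor names")
    for i, a in enumerate(architectures):
        if a.coupling is not None:
            base, _sd = a.coupling
            if base not in names[:i]:
                raise ValidationError(
                    f"coupling base {base!r} of {a.factor_name!r} must be "
                    "generated first"
                )

    n_total = n_promoters + n_enhancers
    # each region owns a slot that contains its gene body and its flank on
    # both sides of the anchor, so no signal leaks into a neighbor's windows
    margin = int(max(flank, gene_length)) + 250
    slot = -(-2 * margin // bin_size) * bin_size
    if layout is None:
        n_chroms = -(-n_total // regions_per_chrom)
        counts = [min(regions_per_chrom, n_total - i * regions_per_chrom)
                  for i in range(n_chroms)]
        layout = GenomeLayout(
            tuple(f"chr{i + 1}" for i in range(n_chroms)),
            tuple((c + 1) * slot for c in counts),
        )

    # --- region placement -------------------------------------------------
    half = bin_size // 2
    anchors, chroms = [], []
    ci, used = 0, 0
    for _ in range(n_total):
        if (used + 2) * slot > layout.chrom_lengths[ci]:
            ci += 1
            used = 0
            if ci >= len(layout.chrom_names):
                raise ValidationError("layout too small for requested regions")
        base = margin + used * slot
        anchors.append((base // bin_size) * bin_size + half)
        chroms.append(layout.chrom_names[ci])
        used += 1
    anchors = np.array(anchors)

    rng_reg = _stream(seed, "regions")
    strands = np.where(rng_reg.random(n_promoters) < 0.5, "+", "-")

    prom_ids = [f"prom{i:05d}" for i in range(n_promoters)]
    enh_ids = [f"enh{i:05d}" for i in range(n_enhancers)]

    gene_rows = []
    for i in range(n_promoters):
        tss = int(anchors[i])
        if strands[i] == "+":
            tes = tss + gene_length - 1
        else:
            tes = tss - gene_length + 1
        gene_rows.append((prom_ids[i], chroms[i], tss, tes, strands[i], ""))
    genes = pd.DataFrame(gene_rows, columns=GENE_TABLE_COLUMNS)

    prom_regions = pd.DataFrame({
        "chrom": chroms[:n_promoters],
        "start": anchors[:n_promoters] - flank,
        "end": anchors[:n_promoters] + flank,
        "region_id": prom_ids,
        "anchor": anchors[:n_promoters],
        "strand": strands,
    })
    enh_regions = pd.DataFrame({
        "chrom": chroms[n_promoters:],
        "start": anchors[n_promoters:] - flank,
        "end": anchors[n_promoters:] + flank,
        "region_id": enh_ids,
        "anchor": anchors[n_promoters:],
        "strand": ["+"] * n_enhancers,
    })
    region_ids = prom_ids + enh_ids

    # divergent-PIC weights per enhancer, shared across factors so that the
    # dominant PIC is the same for every factor
    rng_enh = _stream(seed, "enhancers")
    d = rng_enh.normal(0.0, enhancer_asymmetry_log2_sd, n_enhancers)
    w_left, w_right = 2.0 ** (d / 2), 2.0 ** (-d / 2)
    shift = int(enhancer_spacing // 2 // bin_size) * bin_size
    pic_left = anchors[n_promoters:] - shift
    pic_right = anchors[n_promoters:] + shift

    # --- occupancies ------------------------------------------------------
    log10_occ: dict[str, np.ndarray] = {}
    for a in architectures:
        rng_occ = _stream(seed, "occ", a.factor_name)
        if a.coupling is None:
            log10_occ[a.factor_name] = rng_occ.normal(
                occupancy.log10_mu, occupancy.log10_sd, n_total
            )
        else:
            base, noise_sd = a.coupling
            log10_occ[a.factor_name] = (
                log10_occ[base] + rng_occ.normal(0.0, noise_sd, n_total)
            )

    # planted subsets
    labels: list[list[str]] = [[] for _ in range(n_total)]
    for spec in discordance:
        if spec.numerator not in names or spec.denominator not in names:
            raise ValidationError("discordance names unknown factor")
        rng_p = _stream(seed, "plant", spec.planted_label)
        members = rng_p.random(n_promoters) < spec.planted_fraction
        log10_occ[spec.numerator] = log10_occ[spec.numerator].copy()
        log10_occ[spec.numerator][:n_promoters][members] += (
            spec.log2_shift * np.log10(2.0)
        )
        for i in np.flatnonzero(members):
            labels[i].append(spec.planted_label)

    ds_members = np.zeros(n_total, dtype=bool)
    if downstream_peak is not None:
        if downstream_peak.factor_name not in names:
            raise ValidationError("downstream_peak names unknown factor")
        rng_d = _stream(seed, "plant", downstream_peak.group_label)
        ds_members[:n_promoters] = (
            rng_d.random(n_promoters) < downstream_peak.fraction
        )
        for i in np.flatnonzero(ds_members):
            labels[i].append(downstream_peak.group_label)

    occ = {f: 10.0 ** v for f, v in log10_occ.items()}
    if pause_spec is not None:
        po = occ.get(pause_spec.factor_name)
        if po is None:
            raise ValidationError("pause_spec names unknown factor")
        med = np.median(po[:n_promoters]) if n_promoters else 1.0
        body_ratio = pause_spec.body_level_ratio * (po / med) ** (
            pause_spec.occupancy_exponent
        )

    # --- painting ---------------------------------------------------------
    sign = np.where(strands == "+", 1.0, -1.0)
    tracks: dict[tuple[str, int], CoverageTrack] = {}
    summit_rows = []
    for a in architectures:
        f = a.factor_name
        for rep in range(a.n_replicates):
            track = CoverageTrack.zeros(f, layout, bin_size)
            rng_j = _stream(seed, "jitter", f, rep)
            jit_prom = rng_j.normal(0.0, a.jitter_sd_bp, n_promoters) \
                if a.jitter_sd_bp > 0 else np.zeros(n_promoters)
            jit_enh = rng_j.normal(0.0, a.jitter_sd_bp, (n_enhancers, 2)) \
                if a.jitter_sd_bp > 0 else np.zeros((n_enhancers, 2))

            for i in range(n_promoters):
                arr = track.data[chroms[i]]
                nb = len(arr)
                h = occ[f][i]
                center = anchors[i] + sign[i] * (a.offset_bp + jit_prom[i])
                main_center, main_h = center, h
                if downstream_peak is not None and ds_members[i] \
                        and downstream_peak.factor_name == f:
                    dcen = anchors[i] + sign[i] * (
                        downstream_peak.offset_bp + jit_prom[i]
                    )
                    if downstream_peak.mode == "shifted":
                        main_center, main_h = dcen, h
                        _paint_gaussian(arr, dcen, h, a.peak_sd_bp, bin_size, nb)
                    else:
                        _paint_gaussian(arr, center, h, a.peak_sd_bp, bin_size, nb)
                        _paint_gaussian(
                            arr, dcen, h * downstream_peak.minor_to_major_height,
                            a.peak_sd_bp, bin_size, nb,
                        )
                        if downstream_peak.minor_to_major_height > 1.0:
                            main_center = dcen
                else:
                    _paint_gaussian(arr, center, h, a.peak_sd_bp, bin_size, nb)
                if pause_spec is not None and pause_spec.factor_name == f:
                    g = genes.iloc[i]
                    lo, hi = sorted((int(g.tss), int(g.tes) + 1))
                    _paint_plateau(arr, lo, hi, body_ratio[i] * h, bin_size, nb)
                summit_rows.append((region_ids[i], f, rep, float(main_center)))

            for k in range(n_enhancers):
                i = n_promoters + k
                arr = track.data[chroms[i]]
                nb = len(arr)
                h = occ[f][i]
                # left PIC transcribes leftward, right PIC rightward
                c_left = pic_left[k] - (a.offset_bp + jit_enh[k, 0])
                c_right = pic_right[k] + (a.offset_bp + jit_enh[k, 1])
                _paint_gaussian(arr, c_left, h * w_left[k], a.peak_sd_bp, bin_size, nb)
                _paint_gaussian(arr, c_right, h * w_right[k], a.peak_sd_bp, bin_size, nb)
                dom = c_left if w_left[k] >= w_right[k] else c_right
                summit_rows.append((region_ids[i], f, rep, float(dom)))

            if noise.background_cpm > 0:
                for c in track.data:
                    track.data[c] += noise.background_cpm
            if noise.poisson:
                rng_n = _stream(seed, "noise", f, rep)
                for c in track.data:
                    track.data[c] = (
                        rng_n.poisson(track.data[c] * noise.counts_per_cpm)
                        / noise.counts_per_cpm
                    ).astype(float)
            track.total_mapped = 1e6  # unit library: CPM equals raw values
            tracks[(f, rep)] = track

    # --- truth ------------------------------------------------------------
    occ_rows = [
        (rid, f, float(occ[f][i]))
        for f in names for i, rid in enumerate(region_ids)
    ]
    truth = SyntheticTruth(
        summits=pd.DataFrame(
            summit_rows, columns=["region_id", "factor", "replicate", "summit"]
        ),
        occupancy=pd.DataFrame(
            occ_rows, columns=["region_id", "factor", "occupancy"]
        ),
        regions=pd.DataFrame({
            "region_id": region_ids,
            "labels": [";".join(l) for l in labels],
            "is_enhancer": [False] * n_promoters + [True] * n_enhancers,
        }),
        seed=seed,
        params=_echo_params(locals()),
    )
    genes = genes.copy()
    lab = {rid: ";".join(l) for rid, l in zip(region_ids, labels)}
    genes["gene_class"] = [lab[g] for g in genes["gene_id"]]
    return SimulatedDataset(
        layout=layout, genes=genes,
        promoters=RegionSet(prom_regions), enhancers=RegionSet(enh_regions),
        tracks=tracks, truth=truth, bin_size=bin_size,
    )


def _echo_params(ns: dict) -> dict:
    out = {
        "seed": ns["seed"], "n_promoters": ns["n_promoters"],
        "n_enhancers": ns["n_enhancers"], "bin_size": ns["bin_size"],
        "flank": ns["flank"], "gene_length": ns["gene_length"],
        "enhancer_spacing": ns["enhancer_spacing"],
        "enhancer_asymmetry_log2_sd": ns["enhancer_asymmetry_log2_sd"],
        "occupancy": asdict(ns["occupancy"]),
        "noise": asdict(ns["noise"]),
        "architectures": [asdict(a) for a in ns["architectures"]],
        "discordance": [asdict(s) for s in ns["discordance"]],
    }
    if ns["downstream_peak"] is not None:
        out["downstream_peak"] = asdict(ns["downstream_peak"])
    if ns["pause_spec"] is not None:
        out["pause_spec"] = asdict(ns["pause_spec"])
    return out


def truth_report(truth: SyntheticTruth, outdir) -> None:
    """Write planted truth as TSVs plus a YAML parameter echo."""
    import os

    os.makedirs(outdir, exist_ok=True)
    truth.summits.to_csv(
        os.path.join(outdir, "truth_summits.tsv"), sep="\t", index=False
    )
    truth.occupancy.to_csv(
        os.path.join(outdir, "truth_occupancy.tsv"), sep="\t", index=False
    )
    truth.regions.to_csv(
        os.path.join(outdir, "truth_regions.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "params.yaml"), "w") as fh:
        yaml.safe_dump(
            {"seed": truth.seed, **truth.params}, fh, sort_keys=True
        )


def human_mode_architectures(
    jitter_sd_bp: float = 0.0, peak_sd_bp: float = 60.0, n_replicates: int = 1,
    couple_polii_to_tbp: float | None = None,
) -> list[FactorArchitecture]:
    """PIC geometry of human/mouse promoters: a GTF-class factor (TBP) at
    the TSS, paused Pol II 50 bp downstream, a proximal activator (SP1)
    80 bp upstream."""
    pol_coupling = None if couple_polii_to_tbp is None else ("TBP", couple_polii_to_tbp)
    common = dict(peak_sd_bp=peak_sd_bp, jitter_sd_bp=jitter_sd_bp,
                  n_replicates=n_replicates)
    return [
        FactorArchitecture("TBP", offset_bp=0.0, **common),
        FactorArchitecture("PolII", offset_bp=HUMAN_PAUSE_OFFSET,
                           coupling=pol_coupling, **common),
        FactorArchitecture("SP1", offset_bp=PROXIMAL_ACTIVATOR_OFFSET, **common),
    ]


def fly_mode_architectures(
    jitter_sd_bp: float = 0.0, peak_sd_bp: float = 60.0, n_replicates: int = 1,
) -> list[FactorArchitecture]:
    """PIC geometry of Drosophila promoters: TBP and Mediator at the TSS,
    TAFs 60 bp downstream (over the downstream promoter elements), paused
    Pol II 60 bp downstream, a GAGA-class activator 60 bp upstream."""
    common = dict(peak_sd_bp=peak_sd_bp, jitter_sd_bp=jitter_sd_bp,
                  n_replicates=n_replicates)
    return [
        FactorArchitecture("TBP", offset_bp=0.0, **common),
        FactorArchitecture("Med1", offset_bp=0.0, **common),
        FactorArchitecture("Taf2", offset_bp=FLY_DOWNSTREAM_TAF_OFFSET, **common),
        FactorArchitecture("PolII", offset_bp=FLY_PAUSE_OFFSET, **common),
        FactorArchitecture("GAGA", offset_bp=FLY_ACTIVATOR_OFFSET, **common),
    ]
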