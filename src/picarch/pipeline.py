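"""Run configuration, orchestration, and reproducibility.

A run is described by a single YAML document with exactly one input
source — a ``simulate`` block (synthetic data with ground truth) or an
``inputs`` block (bedGraph tracks plus a gene table) — and an
``analysis`` block switching on the stages to run. Every stage writes
TSV/JSON into the output directory, all parameters (including defaults
the user never set) are echoed into a run manifest together with package
and library versions and input checksums, and the whole run is
deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import (
    GenomeLayout, RegionSet, promoters_from_genes, read_gene_table,
    read_bed_regions,
)
from .tracks import CoverageTrack, read_bedgraph, cpm_normalize
from .synthetic import (
    DiscordanceSpec, DownstreamPeakSpec, FactorArchitecture, NoiseSpec,
    OccupancyModel, PauseSpec, SimulatedDataset, simulate_dataset,
    human_mode_architectures, fly_mode_architectures,
)
from .metagene import metagene, profile_offset, ProfileError
from .peaks import call_summits, classify_peak_shapes
from .pairing import summit_distances, replicate_null
from .occupancy import (
    occupancy_table, rank_most_active, correlate, ratio_analysis,
    decile_summary, group_overlap, label_enrichment,
)
from .pausing import pausing_table

logger = logging.getLogger(__name__)

ANALYSIS_DEFAULTS: dict = {
    "metagene": {"flank": 1000, "aggregator": "mean"},
    "summits": {"min_enrichment": 2.0, "bandwidth": 25.0},
    "distances": {"pairs": [], "replicate_null_factors": [], "max_distance": 500},
    "occupancy": {"method": "summit_height", "window": 200, "top_n": None,
                  "rank_by": None},
    "correlations": {"pairs": [], "scale": "log10", "pseudocount": 0.1},
    "ratios": [],
    "pausing": {"factor": None, "proximal_window": [-50, 300],
                "body_window": [2000, 4000], "min_body": 500},
    "deciles": {"rank_by": None, "response": "pausing_index"},
    "shapes": {"factor": None, "tss_zone": 50, "downstream_zone": [80, 300],
               "min_separation": 40, "minor_ratio": 0.3},
    "enrichment": {"from_ratio_group": None},
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def validate_config(cfg) -> list[str]:
    """Return a list of violated constraints (empty when valid); each
    message carries a dotted path into the config."""
    if isinstance(cfg, (str, os.PathLike)):
        try:
            cfg = load_config(cfg)
        except Exception as exc:  # unreadable/invalid YAML is the error list
            return [f"<root>: {exc}"]
    errs: list[str] = []
    has_sim = "simulate" in cfg
    has_inp = "inputs" in cfg
    if has_sim == has_inp:
        errs.append("<root>: exactly one of 'simulate' or 'inputs' is required"
                    " (mutually exclusive)")
    if not isinstance(cfg.get("seed", 0), int):
        errs.append("seed: must be an integer")
    if has_sim:
        sim = cfg["simulate"] or {}
        if sim.get("n_promoters", 0) <= 0:
            errs.append("simulate.n_promoters: must be > 0")
        if sim.get("mode") not in (None, "human", "fly") and "factors" not in sim:
            errs.append("simulate.mode: must be 'human' or 'fly', or give"
                        " simulate.factors")
        for key in ("flank", "gene_length", "bin_size"):
            if key in sim and sim[key] <= 0:
                errs.append(f"simulate.{key}: must be > 0")
        if sim.get("jitter_sd_bp", 0) < 0:
            errs.append("simulate.jitter_sd_bp: must be >= 0")
    if has_inp:
        inp = cfg["inputs"] or {}
        if "genes" not in inp:
            errs.append("inputs.genes: required")
        if not inp.get("tracks"):
            errs.append("inputs.tracks: at least one track required")
        for i, t in enumerate(inp.get("tracks", [])):
            for key in ("factor", "path"):
                if key not in t:
                    errs.append(f"inputs.tracks[{i}].{key}: required")
        if "chrom_lengths" not in inp:
            errs.append("inputs.chrom_lengths: required (mapping chrom -> bp)")
    ana = cfg.get("analysis", {}) or {}
    mg = {**ANALYSIS_DEFAULTS["metagene"], **(ana.get("metagene") or {})}
    if mg["flank"] <= 0:
        errs.append("analysis.metagene.flank: must be > 0")
    if mg["aggregator"] not in ("mean", "median"):
        errs.append("analysis.metagene.aggregator: must be 'mean' or 'median'")
    for i, r in enumerate(ana.get("ratios") or []):
        for key in ("numerator", "denominator"):
            if key not in r:
                errs.append(f"analysis.ratios[{i}].{key}: required")
    return errs


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_simulated(cfg: dict, seed: int) -> SimulatedDataset:
    sim = dict(cfg["simulate"] or {})
    mode = sim.pop("mode", None)
    jitter = sim.pop("jitter_sd_bp", 0.0)
    peak_sd = sim.pop("peak_sd_bp", 60.0)
    n_rep = sim.pop("n_replicates", 1)
    if "factors" in sim:
        archs = [FactorArchitecture(**{**f, "coupling": tuple(f["coupling"])
                                       if f.get("coupling") else None})
                 for f in sim.pop("factors")]
    elif mode == "fly":
        archs = fly_mode_architectures(jitter, peak_sd, n_rep)
    else:
        archs = human_mode_architectures(jitter, peak_sd, n_rep)
    kwargs = {}
    for key in ("n_promoters", "n_enhancers", "bin_size", "flank",
                "gene_length", "enhancer_spacing",
                "enhancer_asymmetry_log2_sd"):
        if key in sim:
            kwargs[key] = sim[key]
    if "noise" in sim:
        kwargs["noise"] = NoiseSpec(**sim["noise"])
    if "occupancy" in sim:
        kwargs["occupancy"] = OccupancyModel(**sim["occupancy"])
    if "discordance" in sim:
        kwargs["discordance"] = [DiscordanceSpec(**d) for d in sim["discordance"]]
    if "downstream_peak" in sim:
        kwargs["downstream_peak"] = DownstreamPeakSpec(**sim["downstream_peak"])
    if "pause_spec" in sim:
        kwargs["pause_spec"] = PauseSpec(**sim["pause_spec"])
    return simulate_dataset(architectures=archs, seed=seed, **kwargs)


def _load_inputs(cfg: dict):
    inp = cfg["inputs"]
    bin_size = inp.get("bin_size", 5)
    layout = GenomeLayout(tuple(inp["chrom_lengths"].keys()),
                          tuple(inp["chrom_lengths"].values()))
    genes = read_gene_table(inp["genes"])
    flank = inp.get("flank", 1000)
    if "promoters" in inp:
        promoters = read_bed_regions(inp["promoters"], anchor="start")
        # anchors for promoter BEDs are TSSs from the gene table
        tss = genes.set_index("gene_id")
        df = promoters.regions.copy()
        known = df["region_id"].isin(tss.index)
        df.loc[known, "anchor"] = tss.loc[
            df.loc[known, "region_id"], "tss"
        ].to_numpy()
        df.loc[known, "strand"] = tss.loc[
            df.loc[known, "region_id"], "strand"
        ].to_numpy()
        promoters = RegionSet(df)
    else:
        promoters = promoters_from_genes(genes, layout, flank, flank)
    enhancers = (read_bed_regions(inp["enhancers"], anchor="midpoint")
                 if "enhancers" in inp else RegionSet())
    tracks: dict[tuple[str, int], CoverageTrack] = {}
    checksums = {}
    for t in inp["tracks"]:
        track = read_bedgraph(t["path"], layout, bin_size, t["factor"])
        total = t.get("total_mapped")
        if total:
            track = cpm_normalize(track, total)
        tracks[(t["factor"], t.get("replicate", 0))] = track
        checksums[os.path.basename(t["path"])] = _sha256(t["path"])
    return layout, genes, promoters, enhancers, tracks, checksums


def run(cfg, outdir: str | None = None, seed: int | None = None) -> dict:
    """Execute a full run: build or load data, run the requested analysis
    stages, and write the report bundle plus a manifest.

    Independent stages continue past a failed one; the returned dict maps
    stage names to results and carries a 'failures' list.
    """
    if isinstance(cfg, (str, os.PathLike)):
        cfg = load_config(cfg)
    errs = validate_config(cfg)
    if errs:
        raise ConfigError("; ".join(errs))
    seed = seed if seed is not None else cfg.get("seed", 0)
    outdir = outdir or cfg.get("outdir", "picarch_out")
    os.makedirs(outdir, exist_ok=True)

    checksums: dict = {}
    truth = None
    if "simulate" in cfg:
        ds = _build_simulated(cfg, seed)
        genes, promoters, enhancers = ds.genes, ds.promoters, ds.enhancers
        raw_tracks = ds.tracks
        truth = ds.truth
        if cfg.get("simulate_output", True):
            simdir = os.path.join(outdir, "simulated")
            for name in ds.write(simdir):
                checksums[name] = _sha256(os.path.join(simdir, name))
    else:
        _layout, genes, promoters, enhancers, raw_tracks, checksums = \
            _load_inputs(cfg)

    # CPM normalization for tracks that still carry raw counts
    tracks: dict[tuple[str, int], CoverageTrack] = {}
    for key, tr in raw_tracks.items():
        if not tr.normalized and tr.total_mapped:
            tr = cpm_normalize(tr, tr.total_mapped)
        tracks[key] = tr
    rep0 = {f: tr for (f, r), tr in tracks.items() if r == 0}

    ana = cfg.get("analysis", {}) or {}
    results: dict = {"failures": [], "outdir": outdir}
    counts: dict = {}

    def _stage(name, fn):
        if name not in ana:
            return
        try:
            results[name] = fn({**ANALYSIS_DEFAULTS.get(name, {}),
                                **(ana.get(name) or {})}
                               if not isinstance(ana.get(name), list)
                               else ana[name])
        except Exception as exc:
            logger.exception("stage %s failed", name)
            results["failures"].append({"stage": name, "error": str(exc)})

    def _metagene(p):
        profiles = {}
        for f, tr in rep0.items():
            prof = metagene(tr, promoters, p["flank"], p["aggregator"])
            prof.to_tsv(os.path.join(outdir, f"metagene_{f}.tsv"))
            profiles[f] = prof
        counts["metagene_dropped_anchors"] = {
            f: pr.n_dropped for f, pr in profiles.items()
        }
        offs = {}
        for f in profiles:
            for g in profiles:
                if f < g:
                    try:
                        offs[f"{f}->{g}"] = profile_offset(profiles[f], profiles[g])
                    except ProfileError as exc:
                        offs[f"{f}->{g}"] = str(exc)
        with open(os.path.join(outdir, "profile_offsets.json"), "w") as fh:
            json.dump(offs, fh, indent=1)
        return {"profiles": profiles, "offsets": offs}

    _stage("metagene", _metagene)

    summit_calls: dict[tuple[str, int], pd.DataFrame] = {}

    def _summits(p):
        regions = promoters
        if len(enhancers):
            regions = RegionSet(pd.concat(
                [promoters.regions, enhancers.regions], ignore_index=True
            ))
        for key, tr in tracks.items():
            summit_calls[key] = call_summits(
                tr, regions, min_enrichment=p["min_enrichment"],
                bandwidth=p["bandwidth"],
            )
        all_calls = pd.concat(
            [c.assign(replicate=k[1]) for k, c in summit_calls.items()],
            ignore_index=True,
        )
        all_calls.to_csv(os.path.join(outdir, "summit_calls.tsv"),
                         sep="\t", index=False)
        return summit_calls

    _stage("summits", _summits)

    def _distances(p):
        out = {}
        for a, b in p["pairs"]:
            st = summit_distances(summit_calls[(a, 0)], summit_calls[(b, 0)],
                                  p["max_distance"])
            st.to_json(os.path.join(outdir, f"distances_{a}_{b}.json"))
            out[f"{a}|{b}"] = st
        for f in p["replicate_null_factors"]:
            st = replicate_null(summit_calls[(f, 0)], summit_calls[(f, 1)],
                                p["max_distance"])
            st.to_json(os.path.join(outdir, f"replicate_null_{f}.json"))
            out[f"{f}|replicate"] = st
        counts["distance_pairs_excluded"] = {
            k: v.n_excluded_distance + v.n_excluded_detection
            for k, v in out.items()
        }
        return out

    _stage("distances", _distances)

    occ_tab: pd.DataFrame | None = None

    def _occupancy(p):
        nonlocal occ_tab, promoters_active
        occ_tab = occupancy_table(rep0, promoters, p["method"], p["window"])
        occ_tab.to_csv(os.path.join(outdir, "occupancy.tsv"), sep="\t")
        if p.get("top_n") and p.get("rank_by"):
            top = rank_most_active(occ_tab, p["rank_by"], p["top_n"])
            occ_tab = occ_tab.loc[top]
            promoters_active = promoters.subset(top)
            occ_tab.to_csv(os.path.join(outdir, "occupancy_top.tsv"), sep="\t")
        return occ_tab

    promoters_active = promoters
    _stage("occupancy", _occupancy)

    def _correlations(p):
        rows = []
        for a, b in p["pairs"]:
            res = correlate(occ_tab, a, b, p["scale"], p["pseudocount"])
            rows.append({"factor_a": a, "factor_b": b, "pearson_r": res.pearson_r,
                         "n": res.n, "scale": res.scale,
                         "pseudocount": res.pseudocount})
        df = pd.DataFrame(rows)
        df.to_csv(os.path.join(outdir, "correlations.tsv"), sep="\t", index=False)
        return df

    _stage("correlations", _correlations)

    ratio_results: dict[str, pd.DataFrame] = {}

    def _ratios(specs):
        for r in specs:
            res = ratio_analysis(
                occ_tab, r["numerator"], r["denominator"],
                r.get("pseudocount", 0.1), r.get("high_cut", 1.0),
                r.get("low_cut", 1.0),
            )
            name = f"{r['numerator']}_over_{r['denominator']}"
            res.to_csv(os.path.join(outdir, f"ratio_{name}.tsv"), sep="\t")
            ratio_results[name] = res
        return ratio_results

    _stage("ratios", _ratios)

    pause_tab: pd.DataFrame | None = None

    def _pausing(p):
        nonlocal pause_tab
        tr = rep0[p["factor"]]
        sub = genes[genes["gene_id"].isin(occ_tab.index)] \
            if occ_tab is not None else genes
        pause_tab = pausing_table(
            tr, sub, proximal_window=tuple(p["proximal_window"]),
            body_window=tuple(p["body_window"]), min_body=p["min_body"],
        )
        pause_tab.to_csv(os.path.join(outdir, "pausing.tsv"), sep="\t")
        counts["pausing_truncated"] = int(
            (pause_tab["status"] == "short_gene_adjusted").sum())
        counts["pausing_excluded"] = int(
            (pause_tab["status"] == "excluded").sum())
        return pause_tab

    _stage("pausing", _pausing)

    def _deciles(p):
        if p["response"] == "pausing_index":
            resp = pause_tab["pausing_index"]
        else:
            resp = occ_tab[p["response"]]
        df = decile_summary(occ_tab, p["rank_by"], resp)
        df.to_csv(os.path.join(outdir, "deciles.tsv"), sep="\t", index=False)
        return df

    _stage("deciles", _deciles)

    shape_calls: pd.DataFrame | None = None

    def _shapes(p):
        nonlocal shape_calls
        tr = rep0[p["factor"]]
        shape_calls = classify_peak_shapes(
            tr, genes, tss_zone=p["tss_zone"],
            downstream_zone=tuple(p["downstream_zone"]),
            min_separation=p["min_separation"], minor_ratio=p["minor_ratio"],
        )
        shape_calls.to_csv(os.path.join(outdir, "peak_shapes.tsv"),
                           sep="\t", index=False)
        return shape_calls

    _stage("shapes", _shapes)

    def _enrichment(p):
        group_name = p.get("from_ratio_group") or "low"
        name, res = next(iter(ratio_results.items()))
        group = res.index[res["group"] == group_name]
        labels = genes.set_index("gene_id")["gene_class"]
        df = label_enrichment(group, res.index, labels)
        df.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)
        return df

    _stage("enrichment", _enrichment)

    manifest = {
        "picarch_version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": seed,
        "config": cfg,
        "analysis_defaults": ANALYSIS_DEFAULTS,
        "input_checksums": checksums,
        "counts": counts,
        "failures": results["failures"],
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    results["truth"] = truth
    return results
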