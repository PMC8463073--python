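"""Per-region occupancy tables and the statistics built on them.

The occupancy table is a plain pandas DataFrame: one row per region_id,
one column per factor, values on the CPM scale, with the quantification
method recorded in ``df.attrs["method"]``. On top of it sit the analyses
used to characterize promoter composition: activity ranking, pairwise
log-scale correlations, median-centered occupancy-ratio classification
(discordant gene groups), decile summaries, group overlap counts, and
hypergeometric label enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr
from statsmodels.stats.multitest import multipletests

from .annotations import RegionSet, ValidationError
from .tracks import CoverageTrack, smooth


def quantify_occupancy(
    track: CoverageTrack,
    regions: RegionSet,
    method: str = "summit_height",
    window: int = 200,
    bandwidth: float = 25.0,
) -> pd.Series:
    """One occupancy scalar per region for one factor.

    summit_height: maximum of the smoothed signal within the region.
    window_mean: mean CPM within ±window bp of the anchor.
    """
    if method not in ("summit_height", "window_mean"):
        raise ValidationError(f"unknown occupancy method {method!r}")
    vals = []
    for r in regions:
        if method == "summit_height":
            sm = smooth(track.values_in(r.chrom, r.start, r.end), bandwidth,
                        track.bin_size)
            vals.append(float(sm.max()))
        else:
            v = track.values_in(r.chrom, r.anchor - window, r.anchor + window)
            vals.append(float(v.mean()))
    s = pd.Series(vals, index=regions.region_ids, name=track.factor_name)
    s.attrs["method"] = method
    return s


def occupancy_table(
    tracks: dict[str, CoverageTrack],
    regions: RegionSet,
    method: str = "summit_height",
    window: int = 200,
    bandwidth: float = 25.0,
) -> pd.DataFrame:
    cols = {
        f: quantify_occupancy(t, regions, method, window, bandwidth)
        for f, t in tracks.items()
    }
    df = pd.DataFrame(cols)
    df.index.name = "region_id"
    df.attrs["method"] = method
    return df


def rank_most_active(table: pd.DataFrame, by_factor: str, top_n: int) -> pd.Index:
    """region_ids of the top_n regions by one factor's occupancy,
    descending; ties broken lexicographically by region_id."""
    if top_n <= 0:
        raise ValidationError("top_n must be > 0")
    if by_factor not in table.columns:
        raise ValidationError(f"factor {by_factor!r} not in table")
    if top_n > len(table):
        raise ValidationError("top_n exceeds table size")
    order = table.assign(_id=table.index.astype(str)).sort_values(
        [by_factor, "_id"], ascending=[False, True], kind="mergesort"
    )
    return order.index[:top_n]


@dataclass
class CorrelationResult:
    factor_pair: tuple[str, str]
    pearson_r: float
    n: int
    scale: str          # log10 | linear
    pseudocount: float


def correlate(
    table: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    scale: str = "log10",
    pseudocount: float = 0.1,
) -> CorrelationResult:
    """Pearson correlation of two factors' occupancies, optionally on
    log10(x + pseudocount)."""
    if scale not in ("log10", "linear"):
        raise ValidationError(f"unknown scale {scale!r}")
    x = table[factor_a].to_numpy(dtype=float)
    y = table[factor_b].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValidationError("need at least 3 regions to correlate")
    if scale == "log10":
        x = np.log10(x + pseudocount)
        y = np.log10(y + pseudocount)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidationError("zero variance after transform")
    r = float(pearsonr(x, y).statistic)
    return CorrelationResult((factor_a, factor_b), r, len(x), scale, pseudocount)


def ratio_analysis(
    table: pd.DataFrame,
    numerator: str,
    denominator: str,
    pseudocount: float = 0.1,
    high_cut: float = 1.0,
    low_cut: float = 1.0,
) -> pd.DataFrame:
    """Median-centered occupancy ratios with high/low group calls.

    raw_ratio = (num + pc) / (den + pc); normalized_ratio divides by the
    median so the median normalized ratio is exactly 1.0; groups are
    called on log2(normalized_ratio) at ±(high_cut/low_cut).
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    if len(table) < 3:
        raise ValidationError("need at least 3 regions for ratio analysis")
    raw = (table[numerator] + pseudocount) / (table[denominator] + pseudocount)
    norm = raw / np.median(raw)
    log2n = np.log2(norm)
    group = pd.Series("normal", index=table.index)
    group[log2n >= high_cut] = "high"
    group[log2n <= -low_cut] = "low"
    out = pd.DataFrame({
        "raw_ratio": raw, "normalized_ratio": norm,
        "log2_normalized": log2n, "group": group,
    })
    out.attrs["factor_pair"] = (numerator, denominator)
    return out


def decile_summary(
    table: pd.DataFrame,
    rank_by: str,
    response: pd.Series,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Median response per decile of one factor's occupancy.

    Regions are ranked by ``rank_by`` (ascending: decile 10 holds the
    highest occupancies) and split into bins whose sizes differ by at
    most one; rows of ``response`` are aligned by region_id and must be
    finite.
    """
    resp = response.reindex(table.index)
    ok = np.isfinite(resp.to_numpy(dtype=float))
    sub = table.loc[ok]
    resp = resp.loc[ok]
    if len(sub) < n_bins:
        raise ValidationError(f"need at least {n_bins} regions with finite response")
    order = sub.assign(_id=sub.index).sort_values(
        [rank_by, "_id"], ascending=[True, True], kind="mergesort"
    ).index
    chunks = np.array_split(np.arange(len(order)), n_bins)
    rows = []
    for i, idx in enumerate(chunks, start=1):
        ids = order[idx]
        rows.append({
            "decile": i,
            "n": len(ids),
            "rank_by_median": float(sub.loc[ids, rank_by].median()),
            "response_median": float(resp.loc[ids].median()),
        })
    return pd.DataFrame(rows)


def group_overlap(set_a, set_b, universe) -> dict[str, int]:
    """Venn counts (a_only, b_only, both, neither) over a region universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValidationError("group element outside universe")
    both = len(a & b)
    return {
        "a_only": len(a) - both,
        "b_only": len(b) - both,
        "both": both,
        "neither": len(u) - len(a | b),
    }


def label_enrichment(
    group,
    universe,
    labels: pd.Series,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of gene-class labels in a group.

    For each label with K carriers among N universe regions and k among
    the n group members: p = P(X >= k) (upper tail including k), fold =
    (k/n) / (K/N). Benjamini–Hochberg-adjusted p-values are reported
    alongside the raw ones.
    """
    group = set(group)
    universe = list(universe)
    if not group:
        raise ValidationError("empty group")
    if not group <= set(universe):
        raise ValidationError("group element outside universe")
    labels = labels.reindex(universe).fillna("")
    N, n = len(universe), len(group)
    rows = []
    all_labels = sorted({l for ls in labels for l in str(ls).split(";") if l})
    for lab in all_labels:
        carriers = {r for r, ls in labels.items() if lab in str(ls).split(";")}
        K = len(carriers)
        k = len(carriers & group)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if K else float("nan")
        rows.append({"label": lab, "k": k, "n": n, "K": K, "N": N,
                     "fold": fold, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
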