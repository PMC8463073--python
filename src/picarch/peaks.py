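"""Per-region summit detection and peak-shape classification.

This is a deliberately simple, per-region summit caller: within each
candidate region the summit is the argmax of the smoothed signal, and a
call is made only when the summit height clears a fold-enrichment over
background. Shape classification separates genes whose factor peak sits
at the TSS from those with a downstream peak (at or near the paused
Pol II position) or with both components (bimodal shape).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import RegionSet, ValidationError
from .tracks import CoverageTrack, smooth


@dataclass
class SummitCall:
    region_id: str
    factor_name: str
    summit: int          # genomic base (center of the argmax bin)
    height: float        # smoothed CPM at the summit
    prominence: float    # height minus the flanking minimum
    detected: bool


def call_summit(
    track: CoverageTrack,
    region,
    background: float = 0.0,
    min_enrichment: float = 2.0,
    bandwidth: float = 25.0,
    strand: str = "+",
) -> SummitCall:
    """Summit = argmax of the smoothed signal within the region.

    detected iff height >= min_enrichment * background. Ties go to the
    leftmost bin in strand-transformed coordinates (leftmost genomic bin
    for plus-strand regions, rightmost for minus).
    """
    if background < 0:
        raise ValidationError("background must be >= 0")
    chrom, start, end = region.chrom, int(region.start), int(region.end)
    rid = getattr(region, "region_id", "")
    b = track.bin_size
    if end - start < b:
        raise ValidationError(f"region {rid!r} shorter than one bin")
    b0 = max(0, start // b)
    b1 = min(track.n_bins(chrom), -(-end // b))
    sm = smooth(track.data[chrom][b0:b1], bandwidth, b)
    top = sm.max()
    cand = np.flatnonzero(sm == top)
    k = cand[0] if strand == "+" else cand[-1]
    summit = (b0 + int(k)) * b + b // 2
    prominence = float(top - min(sm[: k + 1].min(), sm[k:].min()))
    detected = bool(top >= min_enrichment * background)
    return SummitCall(rid, track.factor_name, summit, float(top),
                      prominence, detected)


def call_summits(
    track: CoverageTrack,
    regions: RegionSet,
    background: float | None = None,
    min_enrichment: float = 2.0,
    bandwidth: float = 25.0,
) -> pd.DataFrame:
    """Summit calls for every region, as a DataFrame (one row per region).

    background defaults to the track's genome-wide median CPM.
    """
    if background is None:
        background = track.genome_median()
    rows = [
        call_summit(track, r, background, min_enrichment, bandwidth, r.strand)
        for r in regions
    ]
    df = pd.DataFrame([vars(c) for c in rows])
    df.insert(0, "chrom", list(regions.regions["chrom"]))
    return df


def summits_to_bed(calls: pd.DataFrame, path) -> None:
    """6-column BED of detected summits, score = summit height."""
    det = calls[calls["detected"]]
    out = pd.DataFrame({
        "chrom": det["chrom"],
        "start": det["summit"], "end": det["summit"] + 1,
        "name": det["region_id"] + ":" + det["factor_name"],
        "score": det["height"], "strand": "+",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class PeakShapeCall:
    region_id: str
    factor_name: str
    shape: str                   # at_TSS | downstream | bimodal | none
    tss_component_height: float
    downstream_component_height: float
    downstream_offset: float     # bp downstream of the TSS (orientation-aware)


def classify_peak_shape(
    track: CoverageTrack,
    gene,
    tss_zone: float = 50.0,
    downstream_zone: tuple[float, float] = (80.0, 300.0),
    min_separation: float = 40.0,
    minor_ratio: float = 0.3,
    background: float = 0.0,
    bandwidth: float = 25.0,
) -> PeakShapeCall:
    """Classify a gene's peak shape from local maxima in two zones.

    A TSS component is a local maximum within ±tss_zone of the TSS; a
    downstream component is one inside downstream_zone (orientation-
    aware). bimodal requires both with minor/major height >= minor_ratio
    and separation >= min_separation; otherwise the single qualifying
    component decides, and none if neither clears background.
    """
    if downstream_zone[0] < tss_zone:
        raise ValidationError("downstream_zone must not overlap the TSS zone")
    b = track.bin_size
    s = 1 if gene.strand == "+" else -1
    tss = int(gene.tss)
    span = downstream_zone[1] + 4 * bandwidth
    lo_bp = tss - s * (tss_zone + 4 * bandwidth) if s > 0 else tss - span
    hi_bp = tss + span if s > 0 else tss + (tss_zone + 4 * bandwidth)
    b0 = max(0, int(lo_bp) // b)
    b1 = min(track.n_bins(gene.chrom), -(-int(hi_bp) // b))
    sm = smooth(track.data[gene.chrom][b0:b1], bandwidth, b)
    centers = (np.arange(b0, b1) + 0.5) * b
    off = s * (centers - tss)  # orientation-aware offset from TSS

    interior = (sm >= np.roll(sm, 1)) & (sm >= np.roll(sm, -1))
    interior[[0, -1]] = True  # allow maxima at the scan edges

    def _best(mask):
        m = mask & interior & (sm > background)
        if not m.any():
            return None, 0.0
        k = np.flatnonzero(m)[np.argmax(sm[m])]
        return float(off[k]), float(sm[k])

    tss_off, tss_h = _best(np.abs(off) <= tss_zone)
    ds_off, ds_h = _best((off >= downstream_zone[0]) & (off <= downstream_zone[1]))

    rid = getattr(gene, "gene_id", getattr(gene, "region_id", ""))
    if tss_off is not None and ds_off is not None:
        if abs(ds_off - tss_off) >= min_separation and (
            min(tss_h, ds_h) / max(tss_h, ds_h) >= minor_ratio
        ):
            shape = "bimodal"
        else:
            shape = "at_TSS" if tss_h >= ds_h else "downstream"
    elif ds_off is not None:
        shape = "downstream"
    elif tss_off is not None:
        shape = "at_TSS"
    else:
        shape = "none"
    return PeakShapeCall(
        rid, track.factor_name, shape, tss_h, ds_h,
        ds_off if ds_off is not None else float("nan"),
    )


def classify_peak_shapes(track: CoverageTrack, genes: pd.DataFrame,
                         **kwargs) -> pd.DataFrame:
    rows = [classify_peak_shape(track, g, **kwargs)
            for g in genes.itertuples(index=False)]
    return pd.DataFrame([vars(c) for c in rows])
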