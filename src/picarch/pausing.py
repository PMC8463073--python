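"""Pol II pausing index per gene.

The pausing index is the ratio of Pol II signal in the promoter-proximal
peak to the mean signal in the coding region, taken as the mean CPM
2000–4000 bp downstream of the TSS — or less for genes shorter than the
body window, in which case the window is truncated at the TES and the
result flagged. Genes whose remaining body window is shorter than a
floor, or whose body signal is zero, are excluded with a reason rather
than producing a division error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import ValidationError
from .tracks import CoverageTrack


@dataclass
class PausingResult:
    gene_id: str
    proximal_mean: float
    body_mean: float
    body_window_used: tuple[int, int]   # bp offsets downstream of TSS
    pausing_index: float                # proximal_mean / body_mean; NaN if excluded
    status: str                         # ok | short_gene_adjusted | excluded


def _window_mean(track: CoverageTrack, chrom: str, tss: int, strand: str,
                 w0: float, w1: float) -> float:
    """Mean CPM over the orientation-aware half-open offset window [w0, w1)."""
    if strand == "+":
        lo, hi = tss + w0, tss + w1
    else:
        lo, hi = tss - w1 + 1, tss - w0 + 1
    v = track.values_in(chrom, int(lo), int(hi))
    if len(v) == 0:
        return float("nan")
    return float(v.mean())


def pausing_index(
    track: CoverageTrack,
    gene,
    proximal_window: tuple[float, float] = (-50, 300),
    body_window: tuple[float, float] = (2000, 4000),
    min_body: int = 500,
) -> PausingResult:
    """Pausing index of one gene from a Pol II coverage track.

    proximal_mean is the mean CPM in proximal_window around the TSS (in
    transcription orientation); the body window is truncated at the TES
    for short genes (status short_gene_adjusted) and the gene excluded if
    fewer than min_body bp remain or the body mean is zero.
    """
    if proximal_window[0] >= proximal_window[1] or body_window[0] >= body_window[1]:
        raise ValidationError("windows must satisfy start < end")
    length = abs(int(gene.tes) - int(gene.tss)) + 1
    gid = getattr(gene, "gene_id", "")
    if length < proximal_window[1]:
        raise ValidationError(f"gene {gid!r} shorter than the proximal window")

    prox = _window_mean(track, gene.chrom, int(gene.tss), gene.strand,
                        proximal_window[0], proximal_window[1])

    b0, b1 = body_window
    status = "ok"
    if length < b1:
        b1 = length
        status = "short_gene_adjusted"
    if b1 - b0 < min_body:
        return PausingResult(gid, prox, float("nan"), (int(b0), int(b1)),
                             float("nan"), "excluded")
    body = _window_mean(track, gene.chrom, int(gene.tss), gene.strand, b0, b1)
    if not np.isfinite(body) or body == 0:
        return PausingResult(gid, prox, body, (int(b0), int(b1)),
                             float("nan"), "excluded")
    return PausingResult(gid, prox, body, (int(b0), int(b1)),
                         prox / body, status)


def pausing_table(track: CoverageTrack, genes: pd.DataFrame,
                  **kwargs) -> pd.DataFrame:
    """Per-gene pausing results as a DataFrame indexed by gene_id."""
    rows = [pausing_index(track, g, **kwargs)
            for g in genes.itertuples(index=False)]
    df = pd.DataFrame([vars(r) for r in rows]).set_index("gene_id")
    return df
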