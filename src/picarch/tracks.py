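"""Binned coverage tracks: bedGraph I/O, CPM normalization, smoothing.

A :class:`CoverageTrack` holds one signal vector per chromosome at a fixed
bin size. Values are length-weighted means of the underlying base-pair
signal over each bin (uncovered bases contribute zero), so a track read at
its native resolution round-trips exactly through bedGraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .annotations import GenomeLayout, ParseError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    factor_name: str
    bin_size: int
    layout: GenomeLayout
    data: dict[str, np.ndarray] = field(default_factory=dict)
    total_mapped: float | None = None
    normalized: bool = False

    @classmethod
    def zeros(cls, factor_name: str, layout: GenomeLayout, bin_size: int) -> "CoverageTrack":
        if bin_size < 1:
            raise ValidationError("bin_size must be >= 1")
        data = {
            c: np.zeros(-(-l // bin_size))  # ceil division
            for c, l in layout.lengths.items()
        }
        return cls(factor_name, bin_size, layout, data)

    def n_bins(self, chrom: str) -> int:
        return len(self.data[chrom])

    def values_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bin values for bins overlapping [start, end)."""
        if chrom not in self.data:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        b0 = max(0, start // self.bin_size)
        b1 = min(len(self.data[chrom]), -(-end // self.bin_size))
        return self.data[chrom][b0:b1]

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.data[chrom][pos // self.bin_size])

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            self.factor_name, self.bin_size, self.layout,
            {c: v * factor for c, v in self.data.items()},
            self.total_mapped, self.normalized,
        )

    def genome_median(self) -> float:
        return float(np.median(np.concatenate(list(self.data.values()))))


def read_bedgraph(path, layout: GenomeLayout, bin_size: int,
                  factor_name: str | None = None) -> CoverageTrack:
    """Read a bedGraph file into a binned track.

    Each bin holds the integral of the piecewise-constant bedGraph signal
    over the bin divided by the bin width; uncovered bases count as zero.
    Where intervals overlap, later lines overwrite earlier ones (the
    dialect leaves this ambiguous; a warning is logged).
    """
    if bin_size < 1:
        raise ValidationError("bin_size must be >= 1")
    name = factor_name or str(path)
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ParseError(f"line {lineno}: expected 4 bedGraph columns")
        chrom = fields[0]
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError:
            raise ParseError(f"line {lineno}: malformed coordinates or value") from None
        if start >= end:
            raise ParseError(f"line {lineno}: start >= end ({start} >= {end})")
        if chrom not in layout.lengths:
            raise ValidationError(f"line {lineno}: unknown chromosome {chrom!r}")
        if end > layout.length_of(chrom):
            raise ValidationError(
                f"line {lineno}: interval exceeds length of {chrom}"
            )
        per_chrom.setdefault(chrom, []).append((start, end, value))

    track = CoverageTrack.zeros(name, layout, bin_size)
    for chrom, ivals in per_chrom.items():
        segs = _resolve_overlaps(ivals, chrom)
        track.data[chrom] = _bin_segments(
            segs, layout.length_of(chrom), bin_size
        )
    return track


def _resolve_overlaps(ivals, chrom):
    """Reduce possibly-overlapping intervals to disjoint segments,
    later lines winning on overlap."""
    starts = np.array([i[0] for i in ivals])
    ends = np.array([i[1] for i in ivals])
    order_ok = np.all(starts[1:] >= ends[:-1]) if len(ivals) > 1 else True
    if order_ok:
        return ivals
    logger.warning("overlapping bedGraph intervals on %s: later lines win", chrom)
    # sweep breakpoints; for each elementary segment the last-written
    # interval covering it supplies the value
    points = np.unique(np.concatenate([starts, ends]))
    segs = []
    for s, e in zip(points[:-1], points[1:]):
        cover = [k for k, (a, b, _) in enumerate(ivals) if a <= s and b >= e]
        if cover:
            segs.append((int(s), int(e), ivals[max(cover)][2]))
    return segs


def _bin_segments(segs, chrom_len, bin_size):
    """Integrate disjoint constant segments over bins via the cumulative
    integral of the step function, evaluated at bin edges.

    Bin-aligned segments (the common case for tracks written by this
    package) are assigned directly, which makes read(write(track))
    bit-exact."""
    n_bins = -(-chrom_len // bin_size)
    if all(s % bin_size == 0 and (e % bin_size == 0 or e == chrom_len)
           for s, e, _ in segs):
        out = np.zeros(n_bins)
        for s, e, v in segs:
            out[s // bin_size: -(-e // bin_size)] = v
        return out
    xs = [0.0]
    cum = [0.0]
    for s, e, v in sorted(segs):
        if s > xs[-1]:
            xs.append(float(s))
            cum.append(cum[-1])
        xs.append(float(e))
        cum.append(cum[-1] + v * (e - s))
    edges = np.arange(n_bins + 1, dtype=float) * bin_size
    F = np.interp(edges, xs, cum, right=cum[-1])
    return np.diff(F) / bin_size


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write non-zero runs of equal-valued bins as bedGraph lines."""
    own = not hasattr(path, "write")
    fh = open(path, "w") if own else path
    try:
        for chrom in track.layout.chrom_names:
            v = track.data[chrom]
            if not len(v):
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            clen = track.layout.length_of(chrom)
            for b0, b1 in zip(starts, ends):
                val = v[b0]
                if val == 0:
                    continue
                # shortest round-trip float repr: read-back is bit-exact
                fh.write(
                    f"{chrom}\t{b0 * track.bin_size}"
                    f"\t{min(b1 * track.bin_size, clen)}\t{float(val)!r}\n"
                )
    finally:
        if own:
            fh.close()


def cpm_normalize(track: CoverageTrack, total_mapped: float) -> CoverageTrack:
    """Scale every value by 1e6 / total_mapped (counts per million).

    Fragment-size scaling is folded into ``total_mapped`` by the caller;
    the inputs here are coverage tracks, not reads.
    """
    if total_mapped <= 0:
        raise ValidationError("total_mapped must be > 0")
    if track.normalized:
        raise ValidationError(f"track {track.factor_name!r} already normalized")
    out = track.scaled(1e6 / total_mapped)
    out.total_mapped = total_mapped
    out.normalized = True
    return out


def smooth(values: np.ndarray, bandwidth: float, bin_size: int = 1) -> np.ndarray:
    """Gaussian smoothing with SD = ``bandwidth`` bp, truncated at ±4 SD
    and renormalized at the edges so interior mass is conserved.

    bandwidth 0 returns the input unchanged (a copy).
    """
    if bandwidth < 0:
        raise ValidationError("bandwidth must be >= 0")
    x = np.asarray(values, dtype=float)
    sigma = bandwidth / bin_size
    if sigma < 1e-6 or len(x) == 0:  # kernel narrower than any bin: identity
        return x.copy()
    num = gaussian_filter1d(x, sigma, mode="constant", truncate=4.0)
    den = gaussian_filter1d(np.ones_like(x), sigma, mode="constant", truncate=4.0)
    return num / den
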