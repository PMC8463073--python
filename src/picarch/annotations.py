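"""Genome layout, gene/TSS annotations, and region sets.

All coordinates are 0-based, half-open (BED native). GFF-style 1-based
inputs must be converted on read by the caller; nothing downstream ever
sees 1-based coordinates. For a minus-strand gene the TSS is the last
base of its half-open interval (``end - 1``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_TABLE_COLUMNS = ["gene_id", "chrom", "tss", "tes", "strand", "gene_class"]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Input violates a documented invariant."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be > 0")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class RegionSet:
    """Half-open genomic intervals with an anchor base for alignment.

    The anchor is the TSS for promoter regions and the interval midpoint
    for enhancer-style regions; metagene profiles and occupancy windows
    are all taken relative to it, in the orientation given by ``strand``.
    """

    regions: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ["chrom", "start", "end", "region_id", "anchor", "strand"]

    def __post_init__(self) -> None:
        df = self.regions
        if df.empty:
            object.__setattr__(
                self, "regions", pd.DataFrame(columns=self.COLUMNS)
            )
            return
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"RegionSet missing columns: {missing}")
        if (df["start"] >= df["end"]).any():
            raise ValidationError("regions must satisfy start < end")
        if (df["start"] < 0).any():
            raise ValidationError("negative region start")
        if df["region_id"].duplicated().any():
            dup = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
            raise ValidationError(f"duplicate region_id {dup!r}")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValidationError(
                f"unknown strand symbol {df.loc[bad, 'strand'].iloc[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions.itertuples(index=False))

    @property
    def region_ids(self) -> pd.Index:
        return pd.Index(self.regions["region_id"])

    def subset(self, region_ids) -> "RegionSet":
        ids = pd.Index(region_ids)
        df = self.regions.set_index("region_id", drop=False)
        missing = ids.difference(df.index)
        if len(missing):
            raise ValidationError(f"unknown region ids: {list(missing)[:5]}")
        return RegionSet(df.loc[ids].reset_index(drop=True))

    def to_bed(self, path) -> None:
        out = self.regions[["chrom", "start", "end", "region_id"]].copy()
        out["score"] = 0
        out["strand"] = self.regions["strand"]
        out.to_csv(path, sep="\t", header=False, index=False)


def _validate_gene_table(df: pd.DataFrame) -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id {dup!r}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValidationError(
            f"unknown strand symbol {df.loc[bad, 'strand'].iloc[0]!r}"
        )
    plus = df["strand"] == "+"
    if (df.loc[plus, "tss"] >= df.loc[plus, "tes"]).any():
        raise ValidationError("plus-strand gene with tss >= tes")
    if (df.loc[~plus, "tss"] <= df.loc[~plus, "tes"]).any():
        raise ValidationError("minus-strand gene with tss <= tes")
    return df.reset_index(drop=True)


def read_gene_table(path) -> pd.DataFrame:
    """Read genes from TSV (with header) or BED6 into a gene table.

    The table has columns gene_id, chrom, tss, tes, strand, gene_class.
    BED6 intervals are converted so that the TSS is the first transcribed
    base: ``start`` for plus-strand genes and ``end - 1`` for minus-strand
    genes (the last base of the half-open interval).
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [l for l in text.splitlines()]
    data_lines = [
        (i + 1, l) for i, l in enumerate(lines)
        if l.strip() and not l.startswith(("#", "track", "browser"))
    ]
    if not data_lines:
        return pd.DataFrame(columns=GENE_TABLE_COLUMNS)

    first = data_lines[0][1]
    header_fields = first.split("\t") if "\t" in first else first.split()
    if "gene_id" in header_fields:  # TSV with header
        df = pd.read_csv(io.StringIO(text), sep="\t")
        missing = [c for c in GENE_TABLE_COLUMNS[:5] if c not in df.columns]
        if missing:
            raise ParseError(f"gene TSV missing required columns: {missing}")
        if "gene_class" not in df.columns:
            df["gene_class"] = ""
        df["gene_class"] = df["gene_class"].fillna("").astype(str)
        return _validate_gene_table(df[GENE_TABLE_COLUMNS])

    rows = []
    for lineno, line in data_lines:
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 6:
            raise ParseError(f"line {lineno}: BED6 requires 6 columns, got {len(fields)}")
        chrom, start_s, end_s, name, _score, strand = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinates") from None
        if start < 0 or start >= end:
            raise ParseError(f"line {lineno}: invalid interval {start}-{end}")
        if strand == "+":
            tss, tes = start, end - 1
        elif strand == "-":
            tss, tes = end - 1, start
        else:
            raise ValidationError(f"line {lineno}: unknown strand symbol {strand!r}")
        rows.append((name, chrom, tss, tes, strand, ""))
    return _validate_gene_table(pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS))


def write_gene_table(genes: pd.DataFrame, path) -> None:
    """Write a gene table as TSV; round-trips through read_gene_table."""
    genes[GENE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def genes_to_bed6(genes: pd.DataFrame, path) -> None:
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["tss"], genes["tes"])
    end = np.where(plus, genes["tes"] + 1, genes["tss"] + 1)
    out = pd.DataFrame({
        "chrom": genes["chrom"], "start": start, "end": end,
        "name": genes["gene_id"], "score": 0, "strand": genes["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def promoters_from_genes(
    genes: pd.DataFrame,
    layout: GenomeLayout,
    upstream: int = 500,
    downstream: int = 500,
) -> RegionSet:
    """Promoter windows ``[tss - upstream, tss + downstream]`` in
    transcription orientation, clipped to chromosome bounds; anchor = TSS.
    """
    if upstream < 0 or downstream < 0:
        raise ValidationError("upstream and downstream must be >= 0")
    rows = []
    for g in genes.itertuples(index=False):
        clen = layout.length_of(g.chrom)
        if not (0 <= g.tss < clen):
            raise ValidationError(f"gene {g.gene_id!r} TSS off chromosome {g.chrom}")
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss + downstream
        else:
            start, end = g.tss - downstream, g.tss + upstream
        start = max(0, start)
        end = min(clen, end)
        rows.append((g.chrom, start, end, g.gene_id, g.tss, g.strand))
    return RegionSet(pd.DataFrame(rows, columns=RegionSet.COLUMNS))


def read_bed_regions(path, anchor: str = "midpoint") -> RegionSet:
    """Read a BED file as a RegionSet; anchor = 'midpoint' or 'start'."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"line {lineno}: BED region needs >= 4 columns")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) >= 6 else "+"
            a = (start + end) // 2 if anchor == "midpoint" else start
            rows.append((chrom, start, end, name, a, strand))
    return RegionSet(pd.DataFrame(rows, columns=RegionSet.COLUMNS))
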