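"""Genomic intervals: lengths, gene-model readers, and overlap counting.

Coordinates are 1-based inclusive internally (length = end - start + 1,
matching how array-region lengths are conventionally printed); BED input
and output use the standard 0-based half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start_bp: int
    end_bp: int
    label: str = ""

    def __post_init__(self):
        if self.end_bp < self.start_bp:
            raise ValueError(f"region end {self.end_bp} precedes start "
                             f"{self.start_bp}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self):
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")


def region_length(region: GenomicRegion) -> tuple[int, float]:
    """Length of a region in bp and kb (kb rounded to 3 decimals)."""
    bp = region.length_bp
    return bp, round(bp / 1000.0, 3)


def parse_region(text: str, label: str = "") -> GenomicRegion:
    """Parse "chrom:start-end" (1-based inclusive)."""
    chrom, _, span = text.partition(":")
    start, _, end = span.partition("-")
    return GenomicRegion(chrom, int(start), int(end), label or text)


def read_gene_models(path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene intervals from BED (0-based half-open) or GFF3.

    GFF3 input keeps only ``gene`` features; the format is inferred from
    the file suffix when ``fmt`` is not given.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in {".gff", ".gff3"} else "bed"
    fmt = fmt.lower()
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 3:
                        raise ValueError("BED needs >= 3 columns")
                    chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else f"bed_{lineno}"
                    strand = fields[5] if len(fields) > 5 else "."
                    genes.append(GeneModel(name, chrom, start0 + 1, end0,
                                           strand))
                elif fmt == "gff3":
                    if len(fields) < 9:
                        raise ValueError("GFF3 needs 9 columns")
                    if fields[2] != "gene":
                        continue
                    attrs = dict(kv.partition("=")[::2]
                                 for kv in fields[8].split(";") if kv)
                    gene_id = attrs.get("ID") or attrs.get("gene_id") \
                        or f"gene_{lineno}"
                    genes.append(GeneModel(gene_id, fields[0],
                                           int(fields[3]), int(fields[4]),
                                           fields[6] if fields[6] in "+-"
                                           else "."))
                else:
                    raise ValueError(f"unknown gene-model format {fmt!r}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {fmt} line "
                                 f"({exc})") from exc
    return genes


def genes_in_regions(regions, genes) -> pd.DataFrame:
    """Count genes overlapping each region by >= 1 bp (partly or entirely).

    Strand is ignored; overlap is on the 1-based inclusive intervals.
    Returns one row per region with the gene count and the gene ids.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # interval tree is half-open; +1 makes the inclusive end queryable
        trees.setdefault(str(g.chrom), IntervalTree()).addi(
            g.start_bp, g.end_bp + 1, g.gene_id)
    rows = []
    for r in regions:
        tree = trees.get(str(r.chrom))
        hits = sorted(iv.data for iv in
                      tree.overlap(r.start_bp, r.end_bp + 1)) if tree else []
        rows.append({"label": r.label or f"{r.chrom}:{r.start_bp}-{r.end_bp}",
                     "chrom": str(r.chrom), "start_bp": r.start_bp,
                     "end_bp": r.end_bp, "n_genes": len(hits),
                     "genes": ",".join(hits)})
    return pd.DataFrame(rows)


def write_bed(regions, path) -> None:
    """Export regions as BED (conversion to 0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.label or f"{r.chrom}:{r.start_bp}-{r.end_bp}"
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\n")


def read_bed_regions(path) -> list[GenomicRegion]:
    """Read BED intervals back as 1-based inclusive regions."""
    regions = []
    for g in read_gene_models(path, fmt="bed"):
        regions.append(GenomicRegion(g.chrom, g.start_bp, g.end_bp,
                                     g.gene_id))
    return regions
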