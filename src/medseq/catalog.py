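"""Genome-wide LpnPI site catalogue and annotated region universe.

The catalogue records every occurrence of the recognition motif (both
strands, forward coordinates) and gives each a dense integer ``site_id``;
it is the coordinate backbone every counting and testing stage shares.
Regions are the three annotation classes over which counts are aggregated:
promoter (TSS +/- 1 kb), gene body (1 kb downstream of the TSS to the TES)
and CpG islands.  All internal coordinates are 0-based half-open.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .motif import DEFAULT_MOTIF, find_occurrences, validate_motif

logger = logging.getLogger(__name__)

TSS = "TSS"
GENE_BODY = "gene_body"
CPG_ISLAND = "CpG_island"
REGION_KINDS = (TSS, GENE_BODY, CPG_ISLAND)


class SiteCatalog:
    """Sorted, duplicate-free LpnPI site list with dense integer ids."""

    def __init__(self, records: pd.DataFrame, motif: str = DEFAULT_MOTIF):
        required = {"chrom", "pos", "strand"}
        if not required <= set(records.columns):
            raise ValueError(f"catalog frame needs columns {sorted(required)}")
        df = (
            records[["chrom", "pos", "strand"]]
            .drop_duplicates()
            .sort_values(["chrom", "pos", "strand"], kind="stable")
            .reset_index(drop=True)
        )
        df.insert(0, "site_id", np.arange(len(df)))
        self._df = df
        self.motif = validate_motif(motif)

    def __len__(self) -> int:
        return len(self._df)

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self._df["chrom"]))

    def chrom_slice(self, chrom: str) -> pd.DataFrame:
        return self._df[self._df["chrom"] == chrom]

    def positions(self, chrom: str) -> np.ndarray:
        return self.chrom_slice(chrom)["pos"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self._df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, motif: str = DEFAULT_MOTIF) -> "SiteCatalog":
        return cls(pd.read_csv(path, sep="\t"), motif=motif)


def _read_fasta(genome) -> dict[str, str]:
    """Accept a dict of sequences, a FASTA path, or anything with ``sequences()``."""
    if isinstance(genome, dict):
        return genome
    if hasattr(genome, "sequences"):
        return genome.sequences()
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}


def scan_sites(
    genome,
    motif: str = DEFAULT_MOTIF,
    collapse_cpg: bool = False,
) -> SiteCatalog:
    """Scan a genome for all recognition-site occurrences on both strands.

    Forward-strand matches of the motif and forward-sequence matches of its
    reverse complement (recorded as minus strand) are both reported, at the
    0-based start of the matched window; overlapping occurrences are kept.
    ``collapse_cpg=True`` merges strand-symmetric occurrences at the same
    position into a single plus-strand record (palindromic instances such as
    CCGG otherwise yield one site per strand).
    """
    motif = validate_motif(motif)
    sequences = _read_fasta(genome)
    rows: list[tuple[str, int, str]] = []
    for chrom, seq in sequences.items():
        rows.extend((chrom, pos, strand) for pos, strand in find_occurrences(seq, motif))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    if collapse_cpg and len(df):
        df = df.sort_values(["chrom", "pos", "strand"]).drop_duplicates(["chrom", "pos"])
    return SiteCatalog(df, motif=motif)


# ---------------------------------------------------------------------------
# Regions


@dataclass(frozen=True)
class Region:
    """One annotation interval (0-based half-open)."""

    region_id: int
    chrom: str
    start: int
    end: int
    kind: str
    gene_id: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


class RegionSet:
    """Region list with a per-chromosome interval index for point/interval queries."""

    def __init__(self, regions: list[Region]):
        self.regions = list(regions)
        self._trees: dict[str, IntervalTree] = {}
        for r in self.regions:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def at(self, chrom: str, pos: int) -> list[Region]:
        """Regions containing a point (half-open membership)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda r: r.region_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Region]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)), key=lambda r: r.region_id)

    def by_id(self, region_id: int) -> Region:
        return self.regions[region_id]

    def of_kind(self, kind: str) -> list[Region]:
        return [r for r in self.regions if r.kind == kind]

    def gene_ids(self) -> list[str]:
        return sorted({r.gene_id for r in self.regions if r.gene_id})

    def to_bed(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for r in self.regions:
                name = f"{r.kind}:{r.gene_id}" if r.gene_id else r.kind
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


def _read_gene_table(genes) -> pd.DataFrame:
    """Gene spans as a frame with chrom/start/end/gene_id/strand.

    Accepts a DataFrame, a BED6 path, or a GTF path (gene/transcript features;
    1-based closed coordinates converted to 0-based half-open).
    """
    if isinstance(genes, pd.DataFrame):
        df = genes.copy()
    else:
        path = Path(genes)
        if path.suffix.lower() in {".gtf", ".gff"}:
            df = _read_gtf_genes(path)
        else:
            df = pd.read_csv(
                path, sep="\t", header=None, comment="#",
                names=["chrom", "start", "end", "gene_id", "score", "strand"],
                usecols=range(6),
            )
    required = {"chrom", "start", "end", "gene_id", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    valid_strand = df["strand"].isin(["+", "-"])
    if not valid_strand.all():
        bad = df.index[~valid_strand][0]
        raise ValueError(f"gene record {bad} lacks a +/- strand")
    return df


def _read_gtf_genes(path: Path) -> pd.DataFrame:
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line ({len(fields)} fields)")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature not in {"gene", "transcript"}:
                continue
            import re

            m = re.search(r'gene_id "([^"]+)"', attrs)
            if not m:
                raise ValueError(f"{path}:{lineno}: no gene_id attribute")
            # GTF is 1-based closed; convert to 0-based half-open.
            rows.append((chrom, int(start) - 1, int(end), m.group(1), strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])
    # prefer explicit gene features when present
    return df


def _read_bed_intervals(bed) -> pd.DataFrame:
    if isinstance(bed, pd.DataFrame):
        return bed.copy()
    return pd.read_csv(
        bed, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=range(3),
    )


def build_regions(
    genes,
    cpg_islands=None,
    tss_flank: int = 1000,
    chrom_lengths: dict[str, int] | None = None,
) -> RegionSet:
    """Construct the promoter / gene-body / CpG-island region universe.

    For a plus-strand gene spanning ``[s, e)`` the promoter (TSS) region is
    ``[s - tss_flank, s + tss_flank)`` and the gene body ``[s + tss_flank, e)``;
    minus-strand genes mirror this around ``e``.  Genes whose body would be
    empty are kept with their promoter only (the degenerate body is dropped
    with a warning).  Multiple records per gene_id are collapsed to the union
    span before region construction.  TSS regions are clipped to chromosome
    bounds when ``chrom_lengths`` is given, and to 0 otherwise.
    """
    df = _read_gene_table(genes)
    collapsed = (
        df.groupby("gene_id", sort=True)
        .agg(chrom=("chrom", "first"), start=("start", "min"),
             end=("end", "max"), strand=("strand", "first"))
        .reset_index()
    )
    regions: list[Region] = []

    def clip(chrom: str, lo: int, hi: int) -> tuple[int, int]:
        lo = max(lo, 0)
        if chrom_lengths and chrom in chrom_lengths:
            hi = min(hi, chrom_lengths[chrom])
        return lo, hi

    for row in collapsed.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        if row.strand == "+":
            tss_lo, tss_hi = clip(row.chrom, s - tss_flank, s + tss_flank)
            body_lo, body_hi = s + tss_flank, e
        else:
            tss_lo, tss_hi = clip(row.chrom, e - tss_flank, e + tss_flank)
            body_lo, body_hi = s, e - tss_flank
        regions.append(Region(len(regions), row.chrom, tss_lo, tss_hi, TSS,
                              row.gene_id, row.strand))
        if body_hi > body_lo:
            regions.append(Region(len(regions), row.chrom, body_lo, body_hi, GENE_BODY,
                                  row.gene_id, row.strand))
        else:
            logger.warning("gene %s shorter than tss_flank: gene body dropped", row.gene_id)

    if cpg_islands is not None:
        for row in _read_bed_intervals(cpg_islands).itertuples(index=False):
            regions.append(Region(len(regions), row.chrom, int(row.start), int(row.end),
                                  CPG_ISLAND))
    return RegionSet(regions)


def assign_sites(catalog: SiteCatalog, regions: RegionSet) -> dict[int, list[int]]:
    """Map every site_id to the region_ids containing its motif start.

    The map is total: sites contained in no region map to an empty list.  A
    site may belong to several regions (e.g. a CpG island inside a promoter).
    """
    region_chroms = {r.chrom for r in regions}
    mapping: dict[int, list[int]] = {}
    for row in catalog.frame().itertuples(index=False):
        if row.chrom not in region_chroms:
            mapping.setdefault(row.site_id, [])
            continue
        mapping[row.site_id] = [r.region_id for r in regions.at(row.chrom, row.pos)]
    unseen = region_chroms - set(catalog.chroms)
    if unseen:
        logger.warning("regions on chromosomes without catalogued sites: %s", sorted(unseen))
    return mapping
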