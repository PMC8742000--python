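"""FASTQ/SAM to per-site counts: adapter trimming, position filter, counting.

The defining MeD-seq step is the position filter: a read is kept only when a
recognition-site occurrence sits 13-17 bp from the 5' or 3' end, the geometry
LpnPI digestion imposes on genuine fragments.  Offsets are measured to the
motif start (5' side) and motif end (3' side), inclusive bounds.

Alignment is deliberately simple: an exact-match mapper sufficient for
synthetic genomes, plus SAM/BAM ingestion for externally aligned real data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .catalog import SiteCatalog, _read_fasta
from .matrix import SiteCountMatrix
from .motif import motif_regex, reverse_complement, validate_motif
from .simulate import ReadRecord

logger = logging.getLogger(__name__)

MIN_OFFSET = 13
MAX_OFFSET = 17


def trim_adapter(read: ReadRecord, adapter: str, min_overlap: int = 3) -> ReadRecord:
    """Remove the longest 3' suffix of the read matching a prefix of the adapter.

    Only exact overlaps of at least ``min_overlap`` bases are removed;
    qualities are trimmed in lockstep.  Reads without an adapter suffix pass
    through unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty when trimming is enabled")
    adapter = adapter.upper()
    seq = read.sequence.upper()
    best = len(seq)
    max_ov = min(len(seq), len(adapter))
    for ov in range(max_ov, min_overlap - 1, -1):
        if seq.endswith(adapter[:ov]):
            best = len(seq) - ov
            break
    if best == len(seq):
        return read
    return ReadRecord(read.id, read.sequence[:best], read.qualities[:best])


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    offset: int | None = None      # motif start within the read (smallest qualifying)
    end: str | None = None         # which end qualified: "5p" or "3p"


def _site_offsets(interval_len: int, motif_start: int, motif_len: int) -> tuple[int, int]:
    """(d5, d3): bases strictly before the motif start / after the motif end."""
    return motif_start, interval_len - (motif_start + motif_len)


def position_filter(
    read: ReadRecord | str,
    motif: str = "CCDG",
    min_offset: int = MIN_OFFSET,
    max_offset: int = MAX_OFFSET,
) -> FilterResult:
    """PASS iff a motif occurrence (either orientation) lies ``min..max`` bp from an end.

    For an occurrence at read positions ``[s, s+m)``: the 5' distance is ``s``
    and the 3' distance ``len(read) - (s+m)``; either falling inside the
    inclusive band qualifies.  On ties the occurrence with the smallest ``s``
    is recorded.
    """
    seq = (read if isinstance(read, str) else read.sequence).upper()
    if not seq:
        return FilterResult(False)
    motif = validate_motif(motif)
    m = len(motif)
    occurrences = sorted(
        {mt.start() for mt in motif_regex(motif).finditer(seq)}
        | {mt.start() for mt in motif_regex(reverse_complement(motif)).finditer(seq)}
    )
    for s in occurrences:
        d5, d3 = _site_offsets(len(seq), s, m)
        if min_offset <= d5 <= max_offset:
            return FilterResult(True, s, "5p")
        if min_offset <= d3 <= max_offset:
            return FilterResult(True, s, "3p")
    return FilterResult(False)


@dataclass
class SampleQC:
    """Per-sample processing tallies (reads in, trimmed, passing, assigned)."""

    reads_in: int = 0
    trimmed: int = 0
    passed_filter: int = 0
    assigned: int = 0
    unassigned: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


class _ExactMapper:
    """Exact-match lookup of read sequences against a small genome, both strands."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self._cache: dict[str, list[tuple[str, int, int]]] = {}

    def locate(self, seq: str) -> list[tuple[str, int, int]]:
        """All (chrom, start, end) intervals matching the read exactly."""
        seq = seq.upper()
        hit = self._cache.get(seq)
        if hit is not None:
            return hit
        out: list[tuple[str, int, int]] = []
        for query in {seq, reverse_complement(seq)}:
            for chrom, ref in self.sequences.items():
                i = ref.find(query)
                while i != -1:
                    out.append((chrom, i, i + len(query)))
                    i = ref.find(query, i + 1)
        out = sorted(set(out))
        self._cache[seq] = out
        return out


def _sites_in_interval(
    catalog_positions: np.ndarray,
    start: int,
    end: int,
    motif_len: int,
    min_offset: int,
    max_offset: int,
) -> np.ndarray:
    """Indices (into the per-chromosome position array) of sites whose motif lies
    ``min..max`` bp from either end of ``[start, end)``."""
    lo, hi = np.searchsorted(catalog_positions, [start, end])
    idx = np.arange(lo, hi)
    if len(idx) == 0:
        return idx
    d5 = catalog_positions[idx] - start
    d3 = end - (catalog_positions[idx] + motif_len)
    keep = ((d5 >= min_offset) & (d5 <= max_offset)) | ((d3 >= min_offset) & (d3 <= max_offset))
    return idx[keep]


def assign_and_count(
    reads_by_sample: dict[str, list[ReadRecord]],
    catalog: SiteCatalog,
    genome,
    groups: dict[str, str] | None = None,
    adapter: str = "",
    min_offset: int = MIN_OFFSET,
    max_offset: int = MAX_OFFSET,
    fractional: bool = False,
) -> tuple[SiteCountMatrix, dict[str, SampleQC]]:
    """Trim, filter, exact-match map and count reads into a site matrix.

    Every catalogued site whose motif lies ``min..max`` bp from either end of
    a matched interval receives one count per matching location (multi-mapper
    convention; ``fractional=True`` weights each location 1/n and rounds the
    final matrix).  Reads matching no location are tallied as unassigned.
    """
    sequences = _read_fasta(genome)
    mapper = _ExactMapper(sequences)
    cat = catalog.frame()
    positions_by_chrom = {c: g["pos"].to_numpy() for c, g in cat.groupby("chrom")}
    first_id = {c: int(g["site_id"].iloc[0]) for c, g in cat.groupby("chrom")}
    mlen = catalog.motif_length

    samples = list(reads_by_sample)
    acc = np.zeros((len(catalog), len(samples)), dtype=float)
    totals: dict[str, int] = {}
    qc: dict[str, SampleQC] = {}

    for col, sample in enumerate(samples):
        tally = SampleQC()
        n_pass = 0
        for read in reads_by_sample[sample]:
            tally.reads_in += 1
            if adapter:
                trimmed = trim_adapter(read, adapter)
                if len(trimmed.sequence) != len(read.sequence):
                    tally.trimmed += 1
                read = trimmed
            if not read.sequence:
                continue
            if not position_filter(read, catalog.motif, min_offset, max_offset).passed:
                continue
            tally.passed_filter += 1
            n_pass += 1
            locations = mapper.locate(read.sequence)
            hit_any = False
            weight = 1.0 / len(locations) if (fractional and locations) else 1.0
            for chrom, start, end in locations:
                pos = positions_by_chrom.get(chrom)
                if pos is None:
                    continue
                idx = _sites_in_interval(pos, start, end, mlen, min_offset, max_offset)
                for i in idx:
                    acc[first_id[chrom] + int(i), col] += weight
                    hit_any = True
            if hit_any:
                tally.assigned += 1
            else:
                tally.unassigned += 1
        totals[sample] = n_pass
        qc[sample] = tally

    counts = np.rint(acc).astype(np.int64) if fractional else acc.astype(np.int64)
    matrix = SiteCountMatrix(
        site_ids=cat["site_id"].to_numpy(),
        samples=samples,
        counts=counts,
        totals=totals,
        groups=dict(groups) if groups else {s: s for s in samples},
    )
    return matrix, qc


def ingest_alignments(
    alignments_by_sample: dict[str, str | Path],
    catalog: SiteCatalog,
    groups: dict[str, str] | None = None,
    min_offset: int = MIN_OFFSET,
    max_offset: int = MAX_OFFSET,
) -> SiteCountMatrix:
    """Count pre-aligned SAM/BAM records into a site matrix.

    Each mapped, non-supplementary record contributes to every site whose
    motif lies ``min..max`` bp from either end of its reference interval;
    secondary alignments are included (multi-mapper convention).  Records on
    references absent from the catalogue are skipped with a warning.
    """
    import pysam

    cat = catalog.frame()
    positions_by_chrom = {c: g["pos"].to_numpy() for c, g in cat.groupby("chrom")}
    first_id = {c: int(g["site_id"].iloc[0]) for c, g in cat.groupby("chrom")}
    mlen = catalog.motif_length

    samples = list(alignments_by_sample)
    counts = np.zeros((len(catalog), len(samples)), dtype=np.int64)
    totals: dict[str, int] = {}
    warned: set[str] = set()

    for col, sample in enumerate(samples):
        n_records = 0
        with pysam.AlignmentFile(str(alignments_by_sample[sample]), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_supplementary:
                    continue
                if not rec.is_secondary:
                    n_records += 1
                chrom = rec.reference_name
                pos = positions_by_chrom.get(chrom)
                if pos is None:
                    if chrom not in warned:
                        logger.warning("reference %s absent from catalogue; records skipped", chrom)
                        warned.add(chrom)
                    continue
                idx = _sites_in_interval(
                    pos, rec.reference_start, rec.reference_end, mlen, min_offset, max_offset
                )
                for i in idx:
                    counts[first_id[chrom] + int(i), col] += 1
        totals[sample] = n_records
    return SiteCountMatrix(
        site_ids=cat["site_id"].to_numpy(),
        samples=samples,
        counts=counts,
        totals=totals,
        groups=dict(groups) if groups else {s: s for s in samples},
    )
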