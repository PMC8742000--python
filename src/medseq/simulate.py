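"""Synthetic MeD-seq data: toy genomes, planted methylomes, digest reads and counts.

Every input the pipeline consumes can be generated here with a machine-readable
truth manifest, so the whole analysis is testable without patient data.  The
generator emulates the assay geometry: LpnPI cleaves only methylated
recognition sites and releases ~32 bp fragments with the site 13-17 bp from a
fragment end; per-site methylation probability doubles as fragment-emission
probability (hemi-methylation is not modelled).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import GENE_BODY, TSS, RegionSet, SiteCatalog
from .motif import DEFAULT_MOTIF, find_occurrences, motif_regex, reverse_complement

FRAGMENT_LENGTH = 32           # bp released around a methylated site
OFFSET_MIN = 13                # closest allowed motif-to-end distance
OFFSET_MAX = 17                # farthest allowed motif-to-end distance


@dataclass
class ReadRecord:
    """One FASTQ record (Phred+33 qualities)."""

    id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")


@dataclass
class GenomeFixture:
    """Toy genome plus the recognition-site positions planted in it."""

    chromosomes: list[tuple[str, str]]
    site_positions: list[tuple[str, int, str]]   # (chrom, motif start, strand)
    motif: str = DEFAULT_MOTIF

    def sequences(self) -> dict[str, str]:
        return dict(self.chromosomes)

    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    def to_catalog(self) -> SiteCatalog:
        df = pd.DataFrame(self.site_positions, columns=["chrom", "pos", "strand"])
        return SiteCatalog(df, motif=self.motif)

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with Path(path).open("w") as fh:
            for name, seq in self.chromosomes:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


@dataclass
class PlantedDmr:
    chrom: str
    start: int
    end: int            # half-open, last motif start + motif length
    group: str
    direction: str      # hyper | hypo, w.r.t. the affected group
    fold_change: float
    site_ids: list[int] = field(default_factory=list)


@dataclass
class MethylationProfile:
    """Per-site methylation probability per group, with planted ground truth."""

    groups: dict[str, np.ndarray]        # group -> probability per site
    planted_dmrs: list[PlantedDmr]
    baseline: float

    def __post_init__(self) -> None:
        for g, p in self.groups.items():
            p = np.asarray(p, dtype=float)
            if ((p < 0) | (p > 1)).any():
                raise ValueError(f"group {g}: probabilities outside [0, 1]")
            self.groups[g] = p

    def group_names(self) -> list[str]:
        return list(self.groups)

    def probabilities(self, group: str) -> np.ndarray:
        if group not in self.groups:
            raise KeyError(f"unknown group/sample {group!r}")
        return self.groups[group]


@dataclass
class TruthManifest:
    """Machine-readable ground truth written beside every generated fixture."""

    seed: int
    planted_dmrs: list[PlantedDmr] = field(default_factory=list)
    planted_de_genes: list[dict] = field(default_factory=list)
    library_sizes: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted_dmrs": [asdict(d) for d in self.planted_dmrs],
            "planted_de_genes": self.planted_de_genes,
            "library_sizes": self.library_sizes,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        raw = json.loads(Path(path).read_text())
        return cls(
            seed=raw["seed"],
            planted_dmrs=[PlantedDmr(**d) for d in raw["planted_dmrs"]],
            planted_de_genes=raw["planted_de_genes"],
            library_sizes=raw["library_sizes"],
        )


# ---------------------------------------------------------------------------
# Genome generation

_EDGE_MARGIN = 50   # keep sites clear of chromosome ends so any fragment fits


def _motif_free(rng: np.random.Generator, n: int, motif: str) -> str:
    """Random sequence of length n guaranteed free of the motif on both strands."""
    if n <= 0:
        return ""
    seq = list(rng.choice(list("ACGT"), size=n))
    fwd = motif_regex(motif)
    rev = motif_regex(reverse_complement(motif))
    for _ in range(200):
        text = "".join(seq)
        hits = [m.start() for m in fwd.finditer(text)]
        hits += [m.start() for m in rev.finditer(text)]
        if not hits:
            return text
        for h in set(hits):
            seq[h] = str(rng.choice(list("AT")))
    raise RuntimeError("could not generate motif-free spacer")   # pragma: no cover


def generate_toy_genome(
    n_chrom: int,
    chrom_length: int,
    target_site_spacing: int,
    seed: int,
    motif: str = DEFAULT_MOTIF,
) -> GenomeFixture:
    """Generate a toy genome with recognition sites at a controlled density.

    Sites are planted at gaps drawn uniformly from 0.5-1.5x the target
    spacing into a motif-free background, each instance flanked by a TTT pad
    that provably cannot combine with neighbouring bases into a spurious
    occurrence.  Planted instances use D in {A, T} so no palindromic
    double-strand records arise and a full rescan reproduces the site list
    exactly.  Deterministic given the seed.
    """
    if n_chrom <= 0:
        raise ValueError("n_chrom must be positive")
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    if target_site_spacing < 50:
        raise ValueError("target_site_spacing must be >= 50")

    rng = np.random.default_rng(seed)
    mlen = len(motif)
    chromosomes: list[tuple[str, str]] = []
    site_positions: list[tuple[str, int, str]] = []

    for c in range(n_chrom):
        name = f"chr{c + 1}"
        parts: list[str] = []
        pos = 0
        pending_gap = _EDGE_MARGIN
        sites_here: list[tuple[int, str]] = []
        while True:
            gap = max(int(pending_gap), 8)
            next_site = pos + gap + 3            # 3 bp TTT pad before the motif
            if next_site + mlen + 3 + _EDGE_MARGIN > chrom_length:
                break
            parts.append(_motif_free(rng, gap, motif))
            parts.append("TTT")
            d = str(rng.choice(list("AT")))       # D in {A,T}: non-palindromic
            instance = motif.replace("D", d)
            strand = "+"
            if rng.random() < 0.5:
                instance = reverse_complement(instance)
                strand = "-"
            parts.append(instance)
            parts.append("TTT")
            sites_here.append((next_site, strand))
            pos = next_site + mlen + 3
            pending_gap = rng.uniform(0.5, 1.5) * target_site_spacing - 6 - mlen
        parts.append(_motif_free(rng, chrom_length - pos, motif))
        seq = "".join(parts)
        assert len(seq) == chrom_length
        chromosomes.append((name, seq))
        site_positions.extend((name, p, s) for p, s in sites_here)

    fixture = GenomeFixture(chromosomes, site_positions, motif=motif)
    # paranoia: the planted list must equal a fresh scan
    for chrom, seq in fixture.chromosomes:
        expected = [(p, s) for c2, p, s in fixture.site_positions if c2 == chrom]
        assert find_occurrences(seq, motif) == expected
    return fixture


# ---------------------------------------------------------------------------
# Methylation profiles

def plant_methylation(
    fixture: GenomeFixture,
    groups: list[str],
    n_dmrs: int,
    dmr_sites: int = 12,
    effect_fc: float = 4.0,
    baseline: float = 0.1,
    seed: int = 0,
    min_span_bp: int = 100,
    min_gap_bp: int = 2000,
    affected_groups: list[str] | None = None,
) -> MethylationProfile:
    """Plant disjoint DMRs of known direction into a flat baseline methylome.

    Each planted DMR covers ``dmr_sites`` consecutive catalogue sites spanning
    at least ``min_span_bp``; directions alternate hyper/hypo and the affected
    group cycles through ``groups``.  Inside a hyper DMR the affected group's
    site probability is ``baseline * effect_fc``; inside a hypo DMR it is
    ``baseline / effect_fc``; everywhere else every group sits at baseline.
    Planted DMRs are separated by at least ``min_gap_bp`` (kept above the
    detector's window distance) so each detected region maps to one truth unit.
    ``affected_groups`` restricts which groups receive DMRs (default: all).
    """
    if effect_fc <= 1:
        raise ValueError("effect_fc must exceed 1")
    if dmr_sites < 10:
        raise ValueError("dmr_sites must be >= 10 so planted DMRs are detectable")
    if not 0 < baseline < 1:
        raise ValueError("baseline must be in (0, 1)")
    if baseline * effect_fc > 1:
        raise ValueError("baseline * effect_fc exceeds 1: hyper DMRs unrepresentable")
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    catalog = fixture.to_catalog().frame()
    n_sites = len(catalog)
    rng = np.random.default_rng(seed)

    # candidate start indices: runs of dmr_sites sites on one chromosome
    starts: list[int] = []
    used = np.zeros(n_sites, dtype=bool)
    order = rng.permutation(n_sites - dmr_sites + 1) if n_sites >= dmr_sites else []
    chroms = catalog["chrom"].to_numpy()
    positions = catalog["pos"].to_numpy()
    mlen = len(fixture.motif)
    for i in order:
        j = i + dmr_sites
        if chroms[i] != chroms[j - 1]:
            continue
        if used[i:j].any():
            continue
        if positions[j - 1] + mlen - positions[i] < min_span_bp:
            continue
        starts.append(i)
        # block the run plus a buffer of min_gap_bp on both sides
        same = chroms == chroms[i]
        buffered = same & (positions >= positions[i] - min_gap_bp) \
                        & (positions <= positions[j - 1] + mlen + min_gap_bp)
        used |= buffered
        if len(starts) == n_dmrs:
            break
    if len(starts) < n_dmrs:
        raise ValueError(
            f"catalogue has room for only {len(starts)} of {n_dmrs} disjoint DMRs"
        )
    starts.sort()

    probs = {g: np.full(n_sites, baseline) for g in groups}
    planted: list[PlantedDmr] = []
    cycle = list(affected_groups) if affected_groups else list(groups)
    if not set(cycle) <= set(groups):
        raise ValueError("affected_groups must be a subset of groups")
    for k, i in enumerate(starts):
        j = i + dmr_sites
        group = cycle[k % len(cycle)]
        # alternate per cycle of groups so direction stays balanced within
        # every group (a group-direction correlation would skew each group's
        # emission normalisation and shrink realised fold changes)
        direction = "hyper" if (k // len(cycle)) % 2 == 0 else "hypo"
        level = baseline * effect_fc if direction == "hyper" else baseline / effect_fc
        probs[group][i:j] = level
        planted.append(
            PlantedDmr(
                chrom=str(chroms[i]),
                start=int(positions[i]),
                end=int(positions[j - 1]) + mlen,
                group=group,
                direction=direction,
                fold_change=effect_fc,
                site_ids=list(range(i, j)),
            )
        )
    return MethylationProfile(groups=probs, planted_dmrs=planted, baseline=baseline)


# ---------------------------------------------------------------------------
# Count-level simulation

def simulate_count_matrix(
    profile: MethylationProfile,
    samples_per_group: int,
    mean_library_size: int,
    dispersion: float = 0.0,
    seed: int = 0,
    library_sigma: float = 0.1,
):
    """Draw a per-site count matrix from a methylation profile.

    Per sample, a library size L is drawn lognormally around the group mean
    (``library_sigma`` on the log scale; 0 fixes L exactly); the per-site
    expectation is ``L * p_i / sum(p)``.  Counts are Poisson when
    ``dispersion == 0`` and negative binomial with variance
    ``mu + dispersion * mu^2`` otherwise.
    """
    from .matrix import SiteCountMatrix

    if samples_per_group < 2:
        raise ValueError("samples_per_group must be >= 2")
    if mean_library_size < 10_000:
        raise ValueError("mean_library_size must be >= 10000")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")

    rng = np.random.default_rng(seed)
    samples: list[str] = []
    groups: dict[str, str] = {}
    columns: list[np.ndarray] = []
    totals: dict[str, int] = {}
    drawn: dict[str, int] = {}
    for g in profile.group_names():
        p = profile.probabilities(g)
        rates = p / p.sum()
        for r in range(samples_per_group):
            name = f"{g}_{r + 1}"
            lib = int(mean_library_size * rng.lognormal(0.0, library_sigma)) \
                if library_sigma > 0 else int(mean_library_size)
            mu = lib * rates
            if dispersion == 0:
                col = rng.poisson(mu)
            else:
                # NB2: variance mu + dispersion mu^2; gamma-Poisson mixture
                shape = 1.0 / dispersion
                col = rng.poisson(rng.gamma(shape, mu * dispersion))
            samples.append(name)
            groups[name] = g
            columns.append(col.astype(np.int64))
            totals[name] = int(col.sum())
            drawn[name] = lib
    counts = np.column_stack(columns)
    matrix = SiteCountMatrix(
        site_ids=np.arange(counts.shape[0]),
        samples=samples,
        counts=counts,
        totals=totals,
        groups=groups,
    )
    matrix.drawn_library_sizes = drawn
    return matrix


# ---------------------------------------------------------------------------
# Digest-read simulation

def simulate_digest_reads(
    fixture: GenomeFixture,
    profile: MethylationProfile,
    sample: str,
    n_reads: int,
    read_length: int = 50,
    adapter: str = "",
    seed: int = 0,
    group: str | None = None,
) -> tuple[list[ReadRecord], np.ndarray]:
    """Simulate single-end digest reads for one sample.

    Each read derives from a 32 bp fragment containing exactly one sampled
    site, the motif placed uniformly over the offsets that leave it 13-17 bp
    from at least one fragment end; fragment orientation is random.  When an
    adapter is given and ``read_length`` exceeds 32, the 3' end is padded with
    adapter sequence up to ``read_length``.  Returns the reads plus per-site
    truth counts (summing to ``n_reads``).  Byte-identical given the seed.
    """
    if read_length < FRAGMENT_LENGTH:
        raise ValueError(f"read_length must be >= {FRAGMENT_LENGTH}")
    p = profile.probabilities(group if group is not None else sample)

    catalog = fixture.to_catalog().frame()
    if len(catalog) != len(p):
        raise ValueError("profile does not match fixture site count")
    sequences = fixture.sequences()
    mlen = len(fixture.motif)
    rng = np.random.default_rng(seed)

    truth = np.zeros(len(catalog), dtype=np.int64)
    reads: list[ReadRecord] = []
    if n_reads == 0 or p.sum() == 0:
        return reads, truth

    chroms = catalog["chrom"].to_numpy()
    positions = catalog["pos"].to_numpy()
    # exclude sites whose fragment would overrun a chromosome end
    lengths = fixture.chrom_lengths()
    lo_off = FRAGMENT_LENGTH - mlen - OFFSET_MAX          # smallest allowed d5
    hi_off = OFFSET_MAX                                   # largest allowed d5
    eligible = np.array(
        [positions[i] - hi_off >= 0
         and positions[i] - lo_off + FRAGMENT_LENGTH <= lengths[chroms[i]]
         for i in range(len(catalog))]
    )
    weights = np.where(eligible, p, 0.0)
    weights = weights / weights.sum()

    site_idx = rng.choice(len(catalog), size=n_reads, p=weights)
    d5s = rng.integers(lo_off, hi_off + 1, size=n_reads)
    flips = rng.random(n_reads) < 0.5
    pad = ""
    if adapter and read_length > FRAGMENT_LENGTH:
        needed = read_length - FRAGMENT_LENGTH
        if len(adapter) < needed:
            raise ValueError(
                f"adapter ({len(adapter)} bp) shorter than the 3' fill "
                f"({needed} bp); suffix-prefix trimming could not recover the insert"
            )
        pad = adapter.upper()[:needed]

    for k in range(n_reads):
        i = int(site_idx[k])
        truth[i] += 1
        chrom, pos = chroms[i], int(positions[i])
        start = pos - int(d5s[k])
        frag = sequences[chrom][start:start + FRAGMENT_LENGTH]
        if flips[k]:
            frag = reverse_complement(frag)
        seq = frag + pad
        reads.append(ReadRecord(
            id=f"{sample}:read{k}:{chrom}:{pos}",
            sequence=seq,
            qualities="I" * len(seq),
        ))
    return reads, truth


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(id=rec.id, sequence=str(rec.seq), qualities=quals))
    return out


# ---------------------------------------------------------------------------
# Expression tables

_EXPECTED_DE_SIGN = {            # (direction, region kind) -> expected expression sign
    ("hyper", TSS): -1,
    ("hypo", TSS): +1,
    ("hyper", GENE_BODY): +1,
    ("hypo", GENE_BODY): -1,
}


def generate_expression_table(
    region_set: RegionSet,
    manifest: TruthManifest,
    concordant_fraction: float,
    de_lfc: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a per-gene log2FC/FDR table tied to the planted DMRs.

    For the stated fraction of genes whose promoter or gene body overlaps a
    planted DMR, assign a differential-expression call whose sign follows the
    methylation-expression concordance rule (hyper promoter -> down, hypo
    promoter -> up, hyper body -> up, hypo body -> down) with FDR < 0.05;
    every other gene gets small null log2FC noise and FDR >= 0.05.  Planted
    DE genes are recorded in the manifest.
    """
    if not 0 <= concordant_fraction <= 1:
        raise ValueError("concordant_fraction must be in [0, 1]")
    if de_lfc < 1.5:
        raise ValueError("de_lfc must be >= 1.5 to clear the DE threshold")
    genes = region_set.gene_ids()
    if not genes:
        raise ValueError("region set contains no genes")

    rng = np.random.default_rng(seed)

    # expected sign per gene overlapping a planted DMR (promoter rule wins ties)
    expected_sign: dict[str, int] = {}
    for dmr in manifest.planted_dmrs:
        hits = region_set.overlapping(dmr.chrom, dmr.start, dmr.end)
        by_gene: dict[str, set[str]] = {}
        for r in hits:
            if r.gene_id:
                by_gene.setdefault(r.gene_id, set()).add(r.kind)
        for gene, kinds in by_gene.items():
            kind = TSS if TSS in kinds else GENE_BODY if GENE_BODY in kinds else None
            if kind is None:
                continue
            expected_sign.setdefault(gene, _EXPECTED_DE_SIGN[(dmr.direction, kind)])

    overlapping = sorted(expected_sign)
    n_conc = int(round(concordant_fraction * len(overlapping)))
    concordant = set(rng.permutation(overlapping)[:n_conc]) if overlapping else set()

    rows = []
    for gene in genes:
        if gene in concordant:
            lfc = expected_sign[gene] * (de_lfc + abs(rng.normal(0, 0.3)))
            fdr = float(rng.uniform(1e-6, 0.04))
            manifest.planted_de_genes.append(
                {"gene_id": gene, "log2fc": float(lfc), "fdr": fdr}
            )
        else:
            lfc = float(np.clip(rng.normal(0, 0.3), -1.4, 1.4))
            fdr = float(rng.uniform(0.05, 1.0))
        rows.append((gene, float(lfc), float(fdr)))
    return pd.DataFrame(rows, columns=["gene_id", "log2FC", "FDR"])
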