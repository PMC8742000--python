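"""Chi-squared differential-methylation testing and sliding-window DMR detection.

Counts are pooled across samples within each group and every site (or region)
is tested with a Pearson chi-squared on the 2x2 table

    [[reads in site, other reads in group A],
     [reads in site, other reads in group B]]

against the pooled group totals.  Fold changes are computed on the RPM scale
with a small pseudocount so library-size differences between groups cancel.
A DMR is a run of significantly, concordantly changed sites found by a
sliding window: from each significant seed site, up to ``max_neighbors``
catalogue sites on each side and within ``max_distance_bp`` of the seed are
collected; candidates with at least ``min_sites`` significant sites spanning
at least ``min_span_bp`` are kept and overlapping candidates merged.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist
from statsmodels.stats.multitest import multipletests

from .catalog import RegionSet, SiteCatalog
from .matrix import SiteCountMatrix

HYPER = "hyper"
HYPO = "hypo"


@dataclass(frozen=True)
class DmrConfig:
    """Detection thresholds; defaults follow the published pipeline settings."""

    alpha: float = 0.05
    correction: str = "bonferroni"        # bonferroni | bh
    fc_threshold: float = 2.0             # 5.0 for the clustering configuration
    min_sites: int = 10
    min_span_bp: int = 100
    max_neighbors: int = 50
    max_distance_bp: int = 1000
    pseudocount: float = 0.5              # RPM units

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if self.min_sites < 1 or self.min_span_bp < 1:
            raise ValueError("min_sites and min_span_bp must be >= 1")
        if self.correction not in {"bonferroni", "bh"}:
            raise ValueError("correction must be 'bonferroni' or 'bh'")


@dataclass
class GroupContrast:
    """A two-group comparison, e.g. one mutation group versus the pooled rest."""

    name: str
    samples_a: list[str]
    samples_b: list[str]

    def __post_init__(self) -> None:
        if set(self.samples_a) & set(self.samples_b):
            raise ValueError(f"contrast {self.name}: groups share samples")
        if not self.samples_a or not self.samples_b:
            raise ValueError(f"contrast {self.name}: empty group")


def one_vs_rest_contrasts(groups: dict[str, str]) -> list[GroupContrast]:
    """Build a one-vs-rest contrast per group label (A = the group, B = all others)."""
    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        raise ValueError("need at least two group labels")
    out = []
    for g in labels:
        a = [s for s, lab in groups.items() if lab == g]
        b = [s for s, lab in groups.items() if lab != g]
        out.append(GroupContrast(f"{g}_vs_rest", a, b))
    return out


@dataclass
class DMR:
    """A detected differentially methylated region."""

    chrom: str
    start: int
    end: int                       # half-open; last member motif start + motif length
    site_ids: list[int]            # all catalogue sites inside the span
    n_significant_sites: int
    count_a: int
    count_b: int
    fold_change: float             # group A over group B, RPM scale
    direction: str                 # hyper | hypo w.r.t. group A
    p_value: float
    adjusted_p: float
    contrast: str = ""
    region_ids: list[int] = field(default_factory=list)
    region_kinds: list[str] = field(default_factory=list)    # aligned with region_ids
    region_genes: list[str] = field(default_factory=list)    # aligned; "" for CpG islands
    gene_ids: list[str] = field(default_factory=list)        # deduplicated convenience

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "DMR") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


# ---------------------------------------------------------------------------
# Statistical primitives


def chi_squared_2x2(a: int, total_a: int, b: int, total_b: int) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) for count enrichment.

    Table: ``[[a, total_a - a], [b, total_b - b]]``.  Degenerate tables with a
    zero marginal return ``(0.0, 1.0)``.
    """
    if min(a, b, total_a, total_b) < 0:
        raise ValueError("negative counts")
    if total_a < a or total_b < b:
        raise ValueError("count exceeds its total")
    if total_a + total_b == 0:
        raise ValueError("both totals zero")
    stat = _chi2_stat_vec(
        np.array([a], dtype=float), np.array([total_a], dtype=float),
        np.array([b], dtype=float), np.array([total_b], dtype=float),
    )[0]
    if stat == 0.0:
        return 0.0, 1.0
    return float(stat), float(_chi2_dist.sf(stat, 1))


def _chi2_stat_vec(a, total_a, b, total_b) -> np.ndarray:
    """Vectorised Pearson statistic; 0 wherever a table marginal is zero."""
    c, d = total_a - a, total_b - b
    n = total_a + total_b
    row1, row2 = a + b, c + d
    denom = total_a * total_b * row1 * row2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / denom
    return np.where(denom > 0, stat, 0.0)


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method in {"bh", "fdr_bh"}:
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown correction {method!r}")


def fold_change(a: int, total_a: int, b: int, total_b: int, pseudocount: float = 0.5) -> float:
    """RPM-scale fold change (A over B) with a pseudocount in RPM units."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    rpm_a = 1e6 * a / total_a
    rpm_b = 1e6 * b / total_b
    return (rpm_a + pseudocount) / (rpm_b + pseudocount)


# ---------------------------------------------------------------------------
# Per-site testing


@dataclass
class SiteTestResult:
    """Vectorised per-site test results for one contrast."""

    site_ids: np.ndarray
    count_a: np.ndarray
    count_b: np.ndarray
    total_a: int
    total_b: int
    p_raw: np.ndarray          # NaN for untested (all-zero) sites
    p_adj: np.ndarray
    fc: np.ndarray
    significant: np.ndarray    # bool
    direction: np.ndarray      # +1 hyper, -1 hypo, 0 n.s.


def test_sites(
    matrix: SiteCountMatrix,
    contrast: GroupContrast,
    config: DmrConfig = DmrConfig(),
) -> SiteTestResult:
    """Chi-squared test of every site with nonzero pooled count, with correction.

    The correction family is the set of sites with a nonzero pooled count;
    a site is significant when its adjusted p falls below alpha AND its
    fold change clears the threshold in either direction.
    """
    for s in contrast.samples_a + contrast.samples_b:
        if s not in matrix.samples:
            raise ValueError(f"sample {s!r} not in matrix")
    a, total_a = matrix.pooled(contrast.samples_a)
    b, total_b = matrix.pooled(contrast.samples_b)
    if total_a <= 0 or total_b <= 0:
        raise ValueError("contrast has a zero pooled total")

    tested = (a + b) > 0
    af, bf = a.astype(float), b.astype(float)
    stat = _chi2_stat_vec(af, float(total_a), bf, float(total_b))
    p_raw = np.full(len(a), np.nan)
    p_raw[tested] = np.where(stat[tested] > 0, _chi2_dist.sf(stat[tested], 1), 1.0)
    p_adj = np.full(len(a), np.nan)
    p_adj[tested] = adjust_pvalues(p_raw[tested], config.correction)

    fc = (1e6 * af / total_a + config.pseudocount) / (1e6 * bf / total_b + config.pseudocount)
    beyond = (fc >= config.fc_threshold) | (fc <= 1.0 / config.fc_threshold)
    significant = tested & (p_adj < config.alpha) & beyond
    direction = np.where(significant, np.where(fc > 1, 1, -1), 0)
    return SiteTestResult(
        site_ids=matrix.site_ids,
        count_a=a, count_b=b,
        total_a=total_a, total_b=total_b,
        p_raw=p_raw, p_adj=p_adj, fc=fc,
        significant=significant, direction=direction,
    )


# ---------------------------------------------------------------------------
# Sliding-window detection


def window_members(
    positions: np.ndarray,
    seed_index: int,
    max_neighbors: int,
    max_distance_bp: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate neighbour indices (left, right) for one seed site.

    At most ``max_neighbors`` catalogue sites are examined on each side, and
    only those within ``max_distance_bp`` of the seed's position are returned.
    """
    pos0 = positions[seed_index]
    lo = max(0, seed_index - max_neighbors)
    left = np.arange(lo, seed_index)
    left = left[positions[left] >= pos0 - max_distance_bp]
    hi = min(len(positions), seed_index + max_neighbors + 1)
    right = np.arange(seed_index + 1, hi)
    right = right[positions[right] <= pos0 + max_distance_bp]
    return left, right


def detect_dmrs_sliding_window(
    matrix: SiteCountMatrix,
    catalog: SiteCatalog,
    contrast: GroupContrast,
    config: DmrConfig = DmrConfig(),
) -> list[DMR]:
    """Genome-wide sliding-window DMR detection for one contrast.

    From every significant seed site, significant same-direction sites among
    the neighbour budget are collected; candidates with >= ``min_sites``
    significant sites spanning >= ``min_span_bp`` survive, candidates sharing
    a site are merged, and DMR-level counts, fold change and p-value are
    recomputed over every catalogue site inside the merged span.  Emitted
    DMRs satisfy all config thresholds and are sorted by coordinate.
    """
    if len(matrix.site_ids) != len(catalog):
        raise ValueError("matrix and catalogue disagree on site count")
    result = test_sites(matrix, contrast, config)
    cat = catalog.frame()
    mlen = catalog.motif_length

    candidates: list[tuple[str, set[int], int]] = []   # (chrom, sig site rows, direction)
    for chrom, sub in cat.groupby("chrom", sort=False):
        rows = sub.index.to_numpy()                    # global rows, catalogue order
        positions = sub["pos"].to_numpy()
        sig = result.significant[rows]
        if not sig.any():
            continue
        for local_seed in np.flatnonzero(sig):
            seed_dir = result.direction[rows[local_seed]]
            left, right = window_members(
                positions, int(local_seed), config.max_neighbors, config.max_distance_bp
            )
            local = np.concatenate([left, [local_seed], right])
            member = local[
                result.significant[rows[local]]
                & (result.direction[rows[local]] == seed_dir)
            ]
            if len(member) < config.min_sites:
                continue
            span = positions[member[-1]] + mlen - positions[member[0]]
            if span < config.min_span_bp:
                continue
            candidates.append((chrom, set(rows[member].tolist()), int(seed_dir)))

    merged = _merge_candidates(candidates)

    # recompute on merged spans
    total_a, total_b = result.total_a, result.total_b
    pos_all = cat["pos"].to_numpy()
    chrom_all = cat["chrom"].to_numpy()
    dmrs: list[DMR] = []
    for chrom, sites, direction in merged:
        rows = np.array(sorted(sites))
        start = int(pos_all[rows[0]])
        end = int(pos_all[rows[-1]]) + mlen
        # all catalogue sites inside the span, significant or not
        in_span = np.flatnonzero(
            (chrom_all == chrom) & (pos_all >= start) & (pos_all + mlen <= end)
        )
        a = int(result.count_a[in_span].sum())
        b = int(result.count_b[in_span].sum())
        fc = fold_change(a, total_a, b, total_b, config.pseudocount)
        if not (fc >= config.fc_threshold or fc <= 1.0 / config.fc_threshold):
            continue
        _, p = chi_squared_2x2(a, total_a, b, total_b)
        dmrs.append(DMR(
            chrom=chrom, start=start, end=end,
            site_ids=[int(i) for i in in_span],
            n_significant_sites=int(len(rows)),
            count_a=a, count_b=b,
            fold_change=float(fc),
            direction=HYPER if fc > 1 else HYPO,
            p_value=float(p),
            adjusted_p=np.nan,
            contrast=contrast.name,
        ))
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.end))
    if dmrs:
        adj = adjust_pvalues(np.array([d.p_value for d in dmrs]), config.correction)
        for d, q in zip(dmrs, adj):
            d.adjusted_p = float(q)
    return dmrs


def _merge_candidates(
    candidates: list[tuple[str, set[int], int]],
) -> list[tuple[str, set[int], int]]:
    """Union candidates that share at least one site (per chromosome)."""
    merged: list[tuple[str, set[int], int]] = []
    for chrom, sites, direction in sorted(candidates, key=lambda c: (c[0], min(c[1]))):
        if merged:
            pchrom, psites, pdir = merged[-1]
            if pchrom == chrom and pdir == direction and psites & sites:
                psites |= sites
                continue
        merged.append((chrom, set(sites), direction))
    return merged


# ---------------------------------------------------------------------------
# Region-level testing


def test_regions(
    matrix: SiteCountMatrix,
    site_region_map: dict[int, list[int]],
    regions: RegionSet,
    contrast: GroupContrast,
    config: DmrConfig = DmrConfig(alpha=0.05, correction="bh"),
) -> pd.DataFrame:
    """Chi-squared enrichment per annotated region, corrected within region kind.

    Region counts pool the member-site counts over each group's samples.
    Regions without assigned sites are reported with NA statistics and are
    excluded from the correction family.
    """
    a, total_a = matrix.pooled(contrast.samples_a)
    b, total_b = matrix.pooled(contrast.samples_b)
    region_sites: dict[int, list[int]] = {}
    for site_id, region_ids in site_region_map.items():
        for rid in region_ids:
            region_sites.setdefault(rid, []).append(site_id)

    rows = []
    for r in regions:
        sites = region_sites.get(r.region_id, [])
        ca = int(a[sites].sum()) if sites else 0
        cb = int(b[sites].sum()) if sites else 0
        if sites:
            _, p = chi_squared_2x2(ca, total_a, cb, total_b)
            fc = fold_change(ca, total_a, cb, total_b, config.pseudocount)
        else:
            p, fc = np.nan, np.nan
        rows.append((r.region_id, r.chrom, r.start, r.end, r.kind, r.gene_id,
                     len(sites), ca, cb, fc, p))
    df = pd.DataFrame(rows, columns=[
        "region_id", "chrom", "start", "end", "kind", "gene_id",
        "n_sites", "count_a", "count_b", "fc", "p",
    ])
    df["p_adj"] = np.nan
    for kind, sub in df.groupby("kind"):
        tested = sub.index[sub["p"].notna()]
        if len(tested):
            df.loc[tested, "p_adj"] = adjust_pvalues(
                df.loc[tested, "p"].to_numpy(), config.correction
            )
    beyond = (df["fc"] >= config.fc_threshold) | (df["fc"] <= 1.0 / config.fc_threshold)
    df["significant"] = (df["p_adj"] < config.alpha) & beyond
    df["direction"] = np.where(df["fc"] > 1, HYPER, HYPO)
    df.loc[df["p"].isna(), "direction"] = ""
    return df


# ---------------------------------------------------------------------------
# Group-unique calling and annotation


def call_group_unique_dmrs(
    dmrs_by_contrast: dict[str, list[DMR]],
) -> dict[str, list[DMR]]:
    """DMRs unique to each one-vs-rest contrast (zero-bp overlap with any other).

    A DMR emitted by contrast g is unique to g iff no DMR from any other
    contrast overlaps it by even one base; the resulting sets are disjoint.
    """
    if len(dmrs_by_contrast) < 2:
        raise ValueError("need at least two contrasts")
    unique: dict[str, list[DMR]] = {}
    for name, dmrs in dmrs_by_contrast.items():
        others = [d for other, lst in dmrs_by_contrast.items() if other != name for d in lst]
        unique[name] = [d for d in dmrs if not any(d.overlaps(o) for o in others)]
    return unique


def annotate_dmrs(dmrs: list[DMR], regions: RegionSet) -> list[DMR]:
    """Attach overlapping region ids, kinds and gene ids (any overlap, partial or total)."""
    out = []
    for d in dmrs:
        hits = regions.overlapping(d.chrom, d.start, d.end)
        out.append(replace(
            d,
            region_ids=[r.region_id for r in hits],
            region_kinds=[r.kind for r in hits],
            region_genes=[r.gene_id for r in hits],
            gene_ids=sorted({r.gene_id for r in hits if r.gene_id}),
        ))
    return out


# ---------------------------------------------------------------------------
# I/O


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": d.chrom, "start": d.start, "end": d.end,
        "n_sites": len(d.site_ids), "n_significant": d.n_significant_sites,
        "count_a": d.count_a, "count_b": d.count_b,
        "fold_change": d.fold_change, "direction": d.direction,
        "p_value": d.p_value, "adjusted_p": d.adjusted_p,
        "contrast": d.contrast,
        "region_kinds": ",".join(d.region_kinds),
        "region_genes": ",".join(d.region_genes),
        "gene_ids": ",".join(d.gene_ids),
    } for d in dmrs])


def write_dmr_bed(dmrs: list[DMR], path: str | Path) -> None:
    """BED6+ export: name=DMR index, score=-log10 adjusted p (capped at 1000)."""
    with Path(path).open("w") as fh:
        for i, d in enumerate(dmrs):
            q = d.adjusted_p if np.isfinite(d.adjusted_p) and d.adjusted_p > 0 else None
            score = min(1000, int(round(-10 * np.log10(q)))) if q else 1000
            extras = "\t".join([
                str(len(d.site_ids)), str(d.n_significant_sites),
                f"{d.fold_change:.4g}", d.direction,
                ",".join(d.region_kinds) or ".",
                ",".join(d.gene_ids) or ".",
            ])
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tDMR{i}\t{score}\t.\t{extras}\n")
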