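"""Directional integration of DMRs with differential gene expression.

Methylation is matched to expression by the standard concordance rule:
promoter hypermethylation or gene-body hypomethylation is expected to
accompany downregulation, and promoter hypomethylation or gene-body
hypermethylation upregulation.  A DMR is "associated" with expression change
when at least one overlapping gene is differentially expressed with the
expected sign.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import logging
import numpy as np
import pandas as pd

from .catalog import CPG_ISLAND, GENE_BODY, TSS, RegionSet
from .dmr import DMR, HYPER, HYPO

logger = logging.getLogger(__name__)

CONCORDANT = "concordant"
DISCORDANT = "discordant"
GENE_NOT_DE = "gene_not_DE"
NO_GENE = "no_gene"


def call_de_genes(
    table: pd.DataFrame,
    lfc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag differentially expressed genes: |log2FC| >= 1.5 and FDR < 0.05.

    The magnitude bound is inclusive, the FDR bound strict.  Returns a copy
    with ``de`` and ``sign`` (+1/-1/0) columns; duplicate gene ids are an error.
    """
    required = {"gene_id", "log2FC", "FDR"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    dup = table["gene_id"][table["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id in expression table: {dup.iloc[0]!r}")
    out = table.copy()
    out["de"] = (out["log2FC"].abs() >= lfc_threshold) & (out["FDR"] < fdr_threshold)
    out["sign"] = np.where(out["de"], np.sign(out["log2FC"]).astype(int), 0)
    return out


# rule: (DMR direction, region kind, expression sign) -> concordant?
_CONCORDANT_RULE = {
    (HYPO, TSS, +1), (HYPER, GENE_BODY, +1),
    (HYPER, TSS, -1), (HYPO, GENE_BODY, -1),
}


def is_concordant(direction: str, kind: str, sign: int) -> bool:
    """True iff a DMR direction / region kind / DE sign triple fits the rule."""
    return (direction, kind, int(sign)) in _CONCORDANT_RULE


@dataclass
class ConcordanceReport:
    """Per-DMR verdicts plus summary fractions for one contrast."""

    rows: pd.DataFrame          # one row per DMR (best verdict over its genes)
    pairs: pd.DataFrame         # one row per DMR x gene x region kind

    @property
    def n_dmrs(self) -> int:
        return len(self.rows)

    def verdict_counts(self) -> dict[str, int]:
        counts = self.rows["verdict"].value_counts().to_dict()
        return {v: int(counts.get(v, 0)) for v in (CONCORDANT, DISCORDANT, GENE_NOT_DE, NO_GENE)}

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def _gene_kinds(dmr: DMR, regions: RegionSet | None) -> dict[str, set[str]]:
    """Gene -> region kinds the DMR overlaps; CpG-island-only overlaps are
    promoted to the promoter of a gene whose TSS region the island touches."""
    genes = dmr.region_genes
    if not genes and regions is not None:
        genes = [regions.by_id(rid).gene_id for rid in dmr.region_ids]
    by_gene: dict[str, set[str]] = {}
    for kind, gene in zip(dmr.region_kinds, genes):
        if kind in (TSS, GENE_BODY) and gene:
            by_gene.setdefault(gene, set()).add(kind)
    if not by_gene and regions is not None:
        # CpG-island-only overlap: map to promoters the island intersects
        for rid, kind in zip(dmr.region_ids, dmr.region_kinds):
            if kind != CPG_ISLAND:
                continue
            island = regions.by_id(rid)
            for r in regions.overlapping(island.chrom, island.start, island.end):
                if r.kind == TSS and r.gene_id:
                    by_gene.setdefault(r.gene_id, set()).add(TSS)
    return by_gene


def match_dmr_expression(
    dmrs: list[DMR],
    expression: pd.DataFrame,
    regions: RegionSet | None = None,
) -> ConcordanceReport:
    """Assign a concordance verdict to every DMR.

    DMRs must already carry their region overlaps (see ``annotate_dmrs``).
    A DMR overlapping both region kinds of a gene is evaluated per kind and
    counted concordant if any rule fires; best verdict order is
    concordant > discordant > gene_not_DE > no_gene.
    """
    expr = call_de_genes(expression) if "de" not in expression.columns else expression
    by_gene_expr = expr.set_index("gene_id")

    order = {CONCORDANT: 0, DISCORDANT: 1, GENE_NOT_DE: 2, NO_GENE: 3}
    row_records, pair_records = [], []
    for i, d in enumerate(dmrs):
        gene_kinds = _gene_kinds(d, regions)
        verdicts = []
        for gene, kinds in sorted(gene_kinds.items()):
            if gene not in by_gene_expr.index:
                logger.warning("gene %s overlaps a DMR but is absent from expression table", gene)
                verdicts.append(GENE_NOT_DE)
                pair_records.append((i, d.contrast, gene, ",".join(sorted(kinds)),
                                     d.direction, np.nan, np.nan, GENE_NOT_DE))
                continue
            g = by_gene_expr.loc[gene]
            if not bool(g["de"]):
                verdict = GENE_NOT_DE
            elif any(is_concordant(d.direction, k, int(g["sign"])) for k in kinds):
                verdict = CONCORDANT
            else:
                verdict = DISCORDANT
            verdicts.append(verdict)
            pair_records.append((i, d.contrast, gene, ",".join(sorted(kinds)),
                                 d.direction, float(g["log2FC"]), float(g["FDR"]), verdict))
        best = min(verdicts, key=order.get) if verdicts else NO_GENE
        row_records.append((i, d.contrast, d.chrom, d.start, d.end, d.direction, best))

    rows = pd.DataFrame(row_records, columns=[
        "dmr_index", "contrast", "chrom", "start", "end", "direction", "verdict",
    ])
    pairs = pd.DataFrame(pair_records, columns=[
        "dmr_index", "contrast", "gene_id", "region_kinds",
        "direction", "log2FC", "FDR", "verdict",
    ])
    return ConcordanceReport(rows=rows, pairs=pairs)


def summarize_association(report: ConcordanceReport) -> dict[str, float]:
    """Headline fractions: expression-associated and intergenic DMRs.

    ``associated_fraction`` counts concordant DMRs against all DMRs (the
    intergenic ones included); ``associated_fraction_genic`` uses only
    gene-overlapping DMRs as denominator.  Verdict counts partition the DMRs.
    """
    if report.n_dmrs == 0:
        raise ValueError("empty concordance report")
    counts = report.verdict_counts()
    n = report.n_dmrs
    n_genic = n - counts[NO_GENE]
    return {
        "n_dmrs": n,
        **{f"n_{k}": v for k, v in counts.items()},
        "intergenic_fraction": counts[NO_GENE] / n,
        "associated_fraction": counts[CONCORDANT] / n,
        "associated_fraction_genic": counts[CONCORDANT] / n_genic if n_genic else float("nan"),
    }
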