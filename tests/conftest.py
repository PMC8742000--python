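"""Shared synthetic fixtures: a toy genome with planted DMRs and simulated counts."""
import numpy as np
import pandas as pd
import pytest

import medseq as m

ILLUMINA_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


@pytest.fixture(scope="session")
def toy_fixture():
    """One 100 kb chromosome with ~1000 LpnPI sites at ~100 bp spacing."""
    return m.generate_toy_genome(1, 100_000, 100, seed=7)


@pytest.fixture(scope="session")
def toy_catalog(toy_fixture):
    return toy_fixture.to_catalog()


@pytest.fixture(scope="session")
def profile_ab(toy_fixture):
    """Two groups, 8 planted DMRs (12 sites each) at fold change 4."""
    return m.plant_methylation(toy_fixture, ["A", "B"], 8, 12, 4.0, 0.1, seed=3)


@pytest.fixture(scope="session")
def counts_ab(profile_ab):
    """6 vs 6 samples at 100k reads/sample, Poisson noise."""
    return m.simulate_count_matrix(profile_ab, 6, 100_000, seed=11)


@pytest.fixture(scope="session")
def contrast_a(counts_ab):
    return m.GroupContrast(
        "A_vs_rest",
        counts_ab.group_samples("A"),
        counts_ab.group_samples("B"),
    )


@pytest.fixture(scope="session")
def toy_regions():
    """Hand-laid annotation: two genes and one CpG island on a 20 kb chromosome."""
    genes = pd.DataFrame(
        [
            ("chr1", 5000, 9000, "geneP", "+"),
            ("chr1", 12000, 16000, "geneM", "-"),
        ],
        columns=["chrom", "start", "end", "gene_id", "strand"],
    )
    islands = pd.DataFrame([("chr1", 6500, 7000)], columns=["chrom", "start", "end"])
    return m.build_regions(genes, islands, chrom_lengths={"chr1": 20_000})


def reciprocal_overlap(a_start, a_end, b_start, b_end, frac=0.5):
    ov = max(0, min(a_end, b_end) - max(a_start, b_start))
    return ov >= frac * (a_end - a_start) and ov >= frac * (b_end - b_start)


def recovered_planted(planted, dmrs_by_contrast, frac=0.5):
    """Planted DMRs recovered (>=frac reciprocal overlap, matching direction)
    by their affected group's one-vs-rest contrast."""
    hits = []
    for d in planted:
        detected = dmrs_by_contrast[f"{d.group}_vs_rest"]
        hits.append(any(
            x.chrom == d.chrom
            and x.direction == d.direction
            and reciprocal_overlap(d.start, d.end, x.start, x.end, frac)
            for x in detected
        ))
    return np.array(hits)
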