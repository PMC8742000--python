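# Methods

## The assay and its in-silico model

LpnPI is a methylation-dependent restriction enzyme: it cuts only when its
recognition site (CCDG class, D ∈ {A,G,T}; the motif is a configuration
string, default `CCDG`, scanned on both strands) carries a methylated CpG,
releasing ~32 bp fragments with the site 13–17 bp from a fragment end.
Sequencing these fragments and counting reads per recognition site yields a
genome-wide methylation readout covering over half of all CpGs.

The simulator treats the per-site methylation probability directly as the
fragment-emission probability: a site with probability *p* contributes reads
in proportion to *p*. Hemi-methylation is not modelled ("fully methylated or
nothing"), and neither are sequencing errors, PCR duplicates or copy-number
effects — the generator emulates counting noise and planted biology, not
platform artefacts. Consequently, passing tests demonstrate the correctness
of the counting, testing and windowing logic under the stated noise model,
not robustness to alignment error or tumour heterogeneity.

## Synthetic data generation

**Toy genome.** Recognition-site instances are planted into a motif-free
random background at gaps drawn uniformly from 0.5–1.5× the target spacing
(default 100 bp), each instance flanked by a `TTT` pad that provably cannot
combine with adjacent bases into a spurious occurrence. Planted instances
use D ∈ {A,T} only: the D = G instance (`CCGG`) is its own reverse
complement and would register as two sites (one per strand) at one locus,
breaking the one-record-per-planted-site bookkeeping; the scanner itself
handles palindromic instances and reports both strands (a `collapse_cpg`
option merges them). Every generated genome is verified by a full rescan
before it is returned.

**Planted DMRs.** Each DMR covers a fixed number of consecutive catalogue
sites (default 12, at least 10 so it is detectable) and spans ≥ 100 bp.
Inside a hyper DMR the affected group's site probability is
`baseline × effect_fc`; hypo uses the reciprocal. Two placement rules keep
ground truth unambiguous: (i) planted DMRs are separated by ≥ 2 kb — above
the detector's 1 kb window distance — so two truth units can never fuse into
one detected region; (ii) the direction assignment alternates per *cycle* of
groups rather than per DMR, because with two groups a per-DMR alternation
makes direction a deterministic function of the affected group, which skews
each group's emission normalisation and shrinks the realised fold change
well below the planted one (about 4.6 where 6 was planted, in our
measurements). Realised count-level fold changes still deviate by a few
percent from the planted factor, because emission probabilities are
normalised within each group; tests assert the count-level ratio within 20%
and the probability-level ratio exactly.

**Counts.** Per sample, a library size is drawn lognormally around the group
mean (σ = 0.1 on the log scale; σ = 0 fixes it) and per-site counts are
Poisson (`dispersion = 0`) or negative binomial with variance
`μ + dispersion·μ²` (gamma–Poisson mixture). Defaults used throughout the
test suite: 6 samples per group, 100,000 reads per sample, baseline
methylation 0.1, planted fold change 4 — small enough to run in seconds,
deep enough that a 12-site FC-4 DMR is unambiguous.

**Reads.** Each simulated read derives from a 32 bp window containing
exactly one sampled site, with the motif placed uniformly over the seven
offsets that leave it 13–17 bp from at least one end, in random orientation.
When a read length above 32 is requested together with an adapter, the 3'
end is filled with a single adapter prefix — exactly the read-through
structure suffix–prefix trimming inverts — so trimming recovers the insert
byte-exactly. The adapter must therefore be at least `read_length − 32` bp.

**Expression tables.** For a chosen fraction of the genes whose promoter or
gene body overlaps a planted DMR, a differential-expression call is
generated with the sign the concordance rule expects (promoter rule takes
precedence when a DMR touches both region kinds of a gene) and FDR < 0.05;
all other genes receive null log2FC noise (|log2FC| < 1.4) and FDR ≥ 0.05.

## Statistical choices

* **2×2 table.** "Reads in the site/region" versus "all other reads" per
  pooled group. Pooling across samples within a group means per-sample
  biological dispersion is not part of the test — a documented limitation;
  the deep pooled totals make the chi-squared extremely sensitive, which is
  why the fold-change threshold, not the p-value, does most of the filtering.
* **Degenerate tables** (any zero marginal) return statistic 0, p = 1 rather
  than an error, so all-zero sites are harmlessly non-significant.
* **Correction families.** Sites: all sites with a nonzero pooled count
  (testing a site no read ever hit is impossible a priori and would only
  dilute the family). Regions: all regions of the same kind. Defaults:
  Bonferroni α = 0.05 for sites, BH 0.05 for regions; both configurable.
* **Fold change** is computed on the RPM scale with a 0.5-RPM pseudocount,
  making it library-size invariant and finite at zero counts.
* **Window semantics.** "Within 1000 bp" is measured from the seed site's
  position, not chained from the previously included site; at most 50
  catalogue sites are examined per side regardless of significance, and
  significant same-direction sites among them are collected (gaps of
  non-significant sites do not stop the window). Candidates sharing a site
  are merged; merged DMRs are re-tested over every catalogue site in their
  span, and the DMR-level fold change must still clear the threshold.
* **Group-unique DMRs** use a zero-overlap rule: a DMR is unique to its
  contrast only if no other contrast emits a DMR overlapping it by even one
  base. With one-vs-rest pooling, a strong DMR (FC ≥ ~3) in one group leaks
  into the *other* groups' contrasts with FC `2/(1+FC) < 1/2` and is emitted
  there in mirror direction, so strong planted DMRs are never unique. This
  is a property of the contrast design, not a bug; synthetic unique-recovery
  runs therefore use three groups at moderate effect (FC 2.5), where the
  leakage FC ≈ 0.57 stays inside the two-fold band.
* **Z-scores** use the population SD (ddof = 0); zero-variance rows are
  dropped with a warning. Clustering is scipy's complete-linkage
  agglomeration under the cityblock metric on samples; tests verify it
  against a brute-force O(n³) agglomerator on ≤ 8 samples with untied
  distances (tie order between equal-distance pairs is otherwise
  implementation-defined).

## Numerical and boundary conventions

* All coordinates are 0-based half-open; GTF input is converted on
  ingestion. A site belongs to a region iff its motif start lies in
  `[start, end)`; a DMR's end is the last member motif start plus the motif
  length.
* Promoter regions are clipped to chromosome bounds; genes shorter than the
  1 kb flank keep their promoter but drop the empty gene body with a warning.
  Multiple records per gene id collapse to the union span.
* The read filter measures the 5' offset to the motif start and the 3'
  offset from the motif end, both bounds inclusive; the qualifying occurrence
  with the smallest read position is recorded on ties.
* The DE thresholds are inclusive in magnitude (|log2FC| ≥ 1.5) and strict
  in FDR (< 0.05).
* Multi-mapped reads count once per location by default; a fractional
  (1/n per location) mode exists but is off by default.

## Problem sizes

The test suite and acceptance script run on one 100 kb chromosome
(~1000 sites, 6 vs 6 samples, 100k reads/sample; 400 kb with 40 planted
DMRs for concordance-fraction recovery; 20 seeds for the null calibration).
These sizes make every planted effect unambiguous while the full suite
completes in well under a minute.

## Known limitations

* No mismatch-tolerant alignment: the built-in mapper is exact-match and
  intended for synthetic genomes; real data should arrive as SAM/BAM.
* Pooled testing ignores within-group dispersion, so p-values on deep real
  data will be anti-conservative; the fold-change threshold is the effective
  gatekeeper, as in the original design.
* Copy-number alterations inflate counts and can masquerade as DMRs; the
  expression-integration step is the intended mitigation, not a correction
  of the counts themselves.
* The simulator emits no sequencing errors, duplicates or bisulphite-style
  conversion noise.
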