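# Methods

## Matrisome classification

The classifier is a deterministic composition of per-contig rules over three
evidence streams: InterPro-style domain hits, bidirectional BLAST homology
to the human matrisome, and topology predictions (signal peptide, TM
segments, GPI anchor). Its stages run in a fixed order — deduplicate
domains, categorize by domains, apply excluding-domain vetoes, categorize by
BLAST, reconcile, filter transmembrane proteins, apply GPI, assign
confidence — and every decision is recorded on the call (provenance, flags,
exclusion reason), so the output is auditable and the whole procedure is
idempotent and independent of input row order.

Design choices where the procedure was genuinely open:

- **Category tie-breaks.** When two categories tie on defining-domain
  counts, the fixed priority core > affiliated > regulator > secreted wins
  and the call is flagged `tie_broken`. Core is the most conservatively
  curated tier, so ties err toward the structural matrisome while remaining
  visible to a curator.
- **Domain vs BLAST conflicts.** Historically these were resolved by manual
  inspection of domain architecture. As a deterministic proxy, the
  domain-derived category always wins and the call carries
  `category_conflict`; the flag marks exactly the set a curator would
  revisit.
- **Excluding-domain veto is terminal.** A contig whose domain content
  contradicts ECM localization (kinase, phosphatase, integrin, 7TM domains)
  is excluded even when a BLAST hit suggests a matrisome category — the
  domain evidence is direct, the homology transitive. Six domains (C1q,
  animal haem peroxidase, TIL, fringe, C345C, Kazal) never veto: each is a
  legitimate constituent of planarian ECM proteins (e.g. TIL in mucin-like
  core glycoproteins), and their presence instead counts as defining
  evidence in the packaged catalog.
- **Signal-peptide-like TM segments.** A predicted TM segment is discounted
  when the protein has a signal peptide and the segment starts at or before
  the predicted cleavage position; when no cleavage position is available, a
  35-aa N-terminal window is used (generous for eukaryotic signal peptides,
  which rarely exceed ~30 aa).
- **TM keep list by domain family.** Known transmembrane ECM components are
  retained by the presence of collagen triple-helix or MMP catalytic
  domains rather than by gene name, so the rule applies to any assembly,
  including synthetic ones.
- **Confidence as an ordered rule list.** First match wins and the matched
  rule id is recorded: (1) high — signal peptide + defining domain; (2)
  high — reciprocal best hit to a human matrisome protein + defining
  domain; (3) low — defining domain without a called signal peptide (SP
  prediction on fragmented 5' ends is unreliable, so these stay in the
  matrisome at low confidence); (4) low — signal peptide, no defining
  domain, < 200 aa (weakly characterized small secreted factors); (5) low —
  families configured as intracellular-secretory (e.g. lysosomal
  cathepsins); (6) low otherwise. An optional curator allow-list can force
  specific contigs to high; it is empty by default because its historical
  membership was a manual judgement call we do not reconstruct.
- **Thresholds.** Domain hits are consumed at e < 0.1 and BLAST
  categorization requires the best hit at e < 0.01 (strict inequalities);
  both are config keys.
- Coordinates are 1-based inclusive amino-acid positions; unknown domain
  accessions are logged and ignored rather than fatal, to tolerate catalog
  version drift.

`longest_orf` is plumbing for assemblies without gene predictions: the
longest ATG-initiated, stop-terminated ORF over six frames, ties broken by
frame order then 5'-most start, minimum 30 aa. When several contigs belong
to one gene, `representative_contig` picks the one with the largest average
read count in the single-cell data (ties: lexicographically smallest id,
flagged).

## Single-cell analytics

**Normalization.** CP10K (each cell scaled to 10,000 total counts) with
ln(1+x) by default. Scores and logFC are computed on log values; a raw-CP10K
mode is kept behind `log_transform=False` for plain average-expression
displays. All-zero cells are left at zero and warned about.

**Module score.** Genes are cut into 24 equal-frequency bins of mean
expression (ties in the mean break by gene id, making the score invariant
to input gene order); each set gene contributes 100 control genes sampled
from its bin without replacement (with replacement when the bin is smaller),
and the score is mean(set) − mean(control pool) per cell. 24/100 are the
community defaults for expression-matched scoring; both are parameters. The
score is seed-reproducible bit for bit, exactly zero when the set is all
genes and the controls tile the bins, and invariant to adding a constant to
the matrix.

**Specificity AUC.** For each cell-type label, the AUC of the per-cell
statistic (gene expression or module score) for that type versus all other
cells, computed as normalized Mann–Whitney U with mid-rank tie handling;
ties in the argmax break by label sort order and are flagged.

**Matrisome-restricted reclustering.** Subset to the high-confidence gene
set, per-gene z-score with clipping at ±10 (bounds outlier leverage), PCA to
20 components, then shared-nearest-neighbor graph clustering (k = 30,
Jaccard edge weights pruned below 1/15, modularity optimization at
resolution 1.0) and tSNE (perplexity 40) both on the top 6 components. The
clustering algorithm and resolution are free choices — the analyses read
only the composition of clusters against reference labels (recovery and
contamination), never cluster identities, so any modularity-style
community detection yields the same conclusions. tSNE is for display only
and can be disabled.

**Marker ranking and GSEA.** Average log fold change is
ln(mean(e^x − 1) + 1) in-group minus out-group (natural log, pseudocount 1 —
the convention of the standard single-cell marker test); genes enter the
ranking when normalized expression exceeds 0.5 in strictly more than 1% of
cells; ties in logFC break by gene id. The enrichment score is the weighted
running-sum statistic with exponent p = 1.0 — verified to agree exactly with
the Bioconductor reference implementation — with a positive extremum
preferred on exact magnitude ties. The null is gene-set permutation: random
same-size sets from the ranked universe (vectorized over hit positions,
which is exact because the running sum attains extrema only adjacent to
hits); p = (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign
null}); NES = ES / mean |same-sign null ES|; BH across the sets of one call.
p-values are therefore bounded below by 1/(n_perm+1) and the null is
uniform, which the tests check by KS.

## Synthetic data

**Evidence bundles** plant one class of contig per branch of the
classifier: core with/without signal peptide, GPI-anchored ECM-affiliated,
regulators, secreted factors, TIL-bearing mucin-like core proteins (the
exception carve-out), transmembrane collagens (the keep list), small
secreted factors, three decoy classes (kinase-bearing, TM receptors,
intracellular proteins), and an injected domain-vs-BLAST conflict class.
Domain accessions are real InterPro ids from the packaged catalog; BLAST
tables are emitted in both directions and are mutually consistent for
planted reciprocal pairs (the no-signal-peptide class is deliberately not
reciprocal so its confidence rests on domain evidence alone). Truth labels
are written to a separate table and never leak into the evidence files.

**Count matrices** are gamma-Poisson (negative binomial, shared dispersion
0.3): expected counts are library size × relative baseline × planted
fold-change, with library sizes log-normal (ln-μ 8.5, ln-σ 0.35; ≈5,000
UMIs/cell median), baselines Gamma(0.6, 1), nine cell types with muscle at
10% of 3,000 cells, a 50-gene matrisome program at fold-change 8 in muscle,
and 20 marker genes per type at fold-change 5. Fold-changes multiply gene
means directly, so the empirical muscle/other mean ratio of a matrisome gene
recovers the nominal f (over-expressing cells end up with slightly larger
libraries, as secretory cells do). The simulation emulates the statistical
structure the analyses rely on — a distinct cell type coherently
over-expressing an ECM program over an overdispersed count background — and
deliberately omits doublets, ambient RNA, batch effects and realistic
sequence content; passing tests demonstrate correctness of the methods and
recoverability of a planted signal at realistic size and noise, not
performance on any particular real atlas.

Problem sizes used throughout testing and in the acceptance script (3,000
cells × 2,000 genes, 9–20 simulation seeds, 1,000–10,000 permutations) were
chosen as the smallest scales at which the law-of-large-numbers and
calibration properties stabilize.

## Known limitations

- Confidence rules are a deterministic approximation of what was
  historically a partly manual curation; rule ids and flags expose every
  call for review, but borderline cases (e.g. plasma-membrane-localized
  best hits without TM domains) require the explicit allow-list.
- The excluding-domain dictionary packaged here is a compact, curated
  subset adequate for the rule engine and its tests; a production
  annotation run should supply the full matrisome domain dictionary via
  `load_domain_catalog(path)`.
- The SNN clustering is modularity-based; very small clusters below the
  neighborhood scale (k = 30) can be absorbed into neighbors.
- GSEA uses plain permutation p-values; extremely small p-values saturate
  at 1/(n_perm+1) rather than being refined adaptively.
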