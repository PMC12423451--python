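# Methods

This note records the models, conventions and numerical choices behind
`tfcoop`, in the spirit of a package vignette: what each stage computes,
which knobs matter, what the synthetic data do and do not emulate, and
where the design was genuinely open.

## TF catalog and genomic clustering

Gene models come from GFF3 (gene/mRNA/exon/CDS/UTR hierarchy) joined
with a TSV of TF family labels; genes without a label are kept as
structural genes ("SG").  Proteins are derived by splicing CDS intervals
in genomic order, reverse-complementing minus-strand genes, and
translating with the standard code; a CDS whose length is not a multiple
of 3 produces a warning and no protein entry.

Gene GC content is computed over the genomic gene span (not the spliced
transcript), with ambiguous bases excluded from numerator and
denominator.  Protein molecular weight uses average isotopic residue
masses plus one water (18.0153 Da); the theoretical pI is found by
bisection on the Henderson–Hasselbalch net charge under the Bjellqvist
pK set with termini included (Biopython's implementation, widened from
its default pH 4.05–12 search window to 0–14 so strongly basic/acidic
peptides are not clamped).

Clustering tiles each chromosome with fixed nonoverlapping windows
(default 250 kb) anchored at coordinate 1, the last window truncated.  A
TF belongs to the window containing its start coordinate — genes can
span window borders, so a single unambiguous assignment rule is needed
and the start coordinate is the conventional choice.  Windows with ≥ 2
TFs are primary clusters.  Merge edges connect primary clusters on one
chromosome whose window indices differ by at most `max_gap + 1`
(default: strictly consecutive) *and* that share at least one family;
merged clusters are the transitive closures (connected components) of
those edges.  The family-sharing test is between the original primaries,
not the growing union — sharing with a merged union would let an
intermediate window bridge families that never co-occur.  Coefficients
of variation use the sample standard deviation over the mean.

## Motif transfer and promoter scanning

Binding motifs are position probability matrices in minimal MEME format.
The reader/writer is exact: probabilities round-trip to 10⁻⁶ (parsers
that regenerate probabilities through integer counts do not).

Motif transfer assigns each query TF the motif of the reference TF with
the lowest e-value under ungapped local alignment of coding sequences
(match +1, mismatch −2), with Karlin–Altschul e-values
`E = K·m·n·e^(−λS)` at λ = 1.33, K = 0.621 — the standard parameters for
that scoring scheme.  Ties break by higher raw score, then
lexicographically smaller subject id.  The default acceptance threshold
is E ≤ 0.001; references without a motif are excluded from candidacy.  A
precomputed tabular hit file (query, subject, score, e-value) can bypass
the internal aligner to consume an external homology search.

Promoters are the ≤ 500 bp immediately 5′ of the annotated gene start on
the coding strand (minus-strand genes: downstream genomic sequence,
reverse-complemented), truncated at chromosome edges with the actual
length recorded.

Scanning follows FIMO's construction: probabilities get a pseudocount of
10⁻³ and are renormalised; log₂-odds scores against the background
(uniform unless the MEME file provides one) are discretised to integer
units of 10⁻³; the null distribution of the window score is computed
exactly by column-wise convolution over that integer grid, and the
p-value of a hit is the null survival function at its integer score.
Because observed scores are computed on the same grid, DP p-values equal
exhaustive enumeration over all 4^L words exactly.  Both strands are
scanned (the reverse strand via the reverse-complemented matrix);
windows containing ambiguous bases are skipped.  The hit threshold is a
p-value (default 10⁻⁴, FIMO's default): per-position scanning has no
natural e-value semantics, so a p-value threshold stands in for the
source pipeline's stated e-value cutoff.  Hit coordinates are reported
as 1-based distances from the TSS to the two match edges, far edge
first, so a 20-nt motif ending 313 bp upstream reads "332–313".

Self-regulation: a TF is flagged iff a hit of its own assigned motif
lies within its own promoter.

## Palindrome-based dimer cooperation

Motifs are reduced to consensus strings (max-probability letter per
column, ties broken A < C < G < T; degenerate IUPAC letters are rejected
since their complementarity is ambiguous).  Two fragments "form a
complete palindrome" when fragment_b equals the reverse complement of
fragment_a — equivalently their concatenation is its own reverse
complement; spacer-tolerant or unequal-half variants are out of scope.
`find_palindromes` returns every (offset_a, offset_b, k) with k ≥ 3
(palindrome length 2k ≥ 6), longest first, via a longest-common-
extension table between consensus A and the reverse complement of
consensus B.  The network keeps one edge per unordered TF pair carrying
the maximal palindrome (all sub-maximal matches remain available),
labels edges within/cross family, and permits self-loops.  A self-loop
contributes 1 to its TF's within-family degree — one cooperating pair —
rather than the 2 endpoint-counting would give.  The co-expression
intersection keeps edges whose endpoints share a non-background module
(module co-membership is the package's operational definition of
"co-expressed"); connected components of the kept subgraph form the
reported cooperation sets.

## Co-expression modules

Genes with TPM < 1 in ≥ 90 % of samples are removed first (the filter is
idempotent).  The network is unsigned: adjacency `a_ij = |cor_ij|^β`.
The soft power β is the smallest candidate in 1..20 whose scale-free fit
reaches R² ≥ 0.9, where the fit is the squared correlation of log₁₀ p(k)
versus log₁₀ k over ≥ 10 connectivity bins; when no candidate qualifies
— typical for strongly modular synthetic data, whose connectivity
distribution is nearly discrete — the β maximising R² is returned with a
warning.  TOM_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij),
diagonal 1.

Modules come from average-linkage hierarchical clustering of 1 − TOM
with a *static* cut (deterministic and fully specified, in place of
WGCNA's dynamic hybrid cut).  When no cut height is given, the package
scans the dendrogram's merge heights and picks the **highest** height
that maximises the number of clusters of size ≥ `min_module_size`
(default 30): among cuts with equally many valid modules, lower heights
strand peripheral genes in sub-threshold splinters (background), while
the highest such cut attaches them to their module — on planted data
this is the difference between adjusted Rand ≈ 0.7 and exact recovery.
Sub-threshold clusters become "background".  Each module's eigengene is
the first right singular vector of its row-standardised expression
(unit norm, sign-oriented to correlate positively with the module's mean
profile).  Modules whose eigengene dissimilarity (1 − correlation) falls
below the merge height (default 0.25) merge iteratively, closest pair
first.  Expression CV defaults to sd/mean (the standard convention; the
reciprocal mean/sd is available via configuration).

## Variation rates and Ka/Ks

Variants are classified by position against gene models with CDS > UTR >
intron precedence inside a gene and "intergenic" outside; multi-allelic
records are split per alternate allele.  Single-nucleotide CDS variants
are called synonymous/nonsynonymous by mutating the affected codon
(strand-aware) and comparing translations; indels and MNVs in CDS are
"other".  Variants are counted as unique sites, not allele occurrences.
Rates are `sites / (region length × sample count)`; family rates divide
by the summed region length of the family members that possess the
region (e.g. intronless members leave the intron denominator), which
reduces to the per-member-length × member-count form when members have
equal region lengths.

Ka/Ks uses Nei–Gojobori (1986): per-codon synonymous site fractions
(fraction of the nine one-step changes that preserve the amino acid;
changes *to* stop codons count as nonsynonymous) averaged over the two
sequences; observed differences are averaged over all substitution
orderings for codons differing at > 1 position, excluding orderings that
pass through a stop codon (falling back to all orderings when every one
is blocked); proportions are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3).  The correction is undefined at p ≥ 3/4 and the
value is then reported missing — note this already happens for toy
single-codon inputs such as TTT/TTC, where one synonymous difference
against ⅓ of a synonymous site gives p_s = 3.  The ratio is reported
only when Ks > 0.  Family Ka/Ks from variants applies each gene's CDS
SNVs to its reference CDS and runs NG86 on the (reference, alternate)
pair; the family value is the mean over members with a defined ratio.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *structures* the pipeline consumes — clustered
gene models with full exon/CDS/UTR hierarchies on both strands, motif
libraries with palindromic half-site pairs, tissue-structured expression,
per-region variant loads — under exactly known truth, with byte-identical
outputs for identical config + seed (one seeded generator per operation).
They do not emulate read-level noise, alignment artefacts, duplicated or
overlapping gene models, population structure, or batch effects across
expression projects; passing tests demonstrate algorithmic correctness
on well-formed inputs, not robustness to messy annotation.

Specific choices:

- **Genomes.**  Default: 4 chromosomes × 1.5 Mb, 18 TF genes across 6
  families plus 12 structural genes — large enough for several windows
  per chromosome yet fast to regenerate inside tests.  Planted cluster
  members are placed inside their specified window with uniform jitter;
  all remaining TFs get one window each so no accidental cluster can
  form, making cluster truth exact by construction.  Genes are real
  ORFs (ATG … stop, no internal stops, GT/AG intron ends), so the same
  bundle feeds translation, promoter and variant tests.
- **Motif libraries.**  A spurious pair exists iff some 3-mer occurs
  somewhere while its reverse complement occurs in another motif.  The
  generator therefore reasons in reverse-complement 3-mer classes: each
  planted half site receives globally private classes; flanks and decoys
  use the {A,C} alphabet (whose complements never appear); fragment/flank
  junctions are standardised (halves start with A, adjacent flank
  letters are C) so junction windows fall into a small reserved class
  set used in one orientation only.  Because the 24 mixed classes cannot
  host many fully independent pairs, planted pairs form half-site
  *stars*: one centre motif carries the half, satellites carry its
  reverse complement, and every centre–satellite combination is a
  planted pair — mirroring the hub structure of real cooperation
  networks.  A brute-force certification pass over all motif pairs
  remains the final gate and is independent of the production detector.
- **Expression.**  Module genes are loading × tissue-profile + Gaussian
  noise, shifted per gene to nonnegative TPM (an affine map, preserving
  the planted Pearson structure).  Defaults — 3 modules of 50 genes,
  noise sd 0.3, 60 samples over 4 tissues — give a clear but not trivial
  recovery problem.  Low-expression genes are forced below 1 TPM in
  ≥ 95 % of samples.
- **Variants.**  Per-region site counts are planted as
  round(rate × region length × samples), so the rate formulas invert
  exactly.  CDS sites are constructed synonymous or nonsynonymous by
  codon arithmetic per the configured fraction; start/stop codons are
  never touched and stop-creating alleles are never planted, so
  variant-derived alternate CDSs always translate.

## Known limitations

- The homology step is a fixed-parameter ungapped aligner, not a gapped
  search engine; distant homologs that need gaps will be missed (the
  tabular-hit input exists for that case).
- Palindrome search operates on consensus strings; information-weighted
  (PWM-level) complementarity is out of scope.
- The static tree cut plus eigengene merge approximates, but is not,
  WGCNA's dynamic hybrid cut; on weakly separated modules the two can
  split differently.
- Family variation rates assume each variant site belongs to exactly one
  gene; overlapping gene models would need a deduplication policy.
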