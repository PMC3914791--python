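# Methods

This note documents the models and procedures rgakit implements, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted on read and write in `rgakit.io` only. Domain hits are
consumed from a minimal 5-column TSV (`gene_id, domain, aa_start, aa_end,
score`, residue coordinates 0-based half-open) rather than raw HMMER
domtblout — converting domtblout is a one-liner (`awk` over columns 1, 4,
18, 19, 14 of the domain table, subtracting 1 from the start), and the
minimal dialect decouples the pipeline from HMMER version drift. A gene is
"anchored" iff it has a chromosome assignment; unanchored genes stay in
the catalog but are excluded from cluster calling, chromosome composition
and (by default) Ks.

## Architecture classification

A gene qualifies as an RGA iff it has an NB-ARC (NBS) hit. The class
label is the left-to-right order of the *first occurrence* of each token
TIR, CC, NBS, LRR along the protein: TNL, NLT, TCNL, TCN, TN, CNL, NL,
CN, N. The label → superclass map is fixed: all TIR-containing labels are
TIR-NBS; NL and CNL are non-TIR NBS-LRR; CN and N are "other". BED and
kinase hits are carried as flags and never enter the label. Proteins with
two NB-ARC hits are classified on the first and flagged `multi-NBS`.

Two deliberately open points were resolved as follows:

- A CC contributed by the coiled-coil scorer has no interval, so its token
  is inserted immediately before NBS — the canonical N-terminal position
  of coiled coils, consistent with every CC-bearing class name.
- Token orders that spell no canonical name (e.g. a C-terminal CC) fall
  back to a content-based label ({T,N,L} → TNL and so on) and are flagged
  `noncanonical-order`; NLT remains reachable only through the literal
  order N, L, T.

## Coiled-coil scoring

The scorer follows the COILS scheme: a window (21 residues by default;
14 and 28 supported) slides over the protein in all seven heptad frames;
each window scores the geometric mean of per-residue, per-heptad-position
propensities; the best score is mapped to a probability through two
Gaussian score distributions (coiled-coil vs globular) with a 30:1
globular prior. The propensity table shipped in `classify.py` is curated
to the canonical coiled-coil signature — hydrophobics favoured at core
positions a/d, charged residues at e/g, proline a near-absolute breaker —
with Gaussian parameters per window size. On this table, five ideal
heptad repeats score > 0.99 while 200-residue random Dayhoff-composition
sequences stay well below 0.9, so the stringent 0.9 acceptance threshold
gives specific CC calls. The threshold is monotone by construction:
raising it can only remove CC tokens.

## Alleles

Putative alleles are same-scaffold pairs with intersecting genomic
intervals whose global protein alignment (BLOSUM62, gap open −11, extend
−1) shows strictly more than 90 % identity over the aligned span, terminal
gaps excluded. Pairs are merged transitively into components; the longest
protein (ties: smallest gene id) represents each component. Alleles are
excluded from clustering, summaries, phylogeny and Ks. Protein rather
than nucleotide similarity is used; at the 90 % level the two are
effectively interchangeable for allele pairs and the protein route reuses
the classifier's sequences.

## Cluster calling

Two or more anchored RGAs form a cluster when each consecutive pair is
within `max_gap` (default 250,000 bp, measured between facing interval
ends) *and* separated by at most `max_intervening` (default 21) non-RGA
genes lying entirely within the open gap. Clusters are maximal chains;
the rule is strand-agnostic. The "average of 250 kb" wording of the
classic Arabidopsis-style definition is ambiguous between a per-pair gap
and a cluster-average spacing; the per-pair reading is the default
(order-independent and the common usage), and
`ClusterConfig(gap_mode="cluster_average")` implements the running-mean
alternative. Larger `max_gap` or `max_intervening` can only grow the
clustered set (verified by property tests against a brute-force
enumerator).

## Summary arithmetic

Percentages of anchored RGAs (clustered share, chromosome shares, top-6
share) are rounded to whole percent, as organization tables print them;
the share of predicted genes and density per Mb to 2 decimals; mean
cluster sizes to 1 decimal. The totals follow the partition invariant
`n_anchored = n_singletons + Σ cluster sizes`.

## Protein distances and trees

Distances come from pairwise comparisons of alignment columns ungapped in
both members (pairwise deletion; complete deletion behind a flag):

- `kimura_corrected`: d = −ln(1 − p − 0.2p²) on the mismatch proportion p;
  pairs past the correction's domain get a configurable ceiling (default
  10) and a saturated flag.
- `dayhoff_ml`: maximum-likelihood distance under a reversible empirical
  rate matrix in Dayhoff's style, built from the symmetric relatedness
  odds of the Dayhoff mutation-data log-odds matrix combined with the
  Dayhoff 1978 equilibrium frequencies (`Q_ij ∝ 10^{S_ij} · f_j`,
  normalized to one expected substitution per site). Each pair's distance
  maximizes Σ n_ij log(f_i P_ij(t)) by bounded scalar optimization, with
  P(t) from a symmetric eigendecomposition computed once.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion. Ties in Q are broken by the smallest sorted pair of subtree
keys (a subtree's key is its lexicographically smallest leaf label), which
makes the tree a pure function of the matrix — the traditional remedy of
jumbling the input order is unnecessary. Negative branch lengths are
clamped to zero with the deficit moved to the sibling branch. The final
three lineages join at a trifurcating root (unrooted convention).

Bootstraps resample alignment columns with replacement (one RNG stream
from the seed; byte-identical reruns), recompute distances under the
configured model and rerun NJ; replicates containing saturated pairs are
kept at the ceiling distance and tallied. The consensus is *strict*
majority rule: exactly the splits in > 50 % of replicates (no greedy
extension with minority splits, unlike Phylip CONSENSE's default
"extended" rule — strictness makes supports exactly interpretable), with
support = round(100 × frequency) written as the label of the child node
of each split.

Clade tools: `genus_specific_clades` reports every internal node whose
leaves carry a single group label, with ≥ `min_size` leaves and a
multi-group parent (so nested single-group clades collapse to the
largest), plus an inventory of which group combinations occur in mixed
clades; `assign_clades` takes clade definitions as input — boundaries of
the kind drawn on published trees are an editorial choice, not an
algorithmic one — and reports monophyly against the tree's splits
(complement-aware, so rooting does not matter).

## Ks estimation and duplication links

Codon alignments are built by threading each CDS through the pairwise
protein alignment (one codon or gap triple per column); translation
mismatches and internal stops are hard errors, a trailing stop codon is
tolerated. Nucleotide-level alignment of diverged NBS genes breaks
reading frames, which is why the protein-threaded route is the only one
implemented.

The estimator is Nei–Gojobori (1986): per-codon synonymous-site fractions
(mutations to stop codons counted as nonsynonymous, so S + N = 3 per
codon) averaged over the two sequences; differences averaged over all
shortest mutational pathways, excluding pathways through stop codons
(falling back to all pathways when none avoids a stop); Jukes–Cantor
correction Ks = −(3/4)·ln(1 − (4/3)·ps), undefined (flagged saturated) at
ps ≥ 0.75. Codons containing gaps or ambiguous bases are skipped
pairwise. `all_pairs_ks` covers every unordered pair of non-allele RGAs —
anchored-only by default, since a survey's pair count C(n_anchored, 2) is
the quantity of record — and short-circuits identical CDS pairs with
cached site counts, which keeps catalog-scale pair counting (hundreds of
thousands of pairs) to seconds.

A chromosome connection is accepted when at least `min_pairs` (default
10) pairs have a defined Ks at or below `ks_threshold` (default 0.25, the
first quartile of the apple RGA Ks distribution; an empirical-quartile
helper is provided, and `strict_less` switches the boundary to <).
Intra-chromosome pairs yield self-links, capturing tandem and
within-chromosome duplication.

## Synthetic data

The generator emulates the statistical structure a real RGA survey
confronts: clustered RGA placement among non-RGA ORFs (planted chains
with controlled spacing and intervening counts, blocks separated by
400 kb so only planted chains satisfy the rule), overlapping same-scaffold
allele pairs at a chosen protein similarity, WGD partners produced by
applying synonymous single-nucleotide substitutions in distinct codons
until the implied NG86 divergence reaches the target Ks, per-chromosome
TIR-fraction bias, and exon-count contrasts (TIR-class genes drawn with
higher exon counts). Domain content is marked with fixed sentinel motifs
(the NBS motif is the real P-loop) so the domain-hit TSV is consistent
without a profile search; coiled-coil segments are genuine heptad
repeats, so the CC path exercises the real scorer. One RNG stream per
concern, all derived from the master seed, keeps outputs byte-identical
across reruns and stable when a new feature is added.

What the generator does *not* model: realistic intergenic or intron
sequence, indel evolution within CDS, profile-search score noise, partial
or fragmented gene models, or nonsynonymous divergence between WGD
partners (planted partners differ only synonymously). Exact-recovery
results on synthetic genomes therefore demonstrate the correctness of the
rules and estimators under clean inputs, not robustness to annotation
error; the published genome-scale counts (total RGAs, per-chromosome
rows) enter the tests only as printed-table fixture inputs.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen to
exercise every code path with comfortable margins: catalog arithmetic on
the full 868-RGA fixture including all C(778, 2) = 302,253 anchored
pairs; 200 random layouts × parameter grid against the brute-force
cluster enumerator; 100 random additive 8-leaf matrices for NJ; 100
NG86 replicates × 300 codons at each true Ks; a 6-chromosome synthetic
genome with a 21-member cluster, 3 allele pairs and two WGD doublets
(12 and 11 pairs); 20 simulated 8-leaf × 400-column alignments for
topology recovery.
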