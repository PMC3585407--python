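# Methods

`candevo` implements the comparative-genetics workflow used to characterize
a deeply conserved developmental gene across a dated phylogeny: a
substitution census and selection statistics on the open reading frame, and
conservation/motif analyses on the untranslated regions, together with the
statistics of a fluorescent reporter assay and a ground-truthed simulator
for all three data types.

## Open-reading-frame analyses

**Substitution census (Fitch parsimony).** For each residue column of the
protein alignment, the census counts the Fitch parsimony length on the given
rooted tree — the minimum number of state changes consistent with the leaf
states, obtained by the intersection/union bottom-up pass. Missing states
('X', '-', '?') are removed from the state sets rather than treated as a
21st character, so incomplete coverage can only lower, never inflate, the
count. Summaries: V variable sites (count ≥ 1), M recurrent sites
(count ≥ 2, the homoplasy signal), T total changes, and T/V. The pairwise
fold over children makes the pass exact on binary trees and a deterministic
resolution on polytomies. Degenerate inputs (all-invariant alignment, or a
column with fewer than two resolved leaves) return zero with a flag.

**Convergence report.** At each recurrent site, leaves are grouped by
residue; a state carried by ≥ 2 leaves that is not unambiguously ancestral
(not the sole Fitch root state) and whose carriers are not monophyletic
among the leaves resolved at that site implies independent origins.
Monophyly is tested against the leaf set below the carriers' MRCA,
restricted to resolved leaves so missing data does not break clades.

**Exon enrichment.** Given per-residue replacement counts and an exon map
(0-based half-open codon coordinates), each exon is scored with the
upper-tail cumulative binomial P(X ≥ r_e), X ~ Binomial(R, L_e/L), where R
and L are the replacement total and residue length over covered exons.
Values are raw; no multiple-testing correction is applied, matching how such
per-exon probabilities are conventionally reported.

**Synonymous/nonsynonymous counting.** Per sense codon, the synonymous site
count s sums over the three positions the fraction of viable single-step
neighbors encoding the same amino acid; mutations to stop codons are
excluded from the viable set, so s + n = 3 exactly. Codon pairs are compared
by averaging synonymous/nonsynonymous steps over all orderings of the
minimal mutational pathway, dropping orderings that pass through a stop and
renormalizing. Both tables (61 codons, 61×61 pairs) are precomputed at
import and all alignment-scale operations are table lookups.

**Neutrality Z-test.** Mean dN and dS are taken over all sequence pairs
(codons with gaps/N/stops skipped pairwise); the standard error of
(mean dN − mean dS) comes from B bootstrap resamples of codon columns
(default B = 1000, minimum 100), and P-values from the standard normal. The
resampling unit is the codon column, so pair-level covariance is preserved.
An alignment with no differences returns a flagged degenerate result.

**Per-site selection test.** Ancestral codons per site are reconstructed by
Fitch parsimony over codon states, ties broken deterministically (parent
state preferred, else lexicographically smallest), and each branch's codon
pair contributes pathway-averaged synonymous/nonsynonymous steps cs and cn.
The expected synonymous proportion p_s is the mean synonymous site fraction
(s/3) of the codons observed at the site. Exact binomial upper tails for
excess nonsynonymous and excess synonymous changes are computed with the
regularized incomplete beta function, which extends the tail to the
fractional counts that pathway averaging can produce. Parsimony rather than
joint maximum-likelihood ancestral codons is a deliberate simplification;
the reconstruction is isolated behind this one function and can be swapped.

**Saturation regressions.** Distances are deliberately uncorrected
difference counts (nucleotide or amino acid, unresolved positions skipped
pairwise): the analysis *wants* multiple hits to show up as loss of
linearity when differences are regressed on t_mrca (OLS; slope, intercept,
R² reported). t_mrca is the age of the pair's MRCA, with node age defined as
the maximum branch-length path to a descendant leaf — on a non-clock tree
this is a lower bound on the calibration. A pair filter (predicate or
explicit list) selects e.g. within-clade vs between-clade pair sets; a fit
needs ≥ 3 pairs spanning ≥ 2 distinct times.

**Neighbor-joining.** Trees come from scikit-bio's Saitou–Nei implementation
on the same raw distances; bootstrap support resamples alignment columns,
recomputes distances and trees, and reports the percentage of replicates
containing each non-trivial bipartition of the full-data tree.

## Untranslated-region analyses

**Divergence profile.** Column divergence is 1 − (modal base frequency)
among resolved bases; profiles are sliding-window means (gap-only columns
excluded). A column is "variant" when ≥ 2 distinct resolved bases occur.

**Shadowing HMM.** A two-state HMM over binary column variant indicators:
conserved columns are variant with probability θ_c, nonconserved with θ_n.
θ_c is calibrated as the variant-column fraction of the open reading frame —
coding sequence defines what "conserved" means for the taxon set — with a
1/(n+2) pseudocount, and is held fixed. θ_n is initialized from the overall
UTR variant fraction (error if not above θ_c: the calibration is then
uninformative) and refined, together with the transition matrix, by
Baum–Welch on the UTR columns; the fixed-θ_c update keeps the EM likelihood
monotone and anchors the conserved state. Initial stay-probabilities are
1 − 1/(2·ℓ_min). Islands are maximal conserved-state runs of the Viterbi
path of length ≥ ℓ_min (default 50 nt), reported with mean divergence and,
when the alignment carries start/stop anchors, offsets to those anchors.
ℓ_min and the pseudocount are pragmatic defaults for island-scale (≥ tens of
nt) conserved elements; they are not fitted quantities.

**Motif scanning.** The built-in pattern is the Musashi binding element
R T{n} A G T, n ∈ {1,2,3} (DNA representation), scanned on the sense strand
only since these are mRNA regulatory elements. The pattern interface is a
degenerate IUPAC prefix + homopolymer run with bounds + suffix, so other UTR
elements can be screened. At a shared start the longest admissible run wins
(for the MBE at most one n can match a given start, so the scan equals an
exhaustive substring check); with overlap disallowed, scanning resumes after
each hit. Per-taxon hits on ungapped sequences are mapped to alignment
columns and merged into loci by single-linkage span overlap; the locus ×
taxon presence matrix yields per-locus cross-taxon frequencies.

## Reporter statistics

Per-measurement green/orange ratios (green is the internal transfection
control) are grouped by construct line and compared with the tie-corrected
mid-rank Kruskal–Wallis H and its chi-square approximation; all-tied data
returns H = 0, P = 1 with a flag. An exact permutation P (full enumeration
over group-size arrangements, feasible for reporter-sized tables) is
available as a cross-check: in the effect-bearing regime such tables occupy,
the chi-square P tracks the exact P to within ~0.01–0.02, though the
approximation is looser mid-range under the null. Shapiro–Wilk (scipy's
Royston approximation, 3 ≤ n ≤ 5000) screens normality; a
leave-one-group-out sweep recomputes H with each line excluded.

## Synthetic data

The generator defines the study conditions and emits full ground truth.

*Tree*: Yule topology on 12 taxa scaled to a 30-My root (or a user Newick).
*ORF*: 342 sense codons; per branch and site, candidate events arrive as a
Poisson process at 3 × rate × t per codon (background rate 0.002 /nt/My; 5%
hotspot sites at 10×); each event proposes a uniform viable (non-stop)
single-nucleotide neighbor, accepted with probability 1 if synonymous, ω
otherwise (ω = 0.05 background, 1.0 at hotspots). Because stop-creating
proposals are excluded from the proposal set rather than counted as rejected
events, the realized event count at ω = 1 is exactly
Poisson(Σ branches · rate · 3 · n_codons). The root sequence is uniform over
sense codons. Truth records every node's sequence, per-site accepted event
counts (total/syn/nonsyn), and per-branch event multiplicities — a site hit
twice on one branch can revert, so parent–child differences equal event
counts exactly only on single-hit sites, and tests distinguish the two.
*UTR*: 800 nt, background mutation rate 0.02 /nt/My against islands of 146
and 204 nt at 0.001 (high background divergence, sharply conserved islands);
four motif loci carry exact MBE instances with per-taxon retention
probabilities 0.92, 0, 0.25, 0.75; a non-retained taxon receives disrupting
substitutions until no element instance overlaps the locus. Motif columns
follow this presence process instead of the column mutation process, and the
default loci sit in the divergent background so the island and motif
processes are independent features. *Reporter*: five lines (no-element
control, 2, 3, 3b, 4 elements) × 4 replicates; green ~ 1000·(1 + 0.05·N),
and orange is scaled so the green/orange ratio equals the line mean × (1 +
0.08·N), line means 1.0 / 0.55 / 0.75 / 0.80 / 1.25.

What the generator does *not* emulate: indels and alignment error (all
alignments are gap-free), codon usage and GC bias (uniform root, uniform
proposals), rate variation beyond the two-class hotspot model, lineage-
specific rates, and correlated motif loss. Passing recovery tests therefore
shows the inference machinery is correct under the stated model, not that
real alignments meet those assumptions.

All randomness in a simulation flows from one integer seed through named
substreams (tree/ORF/UTR/reporter), so each stage is byte-reproducible and
toggling one stage never perturbs another; the pipeline derives per-stage
seeds the same way from its configured seed, and identical configurations
produce byte-identical reports and tables.

## Problem sizes used in the shipped checks

The automated checks run at desk scale by design: neutrality calibration
uses 8 taxa × 200 codons over 100–200 replicates with B = 200; island
recovery and motif-truth checks use the 12-taxon default conditions over
10–25 seeds; the exhaustive Fitch cross-check covers every rooted topology
on ≤ 6 leaves with 200 random columns each; the saturation contrast uses an
8-taxon, 100-My ladder tree with 300 codons.

## Known limitations

- Fitch-based per-site counts can under-count relative to the true history;
  the census is a lower bound by construction.
- The HMM's binary emission discards how *many* taxa differ per column; a
  column with one divergent taxon and one with twelve look identical.
- Node ages on non-ultrametric trees are max-depth lower bounds, not
  calibrations; supply externally dated trees for publication-grade t_mrca.
- The neutrality Z rests on a normal approximation to the bootstrap
  distribution; with very few codons the bootstrap SE is noisy (B ≥ 100
  enforced).
- NJ bootstrap support is support for splits of the full-data tree only.
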