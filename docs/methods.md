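# Methods

## Scope and shape

`pa2c` implements a desk-scale analogue of a genome-wide PA2c-domain
family survey: motif-based discovery, family/clade classification,
disulfide arithmetic, a three-clade phylogeny with bootstrap, motif
logos, promoter cis-element counting and clade-wise expression
summaries.  Genome mining, external annotation servers (ScanProsite,
SignalP, PlantCARE), MAFFT alignment and maximum-likelihood tree
inference are deliberately out of scope; where the original analyses
used such services, this package substitutes transparent, dependency-free
procedures and says so below.  All inputs are plain text (FASTA, TSV,
JSON, newick) and every analysis can run on synthetic data from the
bundled generator.

## Motif engine

Patterns are uppercase literals plus lowercase `x` wildcards — the only
constructs the four diagnostic motifs need.  Bracket classes and `x(n)`
repeats are an extension point, not implemented.  Matching is
conservative under ambiguity: `X` satisfies a wildcard but never a
literal, and `N` in DNA never matches.  All overlapping matches are
reported; consumers take the left-most hit of each motif class, which
makes downstream decisions order-independent.  The approximate PA2c
domain span runs from the calcium-loop start to the catalytic-motif end;
a catalytic hit upstream of the loop is flagged rather than spanned.

The historic catalytic spelling with alanine at position 2 (`DACC...`)
is a strict sub-case of the family-wide `DxCCxxHDxC`; the engine bundles
the general form and records the `DACC` sub-case as a boolean feature.

## Signal-peptide heuristic

A transparent stand-in for annotation-server calls: a sequence is called
secreted iff it starts with Met and a window of ≥ 8 consecutive residues
with mean Kyte–Doolittle hydropathy ≥ 1.6 begins within residues 2–12.
The cleavage estimate is the end of the contiguous per-residue
hydrophobic run plus 3, capped at residue 35.  Window length, threshold,
onset limit and cap are module constants.  Sequences under 25 residues
are undetermined (flagged, treated as negative).  This is not a trained
predictor; on real proteomes it will miss atypical signal peptides, and
the generator constructs peptides that satisfy or violate it by design
so the classifier's contract can be tested exactly.

## Classification

The cascade is: (1) either motif absent → nonPA2c; (2) both variant
motifs and no signal peptide → PLA2-like; (3) both canonical motifs and
a signal peptide → sPLA2; (4) any mixed combination → the family of the
calcium-loop variant with `MOTIF_CONFLICT`/`SP_CONFLICT` flags (the
calcium loop is the primary diagnostic; conflicts are surfaced, never
silently resolved).  QC flags mark atypical cysteine censuses (≠ 12 for
sPLA2, ≠ 6 for PLA2-like) and length-window violations.  The 90–191
window is applied to the *mature* (post-cleavage) length — the heuristic
cleavage point, so a mutation-broken hydrophobic run can shift the
estimate; length flags are QC, not classification inputs.  The cysteine
census counts from the domain start to the sequence end, because the
family-defining counts are quoted per protein rather than per exactly
delimited domain.

Alpha versus beta is a phylogenetic distinction with no single-site
signature, so the sequence-level call is a nearest-centroid decision:
mean global-alignment score (BLOSUM62, affine 10/1) against ≥ 2 labeled
references per clade, with an unresolved band when the margin is below
2% of the observed score range.  Tree placement (below) provides an
independent second opinion.

## Disulfide arithmetic

Bridge capacity is `⌊n_Cys/2⌋`.  The canonical six-bridge template
carries only the two published PLA2-like pairs (C140–C167, C166–C192, in
PLA2-like residue numbering); the remaining four pairs are explicit
`UNSPECIFIED` placeholders excluded from retained-bridge claims — the
full canonical pairing is not published and is not invented here.  The
six-cysteine/three-bridge capacity statement and the four-conserved-
positions/two-retained-bridges template statement answer different
questions and are both exposed without reconciliation.

## Phylogenetics

Distances: global pairwise alignment (BLOSUM62, gap open 10 / extend 1),
p = mismatch fraction over aligned non-gap columns; optional Poisson
correction −ln(1−p), capped at −ln(0.05) for p ≥ 0.95.  When a fixed
multiple alignment is supplied (or produced by the generator), distances
come from its columns directly.

Tree inference is Saitou–Nei neighbor joining.  This is an explicit
substitution for maximum-likelihood inference: deterministic, seconds on
a laptop, and sufficient for clade-recovery claims on desk-scale data;
outputs are labelled as NJ.  Join ties break lexicographically on
cluster representative labels, so the tree is a pure function of the
matrix.  Negative branch lengths are clamped to zero and counted.
Bootstrap resamples alignment columns; replicate *r* draws from
`default_rng([seed, r])`, making runs reproducible and replicates
independent.  Support is the percentage of replicate trees containing
each internal bipartition of the base tree.

Monophyly: a label group is monophyletic iff some edge separates exactly
its leaves; the bipartition set is computed in a rooting-invariant
canonical form, so the count is invariant under re-rooting and leaf
order.  Tree placement joins the query by NJ and reads the labels of the
attachment node's neighbor subtrees: if the label-pure neighbors agree
on one clade the query takes it, otherwise unresolved (covers both a
query on the edge between two clades and noisy attachments).

In MSA mode, columns with > 50% gaps are implicitly down-weighted only
through the pairwise shared-column rule; no manual curation of
non-conserved regions is emulated.

## Sequence logos

Schneider–Stephens information content per column:
`IC_j = log2(S) − H_j − e(n)` with `e(n) = (S−1)/(2·ln2·n)`; the
correction defaults on for blocks under 50 sequences.  Gaps and
ambiguity letters are excluded from both the frequencies and *n*; IC is
clamped at zero; letter height is frequency × IC, so heights sum to the
column IC.  Glyph rendering is a plain stacked-bar SVG; typographic
fidelity to web logo services is a non-goal.

## Promoter scanning

The bundled dictionary holds the 14 elements with a published consensus;
elements known only by name ship disabled, requiring a user-supplied
consensus.  Scanning is exact IUPAC consensus matching on both strands
with overlaps allowed; a locus matched on both strands (palindromes such
as the G-box) counts once, avoiding a systematic ×2.  Counts from exact
consensus matching will not numerically reproduce matrix-based servers
on real promoters; correctness is defined against planted ground truth.
The display matrix clips at 5 copies (heatmap convention: 0 = absent,
5 = five or more).

## Expression summaries

Presence is "any gene of the clade ≥ threshold in that tissue", default
1 TPM; the log2(TPM+1) display transform and the threshold are
conventions, both configurable.  The male-gametophyte tissue set
defaults to {anther, pollen, pollen tube}; dominance means the clade's
maximum over that set exceeds its maximum elsewhere.  Tissue names are
free text and matched literally.

## Synthetic generator

The generator's defaults are the study conditions, not tuning knobs:
mutation rate 0.05 substitutions/site outside protected anchors, 8
sequences per clade, 2000-nt promoters at 50% GC, and lognormal TPM with
the alpha clade hard-zeroed in pollen/pollen tube and the beta clade
given the largest location parameter (natural-log mean 5 vs 2, sigma
0.5) in male tissues.

Proteins descend from fixed clade centroids built once from a constant
seed: canonical centroids are Met + charged pair + 12-residue
hydrophobic run + motif-anchored core with exactly 12 cysteines (2 in
the calcium loop, 3 in the catalytic motif, 7 planted downstream of the
loop); the PLA2-like centroid has a 100-residue disorder-biased
N-extension and 6 cysteines.  Alpha and beta share the architecture but
have independent random fillers (≥ 25% divergence outside anchors).
Mature/total lengths are drawn inside the family windows by variable
C-terminal padding (the beta KxEL terminus is preserved).  Substitutions
draw from the 19 non-cysteine residues, so the census is exact at any
rate; motif literals and counted cysteines are immutable unless
`protect=False`.  The initiator Met is *not* protected, so at the
default rate a few percent of canonical sequences lose the detected
signal peptide and flow through the flagged conflict path — family
assignment is unaffected, which the round-trip tests assert.

Families for phylogeny are mutation-only descendants (no length
padding), giving an indel-free reference alignment by padding rows so
the calcium-loop anchors coincide — exact by construction, and the
reason bootstrap column resampling is meaningful.  This deliberately
omits indel evolution, rate heterogeneity and compositional drift;
passing tests demonstrate pipeline correctness on anchor-preserving
families, not performance on real, indel-rich PA2c alignments.

Promoters are scrubbed: accidental library matches in the random
background are rewritten until a full scan reproduces exactly the
planted ground truth (matches inherent to a planted consensus itself,
e.g. the two methyl-jasmonate elements being reverse complements, are
part of that ground truth).  Planted loci are spaced by at least the
longest consensus, so they never overlap.

## Numerical and degenerate-input choices

1-based inclusive coordinates throughout.  Stop codons are stripped with
a warning.  Alignment ties resolve to Biopython's first reported optimal
alignment; NJ ties resolve lexicographically; all-gap logo columns carry
zero IC; a pair with no shared alignment columns gets the maximum
distance.  Every stochastic routine takes an explicit seed or
`numpy.random.Generator`; nothing touches global RNG state.

## Problem sizes

Defaults used by the test suite and the acceptance script: families of
8 × 3 sequences with 100 bootstrap replicates, classifier sweeps of
100–200 sequences per clade, 5–10 generator seeds for expression and
promoter checks, property tests on sequences ≤ 50 aa / ≤ 200 nt.  These
sizes exercise every code path while keeping a full run in seconds;
all routines scale to hundreds of sequences without modification.

## Known limitations

Signal-peptide detection is a heuristic, not a predictor.  The
alpha/beta centroid call depends on the reference panel.  NJ with
p-distances is not ML; support values are standard bootstrap
percentages.  Promoter counts are exact-consensus, not matrix-based.
The generator's families are indel-free and anchor-protected —
real-data performance claims cannot be read off these tests.
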