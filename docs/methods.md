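# Methods

## The coordinate system

Family GH13 alpha-amylases share a (beta/alpha)8 TIM-barrel catalytic
domain carrying eight short conserved sequence regions (CSRs).  Read in
their order along the chain — CSR-VIII (strand beta1), CSR-VI (beta2),
CSR-I (beta3), CSR-V (domain B), CSR-II (beta4), CSR-III (beta5),
CSR-IV (beta7) and CSR-VII (beta8) — and concatenated, they form a
55-column *fingerprint* that is the package's fixed coordinate frame:

| CSR | fingerprint columns | width |
|-----|--------------------:|------:|
| VIII | 1–3   | 3 |
| VI   | 4–12  | 9 |
| I    | 13–18 | 6 |
| V    | 19–23 | 5 |
| II   | 24–32 | 9 |
| III  | 33–40 | 8 |
| IV   | 41–46 | 6 |
| VII  | 47–55 | 9 |

Landmark columns: the catalytic nucleophile Asp at 28 (CSR-II), the
proton donor Glu at 37 (CSR-III) and the transition-state stabilizer
Asp at 46 (CSR-IV); the chloride-binding triad sites at 26 (Arg), 44
(Asn) and 50 (Arg/Lys).  One documented oddity of the source
literature: the GH13_42 C-terminal motif YYGS is described as spanning
positions 53–56 even though the logo has 55 positions; the layout caps
at 55 and this inconsistency is recorded, not resolved.

## Anchoring

Published CSR assignments rest on expert curation of the multiple
alignment.  The reproducible equivalent used here is *reference-guided
anchoring*: one alignment row comes with known 1-based ungapped CSR
start positions and triad positions (a `ReferenceAnnotation`); mapping
those positions through the row's gaps pins all 55 fingerprint columns
to alignment columns.  Two hard checks guard the mapping: the
reference must show Asp/Glu/Asp at its triad columns, and it must be
gap-free inside every CSR span (CSRs are gapless blocks of fixed
width; an insertion against the reference inside one would break the
layout).  Rows gapped at an anchored column contribute `'-'` at that
fingerprint position.

When no annotated row exists, `infer_reference_by_conservation` can
guess one: it scans for the most conserved Asp/Glu/Asp column triple,
sharpened by two family-invariant context signals (Arg two columns
before the nucleophile, Asn two before the stabilizer) and by the
conservation of the whole CSR window each candidate implies, then
places the remaining CSR windows greedily by window conservation with
a preference for gapless column blocks.  This is a heuristic for
exploration; it needs conserved CSRs over a variable background (a
noise-free family is featureless to it), and an annotated reference is
always preferred.

## Site rules

**Chloride triad.**  A sequence is called chloride-binding-capable
exactly when fingerprint column 26 is R, 44 is N and 50 is R or K
(lysine marks the `lys` variant).  Any other letter, `X`, or a gap
marks the site as missing; no other column influences the verdict.
The positively charged His is deliberately not accepted at column 50 —
only Arg/Lys are documented coordinators.  The rule is strictly
boolean; hedged biological cases are expressible only through the
verdict plus variant fields.

**Surface-binding sites (SBSs).**  SBSs are known only from solved
complex structures; the package ships five templates (PDB 2GUY/2GVY,
2GJP, 6TOZ, 3BC9, 3BLP) with their named sites and residue numbers in
both mature and precursor numbering (the two differ when an
N-terminal signal peptide is retained; the caller declares which
applies to the alignment at hand).  Template residues are mapped
through the template's alignment row to columns, with a hard check
that the row actually shows the template letter at each mapped column.
Conservation summaries count observed letters and the aromatic
fraction, with aromatic = {F, W, Y}; histidine is excluded.  Published
correspondence grids for GH13_1 (39 records), GH13_5 (35) and GH13_24
(23) ship as plain TSVs for regression use.  Where the literature
disagrees with itself (the B. paralicheniformis second SBS residue is
printed both as Y358 and Y368), both readings are kept, the second as
a documented variant.

## Logo statistics

Per fingerprint column: counts over the 20-letter alphabet (gaps and
`X` excluded), information content in bits `IC = log2(20) − H` with
`H = −Σ p·log2 p`, optionally reduced by the small-sample correction
`e_n = 19/(2·ln2·n)` (default off, since the rendering service whose
output the statistic mirrors does not document its setting), and the
most frequent letter as consensus (alphabetical tie-break).  One
profile set is produced per subfamily plus one pooled set — seven for
a full six-subfamily input.  Stacked-letter graphics are out of scope;
the numeric table is the tested surface.

## Alignment

Pairwise global alignment uses BLOSUM62 with affine gaps, open 10 and
extend 0.5 (a gap of length L costs `open + (L−1)·extend`); these are
classic defaults, configurable, and the pairwise engine is Biopython's
`PairwiseAligner`.  The progressive multiple aligner builds a UPGMA
guide tree on 1 − identity distances and stacks profile–profile
alignments up the tree, scoring column pairs by expected substitution
score (gap symbols score 0) and breaking traceback ties diagonal
first.  Identity is matches over residue–residue columns — the least
length-biased common convention, used both for the guide tree and for
redundancy filtering.  Externally computed alignments can be imported
at any point and are first-class.

Redundancy filtering is greedy: records visited longest-first (ties by
accession), each kept only if its identity with every kept
representative is ≤ the threshold (default 0.90; strictly above 90%
triggers removal).  The longest-first rule is a documented choice —
the curation practice it mirrors does not state which member of a
near-identical group was retained.  No k-mer prefilter is attempted;
the intended scale is hundreds, not tens of thousands, of sequences.

## Trees

Two trees are built per study: one on the alignment segment spanning
strands beta1..beta8 (obtained by trimming at the anchored CSR-VIII
start and CSR-VII end) and one on the 55-column fingerprint alignment.
Distances are p-distances with pairwise deletion (complete deletion
available); trees are classic neighbor joining with deterministic
tie-breaking (first minimum of the Q-matrix in row-major order) and
negative branch lengths clamped to zero.  NJ recovers additive
distances exactly and is deterministic at desk scale; it stands in for
the likelihood inference a dedicated phylogenetics program would do,
and both alignments can be exported (aligned FASTA/PHYLIP) for such a
program.  Bootstrap supports resample columns with replacement,
rebuild the NJ tree per replicate, and count replicates containing
each original split; the default of 500 replicates follows the study
design this pipeline mirrors, while tests use 25–100.  Supports are
integer counts attached as internal-node labels in Newick output.

## Synthetic families

The generator emulates the statistical structure of a curated
subfamily alignment: eight consensus CSR motifs at the layout widths
(landmarks D28/E37/D46 always; R26/N44 plus R, K or Q at 50 according
to the chloride option), joined by seven linkers whose lengths are
drawn uniformly from per-gap ranges (default 4–12) out of a
family-wide consensus, with point substitutions at a configurable
per-position rate (default 0.05).  Landmarks, planted SBS aromatics
and (by default) whole CSR blocks are never mutated.  Optional fixed
signal peptide and C-terminal tail exercise mature-vs-precursor
numbering and trimming.  Default chloride triads are RNR for
GH13_15/24 and none elsewhere, matching the biology the site rule
encodes.  Every family comes with a truth table (fingerprints, CSR
starts, triad positions, capability labels, planted SBS positions)
and a *truth alignment* built by right-padding each linker to its
family-wide maximum, so CSR columns align exactly — the oracle against
which anchoring and extraction are tested.

What the generator does **not** emulate: substitution-model evolution
along a tree, indels inside CSRs, compositional biases, or genuinely
homologous linkers between subfamilies.  Passing recovery tests on
synthetic data therefore demonstrates the correctness of the
coordinate bookkeeping and site rules, not the aligner's robustness on
real, indel-rich families — for real data the external-MSA import path
plus a curated reference annotation is the recommended route.

## Numerical and scale choices

Problem sizes in the shipped tests and acceptance script are chosen
for a single-CPU desk run: recovery uses 20 seeds × 60 sequences, the
alignment oracle enumerates all sequence pairs of length ≤ 5 over a
3-letter alphabet in the test suite (length ≤ 4 in the acceptance
script), NJ correctness uses 50 random additive matrices on 5–8
leaves, and bootstrap tests use 25–100 replicates.  All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
pipeline outputs contain no timestamps, so identical config + seed
reproduces byte-identical artifacts.  Alignment traceback ties, NJ
Q-matrix ties and consensus-letter ties all break deterministically
(documented above), which is what makes bit-for-bit reproducibility
possible.

## Known limitations

- Anchoring requires all eight CSRs present at full width; families
  with degenerate or missing CSRs are out of scope.
- The identity computation has no fast prefilter; redundancy filtering
  is quadratic in the number of sequences.
- The conservation fallback can be misled by chance conserved columns
  in small noisy families; it is a convenience, not a substitute for an
  annotated reference.
- NJ topologies are not likelihood estimates; for publication-grade
  trees, export the alignments and use a dedicated ML program.
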