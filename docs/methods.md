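# Methods

## The problem

Given annotated proteomes spanning the deep eukaryote lineages, which
components of a protein complex — here the nuclear pore complex (NPC) and
the COPI/COPII/clathrin coatomer complexes — were already present in the
last eukaryotic common ancestor (LECA)?  The pipeline has three stages:

1. **Screening**: find candidate homologs of each component in each
   proteome with a position-specific scoring profile, then vet candidates
   with rules that discount repeat-confined similarity.
2. **Profiling**: record the accepted calls as a binary components ×
   genomes presence/absence matrix and collapse it to the five eukaryote
   supergroups (Opisthokonts, Amoebozoa, Plantae, Chromalveolates,
   Excavates) by OR over member genomes.
3. **Reconstruction**: assign each component to the root by Dollo
   parsimony under alternative rootings of the eukaryote tree, with an
   unrestricted-parsimony pass to flag root states that are not forced.

The package also ships, as plain text, the presence/absence tables of a
published comparative survey of 31 nucleoporins across 51 genomes (plus a
fungal anchoring-Nup panel, a *Trypanosoma brucei* proteomics control set,
and a 27-component coatomer table across 46 genomes), so the headline
reconstructions are reproducible from the repository alone.

## Profile scoring

A seed alignment is converted to one log-odds column per match state.
Columns with more than 50% gap characters are treated as insert columns
and dropped.  Column residue frequencies are mixed with Robinson–Robinson
background frequencies using a fixed pseudocount weight (default 1.0
background-distributed pseudo-observation per column), which keeps every
score finite; scores are `log2(freq/background)` bits.  The ambiguity code
`X` scores 0 bits everywhere.

Scoring a protein is an affine-gap alignment of the profile to the
sequence (gap open 4.0 bits, extend 0.5 bits, uniform across columns).
Alignments are canonical: they start and end on a match state, and an
insertion is never adjacent to a deletion.  `local` mode maximises over
segments and returns an empty zero-score hit when nothing scores positive;
`global` mode consumes every profile column, charging gap costs for
skipped flanking columns while the protein's own ends are free.  Ties are
broken toward the leftmost interval start, then the shortest interval, so
results are deterministic and independent of input order.  The dynamic
program is verified against an independent alignment-path enumeration
oracle on small instances (both modes).

These are profile scores in bits, comparable across proteins for a fixed
profile; no E-value calibration is attempted, and thresholds are explicit
knobs — absolute bits or a quantile of an empirical decoy score set —
because any fixed constant would be specific to one scoring scheme.

## Vetting rules

Two repeat classes are operationalised as window sets on the candidate
sequence:

* **FG**: every FG dipeptide occurrence (covering GLFG/FxFG contexts)
  expanded by ±2 residues, merged.
* **WD**: up to 40 residues upstream of the end of every
  `[LIV]-x(6,12)-W-D` match, merged.

A hit whose matched positions fall inside repeat windows at ≥ 0.9 coverage
is rejected as repeat-only similarity *unless* a component-specific motif
(e.g. the SIEGR motif that distinguishes Rae1 among WD-repeat proteins)
occurs outside the windows; coverage ≥ 0.75 on an accepted hit raises a
caution flag rather than a rejection, mirroring how a WD-confined but
otherwise plausible candidate should be kept visible but marked weak.
Components may also declare required motifs whose absence anywhere in the
protein rejects the hit outright.

Reciprocal validation re-scores the candidate against a labelled reference
proteome using substitution-matrix local alignment (BLOSUM62, −11/−1) and
passes only if the best reference protein (ties broken by id) carries the
candidate's component label.  The reference is the shipped labelled
training set, not an external database, so the pipeline runs offline.

Rescue search, for genomes where the primary profiles find nothing,
re-screens the proteome with profiles built from single donor sequences of
related genomes at a permissive threshold — a one-sequence profile
alignment is exactly a pairwise log-odds alignment — so rescue at the
primary threshold reduces to the donor-profile screen, and lowering the
threshold only adds candidates.  Rescued hits re-enter vetting and
reciprocal validation.  Only protein-vs-protein search is implemented;
six-frame translated search is out of scope.

## Parsimony reconstruction

Under Dollo parsimony a component arises exactly once, on the edge above
the last common ancestor of all carriers, and may be lost repeatedly; the
loss set is the maximal all-absent subtrees below the gain, and the cost
is 1 + #losses.  The root carries the component exactly when the gain maps
to the root edge, which depends only on the root bipartition — so the LECA
complement is insensitive to the arrangement inside each side of the root.
Per-lineage event tables do depend on that arrangement; the default
within-side shape is ((Plantae,(Chromalveolates,Excavates)) against
(Opisthokonts,Amoebozoa)), and any rooted (possibly multifurcating)
Newick topology can be supplied instead.

The ambiguity flag reproduces the "gain or loss equally probable" mark:
a component is flagged when an unrestricted binary parsimony mapping
(gains and losses both unit cost, root state free) achieves the opposite
root state at no more than the Dollo cost.  Both the Dollo cost and the
flag are verified against exhaustive enumeration of every internal-state
assignment on all topologies with ≤ 5 leaves (all state vectors) and on
random larger trees.

Built-in rootings: `excavate_basal` (Excavates as outgroup),
`unikont_bikont` (root between {Opisthokonts, Amoebozoa} and the rest),
and `star`, which treats the supergroup tree as unresolved and reports
bounds instead of a set: the lower bound is the number of components
present in every supergroup, the upper bound the smallest per-supergroup
component count (with the supergroup attaining it).

Absence and missing data are not distinguishable from the matrix alone;
states are strictly binary, with an optional per-cell "unknown" mark that
is excluded from OR-collapse (the shipped tables contain none).

## Phenotype association

The fungal anchoring-Nup table is tested against the open/closed mitosis
phenotype with a 2×2 exact conditional test (Fisher; the two-sided p sums
all margin-preserving tables no more probable than the observed one).  The
original survey reported the Pom34 pattern without a statistic; the test
is this package's addition and the rendered report labels it as such.
A *perfect* association additionally requires both off-diagonal cells to
be zero.

## Synthetic data

The generator mirrors the reconstruction's own assumptions, which means
passing tests demonstrate internal consistency and calibration, not
performance on real proteomes:

* **Trees**: uniform sequential leaf attachment, rooted binary.
* **Characters**: one gain edge per component (uniform over edges, or
  root-only), absorbing per-branch loss with probability `p_loss`
  (default 0.1, a survey-like patchiness when combined with ~16 tips).
* **Detection noise**: true presences flip with probability `q`, absences
  with `r` — the "genuine loss versus missing data" confound as simple
  independent noise.
* **Proteomes**: per component a planted homolog (consensus with a fixed
  substitution fraction, default 0.3, plus geometric mean-2 indels at rate
  0.01), among composition-shuffled decoys, FG-repeat-only decoys (≥ 30%
  FG dipeptide density) and WD-window-only decoys.  No site-rate
  heterogeneity, domain shuffling, or realistic indel processes are
  modelled — decoys exercise the vetting rules, nothing more.

All randomness derives from a master seed through labelled substreams
(`SeedSequence([seed, crc32(label)])`), so adding a decoy class does not
perturb tree simulation and every output is a pure function of
(inputs, seed).

The planted-truth screen benchmark uses one family, 100 planted homologs
cycling 20/30/40/50% substitution, and 500 decoys (300 shuffled, 100 FG,
100 WD), with the acceptance threshold at the 99th percentile of the
decoys' own scores; by construction of the empirical quantile about 1% of
decoys sit above it, so the false-discovery proportion is ~5/105 when all
planted homologs are recovered.  The end-to-end scenario scores LECA
recall/precision and gain-edge recovery against the planted histories; at
the default scale (12–16 tips, 100–200 components) it runs in seconds on
one core.

## Numerical and degenerate-input choices

* Score comparisons use a 1e-9 tie tolerance; hit scores are rounded to
  9 decimals to make serialised output stable.
* An alignment with no match columns (every column > 50% gaps) raises a
  degenerate-profile error rather than producing an empty profile.
* A component absent from every tip yields a no-event reconstruction
  (no gain edge, root absent, cost 0).
* Contingency tests require both phenotype classes non-empty after
  dropping unknowns; otherwise a degenerate-input error is raised.
* Tie-breaks are uniform everywhere: score descending, then id
  lexicographic; leftmost-start-then-shortest for alignment intervals.

## Known limitations

* Profile scores are not HMMER-compatible and no E-values are produced;
  only presence/absence decisions, not significance estimates, are
  comparable across screening schemes.
* The transcribed survey tables inherit any errors of the published
  tables; where the source text and its own tables disagree on a derived
  count, the package reports what the tables yield.
* Dollo parsimony with binary states cannot separate deep loss from
  missing data, and the per-lineage event mapping (unlike the root
  complement) depends on the assumed within-side topology.
* The simulators are deliberately minimal; none of the benchmarks say
  anything about sensitivity on real diverged proteomes.
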