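# lecatrace

Phylogenetic profiling and Dollo-parsimony reconstruction of ancestral
protein-complex composition, built around the question: *which components
of the nuclear pore complex (NPC) and of the COPI/COPII/clathrin coatomer
complexes were already present in the last eukaryotic common ancestor
(LECA)?*

It is aimed at comparative genomicists who work with presence/absence
matrices over deeply diverged taxa: the package screens proteomes for
complex components with position-specific scoring profiles plus
repeat-aware vetting rules, collapses the resulting binary matrix to the
five eukaryote supergroups (Opisthokonts, Amoebozoa, Plantae,
Chromalveolates, Excavates), and places each component at the root — or
not — by parsimony, under alternative rootings of the eukaryote tree.

## The model

Each component is a binary character. Under **Dollo parsimony** a
character arises once, on the edge above the last common ancestor of all
carriers, and may then be lost any number of times:

```
cost(component) = 1 gain + #(maximal all-absent subtrees below the gain)
```

The component belongs to the root complement iff the gain maps to the
root edge — equivalently, iff it is present on both sides of the root
bipartition, so the LECA call depends only on where the root is, not on
the arrangement within each side. Two classical rootings are built in
(Excavates basal; unikont/bikont, i.e. {Opisthokonts, Amoebozoa} versus
the rest), plus a `star` rooting that treats the supergroup tree as
unresolved and yields only bounds: `[#components in every supergroup,
min per-supergroup count]`. Root states that an unrestricted
gain/loss parsimony could flip at equal cost are flagged `?`.

The screening stage builds log-odds profiles (bits against background
frequencies, affine gaps) from seed alignments, and vets hits with the
field's cautionary rules: similarity confined to FG-repeat or WD-repeat
windows is insufficient for membership, unless a diagnostic motif (such
as SIEGR in Rae1) lies outside the repeats; surviving candidates must
reciprocally best-hit their own family in a labelled reference set.

The package ships, as plain tab-separated text, the presence/absence
tables of a published comparative survey (31 nucleoporins × 51 genomes;
a 3 × 19 fungal anchoring-Nup panel with mitosis phenotypes; a
24-protein *Trypanosoma brucei* proteomics control; 27 coatomer
components × 46 genomes), so every headline number below is recomputed
from the repository alone — no downloads.

## Worked example

```python
from lecatrace import (load_fixture, supergroup_counts, leca_complement,
                       star_tree_bounds)

matrix = load_fixture("nup_table2")          # 31 nucleoporins x 51 genomes
taxonomy = load_fixture("taxonomy_table2")   # genome -> class -> supergroup

print(supergroup_counts(matrix, taxonomy))
print(len(leca_complement(matrix, taxonomy, "unikont_bikont")),
      len(leca_complement(matrix, taxonomy, "excavate_basal")))
bounds = star_tree_bounds(matrix, taxonomy)
print(bounds.as_tuple(), bounds.witness_supergroup)
```

prints

```
{'Opisthokonts': 31, 'Amoebozoa': 22, 'Plantae': 26, 'Chromalveolates': 25, 'Excavates': 23}
26 23
(20, 22) Amoebozoa
```

Reading: every nucleoporin is found in at least one opisthokont genome;
22–26 are found in each other supergroup. Under the unikont/bikont root
26 nucleoporins trace back to LECA, under the Excavate-basal root 23 —
the difference is exactly {Nup43, Nup88, Nup188}, which are missing from
Excavates. Even with the supergroup relationships left unresolved, the
ancestral pore had between 20 components (present in all five
supergroups) and 22 (the Amoebozoa total): a complete NPC, whichever way
the eukaryote tree is rooted.

The same analyses are available from the shell:

```sh
lecatrace reconstruct --matrix src/lecatrace/fixtures/nup_table2.tsv \
    --taxonomy src/lecatrace/fixtures/taxonomy_table2.tsv \
    --rooting unikont_bikont --out out/
# -> "26 components at the root under unikont_bikont"; out/events.tsv
#    lists per component its gain edge, loss edges, root state and `?` flag
```

`lecatrace screen` scans a FASTA proteome against seed-alignment
profiles and writes per-hit vetting decisions; `lecatrace report`
renders summary tables and the fungal mitosis association (Pom34 present
in exactly the 12 closed-mitosis ascomycetes and absent from all 7
open-mitosis fungi); `lecatrace simulate` runs a synthetic
evolve-screen-reconstruct scenario scored against planted truth.

## Layout

- `src/lecatrace/matrix.py` — presence/absence matrices, taxonomy, TSV I/O
- `src/lecatrace/fixtures.py` + `fixtures/` — the transcribed survey tables
- `src/lecatrace/profiles.py` — seed alignments, log-odds profiles, scoring DP
- `src/lecatrace/screen.py` — screening, repeat vetting, reciprocal/rescue,
  concordance
- `src/lecatrace/trees.py`, `ancestry.py` — rooted topologies, Dollo and
  ambiguity reconstruction, LECA complements and star bounds
- `src/lecatrace/reports.py` — phenotype association, absence reports,
  study comparison, rendered summaries
- `src/lecatrace/simulate.py` — synthetic trees, characters, noise,
  proteomes, benchmarks
- `docs/methods.md` — model assumptions, parameter choices, limitations
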