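# solviface

Structural classification of protein binding regions with interfacial
solvent: detect and physicochemically characterize the interfaces a protein
domain uses to recognize other proteins, peptides, DNA/RNA and saccharides;
cluster those interfaces into family-level *binding regions* on
structure-based alignments; and transfer regions across structurally similar
families as predictions.

It is aimed at structural bioinformaticians building interface databases or
comparative interface analyses from PDB-format coordinate files plus
SCOP-like domain definitions.

## Model

Interactions are classified per heavy-atom pair by distance and the atom
roles of an editable chemistry dictionary:

- **hydrogen bond** — donor/acceptor pair at d ≤ 3.6 Å,
- **salt bridge** — oppositely charged pair at d ≤ 4.0 Å,
- **van der Waals** — any heavy-atom pair at d ≤ 4.5 Å.

All boundaries are inclusive and a pair may carry several labels.
**Water-mediated** interactions are residue pairs bridged by one water whose
oxygen is within hydrogen-bond distance of a donor/acceptor atom on each
side; interface residues are then labeled *dry* (direct contacts only),
*wet* (water-mediated only) or *dual*, and *hydrophobic*/*hydrophilic* by
the character of their contacting atoms.

Entity typing follows interface-database practice: SCOP-like definitions
carve **domains** out of chains; undomained all-ATOM chains shorter than 90
residues are **peptides**; standard-nucleotide chains merge into one
**nucleic-acid** unit when at least one inter-base atomic contact joins them
(RNA iff any nucleotide has an O2′ atom); recognized sugar residues merge
into **oligosaccharides** via covalent connectivity, flagged when covalently
attached to protein (N-/O-glycosylation).

An **interface** (IF) is the set of a domain's residues contacting one
ligand entity. Interfaces of one family are mapped to the columns of the
family's structure-based alignment and clustered single-linkage with
similarity

    sim(A, B) = |A ∩ B| / min(|A|, |B|)

at a configurable cutoff (default 0: any shared column merges two
interfaces) into **binding regions** (BR), giving the FA → BR → IF
hierarchy. Given a non-sequential structural alignment between members of
two families, an observed region whose residues are conserved in the
correspondence (coverage ≥ threshold, default 0.5) is transferred to the
other family as a **predicted** binding region inheriting the source
ligands.

## Worked example

The built-in generator writes a deterministic toy corpus (two bound
families, a DNA, a peptide and a saccharide complex, an apo family, plus
domain tables, alignments and one cross-family correspondence):

```bash
solviface fixtures --seed 7 --out corpus
solviface scan corpus/pdb/*.pdb --domains corpus/domains.tsv --out scan
# -> scanned 4 structures, 4 interfaces
solviface classify --interfaces scan --alignments corpus/alignments \
    --cutoff 0 --cutoff 0.6 --out cls
solviface infer --hierarchy cls/hierarchy.c0.json --interfaces scan \
    --correspondences corpus/correspondences.tsv \
    --alignments corpus/alignments --out pred.json
# -> wrote 1 predicted regions
```

At cutoff 0, family `famA` has one region whose interface list covers two
ligand types (`"ligand_types": ["dna", "peptide"]` in
`cls/hierarchy.c0.json`): its two members bind a DNA duplex and a peptide
through overlapping alignment columns — the same-surface/different-ligand
situation the conjunctive `--ligand dna --ligand peptide` filter selects
for. At cutoff 0.6 the two interfaces split into separate regions (their
column overlap is below that similarity). `pred.json` adds one predicted
region on the apo family `famC` with `"coverage": 0.7333` — 11 of the 15
region columns have counterparts in the famA↔famC correspondence — so
`--only-predicted` reports exactly `famC`, a family with no observed
binding information. The covalently attached sugar in `3pqr` appears in the
entity table with `covalent_to_protein=true` and is excluded from
clustering by default.

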