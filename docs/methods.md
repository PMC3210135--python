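# Methods

## Scope and data model

The package classifies protein binding regions from three kinds of input:
PDB-format coordinate files (ATOM/HETATM/CONECT), a tab-separated domain
table mapping SCOP-like family ids to chain/residue segments, and per-family
gapped-FASTA structure-based alignments (plus, for cross-family inference,
tab-separated residue-correspondence maps from non-sequential structural
alignments). Producing the alignments and correspondences themselves is out
of scope — they are inputs, as is any external crystal-packing classifier.

Residues are identified by the full (chain, sequence number, insertion
code, residue name) tuple. Only the first MODEL of multi-model files is
read, giving one consistent coordinate set. Alternate locations are reduced
to one conformer per atom: highest occupancy wins, ties go to the
lexicographically smallest alt-loc id. Hydrogens are ignored everywhere:
every distance criterion is heavy-atom to heavy-atom, so the method applies
uniformly to structures with and without modeled hydrogens.

## Interaction criteria

Three inclusive distance criteria classify an atom pair, using role flags
from an editable chemistry dictionary (donor, acceptor, positive, negative,
hydrophobic per residue/atom):

| label | condition | cutoff |
|---|---|---|
| hydrogen bond | donor ↔ acceptor (either orientation) | ≤ 3.6 Å |
| salt bridge | positive ↔ negative | ≤ 4.0 Å |
| van der Waals | any heavy-atom pair | ≤ 4.5 Å |

A pair may carry several labels (a 3.2 Å salt bridge is also a hydrogen
bond and a vdW contact); residue-level summaries rank
salt_bridge > hbond > vdw. No angular criterion is applied — hydrogen-bond
geometry beyond distance cannot be evaluated reliably without hydrogens.
Covalently bonded pairs (a CONECT record, or heavy atoms within 1.9 Å) are
excluded from the non-covalent contact lists; 1.9 Å covers C–O/C–N
glycosidic bonds (~1.4–1.5 Å) with margin while staying well below the
shortest heavy-atom hydrogen bonds (~2.4 Å). A numerical slack of 1e-9 Å
keeps boundary distances written with 3-decimal PDB coordinates inclusive
under floating-point arithmetic.

Water-mediated interactions: a residue pair on opposite sides of an
interface is bridged by a water when each residue has at least one
donor/acceptor atom within 3.6 Å of the water oxygen. One record is
synthesized per (residue, residue, water) triple; its distance is the
longer of the two legs. Chains of two or more waters are deliberately not
followed — mediation is defined through a single molecule.

Default role assignments worth noting: histidine ND1/NE2 are donor+acceptor
and uncharged (protonation is unknowable from coordinates; configurable);
the C-terminal OXT is an acceptor; the N-terminal nitrogen is donor only;
carbon atoms of known residues default to hydrophobic; saccharide codes get
generic sugar chemistry (O* donor+acceptor, N* donor, C* hydrophobic)
unless given explicit entries.

## Entity typing

Typing runs in a fixed order so each residue lands in exactly one
non-water entity:

1. **Domains** from the definition table (ATOM residues inside segments;
   overlapping definitions are a hard error, absent chains a warning).
2. **Nucleic acids**: standard-nucleotide chains, merged transitively into
   one unit wherever base-moiety atoms of two chains come within the 4.5 Å
   contact envelope. The base-only reading of "inter-base interaction" is
   deliberate: base pairing, not backbone proximity, is what defines a
   duplex. A merged unit is RNA if any member nucleotide has an O2′ atom
   (an existential rule, so mixed content types as RNA).
3. **Peptides**: chains of standard amino acids (ATOM records; modified
   residues such as MSE count when bonded into the backbone), covered by no
   domain definition, with at most 89 observed residues. Longer undomained
   chains are reported as `unassigned_protein` and never act as ligands.
   Nucleotide-bearing chains are never peptides (step 2 precedes step 3).
   Length counts observed residues, not SEQRES.
4. **Oligosaccharides**: HETATM residues whose code is in the saccharide
   list, merged over covalent connectivity (CONECT, or inter-unit heavy
   atoms ≤ 1.9 Å), with a `covalent_to_protein` flag set by the same
   criterion against protein atoms. The shipped 33-code list is a curated
   subset of common PDB sugars and is user-editable.
5. **Waters** (HOH/WAT/DOD; oxygen only) and, finally, report-only
   `other_het` entities for anything unrecognized — nothing is silently
   dropped.

## Interfaces and regions

An interface is domain-centric: the domain residues with ≥ 1 direct or
water-mediated contact to one ligand entity. Per residue, solvation is dry
(direct only), wet (water-mediated only) or dual; chemistry is hydrophobic
only if every contacting atom of the residue is flagged hydrophobic
(hydrophilic wins on mixed character — conservative for polarity-based
analyses). An interface is homo if the ligand is a domain of the same
family, else hetero; intra if domain and ligand share a chain (or are
covalently linked, as with N-glycosylation), else inter. Covalent
saccharide interfaces are retained but excluded by the default search
filters. Crystal-packing removal is a pluggable hook: an external
classifier returning a biological probability (interfaces < 0.70 are
dropped); without one, filtering is off unless the clearly labeled naive
size floor (< 5 interface residues for protein-protein) is opted in.

Interfaces of one family are projected to alignment columns (0-based
internally, 1-based in all reports; residues missing from the alignment are
counted and reported, not fatal). Similarity between two interfaces is
overlap over the smaller column set, so a sub-region nested in a larger one
scores 1 and clusters with it — the behavior wanted for regions observed at
different completeness. Clustering is single linkage on edges with
similarity **strictly greater** than the cutoff; at the default cutoff 0
any shared column joins two interfaces. The shipped cutoff set is
{0, 0.2, 0.4, 0.6}, fully configurable. Region ids are assigned by each
component's smallest interface id, making output byte-deterministic under
input permutation. The hierarchy groups each region's interfaces by ligand
partner (partner family for protein ligands, ligand type otherwise);
multi-type ligand filters are conjunctive — a region must recognize every
selected type through the same surface.

## Cross-family inference

A correspondence map lists one-to-one residue pairs between a member of a
source and a member of a target family. An observed region is realized as
source-member residues via the alignment, pushed through the pairs, and
projected onto the target alignment. Coverage is the mapped fraction of the
region's residues; the transfer is emitted only at coverage ≥ the
conservation threshold (default 0.5 — "most of the region is conserved";
the original statistical-significance machinery of structural-alignment
scoring is intentionally not reproduced, so the threshold is a named,
documented parameter). Predictions on one family that overlap each other
merge (same similarity measure); predictions overlapping an *observed*
region of the target family are demoted to corroboration and not emitted as
new regions. Predicted regions carry ligand identity and binding-mode
provenance only — no coordinates are modeled for the inferred complex.

## Synthetic fixtures

The fixture generator emulates only what the method consumes: exact
heavy-atom separations. Residue templates are schematic (planar sugars,
idealized extended chains, flat bases with the pairing-edge atom extremal
by construction), so requested distances are exact to the 3-decimal
precision of PDB coordinates, but no fixture is stereochemically refined —
torsions, secondary structure and real base pairing are not represented.
Passing tests therefore validate the distance/connectivity logic and the
classification pipeline, not robustness to the conformational variety of
real crystal structures, nor to real-world pathologies such as chain
breaks, zero-occupancy regions or non-standard residues beyond MSE.

The toy corpus fixes the study conditions: family famA with a 30-residue
member bound to a 7-bp DNA duplex (residues ~5–11) and a second member
bound to an 8-residue peptide (residues ~8–17), overlapping enough to merge
at cutoff 0 and split by 0.6; famB with a non-covalent trisaccharide and a
covalently N-linked sugar; apo famC connected to famA by an 11-pair
correspondence covering ~73 % of the merged famA region, so the default
0.5 threshold admits the transfer and 0.95 rejects it. Ligands approach the
chain's carbonyl face, which is geometrically uniform in the schematic
templates, giving contiguous interfaces; one bridging water is placed on a
protein–DNA polar axis when clash-free geometry allows, yielding wet and
dual residues. Coordinates carry a ±0.04 Å seed-controlled jitter; a fixed
seed reproduces the corpus byte-identically.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs chosen as representative of
the logic rather than of PDB-wide volume: boundary sweeps use 41 separations
(3.00–5.00 Å, 0.05 Å grid) and 21 chain lengths (80–100); oracle-equivalence
checks compare the KD-tree path against O(n²) scans on 100 random two-chain
structures of up to 500 atoms and against union-find/transitive-closure
oracles on instances of up to ~20 elements. Whole-PDB census counts are
input-data products, not method properties, and are not reproduced.

Known limitations: no mmCIF input, no assembly/symmetry expansion, no
hydrogen placement, no hydrogen-bond angles, no buried-surface-area or
energetic characterization, no modified-nucleotide recognition, and the
packing filter ships without a trained classifier.
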