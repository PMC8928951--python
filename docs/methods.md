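# Methods

## The classification model

Ferredoxin Fe–S clusters are ligated by cysteines whose count and
arrangement are characteristic of the cluster type: four cysteines for
2Fe-2S; three plus a proline directly after the last one for 3Fe-4S; four
plus a terminal proline for 4Fe-4S; seven (with prolines after the third and
last) for the dual-cluster 7Fe-8S; eight for the double cluster 2[4Fe-4S];
and nine for its Alvin variant 2[4Fe-4S]Alv, whose extra cysteine sits
exactly three residues after the last cluster cysteine. Within a type, the
exact inter-cysteine spacing — written `CXnCXm...C` — is the *subtype
signature*: two ferredoxins belong to the same subtype iff their gap tuples
(and proline slots) are identical. Subtypes are numbered in order of first
occurrence and named `<type>-ST<n>`.

The model's central assumption is that the spacing pattern of the Fe–S
binding motif is conserved and sufficient for classification; no sequence
similarity outside the motif cysteines/prolines is consulted anywhere in
this package.

### Signature grammar

A signature is a token sequence of cysteines, positive gap lengths and
proline markers. Normal form stores the gap tuple plus the set of cysteine
indices followed by proline; parsing accepts underscore/subscript
typography (`CX_5_C…`) and serialization always emits plain ASCII, so
parse∘format is the identity. Zero-length gaps are rejected: adjacent
motif cysteines are not observed in the inventory, and forbidding them
keeps the grammar unambiguous. The motif length in amino acids is
`n_cys + Σ gaps + n_prolines`, both terminal residues inclusive.

Proline is *not* part of 2[4Fe-4S]/2[4Fe-4S]Alv signatures (it is not
conserved there), and for 7Fe-8S it is carried in the signature but treated
as a type-level feature, not a class-splitting one (one known 7Fe-8S
ferredoxin has arginine in place of the terminal proline; the scanner has a
relaxation flag for exactly this case).

### Cluster-type inference

Purely structural: 9 cysteines → 2[4Fe-4S]Alv, 8 → 2[4Fe-4S], 7 → 7Fe-8S;
3 or 4 with a terminal proline → 3Fe-4S / 4Fe-4S; 3 or 4 without any
proline → 2Fe-2S; anything else → no type (returned as `None`, never an
exception, since impossible structures are expected inputs during
scanning).

## Scanning

Each type has a canonical ranged template (2Fe-2S has three motif shapes):

| type | template |
|---|---|
| 2Fe-2S | `CX3-5CX1-2CX22-82C`, `CX2-12CX30-44CX3C`, `CX4-7CX29-35C` |
| 3Fe-4S | `CX5CX35-49CP` |
| 4Fe-4S | `CX2-5CX2-3CX30-45CP` |
| 7Fe-8S | `CX3-10CX3CPX17-40CX2CX2CX3CP` |
| 2[4Fe-4S] | `CX2-7CX2-4CX2-3CX14-42CX1-2CX2-8CX3C` |
| 2[4Fe-4S]Alv | `CX2CX2CX3CX18-46CX2CX2-8CX3CX3C` |

These ranges are frozen constants rather than recomputed from the registry,
so scanning behaviour is stable under user registry extensions
(`registry-exact` mode exists to match only registered signatures, and
`permissive` mode widens every range by a slack). A hit is any choice of
cysteine positions whose consecutive gaps fall inside a template's ranges
with required prolines present; gap residues are unconstrained, so the
matcher steps over decoy cysteines (it enumerates position subsets
depth-first, not runs of consecutive cysteines). Ambiguity codes (B, Z, X,
U…) never satisfy a cysteine or proline position. Coordinates are 0-based
half-open internally and 1-based inclusive in reports.

Overlapping readings are resolved greedily: hits sharing a cysteine are
ranked by cluster-type precedence 2[4Fe-4S]Alv > 2[4Fe-4S] > 7Fe-8S >
4Fe-4S > 3Fe-4S > 2Fe-2S (a double cluster subsumes its embedded
single-cluster sub-patterns), then leftmost start, then longest span, then
more cysteines. The last tie-break matters: a four-cysteine 2Fe-2S motif can
contain a three-cysteine reading with identical start and span, and the
fuller reading must win deterministically.

Two packaged signatures fall outside their own type's strict template and
are therefore not matchable in strict-canonical mode: 2[4Fe-4S] ST11 (gap 5
= 3, see "Known inconsistencies") and 7Fe-8S ST9 (no terminal proline).
Both are matchable in registry-exact mode.

## Registry and minting

The packaged registry transcribes the published subtype inventory
(55 + 7 + 12 + 10 + 33 + 10 = 127 rows) with per-group counts for
Alphaproteobacteria, Firmicutes, Archaea, literature Bacteria and Eukarya.
Three signatures appear under two subtype numbers (2Fe-2S 3/55, 2Fe-2S
4/19, 3Fe-4S 3/5); the duplicated rows are kept verbatim so column sums
stay faithful, while signature lookup resolves through an alias map to the
lowest number. Novel signatures are minted the next free number within
their type — a pure function of registry state and gap tuple, strictly
increasing and replay-stable.

## Comparative analytics

All analytics run on the subtype × group count matrix.

- **Census**: per-type column sums and per-type counts of subtypes with a
  positive cell.
- **Shared subtypes**: positive in both of two columns.
- **Cross-domain presence**: columns are aggregated into the three domains
  of life with Bacteria = Alphaproteobacteria + Firmicutes + literature
  Bacteria (this aggregation is required to reproduce the published
  cross-domain sets); a subtype is present in a domain iff its aggregated
  count is positive. Reported are the present-in-all-three sets per type
  and, for each domain pair, the subtypes present in exactly those two.
- **Canonical induction**: signatures of one type are partitioned into
  shape classes — by cysteine count under the type's proline template, and
  for four-cysteine 2Fe-2S additionally by the index of the longest gap —
  and each class collapses to per-gap (min, max) ranges. The longest-gap
  rule is this package's design choice: the published three 2Fe-2S motif
  shapes are listed without a stated partition rule, and this rule
  reproduces them exactly. Classes are reported largest first. Ranges are
  serialized `CX35-49CP` style; en-dashes accepted on input.
- **Heat map**: presence is encoded +3 and absence −3 per domain (the
  red/green convention of the original rendering); rows and columns are
  clustered agglomeratively with Euclidean distance and average linkage
  (the original viewer's linkage is unstated; average is its common
  default), leaf order is scipy's deterministic order with ties toward
  lower original index. Dendrograms export as Newick, the matrix as TSV,
  the rendering as PNG.

## Synthetic fixtures

The generator realizes a signature into a concrete peptide (cysteines and
conserved prolines at their slots, gap residues drawn uniformly from a
19-letter background excluding cysteine) and embeds it in cysteine-free
flanks, default 30 residues each side. Two guards keep ground truth exact:
no proline is ever drawn immediately after a cysteine (it would read as a
motif proline marker), including the first flank residue after a motif
ending on a cysteine. Under these conditions the planted motif is the only
match of its type and recall is 100% with zero false positives by
construction — which is what the fixture tests demonstrate. What they do
*not* show is behaviour on real proteomes, where cysteines are everywhere
and structural false positives (motif-shaped spacing without a cluster) are
expected; the scanner is a pattern detector, not a homology or annotation
tool, and protein-family exclusion (e.g. dehydrogenases with Fe–S motifs)
is left to the user. A hostile mode sprinkles decoy cysteines into flanks
for stress tests where only recall is asserted.

Negative controls perturb a signature outside its type's strict templates:
widening a gap past the canonical maximum, dropping a required proline, or
dropping a cysteine (merging its gaps). A candidate perturbation is
validated combinatorially on the signature's own geometry: no cysteine
*subset* of its realization may still match a same-type template (a widened
motif can otherwise retain an in-range sub-pattern). Perturbations that
cannot escape the type this way — e.g. dropping a cysteine from
`CX4CX2CX29C`, which lands squarely in the three-cysteine 2Fe-2S shape —
raise an error rather than emit a weak negative.

All generation is seeded and byte-reproducible.

## Numerical and degenerate-input choices

- Empty sequences and sequences without cysteines scan to an empty hit
  list, not an error; empty signature strings are parse errors with the
  offending position named.
- Singleton heat-map axes skip clustering (trivial dendrogram).
- Registry rows whose printed motif length disagrees with the signature
  arithmetic are loaded as printed and flagged as errata, never silently
  corrected.
- All randomness flows through explicit integer seeds; there is no global
  random state.

## Known inconsistencies in the source inventory

Four registry rows have printed lengths that contradict their own
signatures: 2Fe-2S ST11 (46 vs computed 45), 7Fe-8S ST9 (42 vs 41),
2[4Fe-4S] ST11 (42 vs 41) and 2[4Fe-4S] ST16 (50 vs 62). The suite asserts
exactly this erratum set.

The published 2[4Fe-4S] canonical motif prints `CX1-2` at gap 5, yet
2[4Fe-4S] ST11's signature has gap 5 = 3; induction over the full inventory
therefore necessarily yields `CX1-3` there. Because the correction to ST11
that would reconcile the two is not unique, the signature is kept as
printed and the induced motif differs from the published string in that one
bound (the corresponding acceptance-level test documents the mismatch by
failing against the published string). The other five types' induced
motifs, including all three 2Fe-2S shapes, match the published strings
exactly.

## Problem sizes in the test suite

Property sweeps use 1,000 random signatures for round-tripping, 200 random
sequences (≤ 300 residues, ≤ 12 cysteines) for scanner-vs-brute-force
equivalence, 500 planted motifs for recall/false-positive checks, and the
full registry × three perturbation modes for negative controls; the whole
suite runs in well under a minute on one CPU.

## Limitations

- Detection is purely structural; no BLAST, profiles or HMMs, so database
  annotation steps of a real survey are out of scope by design.
- The scanner reports hits, not proteins; callers aggregate per sequence
  (a sequence with two disjoint 2Fe-2S motifs yields two hits).
- Multiple-sequence alignment and phylogenetic tree building are not
  implemented; `scan --export-fasta-dir` emits per-subtype FASTA for
  external tools.
- The 2Fe-2S plant/mitochondrial/bacterial/thioredoxin naming tradition is
  not modelled; the subtype scheme supersedes it here.
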