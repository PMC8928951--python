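# fdxmotif

Ferredoxins are small iron–sulfur proteins that shuttle electrons in
oxidation–reduction reactions across all domains of life. Their Fe–S cluster
is ligated by a handful of cysteines whose exact spacing along the chain is
conserved — conserved enough that the spacing pattern alone identifies both
the cluster type and, at exact resolution, a *subtype* within it.

`fdxmotif` is a toolkit built around that idea. It provides:

- a grammar for **cysteine-spacing signatures** such as `CX5CX2CX36C`
  (cysteine, 5 residues, cysteine, 2 residues, cysteine, 36 residues,
  cysteine) with parsing, serialization, length arithmetic and structural
  cluster-type inference for the six ferredoxin Fe–S cluster types
  `2Fe-2S`, `3Fe-4S`, `4Fe-4S`, `7Fe-8S`, `2[4Fe-4S]` and `2[4Fe-4S]Alv`;
- a **motif scanner** that locates Fe–S binding motifs in protein sequences
  using ranged canonical templates (e.g. `CX5CX35-49CP` for 3Fe-4S), with
  precedence-based resolution of overlapping readings;
- a packaged **subtype registry** of 127 published subtypes with per-taxon
  occurrence counts (Alphaproteobacteria, Firmicutes, and
  literature-collected Archaea, Bacteria and Eukarya), exact-signature
  lookup, alias resolution for duplicated rows, and deterministic **minting**
  of new subtype numbers, rendered in the `<type>-ST<n>` nomenclature
  (e.g. `2Fe-2S-ST1`);
- **comparative analytics**: per-group censuses, subtype sets shared between
  taxa, cross-domain presence (the lateral-gene-transfer signal), canonical
  motif induction, and ±3-encoded presence/absence heat maps with
  Euclidean hierarchical clustering;
- a seeded **synthetic fixture generator** that plants known motifs in
  cysteine-free backgrounds (plus perturbed negative controls), so every
  code path is testable offline.

## Worked example

```python
from fdxmotif import (
    ClusterType, realize_signature, scan_sequence, nomenclature_label,
    load_builtin_registry, group_count_matrix, summarize_counts,
    shared_subtypes,
)

reg = load_builtin_registry()

# plant the 2Fe-2S subtype-1 motif at offset 10 of a synthetic sequence
seq = "M" + "A" * 9 + realize_signature("CX5CX2CX36C", seed=4) + "G" * 12
(hit,) = scan_sequence(seq, "demo_fdx")
print(hit.cluster_type.value, hit.cys_positions, str(hit.signature))
number, novel = reg.assign_subtype(hit.cluster_type, hit.signature)
print(nomenclature_label(hit.cluster_type, number), novel)

matrix = group_count_matrix(reg)
census = summarize_counts(matrix, "Alphaproteobacteria")
print(census.grand_total, census.per_type_totals)
print(sorted(shared_subtypes(matrix, ClusterType.FE2S2,
                             "Alphaproteobacteria", "Firmicutes")))
```

prints

```
2Fe-2S (10, 16, 19, 56) CX5CX2CX36C
2Fe-2S-ST1 False
1307 {'2Fe-2S': 490, '3Fe-4S': 60, '4Fe-4S': 2, '7Fe-8S': 12, '2[4Fe-4S]': 712, '2[4Fe-4S]Alv': 31}
[2, 3, 4, 5, 6, 8, 9, 18]
```

The scanner found one motif whose four cysteines sit at (0-based) positions
10, 16, 19 and 56; its extracted signature is exactly the registered 2Fe-2S
subtype-1 signature, so it is labelled `2Fe-2S-ST1` rather than minted as
novel. The census says the alphaproteobacterial survey holds 1307
ferredoxins (490 of them 2Fe-2S, 712 double-cluster 2[4Fe-4S], …), and eight
2Fe-2S subtypes are shared between Alphaproteobacteria and Firmicutes.

## Command line

```sh
fdxmotif simulate --entry CX5CX2CX36C:10 --seed 7 \
    --out-fasta fx.fasta --out-truth truth.tsv
fdxmotif scan fx.fasta -o hits.tsv --export-fasta-dir by_subtype/
fdxmotif summarize --group Firmicutes
fdxmotif compare --type 2Fe-2S --groups Alphaproteobacteria Firmicutes
fdxmotif crossdomain
fdxmotif heatmap --out-dir heatmap/
fdxmotif export-registry -o registry.json
```

`scan` writes a TSV hit table (1-based inclusive coordinates by default)
and optional per-subtype FASTA exports for external phylogenetics tools.
All reports are byte-deterministic for identical inputs.

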