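"""Comparative analytics over the subtype inventory.

Everything here operates on a *group count matrix*: subtype rows (cluster
type, subtype number) by taxon-group columns, cells holding occurrence
counts.  From it we derive per-group summaries, subtype sets shared between
groups, cross-domain presence (the signal used to argue lateral gene
transfer of a subtype between domains of life), ranged canonical motifs
induced over each cluster type's signatures, and the presence/absence
heat map with hierarchical clustering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch

from .registry import GROUPS, Registry
from .signature import (
    ClusterType,
    SpacingSignature,
    TYPE_ORDER,
)

__all__ = [
    "DOMAINS",
    "DEFAULT_DOMAIN_PARTITION",
    "group_count_matrix",
    "CountSummary",
    "summarize_counts",
    "shared_subtypes",
    "CrossDomainPresence",
    "cross_domain_presence",
    "CanonicalMotif",
    "induce_canonical_motifs",
    "HeatmapResult",
    "heatmap",
]

#: the three domains of life, in fixed display order
DOMAINS: tuple[str, ...] = ("Archaea", "Bacteria", "Eukarya")

#: default mapping of matrix columns onto domains: the two surveyed bacterial
#: clades and the literature Bacteria column together form the Bacteria domain.
DEFAULT_DOMAIN_PARTITION: dict[str, str] = {
    "Alphaproteobacteria": "Bacteria",
    "Firmicutes": "Bacteria",
    "Bacteria_lit": "Bacteria",
    "Archaea": "Archaea",
    "Eukarya": "Eukarya",
}


def group_count_matrix(reg: Registry) -> pd.DataFrame:
    """Subtype-by-group count table from a registry.

    Rows are a (cluster_type, subtype) MultiIndex — types in conventional
    order, subtype numbers ascending — columns the five taxon groups; this
    fixed ordering makes every downstream report deterministic.
    """
    rows = []
    index = []
    for ct in TYPE_ORDER:
        for rec in reg.records_for(ct):
            index.append((ct.value, rec.subtype_number))
            rows.append([rec.count(g) for g in GROUPS])
    idx = pd.MultiIndex.from_tuples(index, names=["cluster_type", "subtype"])
    return pd.DataFrame(rows, index=idx, columns=list(GROUPS), dtype=int)


@dataclass(frozen=True)
class CountSummary:
    """Per-group census: totals and distinct-subtype counts by cluster type."""

    group: str
    per_type_totals: dict[str, int]
    per_type_subtype_counts: dict[str, int]
    grand_total: int


def summarize_counts(matrix: pd.DataFrame, group: str) -> CountSummary:
    """Census of one taxon-group column.

    ``per_type_totals`` are column sums within each cluster type;
    ``per_type_subtype_counts`` count the subtypes actually observed
    (cell > 0) in that group.
    """
    if group not in matrix.columns:
        raise KeyError(f"unknown group: {group!r}; columns are {list(matrix.columns)}")
    col = matrix[group]
    totals: dict[str, int] = {}
    ntypes: dict[str, int] = {}
    for ct in TYPE_ORDER:
        if ct.value in matrix.index.get_level_values("cluster_type"):
            sub = col.loc[ct.value]
            totals[ct.value] = int(sub.sum())
            ntypes[ct.value] = int((sub > 0).sum())
        else:
            totals[ct.value] = 0
            ntypes[ct.value] = 0
    return CountSummary(
        group=group,
        per_type_totals=totals,
        per_type_subtype_counts=ntypes,
        grand_total=int(col.sum()),
    )


def shared_subtypes(
    matrix: pd.DataFrame, cluster_type: ClusterType, group_a: str, group_b: str
) -> set[int]:
    """Subtypes of one cluster type observed (>0) in both groups."""
    for g in (group_a, group_b):
        if g not in matrix.columns:
            raise KeyError(f"unknown group: {g!r}")
    if cluster_type.value not in matrix.index.get_level_values("cluster_type"):
        return set()
    sub = matrix.loc[cluster_type.value]
    mask = (sub[group_a] > 0) & (sub[group_b] > 0)
    return set(sub.index[mask].astype(int))


def _domain_presence(
    matrix: pd.DataFrame, domain_partition: Mapping[str, str]
) -> pd.DataFrame:
    unmapped = [c for c in matrix.columns if c not in domain_partition]
    if unmapped:
        raise KeyError(f"column(s) not mapped to a domain: {unmapped}")
    agg = matrix.T.groupby([domain_partition[c] for c in matrix.columns]).sum().T
    agg = agg.reindex(columns=[d for d in DOMAINS if d in agg.columns])
    return agg > 0


@dataclass(frozen=True)
class CrossDomainPresence:
    """Subtype sets by domain coverage.

    ``all_domains`` maps each cluster type to the subtypes present in every
    domain; ``pairwise_only`` maps an (alphabetical) domain pair to the
    subtypes present in exactly those two domains.  Presence of the same
    subtype in several domains is the pattern read as lateral gene transfer.
    """

    all_domains: dict[str, set[int]]
    pairwise_only: dict[tuple[str, str], dict[str, set[int]]]


def cross_domain_presence(
    matrix: pd.DataFrame,
    domain_partition: Mapping[str, str] | None = None,
) -> CrossDomainPresence:
    """Classify subtypes by which domains of life they occur in.

    A subtype is present in a domain iff the sum of its cells over that
    domain's columns is positive.
    """
    part = dict(domain_partition or DEFAULT_DOMAIN_PARTITION)
    pres = _domain_presence(matrix, part)
    domains = list(pres.columns)
    all_sets: dict[str, set[int]] = {}
    pair_sets: dict[tuple[str, str], dict[str, set[int]]] = {
        pair: {}
        for pair in (
            (a, b) for i, a in enumerate(domains) for b in domains[i + 1:]
        )
    }
    for ct in TYPE_ORDER:
        if ct.value not in pres.index.get_level_values("cluster_type"):
            continue
        sub = pres.loc[ct.value]
        everywhere = set(sub.index[sub.all(axis=1)].astype(int))
        if everywhere:
            all_sets[ct.value] = everywhere
        for pair, bucket in pair_sets.items():
            mask = sub[list(pair)].all(axis=1) & ~sub.drop(columns=list(pair)).any(axis=1)
            only = set(sub.index[mask].astype(int))
            if only:
                bucket[ct.value] = only
    return CrossDomainPresence(all_domains=all_sets, pairwise_only=pair_sets)


# ---------------------------------------------------------------------------
# canonical motif induction


@dataclass(frozen=True)
class CanonicalMotif:
    """A ranged generalization of a class of signatures, e.g. ``CX5CX35-49CP``."""

    cluster_type: ClusterType
    gap_ranges: tuple[tuple[int, int], ...]
    proline_slots: tuple[int, ...]
    member_subtypes: tuple[int, ...] = ()

    @property
    def n_cys(self) -> int:
        return len(self.gap_ranges) + 1

    def admits(self, sig: SpacingSignature) -> bool:
        if sig.n_cys != self.n_cys:
            return False
        return all(lo <= g <= hi for g, (lo, hi) in zip(sig.gaps, self.gap_ranges))

    def to_string(self) -> str:
        parts = ["C"]
        for i, (lo, hi) in enumerate(self.gap_ranges, start=1):
            if i in self.proline_slots:
                parts.append("P")
            parts.append(f"X{lo}C" if lo == hi else f"X{lo}-{hi}C")
        if self.n_cys in self.proline_slots:
            parts.append("P")
        return "".join(parts)

    @classmethod
    def from_string(cls, text: str, cluster_type: ClusterType) -> "CanonicalMotif":
        """Parse ``CX3-5CX1-2CX22-82C``; en-dashes and underscores accepted."""
        norm = re.sub(r"[\s_]+", "", text).replace("–", "-").replace("—", "-")
        ranges: list[tuple[int, int]] = []
        slots: list[int] = []
        n_cys = 0
        pos = 0
        pat = re.compile(r"C|P|X(\d+)(?:-(\d+))?")
        while pos < len(norm):
            m = pat.match(norm, pos)
            if not m:
                raise ValueError(f"cannot parse canonical motif at position {pos}: {text!r}")
            tok = m.group(0)
            if tok == "C":
                n_cys += 1
            elif tok == "P":
                slots.append(n_cys)
            else:
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                ranges.append((lo, hi))
            pos = m.end()
        return cls(cluster_type, tuple(ranges), tuple(slots))

    def __str__(self) -> str:
        return self.to_string()


def _shape_class(sig: SpacingSignature, cluster_type: ClusterType) -> tuple:
    """Partition key for canonical induction.

    Signatures are classed by cysteine count under the cluster type's own
    proline template (per-signature proline deviations, known to occur for
    7Fe-8S, do not split a class).  Four-cysteine 2Fe-2S signatures are
    additionally split by the index of their longest gap: the cluster-distal
    long stretch sits after the third cysteine in one motif shape and after
    the second in the other, and that index separates the two published
    shapes exactly.
    """
    key: tuple = (sig.n_cys,)
    if cluster_type is ClusterType.FE2S2 and sig.n_cys == 4:
        key += (int(np.argmax(sig.gaps)),)
    return key


def induce_canonical_motifs(
    signatures: Sequence[SpacingSignature],
    cluster_type: ClusterType,
    subtype_numbers: Sequence[int] | None = None,
) -> list[CanonicalMotif]:
    """Generalize a set of signatures into ranged canonical motifs.

    Signatures are partitioned into shape classes (see :func:`_shape_class`)
    and each class is collapsed to per-gap (min, max) ranges over its
    members.  Classes are returned largest first (ties: by first member's
    input position).  Proline slots on the result are the cluster type's
    conserved slots.  Empty input yields an empty list.
    """
    if subtype_numbers is not None and len(subtype_numbers) != len(signatures):
        raise ValueError("subtype_numbers must align with signatures")
    classes: dict[tuple, list[int]] = {}
    for i, sig in enumerate(signatures):
        if sig.n_cys not in cluster_type.cysteine_count_allowed:
            raise ValueError(
                f"signature {sig} ({sig.n_cys} cysteines) not structurally valid "
                f"for {cluster_type.value}"
            )
        classes.setdefault(_shape_class(sig, cluster_type), []).append(i)
    out: list[CanonicalMotif] = []
    for _, members in sorted(classes.items(), key=lambda kv: (-len(kv[1]), kv[1][0])):
        sigs = [signatures[i] for i in members]
        ngap = sigs[0].n_cys - 1
        ranges = tuple(
            (min(s.gaps[j] for s in sigs), max(s.gaps[j] for s in sigs))
            for j in range(ngap)
        )
        slots = tuple(s for s in cluster_type.proline_slots if s <= sigs[0].n_cys)
        member_subs = (
            tuple(subtype_numbers[i] for i in members) if subtype_numbers is not None else ()
        )
        out.append(CanonicalMotif(cluster_type, ranges, slots, member_subs))
    return out


# ---------------------------------------------------------------------------
# heat map


@dataclass(frozen=True)
class HeatmapResult:
    """Presence/absence matrix with hierarchical clustering of both axes.

    ``encoded`` holds 3 for subtype presence and -3 for absence (the scheme
    used for red/green heat-map rendering); orders are post-clustering leaf
    orders; linkages are scipy linkage matrices (None for singleton axes).
    """

    encoded: pd.DataFrame
    row_order: tuple
    col_order: tuple
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None

    def reordered(self) -> pd.DataFrame:
        return self.encoded.loc[list(self.row_order), list(self.col_order)]

    def to_newick(self, axis: str = "rows") -> str:
        """Dendrogram of one axis in Newick format (branch lengths = merge heights)."""
        if axis == "rows":
            linkage, labels = self.row_linkage, list(self.encoded.index)
        elif axis == "columns":
            linkage, labels = self.col_linkage, list(self.encoded.columns)
        else:
            raise ValueError("axis must be 'rows' or 'columns'")
        names = [_leaf_name(l) for l in labels]
        if linkage is None:
            return f"({names[0]});" if len(names) == 1 else "();"
        tree = sch.to_tree(linkage)
        return _tree_to_newick(tree, names) + ";"

    def plot(self, path: str) -> None:
        """Render the clustered matrix as a red/green heat map image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        data = self.reordered()
        fig, ax = plt.subplots(
            figsize=(2 + 0.6 * data.shape[1], 2 + 0.12 * data.shape[0])
        )
        cmap = ListedColormap(["#1a9850", "#d73027"])  # absent green, present red
        ax.imshow((data.values > 0).astype(int), cmap=cmap, aspect="auto", vmin=0, vmax=1)
        ax.set_xticks(range(data.shape[1]), [str(c) for c in data.columns], rotation=45)
        ax.set_yticks(range(data.shape[0]), [_leaf_name(i) for i in data.index], fontsize=4)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _leaf_name(label) -> str:
    if isinstance(label, tuple):
        return "|".join(str(x) for x in label).replace(" ", "")
    return str(label)


def _tree_to_newick(node, names: list[str]) -> str:
    if node.is_leaf():
        return f"{names[node.id]}:{node.dist:.6g}"
    left = _tree_to_newick(node.get_left(), names)
    right = _tree_to_newick(node.get_right(), names)
    return f"({left},{right}):{node.dist:.6g}"


def heatmap(
    matrix: pd.DataFrame,
    domain_partition: Mapping[str, str] | None = None,
) -> HeatmapResult:
    """Encode domain presence as +/-3 and cluster both axes.

    Agglomerative clustering with Euclidean distances and average linkage;
    leaf order is scipy's deterministic order, so ties resolve toward lower
    original index.  Singleton axes are left unclustered.
    """
    if matrix.empty:
        raise ValueError("matrix must be non-empty")
    part = dict(domain_partition or DEFAULT_DOMAIN_PARTITION)
    pres = _domain_presence(matrix, part)
    encoded = pres.astype(int) * 6 - 3  # True -> 3, False -> -3
    row_linkage = col_linkage = None
    row_order = tuple(encoded.index)
    col_order = tuple(encoded.columns)
    if encoded.shape[0] > 1:
        row_linkage = sch.linkage(encoded.values, method="average", metric="euclidean")
        row_order = tuple(encoded.index[i] for i in sch.leaves_list(row_linkage))
    if encoded.shape[1] > 1:
        col_linkage = sch.linkage(encoded.values.T, method="average", metric="euclidean")
        col_order = tuple(encoded.columns[i] for i in sch.leaves_list(col_linkage))
    return HeatmapResult(
        encoded=encoded,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
    )
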