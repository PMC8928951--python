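"""Subtype registry: the packaged subtype inventory, lookup and minting.

Every ferredoxin subtype is defined by its exact cysteine-spacing signature
within a cluster type.  The packaged registry transcribes the full published
inventory — 55 2Fe-2S, 7 3Fe-4S, 12 4Fe-4S, 10 7Fe-8S, 33 2[4Fe-4S] and 10
2[4Fe-4S]Alv subtypes — together with per-taxon occurrence counts for five
groups: the two surveyed bacterial clades (Alphaproteobacteria, Firmicutes)
and the literature/PDB collections for Archaea, other Bacteria and Eukarya.

Subtype numbers were assigned in order of first occurrence, so a handful of
signatures appear under two numbers (2Fe-2S 3/55 and 4/19, 3Fe-4S 3/5).  The
printed numbering is kept verbatim for count bookkeeping; signature lookup
resolves such duplicates to the lowest number via an alias map.  Unknown
signatures can be *minted*: they deterministically receive the next free
number within their type.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .signature import (
    ClusterType,
    SpacingSignature,
    TYPE_ORDER,
    format_signature,
    infer_cluster_type,
    parse_signature,
    signature_length,
)

__all__ = [
    "GROUPS",
    "SubtypeRecord",
    "Registry",
    "RegistryLoadError",
    "load_builtin_registry",
    "load_registry_tsv",
    "assign_subtype",
    "nomenclature_label",
]

#: taxon-group columns of the registry, in canonical order
GROUPS: tuple[str, ...] = (
    "Alphaproteobacteria",
    "Firmicutes",
    "Archaea",
    "Bacteria_lit",
    "Eukarya",
)

_DATA_PACKAGE = "fdxmotif.data"
_BUILTIN_FILE = "table2_registry.tsv"


class RegistryLoadError(ValueError):
    """A registry data file is malformed; the message names the row."""


@dataclass(frozen=True)
class SubtypeRecord:
    """One registry row: a subtype of one cluster type.

    ``printed_length`` is the motif length as published; for four rows it
    disagrees with the arithmetic length of the signature (typographical
    errata in the source table) and ``length_erratum`` is then True.
    """

    cluster_type: ClusterType
    subtype_number: int
    signature: SpacingSignature
    printed_length: int
    counts: dict[str, int] = field(default_factory=dict)
    minted: bool = False

    def __post_init__(self) -> None:
        if self.subtype_number < 1:
            raise ValueError("subtype numbers start at 1")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        unknown = set(self.counts) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group column(s): {sorted(unknown)}")

    @property
    def computed_length(self) -> int:
        return signature_length(self.signature)

    @property
    def length_erratum(self) -> bool:
        return self.printed_length != self.computed_length

    @property
    def label(self) -> str:
        return nomenclature_label(self.cluster_type, self.subtype_number)

    def count(self, group: str) -> int:
        return self.counts.get(group, 0)


def nomenclature_label(cluster_type: ClusterType, subtype_number: int) -> str:
    """Render the nomenclature label, e.g. ``2Fe-2S-ST1``.

    Cluster type spelled in full, then ``ST`` for subtype, then the numeral;
    the hyphen separator is this package's serialization choice.
    """
    if subtype_number < 1:
        raise ValueError("subtype numbers start at 1")
    return f"{cluster_type.value}-ST{subtype_number}"


def _sig_key(sig: SpacingSignature) -> tuple:
    return (sig.gaps, sig.proline_after)


class Registry:
    """Keyed collection of subtype records with alias resolution and minting."""

    def __init__(self, records: Iterable[SubtypeRecord] = ()):
        self.records: list[SubtypeRecord] = []
        # (cluster_type, gap/proline key) -> canonical (lowest) subtype number
        self._lookup: dict[tuple[ClusterType, tuple], int] = {}
        #: duplicate signatures: (cluster_type, signature string) -> canonical number
        self.alias_map: dict[tuple[ClusterType, str], int] = {}
        self._max_number: dict[ClusterType, int] = {t: 0 for t in ClusterType}
        for rec in records:
            self.add(rec)

    def add(self, rec: SubtypeRecord) -> None:
        key = (rec.cluster_type, rec.subtype_number)
        if any(
            (r.cluster_type, r.subtype_number) == key for r in self.records
        ):
            raise ValueError(f"duplicate subtype number {rec.label}")
        self.records.append(rec)
        lk = (rec.cluster_type, _sig_key(rec.signature))
        if lk in self._lookup:
            canonical = min(self._lookup[lk], rec.subtype_number)
            self._lookup[lk] = canonical
            self.alias_map[(rec.cluster_type, format_signature(rec.signature))] = canonical
        else:
            self._lookup[lk] = rec.subtype_number
        if rec.subtype_number > self._max_number[rec.cluster_type]:
            self._max_number[rec.cluster_type] = rec.subtype_number

    # -- queries ---------------------------------------------------------

    def records_for(self, cluster_type: ClusterType) -> list[SubtypeRecord]:
        recs = [r for r in self.records if r.cluster_type is cluster_type]
        recs.sort(key=lambda r: r.subtype_number)
        return recs

    def get(self, cluster_type: ClusterType, subtype_number: int) -> SubtypeRecord:
        for r in self.records:
            if r.cluster_type is cluster_type and r.subtype_number == subtype_number:
                return r
        raise KeyError(nomenclature_label(cluster_type, subtype_number))

    def lookup(
        self, cluster_type: ClusterType, sig: SpacingSignature | str
    ) -> int | None:
        """Canonical subtype number for a signature, or None if unregistered."""
        if isinstance(sig, str):
            sig = parse_signature(sig)
        return self._lookup.get((cluster_type, _sig_key(sig)))

    def max_subtype(self, cluster_type: ClusterType) -> int:
        return self._max_number[cluster_type]

    # -- minting ---------------------------------------------------------

    def assign_subtype(
        self, cluster_type: ClusterType, sig: SpacingSignature | str
    ) -> tuple[int, bool]:
        """Assign a subtype number to a signature, minting when novel.

        An exact gap-tuple (and proline-slot) match returns the existing
        number — the canonical one when the signature is duplicated — with
        ``novel=False``.  Otherwise the next free number within the cluster
        type is minted, the registry updated, and ``novel=True`` returned.
        Minting is deterministic and idempotent: replaying the same signature
        stream yields the same numbers.
        """
        if isinstance(sig, str):
            sig = parse_signature(sig)
        inferred = infer_cluster_type(sig)
        if inferred is not cluster_type:
            raise ValueError(
                f"signature {format_signature(sig)} has the structure of "
                f"{inferred.value if inferred else 'no known type'}, not {cluster_type.value}"
            )
        existing = self.lookup(cluster_type, sig)
        if existing is not None:
            return existing, False
        number = self._max_number[cluster_type] + 1
        self.add(
            SubtypeRecord(
                cluster_type=cluster_type,
                subtype_number=number,
                signature=sig,
                printed_length=signature_length(sig),
                counts={},
                minted=True,
            )
        )
        return number, True

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "groups": list(GROUPS),
            "records": [
                {
                    "cluster_type": r.cluster_type.value,
                    "subtype": r.subtype_number,
                    "label": r.label,
                    "signature": format_signature(r.signature),
                    "length": r.computed_length,
                    "printed_length": r.printed_length,
                    "length_erratum": r.length_erratum,
                    "minted": r.minted,
                    "counts": {g: r.count(g) for g in GROUPS},
                }
                for r in sorted(
                    self.records,
                    key=lambda r: (TYPE_ORDER.index(r.cluster_type), r.subtype_number),
                )
            ],
            "aliases": [
                {
                    "cluster_type": t.value,
                    "signature": s,
                    "canonical_subtype": n,
                }
                for (t, s), n in sorted(
                    self.alias_map.items(), key=lambda kv: (kv[0][0].value, kv[1])
                )
            ],
        }
        return json.dumps(payload, indent=2)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["cluster_type", "subtype", "signature", "length_printed", *GROUPS])
            for r in sorted(
                self.records,
                key=lambda r: (TYPE_ORDER.index(r.cluster_type), r.subtype_number),
            ):
                w.writerow(
                    [
                        r.cluster_type.value,
                        r.subtype_number,
                        format_signature(r.signature),
                        r.printed_length,
                        *[r.count(g) for g in GROUPS],
                    ]
                )


def _parse_row(row: dict[str, str], rownum: int) -> SubtypeRecord:
    try:
        cluster_type = ClusterType.from_name(row["cluster_type"].strip())
        number = int(row["subtype"])
        sig = parse_signature(row["signature"])
        printed = int(row["length_printed"])
        counts = {g: int(row[g] or 0) for g in GROUPS if g in row and row[g] != ""}
    except (KeyError, ValueError) as exc:
        raise RegistryLoadError(f"registry row {rownum}: {exc}") from exc
    if sig.n_cys not in cluster_type.cysteine_count_allowed:
        raise RegistryLoadError(
            f"registry row {rownum}: {sig.n_cys} cysteines not allowed for "
            f"{cluster_type.value}"
        )
    return SubtypeRecord(
        cluster_type=cluster_type,
        subtype_number=number,
        signature=sig,
        printed_length=printed,
        counts=counts,
    )


def load_registry_tsv(path: str | Path) -> Registry:
    """Load a registry from a tab-separated file (same columns as packaged)."""
    reg = Registry()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rownum, row in enumerate(reader, start=2):
            reg.add(_parse_row(row, rownum))
    return reg


def load_builtin_registry() -> Registry:
    """Load the packaged subtype inventory (127 subtype rows)."""
    ref = resources.files(_DATA_PACKAGE).joinpath(_BUILTIN_FILE)
    with resources.as_file(ref) as path:
        return load_registry_tsv(path)


def assign_subtype(
    reg: Registry, cluster_type: ClusterType, sig: SpacingSignature | str
) -> tuple[int, bool]:
    """Module-level convenience wrapper around :meth:`Registry.assign_subtype`."""
    return reg.assign_subtype(cluster_type, sig)
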