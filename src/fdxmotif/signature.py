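"""Cysteine-spacing signature grammar for ferredoxin Fe-S binding motifs.

A ferredoxin Fe-S cluster is ligated by a small set of cysteines whose exact
spacing along the chain is conserved within a subtype.  A *spacing signature*
writes that pattern down, e.g. ``CX5CX2CX36C``: a cysteine, five arbitrary
residues, a cysteine, and so on.  Some cluster types additionally carry a
conserved proline immediately after particular cysteines, written ``CP`` (for
3Fe-4S and 4Fe-4S after the final cysteine, for 7Fe-8S after the third and
final ones).

This module defines the six cluster types, the signature value object with
parse/format round-tripping, motif length arithmetic, and structural
cluster-type inference from a bare signature.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterator, Union

__all__ = [
    "ClusterType",
    "SpacingSignature",
    "SignatureParseError",
    "CYS",
    "PRO",
    "GAP",
    "parse_signature",
    "format_signature",
    "signature_length",
    "infer_cluster_type",
]


class SignatureParseError(ValueError):
    """Raised when a signature string violates the grammar.

    Carries ``position``, the 0-based offset of the offending character in the
    normalized (underscore-stripped) input.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ClusterType(enum.Enum):
    """The six ferredoxin Fe-S cluster types.

    ``cysteine_count_allowed`` is the set of cluster-ligating cysteine counts a
    signature of this type may have; ``proline_slots`` lists the (1-based)
    cysteine indices after which a conserved proline is part of the motif.
    Proline is not conserved in 2[4Fe-4S]/2[4Fe-4S]Alv ferredoxins and is
    therefore never part of those signatures.
    """

    FE2S2 = "2Fe-2S"
    FE3S4 = "3Fe-4S"
    FE4S4 = "4Fe-4S"
    FE7S8 = "7Fe-8S"
    BIS_FE4S4 = "2[4Fe-4S]"
    BIS_FE4S4_ALV = "2[4Fe-4S]Alv"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def cysteine_count_allowed(self) -> frozenset[int]:
        return _CYS_COUNTS[self]

    @property
    def proline_slots(self) -> tuple[int, ...]:
        return _PRO_SLOTS[self]

    @classmethod
    def from_name(cls, name: str) -> "ClusterType":
        for member in cls:
            if member.value == name:
                return member
        raise KeyError(f"unknown cluster type: {name!r}")


_CYS_COUNTS = {
    ClusterType.FE2S2: frozenset({3, 4}),
    ClusterType.FE3S4: frozenset({3}),
    ClusterType.FE4S4: frozenset({4}),
    ClusterType.FE7S8: frozenset({7}),
    ClusterType.BIS_FE4S4: frozenset({8}),
    ClusterType.BIS_FE4S4_ALV: frozenset({9}),
}

_PRO_SLOTS = {
    ClusterType.FE2S2: (),
    ClusterType.FE3S4: (3,),
    ClusterType.FE4S4: (4,),
    ClusterType.FE7S8: (3, 7),
    ClusterType.BIS_FE4S4: (),
    ClusterType.BIS_FE4S4_ALV: (),
}

#: order in which the cluster types are conventionally listed
TYPE_ORDER: tuple[ClusterType, ...] = (
    ClusterType.FE2S2,
    ClusterType.FE3S4,
    ClusterType.FE4S4,
    ClusterType.FE7S8,
    ClusterType.BIS_FE4S4,
    ClusterType.BIS_FE4S4_ALV,
)


# Token model: a signature is a sequence of CYS, GAP(n) and PRO tokens.  PRO
# may only follow CYS, GAP must sit between two CYS (or CYS-PRO ... CYS for
# the 7Fe-8S internal proline).
class _Cys:
    __slots__ = ()

    def __repr__(self) -> str:
        return "CYS"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _Cys)

    def __hash__(self) -> int:
        return hash("CYS")


class _Pro:
    __slots__ = ()

    def __repr__(self) -> str:
        return "PRO"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _Pro)

    def __hash__(self) -> int:
        return hash("PRO")


@dataclass(frozen=True)
class GAP:
    """A run of ``n`` arbitrary residues between two motif cysteines."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("gap length must be a positive residue count")

    def __repr__(self) -> str:
        return f"GAP {self.n}"


CYS = _Cys()
PRO = _Pro()
Token = Union[_Cys, _Pro, GAP]


@dataclass(frozen=True)
class SpacingSignature:
    """One cysteine-spacing signature.

    Stored in normal form as the inter-cysteine gap tuple plus the set of
    (1-based) cysteine indices followed by a conserved proline; the token list
    and string form are derived.  Instances are immutable and hashable, so
    they can key registry lookups.
    """

    gaps: tuple[int, ...]
    proline_after: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gaps", tuple(int(g) for g in self.gaps))
        object.__setattr__(self, "proline_after", frozenset(int(i) for i in self.proline_after))
        if any(g < 1 for g in self.gaps):
            raise ValueError("all gaps must be positive residue counts")
        bad = [i for i in self.proline_after if not 1 <= i <= self.n_cys]
        if bad:
            raise ValueError(f"proline slot(s) {sorted(bad)} outside cysteine range 1..{self.n_cys}")

    @property
    def n_cys(self) -> int:
        return len(self.gaps) + 1

    @property
    def tokens(self) -> list[Token]:
        out: list[Token] = [CYS]
        for i, g in enumerate(self.gaps, start=1):
            if i in self.proline_after:
                out.append(PRO)
            out.append(GAP(g))
            out.append(CYS)
        if self.n_cys in self.proline_after:
            out.append(PRO)
        return out

    def __str__(self) -> str:
        return format_signature(self)

    def __len__(self) -> int:
        return signature_length(self)


_TOKEN_RE = re.compile(r"C|P|X(\d*)|(.)")


def parse_signature(text: str) -> SpacingSignature:
    """Parse a signature string like ``CX5CX2CX36C`` or ``CX5CX38CP``.

    Underscores and whitespace (artifacts of subscript typography, e.g.
    ``CX_5_CX_2_CX_36_C``) are stripped before parsing.  The pattern must
    start on a cysteine and end on a cysteine or a cysteine-proline; ``P`` is
    only legal immediately after a ``C``; every ``X`` must carry an explicit
    positive residue count.

    Raises :class:`SignatureParseError` naming the offending position.
    """
    if not isinstance(text, str):
        raise TypeError("signature must be a string")
    norm = re.sub(r"[\s_]+", "", text)
    if not norm:
        raise SignatureParseError("empty signature", 0)

    gaps: list[int] = []
    proline_after: set[int] = set()
    n_cys = 0
    # state: what we may accept next
    expect_cys = True          # at start, only C
    last_was_gap = False
    pos = 0
    for m in _TOKEN_RE.finditer(norm):
        pos = m.start()
        tok = m.group(0)
        if m.group(2) is not None:
            raise SignatureParseError(f"illegal character {tok!r}", pos)
        if tok == "C":
            if n_cys > 0 and not last_was_gap:
                raise SignatureParseError("cysteine must be separated by a gap", pos)
            n_cys += 1
            last_was_gap = False
            expect_cys = False
        elif tok == "P":
            if n_cys == 0 or last_was_gap:
                raise SignatureParseError("proline only legal immediately after a cysteine", pos)
            if n_cys in proline_after:
                raise SignatureParseError("duplicate proline marker", pos)
            proline_after.add(n_cys)
        else:  # X...
            digits = m.group(1)
            if n_cys == 0:
                raise SignatureParseError("signature must start with a cysteine", pos)
            if last_was_gap:
                raise SignatureParseError("two adjacent gaps", pos)
            if not digits:
                raise SignatureParseError("gap lacks a residue count", pos)
            n = int(digits)
            if n == 0:
                raise SignatureParseError("zero-length gap not allowed", pos)
            gaps.append(n)
            last_was_gap = True
    if last_was_gap:
        raise SignatureParseError("signature must end with a cysteine", len(norm) - 1)
    return SpacingSignature(gaps=tuple(gaps), proline_after=frozenset(proline_after))


def format_signature(sig: SpacingSignature) -> str:
    """Serialize to the plain-ASCII canonical form (``CX5CX2CX36C``).

    Inverse of :func:`parse_signature`; underscores are never emitted.
    """
    parts = ["C"]
    for i, g in enumerate(sig.gaps, start=1):
        if i in sig.proline_after:
            parts.append("P")
        parts.append(f"X{g}C")
    if sig.n_cys in sig.proline_after:
        parts.append("P")
    return "".join(parts)


def signature_length(sig: SpacingSignature) -> int:
    """Motif length in residues, both terminal residues inclusive.

    Cysteines + gap residues + conserved prolines; this is the quantity the
    registry prints as the motif's amino-acid count.
    """
    return sig.n_cys + sum(sig.gaps) + len(sig.proline_after)


def infer_cluster_type(sig: SpacingSignature) -> ClusterType | None:
    """Infer the Fe-S cluster type from signature structure alone.

    Decision is purely structural: nine cysteines are the Alvin-type double
    cluster (extra cysteine after the second 4Fe-4S cluster), eight the plain
    double cluster, seven the 7Fe-8S dual cluster; three or four cysteines
    with a terminal proline are 3Fe-4S / 4Fe-4S respectively, without any
    proline 2Fe-2S.  Impossible structures return ``None`` rather than raise.
    """
    n = sig.n_cys
    if n == 9:
        return ClusterType.BIS_FE4S4_ALV
    if n == 8:
        return ClusterType.BIS_FE4S4
    if n == 7:
        return ClusterType.FE7S8
    if n in (3, 4):
        if not sig.proline_after:
            return ClusterType.FE2S2
        if sig.proline_after == frozenset({n}):
            return ClusterType.FE3S4 if n == 3 else ClusterType.FE4S4
    return None
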