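"""Pattern-structural scanner for ferredoxin Fe-S binding motifs.

Detection is template driven: each cluster type has a canonical motif whose
inter-cysteine gaps are allowed ranges rather than fixed counts (the 2Fe-2S
type has three such canonical motifs).  A hit is any choice of cysteine
positions in the sequence whose consecutive gaps all fall inside one
template's ranges and whose required prolines are present.  No homology or
profile scoring is involved; detection is purely structural.

Gap residues are unconstrained, so decoy cysteines inside a gap do not block
a match — the scanner considers every cysteine subset consistent with the
ranges, not just runs of consecutive cysteines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .signature import (
    ClusterType,
    SpacingSignature,
    TYPE_ORDER,
)

__all__ = [
    "CanonicalTemplate",
    "ScanConfig",
    "MotifHit",
    "MotifIntegrityError",
    "CANONICAL_TEMPLATES",
    "build_templates",
    "scan_sequence",
    "resolve_overlaps",
    "extract_signature",
]

#: residues that may satisfy a cysteine/proline template position.  Ambiguity
#: codes (B, Z, X, U, ...) never match; they are legal only inside gaps.
_CYS_RES = "C"
_PRO_RES = "P"


class MotifIntegrityError(ValueError):
    """A hit's recorded coordinates disagree with the sequence content."""


@dataclass(frozen=True)
class CanonicalTemplate:
    """A ranged motif pattern for one cluster type.

    ``gap_ranges[i]`` bounds (inclusive) the residue count between cysteine
    i+1 and cysteine i+2; ``proline_slots`` lists 1-based cysteine indices
    that must be directly followed by a proline.  A proline occupies one
    residue between its cysteine and the following gap.
    """

    cluster_type: ClusterType
    gap_ranges: tuple[tuple[int, int], ...]
    proline_slots: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for lo, hi in self.gap_ranges:
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid gap range ({lo},{hi})")

    @property
    def n_cys(self) -> int:
        return len(self.gap_ranges) + 1

    def admits(self, sig: SpacingSignature) -> bool:
        """True if every gap of ``sig`` lies inside this template's ranges.

        Only the gap geometry is compared; proline slots are the template's
        responsibility during sequence matching (proline conservation is
        known to be imperfect, e.g. the 7Fe-8S terminal slot).
        """
        if sig.n_cys != self.n_cys:
            return False
        return all(lo <= g <= hi for g, (lo, hi) in zip(sig.gaps, self.gap_ranges))


# Canonical gap ranges per cluster type, as deduced from the full subtype
# inventory.  2Fe-2S admits three distinct motif shapes; every other type a
# single one.  These are frozen here (not recomputed from the registry) so
# scanning behaviour stays put even when users extend the registry.
CANONICAL_TEMPLATES: tuple[CanonicalTemplate, ...] = (
    CanonicalTemplate(ClusterType.FE2S2, ((3, 5), (1, 2), (22, 82))),
    CanonicalTemplate(ClusterType.FE2S2, ((2, 12), (30, 44), (3, 3))),
    CanonicalTemplate(ClusterType.FE2S2, ((4, 7), (29, 35))),
    CanonicalTemplate(ClusterType.FE3S4, ((5, 5), (35, 49)), proline_slots=(3,)),
    CanonicalTemplate(ClusterType.FE4S4, ((2, 5), (2, 3), (30, 45)), proline_slots=(4,)),
    CanonicalTemplate(
        ClusterType.FE7S8,
        ((3, 10), (3, 3), (17, 40), (2, 2), (2, 2), (3, 3)),
        proline_slots=(3, 7),
    ),
    CanonicalTemplate(
        ClusterType.BIS_FE4S4,
        ((2, 7), (2, 4), (2, 3), (14, 42), (1, 2), (2, 8), (3, 3)),
    ),
    CanonicalTemplate(
        ClusterType.BIS_FE4S4_ALV,
        ((2, 2), (2, 2), (3, 3), (18, 46), (2, 2), (2, 8), (3, 3), (3, 3)),
    ),
)

#: ambiguity precedence when hits overlap: the most information-rich (largest)
#: cluster wins, mirroring how a double cluster subsumes its single-cluster
#: sub-patterns.
PRECEDENCE: dict[ClusterType, int] = {
    ClusterType.BIS_FE4S4_ALV: 6,
    ClusterType.BIS_FE4S4: 5,
    ClusterType.FE7S8: 4,
    ClusterType.FE4S4: 3,
    ClusterType.FE3S4: 2,
    ClusterType.FE2S2: 1,
}


@dataclass(frozen=True)
class ScanConfig:
    """Scanner behaviour.

    mode
        ``strict-canonical`` (default) uses the frozen canonical ranges;
        ``permissive`` widens every canonical range by ``slack`` on both sides
        (minimum floored at 1); ``registry-exact`` matches only the exact
        signatures of a supplied registry, one degenerate template per
        distinct signature.
    require_terminal_proline_7fe8s
        The 7Fe-8S terminal proline is conserved in all but one known case
        (an arginine in M. tuberculosis FdxA/Rv2007c); set False to relax it.
    """

    mode: str = "strict-canonical"
    slack: int = 0
    require_terminal_proline_7fe8s: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("strict-canonical", "registry-exact", "permissive"):
            raise ValueError(f"unknown scan mode: {self.mode!r}")
        if self.slack < 0:
            raise ValueError("slack must be non-negative")
        if self.mode == "strict-canonical" and self.slack != 0:
            raise ValueError("slack must be 0 in strict-canonical mode")


@dataclass(frozen=True)
class MotifHit:
    """A located motif occurrence.

    Coordinates are 0-based; ``span`` is half-open and covers the first
    cysteine through the last motif residue (cysteine or terminal proline).
    """

    sequence_id: str
    cys_positions: tuple[int, ...]
    pro_positions: tuple[int, ...]
    cluster_type: ClusterType
    signature: SpacingSignature
    span: tuple[int, int]

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


def build_templates(config: ScanConfig, registry=None) -> list[CanonicalTemplate]:
    """Materialize the template set for a configuration.

    ``registry`` is only consulted in ``registry-exact`` mode, where each
    distinct registered signature becomes one degenerate (min==max) template.
    """
    if config.mode == "registry-exact":
        if registry is None:
            raise ValueError("registry-exact mode needs a registry")
        seen: set[tuple] = set()
        out: list[CanonicalTemplate] = []
        for rec in registry.records:
            sig = rec.signature
            key = (rec.cluster_type, sig.gaps, sig.proline_after)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                CanonicalTemplate(
                    rec.cluster_type,
                    tuple((g, g) for g in sig.gaps),
                    proline_slots=tuple(sorted(sig.proline_after)),
                )
            )
        return out

    out = []
    for tpl in CANONICAL_TEMPLATES:
        ranges = tpl.gap_ranges
        if config.mode == "permissive" and config.slack:
            ranges = tuple((max(1, lo - config.slack), hi + config.slack) for lo, hi in ranges)
        slots = tpl.proline_slots
        if (
            tpl.cluster_type is ClusterType.FE7S8
            and not config.require_terminal_proline_7fe8s
        ):
            slots = tuple(s for s in slots if s != tpl.n_cys)
        out.append(replace(tpl, gap_ranges=ranges, proline_slots=slots))
    return out


def _match_template(
    seq: str, cys_at: Sequence[int], tpl: CanonicalTemplate
) -> Iterable[tuple[int, ...]]:
    """Yield every tuple of cysteine positions matching ``tpl`` in ``seq``.

    Depth-first extension over the (sorted) cysteine position list; the next
    cysteine of a partial match may be any cysteine whose distance lands the
    gap inside the allowed range, so decoys inside gaps are stepped over.
    """
    n = len(seq)
    slots = set(tpl.proline_slots)

    def pro_ok(cys_index_1based: int, pos: int) -> bool:
        if cys_index_1based not in slots:
            return True
        return pos + 1 < n and seq[pos + 1] == _PRO_RES

    def extend(chosen: list[int], depth: int) -> Iterable[tuple[int, ...]]:
        if depth == len(tpl.gap_ranges):
            if pro_ok(tpl.n_cys, chosen[-1]):
                yield tuple(chosen)
            return
        prev = chosen[-1]
        pro = 1 if (depth + 1) in slots else 0
        if pro and not pro_ok(depth + 1, prev):
            return
        lo, hi = tpl.gap_ranges[depth]
        lo_pos = prev + 1 + pro + lo
        hi_pos = prev + 1 + pro + hi
        for q in cys_at:
            if q < lo_pos:
                continue
            if q > hi_pos:
                break
            chosen.append(q)
            yield from extend(chosen, depth + 1)
            chosen.pop()

    for p in cys_at:
        yield from extend([p], 0)


def _hit_from_positions(
    seq: str, seq_id: str, positions: tuple[int, ...], tpl: CanonicalTemplate
) -> MotifHit:
    # record prolines on the cluster type's slots (not just the template's):
    # a conserved proline present in the sequence is part of the motif even
    # when matching ran with a relaxed requirement.
    pro_positions = tuple(
        positions[s - 1] + 1
        for s in tpl.cluster_type.proline_slots
        if positions[s - 1] + 1 < len(seq) and seq[positions[s - 1] + 1] == _PRO_RES
    )
    sig = _signature_from_positions(positions, pro_positions, tpl.cluster_type)
    last = max((positions[-1],) + pro_positions)
    return MotifHit(
        sequence_id=seq_id,
        cys_positions=positions,
        pro_positions=pro_positions,
        cluster_type=tpl.cluster_type,
        signature=sig,
        span=(positions[0], last + 1),
    )


def _signature_from_positions(
    cys_positions: Sequence[int],
    pro_positions: Sequence[int],
    cluster_type: ClusterType,
) -> SpacingSignature:
    pro_set = set(pro_positions)
    proline_after = frozenset(
        i for i, p in enumerate(cys_positions, start=1) if p + 1 in pro_set
    )
    gaps = []
    for i in range(len(cys_positions) - 1):
        pro = 1 if (i + 1) in proline_after else 0
        gap = cys_positions[i + 1] - cys_positions[i] - 1 - pro
        gaps.append(gap)
    return SpacingSignature(gaps=tuple(gaps), proline_after=proline_after)


def scan_sequence(
    seq: str,
    seq_id: str = "",
    config: ScanConfig | None = None,
    registry=None,
    resolve: bool = True,
) -> list[MotifHit]:
    """Find all Fe-S motif occurrences in one amino-acid sequence.

    The sequence must be uppercase one-letter amino-acid text; ambiguity
    characters are legal but never satisfy a cysteine or proline position.
    Hits are returned in ascending start order; when ``resolve`` is true,
    overlapping hits are reduced per :func:`resolve_overlaps`.  An empty
    sequence yields an empty list.
    """
    config = config or ScanConfig()
    templates = build_templates(config, registry=registry)
    cys_at = [i for i, ch in enumerate(seq) if ch == _CYS_RES]
    hits: list[MotifHit] = []
    seen: set[tuple[ClusterType, tuple[int, ...]]] = set()
    for tpl in templates:
        if len(cys_at) < tpl.n_cys:
            continue
        for positions in _match_template(seq, cys_at, tpl):
            key = (tpl.cluster_type, positions)
            if key in seen:
                continue
            seen.add(key)
            hits.append(_hit_from_positions(seq, seq_id, positions, tpl))
    hits.sort(key=lambda h: (h.start, h.end, PRECEDENCE[h.cluster_type]))
    if resolve:
        hits = resolve_overlaps(hits)
    return hits


def resolve_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    """Reduce a hit list from one sequence to non-conflicting hits.

    Two hits conflict when they share a cysteine position.  Greedy selection
    in priority order: higher cluster-type precedence first (the double
    clusters subsume their embedded single-cluster sub-patterns), then
    leftmost start, then longest span.  Hits that conflict with an already
    kept hit are dropped; non-overlapping hits are all retained.  Output is
    in ascending start order.
    """
    order = sorted(
        hits,
        key=lambda h: (
            -PRECEDENCE[h.cluster_type],
            h.start,
            -(h.end - h.start),
            -len(h.cys_positions),
        ),
    )
    kept: list[MotifHit] = []
    used: set[int] = set()
    for h in order:
        if used.intersection(h.cys_positions):
            continue
        used.update(h.cys_positions)
        kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end))
    return kept


def extract_signature(seq: str, hit: MotifHit) -> SpacingSignature:
    """Recover the exact spacing signature of a hit from the sequence.

    Gaps are the differences between consecutive cysteine positions minus one
    (minus one more where a recorded proline sits between them); proline
    markers are attached only at the hit's cluster-type slots.  Raises
    :class:`MotifIntegrityError` if the recorded coordinates do not point at
    the residues they claim.
    """
    for p in hit.cys_positions:
        if p >= len(seq) or seq[p] != _CYS_RES:
            raise MotifIntegrityError(
                f"position {p} of {hit.sequence_id or 'sequence'} is not a cysteine"
            )
    for p in hit.pro_positions:
        if p >= len(seq) or seq[p] != _PRO_RES:
            raise MotifIntegrityError(
                f"position {p} of {hit.sequence_id or 'sequence'} is not a proline"
            )
    allowed = {hit.cys_positions[s - 1] + 1 for s in hit.cluster_type.proline_slots
               if s - 1 < len(hit.cys_positions)}
    if not set(hit.pro_positions) <= allowed:
        raise MotifIntegrityError("recorded proline positions off the cluster-type slots")
    return _signature_from_positions(hit.cys_positions, hit.pro_positions, hit.cluster_type)
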