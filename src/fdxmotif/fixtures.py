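"""Seeded synthetic sequences with known embedded Fe-S motifs.

The generator writes a signature into a cysteine-free random background, so
the embedded motif is the only structural match and ground truth is exact:
scanning must recover every planted motif at its exact coordinates with no
spurious hits.  A "hostile" mode sprinkles decoy cysteines into the flanks
for stress testing (recall still holds; zero-false-positive does not, by
design).  Perturbed signatures — a gap pushed past its canonical maximum, a
required proline or a cysteine removed — serve as negative controls that a
strict scan must reject.

Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scanner import CANONICAL_TEMPLATES, CanonicalTemplate
from .signature import (
    ClusterType,
    SpacingSignature,
    format_signature,
    infer_cluster_type,
    parse_signature,
    signature_length,
)

__all__ = [
    "BACKGROUND_ALPHABET",
    "FixtureSpec",
    "FixtureEntry",
    "TruthRecord",
    "realize_signature",
    "generate_dataset",
    "perturb_motif",
]

#: standard amino acids minus cysteine (and retaining proline; proline is
#: suppressed only directly after an embedded cysteine, where it would read
#: as a motif proline marker)
BACKGROUND_ALPHABET = "ADEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureEntry:
    """One planted motif family: a signature, flank lengths and a copy count."""

    signature: str
    flank: tuple[int, int] = (30, 30)
    count: int = 1

    def __post_init__(self) -> None:
        if self.flank[0] < 0 or self.flank[1] < 0:
            raise ValueError("flank lengths must be non-negative")
        if self.count < 1:
            raise ValueError("count must be positive")


@dataclass(frozen=True)
class FixtureSpec:
    """A reproducible synthetic dataset description."""

    entries: tuple[FixtureEntry, ...]
    background_alphabet: str = BACKGROUND_ALPHABET
    seed: int = 0
    hostile_decoys: int = 0  # decoy cysteines sprinkled into each record's flanks

    def __post_init__(self) -> None:
        if "C" in self.background_alphabet:
            raise ValueError("background alphabet must exclude cysteine")
        if self.hostile_decoys < 0:
            raise ValueError("hostile_decoys must be non-negative")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted sequence."""

    sequence_id: str
    cluster_type: ClusterType
    signature: str
    cys_positions: tuple[int, ...]
    start: int
    end: int


def _draw(rng: random.Random, alphabet: str, forbid: str = "") -> str:
    choices = [a for a in alphabet if a not in forbid]
    return rng.choice(choices)


def realize_signature(
    sig: SpacingSignature | str,
    seed: int | random.Random = 0,
    alphabet: str = BACKGROUND_ALPHABET,
) -> str:
    """Turn a signature into a concrete motif-length peptide.

    Cysteines and conserved prolines go at their signature slots; gap
    residues are drawn uniformly from the background alphabet, except that a
    residue immediately following a cysteine is never proline (it would be
    indistinguishable from a motif proline marker).  The result has exactly
    the signature's motif length and identical realizations follow from
    identical seeds.
    """
    if isinstance(sig, str):
        sig = parse_signature(sig)
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    out: list[str] = []
    for i in range(sig.n_cys):
        out.append("C")
        if (i + 1) in sig.proline_after:
            out.append("P")
        elif i + 1 <= len(sig.gaps):
            out.append(_draw(rng, alphabet, forbid="P"))
            for _ in range(sig.gaps[i] - 1):
                out.append(_draw(rng, alphabet))
            continue
        if i < len(sig.gaps):
            for _ in range(sig.gaps[i]):
                out.append(_draw(rng, alphabet))
    return "".join(out)


def _flank(rng: random.Random, length: int, alphabet: str, no_pro_first: bool) -> str:
    out = []
    for j in range(length):
        forbid = "P" if (no_pro_first and j == 0) else ""
        out.append(_draw(rng, alphabet, forbid=forbid))
    return "".join(out)


def generate_dataset(
    spec: FixtureSpec,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Emit FASTA records with planted motifs plus an aligned truth table.

    Each entry yields ``count`` records with fresh random flanks.  The truth
    table has one row per record (sequence_id, cluster_type, signature,
    0-based cysteine positions comma-joined, motif start, half-open end) and
    aligns 1:1 with the record list.
    """
    rng = random.Random(spec.seed)
    records: list[SeqRecord] = []
    truth_rows: list[dict] = []
    idx = 0
    for entry in spec.entries:
        sig = parse_signature(entry.signature)
        ct = infer_cluster_type(sig)
        if ct is None:
            raise ValueError(f"signature {entry.signature!r} fits no cluster type")
        for _ in range(entry.count):
            idx += 1
            motif = realize_signature(sig, rng, spec.background_alphabet)
            left = _flank(rng, entry.flank[0], spec.background_alphabet, no_pro_first=False)
            # first flank residue after a motif ending on a cysteine must not
            # be proline, or the planted motif could read as a proline-bearing
            # type
            ends_on_c = sig.n_cys not in sig.proline_after
            right = _flank(rng, entry.flank[1], spec.background_alphabet, no_pro_first=ends_on_c)
            seqtext = left + motif + right
            if spec.hostile_decoys:
                seqtext = _sprinkle_decoys(
                    rng, seqtext, len(left), len(left) + len(motif), spec.hostile_decoys
                )
            start = len(left)
            cys_positions = _cys_slots(sig, start)
            seq_id = f"fx{idx:04d}"
            records.append(
                SeqRecord(
                    Seq(seqtext),
                    id=seq_id,
                    description=f"{ct.value} {format_signature(sig)}",
                )
            )
            truth_rows.append(
                {
                    "sequence_id": seq_id,
                    "cluster_type": ct.value,
                    "signature": format_signature(sig),
                    "cys_positions": ",".join(str(p) for p in cys_positions),
                    "start": start,
                    "end": start + signature_length(sig),
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sequence_id", "cluster_type", "signature", "cys_positions", "start", "end"],
    )
    return records, truth


def _cys_slots(sig: SpacingSignature, offset: int) -> tuple[int, ...]:
    pos = offset
    out = [pos]
    for i, g in enumerate(sig.gaps, start=1):
        pos += 1 + (1 if i in sig.proline_after else 0) + g
        out.append(pos)
    return tuple(out)


def _sprinkle_decoys(
    rng: random.Random, seqtext: str, mstart: int, mend: int, n: int
) -> str:
    """Replace up to ``n`` flank residues with decoy cysteines (never adjacent
    to the motif, so planted coordinates stay valid)."""
    chars = list(seqtext)
    candidates = [
        i for i in range(len(chars)) if (i < mstart - 1 or i > mend) and chars[i] != "C"
    ]
    rng.shuffle(candidates)
    for i in candidates[:n]:
        chars[i] = "C"
    return "".join(chars)


def truth_record(row: pd.Series) -> TruthRecord:
    """View a truth-table row as a typed record."""
    return TruthRecord(
        sequence_id=row["sequence_id"],
        cluster_type=ClusterType.from_name(row["cluster_type"]),
        signature=row["signature"],
        cys_positions=tuple(int(x) for x in str(row["cys_positions"]).split(",")),
        start=int(row["start"]),
        end=int(row["end"]),
    )


# ---------------------------------------------------------------------------
# negative controls


def _strict_templates_for(ct: ClusterType) -> list[CanonicalTemplate]:
    return [t for t in CANONICAL_TEMPLATES if t.cluster_type is ct]


def perturb_motif(
    sig: SpacingSignature | str,
    mode: str,
    seed: int = 0,
) -> SpacingSignature:
    """Derive a negative-control signature guaranteed outside its type's
    strict canonical template(s).

    widen-gap
        one gap is pushed past the canonical maximum for its position.
    drop-proline
        the terminal conserved proline is removed (errors for types whose
        signatures carry none).
    drop-cysteine
        one internal cysteine is removed, merging its two gaps.

    The result is checked against every strict template of the original
    cluster type; a perturbation that cannot take the signature outside all
    of them raises ``ValueError``.
    """
    if isinstance(sig, str):
        sig = parse_signature(sig)
    ct = infer_cluster_type(sig)
    if ct is None:
        raise ValueError("signature fits no cluster type; nothing to perturb")
    templates = _strict_templates_for(ct)
    rng = random.Random(seed)

    candidates: list[SpacingSignature] = []
    if mode == "widen-gap":
        order = list(range(len(sig.gaps)))
        rng.shuffle(order)
        for j in order:
            hi = max(
                (t.gap_ranges[j][1] for t in templates if len(t.gap_ranges) == len(sig.gaps)),
                default=max(sig.gaps),
            )
            gaps = list(sig.gaps)
            gaps[j] = hi + 1 + rng.randrange(0, 5)
            candidates.append(SpacingSignature(tuple(gaps), sig.proline_after))
    elif mode == "drop-proline":
        if not sig.proline_after:
            raise ValueError(f"drop-proline not applicable: {ct.value} signatures carry no proline")
        slot = max(sig.proline_after)
        candidates.append(
            SpacingSignature(sig.gaps, sig.proline_after - {slot})
        )
    elif mode == "drop-cysteine":
        order = list(range(2, sig.n_cys))  # internal cysteines, 1-based index
        rng.shuffle(order)
        for i in order:
            gaps = list(sig.gaps)
            merged = gaps[i - 2] + 1 + gaps[i - 1]
            new_gaps = gaps[: i - 2] + [merged] + gaps[i:]
            slots = frozenset(
                s if s < i else s - 1 for s in sig.proline_after if s != i
            )
            candidates.append(SpacingSignature(tuple(new_gaps), slots))
    else:
        raise ValueError(f"unknown perturbation mode: {mode!r}")

    for cand in candidates:
        if not _realization_matches_type(cand, templates):
            return cand
    raise ValueError(f"could not perturb {format_signature(sig)} outside {ct.value} templates")


def _realization_matches_type(
    sig: SpacingSignature, templates: list[CanonicalTemplate]
) -> bool:
    """Would any cysteine subset of this signature's realization still match
    one of the type's strict templates?

    Checked combinatorially on the signature's own geometry (no sequence
    needed): subsets of its cysteine slots with gap arithmetic, prolines
    present exactly where the signature carries them.  This is stricter than
    checking the full signature alone — a widened motif may still contain an
    in-range sub-pattern.
    """
    pos = [0]
    for i, g in enumerate(sig.gaps, start=1):
        pos.append(pos[-1] + 1 + (1 if i in sig.proline_after else 0) + g)
    pro_at = {pos[i - 1] + 1 for i in sig.proline_after}
    for tpl in templates:
        if tpl.n_cys > len(pos):
            continue
        for combo in itertools.combinations(pos, tpl.n_cys):
            ok = True
            for j in range(len(combo) - 1):
                pro = 0
                if (j + 1) in tpl.proline_slots:
                    if combo[j] + 1 not in pro_at:
                        ok = False
                        break
                    pro = 1
                gap = combo[j + 1] - combo[j] - 1 - pro
                lo, hi = tpl.gap_ranges[j]
                if not lo <= gap <= hi:
                    ok = False
                    break
            if ok and tpl.n_cys in tpl.proline_slots and combo[-1] + 1 not in pro_at:
                ok = False
            if ok:
                return True
    return False
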