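"""Shared fixtures: the packaged registry, count matrix, random-sequence
generation and an independent brute-force scanning oracle.

The oracle enumerates every cysteine subset of each template's cardinality
with ``itertools.combinations`` and checks gap ranges and prolines directly
against the sequence — deliberately naive, sharing no code path with the
scanner's depth-first matcher.
"""

from __future__ import annotations

import itertools
import random

import pytest

from fdxmotif import (
    ClusterType,
    ScanConfig,
    build_templates,
    group_count_matrix,
    load_builtin_registry,
)


@pytest.fixture(scope="session")
def registry():
    return load_builtin_registry()


@pytest.fixture(scope="session")
def matrix(registry):
    return group_count_matrix(registry)


@pytest.fixture(scope="session")
def strict_templates():
    return build_templates(ScanConfig())


def oracle_scan(seq: str, templates) -> set[tuple[ClusterType, tuple[int, ...]]]:
    """All (cluster_type, cysteine positions) matches, by exhaustive subset
    enumeration with direct gap/proline checks."""
    out: set[tuple[ClusterType, tuple[int, ...]]] = set()
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    for tpl in templates:
        for combo in itertools.combinations(cys, tpl.n_cys):
            if _combo_matches(seq, combo, tpl):
                out.add((tpl.cluster_type, combo))
    return out


def _combo_matches(seq, combo, tpl) -> bool:
    for j in range(len(combo) - 1):
        pro = 0
        if (j + 1) in tpl.proline_slots:
            if not (combo[j] + 1 < len(seq) and seq[combo[j] + 1] == "P"):
                return False
            pro = 1
        gap = combo[j + 1] - combo[j] - 1 - pro
        lo, hi = tpl.gap_ranges[j]
        if not lo <= gap <= hi:
            return False
    if tpl.n_cys in tpl.proline_slots:
        p = combo[-1]
        if not (p + 1 < len(seq) and seq[p + 1] == "P"):
            return False
    return True


def random_protein(rng: random.Random, max_len: int = 300, max_cys: int = 12) -> str:
    """A random amino-acid sequence with a bounded cysteine count and an
    enriched proline supply (so proline-slot logic actually gets exercised)."""
    n = rng.randint(20, max_len)
    base = "ADEFGHIKLMNQRSTVWY"
    chars = [rng.choice(base + "PPP") for _ in range(n)]
    k = rng.randint(0, min(max_cys, n))
    for i in rng.sample(range(n), k):
        chars[i] = "C"
    return "".join(chars)
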