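"""Shared fixtures: random-but-seeded trees, records and hit tables.

Everything is generated in memory; nothing is downloaded or stored.
"""

from __future__ import annotations

import random
import string

import pytest

from orthofam.io import ProteinRecord, SimilarityHit


def random_tree_newick(
    rng: random.Random,
    leaves: list[str],
    with_supports: bool = True,
    with_lengths: bool = True,
) -> str:
    """A random binary topology over the given leaf labels."""

    def fmt(sub: str, support: int | None) -> str:
        label = "" if support is None else str(support)
        length = f":{rng.uniform(0.05, 1.0):.3f}" if with_lengths else ""
        return f"{sub}{label}{length}"

    parts = [fmt(leaf, None) for leaf in leaves]
    while len(parts) > 1:
        i = rng.randrange(len(parts))
        a = parts.pop(i)
        j = rng.randrange(len(parts))
        b = parts.pop(j)
        support = rng.randint(0, 100) if with_supports else None
        parts.append(fmt(f"({a},{b})", support))
    return parts[0] + ";"


def random_records(rng: random.Random, n: int) -> list[ProteinRecord]:
    records = []
    for i in range(n):
        seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(5, 120)))
        records.append(
            ProteinRecord(
                accession=f"P{i}",
                organism=rng.choice(["Hsa", "Dme", "Sce"]),
                gene_id=f"G{rng.randint(0, max(1, n // 3))}",
                sequence=seq,
            )
        )
    return records


def random_hits(rng: random.Random, queries: list[str], subjects: list[str],
                density: float = 0.7) -> list[SimilarityHit]:
    hits = []
    for q in queries:
        for s in subjects:
            if rng.random() < density:
                e = 10.0 ** rng.uniform(-80, -2)
                hits.append(SimilarityHit(q, s, e, -rng.uniform(1, 3) * 10))
    return hits


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240117)
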