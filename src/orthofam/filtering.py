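"""Sequence-collection filters that turn raw search output into a curated
family set.

The stages mirror standard gene-family curation practice: keep one (the
longest) isoform per gene; require the family's diagnostic domain below an
E-value threshold (default 1e-4, the usual HMM-search cutoff for the
Cyclin_N domain); remove known non-family domain carriers (e.g. CABLES/CNTD
homologs among Cyclin_N proteins) by reciprocal best hit against a
reference proteome; and screen candidates on a guide tree so that proteins
grouping with non-family kinases (e.g. MAP kinases among CDK candidates)
are dropped. A gap-fraction column trimmer stands in for the manual removal
of poorly aligned positions before tree inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import MultipleAlignment, ProteinRecord, SimilarityHit, DomainHit, best_hits_per_pair
from .trees import GeneTree, first_reference_ancestor

__all__ = [
    "FilterParams",
    "ScreenResult",
    "select_longest_isoform",
    "filter_by_domain",
    "reciprocal_best_hits",
    "exclude_by_rbh",
    "screen_by_family_cluster",
    "trim_alignment",
]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the domain filter and alignment trimming."""

    required_domain: str = "Cyclin_N"
    domain_max_evalue: float = 1e-4
    max_gap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.domain_max_evalue <= 0:
            raise ValueError("domain_max_evalue must be positive")
        if not (0.0 <= self.max_gap_fraction <= 1.0):
            raise ValueError("max_gap_fraction must lie in [0, 1]")


def select_longest_isoform(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep exactly one record per gene_id: the longest sequence.

    Length ties break to the lexicographically smallest accession; output
    is sorted by (organism, gene_id) for determinism.
    """
    best: dict[str, ProteinRecord] = {}
    for rec in records:
        cur = best.get(rec.gene_id)
        if (
            cur is None
            or rec.length > cur.length
            or (rec.length == cur.length and rec.accession < cur.accession)
        ):
            best[rec.gene_id] = rec
    return sorted(best.values(), key=lambda r: (r.organism, r.gene_id))


def filter_by_domain(
    records: Sequence[ProteinRecord],
    domain_hits: Iterable[DomainHit],
    params: FilterParams,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records by presence of the required domain.

    A record is kept iff it has at least one annotation of
    ``params.required_domain`` with E-value <= ``params.domain_max_evalue``
    (closed boundary, for floating-point robustness).
    """
    qualifying: set[str] = {
        h.protein
        for h in domain_hits
        if h.domain == params.required_domain and h.evalue <= params.domain_max_evalue
    }
    kept = [r for r in records if r.accession in qualifying]
    discarded = [r for r in records if r.accession not in qualifying]
    return kept, discarded


def reciprocal_best_hits(
    forward_hits: Iterable[SimilarityHit],
    reverse_hits: Iterable[SimilarityHit],
) -> set[tuple[str, str]]:
    """All (query, subject) pairs that are mutual minimum-E-value best hits.

    Best-partner ties break to the lexicographically smallest accession so
    the relation is deterministic.
    """

    def best_partner(pair_scores: Mapping[tuple[str, str], float]) -> dict[str, str]:
        best: dict[str, tuple[float, str]] = {}
        for (q, s), e in pair_scores.items():
            if q not in best or (e, s) < best[q]:
                best[q] = (e, s)
        return {q: s for q, (_, s) in best.items()}

    fwd = best_partner(best_hits_per_pair(forward_hits))
    rev = best_partner(best_hits_per_pair(reverse_hits))
    return {
        (q, s) for q, s in fwd.items() if rev.get(s) == q
    }


def exclude_by_rbh(
    records: Sequence[ProteinRecord],
    forward_hits: Iterable[SimilarityHit] | None,
    reverse_hits: Iterable[SimilarityHit] | None,
    exclusion_refs: Iterable[str],
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Remove records forming a reciprocal best hit with any exclusion
    reference (known non-family proteins sharing the diagnostic domain)."""
    refs = set(exclusion_refs)
    if not refs:
        return list(records), []
    if forward_hits is None or reverse_hits is None:
        raise ValueError("both forward and reverse hit tables are required for RBH")
    rbh = reciprocal_best_hits(forward_hits, reverse_hits)
    excluded_accessions = {q for q, s in rbh if s in refs}
    kept = [r for r in records if r.accession not in excluded_accessions]
    excluded = [r for r in records if r.accession in excluded_accessions]
    return kept, excluded


@dataclass
class ScreenResult:
    """Outcome of the guide-tree screen; ambiguous queries are kept but
    flagged (their nearest reference clade mixes family and non-family)."""

    kept: list[str] = field(default_factory=list)
    discarded: list[str] = field(default_factory=list)
    ambiguous: list[str] = field(default_factory=list)


def screen_by_family_cluster(
    guide_tree: GeneTree,
    queries: Sequence[str],
    family_refs: Iterable[str],
    nonfamily_refs: Iterable[str],
) -> ScreenResult:
    """Keep queries whose first reference-containing ancestor on the guide
    tree holds only family references; discard those grouping exclusively
    with non-family references; keep-and-flag mixed cases."""
    ref_map = {r: "family" for r in family_refs}
    ref_map.update({r: "nonfamily" for r in nonfamily_refs})
    result = ScreenResult()
    for q in queries:
        if q not in guide_tree:
            raise ValueError(f"query {q!r} absent from guide tree")
        clade = first_reference_ancestor(guide_tree, q, ref_map)
        groups = clade.subfamilies_present
        if groups == {"nonfamily"}:
            result.discarded.append(q)
        else:
            result.kept.append(q)
            if "nonfamily" in groups:
                result.ambiguous.append(q)
    return result


def trim_alignment(
    alignment: MultipleAlignment, params: FilterParams
) -> tuple[MultipleAlignment, list[int]]:
    """Drop alignment columns whose gap fraction exceeds the threshold.

    Returns the trimmed alignment and the column map (old indices, 0-based,
    of the retained columns in order). At threshold 1.0 this is the
    identity.
    """
    if not alignment.rows:
        return MultipleAlignment(rows=[]), []
    nrow = len(alignment.rows)
    keep: list[int] = []
    for j in range(alignment.ncol):
        gaps = sum(1 for _, seq in alignment.rows if seq[j] in "-.")
        if gaps / nrow <= params.max_gap_fraction:
            keep.append(j)
    if alignment.ncol > 0 and not keep:
        raise ValueError(
            "trimming removed every column; raise max_gap_fraction "
            f"(currently {params.max_gap_fraction})"
        )
    rows = [(acc, "".join(seq[j] for j in keep)) for acc, seq in alignment.rows]
    return MultipleAlignment(rows=rows), keep
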