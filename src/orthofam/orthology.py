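"""Subfamily assignment of query proteins from gene trees and similarity
searches.

The decision procedure, applied per query:

1. **Tree rule.** Find the query's first reference-containing ancestor in
   each gene tree holding it. If that clade's references belong to a single
   subfamily and the clade's bootstrap support exceeds ``min_support``
   (default 50, strict), the query is that subfamily's ortholog.
2. **Five-orders fallback.** Otherwise compare the query's best E-value per
   subfamily (minimum over each subfamily's reference members): assign the
   best-scoring subfamily iff its E-value is at least five orders of
   magnitude smaller than the next-best subfamily's (E1 <= 1e-5 * E2).
3. **Unclassified.** Queries passing neither test keep the family label
   but no subfamily.

Within a subfamily that is itself divided into clades (e.g. CDK9 into CDK9
and CDK12/13), the tree rule is re-applied with clade-level references; a
query attaching below the clades' common stem keeps a subfamily-level-only
assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .io import SimilarityHit, best_hits_per_pair
from .trees import GeneTree, first_reference_ancestor

__all__ = [
    "ReferenceSet",
    "ClassifyParams",
    "Assignment",
    "UNCLASSIFIED",
    "assign_by_tree",
    "subfamily_evalue_profile",
    "assign_by_five_orders",
    "assign_clade",
    "classify",
    "write_assignments_tsv",
    "write_assignments_json",
]

UNCLASSIFIED = "unclassified"

EVIDENCE_TREE = "tree"
EVIDENCE_FIVE_ORDERS = "five_orders"
EVIDENCE_UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ReferenceSet:
    """The classification taxonomy: subfamily -> clade -> reference
    accessions, plus the outgroup anchors used to root family trees.

    ``groups`` optionally tags each subfamily with a higher-level group
    (e.g. cyclin B-like / Y-like / C-like) for profiling output.
    """

    family: str
    subfamilies: tuple[tuple[str, tuple[tuple[str, tuple[str, ...]], ...]], ...]
    outgroups: tuple[str, ...] = ()
    groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen_refs: set[str] = set()
        seen_labels: set[str] = set()
        for sub_label, clades in self.subfamilies:
            if sub_label in seen_labels:
                raise ValueError(f"duplicate subfamily label {sub_label!r}")
            seen_labels.add(sub_label)
            for clade_label, refs in clades:
                for acc in refs:
                    if acc in seen_refs:
                        raise ValueError(
                            f"reference {acc!r} appears in more than one clade"
                        )
                    seen_refs.add(acc)

    # -- lookups ---------------------------------------------------------
    def subfamily_labels(self) -> list[str]:
        return [label for label, _ in self.subfamilies]

    def reference_map(self) -> dict[str, str]:
        """accession -> subfamily label, over all references."""
        out: dict[str, str] = {}
        for sub_label, clades in self.subfamilies:
            for _, refs in clades:
                for acc in refs:
                    out[acc] = sub_label
        return out

    def clade_map(self, subfamily: str) -> dict[str, str]:
        """accession -> clade label, for one subfamily's references."""
        for sub_label, clades in self.subfamilies:
            if sub_label == subfamily:
                return {acc: cl for cl, refs in clades for acc in refs}
        raise KeyError(f"unknown subfamily {subfamily!r}")

    def clades_of(self, subfamily: str) -> list[str]:
        for sub_label, clades in self.subfamilies:
            if sub_label == subfamily:
                return [cl for cl, _ in clades]
        raise KeyError(f"unknown subfamily {subfamily!r}")

    def all_references(self) -> set[str]:
        return set(self.reference_map())

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_dict(cls, data: Mapping) -> "ReferenceSet":
        subfamilies = tuple(
            (
                sub["label"],
                tuple(
                    (cl["label"], tuple(cl["references"]))
                    for cl in sub["clades"]
                ),
            )
            for sub in data["subfamilies"]
        )
        groups = {
            sub["label"]: sub["group"] for sub in data["subfamilies"] if "group" in sub
        }
        return cls(
            family=data["family"],
            subfamilies=subfamilies,
            outgroups=tuple(data.get("outgroups", ())),
            groups=groups,
        )

    def to_dict(self) -> dict:
        subs = []
        for label, clades in self.subfamilies:
            sub: dict = {
                "label": label,
                "clades": [
                    {"label": cl, "references": list(refs)} for cl, refs in clades
                ],
            }
            if label in self.groups:
                sub["group"] = self.groups[label]
            subs.append(sub)
        return {
            "family": self.family,
            "outgroups": list(self.outgroups),
            "subfamilies": subs,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds of the assignment procedure.

    min_support: bootstrap percentage a clade must *exceed* for the tree
        rule (the comparison is strict).
    margin: E-value ratio of the five-orders criterion (best <= margin *
        next-best, inclusive).
    evalue_floor: zero/underflowed E-values are floored here before ratios.
    solo_hit_ceiling: absolute E-value a profile hitting a single subfamily
        must reach to qualify (the margin is undefined with one subfamily).
    """

    min_support: float = 50.0
    margin: float = 1e-5
    evalue_floor: float = 1e-180
    solo_hit_ceiling: float = 1e-10

    def __post_init__(self) -> None:
        if not (0.0 < self.margin < 1.0):
            raise ValueError("margin must lie in (0, 1)")
        if self.evalue_floor <= 0:
            raise ValueError("evalue_floor must be positive")
        if not (0.0 <= self.min_support <= 100.0):
            raise ValueError("min_support must lie in [0, 100]")


@dataclass(frozen=True)
class Assignment:
    """Classification outcome for one query."""

    query: str
    organism: str
    subfamily: str
    clade: str | None = None
    evidence: str = EVIDENCE_UNCLASSIFIED
    statistic: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if (self.evidence == EVIDENCE_UNCLASSIFIED) != (self.subfamily == UNCLASSIFIED):
            raise ValueError("evidence 'unclassified' iff subfamily 'unclassified'")
        if self.evidence != EVIDENCE_UNCLASSIFIED and self.statistic is None:
            raise ValueError("tree/five_orders assignments carry a statistic")

    def to_dict(self) -> dict:
        return {
            "query": self.query,
            "organism": self.organism,
            "subfamily": self.subfamily,
            "clade": self.clade,
            "evidence": self.evidence,
            "statistic": self.statistic,
            "notes": self.notes,
        }


def assign_by_tree(
    tree: GeneTree,
    query: str,
    refset: ReferenceSet,
    params: ClassifyParams,
    organism: str = "",
) -> Assignment | None:
    """Tree rule: single-subfamily first-reference ancestor with support
    strictly above the threshold, else None."""
    clade = first_reference_ancestor(tree, query, refset.reference_map())
    if len(clade.subfamilies_present) != 1:
        return None
    if clade.effective_support <= params.min_support:
        return None
    (subfamily,) = clade.subfamilies_present
    return Assignment(
        query=query,
        organism=organism,
        subfamily=subfamily,
        evidence=EVIDENCE_TREE,
        statistic=clade.effective_support,
    )


def subfamily_evalue_profile(
    query: str,
    hits: Iterable[SimilarityHit],
    refset: ReferenceSet,
    params: ClassifyParams = ClassifyParams(),
) -> dict[str, float]:
    """Minimum E-value from a query to each subfamily's references.

    Zero/underflow E-values are floored at ``params.evalue_floor``;
    subfamilies with no hit are omitted.
    """
    ref_map = refset.reference_map()
    pair_best = best_hits_per_pair(hits)
    profile: dict[str, float] = {}
    for (q, s), e in pair_best.items():
        if q != query or s not in ref_map:
            continue
        e = max(e, params.evalue_floor)
        sub = ref_map[s]
        if sub not in profile or e < profile[sub]:
            profile[sub] = e
    return profile


def assign_by_five_orders(
    query: str,
    profile: Mapping[str, float],
    params: ClassifyParams,
    organism: str = "",
) -> Assignment | None:
    """E-value margin rule on a subfamily profile.

    With two or more subfamilies: assign the best iff best <= margin *
    next-best. With exactly one: assign iff it clears the absolute
    ``solo_hit_ceiling``. Empty profile: None.
    """
    if not profile:
        return None
    ranked = sorted(profile.items(), key=lambda kv: (kv[1], kv[0]))
    best_sub, best_e = ranked[0]
    if len(ranked) == 1:
        if best_e <= params.solo_hit_ceiling:
            return Assignment(
                query=query,
                organism=organism,
                subfamily=best_sub,
                evidence=EVIDENCE_FIVE_ORDERS,
                statistic=0.0,
                notes="single-subfamily profile under absolute ceiling",
            )
        return None
    next_e = ranked[1][1]
    if best_e <= params.margin * next_e:
        return Assignment(
            query=query,
            organism=organism,
            subfamily=best_sub,
            evidence=EVIDENCE_FIVE_ORDERS,
            statistic=best_e / next_e,
        )
    return None


def assign_clade(
    tree: GeneTree,
    query: str,
    subfamily: str,
    refset: ReferenceSet,
    params: ClassifyParams,
) -> str | None:
    """Within-subfamily clade call, re-applying the tree rule with that
    subfamily's clade-level references only.

    None means the query attaches below the clades' common stem (or with
    insufficient support) and keeps a subfamily-level-only assignment.
    """
    clades = refset.clades_of(subfamily)
    if len(clades) == 1:
        return clades[0]
    clade_map = refset.clade_map(subfamily)
    result = first_reference_ancestor(tree, query, clade_map)
    if len(result.subfamilies_present) != 1:
        return None
    if result.effective_support <= params.min_support:
        return None
    (label,) = result.subfamilies_present
    return label


def _organism_of(accession: str, organisms: Mapping[str, str] | None) -> str:
    if organisms and accession in organisms:
        return organisms[accession]
    # leaf names of the form org|subfamily|serial or org-accession
    for sep in ("|", "-"):
        if sep in accession:
            return accession.split(sep, 1)[0]
    return ""


def classify(
    trees: Sequence[GeneTree],
    hits: Iterable[SimilarityHit],
    refset: ReferenceSet,
    params: ClassifyParams = ClassifyParams(),
    queries: Sequence[str] | None = None,
    organisms: Mapping[str, str] | None = None,
) -> list[Assignment]:
    """Run the full decision chain, one Assignment per query.

    Evidence precedence is tree > five-orders > unclassified, never
    skipping forward. A query recovered in several trees takes the
    passing tree call with the highest support; if passing calls disagree
    on the subfamily the conflict is flagged and the query falls back to
    the five-orders rule.
    """
    hits = list(hits)
    refs = refset.all_references() | set(refset.outgroups)
    if queries is None:
        found: set[str] = set()
        for t in trees:
            found |= t.leaf_set()
        found |= {h.query for h in hits}
        queries = sorted(found - refs)

    assignments: list[Assignment] = []
    hit_queries = {h.query for h in hits}
    for q in queries:
        holding = [t for t in trees if q in t]
        if not holding and q not in hit_queries:
            raise ValueError(f"query {q!r} appears in no tree and no hit table")
        org = _organism_of(q, organisms)

        candidates: list[tuple[Assignment, GeneTree]] = []
        for t in holding:
            a = assign_by_tree(t, q, refset, params, organism=org)
            if a is not None:
                candidates.append((a, t))
        note = ""
        chosen: tuple[Assignment, GeneTree] | None = None
        if candidates:
            subfams = {a.subfamily for a, _ in candidates}
            if len(subfams) == 1:
                chosen = max(candidates, key=lambda at: at[0].statistic)
            else:
                note = (
                    "conflicting tree assignments ("
                    + ", ".join(sorted(subfams))
                    + "); fell back to E-value margin"
                )
        if chosen is not None:
            a, t = chosen
            clade = assign_clade(t, q, a.subfamily, refset, params)
            assignments.append(
                Assignment(
                    query=a.query,
                    organism=a.organism,
                    subfamily=a.subfamily,
                    clade=clade,
                    evidence=a.evidence,
                    statistic=a.statistic,
                )
            )
            continue

        profile = subfamily_evalue_profile(q, hits, refset, params)
        a = assign_by_five_orders(q, profile, params, organism=org)
        if a is not None:
            clade = None
            clades = refset.clades_of(a.subfamily)
            if len(clades) == 1:
                clade = clades[0]
            assignments.append(
                Assignment(
                    query=a.query,
                    organism=a.organism,
                    subfamily=a.subfamily,
                    clade=clade,
                    evidence=a.evidence,
                    statistic=a.statistic,
                    notes=(a.notes + ("; " if a.notes and note else "") + note).strip(),
                )
            )
            continue

        assignments.append(
            Assignment(
                query=q,
                organism=org,
                subfamily=UNCLASSIFIED,
                evidence=EVIDENCE_UNCLASSIFIED,
                notes=note,
            )
        )
    return assignments


_TSV_HEADER = "query\torganism\tsubfamily\tclade\tevidence\tstatistic\tnotes"


def write_assignments_tsv(assignments: Iterable[Assignment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_TSV_HEADER + "\n")
        for a in assignments:
            stat = "" if a.statistic is None else f"{a.statistic:.6g}"
            fh.write(
                f"{a.query}\t{a.organism}\t{a.subfamily}\t{a.clade or '-'}\t"
                f"{a.evidence}\t{stat}\t{a.notes}\n"
            )


def write_assignments_json(
    assignments: Iterable[Assignment],
    path: str | Path,
    provenance: Mapping | None = None,
) -> None:
    payload = {
        "provenance": dict(provenance or {}),
        "assignments": [a.to_dict() for a in assignments],
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_assignments_tsv(path: str | Path) -> list[Assignment]:
    out: list[Assignment] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        while header.startswith("#"):
            header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected assignments header in {path}")
        for line in fh:
            if line.startswith("#"):
                continue
            q, org, sub, clade, ev, stat, notes = line.rstrip("\n").split("\t")
            out.append(
                Assignment(
                    query=q,
                    organism=org,
                    subfamily=sub,
                    clade=None if clade == "-" else clade,
                    evidence=ev,
                    statistic=float(stat) if stat else None,
                    notes=notes,
                )
            )
    return out
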