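"""Presence/absence profiling: per-organism counts and the organism x
subfamily matrix summarizing which lineages retain which subfamilies.

Presence is binary — a subfamily is present in an organism iff at least one
query from that organism was assigned to it. Unclassified queries are kept
in a side table, never in the matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io import ProteinRecord
from .orthology import Assignment, ReferenceSet, UNCLASSIFIED

__all__ = [
    "ProfileMatrix",
    "count_by_organism",
    "build_profile",
    "write_profile",
    "read_profile_json",
    "format_counts_report",
]


@dataclass
class ProfileMatrix:
    """Organism x subfamily membership matrix with accession lists."""

    organisms: list[str]
    subfamilies: list[str]
    cells: dict[tuple[str, str], list[str]]
    groups: dict[str, str] = field(default_factory=dict)
    unclassified: dict[str, list[str]] = field(default_factory=dict)

    def members(self, organism: str, subfamily: str) -> list[str]:
        return self.cells.get((organism, subfamily), [])

    def present(self, organism: str, subfamily: str) -> bool:
        return bool(self.members(organism, subfamily))

    def presence_pattern(self) -> dict[tuple[str, str], bool]:
        return {
            (o, s): self.present(o, s)
            for o in self.organisms
            for s in self.subfamilies
        }

    def n_members(self) -> int:
        return sum(len(v) for v in self.cells.values())


def count_by_organism(
    records: Sequence[ProteinRecord], family_tag: str = ""
) -> dict[str, int]:
    """Record counts per organism with a ``total`` row (the family census
    table). Order of first appearance is preserved by dict insertion."""
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.organism] = counts.get(rec.organism, 0) + 1
    counts["total"] = sum(counts.values())
    return counts


def build_profile(
    assignments: Iterable[Assignment],
    organism_order: Sequence[str] | None,
    refset: ReferenceSet,
) -> ProfileMatrix:
    """Populate the matrix from non-unclassified assignments.

    Organisms not in ``organism_order`` are appended in sorted order;
    passing None derives the order from the assignments. Member lists are
    sorted, so the result is invariant to assignment order.
    """
    subfamilies = refset.subfamily_labels()
    known = set(subfamilies)
    cells: dict[tuple[str, str], list[str]] = {}
    unclassified: dict[str, list[str]] = {}
    seen_orgs: list[str] = []
    for a in assignments:
        if a.organism not in seen_orgs:
            seen_orgs.append(a.organism)
        if a.subfamily == UNCLASSIFIED:
            unclassified.setdefault(a.organism, []).append(a.query)
            continue
        if a.subfamily not in known:
            raise ValueError(
                f"assignment {a.query!r} names subfamily {a.subfamily!r} "
                f"absent from the {refset.family} reference set"
            )
        cells.setdefault((a.organism, a.subfamily), []).append(a.query)
    for v in cells.values():
        v.sort()
    for v in unclassified.values():
        v.sort()
    if organism_order is None:
        organisms = sorted(seen_orgs)
    else:
        organisms = list(organism_order)
        organisms += sorted(set(seen_orgs) - set(organisms))
    return ProfileMatrix(
        organisms=organisms,
        subfamilies=subfamilies,
        cells=cells,
        groups=dict(refset.groups),
        unclassified=unclassified,
    )


def write_profile(matrix: ProfileMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write the matrix; TSV cells are semicolon-joined accessions, with
    ``-`` (never an empty string) marking absence."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("organism\t" + "\t".join(matrix.subfamilies) + "\n")
            for org in matrix.organisms:
                row = [
                    ";".join(matrix.members(org, s)) or "-"
                    for s in matrix.subfamilies
                ]
                fh.write(org + "\t" + "\t".join(row) + "\n")
    elif format == "json":
        payload = {
            "organisms": matrix.organisms,
            "subfamilies": matrix.subfamilies,
            "groups": matrix.groups,
            "cells": {
                f"{o}\t{s}": members
                for (o, s), members in sorted(matrix.cells.items())
            },
            "unclassified": matrix.unclassified,
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown profile format {format!r}")


def read_profile_json(path: str | Path) -> ProfileMatrix:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    cells: dict[tuple[str, str], list[str]] = {}
    for key, members in payload["cells"].items():
        org, sub = key.split("\t")
        cells[(org, sub)] = list(members)
    return ProfileMatrix(
        organisms=list(payload["organisms"]),
        subfamilies=list(payload["subfamilies"]),
        cells=cells,
        groups=dict(payload.get("groups", {})),
        unclassified={k: list(v) for k, v in payload.get("unclassified", {}).items()},
    )


def format_counts_report(matrix: ProfileMatrix, family: str) -> str:
    """Human-readable per-organism / per-subfamily member counts."""
    lines = [f"{family} family profile", ""]
    lines.append("Per organism:")
    for org in matrix.organisms:
        n = sum(len(matrix.members(org, s)) for s in matrix.subfamilies)
        extra = len(matrix.unclassified.get(org, []))
        tail = f" (+{extra} unclassified)" if extra else ""
        lines.append(f"  {org}\t{n}{tail}")
    lines.append("")
    lines.append("Per subfamily (organisms present / total):")
    for s in matrix.subfamilies:
        n_orgs = sum(matrix.present(o, s) for o in matrix.organisms)
        n_mem = sum(len(matrix.members(o, s)) for o in matrix.organisms)
        group = matrix.groups.get(s)
        tag = f" [{group}]" if group else ""
        lines.append(f"  {s}{tag}\t{n_orgs}/{len(matrix.organisms)}\t{n_mem} members")
    total = matrix.n_members() + sum(len(v) for v in matrix.unclassified.values())
    lines.append("")
    lines.append(f"Total queries: {total}")
    return "\n".join(lines) + "\n"
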