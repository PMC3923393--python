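"""Synthetic gene families with known truth, for end-to-end benchmarking.

Each of K founder subfamilies evolves independently down a species tree
under a linear birth-death process: a duplication (rate ``dup_rate`` per
unit branch length) bifurcates a gene lineage inside a species branch, a
loss (rate ``loss_rate``) terminates it, and every speciation copies the
lineage into both descendant branches. Founder subtrees hang off a common
root via long stem branches, so subfamilies are well separated — the
statistical structure the classification procedure assumes.

Two emulators decorate the true gene tree with the observables the real
pipeline consumes instead of running bootstrap analyses or BLAST:

* supports: an edge of length l gets ``100 * (1 - exp(-kappa * l))`` plus
  Gaussian noise, clamped to [0, 100] — longer branches are easier to
  resolve, hence better supported;
* E-values: a (query, reference) pair at patristic distance d gets
  ``log10 E = -beta * exp(-d / tau)`` plus Gaussian noise (log10 units),
  floored at -180, with weak pairs (log10 E > -2) dropped, emulating a
  search reporting threshold.

Everything is driven by one seed; stages draw from independent spawned
streams, so a stage can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .io import ProteinRecord, SimilarityHit, write_fasta, write_hit_table
from .orthology import Assignment, ClassifyParams, ReferenceSet, classify
from .profiling import ProfileMatrix, build_profile
from .trees import GeneTree, read_newick, write_newick

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "Benchmark",
    "default_species_tree",
    "DEFAULT_FOUNDERS",
    "simulate_gene_tree",
    "emulate_supports",
    "emulate_evalues",
    "emulate_sequences",
    "make_benchmark",
    "expected_family_size",
    "score_assignments",
    "recovered_profile",
]

#: Eight founder subfamilies, the size of the CDK classification scheme.
DEFAULT_FOUNDERS = (
    "CDK1", "CDK4/6", "CDK5", "CDK7", "CDK8/19", "CDK9", "CDK10/11", "CDK20",
)


def default_species_tree() -> str:
    """The shipped 18-organism species tree (Newick, branch lengths in
    substitutions/site-like units; minimum internal branch 0.1)."""
    return (
        resources.files("orthofam.data").joinpath("species_tree_18.nwk")
        .read_text(encoding="utf-8").strip()
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate an 18-organism, 8-subfamily
    family with moderate turnover and realistic observation noise."""

    species_tree: str = ""
    founders: tuple[str, ...] = DEFAULT_FOUNDERS
    dup_rate: float = 0.2
    loss_rate: float = 0.1
    support_sharpness: float = 25.0
    support_noise_sd: float = 5.0
    evalue_slope: float = 50.0
    evalue_scale: float = 2.0
    evalue_noise_sd: float = 0.5
    seed: int = 0
    founder_stem: float = 2.0
    reference_organism: str | None = None

    def __post_init__(self) -> None:
        if len(self.founders) < 1:
            raise ValueError("need at least one founder subfamily")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.support_sharpness <= 0 or self.evalue_slope <= 0 or self.evalue_scale <= 0:
            raise ValueError("sharpness/slope/scale must be positive")
        if self.support_noise_sd < 0 or self.evalue_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not self.species_tree:
            object.__setattr__(self, "species_tree", default_species_tree())

    def stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass
class TruthTable:
    """Ground truth for one simulated family."""

    members: dict[str, tuple[str, str]]  # accession -> (organism, subfamily)
    references: dict[str, str]  # accession -> subfamily
    matrix: ProfileMatrix

    def queries(self) -> list[str]:
        return sorted(set(self.members) - set(self.references))


class _GN:
    """Minimal gene-tree node used during simulation."""

    __slots__ = ("children", "length", "name", "open")

    def __init__(self, length: float = 0.0, children: list | None = None,
                 name: str | None = None):
        self.children = children or []
        self.length = length
        self.name = name
        self.open = False


def _bd_segment(rng: np.random.Generator, t: float, lam: float, mu: float) -> _GN | None:
    """One gene lineage evolving for time t within a species branch.

    Returns a fragment whose leaves marked ``open`` sit at the branch end,
    or None if every descendant lineage was lost. Pass-through nodes
    (duplications with one surviving side) are spliced out.
    """
    total = lam + mu
    wait = rng.exponential(1.0 / total) if total > 0 else math.inf
    if wait >= t:
        node = _GN(length=t)
        node.open = True
        return node
    if rng.random() < (lam / total if total else 0.0):
        left = _bd_segment(rng, t - wait, lam, mu)
        right = _bd_segment(rng, t - wait, lam, mu)
        kids = [k for k in (left, right) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += wait
            return kids[0]
        return _GN(length=wait, children=kids)
    return None  # loss


def _lineage_through(
    sp_node: dendropy.Node, rng: np.random.Generator, lam: float, mu: float
) -> _GN | None:
    """One gene lineage entering a species branch; evolves along the branch
    then continues (copied at speciations) through the subtended clade."""
    branch = sp_node.edge.length or 0.0
    frag = _bd_segment(rng, branch, lam, mu)
    if frag is None:
        return None
    return _resolve_open_tips(frag, sp_node, rng, lam, mu)


def _resolve_open_tips(
    node: _GN, sp_node: dendropy.Node, rng: np.random.Generator,
    lam: float, mu: float,
) -> _GN | None:
    if node.open:
        node.open = False
        if sp_node.is_leaf():
            node.name = sp_node.taxon.label  # organism; renamed later
            return node
        conts = []
        for child in sp_node.child_nodes():
            c = _lineage_through(child, rng, lam, mu)
            if c is not None:
                conts.append(c)
        if not conts:
            return None
        if len(conts) == 1:
            conts[0].length += node.length
            return conts[0]
        return _GN(length=node.length, children=conts)
    kids = []
    for child in node.children:
        c = _resolve_open_tips(child, sp_node, rng, lam, mu)
        if c is not None:
            kids.append(c)
    if not kids:
        return None
    if len(kids) == 1:
        kids[0].length += node.length
        return kids[0]
    node.children = kids
    return node


def _gn_newick(node: _GN) -> str:
    if not node.children:
        return f"{node.name}:{node.length:.6g}"
    inner = ",".join(_gn_newick(c) for c in node.children)
    return f"({inner}):{node.length:.6g}"


def _species_tip_order(species_tree: str) -> list[str]:
    st = dendropy.Tree.get(data=species_tree, schema="newick",
                           suppress_internal_node_taxa=True,
                           preserve_underscores=True)
    return [lf.taxon.label for lf in st.leaf_node_iter()]


def simulate_gene_tree(config: SimulationConfig) -> tuple[GeneTree, TruthTable]:
    """Simulate the family gene tree and its truth table.

    Leaves are named ``{organism}|{subfamily}|{serial}``. For each
    subfamily one surviving member of the designated reference organism
    (falling back down the tip order if the subfamily died out there) is
    designated as that subfamily's reference anchor. A founder whose
    lineage went extinct everywhere is recorded as absent, not an error.
    """
    rng = config.stage_rng(0)
    st = dendropy.Tree.get(data=config.species_tree, schema="newick",
                           suppress_internal_node_taxa=True,
                           preserve_underscores=True)
    tip_order = [lf.taxon.label for lf in st.leaf_node_iter()]
    ref_org = config.reference_organism or tip_order[0]
    if ref_org not in tip_order:
        raise ValueError(f"reference organism {ref_org!r} not a species-tree tip")

    founder_roots: list[tuple[str, _GN]] = []
    for founder in config.founders:
        root = _lineage_through(st.seed_node, rng, config.dup_rate, config.loss_rate)
        if root is not None:
            root.length += config.founder_stem
            founder_roots.append((founder, root))

    members: dict[str, tuple[str, str]] = {}
    for founder, root in founder_roots:
        serial: dict[str, int] = {}
        stack = [root]
        # name leaves in deterministic traversal order
        def _walk(n: _GN) -> None:
            if not n.children:
                org = n.name
                serial[org] = serial.get(org, 0) + 1
                n.name = f"{org}|{founder}|{serial[org]}"
                members[n.name] = (org, founder)
                return
            for c in n.children:
                _walk(c)
        _walk(root)

    if founder_roots:
        top = _GN(children=[r for _, r in founder_roots])
        text = "(" + ",".join(_gn_newick(c) for c in top.children) + ");"
    else:
        raise ValueError("every founder lineage went extinct; nothing to simulate")
    tree = read_newick(text)

    references: dict[str, str] = {}
    for founder, _ in founder_roots:
        for org in [ref_org] + [o for o in tip_order if o != ref_org]:
            acc = f"{org}|{founder}|1"
            if acc in members:
                references[acc] = founder
                break

    cells: dict[tuple[str, str], list[str]] = {}
    for acc, (org, sub) in members.items():
        cells.setdefault((org, sub), []).append(acc)
    for v in cells.values():
        v.sort()
    matrix = ProfileMatrix(
        organisms=tip_order,
        subfamilies=list(config.founders),
        cells=cells,
    )
    return tree, TruthTable(members=members, references=references, matrix=matrix)


def truth_reference_set(truth: TruthTable, family: str = "SYN") -> ReferenceSet:
    """Reference-set config anchored on the simulation's designated
    reference leaves (one single-clade subfamily per founder)."""
    by_sub: dict[str, list[str]] = {}
    for acc, sub in truth.references.items():
        by_sub.setdefault(sub, []).append(acc)
    subfamilies = tuple(
        (sub, ((sub, tuple(sorted(accs))),))
        for sub, accs in sorted(by_sub.items(), key=lambda kv: truth.matrix.subfamilies.index(kv[0]))
    )
    return ReferenceSet(family=family, subfamilies=subfamilies)


def emulate_supports(tree: GeneTree, config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> GeneTree:
    """Attach supports increasing with subtending branch length.

    support = clamp[0,100]( round( 100 * (1 - exp(-kappa * l)) + eps ) ),
    eps ~ Normal(0, support_noise_sd). Missing lengths count as 0.
    """
    if rng is None:
        rng = config.stage_rng(1)
    out = tree.copy()
    for node in out.tree.preorder_node_iter():
        if node.is_leaf() or node is out.tree.seed_node:
            continue
        length = node.edge.length or 0.0
        base = 100.0 * (1.0 - math.exp(-config.support_sharpness * length))
        eps = rng.normal(0.0, config.support_noise_sd) if config.support_noise_sd else 0.0
        node.support = float(min(100.0, max(0.0, round(base + eps))))
    return out


def emulate_evalues(
    tree: GeneTree, truth: TruthTable, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SimilarityHit]:
    """Similarity hits decaying with patristic distance.

    log10 E = -slope * exp(-d / scale) + eps, floored at -180; pairs above
    the reporting threshold (log10 E > -2) are omitted.
    """
    if rng is None:
        rng = config.stage_rng(2)
    dists = tree.patristic_distances()
    refs = sorted(truth.references)
    hits: list[SimilarityHit] = []
    for q in truth.queries():
        for r in refs:
            d = dists[(q, r)]
            log10e = -config.evalue_slope * math.exp(-d / config.evalue_scale)
            if config.evalue_noise_sd:
                log10e += rng.normal(0.0, config.evalue_noise_sd)
            log10e = max(log10e, -180.0)
            if log10e > -2.0:
                continue
            hits.append(
                SimilarityHit(q, r, 10.0 ** log10e, max(0.0, -2.0 * log10e))
            )
    return hits


_AA = "ACDEFGHIKLMNPQRSTVWY"


def emulate_sequences(
    tree: GeneTree, truth: TruthTable, config: SimulationConfig,
    length: int = 200, rng: np.random.Generator | None = None,
) -> list[ProteinRecord]:
    """Toy sequences under a Poisson substitution model (one expected
    substitution per site per unit branch length); for smoke-testing
    sequence plumbing, not for realism."""
    if rng is None:
        rng = config.stage_rng(3)
    aa = np.array(list(_AA))

    def evolve(seq: np.ndarray, t: float) -> np.ndarray:
        seq = seq.copy()
        p = 1.0 - math.exp(-t)
        mask = rng.random(len(seq)) < p
        n = int(mask.sum())
        if n:
            seq[mask] = aa[rng.integers(0, len(aa), size=n)]
        return seq

    records: list[ProteinRecord] = []

    def walk(node, seq: np.ndarray) -> None:
        seq = evolve(seq, node.edge.length or 0.0)
        if node.is_leaf():
            acc = node.taxon.label
            org = truth.members.get(acc, ("unknown",))[0]
            records.append(ProteinRecord(acc, org, acc, "".join(seq)))
            return
        for child in node.child_nodes():
            walk(child, seq)

    root_seq = aa[rng.integers(0, len(aa), size=length)]
    for child in tree.tree.seed_node.child_nodes():
        walk(child, root_seq)
    records.sort(key=lambda r: r.accession)
    return records


@dataclass
class Benchmark:
    """An on-disk bundle plus its in-memory objects."""

    config: SimulationConfig
    tree: GeneTree
    truth: TruthTable
    refset: ReferenceSet
    hits: list[SimilarityHit]
    paths: dict[str, Path]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_benchmark(
    config: SimulationConfig, outdir: str | Path,
    include_sequences: bool = False,
) -> Benchmark:
    """Simulate and write a complete bundle: gene tree (with supports),
    hit table, reference config, truth TSV + profile, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, truth = simulate_gene_tree(config)
    tree = emulate_supports(tree, config)
    hits = emulate_evalues(tree, truth, config)
    refset = truth_reference_set(truth)

    paths = {
        "tree": outdir / "gene_tree.nwk",
        "hits": outdir / "hits.tsv",
        "reference": outdir / "reference.yaml",
        "truth": outdir / "truth.tsv",
        "truth_profile": outdir / "truth_profile.json",
    }
    paths["tree"].write_text(write_newick(tree) + "\n", encoding="utf-8")
    write_hit_table(hits, paths["hits"])
    refset.to_yaml(paths["reference"])
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("accession\torganism\tsubfamily\tis_reference\n")
        for acc in sorted(truth.members):
            org, sub = truth.members[acc]
            fh.write(f"{acc}\t{org}\t{sub}\t{int(acc in truth.references)}\n")
    from .profiling import write_profile  # local import avoids cycle at module load
    write_profile(truth.matrix, paths["truth_profile"], format="json")

    if include_sequences:
        paths["sequences"] = outdir / "sequences.fasta"
        write_fasta(emulate_sequences(tree, truth, config), paths["sequences"])

    manifest = {
        "config": asdict(config),
        "files": {
            name: {"path": p.name, "sha256": _sha256(p)} for name, p in paths.items()
        },
    }
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return Benchmark(config=config, tree=tree, truth=truth, refset=refset,
                     hits=hits, paths=paths)


def expected_family_size(species_tree: str, dup_rate: float, loss_rate: float) -> float:
    """Analytic mean number of surviving members per founder.

    By the branching property of the linear birth-death process the
    expected copy number at a tip of root-path length d is
    ``exp((dup_rate - loss_rate) * d)``; summing over tips gives the mean
    family size (``S * exp((lam - mu) * T)`` on an ultrametric depth-T,
    S-tip tree).
    """
    st = dendropy.Tree.get(data=species_tree, schema="newick",
                           suppress_internal_node_taxa=True,
                           preserve_underscores=True)
    total = 0.0
    for leaf in st.leaf_node_iter():
        depth = 0.0
        node = leaf
        while node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        total += math.exp((dup_rate - loss_rate) * depth)
    return total


def score_assignments(assignments: Sequence[Assignment], truth: TruthTable) -> float:
    """Fraction of queries whose assigned subfamily matches the truth."""
    queries = truth.queries()
    if not queries:
        return 1.0
    by_query = {a.query: a for a in assignments}
    correct = sum(
        1
        for q in queries
        if q in by_query and by_query[q].subfamily == truth.members[q][1]
    )
    return correct / len(queries)


def recovered_profile(
    assignments: Sequence[Assignment], truth: TruthTable, refset: ReferenceSet
) -> ProfileMatrix:
    """Profile matrix from assignments plus the reference anchors (which
    are inputs, not queries, but are true family members)."""
    ref_assignments = [
        Assignment(query=acc, organism=truth.members[acc][0], subfamily=sub,
                   evidence="tree", statistic=100.0, notes="reference anchor")
        for acc, sub in sorted(truth.references.items())
    ]
    return build_profile(
        list(assignments) + ref_assignments, truth.matrix.organisms, refset
    )


def run_benchmark(
    config: SimulationConfig, params: ClassifyParams = ClassifyParams()
) -> tuple[float, bool]:
    """Simulate in memory, classify, and score.

    Returns (label recovery fraction, presence-pattern equality with
    truth)."""
    tree, truth = simulate_gene_tree(config)
    tree = emulate_supports(tree, config)
    hits = emulate_evalues(tree, truth, config)
    refset = truth_reference_set(truth)
    assignments = classify([tree], hits, refset, params, queries=truth.queries())
    acc = score_assignments(assignments, truth)
    rec = recovered_profile(assignments, truth, refset)
    # A founder extinct everywhere has an all-absent truth row and no
    # column in the recovered matrix; treat a missing cell as absence.
    tm = truth.matrix.presence_pattern()
    rm = rec.presence_pattern()
    same = all(rm.get(k, False) == v for k, v in tm.items()) and all(
        tm.get(k, False) == v for k, v in rm.items()
    )
    return acc, same
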