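"""orthofam: gene-family subfamily classification and phylogenetic profiling.

Classifies query proteins into reference-anchored subfamilies from gene
trees (bootstrap-supported clustering) with a reciprocal-BLAST E-value
margin fallback, filters raw search output into curated family sets, turns
assignments into organism x subfamily presence/absence profiles, and ships
a duplication-loss simulator so the whole pipeline is testable against
known truth.
"""

from importlib import resources

from .io import (
    DomainHit,
    MultipleAlignment,
    ProteinRecord,
    SimilarityHit,
    read_domain_table,
    read_fasta,
    read_hit_table,
    write_fasta,
)
from .trees import (
    GeneTree,
    CladeResult,
    first_reference_ancestor,
    is_monophyletic,
    normalize_support,
    read_newick,
    root_at_outgroup,
    write_newick,
)
from .filtering import (
    FilterParams,
    exclude_by_rbh,
    filter_by_domain,
    screen_by_family_cluster,
    select_longest_isoform,
    trim_alignment,
)
from .orthology import (
    Assignment,
    ClassifyParams,
    ReferenceSet,
    UNCLASSIFIED,
    assign_by_five_orders,
    assign_by_tree,
    assign_clade,
    classify,
    subfamily_evalue_profile,
)
from .profiling import ProfileMatrix, build_profile, count_by_organism, write_profile
from .simulate import (
    DEFAULT_FOUNDERS,
    SimulationConfig,
    TruthTable,
    default_species_tree,
    emulate_evalues,
    emulate_supports,
    expected_family_size,
    make_benchmark,
    simulate_gene_tree,
)

__version__ = "0.1.0"

#: Census-table organism order for the 18-organism study set.
ORGANISM_ORDER_18 = (
    "Hsa", "Cin", "Spu", "Bfl", "Dme", "Nve", "Tad", "Aqe", "Mbr",
    "Sro", "Cow", "Sar", "Sce", "Spo", "Cci", "Spn", "Ttr", "Ddi",
)


def load_reference_set(family: str) -> ReferenceSet:
    """Load a shipped reference taxonomy: ``"cdk"`` or ``"cyclin"``."""
    name = {"cdk": "cdk_reference.yaml", "cyclin": "cyclin_reference.yaml"}.get(
        family.lower()
    )
    if name is None:
        raise ValueError(f"no shipped reference set for {family!r}")
    import yaml

    text = resources.files("orthofam.data").joinpath(name).read_text(encoding="utf-8")
    return ReferenceSet.from_dict(yaml.safe_load(text))
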