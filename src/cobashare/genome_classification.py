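"""Cobamide biosynthesis category and dependence calls for genomes.

De novo cobamide biosynthesis splits into subsections: tetrapyrrole
precursor synthesis, corrin ring synthesis (parallel aerobic cob and
anaerobic cbi orthologue series), nucleotide loop assembly, and lower
ligand synthesis.  A genome's subsection completeness is the fraction of
that subsection's genes it carries, with corrin-ring completeness taken as
the better of the two orthologue series.  Categories:

* producer — corrin-ring and nucleotide-loop completeness both meet the
  producer thresholds (de novo synthesis plausible);
* precursor salvager — not a producer, but carries enough of the late
  nucleotide-loop salvage genes (cobQ/cbiP, cobD/cbiB, cobP/cobU, cobS)
  to finish a cobamide from advanced intermediates;
* nonproducer — neither.

Cobamide dependence is a separate axis: a genome is dependent when it
encodes at least one of seven cobamide-dependent enzyme families.  bluB
(aerobic DMB synthesis) marks benzimidazolyl-cobamide capability but is
never required for producer status — documented producers lack it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

DEFAULT_SUBSECTIONS: dict[str, tuple[str, ...]] = {
    "tetrapyrrole_precursor": ("hemA", "hemL", "hemB", "hemC", "hemD", "cobA"),
    "corrin_ring_aerobic": (
        "cobG", "cobJ", "cobM", "cobF", "cobK", "cobL", "cobH", "cobB", "cobN",
    ),
    "corrin_ring_anaerobic": (
        "cbiK", "cbiL", "cbiH", "cbiF", "cbiD", "cbiJ", "cbiG",
        "cbiE", "cbiT", "cbiC", "cbiA",
    ),
    "nucleotide_loop": ("cobO", "cobQ", "cobD", "cobP", "cobS", "cobT", "cobC"),
    "lower_ligand": ("bluB",),
}

DEFAULT_SALVAGE_GENES = ("cobQ", "cobD", "cobP", "cobS")

#: seven cobamide-dependent enzyme families (gene-symbol stand-ins):
#: B12-dependent ribonucleotide reductase, methionine synthase,
#: methylmalonyl-CoA mutase family, ethanolamine ammonia lyase,
#: B12-dependent glycerol/diol dehydratase, D-ornithine 4,5-aminomutase,
#: epoxyqueuosine reductase.
DEFAULT_DEPENDENT_ENZYMES = (
    "nrdJ", "metH", "mcmA", "eutB", "pduC", "oraS", "queG",
)

#: anaerobic -> aerobic orthologue equivalences (either member satisfies
#: a requirement in the other series); nucleotide-loop synonyms included.
DEFAULT_ORTHOLOGUE_PAIRS: dict[str, str] = {
    "cbiL": "cobI",   # C-2 methyltransferase analogues (cobI not scored)
    "cbiH": "cobJ",
    "cbiF": "cobM",
    "cbiD": "cobF",
    "cbiJ": "cobK",
    "cbiE": "cobL",
    "cbiT": "cobL",
    "cbiC": "cobH",
    "cbiA": "cobB",
    "cbiK": "cobN",
    "cbiP": "cobQ",
    "cbiB": "cobD",
    "cobU": "cobP",
}


@dataclass(frozen=True)
class PathwayModel:
    """Gene vocabulary of the biosynthesis pathway, by subsection."""

    subsections: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SUBSECTIONS)
    )
    salvage_genes: tuple[str, ...] = DEFAULT_SALVAGE_GENES
    dependent_enzymes: tuple[str, ...] = DEFAULT_DEPENDENT_ENZYMES
    orthologue_pairs: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ORTHOLOGUE_PAIRS)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, genes in self.subsections.items():
            if not genes:
                raise ValueError(f"empty subsection {name!r}")
            dup = seen & set(genes)
            if dup:
                raise ValueError(f"genes in multiple subsections: {dup}")
            seen |= set(genes)
        loop = set(self.subsections.get("nucleotide_loop", ()))
        if not set(self.salvage_genes) <= loop:
            raise ValueError("salvage_genes must be nucleotide_loop genes")

    @property
    def all_genes(self) -> set[str]:
        return {g for genes in self.subsections.values() for g in genes}

    def pathway_gene_set(self) -> set[str]:
        """Complete gene complement of a canonical de novo producer."""
        return self.all_genes

    def canonicalize(self, genes: Iterable[str]) -> set[str]:
        """Expand a gene set with its orthologue-pair equivalents."""
        out = set(genes)
        for a, b in self.orthologue_pairs.items():
            if a in out:
                out.add(b)
            if b in out:
                out.add(a)
        return out


@dataclass(frozen=True)
class CategoryRules:
    producer_corrin_min: float = 0.5
    producer_loop_min: float = 0.5
    salvager_min_salvage_genes: int = 3


@dataclass
class CobamideAnnotation:
    """Per-genome cobamide biosynthesis and dependence annotation."""

    genome_id: str
    genes: set[str]
    category: str
    dependent: bool
    dependent_enzymes_found: set[str]
    benzimidazolyl_capable: bool
    subsection_completeness: dict[str, float]
    decision_trace: str = ""
    association: str | None = None  # host | environment


def subsection_completeness(
    genes: Iterable[str], model: PathwayModel | None = None
) -> dict[str, float]:
    """Fraction of each subsection's genes present in a genome.

    The gene set is first expanded with orthologue equivalences, then
    intersected per subsection.  The reported ``corrin_ring`` completeness
    is the max of the aerobic and anaerobic series.
    """
    model = model or PathwayModel()
    expanded = model.canonicalize(genes)
    out: dict[str, float] = {}
    for name, members in model.subsections.items():
        out[name] = len(expanded & set(members)) / len(members)
    out["corrin_ring"] = max(
        out.get("corrin_ring_aerobic", 0.0), out.get("corrin_ring_anaerobic", 0.0)
    )
    return out


def classify_biosynthesis(
    genes: Iterable[str],
    model: PathwayModel | None = None,
    rules: CategoryRules | None = None,
) -> tuple[str, str]:
    """Assign producer / salvager / nonproducer, with a decision trace."""
    model = model or PathwayModel()
    rules = rules or CategoryRules()
    gene_set = set(genes)
    comp = subsection_completeness(gene_set, model)
    corrin = comp["corrin_ring"]
    loop = comp["nucleotide_loop"]
    if corrin >= rules.producer_corrin_min and loop >= rules.producer_loop_min:
        return "producer", (
            f"corrin_ring {corrin:.3f} >= {rules.producer_corrin_min} and "
            f"nucleotide_loop {loop:.3f} >= {rules.producer_loop_min}"
        )
    expanded = model.canonicalize(gene_set)
    n_salvage = len(expanded & set(model.salvage_genes))
    if n_salvage >= rules.salvager_min_salvage_genes:
        return "salvager", (
            f"{n_salvage} of {len(model.salvage_genes)} salvage genes "
            f">= {rules.salvager_min_salvage_genes}"
        )
    return "nonproducer", (
        f"corrin_ring {corrin:.3f} or nucleotide_loop {loop:.3f} below producer "
        f"thresholds; only {n_salvage} salvage genes"
    )


def classify_dependence(
    genes: Iterable[str], model: PathwayModel | None = None
) -> tuple[bool, set[str]]:
    """Cobamide dependence: any of the seven dependent enzyme families."""
    model = model or PathwayModel()
    found = set(genes) & set(model.dependent_enzymes)
    return bool(found), found


def annotate_genome(
    genome_id: str,
    genes: Iterable[str],
    model: PathwayModel | None = None,
    rules: CategoryRules | None = None,
    association: str | None = None,
) -> CobamideAnnotation:
    """Full annotation: category, dependence, bluB flag, completeness."""
    model = model or PathwayModel()
    gene_set = set(genes)
    category, trace = classify_biosynthesis(gene_set, model, rules)
    dependent, found = classify_dependence(gene_set, model)
    return CobamideAnnotation(
        genome_id=genome_id,
        genes=gene_set,
        category=category,
        dependent=dependent,
        dependent_enzymes_found=found,
        benzimidazolyl_capable="bluB" in gene_set,
        subsection_completeness=subsection_completeness(gene_set, model),
        decision_trace=trace,
        association=association,
    )


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float  # Mann-Whitney U of the first group
    pvalue: float
    method: str


def compare_groups(
    annotations: Sequence[CobamideAnnotation],
    metric: Mapping[str, float],
    group_field: str = "association",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test of a per-genome metric between groups.

    Groups come from the annotations' ``association`` labels; ``metric``
    maps genome_id to the numeric value compared (genome length, gene
    cluster count, ...).  Exact null distribution when both groups have
    n <= 8; tie-corrected normal approximation otherwise.
    """
    groups: dict[str, list[float]] = {}
    for a in annotations:
        label = getattr(a, group_field)
        if label is None:
            raise ValueError(f"genome {a.genome_id} lacks {group_field}")
        groups.setdefault(label, []).append(float(metric[a.genome_id]))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {sorted(groups)}")
    (name_a, xa), (name_b, xb) = sorted(groups.items())
    if not xa or not xb:
        raise ValueError("a comparison group is empty")
    xa, xb = np.asarray(xa, float), np.asarray(xb, float)
    exact = len(xa) <= 8 and len(xb) <= 8
    res = stats.mannwhitneyu(
        xa, xb, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return GroupComparison(
        group_a=name_a,
        group_b=name_b,
        n_a=len(xa),
        n_b=len(xb),
        median_a=float(np.median(xa)),
        median_b=float(np.median(xb)),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method="exact" if exact else "normal approximation (tie-corrected)",
    )
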