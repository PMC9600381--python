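"""Read-based functional profiling of cobamide genes in metagenomes.

The workflow mirrors a read-level profile-HMM survey: translated reads are
searched against per-gene profile HMMs, hits are filtered at an E-value
cutoff (default 1e-6), multi-HMM reads are resolved to a single best hit,
and a gene is called present in a sample only when the union of hit
envelopes covers at least 20% of the HMM length.  Retained hits are joined
with read-level taxonomy into a gene x taxon table with two normalizations:
by HMM length (within-sample comparisons) and by HMM length and sequencing
depth (cross-sample comparisons).  Rare species-gene pairings — those not
seen in at least five samples spanning two or more data sets — are removed,
as are hits to known contaminant taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import ProfileHMMHit, SampleMetadata, TaxonAssignment

logger = logging.getLogger(__name__)

#: reserved taxon bucket for reads the classifier could not place
UNCLASSIFIED = "unclassified"

#: default cobamide biosynthesis marker genes spanning the pathway:
#: tetrapyrrole precursor (cobA), corrin ring (cbi series, anaerobic
#: nomenclature; aerobic orthologues are mapped by the pathway model),
#: nucleotide loop (cobQ/cobD/cobP/cobS), and lower ligand (bluB).
MARKER_GENES_11 = (
    "cobA", "cbiL", "cbiH", "cbiF", "cbiC", "cbiA",
    "cobQ", "cobD", "cobP", "cobS", "bluB",
)

#: producer-call markers: the 11 above minus bluB, which some documented
#: producers of non-benzimidazolyl cobamides lack.
PRODUCER_MARKERS_10 = tuple(g for g in MARKER_GENES_11 if g != "bluB")


@dataclass(frozen=True)
class ProfilingParams:
    """Thresholds for hit filtering, presence calling, and normalization."""

    evalue_max: float = 1e-6
    min_coverage: float = 0.20
    min_samples: int = 5
    min_datasets: int = 2
    depth_scale: float = 1e6  # hits per million post-QC reads
    producer_min_markers: int = 5
    producer_marker_genes: tuple[str, ...] = PRODUCER_MARKERS_10

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")
        if self.producer_min_markers > len(self.producer_marker_genes):
            raise ValueError("producer_min_markers exceeds marker list size")


# required columns of the underlying entries frame
_COLUMNS = ["sample_id", "gene", "taxon", "raw_hits", "norm_length",
            "norm_length_depth"]


@dataclass
class GeneTaxonTable:
    """Per-sample normalized hit counts keyed by (sample, gene, taxon).

    Backed by a pandas DataFrame with columns ``sample_id, gene, taxon,
    raw_hits, norm_length, norm_length_depth``.  No entry has raw_hits == 0;
    norm_length = raw_hits / hmm_length and norm_length_depth =
    norm_length / total_reads * depth_scale hold exactly.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"entries missing columns {missing}")
        if (self.entries["raw_hits"] <= 0).any():
            raise ValueError("entries with raw_hits <= 0 are not allowed")
        self.entries = self.entries.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def taxa(self) -> set[str]:
        return set(self.entries["taxon"])

    @property
    def genes(self) -> set[str]:
        return set(self.entries["gene"])

    @property
    def samples(self) -> set[str]:
        return set(self.entries["sample_id"])

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneTaxonTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str,
                                                "taxon": str})
        return cls(df)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def six_frame_translate(dna: str) -> dict[int, str]:
    """Translate a read in all six frames with the standard genetic code.

    Frames +1..+3 read the forward strand at offsets 0..2; frames -1..-3
    read the reverse complement likewise.  Stops are ``*``; codons with N
    translate to ``X``; trailing partial codons are dropped.
    """
    dna = dna.upper()
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    if set(dna) - set("ACGTN"):
        raise ValueError(f"invalid characters in sequence: {set(dna) - set('ACGTN')}")
    rc = dna.translate(_COMPLEMENT)[::-1]
    frames: dict[int, str] = {}
    for offset in range(3):
        for strand, seq, key in ((1, dna, offset + 1), (-1, rc, -(offset + 1))):
            sub = seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[key] = str(Seq(sub).translate())
    return frames


def select_best_hits(
    hits: Sequence[ProfileHMMHit], params: ProfilingParams | None = None
) -> list[ProfileHMMHit]:
    """Apply the E-value cutoff and resolve multi-HMM reads to one hit each.

    Among a read's surviving hits exactly one is retained: minimal E-value,
    ties broken by maximal bit score, residual ties by lexicographically
    smallest HMM name.  Reads are identified after frame-suffix stripping,
    so the same read hitting in two frames still yields one hit.
    """
    params = params or ProfilingParams()
    best: dict[str, ProfileHMMHit] = {}
    for h in hits:
        if h.evalue > params.evalue_max:
            continue
        cur = best.get(h.read_id)
        if cur is None or _hit_key(h) < _hit_key(cur):
            best[h.read_id] = h
    return list(best.values())


def _hit_key(h: ProfileHMMHit) -> tuple[float, float, str]:
    return (h.evalue, -h.bitscore, h.hmm_name)


def gene_presence(
    hits: Sequence[ProfileHMMHit],
    hmm_length: int,
    params: ProfilingParams | None = None,
) -> tuple[bool, float]:
    """Coverage-gated presence call for one (sample, gene).

    Coverage is the length of the union of hit envelopes (1-based inclusive
    HMM coordinates) divided by the HMM length; the gene is present when
    coverage >= min_coverage (inclusive boundary).
    """
    params = params or ProfilingParams()
    if hmm_length <= 0:
        raise ValueError("hmm_length must be positive")
    if not hits:
        return False, 0.0
    ivals = sorted((h.hmm_from, h.hmm_to) for h in hits)
    covered = 0
    cur_from, cur_to = ivals[0]
    for a, b in ivals[1:]:
        if a <= cur_to + 1:
            cur_to = max(cur_to, b)
        else:
            covered += cur_to - cur_from + 1
            cur_from, cur_to = a, b
    covered += cur_to - cur_from + 1
    coverage = covered / hmm_length
    return coverage >= params.min_coverage, coverage


def build_gene_taxon_table(
    hits_by_sample: Mapping[str, Sequence[ProfileHMMHit]],
    assignments: Mapping[str, Sequence[TaxonAssignment]] | Sequence[TaxonAssignment],
    metadata: Mapping[str, SampleMetadata],
    hmm_lengths: Mapping[str, int],
    params: ProfilingParams | None = None,
) -> GeneTaxonTable:
    """Join best hits with taxonomy into a normalized gene x taxon table.

    ``hits_by_sample`` maps sample_id to already-deduplicated hits;
    ``assignments`` is either one pooled sequence or a per-sample mapping.
    Genes failing the coverage gate in a sample contribute no entries for
    that sample; the coverage union is computed across taxa jointly.
    Unclassified or unassigned reads are aggregated under the reserved
    taxon ``"unclassified"``.
    """
    params = params or ProfilingParams()
    per_sample_tax = isinstance(assignments, Mapping)
    if not per_sample_tax:
        pooled = {a.read_id: a for a in assignments}

    rows: list[tuple[str, str, str, int]] = []
    for sample_id, hits in hits_by_sample.items():
        if sample_id not in metadata:
            raise KeyError(f"sample {sample_id!r} missing from metadata")
        if per_sample_tax:
            tax = {a.read_id: a for a in assignments[sample_id]}
        else:
            tax = pooled
        by_gene: dict[str, list[ProfileHMMHit]] = {}
        for h in hits:
            by_gene.setdefault(h.hmm_name, []).append(h)
        for gene, gene_hits in by_gene.items():
            present, _cov = gene_presence(gene_hits, hmm_lengths[gene], params)
            if not present:
                continue
            for h in gene_hits:
                a = tax.get(h.read_id)
                taxon = (
                    UNCLASSIFIED
                    if a is None or a.rank == "unclassified"
                    else a.taxon_name
                )
                rows.append((sample_id, gene, taxon, 1))

    if not rows:
        return GeneTaxonTable(pd.DataFrame(columns=_COLUMNS))
    df = (
        pd.DataFrame(rows, columns=["sample_id", "gene", "taxon", "raw_hits"])
        .groupby(["sample_id", "gene", "taxon"], as_index=False)["raw_hits"]
        .sum()
    )
    lengths = df["gene"].map(hmm_lengths)
    depths = df["sample_id"].map({s: m.total_reads for s, m in metadata.items()})
    df["norm_length"] = df["raw_hits"] / lengths
    df["norm_length_depth"] = df["norm_length"] / depths * params.depth_scale
    return GeneTaxonTable(df)


def filter_rare_pairs(
    table: GeneTaxonTable,
    metadata: Mapping[str, SampleMetadata],
    params: ProfilingParams | None = None,
) -> GeneTaxonTable:
    """Drop species-gene pairings lacking multi-sample, multi-study support.

    A (gene, taxon) pairing survives iff it appears (raw_hits >= 1) in at
    least ``min_samples`` samples AND those samples span at least
    ``min_datasets`` distinct studies.
    """
    params = params or ProfilingParams()
    df = table.entries
    if df.empty:
        return GeneTaxonTable(df.copy())
    study = df["sample_id"].map({s: m.study_id for s, m in metadata.items()})
    if study.isna().any():
        missing = df.loc[study.isna(), "sample_id"].unique()
        raise KeyError(f"samples missing from metadata: {list(missing)}")
    support = df.assign(study_id=study).groupby(["gene", "taxon"]).agg(
        n_samples=("sample_id", "nunique"), n_studies=("study_id", "nunique")
    )
    keep = support[
        (support["n_samples"] >= params.min_samples)
        & (support["n_studies"] >= params.min_datasets)
    ].index
    mask = pd.MultiIndex.from_frame(df[["gene", "taxon"]]).isin(keep)
    return GeneTaxonTable(df[mask].copy())


def remove_contaminants(
    table: GeneTaxonTable, contaminant_taxa: Iterable[str]
) -> GeneTaxonTable:
    """Remove all entries whose taxon is in the contaminant list."""
    contaminants = set(contaminant_taxa)
    df = table.entries
    mask = ~df["taxon"].isin(contaminants)
    n_removed = int((~mask).sum())
    if n_removed:
        logger.info("removed %d contaminant entries", n_removed)
    return GeneTaxonTable(df[mask].copy())


def taxon_contribution(
    table: GeneTaxonTable, sample_id: str, gene_subset: Iterable[str]
) -> dict[str, float]:
    """Per-taxon share of a sample's length-normalized hits to a gene set.

    contribution(t) = sum over genes g in the subset of norm_length(s,g,t),
    divided by the sample's total over all taxa; shares sum to 1.
    """
    genes = set(gene_subset)
    df = table.entries
    sel = df[(df["sample_id"] == sample_id) & (df["gene"].isin(genes))]
    total = sel["norm_length"].sum()
    if total <= 0:
        raise ValueError(
            f"no hits in sample {sample_id!r} for gene subset"
        )
    shares = sel.groupby("taxon")["norm_length"].sum() / total
    return shares.to_dict()


def gene_frequency_profile(table: GeneTaxonTable, gene: str) -> dict[str, float]:
    """Per-taxon share of a gene's depth-normalized hits across samples."""
    df = table.entries
    sel = df[df["gene"] == gene]
    total = sel["norm_length_depth"].sum()
    if sel.empty or total <= 0:
        raise ValueError(f"gene {gene!r} absent from table")
    shares = sel.groupby("taxon")["norm_length_depth"].sum() / total
    return shares.to_dict()


def call_metagenomic_producers(
    table: GeneTaxonTable, params: ProfilingParams | None = None
) -> set[str]:
    """Call de novo producers from read evidence.

    A taxon is a metagenomic producer when it retains at least one entry
    (any sample, post-filtering) for at least ``producer_min_markers``
    distinct genes from the producer marker set.
    """
    params = params or ProfilingParams()
    markers = set(params.producer_marker_genes)
    df = table.entries
    sel = df[df["gene"].isin(markers)]
    counts = sel.groupby("taxon")["gene"].nunique()
    producers = set(counts[counts >= params.producer_min_markers].index)
    producers.discard(UNCLASSIFIED)
    return producers


def mock_false_positive_rate(
    table: GeneTaxonTable, expected_taxa: Iterable[str]
) -> float:
    """Fraction of hits assigned to taxa absent from a mock community.

    Unclassified reads count in neither numerator nor denominator.
    """
    expected = set(expected_taxa)
    df = table.entries
    df = df[df["taxon"] != UNCLASSIFIED]
    total = df["raw_hits"].sum()
    if total <= 0:
        raise ValueError("no classified hits in table")
    foreign = df.loc[~df["taxon"].isin(expected), "raw_hits"].sum()
    return float(foreign) / float(total)
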