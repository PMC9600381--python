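"""Cobalamin riboswitch hit filtering and genomic context assignment.

Cobalamin riboswitches are cobamide-binding mRNA leader elements that
regulate downstream genes; covariance-model hits against them are filtered
at an E-value cutoff (counts are reported raw, not length-normalized,
because read and model lengths are comparable), and riboswitch loci mapped
onto genomes are annotated with their flanking genes.  Because a riboswitch
acts in the 5' UTR of the transcript it controls, "downstream" is defined
on the riboswitch's own strand, and the functional category of a locus is
that of the nearest same-strand downstream gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import ParseError, RiboswitchHit

FUNCTIONAL_CATEGORIES = (
    "cobamide_biosynthesis",
    "abc_transport",
    "cobalt_transport",
    "cobamide_dependent",
    "cobamide_independent_isozyme",
    "hypothetical",
    "other",
)


def filter_riboswitch_hits(
    hits: Sequence[RiboswitchHit], evalue_max: float = 1e-6
) -> list[RiboswitchHit]:
    """Keep hits at or below the E-value cutoff."""
    return [h for h in hits if h.evalue <= evalue_max]


def riboswitch_counts(hits: Sequence[RiboswitchHit]) -> dict[str, int]:
    """Raw per-model hit counts (no length normalization)."""
    out: dict[str, int] = {}
    for h in hits:
        out[h.model_name] = out.get(h.model_name, 0) + 1
    return out


@dataclass(frozen=True)
class GeneFeature:
    """One gene/CDS row from a GFF3 annotation (1-based inclusive)."""

    seqid: str
    gene_id: str
    start: int
    end: int
    strand: str
    product: str | None = None


@dataclass(frozen=True)
class FlankingGene:
    gene_id: str
    product: str | None
    strand: str            # relative to the reference
    same_strand: bool      # relative to the riboswitch
    distance: int          # bp gap to the riboswitch (0 when overlapping)


@dataclass
class GeneContext:
    """Genomic neighborhood of one riboswitch locus."""

    seqid: str
    start: int
    end: int
    strand: str
    upstream_genes: list[FlankingGene]
    downstream_genes: list[FlankingGene]
    functional_category: str


def read_gff3_genes(path: str | Path) -> list[GeneFeature]:
    """Minimal GFF3 reader returning gene/CDS features.

    Keeps ``gene`` and ``CDS`` rows (CDS only where no gene row shares its
    ID span), with ``ID``/``locus_tag`` as identifier and ``product`` from
    the attribute column.
    """
    feats: list[GeneFeature] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"line {lineno}: GFF3 needs 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
            if ftype not in ("gene", "CDS"):
                continue
            attr_map: dict[str, str] = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene_id = (
                attr_map.get("ID")
                or attr_map.get("locus_tag")
                or attr_map.get("Name")
                or f"feature_{lineno}"
            )
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ParseError(f"line {lineno}: malformed coordinates") from None
            feats.append(GeneFeature(
                seqid=seqid, gene_id=gene_id, start=s, end=e,
                strand=strand, product=attr_map.get("product"),
            ))
    # prefer gene rows over CDS rows sharing the same identifier
    by_id: dict[tuple[str, str], GeneFeature] = {}
    for f in feats:
        key = (f.seqid, f.gene_id)
        if key not in by_id:
            by_id[key] = f
    return list(by_id.values())


def read_riboswitch_bed(path: str | Path) -> pd.DataFrame:
    """BED-like TSV of riboswitch loci: seqid, start, end, strand[, name].

    Coordinates are 1-based inclusive (matching the GFF3 convention used
    throughout this package).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["seqid", "start", "end", "strand", "name"],
        dtype={"seqid": str},
    )
    if df["strand"].isna().any():
        raise ParseError("riboswitch table needs seqid, start, end, strand")
    return df


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp distance between two 1-based inclusive intervals (coordinate
    difference between the facing ends); 0 when overlapping."""
    if b_start > a_end:
        return b_start - a_end
    if a_start > b_end:
        return a_start - b_end
    return 0


def assign_context(
    riboswitches: pd.DataFrame,
    annotations: Sequence[GeneFeature],
    window_bp: int = 5000,
    function_map: Mapping[str, str] | None = None,
) -> list[GeneContext]:
    """Annotate each riboswitch locus with flanking genes and a category.

    Genes overlapping the riboswitch or within ``window_bp`` on either side
    are listed as upstream/downstream relative to the riboswitch's strand,
    sorted by distance.  The locus category is that of the nearest
    same-strand downstream gene looked up in ``function_map`` (keyed by
    gene_id, falling back to product string); a mapped-but-productless gene
    is ``hypothetical``, an unmapped gene or empty neighborhood ``other``.
    """
    function_map = function_map or {}
    by_seq: dict[str, list[GeneFeature]] = {}
    for f in annotations:
        by_seq.setdefault(f.seqid, []).append(f)
    contexts: list[GeneContext] = []
    for row in riboswitches.itertuples(index=False):
        if row.seqid not in by_seq:
            raise KeyError(f"sequence {row.seqid!r} absent from GFF3 annotation")
        rs_start, rs_end, rs_strand = int(row.start), int(row.end), row.strand
        up: list[FlankingGene] = []
        down: list[FlankingGene] = []
        for g in by_seq[row.seqid]:
            d = _gap(rs_start, rs_end, g.start, g.end)
            if d > window_bp:
                continue
            # position of the gene relative to the riboswitch on its strand
            if d == 0:
                after = True  # overlapping genes count as downstream targets
            elif rs_strand == "+":
                after = g.start > rs_end
            else:
                after = g.end < rs_start
            fg = FlankingGene(
                gene_id=g.gene_id,
                product=g.product,
                strand=g.strand,
                same_strand=(g.strand == rs_strand),
                distance=d,
            )
            (down if after else up).append(fg)
        up.sort(key=lambda f: (f.distance, f.gene_id))
        down.sort(key=lambda f: (f.distance, f.gene_id))
        category = "other"
        for fg in down:
            if not fg.same_strand:
                continue
            mapped = function_map.get(fg.gene_id)
            if mapped is None and fg.product is not None:
                mapped = function_map.get(fg.product)
            if mapped is not None:
                category = mapped
            elif fg.product is None:
                category = "hypothetical"
            else:
                category = "other"
            break
        if category not in FUNCTIONAL_CATEGORIES:
            raise ValueError(f"unknown functional category {category!r}")
        contexts.append(GeneContext(
            seqid=row.seqid, start=rs_start, end=rs_end, strand=rs_strand,
            upstream_genes=up, downstream_genes=down,
            functional_category=category,
        ))
    return contexts
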