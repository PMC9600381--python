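"""Readers and writers for the external formats the pipeline touches.

All tabular formats are UTF-8, whitespace- or tab-delimited, with
``#``-prefixed comment lines.  Coordinates are 1-based inclusive on disk
(the HMMER/GFF3 convention); interval arithmetic elsewhere in the package
converts to 0-based half-open as needed.

Six-frame translated reads carry a ``_frameK`` suffix (K in 1..6, with 4-6
denoting reverse-strand frames).  Parsers strip the suffix to recover the
original read identifier and record the signed frame.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_FRAME_SUFFIX = re.compile(r"^(?P<read>.+)_frame(?P<k>[1-6])$")

#: suffix index -> signed frame
FRAME_CODES = {1: 1, 2: 2, 3: 3, 4: -1, 5: -2, 6: -3}

VALID_RANKS = ("species", "genus", "family", "phylum", "unclassified")


class ParseError(ValueError):
    """Malformed row in an input file; message carries the line number."""


class UnregisteredModelError(KeyError):
    """A hit names a profile HMM absent from the registered model lengths."""


@dataclass(frozen=True)
class ProfileHMMHit:
    """One translated-read vs profile-HMM alignment (per-domain row)."""

    read_id: str
    frame: int
    hmm_name: str
    hmm_accession: str
    evalue: float  # independent E-value
    bitscore: float
    hmm_from: int  # 1-based inclusive
    hmm_to: int    # 1-based inclusive
    hmm_length: int

    def __post_init__(self) -> None:
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")
        if self.evalue <= 0:
            raise ValueError(f"E-value must be positive, got {self.evalue}")
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_length):
            raise ValueError(
                f"invalid HMM envelope [{self.hmm_from}, {self.hmm_to}] "
                f"for model of length {self.hmm_length}"
            )


@dataclass(frozen=True)
class TaxonAssignment:
    """Read-level taxonomic assignment (one per read per classifier run)."""

    read_id: str
    taxon_id: int
    taxon_name: str
    rank: str = "species"

    def __post_init__(self) -> None:
        if self.rank not in VALID_RANKS:
            raise ValueError(f"invalid rank {self.rank!r}")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample study context; ``total_reads`` is the post-QC depth."""

    sample_id: str
    study_id: str
    subject_id: str
    site: str
    microenvironment: str
    total_reads: int

    def __post_init__(self) -> None:
        if self.microenvironment not in ("sebaceous", "moist", "dry", "foot"):
            raise ValueError(f"invalid microenvironment {self.microenvironment!r}")
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")


@dataclass(frozen=True)
class RiboswitchHit:
    """One read vs cobalamin-riboswitch covariance-model hit."""

    read_id: str
    model_name: str
    evalue: float
    strand: str

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("E-value must be positive")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


def split_frame_suffix(target_name: str) -> tuple[str, int]:
    """Strip a ``_frameK`` suffix, returning (read_id, signed frame).

    Names without the suffix are returned unchanged with frame +1.
    """
    m = _FRAME_SUFFIX.match(target_name)
    if m is None:
        return target_name, 1
    return m.group("read"), FRAME_CODES[int(m.group("k"))]


def _float(token: str, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: malformed {what} {token!r}") from None


def _int(token: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"line {lineno}: malformed {what} {token!r}") from None


def read_domtblout(
    path: str | Path, hmm_lengths: Mapping[str, int]
) -> list[ProfileHMMHit]:
    """Parse HMMER per-domain tabular output (``--domtblout``).

    Column layout follows hmmsearch: target (translated read) in column 1,
    query (profile HMM) in column 4, query length in column 6, independent
    E-value in column 13, bit score in column 14, HMM envelope in columns
    16-17.  The registered ``hmm_lengths`` are cross-checked against the
    file's qlen column.

    Raises
    ------
    UnregisteredModelError
        if a row names an HMM absent from ``hmm_lengths``.
    ParseError
        on truncated rows or malformed numeric fields (with line number).
    """
    hits: list[ProfileHMMHit] = []
    n_rejected = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 17:
                raise ParseError(f"line {lineno}: truncated row ({len(fields)} fields)")
            target, _tacc = fields[0], fields[1]
            hmm_name = fields[3]
            if hmm_name not in hmm_lengths:
                raise UnregisteredModelError(
                    f"unregistered model {hmm_name!r} at line {lineno}"
                )
            read_id, frame = split_frame_suffix(target)
            hit = ProfileHMMHit(
                read_id=read_id,
                frame=frame,
                hmm_name=hmm_name,
                hmm_accession=fields[4],
                evalue=_float(fields[12], lineno, "E-value"),
                bitscore=_float(fields[13], lineno, "bit score"),
                hmm_from=_int(fields[15], lineno, "hmm_from"),
                hmm_to=_int(fields[16], lineno, "hmm_to"),
                hmm_length=hmm_lengths[hmm_name],
            )
            hits.append(hit)
    if n_rejected:
        logger.warning("rejected %d malformed rows in %s", n_rejected, path)
    return hits


_FRAME_TO_SUFFIX = {v: k for k, v in FRAME_CODES.items()}


def write_domtblout(path: str | Path, hits: Iterable[ProfileHMMHit]) -> None:
    """Write hits back out in the domtblout column layout (round-trip safe)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# target_name t_acc tlen query_name q_acc qlen full_evalue "
                 "full_score full_bias dom_n dom_of c_evalue i_evalue score bias "
                 "hmm_from hmm_to ali_from ali_to env_from env_to acc\n")
        for h in hits:
            target = f"{h.read_id}_frame{_FRAME_TO_SUFFIX[h.frame]}"
            fh.write(
                f"{target} - {h.hmm_length} {h.hmm_name} {h.hmm_accession} "
                f"{h.hmm_length} {h.evalue:.6g} {h.bitscore:.6g} 0.0 1 1 "
                f"{h.evalue:.6g} {h.evalue:.6g} {h.bitscore:.6g} 0.0 "
                f"{h.hmm_from} {h.hmm_to} {h.hmm_from} {h.hmm_to} "
                f"{h.hmm_from} {h.hmm_to} 0.90\n"
            )


_KRAKEN_NAME_TAXID = re.compile(r"^(?P<name>.*?)\s*\(taxid\s+(?P<id>\d+)\)$")


def read_taxonomy(
    path: str | Path,
    dialect: str = "kraken2",
    taxon_names: Mapping[int, str] | None = None,
) -> list[TaxonAssignment]:
    """Parse read-level taxonomy.

    ``kraken2`` dialect: the 5-column read output (C/U, read id, taxon,
    length, LCA map).  The taxon column is either a bare taxid or the
    ``--use-names`` form ``Name (taxid N)``.  ``tsv`` dialect: a header row
    ``read_id  taxon_id  taxon_name  rank``.

    Unclassified reads are yielded with ``rank="unclassified"`` and taxon id
    0.  A duplicated ``read_id`` keeps the last assignment and logs a
    warning.  An empty file yields an empty list.
    """
    if dialect not in ("kraken2", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    by_read: dict[str, TaxonAssignment] = {}
    n_dup = 0

    def _add(a: TaxonAssignment) -> None:
        nonlocal n_dup
        if a.read_id in by_read:
            n_dup += 1
            logger.warning("duplicate assignment for read %s; keeping last", a.read_id)
        by_read[a.read_id] = a

    with open(path, encoding="utf-8") as fh:
        if dialect == "kraken2":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 4:
                    fields = line.split()
                if len(fields) < 4:
                    raise ParseError(f"line {lineno}: expected >=4 kraken2 columns")
                status, read_id, taxon_field = fields[0], fields[1], fields[2]
                if status == "U":
                    _add(TaxonAssignment(read_id, 0, "unclassified", "unclassified"))
                    continue
                m = _KRAKEN_NAME_TAXID.match(taxon_field)
                if m:
                    taxid = int(m.group("id"))
                    name = m.group("name")
                else:
                    taxid = _int(taxon_field, lineno, "taxid")
                    name = (taxon_names or {}).get(taxid, f"taxon_{taxid}")
                _add(TaxonAssignment(read_id, taxid, name, "species"))
        else:
            header = fh.readline()
            if not header:
                return []
            cols = header.rstrip("\n").split("\t")
            required = ["read_id", "taxon_id", "taxon_name", "rank"]
            if any(c not in cols for c in required):
                raise ParseError(f"missing columns; need {required}, got {cols}")
            idx = {c: cols.index(c) for c in required}
            for lineno, line in enumerate(fh, start=2):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < len(cols):
                    raise ParseError(f"line {lineno}: truncated row")
                _add(TaxonAssignment(
                    fields[idx["read_id"]],
                    _int(fields[idx["taxon_id"]], lineno, "taxon_id"),
                    fields[idx["taxon_name"]],
                    fields[idx["rank"]],
                ))
    if n_dup:
        logger.warning("%d duplicate read_id rows in %s (last wins)", n_dup, path)
    return list(by_read.values())


def write_taxonomy(path: str | Path, assignments: Iterable[TaxonAssignment]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\ttaxon_id\ttaxon_name\trank\n")
        for a in assignments:
            fh.write(f"{a.read_id}\t{a.taxon_id}\t{a.taxon_name}\t{a.rank}\n")


def read_cmsearch_tblout(path: str | Path) -> list[RiboswitchHit]:
    """Parse Infernal ``cmsearch --tblout`` output.

    Strand comes from column 10; no E-value filtering happens here (that is
    :func:`cobashare.riboswitch_context.filter_riboswitch_hits`).
    """
    hits: list[RiboswitchHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 16:
                raise ParseError(f"line {lineno}: truncated cmsearch row")
            hits.append(RiboswitchHit(
                read_id=fields[0],
                model_name=fields[2],
                evalue=_float(fields[15], lineno, "E-value"),
                strand=fields[9],
            ))
    return hits


def write_cmsearch_tblout(path: str | Path, hits: Iterable[RiboswitchHit]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#target_name accession query_name q_acc mdl mdl_from mdl_to "
                 "seq_from seq_to strand trunc pass gc bias score evalue inc\n")
        for h in hits:
            fh.write(
                f"{h.read_id} - {h.model_name} - cm 1 100 1 100 {h.strand} "
                f"no 1 0.5 0.0 50.0 {h.evalue:.6g} !\n"
            )


def read_gene_table(
    path: str | Path,
    vocabulary: Iterable[str] | None = None,
    roster: Iterable[str] | None = None,
) -> dict[str, set[str]]:
    """Read a per-genome gene-presence TSV (columns genome_id, gene).

    Gene symbols are matched case-insensitively against ``vocabulary`` when
    one is given; unknown symbols are kept verbatim with a warning.  Genomes
    listed in ``roster`` but absent from the file map to an empty set.
    """
    vocab = {g.lower(): g for g in vocabulary} if vocabulary is not None else None
    genomes: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["genome_id", "gene"]:
            raise ParseError(f"expected header genome_id<TAB>gene, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: truncated row")
            genome, gene = fields[0], fields[1]
            if vocab is not None:
                canon = vocab.get(gene.lower())
                if canon is None:
                    logger.warning("unknown gene symbol %r (kept verbatim)", gene)
                else:
                    gene = canon
            genomes.setdefault(genome, set()).add(gene)
    for g in roster or ():
        genomes.setdefault(g, set())
    return genomes


def write_gene_table(path: str | Path, genomes: Mapping[str, set[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tgene\n")
        for genome in sorted(genomes):
            for gene in sorted(genomes[genome]):
                fh.write(f"{genome}\t{gene}\n")


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read the sample metadata TSV keyed by sample_id."""
    out: dict[str, SampleMetadata] = {}
    cols = ["sample_id", "study_id", "subject_id", "site",
            "microenvironment", "total_reads"]
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if any(c not in header for c in cols):
            raise ParseError(f"metadata needs columns {cols}, got {header}")
        idx = {c: header.index(c) for c in cols}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            md = SampleMetadata(
                sample_id=f[idx["sample_id"]],
                study_id=f[idx["study_id"]],
                subject_id=f[idx["subject_id"]],
                site=f[idx["site"]],
                microenvironment=f[idx["microenvironment"]],
                total_reads=_int(f[idx["total_reads"]], lineno, "total_reads"),
            )
            out[md.sample_id] = md
    return out


def write_metadata(path: str | Path, metadata: Mapping[str, SampleMetadata]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tstudy_id\tsubject_id\tsite\tmicroenvironment\ttotal_reads\n")
        for md in metadata.values():
            fh.write(f"{md.sample_id}\t{md.study_id}\t{md.subject_id}\t"
                     f"{md.site}\t{md.microenvironment}\t{md.total_reads}\n")
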