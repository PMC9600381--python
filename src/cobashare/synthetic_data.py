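"""Synthetic multi-study metagenome inputs with known ground truth.

Every generator returns the simulated data together with a
:class:`SyntheticTruth` record (planted categories, abundances, noise
rates, association graph, seed), so downstream recovery can be scored
exactly.  All randomness flows through one ``numpy`` generator seeded per
call; identical parameters and seed reproduce identical outputs bit for
bit.

Three generators cover the pipeline's inputs:

* :func:`make_community` — a species roster with planted producer /
  salvager / nonproducer categories, cobamide-dependence flags, and
  marker-gene complements;
* :func:`simulate_hit_table` — per-sample profile-HMM hit tables plus
  read taxonomy and metadata, with log-normal species abundances, hit
  counts proportional to abundance x HMM length, envelopes constructed so
  that truly present genes pass the 20% coverage gate while planted
  "trace" genes stay below it, and a flat false-positive rate of reads
  reassigned to out-of-roster taxa;
* :func:`simulate_count_matrices` — per-study species count matrices
  drawn from a known sparse association graph by a Gaussian copula
  (latent multivariate normal mapped through the marginal's inverse CDF),
  which preserves the planted graph's rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io_formats
from .io_formats import ProfileHMMHit, SampleMetadata, TaxonAssignment
from .genome_classification import PathwayModel
from .read_profiling import MARKER_GENES_11

PHYLA = ("Actinobacteria", "Firmicutes", "Proteobacteria", "Bacteroidetes")
MICROENVIRONMENTS = ("sebaceous", "moist", "dry", "foot")
SITES = {"sebaceous": "back", "moist": "antecubital_fossa",
         "dry": "forearm", "foot": "toe_web"}

#: gene with a registered HMM that no roster species ever emits reads for;
#: used to plant sub-coverage "trace" signals
TRACE_GENE = "cbiZ"

#: universal single-copy phylogenetic marker carried by every species
UNIVERSAL_GENE = "rpoB"


@dataclass(frozen=True)
class SyntheticSpecies:
    name: str
    phylum: str
    category: str           # producer | salvager | nonproducer
    dependent: bool
    genes: frozenset[str]   # genome gene complement


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every simulated dataset."""

    species: list[SyntheticSpecies]
    hmm_lengths: dict[str, int]
    seed: int
    params: dict
    fp_rate: float = 0.0
    abundances: pd.DataFrame | None = None        # sample x species, sums to 1
    trace_plantings: list[tuple[str, str]] = field(default_factory=list)
    graph: list[tuple[int, int, int]] | None = None   # (i, j, sign)
    precision: np.ndarray | None = None

    @property
    def producers(self) -> set[str]:
        return {s.name for s in self.species if s.category == "producer"}

    @property
    def salvagers(self) -> set[str]:
        return {s.name for s in self.species if s.category == "salvager"}

    @property
    def categories(self) -> dict[str, str]:
        return {s.name: s.category for s in self.species}


def _default_hmm_lengths(genes: Sequence[str], rng: np.random.Generator) -> dict[str, int]:
    return {g: int(rng.integers(150, 450)) for g in genes}


def make_community(
    n_species: int,
    n_producers: int,
    n_salvagers: int,
    frac_dependent: float,
    seed: int,
    model: PathwayModel | None = None,
) -> SyntheticTruth:
    """Plant a species roster with known cobamide categories.

    Producers carry the complete de novo pathway gene complement (hence all
    biosynthesis markers), salvagers only the nucleotide-loop salvage set,
    nonproducers neither.  A ``frac_dependent`` share of species (rounded)
    additionally carries 1-3 of the seven cobamide-dependent enzyme
    families.  Phyla are assigned round-robin over four labels.
    """
    if n_producers + n_salvagers > n_species:
        raise ValueError("producers + salvagers exceed n_species")
    if not (0 <= frac_dependent <= 1):
        raise ValueError("frac_dependent must be in [0, 1]")
    model = model or PathwayModel()
    rng = np.random.default_rng(seed)
    categories = (
        ["producer"] * n_producers
        + ["salvager"] * n_salvagers
        + ["nonproducer"] * (n_species - n_producers - n_salvagers)
    )
    n_dependent = round(frac_dependent * n_species)
    dependent_idx = set(rng.choice(n_species, size=n_dependent, replace=False).tolist())
    pathway = frozenset(model.pathway_gene_set())
    salvage = frozenset(model.salvage_genes)
    species: list[SyntheticSpecies] = []
    for i in range(n_species):
        genes: set[str] = {UNIVERSAL_GENE}
        if categories[i] == "producer":
            genes |= pathway
        elif categories[i] == "salvager":
            genes |= salvage
        dependent = i in dependent_idx
        if dependent:
            k = int(rng.integers(1, 4))
            genes |= set(rng.choice(model.dependent_enzymes, size=k, replace=False))
        species.append(SyntheticSpecies(
            name=f"Species_{i:04d}",
            phylum=PHYLA[i % len(PHYLA)],
            category=categories[i],
            dependent=dependent,
            genes=frozenset(genes),
        ))
    hmm_genes = list(MARKER_GENES_11) + [UNIVERSAL_GENE, TRACE_GENE]
    return SyntheticTruth(
        species=species,
        hmm_lengths=_default_hmm_lengths(hmm_genes, rng),
        seed=seed,
        params=dict(
            n_species=n_species, n_producers=n_producers,
            n_salvagers=n_salvagers, frac_dependent=frac_dependent,
        ),
    )


def _emitted_genes(sp: SyntheticSpecies, hmm_genes: set[str]) -> list[str]:
    """Genes of this species that have a registered HMM (reads observable)."""
    return sorted(sp.genes & hmm_genes)


def simulate_hit_table(
    truth: SyntheticTruth,
    n_samples: int,
    n_studies: int,
    reads_per_sample: int,
    fp_rate: float,
    seed: int,
    sigma: float = 1.0,
    depth_multiplier: int = 100,
    n_trace_genes: int = 0,
    outdir: str | Path | None = None,
) -> tuple[
    dict[str, list[ProfileHMMHit]],
    dict[str, list[TaxonAssignment]],
    dict[str, SampleMetadata],
    SyntheticTruth,
]:
    """Simulate per-sample HMM hit tables, taxonomy, and metadata.

    Per sample, species relative abundances are drawn log-normal(0, sigma);
    ``reads_per_sample`` hit-yielding reads are allocated to (species, gene)
    cells with probability proportional to abundance x HMM length over the
    species' observable genes.  Envelope length is max(20% of the model,
    40 aa), with tiled starts, so any gene with >= 1 read passes the 20%
    coverage gate; planted trace genes (``n_trace_genes`` per sample, on a
    gene no roster species carries) get 2 reads pinned to the first 15% of
    the model and therefore fail it.  Each read is independently reassigned
    to an out-of-roster contaminant taxon with probability ``fp_rate``.
    Metadata depth is ``reads_per_sample * depth_multiplier`` (hits are a
    small fraction of a metagenome).  When ``outdir`` is given the tables
    are also written in the on-disk dialects.
    """
    if not (0 <= fp_rate < 0.5):
        raise ValueError("fp_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    hmm_genes = set(truth.hmm_lengths)
    names = [sp.name for sp in truth.species]
    cells: list[tuple[str, str]] = []     # (species, gene) allocation cells
    for sp in truth.species:
        for g in _emitted_genes(sp, hmm_genes):
            cells.append((sp.name, g))

    hits_by_sample: dict[str, list[ProfileHMMHit]] = {}
    tax_by_sample: dict[str, list[TaxonAssignment]] = {}
    metadata: dict[str, SampleMetadata] = {}
    abund_rows = []
    trace_plantings: list[tuple[str, str]] = []
    taxon_ids = {name: 1000 + i for i, name in enumerate(names)}

    for s in range(n_samples):
        sample_id = f"S{s:04d}"
        study_id = f"study{s % n_studies + 1}"
        micro = MICROENVIRONMENTS[s % len(MICROENVIRONMENTS)]
        metadata[sample_id] = SampleMetadata(
            sample_id=sample_id,
            study_id=study_id,
            subject_id=f"subj{s:04d}",
            site=SITES[micro],
            microenvironment=micro,
            total_reads=reads_per_sample * depth_multiplier,
        )
        ab = rng.lognormal(mean=0.0, sigma=sigma, size=len(names))
        ab /= ab.sum()
        abund_rows.append(ab)
        ab_by_name = dict(zip(names, ab))
        weights = np.array(
            [ab_by_name[spn] * truth.hmm_lengths[g] for spn, g in cells]
        )
        weights /= weights.sum()
        counts = rng.multinomial(reads_per_sample, weights)

        hits: list[ProfileHMMHit] = []
        tax: list[TaxonAssignment] = []
        read_no = 0
        per_gene_tile: dict[str, int] = {}
        for (spn, gene), c in zip(cells, counts):
            if c == 0:
                continue
            L = truth.hmm_lengths[gene]
            env_len = min(L, max(int(np.ceil(0.2 * L)), 40))
            n_tiles = max(1, (L - env_len) // env_len + 1)
            for _ in range(int(c)):
                read_id = f"{sample_id}_r{read_no:07d}"
                read_no += 1
                tile = per_gene_tile.get(gene, 0)
                per_gene_tile[gene] = tile + 1
                start = 1 + (tile % n_tiles) * env_len
                end = min(L, start + env_len - 1)
                hits.append(ProfileHMMHit(
                    read_id=read_id,
                    frame=io_formats.FRAME_CODES[int(rng.integers(1, 7))],
                    hmm_name=gene,
                    hmm_accession=f"SYN{abs(hash(gene)) % 100000:05d}",
                    evalue=float(10.0 ** -rng.uniform(7, 30)),
                    bitscore=float(rng.uniform(30, 200)),
                    hmm_from=start,
                    hmm_to=end,
                    hmm_length=L,
                ))
                if fp_rate > 0 and rng.random() < fp_rate:
                    alien = f"Contaminant_sp_{int(rng.integers(1, 6))}"
                    tax.append(TaxonAssignment(read_id, 9000, alien, "species"))
                else:
                    tax.append(TaxonAssignment(
                        read_id, taxon_ids[spn], spn, "species"))

        for _ in range(n_trace_genes):
            L = truth.hmm_lengths[TRACE_GENE]
            hi = max(1, int(np.floor(0.15 * L)))
            carrier = names[int(rng.integers(len(names)))]
            for _ in range(2):
                read_id = f"{sample_id}_r{read_no:07d}"
                read_no += 1
                hits.append(ProfileHMMHit(
                    read_id=read_id, frame=1, hmm_name=TRACE_GENE,
                    hmm_accession="SYNTRACE",
                    evalue=float(10.0 ** -rng.uniform(7, 30)),
                    bitscore=float(rng.uniform(30, 200)),
                    hmm_from=1, hmm_to=hi, hmm_length=L,
                ))
                tax.append(TaxonAssignment(read_id, taxon_ids[carrier],
                                           carrier, "species"))
            trace_plantings.append((sample_id, TRACE_GENE))

        hits_by_sample[sample_id] = hits
        tax_by_sample[sample_id] = tax

    out_truth = SyntheticTruth(
        species=truth.species,
        hmm_lengths=truth.hmm_lengths,
        seed=seed,
        params={**truth.params, "n_samples": n_samples, "n_studies": n_studies,
                "reads_per_sample": reads_per_sample, "sigma": sigma},
        fp_rate=fp_rate,
        abundances=pd.DataFrame(abund_rows, index=list(metadata), columns=names),
        trace_plantings=trace_plantings,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample_id in metadata:
            io_formats.write_domtblout(
                outdir / f"{sample_id}.domtblout", hits_by_sample[sample_id])
            io_formats.write_taxonomy(
                outdir / f"{sample_id}.taxonomy.tsv", tax_by_sample[sample_id])
        io_formats.write_metadata(outdir / "metadata.tsv", metadata)
    return hits_by_sample, tax_by_sample, metadata, out_truth


def band_graph(p: int, k: int = 1) -> list[tuple[int, int, int]]:
    """Band association graph: node i linked to its k nearest successors."""
    return [(i, j, 1) for i in range(p) for j in range(i + 1, min(i + k + 1, p))]


def graph_precision(
    graph: Sequence[tuple[int, int, int]],
    p: int,
    strength: float = 0.3,
    min_eigenvalue: float = 0.01,
) -> np.ndarray:
    """Sparse precision matrix from a signed edge list.

    A positive association (sign +1) maps to a negative precision
    off-diagonal.  The diagonal is ridge-inflated until the smallest
    eigenvalue reaches ``min_eigenvalue``.
    """
    omega = np.eye(p)
    for i, j, sign in graph:
        omega[i, j] = omega[j, i] = -sign * strength
    w = np.linalg.eigvalsh(omega).min()
    if w < min_eigenvalue:
        omega += (min_eigenvalue - w) * np.eye(p)
    if np.linalg.eigvalsh(omega).min() <= 0:
        raise ValueError("precision matrix not positive definite after loading")
    return omega


def simulate_count_matrices(
    graph: Sequence[tuple[int, int, int]],
    p: int,
    n_samples: int,
    n_studies: int,
    seed: int,
    marginal: str = "negative_binomial",
    strength: float = 0.3,
    mean_log: float = np.log(50.0),
    mean_sigma: float = 1.0,
    nb_size: float = 5.0,
) -> tuple[list[pd.DataFrame], SyntheticTruth]:
    """Per-study count matrices from a known sparse association graph.

    A Gaussian copula: latent draws from the covariance implied by the
    graph's precision matrix are mapped through the standard normal CDF to
    uniforms and then through the marginal's inverse CDF (negative binomial
    with species-specific log-normal means and common size ``nb_size``, or
    Poisson).  Studies share the graph and the marginals but use
    independent draws.
    """
    if marginal not in ("negative_binomial", "poisson"):
        raise ValueError(f"unknown marginal {marginal!r}")
    rng = np.random.default_rng(seed)
    omega = graph_precision(graph, p, strength)
    cov = np.linalg.inv(omega)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    chol = np.linalg.cholesky(corr)
    mu = rng.lognormal(mean=mean_log, sigma=mean_sigma, size=p)
    names = [f"Species_{i:04d}" for i in range(p)]
    matrices: list[pd.DataFrame] = []
    for study in range(n_studies):
        z = rng.standard_normal((n_samples, p)) @ chol.T
        u = stats.norm.cdf(z)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        if marginal == "negative_binomial":
            pr = nb_size / (nb_size + mu)
            counts = stats.nbinom.ppf(u, n=nb_size, p=pr[None, :])
        else:
            counts = stats.poisson.ppf(u, mu[None, :])
        idx = [f"study{study + 1}_S{i:04d}" for i in range(n_samples)]
        matrices.append(pd.DataFrame(
            counts.astype(np.int64), index=idx, columns=names))
    truth = SyntheticTruth(
        species=[],
        hmm_lengths={},
        seed=seed,
        params=dict(p=p, n_samples=n_samples, n_studies=n_studies,
                    marginal=marginal, strength=strength, nb_size=nb_size),
        graph=[tuple(e) for e in graph],
        precision=omega,
    )
    return matrices, truth
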