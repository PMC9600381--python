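"""Community diversity statistics around cobamide-producer abundance.

Samples are rarefied to a common depth (sampling without replacement),
alpha diversity is the Shannon index, beta diversity is Bray-Curtis on
square-root transformed abundances (the transform up-weights rare taxa),
and the cumulative relative abundance of producer species (e.g. the
cobamide-producing corynebacteria, CPC) is related to diversity and to
sample groupings with rank tests: Spearman correlation, Mann-Whitney U,
and Kruskal-Wallis followed by Dunn's test with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class CommunityParams:
    rarefaction_depth: int = 1_500_000
    sqrt_transform: bool = True
    quartile_low: float | None = None   # computed from data when None
    quartile_high: float | None = None
    alpha: float = 0.05
    seed: int = 0


class SampleDiscarded(ValueError):
    """Raised when a sample's total count is below the rarefaction depth."""


def rarefy(counts: Sequence[int] | np.ndarray, depth: int, seed: int = 0) -> np.ndarray:
    """Subsample a species count vector to exactly ``depth`` reads.

    Multivariate hypergeometric draw (without replacement); a sample whose
    total is below ``depth`` raises :class:`SampleDiscarded` rather than
    being silently dropped.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = int(counts.sum())
    if total < depth:
        raise SampleDiscarded(
            f"sample has {total} reads, below rarefaction depth {depth}"
        )
    if total == depth:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def shannon(rel_abund: Sequence[float] | np.ndarray, base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i over positive entries.

    Natural log by default; pass ``base`` to change (e.g. 2).
    """
    p = np.asarray(rel_abund, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundance")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def bray_curtis(
    matrix: np.ndarray | pd.DataFrame, sqrt_transform: bool = True
) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity between samples (rows).

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i), after an optional square
    root of every entry.  Pairs of all-zero samples are NaN (undefined).
    """
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    if sqrt_transform:
        x = np.sqrt(x)
    d = squareform(pdist(x, metric="braycurtis"))
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    for i in zero_rows:
        for j in zero_rows:
            if i != j:
                d[i, j] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def cpc_abundance(
    rel_abund: Mapping[str, float] | pd.Series, producer_species: Iterable[str]
) -> float:
    """Cumulative relative abundance of the producer species present."""
    if isinstance(rel_abund, pd.Series):
        rel_abund = rel_abund.to_dict()
    producers = set(producer_species)
    return float(sum(v for k, v in rel_abund.items() if k in producers))


def quartile_grouping(
    values: Sequence[float] | np.ndarray, params: CommunityParams | None = None
) -> list[str]:
    """Label each value Low / Mid / High against quartile bounds.

    Bounds default to the first and third quartiles of ``values`` (type-7,
    linear interpolation).  Inequalities are strict: a value below the low
    bound is Low, above the high bound is High, everything else (including
    values exactly at a bound) is Mid.
    """
    params = params or CommunityParams()
    v = np.asarray(values, dtype=float)
    low = params.quartile_low
    high = params.quartile_high
    if low is None:
        low = float(np.quantile(v, 0.25))
    if high is None:
        high = float(np.quantile(v, 0.75))
    if low > high:
        raise ValueError("quartile_low exceeds quartile_high")
    return ["Low" if x < low else "High" if x > high else "Mid" for x in v]


@dataclass
class RankTestReport:
    design: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None = None  # Dunn-Bonferroni, when applicable


def dunn_test(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's post hoc z-tests on pooled ranks with tie correction.

    Returns one row per group pair with the z statistic, the unadjusted
    two-sided p-value, and the Bonferroni-adjusted p-value (multiplied by
    the number of comparisons and capped at 1).
    """
    names = sorted(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term for the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_ranks, sizes = [], []
    start = 0
    for v in values:
        mean_ranks.append(ranks[start:start + len(v)].mean())
        sizes.append(len(v))
        start += len(v)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append((names[i], names[j], z, p, min(1.0, p * m)))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "z", "pvalue", "pvalue_bonferroni"]
    )


def rank_tests(
    groups: Mapping[str, Sequence[float]],
    design: str = "kruskal_dunn_bonferroni",
) -> RankTestReport:
    """Rank-based group comparisons.

    ``kruskal_dunn_bonferroni``: Kruskal-Wallis H over all groups, then
    Dunn's pairwise z-tests with Bonferroni correction.
    ``mann_whitney``: two-sided Mann-Whitney U on exactly two groups.
    ``spearman``: Spearman rank correlation on exactly two paired vectors.
    """
    for name, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"group {name!r} is empty")
    vals = [np.asarray(v, dtype=float) for v in groups.values()]
    if design == "kruskal_dunn_bonferroni":
        if len(vals) < 2:
            raise ValueError("need at least 2 groups")
        h, p = stats.kruskal(*vals)
        return RankTestReport(design, float(h), float(p), dunn_test(groups))
    if design == "mann_whitney":
        if len(vals) != 2:
            raise ValueError("mann_whitney needs exactly 2 groups")
        res = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        return RankTestReport(design, float(res.statistic), float(res.pvalue))
    if design == "spearman":
        if len(vals) != 2 or len(vals[0]) != len(vals[1]):
            raise ValueError("spearman needs 2 paired vectors of equal length")
        rho, p = stats.spearmanr(vals[0], vals[1])
        return RankTestReport(design, float(rho), float(p))
    raise ValueError(f"unknown design {design!r}")
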