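"""Diversity and differentiation statistics on haplotype frequency tables.

Haplotypes are treated as alleles of a single locus, as is standard for
HLA region analyses: gene diversity is the unbiased expected
heterozygosity (2n/(2n-1))(1 - sum p^2) averaged over variation sites;
haplotype diversity is the same estimator applied to haplotype
frequencies; nucleotide diversity is the mean weighted pairwise difference
between two random haplotypes, divided by the region length, as a
percentage.  The 14-bp 3'UTR insertion/deletion is weighted as 14
nucleotide differences in diversity calculations (it is one site
everywhere else).

Differentiation statistics follow the variance-partition (AMOVA) family:
pairwise F_ST on haplotype identity with permutation p-values, Reynolds'
coancestry distance -ln(1 - F_ST), a Markov-chain exact test of population
differentiation on the haplotype x population contingency table, the
Guo-Thompson Markov-chain exact test of Hardy-Weinberg equilibrium, a
two-level (group / population / within) AMOVA with the three standard
permutation schemes, Bonferroni adjustment, and classical metric MDS for
visualising distance matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyTable", "WeightScheme", "DiversityReport", "DistanceMatrix",
    "AmovaResult", "haplotype_diversity", "gene_diversity",
    "nucleotide_diversity", "private_haplotypes", "hwe_exact_test",
    "pairwise_fst", "reynolds_distance", "exact_differentiation_test",
    "amova", "bonferroni", "classical_mds", "diversity_report",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class FrequencyTable:
    """Haplotype (or allele) counts per population.

    ``counts`` is a DataFrame with haplotype labels as index and population
    labels as columns; entries are non-negative integer counts and each
    column sums to that population's chromosome count 2n.
    """

    counts: pd.DataFrame

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative haplotype counts")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("haplotype counts must be integers")
        self.counts = self.counts.astype(int)

    @classmethod
    def from_frequencies(cls, freqs: pd.DataFrame, sizes: Mapping[str, int],
                         residual_label: str = "others") -> "FrequencyTable":
        """Convert a frequency table to counts at the stated 2n per column.

        Frequencies are rounded to the nearest count; any rounding residue
        (the columns of published tables are rounded from counts) is
        absorbed into the residual row so every column sums exactly to 2n.
        """
        counts = {}
        for pop in freqs.columns:
            n2 = int(sizes[pop])
            col = np.round(freqs[pop].to_numpy(dtype=float) * n2).astype(int)
            index = list(freqs.index)
            residue = n2 - col.sum()
            if residual_label in index:
                col[index.index(residual_label)] += residue
            elif residue != 0:
                index = index + [residual_label]
                col = np.append(col, residue)
            counts[pop] = pd.Series(col, index=index)
        df = pd.DataFrame(counts).fillna(0).astype(int)
        if (df.to_numpy() < 0).any():
            raise ValueError("rounding produced a negative residual count")
        return cls(df)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def chromosome_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.chromosome_counts

    def pooled(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class WeightScheme:
    """Per-site difference weights and region length for nucleotide diversity."""

    weights: Mapping[int, float] = field(default_factory=dict)
    default_weight: float = 1.0
    region_length: float = 286.0

    def __post_init__(self):
        if self.region_length <= 0:
            raise ValueError("region length must be positive")
        if self.default_weight < 1 or any(w < 1 for w in self.weights.values()):
            raise ValueError("site weights must be >= 1")

    def weight(self, site: int) -> float:
        return float(self.weights.get(site, self.default_weight))


@dataclass(frozen=True)
class DiversityReport:
    gene_diversity: float
    gene_diversity_sd: float
    haplotype_diversity: float
    haplotype_diversity_sd: float
    nucleotide_diversity_pct: float
    nucleotide_diversity_pct_sd: float
    mean_pairwise_differences: float
    private_haplotypes: Optional[int]
    n_chromosomes: int


@dataclass
class DistanceMatrix:
    values: pd.DataFrame
    metric: str
    pvalues: Optional[pd.DataFrame] = None
    pvalue_se: Optional[pd.DataFrame] = None

    def __post_init__(self):
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass(frozen=True)
class AmovaResult:
    sigma_among_groups: Optional[float]
    sigma_among_pops: float
    sigma_within: float
    pct_among_groups: Optional[float]
    pct_among_pops: float
    pct_within: float
    f_ct: Optional[float]
    f_sc: Optional[float]
    f_st: float
    p_f_ct: Optional[float] = None
    p_f_sc: Optional[float] = None
    p_f_st: Optional[float] = None


# ---------------------------------------------------------------------------
# diversity

def _check_freqs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative frequencies")
    if p.sum() > 1 + 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()} > 1")
    return p


def unbiased_heterozygosity(p: Iterable[float], n_chromosomes: int) -> float:
    """(2n/(2n-1)) * (1 - sum p_i^2)."""
    p = _check_freqs(np.fromiter(p, dtype=float))
    if n_chromosomes < 2:
        raise ValueError("need at least two chromosomes")
    return n_chromosomes / (n_chromosomes - 1) * (1.0 - float(np.sum(p ** 2)))


def _heterozygosity_sd(p: np.ndarray, n: int) -> float:
    """Sampling standard deviation of unbiased heterozygosity (Nei 1987)."""
    s2 = float(np.sum(p ** 2))
    s3 = float(np.sum(p ** 3))
    var = (2.0 / (n * (n - 1))) * (2.0 * (n - 2) * (s3 - s2 ** 2) + s2 - s2 ** 2)
    return math.sqrt(max(var, 0.0))


def haplotype_diversity(freqs: Iterable[float], n_chromosomes: int,
                        with_sd: bool = False):
    """Unbiased haplotype diversity H from haplotype frequencies.

    Residual rare-haplotype mass not listed in ``freqs`` contributes no
    squared-frequency mass (it is treated as negligible); pass the full
    frequency vector if the residual matters.
    """
    p = _check_freqs(np.fromiter(freqs, dtype=float))
    h = unbiased_heterozygosity(p, n_chromosomes)
    if not with_sd:
        return h
    return h, _heterozygosity_sd(p, n_chromosomes)


def gene_diversity(site_freqs: Sequence[Sequence[float]], n_chromosomes: int
                   ) -> tuple[float, float]:
    """Mean and sd over sites of per-site unbiased expected heterozygosity."""
    if not len(site_freqs):
        raise ValueError("need at least one site")
    hs = np.array([unbiased_heterozygosity(p, n_chromosomes) for p in site_freqs])
    return float(hs.mean()), float(hs.std(ddof=1)) if len(hs) > 1 else 0.0


def nucleotide_diversity(
    site_freqs: Mapping[int, Sequence[float]],
    n_chromosomes: int,
    weights: WeightScheme = WeightScheme(),
) -> tuple[float, float]:
    """Mean weighted pairwise differences k and nucleotide diversity pi (%).

    Frequency form: k = (2n/(2n-1)) * sum_s w_s (1 - sum_a p_sa^2), which
    equals the frequency-weighted mean pairwise weighted Hamming distance
    between two random haplotypes; pi% = 100 k / L.
    """
    k = 0.0
    for site, p in site_freqs.items():
        k += weights.weight(site) * (1.0 - float(np.sum(_check_freqs(np.asarray(p)) ** 2)))
    k *= n_chromosomes / (n_chromosomes - 1)
    return k, 100.0 * k / weights.region_length


def nucleotide_diversity_from_pool(
    haplotypes: Mapping[str, float],
    vectors: Mapping[str, Sequence[str]],
    sites: Sequence[int],
    n_chromosomes: int,
    weights: WeightScheme = WeightScheme(),
) -> tuple[float, float]:
    """Pairwise form of nucleotide diversity from a haplotype pool."""
    names = list(haplotypes)
    p = _check_freqs(np.array([haplotypes[n] for n in names]))
    w = np.array([weights.weight(s) for s in sites])
    k = 0.0
    for i, a in enumerate(names):
        va = vectors[a]
        for j, b in enumerate(names):
            if j <= i:
                continue
            d = sum(wi for wi, x, y in zip(w, va, vectors[b]) if x != y)
            k += 2.0 * p[i] * p[j] * d
    k *= n_chromosomes / (n_chromosomes - 1)
    return k, 100.0 * k / weights.region_length


def _tajima_sd(k: float, n: int) -> float:
    """Total sampling sd of mean pairwise differences (Tajima 1983 variance)."""
    if n < 8:
        return float("nan")
    var = (3.0 * n * (n + 1) * k + 2.0 * (n * n + n + 3) * k * k) / (
        11.0 * (n * n - 7 * n + 6))
    return math.sqrt(max(var, 0.0))


def private_haplotypes(table: FrequencyTable,
                       grouping: Optional[Mapping[str, str]] = None) -> pd.Series:
    """Count of haplotypes observed in exactly one population (or group)."""
    counts = table.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least two populations")
    if grouping is not None:
        counts = counts.T.groupby(pd.Series(grouping)).sum().T
    present = counts > 0
    is_private = present.sum(axis=1) == 1
    out = {}
    for unit in counts.columns:
        out[unit] = int((is_private & present[unit]).sum())
    return pd.Series(out)


def diversity_report(
    table: FrequencyTable,
    population: str,
    site_freqs: Mapping[int, Sequence[float]],
    weights: WeightScheme = WeightScheme(),
) -> DiversityReport:
    """Assemble the per-population diversity summary."""
    n2 = int(table.chromosome_counts[population])
    p = table.frequencies()[population].to_numpy()
    p = p[p > 0]
    h, h_sd = haplotype_diversity(p, n2, with_sd=True)
    g, g_sd = gene_diversity(list(site_freqs.values()), n2)
    k, pi = nucleotide_diversity(site_freqs, n2, weights)
    k_sd = _tajima_sd(k, n2)
    try:
        priv = int(private_haplotypes(table)[population])
    except ValueError:
        priv = None
    return DiversityReport(
        gene_diversity=g, gene_diversity_sd=g_sd,
        haplotype_diversity=h, haplotype_diversity_sd=h_sd,
        nucleotide_diversity_pct=pi,
        nucleotide_diversity_pct_sd=100.0 * k_sd / weights.region_length,
        mean_pairwise_differences=k,
        private_haplotypes=priv,
        n_chromosomes=n2,
    )


# ---------------------------------------------------------------------------
# F_ST / AMOVA machinery (haplotype identity distance: d = 0 same, 1 different)

def _ssd_within(counts: np.ndarray) -> float:
    """Within-population sum of squared deviations for one population column."""
    n = counts.sum()
    if n == 0:
        return 0.0
    return (n - (counts ** 2).sum() / n) / 2.0


def _theta_two_pops(c1: np.ndarray, c2: np.ndarray) -> float:
    """Two-population variance-partition F_ST on haplotype identity."""
    n1, n2 = c1.sum(), c2.sum()
    n = n1 + n2
    ssd_wp = _ssd_within(c1) + _ssd_within(c2)
    ssd_total = _ssd_within(c1 + c2)
    ssd_ap = ssd_total - ssd_wp
    sigma_w = ssd_wp / (n - 2)
    n_prime = (n - (n1 ** 2 + n2 ** 2) / n)  # / (K-1) with K=2
    sigma_a = (ssd_ap / 1.0 - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    return float(sigma_a / denom) if denom > 0 else 0.0


def pairwise_fst(table: FrequencyTable, permutations: int = 1000,
                 seed: int = 0) -> DistanceMatrix:
    """Pairwise F_ST between populations with permutation p-values.

    The p-value is the proportion of permuted chromosome-label assignments
    (the observed one included) whose F_ST is at least the observed value.
    Small negative estimates are legitimate sampling outcomes and are kept.
    """
    pops = table.populations
    sizes = table.chromosome_counts
    if (sizes < 2).any():
        raise ValueError("every population needs at least two chromosomes")
    n_hap = table.counts.shape[0]
    vals = pd.DataFrame(0.0, index=pops, columns=pops)
    pvals = pd.DataFrame(np.nan, index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            c1 = table.counts[a].to_numpy()
            c2 = table.counts[b].to_numpy()
            theta = _theta_two_pops(c1, c2)
            vals.loc[a, b] = vals.loc[b, a] = theta
            if permutations > 0:
                pooled = np.repeat(np.arange(n_hap), c1 + c2)
                n1 = c1.sum()
                hits = 1  # the observed assignment
                for _ in range(permutations):
                    rng.shuffle(pooled)
                    p1 = np.bincount(pooled[:n1], minlength=n_hap)
                    p2 = np.bincount(pooled[n1:], minlength=n_hap)
                    if _theta_two_pops(p1, p2) >= theta - 1e-12:
                        hits += 1
                p = hits / (permutations + 1)
                pvals.loc[a, b] = pvals.loc[b, a] = p
    np.fill_diagonal(pvals.values, 0.0)
    np.fill_diagonal(vals.values, 0.0)
    return DistanceMatrix(values=vals, metric="FST",
                          pvalues=None if permutations == 0 else pvals)


def reynolds_distance(table: FrequencyTable, fst: Optional[DistanceMatrix] = None
                      ) -> DistanceMatrix:
    """Reynolds' coancestry distance D = -ln(1 - F_ST) per population pair."""
    if fst is None:
        fst = pairwise_fst(table, permutations=0)
    theta = fst.values.to_numpy().clip(0.0, 1.0 - 1e-12)
    d = -np.log(1.0 - theta)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        values=pd.DataFrame(d, index=fst.values.index, columns=fst.values.columns),
        metric="Reynolds")


def amova(
    table: FrequencyTable,
    grouping: Optional[Mapping[str, str]] = None,
    permutations: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """Hierarchical AMOVA on haplotype identity distance.

    With a grouping (population -> group, at least two groups) the
    three-level decomposition yields F_CT (among groups), F_SC (among
    populations within groups) and F_ST (within populations vs total);
    without one, the two-level decomposition yields F_ST only.  P-values
    use the three standard permutation schemes: whole populations among
    groups (F_CT), chromosomes among populations within groups (F_SC), and
    chromosomes among all populations (F_ST).
    """
    counts = table.counts.to_numpy()
    pops = table.populations
    rng = np.random.default_rng(seed)

    if grouping is None or len(set(grouping.values())) < 2:
        if grouping is not None:
            raise ValueError("grouping must contain at least two groups")
        sigma_a, sigma_w = _two_level_components(counts)
        total = sigma_a + sigma_w
        fst = sigma_a / total if total > 0 else 0.0
        p_st = _perm_pvalue_two_level(counts, fst, permutations, rng)
        return AmovaResult(
            sigma_among_groups=None, sigma_among_pops=sigma_a, sigma_within=sigma_w,
            pct_among_groups=None,
            pct_among_pops=100 * sigma_a / total if total else 0.0,
            pct_within=100 * sigma_w / total if total else 100.0,
            f_ct=None, f_sc=None, f_st=fst, p_f_st=p_st)

    groups = sorted(set(grouping.values()))
    gidx = [groups.index(grouping[p]) for p in pops]
    sa, sb, sc = _three_level_components(counts, np.array(gidx))
    total = sa + sb + sc
    f_ct = sa / total if total > 0 else 0.0
    f_sc = sb / (sb + sc) if (sb + sc) > 0 else 0.0
    f_st = (sa + sb) / total if total > 0 else 0.0

    p_ct = p_sc = p_st = None
    if permutations > 0:
        gi = np.array(gidx)
        # F_CT: permute whole populations among groups
        hits = 1
        for _ in range(permutations):
            perm = rng.permutation(gi)
            a, b, c = _three_level_components(counts, perm)
            t = a + b + c
            if (a / t if t > 0 else 0.0) >= f_ct - 1e-12:
                hits += 1
        p_ct = hits / (permutations + 1)
        # F_SC: permute chromosomes among populations within each group
        hits = 1
        for _ in range(permutations):
            shuf = _shuffle_within_groups(counts, gi, rng)
            a, b, c = _three_level_components(shuf, gi)
            if (b / (b + c) if (b + c) > 0 else 0.0) >= f_sc - 1e-12:
                hits += 1
        p_sc = hits / (permutations + 1)
        # F_ST: permute chromosomes among all populations
        hits = 1
        sizes = counts.sum(axis=0)
        for _ in range(permutations):
            shuf = _shuffle_all(counts, sizes, rng)
            a, b, c = _three_level_components(shuf, gi)
            t = a + b + c
            if ((a + b) / t if t > 0 else 0.0) >= f_st - 1e-12:
                hits += 1
        p_st = hits / (permutations + 1)

    return AmovaResult(
        sigma_among_groups=sa, sigma_among_pops=sb, sigma_within=sc,
        pct_among_groups=100 * sa / total if total else 0.0,
        pct_among_pops=100 * sb / total if total else 0.0,
        pct_within=100 * sc / total if total else 100.0,
        f_ct=f_ct, f_sc=f_sc, f_st=f_st,
        p_f_ct=p_ct, p_f_sc=p_sc, p_f_st=p_st)


def _two_level_components(counts: np.ndarray) -> tuple[float, float]:
    sizes = counts.sum(axis=0)
    n = sizes.sum()
    k = counts.shape[1]
    ssd_wp = sum(_ssd_within(counts[:, j]) for j in range(k))
    ssd_total = _ssd_within(counts.sum(axis=1))
    sigma_w = ssd_wp / (n - k)
    n_prime = (n - (sizes ** 2).sum() / n) / (k - 1)
    sigma_a = ((ssd_total - ssd_wp) / (k - 1) - sigma_w) / n_prime
    return float(sigma_a), float(sigma_w)


def _three_level_components(counts: np.ndarray, gidx: np.ndarray
                            ) -> tuple[float, float, float]:
    """Excoffier three-level variance components on identity distance."""
    sizes = counts.sum(axis=0).astype(float)
    n = sizes.sum()
    k = counts.shape[1]
    groups = np.unique(gidx)
    g = len(groups)
    ssd_wp = sum(_ssd_within(counts[:, j]) for j in range(k))
    ssd_total = _ssd_within(counts.sum(axis=1))
    ssd_ag = ssd_total
    ssd_apwg = 0.0
    group_sizes = []
    sum_n2_over_ng = 0.0
    for grp in groups:
        cols = np.where(gidx == grp)[0]
        gc = counts[:, cols]
        ng = sizes[cols].sum()
        group_sizes.append(ng)
        ssd_g = _ssd_within(gc.sum(axis=1))
        ssd_apwg += ssd_g - sum(_ssd_within(gc[:, j]) for j in range(gc.shape[1]))
        ssd_ag -= ssd_g
        sum_n2_over_ng += (sizes[cols] ** 2).sum() / ng
    group_sizes = np.array(group_sizes)
    df_ag, df_apwg, df_wp = g - 1, k - g, n - k
    sigma_c = ssd_wp / df_wp
    if df_apwg == 0:
        # one population per group: no among-populations-within-groups level
        sigma_b = 0.0
    else:
        n1 = (n - sum_n2_over_ng) / df_apwg
        sigma_b = (ssd_apwg / df_apwg - sigma_c) / n1
    n2c = (sum_n2_over_ng - (sizes ** 2).sum() / n) / df_ag
    n3 = (n - (group_sizes ** 2).sum() / n) / df_ag
    sigma_a = (ssd_ag / df_ag - sigma_c - n2c * sigma_b) / n3
    return float(sigma_a), float(sigma_b), float(sigma_c)


def _shuffle_all(counts: np.ndarray, sizes: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    pooled = np.repeat(np.arange(counts.shape[0]), counts.sum(axis=1))
    rng.shuffle(pooled)
    out = np.zeros_like(counts)
    start = 0
    for j, n in enumerate(sizes):
        out[:, j] = np.bincount(pooled[start:start + n], minlength=counts.shape[0])
        start += n
    return out


def _shuffle_within_groups(counts: np.ndarray, gidx: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(counts)
    for grp in np.unique(gidx):
        cols = np.where(gidx == grp)[0]
        sizes = counts[:, cols].sum(axis=0)
        pooled = np.repeat(np.arange(counts.shape[0]), counts[:, cols].sum(axis=1))
        rng.shuffle(pooled)
        start = 0
        for j, n in zip(cols, sizes):
            out[:, j] = np.bincount(pooled[start:start + n], minlength=counts.shape[0])
            start += n
    return out


def _perm_pvalue_two_level(counts, observed, permutations, rng) -> Optional[float]:
    if permutations <= 0:
        return None
    sizes = counts.sum(axis=0)
    hits = 1
    for _ in range(permutations):
        shuf = _shuffle_all(counts, sizes, rng)
        a, w = _two_level_components(shuf)
        t = a + w
        if (a / t if t > 0 else 0.0) >= observed - 1e-12:
            hits += 1
    return hits / (permutations + 1)


# ---------------------------------------------------------------------------
# exact tests

def _log_factorials(n: int) -> np.ndarray:
    out = np.zeros(n + 1)
    out[1:] = np.cumsum(np.log(np.arange(1, n + 1)))
    return out


def hwe_exact_test(
    genotype_counts: Mapping[tuple[int, int], int],
    chain_length: int = 100_000,
    dememorization: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Guo-Thompson Markov-chain exact test of Hardy-Weinberg equilibrium.

    ``genotype_counts`` maps unordered allele-index pairs (i <= j) to
    diplotype counts; haplotypes are the alleles of a single multiallelic
    locus.  The chain proposes the classical two-individual allele switch
    and the p-value is the fraction of visited tables whose conditional
    probability (given allele counts) does not exceed the observed one.
    Returns (p, Monte-Carlo standard error).  Monomorphic input returns
    (1.0, 0.0) by convention.
    """
    counts: dict[tuple[int, int], int] = {}
    alleles: set[int] = set()
    for (i, j), c in genotype_counts.items():
        if c < 0:
            raise ValueError("negative genotype count")
        if c:
            key = (min(i, j), max(i, j))
            counts[key] = counts.get(key, 0) + int(c)
            alleles.update(key)
    if len(alleles) < 2:
        warnings.warn("monomorphic sample: HWE p-value is 1 by convention")
        return 1.0, 0.0
    n = sum(counts.values())
    lf = _log_factorials(2 * n + 1)

    def log_cond(table: Mapping[tuple[int, int], int]) -> float:
        # P(table | allele counts) = n! prod m_i! 2^h / ((2n)! prod n_ij!)
        h = sum(c for (i, j), c in table.items() if i != j)
        m: dict[int, int] = {}
        for (i, j), c in table.items():
            m[i] = m.get(i, 0) + c
            m[j] = m.get(j, 0) + c
        val = lf[n] + h * math.log(2.0) - lf[2 * n]
        for c in m.values():
            val += lf[c]
        for c in table.values():
            val -= lf[c]
        return val

    rng = np.random.default_rng(seed)
    table = dict(counts)
    log_obs = log_cond(table)
    log_cur = log_obs

    def pair_sel_logprob(tab, x, y):
        # unordered probability of drawing one individual of genotype x and
        # one of genotype y (sequential count-weighted draws)
        if x == y:
            num = tab.get(x, 0) * (tab.get(x, 0) - 1)
        else:
            num = 2 * tab.get(x, 0) * tab.get(y, 0)
        return math.log(num) if num > 0 else -math.inf

    def repairings(x, y):
        a, b = x
        c, d = y
        opts = {
            tuple(sorted(((min(a, d), max(a, d)), (min(c, b), max(c, b))))),
            tuple(sorted(((min(a, c), max(a, c)), (min(b, d), max(b, d))))),
        }
        return list(opts)

    indicators: list[int] = []
    for step in range(dememorization + chain_length):
        ks = list(table.keys())
        w = np.array([table[k] for k in ks], dtype=float)
        g1 = ks[rng.choice(len(ks), p=w / w.sum())]
        w2 = w.copy()
        w2[ks.index(g1)] -= 1
        if w2.sum() > 0:
            g2 = ks[rng.choice(len(ks), p=w2 / w2.sum())]
            opts = repairings(g1, g2)
            new1, new2 = opts[int(rng.integers(len(opts)))]
            if tuple(sorted((new1, new2))) != tuple(sorted((g1, g2))):
                trial = dict(table)
                trial[g1] -= 1
                trial[g2] = trial.get(g2, 0) - 1
                if trial[g1] >= 0 and trial[g2] >= 0:
                    trial[new1] = trial.get(new1, 0) + 1
                    trial[new2] = trial.get(new2, 0) + 1
                    trial = {k: v for k, v in trial.items() if v > 0}
                    log_new = log_cond(trial)
                    # Hastings correction: forward draw of (g1,g2) with a
                    # 1/len(opts) re-pairing choice, reverse symmetric
                    rev_opts = repairings(new1, new2)
                    log_q_fwd = pair_sel_logprob(table, g1, g2) - math.log(len(opts))
                    log_q_rev = pair_sel_logprob(trial, new1, new2) - math.log(len(rev_opts))
                    log_ratio = (log_new - log_cur) + (log_q_rev - log_q_fwd)
                    if math.log(rng.random()) < log_ratio:
                        table = trial
                        log_cur = log_new
        if step >= dememorization:
            indicators.append(1 if log_cur <= log_obs + 1e-9 else 0)
    if not indicators:
        raise RuntimeError("HWE chain produced no samples")
    return _batch_mean_se(indicators)


def _batch_mean_se(indicators: Sequence[int], n_batches: int = 50) -> tuple[float, float]:
    """Chain mean with a batch-means standard error (autocorrelation-aware)."""
    x = np.asarray(indicators, dtype=float)
    p = float(x.mean())
    n_batches = min(n_batches, max(1, len(x) // 20))
    if n_batches < 2:
        return p, float(math.sqrt(p * (1 - p) / len(x)))
    batches = np.array_split(x, n_batches)
    means = np.array([b.mean() for b in batches])
    se = float(means.std(ddof=1) / math.sqrt(n_batches))
    return p, se


def _enumerate_tables(rows: list[int], cols: list[int]):
    """All non-negative integer tables with the given margins (small tables)."""
    r, c = len(rows), len(cols)

    def fill(i, remaining_cols, acc):
        if i == r - 1:
            if all(v >= 0 for v in remaining_cols):
                yield acc + [list(remaining_cols)]
            return
        def fill_row(j, left, row, rem):
            if j == c - 1:
                if 0 <= left <= rem[j]:
                    yield row + [left]
                return
            for v in range(0, min(left, rem[j]) + 1):
                yield from fill_row(j + 1, left - v, row + [v], rem)
        for row in fill_row(0, rows[i], [], remaining_cols):
            yield from fill(i + 1, [rc - rv for rc, rv in zip(remaining_cols, row)],
                            acc + [row])

    yield from fill(0, list(cols), [])


def exact_differentiation_test(
    table: np.ndarray | pd.DataFrame,
    chain_length: int = 100_000,
    dememorization: int = 10_000,
    seed: int = 0,
    enumeration_limit: int = 200_000,
) -> tuple[float, float]:
    """Exact test of population differentiation on a haplotype x population table.

    The p-value is the probability, under fixed margins, of tables no more
    probable than the observed one (the probability-mass criterion, as in
    the Fisher exact test).  Small state spaces are enumerated exactly
    (returning se 0); larger ones use a Metropolis chain over 2x2 diamond
    moves.  Degenerate margins give p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.size == 0:
        raise ValueError("need a 2-D contingency table")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if t.shape[0] < 2 or t.shape[1] < 2:
        warnings.warn("degenerate margins: differentiation p-value is 1")
        return 1.0, 0.0
    lf = _log_factorials(int(t.sum()) + 1)

    def log_prob(tab: np.ndarray) -> float:
        return (lf[rows].sum() + lf[cols].sum() - lf[int(tab.sum())]
                - lf[tab.ravel()].sum())

    log_obs = log_prob(t)

    # exact enumeration for small state spaces
    est_states = 1.0
    for rv in rows[:-1]:
        est_states *= math.comb(int(rv) + t.shape[1] - 1, t.shape[1] - 1)
    if est_states <= enumeration_limit:
        total = 0.0
        mass = 0.0
        for tab in _enumerate_tables([int(x) for x in rows], [int(x) for x in cols]):
            lp = log_prob(np.array(tab))
            pr = math.exp(lp)
            total += pr
            if lp <= log_obs + 1e-9:
                mass += pr
        return mass / total, 0.0

    rng = np.random.default_rng(seed)
    cur = t.copy()
    log_cur = log_obs
    indicators: list[int] = []
    r, c = cur.shape
    for step in range(dememorization + chain_length):
        i, k = rng.choice(r, size=2, replace=False)
        j, l = rng.choice(c, size=2, replace=False)
        # diamond move: +1 at (i,j),(k,l); -1 at (i,l),(k,j)
        if cur[i, l] > 0 and cur[k, j] > 0:
            delta = (math.log(cur[i, l]) + math.log(cur[k, j])
                     - math.log(cur[i, j] + 1) - math.log(cur[k, l] + 1))
            if math.log(rng.random()) < delta:
                cur[i, j] += 1
                cur[k, l] += 1
                cur[i, l] -= 1
                cur[k, j] -= 1
                log_cur = log_prob(cur)
        if step >= dememorization:
            indicators.append(1 if log_cur <= log_obs + 1e-9 else 0)
    return _batch_mean_se(indicators)


def differentiation_matrix(table: FrequencyTable, seed: int = 0,
                           **kwargs) -> DistanceMatrix:
    """Pairwise exact-differentiation p-value matrix (p stored as values=0 diag)."""
    pops = table.populations
    pv = pd.DataFrame(np.nan, index=pops, columns=pops)
    se = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for k, b in enumerate(pops[i + 1:], start=i + 1):
            sub = table.counts[[a, b]].to_numpy()
            p, s = exact_differentiation_test(sub, seed=seed + 97 * (i * len(pops) + k),
                                              **kwargs)
            pv.loc[a, b] = pv.loc[b, a] = p
            se.loc[a, b] = se.loc[b, a] = s
    zeros = pd.DataFrame(0.0, index=pops, columns=pops)
    return DistanceMatrix(values=zeros, metric="exact-differentiation",
                          pvalues=pv, pvalue_se=se)


# ---------------------------------------------------------------------------
# multiple testing and ordination

def bonferroni(alpha: float, m: int) -> dict:
    """Bonferroni-adjusted significance threshold alpha/m.

    The reported threshold is rounded to one significant figure, the
    convention used when quoting adjusted levels; the raw value is kept.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    raw = alpha / m
    if raw > 0:
        digits = -int(math.floor(math.log10(raw)))
        reported = round(raw, digits)
    else:
        reported = 0.0
    return {"raw": raw, "reported": reported, "m": m, "alpha": alpha}


def classical_mds(distances: pd.DataFrame | np.ndarray, dimensions: int = 2
                  ) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of a symmetric distance matrix.

    Double-centers the squared distances and takes the top eigenpairs;
    negative eigenvalues (non-Euclidean input) are clipped with a warning.
    Coordinates are centered at the origin.
    """
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        labels = list(range(d.shape[0]))
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if (evals[:dimensions] < -1e-10 * max(1.0, abs(evals[0]))).any():
        warnings.warn("negative eigenvalues clipped: distances are not Euclidean")
    k = min(dimensions, n)
    lam = np.clip(evals[:k], 0.0, None)
    coords = evecs[:, :k] * np.sqrt(lam)
    if k < dimensions:
        coords = np.hstack([coords, np.zeros((n, dimensions - k))])
    coords -= coords.mean(axis=0)
    return pd.DataFrame(coords, index=labels,
                        columns=[f"dim{i + 1}" for i in range(dimensions)])
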