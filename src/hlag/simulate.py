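"""Synthetic low-coverage cohorts drawn from the bundled haplotype tables.

The generator emulates the observation model of low-pass whole-genome
sequencing over the HLA-G panel: true diplotypes are drawn by random union
of gametes (Hardy-Weinberg) from a haplotype frequency table, and each
sample x site yields Poisson-distributed reads that copy one of the two
true alleles, with per-read corruption to another panel allele (base and
mapping error) and an extra Poisson stream of contaminant reads carrying a
random panel allele (miss-mapping from related loci).  Defaults mirror the
study conditions: the fourteen 1000Genomes Phase 1 population sizes and a
mean depth of 4 reads/site.

Error corruption stays inside the finite panel allele space: downstream
refinement operates on called alternate alleles, not raw base space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .refine import AlleleDepthRecord, GenotypeMatrix

#: 2n chromosome counts of the fourteen cohort populations.
DEFAULT_POPULATION_SIZES = {
    "CEU": 170, "TSI": 196, "GBR": 174, "FIN": 184, "IBS": 28,
    "CHB": 192, "CHS": 200, "JPT": 178,
    "YRI": 174, "LWK": 188,
    "ASW": 118, "MXL": 124, "PUR": 110, "CLM": 116,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Observation-model parameters for the synthetic cohort."""

    mean_depth: float = 4.0        # lambda, reads per site
    error_rate: float = 0.005      # epsilon, per-read allele corruption
    mismap_rate: float = 0.1       # rho, expected contaminant reads per site
    seed: int = 0
    population_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_SIZES))

    def __post_init__(self):
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.mismap_rate < 0:
            raise ValueError("mismap_rate must be >= 0")
        for pop, n in self.population_sizes.items():
            if n % 2:
                raise ValueError(f"population {pop}: chromosome count {n} is odd")


@dataclass(frozen=True)
class HaplotypeFrequencySet:
    """Haplotype allele vectors with sampling frequencies over a site panel."""

    sites: tuple[int, ...]
    names: tuple[str, ...]
    vectors: dict[str, tuple[str, ...]]
    frequencies: dict[str, float]
    site_alleles: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.names:
            raise ValueError("empty haplotype table")
        for name in self.names:
            if self.frequencies[name] < 0:
                raise ValueError(f"negative frequency for {name}")
            if len(self.vectors[name]) != len(self.sites):
                raise ValueError(f"{name}: vector does not span the site panel")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if not self.site_alleles:
            alleles = {
                p: tuple(sorted({self.vectors[n][i] for n in self.names}))
                for i, p in enumerate(self.sites)
            }
            object.__setattr__(self, "site_alleles", alleles)


def expand_residual(
    sites: Sequence[int],
    names: Sequence[str],
    vectors: Mapping[str, Sequence[str]],
    frequencies: Mapping[str, float],
    site_alleles: Mapping[int, Sequence[str]],
    seed: int,
    n_pseudo: int = 5,
) -> HaplotypeFrequencySet:
    """Normalize a frequency table whose rows sum to less than one.

    The residual ("others") mass is spread uniformly over ``n_pseudo``
    unnamed pseudo-haplotypes, each a single random edit of the most
    frequent haplotype, which exercises the new/unknown nomenclature path
    while keeping frequencies on the simplex.
    """
    freqs = {n: float(frequencies[n]) for n in names}
    vecs = {n: tuple(vectors[n]) for n in names}
    residual = 1.0 - sum(freqs.values())
    if residual < -1e-9:
        raise ValueError(f"frequencies sum above 1 by {-residual}")
    names = list(names)
    if residual > 1e-9:
        rng = np.random.default_rng(seed)
        top = max(names, key=lambda n: freqs[n])
        base = vecs[top]
        existing = set(vecs.values())
        made = 0
        guard = 0
        while made < n_pseudo and guard < 1000:
            guard += 1
            idx = int(rng.integers(len(sites)))
            options = [a for a in site_alleles[sites[idx]] if a != base[idx]]
            if not options:
                continue
            allele = options[int(rng.integers(len(options)))]
            cand = base[:idx] + (allele,) + base[idx + 1:]
            if cand in existing:
                continue
            made += 1
            name = f"unnamed-{made}"
            names.append(name)
            vecs[name] = cand
            freqs[name] = residual / n_pseudo
            existing.add(cand)
        if made < n_pseudo:  # tiny panels may not offer enough distinct edits
            scale = residual / made if made else 0.0
            for k in range(1, made + 1):
                freqs[f"unnamed-{k}"] = scale
        if made == 0:
            # fall back: renormalize the listed rows
            total = sum(freqs.values())
            freqs = {n: f / total for n, f in freqs.items()}
    return HaplotypeFrequencySet(
        sites=tuple(sites),
        names=tuple(names),
        vectors=vecs,
        frequencies=freqs,
        site_alleles={p: tuple(site_alleles[p]) for p in sites},
    )


@dataclass
class TruthSet:
    """True diplotypes of a simulated cohort."""

    sites: tuple[int, ...]
    samples: tuple[str, ...]
    populations: dict[str, str]
    hap_names: dict[str, tuple[str, str]]
    hap_vectors: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]
    site_alleles: dict[int, tuple[str, ...]]

    def genotype(self, sample: str, site: int) -> tuple[str, str]:
        i = self.sites.index(site)
        h1, h2 = self.hap_vectors[sample]
        return (h1[i], h2[i])


def sample_diplotypes(
    freqs: HaplotypeFrequencySet,
    n_individuals: int,
    seed: int,
    population: str = "POP",
    sample_prefix: str = "S",
) -> TruthSet:
    """Draw diplotypes i.i.d. from haplotype frequencies (random union of gametes)."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    rng = np.random.default_rng(seed)
    names = list(freqs.names)
    p = np.array([freqs.frequencies[n] for n in names])
    draws = rng.choice(len(names), size=(n_individuals, 2), p=p)
    samples = tuple(f"{sample_prefix}{i:05d}" for i in range(n_individuals))
    hap_names = {}
    hap_vectors = {}
    for i, s in enumerate(samples):
        a, b = names[draws[i, 0]], names[draws[i, 1]]
        hap_names[s] = (a, b)
        hap_vectors[s] = (freqs.vectors[a], freqs.vectors[b])
    return TruthSet(
        sites=freqs.sites,
        samples=samples,
        populations={s: population for s in samples},
        hap_names=hap_names,
        hap_vectors=hap_vectors,
        site_alleles=dict(freqs.site_alleles),
    )


def sample_cohort(
    freq_sets: Mapping[str, HaplotypeFrequencySet],
    config: SimulationConfig,
) -> TruthSet:
    """Draw one truth set per population and concatenate them.

    Per-population RNG streams derive from the global seed by fixed
    offsets, so adding a population does not perturb the others.
    """
    parts = []
    for k, (pop, fs) in enumerate(sorted(freq_sets.items())):
        n2 = config.population_sizes.get(pop)
        if n2 is None:
            raise KeyError(f"no population size configured for {pop}")
        parts.append(sample_diplotypes(
            fs, n2 // 2, seed=config.seed + 1000 * (k + 1),
            population=pop, sample_prefix=f"{pop}_"))
    first = parts[0]
    merged = TruthSet(
        sites=first.sites,
        samples=tuple(s for p in parts for s in p.samples),
        populations={s: p.populations[s] for p in parts for s in p.samples},
        hap_names={s: p.hap_names[s] for p in parts for s in p.samples},
        hap_vectors={s: p.hap_vectors[s] for p in parts for s in p.samples},
        site_alleles=dict(first.site_alleles),
    )
    for p in parts[1:]:
        if p.sites != merged.sites:
            raise ValueError("populations simulated over different site panels")
    return merged


def simulate_depths(truth: TruthSet, config: SimulationConfig) -> list[AlleleDepthRecord]:
    """Generate per-sample, per-site allele read counts under the observation model."""
    rng = np.random.default_rng(config.seed + 17)
    records = []
    for s in truth.samples:
        h1, h2 = truth.hap_vectors[s]
        for i, site in enumerate(truth.sites):
            panel = truth.site_alleles[site]
            counts: dict[str, int] = {}
            depth = rng.poisson(config.mean_depth)
            if depth:
                which = rng.integers(2, size=depth)
                for w in which:
                    allele = (h1, h2)[w][i]
                    if config.error_rate and rng.random() < config.error_rate:
                        others = [a for a in panel if a != allele]
                        if others:
                            allele = others[int(rng.integers(len(others)))]
                    counts[allele] = counts.get(allele, 0) + 1
            n_contam = rng.poisson(config.mismap_rate) if config.mismap_rate else 0
            for _ in range(n_contam):
                allele = panel[int(rng.integers(len(panel)))]
                counts[allele] = counts.get(allele, 0) + 1
            records.append(AlleleDepthRecord(site=site, sample=s, counts=counts))
    return records


def evaluate_calls(
    truth: TruthSet,
    calls: GenotypeMatrix,
    phased: Optional[Mapping[str, tuple[Sequence[str], Sequence[str]]]] = None,
) -> dict:
    """Concordance of refined (and optionally phased) calls against truth.

    Genotype concordance is computed over fully-called sites (unordered
    comparison); half calls count as concordant-compatible only through
    the half-call rate, not concordance.  Switch error is measured over
    consecutive unambiguously phased heterozygous site pairs.
    """
    if tuple(calls.sites) != tuple(truth.sites) or tuple(calls.samples) != tuple(truth.samples):
        raise ValueError("truth and calls cover different sample/site panels")
    n_full = n_conc = n_half = n_miss = n_total = 0
    for s in truth.samples:
        for site in truth.sites:
            call = calls.call(s, site)
            n_total += 1
            if call.kind == "missing":
                n_miss += 1
            elif call.kind == "half":
                n_half += 1
            else:
                n_full += 1
                if tuple(sorted(call.alleles)) == tuple(sorted(truth.genotype(s, site))):
                    n_conc += 1
    out = {
        "concordance": n_conc / n_full if n_full else float("nan"),
        "half_call_rate": n_half / n_total,
        "missing_rate": (n_miss + 0.5 * n_half) / n_total,
        "n_sites": len(truth.sites),
        "n_samples": len(truth.samples),
    }
    if phased is not None:
        n_pairs = n_switch = 0
        for s, (p1, p2) in phased.items():
            t1, t2 = truth.hap_vectors[s]
            het_idx = [i for i in range(len(truth.sites))
                       if t1[i] != t2[i] and {p1[i], p2[i]} == {t1[i], t2[i]}]
            orient = [p1[i] == t1[i] for i in het_idx]
            for a, b in zip(orient, orient[1:]):
                n_pairs += 1
                n_switch += a != b
        out["switch_error"] = n_switch / n_pairs if n_pairs else 0.0
    return out


# -- frequency-set constructors ---------------------------------------------

def freqset_from_reference_table(table, seed: int = 0) -> HaplotypeFrequencySet:
    """Frequency set from a regional reference haplotype table (residual expanded)."""
    return expand_residual(
        table.sites, table.names, table.alleles, table.frequencies,
        _panel_alleles(table), seed=seed,
    )


def _panel_alleles(table) -> dict[int, tuple[str, ...]]:
    return {
        p: tuple(sorted({table.alleles[n][i] for n in table.names}))
        for i, p in enumerate(table.sites)
    }


def freqset_from_population_column(
    table, pop_freqs: pd.DataFrame, population: str, seed: int = 0
) -> HaplotypeFrequencySet:
    """Frequency set for one population from a per-population frequency table.

    ``pop_freqs`` rows are haplotype names (an ``others`` row, or implicit
    residual mass, becomes unnamed pseudo-haplotypes).
    """
    col = pop_freqs.set_index("haplotype")[population].astype(float)
    named = {n: f for n, f in col.items() if n in table.names}
    return expand_residual(
        table.sites, list(named), table.alleles, named,
        _panel_alleles(table), seed=seed,
    )
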