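"""Low-coverage genotype refinement from per-allele read depths.

Low-pass sequencing calls are unreliable in two directions: a true
heterozygote may be reported homozygous because the second allele was
never sampled, and miss-mapped or error reads may suggest an allele that
is not there.  The refinement stage converts per-sample, per-site allele
read counts into conservative genotype calls using depth and
read-proportion bands:

* one observed allele: homozygous only with depth >= 7, otherwise missing;
* a minor allele under 5% of reads (possible only at depth >= 20):
  discarded, homozygous major;
* a minor allele at 5-20% of reads: a half call — the major allele plus an
  explicit missing allele, left for the imputation/phasing stage;
* a minor allele above 20%: a clean heterozygote.

Proportions always use the total depth over all observed alleles.  With
three or more observed alleles each non-major allele is banded
independently and the two best-supported surviving alleles form the call,
which handles the triallelic promoter site at -725 (C/T/G).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

MISSING = "."

CALL_KINDS = ("hom", "het", "half", "missing")


@dataclass(frozen=True)
class RefinementConfig:
    """Depth/proportion thresholds of the refinement rules."""

    min_hom_depth: int = 7
    low_prop: float = 0.05
    high_prop: float = 0.20
    high_depth_threshold: int = 20

    def __post_init__(self):
        if not (0 < self.low_prop < self.high_prop < 0.5):
            raise ValueError("need 0 < low_prop < high_prop < 0.5")
        if self.min_hom_depth < 1:
            raise ValueError("min_hom_depth must be >= 1")


@dataclass(frozen=True)
class AlleleDepthRecord:
    """Observed allele read counts for one sample at one site."""

    site: int                       # gene position
    sample: str
    counts: Mapping[str, int]

    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class GenotypeCall:
    kind: str
    allele_a: str = MISSING
    allele_b: str = MISSING
    rule: str = ""

    def __post_init__(self):
        known = [a for a in (self.allele_a, self.allele_b) if a != MISSING]
        ok = {
            "hom": len(known) == 2 and self.allele_a == self.allele_b,
            "het": len(known) == 2 and self.allele_a != self.allele_b,
            "half": len(known) == 1,
            "missing": len(known) == 0,
        }.get(self.kind, False)
        if not ok:
            raise ValueError(f"inconsistent call {self.kind}: {self.allele_a}/{self.allele_b}")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    @property
    def n_missing(self) -> int:
        return (self.allele_a == MISSING) + (self.allele_b == MISSING)


def refine_call(record: AlleleDepthRecord, config: RefinementConfig = RefinementConfig()) -> GenotypeCall:
    """Apply the depth/proportion rules to one allele-depth record."""
    counts = {a: int(c) for a, c in record.counts.items() if c != 0}
    if any(c < 0 for c in counts.values()):
        raise ValueError(f"negative read count in {record.sample}@{record.site}")
    depth = sum(counts.values())
    if depth == 0:
        return GenotypeCall("missing", rule="zero_depth")
    # deterministic support order: count desc, then allele string
    ranked = sorted(counts, key=lambda a: (-counts[a], a))
    major = ranked[0]
    if len(ranked) == 1:
        if depth >= config.min_hom_depth:
            return GenotypeCall("hom", major, major, rule="hom_depth")
        return GenotypeCall("missing", rule="hom_low_depth")
    # band every non-major allele independently on its share of total depth
    supported = [major]
    uncertain = []
    for allele in ranked[1:]:
        prop = counts[allele] / depth
        if prop < config.low_prop:
            # only reachable at high depth; below it a single read already
            # exceeds the 5% band
            if depth >= config.high_depth_threshold:
                continue  # treated as miss-mapping / error noise
            uncertain.append(allele)
        elif prop <= config.high_prop:
            uncertain.append(allele)
        else:
            supported.append(allele)
    if len(supported) >= 2:
        a, b = sorted(supported[:2])
        return GenotypeCall("het", a, b, rule="het_high_prop")
    if uncertain:
        return GenotypeCall("half", major, MISSING, rule="half_mid_prop")
    return GenotypeCall("hom", major, major, rule="hom_low_minor")


@dataclass
class GenotypeMatrix:
    """Refined genotype calls for a shared site panel.

    ``calls[sample][site]`` is a :class:`GenotypeCall`; all samples share
    the ordered site panel.  Population labels are carried for the
    population-genetics stages.
    """

    sites: tuple[int, ...]
    samples: tuple[str, ...]
    calls: dict[str, dict[int, GenotypeCall]]
    populations: dict[str, str] = field(default_factory=dict)
    site_alleles: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for s in self.samples:
            missing_sites = set(self.sites) - set(self.calls.get(s, {}))
            if missing_sites:
                raise ValueError(f"sample {s} lacks calls at {sorted(missing_sites)[:3]}...")

    def call(self, sample: str, site: int) -> GenotypeCall:
        return self.calls[sample][site]

    def subset_sites(self, keep: Iterable[int]) -> "GenotypeMatrix":
        keep = tuple(k for k in self.sites if k in set(keep))
        return GenotypeMatrix(
            sites=keep,
            samples=self.samples,
            calls={s: {p: self.calls[s][p] for p in keep} for s in self.samples},
            populations=dict(self.populations),
            site_alleles={p: a for p, a in self.site_alleles.items() if p in set(keep)},
        )


def refine_matrix(
    records: Iterable[AlleleDepthRecord],
    sites: Iterable[int],
    samples: Iterable[str],
    config: RefinementConfig = RefinementConfig(),
    populations: Optional[Mapping[str, str]] = None,
    site_alleles: Optional[Mapping[int, tuple[str, ...]]] = None,
) -> GenotypeMatrix:
    """Refine a stream of allele-depth records into a genotype matrix.

    Sites with no record for a sample are coded missing.
    """
    sites = tuple(sites)
    samples = tuple(samples)
    calls: dict[str, dict[int, GenotypeCall]] = {
        s: {p: GenotypeCall("missing", rule="no_record") for p in sites} for s in samples
    }
    for rec in records:
        calls[rec.sample][rec.site] = refine_call(rec, config)
    return GenotypeMatrix(
        sites=sites,
        samples=samples,
        calls=calls,
        populations=dict(populations or {}),
        site_alleles=dict(site_alleles or {}),
    )


def apply_site_filters(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop sites monomorphic after refinement and singleton sites.

    A singleton site is one whose minor allele occurs exactly once among
    the non-missing called alleles.  Returns the filtered matrix and a
    report of removed sites with reasons.
    """
    removed = []
    keep = []
    for site in matrix.sites:
        tally: dict[str, int] = {}
        for s in matrix.samples:
            for a in matrix.call(s, site).alleles:
                if a != MISSING:
                    tally[a] = tally.get(a, 0) + 1
        if len(tally) <= 1:
            removed.append({"site": site, "reason": "monomorphic"})
            continue
        # variable only if at least two alleles are each seen more than once;
        # otherwise every non-major allele is a singleton and the site drops
        n_recurrent = sum(1 for c in tally.values() if c > 1)
        if n_recurrent < 2:
            removed.append({"site": site, "reason": "singleton"})
            continue
        keep.append(site)
    report = pd.DataFrame(removed, columns=["site", "reason"])
    return matrix.subset_sites(keep), report


def missing_rate(matrix: GenotypeMatrix) -> dict:
    """Fraction of allele slots coded missing: overall, per site, per sample."""
    per_site = {}
    per_sample = {s: 0 for s in matrix.samples}
    total_missing = 0
    for site in matrix.sites:
        m = 0
        for s in matrix.samples:
            nm = matrix.call(s, site).n_missing
            m += nm
            per_sample[s] += nm
        per_site[site] = m / (2 * len(matrix.samples))
        total_missing += m
    n_slots = 2 * len(matrix.samples) * len(matrix.sites)
    return {
        "overall": total_missing / n_slots if n_slots else 0.0,
        "per_site": per_site,
        "per_sample": {s: v / (2 * len(matrix.sites)) if matrix.sites else 0.0
                       for s, v in per_sample.items()},
    }
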