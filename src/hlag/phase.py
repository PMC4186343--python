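"""Haplotype phasing and missing-allele imputation by EM with partition-ligation.

Haplotype frequencies are estimated by the classical gene-counting EM
(Excoffier-Slatkin): each sample's genotype — including half calls and
missing alleles — is expanded into the set of unordered haplotype pairs
consistent with it, and EM alternates posterior pair weights with
frequency updates, which monotonically increases the observed-data
log-likelihood.  Windows of a few sites keep the haplotype space
enumerable; adjacent windows are then ligated by re-running EM over the
cross-product of each window's retained haplotypes (partition-ligation),
which scales the estimator to the full 133-site panel.  The best pair per
sample imputes its missing alleles and carries a posterior probability.

The estimator is exposed statsmodels-style: :class:`EMPhasingModel` is
built from a genotype matrix and ``fit()`` returns a
:class:`PhasingResults` with the frequency pool, per-sample assignments,
log-likelihood and summary table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .refine import MISSING, GenotypeMatrix

Hap = tuple[str, ...]
Pair = tuple[Hap, Hap]

#: Hard cap on per-sample pair expansions inside one window.
MAX_EXPANSIONS = 65536


class PhasingError(ValueError):
    pass


def _site_pairs(call, alleles: Sequence[str]) -> list[tuple[str, str]]:
    """Unordered allele pairs consistent with one genotype call."""
    if call.kind == "hom":
        return [(call.allele_a, call.allele_a)]
    if call.kind == "het":
        a, b = sorted((call.allele_a, call.allele_b))
        return [(a, b)]
    if call.kind == "half":
        known = call.allele_a if call.allele_a != MISSING else call.allele_b
        return [tuple(sorted((known, x))) for x in alleles]
    return [tuple(sorted(p)) for p in itertools.combinations_with_replacement(alleles, 2)]


def _expand_sample(matrix: GenotypeMatrix, sample: str, sites: Sequence[int],
                   site_alleles: dict[int, Sequence[str]],
                   cap: int = MAX_EXPANSIONS) -> list[Pair]:
    """Unordered haplotype pairs consistent with one sample's genotypes.

    Samples with many missing alleles can expand combinatorially; beyond
    ``cap`` partial expansions the enumeration is truncated
    deterministically (missing-site completions are ordered with the
    site's first-listed alleles first), which bounds memory at the cost of
    exhaustiveness for near-empty samples.
    """
    partial: list[tuple[Hap, Hap]] = [((), ())]
    for site in sites:
        call = matrix.call(sample, site)
        options = _site_pairs(call, site_alleles[site])
        nxt: list[tuple[Hap, Hap]] = []
        for h1, h2 in partial:
            for x, y in options:
                nxt.append((h1 + (x,), h2 + (y,)))
                if x != y:
                    nxt.append((h1 + (y,), h2 + (x,)))
            if len(nxt) > cap:
                break
        partial = nxt[:cap]
    return sorted({tuple(sorted((h1, h2))) for h1, h2 in partial})


@dataclass
class HaplotypePool:
    """Estimated haplotype frequencies over an ordered site list."""

    sites: tuple[int, ...]
    frequencies: dict[Hap, float]
    loglike: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    provenance: str = ""

    def __post_init__(self):
        total = sum(self.frequencies.values())
        if self.frequencies and abs(total - 1.0) > 1e-8:
            raise PhasingError(f"pool frequencies sum to {total}")

    def top(self, k: int) -> list[Hap]:
        return sorted(self.frequencies, key=lambda h: (-self.frequencies[h], h))[:k]


def _em(
    sample_pairs: dict[str, list[Pair]],
    tol: float,
    max_iter: int,
    rng: Optional[np.random.Generator],
    prune_floor: float,
    assert_monotone: bool = False,
) -> tuple[dict[Hap, float], float, int, bool]:
    """Gene-counting EM over enumerated per-sample pair expansions."""
    haps = sorted({h for pairs in sample_pairs.values() for pair in pairs for h in pair})
    if not haps:
        raise PhasingError("no haplotypes to estimate")
    hidx = {h: i for i, h in enumerate(haps)}
    i1, i2, mult, seg_len = [], [], [], []
    for pairs in sample_pairs.values():
        if not pairs:
            raise PhasingError("sample with no consistent pair expansion")
        seg_len.append(len(pairs))
        for h1, h2 in pairs:
            i1.append(hidx[h1])
            i2.append(hidx[h2])
            mult.append(2.0 if h1 != h2 else 1.0)
    i1 = np.asarray(i1)
    i2 = np.asarray(i2)
    mult = np.asarray(mult)
    seg_len = np.asarray(seg_len)
    starts = np.concatenate([[0], np.cumsum(seg_len)[:-1]])

    if rng is None:
        f = np.full(len(haps), 1.0 / len(haps))
    else:
        f = rng.random(len(haps)) + 0.1
        f /= f.sum()
    n_chrom = 2 * len(sample_pairs)
    prev_ll = -math.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        w = f[i1] * f[i2] * mult
        tots = np.add.reduceat(w, starts)
        # samples whose candidate pairs are all at zero frequency fall back
        # to uniform responsibility
        dead = tots <= 0.0
        if dead.any():
            dead_mask = np.repeat(dead, seg_len)
            w[dead_mask] = 1.0
            tots = np.where(dead, seg_len.astype(float), tots)
        ll = float(np.log(tots).sum())
        if assert_monotone and ll < prev_ll - 1e-9:
            raise PhasingError(f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        share = w / np.repeat(tots, seg_len)
        counts = (np.bincount(i1, weights=share, minlength=len(haps))
                  + np.bincount(i2, weights=share, minlength=len(haps)))
        f = counts / n_chrom
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    fdict = {h: float(v) for h, v in zip(haps, f)}
    if prune_floor > 0:
        fdict = {h: v for h, v in fdict.items() if v >= prune_floor}
        total = sum(fdict.values())
        if total <= 0:
            raise PhasingError("prune floor removed every haplotype")
        fdict = {h: v / total for h, v in fdict.items()}
    return fdict, prev_ll, n_iter, converged


def em_frequencies(
    matrix: GenotypeMatrix,
    sites: Optional[Sequence[int]] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: Optional[int] = None,
    restarts: int = 1,
    prune_floor: Optional[float] = None,
    assert_monotone: bool = False,
) -> HaplotypePool:
    """EM haplotype-frequency estimate over one enumerable window.

    ``seed`` draws random restarts in addition to the uniform start; the
    best log-likelihood wins.  The default prune floor is one tenth of a
    chromosome's worth of frequency, ``1 / (10 * 2N)``.
    """
    sites = tuple(sites if sites is not None else matrix.sites)
    alleles = _window_alleles(matrix, sites)
    sample_pairs = {s: _expand_sample(matrix, s, sites, alleles) for s in matrix.samples}
    if prune_floor is None:
        prune_floor = 1.0 / (10 * 2 * len(matrix.samples))
    best = None
    starts: list[Optional[np.random.Generator]] = [None]
    if seed is not None and restarts > 1:
        starts += [np.random.default_rng(seed + k) for k in range(restarts - 1)]
    for rng in starts:
        f, ll, n_iter, conv = _em(sample_pairs, tol, max_iter, rng, prune_floor,
                                  assert_monotone=assert_monotone)
        if best is None or ll > best[1]:
            best = (f, ll, n_iter, conv)
    f, ll, n_iter, conv = best
    return HaplotypePool(sites=sites, frequencies=f, loglike=ll, n_iter=n_iter,
                         converged=conv, provenance=f"em[{sites[0]}..{sites[-1]}]")


def _window_alleles(matrix: GenotypeMatrix, sites: Sequence[int]) -> dict[int, tuple[str, ...]]:
    alleles = {}
    for site in sites:
        known = set(matrix.site_alleles.get(site, ()))
        for s in matrix.samples:
            for a in matrix.call(s, site).alleles:
                if a != MISSING:
                    known.add(a)
        if not known:
            raise PhasingError(f"site {site}: no observed allele in any sample")
        alleles[site] = tuple(sorted(known))
    return alleles


@dataclass(frozen=True)
class DiplotypeAssignment:
    sample: str
    haplotypes: Pair
    posterior: float
    imputed_sites: tuple[int, ...]
    fallback: bool = False


@dataclass
class PhasingResults:
    """Fitted phasing estimate: frequency pool plus per-sample assignments."""

    pool: HaplotypePool
    assignments: dict[str, DiplotypeAssignment]
    window_trace: list[str] = field(default_factory=list)

    @property
    def loglike(self) -> float:
        return self.pool.loglike

    def phasing_summary(self) -> tuple[float, float, int]:
        """(mean best-pair posterior, fraction with posterior > 0.9, haplotype count)."""
        if not self.assignments:
            raise PhasingError("no assignments")
        post = [a.posterior for a in self.assignments.values()]
        return (
            float(np.mean(post)),
            float(np.mean([p > 0.9 for p in post])),
            len(self.pool.frequencies),
        )

    def haplotype_table(self) -> pd.DataFrame:
        rows = [{"haplotype": "|".join(h), "frequency": f}
                for h, f in sorted(self.pool.frequencies.items(),
                                   key=lambda kv: -kv[1])]
        return pd.DataFrame(rows)

    def assignment_table(self) -> pd.DataFrame:
        rows = []
        for a in self.assignments.values():
            rows.append({
                "sample": a.sample,
                "hap1": "|".join(a.haplotypes[0]),
                "hap2": "|".join(a.haplotypes[1]),
                "posterior": a.posterior,
                "n_imputed": len(a.imputed_sites),
                "fallback": a.fallback,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        mean_post, frac_hi, n_hap = self.phasing_summary()
        lines = [
            "EM partition-ligation phasing",
            "=" * 34,
            f"samples:               {len(self.assignments)}",
            f"sites:                 {len(self.pool.sites)}",
            f"haplotypes in pool:    {n_hap}",
            f"log-likelihood:        {self.pool.loglike:.4f}",
            f"mean pair posterior:   {mean_post:.4f}",
            f"posterior > 0.9:       {100 * frac_hi:.2f}%",
        ]
        return "\n".join(lines)


class EMPhasingModel:
    """Haplotype-frequency model for a refined genotype matrix.

    Parameters
    ----------
    matrix : GenotypeMatrix
        Refined calls sharing a site panel (half calls and missing alleles
        are handled by summing over completions).
    window_size : int
        Sites per partition window (must keep the expansion enumerable).
    ligation_keep : int
        Haplotypes retained per block when ligating adjacent windows.
    restarts : int
        Random EM restarts (in addition to the uniform start) per block.
    """

    def __init__(self, matrix: GenotypeMatrix, window_size: int = 8,
                 ligation_keep: int = 50, restarts: int = 3, seed: int = 0,
                 tol: float = 1e-6, max_iter: int = 500, pair_beam: int = 64,
                 expansion_cap: int = 4096):
        if window_size < 1:
            raise PhasingError("window_size must be >= 1")
        self.expansion_cap = expansion_cap
        self.matrix = matrix
        self.window_size = window_size
        self.ligation_keep = ligation_keep
        self.restarts = restarts
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter
        # per-sample cap on candidate pairs carried between ligation levels;
        # keeps samples with many missing alleles from exploding the
        # cross-product (a beam over the current pair posterior)
        self.pair_beam = pair_beam

    def fit(self) -> PhasingResults:
        matrix = self.matrix
        sites = tuple(matrix.sites)
        alleles = _window_alleles(matrix, sites)
        prune_floor = 1.0 / (10 * 2 * len(matrix.samples))
        windows = [sites[i:i + self.window_size]
                   for i in range(0, len(sites), self.window_size)]
        trace = []

        # per-window EM
        blocks: list[tuple[tuple[int, ...], dict[str, list[Pair]], dict[Hap, float]]] = []
        for w_idx, w_sites in enumerate(windows):
            pairs = {s: _expand_sample(matrix, s, w_sites, alleles,
                                       cap=self.expansion_cap)
                     for s in matrix.samples}
            f, ll, n_iter, conv = self._best_em(pairs, prune_floor, self.seed + w_idx)
            trace.append(f"window {w_sites[0]}..{w_sites[-1]}: "
                         f"{len(f)} haplotypes, ll={ll:.3f}, iter={n_iter}")
            blocks.append((tuple(w_sites), self._restrict(pairs, f), f))

        # hierarchical ligation of adjacent blocks
        level = 0
        while len(blocks) > 1:
            level += 1
            merged = []
            for k in range(0, len(blocks) - 1, 2):
                merged.append(self._ligate(blocks[k], blocks[k + 1], prune_floor,
                                           self.seed + 100 * level + k, trace))
            if len(blocks) % 2:
                merged.append(blocks[-1])
            blocks = merged

        w_sites, sample_pairs, f = blocks[0]
        f, ll, n_iter, conv = self._best_em(sample_pairs, prune_floor, self.seed + 9999,
                                            final=True)
        pool = HaplotypePool(sites=w_sites, frequencies=f, loglike=ll, n_iter=n_iter,
                             converged=conv, provenance="partition-ligation")
        assignments = self._assign(sample_pairs, f)
        return PhasingResults(pool=pool, assignments=assignments, window_trace=trace)

    # -- internals -----------------------------------------------------------
    def _best_em(self, sample_pairs, prune_floor, seed, final=False):
        best = None
        starts: list[Optional[np.random.Generator]] = [None]
        if self.restarts > 1:
            starts += [np.random.default_rng(seed + 31 * k) for k in range(self.restarts - 1)]
        for rng in starts:
            out = _em(sample_pairs, self.tol, self.max_iter, rng,
                      prune_floor if not final else prune_floor)
            if best is None or out[1] > best[1]:
                best = out
        return best

    def _pair_weight(self, pair: Pair, f: dict[Hap, float]) -> float:
        w = f.get(pair[0], 0.0) * f.get(pair[1], 0.0)
        return w * 2.0 if pair[0] != pair[1] else w

    def _restrict(self, sample_pairs: dict[str, list[Pair]], f: dict[Hap, float]):
        keep = set(sorted(f, key=lambda h: (-f[h], h))[: self.ligation_keep])
        out = {}
        for s, pairs in sample_pairs.items():
            kept = [p for p in pairs if p[0] in keep and p[1] in keep]
            if not kept:
                kept = pairs  # inconsistent sample: keep full expansion
            if len(kept) > self.pair_beam:
                kept = sorted(kept, key=lambda p: (-self._pair_weight(p, f), p)
                              )[: self.pair_beam]
            out[s] = sorted(kept)
        return out

    def _ligate(self, left, right, prune_floor, seed, trace):
        l_sites, l_pairs, f_l = left
        r_sites, r_pairs, f_r = right
        sample_pairs: dict[str, list[Pair]] = {}
        for s in self.matrix.samples:
            combos: dict[Pair, float] = {}
            for lp in l_pairs[s]:
                wl = max(self._pair_weight(lp, f_l), 1e-300)
                l1, l2 = lp
                for rp in r_pairs[s]:
                    w = wl * max(self._pair_weight(rp, f_r), 1e-300)
                    r1, r2 = rp
                    for cand in (tuple(sorted((l1 + r1, l2 + r2))),
                                 tuple(sorted((l1 + r2, l2 + r1)))):
                        if w > combos.get(cand, -1.0):
                            combos[cand] = w
            ranked = sorted(combos, key=lambda p: (-combos[p], p))
            sample_pairs[s] = sorted(ranked[: self.pair_beam])
        f, ll, n_iter, conv = self._best_em(sample_pairs, prune_floor, seed)
        trace.append(f"ligate {l_sites[0]}..{r_sites[-1]}: "
                     f"{len(f)} haplotypes, ll={ll:.3f}, iter={n_iter}")
        sites = l_sites + r_sites
        return (sites, self._restrict(sample_pairs, f), f)

    def _assign(self, sample_pairs, f) -> dict[str, DiplotypeAssignment]:
        floor = min(f.values()) * 1e-3 if f else 1e-12
        assignments = {}
        for s in self.matrix.samples:
            pairs = sample_pairs[s]
            weights = []
            fallback = False
            for h1, h2 in pairs:
                p = f.get(h1, 0.0) * f.get(h2, 0.0) * (2.0 if h1 != h2 else 1.0)
                weights.append(p)
            tot = sum(weights)
            if tot <= 0.0:
                # no retained-pool pair fits: per-sample ML completion with a
                # floor frequency for unseen haplotypes
                fallback = True
                weights = [max(f.get(h1, floor), floor) * max(f.get(h2, floor), floor)
                           * (2.0 if h1 != h2 else 1.0) for h1, h2 in pairs]
                tot = sum(weights)
            best_i = int(np.argmax(weights))
            imputed = tuple(
                site for site in self.matrix.sites
                if self.matrix.call(s, site).n_missing > 0
            )
            assignments[s] = DiplotypeAssignment(
                sample=s,
                haplotypes=pairs[best_i],
                posterior=weights[best_i] / tot,
                imputed_sites=imputed,
                fallback=fallback,
            )
        return assignments


def partition_ligation_phase(
    matrix: GenotypeMatrix, window_size: int = 8, seed: int = 0, **kwargs
) -> tuple[HaplotypePool, dict[str, DiplotypeAssignment]]:
    """Functional wrapper around :class:`EMPhasingModel`."""
    res = EMPhasingModel(matrix, window_size=window_size, seed=seed, **kwargs).fit()
    return res.pool, res.assignments


def phasing_summary(assignments: dict[str, DiplotypeAssignment],
                    pool: Optional[HaplotypePool] = None) -> tuple[float, float, int]:
    """(mean posterior, fraction posterior > 0.9, haplotype count)."""
    if not assignments:
        raise PhasingError("no assignments")
    post = [a.posterior for a in assignments.values()]
    n_hap = len(pool.frequencies) if pool is not None else len(
        {h for a in assignments.values() for h in a.haplotypes})
    return float(np.mean(post)), float(np.mean([p > 0.9 for p in post])), n_hap


def pool_from_assignments(assignments: dict[str, DiplotypeAssignment],
                          sites: Sequence[int]) -> HaplotypePool:
    """Haplotype frequencies by direct counting of best-pair assignments."""
    counts: dict[Hap, float] = {}
    for a in assignments.values():
        for h in a.haplotypes:
            counts[h] = counts.get(h, 0.0) + 1.0
    n = sum(counts.values())
    return HaplotypePool(sites=tuple(sites),
                         frequencies={h: c / n for h, c in counts.items()},
                         loglike=float("nan"), provenance="direct-counting")


def extract_region(pool: HaplotypePool, site_list: Sequence[int]) -> HaplotypePool:
    """Project a haplotype pool onto an ordered sub-list of its sites.

    Haplotypes with identical projections merge and their frequencies add.
    """
    idx = []
    for site in site_list:
        if site not in pool.sites:
            raise KeyError(f"site {site} not in pool panel")
        idx.append(pool.sites.index(site))
    out: dict[Hap, float] = {}
    for hap, freq in pool.frequencies.items():
        proj = tuple(hap[i] for i in idx)
        out[proj] = out.get(proj, 0.0) + freq
    return HaplotypePool(sites=tuple(site_list), frequencies=out,
                         loglike=float("nan"), provenance=f"{pool.provenance}|region")
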