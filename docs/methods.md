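# Methods

## The locus model

HLA-G spans 4144 nt over 15 exon/intron segments on chromosome 6. The
package anchors all gene-relative coordinates at the first base of the CDS
(position +1); upstream positions are negative and position 0 does not
exist. Exon 1 and the first 112 nt of exon 2 form the 178-nt 5'UTR; exon 2
contributes 73 coding nt, exons 3–6 their full lengths and exon 7 the
final 5 nt (stop codon at +2536..+2538) of the 1017-nt CDS; the remainder
of exon 7 plus exon 8 form the 383-nt 3'UTR. These partitions are asserted
at model construction and the build fails loudly if the bundled constants
drift.

Two conventions deserve explicit note:

* **The 14-bp indel and hg19.** The ancestral 3'UTR allele carries a 14-bp
  insertion (rs371194629) that hg19 lacks. Gene positions are counted on
  the insertion-bearing scale, so positions beyond +2960 map to hg19
  coordinates offset by −14, and positions +2961..+2974 have no hg19
  coordinate at all. The bundled site tables (133 gene/hg19 coordinate
  pairs) validate this mapping exhaustively in the tests.
* **Mature-protein codons.** HLA proteins are numbered after cleavage of
  the 24-residue leader peptide; the model reports both the CDS codon and
  the mature codon (CDS codon − 24). The exon-2 coding length (73 nt) and
  the leader length are not independently tabulated anywhere; they are
  pinned by the codon anchors +292→31, +755→110 and +1799→258, which the
  tests assert.

Effect classification uses a 2-nt splice window at each intron end (the
canonical GT/AG dinucleotides); this window reproduces the single
annotated splice-acceptor site at +201. In coding exons an indel with a
length difference not divisible by three is a frameshift; substitutions
are resolved against a user-supplied 1017-nt CDS sequence and degrade to
`indeterminate` without one (no failure).

## Genotype refinement

Rules operate per sample × site on allele read counts, with proportions
taken over total depth:

| observation | call |
|---|---|
| one allele, depth ≥ 7 | homozygote |
| one allele, depth < 7 | missing |
| minor < 5 % (only possible at depth ≥ 20) | homozygote for the major |
| minor in [5 %, 20 %] | half call (major + missing allele) |
| minor > 20 % | heterozygote |

Boundary handling is a literal reading of the rule wording: "under 5 %" is
strict, the middle band inclusive on both ends, "higher than 20 %" strict.
With integer counts the sub-5 % band is unreachable below depth 20 (one
read at depth 19 is already 5.3 %), so the high-depth condition of the
second rule is never vacuously violated — a property the tests assert.
With three or more observed alleles each non-major allele is banded
independently and the two best-supported surviving alleles form the call;
ties break by count then allele string. Zero depth is missing, not an
error. After refinement, sites that became monomorphic and sites whose
minor allele survives exactly once (singletons) are removed, with a
reported reason per site.

## Phasing by EM with partition–ligation

The coalescent-based phasing used in the original workflow is replaced by
a deliberately simpler, dependency-free estimator: the Excoffier–Slatkin
gene-counting EM. Each sample's genotypes over a window (default 8 sites)
expand into the set of unordered haplotype pairs consistent with its
calls — half calls and missing alleles enumerate all completions over the
site's allele dictionary. EM weights each pair by `f(h1)f(h2)` (doubled
for heterozygous pairs) and re-estimates frequencies from expected counts;
the observed-data log-likelihood is non-decreasing per iteration (asserted
in tests). Frequencies below the prune floor `1/(10·2N)` are dropped and
the pool renormalised. Random restarts (default 3, seeded) guard against
local optima.

Adjacent windows are ligated by re-running EM over candidate
concatenations of each window's retained haplotypes (top 50 per block).
Two bounds keep the procedure desk-scale: a per-sample beam keeps the 64
most probable candidate pairs between ligation levels, and the raw
genotype expansion of a near-empty sample is truncated deterministically
at 4096 partial expansions. Both are approximations only for samples with
very many missing alleles; a sample whose retained pairs all conflict with
its genotypes falls back to a maximum-likelihood completion and is
flagged. Partition–ligation is itself a heuristic: on ambiguous data a
split fit can settle in a marginally different local optimum than a
single-window fit, which is why the window-invariance test uses an
identifiable toy panel.

The best pair per sample is the argmax of `f(h1)f(h2)` (×2 if
heterozygous) over its consistent pairs; its normalised weight is the
reported pair posterior, and missing alleles are imputed from it. Summary
metrics (mean pair posterior, fraction above 0.9, haplotype count) mirror
the quality measures conventionally reported for this kind of inference;
they are data-dependent and not matched to any published value.

## Nomenclature

Reference haplotypes for each region ship as package data: 9 named 3'UTR
haplotypes over 9 sites, 11 coding alleles over 51 sites, 10 promoter
haplotypes over 27 sites (including +15, which the promoter naming system
lists even though it is a coding-region site — region definitions for
naming are the tables' site lists, not coordinate cuts), and 24 extended
haplotypes linking the three names with an HLA-G lineage. Indel alleles
are stored as full allele strings (`G` vs `GATTTGTTCATGCCT`), so loaders
need no display conventions like Ins/Del.

Classification is by Hamming distance over sites (an indel counts as one
site here, unlike the diversity weighting): exact match takes the
reference name; a unique distance-1 neighbour takes the name with the
`-Like` suffix; distance-1 ties break by higher reference global
frequency, then name order, with the tie recorded; anything else is `new`
with a deterministic region-prefixed ordinal. Extended labels join the
three regional names (`G010101a/G*01:01:01:01/UTR-1`); lineages resolve
only for triples present in the extended table, accepting the
family-prefix aliases (`0104a` ↔ `010104a`) used there.

A few extended-table components (`0103c`, `G*01:01:01:06`, `G*01:01:09`,
`UTR-13`, the `-Like` and unknown rows) have no printed allele vector.
Their full-panel vectors are synthetic stand-ins — one deterministic edit
away from the closest listed relative — flagged in the `synthetic` column,
so simulations from the extended table keep the full frequency mass while
the genuinely known rows remain authoritative.

## Synthetic cohorts

The generator draws diplotypes by random union of gametes from a bundled
frequency table (worldwide or per population; the fourteen cohort sizes,
2n = 28…200, are the defaults) and then simulates, per sample × site:
Poisson(λ) reads copying one of the two true alleles each, per-read
corruption to a uniformly random other panel allele with probability ε,
and Poisson(ρ) contaminant reads with a random panel allele. Defaults are
λ = 4 reads/site (the low-coverage regime the refinement rules were
designed for), ε = 0.005 and ρ = 0.1 — plausible magnitudes for low-pass
data chosen once for the default conditions; the original study states no
error or contamination rates, so no claim of numerical correspondence is
made, and the tests sweep these parameters instead. Residual "others"
frequency mass becomes unnamed pseudo-haplotypes one random edit from the
most frequent haplotype, exercising the `new` naming path. Corruption
stays inside the panel allele space because refinement operates on called
alternates, not raw base space; read position, base quality and mapping
quality are not modelled. Passing recovery tests therefore shows
correctness of the inference chain under this observation model, not
performance on real reads.

One RNG stream per run is derived from the seed; per-population streams
use fixed offsets, so runs are reproducible and populations independent.

Note that at the 4× default most homozygous sites fail the seven-read
homozygosity rule, so missing-allele rates are high (~2/3 of allele slots)
and the burden shifts to EM imputation — an intentionally harsh stress of
the full chain. Real low-coverage studies mix in exome reads and achieve
far lower missingness; the recovery benchmarks use 30× with no error,
where refinement is essentially lossless.

## Population genetics

All statistics treat haplotypes as alleles of a single locus.

* **Diversity.** Unbiased heterozygosity `(2n/(2n−1))(1 − Σp²)` serves
  both gene diversity (averaged over variation sites, ± sd across sites)
  and haplotype diversity (± Nei's sampling sd). Nucleotide diversity uses
  the frequency form `k = (2n/(2n−1))·Σ_s w_s(1 − Σp²)`, proven equal to
  the frequency-weighted pairwise weighted Hamming distance by a
  brute-force oracle in the tests; π% = 100·k/L. The 14-bp indel carries
  weight 14 — the one weighting that reproduces the worldwide 3'UTR mean
  pairwise difference of 8.19 from the bundled per-site frequencies — and
  the 3'UTR analysed length is 286 bp (+2942..+3227 on the
  insertion-bearing scale). The reported sd of π uses Tajima's total
  variance; it is a convention, not a fitted quantity.
* **HWE.** The Guo–Thompson Markov chain on diplotype count tables with
  fixed allele counts, with the classical two-individual switch proposal
  and an explicit Metropolis–Hastings correction for proposal asymmetry.
  The p-value is the visited-state mass with conditional probability not
  exceeding the observed table's; the standard error is batch-means
  (autocorrelation-aware). Defaults: 100 000 steps after 10 000
  dememorisation. Monomorphic samples report p = 1 with a warning.
* **Differentiation.** Pairwise F_ST is the two-population AMOVA θ on
  haplotype identity distance (pure frequency form; no molecular distance
  between haplotypes), with p-values from permuting chromosomes between
  the pair (observed assignment included in the numerator and
  denominator). Small negative θ estimates are kept. Reynolds distance is
  −ln(1 − θ) with θ clamped to [0, 1). The exact test of differentiation
  enumerates all tables with the observed margins when the state space is
  small (exact p, zero se) and otherwise runs a Metropolis chain over 2×2
  diamond moves; the criterion is the probability mass of tables no more
  probable than the observed one, matching the Fisher exact test on 2×2
  tables to machine precision.
* **AMOVA.** Two- or three-level sums of squares on identity distance with
  the standard variance-component coefficient equations; percentages are
  components over their total (negative components can push the within
  percentage slightly above 100, as is conventional). P-values use the
  three standard permutation schemes: whole populations among groups
  (F_CT), chromosomes among populations within groups (F_SC), chromosomes
  among all populations (F_ST). When every group holds one population the
  middle level is degenerate and its component is zero. With a single
  group the two-level result is returned and F_CT reported absent.
* **Multiple testing and ordination.** Bonferroni α/m (the 14 populations
  give C(14,2) = 91 pairwise comparisons, hence the conventional reported
  threshold 0.0005); classical (Torgerson) MDS by double-centering, with
  negative eigenvalues clipped under a warning and coordinates centred.

## Pipeline defaults and problem sizes

The `hlag run` default executes the full chain on the 3'UTR panel (9
sites), the most informative region per base pair, which keeps a
full-cohort run (1076 individuals) desk-scale; any region is selectable.
Orchestrated runs default to 200 permutations and 20 000-step chains, and
the test suite uses cohorts of 40–500 individuals with 20–99 permutations
and 2 000–60 000-step chains — sizes chosen so the whole suite exercises
every stage, including 1000-chromosome frequency-recovery at depth 30,
in well under a minute per test. Standalone statistical functions default
to the larger conventional values (10⁴ permutations, 10⁵-step chains).

## Known limitations

* Phasing is frequency-based EM, not coalescent-aware: no recombination
  model, no reference-panel imputation, and published pair-posterior
  summaries from coalescent software are not numerically matched.
* Gene-diversity *totals* over pooled worldwide samples depend on an
  averaging convention of the original analysis software that is not
  reproduced here; per-site and haplotype-level quantities are exact.
* The effect annotator handles a single locus and single-nucleotide
  substitutions plus simple indels; multi-nucleotide substitutions return
  `indeterminate`, and the seven alternative-splicing isoforms are
  documented but not modelled.
* Read-level artefacts (mapping quality, duplicates, reference bias) are
  upstream of this pipeline and out of scope.
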