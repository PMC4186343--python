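"""End-to-end orchestration: simulate -> refine -> phase -> name -> stats.

A run takes a :class:`RunConfig`, executes the enabled stages in order on
one regional panel, writes every artifact with a checksum into the output
directory, and records a manifest (parameters, seeds, artifact digests) so
that a rerun with the same configuration reproduces byte-identical
stochastic outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import io as hio
from .nomenclature import HaplotypeNamer
from .phase import EMPhasingModel
from .popgen import (
    FrequencyTable, WeightScheme, amova, bonferroni, classical_mds,
    differentiation_matrix, diversity_report, hwe_exact_test, pairwise_fst,
    reynolds_distance,
)
from .refine import RefinementConfig, apply_site_filters, missing_rate, refine_matrix
from .simulate import (
    SimulationConfig, evaluate_calls, freqset_from_population_column,
    sample_cohort, simulate_depths,
)
from .tables import load_reference_tables
from .gene_model import data_path

#: Default group membership of the fourteen cohort populations.
DEFAULT_GROUPS = {
    "CEU": "Europe", "TSI": "Europe", "GBR": "Europe", "FIN": "Europe", "IBS": "Europe",
    "CHB": "Asia", "CHS": "Asia", "JPT": "Asia",
    "YRI": "Africa", "LWK": "Africa",
    "ASW": "Admixed", "MXL": "Admixed", "PUR": "Admixed", "CLM": "Admixed",
}

#: 14-bp indel site and 3'UTR analyzed length for nucleotide diversity.
UTR3_WEIGHTS = WeightScheme(weights={2960: 14.0}, region_length=286.0)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "hlag_run"
    seed: int = 1
    region: str = "utr3"                  # promoter | coding | utr3
    populations: Optional[list[str]] = None
    stages: tuple[str, ...] = ("simulate", "refine", "phase", "name", "stats")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    window_size: int = 8
    restarts: int = 2
    permutations: int = 200
    hwe_chain: int = 20_000
    hwe_dememorization: int = 2_000
    groups: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))

    def validate(self) -> None:
        order = ("simulate", "refine", "phase", "name", "stats")
        enabled = [s for s in order if s in self.stages]
        unknown = set(self.stages) - set(order)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        needs = {"refine": "simulate", "phase": "refine", "name": "phase", "stats": "name"}
        for stage, dep in needs.items():
            if stage in enabled and dep not in enabled:
                raise ConfigError(f"stage '{stage}' requires stage '{dep}'")
        if self.region not in ("promoter", "coding", "utr3"):
            raise ConfigError(f"unknown region {self.region!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        ref = RefinementConfig(**raw.pop("refinement", {}))
        stages = tuple(raw.pop("stages", ("simulate", "refine", "phase", "name", "stats")))
        return cls(simulation=sim, refinement=ref, stages=stages, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "region": config.region,
        "stages": list(config.stages),
        "parameters": {
            "simulation": dataclasses.asdict(config.simulation) | {
                "population_sizes": dict(config.simulation.population_sizes)},
            "refinement": dataclasses.asdict(config.refinement),
            "window_size": config.window_size,
            "restarts": config.restarts,
            "permutations": config.permutations,
        },
        "artifacts": {},
    }

    ref = load_reference_tables()
    table = ref.regional(config.region)
    pop_freqs = pd.read_csv(
        data_path(f"{config.region}_pop_freqs.tsv"), sep="\t")
    pops = config.populations or list(config.simulation.population_sizes)

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["artifacts"][name] = _sha256(path)

    truth = depths = matrix = results = None
    if "simulate" in config.stages:
        sim = dataclasses.replace(
            config.simulation, seed=config.seed,
            population_sizes={p: config.simulation.population_sizes[p] for p in pops})
        freq_sets = {
            p: freqset_from_population_column(table, pop_freqs, p, seed=config.seed + 7)
            for p in pops
        }
        truth = sample_cohort(freq_sets, sim)
        depths = simulate_depths(truth, sim)
        site_info = ref.panel.table[ref.panel.table["gene_pos"].isin(truth.sites)].copy()
        # simulated reads may only carry table alleles; widen to panel alleles
        site_info["alleles"] = [
            tuple(dict.fromkeys(list(truth.site_alleles[p]) + list(a)))
            for p, a in zip(site_info["gene_pos"], site_info["alleles"])
        ]
        manifest["n_samples"] = len(truth.samples)
        emit("truth.tsv", lambda p: hio.write_truth_tsv(p, truth))
        emit("depths.vcf", lambda p: hio.write_allele_depth_vcf(
            p, depths, site_info, truth.samples))

    fill_alleles: dict[int, str] = {}
    if "refine" in config.stages:
        matrix = refine_matrix(
            depths, truth.sites, truth.samples, config.refinement,
            populations=truth.populations, site_alleles=truth.site_alleles)
        prefilter = matrix
        matrix, removed = apply_site_filters(matrix)
        # sites dropped as monomorphic/singleton still need an allele when
        # haplotypes are projected onto the reference site lists
        for site in set(prefilter.sites) - set(matrix.sites):
            tally: dict[str, int] = {}
            for s in prefilter.samples:
                for a in prefilter.call(s, site).alleles:
                    if a != ".":
                        tally[a] = tally.get(a, 0) + 1
            if tally:
                fill_alleles[site] = max(tally, key=lambda a: (tally[a], a))
            else:
                fill_alleles[site] = ref.panel.major_allele(site) \
                    if site in ref.panel.gene_positions else "."
        rates = missing_rate(matrix)
        manifest["missing_rate"] = rates["overall"]
        manifest["sites_removed"] = removed.to_dict("records")
        site_info = ref.panel.table[ref.panel.table["gene_pos"].isin(matrix.sites)]
        emit("genotypes.vcf", lambda p: hio.write_genotype_vcf(p, matrix, site_info))
        emit("refinement_audit.tsv", lambda p: hio.write_refinement_audit(p, matrix))

    if "phase" in config.stages:
        model = EMPhasingModel(matrix, window_size=config.window_size,
                               restarts=config.restarts, seed=config.seed)
        results = model.fit()
        mean_post, frac_hi, n_hap = results.phasing_summary()
        manifest["phasing"] = {
            "mean_pair_posterior": mean_post,
            "fraction_posterior_gt_0.9": frac_hi,
            "n_haplotypes": n_hap,
            "loglike": results.loglike,
        }
        concordance = evaluate_calls(
            truth, _pad_matrix(matrix, truth), phased={
                s: _pad_pair(results.assignments[s], matrix.sites, truth.sites)
                for s in matrix.samples})
        manifest["evaluation"] = concordance
        emit("haplotype_pool.tsv", lambda p: results.haplotype_table().to_csv(
            p, sep="\t", index=False))
        emit("assignments.tsv", lambda p: results.assignment_table().to_csv(
            p, sep="\t", index=False))

    named = None
    if "name" in config.stages:
        namer = HaplotypeNamer(table)
        pool_index = {s: i for i, s in enumerate(results.pool.sites)}
        rows = []
        sample_names = {}
        for s in matrix.samples:
            pair = results.assignments[s].haplotypes
            labels = []
            for hap in pair:
                proj = tuple(
                    hap[pool_index[p]] if p in pool_index else fill_alleles[p]
                    for p in table.sites)
                nm = namer.classify(proj)
                labels.append(nm.label)
                rows.append({"sample": s, "haplotype": "|".join(proj),
                             "name": nm.label, "qualifier": nm.qualifier,
                             "distance": nm.distance})
            sample_names[s] = tuple(labels)
        named = pd.DataFrame(rows)
        emit("named_haplotypes.tsv", lambda p: named.to_csv(p, sep="\t", index=False))

    if "stats" in config.stages:
        counts = (
            named.assign(population=named["sample"].map(matrix.populations))
            .groupby(["name", "population"]).size().unstack(fill_value=0)
        )
        ftab = FrequencyTable(counts)
        weights = UTR3_WEIGHTS if config.region == "utr3" else WeightScheme(
            region_length=float(abs(max(matrix.sites) - min(matrix.sites)) + 1))
        freqs = ftab.frequencies()
        site_freqs = _site_freqs_from_assignments(results, matrix)
        reports = {}
        for pop in ftab.populations:
            reports[pop] = dataclasses.asdict(diversity_report(
                ftab, pop, site_freqs[pop], weights))
        manifest["diversity"] = reports
        fst = pairwise_fst(ftab, permutations=config.permutations, seed=config.seed)
        emit("fst.tsv", lambda p: hio.write_distance_matrix(p, fst))
        rey = reynolds_distance(ftab, fst)
        emit("reynolds.tsv", lambda p: hio.write_distance_matrix(p, rey))
        diff = differentiation_matrix(
            ftab, seed=config.seed, chain_length=config.hwe_chain,
            dememorization=config.hwe_dememorization)
        emit("exact_differentiation.tsv", lambda p: diff.pvalues.to_csv(p, sep="\t"))
        hwe = {}
        for pop in ftab.populations:
            gcounts = _diplotype_counts(results, matrix, counts.index, pop, sample_names)
            p_hwe, se = hwe_exact_test(
                gcounts, chain_length=config.hwe_chain,
                dememorization=config.hwe_dememorization, seed=config.seed)
            hwe[pop] = {"p": p_hwe, "se": se}
        manifest["hwe"] = hwe
        groups = {p: g for p, g in config.groups.items() if p in ftab.populations}
        if len(set(groups.values())) < 2 or len(ftab.populations) < 2:
            groups = None
        if len(ftab.populations) >= 2:
            amova_all = amova(ftab, groups, permutations=config.permutations,
                              seed=config.seed)
            manifest["amova"] = {"all_groups": dataclasses.asdict(amova_all)}
        else:
            groups = {}
            manifest["amova"] = {}
        no_admixed = {p: g for p, g in (groups or {}).items() if g != "Admixed"}
        if len(set(no_admixed.values())) >= 2:
            sub = FrequencyTable(counts[[p for p in ftab.populations if p in no_admixed]])
            manifest["amova"]["admixed_removed"] = dataclasses.asdict(
                amova(sub, no_admixed, permutations=config.permutations,
                      seed=config.seed))
        mds = classical_mds(rey.values)
        emit("mds.tsv", lambda p: mds.to_csv(p, sep="\t"))
        emit("frequency_table.tsv", lambda p: ftab.counts.to_csv(p, sep="\t"))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _pad_matrix(matrix, truth):
    """Re-expand a site-filtered matrix to the truth panel (filtered sites missing)."""
    from .refine import GenotypeCall, GenotypeMatrix
    calls = {}
    for s in matrix.samples:
        calls[s] = {}
        for site in truth.sites:
            if site in matrix.sites:
                calls[s][site] = matrix.call(s, site)
            else:
                calls[s][site] = GenotypeCall("missing", rule="site_filtered")
    return GenotypeMatrix(sites=truth.sites, samples=matrix.samples, calls=calls,
                          populations=dict(matrix.populations))


def _pad_pair(assignment, sites, truth_sites):
    h1, h2 = assignment.haplotypes
    m = dict(zip(sites, zip(h1, h2)))
    p1 = tuple(m.get(s, (None, None))[0] for s in truth_sites)
    p2 = tuple(m.get(s, (None, None))[1] for s in truth_sites)
    return p1, p2


def _site_freqs_from_assignments(results, matrix):
    """Per-population per-site allele frequencies from phased chromosomes."""
    out: dict[str, dict[int, list[float]]] = {}
    pools: dict[str, dict] = {}
    for s in matrix.samples:
        pop = matrix.populations.get(s, "POP")
        pools.setdefault(pop, {"haps": []})["haps"].extend(
            results.assignments[s].haplotypes)
    for pop, d in pools.items():
        haps = d["haps"]
        site_freqs = {}
        for i, site in enumerate(results.pool.sites):
            tally: dict[str, int] = {}
            for h in haps:
                tally[h[i]] = tally.get(h[i], 0) + 1
            total = sum(tally.values())
            site_freqs[site] = [c / total for c in tally.values()]
        out[pop] = site_freqs
    return out


def _diplotype_counts(results, matrix, hap_index, population, sample_names):
    labels = list(hap_index)
    idx = {name: k for k, name in enumerate(labels)}
    gcounts: dict[tuple[int, int], int] = {}
    for s in matrix.samples:
        if matrix.populations.get(s) != population:
            continue
        a, b = sample_names[s]
        key = tuple(sorted((idx[a], idx[b])))
        gcounts[key] = gcounts.get(key, 0) + 1
    return gcounts


def render_report(out_dir) -> Path:
    """Render a markdown summary of a finished run's artifacts."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    lines = ["# HLA-G pipeline report", ""]
    lines.append(f"Region: {manifest['region']}; seed {manifest['seed']}; "
                 f"{manifest.get('n_samples', '?')} samples")
    if "missing_rate" in manifest:
        lines.append(f"\nMissing allele rate after refinement: "
                     f"{100 * manifest['missing_rate']:.2f}%")
    if "phasing" in manifest:
        ph = manifest["phasing"]
        lines.append(
            f"\nPhasing: {ph['n_haplotypes']} haplotypes, mean pair posterior "
            f"{ph['mean_pair_posterior']:.4f}, "
            f"{100 * ph['fraction_posterior_gt_0.9']:.2f}% of samples above 0.9")
    if "diversity" in manifest:
        lines.append("\n## Diversity per population\n")
        lines.append("population | gene diversity | haplotype diversity | pi (%) | pHWE")
        lines.append("---|---|---|---|---")
        for pop, rep in sorted(manifest["diversity"].items()):
            hwe = manifest.get("hwe", {}).get(pop, {})
            lines.append(
                f"{pop} | {rep['gene_diversity']:.4f} ± {rep['gene_diversity_sd']:.4f}"
                f" | {rep['haplotype_diversity']:.4f} ± {rep['haplotype_diversity_sd']:.4f}"
                f" | {rep['nucleotide_diversity_pct']:.4f}"
                f" | {hwe.get('p', float('nan')):.4f}")
    fst_path = out / "fst.tsv"
    if fst_path.exists():
        fst = pd.read_csv(fst_path, sep="\t", index_col=0)
        pv_path = out / "fst.pvalues.tsv"
        lines.append("\n## Pairwise FST\n")
        lines.append(fst.round(4).to_markdown())
        if pv_path.exists():
            pv = pd.read_csv(pv_path, sep="\t", index_col=0)
            m = (len(fst) * (len(fst) - 1)) // 2
            alpha = bonferroni(0.05, m)
            sig = (pv < alpha["raw"]) & ~pv.isna()
            lines.append(f"\nBonferroni-adjusted threshold: {alpha['reported']} "
                         f"(0.05/{m}); significant pairs marked below\n")
            lines.append(sig.replace({True: "*", False: ""}).to_markdown())
    if "amova" in manifest:
        lines.append("\n## AMOVA\n")
        for scheme, res in manifest["amova"].items():
            lines.append(f"**{scheme}**: among groups "
                         f"{_fmt_pct(res['pct_among_groups'])}, "
                         f"among populations within groups {res['pct_among_pops']:.2f}%, "
                         f"within populations {res['pct_within']:.2f}%")
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


def _fmt_pct(v) -> str:
    return "n/a" if v is None else f"{v:.2f}%"
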