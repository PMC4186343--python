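"""Reading and writing the pipeline's file formats.

Allele-depth observations travel as VCF with per-sample ``AD`` fields
(one record per panel site, allele strings as REF/ALT, the gene-relative
position in ``INFO/GPOS``); refined genotypes as VCF ``GT`` (half calls use
a missing allele index, e.g. ``0/.``); haplotype pools, assignments,
frequency tables, distance matrices and reports as TSV.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
import pysam

from .refine import MISSING, AlleleDepthRecord, GenotypeMatrix

CHROM = "6"


def _vcf_header(samples: Sequence[str], with_ad: bool) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CHROM}>",
        '##INFO=<ID=GPOS,Number=1,Type=Integer,Description="CDS-anchored gene position">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if with_ad:
        lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Read depth per allele">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    return "\n".join(lines) + "\n"


def write_allele_depth_vcf(
    path,
    records: Iterable[AlleleDepthRecord],
    site_info: pd.DataFrame,
    samples: Sequence[str],
) -> None:
    """Write allele-depth records as a VCF with per-sample AD.

    ``site_info`` needs columns gene_pos, genomic_pos_hg19, rsid, alleles
    (tuple of allele strings; the first is REF).
    """
    by_site: dict[int, dict[str, AlleleDepthRecord]] = {}
    for rec in records:
        by_site.setdefault(rec.site, {})[rec.sample] = rec
    with open(path, "w") as fh:
        fh.write(_vcf_header(samples, with_ad=True))
        for _, row in site_info.sort_values("gene_pos").iterrows():
            gene_pos = int(row["gene_pos"])
            alleles = list(row["alleles"])
            ref, alts = alleles[0], alleles[1:]
            rsid = row.get("rsid") if isinstance(row.get("rsid"), str) else "."
            fields = [
                CHROM, str(int(row["genomic_pos_hg19"])), rsid or ".",
                ref, ",".join(alts) if alts else ".", ".", ".",
                f"GPOS={gene_pos}", "GT:AD",
            ]
            for s in samples:
                rec = by_site.get(gene_pos, {}).get(s)
                counts = dict(rec.counts) if rec else {}
                ad = ",".join(str(counts.pop(a, 0)) for a in alleles)
                if counts:
                    raise ValueError(
                        f"{s}@{gene_pos}: observed alleles {sorted(counts)} not in site alleles")
                fields.append(f"./.:{ad}")
            fh.write("\t".join(fields) + "\n")


def read_allele_depth_vcf(path) -> tuple[list[AlleleDepthRecord], pd.DataFrame, list[str]]:
    """Read a VCF with per-sample AD into allele-depth records + site info."""
    records = []
    info_rows = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alleles = [rec.ref] + [a for a in (rec.alts or ())]
            gene_pos = int(rec.info["GPOS"])
            info_rows.append({
                "gene_pos": gene_pos,
                "genomic_pos_hg19": rec.pos,
                "rsid": rec.id or ".",
                "alleles": tuple(alleles),
            })
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None:
                    continue
                counts = {a: int(c) for a, c in zip(alleles, ad)
                          if c is not None and int(c) > 0}
                records.append(AlleleDepthRecord(site=gene_pos, sample=s, counts=counts))
    return records, pd.DataFrame(info_rows), samples


def write_genotype_vcf(path, matrix: GenotypeMatrix, site_info: pd.DataFrame) -> None:
    """Write refined genotype calls as VCF GT (half calls as allele/.)."""
    info = site_info.set_index("gene_pos")
    with open(path, "w") as fh:
        fh.write(_vcf_header(matrix.samples, with_ad=False))
        for site in matrix.sites:
            row = info.loc[site]
            alleles = list(row["alleles"])
            index = {a: str(i) for i, a in enumerate(alleles)}
            rsid = row.get("rsid") if isinstance(row.get("rsid"), str) else "."
            fields = [
                CHROM, str(int(row["genomic_pos_hg19"])), rsid or ".",
                alleles[0], ",".join(alleles[1:]) if len(alleles) > 1 else ".",
                ".", ".", f"GPOS={site}", "GT",
            ]
            for s in matrix.samples:
                call = matrix.call(s, site)
                gt = "/".join(index.get(a, ".") if a != MISSING else "."
                              for a in call.alleles)
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def write_refinement_audit(path, matrix: GenotypeMatrix) -> None:
    rows = []
    for s in matrix.samples:
        for site in matrix.sites:
            call = matrix.call(s, site)
            rows.append({"site": site, "sample": s, "kind": call.kind,
                         "allele_a": call.allele_a, "allele_b": call.allele_b,
                         "rule": call.rule})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth_tsv(path, truth) -> None:
    rows = []
    for s in truth.samples:
        n1, n2 = truth.hap_names[s]
        v1, v2 = truth.hap_vectors[s]
        rows.append({"sample": s, "population": truth.populations[s],
                     "hap1_name": n1, "hap2_name": n2,
                     "hap1": "|".join(v1), "hap2": "|".join(v2)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_distance_matrix(path, dm) -> None:
    dm.values.to_csv(path, sep="\t")
    if dm.pvalues is not None:
        pv_path = str(path).replace(".tsv", "") + ".pvalues.tsv"
        dm.pvalues.to_csv(pv_path, sep="\t")
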