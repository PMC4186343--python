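"""Bundled reference tables of worldwide HLA-G variation.

The package ships, as TSV package data, the published reference description
of HLA-G variation in the 1000Genomes Phase 1 cohort: the variant site
lists for the promoter, coding and 3'UTR regions with their global allele
frequencies; the named haplotypes of each region with global frequencies;
the extended (promoter/coding/3'UTR) haplotypes with their lineage labels;
and the per-population haplotype frequency tables for the 14 cohort
populations.  This module loads and integrity-checks those tables and
assembles the full 133-site panel used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .gene_model import build_gene_model, data_path, read_site_list

REGIONS = ("promoter", "coding", "utr3")

#: Extended-table promoter names abbreviate the family prefix ("0104a" for
#: "010104a"); normalize before resolving against the promoter table.
PROMOTER_ALIASES = {"0104a": "010104a", "0104b": "010104b"}


class ReferenceDataError(ValueError):
    """Raised when a bundled table fails an integrity check."""


@dataclass(frozen=True)
class ReferenceHaplotypeTable:
    """Named reference haplotypes over an ordered site list for one region."""

    region: str
    sites: tuple[int, ...]                      # gene positions
    names: tuple[str, ...]
    alleles: dict[str, tuple[str, ...]]         # name -> allele vector
    frequencies: dict[str, float]               # name -> global frequency

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ReferenceDataError(f"{self.region}: duplicate haplotype names")
        for name, vec in self.alleles.items():
            if len(vec) != len(self.sites):
                raise ReferenceDataError(
                    f"{self.region}/{name}: vector length {len(vec)} != {len(self.sites)} sites")
        for name, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ReferenceDataError(f"{self.region}/{name}: frequency {f} outside [0,1]")

    def vector(self, name: str) -> tuple[str, ...]:
        return self.alleles[name]

    def frequency_sum(self) -> float:
        return float(sum(self.frequencies.values()))


@dataclass(frozen=True)
class SitePanel:
    """Ordered union of the three regional site lists (133 sites)."""

    table: pd.DataFrame  # columns: gene_pos, genomic_pos_hg19, rsid, region, alleles, freqs

    @property
    def gene_positions(self) -> tuple[int, ...]:
        return tuple(self.table["gene_pos"].tolist())

    def __len__(self) -> int:
        return len(self.table)

    def alleles_at(self, gene_pos: int) -> tuple[str, ...]:
        row = self.table.loc[self.table["gene_pos"] == gene_pos]
        if row.empty:
            raise KeyError(gene_pos)
        return tuple(row.iloc[0]["alleles"])

    def major_allele(self, gene_pos: int) -> str:
        row = self.table.loc[self.table["gene_pos"] == gene_pos].iloc[0]
        freqs = row["freqs"]
        return row["alleles"][int(np.argmax(freqs))]

    def region_positions(self, region: str) -> tuple[int, ...]:
        sub = self.table.loc[self.table["region"] == region, "gene_pos"]
        return tuple(sub.tolist())


def _load_sites(fname: str, region: str) -> pd.DataFrame:
    df = read_site_list(data_path(fname))
    alleles, freqs = [], []
    for _, row in df.iterrows():
        al = [str(row["ref"]), str(row["alt"])]
        fr = [float(row["ref_freq"]), float(row["alt_freq"])]
        if "alt2" in df.columns and isinstance(row.get("alt2"), str) and row["alt2"]:
            al.append(str(row["alt2"]))
            fr.append(float(row["alt2_freq"]))
        alleles.append(tuple(al))
        freqs.append(tuple(fr))
    out = pd.DataFrame({
        "gene_pos": df["gene_pos"].astype(int),
        "genomic_pos_hg19": df["genomic_pos_hg19"].astype(int),
        "rsid": df["rsid"],
        "region": region,
        "alleles": alleles,
        "freqs": freqs,
    })
    if "annotation" in df.columns:
        out["annotation"] = df["annotation"]
    return out


def load_site_panel() -> SitePanel:
    """Load the union of promoter, coding and 3'UTR site lists, in gene order."""
    parts = [
        _load_sites("promoter_sites.tsv", "promoter"),
        _load_sites("coding_sites.tsv", "coding"),
        _load_sites("utr3_sites.tsv", "utr3"),
    ]
    panel = pd.concat(parts, ignore_index=True).sort_values("gene_pos").reset_index(drop=True)
    if panel["gene_pos"].duplicated().any():
        raise ReferenceDataError("duplicate gene positions across regional site lists")
    model = build_gene_model()
    for _, row in panel.iterrows():
        if model.gene_to_genomic(int(row["gene_pos"])) != int(row["genomic_pos_hg19"]):
            raise ReferenceDataError(
                f"site {row['gene_pos']}: genomic coordinate mismatch")
        sfreq = sum(row["freqs"])
        if abs(sfreq - 1.0) > 5e-4:
            raise ReferenceDataError(f"site {row['gene_pos']}: allele frequencies sum to {sfreq}")
    return SitePanel(table=panel)


def _load_haplotype_table(fname: str, region: str) -> ReferenceHaplotypeTable:
    df = pd.read_csv(data_path(fname), sep="\t", dtype=str)
    site_cols = [c for c in df.columns if c not in ("name", "global_freq")]
    sites = tuple(int(c) for c in site_cols)
    names = tuple(df["name"].tolist())
    alleles = {row["name"]: tuple(row[c] for c in site_cols) for _, row in df.iterrows()}
    freqs = {row["name"]: float(row["global_freq"]) for _, row in df.iterrows()}
    return ReferenceHaplotypeTable(region, sites, names, alleles, freqs)


@dataclass(frozen=True)
class ExtendedHaplotypeTable:
    """Linkage of promoter/coding/3'UTR names into extended haplotypes."""

    table: pd.DataFrame  # promoter, coding, utr3, lineage, global_freq, label

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.table["label"].tolist())

    def frequency_sum(self) -> float:
        return float(self.table["global_freq"].sum())

    def lineage_for(self, promoter: str, coding: str, utr3: str) -> Optional[str]:
        m = self.table[
            (self.table["promoter"] == promoter)
            & (self.table["coding"] == coding)
            & (self.table["utr3"] == utr3)
        ]
        return None if m.empty else str(m.iloc[0]["lineage"])


@dataclass(frozen=True)
class ReferenceTables:
    panel: SitePanel
    promoter: ReferenceHaplotypeTable
    coding: ReferenceHaplotypeTable
    utr3: ReferenceHaplotypeTable
    extended: ExtendedHaplotypeTable

    def regional(self, region: str) -> ReferenceHaplotypeTable:
        return {"promoter": self.promoter, "coding": self.coding, "utr3": self.utr3}[region]


def load_reference_tables() -> ReferenceTables:
    """Load and cross-check all bundled reference tables.

    Integrity checks: every haplotype-table site exists in the site panel
    with a matching allele; extended-table component names resolve against
    the regional tables (directly, through the documented family aliases,
    or as a "-Like"/"new"/unlisted variant).
    """
    panel = load_site_panel()
    promoter = _load_haplotype_table("promoter_haplotypes.tsv", "promoter")
    coding = _load_haplotype_table("coding_haplotypes.tsv", "coding")
    utr3 = _load_haplotype_table("utr3_haplotypes.tsv", "utr3")
    ext = pd.read_csv(data_path("extended_haplotypes.tsv"), sep="\t", dtype=str)
    ext["global_freq"] = ext["global_freq"].astype(float)
    extended = ExtendedHaplotypeTable(table=ext)

    panel_positions = set(panel.gene_positions)
    for tab in (promoter, coding, utr3):
        for pos in tab.sites:
            if pos not in panel_positions:
                raise ReferenceDataError(f"{tab.region}: site {pos} not in site panel")
        for name, vec in tab.alleles.items():
            for pos, allele in zip(tab.sites, vec):
                if allele not in panel.alleles_at(pos):
                    raise ReferenceDataError(
                        f"{tab.region}/{name}: allele {allele!r} at {pos} not a panel allele")
    if len(panel) != 133:
        raise ReferenceDataError(f"site panel has {len(panel)} sites, expected 133")

    for _, row in ext.iterrows():
        for region, col in (("promoter", "promoter"), ("coding", "coding"), ("utr3", "utr3")):
            resolve_component_name(str(row[col]), load_into=None)  # syntax check only
    return ReferenceTables(panel, promoter, coding, utr3, extended)


def resolve_component_name(name: str, load_into=None) -> tuple[str, str]:
    """Split an extended-table component name into (base, qualifier).

    Qualifier is ``exact`` for a plain name, ``like`` for the "-Like"
    suffix (one nucleotide away from the base haplotype) and ``new`` for
    names flagged unknown/new.
    """
    if name.lower().startswith("unknown"):
        return name, "new"
    if name.endswith("-Like"):
        return name[: -len("-Like")], "like"
    if name.endswith("new"):
        return name, "exact"  # the "new" allele is itself a named table row
    return name, "exact"


def normalize_promoter_name(name: str) -> str:
    return PROMOTER_ALIASES.get(name, name)
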