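"""Structure of the HLA-G locus and variant-position annotation.

The locus model is an ordered list of exon/intron segments whose lengths
are fixed constants of the gene.  Positions along the gene use the
CDS-anchored convention common in the HLA-G literature: the adenine of the
main translation-start ATG is position +1, every nucleotide upstream of it
is negative, and there is no position 0.  The model converts between this
gene-relative scale and 1-based hg19 genomic coordinates on chromosome 6,
places a position into its segment (promoter, 5'UTR, exon, intron, 3'UTR),
maps coding positions to CDS/codon numbers, and classifies the predicted
effect of a substitution or indel.

Codon numbering follows mature-protein convention: HLA class I proteins
are numbered after cleavage of the 24-residue leader peptide, so the codon
reported for a coding variant is the CDS codon minus 24.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

#: hg19 coordinate of gene position +1 (first base of the CDS).
GENOMIC_ANCHOR = 29795622

#: The ancestral 14-bp 3'UTR insertion (rs371194629) is part of the gene
#: coordinate scale (positions +2961..+2974) but absent from hg19, so
#: genomic coordinates beyond the insertion point are offset by 14.
INDEL_INSERTION_SPAN = (2961, 2974)
INDEL_SHIFT = 14

#: Number of leader-peptide codons removed in mature-protein numbering.
LEADER_CODONS = 24

#: Coding nucleotides contributed by exon 2 (the rest of it is 5'UTR).
EXON2_CODING_LENGTH = 73

#: Ordered (name, role, length_nt, imgt_alias) segments of the locus.
_SEGMENTS = [
    ("exon1", "exon", 66, None),
    ("intron1", "intron", 688, None),
    ("exon2", "exon", 185, "exon1"),
    ("intron2", "intron", 129, "intron1"),
    ("exon3", "exon", 270, "exon2"),
    ("intron3", "intron", 226, "intron2"),
    ("exon4", "exon", 276, "exon3"),
    ("intron4", "intron", 599, "intron3"),
    ("exon5", "exon", 276, "exon4"),
    ("intron5", "intron", 122, "intron4"),
    ("exon6", "exon", 117, "exon5"),
    ("intron6", "intron", 445, "intron5"),
    ("exon7", "exon", 33, "exon6"),
    ("intron7", "intron", 357, None),
    ("exon8", "exon", 355, None),
]

#: Gene-relative span considered part of the locus (promoter included).
GENE_SPAN = (-1500, 3278)

#: Exons that contribute to the CDS, in order, with the number of coding
#: nucleotides each contributes (1017 in total; exon 7 holds the stop).
_CODING_EXONS = ["exon2", "exon3", "exon4", "exon5", "exon6", "exon7"]

_STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

EFFECT_CLASSES = (
    "intronic", "splice_acceptor", "splice_donor", "synonymous",
    "non_synonymous", "stop_gained", "frameshift", "utr", "indeterminate",
)


class GeneModelError(ValueError):
    """Raised when the bundled locus constants violate a structural check."""


@dataclass(frozen=True)
class Segment:
    name: str
    role: str  # "exon" | "intron"
    length: int
    imgt_alias: Optional[str]
    start: int  # gene position of first base (no zero on this scale)
    end: int    # gene position of last base


@dataclass(frozen=True)
class SiteAnnotation:
    """Positional and effect annotation of a single gene position."""

    region: str            # promoter | 5UTR | coding_exon | intron | 3UTR
    segment_name: str
    cds_position: Optional[int] = None
    cds_codon: Optional[int] = None
    mature_codon: Optional[int] = None
    codon_phase: Optional[int] = None
    effect: Optional[str] = None


def _gene_range(first: int, length: int) -> tuple[int, int]:
    """Span of `length` bases starting at gene position `first`, skipping 0."""
    last = first + length - 1
    if first < 0 and last >= 0:
        last += 1
    return first, last


@dataclass(frozen=True)
class GeneModel:
    """The HLA-G locus: ordered segments anchored at CDS position +1."""

    segments: tuple[Segment, ...]
    genomic_anchor: int = GENOMIC_ANCHOR
    leader_codons: int = LEADER_CODONS
    exon2_coding_length: int = EXON2_CODING_LENGTH
    _coding_offsets: dict = field(default_factory=dict, repr=False)

    # -- derived quantities -------------------------------------------------
    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def cds_length(self) -> int:
        return sum(self._coding_lengths().values())

    def _coding_lengths(self) -> dict[str, int]:
        lengths = {s.name: s.length for s in self.segments}
        out = {"exon2": self.exon2_coding_length}
        for name in ("exon3", "exon4", "exon5", "exon6"):
            out[name] = lengths[name]
        # exon 7 contributes whatever remains up to a 1017 nt CDS
        out["exon7"] = 1017 - sum(out.values())
        return out

    @property
    def utr5_length(self) -> int:
        lengths = {s.name: s.length for s in self.segments}
        return lengths["exon1"] + (lengths["exon2"] - self.exon2_coding_length)

    @property
    def utr3_length(self) -> int:
        lengths = {s.name: s.length for s in self.segments}
        coding7 = self._coding_lengths()["exon7"]
        return (lengths["exon7"] - coding7) + lengths["exon8"]

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- coordinate conversion ---------------------------------------------
    def gene_to_genomic(self, pos: int) -> int:
        """Map a CDS-anchored gene position to its hg19 coordinate.

        Positions inside the ancestral 14-bp insertion (+2961..+2974) have
        no hg19 coordinate and raise; positions beyond it are shifted by
        the 14 bases hg19 lacks.
        """
        if pos == 0:
            raise ValueError("gene position 0 does not exist (+1/-1 are adjacent)")
        if INDEL_INSERTION_SPAN[0] <= pos <= INDEL_INSERTION_SPAN[1]:
            raise ValueError(
                f"gene position {pos} lies inside the 14-bp insertion absent from hg19")
        if pos > INDEL_INSERTION_SPAN[1]:
            return self.genomic_anchor - 1 + pos - INDEL_SHIFT
        if pos >= 1:
            return self.genomic_anchor - 1 + pos
        return self.genomic_anchor + pos

    def genomic_to_gene(self, coord: int) -> int:
        """Inverse of :meth:`gene_to_genomic`; restricted to the locus span."""
        lo = self.gene_to_genomic(GENE_SPAN[0])
        hi = self.gene_to_genomic(GENE_SPAN[1])
        if not lo <= coord <= hi:
            raise ValueError(f"genomic coordinate {coord} outside the locus span")
        if coord < self.genomic_anchor:
            return coord - self.genomic_anchor
        pos = coord - self.genomic_anchor + 1
        if pos >= INDEL_INSERTION_SPAN[0]:
            pos += INDEL_SHIFT
        return pos

    # -- positional annotation ----------------------------------------------
    def locate(self, pos: int) -> SiteAnnotation:
        """Place a gene position into its segment and, if coding, its codon."""
        if pos == 0:
            raise ValueError("gene position 0 does not exist")
        if pos < GENE_SPAN[0] or pos > GENE_SPAN[1]:
            raise ValueError(f"gene position {pos} outside the modeled span {GENE_SPAN}")
        seg = None
        for s in self.segments:
            if s.start <= pos <= s.end and not (pos == 0):
                seg = s
                break
        if seg is None:
            # upstream of exon 1: promoter / 5' upstream regulatory region
            return SiteAnnotation(region="promoter", segment_name="promoter")
        if seg.role == "intron":
            return SiteAnnotation(region="intron", segment_name=seg.name)
        coding = self._coding_offsets
        if seg.name in coding:
            c_start, c_end, cds_offset = coding[seg.name]
            if c_start <= pos <= c_end:
                cds = cds_offset + _count_positions(c_start, pos)
                codon = (cds + 2) // 3
                phase = cds - 3 * (codon - 1)
                return SiteAnnotation(
                    region="coding_exon", segment_name=seg.name,
                    cds_position=cds, cds_codon=codon,
                    mature_codon=codon - self.leader_codons, codon_phase=phase,
                )
        if pos < 0 or (seg.name == "exon2" and pos < 1):
            return SiteAnnotation(region="5UTR", segment_name=seg.name)
        return SiteAnnotation(region="3UTR", segment_name=seg.name)

    def classify_effect(
        self,
        pos: int,
        ref: str,
        alt: str,
        cds_sequence: Optional[str] = None,
    ) -> str:
        """Predict the effect class of a ref->alt change at a gene position.

        Splice sites are the terminal dinucleotides of each intron (the
        canonical GT donor / AG acceptor positions).  In coding exons an
        indel whose length difference is not a multiple of three is a
        frameshift; substitutions are resolved against ``cds_sequence``
        (1017 nt) when given, otherwise reported ``indeterminate``.
        """
        for allele in (ref, alt):
            if not allele or any(b not in "ACGTN" for b in allele.upper()):
                raise ValueError(f"malformed allele {allele!r}")
        ann = self.locate(pos)
        if ann.region == "intron":
            seg = self.segment(ann.segment_name)
            if pos in (seg.end, seg.end - 1):
                return "splice_acceptor"
            if pos in (seg.start, seg.start + 1):
                return "splice_donor"
            return "intronic"
        if ann.region in ("promoter", "5UTR", "3UTR"):
            return "utr" if ann.region != "promoter" else "utr"
        # coding exon
        if len(ref) != len(alt):
            return "frameshift" if abs(len(ref) - len(alt)) % 3 else "indeterminate"
        if cds_sequence is None:
            return "indeterminate"
        cds_sequence = cds_sequence.upper()
        if len(cds_sequence) != 1017:
            raise ValueError("cds_sequence must be the 1017 nt coding sequence")
        if len(ref) != 1:
            return "indeterminate"  # in-frame MNV substitution: not modeled
        idx = ann.cds_position - 1
        codon_start = 3 * (ann.cds_codon - 1)
        codon = cds_sequence[codon_start:codon_start + 3]
        mutated = list(codon)
        mutated[idx - codon_start] = alt.upper()
        aa_ref = _STANDARD_TABLE.get(codon)
        aa_alt = _STANDARD_TABLE.get("".join(mutated))
        if aa_ref is None or aa_alt is None:
            return "indeterminate"
        if aa_alt == "*" and aa_ref != "*":
            return "stop_gained"
        return "synonymous" if aa_ref == aa_alt else "non_synonymous"


def _count_positions(start: int, stop: int) -> int:
    """Number of gene positions in [start, stop], accounting for the absent 0."""
    n = stop - start + 1
    if start < 0 and stop > 0:
        n -= 1
    return n


def build_gene_model() -> GeneModel:
    """Assemble the locus model and verify its structural invariants.

    Raises :class:`GeneModelError` if the bundled constants are mutually
    inconsistent (total length 4144 nt, 178 nt 5'UTR, 1017 nt CDS,
    383 nt 3'UTR).
    """
    # exon 2 must start so that its coding part spans +1..+73
    exon2_start = -(185 - EXON2_CODING_LENGTH)  # -112
    # walk backwards for intron1/exon1, forwards for the rest
    starts: dict[str, int] = {"exon2": exon2_start}
    intron1_start, _ = _gene_range(exon2_start - 688, 688)
    starts["intron1"] = intron1_start
    starts["exon1"], _ = _gene_range(intron1_start - 66, 66)
    pos = _gene_range(exon2_start, 185)[1] + 1
    for name, role, length, _alias in _SEGMENTS[3:]:
        starts[name] = pos
        pos = _gene_range(pos, length)[1] + 1

    segments = []
    for name, role, length, alias in _SEGMENTS:
        start = starts[name]
        s, e = _gene_range(start, length)
        segments.append(Segment(name, role, length, alias, s, e))
    model = GeneModel(segments=tuple(segments))

    # cumulative CDS offsets per coding exon
    coding_lengths = model._coding_lengths()
    offsets = {}
    acc = 0
    for name in _CODING_EXONS:
        seg = model.segment(name)
        c_start = 1 if name == "exon2" else seg.start
        c_end_count = coding_lengths[name]
        c_end = _gene_range(c_start, c_end_count)[1]
        offsets[name] = (c_start, c_end, acc)
        acc += c_end_count
    model._coding_offsets.update(offsets)

    checks = {
        "total length 4144": model.total_length == 4144,
        "5'UTR length 178": model.utr5_length == 178,
        "CDS length 1017": model.cds_length == 1017,
        "3'UTR length 383": model.utr3_length == 383,
        "exon7 coding part 5": coding_lengths["exon7"] == 5,
        "anchor round-trip": model.genomic_to_gene(model.gene_to_genomic(1)) == 1,
    }
    failed = [k for k, ok in checks.items() if not ok]
    if failed:
        raise GeneModelError(f"gene model integrity failure: {failed}")
    return model


# -- site-list I/O -----------------------------------------------------------

def data_path(name: str) -> Path:
    """Path to a bundled reference data file."""
    return Path(importlib.resources.files("hlag") / "data" / name)


def read_site_list(path) -> pd.DataFrame:
    """Read a variant site list TSV (gene_pos, genomic_pos_hg19, rsid, alleles)."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    df["gene_pos"] = df["gene_pos"].astype(int)
    df["genomic_pos_hg19"] = df["genomic_pos_hg19"].astype(int)
    return df


def write_site_list(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cds_fasta(path) -> str:
    """Read a single-record FASTA holding the 1017 nt coding sequence."""
    seq_lines: list[str] = []
    n_records = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                n_records += 1
                if n_records > 1:
                    raise ValueError("expected a single-record CDS FASTA")
                continue
            seq_lines.append(line)
    seq = "".join(seq_lines).upper()
    if len(seq) != 1017:
        raise ValueError(f"CDS sequence must be 1017 nt, got {len(seq)}")
    return seq
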