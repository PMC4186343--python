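"""Assigning established names to inferred HLA-G haplotypes.

Each HLA-G region carries its own naming system: coding haplotypes map to
IMGT/HLA-style allele names (G*01:01:01:01, ...), 3'UTR haplotypes to the
UTR-n series, and promoter haplotypes to the promoter-lineage names
(010101a, ...).  An inferred haplotype is matched against the bundled
reference rows of its region: an identical allele vector takes the
reference name (``exact``); a vector one nucleotide away from a single
reference takes that name with the ``-Like`` suffix; anything further away
is a ``new`` haplotype and receives a deterministic region-prefixed
ordinal.  Extended haplotypes are labelled by joining the three regional
names, and known promoter/coding/UTR triples carry an HLA-G lineage label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .tables import (
    ExtendedHaplotypeTable,
    ReferenceHaplotypeTable,
    ReferenceTables,
    load_reference_tables,
    normalize_promoter_name,
    resolve_component_name,
)

__all__ = [
    "HaplotypeName", "HaplotypeNamer", "classify", "name_extended",
    "load_reference_tables", "build_extended_vectors",
]


@dataclass(frozen=True)
class HaplotypeName:
    base: str
    qualifier: str              # exact | like | new
    distance: int
    lineage: Optional[str] = None
    note: Optional[str] = None  # e.g. tie-break documentation

    @property
    def label(self) -> str:
        if self.qualifier == "like":
            return f"{self.base}-Like"
        return self.base


def hamming(a: Sequence[str], b: Sequence[str]) -> int:
    """Site-count distance between allele vectors (an indel allele is one site)."""
    if len(a) != len(b):
        raise ValueError(f"vector length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def classify(
    vector: Sequence[str],
    table: ReferenceHaplotypeTable,
    namer: Optional["HaplotypeNamer"] = None,
) -> HaplotypeName:
    """Match an allele vector against a region's reference haplotypes.

    Ties at distance 1 are broken by the higher reference global frequency,
    then by name order, and the tie is recorded in ``note``.
    """
    vector = tuple(vector)
    if len(vector) != len(table.sites):
        raise ValueError(
            f"vector spans {len(vector)} sites; {table.region} table has {len(table.sites)}")
    distances = {name: hamming(vector, table.vector(name)) for name in table.names}
    exact = [n for n, d in distances.items() if d == 0]
    if exact:
        return HaplotypeName(exact[0], "exact", 0)
    near = sorted(
        (n for n, d in distances.items() if d == 1),
        key=lambda n: (-table.frequencies.get(n, 0.0), n),
    )
    if near:
        note = None
        if len(near) > 1:
            note = "distance-1 tie with " + ", ".join(near[1:])
        return HaplotypeName(near[0], "like", 1, note=note)
    name = namer.new_name(vector) if namer is not None else f"{table.region}-new"
    return HaplotypeName(name, "new", min(distances.values()) if distances else -1)


class HaplotypeNamer:
    """Issues deterministic names for one region's novel haplotypes.

    New haplotypes are named ``<region>-new-<ordinal>`` in order of first
    occurrence, so repeated runs over the same data produce identical names.
    """

    def __init__(self, table: ReferenceHaplotypeTable):
        self.table = table
        self._new: dict[tuple[str, ...], str] = {}

    def new_name(self, vector: Sequence[str]) -> str:
        key = tuple(vector)
        if key not in self._new:
            self._new[key] = f"{self.table.region}-new-{len(self._new) + 1}"
        return self._new[key]

    def classify(self, vector: Sequence[str]) -> HaplotypeName:
        return classify(vector, self.table, namer=self)


def name_extended(
    promoter_name: str,
    coding_name: str,
    utr_name: str,
    extended: ExtendedHaplotypeTable,
) -> tuple[str, Optional[str]]:
    """Join the three regional names into an extended label and look up its lineage.

    The label follows the published convention ``G<promoter>/<coding>/<utr>``.
    The lineage is reported only when the exact triple appears in the
    bundled extended-haplotype table (family-prefix aliases accepted).
    """
    label = f"G{promoter_name}/{coding_name}/{utr_name}"
    candidates = {promoter_name}
    for alias, full in (("0104a", "010104a"), ("0104b", "010104b")):
        if promoter_name == full:
            candidates.add(alias)
        if promoter_name == alias:
            candidates.add(full)
    for cand in candidates:
        lineage = extended.lineage_for(cand, coding_name, utr_name)
        if lineage is not None:
            return label, lineage
    return label, None


# -- full-panel allele vectors for the extended haplotypes -------------------

def _synthetic_edit(
    base: tuple[str, ...],
    table: ReferenceHaplotypeTable,
    panel,
    taken: set[tuple[str, ...]],
    ordinal: int,
) -> tuple[str, ...]:
    """Deterministic single-site edit of ``base`` avoiding existing vectors.

    Used to build synthetic stand-in vectors for extended-table component
    names whose allele vectors are not printed in the reference tables
    (rare "-Like", "new" and unlisted variants).  The edit site cycles with
    ``ordinal`` so distinct names receive distinct vectors.
    """
    n = len(table.sites)
    reference = {table.vector(name) for name in table.names} | taken
    for step in range(2 * n):
        idx = (ordinal + step) % n
        pos = table.sites[idx]
        for allele in panel.alleles_at(pos):
            if allele == base[idx]:
                continue
            cand = base[:idx] + (allele,) + base[idx + 1:]
            if cand not in reference:
                return cand
    raise RuntimeError("could not construct a distinct synthetic vector")


def _component_vector(
    name: str,
    table: ReferenceHaplotypeTable,
    panel,
    taken: dict[str, tuple[str, ...]],
    ordinal: int,
) -> tuple[tuple[str, ...], bool]:
    """Allele vector for an extended-table component name.

    Returns ``(vector, synthetic)``.  Listed names resolve directly;
    "-Like" names and names absent from the regional table receive a
    deterministic synthetic stand-in one edit away from the closest listed
    relative (family prefix match, else the region's most frequent row).
    """
    if name in taken:
        return taken[name], False
    if table.region == "promoter":
        name_n = normalize_promoter_name(name)
    else:
        name_n = name
    base_name, qualifier = resolve_component_name(name_n)
    if qualifier == "exact" and base_name in table.names:
        return table.vector(base_name), False
    if qualifier == "like" and base_name in table.names:
        base = table.vector(base_name)
    else:
        # unlisted or unknown: closest family member by name prefix
        def shared_prefix(other: str) -> int:
            k = 0
            for x, y in zip(base_name, other):
                if x != y:
                    break
                k += 1
            return k
        family = max(table.names, key=lambda n: (shared_prefix(n), table.frequencies.get(n, 0)))
        base = table.vector(family)
    vec = _synthetic_edit(base, table, panel, set(taken.values()), ordinal)
    return vec, True


def build_extended_vectors(ref: ReferenceTables) -> "pd.DataFrame":
    """Full 133-site allele vectors for the bundled extended haplotypes.

    Each extended haplotype is assembled from its promoter (27 sites),
    coding (51 sites) and 3'UTR (9 sites) component vectors; the remaining
    panel sites — rare positions dropped from the printed haplotype tables —
    carry the panel's major allele.  Components without a printed vector
    are synthetic stand-ins (flagged in the ``synthetic`` column).
    """
    import pandas as pd

    panel = ref.panel
    positions = ref.panel.gene_positions
    pos_index = {p: i for i, p in enumerate(positions)}
    majors = [panel.major_allele(p) for p in positions]

    rows = []
    seen: dict[str, dict[str, tuple[str, ...]]] = {r: {} for r in ("promoter", "coding", "utr3")}
    for ordinal, (_, row) in enumerate(ref.extended.table.iterrows()):
        vec = list(majors)
        synthetic = False
        for region in ("promoter", "coding", "utr3"):
            table = ref.regional(region)
            comp, synth = _component_vector(
                str(row[region]), table, panel, seen[region], ordinal)
            seen[region][str(row[region])] = comp
            synthetic = synthetic or synth
            for pos, allele in zip(table.sites, comp):
                # the shared +15 site belongs to both promoter and coding
                # component definitions; the coding component wins
                if region == "promoter" and pos == 15 and str(row["coding"]) in ref.coding.names:
                    continue
                vec[pos_index[pos]] = allele
        rows.append({
            "label": row["label"],
            "lineage": row["lineage"],
            "frequency": float(row["global_freq"]),
            "synthetic": synthetic,
            "vector": tuple(vec),
        })
    return pd.DataFrame(rows)
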