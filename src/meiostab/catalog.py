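"""Per-gene haplotype reference catalog.

Identifies allele-diagnostic SNP sites from a length-aligned allele set,
assigns allele origin by nearest diploid reference (a distance proxy for the
ploidy-clean clustering seen in full phylogenies), and summarizes derived
allele frequencies by population from dosage calls.

Coordinates are 1-based on the gene's reference/alignment coordinate.
Columns containing a gap or N in any compared sequence are ignored
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alleles import HaplotypeAllele

_UNINFORMATIVE = {"-", "N"}


class AlignmentError(ValueError):
    """Sequences are not length-aligned."""


@dataclass(frozen=True)
class DiagnosticSite:
    """A column that separates at least two allele groups.

    ``base_by_group`` maps each group that is unanimous at this column to its
    base; only groups with a single (non-gap, non-N) base are listed.
    """

    position: int  # 1-based
    base_by_group: dict[str, str]


@dataclass
class DiagnosticSiteSet:
    gene: str
    sites: list[DiagnosticSite]
    reference_length: int

    def positions(self) -> list[int]:
        return [s.position for s in self.sites]


def find_diagnostic_sites(
    alleles: list[HaplotypeAllele],
    grouping: dict[str, str],
    majority_threshold: float | None = None,
) -> DiagnosticSiteSet:
    """Columns where one allele group's shared base differs from another's.

    A column qualifies when two groups are each unanimous (or, with
    ``majority_threshold`` set, reach that consensus fraction) for different
    bases.  Columns with a gap or N in any allele are excluded.  Requires a
    length-aligned allele set covering at least two groups.
    """
    if not alleles:
        raise ValueError("empty allele set")
    lengths = {len(a) for a in alleles}
    if len(lengths) != 1:
        raise AlignmentError(f"alleles not length-aligned: lengths {sorted(lengths)}")
    missing = [a.allele_id for a in alleles if a.allele_id not in grouping]
    if missing:
        raise KeyError(f"alleles missing from grouping: {missing}")
    groups: dict[str, list[str]] = {}
    for a in alleles:
        groups.setdefault(grouping[a.allele_id], []).append(a.sequence)
    if len(groups) < 2:
        raise ValueError("need at least two allele groups")

    (length,) = lengths
    gene = alleles[0].gene
    sites: list[DiagnosticSite] = []
    for i in range(length):
        col = {g: [s[i] for s in seqs] for g, seqs in groups.items()}
        if any(b in _UNINFORMATIVE for bases in col.values() for b in bases):
            continue
        consensus: dict[str, str] = {}
        for g, bases in col.items():
            if majority_threshold is None:
                if len(set(bases)) == 1:
                    consensus[g] = bases[0]
            else:
                top = max(set(bases), key=bases.count)
                if bases.count(top) / len(bases) >= majority_threshold:
                    consensus[g] = top
        if len(set(consensus.values())) >= 2:
            sites.append(DiagnosticSite(i + 1, consensus))
    return DiagnosticSiteSet(gene, sites, length)


@dataclass
class OriginAssignment:
    origin: str
    distances: pd.DataFrame  # allele_id, origin, distance, n_compared


def assign_origin(
    query: HaplotypeAllele, references: list[HaplotypeAllele]
) -> OriginAssignment:
    """Origin of the reference at minimum Hamming distance from the query.

    Distances are counted over columns where neither sequence has a gap or N;
    sequences must be length-aligned.  Ties between references of different
    origins yield ``unknown``.
    """
    if not references:
        raise ValueError("no references")
    rows = []
    for ref in references:
        if len(ref) != len(query):
            raise AlignmentError(
                f"reference {ref.allele_id} length {len(ref)} != query {len(query)}"
            )
        dist = n_comp = 0
        for a, b in zip(query.sequence, ref.sequence):
            if a in _UNINFORMATIVE or b in _UNINFORMATIVE:
                continue
            n_comp += 1
            dist += a != b
        if n_comp == 0:
            raise ValueError(f"no comparable positions vs {ref.allele_id}")
        rows.append((ref.allele_id, ref.origin, dist, n_comp))
    table = pd.DataFrame(rows, columns=["allele_id", "origin", "distance", "n_compared"])
    dmin = table["distance"].min()
    best = table.loc[table["distance"] == dmin, "origin"].unique()
    origin = best[0] if len(best) == 1 else "unknown"
    return OriginAssignment(origin, table.sort_values("distance", ignore_index=True))


def summarize_allele_frequencies(
    calls: pd.DataFrame, populations: dict[str, str]
) -> pd.DataFrame:
    """Derived-haplotype frequency per population x gene from dosage calls.

    Frequency = sum of derived dosages / (4 x number of plants); the
    complementary ancestral frequency is 1 minus that, so the two groups sum
    to one per gene.
    """
    if calls.empty:
        raise ValueError("no dosage calls")
    missing = sorted(set(calls["plant_id"]) - set(populations))
    if missing:
        raise KeyError(f"plants missing population labels: {missing}")
    df = calls.copy()
    df["population"] = df["plant_id"].map(populations)
    grouped = df.groupby(["population", "gene"], as_index=False).agg(
        n_plants=("plant_id", "nunique"), total_dosage=("dosage", "sum")
    )
    grouped["derived_freq"] = grouped["total_dosage"] / (4.0 * grouped["n_plants"])
    grouped["ancestral_freq"] = 1.0 - grouped["derived_freq"]
    return grouped.drop(columns="total_dosage")


def write_diagnostic_sites(dss: DiagnosticSiteSet, path: str | Path) -> None:
    rows = [
        (dss.gene, s.position, g, b)
        for s in dss.sites
        for g, b in sorted(s.base_by_group.items())
    ]
    pd.DataFrame(rows, columns=["gene", "site", "group", "base"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_diagnostic_sites(path: str | Path, reference_length: int = 0) -> dict[str, DiagnosticSiteSet]:
    """Read a ``diagnostic_sites.tsv`` into per-gene site sets."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, DiagnosticSiteSet] = {}
    for gene, gdf in df.groupby("gene"):
        sites = [
            DiagnosticSite(int(pos), dict(zip(sdf["group"], sdf["base"])))
            for pos, sdf in gdf.groupby("site")
        ]
        sites.sort(key=lambda s: s.position)
        out[str(gene)] = DiagnosticSiteSet(
            str(gene), sites, reference_length or max(s.position for s in sites)
        )
    return out
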