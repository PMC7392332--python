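"""Synthetic study generator: allele sets, tetraploid populations, amplicon
read counts and metaphase-I cytology tables.

The generator emulates the structure of a genotype-phenotype association study
of meiotic stability in autotetraploid *Arabidopsis lyrata*/*A. arenosa*:

* per-gene allele sets with diagnostic SNPs separating ancestral diploid from
  derived tetraploid haplotypes, including presets for the known structural
  lesions (the 78 bp in-frame *ASY3* tandem duplication and matching deletion
  flanked by AGAGA microhomology, the 1474 bp terminal *ZYP1b* -> *ZYP1a* gene
  conversion, and the chimeric *PRD3* allele switching ancestry after 740 bp);
* a population of tetraploid plants with known derived-haplotype dosage per
  gene and a per-plant meiotic stability probability driven by the genotype
  class at a causal gene (*ASY3* by default);
* per-site base counts at ~2000x amplicon depth with a symmetric sequencing
  error model;
* cell- and bivalent-level cytology tables (metaphase-I stability, chiasma
  zones, rDNA FISH classes, pachytene HEI10 focus counts).

All randomness flows from one integer seed through named
:class:`numpy.random.Generator` streams; per-plant substreams are derived
deterministically, so outputs are byte-identical across runs for a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .alleles import HaplotypeAllele, write_fasta

SV_PRESETS = ("none", "ASY3_TD", "ASY3_DEL", "ZYP1b_GC", "PRD3_chimera")
GENOTYPE_CLASSES = ("HOM_DERIVED", "HET", "HOM_ANCESTRAL")
BASES = ("A", "C", "G", "T")

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
_SAFE_CODONS = [c for c in _CODONS if c not in _STOPS]

#: AGAGA microhomology motif flanking the ASY3 structural-variant unit.
MICROHOMOLOGY_MOTIF = "AGAGA"
TD_UNIT_LENGTH = 78
ZYP1B_GC_TRACT = 1474
PRD3_JUNCTION = 740

POPULATIONS = ("LIC", "MAU", "MOD", "PIL", "SCB", "KAG", "ROK", "TBG", "SEN", "WEK")


class SizingError(ValueError):
    """cds_length too short to host the requested structural preset."""


# --------------------------------------------------------------------------
# gene specification


@dataclass(frozen=True)
class GeneSpec:
    """Gene-level facts driving allele-set construction."""

    gene_name: str
    cds_length: int
    n_diagnostic_sites: int = 10
    divergence_lyr_are: float = 0.02
    sv_preset: str = "none"

    def __post_init__(self) -> None:
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_name}: cds_length must be divisible by 3")
        if self.n_diagnostic_sites < 1:
            raise ValueError(f"{self.gene_name}: need >=1 diagnostic site")
        if not (0.0 < self.divergence_lyr_are < 1.0):
            raise ValueError(f"{self.gene_name}: divergence must be in (0,1)")
        if self.sv_preset not in SV_PRESETS:
            raise ValueError(f"{self.gene_name}: unknown sv_preset {self.sv_preset!r}")
        minima = {
            "ASY3_TD": 399,
            "ASY3_DEL": 399,
            "ZYP1b_GC": ZYP1B_GC_TRACT + 120,
            "PRD3_chimera": PRD3_JUNCTION + 120,
        }
        need = minima.get(self.sv_preset, 30)
        if self.cds_length < need:
            raise SizingError(
                f"{self.gene_name}: cds_length {self.cds_length} < {need} required "
                f"for preset {self.sv_preset}"
            )


#: Default gene panel: eight synaptonemal-complex-associated meiosis genes.
#: Lengths are plausible CDS sizes (divisible by 3), not the real genes'.
DEFAULT_GENES: dict[str, GeneSpec] = {
    "ASY1": GeneSpec("ASY1", 1791),
    "ASY3": GeneSpec("ASY3", 2382, sv_preset="ASY3_TD"),
    "PDS5b": GeneSpec("PDS5b", 3330),
    "PRD3": GeneSpec("PRD3", 1365, sv_preset="PRD3_chimera"),
    "REC8": GeneSpec("REC8", 1851),
    "SMC3": GeneSpec("SMC3", 3618),
    "ZYP1a": GeneSpec("ZYP1a", 2628),
    "ZYP1b": GeneSpec("ZYP1b", 2625, sv_preset="ZYP1b_GC"),
}


@dataclass(frozen=True)
class DiagnosticSiteTruth:
    """One derived-vs-ancestral diagnostic SNP (1-based position)."""

    position: int
    derived_base: str
    ancestral_base: str


@dataclass
class AlleleSet:
    """Alleles for one gene plus the diagnostic-site truth used to place reads.

    ``event`` records structural-preset metadata, including the clean
    reference/alternate pair that differs by the structural event alone (the
    input expected by the prefix/suffix SV detectors).
    """

    gene: str
    alleles: list[HaplotypeAllele]
    diag_sites: list[DiagnosticSiteTruth]
    event: dict | None = None

    def by_id(self, allele_id: str) -> HaplotypeAllele:
        for a in self.alleles:
            if a.allele_id == allele_id:
                return a
        raise KeyError(allele_id)


# --------------------------------------------------------------------------
# sequence construction helpers


def _gene_stream(name: str) -> int:
    return zlib.crc32(name.encode()) & 0x7FFFFFFF


def _rng_for(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *streams]))


def _random_cds(rng: np.random.Generator, length: int) -> list[str]:
    n_codons = length // 3
    idx = rng.integers(0, len(_SAFE_CODONS), size=n_codons - 2)
    codons = ["ATG"] + [_SAFE_CODONS[i] for i in idx] + ["TAA"]
    return list("".join(codons))


def _mutate(seq: list[str], pos0: int, rng: np.random.Generator) -> str:
    """Substitute the base at 0-based ``pos0``, avoiding in-frame stop codons."""
    old = seq[pos0]
    frame = pos0 % 3
    start = pos0 - frame
    for _ in range(16):
        new = BASES[rng.integers(0, 4)]
        if new == old:
            continue
        codon = seq[start : start + 3]
        codon[frame] = new
        if "".join(codon) not in _STOPS:
            return new
    # fall back deterministically
    for new in BASES:
        if new != old:
            codon = seq[start : start + 3]
            codon[frame] = new
            if "".join(codon) not in _STOPS:
                return new
    raise RuntimeError("unreachable")


def _sample_positions(
    rng: np.random.Generator, lo: int, hi: int, n: int, exclude: set[int]
) -> list[int]:
    """n distinct 0-based positions in [lo, hi) avoiding ``exclude``."""
    pool = np.array([p for p in range(lo, hi) if p not in exclude])
    if len(pool) < n:
        raise SizingError(f"cannot place {n} sites in [{lo},{hi}) after exclusions")
    picked = rng.choice(pool, size=n, replace=False)
    return sorted(int(p) for p in picked)


def _serine_unit_codons() -> list[str]:
    """26 codons (78 bp) of the ASY3 serine-rich unit.

    Starts AGA GAT so the unit begins with the AGAGA motif; 7 of the remaining
    24 codons are serine (TCT), the rest alanine (GCC), so one unit translates
    to 7 serines and the tandem duplication to 14.
    """
    fill = []
    for i in range(24):
        fill.append("TCT" if i % 3 == 0 and len([c for c in fill if c == "TCT"]) < 7 else "GCC")
    assert fill.count("TCT") == 7
    return ["AGA", "GAT"] + fill


def _asy3_backbone(rng: np.random.Generator, length: int) -> tuple[list[str], int]:
    """Lyrata ND backbone containing the serine-rich unit; returns (seq, u0).

    Layout (0-based): ``seq[u0:u0+78]`` is the unit (begins AGAGA), followed by
    AGAGA then a non-T base, so the junction microhomology is exactly AGAGA.
    The codon preceding the unit is GAA so the left flank shares nothing with
    the unit's tail (leftmost-placement recovery is unambiguous).
    """
    seq = _random_cds(rng, length)
    u0 = 3 * max(31, length // 12)
    if u0 + 78 + 6 > length - 3:
        u0 = 3 * ((length - 96) // 3)
    unit = list("".join(_serine_unit_codons()))
    seq[u0 - 3 : u0] = list("GAA")
    seq[u0 : u0 + 78] = unit
    seq[u0 + 78 : u0 + 83] = list(MICROHOMOLOGY_MOTIF)
    seq[u0 + 83] = "C"  # caps the junction microhomology at 5 bp
    return seq, u0


# --------------------------------------------------------------------------
# allele-set construction


def build_allele_set(spec: GeneSpec, seed: int) -> AlleleSet:
    """Build the per-gene allele set with diagnostic-site truth.

    Always returns at least a diploid *A. lyrata* reference, a diploid
    *A. arenosa* reference and a derived tetraploid allele; structural presets
    add the lesion described in the module docstring.
    """
    rng = _rng_for(seed, _gene_stream(spec.gene_name), 1)
    if spec.sv_preset == "none":
        return _build_plain(spec, rng)
    if spec.sv_preset in ("ASY3_TD", "ASY3_DEL"):
        return _build_asy3(spec, rng)
    if spec.sv_preset == "ZYP1b_GC":
        return _build_zyp1b(spec, rng)
    if spec.sv_preset == "PRD3_chimera":
        return _build_prd3(spec, rng)
    raise AssertionError(spec.sv_preset)


def _diverge(
    seq: list[str], positions: Sequence[int], rng: np.random.Generator
) -> list[str]:
    out = list(seq)
    for p in positions:
        out[p] = _mutate(out, p, rng)
    return out


def _build_plain(spec: GeneSpec, rng: np.random.Generator) -> AlleleSet:
    L = spec.cds_length
    ly = _random_cds(rng, L)
    n_div = max(1, round(spec.divergence_lyr_are * L))
    div_pos = _sample_positions(rng, 3, L - 3, n_div, set())
    ar = _diverge(ly, div_pos, rng)
    diag_pos = _sample_positions(rng, 3, L - 3, spec.n_diagnostic_sites, set(div_pos))
    derived = list(ly)
    sites = []
    for p in diag_pos:
        new = _mutate(derived, p, rng)
        sites.append(DiagnosticSiteTruth(p + 1, new, ly[p]))
        derived[p] = new
    g = spec.gene_name
    alleles = [
        HaplotypeAllele(g, f"{g}_ly2", "diploid_lyrata", "".join(ly), 2),
        HaplotypeAllele(g, f"{g}_ar2", "diploid_arenosa", "".join(ar), 2),
        HaplotypeAllele(g, f"{g}_4n", "derived_tetraploid", "".join(derived), 4),
    ]
    return AlleleSet(g, alleles, sites)


def _build_asy3(spec: GeneSpec, rng: np.random.Generator) -> AlleleSet:
    L = spec.cds_length
    nd, u0 = _asy3_backbone(rng, L)
    event_window = set(range(u0 - 6, u0 + 90))
    n_div = max(1, round(spec.divergence_lyr_are * L))
    div_pos = _sample_positions(rng, 3, L - 3, n_div, event_window)
    ar = _diverge(nd, div_pos, rng)

    unit = nd[u0 : u0 + TD_UNIT_LENGTH]
    td_clean = nd[:u0] + unit + nd[u0:]
    del_clean = nd[:u0] + nd[u0 + TD_UNIT_LENGTH :]

    # diagnostic SNPs strictly 5' of the event so the TD/DEL lesion region
    # stays clean in the marked derived allele
    diag_pos = _sample_positions(
        rng, 3, u0 - 9, spec.n_diagnostic_sites, set(div_pos)
    )
    derived = list(td_clean) if spec.sv_preset == "ASY3_TD" else list(nd)
    sites = []
    for p in diag_pos:
        new = _mutate(derived, p, rng)
        sites.append(DiagnosticSiteTruth(p + 1, new, nd[p]))
        derived[p] = new

    g = spec.gene_name
    nd_a = HaplotypeAllele(g, f"{g}_ND_ly2", "diploid_lyrata", "".join(nd), 2)
    alt_id = "TD" if spec.sv_preset == "ASY3_TD" else "DEL"
    alt_seq = td_clean if spec.sv_preset == "ASY3_TD" else del_clean
    alt_origin = "derived_tetraploid" if alt_id == "TD" else "diploid_lyrata"
    alt_a = HaplotypeAllele(
        g, f"{g}_{alt_id}", alt_origin, "".join(alt_seq), 4 if alt_id == "TD" else 2
    )
    alleles = [
        nd_a,
        HaplotypeAllele(g, f"{g}_ar2", "diploid_arenosa", "".join(ar), 2),
        alt_a,
        HaplotypeAllele(g, f"{g}_4n_marked", "derived_tetraploid", "".join(derived), 4),
    ]
    event = {
        "type": "tandem_duplication" if alt_id == "TD" else "deletion",
        "ref": nd_a,
        "alt": alt_a,
        "unit_start": u0 + 1,
        "unit_end": u0 + TD_UNIT_LENGTH,
        "unit_length": TD_UNIT_LENGTH,
        "microhomology": MICROHOMOLOGY_MOTIF,
        "serine_region_nd": (u0 + 1, u0 + TD_UNIT_LENGTH),
        "serine_region_td": (u0 + 1, u0 + 2 * TD_UNIT_LENGTH),
    }
    return AlleleSet(g, alleles, sites, event)


def structural_pair(spec: GeneSpec, seed: int) -> tuple[HaplotypeAllele, HaplotypeAllele]:
    """The clean (reference, alternate) pair for an SV preset.

    The pair differs by the structural event alone, the single-clean-event
    input assumed by the prefix/suffix detectors.
    """
    aset = build_allele_set(spec, seed)
    if aset.event is None or aset.event["type"] not in ("tandem_duplication", "deletion"):
        raise ValueError(f"{spec.gene_name}: preset {spec.sv_preset} has no SV pair")
    return aset.event["ref"], aset.event["alt"]


def _build_zyp1b(spec: GeneSpec, rng: np.random.Generator) -> AlleleSet:
    L = spec.cds_length
    b = _random_cds(rng, L)
    j0 = L - ZYP1B_GC_TRACT  # 0-based boundary: left = positions 1..j0
    n_div = max(4, round(spec.divergence_lyr_are * L))
    forced = [j0 - 1, j0]  # 1-based j0 and j0+1, straddling the junction
    div_pos = sorted(
        set(forced)
        | set(_sample_positions(rng, 3, L - 3, n_div - 2, set(forced)))
    )
    a = _diverge(b, div_pos, rng)
    query = b[:j0] + a[j0:]
    # derived-specific SNPs at paralog-agreeing columns, invisible to the
    # chimera objective
    agree = {p for p in range(3, L - 3) if a[p] == b[p]}
    near_junction = set(range(j0 - 6, j0 + 6))
    diag_pool = sorted(agree - near_junction)
    diag_pos = sorted(
        int(p)
        for p in rng.choice(np.array(diag_pool), spec.n_diagnostic_sites, replace=False)
    )
    sites = []
    for p in diag_pos:
        new = _mutate(query, p, rng)
        sites.append(DiagnosticSiteTruth(p + 1, new, b[p]))
        query[p] = new
    g = spec.gene_name
    pb = HaplotypeAllele(g, f"{g}_anc", "unknown", "".join(b), 4)
    pa = HaplotypeAllele(g, "ZYP1a_paralog", "unknown", "".join(a), 4)
    q = HaplotypeAllele(g, f"{g}_4n_GC", "derived_tetraploid", "".join(query), 4)
    event = {
        "type": "gene_conversion",
        "parent_a": pb,
        "parent_b": pa,
        "query": q,
        "breakpoint": j0,
        "tract_length": ZYP1B_GC_TRACT,
    }
    return AlleleSet(g, [pb, pa, q], sites, event)


def _build_prd3(spec: GeneSpec, rng: np.random.Generator) -> AlleleSet:
    L = spec.cds_length
    j = PRD3_JUNCTION  # 1-based: first j bases arenosa-like, rest lyrata-like
    ly = _random_cds(rng, L)
    left = sorted(
        set(_sample_positions(rng, 5, j - 2, 27, set())) | {j - 1}
    )  # 0-based; includes position 740
    right = sorted(
        set(_sample_positions(rng, j + 1, L - 3, 28, set())) | {j}
    )  # includes position 741
    div_pos = left + right
    ar = _diverge(ly, div_pos, rng)

    query = ar[:j] + ly[j:]
    # back-mutations giving the per-segment difference counts 7-vs-21 and
    # 5-vs-24; flip sites are isolated (non-adjacent in site order) and away
    # from the junction so the parsimony optimum is unique
    for i in (3, 6, 9, 12, 15, 18, 21):  # 0-based indices into `left`
        p = left[i]
        query[p] = ly[p]
    for i in (4, 8, 12, 16, 20):  # indices into `right`; right[0] = 741
        p = right[i]
        query[p] = ar[p]

    agree = {p for p in range(3, L - 3) if ar[p] == ly[p]}
    near_junction = set(range(j - 6, j + 6))
    diag_pool = sorted(agree - near_junction)
    diag_pos = sorted(
        int(p)
        for p in rng.choice(np.array(diag_pool), spec.n_diagnostic_sites, replace=False)
    )
    sites = []
    for p in diag_pos:
        new = _mutate(query, p, rng)
        sites.append(DiagnosticSiteTruth(p + 1, new, ly[p]))
        query[p] = new

    g = spec.gene_name
    aly = HaplotypeAllele(g, f"{g}_ly2", "diploid_lyrata", "".join(ly), 2)
    aar = HaplotypeAllele(g, f"{g}_ar2", "diploid_arenosa", "".join(ar), 2)
    q = HaplotypeAllele(g, f"{g}_chimera", "derived_tetraploid", "".join(query), 2)
    event = {
        "type": "chimera",
        "parent_a": aar,
        "parent_b": aly,
        "query": q,
        "breakpoint": j,
        "segment_diffs": ((7, 21), (5, 24)),
    }
    return AlleleSet(g, [aly, aar, q], sites, event)


# --------------------------------------------------------------------------
# population truth


@dataclass
class StabilityParams:
    """Logit-normal stability distributions per genotype class.

    Medians 0.889 (HOM_DERIVED) and 0.66 (HET) match the study's reported
    group medians; scales reproduce the reported IQR spread.  HOM_ANCESTRAL
    plants are rare in the study; they are given the HET scale around a lower
    median.
    """

    median: dict[str, float] = field(
        default_factory=lambda: {
            "HOM_DERIVED": 0.889,
            "HET": 0.66,
            "HOM_ANCESTRAL": 0.50,
        }
    )
    scale: dict[str, float] = field(
        default_factory=lambda: {"HOM_DERIVED": 0.8, "HET": 1.5, "HOM_ANCESTRAL": 1.5}
    )

    def draw(self, cls: str, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        z = rng.standard_normal(n)
        return expit(logit(self.median[cls]) + self.scale[cls] * z)


#: Genotype-class frequencies (HOM_DERIVED, HET, HOM_ANCESTRAL) per gene.
#: ASY3 reproduces the study's 41-vs-11 split at n=52; ZYP1b is heterozygous
#: in all populations; other genes are mostly fixed for the derived allele.
DEFAULT_CLASS_FREQS: dict[str, tuple[float, float, float]] = {
    "ASY1": (0.86, 0.12, 0.02),
    "ASY3": (41 / 52, 11 / 52, 0.0),
    "PDS5b": (0.85, 0.13, 0.02),
    "PRD3": (0.85, 0.13, 0.02),
    "REC8": (0.80, 0.17, 0.03),
    "SMC3": (0.75, 0.21, 0.04),
    "ZYP1a": (0.85, 0.13, 0.02),
    "ZYP1b": (0.0, 1.0, 0.0),
}

_DOSAGE_BY_CLASS = {"HOM_DERIVED": 4, "HOM_ANCESTRAL": 0}


@dataclass
class TruthTable:
    """Ground truth for a simulated population.

    ``plants``: plant_id, population, genotype class at the causal gene and
    true stability probability pi.  ``genotypes``: long table of true derived
    dosage (0-4) and genotype class per plant x gene.
    """

    plants: pd.DataFrame
    genotypes: pd.DataFrame
    causal_gene: str


def simulate_population(
    n_plants: int = 52,
    class_freqs: dict[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
    causal_gene: str = "ASY3",
    stability: StabilityParams | None = None,
) -> TruthTable:
    """Draw a tetraploid population with known dosages and stability truth.

    Plants are independent.  HET plants receive a dosage uniform on {1,2,3};
    stability pi is drawn from the causal gene's class-specific logit-normal
    distribution.
    """
    if n_plants <= 0:
        raise ValueError("n_plants must be positive")
    class_freqs = dict(class_freqs or DEFAULT_CLASS_FREQS)
    if causal_gene not in class_freqs:
        raise ValueError(f"causal gene {causal_gene!r} missing from class_freqs")
    for g, freqs in class_freqs.items():
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError(f"{g}: class frequencies must sum to 1")
    stability = stability or StabilityParams()

    rng = _rng_for(seed, 2)
    plant_ids = [f"P{i+1:03d}" for i in range(n_plants)]
    pops = rng.choice(np.array(POPULATIONS), size=n_plants)

    rows = []
    for g, freqs in class_freqs.items():
        cls = rng.choice(np.array(GENOTYPE_CLASSES), size=n_plants, p=np.array(freqs))
        dos = np.array(
            [_DOSAGE_BY_CLASS.get(c, 0) for c in cls]
        )
        het = cls == "HET"
        dos[het] = rng.integers(1, 4, size=int(het.sum()))
        for pid, c, d in zip(plant_ids, cls, dos):
            rows.append((pid, g, int(d), str(c)))
    genotypes = pd.DataFrame(rows, columns=["plant_id", "gene", "dosage", "genotype_class"])

    causal = genotypes[genotypes["gene"] == causal_gene].set_index("plant_id")
    pi = np.empty(n_plants)
    for i, pid in enumerate(plant_ids):
        cls = causal.loc[pid, "genotype_class"]
        pi[i] = stability.draw(cls, _rng_for(seed, 3, i))[0]
    plants = pd.DataFrame(
        {
            "plant_id": plant_ids,
            "population": pops,
            "causal_class": causal.loc[plant_ids, "genotype_class"].to_numpy(),
            "stability_pi": pi,
        }
    )
    return TruthTable(plants, genotypes, causal_gene)


# --------------------------------------------------------------------------
# read counts


def expected_derived_fraction(d: int | np.ndarray, error_rate: float) -> np.ndarray:
    """Expected derived-base read fraction for dosage d with error rate eps."""
    d = np.asarray(d, dtype=float)
    return (d / 4.0) * (1.0 - error_rate) + (1.0 - d / 4.0) * (error_rate / 3.0)


def simulate_read_counts(
    truth: TruthTable,
    sites_by_gene: dict[str, Sequence[DiagnosticSiteTruth]],
    depth: int = 2000,
    error_rate: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Per plant x gene x diagnostic-site base counts at fixed depth.

    At each site the four base probabilities are: derived base
    ``(d/4)(1-eps) + (1-d/4) eps/3``, ancestral base the mirror image, and
    eps/3 for each of the two remaining bases; counts are multinomial and sum
    to ``depth``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0.0 <= error_rate < 0.25):
        raise ValueError("error_rate must be in [0, 0.25)")
    base_idx = {b: i for i, b in enumerate(BASES)}
    geno = truth.genotypes.set_index(["plant_id", "gene"])["dosage"]
    rows = []
    for pi_idx, pid in enumerate(truth.plants["plant_id"]):
        rng = _rng_for(seed, 4, pi_idx)
        for gene, sites in sites_by_gene.items():
            d = int(geno.loc[(pid, gene)])
            p_derived = float(expected_derived_fraction(d, error_rate))
            p_ancestral = float(expected_derived_fraction(4 - d, error_rate))
            for s in sites:
                probs = np.full(4, error_rate / 3.0)
                probs[base_idx[s.derived_base]] = p_derived
                probs[base_idx[s.ancestral_base]] = p_ancestral
                probs /= probs.sum()
                counts = (
                    rng.multinomial(depth, probs) if depth > 0 else np.zeros(4, int)
                )
                rows.append((pid, gene, s.position, *counts.tolist(), int(counts.sum())))
    return pd.DataFrame(
        rows,
        columns=[
            "plant_id",
            "gene",
            "site",
            "count_A",
            "count_C",
            "count_G",
            "count_T",
            "depth",
        ],
    )


# --------------------------------------------------------------------------
# cytology


@dataclass
class CytoModelParams:
    """Rates of the metaphase-I/pachytene generative model.

    ``extra_rates`` are per-bivalent probabilities of one extra chiasma in the
    (second-arm distal, interstitial, proximal) zones beyond the obligate
    distal chiasma; they calibrate the group mean chiasma frequencies to
    1.52 (diploid), 1.12 (stable tetraploid) and 1.26 (unstable tetraploid).
    ``hei10_mu`` is the Poisson rate of extra HEI10 foci per bivalent beyond
    the obligate one (0.275 gives the reported 20.4 foci/cell).  ``rho``
    multiplies the odds that a 45S-bearing chromosome pair joins a multivalent
    (hence drops out of the scoreable set).  ``karyotype`` is the rDNA FISH
    composition of the 16 chromosome pairs (none, 5S only, 45S only, both).
    """

    extra_rates: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "diploid": (0.20, 0.20, 0.12),
            "stable_4n": (0.08, 0.03, 0.01),
            "unstable_4n": (0.12, 0.09, 0.05),
        }
    )
    hei10_mu: dict[str, float] = field(
        default_factory=lambda: {
            "diploid": 0.52,
            "stable_4n": 0.275,
            "unstable_4n": 0.40625,
        }
    )
    rho: float = 2.5
    karyotype: tuple[int, int, int, int] = (7, 5, 2, 2)
    stability: StabilityParams = field(default_factory=StabilityParams)

    def __post_init__(self) -> None:
        for grp, rates in self.extra_rates.items():
            if any(r < 0 for r in rates):
                raise ValueError(f"{grp}: extra-chiasma rates must be >= 0")
        if any(m < 0 for m in self.hei10_mu.values()):
            raise ValueError("HEI10 rates must be >= 0")
        if sum(self.karyotype) != 16:
            raise ValueError("karyotype counts must sum to 16")


RDNA_CLASSES = ("none", "fiveS", "fortyfiveS", "both")
_HAS_45S = {"fortyfiveS", "both"}


@dataclass
class CytologyTables:
    cells: pd.DataFrame
    bivalents: pd.DataFrame
    hei10: pd.DataFrame


def _bivalent_rows(
    rng: np.random.Generator,
    group: str,
    rdna: Sequence[str],
    params: CytoModelParams,
) -> list[tuple[int, int, int, int, int, int, str]]:
    """Zone counts (arm1/arm2 x distal/interstitial/proximal) per bivalent."""
    d2, ints, prox = params.extra_rates[group]
    out = []
    for cls in rdna:
        a1 = [1, 0, 0]  # obligate distal chiasma on arm 1
        a2 = [0, 0, 0]
        if rng.random() < d2:
            a2[0] += 1
        if rng.random() < ints:
            (a1 if rng.random() < 0.5 else a2)[1] += 1
        if rng.random() < prox:
            (a1 if rng.random() < 0.5 else a2)[2] += 1
        out.append((*a1, *a2, cls))
    return out


def _stable_karyotype(params: CytoModelParams) -> list[str]:
    out: list[str] = []
    for cls, n in zip(RDNA_CLASSES, params.karyotype):
        out.extend([cls] * n)
    return out


def simulate_stability_phenotype(
    truth: TruthTable, n_cells_per_plant: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Fast path: per-plant stable-cell counts, binomial(n_cells, pi)."""
    rng = _rng_for(seed, 5)
    n = len(truth.plants)
    stable = rng.binomial(n_cells_per_plant, truth.plants["stability_pi"].to_numpy())
    return pd.DataFrame(
        {
            "plant_id": truth.plants["plant_id"],
            "n_cells": n_cells_per_plant,
            "n_stable": stable,
            "stability_percent": 100.0 * stable / n_cells_per_plant,
        }
    )


def simulate_cytology(
    truth: TruthTable,
    params: CytoModelParams | None = None,
    n_cells_per_plant: int = 50,
    seed: int = 0,
) -> CytologyTables:
    """Cell-, bivalent- and focus-level cytology tables for a population.

    Each cell is stable with probability pi.  Stable cells expose all 16
    bivalents with the fixed rDNA karyotype; unstable cells expose 1-11
    scoreable bivalents drawn with 45S-bearing classes' odds divided by rho,
    and carry a multivalent.  HEI10 foci per cell are 16 + Poisson(16 mu) for
    the plant's meiotic group (stable_4n if pi >= 0.5 else unstable_4n).
    """
    if n_cells_per_plant < 1:
        raise ValueError("n_cells_per_plant must be >= 1")
    params = params or CytoModelParams()
    kary = np.array(params.karyotype, dtype=float)
    w_unstable = kary * np.array(
        [1.0 if c not in _HAS_45S else 1.0 / params.rho for c in RDNA_CLASSES]
    )
    w_unstable /= w_unstable.sum()
    stable_classes = _stable_karyotype(params)

    cells, bivs, foci = [], [], []
    for pi_idx, row in enumerate(truth.plants.itertuples()):
        rng = _rng_for(seed, 6, pi_idx)
        group = "stable_4n" if row.stability_pi >= 0.5 else "unstable_4n"
        mu = params.hei10_mu[group]
        for c in range(n_cells_per_plant):
            cid = f"c{c+1:03d}"
            is_stable = rng.random() < row.stability_pi
            if is_stable:
                rdna = stable_classes
                n_scored = 16
                brows = _bivalent_rows(rng, "stable_4n", rdna, params)
            else:
                n_scored = int(rng.integers(1, 12))
                rdna = [
                    RDNA_CLASSES[i]
                    for i in rng.choice(4, size=n_scored, p=w_unstable)
                ]
                brows = _bivalent_rows(rng, "unstable_4n", rdna, params)
            cells.append((row.plant_id, cid, n_scored, not is_stable))
            for b, br in enumerate(brows):
                bivs.append((row.plant_id, cid, f"b{b+1:02d}", *br))
            foci.append((row.plant_id, cid, int(16 + rng.poisson(16.0 * mu))))

    cells_df = pd.DataFrame(
        cells, columns=["plant_id", "cell_id", "n_bivalents_scored", "multivalent_present"]
    )
    biv_df = pd.DataFrame(
        bivs,
        columns=[
            "plant_id",
            "cell_id",
            "bivalent_id",
            "arm1_distal",
            "arm1_interstitial",
            "arm1_proximal",
            "arm2_distal",
            "arm2_interstitial",
            "arm2_proximal",
            "rdna_class",
        ],
    )
    hei10_df = pd.DataFrame(foci, columns=["plant_id", "cell_id", "foci"])
    return CytologyTables(cells_df, biv_df, hei10_df)


def simulate_group_bivalents(
    group: str,
    n_bivalents: int,
    params: CytoModelParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Bivalent-level table for one meiotic group (e.g. the diploid control)."""
    params = params or CytoModelParams()
    if group not in params.extra_rates:
        raise KeyError(group)
    rng = _rng_for(seed, 7, _gene_stream(group))
    rdna = [
        RDNA_CLASSES[i]
        for i in rng.choice(
            4, size=n_bivalents, p=np.array(params.karyotype) / 16.0
        )
    ]
    rows = _bivalent_rows(rng, group, rdna, params)
    return pd.DataFrame(
        [(group, f"b{i+1:04d}", *r) for i, r in enumerate(rows)],
        columns=[
            "group",
            "bivalent_id",
            "arm1_distal",
            "arm1_interstitial",
            "arm1_proximal",
            "arm2_distal",
            "arm2_interstitial",
            "arm2_proximal",
            "rdna_class",
        ],
    )


# --------------------------------------------------------------------------
# run writer


def write_run(
    outdir: str | Path,
    allele_sets: Sequence[AlleleSet],
    truth: TruthTable,
    counts: pd.DataFrame,
    cyto: CytologyTables,
) -> None:
    """Write a full synthetic run as plain-text files.

    Produces ``alleles.fasta``, ``snp_counts.tsv``, ``truth.tsv``,
    ``cells.tsv``, ``bivalents.tsv`` and ``hei10.tsv`` (TSV, header row,
    UTF-8, Unix newlines).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([a for s in allele_sets for a in s.alleles], outdir / "alleles.fasta")
    counts.to_csv(outdir / "snp_counts.tsv", sep="\t", index=False, lineterminator="\n")
    truth_long = truth.genotypes.merge(truth.plants, on="plant_id")
    truth_long.to_csv(outdir / "truth.tsv", sep="\t", index=False, lineterminator="\n")
    cyto.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False, lineterminator="\n")
    cyto.bivalents.to_csv(
        outdir / "bivalents.tsv", sep="\t", index=False, lineterminator="\n"
    )
    cyto.hei10.to_csv(outdir / "hei10.tsv", sep="\t", index=False, lineterminator="\n")
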