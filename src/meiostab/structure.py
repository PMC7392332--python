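"""Chimeric-allele and structural-variant characterization.

Chimeric (gene-converted) alleles are detected by a parsimony segmentation of
the query's per-site ancestry at columns where the two parental references
disagree: the objective is (mismatches to the assigned parent) + lambda x
(number of breakpoints), minimized exhaustively over 0, 1 or 2 breakpoints
placed between adjacent diagnostic sites.  Breakpoints are reported as the
1-based position of the last diagnostic site of the left segment (so "the
first 740 bp" reads off directly).

Tandem duplications and deletions are detected by longest-common-prefix /
-suffix comparison of an unaligned reference/alternate pair, valid for a
single clean event; junction microhomology (e.g. the AGAGA motif at the ASY3
serine-rich unit) is the longest exact match between the sequences flanking
the junction copies.  Ambiguous (rotationally equivalent) placements resolve
to the leftmost unit start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio.Seq import Seq

from .alleles import HaplotypeAllele

_UNINFORMATIVE = {"-", "N"}


class NotAssessableError(ValueError):
    """No diagnostic (parentA != parentB) sites to segment over."""


# --------------------------------------------------------------------------
# chimera / gene conversion


@dataclass(frozen=True)
class AncestrySite:
    position: int  # 1-based
    state: str  # 'A', 'B' or 'other'


@dataclass(frozen=True)
class ChimeraSegment:
    start: int  # 1-based inclusive
    end: int
    parent: str  # 'A' or 'B'
    diffs_vs_a: int
    diffs_vs_b: int
    n_sites: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ChimeraResult:
    n_breakpoints: int
    breakpoint_positions: list[int]
    segments: list[ChimeraSegment]
    total_mismatch: int
    objective: float
    ancestry: list[AncestrySite] = field(repr=False, default_factory=list)


def _ancestry_vector(
    query: str, a: str, b: str
) -> list[AncestrySite]:
    sites = []
    for i, (q, x, y) in enumerate(zip(query, a, b)):
        if x == y or {q, x, y} & _UNINFORMATIVE:
            continue
        state = "A" if q == x else ("B" if q == y else "other")
        sites.append(AncestrySite(i + 1, state))
    return sites


def detect_chimera(
    query: HaplotypeAllele,
    parent_a: HaplotypeAllele,
    parent_b: HaplotypeAllele,
    penalty: float = 2.0,
    max_breakpoints: int = 2,
) -> ChimeraResult:
    """Parsimony ancestry segmentation of ``query`` against two parents.

    All three sequences must be length-aligned.  All segmentations with up to
    ``max_breakpoints`` breakpoints between adjacent diagnostic sites are
    enumerated; the minimum of mismatches + penalty x breakpoints is returned
    (ties broken toward fewer, then earlier, breakpoints).  Per-segment counts
    of differences to each parent ("x vs y SNPs") are emitted.
    """
    L = len(query)
    if len(parent_a) != L or len(parent_b) != L:
        raise ValueError("query and parents must be length-aligned")
    sites = _ancestry_vector(query.sequence, parent_a.sequence, parent_b.sequence)
    m = len(sites)
    if m == 0:
        raise NotAssessableError("no diagnostic sites between the parents")

    # prefix counts of mismatches if a site range is assigned to A or B
    mis_a = np.cumsum([0] + [s.state != "A" for s in sites])
    mis_b = np.cumsum([0] + [s.state != "B" for s in sites])

    def seg_cost(i: int, j: int) -> tuple[int, str]:
        """Min mismatches and parent for sites[i:j]."""
        ca = int(mis_a[j] - mis_a[i])
        cb = int(mis_b[j] - mis_b[i])
        return (ca, "A") if ca <= cb else (cb, "B")

    best: tuple[float, int, tuple[int, ...]] | None = None
    for n_bp in range(min(max_breakpoints, m - 1) + 1):
        for cuts in combinations(range(1, m), n_bp):
            bounds = (0, *cuts, m)
            cost = sum(
                seg_cost(bounds[i], bounds[i + 1])[0] for i in range(len(bounds) - 1)
            )
            obj = cost + penalty * n_bp
            key = (obj, n_bp, cuts)
            if best is None or key < best:
                best = key
    assert best is not None
    obj, n_bp, cuts = best
    bounds = (0, *cuts, m)
    segments = []
    total_mis = 0
    for k in range(len(bounds) - 1):
        i, j = bounds[k], bounds[k + 1]
        cost, parent = seg_cost(i, j)
        total_mis += cost
        start = 1 if k == 0 else sites[i - 1].position + 1
        end = L if k == len(bounds) - 2 else sites[j - 1].position
        segments.append(
            ChimeraSegment(
                start,
                end,
                parent,
                int(mis_a[j] - mis_a[i]),
                int(mis_b[j] - mis_b[i]),
                j - i,
            )
        )
    bp_positions = [sites[c - 1].position for c in cuts]
    return ChimeraResult(n_bp, bp_positions, segments, total_mis, float(obj), sites)


# --------------------------------------------------------------------------
# tandem duplication / deletion


@dataclass
class SVResult:
    sv_type: str  # tandem_duplication | deletion | none
    unit_start: int = 0  # 1-based on the reference allele
    unit_end: int = 0
    unit_length: int = 0
    in_frame: bool = False
    microhomology: str = ""
    microhomology_length: int = 0
    diagnostics: str = ""


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def _junction_microhomology(ref: str, k: int, d: int, min_mh: int) -> tuple[str, int]:
    """Longest flank match at a unit ``ref[k:k+d]``; empty below ``min_mh``."""
    unit = ref[k : k + d]
    right = _lcp(unit, ref[k + d :])
    left = _lcs(unit, ref[:k])
    if max(right, left) < min_mh:
        return "", 0
    if right >= left:
        return unit[:right], right
    return unit[-left:], left


def _locate_indel(longer: str, shorter: str) -> tuple[int, int] | None:
    """Leftmost (k, d) such that longer = shorter[:k] + block + shorter[k:]."""
    d = len(longer) - len(shorter)
    lcp = _lcp(longer, shorter)
    lcs = _lcs(longer, shorter)
    k = max(0, len(longer) - d - lcs)
    if k > lcp:
        return None
    return k, d


def detect_tandem_duplication(
    ref: HaplotypeAllele, alt: HaplotypeAllele, min_microhomology: int = 3
) -> SVResult:
    """Detect a single clean tandem duplication of ``ref`` sequence in ``alt``.

    The inserted block must equal the adjacent reference block (a tandem
    copy); otherwise ``sv_type='none'`` with diagnostics.  ``in_frame`` is the
    unit length mod 3 test (CDS input).
    """
    r, a = ref.sequence, alt.sequence
    if a == r:
        return SVResult("none", diagnostics="sequences identical")
    if len(a) <= len(r):
        return SVResult("none", diagnostics="alternate not longer than reference")
    loc = _locate_indel(a, r)
    if loc is None:
        return SVResult("none", diagnostics="not a single clean insertion")
    k, d = loc
    ins = a[k : k + d]
    if r[k : k + d] != ins:
        return SVResult(
            "none", diagnostics=f"inserted {d} bp at ref position {k + 1} is not a tandem copy"
        )
    mh, mh_len = _junction_microhomology(r, k, d, min_microhomology)
    return SVResult(
        "tandem_duplication",
        unit_start=k + 1,
        unit_end=k + d,
        unit_length=d,
        in_frame=d % 3 == 0,
        microhomology=mh,
        microhomology_length=mh_len,
    )


def detect_deletion(
    ref: HaplotypeAllele, alt: HaplotypeAllele, min_microhomology: int = 3
) -> SVResult:
    """Detect a single clean deletion of a ``ref`` block in ``alt`` (mirror of
    :func:`detect_tandem_duplication`; the deleted block is located on the
    reference, leftmost placement)."""
    r, a = ref.sequence, alt.sequence
    if a == r:
        return SVResult("none", diagnostics="sequences identical")
    if len(a) >= len(r):
        return SVResult("none", diagnostics="alternate not shorter than reference")
    loc = _locate_indel(r, a)
    if loc is None:
        return SVResult("none", diagnostics="not a single clean deletion")
    k, d = loc
    mh, mh_len = _junction_microhomology(r, k, d, min_microhomology)
    return SVResult(
        "deletion",
        unit_start=k + 1,
        unit_end=k + d,
        unit_length=d,
        in_frame=d % 3 == 0,
        microhomology=mh,
        microhomology_length=mh_len,
    )


def apply_deletion(sequence: str, start: int, length: int) -> str:
    """Remove ``length`` bases starting at 1-based ``start`` (test helper and
    round-trip oracle partner of :func:`detect_deletion`)."""
    if start < 1 or start + length - 1 > len(sequence):
        raise ValueError("deletion outside sequence")
    return sequence[: start - 1] + sequence[start - 1 + length :]


def apply_tandem_duplication(sequence: str, start: int, length: int) -> str:
    """Duplicate ``length`` bases starting at 1-based ``start`` in tandem."""
    if start < 1 or start + length - 1 > len(sequence):
        raise ValueError("unit outside sequence")
    unit = sequence[start - 1 : start - 1 + length]
    return sequence[: start - 1] + unit + sequence[start - 1 :]


# --------------------------------------------------------------------------
# protein-level metrics


@dataclass
class SerineMetrics:
    n_serine: int
    n_threonine: int
    n_residues: int
    internal_stop: bool


def region_serine_metrics(
    cds: HaplotypeAllele | str, start: int, end: int, frame_offset: int = 0
) -> SerineMetrics:
    """Serine/threonine counts in the translation of a CDS region.

    ``start``/``end`` are 1-based inclusive on the nucleotide sequence;
    ``frame_offset`` (0-2) skips leading bases when the region does not start
    on a codon boundary.  Translation uses the standard genetic code; an
    internal stop is flagged and counting proceeds up to it.
    """
    seq = cds.sequence if isinstance(cds, HaplotypeAllele) else cds.upper()
    if not (1 <= start <= end <= len(seq)):
        raise ValueError("region outside CDS")
    region = seq[start - 1 + frame_offset : end]
    region = region[: len(region) - len(region) % 3]
    aa = str(Seq(region).translate())
    internal_stop = "*" in aa[:-1] if aa.endswith("*") else "*" in aa
    if "*" in aa:
        aa = aa[: aa.index("*")]
    return SerineMetrics(aa.count("S"), aa.count("T"), len(aa), internal_stop)


def tally_substitutions(aln_a: str, aln_b: str) -> tuple[int, int, int]:
    """Residue substitutions between two aligned proteins.

    Returns (n_substitutions, n_ST_gain, n_ST_loss): gains are columns where B
    carries S/T and A does not; losses the mirror.  Gap columns are excluded.
    """
    if len(aln_a) != len(aln_b):
        raise ValueError("aligned proteins must have equal length")
    n_sub = gain = loss = 0
    for x, y in zip(aln_a.upper(), aln_b.upper()):
        if x == "-" or y == "-":
            continue
        if x != y:
            n_sub += 1
            if y in "ST" and x not in "ST":
                gain += 1
            if x in "ST" and y not in "ST":
                loss += 1
    return n_sub, gain, loss
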