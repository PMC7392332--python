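"""Derived-haplotype dosage calling from diagnostic-site read counts.

A tetraploid carrying d copies of the derived haplotype (d in 0..4) is
expected to show the derived base in a fraction

    p_d = (d/4)(1 - eps) + (1 - d/4) eps/3

of reads at each diagnostic site, where eps is the per-base sequencing error
rate (symmetric substitution, eps/3 to each wrong base).  The caller treats
sites as independent and maximizes the summed binomial log-likelihood
sum_i log Binomial(k_i; n_i, p_d) over d, which formalizes proportion-based
("SNP frequency") genotyping while quantifying confidence.

Genotype classes: d=4 -> HOM_DERIVED, d=0 -> HOM_ANCESTRAL, 1-3 -> HET.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .simulate import DiagnosticSiteTruth, expected_derived_fraction

DOSAGES = np.arange(5)

#: Geneious's SNP-calling minimum variant frequency; used as an informational
#: flag only, because a hard filter at 0.25 would erase legitimate dosage-1
#: signal whose expected derived fraction is exactly 0.25.
MIN_VARIANT_FREQUENCY = 0.25


class InsufficientSitesError(ValueError):
    """Fewer usable diagnostic sites than ``min_sites``."""


def classify_genotype(dosage: int) -> str:
    if dosage == 4:
        return "HOM_DERIVED"
    if dosage == 0:
        return "HOM_ANCESTRAL"
    if dosage in (1, 2, 3):
        return "HET"
    raise ValueError(f"dosage must be 0..4, got {dosage}")


def site_frequencies(
    counts: pd.DataFrame,
    sites_by_gene: Mapping[str, Sequence[DiagnosticSiteTruth]],
    min_depth: int = 50,
) -> pd.DataFrame:
    """Per-site derived-base fractions with QC flags.

    Sites with depth below ``min_depth`` are flagged ``low_depth`` and marked
    unusable; expected sites absent from the counts are emitted with flag
    ``missing``.  Sites whose minor-base fraction falls below 0.25 get the
    informational ``below_min_variant_freq`` flag (the SNP-caller threshold
    the study used; not applied as a filter here).
    """
    indexed = counts.set_index(["plant_id", "gene", "site"], drop=False)
    rows = []
    plants = counts["plant_id"].unique()
    for pid in plants:
        for gene, sites in sites_by_gene.items():
            for s in sites:
                key = (pid, gene, s.position)
                flags = []
                if key not in indexed.index:
                    rows.append((pid, gene, s.position, 0, 0, np.nan, False, "missing"))
                    continue
                rec = indexed.loc[key]
                depth = int(rec["depth"])
                k = int(rec[f"count_{s.derived_base}"])
                frac = k / depth if depth > 0 else np.nan
                usable = True
                if depth < min_depth:
                    flags.append("low_depth")
                    usable = False
                if depth > 0 and min(frac, 1.0 - frac) < MIN_VARIANT_FREQUENCY:
                    flags.append("below_min_variant_freq")
                rows.append((pid, gene, s.position, k, depth, frac, usable, ";".join(flags)))
    return pd.DataFrame(
        rows,
        columns=[
            "plant_id",
            "gene",
            "site",
            "derived_count",
            "depth",
            "fraction",
            "usable",
            "flags",
        ],
    )


@dataclass
class DosageCall:
    plant_id: str
    gene: str
    dosage: int
    log_likelihoods: np.ndarray  # d = 0..4
    genotype_class: str
    n_sites_used: int
    qc_flags: list[str] = field(default_factory=list)


def call_dosage(
    derived_counts: Sequence[int],
    depths: Sequence[int],
    error_rate: float = 0.01,
    min_sites: int = 2,
    plant_id: str = "",
    gene: str = "",
) -> DosageCall:
    """Maximum-likelihood dosage from per-site derived counts and depths.

    Ties in the log-likelihood (within 1e-9 relative) are broken toward the
    heterozygous dosage nearest 2 and flagged ``ambiguous``.
    """
    if not (0.0 <= error_rate < 0.25):
        raise ValueError("error_rate must be in [0, 0.25)")
    k = np.asarray(derived_counts, dtype=int)
    n = np.asarray(depths, dtype=int)
    if k.shape != n.shape:
        raise ValueError("derived_counts and depths must have equal length")
    if len(k) < min_sites:
        raise InsufficientSitesError(
            f"{plant_id}/{gene}: {len(k)} usable sites < min_sites={min_sites}"
        )
    p = expected_derived_fraction(DOSAGES, error_rate)
    ll = binom.logpmf(k[:, None], n[:, None], p[None, :]).sum(axis=0)
    best = ll.max()
    tol = 1e-9 * max(1.0, abs(best))
    cands = [int(d) for d in DOSAGES if ll[d] >= best - tol]
    dosage = min(cands, key=lambda d: (abs(d - 2), d))
    flags = ["ambiguous"] if len(cands) > 1 else []
    return DosageCall(
        plant_id, gene, dosage, ll, classify_genotype(dosage), len(k), flags
    )


class DosageModel:
    """Binomial maximum-likelihood dosage model over a count table.

    Parameters
    ----------
    counts : DataFrame with columns plant_id, gene, site, count_A..count_T,
        depth (the ``snp_counts.tsv`` layout).
    sites : mapping gene -> sequence of diagnostic sites giving the derived
        (and ancestral) base per 1-based position.
    error_rate : symmetric per-base sequencing error rate eps.
    min_depth : sites below this depth are excluded and flagged.
    min_sites : minimum usable sites required to call a plant x gene.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        sites: Mapping[str, Sequence[DiagnosticSiteTruth]],
        error_rate: float = 0.01,
        min_depth: int = 50,
        min_sites: int = 2,
    ) -> None:
        if not (0.0 <= error_rate < 0.25):
            raise ValueError("error_rate must be in [0, 0.25)")
        self.counts = counts
        self.sites = sites
        self.error_rate = error_rate
        self.min_depth = min_depth
        self.min_sites = min_sites

    def fit(self) -> "DosageResults":
        freqs = site_frequencies(self.counts, self.sites, self.min_depth)
        rows = []
        for (pid, gene), grp in freqs.groupby(["plant_id", "gene"], sort=False):
            usable = grp[grp["usable"]]
            flags = sorted(
                {f for fl in grp["flags"] if fl for f in fl.split(";")}
            )
            try:
                call = call_dosage(
                    usable["derived_count"].to_numpy(),
                    usable["depth"].to_numpy(),
                    self.error_rate,
                    self.min_sites,
                    plant_id=str(pid),
                    gene=str(gene),
                )
            except InsufficientSitesError:
                rows.append(
                    (pid, gene, pd.NA, pd.NA, *[np.nan] * 5, len(usable),
                     ";".join(sorted(set(flags) | {"insufficient_sites"})))
                )
                continue
            all_flags = sorted(set(flags) | set(call.qc_flags))
            rows.append(
                (
                    pid,
                    gene,
                    call.dosage,
                    call.genotype_class,
                    *call.log_likelihoods.tolist(),
                    call.n_sites_used,
                    ";".join(all_flags),
                )
            )
        calls = pd.DataFrame(
            rows,
            columns=[
                "plant_id",
                "gene",
                "dosage",
                "genotype_class",
                "loglik_d0",
                "loglik_d1",
                "loglik_d2",
                "loglik_d3",
                "loglik_d4",
                "n_sites",
                "flags",
            ],
        )
        return DosageResults(self, calls, freqs)


@dataclass
class DosageResults:
    """Fitted dosage calls with per-site QC; ``calls`` is the genotypes table."""

    model: DosageModel
    calls: pd.DataFrame
    site_table: pd.DataFrame

    def summary(self) -> str:
        ok = self.calls.dropna(subset=["dosage"])
        lines = [
            "Dosage calls (binomial ML over diagnostic sites)",
            f"  plants x genes called : {len(ok)} of {len(self.calls)}",
            f"  error rate eps        : {self.model.error_rate}",
            f"  min depth / min sites : {self.model.min_depth} / {self.model.min_sites}",
            "",
            "  genotype class counts per gene:",
        ]
        tab = (
            ok.groupby(["gene", "genotype_class"]).size().unstack(fill_value=0)
        )
        lines.append(tab.to_string())
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t", index=False, lineterminator="\n")
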