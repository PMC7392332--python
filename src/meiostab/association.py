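"""Genotype-phenotype association of meiotic stability.

For each gene, plants are grouped by genotype class (homozygous derived,
heterozygous, homozygous ancestral) and per-plant stability percentages are
compared between classes with two-sided Mann-Whitney-Wilcoxon rank-sum tests
(exact when the combined sample size is <= 16 with no ties, otherwise the
normal approximation with tie and continuity corrections), Bonferroni-adjusted
across the family of pairwise tests.  Genes with a single observed class
(e.g. a gene heterozygous in every plant) are skipped with a logged reason.

The model object follows the statsmodels convention: build
:class:`StabilityAssociation` from a long data frame, call :meth:`fit`, and
read estimates off the returned results object (``summary()``, ``table``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

CLASS_ORDER = ("HOM_DERIVED", "HET", "HOM_ANCESTRAL")


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of the U null distribution when n1 + n2 <= 16 and
    there are no ties; otherwise the normal approximation with midranks, tie
    correction and continuity correction.  Returns (U for sample_a, p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size + b.size <= 16 and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(1.0, res.pvalue))


def adjust_bonferroni(p_values: Sequence[float], family_size: int) -> np.ndarray:
    """p_adj = min(1, m * p); order-preserving, idempotent at m = 1."""
    p = np.asarray(p_values, dtype=float)
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    if family_size < p.size:
        raise ValueError("family size smaller than number of p-values")
    return np.minimum(1.0, family_size * p)


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    return float(q3 - q1)


@dataclass
class AssociationResult:
    gene: str
    comparison: str
    class1: str
    class2: str
    n1: int
    n2: int
    median1: float
    median2: float
    iqr1: float
    iqr2: float
    u_statistic: float
    p_raw: float
    p_adjusted: float = np.nan
    family_size: int = 0


def associate_gene(
    stability: Sequence[float],
    genotype_class: Sequence[str],
    gene: str,
) -> tuple[list[AssociationResult], str | None]:
    """All pairwise class comparisons for one gene.

    Returns the comparison list (p_adjusted unset until the family size is
    known) and a skip reason when fewer than two classes are observed.
    """
    stab = np.asarray(stability, dtype=float)
    cls = np.asarray(genotype_class)
    if stab.size != cls.size:
        raise ValueError("stability and genotype_class lengths differ")
    present = [c for c in CLASS_ORDER if (cls == c).any()]
    if len(present) < 2:
        only = present[0] if present else "none"
        return [], f"single genotype class observed ({only}); not testable"
    out = []
    for i, c1 in enumerate(present):
        for c2 in present[i + 1 :]:
            x, y = stab[cls == c1], stab[cls == c2]
            u, p = rank_sum_test(x, y)
            out.append(
                AssociationResult(
                    gene,
                    f"{c1} vs {c2}",
                    c1,
                    c2,
                    len(x),
                    len(y),
                    float(np.median(x)),
                    float(np.median(y)),
                    _iqr(x),
                    _iqr(y),
                    u,
                    p,
                )
            )
    return out, None


class StabilityAssociation:
    """Rank-sum association of per-plant stability with genotype class.

    Parameters
    ----------
    data : long DataFrame with one row per plant x gene and columns
        ``plant_id``, ``gene``, ``genotype_class``, ``stability_percent``.
    family_size : Bonferroni family; defaults to the total number of pairwise
        tests across all testable genes in the data.
    """

    def __init__(self, data: pd.DataFrame, family_size: int | None = None) -> None:
        required = {"plant_id", "gene", "genotype_class", "stability_percent"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data missing columns: {sorted(missing)}")
        self.data = data.dropna(subset=["genotype_class", "stability_percent"]).copy()
        self.family_size = family_size

    @classmethod
    def from_dataframe(
        cls,
        genotypes: pd.DataFrame,
        phenotypes: pd.DataFrame,
        family_size: int | None = None,
    ) -> "StabilityAssociation":
        """Join a genotypes table (plant_id, gene, genotype_class) with a
        per-plant phenotype table (plant_id, stability_percent)."""
        data = genotypes.merge(
            phenotypes[["plant_id", "stability_percent"]], on="plant_id", how="inner"
        )
        return cls(data, family_size)

    def fit(self) -> "StabilityAssociationResults":
        per_gene: list[AssociationResult] = []
        skipped: dict[str, str] = {}
        for gene, grp in self.data.groupby("gene", sort=True):
            results, reason = associate_gene(
                grp["stability_percent"].to_numpy(),
                grp["genotype_class"].to_numpy(),
                str(gene),
            )
            if reason is not None:
                skipped[str(gene)] = reason
            per_gene.extend(results)
        m = self.family_size if self.family_size is not None else max(1, len(per_gene))
        if per_gene:
            adj = adjust_bonferroni([r.p_raw for r in per_gene], m)
            for r, pa in zip(per_gene, adj):
                r.p_adjusted = float(pa)
                r.family_size = m
        return StabilityAssociationResults(self, per_gene, skipped, m)


@dataclass
class StabilityAssociationResults:
    """Fitted association results; ``table`` mirrors the per-gene report."""

    model: StabilityAssociation
    results: list[AssociationResult]
    skipped: dict[str, str]
    family_size: int

    @property
    def table(self) -> pd.DataFrame:
        cols = [
            "gene",
            "comparison",
            "n1",
            "n2",
            "median1",
            "median2",
            "iqr1",
            "iqr2",
            "u_statistic",
            "p_raw",
            "p_adjusted",
            "family_size",
        ]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.results], columns=cols)

    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            "Meiotic stability ~ genotype class (pairwise Mann-Whitney-Wilcoxon,",
            f"Bonferroni family m = {self.family_size}, two-sided)",
            "=" * 78,
        ]
        if self.results:
            t = self.table.copy()
            for c in ("median1", "median2", "iqr1", "iqr2", "u_statistic"):
                t[c] = t[c].map(lambda v: f"{v:.1f}")
            for c in ("p_raw", "p_adjusted"):
                t[c] = t[c].map(lambda v: f"{v:.4g}")
            lines.append(t.to_string(index=False))
            sig = [r for r in self.results if r.p_adjusted < alpha]
            lines.append("-" * 78)
            if sig:
                lines.append(
                    "significant after Bonferroni (alpha=%.2g): %s"
                    % (alpha, ", ".join(f"{r.gene} ({r.comparison})" for r in sig))
                )
            else:
                lines.append(f"no comparison significant after Bonferroni (alpha={alpha:g})")
        else:
            lines.append("no testable genes")
        for gene, reason in sorted(self.skipped.items()):
            lines.append(f"skipped {gene}: {reason}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Strip plot of per-plant stability by genotype class per gene."""
        import matplotlib.pyplot as plt

        data = self.model.data
        genes = sorted(data["gene"].unique())
        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * len(genes) + 2, 4))
        colors = {"HOM_DERIVED": "C0", "HET": "C1", "HOM_ANCESTRAL": "C2"}
        rng = np.random.default_rng(0)
        for gi, gene in enumerate(genes):
            grp = data[data["gene"] == gene]
            for ci, cls in enumerate(CLASS_ORDER):
                y = grp.loc[grp["genotype_class"] == cls, "stability_percent"]
                if y.empty:
                    continue
                x = gi + (ci - 1) * 0.25 + rng.uniform(-0.06, 0.06, len(y))
                ax.scatter(x, y, s=12, color=colors[cls], alpha=0.7,
                           label=cls if gi == 0 else None)
        ax.set_xticks(range(len(genes)), genes, rotation=45)
        ax.set_ylabel("meiotic stability (%)")
        ax.legend(frameon=False, fontsize=8)
        return ax


def build_report(
    association: StabilityAssociationResults,
    cytology_summary: pd.DataFrame | None,
    dosage_calls: pd.DataFrame | None,
    outdir: str | Path,
) -> dict:
    """Machine-readable JSON + TSV run report.

    Includes per-gene class counts, the long (plant, gene, class, stability)
    table, all pairwise test results, skipped-gene reasons and QC flags.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = association.model.data
    class_counts = {
        str(g): grp["genotype_class"].value_counts().to_dict()
        for g, grp in data.groupby("gene")
    }
    qc_flags = {}
    if dosage_calls is not None and "flags" in dosage_calls.columns:
        flagged = dosage_calls[dosage_calls["flags"].fillna("") != ""]
        qc_flags = {
            f"{r.plant_id}/{r.gene}": r.flags for r in flagged.itertuples()
        }
    report = {
        "n_plants": int(data["plant_id"].nunique()),
        "n_genes": int(data["gene"].nunique()),
        "family_size": association.family_size,
        "class_counts": class_counts,
        "tests": [
            {k: (v.item() if isinstance(v, np.generic) else v) for k, v in vars(r).items()}
            for r in association.results
        ],
        "skipped_genes": association.skipped or {},
        "qc_flags": qc_flags,
    }
    if not association.results:
        report["note"] = "no testable genes"
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    association.table.to_csv(outdir / "association.tsv", sep="\t", index=False, lineterminator="\n")
    data[["plant_id", "gene", "genotype_class", "stability_percent"]].to_csv(
        outdir / "stability_long.tsv", sep="\t", index=False, lineterminator="\n"
    )
    if cytology_summary is not None:
        cytology_summary.to_csv(
            outdir / "cytology_summary.tsv", sep="\t", index=False, lineterminator="\n"
        )
    return report
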