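"""Metaphase-I cytology statistics.

Computes per-plant stability (percent of nuclei showing 16 individual
bivalents and no multivalent), rod/ring bivalent classification, chiasma
frequency and zone summaries, random grouping of scoreable bivalents from
unstable cells into pseudo-nuclei of 16, the chi-square test of rDNA
FISH-class representation against the karyotype, and HEI10 focus summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

ZONES = ("distal", "interstitial", "proximal")
_ARM_COLS = [f"arm{a}_{z}" for a in (1, 2) for z in ZONES]


def round_half_away(x: float, ndigits: int) -> float:
    """Decimal rounding, halves away from zero (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def stability_summary(cells: pd.DataFrame) -> pd.DataFrame:
    """Percent stable nuclei per plant.

    A nucleus is stable iff all 16 bivalents were scored individually and no
    multivalent was present.
    """
    if cells.empty:
        raise ValueError("no cells")
    df = cells.copy()
    df["stable"] = (df["n_bivalents_scored"] == 16) & (~df["multivalent_present"].astype(bool))
    out = df.groupby("plant_id", as_index=False).agg(
        n_cells=("stable", "size"), n_stable=("stable", "sum")
    )
    out["stability_percent"] = 100.0 * out["n_stable"] / out["n_cells"]
    return out


def classify_bivalent(record: pd.Series | dict) -> str:
    """'ring' iff both arms carry at least one chiasma, else 'rod'."""
    arm1 = sum(record[f"arm1_{z}"] for z in ZONES)
    arm2 = sum(record[f"arm2_{z}"] for z in ZONES)
    if arm1 + arm2 == 0:
        raise ValueError("bivalent with zero chiasmata")
    return "ring" if arm1 >= 1 and arm2 >= 1 else "rod"


def chiasma_summary(bivalents: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Chiasma frequency mean +/- sd and per-zone per-bivalent frequencies.

    The chiasma count of a bivalent is the sum of its zone counts over both
    arms; zone frequencies are mean counts per bivalent (both arms pooled).
    """
    if bivalents.empty:
        raise ValueError("no bivalents")
    df = bivalents.copy()
    df["chiasmata"] = df[_ARM_COLS].sum(axis=1)
    for z in ZONES:
        df[z] = df[f"arm1_{z}"] + df[f"arm2_{z}"]
    out = df.groupby(group_col, as_index=False).agg(
        n_bivalents=("chiasmata", "size"),
        mean_chiasmata=("chiasmata", "mean"),
        sd_chiasmata=("chiasmata", lambda s: s.std(ddof=1)),
        **{f"freq_{z}": (z, "mean") for z in ZONES},
    )
    return out


def group_pseudo_nuclei(
    bivalents: pd.DataFrame, seed: int = 0
) -> tuple[list[pd.DataFrame], int]:
    """Randomly group scoreable bivalents into pseudo-nuclei of 16.

    Returns the list of groups and the number of remainder bivalents dropped
    (the shuffle is seeded; same seed, same grouping).
    """
    n = len(bivalents)
    if n < 16:
        raise ValueError(f"need >=16 bivalents, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_groups = n // 16
    groups = [
        bivalents.iloc[order[i * 16 : (i + 1) * 16]].reset_index(drop=True)
        for i in range(n_groups)
    ]
    return groups, n - 16 * n_groups


@dataclass
class Chi2Result:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    observed: np.ndarray


def rdna_representation_test(
    observed, karyotype: tuple[int, int, int, int] = (7, 5, 2, 2)
) -> Chi2Result:
    """Pearson chi-square of rDNA-class counts against karyotype proportions.

    Expected counts are total x karyotype_j / 16 *unrounded*: with the
    study's observed counts (46, 21, 6, 4) this reproduces chi2 = 9.54 (df 3),
    whereas pre-rounded expected values (34, 24, 9.5, 9.5) give ~9.08.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (4,):
        raise ValueError("need 4 observed counts")
    if sum(karyotype) != 16:
        raise ValueError("karyotype must sum to 16")
    total = obs.sum()
    if total <= 0:
        raise ValueError("zero total observed count")
    expected = total * np.asarray(karyotype, dtype=float) / 16.0
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    return Chi2Result(chi2, df, float(chi2_dist.sf(chi2, df)), expected, obs)


@dataclass
class Hei10Summary:
    plant_id: str
    n_cells: int
    mean_per_cell: float
    mean_per_bivalent: float  # unrounded, = mean_per_cell / 16
    mean_per_bivalent_2dp: float


def foci_per_bivalent(mean_per_cell: float, ndigits: int = 2) -> float:
    """Per-bivalent HEI10 mean = per-cell mean / 16, rounded half away."""
    return round_half_away(mean_per_cell / 16.0, ndigits)


def hei10_summary(hei10: pd.DataFrame) -> list[Hei10Summary]:
    """Per-plant HEI10 focus summaries from per-cell counts."""
    if hei10.empty:
        raise ValueError("no HEI10 counts")
    out = []
    for pid, grp in hei10.groupby("plant_id"):
        mean = float(grp["foci"].mean())
        out.append(
            Hei10Summary(
                str(pid), len(grp), mean, mean / 16.0, foci_per_bivalent(mean, 2)
            )
        )
    return out


def cytology_summary(
    cells: pd.DataFrame, bivalents: pd.DataFrame, hei10: pd.DataFrame
) -> pd.DataFrame:
    """Per-plant combined table: stability, chiasma frequency, HEI10 means."""
    stab = stability_summary(cells)
    biv = bivalents.copy()
    biv["chiasmata"] = biv[_ARM_COLS].sum(axis=1)
    chia = biv.groupby("plant_id", as_index=False).agg(
        n_bivalents=("chiasmata", "size"), mean_chiasmata=("chiasmata", "mean")
    )
    h = pd.DataFrame(
        [
            {
                "plant_id": s.plant_id,
                "hei10_mean_per_cell": s.mean_per_cell,
                "hei10_mean_per_bivalent": s.mean_per_bivalent_2dp,
            }
            for s in hei10_summary(hei10)
        ]
    )
    return stab.merge(chia, on="plant_id", how="left").merge(h, on="plant_id", how="left")
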