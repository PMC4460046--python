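"""Enrichment statistics and the composite positive-selection caller.

Element-vs-background contrasts are 2×2 tables tested by Pearson's χ²
with 1 d.f. (no continuity correction by default; Yates behind a flag),
substituting Fisher's exact test whenever an expected cell drops below 5.
The enrichment ratio is P_O/P_E: the element proportion satisfying the
predicate over the background proportion.

The caller flags a variant as positively selected when at least k of
three criteria hold (strict inequalities): DAF > 0.5, F_ST > 0.3 and
|standardized iHS| > 2; thresholds are configurable, including empirical
top-percentile thresholding.  Calls are annotated with genes overlapping
or within a 5 kb flank.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneTrack

__all__ = [
    "EnrichmentResult",
    "enrichment_test",
    "call_selection",
    "annotate_genes",
    "gwas_daf_profile",
    "bh_fdr",
    "top_percentile_threshold",
]


@dataclass
class EnrichmentResult:
    element_class: str
    predicate: str
    table: np.ndarray        # [[elem_in, elem_out], [bg_in, bg_out]]
    chi2: float
    p_value: float
    test: str                # "chi2" or "fisher"
    ratio: float             # P_O / P_E
    direction: str           # "enriched" / "depleted" / "none"


def enrichment_test(
    element_mask: np.ndarray,
    background_mask: np.ndarray,
    element_class: str = "",
    predicate: str = "",
    yates: bool = False,
) -> EnrichmentResult:
    """χ²/Fisher 2×2 test of a predicate in an element vs the background.

    Inputs are boolean arrays over the element's and the background's
    sites (NaN-valued sites must be excluded symmetrically upstream).
    Fisher's exact test replaces the χ² whenever any expected cell < 5.
    """
    em = np.asarray(element_mask, dtype=bool)
    bm = np.asarray(background_mask, dtype=bool)
    if em.size == 0 or bm.size == 0:
        raise ValueError("both site sets must be non-empty")
    a, b = int(em.sum()), int((~em).sum())
    c, d = int(bm.sum()), int((~bm).sum())
    table = np.array([[a, b], [c, d]])
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    p_o = a / (a + b)
    p_e = c / (c + d)
    if p_e == 0:
        ratio = math.inf if p_o > 0 else math.nan
    else:
        ratio = p_o / p_e
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
        chi2 = math.nan
        test = "fisher"
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        test = "chi2"
    direction = "enriched" if p_o > p_e else ("depleted" if p_o < p_e else "none")
    return EnrichmentResult(
        element_class=element_class,
        predicate=predicate,
        table=table,
        chi2=float(chi2),
        p_value=float(p),
        test=test,
        ratio=float(ratio),
        direction=direction,
    )


def top_percentile_threshold(values: np.ndarray, percentile: float = 99.0) -> float:
    """Empirical percentile over defined values (ties fall above the cut)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no defined values")
    return float(np.percentile(v, percentile))


def call_selection(
    records: pd.DataFrame,
    daf_threshold: float = 0.5,
    fst_threshold: float = 0.3,
    ihs_threshold: float = 2.0,
    k: int = 2,
) -> pd.DataFrame:
    """Composite caller over per-site DAF / F_ST / standardized iHS records.

    ``records`` needs columns ``daf``, ``fst`` and ``ihs`` (standardized;
    absolute value is taken here).  Criteria use strict ``>`` comparisons
    and an undefined (NaN) statistic never satisfies its criterion.  A
    site is called when at least k of the three criteria are met.
    """
    out = records.copy()
    daf = out["daf"].to_numpy(dtype=float)
    fst = out["fst"].to_numpy(dtype=float)
    ihs = np.abs(out["ihs"].to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        out["crit_daf"] = ~np.isnan(daf) & (daf > daf_threshold)
        out["crit_fst"] = ~np.isnan(fst) & (fst > fst_threshold)
        out["crit_ihs"] = ~np.isnan(ihs) & (ihs > ihs_threshold)
    out["n_criteria_met"] = (
        out["crit_daf"].astype(int) + out["crit_fst"].astype(int) + out["crit_ihs"].astype(int)
    )
    out["called"] = out["n_criteria_met"] >= k
    return out


def annotate_genes(
    calls: pd.DataFrame, genes: GeneTrack, flank: int = 5_000
) -> pd.DataFrame:
    """Attach genes overlapping or within ``flank`` bp of each call.

    A gene is attached iff the call position lies strictly inside the
    flanked window (start − flank < pos < end + flank): a variant exactly
    ``flank`` bp upstream of the gene start is not attached.  Multiple
    genes are listed sorted by distance (0 inside the gene) then name,
    semicolon-joined.
    """
    gdf = genes.df
    names: list[str] = []
    for _, row in calls.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        sub = gdf[
            (gdf["chrom"] == chrom)
            & (pos > gdf["start"] - flank)
            & (pos < gdf["end"] + flank)
        ]
        hits = []
        for _, g in sub.iterrows():
            if g["start"] <= pos < g["end"]:
                dist = 0
            elif pos < g["start"]:
                dist = int(g["start"] - pos)
            else:
                dist = int(pos - g["end"] + 1)
            hits.append((dist, g["gene"]))
        hits.sort()
        names.append(";".join(f"{g}" for _, g in hits))
    out = calls.copy()
    out["genes"] = names
    return out


def gwas_daf_profile(
    risk_table: pd.DataFrame, edges: np.ndarray
) -> pd.DataFrame:
    """Binned DAF counts for risk-derived vs other variants with Fisher tests.

    ``risk_table`` needs a ``daf`` column and a boolean ``risk_is_derived``
    flag.  For each half-open DAF bin, the 2×2 (group × in/out of bin)
    Fisher exact P is reported — the machinery behind comparing the
    frequency profile of risk-associated derived alleles against the rest.
    """
    edges = np.asarray(edges, dtype=float)
    g1 = risk_table[risk_table["risk_is_derived"]]["daf"].to_numpy(dtype=float)
    g2 = risk_table[~risk_table["risk_is_derived"]]["daf"].to_numpy(dtype=float)
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in1 = int(np.sum((g1 >= lo) & (g1 < hi)))
        in2 = int(np.sum((g2 >= lo) & (g2 < hi)))
        _, p = stats.fisher_exact([[in1, g1.size - in1], [in2, g2.size - in2]])
        rows.append((lo, hi, in1, in2, p))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "risk_derived", "other", "fisher_p"])


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted P-values (optional FDR control)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
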