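"""End-to-end orchestration: files in, selection-scan tables out.

Given phased VCF, element BED, conservation bedGraph, gene BED and a
population panel, runs the full element-partitioned scan:

1. per-element concatenated sliding-window SFS statistics per population,
   with bootstrap means and a permutation comparison of each element
   class against the genome-wide window background;
2. per-site MAF/DAF, global and pairwise pooled Weir–Cockerham F_ST;
3. GERP-style conservation classes at the configured thresholds, the
   per-element conserved length fractions, and low-DAF fractions by
   conservation class;
4. a per-population iHS scan;
5. the composite caller (DAF / F_ST / |iHS| criteria) with 5 kb gene
   annotation, written as TSV and BED.

All randomness (bootstrap, permutation) flows from one seed.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as ncio
from .enrichment import annotate_genes, call_selection, enrichment_test
from .freq import (
    classify_conservation,
    element_conserved_fraction,
    fraction_low_daf,
    maf_daf,
    weir_cockerham_fst,
)
from .haplotype import ihs_scan
from .windows import (
    bootstrap_mean,
    concatenate_element,
    permutation_test,
    sliding_windows,
    windows_to_frame,
)

STATS = ("tajima_d", "fu_li_d_star", "fu_li_f_star", "fay_wu_h", "pi_per_site")


@dataclass
class PipelineResult:
    window_stats: pd.DataFrame
    comparisons: pd.DataFrame
    site_table: pd.DataFrame
    conservation_fractions: pd.DataFrame
    calls: pd.DataFrame


def run_pipeline(
    vcf_path: str,
    elements_bed: str,
    scores_bedgraph: str,
    genes_bed: str,
    panel_tsv: str,
    out_dir: str,
    seed: int = 0,
    window: int = 10_000,
    step: int = 5_000,
    n_boot: int = 1000,
    n_perm: int = 1000,
    daf_threshold: float = 0.5,
    fst_threshold: float = 0.3,
    ihs_threshold: float = 2.0,
    k_criteria: int = 2,
) -> PipelineResult:
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    block = ncio.read_vcf(vcf_path)
    elements = ncio.read_bed(elements_bed, kind="element")
    cons = ncio.read_score_track(scores_bedgraph)
    genes = ncio.read_bed(genes_bed, kind="gene")
    panel = ncio.read_panel(panel_tsv)
    chrom_size = int(
        max(elements.df["end"].max(), block.positions.max() + 1)
    )

    # --- window statistics per element class and population, plus background
    win_frames = []
    comparisons = []
    pops = panel.populations
    for pop in pops:
        idx = panel.haplotype_indices(block, pop)
        pop_block = block.take_haplotypes(idx)
        bg = windows_to_frame(
            sliding_windows(pop_block, chrom_size, window, step), "genome", pop
        )
        win_frames.append(bg)
        for cls in elements.classes:
            cblock, cmap = concatenate_element(pop_block, elements, cls)
            wf = windows_to_frame(sliding_windows(cblock, cmap.length, window, step), cls, pop)
            win_frames.append(wf)
            if wf.empty or bg.empty:
                continue  # class shorter than one full window
            for stat in STATS:
                ev = wf.loc[wf["defined"], stat].to_numpy()
                bv = bg.loc[bg["defined"], stat].to_numpy()
                if ev.size == 0 or bv.size == 0:
                    continue
                boot_mean, boot_se = bootstrap_mean(
                    ev, n_boot=n_boot, seed=int(rng.integers(2**31))
                )
                res = permutation_test(
                    ev, bv, n_perm=n_perm, seed=int(rng.integers(2**31)),
                    element_class=cls, statistic=stat,
                )
                comparisons.append(
                    {
                        "population": pop,
                        "element_class": cls,
                        "statistic": stat,
                        "element_mean": res.element_mean,
                        "element_boot_mean": boot_mean,
                        "element_boot_se": boot_se,
                        "background_mean": res.background_mean,
                        "delta_obs": res.delta_obs,
                        "perm_p": res.p_value,
                        "n_perm": res.n_perm,
                    }
                )
    window_stats = pd.concat([w for w in win_frames if not w.empty], ignore_index=True)
    comparisons = pd.DataFrame(comparisons)

    # --- per-site table: frequencies, F_ST, conservation, element class
    site = maf_daf(block)
    fst = weir_cockerham_fst(block, panel, pops[: min(3, len(pops))])
    site["fst_global"] = fst.theta
    sup_groups = {s: sorted(g["pop"].unique()) for s, g in panel.df.groupby("superpop")}
    sups = sorted(sup_groups)
    for i, si in enumerate(sups):
        for sj in sups[i + 1 :]:
            pair = weir_cockerham_fst(block, panel, [sup_groups[si], sup_groups[sj]])
            site[f"fst_{si}_{sj}"] = pair.theta
    consif = classify_conservation(block, cons)
    site = site.merge(consif.drop(columns="chrom"), on="pos")
    cls_col = np.array(["" for _ in range(block.n_sites)], dtype=object)
    for cls in elements.classes:
        for _, iv in elements.intervals(cls).iterrows():
            inside = (block.positions >= iv["start"]) & (block.positions < iv["end"])
            cls_col[inside] = cls
    site["element_class"] = cls_col

    cons_fracs = []
    for t in (2.0, 3.0):
        f = element_conserved_fraction(elements, cons, t)
        f["threshold"] = t
        cons_fracs.append(f)
    cons_fracs = pd.concat(cons_fracs, ignore_index=True)
    cons_fracs["fraction_low_daf_conserved"] = np.nan
    cons_fracs["fraction_low_daf_nonconserved"] = np.nan
    for i, row in cons_fracs.iterrows():
        in_cls = site["element_class"] == row["element_class"]
        conserved = site[f"conserved_ge{row['threshold']:g}"]
        cons_fracs.loc[i, "fraction_low_daf_conserved"] = fraction_low_daf(
            site.loc[in_cls & conserved, "daf"].to_numpy()
        )
        cons_fracs.loc[i, "fraction_low_daf_nonconserved"] = fraction_low_daf(
            site.loc[in_cls & ~conserved, "daf"].to_numpy()
        )

    # --- iHS per population; the caller uses the max |standardized| score
    ihs_best = np.full(block.n_sites, np.nan)
    pos_index = {int(p): j for j, p in enumerate(block.positions)}
    for pop in pops:
        idx = panel.haplotype_indices(block, pop)
        scan = ihs_scan(block.take_haplotypes(idx))
        scan.to_csv(os.path.join(out_dir, f"ihs_{pop}.tsv"), sep="\t", index=False)
        for _, r in scan.iterrows():
            j = pos_index[int(r["pos"])]
            if np.isnan(ihs_best[j]) or abs(r["ihs_std"]) > abs(ihs_best[j]):
                ihs_best[j] = r["ihs_std"]
    site["ihs_max_abs"] = ihs_best

    records = pd.DataFrame(
        {
            "chrom": site["chrom"],
            "pos": site["pos"],
            "daf": site["daf"],
            "fst": site["fst_global"],
            "ihs": site["ihs_max_abs"],
            "element_class": site["element_class"],
        }
    )
    calls = call_selection(
        records,
        daf_threshold=daf_threshold,
        fst_threshold=fst_threshold,
        ihs_threshold=ihs_threshold,
        k=k_criteria,
    )
    calls = annotate_genes(calls, genes)

    # --- per-element enrichment of calls vs the genome background
    enr_rows = []
    called = calls["called"].to_numpy()
    for cls in elements.classes:
        in_cls = (calls["element_class"] == cls).to_numpy()
        if in_cls.sum() == 0:
            continue
        res = enrichment_test(called[in_cls], called, cls, "called")
        enr_rows.append(
            {
                "element_class": cls,
                "n_sites": int(in_cls.sum()),
                "n_called": int(called[in_cls].sum()),
                "ratio": res.ratio,
                "p_value": res.p_value,
                "test": res.test,
                "direction": res.direction,
            }
        )
    enrichment = pd.DataFrame(enr_rows)

    window_stats.to_csv(os.path.join(out_dir, "window_stats.tsv"), sep="\t", index=False)
    comparisons.to_csv(os.path.join(out_dir, "comparisons.tsv"), sep="\t", index=False)
    site.to_csv(os.path.join(out_dir, "site_table.tsv"), sep="\t", index=False)
    cons_fracs.to_csv(os.path.join(out_dir, "conservation.tsv"), sep="\t", index=False)
    calls.to_csv(os.path.join(out_dir, "selection_calls.tsv"), sep="\t", index=False)
    enrichment.to_csv(os.path.join(out_dir, "call_enrichment.tsv"), sep="\t", index=False)
    sel = calls[calls["called"]]
    with open(os.path.join(out_dir, "selection_calls.bed"), "w") as fh:
        for _, r in sel.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['pos'])}\t{int(r['pos']) + 1}\t{r['genes'] or '.'}\n")
    return PipelineResult(window_stats, comparisons, site, cons_fracs, calls)
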