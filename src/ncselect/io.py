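"""Readers and writers for the standard formats the pipeline touches.

VCF 4.x with phased GT and the 1000 Genomes style ``AA`` INFO tag, BED3/BED4,
bedGraph score runs, and the ``sample<TAB>pop<TAB>superpop`` panel TSV.
Ingest normalizes everything into the 0-based half-open internal model.
"""
from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    ConservationTrack,
    ElementTrack,
    GeneTrack,
    HaplotypeBlock,
    PopulationPanel,
)

logger = logging.getLogger(__name__)


def read_vcf(path: str, region: str | None = None) -> HaplotypeBlock:
    """Read phased biallelic SNPs into a polarized HaplotypeBlock.

    REF/ALT codes are re-polarized to ancestral/derived using the ``AA``
    INFO field when it matches REF or ALT (case-insensitive; only the first
    ``|``-separated field of extended 1000G encodings is used).  Sites with
    a missing or unmatched AA keep ALT-count coding and are flagged
    ``ancestral_known=False``.  Multiallelic sites and indels are skipped
    with a logged count; an unphased genotype raises.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    sample_ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    positions: list[int] = []
    known: list[bool] = []
    cols: list[np.ndarray] = []
    chrom = None
    n_skipped = 0
    it = vcf(region) if region else vcf
    for var in it:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("read_vcf handles one chromosome at a time; use region=")
        gts = var.genotype.array()
        if gts.shape[1] < 3 or not np.all(gts[:, 2]):
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        hap = gts[:, :2].astype(np.int8).reshape(-1)
        if (hap < 0).any() or (hap > 1).any():
            raise ValueError(f"missing or non-biallelic allele at {var.CHROM}:{var.POS}")
        aa = var.INFO.get("AA")
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        anc = str(aa).split("|")[0].upper() if aa is not None else ""
        if anc == ref:
            col, is_known = hap, True
        elif anc == alt:
            col, is_known = 1 - hap, True  # REF is the derived allele
        else:
            col, is_known = hap, False
        positions.append(var.POS - 1)  # 1-based VCF -> 0-based internal
        known.append(is_known)
        cols.append(col.astype(np.uint8))
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/indel records", n_skipped)
    if chrom is None:
        raise ValueError("no usable SNP records in VCF")
    alleles = np.stack(cols, axis=1) if cols else np.zeros((len(sample_ids), 0), np.uint8)
    return HaplotypeBlock(
        chrom=chrom,
        positions=np.array(positions, dtype=np.int64),
        alleles=alleles,
        ancestral_known=np.array(known, dtype=bool),
        sample_ids=sample_ids,
    )


def write_vcf(block: HaplotypeBlock, path: str) -> None:
    """Write a block as minimal VCF 4.2 (synthetic A/G alleles, AA INFO).

    The ancestral allele is written as REF so a round trip through
    :func:`read_vcf` reproduces the allele matrix exactly; unpolarized
    sites are written with ``AA=.``.
    """
    stems = block.sample_stems()
    if block.n_haplotypes % 2:
        raise ValueError("VCF output requires an even haplotype count (diploids)")
    samples = stems[0::2]
    if stems[1::2] != samples:
        raise ValueError("haplotypes must be ordered in sample pairs")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={block.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(block.n_sites):
            aa = "AA=A" if block.ancestral_known[j] else "AA=."
            col = block.alleles[:, j]
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(len(samples)))
            fh.write(f"{block.chrom}\t{block.positions[j] + 1}\t.\tA\tG\t.\tPASS\t{aa}\tGT\t{gts}\n")


def read_bed(path: str, kind: str = "element") -> ElementTrack | GeneTrack:
    """Read BED3/BED4 into an ElementTrack (default) or GeneTrack.

    The optional 4th column is the element class / gene name; absent names
    default to ``"region"``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else "region"
            rows.append((chrom, start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if kind == "element":
        return ElementTrack(df.rename(columns={"name": "element_class"}))
    if kind == "gene":
        return GeneTrack(df.rename(columns={"name": "gene"}))
    raise ValueError("kind must be 'element' or 'gene'")


def write_bed(track: ElementTrack | GeneTrack, path: str) -> None:
    df = track.df
    label = "element_class" if "element_class" in df.columns else "gene"
    df[["chrom", "start", "end", label]].to_csv(path, sep="\t", header=False, index=False)


def read_score_track(path: str) -> ConservationTrack:
    """Read a 4-column bedGraph into a ConservationTrack."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    return ConservationTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]))


def write_score_track(track: ConservationTrack, path: str) -> None:
    track.df.to_csv(path, sep="\t", header=False, index=False)


def read_panel(path: str) -> PopulationPanel:
    """Read a ``sample<TAB>pop<TAB>superpop`` TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] in ("sample", "sample_id"):
        df = df.iloc[1:].reset_index(drop=True)
    df.columns = ["sample", "pop", "superpop"][: df.shape[1]]
    if "superpop" not in df.columns:
        df["superpop"] = df["pop"]
    return PopulationPanel(df)


def write_panel(panel: PopulationPanel, path: str) -> None:
    panel.df.to_csv(path, sep="\t", header=False, index=False)


def derive_intergenic(
    elements: ElementTrack,
    chrom_sizes: Mapping[str, int],
    block: HaplotypeBlock | None = None,
    buffer: int = 10_000,
    tile: bool = False,
) -> ElementTrack:
    """Intergenic track: bases at least ``buffer`` bp from every element.

    When a HaplotypeBlock is supplied, intergenic stretches longer than
    ``buffer`` that contain no variant are removed.  With ``tile=True`` the
    retained stretches are additionally cut into ``buffer``-sized tiles
    (discarding the remainder), the alternative reading of the derivation
    rule.
    """
    if not chrom_sizes:
        raise ValueError("chrom_sizes is required")
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = elements.df[elements.df["chrom"] == chrom]
        dilated = [
            (max(0, s - buffer), min(size, e + buffer))
            for s, e in zip(sub["start"], sub["end"])
        ]
        dilated.sort()
        merged: list[list[int]] = []
        for s, e in dilated:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = 0
        gaps = []
        for s, e in merged:
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < size:
            gaps.append((cursor, size))
        for s, e in gaps:
            if block is not None and block.chrom == chrom and e - s > buffer:
                n_var = int(np.sum((block.positions >= s) & (block.positions < e)))
                if n_var == 0:
                    continue
            if tile:
                for t in range(s, e - buffer + 1, buffer):
                    rows.append((chrom, t, t + buffer, "intergenic"))
            else:
                rows.append((chrom, s, e, "intergenic"))
    return ElementTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "element_class"]))
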