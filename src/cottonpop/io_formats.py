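"""Readers and writers for VCF 4.2, GFF3, BED/TSV intervals and panel tables.

All coordinates become 0-based half-open in memory; VCF/GFF stay 1-based on
disk.  Genotypes are diploid alt-allele dosages; ``./.`` becomes -1.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF
import gffutils

from .core import (AccessionPanel, GeneModel, GenomeLayout, GenotypeMatrix,
                   IntervalSet, MISSING)

__all__ = ["read_vcf", "write_vcf", "read_panel", "write_panel", "read_gff",
           "read_intervals", "write_bed", "read_fasta", "write_fasta"]


def read_panel(path) -> AccessionPanel:
    """Read a tab-separated panel table with columns id, species, group,
    origin (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return AccessionPanel(df)


def write_panel(panel: AccessionPanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_vcf(path, panel: AccessionPanel,
             multiallelic: str = "drop") -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix.

    Sample names must be a subset of the panel ids; the returned matrix is
    restricted to (and ordered by) the panel rows present in the VCF.
    Multiallelic records are dropped by default (``multiallelic="split"``
    expands them into one biallelic record per alt allele).
    """
    if multiallelic not in ("drop", "split"):
        raise ValueError("multiallelic must be 'drop' or 'split'")
    vcf = VCF(os.fspath(path), gts012=True)
    samples = list(vcf.samples)
    unknown = set(samples) - set(panel.ids)
    if unknown:
        raise ValueError(f"VCF samples not in panel: {sorted(unknown)}")
    sub_panel = panel.subset([a for a in panel.ids if a in set(samples)])
    order = [samples.index(a) for a in sub_panel.ids]

    rows, cols = [], []
    last = {}
    for rec in vcf:
        if len(rec.ALT) == 0:
            continue
        if len(rec.ALT) > 1 and multiallelic == "drop":
            continue
        if rec.POS < last.get(rec.CHROM, 0):
            raise ValueError(f"unsorted VCF at {rec.CHROM}:{rec.POS}")
        last[rec.CHROM] = rec.POS
        if len(rec.ALT) == 1:
            alts = [rec.ALT[0]]
            # gts012: 0/1/2 dosage, 3 = missing
            g = rec.gt_types.astype(np.int8)
            g[g == 3] = MISSING
            dosages = [g]
        else:
            # split: per alt allele, dosage counts that allele only
            gts = np.array(rec.genotypes, dtype=object)
            alleles = np.array([[a[0], a[1]] for a in rec.genotypes])
            alts, dosages = [], []
            for ai, alt in enumerate(rec.ALT, start=1):
                d = (alleles == ai).sum(axis=1).astype(np.int8)
                miss = (alleles < 0).any(axis=1)
                d[miss] = MISSING
                alts.append(alt)
                dosages.append(d)
        for alt, d in zip(alts, dosages):
            vtype = "snp" if len(rec.REF) == 1 and len(alt) == 1 else "indel"
            rows.append((rec.CHROM, rec.POS, rec.REF, alt, vtype))
            cols.append(d[order])
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                        "vtype"])
    calls = (np.stack(cols, axis=1) if cols
             else np.empty((len(sub_panel), 0), dtype=np.int8))
    return GenotypeMatrix(sub_panel, sites, calls)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path,
              layout: GenomeLayout | None = None) -> None:
    """Write a GenotypeMatrix as uncompressed VCF 4.2 (deterministic)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if layout is not None:
            for c in layout.chromosomes:
                fh.write(f"##contig=<ID={c.name},length={c.length}>\n")
        else:
            for chrom in matrix.sites["chrom"].drop_duplicates():
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.panel.ids) + "\n")
        calls = matrix.calls
        for j, row in enumerate(matrix.sites.itertuples(index=False)):
            gts = "\t".join(_GT_CODE[int(g)] for g in calls[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t"
                     f"PASS\t.\tGT\t{gts}\n")


def read_gff(path) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/CDS features into GeneModels (one per mRNA)."""
    db = gffutils.create_db(os.fspath(path), ":memory:",
                            merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        strand = mrna.strand
        # phase of the transcript-first segment
        first = cds[-1] if strand == "-" else cds[0]
        phase = int(first.frame) if first.frame not in (None, ".") else 0
        models.append(GeneModel(gene_id=mrna.id, chrom=mrna.seqid,
                                strand=strand,
                                cds=[(c.start, c.end) for c in cds],
                                phase=phase))
    return models


def write_gff(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            segs = sorted(m.cds)
            start, end = segs[0][0], segs[-1][1]
            fh.write(f"{m.chrom}\t.\tgene\t{start}\t{end}\t.\t{m.strand}\t."
                     f"\tID={m.gene_id}_g\n")
            fh.write(f"{m.chrom}\t.\tmRNA\t{start}\t{end}\t.\t{m.strand}\t."
                     f"\tID={m.gene_id};Parent={m.gene_id}_g\n")
            # per-segment phase in transcript order
            order = segs[::-1] if m.strand == "-" else segs
            phase = m.phase
            phases = {}
            for s, e in order:
                phases[(s, e)] = phase
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for i, (s, e) in enumerate(segs):
                fh.write(f"{m.chrom}\t.\tCDS\t{s}\t{e}\t.\t{m.strand}\t"
                         f"{phases[(s, e)]}\tID={m.gene_id}.cds{i};"
                         f"Parent={m.gene_id}\n")


def read_intervals(path, fmt: str = "bed") -> IntervalSet:
    """Read intervals from BED (0-based half-open) or 1-based closed TSV.

    TSV columns: chrom, start, end[, label]; BED: chrom, chromStart,
    chromEnd[, name].
    """
    if fmt not in ("bed", "tsv1"):
        raise ValueError("fmt must be 'bed' or 'tsv1'")
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, a, b = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else f"iv{len(rows)}"
            if fmt == "tsv1":
                a -= 1  # 1-based closed -> 0-based half-open
            rows.append((chrom, a, b, label))
    return IntervalSet.from_tuples(rows)


def write_bed(intervals: IntervalSet, path) -> None:
    intervals.df.to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(path),
                                                        "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
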