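"""SNP/indel filtering cascade and site classification.

The cascade order is: non-singleton -> MAF/missing -> spacing.  Each step
only removes sites.  Allele frequency is always alt-allele count over
called-allele count (missing calls excluded from the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core import GeneModel, GenotypeMatrix, MISSING

__all__ = ["nonsingleton_filter", "maf_missing_filter", "spacing_filter",
           "filter_cascade", "classify_snp_categories",
           "annotate_coding_effects", "SnpCategory", "VariantEffect"]


def nonsingleton_filter(matrix: GenotypeMatrix,
                        min_accessions: int = 2) -> GenotypeMatrix:
    """Keep sites where the alternative allele is present (dosage >= 1) in
    at least ``min_accessions`` accessions.

    The source analysis states the rule two ways ("more than two" vs "at
    least two" accessions); the reported SNP set matches >= 2, which is the
    default, and the threshold is exposed for the stricter reading.
    """
    carriers = (matrix.calls >= 1).sum(axis=0)
    return matrix.take_sites(carriers >= min_accessions)


def maf_missing_filter(matrix: GenotypeMatrix, maf: float = 0.05,
                       miss: float = 0.10) -> GenotypeMatrix:
    """Keep sites with minor allele frequency > ``maf`` and missing-call
    fraction < ``miss``, both over all accessions."""
    freq, n_alleles = matrix.alt_frequency()
    with np.errstate(invalid="ignore"):
        minor = np.fmin(freq, 1 - freq)
    missing_frac = (matrix.calls == MISSING).mean(axis=0)
    keep = (np.nan_to_num(minor, nan=-1) > maf) & (missing_frac < miss)
    return matrix.take_sites(keep)


def spacing_filter(matrix: GenotypeMatrix, min_gap: int = 10,
                   seed: int = 0) -> GenotypeMatrix:
    """Thin sites until neighbours on each chromosome are >= ``min_gap`` bp
    apart.

    Conflicts are resolved by repeatedly taking the closest conflicting
    pair (leftmost on ties) and removing one of its two members uniformly
    at random; reproducible from ``seed``.
    """
    import heapq

    rng = np.random.default_rng(seed)
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    keep_mask = np.ones(matrix.n_sites, dtype=bool)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        n = len(idx)
        if n < 2:
            continue
        p = pos[idx]
        nxt = np.arange(1, n + 1)
        prv = np.arange(-1, n - 1)
        alive = np.ones(n, dtype=bool)
        heap = [(int(p[i + 1] - p[i]), i, i + 1) for i in range(n - 1)
                if p[i + 1] - p[i] < min_gap]
        heapq.heapify(heap)
        while heap:
            gap, i, j = heapq.heappop(heap)
            # skip stale entries (a member died or the pair is no longer
            # adjacent)
            if not (alive[i] and alive[j]) or nxt[i] != j:
                continue
            victim = j if rng.integers(2) else i
            alive[victim] = False
            keep_mask[idx[victim]] = False
            left, right = prv[victim], nxt[victim]
            if left >= 0:
                nxt[left] = right
            if right < n:
                prv[right] = left
            if left >= 0 and right < n:
                g = int(p[right] - p[left])
                if g < min_gap:
                    heapq.heappush(heap, (g, left, right))
    return matrix.take_sites(keep_mask)


def filter_cascade(matrix: GenotypeMatrix, min_accessions: int = 2,
                   maf: float = 0.05, miss: float = 0.10,
                   min_gap: int = 10, seed: int = 0) -> GenotypeMatrix:
    """The full cascade in its fixed order:
    non-singleton -> MAF/missing -> spacing."""
    m = nonsingleton_filter(matrix, min_accessions)
    m = maf_missing_filter(m, maf, miss)
    return spacing_filter(m, min_gap, seed)


@dataclass(frozen=True)
class SnpCategory:
    chrom: str
    pos: int
    intraspecific_hirsutum: bool
    intraspecific_barbadense: bool
    nearly_fixed_interspecific: bool
    undefined: bool  # a species had no called alleles at the site


def classify_snp_categories(matrix: GenotypeMatrix, panel=None,
                            fix_hi: float = 0.95, fix_lo: float = 0.05,
                            intra_maf: float = 0.05) -> pd.DataFrame:
    """Classify each site with respect to the two species.

    nearly_fixed_interspecific: alt frequency > ``fix_hi`` in one species
    and < ``fix_lo`` in the other (either orientation).
    intraspecific_<species>: within-species minor allele frequency >
    ``intra_maf``.  The categories are not mutually exclusive across
    species; a site with no called alleles in a species is flagged
    ``undefined``.  Returns a DataFrame (one row per site).
    """
    panel = matrix.panel if panel is None else panel
    gh = panel.ids_where(species="hirsutum")
    gb = panel.ids_where(species="barbadense")
    f_h, n_h = matrix.alt_frequency(gh)
    f_b, n_b = matrix.alt_frequency(gb)
    undefined = (n_h == 0) | (n_b == 0)
    with np.errstate(invalid="ignore"):
        nearly = (((f_h > fix_hi) & (f_b < fix_lo))
                  | ((f_b > fix_hi) & (f_h < fix_lo)))
        intra_h = np.fmin(f_h, 1 - f_h) > intra_maf
        intra_b = np.fmin(f_b, 1 - f_b) > intra_maf
    out = pd.DataFrame({
        "chrom": matrix.sites["chrom"],
        "pos": matrix.sites["pos"],
        "intraspecific_hirsutum": np.where(undefined, False, intra_h),
        "intraspecific_barbadense": np.where(undefined, False, intra_b),
        "nearly_fixed_interspecific": np.where(undefined, False, nearly),
        "undefined": undefined,
    })
    return out


@dataclass(frozen=True)
class VariantEffect:
    chrom: str
    pos: int
    gene_id: str
    effect: str  # synonymous|nonsynonymous|stop_gained|frameshift|inframe_indel|noncoding


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def annotate_coding_effects(sites: pd.DataFrame, gene_models: list[GeneModel],
                            genome: dict[str, str]) -> list[VariantEffect]:
    """Classify variants against gene models on a reference genome.

    SNPs inside a CDS are classified by substituting the base into the
    reconstructed codon on the coding strand (synonymous / nonsynonymous /
    stop_gained).  Indels whose affected bases touch a CDS are frameshift
    iff their length is not a multiple of 3, else inframe_indel.  Everything
    else is noncoding.  A SNP whose stated reference allele disagrees with
    the reference genome raises ValueError.
    """
    # per-chromosome lookup: genomic position (1-based) -> (model, cpos)
    lookup: dict[str, dict[int, tuple[GeneModel, int]]] = {}
    coding_cache: dict[str, str] = {}
    for m in gene_models:
        gpos = m.genomic_positions()
        d = lookup.setdefault(m.chrom, {})
        for cpos, gp in enumerate(gpos):
            d[int(gp)] = (m, cpos)
        coding_cache[m.gene_id] = "".join(
            genome[m.chrom][s - 1:e] for s, e in sorted(m.cds))
        if m.strand == "-":
            coding_cache[m.gene_id] = \
                coding_cache[m.gene_id].translate(_COMPLEMENT)[::-1]

    effects = []
    for row in sites.itertuples(index=False):
        chrom, pos, ref, alt = row.chrom, int(row.pos), row.ref, row.alt
        vtype = row.vtype
        d = lookup.get(chrom, {})
        if vtype == "snp":
            hit = d.get(pos)
            if hit is None:
                effects.append(VariantEffect(chrom, pos, "", "noncoding"))
                continue
            m, cpos = hit
            if genome[chrom][pos - 1] != ref:
                raise ValueError(f"reference mismatch at {chrom}:{pos}: "
                                 f"genome has {genome[chrom][pos-1]}, "
                                 f"site says {ref}")
            coding = coding_cache[m.gene_id]
            if m.strand == "-":
                new_base = alt.translate(_COMPLEMENT)
            else:
                new_base = alt
            ci = cpos // 3
            codon = coding[3 * ci:3 * ci + 3]
            if len(codon) < 3:
                effects.append(VariantEffect(chrom, pos, m.gene_id,
                                             "noncoding"))
                continue
            mutated = codon[:cpos % 3] + new_base + codon[cpos % 3 + 1:]
            aa0 = str(Seq(codon).translate())
            aa1 = str(Seq(mutated).translate())
            if aa1 == aa0:
                eff = "synonymous"
            elif aa1 == "*":
                eff = "stop_gained"
            else:
                eff = "nonsynonymous"
            effects.append(VariantEffect(chrom, pos, m.gene_id, eff))
        else:
            length = len(alt) - len(ref)
            if length < 0:  # deletion: bases pos+1 .. pos+|length| removed
                affected = range(pos + 1, pos + 1 - length)
            else:           # insertion between pos and pos+1
                affected = (pos, pos + 1)
            hit = None
            for gp in affected:
                if gp in d:
                    hit = d[gp]
                    break
            if hit is None:
                effects.append(VariantEffect(chrom, pos, "", "noncoding"))
                continue
            m, _ = hit
            eff = "frameshift" if length % 3 != 0 else "inframe_indel"
            effects.append(VariantEffect(chrom, pos, m.gene_id, eff))
    return effects
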