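"""Windowed diversity and differentiation statistics, Ka/Ks, LD decay.

pi uses the per-site unbiased heterozygosity 2*p*(1-p)*n/(n-1) (n = called
alleles) summed over variant sites and divided by the full window length
(unsequenced positions assumed monomorphic).  F_ST is the Hudson estimator
windowed as a ratio of sums, robust to unequal sample sizes.  Ka/Ks uses
NG86 site counting on the CDS with plain SNP-class counts (no multiple-hit
correction): the quantity of interest is a ratio of polymorphism classes,
not a divergence model.  LD r^2 is the squared correlation of unphased
dosages with pairwise-complete handling of missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core import GeneModel, GenotypeMatrix, IntervalSet, MISSING

__all__ = ["window_pi", "window_fst", "site_pi", "ng86_site_counts",
           "kaks_ratio", "KaKsResult", "ld_decay"]


def _window_cols(matrix: GenotypeMatrix, windows: IntervalSet):
    chroms = matrix.sites["chrom"].to_numpy()
    pos0 = matrix.sites["pos"].to_numpy() - 1  # 0-based
    for chrom, start, end, label in windows:
        yield (chrom, start, end, label,
               np.flatnonzero((chroms == chrom) & (pos0 >= start)
                              & (pos0 < end)))


def site_pi(matrix: GenotypeMatrix, population) -> np.ndarray:
    """Per-site unbiased heterozygosity for a population (NaN where fewer
    than two alleles are called)."""
    p, n = matrix.alt_frequency(population)
    with np.errstate(invalid="ignore"):
        h = 2 * p * (1 - p) * n / np.maximum(n - 1, 1)
    h = np.where(n >= 2, h, np.nan)
    return h


def window_pi(matrix: GenotypeMatrix, population, windows: IntervalSet
              ) -> pd.DataFrame:
    """Nucleotide diversity per window for one population.

    Returns a DataFrame with columns chrom, start, end, label, pi, n_snps,
    n_informative, undefined.  ``undefined`` marks windows that contain
    sites but none with >= 2 called alleles; their pi is NaN.  Windows with
    no sites at all have pi = 0 under the monomorphic-site assumption.
    """
    if len(matrix.panel.index_of(population)) < 2:
        raise ValueError("population needs >= 2 accessions")
    h = site_pi(matrix, population)
    rows = []
    for chrom, start, end, label, cols in _window_cols(matrix, windows):
        length = end - start
        n_inf = int(np.isfinite(h[cols]).sum())
        if len(cols) > 0 and n_inf == 0:
            pi, undef = np.nan, True
        else:
            pi, undef = float(np.nansum(h[cols])) / length, False
        rows.append((chrom, start, end, label, pi, len(cols), n_inf, undef))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label",
                                       "pi", "n_snps", "n_informative",
                                       "undefined"])


def hudson_fst_components(matrix: GenotypeMatrix, pop_a, pop_b):
    """Per-site Hudson numerator and denominator (NaN where either
    population has < 2 called alleles)."""
    p1, n1 = matrix.alt_frequency(pop_a)
    p2, n2 = matrix.alt_frequency(pop_b)
    with np.errstate(invalid="ignore"):
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
               - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n1 < 2) | (n2 < 2)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def window_fst(matrix: GenotypeMatrix, pop_a, pop_b,
               windows: IntervalSet) -> pd.DataFrame:
    """Hudson F_ST per window as a ratio of sums over informative sites."""
    for pop in (pop_a, pop_b):
        if len(matrix.panel.index_of(pop)) < 2:
            raise ValueError("both populations need >= 2 accessions")
    num, den = hudson_fst_components(matrix, pop_a, pop_b)
    rows = []
    for chrom, start, end, label, cols in _window_cols(matrix, windows):
        d = np.nansum(den[cols])
        informative = int(np.isfinite(den[cols]).sum())
        if informative == 0 or d == 0:
            fst, undef = np.nan, True
        else:
            fst, undef = float(np.nansum(num[cols]) / d), False
        rows.append((chrom, start, end, label, fst, len(cols), informative,
                     undef))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label",
                                       "fst", "n_snps", "n_informative",
                                       "undefined"])


# ---------------------------------------------------------------------------
# Ka/Ks (NG86 site counting, SNP-count ratio)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KaKsResult:
    n_nonsyn_snps: int
    n_syn_snps: int
    nonsyn_sites: float
    syn_sites: float
    ka: float
    ks: float
    ratio: float  # NaN when Ks undefined


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """NG86 nonsynonymous/synonymous site counts for one codon.

    Each of the 9 single-base mutations contributes 1/3 of a site to the
    class given by its amino-acid effect; mutations creating a stop codon
    count as nonsynonymous.  Returns (nonsyn_sites, syn_sites), summing to 3.
    """
    aa0 = str(Seq(codon).translate())
    nonsyn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if str(Seq(mut).translate()) != aa0:
                nonsyn += 1 / 3
    return nonsyn, 3.0 - nonsyn


def _gene_site_counts(model: GeneModel, genome: dict[str, str]
                      ) -> tuple[float, float]:
    from .variant_filter import _COMPLEMENT
    seq = "".join(genome[model.chrom][s - 1:e] for s, e in sorted(model.cds))
    if model.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    n_sites = s_sites = 0.0
    for i in range(0, len(seq) - len(seq) % 3, 3):
        n, s = ng86_site_counts(seq[i:i + 3])
        n_sites += n
        s_sites += s
    return n_sites, s_sites


def kaks_ratio(effects, gene_models: list[GeneModel],
               genome: dict[str, str], gene_set=None) -> KaKsResult:
    """Ka/Ks over a gene set from annotated SNP effects.

    Ka = nonsynonymous SNPs / NG86 nonsynonymous sites; Ks likewise for
    synonymous.  ``effects`` is the output of annotate_coding_effects;
    ``gene_set`` restricts the genes (default: all models).  The ratio is
    NaN when no synonymous SNPs fall in the set.
    """
    if gene_set is None:
        gene_set = {m.gene_id for m in gene_models}
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    models = [m for m in gene_models if m.gene_id in gene_set]
    n_sites = s_sites = 0.0
    for m in models:
        n, s = _gene_site_counts(m, genome)
        n_sites += n
        s_sites += s
    n_snps = sum(1 for e in effects if e.gene_id in gene_set
                 and e.effect in ("nonsynonymous", "stop_gained"))
    s_snps = sum(1 for e in effects if e.gene_id in gene_set
                 and e.effect == "synonymous")
    ka = n_snps / n_sites if n_sites > 0 else np.nan
    ks = s_snps / s_sites if s_sites > 0 else np.nan
    ratio = ka / ks if s_snps > 0 and s_sites > 0 and n_sites > 0 else np.nan
    return KaKsResult(n_snps, s_snps, n_sites, s_sites, ka, ks, ratio)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(matrix: GenotypeMatrix, population, max_dist: int = 1_000_000,
             bins=None) -> pd.DataFrame:
    """Mean pairwise r^2 binned by physical distance.

    All intra-chromosomal site pairs within ``max_dist`` are used; r^2 is
    the squared Pearson correlation of dosages over accessions with both
    sites called (pairwise-complete).  ``bins`` are bp edges (default 10
    log-spaced bins from 100 bp to ``max_dist``).  Returns a DataFrame with
    bin edges, mean r^2 and pair counts (NaN mean for empty bins).
    """
    if bins is None:
        bins = np.unique(np.geomspace(100, max_dist, 11).astype(int))
    bins = np.asarray(bins)
    sub = matrix.rows(population).astype(float)
    sub[sub == MISSING] = np.nan
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()

    sums = np.zeros(len(bins) - 1)
    counts = np.zeros(len(bins) - 1, dtype=int)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < 2:
            continue
        p = pos[idx]
        g = sub[:, idx]
        for i in range(len(idx) - 1):
            j_hi = np.searchsorted(p, p[i] + max_dist, side="right")
            for j in range(i + 1, j_hi):
                both = ~np.isnan(g[:, i]) & ~np.isnan(g[:, j])
                if both.sum() < 2:
                    continue
                x, y = g[both, i], g[both, j]
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    continue
                r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
                d = p[j] - p[i]
                b = np.searchsorted(bins, d, side="right") - 1
                if 0 <= b < len(counts):
                    sums[b] += r * r
                    counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"bin_lo": bins[:-1], "bin_hi": bins[1:],
                         "mean_r2": mean_r2, "n_pairs": counts})
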