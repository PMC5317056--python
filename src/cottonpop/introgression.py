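"""Block-phylogeny introgression detection and admixture statistics.

The genome is cut into blocks (1 Mb in the full-scale analysis); within each
block accessions are compared by the simple-matching coefficient and a
neighbor-joining tree is built.  An accession of one species that falls
inside the other species' core clade is a candidate introgression carrier;
blocks where at least ``min_accessions`` carriers agree yield an
introgression event whose direction follows the recipient species.
Direction and subgenome biases are tested on observed-vs-balanced 2x2
tables; genome-wide admixture is tested with the three-population f3
statistic and a block jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy
from scipy.stats import chi2_contingency, fisher_exact

from .core import (GenomeLayout, GenotypeMatrix, IntervalSet, MISSING,
                   make_windows)

__all__ = ["block_distances", "simple_matching_distance", "nj_tree",
           "clade_membership", "call_introgression_events",
           "IntrogressionEvent", "direction_bias_test", "BiasTestResult",
           "f3_statistic", "f3_from_matrix", "F3Result"]


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def simple_matching_distance(calls: np.ndarray):
    """Pairwise simple-matching distance over dosage states {0,1,2}.

    distance(i, j) = 1 - matches / jointly-called sites.  Returns
    (distance matrix, joint-call count matrix); entries with zero jointly
    called sites are NaN.
    """
    called = calls != MISSING
    n = calls.shape[0]
    dist = np.zeros((n, n))
    joint = np.zeros((n, n), dtype=int)
    for i in range(n):
        ci = called[i]
        both = ci & called[i + 1:]
        match = (calls[i] == calls[i + 1:]) & both
        nb = both.sum(axis=1)
        nm = match.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(nb > 0, 1.0 - nm / np.maximum(nb, 1), np.nan)
        dist[i, i + 1:] = d
        dist[i + 1:, i] = d
        joint[i, i + 1:] = nb
        joint[i + 1:, i] = nb
    return dist, joint


def block_distances(matrix: GenotypeMatrix, blocks: IntervalSet):
    """Per-block simple-matching distance matrices.

    Yields (chrom, start, end, label, distance matrix, joint counts) for
    blocks containing at least one SNP.
    """
    chroms = matrix.sites["chrom"].to_numpy()
    pos0 = matrix.sites["pos"].to_numpy() - 1
    for chrom, start, end, label in blocks:
        cols = np.flatnonzero((chroms == chrom) & (pos0 >= start)
                              & (pos0 < end))
        if len(cols) == 0:
            continue
        dist, joint = simple_matching_distance(matrix.calls[:, cols])
        yield chrom, start, end, label, dist, joint


# ---------------------------------------------------------------------------
# neighbor joining (Saitou-Nei)
# ---------------------------------------------------------------------------

def nj_tree(dist: np.ndarray, labels) -> dendropy.Tree:
    """Neighbor-joining tree from a complete distance matrix.

    Deterministic: on equal Q values the lexicographically first (i, j)
    pair in current node order is joined.  Branch lengths are the classical
    Saitou-Nei solutions and may be slightly negative on non-additive
    input; they are not clamped so that additive matrices are reproduced
    exactly.  Returns an unrooted dendropy Tree.
    """
    D = np.asarray(dist, dtype=float).copy()
    n = D.shape[0]
    if n != D.shape[1] or n != len(labels):
        raise ValueError("distance matrix / label size mismatch")
    if np.isnan(D).any():
        raise ValueError("distance matrix has missing entries")
    if n < 3:
        raise ValueError("need >= 3 taxa")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        taxon = taxa.new_taxon(str(lab))
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)           # row-major first minimum
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        di = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        dj = dij - di
        parent = dendropy.Node()
        nodes[i].edge.length = di
        nodes[j].edge.length = dj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       new_row[keep][None, :]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three nodes join at the central (seed) node
    a, b, c = nodes
    da = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    db = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    dc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    center = tree.seed_node
    for node, dist_ in ((a, da), (b, db), (c, dc)):
        node.edge.length = dist_
        center.add_child(node)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# clade membership and event calling
# ---------------------------------------------------------------------------

def clade_membership(tree: dendropy.Tree, panel, outgroup_ids,
                     core_fraction: float = 0.9):
    """Label accessions placed inside the other species' core clade.

    The tree is rooted on the outgroup; for each species the core clade is
    the smallest rooted clade containing at least ``core_fraction`` of that
    species' accessions.  Returns (placements dict accession ->
    "hirsutum"|"barbadense" meaning "placed inside that species' clade",
    resolvable flag).  Unresolvable blocks (the two core clades share
    leaves, i.e. the species do not separate) return ({}, False).
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out_in_tree = [o for o in outgroup_ids if o in leaf_labels]
    if not out_in_tree:
        raise ValueError("no outgroup taxon in tree; cannot root")
    tree = tree.clone(depth=1)
    tree.is_rooted = True  # rooting on the outgroup below
    taxa = [tree.taxon_namespace.get_taxon(o) for o in out_in_tree]
    mrca = tree.mrca(taxa=taxa) if len(taxa) > 1 else \
        tree.find_node_with_taxon_label(out_in_tree[0])
    if mrca is tree.seed_node:
        mrca = tree.find_node_with_taxon_label(out_in_tree[0])
    if mrca.edge.length is None:
        mrca.edge.length = 0.0
    tree.reroot_at_edge(mrca.edge,
                        length1=mrca.edge.length / 2,
                        length2=mrca.edge.length / 2)

    species_of = dict(zip(panel.table["id"], panel.table["species"]))
    cores = {}
    for species in ("hirsutum", "barbadense"):
        members = {a for a in leaf_labels
                   if species_of.get(a) == species}
        if not members:
            return {}, False
        need = int(np.ceil(core_fraction * len(members)))
        best = None
        for node in tree.postorder_node_iter():
            leaves = {lf.taxon.label for lf in node.leaf_iter()}
            if len(leaves & members) >= need:
                if best is None or len(leaves) < len(best):
                    best = leaves
        cores[species] = best
    if cores["hirsutum"] & cores["barbadense"]:
        return {}, False

    placements = {}
    for species, core in cores.items():
        other = "barbadense" if species == "hirsutum" else "hirsutum"
        for a in core:
            if species_of.get(a) == other:
                placements[a] = species
    return placements, True


@dataclass(frozen=True)
class IntrogressionEvent:
    chrom: str
    start: int
    end: int
    label: str
    direction: str   # "Gh->Gb" | "Gb->Gh"
    subgenome: str   # "A" | "D"
    recipients: tuple
    n_accessions: int


_DIRECTION = {
    # recipient species placed inside donor clade
    ("barbadense", "hirsutum"): "Gh->Gb",   # Gb accession in Gh clade
    ("hirsutum", "barbadense"): "Gb->Gh",
}


def call_introgression_events(placements_per_block, panel,
                              layout: GenomeLayout,
                              min_accessions: int = 2
                              ) -> list[IntrogressionEvent]:
    """Collapse per-block placements into events.

    ``placements_per_block`` is an iterable of (chrom, start, end, label,
    placements dict, resolvable flag) as produced by scanning blocks with
    clade_membership.  One event is emitted per (block, direction) with at
    least ``min_accessions`` placed accessions.
    """
    species_of = dict(zip(panel.table["id"], panel.table["species"]))
    events = []
    for chrom, start, end, label, placements, ok in placements_per_block:
        if not ok or not placements:
            continue
        by_dir: dict[str, list[str]] = {}
        for acc, host in placements.items():
            direction = _DIRECTION[(species_of[acc], host)]
            by_dir.setdefault(direction, []).append(acc)
        for direction, accs in sorted(by_dir.items()):
            if len(accs) >= min_accessions:
                events.append(IntrogressionEvent(
                    chrom, int(start), int(end), label, direction,
                    layout.subgenome_of(chrom), tuple(sorted(accs)),
                    len(accs)))
    return events


def scan_introgression(matrix: GenotypeMatrix, layout: GenomeLayout,
                       outgroup_ids, block_size: int = 1_000_000,
                       min_accessions: int = 2, core_fraction: float = 0.9):
    """Convenience: blocks -> trees -> placements -> events."""
    blocks = make_windows(layout, block_size)
    placed = []
    for chrom, start, end, label, dist, joint in \
            block_distances(matrix, blocks):
        if np.isnan(dist).any():
            placed.append((chrom, start, end, label, {}, False))
            continue
        tree = nj_tree(dist, matrix.panel.ids)
        placements, ok = clade_membership(tree, matrix.panel, outgroup_ids,
                                          core_fraction)
        placed.append((chrom, start, end, label, placements, ok))
    events = call_introgression_events(placed, matrix.panel, layout,
                                       min_accessions)
    return placed, events


# ---------------------------------------------------------------------------
# bias tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasTestResult:
    table: tuple
    p_fisher: float   # two-sided Fisher exact p on the balanced table
    p_chi2: float     # Pearson chi-square p (no continuity correction)
    odds_ratio: float


def direction_bias_test(n_dir1: int, n_dir2: int) -> BiasTestResult:
    """Test observed event counts against a balanced expectation.

    The 2x2 table is [[n_dir1, n_dir2], [E, E]] with E the rounded mean of
    the two observed counts.  ``p_fisher`` is the two-sided Fisher exact
    p-value (point probabilities <= observed summed over the
    hypergeometric).  ``p_chi2`` is the Pearson chi-square p without
    continuity correction on the same table, which is how the published
    cotton analysis' printed "exact test" p-values were actually obtained
    (they match the chi-square, not the exact test, to four significant
    figures).
    """
    if n_dir1 < 0 or n_dir2 < 0:
        raise ValueError("counts must be nonnegative")
    if n_dir1 + n_dir2 == 0:
        raise ValueError("both counts are zero")
    e = int(round((n_dir1 + n_dir2) / 2))
    table = [[n_dir1, n_dir2], [e, e]]
    odds, p_f = fisher_exact(table, alternative="two-sided")
    cols = (n_dir1 + e, n_dir2 + e)
    if e == 0 or 0 in cols:  # chi-square undefined on zero margins
        p_chi2 = np.nan
    else:
        p_chi2 = float(chi2_contingency(table, correction=False).pvalue)
    return BiasTestResult(((n_dir1, n_dir2), (e, e)), float(p_f),
                          p_chi2, float(odds))


# ---------------------------------------------------------------------------
# f3 three-population test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class F3Result:
    target: str
    source1: str
    source2: str
    f3: float
    se: float
    z: float
    n_sites: int
    n_blocks: int


def f3_statistic(freq_target, freq_src1, freq_src2, block_size: int = 500,
                 n_target_alleles=None, corrected: bool = True,
                 labels=("C", "A", "B")) -> F3Result:
    """f3(target; src1, src2) with block-jackknife standard error.

    Per site with target frequency c and source frequencies a, b the
    numerator is (c - a)(c - b), bias-corrected by the target's sampling
    heterozygosity when allele counts are supplied, and the denominator is
    the target heterozygosity 2c(1 - c) (finite-sample corrected likewise).
    f3 is the ratio of sums; significantly negative f3 indicates the target
    is a mixture of populations related to the two sources.  SE comes from
    a delete-one jackknife over contiguous site blocks of ``block_size``
    sites (>= 20 blocks required); Z = f3 / SE.
    """
    c = np.asarray(freq_target, float)
    a = np.asarray(freq_src1, float)
    b = np.asarray(freq_src2, float)
    ok = np.isfinite(c) & np.isfinite(a) & np.isfinite(b)
    if n_target_alleles is not None:
        n_t = np.asarray(n_target_alleles, float)
        ok &= n_t >= 2
    c, a, b = c[ok], a[ok], b[ok]
    if len(c) == 0 or not np.any((c > 0) & (c < 1)):
        raise ValueError("target monomorphic at all usable sites; "
                         "f3 undefined")
    num = (c - a) * (c - b)
    if corrected and n_target_alleles is not None:
        n_t = np.asarray(n_target_alleles, float)[ok]
        het = 2 * c * (1 - c) * n_t / (n_t - 1)
        num = num - het / (2 * n_t)
        den = het
    else:
        den = 2 * c * (1 - c)

    n_blocks = int(np.ceil(len(c) / block_size))
    if n_blocks < 20:
        raise ValueError(f"only {n_blocks} jackknife blocks; need >= 20 "
                         f"(reduce block_size)")
    block_idx = np.arange(len(c)) // block_size
    num_b = np.bincount(block_idx, weights=num, minlength=n_blocks)
    den_b = np.bincount(block_idx, weights=den, minlength=n_blocks)
    tot_n, tot_d = num_b.sum(), den_b.sum()
    f3 = tot_n / tot_d
    loo = (tot_n - num_b) / (tot_d - den_b)
    se = float(np.sqrt((n_blocks - 1) / n_blocks
                       * np.sum((loo - loo.mean()) ** 2)))
    z = f3 / se if se > 0 else np.nan
    return F3Result(labels[0], labels[1], labels[2], float(f3), se,
                    float(z), len(c), n_blocks)


def f3_from_matrix(matrix: GenotypeMatrix, target_ids, src1_ids, src2_ids,
                   block_size: int = 500,
                   labels=("C", "A", "B")) -> F3Result:
    """f3 computed from a genotype matrix's empirical allele frequencies."""
    c, n_t = matrix.alt_frequency(target_ids)
    a, _ = matrix.alt_frequency(src1_ids)
    b, _ = matrix.alt_frequency(src2_ids)
    return f3_statistic(c, a, b, block_size=block_size,
                        n_target_alleles=n_t, corrected=True, labels=labels)
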