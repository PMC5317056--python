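"""Genome-wide structure: simple-matching NJ tree and allele-frequency PCA.

The distance is the whole-genome simple-matching coefficient (pairwise
complete over missing calls); the tree is the same neighbor-joining used for
block phylogenies, serialized as newick.  PCA normalizes each site by its
estimated allele frequency (center by 2p, scale by sqrt(p(1-p))) with mean
imputation of missing dosages, the convention of allele-frequency-based
ordination in resequencing panels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MISSING
from .introgression import nj_tree, simple_matching_distance

__all__ = ["genomewide_distance", "build_tree", "pca"]


def genomewide_distance(matrix: GenotypeMatrix):
    """Accession x accession simple-matching distance over all sites.

    Returns (distance DataFrame, joint-call count DataFrame).  Raises if
    any accession pair shares no called site.
    """
    if matrix.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    dist, joint = simple_matching_distance(matrix.calls)
    if np.isnan(dist).any():
        i, j = np.argwhere(np.isnan(dist))[0]
        raise ValueError(f"accessions {matrix.panel.ids[i]} and "
                         f"{matrix.panel.ids[j]} share no called site")
    ids = matrix.panel.ids
    return (pd.DataFrame(dist, index=ids, columns=ids),
            pd.DataFrame(joint, index=ids, columns=ids))


def build_tree(distance: pd.DataFrame) -> str:
    """Neighbor-joining tree from a distance DataFrame, as newick."""
    tree = nj_tree(distance.to_numpy(), list(distance.index))
    return tree.as_string(schema="newick").strip()


def pca(matrix: GenotypeMatrix, n_components: int = 10):
    """Frequency-normalized PCA of the genotype matrix.

    Each site column is centered by 2p and scaled by sqrt(p(1 - p)) with p
    the site's alt-allele frequency; missing dosages are mean-imputed
    (i.e. zero after centering).  Sign convention: within each component
    the accession coordinate of largest magnitude is positive.  Returns
    (coordinates DataFrame accessions x PCs, eigenvalues array).
    """
    if matrix.n_accessions < 2 or matrix.n_sites < 2:
        raise ValueError("need >= 2 accessions and >= 2 sites")
    g = matrix.calls.astype(float)
    g[g == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2
    if np.isnan(p).any():
        raise ValueError("site with all calls missing")
    keep = (p > 0) & (p < 1)
    g, p = g[:, keep], p[keep]
    x = (g - 2 * p) / np.sqrt(p * (1 - p))
    x[np.isnan(x)] = 0.0
    n_components = min(n_components, min(x.shape) - 1)
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals = np.maximum(evals[order], 0.0)
    coords = evecs[:, order] * np.sqrt(np.maximum(evals, 0))
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    cols = [f"PC{k+1}" for k in range(coords.shape[1])]
    return pd.DataFrame(coords, index=matrix.panel.ids, columns=cols), evals
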