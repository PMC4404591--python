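"""Shared numerical helpers: sequential projections, tree utilities, RNG plumbing."""

from __future__ import annotations

import numpy as np
import scipy.linalg
from scipy.cluster.hierarchy import linkage


def child_seed(seed: int | None, index: int) -> int:
    """Derive an independent 31-bit child seed from a master seed."""
    ss = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def sequential_block_projection(blocks, n_rows, tol=1e-9):
    """Orthonormalize design-matrix blocks sequentially (Type I order).

    Parameters
    ----------
    blocks : list of (name, ndarray of shape (n_rows, k))
        Design blocks in fitting order.  Columns collinear with earlier
        blocks are dropped, so each block's df is its *additional* rank.

    Returns
    -------
    list of (name, Q_block, df) where Q_block has orthonormal columns
    spanning the block's contribution beyond all earlier blocks.
    """
    q_acc = np.zeros((n_rows, 0))
    out = []
    for name, xb in blocks:
        xb = np.asarray(xb, dtype=float)
        if xb.ndim == 1:
            xb = xb[:, None]
        r = xb - q_acc @ (q_acc.T @ xb)
        r = r - q_acc @ (q_acc.T @ r)  # second pass for numerical stability
        scale = max(np.abs(xb).max(initial=0.0), 1.0)
        q, rr, _ = scipy.linalg.qr(r, mode="economic", pivoting=True)
        diag = np.abs(np.diag(rr)) if rr.size else np.array([])
        rank = int((diag > tol * scale * np.sqrt(n_rows)).sum())
        qb = q[:, :rank]
        out.append((name, qb, rank))
        if rank:
            q_acc = np.hstack([q_acc, qb])
    return out


def upgma_linkage(dist_matrix):
    """Average-linkage agglomeration of a square distance matrix."""
    d = np.asarray(dist_matrix, dtype=float)
    iu = np.triu_indices_from(d, k=1)
    return linkage(d[iu], method="average")


def linkage_to_newick(z, labels):
    """Render a scipy linkage matrix as a newick string with branch lengths.

    Heights are interpreted as cophenetic distances, so each branch gets
    half the height difference between parent and child (ultrametric tree).
    """
    z = np.asarray(z)
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: str(labels[i]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = (h - heights[a]) / 2.0
        lb = (h - heights[b]) / 2.0
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(z) - 1] + ";"


def leaf_clusters(z, n_leaves):
    """Map each internal node of a linkage matrix to its set of leaf indices."""
    clusters = {i: frozenset([i]) for i in range(n_leaves)}
    for k, row in enumerate(z):
        a, b = int(row[0]), int(row[1])
        clusters[n_leaves + k] = clusters[a] | clusters[b]
    return clusters


def is_exclusive_clade(z, n_leaves, leaf_set):
    """True if some node of the tree contains exactly `leaf_set` (monophyly)."""
    target = frozenset(leaf_set)
    for node_set in leaf_clusters(z, n_leaves).values():
        if node_set == target:
            return True
    return False


def bh_adjust(pvalues):
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
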