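"""Nei's standard genetic distance and neighbour-joining trees.

Individuals are treated as populations of four allele draws: the dosage code
itself is the individual's reference-allele frequency p (q = 1 - p).  For a
pair (x, y) over L loci,

    J_xy = mean_L(p_x p_y + q_x q_y),  J_x = mean_L(p_x^2 + q_x^2),

and Nei's distance is D = -ln(J_xy / sqrt(J_x J_y)).  Averaging the J's over
loci makes cohorts with different marker counts comparable.
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .matrices import DosageMatrix

#: Sentinel distance for pairs with zero shared identity (J_xy = 0).
INFINITE_DISTANCE_CAP = 700.0


def nei_distance(dosages: DosageMatrix) -> DistanceMatrix:
    """Pairwise Nei (1972) standard distance between individuals.

    Requires a complete (imputed) matrix.  Pairs with J_xy = 0 have infinite
    distance; these are reported as :data:`INFINITE_DISTANCE_CAP` with a
    warning.  The result is symmetric with a zero diagonal, and is invariant
    to swapping ref/alt coding at any subset of loci.
    """
    P = dosages.codes
    if np.isnan(P).any():
        raise ValueError("distance needs a complete matrix; impute first")
    L = dosages.n_loci
    if L == 0:
        raise ValueError("no loci")
    Q = 1.0 - P
    J = (P @ P.T + Q @ Q.T) / L
    diag = np.diag(J).copy()
    norm = np.sqrt(np.outer(diag, diag))
    with np.errstate(divide="ignore"):
        ratio = J / norm
        D = -np.log(np.clip(ratio, 0.0, 1.0))
    if np.isinf(D).any():
        warnings.warn(
            "pairs with zero shared identity; capping infinite Nei distances",
            stacklevel=2,
        )
        D[np.isinf(D)] = INFINITE_DISTANCE_CAP
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, ids=list(dosages.samples))


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Classic neighbour joining (Saitou-Nei) on a distance matrix.

    At each step the pair minimising the Q-criterion is joined, with ties
    broken by the smallest (i, j) index pair in current matrix order.
    Negative branch-length estimates are clamped to zero and the deficit
    moved to the sister branch (flagged with a warning).  Returns an unrooted
    tree represented with a trifurcating root.
    """
    if isinstance(dist, DistanceMatrix):
        D = dist.data.astype(float).copy()
        ids = list(dist.ids)
    else:
        D = np.asarray(dist, dtype=float).copy()
        ids = [str(i) for i in range(len(D))]
        if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
            raise ValueError("distance matrix must be square and symmetric")
    n = len(ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 samples")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    clamped = False
    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        best = (np.inf, -1, -1)
        for i in range(r):
            for j in range(i + 1, r):
                if Q[i, j] < best[0]:
                    best = (Q[i, j], i, j)
        _, i, j = best
        d_ij = D[i, j]
        li = 0.5 * d_ij + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = d_ij - li
        if li < 0:
            lj += li
            li = 0.0
            clamped = True
        if lj < 0:
            li += lj
            lj = 0.0
            clamped = True
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(max(lj, 0.0))
        parent.append(nodes[i])
        parent.append(nodes[j])
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(r) if k not in (i, j)]
        D_next = np.empty((r - 1, r - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = d_new[keep]
        D_next[:-1, -1] = d_new[keep]
        D_next[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        D = D_next
    # final three-way join: closed-form terminal branch lengths
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    lens = [la, lb, lc]
    if min(lens) < 0:
        clamped = True
        lens = [max(x, 0.0) for x in lens]
    root = TreeNode()
    for node, ln in zip(nodes, lens):
        node.length = float(ln)
        root.append(node)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to zero", stacklevel=2)
    return root
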