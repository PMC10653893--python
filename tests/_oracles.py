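"""Independent brute-force oracles used to validate the implementation.

Each oracle is written from the definition of the quantity it checks and
shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np

NEG_INF = float("-inf")


def gotoh_score(a, b, sub, gap_open=-11.0, gap_extend=-1.0, local=False):
    """Quadratic-space affine-gap optimal alignment score.

    ``sub(x, y)`` returns the substitution score.  The first residue of a
    gap costs ``gap_open``, each further residue ``gap_extend``.  Global
    (Needleman-Wunsch-Gotoh) or local (Smith-Waterman) per ``local``.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF)
    Ix = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
        if local:
            M[i, 0] = 0.0
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
        if local:
            M[0, j] = 0.0
    best_local = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(a[i - 1], b[j - 1])
            diag = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = diag + s
            if local:
                M[i, j] = max(M[i, j], 0.0)
            Ix[i, j] = max(
                M[i - 1, j] + gap_open,
                Ix[i - 1, j] + gap_extend,
                Iy[i - 1, j] + gap_open,
            )
            Iy[i, j] = max(
                M[i, j - 1] + gap_open,
                Iy[i, j - 1] + gap_extend,
                Ix[i, j - 1] + gap_open,
            )
            if local:
                best_local = max(best_local, M[i, j])
    if local:
        return best_local
    return max(M[n, m], Ix[n, m], Iy[n, m])


class UnionFind:
    """Textbook union-find with path compression."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def groups(self):
        out = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return sorted((sorted(g) for g in out.values()), key=lambda g: (-len(g), g[0]))


def irls_logistic(X, y, l2=1.0, tol=1e-12, max_iter=200):
    """Iteratively reweighted least squares for L2-penalized logistic
    regression (intercept unpenalized).  Returns (weights, intercept)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    Z = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    pen = np.diag([0.0] + [l2] * p)
    for _ in range(max_iter):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = Z.T @ (y - mu) - pen @ beta
        H = (Z.T * W) @ Z + pen
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta[1:], beta[0]


def trimmed_mean_sorted(depths, trim_frac):
    """Sort-slice-mean trimmed mean used as the coverage oracle."""
    d = np.sort(np.asarray(depths))
    k = int(np.floor(trim_frac * d.size))
    sl = d[k : d.size - k] if k else d
    return float(sl.mean())


def greedy_derep_oracle(seqs, threshold, identity):
    """Evaluate the greedy dereplication rule directly from its definition.

    ``identity(a, b)`` -> fraction; sequences processed longest-first (ties
    by id); each joins the first best-identity representative >= threshold.
    """
    order = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    reps, members = [], {}
    for s in order:
        best, best_i = None, -1.0
        for r in reps:
            i = identity(s, r)
            if i > best_i:
                best, best_i = r, i
        if best is not None and best_i >= threshold:
            members[best.id].append(s.id)
        else:
            reps.append(s)
            members[s.id] = [s.id]
    return [(r.id, members[r.id]) for r in reps]
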