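"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computational paths: dense
matrix algebra instead of blockwise REML, all-triangle containment instead
of monotone chains, exhaustive relabeling instead of sampled permutations.
"""

import itertools
import math

import numpy as np


def dense_reml_neg2(lam, y, X, codes):
    """-2 REML log-likelihood via explicit dense V = I + lam*ZZ'."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    Z = np.eye(int(codes.max()) + 1)[codes]
    V = np.eye(n) + lam * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = max(float(r @ Vi @ r) / (n - p), 1e-300)
    neg2 = (
        (n - p) * (math.log(2 * math.pi * s2) + 1)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
    )
    return neg2, beta, s2


def grid_search_reml(y, X, codes, n_grid=2000, lo=-10.0, hi=10.0):
    """Grid search over log(lambda), including the lambda=0 boundary."""
    grid = np.concatenate(([0.0], np.exp(np.linspace(lo, hi, n_grid))))
    best = None
    for lam in grid:
        neg2, beta, s2 = dense_reml_neg2(lam, y, X, codes)
        if best is None or neg2 < best[0]:
            best = (neg2, lam, beta, s2)
    return {"neg2": best[0], "lam": best[1], "beta": best[2], "sigma2": best[3]}


def _in_triangle(p, a, b, c, tol=1e-12):
    """Barycentric point-in-triangle test, boundary inclusive."""
    v0, v1, v2 = c - a, b - a, p - a
    d00, d01, d02 = v0 @ v0, v0 @ v1, v0 @ v2
    d11, d12 = v1 @ v1, v1 @ v2
    denom = d00 * d11 - d01 * d01
    if abs(denom) < tol:
        return False
    u = (d11 * d02 - d01 * d12) / denom
    v = (d00 * d12 - d01 * d02) / denom
    return u >= -tol and v >= -tol and u + v <= 1 + tol


def hull_vertices_bruteforce(points):
    """A point is a hull vertex iff it is in no triangle of the other points.

    O(n^4); valid for points in general position (no exact collinear
    triples), which random continuous coordinates satisfy a.s.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    vertices = []
    for i in range(n):
        others = [pts[j] for j in range(n) if j != i]
        inside = any(
            _in_triangle(pts[i], a, b, c)
            for a, b, c in itertools.combinations(others, 3)
        )
        if not inside:
            vertices.append(tuple(np.round(pts[i], 12)))
    return set(vertices)


def exhaustive_mantel(D1, D2, alternative="two_sided"):
    """Exact permutation p over all relabelings of D2 (n! of them)."""
    D1 = np.asarray(D1, float)
    D2 = np.asarray(D2, float)
    n = D1.shape[0]
    iu = np.triu_indices(n, k=1)
    a = D1[iu]
    r_obs = float(np.corrcoef(a, D2[iu])[0, 1])
    count, total = 0, 0
    for perm in itertools.permutations(range(n)):
        P = np.array(perm)
        r = float(np.corrcoef(a, D2[np.ix_(P, P)][iu])[0, 1])
        total += 1
        if alternative == "two_sided":
            count += abs(r) >= abs(r_obs) - 1e-12
        elif alternative == "greater":
            count += r >= r_obs - 1e-12
        else:
            count += r <= r_obs + 1e-12
    return {"r": r_obs, "p": count / total}
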