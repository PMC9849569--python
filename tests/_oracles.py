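"""Independent oracles used by the tests: generic optimizers and brute-force
graph enumeration, deliberately sharing no code with the package."""

import itertools

import numpy as np


def prox_gradient_glasso(R, lam, max_iter=100_000, tol=1e-12):
    """Generic proximal-gradient minimizer of
    -log det K + tr(RK) + lam * sum_{i!=j} |K_ij| with backtracking."""
    p = R.shape[0]
    K = np.linalg.inv(R + 0.1 * np.eye(p))
    off = ~np.eye(p, dtype=bool)

    def smooth(Km):
        sgn, ld = np.linalg.slogdet(Km)
        return -ld + float(np.sum(R * Km))

    t = 0.1
    for _ in range(max_iter):
        G = R - np.linalg.inv(K)
        f0 = smooth(K)
        while True:
            Kn = K - t * G
            Kn[off] = np.sign(Kn[off]) * np.maximum(np.abs(Kn[off]) - t * lam,
                                                    0.0)
            Kn = 0.5 * (Kn + Kn.T)
            if np.linalg.eigvalsh(Kn).min() > 1e-10:
                diff = Kn - K
                if smooth(Kn) <= (f0 + np.sum(G * diff)
                                  + np.sum(diff ** 2) / (2 * t) + 1e-14):
                    break
            t *= 0.5
        if np.max(np.abs(Kn - K)) < tol:
            return Kn
        K = Kn
        t *= 1.05
    return K


def random_pd_correlation(rng, p):
    A = rng.normal(size=(p, 3 * p))
    R = np.corrcoef(A)
    return R


def brute_force_distances(weights, nodes):
    """Shortest 1/|w| path lengths by exhaustive simple-path enumeration."""
    p = len(nodes)
    D = np.full((p, p), np.inf)
    np.fill_diagonal(D, 0.0)
    for s in range(p):
        for t in range(p):
            if s == t:
                continue
            best = np.inf
            for r in range(p - 1):
                inner = [v for v in range(p) if v not in (s, t)]
                for mid in itertools.permutations(inner, r):
                    path = (s, *mid, t)
                    length = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if weights[a, b] == 0:
                            ok = False
                            break
                        length += 1.0 / abs(weights[a, b])
                    if ok and length < best:
                        best = length
            D[s, t] = best
    return D


def brute_force_bridge_betweenness(weights, communities, tol=1e-9):
    """Fractional shortest-path counts through intermediates, restricted to
    cross-community endpoint pairs, by exhaustive enumeration."""
    p = weights.shape[0]
    D = brute_force_distances(weights, range(p))
    counts = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            if communities[s] == communities[t] or not np.isfinite(D[s, t]):
                continue
            # enumerate all simple paths, keep the shortest ones
            shortest = []
            inner = [v for v in range(p) if v not in (s, t)]
            for r in range(p - 1):
                for mid in itertools.permutations(inner, r):
                    path = (s, *mid, t)
                    length = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if weights[a, b] == 0:
                            ok = False
                            break
                        length += 1.0 / abs(weights[a, b])
                    if ok and abs(length - D[s, t]) < tol:
                        shortest.append(path)
            sigma = len(shortest)
            for path in shortest:
                for v in path[1:-1]:
                    counts[v] += 1.0 / sigma
    return counts
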