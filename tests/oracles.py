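"""Independent brute-force oracles shared by metric tests.

Deliberately naive: per-point python loops and sorts, no shared code with the
package's vectorized implementations.
"""

import numpy as np


def brute_radii(X, k):
    out = []
    for i, xi in enumerate(X):
        dists = sorted(
            float(np.linalg.norm(np.asarray(xi) - np.asarray(xj)))
            for j, xj in enumerate(X) if j != i
        )
        out.append(dists[k - 1])
    return np.array(out)


def brute_prdc(X, Y, k):
    """Double-loop precision, recall, density, coverage."""
    rx = brute_radii(X, k)
    ry = brute_radii(Y, k)
    in_ball = np.array([
        [float(np.linalg.norm(np.asarray(y) - np.asarray(x))) <= rx[i]
         for i, x in enumerate(X)]
        for y in Y
    ])
    prec = np.mean([row.any() for row in in_ball])
    rec = np.mean([
        any(float(np.linalg.norm(np.asarray(x) - np.asarray(y))) <= ry[j]
            for j, y in enumerate(Y))
        for x in X
    ])
    dens = in_ball.sum() / (k * len(Y))
    cov = np.mean([in_ball[:, i].any() for i in range(len(X))])
    return float(prec), float(rec), float(dens), float(cov)
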