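"""Independent numerical oracles used only by the test suite.

These deliberately avoid the closed forms used in the package: the beam
solvers discretize the Euler–Bernoulli energy directly, the second moment is
computed by quadrature over the disc, and regression slopes come from the
normal equations assembled by hand.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve


def fd_tip_stiffness_foundation(EI: float, k_w: float, free_length: float,
                                embedded_length: float, n: int = 6001) -> float:
    """Tip stiffness (N/m) of a beam with a free segment and a Winkler-supported
    embedded segment, by finite differences on the bending energy.

    Node 0 is the loaded tip; the far end is free (the foundation alone
    restrains the embedded segment). Minimizes
    ∫ EI/2 y''² dx + ∫ k_w/2 y² dx − F·y(0). The problem is solved in
    nondimensional form (EI = 1, characteristic length 1/λ) to keep the
    biharmonic operator well conditioned across foundation stiffnesses.
    """
    lam = (k_w / (4.0 * EI)) ** 0.25
    free_s = free_length * lam
    emb_s = embedded_length * lam
    L = free_s + emb_s
    h = L / (n - 1)
    x = np.linspace(0.0, L, n)
    # second-difference operator on interior nodes, EI' = 1, k_w' = 4
    main = np.ones(n - 2)
    D = sparse.diags([main, -2 * main, main], [0, 1, 2],
                     shape=(n - 2, n)) / h**2
    K = h * (D.T @ D)
    kw_diag = np.where(x >= free_s, 4.0, 0.0) * h
    K = (K + sparse.diags(kw_diag)).tocsc()
    f = np.zeros(n)
    f[0] = 1.0
    y = spsolve(K, f)
    # scaled stiffness k' maps back as k = k'·EI·λ³
    return (1.0 / y[0]) * EI * lam**3


def fd_tip_stiffness_cantilever(EI: float, length: float, n: int = 1001) -> float:
    """Tip stiffness (N/m) of a clamped-free Euler–Bernoulli cantilever.

    The clamp at the far end is imposed by eliminating the last two nodes
    (y = y' = 0 to first order)."""
    h = length / (n - 1)
    main = np.ones(n - 2)
    D = sparse.diags([main, -2 * main, main], [0, 1, 2],
                     shape=(n - 2, n)) / h**2
    # clamp: y_{n-2} = y_{n-1} = 0, eliminated by restricting to free DOFs
    K = (EI * h * (D.T @ D)).tocsc()[:-2, :-2]
    f = np.zeros(n - 2)
    f[0] = 1.0
    y = spsolve(K, f)
    return 1.0 / y[0]


def quadrature_second_moment(diameter: float, n: int = 4000) -> float:
    """I = ∫ y² dA over the disc, by midpoint quadrature on horizontal strips."""
    r = diameter / 2.0
    y = (np.arange(n) + 0.5) / n * 2 * r - r
    width = 2.0 * np.sqrt(np.maximum(r**2 - y**2, 0.0))
    return float(np.sum(y**2 * width) * (2 * r / n))


def normal_equations_slope(x, y) -> tuple[float, float]:
    """OLS slope/intercept assembled from the normal equations by hand."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def enumerate_permutation_p(a, b) -> float:
    """Two-sided mean-difference permutation p by brute-force enumeration."""
    from itertools import combinations

    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    na, n = len(a), len(a) + len(b)
    obs = abs(np.mean(a) - np.mean(b))
    count = total = 0
    for idx in combinations(range(n), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if abs(np.mean(ga) - np.mean(gb)) >= obs - 1e-12:
            count += 1
    return count / total
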