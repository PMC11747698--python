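"""Default genetic parameters for the simulated boar-taint population.

The defaults emulate a German Pietrain progeny-test population in which
backfat skatole and androstenone (log10 scale: SKAt, ANONt) and the 0-5
sensory scores of 10 trained assessors were recorded on ~1,000 intact
males.  Heritabilities, genetic and residual variances of the assessor
traits, and the correlation structure among traits follow the published
parameter estimates for that population; the compound-trait phenotypic
variances (not published) are set to realistic log10-scale values.

The assembled 12x12 covariance matrices are built from rounded printed
values and are therefore projected to the nearest positive semidefinite
matrix when necessary (eigenvalue clipping); the projection distance is
tiny and does not alter the qualitative structure.
"""

from __future__ import annotations

import numpy as np

#: Canonical trait order used throughout the package.
CAUSAL_TRAITS = ("SKAt", "ANONt")

# ---------------------------------------------------------------------------
# Study-like parameter values (assessors 1..10)
# ---------------------------------------------------------------------------

#: Genetic variances of the Snell-transformed assessor scores.
ASSESSOR_GENETIC_VAR = np.array(
    [0.18, 0.27, 0.14, 0.51, 0.15, 0.14, 0.37, 0.16, 0.50, 0.14])

#: Residual variances of the Snell-transformed assessor scores.
ASSESSOR_RESIDUAL_VAR = np.array(
    [1.50, 1.33, 1.99, 1.54, 1.25, 2.14, 0.88, 1.90, 1.65, 1.16])

#: Genetic correlations of each assessor trait with SKAt and ANONt.
ASSESSOR_RG_SKA = np.array(
    [0.84, 0.46, 0.81, 0.83, 0.79, 0.87, 0.72, 0.37, 0.86, 0.61])
ASSESSOR_RG_ANON = np.array(
    [0.52, 0.44, 0.29, 0.52, 0.61, 0.58, 0.50, 0.25, 0.53, 0.53])

#: Residual correlations of each assessor trait with SKAt and ANONt.
ASSESSOR_RR_SKA = np.array(
    [0.24, 0.20, 0.13, 0.15, 0.30, 0.11, 0.25, 0.00, 0.25, 0.17])
ASSESSOR_RR_ANON = np.array(
    [0.13, 0.20, 0.10, 0.14, 0.24, 0.10, 0.17, 0.07, 0.13, 0.14])

#: Genetic correlations among assessors (upper triangle, row < col).
_RG_UPPER = [
    (0, 1, 0.56), (0, 2, 0.58), (0, 3, 0.70), (0, 4, 0.58), (0, 5, 0.69),
    (0, 6, 0.63), (0, 7, 0.19), (0, 8, 0.76), (0, 9, 0.48),
    (1, 2, 0.63), (1, 3, 0.35), (1, 4, 0.53), (1, 5, 0.61), (1, 6, 0.37),
    (1, 7, 0.35), (1, 8, 0.56), (1, 9, 0.58),
    (2, 3, 0.79), (2, 4, 0.70), (2, 5, 0.73), (2, 6, 0.49), (2, 7, 0.38),
    (2, 8, 0.76), (2, 9, 0.65),
    (3, 4, 0.63), (3, 5, 0.62), (3, 6, 0.58), (3, 7, 0.17), (3, 8, 0.83),
    (3, 9, 0.56),
    (4, 5, 0.89), (4, 6, 0.65), (4, 7, 0.20), (4, 8, 0.85), (4, 9, 0.47),
    (5, 6, 0.77), (5, 7, 0.52), (5, 8, 0.80), (5, 9, 0.71),
    (6, 7, 0.48), (6, 8, 0.78), (6, 9, 0.69),
    (7, 8, 0.11), (7, 9, 0.84),
    (8, 9, 0.51),
]

#: Phenotypic correlations among assessors (row > col in the source table).
_RP_LOWER = [
    (1, 0, 0.29),
    (2, 0, 0.18), (2, 1, 0.18),
    (3, 0, 0.26), (3, 1, 0.30), (3, 2, 0.16),
    (4, 0, 0.27), (4, 1, 0.25), (4, 2, 0.15), (4, 3, 0.26),
    (5, 0, 0.21), (5, 1, 0.21), (5, 2, 0.12), (5, 3, 0.24), (5, 4, 0.18),
    (6, 0, 0.32), (6, 1, 0.25), (6, 2, 0.14), (6, 3, 0.35), (6, 4, 0.31),
    (6, 5, 0.23),
    (7, 0, 0.06), (7, 1, 0.06), (7, 2, 0.06), (7, 3, 0.09), (7, 4, 0.07),
    (7, 5, 0.03), (7, 6, 0.13),
    (8, 0, 0.20), (8, 1, 0.19), (8, 2, 0.07), (8, 3, 0.23), (8, 4, 0.23),
    (8, 5, 0.17), (8, 6, 0.29), (8, 7, 0.04),
    (9, 0, 0.27), (9, 1, 0.31), (9, 2, 0.17), (9, 3, 0.23), (9, 4, 0.24),
    (9, 5, 0.17), (9, 6, 0.22), (9, 7, 0.05), (9, 8, 0.18),
]

#: Score-class frequencies (classes 0-5) per assessor, used both to derive
#: default liability cutpoints and as worked-example inputs.
SCORE_FREQUENCIES = np.array([
    [0.43, 0.10, 0.12, 0.17, 0.13, 0.05],
    [0.48, 0.00, 0.08, 0.19, 0.19, 0.06],
    [0.28, 0.02, 0.17, 0.25, 0.21, 0.07],
    [0.35, 0.00, 0.07, 0.23, 0.20, 0.15],
    [0.52, 0.00, 0.05, 0.22, 0.12, 0.09],
    [0.13, 0.17, 0.14, 0.20, 0.22, 0.14],
    [0.59, 0.08, 0.11, 0.10, 0.06, 0.06],
    [0.28, 0.09, 0.21, 0.19, 0.17, 0.06],
    [0.21, 0.18, 0.26, 0.19, 0.11, 0.05],
    [0.52, 0.00, 0.22, 0.14, 0.07, 0.05],
])

# Compound traits: heritabilities and correlations as estimated in the
# study population; phenotypic variances chosen at realistic log10 scale.
SKAT_PHENO_VAR = 0.12
ANONT_PHENO_VAR = 0.16
SKAT_H2 = 0.52
ANONT_H2 = 0.53
CAUSAL_RG = 0.46
CAUSAL_RP = 0.38

#: Observed-scale means of the log10 compounds (ppm -> log10 ppm).
SKAT_MEAN = -0.9
ANONT_MEAN = 0.0


def nearest_psd(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    floor = eps * max(vals.max(), 1.0)
    if vals.min() >= 0.0:
        return sym
    clipped = np.clip(vals, floor, None)
    return (vecs * clipped) @ vecs.T


def study_covariances(n_assessors: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Assemble genetic (G) and residual (R) covariance matrices.

    Trait order is (SKAt, ANONt, assessor 1..n_assessors).  Genetic blocks
    come directly from the published-style correlations and variances;
    residual covariances among assessors are derived from the phenotypic
    correlations (r_P * sd_Pi * sd_Pj - g_ij).  Both matrices are PSD
    projected if rounding made them indefinite.
    """
    if not 1 <= n_assessors <= 10:
        raise ValueError("n_assessors must be between 1 and 10")
    k = n_assessors
    m = 2 + k
    g_ska = SKAT_H2 * SKAT_PHENO_VAR
    g_anon = ANONT_H2 * ANONT_PHENO_VAR
    r_ska = SKAT_PHENO_VAR - g_ska
    r_anon = ANONT_PHENO_VAR - g_anon

    G = np.zeros((m, m))
    R = np.zeros((m, m))
    G[0, 0], G[1, 1] = g_ska, g_anon
    G[0, 1] = G[1, 0] = CAUSAL_RG * np.sqrt(g_ska * g_anon)
    R[0, 0], R[1, 1] = r_ska, r_anon
    pheno_cov = CAUSAL_RP * np.sqrt(SKAT_PHENO_VAR * ANONT_PHENO_VAR)
    R[0, 1] = R[1, 0] = pheno_cov - G[0, 1]

    gv = ASSESSOR_GENETIC_VAR[:k]
    rv = ASSESSOR_RESIDUAL_VAR[:k]
    for i in range(k):
        G[2 + i, 2 + i] = gv[i]
        R[2 + i, 2 + i] = rv[i]
        G[0, 2 + i] = G[2 + i, 0] = ASSESSOR_RG_SKA[i] * np.sqrt(g_ska * gv[i])
        G[1, 2 + i] = G[2 + i, 1] = ASSESSOR_RG_ANON[i] * np.sqrt(g_anon * gv[i])
        R[0, 2 + i] = R[2 + i, 0] = ASSESSOR_RR_SKA[i] * np.sqrt(r_ska * rv[i])
        R[1, 2 + i] = R[2 + i, 1] = ASSESSOR_RR_ANON[i] * np.sqrt(r_anon * rv[i])

    pheno = gv + rv
    for i, j, rg in _RG_UPPER:
        if i < k and j < k:
            G[2 + i, 2 + j] = G[2 + j, 2 + i] = rg * np.sqrt(gv[i] * gv[j])
    for i, j, rp in _RP_LOWER:
        if i < k and j < k:
            cov_p = rp * np.sqrt(pheno[i] * pheno[j])
            cov_r = cov_p - G[2 + i, 2 + j]
            R[2 + i, 2 + j] = R[2 + j, 2 + i] = cov_r

    return nearest_psd(G), nearest_psd(R)


def trait_labels(n_assessors: int = 10) -> list[str]:
    """Canonical trait labels (SKAt, ANONt, SENSt_1..k)."""
    return list(CAUSAL_TRAITS) + [f"SENSt_{i}" for i in range(1, n_assessors + 1)]


def default_thresholds(n_assessors: int = 10) -> np.ndarray:
    """Liability cutpoints (z scale) implied by the default score frequencies.

    Thresholds are the standard-normal quantiles of the cumulative class
    frequencies; a zero-frequency class yields a tied (repeated) cutpoint
    and therefore stays empty under the simulated liabilities.
    """
    freq = SCORE_FREQUENCIES[:n_assessors]
    cum = np.cumsum(freq[:, :5], axis=1)
    from scipy.stats import norm

    return norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))
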