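"""A posteriori recursive reparameterization of fitted (co)variances.

The multivariate animal model treats the compound traits (SKAt, ANONt)
and the sensory traits symmetrically.  The recursive model is the
statistically equivalent reparameterization in which the two compound
traits causally drive each sensory trait: a structured matrix Lambda
with unit diagonal and entries -lambda_{c->j} in the causal columns of
each dependent row transforms the fitted components as

    G_RM = Lambda G Lambda',   R_RM = Lambda R Lambda'.

The coefficients are the residual regressions of each dependent trait on
the two causal traits (the causal-block restricted step of an LDL
factorization of R), which zeroes the causal<->dependent block of R_RM
exactly while leaving the causal 2x2 blocks and the dependent<->dependent
residual covariances untouched.  Sign convention: the matrix stores
-lambda, so a *positive* stored entry means a negative recursive effect
(higher dependent trait at lower causal trait).

Applied after any fit, this quantifies how much of each sensory trait's
genetic variance is channelled through the causal compounds
(Delta sigma_u^2, in percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reml import GeneticParameters, VarianceComponents, derived_parameters


class SingularCausalBlock(ValueError):
    """The causal 2x2 residual block is singular."""


@dataclass(frozen=True)
class LambdaMatrix:
    """Structured recursive-parameter matrix (stores -lambda entries)."""

    matrix: np.ndarray
    causal_indices: tuple[int, ...]

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        m = mat.shape[0]
        if mat.shape != (m, m):
            raise ValueError("Lambda must be square")
        if not np.allclose(np.diag(mat), 1.0):
            raise ValueError("Lambda diagonal must be 1")
        mask = np.zeros((m, m), dtype=bool)
        np.fill_diagonal(mask, True)
        dep = [j for j in range(m) if j not in self.causal_indices]
        for j in dep:
            for c in self.causal_indices:
                mask[j, c] = True
        if np.any(mat[~mask] != 0.0):
            raise ValueError("Lambda has entries outside its structure")
        object.__setattr__(self, "matrix", mat)

    def lambdas(self) -> np.ndarray:
        """Regression coefficients lambda_{c->j} (sign convention undone)."""
        return -self.matrix[:, list(self.causal_indices)]


@dataclass
class RecursiveComponents:
    """Transformed components and derived recursive-model parameters."""

    lam: LambdaMatrix
    G_RM: np.ndarray
    R_RM: np.ndarray
    parameters: GeneticParameters
    delta_gvar: np.ndarray      # percent reduction per trait (0 for causal)


def structural_lambda(R: np.ndarray,
                      causal_indices: tuple[int, int] = (0, 1)
                      ) -> LambdaMatrix:
    """Recursive coefficients from the residual covariance matrix.

    For each dependent trait j the pair (lambda_1->j, lambda_2->j) solves
    R_cc lambda = R_cj (the residual regression of trait j on the causal
    traits); stored negated in row j.  This choice makes the
    causal<->dependent block of Lambda R Lambda' exactly zero.
    """
    R = np.asarray(R, dtype=float)
    m = R.shape[0]
    ci = list(causal_indices)
    Rcc = R[np.ix_(ci, ci)]
    if np.linalg.matrix_rank(Rcc) < len(ci) or np.linalg.det(Rcc) <= 0:
        raise SingularCausalBlock("causal residual block is singular")
    lam = np.eye(m)
    for j in range(m):
        if j in ci:
            continue
        coef = np.linalg.solve(Rcc, R[ci, j])
        lam[j, ci] = -coef
    return LambdaMatrix(lam, tuple(ci))


def transform_components(G: np.ndarray, R: np.ndarray, lam: LambdaMatrix
                         ) -> RecursiveComponents:
    """G_RM = Lambda G Lambda', R_RM = Lambda R Lambda' plus derived values."""
    L = lam.matrix
    G = np.asarray(G, float); R = np.asarray(R, float)
    if G.shape != L.shape or R.shape != L.shape:
        raise ValueError("dimension mismatch between components and Lambda")
    G_RM = L @ G @ L.T
    R_RM = L @ R @ L.T
    vc = VarianceComponents(
        trait_labels=[f"t{i}" for i in range(L.shape[0])], G=G_RM, R=R_RM)
    pars = derived_parameters(vc)
    delta = variance_reduction(G, G_RM, lam.causal_indices)
    return RecursiveComponents(lam, G_RM, R_RM, pars, delta)


def variance_reduction(G: np.ndarray, G_RM: np.ndarray,
                       causal_indices: tuple[int, ...] = (0, 1)
                       ) -> np.ndarray:
    """Percent reduction of genetic variance, per trait.

    Delta_j = 100 (g_jj - g_RM,jj) / g_jj for dependent traits; causal
    traits are 0 by construction (their blocks are preserved).
    """
    g = np.diag(np.asarray(G, float))
    g_rm = np.diag(np.asarray(G_RM, float))
    if np.any(g <= 0):
        raise ValueError("multivariate genetic variances must be positive")
    delta = 100.0 * (g - g_rm) / g
    delta[list(causal_indices)] = 0.0
    return delta


def recursive_analysis(components: VarianceComponents,
                       causal_traits: tuple[str, str] = ("SKAt", "ANONt")
                       ) -> RecursiveComponents:
    """Convenience wrapper resolving causal trait labels to indices."""
    idx = tuple(components.trait_labels.index(t) for t in causal_traits)
    lam = structural_lambda(components.R, idx)
    out = transform_components(components.G, components.R, lam)
    out.parameters.trait_labels = list(components.trait_labels)
    return out
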