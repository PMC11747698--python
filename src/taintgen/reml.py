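"""Multivariate animal-model REML: EM estimation, AI acceleration and SEs.

Model: y = Xb + Zu + e with u ~ N(0, A x G) and e ~ N(0, I x R), where A
is the pedigree relationship matrix, G and R the m x m genetic and
residual covariance matrices, the fixed part a station-by-month class
factor plus regressions on slaughter weight and age (one coefficient set
per trait).  Records may miss traits; each record contributes through
the observed-subset block of R.

The E step solves the mixed-model equations (MME) at the current (G, R)
and takes the exact conditional expectations of the complete-data
sufficient statistics, including the conditional mean/variance of
residuals for unobserved traits; the M step is

    G <- (U' A^-1 U + sum_ij A^-1_ij C_ij) / q
    R <- sum_j E[e_j e_j' | y] / n

which makes the restricted log-likelihood monotone nondecreasing.  Pure
EM is robust but slow near the optimum, so ``accelerate=True`` (the
default entry point for data of any size) switches after a few EM
warm-up rounds to average-information (AI) Newton updates built from the
same MME factorization; any AI proposal that loses positive
definiteness or decreases the restricted likelihood is backtracked and
ultimately replaced by a plain EM step, so accepted iterates never
decrease the likelihood.  Standard errors come from the AI matrix at
convergence; SEs of derived parameters use a delta method on its
inverse.

Pedigrees are pruned (exactly, see ``Pedigree.prune``) to the ancestors
that carry information before the MME are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.linalg import lapack

from .pedigree import Pedigree


class DesignError(ValueError):
    """Singular or inconsistent fixed-effect design."""


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Specifications and results
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Trait list plus fixed-effect layout of the analysis model."""

    traits: list[str]
    class_columns: tuple[str, ...] = ("station", "month")
    covariate_columns: tuple[str, ...] = ("weight_kg", "age_d")

    @property
    def n_traits(self) -> int:
        return len(self.traits)


@dataclass
class VarianceComponents:
    """Symmetric G and R with trait labels and optional fit metadata."""

    trait_labels: list[str]
    G: np.ndarray
    R: np.ndarray
    se_G: np.ndarray | None = None
    se_R: np.ndarray | None = None
    param_cov: np.ndarray | None = None
    param_index: list[tuple[str, int, int]] | None = None
    loglik: float | None = None
    loglik_trace: list[float] = field(default_factory=list)
    rounds: int = 0
    stop_reason: str = ""
    psd_projections: int = 0
    fixed_effects: pd.DataFrame | None = None

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.trait_labels)
        for name, mat in (("G", self.G), ("R", self.R)):
            if mat.shape != (m, m):
                raise ValueError(f"{name} must be {m}x{m}")
            if not np.allclose(mat, mat.T, atol=1e-8):
                raise ValueError(f"{name} is not symmetric")


@dataclass
class GeneticParameters:
    """Heritabilities and correlation matrices derived from (G, R)."""

    trait_labels: list[str]
    h2: np.ndarray
    r_G: np.ndarray
    r_R: np.ndarray
    r_P: np.ndarray
    se_h2: np.ndarray | None = None
    se_r_G: np.ndarray | None = None
    se_r_R: np.ndarray | None = None
    se_r_P: np.ndarray | None = None


@dataclass
class AIResult:
    """Average-information matrix and derived sampling (co)variances."""

    param_index: list[tuple[str, int, int]]
    ai: np.ndarray
    param_cov: np.ndarray
    se_G: np.ndarray
    se_R: np.ndarray
    used_pseudo_inverse: bool = False


# ---------------------------------------------------------------------------
# vech packing over (G, R)
# ---------------------------------------------------------------------------

def _param_index(m: int) -> list[tuple[str, int, int]]:
    idx = [("G", i, j) for i in range(m) for j in range(i, m)]
    idx += [("R", i, j) for i in range(m) for j in range(i, m)]
    return idx


def _pack(G: np.ndarray, R: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(G.shape[0])
    return np.concatenate([G[iu], R[iu]])


def _unpack(theta: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(m)
    k = iu[0].size
    G = np.zeros((m, m)); R = np.zeros((m, m))
    G[iu] = theta[:k]; G.T[iu] = theta[:k]
    R[iu] = theta[k:]; R.T[iu] = theta[k:]
    return G, R


def _project_psd(mat: np.ndarray, floor: float = 1e-10
                 ) -> tuple[np.ndarray, bool]:
    vals, vecs = np.linalg.eigh(mat)
    lo = floor * max(abs(vals).max(), 1.0)
    if vals.min() > lo:
        return mat, False
    vals = np.clip(vals, lo, None)
    return (vecs * vals) @ vecs.T, True


def _is_pd(mat: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(mat)
        return True
    except np.linalg.LinAlgError:
        return False


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_fixed_design(df: pd.DataFrame, model: ModelSpec
                       ) -> tuple[np.ndarray, list[str]]:
    """Per-record fixed design: intercept, class dummies, centered covariates.

    One aliased class level is dropped; covariates are centered so the
    intercept absorbs their means (affects b, not G or R).
    """
    names = ["intercept"]
    cols = [np.ones(len(df))]
    if model.class_columns:
        cls = df[list(model.class_columns)].astype(str).agg(":".join, axis=1)
        levels = sorted(cls.unique())
        names += [f"class[{l}]" for l in levels[1:]]
        for l in levels[1:]:
            cols.append((cls == l).to_numpy(float))
    for cov in model.covariate_columns:
        x = df[cov].to_numpy(float)
        if np.any(np.isnan(x)):
            raise DesignError(f"covariate {cov} has missing values")
        cols.append(x - x.mean())
        names.append(cov)
    F = np.column_stack(cols)
    if np.linalg.matrix_rank(F) < F.shape[1]:
        raise DesignError(
            "fixed-effect design is rank deficient (aliased class levels)")
    return F, names


# ---------------------------------------------------------------------------
# MME workspace
# ---------------------------------------------------------------------------

class _Pattern:
    __slots__ = ("obs", "mis", "idx", "F", "Y", "anim", "S")

    def __init__(self, obs, mis, idx, F, Y, anim):
        self.obs = obs          # observed trait indices
        self.mis = mis
        self.idx = idx          # record row indices
        self.F = F              # (n_pat, pf)
        self.Y = Y              # (n_pat, n_obs) observed values
        self.anim = anim        # pedigree positions (pruned)
        self.S = F.T @ F


class _Workspace:
    """Precomputed design pieces; assembles and solves the MME per round."""

    def __init__(self, phenotypes: pd.DataFrame, pedigree: Pedigree,
                 model: ModelSpec, prune: bool = True):
        self.model = model
        m = model.n_traits
        Y = phenotypes[model.traits].to_numpy(dtype=float)
        keep = ~np.all(np.isnan(Y), axis=1)
        df = phenotypes.loc[keep].reset_index(drop=True)
        Y = Y[keep]
        if len(df) == 0:
            raise DesignError("no records with any observed trait")
        ids = df["animal_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise DesignError("phenotype table must have one row per animal")
        self.ped = pedigree.prune(ids) if prune else pedigree
        apos = self.ped.positions(ids)
        F, self.fixed_names = build_fixed_design(df, model)

        self.m, self.pf = m, F.shape[1]
        self.p = m * self.pf
        self.q = len(self.ped)
        self.n = len(df)
        self.dim = self.p + self.q * m
        Ainv = self.ped.a_inverse().tocoo()
        self.Ainv = Ainv.tocsr()
        self.Ai, self.Aj, self.Av = Ainv.row, Ainv.col, Ainv.data
        self.logdetA = self.ped.log_det_a()

        masks = ~np.isnan(Y)
        self.patterns: list[_Pattern] = []
        uniq, inverse = np.unique(masks, axis=0, return_inverse=True)
        for k in range(uniq.shape[0]):
            idx = np.flatnonzero(inverse == k)
            obs = np.flatnonzero(uniq[k])
            mis = np.flatnonzero(~uniq[k])
            self.patterns.append(_Pattern(
                obs, mis, idx, F[idx], Y[np.ix_(idx, obs)], apos[idx]))
        self.F = F
        self.Y = Y
        self.obs_mask = masks
        self.anim_of_record = apos

    # -- per-trait OLS residual variances, used for default init ----------

    def default_init(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.m
        v = np.ones(m)
        for t in range(m):
            obs = ~np.isnan(self.Y[:, t])
            if obs.sum() > self.pf:
                coef, *_ = np.linalg.lstsq(
                    self.F[obs], self.Y[obs, t], rcond=None)
                resid = self.Y[obs, t] - self.F[obs] @ coef
                v[t] = max(resid.var(), 1e-8)
        return 0.5 * np.diag(v), 0.5 * np.diag(v)

    # -- assembly ----------------------------------------------------------

    def _assemble(self, G: np.ndarray, R: np.ndarray):
        m, pf, p = self.m, self.pf, self.p
        cG = sla.cho_factor(G, lower=True)
        Ginv = sla.cho_solve(cG, np.eye(m))
        logdetG = 2.0 * np.sum(np.log(np.diag(cG[0])))
        M = np.zeros((self.dim, self.dim))
        rhs = np.zeros(self.dim)
        logdetR = 0.0
        yRy = 0.0
        Rinv_pats = []
        for pat in self.patterns:
            o = pat.obs
            Roo = R[np.ix_(o, o)]
            cR = sla.cho_factor(Roo, lower=True)
            Rinv = sla.cho_solve(cR, np.eye(o.size))
            logdetR += pat.idx.size * 2.0 * np.sum(np.log(np.diag(cR[0])))
            cols_base = p + pat.anim * m
            for a, s in enumerate(o):
                sb = slice(s * pf, (s + 1) * pf)
                for b, t in enumerate(o):
                    val = Rinv[a, b]
                    tb = slice(t * pf, (t + 1) * pf)
                    M[sb, tb] += val * pat.S
                    colz = cols_base + t
                    M[sb, colz] += val * pat.F.T
                    M[colz[:, None],
                      np.arange(sb.start, sb.stop)[None, :]] += val * pat.F
                    M[cols_base + s, colz] += val
            yt = pat.Y @ Rinv
            yRy += float(np.sum(pat.Y * yt))
            for a, s in enumerate(o):
                rhs[s * pf:(s + 1) * pf] += pat.F.T @ yt[:, a]
                rhs[cols_base + s] += yt[:, a]
            Rinv_pats.append(Rinv)
        # + A^-1 x G^-1 on the u block
        tr = np.arange(m)
        bi = p + self.Ai[:, None] * m + tr[None, :]
        bj = p + self.Aj[:, None] * m + tr[None, :]
        np.add.at(M, (bi[:, :, None], bj[:, None, :]),
                  self.Av[:, None, None] * Ginv[None, :, :])
        consts = {"logdetR": logdetR, "logdetG": logdetG, "yRy": yRy,
                  "Rinv": Rinv_pats, "Ginv": Ginv}
        return M, rhs, consts

    def factor_solve(self, G: np.ndarray, R: np.ndarray):
        """Assemble and Cholesky-factor the MME; solve for (b, u).

        Returns ``(factor, sol, loglik, consts)`` where ``factor`` can be
        fed to ``scipy.linalg.cho_solve``.
        """
        M, rhs, consts = self._assemble(G, R)
        c, info = lapack.dpotrf(M, lower=1, overwrite_a=1, clean=0)
        if info != 0:
            raise DesignError(
                "MME coefficient matrix not positive definite "
                "(singular fixed-effect design or degenerate covariances)")
        logdetM = 2.0 * np.sum(np.log(np.diag(c)))
        sol = sla.cho_solve((c, True), rhs)
        ll = -0.5 * (consts["logdetR"] + self.m * self.logdetA
                     + self.q * consts["logdetG"] + logdetM
                     + consts["yRy"] - rhs @ sol)
        return (c, True), sol, float(ll), consts

    def loglik(self, G, R) -> float:
        return self.factor_solve(G, R)[2]

    # -- EM sufficient statistics and the REML score -----------------------

    def em_quantities(self, G, R, factor, sol, consts):
        """EM updates (G_new, R_new) and the REML score at (G, R).

        Consumes the factor (the full MME inverse is formed in place
        from a copy of it).
        """
        m, pf, p, q = self.m, self.pf, self.p, self.q
        Ginv = consts["Ginv"]
        c = factor[0]
        Cinv, info = lapack.dpotri(c.copy(), lower=1, overwrite_c=1)
        if info != 0:
            raise DesignError("MME inversion failed")
        C = np.tril(Cinv)
        C += np.tril(Cinv, -1).T
        U = sol[p:].reshape(q, m)
        B = sol[:p].reshape(m, pf)
        Cuu = C[p:, p:]
        Cbb4 = C[:p, :p].reshape(m, pf, m, pf)
        Cbu3 = C[:p, p:].reshape(m, pf, q * m)

        # genetic statistics
        quad = U.T @ (self.Ainv @ U)
        tr = np.arange(m)
        bi = self.Ai[:, None] * m + tr[None, :]
        bj = self.Aj[:, None] * m + tr[None, :]
        blocks = Cuu[bi[:, :, None], bj[:, None, :]]
        traceG = np.einsum("n,nst->st", self.Av, blocks)
        S_G = quad + traceG
        G_new = S_G / q

        # residual statistics; score for R accumulated per pattern
        Racc = np.zeros((m, m))
        D_R = np.zeros((m, m))
        for pat, Rinv in zip(self.patterns, consts["Rinv"]):
            o, mi = pat.obs, pat.mis
            pred = pat.F @ B[o].T + U[np.ix_(pat.anim, o)]
            E = pat.Y - pred
            S = np.einsum("ja,jb->jab", E, E)
            cols = pat.anim[:, None] * m + o[None, :]
            S += Cuu[cols[:, :, None], cols[:, None, :]]
            sub = Cbb4[np.ix_(o, np.arange(pf), o, np.arange(pf))]
            S += np.einsum("jp,apbq,jq->jab", pat.F, sub, pat.F,
                           optimize=True)
            arr = Cbu3[o][:, :, cols]          # (mo, pf, n_pat, mo)
            cross = np.einsum("jp,apjb->jab", pat.F, arr)
            S += cross + np.transpose(cross, (0, 2, 1))
            Soo = S.sum(axis=0)
            npat = pat.idx.size
            # score contribution: -1/2 (n R_oo^-1 - R_oo^-1 Soo R_oo^-1)
            Dloc = -0.5 * (npat * Rinv - Rinv @ Soo @ Rinv)
            D_R[np.ix_(o, o)] += Dloc
            Racc[np.ix_(o, o)] += Soo
            if mi.size:
                Bmo = R[np.ix_(mi, o)] @ Rinv
                Vcond = R[np.ix_(mi, mi)] - Bmo @ R[np.ix_(o, mi)]
                BS = Bmo @ Soo
                Racc[np.ix_(mi, o)] += BS
                Racc[np.ix_(o, mi)] += BS.T
                Racc[np.ix_(mi, mi)] += BS @ Bmo.T + npat * Vcond
        R_new = Racc / self.n
        G_new = 0.5 * (G_new + G_new.T)
        R_new = 0.5 * (R_new + R_new.T)

        D_G = -0.5 * (q * Ginv - Ginv @ S_G @ Ginv)
        score = np.concatenate([
            self._matrix_to_score(D_G, m), self._matrix_to_score(D_R, m)])
        return G_new, R_new, score

    @staticmethod
    def _matrix_to_score(D: np.ndarray, m: int) -> np.ndarray:
        iu = np.triu_indices(m)
        mult = np.where(iu[0] == iu[1], 1.0, 2.0)
        return D[iu] * mult

    # -- average information ------------------------------------------------

    def ai_matrix(self, G, R, factor, sol, consts) -> np.ndarray:
        """AI matrix via MME solves (factor must still be valid)."""
        m, pf, p, q = self.m, self.pf, self.p, self.q
        Ginv = consts["Ginv"]
        U = sol[p:].reshape(q, m)
        B = sol[:p].reshape(m, pf)
        PY = np.zeros((self.n, m))
        for pat, Rinv in zip(self.patterns, consts["Rinv"]):
            o = pat.obs
            pred = pat.F @ B[o].T + U[np.ix_(pat.anim, o)]
            PY[np.ix_(pat.idx, o)] = (pat.Y - pred) @ Rinv

        index = _param_index(m)
        npar = len(index)
        Fvecs = np.zeros((npar, self.n, m))
        for k, (kind, s, t) in enumerate(index):
            E = np.zeros((m, m))
            E[s, t] += 1.0
            if s != t:
                E[t, s] += 1.0
            if kind == "G":
                H = E @ Ginv
                Fvecs[k] = U[self.anim_of_record] @ H.T
            else:
                Fvecs[k] = PY @ E
            Fvecs[k][~self.obs_mask] = 0.0

        def project(vec: np.ndarray) -> np.ndarray:
            rv = np.zeros(self.dim)
            for pat, Rinv in zip(self.patterns, consts["Rinv"]):
                o = pat.obs
                vt = vec[np.ix_(pat.idx, o)] @ Rinv
                cols_base = p + pat.anim * m
                for a, s in enumerate(o):
                    rv[s * pf:(s + 1) * pf] += pat.F.T @ vt[:, a]
                    rv[cols_base + s] += vt[:, a]
            sv = sla.cho_solve(factor, rv)
            Bv = sv[:p].reshape(m, pf)
            Uv = sv[p:].reshape(q, m)
            out = np.zeros_like(vec)
            for pat, Rinv in zip(self.patterns, consts["Rinv"]):
                o = pat.obs
                resid = (vec[np.ix_(pat.idx, o)]
                         - pat.F @ Bv[o].T - Uv[np.ix_(pat.anim, o)])
                out[np.ix_(pat.idx, o)] = resid @ Rinv
            return out

        PF = np.array([project(Fvecs[k]) for k in range(npar)])
        AI = 0.5 * np.einsum("anm,bnm->ab", Fvecs, PF)
        return 0.5 * (AI + AI.T)


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------

def reml_loglik(components: VarianceComponents, phenotypes: pd.DataFrame,
                pedigree: Pedigree, model: ModelSpec) -> float:
    """Restricted log-likelihood at (G, R), up to a fixed additive constant.

    The constant (the -n/2 log 2pi term) is omitted but identical across
    calls with the same data and model, so differences are meaningful.
    """
    ws = _Workspace(phenotypes, pedigree, model)
    return ws.loglik(components.G, components.R)


def em_reml(phenotypes: pd.DataFrame, pedigree: Pedigree, model: ModelSpec,
            init: VarianceComponents | None = None, tol: float = 1e-8,
            max_rounds: int = 2000, accelerate: bool = False,
            warmup: int = 3, verbose: bool = False) -> VarianceComponents:
    """Estimate (G, R) by EM-REML, optionally AI-accelerated.

    ``tol`` is the largest relative change of any (co)variance parameter
    between successive accepted iterates; ``max_rounds`` counts MME
    factorizations.  With ``accelerate=True``, AI-Newton updates take
    over after ``warmup`` plain EM rounds; proposals are backtracked
    (step halving, EM fallback) whenever they leave the PD cone or lower
    the restricted likelihood, so the accepted likelihood trace stays
    nondecreasing either way.
    """
    ws = _Workspace(phenotypes, pedigree, model)
    m = ws.m
    if init is not None:
        G, R = init.G.copy(), init.R.copy()
        if not (_is_pd(G) and _is_pd(R)):
            raise ValueError("initial G and R must be positive definite")
    else:
        G, R = ws.default_init()

    scale = max(np.trace(G + R) / m, 1e-12)
    n_proj = 0
    trace: list[float] = []
    rounds = 0
    stop = "max_rounds"

    def rel_change(t_new, t_old):
        return float(np.max(np.abs(t_new - t_old)
                            / np.maximum(np.abs(t_old), 1e-3 * scale)))

    def clamp_psd(Gc, Rc):
        nonlocal n_proj
        Gc, pg = _project_psd(Gc)
        Rc, pr = _project_psd(Rc)
        n_proj += int(pg) + int(pr)
        return Gc, Rc

    theta = _pack(G, R)
    while rounds < max_rounds:
        G, R = _unpack(theta, m)
        factor, sol, ll, consts = ws.factor_solve(G, R)
        rounds += 1
        trace.append(ll)
        if verbose:
            print(f"round {rounds}: loglik {ll:.6f}")
        ai = None
        if accelerate and rounds > warmup:
            ai = ws.ai_matrix(G, R, factor, sol, consts)
        G_em, R_em, score = ws.em_quantities(G, R, factor, sol, consts)
        G_em, R_em = clamp_psd(G_em, R_em)
        theta_em = _pack(G_em, R_em)

        theta_new = None
        if ai is not None:
            try:
                step = np.linalg.solve(
                    ai + 1e-10 * np.eye(ai.shape[0]) * max(ai.max(), 1.0),
                    score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(ai, score, rcond=None)[0]
            frac = 1.0
            for _ in range(12):
                cand = theta + frac * step
                Gc, Rc = _unpack(cand, m)
                if _is_pd(Gc) and _is_pd(Rc):
                    ll_cand = ws.loglik(Gc, Rc)
                    rounds += 1
                    if ll_cand >= ll - 1e-10:
                        theta_new = cand
                        break
                frac *= 0.5
                if rounds >= max_rounds:
                    break
        if theta_new is None:
            theta_new = theta_em     # plain EM step (always ascends)

        if rel_change(theta_new, theta) < tol:
            theta = theta_new
            stop = "converged"
            break
        theta = theta_new

    G, R = _unpack(theta, m)
    # final likelihood and fixed-effect solutions at the returned estimates
    _, sol, ll_final, _ = ws.factor_solve(G, R)
    coef = sol[:ws.p].reshape(m, ws.pf)
    fixed = pd.DataFrame(coef.T, index=ws.fixed_names, columns=model.traits)
    return VarianceComponents(
        trait_labels=list(model.traits), G=G, R=R, loglik=ll_final,
        loglik_trace=trace, rounds=rounds, stop_reason=stop,
        psd_projections=n_proj, fixed_effects=fixed)


def ai_information(components: VarianceComponents, phenotypes: pd.DataFrame,
                   pedigree: Pedigree, model: ModelSpec) -> AIResult:
    """AI matrix and sampling (co)variances at (near-)converged (G, R).

    Uses the identities Z'Py = (A^-1 x G^-1) u_hat and Py = R^-1 e_hat
    so every working vector costs one MME solve against the factored
    coefficient matrix.
    """
    ws = _Workspace(phenotypes, pedigree, model)
    m = ws.m
    factor, sol, _, consts = ws.factor_solve(components.G, components.R)
    AI = ws.ai_matrix(components.G, components.R, factor, sol, consts)
    index = _param_index(m)
    used_pinv = False
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
        used_pinv = True
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se_G = np.zeros((m, m)); se_R = np.zeros((m, m))
    for k, (kind, s, t) in enumerate(index):
        target = se_G if kind == "G" else se_R
        target[s, t] = target[t, s] = se[k]
    return AIResult(index, AI, cov, se_G, se_R, used_pinv)


# ---------------------------------------------------------------------------
# Derived parameters
# ---------------------------------------------------------------------------

def _derived_vector(theta: np.ndarray, m: int) -> np.ndarray:
    G, R = _unpack(theta, m)
    P = G + R
    h2 = np.diag(G) / np.diag(P)
    out = [h2]
    iu = np.triu_indices(m, 1)
    for mat in (G, R, P):
        d = np.sqrt(np.diag(mat))
        corr = mat / np.outer(d, d)
        out.append(corr[iu])
    return np.concatenate(out)


def derived_parameters(components: VarianceComponents) -> GeneticParameters:
    """Heritabilities and genetic/residual/phenotypic correlations.

    h2_i = g_ii / (g_ii + r_ii); correlations are the usual matrix
    normalizations, with r_P computed model-based from G + R.  When the
    components carry an AI parameter covariance, SEs follow by a
    first-order delta method (numerical Jacobian).
    """
    G, R = components.G, components.R
    m = G.shape[0]
    if np.any(np.diag(G) < 0) or np.any(np.diag(R) < 0):
        raise ValueError("negative variance on a diagonal")
    with np.errstate(divide="ignore", invalid="ignore"):
        P = G + R
        h2 = np.diag(G) / np.diag(P)
        dG = np.sqrt(np.diag(G)); dR = np.sqrt(np.diag(R))
        dP = np.sqrt(np.diag(P))
        r_G = G / np.outer(dG, dG)
        r_R = R / np.outer(dR, dR)
        r_P = P / np.outer(dP, dP)
    for mat in (r_G, r_R, r_P):
        np.fill_diagonal(mat, 1.0)

    se_h2 = se_rg = se_rr = se_rp = None
    if components.param_cov is not None:
        theta = _pack(G, R)
        eps = 1e-6 * max(np.abs(theta).max(), 1.0)
        J = np.empty((_derived_vector(theta, m).size, theta.size))
        for k in range(theta.size):
            tp = theta.copy(); tp[k] += eps
            tm = theta.copy(); tm[k] -= eps
            J[:, k] = (_derived_vector(tp, m)
                       - _derived_vector(tm, m)) / (2 * eps)
        var = np.einsum("ik,kl,il->i", J, components.param_cov, J)
        se = np.sqrt(np.clip(var, 0.0, None))
        iu = np.triu_indices(m, 1)
        noff = iu[0].size
        se_h2 = se[:m]
        se_rg = np.zeros((m, m)); se_rr = np.zeros((m, m))
        se_rp = np.zeros((m, m))
        for mat, chunk in zip((se_rg, se_rr, se_rp),
                              (se[m:m + noff], se[m + noff:m + 2 * noff],
                               se[m + 2 * noff:])):
            mat[iu] = chunk
            mat.T[iu] = chunk
    return GeneticParameters(
        trait_labels=list(components.trait_labels), h2=h2,
        r_G=r_G, r_R=r_R, r_P=r_P,
        se_h2=se_h2, se_r_G=se_rg, se_r_R=se_rr, se_r_P=se_rp)
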