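"""Combining assessors for selection: covariance-function transforms.

Given the fitted multivariate (G, R), the genetic parameters of the mean
of a group of assessors are obtained a posteriori with a 3 x m
transformation T whose rows select SKAt, ANONt and the equally weighted
group average (weights 1/n for members, 0 otherwise):

    G_T = T G T',   R_T = T R T'.

Groups are ranked by combined heritability or by genetic correlation
with either compound, and predicted selection responses are compared via
the correlated-response ratio sqrt(h2) * r_G (selection intensity and
the target trait's phenotypic SD cancel in the ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

RANK_KEYS = ("h2", "rG_SKAt", "rG_ANONt")


@dataclass(frozen=True)
class GroupSpec:
    """Equally weighted group of assessors (1-based member ids)."""

    members: tuple[int, ...]
    n_assessors: int

    def __post_init__(self):
        if len(self.members) == 0:
            raise ValueError("empty assessor group")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate group members")
        if any(not 1 <= a <= self.n_assessors for a in self.members):
            raise ValueError("group member outside assessor range")
        object.__setattr__(self, "members", tuple(sorted(self.members)))

    def weights(self) -> np.ndarray:
        """Contribution c_i per assessor (1/n for members, else 0)."""
        w = np.zeros(self.n_assessors)
        w[[a - 1 for a in self.members]] = 1.0 / len(self.members)
        return w


@dataclass
class GroupResult:
    group: GroupSpec
    h2: float
    rG_SKAt: float
    rG_ANONt: float
    rP_SKAt: float
    rP_ANONt: float
    G_T: np.ndarray
    R_T: np.ndarray


def _transform_matrix(group: GroupSpec, m: int,
                      causal_indices=(0, 1)) -> np.ndarray:
    T = np.zeros((3, m))
    T[0, causal_indices[0]] = 1.0
    T[1, causal_indices[1]] = 1.0
    T[2, 2:] = group.weights()
    return T


def combination_transform(G: np.ndarray, R: np.ndarray, group: GroupSpec
                          ) -> GroupResult:
    """Genetic parameters of the group mean from the fitted (G, R).

    Trait order of G/R must be (SKAt, ANONt, assessor 1..k).  A singleton
    group reproduces that trait's own parameters exactly.
    """
    G = np.asarray(G, float); R = np.asarray(R, float)
    m = G.shape[0]
    if group.n_assessors != m - 2:
        raise ValueError("group was built for a different panel size")
    T = _transform_matrix(group, m)
    G_T = T @ G @ T.T
    R_T = T @ R @ T.T
    P_T = G_T + R_T
    h2 = G_T[2, 2] / P_T[2, 2]
    rg = lambda c: G_T[2, c] / np.sqrt(G_T[2, 2] * G_T[c, c])
    rp = lambda c: P_T[2, c] / np.sqrt(P_T[2, 2] * P_T[c, c])
    return GroupResult(group, float(h2), float(rg(0)), float(rg(1)),
                       float(rp(0)), float(rp(1)), G_T, R_T)


def enumerate_groups(G: np.ndarray, R: np.ndarray, size: int = 3,
                     rank_by: str = "h2") -> list[GroupResult]:
    """All C(k, size) groups, sorted descending by the chosen key.

    Ties are broken by lexicographic member order (stable sort).
    """
    if rank_by not in RANK_KEYS:
        raise ValueError(f"rank_by must be one of {RANK_KEYS}")
    k = np.asarray(G).shape[0] - 2
    if size < 1:
        raise ValueError("group size must be >= 1")
    if size > k:
        raise ValueError("group size exceeds number of assessors")
    results = [combination_transform(G, R, GroupSpec(members, k))
               for members in combinations(range(1, k + 1), size)]
    results.sort(key=lambda r: r.group.members)
    results.sort(key=lambda r: getattr(r, rank_by), reverse=True)
    return results


def relative_correlated_response(h2_a: float, rG_a: float,
                                 h2_b: float, rG_b: float) -> float:
    """Ratio of predicted correlated responses, (sqrt(h2_a) rG_a)/(sqrt(h2_b) rG_b).

    Assumes equal selection intensity and equal target-trait phenotypic
    SD in both schemes (both cancel).  Values > 1 favour scheme a.
    """
    for h2 in (h2_a, h2_b):
        if not 0.0 < h2 <= 1.0:
            raise ValueError("heritabilities must be in (0, 1]")
    for rg in (rG_a, rG_b):
        if not -1.0 <= rg <= 1.0:
            raise ValueError("correlations must be in [-1, 1]")
    denom = np.sqrt(h2_b) * rG_b
    if denom == 0.0:
        raise ZeroDivisionError("reference response is zero")
    return float(np.sqrt(h2_a) * rG_a / denom)
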