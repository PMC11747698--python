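"""Pedigree handling and the additive (numerator) relationship matrix.

A pedigree is a list of (animal, sire, dam) integer triplets with 0 coding
an unknown parent.  Records are topologically sorted at construction so
parents always precede offspring; cycles and duplicate ids are rejected.

The additive relationship matrix A is built by the tabular recursion;
its sparse inverse uses Henderson's rules with inbreeding accounted for
via the Mendelian-sampling variances d_i, which also give log|A| = sum
log d_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class PedigreeError(ValueError):
    """Invalid pedigree structure (cycles, duplicates, unknown references)."""


@dataclass(frozen=True)
class Pedigree:
    """Topologically sorted pedigree with integer ids (0 = unknown parent)."""

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    _pos: dict = field(default_factory=dict, repr=False, compare=False)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, animal, sire, dam) -> "Pedigree":
        animal = np.asarray(animal, dtype=np.int64)
        sire = np.asarray(sire, dtype=np.int64)
        dam = np.asarray(dam, dtype=np.int64)
        if animal.size != sire.size or animal.size != dam.size:
            raise PedigreeError("animal/sire/dam columns differ in length")
        if animal.size == 0:
            raise PedigreeError("empty pedigree")
        if np.any(animal <= 0):
            raise PedigreeError("animal ids must be positive integers")
        if len(np.unique(animal)) != animal.size:
            raise PedigreeError("duplicate animal ids")
        known = set(animal.tolist())
        for name, parents in (("sire", sire), ("dam", dam)):
            bad = set(parents[parents != 0].tolist()) - known
            if bad:
                raise PedigreeError(
                    f"{name} ids not listed as animals: {sorted(bad)[:5]}")
        order = cls._topological_order(animal, sire, dam)
        obj = cls(animal[order], sire[order], dam[order])
        object.__setattr__(obj, "_pos",
                           {a: i for i, a in enumerate(obj.animal.tolist())})
        return obj

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls.from_records(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])

    @staticmethod
    def _topological_order(animal, sire, dam) -> np.ndarray:
        n = animal.size
        pos = {a: i for i, a in enumerate(animal.tolist())}
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in (sire[i], dam[i]):
                if p != 0:
                    children[pos[p]].append(i)
                    indeg[i] += 1
        stack = sorted(np.flatnonzero(indeg == 0).tolist(), reverse=True)
        order = []
        while stack:
            i = stack.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if len(order) != n:
            raise PedigreeError("pedigree contains a cycle")
        return np.asarray(order, dtype=np.int64)

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return self.animal.size

    def positions(self, ids) -> np.ndarray:
        """Row positions of the given animal ids (raises on unknown id)."""
        try:
            return np.asarray([self._pos[int(a)] for a in np.asarray(ids)],
                              dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]} not in pedigree") from exc

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of sire/dam per animal, -1 for unknown."""
        si = np.array([self._pos[s] if s else -1 for s in self.sire.tolist()],
                      dtype=np.int64)
        di = np.array([self._pos[d] if d else -1 for d in self.dam.tolist()],
                      dtype=np.int64)
        return si, di

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animal, "sire": self.sire, "dam": self.dam})

    # -- relationship machinery -------------------------------------------

    def relationship_matrix(self) -> np.ndarray:
        """Dense numerator relationship matrix A (tabular method)."""
        n = len(self)
        si, di = self.parent_indices()
        A = np.zeros((n, n))
        for i in range(n):
            s, d = si[i], di[i]
            A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
            if i == 0:
                continue
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[:i, s]
            if d >= 0:
                row += 0.5 * A[:i, d]
            A[:i, i] = row
            A[i, :i] = row
        return A

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F_i = kinship(sire, dam).

        Uses a memoized kinship recursion instead of the dense tabular
        matrix, so it stays cheap for large shallow pedigrees.
        """
        si, di = self.parent_indices()
        memo: dict[tuple[int, int], float] = {}

        def kinship(i: int, j: int) -> float:
            if i < 0 or j < 0:
                return 0.0
            if i > j:
                i, j = j, i
            key = (i, j)
            if key in memo:
                return memo[key]
            if i == j:
                val = 0.5 * (1.0 + kinship(si[i], di[i]))
            else:
                # j is the younger animal (topological order)
                val = 0.5 * (kinship(i, si[j]) + kinship(i, di[j]))
            memo[key] = val
            return val

        return np.array([kinship(si[i], di[i]) for i in range(len(self))])

    def mendelian_variances(self) -> np.ndarray:
        """Within-family (Mendelian-sampling) variance scalars d_i."""
        F = self.inbreeding()
        si, di = self.parent_indices()
        d = np.ones(len(self))
        both = (si >= 0) & (di >= 0)
        d[both] = 0.5 - 0.25 * (F[si[both]] + F[di[both]])
        one_s = (si >= 0) & (di < 0)
        d[one_s] = 0.75 - 0.25 * F[si[one_s]]
        one_d = (si < 0) & (di >= 0)
        d[one_d] = 0.75 - 0.25 * F[di[one_d]]
        return d

    def a_inverse(self) -> sp.csr_matrix:
        """Sparse inverse of A (Henderson's rules with inbreeding)."""
        n = len(self)
        si, di = self.parent_indices()
        alpha = 1.0 / self.mendelian_variances()
        rows, cols, vals = [], [], []
        for i in range(n):
            a = alpha[i]
            rows.append(i); cols.append(i); vals.append(a)
            parents = [p for p in (si[i], di[i]) if p >= 0]
            for p in parents:
                rows += [i, p]; cols += [p, i]; vals += [-0.5 * a, -0.5 * a]
            for p in parents:
                for q in parents:
                    rows.append(p); cols.append(q); vals.append(0.25 * a)
        return sp.csr_matrix(
            sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))

    def log_det_a(self) -> float:
        """log determinant of A (= sum of log Mendelian variances)."""
        return float(np.sum(np.log(self.mendelian_variances())))

    # -- pruning -----------------------------------------------------------

    def prune(self, keep_ids) -> "Pedigree":
        """Drop animals irrelevant to the kept set without changing their A.

        Iteratively removes (a) animals outside ``keep_ids`` that have no
        offspring in the current pedigree, and (b) unknown-parent founders
        outside ``keep_ids`` with exactly one offspring (their only effect
        is on that offspring's Mendelian variance, not on relationships
        among remaining animals).  The submatrix of A over the kept
        animals is exactly preserved.
        """
        keep = {int(a) for a in np.asarray(keep_ids).ravel()}
        missing = keep - set(self.animal.tolist())
        if missing:
            raise PedigreeError(
                f"keep ids not in pedigree: {sorted(missing)[:5]}")
        animal = self.animal.copy()
        sire = self.sire.copy()
        dam = self.dam.copy()
        while True:
            present = set(animal.tolist())
            n_off = {}
            for p in np.concatenate([sire, dam]).tolist():
                if p:
                    n_off[p] = n_off.get(p, 0) + 1
            drop = set()
            for i, a in enumerate(animal.tolist()):
                if a in keep:
                    continue
                offspring = n_off.get(a, 0)
                founder = sire[i] == 0 and dam[i] == 0
                if offspring == 0 or (founder and offspring == 1):
                    drop.add(a)
            if not drop:
                break
            mask = np.array([a not in drop for a in animal.tolist()])
            animal, sire, dam = animal[mask], sire[mask], dam[mask]
            sire = np.where(np.isin(sire, list(drop)), 0, sire)
            dam = np.where(np.isin(dam, list(drop)), 0, dam)
            present = set(animal.tolist())
        return Pedigree.from_records(animal, sire, dam)
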