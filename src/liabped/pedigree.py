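"""Pedigree handling for the animal model.

A :class:`Pedigree` holds a validated, topologically ordered pedigree:
every parent's internal code precedes its offspring's, unknown parents are
treated as unrelated founders, and animals that appear only as parents are
pulled in as founder rows.  From an ordered pedigree the class derives the
quantities the animal model needs: per-animal inbreeding coefficients F,
the dense additive (numerator) relationship matrix A with diagonal 1 + F,
and its sparse inverse assembled by Henderson's rules with
inbreeding-adjusted Mendelian-sampling variances.
"""

from __future__ import annotations

import heapq
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

__all__ = ["Pedigree", "PedigreeError", "CycleError", "read_pedigree"]

#: parent entries read as "unknown" (case-insensitive), besides NaN/empty
MISSING_PARENT_TOKENS = {"", "0", "na", "nan", ".", "unknown", "-"}

SEX_CODES = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "2": "female",
}


class PedigreeError(ValueError):
    """Invalid pedigree input (duplicate ids, unknown focal animals...)."""


class CycleError(PedigreeError):
    """The parent graph contains a cycle (an animal is its own ancestor)."""


def _norm_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s.lower() in MISSING_PARENT_TOKENS:
        return None
    return s


def _norm_sex(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    return SEX_CODES.get(str(value).strip().lower(), "unknown")


@njit(cache=True)
def _tabular_A(sire_idx, dam_idx):
    n = sire_idx.shape[0]
    A = np.zeros((n, n))
    for j in range(n):
        sj, dj = sire_idx[j], dam_idx[j]
        if sj >= 0 and dj >= 0:
            A[j, j] = 1.0 + 0.5 * A[sj, dj]
        else:
            A[j, j] = 1.0
        for i in range(j):
            v = 0.0
            if sj >= 0:
                v += A[i, sj]
            if dj >= 0:
                v += A[i, dj]
            v *= 0.5
            A[i, j] = v
            A[j, i] = v
    return A


class Pedigree:
    """Validated, topologically ordered pedigree.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``id``, ``sire``, ``dam`` (``None`` for unknown parent) and
        optionally ``sex`` and ``birth_date``.  Order is arbitrary; the
        constructor recodes animals so parents precede offspring.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per animal in code order, with columns ``id``, ``sire``,
        ``dam``, ``sex``, ``birth_date`` and ``code`` (1-based, consecutive,
        parents before offspring).
    sire_idx, dam_idx : numpy.ndarray
        0-based positional parent indices, -1 where unknown.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        if "id" not in df.columns or "sire" not in df.columns or "dam" not in df.columns:
            raise PedigreeError("pedigree table needs columns id, sire, dam")
        df["id"] = df["id"].astype(str).str.strip()
        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicate animal id(s): {sorted(set(dup))[:5]}")
        df["sire"] = [_norm_parent(v) for v in df["sire"]]
        df["dam"] = [_norm_parent(v) for v in df["dam"]]
        if "sex" not in df.columns:
            df["sex"] = "unknown"
        else:
            df["sex"] = [_norm_sex(v) for v in df["sex"]]
        if "birth_date" not in df.columns:
            df["birth_date"] = pd.NaT
        df["birth_date"] = pd.to_datetime(df["birth_date"], errors="coerce")

        # closure: parents referenced but absent become founders
        ids = set(df["id"])
        extra_sires = [p for p in df["sire"] if p is not None and p not in ids]
        extra_dams = [p for p in df["dam"] if p is not None and p not in ids]
        extras = []
        seen: set[str] = set()
        for p, sex in [(p, "male") for p in extra_sires] + [(p, "female") for p in extra_dams]:
            if p not in seen:
                seen.add(p)
                extras.append({"id": p, "sire": None, "dam": None,
                               "sex": sex, "birth_date": pd.NaT})
        if extras:
            df = pd.concat([df, pd.DataFrame(extras)], ignore_index=True)

        self.table = self._topo_order(df)
        n = len(self.table)
        pos = {a: i for i, a in enumerate(self.table["id"])}
        self.sire_idx = np.array(
            [pos[s] if s is not None else -1 for s in self.table["sire"]], dtype=np.int64
        )
        self.dam_idx = np.array(
            [pos[d] if d is not None else -1 for d in self.table["dam"]], dtype=np.int64
        )
        self._pos = pos
        self._F: np.ndarray | None = None
        self._A: np.ndarray | None = None
        assert (self.sire_idx < np.arange(n)).all() and (self.dam_idx < np.arange(n)).all()

    @staticmethod
    def _topo_order(df: pd.DataFrame) -> pd.DataFrame:
        """Kahn's algorithm; ties broken by birth date, then input order."""
        df = df.reset_index(drop=True)
        ids = list(df["id"])
        pos = {a: i for i, a in enumerate(ids)}
        n = len(ids)
        parents = [
            [pos[p] for p in (df["sire"][i], df["dam"][i]) if p is not None]
            for i in range(n)
        ]
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=int)
        for i, ps in enumerate(parents):
            indeg[i] = len(ps)
            for p in ps:
                children[p].append(i)
        bdate = df["birth_date"]
        far_future = pd.Timestamp.max

        def key(i: int):
            b = bdate.iloc[i]
            return (b if pd.notna(b) else far_future, i)

        heap = [key(i) for i in range(n) if indeg[i] == 0]
        heapq.heapify(heap)
        order: list[int] = []
        while heap:
            _, i = heapq.heappop(heap)
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(heap, key(c))
        if len(order) < n:
            stuck = [ids[i] for i in range(n) if indeg[i] > 0]
            raise CycleError(
                f"pedigree cycle detected: animal {stuck[0]!r} is its own ancestor"
            )
        out = df.iloc[order].reset_index(drop=True)
        out["code"] = np.arange(1, n + 1)
        return out

    # ------------------------------------------------------------------
    @classmethod
    def from_csv(
        cls,
        path,
        sep: str = ",",
        id_col: str = "animal",
        sire_col: str = "sire",
        dam_col: str = "dam",
        sex_col: str = "sex",
        birth_col: str = "birthdate",
    ) -> "Pedigree":
        """Read a delimited pedigree file (one header row, one row per animal)."""
        raw = pd.read_csv(path, sep=sep, dtype=str)
        cols = {id_col: "id", sire_col: "sire", dam_col: "dam"}
        missing = [c for c in (id_col, sire_col, dam_col) if c not in raw.columns]
        if missing:
            raise PedigreeError(f"pedigree file lacks column(s) {missing}")
        if sex_col in raw.columns:
            cols[sex_col] = "sex"
        if birth_col in raw.columns:
            cols[birth_col] = "birth_date"
        return cls(raw.rename(columns=cols)[list(cols.values())])

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def position(self, animal_id: str) -> int:
        """0-based code-order position of an animal."""
        return self._pos[str(animal_id)]

    def positions(self, animal_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.position(a) for a in animal_ids], dtype=np.int64)

    def __contains__(self, animal_id) -> bool:
        return str(animal_id) in self._pos

    # ------------------------------------------------------------------
    def trace(self, focal_ids: Sequence[str]) -> "Pedigree":
        """Restrict to the focal animals plus all their ancestors (recoded).

        Mirrors tracing study animals back through registry pedigree files.
        """
        focal = [str(a) for a in focal_ids]
        unknown = sorted({a for a in focal if a not in self._pos})
        if unknown:
            raise PedigreeError(f"focal id(s) not in pedigree: {unknown[:10]}")
        keep = np.zeros(self.n, dtype=bool)
        stack = [self._pos[a] for a in set(focal)]
        while stack:
            i = stack.pop()
            if keep[i]:
                continue
            keep[i] = True
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0 and not keep[p]:
                    stack.append(p)
        sub = self.table.loc[keep, ["id", "sire", "dam", "sex", "birth_date"]]
        return Pedigree(sub)

    # ------------------------------------------------------------------
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficients F (founders 0).

        Computed by the tabular method, i.e. F = diag(A) - 1 from the same
        recursion that builds A.
        """
        if self._F is None:
            self._F = np.ascontiguousarray(np.diag(self.relationship_matrix()) - 1.0)
        return self._F

    def relationship_matrix(self) -> np.ndarray:
        """Dense additive relationship matrix A (tabular method).

        A[j, j] = 1 + 0.5 * A[sire(j), dam(j)];
        A[i, j] = 0.5 * (A[i, sire(j)] + A[i, dam(j)]) for i < j;
        unknown parents contribute 0.
        """
        if self._A is not None:
            return self._A
        self._A = _tabular_A(self.sire_idx, self.dam_idx)
        return self._A

    def a_inverse(self) -> sparse.csr_matrix:
        """Sparse inverse of A by Henderson's rules with inbreeding.

        Each animal contributes alpha = 1/d, where d is its Mendelian-sampling
        variance given parental inbreeding: d = 0.5 - 0.25 (F_s + F_d) with
        both parents known, 0.75 - 0.25 F_p with one, 1 with none.
        """
        F = self.inbreeding()
        n = self.n
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []

        def add(i: int, j: int, v: float) -> None:
            rows.append(i)
            cols.append(j)
            vals.append(v)

        for i in range(n):
            s, d = self.sire_idx[i], self.dam_idx[i]
            if s >= 0 and d >= 0:
                mend = 0.5 - 0.25 * (F[s] + F[d])
            elif s >= 0 or d >= 0:
                p = s if s >= 0 else d
                mend = 0.75 - 0.25 * F[p]
            else:
                mend = 1.0
            alpha = 1.0 / mend
            add(i, i, alpha)
            for p in (s, d):
                if p >= 0:
                    add(i, p, -0.5 * alpha)
                    add(p, i, -0.5 * alpha)
                    add(p, p, 0.25 * alpha)
            if s >= 0 and d >= 0:
                add(s, d, 0.25 * alpha)
                add(d, s, 0.25 * alpha)
        Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        Ainv.sum_duplicates()
        return Ainv

    # ------------------------------------------------------------------
    def parent_subset(self) -> set[str]:
        """Ids of animals that appear as sire or dam of at least one animal."""
        par = set(self.sire_idx[self.sire_idx >= 0]) | set(self.dam_idx[self.dam_idx >= 0])
        ids = self.ids
        return {ids[i] for i in par}

    def parent_positions(self) -> np.ndarray:
        """Code-order positions of the parent subset, sorted."""
        par = set(self.sire_idx[self.sire_idx >= 0]) | set(self.dam_idx[self.dam_idx >= 0])
        return np.array(sorted(par), dtype=np.int64)

    def parent_subpedigree(self) -> tuple["Pedigree", np.ndarray]:
        """Pedigree restricted to animals with offspring, plus their positions.

        The subset is closed under ancestry (a parent's parents are parents
        themselves), so this is a valid pedigree whose relationship matrix is
        exactly the corresponding submatrix of the full A.
        """
        pos = self.parent_positions()
        ids = self.ids[pos]
        sub = self.trace(ids)
        return sub, pos

    def mean_inbreeding(self) -> float:
        return float(self.inbreeding().mean())

    def summary(self) -> str:
        F = self.inbreeding()
        npar = len(self.parent_positions())
        lines = [
            "Pedigree summary",
            f"  animals:            {self.n}",
            f"  with offspring:     {npar}",
            f"  founders (no known parents): "
            f"{int(((self.sire_idx < 0) & (self.dam_idx < 0)).sum())}",
            f"  mean F:             {F.mean():.4f}",
            f"  max F:              {F.max():.4f}",
        ]
        return "\n".join(lines)


def read_pedigree(path, sep: str = ",", **kwargs) -> Pedigree:
    """Convenience wrapper: :meth:`Pedigree.from_csv`."""
    return Pedigree.from_csv(path, sep=sep, **kwargs)
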