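"""Pedigree handling and the numerator relationship matrix.

The sire additive-genetic effect of the threshold-linear model carries prior
covariance ``A ⊗ S`` where ``A`` is the numerator relationship matrix of the
pedigree.  This module builds ``A`` by the tabular (recursive) method, its
inverse directly by Henderson's rules (with inbreeding), and the per-individual
inbreeding coefficients needed for both.

Identifiers are arbitrary hashables; ``0``, ``"0"``, ``None``, ``NaN`` and the
empty string denote an unknown parent.  Individuals may appear in any order in
the input; a topological sort is performed internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "build_A",
    "build_A_inverse",
]

_UNKNOWN = {None, 0, "0", "", "NA", "."}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, unknown identifier)."""


def _is_unknown(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    return x in _UNKNOWN


@dataclass
class Pedigree:
    """An ordered pedigree: per individual the sire and dam (or unknown).

    Parameters
    ----------
    ids, sires, dams
        Parallel sequences.  Parents must themselves be listed as individuals;
        a parent id absent from `ids` raises :class:`PedigreeError`.
    """

    ids: list
    sires: list
    dams: list
    # filled by __post_init__: topological order and integer parent indices
    order: np.ndarray = field(init=False, repr=False)
    sire_idx: np.ndarray = field(init=False, repr=False)
    dam_idx: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if not (len(self.sires) == len(self.dams) == n):
            raise PedigreeError("ids, sires and dams must have equal length")
        pos = {}
        for i, ident in enumerate(self.ids):
            if ident in pos:
                raise PedigreeError(f"duplicate individual id {ident!r}")
            if _is_unknown(ident):
                raise PedigreeError("individual id may not be the unknown code")
            pos[ident] = i
        sire_idx = np.full(n, -1, dtype=np.int64)
        dam_idx = np.full(n, -1, dtype=np.int64)
        for i, (s, d) in enumerate(zip(self.sires, self.dams)):
            if not _is_unknown(s):
                if s not in pos:
                    raise PedigreeError(f"sire {s!r} not listed as an individual")
                sire_idx[i] = pos[s]
            if not _is_unknown(d):
                if d not in pos:
                    raise PedigreeError(f"dam {d!r} not listed as an individual")
                dam_idx[i] = pos[d]
        self.sire_idx = sire_idx
        self.dam_idx = dam_idx
        self.order = self._toposort()

    def _toposort(self) -> np.ndarray:
        """Kahn's algorithm parent→offspring; raises on cycles."""
        n = len(self.ids)
        indeg = np.zeros(n, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0:
                    children[p].append(i)
                    indeg[i] += 1
        queue = [i for i in range(n) if indeg[i] == 0]
        out: list[int] = []
        while queue:
            i = queue.pop()
            out.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(out) != n:
            bad = [self.ids[i] for i in range(n) if indeg[i] > 0][:5]
            raise PedigreeError(f"pedigree contains a cycle involving {bad}")
        return np.asarray(out, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, idents) -> np.ndarray:
        pos = {ident: i for i, ident in enumerate(self.ids)}
        return np.asarray([pos[x] for x in idents], dtype=np.int64)

    # ------------------------------------------------------------------
    def relationship_matrix(self) -> np.ndarray:
        """Numerator relationship matrix A by the tabular method.

        ``a_ii = 1 + a_{sd}/2`` and ``a_ij = (a_{j,s_i} + a_{j,d_i})/2`` with a
        missing parent contributing zero.  Unknown parents are unrelated
        founders.  O(n^2) memory and time.
        """
        n = len(self)
        A = np.zeros((n, n))
        # rank of each individual in topological order so offspring come later
        rank = np.empty(n, dtype=np.int64)
        rank[self.order] = np.arange(n)
        for i in self.order:
            s, d = self.sire_idx[i], self.dam_idx[i]
            earlier = self.order[: rank[i]]
            row_s = A[s, earlier] if s >= 0 else 0.0
            row_d = A[d, earlier] if d >= 0 else 0.0
            cross = 0.5 * (row_s + row_d)
            A[i, earlier] = cross
            A[earlier, i] = cross
            A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        return A

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F_i = a_ii - 1 (via the tabular method)."""
        return np.diag(self.relationship_matrix()) - 1.0

    def inverse_relationship_matrix(self) -> np.ndarray:
        """A^{-1} assembled directly by Henderson's rules.

        Uses the Mendelian-sampling variance
        ``d_i = 0.5 - 0.25 (F_s + F_d)`` (both parents known),
        ``0.75 - 0.25 F_p`` (one parent) or ``1`` (none), which reduces to the
        classical 1, 3/4, 1/2 rules for non-inbred parents.
        """
        n = len(self)
        F = self.inbreeding()
        Ainv = np.zeros((n, n))
        for i in range(n):
            s, d = self.sire_idx[i], self.dam_idx[i]
            di = 1.0
            if s >= 0:
                di -= 0.25 * (1.0 + F[s])
            if d >= 0:
                di -= 0.25 * (1.0 + F[d])
            alpha = 1.0 / di
            Ainv[i, i] += alpha
            for p in (s, d):
                if p >= 0:
                    Ainv[i, p] -= alpha / 2.0
                    Ainv[p, i] -= alpha / 2.0
            if s >= 0 and d >= 0:
                Ainv[s, s] += alpha / 4.0
                Ainv[d, d] += alpha / 4.0
                Ainv[s, d] += alpha / 4.0
                Ainv[d, s] += alpha / 4.0
            elif s >= 0:
                Ainv[s, s] += alpha / 4.0
            elif d >= 0:
                Ainv[d, d] += alpha / 4.0
        return Ainv


def build_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix over the whole pedigree."""
    return ped.relationship_matrix()


def build_A_inverse(ped: Pedigree) -> np.ndarray:
    """Inverse of A by Henderson's rules with computed inbreeding."""
    return ped.inverse_relationship_matrix()


def read_pedigree(path: str | Path, delimiter: str | None = None) -> Pedigree:
    """Read a 3-column (id, sire, dam) delimited text file.

    "0" or an empty field codes an unknown parent.  `delimiter=None` means
    any whitespace.
    """
    df = pd.read_csv(
        path,
        sep=delimiter if delimiter is not None else r"\s+",
        header=None,
        names=["id", "sire", "dam"],
        dtype=str,
        comment="#",
        engine="python",
    )
    df = df.fillna("0")
    return Pedigree(df["id"].tolist(), df["sire"].tolist(), df["dam"].tolist())
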