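"""Numerator relationship matrix machinery for pedigree-based animal models.

The additive genetic covariance among individuals is ``A * sigma2_a`` where
``A`` is the numerator relationship matrix: ``a_ij`` equals twice the
coancestry (kinship) coefficient and the diagonal is ``1 + F_i`` with ``F_i``
the inbreeding coefficient.  Two independent constructions are provided —
the tabular method (:func:`build_A`) and a memoised coancestry recursion
(:func:`kinship`) — plus the sparse direct inverse assembled with
Henderson's rules and inbreeding-adjusted Mendelian-sampling variances
(:func:`build_A_inverse`), which is what the Gibbs samplers consume.

Animal ids are arbitrary positive integers; 0 marks an unknown parent.
Founders are assumed unrelated and non-inbred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = 0


class PedigreeError(ValueError):
    """Structural problem in a pedigree (bad ids, duplicate animals...)."""


class PedigreeCycleError(PedigreeError):
    """An animal is its own ancestor; carries one offending chain."""

    def __init__(self, chain: list[int]):
        self.chain = chain
        super().__init__(
            "pedigree contains a cycle: " + " -> ".join(str(i) for i in chain)
        )


@dataclass
class Pedigree:
    """Ordered pedigree with parents guaranteed to precede offspring.

    Parameters
    ----------
    ids, sire, dam
        Equal-length integer arrays; ``sire``/``dam`` entries are animal ids
        or 0 for unknown.  Any input order is accepted; the constructor
        topologically sorts and raises :class:`PedigreeCycleError` on a loop.
    generation
        Optional small-integer cohort label, re-ordered alongside.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None
    # id -> 0-based position in topological order
    _pos: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not (len(self.ids) == len(self.sire) == len(self.dam)):
            raise PedigreeError("ids, sire and dam must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise PedigreeError("duplicate animal ids")
        if np.any(self.ids <= 0):
            raise PedigreeError("animal ids must be positive (0 is the unknown marker)")
        known = set(self.ids.tolist())
        for arr, lab in ((self.sire, "sire"), (self.dam, "dam")):
            missing = set(arr.tolist()) - known - {UNKNOWN}
            if missing:
                raise PedigreeError(f"{lab} ids not in pedigree: {sorted(missing)}")
        order = self._toposort()
        self.ids = self.ids[order]
        self.sire = self.sire[order]
        self.dam = self.dam[order]
        if self.generation is not None:
            self.generation = np.asarray(self.generation)[order]
        self._pos = {int(a): k for k, a in enumerate(self.ids)}

    def _toposort(self) -> np.ndarray:
        """Kahn topological sort (parents first); detect cycles."""
        n = len(self.ids)
        pos = {int(a): k for k, a in enumerate(self.ids)}
        indeg = np.zeros(n, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        for k in range(n):
            for p in (self.sire[k], self.dam[k]):
                if p != UNKNOWN:
                    children[pos[int(p)]].append(k)
                    indeg[k] += 1
        queue = [k for k in range(n) if indeg[k] == 0]
        out: list[int] = []
        while queue:
            # stable: keep original file order among ready animals
            queue.sort()
            k = queue.pop(0)
            out.append(k)
            for ch in children[k]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(out) < n:
            stuck = [k for k in range(n) if indeg[k] > 0]
            chain = [int(self.ids[stuck[0]])]
            seen = {chain[0]}
            cur = stuck[0]
            while True:
                par = int(self.sire[cur]) if self.sire[cur] != UNKNOWN else int(self.dam[cur])
                chain.append(par)
                if par in seen:
                    break
                seen.add(par)
                cur = pos[par]
            raise PedigreeCycleError(chain)
        return np.asarray(out, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ids)

    def position(self, animal_id: int) -> int:
        try:
            return self._pos[int(animal_id)]
        except KeyError:
            raise KeyError(f"unknown animal id {animal_id}") from None

    @property
    def parent_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based sire/dam positions, -1 for unknown."""
        sp_ = np.array(
            [self._pos[int(s)] if s != UNKNOWN else -1 for s in self.sire], dtype=np.int64
        )
        dp_ = np.array(
            [self._pos[int(d)] if d != UNKNOWN else -1 for d in self.dam], dtype=np.int64
        )
        return sp_, dp_

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        gen = frame["generation"].to_numpy() if "generation" in frame.columns else None
        return cls(
            frame["animal"].to_numpy(),
            frame["sire"].to_numpy(),
            frame["dam"].to_numpy(),
            generation=gen,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"animal": self.ids, "sire": self.sire, "dam": self.dam})
        if self.generation is not None:
            out["generation"] = self.generation
        return out


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix in pedigree order."""

    ids: np.ndarray
    A: np.ndarray
    F: np.ndarray


@dataclass
class RelationshipInverse:
    """Sparse A-inverse (CSR) in pedigree order, with inbreeding."""

    ids: np.ndarray
    A_inv: sp.csr_matrix
    F: np.ndarray


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F.

    F_i is the coancestry of the parents, computed with the memoised
    kinship recursion, so arbitrary-depth inbred pedigrees are handled.
    Animals with any unknown parent get F = 0.
    """
    spos, dpos = pedigree.parent_positions
    memo: dict[tuple[int, int], float] = {}
    f = np.empty(len(pedigree))
    for i in range(len(pedigree)):
        f[i] = _kin(spos[i], dpos[i], spos, dpos, memo) if spos[i] >= 0 and dpos[i] >= 0 else 0.0
    return f


def _kin(i: int, j: int, spos: np.ndarray, dpos: np.ndarray,
         memo: dict[tuple[int, int], float]) -> float:
    """Coancestry of positions i, j (-1 = unknown founder parent)."""
    if i < 0 or j < 0:
        return 0.0
    if i > j:
        i, j = j, i
    key = (i, j)
    hit = memo.get(key)
    if hit is not None:
        return hit
    if i == j:
        val = 0.5 * (1.0 + _kin(spos[i], dpos[i], spos, dpos, memo))
    else:
        # j is the later-born animal: recurse through its parents
        val = 0.5 * (_kin(i, spos[j], spos, dpos, memo) + _kin(i, dpos[j], spos, dpos, memo))
    memo[key] = val
    return val


def kinship(pedigree: Pedigree, i: int, j: int) -> float:
    """Coancestry coefficient of animals ``i`` and ``j`` (by id).

    ``a_ij = 2 * kinship(i, j)`` for i != j; ``kinship(i, i) = (1 + F_i)/2``.
    Serves as the independent oracle for the tabular construction.
    """
    pi, pj = pedigree.position(i), pedigree.position(j)
    spos, dpos = pedigree.parent_positions
    return _kin(pi, pj, spos, dpos, {})


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``a_ij = (a_{j,s(i)} + a_{j,d(i)})/2`` for j earlier than i, and
    ``a_ii = 1 + a_{s(i),d(i)}/2``.  Dense; intended for pedigrees up to a
    few thousand animals (the scale of the analyses here).
    """
    n = len(pedigree)
    spos, dpos = pedigree.parent_positions
    A = np.zeros((n, n))
    for i in range(n):
        s, d = spos[i], dpos[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(pedigree.ids.copy(), A, np.diag(A) - 1.0)


def build_A_inverse(pedigree: Pedigree) -> RelationshipInverse:
    """Sparse inverse of A via Henderson's rules.

    The Mendelian-sampling variance of animal i is
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` with both parents known,
    ``0.75 - 0.25 F_p`` with one, and 1 for founders.  Nonzeros appear only
    within {animal, sire, dam} triples, so the result is very sparse and is
    consumed directly by the Gibbs samplers.
    """
    n = len(pedigree)
    F = inbreeding(pedigree)
    spos, dpos = pedigree.parent_positions
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = spos[i], dpos[i]
        if s >= 0 and d >= 0:
            dvar = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            dvar = 0.75 - 0.25 * F[p]
        else:
            dvar = 1.0
        alpha = 1.0 / dvar
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s, d):
            if p >= 0:
                add(p, p, 0.25 * alpha)
        if s >= 0 and d >= 0:
            add(s, d, 0.25 * alpha)
            add(d, s, 0.25 * alpha)
    A_inv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A_inv.sum_duplicates()
    return RelationshipInverse(pedigree.ids.copy(), A_inv, F)
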