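"""Pedigree numerator relationship matrices.

Builds the additive (numerator) relationship matrix A by the tabular
method, its sparse inverse by Henderson's rules with inbreeding
(Meuwissen–Luo recursion for the diagonal), and principal submatrices
for genotyped animals, as used on the pedigree side of single-step
GBLUP.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = "0"


class PedigreeError(ValueError):
    """Raised for cyclic or otherwise malformed pedigrees."""


@dataclass
class Pedigree:
    """Animal/sire/dam triples in topological order (parents first).

    ``sire`` and ``dam`` hold integer positions into ``ids`` or -1 for an
    unknown parent. Construct via :meth:`from_frame` or :meth:`from_triples`,
    which validate acyclicity and reorder so every parent precedes its
    offspring.
    """

    ids: list[str]
    sire: np.ndarray  # int64, -1 = unknown
    dam: np.ndarray
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_triples(cls, triples) -> "Pedigree":
        """Build from an iterable of (animal, sire, dam); "0"/None/NaN = unknown."""
        rows = [(str(a), _norm(s), _norm(d)) for a, s, d in triples]
        known = {a for a, _, _ in rows}
        seen = set()
        for a, _, _ in rows:
            if a in seen:
                raise PedigreeError(f"duplicate animal id {a!r}")
            seen.add(a)
        # phantom parents (referenced but not listed) become founders
        phantoms = []
        for _, s, d in rows:
            for par in (s, d):
                if par != UNKNOWN and par not in known and par not in phantoms:
                    phantoms.append(par)
        rows = [(p, UNKNOWN, UNKNOWN) for p in phantoms] + rows
        order = _toposort(rows)
        ids = [rows[i][0] for i in order]
        index = {a: i for i, a in enumerate(ids)}
        sire = np.array(
            [index[rows[i][1]] if rows[i][1] != UNKNOWN else -1 for i in order],
            dtype=np.int64,
        )
        dam = np.array(
            [index[rows[i][2]] if rows[i][2] != UNKNOWN else -1 for i in order],
            dtype=np.int64,
        )
        return cls(ids=ids, sire=sire, dam=dam, _index=index)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        cols = list(frame.columns[:3])
        return cls.from_triples(frame[cols].itertuples(index=False, name=None))

    def position(self, animal_id: str) -> int:
        try:
            return self._index[str(animal_id)]
        except KeyError:
            raise KeyError(f"animal {animal_id!r} not in pedigree") from None

    def with_founders(self, extra_ids) -> "Pedigree":
        """Return a pedigree extended with unknown-parent founders.

        Genotyped animals absent from the pedigree file must still appear
        in A for single-step analyses; they are attached as founders with
        a warning.
        """
        missing = [str(a) for a in extra_ids if str(a) not in self._index]
        if not missing:
            return self
        warnings.warn(
            f"{len(missing)} genotyped animal(s) absent from the pedigree "
            "attached as unknown-parent founders",
            stacklevel=2,
        )
        triples = [(m, UNKNOWN, UNKNOWN) for m in missing] + [
            (
                self.ids[i],
                self.ids[self.sire[i]] if self.sire[i] >= 0 else UNKNOWN,
                self.ids[self.dam[i]] if self.dam[i] >= 0 else UNKNOWN,
            )
            for i in range(len(self))
        ]
        return Pedigree.from_triples(triples)

    # -- relationship matrices -------------------------------------------

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F by the Meuwissen–Luo recursion.

        Does not form A; cost is O(sum of ancestor-path sizes). The
        convention F = -1 for an unknown parent folds the founder and
        one-parent-known cases into the single Mendelian-sampling formula
        d_j = 0.5 - 0.25 (F_s + F_d).
        """
        n = len(self)
        F = np.zeros(n)
        sire, dam = self.sire, self.dam
        for i in range(n):
            s, d = sire[i], dam[i]
            if s < 0 and d < 0:
                continue
            # accumulate L coefficients of i's ancestors, youngest first
            f_acc = -1.0
            pending = [i]
            coeff = {i: 1.0}
            while pending:
                j = max(pending)
                pending.remove(j)
                lj = coeff.pop(j)
                fs = F[sire[j]] if sire[j] >= 0 else -1.0
                fd = F[dam[j]] if dam[j] >= 0 else -1.0
                dj = 0.5 - 0.25 * (fs + fd)
                f_acc += lj * lj * dj
                for par in (sire[j], dam[j]):
                    if par >= 0:
                        if par in coeff:
                            coeff[par] += 0.5 * lj
                        else:
                            coeff[par] = 0.5 * lj
                            pending.append(par)
            F[i] = f_acc
        return F

    def mendelian_sampling_variance(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variances d_i given parental F."""
        F = self.inbreeding()
        fs = np.where(self.sire >= 0, F[np.maximum(self.sire, 0)], -1.0)
        fd = np.where(self.dam >= 0, F[np.maximum(self.dam, 0)], -1.0)
        return 0.5 - 0.25 * (fs + fd)

    def relationship_matrix(self) -> np.ndarray:
        """Dense A by the tabular method (animals in pedigree order)."""
        n = len(self)
        A = np.zeros((n, n))
        sire, dam = self.sire, self.dam
        for i in range(n):
            s, d = sire[i], dam[i]
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
            A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        return A

    def relationship_inverse(self) -> sparse.csr_matrix:
        """Sparse A⁻¹ assembled from Henderson's per-animal contributions."""
        n = len(self)
        d = self.mendelian_sampling_variance()
        alpha = 1.0 / d
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []

        def add(r: int, c: int, v: float) -> None:
            rows.append(r)
            cols.append(c)
            vals.append(v)

        for i in range(n):
            a = alpha[i]
            add(i, i, a)
            parents = [p for p in (self.sire[i], self.dam[i]) if p >= 0]
            for p in parents:
                add(i, p, -0.5 * a)
                add(p, i, -0.5 * a)
            for p in parents:
                for q in parents:
                    add(p, q, 0.25 * a)
        return sparse.csr_matrix(
            sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
        )

    def relationship_logdet(self) -> float:
        """log|A| = Σ log d_i (A = L D L' with unit-triangular L)."""
        return float(np.sum(np.log(self.mendelian_sampling_variance())))

    def submatrix(self, animal_ids) -> np.ndarray:
        """Principal submatrix A22 of A for ``animal_ids``, in that order."""
        idx = np.array([self.position(a) for a in animal_ids])
        A = self.relationship_matrix()
        return A[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [self.ids[s] if s >= 0 else UNKNOWN for s in self.sire],
                "dam": [self.ids[d] if d >= 0 else UNKNOWN for d in self.dam],
            }
        )


def _norm(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return UNKNOWN
    s = str(x).strip()
    return UNKNOWN if s in {"", "0", "NA", "nan", ".", "*"} else s


def _toposort(rows: list[tuple[str, str, str]]) -> list[int]:
    """Topological order of row indices (parents before offspring).

    Raises :class:`PedigreeError` naming an animal on a cycle.
    """
    index = {a: i for i, (a, _, _) in enumerate(rows)}
    n = len(rows)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = [0] * n
    for i, (_, s, d) in enumerate(rows):
        for par in {s, d} - {UNKNOWN}:
            children[index[par]].append(i)
            indeg[i] += 1
    # parent counted once per distinct parent; self-parenting is a cycle too
    order = []
    ready = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(ready)  # keep input order among simultaneously-ready animals
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) < n:
        stuck = [rows[i][0] for i in range(n) if indeg[i] > 0]
        raise PedigreeError(
            f"pedigree contains a cycle involving animal(s): {', '.join(stuck[:5])}"
        )
    return order
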