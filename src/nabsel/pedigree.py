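"""Pedigree handling: validation, the numerator relationship matrix and inbreeding.

A pedigree is a directed acyclic parentage structure.  From it this module
derives the additive (numerator) relationship matrix ``A`` by the tabular
recursion, per-animal inbreeding coefficients ``F = diag(A) - 1`` via the
Meuwissen & Luo ancestor-tracing algorithm (no dense matrix needed), and the
sparse inverse of ``A`` by Henderson's rules with the inbreeding correction.
The sparse inverse is what the mixed-model machinery consumes; the dense
matrix is only materialised for small pedigrees (tests and oracles).

Identifiers are treated as opaque strings and mapped to dense indices in a
topological order in which parents precede offspring.  Unknown parents
(sentinel ``0`` or empty) are treated as unrelated, non-inbred founders.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "RelationshipSummary",
    "PedigreeError",
    "CycleError",
    "SexConflictError",
    "UndefinedParentError",
    "build_pedigree",
    "read_pedigree",
    "relationship_matrix",
    "a_inverse",
    "inbreeding_trend",
]

_UNKNOWN_TOKENS = {"0", "", "nan", "none", "na", ".", "-", "<na>"}


class PedigreeError(ValueError):
    """Invalid pedigree structure."""


class CycleError(PedigreeError):
    """An animal is its own ancestor."""


class SexConflictError(PedigreeError):
    """An animal is used as both sire and dam, or against its declared sex."""


class UndefinedParentError(PedigreeError):
    """A parent is referenced but never defined as an animal."""


def _norm_id(value) -> str:
    """Normalise an identifier; return '' for an unknown-parent sentinel."""
    if value is None:
        return ""
    if isinstance(value, float) and np.isnan(value):
        return ""
    s = str(value).strip()
    if s.lower() in _UNKNOWN_TOKENS:
        return ""
    # integers arriving as floats ("12.0") from CSV round-trips
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


def _norm_sex(value) -> str:
    s = str(value).strip().lower() if value is not None else ""
    if s in {"m", "male", "1"}:
        return "M"
    if s in {"f", "female", "2"}:
        return "F"
    return ""


@dataclass
class Pedigree:
    """Validated, topologically sorted pedigree.

    Attributes
    ----------
    ids : ndarray of str
        Animal identifiers in topological order (parents before offspring).
    sire, dam : ndarray of int
        Index of the parent in ``ids``; ``-1`` when unknown.
    sex : ndarray of str
        ``'M'``, ``'F'`` or ``''``.
    generation : ndarray of int
        Generation label, ``-1`` when unknown.
    line : ndarray of str
        Line label (``'base'``, ``'high'``, ``'low'``, ... or ``''``).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    line: np.ndarray
    _pos: dict = field(default_factory=dict, repr=False)
    _F: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self._pos:
            self._pos = {i: k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return self.ids.size

    def indices(self, ids) -> np.ndarray:
        """Map identifiers to dense pedigree positions."""
        try:
            return np.array([self._pos[_norm_id(i)] for i in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from None

    # -- inbreeding / Mendelian sampling -----------------------------------

    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficients (Meuwissen & Luo tracing)."""
        if self._F is None:
            self._F = _meuwissen_luo_f(self.sire, self.dam)
        return self._F

    def mendelian_variances(self) -> np.ndarray:
        """Variance of the Mendelian sampling term per animal (the D of A = TDT')."""
        F = self.inbreeding()
        s, d = self.sire, self.dam
        out = np.ones(self.n)
        both = (s >= 0) & (d >= 0)
        out[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
        one = (s >= 0) ^ (d >= 0)
        p = np.where(s >= 0, s, d)
        out[one] = 0.75 - 0.25 * F[p[one]]
        return out

    def log_det_a(self) -> float:
        """log determinant of A (product of Mendelian sampling variances)."""
        return float(np.sum(np.log(self.mendelian_variances())))

    def prune(self, keep_ids) -> "Pedigree":
        """Subset to the given animals plus all of their ancestors.

        Standard pedigree pruning before model fitting: relationships among
        the kept animals are unchanged because every connecting ancestor is
        retained.
        """
        keep = np.zeros(self.n, dtype=bool)
        stack = list(self.indices(keep_ids))
        while stack:
            k = stack.pop()
            if keep[k]:
                continue
            keep[k] = True
            for p in (self.sire[k], self.dam[k]):
                if p >= 0 and not keep[p]:
                    stack.append(p)
        idx = np.where(keep)[0]
        remap = -np.ones(self.n, dtype=np.int64)
        remap[idx] = np.arange(idx.size)
        def par(arr):
            out = arr[idx].copy()
            known = out >= 0
            out[known] = remap[out[known]]
            return out
        return Pedigree(
            ids=self.ids[idx],
            sire=par(self.sire),
            dam=par(self.dam),
            sex=self.sex[idx],
            generation=self.generation[idx],
            line=self.line[idx],
        )

    # -- export ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        def name(idx):
            return np.where(idx >= 0, self.ids[np.maximum(idx, 0)], "0")

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": name(self.sire),
                "dam": name(self.dam),
                "sex": self.sex,
                "generation": self.generation,
                "line": self.line,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RelationshipSummary:
    """Dense additive relationship matrix with inbreeding summaries."""

    ids: np.ndarray
    a_matrix: np.ndarray
    inbreeding: np.ndarray
    group_means: pd.DataFrame | None = None


def build_pedigree(records, undefined_parents: str = "founder") -> Pedigree:
    """Validate raw parentage rows and return a topologically sorted pedigree.

    Parameters
    ----------
    records : DataFrame or iterable of mappings
        Must carry ``animal``, ``sire``, ``dam``; optionally ``sex``,
        ``generation`` and ``line``.  Unknown parents are encoded by ``0`` or
        an empty field.
    undefined_parents : {'founder', 'error'}
        Whether a parent that never appears as an animal is auto-added as a
        founder or raises :class:`UndefinedParentError`.

    Raises
    ------
    CycleError
        If an animal is its own ancestor (including self-parenting).
    SexConflictError
        If an animal is used as both sire and dam, or used against its
        declared sex.
    """
    df = pd.DataFrame(records)
    if not {"animal", "sire", "dam"}.issubset(df.columns):
        raise PedigreeError("records must have 'animal', 'sire' and 'dam' columns")

    animal = df["animal"].map(_norm_id).to_numpy()
    sire = df["sire"].map(_norm_id).to_numpy()
    dam = df["dam"].map(_norm_id).to_numpy()
    if (animal == "").any():
        raise PedigreeError("empty animal identifier")
    if len(set(animal)) != len(animal):
        dup = pd.Series(animal).value_counts()
        raise PedigreeError(f"duplicate animal id(s): {list(dup[dup > 1].index)[:5]}")

    sex = (
        df["sex"].map(_norm_sex).to_numpy()
        if "sex" in df.columns
        else np.full(len(df), "", dtype=object)
    )
    gen = (
        pd.to_numeric(df["generation"], errors="coerce").fillna(-1).astype(int).to_numpy()
        if "generation" in df.columns
        else np.full(len(df), -1, dtype=int)
    )
    line = (
        df["line"].fillna("").astype(str).to_numpy()
        if "line" in df.columns
        else np.full(len(df), "", dtype=object)
    )

    defined = set(animal)
    extra = []
    for p in np.concatenate([sire, dam]):
        if p and p not in defined:
            if undefined_parents == "error":
                raise UndefinedParentError(f"parent {p!r} referenced but never defined")
            defined.add(p)
            extra.append(p)
    if extra:
        animal = np.concatenate([np.array(extra, dtype=object), animal])
        sire = np.concatenate([np.full(len(extra), "", dtype=object), sire])
        dam = np.concatenate([np.full(len(extra), "", dtype=object), dam])
        sex = np.concatenate([np.full(len(extra), "", dtype=object), sex])
        gen = np.concatenate([np.full(len(extra), -1, dtype=int), gen])
        line = np.concatenate([np.full(len(extra), "", dtype=object), line])

    # sex consistency: usage as parent vs declared sex and cross-usage
    sires_used = {s for s in sire if s}
    dams_used = {d for d in dam if d}
    both = sires_used & dams_used
    if both:
        raise SexConflictError(f"used as both sire and dam: {sorted(both)[:5]}")
    declared = dict(zip(animal, sex))
    for s in sires_used:
        if declared.get(s) == "F":
            raise SexConflictError(f"female animal {s!r} used as sire")
    for d in dams_used:
        if declared.get(d) == "M":
            raise SexConflictError(f"male animal {d!r} used as dam")

    # Kahn topological sort, stable in input order
    pos = {a: k for k, a in enumerate(animal)}
    n = len(animal)
    if any(animal[k] in (sire[k], dam[k]) and animal[k] for k in range(n)):
        bad = [animal[k] for k in range(n) if animal[k] in (sire[k], dam[k])]
        raise CycleError(f"animal is its own parent: {bad[:5]}")
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for k in range(n):
        for p in (sire[k], dam[k]):
            if p:
                children[pos[p]].append(k)
                indeg[k] += 1
    heap = [k for k in range(n) if indeg[k] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        k = heapq.heappop(heap)
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(order) != n:
        left = [animal[k] for k in range(n) if indeg[k] > 0]
        raise CycleError(f"pedigree contains a cycle involving: {left[:5]}")

    order = np.asarray(order)
    ids = animal[order]
    newpos = {a: k for k, a in enumerate(ids)}
    sire_ix = np.array([newpos[s] if s else -1 for s in sire[order]], dtype=np.int64)
    dam_ix = np.array([newpos[d] if d else -1 for d in dam[order]], dtype=np.int64)
    sex_o = sex[order].astype(object)
    # fill sex from parental usage where undeclared
    for k, a in enumerate(ids):
        if not sex_o[k]:
            if a in sires_used:
                sex_o[k] = "M"
            elif a in dams_used:
                sex_o[k] = "F"
    return Pedigree(
        ids=ids,
        sire=sire_ix,
        dam=dam_ix,
        sex=np.asarray(sex_o, dtype=object),
        generation=gen[order],
        line=np.asarray(line[order], dtype=object),
    )


def read_pedigree(path, **kwargs) -> Pedigree:
    """Read a pedigree CSV (``animal,sire,dam,sex,generation,line``)."""
    return build_pedigree(pd.read_csv(path, dtype=str), **kwargs)


def _meuwissen_luo_f(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients by tracing ancestor path coefficients.

    For each animal the diagonal of A is accumulated as sum_j t_j^2 d_j over
    its ancestors j, where t_j are the path coefficients of T (A = TDT') and
    d_j the Mendelian sampling variances.  Ancestors are visited in
    decreasing topological index so every coefficient is complete when used.
    """
    n = sire.size
    F = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            continue  # F = 0 with any unknown parent (unrelated founders)
        coefs = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            c = coefs.pop(j, None)
            if c is None:
                continue
            sj, dj = sire[j], dam[j]
            if sj >= 0 and dj >= 0:
                dv = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0 or dj >= 0:
                dv = 0.75 - 0.25 * F[max(sj, dj)]
            else:
                dv = 1.0
            aii += c * c * dv
            half = 0.5 * c
            for p in (sj, dj):
                if p >= 0:
                    if p in coefs:
                        coefs[p] += half
                    else:
                        coefs[p] = half
                        heapq.heappush(heap, -p)
        F[i] = aii - 1.0
    return F


def relationship_matrix(ped: Pedigree, max_n: int = 2000, force: bool = False) -> RelationshipSummary:
    """Dense numerator relationship matrix by the tabular recursion.

    ``a_ij = 0.5 (a_{i,sire(j)} + a_{i,dam(j)})`` with diagonal
    ``1 + 0.5 a_{sire,dam}``.  Dense storage is guarded to ``max_n`` animals;
    large pedigrees should use :func:`a_inverse` and
    :meth:`Pedigree.inbreeding` instead.
    """
    n = ped.n
    if n > max_n and not force:
        raise PedigreeError(
            f"dense A for {n} animals exceeds the {max_n}-animal guard; "
            "use a_inverse()/inbreeding() or pass force=True"
        )
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            if i:
                A[i, :i] = 0.5 * (A[si, :i] + A[di, :i])
            A[i, i] = 1.0 + 0.5 * A[si, di]
        elif si >= 0 or di >= 0:
            p = max(si, di)
            if i:
                A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    F = np.diag(A) - 1.0
    gm = None
    if (ped.generation >= 0).any():
        gm = _group_mean_f(ped, F)
    return RelationshipSummary(ids=ped.ids, a_matrix=A, inbreeding=F, group_means=gm)


def a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding correction.

    The Mendelian sampling precision of each animal contributes to its own
    diagonal, to animal-parent entries and to parent-parent entries.  Parental
    inbreeding enters through the sampling variances, so ``A @ a_inverse(ped)``
    is the identity on any valid pedigree.
    """
    n = ped.n
    alpha = 1.0 / ped.mendelian_variances()
    s, d = ped.sire, ped.dam
    i = np.arange(n)

    rows = [i]
    cols = [i]
    vals = [alpha]
    for p in (s, d):
        m = p >= 0
        rows += [i[m], p[m], p[m]]
        cols += [p[m], i[m], p[m]]
        vals += [-0.5 * alpha[m], -0.5 * alpha[m], 0.25 * alpha[m]]
    m2 = (s >= 0) & (d >= 0)
    rows += [s[m2], d[m2]]
    cols += [d[m2], s[m2]]
    vals += [0.25 * alpha[m2], 0.25 * alpha[m2]]

    Ainv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def _group_mean_f(ped: Pedigree, F: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(
        {"line": ped.line, "generation": ped.generation, "F": F}
    )
    df = df[df["generation"] >= 0]
    out = (
        df.groupby(["line", "generation"], sort=True)["F"]
        .agg(mean_F="mean", n="size")
        .reset_index()
    )
    return out


def inbreeding_trend(ped: Pedigree) -> pd.DataFrame:
    """Mean inbreeding per line x generation with per-generation increments.

    The increment uses the rate-of-inbreeding convention
    ``dF_t = (F_t - F_{t-1}) / (1 - F_{t-1})`` within each line, which makes
    rates comparable across generations.
    """
    F = ped.inbreeding()
    out = _group_mean_f(ped, F)
    if out.empty:
        warnings.warn("no generation labels; empty inbreeding trend")
        return out.assign(delta_F=np.nan)
    parts = []
    for _, g in out.groupby("line", sort=True):
        g = g.sort_values("generation").copy()
        prev = g["mean_F"].shift(1)
        g["delta_F"] = (g["mean_F"] - prev) / (1.0 - prev)
        parts.append(g)
    return pd.concat(parts, ignore_index=True)
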