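"""Pedigrees and additive-relationship structures.

The numerator relationship matrix ``A`` holds the expected additive genetic
relationships a_ij (twice the kinship coefficient) implied by a pedigree; the
diagonal matrix ``D`` holds the Mendelian-sampling relationship coefficients
d_ii, the part of an animal's additive variance not explained by the average
of its parents.  Both are the sufficient statistics for every analytic moment
computed elsewhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PedigreeError",
    "Pedigree",
    "RelationshipSet",
    "HalfSibDesign",
    "build_A",
    "build_D",
    "halfsib_design",
]

MISSING = {"0", "", ".", "NA", None}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (unknown parent, cycle, duplicate id)."""


@dataclass
class Pedigree:
    """Ordered pedigree of (animal, sire, dam) triples.

    Ids are opaque strings; a parent of ``None`` marks an unknown (founder)
    parent.  On construction the records are validated and re-ordered
    topologically so that parents always precede offspring.
    """

    records: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        cleaned = []
        for animal, sire, dam in self.records:
            animal = str(animal)
            sire = None if sire in MISSING or str(sire) in MISSING else str(sire)
            dam = None if dam in MISSING or str(dam) in MISSING else str(dam)
            cleaned.append((animal, sire, dam))
        ids = [a for a, _, _ in cleaned]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate animal ids: {dup}")
        known = set(ids)
        for animal, sire, dam in cleaned:
            for parent in (sire, dam):
                if parent is not None and parent not in known:
                    raise PedigreeError(
                        f"parent {parent!r} of {animal!r} does not appear as an animal"
                    )
        self.records = _toposort(cleaned)

    @property
    def ids(self) -> list[str]:
        return [a for a, _, _ in self.records]

    @property
    def n(self) -> int:
        return len(self.records)

    def parents(self, animal: str) -> tuple[str | None, str | None]:
        for a, s, d in self.records:
            if a == animal:
                return s, d
        raise KeyError(animal)

    def founders(self) -> list[str]:
        return [a for a, s, d in self.records if s is None and d is None]


def _toposort(records):
    """Order records so parents precede offspring; reject cycles."""
    index = {a: (s, d) for a, s, d in records}
    order: list[str] = []
    state: dict[str, int] = {}  # 0 in progress, 1 done

    for root in index:
        if root in state:
            continue
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                state[node] = 1
                order.append(node)
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise PedigreeError(f"pedigree cycle involving {node!r}")
            state[node] = 0
            stack.append((node, True))
            for parent in index[node]:
                if parent is not None and state.get(parent) != 1:
                    if state.get(parent) == 0:
                        raise PedigreeError(f"pedigree cycle involving {parent!r}")
                    stack.append((parent, False))
    return [(a, *index[a]) for a in order]


@dataclass
class RelationshipSet:
    """Additive relationship matrix A and Mendelian-sampling diagonal D."""

    A: np.ndarray
    D: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if not np.allclose(self.A, self.A.T, atol=1e-8):
            i, j = np.unravel_index(np.argmax(np.abs(self.A - self.A.T)), self.A.shape)
            raise ValueError(f"A is not symmetric (largest asymmetry at ({i},{j}))")
        if self.D.shape != (n, n):
            raise ValueError("D must match A's shape")
        if not np.allclose(self.D, np.diag(np.diag(self.D))):
            raise ValueError("D must be diagonal")
        if not self.ids:
            self.ids = [str(i) for i in range(n)]

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def index(self, animal_ids) -> np.ndarray:
        lookup = {a: k for k, a in enumerate(self.ids)}
        return np.array([lookup[a] for a in animal_ids], dtype=int)

    def subset(self, animal_ids) -> "RelationshipSet":
        """Restrict A and D to the given animals (e.g. the phenotyped offspring)."""
        idx = self.index(animal_ids)
        return RelationshipSet(
            self.A[np.ix_(idx, idx)], self.D[np.ix_(idx, idx)], list(animal_ids)
        )


def build_A(ped: Pedigree) -> RelationshipSet:
    """Numerator relationship matrix by the tabular (recursive) method.

    a_ij = (a_{j,s_i} + a_{j,d_i}) / 2 for j preceding i, and
    a_ii = 1 + a_{s_i,d_i} / 2; unknown parents contribute 0.
    Returns a RelationshipSet whose D part is filled by :func:`build_D`.
    """
    ids = ped.ids
    pos = {a: k for k, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, (animal, sire, dam) in enumerate(ped.records):
        s = pos[sire] if sire is not None else None
        d = pos[dam] if dam is not None else None
        a_sd = A[s, d] if (s is not None and d is not None) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        row = np.zeros(i)
        if s is not None:
            row += 0.5 * A[s, :i]
        if d is not None:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    D = build_D(ped, A)
    return RelationshipSet(A, D, ids)


def build_D(ped: Pedigree, A: np.ndarray) -> np.ndarray:
    """Mendelian-sampling relationship diagonal.

    For an animal with both parents recorded,
    d_ii = a_ii - a_{ss}/4 - a_{dd}/4 - a_{sd}/2.  With a single recorded
    parent the unrecorded one acts as an unrelated non-inbred founder
    (d_ii = a_ii - a_{ss}/4 - 1/4); for founders the whole genotype is
    Mendelian sampling, d_ii = a_ii.
    """
    ids = ped.ids
    pos = {a: k for k, a in enumerate(ids)}
    n = len(ids)
    A = np.asarray(A, dtype=float)
    if A.shape != (n, n):
        raise ValueError("A does not match the pedigree")
    d = np.empty(n)
    for i, (animal, sire, dam) in enumerate(ped.records):
        s = pos[sire] if sire is not None else None
        dd = pos[dam] if dam is not None else None
        val = A[i, i]
        for parent in (s, dd):
            val -= 0.25 * (A[parent, parent] if parent is not None else 1.0)
        if s is not None and dd is not None:
            val -= 0.5 * A[s, dd]
        if s is None and dd is None:
            val = A[i, i]  # founder: no parental average to subtract
        d[i] = val
    return np.diag(d)


@dataclass
class HalfSibDesign:
    """Paternal half-sib design: ``n_families`` unrelated sires, each with
    ``family_size`` offspring out of distinct unrelated dams.

    Only the offspring are phenotyped and genotyped for the association
    tests; sires and dams are genotyped founders (needed by the QTDT).
    On the offspring, A is block diagonal (1 on the diagonal, 1/4 between
    half-sibs, 0 across families) and D = I/2.
    """

    n_families: int
    family_size: int

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.family_size < 1:
            raise ValueError("n_families and family_size must be >= 1")

    @property
    def n(self) -> int:
        return self.n_families * self.family_size

    def pedigree(self) -> Pedigree:
        records: list[tuple[str, str | None, str | None]] = []
        for f in range(self.n_families):
            records.append((f"S{f}", None, None))
        for f in range(self.n_families):
            for k in range(self.family_size):
                records.append((f"D{f}_{k}", None, None))
                records.append((f"O{f}_{k}", f"S{f}", f"D{f}_{k}"))
        return Pedigree(records)

    def offspring_ids(self) -> list[str]:
        return [
            f"O{f}_{k}"
            for f in range(self.n_families)
            for k in range(self.family_size)
        ]

    def relationships(self) -> RelationshipSet:
        """Offspring-level A (block structure) and D = I/2, built directly."""
        f, m = self.n_families, self.family_size
        block = np.full((m, m), 0.25)
        np.fill_diagonal(block, 1.0)
        A = np.kron(np.eye(f), block)
        D = 0.5 * np.eye(f * m)
        return RelationshipSet(A, D, self.offspring_ids())


def halfsib_design(n_families: int, family_size: int) -> tuple[Pedigree, RelationshipSet]:
    """Explicit pedigree and offspring-level relationships of a half-sib design."""
    design = HalfSibDesign(n_families, family_size)
    return design.pedigree(), design.relationships()
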