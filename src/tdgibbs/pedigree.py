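"""Pedigree reading, ordering, and numerator-relationship-matrix algebra.

The additive genetic effects of an animal model are correlated across
relatives through the numerator relationship matrix ``A``.  The mixed-model
machinery never needs ``A`` itself, only its sparse inverse, which
Henderson's rules assemble directly from the pedigree in one pass once the
inbreeding coefficients are known.  The dense tabular ``A`` is kept for
small pedigrees as the reference implementation the sparse path is tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

UNKNOWN = -1


@dataclass(frozen=True)
class PedigreeEntry:
    """One animal-sire-dam triple; ``None`` marks an unknown parent."""

    animal: str
    sire: str | None = None
    dam: str | None = None


@dataclass
class RelationshipStructure:
    """Ordered pedigree with inbreeding and the sparse inverse of A.

    All arrays are aligned to ``ids``, a topological ordering in which every
    parent precedes its offspring.  ``F`` is the inbreeding coefficient
    (``diag(A) - 1``) and ``a_inv`` the symmetric sparse inverse numerator
    relationship matrix.
    """

    ids: list[str]
    sire: np.ndarray  # index into ids, UNKNOWN if missing
    dam: np.ndarray
    F: np.ndarray
    a_inv: sparse.csr_matrix
    accounted_inbreeding: bool = True
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def write_id_map(self, path) -> None:
        """Persist the identifier -> consecutive-code map (2 columns)."""
        with open(path, "w") as fh:
            fh.write("id\tcode\n")
            for i, a in enumerate(self.ids):
                fh.write(f"{a}\t{i}\n")

    def write_a_inverse(self, path) -> None:
        """Persist A-inverse as coordinate triplets (row, col, value)."""
        coo = self.a_inv.tocoo()
        with open(path, "w") as fh:
            fh.write("row\tcol\tvalue\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r}\t{c}\t{v!r}\n")


def read_pedigree(path, unknown: str = "0") -> list[PedigreeEntry]:
    """Read a 3-column (animal sire dam) text pedigree.

    Whitespace- or comma-delimited.  ``unknown`` is the sentinel for a
    missing parent.  Exact duplicate lines collapse; a duplicate animal with
    conflicting parents is an error, as is an animal listed as its own
    parent.  Parents that never appear in the animal column are appended as
    founder entries.
    """
    seen: dict[str, tuple[str | None, str | None]] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 3:
                raise ValueError(f"line {ln}: expected 3 columns, got {len(parts)}")
            animal, sire, dam = parts
            s = None if sire == unknown else sire
            d = None if dam == unknown else dam
            if animal == sire or animal == dam:
                raise ValueError(f"line {ln}: animal {animal!r} is its own parent")
            if animal in seen:
                if seen[animal] != (s, d):
                    raise ValueError(
                        f"line {ln}: duplicate animal {animal!r} with conflicting parents"
                    )
                continue
            seen[animal] = (s, d)
            order.append(animal)
    # parents never listed as animals become founders, appended in first-use order
    for animal in list(order):
        for p in seen[animal]:
            if p is not None and p not in seen:
                seen[p] = (None, None)
                order.append(p)
    return [PedigreeEntry(a, *seen[a]) for a in order]


def topological_order(ped: list[PedigreeEntry]) -> list[int]:
    """Indices of ``ped`` reordered so every parent precedes its offspring.

    Kahn's algorithm over the parent->offspring graph; deterministic
    (input-order tie-break).  A cycle raises ``ValueError`` naming one
    animal on it.
    """
    idx = {e.animal: i for i, e in enumerate(ped)}
    n = len(ped)
    n_pending = np.zeros(n, dtype=np.int64)  # unplaced parents per animal
    children: list[list[int]] = [[] for _ in range(n)]
    for i, e in enumerate(ped):
        for p in (e.sire, e.dam):
            if p is not None:
                if p not in idx:
                    raise ValueError(f"parent {p!r} of {e.animal!r} not in pedigree")
                n_pending[i] += 1
                children[idx[p]].append(i)
    ready = [i for i in range(n) if n_pending[i] == 0]
    out: list[int] = []
    head = 0
    while head < len(ready):
        i = ready[head]
        head += 1
        out.append(i)
        for c in children[i]:
            n_pending[c] -= 1
            if n_pending[c] == 0:
                ready.append(c)
    if len(out) != n:
        stuck = next(i for i in range(n) if n_pending[i] > 0)
        raise ValueError(f"pedigree cycle detected involving animal {ped[stuck].animal!r}")
    return out


def _recode(ped: list[PedigreeEntry]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Topologically ordered ids and integer sire/dam arrays (UNKNOWN = -1)."""
    order = topological_order(ped)
    ids = [ped[i].animal for i in order]
    pos = {a: i for i, a in enumerate(ids)}
    sire = np.full(len(ped), UNKNOWN, dtype=np.int64)
    dam = np.full(len(ped), UNKNOWN, dtype=np.int64)
    for new_i, old_i in enumerate(order):
        e = ped[old_i]
        if e.sire is not None:
            sire[new_i] = pos[e.sire]
        if e.dam is not None:
            dam[new_i] = pos[e.dam]
    return ids, sire, dam


def relationship_matrix(ped: list[PedigreeEntry]) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    Rows/columns follow the order of ``ped``.  Quadratic in pedigree size;
    meant for small pedigrees and as the oracle for :func:`a_inverse`.
    """
    ids, sire, dam = _recode(ped)
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        if i:
            row = np.zeros(i)
            if s != UNKNOWN:
                row += 0.5 * A[:i, s]
            if d != UNKNOWN:
                row += 0.5 * A[:i, d]
            A[i, :i] = A[:i, i] = row
    # permute back to input entry order
    input_pos = {e.animal: i for i, e in enumerate(ped)}
    perm = np.array([input_pos[a] for a in ids])
    out = np.empty_like(A)
    out[np.ix_(perm, perm)] = A
    return out


def _kinship_inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients by memoised recursive kinship.

    F(i) = phi(sire_i, dam_i) with the classical kinship recursion
    phi(i, j) = 0.5 (phi(j, s_i) + phi(j, d_i)) for j < i and
    phi(i, i) = 0.5 (1 + phi(s_i, d_i)).  Iterative worklist, so deep
    pedigrees do not hit the recursion limit.
    """
    n = len(sire)
    memo: dict[tuple[int, int], float] = {}

    def phi(i: int, j: int) -> float:
        stack = [(i, j)]
        while stack:
            a, b = stack[-1]
            if a < b:
                a, b = b, a
            key = (a, b)
            if key in memo:
                stack.pop()
                continue
            if b == UNKNOWN:
                memo[key] = 0.0
                stack.pop()
                continue
            if a == b:
                s, d = sire[a], dam[a]
                if s == UNKNOWN or d == UNKNOWN:
                    memo[key] = 0.5
                elif (max(s, d), min(s, d)) in memo:
                    memo[key] = 0.5 * (1.0 + memo[(max(s, d), min(s, d))])
                    stack.pop()
                else:
                    stack.append((s, d))
                continue
            # a > b: recurse through a's parents (both earlier than a)
            s, d = sire[a], dam[a]
            ks = (max(b, s), min(b, s)) if s != UNKNOWN else None
            kd = (max(b, d), min(b, d)) if d != UNKNOWN else None
            pending = False
            for k in (ks, kd):
                if k is not None and k not in memo:
                    stack.append(k)
                    pending = True
            if pending:
                continue
            val = 0.0
            if ks is not None:
                val += 0.5 * memo[ks]
            if kd is not None:
                val += 0.5 * memo[kd]
            memo[key] = val
            stack.pop()
        i, j = max(i, j), min(i, j)
        return memo[(i, j)]

    F = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            F[i] = phi(s, d)
    return F


def inbreeding_coefficients(ped: list[PedigreeEntry]) -> np.ndarray:
    """Inbreeding coefficient per animal, in the order of ``ped``.

    F(i) = half the additive relationship of the parents; founders and
    animals with an unknown parent get 0.
    """
    ids, sire, dam = _recode(ped)
    F_topo = _kinship_inbreeding(sire, dam)
    input_pos = {e.animal: i for i, e in enumerate(ped)}
    F = np.empty(len(ped))
    for topo_i, a in enumerate(ids):
        F[input_pos[a]] = F_topo[topo_i]
    return F


def a_inverse(ped: list[PedigreeEntry], account_inbreeding: bool = True) -> RelationshipStructure:
    """Sparse inverse of A by Henderson's rules.

    The Mendelian-sampling variance of animal ``i`` is

    * both parents known:  d = 0.5 - 0.25 (F_s + F_d)
    * one parent known:    d = 0.75 - 0.25 F_p
    * no parent known:     d = 1

    (with ``account_inbreeding=False`` the F terms are dropped).  For each
    animal, 1/d is added at (a, a), -1/(2d) at (a, parent) and its mirror,
    and 1/(4d) at every (parent, parent) cell.
    """
    ids, sire, dam = _recode(ped)
    n = len(ids)
    F = _kinship_inbreeding(sire, dam) if account_inbreeding else np.zeros(n)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)  # type: ignore[arg-type]
        cols.append(c)  # type: ignore[arg-type]
        vals.append(v)  # type: ignore[arg-type]

    for i in range(n):
        parents = [p for p in (sire[i], dam[i]) if p != UNKNOWN]
        d = 1.0 - 0.25 * len(parents)
        if account_inbreeding:
            d -= 0.25 * sum(F[p] for p in parents)
        if d <= 0:
            raise ValueError(
                f"nonpositive Mendelian sampling variance for animal {ids[i]!r} (d={d})"
            )
        b = 1.0 / d
        add(i, i, b)
        for p in parents:
            add(i, p, -0.5 * b)
            add(p, i, -0.5 * b)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * b)

    a_inv = sparse.coo_matrix(
        (np.asarray(vals, dtype=float), (np.asarray(rows), np.asarray(cols))),
        shape=(n, n),
    ).tocsr()
    return RelationshipStructure(
        ids=ids, sire=sire, dam=dam, F=F, a_inv=a_inv, accounted_inbreeding=account_inbreeding
    )
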