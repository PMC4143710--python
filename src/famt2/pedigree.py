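"""Pedigree parsing and kinship-derived individual correlation matrices.

A pedigree is read from a whitespace-delimited PED/FAM file (family,
individual, father, mother, sex, phenotype, ...).  The phenotype column is
ignored: binary outcomes come from the longitudinal phenotype table.  From a
valid (acyclic) pedigree the expected genotype-correlation matrix ``Phi`` is
computed by the classical recursive kinship algorithm, with founders assumed
non-inbred.  By default ``Phi = 2 * phi`` (the additive relationship matrix,
unit diagonal for non-inbred individuals) so that ``Phi`` equals the identity
for a sample of unrelated individuals; the raw kinship coefficients ``phi``
(diagonal 1/2) are available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "compute_kinship",
]

MISSING_PARENT = "0"


class PedigreeError(ValueError):
    """Raised for malformed or inconsistent pedigree files."""


@dataclass
class Pedigree:
    """Ordered collection of individuals with parent links.

    ``father[i]`` / ``mother[i]`` are identifiers or ``None`` for founders.
    Order of ``ids`` is the file order and is the reference order for every
    matrix aligned to this pedigree.
    """

    ids: list[str]
    father: list[str | None]
    mother: list[str | None]
    family: list[str]
    sex: list[int]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {iid: k for k, iid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate individual identifiers")
        self.validate()

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    def is_founder(self, iid: str) -> bool:
        k = self._index[iid]
        return self.father[k] is None and self.mother[k] is None

    @property
    def founders(self) -> list[str]:
        return [i for i in self.ids if self.is_founder(i)]

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.family:
            seen.setdefault(f)
        return list(seen)

    def validate(self) -> None:
        """Check parent resolution, family consistency and acyclicity."""
        for k, iid in enumerate(self.ids):
            for par in (self.father[k], self.mother[k]):
                if par is None:
                    continue
                j = self._index.get(par)
                if j is None:
                    raise PedigreeError(
                        f"parent {par!r} of {iid!r} not present in pedigree"
                    )
                if self.family[j] != self.family[k]:
                    raise PedigreeError(
                        f"parent {par!r} of {iid!r} belongs to a different family"
                    )
        self.topological_order()

    def topological_order(self) -> list[int]:
        """Indices ordered parents-before-children; raises on cyclic ancestry."""
        n = len(self.ids)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = [0] * n
        for k in range(n):
            for par in (self.father[k], self.mother[k]):
                if par is not None:
                    children[self._index[par]].append(k)
                    indeg[k] += 1
        queue = [k for k in range(n) if indeg[k] == 0]
        order: list[int] = []
        while queue:
            k = queue.pop()
            order.append(k)
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            raise PedigreeError("cyclic ancestry: an individual is its own ancestor")
        return order


@dataclass
class KinshipMatrix:
    """Symmetric PSD individual-correlation matrix with its row/column order."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship matrix shape does not match id list")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, new_ids: list[str]) -> "KinshipMatrix":
        """Conjugate by the permutation taking ``self.ids`` to ``new_ids``."""
        pos = {iid: k for k, iid in enumerate(self.ids)}
        try:
            idx = np.array([pos[i] for i in new_ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown individual id {exc.args[0]!r}")
        if len(idx) != self.n:
            raise ValueError("reorder must use the full id set")
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(new_ids))

    def permute(self, idx: np.ndarray) -> "KinshipMatrix":
        idx = np.asarray(idx)
        return KinshipMatrix(
            self.values[np.ix_(idx, idx)], [self.ids[k] for k in idx]
        )

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.ids) + "\n")
            for row in self.values:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_pedigree(path: str, missing: str = MISSING_PARENT) -> Pedigree:
    """Parse a whitespace-delimited PED/FAM file (>= 6 columns).

    Column order: family, individual, father, mother, sex, phenotype[, ...].
    The phenotype column and anything after it are ignored.
    """
    ids: list[str] = []
    father: list[str | None] = []
    mother: list[str | None] = []
    family: list[str] = []
    sex: list[int] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}"
                )
            fam, iid, fid, mid, sx = fields[:5]
            if iid in seen:
                raise PedigreeError(f"{path}:{lineno}: duplicate individual {iid!r}")
            seen.add(iid)
            ids.append(iid)
            family.append(fam)
            father.append(None if fid == missing else fid)
            mother.append(None if mid == missing else mid)
            try:
                sex.append(int(sx))
            except ValueError:
                sex.append(0)
    return Pedigree(ids=ids, father=father, mother=mother, family=family, sex=sex)


def compute_kinship(ped: Pedigree, scaled: bool = True) -> KinshipMatrix:
    """Recursive kinship over a pedigree; founders assumed non-inbred.

    Returns ``2 * phi`` when ``scaled`` (default, unit diagonal), else the raw
    kinship coefficients ``phi`` (diagonal 1/2).  The result is block-diagonal
    across families because cross-family kinship is zero.
    """
    n = ped.n
    phi = np.zeros((n, n))
    order = ped.topological_order()
    processed = np.zeros(n, dtype=bool)
    for k in order:
        f = ped.father[k]
        m = ped.mother[k]
        fi = ped.index_of(f) if f is not None else None
        mi = ped.index_of(m) if m is not None else None
        prev = processed.nonzero()[0]
        if prev.size:
            row = np.zeros(prev.size)
            if fi is not None:
                row += 0.5 * phi[fi, prev]
            if mi is not None:
                row += 0.5 * phi[mi, prev]
            phi[k, prev] = row
            phi[prev, k] = row
        self_kin = 0.5
        if fi is not None and mi is not None:
            self_kin += 0.5 * phi[fi, mi]
        phi[k, k] = self_kin
        processed[k] = True
    values = 2.0 * phi if scaled else phi
    return KinshipMatrix(values, list(ped.ids))
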