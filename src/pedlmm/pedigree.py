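"""Pedigrees and expected kinship.

A :class:`Pedigree` is a validated collection of families with parent
links, stored in topological order (parents before offspring).  The
kinship coefficient phi(a, b) is the probability that one allele sampled
at random from *a* and one from *b* are identical by descent; the
additive relationship matrix is ``A = 2 * phi`` and supplies the
covariance structure ``Var(G) = A * sigma_g2`` of the polygenic random
effect used throughout the association models.

Files follow the PLINK ``.fam`` convention for the first five columns
(FID IID PAT MAT SEX, with "0" marking a missing parent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

MISSING_PARENT = "0"

_SEX_MAP = {
    "1": "male",
    "2": "female",
    "m": "male",
    "f": "female",
    "male": "male",
    "female": "female",
    "0": "unknown",
    "-9": "unknown",
    "unknown": "unknown",
}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or unparsable files."""


@dataclass(frozen=True)
class Member:
    """One individual: family id, own id, parent ids (None = founder), sex."""

    fid: str
    iid: str
    father: str | None
    mother: str | None
    sex: str = "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father is None


class Pedigree:
    """Validated set of families, members in topological order.

    Invariants enforced at construction:

    * individual ids are unique (globally: matrices downstream are keyed
      by IID alone);
    * each named parent exists in the same family;
    * parentage is all-or-nothing — half-specified parents are rejected
      rather than patched with a dummy founder;
    * the parent graph is acyclic.
    """

    def __init__(self, members: Iterable[Member]):
        members = list(members)
        self._validate(members)
        self.members: list[Member] = _topological_order(members)
        self.id_index: dict[str, int] = {m.iid: k for k, m in enumerate(self.members)}

    @staticmethod
    def _validate(members: Sequence[Member]) -> None:
        seen: set[str] = set()
        by_family: dict[str, set[str]] = {}
        for m in members:
            if m.iid in seen:
                raise PedigreeError(f"duplicate individual id {m.iid!r}")
            seen.add(m.iid)
            by_family.setdefault(m.fid, set()).add(m.iid)
        for m in members:
            if (m.father is None) != (m.mother is None):
                raise PedigreeError(
                    f"individual {m.iid!r}: exactly one parent specified; "
                    "founders must have both parents missing"
                )
            if m.father is not None:
                fam = by_family[m.fid]
                for parent in (m.father, m.mother):
                    if parent not in fam:
                        raise PedigreeError(
                            f"individual {m.iid!r} names parent {parent!r} "
                            f"absent from family {m.fid!r}"
                        )
                if m.father == m.iid or m.mother == m.iid:
                    raise PedigreeError(f"individual {m.iid!r} is its own parent")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Member]:
        return iter(self.members)

    @property
    def ids(self) -> list[str]:
        return [m.iid for m in self.members]

    @property
    def founders(self) -> list[Member]:
        return [m for m in self.members if m.is_founder]

    @property
    def families(self) -> list[str]:
        out: list[str] = []
        for m in self.members:
            if m.fid not in out:
                out.append(m.fid)
        return out

    def generation_depth(self) -> np.ndarray:
        """0 for founders, 1 + max(parent depth) otherwise (topological order)."""
        depth = np.zeros(len(self), dtype=int)
        for k, m in enumerate(self.members):
            if not m.is_founder:
                depth[k] = 1 + max(
                    depth[self.id_index[m.father]], depth[self.id_index[m.mother]]
                )
        return depth


def _topological_order(members: Sequence[Member]) -> list[Member]:
    placed: set[str] = set()
    order: list[Member] = []
    remaining = list(members)
    while remaining:
        deferred: list[Member] = []
        for m in remaining:
            if m.is_founder or (m.father in placed and m.mother in placed):
                order.append(m)
                placed.add(m.iid)
            else:
                deferred.append(m)
        if len(deferred) == len(remaining):
            stuck = ", ".join(m.iid for m in deferred[:5])
            raise PedigreeError(f"pedigree contains a cycle (involving: {stuck})")
        remaining = deferred
    return order


def read_pedigree(path) -> Pedigree:
    """Read a PLINK .fam-style pedigree file.

    Whitespace-delimited, one row per individual, columns
    FID IID PAT MAT SEX (extra columns such as the .fam phenotype are
    ignored); a parent id of "0" means missing.
    """
    members: list[Member] = []
    lines: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 5:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected at least 5 columns "
                    f"(FID IID PAT MAT SEX), got {len(fields)}"
                )
            fid, iid, pat, mat, sex = fields[:5]
            members.append(
                Member(
                    fid=fid,
                    iid=iid,
                    father=None if pat == MISSING_PARENT else pat,
                    mother=None if mat == MISSING_PARENT else mat,
                    sex=_SEX_MAP.get(sex.lower(), "unknown"),
                )
            )
            lines[iid] = lineno
    try:
        return Pedigree(members)
    except PedigreeError as err:
        # attach file/row context to the structural error
        row = next((lines[m.iid] for m in members if m.iid in str(err)), None)
        loc = f"{path}" + (f": line {row}" if row is not None else "")
        raise PedigreeError(f"{loc}: {err}") from err


def write_pedigree(ped: Pedigree, path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for m in ped:
            fh.write(
                f"{m.fid}\t{m.iid}\t{m.father or '0'}\t{m.mother or '0'}"
                f"\t{sex_code[m.sex]}\n"
            )


@dataclass
class KinshipMatrix:
    """Kinship coefficients over an ordered set of individuals."""

    ids: tuple[str, ...]
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("phi shape does not match number of ids")
        self.id_index = {iid: k for k, iid in enumerate(self.ids)}

    def coefficient(self, a: str, b: str) -> float:
        return float(self.phi[self.id_index[a], self.id_index[b]])

    def write(self, path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(sep.join(("IID", *self.ids)) + "\n")
            for iid, row in zip(self.ids, self.phi):
                fh.write(iid + sep + sep.join(f"{v:.10g}" for v in row) + "\n")


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Expected kinship by the standard recursion in topological order.

    phi(a, a) = (1 + phi(father_a, mother_a)) / 2 (0.5 for non-inbred);
    phi(a, b) = (phi(father_a, b) + phi(mother_a, b)) / 2 for b processed
    before a.  Founders are unrelated and non-inbred by definition, so
    cross-family entries are exactly zero.
    """
    n = len(ped)
    phi = np.zeros((n, n))
    idx = ped.id_index
    for a, m in enumerate(ped.members):
        if m.is_founder:
            phi[a, a] = 0.5
        else:
            f, mo = idx[m.father], idx[m.mother]
            phi[a, a] = 0.5 * (1.0 + phi[f, mo])
            if a:
                row = 0.5 * (phi[f, :a] + phi[mo, :a])
                phi[a, :a] = row
                phi[:a, a] = row
    return KinshipMatrix(ids=tuple(ped.ids), phi=phi)


def relationship_matrix(kin: KinshipMatrix, ids: Sequence[str] | None = None) -> np.ndarray:
    """Additive relationship matrix A = 2*phi, optionally over a subset/order.

    A is positive semi-definite for any valid pedigree; eigenvalues below
    ``-1e-8 * max`` trigger an error, tiny negatives are clipped to zero
    with a warning.
    """
    if ids is None:
        a = 2.0 * kin.phi
    else:
        take = [kin.id_index[i] for i in ids]
        a = 2.0 * kin.phi[np.ix_(take, take)]
    evals = np.linalg.eigvalsh(a)
    top = max(evals[-1], 1.0)
    if evals[0] < -1e-8 * top:
        raise ValueError(
            f"relationship matrix is not positive semi-definite "
            f"(min eigenvalue {evals[0]:.3e})"
        )
    if evals[0] < 0:
        warnings.warn(
            "clipping tiny negative eigenvalues of the relationship matrix to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        w, v = np.linalg.eigh(a)
        a = (v * np.clip(w, 0.0, None)) @ v.T
        a = 0.5 * (a + a.T)
    return a
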