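"""Pedigrees and relationship matrices.

Two sources of the N x N relationship matrix ``Phi`` are supported: the
expected (pedigree) matrix, with entries ``2 * kinship`` off the diagonal and
``1 + inbreeding`` on it, and the empirical genomic relationship matrix (GRM)
estimated from a dense panel of null markers by the standardized
cross-product estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mfqls.exceptions import DataError, PedigreeError, RelationshipMatrixError

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "kinship_from_pedigree",
    "grm_from_genotypes",
    "canonical_pedigree",
]

MISSING_PARENT = "0"

_FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


@dataclass
class Pedigree:
    """A collection of families with parent links, in .fam column order.

    Invariants (checked on construction): ids are unique within a family,
    parents are either both specified or both missing, every named parent
    exists in the same family, and no individual is its own ancestor.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _FAM_COLUMNS[:5] if c not in self.table.columns]
        if missing:
            raise PedigreeError(f"pedigree table lacks columns: {missing}")
        if "phenotype" not in self.table.columns:
            self.table = self.table.assign(phenotype="-9")
        self.table = self.table.reset_index(drop=True)
        for col in ("fid", "iid", "father", "mother"):
            self.table[col] = self.table[col].astype(str)
        self._validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        """Total number of individuals N."""
        return len(self.table)

    @property
    def ids(self) -> list[tuple[str, str]]:
        """(family id, individual id) keys in dataset order."""
        return list(zip(self.table["fid"], self.table["iid"]))

    @property
    def families(self) -> list[str]:
        return list(dict.fromkeys(self.table["fid"]))

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.table["father"] == MISSING_PARENT).to_numpy()

    def _validate(self) -> None:
        t = self.table
        dup = t.duplicated(subset=["fid", "iid"])
        if dup.any():
            bad = t.loc[dup, ["fid", "iid"]].iloc[0].tolist()
            raise PedigreeError(f"duplicate individual id within family: {bad}")
        half = (t["father"] == MISSING_PARENT) != (t["mother"] == MISSING_PARENT)
        if half.any():
            bad = t.loc[half, ["fid", "iid"]].iloc[0].tolist()
            raise PedigreeError(f"half-specified parents for individual: {bad}")
        members = {(f, i) for f, i in zip(t["fid"], t["iid"])}
        for col in ("father", "mother"):
            named = t[t[col] != MISSING_PARENT]
            for fid, pid in zip(named["fid"], named[col]):
                if (fid, pid) not in members:
                    raise PedigreeError(
                        f"unknown {col} id {pid!r} in family {fid!r}"
                    )
        self._topological_order()  # raises on cycles

    def _topological_order(self) -> list[int]:
        """Row indices ordered parents-before-children; raises on cycles."""
        t = self.table
        index = {(f, i): k for k, (f, i) in enumerate(zip(t["fid"], t["iid"]))}
        parents: list[tuple[int, ...]] = []
        for fid, fa, mo in zip(t["fid"], t["father"], t["mother"]):
            if fa == MISSING_PARENT:
                parents.append(())
            else:
                parents.append((index[(fid, fa)], index[(fid, mo)]))
        order: list[int] = []
        state = np.zeros(self.n, dtype=np.int8)  # 0 new, 1 open, 2 done

        def visit(k: int) -> None:
            stack = [(k, 0)]
            while stack:
                node, phase = stack.pop()
                if phase == 0:
                    if state[node] == 2:
                        continue
                    if state[node] == 1:
                        raise PedigreeError(
                            "cycle detected in pedigree near individual "
                            f"{self.ids[node]}"
                        )
                    state[node] = 1
                    stack.append((node, 1))
                    for p in parents[node]:
                        if state[p] == 1:
                            raise PedigreeError(
                                "cycle detected in pedigree near individual "
                                f"{self.ids[p]}"
                            )
                        if state[p] == 0:
                            stack.append((p, 0))
                else:
                    state[node] = 2
                    order.append(node)

        for k in range(self.n):
            if state[k] == 0:
                visit(k)
        return order

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_fam(cls, path) -> "Pedigree":
        """Read a PLINK .fam file (FID IID PAT MAT SEX PHENO)."""
        table = pd.read_csv(
            path, sep=r"\s+", header=None, names=_FAM_COLUMNS, dtype=str
        )
        table["sex"] = pd.to_numeric(table["sex"], errors="coerce").fillna(0).astype(int)
        return cls(table)

    def to_fam(self, path) -> None:
        self.table[_FAM_COLUMNS].to_csv(path, sep="\t", header=False, index=False)

    def parent_indices(self) -> np.ndarray:
        """(N, 2) array of row indices of (father, mother); -1 for founders."""
        t = self.table
        index = {(f, i): k for k, (f, i) in enumerate(zip(t["fid"], t["iid"]))}
        out = np.full((self.n, 2), -1, dtype=np.int64)
        for k, (fid, fa, mo) in enumerate(zip(t["fid"], t["father"], t["mother"])):
            if fa != MISSING_PARENT:
                out[k, 0] = index[(fid, fa)]
                out[k, 1] = index[(fid, mo)]
        return out


@dataclass
class RelationshipMatrix:
    """Symmetric N x N relationship matrix aligned to a dataset ordering.

    ``source`` is ``"pedigree"`` (2*kinship off-diagonal, 1+inbreeding on the
    diagonal) or ``"genomic"`` (standardized GRM).
    """

    values: np.ndarray = field(repr=False)
    ids: list[tuple[str, str]]
    source: str = "pedigree"
    n_markers: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise RelationshipMatrixError("relationship matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise RelationshipMatrixError("id list does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-8):
            raise RelationshipMatrixError("relationship matrix is not symmetric")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def ensure_positive_definite(
        self, min_eigenvalue: float = 1e-8, ridge: float | None = None
    ) -> "RelationshipMatrix":
        """Reject a near-singular matrix, or regularize it with a ridge.

        MZ-twin duplicate rows make a pedigree matrix exactly singular; with
        ``ridge`` set, ``ridge * I`` is added whenever the smallest eigenvalue
        falls below ``min_eigenvalue``.
        """
        smallest = float(np.linalg.eigvalsh(self.values)[0])
        if smallest >= min_eigenvalue:
            return self
        if ridge is None:
            raise RelationshipMatrixError(
                f"relationship matrix is numerically singular "
                f"(min eigenvalue {smallest:.3e}); pass a ridge to regularize"
            )
        bumped = self.values + (ridge + max(0.0, -smallest)) * np.eye(self.n)
        return RelationshipMatrix(bumped, self.ids, self.source, self.n_markers)

    def subset(self, rows: Sequence[int]) -> "RelationshipMatrix":
        rows = np.asarray(rows)
        return RelationshipMatrix(
            self.values[np.ix_(rows, rows)],
            [self.ids[i] for i in rows],
            self.source,
            self.n_markers,
        )

    # -- I/O ---------------------------------------------------------------
    def to_grm_text(self, prefix) -> None:
        """Write GCTA text GRM: ``<prefix>.grm`` (i j nsnp value, 1-based,
        lower triangle) and ``<prefix>.grm.id``."""
        nm = self.n_markers if self.n_markers is not None else 0
        with open(f"{prefix}.grm", "w") as fh:
            for i in range(self.n):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t{nm}\t{self.values[i, j]:.8g}\n")
        with open(f"{prefix}.grm.id", "w") as fh:
            for fid, iid in self.ids:
                fh.write(f"{fid}\t{iid}\n")

    @classmethod
    def from_grm_text(cls, prefix, source: str = "genomic") -> "RelationshipMatrix":
        ids = [
            tuple(line.split()[:2])
            for line in open(f"{prefix}.grm.id")
            if line.strip()
        ]
        n = len(ids)
        values = np.zeros((n, n))
        n_markers = None
        with open(f"{prefix}.grm") as fh:
            for line in fh:
                i, j, nm, v = line.split()
                i, j = int(i) - 1, int(j) - 1
                values[i, j] = values[j, i] = float(v)
                n_markers = int(float(nm)) or n_markers
        return cls(values, ids, source, n_markers)

    def to_tsv(self, path) -> None:
        cols = [f"{f}:{i}" for f, i in self.ids]
        pd.DataFrame(self.values, index=cols, columns=cols).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, source: str = "pedigree") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [tuple(c.split(":", 1)) for c in df.columns]
        return cls(df.to_numpy(dtype=float), ids, source)


def kinship_from_pedigree(ped: Pedigree) -> RelationshipMatrix:
    """Expected relationship matrix from a pedigree.

    Entry (a, b) is ``2 * pi_ab`` for a != b and ``1 + d_a`` on the diagonal,
    where ``pi`` is the kinship coefficient and ``d`` the inbreeding
    coefficient, computed by the standard recursion over a topological
    ordering. The result is block-diagonal across families.
    """
    order = ped._topological_order()
    parents = ped.parent_indices()
    n = ped.n
    phi = np.zeros((n, n))  # kinship coefficients
    seen: list[int] = []
    for a in order:
        fa, mo = parents[a]
        if fa < 0:
            phi[a, a] = 0.5
            # founders: unrelated to everyone processed so far (phi stays 0)
        else:
            phi[a, a] = 0.5 * (1.0 + phi[fa, mo])
            for b in seen:
                phi[a, b] = phi[b, a] = 0.5 * (phi[fa, b] + phi[mo, b])
        seen.append(a)
    values = 2.0 * phi
    np.fill_diagonal(values, 2.0 * np.diag(phi))  # = 1 + d
    return RelationshipMatrix(values, ped.ids, source="pedigree")


def grm_from_genotypes(
    genotypes: np.ndarray,
    ids: Iterable[tuple[str, str]] | None = None,
    freqs: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Standardized genomic relationship matrix from a null marker panel.

    Entry (a, b) = mean over markers of
    ``(x_am - 2 p_m)(x_bm - 2 p_m) / (2 p_m (1 - p_m))``; the diagonal uses
    the same standardized cross-product. Monomorphic markers are excluded
    with a warning. ``freqs`` defaults to sample allele frequencies.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2:
        raise DataError("genotype panel must be 2-dimensional (N x M)")
    n, m = X.shape
    if m < 1:
        raise DataError("GRM needs at least one marker")
    if freqs is None:
        freqs = np.nanmean(X, axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    poly = (freqs > 0.0) & (freqs < 1.0)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic marker(s) from GRM",
            stacklevel=2,
        )
    if not poly.any():
        raise DataError("all markers monomorphic; cannot estimate GRM")
    Xp = X[:, poly]
    p = freqs[poly]
    W = (Xp - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    values = (W @ W.T) / W.shape[1]
    if ids is None:
        ids = [("0", str(i + 1)) for i in range(n)]
    return RelationshipMatrix(values, list(ids), source="genomic",
                              n_markers=int(poly.sum()))


def canonical_pedigree(n_families: int = 1) -> Pedigree:
    """Ten-member, three-generation family template used in simulations.

    Two grandparents; two of their children, each married to a founder
    spouse; and two grandchildren per couple. Individuals 1, 2, 5, 6 are
    founders.
    """
    rows = []
    #       iid father mother sex
    template = [
        ("1", "0", "0", 1),
        ("2", "0", "0", 2),
        ("3", "1", "2", 1),
        ("4", "1", "2", 2),
        ("5", "0", "0", 2),  # spouse of 3
        ("6", "0", "0", 1),  # spouse of 4
        ("7", "3", "5", 1),
        ("8", "3", "5", 2),
        ("9", "6", "4", 1),
        ("10", "6", "4", 2),
    ]
    for f in range(1, n_families + 1):
        fid = f"F{f}"
        for iid, fa, mo, sex in template:
            rows.append((fid, iid, fa, mo, sex, "-9"))
    return Pedigree(pd.DataFrame(rows, columns=_FAM_COLUMNS))
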