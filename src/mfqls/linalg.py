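"""Cached linear algebra on the relationship matrix.

The score test, the REML fits and the BLUP offsets all reduce to a handful
of primitives on ``Phi``: solves, products, the weight vector
``Phi^{-1} 1`` and the eigenbasis. ``PhiOps`` caches these for a dense
matrix; ``BlockPhiOps`` exploits a block-diagonal ``Phi`` built from many
copies of one family block, which makes replicate studies with a shared
pedigree template cheap.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh

from mfqls.exceptions import RelationshipMatrixError

__all__ = ["PhiOps", "BlockPhiOps", "as_phi_ops"]


class PhiOps:
    """Cached operations for a dense symmetric positive definite Phi."""

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float)
        self.n = self.values.shape[0]
        try:
            self._chol = cho_factor(self.values, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises
            raise RelationshipMatrixError(
                "relationship matrix is not positive definite"
            ) from exc
        self._eig: tuple[np.ndarray, np.ndarray] | None = None
        self.phi_inv_one = self.solve(np.ones(self.n))
        s = float(self.phi_inv_one.sum())
        if s <= 0:
            raise RelationshipMatrixError("1' Phi^-1 1 must be positive")
        self.c = 1.0 / s  # (1' Phi^-1 1)^-1

    def solve(self, b: np.ndarray) -> np.ndarray:
        return cho_solve(self._chol, b)

    def mul(self, b: np.ndarray) -> np.ndarray:
        return self.values @ b

    # -- eigenbasis --------------------------------------------------------
    def _ensure_eig(self) -> None:
        if self._eig is None:
            d, U = eigh(self.values)
            if d[0] <= 0:
                raise RelationshipMatrixError(
                    "relationship matrix is not positive definite"
                )
            self._eig = (d, U)

    @property
    def eigenvalues(self) -> np.ndarray:
        self._ensure_eig()
        return self._eig[0]

    def to_eigenbasis(self, b: np.ndarray) -> np.ndarray:
        """U' b."""
        self._ensure_eig()
        return self._eig[1].T @ b

    def from_eigenbasis(self, b: np.ndarray) -> np.ndarray:
        """U b."""
        self._ensure_eig()
        return self._eig[1] @ b


class BlockPhiOps:
    """Same interface as :class:`PhiOps` for Phi = I_F kron block.

    All primitives run blockwise, so the cost is linear in the number of
    families instead of quadratic in N.
    """

    def __init__(self, block: np.ndarray, n_blocks: int):
        self.block = np.asarray(block, dtype=float)
        self.k = self.block.shape[0]
        self.n_blocks = n_blocks
        self.n = self.k * n_blocks
        d, V = eigh(self.block)
        if d[0] <= 0:
            raise RelationshipMatrixError("family block is not positive definite")
        self._d_block, self._V = d, V
        self._block_inv = V @ np.diag(1.0 / d) @ V.T
        self.eigenvalues = np.tile(d, n_blocks)
        w_block = self._block_inv @ np.ones(self.k)
        self.phi_inv_one = np.tile(w_block, n_blocks)
        self.c = 1.0 / float(self.phi_inv_one.sum())

    @property
    def values(self) -> np.ndarray:
        out = np.zeros((self.n, self.n))
        for f in range(self.n_blocks):
            sl = slice(f * self.k, (f + 1) * self.k)
            out[sl, sl] = self.block
        return out

    def _blockwise(self, mat: np.ndarray, b: np.ndarray) -> np.ndarray:
        vec = b.ndim == 1
        b2 = b.reshape(self.n_blocks, self.k, -1)
        out = np.einsum("ij,fjq->fiq", mat, b2).reshape(self.n, -1)
        return out[:, 0] if vec else out

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self._blockwise(self._block_inv, b)

    def mul(self, b: np.ndarray) -> np.ndarray:
        return self._blockwise(self.block, b)

    def to_eigenbasis(self, b: np.ndarray) -> np.ndarray:
        return self._blockwise(self._V.T, b)

    def from_eigenbasis(self, b: np.ndarray) -> np.ndarray:
        return self._blockwise(self._V, b)


def as_phi_ops(phi) -> PhiOps | BlockPhiOps:
    """Coerce a RelationshipMatrix, ndarray or existing ops object."""
    if isinstance(phi, (PhiOps, BlockPhiOps)):
        return phi
    values = getattr(phi, "values", phi)
    return PhiOps(np.asarray(values, dtype=float))
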