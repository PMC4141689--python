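"""Additive genetic relationship matrix (A) from pedigree, with cached factorizations.

The tabular (recursive) method is exact under inbreeding:

    a_ii = 1 + a_{sire(i), dam(i)} / 2
    a_ij = (a_{j, sire(i)} + a_{j, dam(i)}) / 2      for j ordered before i,

with an unknown parent contributing 0.  A is dense; the intended scale is a
few thousand individuals, where a one-off eigendecomposition is cheap and is
reused by every downstream mixed-model computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .panel import PanelError, PedigreeTable, UNKNOWN_PARENT


class KinshipError(ValueError):
    pass


@dataclass
class AMatrix:
    """Dense symmetric additive relationship matrix with its id order."""

    values: np.ndarray
    id_order: list[str]
    _cho_cache: dict = field(default_factory=dict, repr=False, compare=False)
    _eig_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise KinshipError("A must be square")
        if len(self.id_order) != n:
            raise KinshipError("id_order length mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise KinshipError("A must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition ``A = U diag(d) U^T`` (ascending d)."""
        if self._eig_cache is None:
            d, u = linalg.eigh(self.values)
            if d.min() < -1e-8 * max(1.0, d.max()):
                raise KinshipError(f"A is not PSD (min eigenvalue {d.min():g})")
            self._eig_cache = (np.maximum(d, 0.0), u)
        return self._eig_cache

    def solve(self, shift: float, rhs: np.ndarray) -> np.ndarray:
        """Solve ``(shift*I + A) x = rhs`` via a cached Cholesky factorization."""
        return a_solve(self, shift, rhs)

    def submatrix(self, ids: list[str]) -> "AMatrix":
        """Restrict to a subset of individuals, in the given order."""
        pos = {iid: k for k, iid in enumerate(self.id_order)}
        try:
            idx = np.array([pos[str(i)] for i in ids])
        except KeyError as e:
            raise KinshipError(f"individual {e.args[0]!r} not in A") from None
        return AMatrix(self.values[np.ix_(idx, idx)], [str(i) for i in ids])


def a_matrix(pedigree: PedigreeTable) -> AMatrix:
    """Build A by the tabular method (exact, handles inbreeding).

    Founders get diagonal 1 and founder-founder off-diagonals 0; a known
    sire/dam pair with relationship ``a_sd`` gives their offspring diagonal
    ``1 + a_sd/2``.
    """
    order = pedigree.topological_order()  # raises PanelError naming a cycle
    idx = {iid: k for k, iid in enumerate(order)}
    parents = {i: (s, d) for i, s, d in pedigree.records}
    n = len(order)
    a = np.zeros((n, n))
    for k, iid in enumerate(order):
        s, d = parents[iid]
        si = idx.get(s) if s != UNKNOWN_PARENT else None
        di = idx.get(d) if d != UNKNOWN_PARENT else None
        if s != UNKNOWN_PARENT and si is None:
            raise PanelError(f"sire {s!r} of {iid!r} is not in the pedigree")
        if d != UNKNOWN_PARENT and di is None:
            raise PanelError(f"dam {d!r} of {iid!r} is not in the pedigree")
        row = np.zeros(k)
        if si is not None:
            row += 0.5 * a[si, :k]
        if di is not None:
            row += 0.5 * a[di, :k]
        a[k, :k] = row
        a[:k, k] = row
        a_sd = a[si, di] if (si is not None and di is not None) else 0.0
        a[k, k] = 1.0 + 0.5 * a_sd
    return AMatrix(a, order)


def a_solve(A: AMatrix, shift: float, rhs: np.ndarray) -> np.ndarray:
    """Solve ``(shift*I + A) x = rhs`` with a cached symmetric factorization.

    ``shift`` must be non-negative; with ``shift = 0`` and singular A an
    explicit error is raised.
    """
    if shift < 0:
        raise KinshipError("shift must be non-negative")
    rhs = np.asarray(rhs, dtype=float)
    key = float(shift)
    if key not in A._cho_cache:
        m = A.values + shift * np.eye(A.n)
        try:
            A._cho_cache[key] = linalg.cho_factor(m, lower=True)
        except linalg.LinAlgError:
            raise KinshipError(
                f"(shift*I + A) is singular or indefinite at shift={shift:g}") from None
    return linalg.cho_solve(A._cho_cache[key], rhs)
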