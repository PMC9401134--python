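"""Penalized spline bases for smooth regression terms.

Two basis families are provided:

* 1-D cubic B-splines on an even knot grid with a second-order difference
  (wiggliness) penalty, whose null space contains linear functions; and
* an isotropic 2-D thin-plate-type radial basis (r^2 log r kernel on a
  deterministic space-filling knot set) for joint wind-component terms,
  penalized by the thin-plate bending energy restricted to the knots.

Each term is centred against the intercept (its fitted values sum to zero
over the training rows), implemented by reparameterizing onto the null
space of the column-sum constraint, so a term with ``basis_dim = k``
contributes k - 1 identifiable columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = ["SmoothTerm", "TermBasis", "build_basis"]


@dataclass(frozen=True)
class SmoothTerm:
    """Specification of one smooth model term.

    variables : one predictor name (1-D spline) or a pair (isotropic 2-D
        smooth, used for U/V wind components which only enter jointly).
    basis_dim : number of basis functions before the centring constraint
        (default 10 for 1-D, 30 for 2-D).
    """

    variables: tuple[str, ...]
    basis: str = "spline_1d"
    basis_dim: int = 0

    def __post_init__(self):
        if self.basis not in ("spline_1d", "isotropic_2d"):
            raise ValueError(f"unknown basis {self.basis!r}")
        nvar = 2 if self.basis == "isotropic_2d" else 1
        if len(self.variables) != nvar:
            raise ValueError(f"{self.basis} terms need exactly {nvar} variable(s)")
        if self.basis_dim == 0:
            object.__setattr__(self, "basis_dim", 10 if self.basis == "spline_1d" else 30)
        if self.basis_dim < (4 if self.basis == "spline_1d" else 5):
            raise ValueError("basis_dim too small")

    @property
    def name(self) -> str:
        return "s(" + ",".join(self.variables) + ")"


class TermBasis:
    """A smooth term's design-column builder and penalty, fitted to data.

    Attributes
    ----------
    columns : (n, q) centred design block for the training data.
    penalty : (q, q) positive semi-definite penalty matrix.
    rank : rank of the penalty; q - rank is the term's unpenalized
        (polynomial) null-space dimension.
    """

    def __init__(self, term: SmoothTerm, data: pd.DataFrame):
        self.term = term
        vals = data[list(term.variables)].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError(f"non-finite values in term {term.name}")
        if term.basis == "spline_1d":
            raw, S = self._fit_1d(vals[:, 0])
        else:
            raw, S = self._fit_2d(vals)
        # Centring constraint: column sums orthogonal to the intercept.
        C = raw.sum(axis=0, keepdims=True)
        self._Z = null_space(C)
        self.columns = raw @ self._Z
        S = self._Z.T @ S @ self._Z
        self.penalty = (S + S.T) / 2.0
        eigvals = np.linalg.eigvalsh(self.penalty)
        self.rank = int(np.sum(eigvals > max(eigvals[-1], 1e-300) * 1e-9))
        pos = eigvals[eigvals > max(eigvals[-1], 1e-300) * 1e-9]
        self.log_det_plus = float(np.sum(np.log(pos))) if len(pos) else 0.0

    # -- 1-D cubic B-spline with difference penalty --------------------

    def _fit_1d(self, x: np.ndarray):
        # Uniform unclamped knots (P-spline convention): the coefficients of
        # any linear function then have vanishing second differences, so the
        # difference penalty's null space contains linear trends exactly.
        k = self.term.basis_dim
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise ValueError(f"constant predictor in term {self.term.name}")
        self._range = (lo, hi)
        inner = np.linspace(lo, hi, k - 2)  # hits lo and hi exactly
        h = inner[1] - inner[0]
        self._knots = np.concatenate(
            [[lo - 3 * h, lo - 2 * h, lo - h], inner, [hi + h, hi + 2 * h, hi + 3 * h]]
        )
        raw = self._design_1d(x)
        D = np.diff(np.eye(k), n=2, axis=0)
        return raw, D.T @ D

    def _design_1d(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self._range
        xc = np.clip(x, lo, hi)
        return BSpline.design_matrix(xc, self._knots, 3).toarray()

    # -- isotropic 2-D thin-plate-type radial basis --------------------

    def _fit_2d(self, xy: np.ndarray):
        # A single isotropic scale keeps the basis rotation-invariant.
        self._center = xy.mean(axis=0)
        z = xy - self._center
        self._scale = float(np.sqrt(np.mean(np.sum(z**2, axis=1)) / 2.0))
        if self._scale <= 0:
            raise ValueError(f"constant predictor in term {self.term.name}")
        z = z / self._scale
        self._range2 = (z.min(axis=0), z.max(axis=0))
        m = self.term.basis_dim + 1  # knots; m-3 radial + 2 linear columns
        knots = _farthest_point_knots(z, m)
        self._knots2 = knots
        m = len(knots)
        Ekk = _tps_kernel(_sqdist(knots, knots))
        Tk = np.column_stack([np.ones(m), knots])
        self._Zk = null_space(Tk.T)  # (m, m-3)
        raw = self._design_2d_scaled(z)
        S = np.zeros((raw.shape[1], raw.shape[1]))
        S[2:, 2:] = self._Zk.T @ Ekk @ self._Zk
        return raw, S

    def _design_2d_scaled(self, z: np.ndarray) -> np.ndarray:
        E = _tps_kernel(_sqdist(z, self._knots2))
        return np.column_stack([z, E @ self._Zk])

    # -- prediction ----------------------------------------------------

    def design(self, data: pd.DataFrame) -> np.ndarray:
        """Centred design block for new data, using the training transform."""
        vals = data[list(self.term.variables)].to_numpy(dtype=float)
        if self.term.basis == "spline_1d":
            raw = self._design_1d(vals[:, 0])
        else:
            raw = self._design_2d_scaled((vals - self._center) / self._scale)
        return raw @ self._Z

    def extrapolates(self, data: pd.DataFrame) -> np.ndarray:
        """Boolean mask of rows outside the training range of this term."""
        vals = data[list(self.term.variables)].to_numpy(dtype=float)
        if self.term.basis == "spline_1d":
            lo, hi = self._range
            return (vals[:, 0] < lo) | (vals[:, 0] > hi)
        z = (vals - self._center) / self._scale
        lo, hi = self._range2
        return np.any((z < lo) | (z > hi), axis=1)


def build_basis(term: SmoothTerm, data: pd.DataFrame) -> TermBasis:
    """Construct the design columns and penalty of ``term`` on ``data``."""
    if len(data) <= term.basis_dim:
        raise ValueError(
            f"term {term.name}: need more rows ({len(data)}) than basis_dim ({term.basis_dim})"
        )
    return TermBasis(term, data)


def _sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    return np.sum(d * d, axis=-1)


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """Thin-plate kernel r^2 log r = 0.5 r^2 log r^2, with value 0 at r = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)
    return np.where(r2 > 0.0, out, 0.0)


def _farthest_point_knots(z: np.ndarray, m: int) -> np.ndarray:
    """Deterministic space-filling knot selection (greedy k-centre).

    Starts from the point nearest the centroid and repeatedly adds the point
    farthest from the chosen set; ties break toward the lowest row index.
    Duplicate coordinates are collapsed first.
    """
    uniq = np.unique(z, axis=0)
    if len(uniq) <= max(m, 3):
        if len(uniq) < 4:
            raise ValueError("2-D smooth needs at least 4 distinct points")
        return uniq
    centroid = uniq.mean(axis=0)
    first = int(np.argmin(np.sum((uniq - centroid) ** 2, axis=1)))
    chosen = [first]
    mind = np.sum((uniq - uniq[first]) ** 2, axis=1)
    for _ in range(m - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.sum((uniq - uniq[nxt]) ** 2, axis=1))
    return uniq[np.sort(chosen)]
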