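"""C2-continuous piecewise quintic Bezier curves.

Normalized muscle characteristic curves (active-torque-angle, torque-
angular-velocity) and the orthosis torque-angle profile are all represented
as chains of quintic Bezier spans with twice-continuous junctions, so that
every quantity entering the optimal control problem has smooth first and
second derivatives.

The abscissa control points of each span are uniformly spaced, which makes
each span an ordinary quintic polynomial in x expressed in the Bernstein
basis.  Evaluation is analytic in x (complex inputs are supported, which the
optimal-control layer exploits for complex-step differentiation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.special import comb

__all__ = ["NormalizedCurve", "fit_c2_bezier", "CurveFitError"]

_DEGREE = 5


class CurveFitError(ValueError):
    """Raised when curve samples are unsuitable for fitting."""


def _bernstein_matrix(t: np.ndarray, degree: int = _DEGREE) -> np.ndarray:
    """Bernstein basis values B_{k,degree}(t) for each t; shape (len(t), degree+1)."""
    t = np.asarray(t)
    k = np.arange(degree + 1)
    return comb(degree, k) * t[..., None] ** k * (1.0 - t[..., None]) ** (degree - k)


@dataclass(frozen=True)
class NormalizedCurve:
    """Piecewise quintic in Bernstein form with C2 junctions.

    Parameters
    ----------
    breakpoints:
        Strictly increasing span boundaries, length ``n_spans + 1``.
    control:
        Ordinate control values, shape ``(n_spans, 6)``.  Abscissa controls
        are implicitly uniform within each span.

    Outside ``[breakpoints[0], breakpoints[-1]]`` the curve extrapolates
    linearly using the boundary value and tangent.
    """

    breakpoints: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        ctrl = np.asarray(self.control, dtype=float)
        if bp.ndim != 1 or bp.size < 2 or np.any(np.diff(bp) <= 0):
            raise CurveFitError("breakpoints must be strictly increasing, >= 2 entries")
        if ctrl.shape != (bp.size - 1, _DEGREE + 1):
            raise CurveFitError(f"control must have shape ({bp.size - 1}, 6)")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "control", ctrl)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.breakpoints[0]), float(self.breakpoints[-1])

    # -- evaluation ----------------------------------------------------
    def _locate(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Span index and local parameter for each x (complex-safe)."""
        xr = np.real(x)
        idx = np.clip(np.searchsorted(self.breakpoints, xr, side="right") - 1,
                      0, self.breakpoints.size - 2)
        x0 = self.breakpoints[idx]
        widths = np.diff(self.breakpoints)[idx]
        t = (x - x0) / widths
        return idx, t, widths

    def __call__(self, x, deriv: int = 0):
        """Evaluate the curve (or its first/second derivative) at x.

        Values outside the domain are linearly extrapolated from the
        boundary tangent; the second derivative is zero there.
        """
        x_arr = np.asarray(x)
        scalar = x_arr.ndim == 0
        xf = np.atleast_1d(x_arr)
        idx, t, widths = self._locate(xf)
        # clamp local parameter for extrapolation; handled analytically below
        t_in = np.clip(np.real(t), 0.0, 1.0) + (t - np.real(t))
        out = self._eval_spans(idx, t_in, widths, deriv)

        lo, hi = self.domain
        below = np.real(xf) < lo
        above = np.real(xf) > hi
        if np.any(below) or np.any(above):
            out = out.astype(np.result_type(out, xf))
            for mask, xb in ((below, lo), (above, hi)):
                if not np.any(mask):
                    continue
                y0 = self._boundary(xb, 0)
                d0 = self._boundary(xb, 1)
                if deriv == 0:
                    out[mask] = y0 + d0 * (xf[mask] - xb)
                elif deriv == 1:
                    out[mask] = d0
                else:
                    out[mask] = 0.0
        return out[0] if scalar else out

    def _boundary(self, x: float, deriv: int) -> float:
        idx = 0 if x <= self.breakpoints[0] else self.breakpoints.size - 2
        widths = float(self.breakpoints[idx + 1] - self.breakpoints[idx])
        t = 0.0 if idx == 0 and x <= self.breakpoints[0] else 1.0
        return float(self._eval_spans(np.array([idx]), np.array([t]),
                                      np.array([widths]), deriv)[0])

    def _eval_spans(self, idx, t, widths, deriv):
        if deriv == 0:
            coef = self.control[idx]
            basis = _bernstein_matrix(t, _DEGREE)
            return np.sum(basis * coef, axis=-1)
        if deriv == 1:
            dctrl = np.diff(self.control, axis=1) * _DEGREE
            basis = _bernstein_matrix(t, _DEGREE - 1)
            return np.sum(basis * dctrl[idx], axis=-1) / widths
        if deriv == 2:
            ddctrl = np.diff(self.control, n=2, axis=1) * _DEGREE * (_DEGREE - 1)
            basis = _bernstein_matrix(t, _DEGREE - 2)
            return np.sum(basis * ddctrl[idx], axis=-1) / widths**2
        raise ValueError("deriv must be 0, 1 or 2")

    # -- diagnostics ---------------------------------------------------
    def junction_jumps(self) -> np.ndarray:
        """|value, d1, d2| discontinuities at interior junctions, shape (n-1, 3)."""
        interior = self.breakpoints[1:-1]
        jumps = np.empty((interior.size, 3))
        for d in range(3):
            left = np.array([self._one_sided(x, d, side=-1) for x in interior])
            right = np.array([self._one_sided(x, d, side=+1) for x in interior])
            jumps[:, d] = np.abs(left - right)
        return jumps

    def _one_sided(self, x: float, deriv: int, side: int) -> float:
        j = int(np.searchsorted(self.breakpoints, x))
        idx = j - 1 if side < 0 else j
        idx = int(np.clip(idx, 0, self.breakpoints.size - 2))
        widths = float(self.breakpoints[idx + 1] - self.breakpoints[idx])
        t = 1.0 if side < 0 else 0.0
        return float(self._eval_spans(np.array([idx]), np.array([t]),
                                      np.array([widths]), deriv)[0])

    def sample_csv(self, n: int = 400):
        """(x, y) samples across the domain, for export/plotting."""
        x = np.linspace(*self.domain, n)
        return np.column_stack([x, self(x)])

    # -- constructors --------------------------------------------------
    @staticmethod
    def from_hermite_segments(breakpoints, values, d1, d2) -> "NormalizedCurve":
        """Build spans from value/slope/curvature prescribed at every breakpoint.

        Each span is the unique quintic matching (y, y', y'') at both ends,
        which guarantees C2 continuity by construction.
        """
        bp = np.asarray(breakpoints, dtype=float)
        y = np.asarray(values, dtype=float)
        s = np.asarray(d1, dtype=float)
        c = np.asarray(d2, dtype=float)
        n = bp.size - 1
        ctrl = np.empty((n, 6))
        for i in range(n):
            h = bp[i + 1] - bp[i]
            ctrl[i, 0] = y[i]
            ctrl[i, 1] = y[i] + h * s[i] / 5.0
            ctrl[i, 2] = y[i] + 2.0 * h * s[i] / 5.0 + h * h * c[i] / 20.0
            ctrl[i, 5] = y[i + 1]
            ctrl[i, 4] = y[i + 1] - h * s[i + 1] / 5.0
            ctrl[i, 3] = y[i + 1] - 2.0 * h * s[i + 1] / 5.0 + h * h * c[i + 1] / 20.0
        return NormalizedCurve(bp, ctrl)

    def scaled(self, factor: float) -> "NormalizedCurve":
        """Curve with all ordinates multiplied by ``factor``."""
        return NormalizedCurve(self.breakpoints.copy(), self.control * factor)


def fit_c2_bezier(x, y, n_spans: int = 6, interpolate_ends: bool = True) -> NormalizedCurve:
    """Least-squares fit of a C2 piecewise quintic to samples.

    Parameters
    ----------
    x, y:
        Sample abscissae (strictly increasing, >= 4 points) and ordinates.
    n_spans:
        Number of quintic spans spread uniformly over ``[x[0], x[-1]]``.
    interpolate_ends:
        If true, the first and last samples are interpolated exactly.

    The C2 junction conditions (and optional endpoint interpolation) are
    imposed as hard linear equality constraints; the remaining freedom is
    resolved in the least-squares sense through a null-space reduction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise CurveFitError("need at least 4 samples")
    if np.any(np.diff(x) <= 0):
        raise CurveFitError("sample abscissae must be strictly increasing")
    if y.shape != x.shape:
        raise CurveFitError("x and y must have identical shapes")

    bp = np.linspace(x[0], x[-1], n_spans + 1)
    widths = np.diff(bp)
    n_par = n_spans * 6

    # design matrix: each sample maps to the Bernstein basis of its span
    idx = np.clip(np.searchsorted(bp, x, side="right") - 1, 0, n_spans - 1)
    t = (x - bp[idx]) / widths[idx]
    basis = _bernstein_matrix(np.clip(t, 0.0, 1.0))
    A = np.zeros((x.size, n_par))
    for i in range(x.size):
        A[i, idx[i] * 6:(idx[i] + 1) * 6] = basis[i]

    # equality constraints: C2 at junctions (+ optional end interpolation)
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    for j in range(n_spans - 1):
        hl, hr = widths[j], widths[j + 1]
        r = np.zeros(n_par)
        r[j * 6 + 5] = 1.0
        r[(j + 1) * 6 + 0] = -1.0
        rows.append(r); rhs.append(0.0)
        r = np.zeros(n_par)
        r[j * 6 + 5] = 1.0 / hl
        r[j * 6 + 4] = -1.0 / hl
        r[(j + 1) * 6 + 1] = -1.0 / hr
        r[(j + 1) * 6 + 0] = 1.0 / hr
        rows.append(r); rhs.append(0.0)
        r = np.zeros(n_par)
        r[j * 6 + 5] = 1.0 / hl**2
        r[j * 6 + 4] = -2.0 / hl**2
        r[j * 6 + 3] = 1.0 / hl**2
        r[(j + 1) * 6 + 2] = -1.0 / hr**2
        r[(j + 1) * 6 + 1] = 2.0 / hr**2
        r[(j + 1) * 6 + 0] = -1.0 / hr**2
        rows.append(r); rhs.append(0.0)
    if interpolate_ends:
        r = np.zeros(n_par); r[0] = 1.0
        rows.append(r); rhs.append(float(y[0]))
        r = np.zeros(n_par); r[-1] = 1.0
        rows.append(r); rhs.append(float(y[-1]))

    C = np.array(rows)
    d = np.array(rhs)
    c_part, *_ = np.linalg.lstsq(C, d, rcond=None)
    N = null_space(C)
    z, *_ = np.linalg.lstsq(A @ N, y - A @ c_part, rcond=None)
    coeffs = c_part + N @ z
    return NormalizedCurve(bp, coeffs.reshape(n_spans, 6))
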