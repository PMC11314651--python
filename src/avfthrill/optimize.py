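"""Optimal kernel size from cohort-averaged SNR curves.

The normal and stenosis cohorts each yield a mean SNR_thr(N) curve. Both are
min-max normalized to [0, 1], their residual (normal minus stenosis) is
smoothed with a 6th-order least-squares polynomial, and the kernel size at
which the smoothed residual peaks is taken as N_opt — the kernel that best
separates the two cohorts.

The polynomial is fitted on an abscissa rescaled to [-1, 1]; raw powers of N
up to N^6 with N in the hundreds are numerically hopeless.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import DegenerateInputError
from .snr import SnrCurve

__all__ = [
    "OptResult",
    "cohort_curve",
    "normalize_curve",
    "fit_residual_poly",
    "select_n_opt",
    "optimize_kernel",
]


@dataclass
class OptResult:
    """Residual analysis of normalized cohort SNR curves."""

    n_values: np.ndarray
    curve_normal: np.ndarray
    curve_stenosis: np.ndarray
    residual: np.ndarray
    poly_coeffs: np.ndarray   # 7 coefficients on the [-1, 1]-scaled abscissa
    poly_domain: tuple[float, float]
    r_squared: float
    n_opt: int

    def fitted(self, n: np.ndarray | None = None) -> np.ndarray:
        """Evaluate the smoothing polynomial at kernel sizes ``n``."""
        if n is None:
            n = self.n_values
        p = np.polynomial.Polynomial(self.poly_coeffs, domain=self.poly_domain)
        return p(np.asarray(n, dtype=float))

    def to_json(self, path: str | Path, extra: dict | None = None) -> Path:
        path = Path(path)
        payload = {
            "n_values": self.n_values.tolist(),
            "curve_normal": self.curve_normal.tolist(),
            "curve_stenosis": self.curve_stenosis.tolist(),
            "residual": self.residual.tolist(),
            "poly_coeffs": self.poly_coeffs.tolist(),
            "poly_domain": list(self.poly_domain),
            "r_squared": self.r_squared,
            "n_opt": int(self.n_opt),
        }
        if extra:
            payload.update(extra)
        path.write_text(json.dumps(payload, indent=2))
        return path


def cohort_curve(
    curves: list[SnrCurve], label: str, agg: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-kernel aggregate SNR over recordings with the given cohort label.

    Returns ``(n_values, aggregated snr)``. ``agg`` is ``"mean"`` (default) or
    ``"median"`` for robustness.
    """
    selected = [c for c in curves if c.cohort_label == label]
    if not selected:
        raise ValueError(f"no curves with cohort label {label!r}")
    grid = selected[0].kernel_n
    for c in selected[1:]:
        if not np.array_equal(c.kernel_n, grid):
            raise ValueError("all curves must share the same kernel grid")
    mat = np.vstack([c.snr for c in selected])
    if agg == "mean":
        return grid.copy(), mat.mean(axis=0)
    if agg == "median":
        return grid.copy(), np.median(mat, axis=0)
    raise ValueError(f"unknown aggregation {agg!r}")


def normalize_curve(values: np.ndarray) -> np.ndarray:
    """Min-max scale a curve to [0, 1]; invariant to positive affine maps."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateInputError("cannot normalize a constant curve")
    return (values - lo) / (hi - lo)


def fit_residual_poly(
    n_values: np.ndarray, residual: np.ndarray, order: int = 6
) -> tuple[np.polynomial.Polynomial, float]:
    """Least-squares polynomial smoothing of the residual curve.

    Returns the fitted :class:`numpy.polynomial.Polynomial` (coefficients live
    on the [-1, 1]-mapped domain) and the coefficient of determination
    R^2 = 1 - SS_res / SS_tot. A constant residual is degenerate (SS_tot = 0).
    """
    n_values = np.asarray(n_values, dtype=float)
    residual = np.asarray(residual, dtype=float)
    if n_values.size < order + 1:
        raise ValueError(
            f"need at least {order + 1} points for an order-{order} fit, got {n_values.size}"
        )
    poly = np.polynomial.Polynomial.fit(n_values, residual, deg=order)
    fitted = poly(n_values)
    ss_res = float(((residual - fitted) ** 2).sum())
    ss_tot = float(((residual - residual.mean()) ** 2).sum())
    if ss_tot == 0:
        raise DegenerateInputError("residual curve is constant; R^2 undefined")
    return poly, 1.0 - ss_res / ss_tot


def select_n_opt(n_values: np.ndarray, poly: np.polynomial.Polynomial) -> int:
    """Grid member maximizing the smoothed residual; ties go to smaller N."""
    vals = poly(np.asarray(n_values, dtype=float))
    return int(n_values[int(np.argmax(vals))])


def optimize_kernel(
    curves: list[SnrCurve],
    order: int = 6,
    agg: str = "mean",
    joint_normalization: bool = False,
    normal_label: str = "normal",
    stenosis_label: str = "stenosis",
) -> OptResult:
    """Full kernel optimization from per-recording SNR curves.

    ``joint_normalization`` rescales both cohort curves by the pooled min/max
    instead of per-curve min-max (the default).
    """
    grid, raw_nor = cohort_curve(curves, normal_label, agg=agg)
    _, raw_ste = cohort_curve(curves, stenosis_label, agg=agg)
    if joint_normalization:
        pooled = np.concatenate([raw_nor, raw_ste])
        lo, hi = pooled.min(), pooled.max()
        if hi == lo:
            raise DegenerateInputError("cannot normalize constant curves")
        nor = (raw_nor - lo) / (hi - lo)
        ste = (raw_ste - lo) / (hi - lo)
    else:
        nor = normalize_curve(raw_nor)
        ste = normalize_curve(raw_ste)
    residual = nor - ste
    poly, r2 = fit_residual_poly(grid, residual, order=order)
    n_opt = select_n_opt(grid, poly)
    return OptResult(
        n_values=grid,
        curve_normal=nor,
        curve_stenosis=ste,
        residual=residual,
        poly_coeffs=poly.coef.copy(),
        poly_domain=(float(poly.domain[0]), float(poly.domain[1])),
        r_squared=r2,
        n_opt=n_opt,
    )
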