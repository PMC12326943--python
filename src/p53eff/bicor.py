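"""Biweight midcorrelation (bicor) with Student-t significance.

bicor is a robust correlation that median-centers each vector and
down-weights points far from the median with Tukey biweights:

    u_i = (x_i - med(x)) / (9 * MAD(x)),   MAD unscaled (median of |x - med|)
    w_i = (1 - u_i^2)^2 * I(|u_i| < 1)
    x~_i = (x_i - med(x)) * w_i / sqrt(sum_j [(x_j - med(x)) * w_j]^2)
    bicor(x, y) = sum_i x~_i * y~_i

When MAD is zero for a vector (more than half its values tied) robust
weighting is undefined; that vector falls back to Pearson-style uniform
weights around the mean and the result is flagged.

Significance uses the conventional correlation t-transform,
t = r * sqrt(n - 2) / sqrt(1 - r^2) with n - 2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionMatrix


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (constant input even under the Pearson fallback)."""


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return x, y


def _biweight_standardize(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Weighted, median-centered, norm-standardized vector and fallback flag."""
    med = np.median(x)
    dev = x - med
    mad = np.median(np.abs(dev))
    if mad == 0.0:
        # robust scale degenerate: uniform weights, mean centering
        dev = x - x.mean()
        weighted = dev
        fallback = True
    else:
        u = dev / (9.0 * mad)
        w = (1.0 - u * u) ** 2 * (np.abs(u) < 1.0)
        weighted = dev * w
        fallback = False
    norm = np.sqrt(np.sum(weighted * weighted))
    if norm == 0.0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    return weighted / norm, fallback


def bicor(x, y, return_fallback: bool = False):
    """Biweight midcorrelation of two equal-length vectors (n >= 3).

    Returns a scalar in [-1, 1]; with ``return_fallback=True`` also returns
    whether either vector required the Pearson-style zero-MAD fallback.
    """
    x, y = _validate_pair(x, y)
    xt, fx = _biweight_standardize(x)
    yt, fy = _biweight_standardize(y)
    r = float(np.clip(np.dot(xt, yt), -1.0, 1.0))
    if return_fallback:
        return r, fx or fy
    return r


def bicor_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a correlation of magnitude |r| at sample size n.

    Uses t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 df. |r| = 1 returns the
    smallest positive float rather than dividing by zero.
    """
    n = int(n)
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    r = float(r)
    if abs(r) > 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    tiny = float(np.finfo(float).tiny)
    if abs(r) == 1.0:
        return tiny
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(min(max(p, tiny), 1.0))


def critical_bicor(alpha: float, n: int) -> float:
    """|r| above which the two-sided t-test rejects at level ``alpha``."""
    tcrit = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(tcrit / np.sqrt(n - 2 + tcrit * tcrit))


@dataclass
class CorrelationResult:
    """bicor of a gene pair with sample count and two-sided significance."""

    gene_a: str
    gene_b: str
    bicor: float
    n: int
    p_value: float
    fallback: bool = False


def correlate_anchor_panel(
    matrix: ExpressionMatrix,
    anchor: str,
    panel: Sequence[str],
    groups: Iterable[str] | None = None,
) -> list[CorrelationResult]:
    """bicor of one anchor gene against each available panel gene.

    Samples are restricted to ``groups`` when given (e.g. tumor only).
    Results are sorted by descending bicor; panel genes absent from the
    matrix are reported in a warning.
    """
    if anchor not in matrix.values.index:
        raise ValueError(f"anchor gene {anchor!r} absent from matrix")
    cols = matrix.sample_ids if groups is None else matrix.samples_in(groups)
    if len(cols) < 3:
        raise ValueError(f"need >= 3 samples, got {len(cols)} in groups {groups}")
    missing = [g for g in panel if g not in matrix.values.index]
    if missing:
        warnings.warn(f"panel genes absent from matrix, skipped: {missing}")
    present = [g for g in panel if g in matrix.values.index]
    if not present:
        raise ValueError("no panel gene present in matrix")
    xa = matrix.values.loc[anchor, cols].to_numpy(dtype=float)
    out = []
    for g in present:
        r, fb = bicor(xa, matrix.values.loc[g, cols].to_numpy(dtype=float), return_fallback=True)
        out.append(CorrelationResult(anchor, g, r, len(cols), bicor_pvalue(r, len(cols)), fb))
    out.sort(key=lambda c: c.bicor, reverse=True)
    return out
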