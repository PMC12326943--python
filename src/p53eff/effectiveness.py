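"""Per-sample p53 transcriptional effectiveness from target-gene panels.

The inference assumes nontumor samples carry normally functioning p53. On
those calibration samples each target gene g is related to the regulator by
least squares (default linear in log2 space):

    target_g = a_g + b_g * p53            (optionally + c_g * p53^2)

For every scored sample an expected level is computed for each target from
the sample's own p53 value, and the straight line through the (expected,
measured) cloud across panel genes is fit by ordinary least squares. The
slope of that line summarizes how strongly the sample's p53 targets respond
relative to the nontumor calibration: slopes in [0.9, 1.1] are
``normal_like``, below 0.9 ``impaired``, above 1.1 ``above_range``.
Impaired samples can then be removed and gene-pair correlations recomputed
to quantify how much an apparent correlation loss was driven by them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .bicor import CorrelationResult, bicor, bicor_pvalue
from .io import ExpressionMatrix, GenePanel

logger = logging.getLogger("p53eff")

CLASS_NORMAL = "normal_like"
CLASS_IMPAIRED = "impaired"
CLASS_ABOVE = "above_range"

DEFAULT_LOWER = 0.9
DEFAULT_UPPER = 1.1


@dataclass
class TargetResponseModel:
    """Fitted response of one target gene to the regulator in nontumor samples."""

    target: str
    intercept: float
    slope: float
    residual_sd: float
    r_squared: float
    n_fit: int
    quad: float = 0.0  # quadratic coefficient, 0 for the linear form


@dataclass
class SampleSlope:
    """Measured-vs-expected OLS line for one sample and its class label."""

    sample_id: str
    slope: float
    intercept: float
    n_targets: int
    label: str


@dataclass
class RestorationReport:
    """Gene-pair bicor before and after removing p53-impaired samples."""

    pair: tuple[str, str]
    bicor_all: float
    p_all: float
    bicor_filtered: float
    p_filtered: float
    n_all: int
    n_filtered: int
    n_removed: int


def classify_slope(slope: float, lower: float = DEFAULT_LOWER, upper: float = DEFAULT_UPPER) -> str:
    """Class label for a measured-vs-expected slope; boundaries are normal_like."""
    if slope < lower:
        return CLASS_IMPAIRED
    if slope > upper:
        return CLASS_ABOVE
    return CLASS_NORMAL


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple OLS: returns (intercept, slope)."""
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    sxx = float(np.dot(dx, dx))
    if sxx == 0.0:
        raise ValueError("degenerate predictor: zero variance")
    slope = float(np.dot(dx, y - ym)) / sxx
    return ym - slope * xm, slope


def _fit_response(x: np.ndarray, y: np.ndarray, form: str) -> tuple[float, float, float, float, float]:
    """Fit one target's response; returns (a, b, quad, residual_sd, r_squared)."""
    if form == "linear":
        a, b = _ols_line(x, y)
        c = 0.0
        fitted = a + b * x
        n_par = 2
    elif form == "quadratic":
        coef = np.polyfit(x, y, 2)
        c, b, a = float(coef[0]), float(coef[1]), float(coef[2])
        fitted = a + b * x + c * x * x
        n_par = 3
    else:
        raise ValueError(f"unknown functional form {form!r}")
    resid = y - fitted
    ss_res = float(np.dot(resid, resid))
    dof = len(x) - n_par
    residual_sd = float(np.sqrt(ss_res / dof)) if dof > 0 else 0.0
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return a, b, c, residual_sd, float(np.clip(r2, 0.0, 1.0))


class P53EffectivenessClassifier(BaseEstimator):
    """Classify samples by p53 transcriptional effectiveness.

    scikit-learn style estimator. ``fit`` expects a samples x genes
    DataFrame of log2 expression from calibration (nontumor) samples
    containing the regulator column and the target panel; ``predict``
    labels new samples as ``normal_like`` / ``impaired`` / ``above_range``
    from their measured-vs-expected regression slope.

    Parameters
    ----------
    regulator
        Column name of the regulator gene (p53 analog).
    targets
        Target panel; ``None`` uses every non-regulator column seen at fit.
    lower, upper
        Slope bounds of the normal_like class (inclusive).
    form
        Per-target calibration form, ``"linear"`` (default) or ``"quadratic"``.
    through_origin
        Fit the per-sample measured-vs-expected line without an intercept.
    min_r_squared
        Optional calibration-quality filter; targets whose nontumor fit has
        a lower r^2 are excluded from scoring. Default: no filter.

    Attributes
    ----------
    models_ : list of TargetResponseModel
    targets_ : list of target genes actually modeled
    n_fit_ : number of calibration samples
    """

    def __init__(
        self,
        regulator: str = "TP53",
        targets: Sequence[str] | None = None,
        lower: float = DEFAULT_LOWER,
        upper: float = DEFAULT_UPPER,
        form: str = "linear",
        through_origin: bool = False,
        min_r_squared: float | None = None,
    ):
        self.regulator = regulator
        self.targets = targets
        self.lower = lower
        self.upper = upper
        self.form = form
        self.through_origin = through_origin
        self.min_r_squared = min_r_squared

    # -- helpers ----------------------------------------------------------
    def _check_frame(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes pandas DataFrame with gene-named columns")
        if self.regulator not in X.columns:
            raise ValueError(f"regulator gene {self.regulator!r} absent from input")
        return X

    # -- estimator API ------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "P53EffectivenessClassifier":
        """Calibrate per-target responses on (nontumor) samples in ``X``."""
        if not (self.lower < self.upper):
            raise ValueError(f"need lower < upper, got {self.lower} >= {self.upper}")
        X = self._check_frame(X)
        if len(X) < 3:
            raise ValueError(f"need >= 3 calibration samples, got {len(X)}")
        wanted = [t for t in (self.targets if self.targets is not None else X.columns)
                  if t != self.regulator]
        if not wanted:
            raise ValueError("empty target panel")
        missing = [t for t in wanted if t not in X.columns]
        if missing:
            warnings.warn(f"targets absent from calibration data, skipped: {missing}")
        p53 = X[self.regulator].to_numpy(dtype=float)
        if np.all(p53 == p53[0]):
            raise ValueError(f"regulator {self.regulator!r} is constant in calibration samples")
        min_n = 3 if self.form == "linear" else 4
        models: list[TargetResponseModel] = []
        for t in wanted:
            if t not in X.columns:
                continue
            y_t = X[t].to_numpy(dtype=float)
            ok = np.isfinite(p53) & np.isfinite(y_t)
            if ok.sum() < min_n:
                warnings.warn(f"target {t!r}: insufficient data ({int(ok.sum())} samples), skipped")
                continue
            a, b, c, sd, r2 = _fit_response(p53[ok], y_t[ok], self.form)
            models.append(TargetResponseModel(t, a, b, sd, r2, int(ok.sum()), quad=c))
        if self.min_r_squared is not None:
            dropped = [m.target for m in models if m.r_squared < self.min_r_squared]
            if dropped:
                logger.info("dropping %d low-r^2 targets: %s", len(dropped), dropped)
            models = [m for m in models if m.r_squared >= self.min_r_squared]
        if not models:
            raise ValueError("no target could be calibrated")
        self.models_ = models
        self.targets_ = [m.target for m in models]
        self.n_fit_ = int(len(X))
        return self

    @classmethod
    def from_models(cls, models: Sequence[TargetResponseModel], **params) -> "P53EffectivenessClassifier":
        """Build an already-calibrated classifier from fitted response models."""
        est = cls(**params)
        est.models_ = list(models)
        est.targets_ = [m.target for m in est.models_]
        est.n_fit_ = est.models_[0].n_fit if est.models_ else 0
        return est

    def _require_fitted(self) -> None:
        if not hasattr(self, "models_"):
            raise NotFittedError("estimator is not fitted; call fit() first")

    def sample_slopes(self, X: pd.DataFrame) -> list[SampleSlope]:
        """Measured-vs-expected OLS slope and class for every row of ``X``."""
        self._require_fitted()
        X = self._check_frame(X)
        out = []
        for sample_id, row in X.iterrows():
            p53 = float(row[self.regulator])
            expected = predict_expected(self.models_, p53)
            observed = np.array(
                [float(row[t]) if t in row.index else np.nan for t in self.targets_]
            )
            ok = np.isfinite(observed) & np.isfinite(expected)
            if ok.sum() < 3:
                raise ValueError(f"sample {sample_id!r}: fewer than 3 usable panel genes")
            out.append(
                sample_response_slope(
                    observed[ok],
                    expected[ok],
                    sample_id=str(sample_id),
                    through_origin=self.through_origin,
                    lower=self.lower,
                    upper=self.upper,
                )
            )
        return out

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Per-sample slope values (the quantity the class labels threshold)."""
        return np.array([s.slope for s in self.sample_slopes(X)])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Class label per sample: normal_like / impaired / above_range."""
        return np.array([s.label for s in self.sample_slopes(X)], dtype=object)


# ---------------------------------------------------------------------------
# functional interface (thin wrappers over the estimator)
# ---------------------------------------------------------------------------

def fit_target_responses(
    matrix: ExpressionMatrix,
    panel: GenePanel,
    form: str = "linear",
    calibration_group: str = "nontumor",
) -> list[TargetResponseModel]:
    """Least-squares response of each panel target to the regulator in nontumor samples."""
    cal = matrix.samples_in([calibration_group])
    if len(cal) < 3:
        raise ValueError(f"need >= 3 {calibration_group} samples, got {len(cal)}")
    X = matrix.subset(groups=[calibration_group]).to_samples_by_genes()
    est = P53EffectivenessClassifier(regulator=panel.regulator, targets=panel.targets, form=form)
    est.fit(X)
    return est.models_


def predict_expected(models: Sequence[TargetResponseModel], p53_level: float) -> np.ndarray:
    """Expected log2 level of each modeled target at a given regulator level."""
    if not models:
        raise ValueError("no fitted models")
    lvl = float(p53_level)
    return np.array([m.intercept + m.slope * lvl + m.quad * lvl * lvl for m in models])


def sample_response_slope(
    observed,
    expected,
    sample_id: str = "sample",
    through_origin: bool = False,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
) -> SampleSlope:
    """OLS fit of measured values against expected values across panel genes."""
    observed = np.asarray(observed, dtype=float).ravel()
    expected = np.asarray(expected, dtype=float).ravel()
    if observed.shape != expected.shape:
        raise ValueError(f"sample {sample_id!r}: observed/expected length mismatch")
    if observed.size < 3:
        raise ValueError(f"sample {sample_id!r}: need >= 3 panel genes, got {observed.size}")
    if np.all(expected == expected[0]):
        raise ValueError(f"sample {sample_id!r}: expected vector is degenerate (all identical)")
    if through_origin:
        slope = float(np.dot(expected, observed) / np.dot(expected, expected))
        intercept = 0.0
    else:
        intercept, slope = _ols_line(expected, observed)
    return SampleSlope(sample_id, slope, intercept, int(observed.size), classify_slope(slope, lower, upper))


def classify_samples(
    matrix: ExpressionMatrix,
    panel: GenePanel,
    models: Sequence[TargetResponseModel],
    groups: Iterable[str] = ("tumor",),
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
    through_origin: bool = False,
) -> list[SampleSlope]:
    """Score and classify every sample in the requested groups."""
    samples = matrix.samples_in(groups)
    if not samples:
        raise ValueError(f"no samples in requested groups {list(groups)}")
    est = P53EffectivenessClassifier.from_models(
        models,
        regulator=panel.regulator,
        targets=panel.targets,
        lower=lower,
        upper=upper,
        through_origin=through_origin,
    )
    X = matrix.subset(groups=groups).to_samples_by_genes()
    slopes = est.sample_slopes(X)
    n_imp = sum(s.label == CLASS_IMPAIRED for s in slopes)
    logger.info(
        "classified %d samples: %d impaired (%.1f%%), %d normal_like, %d above_range",
        len(slopes), n_imp, 100.0 * n_imp / len(slopes),
        sum(s.label == CLASS_NORMAL for s in slopes),
        sum(s.label == CLASS_ABOVE for s in slopes),
    )
    return slopes


def impaired_fraction(slopes: Sequence[SampleSlope]) -> float:
    """Fraction of scored samples classified impaired."""
    if not slopes:
        raise ValueError("no slopes")
    return sum(s.label == CLASS_IMPAIRED for s in slopes) / len(slopes)


def filter_impaired(matrix: ExpressionMatrix, slopes: Sequence[SampleSlope]) -> ExpressionMatrix:
    """Remove samples classified impaired; all other samples are retained.

    above_range samples stay: only low-slope (p53-impaired) samples are
    removed before recomputing correlations.
    """
    ids = {s.sample_id for s in slopes}
    absent = ids - set(matrix.sample_ids)
    if absent:
        raise ValueError(f"slope sample ids absent from matrix: {sorted(absent)}")
    drop = {s.sample_id for s in slopes if s.label == CLASS_IMPAIRED}
    keep = [s for s in matrix.sample_ids if s not in drop]
    if not keep:
        raise ValueError("all samples classified impaired; nothing left")
    return ExpressionMatrix(matrix.values[keep].copy(), matrix.group[keep].copy())


def restoration_analysis(
    matrix: ExpressionMatrix,
    slopes: Sequence[SampleSlope],
    pairs: Sequence[tuple[str, str]],
    groups: Iterable[str] = ("tumor",),
) -> list[RestorationReport]:
    """Gene-pair bicor on all samples in ``groups`` vs the impaired-free subset."""
    for a, b in pairs:
        for g in (a, b):
            if g not in matrix.values.index:
                raise ValueError(f"pair gene {g!r} absent from matrix")
    all_samples = matrix.samples_in(groups)
    impaired = {s.sample_id for s in slopes if s.label == CLASS_IMPAIRED}
    kept = [s for s in all_samples if s not in impaired]
    if len(kept) < 3:
        raise ValueError(f"fewer than 3 samples remain after filtering ({len(kept)})")
    reports = []
    for a, b in pairs:
        xa = matrix.values.loc[a, all_samples].to_numpy(dtype=float)
        xb = matrix.values.loc[b, all_samples].to_numpy(dtype=float)
        r_all = bicor(xa, xb)
        xa_f = matrix.values.loc[a, kept].to_numpy(dtype=float)
        xb_f = matrix.values.loc[b, kept].to_numpy(dtype=float)
        r_f = bicor(xa_f, xb_f)
        reports.append(
            RestorationReport(
                pair=(a, b),
                bicor_all=r_all,
                p_all=bicor_pvalue(r_all, len(all_samples)),
                bicor_filtered=r_f,
                p_filtered=bicor_pvalue(r_f, len(kept)),
                n_all=len(all_samples),
                n_filtered=len(kept),
                n_removed=len(all_samples) - len(kept),
            )
        )
    return reports
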