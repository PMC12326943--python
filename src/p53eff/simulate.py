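"""Synthetic expression cohorts with known regulator impairment.

The generator emulates the statistical structure the effectiveness inference
assumes: a regulator gene whose level varies across samples, a panel of
target genes responding linearly (in log2 space) to it, a known fraction of
tumor samples whose whole target-response profile is attenuated by a factor
lambda < 0.9, and two co-regulated anchor genes (ZNF224/p21 analogs) whose
mutual coupling is degraded in impaired samples. Nontumor samples are always
fully functional (lambda = 1).

Generated values for a functional sample:

    target_g   = a_g + b_g * reg + eps
    anchor1    = c0 + c1 * reg + eps
    anchor2    = d0 + d1 * reg + d2 * anchor1 + eps

For an impaired sample with attenuation lambda the modeled target profile is
scaled as target_g = lambda * (a_g + b_g * reg) + eps, so in the noise-free
limit the measured-vs-expected OLS slope of such a sample equals lambda
exactly; anchor2's couplings (d1, d2) are likewise multiplied by lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .effectiveness import CLASS_IMPAIRED, SampleSlope
from .io import ExpressionMatrix


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort (all expression in log2 units)."""

    n_nontumor: int = 40
    n_tumor: int = 100
    n_targets: int = 59
    impaired_fraction: float = 0.2
    attenuation_range: tuple[float, float] = (0.3, 0.7)
    regulator_mean: float = 8.0
    regulator_sd: float = 1.0
    intercept_range: tuple[float, float] = (1.0, 4.0)
    slope_range: tuple[float, float] = (0.4, 1.2)
    noise_sd: float = 0.3
    #: (c0, c1): anchor1 = c0 + c1*regulator + noise
    anchor1_coupling: tuple[float, float] = (2.0, 0.8)
    #: (d0, d1, d2): anchor2 = d0 + d1*regulator + d2*anchor1 + noise
    anchor2_coupling: tuple[float, float, float] = (1.0, 0.4, 0.5)
    #: optional per-target noise sds (length n_targets); None = global noise_sd
    per_gene_noise_sd: tuple[float, ...] | None = None
    regulator_name: str = "TP53"
    anchor_names: tuple[str, str] = ("ZNF224", "CDKN1A")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nontumor < 3:
            raise ValueError(f"need n_nontumor >= 3, got {self.n_nontumor}")
        if self.n_targets < 1 or self.n_tumor < 0:
            raise ValueError("invalid cohort sizes")
        if not (0.0 <= self.impaired_fraction <= 1.0):
            raise ValueError(f"impaired_fraction must be in [0, 1], got {self.impaired_fraction}")
        lo, hi = self.attenuation_range
        if not (0.0 <= lo <= hi < 0.9):
            raise ValueError(f"attenuation_range must satisfy 0 <= lo <= hi < 0.9, got {lo, hi}")
        if self.noise_sd < 0 or self.regulator_sd <= 0:
            raise ValueError("invalid noise/regulator scale")
        if self.per_gene_noise_sd is not None and len(self.per_gene_noise_sd) != self.n_targets:
            raise ValueError("per_gene_noise_sd must have one entry per target")


@dataclass
class SimulationTruth:
    """Ground-truth impairment labels and attenuation factors per sample."""

    is_impaired: pd.Series  # bool, indexed by sample id
    attenuation: pd.Series  # lambda in (0, 0.9) for impaired, 1.0 otherwise
    intercepts: np.ndarray = field(repr=False, default=None)  # a_g per target
    slopes: np.ndarray = field(repr=False, default=None)  # b_g per target

    def lam(self, sample_id: str) -> float:
        return float(self.attenuation[sample_id])


def target_names(n: int) -> list[str]:
    return [f"TGT{i + 1:02d}" for i in range(n)]


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Deterministic (per seed) synthetic cohort and its ground truth.

    The impaired set has exactly ``round(impaired_fraction * n_tumor)``
    members, chosen as the head of one seeded shuffle of the tumor samples.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nontumor + cfg.n_tumor
    nontumor_ids = [f"N{i + 1:03d}" for i in range(cfg.n_nontumor)]
    tumor_ids = [f"T{i + 1:03d}" for i in range(cfg.n_tumor)]
    sample_ids = nontumor_ids + tumor_ids
    group = pd.Series(
        ["nontumor"] * cfg.n_nontumor + ["tumor"] * cfg.n_tumor, index=sample_ids, dtype=object
    )

    reg = rng.normal(cfg.regulator_mean, cfg.regulator_sd, size=n)
    a = rng.uniform(*cfg.intercept_range, size=cfg.n_targets)
    b = rng.uniform(*cfg.slope_range, size=cfg.n_targets)

    n_impaired = int(round(cfg.impaired_fraction * cfg.n_tumor))
    order = rng.permutation(cfg.n_tumor)
    impaired_pos = set(order[:n_impaired].tolist())
    lam = np.ones(n)
    lo, hi = cfg.attenuation_range
    draws = rng.uniform(lo, hi, size=n_impaired)
    for k, pos in enumerate(sorted(impaired_pos)):
        lam[cfg.n_nontumor + pos] = draws[k]

    noise_sd = (
        np.asarray(cfg.per_gene_noise_sd, dtype=float)[:, None]
        if cfg.per_gene_noise_sd is not None
        else cfg.noise_sd
    )
    # impairment scales the whole modeled profile: noise-free observed equals
    # lambda * expected, so the recovered slope is the generating lambda
    clean = a[:, None] + b[:, None] * reg[None, :]
    targets = lam[None, :] * clean + rng.normal(0.0, 1.0, size=(cfg.n_targets, n)) * noise_sd

    c0, c1 = cfg.anchor1_coupling
    d0, d1, d2 = cfg.anchor2_coupling
    anchor1 = c0 + c1 * reg + rng.normal(0.0, cfg.noise_sd, size=n)
    anchor2 = d0 + lam * (d1 * reg + d2 * anchor1) + rng.normal(0.0, cfg.noise_sd, size=n)

    rows = [cfg.regulator_name, cfg.anchor_names[0], cfg.anchor_names[1]]
    rows += target_names(cfg.n_targets)
    values = pd.DataFrame(
        np.vstack([reg, anchor1, anchor2, targets]), index=rows, columns=sample_ids
    )
    matrix = ExpressionMatrix(values, group)
    truth = SimulationTruth(
        is_impaired=pd.Series(lam < 1.0, index=sample_ids),
        attenuation=pd.Series(lam, index=sample_ids),
        intercepts=a,
        slopes=b,
    )
    return matrix, truth


def write_truth_tsv(truth: SimulationTruth, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": truth.is_impaired.index,
            "is_impaired": truth.is_impaired.to_numpy().astype(int),
            "lambda": truth.attenuation.to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def recovery_metrics(truth: SimulationTruth, slopes: Sequence[SampleSlope]) -> dict[str, float]:
    """Confusion-matrix rates of impaired detection plus slope error vs lambda.

    ``impaired`` is the positive class. ``slope_mae_vs_lambda`` is the mean
    absolute difference between each scored sample's recovered slope and its
    generating attenuation factor (1.0 for functional samples).
    """
    ids = [s.sample_id for s in slopes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in slopes")
    missing = set(ids) - set(truth.is_impaired.index)
    if missing:
        raise ValueError(f"slope sample ids not in truth: {sorted(missing)}")
    pred = np.array([s.label == CLASS_IMPAIRED for s in slopes])
    true = truth.is_impaired[ids].to_numpy()
    tp = int(np.sum(pred & true))
    tn = int(np.sum(~pred & ~true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    accuracy = (tp + tn) / len(ids)
    lam = truth.attenuation[ids].to_numpy()
    mae = float(np.mean(np.abs(np.array([s.slope for s in slopes]) - lam)))
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "accuracy": accuracy,
        "slope_mae_vs_lambda": mae,
    }


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
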