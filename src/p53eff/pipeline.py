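"""End-to-end run: ingest -> calibrate/classify -> filter -> correlate -> report.

Outputs are flat, diff-able TSVs (each prefixed with a one-line comment
naming the log2 scale and the config hash) plus a JSON manifest with the
config echo and content hashes. Two runs with the same config and inputs
produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import effectiveness as eff
from .bicor import correlate_anchor_panel
from .io import (
    ExpressionMatrix,
    GenePanel,
    default_panel,
    load_gene_list,
    read_expression_tsv,
    read_group_tsv,
    read_series_matrix,
    write_expression_tsv,
)
from .simulate import SimulationConfig, simulate_dataset, write_truth_tsv

logger = logging.getLogger("p53eff")


class PipelineError(RuntimeError):
    """Stage failure with the stage name and context preserved."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: str = "p53eff_run"
    seed: int = 0
    # exactly one of `input` / `simulate` drives the matrix
    input: dict[str, Any] | None = None  # path, format(tsv|series-matrix), groups/group_rules...
    simulate: dict[str, Any] | None = None  # SimulationConfig fields
    regulator: str = "TP53"
    panel: Sequence[str] | str | None = None  # gene list, path to list, or None = shipped panel
    anchor: str = "ZNF224"
    pairs: Sequence[Sequence[str]] = (("ZNF224", "CDKN1A"), ("TP53", "CDKN1A"))
    lower: float = 0.9
    upper: float = 1.1
    through_origin: bool = False
    tumor_only: bool = True  # correlations on tumor samples only
    nontumor_group: str = "nontumor"
    form: str = "linear"
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ValueError(f"thresholds must satisfy lower < upper, got {self.lower}, {self.upper}")
        if (self.input is None) == (self.simulate is None):
            raise ValueError("exactly one of 'input' or 'simulate' must be configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["pairs"] = [list(p) for p in self.pairs]
        return d


def _config_hash(config: RunConfig) -> str:
    # hash only analysis-relevant settings, not output location or verbosity,
    # so identical analyses written to different directories hash identically
    d = config.to_dict()
    d.pop("out_dir", None)
    d.pop("verbosity", None)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scale=log2\tconfig_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _resolve_panel(config: RunConfig) -> GenePanel:
    if config.panel is None:
        base = default_panel(regulator=config.regulator)
        targets = base.targets
    elif isinstance(config.panel, (str, Path)):
        targets = tuple(load_gene_list(config.panel))
    else:
        targets = tuple(config.panel)
    targets = tuple(t for t in targets if t != config.regulator)
    anchors = (config.anchor,) + tuple({g for p in config.pairs for g in p} - {config.anchor})
    return GenePanel(regulator=config.regulator, targets=targets, anchors=anchors)


def _ingest(config: RunConfig, out: Path) -> ExpressionMatrix:
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim = SimulationConfig(**sim_kwargs)
        matrix, truth = simulate_dataset(sim)
        write_expression_tsv(matrix, out / "matrix.tsv", out / "samples.tsv")
        write_truth_tsv(truth, out / "truth.tsv")
        return matrix
    spec = dict(config.input)
    fmt = spec.get("format", "tsv")
    path = spec["path"]
    if fmt == "tsv":
        groups = spec.get("groups")
        if isinstance(groups, (str, Path)):
            groups = read_group_tsv(groups)
        return read_expression_tsv(path, group_spec=groups, log2_transform=spec.get("log2_transform", False))
    if fmt == "series-matrix":
        return read_series_matrix(
            path,
            group_field=spec.get("group_field", "title"),
            group_rules=spec.get("group_rules"),
            annotation=spec.get("annotation"),
            log2_transform=spec.get("log2_transform", False),
        )
    raise ValueError(f"unknown input format {fmt!r}")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the run summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    try:
        return _run(config, out, chash)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path, chash: str) -> dict[str, Any]:
    corr_groups = ("tumor",) if config.tumor_only else None

    try:
        matrix = _ingest(config, out)
    except Exception as exc:
        raise PipelineError("ingest", str(exc)) from exc
    logger.info("ingest: %d genes x %d samples (%d nontumor, %d tumor)",
                matrix.n_genes, matrix.n_samples,
                len(matrix.samples_in(["nontumor"])), len(matrix.samples_in(["tumor"])))

    panel = _resolve_panel(config)
    try:
        models = eff.fit_target_responses(
            matrix, panel, form=config.form, calibration_group=config.nontumor_group
        )
        slopes = eff.classify_samples(
            matrix, panel, models,
            groups=("tumor",), lower=config.lower, upper=config.upper,
            through_origin=config.through_origin,
        )
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    models_df = pd.DataFrame(
        [
            {"target": m.target, "intercept": m.intercept, "slope": m.slope,
             "residual_sd": m.residual_sd, "r_squared": m.r_squared, "n_fit": m.n_fit}
            for m in models
        ]
    )
    slopes_df = pd.DataFrame(
        [
            {"sample_id": s.sample_id, "slope": s.slope, "intercept": s.intercept,
             "n_targets": s.n_targets, "class": s.label}
            for s in slopes
        ]
    )
    _write_table(models_df, out / "models.tsv", chash)
    _write_table(slopes_df, out / "slopes.tsv", chash)
    frac_impaired = eff.impaired_fraction(slopes)

    try:
        filtered = eff.filter_impaired(matrix, slopes)
        partners = [g for pr in config.pairs for g in pr if g != config.anchor]
        partners = list(dict.fromkeys(partners))
        corr_all = correlate_anchor_panel(matrix, config.anchor, partners, groups=corr_groups)
        corr_flt = correlate_anchor_panel(filtered, config.anchor, partners, groups=corr_groups)
        reports = eff.restoration_analysis(
            matrix, slopes, [tuple(p) for p in config.pairs],
            groups=corr_groups if corr_groups else ("nontumor", "tumor", "unknown"),
        )
    except Exception as exc:
        raise PipelineError("correlate", str(exc)) from exc

    def corr_df(results):
        return pd.DataFrame(
            [
                {"gene_a": c.gene_a, "gene_b": c.gene_b, "bicor": c.bicor,
                 "n": c.n, "p_value": c.p_value, "fallback": int(c.fallback)}
                for c in results
            ]
        )

    _write_table(corr_df(corr_all), out / "correlations_all.tsv", chash)
    _write_table(corr_df(corr_flt), out / "correlations_filtered.tsv", chash)
    rest_df = pd.DataFrame(
        [
            {"anchor": r.pair[0], "partner": r.pair[1],
             "bicor_all": r.bicor_all, "p_all": r.p_all, "n_all": r.n_all,
             "bicor_filtered": r.bicor_filtered, "p_filtered": r.p_filtered,
             "n_filtered": r.n_filtered, "n_removed": r.n_removed}
            for r in reports
        ]
    )
    _write_table(rest_df, out / "restoration.tsv", chash)

    summary = {
        "config_hash": chash,
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "n_models": len(models),
        "n_scored": len(slopes),
        "impaired_fraction": frac_impaired,
        "restoration": [
            {"pair": list(r.pair), "bicor_all": r.bicor_all, "bicor_filtered": r.bicor_filtered}
            for r in reports
        ],
    }
    lines = [
        f"config_hash: {chash}",
        f"samples scored (tumor): {len(slopes)}",
        f"impaired fraction: {frac_impaired:.4f}",
        "pair\tbicor_all\tbicor_filtered",
    ]
    for r in reports:
        lines.append(f"{r.pair[0]}/{r.pair[1]}\t{r.bicor_all:.4f}\t{r.bicor_filtered:.4f}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.tsv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("impaired fraction %.4f over %d tumor samples", frac_impaired, len(slopes))
    return summary
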