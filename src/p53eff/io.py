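"""Reading, validating and reshaping expression matrices.

The pipeline consumes already-normalized, log2-scale expression (e.g. RMA
output) as genes x samples tables, with each sample labeled ``nontumor``,
``tumor`` or ``unknown``. Two on-disk formats are supported: plain TSV
(first column gene identifiers, header row sample identifiers) and the GEO
series-matrix flat-text convention (metadata lines prefixed with ``!``, an
expression block between table-begin/table-end markers).
"""

from __future__ import annotations

import csv
import io as _io
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("p53eff")

GROUPS = ("nontumor", "tumor", "unknown")

#: string tokens treated as missing values in tabular input
_NA_TOKENS = frozenset({"", "na", "nan", "null", "n/a", "none"})


class ExpressionIOError(ValueError):
    """Malformed or inconsistent expression input."""


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen:
            dups.append(it)
        seen.add(it)
    if dups:
        raise ExpressionIOError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Validated log2 expression values, genes x samples, with group labels.

    Parameters
    ----------
    values
        DataFrame of finite floats; index = gene symbols, columns = sample ids.
    group
        Series mapping each sample id to one of ``nontumor``/``tumor``/``unknown``.
    """

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene_ids")
        _check_unique(list(self.values.columns), "sample_ids")
        self.values = self.values.astype(float)
        try:
            self.group = self.group.reindex(self.values.columns)
        except Exception as exc:  # pragma: no cover - defensive
            raise ExpressionIOError(f"group labels do not align with samples: {exc}")
        if self.group.isna().any():
            missing = list(self.group.index[self.group.isna()])
            raise ExpressionIOError(f"samples without group label: {missing}")
        bad = sorted(set(self.group) - set(GROUPS))
        if bad:
            raise ExpressionIOError(f"invalid group labels {bad}; allowed: {GROUPS}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ExpressionIOError(
                f"non-finite value for gene {self.values.index[r]!r} "
                f"in sample {self.values.columns[c]!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, groups: Iterable[str]) -> list[str]:
        groups = set(groups)
        return [s for s in self.sample_ids if self.group[s] in groups]

    def to_samples_by_genes(self) -> pd.DataFrame:
        """Samples-as-rows view used by the scikit-learn style estimator."""
        return self.values.T.copy()

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.group.copy())

    # -- subsetting ------------------------------------------------------
    def subset(
        self,
        genes: Sequence[str] | None = None,
        groups: Iterable[str] | None = None,
        tolerate_missing: bool = False,
    ) -> "ExpressionMatrix":
        """Row/column subset preserving the requested order.

        Missing genes raise unless ``tolerate_missing``, in which case they
        are reported in a warning and the remainder is returned. An empty
        result is always an error.
        """
        vals = self.values
        if genes is not None:
            present = [g for g in genes if g in vals.index]
            absent = [g for g in genes if g not in vals.index]
            if absent and not tolerate_missing:
                raise ExpressionIOError(f"genes absent from matrix: {absent}")
            if absent:
                warnings.warn(f"genes absent from matrix, skipped: {absent}")
            if not present:
                raise ExpressionIOError("subset is empty: no requested gene present")
            vals = vals.loc[present]
        cols = self.sample_ids if groups is None else self.samples_in(groups)
        if not cols:
            raise ExpressionIOError(f"subset is empty: no sample in groups {list(groups)}")
        return ExpressionMatrix(vals[cols].copy(), self.group[cols].copy())


@dataclass
class GenePanel:
    """A regulator, its target-gene panel and anchor genes for correlation."""

    regulator: str = "TP53"
    targets: tuple[str, ...] = ()
    anchors: tuple[str, ...] = ("ZNF224", "CDKN1A")

    def __post_init__(self) -> None:
        self.targets = tuple(self.targets)
        self.anchors = tuple(self.anchors)
        if not self.targets:
            raise ValueError("target panel must be non-empty")
        _check_unique(self.targets, "panel targets")
        if self.regulator in self.targets:
            raise ValueError(f"regulator {self.regulator!r} must not appear in targets")


def load_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out


def default_panel(regulator: str = "TP53", anchors: Sequence[str] = ("ZNF224", "CDKN1A")) -> GenePanel:
    """The shipped 59-gene panel of canonical p53 transcriptional targets."""
    text = resources.files("p53eff.data").joinpath("p53_targets.txt").read_text()
    targets = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return GenePanel(regulator=regulator, targets=tuple(targets), anchors=tuple(anchors))


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _parse_numeric(df: pd.DataFrame, source: str) -> pd.DataFrame:
    """String frame -> float frame; NA tokens -> NaN; anything else is an error."""
    out = {}
    for col in df.columns:
        s = df[col].astype(str).str.strip()
        is_na = s.str.lower().isin(_NA_TOKENS)
        num = pd.to_numeric(s.mask(is_na), errors="coerce")
        bad = num.isna() & ~is_na
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ExpressionIOError(
                f"{source}: non-numeric value {s.iloc[i]!r} for gene "
                f"{df.index[i]!r} in sample {col!r}"
            )
        out[col] = num
    return pd.DataFrame(out, index=df.index)


def _collapse_rows(values: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """Keep, per gene, the row with the highest mean across samples.

    Ties keep the earlier row (file order). Output genes follow first
    appearance order.
    """
    means = values.mean(axis=1).to_numpy()
    best: dict[str, int] = {}
    for i, g in enumerate(genes):
        if g not in best or means[i] > means[best[g]]:
            best[g] = i
    out = values.iloc[list(best.values())].copy()
    out.index = pd.Index(best.keys(), name=values.index.name)
    return out


def collapse_probes(values: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probes x samples frame to genes x samples.

    Unmapped probes are dropped. For genes measured by several probes the
    probe with the highest mean expression across all samples is retained
    (deterministic; ties broken by file order).
    """
    keep = [p for p in values.index if p in probe_map]
    if not keep:
        raise ExpressionIOError("no probe in the matrix is covered by the probe->gene map")
    mapped = values.loc[keep]
    return _collapse_rows(mapped, [probe_map[p] for p in keep])


def _impute_missing(
    values: pd.DataFrame, group: pd.Series, max_missing: float = 0.2
) -> pd.DataFrame:
    """Per-gene, within-group median imputation.

    Genes with >= ``max_missing`` fraction of missing cells are dropped with
    a warning; remaining NAs are filled by the gene's median within the
    sample's group, falling back to the gene's overall median.
    """
    na_frac = values.isna().mean(axis=1)
    drop = na_frac.index[(na_frac >= max_missing) & (na_frac > 0)]
    if len(drop):
        warnings.warn(
            f"dropping {len(drop)} gene(s) with >= {max_missing:.0%} missing values: "
            f"{list(drop[:10])}"
        )
        values = values.drop(index=drop)
    if not values.isna().any().any():
        return values
    values = values.copy()
    for g in set(group):
        cols = [s for s in values.columns if group[s] == g]
        if not cols:
            continue
        block = values[cols]
        values[cols] = block.T.fillna(block.median(axis=1)).T
    # groups that were entirely missing for a gene fall back to overall median
    if values.isna().any().any():
        values = values.T.fillna(values.median(axis=1)).T
    return values


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_tsv(
    path: str | Path,
    group_spec: Mapping[str, str] | None = None,
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    First column holds gene identifiers, the header row sample identifiers.
    Leading ``#`` comment lines are skipped. Samples absent from
    ``group_spec`` are labeled ``unknown``; duplicated gene rows are
    collapsed by the highest-mean rule with a warning.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
    if not lines or "\t" not in lines[0]:
        raise ExpressionIOError(f"{path}: malformed header (expected tab-delimited sample ids)")
    header = lines[0].split("\t")
    _check_unique(header[1:], f"sample_ids in {path}")
    df = pd.read_csv(
        _io.StringIO("\n".join(lines)),
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    values = _parse_numeric(df, str(path))
    if values.index.has_duplicates:
        dups = sorted(set(values.index[values.index.duplicated()]))
        warnings.warn(f"{path}: duplicate gene rows collapsed by highest mean: {dups}")
        values = _collapse_rows(values, list(values.index))
    if log2_transform:
        if (values < 0).any().any():
            raise ExpressionIOError(f"{path}: negative values cannot be log2(x+1) transformed")
        values = np.log2(values + 1.0)
    group_spec = dict(group_spec or {})
    group = pd.Series(
        [group_spec.get(s, "unknown") for s in values.columns],
        index=values.columns,
        dtype=object,
    )
    values = _impute_missing(values, group)
    return ExpressionMatrix(values, group)


def write_expression_tsv(
    matrix: ExpressionMatrix,
    path: str | Path,
    annotation_path: str | Path | None = None,
) -> None:
    """Write the matrix as plain TSV plus an optional sample-annotation TSV."""
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if annotation_path is not None:
        ann = pd.DataFrame({"sample_id": matrix.sample_ids, "group": matrix.group.to_numpy()})
        ann.to_csv(annotation_path, sep="\t", index=False)


def read_group_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) annotation TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ExpressionIOError(f"{path}: expected columns sample_id, group")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        token = token[1:-1]
    return token


def read_series_matrix(
    path: str | Path,
    group_field: str = "title",
    group_rules: Mapping[str, str] | None = None,
    annotation: Mapping[str, str] | str | Path | None = None,
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Read a GEO series-matrix text file.

    Parameters
    ----------
    group_field
        Sample metadata key used for group assignment, matched against the
        ``!Sample_<key>`` lines (e.g. ``title``, ``source_name_ch1``).
        Repeated keys (characteristics lines) are concatenated with ``"; "``.
    group_rules
        Ordered mapping of case-insensitive substrings to group labels;
        the first matching rule wins, unmatched samples become ``unknown``.
    annotation
        Optional probe -> gene-symbol map (mapping, or path to a TSV whose
        first two columns are probe id and symbol). When given, probes are
        collapsed to gene symbols; otherwise probe ids are kept as gene_ids.
    """
    path = Path(path)
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = saw_begin = saw_end = False
    for line in path.read_text().splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table, saw_begin = True, True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table, saw_end = False, True
            continue
        if in_table:
            table_lines.append(line)
        elif line.startswith("!Sample_"):
            key = line.split("\t", 1)[0][len("!Sample_"):]
            vals = [_unquote(v) for v in line.split("\t")[1:]]
            if key in meta:
                meta[key] = [f"{a}; {b}" for a, b in zip(meta[key], vals)]
            else:
                meta[key] = vals
    if not (saw_begin and saw_end) or not table_lines:
        raise ExpressionIOError(f"{path}: missing series-matrix table markers")

    df = pd.read_csv(
        _io.StringIO("\n".join(table_lines)),
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    df.index = [_unquote(str(i)) for i in df.index]
    df.columns = [_unquote(str(c)) for c in df.columns]
    values = _parse_numeric(df, str(path))

    if annotation is not None:
        if not isinstance(annotation, Mapping):
            ann = pd.read_csv(annotation, sep="\t", dtype=str, comment="#")
            annotation = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
        values = collapse_probes(values, annotation)
    elif values.index.has_duplicates:
        values = _collapse_rows(values, list(values.index))
    if log2_transform:
        values = np.log2(values + 1.0)

    field_vals = meta.get(group_field) or meta.get(f"{group_field}_ch1")
    labels = {}
    rules = dict(group_rules or {})
    matched_any = False
    for i, sample in enumerate(values.columns):
        text = field_vals[i].lower() if field_vals and i < len(field_vals) else ""
        label = "unknown"
        for substr, grp in rules.items():
            if substr.lower() in text:
                label, matched_any = grp, True
                break
        labels[sample] = label
    if rules and not matched_any:
        warnings.warn(f"{path}: no sample matches any group rule; all labeled unknown")
    group = pd.Series([labels[s] for s in values.columns], index=values.columns, dtype=object)
    values = _impute_missing(values, group)
    return ExpressionMatrix(values, group)


def subset(
    matrix: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    groups: Iterable[str] | None = None,
    tolerate_missing: bool = False,
) -> ExpressionMatrix:
    """Functional alias for :meth:`ExpressionMatrix.subset`."""
    return matrix.subset(genes=genes, groups=groups, tolerate_missing=tolerate_missing)
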