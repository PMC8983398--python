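"""Cell-level QC filtering, composition tables and group statistics.

The QC filter reproduces the conventional Seurat-style cell filter with
strict inequalities: a cell is retained iff
``min_features < n_features < max_features`` and ``percent_mt < max_percent_mt``
(defaults 200 / 4,000 / 8).

Group comparisons use a two-sided Welch (unequal-variance) t test on
per-sample proportions, and a two-sided Wilcoxon rank-sum test on per-cell
log-normalized expression; multiple testing is corrected with
Benjamini-Hochberg across the tested family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError, InsufficientSeriesError, LookupFailure
from .vocab import DETAILED_TYPES, MAJOR_TYPES, major_type

# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int
    n_retained: int
    n_low_features: int
    n_high_features: int
    n_high_mt: int
    thresholds: dict

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed": {
                "low_features": self.n_low_features,
                "high_features": self.n_high_features,
                "high_percent_mt": self.n_high_mt,
            },
            "thresholds": self.thresholds,
        }


def filter_cells(
    cells: pd.DataFrame,
    min_features: int = 200,
    max_features: int = 4000,
    max_percent_mt: float = 8.0,
) -> tuple[pd.DataFrame, QCReport]:
    """Retain cells with ``min_features < n_features < max_features`` and
    ``percent_mt < max_percent_mt`` (all strict).

    Returns the retained cells and a report counting removals per criterion
    (a cell failing several criteria is counted under each).
    """
    for col in ("n_features", "percent_mt"):
        if col not in cells.columns:
            raise DataError(f"QC field missing from cell table: {col!r}")
    low = cells["n_features"] <= min_features
    high = cells["n_features"] >= max_features
    mt = cells["percent_mt"] >= max_percent_mt
    keep = ~(low | high | mt)
    report = QCReport(
        n_input=len(cells),
        n_retained=int(keep.sum()),
        n_low_features=int(low.sum()),
        n_high_features=int(high.sum()),
        n_high_mt=int(mt.sum()),
        thresholds={"min_features": min_features, "max_features": max_features,
                    "max_percent_mt": max_percent_mt},
    )
    return cells[keep].copy(), report


# ---------------------------------------------------------------------------
# Composition tables
# ---------------------------------------------------------------------------

def compute_proportions(
    cells: pd.DataFrame,
    level: str = "major",
    sample_col: str = "sample_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample cell-type proportion table (and its raw-count companion).

    ``level`` is ``"major"`` or ``"detailed"``; zero-count types are present
    as 0 so every row covers the full vocabulary and sums to 1.
    """
    if level == "major":
        types = cells["cell_type"].map(major_type)
        columns = list(MAJOR_TYPES)
    elif level == "detailed":
        types = cells["cell_type"]
        columns = list(DETAILED_TYPES)
    else:
        raise ConfigurationError(f"level: unknown composition level {level!r}")
    counts = (
        pd.crosstab(cells[sample_col], types)
        .reindex(columns=columns, fill_value=0)
    )
    counts.columns.name = None
    counts.index.name = sample_col
    props = counts.div(counts.sum(axis=1), axis=0)
    return props, counts


# ---------------------------------------------------------------------------
# Group comparison machinery
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    feature: str
    statistic: float
    p_value: float
    p_adjusted: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    test: str


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    # identical constant groups: no difference by construction
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _bh_adjust(results: list[GroupComparisonResult]) -> list[GroupComparisonResult]:
    if not results:
        return results
    raw = np.array([r.p_value for r in results])
    adjusted = multipletests(raw, method="fdr_bh")[1]
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
    return results


def compare_proportion_tables(
    props_a: pd.DataFrame,
    props_b: pd.DataFrame,
    paired: bool = False,
) -> pd.DataFrame:
    """Welch t test per cell type between two proportion tables (rows = samples),
    BH-adjusted across cell types.  ``paired=True`` runs a paired t test on
    row-aligned tables instead."""
    if len(props_a) < 2 or len(props_b) < 2:
        raise InsufficientSeriesError(
            f"need >=2 samples per group (got {len(props_a)} and {len(props_b)})")
    shared = [c for c in props_a.columns if c in props_b.columns]
    if not shared:
        raise DataError("no shared cell types between the two groups")
    results: list[GroupComparisonResult] = []
    for ctype in shared:
        a = props_a[ctype].to_numpy(dtype=float)
        b = props_b[ctype].to_numpy(dtype=float)
        if paired:
            if len(a) != len(b):
                raise DataError("paired comparison requires equal group sizes")
            diff = a - b
            if diff.var(ddof=1) == 0 and diff.mean() == 0:
                t, p = 0.0, 1.0
            else:
                t, p = (float(x) for x in stats.ttest_rel(a, b))
        else:
            t, p = _welch(a, b)
        results.append(GroupComparisonResult(
            feature=ctype, statistic=t, p_value=p, p_adjusted=np.nan,
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            n_a=len(a), n_b=len(b),
            test="paired t" if paired else "Welch t"))
    _bh_adjust(results)
    return pd.DataFrame([vars(r) for r in results])


def compare_proportions(
    cells_a: pd.DataFrame,
    cells_b: pd.DataFrame,
    level: str = "major",
    paired: bool = False,
) -> pd.DataFrame:
    """Per-cell-type comparison between two groups of samples (cell tables)."""
    props_a, _ = compute_proportions(cells_a, level=level)
    props_b, _ = compute_proportions(cells_b, level=level)
    return compare_proportion_tables(props_a, props_b, paired=paired)


# ---------------------------------------------------------------------------
# Expression helpers
# ---------------------------------------------------------------------------

def lognormalize(counts: pd.DataFrame, gene_cols: list[str],
                 scale: float = 1e4) -> pd.DataFrame:
    """Scale each cell's counts to ``scale`` total over the panel, then log1p.

    The conventional per-cell normalization; stated explicitly because the
    marker panel is small (totals are panel totals, not transcriptome totals).
    """
    out = counts.copy()
    totals = out[gene_cols].sum(axis=1).replace(0, np.nan)
    out[gene_cols] = np.log1p(out[gene_cols].div(totals, axis=0) * scale).fillna(0.0)
    return out


def compare_marker_expression(
    expr: pd.DataFrame,
    group_labels: pd.Series,
    gene: str,
    gene_cols: list[str] | None = None,
    min_cells: int = 3,
    normalized: bool = False,
) -> GroupComparisonResult:
    """Two-sided Wilcoxon rank-sum between two cell groups for one gene.

    ``expr`` holds one row per cell; ``group_labels`` (aligned on the index)
    assigns each cell to one of exactly two groups.  Expression is
    log-normalized per cell unless ``normalized`` is set.  BH adjustment is
    applied by the caller when several genes/groups form a family (see
    :func:`compare_marker_panel`).
    """
    if gene not in expr.columns:
        raise LookupFailure(f"gene {gene!r} not in the expression panel")
    groups = [g for g in pd.unique(group_labels.dropna())]
    if len(groups) != 2:
        raise DataError(f"expected exactly 2 groups, got {groups}")
    if gene_cols is None:
        gene_cols = [c for c in expr.columns
                     if c not in ("sample_id", "barcode")
                     and pd.api.types.is_numeric_dtype(expr[c])]
    data = expr if normalized else lognormalize(expr, gene_cols)
    a = data.loc[group_labels == groups[0], gene].to_numpy(dtype=float)
    b = data.loc[group_labels == groups[1], gene].to_numpy(dtype=float)
    if len(a) < min_cells or len(b) < min_cells:
        raise DataError(
            f"need >= {min_cells} cells per group (got {len(a)}, {len(b)})")
    stat, p = stats.ranksums(a, b)
    return GroupComparisonResult(
        feature=gene, statistic=float(stat), p_value=float(p),
        p_adjusted=float(p), mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=len(a), n_b=len(b), test="Wilcoxon rank-sum")


def compare_marker_panel(
    expr: pd.DataFrame,
    group_labels: pd.Series,
    genes: list[str],
    **kwargs,
) -> pd.DataFrame:
    """Rank-sum test per gene with BH adjustment across the gene family."""
    results = [compare_marker_expression(expr, group_labels, g, **kwargs)
               for g in genes]
    _bh_adjust(results)
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# Fresh-vs-frozen concordance
# ---------------------------------------------------------------------------

def fresh_frozen_concordance(
    expr_fresh: pd.DataFrame,
    expr_frozen: pd.DataFrame,
    cell_types_fresh: pd.Series,
    cell_types_frozen: pd.Series,
    r_threshold: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-gene concordance between matched fresh and frozen samples.

    For each condition, per cell type, genes are summarized as the mean
    log-normalized expression (pseudobulk).  Each gene's concordance is the
    Pearson correlation of its pseudobulk profile across cell types; each
    cell type's overall concordance is the Pearson correlation across genes.
    Genes with r below ``r_threshold`` (or with an undefined r from a
    degenerate profile that differs between conditions) are listed as
    low-concordance.
    """
    gene_cols = [c for c in expr_fresh.columns
                 if c not in ("sample_id", "barcode")]
    shared = [g for g in gene_cols if g in expr_frozen.columns]
    if not shared:
        raise DataError("no shared genes between fresh and frozen matrices")

    def pseudobulk(expr: pd.DataFrame, types: pd.Series) -> pd.DataFrame:
        norm = lognormalize(expr, shared)
        return norm[shared].groupby(types.to_numpy()).mean()

    pb_fresh = pseudobulk(expr_fresh, cell_types_fresh)
    pb_frozen = pseudobulk(expr_frozen, cell_types_frozen)
    types = sorted(set(pb_fresh.index) & set(pb_frozen.index))
    if not types:
        raise DataError("no shared cell types between conditions")
    pb_fresh, pb_frozen = pb_fresh.loc[types], pb_frozen.loc[types]

    gene_rows, low = [], []
    for g in shared:
        x, y = pb_fresh[g].to_numpy(), pb_frozen[g].to_numpy()
        if np.allclose(x, y):
            r = 1.0
        elif x.std() == 0 or y.std() == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(x, y)[0])
        gene_rows.append((g, r, len(types)))
        if np.isnan(r) or r < r_threshold:
            low.append(g)
    gene_table = pd.DataFrame(gene_rows, columns=["gene", "pearson_r", "n_cell_types"])

    type_rows = []
    for t in types:
        x, y = pb_fresh.loc[t].to_numpy(), pb_frozen.loc[t].to_numpy()
        if np.allclose(x, y):
            r = 1.0
        elif x.std() == 0 or y.std() == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(x, y)[0])
        type_rows.append((t, r, len(shared)))
    type_table = pd.DataFrame(type_rows, columns=["cell_type", "pearson_r", "n_genes"])
    return gene_table, type_table, low


# ---------------------------------------------------------------------------
# Cross-modality correlation
# ---------------------------------------------------------------------------

def modality_correlation(
    composition_scrna: pd.DataFrame,
    composition_cytof: pd.DataFrame,
    label_mapping: dict[str, str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pearson r between scRNA-seq and CyTOF proportions over matched
    (sample, cell type) pairs.

    ``label_mapping`` renames CyTOF panel labels to the annotation
    vocabulary before matching.  Returns r and the matched pair list.
    """
    cytof = composition_cytof.rename(columns=label_mapping or {})
    shared_types = [c for c in composition_scrna.columns if c in cytof.columns]
    if not shared_types:
        raise DataError(
            "no overlapping cell types between modalities after label mapping")
    shared_samples = [s for s in composition_scrna.index if s in cytof.index]
    if not shared_samples:
        raise DataError("no overlapping samples between modalities")
    pairs = []
    for s in shared_samples:
        for t in shared_types:
            pairs.append((s, t, float(composition_scrna.loc[s, t]),
                          float(cytof.loc[s, t])))
    table = pd.DataFrame(pairs, columns=["sample_id", "cell_type",
                                         "proportion_scrna", "proportion_cytof"])
    x, y = table["proportion_scrna"], table["proportion_cytof"]
    if np.allclose(x, y):
        return 1.0, table
    r = float(stats.pearsonr(x, y)[0])
    return r, table
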