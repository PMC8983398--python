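"""Repertoire diversity and gene-usage profiling.

Shannon entropy over clonotype frequencies, V-gene (and isotype) usage
matrices, and chain-resolved unique/overlap ratios.  The Shannon index is
computed in natural log with no pseudocount and no subsampling:

    H = -sum_i p_i ln p_i,   p_i = count_i / total

Raw H confounds richness with evenness, so the normalized evenness
H / ln(n_clonotypes) is reported alongside.  An optional seeded fixed-depth
resampling mode supports fair cross-sample comparison at unequal depths.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InsufficientSeriesError
from .io import TimeSeriesCohort
from .keys import chain_segment
from .vocab import CHAINS, IGH_ISOTYPES

logger = logging.getLogger(__name__)


@dataclass
class DiversityResult:
    sample_id: str
    chain_or_class: str
    shannon: float          # H, in nats
    n_clonotypes: int
    n_cells: int
    evenness: float         # H / ln(n_clonotypes); 0 for a single clonotype


# ---------------------------------------------------------------------------
# Shannon entropy
# ---------------------------------------------------------------------------

def shannon_index(
    clonotype_counts: Mapping[str, int] | pd.Series,
    sample_id: str = "",
    chain_or_class: str = "",
) -> DiversityResult:
    """Shannon index H = -sum p_i ln p_i over clonotype frequencies.

    Zero-count clonotypes are ignored; no pseudocounts are added.  All-zero
    input is a domain error.
    """
    counts = pd.Series(dict(clonotype_counts), dtype=float)
    if (counts < 0).any():
        raise DataError("negative clonotype counts")
    counts = counts[counts > 0]
    if counts.empty:
        raise DataError("all clonotype counts are zero")
    p = counts.to_numpy() / counts.sum()
    h = float(-(p * np.log(p)).sum())
    n = len(counts)
    evenness = h / np.log(n) if n > 1 else 0.0
    return DiversityResult(
        sample_id=sample_id, chain_or_class=chain_or_class,
        shannon=max(h, 0.0), n_clonotypes=n, n_cells=int(counts.sum()),
        evenness=float(evenness))


def subsampled_shannon(
    clonotype_counts: Mapping[str, int] | pd.Series,
    depth: int,
    seed: int,
    **kwargs,
) -> DiversityResult:
    """Shannon index after seeded resampling to a fixed cell depth
    (without replacement); for cross-sample comparisons at unequal depths."""
    counts = pd.Series(dict(clonotype_counts), dtype=int)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise DataError(f"depth {depth} exceeds available cells {total}")
    rng = np.random.default_rng(seed)
    cells = np.repeat(np.arange(len(counts)), counts.to_numpy())
    take = rng.choice(cells, size=depth, replace=False)
    sub = pd.Series(take).value_counts()
    resampled = {counts.index[i]: int(n) for i, n in sub.items()}
    return shannon_index(resampled, **kwargs)


# ---------------------------------------------------------------------------
# Chain-level helpers
# ---------------------------------------------------------------------------

def chain_keys(contigs: pd.DataFrame, chain: str) -> pd.Series:
    """Single-chain clonotype key per productive contig of ``chain``."""
    sub = contigs[(contigs["chain"] == chain)
                  & contigs["productive"].astype(bool)]
    return (sub["chain"].astype(str) + ":" + sub["v_gene"].astype(str)
            + ":" + sub["j_gene"].astype(str) + ":" + sub["cdr3_nt"].astype(str))


def shannon_by_sample(
    contigs: pd.DataFrame,
    chain: str = "IGH",
) -> pd.DataFrame:
    """Per-sample Shannon diversity over single-chain clonotypes of ``chain``."""
    rows = []
    for sid, group in contigs.groupby("sample_id", sort=True):
        keys = chain_keys(group, chain)
        if keys.empty:
            logger.warning("%s: no productive %s contigs", sid, chain)
            continue
        res = shannon_index(keys.value_counts().to_dict(),
                            sample_id=str(sid), chain_or_class=chain)
        rows.append(vars(res))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Usage matrices
# ---------------------------------------------------------------------------

def v_gene_usage(
    contigs: pd.DataFrame,
    chain: str,
    by: str = "sample_id",
) -> pd.DataFrame:
    """V-gene usage frequencies among productive contigs of one chain.

    Rows = samples (or the grouping in ``by``); columns = every V segment
    observed across the cohort (zeros filled); rows sum to 1 when any contig
    is present.  A group with no contigs of the chain yields an all-zero row
    with a warning.
    """
    if chain not in CHAINS:
        raise DataError(f"unknown chain {chain!r}")
    prod = contigs[(contigs["chain"] == chain)
                   & contigs["productive"].astype(bool)]
    all_groups = sorted(contigs[by].unique())
    segments = sorted(prod["v_gene"].dropna().unique())
    usage = (
        pd.crosstab(prod[by], prod["v_gene"])
        .reindex(index=all_groups, columns=segments, fill_value=0)
        .astype(float)
    )
    totals = usage.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("no productive %s contigs for: %s", chain,
                       list(usage.index[empty]))
    usage.loc[~empty] = usage.loc[~empty].div(totals[~empty], axis=0)
    usage.index.name = by
    usage.columns.name = None
    return usage


def chain_overlap_ratio(
    contigs_by_timepoint: pd.DataFrame,
    chain: str,
) -> pd.DataFrame:
    """Unique vs overlapped proportions for single-chain clonotypes.

    ``contigs_by_timepoint`` must carry a ``time_point`` column spanning
    >= 2 time points of one individual.  A clonotype is *unique* when seen at
    exactly one time point, *overlapped* otherwise; proportions are reported
    both at the clonotype level and at the cell (contig) level.
    """
    tps = contigs_by_timepoint["time_point"].unique()
    if len(tps) < 2:
        raise InsufficientSeriesError(
            f"chain overlap needs >= 2 time points, got {len(tps)}")
    sub = contigs_by_timepoint[
        (contigs_by_timepoint["chain"] == chain)
        & contigs_by_timepoint["productive"].astype(bool)].copy()
    if sub.empty:
        logger.warning("no productive %s contigs", chain)
        return pd.DataFrame([{
            "chain": chain, "n_clonotypes": 0, "n_cells": 0,
            "unique_fraction_clonotypes": 0.0,
            "overlapped_fraction_clonotypes": 0.0,
            "unique_fraction_cells": 0.0, "overlapped_fraction_cells": 0.0}])
    sub["key"] = chain_keys(sub, chain)
    k = sub.groupby("key")["time_point"].nunique()
    cells_per_key = sub["key"].value_counts()
    unique_keys = k[k == 1].index
    n_keys = len(k)
    n_cells = int(cells_per_key.sum())
    n_unique_cells = int(cells_per_key[unique_keys].sum())
    return pd.DataFrame([{
        "chain": chain,
        "n_clonotypes": n_keys,
        "n_cells": n_cells,
        "unique_fraction_clonotypes": len(unique_keys) / n_keys,
        "overlapped_fraction_clonotypes": 1 - len(unique_keys) / n_keys,
        "unique_fraction_cells": n_unique_cells / n_cells,
        "overlapped_fraction_cells": 1 - n_unique_cells / n_cells,
    }])


def isotype_composition(
    contigs_by_timepoint: pd.DataFrame,
    labels: dict[str, "object"] | None = None,
) -> pd.DataFrame:
    """IGH constant-gene (isotype) composition of unique vs overlapped clonotypes.

    ``labels`` maps single-chain IGH clonotype keys to persistence labels
    (anything with a ``category`` attribute); when omitted, labels are
    derived from the table's time points.  Contigs lacking a C gene count as
    ``unassigned``; each group row sums to 1.
    """
    sub = contigs_by_timepoint[
        (contigs_by_timepoint["chain"] == "IGH")
        & contigs_by_timepoint["productive"].astype(bool)].copy()
    columns = list(IGH_ISOTYPES) + ["unassigned"]
    if sub.empty:
        logger.warning("no productive IGH contigs; empty isotype composition")
        return pd.DataFrame(columns=columns)
    sub["key"] = chain_keys(sub, "IGH")
    if labels is None:
        k = sub.groupby("key")["time_point"].nunique()
        group = sub["key"].map(lambda key: "unique" if k[key] == 1 else "overlapped")
    else:
        group = sub["key"].map(
            lambda key: labels[key].category if key in labels else None)
    sub["group"] = group
    sub = sub[sub["group"].notna()]
    c = sub["c_gene"].where(sub["c_gene"].isin(IGH_ISOTYPES), "unassigned")
    counts = (
        pd.crosstab(sub["group"], c)
        .reindex(index=["unique", "overlapped"], columns=columns, fill_value=0)
        .astype(float)
    )
    totals = counts.sum(axis=1)
    nonzero = totals > 0
    counts.loc[nonzero] = counts.loc[nonzero].div(totals[nonzero], axis=0)
    counts.index.name = "group"
    counts.columns.name = None
    return counts


def cohort_contigs(cohort: TimeSeriesCohort, contigs: pd.DataFrame) -> pd.DataFrame:
    """Attach time points to contigs of one individual's samples."""
    tp_by_sample = {s.sample_id: s.time_point for s in cohort.samples}
    sub = contigs[contigs["sample_id"].isin(tp_by_sample)].copy()
    sub["time_point"] = sub["sample_id"].map(tp_by_sample)
    return sub
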