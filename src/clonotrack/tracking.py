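"""Longitudinal clonotype tracking.

The central procedure of the pipeline: classify each clonotype of an
individual's time series as *unique* (sporadic — seen at exactly one time
point) or *overlapped* (sustained — seen at k >= 2 distinct time points);
around a vaccination, remove every clonotype seen in the baseline repertoire
(and optionally in a prior study's repertoire) to isolate vaccine-associated
clonotypes; detect clonotypes with dynamic frequency changes; and trace
per-clonotype trajectories with detailed cell-type breakdowns.

All operations are deterministic set/count computations — no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientSeriesError, LookupFailure
from .io import RepertoireSample, TimeSeriesCohort
from .keys import check_same_scheme, receptor_class
from .vocab import DETAILED_TYPES

# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PersistenceLabel:
    """Persistence classification of one clonotype across a time series.

    ``k`` is the number of distinct time points at which the clonotype was
    observed; ``category`` is ``"unique"`` iff k == 1, else ``"overlapped"``.
    ``post_vaccination_class`` (``ovl_pre`` / ``not_pre_unique`` /
    ``not_pre_ovl_<k>``) is set only by :func:`classify_post_vaccination`.
    """

    category: str
    k: int
    post_vaccination_class: str | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        expected = "unique" if self.k == 1 else "overlapped"
        if self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with k={self.k}")


@dataclass
class PersistenceResult:
    labels: dict[str, PersistenceLabel]
    #: per time point, cell counts/fractions in the unique vs overlapped group
    cell_fractions: pd.DataFrame


@dataclass
class DynamicCallSet:
    increased: set[str]
    decreased: set[str]
    fold: float
    min_cells: int
    #: per-clonotype frequency table used for the calls
    frequencies: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class ClonotypeTrajectory:
    key: str
    #: rows = time points; columns: frequency, n_cells, one column per detailed type
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _require_series(cohort: TimeSeriesCohort, n: int = 2) -> None:
    if len(cohort.samples) < n:
        raise InsufficientSeriesError(
            f"individual {cohort.individual}: need >= {n} time points, "
            f"got {len(cohort.samples)}")


def _presence(cohort: TimeSeriesCohort) -> pd.DataFrame:
    """Clonotype x time-point cell-count matrix (zeros where absent)."""
    counts = {}
    for s in cohort.samples:
        counts[s.time_point] = s.clonotype_counts
    mat = pd.DataFrame(counts).fillna(0).astype(int)
    mat = mat.reindex(columns=cohort.time_points, fill_value=0)
    return mat.sort_index()


def _class_mask(keys: pd.Index, cls: str | None) -> np.ndarray:
    if cls is None:
        return np.ones(len(keys), dtype=bool)
    return np.array([receptor_class(k) == cls for k in keys])


# ---------------------------------------------------------------------------
# Persistence classification
# ---------------------------------------------------------------------------

def classify_persistence(cohort: TimeSeriesCohort) -> PersistenceResult:
    """Label every clonotype of the series as unique (k=1) or overlapped (k>=2).

    Also returns, per time point, the number and fraction of keyed cells
    carried by unique vs overlapped clonotypes (the stacked-bar readout).
    """
    _require_series(cohort)
    mat = _presence(cohort)
    k = (mat > 0).sum(axis=1)
    labels = {
        key: PersistenceLabel("unique" if kk == 1 else "overlapped", int(kk))
        for key, kk in k.items()
    }
    rows = []
    overlapped = k >= 2
    for tp in cohort.time_points:
        col = mat[tp]
        n_unique = int(col[~overlapped].sum())
        n_overlapped = int(col[overlapped].sum())
        total = n_unique + n_overlapped
        rows.append((tp, n_unique, n_overlapped,
                     n_unique / total if total else 0.0,
                     n_overlapped / total if total else 0.0))
    fractions = pd.DataFrame(rows, columns=[
        "time_point", "n_cells_unique", "n_cells_overlapped",
        "fraction_unique", "fraction_overlapped"])
    return PersistenceResult(labels=labels, cell_fractions=fractions)


def celltype_breakdown(
    cohort: TimeSeriesCohort,
    labels: dict[str, PersistenceLabel],
) -> pd.DataFrame:
    """Detailed-cell-type fractions within the unique vs overlapped cell groups.

    Long-format table with one row per (group, time_point, cell_type) plus
    averaged rows (``time_point`` = NA), carrying counts and within-group
    fractions.  An empty group yields all-zero rows.
    """
    cells = cohort.cells()
    keyed = cells[cells["clonotype_key"].notna()].copy()
    keyed["group"] = keyed["clonotype_key"].map(
        lambda key: labels[key].category if key in labels else None)
    keyed = keyed[keyed["group"].notna()]

    rows = []
    for group in ("unique", "overlapped"):
        sub = keyed[keyed["group"] == group]
        for tp in cohort.time_points:
            at_tp = sub[sub["time_point"] == tp]
            counts = at_tp["cell_type"].value_counts()
            total = int(counts.sum())
            for ctype in DETAILED_TYPES:
                n = int(counts.get(ctype, 0))
                rows.append((group, tp, ctype, n,
                             n / total if total else 0.0))
        counts = sub["cell_type"].value_counts()
        total = int(counts.sum())
        for ctype in DETAILED_TYPES:
            n = int(counts.get(ctype, 0))
            rows.append((group, pd.NA, ctype, n, n / total if total else 0.0))
    return pd.DataFrame(rows, columns=[
        "group", "time_point", "cell_type", "n_cells", "fraction"])


# ---------------------------------------------------------------------------
# Baseline subtraction
# ---------------------------------------------------------------------------

def subtract_baseline(
    cohort_post: TimeSeriesCohort,
    baseline_sets: list[set[str]] | set[str],
    baseline_scheme: str | None = None,
) -> tuple[TimeSeriesCohort, pd.DataFrame]:
    """Remove every cell whose clonotype was seen in any baseline set.

    ``baseline_sets`` is one set of clonotype keys or a list of them (their
    union is subtracted).  Keys must have been built under the same scheme on
    both sides; pass ``baseline_scheme`` to enforce the contract.  Returns
    the filtered cohort and a per-sample removal report.  The remaining key
    set is asserted disjoint from the baseline union.
    """
    if baseline_scheme is not None:
        check_same_scheme(cohort_post.scheme, baseline_scheme)
    if isinstance(baseline_sets, set):
        baseline_sets = [baseline_sets]
    union: set[str] = set().union(*baseline_sets) if baseline_sets else set()

    new_samples, rows = [], []
    for s in cohort_post.samples:
        in_baseline = s.cells["clonotype_key"].isin(union)
        kept = s.cells[~in_baseline].reset_index(drop=True)
        rows.append((s.sample_id, s.time_point, len(s.cells),
                     int(in_baseline.sum()), len(kept)))
        new_samples.append(RepertoireSample(
            individual=s.individual, time_point=s.time_point,
            sample_id=s.sample_id, cells=kept, scheme=s.scheme,
            n_orphan_vdj=s.n_orphan_vdj))
    filtered = TimeSeriesCohort(individual=cohort_post.individual,
                                samples=new_samples)
    assert not (filtered.all_keys() & union), \
        "baseline subtraction left baseline clonotypes behind"
    report = pd.DataFrame(rows, columns=[
        "sample_id", "time_point", "n_cells_in", "n_cells_removed",
        "n_cells_out"])
    return filtered, report


def classify_post_vaccination(
    cohort_post: TimeSeriesCohort,
    pre_set: set[str],
    pre_scheme: str | None = None,
) -> tuple[dict[str, PersistenceLabel], pd.DataFrame]:
    """Partition post-vaccination clonotypes against the pre-vaccination set.

    Keys present in ``pre_set`` are ``ovl_pre`` (regardless of how often they
    recur afterwards); the rest are ``not_pre``, subdivided into
    ``not_pre_unique`` (one post time point) and ``not_pre_ovl_<k>``
    (k >= 2 post time points).  Also returns the per-time-point stacked
    cell-count/fraction table.
    """
    if pre_scheme is not None:
        check_same_scheme(cohort_post.scheme, pre_scheme)
    _require_series(cohort_post, 1)
    mat = _presence(cohort_post)
    k = (mat > 0).sum(axis=1)

    labels: dict[str, PersistenceLabel] = {}
    classes: dict[str, str] = {}
    for key, kk in k.items():
        kk = int(kk)
        if key in pre_set:
            cls = "ovl_pre"
        elif kk == 1:
            cls = "not_pre_unique"
        else:
            cls = f"not_pre_ovl_{kk}"
        classes[key] = cls
        labels[key] = PersistenceLabel(
            "unique" if kk == 1 else "overlapped", kk,
            post_vaccination_class=cls)

    cls_series = pd.Series(classes)
    rows = []
    for tp in cohort_post.time_points:
        col = mat[tp]
        totals = col.groupby(cls_series).sum()
        total = int(col.sum())
        for cls, n in sorted(totals.items()):
            rows.append((tp, cls, int(n), n / total if total else 0.0))
    stacked = pd.DataFrame(rows, columns=[
        "time_point", "post_vaccination_class", "n_cells", "fraction"])
    return labels, stacked


# ---------------------------------------------------------------------------
# Dynamic clonotypes
# ---------------------------------------------------------------------------

def detect_dynamic_clonotypes(
    cohort: TimeSeriesCohort,
    fold: float = 2.0,
    min_cells: int = 3,
    receptor: str = "TCR",
) -> DynamicCallSet:
    """Call clonotypes whose frequency rises or falls across the series.

    Frequencies are computed among keyed cells of the requested receptor
    class at each time point.  With f = ``fold`` and first observation at
    time t0:

    * *increased*: max frequency over time points after t0 >= f x freq(t0),
      and peak cell count >= ``min_cells``;
    * *decreased*: freq(t0) >= f x min frequency over time points after t0
      (drops to zero count), and count(t0) >= ``min_cells``.

    Clonotypes observed at a single time point are excluded.  A clonotype
    satisfying both rules (a rise followed by extinction) is reported as
    increased only, keeping the two call sets disjoint.
    """
    if fold <= 1:
        raise ConfigurationError(f"fold: must be > 1, got {fold}")
    if min_cells < 1:
        raise ConfigurationError(f"min_cells: must be >= 1, got {min_cells}")
    _require_series(cohort)

    mat = _presence(cohort)
    mask = _class_mask(mat.index, receptor)
    mat = mat.loc[mask]
    totals = mat.sum(axis=0).replace(0, np.nan)
    freq = mat.div(totals, axis=1).fillna(0.0)

    increased, decreased = set(), set()
    tps = list(mat.columns)
    counts = mat.to_numpy()
    freqs = freq.to_numpy()
    for i, key in enumerate(mat.index):
        observed = np.nonzero(counts[i] > 0)[0]
        if len(observed) < 2:
            continue
        first = observed[0]
        later = slice(first + 1, len(tps))
        f0, c0 = freqs[i, first], counts[i, first]
        later_freqs = freqs[i, later]
        if later_freqs.size == 0:
            continue
        peak = counts[i].max()
        if later_freqs.max() >= fold * f0 and peak >= min_cells:
            increased.add(key)
        elif f0 >= fold * later_freqs.min() and c0 >= min_cells:
            # a zero min frequency (drop to extinction) always satisfies this
            decreased.add(key)
    freq_table = freq.copy()
    freq_table.index.name = "clonotype_key"
    return DynamicCallSet(increased=increased, decreased=decreased,
                          fold=fold, min_cells=min_cells,
                          frequencies=freq_table)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def trace_clonotype(
    cohort: TimeSeriesCohort,
    key: str,
    receptor: str | None = None,
) -> ClonotypeTrajectory:
    """Per-time-point frequency and detailed-type breakdown of one clonotype.

    Frequency is among keyed cells of the clonotype's receptor class.  Time
    points where the clonotype is absent get frequency 0 and an empty
    breakdown.
    """
    if receptor is None:
        receptor = receptor_class(key)
    rows = []
    seen = False
    for s in cohort.samples:
        keyed = s.cells[s.cells["clonotype_key"].notna()]
        class_mask = keyed["clonotype_key"].map(
            lambda k: receptor is None or receptor_class(k) == receptor)
        denom = int(class_mask.sum())
        mine = keyed[keyed["clonotype_key"] == key]
        n = len(mine)
        seen = seen or n > 0
        counts = mine["cell_type"].value_counts()
        row = {"time_point": s.time_point, "n_cells": n,
               "frequency": n / denom if denom else 0.0}
        for ctype in DETAILED_TYPES:
            row[ctype] = int(counts.get(ctype, 0))
        rows.append(row)
    if not seen:
        raise LookupFailure(
            f"clonotype {key!r} not observed in cohort {cohort.individual}")
    return ClonotypeTrajectory(key=key, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Rankings / filters
# ---------------------------------------------------------------------------

def top_clonotypes(
    samples: list[RepertoireSample],
    n: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-n clonotypes per sample plus the cross-individual overlap report.

    Ranking is by cell count, ties broken by earlier first observation (the
    smallest time point at which the key appears anywhere in ``samples``),
    then lexicographically — fully deterministic.  The overlap report counts
    shared top-n keys for every pair of individuals (the expected value
    between unrelated individuals is zero).
    """
    if n < 1:
        raise ConfigurationError(f"n: must be >= 1, got {n}")
    first_seen: dict[str, int] = {}
    for s in sorted(samples, key=lambda s: s.time_point):
        for key in s.keys():
            first_seen.setdefault(key, s.time_point)

    rows = []
    top_by_individual: dict[str, set[str]] = {}
    for s in samples:
        counts = s.clonotype_counts
        ranked = sorted(
            counts.items(),
            key=lambda kv: (-kv[1], first_seen[kv[0]], kv[0]))[:n]
        for rank, (key, count) in enumerate(ranked, start=1):
            rows.append((s.individual, s.sample_id, s.time_point, rank, key,
                         int(count)))
            top_by_individual.setdefault(s.individual, set()).add(key)
    table = pd.DataFrame(rows, columns=[
        "individual", "sample_id", "time_point", "rank", "clonotype_key",
        "n_cells"])

    individuals = sorted(top_by_individual)
    overlap_rows = [
        (a, b, len(top_by_individual[a] & top_by_individual[b]))
        for i, a in enumerate(individuals) for b in individuals[i + 1:]
    ]
    overlap = pd.DataFrame(overlap_rows, columns=[
        "individual_a", "individual_b", "n_shared_top_clonotypes"])
    return table, overlap


def min_timepoint_filter(
    labels: dict[str, PersistenceLabel],
    t_min: int = 3,
    strict: bool = False,
) -> set[str]:
    """Clonotypes observed at >= ``t_min`` time points (> with ``strict``)."""
    if t_min < 1:
        raise ConfigurationError(f"t_min: must be >= 1, got {t_min}")
    if strict:
        return {k for k, lab in labels.items() if lab.k > t_min}
    return {k for k, lab in labels.items() if lab.k >= t_min}
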