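"""Clonotype persistence, baseline subtraction, dynamic detection, tracing."""

import numpy as np
import pandas as pd
import pytest

from clonotrack import (build_cohorts, build_clonotype_keys,
                        classify_persistence, classify_post_vaccination,
                        celltype_breakdown, detect_dynamic_clonotypes,
                        min_timepoint_filter, subtract_baseline,
                        top_clonotypes, trace_clonotype)
from clonotrack.errors import (ConfigurationError, InsufficientSeriesError,
                               LookupFailure, SchemeMismatchError)
from clonotrack.io import RepertoireSample, TimeSeriesCohort
from clonotrack.tracking import PersistenceLabel

from conftest import random_cohort
from oracles import (min_timepoint_oracle, persistence_oracle,
                     post_vaccination_oracle, subtract_oracle)


def toy_cohort(spec: dict[int, list[tuple[str | None, str]]],
               individual="T1") -> TimeSeriesCohort:
    """Cohort from {time_point: [(key_or_None, cell_type), ...]}."""
    samples = []
    for tp, cells in spec.items():
        frame = pd.DataFrame({
            "barcode": [f"b{i}" for i in range(len(cells))],
            "sample_id": f"{individual}_d{tp}",
            "individual": individual,
            "time_point": tp,
            "cell_type": [c[1] for c in cells],
            "clonotype_key": pd.array([c[0] for c in cells], dtype=object),
        })
        samples.append(RepertoireSample(
            individual=individual, time_point=tp,
            sample_id=f"{individual}_d{tp}", cells=frame))
    return TimeSeriesCohort(individual=individual, samples=samples)


K1, K2, K3 = "TRB:V1:J1:AAA", "TRB:V2:J1:CCC", "TRB:V3:J2:GGG"
NT = "CD4+ naive T"
ET = "CD8+ effector T"


# ---------------------------------------------------------------------------
# classify_persistence
# ---------------------------------------------------------------------------

def test_persistence_definitions():
    cohort = toy_cohort({
        0: [(K1, NT), (K2, ET)],
        21: [(K2, ET)],
        84: [(K2, ET), (K3, NT)]})
    res = classify_persistence(cohort)
    assert res.labels[K1] == PersistenceLabel("unique", 1)
    assert res.labels[K2] == PersistenceLabel("overlapped", 3)
    assert res.labels[K3] == PersistenceLabel("unique", 1)
    day0 = res.cell_fractions.set_index("time_point").loc[0]
    assert day0["fraction_unique"] == 0.5
    assert day0["fraction_overlapped"] == 0.5


def test_persistence_requires_series():
    with pytest.raises(InsufficientSeriesError):
        classify_persistence(toy_cohort({0: [(K1, NT)]}))


def test_persistence_invariant_to_cell_order():
    rng = np.random.default_rng(0)
    cohort = random_cohort(rng)
    res1 = classify_persistence(cohort)
    shuffled = TimeSeriesCohort(
        individual=cohort.individual,
        samples=[RepertoireSample(
            individual=s.individual, time_point=s.time_point,
            sample_id=s.sample_id,
            cells=s.cells.sample(frac=1, random_state=1).reset_index(drop=True))
            for s in cohort.samples])
    res2 = classify_persistence(shuffled)
    assert res1.labels == res2.labels


def test_persistence_planted_recovery(small_sim):
    """>=95% of planted persistent clones are labelled overlapped."""
    _, ann, contigs, _, truth = small_sim
    cohort = build_cohorts(ann, contigs)["H1"]
    res = classify_persistence(cohort)
    oracle = persistence_oracle(cohort)
    assert {k: (l.category, l.k) for k, l in res.labels.items()} == oracle
    planted = truth.persistent_t_clonotypes["H1"]
    observed = [k for k in planted if k in res.labels]
    overlapped = sum(1 for k in observed
                     if res.labels[k].category == "overlapped")
    assert overlapped / len(observed) >= 0.95


# ---------------------------------------------------------------------------
# celltype_breakdown
# ---------------------------------------------------------------------------

def test_breakdown_constructed():
    cohort = toy_cohort({
        0: [(K1, NT), (K2, ET)],
        21: [(K2, ET)]})
    labels = classify_persistence(cohort).labels
    table = celltype_breakdown(cohort, labels)
    avg = table[table["time_point"].isna()].set_index(["group", "cell_type"])
    assert avg.loc[("unique", NT), "fraction"] == 1.0
    assert avg.loc[("overlapped", ET), "fraction"] == 1.0
    # counts conserved: per-group totals equal keyed cells
    keyed = cohort.cells()["clonotype_key"].notna().sum()
    assert avg["n_cells"].sum() == keyed


def test_breakdown_persistent_enriched_in_memory(small_sim):
    """Overlapped cells are dominated by memory/effector types, unique by naive."""
    _, ann, contigs, _, _ = small_sim
    cohort = build_cohorts(ann, contigs)["H1"]
    labels = classify_persistence(cohort).labels
    table = celltype_breakdown(cohort, labels)
    avg = table[table["time_point"].isna()].set_index(["group", "cell_type"])
    memory = ["CD4+ memory T", "CD8+ effector T", "CD8+ memory T", "MAIT", "gdT"]
    ovl_mem = sum(avg.loc[("overlapped", t), "fraction"] for t in memory)
    uni_mem = sum(avg.loc[("unique", t), "fraction"] for t in memory)
    assert ovl_mem > uni_mem


# ---------------------------------------------------------------------------
# subtract_baseline
# ---------------------------------------------------------------------------

def test_subtraction_set_difference():
    cohort = toy_cohort({0: [(K1, NT), (K2, ET), (K3, NT)],
                         7: [(K1, NT)]})
    filtered, report = subtract_baseline(cohort, {K2})
    assert filtered.all_keys() == {K1, K3}
    assert report["n_cells_removed"].sum() == 1
    # union associativity: two sets equal their single-set union
    f2, _ = subtract_baseline(cohort, [{K2}, {K3}])
    f3, _ = subtract_baseline(cohort, {K2, K3})
    assert f2.all_keys() == f3.all_keys() == {K1}


def test_subtraction_scheme_contract():
    cohort = toy_cohort({0: [(K1, NT)], 7: [(K2, ET)]})
    with pytest.raises(SchemeMismatchError):
        subtract_baseline(cohort, {K1}, baseline_scheme="paired_aa")


def test_subtraction_planted_recovery(vaccination_sim):
    """Subtracting the pre-dose repertoire keeps >=95% of induced clonotypes
    and removes every baseline-pool clonotype."""
    _, ann, contigs, _, truth = vaccination_sim
    cohort = build_cohorts(ann, contigs)["H1"]
    pre = set().union(*(s.keys() for s in cohort.samples if s.time_point <= 0))
    post = TimeSeriesCohort(
        individual="H1",
        samples=[s for s in cohort.samples if s.time_point > 0])
    filtered, _ = subtract_baseline(post, pre)
    remaining = filtered.all_keys()
    induced = truth.induced_clonotypes["H1"]
    emitted_induced = induced & post.all_keys()
    assert len(remaining & emitted_induced) / len(emitted_induced) >= 0.95
    assert not (remaining & pre)


# ---------------------------------------------------------------------------
# classify_post_vaccination
# ---------------------------------------------------------------------------

def test_post_vaccination_classes():
    cohort = toy_cohort({1: [(K1, NT), (K2, ET)],
                         7: [(K1, NT), (K3, NT)],
                         28: [(K1, NT)]})
    labels, stacked = classify_post_vaccination(cohort, pre_set={K1})
    assert labels[K1].post_vaccination_class == "ovl_pre"  # pre takes precedence
    assert labels[K2].post_vaccination_class == "not_pre_unique"
    labels2, _ = classify_post_vaccination(cohort, pre_set=set())
    assert labels2[K1].post_vaccination_class == "not_pre_ovl_3"
    day1 = stacked[stacked["time_point"] == 1].set_index(
        "post_vaccination_class")
    assert day1.loc["ovl_pre", "fraction"] == 0.5


def test_post_vaccination_not_pre_ovl_k():
    cohort = toy_cohort({1: [(K2, ET)], 7: [(K2, ET)]})
    labels, _ = classify_post_vaccination(cohort, pre_set=set())
    assert labels[K2].post_vaccination_class == "not_pre_ovl_2"


def test_post_vaccination_induced_are_not_pre(vaccination_sim):
    _, ann, contigs, _, truth = vaccination_sim
    cohort = build_cohorts(ann, contigs)["H1"]
    pre = set().union(*(s.keys() for s in cohort.samples if s.time_point <= 0))
    post = TimeSeriesCohort(
        individual="H1",
        samples=[s for s in cohort.samples if s.time_point > 0])
    labels, _ = classify_post_vaccination(post, pre)
    oracle = post_vaccination_oracle(post, pre)
    assert {k: l.post_vaccination_class for k, l in labels.items()} == oracle
    induced = truth.induced_clonotypes["H1"] & set(labels)
    not_pre = sum(1 for k in induced
                  if labels[k].post_vaccination_class != "ovl_pre")
    assert not_pre / len(induced) >= 0.95


# ---------------------------------------------------------------------------
# dynamic clonotypes
# ---------------------------------------------------------------------------

def _freq_cohort(freqs: dict[str, list[int]], n_fill=1000):
    """Cohort where each key has given absolute counts per time point, padded
    with unique filler clones to a fixed keyed total."""
    tps = range(len(next(iter(freqs.values()))))
    spec = {}
    filler = 0
    for i, tp in enumerate(tps):
        cells = []
        for key, counts in freqs.items():
            cells.extend((key, ET) for _ in range(counts[i]))
        while len(cells) < n_fill:
            cells.append((f"TRB:VF:JF:F{filler:05d}", NT))
            filler += 1
        spec[tp] = cells
    return toy_cohort(spec)


def test_dynamic_fourfold_rise_called():
    cohort = _freq_cohort({K1: [1, 4, 2]}, n_fill=1000)
    calls = detect_dynamic_clonotypes(cohort, fold=2, min_cells=3)
    assert K1 in calls.increased
    assert K1 not in calls.decreased


def test_dynamic_flat_not_called():
    cohort = _freq_cohort({K1: [3, 3, 3]}, n_fill=1000)
    calls = detect_dynamic_clonotypes(cohort)
    assert K1 not in calls.increased | calls.decreased


def test_dynamic_decrease_including_extinction():
    cohort = _freq_cohort({K1: [6, 2, 1], K2: [4, 4, 0]}, n_fill=1000)
    calls = detect_dynamic_clonotypes(cohort)
    assert {K1, K2} <= calls.decreased


def test_dynamic_single_timepoint_excluded():
    cohort = _freq_cohort({K1: [9, 0, 0]}, n_fill=1000)
    calls = detect_dynamic_clonotypes(cohort)
    assert K1 not in calls.increased | calls.decreased


def test_dynamic_scale_invariance():
    """Calls depend on frequencies, not absolute counts per time point."""
    c1 = _freq_cohort({K1: [2, 8, 4]}, n_fill=500)
    c2 = _freq_cohort({K1: [4, 16, 8]}, n_fill=1000)  # doubled everything
    calls1 = detect_dynamic_clonotypes(c1)
    calls2 = detect_dynamic_clonotypes(c2)
    assert (K1 in calls1.increased) == (K1 in calls2.increased)


def test_dynamic_parameter_validation():
    cohort = _freq_cohort({K1: [1, 4]}, n_fill=100)
    with pytest.raises(ConfigurationError):
        detect_dynamic_clonotypes(cohort, fold=1.0)
    with pytest.raises(ConfigurationError):
        detect_dynamic_clonotypes(cohort, min_cells=0)


def test_dynamic_disjoint_and_params_recorded():
    rng = np.random.default_rng(5)
    for _ in range(20):
        cohort = random_cohort(rng)
        calls = detect_dynamic_clonotypes(cohort)
        assert not (calls.increased & calls.decreased)
        assert calls.fold == 2.0 and calls.min_cells == 3


def test_dynamic_planted_recovery(vaccination_sim):
    """Induced clonotypes (5x planted rise): recall and precision >= 0.9."""
    _, ann, contigs, _, truth = vaccination_sim
    cohort = build_cohorts(ann, contigs)["H1"]
    calls = detect_dynamic_clonotypes(cohort)
    induced = truth.induced_clonotypes["H1"]
    hits = calls.increased & induced
    assert len(hits) / len(induced) >= 0.9
    assert len(hits) / len(calls.increased) >= 0.9
    # false-positive rate among flat planted persistent clones <= 5%
    flat = truth.persistent_t_clonotypes["H1"] - induced
    fp = len(calls.increased & flat)
    assert fp / len(flat) <= 0.05


# ---------------------------------------------------------------------------
# trace_clonotype
# ---------------------------------------------------------------------------

def test_trace_arithmetic_and_absence():
    cells_tp0 = [(K1, ET)] * 5 + [(f"TRB:VF:JF:F{i:03d}", NT)
                                  for i in range(495)]
    cohort = toy_cohort({1: cells_tp0, 3: [(K2, ET)] * 10})
    traj = trace_clonotype(cohort, K1)
    t = traj.table.set_index("time_point")
    assert t.loc[1, "frequency"] == pytest.approx(5 / 500)
    assert t.loc[1, ET] == 5
    assert t.loc[3, "frequency"] == 0.0
    assert t.loc[3, ET] == 0
    with pytest.raises(LookupFailure):
        trace_clonotype(cohort, "TRB:VX:JX:NONE")


def test_trace_transition_schedule():
    """Planted effector->memory relabeling is read back from the trajectory."""
    from clonotrack import SimConfig, simulate_cohort

    cfg = SimConfig(seed=21, individuals=[{"id": "H1"}],
                    time_points=[0, 7, 21, 84], cells_per_sample=800,
                    n_transition_clonotypes=3, dropout_rate_vdj=0.0)
    ann, contigs, _, truth = simulate_cohort(cfg)
    cohort = build_cohorts(ann, contigs)["H1"]
    schedules = truth.transition_schedule["H1"]
    checked = 0
    for key, schedule in schedules.items():
        if key not in cohort.all_keys():
            continue
        traj = trace_clonotype(cohort, key).table.set_index("time_point")
        for tp, expected_type in schedule.items():
            if traj.loc[tp, "n_cells"] > 0:
                assert traj.loc[tp, expected_type] == traj.loc[tp, "n_cells"]
                checked += 1
    assert checked > 0


# ---------------------------------------------------------------------------
# top_clonotypes / min_timepoint_filter
# ---------------------------------------------------------------------------

def test_top_tie_rule():
    cohort = toy_cohort({
        0: [(K1, ET)] * 2,
        7: [(K1, ET)] * 3 + [(K2, ET)] * 5 + [(K3, NT)]})
    # at day 7: K2 has 5 cells, K1 has 3; with n=2 -> (K2, K1)
    table, _ = top_clonotypes(cohort.samples, n=2)
    day7 = table[table["time_point"] == 7]
    assert list(day7["clonotype_key"]) == [K2, K1]
    # equal counts: earlier-first-seen wins
    cohort2 = toy_cohort({0: [(K1, ET)], 7: [(K1, ET)] * 5 + [(K2, ET)] * 5})
    table2, _ = top_clonotypes(cohort2.samples, n=2)
    day7 = table2[table2["time_point"] == 7]
    assert list(day7["clonotype_key"]) == [K1, K2]


def test_top_n_larger_than_repertoire():
    cohort = toy_cohort({0: [(K1, ET), (K2, ET)], 7: [(K1, ET)]})
    table, _ = top_clonotypes(cohort.samples, n=50)
    assert len(table[table["time_point"] == 0]) == 2


def test_top_disjoint_individuals_zero_overlap():
    a = toy_cohort({0: [(K1, ET)], 7: [(K2, ET)]}, individual="A")
    b = toy_cohort({0: [("TRB:VX:JX:XXX", ET)], 7: [("TRB:VY:JY:YYY", ET)]},
                   individual="B")
    _, overlap = top_clonotypes(a.samples + b.samples, n=10)
    assert (overlap["n_shared_top_clonotypes"] == 0).all()


def test_min_timepoint_filter_rules():
    labels = {
        "a": PersistenceLabel("unique", 1),
        "b": PersistenceLabel("overlapped", 3),
        "c": PersistenceLabel("overlapped", 5)}
    assert min_timepoint_filter(labels, t_min=3) == {"b", "c"}
    assert min_timepoint_filter(labels, t_min=3, strict=True) == {"c"}
    assert min_timepoint_filter(labels, t_min=1) == {"a", "b", "c"}
    with pytest.raises(ConfigurationError):
        min_timepoint_filter(labels, t_min=0)


# ---------------------------------------------------------------------------
# oracle equivalence on random cohorts (property-style)
# ---------------------------------------------------------------------------

def test_random_cohorts_match_oracles():
    rng = np.random.default_rng(123)
    for _ in range(40):
        cohort = random_cohort(rng)
        res = classify_persistence(cohort)
        assert ({k: (l.category, l.k) for k, l in res.labels.items()}
                == persistence_oracle(cohort))
        pre = set(k for k in cohort.all_keys() if rng.random() < 0.3)
        labels, _ = classify_post_vaccination(cohort, pre)
        assert ({k: l.post_vaccination_class for k, l in labels.items()}
                == post_vaccination_oracle(cohort, pre))
        filtered, _ = subtract_baseline(cohort, pre)
        expected = subtract_oracle(cohort, pre)
        for s in filtered.samples:
            got = [k if isinstance(k, str) else None
                   for k in s.cells["clonotype_key"]]
            assert sorted(got, key=str) == sorted(
                expected.get(s.time_point, []), key=str)
        for t_min in (1, 2, 3):
            assert (min_timepoint_filter(res.labels, t_min)
                    == min_timepoint_oracle(cohort, t_min))
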