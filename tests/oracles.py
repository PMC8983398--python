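"""Independent brute-force oracles for the tracking/diversity set operations.

Deliberately written as plain dict/set loops over individual cells, sharing
no code path with the library implementations they check.
"""

from collections import defaultdict

import pandas as pd


def _cells(cohort) -> list[tuple[int, str | None]]:
    out = []
    for s in cohort.samples:
        for key in s.cells["clonotype_key"]:
            out.append((s.time_point, key if isinstance(key, str) else None))
    return out


def persistence_oracle(cohort) -> dict[str, tuple[str, int]]:
    """key -> (category, k) by explicit set membership."""
    tps_by_key: dict[str, set[int]] = defaultdict(set)
    for tp, key in _cells(cohort):
        if key is not None:
            tps_by_key[key].add(tp)
    return {
        key: ("unique" if len(tps) == 1 else "overlapped", len(tps))
        for key, tps in tps_by_key.items()
    }


def post_vaccination_oracle(cohort_post, pre_set) -> dict[str, str]:
    tps_by_key: dict[str, set[int]] = defaultdict(set)
    for tp, key in _cells(cohort_post):
        if key is not None:
            tps_by_key[key].add(tp)
    out = {}
    for key, tps in tps_by_key.items():
        if key in pre_set:
            out[key] = "ovl_pre"
        elif len(tps) == 1:
            out[key] = "not_pre_unique"
        else:
            out[key] = f"not_pre_ovl_{len(tps)}"
    return out


def subtract_oracle(cohort, baseline_union) -> dict[int, list[str | None]]:
    """time_point -> surviving cell key list (None kept)."""
    out: dict[int, list[str | None]] = defaultdict(list)
    for tp, key in _cells(cohort):
        if key is None or key not in baseline_union:
            out[tp].append(key)
    return dict(out)


def min_timepoint_oracle(cohort, t_min: int) -> set[str]:
    return {key for key, (_, k) in persistence_oracle(cohort).items()
            if k >= t_min}


def chain_overlap_oracle(contigs: pd.DataFrame, chain: str):
    """(unique_fraction_clonotypes, unique_fraction_cells) by explicit loops."""
    tps_by_key: dict[str, set[int]] = defaultdict(set)
    cells_by_key: dict[str, int] = defaultdict(int)
    for row in contigs.itertuples(index=False):
        if row.chain != chain or not row.productive:
            continue
        key = f"{row.chain}:{row.v_gene}:{row.j_gene}:{row.cdr3_nt}"
        tps_by_key[key].add(row.time_point)
        cells_by_key[key] += 1
    if not tps_by_key:
        return None
    unique = [k for k, tps in tps_by_key.items() if len(tps) == 1]
    n_cells = sum(cells_by_key.values())
    n_unique_cells = sum(cells_by_key[k] for k in unique)
    return len(unique) / len(tps_by_key), n_unique_cells / n_cells


def clonotype_key_oracle(contig_rows) -> dict[tuple[str, str], str]:
    """Paired-nt keys rebuilt rule by rule from a list of contig dicts."""
    by_cell_chain: dict[tuple, list[dict]] = defaultdict(list)
    for c in contig_rows:
        if not c["productive"]:
            continue
        by_cell_chain[(c["sample_id"], c["barcode"], c["chain"])].append(c)
    best: dict[tuple, dict] = {}
    for (sid, bc, chain), group in by_cell_chain.items():
        group = sorted(group, key=lambda c: (-c["umis"], c["cdr3_nt"]))
        best[(sid, bc, chain)] = group[0]
    segs_by_cell: dict[tuple[str, str], list[str]] = defaultdict(list)
    for (sid, bc, chain), c in best.items():
        segs_by_cell[(sid, bc)].append(
            f"{chain}:{c['v_gene']}:{c['j_gene']}:{c['cdr3_nt']}")
    return {cell: "|".join(sorted(segs)) for cell, segs in segs_by_cell.items()}
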