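import numpy as np
import pandas as pd
import pytest

from clonotrack import SimConfig, simulate_cohort
from clonotrack.io import RepertoireSample, TimeSeriesCohort


@pytest.fixture(scope="session")
def small_sim():
    """Four-time-point single-individual cohort, no vaccination."""
    cfg = SimConfig(
        seed=11,
        individuals=[{"id": "H1"}],
        time_points=[0, 7, 21, 84],
        cells_per_sample=1000,
    )
    ann, contigs, expr, truth = simulate_cohort(cfg)
    return cfg, ann, contigs, expr, truth


@pytest.fixture(scope="session")
def vaccination_sim():
    """Influenza-style vaccination scenario: pre-dose day -1, dose at day 0,
    post days 1/3/7/28, 50 induced clonotypes rising 5-fold."""
    cfg = SimConfig(
        seed=3,
        individuals=[{"id": "H1"}],
        time_points=[-1, 1, 3, 7, 28],
        cells_per_sample=2000,
        vaccination={"dose_days": [0], "n_induced_clonotypes": 50},
    )
    ann, contigs, expr, truth = simulate_cohort(cfg)
    return cfg, ann, contigs, expr, truth


# ---------------------------------------------------------------------------
# Random small cohorts for oracle-equivalence and fuzz testing
# ---------------------------------------------------------------------------

_CELL_TYPES = ("CD4+ naive T", "CD8+ naive T", "CD8+ effector T",
               "CD8+ memory T", "MAIT", "naive B", "memory B")


def random_cohort(rng: np.random.Generator, max_cells: int = 200,
                  max_tps: int = 6, key_pool: int = 25) -> TimeSeriesCohort:
    """Random keyed cohort drawn from a small clonotype alphabet (so time
    points share keys by chance), independent of the simulator."""
    n_tps = int(rng.integers(2, max_tps + 1))
    tps = sorted(rng.choice(100, size=n_tps, replace=False).tolist())
    pool = [f"TRB:TRBV{i % 7}:TRBJ{i % 4}:NT{i:03d}" for i in range(key_pool)]
    weights = 1.0 / np.arange(1, key_pool + 1)
    weights /= weights.sum()
    samples = []
    for tp in tps:
        n_cells = int(rng.integers(5, max(6, max_cells // n_tps)))
        keys = [
            None if rng.random() < 0.2
            else pool[int(rng.choice(key_pool, p=weights))]
            for _ in range(n_cells)
        ]
        cells = pd.DataFrame({
            "barcode": [f"BC{i:05d}" for i in range(n_cells)],
            "sample_id": f"R1_d{tp}",
            "individual": "R1",
            "time_point": tp,
            "cell_type": rng.choice(_CELL_TYPES, size=n_cells),
            "clonotype_key": pd.array(keys, dtype=object),
        })
        samples.append(RepertoireSample(
            individual="R1", time_point=tp, sample_id=f"R1_d{tp}",
            cells=cells))
    return TimeSeriesCohort(individual="R1", samples=samples)


def random_contig_table(rng: np.random.Generator, max_rows: int = 150,
                        max_tps: int = 6) -> pd.DataFrame:
    """Random productive contig table spanning several time points."""
    n_tps = int(rng.integers(2, max_tps + 1))
    tps = sorted(rng.choice(100, size=n_tps, replace=False).tolist())
    chains = ("IGH", "IGK", "IGL", "TRB")
    rows = []
    for tp in tps:
        for i in range(int(rng.integers(5, max_rows // n_tps + 5))):
            chain = chains[int(rng.integers(0, len(chains)))]
            rows.append({
                "barcode": f"BC{i:05d}",
                "sample_id": f"R1_d{tp}",
                "time_point": tp,
                "chain": chain,
                "v_gene": f"{chain}V{int(rng.integers(0, 4))}",
                "j_gene": f"{chain}J{int(rng.integers(0, 3))}",
                "cdr3": "CASSF",
                "cdr3_nt": f"NT{int(rng.integers(0, 12)):02d}",
                "c_gene": None,
                "umis": int(rng.integers(1, 10)),
                "productive": bool(rng.random() < 0.9),
            })
    return pd.DataFrame(rows)
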