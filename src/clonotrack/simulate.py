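"""Synthetic longitudinal PBMC cohort simulator.

Generates per-sample cell annotation tables, VDJ contig tables and a small
marker-gene expression matrix with the statistical structure the downstream
analysis assumes, together with the planted ground truth needed for recovery
testing:

* individual-specific cell-type compositions drawn from a Dirichlet around a
  baseline inside the canonical PBMC ranges (lymphocytes 70-90%, monocytes
  10-20%, CD4:CD8 roughly 2:1);
* heavy-tailed clonal repertoires: clone sizes follow a discrete power law
  P(size = s) proportional to s^-gamma truncated at the sample size;
* a per-individual pool of persistent (memory/effector) clonotypes that
  reappear across time points with a fixed intrinsic size, against a
  background of fresh single-time-point naive clonotypes with globally unique
  CDR3 nucleotide sequences;
* optional vaccination perturbations: a transient monocyte expansion around
  each dose and a set of induced clonotypes absent before the first dose that
  rise after dose 1 and are boosted after dose 2, with elevated CD69 in their
  cells.

Everything is driven by a single integer seed; identical configurations
produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator
from scipy import optimize, special

from .errors import ConfigurationError, LookupFailure
from .io import write_annotations, write_contigs, write_expression
from .keys import keys_from_cells
from . import vocab

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: default baseline composition over detailed cell types.  Lymphocytes sum to
#: 0.80, monocytes to 0.15, CD4:CD8 T cells are 0.39:0.19 (~2:1).
DEFAULT_BASELINE: dict[str, float] = {
    "CD4+ naive T": 0.19,
    "CD4+ memory T": 0.20,
    "CD8+ naive T": 0.08,
    "CD8+ effector T": 0.06,
    "CD8+ memory T": 0.05,
    "MAIT": 0.015,
    "gdT": 0.005,
    "naive B": 0.05,
    "memory B": 0.025,
    "plasmablast": 0.005,
    "NK": 0.12,
    "CD14+ monocyte": 0.12,
    "CD16+ monocyte": 0.03,
    "DC": 0.02,
    "platelet": 0.03,
}

DEFAULT_MARKER_MEANS: dict[str, dict[str, float]] = {
    "CD3E": {"T": 8.0, "*": 0.3},
    "CD69": {"T": 2.0, "NK": 3.0, "B": 1.0, "*": 0.5},
    "MS4A1": {"B": 10.0, "*": 0.2},
    "NKG7": {"NK": 12.0, "T": 1.5, "*": 0.2},
    "LYZ": {"Monocyte": 20.0, "DC": 10.0, "*": 0.3},
}


class IndividualSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    baseline_composition: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_BASELINE),
        validate_default=True)
    alpha: float = Field(default=500.0, gt=0.0,
                         description="Dirichlet concentration")

    @field_validator("baseline_composition")
    @classmethod
    def _check_composition(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(vocab.DETAILED_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types: {sorted(unknown)}")
        vals = np.array(list(v.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("baseline_composition has negative entries")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"baseline_composition sums to {vals.sum():.12f}, expected 1")
        return v


class MarkerSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gene: str
    mean: dict[str, float]  # major cell type -> NB mean; "*" = fallback
    dispersion: float = Field(default=2.0, gt=0.0)

    def mean_for(self, major: str) -> float:
        return self.mean.get(major, self.mean.get("*", 0.1))


class VaccinationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dose_days: list[int]
    monocyte_fold: float = Field(default=1.5, ge=1.0)
    monocyte_response_days: int = Field(default=3, ge=0)
    n_induced_clonotypes: int = Field(default=50, ge=0)
    induction_trajectory: dict[int, float] | None = None
    induced_base_cells: int = Field(default=3, ge=1)
    cd69_induced_factor: float = Field(default=4.0, ge=1.0)

    @field_validator("dose_days")
    @classmethod
    def _doses_increasing(cls, v: list[int]) -> list[int]:
        if not v:
            raise ValueError("dose_days is empty")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("dose_days must be strictly increasing")
        return v

    @field_validator("induction_trajectory")
    @classmethod
    def _traj_nonneg(cls, v):
        if v is not None and any(m < 0 for m in v.values()):
            raise ValueError("induction_trajectory multipliers must be >= 0")
        return v


def _default_markers() -> list[MarkerSpec]:
    return [MarkerSpec(gene=g, mean=dict(m)) for g, m in DEFAULT_MARKER_MEANS.items()]


class SimConfig(BaseModel):
    """Full generative specification of a synthetic cohort."""

    model_config = ConfigDict(extra="forbid")

    seed: int = Field(ge=0)
    individuals: list[IndividualSpec]
    time_points: list[int]
    cells_per_sample: int = Field(gt=0)
    clone_size_exponent: float = Field(default=2.5, gt=1.0)
    persistent_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    persistent_pool_size: int = Field(default=100, gt=0)
    b_pool_size: int = Field(default=60, gt=0)
    n_transition_clonotypes: int = Field(default=0, ge=0)
    vaccination: VaccinationSpec | None = None
    marker_panel: list[MarkerSpec] = Field(default_factory=_default_markers)
    dropout_rate_vdj: float = Field(default=0.1, ge=0.0, le=1.0)

    @field_validator("time_points")
    @classmethod
    def _tps_increasing(cls, v: list[int]) -> list[int]:
        if not v:
            raise ValueError("time_points is empty")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("time_points must be strictly increasing")
        return v

    @field_validator("individuals")
    @classmethod
    def _unique_ids(cls, v: list[IndividualSpec]) -> list[IndividualSpec]:
        ids = [ind.id for ind in v]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        if not ids:
            raise ValueError("individuals is empty")
        return v

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        """Validate a plain dict, raising ConfigurationError naming the field."""
        try:
            return cls.model_validate(data)
        except ValidationError as exc:
            fields = ", ".join(
                ".".join(str(p) for p in err["loc"]) or "<root>"
                for err in exc.errors())
            raise ConfigurationError(
                f"invalid simulation config (field(s): {fields}):\n{exc}") from exc

    def individual_spec(self, individual: str) -> IndividualSpec:
        for ind in self.individuals:
            if ind.id == individual:
                return ind
        raise LookupFailure(f"unknown individual: {individual!r}")


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a simulated cohort."""

    #: individual -> clonotype keys of the persistent pool (T and B)
    persistent_clonotypes: dict[str, set[str]] = dc_field(default_factory=dict)
    persistent_t_clonotypes: dict[str, set[str]] = dc_field(default_factory=dict)
    persistent_b_clonotypes: dict[str, set[str]] = dc_field(default_factory=dict)
    #: individual -> clonotype keys induced by vaccination (never emitted pre-dose)
    induced_clonotypes: dict[str, set[str]] = dc_field(default_factory=dict)
    #: (individual, time_point) -> expected detailed composition (multinomial p)
    expected_composition: dict[tuple[str, int], pd.Series] = dc_field(default_factory=dict)
    #: (individual, time_point) -> expected major-level composition
    expected_major_composition: dict[tuple[str, int], pd.Series] = dc_field(default_factory=dict)
    #: individual -> chain -> V-gene usage weights (Series over the panel)
    v_usage: dict[str, dict[str, pd.Series]] = dc_field(default_factory=dict)
    #: individual -> clonotype key -> planted detailed cell type
    clone_cell_types: dict[str, dict[str, str]] = dc_field(default_factory=dict)
    #: individual -> key -> {time_point: detailed type} for transition clones
    transition_schedule: dict[str, dict[str, dict[int, str]]] = dc_field(default_factory=dict)
    #: clonotype key -> isotype (C gene) for B clones
    clone_isotypes: dict[str, str] = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# Power-law clone sizes
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _powerlaw_pmf(gamma: float, s_max: int) -> np.ndarray:
    s = np.arange(1, s_max + 1, dtype=float)
    p = s ** (-gamma)
    return p / p.sum()


def sample_clone_sizes(rng: np.random.Generator, gamma: float, s_max: int,
                       n: int) -> np.ndarray:
    """Draw ``n`` iid clone sizes from the truncated discrete power law."""
    pmf = _powerlaw_pmf(float(gamma), int(s_max))
    return rng.choice(np.arange(1, s_max + 1), size=n, p=pmf)


def fit_clone_size_exponent(sizes, s_min: int = 1) -> float:
    """Maximum-likelihood exponent of a discrete power law P(s) ~ s^-gamma.

    Untruncated Hurwitz-zeta likelihood; adequate for fitted exponents well
    below the truncation point.  The simulator never calls this — it exists
    as an independent check on emitted clone-size distributions.
    """
    sizes = np.asarray(sizes, dtype=float)
    sizes = sizes[sizes >= s_min]
    if sizes.size == 0:
        raise ValueError("no clone sizes >= s_min")
    log_sum = np.log(sizes).sum()
    n = sizes.size

    def nll(gamma: float) -> float:
        return n * np.log(special.zeta(gamma, s_min)) + gamma * log_sum

    res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def _perturbed_baseline(config: SimConfig, spec: IndividualSpec,
                        time_point: int) -> pd.Series:
    base = pd.Series(spec.baseline_composition, dtype=float).reindex(
        vocab.DETAILED_TYPES, fill_value=0.0)
    vac = config.vaccination
    if vac is not None and any(
            d <= time_point <= d + vac.monocyte_response_days
            for d in vac.dose_days):
        mono = [t for t in vocab.DETAILED_TYPES
                if vocab.major_type(t) == "Monocyte"]
        base.loc[mono] *= vac.monocyte_fold
        base /= base.sum()
    return base


def simulate_composition_series(
    config: SimConfig,
    individual: str,
    time_point: int,
    size: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Dirichlet composition draw(s) for one individual at one time point.

    Returns a Series over detailed cell types (or a DataFrame with ``size``
    rows).  Vaccination time points have the monocyte components scaled by
    ``monocyte_fold`` before renormalization, so the expected monocyte
    proportion is ``fold*b / (1 + (fold-1)*b)`` for baseline proportion b.
    """
    spec = config.individual_spec(individual)
    if time_point not in config.time_points:
        raise LookupFailure(f"time point {time_point} not in config.time_points")
    base = _perturbed_baseline(config, spec, time_point)
    if rng is None:
        i_ind = [ind.id for ind in config.individuals].index(individual)
        i_tp = config.time_points.index(time_point)
        rng = np.random.default_rng([config.seed, 7, i_ind, i_tp])
    alpha = spec.alpha * base.to_numpy()
    # Dirichlet with zero concentration entries: keep them exactly zero
    pos = alpha > 0
    draws = np.zeros((size or 1, base.size))
    draws[:, pos] = rng.dirichlet(alpha[pos], size=size or 1)
    if size is None:
        return pd.Series(draws[0], index=base.index)
    return pd.DataFrame(draws, columns=base.index)


def _persistence_adjusted(comp: pd.Series, baseline: pd.Series,
                          persistent_fraction: float) -> pd.Series:
    """Redistribute T and B mass between naive and persistent subtypes.

    A fraction ``persistent_fraction`` of each repertoire lineage's mass goes
    to its memory/effector subtypes (clone-pool cells); the rest to naive
    subtypes (fresh clones).  Within each group the baseline's relative
    weights are kept.  Non-repertoire types are untouched.
    """
    out = comp.copy()
    for naive, persistent in ((vocab.NAIVE_T_TYPES, vocab.PERSISTENT_T_TYPES),
                              (vocab.NAIVE_B_TYPES, vocab.PERSISTENT_B_TYPES)):
        lineage = list(naive) + list(persistent)
        mass = comp.loc[lineage].sum()
        for group, frac in ((persistent, persistent_fraction),
                            (naive, 1.0 - persistent_fraction)):
            w = baseline.loc[list(group)].to_numpy()
            w = w / w.sum() if w.sum() > 0 else np.full(len(group), 1 / len(group))
            out.loc[list(group)] = mass * frac * w
    return out


# ---------------------------------------------------------------------------
# Clone machinery
# ---------------------------------------------------------------------------

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_CODON_TO_AA = {}


def _codon_table() -> dict[str, str]:
    global _CODON_TO_AA
    if not _CODON_TO_AA:
        from Bio.Seq import Seq
        _CODON_TO_AA = {c: str(Seq(c).translate()) for c in _SENSE_CODONS}
    return _CODON_TO_AA


def _fresh_cdr3(rng: np.random.Generator, used: set[str]) -> tuple[str, str]:
    """New in-frame CDR3 (nt, aa), 10-18 codons, unique within the run."""
    table = _codon_table()
    while True:
        n_codons = int(rng.integers(10, 19))
        idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
        nt = "".join(_SENSE_CODONS[i] for i in idx)
        if nt not in used:
            used.add(nt)
            aa = "C" + "".join(table[nt[i:i + 3]] for i in range(3, len(nt) - 3, 3)) + "F"
            return nt, aa


@dataclass
class _Chain:
    chain: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    d_gene: str | None = None
    c_gene: str | None = None


@dataclass
class _Clone:
    clone_id: str
    chains: list[_Chain]
    cell_type: str
    size: int = 1

    @property
    def key(self) -> str:
        return keys_from_cells(
            [(c.chain, c.v_gene, c.j_gene, c.cdr3_nt) for c in self.chains])


def _draw_gene(rng: np.random.Generator, chain: str,
               v_weights: dict[str, np.ndarray]) -> tuple[str, str, str | None]:
    v_panel = vocab.V_GENES[chain]
    v = v_panel[int(rng.choice(len(v_panel), p=v_weights[chain]))]
    j = vocab.J_GENES[chain][int(rng.integers(0, len(vocab.J_GENES[chain])))]
    d = None
    if chain in vocab.D_GENES:
        d = vocab.D_GENES[chain][int(rng.integers(0, len(vocab.D_GENES[chain])))]
    return v, j, d


def _make_t_clone(rng, clone_id, cell_type, used, v_weights, mait=False) -> _Clone:
    nt_a, aa_a = _fresh_cdr3(rng, used)
    nt_b, aa_b = _fresh_cdr3(rng, used)
    if mait:
        va, ja, da = vocab.MAIT_TRAV, vocab.MAIT_TRAJ, None
    else:
        va, ja, da = _draw_gene(rng, "TRA", v_weights)
    vb, jb, db = _draw_gene(rng, "TRB", v_weights)
    return _Clone(clone_id, [
        _Chain("TRA", va, ja, nt_a, aa_a, da, vocab.TR_C_GENES["TRA"]),
        _Chain("TRB", vb, jb, nt_b, aa_b, db, vocab.TR_C_GENES["TRB"]),
    ], cell_type)


def _make_b_clone(rng, clone_id, cell_type, used, v_weights, isotype) -> _Clone:
    nt_h, aa_h = _fresh_cdr3(rng, used)
    nt_l, aa_l = _fresh_cdr3(rng, used)
    vh, jh, dh = _draw_gene(rng, "IGH", v_weights)
    light = "IGK" if rng.random() < 0.6 else "IGL"
    vl, jl, dl = _draw_gene(rng, light, v_weights)
    return _Clone(clone_id, [
        _Chain("IGH", vh, jh, nt_h, aa_h, dh, isotype),
        _Chain(light, vl, jl, nt_l, aa_l, dl, vocab.LIGHT_C_GENES[light]),
    ], cell_type)


def _type_weights(baseline: pd.Series, types: tuple[str, ...]) -> np.ndarray:
    w = baseline.loc[list(types)].to_numpy()
    return w / w.sum() if w.sum() > 0 else np.full(len(types), 1 / len(types))


def _emit_pool(rng: np.random.Generator, pool: list[_Clone],
               budget: int) -> list[tuple[_Clone, int]]:
    """Fill ``budget`` cells from a clone pool.

    Clones are taken in a fresh random order with their fixed intrinsic
    sizes; the last clone is trimmed to the remaining budget.  If the pool's
    total size is insufficient the pass repeats (a clone may then contribute
    twice; counts merge downstream).
    """
    out: list[tuple[_Clone, int]] = []
    remaining = budget
    while remaining > 0:
        for i in rng.permutation(len(pool)):
            if remaining <= 0:
                break
            clone = pool[i]
            take = min(clone.size, remaining)
            out.append((clone, take))
            remaining -= take
    return out


# ---------------------------------------------------------------------------
# Vaccination helpers
# ---------------------------------------------------------------------------

def default_induction_trajectory(time_points: list[int],
                                 dose_days: list[int]) -> dict[int, float]:
    """Relative-frequency multipliers for induced clonotypes.

    Zero before the first dose; a rise-peak-decay pattern after dose 1 and a
    stronger boosted pattern after the second dose when present.
    """
    traj: dict[int, float] = {t: 0.0 for t in time_points}
    dose1 = dose_days[0]
    dose2 = dose_days[1] if len(dose_days) > 1 else None
    pattern1 = [1.0, 3.0, 5.0, 2.0]
    pattern2 = [5.0, 8.0, 4.0, 2.0]
    i1 = i2 = 0
    for t in time_points:
        if dose2 is not None and t > dose2:
            traj[t] = pattern2[min(i2, len(pattern2) - 1)]
            i2 += 1
        elif t > dose1:
            traj[t] = pattern1[min(i1, len(pattern1) - 1)]
            i1 += 1
    return traj


# ---------------------------------------------------------------------------
# Main entry point
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimConfig | dict,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate a full cohort.

    Returns ``(annotations, contigs, expression, truth)``:

    * ``annotations`` — one row per cell: barcode, sample_id, individual,
      time_point, cell_type, n_features, percent_mt;
    * ``contigs`` — Cell Ranger-dialect rows for T/B cells that survived VDJ
      dropout (one TRA+TRB or IGH+IGK/IGL pair per cell);
    * ``expression`` — marker-panel counts, one row per cell;
    * ``truth`` — the planted ground truth (see :class:`PlantedTruth`).
    """
    if isinstance(config, dict):
        config = SimConfig.from_dict(config)
    rng = np.random.default_rng(config.seed)
    used_cdr3: set[str] = set()
    truth = PlantedTruth()

    vac = config.vaccination
    trajectory: dict[int, float] = {}
    if vac is not None:
        trajectory = (dict(vac.induction_trajectory)
                      if vac.induction_trajectory is not None
                      else default_induction_trajectory(
                          config.time_points, vac.dose_days))

    ann_rows: list[tuple] = []
    contig_rows: list[tuple] = []
    expr_rows: list[tuple] = []
    markers = config.marker_panel

    n_tp = len(config.time_points)
    transition_split = (n_tp + 1) // 2  # first half effector, rest memory

    for spec in config.individuals:
        ind = spec.id
        baseline = pd.Series(spec.baseline_composition, dtype=float).reindex(
            vocab.DETAILED_TYPES, fill_value=0.0)

        # per-individual, per-chain V-gene usage weights (planted)
        v_weights = {
            chain: rng.dirichlet(np.full(len(panel), 2.0))
            for chain, panel in vocab.V_GENES.items()
        }
        truth.v_usage[ind] = {
            chain: pd.Series(w, index=vocab.V_GENES[chain])
            for chain, w in v_weights.items()
        }

        # ---- persistent pools ------------------------------------------
        t_sizes = sample_clone_sizes(rng, config.clone_size_exponent,
                                     config.cells_per_sample,
                                     config.persistent_pool_size)
        t_type_w = _type_weights(baseline, vocab.PERSISTENT_T_TYPES)
        t_pool: list[_Clone] = []
        for i in range(config.persistent_pool_size):
            ctype = vocab.PERSISTENT_T_TYPES[
                int(rng.choice(len(vocab.PERSISTENT_T_TYPES), p=t_type_w))]
            clone = _make_t_clone(rng, f"{ind}_Tp{i:04d}", ctype, used_cdr3,
                                  v_weights, mait=(ctype == "MAIT"))
            clone.size = int(t_sizes[i])
            t_pool.append(clone)

        b_sizes = sample_clone_sizes(rng, config.clone_size_exponent,
                                     config.cells_per_sample,
                                     config.b_pool_size)
        b_type_w = _type_weights(baseline, vocab.PERSISTENT_B_TYPES)
        b_pool: list[_Clone] = []
        for i in range(config.b_pool_size):
            ctype = vocab.PERSISTENT_B_TYPES[
                int(rng.choice(len(vocab.PERSISTENT_B_TYPES), p=b_type_w))]
            isotype = vocab.SWITCHED_ISOTYPES[
                int(rng.integers(0, len(vocab.SWITCHED_ISOTYPES)))]
            clone = _make_b_clone(rng, f"{ind}_Bp{i:04d}", ctype, used_cdr3,
                                  v_weights, isotype)
            clone.size = int(b_sizes[i])
            b_pool.append(clone)
            truth.clone_isotypes[clone.key] = isotype

        # transition clones: planted effector -> memory relabeling schedule
        transition: dict[str, dict[int, str]] = {}
        for clone in t_pool[:config.n_transition_clonotypes]:
            schedule = {
                tp: ("CD8+ effector T" if i < transition_split else "CD8+ memory T")
                for i, tp in enumerate(config.time_points)
            }
            transition[clone.key] = schedule
        truth.transition_schedule[ind] = transition

        truth.persistent_t_clonotypes[ind] = {c.key for c in t_pool}
        truth.persistent_b_clonotypes[ind] = {c.key for c in b_pool}
        truth.persistent_clonotypes[ind] = (
            truth.persistent_t_clonotypes[ind] | truth.persistent_b_clonotypes[ind])
        truth.clone_cell_types[ind] = {
            c.key: c.cell_type for c in t_pool + b_pool}

        # ---- induced clonotypes ----------------------------------------
        induced: list[_Clone] = []
        if vac is not None and vac.n_induced_clonotypes > 0:
            for i in range(vac.n_induced_clonotypes):
                ctype = "CD8+ effector T" if i % 2 == 0 else "CD4+ memory T"
                induced.append(_make_t_clone(
                    rng, f"{ind}_ind{i:04d}", ctype, used_cdr3, v_weights))
        truth.induced_clonotypes[ind] = {c.key for c in induced}
        induced_keys = truth.induced_clonotypes[ind]

        # ---- per-sample emission ---------------------------------------
        for time_point in config.time_points:
            sample_id = f"{ind}_d{time_point}"
            perturbed = _perturbed_baseline(config, spec, time_point)
            alpha = spec.alpha * perturbed.to_numpy()
            comp = np.zeros_like(alpha)
            pos = alpha > 0
            comp[pos] = rng.dirichlet(alpha[pos])
            comp = pd.Series(comp, index=perturbed.index)
            adjusted = _persistence_adjusted(
                comp, baseline, config.persistent_fraction)

            truth.expected_composition[(ind, time_point)] = adjusted
            truth.expected_major_composition[(ind, time_point)] = (
                adjusted.groupby(adjusted.index.map(vocab.major_type)).sum())

            counts = pd.Series(
                rng.multinomial(config.cells_per_sample, adjusted.to_numpy()),
                index=adjusted.index)

            # cells as (cell_type, clone-or-None) in deterministic order
            cells: list[tuple[str, _Clone | None]] = []

            # non-repertoire + naive cells keep their multinomial type counts
            for ctype in vocab.DETAILED_TYPES:
                if ctype in vocab.PERSISTENT_T_TYPES or ctype in vocab.PERSISTENT_B_TYPES:
                    continue
                n_cells = int(counts[ctype])
                if ctype in vocab.NAIVE_T_TYPES:
                    for _ in range(n_cells):
                        clone = _make_t_clone(
                            rng, "", ctype, used_cdr3, v_weights)
                        cells.append((ctype, clone))
                elif ctype in vocab.NAIVE_B_TYPES:
                    for _ in range(n_cells):
                        iso = vocab.NAIVE_ISOTYPES[
                            0 if rng.random() < 0.85 else 1]
                        clone = _make_b_clone(
                            rng, "", ctype, used_cdr3, v_weights, iso)
                        cells.append((ctype, clone))
                else:
                    cells.extend((ctype, None) for _ in range(n_cells))

            # persistent T/B budgets filled from the pools
            for pool, types in ((t_pool, vocab.PERSISTENT_T_TYPES),
                                (b_pool, vocab.PERSISTENT_B_TYPES)):
                budget = int(counts[list(types)].sum())
                for clone, n_cells in _emit_pool(rng, pool, budget):
                    ctype = transition.get(clone.key, {}).get(
                        time_point, clone.cell_type)
                    cells.extend((ctype, clone) for _ in range(n_cells))

            # induced clonotypes injected on top of the budget
            mult = trajectory.get(time_point, 0.0)
            if induced and mult > 0:
                n_per = int(round(vac.induced_base_cells * mult))
                for clone in induced:
                    cells.extend((clone.cell_type, clone) for _ in range(n_per))

            # shuffle cell order, then emit rows
            order = rng.permutation(len(cells))
            dropout = rng.random(len(cells)) < config.dropout_rate_vdj
            n_feat = np.maximum(
                20, rng.lognormal(np.log(1500.0), 0.45, len(cells))).astype(int)
            pct_mt = np.round(rng.gamma(2.0, 2.0, len(cells)), 4)

            for j, idx in enumerate(order):
                ctype, clone = cells[idx]
                barcode = f"BC{j:06d}-1"
                ann_rows.append((barcode, sample_id, ind, time_point, ctype,
                                 int(n_feat[j]), float(pct_mt[j])))

                is_induced = clone is not None and clone.key in induced_keys
                for m in markers:
                    mean = m.mean_for(vocab.major_type(ctype))
                    if m.gene == "CD69" and is_induced:
                        mean *= vac.cd69_induced_factor
                    r = m.dispersion
                    count = int(rng.negative_binomial(r, r / (r + mean))) if mean > 0 else 0
                    expr_rows.append((sample_id, barcode, m.gene, count))

                if clone is None or dropout[j]:
                    continue
                for ch in clone.chains:
                    umis = int(1 + rng.poisson(3.0))
                    contig_rows.append((
                        barcode, sample_id, ch.chain, ch.v_gene, ch.d_gene,
                        ch.j_gene, ch.c_gene, ch.cdr3_aa, ch.cdr3_nt,
                        umis, True, clone.clone_id))

    annotations = pd.DataFrame(ann_rows, columns=[
        "barcode", "sample_id", "individual", "time_point", "cell_type",
        "n_features", "percent_mt"])
    contigs = pd.DataFrame(contig_rows, columns=[
        "barcode", "sample_id", "chain", "v_gene", "d_gene", "j_gene",
        "c_gene", "cdr3", "cdr3_nt", "umis", "productive",
        "raw_clonotype_id"])
    expression = (
        pd.DataFrame(expr_rows,
                     columns=["sample_id", "barcode", "gene", "count"])
        .pivot_table(index=["sample_id", "barcode"], columns="gene",
                     values="count", fill_value=0, sort=True)
        .reset_index()
        .rename_axis(columns=None)
    )
    return annotations, contigs, expression, truth


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------

def write_cohort(outdir: str | Path, annotations: pd.DataFrame,
                 contigs: pd.DataFrame, expression: pd.DataFrame,
                 config: SimConfig) -> dict:
    """Write the simulated tables in the dialects the io module reads.

    One contig CSV per sample, a single annotation TSV and expression TSV,
    plus a JSON metadata file recording the seed and config.  Returns the
    manifest (sample -> file paths).
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_annotations(annotations, outdir / "annotations.tsv")
    write_expression(expression, outdir / "expression.tsv")
    manifest: dict = {"samples": {}}
    for sid, group in contigs.groupby("sample_id", sort=True):
        path = outdir / f"{sid}_contigs.csv"
        write_contigs(group.rename(columns={"cdr3": "cdr3_aa"}), path)
        manifest["samples"][str(sid)] = path.name
    manifest["annotations"] = "annotations.tsv"
    manifest["expression"] = "expression.tsv"
    manifest["seed"] = config.seed
    (outdir / "simulation_metadata.json").write_text(
        json.dumps({"seed": config.seed,
                    "config": config.model_dump(mode="json")}, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
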