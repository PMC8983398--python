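"""Reading/writing the standard single-cell VDJ and annotation tables, and the
barcode-level join between gene-expression annotations and VDJ clonotypes.

Input dialects
--------------
* Contigs: the Cell Ranger ``filtered_contig_annotations.csv`` dialect — a CSV
  whose header contains at least ``barcode, chain, v_gene, j_gene, cdr3,
  cdr3_nt, umis, productive`` (headers are case-sensitive).
* Annotations: TSV with ``barcode, sample_id, individual, time_point,
  cell_type, n_features, percent_mt``.
* Marker expression: wide TSV, one row per cell (``sample_id, barcode``
  followed by one column per gene).

Cell barcodes may carry a trailing GEM-well suffix (``-1``); the join strips
it on both sides because GEX and VDJ pipelines emit it inconsistently.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, JoinError
from .keys import DEFAULT_SCHEME, build_clonotype_keys, is_partial_key
from .vocab import CHAINS, GENE_PREFIX_TO_CHAIN

logger = logging.getLogger(__name__)

CONTIG_REQUIRED_COLUMNS = (
    "barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt",
    "umis", "productive",
)
ANNOTATION_COLUMNS = (
    "barcode", "sample_id", "individual", "time_point", "cell_type",
    "n_features", "percent_mt",
)

_TRUE_STRINGS = {"True", "true", "TRUE"}
_BARCODE_SUFFIX = re.compile(r"-\d$")


def normalize_barcode(barcode: str) -> str:
    """Strip a trailing ``-<digit>`` GEM-well suffix."""
    return _BARCODE_SUFFIX.sub("", barcode)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigRecord:
    """One assembled VDJ chain of one cell."""

    barcode: str
    sample_id: str
    chain: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    umis: int
    productive: bool
    d_gene: str | None = None
    c_gene: str | None = None
    raw_clonotype_id: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        flags = list(self.flags)
        if self.productive and len(self.cdr3_nt) % 3 != 0:
            flags.append("cdr3_nt_not_in_frame")
        implied = GENE_PREFIX_TO_CHAIN.get(self.v_gene[:3]) if self.v_gene else None
        if implied is not None and implied != self.chain:
            flags.append("chain_gene_mismatch")
        object.__setattr__(self, "flags", tuple(flags))


@dataclass(frozen=True)
class CellAnnotation:
    """Per-cell transcriptome annotation (cell type + QC metrics)."""

    barcode: str
    sample_id: str
    individual: str
    time_point: int
    cell_type: str
    n_features: int
    percent_mt: float


# ---------------------------------------------------------------------------
# Sample / cohort containers
# ---------------------------------------------------------------------------

@dataclass
class RepertoireSample:
    """Annotated cells of one individual at one time point, with clonotype keys.

    ``cells`` holds one row per annotated cell; ``clonotype_key`` is NA for
    cells without a recovered productive VDJ chain.
    """

    individual: str
    time_point: int
    sample_id: str
    cells: pd.DataFrame
    scheme: str = DEFAULT_SCHEME
    n_orphan_vdj: int = 0

    @property
    def clonotype_counts(self) -> pd.Series:
        keyed = self.cells["clonotype_key"].dropna()
        return keyed.value_counts()

    @property
    def n_keyed(self) -> int:
        return int(self.cells["clonotype_key"].notna().sum())

    def keys(self) -> set[str]:
        return set(self.cells["clonotype_key"].dropna().unique())


@dataclass
class TimeSeriesCohort:
    """Per-individual series of repertoire samples, ordered by time point."""

    individual: str
    samples: list[RepertoireSample] = field(default_factory=list)

    def __post_init__(self):
        self.samples = sorted(self.samples, key=lambda s: s.time_point)
        tps = [s.time_point for s in self.samples]
        if len(set(tps)) != len(tps):
            raise ValueError(
                f"duplicate time points for individual {self.individual}: {tps}")
        if any(s.individual != self.individual for s in self.samples):
            raise ValueError("cohort mixes individuals")

    @property
    def time_points(self) -> list[int]:
        return [s.time_point for s in self.samples]

    @property
    def scheme(self) -> str:
        return self.samples[0].scheme if self.samples else DEFAULT_SCHEME

    def cells(self) -> pd.DataFrame:
        """All cells across the series (columns include time_point)."""
        return pd.concat([s.cells for s in self.samples], ignore_index=True)

    def all_keys(self) -> set[str]:
        out: set[str] = set()
        for s in self.samples:
            out |= s.keys()
        return out


# ---------------------------------------------------------------------------
# Contig IO
# ---------------------------------------------------------------------------

def read_contigs(path: str | Path, sample_id: str) -> list[ContigRecord]:
    """Read a ``filtered_contig_annotations.csv``-dialect file.

    Malformed rows (unparsable UMI count, unknown chain, empty barcode or
    CDR3) are dropped and logged, never silently ignored.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CONTIG_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory contig column(s): {', '.join(missing)}")

    records: list[ContigRecord] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            umis = int(d["umis"])
            if umis < 0:
                raise ValueError
        except ValueError:
            n_bad += 1
            logger.warning("%s: dropping row with bad umis=%r", path, d["umis"])
            continue
        if d["chain"] not in CHAINS or not d["barcode"] or not d["cdr3_nt"]:
            n_bad += 1
            logger.warning(
                "%s: dropping malformed row (barcode=%r chain=%r)",
                path, d["barcode"], d["chain"])
            continue
        records.append(ContigRecord(
            barcode=d["barcode"],
            sample_id=sample_id,
            chain=d["chain"],
            v_gene=_gene_or_none(d["v_gene"]) or "",
            d_gene=_gene_or_none(d.get("d_gene", "")),
            j_gene=_gene_or_none(d["j_gene"]) or "",
            c_gene=_gene_or_none(d.get("c_gene", "")),
            cdr3_aa=d["cdr3"],
            cdr3_nt=d["cdr3_nt"],
            umis=umis,
            productive=d["productive"] in _TRUE_STRINGS,
            raw_clonotype_id=d.get("raw_clonotype_id", ""),
        ))
    if n_bad:
        logger.info("%s: dropped %d malformed contig rows", path, n_bad)
    return records


def _gene_or_none(value: str) -> str | None:
    return None if value in ("", "None", "none") else value


def contigs_to_frame(records: list[ContigRecord]) -> pd.DataFrame:
    """Tidy contig table (one row per contig) from records."""
    cols = ["barcode", "sample_id", "chain", "v_gene", "d_gene", "j_gene",
            "c_gene", "cdr3", "cdr3_nt", "umis", "productive",
            "raw_clonotype_id"]
    rows = [
        (r.barcode, r.sample_id, r.chain, r.v_gene, r.d_gene, r.j_gene,
         r.c_gene, r.cdr3_aa, r.cdr3_nt, r.umis, r.productive,
         r.raw_clonotype_id)
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)


def write_contigs(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a contig table in the Cell Ranger CSV dialect."""
    out = frame.copy()
    out["productive"] = out["productive"].map({True: "True", False: "False"})
    for col in ("d_gene", "c_gene"):
        if col in out.columns:
            out[col] = out[col].fillna("None")
    out.rename(columns={"cdr3_aa": "cdr3"}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Annotation / expression IO
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory annotation column(s): {', '.join(missing)}")
    df["time_point"] = df["time_point"].astype(int)
    df["n_features"] = df["n_features"].astype(int)
    df["percent_mt"] = df["percent_mt"].astype(float)
    return df


def write_annotations(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Wide marker-expression TSV: sample_id, barcode, then one column per gene."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "barcode"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing expression column {col!r}")
    return df


def write_expression(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GEX <-> VDJ join
# ---------------------------------------------------------------------------

def join_gex_vdj(
    cells: pd.DataFrame,
    key_map: dict[tuple[str, str], str],
    sample_id: str | None = None,
    scheme: str = DEFAULT_SCHEME,
) -> RepertoireSample:
    """Attach clonotype keys to annotated cells of one sample by barcode.

    Every annotated cell is kept; cells whose (suffix-normalized) barcode has
    no key get NA.  VDJ-side barcodes absent from the annotation table are
    counted in ``n_orphan_vdj`` and logged, never silently dropped.
    """
    if cells.empty:
        raise JoinError("no annotated cells supplied")
    sample_ids = set(cells["sample_id"].unique())
    if sample_id is None:
        if len(sample_ids) != 1:
            raise JoinError(f"cells span multiple samples: {sorted(sample_ids)}")
        sample_id = next(iter(sample_ids))
    elif sample_ids != {sample_id}:
        raise JoinError(
            f"sample_id mismatch: cells carry {sorted(sample_ids)}, "
            f"expected {sample_id!r}")

    norm_map: dict[str, str] = {}
    for (sid, bc), key in key_map.items():
        if sid == sample_id:
            norm_map[normalize_barcode(bc)] = key

    out = cells.copy().reset_index(drop=True)
    norm_bc = out["barcode"].map(normalize_barcode)
    if norm_bc.duplicated().any():
        raise JoinError(f"{sample_id}: duplicate cell barcodes after normalization")
    out["clonotype_key"] = norm_bc.map(norm_map)
    out["partial_key"] = out["clonotype_key"].map(
        lambda k: is_partial_key(k) if isinstance(k, str) else False)

    orphans = set(norm_map) - set(norm_bc)
    if orphans:
        logger.info(
            "%s: %d VDJ barcodes have no annotated cell", sample_id, len(orphans))

    individual = str(out["individual"].iloc[0])
    time_point = int(out["time_point"].iloc[0])
    return RepertoireSample(
        individual=individual,
        time_point=time_point,
        sample_id=sample_id,
        cells=out,
        scheme=scheme,
        n_orphan_vdj=len(orphans),
    )


def build_cohorts(
    annotations: pd.DataFrame,
    contigs: pd.DataFrame,
    scheme: str = DEFAULT_SCHEME,
) -> dict[str, TimeSeriesCohort]:
    """Join all samples and group them into per-individual cohorts."""
    key_map = build_clonotype_keys(contigs, scheme=scheme)
    cohorts: dict[str, list[RepertoireSample]] = {}
    for sid, cells in annotations.groupby("sample_id", sort=True):
        sample = join_gex_vdj(cells, key_map, sample_id=str(sid), scheme=scheme)
        cohorts.setdefault(sample.individual, []).append(sample)
    return {
        ind: TimeSeriesCohort(individual=ind, samples=samples)
        for ind, samples in sorted(cohorts.items())
    }
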