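"""Clonotype identity.

Two cells belong to the same clonotype when they carry the same recombined
receptor chains.  The canonical key is the lexicographically sorted
concatenation, over a cell's productive chains, of ``chain:v_gene:j_gene:cdr3``
segments joined by ``|``.  Sorting makes the key order-independent; using the
CDR3 nucleotide sequence (scheme ``paired_nt``, the default) is the strictest
reading of "same VDJ sequence" and matches the vendor default.

Schemes
-------
``paired_nt``
    all productive chains, CDR3 at nucleotide level (default).
``paired_aa``
    all productive chains, CDR3 at amino-acid level.
``single_chain:<CHAIN>``
    one chain only (e.g. ``single_chain:IGH``) — used for chain-resolved
    analyses such as heavy-chain overlap and isotype composition.

Cells with a single recovered productive chain keep a single-segment key; such
"partial" keys are automatically distinct from any paired key, so chain
dropout can never create false persistence matches.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError
from .vocab import CHAINS

DEFAULT_SCHEME = "paired_nt"
_SEGMENT_SEP = "|"


def parse_scheme(scheme: str) -> tuple[str, str | None]:
    """Validate *scheme* and return ``(mode, chain)``.

    ``mode`` is ``"paired_nt"``, ``"paired_aa"`` or ``"single_chain"``;
    ``chain`` is set only for single-chain schemes.
    """
    if scheme in ("paired_nt", "paired_aa"):
        return scheme, None
    if scheme.startswith("single_chain:"):
        chain = scheme.split(":", 1)[1]
        if chain not in CHAINS:
            raise ConfigurationError(
                f"scheme: unknown chain {chain!r} (expected one of {CHAINS})")
        return "single_chain", chain
    raise ConfigurationError(
        f"scheme: unknown clonotype keying scheme {scheme!r}")


def is_partial_key(key: str) -> bool:
    """True when the key covers a single chain (possible chain dropout)."""
    return bool(key) and _SEGMENT_SEP not in key


def chain_segment(chain: str, v_gene: str, j_gene: str, cdr3: str) -> str:
    return f"{chain}:{v_gene}:{j_gene}:{cdr3}"


def build_clonotype_keys(
    contigs: pd.DataFrame,
    scheme: str = DEFAULT_SCHEME,
) -> dict[tuple[str, str], str]:
    """Map ``(sample_id, barcode)`` to the cell's canonical clonotype key.

    Non-productive contigs are excluded.  When a cell carries several
    productive contigs of the same chain, the one with the highest UMI count
    wins (ties broken by lexicographically smallest ``cdr3_nt``).  Cells left
    with no productive contig are omitted from the mapping.

    Parameters
    ----------
    contigs
        Table with columns ``sample_id, barcode, chain, v_gene, j_gene,
        cdr3, cdr3_nt, umis, productive``.
    scheme
        Keying scheme (see module docstring).
    """
    mode, only_chain = parse_scheme(scheme)
    cdr3_col = "cdr3" if mode == "paired_aa" else "cdr3_nt"

    prod = contigs[contigs["productive"].astype(bool)]
    if only_chain is not None:
        prod = prod[prod["chain"] == only_chain]
    if prod.empty:
        return {}

    # best contig per (cell, chain): max UMIs, tie -> smallest cdr3_nt
    prod = prod.sort_values(
        ["sample_id", "barcode", "chain", "umis", "cdr3_nt"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    )
    best = prod.drop_duplicates(["sample_id", "barcode", "chain"], keep="first")

    segs = (
        best["chain"].astype(str) + ":" + best["v_gene"].astype(str)
        + ":" + best["j_gene"].astype(str) + ":" + best[cdr3_col].astype(str)
    )
    frame = pd.DataFrame({
        "sample_id": best["sample_id"].to_numpy(),
        "barcode": best["barcode"].to_numpy(),
        "seg": segs.to_numpy(),
    })
    joined = (
        frame.sort_values(["sample_id", "barcode", "seg"], kind="mergesort")
        .groupby(["sample_id", "barcode"], sort=False)["seg"]
        .agg(_SEGMENT_SEP.join)
    )
    return dict(joined.items())


def keys_from_cells(
    cell_chains: Iterable[tuple[str, str, str, str]],
) -> str:
    """Canonical key from explicit ``(chain, v, j, cdr3)`` tuples (any order)."""
    return _SEGMENT_SEP.join(sorted(chain_segment(*c) for c in cell_chains))


def key_chains(key: str) -> tuple[str, ...]:
    """Chains covered by a canonical key."""
    if not key:
        return ()
    return tuple(seg.split(":", 1)[0] for seg in key.split(_SEGMENT_SEP))


def receptor_class(key: str) -> str | None:
    """``"TCR"``, ``"BCR"`` or None (empty/mixed key)."""
    chains = set(key_chains(key))
    if chains and chains <= {"TRA", "TRB"}:
        return "TCR"
    if chains and chains <= {"IGH", "IGK", "IGL"}:
        return "BCR"
    return None


def check_same_scheme(scheme_a: str, scheme_b: str) -> None:
    from .errors import SchemeMismatchError

    if scheme_a != scheme_b:
        raise SchemeMismatchError(
            f"clonotype sets built under different schemes: "
            f"{scheme_a!r} vs {scheme_b!r}")


def key_map_to_frame(key_map: Mapping[tuple[str, str], str]) -> pd.DataFrame:
    """Tidy view of a key map: columns sample_id, barcode, clonotype_key, partial."""
    rows = [
        (s, b, k, is_partial_key(k)) for (s, b), k in key_map.items()
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "barcode", "clonotype_key", "partial"]
    )
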