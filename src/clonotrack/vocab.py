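"""Controlled vocabularies: cell types, receptor chains, gene-segment panels.

The detailed cell-type vocabulary follows the standard PBMC annotation used in
5' single-cell studies (Seurat/Azimuth-style labels).  Every detailed type maps
to exactly one major type; the composition machinery can aggregate freely.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Cell types
# ---------------------------------------------------------------------------

#: detailed label -> major label
DETAILED_TO_MAJOR: dict[str, str] = {
    "CD4+ naive T": "T",
    "CD4+ memory T": "T",
    "CD8+ naive T": "T",
    "CD8+ effector T": "T",
    "CD8+ memory T": "T",
    "MAIT": "T",
    "gdT": "T",
    "naive B": "B",
    "memory B": "B",
    "plasmablast": "B",
    "NK": "NK",
    "CD14+ monocyte": "Monocyte",
    "CD16+ monocyte": "Monocyte",
    "DC": "DC",
    "platelet": "Platelet",
}

MAJOR_TYPES: tuple[str, ...] = tuple(dict.fromkeys(DETAILED_TO_MAJOR.values()))
DETAILED_TYPES: tuple[str, ...] = tuple(DETAILED_TO_MAJOR)

#: T subtypes whose cells carry clonotypes from the persistent (memory) pool
PERSISTENT_T_TYPES: tuple[str, ...] = (
    "CD4+ memory T",
    "CD8+ effector T",
    "CD8+ memory T",
    "MAIT",
    "gdT",
)
NAIVE_T_TYPES: tuple[str, ...] = ("CD4+ naive T", "CD8+ naive T")

PERSISTENT_B_TYPES: tuple[str, ...] = ("memory B", "plasmablast")
NAIVE_B_TYPES: tuple[str, ...] = ("naive B",)

T_TYPES: tuple[str, ...] = NAIVE_T_TYPES + PERSISTENT_T_TYPES
B_TYPES: tuple[str, ...] = NAIVE_B_TYPES + PERSISTENT_B_TYPES


def major_type(detailed: str) -> str:
    if detailed not in DETAILED_TO_MAJOR:
        raise KeyError(f"unknown detailed cell type: {detailed!r}")
    return DETAILED_TO_MAJOR[detailed]


# ---------------------------------------------------------------------------
# Receptor chains
# ---------------------------------------------------------------------------

CHAINS: tuple[str, ...] = ("TRA", "TRB", "IGH", "IGK", "IGL")
T_CHAINS: tuple[str, ...] = ("TRA", "TRB")
B_CHAINS: tuple[str, ...] = ("IGH", "IGK", "IGL")

#: chain implied by a gene-segment name prefix (longest match wins)
GENE_PREFIX_TO_CHAIN: dict[str, str] = {
    "TRA": "TRA",
    "TRB": "TRB",
    "IGH": "IGH",
    "IGK": "IGK",
    "IGL": "IGL",
}

# ---------------------------------------------------------------------------
# Gene-segment panels used by the simulator (small but realistically named)
# ---------------------------------------------------------------------------

V_GENES: dict[str, tuple[str, ...]] = {
    "TRA": ("TRAV1-2", "TRAV8-2", "TRAV12-1", "TRAV13-1", "TRAV19",
            "TRAV21", "TRAV29DV5", "TRAV38-1"),
    "TRB": ("TRBV2", "TRBV5-1", "TRBV6-5", "TRBV7-9", "TRBV19",
            "TRBV20-1", "TRBV28", "TRBV30"),
    "IGH": ("IGHV1-2", "IGHV1-69", "IGHV3-23", "IGHV3-30", "IGHV4-34",
            "IGHV4-59", "IGHV5-51"),
    "IGK": ("IGKV1-5", "IGKV3-20", "IGKV4-1"),
    "IGL": ("IGLV1-44", "IGLV2-14", "IGLV3-21"),
}

J_GENES: dict[str, tuple[str, ...]] = {
    "TRA": ("TRAJ12", "TRAJ20", "TRAJ33", "TRAJ42", "TRAJ49"),
    "TRB": ("TRBJ1-1", "TRBJ1-2", "TRBJ2-1", "TRBJ2-3", "TRBJ2-7"),
    "IGH": ("IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6"),
    "IGK": ("IGKJ1", "IGKJ2", "IGKJ4"),
    "IGL": ("IGLJ2", "IGLJ3"),
}

D_GENES: dict[str, tuple[str, ...]] = {
    "TRB": ("TRBD1", "TRBD2"),
    "IGH": ("IGHD2-2", "IGHD3-10", "IGHD6-19"),
}

#: IGH constant-region classes (isotypes), heavy chain only
IGH_ISOTYPES: tuple[str, ...] = (
    "IGHM", "IGHD", "IGHG1", "IGHG2", "IGHG3", "IGHG4",
    "IGHA1", "IGHA2", "IGHE",
)
NAIVE_ISOTYPES: tuple[str, ...] = ("IGHM", "IGHD")
SWITCHED_ISOTYPES: tuple[str, ...] = ("IGHG1", "IGHG2", "IGHG3", "IGHA1")

LIGHT_C_GENES: dict[str, str] = {"IGK": "IGKC", "IGL": "IGLC2"}
TR_C_GENES: dict[str, str] = {"TRA": "TRAC", "TRB": "TRBC2"}

#: the semi-invariant MAIT alpha-chain rearrangement
MAIT_TRAV, MAIT_TRAJ = "TRAV1-2", "TRAJ33"

#: default marker panel simulated alongside the repertoire
DEFAULT_MARKER_PANEL: tuple[str, ...] = ("CD3E", "CD69", "MS4A1", "NKG7", "LYZ")
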