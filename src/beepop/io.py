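"""Flat-file dialects shared by the pipeline stages.

Everything is plain delimited text: roster CSV, design CSV (one row per
sample), PSM TSV (one row per spectrum match), ratio-matrix TSV (one row per
protein, one ``block:channel`` column per measurement), annotation TSV
(protein_id, term_id, ...) and pathway-map TSV (pathway_id, ..., protein_id).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .design import BlockDesign, design_frame, design_from_frame
from .roster import PopulationSpec, roster_frame

__all__ = [
    "write_roster", "read_roster",
    "write_design", "read_design",
    "write_psms", "read_psms",
    "write_ratio_matrix", "read_ratio_matrix",
    "read_annotations", "read_pathway_map",
]


def write_roster(roster: Sequence[PopulationSpec], path: str | Path) -> None:
    roster_frame(roster).to_csv(path, index=False)


def read_roster(path: str | Path) -> list[PopulationSpec]:
    df = pd.read_csv(path)
    return [
        PopulationSpec(str(r.population), int(r.n_colonies), float(r.latitude_deg))
        for r in df.itertuples()
    ]


def write_design(design: BlockDesign, path: str | Path) -> None:
    design_frame(design).to_csv(path, index=False)


def read_design(path: str | Path) -> BlockDesign:
    return design_from_frame(pd.read_csv(path))


def write_psms(psms: pd.DataFrame, path: str | Path) -> None:
    psms.to_csv(path, sep="\t", index=False)


def read_psms(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df


def write_ratio_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    flat = matrix.copy()
    flat.columns = [f"{b}:{ch}" for b, ch in matrix.columns]
    flat.to_csv(path, sep="\t", index=True, index_label="protein_id")


def read_ratio_matrix(path: str | Path) -> pd.DataFrame:
    flat = pd.read_csv(path, sep="\t", index_col="protein_id")
    cols = pd.MultiIndex.from_tuples(
        [tuple(c.split(":", 1)) for c in flat.columns], names=["block_id", "channel"]
    )
    flat.columns = cols
    return flat


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Annotation TSV (protein_id, term_id, ...) -> protein -> term-id set."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for pid, term in zip(df["protein_id"], df["term_id"]):
        out.setdefault(str(pid), set()).add(str(term))
    return out


def read_pathway_map(path: str | Path) -> dict[str, list[str]]:
    """Pathway TSV (pathway_id, ..., protein_id) -> pathway -> member ids."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for pw, pid in zip(df["pathway_id"], df["protein_id"]):
        out.setdefault(str(pw), []).append(str(pid))
    return out
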