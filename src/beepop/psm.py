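"""PSM filtering, decoy FDR, parsimonious protein inference and ratio assembly.

The assembly stage turns a peptide-spectrum-match table (one row per PSM with
three channel intensities) into a protein x (block, channel) log2 matrix:

1. score filter (ion score >= 25 by default);
2. decoy FDR estimate, rev / (for + rev), at the chosen cut-off;
3. minimal-set-cover protein grouping (Occam's razor): proteins whose
   peptides are explained by an already-accepted protein join that group as
   members instead of founding a new one;
4. per group and block, channel intensities are log2-transformed and averaged
   over the group's supporting peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import LABELS, BlockDesign

__all__ = [
    "ProteinGroup",
    "filter_psms",
    "estimate_fdr",
    "infer_protein_groups",
    "aggregate_ratios",
]

_INTENSITY_COLS = ["intensity_light", "intensity_medium", "intensity_heavy"]


@dataclass
class ProteinGroup:
    leader_accession: str
    member_accessions: set[str] = field(default_factory=set)
    supporting_peptides: set[str] = field(default_factory=set)

    @property
    def accessions(self) -> set[str]:
        return {self.leader_accession} | self.member_accessions


def _acc_list(value) -> list[str]:
    if isinstance(value, str):
        return [a for a in value.split(";") if a]
    return list(value)


def filter_psms(psms: pd.DataFrame, min_score: float = 25.0) -> pd.DataFrame:
    """Retain PSMs with ion_score >= min_score (boundary inclusive)."""
    return psms.loc[psms["ion_score"] >= min_score].copy()


def estimate_fdr(psms: pd.DataFrame) -> float:
    """Decoy FDR at the current cut-off: rev / (for + rev); 0 if empty."""
    if len(psms) == 0:
        return 0.0
    rev = int(psms["is_decoy"].sum())
    return rev / len(psms)


def infer_protein_groups(psms: pd.DataFrame) -> list[ProteinGroup]:
    """Greedy minimal set cover over target peptides.

    Proteins are ranked by distinct-peptide count (ties broken by accession so
    the result is deterministic). A protein whose peptide set is contained in
    an accepted group's peptides becomes a member of that group; a protein
    explaining at least one new peptide founds a new group; a protein covered
    only by the union of several groups joins the group sharing the most
    peptides with it. Every peptide ends up explained by at least one group.
    """
    targets = psms.loc[~psms["is_decoy"]]
    prot_peps: dict[str, set[str]] = {}
    for pep, accs in zip(targets["peptide_seq"], targets["accessions"]):
        for acc in _acc_list(accs):
            prot_peps.setdefault(acc, set()).add(pep)
    ranked = sorted(prot_peps, key=lambda a: (-len(prot_peps[a]), a))
    groups: list[ProteinGroup] = []
    covered: set[str] = set()
    for acc in ranked:
        peps = prot_peps[acc]
        host = None
        for g in groups:
            if peps <= g.supporting_peptides:
                host = g
                break
        if host is not None:
            host.member_accessions.add(acc)
            continue
        if peps - covered:
            groups.append(ProteinGroup(acc, set(), set(peps)))
            covered |= peps
        else:
            # explained only jointly; attach to the most-overlapping group
            best_i = max(
                range(len(groups)),
                key=lambda i: (len(peps & groups[i].supporting_peptides), -i),
            )
            groups[best_i].member_accessions.add(acc)
    return groups


def aggregate_ratios(
    groups: list[ProteinGroup],
    psms: pd.DataFrame,
    design: BlockDesign,
    shared: str = "all",
) -> pd.DataFrame:
    """Average log2 channel intensities per protein group and block.

    ``shared='all'`` (default) lets a peptide mapping to several groups count
    toward each; ``shared='unique'`` restricts every group to peptides that
    support no other group. Cells with no supporting PSM are NaN. Intensities
    of zero are treated as unquantified.
    """
    if shared not in {"all", "unique"}:
        raise ValueError("shared must be 'all' or 'unique'")
    known_blocks = set(design.block_ids)
    bad = set(psms["block_id"]) - known_blocks
    if bad:
        raise ValueError(f"PSM block ids absent from design: {sorted(bad)[:5]}")

    targets = psms.loc[~psms["is_decoy"]].copy()
    with np.errstate(divide="ignore"):
        logged = np.log2(targets[_INTENSITY_COLS].to_numpy(float))
    logged[~np.isfinite(logged)] = np.nan

    pep_groups: dict[str, list[int]] = {}
    for gi, g in enumerate(groups):
        for pep in g.supporting_peptides:
            pep_groups.setdefault(pep, []).append(gi)

    cols = pd.MultiIndex.from_product(
        [design.block_ids, LABELS], names=["block_id", "channel"]
    )
    block_pos = {b: i for i, b in enumerate(design.block_ids)}
    sums = np.zeros((len(groups), len(cols)))
    counts = np.zeros((len(groups), len(cols)))
    peps = targets["peptide_seq"].to_numpy()
    blocks = targets["block_id"].to_numpy()
    for i in range(len(targets)):
        gis = pep_groups.get(peps[i], ())
        if shared == "unique" and len(gis) > 1:
            continue
        base = block_pos[blocks[i]] * 3
        row = logged[i]
        for gi in gis:
            for k in range(3):
                if np.isfinite(row[k]):
                    sums[gi, base + k] += row[k]
                    counts[gi, base + k] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    index = pd.Index([g.leader_accession for g in groups], name="protein_id")
    return pd.DataFrame(values, index=index, columns=cols)
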