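"""Overlap statistics between population signatures and term enrichment.

Two populations' significant-protein sets are compared with the
representation factor

    RF = o * N / (n_x * n_y)

where ``o`` is the overlap, ``n_x`` and ``n_y`` the set sizes and ``N`` the
size of the quantified background; RF > 1 means more shared proteins than
expected by chance, and significance comes from the upper tail of the exact
hypergeometric distribution, P(X >= o). Term enrichment of a foreground set
against the same background uses the identical upper-tail test per term with
Benjamini-Hochberg FDR adjustment across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .lme import SignificanceTable

__all__ = [
    "OverlapResult",
    "representation_factor",
    "hypergeom_overlap_test",
    "similarity_matrix",
    "term_enrichment",
]


@dataclass(frozen=True)
class OverlapResult:
    pop_x: str
    pop_y: str
    n_overlap: int
    n_x: int
    n_y: int
    n_background: int
    representation_factor: float  # NaN when either set is empty
    p_value: float
    significant: bool


def _check_bounds(o: int, n_x: int, n_y: int, N: int) -> None:
    if not (0 <= o <= min(n_x, n_y) <= N):
        raise ValueError(f"invalid overlap counts: o={o}, n_x={n_x}, n_y={n_y}, N={N}")
    if n_x <= 0 or n_y <= 0:
        raise ValueError("set sizes must be positive")


def representation_factor(o: int, n_x: int, n_y: int, N: int) -> float:
    """Observed/expected overlap: o * N / (n_x * n_y)."""
    _check_bounds(o, n_x, n_y, N)
    return o * N / (n_x * n_y)


def hypergeom_overlap_test(o: int, n_x: int, n_y: int, N: int) -> float:
    """Exact one-tailed test: P(X >= o) with X ~ Hypergeom(N, n_x, n_y)."""
    _check_bounds(o, n_x, n_y, N)
    return float(hypergeom.sf(o - 1, N, n_x, n_y))


def similarity_matrix(
    sig_table: SignificanceTable,
    background_ids: Iterable[str],
    direction: str = "signed",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise overlap of population signatures against the background.

    ``direction='signed'`` (default) counts a protein as shared only when it
    moves the same way in both populations (up in both or down in both);
    ``'blind'`` ignores direction. Pairs where either signature is empty get a
    NaN representation factor and are flagged non-significant.
    """
    if direction not in {"signed", "blind"}:
        raise ValueError("direction must be 'signed' or 'blind'")
    background = set(background_ids)
    N = len(background)
    pops = list(sig_table.up)
    rows = []
    for i, px in enumerate(pops):
        for py in pops[i + 1 :]:
            ux, dx = sig_table.up[px] & background, sig_table.down[px] & background
            uy, dy = sig_table.up[py] & background, sig_table.down[py] & background
            n_x, n_y = len(ux | dx), len(uy | dy)
            if direction == "signed":
                o = len(ux & uy) + len(dx & dy)
            else:
                o = len((ux | dx) & (uy | dy))
            if n_x == 0 or n_y == 0:
                rows.append(
                    OverlapResult(px, py, o, n_x, n_y, N, float("nan"), 1.0, False)
                )
                continue
            rf = representation_factor(o, n_x, n_y, N)
            p = hypergeom_overlap_test(o, n_x, n_y, N)
            rows.append(OverlapResult(px, py, o, n_x, n_y, N, rf, p, p < alpha))
    return pd.DataFrame([r.__dict__ for r in rows])


def term_enrichment(
    foreground_ids: Iterable[str],
    background_ids: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every term hit by the foreground.

    ``annotations`` maps protein id -> term ids. Background proteins missing
    from the map count as un-annotated members of the background (they still
    inflate N), matching how a flat GO-slim table behaves. Raw P-values are
    BH-adjusted across the tested terms; rows are sorted by adjusted P.
    """
    background = set(background_ids)
    foreground = set(foreground_ids)
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    term_bg: dict[str, set[str]] = {}
    for pid in background:
        for t in annotations.get(pid, ()):
            term_bg.setdefault(t, set()).add(pid)
    N, n_fg = len(background), len(foreground)
    rows = []
    for term in sorted(term_bg):
        hits_bg = term_bg[term]
        hits_fg = hits_bg & foreground
        if not hits_fg:
            continue
        p = hypergeom_overlap_test(len(hits_fg), n_fg, len(hits_bg), N)
        rows.append(
            {
                "term_id": term,
                "n_fg_with_term": len(hits_fg),
                "n_fg": n_fg,
                "n_bg_with_term": len(hits_bg),
                "n_bg": N,
                "p_value": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "n_fg_with_term", "n_fg", "n_bg_with_term", "n_bg",
                "p_value", "fdr_adjusted_p", "significant",
            ]
        )
    out = pd.DataFrame(rows)
    out["fdr_adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr_adjusted_p"] < alpha
    return out.sort_values(["fdr_adjusted_p", "p_value", "term_id"]).reset_index(drop=True)
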