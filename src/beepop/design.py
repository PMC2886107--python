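"""Constrained randomized incomplete block design for triplex labelling.

Each block is one triplex LC-MS/MS run mixing three differentially labelled
samples. The design must satisfy:

* every sample (colony replicate) appears in exactly one block;
* the three labels within a block are distinct;
* the three colonies within a block are distinct and, under the strict
  population constraint, come from three distinct populations;
* across a colony's three replicates each label is used exactly once.

Designs are scored by a Ds-type criterion: the log-determinant of the
information submatrix for the population contrasts after adjusting for block
and label nuisance columns. Larger is better; it is the determinant analogue
of minimizing the standard errors of the population effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .roster import PopulationSpec

__all__ = [
    "LABELS",
    "SampleUnit",
    "BlockDesign",
    "DesignScore",
    "ConstraintReport",
    "InfeasibleDesignError",
    "enumerate_samples",
    "generate_design",
    "validate_design",
    "d_criterion",
    "design_frame",
    "design_from_frame",
]

#: Isotopologue channels in fixed order (light, medium, heavy formaldehyde).
LABELS: tuple[str, str, str] = ("light", "medium", "heavy")


class SampleUnit(NamedTuple):
    colony_id: str
    population: str
    replicate: int


class InfeasibleDesignError(ValueError):
    """No assignment can satisfy the block constraints for this roster."""


@dataclass(frozen=True)
class BlockDesign:
    """Ordered blocks; each block is three (sample, label) pairs."""

    blocks: tuple[tuple[tuple[SampleUnit, str], ...], ...]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_ids(self) -> list[str]:
        return [f"b{i + 1:02d}" for i in range(self.n_blocks)]

    def samples(self) -> list[SampleUnit]:
        return [s for block in self.blocks for s, _ in block]

    def channel_map(self) -> dict[tuple[str, str], SampleUnit]:
        """(block_id, label) -> sample unit; the key layout of a RatioMatrix."""
        out: dict[tuple[str, str], SampleUnit] = {}
        for bid, block in zip(self.block_ids, self.blocks):
            for s, lab in block:
                out[(bid, lab)] = s
        return out


@dataclass(frozen=True)
class DesignScore:
    criterion_value: float
    feasible: bool


@dataclass
class ConstraintReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def enumerate_samples(roster: Sequence[PopulationSpec], n_replicates: int = 3) -> list[SampleUnit]:
    """Expand a roster into sample units: each colony sampled in triplicate.

    Ordering is stable: populations in roster order, colonies numbered within
    population, replicates innermost.
    """
    if not roster:
        raise ValueError("roster is empty")
    units: list[SampleUnit] = []
    for pop in roster:
        for c in range(1, pop.n_colonies + 1):
            cid = f"{pop.name}-c{c}"
            for r in range(1, n_replicates + 1):
                units.append(SampleUnit(cid, pop.name, r))
    return units


# ---------------------------------------------------------------------------
# feasible construction


def _greedy_blocks(
    samples: Sequence[SampleUnit],
    rng: np.random.Generator,
    strict_populations: bool,
) -> list[list[str]]:
    """Partition colonies (with multiplicity) into blocks of three.

    Largest-remaining-first over populations (colonies, if not strict) keeps
    the schedule feasible whenever max multiplicity <= number of blocks.
    """
    colony_pop = {s.colony_id: s.population for s in samples}
    remaining: dict[str, int] = {}
    for s in samples:
        remaining[s.colony_id] = remaining.get(s.colony_id, 0) + 1
    n_blocks = len(samples) // 3
    blocks: list[list[str]] = []
    for _ in range(n_blocks):
        if strict_populations:
            pop_rem: dict[str, int] = {}
            for cid, k in remaining.items():
                if k > 0:
                    pop_rem[colony_pop[cid]] = pop_rem.get(colony_pop[cid], 0) + k
            pops = sorted(pop_rem)
            rng.shuffle(pops)
            pops.sort(key=lambda p: -pop_rem[p])  # stable: ties stay shuffled
            chosen_pops = pops[:3]
            block: list[str] = []
            for p in chosen_pops:
                cands = [c for c, k in remaining.items() if k > 0 and colony_pop[c] == p]
                rng.shuffle(cands)
                cands.sort(key=lambda c: -remaining[c])
                block.append(cands[0])
        else:
            cands = [c for c, k in remaining.items() if k > 0]
            rng.shuffle(cands)
            cands.sort(key=lambda c: -remaining[c])
            block = cands[:3]
        for c in block:
            remaining[c] -= 1
        blocks.append(block)
    return blocks


def _assign_labels(block_colonies: Sequence[Sequence[str]]) -> list[list[str]]:
    """Proper 3-edge-coloring of the colony x block incidence graph.

    Each colony meets each label once across its blocks and each block uses
    each label once. Alternating-chain recoloring (Konig) guarantees success
    on this bipartite graph with maximum degree three.
    """
    colony_color: dict[str, dict[str, int]] = {}
    block_color: list[dict[str, str]] = [dict() for _ in block_colonies]

    def flip_chain(start_block: int, a: str, b: str) -> None:
        edges: list[tuple[str, int, str]] = []
        node_is_block, node = True, start_block
        want = a
        while True:
            if node_is_block:
                c2 = block_color[node].get(want)
                if c2 is None:
                    break
                edges.append((c2, node, want))
                node_is_block, node = False, c2
            else:
                b2 = colony_color.get(node, {}).get(want)
                if b2 is None:
                    break
                edges.append((node, b2, want))
                node_is_block, node = True, b2
            want = b if want == a else a
        for c2, b2, col in edges:
            del colony_color[c2][col]
            del block_color[b2][col]
        for c2, b2, col in edges:
            other = b if col == a else a
            colony_color[c2][other] = b2
            block_color[b2][other] = c2

    for bi, cols in enumerate(block_colonies):
        for c in cols:
            used_c = colony_color.setdefault(c, {})
            free_c = [l for l in LABELS if l not in used_c]
            free_b = [l for l in LABELS if l not in block_color[bi]]
            common = [l for l in free_c if l in free_b]
            if common:
                lab = common[0]
            else:
                lab = free_c[0]
                flip_chain(bi, lab, free_b[0])
            colony_color[c][lab] = bi
            block_color[bi][lab] = c

    out: list[list[str]] = []
    for bi, cols in enumerate(block_colonies):
        inv = {c2: lab for lab, c2 in block_color[bi].items()}
        out.append([inv[c] for c in cols])
    return out


def _build_design(block_colonies: Sequence[Sequence[str]], colony_pop: dict[str, str]) -> BlockDesign:
    labels = _assign_labels(block_colonies)
    next_rep: dict[str, int] = {}
    blocks = []
    for cols, labs in zip(block_colonies, labels):
        entries = []
        for c, lab in zip(cols, labs):
            next_rep[c] = next_rep.get(c, 0) + 1
            entries.append((SampleUnit(c, colony_pop[c], next_rep[c]), lab))
        blocks.append(tuple(entries))
    return BlockDesign(tuple(blocks))


# ---------------------------------------------------------------------------
# scoring


def _model_columns(pops: np.ndarray, blocks: np.ndarray, labels: np.ndarray):
    """Sum-to-zero population contrasts plus intercept/block/label nuisance."""

    def onehot(v: np.ndarray) -> np.ndarray:
        u, inv = np.unique(v, return_inverse=True)
        d = np.zeros((len(v), len(u)))
        d[np.arange(len(v)), inv] = 1.0
        return d

    P = onehot(pops)
    if P.shape[1] < 2:
        return None, None
    S = P[:, :-1] - P[:, -1:]
    B = onehot(blocks)[:, 1:]
    L = onehot(labels)[:, 1:]
    nuisance = np.column_stack([np.ones(len(pops)), B, L])
    return S, nuisance


def d_criterion(design: BlockDesign, strict_populations: bool = True) -> DesignScore:
    """Ds-criterion: log det of the population-contrast information after
    projecting out intercept, block and label columns. -inf when singular."""
    pops, blocks, labels = [], [], []
    for bi, block in enumerate(design.blocks):
        for s, lab in block:
            pops.append(s.population)
            blocks.append(bi)
            labels.append(lab)
    S, N = _model_columns(np.array(pops), np.array(blocks), np.array(labels))
    if S is None:
        return DesignScore(float("-inf"), False)
    # residualize contrasts against nuisance, then take the Gram determinant
    coef, *_ = np.linalg.lstsq(N, S, rcond=None)
    R = S - N @ coef
    sign, logdet = np.linalg.slogdet(R.T @ R)
    if sign <= 0 or not np.isfinite(logdet):
        return DesignScore(float("-inf"), False)
    return DesignScore(float(logdet), True)


# ---------------------------------------------------------------------------
# validation


def validate_design(
    design: BlockDesign, expected_samples: Sequence[SampleUnit] | None = None
) -> ConstraintReport:
    """Check every block-design invariant; report lists each violation."""
    rep = ConstraintReport()
    seen: dict[tuple[str, int], int] = {}
    colony_labels: dict[str, list[str]] = {}
    for bi, block in enumerate(design.blocks):
        if len(block) != 3:
            rep.violations.append(f"block {bi}: has {len(block)} entries, expected 3")
        labs = [lab for _, lab in block]
        if len(set(labs)) != len(labs):
            rep.violations.append(f"block {bi}: duplicate labels {labs}")
        if any(lab not in LABELS for lab in labs):
            rep.violations.append(f"block {bi}: unknown label among {labs}")
        cols = [s.colony_id for s, _ in block]
        if len(set(cols)) != len(cols):
            rep.violations.append(f"block {bi}: duplicate colonies {cols}")
        ps = [s.population for s, _ in block]
        if len(set(ps)) != len(ps):
            rep.violations.append(f"block {bi}: populations not distinct {ps}")
        for s, lab in block:
            key = (s.colony_id, s.replicate)
            if key in seen:
                rep.violations.append(
                    f"sample {key} appears in blocks {seen[key]} and {bi}"
                )
            seen[key] = bi
            colony_labels.setdefault(s.colony_id, []).append(lab)
    for cid, labs in colony_labels.items():
        if len(labs) != len(set(labs)):
            rep.violations.append(f"colony {cid}: label used more than once {sorted(labs)}")
    if expected_samples is not None:
        want = {(s.colony_id, s.replicate) for s in expected_samples}
        got = set(seen)
        for missing in sorted(want - got):
            rep.violations.append(f"sample {missing} missing from design")
        for extra in sorted(got - want):
            rep.violations.append(f"unexpected sample {extra} in design")
    return rep


# ---------------------------------------------------------------------------
# optimization


def _check_feasible(samples: Sequence[SampleUnit], strict_populations: bool) -> None:
    n = len(samples)
    if n == 0 or n % 3:
        raise InfeasibleDesignError(f"sample count {n} not a positive multiple of 3")
    n_blocks = n // 3
    if strict_populations:
        counts: dict[str, int] = {}
        for s in samples:
            counts[s.population] = counts.get(s.population, 0) + 1
        if len(counts) < 3:
            raise InfeasibleDesignError(
                "strict population constraint needs >= 3 populations "
                f"(got {len(counts)})"
            )
        worst = max(counts, key=counts.get)
        if counts[worst] > n_blocks:
            raise InfeasibleDesignError(
                f"population {worst!r} supplies {counts[worst]} samples but only "
                f"{n_blocks} blocks exist"
            )
    else:
        counts = {}
        for s in samples:
            counts[s.colony_id] = counts.get(s.colony_id, 0) + 1
        if len(counts) < 3:
            raise InfeasibleDesignError("need >= 3 distinct colonies")
        worst = max(counts, key=counts.get)
        if counts[worst] > n_blocks:
            raise InfeasibleDesignError(
                f"colony {worst!r} has {counts[worst]} replicates but only "
                f"{n_blocks} blocks exist"
            )


def generate_design(
    samples: Sequence[SampleUnit],
    seed: int = 0,
    n_restarts: int = 3,
    n_sweeps: int = 2,
    strict_populations: bool = True,
) -> BlockDesign:
    """Seeded multi-restart exchange search for a high-Ds feasible design.

    Each restart builds a random feasible design, then greedily accepts
    colony swaps between blocks that preserve feasibility and improve the
    criterion. The best design over all restarts (including the unimproved
    random starts) is returned, so the result is never worse than the best
    purely random feasible design found under the same budget.
    """
    _check_feasible(samples, strict_populations)
    colony_pop = {s.colony_id: s.population for s in samples}
    rng = np.random.default_rng(seed)
    n_blocks = len(samples) // 3

    best_design: BlockDesign | None = None
    best_score = float("-inf")
    for _ in range(max(1, n_restarts)):
        bc = _greedy_blocks(samples, rng, strict_populations)
        design = _build_design(bc, colony_pop)
        score = d_criterion(design).criterion_value
        for _ in range(max(0, n_sweeps)):
            n_prop = 6 * n_blocks
            bi_arr = rng.integers(0, n_blocks, size=n_prop)
            bj_arr = rng.integers(0, n_blocks, size=n_prop)
            pi_arr = rng.integers(0, 3, size=n_prop)
            pj_arr = rng.integers(0, 3, size=n_prop)
            for bi, bj, pi, pj in zip(bi_arr, bj_arr, pi_arr, pj_arr):
                if bi == bj:
                    continue
                x, y = bc[bi][pi], bc[bj][pj]
                if x == y or x in bc[bj] or y in bc[bi]:
                    continue
                if strict_populations:
                    rest_i = {colony_pop[c] for k, c in enumerate(bc[bi]) if k != pi}
                    rest_j = {colony_pop[c] for k, c in enumerate(bc[bj]) if k != pj}
                    if colony_pop[y] in rest_i or colony_pop[x] in rest_j:
                        continue
                bc[bi][pi], bc[bj][pj] = y, x
                cand = _build_design(bc, colony_pop)
                cand_score = d_criterion(cand).criterion_value
                if cand_score > score + 1e-12:
                    design, score = cand, cand_score
                else:
                    bc[bi][pi], bc[bj][pj] = x, y
        if score > best_score:
            best_design, best_score = design, score
    assert best_design is not None
    report = validate_design(best_design, samples)
    if not report.ok:  # pragma: no cover - construction guarantees validity
        raise InfeasibleDesignError("; ".join(report.violations))
    return best_design


# ---------------------------------------------------------------------------
# round-tripping


def design_frame(design: BlockDesign) -> pd.DataFrame:
    """One row per sample: block_id, colony_id, population, replicate, label."""
    rows = []
    for bid, block in zip(design.block_ids, design.blocks):
        for s, lab in block:
            rows.append((bid, s.colony_id, s.population, s.replicate, lab))
    return pd.DataFrame(
        rows, columns=["block_id", "colony_id", "population", "replicate", "label"]
    )


def design_from_frame(df: pd.DataFrame) -> BlockDesign:
    blocks = []
    for _, sub in df.groupby("block_id", sort=True):
        entries = tuple(
            (SampleUnit(r.colony_id, r.population, int(r.replicate)), r.label)
            for r in sub.itertuples()
        )
        blocks.append(entries)
    return BlockDesign(tuple(blocks))
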