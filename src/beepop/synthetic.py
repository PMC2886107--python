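"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates, on the log2 scale, what a triplex dimethyl-labelling
experiment produces per protein and block: three channel measurements that
combine a population effect (zero-mean across populations), a block effect,
a label effect, a colony random intercept and Gaussian residual noise, with
whole protein x block cells missing at random. A companion PSM simulator
feeds the identification/assembly stage, including reversed-decoy records.

Effect sizes and noise levels are calibration choices, not reproductions:
the defaults are typical of replicate variability in dimethyl-labelling
work (residual sd 0.25 log2 units, colony sd 0.10, ~30% missingness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import LABELS, BlockDesign, validate_design

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "simulate_ratio_matrix",
    "simulate_psm_table",
]


@dataclass(frozen=True)
class GroundTruth:
    """Planted simulation parameters, the oracle for recovery tests.

    ``population_effect`` is proteins x populations, each row summing to zero
    (relative expression is only defined up to the across-population mean).
    Block and label effects are shared across proteins; the colony intercepts
    are drawn inside the simulator from ``colony_sd``.
    """

    populations: tuple[str, ...]
    population_effect: np.ndarray  # (n_proteins, n_populations)
    block_effect: np.ndarray  # (n_blocks,)
    label_effect: np.ndarray  # (3,) in LABELS order
    colony_sd: float = 0.10
    residual_sd: float = 0.25
    missing_prob: float = 0.30
    decoy_frac: float = 0.01

    def __post_init__(self) -> None:
        pe = np.asarray(self.population_effect, float)
        if pe.ndim != 2 or pe.shape[1] != len(self.populations):
            raise ValueError("population_effect must be (n_proteins, n_populations)")
        if not np.allclose(pe.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("population effects must sum to zero per protein")
        if len(self.label_effect) != 3:
            raise ValueError("label_effect must have three entries")
        for name in ("colony_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("missing_prob", "decoy_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_proteins(self) -> int:
        return self.population_effect.shape[0]


def make_ground_truth(
    design: BlockDesign,
    n_proteins: int,
    seed: int = 0,
    effect_sd: float = 0.5,
    frac_differential: float = 0.25,
    block_sd: float = 0.2,
    label_sd: float = 0.05,
    colony_sd: float = 0.10,
    residual_sd: float = 0.25,
    missing_prob: float = 0.30,
    decoy_frac: float = 0.01,
) -> GroundTruth:
    """Draw a GroundTruth for a design: a fraction of proteins receive
    zero-mean population effects of scale ``effect_sd``; the rest are null."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    pops = tuple(dict.fromkeys(s.population for s in design.samples()))
    pe = np.zeros((n_proteins, len(pops)))
    n_diff = int(round(frac_differential * n_proteins))
    if n_diff and effect_sd > 0:
        idx = rng.choice(n_proteins, size=n_diff, replace=False)
        raw = rng.normal(0.0, effect_sd, size=(n_diff, len(pops)))
        pe[np.sort(idx)] = raw - raw.mean(axis=1, keepdims=True)
    return GroundTruth(
        populations=pops,
        population_effect=pe,
        block_effect=rng.normal(0.0, block_sd, size=design.n_blocks),
        label_effect=rng.normal(0.0, label_sd, size=3),
        colony_sd=colony_sd,
        residual_sd=residual_sd,
        missing_prob=missing_prob,
        decoy_frac=decoy_frac,
    )


def simulate_ratio_matrix(
    design: BlockDesign,
    truth: GroundTruth,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a protein x (block, channel) log2 ratio matrix.

    Each observed cell's channel value is the sum of the population, block,
    label and colony effects plus Normal(0, residual_sd) noise; a protein is
    missing from a block (all three channels NaN) with ``missing_prob``,
    independently across proteins and blocks. Deterministic for a fixed seed.
    """
    report = validate_design(design)
    if not report.ok:
        raise ValueError("invalid design: " + "; ".join(report.violations[:3]))
    rng = np.random.default_rng(seed)
    n_p = truth.n_proteins
    pops = list(truth.populations)
    colonies = list(dict.fromkeys(s.colony_id for s in design.samples()))
    colony_eff = rng.normal(0.0, truth.colony_sd, size=(n_p, len(colonies)))
    col_idx = {c: i for i, c in enumerate(colonies)}
    pop_idx = {p: i for i, p in enumerate(pops)}

    observed = rng.random(size=(n_p, design.n_blocks)) >= truth.missing_prob
    cols = pd.MultiIndex.from_product(
        [design.block_ids, LABELS], names=["block_id", "channel"]
    )
    values = np.full((n_p, len(cols)), np.nan)
    noise = rng.normal(0.0, truth.residual_sd, size=(n_p, design.n_blocks, 3))
    lab_pos = {lab: k for k, lab in enumerate(LABELS)}
    for bi, block in enumerate(design.blocks):
        obs = observed[:, bi]
        for s, lab in block:
            k = lab_pos[lab]
            v = (
                truth.population_effect[:, pop_idx[s.population]]
                + truth.block_effect[bi]
                + truth.label_effect[k]
                + colony_eff[:, col_idx[s.colony_id]]
                + noise[:, bi, k]
            )
            values[obs, bi * 3 + k] = v[obs]
    index = pd.Index([f"P{i + 1:04d}" for i in range(n_p)], name="protein_id")
    return pd.DataFrame(values, index=index, columns=cols)


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_peptides(rng: np.random.Generator, n: int, length: int = 10) -> list[str]:
    letters = rng.integers(0, len(_AA), size=(n, length))
    return ["".join(_AA[row]) + "K" for row in letters]


def simulate_psm_table(
    n_targets: int,
    n_decoys: int,
    score_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    peptide_map: Mapping[str, Sequence[str]] | None = None,
    block_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate a peptide-spectrum-match table.

    Target records map to accessions ``ACC0001...``; decoys are flagged and
    map to reversed accessions. ``peptide_map`` (peptide -> accession list)
    injects shared-peptide structure for the parsimony stage: its entries are
    cycled over the target records in order. ``score_dist(rng, n)`` draws ion
    scores; by default targets ~ N(45, 12) and decoys ~ N(18, 6), floored at 0.
    """
    if n_targets < 0 or n_decoys < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_targets + n_decoys
    if score_dist is not None:
        scores = np.asarray(score_dist(rng, n), float)
    else:
        scores = np.concatenate(
            [
                rng.normal(45.0, 12.0, size=n_targets),
                rng.normal(18.0, 6.0, size=n_decoys),
            ]
        )
    scores = np.clip(scores, 0.0, None)
    if peptide_map is not None:
        items = list(peptide_map.items())
        peptides = [items[i % len(items)][0] for i in range(n_targets)]
        accs = [";".join(items[i % len(items)][1]) for i in range(n_targets)]
    else:
        peptides = _random_peptides(rng, n_targets)
        accs = [f"ACC{rng.integers(1, max(2, n_targets // 3)):04d}" for _ in range(n_targets)]
    dec_peps = _random_peptides(rng, n_decoys)
    dec_accs = [f"REV_ACC{i + 1:04d}" for i in range(n_decoys)]
    blocks = list(block_ids) if block_ids is not None else ["b01"]
    intensities = rng.lognormal(mean=14.0, sigma=1.0, size=(n, 3))
    return pd.DataFrame(
        {
            "peptide_seq": peptides + dec_peps,
            "accessions": accs + dec_accs,
            "is_decoy": [False] * n_targets + [True] * n_decoys,
            "ion_score": scores,
            "block_id": [blocks[i % len(blocks)] for i in range(n)],
            "intensity_light": intensities[:, 0],
            "intensity_medium": intensities[:, 1],
            "intensity_heavy": intensities[:, 2],
        }
    )
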