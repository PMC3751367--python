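"""Synthetic inputs: a deterministic worked example and seeded simulations.

:func:`toy_example` is a fixed 5-gene, 4-timepoint, triplicate,
two-condition dataset (plus a 5-node star GRN) whose pipeline outputs hit
an exact set of reference quantities used throughout the test suite.

:func:`simulate` produces seeded datasets with planted condition-specific
co-regulated modules, condition-shared co-expression, background noise and
a GRN that preferentially wires module genes together, plus a ground-truth
description for recovery scoring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .impact import build_grn
from .miner import TopKResult
from .relations import disassemble
from .transactions import DOWN, UP, ExpressionDataset, InputError

TOY_CONDITIONS = ("Condition1", "Condition2")

# Per (condition, gene, timepoint): the three replicate values.  Cells marked
# "constrained" are forced by the reference quantities the pipeline must
# reproduce; all other cells are free and fixed arbitrarily at values that
# create no items.  The constrained outcomes are:
#   integrated Condition1:      q(G5down, T1) = 3
#   differentiated Condition1:  q(G4up, T4) = 2   (integrated 3 vs 1)
#   differentiated Condition2:  q(G5down, T4) = 3 (integrated 0 vs 3),
#                               q(G1up, T1) = 2, q(G5up, T1) = 1, q(G5up, T2) = 2
#   significant genes: {G1, G3, G4, G5}; G2 not significant
#   impact degrees on the star GRN: d(G1) = 3, d(G5) = 1
# Significance for G1/G3/G4/G5 is pinned by zero-variance mean shifts inside
# the (-0.2, 0.2) band (0.1 vs -0.1), which create no items; G2 is identical
# in both conditions everywhere.
_TOY_VALUES = {
    ("Condition1", "G1"): {1: (0.0, 0.0, 0.0), 2: (0.0, 0.0, 0.0),
                           3: (0.1, 0.1, 0.1), 4: (0.0, 0.0, 0.0)},
    ("Condition1", "G2"): {1: (0.0, 0.0, 0.0), 2: (0.0, 0.0, 0.0),
                           3: (0.0, 0.0, 0.0), 4: (0.0, 0.0, 0.0)},
    ("Condition1", "G3"): {1: (0.0, 0.0, 0.0), 2: (0.1, 0.1, 0.1),
                           3: (0.0, 0.0, 0.0), 4: (0.0, 0.0, 0.0)},
    ("Condition1", "G4"): {1: (0.1, 0.1, 0.1), 2: (0.0, 0.0, 0.0),
                           3: (0.0, 0.0, 0.0), 4: (0.3, 0.3, 0.3)},  # constrained: T4 up x3
    ("Condition1", "G5"): {1: (-0.3, -0.3, -0.3),                      # constrained: T1 down x3
                           2: (0.0, 0.0, 0.0), 3: (0.1, 0.1, 0.1), 4: (0.0, 0.0, 0.0)},
    ("Condition2", "G1"): {1: (0.3, 0.3, 0.0),                         # constrained: T1 up x2
                           2: (0.0, 0.0, 0.0), 3: (-0.1, -0.1, -0.1), 4: (0.0, 0.0, 0.0)},
    ("Condition2", "G2"): {1: (0.0, 0.0, 0.0), 2: (0.0, 0.0, 0.0),
                           3: (0.0, 0.0, 0.0), 4: (0.0, 0.0, 0.0)},
    ("Condition2", "G3"): {1: (0.0, 0.0, 0.0), 2: (-0.1, -0.1, -0.1),
                           3: (0.0, 0.0, 0.0), 4: (0.0, 0.0, 0.0)},
    ("Condition2", "G4"): {1: (-0.1, -0.1, -0.1), 2: (0.0, 0.0, 0.0),
                           3: (0.0, 0.0, 0.0), 4: (0.3, 0.0, 0.0)},   # constrained: T4 up x1
    ("Condition2", "G5"): {1: (0.3, 0.0, 0.0),                         # constrained: T1 up x1
                           2: (0.3, 0.3, 0.0),                         # constrained: T2 up x2
                           3: (-0.1, -0.1, -0.1),
                           4: (-0.3, -0.3, -0.3)},                     # constrained: T4 down x3
}

TOY_GRN_EDGES = (("G1", "G2"), ("G1", "G3"), ("G1", "G4"), ("G1", "G5"))


def toy_example() -> tuple[ExpressionDataset, nx.Graph]:
    """The deterministic worked-example dataset and its star GRN."""
    genes = ["G1", "G2", "G3", "G4", "G5"]
    timepoints = [1, 2, 3, 4]
    replicates = [1, 2, 3]
    cols: dict[str, list[float]] = {}
    rows = []
    for cond in TOY_CONDITIONS:
        for rep in replicates:
            for tp in timepoints:
                sid = f"{cond.lower()}_r{rep}_t{tp}"
                cols[sid] = [_TOY_VALUES[(cond, g)][tp][rep - 1] for g in genes]
                rows.append({"sample_id": sid, "condition": cond,
                             "replicate": rep, "timepoint": tp})
    values = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(rows).set_index("sample_id")
    grn = build_grn(TOY_GRN_EDGES)
    return ExpressionDataset(values, samples), grn


# ---------------------------------------------------------------------------
# seeded simulation


@dataclass
class SimulationParams:
    """Knobs of the planted-module simulation.

    Defaults describe the standard recovery scenario: 50 genes over 8
    timepoints in triplicate, two condition-specific modules of 4 genes
    (alternating up/down, each active in its own half of the time course)
    planted in the treatment condition with per-replicate threshold-crossing
    probability ``p_signal``, a 12-gene co-expressed set shared by both
    conditions (the non-differential transcriptional program that
    differentiation is meant to cancel), Gaussian background with
    occasional threshold-crossing flips, and a GRN that is dense inside
    modules and sparse elsewhere.
    """

    n_genes: int = 50
    n_timepoints: int = 8
    n_replicates: int = 3
    n_modules: int = 2
    module_size: int = 4
    p_signal: float = 0.9
    background_sd: float = 0.05  # log10 units
    background_flip_prob: float = 0.02
    within_module_edge_prob: float = 0.9
    background_edge_prob: float = 0.02
    n_shared_genes: int = 12
    signal_magnitude: float = 0.5  # log10 units, well past the 0.2 threshold
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_signal", "background_flip_prob",
                     "within_module_edge_prob", "background_edge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        if self.module_size < 2:
            raise InputError(f"module size must be >= 2, got {self.module_size}")
        if self.n_modules * self.module_size + self.n_shared_genes > self.n_genes:
            raise InputError(
                "infeasible params: "
                f"{self.n_modules} modules x {self.module_size} genes "
                f"+ {self.n_shared_genes} shared genes exceed {self.n_genes} genes"
            )
        if self.n_replicates < 1 or self.n_timepoints < 1:
            raise InputError("need at least 1 replicate and 1 timepoint")


CONTROL = "control"
TREATMENT = "treatment"


def _module_windows(n_timepoints: int, n_modules: int) -> list[list[int]]:
    """Split 1..T into contiguous per-module activity windows."""
    bounds = np.linspace(0, n_timepoints, n_modules + 1).round().astype(int)
    return [list(range(bounds[m] + 1, bounds[m + 1] + 1)) for m in range(n_modules)]


def simulate(params: SimulationParams) -> tuple[ExpressionDataset, nx.Graph, dict]:
    """Generate a seeded dataset with planted differential modules.

    Returns the dataset, the GRN and a ground-truth dict with the planted
    modules (genes, direction, active timepoints), the shared gene set and
    the list of true within-module item pairs.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes = [f"g{i + 1:03d}" for i in range(params.n_genes)]
    modules = []
    cursor = 0
    windows = _module_windows(params.n_timepoints, params.n_modules)
    for m in range(params.n_modules):
        mod_genes = genes[cursor:cursor + params.module_size]
        cursor += params.module_size
        modules.append({
            "genes": mod_genes,
            "direction": UP if m % 2 == 0 else DOWN,
            "timepoints": windows[m],
        })
    shared = genes[cursor:cursor + params.n_shared_genes]
    gene_idx = {g: i for i, g in enumerate(genes)}
    timepoints = list(range(1, params.n_timepoints + 1))
    replicates = list(range(1, params.n_replicates + 1))

    signal_cell: dict[tuple[str, str, int], float] = {}  # (cond, gene, tp) -> signed magnitude
    for mod in modules:
        sign = 1.0 if mod["direction"] == UP else -1.0
        for g in mod["genes"]:
            for tp in mod["timepoints"]:
                signal_cell[(TREATMENT, g, tp)] = sign
    for g in shared:
        for tp in timepoints:
            signal_cell[(CONTROL, g, tp)] = 1.0
            signal_cell[(TREATMENT, g, tp)] = 1.0

    cols: dict[str, np.ndarray] = {}
    rows = []
    for cond in (CONTROL, TREATMENT):
        for rep in replicates:
            for tp in timepoints:
                base = rng.normal(0.0, params.background_sd, size=params.n_genes)
                flips = rng.random(params.n_genes) < params.background_flip_prob
                flip_sign = rng.choice([-1.0, 1.0], size=params.n_genes)
                base = np.where(flips, flip_sign * 0.35, base)
                for g in genes:
                    sign = signal_cell.get((cond, g, tp))
                    if sign is not None and rng.random() < params.p_signal:
                        base[gene_idx[g]] = sign * params.signal_magnitude + rng.normal(0.0, 0.05)
                sid = f"{cond}_r{rep}_t{tp}"
                cols[sid] = base.copy()
                rows.append({"sample_id": sid, "condition": cond,
                             "replicate": rep, "timepoint": tp})
    values = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(rows).set_index("sample_id")
    dataset = ExpressionDataset(values, samples)

    edges = []
    module_mates = set()
    for mod in modules:
        for a, b in itertools.combinations(mod["genes"], 2):
            module_mates.add(frozenset((a, b)))
            if rng.random() < params.within_module_edge_prob:
                edges.append((a, b))
    for a, b in itertools.combinations(genes, 2):
        if frozenset((a, b)) in module_mates:
            continue
        if rng.random() < params.background_edge_prob:
            edges.append((a, b))
    grn = build_grn(edges, nodes=genes)

    truth = {
        "conditions": [CONTROL, TREATMENT],
        "signal_condition": TREATMENT,
        "modules": modules,
        "shared_genes": shared,
        "item_pairs": [
            [[ga, mod["direction"]], [gb, mod["direction"]]]
            for mod in modules
            for ga, gb in itertools.combinations(sorted(mod["genes"]), 2)
        ],
        "params": asdict(params),
    }
    return dataset, grn, truth


def true_module_pairs(truth: Mapping) -> set[frozenset]:
    """Direction-aware within-module item pairs from a ground-truth dict."""
    return {
        frozenset(((a, da), (b, db)))
        for (a, da), (b, db) in truth["item_pairs"]
    }


def module_pair_recall(results: Mapping[str, TopKResult], truth: Mapping) -> float:
    """Fraction of true within-module item pairs found in the disassembled top-k.

    Pairs are pooled over both conditions' result lists.
    """
    target = true_module_pairs(truth)
    found: set[frozenset] = set()
    for topk in results.values():
        found |= disassemble(topk).pairs()
    return len(found & target) / len(target)
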