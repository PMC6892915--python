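"""Synthetic expression compendia with known ground truth.

The generator emulates the generative model behind the decomposition:
X = S_true A_true + noise, with sparse unit-norm gene-weight columns
(each planted module has a small member set whose |weights| dominate a
weak Gaussian background), condition-block activities with replicate
jitter, two designated reference samples with zero true activity, and a
matching toy regulator->gene table (each module's regulator covers a
configurable fraction of its members, plus size-matched decoy regulons
that test enrichment specificity).

Activity levels are drawn from a sparse signed-block distribution: a
condition is either inactive (level 0) or active at a level far from
zero.  This makes the sources strongly non-Gaussian, which is what makes
them identifiable by ICA in the first place; the i.i.d. Gaussian noise
floor is what the robustness filtering must reject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compendium import Compendium, RegulonTable, build_regulon_table

logger = logging.getLogger(__name__)

# study-condition defaults
N_GENES = 4000
N_SAMPLES = 60
N_MODULES = 10
MODULE_SIZE = (10, 30)
REPLICATE_SIZE = 2
NOISE_SIGMA = 0.05
REGULON_COVERAGE = 0.8
N_DECOY_REGULONS = 20

# activity-block design: fraction of conditions in which a module is
# active, the signed level range when active, and replicate jitter
ACTIVE_FRACTION = 0.5
MIN_ACTIVE_CONDITIONS = 3
ACTIVITY_LEVEL = (10.0, 30.0)
REPLICATE_JITTER_SD = 0.5

# sparse-weight design: member |weights| before normalization vs the
# Gaussian background SD (>= 5x separation by construction)
MEMBER_WEIGHT = (0.5, 1.0)
POSITIVE_WEIGHT_FRACTION = 0.8
BACKGROUND_WEIGHT_SD = 0.02

KNOCKOUT_VALUE = -10.0  # centered log2 value representing zeroed expression


class SimulationError(ValueError):
    """Raised for infeasible generator parameters."""


@dataclass
class GroundTruth:
    """Planted structure of a synthetic compendium."""

    S_true: pd.DataFrame  # genes x modules, unit-norm columns
    A_true: pd.DataFrame  # modules x samples (noise-free block levels + jitter)
    members: dict[str, list[str]]  # module -> member genes
    regulators: dict[str, str]  # module -> true regulator name
    regulator_genes: dict[str, str]  # regulator -> its own gene in the compendium
    noise_sigma: float
    seed: int
    decoy_regulators: list[str] = field(default_factory=list)

    @property
    def modules(self) -> list[str]:
        return list(self.S_true.columns)


def generate_compendium(
    n_genes: int = N_GENES,
    n_samples: int = N_SAMPLES,
    n_modules: int = N_MODULES,
    module_size: tuple[int, int] = MODULE_SIZE,
    replicate_size: int = REPLICATE_SIZE,
    noise_sigma: float = NOISE_SIGMA,
    regulon_coverage: float = REGULON_COVERAGE,
    n_decoy_regulons: int = N_DECOY_REGULONS,
    seed: int = 0,
) -> tuple[Compendium, GroundTruth, RegulonTable]:
    """Generate (Compendium, GroundTruth, RegulonTable) from one seed.

    Samples are grouped into conditions of ``replicate_size`` replicates;
    the first condition is the reference with zero true activity for
    every module.  The compendium is emitted uncentered (reference-sample
    noise means are not exactly zero); run it through
    ``center_to_reference`` like any real dataset.
    """
    if n_modules > n_samples // 2:
        raise SimulationError("n_modules must be <= n_samples / 2")
    if min(n_genes, n_samples, n_modules, replicate_size) <= 0:
        raise SimulationError("sizes must be positive")
    if module_size[0] < 5:
        raise SimulationError("planted modules need >= 5 member genes")
    if n_samples % replicate_size:
        raise SimulationError("n_samples must be a multiple of replicate_size")
    if n_modules * (module_size[1] + 1) + n_decoy_regulons > n_genes:
        raise SimulationError("not enough genes for modules and regulator genes")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"g{i:0{width}d}" for i in range(n_genes)]
    modules = [f"mod_{m}" for m in range(n_modules)]

    # disjoint member sets plus one dedicated regulator gene per module
    shuffled = rng.permutation(n_genes)
    pos = 0
    S = np.zeros((n_genes, n_modules))
    members: dict[str, list[str]] = {}
    regulators: dict[str, str] = {}
    regulator_genes: dict[str, str] = {}
    for m, mod in enumerate(modules):
        size = int(rng.integers(module_size[0], module_size[1] + 1))
        idx = shuffled[pos : pos + size]
        pos += size
        signs = rng.choice(
            [1.0, -1.0],
            size,
            p=[POSITIVE_WEIGHT_FRACTION, 1 - POSITIVE_WEIGHT_FRACTION],
        )
        weights = rng.uniform(*MEMBER_WEIGHT, size) * signs
        col = rng.normal(0.0, BACKGROUND_WEIGHT_SD, n_genes)
        col[idx] = weights
        S[:, m] = col / np.linalg.norm(col)
        members[mod] = [genes[i] for i in idx]
        reg = f"reg_{m}"
        regulators[mod] = reg
        reg_gene_idx = shuffled[pos]
        pos += 1
        regulator_genes[reg] = genes[reg_gene_idx]

    # condition-block activities with replicate jitter; condition 0 = reference
    n_conditions = n_samples // replicate_size
    conditions = [f"cond_{c:02d}" for c in range(n_conditions)]
    conditions[0] = "reference"
    A = np.zeros((n_modules, n_samples))
    for m in range(n_modules):
        active = rng.random(n_conditions) < ACTIVE_FRACTION
        active[0] = False
        if active[1:].sum() < MIN_ACTIVE_CONDITIONS:
            forced = rng.choice(
                np.arange(1, n_conditions), MIN_ACTIVE_CONDITIONS, replace=False
            )
            active[forced] = True
        levels = np.zeros(n_conditions)
        levels[active] = rng.uniform(*ACTIVITY_LEVEL, active.sum()) * rng.choice(
            [1.0, -1.0], active.sum()
        )
        jitter = rng.normal(0.0, REPLICATE_JITTER_SD, n_samples)
        A[m] = np.repeat(levels, replicate_size) + jitter
        A[m, :replicate_size] = jitter[:replicate_size]  # reference: jitter only

    noise = (
        rng.normal(0.0, noise_sigma, (n_genes, n_samples))
        if noise_sigma > 0
        else np.zeros((n_genes, n_samples))
    )
    X = S @ A + noise

    samples = [
        f"{cond}__rep{r + 1}"
        for cond in conditions
        for r in range(replicate_size)
    ]
    values = pd.DataFrame(X, index=genes, columns=samples)
    metadata = pd.DataFrame(
        {
            "project": "synthetic",
            "condition": np.repeat(conditions, replicate_size),
            "replicate_group": np.repeat(conditions, replicate_size),
            "is_reference": np.repeat(
                [c == "reference" for c in conditions], replicate_size
            ),
        },
        index=samples,
    )
    reference_samples = [s for s in samples if s.startswith("reference__")]
    compendium = Compendium(
        values, metadata, centered=False, reference_samples=reference_samples
    )

    truth = GroundTruth(
        S_true=pd.DataFrame(S, index=genes, columns=modules),
        A_true=pd.DataFrame(A, index=modules, columns=samples),
        members=members,
        regulators=regulators,
        regulator_genes=regulator_genes,
        noise_sigma=noise_sigma,
        seed=seed,
        decoy_regulators=[f"decoy_{d:02d}" for d in range(n_decoy_regulons)],
    )

    # regulon table: per-module regulator covering a fraction of members,
    # plus size-matched decoy regulons drawn from the whole gene pool
    rows = []
    for mod in modules:
        mem = members[mod]
        n_cov = max(1, int(round(regulon_coverage * len(mem))))
        covered = list(rng.choice(mem, n_cov, replace=False))
        for g in covered:
            rows.append({"regulator": regulators[mod], "gene": g, "effect": "unknown"})
    module_sizes = [len(members[m]) for m in modules]
    for d, decoy in enumerate(truth.decoy_regulators):
        size = int(module_sizes[d % len(module_sizes)])
        targets = rng.choice(genes, size, replace=False)
        for g in targets:
            rows.append({"regulator": decoy, "gene": g, "effect": "unknown"})
    trn = build_regulon_table(pd.DataFrame(rows), genes)

    return compendium, truth, trn


def generate_knockout_fixture(
    compendium: Compendium,
    truth: GroundTruth,
    regulator: str,
    effect_size: float = 20.0,
    n_replicates: int = REPLICATE_SIZE,
    knockout_value: float = KNOCKOUT_VALUE,
    seed: int = 0,
) -> tuple[Compendium, GroundTruth]:
    """Append knockout samples for a regulator's module.

    The knockout condition copies the reference condition, shifts the
    regulated module's activity by ``effect_size``, and forces the
    regulator gene's (centered) expression to ``knockout_value`` —
    a strongly negative log2 value standing in for zero transcript.
    """
    module = next(
        (m for m, r in truth.regulators.items() if r == regulator), None
    )
    if module is None:
        raise SimulationError(f"unknown regulator: {regulator}")
    rng = np.random.default_rng(seed)
    reg_gene = truth.regulator_genes[regulator]
    ko_samples = [f"ko_{regulator}__rep{r + 1}" for r in range(n_replicates)]

    s_col = truth.S_true[module].to_numpy()
    new_cols = {}
    a_new = {}
    for s in ko_samples:
        activity = effect_size + rng.normal(0.0, REPLICATE_JITTER_SD)
        profile = s_col * activity + rng.normal(
            0.0, truth.noise_sigma, len(compendium.genes)
        )
        profile = pd.Series(profile, index=compendium.genes)
        profile[reg_gene] = knockout_value
        new_cols[s] = profile
        a_new[s] = activity

    values = pd.concat([compendium.values, pd.DataFrame(new_cols)], axis=1)
    extra_meta = pd.DataFrame(
        {
            "project": "synthetic",
            "condition": f"ko_{regulator}",
            "replicate_group": f"ko_{regulator}",
            "is_reference": False,
        },
        index=ko_samples,
    )
    metadata = pd.concat([compendium.metadata, extra_meta])
    new_compendium = Compendium(
        values,
        metadata,
        centered=False,
        reference_samples=list(compendium.reference_samples),
    )
    A_true = truth.A_true.copy()
    for s in ko_samples:
        A_true[s] = 0.0
        A_true.loc[module, s] = a_new[s]
    new_truth = GroundTruth(
        S_true=truth.S_true,
        A_true=A_true,
        members=truth.members,
        regulators=truth.regulators,
        regulator_genes=truth.regulator_genes,
        noise_sigma=truth.noise_sigma,
        seed=truth.seed,
        decoy_regulators=list(truth.decoy_regulators),
    )
    return new_compendium, new_truth


def membership_f1(recovered: set[str], planted: set[str]) -> float:
    """F1 between a recovered gene set and a planted module."""
    if not recovered or not planted:
        return 0.0
    k = len(recovered & planted)
    if k == 0:
        return 0.0
    precision = k / len(recovered)
    recall = k / len(planted)
    return 2 * precision * recall / (precision + recall)
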