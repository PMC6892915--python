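"""Linking gene modules to known regulons.

An i-modulon is hypothesized to be the target set of a transcriptional
regulator.  The link is tested with the two-sided Fisher's exact test on
the 2x2 table (in module x in regulon) over the gene universe of the
compendium, with Benjamini-Hochberg control of the false discovery rate
across the candidate regulators tested for that module.  Joint regulation
is captured by combined regulons: intersections ("+") and unions ("/") of
up to three regulons.  Precision (fraction of module genes in the regulon)
and recall (fraction of regulon genes in the module) summarize agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .compendium import RegulonTable

logger = logging.getLogger(__name__)

FDR_ALPHA = 1e-5
MAX_REGULATORS = 3

MODE_INTERSECTION = "+"
MODE_UNION = "/"

CATEGORY_REGULATORY = "regulatory"
CATEGORY_GENOMIC = "genomic"
CATEGORY_BIOLOGICAL = "biological"
CATEGORY_UNCHARACTERIZED = "uncharacterized"


@dataclass
class EnrichmentRecord:
    """One module-regulon(s) association with its test statistics."""

    imodulon: str
    regulators: tuple[str, ...]
    modes: tuple[str, ...]  # pairwise join modes, left-to-right
    k: int  # overlap
    n: int  # module size
    K: int  # regulon size
    N: int  # universe size
    p_value: float
    fdr: float
    precision: float
    recall: float
    f1: float

    @property
    def label(self) -> str:
        parts = [self.regulators[0]]
        for mode, reg in zip(self.modes, self.regulators[1:]):
            parts.append(mode)
            parts.append(reg)
        return "".join(parts)


def precision_recall_f1(k: int, n: int, K: int) -> tuple[float, float, float]:
    """Exact precision k/n, recall k/K, and their harmonic mean.

    F1 is defined as 0 when the overlap is empty.
    """
    if n < 1 or K < 1:
        raise ValueError("module and regulon must be nonempty")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"invalid contingency: k={k}, n={n}, K={K}")
    precision = k / n
    recall = k / K
    f1 = 0.0 if k == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def fisher_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Two-sided Fisher's exact p-value for the (k, n, K, N) contingency.

    The 2x2 table is (in module x in regulon) over a universe of N genes:
    [[k, n - k], [K - k, N - n - K + k]].
    """
    if n == 0 or K == 0:
        return 1.0
    table = [[k, n - k], [K - k, N - n - K + k]]
    _, p = fisher_exact(table, alternative="two-sided")
    return float(p)


def fisher_enrichment(
    module_genes: Iterable[str],
    regulon_genes: Iterable[str],
    universe: Iterable[str],
) -> tuple[float, tuple[int, int, int, int]]:
    """Two-sided Fisher's exact p-value with its (k, n, K, N) contingency.

    Empty module or regulon yields p = 1 with k = 0.
    """
    universe_set = set(universe)
    if len(universe_set) < 2:
        raise ValueError("universe must contain at least 2 genes")
    module = set(module_genes) & universe_set
    regulon = set(regulon_genes) & universe_set
    n, K, N = len(module), len(regulon), len(universe_set)
    k = len(module & regulon)
    return fisher_pvalue(k, n, K, N), (k, n, K, N)


def combine_regulons(
    regulon_table: RegulonTable,
    regulators: Sequence[str],
    modes: Sequence[str] = (),
) -> set[str]:
    """Gene set of a combined regulon, joined left-to-right.

    ``modes`` holds one join per additional regulator: "+" intersects,
    "/" unions.  A single regulator returns its regulon unchanged.
    """
    if not 1 <= len(regulators) <= MAX_REGULATORS:
        raise ValueError(f"need 1..{MAX_REGULATORS} regulators")
    if len(modes) != len(regulators) - 1:
        raise ValueError("need one mode per additional regulator")
    genes = regulon_table.regulon(regulators[0])
    for mode, reg in zip(modes, regulators[1:]):
        other = regulon_table.regulon(reg)
        if mode == MODE_INTERSECTION:
            genes = genes & other
        elif mode == MODE_UNION:
            genes = genes | other
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return genes


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (order-preserving)."""
    if len(p_values) == 0:
        return np.array([])
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def enumerate_and_test(
    imodulon_genes: Iterable[str],
    regulon_table: RegulonTable,
    imodulon_name: str = "imodulon",
    fdr_alpha: float = FDR_ALPHA,
    max_regs: int = MAX_REGULATORS,
) -> list[EnrichmentRecord]:
    """All single and combined regulon enrichments passing the FDR cut.

    Candidate combinations are restricted to regulators that individually
    share at least one gene with the module (a combination of
    non-overlapping regulons cannot improve the overlap).  BH-FDR is
    applied across all candidates tested for this module; records with
    FDR < ``fdr_alpha`` are returned sorted by p-value.
    """
    module = set(imodulon_genes)
    universe = regulon_table.gene_universe
    overlapping = [
        r for r in regulon_table.regulators if regulon_table.regulon(r) & module
    ]
    candidates: list[tuple[tuple[str, ...], tuple[str, ...], set[str]]] = []
    for r in overlapping:
        candidates.append(((r,), (), regulon_table.regulon(r)))
    for size in range(2, max_regs + 1):
        for regs in combinations(overlapping, size):
            for modes in product((MODE_INTERSECTION, MODE_UNION), repeat=size - 1):
                genes = combine_regulons(regulon_table, regs, modes)
                if genes:
                    candidates.append((regs, modes, genes))
    if not candidates:
        return []
    results = []
    for regs, modes, genes in candidates:
        p, (k, n, K, N) = fisher_enrichment(module, genes, universe)
        results.append((regs, modes, p, k, n, K, N))
    fdrs = bh_fdr([r[2] for r in results])
    records = []
    for (regs, modes, p, k, n, K, N), fdr in zip(results, fdrs):
        if fdr < fdr_alpha:
            prec, rec, f1 = precision_recall_f1(k, n, K)
            records.append(
                EnrichmentRecord(
                    imodulon=imodulon_name,
                    regulators=regs,
                    modes=modes,
                    k=k,
                    n=n,
                    K=K,
                    N=N,
                    p_value=p,
                    fdr=float(fdr),
                    precision=prec,
                    recall=rec,
                    f1=f1,
                )
            )
    records.sort(key=lambda r: (r.p_value, len(r.regulators)))
    return records


def categorize_imodulon(
    enrichments: Sequence[EnrichmentRecord],
    genomic_signal: bool = False,
    annotation: str | None = None,
) -> str:
    """Assign a category from enrichment results and explicit signals.

    regulatory: a passing enrichment exists; genomic: flagged by a
    supplied rule (e.g. a single dominant gene matching a knockout strain,
    or a contiguous same-sign genomic block); biological: only by explicit
    annotation; otherwise uncharacterized.  Nothing is guessed silently.
    """
    if enrichments:
        return CATEGORY_REGULATORY
    if genomic_signal:
        return CATEGORY_GENOMIC
    if annotation == CATEGORY_BIOLOGICAL:
        return CATEGORY_BIOLOGICAL
    return CATEGORY_UNCHARACTERIZED


def dominant_gene_knockout_signal(
    weights: pd.Series,
    knocked_out_genes: Iterable[str],
    weight_fraction: float = 0.5,
) -> bool:
    """Genomic rule: one gene holds > ``weight_fraction`` of the squared
    weight and that gene is knocked out in some strain of the compendium."""
    if len(weights) == 0:
        return False
    sq = weights.pow(2)
    top = sq.idxmax()
    return bool(sq[top] / sq.sum() > weight_fraction and top in set(knocked_out_genes))


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabular summary (one row per record) mirroring a regulon-link table."""
    rows = [
        {
            "imodulon": r.imodulon,
            "n_genes": r.n,
            "regulators": r.label,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "precision": r.precision,
            "recall": r.recall,
            "f1": r.f1,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "imodulon",
            "n_genes",
            "regulators",
            "p_value",
            "fdr",
            "precision",
            "recall",
            "f1",
        ],
    )
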