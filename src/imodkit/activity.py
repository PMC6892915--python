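"""Statistical analysis of i-modulon activities.

Activities (rows of A) quantify condition-specific up/down-regulation of
each i-modulon relative to the reference condition.  Technical noise is
estimated from biological replicates: within each replicate group the
absolute pairwise activity differences of an i-modulon are pooled and fit
with a log-normal distribution; the fitted upper tail then supplies the
p-value for a difference in mean activity between two conditions.  A
change is called significant when |dA| > 5 and the BH-adjusted FDR across
i-modulons is below 0.01.

The module also implements the linear-algebra uses of a fixed basis:
removing selected i-modulon effects from an expression profile
(x2' = x2 - sum_i s~_i (a_i2 - a_i1), where s~_i is the component
restricted to its significant genes), projecting new centered profiles
onto the basis via the Moore-Penrose pseudo-inverse (A' = pinv(S) X'),
and relating an activity to its regulator's own expression level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kstest, lognorm

from .enrichment import bh_fdr
from .thresholding import IModulon

logger = logging.getLogger(__name__)

ABS_THRESHOLD = 5.0
DIFF_FDR_ALPHA = 0.01
MIN_NOISE_OBSERVATIONS = 5


class ActivityError(ValueError):
    """Raised for invalid activity-analysis inputs."""


@dataclass
class ActivityTable:
    """I-modulon x sample activities with condition and replicate labels."""

    A: pd.DataFrame
    condition_map: pd.Series  # sample -> condition
    replicate_groups: pd.Series  # sample -> replicate-group key

    def __post_init__(self) -> None:
        samples = set(self.A.columns)
        if not samples <= set(self.condition_map.index):
            raise ActivityError("condition_map must cover all samples")
        if not samples <= set(self.replicate_groups.index):
            raise ActivityError("replicate_groups must cover all samples")

    def condition_samples(self, condition: str) -> list[str]:
        hits = [
            s for s in self.A.columns if self.condition_map[s] == condition
        ]
        if not hits:
            raise ActivityError(f"condition {condition!r} has no samples")
        return hits


@dataclass
class NoiseModel:
    """Per-i-modulon log-normal replicate-noise parameters.

    ``params`` rows: mu and sigma of log absolute replicate differences,
    number of differences used, Kolmogorov-Smirnov statistic and p of the
    fit, and a ``degenerate`` flag for i-modulons without usable
    differences (all zero, or fewer than ``MIN_NOISE_OBSERVATIONS``).
    """

    params: pd.DataFrame = field(default_factory=pd.DataFrame)

    def is_degenerate(self, imodulon: str) -> bool:
        return bool(self.params.loc[imodulon, "degenerate"])

    def tail_probability(self, imodulon: str, abs_diff: float) -> float:
        """P(|difference| >= abs_diff) under the fitted log-normal."""
        if self.is_degenerate(imodulon):
            raise ActivityError(f"degenerate noise model for {imodulon}")
        mu = self.params.loc[imodulon, "mu"]
        sigma = self.params.loc[imodulon, "sigma"]
        return float(lognorm.sf(abs_diff, s=sigma, scale=np.exp(mu)))


def replicate_differences(table: ActivityTable, imodulon: str) -> np.ndarray:
    """Pooled within-group absolute pairwise activity differences."""
    row = table.A.loc[imodulon]
    groups = table.replicate_groups[row.index]
    diffs: list[float] = []
    for _, members in groups.groupby(groups):
        for a, b in combinations(list(members.index), 2):
            diffs.append(abs(row[a] - row[b]))
    return np.asarray(diffs, dtype=float)


def fit_replicate_noise(table: ActivityTable) -> NoiseModel:
    """Fit the per-i-modulon log-normal replicate-noise model.

    Differences are pooled across replicate groups; zeros are dropped
    before the log-domain maximum-likelihood fit (mean/SD of logs, no
    location shift).  A KS statistic of the fit is recorded.  I-modulons
    with fewer than ``MIN_NOISE_OBSERVATIONS`` positive differences are
    flagged degenerate and excluded from testing.
    """
    group_sizes = table.replicate_groups[table.A.columns].value_counts()
    if (group_sizes >= 2).sum() < 2:
        raise ActivityError("need >= 2 replicate groups of size >= 2")
    rows = []
    for imod in table.A.index:
        diffs = replicate_differences(table, imod)
        positive = diffs[diffs > 0]
        if len(positive) < MIN_NOISE_OBSERVATIONS:
            logger.warning(
                "i-modulon %s: %d positive replicate differences; noise model "
                "flagged degenerate",
                imod,
                len(positive),
            )
            rows.append(
                {
                    "imodulon": imod,
                    "mu": np.nan,
                    "sigma": np.nan,
                    "n": len(positive),
                    "ks_stat": np.nan,
                    "ks_p": np.nan,
                    "degenerate": True,
                }
            )
            continue
        logs = np.log(positive)
        mu = float(np.mean(logs))
        sigma = float(np.std(logs, ddof=1))
        if sigma == 0:
            sigma = np.finfo(float).tiny
        ks_stat, ks_p = kstest(positive, lognorm(s=sigma, scale=np.exp(mu)).cdf)
        rows.append(
            {
                "imodulon": imod,
                "mu": mu,
                "sigma": sigma,
                "n": len(positive),
                "ks_stat": float(ks_stat),
                "ks_p": float(ks_p),
                "degenerate": False,
            }
        )
    params = pd.DataFrame(rows).set_index("imodulon")
    return NoiseModel(params)


def test_differential_activity(
    table: ActivityTable,
    noise: NoiseModel,
    condition_1: str,
    condition_2: str,
    abs_threshold: float = ABS_THRESHOLD,
    fdr_alpha: float = DIFF_FDR_ALPHA,
) -> pd.DataFrame:
    """Differential-activity test between two conditions.

    Activities are replicate-averaged per condition; the p-value of each
    i-modulon is the upper-tail probability of |dA| under its fitted
    log-normal noise model, BH-adjusted across i-modulons.  Significance
    requires both |dA| > ``abs_threshold`` and FDR < ``fdr_alpha``.
    I-modulons with degenerate noise models are skipped.
    """
    s1 = table.condition_samples(condition_1)
    s2 = table.condition_samples(condition_2)
    mean1 = table.A[s1].mean(axis=1)
    mean2 = table.A[s2].mean(axis=1)
    rows = []
    for imod in table.A.index:
        if noise.is_degenerate(imod):
            logger.warning("skipping %s: degenerate noise model", imod)
            continue
        delta = float(mean2[imod] - mean1[imod])
        p = noise.tail_probability(imod, abs(delta))
        rows.append(
            {
                "imodulon": imod,
                "condition_1": condition_1,
                "condition_2": condition_2,
                "delta_A": delta,
                "pvalue": p,
            }
        )
    result = pd.DataFrame(
        rows, columns=["imodulon", "condition_1", "condition_2", "delta_A", "pvalue"]
    )
    if len(result):
        result["fdr"] = bh_fdr(result["pvalue"].tolist())
        result["significant"] = (result["delta_A"].abs() > abs_threshold) & (
            result["fdr"] < fdr_alpha
        )
    else:
        result["fdr"] = []
        result["significant"] = []
    return result


def correct_profile(
    x2: pd.Series,
    imodulons: Sequence[IModulon],
    S: pd.DataFrame,
    a_target: pd.Series | dict,
    a_ref: pd.Series | dict,
) -> pd.Series:
    """Remove selected i-modulon effects from a centered profile.

    Computes x2' = x2 - sum_i s~_i (a_i,target - a_i,ref), where s~_i is
    the full component column zeroed outside the i-modulon's significant
    genes.  Genes outside all selected i-modulons are unchanged.
    """
    if not x2.index.equals(S.index):
        raise ActivityError("profile and S must share the gene index")
    corrected = x2.astype(float).copy()
    for im in imodulons:
        col = S.columns[im.component_index]
        s_tilde = pd.Series(0.0, index=S.index)
        genes = [g for g in im.gene_weights.index]
        missing = set(genes) - set(S.index)
        if missing:
            raise ActivityError(f"i-modulon genes missing from S: {sorted(missing)[:5]}")
        s_tilde[genes] = S.loc[genes, col]
        delta = float(a_target[col]) - float(a_ref[col])
        corrected = corrected - s_tilde * delta
    return corrected


def project_onto_basis(
    S: pd.DataFrame, X_new: pd.DataFrame
) -> pd.DataFrame:
    """Least-squares activities for new centered profiles: A' = pinv(S) X'.

    The profiles are first restricted to the genes shared with the basis
    (e.g. the core genes conserved across strains); S rows are subset to
    match.  If the restricted basis is rank-deficient the minimum-norm
    solution is returned with a warning.  The shared-gene list is stored
    in ``A'.attrs['shared_genes']``.
    """
    shared = S.index.intersection(X_new.index)
    if len(shared) == 0:
        raise ActivityError("no shared genes between basis and profiles")
    S_sub = S.loc[shared].to_numpy(dtype=float)
    X_sub = X_new.loc[shared].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(S_sub)
    if rank < S_sub.shape[1]:
        logger.warning(
            "basis restricted to %d genes is rank-deficient (rank %d < %d); "
            "returning the minimum-norm solution",
            len(shared),
            rank,
            S_sub.shape[1],
        )
    A_new = np.linalg.pinv(S_sub) @ X_sub
    out = pd.DataFrame(A_new, index=S.columns, columns=X_new.columns)
    out.attrs["shared_genes"] = list(shared)
    return out


@dataclass
class AssociationRecord:
    """Activity-versus-regulator-expression association summary."""

    r2: float
    adj_r2: float
    slope: float
    intercept: float
    n: int
    breakpoint: float | None = None
    piecewise_r2: float | None = None
    piecewise_adj_r2: float | None = None


def _adjusted_r2(r2: float, n: int, n_params: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)


def activity_expression_association(
    activity: pd.Series,
    expression: pd.Series,
    exclude_samples: Iterable[str] = (),
) -> AssociationRecord:
    """OLS fit of i-modulon activity on regulator expression.

    Excluded samples (typically the regulator's own knockout) are removed
    first.  Besides the straight-line fit, a single-breakpoint hinge fit
    (flat below the breakpoint, linear above) is scanned over candidate
    breakpoints and reported alongside, since some regulators require a
    minimum expression level before their targets respond.
    """
    keep = [s for s in activity.index if s not in set(exclude_samples)]
    keep = [s for s in keep if s in expression.index]
    if len(keep) < 3:
        raise ActivityError("need >= 3 samples after exclusion")
    y = activity[keep].to_numpy(dtype=float)
    x = expression[keep].to_numpy(dtype=float)
    n = len(keep)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    record = AssociationRecord(
        r2=r2,
        adj_r2=_adjusted_r2(r2, n, 2),
        slope=float(slope),
        intercept=float(intercept),
        n=n,
    )
    if n >= 5 and ss_tot > 0:
        best = None
        for c in np.unique(x)[1:-1]:
            hinge = np.maximum(0.0, x - c)
            design = np.column_stack([np.ones(n), hinge])
            coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
            res = float(np.sum((y - design @ coef) ** 2))
            if best is None or res < best[1]:
                best = (float(c), res)
        if best is not None:
            pw_r2 = 1.0 - best[1] / ss_tot
            record.breakpoint = best[0]
            record.piecewise_r2 = pw_r2
            record.piecewise_adj_r2 = _adjusted_r2(pw_r2, n, 3)
    return record
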