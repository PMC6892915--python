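"""Robust independent component analysis of an expression compendium.

The centered compendium X (genes x samples) is modeled as X = S A: columns
of S are statistically independent gene-coefficient signatures and rows of
A are their condition-specific activities.  A single FastICA run is not
reproducible — the algorithm converges to different local optima from
different seeds — so the decomposition is stabilized in two stages:

1. Within one repetition, FastICA is restarted many times with different
   seeds, the pooled components are clustered with DBSCAN under the
   sign-invariant correlation distance d(x, y) = 1 - |rho(x, y)|, and each
   cluster is collapsed to its sign-aligned centroid.  The cluster count
   estimates the intrinsic dimensionality.
2. The whole restart-and-cluster procedure is repeated several times with
   disjoint seed streams; only components re-identified in every
   repetition (a match at distance < d_max) are retained as robust.

Components are ordered by the L2 norm of their activity rows, so the
leading components explain the most variance; `cumulative_explained_variance`
quantifies the reconstruction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

#: defaults for the robust-decomposition procedure
N_RESTARTS = 256
N_REPETITIONS = 100
TOLERANCE = 1e-8
DBSCAN_EPS = 0.1
D_MAX = 0.1
VARIANCE_FRACTION = 0.99
MAX_ITER = 1000


class DecompositionError(ValueError):
    """Raised for invalid decomposition inputs."""


@dataclass
class Decomposition:
    """Robust component matrix S and activity matrix A with provenance.

    Columns of ``S`` (genes x components) have zero mean and unit L2 norm,
    with the sign convention that the gene of maximum |coefficient| is
    positive.  Rows of ``A`` (components x samples) carry the matching
    activities so that S @ A reconstructs the dimension-reduced compendium.
    """

    S: pd.DataFrame
    A: pd.DataFrame
    n_restarts: int
    n_repetitions: int
    cluster_sizes: list[int] = field(default_factory=list)
    robustness_count: list[int] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.S.columns) != list(self.A.index):
            raise DecompositionError("S columns and A rows must align")

    @property
    def n_components(self) -> int:
        return self.S.shape[1]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.S.to_csv(out / "S.tsv", sep="\t", float_format="%.10g")
        self.A.to_csv(out / "A.tsv", sep="\t", float_format="%.10g")
        sidecar = {
            "n_restarts": self.n_restarts,
            "n_repetitions": self.n_repetitions,
            "cluster_sizes": self.cluster_sizes,
            "robustness_count": self.robustness_count,
            "params": self.params,
        }
        (out / "decomposition.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path) -> "Decomposition":
        out = Path(out_dir)
        S = pd.read_csv(out / "S.tsv", sep="\t", index_col=0)
        A = pd.read_csv(out / "A.tsv", sep="\t", index_col=0)
        sidecar = json.loads((out / "decomposition.json").read_text())
        return cls(
            S,
            A,
            n_restarts=sidecar["n_restarts"],
            n_repetitions=sidecar["n_repetitions"],
            cluster_sizes=sidecar["cluster_sizes"],
            robustness_count=sidecar["robustness_count"],
            params=sidecar.get("params", {}),
        )


def estimate_dimension(
    X: np.ndarray | pd.DataFrame, variance_fraction: float = VARIANCE_FRACTION
) -> int:
    """Smallest K whose top-K principal components reach the variance target.

    The problem dimension is the sample axis (PCA over columns of the
    genes x samples matrix).
    """
    Xv = np.asarray(X, dtype=float)
    if not np.any(Xv):
        raise DecompositionError("all-zero matrix")
    pca = PCA().fit(Xv.T)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    return min(k, min(Xv.shape))


def run_ica_restart(
    X: np.ndarray,
    n_components: int,
    tolerance: float = TOLERANCE,
    seed: int | None = None,
    max_iter: int = MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One FastICA run: (S_run, A_run, converged).

    Uses the logcosh contrast with symmetric (parallel) updates.  Returned
    components are standardized to zero mean and unit L2 norm, with A
    rescaled so S_run @ A_run is unchanged.
    """
    Xv = np.asarray(X, dtype=float)
    if n_components > min(Xv.shape):
        raise DecompositionError(
            f"n_components={n_components} exceeds min(matrix shape)={min(Xv.shape)}"
        )
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        tol=tolerance,
        max_iter=max_iter,
        whiten="unit-variance",
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            S = ica.fit_transform(Xv)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = FastICA(
                    n_components=n_components,
                    algorithm="parallel",
                    fun="logcosh",
                    tol=tolerance,
                    max_iter=max_iter,
                    whiten="unit-variance",
                    random_state=seed,
                )
                S = ica.fit_transform(Xv)
    A = ica.mixing_.T
    S = S - S.mean(axis=0)
    norms = np.linalg.norm(S, axis=0)
    if np.any(norms == 0):
        raise DecompositionError("degenerate (zero) component from FastICA")
    S = S / norms
    A = A * norms[:, None]
    return S, A, converged


def component_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Sign-invariant correlation distance d = 1 - |Pearson rho|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise DecompositionError("zero-variance vector in component_distance")
    rho = np.corrcoef(x, y)[0, 1]
    return float(np.clip(1.0 - abs(rho), 0.0, 1.0))


def pairwise_distance_matrix(components: np.ndarray) -> np.ndarray:
    """Full d = 1 - |rho| matrix for columns of ``components``."""
    C = np.corrcoef(components.T)
    return np.clip(1.0 - np.abs(C), 0.0, None)


def cluster_runs(
    pooled_S: np.ndarray,
    n_restarts: int,
    eps: float = DBSCAN_EPS,
    min_members: int | None = None,
) -> np.ndarray:
    """DBSCAN labels for pooled components (columns), -1 = unclustered.

    ``min_members`` defaults to ceil(0.5 * n_restarts); DBSCAN's
    neighborhood count includes the point itself.
    """
    if min_members is None:
        min_members = int(np.ceil(0.5 * n_restarts))
    D = pairwise_distance_matrix(pooled_S)
    db = DBSCAN(eps=eps, min_samples=min_members, metric="precomputed").fit(D)
    return db.labels_


def align_and_centroid(
    members_S: np.ndarray, members_A: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sign-align cluster members and return renormalized centroids.

    Each member column is flipped so its maximum-|coefficient| gene is
    positive (ties broken toward the lowest gene index), with the paired
    activity row flipped consistently.  The S centroid is renormalized to
    unit L2 norm and the A centroid rescaled by the same factor, so the
    implied product S @ A is preserved.
    """
    S = np.array(members_S, dtype=float)
    A = np.array(members_A, dtype=float)
    if S.size == 0:
        raise DecompositionError("empty cluster")
    for j in range(S.shape[1]):
        g = int(np.argmax(np.abs(S[:, j])))  # argmax -> lowest index on ties
        if S[g, j] < 0:
            S[:, j] = -S[:, j]
            A[j] = -A[j]
    centroid = S.mean(axis=1)
    activity = A.mean(axis=0)
    norm = np.linalg.norm(centroid)
    if norm == 0:
        raise DecompositionError("zero centroid")
    return centroid / norm, activity * norm


def _single_repetition(
    X: np.ndarray,
    n_components: int,
    n_restarts: int,
    tolerance: float,
    eps: float,
    seeds: list[int],
    max_iter: int,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[int]]:
    """Restart + cluster + centroid pass; returns (centroids, cluster sizes)."""
    pool_S: list[np.ndarray] = []
    pool_A: list[np.ndarray] = []
    n_failed = 0
    for seed in seeds:
        S, A, converged = run_ica_restart(
            X, n_components, tolerance=tolerance, seed=seed, max_iter=max_iter
        )
        if not converged:
            n_failed += 1
            continue
        pool_S.append(S)
        pool_A.append(A)
    if n_failed:
        logger.info("%d of %d restarts did not converge", n_failed, len(seeds))
    if not pool_S:
        # keep all runs rather than abort: unconverged runs still carry the
        # strong components, only the residual rotation is unsettled
        logger.warning("no restart converged; clustering unconverged runs")
        for seed in seeds:
            S, A, _ = run_ica_restart(
                X, n_components, tolerance=tolerance, seed=seed, max_iter=max_iter
            )
            pool_S.append(S)
            pool_A.append(A)
    P = np.hstack(pool_S)
    PA = np.vstack(pool_A)
    labels = cluster_runs(P, n_restarts=n_restarts, eps=eps)
    centroids: list[tuple[np.ndarray, np.ndarray]] = []
    sizes: list[int] = []
    for label in sorted(set(labels) - {-1}):
        idx = np.where(labels == label)[0]
        c, a = align_and_centroid(P[:, idx], PA[idx])
        centroids.append((c, a))
        sizes.append(len(idx))
    if not centroids:
        logger.warning("DBSCAN found no clusters; empty decomposition")
    return centroids, sizes


def robust_components(
    X: np.ndarray | pd.DataFrame,
    n_components: int | None = None,
    n_restarts: int = N_RESTARTS,
    n_repetitions: int = N_REPETITIONS,
    tolerance: float = TOLERANCE,
    eps: float = DBSCAN_EPS,
    d_max: float = D_MAX,
    variance_fraction: float = VARIANCE_FRACTION,
    seed: int = 0,
    max_iter: int = MAX_ITER,
) -> Decomposition:
    """Robust decomposition of a centered compendium.

    Runs the restart + DBSCAN + centroid pass ``n_repetitions`` times with
    disjoint deterministic seed streams derived from ``seed``; retains
    only the first repetition's centroids that are re-identified in every
    other repetition at distance < ``d_max``.  Components are ordered by
    descending L2 norm of their activity rows.
    """
    if n_repetitions <= 0:
        raise DecompositionError("n_repetitions must be positive")
    if n_restarts < 2:
        raise DecompositionError("need at least 2 restarts")
    if isinstance(X, pd.DataFrame):
        genes = list(X.index)
        samples = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        genes = [f"g{i}" for i in range(Xv.shape[0])]
        samples = [f"s{j}" for j in range(Xv.shape[1])]
    if n_components is None:
        n_components = estimate_dimension(Xv, variance_fraction)

    # one deterministic 31-bit seed per (repetition, restart)
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(n_repetitions * n_restarts, dtype=np.uint64)
    seeds = (state % (2**31 - 1)).astype(np.int64).reshape(n_repetitions, n_restarts)

    repetitions = []
    first_sizes: list[int] = []
    for r in range(n_repetitions):
        centroids, sizes = _single_repetition(
            Xv,
            n_components,
            n_restarts,
            tolerance,
            eps,
            [int(s) for s in seeds[r]],
            max_iter,
        )
        if r == 0:
            first_sizes = sizes
        repetitions.append(centroids)

    reference = repetitions[0]
    retained: list[tuple[np.ndarray, np.ndarray, int, int]] = []
    for i, (c, a) in enumerate(reference):
        matches = 1  # the reference repetition contains itself
        for other in repetitions[1:]:
            if other and min(
                component_distance(c, c2) for c2, _ in other
            ) < d_max:
                matches += 1
        if matches == n_repetitions:
            retained.append((c, a, first_sizes[i], matches))
        else:
            logger.info(
                "component %d dropped: matched %d/%d repetitions",
                i,
                matches,
                n_repetitions,
            )

    if not retained:
        logger.warning("no robust components retained")
        S_df = pd.DataFrame(index=genes)
        A_df = pd.DataFrame(columns=samples)
        A_df.index = S_df.columns
    else:
        order = np.argsort([-np.linalg.norm(a) for _, a, _, _ in retained])
        retained = [retained[i] for i in order]
        names = [f"M{i}" for i in range(len(retained))]
        S_df = pd.DataFrame(
            np.column_stack([c for c, _, _, _ in retained]),
            index=genes,
            columns=names,
        )
        A_df = pd.DataFrame(
            np.vstack([a for _, a, _, _ in retained]), index=names, columns=samples
        )
    return Decomposition(
        S=S_df,
        A=A_df,
        n_restarts=n_restarts,
        n_repetitions=n_repetitions,
        cluster_sizes=[s for _, _, s, _ in retained],
        robustness_count=[m for _, _, _, m in retained],
        params={
            "n_components": int(n_components),
            "tolerance": tolerance,
            "eps": eps,
            "d_max": d_max,
            "variance_fraction": variance_fraction,
            "seed": int(seed),
            "max_iter": int(max_iter),
        },
    )


def total_sum_of_squares(Y: np.ndarray | pd.DataFrame) -> float:
    """TSS(Y) = sum of squared entries."""
    return float(np.sum(np.square(np.asarray(Y, dtype=float))))


def cumulative_explained_variance(
    X: np.ndarray | pd.DataFrame,
    S: np.ndarray | pd.DataFrame,
    A: np.ndarray | pd.DataFrame,
    K: int | None = None,
) -> float:
    """CEV(K) = 1 - TSS(X - sum_{k<=K} s_k a_k) / TSS(X).

    Uses the first ``K`` components in their stored (activity-norm) order;
    ``K=None`` uses all components.  CEV(0) = 0 by construction.
    """
    Xv = np.asarray(X, dtype=float)
    Sv = np.asarray(S, dtype=float)
    Av = np.asarray(A, dtype=float)
    tss = total_sum_of_squares(Xv)
    if tss == 0:
        raise DecompositionError("TSS(X) = 0")
    if K is None:
        K = Sv.shape[1]
    if not 0 <= K <= Sv.shape[1]:
        raise DecompositionError(f"K={K} out of range 0..{Sv.shape[1]}")
    residual = Xv - Sv[:, :K] @ Av[:K]
    return 1.0 - total_sum_of_squares(residual) / tss


def cev_curve(
    X: np.ndarray | pd.DataFrame, decomposition: Decomposition
) -> pd.Series:
    """Cumulative explained variance for K = 0 .. n_components."""
    vals = [
        cumulative_explained_variance(X, decomposition.S, decomposition.A, K)
        for K in range(decomposition.n_components + 1)
    ]
    return pd.Series(vals, index=range(decomposition.n_components + 1), name="CEV")
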