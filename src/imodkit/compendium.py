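"""Expression-compendium I/O, quality control, and reference centering.

The analysis operates on a genes x samples matrix of log-TPM values
(log2(TPM + 1)), optionally centered so that the per-gene mean over a set
of designated reference samples is zero.  After centering, each column is
a log2 fold-change profile relative to the reference condition, which is
the input expected by the decomposition stage.

Quality control follows two rules: genes must be at least 100 nt long and
reach 10 fragments per million mapped reads (FPM) in at least one sample;
biological replicates must agree at R^2 >= 0.9 in log-TPM or the
discordant samples are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: QC defaults
MIN_GENE_LENGTH = 100
MIN_FPM = 10.0
MIN_REPLICATE_R2 = 0.9

METADATA_COLUMNS = ("project", "condition", "replicate_group", "is_reference")

EFFECT_ACTIVATION = "activation"
EFFECT_REPRESSION = "repression"
EFFECT_UNKNOWN = "unknown"


class CompendiumError(ValueError):
    """Raised for malformed or inconsistent compendium inputs."""


@dataclass
class Compendium:
    """A genes x samples expression matrix with per-sample metadata.

    Parameters
    ----------
    values
        Genes x samples matrix (log-TPM, or centered log fold-change when
        ``centered`` is True). Index: gene identifiers; columns: sample
        identifiers.
    metadata
        Per-sample table indexed by sample id with columns ``project``,
        ``condition``, ``replicate_group`` and ``is_reference``.
    centered
        Whether per-gene means over ``reference_samples`` have been
        subtracted.
    reference_samples
        Samples used (or to be used) for centering.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    centered: bool = False
    reference_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise CompendiumError("duplicate gene identifiers")
        if v.columns.duplicated().any():
            raise CompendiumError("duplicate sample identifiers")
        if v.isna().any().any():
            raise CompendiumError("expression matrix contains missing values")
        missing_meta = set(v.columns) - set(self.metadata.index)
        if missing_meta:
            raise CompendiumError(f"samples without metadata: {sorted(missing_meta)}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise CompendiumError(f"metadata missing column {col!r}")
        if self.metadata.loc[list(v.columns), "replicate_group"].isna().any():
            raise CompendiumError("every sample needs a replicate_group key")
        unknown_refs = set(self.reference_samples) - set(v.columns)
        if unknown_refs:
            raise CompendiumError(f"unknown reference samples: {sorted(unknown_refs)}")
        if self.centered:
            if not self.reference_samples:
                raise CompendiumError("centered compendium requires reference_samples")
            ref_mean = v[self.reference_samples].mean(axis=1)
            if not np.allclose(ref_mean, 0.0, atol=1e-9):
                raise CompendiumError(
                    "centered compendium has nonzero reference means"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def replicate_groups(self) -> pd.Series:
        return self.metadata.loc[list(self.samples), "replicate_group"]

    def condition_map(self) -> pd.Series:
        return self.metadata.loc[list(self.samples), "condition"]

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(
        cls,
        values_path: str | Path,
        metadata_path: str | Path,
        centered: bool = False,
    ) -> "Compendium":
        values = read_expression_tsv(values_path)
        metadata = read_metadata(metadata_path)
        refs = list(metadata.index[metadata["is_reference"]])
        return cls(values, metadata, centered=centered, reference_samples=refs)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (gene ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise CompendiumError(f"empty expression table: {path}")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, project, condition,
    replicate_group, is_reference)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise CompendiumError("metadata requires a sample_id column")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise CompendiumError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("sample_id")
    meta["is_reference"] = meta["is_reference"].astype(bool)
    return meta


def gene_lengths_from_table(path: str | Path) -> pd.Series:
    """Read gene lengths from a two-column TSV (gene id, length in nt)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise CompendiumError("length table needs two columns: gene, length")
    lengths = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str))
    return lengths.astype(float)


def gene_lengths_from_gff(
    path: str | Path,
    feature_types: Sequence[str] = ("gene",),
    id_attribute: str = "locus_tag",
) -> pd.Series:
    """Gene lengths from a GFF3 file as the union of feature intervals.

    For bacterial annotations the gene span equals the CDS span, so the
    union of ``gene`` features per locus tag is the gene length.  GFF
    coordinates are 1-based inclusive, hence length = end - start + 1 per
    interval, merged over overlapping intervals of the same gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    intervals: dict[str, list[tuple[int, int]]] = {}
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            attrs = feat.attributes
            if id_attribute in attrs:
                name = attrs[id_attribute][0]
            elif "ID" in attrs:
                name = attrs["ID"][0]
            else:
                raise CompendiumError(
                    f"feature at {feat.seqid}:{feat.start} lacks {id_attribute!r}/ID"
                )
            intervals.setdefault(name, []).append((feat.start, feat.end))
    if not intervals:
        raise CompendiumError(f"no {feature_types} features in {path}")
    lengths = {}
    for name, ivs in intervals.items():
        ivs.sort()
        total = 0
        cur_start, cur_end = ivs[0]
        for start, end in ivs[1:]:
            if start <= cur_end + 1:
                cur_end = max(cur_end, end)
            else:
                total += cur_end - cur_start + 1
                cur_start, cur_end = start, end
        total += cur_end - cur_start + 1
        lengths[name] = float(total)
    return pd.Series(lengths, name="length")


def compute_log_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """log2(TPM + 1) from fragment counts and gene lengths.

    TPM: divide each count by gene length (rate per nucleotide), then
    normalize each sample's rates to sum to 1e6.

    Raises if any sample has zero total counts or any gene lacks a length.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise CompendiumError(f"missing gene length for: {sorted(missing)[:5]}")
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise CompendiumError(f"non-positive gene length for: {bad[:5]}")
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise CompendiumError(f"zero-count sample(s): {zero}")
    rates = counts.div(lengths, axis=0)
    tpm = rates.div(rates.sum(axis=0), axis=1) * 1e6
    return np.log2(tpm + 1.0)


def fragments_per_million(counts: pd.DataFrame) -> pd.DataFrame:
    """Fragments per million mapped reads, per sample."""
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise CompendiumError(f"zero-count sample(s): {zero}")
    return counts.div(totals, axis=1) * 1e6


def qc_filter_genes(
    counts: pd.DataFrame,
    lengths: pd.Series,
    min_length: float = MIN_GENE_LENGTH,
    min_fpm: float = MIN_FPM,
) -> list[str]:
    """Genes passing length and expression QC, in input order.

    A gene is kept when its length is >= ``min_length`` nt and it reaches
    ``min_fpm`` fragments per million in at least one sample; a gene below
    the FPM floor in every sample carries no usable signal anywhere in the
    compendium.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise CompendiumError(f"missing gene length for: {missing[:5]}")
    fpm = fragments_per_million(counts)
    keep = (lengths >= min_length) & (fpm.max(axis=1) >= min_fpm)
    retained = [g for g in counts.index if keep[g]]
    if not retained:
        raise CompendiumError("all genes filtered")
    n_removed = len(counts.index) - len(retained)
    if n_removed:
        logger.info("gene QC removed %d of %d genes", n_removed, len(counts.index))
    return retained


def qc_filter_replicates(
    logtpm: pd.DataFrame,
    replicate_groups: Mapping[str, str] | pd.Series,
    min_r2: float = MIN_REPLICATE_R2,
) -> list[str]:
    """Samples passing replicate-concordance QC, in input order.

    Within each replicate group of size >= 2, a sample is kept only if its
    squared Pearson correlation of log-TPM with at least one other group
    member is >= ``min_r2``.  In a discordant pair both samples are
    removed (no third replicate can arbitrate).  Singleton groups are kept
    unchanged.
    """
    groups = pd.Series(replicate_groups)
    retained: list[str] = []
    for sample in logtpm.columns:
        group = groups[sample]
        members = [s for s in logtpm.columns if groups[s] == group and s != sample]
        if not members:
            retained.append(sample)
            continue
        r2s = [
            np.corrcoef(logtpm[sample], logtpm[other])[0, 1] ** 2
            for other in members
        ]
        if max(r2s) >= min_r2:
            retained.append(sample)
        else:
            logger.info(
                "replicate QC removed sample %s (max R2 %.3f < %.2f)",
                sample,
                max(r2s),
                min_r2,
            )
    return retained


def center_to_reference(
    logtpm: pd.DataFrame,
    reference_samples: Sequence[str],
    metadata: pd.DataFrame | None = None,
) -> Compendium:
    """Subtract the per-gene mean over the reference samples.

    Every column is shifted by the same per-gene offset, so pairwise
    differences between samples are preserved exactly and the operation is
    idempotent.  Returns a centered :class:`Compendium`.
    """
    refs = list(reference_samples)
    if not refs:
        raise CompendiumError("reference_samples must be nonempty")
    unknown = set(refs) - set(logtpm.columns)
    if unknown:
        raise CompendiumError(f"unknown reference samples: {sorted(unknown)}")
    offset = logtpm[refs].mean(axis=1)
    centered = logtpm.sub(offset, axis=0)
    if metadata is None:
        metadata = pd.DataFrame(
            {
                "project": "unknown",
                "condition": "unknown",
                "replicate_group": list(logtpm.columns),
                "is_reference": [s in refs for s in logtpm.columns],
            },
            index=logtpm.columns,
        )
    return Compendium(
        centered, metadata, centered=True, reference_samples=refs
    )


@dataclass
class RegulonTable:
    """Regulator -> target-gene interactions restricted to a gene universe.

    ``interactions`` has columns ``regulator``, ``gene``, ``effect`` with
    effect one of {activation, repression, unknown}; duplicate pairs are
    collapsed and conflicting effects become unknown.
    """

    interactions: pd.DataFrame
    gene_universe: frozenset[str]

    def __post_init__(self) -> None:
        needed = {"regulator", "gene", "effect"}
        if not needed <= set(self.interactions.columns):
            raise CompendiumError(
                f"regulon table needs columns {sorted(needed)}"
            )
        outside = set(self.interactions["gene"]) - set(self.gene_universe)
        if outside:
            raise CompendiumError(
                f"interactions outside gene universe: {sorted(outside)[:5]}"
            )
        dup = self.interactions.duplicated(["regulator", "gene"])
        if dup.any():
            raise CompendiumError("duplicate (regulator, gene) interactions")

    @property
    def regulators(self) -> list[str]:
        return sorted(self.interactions["regulator"].unique())

    def regulon(self, regulator: str) -> set[str]:
        if regulator not in set(self.interactions["regulator"]):
            raise KeyError(f"unknown regulator: {regulator}")
        rows = self.interactions["regulator"] == regulator
        return set(self.interactions.loc[rows, "gene"])

    def __len__(self) -> int:
        return len(self.interactions)


def build_regulon_table(
    interactions: pd.DataFrame, gene_universe: Iterable[str]
) -> RegulonTable:
    """Normalize a raw interaction table against a gene universe.

    Drops interactions for genes outside the universe (logged), collapses
    duplicate (regulator, gene) rows, and resolves conflicting effect
    annotations to ``unknown``.
    """
    universe = frozenset(gene_universe)
    df = interactions.copy()
    if not {"regulator", "gene"} <= set(df.columns):
        raise CompendiumError("regulon table needs columns regulator, gene")
    if "effect" not in df.columns:
        df["effect"] = EFFECT_UNKNOWN
    df["effect"] = df["effect"].fillna(EFFECT_UNKNOWN)
    if df.empty:
        logger.warning("empty regulon table")
        return RegulonTable(
            pd.DataFrame(columns=["regulator", "gene", "effect"]), universe
        )
    in_universe = df["gene"].isin(universe)
    n_dropped = int((~in_universe).sum())
    if n_dropped:
        logger.info(
            "dropped %d interactions for genes outside the compendium", n_dropped
        )
    df = df[in_universe]

    def collapse(effects: pd.Series) -> str:
        vals = set(effects) - {EFFECT_UNKNOWN}
        if len(vals) == 1:
            return vals.pop()
        return EFFECT_UNKNOWN

    collapsed = (
        df.groupby(["regulator", "gene"], sort=False)["effect"]
        .agg(collapse)
        .reset_index()
    )
    return RegulonTable(collapsed, universe)


def read_regulon_table(
    path: str | Path, gene_universe: Iterable[str]
) -> RegulonTable:
    """Read a RegulonDB-style CSV (regulator, gene[, effect])."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if not {"regulator", "gene"} <= set(df.columns):
        raise CompendiumError(
            f"regulon table {path} needs columns regulator, gene"
        )
    return build_regulon_table(df, gene_universe)


def preprocess(
    counts: pd.DataFrame,
    lengths: pd.Series,
    metadata: pd.DataFrame,
    min_length: float = MIN_GENE_LENGTH,
    min_fpm: float = MIN_FPM,
    min_rep_r2: float = MIN_REPLICATE_R2,
) -> Compendium:
    """Full preprocessing: gene QC -> log-TPM -> replicate QC -> centering.

    Reference samples are those flagged ``is_reference`` in the metadata.
    """
    genes = qc_filter_genes(counts, lengths, min_length, min_fpm)
    logtpm = compute_log_tpm(counts.loc[genes], lengths)
    groups = metadata.loc[list(logtpm.columns), "replicate_group"]
    samples = qc_filter_replicates(logtpm, groups, min_rep_r2)
    logtpm = logtpm[samples]
    refs = [s for s in samples if metadata.loc[s, "is_reference"]]
    if not refs:
        raise CompendiumError("no reference samples survived QC")
    return center_to_reference(logtpm, refs, metadata.loc[samples])
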