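"""End-to-end workflow: preprocess -> decompose -> threshold -> enrich.

`RunConfig` holds every stage parameter with its standard default and a
single master seed; `run_pipeline` chains the stages, writes all
artifacts to the output directory, and records a manifest with parameter
values, seeds, and input checksums so a run is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compendium import (
    Compendium,
    gene_lengths_from_gff,
    gene_lengths_from_table,
    preprocess,
    read_expression_tsv,
    read_metadata,
    read_regulon_table,
)
from .decomposition import (
    D_MAX,
    DBSCAN_EPS,
    N_REPETITIONS,
    N_RESTARTS,
    TOLERANCE,
    VARIANCE_FRACTION,
    cev_curve,
    robust_components,
)
from .enrichment import FDR_ALPHA, MAX_REGULATORS, enrichment_table, enumerate_and_test
from .thresholding import (
    CUTOFF_GRID,
    DEFAULT_CUTOFF,
    ThresholdingError,
    compute_imodulons,
    imodulons_to_frame,
    scan_cutoff,
)

logger = logging.getLogger(__name__)

ARTIFACTS = (
    "compendium.tsv",
    "S.tsv",
    "A.tsv",
    "imodulons.json",
    "enrichment.tsv",
    "manifest.json",
)


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters, with standard defaults."""

    # inputs: either counts + lengths, or a precomputed log-TPM matrix
    counts: str | None = None
    lengths: str | None = None
    logtpm: str | None = None
    metadata: str | None = None
    trn: str | None = None
    out_dir: str = "imodkit_run"

    # preprocessing
    min_gene_length: float = 100.0
    min_fpm: float = 10.0
    min_rep_r2: float = 0.9

    # decomposition
    n_restarts: int = N_RESTARTS
    n_repetitions: int = N_REPETITIONS
    tolerance: float = TOLERANCE
    eps: float = DBSCAN_EPS
    d_max: float = D_MAX
    variance_fraction: float = VARIANCE_FRACTION
    n_components: int | None = None

    # thresholding / enrichment
    cutoff: float = DEFAULT_CUTOFF
    scan_grid: list[float] | None = None
    enrichment_fdr: float = FDR_ALPHA
    max_regulators: int = MAX_REGULATORS

    # differential activity defaults (recorded for provenance)
    abs_activity_threshold: float = 5.0
    diff_fdr: float = 0.01

    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow and return the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    logger.info("[preprocess] loading inputs")
    if config.metadata is None:
        raise ValueError("config.metadata is required")
    metadata = read_metadata(config.metadata)
    inputs["metadata"] = _checksum(config.metadata)
    if config.logtpm is not None:
        logtpm = read_expression_tsv(config.logtpm)
        inputs["logtpm"] = _checksum(config.logtpm)
        refs = [s for s in logtpm.columns if metadata.loc[s, "is_reference"]]
        from .compendium import center_to_reference

        compendium = center_to_reference(logtpm, refs, metadata.loc[list(logtpm.columns)])
    elif config.counts is not None and config.lengths is not None:
        counts = read_expression_tsv(config.counts)
        inputs["counts"] = _checksum(config.counts)
        if str(config.lengths).endswith((".gff", ".gff3")):
            lengths = gene_lengths_from_gff(config.lengths)
        else:
            lengths = gene_lengths_from_table(config.lengths)
        inputs["lengths"] = _checksum(config.lengths)
        compendium = preprocess(
            counts,
            lengths,
            metadata,
            min_length=config.min_gene_length,
            min_fpm=config.min_fpm,
            min_rep_r2=config.min_rep_r2,
        )
    else:
        raise ValueError("config needs either logtpm or counts + lengths")
    compendium.to_tsv(out / "compendium.tsv")

    logger.info("[decompose] robust ICA")
    decomposition = robust_components(
        compendium.values,
        n_components=config.n_components,
        n_restarts=config.n_restarts,
        n_repetitions=config.n_repetitions,
        tolerance=config.tolerance,
        eps=config.eps,
        d_max=config.d_max,
        variance_fraction=config.variance_fraction,
        seed=config.seed,
    )

    trn = None
    if config.trn is not None:
        trn = read_regulon_table(config.trn, compendium.genes)
        inputs["trn"] = _checksum(config.trn)

    logger.info("[threshold] gene-coefficient cutoff")
    cutoff = config.cutoff
    scan_curve = None
    if config.scan_grid and trn is not None and len(trn):
        try:
            cutoff, scan_curve = scan_cutoff(
                decomposition.S, trn, grid=config.scan_grid
            )
        except ThresholdingError as err:
            logger.warning("cutoff scan failed (%s); using default %.0f", err, cutoff)
    elif trn is None:
        logger.warning("no TRN supplied; using default cutoff %.0f", cutoff)
    imodulons, oriented = compute_imodulons(decomposition, cutoff)
    oriented.save(out)

    logger.info("[enrich] regulon associations")
    records = []
    if trn is not None and len(trn):
        for im in imodulons:
            hits = enumerate_and_test(
                im.genes,
                trn,
                imodulon_name=im.name,
                fdr_alpha=config.enrichment_fdr,
                max_regs=config.max_regulators,
            )
            if hits:
                im.enrichment = hits[0]
                im.category = "regulatory"
            records.extend(hits)
    else:
        logger.warning("enrichment skipped: no TRN")
    enrichment_table(records).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    imod_payload = [
        {
            "name": im.name,
            "component_index": im.component_index,
            "threshold_stat": im.threshold_stat,
            "orientation_flipped": im.orientation_flipped,
            "category": im.category,
            "genes": {g: float(w) for g, w in im.gene_weights.items()},
            "regulators": im.enrichment.label if im.enrichment else None,
        }
        for im in imodulons
    ]
    (out / "imodulons.json").write_text(json.dumps(imod_payload, indent=2))
    imodulons_to_frame(imodulons).to_csv(out / "imodulons.tsv", sep="\t", index=False)

    cev = cev_curve(compendium.values, oriented)
    manifest = {
        "imodkit_version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "inputs_sha256": inputs,
        "cutoff_used": float(cutoff),
        "n_robust_components": decomposition.n_components,
        "n_imodulons": len(imodulons),
        "cev_all_components": float(cev.iloc[-1]) if len(cev) else 0.0,
        "artifacts": list(ARTIFACTS),
        "tsv_precision": "10 significant digits",
    }
    if scan_curve is not None:
        manifest["scan_curve"] = scan_curve.to_dict(orient="list")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("[done] %d i-modulons in %s", len(imodulons), out)
    return out
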