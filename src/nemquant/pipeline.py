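"""Pipeline configuration, atomic artifact writing, and the end-to-end demo.

The demo runs simulate -> classify -> excess curve -> GO-stratified excess ->
Fisher enrichment -> chronogram lag on synthetic data and bundles everything
into a single JSON report that embeds every parameter needed to regenerate it
(no timestamps, so equal seeds give byte-identical reports).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import DEFAULT_EVALUE_CUTOFF, classify_genes
from .enrich import DEFAULT_LEVELS, enrichment_test
from .errors import DataValidationError
from .excess import (
    DEFAULT_THRESHOLDS,
    MatchingScheme,
    estimates_to_frame,
    excess_curve,
    go_excess,
)
from .io import write_gene_stats
from .lag import compute_lag, write_clade_map
from .simulate import generate_gene_stats, generate_paired_chronograms, \
    generate_similarity_table, preset_config

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every knob of the demo pipeline, checkable at load time."""

    seed: int = 0
    out_dir: str = "nemquant_demo"
    # synthetic data
    preset: str = "headline"
    n_nem: int = 300
    n_nonnem: int = 3000
    # similarity / classification
    hit_rate_nem: float = 0.95
    false_hit_rate: float = 0.02
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    # matching scheme
    alpha: float = 0.95
    x_period: int = 3
    band_low: float = 0.95
    band_high: float = 1.05
    initial_free_draws: int = 5
    max_tries_per_slot: int = 10000
    # quantification
    thresholds: tuple = DEFAULT_THRESHOLDS
    n_perm: int = 200
    # GO stratification
    min_genes: int = 20
    top_k: int = 10
    # enrichment
    levels: tuple = DEFAULT_LEVELS
    # calibration
    alpha_grid: tuple = (0.90, 0.95, 1.0)
    x_grid: tuple = (1, 3, 5)
    n_cal: int = 200
    # chronograms
    n_taxa: int = 8
    lag: float = 44.0
    root_age: float = 740.0
    lag_jitter: float = 10.0
    verbosity: str = "INFO"

    def __post_init__(self):
        self.scheme  # validates scheme fields
        if self.n_perm < 1 or self.n_nem < 1 or self.n_nonnem < 1:
            raise DataValidationError("counts must be positive")
        if list(self.thresholds) != sorted(self.thresholds, reverse=True):
            raise DataValidationError("thresholds must be sorted descending")

    @property
    def scheme(self) -> MatchingScheme:
        return MatchingScheme(
            alpha=self.alpha,
            x_period=self.x_period,
            band_low=self.band_low,
            band_high=self.band_high,
            initial_free_draws=self.initial_free_draws,
            max_tries_per_slot=self.max_tries_per_slot,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DataValidationError(f"unknown config key(s): {sorted(unknown)}")
        data = {
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        }
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise DataValidationError("config file must hold a key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for k, v in out.items():
            if isinstance(v, tuple):
                out[k] = list(v)
        return out


def atomic_write_text(text: str, dest: Path) -> None:
    """Write via a temp file in the same directory, then rename."""
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=dest.parent, prefix=f".{dest.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, dest)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_frame(df: pd.DataFrame, dest: Path) -> None:
    atomic_write_text(df.to_csv(sep="\t", index=False), dest)


def run_demo(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline; write artifacts; return the report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme

    logger.info("simulate: preset=%s n_nem=%d n_nonnem=%d seed=%d",
                config.preset, config.n_nem, config.n_nonnem, config.seed)
    sim_config = preset_config(
        config.preset, n_nem=config.n_nem, n_nonnem=config.n_nonnem, seed=config.seed
    )
    records = generate_gene_stats(sim_config)
    write_gene_stats(
        records.drop(columns=["true_class", "true_mu"]), out_dir / "gene_stats.tsv"
    )

    similarity = generate_similarity_table(
        records, config.hit_rate_nem, config.false_hit_rate, seed=config.seed + 1
    )
    atomic_write_frame(similarity, out_dir / "similarity.tsv")
    classification = classify_genes(similarity, records["gene_id"], config.evalue_cutoff)
    atomic_write_frame(
        pd.DataFrame(
            {"gene_id": list(classification), "nem_status": list(classification.values())}
        ),
        out_dir / "classification.tsv",
    )
    n_mismatch = int(
        (records["nem_status"].to_numpy() != [classification[g] for g in records["gene_id"]]).sum()
    )
    logger.info("classify: %d/%d labels differ from ground truth", n_mismatch, len(records))

    logger.info("excess curve over %d thresholds, n_perm=%d", len(config.thresholds), config.n_perm)
    curve = excess_curve(
        records,
        thresholds=config.thresholds,
        scheme=scheme,
        n_perm=config.n_perm,
        seed=config.seed + 2,
    )
    atomic_write_frame(estimates_to_frame(curve), out_dir / "excess_curve.tsv")

    categories = go_excess(
        records,
        threshold=0.5,
        scheme=scheme,
        n_perm=config.n_perm,
        min_genes=config.min_genes,
        top_k=config.top_k,
        seed=config.seed + 3,
    )
    go_frame = estimates_to_frame([c.estimate for c in categories])
    if len(go_frame):
        go_frame["q_value"] = [c.q_value for c in categories]
    atomic_write_frame(go_frame, out_dir / "go_excess.tsv")

    enrichment = enrichment_test(records, levels=config.levels)
    atomic_write_frame(
        pd.DataFrame([e.to_dict() for e in enrichment]), out_dir / "enrichment.tsv"
    )

    nem_tree, org_tree, clade_map = generate_paired_chronograms(
        config.n_taxa,
        config.lag,
        config.root_age,
        seed=config.seed + 4,
        jitter=config.lag_jitter,
    )
    atomic_write_text(nem_tree.as_newick(), out_dir / "nematocyst.nwk")
    atomic_write_text(org_tree.as_newick(), out_dir / "organismal.nwk")
    write_clade_map(clade_map, out_dir / "clade_map.tsv")
    lag_report = compute_lag(nem_tree, org_tree, clade_map)
    atomic_write_frame(lag_report.to_frame(), out_dir / "lag.tsv")

    cfg_payload = config.to_dict()
    cfg_payload.pop("out_dir")  # not a scientific parameter; keep reports comparable
    report = {
        "nemquant_version": __version__,
        "config": cfg_payload,
        "classification_mismatches": n_mismatch,
        "excess_curve": [e.to_dict() for e in curve],
        "go_excess": [
            {**c.estimate.to_dict(), "q_value": c.q_value} for c in categories
        ],
        "enrichment": [e.to_dict() for e in enrichment],
        "lag": {
            "clades": [c.to_dict() for c in lag_report.clades],
            "min_lag": lag_report.min_lag,
            "max_lag": lag_report.max_lag,
            "mean_lag": lag_report.mean_lag,
        },
    }
    atomic_write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                      out_dir / "report.json")
    logger.info("demo complete; report at %s", out_dir / "report.json")
    return report
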