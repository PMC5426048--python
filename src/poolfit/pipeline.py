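"""End-to-end orchestration: simulate -> count -> fit -> hits/survivors.

A :class:`PipelineConfig` collects every fixed constant of the screen's
analysis (read filter 30, Z cut -1.5, abundance cut 2, last-2-time-points
survivor window, 1-mismatch barcode matching) together with input/output
paths and the random seed.  ``run_pipeline`` executes the stages in order,
writes every intermediate table as TSV, and emits a JSON run manifest
(package version, seed, config hash, per-stage row counts, output file
hashes) sufficient to verify a byte-identical re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .config import ConfigurationError, FitnessSpec, InitSpec, SimConfig, TakeoverSpec
from .counting import count_reads, load_manifest, load_reference
from .fitness import (
    call_hits,
    call_survivors,
    collapse_technical,
    count_identified,
    fit_growth_rates,
    normalize,
    summarize_hits,
)
from .simulate import emit_fastq, make_reference, make_tag_manifest, simulate_counts

logger = logging.getLogger("poolfit")


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    out_dir: Path
    counts: Path | None = None  # existing CountTable TSV; simulate when None
    sim: dict = field(default_factory=dict)  # SimConfig field overrides
    via_fastq: bool = False  # simulate -> FASTQ -> counting round trip
    min_reads: int = 30
    z_threshold: float = -1.5
    abundance_threshold: float = 2.0
    last_k: int = 2
    max_mismatch: int = 1
    truncate: dict = field(default_factory=dict)  # condition -> leading time points
    survivors: dict | None = None  # {'pool': ..., 'condition': ...}
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        cfg.out_dir = Path(cfg.out_dir)
        if cfg.counts is not None:
            cfg.counts = Path(cfg.counts)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("min_reads", "z_threshold", "abundance_threshold", "last_k", "max_mismatch"):
            v = getattr(self, name)
            if v is None or not pd.notna(v):
                raise ConfigurationError(f"threshold {name} must be finite, got {v!r}")
        if self.counts is not None and not Path(self.counts).exists():
            raise ConfigurationError(f"counts file not found: {self.counts}")
        if self.truncate and not all(isinstance(k, str) and int(v) >= 2 for k, v in self.truncate.items()):
            raise ConfigurationError("truncate must map condition names to >= 2 time points")
        self.sim_config()  # validates simulator overrides

    def sim_config(self) -> SimConfig:
        return sim_config_from_dict({"seed": self.seed, **self.sim})

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in dataclasses.asdict(self).items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def sim_config_from_dict(raw: Mapping[str, Any]) -> SimConfig:
    """Build a SimConfig from a flat dict (nested specs as sub-dicts)."""
    raw = dict(raw)
    kwargs: dict[str, Any] = {}
    if "fitness_spec" in raw:
        kwargs["fitness_spec"] = FitnessSpec(**raw.pop("fitness_spec"))
    if "init_spec" in raw:
        kwargs["init_spec"] = InitSpec(**raw.pop("init_spec"))
    if "takeover" in raw and raw["takeover"] is not None:
        kwargs["takeover"] = TakeoverSpec(**raw.pop("takeover"))
    else:
        raw.pop("takeover", None)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown simulator keys: {sorted(unknown)}")
    kwargs.update(raw)
    if "schedule" in kwargs:
        kwargs["schedule"] = tuple(float(g) for g in kwargs["schedule"])
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and return the run manifest.

    Stages: obtain counts (load, simulate directly, or simulate through a
    FASTQ round trip), fit growth rates, call hits, optionally call
    survivors, and summarize screen yield.  Every table is written under
    ``config.out_dir`` and hashed into ``manifest.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "poolfit_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    # --- counts -----------------------------------------------------------
    if config.counts is not None:
        counts = read_count_table(config.counts)
        truth = None
        logger.info("loaded %d count rows from %s", len(counts), config.counts)
    else:
        sim_cfg = config.sim_config()
        truth, counts = simulate_counts(sim_cfg)
        truth.write_tsv(out / "truth.tsv")
        if config.via_fastq:
            ref = make_reference(sim_cfg)
            _write(ref, out / "reference.tsv")
            fq, mani_path = emit_fastq(counts, ref, sim_cfg, out)
            result = count_reads(fq, load_manifest(mani_path), load_reference(out / "reference.tsv"),
                                 max_mismatch=config.max_mismatch, barcode_len=sim_cfg.barcode_len)
            _write(result.qc, out / "counting_qc.tsv")
            counts = result.counts
            manifest["stages"]["counting"] = {
                "total_reads": result.total_reads,
                "unassigned": result.unassigned,
            }
        logger.info("simulated %d count rows", len(counts))
    _write(counts, out / "counts.tsv")
    manifest["stages"]["counts"] = {"rows": int(len(counts))}

    # --- abundance and growth rates --------------------------------------
    abundance = collapse_technical(normalize(counts))
    _write(abundance, out / "abundance.tsv")
    growth = fit_growth_rates(
        counts, min_reads=config.min_reads, truncate=config.truncate, abundance=abundance
    )
    _write(growth, out / "growth_rates.tsv")
    manifest["stages"]["growth_rates"] = {"rows": int(len(growth))}

    # --- hits -------------------------------------------------------------
    hits = call_hits(growth, z_threshold=config.z_threshold)
    _write(hits, out / "hits.tsv")
    manifest["stages"]["hits"] = {
        "rows": int(len(hits)),
        **summarize_hits(hits),
    }

    # --- survivors --------------------------------------------------------
    if config.survivors:
        surv = call_survivors(
            abundance,
            pool=config.survivors["pool"],
            condition=config.survivors["condition"],
            threshold=config.abundance_threshold,
            last_k=config.last_k,
        )
        _write(surv, out / "survivors.tsv")
        manifest["stages"]["survivors"] = {
            "rows": int(len(surv)),
            "n_survivors": int(surv["is_survivor"].sum()),
        }

    # --- screen yield -----------------------------------------------------
    per_pool, per_tp = count_identified(counts, min_reads=config.min_reads)
    _write(per_tp, out / "identified_per_timepoint.tsv")
    manifest["stages"]["identified"] = {p: int(v) for p, v in per_pool.items()}

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a CountTable TSV, enforcing the documented schema."""
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str, "bio_rep": str})
    from .simulate import COUNT_COLUMNS

    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"count table missing columns: {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ConfigurationError("negative counts in count table")
    return df
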