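"""One-shot pipeline: loci building, preprocessing, discovery,
replicate intersection, condition union and quantification.

The stage order mirrors typical use on a multi-replicate experiment:
per-sample DoGs are intersected within each condition (DoGs common to
all replicates), the per-condition sets are unified into one
annotation, and every sample is quantified over that unified
annotation so expression is comparable across conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import yaml

from . import __version__, formats_io
from .discovery import discover_dogs
from .genomic_model import DoGParams, DoGRecord
from .loci_builder import build_loci
from .preprocess import (
    DEFAULT_SAMPLE_SIZE,
    DEFAULT_STRAND_THRESHOLD,
    SampleManifest,
    preprocess_samples,
)
from .quantification import compute_rpkm
from .setops import common_dogs, union_dogs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_all"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    annotations: List[str]
    samples: List[Dict[str, str]]  # each: {"path": ..., "condition": ...}
    out_dir: str
    params: DoGParams = dc_field(default_factory=DoGParams)
    downsample_target: Union[int, str] = "auto"
    seed: int = 1
    strand_threshold: float = DEFAULT_STRAND_THRESHOLD
    strand_sample_size: int = DEFAULT_SAMPLE_SIZE
    threads: int = 1

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            annotations = list(raw["annotations"])
            samples = list(raw["samples"])
            out_dir = raw["out_dir"]
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc.args[0]}") from exc
        params = DoGParams(**raw.get("params", {}))
        cfg = cls(
            annotations=annotations,
            samples=[
                s if isinstance(s, dict) else {"path": s, "condition": "all"}
                for s in samples
            ],
            out_dir=out_dir,
            params=params,
            downsample_target=raw.get("downsample_target", "auto"),
            seed=int(raw.get("seed", 1)),
            strand_threshold=float(raw.get("strand_threshold", DEFAULT_STRAND_THRESHOLD)),
            strand_sample_size=int(raw.get("strand_sample_size", DEFAULT_SAMPLE_SIZE)),
            threads=int(raw.get("threads", 1)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.annotations:
            raise ConfigError("at least one annotation file is required")
        if not self.samples:
            raise ConfigError("at least one sample is required")
        for p in self.annotations:
            if not Path(p).exists():
                raise ConfigError(f"annotation file not found: {p}")
        for s in self.samples:
            if "path" not in s:
                raise ConfigError(f"sample entry without a path: {s!r}")
            if not Path(s["path"]).exists():
                raise ConfigError(f"sample file not found: {s['path']}")
            s.setdefault("condition", "all")

    def to_yaml(self, path: Union[str, Path]) -> None:
        payload = {
            "dogscan_version": __version__,
            "annotations": self.annotations,
            "samples": self.samples,
            "out_dir": self.out_dir,
            "params": {
                "min_dog_len": self.params.min_dog_len,
                "min_dog_cov": self.params.min_dog_cov,
                "window_len": self.params.window_len,
                "window_step": self.params.window_step,
            },
            "downsample_target": self.downsample_target,
            "seed": self.seed,
            "strand_threshold": self.strand_threshold,
            "strand_sample_size": self.strand_sample_size,
            "threads": self.threads,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _sample_names(samples: Sequence[Dict[str, str]]) -> List[str]:
    """Unique per-sample output names (file stem, suffixed on collision)."""
    names: List[str] = []
    seen: Dict[str, int] = {}
    for s in samples:
        base = s.get("name") or Path(s["path"]).stem
        seen[base] = seen.get(base, 0) + 1
        names.append(base if seen[base] == 1 else f"{base}_{seen[base]}")
    return names


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Stage failures abort with the stage name; outputs of completed
    stages are retained.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "run_config.yaml")

    stage = "build-loci"
    try:
        loci = build_loci(config.annotations)
        loci.to_bed(out_dir / "loci.bed")

        stage = "preprocess"
        names = _sample_names(config.samples)
        manifest: SampleManifest = preprocess_samples(
            [s["path"] for s in config.samples],
            loci,
            out_dir,
            target=config.downsample_target,
            seed=config.seed,
            sample_size=config.strand_sample_size,
            threshold=config.strand_threshold,
            threads=config.threads,
            names=names,
        )
        manifest.to_json(out_dir / "manifest.json")

        stage = "get-dogs"
        per_sample: Dict[str, List[DoGRecord]] = {}
        for entry, name in zip(manifest.samples, names):
            dogs = discover_dogs(
                entry.downsampled_path, loci, config.params, entry.spec
            )
            formats_io.write_bed(dogs, out_dir / f"{name}.dogs.bed")
            per_sample[name] = dogs

        stage = "common"
        conditions: Dict[str, List[str]] = {}
        for sample, name in zip(config.samples, names):
            conditions.setdefault(sample["condition"], []).append(name)
        per_condition: Dict[str, List[DoGRecord]] = {}
        for condition, member_names in conditions.items():
            sets = [per_sample[n] for n in member_names]
            combined = common_dogs(sets) if len(sets) >= 2 else sets[0]
            formats_io.write_bed(combined, out_dir / f"{condition}.common.bed")
            per_condition[condition] = combined

        stage = "union"
        unified = union_dogs(list(per_condition.values()))
        formats_io.write_bed(unified, out_dir / "dogs.union.bed")

        stage = "rpkm"
        for entry, name in zip(manifest.samples, names):
            out_path = out_dir / f"{name}.dogs.tsv"
            if not unified:
                formats_io.write_expression_table([], out_path)
                continue
            expr = compute_rpkm(entry.downsampled_path, unified, entry.spec)
            formats_io.write_expression_table(
                expr,
                out_path,
                comments=[
                    f"sample: {name}",
                    f"total_mapped (downsampled): {expr[0].total_mapped}",
                ],
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline complete: %s", out_dir)
    return out_dir
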