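"""End-to-end pipeline: read, subset, filter, fit, call, compare.

A :class:`PipelineConfig` (built directly, from a dict, or from a YAML file)
drives :func:`run_pipeline`, which writes every intermediate table as TSV to
the output directory together with a ``manifest.json`` listing each stage's
outputs with content hashes.  Reruns with the same inputs and config produce
byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .compare import crosstab, region_table
from .decision import Thresholds, run_method_one, run_method_two
from .filtering import FilterRule, filter_genes, subset_weeks

log = logging.getLogger("interactdeg")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    counts: str
    metadata: str
    outdir: str
    weeks: tuple[int, ...] = (3, 6)
    filter_kind: str = "max_zero_fraction"
    filter_threshold: float = 0.5
    alpha_fdr: float = 0.05
    lfc_threshold: float = float(np.log2(1.5))
    lfc_basis: str = "shrunk"
    methods: tuple[str, ...] = ("I", "II")
    ref_week: int = 3
    target_week: int = 6
    seed: int = 0

    def __post_init__(self):
        self.weeks = tuple(int(w) for w in self.weeks)
        self.methods = tuple(self.methods)
        unknown = set(self.methods) - {"I", "II"}
        if unknown:
            raise PipelineError(f"unknown method(s) {sorted(unknown)}")
        if self.lfc_basis not in {"shrunk", "raw"}:
            raise PipelineError("lfc_basis must be 'shrunk' or 'raw'")
        if self.ref_week not in self.weeks or self.target_week not in self.weeks:
            raise PipelineError("ref_week and target_week must be in the week subset")
        Thresholds(self.alpha_fdr, self.lfc_threshold)  # validates
        FilterRule(self.filter_kind, self.filter_threshold)  # validates

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(self.alpha_fdr, self.lfc_threshold)


class PipelineResult(NamedTuple):
    decisions: dict[str, pd.DataFrame]
    overlap: pd.DataFrame | None
    regions: pd.DataFrame | None
    manifest_path: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, stage: str, manifest: list) -> None:
    df.to_csv(path, sep="\t")
    manifest.append(
        {"stage": stage, "path": path.name, "sha256": _sha256(path), "n_rows": len(df)}
    )
    log.info("%s: wrote %s (%d rows)", stage, path.name, len(df))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the configured stages and write a manifest of every output."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    counts = _io.read_counts(config.counts)
    metadata = _io.align(counts, _io.read_metadata(config.metadata))
    missing = set(config.weeks) - set(metadata["weeks"])
    if missing:
        raise PipelineError(f"configured week(s) {sorted(missing)} absent from metadata")

    counts, metadata = subset_weeks(counts, metadata, config.weeks)
    rule = FilterRule(config.filter_kind, config.filter_threshold)
    counts, removal = filter_genes(counts, rule)
    _write(removal.set_index("gene_id"), outdir / "removed_genes.tsv", "filter", manifest)

    thresholds = config.thresholds
    decisions: dict[str, pd.DataFrame] = {}
    run_ii = None
    if "I" in config.methods:
        run_i = run_method_one(
            counts,
            metadata,
            ref_week=config.ref_week,
            target_week=config.target_week,
            thresholds=thresholds,
            basis=config.lfc_basis,
        )
        decisions["I"] = run_i.decisions
        for name, tab in run_i.tests.items():
            _write(tab, outdir / f"tests_method_I_{name}.tsv", "fit", manifest)
        _write(run_i.decisions, outdir / "decisions_method_I.tsv", "call", manifest)
    if "II" in config.methods:
        run_ii = run_method_two(
            counts,
            metadata,
            target_week=config.target_week,
            thresholds=thresholds,
            basis=config.lfc_basis,
        )
        decisions["II"] = run_ii.decisions
        for name, tab in run_ii.tests.items():
            safe = name.replace(":", "_").replace("[", "").replace("]", "")
            _write(tab, outdir / f"tests_method_II_{safe}.tsv", "fit", manifest)
        _write(run_ii.decisions, outdir / "decisions_method_II.tsv", "call", manifest)

    overlap = None
    if set(decisions) == {"I", "II"}:
        overlap = crosstab(decisions["I"], decisions["II"])
        overlap.index.name = "direction"
        _write(overlap, outdir / "overlap.tsv", "compare", manifest)

    regions = None
    if run_ii is not None:
        res = run_ii.fits["interaction"]
        contrast = run_ii.decisions.attrs["contrast"]
        main = contrast.split(":")[0]
        regions = region_table(res, main, contrast, config.lfc_threshold, tests=run_ii.tests)
        _write(regions, outdir / "regions.tsv", "compare", manifest)

    manifest_path = outdir / "manifest.json"
    manifest_doc = {"config": asdict(config), "outputs": manifest}
    manifest_path.write_text(json.dumps(manifest_doc, indent=2, default=str) + "\n")
    return PipelineResult(decisions, overlap, regions, manifest_path)
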