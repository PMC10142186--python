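"""End-to-end orchestration: files in, model-output table and artifacts out.

Stages: read venom table -> clean -> read diet records -> aggregate and
filter at each taxonomic level -> per-record diversity table -> read tree
sample -> select MCC tree -> per (index, level): prune, build Brownian
covariance, collapse replicates, multistart fit + LRT -> report.

All intermediates are written to the output directory (diversity.tsv,
cleaning.json, mcc.nwk, report.tsv, welch.json, run.log) so any stage can be
audited or restarted from disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import compositions as comp
from . import inference, phylo, regression
from .errors import DataFormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and run controls for one pipeline invocation."""

    venom_path: str
    diet_path: str
    trees_path: str
    outdir: str
    max_total_percent: float = 110.0
    min_total_percent: float = 90.0
    min_diet_items: int = 5
    indices: tuple[str, ...] = ("simpson", "shannon")
    levels: tuple[str, ...] = ("family", "order")
    n_runs: int = 100
    n_starts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_total_percent <= 0 or self.min_total_percent < 0:
            raise ValidationError("abundance thresholds must be positive")
        if not self.indices or not self.levels:
            raise ValidationError("select at least one index and one diet level")
        bad = set(self.indices) - {"shannon", "simpson"}
        if bad:
            raise DataFormatError(f"unknown indices {sorted(bad)}")
        bad = set(self.levels) - {"family", "order"}
        if bad:
            raise DataFormatError(f"unknown diet levels {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("indices", "levels"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> list[inference.AnalysisSummary]:
    """Execute every stage and write all artifacts; returns the summaries."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("venomdiet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> list[inference.AnalysisSummary]:
    profiles = comp.read_venom_profiles(config.venom_path)
    profiles, venom_report = comp.clean_venom_profiles(
        profiles, config.max_total_percent, config.min_total_percent
    )
    logger.info(
        "venom cleaning: %d/%d records retained", venom_report.n_retained, venom_report.n_input
    )

    diet_records = comp.read_diet_records(config.diet_path)
    diet_by_level, diet_reports = {}, []
    for level in ("family", "order"):
        tables = comp.aggregate_diet(diet_records, level)
        kept, report = comp.filter_diet(tables, config.min_diet_items)
        diet_by_level[level] = kept
        diet_reports.append(report)
        logger.info("diet filter (%s): %d/%d species retained", level,
                    report.n_retained, report.n_input)

    comp.CleaningReport.merged([venom_report, *diet_reports]).to_json(outdir / "cleaning.json")

    table, dropped = comp.diversity_table(
        profiles, diet_by_level["family"], diet_by_level["order"]
    )
    if dropped:
        logger.info("species with venom but no diet data: %s", dropped)
    table.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    logger.info(
        "diversity table: %d records across %d species",
        len(table), table["species"].nunique(),
    )

    sample = phylo.read_trees(config.trees_path)
    tree, score = phylo.mcc_tree(sample)
    logger.info("MCC tree selected from %d trees (score %.4f)", len(sample), score)
    phylo.write_tree(tree, outdir / "mcc.nwk")

    # methodological bias check: proteome vs transcriptome venom diversity
    welch = {}
    for index in config.indices:
        col = f"venom_{index}"
        a = table.loc[table["method"] == "proteome", col]
        b = table.loc[table["method"] == "transcriptome", col]
        if len(a) >= 2 and len(b) >= 2:
            res = inference.welch_t_test(a, b)
            welch[index] = dataclasses.asdict(res)
            logger.info("Welch t (proteome vs transcriptome, %s): t=%.3f df=%.3f p=%.3f",
                        index, res.t, res.df, res.p)
    (outdir / "welch.json").write_text(json.dumps(welch, indent=2) + "\n")

    tips = set(phylo.tip_labels(tree))
    summaries = []
    for index in config.indices:
        for level in config.levels:
            dataset = comp.analysis_dataset(table, index, level)
            species = sorted(set(dataset["species"]))
            overlap = [s for s in species if s in tips]
            if len(overlap) < 3:
                raise ValidationError(
                    f"({index}, {level}): only {len(overlap)} species shared between "
                    f"data and tree; data species {species}, tree tips {sorted(tips)}"
                )
            missing = sorted(set(species) - tips)
            if missing:
                logger.info("(%s, %s): %d species not in tree, dropped: %s",
                            index, level, len(missing), missing)
                dataset = dataset[dataset["species"].isin(overlap)]
            pruned = phylo.prune_to_taxa(tree, overlap)
            C = phylo.bm_covariance(pruned)
            data = regression.summarize_replicates(dataset)
            summary = inference.multistart_analysis(
                data,
                C,
                n_runs=config.n_runs,
                seed=config.seed,
                n_starts=config.n_starts,
                index=index,
                diet_level=level,
            )
            logger.info(
                "(%s, %s): n=%d species, coefficient %.4f, LR %.3f, p %.3g, "
                "%d/%d runs converged",
                index, level, data.n, summary.mean_coefficient, summary.LR, summary.p,
                summary.n_runs - summary.n_nonconverged, summary.n_runs,
            )
            summaries.append(summary)

    inference.build_report(summaries, outdir / "report.tsv")
    return summaries
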