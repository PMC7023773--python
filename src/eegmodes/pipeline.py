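"""End-to-end pipeline: simulate -> decompose -> select -> featurize ->
classify -> report.

Every stage consumes and produces plain files plus the config, so stages
are rerunnable individually; ``run_pipeline`` chains them and writes a run
log recording the seeds and every default actually used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np

from . import __version__
from .classify import CLASSIFIERS, CVResult, cross_validate, hemisphere_summary
from .decompose import IMFSet, SiftConfig, emd, eemd
from .features import FeatureTable, build_feature_table
from .io import (
    read_segments,
    summary_table,
    write_cv_results,
    write_feature_table,
    write_ranking_matrix,
    write_segments,
    write_selection,
)
from .selection import SelectionResult, build_ranking_matrix, consensus_select
from .synthetic import CHANNELS_10, EEGEpoch, GeneratorConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

DECOMPOSERS = ("emd", "eemd", "dwt", "raw")


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible end-to-end run."""

    decomposer: str = "emd"
    sift: SiftConfig = field(default_factory=SiftConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    selection_k: int = 3
    feature_groups: Sequence[str] = ("time", "spectral", "nonlinear")
    classifiers: Sequence[str] = CLASSIFIERS
    folds: int = 5
    seed: int = 0
    input_path: str | None = None  # None -> simulate
    output_dir: str = "eegmodes_out"
    per_channel_summary: bool = True

    def __post_init__(self) -> None:
        if self.decomposer not in DECOMPOSERS:
            raise ValueError(f"decomposer must be one of {DECOMPOSERS}")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")
        # one master seed flows to every stage
        self.sift = dataclasses.replace(self.sift, seed=self.seed)
        self.generator = dataclasses.replace(self.generator, seed=self.seed)

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sift = SiftConfig(**raw.pop("sift", {}))
        gen = GeneratorConfig(**raw.pop("generator", {}))
        return cls(sift=sift, generator=gen, **raw)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["generator"].pop("channel_names", None)
        return d


def _load_or_simulate(config: PipelineConfig) -> List[EEGEpoch]:
    if config.input_path is None:
        return generate_dataset(config.generator)
    return read_segments(config.input_path)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages in order and write the report bundle.

    Writes, under ``config.output_dir``: the segment manifest (when
    simulating), the ranking matrix and selection histogram (EMD/EEMD
    modes), one feature table per feature group, cross-validation results
    for every classifier, the optional per-channel hemisphere summary,
    and ``run_log.json``.  Returns the report as a dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {"config": config.to_dict(), "versions": _versions()}

    segments = _load_or_simulate(config)
    if config.input_path is None:
        write_segments(segments, out / "segments")
    labels = [s.label for s in segments]
    report["n_segments"] = len(segments)
    report["class_counts"] = {
        lab: int(sum(l == lab for l in labels)) for lab in sorted(set(labels))
    }

    selection: SelectionResult | None = None
    imf_sets: List[IMFSet] | None = None
    if config.decomposer in ("emd", "eemd"):
        decompose = emd if config.decomposer == "emd" else eemd
        imf_sets = [decompose(s.data[0], config.sift) for s in segments]
        matrix = build_ranking_matrix(
            segments, config.decomposer, config.sift, imf_sets=imf_sets
        )
        write_ranking_matrix(matrix, out / "ranking_matrix.tsv")
        selection = consensus_select(matrix, k=config.selection_k)
        write_selection(selection, out / "selection.json")
        report["ranking_matrix_shape"] = list(matrix.shape)
        report["selected_imfs"] = list(selection.selected)
        components = "imf"
    elif config.decomposer == "dwt":
        components = "dwt"
    else:
        components = "raw"

    tables: Dict[str, FeatureTable] = {}
    for group in config.feature_groups:
        table = build_feature_table(
            segments,
            components=components,
            groups=(group,),
            selected_imfs=selection.selected if selection else (1, 2, 3),
            decomposer=config.decomposer if components == "imf" else "emd",
            sift_config=config.sift,
            imf_sets=imf_sets,
        )
        tables[group] = table
        write_feature_table(
            table,
            out / f"features_{group}.tsv",
            meta={"group": group, "components": components},
        )
    report["feature_table_shapes"] = {g: list(t.shape) for g, t in tables.items()}

    results: List[CVResult] = []
    for group, table in tables.items():
        for clf in config.classifiers:
            result = cross_validate(
                table,
                classifier=clf,
                folds=config.folds,
                seed=config.seed,
                feature_group=group,
                component_set=components,
            )
            results.append(result)
    write_cv_results(results, out / "cv_results.json")
    summary_table(results).to_csv(out / "cv_summary.tsv", sep="\t", index=False)
    report["cv_mean_acc"] = {
        f"{r.feature_group}/{r.classifier_name}": r.mean_metrics.acc for r in results
    }

    if config.per_channel_summary:
        hemi = _per_channel_summary(segments, tables, config)
        if hemi is not None:
            report["hemisphere_mean_acc"] = hemi
            (out / "hemisphere_summary.json").write_text(json.dumps(hemi, indent=1))

    report["dropped_rows"] = {g: t.dropped_rows for g, t in tables.items()}
    (out / "run_log.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _per_channel_summary(
    segments: List[EEGEpoch],
    tables: Dict[str, FeatureTable],
    config: PipelineConfig,
) -> Dict | None:
    """Per-channel CV with the first classifier on the first feature
    group, averaged into hemisphere means."""
    group = next(iter(tables))
    table = tables[group]
    channels = table.row_meta["channel"]
    present = [ch for ch in CHANNELS_10 if (channels == ch).any()]
    if len(present) < len(CHANNELS_10):
        logger.info("channels not matching the 10-channel montage; skipping summary")
        return None
    clf = config.classifiers[0]
    per_channel: Dict[str, CVResult] = {}
    for ch in CHANNELS_10:
        mask = (channels == ch).to_numpy()
        y = table.labels[mask]
        n_min = min(np.sum(y == lab) for lab in np.unique(y))
        folds = min(config.folds, int(n_min))
        if folds < 2:
            logger.info("too few samples per class on %s; skipping summary", ch)
            return None
        sub = FeatureTable(
            values=table.values[mask],
            feature_names=table.feature_names,
            labels=y,
            row_meta=table.row_meta.loc[mask],
        )
        per_channel[ch] = cross_validate(
            sub, classifier=clf, folds=folds, seed=config.seed,
            feature_group=group, component_set="per-channel",
        )
    left, right = hemisphere_summary(per_channel)
    return {
        "classifier": clf,
        "feature_group": group,
        "left": left,
        "right": right,
        "per_channel": {ch: r.mean_metrics.acc for ch, r in per_channel.items()},
    }


def _versions() -> Dict[str, str]:
    import pandas
    import scipy
    import sklearn

    return {
        "eegmodes": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
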