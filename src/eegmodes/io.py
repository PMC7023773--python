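"""File I/O: delimited-text segments with a JSON manifest, EDF reading,
and serialization of intermediate results.

The native on-disk format is deliberately plain: one text file per
single-channel segment (one sample per line, a commented header carrying
fs/label/identifiers) plus a ``manifest.json`` listing every segment with
its metadata.  European Data Format (EDF) recordings are read through
MNE; EDF carries no class labels, so a label must be supplied by the
caller or a manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .classify import CVResult
from .decompose import IMFSet
from .features import FeatureTable
from .selection import RankingMatrix, SelectionResult
from .synthetic import EEGEpoch, LABELS

__all__ = [
    "write_segments",
    "read_segments",
    "read_edf",
    "write_imf_set",
    "write_ranking_matrix",
    "write_selection",
    "write_feature_table",
    "write_cv_results",
]

MANIFEST_NAME = "manifest.json"


def write_segments(segments: Iterable[EEGEpoch], directory: str | Path) -> Path:
    """Write single-channel segments as text files plus a JSON manifest.

    Returns the manifest path.  Each segment file has ``# key: value``
    header lines (fs, label, subject, channel) followed by one sample per
    line.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries: List[Dict] = []
    for i, seg in enumerate(segments):
        if seg.n_channels != 1:
            raise ValueError("write_segments expects single-channel segments")
        fname = f"segment_{i:04d}.txt"
        path = directory / fname
        header = (
            f"# fs: {seg.fs}\n"
            f"# label: {seg.label}\n"
            f"# subject: {seg.subject_id}\n"
            f"# channel: {seg.channel_names[0]}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, seg.data[0], fmt="%.10g")
        entries.append(
            {
                "file": fname,
                "fs": seg.fs,
                "label": seg.label,
                "subject": seg.subject_id,
                "channel": seg.channel_names[0],
                "n_samples": int(seg.n_samples),
            }
        )
    manifest = directory / MANIFEST_NAME
    manifest.write_text(json.dumps({"segments": entries}, indent=1))
    return manifest


def _read_delimited(manifest_path: Path) -> List[EEGEpoch]:
    spec = json.loads(manifest_path.read_text())
    directory = manifest_path.parent
    segments: List[EEGEpoch] = []
    fs_seen = set()
    for entry in spec["segments"]:
        for key in ("file", "fs", "label", "subject", "channel"):
            if key not in entry:
                raise ValueError(
                    f"manifest entry for {entry.get('file', '<unknown>')} "
                    f"is missing required key {key!r}"
                )
        if entry["label"] not in LABELS:
            raise ValueError(
                f"{entry['file']}: label {entry['label']!r} not in {LABELS}"
            )
        data = np.loadtxt(directory / entry["file"], comments="#")
        fs_seen.add(float(entry["fs"]))
        segments.append(
            EEGEpoch(
                data=data[np.newaxis, :],
                fs=float(entry["fs"]),
                label=entry["label"],
                subject_id=entry["subject"],
                channel_names=[entry["channel"]],
            )
        )
    if len(fs_seen) > 1:
        raise ValueError(f"segments mix sampling rates: {sorted(fs_seen)}")
    return segments


def read_edf(
    path: str | Path, label: str, subject_id: str = "S01"
) -> EEGEpoch:
    """Read one EDF recording as a labelled multichannel epoch.

    EDF files carry no seizure/pre-seizure annotation usable here, so the
    class label is an explicit argument.
    """
    import mne

    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGEpoch(
        data=raw.get_data(units="uV"),
        fs=float(raw.info["sfreq"]),
        label=label,
        subject_id=subject_id,
        channel_names=list(raw.ch_names),
    )


def read_segments(
    path: str | Path, format: str = "auto", label: str | None = None
) -> List[EEGEpoch]:
    """Load segments from a manifest directory/file or an EDF recording.

    ``format='delimited'`` expects ``path`` to be a ``manifest.json`` (or
    a directory containing one).  ``format='edf'`` reads a single EDF file
    and splits it into single-channel segments; this requires ``label``.
    ``'auto'`` dispatches on the file suffix.
    """
    path = Path(path)
    if format == "auto":
        if path.suffix.lower() == ".edf":
            format = "edf"
        else:
            format = "delimited"
    if format == "delimited":
        manifest = path / MANIFEST_NAME if path.is_dir() else path
        if not manifest.exists():
            raise FileNotFoundError(f"no manifest found at {manifest}")
        return _read_delimited(manifest)
    if format == "edf":
        if label is None:
            raise ValueError("reading EDF requires an explicit class label")
        return read_edf(path, label).split_channels()
    raise ValueError(f"unknown format {format!r}")


def write_imf_set(imf_set: IMFSet, path: str | Path, meta: Dict | None = None) -> None:
    """One component per column (residue last) plus a JSON sidecar."""
    path = Path(path)
    matrix = imf_set.as_matrix()
    header = [f"IMF{i + 1}" for i in range(len(imf_set))] + ["residue"]
    np.savetxt(path, matrix, delimiter="\t", header="\t".join(header), fmt="%.10g")
    sidecar = {
        "n_imfs": len(imf_set),
        "source_length": imf_set.source_length,
        "has_ensemble_residue": imf_set.ensemble_residue is not None,
    }
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def write_ranking_matrix(matrix: RankingMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index=False)


def write_selection(result: SelectionResult, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "selected": list(result.selected),
                "histogram": {str(k): v for k, v in sorted(result.histogram.items())},
            },
            indent=1,
        )
    )


def write_feature_table(table: FeatureTable, path: str | Path, meta: Dict | None = None) -> None:
    """Tab-delimited table with header row plus a JSON sidecar."""
    path = Path(path)
    table.to_dataframe().to_csv(path, sep="\t", index=False)
    sidecar = {
        "n_rows": int(table.shape[0]),
        "n_features": int(table.shape[1]),
        "feature_names": table.feature_names,
        "dropped_rows": table.dropped_rows,
    }
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def write_cv_results(results: Sequence[CVResult], path: str | Path) -> None:
    """JSON dump mirroring the component-set x feature-group x classifier
    layout, plus per-fold confusion counts."""
    payload = []
    for r in results:
        payload.append(
            {
                "classifier": r.classifier_name,
                "feature_group": r.feature_group,
                "component_set": r.component_set,
                "seed": r.seed,
                "mean": dict(zip(("ACC", "SEN", "SPE", "PRE", "F"), r.mean_metrics)),
                "folds": [
                    {
                        "tp": c.tp,
                        "tn": c.tn,
                        "fp": c.fp,
                        "fn": c.fn,
                        "metrics": dict(zip(("ACC", "SEN", "SPE", "PRE", "F"), m)),
                    }
                    for c, m in zip(r.per_fold, r.per_fold_metrics)
                ],
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=True))


def summary_table(results: Sequence[CVResult]) -> pd.DataFrame:
    rows = [
        {
            "component_set": r.component_set,
            "feature_group": r.feature_group,
            "classifier": r.classifier_name,
            "ACC": r.mean_metrics.acc,
            "SEN": r.mean_metrics.sen,
            "SPE": r.mean_metrics.spe,
            "PRE": r.mean_metrics.pre,
            "F": r.mean_metrics.f,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
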