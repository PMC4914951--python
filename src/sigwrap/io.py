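"""Delimited-text input, result tables and the JSON run report.

Feature tables travel as TSV/CSV (delimiter chosen by extension) with the
first column holding row names.  Results are written as ``tiers.tsv`` (one
row per feature, one tier column per classifier), ``accuracies.tsv``
(method x full/S/AS mean OOB balanced accuracy) and ``report.json`` — a
full-provenance record (config echo, per-round search traces, software
version) from which the run can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .core import BinaryLabels, DataValidationError, FeatureTable, SelectionConfig
from .selection import TierTable

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "write_tiers",
    "build_report",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_feature_table(
    path: str | Path, orientation: str = "samples_in_rows"
) -> FeatureTable:
    """Parse a delimited intensity table (first row/column are names)."""
    path = Path(path)
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, float_precision="round_trip"
    )
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "features_in_rows":
        frame = frame.T
    return FeatureTable.from_frame(frame)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    # shortest round-trippable float representation, so write/read is exact
    path = Path(path)
    table.to_frame().to_csv(
        path,
        sep=_sep_for(path),
        index_label="sample_id",
        float_format=lambda x: repr(float(x)),
    )


def read_labels(
    path: str | Path,
    class_column: str,
    sample_ids: tuple[str, ...] | None = None,
    positive_level: str | None = None,
) -> BinaryLabels:
    """Read a two-level class column from a sample-metadata table.

    When ``sample_ids`` is given (the feature table's sample order) the
    labels are re-aligned to it; every sample must be present.
    """
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    meta.index = meta.index.astype(str)
    if class_column not in meta.columns:
        raise KeyError(f"column {class_column!r} not in {path}")
    col = meta[class_column].astype(str)
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in col.index]
        if missing:
            raise DataValidationError(
                f"sample(s) missing from metadata: {missing[:5]}"
            )
        col = col.loc[list(sample_ids)]
    levels = sorted(col.unique())
    if len(levels) != 2:
        raise DataValidationError(
            f"class column {class_column!r} must have exactly two levels, got {levels}"
        )
    return BinaryLabels(tuple(col), positive_level=positive_level or "")


def _fmt(x: float | None) -> str:
    return "na" if x is None else f"{x:.4f}"


def write_tiers(tiers: TierTable, out_dir: str | Path) -> dict[str, Path]:
    """Write tiers.tsv and accuracies.tsv; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    methods = list(tiers.methods)

    tier_path = out_dir / "tiers.tsv"
    with tier_path.open("w") as fh:
        fh.write("feature_id\t" + "\t".join(f"{m}_tier" for m in methods) + "\n")
        for fid in tiers.feature_ids:
            row = [tiers.tier(m, fid) for m in methods]
            fh.write(fid + "\t" + "\t".join(row) + "\n")

    acc_path = out_dir / "accuracies.tsv"
    with acc_path.open("w") as fh:
        fh.write("method\tfull\tS\tAS\n")
        for m in methods:
            acc = tiers.results[m].accuracies
            fh.write(
                f"{m}\t{_fmt(acc['full'])}\t{_fmt(acc['S'])}\t{_fmt(acc['AS'])}\n"
            )
    return {"tiers": tier_path, "accuracies": acc_path}


def build_report(
    tiers: TierTable, config: SelectionConfig, wall_clock_seconds: float
) -> dict:
    """Assemble the JSON-serializable run report (full provenance)."""
    from . import __version__

    methods = {}
    for name, res in tiers.results.items():
        methods[name] = {
            "signature": list(res.signature),
            "tiers": dict(res.tiers),
            "converged": res.converged,
            "accuracies": res.accuracies,
            "rounds": [
                {
                    "n_features": len(rec.feature_ids),
                    "registered": rec.registered,
                    "significant": list(rec.significant_ids),
                    "discarded": list(rec.discarded_ids),
                    "mean_oob_accuracy": rec.mean_accuracy,
                    "trace": [
                        {
                            "candidate_rank": s.candidate_rank,
                            "proportion": s.proportion,
                            "significant": s.significant,
                        }
                        for s in rec.trace
                    ],
                }
                for rec in res.rounds
            ],
        }
    return {
        "software": {"name": "sigwrap", "version": __version__},
        "config": dataclasses.asdict(config),
        "wall_clock_seconds": wall_clock_seconds,
        "n_features": len(tiers.feature_ids),
        "methods": methods,
        "errors": dict(tiers.errors),
    }


def write_report(report: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
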