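"""Model persistence: a versioned, self-describing JSON document holding the
configuration, all weight matrices, the per-sequence PB table and the
normalization bounds.  Plain text (diffable); floats are stored at full
double precision so a save -> load round trip is exact."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .model import RNNPBResults, SensorimotorRNNPB
from .network import ModelWeights, NetworkConfig, PBVector
from .training import PBTable, TrainingParams, TrainingReport

__all__ = ["FORMAT_VERSION", "save_model", "load_model"]

FORMAT_VERSION = 1


class ArchiveError(ValueError):
    """Raised for unreadable, truncated or version-incompatible archives."""


def save_model(results: RNNPBResults, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "config": asdict(results.model.config),
        "params": asdict(results.model.params),
        "seed": results.seed,
        "weights": {
            name: getattr(results.weights, name).tolist()
            for name in ModelWeights.MATRIX_FIELDS
        },
        "norm_bounds": results.weights.norm_bounds.tolist(),
        "pb_table": {
            sid: {"rho1": pb.rho1.tolist(), "rho2": pb.rho2.tolist()}
            for sid, pb in results.pb_table.items()
        },
        "report": {
            "cost_per_epoch": results.report.cost_per_epoch,
            "epochs_run": results.report.epochs_run,
            "stop_reason": results.report.stop_reason,
        },
        "labels": {
            s.sequence_id: {"color": s.color_label, "curve": s.curve_label}
            for s in results.model.dataset
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> RNNPBResults:
    """Rebuild a :class:`RNNPBResults` from an archive.

    The attached model holds placeholder sequences carrying only the ids
    and labels of the training set (enough for centroid classification and
    all recognition / generation work); the raw training values are not
    archived.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise ArchiveError(f"cannot parse model archive {path}: {exc}") from exc
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ArchiveError(
            f"archive {path} has format_version={version}, expected {FORMAT_VERSION}"
        )
    for key in ("config", "weights", "pb_table", "norm_bounds"):
        if key not in doc:
            raise ArchiveError(f"archive {path} is missing section {key!r}")

    config = NetworkConfig(**doc["config"])
    params = TrainingParams(**doc.get("params", {}))
    weights = ModelWeights(
        **{name: np.array(doc["weights"][name]) for name in ModelWeights.MATRIX_FIELDS},
        norm_bounds=np.array(doc["norm_bounds"]),
    )
    pb_table: PBTable = {
        sid: PBVector(rho1=np.array(d["rho1"]), rho2=np.array(d["rho2"]))
        for sid, d in doc["pb_table"].items()
    }
    report = TrainingReport(
        cost_per_epoch=list(doc.get("report", {}).get("cost_per_epoch", [])),
        epochs_run=doc.get("report", {}).get("epochs_run", 0),
        stop_reason=doc.get("report", {}).get("stop_reason", ""),
    )

    # placeholder sequences: two constant steps, real ids + labels
    from .trajectories import SensorimotorSequence

    dataset = []
    for sid, lab in doc.get("labels", {}).items():
        dataset.append(
            SensorimotorSequence(
                values=np.zeros((2, config.n_in)),
                color_label=lab["color"],
                curve_label=lab["curve"],
                sequence_id=sid,
            )
        )
    if not dataset:
        dataset = [
            SensorimotorSequence(
                values=np.zeros((2, config.n_in)),
                color_label="yellow",
                curve_label="cosine",
                sequence_id=sid,
            )
            for sid in doc["pb_table"]
        ]
    model = SensorimotorRNNPB(
        dataset, config=config, params=params, norm_bounds=weights.norm_bounds
    )
    return RNNPBResults(
        model=model,
        weights=weights,
        pb_table=pb_table,
        report=report,
        seed=doc.get("seed", 0),
    )
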