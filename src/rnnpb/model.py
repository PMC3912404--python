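"""Model / Results front-end over the two-stream RNNPB.

Usage mirrors the fitting-object convention of statistical packages::

    seqs = trajectories.make_dataset(trajectories.DatasetProtocol(base_seed=1))
    model = SensorimotorRNNPB(seqs)
    res = model.fit(seed=1, max_epochs=1500)
    print(res.summary())
    rec = res.recognize(new_sequence)
    gen = res.generate(rec.pb, new_sequence.values[0], horizon=19)

The :class:`SensorimotorRNNPB` model holds the data and configuration;
:meth:`fit` runs the learning mode and returns a :class:`RNNPBResults`
object carrying the trained weights, the per-sequence PB table, the cost
trace and diagnostics, with recognition / generation / evaluation methods
hanging off it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import modes, trajectories
from .network import ModelWeights, NetworkConfig, PBVector
from .training import PBTable, TrainingParams, TrainingReport, train
from .trajectories import SensorimotorSequence

__all__ = ["SensorimotorRNNPB", "RNNPBResults"]


class SensorimotorRNNPB:
    """Two-stream horizontal-product RNN with parametric biases, built from
    a set of labeled sensorimotor sequences.

    Parameters
    ----------
    dataset : list of SensorimotorSequence
        Training sequences (normalized T x 4 series with class labels).
    config : NetworkConfig, optional
        Layer sizes; defaults to the reference architecture (50 + 50
        hidden units, one PB unit per group).
    params : TrainingParams, optional
        Learning hyperparameters (adaptive-rate constants, PB rate
        constant, stopping rule).
    """

    def __init__(
        self,
        dataset: list[SensorimotorSequence],
        config: NetworkConfig | None = None,
        params: TrainingParams | None = None,
        norm_bounds: np.ndarray | None = None,
    ):
        if not dataset:
            raise ValueError("dataset is empty")
        self.dataset = list(dataset)
        self.config = config or NetworkConfig(n_in=dataset[0].values.shape[1])
        self.params = params or TrainingParams()
        self.norm_bounds = (
            norm_bounds if norm_bounds is not None else trajectories.NORM_BOUNDS
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        config: NetworkConfig | None = None,
        params: TrainingParams | None = None,
    ) -> "SensorimotorRNNPB":
        """Build from a long-format frame with the sequence-CSV columns
        (sequence_id, t_index, in1..in4, color_label, curve_label)."""
        seqs = []
        for sid, grp in df.groupby("sequence_id", sort=False):
            grp = grp.sort_values("t_index")
            seqs.append(
                SensorimotorSequence(
                    values=grp[["in1", "in2", "in3", "in4"]].to_numpy(),
                    color_label=str(grp["color_label"].iloc[0]),
                    curve_label=str(grp["curve_label"].iloc[0]),
                    sequence_id=str(sid),
                )
            )
        return cls(seqs, config=config, params=params)

    def fit(
        self,
        seed: int = 0,
        max_epochs: int | None = None,
        cost_threshold: float | None = None,
        pb_update: bool = True,
        callback=None,
    ) -> "RNNPBResults":
        """Run the learning mode and return the fitted results."""
        params = self.params
        if max_epochs is not None:
            params = replace(params, max_epochs=max_epochs)
        if cost_threshold is not None:
            params = replace(params, cost_threshold=cost_threshold)
        weights, pb_table, report = train(
            self.dataset,
            config=self.config,
            params=params,
            seed=seed,
            norm_bounds=self.norm_bounds,
            pb_update=pb_update,
            callback=callback,
        )
        return RNNPBResults(
            model=self, weights=weights, pb_table=pb_table, report=report, seed=seed
        )


@dataclass
class RNNPBResults:
    """Fitted RNNPB: trained weights, per-sequence PB codes and diagnostics."""

    model: SensorimotorRNNPB
    weights: ModelWeights
    pb_table: PBTable
    report: TrainingReport
    seed: int

    # ------------------------------------------------------------------
    # PB geometry

    def pb_frame(self) -> pd.DataFrame:
        """Trained PB internal values with class labels, one row per
        training sequence (the scatter behind the self-organization
        analysis)."""
        labels = {
            s.sequence_id: (s.color_label, s.curve_label) for s in self.model.dataset
        }
        rows = []
        for sid, pb in self.pb_table.items():
            color, curve = labels.get(sid, (None, None))
            row = {"sequence_id": sid, "color": color, "curve": curve}
            for i, v in enumerate(pb.rho1):
                row[f"rho1_{i}"] = v
            for i, v in enumerate(pb.rho2):
                row[f"rho2_{i}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def class_centroids(self) -> dict[tuple[str, str], np.ndarray]:
        """Mean trained PB vector (rho1 + rho2 concatenated) per
        (color, curve) class."""
        groups: dict[tuple[str, str], list[np.ndarray]] = {}
        labels = {
            s.sequence_id: (s.color_label, s.curve_label) for s in self.model.dataset
        }
        for sid, pb in self.pb_table.items():
            key = labels[sid]
            groups.setdefault(key, []).append(np.concatenate([pb.rho1, pb.rho2]))
        return {k: np.mean(v, axis=0) for k, v in groups.items()}

    def classify_pb(self, pb: PBVector) -> tuple[str, str]:
        """Nearest-centroid class assignment of a PB vector (Euclidean)."""
        vec = np.concatenate([pb.rho1, pb.rho2])
        cents = self.class_centroids()
        return min(cents, key=lambda k: float(np.linalg.norm(vec - cents[k])))

    # ------------------------------------------------------------------
    # modes

    def recognize(
        self,
        observed: SensorimotorSequence | np.ndarray,
        cfg: modes.RecognitionConfig | None = None,
    ) -> modes.RecognitionResult:
        """Infer the PB code of an observed sequence (weights frozen)."""
        return modes.recognize(self.weights, observed, cfg or modes.RecognitionConfig())

    def generate(
        self, pb: PBVector, initial_input: np.ndarray, horizon: int
    ) -> np.ndarray:
        """Closed-loop generation from a PB code and a seed observation."""
        return modes.predict(self.weights, pb, initial_input, horizon)

    def evaluate(
        self, observed: SensorimotorSequence | np.ndarray, pb: PBVector | None = None
    ) -> np.ndarray:
        """Per-unit MSE of closed-loop generation against an observed
        series (PB from recognition when not supplied)."""
        values = (
            observed.values
            if isinstance(observed, SensorimotorSequence)
            else np.asarray(observed, float)
        )
        if pb is None:
            pb = self.recognize(values).pb
        gen = self.generate(pb, values[0], horizon=values.shape[0] - 1)
        return modes.evaluate_prediction(gen, values[1:])

    # ------------------------------------------------------------------

    @property
    def final_cost(self) -> float:
        return self.report.cost_per_epoch[-1]

    def summary(self) -> str:
        """Plain-text fit report: architecture, stopping, cost, PB table."""
        cfg = self.model.config
        lines = [
            "Two-stream RNNPB (horizontal product) — fit summary",
            "=" * 55,
            f"inputs/outputs: {cfg.n_in}   dorsal: {cfg.n_d}   ventral: {cfg.n_v}",
            f"PB units: group1 (->ventral) {cfg.n_pb1}, group2 (->dorsal) {cfg.n_pb2}",
            f"sequences: {len(self.model.dataset)}   seed: {self.seed}",
            f"epochs run: {self.report.epochs_run}   stop: {self.report.stop_reason}",
            f"initial cost: {self.report.cost_per_epoch[0]:.6g}"
            f"   final cost: {self.final_cost:.6g}",
            "",
            "Trained PB internal values (rho):",
        ]
        frame = self.pb_frame()
        lines.append(frame.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)
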