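"""Recognition and prediction modes.

*Recognition* runs the trained network against an observed sequence with
the synaptic weights frozen: only the PB internal values are updated, by
the error back-propagated to the PB units accumulated over a sliding
window covering the last ``a`` steps of the series.  The converged PB
vector identifies which stored dynamics the observation belongs to.

*Prediction* runs the network closed-loop: the PB vector is fixed
(manually set or obtained from recognition), the true observation is
consumed only at the first step, and each one-step prediction is fed back
as the next input, generating a whole trajectory from the PB code alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import HiddenState, ModelWeights, PBVector, step
from .training import bptt_gradients
from .trajectories import SensorimotorSequence

__all__ = [
    "RecognitionConfig",
    "RecognitionResult",
    "recognize",
    "predict",
    "evaluate_prediction",
]


@dataclass(frozen=True)
class RecognitionConfig:
    """Recognition-mode settings.

    window_a: sliding-window length (None means the full series, the
    configuration used for all offline experiments).  gamma_recog: the PB
    update rate, constant in this mode and much larger than the adaptive
    learning-mode rate (which is itself proportional to the shrinking
    back-propagated error); rates much above ~1e-2 can overshoot into
    spurious distant basins on some trained networks.  recog_epochs:
    iteration budget.  tol: early stop when no rho component moves more
    than this in one iteration.
    """

    window_a: int | None = None
    gamma_recog: float = 0.01
    recog_epochs: int = 1000
    tol: float = 1e-6


@dataclass
class RecognitionResult:
    pb: PBVector
    trace: np.ndarray  # (epochs, n_pb1 + n_pb2) rho trajectory
    epochs_run: int
    converged: bool


def recognize(
    weights: ModelWeights,
    observed: SensorimotorSequence | np.ndarray,
    cfg: RecognitionConfig = RecognitionConfig(),
) -> RecognitionResult:
    """Infer the PB vector of an observed sequence with frozen weights.

    Starting from rho = 0, repeatedly: teacher-forced forward pass,
    back-propagate the error to the PB units only, and add
    gamma * sum of the last ``a`` per-step PB deltas to rho.  The weights
    are never touched.
    """
    values = observed.values if isinstance(observed, SensorimotorSequence) else np.asarray(observed, float)
    n_steps = values.shape[0] - 1
    a = cfg.window_a if cfg.window_a is not None else values.shape[0]
    if not (1 <= a <= values.shape[0]):
        raise ValueError(
            f"window_a={a} outside [1, T={values.shape[0]}]"
        )
    window = min(a, n_steps)  # deltas exist for the T-1 prediction steps

    config = weights.config
    pb = PBVector.zeros(config)
    trace = []
    converged = False
    epochs_run = 0
    for _ in range(cfg.recog_epochs):
        _, deltas, _ = bptt_gradients(weights, pb, values)
        d1 = deltas["delta1"][-window:].sum(axis=0)
        d2 = deltas["delta2"][-window:].sum(axis=0)
        pb.rho1 += cfg.gamma_recog * d1
        pb.rho2 += cfg.gamma_recog * d2
        pb.refresh()
        trace.append(np.concatenate([pb.rho1, pb.rho2]))
        epochs_run += 1
        change = cfg.gamma_recog * max(
            np.max(np.abs(d1), initial=0.0), np.max(np.abs(d2), initial=0.0)
        )
        if change < cfg.tol:
            converged = True
            break
    return RecognitionResult(
        pb=pb, trace=np.array(trace), epochs_run=epochs_run, converged=converged
    )


def predict(
    weights: ModelWeights,
    pb: PBVector,
    initial_input: np.ndarray,
    horizon: int,
    feedback_clip: tuple[float, float] | None = (0.0, 1.0),
) -> np.ndarray:
    """Closed-loop generation for ``horizon`` steps (normalized units).

    The hidden state starts at zero; the true observation is consumed only
    as the very first input and thereafter each one-step prediction is fed
    back as the next input.  Row t of the returned (horizon, n_in) array is
    the prediction for time t+1 given the seed observation at time 0, so
    ``horizon=1`` is exactly one open-loop step.

    Because the fed-back prediction stands in for an *observation*, it is
    clipped to the valid normalized observation range before re-entering
    the input layer (``feedback_clip``, pass None to disable).  The
    returned series itself is the raw network output.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    initial_input = np.asarray(initial_input, dtype=float)
    state = HiddenState.zeros(weights.config)
    out = np.empty((horizon, initial_input.shape[0]))
    x = initial_input
    for t in range(horizon):
        state, so = step(weights, state, x, pb)
        if not np.all(np.isfinite(so.s_o)):
            raise RuntimeError(f"closed-loop generation diverged at step {t}")
        out[t] = so.s_o
        x = so.s_o
        if feedback_clip is not None:
            x = np.clip(x, feedback_clip[0], feedback_clip[1])
    return out


def evaluate_prediction(generated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-output-unit mean squared deviation between a generated series and
    the true one, over all steps (normalized units)."""
    generated = np.asarray(generated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if generated.shape != truth.shape:
        raise ValueError(
            f"generated shape {generated.shape} != truth shape {truth.shape}"
        )
    return np.mean((generated - truth) ** 2, axis=0)
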