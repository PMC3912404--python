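"""Learning mode: backpropagation through time over each sequence,
per-weight sign-based adaptive learning rates, and adaptive per-sequence
parametric-bias (PB) updates.

One weight set stores several sequence classes; what distinguishes the
classes is a per-sequence PB vector, learned jointly with the weights.  Per
epoch every sequence is presented in turn: its gradients are computed by a
full unroll (errors flow through the recurrent connections across all time
steps), the weights take a gradient-descent step with per-weight rates, and
the sequence's own PB internal values move by the accumulated
back-propagated PB error with a rate proportional to that error's absolute
mean.  The per-weight rates adapt once per epoch by the sign of the product
of consecutive epochs' gradients (grow by xi_plus when the sign repeats,
shrink by xi_minus when it flips), clipped to [eta_min, eta_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    ModelWeights,
    NetworkConfig,
    PBVector,
    forward_pass,
    transfer_derivative_from_activation,
)
from .trajectories import SensorimotorSequence

__all__ = [
    "TrainingParams",
    "AdaptiveRateState",
    "PBTable",
    "TrainingReport",
    "bptt_gradients",
    "adapt_learning_rates",
    "update_pb_learning",
    "train",
]

# The per-stream learning rates apply to the stream-internal matrices
# (input->hidden, recurrent, PB->hidden).  The output layer — where the two
# streams meet in the horizontal product — is shared, and both its matrices
# train at their own rate (eta_output, defaulting to the fast dorsal value):
# with the ventral output weights at the slow ventral rate the stream
# amplitudes become so lopsided that closed-loop generation is unstable for
# any training length, while the slow rate on the ventral *hidden* dynamics
# preserves the intended fast-where / slow-what division of labor.
DORSAL_MATRICES = ("w_d", "v_d", "wbar_d")
VENTRAL_MATRICES = ("w_v", "v_v", "wbar_v")
OUTPUT_MATRICES = ("u_d", "u_v")


class DivergenceError(RuntimeError):
    """Raised when training or gradient computation produces non-finite values."""


@dataclass(frozen=True)
class TrainingParams:
    """Learning-mode hyperparameters (reference values in parentheses).

    eta_dorsal / eta_ventral: initial per-weight learning rates of the
    dorsal and ventral stream-internal matrices (1e-3 / 1e-5); eta_output:
    initial rate of both hidden->output matrices (1e-3).  eta_max / eta_min:
    bounds of the adaptive rates (1e-1 / 1e-7).  xi_plus / xi_minus:
    multiplicative growth / decay of a rate when consecutive epochs'
    gradients agree / disagree in sign (1.000001 / 0.999999).  m_gamma: the
    proportionality constant of the PB updating rate (1e-2).
    """

    eta_dorsal: float = 1e-3
    eta_ventral: float = 1e-5
    eta_output: float = 1e-3
    eta_max: float = 1e-1
    eta_min: float = 1e-7
    xi_plus: float = 1.000001
    xi_minus: float = 0.999999
    m_gamma: float = 1e-2
    max_epochs: int = 5000
    cost_threshold: float = 1e-4
    init_scale: float = 0.1


@dataclass
class AdaptiveRateState:
    """Per-weight learning rates and the previous epoch's gradients."""

    eta: dict[str, np.ndarray]
    prev_grad: dict[str, np.ndarray] | None = None
    eta_max: float = 1e-1
    eta_min: float = 1e-7
    xi_plus: float = 1.000001
    xi_minus: float = 0.999999

    @classmethod
    def initial(cls, weights: ModelWeights, params: TrainingParams) -> "AdaptiveRateState":
        eta = {}
        for name in DORSAL_MATRICES:
            eta[name] = np.full_like(getattr(weights, name), params.eta_dorsal)
        for name in VENTRAL_MATRICES:
            eta[name] = np.full_like(getattr(weights, name), params.eta_ventral)
        for name in OUTPUT_MATRICES:
            eta[name] = np.full_like(getattr(weights, name), params.eta_output)
        return cls(
            eta=eta,
            prev_grad=None,
            eta_max=params.eta_max,
            eta_min=params.eta_min,
            xi_plus=params.xi_plus,
            xi_minus=params.xi_minus,
        )


#: Mapping sequence-id -> PBVector, one per training sequence.
PBTable = dict


@dataclass
class TrainingReport:
    """Per-epoch cost trace, per-sequence PB trajectories and stop reason."""

    cost_per_epoch: list[float] = field(default_factory=list)
    pb_trace: dict[str, list[np.ndarray]] = field(default_factory=dict)
    epochs_run: int = 0
    stop_reason: str = ""

    def record_epoch(self, cost: float, pb_table: PBTable) -> None:
        self.cost_per_epoch.append(cost)
        for sid, pb in pb_table.items():
            self.pb_trace.setdefault(sid, []).append(
                np.concatenate([pb.rho1, pb.rho2])
            )
        self.epochs_run += 1


def bptt_gradients(
    weights: ModelWeights,
    pb: PBVector,
    sequence: SensorimotorSequence | np.ndarray,
    fwd: dict | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], float]:
    """Full-unroll gradients of the prediction cost for one sequence.

    Returns ``(grads, pb_deltas, cost)`` where ``grads`` maps each weight
    matrix name to dC/dw, and ``pb_deltas`` holds the per-step
    back-propagated PB errors ``delta1``/``delta2`` (negative cost
    gradients, so a positive accumulated delta moves rho to *reduce* the
    cost).  Group-2 deltas route through the dorsal layer and group-1
    deltas through the ventral layer, matching the cross-wiring of the
    forward pass.
    """
    values = sequence.values if isinstance(sequence, SensorimotorSequence) else np.asarray(sequence, float)
    if fwd is None:
        fwd = forward_pass(weights, pb, values)
    targets = values[1:]
    err = targets - fwd["s_o"]  # (T-1, n_out)
    cost = 0.5 * float(np.sum(err * err))

    # dC/dx contributions through the horizontal product
    g_xd = -err * fwd["x_v"]  # (T-1, n_out)
    g_xv = -err * fwd["x_d"]

    n_steps = err.shape[0]
    fpd = transfer_derivative_from_activation(fwd["s_d"])  # f'(y_d)
    fpv = transfer_derivative_from_activation(fwd["s_v"])

    dy_d = np.empty_like(fwd["s_d"])  # dC/dy_d per step
    dy_v = np.empty_like(fwd["s_v"])
    carry_d = np.zeros(weights.v_d.shape[0])
    carry_v = np.zeros(weights.v_v.shape[0])
    u_d_T, u_v_T = weights.u_d.T, weights.u_v.T
    v_d_T, v_v_T = weights.v_d.T, weights.v_v.T
    for t in range(n_steps - 1, -1, -1):
        gd = u_d_T @ g_xd[t] + carry_d
        gv = u_v_T @ g_xv[t] + carry_v
        dy_d[t] = gd * fpd[t]
        dy_v[t] = gv * fpv[t]
        carry_d = v_d_T @ dy_d[t]
        carry_v = v_v_T @ dy_v[t]

    inputs = values[:-1]
    grads = {
        "u_d": g_xd.T @ fwd["s_d"],
        "u_v": g_xv.T @ fwd["s_v"],
        "w_d": dy_d.T @ inputs,
        "w_v": dy_v.T @ inputs,
        "v_d": dy_d.T @ fwd["s_d_prev"],
        "v_v": dy_v.T @ fwd["s_v_prev"],
        "wbar_d": np.outer(dy_d.sum(axis=0), pb.act2),
        "wbar_v": np.outer(dy_v.sum(axis=0), pb.act1),
    }

    # per-step PB errors (negative gradient convention); the transfer
    # derivative at rho is constant within the pass
    fp_rho1 = transfer_derivative_from_activation(pb.act1)
    fp_rho2 = transfer_derivative_from_activation(pb.act2)
    delta1 = -(dy_v @ weights.wbar_v) * fp_rho1  # (T-1, n_pb1)
    delta2 = -(dy_d @ weights.wbar_d) * fp_rho2  # (T-1, n_pb2)

    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise DivergenceError(f"non-finite gradient in {name}")
    if not (np.all(np.isfinite(delta1)) and np.all(np.isfinite(delta2))):
        raise DivergenceError("non-finite PB deltas")
    return grads, {"delta1": delta1, "delta2": delta2}, cost


def adapt_learning_rates(
    state: AdaptiveRateState, grad: dict[str, np.ndarray]
) -> AdaptiveRateState:
    """Sign rule on consecutive epochs' gradients, applied in place.

    Per weight, with sigma = prev_grad * grad: sigma > 0 grows the rate by
    xi_plus (capped at eta_max); sigma < 0 shrinks it by xi_minus (floored
    at eta_min); sigma = 0 leaves it unchanged.  On the first call (no
    previous gradient) rates are unchanged and the gradient is stored.
    """
    if state.prev_grad is not None:
        for name, g in grad.items():
            sigma = state.prev_grad[name] * g
            eta = state.eta[name]
            np.minimum(
                np.where(sigma > 0, eta * state.xi_plus, eta), state.eta_max, out=eta
            )
            np.maximum(
                np.where(sigma < 0, eta * state.xi_minus, eta), state.eta_min, out=eta
            )
    state.prev_grad = {name: g.copy() for name, g in grad.items()}
    return state


def update_pb_learning(
    pb: PBVector, pb_deltas: dict[str, np.ndarray], m_gamma: float
) -> PBVector:
    """Adaptive PB update from one sequence's accumulated deltas.

    Per PB node i: gamma_i = m_gamma * |mean_t delta_i(t)| and
    rho_i <- rho_i + gamma_i * sum_t delta_i(t); activations refreshed.
    """
    new = pb.copy()
    for rho, deltas in ((new.rho1, pb_deltas["delta1"]), (new.rho2, pb_deltas["delta2"])):
        total = deltas.sum(axis=0)
        gamma = m_gamma * np.abs(total / deltas.shape[0])
        rho += gamma * total
    new.refresh()
    return new


def train(
    dataset: list[SensorimotorSequence],
    config: NetworkConfig = NetworkConfig(),
    params: TrainingParams = TrainingParams(),
    seed: int = 0,
    norm_bounds: np.ndarray | None = None,
    pb_update: bool = True,
    callback=None,
) -> tuple[ModelWeights, PBTable, TrainingReport]:
    """Learning mode over a dataset of sequences.

    Weights start from a seeded uniform distribution on
    [-init_scale, init_scale]; each sequence gets its own PB vector starting
    at rho = 0.  Stops at ``max_epochs`` or when the epoch-summed cost drops
    below ``cost_threshold``.  ``pb_update=False`` freezes all PB vectors at
    zero, reducing training to plain two-stream Elman BPTT.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    n_in = dataset[0].values.shape[1]
    if any(s.values.shape[1] != n_in for s in dataset):
        raise ValueError("all sequences must share the same channel count")
    if config.n_in != n_in:
        raise ValueError(
            f"config.n_in={config.n_in} does not match data channels {n_in}"
        )

    rng = np.random.default_rng(seed)
    weights = ModelWeights.random(config, rng, scale=params.init_scale,
                                  norm_bounds=norm_bounds)
    pb_table: PBTable = {s.sequence_id: PBVector.zeros(config) for s in dataset}
    rate_state = AdaptiveRateState.initial(weights, params)
    report = TrainingReport()

    from . import _fast

    lengths = {s.values.shape[0] for s in dataset}
    use_fast = _fast.HAVE_NUMBA and len(lengths) == 1

    if use_fast:
        stacked = np.ascontiguousarray(
            np.stack([s.values for s in dataset]).astype(float)
        )
        rho1 = np.stack([pb_table[s.sequence_id].rho1 for s in dataset])
        rho2 = np.stack([pb_table[s.sequence_id].rho2 for s in dataset])

    for epoch in range(params.max_epochs):
        epoch_grads = {name: np.zeros_like(getattr(weights, name))
                       for name in ModelWeights.MATRIX_FIELDS}
        if use_fast:
            epoch_cost = _fast.epoch_kernel(
                stacked,
                weights.w_d, weights.v_d, weights.wbar_d,
                weights.w_v, weights.v_v, weights.wbar_v,
                weights.u_d, weights.u_v,
                rate_state.eta["w_d"], rate_state.eta["v_d"],
                rate_state.eta["wbar_d"], rate_state.eta["w_v"],
                rate_state.eta["v_v"], rate_state.eta["wbar_v"],
                rate_state.eta["u_d"], rate_state.eta["u_v"],
                rho1, rho2,
                params.m_gamma, pb_update,
                epoch_grads["w_d"], epoch_grads["v_d"], epoch_grads["wbar_d"],
                epoch_grads["w_v"], epoch_grads["v_v"], epoch_grads["wbar_v"],
                epoch_grads["u_d"], epoch_grads["u_v"],
            )
            if not np.isfinite(epoch_cost):
                raise DivergenceError(f"cost diverged at epoch {epoch}")
            for i, seq in enumerate(dataset):
                pb_table[seq.sequence_id] = PBVector(
                    rho1=rho1[i].copy(), rho2=rho2[i].copy()
                )
        else:
            epoch_cost = 0.0
            for seq in dataset:
                pb = pb_table[seq.sequence_id]
                grads, deltas, cost = bptt_gradients(weights, pb, seq)
                epoch_cost += cost
                for name, g in grads.items():
                    arr = getattr(weights, name)
                    arr -= rate_state.eta[name] * g
                    epoch_grads[name] += g
                if pb_update:
                    pb_table[seq.sequence_id] = update_pb_learning(
                        pb, deltas, params.m_gamma
                    )
        if not np.isfinite(epoch_cost):
            raise DivergenceError(f"cost diverged at epoch {epoch}")
        adapt_learning_rates(rate_state, epoch_grads)
        report.record_epoch(epoch_cost, pb_table)
        if callback is not None:
            callback(epoch, epoch_cost, pb_table)
        if epoch_cost < params.cost_threshold:
            report.stop_reason = "cost-threshold"
            break
    else:
        report.stop_reason = "max-epochs"
    return weights, pb_table, report
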