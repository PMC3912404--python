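"""Core two-stream recurrent network with parametric biases (PB).

The network has two independent Elman-style recurrent hidden layers — a
"dorsal" (where / movement) stream and a "ventral" (what / feature) stream —
that share the input layer and are joined only at the output through a
*horizontal product*: each output unit is the element-wise product of one
linear contribution from each stream,

    s_o[k] = x_d[k] * x_v[k].

A small group of parametric-bias units feeds each stream like a constant
bias, but cross-wired: PB group 1 enters the *ventral* pre-activations and
PB group 2 enters the *dorsal* pre-activations.  PB internal values (rho)
are held constant during a forward pass; they are learned per sequence (see
:mod:`rnnpb.training`) and act as bifurcation parameters selecting which
stored dynamics the network exhibits.

All hidden and PB units use the scaled hyperbolic tangent
``1.7159 * tanh(2/3 * y)``; output units are linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TANH_SCALE",
    "TANH_GAIN",
    "NetworkConfig",
    "ModelWeights",
    "HiddenState",
    "PBVector",
    "StepOutput",
    "transfer",
    "transfer_derivative",
    "step",
    "run_sequence",
    "forward_pass",
    "sequence_cost",
]

#: Amplitude of the scaled tanh transfer function (LeCun's recommendation).
TANH_SCALE = 1.7159
#: Gain inside the tanh.
TANH_GAIN = 2.0 / 3.0


class NetworkShapeError(ValueError):
    """Raised when array shapes are inconsistent with the configuration."""


@dataclass(frozen=True)
class NetworkConfig:
    """Layer sizes of the two-stream network.

    Defaults follow the reference parameterization: 4 input/output units
    (two color layers x 2-D position), 50 hidden units per stream and a
    single PB unit per group.
    """

    n_in: int = 4
    n_d: int = 50
    n_v: int = 50
    n_pb1: int = 1
    n_pb2: int = 1

    @property
    def n_out(self) -> int:
        # the network predicts its own next input
        return self.n_in

    def __post_init__(self) -> None:
        for name in ("n_in", "n_d", "n_v", "n_pb1", "n_pb2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")


@dataclass
class ModelWeights:
    """All eight weight matrices plus input-normalization metadata.

    Naming: ``w_*`` input->hidden, ``v_*`` recurrent, ``wbar_*`` PB->hidden,
    ``u_*`` hidden->output.  ``wbar_d`` carries PB *group 2* into the dorsal
    layer; ``wbar_v`` carries PB *group 1* into the ventral layer.
    ``norm_bounds`` holds the per-input-column affine normalization bounds
    (lo, hi) used to map raw trajectory coordinates into network units.
    """

    w_d: np.ndarray  # (n_d, n_in)
    v_d: np.ndarray  # (n_d, n_d)
    wbar_d: np.ndarray  # (n_d, n_pb2)
    w_v: np.ndarray  # (n_v, n_in)
    v_v: np.ndarray  # (n_v, n_v)
    wbar_v: np.ndarray  # (n_v, n_pb1)
    u_d: np.ndarray  # (n_out, n_d)
    u_v: np.ndarray  # (n_out, n_v)
    norm_bounds: np.ndarray = field(default=None)  # (n_in, 2) lo/hi per column

    MATRIX_FIELDS = ("w_d", "v_d", "wbar_d", "w_v", "v_v", "wbar_v", "u_d", "u_v")

    def __post_init__(self) -> None:
        for name in self.MATRIX_FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2:
                raise NetworkShapeError(f"{name} must be 2-D, got shape {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, arr)
        if self.norm_bounds is None:
            n_in = self.w_d.shape[1]
            self.norm_bounds = np.column_stack(
                [np.zeros(n_in), np.ones(n_in)]
            )
        self.norm_bounds = np.asarray(self.norm_bounds, dtype=float)
        self._check_shapes()

    def _check_shapes(self) -> None:
        n_d, n_in = self.w_d.shape
        n_v = self.w_v.shape[0]
        n_out = self.u_d.shape[0]
        expected = {
            "w_d": (n_d, n_in),
            "v_d": (n_d, n_d),
            "wbar_d": (n_d, self.wbar_d.shape[1]),
            "w_v": (n_v, n_in),
            "v_v": (n_v, n_v),
            "wbar_v": (n_v, self.wbar_v.shape[1]),
            "u_d": (n_out, n_d),
            "u_v": (n_out, n_v),
        }
        for name, shape in expected.items():
            if getattr(self, name).shape != shape:
                raise NetworkShapeError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}"
                )
        if n_out != n_in:
            raise NetworkShapeError(
                f"output size {n_out} must equal input size {n_in}"
            )

    @property
    def config(self) -> NetworkConfig:
        return NetworkConfig(
            n_in=self.w_d.shape[1],
            n_d=self.w_d.shape[0],
            n_v=self.w_v.shape[0],
            n_pb1=self.wbar_v.shape[1],
            n_pb2=self.wbar_d.shape[1],
        )

    def copy(self) -> "ModelWeights":
        return ModelWeights(
            **{name: getattr(self, name).copy() for name in self.MATRIX_FIELDS},
            norm_bounds=self.norm_bounds.copy(),
        )

    @classmethod
    def random(
        cls,
        config: NetworkConfig,
        rng: np.random.Generator,
        scale: float = 0.1,
        norm_bounds: np.ndarray | None = None,
    ) -> "ModelWeights":
        """Uniform initialization on [-scale, scale] (small: keeps the tanh
        units in their near-linear regime at the start of training)."""

        def u(*shape):
            return rng.uniform(-scale, scale, size=shape)

        return cls(
            w_d=u(config.n_d, config.n_in),
            v_d=u(config.n_d, config.n_d),
            wbar_d=u(config.n_d, config.n_pb2),
            w_v=u(config.n_v, config.n_in),
            v_v=u(config.n_v, config.n_v),
            wbar_v=u(config.n_v, config.n_pb1),
            u_d=u(config.n_out, config.n_d),
            u_v=u(config.n_out, config.n_v),
            norm_bounds=norm_bounds,
        )


@dataclass
class PBVector:
    """Internal values (rho) and squashed activations of the two PB groups.

    ``rho1``/``act1`` belong to group 1 (feeds the ventral layer);
    ``rho2``/``act2`` to group 2 (feeds the dorsal layer).  Activations are
    always ``transfer(rho)`` — use :meth:`with_rho` or :meth:`refresh` after
    changing rho.
    """

    rho1: np.ndarray
    rho2: np.ndarray
    act1: np.ndarray = field(default=None)
    act2: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.rho1 = np.atleast_1d(np.asarray(self.rho1, dtype=float))
        self.rho2 = np.atleast_1d(np.asarray(self.rho2, dtype=float))
        if self.act1 is None or self.act2 is None:
            self.refresh()
        else:
            self.act1 = np.atleast_1d(np.asarray(self.act1, dtype=float))
            self.act2 = np.atleast_1d(np.asarray(self.act2, dtype=float))

    def refresh(self) -> None:
        self.act1 = transfer(self.rho1)
        self.act2 = transfer(self.rho2)

    def with_rho(self, rho1: np.ndarray, rho2: np.ndarray) -> "PBVector":
        return PBVector(rho1=np.asarray(rho1, float), rho2=np.asarray(rho2, float))

    @classmethod
    def zeros(cls, config: NetworkConfig) -> "PBVector":
        return cls(rho1=np.zeros(config.n_pb1), rho2=np.zeros(config.n_pb2))

    def copy(self) -> "PBVector":
        return PBVector(rho1=self.rho1.copy(), rho2=self.rho2.copy())


@dataclass
class HiddenState:
    """Recurrent state of both streams at one time step.

    ``y_d``/``y_v`` are the pre-activations, kept because the gradient of
    the transfer function is evaluated there.
    """

    s_d: np.ndarray
    s_v: np.ndarray
    y_d: np.ndarray = None
    y_v: np.ndarray = None

    @classmethod
    def zeros(cls, config: NetworkConfig) -> "HiddenState":
        return cls(
            s_d=np.zeros(config.n_d),
            s_v=np.zeros(config.n_v),
            y_d=np.zeros(config.n_d),
            y_v=np.zeros(config.n_v),
        )


@dataclass
class StepOutput:
    """Per-step output decomposition: dorsal and ventral linear contributions
    and their horizontal product."""

    x_d: np.ndarray
    x_v: np.ndarray
    s_o: np.ndarray


def transfer(y: np.ndarray) -> np.ndarray:
    """Scaled tanh transfer function ``1.7159 * tanh(2/3 * y)``.

    Odd, strictly increasing, bounded by +-1.7159 (never attained for
    finite input).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("transfer() received non-finite pre-activations")
    return TANH_SCALE * np.tanh(TANH_GAIN * y)


def transfer_derivative_from_activation(s: np.ndarray) -> np.ndarray:
    """d transfer/dy expressed through the activation s = transfer(y):
    A*B*(1 - (s/A)^2) with A = 1.7159, B = 2/3."""
    s = np.asarray(s, dtype=float)
    return TANH_SCALE * TANH_GAIN * (1.0 - (s / TANH_SCALE) ** 2)


# alias used by callers that hold pre-activations instead
def transfer_derivative(y: np.ndarray) -> np.ndarray:
    """d transfer/dy at pre-activation y."""
    return transfer_derivative_from_activation(transfer(y))


def step(
    weights: ModelWeights,
    state: HiddenState,
    x_in: np.ndarray,
    pb: PBVector,
) -> tuple[HiddenState, StepOutput]:
    """One deterministic forward step of the two-stream network.

    Pre-activations: each stream receives its input term, its own recurrent
    term, and the (cross-wired) PB term; hidden activations go through the
    scaled tanh; the output is the element-wise product of the two linear
    stream contributions.
    """
    x_in = np.asarray(x_in, dtype=float)
    if x_in.shape != (weights.w_d.shape[1],):
        raise NetworkShapeError(
            f"input has shape {x_in.shape}, expected ({weights.w_d.shape[1]},)"
        )
    y_d = weights.w_d @ x_in + weights.v_d @ state.s_d + weights.wbar_d @ pb.act2
    y_v = weights.w_v @ x_in + weights.v_v @ state.s_v + weights.wbar_v @ pb.act1
    s_d = transfer(y_d)
    s_v = transfer(y_v)
    x_d = weights.u_d @ s_d
    x_v = weights.u_v @ s_v
    new_state = HiddenState(s_d=s_d, s_v=s_v, y_d=y_d, y_v=y_v)
    return new_state, StepOutput(x_d=x_d, x_v=x_v, s_o=x_d * x_v)


def forward_pass(weights: ModelWeights, pb: PBVector, values: np.ndarray) -> dict:
    """Teacher-forced forward pass over a whole sequence, returning all
    intermediate arrays needed by backpropagation through time.

    ``values`` is the (T, n_in) observed series; the hidden state starts at
    zero and the input at each step is the observed value.  Outputs are the
    T-1 one-step-ahead predictions.

    Returns a dict with keys ``y_d, s_d, y_v, s_v, x_d, x_v, s_o`` — arrays
    of shape (T-1, layer size) — and ``s_d_prev, s_v_prev`` (states entering
    each step, first row zero).
    """
    values = np.asarray(values, dtype=float)
    T = values.shape[0]
    if T < 2:
        raise ValueError(f"sequence must have at least 2 steps, got {T}")
    n_steps = T - 1
    n_d = weights.w_d.shape[0]
    n_v = weights.w_v.shape[0]

    # input and PB terms do not depend on the recurrent state: precompute
    in_d = values[:-1] @ weights.w_d.T + weights.wbar_d @ pb.act2
    in_v = values[:-1] @ weights.w_v.T + weights.wbar_v @ pb.act1

    y_d = np.empty((n_steps, n_d))
    s_d = np.empty((n_steps, n_d))
    y_v = np.empty((n_steps, n_v))
    s_v = np.empty((n_steps, n_v))
    s_d_prev = np.zeros((n_steps, n_d))
    s_v_prev = np.zeros((n_steps, n_v))

    sd = np.zeros(n_d)
    sv = np.zeros(n_v)
    tanh = np.tanh
    for t in range(n_steps):
        s_d_prev[t] = sd
        s_v_prev[t] = sv
        yd = in_d[t] + weights.v_d @ sd
        yv = in_v[t] + weights.v_v @ sv
        sd = TANH_SCALE * tanh(TANH_GAIN * yd)
        sv = TANH_SCALE * tanh(TANH_GAIN * yv)
        y_d[t] = yd
        y_v[t] = yv
        s_d[t] = sd
        s_v[t] = sv

    x_d = s_d @ weights.u_d.T
    x_v = s_v @ weights.u_v.T
    return {
        "y_d": y_d,
        "s_d": s_d,
        "y_v": y_v,
        "s_v": s_v,
        "s_d_prev": s_d_prev,
        "s_v_prev": s_v_prev,
        "x_d": x_d,
        "x_v": x_v,
        "s_o": x_d * x_v,
    }


def run_sequence(
    weights: ModelWeights, pb: PBVector, values: np.ndarray
) -> list[StepOutput]:
    """Teacher-forced pass over a sequence; returns the T-1 one-step-ahead
    predictions as :class:`StepOutput` records."""
    fwd = forward_pass(weights, pb, values)
    return [
        StepOutput(x_d=fwd["x_d"][t], x_v=fwd["x_v"][t], s_o=fwd["s_o"][t])
        for t in range(fwd["s_o"].shape[0])
    ]


def sequence_cost(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Half sum-of-squares prediction cost C = 1/2 sum_t sum_k (target - output)^2.

    ``targets`` at step t is the observation at t+1; both arrays are
    (T-1, n_out).
    """
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape:
        raise ValueError(
            f"outputs shape {outputs.shape} != targets shape {targets.shape}"
        )
    diff = targets - outputs
    return 0.5 * float(np.sum(diff * diff))
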