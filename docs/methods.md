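# Methods

## The model

The package implements a two-stream Elman-style recurrent network with
parametric biases (an RNNPB) whose streams are joined by a *horizontal
product*. It models an observer that watches a colored ball being moved
along a closed planar curve and learns, from passive observation alone,
both *what* it sees (the ball's color) and *how it moves* (the curve),
compressing the identity of each observed sequence into a two-dimensional
latent code.

The observation at time t is a 4-vector over two color layers,
`(layer1_y, layer1_z, layer2_y, layer2_z)`: a yellow ball occupies layer 1
(layer 2 exactly zero), a green ball layer 2. Two independent recurrent
hidden layers process this input:

* the **dorsal** ("where") stream `y_d(t) = W_d s_b(t) + V_d s_d(t-1) + Wbar_d PB_2`,
* the **ventral** ("what") stream `y_v(t) = W_v s_b(t) + V_v s_v(t-1) + Wbar_v PB_1`,

with the scaled hyperbolic tangent `f(y) = 1.7159 tanh(2y/3)` on all hidden
and PB units. Each stream contributes a linear readout `x_d = U_d s_d`,
`x_v = U_v s_v`, and the network output is their element-wise product

    s_o[k] = x_d[k] * x_v[k],

a one-step-ahead prediction of the next observation. The product couples
the streams only at the output: either stream can veto (gate) a channel by
holding its factor at zero, which is how the color identity learned by one
pathway silences the inactive color layer.

The **parametric-bias (PB) units** enter like constant biases but are
cross-wired — group 1 feeds the ventral layer, group 2 the dorsal layer —
and their internal values rho are *learned per sequence* by the error
back-propagated to them. After training, one weight set stores all sequence
classes and the tiny PB vector acts as a bifurcation parameter selecting
which dynamics the network reproduces. Back-propagating through the
horizontal product routes, at first order, the *other* stream's dynamics
into each PB group, which is why the dorsal-attached PB self-organizes by
color (the ventral factor) and the ventral-attached PB by curve type.

## Modes of operation

**Learning.** Full backpropagation through time over each sequence (errors
flow through the recurrent connections across all time steps; gradients
verified against central finite differences to relative error ~1e-9 on
small instances). Per epoch, the sequences are presented one after another:
each sequence's gradients update the weights immediately
(`dw = -eta_ij dC/dw_ij` with per-weight rates) and its own PB vector moves
by `rho_i += gamma_i sum_t delta_i(t)` with the adaptive rate
`gamma_i = M_gamma |mean_t delta_i(t)|`. Once per epoch the per-weight
rates adapt by the sign of the product of consecutive epochs' summed
gradients: same sign multiplies by xi_plus, opposite sign by xi_minus,
clipped to [eta_min, eta_max].

**Recognition.** Weights frozen; starting from rho = 0 the PB vector is
updated by `rho_i += gamma sum_{t in window} delta_i(t)` with a constant
rate gamma over a sliding window covering the last `a` steps (default: the
whole series). A recognized sequence is classified by the nearest
(Euclidean) trained-PB class centroid. The default gamma is 0.01 — equal to
M_gamma and still far above the learning-mode adaptive PB rates (which are
proportional to the shrinking error): larger values (e.g. 0.1) make the
fixed-rate ascent overshoot on some trained networks and escape to spurious
basins far from every trained code.

**Prediction.** PB fixed (set manually or from recognition), hidden state
zeroed, the true observation consumed only at the first step, and each
one-step prediction fed back as the next input. Because the fed-back
prediction stands in for an observation — which is bounded by the image
frame — it is clipped to the valid normalized range [0, 1] before
re-entering the input layer (configurable; the reported output series is
raw). Without this the components of the input that training can never
constrain (see *Limitations*) drift without bound.

## Parameters

| name | meaning | default |
|------|---------|---------|
| eta_dorsal | initial rate, dorsal stream-internal matrices (W_d, V_d, Wbar_d) | 1e-3 |
| eta_ventral | initial rate, ventral stream-internal matrices | 1e-5 |
| eta_output | initial rate, both output matrices U_d, U_v | 1e-3 |
| eta_max / eta_min | adaptive-rate bounds | 1e-1 / 1e-7 |
| xi_plus / xi_minus | rate growth / decay per epoch | 1.000001 / 0.999999 |
| M_gamma | PB update-rate proportionality constant | 1e-2 |
| n_d / n_v | hidden units per stream | 50 / 50 |
| n_pb1 / n_pb2 | PB units per group | 1 / 1 |
| max_epochs | training length | 5000 (library); 25000 in the protocol drivers |
| gamma_recog / recog_epochs | recognition rate / iterations | 0.01 / 1000 |

The stream rates deliberately differ by two orders of magnitude: the
dorsal ("fast") stream tracks movement while the ventral ("slow") stream
maintains a persistent feature representation. The package applies these
per-stream rates to the stream-internal matrices only and trains both
output matrices at the fast rate (`eta_output`). This is a considered
design choice: if the ventral *output* weights also use the slow rate, the
two streams' output amplitudes become extremely lopsided (the dorsal factor
grows 100-300x the ventral one, since each factor's gradient is scaled by
the other factor), and the closed-loop generator is then unstable at every
training length we measured, while recognition degrades with further
training. With a shared output rate the slow/fast division of labor remains
in the hidden dynamics, and recognition and generation behave as intended.

Note that with xi_plus - 1 = 1e-6 per epoch, the sign-based rate adaptation
moves any rate by well under 1% over 10^4 epochs; the mechanism is
implemented exactly as specified, but at these settings it is a very gentle
trim rather than a driver of convergence.

## The synthetic-data generator

The generator emulates the two-robot protocol: a presenter moves a yellow
or green ball (two colors) along a cosine or square loop (two curves),
five repetitions each — 20 training sequences of 20 time steps. Curves are
parameterized by a phase t on an even grid over (-pi, pi]; the camera is
modeled as an orthographic projection of the presenter-frame (y, z)
coordinates; the projected point is affinely normalized into [0.1, 0.9]
with fixed global bounds derived from the curve equations, placed into the
ball's color layer (the other layer stays exactly zero), and perturbed by
seeded Gaussian noise (sigma = 0.01 normalized units) emulating imperfect
arm control. A circle curve (never trained) supports the generalization
experiment, and a speed variant scales the phase step at fixed sequence
length (the loop is traversed multiple times).

The printed square-curve z-branches are mutually inconsistent; the
implementation uses the unique continuous closed loop that keeps the
printed slopes +-16/pi, the hold value 14 and two of the printed linear
branches, repairing one intercept and filling one omitted hold value (see
the `square_curve` docstring). Raw-coordinate offsets are irrelevant after
per-channel normalization.

What the generator does **not** emulate: camera geometry and lens
distortion, HSV thresholding and centroid extraction, occlusions, varying
start phase of the recorded loops (every generated sequence starts at the
same phase), and structured (non-Gaussian, autocorrelated) servo noise.
Passing tests therefore show that the architecture and algorithms behave as
designed under the stated idealized conditions, not that they would survive
a real robot's sensorium.

## Numerical choices

* Hidden state at t = 0 is the zero vector; initial PB internal values are 0.
* Weights initialize uniformly on [-0.1, 0.1] (seeded); output units are
  linear; there are no bias terms other than the PB units.
* PB activations are recomputed only when rho changes (they are constant
  within a forward pass).
* Training stops at max_epochs or when the epoch-summed cost falls below
  1e-4 (with the default noisy data the noise floor is ~0.15, so the
  epoch budget is the effective stop). The protocol drivers train for
  25000 epochs, which puts the cost within ~15% of the noise floor; the
  first epoch leaves the adaptive rates unchanged (no previous gradient).
* Recognition stops early when no rho component moves more than 1e-6 in an
  iteration.
* The training inner loop has a numba-compiled kernel replaying the exact
  reference schedule (numpy fallback when numba is absent or sequence
  lengths differ); a regression test keeps the two paths aligned to ~1e-13
  on 50-epoch cost traces.
* Prediction-error tables (the per-unit MSE of closed-loop generation) are
  computed in normalized units over the full generated series; the error
  metric is mean squared deviation per output unit, matching the form of
  the training cost.

## Known limitations

* **Closed-loop identifiability.** The channel-exclusive encoding means the
  inactive color layer is exactly zero throughout every training sequence
  of that class, so no data constrain the network's sensitivity to
  perturbations of those inputs. Closed-loop generation re-injects small
  prediction residuals precisely there, and the (random, untrained)
  feedback gain can exceed 1. Clipping the fed-back observation bounds the
  effect; it cannot remove it. Generated-trajectory errors on the inactive
  channels are therefore seed-dependent and systematically larger than
  open-loop errors.
* **Early-transient shape.** Because every generated sequence starts at the
  same phase as every training sequence, the first closed-loop steps are
  the *best*-predicted ones (the zero-state start is in-distribution), and
  the error grows with horizon as drift accumulates. A large early
  transient that decays — the signature of attractor capture from an
  ambiguous start — requires start-phase diversity in the data, which the
  fixed-phase protocol deliberately does not provide (a randomized-phase
  variant was evaluated and makes the 20-sequence task unlearnable).
* **PB scale.** The adaptive PB rate is proportional to the back-propagated
  error magnitude, so PB codes grow quadratically slowly as the fit
  improves and remain small (|rho| ~ 1e-2); class structure in the PB plane
  is present but with thin margins, and strict threshold separation of both
  factors is seed-dependent.
* The adaptive-rate constants as printed (xi +- 1e-6 of unity) barely move
  the rates at realistic epoch counts (see above).
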