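"""From-scratch first-order optimizer update rules.

Pure, functional single-step implementations of SGD, RMSprop, Adam, and
Adadelta operating on NumPy arrays, plus a small object wrapper used by the
model-training loop.  Each ``*_step`` takes an :class:`OptimizerState` and a
gradient and returns a new state, so every rule is unit-testable one step at
a time against direct substitution into its recurrence.

Conventions:

* SGD:       W <- W - a * g
* RMSprop:   ms <- r*ms + (1-r)*g^2;  W <- W - a * g / (sqrt(ms) + eps)
* Adam:      m <- r1*m + (1-r1)*g;  u <- r2*u + (1-r2)*g^2; bias-corrected
             m^ = m/(1-r1^t), u^ = u/(1-r2^t);  W <- W - a * m^/(sqrt(u^)+eps)
* Adadelta:  Eg <- r*Eg + (1-r)*g^2;  dW = -a * sqrt(Edx+eps)/sqrt(Eg+eps) * g;
             Edx <- r*Edx + (1-r)*dW^2  (a defaults to 1; exposed because the
             hyperparameter grid varies the learning rate for every rule)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "OptimizerState",
    "init_state",
    "sgd_step",
    "rmsprop_step",
    "adam_step",
    "adadelta_step",
    "step_fn",
    "Optimizer",
    "minimize_quadratic",
    "OPTIMIZER_IDS",
]

OPTIMIZER_IDS = ("sgd", "rmsprop", "adam", "adadelta")


@dataclass(frozen=True)
class OptimizerState:
    """Weights plus every accumulator any of the four rules may need."""

    weights: np.ndarray
    step: int = 0
    learning_rate: float = 0.001
    rho: float = 0.9              # RMSprop forgetting factor / Adadelta decay
    rho1: float = 0.9             # Adam first-moment decay
    rho2: float = 0.999           # Adam second-moment decay
    epsilon: float = 1e-8
    mean_square: np.ndarray | None = None     # RMSprop
    first_moment: np.ndarray | None = None    # Adam m
    second_moment: np.ndarray | None = None   # Adam u
    sq_grad: np.ndarray | None = None         # Adadelta E[g^2]
    sq_update: np.ndarray | None = None       # Adadelta E[dW^2]


def init_state(weights, learning_rate: float = 0.001, **kwargs) -> OptimizerState:
    """Fresh state with all accumulators at zero, shaped like ``weights``."""
    w = np.asarray(weights, dtype=float)
    zeros = np.zeros_like(w)
    state = OptimizerState(
        weights=w,
        learning_rate=learning_rate,
        mean_square=zeros.copy(),
        first_moment=zeros.copy(),
        second_moment=zeros.copy(),
        sq_grad=zeros.copy(),
        sq_update=zeros.copy(),
        **kwargs,
    )
    if state.epsilon <= 0:
        raise InvalidArgumentError("epsilon must be positive")
    return state


def _check(state: OptimizerState, gradient) -> np.ndarray:
    g = np.asarray(gradient, dtype=float)
    if g.shape != state.weights.shape:
        raise InvalidArgumentError("gradient shape must match weights")
    return g


def sgd_step(state: OptimizerState, gradient) -> OptimizerState:
    g = _check(state, gradient)
    return replace(
        state,
        weights=state.weights - state.learning_rate * g,
        step=state.step + 1,
    )


def rmsprop_step(state: OptimizerState, gradient) -> OptimizerState:
    g = _check(state, gradient)
    ms = state.rho * state.mean_square + (1 - state.rho) * g**2
    w = state.weights - state.learning_rate * g / (np.sqrt(ms) + state.epsilon)
    return replace(state, weights=w, mean_square=ms, step=state.step + 1)


def adam_step(state: OptimizerState, gradient) -> OptimizerState:
    g = _check(state, gradient)
    if not (0 < state.rho1 < 1 and 0 < state.rho2 < 1):
        raise InvalidArgumentError("adam decay rates must lie in (0, 1)")
    t = state.step + 1
    m = state.rho1 * state.first_moment + (1 - state.rho1) * g
    u = state.rho2 * state.second_moment + (1 - state.rho2) * g**2
    m_hat = m / (1 - state.rho1**t)
    u_hat = u / (1 - state.rho2**t)
    w = state.weights - state.learning_rate * m_hat / (np.sqrt(u_hat) + state.epsilon)
    return replace(state, weights=w, first_moment=m, second_moment=u, step=t)


def adadelta_step(state: OptimizerState, gradient) -> OptimizerState:
    g = _check(state, gradient)
    eg = state.rho * state.sq_grad + (1 - state.rho) * g**2
    delta = -np.sqrt(state.sq_update + state.epsilon) / np.sqrt(eg + state.epsilon) * g
    delta = state.learning_rate * delta
    edx = state.rho * state.sq_update + (1 - state.rho) * delta**2
    return replace(
        state,
        weights=state.weights + delta,
        sq_grad=eg,
        sq_update=edx,
        step=state.step + 1,
    )


_STEPS = {
    "sgd": sgd_step,
    "rmsprop": rmsprop_step,
    "adam": adam_step,
    "adadelta": adadelta_step,
}


def step_fn(rule: str):
    """The single-step function for an optimizer identifier."""
    try:
        return _STEPS[rule]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown optimizer {rule!r}; expected one of {OPTIMIZER_IDS}"
        ) from None


@dataclass
class Optimizer:
    """Stateful wrapper applying one rule to a list of parameter tensors."""

    rule: str
    learning_rate: float
    states: list[OptimizerState] = field(default_factory=list)

    def bind(self, params: list[np.ndarray]) -> None:
        self.states = [init_state(p, self.learning_rate) for p in params]
        self._step = step_fn(self.rule)

    def update(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        """Update each tensor in place from its gradient."""
        for i, (p, g) in enumerate(zip(params, grads)):
            st = replace(self.states[i], weights=p.astype(float, copy=False))
            st = self._step(st, g)
            self.states[i] = st
            p[...] = st.weights


def minimize_quadratic(
    rule: str,
    learning_rate: float,
    start,
    iterations: int,
    **hyper,
) -> np.ndarray:
    """Run a rule on f(w) = 0.5 * ||w||^2 (gradient w); return the trajectory.

    The returned array has ``iterations + 1`` rows, the first being the start
    point — a tiny convergence harness for comparing the four rules.
    """
    w0 = np.atleast_1d(np.asarray(start, dtype=float))
    state = init_state(w0, learning_rate, **hyper)
    step = step_fn(rule)
    trajectory = [state.weights.copy()]
    for _ in range(iterations):
        state = step(state, state.weights)
        trajectory.append(state.weights.copy())
    return np.asarray(trajectory)
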