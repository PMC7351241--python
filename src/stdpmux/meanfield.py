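"""Deterministic slow-learning weight dynamics on the ring.

In the limit of a slow learning rate the stochastic STDP updates average into
a deterministic drift for the weight profile ``w_eta(phi, t)`` of each
population (phases sampled at the ``N`` preferred phases of the ring):

``dw_eta(phi)/dt / lambda = F_d + w_bar_eta * F_0 * (1+sigma**2)
+ w_tilde_eta * F_1 + sum_xi w_bar_xi * F_0``

with a self-interaction term ``F_d`` proportional to ``K_±(d)/N``, a uniform
term ``F_0 = D**2 (f_+ - f_-)`` and a rhythmic term ``F_1`` whose cosine
arguments are ``phi - Omega_± - nu*d - psi_eta``.  Cross-population coupling
enters only through the mean weights ``w_bar_xi`` — the rhythmic components
of different populations never interact directly, which is what limits the
winner-take-all competition between rhythms.

Order parameters use the half-amplitude first-Fourier convention:
``w_tilde * exp(i*psi) = mean_j w_j * exp(i*phi_j)``, so a profile
``c + a*cos(phi - theta)`` has ``w_bar = c``, ``w_tilde = a/2``,
``psi = theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stdp_rules import STDPRule, eval_kernels, eval_weight_dependence, kernel_fourier

__all__ = [
    "MeanFieldState",
    "OrderParams",
    "DriftDecomposition",
    "MeanFieldTrajectory",
    "initial_state",
    "order_parameters",
    "drift_field",
    "drift_decomposition",
    "integrate_meanfield",
    "phase_velocity",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class MeanFieldState:
    """Weight profiles (one array of length ``N_eta`` per population) at a time."""

    weights: list
    time: float = 0.0

    def copy(self) -> "MeanFieldState":
        return MeanFieldState([w.copy() for w in self.weights], self.time)


@dataclass
class OrderParams:
    """Per-population mean weight, first-Fourier magnitude, and phase."""

    w_bar: np.ndarray
    w_tilde: np.ndarray
    psi: np.ndarray  # in [0, 2*pi)
    time: float = 0.0


@dataclass
class DriftDecomposition:
    """Components of the drift and their circular means / first Fourier data."""

    f_d: list
    f_0: list
    f_1: list
    means: list  # per population: dict x -> F_bar_x
    fourier: list  # per population: dict x -> (F_tilde_x, Phi_x)


def initial_state(specs, kind: str = "uniform", low: float = 0.45, high: float = 0.55,
                  rng=None) -> MeanFieldState:
    """Uniform-in-[low, high] random profiles, or the constant ``(low+high)/2``."""
    rng = np.random.default_rng(rng)
    weights = []
    for spec in specs:
        if kind == "random":
            weights.append(rng.uniform(low, high, spec.size))
        elif kind == "uniform":
            weights.append(np.full(spec.size, 0.5 * (low + high)))
        else:
            raise ValueError("kind must be 'uniform' or 'random'")
    return MeanFieldState(weights=weights, time=0.0)


def _order(w: np.ndarray):
    phis = 2.0 * math.pi * np.arange(len(w)) / len(w)
    z = np.mean(w * np.exp(1j * phis))
    return float(np.mean(w)), float(abs(z)), float(np.angle(z) % (2.0 * math.pi))


def order_parameters(state: MeanFieldState) -> OrderParams:
    """Discrete circular mean and first Fourier magnitude/phase per population."""
    w_bar, w_tilde, psi = [], [], []
    for w in state.weights:
        if len(w) == 0:
            raise ValueError("empty weight profile")
        b, t, p = _order(w)
        w_bar.append(b)
        w_tilde.append(t)
        psi.append(p if t > 1e-12 else 0.0)  # psi undefined on a flat profile
    return OrderParams(np.array(w_bar), np.array(w_tilde), np.array(psi), state.time)


def _drift_terms(state: MeanFieldState, rule: STDPRule, specs, d: float):
    """Per-population (F_d, F_0_weighted, F_1_scaled, w_tilde) arrays.

    ``F_0_weighted`` already includes the mean-weight couplings (own and
    cross-population); ``F_1_scaled`` is ``w_tilde * F_1``.
    """
    specs = list(specs)
    if len(specs) != len(state.weights):
        raise ValueError(
            f"{len(state.weights)} weight profiles but {len(specs)} population specs"
        )
    kpd, kmd = eval_kernels(rule, d)
    bars = [float(np.mean(w)) for w in state.weights]
    out = []
    for eta, (spec, w) in enumerate(zip(specs, state.weights)):
        if len(w) != spec.size:
            raise ValueError("profile length does not match population size")
        D = spec.intensity_mean
        sig2 = spec.sigma**2
        fp, fm = eval_weight_dependence(rule, np.clip(w, 0.0, 1.0))
        phis = spec.phases
        _, wt, psi = _order(w)
        ks = kernel_fourier(rule, spec.nu)
        f_d = w * (D / spec.size) * (fp * kpd - fm * kmd)
        # own-mean term carries (1+sigma^2); cross terms couple via D_eta*D_xi
        coupling = bars[eta] * D * D * (1.0 + sig2)
        for xi, other in enumerate(specs):
            if xi != eta:
                coupling += bars[xi] * D * other.intensity_mean
        f_0 = fp - fm
        f_1 = (
            D
            * D
            * (spec.gamma**2 / 2.0)
            * (1.0 + sig2)
            * (
                ks.k_tilde_plus * fp * np.cos(phis - ks.omega_plus - spec.nu * d - psi)
                - ks.k_tilde_minus * fm * np.cos(phis - ks.omega_minus - spec.nu * d - psi)
            )
        )
        out.append((f_d, coupling * f_0, wt * f_1, f_0, f_1))
    return out


def drift_field(state: MeanFieldState, rule: STDPRule, specs, d: float) -> list:
    """Per-phase drift ``dw/dt / lambda`` for each population.

    The integrator multiplies by ``rule.learning_rate``; at the homogeneous
    fixed point of :func:`stdpmux.stability.homogeneous_fixed_point` this
    vanishes identically.
    """
    return [fd + f0w + wtf1 for fd, f0w, wtf1, _, _ in _drift_terms(state, rule, specs, d)]


def drift_decomposition(state: MeanFieldState, rule: STDPRule, specs, d: float) -> DriftDecomposition:
    """Drift components with circular means and first-Fourier data per population."""
    specs = list(specs)
    terms = _drift_terms(state, rule, specs, d)
    f_ds, f_0s, f_1s, means, fouriers = [], [], [], [], []
    for spec, (fd, _, _, f0_raw, f1) in zip(specs, terms):
        f0 = spec.intensity_mean**2 * f0_raw
        f_ds.append(fd)
        f_0s.append(f0)
        f_1s.append(f1)
        m, four = {}, {}
        for name, arr in (("d", fd), ("0", f0), ("1", f1)):
            m[name] = float(np.mean(arr))
            n = len(arr)
            z = np.mean(arr * np.exp(1j * 2.0 * math.pi * np.arange(n) / n))
            four[name] = (float(abs(z)), float(np.angle(z) % (2.0 * math.pi)))
        means.append(m)
        fouriers.append(four)
    return DriftDecomposition(f_ds, f_0s, f_1s, means, fouriers)


@dataclass
class MeanFieldTrajectory:
    """Order-parameter time series (rows = output strides, cols = populations)."""

    times: np.ndarray
    w_bar: np.ndarray
    w_tilde: np.ndarray
    psi: np.ndarray
    final_state: MeanFieldState
    profiles: list = field(default_factory=list)  # (t, [arrays]) snapshots


def integrate_meanfield(
    initial: MeanFieldState,
    rule: STDPRule,
    specs,
    d: float,
    horizon: float,
    step: float = 1.0,
    output_stride: float = 1.0,
    record_profiles: bool = False,
    max_dw: float = 0.01,
    psi_floor: float = 0.005,
) -> MeanFieldTrajectory:
    """Explicit Euler integration of the mean-field drift.

    Weights are clipped to ``[0, 1]`` after each step.  If a step would move
    any weight by more than ``max_dw`` the step is internally halved (an
    uncatchable change > 0.1 at the *requested* step size raises
    :class:`IntegrationError`).  ``psi`` is carried forward from the last
    stride where ``w_tilde`` exceeded ``psi_floor`` — the phase is undefined
    on an unstructured profile.
    """
    specs = list(specs)
    lam = rule.learning_rate
    state = initial.copy()
    times, bars, tildes, psis = [], [], [], []
    profiles = []
    last_psi = np.zeros(len(specs))

    def record():
        op = order_parameters(state)
        for i in range(len(specs)):
            if op.w_tilde[i] >= psi_floor:
                last_psi[i] = op.psi[i]
        times.append(state.time)
        bars.append(op.w_bar.copy())
        tildes.append(op.w_tilde.copy())
        psis.append(last_psi.copy())
        if record_profiles:
            profiles.append((state.time, [w.copy() for w in state.weights]))

    record()
    next_output = output_stride
    t_end = horizon
    while state.time < t_end - 1e-12:
        dt = min(step, t_end - state.time, next_output - state.time + 1e-12)
        drifts = drift_field(state, rule, specs, d)
        peak = max(float(np.max(np.abs(dr))) * lam * dt for dr in drifts)
        if peak > 0.1:
            raise IntegrationError(
                f"step {dt:.3g}s moves a weight by {peak:.3g} (> 0.1); reduce step"
            )
        n_sub = max(1, int(math.ceil(peak / max_dw)))
        sub = dt / n_sub
        for _ in range(n_sub):
            if n_sub > 1:
                drifts = drift_field(state, rule, specs, d)
            for w, dr in zip(state.weights, drifts):
                np.clip(w + lam * sub * dr, 0.0, 1.0, out=w)
            state.time += sub
        if state.time >= next_output - 1e-9:
            record()
            next_output += output_stride
    if times[-1] < state.time - 1e-9:
        record()
    return MeanFieldTrajectory(
        times=np.array(times),
        w_bar=np.array(bars),
        w_tilde=np.array(tildes),
        psi=np.array(psis),
        final_state=state,
        profiles=profiles,
    )


def phase_velocity(
    traj: MeanFieldTrajectory,
    window: float,
    w_tilde_floor: float = 0.005,
) -> list:
    """Linear-drift fit of ``psi(t)`` over the trailing ``window`` seconds.

    Returns one dict per population with keys ``defined``, ``velocity``
    (rad/s), and ``residual_rms`` (rad).  Populations whose mean ``w_tilde``
    in the window falls below ``w_tilde_floor`` are flagged undefined.
    """
    t = traj.times
    mask = t >= t[-1] - window
    if mask.sum() < 3:
        raise ValueError("window too short: fewer than 3 recorded strides")
    out = []
    for i in range(traj.psi.shape[1]):
        if float(np.mean(traj.w_tilde[mask, i])) < w_tilde_floor:
            out.append({"defined": False, "velocity": np.nan, "residual_rms": np.nan})
            continue
        psi = np.unwrap(traj.psi[mask, i])
        coef = np.polyfit(t[mask], psi, 1)
        resid = psi - np.polyval(coef, t[mask])
        out.append(
            {
                "defined": True,
                "velocity": float(coef[0]),
                "residual_rms": float(np.sqrt(np.mean(resid**2))),
            }
        )
    return out
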