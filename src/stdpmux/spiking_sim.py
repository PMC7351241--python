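"""Finite-learning-rate spiking simulations.

Two downstream neuron models are available:

* :class:`LinearPoissonNeuron` — the instantaneous rate is the delayed
  weighted sum of the pre-synaptic spike trains,
  ``r_post(t) = (1/N) sum_eta sum_k w_eta,k rho_eta,k(t - d)``, converted to
  spikes bin-by-bin as a Bernoulli process;
* :class:`ConductanceNeuron` — a Hodgkin–Huxley point neuron with a transient
  potassium A-current (strong A-current yields an approximately
  threshold-linear f-I curve) driven through alpha-function synaptic
  conductances ``g0 * w * (t/tau) * exp(-t/tau)``.

In both cases the synaptic weights are updated once per second of simulated
time by the all-pairs STDP rule, with a rolling spike buffer spanning the
kernel support so that pairs straddling update boundaries are not dropped.
Weights are clipped to ``[0, 1]`` after each update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stdp_rules import STDPRule, eval_kernels, eval_weight_dependence
from .synthetic_inputs import PopulationSpec, sample_intensities
from .meanfield import MeanFieldState, order_parameters

__all__ = [
    "LinearPoissonNeuron",
    "ConductanceNeuron",
    "SimulationResult",
    "run_linear_poisson",
    "run_conductance",
    "stdp_online_update",
    "hh_step",
    "fi_curve",
]


@dataclass(frozen=True)
class LinearPoissonNeuron:
    """Linear Poisson downstream neuron with characteristic delay ``d`` (s)."""

    delay: float = 0.010
    bin_width: float = 1e-3

    def __post_init__(self):
        if self.delay < 0:
            raise ValueError("delay must be non-negative")


@dataclass(frozen=True)
class ConductanceNeuron:
    """Shriki-type conductance-based neuron (units: mV, ms, mS/cm2, uA/cm2)."""

    c_m: float = 0.1  # uF/cm2
    g_l: float = 0.05
    g_na: float = 100.0
    g_k: float = 40.0
    g_a: float = 20.0  # 0 disables the A-current (non-linear f-I curve)
    e_l: float = -65.0
    e_na: float = 55.0
    e_k: float = -80.0
    e_exc: float = 0.0
    tau_a: float = 20.0  # ms
    tau_syn: float = 5.0  # ms, alpha-function time constant
    g_r: float = 9e-4  # mS/cm2 (900 nS/cm2), per-synapse scale before S = 1000/N

    def g0(self, population_size: int) -> float:
        """Per-population synaptic scale ``g_R * 1000/N`` in mS/cm2."""
        return self.g_r * 1000.0 / population_size


@dataclass
class SimulationResult:
    """Weight trajectory (update cadence), downstream spikes, and run metadata."""

    times: np.ndarray  # s, weight-sample instants
    w_bar: np.ndarray  # (n_samples, n_populations)
    w_tilde: np.ndarray
    psi: np.ndarray
    weight_traj: list  # per population: (n_samples, N) arrays
    post_spikes: np.ndarray  # s
    duration: float
    seed: int | None
    config: dict = field(default_factory=dict)
    pre_rasters: list | None = None
    voltage: tuple | None = None  # (times_s, V_mV), decimated


# ---------------------------------------------------------------------------
# STDP pair bookkeeping


def _pair_sums(rule, pre_t, pre_idx, post_t, n_syn):
    """Sums of K_+ and K_- over all (pre, post) pairs, aggregated per synapse."""
    acc_p = np.zeros(n_syn)
    acc_m = np.zeros(n_syn)
    if len(pre_t) == 0 or len(post_t) == 0:
        return acc_p, acc_m
    dt = post_t[None, :] - pre_t[:, None]
    kp, km = eval_kernels(rule, dt)
    np.add.at(acc_p, pre_idx, kp.sum(axis=1))
    np.add.at(acc_m, pre_idx, km.sum(axis=1))
    return acc_p, acc_m


def stdp_online_update(pre_spikes, post_spikes, weights, rule: STDPRule) -> np.ndarray:
    """All-pairs STDP update of a weight vector over one window.

    ``pre_spikes`` is a list of per-synapse spike-time arrays, ``post_spikes``
    the downstream spike times covering the same window (both extended by the
    kernel support where cross-boundary pairs matter).  Returns the updated,
    clipped weights; pair order is immaterial (additive rule).
    """
    weights = np.asarray(weights, dtype=float)
    post_t = np.asarray(post_spikes, dtype=float)
    pre_t = np.concatenate([np.asarray(s, dtype=float) for s in pre_spikes]) if pre_spikes else np.empty(0)
    pre_idx = (
        np.concatenate([np.full(len(s), j) for j, s in enumerate(pre_spikes)]).astype(int)
        if pre_spikes
        else np.empty(0, dtype=int)
    )
    acc_p, acc_m = _pair_sums(rule, pre_t, pre_idx, post_t, len(weights))
    f_plus, f_minus = eval_weight_dependence(rule, np.clip(weights, 0.0, 1.0))
    w = weights + rule.learning_rate * (f_plus * acc_p - f_minus * acc_m)
    return np.clip(w, 0.0, 1.0)


class _PairBuffer:
    """Rolling pre/post spike buffer counting each pair exactly once."""

    def __init__(self, rule: STDPRule, n_syn: int):
        self.rule = rule
        self.n_syn = n_syn
        self.support = rule.kernel_support
        self.old_pre_t = np.empty(0)
        self.old_pre_idx = np.empty(0, dtype=int)
        self.old_post_t = np.empty(0)

    def update(self, weights, pre_t, pre_idx, post_t, t_end):
        """Apply all new pairs (new x new, new x old-tail, old-tail x new)."""
        rule = self.rule
        acc_p = np.zeros(self.n_syn)
        acc_m = np.zeros(self.n_syn)
        for a, b in ((pre_t, post_t), (pre_t, self.old_post_t)):
            p, m = _pair_sums(rule, a, pre_idx, b, self.n_syn)
            acc_p += p
            acc_m += m
        p, m = _pair_sums(rule, self.old_pre_t, self.old_pre_idx, post_t, self.n_syn)
        acc_p += p
        acc_m += m
        f_plus, f_minus = eval_weight_dependence(self.rule, np.clip(weights, 0.0, 1.0))
        w = weights + rule.learning_rate * (f_plus * acc_p - f_minus * acc_m)
        np.clip(w, 0.0, 1.0, out=w)
        keep = pre_t > t_end - self.support
        self.old_pre_t = pre_t[keep]
        self.old_pre_idx = pre_idx[keep]
        self.old_post_t = post_t[post_t > t_end - self.support]
        return w


def _spike_matrix(spec: PopulationSpec, d_value: float, t0: float, n_bins: int,
                  bin_s: float, rng) -> np.ndarray:
    """Bernoulli spike matrix (n_bins, N) for one window at fixed intensity."""
    t = t0 + (np.arange(n_bins) + 0.5) * bin_s
    p = d_value * (1.0 + spec.gamma * np.cos(spec.nu * t[:, None] - spec.phases[None, :])) * bin_s
    if np.any(p >= 1.0):
        raise ValueError("pre-synaptic spike probability >= 1; decrease bin width")
    return rng.random(p.shape) < p


def _flatten_spikes(mat: np.ndarray, t0: float, bin_s: float, idx_offset: int, rng):
    """(times, synapse indices) of True entries of a (n_bins, N) matrix.

    Spike times are jittered uniformly within their bin: exact bin-center
    times would place pre/post coincidences at a zero lag that always falls
    on the potentiation branch of the (discontinuous) asymmetric kernel,
    biasing the STDP drift upward.
    """
    rows, cols = np.nonzero(mat)
    return t0 + (rows + rng.random(len(rows))) * bin_s, cols + idx_offset


def run_linear_poisson(
    specs,
    rule: STDPRule,
    neuron: LinearPoissonNeuron,
    duration: float,
    seed=None,
    initial_weights=None,
    update_interval: float = 1.0,
    intensity=None,
    freeze_weights: bool = False,
    record_pre: bool = False,
) -> SimulationResult:
    """Simulate the linear Poisson downstream neuron with online STDP.

    ``initial_weights`` may be ``None`` (i.i.d. uniform on [0, 1]), a scalar,
    or a list of per-population arrays.  ``freeze_weights=True`` disables
    plasticity (used to measure transfer through a fixed profile).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    specs = list(specs)
    rng = np.random.default_rng(seed)
    bin_s = neuron.bin_width
    bins_per_win = int(round(update_interval / bin_s))
    n_windows = int(round(duration / update_interval))
    d_bins = int(round(neuron.delay / bin_s))
    sizes = [s.size for s in specs]
    offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    n_syn = int(sum(sizes))

    if initial_weights is None:
        weights = rng.uniform(0.0, 1.0, n_syn)
    elif np.isscalar(initial_weights):
        weights = np.full(n_syn, float(initial_weights))
    else:
        weights = np.concatenate([np.asarray(w, dtype=float) for w in initial_weights])
    weights = np.clip(weights, 0.0, 1.0)

    if intensity is None:
        intensity = sample_intensities(specs, duration, rng, refresh_period=update_interval)

    buf = _PairBuffer(rule, n_syn)
    tails = [np.zeros((d_bins, s.size), dtype=bool) for s in specs]
    post_all = []
    pre_all = [[[] for _ in range(s.size)] for s in specs] if record_pre else None
    times, bars, tildes, psis, traj = [], [], [], [], []

    def record(t):
        state = MeanFieldState(
            [weights[offsets[i]: offsets[i] + sizes[i]].copy() for i in range(len(specs))], t
        )
        op = order_parameters(state)
        times.append(t)
        bars.append(op.w_bar)
        tildes.append(op.w_tilde)
        psis.append(op.psi)
        traj.append([w.copy() for w in state.weights])

    record(0.0)
    for win in range(n_windows):
        t0 = win * update_interval
        p_post = np.zeros(bins_per_win)
        pre_t_list, pre_idx_list = [], []
        for i, spec in enumerate(specs):
            d_val = intensity.value_at(t0, i)
            mat = _spike_matrix(spec, d_val, t0, bins_per_win, bin_s, rng)
            delayed = np.vstack([tails[i], mat[: bins_per_win - d_bins]]) if d_bins else mat
            w_i = weights[offsets[i]: offsets[i] + sizes[i]]
            p_post += delayed @ w_i / spec.size
            tails[i] = mat[bins_per_win - d_bins:] if d_bins else tails[i]
            ts, idx = _flatten_spikes(mat, t0, bin_s, offsets[i], rng)
            pre_t_list.append(ts)
            pre_idx_list.append(idx)
            if record_pre:
                for k in range(spec.size):
                    pre_all[i][k].append(t0 + (np.nonzero(mat[:, k])[0] + 0.5) * bin_s)
        if np.any(p_post >= 1.0):
            bad = int(np.argmax(p_post >= 1.0))
            raise ValueError(
                f"post-synaptic spike probability {p_post[bad]:.3f} >= 1 in bin at "
                f"t={t0 + bad * bin_s:.3f}s; decrease bin width or weights"
            )
        post_hits = rng.random(bins_per_win) < p_post
        post_t = t0 + (np.nonzero(post_hits)[0] + rng.random(int(post_hits.sum()))) * bin_s
        post_all.append(post_t)
        if not freeze_weights:
            weights = buf.update(
                weights,
                np.concatenate(pre_t_list),
                np.concatenate(pre_idx_list),
                post_t,
                t0 + update_interval,
            )
        record(t0 + update_interval)

    pre_rasters = None
    if record_pre:
        from .synthetic_inputs import SpikeRaster

        pre_rasters = [
            SpikeRaster(
                spikes=[np.concatenate(neuron_spikes) for neuron_spikes in pre_all[i]],
                population_id=i,
                duration=duration,
                bin_width=bin_s,
            )
            for i in range(len(specs))
        ]
    return SimulationResult(
        times=np.array(times),
        w_bar=np.array(bars),
        w_tilde=np.array(tildes),
        psi=np.array(psis),
        weight_traj=[np.array([t[i] for t in traj]) for i in range(len(specs))],
        post_spikes=np.concatenate(post_all) if post_all else np.empty(0),
        duration=duration,
        seed=seed if isinstance(seed, int) else None,
        pre_rasters=pre_rasters,
        config={"neuron": "linear", "delay_s": neuron.delay, "bin_s": bin_s},
    )


# ---------------------------------------------------------------------------
# Conductance-based (Shriki) downstream neuron

# Gating rate functions (V in mV, rates in 1/ms); m and a are instantaneous.


def _rates(v):
    am = -0.1 * (v + 30.0) / (math.expm1(-0.1 * (v + 30.0))) if v != -30.0 else 1.0
    bm = 4.0 * math.exp(-(v + 55.0) / 18.0)
    ah = 0.07 * math.exp(-(v + 44.0) / 20.0)
    bh = 1.0 / (math.exp(-0.1 * (v + 14.0)) + 1.0)
    an = -0.01 * (v + 34.0) / (math.expm1(-0.1 * (v + 34.0))) if v != -34.0 else 0.1
    bn = 0.125 * math.exp(-(v + 44.0) / 80.0)
    return am, bm, ah, bh, an, bn


def _xinf_tau(a, b):
    return a / (a + b), 0.1 / (a + b)


def hh_step(neuron: ConductanceNeuron, state: dict, g_syn: float, dt: float,
            i_ext: float = 0.0) -> tuple:
    """Advance the conductance neuron one step of ``dt`` ms.

    ``state`` holds ``V`` (mV), gating ``h``, ``n``, ``b``, and the spike
    latch ``refractory``.  ``g_syn`` is the total excitatory conductance in
    mS/cm2 (held constant over the step), ``i_ext`` an injected current in
    uA/cm2.  Returns ``(new_state, spiked)`` where the spike flag marks an
    upward crossing of 0 mV (latched until V < -20 mV).  Exponential Euler on
    the gating variables and the membrane equation; m (and the A-current
    activation) are instantaneous.
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms for the HH integration")
    v, h, n, b = state["V"], state["h"], state["n"], state["b"]
    refractory = state.get("refractory", False)
    am, bm, ah, bh, an, bn = _rates(v)
    minf = am / (am + bm)
    hinf, tauh = _xinf_tau(ah, bh)
    ninf, taun = _xinf_tau(an, bn)
    ainf = 1.0 / (math.exp(-(v + 50.0) / 20.0) + 1.0)
    binf = 1.0 / (math.exp((v + 80.0) / 6.0) + 1.0)
    h = hinf + (h - hinf) * math.exp(-dt / tauh)
    n = ninf + (n - ninf) * math.exp(-dt / taun)
    b = binf + (b - binf) * math.exp(-dt / neuron.tau_a)
    g_na = neuron.g_na * minf**3 * h
    g_k = neuron.g_k * n**4
    g_a = neuron.g_a * ainf**3 * b
    g_tot = neuron.g_l + g_na + g_k + g_a + g_syn
    i_tot = (
        neuron.g_l * neuron.e_l
        + g_na * neuron.e_na
        + (g_k + g_a) * neuron.e_k
        + g_syn * neuron.e_exc
        + i_ext
    )
    v_inf = i_tot / g_tot
    v_new = v_inf + (v - v_inf) * math.exp(-g_tot * dt / neuron.c_m)
    if abs(v_new) > 200.0:
        raise RuntimeError(f"membrane potential blew up (|V| = {abs(v_new):.1f} mV)")
    spiked = False
    if not refractory and v < 0.0 <= v_new:
        spiked = True
        refractory = True
    elif refractory and v_new < -20.0:
        refractory = False
    new_state = {"V": v_new, "h": h, "n": n, "b": b, "refractory": refractory}
    return new_state, spiked


def _hh_window_py(v, h, n, b, refr, syn_g, syn_b, drive, params, dt, substeps, i_ext,
                  spike_out, g_out, v_out):
    """Integrate one window of binned synaptic drive; returns state + n spikes.

    ``drive[t, eta]`` is the conductance impulse injected into population
    eta's alpha-synapse cascade at the start of bin ``t``; ``g_out``/``v_out``
    record the total synaptic conductance and membrane potential at each bin
    end.  Pure-Python reference implementation; a numba-compiled twin is used
    when available.
    """
    (c_m, g_l, g_na_max, g_k_max, g_a_max, e_l, e_na, e_k, e_exc, tau_a, tau_syn) = params
    n_bins, n_pop = drive.shape
    decay = math.exp(-dt / tau_syn)
    n_spikes = 0
    for t in range(n_bins):
        for p in range(n_pop):
            syn_b[p] += drive[t, p]
        for ss in range(substeps):
            g_syn = 0.0
            for p in range(n_pop):
                g_new = decay * (syn_g[p] + syn_b[p] * dt / tau_syn)
                syn_b[p] *= decay
                syn_g[p] = g_new
                g_syn += g_new
            if v != -30.0:
                am = -0.1 * (v + 30.0) / (math.expm1(-0.1 * (v + 30.0)))
            else:
                am = 1.0
            bm = 4.0 * math.exp(-(v + 55.0) / 18.0)
            ah = 0.07 * math.exp(-(v + 44.0) / 20.0)
            bh = 1.0 / (math.exp(-0.1 * (v + 14.0)) + 1.0)
            if v != -34.0:
                an = -0.01 * (v + 34.0) / (math.expm1(-0.1 * (v + 34.0)))
            else:
                an = 0.1
            bn = 0.125 * math.exp(-(v + 44.0) / 80.0)
            minf = am / (am + bm)
            hinf = ah / (ah + bh)
            tauh = 0.1 / (ah + bh)
            ninf = an / (an + bn)
            taun = 0.1 / (an + bn)
            ainf = 1.0 / (math.exp(-(v + 50.0) / 20.0) + 1.0)
            binf = 1.0 / (math.exp((v + 80.0) / 6.0) + 1.0)
            h = hinf + (h - hinf) * math.exp(-dt / tauh)
            n = ninf + (n - ninf) * math.exp(-dt / taun)
            b = binf + (b - binf) * math.exp(-dt / tau_a)
            g_na = g_na_max * minf * minf * minf * h
            g_k = g_k_max * n * n * n * n
            g_a = g_a_max * ainf * ainf * ainf * b
            g_tot = g_l + g_na + g_k + g_a + g_syn
            i_tot = (
                g_l * e_l + g_na * e_na + (g_k + g_a) * e_k + g_syn * e_exc + i_ext
            )
            v_inf = i_tot / g_tot
            v_new = v_inf + (v - v_inf) * math.exp(-g_tot * dt / c_m)
            if refr == 0 and v < 0.0 and v_new >= 0.0 and n_spikes < spike_out.shape[0]:
                # linear interpolation of the threshold crossing inside the step
                frac = (0.0 - v) / (v_new - v)
                spike_out[n_spikes] = (t * substeps + ss + frac) * dt
                n_spikes += 1
                refr = 1
            elif refr == 1 and v_new < -20.0:
                refr = 0
            v = v_new
        g_out[t] = g_syn
        v_out[t] = v
    return v, h, n, b, refr, n_spikes


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _hh_window = njit(cache=False)(_hh_window_py)
except Exception:  # pragma: no cover
    _hh_window = _hh_window_py


def fi_curve(neuron: ConductanceNeuron, currents, t_ms: float = 2000.0,
             dt: float = 0.025) -> np.ndarray:
    """Firing rate (Hz) for each injected current (uA/cm2), no synaptic input."""
    rates = []
    n_bins = int(round(t_ms))  # 1 ms bins
    substeps = int(round(1.0 / dt))
    drive = np.zeros((n_bins, 1))
    for i_ext in currents:
        params = _neuron_params(neuron)
        spike_out = np.empty(int(t_ms), dtype=np.float64)
        g_out = np.empty(n_bins)
        v_out = np.empty(n_bins)
        v, h, n, b, refr = -65.0, 0.8, 0.1, 0.2, 0
        syn_g = np.zeros(1)
        syn_b = np.zeros(1)
        v, h, n, b, refr, n_sp = _hh_window(
            v, h, n, b, refr, syn_g, syn_b, drive, params, dt, substeps, float(i_ext),
            spike_out, g_out, v_out,
        )
        rates.append(n_sp / (t_ms / 1000.0))
    return np.array(rates)


def _neuron_params(neuron: ConductanceNeuron):
    return (
        neuron.c_m,
        neuron.g_l,
        neuron.g_na,
        neuron.g_k,
        neuron.g_a,
        neuron.e_l,
        neuron.e_na,
        neuron.e_k,
        neuron.e_exc,
        neuron.tau_a,
        neuron.tau_syn,
    )


def run_conductance(
    specs,
    rule: STDPRule,
    neuron: ConductanceNeuron,
    duration: float,
    seed=None,
    initial_weights=0.5,
    update_interval: float = 1.0,
    bin_s: float = 1e-3,
    dt_ms: float = 0.025,
    intensity=None,
    record_voltage: bool = False,
) -> SimulationResult:
    """Simulate the conductance-based downstream neuron with online STDP.

    Pre-synaptic rasters are binned at ``bin_s``; each spike injects an
    alpha-function conductance ``g0 * w * (t/tau) exp(-t/tau)`` with
    ``g0 = g_R * 1000/N``.  The membrane equation is integrated with
    exponential Euler at ``dt_ms`` (default 0.025 ms).  Weights start uniform
    at ``initial_weights`` and are updated every ``update_interval`` seconds.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    specs = list(specs)
    rng = np.random.default_rng(seed)
    bins_per_win = int(round(update_interval / bin_s))
    n_windows = int(round(duration / update_interval))
    substeps = int(round(bin_s * 1e3 / dt_ms))
    sizes = [s.size for s in specs]
    offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    n_syn = int(sum(sizes))
    g0s = np.array([neuron.g0(s.size) for s in specs])

    if np.isscalar(initial_weights):
        weights = np.full(n_syn, float(initial_weights))
    else:
        weights = np.concatenate([np.asarray(w, dtype=float) for w in initial_weights])
    weights = np.clip(weights, 0.0, 1.0)

    if intensity is None:
        intensity = sample_intensities(specs, duration, rng, refresh_period=update_interval)

    params = _neuron_params(neuron)
    v, h, n, b, refr = -65.0, 0.8, 0.1, 0.2, 0
    syn_g = np.zeros(len(specs))
    syn_b = np.zeros(len(specs))
    buf = _PairBuffer(rule, n_syn)
    post_all = []
    spike_out = np.empty(4 * bins_per_win, dtype=np.float64)
    g_out = np.empty(bins_per_win)
    v_out = np.empty(bins_per_win)
    times, bars, tildes, psis, traj = [], [], [], [], []
    volt_t, volt_v = [], []

    def record(t):
        state = MeanFieldState(
            [weights[offsets[i]: offsets[i] + sizes[i]].copy() for i in range(len(specs))], t
        )
        op = order_parameters(state)
        times.append(t)
        bars.append(op.w_bar)
        tildes.append(op.w_tilde)
        psis.append(op.psi)
        traj.append([w.copy() for w in state.weights])

    record(0.0)
    for win in range(n_windows):
        t0 = win * update_interval
        drive = np.zeros((bins_per_win, len(specs)))
        pre_t_list, pre_idx_list = [], []
        for i, spec in enumerate(specs):
            d_val = intensity.value_at(t0, i)
            mat = _spike_matrix(spec, d_val, t0, bins_per_win, bin_s, rng)
            w_i = weights[offsets[i]: offsets[i] + sizes[i]]
            drive[:, i] = g0s[i] * (mat @ w_i)
            ts, idx = _flatten_spikes(mat, t0, bin_s, offsets[i], rng)
            pre_t_list.append(ts)
            pre_idx_list.append(idx)
        v, h, n, b, refr, n_sp = _hh_window(
            v, h, n, b, refr, syn_g, syn_b, drive, params, dt_ms, substeps, 0.0,
            spike_out, g_out, v_out,
        )
        if abs(v) > 200.0:
            raise RuntimeError("membrane potential blew up during window integration")
        post_t = t0 + spike_out[:n_sp] / 1e3  # ms within window -> s
        post_all.append(post_t.copy())
        if record_voltage:
            volt_t.append(t0 + (np.arange(bins_per_win) + 1.0) * bin_s)
            volt_v.append(v_out.copy())
        weights = buf.update(
            weights,
            np.concatenate(pre_t_list),
            np.concatenate(pre_idx_list),
            post_t,
            t0 + update_interval,
        )
        record(t0 + update_interval)

    return SimulationResult(
        times=np.array(times),
        w_bar=np.array(bars),
        w_tilde=np.array(tildes),
        psi=np.array(psis),
        weight_traj=[np.array([t[i] for t in traj]) for i in range(len(specs))],
        post_spikes=np.concatenate(post_all) if post_all else np.empty(0),
        duration=duration,
        seed=seed if isinstance(seed, int) else None,
        voltage=(np.concatenate(volt_t), np.concatenate(volt_v)) if record_voltage else None,
        config={
            "neuron": "conductance",
            "g_a": neuron.g_a,
            "dt_ms": dt_ms,
            "bin_s": bin_s,
        },
    )
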