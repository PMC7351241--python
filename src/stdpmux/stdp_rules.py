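"""Spike-timing-dependent plasticity rules.

Two kernel families are supported:

* ``asymmetric`` — exponential windows with potentiation for pre-before-post
  (``dt = t_post - t_pre > 0``) and depression for post-before-pre,
  ``K_+(dt) = exp(-dt/tau_+)/tau_+ * H(dt)`` and
  ``K_-(dt) = exp(dt/tau_-)/tau_- * H(-dt)``;
* ``symmetric`` — a difference of Gaussians depending only on ``|dt|``,
  ``K_±(dt) = N(0, tau_±)`` densities.

Both kernels are normalized to unit integral.  Weight dependence follows the
soft-bound form ``f_+(w) = (1-w)^mu`` and ``f_-(w) = alpha * w^mu``, which
confines weights to ``[0, 1]``: depression vanishes at ``w = 0`` and
potentiation vanishes at ``w = 1``.  A single pre/post spike pair updates the
weight by ``lambda * [f_+(w) K_+(dt) - f_-(w) K_-(dt)]``; all pairs contribute
additively.

Fourier data of the kernels are used by the stability analysis.  For the
asymmetric family the complex transform ``∫ K_±(Δ) e^{-i ν Δ} dΔ`` is split
into modulus ``k̃_± = 1/sqrt(1+(ν τ_±)²)`` and phase ``Ω_± = ∓ arctan(ν τ_±)``.
Note: one printed form of the asymmetric result drops the square root in the
modulus; the modulus form implemented here is the one consistent with a direct
quadrature of the transform (see tests) and with the reported eigenvalues.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "STDPRule",
    "KernelSpectrum",
    "eval_kernels",
    "eval_weight_dependence",
    "kernel_fourier",
    "pair_update",
    "rule_to_config",
    "rule_from_config",
]

_FAMILIES = ("asymmetric", "symmetric")


@dataclass(frozen=True)
class STDPRule:
    """Parameters of one STDP rule.

    Parameters
    ----------
    family
        ``"asymmetric"`` (exponential) or ``"symmetric"`` (difference of
        Gaussians).
    tau_plus, tau_minus
        Potentiation / depression time constants in seconds.
    alpha
        Relative strength of depression (> 0).
    mu
        Weight-dependence exponent in ``[0, 1]``; ``mu = 0`` is the additive
        model, ``mu = 1`` the linear (multiplicative) model.
    learning_rate
        Learning rate ``lambda``.  Treated as carrying time units so that
        ``lambda * D**2`` is a rate in 1/s.
    kernel_support
        Truncation of kernel evaluation in seconds.  Defaults to
        ``7 * max(tau_plus, tau_minus)`` which keeps the truncated mass below
        1e-3.
    """

    family: str
    tau_plus: float = 0.020
    tau_minus: float = 0.050
    alpha: float = 1.05
    mu: float = 0.01
    learning_rate: float = 0.001
    kernel_support: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if not (self.tau_plus > 0 and self.tau_minus > 0):
            raise ValueError("tau_plus and tau_minus must be positive")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.kernel_support <= 0.0:
            object.__setattr__(
                self, "kernel_support", 7.0 * max(self.tau_plus, self.tau_minus)
            )


@dataclass(frozen=True)
class KernelSpectrum:
    """Fourier data of the STDP kernels at one angular frequency.

    ``k_bar_±`` are the zero-frequency integrals (1 for normalized kernels);
    ``k_tilde_±`` the transform moduli and ``omega_±`` the phases, so the
    complex transform is ``k_tilde e^{i omega}``.
    """

    k_tilde_plus: float
    k_tilde_minus: float
    omega_plus: float
    omega_minus: float
    at_frequency: float
    k_bar_plus: float = 1.0
    k_bar_minus: float = 1.0


def eval_kernels(rule: STDPRule, dt):
    """Evaluate ``(K_+(dt), K_-(dt))`` in 1/s.

    ``dt = t_post - t_pre`` may be a scalar or array; values beyond
    ``rule.kernel_support`` evaluate to 0.
    """
    dt = np.asarray(dt, dtype=float)
    if not np.all(np.isfinite(dt)):
        raise ValueError("dt must be finite")
    inside = np.abs(dt) <= rule.kernel_support
    if rule.family == "asymmetric":
        kp = np.where(
            (dt >= 0) & inside, np.exp(-np.abs(dt) / rule.tau_plus) / rule.tau_plus, 0.0
        )
        km = np.where(
            (dt < 0) & inside, np.exp(-np.abs(dt) / rule.tau_minus) / rule.tau_minus, 0.0
        )
    else:
        kp = np.where(
            inside,
            np.exp(-0.5 * (dt / rule.tau_plus) ** 2)
            / (rule.tau_plus * math.sqrt(2.0 * math.pi)),
            0.0,
        )
        km = np.where(
            inside,
            np.exp(-0.5 * (dt / rule.tau_minus) ** 2)
            / (rule.tau_minus * math.sqrt(2.0 * math.pi)),
            0.0,
        )
    if kp.ndim == 0:
        return float(kp), float(km)
    return kp, km


def eval_weight_dependence(rule: STDPRule, w):
    """Soft-bound factors ``(f_+(w), f_-(w)) = ((1-w)^mu, alpha*w^mu)``.

    ``w`` must already lie in ``[0, 1]``; callers clip before evaluating.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0.0) or np.any(w > 1.0):
        raise ValueError("w must lie in [0, 1]; clip before calling")
    f_plus = np.power(1.0 - w, rule.mu)
    f_minus = rule.alpha * np.power(w, rule.mu)
    if f_plus.ndim == 0:
        return float(f_plus), float(f_minus)
    return f_plus, f_minus


def kernel_fourier(rule: STDPRule, nu: float) -> KernelSpectrum:
    """Fourier transform data of both kernels at angular frequency ``nu`` (rad/s)."""
    if not np.isfinite(nu) or nu < 0:
        raise ValueError("nu must be a finite non-negative angular frequency")
    if rule.family == "asymmetric":
        ktp = 1.0 / math.sqrt(1.0 + (nu * rule.tau_plus) ** 2)
        ktm = 1.0 / math.sqrt(1.0 + (nu * rule.tau_minus) ** 2)
        omp = -math.atan(nu * rule.tau_plus)
        omm = math.atan(nu * rule.tau_minus)
    else:
        ktp = math.exp(-0.5 * (nu * rule.tau_plus) ** 2)
        ktm = math.exp(-0.5 * (nu * rule.tau_minus) ** 2)
        omp = omm = 0.0
    return KernelSpectrum(
        k_tilde_plus=ktp,
        k_tilde_minus=ktm,
        omega_plus=omp,
        omega_minus=omm,
        at_frequency=nu,
    )


def pair_update(rule: STDPRule, w: float, dt):
    """Weight increment contributed by pre/post pair(s) at lag(s) ``dt``.

    Returns ``lambda * [f_+(w) K_+(dt) - f_-(w) K_-(dt)]`` summed over ``dt``
    if ``dt`` is an array (all pairs contribute additively).  The caller is
    responsible for clipping the resulting weight to ``[0, 1]``.
    """
    f_plus, f_minus = eval_weight_dependence(rule, w)
    kp, km = eval_kernels(rule, dt)
    return rule.learning_rate * float(np.sum(f_plus * kp - f_minus * km))


def rule_to_config(rule: STDPRule) -> dict:
    """Serialize to the JSON config block (time constants in ms)."""
    return {
        "family": rule.family,
        "tau_plus_ms": rule.tau_plus * 1e3,
        "tau_minus_ms": rule.tau_minus * 1e3,
        "alpha": rule.alpha,
        "mu": rule.mu,
        "learning_rate": rule.learning_rate,
    }


def rule_from_config(block: dict | str) -> STDPRule:
    """Deserialize an :class:`STDPRule` from a config dict or JSON string."""
    if isinstance(block, str):
        block = json.loads(block)
    return STDPRule(
        family=block["family"],
        tau_plus=block["tau_plus_ms"] / 1e3,
        tau_minus=block["tau_minus_ms"] / 1e3,
        alpha=block["alpha"],
        mu=block["mu"],
        learning_rate=block.get("learning_rate", 0.001),
    )


def with_learning_rate(rule: STDPRule, learning_rate: float) -> STDPRule:
    """Copy of ``rule`` with a different learning rate."""
    return replace(rule, learning_rate=learning_rate)
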