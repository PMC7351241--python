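"""Homogeneous fixed point and linear stability of the weight dynamics.

For two (or more) symmetric rhythmic populations driving one linear Poisson
neuron under STDP, the homogeneous weight profile ``w_eta,j = w*`` is a fixed
point.  Its linear stability is captured by four prominent eigenvalues of the
stability matrix (all dimensionless; physical rates are ``lambda * D**2``
times these):

* ``lambda_u = -g0`` — uniform mode, eigenvector ``(1, 1)``; always <= 0.
* ``lambda_wta = lambda_u + 2*delta_f`` — winner-take-all mode ``(1, -1)``;
  ``lambda_wta > 0`` means one population suppresses the other.
* ``lambda_rhythmic[nu_eta]`` — growth of a phase-selective (first Fourier)
  perturbation of population eta, gated by the kernel-spectrum combination
  ``Q~(nu) = k~_+ cos(Omega_+ + nu d) - alpha_c k~_- cos(Omega_- + nu d)``.

Multiplexing requires ``lambda_wta < 0`` with both rhythmic eigenvalues > 0.

Conventions for the rhythmic eigenvalue
---------------------------------------
Two values are reported.  ``lambda_rhythmic`` follows the reported closed
form ``lambda_u + (2+sigma**2)*delta_f + gamma**2*(1+sigma**2)*f_+(w*)*Q~``.
``lambda_rhythmic_dyn`` replaces the ``gamma**2`` coefficient by
``gamma**2/4`` and is the exact growth rate of the first-Fourier order
parameter under the mean-field drift implemented in :mod:`stdpmux.meanfield`
(the factor arises from the ``gamma**2/2`` amplitude of the rhythmic drift
component together with the half-amplitude order-parameter convention).  The
two conventions differ by a constant positive factor in the ``Q~`` term only,
so they can disagree about marginal cells in a phase diagram; the ``_dyn``
value is the one the integrator reproduces (see tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stdp_rules import STDPRule, eval_kernels, eval_weight_dependence, kernel_fourier

__all__ = [
    "FixedPointSummary",
    "EigenSummary",
    "coupling_and_alpha_c",
    "fixed_point",
    "homogeneous_fixed_point",
    "qtilde",
    "eigenvalues",
    "phase_diagram",
    "classify_eigenvalues",
    "potentiation_signflip_frequency",
]


@dataclass(frozen=True)
class FixedPointSummary:
    """Homogeneous fixed point and the scalars entering the eigenvalues."""

    x_plus: float
    x_minus: float
    alpha_c: float
    w_star: float
    post_rate: float  # Hz, = n_populations * D * w_star (2 D w* for two)
    g0: float
    g0_hat: float
    delta_f: float  # f_-(w*) - f_+(w*)
    f_plus: float
    f_minus: float
    degenerate: bool = False


@dataclass(frozen=True)
class EigenSummary:
    """The four prominent eigenvalues (dimensionless)."""

    lambda_u: float
    lambda_wta: float
    lambda_rhythmic: dict  # freq_hz -> reported-convention value
    lambda_rhythmic_dyn: dict  # freq_hz -> mean-field-consistent value
    q_tilde: dict  # freq_hz -> Q~
    fixed_point: FixedPointSummary
    eigenvector_u: tuple = (1, 1)
    eigenvector_wta: tuple = (1, -1)


def coupling_and_alpha_c(rule: STDPRule, d: float, sigma: float, N: int, D: float):
    """Self-coupling corrections ``X_± = K_±(d)/((2+sigma**2)*N*D)`` and ``alpha_c``.

    For the asymmetric rule at any delay ``d > 0`` the depression kernel
    vanishes, so ``X_- = 0`` exactly and ``alpha_c > 1``.
    """
    if N <= 0 or D <= 0:
        raise ValueError("N and D must be positive")
    if d < 0:
        raise ValueError("delay d must be non-negative")
    kp, km = eval_kernels(rule, d)
    denom = (2.0 + sigma**2) * N * D
    x_plus = kp / denom
    x_minus = km / denom
    alpha_c = (1.0 + x_plus) / (1.0 + x_minus)
    return x_plus, x_minus, alpha_c


def fixed_point(
    rule: STDPRule,
    alpha_c: float,
    sigma: float,
    D: float,
    x_plus: float = 0.0,
    x_minus: float = 0.0,
    n_populations: int = 2,
) -> FixedPointSummary:
    """Solve ``f_-(w*)/f_+(w*) = alpha_c`` for the homogeneous weight.

    ``w* = (1 + (alpha/alpha_c)**(1/mu))**-1`` for ``mu > 0``; the additive
    limit ``mu = 0`` is handled by its one-sided limits (``w* -> 0`` with
    ``f_- -> alpha_c`` for ``alpha > alpha_c``; ``w* -> 1`` with
    ``g0 -> inf`` for ``alpha < alpha_c``; ``w* = 1/2`` flagged degenerate at
    ``alpha = alpha_c``).
    """
    if alpha_c <= 0:
        raise ValueError("alpha_c must be positive")
    alpha, mu = rule.alpha, rule.mu
    two_sig = 2.0 + sigma**2
    degenerate = False
    if mu > 0.0:
        # log-domain evaluation: w* = 1/(1 + exp(L)), L = ln(alpha/alpha_c)/mu,
        # which overflows naive powers already at mu ~ 1e-3
        L = math.log(alpha / alpha_c) / mu
        ln1pe = max(L, 0.0) + math.log1p(math.exp(-abs(L)))  # ln(1 + e^L)
        w_star = math.exp(-ln1pe)
        ln_one_minus = L - ln1pe  # ln(1 - w*)
        f_plus = math.exp(mu * ln_one_minus)
        f_minus = alpha * math.exp(-mu * ln1pe)
        g0_exponent = -mu * ln1pe - ln_one_minus
        g0 = (
            math.inf
            if g0_exponent > 700.0
            else alpha * mu * two_sig * (1.0 + x_minus) * math.exp(g0_exponent)
        )
    elif alpha > alpha_c:  # mu = 0, additive limit from above
        w_star, f_plus, f_minus, g0 = 0.0, 1.0, alpha_c, 0.0
    elif alpha < alpha_c:
        w_star, f_plus, f_minus, g0 = 1.0, alpha / alpha_c, alpha, math.inf
    else:
        w_star, f_plus, f_minus, g0, degenerate = 0.5, 1.0, alpha, 0.0, True
    delta_f = f_minus - f_plus
    g0_hat = g0 - two_sig * delta_f
    return FixedPointSummary(
        x_plus=x_plus,
        x_minus=x_minus,
        alpha_c=alpha_c,
        w_star=w_star,
        post_rate=n_populations * D * w_star,
        g0=g0,
        g0_hat=g0_hat,
        delta_f=delta_f,
        f_plus=f_plus,
        f_minus=f_minus,
        degenerate=degenerate,
    )


def homogeneous_fixed_point(
    rule: STDPRule, d: float, sigma: float, N: int, D: float, n_populations: int = 2
) -> FixedPointSummary:
    """Convenience: couplings + fixed point in one call."""
    x_plus, x_minus, alpha_c = coupling_and_alpha_c(rule, d, sigma, N, D)
    return fixed_point(rule, alpha_c, sigma, D, x_plus, x_minus, n_populations)


def qtilde(rule: STDPRule, nu: float, d: float, alpha_c: float) -> float:
    """Rhythmic gating factor ``Q~`` at angular frequency ``nu`` (rad/s).

    ``Q~(0) = 1 - alpha_c`` and ``Q~ -> 0`` as ``nu -> inf`` for both kernel
    families.  For the symmetric family this reduces to
    ``cos(nu*d) * (exp(-(nu*tau_+)**2/2) - alpha_c*exp(-(nu*tau_-)**2/2))``.
    """
    spec = kernel_fourier(rule, nu)
    return spec.k_tilde_plus * math.cos(spec.omega_plus + nu * d) - alpha_c * (
        spec.k_tilde_minus * math.cos(spec.omega_minus + nu * d)
    )


def eigenvalues(
    rule: STDPRule,
    specs,
    d: float,
    sigma: float | None = None,
    gamma: float | None = None,
) -> EigenSummary:
    """Compute the four prominent eigenvalues for the given populations.

    ``specs`` is a sequence of :class:`~stdpmux.synthetic_inputs.PopulationSpec`
    (assumed symmetric: same size, mean intensity, sigma and gamma — the
    regime the closed forms cover).  ``sigma``/``gamma`` override the specs'
    values when given.
    """
    specs = list(specs)
    N = specs[0].size
    D = specs[0].intensity_mean
    sigma = specs[0].sigma if sigma is None else sigma
    gamma = specs[0].gamma if gamma is None else gamma
    for s in specs[1:]:
        if s.size != N or s.intensity_mean != D:
            raise ValueError("eigenvalues assume symmetric populations (equal N, D)")
    fp = homogeneous_fixed_point(rule, d, sigma, N, D, n_populations=len(specs))
    if fp.degenerate:
        raise ValueError("degenerate additive fixed point (mu = 0, alpha = alpha_c)")
    lambda_u = -fp.g0
    lambda_wta = lambda_u + 2.0 * fp.delta_f
    base = lambda_u + (2.0 + sigma**2) * fp.delta_f  # == -g0_hat
    lam_r, lam_r_dyn, qts = {}, {}, {}
    for s in specs:
        qt = qtilde(rule, s.nu, d, fp.alpha_c)
        rhythm = (1.0 + sigma**2) * fp.f_plus * qt
        qts[s.freq_hz] = qt
        lam_r[s.freq_hz] = base + gamma**2 * rhythm
        lam_r_dyn[s.freq_hz] = base + 0.25 * gamma**2 * rhythm
    return EigenSummary(
        lambda_u=lambda_u,
        lambda_wta=lambda_wta,
        lambda_rhythmic=lam_r,
        lambda_rhythmic_dyn=lam_r_dyn,
        q_tilde=qts,
        fixed_point=fp,
    )


def classify_eigenvalues(lambda_wta: float, lambda_rhythmic) -> str:
    """Regime label from eigenvalue signs.

    ``WTA`` if the competitive mode is unstable; otherwise ``R`` if every
    rhythmic eigenvalue is positive (multiplexing), ``NR`` if none is, and
    ``partial_R`` if only a strict subset is.
    """
    lam = list(lambda_rhythmic)
    if lambda_wta > 0:
        return "WTA"
    n_pos = sum(1 for v in lam if v > 0)
    if n_pos == len(lam):
        return "R"
    if n_pos == 0:
        return "NR"
    return "partial_R"


_AXES = ("mu", "alpha", "tau_plus", "tau_minus", "d", "gamma", "sigma")


def phase_diagram(
    axis1: tuple,
    axis2: tuple,
    rule: STDPRule,
    specs,
    d: float,
    sigma: float | None = None,
    gamma: float | None = None,
    convention: str = "printed",
) -> pd.DataFrame:
    """Regime label grid over two parameter axes.

    ``axis1``/``axis2`` are ``(name, values)`` with name one of ``mu``,
    ``alpha``, ``tau_plus``, ``tau_minus``, ``d``, ``gamma``, ``sigma``.
    ``convention`` selects which rhythmic eigenvalue drives the labels
    (``"printed"`` or ``"dynamic"``).  Frequencies come from ``specs`` and
    must be passed explicitly by the caller.
    """
    if convention not in ("printed", "dynamic"):
        raise ValueError("convention must be 'printed' or 'dynamic'")
    for name, _ in (axis1, axis2):
        if name not in _AXES:
            raise ValueError(f"unknown axis {name!r}; choose from {_AXES}")
    specs = list(specs)
    freqs = [s.freq_hz for s in specs]
    rows = []
    for v1 in axis1[1]:
        for v2 in axis2[1]:
            params = {axis1[0]: v1, axis2[0]: v2}
            r = rule
            rule_kw = {k: v for k, v in params.items() if k in ("mu", "alpha", "tau_plus", "tau_minus")}
            if rule_kw:
                from dataclasses import replace

                r = replace(rule, **rule_kw)
            d_eff = params.get("d", d)
            sig_eff = params.get("sigma", sigma)
            gam_eff = params.get("gamma", gamma)
            try:
                es = eigenvalues(r, specs, d_eff, sigma=sig_eff, gamma=gam_eff)
                lam = es.lambda_rhythmic if convention == "printed" else es.lambda_rhythmic_dyn
                label = classify_eigenvalues(es.lambda_wta, lam.values())
                row = {
                    axis1[0]: v1,
                    axis2[0]: v2,
                    "lambda_wta": es.lambda_wta,
                    "label": label,
                }
                for i, f in enumerate(freqs, start=1):
                    row[f"lambda_r{i}"] = lam[f]
            except ValueError:
                row = {axis1[0]: v1, axis2[0]: v2, "lambda_wta": np.nan, "label": "degenerate"}
                for i in range(1, len(freqs) + 1):
                    row[f"lambda_r{i}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def potentiation_signflip_frequency(rule: STDPRule, d: float) -> float:
    """Angular frequency ``nu*`` where the potentiation term of ``Q~`` flips sign.

    Solves ``Omega_+(nu) + nu*d = pi/2`` (asymmetric rule:
    ``-arctan(nu*tau_+) + nu*d = pi/2``), the upper cutoff of the unstable
    rhythmic band when ``tau_+ >> d``.
    """
    from scipy.optimize import brentq

    if rule.family != "asymmetric":
        raise ValueError("sign-flip analysis applies to the asymmetric rule")
    if d <= 0:
        raise ValueError("requires a positive delay")

    def g(nu):
        return -math.atan(nu * rule.tau_plus) + nu * d - math.pi / 2.0

    hi = (math.pi / 2.0 + math.pi / 2.0) / d + 1.0 / rule.tau_plus
    return brentq(g, 1e-9, hi)
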