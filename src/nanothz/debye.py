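"""Two-process Debye relaxation model and its least-squares fit.

The complex permittivity is modelled as two superposed exponential
relaxations,

    ε(ν) = ε∞ + (ε1 − ε2)/(1 + i·2πντ1) + (ε2 − ε∞)/(1 + i·2πντ2),

where τ1 is the slow, cooperative hydrogen-bond-network relaxation and τ2
the fast reorientation of quasi-free water.  Fitting the model to a
spectrum yields the two relaxation times; the signature of confinement is
τ1 growing while τ2 stays put.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DebyeParams", "DebyeFitResult", "debye_model", "fit_debye"]


@dataclass(frozen=True)
class DebyeParams:
    """Static (ε1), intermediate (ε2) and high-frequency (ε∞) permittivities
    plus slow/fast relaxation times τ1 > τ2 (ps)."""

    eps1: float
    eps2: float
    eps_inf: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if not (self.tau1 > self.tau2 > 0):
            raise ValueError("need tau1 > tau2 > 0")
        if not (self.eps1 >= self.eps2 >= self.eps_inf >= 1.0):
            raise ValueError("need eps1 >= eps2 >= eps_inf >= 1")


@dataclass(frozen=True)
class DebyeFitResult:
    params: DebyeParams
    stderr: dict | None  # per-parameter 1-sigma, None unless converged
    rss: float
    converged: bool
    message: str = ""


def debye_model(
    params: DebyeParams, frequencies: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the two-process model on a THz frequency grid.

    Returns (ε′, ε″) with the loss ε″ ≥ 0 (absorptive sign convention).
    """
    nu = np.asarray(frequencies, dtype=float)
    x1 = 2.0 * np.pi * nu * params.tau1
    x2 = 2.0 * np.pi * nu * params.tau2
    a1 = params.eps1 - params.eps2
    a2 = params.eps2 - params.eps_inf
    e_real = params.eps_inf + a1 / (1.0 + x1**2) + a2 / (1.0 + x2**2)
    e_imag = a1 * x1 / (1.0 + x1**2) + a2 * x2 / (1.0 + x2**2)
    return e_real, e_imag


def _default_init(
    nu: np.ndarray, e1: np.ndarray, e2: np.ndarray
) -> np.ndarray:
    """Feature-based starting point: static level from the lowest frequency,
    ε∞ from the highest, τ1 from the loss peak, fast process a small
    fraction of the slow one."""
    order = np.argsort(nu)
    eps_static = max(float(e1[order[0]]), 1.0 + 1e-6)
    eps_inf = min(max(float(e1[order[-1]]), 1.0), eps_static)
    pos = nu > 0
    if np.any(pos) and np.max(e2[pos]) > 0:
        nu_peak = float(nu[pos][np.argmax(e2[pos])])
        tau1 = 1.0 / (2.0 * np.pi * nu_peak)
    else:
        tau1 = 1.0 / (2.0 * np.pi * max(float(np.median(nu[pos])) if np.any(pos)
                                        else 1.0, 1e-6))
    amp = max(eps_static - eps_inf, 1e-3)
    return np.array([eps_inf, 0.9 * amp, 0.1 * amp, tau1, 1 / 16.0])


def fit_debye(
    frequencies: np.ndarray,
    eps_real_vals: np.ndarray,
    eps_imag_vals: np.ndarray,
    init: DebyeParams | None = None,
) -> DebyeFitResult:
    """Joint least squares on concatenated (ε′, ε″) residuals, equal weights.

    Internally parameterised as (ε∞, a1, a2, τ1, ρ) with a1, a2 ≥ 0,
    ε∞ ≥ 1 and τ2 = ρ·τ1, ρ ∈ (0,1): the parameter invariants hold by
    construction and the two processes cannot label-switch.  Standard errors
    for the natural parameters come from the Jacobian via the delta method.
    """
    nu = np.asarray(frequencies, dtype=float)
    e1 = np.asarray(eps_real_vals, dtype=float)
    e2 = np.asarray(eps_imag_vals, dtype=float)
    if not (nu.shape == e1.shape == e2.shape):
        raise ValueError("frequencies, eps_real, eps_imag must be congruent")
    if nu.size < 10:
        raise ValueError(f"need >= 10 frequency points, got {nu.size}")
    if init is not None:
        theta0 = np.array(
            [init.eps_inf, init.eps1 - init.eps2, init.eps2 - init.eps_inf,
             init.tau1, init.tau2 / init.tau1]
        )
    else:
        theta0 = _default_init(nu, e1, e2)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = _theta_to_params_unchecked(theta)
        m1, m2 = debye_model_unchecked(p, nu)
        return np.concatenate([m1 - e1, m2 - e2])

    eps_tiny = 1e-12
    lower = [1.0, 0.0, 0.0, eps_tiny, eps_tiny]
    upper = [np.inf, np.inf, np.inf, np.inf, 1.0 - eps_tiny]
    theta0 = np.clip(theta0, lower, upper)
    sol = least_squares(residuals, theta0, bounds=(lower, upper), method="trf")
    params = _theta_to_params_unchecked(sol.x)
    rss = float(2.0 * sol.cost)
    converged = bool(sol.success)
    stderr = None
    if converged:
        stderr = _parameter_stderr(sol, nu.size)
    # promote to the checked dataclass (degenerate fits can sit on a bound)
    try:
        params = DebyeParams(**params.__dict__)
    except ValueError:
        converged = False
        stderr = None
    return DebyeFitResult(
        params=params, stderr=stderr, rss=rss, converged=converged,
        message=str(sol.message),
    )


@dataclass(frozen=True)
class _LooseParams:
    eps1: float
    eps2: float
    eps_inf: float
    tau1: float
    tau2: float


def _theta_to_params_unchecked(theta: np.ndarray) -> _LooseParams:
    eps_inf, a1, a2, tau1, rho = theta
    return _LooseParams(
        eps1=float(eps_inf + a1 + a2),
        eps2=float(eps_inf + a2),
        eps_inf=float(eps_inf),
        tau1=float(tau1),
        tau2=float(tau1 * rho),
    )


def debye_model_unchecked(params, frequencies):
    nu = np.asarray(frequencies, dtype=float)
    x1 = 2.0 * np.pi * nu * params.tau1
    x2 = 2.0 * np.pi * nu * params.tau2
    a1 = params.eps1 - params.eps2
    a2 = params.eps2 - params.eps_inf
    e_real = params.eps_inf + a1 / (1.0 + x1**2) + a2 / (1.0 + x2**2)
    e_imag = a1 * x1 / (1.0 + x1**2) + a2 * x2 / (1.0 + x2**2)
    return e_real, e_imag


def _parameter_stderr(sol, n_freq: int) -> dict | None:
    m, p = sol.jac.shape
    dof = m - p
    if dof <= 0:
        return None
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov_theta = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return None
    eps_inf, a1, a2, tau1, rho = sol.x
    # natural params g(theta) = (eps1, eps2, eps_inf, tau1, tau2)
    grad = np.array(
        [
            [1.0, 1.0, 1.0, 0.0, 0.0],   # eps1 = eps_inf + a1 + a2
            [1.0, 0.0, 1.0, 0.0, 0.0],   # eps2 = eps_inf + a2
            [1.0, 0.0, 0.0, 0.0, 0.0],   # eps_inf
            [0.0, 0.0, 0.0, 1.0, 0.0],   # tau1
            [0.0, 0.0, 0.0, rho, tau1],  # tau2 = tau1 * rho
        ]
    )
    cov = grad @ cov_theta @ grad.T
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return dict(zip(("eps1", "eps2", "eps_inf", "tau1", "tau2"), sd.tolist()))
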