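"""Closed-form concentration curves for the two structural models.

Both worked examples use single oral dosing with one-compartment
disposition and first-order elimination; they differ only in the
absorption input:

* first-order absorption from a depot compartment (rate constant ``ka``);
* transit-compartment absorption, where the dose passes through a chain
  of ``n`` hypothetical compartments with rate ``ktr = (n + 1)/MTT``
  before reaching the central compartment, producing an Erlang-shaped
  absorption input.

The public functions accept scalars or numpy arrays of times and return
concentrations in amount/L.  The array kernels (``_onecomp_conc``,
``_transit_conc``) broadcast over per-observation parameter arrays and
are what the simulator and estimator call in bulk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "DoseEvent",
    "OneCompFOAParams",
    "TransitAbsParams",
    "conc_onecomp",
    "conc_transit",
]

#: relative |ka - ke| below which the repeated-eigenvalue limit is used
KA_KE_DEGENERACY_RTOL = 1e-8

#: relative (ktr - ke) below which the transit convolution integral is
#: evaluated by Gauss-Legendre quadrature instead of the incomplete-gamma
#: closed form (which requires ktr > ke)
_TRANSIT_GAMMA_RTOL = 1e-6

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


class InvalidParameterError(ValueError):
    """A pharmacokinetic parameter violates its positivity constraint."""


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose: amount (mass units) given at ``time`` (h)."""

    amount: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise InvalidParameterError(f"dose amount must be > 0, got {self.amount}")


@dataclass(frozen=True)
class OneCompFOAParams:
    """One-compartment disposition with first-order absorption.

    Parameters
    ----------
    ka : absorption rate constant (1/h)
    CL : elimination clearance (L/h)
    V : apparent central volume (L)
    F : bioavailability fraction in (0, 1]
    """

    ka: float
    CL: float
    V: float
    F: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ka", "CL", "V", "F"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.F > 1:
            raise InvalidParameterError(f"F must be in (0, 1], got {self.F}")

    @property
    def ke(self) -> float:
        return self.CL / self.V


@dataclass(frozen=True)
class TransitAbsParams:
    """Transit-compartment absorption into one-compartment disposition.

    ``n_transit`` transit compartments feed the central compartment with
    rate ``ktr = (n_transit + 1) / MTT`` where ``MTT`` is the mean
    transit time (h).
    """

    n_transit: int
    MTT: float
    CL: float
    V: float
    F: float = 1.0

    def __post_init__(self) -> None:
        if self.n_transit < 0 or int(self.n_transit) != self.n_transit:
            raise InvalidParameterError(f"n_transit must be a non-negative integer, got {self.n_transit}")
        for name in ("MTT", "CL", "V", "F"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.F > 1:
            raise InvalidParameterError(f"F must be in (0, 1], got {self.F}")

    @property
    def ktr(self) -> float:
        return (self.n_transit + 1) / self.MTT

    @property
    def ke(self) -> float:
        return self.CL / self.V


# ---------------------------------------------------------------------------
# array kernels


def _onecomp_conc_raw(tau, dose_amount, ka, CL, V, F=1.0):
    """Same-shape fast path: tau = t - dose_time, already clipped >= 0."""
    ke = CL / V
    diff = ka - ke
    degenerate = np.abs(diff) < KA_KE_DEGENERACY_RTOL * ke
    safe_diff = np.where(degenerate, 1.0, diff)
    general = (dose_amount * F * ka / (V * safe_diff)
               * np.exp(-ke * tau) * (-np.expm1(-safe_diff * tau)))
    if np.any(degenerate):
        limit = dose_amount * F * ke * tau * np.exp(-ke * tau) / V
        general = np.where(degenerate, limit, general)
    return np.maximum(general, 0.0)


def _transit_conc_raw(tau, dose_amount, n_transit, MTT, CL, V, F=1.0):
    """Same-shape fast path for the transit model (tau clipped >= 0)."""
    n = float(n_transit)
    ktr = (n + 1.0) / MTT
    ke = CL / V
    a = ktr - ke
    use_gamma = a > _TRANSIT_GAMMA_RTOL * ktr
    if np.all(use_gamma):
        return np.maximum(
            F * dose_amount / V * (ktr / a) ** (n + 1.0)
            * np.exp(-ke * tau) * special.gammainc(n + 1.0, a * tau), 0.0)
    tau_b, a_b, ktr_b, ke_b = np.broadcast_arrays(tau, a, ktr, ke)
    out = np.zeros(tau_b.shape)
    if np.any(use_gamma):
        au = np.where(use_gamma, a, 1.0)
        out = np.where(
            use_gamma,
            F * dose_amount / V * (ktr / au) ** (n + 1.0)
            * np.exp(-ke * tau) * special.gammainc(n + 1.0, au * tau),
            out)
    sel = ~np.broadcast_to(use_gamma, tau_b.shape)
    if np.any(sel):
        tau_s, a_s = tau_b[sel], a_b[sel]
        half = tau_s / 2.0
        s = half[..., None] * (_GL_NODES + 1.0)
        integ = half * np.sum(
            _GL_WEIGHTS * np.exp(n * np.log(np.maximum(s, 1e-300)) - a_s[..., None] * s),
            axis=-1)
        integ = np.where(tau_s > 0, integ, 0.0)
        FDV = np.broadcast_to(np.asarray(F * dose_amount / (V * 1.0)), tau_b.shape)[sel]
        out[sel] = (FDV * ktr_b[sel] ** (n + 1.0) / special.gamma(n + 1.0)
                    * np.exp(-ke_b[sel] * tau_s) * integ)
    return np.maximum(out, 0.0)


def _onecomp_conc(t, dose_amount, dose_time, ka, CL, V, F=1.0):
    """Concentration of the first-order-absorption model, broadcast.

    Uses the expm1 form ``F·D·ka/(V·(ka-ke)) · e^{-ke·τ} · (1 - e^{-(ka-ke)·τ})``
    which is numerically stable as ``ka → ke``; exactly at the degeneracy
    the repeated-eigenvalue limit ``F·D·ke·τ·e^{-ke·τ}/V`` is used.
    """
    t, ka, CL, V, F = np.broadcast_arrays(
        np.asarray(t, float), np.asarray(ka, float), np.asarray(CL, float),
        np.asarray(V, float), np.asarray(F, float),
    )
    tau = np.maximum(t - np.asarray(dose_time, float), 0.0)
    return _onecomp_conc_raw(tau, np.asarray(dose_amount, float), ka, CL, V, F)


def _transit_conc(t, dose_amount, dose_time, n_transit, MTT, CL, V, F=1.0):
    """Concentration of the transit-absorption model, broadcast.

    The Erlang(n+1, ktr) absorption input convolved with first-order
    elimination has the closed form::

        C(t) = F·D/V · (ktr/(ktr-ke))^{n+1} · e^{-ke·τ} · P(n+1, (ktr-ke)·τ)

    with ``P`` the regularized lower incomplete gamma function, valid for
    ``ktr > ke``.  Where ``ktr - ke`` is non-positive (or tiny), the
    convolution integral ``∫₀^τ s^n e^{-(ktr-ke)s} ds`` is evaluated by
    64-point Gauss-Legendre quadrature instead.
    """
    t, MTT, CL, V, F = np.broadcast_arrays(
        np.asarray(t, float), np.asarray(MTT, float), np.asarray(CL, float),
        np.asarray(V, float), np.asarray(F, float),
    )
    tau = np.maximum(t - np.asarray(dose_time, float), 0.0)
    return _transit_conc_raw(tau, np.asarray(dose_amount, float), n_transit, MTT, CL, V, F)


# ---------------------------------------------------------------------------
# public scalar/array API


def conc_onecomp(t, dose: DoseEvent, p: OneCompFOAParams):
    """Central concentration at time(s) ``t`` (h) after a single oral dose."""
    return _onecomp_conc(t, dose.amount, dose.time, p.ka, p.CL, p.V, p.F)


def conc_transit(t, dose: DoseEvent, p: TransitAbsParams):
    """Central concentration for the transit-absorption model at ``t`` (h)."""
    return _transit_conc(t, dose.amount, dose.time, p.n_transit, p.MTT, p.CL, p.V, p.F)
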