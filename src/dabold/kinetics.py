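"""Forward kinetic simulation of reversible-tracer TACs.

Ground-truth time-activity curves are produced from a simplified reference
tissue model (SRTM) driven by a bi-exponential plasma surrogate:

* plasma input  ``C_p(t) = a1*exp(-b1*t) + a2*exp(-b2*t)`` (t in minutes),
* reference region (one-tissue): ``dC_ref/dt = K1p*C_p - k2p*C_ref``,
* target region (SRTM):
  ``dC_t/dt = R1*dC_ref/dt + k2*C_ref - k2a*C_t`` with
  ``k2 = R1*k2p`` and ``k2a = k2/(1 + BP_ND)``.

At ``BP_ND = 0`` and ``R1 = 1`` the target ODE collapses onto the reference
ODE, so the two curves coincide exactly — a useful identity for testing.
The curves are integrated on a fine regular grid and reduced to frame values
as interval averages, the quantity a scanner actually reports. This module
is simulation-side only: the estimator (Logan analysis) never sees these
equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidSpecError
from .frames import FrameSchedule

__all__ = ["PlasmaInput", "KineticParams", "simulate_tac", "fine_grid_curves"]


@dataclass(frozen=True)
class PlasmaInput:
    """Bi-exponential plasma surrogate, amplitudes in kBq/mL, rates in 1/min."""

    a1: float = 800.0
    b1: float = 0.8
    a2: float = 90.0
    b2: float = 0.04

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return self.a1 * np.exp(-self.b1 * t) + self.a2 * np.exp(-self.b2 * t)


@dataclass(frozen=True)
class KineticParams:
    """SRTM parameters for one target/reference pair.

    ``k1p_ref`` and ``k2_ref`` (1/min) govern the reference region;
    ``r1`` is the relative delivery K1/K1'; ``bp_nd`` the binding potential.
    Defaults are in the range reported for [11C]raclopride in older adults.
    """

    bp_nd: float = 2.0
    r1: float = 1.0
    k1p_ref: float = 0.10
    k2_ref: float = 0.16


def fine_grid_curves(
    params: KineticParams,
    plasma: PlasmaInput,
    t_end_min: float,
    dt_min: float = 1.0 / 120.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate reference and target ODEs on a fine regular grid.

    Returns ``(t, c_target, c_ref)``. Trapezoid-consistent exponential
    integrators are used: each one-tissue step is the exact solution for a
    linearly interpolated input, so the scheme is stable at any dt and
    second-order accurate.
    """
    if params.bp_nd < 0:
        raise InvalidSpecError("bp_nd must be >= 0")
    n = int(np.ceil(t_end_min / dt_min)) + 1
    t = np.linspace(0.0, (n - 1) * dt_min, n)
    cp = plasma(t)

    c_ref = _one_tissue(cp, t, k_in=params.k1p_ref, k_out=params.k2_ref)

    # SRTM: C_t = R1*C_ref + (k2 - R1*k2a) * (C_ref conv exp(-k2a t))
    k2 = params.r1 * params.k2_ref
    k2a = k2 / (1.0 + params.bp_nd)
    conv = _one_tissue(c_ref, t, k_in=1.0, k_out=k2a)
    c_t = params.r1 * c_ref + (k2 - params.r1 * k2a) * conv
    return t, c_t, c_ref


def _one_tissue(inp: np.ndarray, t: np.ndarray, k_in: float, k_out: float) -> np.ndarray:
    """Solve dC/dt = k_in*inp - k_out*C, C(0)=0, exactly for piecewise-linear inp."""
    dt = t[1] - t[0]
    out = np.zeros_like(inp)
    if k_out * dt < 1e-12:
        # pure integrator
        out[1:] = k_in * np.cumsum((inp[1:] + inp[:-1]) / 2.0) * dt
        return out
    e = np.exp(-k_out * dt)
    # exact update for linear input u(s) = u0 + (u1-u0)*s/dt on each step
    c0 = (1.0 - e) / k_out
    c1 = (dt - c0) / (k_out * dt)  # weight of the slope term
    for i in range(1, len(t)):
        u0, u1 = inp[i - 1], inp[i]
        out[i] = out[i - 1] * e + k_in * (u0 * c0 + (u1 - u0) * c1)
    return out


def _frame_averages(t: np.ndarray, curve: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame interval (trapezoid)."""
    vals = np.empty(schedule.n_frames)
    starts = schedule.frame_starts / 60.0
    ends = schedule.frame_ends / 60.0
    for i, (a, b) in enumerate(zip(starts, ends)):
        grid = np.linspace(a, b, max(int((b - a) / (t[1] - t[0])), 2) + 1)
        vals[i] = np.trapezoid(np.interp(grid, t, curve), grid) / (b - a)
    return vals


def simulate_tac(
    bp_nd: float,
    r1: float,
    k2_ref: float,
    schedule: FrameSchedule,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    plasma: PlasmaInput | None = None,
    k1p_ref: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a (target, reference) frame-value TAC pair.

    Parameters
    ----------
    bp_nd
        True non-displaceable binding potential of the target region.
    r1, k2_ref
        SRTM relative delivery and reference efflux rate (1/min).
    schedule
        Frame timing; frame values are interval averages of the fine curve.
    noise_sd
        SD of additive Gaussian frame noise (kBq/mL); the same draw structure
        for a given seed makes the simulation bit-reproducible.
    """
    if schedule.n_frames == 0:
        raise InvalidSpecError("schedule must contain at least one frame")
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")
    plasma = plasma or PlasmaInput()
    params = KineticParams(bp_nd=bp_nd, r1=r1, k1p_ref=k1p_ref, k2_ref=k2_ref)
    t_end = schedule.total_duration / 60.0
    t, c_t, c_ref = fine_grid_curves(params, plasma, t_end_min=t_end)
    target = _frame_averages(t, c_t, schedule)
    reference = _frame_averages(t, c_ref, schedule)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        target = target + rng.normal(0.0, noise_sd, size=target.shape)
        reference = reference + rng.normal(0.0, noise_sd, size=reference.shape)
    return target, reference
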