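"""GDP/GTP cycling of Gαo: two-state exchange model and its equilibrium.

In the absence of GEFs, GAPs and GDIs the nucleotide state of Gαo follows
the linear two-state system

    d[Gαo·GDP]/dt = k_hydr·[Gαo·GTP] − k_bind·[Gαo·GDP]
    d[Gαo·GTP]/dt = k_bind·[Gαo·GDP] − k_hydr·[Gαo·GTP]

with k_bind and k_hydr the lumped first-order constants fitted from the
BODIPY assays.  Total Gαo is conserved, and the equilibrium GTP/GDP ratio
is k_bind/k_hydr in closed form.  The module integrates the system with a
fixed-step classical Runge–Kutta scheme (reproducible, no adaptive-solver
nondeterminism) and cross-checks the terminal state against the analytic
equilibrium; both routes are exposed.

The assumed cellular context (10 μM Gαo, ~100-fold nucleotide excess over
G protein, ~10-fold free GTP over GDP) is carried in :class:`CyclingConfig`
for provenance.  Because the rate constants are lumped pseudo-first-order
values, the excess parameters do not enter the dynamics; they document the
regime in which treating nucleotide concentrations as constant is valid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .kinetics import FoldChange, KineticParams, KineticsError

__all__ = [
    "CyclingConfig",
    "CyclingState",
    "CyclingTrajectory",
    "simulate_cycle",
    "steady_state_ratio",
    "ratio_fold_change",
]

#: dimensionless stability margin: (k_bind + k_hydr) * dt must stay below this
_MAX_RATE_DT = 0.01
#: hard cap on the number of integration steps after dt auto-shrink
_MAX_STEPS = 50_000_000


@dataclass(frozen=True)
class CyclingConfig:
    """Cellular context of the cycling simulation.

    total_galphao_uM: total Gαo concentration (default 10 μM).
    gtp_gdp_excess / nucleotide_excess_over_g: free-nucleotide regime, stored
    for reporting only (see module docstring).
    fraction_gtp_initial: initial GTP-bound fraction; 0 by default because
    purified Gαo is GDP loaded.
    """

    total_galphao_uM: float = 10.0
    gtp_gdp_excess: float = 10.0
    nucleotide_excess_over_g: float = 100.0
    fraction_gtp_initial: float = 0.0

    def __post_init__(self) -> None:
        if self.total_galphao_uM <= 0:
            raise KineticsError("total Gαo concentration must be > 0")
        if self.gtp_gdp_excess <= 0 or self.nucleotide_excess_over_g <= 0:
            raise KineticsError("nucleotide excess factors must be > 0")
        if not 0.0 <= self.fraction_gtp_initial <= 1.0:
            raise KineticsError("fraction_gtp_initial must lie in [0, 1]")


@dataclass(frozen=True)
class CyclingState:
    """Instantaneous GDP-/GTP-bound Gαo concentrations (μM) at time t (s)."""

    conc_gdp_bound: float
    conc_gtp_bound: float
    time: float

    @property
    def gtp_gdp_ratio(self) -> float:
        """[Gαo·GTP]/[Gαo·GDP]; +inf sentinel when nothing is GDP-bound."""
        if self.conc_gdp_bound == 0.0:
            return math.inf
        return self.conc_gtp_bound / self.conc_gdp_bound


@dataclass(frozen=True)
class CyclingTrajectory:
    times: np.ndarray
    conc_gdp: np.ndarray
    conc_gtp: np.ndarray
    reached_equilibrium: bool
    dt: float

    @property
    def final_state(self) -> CyclingState:
        return CyclingState(
            conc_gdp_bound=float(self.conc_gdp[-1]),
            conc_gtp_bound=float(self.conc_gtp[-1]),
            time=float(self.times[-1]),
        )

    @property
    def terminal_ratio(self) -> float:
        return self.final_state.gtp_gdp_ratio

    def states(self):
        for t, gdp, gtp in zip(self.times, self.conc_gdp, self.conc_gtp):
            yield CyclingState(float(gdp), float(gtp), float(t))


def simulate_cycle(
    params: KineticParams,
    config: Optional[CyclingConfig] = None,
    t_end: Optional[float] = None,
    dt: Optional[float] = None,
    record_every: int = 1,
    equilibrium_rtol: float = 1e-12,
) -> CyclingTrajectory:
    """Integrate the two-state cycle with fixed-step classical RK4.

    ``dt`` is shrunk automatically until (k_bind + k_hydr)·dt ≤ 0.01; the
    default ``t_end`` is 30/(k_bind + k_hydr), by which the slowest mode has
    decayed to ~1e−13 of its initial weight.  Integration stops early once
    the relative per-step change falls below ``equilibrium_rtol``.  States
    are recorded every ``record_every`` steps (the final state always is).
    """
    config = config or CyclingConfig()
    rate_sum = params.k_bind + params.k_hydr
    if t_end is None:
        t_end = 30.0 / rate_sum
    if t_end <= 0:
        raise KineticsError("t_end must be > 0")
    if dt is None:
        dt = _MAX_RATE_DT / rate_sum
    if dt <= 0:
        raise KineticsError("dt must be > 0")
    while rate_sum * dt > _MAX_RATE_DT:
        dt /= 2.0
    n_steps = int(math.ceil(t_end / dt))
    if n_steps > _MAX_STEPS:
        raise KineticsError(
            f"integration would need {n_steps} steps after dt auto-shrink; "
            "raise dt or lower t_end"
        )
    if record_every < 1:
        raise KineticsError("record_every must be >= 1")

    total = config.total_galphao_uM
    gtp = total * config.fraction_gtp_initial
    gdp = total - gtp
    kb, kh = params.k_bind, params.k_hydr

    def deriv(gdp_c: float, gtp_c: float) -> tuple[float, float]:
        flux = kb * gdp_c - kh * gtp_c  # net GDP -> GTP conversion
        return -flux, flux

    times = [0.0]
    gdp_rec = [gdp]
    gtp_rec = [gtp]
    reached = False
    t = 0.0
    for step in range(1, n_steps + 1):
        h = min(dt, t_end - t)
        d1g, d1t = deriv(gdp, gtp)
        d2g, d2t = deriv(gdp + 0.5 * h * d1g, gtp + 0.5 * h * d1t)
        d3g, d3t = deriv(gdp + 0.5 * h * d2g, gtp + 0.5 * h * d2t)
        d4g, d4t = deriv(gdp + h * d3g, gtp + h * d3t)
        new_gdp = gdp + (h / 6.0) * (d1g + 2 * d2g + 2 * d3g + d4g)
        new_gtp = gtp + (h / 6.0) * (d1t + 2 * d2t + 2 * d3t + d4t)
        t += h
        change = abs(new_gdp - gdp) + abs(new_gtp - gtp)
        gdp, gtp = new_gdp, new_gtp
        if step % record_every == 0 or t >= t_end:
            times.append(t)
            gdp_rec.append(gdp)
            gtp_rec.append(gtp)
        if change <= equilibrium_rtol * total:
            reached = True
            if times[-1] != t:
                times.append(t)
                gdp_rec.append(gdp)
                gtp_rec.append(gtp)
            break
        if t >= t_end:
            break
    if kh == 0.0 and reached:
        # absorbing all-GTP state: snap the converged tail (~1e-12 of the
        # pool) to the exact equilibrium so the ratio reports the sentinel
        gdp_rec[-1], gtp_rec[-1] = 0.0, total
    return CyclingTrajectory(
        times=np.asarray(times),
        conc_gdp=np.asarray(gdp_rec),
        conc_gtp=np.asarray(gtp_rec),
        reached_equilibrium=reached,
        dt=dt,
    )


def steady_state_ratio(params: KineticParams) -> float:
    """Analytic equilibrium [Gαo·GTP]/[Gαo·GDP] = k_bind/k_hydr.

    The GTPase-dead limit k_hydr = 0 is an absorbing all-GTP state; it is
    reported as the +inf sentinel with a warning rather than an overflow.
    """
    if params.k_hydr == 0.0:
        warnings.warn(
            "k_hydr = 0: all Gαo ends GTP-bound, GTP/GDP ratio is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return params.k_bind / params.k_hydr


def ratio_fold_change(mutant: KineticParams, wildtype: KineticParams) -> FoldChange:
    """Fold-change of the equilibrium GTP/GDP ratio, mutant versus wild type.

    Ratios below 1 are reported as a fold-decrease (reciprocal) with the
    direction flag; an infinite mutant ratio (k_hydr = 0) propagates as an
    infinite fold-increase.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r_mut = steady_state_ratio(mutant)
        r_wt = steady_state_ratio(wildtype)
    if math.isinf(r_wt):
        raise KineticsError("wild-type reference has k_hydr = 0 (infinite ratio)")
    if math.isinf(r_mut):
        return FoldChange(factor=math.inf, direction="increase", ratio=math.inf)
    ratio = r_mut / r_wt
    if ratio > 1.0:
        return FoldChange(factor=ratio, direction="increase", ratio=ratio)
    if ratio < 1.0:
        return FoldChange(factor=r_wt / r_mut, direction="decrease", ratio=ratio)
    return FoldChange(factor=1.0, direction="none", ratio=1.0)
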