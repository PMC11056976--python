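"""Free-energy estimation: BAR over λ-windows, log P, and density PMFs.

The Bennett acceptance ratio (BAR) estimator combines forward energy
differences ΔU_f = U_{i+1} − U_i sampled in state i with reverse
differences ΔU_r = U_i − U_{i+1} sampled in state i+1.  ΔG solves the
self-consistent condition that the two Fermi-function averages agree,

    Σ_f 1/(1 + exp(M + βΔU_f − βΔG)) = Σ_r 1/(1 + exp(−M + βΔU_r + βΔG)),

with M = ln(n_f/n_r); the left side is monotone increasing and the
right side monotone decreasing in ΔG, so the root is unique and is
found by bracketed root search in reduced (kT) units to 1e-8 kT.

The octanol/water partition coefficient follows from removal free
energies: log P = (ΔG_solvation − ΔG_hydration)/(RT ln 10), with
ΔG_hydration the cost of removing the solute from water and
ΔG_solvation the cost of removing it from octanol.  A solute costlier
to remove from water (hydrophilic) gets log P < 0.

The water potential of mean force is the Boltzmann inversion of the
water density profile, PMF(z) = −kT ln(ρ(z)/ρ_bulk); bins with zero
density are flagged undefined rather than reported as infinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .density import DensityProfile
from .units import GAS_CONSTANT_KJ, LN10

__all__ = [
    "FEWindowSamples",
    "FreeEnergyResult",
    "bar_delta_g",
    "chain_windows",
    "log_p",
    "pmf_from_density",
]


@dataclass
class FEWindowSamples:
    """Forward/reverse energy-difference samples for one λ-window.

    Energies in kJ/mol; ``lambda_coulomb`` / ``lambda_vdw`` record the
    coupling-parameter values of the window endpoints when known (the
    estimator itself does not use them).
    """

    window_index: int
    forward: np.ndarray
    reverse: np.ndarray
    temperature: float
    lambda_coulomb: tuple[float, float] | None = None
    lambda_vdw: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.forward = np.atleast_1d(np.asarray(self.forward, dtype=float))
        self.reverse = np.atleast_1d(np.asarray(self.reverse, dtype=float))
        if self.forward.size == 0 or self.reverse.size == 0:
            raise ValueError("both sample sets must be non-empty")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class FreeEnergyResult:
    """Total ΔG ± SE (kJ/mol) with per-window contributions."""

    dG: float
    stderr: float
    temperature: float
    per_window: pd.DataFrame = field(default_factory=pd.DataFrame)


class OverlapError(RuntimeError):
    """Forward and reverse work distributions do not overlap."""


def _bar_reduced(wf: np.ndarray, wr: np.ndarray, tol: float = 1e-8
                 ) -> tuple[float, float]:
    """Solve the Bennett equation in reduced units; return (dG, se)."""
    n_f, n_r = len(wf), len(wr)
    M = np.log(n_f / n_r)

    def imbalance(dg: float) -> float:
        lhs = expit(-(M + wf - dg)).sum()   # Fermi f(x)=1/(1+e^x)
        rhs = expit(-(-M + wr + dg)).sum()
        return lhs - rhs

    lo = min(-wr.max(), wf.min()) - 10.0
    hi = max(wf.max(), -wr.min()) + 10.0
    f_lo, f_hi = imbalance(lo), imbalance(hi)
    if f_lo == 0.0 and f_hi == 0.0:
        raise OverlapError(
            "no overlap between forward and reverse work distributions: "
            f"forward in [{wf.min():.2f}, {wf.max():.2f}] kT, "
            f"reverse in [{wr.min():.2f}, {wr.max():.2f}] kT"
        )
    if f_lo * f_hi > 0:
        # expand the bracket; the imbalance is monotone increasing in dg
        span = hi - lo
        for _ in range(60):
            lo -= span
            hi += span
            f_lo, f_hi = imbalance(lo), imbalance(hi)
            if f_lo * f_hi <= 0:
                break
        else:
            raise OverlapError("could not bracket the BAR root")
    dg = brentq(imbalance, lo, hi, xtol=tol)

    # Bennett asymptotic variance from the Fermi-weighted averages
    ff = expit(-(M + wf - dg))
    fr = expit(-(-M + wr + dg))
    if ff.sum() < 1e-10 or fr.sum() < 1e-10:
        gap = wf.min() - (-wr).max()
        raise OverlapError(
            "forward and reverse work distributions do not overlap "
            f"(gap ≈ {gap:.1f} kT between the forward support and the "
            "negated reverse support); the self-consistent equation is "
            "degenerate"
        )
    var = (np.mean(ff ** 2) / np.mean(ff) ** 2 - 1.0) / n_f \
        + (np.mean(fr ** 2) / np.mean(fr) ** 2 - 1.0) / n_r
    return float(dg), float(np.sqrt(max(var, 0.0)))


def bar_delta_g(window: FEWindowSamples) -> FreeEnergyResult:
    """BAR free-energy difference for one window (kJ/mol)."""
    if len(window.forward) < 2 or len(window.reverse) < 2:
        raise ValueError("need at least 2 samples in each direction")
    kt = GAS_CONSTANT_KJ * window.temperature
    dg_red, se_red = _bar_reduced(window.forward / kt, window.reverse / kt)
    per = pd.DataFrame([{
        "window": window.window_index,
        "dG_kJ_per_mol": dg_red * kt,
        "stderr_kJ_per_mol": se_red * kt,
        "n_forward": len(window.forward),
        "n_reverse": len(window.reverse),
    }])
    return FreeEnergyResult(dG=dg_red * kt, stderr=se_red * kt,
                            temperature=window.temperature, per_window=per)


def chain_windows(windows: list[FEWindowSamples]) -> FreeEnergyResult:
    """Total ΔG over an ordered λ-window schedule.

    Window estimates add; variances add (windows are independent
    simulations).  All windows must share one temperature.
    """
    if not windows:
        raise ValueError("no windows given")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError(f"temperature mismatch across windows: {sorted(temps)}")
    results = [bar_delta_g(w) for w in windows]
    per = pd.concat([r.per_window for r in results], ignore_index=True)
    total = float(sum(r.dG for r in results))
    var = float(sum(r.stderr ** 2 for r in results))
    return FreeEnergyResult(dG=total, stderr=float(np.sqrt(var)),
                            temperature=windows[0].temperature, per_window=per)


def log_p(dG_hydration: float, dG_solvation: float, T: float = 298.15) -> float:
    """Octanol/water log P from removal free energies (kJ/mol)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if not (np.isfinite(dG_hydration) and np.isfinite(dG_solvation)):
        raise ValueError("free energies must be finite")
    return float((dG_solvation - dG_hydration) / (GAS_CONSTANT_KJ * T * LN10))


def pmf_from_density(
    profile: DensityProfile, rho_bulk: float, T: float = 305.0
) -> pd.DataFrame:
    """Boltzmann-inverted PMF of a density profile.

    Returns a DataFrame with columns ``z_nm``, ``pmf_kJ_per_mol`` and
    ``defined``; bins with zero density carry ``defined = False`` and a
    NaN PMF (the profile is undefined where the species never visits).
    """
    if rho_bulk <= 0:
        raise ValueError("rho_bulk must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    rho = profile.density
    defined = rho > 0
    pmf = np.full_like(rho, np.nan)
    kt = GAS_CONSTANT_KJ * T
    pmf[defined] = -kt * np.log(rho[defined] / rho_bulk)
    return pd.DataFrame({
        "z_nm": profile.bin_centers,
        "pmf_kJ_per_mol": pmf,
        "defined": defined,
    })
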