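"""Poisson linear-quadratic tumor control probability.

The number of clonogens surviving treatment is modelled as Poisson with
mean  sum_i rho * v_i * SF_i  over DVH bins, where the LQ surviving
fraction after total dose D_i in N fractions of d_i = D_i / N is

    SF_i = exp( -alpha * D_i * (1 + d_i / (alpha/beta)) ).

TCP is the probability of zero survivors:

    TCP = exp( - sum_i rho * v_i * SF_i )
        = prod_i exp( - rho * v_i * SF_i ).

Fractionation enters directly through the LQ exponent, so the target DVH
is used as physical dose (no separate EQD2 pass).  Clonogens are assumed
uniformly distributed at density rho (cells/cm^3) over the absolute
structure volume; the expected-survivor sum is accumulated from
log-space per-bin survival exponents for numerical robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dvh import CumulativeDVH, resample, to_differential

__all__ = ["TCPParams", "poisson_tcp", "tcp_from_bins", "tcp_dose_response"]


@dataclass(frozen=True)
class TCPParams:
    """Radiosensitivity and clonogen parameters for the Poisson-LQ model.

    alpha : intrinsic radiosensitivity (Gy^-1)
    alpha_beta : LQ fractionation sensitivity of the tumor (Gy)
    clonogen_density : clonogenic cell density (cells/cm^3)
    n_fractions : fraction count of the plan
    """

    alpha: float = 0.33
    alpha_beta: float = 10.0
    clonogen_density: float = 1e7
    n_fractions: int = 33

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha_beta <= 0:
            raise ValueError("alpha and alpha_beta must be > 0")
        if self.clonogen_density < 0:
            raise ValueError("clonogen_density must be >= 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")


def survivors_from_bins(bin_dose, bin_volume, params: TCPParams) -> float:
    """Mean number of surviving clonogens, sum_i rho v_i SF_i."""
    d = np.asarray(bin_dose, dtype=float)
    v = np.asarray(bin_volume, dtype=float)
    mask = v > 0
    d, v = d[mask], v[mask]
    if params.clonogen_density == 0 or d.size == 0:
        return 0.0
    frac_dose = d / params.n_fractions
    log_sf = -params.alpha * d * (1.0 + frac_dose / params.alpha_beta)
    # survivors per bin: exp(log(rho v_i) + log SF_i), summed in one pass
    log_terms = np.log(params.clonogen_density * v) + log_sf
    return float(np.exp(log_terms).sum())


def tcp_from_bins(bin_dose, bin_volume, params: TCPParams) -> float:
    """Poisson-LQ TCP of explicit (dose, absolute volume) bins."""
    return float(np.exp(-survivors_from_bins(bin_dose, bin_volume, params)))


def expected_survivors(dvh: CumulativeDVH, params: TCPParams) -> float:
    """Survivor sum of a cumulative DVH after internal resampling."""
    diff = to_differential(resample(dvh))
    return survivors_from_bins(diff.bin_dose, diff.bin_volume, params)


def poisson_tcp(dvh: CumulativeDVH, params: TCPParams) -> float:
    """Tumor control probability of a physical target DVH, in [0, 1]."""
    if dvh.total_volume <= 0:
        raise ValueError("TCP requires absolute volumes (positive total_volume)")
    return float(np.exp(-expected_survivors(dvh, params)))


def tcp_dose_response(
    dvh: CumulativeDVH, params: TCPParams, scale_grid
) -> list[tuple[float, float]]:
    """TCP on uniformly dose-scaled copies of ``dvh``.

    Returns (scale, TCP) pairs; TCP is non-decreasing in the scale
    factor, which makes this the substrate for dose-response and
    sensitivity plots (e.g. delta-TCP versus delta-D95%).
    """
    out = []
    for s in scale_grid:
        if s < 0:
            raise ValueError("scale factors must be >= 0")
        out.append((float(s), poisson_tcp(dvh.scaled(float(s)), params)))
    return out
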