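"""EQD2 (LQED2) fractionation correction of cumulative DVHs.

Under the linear-quadratic model, a total dose D delivered in N equal
fractions of d = D/N is isoeffective with the dose

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)

delivered at the 2 Gy/fraction reference.  Applying this per dose bin
("LQED2 of the DVH") converts a physical cumulative DVH into a 2
Gy/fraction equivalent one; volumes are unchanged and the map is
strictly monotone in D for alpha/beta > 0, so the output is again a
valid cumulative curve.

In a simultaneous-integrated-boost plan every structure is irradiated in
the same N fractions with spatially varying fraction size, so the
per-bin fraction dose is taken as D/N with N the plan's fraction count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dvh import CumulativeDVH

__all__ = ["FractionationParams", "eqd2", "eqd2_transform"]

REFERENCE_DOSE_PER_FRACTION = 2.0  # Gy


@dataclass(frozen=True)
class FractionationParams:
    """LQ fractionation parameters: tissue alpha/beta (Gy) and fraction count."""

    alpha_beta: float = 3.0
    n_fractions: int = 33

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be > 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")


def eqd2(total_dose, alpha_beta: float, n_fractions: int):
    """EQD2 of a total dose delivered in ``n_fractions`` equal fractions."""
    d = np.asarray(total_dose, dtype=float) / n_fractions
    out = np.asarray(total_dose, dtype=float) * (d + alpha_beta) / (REFERENCE_DOSE_PER_FRACTION + alpha_beta)
    return out if out.ndim else float(out)


def eqd2_transform(dvh: CumulativeDVH, params: FractionationParams) -> CumulativeDVH:
    """Map every dose edge of ``dvh`` to its EQD2; volumes unchanged."""
    edges = eqd2(dvh.dose_edges, params.alpha_beta, params.n_fractions)
    return CumulativeDVH(
        dvh.structure_label,
        np.asarray(edges),
        dvh.volume.copy(),
        dvh.total_volume,
        dvh.n_fractions,
    )
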