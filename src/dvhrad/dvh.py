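"""Cumulative and differential dose-volume histograms.

A cumulative DVH gives, for each dose level D, the structure volume
receiving at least D.  It is the universal input object of this package:
every dose metric (D95%, D2%, Dmean), every NTCP model and the TCP model
consume either the cumulative curve or its differential form.

Conventions
-----------
* Dose bins are half-open ``[edge_i, edge_{i+1})``; the cumulative volume
  is defined at the left edges, so ``volume[i]`` is the volume receiving
  at least ``dose_edges[i]``.
* Volumes are stored in absolute cm^3.  Files may declare volumes in
  percent of the total; the reader converts on input.
* The differential representation places each bin's volume at the
  midpoint of the adjacent edges; residual volume at the last edge (a
  curve that does not reach zero) becomes a terminal bin at that edge.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CumulativeDVH",
    "DifferentialDVH",
    "DVHParseError",
    "DVHValidationError",
    "read_dvh_file",
    "write_dvh_file",
    "to_differential",
    "dose_at_volume",
    "mean_dose",
    "resample",
]

#: Internal resampling resolution (Gy) applied before model evaluation,
#: comparable to the export resolution of clinical planning systems.
DEFAULT_BIN_WIDTH_GY = 0.05


class DVHParseError(ValueError):
    """Malformed DVH file."""


class DVHValidationError(ValueError):
    """A curve violating the cumulative-DVH invariants."""


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH of one structure.

    Parameters
    ----------
    structure_label : str
        Name of the contoured structure (e.g. ``"ptv1"``, ``"spinal_cord"``).
    dose_edges : ndarray
        Strictly increasing dose grid in Gy, starting at 0.
    volume : ndarray
        Absolute volume (cm^3) receiving at least each dose edge;
        non-increasing, ``volume[0] == total_volume``.
    total_volume : float
        Structure volume in cm^3.
    n_fractions : int
        Number of fractions the plan delivers the dose in.
    """

    structure_label: str
    dose_edges: np.ndarray
    volume: np.ndarray
    total_volume: float
    n_fractions: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_edges", np.asarray(self.dose_edges, dtype=float))
        object.__setattr__(self, "volume", np.asarray(self.volume, dtype=float))
        d, v = self.dose_edges, self.volume
        lbl = self.structure_label
        if d.ndim != 1 or v.ndim != 1 or d.size != v.size or d.size < 2:
            raise DVHValidationError(f"{lbl}: dose and volume must be 1-D arrays of equal length >= 2")
        if d[0] < 0 or np.any(np.diff(d) <= 0):
            raise DVHValidationError(f"{lbl}: dose_edges must be strictly increasing and >= 0")
        if d[0] != 0.0:
            raise DVHValidationError(f"{lbl}: dose grid must start at 0 Gy")
        if np.any(v < 0):
            raise DVHValidationError(f"{lbl}: negative volume")
        if np.any(np.diff(v) > 1e-9 * max(self.total_volume, 1.0)):
            raise DVHValidationError(f"{lbl}: cumulative volume must be non-increasing")
        if self.total_volume <= 0:
            raise DVHValidationError(f"{lbl}: total_volume must be positive")
        if abs(v[0] - self.total_volume) > 1e-9 * self.total_volume:
            raise DVHValidationError(
                f"{lbl}: volume at 0 Gy ({v[0]:g}) does not equal total_volume ({self.total_volume:g})"
            )
        if not (isinstance(self.n_fractions, (int, np.integer)) and self.n_fractions >= 1):
            raise DVHValidationError(f"{lbl}: n_fractions must be a positive integer")

    @property
    def max_dose(self) -> float:
        """Largest dose edge with non-negligible volume (Gy)."""
        nz = np.nonzero(self.volume > 1e-12 * self.total_volume)[0]
        return float(self.dose_edges[nz[-1]]) if nz.size else 0.0

    def scaled(self, factor: float) -> "CumulativeDVH":
        """Return the DVH with all doses multiplied by ``factor`` > 0."""
        if factor < 0:
            raise ValueError("dose scale factor must be >= 0")
        if factor == 0:
            edges = np.array([0.0, self.dose_edges[-1] if self.dose_edges[-1] > 0 else 1.0])
            vol = np.array([self.total_volume, 0.0])
            return CumulativeDVH(self.structure_label, edges, vol, self.total_volume, self.n_fractions)
        return CumulativeDVH(
            self.structure_label,
            self.dose_edges * factor,
            self.volume.copy(),
            self.total_volume,
            self.n_fractions,
        )


@dataclass(frozen=True)
class DifferentialDVH:
    """Per-bin (dose, volume) pairs derived from a cumulative DVH."""

    structure_label: str
    bin_dose: np.ndarray
    bin_volume: np.ndarray
    n_fractions: int
    total_volume: float = field(default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_dose", np.asarray(self.bin_dose, dtype=float))
        object.__setattr__(self, "bin_volume", np.asarray(self.bin_volume, dtype=float))
        if np.any(self.bin_volume < -1e-12):
            raise DVHValidationError(f"{self.structure_label}: negative differential bin volume")
        if self.total_volume == 0.0:
            object.__setattr__(self, "total_volume", float(self.bin_volume.sum()))


def to_differential(dvh: CumulativeDVH) -> DifferentialDVH:
    """Differentiate a cumulative DVH.

    ``bin_volume[i] = volume[i] - volume[i+1]`` with the representative
    dose at the interval midpoint.  Residual volume at the final edge is
    kept as a terminal bin at that edge so that total volume is conserved.
    """
    dv = -np.diff(dvh.volume)
    dv[np.abs(dv) < 1e-15] = 0.0
    mid = 0.5 * (dvh.dose_edges[:-1] + dvh.dose_edges[1:])
    if dvh.volume[-1] > 1e-12 * dvh.total_volume:
        mid = np.append(mid, dvh.dose_edges[-1])
        dv = np.append(dv, dvh.volume[-1])
    return DifferentialDVH(dvh.structure_label, mid, dv, dvh.n_fractions, dvh.total_volume)


def dose_at_volume(dvh: CumulativeDVH, volume_fraction: float) -> float:
    """Dose (Gy) above which ``volume_fraction`` of the structure lies.

    D95% = ``dose_at_volume(dvh, 0.95)``; D2% = ``dose_at_volume(dvh, 0.02)``.
    Linear interpolation of dose against cumulative volume; on plateaus
    (several doses sharing a volume) the highest such dose is returned,
    so the uniform-dose limit gives the plateau dose.
    """
    if not 0.0 < volume_fraction <= 1.0:
        raise ValueError("volume_fraction must be in (0, 1]")
    target = volume_fraction * dvh.total_volume
    v = dvh.volume
    d = dvh.dose_edges
    if target > v[0] + 1e-9 * dvh.total_volume:
        raise ValueError("requested volume exceeds total volume")
    # index of last point with volume >= target
    ge = np.nonzero(v >= target - 1e-12 * dvh.total_volume)[0]
    i = ge[-1]
    if i == v.size - 1 or v[i] <= target + 1e-12 * dvh.total_volume:
        return float(d[i])
    # interpolate between (d[i], v[i]) and (d[i+1], v[i+1]), v strictly drops here
    frac = (v[i] - target) / (v[i] - v[i + 1])
    return float(d[i] + frac * (d[i + 1] - d[i]))


def mean_dose(dvh: CumulativeDVH) -> float:
    """Volume-weighted mean dose in Gy: sum(D_i v_i) / sum(v_i)."""
    diff = to_differential(dvh)
    vtot = diff.bin_volume.sum()
    if vtot <= 0:
        raise ValueError(f"{dvh.structure_label}: zero total volume")
    return float(np.dot(diff.bin_dose, diff.bin_volume) / vtot)


def resample(dvh: CumulativeDVH, bin_width: float = DEFAULT_BIN_WIDTH_GY) -> CumulativeDVH:
    """Resample the cumulative curve onto a uniform dose grid.

    Applied before model evaluation so that gEUD/TCP integrals are
    insensitive to the input file's binning.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = max(dvh.dose_edges[-1], bin_width)
    n = int(np.ceil(top / bin_width)) + 1
    edges = np.arange(n + 1) * bin_width
    vol = np.interp(edges, dvh.dose_edges, dvh.volume, right=dvh.volume[-1])
    vol = np.minimum.accumulate(vol)  # guard against fp noise
    return CumulativeDVH(dvh.structure_label, edges, vol, dvh.total_volume, dvh.n_fractions)


# ---------------------------------------------------------------------------
# DVH-CSV dialect
#
# UTF-8; '#' comment lines; one `volume_unit,<cc|percent>` header line;
# per-structure block header
#   structure,<label>,total_volume_cc,<float>,n_fractions,<int>
# followed by `dose_gy,volume` rows.  The writer emits doses with 4
# decimals and volumes with 6, in cc.
# ---------------------------------------------------------------------------


def read_dvh_file(path: str | Path) -> dict[str, CumulativeDVH]:
    """Read a DVH-CSV file into cumulative DVHs keyed by structure label."""
    path = Path(path)
    structures: dict[str, CumulativeDVH] = {}
    unit: str | None = None
    label = None
    total = n_frac = None
    doses: list[float] = []
    vols: list[float] = []

    def flush(lineno: int) -> None:
        if label is None:
            return
        if not doses:
            raise DVHParseError(f"{path}:{lineno}: structure '{label}' has no dose rows")
        v = np.asarray(vols)
        if unit == "percent":
            v = v * total / 100.0
        try:
            structures[label] = CumulativeDVH(label, np.asarray(doses), v, total, n_frac)
        except DVHValidationError as exc:
            raise DVHValidationError(f"{path}: {exc}") from exc

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0] == "volume_unit":
                if len(parts) != 2 or parts[1] not in ("cc", "percent"):
                    raise DVHParseError(f"{path}:{lineno}: volume_unit must be 'cc' or 'percent'")
                unit = parts[1]
            elif parts[0] == "structure":
                flush(lineno)
                if len(parts) != 6 or parts[2] != "total_volume_cc" or parts[4] != "n_fractions":
                    raise DVHParseError(
                        f"{path}:{lineno}: malformed structure header (expected "
                        f"'structure,<label>,total_volume_cc,<float>,n_fractions,<int>')"
                    )
                label = parts[1]
                try:
                    total = float(parts[3])
                    n_frac = int(parts[5])
                except ValueError as exc:
                    raise DVHParseError(f"{path}:{lineno}: {exc}") from exc
                doses, vols = [], []
            elif parts[0] == "dose_gy":
                continue  # column header row
            else:
                if label is None or unit is None:
                    raise DVHParseError(f"{path}:{lineno}: data row before structure/volume_unit header")
                if len(parts) != 2:
                    raise DVHParseError(f"{path}:{lineno}: expected 'dose,volume' row")
                try:
                    doses.append(float(parts[0]))
                    vols.append(float(parts[1]))
                except ValueError as exc:
                    raise DVHParseError(f"{path}:{lineno}: {exc}") from exc
        flush(lineno if "lineno" in locals() else 0)
    return structures


def write_dvh_file(path: str | Path, dvhs: dict[str, CumulativeDVH] | list[CumulativeDVH]) -> Path:
    """Write cumulative DVHs in the DVH-CSV dialect (volumes in cc)."""
    if isinstance(dvhs, dict):
        dvhs = list(dvhs.values())
    path = Path(path)
    buf = io.StringIO()
    buf.write("# dvhrad DVH-CSV\nvolume_unit,cc\n")
    for dvh in dvhs:
        buf.write(
            f"structure,{dvh.structure_label},total_volume_cc,{dvh.total_volume:.6f},"
            f"n_fractions,{dvh.n_fractions}\n"
        )
        buf.write("dose_gy,volume\n")
        for d, v in zip(dvh.dose_edges, dvh.volume):
            buf.write(f"{d:.4f},{v:.6f}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path
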