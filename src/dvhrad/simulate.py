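"""Synthetic paired-plan cohorts for nasopharyngeal-carcinoma SIB plans.

No public DVH data exist for the kind of cohort this package analyses,
so this module generates one: per patient, a structure set of three
nested targets (prescriptions 69.96 / 59.40 / 54.45 Gy in 33 fractions)
and nine organs at risk, each with a smooth, monotone cumulative DVH,
plus a second arm in which every structure's dose axis is contracted by
a small sampled percentage — the DVH-level signature of recalculating a
plan with a more accurate dose algorithm at fixed monitor units.

Curve family
------------
Cumulative curves are built from an asymmetric logistic survival
(location mu, separate low/high-side widths), truncated at a hard
maximum dose and renormalized so V(0) = V_total.  The high-risk target
additionally mixes in a small cold tail — an absolute ~1-2.4 cm^3 of
volume spread linearly down to ~41.5-44 Gy — emulating underdosage at
bone/air interfaces; those few cold cm^3 are what give Poisson-LQ TCP
values in the clinically reported 75-90% range rather than ~100%.

Arm-B shift model
-----------------
Per structure the contraction delta(D) (in %) is constant for OARs and,
for targets, affine through the (D95%, D2%) anchors across the falloff,
flat above D2% and tapering quadratically below D95%, so a single
recalculated dose shifts all metrics coherently.  Default medians and
spreads follow the reported
per-structure reductions (e.g. high-risk target D95% median 1.5%,
range 0.1-4.0%; mandible mean dose ~3.4%, pharyngeal constrictor
~0.95%).  A shared per-patient latent severity couples shift size and
cold-tail depth: anatomies with more bone interface show both a deeper
cold tail and a larger recalculation shift.

Randomness: one root seed; per-patient and per-structure substreams
derived via ``SeedSequence(seed, spawn_key=...)`` so that adding a
patient never perturbs earlier patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import PatientPlanPair
from .dvh import CumulativeDVH, dose_at_volume, write_dvh_file

__all__ = [
    "StructureTemplate",
    "AlgorithmShiftModel",
    "default_templates",
    "generate_cohort",
    "write_cohort",
]

N_FRACTIONS = 33
GRID_GY = 0.05


@dataclass(frozen=True)
class StructureTemplate:
    """Sampling ranges for one structure's cumulative-curve family.

    ``mu`` is the falloff midpoint (Gy), ``w_lo``/``w_hi`` the logistic
    widths below/above it, ``cap`` the hard maximum dose.  Targets may
    carry a cold-tail volume in cm^3 (see module docstring).
    """

    label: str
    role: str  # "target" | "serial-oar" | "parallel-oar"
    volume: tuple[float, float]  # cm^3, uniform sampling range
    mu: tuple[float, float]  # (mean, sd) normal sampling
    mu_clip: tuple[float, float]
    w_lo: tuple[float, float]  # uniform range
    w_hi: tuple[float, float]
    cap: tuple[float, float]
    cold_volume: tuple[float, float] = (0.0, 0.0)  # absolute cm^3
    cold_floor: tuple[float, float] = (0.0, 0.0)


def default_templates() -> dict[str, StructureTemplate]:
    """Structure set of a nasopharynx SIB plan (3 targets + 9 OARs).

    Falloff locations/widths are chosen so the cohort's recomputed
    D95%/D2%/Dmean medians and ranges land near the reported clinical
    values (e.g. high-risk target D95 ~66.8 Gy, mandible Dmean ~47 Gy,
    cord D2 ~38 Gy with maximum dose kept below 46 Gy).
    """
    t = {}

    def add(label, role, volume, mu, mu_clip, w_lo, w_hi, cap, cold_volume=(0, 0), cold_floor=(0, 0)):
        t[label] = StructureTemplate(label, role, volume, mu, mu_clip, w_lo, w_hi, cap, cold_volume, cold_floor)

    add("ptv1", "target", (120, 280), (71.0, 0.5), (69.5, 72.5), (1.2, 1.7), (0.35, 0.55),
        (73.2, 74.0), cold_volume=(1.0, 2.4), cold_floor=(41.5, 44.0))
    add("ptv2", "target", (200, 450), (60.8, 2.5), (55.0, 67.0), (0.7, 1.1), (1.1, 1.6), (69.0, 71.0))
    add("ptv3", "target", (300, 600), (55.2, 1.6), (52.0, 61.0), (0.7, 1.0), (0.9, 1.2), (68.0, 71.5))
    add("larynx", "parallel-oar", (20, 45), (44.5, 6.5), (33.5, 62.0), (8, 14), (5, 9), (64, 72))
    add("mandible", "serial-oar", (50, 90), (50.0, 6.5), (28.0, 58.0), (10, 14), (5.0, 6.3), (71.5, 73.5))
    add("parotid_l", "parallel-oar", (15, 35), (28.0, 6.0), (18.0, 48.0), (6, 10), (7, 12), (55, 70))
    add("parotid_r", "parallel-oar", (15, 35), (28.0, 6.0), (18.0, 48.0), (6, 10), (7, 12), (55, 70))
    add("pcm_superior", "parallel-oar", (6, 14), (65.5, 3.5), (49.0, 68.5), (4, 7), (1.5, 3), (68.5, 71.5))
    add("spinal_cord", "serial-oar", (20, 40), (29.5, 3.3), (19.5, 34.0), (5, 8), (1.8, 2.5), (40.0, 45.0))
    add("supraglottic_larynx", "parallel-oar", (4, 10), (46.0, 7.0), (35.0, 68.0), (7, 11), (6, 10), (68, 72))
    add("thyroid", "parallel-oar", (8, 25), (55.0, 6.0), (38.5, 64.0), (6, 9), (4, 6), (66, 70))
    add("brainstem", "serial-oar", (20, 30), (28.0, 5.0), (15.0, 40.0), (8, 12), (4, 7), (50, 56))
    return t


@dataclass(frozen=True)
class AlgorithmShiftModel:
    """Per-structure arm-B dose reductions, in percent.

    ``target_anchors`` maps a target label to ((median, sigma, lo, hi)
    for the D95% shift, same for the D2% shift); OAR entries give the
    Dmean shift median.  High-risk-target shifts are logit-normal with
    support exactly [lo, hi]; OAR shifts are clipped log-normal.
    ``latent_loading`` couples the shifts to the shared per-patient
    severity latent.
    """

    target_anchors: dict = field(
        default_factory=lambda: {
            "ptv1": ((1.5, 1.1, 0.10, 4.00), (0.8, 0.8, 0.30, 1.80)),
            "ptv2": ((0.20, 0.55, -1.0, 1.6), (0.70, 0.8, 0.20, 1.75)),
            "ptv3": ((0.20, 0.55, -1.0, 1.6), (0.60, 0.8, 0.15, 1.60)),
        }
    )
    oar_dmean: dict = field(
        default_factory=lambda: {
            "larynx": 1.8,
            "mandible": 3.4,
            "parotid_l": 3.1,
            "parotid_r": 3.1,
            "pcm_superior": 0.95,
            "spinal_cord": 2.0,
            "supraglottic_larynx": 2.0,
            "thyroid": 1.9,
            "brainstem": 2.0,
        }
    )
    oar_sigma: float = 0.40
    oar_clip: tuple[float, float] = (0.10, 6.5)
    latent_loading: float = 0.75

    def __post_init__(self) -> None:
        for label, (a95, a2) in self.target_anchors.items():
            for med, sigma, lo, hi in (a95, a2):
                if hi < lo or sigma < 0:
                    raise ValueError(f"{label}: invalid shift range/width")
        if self.oar_clip[1] < self.oar_clip[0] or self.oar_sigma < 0:
            raise ValueError("invalid OAR shift range/width")

    @classmethod
    def zero(cls) -> "AlgorithmShiftModel":
        """No algorithm difference: arm B identical to arm A."""
        anchors = {k: ((0, 0, 0, 0), (0, 0, 0, 0)) for k in ("ptv1", "ptv2", "ptv3")}
        oars = {
            k: 0.0
            for k in (
                "larynx", "mandible", "parotid_l", "parotid_r", "pcm_superior",
                "spinal_cord", "supraglottic_larynx", "thyroid", "brainstem",
            )
        }
        return cls(target_anchors=anchors, oar_dmean=oars, oar_sigma=0.0, oar_clip=(0.0, 0.0))

    @staticmethod
    def _logit_normal(median: float, width: float, lo: float, hi: float, x: float) -> float:
        """Sample bounded on (lo, hi) with the given median; x ~ N(0,1).

        A logit-normal law: strictly monotone in x (no tie clusters at
        the range ends, unlike hard clipping) with the declared range
        as its support.
        """
        frac = (median - lo) / (hi - lo)
        a = np.log(frac / (1.0 - frac))
        return float(lo + (hi - lo) / (1.0 + np.exp(-(a + width * x))))

    def sample_target(self, label: str, z_patient: float, rng: np.random.Generator) -> tuple[float, float]:
        (m95, s95, lo95, hi95), (m2, s2, lo2, hi2) = self.target_anchors[label]
        lam = self.latent_loading
        e1, e2 = rng.standard_normal(2)
        if m95 == 0 and s95 == 0:
            d95 = 0.0
        elif label == "ptv1":
            d95 = self._logit_normal(m95, s95, lo95, hi95, lam * z_patient + np.sqrt(1 - lam**2) * e1)
        else:
            # low-dose targets: small, sign-mixed D95 differences
            d95 = float(np.clip(m95 + s95 * (0.5 * z_patient + 0.87 * e1), lo95, hi95))
        d2 = 0.0 if (m2 == 0 and s2 == 0) else self._logit_normal(
            m2, s2, lo2, hi2, 0.6 * z_patient + 0.8 * e2
        )
        return d95, d2

    def sample_oar(self, label: str, z_patient: float, rng: np.random.Generator) -> float:
        med = self.oar_dmean[label]
        if med == 0 and self.oar_sigma == 0:
            return 0.0
        e = rng.standard_normal()
        return float(
            np.clip(med * np.exp(self.oar_sigma * (0.6 * z_patient + 0.8 * e)), *self.oar_clip)
        )


# ---------------------------------------------------------------------------
# Curve construction
# ---------------------------------------------------------------------------


def _asym_logistic_survival(d: np.ndarray, mu: float, w_lo: float, w_hi: float) -> np.ndarray:
    w = np.where(d < mu, w_lo, w_hi)
    return 1.0 / (1.0 + np.exp((d - mu) / w))


def _build_curve(
    label: str,
    total_volume: float,
    mu: float,
    w_lo: float,
    w_hi: float,
    cap: float,
    cold_volume: float,
    cold_floor: float,
) -> CumulativeDVH:
    edges = np.round(np.arange(0.0, cap + GRID_GY, GRID_GY), 4)
    s = _asym_logistic_survival(edges, mu, w_lo, w_hi)
    if cold_volume > 0:
        # interface cold spot: fixed absolute volume, not a fraction of
        # the target, spread linearly from cold_floor up to the plateau
        cold_fraction = min(cold_volume / total_volume, 0.05)
        s_cold = np.clip((mu - edges) / (mu - cold_floor), 0.0, 1.0)
        s = (1.0 - cold_fraction) * s + cold_fraction * s_cold
    s_cap = s[-1]
    v = total_volume * np.clip((s - s_cap) / (s[0] - s_cap), 0.0, 1.0)
    v = np.minimum.accumulate(v)
    v[0] = total_volume
    return CumulativeDVH(label, edges, v, total_volume, N_FRACTIONS)


def _sample_structure(tpl: StructureTemplate, z_patient: float, rng: np.random.Generator) -> CumulativeDVH:
    vol = rng.uniform(*tpl.volume)
    mu = float(np.clip(rng.normal(*tpl.mu), *tpl.mu_clip))
    w_lo = rng.uniform(*tpl.w_lo)
    w_hi = rng.uniform(*tpl.w_hi)
    cap = max(rng.uniform(*tpl.cap), mu + 0.5)
    cold_v = cold_floor = 0.0
    if tpl.cold_volume[1] > 0:
        # deeper/larger cold tails for anatomically severe patients
        cold_v = float(np.clip(
            0.5 * (tpl.cold_volume[0] + tpl.cold_volume[1])
            * np.exp(0.25 * (0.9 * z_patient + 0.44 * rng.standard_normal())),
            tpl.cold_volume[0] * 0.5,
            tpl.cold_volume[1] * 2.0,
        ))
        mid_floor = 0.5 * (tpl.cold_floor[0] + tpl.cold_floor[1])
        half = 0.5 * (tpl.cold_floor[1] - tpl.cold_floor[0])
        cold_floor = float(np.clip(mid_floor - 0.5 * half * np.tanh(z_patient), *tpl.cold_floor))
    return _build_curve(tpl.label, vol, mu, w_lo, w_hi, cap, cold_v, cold_floor)


def _contract(dvh: CumulativeDVH, delta_pct_fn) -> CumulativeDVH:
    """Apply the dose-axis contraction D -> D * (1 - delta(D)/100)."""
    delta = np.asarray(delta_pct_fn(dvh.dose_edges), dtype=float)
    new_edges = dvh.dose_edges * (1.0 - delta / 100.0)
    if np.any(np.diff(new_edges) <= 0):
        raise ValueError(f"{dvh.structure_label}: shift model breaks dose-axis monotonicity")
    return CumulativeDVH(dvh.structure_label, new_edges, dvh.volume.copy(), dvh.total_volume, dvh.n_fractions)


def _target_delta_fn(dvh: CumulativeDVH, d95_shift: float, d2_shift: float):
    """Piecewise target contraction delta(D) in percent.

    Affine through the (D95%, D2%) anchors across the falloff, flat
    above D2%, and tapering as (D/D95)^2 below D95%: the two-algorithm
    difference concentrates around the target periphery, so the cold
    low-dose tail moves by less than the falloff region.
    """
    d95 = dose_at_volume(dvh, 0.95)
    d2 = dose_at_volume(dvh, 0.02)
    lo, hi = min(d95_shift, d2_shift), max(d95_shift, d2_shift)
    slope = (d2_shift - d95_shift) / (d2 - d95)

    def fn(d):
        d = np.asarray(d, dtype=float)
        mid = np.clip(d95_shift + (d - d95) * slope, lo, hi)
        low = d95_shift * (d / d95) ** 2
        return np.where(d < d95, low, mid)

    return fn


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    n_patients: int = 26,
    shift_model: AlgorithmShiftModel | None = None,
    seed: int = 0,
    templates: dict[str, StructureTemplate] | None = None,
    n_missing_swallowing: int | None = None,
) -> list[PatientPlanPair]:
    """Generate a paired cohort of ``n_patients`` synthetic plan pairs.

    Deterministic for a given seed.  When ``n_patients`` is 26 (the
    default cohort size), 3 patients lack the swallowing structures
    (superior PCM, supraglottic larynx), emulating post-surgical
    anatomies that could not be contoured; set
    ``n_missing_swallowing=0`` to disable.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    shift_model = shift_model or AlgorithmShiftModel()
    templates = templates or default_templates()
    if n_missing_swallowing is None:
        n_missing_swallowing = 3 if n_patients == 26 else 0

    root = np.random.SeedSequence(seed)
    missing_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xFFFF,)))
    missing_ids = set(
        missing_rng.choice(n_patients, size=min(n_missing_swallowing, n_patients), replace=False).tolist()
    )

    cohort = []
    labels = sorted(templates)
    for p in range(n_patients):
        prng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(p,)))
        z = float(prng.standard_normal())  # shared anatomical-severity latent
        age = float(np.round(prng.uniform(35, 72), 1))
        dvhs_a: dict[str, CumulativeDVH] = {}
        dvhs_b: dict[str, CumulativeDVH] = {}
        for s_idx, label in enumerate(labels):
            if p in missing_ids and label in ("pcm_superior", "supraglottic_larynx"):
                continue
            srng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(p, s_idx)))
            tpl = templates[label]
            dvh_a = _sample_structure(tpl, z, srng)
            if tpl.role == "target":
                d95s, d2s = shift_model.sample_target(label, z, srng)
                if d95s == 0 and d2s == 0:
                    dvh_b = dvh_a
                else:
                    dvh_b = _contract(dvh_a, _target_delta_fn(dvh_a, d95s, d2s))
            else:
                ds = shift_model.sample_oar(label, z, srng)
                dvh_b = dvh_a if ds == 0 else _contract(dvh_a, lambda d, ds=ds: np.full_like(d, ds))
            dvhs_a[label] = dvh_a
            dvhs_b[label] = dvh_b
        covariates = {"age": age}
        if "thyroid" in dvhs_a:
            covariates["thyroid_volume"] = dvhs_a["thyroid"].total_volume
        cohort.append(PatientPlanPair(f"p{p + 1:02d}", dvhs_a, dvhs_b, covariates))
    return cohort


def write_cohort(cohort: list[PatientPlanPair], directory: str | Path) -> Path:
    """Write DVH-CSV files per patient-arm plus a JSON manifest.

    Returns the manifest path; the manifest is directly consumable by
    :func:`dvhrad.cohort.load_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for pair in cohort:
        fa = f"{pair.patient_id}_armA.csv"
        fb = f"{pair.patient_id}_armB.csv"
        write_dvh_file(directory / fa, pair.dvhs_a)
        write_dvh_file(directory / fb, pair.dvhs_b)
        entries.append(
            {"id": pair.patient_id, "dvh_a": fa, "dvh_b": fb, "covariates": pair.covariates}
        )
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"patients": entries}, indent=1), encoding="utf-8")
    return manifest
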