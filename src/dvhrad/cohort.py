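"""Paired-cohort plan comparison.

Each patient carries two structure-wise DVH sets for the same contours:
arm A (the clinically used dose algorithm) and arm B (the recalculation
with a second algorithm at identical monitor units).  For every
configured endpoint — target D95%/D2%/Dmean, OAR mean doses, D2% of the
serial organs, Poisson-LQ TCP of the high-risk target and the NTCP
models of the registry — the analysis extracts a per-arm value per
patient, forms A-referenced percentage differences

    delta% = 100 * (A - B) / A        (B lower -> positive),

summarizes each arm as median [min, max], and tests the paired samples
with the two-sided Wilcoxon signed-rank test (normality is reported via
Shapiro-Wilk but the comparison is always nonparametric).

The entry point is the model/results pair

    results = PairedCohortAnalysis(cohort, config).fit()
    print(results.summary())

with ``results.frame`` the tidy per-endpoint table and
``results.endpoint_values`` the per-patient values behind it.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .dvh import CumulativeDVH, dose_at_volume, mean_dose, read_dvh_file, resample
from .fractionation import FractionationParams
from .ntcp import LKBParams, LogisticModel, NTCPResult, lkb_ntcp, logistic_ntcp, model_registry
from .tcp import TCPParams, poisson_tcp

__all__ = [
    "PatientPlanPair",
    "PairedCohortSummary",
    "AnalysisConfig",
    "PairedCohortAnalysis",
    "PairedCohortResults",
    "extract_endpoints",
    "percent_difference",
    "wilcoxon_signed_rank",
    "shapiro_wilk",
    "summarize_cohort",
    "load_cohort",
]

log = logging.getLogger("dvhrad")

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class PatientPlanPair:
    """One patient's DVH sets under the two dose algorithms."""

    patient_id: str
    dvhs_a: dict[str, CumulativeDVH]
    dvhs_b: dict[str, CumulativeDVH]
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.dvhs_a) != set(self.dvhs_b):
            raise ValueError(
                f"{self.patient_id}: arm A and arm B structure sets differ: "
                f"{sorted(set(self.dvhs_a) ^ set(self.dvhs_b))}"
            )
        for label in self.dvhs_a:
            va, vb = self.dvhs_a[label].total_volume, self.dvhs_b[label].total_volume
            if abs(va - vb) > 0.01 * va:
                raise ValueError(
                    f"{self.patient_id}/{label}: total volumes differ by more than 1% "
                    f"({va:g} vs {vb:g} cm^3); the arms must share contours"
                )


@dataclass(frozen=True)
class PairedCohortSummary:
    """Per-endpoint paired summary: the row format of the result tables."""

    metric_id: str
    n: int
    median_a: float
    min_a: float
    max_a: float
    median_b: float
    min_b: float
    max_b: float
    per_patient_delta_pct: tuple[float, ...]
    median_delta_pct: float
    delta_pct_of_medians: float
    p_value: float
    significant: bool


@dataclass
class AnalysisConfig:
    """Endpoint and model configuration of the paired analysis.

    Defaults reproduce the published evaluation protocol: alpha/beta =
    3 Gy for the OAR EQD2 correction, 33 fractions, Poisson-LQ TCP with
    alpha = 0.33/Gy, alpha/beta = 10 Gy, rho = 1e7 cells/cm^3 on the
    high-risk target, and the bundled NTCP registry.  Logistic mean-dose
    models consume physical mean dose unless ``eqd2_logistic_means`` is
    set; the solid-food age covariate is used as printed in its source
    unless ``age_as_indicator`` converts it to a >= 65-years indicator.
    """

    alpha_beta_oar: float = 3.0
    n_fractions: int = 33
    tcp: TCPParams = field(default_factory=TCPParams)
    age_as_indicator: bool = False
    age_indicator_threshold: float = 65.0
    eqd2_logistic_means: bool = False
    use_reported_ntcp: bool = True
    registry: dict = field(default_factory=model_registry)

    # structure labels the endpoint battery looks for
    ptvs: tuple[str, ...] = ("ptv1", "ptv2", "ptv3")
    oars: tuple[str, ...] = (
        "larynx",
        "mandible",
        "parotid_l",
        "parotid_r",
        "pcm_superior",
        "spinal_cord",
        "supraglottic_larynx",
        "thyroid",
        "brainstem",
    )
    d2_oars: tuple[str, ...] = ("mandible", "spinal_cord")
    tcp_structure: str = "ptv1"

    @property
    def oar_fractionation(self) -> FractionationParams:
        return FractionationParams(self.alpha_beta_oar, self.n_fractions)

    def endpoint_ids(self) -> list[str]:
        ids = []
        for ptv in self.ptvs:
            ids += [f"{ptv}_d95", f"{ptv}_d2", f"{ptv}_dmean"]
        ids += [f"{o}_dmean" for o in self.oars]
        ids += [f"{o}_d2" for o in self.d2_oars]
        ids.append(f"tcp_{self.tcp_structure}")
        ids += [
            "ntcp_parotid_eisbruch",
            "ntcp_parotid_roesink",
            "ntcp_mandible_necrosis",
            "ntcp_larynx_edema",
            "ntcp_cord_myelopathy",
            "ntcp_hypothyroidism",
            "ntcp_swalm6",
            "ntcp_solid_food",
        ]
        return ids


def percent_difference(a: float, b: float) -> float:
    """A-referenced percentage difference 100 (a - b) / a."""
    if a == 0:
        raise ZeroDivisionError("percentage difference undefined for a = 0")
    return 100.0 * (a - b) / a


def wilcoxon_signed_rank(paired_values) -> float:
    """Two-sided Wilcoxon signed-rank p-value for (a, b) pairs.

    Zero differences are dropped (Wilcoxon's convention); ties get
    average ranks.  The exact null distribution is used for up to 25
    non-zero differences when it is available (no rank ties), otherwise
    the normal approximation with continuity correction.  All pairs
    identical is a degenerate comparison and reports p = 1.
    """
    arr = np.asarray(list(paired_values), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (a, b) pairs")
    diff = arr[:, 0] - arr[:, 1]
    diff = diff[diff != 0.0]
    if diff.size == 0:
        return 1.0
    has_ties = np.unique(np.abs(diff)).size != diff.size
    method = "exact" if (diff.size <= 25 and not has_ties) else "approx"
    res = scipy.stats.wilcoxon(diff, correction=(method == "approx"), method=method)
    return float(res.pvalue)


def shapiro_wilk(values) -> float:
    """Shapiro-Wilk normality p-value (n >= 3, non-constant sample)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    return float(scipy.stats.shapiro(arr).pvalue)


# ---------------------------------------------------------------------------
# Endpoint extraction
# ---------------------------------------------------------------------------


def _combined_parotid(dvhs: dict[str, CumulativeDVH], n_fractions: int) -> CumulativeDVH | None:
    """Merge left and right parotid cumulative DVHs on a common grid."""
    parts = [dvhs[k] for k in ("parotid_l", "parotid_r") if k in dvhs]
    if not parts:
        return None
    if len(parts) == 1:
        return parts[0]
    grids = [resample(p) for p in parts]
    n = max(g.dose_edges.size for g in grids)
    edges = max((g.dose_edges for g in grids), key=len)
    vol = np.zeros(n)
    for g in grids:
        vol += np.interp(edges, g.dose_edges, g.volume, right=0.0)
    total = sum(p.total_volume for p in parts)
    return CumulativeDVH("parotid_combined", edges, vol, total, n_fractions)


def _ntcp_value(result: NTCPResult, config: AnalysisConfig) -> float:
    return result.reported_probability if config.use_reported_ntcp else result.probability


def _arm_endpoints(
    dvhs: dict[str, CumulativeDVH], covariates: dict[str, float], config: AnalysisConfig
) -> dict[str, float]:
    values: dict[str, float] = {}
    frac = config.oar_fractionation
    reg = config.registry

    def have(*labels: str) -> bool:
        missing = [l for l in labels if l not in dvhs]
        if missing:
            log.warning("structures %s missing; dependent endpoints skipped", missing)
            return False
        return True

    for ptv in config.ptvs:
        if have(ptv):
            values[f"{ptv}_d95"] = dose_at_volume(dvhs[ptv], 0.95)
            values[f"{ptv}_d2"] = dose_at_volume(dvhs[ptv], 0.02)
            values[f"{ptv}_dmean"] = mean_dose(dvhs[ptv])
    for oar in config.oars:
        if oar in dvhs:
            values[f"{oar}_dmean"] = mean_dose(dvhs[oar])
    for oar in config.d2_oars:
        if oar in dvhs:
            values[f"{oar}_d2"] = dose_at_volume(dvhs[oar], 0.02)
    if have(config.tcp_structure):
        values[f"tcp_{config.tcp_structure}"] = poisson_tcp(dvhs[config.tcp_structure], config.tcp)

    parotid = _combined_parotid(dvhs, config.n_fractions)
    if parotid is not None:
        for tag, source in (("eisbruch", "eisbruch"), ("roesink", "roesink")):
            params: LKBParams = reg[("parotid", "25% xerostomia at 1 year", source)]
            values[f"ntcp_parotid_{tag}"] = _ntcp_value(lkb_ntcp(parotid, params, frac), config)
    if "mandible" in dvhs:
        params = reg[("mandible", "necrosis", "burman")]
        values["ntcp_mandible_necrosis"] = _ntcp_value(lkb_ntcp(dvhs["mandible"], params, frac), config)
    if "larynx" in dvhs:
        params = reg[("larynx", "grade >= 2 edema", "rancati")]
        values["ntcp_larynx_edema"] = _ntcp_value(lkb_ntcp(dvhs["larynx"], params, frac), config)
    if "spinal_cord" in dvhs:
        params = reg[("spinal_cord", "myelopathy", "kirkpatrick_emami")]
        values["ntcp_cord_myelopathy"] = _ntcp_value(lkb_ntcp(dvhs["spinal_cord"], params, frac), config)

    def logistic_mean(label: str) -> float:
        # Source models were fitted to physical dose at conventional
        # fractionation; EQD2 is available behind a switch.
        if config.eqd2_logistic_means:
            from .fractionation import eqd2_transform

            return mean_dose(eqd2_transform(dvhs[label], frac))
        return mean_dose(dvhs[label])

    if "thyroid" in dvhs:
        model: LogisticModel = reg[("thyroid", "hypothyroidism", "boomsma")]
        cov = {
            "dmean_thyroid": logistic_mean("thyroid"),
            "volume_thyroid": covariates.get("thyroid_volume", dvhs["thyroid"].total_volume),
        }
        values["ntcp_hypothyroidism"] = _ntcp_value(logistic_ntcp(cov, model), config)
    if have("pcm_superior", "supraglottic_larynx"):
        dm_pcm = logistic_mean("pcm_superior")
        dm_sl = logistic_mean("supraglottic_larynx")
        model = reg[("pcm_supraglottic", "SWALM6", "christianen")]
        values["ntcp_swalm6"] = _ntcp_value(
            logistic_ntcp({"dmean_pcm": dm_pcm, "dmean_sl": dm_sl}, model), config
        )
        if "age" in covariates:
            age = covariates["age"]
            if config.age_as_indicator:
                age = 1.0 if age >= config.age_indicator_threshold else 0.0
            model = reg[("pcm_supraglottic", "swallowing solid food", "christianen")]
            values["ntcp_solid_food"] = _ntcp_value(
                logistic_ntcp({"dmean_pcm": dm_pcm, "dmean_sl": dm_sl, "age": age}, model), config
            )
    return values


def extract_endpoints(
    pair: PatientPlanPair, config: AnalysisConfig | None = None
) -> dict[str, dict[str, float]]:
    """Per-arm endpoint values for one patient: ``{"a": {...}, "b": {...}}``.

    Endpoints whose structures are missing (e.g. swallowing structures
    that could not be contoured after surgery) are skipped with a
    logged warning rather than failing the patient.
    """
    config = config or AnalysisConfig()
    return {
        "a": _arm_endpoints(pair.dvhs_a, pair.covariates, config),
        "b": _arm_endpoints(pair.dvhs_b, pair.covariates, config),
    }


def summarize_cohort(
    cohort: list[PatientPlanPair], config: AnalysisConfig | None = None
) -> list[PairedCohortSummary]:
    """Median [min,max] per arm, per-patient delta% and Wilcoxon p per endpoint."""
    if len(cohort) < 2:
        raise ValueError("cohort comparison needs at least 2 patients")
    config = config or AnalysisConfig()
    per_patient = {pair.patient_id: extract_endpoints(pair, config) for pair in cohort}

    summaries = []
    for metric_id in config.endpoint_ids():
        a_vals, b_vals = [], []
        for pid in sorted(per_patient):
            ep = per_patient[pid]
            if metric_id in ep["a"] and metric_id in ep["b"]:
                a_vals.append(ep["a"][metric_id])
                b_vals.append(ep["b"][metric_id])
        if not a_vals:
            continue
        a = np.asarray(a_vals)
        b = np.asarray(b_vals)
        deltas = tuple(percent_difference(x, y) for x, y in zip(a, b) if x != 0)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        p = wilcoxon_signed_rank(zip(a, b))
        summaries.append(
            PairedCohortSummary(
                metric_id=metric_id,
                n=len(a_vals),
                median_a=med_a,
                min_a=float(a.min()),
                max_a=float(a.max()),
                median_b=med_b,
                min_b=float(b.min()),
                max_b=float(b.max()),
                per_patient_delta_pct=deltas,
                median_delta_pct=float(np.median(deltas)) if deltas else math.nan,
                delta_pct_of_medians=percent_difference(med_a, med_b) if med_a != 0 else math.nan,
                p_value=p,
                significant=p < SIGNIFICANCE_LEVEL,
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class PairedCohortAnalysis:
    """Paired two-algorithm plan comparison over a patient cohort.

    Parameters
    ----------
    cohort : list of PatientPlanPair
    config : AnalysisConfig, optional

    ``fit()`` runs the full endpoint battery and statistics and returns
    a :class:`PairedCohortResults`.
    """

    def __init__(self, cohort: list[PatientPlanPair], config: AnalysisConfig | None = None):
        if len(cohort) < 2:
            raise ValueError("cohort comparison needs at least 2 patients")
        self.cohort = list(cohort)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, config: AnalysisConfig | None = None):
        return cls(load_cohort(manifest_path), config)

    def fit(self) -> "PairedCohortResults":
        summaries = summarize_cohort(self.cohort, self.config)
        values = []
        for pair in self.cohort:
            ep = extract_endpoints(pair, self.config)
            for arm in ("a", "b"):
                for metric_id, val in ep[arm].items():
                    values.append(
                        {"patient_id": pair.patient_id, "arm": arm, "metric_id": metric_id, "value": val}
                    )
        return PairedCohortResults(self, summaries, pd.DataFrame(values))


class PairedCohortResults:
    """Fitted paired-cohort comparison.

    Attributes
    ----------
    frame : DataFrame
        One row per endpoint: per-arm median/min/max, median of the
        per-patient delta%, delta% of the medians, Wilcoxon p and the
        significance flag at the 0.05 level.
    endpoint_values : DataFrame
        Long-form per-patient, per-arm endpoint values.
    """

    def __init__(self, model: PairedCohortAnalysis, summaries, endpoint_values: pd.DataFrame):
        self.model = model
        self.summaries = summaries
        self.endpoint_values = endpoint_values
        self.frame = pd.DataFrame(
            [
                {
                    "metric_id": s.metric_id,
                    "n": s.n,
                    "median_a": s.median_a,
                    "min_a": s.min_a,
                    "max_a": s.max_a,
                    "median_b": s.median_b,
                    "min_b": s.min_b,
                    "max_b": s.max_b,
                    "median_delta_pct": s.median_delta_pct,
                    "delta_pct_of_medians": s.delta_pct_of_medians,
                    "p_value": s.p_value,
                    "significant": s.significant,
                }
                for s in summaries
            ]
        )

    def __getitem__(self, metric_id: str) -> PairedCohortSummary:
        for s in self.summaries:
            if s.metric_id == metric_id:
                return s
        raise KeyError(metric_id)

    def normality(self) -> pd.DataFrame:
        """Shapiro-Wilk p-values of the per-patient differences, per endpoint."""
        rows = []
        for s in self.summaries:
            piv = self.endpoint_values.query("metric_id == @s.metric_id").pivot(
                index="patient_id", columns="arm", values="value"
            )
            d = (piv["a"] - piv["b"]).to_numpy()
            try:
                p = shapiro_wilk(d)
            except ValueError:
                p = math.nan
            rows.append({"metric_id": s.metric_id, "shapiro_p": p})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    def summary(self) -> str:
        """Human-readable comparison table, one endpoint per row."""
        df = self.frame.copy()
        lines = [
            "Paired cohort comparison (arm A vs arm B)",
            f"patients: {len(self.model.cohort)}   Wilcoxon signed-rank, two-sided, alpha = {SIGNIFICANCE_LEVEL}",
            "delta% = 100*(A-B)/A, median over patients",
            "",
            f"{'endpoint':<26}{'n':>3} {'A median [min,max]':>26} {'B median [min,max]':>26} "
            f"{'delta%':>8} {'p':>10}  sig",
        ]
        for _, r in df.iterrows():
            a_txt = f"{r.median_a:.4g} [{r.min_a:.4g},{r.max_a:.4g}]"
            b_txt = f"{r.median_b:.4g} [{r.min_b:.4g},{r.max_b:.4g}]"
            d_txt = "--" if pd.isna(r.median_delta_pct) else f"{r.median_delta_pct:.2f}"
            p_txt = "<0.001" if r.p_value < 1e-3 else f"{r.p_value:.3f}"
            lines.append(
                f"{r.metric_id:<26}{r.n:>3} {a_txt:>26} {b_txt:>26} {d_txt:>8} {p_txt:>10}  "
                f"{'*' if r.significant else ''}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Cohort manifest I/O
# ---------------------------------------------------------------------------


def load_cohort(manifest_path: str | Path) -> list[PatientPlanPair]:
    """Load a cohort from a JSON/YAML manifest of per-patient DVH files.

    Manifest layout::

        patients:
          - id: p01
            dvh_a: p01_armA.csv      # paths relative to the manifest
            dvh_b: p01_armB.csv
            covariates: {age: 57, thyroid_volume: 14.2}
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text(encoding="utf-8")
    doc = yaml.safe_load(text) if manifest_path.suffix in (".yaml", ".yml") else json.loads(text)
    cohort = []
    for entry in doc["patients"]:
        base = manifest_path.parent
        cohort.append(
            PatientPlanPair(
                patient_id=str(entry["id"]),
                dvhs_a=read_dvh_file(base / entry["dvh_a"]),
                dvhs_b=read_dvh_file(base / entry["dvh_b"]),
                covariates={k: float(v) for k, v in entry.get("covariates", {}).items()},
            )
        )
    return cohort
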