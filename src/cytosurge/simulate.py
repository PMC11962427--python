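"""Synthetic cohort and tissue generators with recoverable ground truth.

The cohort generator emulates a two-arm longitudinal aging study: a young
stratum (enrollment 20-31 y) and an old stratum (60-96 y) sampled annually for
up to nine years on a 32-cytokine serum panel. Log concentrations follow

    log c[k, s, t] = baseline[k] + subject_effect[s, k] + noise + surge(s, t)

with lognormal subject baselines, an age-escalating noise SD, and an
injectable pre-diagnostic surge: for cancer subjects sampled at or above the
age threshold, the log effect ramps linearly from zero at ``onset`` years
before diagnosis to the peak at diagnosis, then decays exponentially with the
configured half-life. Clinical events are drawn from age-piecewise yearly
hazards. Everything injected is recorded in :class:`GroundTruth`.

The tissue generator emulates an annotated pan-cancer expression matrix:
cytokine-set genes carry an age effect concentrated above 80 y (or a linear
age trend for the contrast scenario) plus a latent inflammation axis shared
with CDKN1A at a requested correlation; decoy genes carry neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, PanelTable, validate_events

# 32 serum analytes typical of a multiplex inflammation panel.
DEFAULT_CYTOKINES = [
    "CXCL10", "IL12B", "IL13", "CCL7", "IL7", "TNF", "PDGFBB", "LTA",
    "IL15", "IL12A", "NGF", "FGF2", "IL1A", "IL4", "TGFA", "IFNG",
    "IL2", "IL5", "IL1B", "CCL3", "VEGFA", "CCL11", "IL10", "CXCL8",
    "CCL4", "IL6", "IL17A", "IL18", "CSF2", "CSF3", "CCL2", "EGF",
]

# Subset with an unambiguous serum-protein -> gene mapping, reused by the
# tissue generator as the cytokine gene set (18 genes).
TISSUE_CYTOKINE_GENES = [
    "CXCL10", "IL15", "IFNG", "IL1A", "IL1B", "IL7", "IL2", "IL4",
    "IL5", "IL6", "IL10", "IL13", "TNF", "LTA", "CCL3", "CCL4",
    "CXCL8", "CCL11",
]

Piecewise = tuple[tuple[float, float, float], ...]  # (age_lo, age_hi, rate/yr)

DEFAULT_CANCER_HAZARD: Piecewise = ((0.0, 60.0, 0.002), (60.0, 80.0, 0.02), (80.0, math.inf, 0.08))
DEFAULT_OTHER_HAZARDS: dict[str, Piecewise] = {
    "cardiovascular": ((0.0, 60.0, 0.005), (60.0, math.inf, 0.04)),
    "inflammatory": ((0.0, 60.0, 0.005), (60.0, math.inf, 0.03)),
    "other": ((0.0, 60.0, 0.01), (60.0, math.inf, 0.05)),
}


@dataclass
class CohortSimParams:
    """Study-design parameters for the longitudinal cohort generator."""

    n_young: int = 63
    n_old: int = 72
    enroll_age_young: tuple[float, float] = (20.0, 31.0)
    enroll_age_old: tuple[float, float] = (60.0, 96.0)
    n_years: int = 9
    visit_prob: float = 0.9
    n_cytokines: int = 32
    baseline_log_mean: np.ndarray | None = None
    baseline_log_sd_between_subject: float = 0.5
    noise_log_sd: float = 0.3
    age_var_slope: float = 0.05          # extra log-SD per decade of age
    cancer_hazard_by_age: Piecewise = DEFAULT_CANCER_HAZARD
    other_event_hazards: dict[str, Piecewise] = field(
        default_factory=lambda: dict(DEFAULT_OTHER_HAZARDS)
    )
    cancer_subtype_probs: dict[str, float] = field(
        default_factory=lambda: {"cancer_nmsc": 0.70, "cancer_invasive": 0.25, "cancer_other": 0.05}
    )
    surge_onset_years_before_dx: float = 4.0
    surge_peak_log_effect: float = 1.0   # natural-log units at diagnosis
    surge_age_threshold: float = 80.0
    post_dx_decay_halflife_years: float = 1.0
    detection_limit: float = 0.05        # pg/mL
    allow_recurrence: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young + self.n_old <= 0:
            raise ValueError("cohort must contain at least one subject")
        if self.n_cytokines <= 0:
            raise ValueError("panel must contain at least one cytokine")
        if not 0 < self.visit_prob <= 1:
            raise ValueError("visit_prob must lie in (0,1]")
        if self.baseline_log_sd_between_subject <= 0 or self.noise_log_sd <= 0:
            raise ValueError("SD parameters must be positive")
        if self.age_var_slope < 0:
            raise ValueError("age_var_slope must be nonnegative")
        for lo, hi, rate in self.cancer_hazard_by_age:
            if rate < 0:
                raise ValueError("hazards must be nonnegative")

    def cytokine_names(self) -> list[str]:
        base = list(DEFAULT_CYTOKINES)
        if self.n_cytokines <= len(base):
            return base[: self.n_cytokines]
        return base + [f"CYT{i:02d}" for i in range(len(base), self.n_cytokines)]

    def baselines(self) -> np.ndarray:
        if self.baseline_log_mean is not None:
            arr = np.asarray(self.baseline_log_mean, dtype=float)
            if arr.shape != (self.n_cytokines,):
                raise ValueError("baseline_log_mean must have length n_cytokines")
            return arr
        # geometric spacing 2..400 pg/mL, deterministic
        return np.log(np.geomspace(2.0, 400.0, self.n_cytokines))


@dataclass
class GroundTruth:
    """Record of every injected effect, sufficient to verify recovery."""

    baseline_log_mean: np.ndarray
    event_times: pd.DataFrame            # subject_id, category, time_years (since enrollment)
    surge_log_effect: pd.Series          # per sample_id, injected log-scale surge
    below_detection: pd.DataFrame | None = None   # samples x cytokines bool
    gene_age_effect: pd.Series | None = None      # per gene, injected raw log2 shift
    params: object | None = None


def _piecewise_rate(pieces: Piecewise, age: float) -> float:
    for lo, hi, rate in pieces:
        if lo <= age < hi:
            return rate
    return 0.0


def _draw_event_times(rng, enroll_age: float, n_years: int, pieces: Piecewise,
                      allow_recurrence: bool = False, min_gap: float = 2.0) -> list[float]:
    """Year-by-year Bernoulli draws from the age-piecewise hazard."""
    times: list[float] = []
    for year in range(n_years):
        rate = _piecewise_rate(pieces, enroll_age + year + 0.5)
        if rate <= 0:
            continue
        if times and not allow_recurrence:
            break
        if times and allow_recurrence and (year - times[-1]) < min_gap:
            continue
        if rng.random() < 1.0 - math.exp(-rate):
            times.append(year + rng.random())
    return times


def surge_log_effect(rel_time: float, onset: float, peak: float, halflife: float) -> float:
    """Injected log-scale surge at ``rel_time`` years from diagnosis (negative = before)."""
    if rel_time < -onset:
        return 0.0
    if rel_time < 0:
        return peak * (1.0 + rel_time / onset)
    return peak * 0.5 ** (rel_time / halflife)


def simulate_cohort(params: CohortSimParams | None = None) -> tuple[PanelTable, pd.DataFrame, GroundTruth]:
    """Simulate a longitudinal serum cytokine cohort.

    Returns the panel, the clinical event table, and the ground truth. Output
    is a deterministic function of ``params.seed``.
    """
    p = params or CohortSimParams()
    rng = np.random.default_rng(p.seed)
    names = p.cytokine_names()
    baselines = p.baselines()
    k = p.n_cytokines

    subjects = []
    start = pd.Timestamp("2007-01-01")
    for i in range(p.n_young + p.n_old):
        lo, hi = p.enroll_age_young if i < p.n_young else p.enroll_age_old
        subjects.append(
            dict(
                subject_id=f"S{i + 1:03d}",
                enroll_age=rng.uniform(lo, hi),
                enroll_date=start + pd.Timedelta(days=float(rng.uniform(0, 365))),
                sex="F" if rng.random() < 0.5 else "M",
            )
        )

    # clinical events
    event_rows = []
    for s in subjects:
        for t in _draw_event_times(rng, s["enroll_age"], p.n_years,
                                   p.cancer_hazard_by_age, p.allow_recurrence):
            cats, probs = zip(*p.cancer_subtype_probs.items())
            cat = cats[rng.choice(len(cats), p=np.asarray(probs) / np.sum(probs))]
            event_rows.append((s["subject_id"], cat, t))
        for cat, pieces in p.other_event_hazards.items():
            for t in _draw_event_times(rng, s["enroll_age"], p.n_years, pieces):
                event_rows.append((s["subject_id"], cat, t))
    truth_events = pd.DataFrame(event_rows, columns=["subject_id", "category", "time_years"])
    subj_lookup = {s["subject_id"]: s for s in subjects}
    if len(truth_events):
        truth_events["diagnosis_date"] = [
            subj_lookup[sid]["enroll_date"] + pd.Timedelta(days=t * 365.25)
            for sid, t in zip(truth_events["subject_id"], truth_events["time_years"])
        ]
        truth_events["age_at_diagnosis"] = [
            subj_lookup[sid]["enroll_age"] + t
            for sid, t in zip(truth_events["subject_id"], truth_events["time_years"])
        ]
    else:
        truth_events["diagnosis_date"] = pd.Series([], dtype="datetime64[ns]")
        truth_events["age_at_diagnosis"] = pd.Series([], dtype=float)

    cancer_times = {
        sid: sorted(g["time_years"])
        for sid, g in truth_events[truth_events["category"].str.startswith("cancer")].groupby("subject_id")
    }

    # visits and concentrations
    rows, log_conc, surge_records = [], [], []
    for s in subjects:
        subj_effect = rng.normal(0.0, p.baseline_log_sd_between_subject, size=k)
        for year in range(p.n_years):
            if rng.random() >= p.visit_prob:
                continue
            t_visit = year + rng.uniform(-0.08, 0.08) if year > 0 else year + rng.uniform(0, 0.08)
            age = s["enroll_age"] + t_visit
            surge = 0.0
            if age >= p.surge_age_threshold:
                for t_dx in cancer_times.get(s["subject_id"], []):
                    surge = max(
                        surge,
                        surge_log_effect(
                            t_visit - t_dx,
                            p.surge_onset_years_before_dx,
                            p.surge_peak_log_effect,
                            p.post_dx_decay_halflife_years,
                        ),
                    )
            noise_sd = p.noise_log_sd + p.age_var_slope * age / 10.0
            logs = baselines + subj_effect + rng.normal(0.0, noise_sd, size=k) + surge
            sample_id = f"{s['subject_id']}_V{year}"
            rows.append(
                dict(
                    sample_id=sample_id,
                    subject_id=s["subject_id"],
                    visit_date=s["enroll_date"] + pd.Timedelta(days=t_visit * 365.25),
                    age_at_sampling=age,
                    sex=s["sex"],
                )
            )
            log_conc.append(logs)
            surge_records.append(surge)

    meta = pd.DataFrame(rows)
    conc = np.exp(np.asarray(log_conc))
    below = conc < p.detection_limit
    conc[below] = p.detection_limit / 2.0
    panel_df = pd.concat([meta, pd.DataFrame(conc, columns=names)], axis=1)
    panel = PanelTable(panel_df, names)

    events = validate_events(
        truth_events[["subject_id", "category", "age_at_diagnosis"]].assign(
            diagnosis_date=truth_events["diagnosis_date"].dt.strftime("%Y-%m-%d")
            if len(truth_events)
            else pd.Series([], dtype=str)
        )[["subject_id", "category", "diagnosis_date", "age_at_diagnosis"]]
    )

    truth = GroundTruth(
        baseline_log_mean=baselines,
        event_times=truth_events,
        surge_log_effect=pd.Series(surge_records, index=meta["sample_id"], name="surge_log_effect"),
        below_detection=pd.DataFrame(below, index=meta["sample_id"], columns=names),
        params=p,
    )
    return panel, events, truth


# ---------------------------------------------------------------------------
# Tissue


DEFAULT_TISSUE_TYPES = ("BRCA", "COAD", "LUAD", "KIRC")
DEFAULT_AGE_BIN_COUNTS = {
    "<60": 100, "60-64": 40, "65-69": 40, "70-74": 40, "75-79": 40, "80-84": 25, "85+": 15,
}
_BIN_RANGES = {
    "<60": (40.0, 60.0), "60-64": (60.0, 65.0), "65-69": (65.0, 70.0),
    "70-74": (70.0, 75.0), "75-79": (75.0, 80.0), "80-84": (80.0, 85.0), "85+": (85.0, 92.0),
}


def simulate_tissue(
    n_per_type: dict[str, dict[str, int]] | None = None,
    effect_80plus: float = 0.6,
    cdkn1a_coupling: float = 0.5,
    seed: int = 0,
    age_effect_shape: str = "threshold",
    n_decoy_genes: int = 60,
    noise_log2_sd: float = 1.0,
) -> tuple[ExpressionMatrix, list[GeneSet], GroundTruth]:
    """Simulate an annotated pan-cancer expression matrix (TPM-like).

    ``effect_80plus`` is the standardized difference injected on the cytokine
    gene set for samples aged >= 80 (``age_effect_shape='threshold'``), or the
    standardized shift reached at 85 y under a linear trend starting at 60 y
    (``'linear'``). ``cdkn1a_coupling`` is the target correlation between
    CDKN1A and the cytokine-set score induced by a shared latent inflammation
    axis; |coupling| must be < 0.94 for the chosen loading geometry.
    """
    if not -0.94 < cdkn1a_coupling < 0.94:
        raise ValueError("cdkn1a_coupling must lie within (-0.94, 0.94)")
    if age_effect_shape not in {"threshold", "linear"}:
        raise ValueError(f"unknown age_effect_shape {age_effect_shape!r}")
    counts = n_per_type or {t: dict(DEFAULT_AGE_BIN_COUNTS) for t in DEFAULT_TISSUE_TYPES}
    if len(counts) < 2:
        raise ValueError("need at least two cancer types")
    rng = np.random.default_rng(seed)

    set_genes = list(TISSUE_CYTOKINE_GENES)
    m = len(set_genes)
    decoys = [f"DECOY{i + 1:03d}" for i in range(n_decoy_genes)]
    genes = set_genes + ["CDKN1A"] + decoys

    sigma = noise_log2_sd
    c_load = 3.0 * sigma  # CDKN1A loading on the latent axis
    rho = cdkn1a_coupling
    if rho == 0:
        lam = 0.0
    else:
        denom = c_load**2 - rho**2 * (c_load**2 + sigma**2)
        lam = math.copysign(
            sigma * math.sqrt(rho**2 * (c_load**2 + sigma**2) / (m * denom)), rho
        )
    score_resid_sd = math.sqrt(lam**2 + sigma**2 / m)
    effect_raw = effect_80plus * score_resid_sd  # log2 shift per set gene

    gene_base = rng.uniform(3.0, 8.0, size=len(genes))
    rows_meta, cols = [], []
    blocks = []
    for ctype, bins in counts.items():
        type_shift = rng.normal(0.0, 0.5, size=len(genes))
        for bin_label, n in bins.items():
            if n < 1:
                raise ValueError("need at least one sample per (type, age bin) cell")
            lo, hi = _BIN_RANGES.get(bin_label, (40.0, 60.0))
            ages = rng.uniform(lo, hi, size=n)
            z = rng.normal(size=n)
            eps = rng.normal(0.0, sigma, size=(len(genes), n))
            mat = gene_base[:, None] + type_shift[:, None] + eps
            if age_effect_shape == "threshold":
                shift = effect_raw * (ages >= 80.0)
            else:
                shift = effect_raw * np.clip(ages - 60.0, 0.0, None) / 25.0
            mat[:m] += shift[None, :]
            mat[:m] += lam * z[None, :]
            mat[m] += c_load * z  # CDKN1A row
            for j in range(n):
                sid = f"{ctype}_{bin_label}_{j + 1:03d}"
                cols.append(sid)
                rows_meta.append(
                    dict(
                        sample_id=sid,
                        age=ages[j],
                        sex="F" if rng.random() < 0.5 else "M",
                        cancer_type=ctype,
                        stage=int(rng.choice([1, 2, 3], p=[0.5, 0.4, 0.1])),
                    )
                )
            blocks.append(mat)

    log2_mat = np.concatenate(blocks, axis=1)
    values = pd.DataFrame(np.maximum(2.0**log2_mat - 1.0, 0.0), index=genes, columns=cols)
    annotations = pd.DataFrame(rows_meta).set_index("sample_id")
    expr = ExpressionMatrix(values, annotations)

    decoy_a = tuple(rng.choice(decoys, size=min(15, n_decoy_genes), replace=False))
    decoy_b = tuple(rng.choice(decoys, size=min(15, n_decoy_genes), replace=False))
    sets = [
        GeneSet("CYTOKINE_SURGE", "cytokine genes carrying the injected age effect", tuple(set_genes)),
        GeneSet("DECOY_A", "random decoy set, no injected effect", decoy_a),
        GeneSet("DECOY_B", "random decoy set, no injected effect", decoy_b),
    ]
    truth = GroundTruth(
        baseline_log_mean=gene_base,
        event_times=pd.DataFrame(columns=["subject_id", "category", "time_years"]),
        surge_log_effect=pd.Series(dtype=float),
        gene_age_effect=pd.Series(
            [effect_raw] * m + [0.0] * (1 + n_decoy_genes), index=genes, name="log2_shift"
        ),
    )
    return expr, sets, truth
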