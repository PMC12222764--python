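"""Synthetic ED cohorts with configurable, stream-distributed outcome signal.

Observable tables are generated first with realistic marginals; each stream
then contributes a standardized signal computed *from its own observables*
— an age term (arrival), abnormal-vitals counts (triage and the periodic
vitals), and high-risk medication / dispensed-drug / diagnosis-code
indicators.  A weighted sum of these signals is the encounter's risk score;
admission is Bernoulli through a logistic link whose intercept is
calibrated by bisection so the empirical prevalence matches the configured
one, and the three decompensation labels are drawn analogously among
admitted encounters (discharge-home with a negative link, so sicker
patients are less likely to go straight home).  Because the signals are
functions of the recorded data, a model can in principle recover the full
risk score from the tables — and only through the streams that carry
weight.  Zero weights make labels independent of the data.  Everything is
driven by one seeded generator and is bit-reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from meme_ed.concepts import CONCEPT_ORDER, ConceptKind
from meme_ed.schema_io import (
    DECOMP_LABELS,
    EncounterBundle,
    EncounterKey,
    LabelSet,
)

# default per-stream effect weights: signal distributed across all six
DEFAULT_WEIGHTS: dict[ConceptKind, float] = {
    ConceptKind.ARRIVAL: 1.2,
    ConceptKind.TRIAGE: 2.2,
    ConceptKind.MEDRECON: 1.4,
    ConceptKind.VITALS: 1.8,
    ConceptKind.PYXIS: 1.5,
    ConceptKind.DIAGNOSIS: 2.2,
}

DEFAULT_MISSINGNESS: dict[ConceptKind, float] = {
    ConceptKind.ARRIVAL: 0.0,
    ConceptKind.TRIAGE: 0.02,
    ConceptKind.MEDRECON: 0.15,
    ConceptKind.VITALS: 0.05,
    ConceptKind.PYXIS: 0.10,
    ConceptKind.DIAGNOSIS: 0.02,
}

HIGH_RISK_COMPLAINTS = (
    "chest pain", "shortness of breath", "altered mental status",
    "severe abdominal pain", "syncope", "gastrointestinal bleeding",
)
LOW_RISK_COMPLAINTS = (
    "ankle sprain", "medication refill", "rash", "sore throat",
    "minor laceration", "back pain", "ear pain", "toothache",
)
HIGH_RISK_HOME_MEDS = (
    "warfarin", "insulin glargine", "digoxin", "methotrexate",
    "furosemide", "prednisone", "clopidogrel", "amiodarone",
)
LOW_RISK_HOME_MEDS = (
    "lisinopril", "atorvastatin", "metformin", "omeprazole",
    "amlodipine", "levothyroxine", "albuterol inhaler", "sertraline",
    "vitamin d", "multivitamin", "loratadine", "ibuprofen",
)
HIGH_RISK_ED_MEDS = (
    "norepinephrine infusion", "heparin drip", "vancomycin",
    "piperacillin-tazobactam", "labetalol drip", "insulin infusion",
)
LOW_RISK_ED_MEDS = (
    "acetaminophen", "ondansetron", "ibuprofen", "normal saline bolus",
    "ketorolac", "diphenhydramine", "omeprazole", "lidocaine patch",
)
HIGH_RISK_DX = (
    ("A41.9", 10, "sepsis unspecified organism"),
    ("I21.4", 10, "acute myocardial infarction"),
    ("J96.00", 10, "acute respiratory failure"),
    ("I61.9", 10, "intracerebral hemorrhage"),
    ("R57.0", 10, "cardiogenic shock"),
    ("584.9", 9, "acute kidney failure"),
)
LOW_RISK_DX = (
    ("S93.4", 10, "sprain of ankle"),
    ("J02.9", 10, "acute pharyngitis"),
    ("M54.5", 10, "low back pain"),
    ("L50.9", 10, "urticaria"),
    ("S61.0", 10, "open wound of finger"),
    ("H66.9", 9, "otitis media"),
    ("786.2", 9, "cough"),
    ("787.0", 9, "nausea and vomiting"),
)

_SEX = ("M", "F")
_RACE = ("WHITE", "AFRICAN AMERICAN", "ASIAN", "OTHER")
_RACE_P = (0.57, 0.19, 0.05, 0.19)
_ARRIVAL_MODES = ("WALK IN", "PRIVATE VEHICLE")


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic generator; defaults are the reference conditions.

    ``admit_prevalence`` and the decompensation prevalences among admitted
    default to MIMIC-like ratios (39.5% admitted; 44.9% discharged home,
    19.7% ICU, 2.9% mortality among admitted).  The default stream weights
    spread a strong signal across all six concepts.
    """

    n_encounters: int = 2000
    seed: int = 0
    admit_prevalence: float = 0.395
    decompensation_prevalences: tuple[float, float, float] = (0.449, 0.197, 0.029)
    stream_effect_weights: Mapping[ConceptKind, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    missingness_rates: Mapping[ConceptKind, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    n_drugs: int = 20
    n_icd: int = 14
    n_complaints: int = 14

    def __post_init__(self) -> None:
        for p in (self.admit_prevalence, *self.decompensation_prevalences):
            if not 0.0 < p < 1.0:
                raise ValueError("prevalences must lie in (0, 1)")
        for k, w in self.stream_effect_weights.items():
            if not math.isfinite(w):
                raise ValueError(f"non-finite weight for {k}")
        for k, m in self.missingness_rates.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"missingness for {k} must lie in [0, 1]")

    def null_signal(self) -> "CohortConfig":
        """Copy with all stream weights zeroed (labels independent of data)."""
        return replace(
            self, stream_effect_weights={k: 0.0 for k in CONCEPT_ORDER}
        )

    def concentrated(self, concept: ConceptKind, weight: float = 2.0) -> "CohortConfig":
        """Copy with all signal concentrated on one stream."""
        w = {k: 0.0 for k in CONCEPT_ORDER}
        w[ConceptKind(concept)] = weight
        return replace(self, stream_effect_weights=w)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def calibrate_intercept(scores: np.ndarray, target: float, lo: float = -30.0,
                        hi: float = 30.0, tol: float = 1e-10) -> float:
    """Bisection for alpha with mean(sigmoid(alpha + scores)) == target."""
    f_lo = _sigmoid(lo + scores).mean() - target
    f_hi = _sigmoid(hi + scores).mean() - target
    if f_lo > 0 or f_hi < 0:
        raise ValueError(f"prevalence {target} unreachable within intercept bounds")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + scores).mean() - target > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / max(sd, 1e-8)


def _round_to(x: np.ndarray, step: float) -> np.ndarray:
    return np.round(x / step) * step


class _Draws:
    """All per-encounter observables plus the derived stream signals."""

    def __init__(self, rng: np.random.Generator, n: int, cfg: CohortConfig):
        # --- arrival: age term + ambulance-arrival indicator
        self.age = np.clip(_round_to(rng.normal(56, 18, n), 1), 18, 98).astype(int)
        self.sex = rng.choice(_SEX, n)
        self.race = rng.choice(_RACE, n, p=_RACE_P)
        self.ambulance = rng.random(n) < 0.25
        self.arrival_mode = np.where(
            self.ambulance, "AMBULANCE", rng.choice(_ARRIVAL_MODES, n)
        )

        # --- triage vitals, charted at clinical granularity
        self.t_hr = np.clip(_round_to(rng.normal(85, 16, n), 5), 40, 190).astype(int)
        self.t_sbp = np.clip(_round_to(rng.normal(125, 18, n), 5), 60, 220).astype(int)
        self.t_dbp = np.clip(_round_to(rng.normal(74, 10, n), 5), 35, 130).astype(int)
        self.t_rr = np.clip(np.round(rng.normal(16, 3.5, n)), 8, 45).astype(int)
        self.t_temp = np.round(np.clip(rng.normal(36.9, 0.55, n), 34.5, 41.5), 1)
        self.t_spo2 = np.clip(np.round(rng.normal(97, 2.2, n)), 75, 100).astype(int)
        self.t_abnormal = (
            (self.t_hr > 100).astype(int) + (self.t_hr < 50)
            + (self.t_sbp < 100) + (self.t_sbp > 180)
            + (self.t_rr > 20) + (self.t_spo2 < 94) + (self.t_temp >= 38.0)
        )
        # acuity mirrors the abnormal count (most informative triage token)
        self.acuity = np.clip(4 - self.t_abnormal, 1, 5).astype(int)
        p_high = _sigmoid(1.6 * self.t_abnormal - 1.2)
        hi = rng.random(n) < p_high
        self.complaint = np.where(
            hi,
            rng.choice(HIGH_RISK_COMPLAINTS, n),
            rng.choice(LOW_RISK_COMPLAINTS, n),
        )

        # --- periodic vitals: 2-6 rows, per-encounter drift
        self.n_vit = 2 + rng.poisson(1.5, n)
        drift = rng.normal(0, 1, n)  # encounter-level instability
        self.v_rows: list[list[dict]] = []
        v_abn_frac = np.zeros(n)
        for i in range(n):
            rows = []
            abn = 0
            for t in range(self.n_vit[i]):
                hr = int(np.clip(_round_to(85 + 16 * drift[i] + rng.normal(0, 5), 5), 40, 190))
                sbp = int(np.clip(_round_to(124 - 13 * drift[i] + rng.normal(0, 6), 5), 60, 220))
                dbp = int(np.clip(_round_to(74 - 6 * drift[i] + rng.normal(0, 5), 5), 35, 130))
                rr = int(np.clip(round(16 + 3.5 * max(drift[i], 0) + rng.normal(0, 1.2)), 8, 45))
                temp = float(np.round(np.clip(36.9 + 0.5 * max(drift[i], 0)
                                              + rng.normal(0, 0.2), 34.5, 41.5), 1))
                spo2 = int(np.clip(round(97 - 3.5 * max(drift[i], 0) + rng.normal(0, 1.0)), 75, 100))
                abn += int(hr > 100) + int(sbp < 100) + int(rr > 20) + int(spo2 < 94) + int(temp >= 38.0)
                rows.append({
                    "heart_rate": hr, "sbp": sbp, "dbp": dbp, "resp_rate": rr,
                    "temperature": temp, "spo2": spo2,
                })
            self.v_rows.append(rows)
            v_abn_frac[i] = abn / len(rows)
        self.v_abn_frac = v_abn_frac

        # --- medication reconciliation: benign meds + high-risk indicator
        self.n_home_meds = rng.poisson(2.5, n)
        self.home_meds = [
            list(rng.choice(LOW_RISK_HOME_MEDS, k)) for k in self.n_home_meds
        ]
        self.med_highrisk = rng.random(n) < 0.25
        n_extra = 1 + rng.integers(0, 2, n)
        for i in np.flatnonzero(self.med_highrisk):
            self.home_meds[i].extend(
                rng.choice(HIGH_RISK_HOME_MEDS, n_extra[i], replace=False)
            )

        # --- pyxis: benign ED meds + high-risk indicator
        self.n_ed_meds = 1 + rng.poisson(1.2, n)
        self.ed_meds = [
            list(rng.choice(LOW_RISK_ED_MEDS, k)) for k in self.n_ed_meds
        ]
        self.pyxis_highrisk = rng.random(n) < 0.25
        for i in np.flatnonzero(self.pyxis_highrisk):
            self.ed_meds[i].append(str(rng.choice(HIGH_RISK_ED_MEDS)))

        # --- diagnoses: benign codes + high-risk indicator
        self.n_dx = 1 + rng.poisson(0.8, n)
        self.dx_highrisk = rng.random(n) < 0.25
        self.dx_rows: list[list[tuple]] = []
        for i in range(n):
            picks = [
                LOW_RISK_DX[j]
                for j in rng.integers(0, len(LOW_RISK_DX), self.n_dx[i])
            ]
            if self.dx_highrisk[i]:
                picks[0] = HIGH_RISK_DX[int(rng.integers(0, len(HIGH_RISK_DX)))]
            self.dx_rows.append(picks)

    def signals(self) -> dict[ConceptKind, np.ndarray]:
        """Standardized per-stream signals computed from the observables."""
        return {
            ConceptKind.ARRIVAL: _standardize(
                _standardize(self.age.astype(float)) + 1.4 * self.ambulance
            ),
            ConceptKind.TRIAGE: _standardize(self.t_abnormal.astype(float)),
            ConceptKind.MEDRECON: _standardize(self.med_highrisk.astype(float)),
            ConceptKind.VITALS: _standardize(self.v_abn_frac),
            ConceptKind.PYXIS: _standardize(self.pyxis_highrisk.astype(float)),
            ConceptKind.DIAGNOSIS: _standardize(self.dx_highrisk.astype(float)),
        }


def generate_cohort(
    config: CohortConfig = CohortConfig(),
) -> tuple[list[EncounterBundle], dict[EncounterKey, LabelSet]]:
    """Draw a cohort of encounter bundles with hierarchical labels."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_encounters

    draws = _Draws(rng, n, cfg)
    s = draws.signals()
    w = {k: float(cfg.stream_effect_weights.get(k, 0.0)) for k in CONCEPT_ORDER}
    risk = np.sum([w[k] * s[k] for k in CONCEPT_ORDER], axis=0)

    alpha = calibrate_intercept(risk, cfg.admit_prevalence)
    admitted = rng.random(n) < _sigmoid(alpha + risk)

    # decompensation links among admitted: discharge-home is anti-severity
    decomp: dict[str, np.ndarray] = {}
    adm_idx = np.flatnonzero(admitted)
    link_sign = {"discharge_home": -1.0, "icu": 1.0, "mortality": 1.0}
    for name, target in zip(DECOMP_LABELS, cfg.decompensation_prevalences):
        if adm_idx.size:
            score = link_sign[name] * risk[adm_idx]
            a = calibrate_intercept(score, target)
            decomp[name] = rng.random(adm_idx.size) < _sigmoid(a + score)
        else:
            decomp[name] = np.zeros(0, dtype=bool)

    drop = {
        k: rng.random(n) < float(cfg.missingness_rates.get(k, 0.0))
        for k in CONCEPT_ORDER
    }

    bundles: list[EncounterBundle] = []
    labels: dict[EncounterKey, LabelSet] = {}
    adm_pos = {int(i): j for j, i in enumerate(adm_idx)}
    base_day = pd.Timestamp("2140-01-01")

    for i in range(n):
        eid = f"E{i:06d}"
        pid = f"P{rng.integers(0, max(2, n // 2)):06d}"
        key = EncounterKey(eid, pid)
        t0 = base_day + pd.Timedelta(minutes=int(rng.integers(0, 525600)))
        bundle = EncounterBundle(key=key)

        stay: dict = {
            "encounter_id": eid,
            "patient_id": pid,
            "arrival_time": t0.isoformat(sep=" "),
            "depart_time": (t0 + pd.Timedelta(hours=int(rng.integers(2, 12)))).isoformat(sep=" "),
            "disposition": "ADMITTED" if admitted[i] else "HOME",
        }
        if admitted[i]:
            j = adm_pos[i]
            for name in DECOMP_LABELS:
                stay[name] = int(decomp[name][j])
        if drop[ConceptKind.ARRIVAL][i]:
            stay.update(age=None, sex=None, race=None, arrival_mode=None)
        else:
            stay.update(
                age=int(draws.age[i]), sex=str(draws.sex[i]),
                race=str(draws.race[i]),
                arrival_mode=str(draws.arrival_mode[i]),
            )
        bundle.rows[ConceptKind.ARRIVAL].append(stay)

        if not drop[ConceptKind.TRIAGE][i]:
            bundle.rows[ConceptKind.TRIAGE].append({
                "heart_rate": int(draws.t_hr[i]), "sbp": int(draws.t_sbp[i]),
                "dbp": int(draws.t_dbp[i]), "resp_rate": int(draws.t_rr[i]),
                "temperature": float(draws.t_temp[i]), "spo2": int(draws.t_spo2[i]),
                "acuity": int(draws.acuity[i]),
                "chief_complaint": str(draws.complaint[i]),
            })
        if not drop[ConceptKind.VITALS][i]:
            for t, row in enumerate(draws.v_rows[i]):
                rec = dict(row)
                rec["charttime"] = (t0 + pd.Timedelta(minutes=45 * (t + 1))).isoformat(sep=" ")
                bundle.rows[ConceptKind.VITALS].append(rec)
        if not drop[ConceptKind.MEDRECON][i]:
            for name in draws.home_meds[i]:
                bundle.rows[ConceptKind.MEDRECON].append({
                    "drug_name": str(name),
                    "drug_code": f"G{zlib.crc32(str(name).encode()) % 90000 + 10000}",
                })
        if not drop[ConceptKind.PYXIS][i]:
            for t, name in enumerate(draws.ed_meds[i]):
                bundle.rows[ConceptKind.PYXIS].append({
                    "charttime": (t0 + pd.Timedelta(minutes=30 * (t + 1))).isoformat(sep=" "),
                    "drug_name": str(name),
                })
        if not drop[ConceptKind.DIAGNOSIS][i]:
            for rank, (code, version, title) in enumerate(draws.dx_rows[i], start=1):
                bundle.rows[ConceptKind.DIAGNOSIS].append({
                    "icd_code": code, "icd_version": version,
                    "icd_title": title, "seq_num": rank,
                })

        bundles.append(bundle)
        if admitted[i]:
            j = adm_pos[i]
            labels[key] = LabelSet(
                disposition=1,
                decompensation={m: int(decomp[m][j]) for m in DECOMP_LABELS},
            )
        else:
            labels[key] = LabelSet(disposition=0)

    return bundles, labels


# ---------------------------------------------------------------------------
# on-disk fixtures

FIXTURE_SIZES = {"tiny": 60, "small": 2000}


def make_fixture(
    out_dir: str | Path, size: str = "tiny", seed: int = 0,
    config: CohortConfig | None = None,
) -> Path:
    """Write a cohort to disk as the six mimic_ed-dialect CSVs + labels.csv.

    The result is readable by :func:`meme_ed.schema_io.read_cohort` with
    ``schema_variant="mimic_ed"``.
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(FIXTURE_SIZES)}")
    cfg = config or CohortConfig()
    cfg = replace(cfg, n_encounters=FIXTURE_SIZES[size], seed=seed)
    bundles, labels = generate_cohort(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # canonical -> dialect column names (inverse of the variant map)
    from meme_ed.schema_io import load_schema_variant

    variant = load_schema_variant("mimic_ed")
    frames: dict[ConceptKind, list[dict]] = {k: [] for k in CONCEPT_ORDER}
    for b in bundles:
        for kind in CONCEPT_ORDER:
            for row in b.rows[kind]:
                rec = dict(row)
                rec["encounter_id"] = b.key.encounter_id
                frames[kind].append(rec)

    for kind in CONCEPT_ORDER:
        colmap = variant["columns"][kind.value]
        df = pd.DataFrame(frames[kind])
        keep = [c for c in colmap if c in df.columns] or list(colmap)
        df = df.reindex(columns=keep).rename(columns=colmap)
        df.to_csv(out / variant["files"][kind.value], index=False)

    lab_rows = []
    for b in bundles:
        lab = labels[b.key]
        rec = {"encounter_id": b.key.encounter_id, "disposition": lab.disposition}
        if lab.decompensation:
            rec.update(lab.decompensation)
        lab_rows.append(rec)
    pd.DataFrame(lab_rows).to_csv(out / "labels.csv", index=False)
    return out
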