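"""Typed readers for the six ED concept tables, labels, and cohort splitting.

The on-disk dialect is six CSV tables keyed by an encounter identifier
(arrival/stay metadata, triage, medication reconciliation, periodic vitals,
dispensed medications, diagnoses).  Column names per table are declared in a
YAML schema-variant file so that institutional dialects can be mapped onto
the same canonical field names without code changes.  The ``ucla_like``
variant has no medication-reconciliation table; its bundles carry that
stream flagged absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from meme_ed.concepts import CONCEPT_ORDER, ConceptKind

logger = logging.getLogger(__name__)

DECOMP_LABELS: tuple[str, ...] = ("discharge_home", "icu", "mortality")

#: canonical per-concept fields (beyond encounter_id) used throughout
CANONICAL_COLUMNS: dict[ConceptKind, tuple[str, ...]] = {
    ConceptKind.ARRIVAL: (
        "patient_id", "age", "sex", "race", "arrival_mode",
        "arrival_time", "depart_time", "disposition",
        "discharge_home", "icu", "mortality",
    ),
    ConceptKind.TRIAGE: (
        "heart_rate", "sbp", "dbp", "resp_rate", "temperature",
        "spo2", "acuity", "chief_complaint",
    ),
    ConceptKind.MEDRECON: ("drug_name", "drug_code"),
    ConceptKind.VITALS: (
        "charttime", "heart_rate", "sbp", "dbp", "resp_rate",
        "temperature", "spo2",
    ),
    ConceptKind.PYXIS: ("charttime", "drug_name"),
    ConceptKind.DIAGNOSIS: ("icd_code", "icd_version", "icd_title", "seq_num"),
}

#: concepts whose rows are ordered by a timestamp column
_TIME_COLUMN: dict[ConceptKind, str] = {
    ConceptKind.VITALS: "charttime",
    ConceptKind.PYXIS: "charttime",
}


class SchemaError(ValueError):
    """A concept file does not match the declared schema variant."""


class LabelError(ValueError):
    """Stay fields are insufficient to construct a label set."""


@dataclass(frozen=True)
class EncounterKey:
    """Identifies one ED encounter; links rows across the six tables."""

    encounter_id: str
    patient_id: str = ""


@dataclass
class EncounterBundle:
    """All rows for one encounter across the six concept streams.

    ``rows`` always has all six keys; an empty list means the stream has no
    rows for this encounter.  ``absent_streams`` marks streams the source
    schema does not record at all (e.g. medrecon in UCLA-like exports), as
    opposed to streams that are merely empty for this encounter.
    """

    key: EncounterKey
    rows: dict[ConceptKind, list[dict]] = field(default_factory=dict)
    absent_streams: frozenset = frozenset()

    def __post_init__(self) -> None:
        for kind in CONCEPT_ORDER:
            self.rows.setdefault(kind, [])

    @property
    def demographics(self) -> dict:
        arr = self.rows[ConceptKind.ARRIVAL]
        return arr[0] if arr else {}


@dataclass(frozen=True)
class LabelSet:
    """Hierarchical outcome labels for one encounter.

    ``disposition`` is 1 for hospital admission, 0 for discharge home.
    ``decompensation`` holds the three binary labels (discharge_home, icu,
    mortality) and is ``None`` — absent, not zero — for non-admitted
    encounters.
    """

    disposition: int
    decompensation: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.disposition == 0 and self.decompensation is not None:
            raise LabelError("decompensation labels defined for a non-admitted encounter")
        if self.disposition == 1:
            if self.decompensation is None or set(self.decompensation) != set(DECOMP_LABELS):
                raise LabelError(
                    "admitted encounter requires all three decompensation labels"
                )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test proportions and the shuffling seed."""

    proportions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("split proportions must sum to 1")


# ---------------------------------------------------------------------------
# schema variants


def load_schema_variant(variant: str | Path | Mapping) -> dict:
    """Resolve a schema variant to its config dict.

    ``variant`` may be a built-in name (``mimic_ed``, ``ucla_like``), a path
    to a YAML file, or an already-loaded mapping.
    """
    if isinstance(variant, Mapping):
        return dict(variant)
    if isinstance(variant, Path) or str(variant).endswith((".yaml", ".yml")):
        with open(variant) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("meme_ed").joinpath(f"data/schema_{variant}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise SchemaError(f"unknown schema variant: {variant!r}") from None
    return yaml.safe_load(text)


def _variant_concepts(cfg: Mapping) -> list[ConceptKind]:
    return [ConceptKind(c) for c in cfg["files"]]


# ---------------------------------------------------------------------------
# reading


def read_cohort(
    paths: Mapping | str | Path,
    schema_variant: str | Path | Mapping = "mimic_ed",
) -> list[EncounterBundle]:
    """Read per-concept CSV files into one :class:`EncounterBundle` per encounter.

    ``paths`` is either a mapping from concept name to CSV path, or a
    directory containing the variant's declared file names.  Rows whose
    encounter identifier does not occur in the arrival table are dropped
    with a logged count.  Duplicate rows are kept as-is.
    """
    cfg = load_schema_variant(schema_variant)
    concepts = _variant_concepts(cfg)
    absent = frozenset(k for k in CONCEPT_ORDER if k not in concepts)

    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {kind: base / cfg["files"][kind.value] for kind in concepts}
    else:
        paths = {ConceptKind(k): Path(v) for k, v in paths.items()}

    if ConceptKind.ARRIVAL not in paths:
        raise SchemaError("an arrival/stay table is required")
    missing_concepts = [k for k in concepts if k not in paths]
    if missing_concepts and missing_concepts != [ConceptKind.MEDRECON]:
        raise SchemaError(f"no path given for concepts: {missing_concepts}")
    if ConceptKind.MEDRECON in concepts and ConceptKind.MEDRECON not in paths:
        # tolerate a missing medrecon path by treating the stream as absent
        concepts = [k for k in concepts if k is not ConceptKind.MEDRECON]
        absent = absent | {ConceptKind.MEDRECON}

    tables: dict[ConceptKind, pd.DataFrame] = {}
    for kind in concepts:
        colmap: Mapping[str, str] = cfg["columns"][kind.value]
        path = paths[kind]
        df = pd.read_csv(path, dtype={colmap["encounter_id"]: str})
        for canonical, actual in colmap.items():
            if actual not in df.columns:
                raise SchemaError(f"{path}: missing required column {actual!r}")
        df = df.rename(columns={v: k for k, v in colmap.items()})
        tables[kind] = df

    arrival = tables[ConceptKind.ARRIVAL]
    known = dict.fromkeys(arrival["encounter_id"])  # insertion-ordered, unique
    bundles: dict[str, EncounterBundle] = {}
    for rec in arrival.to_dict("records"):
        eid = rec["encounter_id"]
        key = EncounterKey(eid, str(rec.get("patient_id", "")))
        if eid not in bundles:
            bundles[eid] = EncounterBundle(key=key, absent_streams=absent)
        bundles[eid].rows[ConceptKind.ARRIVAL].append(_clean_row(rec))

    for kind in concepts:
        if kind is ConceptKind.ARRIVAL:
            continue
        df = tables[kind]
        orphans = 0
        for rec in df.to_dict("records"):
            eid = rec.pop("encounter_id")
            if eid not in known:
                orphans += 1
                continue
            bundles[eid].rows[kind].append(_clean_row(rec))
        if orphans:
            logger.info("%s: dropped %d rows with unknown encounter_id", kind.value, orphans)

    for bundle in bundles.values():
        for kind, tcol in _TIME_COLUMN.items():
            rows = bundle.rows[kind]
            if len(rows) > 1:
                rows.sort(key=lambda r: (r.get(tcol) is None, r.get(tcol, "")))
    return list(bundles.values())


def _clean_row(rec: dict) -> dict:
    """NaN → None so downstream rendering sees explicit missingness."""
    return {
        k: (None if (isinstance(v, float) and np.isnan(v)) else v)
        for k, v in rec.items()
    }


# ---------------------------------------------------------------------------
# labels


def build_labels(
    stay_fields: Mapping,
    admit_codes: Iterable[str] = ("ADMITTED",),
) -> LabelSet:
    """Construct the hierarchical label set from a stay record.

    ``disposition`` is 1 iff the stay's disposition code is in
    ``admit_codes`` (the code vocabulary is dialect configuration).  The
    decompensation triple is populated only for admitted encounters; an
    admitted stay missing any outcome field is a labelling error.
    """
    code = stay_fields.get("disposition")
    if code is None:
        raise LabelError(
            f"stay record has no disposition field "
            f"(encounter {stay_fields.get('encounter_id', '?')})"
        )
    admitted = str(code).strip().upper() in {c.upper() for c in admit_codes}
    if not admitted:
        return LabelSet(disposition=0)
    decomp: dict[str, int] = {}
    missing = []
    for name in DECOMP_LABELS:
        v = stay_fields.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            missing.append(name)
        else:
            decomp[name] = int(float(v))
    if missing:
        raise LabelError(
            f"admitted encounter {stay_fields.get('encounter_id', '?')} "
            f"missing outcome fields: {missing}"
        )
    return LabelSet(disposition=1, decompensation=decomp)


def labels_for_cohort(
    bundles: Sequence[EncounterBundle],
    admit_codes: Iterable[str] = ("ADMITTED",),
) -> dict[EncounterKey, LabelSet]:
    return {b.key: build_labels(b.demographics, admit_codes) for b in bundles}


# ---------------------------------------------------------------------------
# splitting


def split_sizes(
    n: int, proportions: Sequence[float] = (0.70, 0.15, 0.15)
) -> tuple[int, ...]:
    """Partition sizes by the largest-remainder rule.

    Each proportion gets the floor of its ideal share; leftover units go to
    the largest fractional remainders, ties broken by partition order
    (train, then validation, then test).  Sizes sum exactly to ``n``.
    """
    if n < len(proportions):
        raise ValueError(f"cohort of {n} cannot fill {len(proportions)} partitions")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    ideal = [p * n for p in proportions]
    sizes = [int(np.floor(x)) for x in ideal]
    remainders = [x - s for x, s in zip(ideal, sizes)]
    leftover = n - sum(sizes)
    # stable order on (-remainder, index); rounding stabilises float ties
    order = sorted(range(len(sizes)), key=lambda i: (-round(remainders[i], 9), i))
    for i in order[:leftover]:
        sizes[i] += 1
    return tuple(sizes)


def split_cohort(
    keys: Sequence[EncounterKey], spec: SplitSpec = SplitSpec()
) -> tuple[list[EncounterKey], list[EncounterKey], list[EncounterKey]]:
    """Seeded shuffle-and-cut split at the largest-remainder boundaries.

    Visits are treated independently (no patient-level grouping), so the
    same patient may appear in more than one partition.  Identical inputs
    and seed reproduce identical partitions.
    """
    if len(set(keys)) != len(keys):
        raise ValueError("encounter keys must be unique")
    sizes = split_sizes(len(keys), spec.proportions)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(keys))
    shuffled = [keys[i] for i in perm]
    a, b = sizes[0], sizes[0] + sizes[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]


def write_split_manifest(
    path: str | Path,
    partitions: Sequence[Sequence[EncounterKey]],
    seed: int,
    names: Sequence[str] = ("train", "val", "test"),
) -> None:
    rows = [
        {"encounter_id": k.encounter_id, "partition": name, "seed": seed}
        for name, part in zip(names, partitions)
        for k in part
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort summary


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in summary tables."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def cohort_summary(
    bundles: Sequence[EncounterBundle],
    labels: Mapping[EncounterKey, LabelSet],
) -> dict:
    """Demographic and outcome summary of a cohort.

    Demographics and disposition use the whole cohort as denominator;
    decompensation outcomes use the admitted subset.  Percentages are
    rounded half-up to one decimal.
    """
    if not bundles:
        raise ValueError("empty cohort")
    n = len(bundles)
    ages = [b.demographics.get("age") for b in bundles]
    ages = np.asarray([a for a in ages if a is not None], dtype=float)
    if ages.size == 0:
        raise ValueError("no age data in cohort")
    q1, med, q3 = np.percentile(ages, [25, 50, 75])

    def _categorical(field_name: str) -> dict[str, tuple[int, float]]:
        counts: dict[str, int] = {}
        for b in bundles:
            v = b.demographics.get(field_name)
            if v is not None:
                counts[str(v)] = counts.get(str(v), 0) + 1
        return {k: (c, percent(c, n)) for k, c in sorted(counts.items())}

    admitted = [k for k, lab in labels.items() if lab.disposition == 1]
    n_admit = len(admitted)
    outcomes: dict[str, tuple[int, float]] = {
        "admitted": (n_admit, percent(n_admit, n))
    }
    if n_admit:
        for name in DECOMP_LABELS:
            c = sum(labels[k].decompensation[name] for k in admitted)
            outcomes[name] = (c, percent(c, n_admit))

    return {
        "n": n,
        "age_median": float(med),
        "age_iqr": (float(q1), float(q3)),
        "sex": _categorical("sex"),
        "race": _categorical("race"),
        "outcomes": outcomes,
    }
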