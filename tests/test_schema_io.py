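"""Readers, labels, splitting and summary arithmetic."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meme_ed.concepts import ConceptKind
from meme_ed.schema_io import (
    EncounterKey,
    LabelError,
    LabelSet,
    SchemaError,
    SplitSpec,
    build_labels,
    cohort_summary,
    labels_for_cohort,
    percent,
    read_cohort,
    split_cohort,
    split_sizes,
)


# ---------------------------------------------------------------------------
# split arithmetic


@pytest.mark.parametrize(
    "n, expected",
    [
        (400_019, (280_013, 60_003, 60_003)),
        (158_007, (110_605, 23_701, 23_701)),
        (10, (7, 2, 1)),
    ],
)
def test_split_sizes_largest_remainder(n, expected):
    """70/15/15 sizing by largest remainder, ties broken train>val>test."""
    assert split_sizes(n) == expected


@settings(max_examples=200, derandomize=True)
@given(n=st.integers(min_value=3, max_value=10**7))
def test_split_sizes_sum_and_rounding_bound(n):
    sizes = split_sizes(n)
    assert sum(sizes) == n
    for s, p in zip(sizes, (0.70, 0.15, 0.15)):
        assert abs(s - p * n) < 1.0


def test_split_sizes_rejects_tiny_cohorts():
    with pytest.raises(ValueError):
        split_sizes(2)


def _keys(n):
    return [EncounterKey(f"E{i}", f"P{i}") for i in range(n)]


def test_split_cohort_deterministic_disjoint_exhaustive():
    keys = _keys(101)
    spec = SplitSpec(seed=5)
    a1 = split_cohort(keys, spec)
    a2 = split_cohort(keys, spec)
    assert [set(p) for p in a1] == [set(p) for p in a2]
    assert tuple(len(p) for p in a1) == split_sizes(101)
    union = set(a1[0]) | set(a1[1]) | set(a1[2])
    assert union == set(keys)
    assert not (set(a1[0]) & set(a1[1])) and not (set(a1[1]) & set(a1[2]))


def test_split_cohort_varies_with_seed():
    keys = _keys(50)
    base = [set(p) for p in split_cohort(keys, SplitSpec(seed=0))]
    differing = sum(
        [set(p) for p in split_cohort(keys, SplitSpec(seed=s))] != base
        for s in range(1, 21)
    )
    assert differing >= 19  # identical shuffles over 20 seeds would be astonishing


def test_split_cohort_requires_unique_keys():
    keys = _keys(5) + [_keys(1)[0]]
    with pytest.raises(ValueError):
        split_cohort(keys, SplitSpec())


# ---------------------------------------------------------------------------
# reading


def test_read_cohort_round_trips_fixture(tiny_fixture_dir):
    bundles = read_cohort(tiny_fixture_dir, "mimic_ed")
    assert len(bundles) == 60
    assert all(set(b.rows) == set(ConceptKind) for b in bundles)


def _write_toy(tmp_path, diagnosis_extra=None):
    (tmp_path / "edstays.csv").write_text(
        "stay_id,subject_id,age,gender,race,arrival_transport,intime,outtime,"
        "disposition,discharge_home,icu,mortality\n"
        "s1,p1,40,M,WHITE,WALK IN,2140-01-01 10:00:00,2140-01-01 14:00:00,HOME,,,\n"
        "s2,p2,71,F,ASIAN,AMBULANCE,2140-01-02 09:00:00,2140-01-02 20:00:00,ADMITTED,1,0,0\n"
        "s3,p3,55,M,OTHER,WALK IN,2140-01-03 08:00:00,2140-01-03 11:00:00,HOME,,,\n"
    )
    (tmp_path / "triage.csv").write_text(
        "stay_id,heartrate,sbp,dbp,resprate,temperature,o2sat,acuity,chiefcomplaint\n"
        "s1,88,120,80,14,36.8,99,4,ankle sprain\n"
    )
    (tmp_path / "medrecon.csv").write_text("stay_id,name,gsn\n")
    (tmp_path / "vitalsign.csv").write_text(
        "stay_id,charttime,heartrate,sbp,dbp,resprate,temperature,o2sat\n"
    )
    (tmp_path / "pyxis.csv").write_text("stay_id,charttime,name\n")
    rows = "stay_id,icd_code,icd_version,icd_title,seq_num\n"
    if diagnosis_extra:
        rows += diagnosis_extra
    (tmp_path / "diagnosis.csv").write_text(rows)


def test_read_cohort_empty_concept_files(tmp_path):
    """Empty per-concept tables yield bundles with empty row lists."""
    _write_toy(tmp_path)
    bundles = read_cohort(tmp_path, "mimic_ed")
    assert len(bundles) == 3
    assert all(b.rows[ConceptKind.PYXIS] == [] for b in bundles)


def test_read_cohort_drops_and_logs_orphan_rows(tmp_path, caplog):
    _write_toy(tmp_path, diagnosis_extra="sX,A41.9,10,sepsis,1\n")
    with caplog.at_level(logging.INFO, logger="meme_ed.schema_io"):
        bundles = read_cohort(tmp_path, "mimic_ed")
    assert all(not b.rows[ConceptKind.DIAGNOSIS] for b in bundles)
    assert any("unknown encounter_id" in r.message for r in caplog.records)


def test_read_cohort_missing_column_names_file_and_column(tmp_path):
    _write_toy(tmp_path)
    (tmp_path / "triage.csv").write_text("stay_id,heartrate\ns1,88\n")
    with pytest.raises(SchemaError, match="triage.csv.*sbp"):
        read_cohort(tmp_path, "mimic_ed")


def test_ucla_like_variant_flags_medrecon_absent(tmp_path):
    (tmp_path / "encounters.csv").write_text(
        "visit_id,mrn,age_years,sex,race,mode_of_arrival,arrival_dttm,"
        "depart_dttm,ed_disposition,discharge_home,icu,mortality\n"
        "v1,m1,62,F,WHITE,AMBULANCE,2140-01-01 10:00:00,2140-01-01 16:00:00,ADMIT,0,1,0\n"
    )
    (tmp_path / "triage.csv").write_text(
        "visit_id,pulse,bp_systolic,bp_diastolic,respirations,temp,pulse_ox,"
        "esi_level,reason_for_visit\nv1,110,92,60,24,38.5,91,2,chest pain\n"
    )
    (tmp_path / "vitals.csv").write_text(
        "visit_id,recorded_dttm,pulse,bp_systolic,bp_diastolic,respirations,temp,pulse_ox\n"
    )
    (tmp_path / "meds_dispensed.csv").write_text("visit_id,dispense_dttm,medication\n")
    (tmp_path / "diagnoses.csv").write_text(
        "visit_id,icd_code,icd_version,dx_name,dx_rank\n"
    )
    bundles = read_cohort(tmp_path, "ucla_like")
    assert len(bundles) == 1
    assert ConceptKind.MEDRECON in bundles[0].absent_streams
    assert bundles[0].rows[ConceptKind.MEDRECON] == []


# ---------------------------------------------------------------------------
# labels


def test_build_labels_home_has_no_decompensation():
    lab = build_labels({"disposition": "HOME"})
    assert lab.disposition == 0 and lab.decompensation is None


def test_build_labels_admitted_carries_triple():
    lab = build_labels({
        "disposition": "ADMITTED", "discharge_home": 1, "icu": 1, "mortality": 0,
    })
    assert lab.disposition == 1
    assert lab.decompensation == {"discharge_home": 1, "icu": 1, "mortality": 0}


def test_build_labels_mortality_recorded():
    lab = build_labels({
        "disposition": "ADMITTED", "discharge_home": 0, "icu": 1, "mortality": 1,
    })
    assert lab.decompensation["mortality"] == 1


def test_build_labels_admitted_missing_outcomes_errors():
    with pytest.raises(LabelError, match="icu"):
        build_labels({"disposition": "ADMITTED", "discharge_home": 1,
                      "mortality": 0, "encounter_id": "e9"})


def test_labelset_forbids_decompensation_for_non_admitted():
    with pytest.raises(LabelError):
        LabelSet(disposition=0, decompensation={"discharge_home": 0, "icu": 0,
                                                "mortality": 0})


def test_no_decompensation_labels_on_full_synthetic_cohort(tiny_cohort):
    bundles, labels = tiny_cohort
    for b in bundles:
        lab = labels[b.key]
        if lab.disposition == 0:
            assert lab.decompensation is None
        else:
            assert set(lab.decompensation) == {"discharge_home", "icu", "mortality"}


# ---------------------------------------------------------------------------
# summary


@pytest.mark.parametrize(
    "num, den, expected",
    [
        (158_007, 400_019, 39.5),
        (70_945, 158_007, 44.9),
        (31_127, 158_007, 19.7),
        (4_582, 158_007, 2.9),
        (195_189, 400_019, 48.8),
    ],
)
def test_percent_half_up_one_decimal(num, den, expected):
    assert percent(num, den) == expected


def test_cohort_summary_denominators(tiny_cohort):
    bundles, labels = tiny_cohort
    summary = cohort_summary(bundles, labels)
    n = summary["n"]
    n_admit = summary["outcomes"]["admitted"][0]
    assert n == 60
    assert summary["outcomes"]["admitted"][1] == percent(n_admit, n)
    # decompensation outcomes use the admitted subset as denominator
    icu_count, icu_pct = summary["outcomes"]["icu"]
    assert icu_pct == percent(icu_count, n_admit)
    sex_counts = sum(c for c, _ in summary["sex"].values())
    assert sex_counts == n


def test_cohort_summary_singleton_age():
    key = EncounterKey("e1", "p1")
    from meme_ed.schema_io import EncounterBundle

    b = EncounterBundle(key=key)
    b.rows[ConceptKind.ARRIVAL].append(
        {"encounter_id": "e1", "age": 40, "sex": "F", "disposition": "HOME"}
    )
    summary = cohort_summary([b], labels_for_cohort([b]))
    assert summary["age_median"] == 40
    assert summary["age_iqr"] == (40.0, 40.0)


def test_cohort_summary_empty_cohort_errors():
    with pytest.raises(ValueError):
        cohort_summary([], {})
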