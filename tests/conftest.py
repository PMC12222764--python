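"""Shared fixtures: tiny cohorts for unit tests, heavy shared runs for the
acceptance suite (computed once per session and reused across tests)."""

from __future__ import annotations

import numpy as np
import pytest

from meme_ed.concepts import CONCEPT_ORDER
from meme_ed.encoders import EncoderSpec
from meme_ed.evaluation import (
    BenchmarkConfig,
    _task_arrays,
    auprc,
    auroc,
    prepare_cohort,
)
from meme_ed.meme_model import (
    MemeHyperparams,
    predict_proba,
    single_concept_input,
    train_head,
)
from meme_ed.pseudonotes import default_templates
from meme_ed.schema_io import SplitSpec
from meme_ed.synthetic_cohort import CohortConfig, generate_cohort, make_fixture


@pytest.fixture(scope="session")
def tiny_cohort():
    """60 encounters, default generator conditions."""
    return generate_cohort(CohortConfig(n_encounters=60, seed=3))


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return make_fixture(out, size="tiny", seed=3)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def small_encoder():
    """Low-dimensional hashed encoder for fast unit tests."""
    return EncoderSpec(dim=64, seed=0)


def train_all_variants(seed: int) -> dict[str, tuple[float, float]]:
    """One shared cohort/split per seed; disposition AUROC/AUPRC per variant."""
    config = BenchmarkConfig(
        cohort=CohortConfig(n_encounters=2000, seed=seed),
        split=SplitSpec(seed=seed),
        seed=seed,
    )
    art = prepare_cohort(config)
    parts = _task_arrays(art, "disposition")
    (tr, ytr), (va, yva), (te, yte) = parts["train"], parts["val"], parts["test"]
    hp = MemeHyperparams(task_mode="binary", seed=seed)
    out = {}
    for name in ("meme", "msem", *(f"single:{k.value}" for k in CONCEPT_ORDER)):
        if name == "meme":
            X = art.X6
        elif name == "msem":
            X = art.Xmsem
        else:
            X = single_concept_input(art.X6, name.split(":", 1)[1])
        state = train_head(X[tr], ytr, X[va], yva, hp, kind=name)
        scores = predict_proba(state, X[te])[:, 0]
        out[name] = (auroc(yte[:, 0], scores), auprc(yte[:, 0], scores))
    return out


@pytest.fixture(scope="session")
def variant_runs():
    """Disposition metrics for every head variant over five seeds.

    This is the expensive shared computation behind the signal-recovery and
    fusion-ordering checks; everything downstream reads from it.
    """
    return {seed: train_all_variants(seed) for seed in range(5)}


@pytest.fixture(scope="session")
def null_signal_run():
    """MEME trained on a cohort whose labels are independent of the data."""
    config = BenchmarkConfig(
        cohort=CohortConfig(n_encounters=2000, seed=0).null_signal(),
        split=SplitSpec(seed=0),
        seed=0,
    )
    art = prepare_cohort(config)
    parts = _task_arrays(art, "disposition")
    (tr, ytr), (va, yva), (te, yte) = parts["train"], parts["val"], parts["test"]
    state = train_head(
        art.X6[tr], ytr, art.X6[va], yva,
        MemeHyperparams(task_mode="binary", seed=0), kind="meme",
    )
    return auroc(yte[:, 0], predict_proba(state, art.X6[te])[:, 0])
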