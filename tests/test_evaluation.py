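"""Metrics, threshold grid, bootstrap, leakage guard, few-shot mechanics."""

import numpy as np
import pytest
from scipy.stats import rankdata

from meme_ed.evaluation import (
    PartitionLeakageError,
    SingleClassError,
    auprc,
    auroc,
    bootstrap_ci,
    evaluate_model,
    f1_at,
    few_shot_curve,
    select_threshold,
    FEW_SHOT_SIZES,
)
from meme_ed.meme_model import MemeHyperparams, train_head


def _oracle_grid_search(y, s, grid_size=1000):
    """Independent exhaustive search: per-threshold precision/recall by loops."""
    best_t, best_f1 = 0.0, -1.0
    for t in np.linspace(0.0, 1.0, grid_size):
        pred = s >= t
        tp = np.sum(pred & (y == 1))
        fp = np.sum(pred & (y == 0))
        fn = np.sum(~pred & (y == 1))
        f1 = 0.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
        if f1 > best_f1 + 1e-15:
            best_t, best_f1 = t, f1
    return best_t, best_f1


def test_select_threshold_matches_exhaustive_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(5, 40))
        y = rng.integers(0, 2, n)
        while y.min() == y.max():
            y = rng.integers(0, 2, n)
        s = np.round(rng.random(n), 3)
        res = select_threshold(y, s)
        t_oracle, f1_oracle = _oracle_grid_search(y, s)
        assert res.threshold == t_oracle
        assert res.f1_at_threshold == f1_oracle


def test_select_threshold_known_instances():
    res = select_threshold([1, 0, 1, 1], [0.9, 0.2, 0.8, 0.4])
    assert res.f1_at_threshold == 1.0
    assert 0.2 < res.threshold <= 0.4

    # perfectly separated 0/1 scores: ties resolve to lowest grid point > 0
    res = select_threshold([0, 1, 0, 1], [0.0, 1.0, 0.0, 1.0])
    assert res.f1_at_threshold == 1.0
    assert res.threshold == pytest.approx(1.0 / 999.0)

    # constant scores: grid points <= 0.5 predict all-positive
    y = np.array([1, 1, 0, 1])
    res = select_threshold(y, [0.5] * 4)
    all_pos_f1 = f1_at(y, np.array([0.5] * 4), 0.0)
    assert res.f1_at_threshold == all_pos_f1


def test_single_class_labels_rejected_everywhere():
    with pytest.raises(SingleClassError):
        select_threshold([1, 1, 1], [0.1, 0.2, 0.3])
    for metric in (auroc, auprc):
        with pytest.raises(SingleClassError):
            metric([0, 0], [0.1, 0.2])
    with pytest.raises(SingleClassError):
        f1_at([1, 1], [0.5, 0.5], 0.5)


def test_ranking_metric_trivial_cases():
    assert auroc([1, 0], [0.9, 0.1]) == 1.0
    assert auprc([1, 0], [0.9, 0.1]) == 1.0
    assert auroc([1, 0], [0.1, 0.9]) == 0.0
    assert auroc([1, 0], [0.5, 0.5]) == 0.5


def test_auroc_equals_mann_whitney_statistic():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = int(rng.integers(10, 60))
        y = rng.integers(0, 2, n)
        while y.min() == y.max():
            y = rng.integers(0, 2, n)
        s = np.round(rng.random(n), 2)  # ties on purpose
        ranks = rankdata(s)
        n1, n0 = int(y.sum()), int((1 - y).sum())
        u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
        assert auroc(y, s) == pytest.approx(u / (n1 * n0), abs=1e-10)


def test_f1_zero_when_no_positive_predictions():
    assert f1_at([1, 0, 1], [0.1, 0.2, 0.3], 0.9) == 0.0


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_seed_reproducible():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 100)
    s = rng.random(100)
    a = bootstrap_ci(y, s, auroc, n_resamples=100, seed=5)
    b = bootstrap_ci(y, s, auroc, n_resamples=100, seed=5)
    assert (a.lower, a.upper, a.half_width) == (b.lower, b.upper, b.half_width)
    c = bootstrap_ci(y, s, auroc, n_resamples=100, seed=6)
    assert (a.lower, a.upper) != (c.lower, c.upper)


def test_bootstrap_degenerate_zero_width():
    # perfectly separated scores: F1 is 1 on every two-class resample
    y = np.array([0, 1] * 20)
    s = y.astype(float)
    res = bootstrap_ci(y, s, lambda yy, ss: f1_at(yy, ss, 0.5),
                       n_resamples=200, seed=0)
    assert res.half_width == 0.0
    assert res.point == 1.0


def test_bootstrap_interval_contains_point_estimate():
    rng = np.random.default_rng(3)
    hits = 0
    for trial in range(100):
        y = rng.integers(0, 2, 80)
        while y.min() == y.max():
            y = rng.integers(0, 2, 80)
        s = np.clip(y * 0.3 + rng.random(80) * 0.7, 0, 1)
        r = bootstrap_ci(y, s, auroc, n_resamples=200, seed=trial)
        hits += r.lower - 1e-12 <= r.point <= r.upper + 1e-12
    assert hits >= 95


def test_bootstrap_width_shrinks_with_sample_size():
    widths = {200: [], 2000: []}
    for seed in range(5):
        rng = np.random.default_rng(seed)
        for n in widths:
            y = rng.integers(0, 2, n)
            s = np.clip(y * 0.4 + rng.random(n) * 0.8, 0, 1)
            widths[n].append(
                bootstrap_ci(y, s, auroc, n_resamples=200, seed=seed).half_width
            )
    assert np.median(widths[2000]) < np.median(widths[200])


def test_bootstrap_small_sample_warning():
    res = bootstrap_ci([0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8], auroc,
                       n_resamples=50, seed=0)
    assert res.small_sample_warning


# ---------------------------------------------------------------------------
# evaluate_model


def _scores(n, seed, m=1):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, (n, m))
    while any(y[:, j].min() == y[:, j].max() for j in range(m)):
        y = rng.integers(0, 2, (n, m))
    s = np.clip(y * 0.4 + rng.random((n, m)) * 0.8, 0, 1)
    return y, s


def test_evaluate_model_row_counts_and_metadata():
    yv, sv = _scores(60, 0)
    yt, st = _scores(80, 1)
    rep = evaluate_model(sv, yv, st, yt, "disposition", n_resamples=50, seed=0)
    assert len(rep.rows) == 1 and rep.n_resamples == 50
    assert 0.0 <= rep.rows[0].threshold <= 1.0

    yv3, sv3 = _scores(60, 2, m=3)
    yt3, st3 = _scores(80, 3, m=3)
    rep3 = evaluate_model(sv3, yv3, st3, yt3, "decompensation",
                          n_resamples=50, seed=0)
    assert [r.label for r in rep3.rows] == ["discharge_home", "icu", "mortality"]


def test_evaluate_model_detects_partition_leakage():
    yv, sv = _scores(20, 0)
    yt, st = _scores(20, 1)
    with pytest.raises(PartitionLeakageError):
        evaluate_model(
            sv, yv, st, yt, "disposition", n_resamples=10,
            partitions={"train": ["a", "b"], "val": ["c"], "test": ["b", "d"]},
        )


# ---------------------------------------------------------------------------
# few-shot mechanics (cheap synthetic embeddings; real transfer is covered
# by the acceptance suite)


def _tiny_transfer(dim=16, seed=0):
    rng = np.random.default_rng(seed)

    def block(n):
        X = rng.normal(size=(n, 6, dim)).astype(np.float32)
        w = np.ones(dim) / np.sqrt(dim)
        logits = 3.0 * X[:, 0, :] @ w
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
        return X, y

    Xs, ys = block(300)
    hp = MemeHyperparams(task_mode="binary", seed=seed, epochs=5)
    state = train_head(Xs[:240], ys[:240], Xs[240:], ys[240:], hp)
    Xt, yt = block(260)
    target = {
        "X_train": Xt[:150], "y_train": yt[:150],
        "X_val": Xt[150:200], "y_val": yt[150:200],
        "X_test": Xt[200:], "y_test": yt[200:],
    }
    return state, target


def test_few_shot_default_schedule_is_geometric():
    assert FEW_SHOT_SIZES == (2, 4, 8, 16, 32, 64, 128, 256, 512, 1024)


def test_few_shot_curve_runs_and_is_seed_reproducible():
    state, target = _tiny_transfer()
    a = few_shot_curve(state, target, sizes=(2, 8), seed=4)
    b = few_shot_curve(state, target, sizes=(2, 8), seed=4)
    assert a.equals(b)
    assert list(a["n_samples"]) == [2, 8]
    assert set(a.columns) == {"n_samples", "f1", "auroc", "auprc"}


def test_few_shot_rejects_oversized_draws():
    state, target = _tiny_transfer()
    with pytest.raises(ValueError, match="pool"):
        few_shot_curve(state, target, sizes=(4096,), seed=0)


# ---------------------------------------------------------------------------
# benchmark driver (mechanics at reduced size; performance claims live in
# the acceptance suite)


def test_run_benchmark_shape_and_columns():
    from dataclasses import replace

    from meme_ed.evaluation import (
        BenchmarkConfig,
        MODEL_NAMES,
        format_benchmark_table,
        run_benchmark,
    )
    from meme_ed.meme_model import MemeHyperparams
    from meme_ed.schema_io import SplitSpec
    from meme_ed.synthetic_cohort import CohortConfig

    # decompensation prevalences raised so every label keeps both classes
    # in every partition at this reduced cohort size
    config = BenchmarkConfig(
        cohort=CohortConfig(
            n_encounters=900, seed=13,
            decompensation_prevalences=(0.449, 0.30, 0.20),
        ),
        split=SplitSpec(seed=13),
        seed=13,
        n_resamples=30,
        hyperparams=MemeHyperparams(epochs=4, patience=2),
    )
    frame = run_benchmark(config)
    assert set(frame["model"]) == set(MODEL_NAMES)
    labels = {"disposition", "discharge_home", "icu", "mortality"}
    assert set(frame["label"]) == labels
    assert len(frame) == len(MODEL_NAMES) * len(labels)
    for col in ("f1", "auroc", "auprc", "f1_hw", "auroc_hw", "auprc_hw",
                "threshold"):
        assert frame[col].between(0, 1).all()
    wide = format_benchmark_table(frame)
    assert wide.shape == (len(MODEL_NAMES), len(labels) * 3)
    assert wide.loc["meme"].str.match(r"\d\.\d{3} \(\d\.\d{3}\)").all()


def test_split_manifest_round_trip(tmp_path):
    import pandas as pd

    from meme_ed.schema_io import (
        EncounterKey,
        SplitSpec,
        split_cohort,
        write_split_manifest,
    )

    keys = [EncounterKey(f"E{i}", f"P{i}") for i in range(20)]
    parts = split_cohort(keys, SplitSpec(seed=2))
    write_split_manifest(tmp_path / "m.csv", parts, seed=2)
    frame = pd.read_csv(tmp_path / "m.csv")
    assert set(frame.columns) == {"encounter_id", "partition", "seed"}
    assert len(frame) == 20
    assert set(frame["partition"]) == {"train", "val", "test"}
    assert (frame["seed"] == 2).all()
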