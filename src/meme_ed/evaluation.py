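"""Metrics, threshold search, bootstrap CIs, few-shot protocol, benchmark driver.

F1 is thresholded by an exhaustive grid search over 1000 evenly spaced
thresholds in [0, 1]; the threshold is always selected on validation scores
and applied to test scores.  AUROC and AUPRC are threshold-free ranking
metrics.  95% confidence intervals come from resampling the test set with
replacement (1000 resamples by default) and taking the 2.5/97.5
percentiles; the table-style parenthetical value is the interval
half-width.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from meme_ed import meme_model
from meme_ed.baselines import Featurizer, fit_baseline
from meme_ed.concepts import CONCEPT_ORDER, ConceptKind
from meme_ed.encoders import EncoderSpec, embed_cohort
from meme_ed.meme_model import (
    MemeHyperparams,
    fine_tune_head,
    predict_proba,
    single_concept_input,
    train_head,
)
from meme_ed.pseudonotes import render_encounter, render_msem_note
from meme_ed.schema_io import (
    DECOMP_LABELS,
    SplitSpec,
    split_cohort,
)
from meme_ed.synthetic_cohort import CohortConfig, generate_cohort

DEFAULT_GRID_SIZE = 1000
DEFAULT_RESAMPLES = 1000
FEW_SHOT_SIZES = tuple(2 ** k for k in range(1, 11))  # 2 .. 1024


class SingleClassError(ValueError):
    """A metric was requested on labels containing a single class."""


class PartitionLeakageError(RuntimeError):
    """The same encounter key appears in more than one partition."""


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise SingleClassError("labels contain a single class; metric undefined")
    return y


# ---------------------------------------------------------------------------
# point metrics


def f1_at(labels: Sequence[int], scores: Sequence[float], threshold: float) -> float:
    """F1 under the rule score >= threshold -> positive; 0 if no positives."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    denom = 2 * tp + int(np.sum(pred & (y == 0))) + int(np.sum(~pred & (y == 1)))
    return 0.0 if denom == 0 else 2 * tp / denom


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUROC with half-credit for ties."""
    y = _check_binary(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Step-interpolated area under the precision-recall curve."""
    y = _check_binary(labels)
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# threshold search


@dataclass(frozen=True)
class ThresholdSearchResult:
    threshold: float
    f1_at_threshold: float
    grid_size: int = DEFAULT_GRID_SIZE


def select_threshold(
    labels: Sequence[int],
    scores: Sequence[float],
    grid_size: int = DEFAULT_GRID_SIZE,
) -> ThresholdSearchResult:
    """Maximise F1 over ``grid_size`` evenly spaced thresholds in [0, 1].

    Equivalent to exhaustive evaluation over the same grid; ties resolve to
    the lowest threshold.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    grid = np.linspace(0.0, 1.0, grid_size)
    pred = s[None, :] >= grid[:, None]
    pos = y == 1
    tp = (pred & pos).sum(axis=1)
    fp = (pred & ~pos).sum(axis=1)
    fn = (~pred & pos).sum(axis=1)
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    best = int(np.argmax(f1))  # argmax takes the first (lowest) threshold on ties
    return ThresholdSearchResult(float(grid[best]), float(f1[best]), grid_size)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    lower: float
    upper: float
    half_width: float
    n_resamples: int
    small_sample_warning: bool = False


def bootstrap_ci(
    labels: Sequence[int],
    scores: Sequence[float],
    metric: Callable[[np.ndarray, np.ndarray], float],
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
    max_redraws: int = 1000,
) -> BootstrapResult:
    """Percentile bootstrap over (label, score) pairs resampled with replacement.

    Resamples that contain a single class are redrawn, so rank metrics stay
    defined on every replicate.  The half-width is half the 2.5–97.5
    percentile span.  Seed-reproducible.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    point = float(metric(y, s))
    rng = np.random.default_rng(seed)
    n = len(y)
    stats = np.empty(n_resamples)
    for b in range(n_resamples):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() != yb.max() or y.min() == y.max():
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        stats[b] = metric(yb, s[idx])
    lower, upper = np.percentile(stats, [2.5, 97.5])
    return BootstrapResult(
        point=point,
        lower=float(lower),
        upper=float(upper),
        half_width=float((upper - lower) / 2.0),
        n_resamples=n_resamples,
        small_sample_warning=n < 10,
    )


# ---------------------------------------------------------------------------
# model evaluation


@dataclass(frozen=True)
class LabelMetrics:
    label: str
    threshold: float
    f1: BootstrapResult
    auroc: BootstrapResult
    auprc: BootstrapResult


@dataclass(frozen=True)
class MetricsReport:
    task: str
    rows: tuple[LabelMetrics, ...]
    n_resamples: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "label": r.label, "threshold": r.threshold,
                "f1": r.f1.point, "f1_hw": r.f1.half_width,
                "auroc": r.auroc.point, "auroc_hw": r.auroc.half_width,
                "auprc": r.auprc.point, "auprc_hw": r.auprc.half_width,
            })
        return pd.DataFrame(recs)


def _assert_disjoint(partitions: Mapping[str, Sequence]) -> None:
    names = list(partitions)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = set(partitions[a]) & set(partitions[b])
            if overlap:
                raise PartitionLeakageError(
                    f"keys shared between {a} and {b}: {sorted(overlap)[:5]}"
                )


def evaluate_model(
    val_scores: np.ndarray,
    val_labels: np.ndarray,
    test_scores: np.ndarray,
    test_labels: np.ndarray,
    task: str = "disposition",
    *,
    partitions: Mapping[str, Sequence] | None = None,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
) -> MetricsReport:
    """Per-label threshold search on validation, metrics on test.

    ``task`` is ``"disposition"`` (one label) or ``"decompensation"``
    (three labels, evaluated on admitted encounters only — the caller
    passes admitted-subset scores).  If ``partitions`` maps partition names
    to key sequences, any overlap is a hard error.
    """
    if partitions is not None:
        _assert_disjoint(partitions)
    label_names = ("disposition",) if task == "disposition" else DECOMP_LABELS
    vs = np.asarray(val_scores, dtype=float).reshape(len(val_labels), -1)
    ts = np.asarray(test_scores, dtype=float).reshape(len(test_labels), -1)
    vy = np.asarray(val_labels).reshape(len(vs), -1)
    ty = np.asarray(test_labels).reshape(len(ts), -1)
    if vs.shape[1] != len(label_names):
        raise ValueError(
            f"task {task!r} expects {len(label_names)} score columns, got {vs.shape[1]}"
        )
    rows = []
    for j, name in enumerate(label_names):
        thr = select_threshold(vy[:, j], vs[:, j]).threshold
        rows.append(LabelMetrics(
            label=name,
            threshold=thr,
            f1=bootstrap_ci(ty[:, j], ts[:, j],
                            lambda y, s, t=thr: f1_at(y, s, t),
                            n_resamples, seed),
            auroc=bootstrap_ci(ty[:, j], ts[:, j], auroc, n_resamples, seed),
            auprc=bootstrap_ci(ty[:, j], ts[:, j], auprc, n_resamples, seed),
        ))
    return MetricsReport(task=task, rows=tuple(rows),
                         n_resamples=n_resamples, seed=seed)


# ---------------------------------------------------------------------------
# few-shot adaptation


def few_shot_curve(
    source_state: meme_model.MemeModelState,
    target: Mapping[str, np.ndarray],
    sizes: Sequence[int] = FEW_SHOT_SIZES,
    seed: int = 0,
    epochs: int = 10,
    learning_rate: float = 3e-4,
) -> pd.DataFrame:
    """Fine-tune the head on n target samples; evaluate on the target test split.

    ``target`` holds ``X_train``/``y_train`` (adaptation pool),
    ``X_val``/``y_val`` (threshold selection) and ``X_test``/``y_test``.
    For each n the sample is drawn with the seeded generator, the head is
    fine-tuned from the source state (encoder stays frozen), and F1/AUROC/
    AUPRC are measured on the fixed test split.  The trend over n is
    reported, not enforced.
    """
    pool = len(target["X_train"])
    rows = []
    for k, n in enumerate(sizes):
        if n > pool:
            raise ValueError(f"requested {n} samples but the target pool has {pool}")
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        idx = rng.choice(pool, size=n, replace=False)
        state = fine_tune_head(
            source_state,
            target["X_train"][idx],
            np.asarray(target["y_train"])[idx],
            epochs=epochs,
            learning_rate=learning_rate,
            seed=seed + k,
        )
        val_scores = predict_proba(state, target["X_val"])[:, 0]
        test_scores = predict_proba(state, target["X_test"])[:, 0]
        thr = select_threshold(target["y_val"], val_scores).threshold
        rows.append({
            "n_samples": int(n),
            "f1": f1_at(target["y_test"], test_scores, thr),
            "auroc": auroc(target["y_test"], test_scores),
            "auprc": auprc(target["y_test"], test_scores),
        })
    return pd.DataFrame(rows)


def prepare_transfer(
    n_encounters: int = 2000,
    seed: int = 0,
    encoder: EncoderSpec = EncoderSpec(),
    hyperparams: MemeHyperparams = MemeHyperparams(),
):
    """Train a source-site disposition head and embed a shifted target site.

    The source site uses the default generator conditions; the target site
    is a shifted institution — different seed, lower admission prevalence,
    no medication reconciliation (its medrecon stream is always missing),
    and a different clinical mix: outcome signal re-weighted across the
    remaining streams (vitals and dispensed medications dominate instead
    of triage and diagnoses), so the source head's learned concept
    weighting is genuinely suboptimal there and local adaptation has
    something to fix.  Returns ``(source_state, target)`` where ``target``
    holds the adaptation pool, threshold-selection split and test split.
    """
    from meme_ed.concepts import ConceptKind as _CK

    src_cfg = CohortConfig(n_encounters=n_encounters, seed=seed)
    tgt_miss = dict(src_cfg.missingness_rates)
    tgt_miss[_CK.MEDRECON] = 1.0  # target dialect lacks medrecon
    tgt_weights = {
        _CK.ARRIVAL: 1.8, _CK.TRIAGE: 0.6, _CK.MEDRECON: 0.0,
        _CK.VITALS: 2.6, _CK.PYXIS: 2.4, _CK.DIAGNOSIS: 0.5,
    }
    tgt_cfg = replace(
        src_cfg, seed=seed + 10_001, admit_prevalence=0.253,
        missingness_rates=tgt_miss, stream_effect_weights=tgt_weights,
    )

    def _xy(cfg: CohortConfig):
        bundles, labels = generate_cohort(cfg)
        keys = [b.key for b in bundles]
        notes = [n for b in bundles for n in render_encounter(b)]
        store = embed_cohort(notes, encoder)
        X = np.stack([store.encounter_matrix(k.encounter_id) for k in keys])
        y = np.array([labels[k].disposition for k in keys])
        return keys, X, y

    src_keys, Xs, ys = _xy(src_cfg)
    tr, va, _ = (np.asarray(idx) for idx in _split_indices(src_keys, seed))
    hp = replace(hyperparams, task_mode="binary", seed=seed)
    source_state = train_head(Xs[tr], ys[tr], Xs[va], ys[va], hp, kind="meme",
                              encoder_fingerprint=encoder.fingerprint())

    tgt_keys, Xt, yt = _xy(tgt_cfg)
    t_tr, t_va, t_te = (np.asarray(i) for i in _split_indices(tgt_keys, seed + 1))
    target = {
        "X_train": Xt[t_tr], "y_train": yt[t_tr],
        "X_val": Xt[t_va], "y_val": yt[t_va],
        "X_test": Xt[t_te], "y_test": yt[t_te],
    }
    return source_state, target


def source_target_few_shot(
    n_encounters: int = 2000,
    seed: int = 0,
    sizes: Sequence[int] = FEW_SHOT_SIZES,
    encoder: EncoderSpec = EncoderSpec(),
    hyperparams: MemeHyperparams = MemeHyperparams(),
) -> pd.DataFrame:
    """Few-shot transfer of a disposition head between two synthetic sites."""
    source_state, target = prepare_transfer(n_encounters, seed, encoder, hyperparams)
    return few_shot_curve(source_state, target, sizes=sizes, seed=seed)


def _split_indices(keys, seed):
    train_k, val_k, test_k = split_cohort(keys, SplitSpec(seed=seed))
    pos = {k: i for i, k in enumerate(keys)}
    return ([pos[k] for k in train_k], [pos[k] for k in val_k],
            [pos[k] for k in test_k])


# ---------------------------------------------------------------------------
# benchmark driver


@dataclass(frozen=True)
class BenchmarkConfig:
    cohort: CohortConfig = CohortConfig()
    encoder: EncoderSpec = EncoderSpec()
    hyperparams: MemeHyperparams = MemeHyperparams()
    split: SplitSpec = SplitSpec()
    seed: int = 0
    n_resamples: int = DEFAULT_RESAMPLES
    tasks: tuple[str, ...] = ("disposition", "decompensation")


MODEL_NAMES = (
    "meme", "msem",
    *(f"single:{k.value}" for k in CONCEPT_ORDER),
    "logreg", "gbt", "mlp",
)


@dataclass
class CohortArtifacts:
    """Everything the driver derives once and shares across all models."""

    keys: list
    X6: np.ndarray          # (n, 6, dim) per-concept embeddings
    Xmsem: np.ndarray       # (n, dim) whole-narrative embeddings
    Xtab: np.ndarray        # (n, p) tabular features
    y_disposition: np.ndarray
    admitted_mask: np.ndarray
    y_decomp: np.ndarray    # rows align with admitted encounters only
    splits: dict            # name -> index array into the cohort
    featurizer: Featurizer = None


def prepare_cohort(config: BenchmarkConfig) -> CohortArtifacts:
    """Generate, render, embed, featurize and split one shared cohort."""
    bundles, labels = generate_cohort(config.cohort)
    keys = [b.key for b in bundles]
    notes = [note for b in bundles for note in render_encounter(b)]
    store = embed_cohort(notes, config.encoder)
    X6 = np.stack([store.encounter_matrix(k.encounter_id) for k in keys])
    msem_notes = [render_msem_note(b) for b in bundles]
    Xmsem = embed_cohort(msem_notes, config.encoder).matrix

    y_disp = np.array([labels[k].disposition for k in keys])
    admitted = y_disp == 1
    y_decomp = np.array([
        [labels[k].decompensation[m] for m in DECOMP_LABELS]
        for k, adm in zip(keys, admitted) if adm
    ])

    train_k, val_k, test_k = split_cohort(keys, config.split)
    pos = {k: i for i, k in enumerate(keys)}
    splits = {
        "train": np.array([pos[k] for k in train_k]),
        "val": np.array([pos[k] for k in val_k]),
        "test": np.array([pos[k] for k in test_k]),
    }
    fz = Featurizer().fit([bundles[i] for i in splits["train"]])
    Xtab = fz.transform(bundles)
    return CohortArtifacts(
        keys=keys, X6=X6, Xmsem=Xmsem, Xtab=Xtab,
        y_disposition=y_disp, admitted_mask=admitted,
        y_decomp=y_decomp, splits=splits, featurizer=fz,
    )


def _task_arrays(art: CohortArtifacts, task: str):
    """Per-partition (indices, labels) restricted to the task cohort."""
    if task == "disposition":
        y_all = art.y_disposition.reshape(-1, 1)
        sub = np.arange(len(art.keys))
    else:
        sub = np.flatnonzero(art.admitted_mask)
        y_all = np.zeros((len(art.keys), len(DECOMP_LABELS)))
        y_all[sub] = art.y_decomp
    out = {}
    subset = set(sub.tolist())
    for name, idx in art.splits.items():
        part = np.array([i for i in idx if i in subset], dtype=int)
        out[name] = (part, y_all[part])
    return out


def _scores_for_model(
    name: str, art: CohortArtifacts, parts, config: BenchmarkConfig, task: str
):
    (tr, ytr), (va, yva), (te, yte) = parts["train"], parts["val"], parts["test"]
    task_mode = "binary" if task == "disposition" else "multilabel"
    hp = replace(config.hyperparams, task_mode=task_mode, seed=config.seed)
    if name in ("logreg", "gbt", "mlp"):
        model = fit_baseline(name, art.Xtab[tr], ytr, art.Xtab[va], yva,
                             seed=config.seed)
        return model.predict_proba(art.Xtab[va]), model.predict_proba(art.Xtab[te])
    if name == "msem":
        X = art.Xmsem
    elif name == "meme":
        X = art.X6
    elif name.startswith("single:"):
        X = single_concept_input(art.X6, name.split(":", 1)[1])
    else:
        raise ValueError(f"unknown model {name!r}")
    state = train_head(X[tr], ytr, X[va], yva, hp, kind=name,
                       encoder_fingerprint=config.encoder.fingerprint())
    return predict_proba(state, X[va]), predict_proba(state, X[te])


def run_benchmark(
    config: BenchmarkConfig = BenchmarkConfig(),
    models: Sequence[str] = MODEL_NAMES,
    artifacts: CohortArtifacts | None = None,
) -> pd.DataFrame:
    """Train and evaluate every model on one shared cohort and split.

    Returns a long-format frame: one row per (model, task label) with
    F1/AUROC/AUPRC point estimates, CI half-widths and the selected
    threshold.  All models see identical partitions.
    """
    art = artifacts if artifacts is not None else prepare_cohort(config)
    records = []
    for task in config.tasks:
        parts = _task_arrays(art, task)
        part_keys = {
            name: [art.keys[i] for i in idx] for name, (idx, _) in parts.items()
        }
        for name in models:
            val_scores, test_scores = _scores_for_model(
                name, art, parts, config, task
            )
            report = evaluate_model(
                val_scores, parts["val"][1], test_scores, parts["test"][1],
                task, partitions=part_keys,
                n_resamples=config.n_resamples, seed=config.seed,
            )
            for row in report.rows:
                records.append({
                    "model": name, "task": task, "label": row.label,
                    "threshold": row.threshold,
                    "f1": row.f1.point, "f1_hw": row.f1.half_width,
                    "auroc": row.auroc.point, "auroc_hw": row.auroc.half_width,
                    "auprc": row.auprc.point, "auprc_hw": row.auprc.half_width,
                })
    return pd.DataFrame(records)


def format_benchmark_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Wide table with '0.912 (0.003)'-style cells, one row per model."""
    def cell(r, metric):
        return f"{r[metric]:.3f} ({r[f'{metric}_hw']:.3f})"

    out: dict[str, dict[str, str]] = {}
    for _, r in frame.iterrows():
        row = out.setdefault(r["model"], {})
        for metric in ("f1", "auroc", "auprc"):
            row[f"{r['label']}_{metric}"] = cell(r, metric)
    return pd.DataFrame.from_dict(out, orient="index")
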