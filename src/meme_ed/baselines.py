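"""Tabular-feature baselines: logistic regression, boosted trees, and an MLP.

These models deliberately consume structured tabular features only — no
pseudo-note text — so they isolate what the text-serialization pipeline
adds.  The feature set is the minimal reproducible one: demographic
one-hots, triage vitals, per-channel first/last/min/max/mean aggregates of
the periodic vitals, medication counts, and ICD one-hots over the cohort
vocabulary.  Missing numerics are median-imputed with a companion flag
column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier

from meme_ed import nn
from meme_ed.concepts import ConceptKind
from meme_ed.schema_io import EncounterBundle

_VITAL_CHANNELS = ("heart_rate", "sbp", "dbp", "resp_rate", "temperature", "spo2")
_TRIAGE_FIELDS = _VITAL_CHANNELS + ("acuity",)
_AGGS = ("first", "last", "min", "max", "mean")


@dataclass
class Featurizer:
    """Fixed-layout numeric featurizer, fitted on a training cohort.

    Fitting records the categorical vocabularies, the ICD-code vocabulary,
    and imputation medians; transforming any bundle then yields the same
    column layout.  The layout is available as ``columns`` for
    serialization alongside fitted models.
    """

    sex_vocab: tuple = ()
    race_vocab: tuple = ()
    mode_vocab: tuple = ()
    icd_vocab: tuple = ()
    medians: dict = field(default_factory=dict)
    columns: tuple = ()

    def fit(self, bundles: Sequence[EncounterBundle]) -> "Featurizer":
        sexes, races, modes, icds = set(), set(), set(), set()
        raw_numeric: dict[str, list[float]] = {}
        for b in bundles:
            demo = b.demographics
            if demo.get("sex") is not None:
                sexes.add(str(demo["sex"]))
            if demo.get("race") is not None:
                races.add(str(demo["race"]))
            if demo.get("arrival_mode") is not None:
                modes.add(str(demo["arrival_mode"]))
            for row in b.rows[ConceptKind.DIAGNOSIS]:
                if row.get("icd_code") is not None:
                    icds.add(str(row["icd_code"]))
            for name, value in self._numeric_values(b):
                raw_numeric.setdefault(name, []).append(value)
        self.sex_vocab = tuple(sorted(sexes))
        self.race_vocab = tuple(sorted(races))
        self.mode_vocab = tuple(sorted(modes))
        self.icd_vocab = tuple(sorted(icds))
        self.medians = {
            name: float(np.median(vals)) for name, vals in raw_numeric.items()
        }
        self.columns = self._layout()
        return self

    def _layout(self) -> tuple:
        cols: list[str] = ["age", "age_missing"]
        cols += [f"sex={v}" for v in self.sex_vocab]
        cols += [f"race={v}" for v in self.race_vocab]
        cols += [f"arrival_mode={v}" for v in self.mode_vocab]
        for f in _TRIAGE_FIELDS:
            cols += [f"triage_{f}", f"triage_{f}_missing"]
        for ch in _VITAL_CHANNELS:
            for agg in _AGGS:
                cols.append(f"vitals_{ch}_{agg}")
            cols.append(f"vitals_{ch}_missing")
        cols += ["n_medrecon", "n_pyxis", "n_diagnosis"]
        cols += [f"icd={c}" for c in self.icd_vocab]
        return tuple(cols)

    @staticmethod
    def _numeric_values(b: EncounterBundle):
        demo = b.demographics
        if demo.get("age") is not None:
            yield "age", float(demo["age"])
        triage = b.rows[ConceptKind.TRIAGE]
        if triage:
            for f in _TRIAGE_FIELDS:
                v = triage[0].get(f)
                if v is not None:
                    yield f"triage_{f}", float(v)
        rows = b.rows[ConceptKind.VITALS]
        for ch in _VITAL_CHANNELS:
            series = [float(r[ch]) for r in rows if r.get(ch) is not None]
            if series:
                arr = np.asarray(series)
                for agg, val in zip(
                    _AGGS, (arr[0], arr[-1], arr.min(), arr.max(), arr.mean())
                ):
                    yield f"vitals_{ch}_{agg}", float(val)

    def transform(self, bundles: Sequence[EncounterBundle]) -> np.ndarray:
        if not self.columns:
            raise RuntimeError("Featurizer must be fitted before transform")
        out = np.zeros((len(bundles), len(self.columns)), dtype=np.float64)
        col = {name: i for i, name in enumerate(self.columns)}

        def put_numeric(row: np.ndarray, name: str, value) -> None:
            if value is None:
                row[col[name]] = self.medians.get(name, 0.0)
                row[col[f"{name}_missing"]] = 1.0
            else:
                row[col[name]] = float(value)

        for i, b in enumerate(bundles):
            row = out[i]
            demo = b.demographics
            put_numeric(row, "age", demo.get("age"))
            for prefix, vocab, fieldname in (
                ("sex", self.sex_vocab, "sex"),
                ("race", self.race_vocab, "race"),
                ("arrival_mode", self.mode_vocab, "arrival_mode"),
            ):
                v = demo.get(fieldname)
                if v is not None and f"{prefix}={v}" in col:
                    row[col[f"{prefix}={v}"]] = 1.0
            triage = b.rows[ConceptKind.TRIAGE]
            for f in _TRIAGE_FIELDS:
                v = triage[0].get(f) if triage else None
                put_numeric(row, f"triage_{f}", v)
            vit = b.rows[ConceptKind.VITALS]
            for ch in _VITAL_CHANNELS:
                series = [float(r[ch]) for r in vit if r.get(ch) is not None]
                if series:
                    arr = np.asarray(series)
                    vals = (arr[0], arr[-1], arr.min(), arr.max(), arr.mean())
                    for agg, val in zip(_AGGS, vals):
                        row[col[f"vitals_{ch}_{agg}"]] = float(val)
                else:
                    for agg in _AGGS:
                        name = f"vitals_{ch}_{agg}"
                        row[col[name]] = self.medians.get(name, 0.0)
                    row[col[f"vitals_{ch}_missing"]] = 1.0
            row[col["n_medrecon"]] = len(b.rows[ConceptKind.MEDRECON])
            row[col["n_pyxis"]] = len(b.rows[ConceptKind.PYXIS])
            row[col["n_diagnosis"]] = len(b.rows[ConceptKind.DIAGNOSIS])
            for r in b.rows[ConceptKind.DIAGNOSIS]:
                code = r.get("icd_code")
                if code is not None and f"icd={code}" in col:
                    row[col[f"icd={code}"]] = 1.0
        return out

    def fit_transform(self, bundles: Sequence[EncounterBundle]) -> np.ndarray:
        return self.fit(bundles).transform(bundles)


def featurize(
    bundle: EncounterBundle, featurizer: Featurizer
) -> np.ndarray:
    """Feature vector for one bundle under a fitted featurizer's layout."""
    return featurizer.transform([bundle])[0]


# ---------------------------------------------------------------------------
# models

BASELINE_KINDS = ("logreg", "gbt", "mlp")


class BaselineModel:
    """Uniform predict_proba wrapper over the three baseline families."""

    def __init__(self, kind: str, inner, n_out: int, scaler=None):
        self.kind = kind
        self.inner = inner
        self.n_out = n_out
        self.scaler = scaler

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.kind == "mlp":
            mean, std = self.scaler
            Z = (X - mean) / std
            logits = self.inner.forward(Z.astype(nn.DTYPE), train=False)
            return 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        probs = np.column_stack(
            [m.predict_proba(X)[:, 1] for m in self.inner]
        )
        return probs


def fit_baseline(
    kind: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    seed: int = 0,
) -> BaselineModel:
    """Fit one baseline family with its fixed hyperparameters.

    logreg: L2 penalty 1.0, SAGA solver.  gbt: learning rate 0.05, depth 6,
    up to 1000 trees with early stopping on the validation loss.  mlp: five
    hidden layers of 1024/512/256/128/64 units, each with batch
    normalization and ReLU; dropout 0.3 on the first three hidden layers;
    weight decay on all layers; Adam at 1e-3 with the rate halved on
    validation plateau.  Multi-label targets fit one model per label for
    logreg/gbt and a multi-logit output for the mlp.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_val = np.asarray(X_val, dtype=np.float64)
    y_train = np.asarray(y_train).reshape(len(X_train), -1)
    y_val = np.asarray(y_val).reshape(len(X_val), -1)
    n_out = y_train.shape[1]

    if kind == "logreg":
        models = []
        for j in range(n_out):
            m = LogisticRegression(
                penalty="l2", C=1.0, solver="saga", max_iter=500,
                random_state=seed,
            )
            m.fit(X_train, y_train[:, j])
            models.append(m)
        return BaselineModel(kind, models, n_out)

    if kind == "gbt":
        models = []
        for j in range(n_out):
            m = XGBClassifier(
                learning_rate=0.05, max_depth=6, n_estimators=1000,
                early_stopping_rounds=20, eval_metric="logloss",
                n_jobs=1, random_state=seed, tree_method="hist",
                verbosity=0,
            )
            m.fit(X_train, y_train[:, j],
                  eval_set=[(X_val, y_val[:, j])], verbose=False)
            models.append(m)
        return BaselineModel(kind, models, n_out)

    if kind == "mlp":
        return _fit_mlp(X_train, y_train, X_val, y_val, seed, n_out)

    raise ValueError(f"unknown baseline kind {kind!r}; choose from {BASELINE_KINDS}")


_MLP_WIDTHS = (1024, 512, 256, 128, 64)
_MLP_DROPOUT_LAYERS = 3  # the 1024/512/256 layers
_MLP_DROPOUT = 0.3


def build_mlp(
    n_features: int, n_out: int, rng: np.random.Generator
) -> nn.Sequential:
    layers: list[nn.Layer] = []
    width_in = n_features
    for i, width in enumerate(_MLP_WIDTHS):
        layers.append(nn.Dense(width_in, width, rng))
        layers.append(nn.BatchNorm(width))
        layers.append(nn.ReLU())
        if i < _MLP_DROPOUT_LAYERS:
            layers.append(nn.Dropout(_MLP_DROPOUT, rng))
        width_in = width
    layers.append(nn.Dense(width_in, n_out, rng))
    return nn.Sequential(layers)


def _fit_mlp(X_train, y_train, X_val, y_val, seed: int, n_out: int,
             epochs: int = 40, batch_size: int = 128) -> BaselineModel:
    rng = np.random.default_rng(seed)
    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0)
    std[std == 0] = 1.0
    Zt = ((X_train - mean) / std).astype(nn.DTYPE)
    Zv = ((X_val - mean) / std).astype(nn.DTYPE)
    yt = np.asarray(y_train, dtype=np.float64)
    yv = np.asarray(y_val, dtype=np.float64)

    model = build_mlp(X_train.shape[1], n_out, rng)
    opt = nn.Adam(model, lr=1e-3, weight_decay=1e-4)
    best_val, best_arrays, stall, plateau = np.inf, None, 0, 0
    n = len(Zt)
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = model.forward(Zt[idx], train=True)
            grad = nn.bce_with_logits_grad(logits, yt[idx]) / len(idx)
            model.backward(grad)
            opt.step()
        val_logits = model.forward(Zv, train=False)
        val_loss = nn.bce_with_logits_sum(val_logits, yv) / len(Zv)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_arrays = {k: v.copy() for k, v in model.state_arrays().items()}
            stall = plateau = 0
        else:
            stall += 1
            plateau += 1
            if plateau >= 2:  # reduce on plateau
                opt.lr *= 0.5
                plateau = 0
            if stall >= 6:
                break
    model.load_state_arrays(best_arrays)
    return BaselineModel("mlp", model, n_out, scaler=(mean, std))
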