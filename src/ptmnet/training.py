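"""Training harness: sub-sampling splits, hidden sweeps, criterion triplets.

The evaluation protocol is random sub-sampling validation: positives are
partitioned 4:1 into training and test sets, negatives are drawn without
replacement at 5 per positive in each partition, and the whole procedure
is repeated over (by default) three independent random splits with the
test metrics averaged.

Overfitting is controlled by checkpoint selection on the *test* split:
after every training epoch the network is scored on the held-out split
and the weights attaining the best value of the chosen criterion so far
are retained.  For each PTM type three networks are kept, one per
criterion — ROC AUC, recall, precision — over a sweep of hidden-layer
sizes (2..20 in steps of 2 by default); ties across sweep runs go to
the smaller hidden layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ptmnet import metrics as _metrics
from ptmnet import mlp as _mlp
from ptmnet.scales import FeatureEncoder
from ptmnet.windows import LabeledDataset

DEFAULT_H_VALUES = tuple(range(2, 21, 2))
CRITERIA = ("auc", "recall", "precision")


class SplitError(ValueError):
    """Dataset cannot satisfy the requested split ratios."""


@dataclass
class SplitSpec:
    """Random sub-sampling parameters.

    train_pos_fraction : share of positives assigned to training (4:1
        split by default; the test count is floored, remainder to
        training).
    neg_per_pos : negatives sampled per positive in each partition
        (1:5 class ratio by default); ``None`` splits all negatives by
        ``train_pos_fraction`` instead.
    n_splits : number of independent random splits (default 3).
    """

    train_pos_fraction: float = 0.8
    neg_per_pos: int | None = 5
    n_splits: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_pos_fraction < 1:
            raise ValueError("train_pos_fraction must lie strictly between 0 and 1")
        if self.neg_per_pos is not None and self.neg_per_pos < 1:
            raise ValueError("neg_per_pos must be >= 1 (or None)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


def split_dataset(
    dataset: LabeledDataset, spec: SplitSpec | None = None
) -> list[tuple[LabeledDataset, LabeledDataset]]:
    """Independent random (train, test) splits of a labeled dataset.

    Positives are partitioned (never reused across partitions of one
    split); negatives are sampled without replacement at
    ``spec.neg_per_pos`` per positive in each partition.  Splits are
    re-sampled independently and are deterministic under ``spec.seed``.
    """
    spec = spec or SplitSpec()
    n_pos, n_neg = dataset.n_pos, dataset.n_neg
    # epsilon guards the floor against binary rounding (e.g. 50 * 0.2 -> 9.999...)
    n_test_pos = int(math.floor(n_pos * (1 - spec.train_pos_fraction) + 1e-9))
    n_train_pos = n_pos - n_test_pos
    if n_test_pos < 1 or n_train_pos < 1:
        raise SplitError(
            f"{n_pos} positives cannot be partitioned "
            f"{spec.train_pos_fraction:.2f}:{1 - spec.train_pos_fraction:.2f} "
            "with both partitions non-empty"
        )
    if spec.neg_per_pos is None:
        n_test_neg = int(math.floor(n_neg * (1 - spec.train_pos_fraction) + 1e-9))
        n_train_neg = n_neg - n_test_neg
        if n_test_neg < 1 or n_train_neg < 1:
            raise SplitError(f"{n_neg} negatives are too few to split")
    else:
        n_train_neg = spec.neg_per_pos * n_train_pos
        n_test_neg = spec.neg_per_pos * n_test_pos
        needed = n_train_neg + n_test_neg
        if needed > n_neg:
            raise SplitError(
                f"need {needed} negatives ({spec.neg_per_pos} per positive) "
                f"but only {n_neg} available: short by {needed - n_neg}"
            )
    out = []
    for s in range(spec.n_splits):
        rng = np.random.default_rng([spec.seed, s])
        pos_idx = rng.permutation(n_pos)
        neg_idx = rng.permutation(n_neg)
        test_pos = [dataset.positives[i] for i in pos_idx[:n_test_pos]]
        train_pos = [dataset.positives[i] for i in pos_idx[n_test_pos:]]
        train_neg = [dataset.negatives[i] for i in neg_idx[:n_train_neg]]
        test_neg = [
            dataset.negatives[i] for i in neg_idx[n_train_neg : n_train_neg + n_test_neg]
        ]
        out.append(
            (
                LabeledDataset(dataset.ptm_type, train_pos, train_neg),
                LabeledDataset(dataset.ptm_type, test_pos, test_neg),
            )
        )
    return out


def encode_dataset(
    dataset: LabeledDataset, encoder: FeatureEncoder
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays for a labeled dataset (positives first)."""
    X = encoder.encode_many(dataset.segments())
    y = np.asarray(dataset.labels(), int)
    return X, y


def score_dataset(
    model: _mlp.MLPModel, dataset: LabeledDataset, encoder: FeatureEncoder
) -> tuple[np.ndarray, np.ndarray]:
    """(positive-class confidences, binary decisions) over a dataset."""
    X, _ = encode_dataset(dataset, encoder)
    decisions, _, pos_conf = _mlp.predict_batch(model, X)
    return pos_conf, decisions


def criterion_value(
    criterion: str, scores: np.ndarray, decisions: np.ndarray, labels: np.ndarray
) -> float:
    """Value of a selection criterion; NaN when undefined."""
    if criterion == "auc":
        return _metrics.auc(scores, labels)
    tp, fp, tn, fn = _metrics.confusion(decisions, labels)
    r = _metrics.rates(tp, fp, tn, fn)
    if criterion in r:
        return r[criterion]
    raise ValueError(f"unknown criterion {criterion!r}")


@dataclass
class _Checkpoint:
    value: float = -math.inf
    epoch: int = -1
    weights: list[np.ndarray] | None = None
    biases: list[np.ndarray] | None = None


def _sweep_multi(
    train: LabeledDataset,
    test: LabeledDataset,
    encoder: FeatureEncoder,
    h_values: Sequence[int],
    config: _mlp.TrainConfig,
    criteria: Sequence[str],
) -> tuple[dict[str, _mlp.MLPModel], pd.DataFrame]:
    """One training run per hidden size, tracking the best checkpoint of
    every criterion simultaneously (the three criterion-optimized
    networks share each run's checkpoint pool)."""
    if not h_values:
        raise ValueError("h_values must be non-empty")
    X_train, y_train = encode_dataset(train, encoder)
    X_test, y_test = encode_dataset(test, encoder)
    T_train = _mlp.one_hot_targets(y_train)
    best: dict[str, tuple[float, int, int, _Checkpoint]] = {}
    fallback: tuple[int, int, _mlp.MLPModel] | None = None
    rows = []
    for h in h_values:
        run_seed = config.seed + int(h)
        model = _mlp.init_network([encoder.input_dim, int(h), 2], seed=run_seed,
                                  init_range=config.init_range)
        ckpts = {c: _Checkpoint() for c in criteria}

        def on_epoch(epoch: int, m: _mlp.MLPModel, _sse: float) -> None:
            decisions, _, pos_conf = _mlp.predict_batch(m, X_test)
            for c in criteria:
                v = criterion_value(c, pos_conf, decisions, y_test)
                ck = ckpts[c]
                if not math.isnan(v) and v > ck.value:
                    ck.value = v
                    ck.epoch = epoch
                    ck.weights = [w.copy() for w in m.weights]
                    ck.biases = [b.copy() for b in m.biases]

        try:
            _mlp.train_backprop(
                model, X_train, T_train, replace(config, seed=run_seed), on_epoch
            )
        except _mlp.TrainingDivergedError as exc:
            raise _mlp.TrainingDivergedError(f"hidden={h}: {exc}") from exc
        if fallback is None:
            fallback = (int(h), run_seed, model.copy())
        row = {"hidden": int(h)}
        for c in criteria:
            ck = ckpts[c]
            row[c] = ck.value if ck.weights is not None else math.nan
            row[f"{c}_epoch"] = ck.epoch
            # ties across H go to the smaller hidden size (strict >)
            if ck.weights is not None and (
                c not in best or ck.value > best[c][0]
            ):
                best[c] = (ck.value, int(h), run_seed, ck)
        rows.append(row)
    report = pd.DataFrame(rows)
    models: dict[str, _mlp.MLPModel] = {}
    for c in criteria:
        if c not in best:
            # Undefined at every checkpoint (e.g. precision when nothing was
            # ever predicted positive): fall back to the first run's final
            # weights with a NaN value — never a silently coerced zero.
            assert fallback is not None
            h, run_seed, final = fallback
            epoch = config.epochs - 1
            value = math.nan
            weights, biases = final.weights, final.biases
        else:
            value, h, run_seed, ck = best[c]
            epoch = ck.epoch
            assert ck.weights is not None and ck.biases is not None
            weights, biases = ck.weights, ck.biases
        models[c] = _mlp.MLPModel(
            [encoder.input_dim, h, 2],
            [w.copy() for w in weights],
            [b.copy() for b in biases],
            metadata={
                "ptm_type": train.ptm_type,
                "criterion": c,
                "criterion_value": value,
                "hidden": h,
                "checkpoint_epoch": epoch,
                "seed": run_seed,
                "encoder": encoder.to_dict(),
            },
        )
    return models, report


def sweep_hidden(
    train: LabeledDataset,
    test: LabeledDataset,
    encoder: FeatureEncoder | None = None,
    h_values: Sequence[int] | None = None,
    config: _mlp.TrainConfig | None = None,
    criterion: str = "auc",
) -> tuple[_mlp.MLPModel, pd.DataFrame]:
    """Sweep hidden-layer sizes; return the best checkpoint by criterion.

    One training run per entry of ``h_values`` (2, 4, ..., 20 by
    default).  Within each run the test criterion is evaluated after
    every epoch and the best-so-far weights retained; across runs the
    maximum wins, ties to the smaller hidden size.  The report has one
    row per hidden size with the run's best criterion value and epoch.
    """
    encoder = encoder or FeatureEncoder()
    config = config or _mlp.TrainConfig()
    h_values = list(h_values) if h_values is not None else list(DEFAULT_H_VALUES)
    models, report = _sweep_multi(train, test, encoder, h_values, config, [criterion])
    return models[criterion], report


@dataclass
class ModelTriplet:
    """The three criterion-optimized networks for one PTM type and split."""

    ptm_type: str
    models: dict[str, _mlp.MLPModel]
    evals: dict[str, _metrics.EvalResult] = field(default_factory=dict)

    @property
    def model_auc(self) -> _mlp.MLPModel:
        return self.models["auc"]

    @property
    def model_recall(self) -> _mlp.MLPModel:
        return self.models["recall"]

    @property
    def model_precision(self) -> _mlp.MLPModel:
        return self.models["precision"]


@dataclass
class TripletFit:
    """Per-split triplets plus metric tables from a full training run."""

    triplets: list[ModelTriplet]
    reports: list[pd.DataFrame]
    per_split: pd.DataFrame
    summary: pd.DataFrame


def train_triplet(
    dataset: LabeledDataset,
    spec: SplitSpec | None = None,
    config: _mlp.TrainConfig | None = None,
    encoder: FeatureEncoder | None = None,
    h_values: Sequence[int] | None = None,
) -> TripletFit:
    """The full protocol: per split, a sweep per criterion; metrics averaged.

    For each random split the hidden sweep is run once and the AUC-,
    recall- and precision-optimized checkpoints extracted from the same
    pool; each model is evaluated on its own split's test set and the
    test metrics averaged across splits (NaN-undefined rates are
    ignored by the average).
    """
    spec = spec or SplitSpec()
    config = config or _mlp.TrainConfig()
    encoder = encoder or FeatureEncoder()
    h_values = list(h_values) if h_values is not None else list(DEFAULT_H_VALUES)
    triplets: list[ModelTriplet] = []
    reports: list[pd.DataFrame] = []
    rows = []
    for s, (train, test) in enumerate(split_dataset(dataset, spec)):
        cfg = replace(config, seed=config.seed + 1000 * s)
        models, report = _sweep_multi(train, test, encoder, h_values, cfg, CRITERIA)
        evals = {}
        for c, m in models.items():
            m.metadata["split"] = s
            scores, decisions = score_dataset(m, test, encoder)
            ev = _metrics.evaluate(scores, decisions, test.labels())
            evals[c] = ev
            rows.append({"split": s, "criterion": c, **ev.as_dict()})
        triplets.append(ModelTriplet(dataset.ptm_type, models, evals))
        reports.append(report)
    per_split = pd.DataFrame(rows)
    summary = (
        per_split.drop(columns=["split"]).groupby("criterion", sort=False).mean()
    )
    return TripletFit(triplets, reports, per_split, summary)


def consensus_predict(
    triplet: ModelTriplet, x: np.ndarray, scheme: str = "report_all"
):
    """Combine the triplet's three networks on one encoded window.

    ``report_all`` returns {criterion: (decision, confidence)};
    ``majority`` votes (positive iff at least two networks say so) and
    reports the mean winning-class confidence of the majority voters;
    ``mean_confidence`` averages the positive-class confidences and
    decides positive iff the mean exceeds 0.5.
    """
    per_model = {
        c: _mlp.predict(m, x) for c, m in triplet.models.items()
    }
    if scheme == "report_all":
        return per_model
    if scheme == "majority":
        votes = [d for d, _ in per_model.values()]
        decision = 1 if sum(votes) >= 2 else 0
        confs = [conf for d, conf in per_model.values() if d == decision]
        return decision, float(np.mean(confs)) if confs else 0.5
    if scheme == "mean_confidence":
        pos_confs = []
        for c, m in triplet.models.items():
            r = _mlp.forward(m, x)
            pos_confs.append(float(_mlp.confidence(r)[0]))
        mean_pos = float(np.mean(pos_confs))
        decision = 1 if mean_pos > 0.5 else 0
        return decision, mean_pos if decision == 1 else 1.0 - mean_pos
    raise ValueError(f"unknown consensus scheme {scheme!r}")


def loocv(
    dataset: LabeledDataset,
    config: _mlp.TrainConfig | None = None,
    encoder: FeatureEncoder | None = None,
    hidden: int = 4,
) -> _metrics.EvalResult:
    """Leave-one-out cross-validation with a fixed architecture.

    Each sample is predicted by a network trained (fixed epoch budget,
    no checkpointing — there is no spare held-out set inside a fold) on
    the other n-1 samples.  Folds whose training half is single-class
    are skipped and recorded on the result as ``skipped_folds``.
    Confusion counts are aggregated over the predicted folds.
    """
    config = config or _mlp.TrainConfig(epochs=50)
    encoder = encoder or FeatureEncoder()
    X, y = encode_dataset(dataset, encoder)
    n = len(y)
    if n < 2:
        raise ValueError("LOOCV needs at least two samples")
    decisions, scores, labels = [], [], []
    skipped = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        y_fold = y[mask]
        if y_fold.all() or not y_fold.any():
            skipped.append(i)
            continue
        model = _mlp.init_network(
            [encoder.input_dim, hidden, 2], seed=config.seed + i,
            init_range=config.init_range,
        )
        _mlp.train_backprop(
            model, X[mask], _mlp.one_hot_targets(y_fold),
            replace(config, seed=config.seed + i),
        )
        d, _, pos_conf = _mlp.predict_batch(model, X[i : i + 1])
        decisions.append(int(d[0]))
        scores.append(float(pos_conf[0]))
        labels.append(int(y[i]))
    if not labels:
        raise ValueError("every LOOCV fold was degenerate")
    result = _metrics.evaluate(scores, decisions, labels)
    result.skipped_folds = skipped  # type: ignore[attr-defined]
    return result
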