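"""Top-level modelling surface: a fit-from-data model and a results object.

:class:`PTMSiteModel` is constructed from a labeled 9-mer dataset (or a
TSV / DataFrame of segments and labels); ``fit()`` runs the full
protocol — random sub-sampling splits, hidden-size sweep, per-epoch
checkpoint selection for AUC, recall and precision — and returns a
:class:`PTMSiteResults` carrying the trained networks, their test
metrics per split, an averaged summary table and prediction methods.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ptmnet import mlp as _mlp
from ptmnet import training as _training
from ptmnet.scales import FeatureEncoder
from ptmnet.windows import LabeledDataset, read_labeled_segments, SequenceWindow

OPTIMIZATIONS = _training.CRITERIA


class ModelLookupError(FileNotFoundError):
    """No saved network for the requested (ptm_type, optimization)."""


@dataclass(frozen=True)
class PredictionRecord:
    """One predictor output line: segment, 0/1 decision, confidence.

    The confidence belongs to the *winning* class and is rendered to
    four decimals, e.g. ``LCLYTHIGR 0 0.9853``.
    """

    segment: str
    decision: int
    confidence: float

    def render(self) -> str:
        return f"{self.segment} {self.decision} {self.confidence:.4f}"


class PTMSiteModel:
    """A per-PTM-type site classifier specification bound to data.

    Parameters
    ----------
    dataset : LabeledDataset
        Positive and negative 9-mer windows for one PTM type.
    encoder : FeatureEncoder, optional
        Defaults to the ten bundled scales with min-max normalization
        (90-dimensional encoding).
    split_spec : SplitSpec, optional
        Random sub-sampling parameters (4:1 positives, 5 negatives per
        positive, 3 splits by default).
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        encoder: FeatureEncoder | None = None,
        split_spec: _training.SplitSpec | None = None,
    ) -> None:
        if not dataset.positives or not dataset.negatives:
            raise ValueError("training requires both positive and negative windows")
        self.dataset = dataset
        self.encoder = encoder or FeatureEncoder()
        self.split_spec = split_spec or _training.SplitSpec()

    @classmethod
    def from_tsv(cls, path: str | Path, ptm_type: str = "", **kwargs) -> "PTMSiteModel":
        """Build from a labeled-segment TSV (``segment<TAB>label`` rows)."""
        return cls(read_labeled_segments(path, ptm_type=ptm_type), **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, ptm_type: str = "dataset", **kwargs
    ) -> "PTMSiteModel":
        """Build from a DataFrame with ``segment`` and ``label`` columns."""
        pos = [SequenceWindow(s) for s in df.loc[df["label"] == 1, "segment"]]
        neg = [SequenceWindow(s) for s in df.loc[df["label"] == 0, "segment"]]
        return cls(LabeledDataset(ptm_type, pos, neg), **kwargs)

    def fit(
        self,
        config: _mlp.TrainConfig | None = None,
        h_values: Sequence[int] | None = None,
    ) -> "PTMSiteResults":
        """Run the training protocol and return the fitted results."""
        fit = _training.train_triplet(
            self.dataset,
            spec=self.split_spec,
            config=config,
            encoder=self.encoder,
            h_values=h_values,
        )
        return PTMSiteResults(self, fit)


class PTMSiteResults:
    """Trained networks, per-split test metrics and prediction methods."""

    def __init__(self, model: PTMSiteModel, fit: _training.TripletFit) -> None:
        self.model = model
        self.triplets = fit.triplets
        self.sweep_reports = fit.reports
        self.metrics = fit.per_split
        self._summary = fit.summary

    @property
    def ptm_type(self) -> str:
        return self.model.dataset.ptm_type

    def summary_frame(self) -> pd.DataFrame:
        """Test metrics of each criterion-optimized network, averaged
        across the random splits."""
        return self._summary

    def summary(self) -> str:
        """A readable report in the spirit of a regression summary table."""
        d = self.model.dataset
        lines = [
            "PTM site classifier — criterion-optimized MLP triplet",
            "=" * 68,
            f"PTM type:        {d.ptm_type}",
            f"Windows:         {d.n_pos} positive / {d.n_neg} negative (9-mers)",
            f"Encoding:        {self.model.encoder.input_dim}-dimensional "
            f"({self.model.encoder.n_scales} scales x 9 positions, "
            f"{self.model.encoder.normalization})",
            f"Splits:          {self.model.split_spec.n_splits} random sub-samples, "
            f"{self.model.split_spec.train_pos_fraction:.0%} of positives to training",
            "",
            "Test metrics averaged over splits:",
            self._summary.round(4).to_string(),
            "=" * 68,
        ]
        return "\n".join(lines)

    def best_network(self, optimization: str = "auc") -> _mlp.MLPModel:
        """The deployment network for a criterion: across splits, the
        checkpoint whose test criterion value is highest."""
        if optimization not in OPTIMIZATIONS:
            raise ValueError(f"optimization must be one of {OPTIMIZATIONS}")
        best = self.triplets[0].models[optimization]
        best_v = -float("inf")
        for t in self.triplets:
            v = t.models[optimization].metadata.get("criterion_value")
            if v is not None and not math.isnan(v) and v > best_v:
                best_v = v
                best = t.models[optimization]
        return best

    def predict(
        self,
        segments: Sequence[str],
        optimization: str = "auc",
        consensus: str | None = None,
    ) -> list[PredictionRecord]:
        """Classify 9-mers; with ``consensus`` the best split's triplet
        combines its three networks (majority or mean_confidence)."""
        enc = self.model.encoder
        records = []
        if consensus is None:
            net = self.best_network(optimization)
            for seg in segments:
                d, c = _mlp.predict(net, enc.encode(seg))
                records.append(PredictionRecord(seg, d, c))
        else:
            triplet = max(
                self.triplets,
                key=lambda t: t.models["auc"].metadata.get("criterion_value", 0),
            )
            for seg in segments:
                d, c = _training.consensus_predict(triplet, enc.encode(seg), consensus)
                records.append(PredictionRecord(seg, d, c))
        return records

    def save(self, model_dir: str | Path) -> list[Path]:
        """Write one JSON per (ptm_type, criterion) deployment network
        plus the per-split metric table; returns the paths written."""
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for opt in OPTIMIZATIONS:
            net = self.best_network(opt)
            path = model_dir / f"{_slug(self.ptm_type)}__{opt}.json"
            _mlp.save_model(net, path)
            paths.append(path)
        report = model_dir / f"{_slug(self.ptm_type)}__report.tsv"
        self.metrics.to_csv(report, sep="\t", index=False)
        paths.append(report)
        return paths


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "-", name).strip("-") or "unnamed"


def available_models(model_dir: str | Path) -> list[tuple[str, str]]:
    """(ptm_type, optimization) pairs saved in a model directory."""
    out = []
    for path in sorted(Path(model_dir).glob("*.json")):
        try:
            meta = _mlp.load_model(path).metadata
        except _mlp.ModelFormatError:
            continue
        if "criterion" in meta:
            out.append((meta.get("ptm_type", path.stem), meta["criterion"]))
    return out


def load_predictor(
    model_dir: str | Path, ptm_type: str, optimization: str
) -> _mlp.MLPModel:
    """Load the saved network for a (ptm_type, optimization) pair.

    Raises :class:`ModelLookupError` listing the available pairs when
    the requested one is absent.
    """
    model_dir = Path(model_dir)
    candidate = model_dir / f"{_slug(ptm_type)}__{optimization}.json"
    if candidate.exists():
        return _mlp.load_model(candidate)
    for path in sorted(model_dir.glob("*.json")):
        try:
            net = _mlp.load_model(path)
        except _mlp.ModelFormatError:
            continue
        meta = net.metadata
        if meta.get("ptm_type") == ptm_type and meta.get("criterion") == optimization:
            return net
    pairs = available_models(model_dir)
    listing = ", ".join(f"({p}, {o})" for p, o in pairs) or "none"
    raise ModelLookupError(
        f"no model for ptm_type={ptm_type!r} optimization={optimization!r} "
        f"in {model_dir}; available: {listing}"
    )
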