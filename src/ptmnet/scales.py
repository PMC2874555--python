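"""Amino-acid property scales and window encoding.

Each residue of a 9-mer is described by a set of AAindex property scales
(one real value per residue per scale).  With the default ten scales a
window becomes a point in a 90-dimensional space.  The layout is
position-major: positions 1..9 each contribute F consecutive entries in
scale order, where F is the number of scales.

The candidate scale roster (15 rows, 14 unique accessions, 10 selected)
ships as static package data: one ``residue<TAB>value`` table per
accession plus a manifest recording canonical order and selection
status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
WINDOW_LENGTH = 9

_NORMALIZATIONS = ("minmax", "zscore", "raw")
_UNKNOWN_POLICIES = ("error", "impute_mean")


class ScaleLoadError(RuntimeError):
    """A bundled scale table is missing or corrupted."""


@dataclass(frozen=True)
class AminoAcidScale:
    """One AAindex property scale: a real value per standard residue.

    Parameters
    ----------
    accession : str
        AAindex accession, e.g. ``"BIOV880101"``.
    description : str
        Short human-readable description of the property.
    values : mapping
        Exactly the 20 standard one-letter residue codes to finite reals.
    """

    accession: str
    description: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("scale accession must be non-empty")
        keys = set(self.values)
        if keys != set(STANDARD_RESIDUES):
            missing = sorted(set(STANDARD_RESIDUES) - keys)
            extra = sorted(keys - set(STANDARD_RESIDUES))
            raise ValueError(
                f"scale {self.accession}: residue keys must be exactly the 20 "
                f"standard codes (missing {missing}, unexpected {extra})"
            )
        for aa, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"scale {self.accession}: non-finite value for {aa!r}")

    def as_array(self) -> np.ndarray:
        """Values in ``STANDARD_RESIDUES`` order."""
        return np.array([self.values[aa] for aa in STANDARD_RESIDUES], float)


def _scale_resource_dir():
    return resources.files("ptmnet.data") / "aaindex"


def _read_scale_file(accession: str) -> AminoAcidScale:
    path = _scale_resource_dir() / f"{accession}.tsv"
    try:
        text = path.read_text()
    except (FileNotFoundError, OSError) as exc:
        raise ScaleLoadError(f"bundled scale table for {accession} not found") from exc
    description = ""
    values: dict[str, float] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t", 1)
            if len(parts) == 2:
                description = parts[1]
            continue
        try:
            aa, raw = line.split("\t")
            values[aa] = float(raw)
        except ValueError as exc:
            raise ScaleLoadError(
                f"bundled scale table for {accession} is corrupted: {line!r}"
            ) from exc
    try:
        return AminoAcidScale(accession, description, values)
    except ValueError as exc:
        raise ScaleLoadError(f"bundled scale table for {accession} invalid: {exc}") from exc


def read_manifest() -> list[tuple[str, str, str]]:
    """Rows of the bundled scale manifest: (accession, status, description).

    The manifest mirrors the original 15-row candidate roster in canonical
    order; one accession appears twice (once selected, once rejected) and
    is deduplicated by the loaders.
    """
    path = _scale_resource_dir() / "manifest.tsv"
    try:
        lines = path.read_text().splitlines()
    except (FileNotFoundError, OSError) as exc:
        raise ScaleLoadError("bundled scale manifest not found") from exc
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        acc, status, desc = line.split("\t")
        rows.append((acc, status, desc))
    return rows


def load_bundled_scales() -> list[AminoAcidScale]:
    """The ten selected property scales, in canonical (manifest) order.

    These are the scales behind the default 90-dimensional encoding:
    accessibility information values, side-chain hydrophobicity and
    interaction parameters, hydration number, water-site fraction,
    side-chain volume and a transfer free energy.
    """
    out = []
    for acc, status, _ in read_manifest():
        if status == "selected":
            out.append(_read_scale_file(acc))
    return out


def load_candidate_scales() -> list[AminoAcidScale]:
    """All unique candidate scales (14), selected and rejected, in manifest order."""
    seen: set[str] = set()
    out = []
    for acc, _, _ in read_manifest():
        if acc not in seen:
            seen.add(acc)
            out.append(_read_scale_file(acc))
    return out


class FeatureEncoder:
    """Encode k-mers as position-major vectors of normalized scale values.

    Parameters
    ----------
    scales : sequence of AminoAcidScale, optional
        Ordered scale list; defaults to the ten bundled selected scales.
        The order is part of the encoding and is persisted with any
        trained model.
    normalization : {"minmax", "zscore", "raw"}
        Per-scale normalization over the 20 residue values.  ``minmax``
        (default) maps each scale onto [0, 1]; sigmoid networks train
        poorly on raw scales whose ranges differ by orders of magnitude.
    unknown_residue_policy : {"error", "impute_mean"}
        What to do with residues outside the 20-letter alphabet
        (X/B/Z/U...): raise, or substitute each scale's mean normalized
        value.
    """

    def __init__(
        self,
        scales: Sequence[AminoAcidScale] | None = None,
        normalization: str = "minmax",
        unknown_residue_policy: str = "error",
    ) -> None:
        if scales is None:
            scales = load_bundled_scales()
        scales = list(scales)
        if not scales:
            raise ValueError("encoder needs at least one scale")
        if normalization not in _NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {_NORMALIZATIONS}")
        if unknown_residue_policy not in _UNKNOWN_POLICIES:
            raise ValueError(f"unknown_residue_policy must be one of {_UNKNOWN_POLICIES}")
        self.scales = scales
        self.normalization = normalization
        self.unknown_residue_policy = unknown_residue_policy
        # (20, F) matrix of normalized per-residue values, residue rows in
        # STANDARD_RESIDUES order, scale columns in self.scales order.
        cols = []
        for sc in scales:
            v = sc.as_array()
            if normalization == "minmax":
                span = v.max() - v.min()
                col = (v - v.min()) / span if span > 0 else np.zeros_like(v)
            elif normalization == "zscore":
                sd = v.std()
                col = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
            else:
                col = v
            cols.append(col)
        self._table = np.column_stack(cols)
        self._index = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}
        self._mean_row = self._table.mean(axis=0)

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    @property
    def input_dim(self) -> int:
        """Dimensionality of an encoded window (9 x F; 90 by default)."""
        return WINDOW_LENGTH * self.n_scales

    def encode(self, segment: str) -> np.ndarray:
        """Encode one window; see :func:`encode_segment`."""
        if len(segment) != WINDOW_LENGTH:
            raise ValueError(
                f"segment must have length {WINDOW_LENGTH}, got {len(segment)} "
                f"({segment!r})"
            )
        rows = np.empty((WINDOW_LENGTH, self.n_scales))
        for pos, aa in enumerate(segment):
            i = self._index.get(aa)
            if i is None:
                if self.unknown_residue_policy == "error":
                    raise ValueError(
                        f"unknown residue {aa!r} at position {pos + 1} of {segment!r}"
                    )
                rows[pos] = self._mean_row
            else:
                rows[pos] = self._table[i]
        return rows.reshape(-1)

    def encode_many(self, segments: Iterable[str]) -> np.ndarray:
        """Encode an iterable of windows into an (n, input_dim) matrix."""
        segs = list(segments)
        out = np.empty((len(segs), self.input_dim))
        for i, s in enumerate(segs):
            out[i] = self.encode(s)
        return out

    def to_dict(self) -> dict:
        """Serializable settings, embedded in saved model metadata."""
        return {
            "scale_accessions": [s.accession for s in self.scales],
            "normalization": self.normalization,
            "unknown_residue_policy": self.unknown_residue_policy,
            "layout": "position-major",
            "window_length": WINDOW_LENGTH,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureEncoder":
        by_acc = {s.accession: s for s in load_candidate_scales()}
        try:
            scales = [by_acc[a] for a in d["scale_accessions"]]
        except KeyError as exc:
            raise ScaleLoadError(f"encoder references unbundled scale {exc}") from exc
        return cls(
            scales,
            normalization=d.get("normalization", "minmax"),
            unknown_residue_policy=d.get("unknown_residue_policy", "error"),
        )


def encode_segment(segment: str, encoder: FeatureEncoder | None = None) -> np.ndarray:
    """Encode a 9-residue segment into a real vector.

    With the default encoder the result has 90 entries: for each window
    position (1..9, left to right) the ten normalized scale values of the
    residue at that position, in canonical scale order.
    """
    if encoder is None:
        encoder = FeatureEncoder()
    return encoder.encode(segment)


@dataclass
class SubsetReport:
    """AUC of every evaluated scale subset during feature selection."""

    rows: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    def best(self) -> tuple[tuple[str, ...], float]:
        return max(self.rows, key=lambda r: (r[1], -len(r[0])))


def _heldout_auc(scales, dataset, trainer_config, seed: int) -> float:
    # Deferred imports: training/metrics depend on this module.
    from ptmnet import metrics as _metrics
    from ptmnet import mlp as _mlp
    from ptmnet import training as _training

    enc = FeatureEncoder(scales)
    spec = _training.SplitSpec(n_splits=1, seed=seed, neg_per_pos=None)
    (train, test), = _training.split_dataset(dataset, spec)
    cfg = trainer_config or _mlp.TrainConfig(epochs=40, seed=seed)
    model, _ = _training.sweep_hidden(
        train, test, encoder=enc, h_values=[4], config=cfg, criterion="auc"
    )
    scores, _ = _training.score_dataset(model, test, enc)
    return _metrics.auc(scores, test.labels())


def select_feature_subset(
    candidates: Sequence[AminoAcidScale],
    dataset,
    trainer_config=None,
    strategy: str = "greedy_forward",
    max_k: int | None = None,
    seed: int = 0,
) -> tuple[list[str], SubsetReport]:
    """Search scale subsets for the one maximizing held-out AUC.

    ``greedy_forward`` adds one scale at a time, keeping each addition
    only if it improves the held-out AUC; ``exhaustive_upto_k`` scores
    every subset of size at most ``max_k``.  Deterministic for a fixed
    seed.  Returns the accepted accessions (in acceptance order for the
    greedy strategy) and a report of every subset evaluated.

    This is a re-runnable analogue of the original trial-and-error
    feature search; on new data it need not reproduce the bundled
    ten-scale selection.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate scale")
    if not dataset.positives or not dataset.negatives:
        raise ValueError("feature selection requires both classes in the dataset")
    if len(candidates) == 1:
        return [candidates[0].accession], SubsetReport(
            [((candidates[0].accession,), float("nan"))]
        )

    report = SubsetReport()

    def evaluate(subset: Sequence[AminoAcidScale]) -> float:
        score = _heldout_auc(subset, dataset, trainer_config, seed)
        report.rows.append((tuple(s.accession for s in subset), score))
        return score

    if strategy == "greedy_forward":
        chosen: list[AminoAcidScale] = []
        best_auc = -np.inf
        remaining = list(candidates)
        while remaining:
            scored = [(evaluate(chosen + [c]), i) for i, c in enumerate(remaining)]
            top_auc, top_i = max(scored, key=lambda t: (t[0], -t[1]))
            if top_auc > best_auc:
                best_auc = top_auc
                chosen.append(remaining.pop(top_i))
            else:
                break
        return [s.accession for s in chosen], report
    if strategy == "exhaustive_upto_k":
        k = max_k or len(candidates)
        best: list[AminoAcidScale] | None = None
        best_auc = -np.inf
        for r in range(1, k + 1):
            for combo in combinations(candidates, r):
                a = evaluate(combo)
                if a > best_auc:
                    best_auc = a
                    best = list(combo)
        assert best is not None
        return [s.accession for s in best], report
    raise ValueError(f"unknown strategy {strategy!r}")
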