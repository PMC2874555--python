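"""Synthetic kinase-like motif data for end-to-end testing and calibration.

Positives are 9-mers drawn from a position weight matrix (PWM) mixed
with a background distribution by a ``consensus_strength`` in [0, 1];
negatives are drawn from the background alone.  Both classes share the
same constrained central residue (e.g. serine), so a classifier must
learn the sequence *context* of the modified site, not the identity of
the site residue itself — mirroring how real training sets pair
modified sites with unmodified sites of the same residue.  Negatives
never duplicate a positive segment, emulating the rule that negative
sets exclude experimentally verified modification sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ptmnet.scales import STANDARD_RESIDUES
from ptmnet.windows import DEFAULT_K, LabeledDataset, SequenceWindow

_AA = np.array(list(STANDARD_RESIDUES))
_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}
CENTER = DEFAULT_K // 2  # 0-based index of the central residue


class GenerationError(ValueError):
    """Constraints make the requested data impossible to generate."""


@dataclass
class MotifSpec:
    """A 9-position probabilistic sequence motif.

    position_weights : (9, 20) row-stochastic matrix over the standard
        residues (columns in alphabetical one-letter order); defaults to
        the background at every position.  Use :meth:`from_consensus`
        for the common single-consensus case.
    center_residues : residues allowed at the central position (position
        5, 1-based) for positives *and* negatives; default {"S"}.
    consensus_strength : in [0, 1]; sampling uses
        strength * PWM + (1 - strength) * background, so 0 is a
        signal-free null and 1 the pure motif.
    background : length-20 residue frequency vector (uniform default).
    name : label recorded in proteome truth tables.
    """

    position_weights: np.ndarray | None = None
    center_residues: frozenset[str] = frozenset({"S"})
    consensus_strength: float = 1.0
    background: np.ndarray | None = None
    name: str = "motif"

    def __post_init__(self) -> None:
        if not 0 <= self.consensus_strength <= 1:
            raise ValueError("consensus_strength must lie in [0, 1]")
        if not self.center_residues:
            raise ValueError("center_residues must be non-empty")
        bad = set(self.center_residues) - set(STANDARD_RESIDUES)
        if bad:
            raise ValueError(f"center_residues outside the 20-letter alphabet: {bad}")
        if self.background is None:
            self.background = np.full(20, 1 / 20)
        else:
            self.background = np.asarray(self.background, float)
            if self.background.shape != (20,) or not np.isclose(
                self.background.sum(), 1.0
            ):
                raise ValueError("background must be a length-20 probability vector")
        if self.position_weights is None:
            self.position_weights = np.tile(self.background, (DEFAULT_K, 1))
        else:
            self.position_weights = np.asarray(self.position_weights, float)
            if self.position_weights.shape != (DEFAULT_K, 20):
                raise ValueError(
                    f"position_weights must have shape ({DEFAULT_K}, 20)"
                )
            if not np.allclose(self.position_weights.sum(axis=1), 1.0):
                raise ValueError("each position's weights must sum to 1")

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        consensus_strength: float = 1.0,
        center_residues: Sequence[str] | None = None,
        background: np.ndarray | None = None,
        name: str = "motif",
    ) -> "MotifSpec":
        """Point-mass PWM on a 9-mer consensus; 'X' positions are background.

        The central residue of the consensus becomes the default allowed
        center residue.
        """
        if len(consensus) != DEFAULT_K:
            raise ValueError(f"consensus must be a {DEFAULT_K}-mer, got {consensus!r}")
        bg = np.full(20, 1 / 20) if background is None else np.asarray(background, float)
        pwm = np.tile(bg, (DEFAULT_K, 1)).copy()
        for p, aa in enumerate(consensus):
            if aa == "X":
                continue
            if aa not in _AA_INDEX:
                raise ValueError(f"consensus residue {aa!r} not standard")
            pwm[p] = 0.0
            pwm[p, _AA_INDEX[aa]] = 1.0
        if center_residues is None:
            center_residues = (
                [consensus[CENTER]] if consensus[CENTER] != "X" else ["S"]
            )
        return cls(
            position_weights=pwm,
            center_residues=frozenset(center_residues),
            consensus_strength=consensus_strength,
            background=bg,
            name=name,
        )

    def mixed_pwm(self) -> np.ndarray:
        """strength * PWM + (1 - strength) * background, per position."""
        s = self.consensus_strength
        return s * self.position_weights + (1 - s) * self.background

    def _center_probs(self, row: np.ndarray) -> np.ndarray:
        """Renormalize a probability row onto the allowed center residues."""
        mask = np.zeros(20)
        for aa in self.center_residues:
            mask[_AA_INDEX[aa]] = 1.0
        p = row * mask
        total = p.sum()
        if total <= 0:
            # The motif row excludes every allowed center residue; fall
            # back to uniform over the allowed set.
            p = mask / mask.sum()
        else:
            p = p / total
        return p


def default_kinase_motif(
    consensus_strength: float = 0.9, name: str = "basophilic"
) -> MotifSpec:
    """A basophilic kinase-like motif: R-R-x-S-[hydrophobic] in a 9-mer.

    Arginines at positions 2-3 (two and three residues N-terminal of the
    site), serine at the center, leucine at position 6 — the classic
    recognition context of basophilic serine/threonine kinases such as
    PKA.
    """
    return MotifSpec.from_consensus(
        "XRRXSLXXX", consensus_strength=consensus_strength, name=name
    )


def _sample_segments(
    pwm: np.ndarray, center_probs: np.ndarray, n: int, rng: np.random.Generator
) -> list[str]:
    cols = []
    for p in range(DEFAULT_K):
        probs = center_probs if p == CENTER else pwm[p]
        cols.append(rng.choice(20, size=n, p=probs))
    idx = np.column_stack(cols)
    return ["".join(_AA[row]) for row in idx]


def generate_dataset(
    motif: MotifSpec,
    n_pos: int,
    neg_per_pos: int = 5,
    seed: int = 0,
    ptm_type: str | None = None,
) -> LabeledDataset:
    """A labeled 9-mer dataset: motif positives vs background negatives.

    Positives come from the strength-mixed PWM, negatives from the
    background; both have their central residue constrained to the
    motif's allowed center set.  Negatives exactly duplicating a
    positive segment are resampled.  Byte-identical for a fixed seed.
    """
    if n_pos < 1:
        raise GenerationError("n_pos must be >= 1")
    if neg_per_pos < 1:
        raise GenerationError("neg_per_pos must be >= 1")
    rng = np.random.default_rng(seed)
    mixed = motif.mixed_pwm()
    pos_center = motif._center_probs(mixed[CENTER])
    neg_center = motif._center_probs(motif.background)
    positives = _sample_segments(mixed, pos_center, n_pos, rng)
    pos_set = set(positives)
    bg_pwm = np.tile(motif.background, (DEFAULT_K, 1))
    n_neg = n_pos * neg_per_pos
    negatives: list[str] = []
    attempts = 0
    while len(negatives) < n_neg:
        batch = _sample_segments(
            bg_pwm, neg_center, n_neg - len(negatives), rng
        )
        negatives.extend(s for s in batch if s not in pos_set)
        attempts += 1
        if attempts > 100:
            raise GenerationError(
                "cannot draw negatives distinct from the positive set; "
                "the background is too constrained"
            )
    name = ptm_type if ptm_type is not None else f"synthetic/{motif.name}"
    return LabeledDataset(
        name,
        [SequenceWindow(s) for s in positives],
        [SequenceWindow(s) for s in negatives],
    )


def generate_proteome(
    n_seqs: int,
    length_range: tuple[int, int],
    planted_motifs: Sequence[tuple[MotifSpec, float]] = (),
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Background protein sequences with motif instances planted at
    recorded positions.

    ``planted_motifs`` pairs each motif with a rate = expected planted
    instances per sequence (Poisson counts, capped by what fits without
    window overlap; an expectation that cannot fit at all raises).
    Returns FASTA-style (id, sequence) records and a truth table with
    columns parent_id, position (1-based center), motif.
    """
    lo, hi = length_range
    if lo < DEFAULT_K:
        raise GenerationError(f"sequences must be at least {DEFAULT_K} residues")
    if hi < lo:
        raise GenerationError("length_range must be (low, high) with low <= high")
    rng = np.random.default_rng(seed)
    for motif, rate in planted_motifs:
        if rate < 0:
            raise GenerationError("motif rates must be non-negative")
        if rate > lo // DEFAULT_K:
            raise GenerationError(
                f"rate {rate} motif(s)/sequence cannot fit without overlap in "
                f"sequences of length {lo} (capacity {lo // DEFAULT_K})"
            )
    records: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(n_seqs):
        L = int(rng.integers(lo, hi + 1))
        seq = list("".join(rng.choice(_AA, size=L)))
        occupied: list[tuple[int, int]] = []  # 0-based [start, end) of planted windows
        for motif, rate in planted_motifs:
            k_sites = min(int(rng.poisson(rate)), L // DEFAULT_K)
            mixed = motif.mixed_pwm()
            center_probs = motif._center_probs(mixed[CENTER])
            placed = 0
            tries = 0
            while placed < k_sites and tries < 200:
                tries += 1
                start = int(rng.integers(0, L - DEFAULT_K + 1))
                if any(start < e and start + DEFAULT_K > s for s, e in occupied):
                    continue
                segment = _sample_segments(mixed, center_probs, 1, rng)[0]
                seq[start : start + DEFAULT_K] = list(segment)
                occupied.append((start, start + DEFAULT_K))
                truth_rows.append(
                    {
                        "parent_id": f"seq{i + 1}",
                        "position": start + CENTER + 1,
                        "motif": motif.name,
                    }
                )
                placed += 1
        records.append((f"seq{i + 1}", "".join(seq)))
    truth = pd.DataFrame(truth_rows, columns=["parent_id", "position", "motif"])
    return records, truth


def write_fasta(records: Sequence[tuple[str, str]], path, width: int = 60) -> None:
    """Write (id, sequence) records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
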