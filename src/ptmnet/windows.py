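"""FASTA input, sliding 9-mer windows and labeled-segment files.

Coordinates are 1-based and windows are closed intervals, matching the
convention of biological site annotations.  A window's ``center_pos`` is
the 1-based position of its central (5th) residue in the parent
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

DEFAULT_K = 9


class FastaFormatError(ValueError):
    """Empty or malformed FASTA input."""


class SegmentFileError(ValueError):
    """Malformed labeled-segment TSV (message carries the line number)."""


@dataclass(frozen=True)
class SequenceWindow:
    """A k-mer with provenance: parent sequence id and 1-based center."""

    segment: str
    parent_id: str = ""
    center_pos: int = 0

    def __post_init__(self) -> None:
        if len(self.segment) == 0:
            raise ValueError("window segment must be non-empty")


@dataclass
class LabeledDataset:
    """Positive and negative windows for one PTM type.

    No segment may appear in both classes, and all segments must share
    one length (9 for the canonical predictor).
    """

    ptm_type: str
    positives: list[SequenceWindow] = field(default_factory=list)
    negatives: list[SequenceWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lengths = {len(w.segment) for w in self.positives + self.negatives}
        if len(lengths) > 1:
            raise ValueError(f"segments of mixed lengths in dataset: {sorted(lengths)}")
        overlap = {w.segment for w in self.positives} & {
            w.segment for w in self.negatives
        }
        if overlap:
            ex = sorted(overlap)[:3]
            raise ValueError(
                f"{len(overlap)} segment(s) labeled both positive and negative, "
                f"e.g. {ex}"
            )

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def segments(self) -> list[str]:
        return [w.segment for w in self.positives + self.negatives]

    def labels(self) -> list[int]:
        return [1] * self.n_pos + [0] * self.n_neg


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence), in file order.

    Sequences are upper-cased with line wraps and whitespace removed.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace(" ", "").upper()
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def generate_windows(
    sequence: str, k: int = DEFAULT_K, parent_id: str = ""
) -> list[SequenceWindow]:
    """All overlapping k-mers of a sequence, stride 1, in sequence order.

    Returns max(0, L - k + 1) windows; a sequence shorter than k yields
    an empty list.  ``center_pos`` of the window starting at 0-based
    offset i is i + (k - 1) / 2 + 1.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"window length must be odd and >= 1, got {k}")
    half = (k - 1) // 2
    return [
        SequenceWindow(sequence[i : i + k], parent_id, i + half + 1)
        for i in range(len(sequence) - k + 1)
    ]


def extract_site_segment(
    sequence: str,
    site_pos: int,
    k: int = DEFAULT_K,
    edge_policy: str = "skip",
    parent_id: str = "",
) -> SequenceWindow | None:
    """The k-mer centered on a (1-based) site position.

    Sites within (k-1)/2 of a terminus cannot carry a full window;
    ``edge_policy="skip"`` returns None for them, ``"pad_X"`` pads with
    'X' (requiring an encoder with the impute policy downstream).
    """
    if edge_policy not in ("skip", "pad_X"):
        raise ValueError(f"edge_policy must be 'skip' or 'pad_X', got {edge_policy!r}")
    if not 1 <= site_pos <= len(sequence):
        raise IndexError(
            f"site_pos {site_pos} out of range for sequence of length {len(sequence)}"
        )
    half = (k - 1) // 2
    start = site_pos - 1 - half
    end = site_pos - 1 + half + 1
    if start < 0 or end > len(sequence):
        if edge_policy == "skip":
            return None
        left = max(0, -start)
        right = max(0, end - len(sequence))
        core = sequence[max(0, start) : min(len(sequence), end)]
        return SequenceWindow("X" * left + core + "X" * right, parent_id, site_pos)
    return SequenceWindow(sequence[start:end], parent_id, site_pos)


def read_labeled_segments(path: str | Path, ptm_type: str = "") -> LabeledDataset:
    """Read a labeled-segment TSV into a dataset.

    Format: one row per window, ``segment<TAB>label`` with label 0 or 1,
    optionally followed by ``parent_id`` and 1-based ``center_pos``
    columns.  No header.  A segment listed under both labels is
    rejected.
    """
    positives: list[SequenceWindow] = []
    negatives: list[SequenceWindow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SegmentFileError(
                    f"{path}:{lineno}: expected at least segment<TAB>label, got {line!r}"
                )
            segment = parts[0].strip().upper()
            if parts[1] not in ("0", "1"):
                raise SegmentFileError(
                    f"{path}:{lineno}: label must be 0 or 1, got {parts[1]!r}"
                )
            parent_id = parts[2] if len(parts) > 2 else ""
            try:
                center = int(parts[3]) if len(parts) > 3 and parts[3] else 0
            except ValueError:
                raise SegmentFileError(
                    f"{path}:{lineno}: center_pos must be an integer, got {parts[3]!r}"
                ) from None
            window = SequenceWindow(segment, parent_id, center)
            (positives if parts[1] == "1" else negatives).append(window)
    try:
        return LabeledDataset(ptm_type or str(path), positives, negatives)
    except ValueError as exc:
        raise SegmentFileError(f"{path}: {exc}") from exc


def write_labeled_segments(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a dataset in the labeled-segment TSV format (round-trip stable)."""
    with open(path, "w") as fh:
        for label, windows in ((1, dataset.positives), (0, dataset.negatives)):
            for w in windows:
                cols = [w.segment, str(label)]
                if w.parent_id or w.center_pos:
                    cols += [w.parent_id, str(w.center_pos)]
                fh.write("\t".join(cols) + "\n")


def windows_from_file(path: str | Path) -> list[str]:
    """Read a windows file: one 9-mer per line (the Predictor's input)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            seg = line.strip().upper()
            if not seg:
                continue
            if len(seg) != DEFAULT_K:
                raise SegmentFileError(
                    f"{path}:{lineno}: expected a {DEFAULT_K}-mer, got {seg!r}"
                )
            out.append(seg)
    return out


def write_windows(windows: Iterable[SequenceWindow | str], path: str | Path) -> int:
    """Write windows one segment per line; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for w in windows:
            fh.write((w if isinstance(w, str) else w.segment) + "\n")
            n += 1
    return n
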