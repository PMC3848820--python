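"""Protein-disorder meta-prediction data preparation.

Treats each existing per-residue disorder predictor as a noisy annotator, so
the consensus algorithms can build an unsupervised meta-predictor. This
module supplies the plumbing: FASTA ingestion, the 20-dimensional
window-composition features, the per-residue predictor table reader, the
short-segment evaluation filter (disorder runs shorter than four residues are
excluded from evaluation, a standard guard against experimental uncertainty)
and the N-terminus / internal / C-terminus region partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotations_io import MISSING, AnnotationMatrix, FeatureMatrix
from .errors import FormatError, InputError, ValidationError

#: Standard residues in one-letter alphabetical order; the first 19 are the
#: stored composition features (tyrosine's frequency is implied by closure).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity/nonstandard codes tolerated in sequences but excluded from counts.
EXTENDED_CODES = "BXZJUO"
DEFAULT_WINDOW = 21
DEFAULT_MIN_SEGMENT = 4

FEATURE_NAMES = tuple(f"freq_{aa}" for aa in AMINO_ACIDS[:19]) + ("complexity",)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id → uppercase-sequence map.

    Rejects empty records, duplicate ids and letters outside the standard
    alphabet plus ambiguity codes.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r}")
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        bad = set(seq) - set(AMINO_ACIDS + EXTENDED_CODES)
        if bad:
            raise FormatError(f"record {rec.id!r} has invalid letters {sorted(bad)}")
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=pid, description="") for pid, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def window_features(sequence: str, position: int, window: int = DEFAULT_WINDOW
                    ) -> np.ndarray:
    """20-dimensional feature vector for one residue.

    The window of odd length *window* is centred at the 1-based *position*
    and truncated at the sequence ends. Entries 1–19 are the relative
    frequencies of the first 19 amino acids (A…W); entry 20 is the Shannon
    entropy of the full 20-letter composition normalized by log 20, a local
    sequence-complexity measure in [0, 1] (low-complexity regions tend to be
    disordered). Nonstandard letters are excluded from the counts; a window
    with no standard residue yields the zero vector with a warning.
    """
    if window % 2 == 0 or window < 1:
        raise InputError("window must be a positive odd integer")
    seq = sequence.upper()
    length = len(seq)
    if not (1 <= position <= length):
        raise InputError(f"position {position} outside sequence of length {length}")
    half = window // 2
    sub = seq[max(0, position - 1 - half):min(length, position + half)]
    counts = np.array([sub.count(aa) for aa in AMINO_ACIDS], dtype=float)
    total = counts.sum()
    if total == 0:
        warnings.warn(f"window at position {position} holds no standard residue",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(20)
    freqs = counts / total
    nz = freqs[freqs > 0]
    entropy = float(-(nz * np.log(nz)).sum() / math.log(20.0))
    return np.concatenate([freqs[:19], [entropy]])


def sequence_features(sequence: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """L×20 feature grid for a whole sequence."""
    return np.stack([window_features(sequence, pos, window)
                     for pos in range(1, len(sequence) + 1)])


def filter_short_segments(truth, min_len: int = DEFAULT_MIN_SEGMENT) -> np.ndarray:
    """Evaluation mask excluding disorder segments shorter than *min_len*.

    Maximal runs of 1s shorter than *min_len* are masked out (False); ordered
    positions and long runs stay True.
    """
    if min_len < 1:
        raise InputError("min_len must be >= 1")
    t = np.asarray(truth, int)
    if not np.isin(t, (0, 1)).all():
        raise InputError("truth track must be binary")
    mask = np.ones(t.size, dtype=bool)
    padded = np.r_[0, t, 0]
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1)
    for s, e in zip(starts, ends):
        if e - s < min_len:
            mask[s:e] = False
    return mask


def region_of_position(position: int, length: int) -> str:
    """Classify a 1-based residue position as N-terminus / internal / C-terminus.

    The termini are the first and last 20% of residues (ceiling). A position
    satisfying both rules on a very short sequence counts as N-terminus, so
    the three regions always partition the sequence.
    """
    if not (1 <= position <= length):
        raise InputError(f"position {position} outside [1, {length}]")
    t = math.ceil(0.2 * length)
    if position <= t:
        return "N-terminus"
    if position > length - t:
        return "C-terminus"
    return "internal"


@dataclass(frozen=True)
class ResidueTrack:
    """Per-residue predictor calls (and optional truth) for one protein.

    ``predictions`` is an L×R grid of 0/1 calls with :data:`MISSING` for
    residues a predictor did not cover; ``truth`` is the optional 0/1
    order/disorder reference; ``eval_mask`` is False on disorder segments
    shorter than ``min_segment`` residues.
    """

    protein_id: str
    sequence: str
    predictions: np.ndarray
    predictor_ids: tuple[str, ...]
    truth: np.ndarray | None = None
    min_segment: int = DEFAULT_MIN_SEGMENT

    def __post_init__(self) -> None:
        preds = np.asarray(self.predictions, int)
        object.__setattr__(self, "predictions", preds)
        L = len(self.sequence)
        if preds.shape != (L, len(self.predictor_ids)):
            raise ValidationError(
                f"{self.protein_id}: prediction grid shape {preds.shape} does not "
                f"match sequence length {L} × {len(self.predictor_ids)} predictors")
        if not np.isin(preds, (0, 1, MISSING)).all():
            raise ValidationError(f"{self.protein_id}: non-binary predictor call")
        if self.truth is not None:
            t = np.asarray(self.truth, int)
            object.__setattr__(self, "truth", t)
            if t.shape != (L,):
                raise ValidationError(f"{self.protein_id}: truth length mismatch")
            if not np.isin(t, (0, 1)).all():
                raise ValidationError(f"{self.protein_id}: truth must be binary")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def eval_mask(self) -> np.ndarray:
        if self.truth is None:
            return np.ones(self.length, dtype=bool)
        return filter_short_segments(self.truth, self.min_segment)


def read_predictions(path, sequences: dict[str, str], sep: str = "\t",
                     truth_column: str = "truth",
                     min_segment: int = DEFAULT_MIN_SEGMENT) -> list[ResidueTrack]:
    """Read a per-residue predictor table into validated tracks.

    Expected columns: ``protein_id``, ``pos`` (1-based), one 0/1 column per
    predictor and optionally *truth_column*. Residues without a row get
    :data:`MISSING` calls for every predictor.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"protein_id", "pos"}
    if not required.issubset(df.columns):
        raise FormatError(f"prediction table needs columns {sorted(required)}")
    predictor_cols = [c for c in df.columns
                      if c not in required and c != truth_column]
    if not predictor_cols:
        raise FormatError("prediction table has no predictor columns")
    tracks = []
    for pid in sorted(sequences):
        seq = sequences[pid]
        L = len(seq)
        sub = df[df["protein_id"] == pid]
        preds = np.full((L, len(predictor_cols)), MISSING, dtype=int)
        truth = np.full(L, MISSING, dtype=int) if truth_column in df.columns else None
        for _, row in sub.iterrows():
            pos = int(row["pos"])
            if not (1 <= pos <= L):
                raise ValidationError(f"{pid}: position {pos} outside sequence (L={L})")
            for j, col in enumerate(predictor_cols):
                val = row[col]
                if pd.isna(val):
                    continue
                if int(val) not in (0, 1):
                    raise ValidationError(f"{pid} pos {pos}: non-binary call in {col!r}")
                preds[pos - 1, j] = int(val)
            if truth is not None and not pd.isna(row[truth_column]):
                truth[pos - 1] = int(row[truth_column])
        if truth is not None:
            if (truth == MISSING).any():
                if (truth == MISSING).all():
                    truth = None
                else:
                    raise ValidationError(f"{pid}: truth must cover every residue or none")
        tracks.append(ResidueTrack(pid, seq, preds, tuple(predictor_cols), truth,
                                   min_segment=min_segment))
    return tracks


def write_predictions(tracks: list[ResidueTrack], path, sep: str = "\t") -> None:
    rows = []
    for tr in tracks:
        for i in range(tr.length):
            row = {"protein_id": tr.protein_id, "pos": i + 1}
            for j, col in enumerate(tr.predictor_ids):
                val = tr.predictions[i, j]
                row[col] = "" if val == MISSING else int(val)
            if tr.truth is not None:
                row["truth"] = int(tr.truth[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class ResidueDataset:
    """Residue-level instances ready for the consensus algorithms.

    One instance per residue in (protein_id, position) lexicographic order.
    ``eval_mask`` marks the residues that count toward supervised evaluation
    (short disorder segments excluded); all residues take part in the
    unsupervised fit. ``truth`` is MISSING-free only when every track carried
    a reference annotation.
    """

    annotations: AnnotationMatrix
    features: FeatureMatrix
    eval_mask: np.ndarray
    truth: np.ndarray | None
    protein_ids: tuple[str, ...]
    positions: np.ndarray
    lengths: np.ndarray


def residues_to_dataset(tracks: list[ResidueTrack], window: int = DEFAULT_WINDOW
                        ) -> ResidueDataset:
    """Flatten residue tracks into aligned annotation and feature tables."""
    if not tracks:
        raise InputError("no residue tracks supplied")
    tracks = sorted(tracks, key=lambda tr: tr.protein_id)
    predictor_ids = tracks[0].predictor_ids
    for tr in tracks:
        if tr.predictor_ids != predictor_ids:
            raise ValidationError("tracks disagree on predictor columns")
    labels, feats, ids, pids, positions, lengths, masks, truths = \
        [], [], [], [], [], [], [], []
    have_truth = all(tr.truth is not None for tr in tracks)
    for tr in tracks:
        labels.append(tr.predictions)
        feats.append(sequence_features(tr.sequence, window))
        ids.extend(f"{tr.protein_id}:{i + 1}" for i in range(tr.length))
        pids.extend([tr.protein_id] * tr.length)
        positions.extend(range(1, tr.length + 1))
        lengths.extend([tr.length] * tr.length)
        masks.append(tr.eval_mask)
        if have_truth:
            truths.append(tr.truth)
    grid = np.vstack(labels)
    covered = (grid != MISSING).any(axis=1)  # residues no predictor covers are dropped
    if not covered.any():
        raise InputError("no residue has any predictor call")
    ids_arr = np.asarray(ids, dtype=object)[covered]
    ann = AnnotationMatrix(grid[covered], tuple(ids_arr), predictor_ids)
    fm = FeatureMatrix(np.vstack(feats)[covered], FEATURE_NAMES, tuple(ids_arr))
    return ResidueDataset(
        annotations=ann, features=fm,
        eval_mask=np.concatenate(masks)[covered],
        truth=np.concatenate(truths)[covered] if have_truth else None,
        protein_ids=tuple(np.asarray(pids, dtype=object)[covered]),
        positions=np.asarray(positions, int)[covered],
        lengths=np.asarray(lengths, int)[covered],
    )
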