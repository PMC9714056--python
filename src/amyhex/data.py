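"""Peptide dataset handling: I/O, length filtering, balancing, splits.

Labels are binary: amyloid-forming hexapeptides are the positive class (1),
non-amyloid the negative class (0). All stochastic operations take an
explicit integer seed and are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tables import AMINO_ACIDS

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = 1, 0

#: accepted spellings in label tables, case-insensitive
_LABEL_ALIASES = {
    "amyloid": POSITIVE, "positive": POSITIVE, "1": POSITIVE,
    "non-amyloid": NEGATIVE, "nonamyloid": NEGATIVE, "non_amyloid": NEGATIVE,
    "negative": NEGATIVE, "0": NEGATIVE,
}
_LABEL_NAMES = {POSITIVE: "amyloid", NEGATIVE: "non-amyloid"}

_VALID_RESIDUES = frozenset(AMINO_ACIDS)


class DataError(ValueError):
    """Malformed input data (parse errors, label errors, duplicate ids)."""


@dataclass(frozen=True)
class PeptideRecord:
    """A single peptide sequence with optional binary label."""

    id: str
    sequence: str
    label: Optional[int] = None
    source: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise DataError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.label is not None and self.label not in (POSITIVE, NEGATIVE):
            raise DataError(f"record {self.id!r}: label must be 0/1, got {self.label!r}")

    @property
    def is_standard(self) -> bool:
        """True if the sequence uses only the 20 standard residues."""
        return all(c in _VALID_RESIDUES for c in self.sequence)


class LabeledDataset:
    """An ordered collection of uniquely-identified, labelled peptides."""

    def __init__(self, records: Iterable[PeptideRecord]):
        self.records: list[PeptideRecord] = list(records)
        seen = set()
        for r in self.records:
            if r.label is None:
                raise DataError(f"record {r.id!r} is unlabelled")
            if r.id in seen:
                raise DataError(f"duplicate id {r.id!r}")
            seen.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, LabeledDataset) and self.records == other.records

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        y = self.labels
        return int((y == POSITIVE).sum()), int((y == NEGATIVE).sum())

    def subset(self, ids: Sequence[str]) -> "LabeledDataset":
        """Records with the given ids, in the given order."""
        by_id = {r.id: r for r in self.records}
        return LabeledDataset(by_id[i] for i in ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sequence": self.sequences,
                "label": [_LABEL_NAMES[r.label] for r in self.records],
            }
        )

    def dedup_by_sequence(self) -> "LabeledDataset":
        """Drop exact-sequence duplicates, keeping the first occurrence.

        Raises :class:`DataError` when duplicated sequences carry
        conflicting labels.
        """
        kept: dict[str, PeptideRecord] = {}
        out = []
        for r in self.records:
            prev = kept.get(r.sequence)
            if prev is None:
                kept[r.sequence] = r
                out.append(r)
            elif prev.label != r.label:
                raise DataError(
                    f"sequence {r.sequence!r} has conflicting labels "
                    f"({prev.id!r} vs {r.id!r})"
                )
        if len(out) < len(self.records):
            logger.warning("dropped %d duplicate sequences", len(self.records) - len(out))
        return LabeledDataset(out)


@dataclass(frozen=True)
class SplitSpec:
    """Per-class train/test sizes for a balanced split."""

    train_per_class: int = 350
    test_per_class: int = 33
    seed: int = 0

    def __post_init__(self):
        if self.train_per_class <= 0 or self.test_per_class <= 0:
            raise ValueError("split counts must be positive")


@dataclass(frozen=True)
class RobustnessPair:
    """One resampled (train, test) pair of the robustness protocol."""

    index: int
    train: LabeledDataset
    test: LabeledDataset

    def id_set(self) -> frozenset[str]:
        return frozenset(self.train.ids) | frozenset(self.test.ids)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> list[PeptideRecord]:
    """Read peptides from FASTA; the header token before whitespace is the id."""
    path = Path(path)
    # Bio.SeqIO silently ignores leading junk; reject it explicitly.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise DataError(f"{path}:{lineno}: sequence data before first header")
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(PeptideRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[PeptideRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def parse_label(text: str, *, context: str = "") -> int:
    key = str(text).strip().lower()
    if key not in _LABEL_ALIASES:
        raise DataError(f"unknown label {text!r}{context}")
    return _LABEL_ALIASES[key]


def read_label_table(path, fmt: Optional[str] = None) -> LabeledDataset:
    """Read an ``id, sequence, label`` table (TSV or CSV; header required)."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"id", "sequence", "label"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        label = parse_label(row.label, context=f" in {path} row {row_num}")
        records.append(PeptideRecord(id=str(row.id), sequence=str(row.sequence), label=label))
    return LabeledDataset(records)


def write_label_table(ds: LabeledDataset, path, fmt: Optional[str] = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    ds.to_frame().to_csv(path, sep="," if fmt == "csv" else "\t", index=False)


def write_split_manifest(train: LabeledDataset, test: LabeledDataset, path) -> None:
    """TSV manifest (id, sequence, label, partition) that reconstructs a split."""
    frames = []
    for part, ds in (("train", train), ("test", test)):
        df = ds.to_frame()
        df["partition"] = part
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def drop_nonstandard(records: Iterable[PeptideRecord]) -> list[PeptideRecord]:
    """Drop sequences with residues outside the 20-letter alphabet, warning once.

    The descriptor property tables only cover the standard residues, so
    B/J/O/U/X/Z sequences cannot be featurized.
    """
    kept, dropped = [], 0
    for r in records:
        if r.is_standard:
            kept.append(r)
        else:
            dropped += 1
    if dropped:
        logger.warning("rejected %d sequences with non-standard residues", dropped)
    return kept


# ---------------------------------------------------------------------------
# Balancing and splitting


def filter_by_length(ds: LabeledDataset, length: int) -> LabeledDataset:
    """Keep only records of exactly the given sequence length, order preserved."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return LabeledDataset(r for r in ds if len(r.sequence) == length)


def balance_downsample(
    ds: LabeledDataset, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Downsample the majority class to the minority count.

    Returns ``(balanced, removed)``; the removed records are kept so they
    can be reintroduced for the robustness protocol. Dataset order is
    preserved in both outputs.
    """
    n_pos, n_neg = ds.class_counts()
    if n_pos == 0 or n_neg == 0:
        raise DataError("balance_downsample requires both classes present")
    if n_pos == n_neg:
        return ds, LabeledDataset([])
    major = POSITIVE if n_pos > n_neg else NEGATIVE
    excess = abs(n_pos - n_neg)
    rng = np.random.default_rng(seed)
    major_positions = [i for i, r in enumerate(ds.records) if r.label == major]
    removed_positions = set(
        rng.choice(len(major_positions), size=excess, replace=False).tolist()
    )
    removed_idx = {major_positions[i] for i in removed_positions}
    balanced = LabeledDataset(
        r for i, r in enumerate(ds.records) if i not in removed_idx
    )
    removed = LabeledDataset(
        r for i, r in enumerate(ds.records) if i in removed_idx
    )
    return balanced, removed


def make_split(
    ds: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Draw a class-balanced train/test split, discarding any leftovers.

    Each class contributes exactly ``train_per_class`` + ``test_per_class``
    records, sampled without replacement; leftovers are logged and dropped.
    """
    need = spec.train_per_class + spec.test_per_class
    rng = np.random.default_rng(spec.seed)
    train_recs: list[PeptideRecord] = []
    test_recs: list[PeptideRecord] = []
    leftovers = 0
    for cls in (POSITIVE, NEGATIVE):
        members = [r for r in ds if r.label == cls]
        if len(members) < need:
            raise DataError(
                f"class {_LABEL_NAMES[cls]}: need {need} records, have {len(members)}"
            )
        order = rng.permutation(len(members))
        chosen = [members[i] for i in order]
        train_recs.extend(chosen[: spec.train_per_class])
        test_recs.extend(chosen[spec.train_per_class : need])
        leftovers += len(members) - need
    if leftovers:
        logger.info("make_split: discarding %d leftover records", leftovers)
    return LabeledDataset(train_recs), LabeledDataset(test_recs)


def make_robustness_pairs(
    pool: LabeledDataset,
    n_pairs: int,
    spec: SplitSpec,
    seed: int,
    max_retries: int = 1000,
) -> list[RobustnessPair]:
    """Build ``n_pairs`` distinct resampled (train, test) pairs from the pool.

    Pair equality is judged by the id-set of train ∪ test; a duplicate draw
    is retried up to ``max_retries`` times before erroring.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    seen: set[frozenset[str]] = set()
    pairs: list[RobustnessPair] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.generate_state(n_pairs * (max_retries + 1)).tolist())
    for i in range(1, n_pairs + 1):
        for _ in range(max_retries):
            sub_seed = next(child_seeds) % (2**31)
            train, test = make_split(pool, replace(spec, seed=sub_seed))
            pair = RobustnessPair(index=i, train=train, test=test)
            key = pair.id_set()
            if key not in seen:
                seen.add(key)
                pairs.append(pair)
                break
        else:
            raise DataError(
                f"could not draw a distinct pair {i} within {max_retries} retries"
            )
    return pairs
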