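"""FASTA and annotation-table I/O plus the core labelled-sequence containers.

Coordinates in all user-facing files are 1-based closed intervals (the
convention used for signal-peptide positions, e.g. ``SP:1-22``); in memory the
package uses 0-based half-open indexing, converted only at this boundary.

Annotation tables are comma-delimited CSV with semicolon-separated list
fields::

    id,localization,signals
    P1,Nucleus;Cytoplasm,
    P2,Extracellular,SP:1-22

Prediction output follows the same dialect: a summary CSV with one row per
sequence (decided labels plus all per-label scores) and an optional
long-format per-residue attention CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .vocab import (
    ALPHABET,
    LOC_INDEX,
    LOCALIZATION_CLASSES,
    NONCANONICAL_TO_X,
    SIGNAL_CLASSES,
    SIGNAL_INDEX,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "LocalizationLabelSet",
    "SignalAnnotation",
    "LabeledSequence",
    "FastaError",
    "AnnotationError",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "write_predictions",
]


class FastaError(ValueError):
    """Malformed FASTA input."""


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation table."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r} contains letters outside the alphabet: "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LocalizationLabelSet:
    """Subset of the fixed localization vocabulary as a binary vector."""

    vector: tuple[int, ...]
    classes: tuple[str, ...] = LOCALIZATION_CLASSES

    @classmethod
    def from_labels(
        cls, labels: Iterable[str], classes: Sequence[str] = LOCALIZATION_CLASSES
    ) -> "LocalizationLabelSet":
        index = {c: i for i, c in enumerate(classes)}
        vec = [0] * len(classes)
        for lab in labels:
            if lab not in index:
                raise AnnotationError(
                    f"unknown localization label {lab!r}; allowed: {list(classes)}"
                )
            vec[index[lab]] = 1
        return cls(vector=tuple(vec), classes=tuple(classes))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c for c, b in zip(self.classes, self.vector) if b)

    def __len__(self) -> int:
        return sum(self.vector)


@dataclass(frozen=True)
class SignalAnnotation:
    """Sorting-signal types plus their residue intervals on one sequence.

    ``regions`` holds ``(type, start, end)`` with 1-based closed coordinates;
    ``mask`` marks every residue inside at least one region.
    """

    types: tuple[str, ...]
    regions: tuple[tuple[str, int, int], ...]
    length: int

    def __post_init__(self) -> None:
        for t, start, end in self.regions:
            if t not in SIGNAL_INDEX:
                raise AnnotationError(
                    f"unknown signal type {t!r}; allowed: {list(SIGNAL_CLASSES)}"
                )
            if not (1 <= start <= end <= self.length):
                raise AnnotationError(
                    f"signal region {t}:{start}-{end} outside sequence of "
                    f"length {self.length}"
                )
            if t not in self.types:
                raise AnnotationError(
                    f"region type {t!r} missing from declared types {self.types}"
                )
        for t in self.types:
            if t not in SIGNAL_INDEX:
                raise AnnotationError(
                    f"unknown signal type {t!r}; allowed: {list(SIGNAL_CLASSES)}"
                )

    @property
    def type_vector(self) -> np.ndarray:
        vec = np.zeros(len(SIGNAL_CLASSES), dtype=np.int8)
        for t in self.types:
            vec[SIGNAL_INDEX[t]] = 1
        return vec

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.length, dtype=np.int8)
        for _, start, end in self.regions:
            m[start - 1 : end] = 1
        return m

    def mask_for(self, signal_type: str) -> np.ndarray:
        m = np.zeros(self.length, dtype=np.int8)
        for t, start, end in self.regions:
            if t == signal_type:
                m[start - 1 : end] = 1
        return m


@dataclass
class LabeledSequence:
    """A protein record joined with its labels and optional signal annotation."""

    record: ProteinRecord
    localization: LocalizationLabelSet
    signal: SignalAnnotation | None = None
    partition: int | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if self.signal is not None and self.signal.length != self.record.length:
            raise AnnotationError(
                f"signal annotation length {self.signal.length} != sequence "
                f"length {self.record.length} for {self.record.id}"
            )


def _canonicalize(seq: str, record_id: str, on_invalid: str = "mask") -> str:
    seq = seq.upper()
    out = []
    for ch in seq:
        if ch in ALPHABET:
            out.append(ch)
        elif ch in NONCANONICAL_TO_X:
            logger.warning("record %s: residue %s mapped to X", record_id, ch)
            out.append("X")
        elif on_invalid == "mask":
            logger.warning("record %s: invalid residue %r masked to X", record_id, ch)
            out.append("X")
        else:
            raise FastaError(
                f"record {record_id!r}: invalid residue {ch!r} "
                f"(alphabet is {ALPHABET})"
            )
    return "".join(out)


def read_fasta(path: str | Path, on_invalid: str = "mask") -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, in file order.

    Headers are truncated at the first whitespace; lowercase letters are
    uppercased; ambiguous residues (B, Z, J, U, O) become X.  ``on_invalid``
    controls other out-of-alphabet characters: ``"mask"`` replaces them with X
    (logged), ``"error"`` raises.
    """
    path = Path(path)
    # Validate the framing ourselves: Biopython silently skips leading junk
    # and permits duplicate ids, both of which must be hard errors here.
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                seen_header = True
            elif not seen_header:
                raise FastaError(
                    f"{path}: line {lineno}: sequence data before first header"
                )
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = _canonicalize(str(rec.seq), rec.id, on_invalid=on_invalid)
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _parse_signal_field(
    text: str, length: int
) -> SignalAnnotation | None:
    text = (text or "").strip()
    if not text:
        return None
    regions: list[tuple[str, int, int]] = []
    types: list[str] = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            type_part, span = token.split(":")
            start_s, end_s = span.split("-")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationError(
                f"cannot parse signal region {token!r}; expected TYPE:START-END"
            ) from exc
        regions.append((type_part, start, end))
        if type_part not in types:
            types.append(type_part)
    return SignalAnnotation(types=tuple(types), regions=tuple(regions), length=length)


def read_annotations(
    path: str | Path,
    sequences: Sequence[ProteinRecord],
    classes: Sequence[str] = LOCALIZATION_CLASSES,
) -> list[LabeledSequence]:
    """Join an annotation CSV (id, localization, [signals], [partition],
    [family]) to sequence records by id.

    Unmatched table ids are reported via a warning; signal intervals are
    validated against each sequence's length.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns or "localization" not in df.columns:
        raise AnnotationError(
            f"{path}: annotation table needs at least columns 'id' and "
            f"'localization'; found {list(df.columns)}"
        )
    by_id = {rec.id: rec for rec in sequences}
    out: list[LabeledSequence] = []
    unmatched: list[str] = []
    for row in df.itertuples(index=False):
        rid = row.id.strip()
        rec = by_id.get(rid)
        if rec is None:
            unmatched.append(rid)
            continue
        labels = [t.strip() for t in row.localization.split(";") if t.strip()]
        loc = LocalizationLabelSet.from_labels(labels, classes=classes)
        signal = None
        if "signals" in df.columns:
            signal = _parse_signal_field(getattr(row, "signals"), rec.length)
        partition = None
        if "partition" in df.columns and getattr(row, "partition").strip():
            partition = int(getattr(row, "partition"))
        family = None
        if "family" in df.columns and getattr(row, "family").strip():
            family = getattr(row, "family").strip()
        out.append(
            LabeledSequence(
                record=rec, localization=loc, signal=signal,
                partition=partition, family=family,
            )
        )
    if unmatched:
        logger.warning(
            "%d annotation rows had no matching sequence (e.g. %s)",
            len(unmatched), unmatched[:5],
        )
    return out


def write_annotations(data: Iterable[LabeledSequence], path: str | Path) -> None:
    rows = []
    for ls in data:
        sig = ""
        if ls.signal is not None:
            sig = ";".join(f"{t}:{s}-{e}" for t, s, e in ls.signal.regions)
        rows.append(
            {
                "id": ls.record.id,
                "localization": ";".join(ls.localization.labels),
                "signals": sig,
                "partition": "" if ls.partition is None else ls.partition,
                "family": ls.family or "",
            }
        )
    pd.DataFrame(
        rows, columns=["id", "localization", "signals", "partition", "family"]
    ).to_csv(path, index=False)


def write_predictions(
    ids: Sequence[str],
    loc_scores: np.ndarray,
    loc_decided: np.ndarray,
    sig_scores: np.ndarray | None,
    sig_decided: np.ndarray | None,
    path: str | Path,
    attention: Sequence[np.ndarray] | None = None,
    attention_path: str | Path | None = None,
    loc_classes: Sequence[str] = LOCALIZATION_CLASSES,
    sig_classes: Sequence[str] = SIGNAL_CLASSES,
) -> None:
    """Write the prediction summary CSV and, optionally, the long-format
    per-residue attention CSV (id, position, attention).

    The summary has one row per sequence: decided localization labels and
    signal types (semicolon-joined) followed by every per-label score.
    """
    n = len(ids)
    rows = []
    for i in range(n):
        row: dict[str, object] = {"id": ids[i]}
        row["localizations"] = ";".join(
            c for c, b in zip(loc_classes, loc_decided[i]) if b
        )
        if sig_decided is not None:
            row["signals"] = ";".join(
                c for c, b in zip(sig_classes, sig_decided[i]) if b
            )
        for j, c in enumerate(loc_classes):
            row[f"score_{c}"] = float(loc_scores[i, j])
        if sig_scores is not None:
            for j, c in enumerate(sig_classes):
                row[f"score_{c}"] = float(sig_scores[i, j])
        rows.append(row)
    columns = ["id", "localizations"]
    if sig_decided is not None:
        columns.append("signals")
    columns += [f"score_{c}" for c in loc_classes]
    if sig_scores is not None:
        columns += [f"score_{c}" for c in sig_classes]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)

    if attention is not None and attention_path is not None:
        att_rows = []
        for i in range(n):
            a = np.asarray(attention[i], dtype=float)
            for pos in range(a.shape[0]):
                att_rows.append(
                    {"id": ids[i], "position": pos + 1, "attention": a[pos]}
                )
        pd.DataFrame(
            att_rows, columns=["id", "position", "attention"]
        ).to_csv(attention_path, index=False)
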