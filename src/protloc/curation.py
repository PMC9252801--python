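"""Corpus-construction filters and sublocation-term mapping.

Two corpus shapes are produced from raw annotation tables:

- a training-style corpus retaining eukaryotic, non-fragment,
  nucleus-encoded proteins longer than 40 residues whose sublocation terms
  carry experimental evidence (ECO:0000269) and map into the ten-class
  localization vocabulary (fragments are excluded because they may be missing
  the N- or C-terminal sorting signals the model is meant to find);
- an immunofluorescence-benchmark-style corpus retaining only annotations
  with the two highest reliability grades (Enhanced, Supported), mapped into
  the six compartments such benchmarks resolve.

The experimental-evidence requirement is applied per sublocation term: only
terms carrying ECO:0000269 contribute labels, so non-experimental terms never
leak into the label set.

The free-text sublocation -> class mapping ships as a small editable CSV
(``data/subloc_mapping.csv``) covering common terms; it is a working default,
not an exhaustive controlled vocabulary, and callers may supply their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .seq_io import LabeledSequence, LocalizationLabelSet, ProteinRecord
from .vocab import HPA_CLASSES, LOCALIZATION_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "RawEntry",
    "CurationReport",
    "load_default_mapping",
    "load_mapping",
    "read_raw_entries",
    "filter_swissprot_style",
    "filter_hpa_style",
]

EXPERIMENTAL_EVIDENCE = "ECO:0000269"
MIN_LENGTH = 41  # strictly more than 40 residues
HPA_RELIABLE = ("Enhanced", "Supported")

# Filters are pure predicates, so the retained set is order-independent; the
# report counts follow this application order.
FILTER_ORDER = (
    "not_eukaryote",
    "fragment",
    "not_nucleus_encoded",
    "too_short",
    "no_experimental_evidence",
    "unmappable_terms",
)


@dataclass(frozen=True)
class RawEntry:
    """One row of a raw annotation table, before curation."""

    id: str
    sequence: str
    is_eukaryote: bool
    is_fragment: bool
    encoded_in: str  # "nucleus", "mitochondrion", "plastid", ...
    sublocations: tuple[tuple[str, tuple[str, ...]], ...]  # (term, evidence codes)
    hpa_reliability: str | None = None


@dataclass
class CurationReport:
    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    input_count: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"filter": "retained", "removed": self.retained})
        return pd.DataFrame(rows)


def load_mapping(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"term", "class"} <= set(df.columns):
        raise ValueError("mapping table needs columns 'term' and 'class'")
    mapping = {}
    for term, cls in zip(df["term"], df["class"]):
        if cls not in LOCALIZATION_CLASSES:
            raise ValueError(
                f"mapping target {cls!r} is not in the localization vocabulary"
            )
        mapping[str(term).strip().lower()] = cls
    if not mapping:
        raise ValueError("mapping table is empty")
    return mapping


def load_default_mapping() -> dict[str, str]:
    with resources.as_file(
        resources.files("protloc").joinpath("data/subloc_mapping.csv")
    ) as p:
        return load_mapping(p)


def _parse_sublocations(text: str) -> tuple[tuple[str, tuple[str, ...]], ...]:
    # "Nucleolus(ECO:0000269);Cytosol(ECO:0000250,ECO:0000269)"
    out = []
    for token in (text or "").split(";"):
        token = token.strip()
        if not token:
            continue
        if "(" in token:
            term, rest = token.split("(", 1)
            codes = tuple(
                c.strip() for c in rest.rstrip(")").split(",") if c.strip()
            )
        else:
            term, codes = token, ()
        out.append((term.strip(), codes))
    return tuple(out)


def read_raw_entries(path: str | Path) -> list[RawEntry]:
    """Read a raw annotation CSV with columns id, sequence, is_eukaryote,
    is_fragment, encoded_in, sublocations, [hpa_reliability]."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sequence", "is_eukaryote", "is_fragment", "encoded_in",
                "sublocations"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    entries = []
    truthy = {"1", "true", "yes"}
    for row in df.itertuples(index=False):
        reliability = None
        if "hpa_reliability" in df.columns and row.hpa_reliability.strip():
            reliability = row.hpa_reliability.strip()
        entries.append(
            RawEntry(
                id=row.id,
                sequence=row.sequence.upper(),
                is_eukaryote=row.is_eukaryote.strip().lower() in truthy,
                is_fragment=row.is_fragment.strip().lower() in truthy,
                encoded_in=row.encoded_in.strip().lower(),
                sublocations=_parse_sublocations(row.sublocations),
                hpa_reliability=reliability,
            )
        )
    return entries


def _map_terms(
    entry: RawEntry,
    mapping: dict[str, str],
    require_evidence: bool,
    allowed_classes: Sequence[str],
) -> list[str]:
    labels: list[str] = []
    for term, codes in entry.sublocations:
        if require_evidence and EXPERIMENTAL_EVIDENCE not in codes:
            continue
        cls = mapping.get(term.strip().lower())
        if cls is None:
            logger.debug("entry %s: unmapped term %r dropped", entry.id, term)
            continue
        if cls in allowed_classes and cls not in labels:
            labels.append(cls)
    return labels


def filter_swissprot_style(
    entries: Sequence[RawEntry],
    mapping: dict[str, str] | None = None,
) -> tuple[list[LabeledSequence], CurationReport]:
    """Apply the training-corpus filters and label mapping.

    Retains entries that are eukaryotic, not fragments, encoded in the
    nucleus, longer than 40 residues, and that have at least one sublocation
    term with experimental evidence mapping into the ten-class vocabulary.
    The label set is the union of the mapped classes.
    """
    if mapping is None:
        mapping = load_default_mapping()
    if not mapping:
        raise ValueError("empty mapping table")
    report = CurationReport(
        removed={k: 0 for k in FILTER_ORDER}, input_count=len(entries)
    )
    kept: list[LabeledSequence] = []
    for entry in entries:
        if not entry.is_eukaryote:
            report.removed["not_eukaryote"] += 1
            continue
        if entry.is_fragment:
            report.removed["fragment"] += 1
            continue
        if entry.encoded_in != "nucleus":
            report.removed["not_nucleus_encoded"] += 1
            continue
        if len(entry.sequence) < MIN_LENGTH:
            report.removed["too_short"] += 1
            continue
        experimental = [
            (t, c) for t, c in entry.sublocations if EXPERIMENTAL_EVIDENCE in c
        ]
        if not experimental:
            report.removed["no_experimental_evidence"] += 1
            continue
        labels = _map_terms(
            entry, mapping, require_evidence=True,
            allowed_classes=LOCALIZATION_CLASSES,
        )
        if not labels:
            report.removed["unmappable_terms"] += 1
            continue
        kept.append(
            LabeledSequence(
                record=ProteinRecord(id=entry.id, sequence=entry.sequence),
                localization=LocalizationLabelSet.from_labels(labels),
            )
        )
    report.retained = len(kept)
    return kept, report


def filter_hpa_style(
    entries: Sequence[RawEntry],
    mapping: dict[str, str] | None = None,
) -> list[LabeledSequence]:
    """Retain only Enhanced/Supported annotations, mapped to the six-class
    benchmark subset.  Entries without a reliability grade are an error."""
    if mapping is None:
        mapping = load_default_mapping()
    kept: list[LabeledSequence] = []
    for entry in entries:
        if entry.hpa_reliability is None:
            raise ValueError(f"entry {entry.id} lacks an hpa_reliability grade")
        if entry.hpa_reliability not in HPA_RELIABLE:
            continue
        labels = _map_terms(
            entry, mapping, require_evidence=False, allowed_classes=HPA_CLASSES
        )
        if not labels:
            continue
        kept.append(
            LabeledSequence(
                record=ProteinRecord(id=entry.id, sequence=entry.sequence),
                localization=LocalizationLabelSet.from_labels(labels),
            )
        )
    return kept
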