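"""Fixed label vocabularies and the residue alphabet.

The localization vocabulary covers the ten compartments used for the
multi-label task; its order is fixed and every binary label vector in the
package follows it.  The signal vocabulary covers the nine sorting-signal
types (signal peptide, first transmembrane segment, mitochondrial /
chloroplast / thylakoidal transit peptides, nuclear localization and export
signals, peroxisomal targeting signal, GPI-anchor signal).
"""

from __future__ import annotations

LOCALIZATION_CLASSES: tuple[str, ...] = (
    "Cytoplasm",
    "Nucleus",
    "Extracellular",
    "Cell membrane",
    "Mitochondrion",
    "Plastid",
    "Endoplasmic reticulum",
    "Lysosome/Vacuole",
    "Golgi apparatus",
    "Peroxisome",
)

SIGNAL_CLASSES: tuple[str, ...] = (
    "SP",   # signal peptide (N-terminal, secretory pathway)
    "TM",   # first transmembrane segment
    "MT",   # mitochondrial transit peptide
    "CH",   # chloroplast transit peptide
    "TH",   # thylakoidal transit peptide
    "NLS",  # nuclear localization signal
    "NES",  # nuclear export signal
    "PTS",  # peroxisomal targeting signal (C-terminal tripeptide)
    "GPI",  # GPI-anchor attachment signal
)

# Subset of compartments resolvable by immunofluorescence benchmarks such as
# the Human Protein Atlas; used by curation.filter_hpa_style.
HPA_CLASSES: tuple[str, ...] = (
    "Cytoplasm",
    "Nucleus",
    "Cell membrane",
    "Mitochondrion",
    "Endoplasmic reticulum",
    "Golgi apparatus",
)

# 20 canonical residues plus X for anything non-canonical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET: str = AMINO_ACIDS + "X"

# Ambiguous / rare letters folded into X at the I/O boundary so downstream
# encoders see a closed alphabet.
NONCANONICAL_TO_X: frozenset[str] = frozenset("BZJUO")

LOC_INDEX: dict[str, int] = {c: i for i, c in enumerate(LOCALIZATION_CLASSES)}
SIGNAL_INDEX: dict[str, int] = {c: i for i, c in enumerate(SIGNAL_CLASSES)}
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}
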