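"""PPR protein records, repeat annotations and specificity-pair extraction.

A P-type pentatricopeptide-repeat (PPR) protein carries a tandem array of
~35-aa helical repeats; each repeat reads one nucleotide of the RNA target.
The nucleotide preference of a repeat is encoded by two residues: the fifth
residue of the first helix and the final residue of the loop joining the
repeat to the next one.  This module represents the protein, its repeat
boundaries (which are an *input*, typically from a PPR-annotation database),
and extracts those (position-5, last) residue pairs in repeat order.

All protein coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    AlphabetError,
    AnnotationError,
    CoordinateError,
    FormatError,
)

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Average (isotope-abundance weighted) residue masses in Da, i.e. the mass
#: of the amino acid minus one water.  Summing residues and adding one water
#: gives the average molecular mass of the peptide.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153

#: Placeholder mass for an undetermined residue (X); flags the result approximate.
UNKNOWN_RESIDUE_MASS = 110.0

#: Default "strong similarity" residue classes (ClustalW-style). Overlapping
#: groups: two residues are similar if they share at least one class.
STRONG_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK",
                           "MILV", "MILF", "HY", "FYW")
)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence in the standard 20-letter alphabet (X allowed)."""

    id: str
    residues: str

    def __post_init__(self):
        seq = self.residues.upper()
        object.__setattr__(self, "residues", seq)
        if not seq:
            raise AlphabetError(f"protein {self.id!r}: empty sequence")
        bad = set(seq) - STANDARD_AA - {"X"}
        if bad:
            raise AlphabetError(
                f"protein {self.id!r}: residues outside alphabet: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MotifAnnotation:
    """One PPR repeat span, 1-based inclusive on the protein."""

    label: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"motif {self.label!r}: invalid span {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MotifTable:
    """Ordered, validated, non-overlapping repeat annotations on one protein."""

    protein_id: str
    motifs: list[MotifAnnotation] = field(default_factory=list)

    def __post_init__(self):
        labels = [m.label for m in self.motifs]
        if len(set(labels)) != len(labels):
            raise FormatError(f"duplicate motif labels in table for {self.protein_id!r}")
        self.motifs = sorted(self.motifs, key=lambda m: m.start)
        for prev, cur in zip(self.motifs, self.motifs[1:]):
            if cur.start <= prev.end:
                raise FormatError(
                    f"overlapping motifs {prev.label!r} and {cur.label!r}"
                )

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def labels(self) -> list[str]:
        return [m.label for m in self.motifs]


@dataclass(frozen=True)
class SpecificityPair:
    """The (position-5, last-residue) pair of one repeat."""

    motif_label: str
    residue_5: str
    residue_last: str


@dataclass
class AlignedPair:
    """Two gapped, equal-length aligned sequences plus similarity classes."""

    seq_a: str
    seq_b: str
    similarity_groups: Sequence[frozenset[str]] = STRONG_SIMILARITY_GROUPS

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise FormatError(
                f"aligned sequences differ in length: "
                f"{len(self.seq_a)} vs {len(self.seq_b)}"
            )


def load_motif_table(path: str | Path, protein: ProteinRecord) -> MotifTable:
    """Read a repeat-boundary TSV (columns: label, start, end) for *protein*.

    Coordinates are validated against the protein length; duplicate labels
    and overlapping spans are format errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"label": str})
    required = {"label", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"motif table {path}: needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    motifs = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if not (1 <= start <= end <= protein.length):
            raise CoordinateError(
                f"motif {row.label!r}: span {start}-{end} outside protein "
                f"{protein.id!r} (length {protein.length})"
            )
        motifs.append(MotifAnnotation(str(row.label), start, end))
    return MotifTable(protein_id=protein.id, motifs=motifs)


def extract_specificity_pairs(
    protein: ProteinRecord,
    motifs: MotifTable,
    excluded_labels: Iterable[str] = frozenset({"P0"}),
) -> list[SpecificityPair]:
    """Extract (position-5, last) residue pairs in repeat order.

    ``residue_5`` is the 5th residue counting from the annotated motif start;
    ``residue_last`` is the final residue of the span regardless of the
    motif's length (30/35/37/38 aa motifs are handled uniformly).  Motifs
    whose label is in *excluded_labels* (by default the leading P0 repeat,
    which does not contribute to RNA recognition) are skipped.
    """
    excluded = set(excluded_labels)
    pairs: list[SpecificityPair] = []
    for motif in motifs:
        if motif.label in excluded:
            continue
        if motif.length < 5:
            raise AnnotationError(
                f"motif {motif.label!r} has length {motif.length} < 5; "
                "cannot index the specificity residue"
            )
        res5 = protein.residues[motif.start + 4 - 1]
        res_last = protein.residues[motif.end - 1]
        pairs.append(SpecificityPair(motif.label, res5, res_last))
    return pairs


def protein_stats(protein: ProteinRecord) -> tuple[int, float, bool]:
    """Return (length, average molecular mass in Da, approximate flag).

    The mass is the sum of average residue masses plus one water.  Unknown
    residues (X) contribute a placeholder mass and set the approximate flag.
    """
    approximate = False
    mass = WATER_MASS
    for aa in protein.residues:
        if aa == "X":
            mass += UNKNOWN_RESIDUE_MASS
            approximate = True
        else:
            mass += AVERAGE_RESIDUE_MASS[aa]
    if approximate:
        logger.warning(
            "protein %s contains X residues; mass %.2f Da is approximate",
            protein.id, mass,
        )
    return protein.length, mass, approximate


def alignment_stats(pair: AlignedPair) -> tuple[float, float]:
    """Percent identity and similarity over the scored alignment columns.

    Scored columns are those where at least one sequence has a residue
    (double-gap columns are dropped).  A column is identical if both
    residues are present and equal; similar if identical or the residues
    share a similarity class.  A gap against a residue counts in the
    denominator but is neither identical nor similar.
    """
    scored = identical = similar = 0
    for a, b in zip(pair.seq_a.upper(), pair.seq_b.upper()):
        if a == "-" and b == "-":
            continue
        scored += 1
        if a == "-" or b == "-":
            continue
        if a == b:
            identical += 1
            similar += 1
        elif any(a in g and b in g for g in pair.similarity_groups):
            similar += 1
    if scored == 0:
        raise FormatError("alignment has no scored columns")
    return 100.0 * identical / scored, 100.0 * similar / scored
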