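"""The PPR code: residue pairs to nucleotide preferences and the PWM.

The combinatorial PPR code maps the (position-5, last) residue pair of each
repeat to a preference over the four RNA bases.  The code is empirical and
degenerate, so it is represented as *data*: a code table maps residue pairs
to probability vectors over (A, C, G, U), and unseen pairs fall back to the
uniform vector with a logged warning.  Applying the table to an ordered
pair list yields a position weight matrix (PWM), one row per repeat, read
N-to-C on the protein and 5'-to-3' on the RNA.

The packaged default table (``data/ppr_code_default.tsv``) is this
package's own transcription of the canonical published pair→base
associations; it is deliberately swappable, and quantitative conclusions
should state which table was used.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError
from .proteins import STANDARD_AA, SpecificityPair

logger = logging.getLogger(__name__)

RNA_BASES = ("A", "C", "G", "U")

#: Nucleotide set -> IUPAC degenerate letter.
IUPAC_BY_SET = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("U"): "U",
    frozenset("AG"): "R", frozenset("CU"): "Y",
    frozenset("GU"): "K", frozenset("AC"): "M",
    frozenset("AU"): "W", frozenset("CG"): "S",
    frozenset("CGU"): "B", frozenset("AGU"): "D",
    frozenset("ACU"): "H", frozenset("ACG"): "V",
    frozenset("ACGU"): "N",
}

UNIFORM = np.full(4, 0.25)


def _validate_row(probs: np.ndarray, context: str) -> np.ndarray:
    if np.any(probs < 0):
        raise FormatError(f"{context}: negative probability")
    total = probs.sum()
    if abs(total - 1.0) > 1e-6:
        raise FormatError(f"{context}: probabilities sum to {total:.8f}, not 1")
    return probs / total  # renormalize tiny drift


@dataclass
class CodeTable:
    """Residue-pair → base-probability mapping with uniform fallback."""

    entries: dict[tuple[str, str], np.ndarray]
    source_label: str = "unlabelled"

    def __post_init__(self):
        for pair, probs in self.entries.items():
            self.entries[pair] = _validate_row(
                np.asarray(probs, dtype=float), f"code table pair {pair}"
            )

    def lookup(self, residue_5: str, residue_last: str) -> tuple[np.ndarray, bool]:
        """Return (probability vector, seen-in-table flag)."""
        key = (residue_5.upper(), residue_last.upper())
        if key in self.entries:
            return self.entries[key], True
        return UNIFORM.copy(), False

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PWMatrix:
    """Per-repeat base probabilities, one row per specificity pair."""

    probs: np.ndarray  # shape (L, 4), columns in RNA_BASES order
    source_pairs: list[SpecificityPair] = field(default_factory=list)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise FormatError("PWM must have shape (L, 4)")
        for i, row in enumerate(self.probs):
            self.probs[i] = _validate_row(row, f"PWM row {i + 1}")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return consensus_iupac(self, tau=0.25)


def load_code_table(path: str | Path) -> CodeTable:
    """Read a code-table TSV with columns res5, resLast, pA, pC, pG, pU."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"code table {path}: empty file") from None
    required = ["res5", "resLast", "pA", "pC", "pG", "pU"]
    if list(df.columns[:6]) != required:
        raise FormatError(
            f"code table {path}: expected columns {required}, got {list(df.columns)}"
        )
    if df.empty:
        raise FormatError(f"code table {path}: no rows")
    entries: dict[tuple[str, str], np.ndarray] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        r5, rl = str(row.res5).upper(), str(row.resLast).upper()
        for res in (r5, rl):
            if len(res) != 1 or res not in STANDARD_AA:
                raise FormatError(f"code table {path} line {i}: bad residue {res!r}")
        entries[(r5, rl)] = np.array([row.pA, row.pC, row.pG, row.pU], float)
    return CodeTable(entries=entries, source_label=str(path))


def write_code_table(table: CodeTable, path: str | Path) -> None:
    rows = [
        {"res5": r5, "resLast": rl, "pA": p[0], "pC": p[1], "pG": p[2], "pU": p[3]}
        for (r5, rl), p in sorted(table.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9f")


def default_code_table() -> CodeTable:
    """The packaged default pair→base table (see module docstring)."""
    ref = importlib.resources.files("pprchip.data") / "ppr_code_default.tsv"
    with importlib.resources.as_file(ref) as path:
        table = load_code_table(path)
    table.source_label = "pprchip-default"
    return table


def build_pwm(pairs: list[SpecificityPair], table: CodeTable) -> PWMatrix:
    """Map an ordered specificity-pair list to a PWM row by row.

    Pairs missing from the table get the uniform row; each fallback is
    logged naming the pair, because a long run of fallbacks usually means
    the wrong table rather than a genuinely novel repeat.
    """
    if not pairs:
        raise UsageError("cannot build a PWM from an empty pair list")
    rows = []
    for pair in pairs:
        probs, seen = table.lookup(pair.residue_5, pair.residue_last)
        if not seen:
            logger.warning(
                "pair (%s, %s) of motif %s not in code table %s; uniform fallback",
                pair.residue_5, pair.residue_last, pair.motif_label,
                table.source_label,
            )
        rows.append(probs)
    return PWMatrix(probs=np.vstack(rows), source_pairs=list(pairs))


def consensus_iupac(pwm: PWMatrix, tau: float = 0.25) -> str:
    """Degenerate IUPAC consensus: per row, bases with probability >= tau.

    *tau* must lie in (0, 0.5] so the set is never forced empty by a
    too-high threshold on a flat row; if no base reaches tau, the single
    most probable base is used.
    """
    if not (0 < tau <= 0.5):
        raise UsageError(f"tau must be in (0, 0.5], got {tau}")
    letters = []
    for row in pwm.probs:
        chosen = frozenset(b for b, p in zip(RNA_BASES, row) if p >= tau - 1e-12)
        if not chosen:
            chosen = frozenset({RNA_BASES[int(np.argmax(row))]})
        letters.append(IUPAC_BY_SET[chosen])
    return "".join(letters)


def load_pair_list(path: str | Path) -> list[SpecificityPair]:
    """Read a specificity-pair TSV (columns: label, res5, resLast)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"label", "res5", "resLast"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"pair list {path}: needs columns {sorted(required)}"
        )
    return [
        SpecificityPair(str(r.label), str(r.res5).upper(), str(r.resLast).upper())
        for r in df.itertuples(index=False)
    ]


def packaged_pair_list(name: str) -> list[SpecificityPair]:
    """Load one of the packaged pair lists (e.g. 'atcrp1_pairs_synthetic')."""
    ref = importlib.resources.files("pprchip.data") / f"{name}.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_pair_list(path)
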