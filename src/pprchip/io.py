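"""File-format adapters: FASTA, TSV tables, GFF3/BED, MEME-minimal motifs.

Conventions: all internal coordinates are 1-based inclusive (matching how
organellar coordinates are printed); BED output converts to 0-based
half-open as ``(start - 1, end)``; GFF3 keeps 1-based inclusive.  Writers
accept an optional header dict rendered as ``#`` comment lines, so outputs
can carry the config hash and seed.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .code import PWMatrix, RNA_BASES
from .errors import FormatError
from .footprints import FootprintRecord
from .proteins import ProteinRecord
from .ripchip import ExperimentDesign
from .scanner import MotifHit, SequenceRecord


# ---------------------------------------------------------------- FASTA

def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def read_nucleotide_fasta(
    path: str | Path, circular: bool = False
) -> list[SequenceRecord]:
    records = [
        SequenceRecord(id=rec.id, bases=str(rec.seq), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records, path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(getattr(r, "bases", None) or r.residues),
                     id=r.id, description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------- headers

def _write_header(handle, header: dict | None) -> None:
    if header:
        for key, value in header.items():
            handle.write(f"# {key}: {value}\n")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------- hits

def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "sequence_id": h.sequence_id, "start": h.start, "end": h.end,
            "strand": h.strand, "score": h.score, "p_value": h.p_value,
        } for h in hits],
        columns=["sequence_id", "start", "end", "strand", "score", "p_value"],
    )


def write_hits_tsv(
    hits: Iterable[MotifHit], path: str | Path, header: dict | None = None
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        hits_to_frame(hits).to_csv(fh, sep="\t", index=False,
                                   float_format="%.6g")


def write_hits_gff3(
    hits: Iterable[MotifHit], path: str | Path, header: dict | None = None
) -> None:
    """GFF3 (1-based inclusive); score column carries the log2 odds."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        _write_header(fh, header)
        for i, h in enumerate(hits, start=1):
            start, end = min(h.start, h.end), max(h.start, h.end)
            fh.write(
                f"{h.sequence_id}\tpprchip\tbinding_site\t{start}\t{end}\t"
                f"{h.score:.4f}\t{h.strand}\t.\t"
                f"ID=hit{i};pvalue={h.p_value:.3g}\n"
            )


def write_hits_bed(
    hits: Iterable[MotifHit], path: str | Path, header: dict | None = None
) -> None:
    """BED (0-based half-open): chromStart = start - 1, chromEnd = end."""
    with open(path, "w") as fh:
        _write_header(fh, header)
        for i, h in enumerate(hits, start=1):
            start, end = min(h.start, h.end), max(h.start, h.end)
            score = max(0, min(1000, int(round(h.score * 100))))
            fh.write(
                f"{h.sequence_id}\t{start - 1}\t{end}\thit{i}\t{score}\t{h.strand}\n"
            )


def write_footprints_bed(
    footprints: Iterable[FootprintRecord], path: str | Path,
    header: dict | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        for fp in footprints:
            fh.write(
                f"{fp.reference_id}\t{fp.norm_start - 1}\t{fp.norm_end}\t{fp.id}\n"
            )


# ---------------------------------------------------------------- MEME

def write_meme_minimal(
    pwm: PWMatrix, path: str | Path, name: str = "motif1",
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """MEME minimal motif format (RNA alphabet), for external scanners."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} U {:.5f}\n\n".format(*background))
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {len(pwm)} "
            f"nsites= 20 E= 0\n"
        )
        for row in pwm.probs:
            fh.write(" {:.6f} {:.6f} {:.6f} {:.6f}\n".format(*row))


def read_meme_minimal(path: str | Path) -> PWMatrix:
    rows: list[list[float]] = []
    in_matrix = False
    expected = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("letter-probability matrix"):
                in_matrix = True
                try:
                    tokens = dict(
                        zip(stripped.split()[2::2], stripped.split()[3::2])
                    )
                    expected = int(tokens.get("w=", "0")) or None
                except (ValueError, IndexError):
                    raise FormatError(f"{path}:{lineno}: bad matrix header")
                continue
            if in_matrix:
                if not stripped:
                    break
                parts = stripped.split()
                if len(parts) != 4:
                    raise FormatError(
                        f"{path}:{lineno}: expected 4 probabilities, "
                        f"got {len(parts)}"
                    )
                try:
                    rows.append([float(p) for p in parts])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric value")
    if not rows:
        raise FormatError(f"{path}: no letter-probability matrix found")
    if expected is not None and len(rows) != expected:
        raise FormatError(
            f"{path}: header says w={expected} but {len(rows)} rows read"
        )
    return PWMatrix(probs=np.array(rows))


def write_pwm_tsv(
    pwm: PWMatrix, path: str | Path, header: dict | None = None
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        df = pd.DataFrame(pwm.probs, columns=[f"p{b}" for b in RNA_BASES])
        df.insert(0, "position", np.arange(1, len(pwm) + 1))
        df.to_csv(fh, sep="\t", index=False, float_format="%.9f")


def read_pwm_tsv(path: str | Path) -> PWMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [f"p{b}" for b in RNA_BASES]
    missing = set(cols) - set(df.columns)
    if missing:
        raise FormatError(f"PWM table {path}: missing columns {sorted(missing)}")
    return PWMatrix(probs=df[cols].to_numpy())


# ---------------------------------------------------------------- design

def load_design(path: str | Path) -> ExperimentDesign:
    """Read an experiment-design YAML: {treatment: [...], mock: [...]}."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "treatment" not in data or "mock" not in data:
        raise FormatError(f"design file {path}: needs 'treatment' and 'mock' lists")
    return ExperimentDesign(
        treatment_arrays=[str(a) for a in data["treatment"]],
        mock_arrays=[str(a) for a in data["mock"]],
    )


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"treatment": design.treatment_arrays, "mock": design.mock_arrays},
            fh, sort_keys=False,
        )


def write_table(
    df: pd.DataFrame, path: str | Path, header: dict | None = None
) -> None:
    """Generic TSV writer with optional comment header."""
    with open(path, "w") as fh:
        _write_header(fh, header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
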