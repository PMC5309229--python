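"""sRNA footprints and co-mapping with predicted binding sites.

Organellar small RNAs ("footprints") are thought to be the remnants of
RNA regions shielded from exonucleases by a bound protein; their genomic
interval therefore marks an in-vivo binding region.  Footprint coordinate
pairs are often printed in transcript orientation and may run descending
on the reference; they are normalized to ascending intervals, keeping the
original orientation as a flag only (no strand is assigned).

Co-mapping asks whether any predicted PWM hit overlaps a footprint
interval by at least one base, and whether the best (lowest p-value)
overlapping hit passes the reporting threshold.  Containment of the best
hit inside the footprint is reported separately: footprints are usually
longer than the site, so containment is expected but overlap is the
criterion.

All intervals are closed and 1-based; BED export converts at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import CoordinateError, FormatError
from .scanner import MotifHit

logger = logging.getLogger(__name__)


def normalize_interval(a: int, b: int) -> tuple[int, int, bool, int]:
    """Return (norm_start, norm_end, descending_input, length) for a printed pair."""
    if a < 1 or b < 1:
        raise CoordinateError(f"coordinates must be >= 1, got ({a}, {b})")
    start, end = min(a, b), max(a, b)
    return start, end, a > b, end - start + 1


@dataclass(frozen=True)
class FootprintRecord:
    """A normalized footprint interval on a reference sequence."""

    id: str
    reference_id: str
    printed_start: int
    printed_end: int
    norm_start: int = field(init=False)
    norm_end: int = field(init=False)
    descending_input: bool = field(init=False)

    def __post_init__(self):
        start, end, desc, _ = normalize_interval(self.printed_start, self.printed_end)
        object.__setattr__(self, "norm_start", start)
        object.__setattr__(self, "norm_end", end)
        object.__setattr__(self, "descending_input", desc)

    @property
    def length(self) -> int:
        return self.norm_end - self.norm_start + 1


@dataclass
class CoMapping:
    """Intersection of one footprint with the predicted hits."""

    footprint_id: str
    hits_overlapping: list[MotifHit]
    best_p: float | None
    co_mapped: bool
    contained: bool


def load_footprints(path: str | Path) -> list[FootprintRecord]:
    """Read a footprint TSV (id, reference_id, start, end; printed orientation kept)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str, "reference_id": str})
    required = {"id", "reference_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"footprint table {path}: missing columns {sorted(missing)}")
    return [
        FootprintRecord(str(r.id), str(r.reference_id), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def comap(
    hits: list[MotifHit],
    footprints: list[FootprintRecord],
    p_threshold: float = 0.01,
) -> list[CoMapping]:
    """Match hits to footprints by >=1-base overlap of closed intervals.

    ``co_mapped`` requires the best overlapping p-value <= *p_threshold*;
    ``contained`` reports whether the best hit lies fully inside the
    footprint.  Hits on other reference sequences are skipped (warned once
    per footprint if nothing shares its reference).
    """
    out: list[CoMapping] = []
    hit_refs = {h.sequence_id for h in hits}
    for fp in footprints:
        if hits and fp.reference_id not in hit_refs:
            logger.warning(
                "footprint %s: no hits on reference %s; skipping comparison",
                fp.id, fp.reference_id,
            )
        overlapping = [
            h for h in hits
            if h.sequence_id == fp.reference_id
            and min(h.start, h.end) <= fp.norm_end
            and max(h.start, h.end) >= fp.norm_start
        ]
        if overlapping:
            best = min(overlapping, key=lambda h: (h.p_value, h.start))
            best_p = best.p_value
            contained = (
                fp.norm_start <= min(best.start, best.end)
                and max(best.start, best.end) <= fp.norm_end
            )
            co_mapped = best_p <= p_threshold
        else:
            best_p, contained, co_mapped = None, False, False
        out.append(CoMapping(fp.id, overlapping, best_p, co_mapped, contained))
    return out


def footprint_report(
    comappings: list[CoMapping], footprints: list[FootprintRecord]
) -> pd.DataFrame:
    """One row per footprint, ordered by reference then normalized start."""
    by_id = {c.footprint_id: c for c in comappings}
    rows = []
    for fp in sorted(footprints, key=lambda f: (f.reference_id, f.norm_start)):
        cm = by_id.get(fp.id)
        rows.append({
            "id": fp.id,
            "reference_id": fp.reference_id,
            "norm_start": fp.norm_start,
            "norm_end": fp.norm_end,
            "length": fp.length,
            "descending_input": fp.descending_input,
            "n_hits": len(cm.hits_overlapping) if cm else 0,
            "best_p": cm.best_p if cm else None,
            "co_mapped": cm.co_mapped if cm else False,
            "contained": cm.contained if cm else False,
        })
    return pd.DataFrame(
        rows,
        columns=["id", "reference_id", "norm_start", "norm_end", "length",
                 "descending_input", "n_hits", "best_p", "co_mapped", "contained"],
    )
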