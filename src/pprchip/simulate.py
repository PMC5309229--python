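"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised without any download: a
synthetic PPR code table, a repeat protein annotated like a CRP1-type
array (one leading 30-aa repeat plus 35-aa repeats), a genome with
PWM-sampled binding sites planted at known positions, footprints extending
those sites to in-vivo-like lengths (29-41 nt), and a two-color replicate
tiling-array dataset with log-normal spot noise and spiked enrichment at
designated fragments.

Defaults mirror the assayed design: two replicate arrays per experiment,
12 spots per fragment per array (24 pooled per experiment), log2 spot
noise sd 0.3, four spiked fragments among 120, spike effect 2.0 log2
units.  Each generator draws from its own RNG stream spawned from the
master seed, so regenerating one artifact does not shift the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .code import CodeTable, PWMatrix, RNA_BASES
from .errors import UsageError
from .proteins import MotifAnnotation, MotifTable, ProteinRecord
from .ripchip import ExperimentDesign
from .scanner import SequenceRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"

# fixed stream order; spawning by index keeps artifacts independent
_STREAMS = ("code_table", "protein", "genome", "footprints", "ripchip")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated design."""

    seed: int = 0
    genome_length: int = 24_000
    circular: bool = False
    n_motifs: int = 15
    code_sharpness: float = 0.9
    n_code_pairs: int = 8
    n_fragments: int = 120
    spots_per_fragment_per_array: int = 12
    arrays_per_experiment: int = 2
    n_spikes: int = 4
    spike_fragments: list[str] | None = None
    spike_effect: float = 2.0
    noise_sd: float = 0.3
    flag_fail_rate: float = 0.02
    footprint_length_range: tuple[int, int] = (29, 41)
    wrap_one_site: bool = False

    def __post_init__(self):
        for name in ("genome_length", "n_motifs", "n_fragments",
                     "spots_per_fragment_per_array", "arrays_per_experiment",
                     "n_code_pairs"):
            if getattr(self, name) <= 0:
                raise UsageError(f"{name} must be positive")
        for name in ("flag_fail_rate",):
            if not 0 <= getattr(self, name) <= 1:
                raise UsageError(f"{name} must be in [0, 1]")
        if self.spike_effect < 0:
            raise UsageError("spike_effect must be >= 0")
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """The named child RNG stream of the master seed."""
        idx = _STREAMS.index(stream)
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[idx])

    def fragment_ids(self) -> list[str]:
        return [f"frag{i:04d}" for i in range(1, self.n_fragments + 1)]

    def spiked_ids(self) -> list[str]:
        if self.spike_fragments is not None:
            return list(self.spike_fragments)
        ids = self.fragment_ids()
        step = self.n_fragments // (self.n_spikes + 1)
        return [ids[step * (k + 1)] for k in range(self.n_spikes)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["footprint_length_range"] = list(self.footprint_length_range)
        return d


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth location of a PWM-sampled window in the genome."""

    start: int  # 1-based inclusive
    end: int
    bases: str
    wraps: bool = False


def gen_code_table(config: SimulationConfig) -> CodeTable:
    """A synthetic pair→base table with the configured sharpness.

    Each generated residue pair prefers one base with probability mass
    ``code_sharpness``; the remainder is split evenly.  Preferred bases
    cycle through A, C, G, U so all four are representable.  Sharpness at
    or below 0.25 would be uninformative and is rejected.
    """
    s = config.code_sharpness
    if not 0.25 < s <= 1.0:
        raise UsageError(f"code_sharpness must be in (0.25, 1], got {s}")
    rng = config.rng("code_table")
    pairs: list[tuple[str, str]] = []
    seen = set()
    while len(pairs) < config.n_code_pairs:
        pair = (rng.choice(list(_AA)), rng.choice(list(_AA)))
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    entries = {}
    rest = (1.0 - s) / 3.0
    for i, pair in enumerate(pairs):
        probs = np.full(4, rest)
        probs[i % 4] = s
        entries[pair] = probs
    return CodeTable(entries=entries, source_label=f"synthetic(seed={config.seed})")


def gen_protein_with_motifs(
    config: SimulationConfig, table: CodeTable
) -> tuple[ProteinRecord, MotifTable]:
    """A tandem-repeat protein: one 30-aa leading motif (P0) + 35-aa repeats.

    Specificity residues (position 5 and last of each motif) are drawn from
    the code table's pair set so every scoring repeat maps to a known row.
    """
    rng = config.rng("protein")
    pair_keys = sorted(table.entries.keys())
    lengths = [30] + [35] * (config.n_motifs - 1)
    residues: list[str] = []
    motifs: list[MotifAnnotation] = []
    pos = 1
    for i, mlen in enumerate(lengths):
        body = list(rng.choice(list(_AA), size=mlen))
        r5, rlast = pair_keys[rng.integers(len(pair_keys))]
        body[4] = r5
        body[-1] = rlast
        residues.extend(body)
        motifs.append(MotifAnnotation(f"P{i}", pos, pos + mlen - 1))
        pos += mlen
    protein = ProteinRecord(id=f"SYNPPR_seed{config.seed}", residues="".join(residues))
    return protein, MotifTable(protein_id=protein.id, motifs=motifs)


def _sample_window(pwm: PWMatrix, rng: np.random.Generator) -> str:
    return "".join(
        RNA_BASES[rng.choice(4, p=row)] for row in pwm.probs
    )


def gen_genome_with_sites(
    config: SimulationConfig, pwm: PWMatrix, n_sites: int | None = None
) -> tuple[SequenceRecord, list[PlantedSite]]:
    """A uniform-background genome with PWM-sampled sites planted inside
    the spiked fragments (one per spiked fragment by default).

    Sites are non-overlapping by construction (fragment centers).  With
    ``wrap_one_site`` on a circular genome, one extra site straddles the
    origin to exercise wraparound scanning.
    """
    rng = config.rng("genome")
    L = len(pwm)
    bases = rng.choice(list(RNA_BASES), size=config.genome_length)
    flen = config.genome_length // config.n_fragments
    ids = config.fragment_ids()
    targets = config.spiked_ids() if n_sites is None else (
        config.spiked_ids()[:n_sites]
    )
    sites: list[PlantedSite] = []
    for fid in targets:
        idx = ids.index(fid)
        center = idx * flen + flen // 2
        start = center - L // 2 + 1  # 1-based
        window = _sample_window(pwm, rng)
        bases[start - 1: start - 1 + L] = list(window)
        sites.append(PlantedSite(start, start + L - 1, window))
    if config.wrap_one_site:
        if not config.circular:
            raise UsageError("wrap_one_site requires a circular genome")
        window = _sample_window(pwm, rng)
        start = config.genome_length - L // 2 + 1
        for offset, base in enumerate(window):
            bases[(start - 1 + offset) % config.genome_length] = base
        sites.append(
            PlantedSite(start, (start + L - 2) % config.genome_length + 1,
                        window, wraps=True)
        )
    genome = SequenceRecord(
        id=f"syngenome_seed{config.seed}", bases="".join(bases),
        circular=config.circular,
    )
    return genome, sites


def gen_footprints(
    sites: list[PlantedSite],
    config: SimulationConfig,
    reference_id: str,
) -> pd.DataFrame:
    """Footprint intervals extending each planted site by random flanks.

    Total lengths are drawn uniformly from ``footprint_length_range``
    (in-vivo footprints are longer than the site itself); the flank split
    between the two ends is random.  Sites wrapping the origin are skipped
    (footprint coordinates are linear records).
    """
    rng = config.rng("footprints")
    lo, hi = config.footprint_length_range
    rows = []
    n = 0
    for site in sites:
        if site.wraps:
            continue
        n += 1
        site_len = site.end - site.start + 1
        total = int(rng.integers(max(lo, site_len), hi + 1))
        flank = total - site_len
        left = int(rng.integers(0, flank + 1)) if flank > 0 else 0
        start = max(1, site.start - left)
        end = start + total - 1
        rows.append({
            "id": f"fp{n:02d}", "reference_id": reference_id,
            "start": start, "end": end,
        })
    return pd.DataFrame(rows, columns=["id", "reference_id", "start", "end"])


def gen_ripchip_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, ExperimentDesign]:
    """Fragment definitions, spot measurements and the experiment design.

    Fragments tile the genome in equal bins.  Each spot's true log2 ratio
    is ``spike_effect`` for spiked fragments on treatment arrays and 0
    otherwise, plus Gaussian noise (sd ``noise_sd``).  Intensities are
    back-computed from the target ratio around a fixed Cy3 net signal, so
    the stage-level ground truth is exact; manual flags fail at
    ``flag_fail_rate``.
    """
    rng = config.rng("ripchip")
    flen = config.genome_length // config.n_fragments
    ids = config.fragment_ids()
    frags = pd.DataFrame({
        "fragment_id": ids,
        "genome_start": [i * flen + 1 for i in range(config.n_fragments)],
        "genome_end": [(i + 1) * flen for i in range(config.n_fragments)],
        "annotation": [f"gene{i + 1:04d}" for i in range(config.n_fragments)],
    })
    frags.loc[frags.index[-1], "genome_end"] = config.genome_length

    spiked = set(config.spiked_ids())
    t_arrays = [f"T{i + 1}" for i in range(config.arrays_per_experiment)]
    m_arrays = [f"M{i + 1}" for i in range(config.arrays_per_experiment)]
    design = ExperimentDesign(treatment_arrays=t_arrays, mock_arrays=m_arrays)

    n_spots = config.spots_per_fragment_per_array
    rows = []
    f532_net, bg = 1000.0, 100.0
    for array_id in t_arrays + m_arrays:
        is_treatment = array_id in t_arrays
        for fid in ids:
            true = config.spike_effect if (is_treatment and fid in spiked) else 0.0
            ratios = true + rng.normal(0.0, config.noise_sd, size=n_spots)
            fails = rng.random(n_spots) < config.flag_fail_rate
            for ratio, fail in zip(ratios, fails):
                rows.append({
                    "array_id": array_id,
                    "fragment_id": fid,
                    "f635_fg": round(bg + f532_net * 2.0 ** ratio, 3),
                    "f635_bg": bg,
                    "f532_fg": bg + f532_net,
                    "f532_bg": bg,
                    "flag": "fail" if fail else "pass",
                })
    return frags, pd.DataFrame(rows), design
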