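"""End-to-end orchestration: repeats → PWM → scan → enrichment → co-mapping.

The stage order follows the analysis logic: specificity pairs are read off
the annotated repeats, the code table turns them into a PWM, the RIP-chip
stage (when spot data are provided) selects the enriched genome regions,
those regions are scanned for PWM hits, and hits are intersected with the
sRNA footprints.  Without spot data, scanning falls back to the supplied
sequences directly.  Every output file carries the config hash and seed in
its header so a result can be traced to its exact inputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .code import (
    build_pwm,
    consensus_iupac,
    default_code_table,
    load_code_table,
    write_code_table,
)
from .errors import StageError
from .footprints import comap, footprint_report, load_footprints
from .proteins import extract_specificity_pairs, load_motif_table
from .ripchip import (
    fragment_enrichment,
    load_fragments,
    load_spots,
    normalize_arrays,
    plot_genome_order,
    rank_peaks,
    spot_ratios,
)
from .scanner import BackgroundModel, MotifHit, SequenceRecord, scan_all
from .simulate import (
    SimulationConfig,
    gen_code_table,
    gen_footprints,
    gen_genome_with_sites,
    gen_protein_with_motifs,
    gen_ripchip_dataset,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    protein_fasta: str
    motif_table: str
    sequences_fasta: str
    out_dir: str
    code_table: str | None = None          # None -> packaged default
    spots: str | None = None
    fragments: str | None = None
    design: str | None = None
    footprints: str | None = None
    excluded_motifs: list[str] = field(default_factory=lambda: ["P0"])
    p_threshold: float = 0.01
    min_pass: int = 13
    tau: float = 0.25
    top_k: int = 4
    background: str = "uniform"            # uniform | empirical
    strands: str = "given"                 # given | both
    circular: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return decorate


@_stage("ripchip")
def _ripchip_stage(config: PipelineConfig, header: dict, out: Path):
    spots = load_spots(config.spots)
    frags = load_fragments(config.fragments)
    design = pio.load_design(config.design)
    normalized = normalize_arrays(spot_ratios(spots))
    results = fragment_enrichment(
        normalized, design, min_pass=config.min_pass,
        fragment_ids=list(frags["fragment_id"]),
    )
    pio.write_table(results, out / "enrichment.tsv", header=header)
    peaks = rank_peaks(results, config.top_k, fragment_defs=frags)
    pio.write_table(peaks, out / "peaks.tsv", header=header)
    fig = plot_genome_order(results, frags, path=out / "enrichment.png")
    import matplotlib.pyplot as plt
    plt.close(fig)
    return frags, peaks


@_stage("scan")
def _scan_stage(config: PipelineConfig, pwm, seqs):
    if config.background == "empirical":
        background = BackgroundModel.from_sequences(seqs)
    else:
        background = BackgroundModel.uniform()
    return scan_all(
        pwm, seqs, background=background,
        p_threshold=config.p_threshold, strands=config.strands,
    )


def _extract_regions(
    genome: SequenceRecord, frags: pd.DataFrame, peak_ids: list[str]
) -> list[SequenceRecord]:
    """Cut the peak fragments out of the genome, keeping genome coordinates
    recoverable via the per-region offset mapping applied to the hits."""
    regions = []
    offsets = {}
    lookup = frags.set_index("fragment_id")
    for fid in peak_ids:
        start = int(lookup.at[fid, "genome_start"])
        end = int(lookup.at[fid, "genome_end"])
        sub = genome.bases[start - 1:end]
        regions.append(SequenceRecord(id=fid, bases=sub, circular=False))
        offsets[fid] = start
    return regions, offsets


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a summary dict of outputs and key numbers."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash identifies the analysis inputs; the output location is not part of it
    hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    header = {
        "tool": "pprchip",
        "config_hash": pio.config_hash(hashed),
        "seed": config.seed,
    }
    summary: dict = {"outputs": {}, "header": header}

    # repeats -> specificity pairs -> PWM
    try:
        protein = pio.read_protein_fasta(config.protein_fasta)[0]
        motifs = load_motif_table(config.motif_table, protein)
        pairs = extract_specificity_pairs(
            protein, motifs, excluded_labels=config.excluded_motifs
        )
        table = (load_code_table(config.code_table)
                 if config.code_table else default_code_table())
        pwm = build_pwm(pairs, table)
        consensus = consensus_iupac(pwm, tau=config.tau)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("build-pwm", str(exc)) from exc
    pio.write_pwm_tsv(pwm, out / "pwm.tsv", header=header)
    pio.write_meme_minimal(pwm, out / "pwm.meme")
    summary["consensus"] = consensus
    summary["pwm_length"] = len(pwm)

    # RIP-chip enrichment selects which regions are scanned, when available
    seqs = pio.read_nucleotide_fasta(
        config.sequences_fasta, circular=config.circular
    )
    offsets = None
    if config.spots and config.fragments and config.design:
        frags, peaks = _ripchip_stage(config, header, out)
        peak_ids = list(peaks["fragment_id"])
        summary["peak_fragments"] = peak_ids
        regions, offsets = _extract_regions(seqs[0], frags, peak_ids)
        scan_seqs = regions
    else:
        logger.info("no spot dataset; scanning supplied sequences directly")
        scan_seqs = seqs

    hits = _scan_stage(config, pwm, scan_seqs)
    if offsets is not None:
        # remap region-relative hits into genome coordinates
        genome_id = seqs[0].id
        hits = [
            MotifHit(genome_id,
                     h.start + offsets[h.sequence_id] - 1,
                     h.end + offsets[h.sequence_id] - 1,
                     h.strand, h.score, h.p_value)
            for h in hits
        ]
    pio.write_hits_tsv(hits, out / "hits.tsv", header=header)
    pio.write_hits_gff3(hits, out / "hits.gff3", header=header)
    pio.write_hits_bed(hits, out / "hits.bed", header=header)
    summary["n_hits"] = len(hits)

    if config.footprints:
        try:
            fps = load_footprints(config.footprints)
            mappings = comap(hits, fps, p_threshold=config.p_threshold)
            report = footprint_report(mappings, fps)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("comap", str(exc)) from exc
        pio.write_table(report, out / "comap.tsv", header=header)
        summary["n_footprints"] = len(fps)
        summary["n_co_mapped"] = int(report["co_mapped"].sum())

    summary["outputs"] = sorted(p.name for p in out.iterdir())
    return summary


def simulate_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit the full synthetic input bundle for a pipeline run.

    Writes the code table, protein FASTA + motif TSV, genome FASTA, planted
    site ground truth, footprints, fragments, spots and design, plus a
    config echo.  Byte-identical across runs with the same (seed, config).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = gen_code_table(config)
    paths["code_table"] = out / "code_table.tsv"
    write_code_table(table, paths["code_table"])

    protein, motifs = gen_protein_with_motifs(config, table)
    paths["protein"] = out / "protein.fasta"
    pio.write_fasta([protein], paths["protein"])
    paths["motifs"] = out / "motifs.tsv"
    pio.write_table(
        pd.DataFrame(
            [{"label": m.label, "start": m.start, "end": m.end} for m in motifs]
        ),
        paths["motifs"],
    )

    pairs = extract_specificity_pairs(protein, motifs)
    pwm = build_pwm(pairs, table)
    genome, sites = gen_genome_with_sites(config, pwm)
    paths["genome"] = out / "genome.fasta"
    pio.write_fasta([genome], paths["genome"])
    paths["sites"] = out / "sites.tsv"
    pio.write_table(
        pd.DataFrame(
            [{"start": s.start, "end": s.end, "bases": s.bases,
              "wraps": s.wraps} for s in sites]
        ),
        paths["sites"],
    )

    fps = gen_footprints(sites, config, reference_id=genome.id)
    paths["footprints"] = out / "footprints.tsv"
    pio.write_table(fps, paths["footprints"])

    frags, spots, design = gen_ripchip_dataset(config)
    paths["fragments"] = out / "fragments.tsv"
    pio.write_table(frags, paths["fragments"])
    paths["spots"] = out / "spots.tsv"
    pio.write_table(spots, paths["spots"])
    paths["design"] = out / "design.yaml"
    pio.write_design(design, paths["design"])

    paths["config"] = out / "config.yaml"
    echo = config.to_dict()
    echo["config_hash"] = pio.config_hash(echo)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    return paths
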