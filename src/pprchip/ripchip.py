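"""RIP-chip tiling-array differential enrichment.

In an RNA-immunoprecipitation chip assay, RNA from the immunoprecipitation
pellet (labelled Cy5, scanned as F635) competes against supernatant RNA
(Cy3, F532) on a tiling microarray whose fragments cover the plastid
genome.  Transcripts bound by the tagged protein are enriched in the
pellet, so their spots show a high F635/F532 ratio.  A mock experiment
(untagged extract, same antibody) controls for background pull-down.

The analysis is done on log2 ratios: per-spot background-subtracted ratio,
per-array median centering, then per-fragment medians pooled across the
replicate arrays of each experiment, and finally the differential
(treatment median minus mock median).  Fragments with fewer than
``min_pass`` (default 13) passing spots in either experiment are excluded
and appear as gaps when plotted in genome order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

logger = logging.getLogger(__name__)

SPOT_COLUMNS = [
    "array_id", "fragment_id", "f635_fg", "f635_bg", "f532_fg", "f532_bg", "flag",
]

#: Paper-design defaults: two replicate arrays per experiment, spots pass QC
#: only if the fragment keeps at least 13 passing spots per experiment.
DEFAULT_MIN_PASS = 13


@dataclass
class ExperimentDesign:
    """Which arrays belong to the treatment (tagged IP) and mock experiments."""

    treatment_arrays: list[str]
    mock_arrays: list[str]

    def __post_init__(self):
        if not self.treatment_arrays or not self.mock_arrays:
            raise FormatError("design needs >= 1 array per experiment")
        overlap = set(self.treatment_arrays) & set(self.mock_arrays)
        if overlap:
            raise FormatError(f"arrays in both experiments: {sorted(overlap)}")

    def experiment_of(self) -> dict[str, str]:
        out = {a: "treatment" for a in self.treatment_arrays}
        out.update({a: "mock" for a in self.mock_arrays})
        return out


def load_spots(path: str | Path) -> pd.DataFrame:
    """Read a spot TSV (GenePix-results-like subset of columns)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"spot table {path}: missing columns {sorted(missing)}")
    return df[SPOT_COLUMNS].copy()


def load_fragments(path: str | Path) -> pd.DataFrame:
    """Read a fragment-definition TSV (fragment_id, genome_start, genome_end, annotation)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"fragment_id", "genome_start", "genome_end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"fragment table {path}: missing columns {sorted(missing)}")
    if (df["genome_start"] > df["genome_end"]).any():
        raise FormatError(f"fragment table {path}: start > end")
    if "annotation" not in df.columns:
        df["annotation"] = ""
    return df.sort_values("genome_start", kind="mergesort").reset_index(drop=True)


def spot_ratios(spots: pd.DataFrame) -> pd.DataFrame:
    """Per-spot log2 enrichment ratio with validity status.

    ratio = log2((F635_fg - F635_bg) / (F532_fg - F532_bg)).  A spot is
    invalid (status is a reason string, never an exception) if its manual
    flag is ``fail``, its F532 foreground does not exceed background, or
    its Cy5 numerator is non-positive.
    """
    df = spots.copy()
    num = df["f635_fg"] - df["f635_bg"]
    den = df["f532_fg"] - df["f532_bg"]
    reason = np.full(len(df), "", dtype=object)
    reason[(num <= 0) & (reason == "")] = "F635 not above background"
    reason[(den <= 0)] = "F532 below background"
    reason[df["flag"].astype(str).str.lower() == "fail"] = "manual flag"
    valid = reason == ""
    ratio = np.full(len(df), np.nan)
    ok = valid.astype(bool)
    ratio[ok] = np.log2(num[ok] / den[ok])
    df["log2_ratio"] = ratio
    df["valid"] = valid
    df["invalid_reason"] = reason
    return df


def normalize_arrays(ratios: pd.DataFrame) -> pd.DataFrame:
    """Median-center valid log2 ratios within each array.

    Arrays with no valid spot are dropped with a warning.  The operation is
    idempotent: re-centering already centered ratios changes nothing.
    """
    df = ratios.copy()
    kept = []
    for array_id, group in df.groupby("array_id", sort=False):
        valid = group.loc[group["valid"], "log2_ratio"]
        if valid.empty:
            logger.warning("array %s has no valid spots; dropped", array_id)
            continue
        group = group.copy()
        group.loc[group["valid"], "log2_ratio"] = valid - valid.median()
        kept.append(group)
    if not kept:
        raise FormatError("no arrays with valid spots")
    return pd.concat(kept, ignore_index=True)


def fragment_enrichment(
    normalized: pd.DataFrame,
    design: ExperimentDesign,
    min_pass: int = DEFAULT_MIN_PASS,
    fragment_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-fragment medians per experiment and the differential enrichment.

    Valid spots are pooled across the replicate arrays of each experiment
    before the median.  A fragment is included only if both experiments
    have at least *min_pass* passing spots; excluded fragments keep their
    row (``included == False``) with NaN differential.
    """
    if min_pass < 1:
        raise UsageError(f"min_pass must be >= 1, got {min_pass}")
    expmap = design.experiment_of()
    df = normalized[normalized["array_id"].isin(expmap)].copy()
    df["experiment"] = df["array_id"].map(expmap)
    valid = df[df["valid"]]

    counts = (
        valid.groupby(["fragment_id", "experiment"]).size().unstack(fill_value=0)
    )
    medians = (
        valid.groupby(["fragment_id", "experiment"])["log2_ratio"]
        .median()
        .unstack()
    )
    all_ids = fragment_ids if fragment_ids is not None else sorted(
        set(normalized["fragment_id"])
    )
    rows = []
    for fid in all_ids:
        n_t = int(counts.at[fid, "treatment"]) if (
            fid in counts.index and "treatment" in counts.columns
        ) else 0
        n_m = int(counts.at[fid, "mock"]) if (
            fid in counts.index and "mock" in counts.columns
        ) else 0
        med_t = medians.at[fid, "treatment"] if (
            fid in medians.index and "treatment" in medians.columns
        ) else np.nan
        med_m = medians.at[fid, "mock"] if (
            fid in medians.index and "mock" in medians.columns
        ) else np.nan
        included = n_t >= min_pass and n_m >= min_pass
        if n_t == 0 and n_m == 0:
            logger.info("fragment %s has zero passing spots; excluded", fid)
        rows.append({
            "fragment_id": fid,
            "n_pass_treatment": n_t,
            "n_pass_mock": n_m,
            "median_treatment": med_t if included else np.nan,
            "median_mock": med_m if included else np.nan,
            "differential": (med_t - med_m) if included else np.nan,
            "included": included,
        })
    return pd.DataFrame(rows)


def rank_peaks(
    results: pd.DataFrame,
    k: int,
    fragment_defs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Top-*k* included fragments by descending differential enrichment.

    Ties are broken by genome position (ascending) when *fragment_defs* is
    given, otherwise by fragment_id; *k* beyond the included count truncates.
    """
    if k <= 0:
        raise UsageError(f"k must be positive, got {k}")
    if results.empty:
        raise UsageError("rank_peaks needs a nonempty result table")
    inc = results[results["included"]].copy()
    if fragment_defs is not None:
        pos = fragment_defs.set_index("fragment_id")["genome_start"]
        inc["_pos"] = inc["fragment_id"].map(pos)
    else:
        inc["_pos"] = inc["fragment_id"]
    inc = inc.sort_values(
        ["differential", "_pos"], ascending=[False, True], kind="mergesort"
    )
    return inc.drop(columns="_pos").head(k).reset_index(drop=True)


def genome_order_series(
    results: pd.DataFrame, fragment_defs: pd.DataFrame
) -> pd.DataFrame:
    """Differentials ordered by genome coordinate, NaN gaps at excluded fragments."""
    merged = fragment_defs.merge(results, on="fragment_id", how="left")
    merged = merged.sort_values("genome_start", kind="mergesort").reset_index(drop=True)
    merged["differential"] = merged["differential"].where(
        merged["included"].fillna(False).astype(bool)
    )
    return merged[["fragment_id", "genome_start", "genome_end",
                   "annotation", "differential", "included"]]


def plot_genome_order(
    results: pd.DataFrame,
    fragment_defs: pd.DataFrame,
    path: str | Path | None = None,
):
    """Plot differential enrichment in plastid genome order.

    Excluded fragments are missing values, rendered as gaps in the curve.
    Returns the matplotlib figure (saved to *path* if given).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series = genome_order_series(results, fragment_defs)
    fig, ax = plt.subplots(figsize=(10, 3.2))
    if series.empty:
        logger.warning("no fragments to plot")
    else:
        x = (series["genome_start"] + series["genome_end"]) / 2
        ax.plot(x, series["differential"], "-", lw=1, color="0.3")
        ax.plot(x, series["differential"], ".", ms=4, color="tab:red")
    ax.axhline(0, color="0.8", lw=0.8)
    ax.set_xlabel("genome position (bp)")
    ax.set_ylabel("differential median\nlog2(F635/F532)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
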