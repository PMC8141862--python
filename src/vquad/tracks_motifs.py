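"""Percent-mismatch track handling, observed-G4 calling and AID-motif densities.

G4-seq style assays report, per genomic interval, the percentage of sequencing
read mismatches induced by polymerase stalling at folded quadruplexes; a
region whose mismatch level reaches the calling threshold (25% by default) is
an "observed G4".  Tracks are strand-resolved and carried out-of-band (one
bedGraph per strand); all interval coordinates are 0-based half-open, matching
the BED/bedGraph standards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_seq import SequenceError, reverse_complement
from .mutagenesis import classify_context, SYC_COLDSPOT, WRC_HOTSPOT

logger = logging.getLogger("vquad")

DEFAULT_G4_THRESHOLD = 25.0  # percent mismatches


class TrackError(ValueError):
    """Malformed or inconsistent interval data."""


@dataclass
class MismatchTrack:
    """Sorted, non-overlapping percent-mismatch intervals for one strand."""

    strand: str  # top | bottom
    intervals: pd.DataFrame  # columns: chrom, start, end, value

    def __post_init__(self) -> None:
        df = self.intervals.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        if (df["end"] <= df["start"]).any():
            raise TrackError("interval with end <= start")
        if not np.isfinite(df["value"]).all():
            raise TrackError("non-finite track value")
        prev_end = df.groupby("chrom")["end"].shift()
        if (df["start"] < prev_end.fillna(-np.inf)).any():
            raise TrackError("overlapping bedGraph intervals")
        self.intervals = df


@dataclass(frozen=True)
class ObservedG4:
    """A called G4: a maximal run of track intervals at/above the threshold."""

    chrom: str
    start: int
    end: int
    strand: str
    peak_value: float


@dataclass(frozen=True)
class RegionDefinition:
    """A named genomic region (a V gene, an S region or a C region)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    region_class: str  # V | S | C

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise TrackError(f"region {self.name}: end <= start")
        if self.region_class not in ("V", "S", "C"):
            raise TrackError(f"region {self.name}: class {self.region_class!r} not in V/S/C")


@dataclass
class RegionActivity:
    """AGCT density and mismatch statistics for one region."""

    region: RegionDefinition
    agct_density: float | None = None
    mean_mismatch: float | None = None
    max_mismatch: float | None = None


def infer_region_class(name: str) -> str:
    """V/S/C class from a region name (IGHV* -> V, S* -> S, C* or Ig isotype -> C)."""
    if name.startswith("IGHV"):
        return "V"
    if name.startswith(("S", "s")):
        return "S"
    return "C"


def read_bedgraph(path: str | Path, strand: str) -> MismatchTrack:
    """Read a 4-column bedGraph into a validated :class:`MismatchTrack`.

    Strand is out-of-band (one file per strand), matching how strand-resolved
    mismatch tracks are distributed.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise TrackError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise TrackError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise TrackError(f"empty bedGraph {path}")
    return MismatchTrack(
        strand=strand,
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]),
    )


def write_bedgraph(track: MismatchTrack, path: str | Path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> list[RegionDefinition]:
    """Read regions from BED (>= 4 columns, strand in column 6 if present).

    The optional 7th column carries the region class; otherwise it is inferred
    from the name.
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise TrackError(f"{path}:{lineno}: expected >= 4 BED columns")
            strand = "top"
            if len(parts) >= 6:
                strand = {"+": "top", "-": "bottom"}.get(parts[5], parts[5])
            cls = parts[6] if len(parts) >= 7 else infer_region_class(parts[3])
            try:
                regions.append(
                    RegionDefinition(
                        name=parts[3],
                        chrom=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        strand=strand,
                        region_class=cls,
                    )
                )
            except (ValueError, TrackError) as exc:
                raise TrackError(f"{path}:{lineno}: {exc}") from exc
    if not regions:
        raise TrackError(f"empty BED {path}")
    return regions


def write_bed(regions: list[RegionDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            strand = {"top": "+", "bottom": "-"}.get(r.strand, r.strand)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{strand}\t{r.region_class}\n")


def call_observed_g4(track: MismatchTrack, threshold: float = DEFAULT_G4_THRESHOLD) -> list[ObservedG4]:
    """Maximal merged runs of intervals with value >= threshold (zero-gap merge)."""
    calls: list[ObservedG4] = []
    hot = track.intervals[track.intervals["value"] >= threshold]
    for chrom, sub in hot.groupby("chrom", sort=True):
        cur = None  # [start, end, peak]
        for row in sub.itertuples():
            if cur is not None and row.start <= cur[1]:
                cur[1] = max(cur[1], row.end)
                cur[2] = max(cur[2], row.value)
            else:
                if cur is not None:
                    calls.append(ObservedG4(chrom, cur[0], cur[1], track.strand, cur[2]))
                cur = [row.start, row.end, row.value]
        if cur is not None:
            calls.append(ObservedG4(chrom, cur[0], cur[1], track.strand, cur[2]))
    return calls


def region_mismatch_stats(
    track: MismatchTrack, region: RegionDefinition
) -> tuple[float | None, float | None]:
    """(max, width-weighted mean) percent mismatch over the region.

    Only positions covered by track intervals contribute; a region with no
    covered positions reports (None, None) — missing, never zero.
    """
    sub = track.intervals[track.intervals["chrom"] == region.chrom]
    starts = np.maximum(sub["start"].to_numpy(), region.start)
    ends = np.minimum(sub["end"].to_numpy(), region.end)
    widths = ends - starts
    mask = widths > 0
    if not mask.any():
        return None, None
    values = sub["value"].to_numpy()[mask]
    widths = widths[mask]
    return float(values.max()), float(np.average(values, weights=widths))


def motif_density(seq: str, motif: str) -> float:
    """Possibly-overlapping motif occurrences per nt of sequence."""
    if not seq:
        raise SequenceError("empty sequence")
    if not motif or len(motif) > len(seq):
        raise ValueError("motif must be nonempty and no longer than the sequence")
    count = sum(1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif)
    return count / len(seq)


def fold_difference(d1: float, d2: float) -> float:
    """Plain ratio d1/d2 of two densities."""
    if d2 == 0:
        raise ZeroDivisionError("fold difference undefined for zero denominator")
    return d1 / d2


def scan_aid_motifs(seq: str) -> list[tuple[str, str, str, int]]:
    """All WRC hotspot and SYC coldspot occurrences on both strands.

    Returns (motif_class, trinucleotide, strand, pos) tuples where ``pos`` is
    the 1-based top-strand coordinate of the targeted C — for bottom-strand
    motifs, of the complementary top-strand G.  A palindromic AGCT emits its
    two overlapping AGC hotspots, one per strand.
    """
    bad = set(seq) - set("ACGT")
    if bad:
        raise SequenceError(f"invalid characters {sorted(bad)} in sequence")
    hits: list[tuple[str, str, str, int]] = []
    n = len(seq)
    for i in range(n):  # 0-based
        if seq[i] == "C" and i >= 2:
            tri = seq[i - 2 : i + 1]
            cls = classify_context(tri)
            if cls in (WRC_HOTSPOT, SYC_COLDSPOT):
                hits.append((cls, tri, "top", i + 1))
        elif seq[i] == "G" and i <= n - 3:
            tri = reverse_complement(seq[i : i + 3])
            cls = classify_context(tri)
            if cls in (WRC_HOTSPOT, SYC_COLDSPOT):
                hits.append((cls, tri, "bottom", i + 1))
    return hits


def correlate_potential_vs_activity(per_gene: pd.DataFrame) -> dict:
    """Per-strand Spearman correlation of G4 potential vs max percent mismatch.

    ``per_gene`` needs columns gene, strand, potential, max_mismatch.  Returns
    {"spearman": {strand: (rho, p) or None}, "strand_test": MW U p-value}
    where a strand with a constant potential or mismatch vector reports None
    (undefined, not zero) and the strand test compares top vs bottom per-gene
    max mismatches, two-sided.
    """
    required = {"gene", "strand", "potential", "max_mismatch"}
    if not required <= set(per_gene.columns):
        raise ValueError(f"per_gene must have columns {sorted(required)}")
    out: dict = {"spearman": {}, "strand_test": None}
    for strand, sub in per_gene.groupby("strand"):
        if len(sub) < 3:
            raise ValueError(f"need >= 3 genes per strand, got {len(sub)} for {strand}")
        pot = sub["potential"].to_numpy(dtype=float)
        mm = sub["max_mismatch"].to_numpy(dtype=float)
        if np.ptp(pot) == 0 or np.ptp(mm) == 0:
            logger.warning("constant vector on %s strand: correlation undefined", strand)
            out["spearman"][strand] = None
        else:
            r = stats.spearmanr(pot, mm)
            out["spearman"][strand] = (float(r.statistic), float(r.pvalue))
    tops = per_gene.loc[per_gene["strand"] == "top", "max_mismatch"].to_numpy(dtype=float)
    bots = per_gene.loc[per_gene["strand"] == "bottom", "max_mismatch"].to_numpy(dtype=float)
    if len(tops) and len(bots):
        out["strand_test"] = float(
            stats.mannwhitneyu(tops, bots, alternative="two-sided").pvalue
        )
    return out


def region_activity_report(
    regions: list[RegionDefinition],
    tracks: dict[str, MismatchTrack],
    sequences: dict[str, str] | None = None,
    motif: str = "AGCT",
) -> pd.DataFrame:
    """Per-region, per-strand motif density and mismatch statistics.

    ``tracks`` maps strand -> MismatchTrack; ``sequences`` maps region name ->
    DNA string for density computation (density is NaN where absent).
    """
    rows = []
    for region in regions:
        density = np.nan
        if sequences and region.name in sequences:
            density = motif_density(sequences[region.name], motif)
        for strand, track in tracks.items():
            mx, mean = region_mismatch_stats(track, region)
            rows.append(
                (
                    region.name, region.region_class, strand, density,
                    np.nan if mx is None else mx,
                    np.nan if mean is None else mean,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["region", "region_class", "strand", "motif_density", "max_mismatch", "mean_mismatch"],
    )
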