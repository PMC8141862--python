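"""Synthetic study inputs: germline alleles, SHM repertoires, mismatch tracks.

Every external dataset the analyses consume has a generator here that emulates
its statistical structure under full seed control:

* V-like germline alleles (~300 nt) with canonical G4 cassettes planted on a
  chosen strand and AID motifs planted at recorded positions, plus an
  IMGT-style FW/CDR region layout with gap placeholders;
* SHM repertoires in which each site mutates independently at a base rate
  (~1e-3 per bp, the physiological SHM order of magnitude) scaled by
  hotspot/coldspot multipliers and an optional G4 strand-coupling factor;
* strand-resolved percent-mismatch tracks with elevated signal over planted
  cassette footprints on the cassette's strand plus truncated-normal noise.

Backgrounds are sampled with G- and C-runs capped below the canonical minimum
run length, so every canonical G4 match in a simulated allele is a planted
one, on either strand — the ground truth emitted alongside is exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_seq import IghvAllele, reverse_complement
from .shm_analysis import RepertoireAlignment
from .tracks_motifs import MismatchTrack, RegionDefinition
from .mutagenesis import SYC_COLDSPOT, WRC_HOTSPOT
from .tracks_motifs import scan_aid_motifs

logger = logging.getLogger("vquad")

FAMILIES = tuple(f"IGHV{i}" for i in range(1, 8))


@dataclass
class G4CassetteSpec:
    """A planted canonical quadruplex: four G-runs with fixed loops."""

    strand: str = "top"  # top | bottom
    count: int = 1  # cassettes per carrier allele
    min_run: int = 3
    loops: tuple[int, int, int] = (1, 2, 1)

    def sequence(self, rng: np.random.Generator) -> str:
        run = "G" * self.min_run
        parts = [run]
        for loop in self.loops:
            if not 1 <= loop <= 7:
                raise ValueError("loop lengths must be in [1, 7]")
            parts.append("".join(rng.choice(["A", "T"], size=loop)))
            parts.append(run)
        cassette = "".join(parts)
        return cassette if self.strand == "top" else reverse_complement(cassette)


@dataclass
class GermlineSimConfig:
    """Conditions for the simulated germline set.

    Defaults mirror the study design: 40 V genes (the number of functional
    IGHV genes locatable in the reference genome), ~300 nt each, with a
    canonical G4 cassette planted in half of them so cassette carriers and
    non-carriers can be contrasted.
    """

    n_alleles: int = 40
    length: int = 300  # gapped length, nt
    gc_content: float = 0.45
    g4_cassette: G4CassetteSpec = field(default_factory=G4CassetteSpec)
    cassette_fraction: float = 0.5  # fraction of alleles carrying cassettes
    cassette_families: tuple[str, ...] | None = None  # restrict carriers to families
    planted_motifs: tuple[tuple[str, str, int], ...] = (("AGCT", "top", 2),)
    n_gaps_per_cdr: int = 3  # '.' placeholders inserted in CDR1 and CDR2
    id_prefix: str = "S"  # simulated gene names are {family}-{prefix}{i}
    seed: int = 0


@dataclass
class ShmSimConfig:
    """Conditions for a simulated mutated repertoire.

    base_rate defaults to 1e-3 per nt, the order of magnitude of SHM per cell
    division; hotspot and coldspot multipliers scale WRC / SYC targeted-C
    sites; g4_strand_coupling multiplies (a) motif sites whose C lies on the
    strand carrying a planted G4 and (b) CCC coldspots on the opposite strand,
    emulating preferential AID access where the complementary strand folds.
    """

    n_reads: int = 2000
    base_rate: float = 1e-3
    hotspot_multiplier: float = 5.0
    coldspot_multiplier: float = 0.3
    g4_strand_coupling: float = 1.0
    seed: int = 0


@dataclass
class TrackSimConfig:
    """Conditions for simulated percent-mismatch tracks."""

    peak_height: float = 60.0  # percent, over planted cassette footprints
    peak_sd: float = 4.0
    background_mean: float = 5.0
    background_sd: float = 2.0
    interval_width: int = 15  # nt per bedGraph interval
    gene_spacing: int = 100  # nt between genes on the synthetic contig
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.peak_height <= 100 or not 0 <= self.background_mean <= 100:
            raise ValueError("track heights must lie in [0, 100]")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _background(rng: np.random.Generator, length: int, gc: float, max_run: int) -> list[str]:
    """Random background with every G-run and C-run shorter than ``max_run``."""
    probs = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    out: list[str] = []
    for _ in range(length):
        allowed = ["A", "C", "G", "T"]
        for base in ("G", "C"):
            if len(out) >= max_run - 1 and all(x == base for x in out[-(max_run - 1):]):
                allowed.remove(base)
        p = np.array([probs[b] for b in allowed])
        out.append(str(rng.choice(allowed, p=p / p.sum())))
    return out


def _default_region_map(gapped_len: int) -> list[tuple[str, int, int]]:
    # Proportional FW/CDR layout over the gapped length (1-based inclusive).
    fracs = [("FW1", 0.25), ("CDR1", 0.10), ("FW2", 0.17), ("CDR2", 0.10), ("FW3", 0.30), ("CDR3-part", 0.08)]
    bounds = []
    pos = 1
    for name, frac in fracs:
        width = max(1, round(frac * gapped_len))
        end = min(gapped_len, pos + width - 1)
        bounds.append((name, pos, end))
        pos = end + 1
        if pos > gapped_len:
            break
    # Stretch the final region to the end.
    name, start, _ = bounds[-1]
    bounds[-1] = (name, start, gapped_len)
    return bounds


def _plant(seq: list[str], start: int, payload: str) -> None:
    for i, base in enumerate(payload):
        seq[start + i] = base


def simulate_germline_alleles(
    cfg: GermlineSimConfig,
) -> tuple[list[IghvAllele], dict]:
    """Simulate a germline allele set with exact planted-feature ground truth.

    Returns (alleles, ground_truth); ground_truth maps allele_id to its
    planted cassettes and motifs, each with 0-based half-open ungapped
    top-strand coordinates and strand, plus the cassette strand (or None).
    Planted features are flanked by A/T separators and the background carries
    no G- or C-run at the canonical minimum, so scanners recover exactly what
    was planted.
    """
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.g4_cassette
    truth: dict = {"alleles": {}, "config": {"cassette_strand": spec.strand}}
    alleles: list[IghvAllele] = []
    n_gaps = 2 * cfg.n_gaps_per_cdr
    ungapped_len = cfg.length - n_gaps
    for idx in range(cfg.n_alleles):
        family = FAMILIES[idx % len(FAMILIES)]
        allele_id = f"{family}-{cfg.id_prefix}{idx + 1}*01"
        carrier = (
            family in cfg.cassette_families
            if cfg.cassette_families is not None
            else bool(rng.random() < cfg.cassette_fraction)
        )
        seq = _background(rng, ungapped_len, cfg.gc_content, spec.min_run)
        placements: list[tuple[int, int]] = []  # occupied [start, end) incl. flanks

        def place(payload: str, tries: int = 200) -> int:
            length = len(payload) + 2  # A/T flank on both sides
            # Features stay > max_loop nt apart so a G-run of one planted
            # feature can never chain into another's quadruplex.
            margin = 8
            for _ in range(tries):
                start = int(rng.integers(0, ungapped_len - length))
                if all(start + length + margin <= s or start >= e + margin for s, e in placements):
                    flank5 = str(rng.choice(["A", "T"]))
                    flank3 = str(rng.choice(["A", "T"]))
                    _plant(seq, start, flank5 + payload + flank3)
                    placements.append((start, start + length))
                    return start + 1
            raise RuntimeError(
                f"{allele_id}: could not place a {len(payload)} nt feature without collision"
            )

        cassettes = []
        if carrier:
            for _ in range(spec.count):
                payload = spec.sequence(rng)
                start = place(payload)
                cassettes.append(
                    {"start": start, "end": start + len(payload), "strand": spec.strand}
                )
        motifs = []
        for motif, strand, count in cfg.planted_motifs:
            payload = motif if strand == "top" else reverse_complement(motif)
            for _ in range(count):
                start = place(payload)
                motifs.append(
                    {"motif": motif, "strand": strand, "start": start, "end": start + len(payload)}
                )
        # Insert IMGT-style '.' gaps inside CDR1 and CDR2 of the gapped layout.
        region_map = _default_region_map(cfg.length)
        gapped = list("".join(seq))
        for name, start, end in region_map:
            if name in ("CDR1", "CDR2") and cfg.n_gaps_per_cdr > 0:
                gap_at = (start + end) // 2  # 1-based gapped position
                for k in range(cfg.n_gaps_per_cdr):
                    gapped.insert(gap_at - 1 + k, ".")
        gapped_seq = "".join(gapped)
        if len(gapped_seq) != cfg.length:
            raise AssertionError("gap insertion produced wrong gapped length")
        allele = IghvAllele(
            allele_id=allele_id, gapped_seq=gapped_seq, region_map=region_map
        )
        alleles.append(allele)
        truth["alleles"][allele_id] = {
            "family": family,
            "carrier": carrier,
            "cassettes": cassettes,
            "motifs": motifs,
        }
    return alleles, truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def per_site_rates(
    allele: IghvAllele,
    cfg: ShmSimConfig,
    cassette_strand: str | None = None,
    cassette_footprints: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Per-site mutation probabilities for the repertoire simulator.

    Motif multipliers apply at the targeted-C top coordinate of every WRC/SYC
    occurrence on either strand; the coupling factor multiplies (a) motif
    sites whose C lies on ``cassette_strand`` and (b) CCC coldspots on the
    opposite strand lying inside a cassette footprint (0-based half-open
    ungapped intervals) — the CCCs whose complementary GGG belongs to the
    folded strand.  Rates from base_rate x multiplier alone must not exceed 1
    (config error); the coupling product is capped at 1 with a log notice.
    """
    if not 0 <= cfg.base_rate <= 1:
        raise ValueError("base_rate must be in [0, 1]")
    if cfg.hotspot_multiplier < 0 or cfg.coldspot_multiplier < 0:
        raise ValueError("multipliers must be >= 0")
    seq = allele.ungapped_seq
    footprints = cassette_footprints or []
    rates = np.full(len(seq), cfg.base_rate)
    for cls, tri, strand, pos in scan_aid_motifs(seq):
        mult = cfg.hotspot_multiplier if cls == WRC_HOTSPOT else cfg.coldspot_multiplier
        if mult * cfg.base_rate > 1:
            raise ValueError(
                f"base_rate x multiplier = {mult * cfg.base_rate} exceeds 1 at site {pos}"
            )
        rates[pos - 1] = cfg.base_rate * mult
        if cassette_strand is not None and cfg.g4_strand_coupling != 1.0:
            opposite = "bottom" if cassette_strand == "top" else "top"
            in_footprint = any(s <= pos - 1 < e for s, e in footprints)
            coupled = strand == cassette_strand or (
                tri == "CCC"
                and cls == SYC_COLDSPOT
                and strand == opposite
                and in_footprint
            )
            if coupled:
                rates[pos - 1] *= cfg.g4_strand_coupling
    capped = rates > 1.0
    if capped.any():
        logger.warning("per_site_rates: capped %d site rates at 1.0", int(capped.sum()))
        rates = np.minimum(rates, 1.0)
    return rates


def simulate_shm_repertoire(
    allele: IghvAllele,
    cfg: ShmSimConfig,
    cassette_strand: str | None = None,
    cassette_footprints: list[tuple[int, int]] | None = None,
) -> RepertoireAlignment:
    """Simulate ``n_reads`` mutated reads of the germline.

    Each site of each read mutates independently with its per-site rate; the
    substituted base is uniform over the three alternatives.  Reads cover the
    full germline (no N positions)."""
    rng = np.random.default_rng(cfg.seed)
    seq = allele.ungapped_seq
    rates = per_site_rates(allele, cfg, cassette_strand, cassette_footprints)
    germ = np.frombuffer(seq.encode(), dtype=np.uint8)
    n, L = cfg.n_reads, len(seq)
    hit = rng.random((n, L)) < rates
    reads_mat = np.tile(germ, (n, 1))
    if hit.any():
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        # Pick uniformly among the three bases differing from germline.
        choice = rng.integers(0, 3, size=int(hit.sum()))
        germ_idx = np.searchsorted(bases, reads_mat[hit])
        alt_idx = (germ_idx + 1 + choice) % 4
        reads_mat[hit] = bases[alt_idx]
    reads = ["".join(map(chr, row)) for row in reads_mat]
    return RepertoireAlignment(germline=allele, reads=reads)


def simulate_mismatch_track(
    alleles: list[IghvAllele],
    truth: dict,
    cfg: TrackSimConfig,
) -> tuple[dict[str, MismatchTrack], list[RegionDefinition], dict]:
    """Simulate strand-resolved percent-mismatch tracks over a synthetic contig.

    Genes are laid end to end with ``gene_spacing`` nt between them; each
    strand's track tiles every gene with ``interval_width`` nt intervals of
    truncated-normal background, elevated to ~``peak_height`` where an
    interval overlaps a planted cassette footprint on that strand.  Returns
    ({strand: track}, per-gene regions, genome-coordinate ground truth).
    """
    rng = np.random.default_rng(cfg.seed)
    rows: dict[str, list] = {"top": [], "bottom": []}
    regions: list[RegionDefinition] = []
    genome_truth: dict = {"cassettes": []}
    offset = cfg.gene_spacing
    for allele in alleles:
        info = truth["alleles"][allele.allele_id]
        L = len(allele.ungapped_seq)
        footprints = {
            strand: [
                (offset + c["start"], offset + c["end"])
                for c in info["cassettes"]
                if c["strand"] == strand
            ]
            for strand in ("top", "bottom")
        }
        for c in info["cassettes"]:
            genome_truth["cassettes"].append(
                {
                    "gene": allele.gene_id,
                    "strand": c["strand"],
                    "start": offset + c["start"],
                    "end": offset + c["end"],
                }
            )
        edges = list(range(0, L, cfg.interval_width)) + [L]
        for strand in ("top", "bottom"):
            for a, b in zip(edges[:-1], edges[1:]):
                g_start, g_end = offset + a, offset + b
                over_peak = any(
                    g_start < fe and g_end > fs for fs, fe in footprints[strand]
                )
                if over_peak:
                    value = float(_truncnorm(rng, cfg.peak_height, cfg.peak_sd, 1)[0])
                else:
                    value = float(
                        _truncnorm(rng, cfg.background_mean, cfg.background_sd, 1)[0]
                    )
                rows[strand].append((cfg.chrom, g_start, g_end, value))
        regions.append(
            RegionDefinition(
                name=allele.gene_id,
                chrom=cfg.chrom,
                start=offset,
                end=offset + L,
                strand="top",
                region_class="V",
            )
        )
        offset += L + cfg.gene_spacing
    tracks = {
        strand: MismatchTrack(
            strand=strand,
            intervals=pd.DataFrame(rows[strand], columns=["chrom", "start", "end", "value"]),
        )
        for strand in ("top", "bottom")
    }
    return tracks, regions, genome_truth
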