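"""Repertoire mutability analyses against germline V alleles.

Input is a set of mutated reads pre-aligned to their germline allele
(substitutions only, equal length, N = position not covered), or an equivalent
per-site mutation-count table.  From these the module derives per-site
mutation frequencies, per-motif strand-resolved mutability, the correlation of
top-minus-bottom hotspot mutability with G4 potential, and the comparison of
CCC coldspots split by whether mutating them is predicted to lower the
bottom-strand G4 potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_seq import IghvAllele, SequenceError, reverse_complement
from .g4_scoring import G4Scorer, StrandScores, score_both_strands
from .mutagenesis import AVG_G_TO_H, DEFAULT_EPSILON, MutantRecord, SYC_COLDSPOT
from .tracks_motifs import scan_aid_motifs

logger = logging.getLogger("vquad")

WRC_MOTIFS = ("AAC", "AGC", "TAC", "TGC")


@dataclass
class RepertoireAlignment:
    """Mutated reads aligned to a germline (substitutions only).

    Every read has the germline's ungapped length over {A,C,G,T,N}; an N marks
    a position the read does not cover.
    """

    germline: IghvAllele
    reads: list[str]

    def __post_init__(self) -> None:
        n = len(self.germline.ungapped_seq)
        for i, read in enumerate(self.reads):
            if len(read) != n:
                raise SequenceError(
                    f"read {i}: length {len(read)} != germline length {n}"
                )
            bad = set(read) - set("ACGTN")
            if bad:
                raise SequenceError(f"read {i}: invalid characters {sorted(bad)}")

    def reverse_complemented(self) -> "RepertoireAlignment":
        """The same alignment with germline and every read reverse-complemented."""
        flipped = IghvAllele(
            allele_id=self.germline.allele_id,
            gapped_seq=reverse_complement(self.germline.ungapped_seq),
        )
        return RepertoireAlignment(
            germline=flipped, reads=[reverse_complement(r) for r in self.reads]
        )


@dataclass(frozen=True)
class MotifMutability:
    gene_id: str
    motif: str
    strand: str
    mean_freq: float
    n_sites: int


@dataclass
class CccComparison:
    group: str  # no_difference | negative_change
    frequencies: list[float]
    p_value: float | None = None


def site_mutation_frequencies(aln: RepertoireAlignment) -> pd.DataFrame:
    """Per-site coverage, mutated-read count and frequency.

    Columns: pos (1-based), coverage, mutated, frequency (NaN at coverage 0).
    """
    germ = np.frombuffer(aln.germline.ungapped_seq.encode(), dtype=np.uint8)
    if aln.reads:
        mat = np.frombuffer("".join(aln.reads).encode(), dtype=np.uint8).reshape(
            len(aln.reads), len(germ)
        )
        covered = mat != ord("N")
        coverage = covered.sum(axis=0)
        mutated = ((mat != germ) & covered).sum(axis=0)
    else:
        coverage = np.zeros(len(germ), dtype=int)
        mutated = np.zeros(len(germ), dtype=int)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(coverage > 0, mutated / np.maximum(coverage, 1), np.nan)
    return pd.DataFrame(
        {
            "pos": np.arange(1, len(germ) + 1),
            "coverage": coverage,
            "mutated": mutated,
            "frequency": freq,
        }
    )


def read_mutation_counts(path: str | Path) -> pd.DataFrame:
    """Read the tabular alternative input: allele_id, pos, mutated, coverage (TSV).

    Returns the same per-site frame as :func:`site_mutation_frequencies`, with
    an extra allele_id column, for privacy-reduced datasets without reads.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"allele_id", "pos", "mutated", "coverage"}
    if not required <= set(df.columns):
        raise ValueError(f"mutation-count table must have columns {sorted(required)}")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["frequency"] = np.where(
            df["coverage"] > 0, df["mutated"] / df["coverage"].clip(lower=1), np.nan
        )
    return df


def motif_mutability(
    aln: RepertoireAlignment,
    motifs: list[tuple[str, str, str, int]] | None = None,
    site_freqs: pd.DataFrame | None = None,
) -> list[MotifMutability]:
    """Mean targeted-base mutation frequency per motif and strand.

    ``motifs`` defaults to the germline's own AID-motif scan; bottom-strand
    motifs are tallied at the top-strand coordinate of the complementary base.
    Sites with zero coverage are dropped; motifs without any covered site are
    omitted.  Pass ``site_freqs`` to reuse precomputed per-site frequencies
    (e.g. from a mutation-count table).
    """
    if motifs is None:
        motifs = scan_aid_motifs(aln.germline.ungapped_seq)
    if site_freqs is None:
        site_freqs = site_mutation_frequencies(aln)
    freq_at = dict(zip(site_freqs["pos"], site_freqs["frequency"]))
    grouped: dict[tuple[str, str], list[float]] = {}
    for _cls, tri, strand, pos in motifs:
        f = freq_at.get(pos)
        if f is None or np.isnan(f):
            continue
        grouped.setdefault((tri, strand), []).append(float(f))
    out = [
        MotifMutability(
            gene_id=aln.germline.gene_id,
            motif=tri,
            strand=strand,
            mean_freq=float(np.mean(vals)),
            n_sites=len(vals),
        )
        for (tri, strand), vals in sorted(grouped.items())
    ]
    return out


def mutability_table(rows: list[MotifMutability]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "motif": [r.motif for r in rows],
            "strand": [r.strand for r in rows],
            "mean_freq": [r.mean_freq for r in rows],
            "n_sites": [r.n_sites for r in rows],
        }
    )


def topbottom_difference_vs_potential(
    mutab: list[MotifMutability],
    scores: dict[str, StrandScores],
    motifs: tuple[str, ...] = WRC_MOTIFS,
) -> pd.DataFrame:
    """Pearson correlation of per-gene (top - bottom) motif mutability vs potential.

    For each gene the difference is mean frequency on the top strand minus the
    bottom strand, per motif; that difference is correlated against each
    strand's G4 potential.  Requires >= 3 genes with both strand rows and a
    score; genes missing either are dropped.  A constant vector yields NaN
    (undefined) with a flag column.
    """
    df = mutability_table(mutab)
    panel_genes = {g for g in df["gene_id"].unique() if g in scores}
    if len(panel_genes) < 3:
        raise ValueError(f"need >= 3 genes with mutability and scores, got {len(panel_genes)}")
    rows = []
    for motif in motifs:
        sub = df[df["motif"] == motif].pivot_table(
            index="gene_id", columns="strand", values="mean_freq"
        )
        if not {"top", "bottom"} <= set(sub.columns):
            continue
        sub = sub.dropna(subset=["top", "bottom"])
        genes = [g for g in sub.index if g in scores]
        if len(genes) < 3:
            logger.warning("motif %s: only %d usable genes, skipped", motif, len(genes))
            continue
        diff = (sub.loc[genes, "top"] - sub.loc[genes, "bottom"]).to_numpy()
        for strand in ("top", "bottom"):
            pot = np.array([getattr(scores[g], strand) for g in genes])
            if np.ptp(diff) == 0 or np.ptp(pot) == 0:
                logger.warning("motif %s %s strand: constant vector, r undefined", motif, strand)
                rows.append((motif, strand, np.nan, np.nan, len(genes), True))
            else:
                r = stats.pearsonr(diff, pot)
                rows.append((motif, strand, float(r.statistic), float(r.pvalue), len(genes), False))
    return pd.DataFrame(
        rows, columns=["motif", "strand", "pearson_r", "p_value", "n_genes", "undefined"]
    )


def mutated_vs_germline_potential(
    aln: RepertoireAlignment, scorer: G4Scorer
) -> dict[str, dict[str, float]]:
    """Germline score vs mean mutated-read score, per strand.

    Reads with N positions are scored after imputing the germline base there
    (the read does not cover the site, so the germline state is assumed);
    reads the scorer rejects are skipped and counted.
    """
    germ_seq = aln.germline.ungapped_seq
    germ = score_both_strands(germ_seq, scorer, seq_id=aln.germline.allele_id)
    tops, bottoms = [], []
    skipped = 0
    for read in aln.reads:
        filled = "".join(g if b == "N" else b for g, b in zip(germ_seq, read))
        try:
            s = score_both_strands(filled, scorer)
        except Exception:
            skipped += 1
            continue
        tops.append(s.top)
        bottoms.append(s.bottom)
    if skipped:
        logger.warning("mutated_vs_germline_potential: skipped %d unscorable reads", skipped)
    return {
        "germline": {"top": germ.top, "bottom": germ.bottom},
        "mutated_mean": {
            "top": float(np.mean(tops)) if tops else float("nan"),
            "bottom": float(np.mean(bottoms)) if bottoms else float("nan"),
        },
        "n_reads_scored": {"top": len(tops), "bottom": len(bottoms)},
    }


def ccc_split_comparison(
    aln: RepertoireAlignment,
    mutants: list[MutantRecord],
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[CccComparison, CccComparison, float | None]:
    """Compare mutability of top-strand CCC coldspots split by predicted G4 impact.

    Sites whose in-silico C substitution lowers the bottom-strand potential by
    more than ``epsilon`` form the negative_change group; those within the
    +/- epsilon band form no_difference; sites that raise the potential beyond
    +epsilon belong to neither.  Returns the two groups (per-site mutation
    frequencies) plus the two-sided Mann-Whitney U raw p-value, or None when a
    group is empty.
    """
    freqs = site_mutation_frequencies(aln)
    freq_at = dict(zip(freqs["pos"], freqs["frequency"]))
    neg, nodiff = [], []
    for m in mutants:
        if (
            m.allele_id != aln.germline.allele_id
            or m.strand_mutated != "top"
            or m.trinucleotide != "CCC"
            or m.site_class != SYC_COLDSPOT
            or m.alt_base == AVG_G_TO_H
        ):
            continue
        f = freq_at.get(m.ungapped_pos)
        if f is None or np.isnan(f):
            continue
        if m.delta_bottom < -epsilon:
            neg.append(float(f))
        elif abs(m.delta_bottom) <= epsilon:
            nodiff.append(float(f))
    p = None
    if neg and nodiff:
        p = float(stats.mannwhitneyu(neg, nodiff, alternative="two-sided").pvalue)
    else:
        logger.warning(
            "ccc_split_comparison: empty group (negative_change n=%d, no_difference n=%d)",
            len(neg), len(nodiff),
        )
    return (
        CccComparison("negative_change", neg, p),
        CccComparison("no_difference", nodiff, p),
        p,
    )


def read_repertoire_fasta(path: str | Path) -> RepertoireAlignment:
    """Read an aligned-repertoire FASTA: first record is the germline."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no records in {path}")
    germ = IghvAllele(
        allele_id=records[0].description.split()[0],
        gapped_seq=str(records[0].seq).upper(),
    )
    return RepertoireAlignment(
        germline=germ, reads=[str(r.seq).upper() for r in records[1:]]
    )
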