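"""In-silico single-base saturation mutagenesis and AID-context analysis.

Every position of a germline V allele is mutated in two sweeps:

* H>G — each non-G position gets a G (the substitution AID hotspot mutations
  tend to create), one mutant per site;
* G>H — each G position is replaced by each of A/C/T and the three mutant
  scores are averaged into one record per site.

Each record carries the change in G4 potential (delta) on both strands.  Both
strands are always rescored from scratch: a top-strand substitution alters the
bottom-strand context too, so no antisymmetry is assumed.

C sites are classified by their AID context read on the strand where the C
lives: WRC (W=A/T, R=A/G) hotspot, SYC (S=C/G, Y=C/T) coldspot, or neutral C.
Bottom-strand C sites are the top-strand G positions; all coordinates stay in
top-strand space with ``strand_mutated`` distinguishing the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core_seq import IghvAllele, SequenceError, reverse_complement
from .g4_scoring import G4Scorer, score_both_strands

logger = logging.getLogger("vquad")

WRC_HOTSPOT = "WRC_hotspot"
SYC_COLDSPOT = "SYC_coldspot"
NEUTRAL_C = "neutral_C"

AVG_G_TO_H = "avg(G>H)"

#: Default half-width of the "no difference" band on the score scale.
DEFAULT_EPSILON = 0.01

_W = set("AT")
_R = set("AG")
_S = set("CG")
_Y = set("CT")


@dataclass(frozen=True)
class CSiteClass:
    value: str  # WRC_hotspot | SYC_coldspot | neutral_C
    trinucleotide: str  # 3-mer context, targeted C third (e.g. "TGC")


@dataclass
class MutantRecord:
    """One in-silico point substitution with its effect on both strands.

    ``ungapped_pos``/``gapped_pos`` are 1-based top-strand coordinates.  For
    averaged G>H sweeps ``alt_base`` is the marker "avg(G>H)" and the deltas
    are means over the three single substitutions.  ``strand_mutated`` is the
    strand on which the mutated base is a C-side context (top for A/C/T sites,
    bottom for G sites, whose complement on the bottom strand is the C).
    """

    allele_id: str
    ungapped_pos: int
    gapped_pos: int | None
    ref_base: str
    alt_base: str
    strand_mutated: str  # top | bottom
    delta_top: float
    delta_bottom: float
    in_region: str = "unassigned"
    site_class: str | None = None
    trinucleotide: str | None = None


def classify_context(trinucleotide: str) -> str:
    """Classify a 3-mer with the targeted C third: hotspot, coldspot or neutral."""
    a, b, c = trinucleotide
    if c != "C":
        raise SequenceError(f"context {trinucleotide!r} does not target a C")
    if a in _W and b in _R:
        return WRC_HOTSPOT
    if a in _S and b in _Y:
        return SYC_COLDSPOT
    return NEUTRAL_C


def classify_c_site(seq: str, pos: int, strand: str) -> CSiteClass:
    """AID-context class of the C at 1-based top coordinate ``pos`` on ``strand``.

    For the bottom strand the top-strand base must be G; the context is read
    off the reverse complement (the two bases 5' of the C on the bottom strand
    are the complements of the top-strand bases 3' of the G).  Sites with
    fewer than two 5' context bases on their strand are neutral by convention.
    """
    if strand not in ("top", "bottom"):
        raise ValueError("strand must be 'top' or 'bottom'")
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {pos} outside [1, {len(seq)}]")
    base = seq[pos - 1]
    if strand == "top":
        if base != "C":
            raise SequenceError(f"top-strand base at {pos} is {base}, not C")
        if pos < 3:
            return CSiteClass(NEUTRAL_C, seq[: pos - 1].rjust(2, "N") + "C")
        tri = seq[pos - 3 : pos]
    else:
        if base != "G":
            raise SequenceError(
                f"bottom-strand C at {pos} requires a top-strand G, found {base}"
            )
        if pos > len(seq) - 2:
            return CSiteClass(NEUTRAL_C, reverse_complement(seq[pos - 1 :]).rjust(3, "N"))
        tri = reverse_complement(seq[pos - 1 : pos + 2])
    return CSiteClass(classify_context(tri), tri)


def _make_record(
    allele: IghvAllele,
    seq: str,
    pos: int,
    alt_base: str,
    strand_mutated: str,
    delta_top: float,
    delta_bottom: float,
) -> MutantRecord:
    gapped_pos = allele.ungapped_to_gapped(pos)
    site_class = trinuc = None
    if strand_mutated == "top" and seq[pos - 1] == "C":
        cls = classify_c_site(seq, pos, "top")
        site_class, trinuc = cls.value, cls.trinucleotide
    elif strand_mutated == "bottom" and seq[pos - 1] == "G":
        cls = classify_c_site(seq, pos, "bottom")
        site_class, trinuc = cls.value, cls.trinucleotide
    return MutantRecord(
        allele_id=allele.allele_id,
        ungapped_pos=pos,
        gapped_pos=gapped_pos,
        ref_base=seq[pos - 1],
        alt_base=alt_base,
        strand_mutated=strand_mutated,
        delta_top=delta_top,
        delta_bottom=delta_bottom,
        in_region=allele.region_at(gapped_pos) if gapped_pos else "unassigned",
        site_class=site_class,
        trinucleotide=trinuc,
    )


def enumerate_h_to_g(allele: IghvAllele, scorer: G4Scorer) -> list[MutantRecord]:
    """One mutant per non-G position, substituting a G; as many new sequences
    as there are A, C and T bases in the germline."""
    seq = allele.ungapped_seq
    germ = score_both_strands(seq, scorer, seq_id=allele.allele_id)
    records = []
    for pos in range(1, len(seq) + 1):
        if seq[pos - 1] == "G":
            continue
        mutant = seq[: pos - 1] + "G" + seq[pos:]
        try:
            scores = score_both_strands(mutant, scorer)
        except Exception as exc:
            raise RuntimeError(
                f"{allele.allele_id}: scoring failed at position {pos}: {exc}"
            ) from exc
        records.append(
            _make_record(
                allele,
                seq,
                pos,
                "G",
                "top",
                scores.top - germ.top,
                scores.bottom - germ.bottom,
            )
        )
    return records


def enumerate_g_to_h(allele: IghvAllele, scorer: G4Scorer) -> list[MutantRecord]:
    """One averaged record per G position: the three G>A/C/T mutants are scored
    and the mean mutated potential is compared to germline."""
    seq = allele.ungapped_seq
    germ = score_both_strands(seq, scorer, seq_id=allele.allele_id)
    records = []
    for pos in range(1, len(seq) + 1):
        if seq[pos - 1] != "G":
            continue
        tops, bottoms = [], []
        for alt in "ACT":
            mutant = seq[: pos - 1] + alt + seq[pos:]
            try:
                scores = score_both_strands(mutant, scorer)
            except Exception as exc:
                raise RuntimeError(
                    f"{allele.allele_id}: scoring failed at position {pos}: {exc}"
                ) from exc
            tops.append(scores.top)
            bottoms.append(scores.bottom)
        records.append(
            _make_record(
                allele,
                seq,
                pos,
                AVG_G_TO_H,
                "bottom",
                float(np.mean(tops)) - germ.top,
                float(np.mean(bottoms)) - germ.bottom,
            )
        )
    return records


def saturation_mutagenesis(allele: IghvAllele, scorer: G4Scorer) -> list[MutantRecord]:
    """Both sweeps together: exactly one record per germline position."""
    return enumerate_h_to_g(allele, scorer) + enumerate_g_to_h(allele, scorer)


def _affected_delta(record: MutantRecord, strand_affected: str) -> float:
    same = record.strand_mutated
    other = "bottom" if same == "top" else "top"
    strand = same if strand_affected == "same" else other
    return record.delta_top if strand == "top" else record.delta_bottom


def strand_effect_summary(
    mutants: list[MutantRecord], epsilon: float = DEFAULT_EPSILON
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group C-site deltas into the class x strand_mutated x strand_affected grid.

    Each classified mutant contributes its delta on each strand to exactly one
    (strand_mutated, strand_affected) cell.  Returns (cells, tests): ``cells``
    has one row per grid cell with n, mean, median and the fraction of deltas
    inside the +/- epsilon "no difference" band; ``tests`` holds pairwise
    two-sided Mann-Whitney U comparisons between site classes within each
    (strand_mutated, strand_affected) group, raw p-values.
    """
    classified = [m for m in mutants if m.site_class is not None]
    rows = []
    for m in classified:
        for affected in ("same", "opposite"):
            rows.append(
                (m.site_class, m.strand_mutated, affected, _affected_delta(m, affected))
            )
    long = pd.DataFrame(
        rows, columns=["site_class", "strand_mutated", "strand_affected", "delta"]
    )
    if long.empty:
        return (
            pd.DataFrame(
                columns=[
                    "site_class", "strand_mutated", "strand_affected",
                    "n", "mean_delta", "median_delta", "frac_within_epsilon",
                ]
            ),
            pd.DataFrame(columns=["strand_mutated", "strand_affected", "class_a", "class_b", "p_value"]),
        )
    cells = (
        long.groupby(["site_class", "strand_mutated", "strand_affected"])["delta"]
        .agg(
            n="size",
            mean_delta="mean",
            median_delta="median",
            frac_within_epsilon=lambda s: float(np.mean(np.abs(s) <= epsilon)),
        )
        .reset_index()
    )
    test_rows = []
    for (mut, aff), group in long.groupby(["strand_mutated", "strand_affected"]):
        by_class = {cls: sub["delta"].to_numpy() for cls, sub in group.groupby("site_class")}
        for a, b in combinations(sorted(by_class), 2):
            if len(by_class[a]) == 0 or len(by_class[b]) == 0:
                continue
            p = stats.mannwhitneyu(by_class[a], by_class[b], alternative="two-sided").pvalue
            test_rows.append((mut, aff, a, b, float(p)))
    tests = pd.DataFrame(
        test_rows, columns=["strand_mutated", "strand_affected", "class_a", "class_b", "p_value"]
    )
    return cells, tests


def per_trinucleotide_delta(
    mutants: list[MutantRecord], wilcoxon: bool = False
) -> pd.DataFrame:
    """Mean +/- sd delta per trinucleotide context and strand combination.

    One row per (trinucleotide, strand_mutated, strand_affected); contexts with
    no occurrences are simply absent (logged).  ``wilcoxon=True`` adds a
    one-sample two-sided Wilcoxon test of the deltas against 0.
    """
    classified = [m for m in mutants if m.trinucleotide is not None]
    rows = []
    for m in classified:
        for affected in ("same", "opposite"):
            rows.append(
                (
                    m.trinucleotide,
                    m.site_class,
                    m.strand_mutated,
                    affected,
                    _affected_delta(m, affected),
                )
            )
    long = pd.DataFrame(
        rows,
        columns=["trinucleotide", "site_class", "strand_mutated", "strand_affected", "delta"],
    )
    if long.empty:
        logger.info("per_trinucleotide_delta: no classified C-site mutants")
        return pd.DataFrame(
            columns=[
                "trinucleotide", "site_class", "strand_mutated", "strand_affected",
                "n", "mean_delta", "sd_delta",
            ]
        )
    out = (
        long.groupby(["trinucleotide", "site_class", "strand_mutated", "strand_affected"])["delta"]
        .agg(n="size", mean_delta="mean", sd_delta=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    if wilcoxon:
        pvals = []
        for _, row in out.iterrows():
            sub = long[
                (long["trinucleotide"] == row["trinucleotide"])
                & (long["strand_mutated"] == row["strand_mutated"])
                & (long["strand_affected"] == row["strand_affected"])
            ]["delta"].to_numpy()
            if np.allclose(sub, 0.0):
                pvals.append(float("nan"))
            else:
                pvals.append(float(stats.wilcoxon(sub, alternative="two-sided").pvalue))
        out["wilcoxon_p"] = pvals
    return out


def delta_profile_by_position(
    mutants: list[MutantRecord],
    allele: IghvAllele,
    robustness_band: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-position delta series with FW/CDR annotation.

    Expects the full saturation sweep for one allele (one record per ungapped
    position).  Returns the per-position table (gapped/ungapped coordinates,
    ref and alt, both deltas, region) plus a census dict with the fraction of
    positions whose delta stayed within +/- ``robustness_band`` per strand.
    """
    own = sorted(
        (m for m in mutants if m.allele_id == allele.allele_id),
        key=lambda m: m.ungapped_pos,
    )
    if not own:
        raise ValueError(f"no mutants for allele {allele.allele_id}")
    df = pd.DataFrame(
        {
            "ungapped_pos": [m.ungapped_pos for m in own],
            "gapped_pos": [m.gapped_pos for m in own],
            "ref_base": [m.ref_base for m in own],
            "alt_base": [m.alt_base for m in own],
            "delta_top": [m.delta_top for m in own],
            "delta_bottom": [m.delta_bottom for m in own],
            "region": [m.in_region for m in own],
        }
    )
    census = {
        "frac_within_band_top": float(np.mean(np.abs(df["delta_top"]) <= robustness_band)),
        "frac_within_band_bottom": float(
            np.mean(np.abs(df["delta_bottom"]) <= robustness_band)
        ),
    }
    return df, census


def mutants_to_table(mutants: list[MutantRecord]) -> pd.DataFrame:
    """Flat TSV-ready mutant table."""
    return pd.DataFrame(
        {
            "allele_id": [m.allele_id for m in mutants],
            "gapped_pos": [m.gapped_pos for m in mutants],
            "ungapped_pos": [m.ungapped_pos for m in mutants],
            "ref": [m.ref_base for m in mutants],
            "alt": [m.alt_base for m in mutants],
            "strand_mutated": [m.strand_mutated for m in mutants],
            "site_class": [m.site_class for m in mutants],
            "trinucleotide": [m.trinucleotide for m in mutants],
            "delta_top": [m.delta_top for m in mutants],
            "delta_bottom": [m.delta_bottom for m in mutants],
            "region": [m.in_region for m in mutants],
        }
    )
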