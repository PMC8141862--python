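"""Independent brute-force oracles the test suite checks the package against.

These deliberately share no code with the implementation: regex run-finding
plus exhaustive chain enumeration for the quadruplex scanner, explicit motif
tables and naive string scanning for the AID scan, position-wise expansion
for interval statistics, and plain Python column counting for alignments.
"""

from __future__ import annotations

import re

WRC = {"AAC", "AGC", "TAC", "TGC"}
SYC = {"CCC", "CTC", "GCC", "GTC"}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def brute_canonical_matches(seq: str, min_run: int = 3, max_loop: int = 7):
    """All non-overlapping canonical G4 matches by exhaustive enumeration.

    Enumerates every chain of four maximal G-runs with loops in [1, max_loop],
    then repeatedly emits the chain with the smallest (lexicographic) run-index
    tuple among chains lying entirely past the previous match.  Returns a list
    of (start, end, runs, loops) tuples.
    """
    runs = [
        (m.start(), m.end() - m.start())
        for m in re.finditer("G+", seq)
        if m.end() - m.start() >= min_run
    ]
    chains = []
    n = len(runs)
    for i in range(n):
        for j in range(i + 1, n):
            if not 1 <= runs[j][0] - (runs[i][0] + runs[i][1]) <= max_loop:
                continue
            for k in range(j + 1, n):
                if not 1 <= runs[k][0] - (runs[j][0] + runs[j][1]) <= max_loop:
                    continue
                for l in range(k + 1, n):
                    if not 1 <= runs[l][0] - (runs[k][0] + runs[k][1]) <= max_loop:
                        continue
                    chains.append((i, j, k, l))
    out = []
    pointer = 0
    while True:
        candidates = [c for c in chains if c[0] >= pointer]
        if not candidates:
            break
        best = min(candidates)
        chosen = [runs[x] for x in best]
        start = chosen[0][0]
        end = chosen[-1][0] + chosen[-1][1]
        loops = tuple(chosen[x + 1][0] - (chosen[x][0] + chosen[x][1]) for x in range(3))
        out.append((start, end, tuple(chosen), loops))
        pointer = best[-1] + 1
    return out


def brute_aid_scan(seq: str):
    """All WRC/SYC occurrences on both strands as (class, trinuc, strand, pos)."""
    hits = set()
    for i in range(len(seq) - 2):
        tri = seq[i : i + 3]
        if tri in WRC:
            hits.add(("WRC_hotspot", tri, "top", i + 3))
        elif tri in SYC:
            hits.add(("SYC_coldspot", tri, "top", i + 3))
    rcseq = rc(seq)
    n = len(seq)
    for i in range(n - 2):
        tri = rcseq[i : i + 3]
        # targeted C at rc index i+2 maps to top 1-based position n - (i + 2)
        if tri in WRC:
            hits.add(("WRC_hotspot", tri, "bottom", n - i - 2))
        elif tri in SYC:
            hits.add(("SYC_coldspot", tri, "bottom", n - i - 2))
    return hits


def brute_call_g4(intervals, threshold):
    """Position-wise thresholding + adjacency merge; (chrom, start, end, peak)."""
    by_chrom: dict[str, dict[int, float]] = {}
    for chrom, start, end, value in intervals:
        for pos in range(start, end):
            by_chrom.setdefault(chrom, {})[pos] = value
    calls = []
    for chrom in sorted(by_chrom):
        hot = sorted(p for p, v in by_chrom[chrom].items() if v >= threshold)
        if not hot:
            continue
        run_start = prev = hot[0]
        peak = by_chrom[chrom][prev]
        for pos in hot[1:]:
            if pos == prev + 1:
                peak = max(peak, by_chrom[chrom][pos])
            else:
                calls.append((chrom, run_start, prev + 1, peak))
                run_start, peak = pos, by_chrom[chrom][pos]
            prev = pos
        calls.append((chrom, run_start, prev + 1, peak))
    return calls


def brute_region_stats(intervals, chrom, start, end):
    """Position-wise max and mean of covered positions inside [start, end)."""
    values = []
    for c, s, e, v in intervals:
        if c != chrom:
            continue
        for pos in range(s, e):
            if start <= pos < end:
                values.append(v)
    if not values:
        return None, None
    return max(values), sum(values) / len(values)


def brute_motif_count(seq: str, motif: str) -> int:
    return sum(1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif)


def brute_site_freqs(germline: str, reads: list[str]):
    """(coverage, mutated) per position by plain column counting."""
    out = []
    for i in range(len(germline)):
        cov = mut = 0
        for read in reads:
            if read[i] != "N":
                cov += 1
                if read[i] != germline[i]:
                    mut += 1
        out.append((cov, mut))
    return out
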