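"""G-quadruplex potential scoring and attribution.

A G4 "potential" here is any number in [0, 1] mapping a DNA sequence to its
propensity to fold into a quadruplex.  Learned scorers (e.g. a pre-trained CNN)
are plugged in through the :class:`G4Scorer` contract; the package ships a
deterministic built-in scorer driven by the canonical motif

    G{3,} N(1,7) G{3,} N(1,7) G{3,} N(1,7) G{3,}

(four G-runs of length >= 3 separated by loops of 1-7 nt).  The built-in
scorer is a documented surrogate: it makes strand and motif structure exact
and reproducible, but it does not reproduce the numeric outputs of any
trained model.

Attribution of a differentiable scorer's output to input positions uses
integrated gradients: the straight-line path integral of the gradient from an
all-zeros baseline to the actual one-hot input, approximated by a Riemann sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .core_seq import (
    BASE_ORDER,
    IghvAllele,
    OneHotEncoding,
    SequenceError,
    reverse_complement,
)

_DNA = set("ACGT")


@runtime_checkable
class G4Scorer(Protocol):
    """Anything that maps a DNA string to a potential in [0, 1]."""

    name: str
    deterministic: bool

    def score(self, seq: str) -> float: ...


@dataclass(frozen=True)
class CanonicalG4Match:
    """One canonical quadruplex motif match in 0-based half-open top coordinates."""

    start: int
    end: int
    g_runs: tuple[tuple[int, int], ...]  # (start, length) per run, ordered
    loop_lengths: tuple[int, int, int]

    @property
    def min_run_length(self) -> int:
        return min(length for _, length in self.g_runs)


@dataclass(frozen=True)
class StrandScores:
    """Scores of the same locus on both strands, top coordinates throughout."""

    top: float
    bottom: float
    scorer_name: str


def _g_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of G of length >= min_run as (start, length)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= min_run:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def find_canonical_g4_motifs(
    seq: str, min_run: int = 3, max_loop: int = 7
) -> list[CanonicalG4Match]:
    """All non-overlapping canonical G4 matches, scanning left to right.

    Maximal G-runs of length >= ``min_run`` are chained four at a time with
    loop lengths in [1, ``max_loop``].  Scanning is leftmost-first: from the
    earliest run that can anchor a complete chain, the lexicographically
    smallest valid chain of runs is taken (earliest compatible next run, with
    backtracking), the match is emitted, and scanning resumes at the first run
    past its end.  Deterministic by construction.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if max_loop < 1:
        raise ValueError("max_loop must be >= 1")
    bad = set(seq) - _DNA
    if bad:
        raise SequenceError(f"invalid characters {sorted(bad)} in sequence")
    runs = _g_runs(seq, min_run)

    def extend(chain: list[int]) -> list[int] | None:
        # Depth-first for the lex-smallest chain of 4 runs starting at chain[0].
        if len(chain) == 4:
            return chain
        prev_start, prev_len = runs[chain[-1]]
        prev_end = prev_start + prev_len
        for j in range(chain[-1] + 1, len(runs)):
            loop = runs[j][0] - prev_end
            if loop > max_loop:
                break
            if loop < 1:
                continue
            result = extend(chain + [j])
            if result is not None:
                return result
        return None

    matches: list[CanonicalG4Match] = []
    i = 0
    while i < len(runs):
        chain = extend([i])
        if chain is None:
            i += 1
            continue
        chosen = [runs[k] for k in chain]
        start = chosen[0][0]
        end = chosen[-1][0] + chosen[-1][1]
        loops = tuple(
            chosen[k + 1][0] - (chosen[k][0] + chosen[k][1]) for k in range(3)
        )
        matches.append(
            CanonicalG4Match(start=start, end=end, g_runs=tuple(chosen), loop_lengths=loops)
        )
        i = chain[-1] + 1
    return matches


@dataclass
class ReferenceG4Scorer:
    """Deterministic surrogate scorer built on the canonical-motif scanner.

    score = 1 - 2**(-q), with q the sum over non-overlapping canonical matches
    of (shortest G-run length in the match - 2).  A sequence with no canonical
    match scores exactly 0; each extra match or longer minimum run halves the
    remaining distance to 1.  The constants are fixed surrogate choices so
    that downstream tests are bit-exact; the scores are NOT comparable to any
    trained model's outputs.
    """

    min_run: int = 3
    max_loop: int = 7
    name: str = "reference"
    deterministic: bool = True

    def score(self, seq: str) -> float:
        q = sum(
            m.min_run_length - 2
            for m in find_canonical_g4_motifs(seq, self.min_run, self.max_loop)
        )
        return 1.0 - 2.0 ** (-q)


def reference_g4_score(seq: str) -> float:
    """Score ``seq`` with the default built-in scorer (see ReferenceG4Scorer)."""
    return ReferenceG4Scorer().score(seq)


def score_both_strands(seq: str, scorer: G4Scorer, seq_id: str | None = None) -> StrandScores:
    """Score the sequence as given (top) and its reverse complement (bottom)."""
    try:
        top = float(scorer.score(seq))
        bottom = float(scorer.score(reverse_complement(seq)))
    except Exception as exc:
        ident = f" for {seq_id}" if seq_id else ""
        raise RuntimeError(f"scorer {scorer.name!r} failed{ident}: {exc}") from exc
    for value, strand in ((top, "top"), (bottom, "bottom")):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"scorer {scorer.name!r} returned {value} on {strand} strand")
    return StrandScores(top=top, bottom=bottom, scorer_name=scorer.name)


def family_potential_summary(
    alleles: list[IghvAllele], scorer: G4Scorer, group_by: str = "family"
) -> pd.DataFrame:
    """Per-group, per-strand mean/sd of G4 potentials.

    ``group_by`` is "family" (IGHV1..IGHV7) or "gene".  The sd of a single
    observation is reported as 0 so summary tables never contain missing cells;
    groups with n > 1 use the sample (ddof=1) standard deviation.
    """
    if not alleles:
        raise ValueError("empty allele list")
    if group_by not in ("family", "gene"):
        raise ValueError("group_by must be 'family' or 'gene'")
    rows = []
    for allele in alleles:
        scores = score_both_strands(allele.ungapped_seq, scorer, seq_id=allele.allele_id)
        group = allele.family if group_by == "family" else allele.gene_id
        rows.append((group, "top", scores.top))
        rows.append((group, "bottom", scores.bottom))
    df = pd.DataFrame(rows, columns=[group_by, "strand", "score"])
    out = (
        df.groupby([group_by, "strand"], sort=True)["score"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="size")
        .reset_index()
    )
    return out


def allele_score_table(alleles: list[IghvAllele], scorer: G4Scorer) -> pd.DataFrame:
    """Tidy per-allele, per-strand score table (allele_id, strand, scorer, score)."""
    rows = []
    for allele in alleles:
        scores = score_both_strands(allele.ungapped_seq, scorer, seq_id=allele.allele_id)
        rows.append((allele.allele_id, "top", scorer.name, scores.top))
        rows.append((allele.allele_id, "bottom", scorer.name, scores.bottom))
    return pd.DataFrame(rows, columns=["allele_id", "strand", "scorer", "score"])


@dataclass
class AttributionVector:
    """Integrated-gradients attributions over a one-hot input.

    ``values`` is flat, aligned with the encoding's vector.  ``completeness_gap``
    is |sum(values) - (f(input) - f(baseline))|; it scales like 1/n_steps for a
    smooth scorer and is exactly 0 for a linear one.
    """

    values: np.ndarray
    n_steps: int
    completeness_gap: float
    width: int
    base_order: str = BASE_ORDER


def integrated_gradients(
    grad_fn: Callable[[np.ndarray], np.ndarray],
    encoding: OneHotEncoding,
    n_steps: int = 128,
    value_fn: Callable[[np.ndarray], float] | None = None,
) -> AttributionVector:
    """Integrated gradients from an all-zeros baseline to ``encoding``.

    attribution_i = x_i * mean over k=1..n_steps of grad_i((k/n_steps) * x),
    the right-endpoint Riemann approximation of the straight-line path
    integral.  ``grad_fn`` returns the gradient of the scorer at a flat input;
    ``value_fn`` (the scorer itself) is used only to report the completeness
    gap and may be omitted (gap reported as nan).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    x = encoding.vector
    grad_sum = np.zeros_like(x)
    for k in range(1, n_steps + 1):
        g = np.asarray(grad_fn((k / n_steps) * x), dtype=np.float64)
        if g.shape != x.shape:
            raise ValueError(f"gradient shape {g.shape} != input shape {x.shape}")
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite gradient from scorer oracle")
        grad_sum += g
    values = x * grad_sum / n_steps
    if value_fn is not None:
        gap = abs(float(np.sum(values)) - (float(value_fn(x)) - float(value_fn(np.zeros_like(x)))))
    else:
        gap = float("nan")
    return AttributionVector(
        values=values, n_steps=n_steps, completeness_gap=gap, width=encoding.width
    )


def attribution_to_logo_table(attr: AttributionVector, seq: str) -> pd.DataFrame:
    """Per-position, per-base attribution table in logo-ready tidy format.

    Rows are sequence positions (0-based index), columns the four bases; the
    table covers only the real (non-padding) positions of ``seq``.
    """
    if len(seq) > attr.width:
        raise ValueError(
            f"sequence length {len(seq)} exceeds attribution width {attr.width}"
        )
    mat = attr.values.reshape(attr.width, 4)[: len(seq)]
    return pd.DataFrame(mat, columns=list(attr.base_order))
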