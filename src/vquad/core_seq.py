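"""Sequence records for germline IGHV alleles and the fixed-width one-hot convention.

Coordinates
-----------
IMGT/gapped positions are 1-based inclusive throughout (so "IMGT position 50"
means the 50th character of the gapped sequence).  Interval types elsewhere in
the package (BED/bedGraph) are 0-based half-open, matching those standards.

The one-hot layout is the flat row-major convention used by sequence-based
convolutional scorers: 4 slots per nucleotide position in the fixed base order
A, C, G, T; positions past the end of a short sequence are all-zero groups.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("vquad")

#: Fixed input width (nt) of the external learned G4 scorer this package targets.
DEFAULT_ENCODING_WIDTH = 297

#: Fixed base ordering of the one-hot groups.  External scorer adapters that use
#: a different ordering must permute on their side.
BASE_ORDER = "ACGT"

_DNA = set("ACGT")
_DNA_N = set("ACGTN")
_GAPPED = set("ACGTN.")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IMGT region names in gene order.  The trailing V-gene part of CDR3 is kept
#: as its own label because germline V segments end inside CDR3.
REGION_NAMES = ("FW1", "CDR1", "FW2", "CDR2", "FW3", "CDR3-part")

_ALLELE_RE = re.compile(r"(?P<family>IGHV\d+)(?P<gene_rest>[^*\s]*)(\*(?P<allele>[\w]+))?")


class SequenceError(ValueError):
    """Malformed sequence or identifier in an input record."""


@dataclass
class IghvAllele:
    """One germline V-gene allele in IMGT gapped numbering.

    ``gapped_seq`` may contain ``.`` placeholders; ``ungapped_seq`` is derived
    by stripping them.  ``region_map`` holds ``(name, start, end)`` intervals in
    1-based inclusive gapped coordinates, ordered and non-overlapping.
    """

    allele_id: str
    gapped_seq: str
    region_map: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.gapped_seq) - _GAPPED
        if bad:
            raise SequenceError(
                f"{self.allele_id}: invalid characters {sorted(bad)} in sequence"
            )
        self._validate_regions()

    def _validate_regions(self) -> None:
        last_end = 0
        for name, start, end in self.region_map:
            if name not in REGION_NAMES:
                raise SequenceError(f"{self.allele_id}: unknown region name {name!r}")
            if not (1 <= start <= end <= len(self.gapped_seq)):
                raise SequenceError(
                    f"{self.allele_id}: region {name} [{start},{end}] outside sequence"
                )
            if start <= last_end:
                raise SequenceError(f"{self.allele_id}: region {name} overlaps/unordered")
            last_end = end

    @property
    def ungapped_seq(self) -> str:
        return self.gapped_seq.replace(".", "")

    @property
    def gene_id(self) -> str:
        return self.allele_id.split("*")[0]

    @property
    def family(self) -> str:
        m = _ALLELE_RE.match(self.allele_id)
        if m is None:
            raise SequenceError(f"unparsable allele identifier {self.allele_id!r}")
        return m.group("family")

    def gapped_to_ungapped(self, gapped_pos: int) -> int | None:
        """Map a 1-based gapped (IMGT) position to its 1-based ungapped position.

        Returns ``None`` for gap (``.``) positions.
        """
        if not 1 <= gapped_pos <= len(self.gapped_seq):
            raise IndexError(
                f"gapped position {gapped_pos} outside [1, {len(self.gapped_seq)}]"
            )
        if self.gapped_seq[gapped_pos - 1] == ".":
            return None
        return gapped_pos - self.gapped_seq.count(".", 0, gapped_pos - 1)

    def ungapped_to_gapped(self, ungapped_pos: int) -> int:
        """Inverse of :meth:`gapped_to_ungapped` for non-gap positions."""
        if not 1 <= ungapped_pos <= len(self.ungapped_seq):
            raise IndexError(
                f"ungapped position {ungapped_pos} outside [1, {len(self.ungapped_seq)}]"
            )
        seen = 0
        for i, base in enumerate(self.gapped_seq, start=1):
            if base != ".":
                seen += 1
                if seen == ungapped_pos:
                    return i
        raise AssertionError("unreachable")

    def region_at(self, gapped_pos: int) -> str:
        """Region label (FW/CDR) covering a gapped position, or ``unassigned``."""
        for name, start, end in self.region_map:
            if start <= gapped_pos <= end:
                return name
        return "unassigned"


@dataclass(frozen=True)
class OneHotEncoding:
    """Flat 0/1 encoding of a DNA sequence at a fixed width.

    ``vector`` has length ``4 * width``; each consecutive group of four slots
    is one nucleotide position in :data:`BASE_ORDER` order, all-zero when the
    position is padding.
    """

    width: int
    vector: np.ndarray
    base_order: str = BASE_ORDER

    @property
    def matrix(self) -> np.ndarray:
        """``(width, 4)`` view of the flat vector."""
        return self.vector.reshape(self.width, 4)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    bad = set(seq) - _DNA_N
    if bad:
        raise SequenceError(f"invalid characters {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def encode_one_hot(seq: str, width: int = DEFAULT_ENCODING_WIDTH) -> OneHotEncoding:
    """One-hot encode ``seq`` at a fixed width.

    Sequences shorter than ``width`` are zero-padded at the 3' end; longer ones
    keep their 5'-most ``width`` nt, consistent with the 3'-end padding.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if not seq:
        raise SequenceError("cannot encode an empty sequence")
    bad = set(seq) - _DNA
    if bad:
        raise SequenceError(f"invalid characters {sorted(bad)} in sequence")
    seq = seq[:width]
    vec = np.zeros(4 * width, dtype=np.float64)
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    base_slot = np.zeros(256, dtype=np.int64)
    for slot, base in enumerate(BASE_ORDER):
        base_slot[ord(base)] = slot
    pos = np.arange(len(seq)) * 4 + base_slot[idx]
    vec[pos] = 1.0
    return OneHotEncoding(width=width, vector=vec)


def _parse_allele_header(header: str) -> str:
    """Extract an IGHV allele identifier from a FASTA header.

    Accepts bare identifiers ("IGHV3-49*02") and IMGT-style pipe-delimited
    headers where the identifier is the second field.
    """
    for token in header.split("|"):
        token = token.strip()
        if token.startswith("IGHV"):
            m = _ALLELE_RE.match(token)
            if m:
                return token.split()[0]
    raise SequenceError(f"no IGHV allele identifier in header {header!r}")


def read_region_annotations(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read the optional region sidecar TSV.

    Columns: allele_id, region_name, gapped_start, gapped_end (1-based
    inclusive, header optional).
    """
    out: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "allele_id":
                continue
            if len(parts) < 4:
                raise SequenceError(f"{path}:{lineno}: expected 4 columns")
            out.setdefault(parts[0], []).append((parts[1], int(parts[2]), int(parts[3])))
    return out


def read_fasta(
    path: str | Path,
    gapped: bool = False,
    region_annotations: str | Path | dict | None = None,
) -> list[IghvAllele]:
    """Read germline V alleles from FASTA into :class:`IghvAllele` records.

    ``gapped=True`` keeps IMGT ``.`` placeholders; otherwise they are rejected
    as invalid characters.  ``region_annotations`` may be a sidecar TSV path or
    a pre-loaded mapping of allele_id to region intervals.
    """
    if region_annotations is not None and not isinstance(region_annotations, dict):
        region_annotations = read_region_annotations(region_annotations)
    regions = region_annotations or {}
    alleles: list[IghvAllele] = []
    for record in SeqIO.parse(str(path), "fasta"):
        allele_id = _parse_allele_header(record.description)
        seq = str(record.seq).upper()
        allowed = _GAPPED if gapped else _DNA_N
        bad = set(seq) - allowed
        if bad:
            raise SequenceError(
                f"record {allele_id}: invalid characters {sorted(bad)}"
            )
        alleles.append(
            IghvAllele(
                allele_id=allele_id,
                gapped_seq=seq,
                region_map=list(regions.get(allele_id, [])),
            )
        )
    if not alleles:
        raise SequenceError(f"no FASTA records in {path}")
    return alleles


def write_fasta(alleles: list[IghvAllele], path: str | Path, gapped: bool = False) -> None:
    with open(path, "w") as fh:
        for allele in alleles:
            seq = allele.gapped_seq if gapped else allele.ungapped_seq
            fh.write(f">{allele.allele_id}\n{seq}\n")
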