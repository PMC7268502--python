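"""Shared domain types and coordinate conventions.

All genomic intervals are 0-based, half-open ``[start, end)`` internally.
Readers convert 1-based inclusive input on the way in; the consensus writer
emits BED-style 0-based half-open coordinates. Chromosome names are stored
as canonical bare tokens (``"chr1"`` and ``"1"`` both normalise to ``"1"``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(str(i) for i in range(1, 23))
ALLOSOMES = frozenset({"X", "Y"})


class CallerRole(str, Enum):
    """Which calling approach a track represents."""

    COVERAGE = "coverage"
    HYBRID = "hybrid"
    REFEREE = "referee"


class ValueScale(str, Enum):
    """Scale on which a track's values live."""

    ABSOLUTE_CN = "absolute_cn"
    LOG2_VS_MATCHED = "log2_vs_matched"
    RATIO_VS_NULL = "ratio_vs_null"


class CnClass(str, Enum):
    """Three-way copy-number class relative to ploidy."""

    DELETION = "deletion"
    NORMAL = "normal"
    AMPLIFICATION = "amplification"


def normalize_chrom(token: str) -> str:
    """Canonicalise a chromosome name ("chr7" and "7" -> "7", "chrx" -> "X")."""
    t = str(token).strip()
    if t.lower().startswith("chr"):
        t = t[3:]
    if t.upper() in ("X", "Y", "MT", "M"):
        return "M" if t.upper() in ("MT", "M") else t.upper()
    return t


def round1(x: float) -> float:
    """Round to 1 decimal, ties away from zero (locale-independent).

    The one-decimal equality test drives segment merging, so the tie rule
    must be deterministic: 2.25 -> 2.3, -2.25 -> -2.3, 2.04999... -> 2.0.
    """
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IntervalCall:
    """One caller prediction on one genomic interval.

    ``value`` is on the owning track's scale; ``None`` encodes a class-only
    referee call (no usable magnitude).
    """

    chrom: str
    start: int
    end: int
    value: float | None
    cn_class: CnClass | None = None  # explicit class for class-only referee rows

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.value is not None and not math.isfinite(self.value):
            raise ValueError(f"non-finite value {self.value!r} at {self.chrom}:{self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CallerTrack:
    """Ordered, non-overlapping predictions of a single caller.

    ``gap_semantics`` records the implied copy number for uncovered
    positions when the track feeds the per-bin error score: the coverage
    caller is nominally gap-free (implied CN 0 where missing), the hybrid
    caller's gaps imply the ploidy.
    """

    caller_role: CallerRole
    value_scale: ValueScale
    calls: list[IntervalCall]
    name: str = ""
    magnitude_unreliable: bool = False

    def __post_init__(self) -> None:
        self.caller_role = CallerRole(self.caller_role)
        self.value_scale = ValueScale(self.value_scale)
        if self.caller_role is CallerRole.COVERAGE and self.value_scale is not ValueScale.ABSOLUTE_CN:
            raise ValueError("coverage tracks must carry absolute copy numbers")
        self.validate()

    def validate(self) -> None:
        """Assert per-chromosome sortedness and non-overlap."""
        last: dict[str, IntervalCall] = {}
        order: list[str] = []
        for c in self.calls:
            if c.chrom not in last:
                order.append(c.chrom)
            else:
                prev = last[c.chrom]
                if c.start < prev.end:
                    raise ValueError(
                        f"track {self.name or self.caller_role.value}: calls overlap or are "
                        f"unsorted on {c.chrom}: {prev.start}-{prev.end} then {c.start}-{c.end}"
                    )
            last[c.chrom] = c
        # chromosome blocks must be contiguous in the list
        if len(order) != len(set(order)):
            raise ValueError("calls for one chromosome must be contiguous")

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.calls:
            seen.setdefault(c.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[IntervalCall]]:
        out: dict[str, list[IntervalCall]] = {}
        for c in self.calls:
            out.setdefault(c.chrom, []).append(c)
        return out

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.calls)


@dataclass(frozen=True)
class PloidyModel:
    """Expected copy count per chromosome.

    Autosomes carry ``default_ploidy`` (2 in the diploid human setting);
    allosomes carry 2 for a female sample and 1 for a male one. Unknown
    tokens fall back to the default with a logged warning.
    """

    default_ploidy: int = 2
    sex: str = "unspecified"  # {"female", "male", "unspecified"}

    def __post_init__(self) -> None:
        if self.default_ploidy < 1:
            raise ValueError("default_ploidy must be a positive integer")
        if self.sex not in ("female", "male", "unspecified"):
            raise ValueError(f"unknown sex {self.sex!r}")


def ploidy_at(model: PloidyModel, chrom: str) -> int:
    """Ploidy for one chromosome: default for autosomes, sex rule for X/Y."""
    token = normalize_chrom(chrom)
    if token in AUTOSOMES:
        return model.default_ploidy
    if token in ALLOSOMES:
        if model.sex == "female":
            return 2
        if model.sex == "male":
            return 1
        return model.default_ploidy
    logger.warning("unrecognised chromosome %r: falling back to default ploidy %d",
                   chrom, model.default_ploidy)
    return model.default_ploidy


@dataclass(frozen=True)
class Thresholds:
    """Deletion/amplification boundaries on the absolute-CN scale.

    ``t2`` is read off the coverage caller's CN frequency distribution (the
    local minimum between the diploid peak and the first amplified state);
    ``t1`` mirrors it below the ploidy: t1 = 2*P - t2.
    """

    t1: float
    t2: float
    ploidy: int = 2

    def __post_init__(self) -> None:
        if not math.isclose(self.t1, 2 * self.ploidy - self.t2, abs_tol=1e-9):
            raise ValueError(f"t1 must equal 2*P - t2 (got t1={self.t1}, t2={self.t2})")


@dataclass(frozen=True)
class ConsensusSegment:
    """Merged consensus interval with its meta copy number and error score."""

    chrom: str
    start: int
    end: int
    cn_meta: float
    error_score: float
    rule_id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid segment {self.chrom}:{self.start}-{self.end}")
        if self.cn_meta < 0:
            raise ValueError("cn_meta must be >= 0")
        if self.error_score < 0:
            raise ValueError("error_score must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


def validate_segments(segments: Iterable[ConsensusSegment]) -> None:
    """Check ordering, non-overlap and the one-decimal distinctness of neighbours."""
    prev: ConsensusSegment | None = None
    for seg in segments:
        if prev is not None and seg.chrom == prev.chrom:
            if seg.start < prev.end:
                raise ValueError(
                    f"segments overlap on {seg.chrom}: {prev.start}-{prev.end}, "
                    f"{seg.start}-{seg.end}"
                )
            if seg.start == prev.end and round1(seg.cn_meta) == round1(prev.cn_meta):
                raise ValueError(
                    f"adjacent segments on {seg.chrom} at {seg.start} share the same "
                    "copy number to one decimal; they should have been merged"
                )
        prev = seg
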