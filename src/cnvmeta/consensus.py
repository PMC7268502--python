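"""The consensus meta-model.

The genome is partitioned by the union of every input caller's interval
endpoints, so each resulting bin lies strictly inside (or strictly outside)
each caller's prediction. Per bin a small rule table arbitrates between the
coverage caller (trusted for deletions and normal states), the hybrid
caller (trusted for amplifications) and a referee caller whose
deletion/amplification direction is reliable but whose magnitudes are not.
Bins whose consensus copy number agrees to one decimal are merged into
segments carrying a length-weighted error score.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .config import ConsensusConfig
from .core import (
    CallerTrack,
    CnClass,
    ConsensusSegment,
    PloidyModel,
    Thresholds,
    ploidy_at,
    round1,
)
from .harmonize import compute_thresholds, harmonize_hybrid_track, normalize_track

logger = logging.getLogger(__name__)

# rule identifiers, stable across releases (they are written to output files)
RULE_AGREE_DELETION = "agree_deletion"
RULE_AGREE_NORMAL = "agree_normal"
RULE_AGREE_AMPLIFICATION = "agree_amplification"
RULE_COVERAGE_ONLY = "coverage_only"
RULE_HYBRID_ONLY = "hybrid_only"
RULE_CONFLICT_REFEREE_COVERAGE = "conflict_referee_coverage"
RULE_CONFLICT_REFEREE_HYBRID = "conflict_referee_hybrid"
RULE_CONFLICT_REFEREE_MISMATCH = "conflict_referee_mismatch"
RULE_CONFLICT_NO_REFEREE = "conflict_no_referee"
RULE_NO_EVIDENCE = "no_evidence"


@dataclass
class ChromPartition:
    """Bins of one chromosome with each track's (possibly absent) value."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: list[np.ndarray]        # one float array per track; NaN = absent
    classes: list[np.ndarray]       # one object array per track; explicit class or None

    @property
    def n_bins(self) -> int:
        return self.starts.size

    @property
    def covered_length(self) -> int:
        return int((self.ends - self.starts).sum())


@dataclass
class GenomePartition:
    """Union-of-breakpoints partition across all input tracks."""

    tracks: list[CallerTrack]
    chroms: dict[str, ChromPartition]

    @property
    def covered_length(self) -> int:
        return sum(p.covered_length for p in self.chroms.values())


@dataclass(frozen=True)
class BinDecision:
    """Per-bin consensus outcome before merging."""

    chrom: str
    start: int
    end: int
    cn_rd: float | None
    cn_sv: float | None
    referee_class: CnClass | None
    cn_meta: float
    error_score: float
    rule_id: str

    @property
    def length(self) -> int:
        return self.end - self.start


def union_breakpoints(tracks: list[CallerTrack]) -> GenomePartition:
    """Partition each chromosome at the union of all tracks' endpoints.

    A track contributes its value to every bin strictly inside one of its
    intervals; elsewhere it is absent. Bins between breakpoints that no
    track covers are kept (they become no-evidence bins downstream).
    """
    if not tracks:
        raise ValueError("at least one track is required")
    chrom_names: dict[str, None] = {}
    for t in tracks:
        for c in t.chromosomes():
            chrom_names.setdefault(c, None)
    chroms: dict[str, ChromPartition] = {}
    per_track = [t.by_chrom() for t in tracks]
    for chrom in chrom_names:
        bps: set[int] = set()
        for calls in per_track:
            for c in calls.get(chrom, ()):
                bps.add(c.start)
                bps.add(c.end)
        cuts = np.array(sorted(bps), dtype=np.int64)
        starts, ends = cuts[:-1], cuts[1:]
        mids = (starts + ends) / 2.0
        values: list[np.ndarray] = []
        classes: list[np.ndarray] = []
        for calls in per_track:
            val = np.full(starts.size, np.nan)
            cls = np.full(starts.size, None, dtype=object)
            cl = calls.get(chrom, [])
            if cl:
                c_starts = np.array([c.start for c in cl], dtype=np.int64)
                c_ends = np.array([c.end for c in cl], dtype=np.int64)
                idx = np.searchsorted(c_starts, mids) - 1
                ok = (idx >= 0) & (mids < c_ends[np.clip(idx, 0, None)])
                for b in np.nonzero(ok)[0]:
                    call = cl[idx[b]]
                    if call.value is not None:
                        val[b] = call.value
                    cls[b] = call.cn_class
            values.append(val)
            classes.append(cls)
        chroms[chrom] = ChromPartition(chrom, starts, ends, values, classes)
    return GenomePartition(tracks=tracks, chroms=chroms)


def classify_cn(cn: float, thresholds: Thresholds) -> CnClass:
    """Three-way class of an absolute CN: below T1, within [T1, T2], above T2."""
    if cn < thresholds.t1:
        return CnClass.DELETION
    if cn <= thresholds.t2:
        return CnClass.NORMAL
    return CnClass.AMPLIFICATION


def referee_class(
    value: float | None,
    ploidy: int,
    explicit: CnClass | None = None,
) -> CnClass | None:
    """Direction of a referee call: deletion below ploidy, amplification above.

    An explicit class-only call passes through; a value exactly at the
    ploidy, or an absent call, yields no evidence (None).
    """
    if explicit is not None:
        return explicit
    if value is None:
        return None
    if value < ploidy:
        return CnClass.DELETION
    if value > ploidy:
        return CnClass.AMPLIFICATION
    return None


def error_score(cn_rd: float | None, cn_sv: float | None, ploidy: int) -> float:
    """Squared disagreement of the two primary callers on one bin.

    An absent coverage value is taken as CN 0 (the caller is nominally
    gap-free, so a gap means an unsequenced region); an absent hybrid value
    is taken as the ploidy.
    """
    rd = 0.0 if cn_rd is None else cn_rd
    sv = float(ploidy) if cn_sv is None else cn_sv
    return (rd - sv) ** 2


def decide_bin(
    cn_rd: float | None,
    cn_sv: float | None,
    referee: CnClass | None,
    thresholds: Thresholds,
    ploidy: int,
    chrom: str = "",
    start: int = 0,
    end: int = 1,
) -> BinDecision:
    """Apply the consensus rule table to one bin.

    Agreement keeps the class, with the value drawn from the caller trusted
    for that class (coverage for deletion/normal, hybrid for amplification).
    A missing caller leaves the other's call standing. A class conflict is
    arbitrated by the referee's direction, which selects the matching
    caller's value; with no usable referee evidence the bin falls back to
    the ploidy. The referee never contributes a numeric copy number.
    """
    if cn_rd is None and cn_sv is None:
        cn_meta, rule = float(ploidy), RULE_NO_EVIDENCE
    elif cn_sv is None:
        cn_meta, rule = cn_rd, RULE_COVERAGE_ONLY
    elif cn_rd is None:
        cn_meta, rule = cn_sv, RULE_HYBRID_ONLY
    else:
        cls_rd = classify_cn(cn_rd, thresholds)
        cls_sv = classify_cn(cn_sv, thresholds)
        if cls_rd == cls_sv:
            if cls_rd is CnClass.AMPLIFICATION:
                cn_meta, rule = cn_sv, RULE_AGREE_AMPLIFICATION
            elif cls_rd is CnClass.DELETION:
                cn_meta, rule = cn_rd, RULE_AGREE_DELETION
            else:
                cn_meta, rule = cn_rd, RULE_AGREE_NORMAL
        elif referee is None:
            cn_meta, rule = float(ploidy), RULE_CONFLICT_NO_REFEREE
        elif referee == cls_rd:
            cn_meta, rule = cn_rd, RULE_CONFLICT_REFEREE_COVERAGE
        elif referee == cls_sv:
            cn_meta, rule = cn_sv, RULE_CONFLICT_REFEREE_HYBRID
        else:
            cn_meta, rule = float(ploidy), RULE_CONFLICT_REFEREE_MISMATCH
    return BinDecision(
        chrom=chrom,
        start=start,
        end=end,
        cn_rd=cn_rd,
        cn_sv=cn_sv,
        referee_class=referee,
        cn_meta=max(cn_meta, 0.0),
        error_score=error_score(cn_rd, cn_sv, ploidy),
        rule_id=rule,
    )


def merge_segments(decisions: list[BinDecision]) -> list[ConsensusSegment]:
    """Merge adjacent bins whose consensus CN agrees to one decimal.

    The merged copy number and error score are bin-length-weighted means;
    the recorded rule is the one covering the most bases of the segment.
    """
    segments: list[ConsensusSegment] = []
    run: list[BinDecision] = []

    def flush() -> None:
        if not run:
            return
        total = sum(d.length for d in run)
        cn = sum(d.cn_meta * d.length for d in run) / total
        err = sum(d.error_score * d.length for d in run) / total
        by_rule: Counter[str] = Counter()
        for d in run:
            by_rule[d.rule_id] += d.length
        rule = max(by_rule, key=by_rule.__getitem__)
        segments.append(
            ConsensusSegment(run[0].chrom, run[0].start, run[-1].end, cn, err, rule)
        )
        run.clear()

    for d in decisions:
        if run and (
            d.chrom != run[-1].chrom
            or d.start != run[-1].end
            or round1(d.cn_meta) != round1(run[-1].cn_meta)
        ):
            flush()
        run.append(d)
    flush()
    return segments


@dataclass
class ConsensusResult:
    """Everything a consensus run produces, for reporting and diagnostics."""

    segments: list[ConsensusSegment]
    thresholds: Thresholds
    bias: float
    rule_counts: Counter = field(default_factory=Counter)
    decisions: list[BinDecision] = field(default_factory=list)


def call_consensus(
    coverage: CallerTrack,
    hybrid: CallerTrack | None,
    referee: CallerTrack | None,
    ploidy_model: PloidyModel = PloidyModel(),
    config: ConsensusConfig = ConsensusConfig(),
    keep_decisions: bool = False,
) -> ConsensusResult:
    """Run the full consensus pipeline on validated caller tracks.

    Steps: bias-normalise the coverage track, estimate T1/T2 from its CN
    distribution, harmonise the hybrid track onto the absolute scale,
    partition the genome at the union of all breakpoints, decide each bin
    by the rule table with referee arbitration, then merge one-decimal-
    equal neighbours. Deterministic for fixed inputs and config.
    """
    P = ploidy_model.default_ploidy
    cov_norm, bias_est = normalize_track(
        coverage, P, config.histogram_bin_width, config.clamp_limit
    )
    thresholds = compute_thresholds(
        cov_norm, P, config.histogram_bin_width, config.t2_search_interval
    )
    tracks = [cov_norm]
    hybrid_idx = referee_idx = None
    if hybrid is not None and hybrid.calls:
        tracks.append(harmonize_hybrid_track(hybrid, P, config.equalizer))
        hybrid_idx = len(tracks) - 1
    if referee is not None and referee.calls:
        tracks.append(referee)
        referee_idx = len(tracks) - 1

    partition = union_breakpoints(tracks)
    all_decisions: list[BinDecision] = []
    rule_counts: Counter = Counter()
    for chrom in sorted(partition.chroms):
        part = partition.chroms[chrom]
        p_chrom = ploidy_at(ploidy_model, chrom)
        rd_vals = part.values[0]
        sv_vals = part.values[hybrid_idx] if hybrid_idx is not None else None
        ref_vals = part.values[referee_idx] if referee_idx is not None else None
        ref_cls = part.classes[referee_idx] if referee_idx is not None else None
        for b in range(part.n_bins):
            rd = None if np.isnan(rd_vals[b]) else float(rd_vals[b])
            sv = None
            if sv_vals is not None and not np.isnan(sv_vals[b]):
                sv = float(sv_vals[b])
            rc = None
            if referee_idx is not None:
                rv = None if ref_vals is None or np.isnan(ref_vals[b]) else float(ref_vals[b])
                rc = referee_class(rv, p_chrom, explicit=ref_cls[b])
            d = decide_bin(
                rd, sv, rc, thresholds, p_chrom,
                chrom=chrom, start=int(part.starts[b]), end=int(part.ends[b]),
            )
            rule_counts[d.rule_id] += 1
            all_decisions.append(d)

    # decisions are grouped per chromosome and sorted within it
    segments = merge_segments(all_decisions)
    if rule_counts.get(RULE_NO_EVIDENCE):
        logger.info("%d bins had no caller evidence; set to ploidy", rule_counts[RULE_NO_EVIDENCE])
    return ConsensusResult(
        segments=segments,
        thresholds=thresholds,
        bias=bias_est.bias,
        rule_counts=rule_counts,
        decisions=all_decisions if keep_decisions else [],
    )
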