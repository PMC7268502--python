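"""Ground-truthed synthetic CNV scenarios and emulated caller outputs.

The generator produces a piecewise-constant truth profile (per chromosome,
30-50 non-overlapping CNV segments of 10-100 kbp with copy numbers drawn
from {0, 1, 3, ..., 8}, diploid background elsewhere) and three caller
tracks with the statistical signatures the consensus model assumes:

* a gap-free binned coverage caller whose CN distribution is shifted
  slightly below the truth (the frequency-peak bias) plus Gaussian noise;
* a hybrid caller reporting non-negative ratios against a zero-coverage
  null alignment, i.e. values y with ``y * q(y) = true CN`` (the inverse
  of the equaliser correction), noisy and with prediction gaps;
* a referee caller that calls only a subset of the true CNV segments with
  the correct deletion/amplification direction but wildly scaled,
  heavy-tailed magnitudes.

A gene set tiled over the genome and the matching truth table are
generated alongside, so gene-level evaluation runs with no external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import CallerRole, CallerTrack, IntervalCall, ValueScale
from .harmonize import EqualizerParams, equalizer_q
from .tracks_io import GeneRecord, TruthTable


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    The noise and gap levels default to the low-coverage regime: per-bin
    CN noise of 0.5 for both primary callers, 30% missing hybrid bins,
    and a referee that sees only half of the true CNV segments.
    """

    n_chroms: int = 2
    chrom_length: int = 8_000_000
    background_cn: int = 2
    segments_per_chrom: tuple[int, int] = (30, 50)
    segment_length: tuple[int, int] = (10_000, 100_000)
    cnv_states: tuple[int, ...] = (0, 1, 3, 4, 5, 6, 7, 8)
    coverage_bin_size: int = 450
    hybrid_bin_size: int = 400
    coverage_noise_sd: float = 0.5
    hybrid_noise_sd: float = 0.5
    peak_shift: float = 0.1
    hybrid_gap_rate: float = 0.3
    referee_gap_rate: float = 0.5
    referee_magnitude_scale: float = 1000.0
    genes_per_chrom: int = 120
    gene_length: tuple[int, int] = (5_000, 40_000)


@dataclass
class SyntheticScenario:
    """A truth profile, three emulated caller tracks, genes and truth table."""

    seed: int
    config: ScenarioConfig
    truth: list[IntervalCall]                 # CNV segments only (background implied)
    chrom_lengths: dict[str, int]
    coverage: CallerTrack = None
    hybrid: CallerTrack = None
    referee: CallerTrack = None
    genes: list[GeneRecord] = field(default_factory=list)
    truth_table: TruthTable = None


def _chrom_names(n: int) -> list[str]:
    return [str(i + 1) for i in range(n)]


def simulate_truth(config: ScenarioConfig, rng: np.random.Generator) -> list[IntervalCall]:
    """Draw non-overlapping CNV segments per chromosome.

    Segment count, lengths and copy numbers are drawn independently; the
    segments are placed by distributing the leftover space uniformly at
    random between them. The background keeps the configured ploidy and
    is not materialised.
    """
    lo_n, hi_n = config.segments_per_chrom
    lo_l, hi_l = config.segment_length
    truth: list[IntervalCall] = []
    for chrom in _chrom_names(config.n_chroms):
        n_seg = int(rng.integers(lo_n, hi_n + 1))
        lengths = rng.integers(lo_l, hi_l + 1, size=n_seg)
        free = config.chrom_length - int(lengths.sum())
        if free < 0:
            raise ValueError(
                f"chromosome length {config.chrom_length} cannot host "
                f"{n_seg} segments totalling {int(lengths.sum())} bp"
            )
        offsets = np.sort(rng.integers(0, free + 1, size=n_seg))
        cns = rng.choice(config.cnv_states, size=n_seg)
        placed = 0
        for i in range(n_seg):
            start = int(offsets[i]) + placed
            end = start + int(lengths[i])
            truth.append(IntervalCall(chrom, start, end, float(cns[i])))
            placed += int(lengths[i])
    return truth


def truth_by_chrom(truth: list[IntervalCall]) -> dict[str, list[IntervalCall]]:
    out: dict[str, list[IntervalCall]] = {}
    for seg in truth:
        out.setdefault(seg.chrom, []).append(seg)
    return out


def _binned_truth(
    chrom_len: int,
    segs: list[IntervalCall],
    bin_size: int,
    background: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Overlap-weighted true CN per bin of a regular grid."""
    n = math.ceil(chrom_len / bin_size)
    starts = np.arange(n, dtype=np.int64) * bin_size
    ends = np.minimum(starts + bin_size, chrom_len)
    lengths = (ends - starts).astype(float)
    acc = background * lengths
    for seg in segs:
        ov = np.clip(np.minimum(seg.end, ends) - np.maximum(seg.start, starts), 0, None)
        acc += (seg.value - background) * ov
    return starts, ends, acc / lengths


def emulate_coverage_caller(
    truth: list[IntervalCall],
    chrom_lengths: dict[str, int],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> CallerTrack:
    """Gap-free binned absolute CNs with a systematic downward peak shift."""
    by_chrom = truth_by_chrom(truth)
    calls: list[IntervalCall] = []
    for chrom, L in chrom_lengths.items():
        starts, ends, cn = _binned_truth(
            L, by_chrom.get(chrom, []), config.coverage_bin_size, config.background_cn
        )
        noisy = cn - config.peak_shift + rng.normal(0.0, config.coverage_noise_sd, cn.size)
        noisy = np.clip(noisy, 0.0, None)
        calls.extend(
            IntervalCall(chrom, int(s), int(e), float(v))
            for s, e, v in zip(starts, ends, noisy)
        )
    return CallerTrack(CallerRole.COVERAGE, ValueScale.ABSOLUTE_CN, calls, name="emulated-coverage")


def invert_equalizer(
    target: float, params: EqualizerParams = EqualizerParams()
) -> float:
    """Solve ``y * q(y) = target`` for the null-ratio value y (y >= 0).

    ``y * q(y)`` is strictly increasing on [0, inf) so the root is unique;
    it is bracketed by [0, target] since q >= 1.
    """
    if target < 0:
        raise ValueError("target copy number must be >= 0")
    if target == 0.0:
        return 0.0

    def f(y: float) -> float:
        return y * float(equalizer_q(y, params)) - target

    return float(brentq(f, 0.0, target, xtol=1e-13, rtol=8.9e-16))


def emulate_hybrid_caller(
    truth: list[IntervalCall],
    chrom_lengths: dict[str, int],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> CallerTrack:
    """Null-ratio values distorted by the inverse equaliser, with gaps."""
    by_chrom = truth_by_chrom(truth)
    cache: dict[float, float] = {}
    calls: list[IntervalCall] = []
    for chrom, L in chrom_lengths.items():
        starts, ends, cn = _binned_truth(
            L, by_chrom.get(chrom, []), config.hybrid_bin_size, config.background_cn
        )
        y = np.empty_like(cn)
        for i, t in enumerate(cn):
            key = float(t)
            if key not in cache:
                cache[key] = invert_equalizer(key)
            y[i] = cache[key]
        if config.hybrid_noise_sd > 0:
            y = y + rng.normal(0.0, config.hybrid_noise_sd, y.size)
        y = np.clip(y, 0.0, None)
        keep = rng.random(y.size) >= config.hybrid_gap_rate
        calls.extend(
            IntervalCall(chrom, int(s), int(e), float(v))
            for s, e, v, k in zip(starts, ends, y, keep)
            if k
        )
    return CallerTrack(CallerRole.HYBRID, ValueScale.RATIO_VS_NULL, calls, name="emulated-hybrid")


def emulate_referee_caller(
    truth: list[IntervalCall],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> CallerTrack:
    """Direction-correct calls on a subset of true CNV segments.

    Amplified segments get their CN inflated by a heavy-tailed (log-
    exponential) factor capped at ``referee_magnitude_scale``; deleted
    segments get their CN shrunk towards 0. The direction relative to the
    background ploidy is preserved by construction.
    """
    P = config.background_cn
    calls: list[IntervalCall] = []
    for seg in truth:
        if rng.random() < config.referee_gap_rate:
            continue
        if seg.value > P:
            factor = min(float(np.exp(rng.exponential(2.0))), config.referee_magnitude_scale)
            value = seg.value * factor
        else:
            value = seg.value * float(rng.random())
        calls.append(IntervalCall(seg.chrom, seg.start, seg.end, float(value)))
    return CallerTrack(
        CallerRole.REFEREE, ValueScale.ABSOLUTE_CN, calls,
        name="emulated-referee", magnitude_unreliable=True,
    )


def generate_genes(
    truth: list[IntervalCall],
    chrom_lengths: dict[str, int],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[list[GeneRecord], TruthTable]:
    """Non-overlapping gene models tiled at random, with true CNs attached.

    A gene's true copy number is the length-weighted mean of the truth
    profile over its extent, mirroring how predictions are mapped to
    genes.
    """
    by_chrom = truth_by_chrom(truth)
    genes: list[GeneRecord] = []
    true_cn: dict[str, float] = {}
    for chrom, L in chrom_lengths.items():
        n = config.genes_per_chrom
        lengths = rng.integers(config.gene_length[0], config.gene_length[1] + 1, size=n)
        free = L - int(lengths.sum())
        if free < 0:
            raise ValueError("chromosome too short for the requested gene set")
        offsets = np.sort(rng.integers(0, free + 1, size=n))
        placed = 0
        segs = by_chrom.get(chrom, [])
        for i in range(n):
            start = int(offsets[i]) + placed
            end = start + int(lengths[i])
            placed += int(lengths[i])
            gid = f"g{chrom}_{i:04d}"
            genes.append(GeneRecord(gid, chrom, start, end))
            acc = config.background_cn * (end - start)
            for seg in segs:
                ov = min(seg.end, end) - max(seg.start, start)
                if ov > 0:
                    acc += (seg.value - config.background_cn) * ov
            true_cn[gid] = acc / (end - start)
    return genes, TruthTable(true_cn)


def make_scenario(seed: int, config: ScenarioConfig = ScenarioConfig()) -> SyntheticScenario:
    """Generate a full scenario deterministically from (seed, config)."""
    rng = np.random.default_rng(seed)
    chrom_lengths = {c: config.chrom_length for c in _chrom_names(config.n_chroms)}
    truth = simulate_truth(config, rng)
    coverage = emulate_coverage_caller(truth, chrom_lengths, config, rng)
    hybrid = emulate_hybrid_caller(truth, chrom_lengths, config, rng)
    referee = emulate_referee_caller(truth, config, rng)
    genes, truth_table = generate_genes(truth, chrom_lengths, config, rng)
    return SyntheticScenario(
        seed=seed, config=config, truth=truth, chrom_lengths=chrom_lengths,
        coverage=coverage, hybrid=hybrid, referee=referee,
        genes=genes, truth_table=truth_table,
    )


def truth_segments_for_eval(scenario: SyntheticScenario):
    """Truth profile as consensus-style segments (CNVs + background fill)."""
    from .core import ConsensusSegment

    segs: list[ConsensusSegment] = []
    by_chrom = truth_by_chrom(scenario.truth)
    for chrom, L in scenario.chrom_lengths.items():
        pos = 0
        for seg in by_chrom.get(chrom, []):
            if seg.start > pos:
                segs.append(ConsensusSegment(chrom, pos, seg.start,
                                             float(scenario.config.background_cn), 0.0, "truth"))
            segs.append(ConsensusSegment(chrom, seg.start, seg.end, seg.value, 0.0, "truth"))
            pos = seg.end
        if pos < L:
            segs.append(ConsensusSegment(chrom, pos, L,
                                         float(scenario.config.background_cn), 0.0, "truth"))
    return segs


def make_arbitration_fixture() -> SyntheticScenario:
    """Deterministic seven-bin scenario covering the whole rule table.

    One 700-bp toy chromosome with 100-bp bins a-g exercises every
    consensus situation: plain agreement on normal (a), amplification (c)
    and deletion (d); a conflict with no referee evidence (b); conflicts
    arbitrated towards the coverage (e) and hybrid (g) caller; and a
    hybrid prediction gap (f). Hand-built, byte-reproducible.
    """
    chrom = "1"
    cov_vals = [2.0, 3.0, 3.5, 0.5, 3.0, 3.2, 2.0]
    cov = CallerTrack(
        CallerRole.COVERAGE, ValueScale.ABSOLUTE_CN,
        [IntervalCall(chrom, i * 100, (i + 1) * 100, v) for i, v in enumerate(cov_vals)],
        name="fixture-coverage",
    )
    hyb_vals = {0: 2.0, 1: 2.0, 2: 3.8, 3: 0.8, 4: 2.0, 6: 3.4}  # bin f (5) absent
    hyb = CallerTrack(
        CallerRole.HYBRID, ValueScale.RATIO_VS_NULL,
        [IntervalCall(chrom, i * 100, (i + 1) * 100, v) for i, v in sorted(hyb_vals.items())],
        name="fixture-hybrid",
    )
    ref = CallerTrack(
        CallerRole.REFEREE, ValueScale.ABSOLUTE_CN,
        [IntervalCall(chrom, 400, 500, 12.0), IntervalCall(chrom, 600, 700, 40000.0)],
        name="fixture-referee", magnitude_unreliable=True,
    )
    truth = [
        IntervalCall(chrom, 200, 300, 4.0),   # c amplified
        IntervalCall(chrom, 300, 400, 1.0),   # d deleted
        IntervalCall(chrom, 400, 500, 3.0),   # e amplified
        IntervalCall(chrom, 500, 600, 3.0),   # f amplified
        IntervalCall(chrom, 600, 700, 3.0),   # g amplified
    ]
    config = ScenarioConfig(n_chroms=1, chrom_length=700)
    return SyntheticScenario(
        seed=0, config=config, truth=truth, chrom_lengths={chrom: 700},
        coverage=cov, hybrid=hyb, referee=ref, genes=[], truth_table=TruthTable({}),
    )
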