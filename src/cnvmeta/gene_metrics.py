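"""Gene-level accuracy evaluation of copy-number predictions.

Segment predictions are mapped onto genes as length-weighted copy numbers
(uncovered gene bases are filled with the ploidy), and compared against
per-gene true copy numbers with five metrics: mean squared error, mean
absolute error, mean log ratio error MLRE = mean |ln((x+1)/(x̂+1))|, the
mean per-true-CN variance of residuals, and a micro-averaged three-class
Matthews correlation coefficient (deletion < 1.75, amplification > 2.75
for ploidy 2, confusion counts summed one-vs-rest over the classes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .core import CnClass, ConsensusSegment, PloidyModel, ploidy_at
from .tracks_io import GeneRecord, TruthTable

logger = logging.getLogger(__name__)

#: class boundaries for ploidy 2, as fractions of the ploidy for other P
DELETION_FRACTION = 0.875   # 1.75 / 2
AMPLIFICATION_FRACTION = 1.375  # 2.75 / 2


@dataclass(frozen=True)
class GeneCopyNumber:
    """True/predicted copy-number pair for one gene."""

    gene_id: str
    true_cn: float
    predicted_cn: float
    evaluated_length: int

    def __post_init__(self) -> None:
        if self.true_cn < 0 or self.predicted_cn < 0:
            raise ValueError(f"gene {self.gene_id}: copy numbers must be >= 0")


@dataclass
class MetricsReport:
    """All evaluation metrics plus the micro-summed confusion counts."""

    mse: float
    mae: float
    mlre: float
    variance_of_residuals: float
    mcc: float
    confusion: dict[str, int]
    n_genes: int
    n_unique_true_cn: int
    missing_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "mse": self.mse,
            "mae": self.mae,
            "mlre": self.mlre,
            "variance_of_residuals": self.variance_of_residuals,
            "mcc": self.mcc,
            "n_genes": self.n_genes,
            "n_unique_true_cn": self.n_unique_true_cn,
        }
        d.update(self.confusion)
        return d


def track_as_segments(track) -> list[ConsensusSegment]:
    """View a caller track's calls as plain segments for baseline evaluation.

    Values must already be on the absolute scale (harmonise hybrid tracks
    first); class-only referee calls are skipped, negatives floored at 0.
    """
    return [
        ConsensusSegment(c.chrom, c.start, c.end, max(c.value, 0.0), 0.0, "caller")
        for c in track.calls
        if c.value is not None
    ]


def map_segments_to_genes(
    segments: list[ConsensusSegment],
    genes: list[GeneRecord],
    ploidy_model: PloidyModel = PloidyModel(),
) -> dict[str, float]:
    """Length-weighted copy number of each gene under a segment prediction.

    Each overlapping segment contributes ``cn * overlap/gene_length``;
    gene bases no segment covers contribute the chromosome's ploidy. A
    gene on a chromosome absent from the prediction gets the plain ploidy
    (with a warning).
    """
    trees: dict[str, IntervalTree] = {}
    for s in segments:
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, s.cn_meta)
    out: dict[str, float] = {}
    warned: set[str] = set()
    for g in genes:
        P = ploidy_at(ploidy_model, g.chrom)
        tree = trees.get(g.chrom)
        if tree is None:
            if g.chrom not in warned:
                logger.warning("no prediction on chromosome %s; genes there set to ploidy", g.chrom)
                warned.add(g.chrom)
            out[g.gene_id] = float(P)
            continue
        covered = 0
        acc = 0.0
        for iv in tree.overlap(g.start, g.end):
            ov = min(iv.end, g.end) - max(iv.begin, g.start)
            covered += ov
            acc += iv.data * ov
        acc += P * (g.length - covered)
        out[g.gene_id] = acc / g.length
    return out


def pair_with_truth(
    predicted: dict[str, float],
    genes: list[GeneRecord],
    truth: TruthTable,
) -> tuple[list[GeneCopyNumber], list[str]]:
    """Join predictions with the truth table; returns (pairs, missing ids).

    Genes present in the truth table but absent from the gene set are
    reported, never silently dropped.
    """
    by_id = {g.gene_id: g for g in genes}
    pairs: list[GeneCopyNumber] = []
    missing: list[str] = []
    for gid, x in truth.true_cn.items():
        if gid not in by_id or gid not in predicted:
            missing.append(gid)
            continue
        g = by_id[gid]
        length = min(truth.eval_length.get(gid, g.length), g.length)
        pairs.append(GeneCopyNumber(gid, x, predicted[gid], length))
    if missing:
        logger.warning("%d truth genes had no prediction/gene record: %s ...",
                       len(missing), missing[:5])
    return pairs, missing


def _xy(pairs) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) == 0:
        raise ValueError("no gene pairs to evaluate")
    x = np.array([p.true_cn for p in pairs], dtype=float)
    y = np.array([p.predicted_cn for p in pairs], dtype=float)
    return x, y


def mse(pairs: list[GeneCopyNumber]) -> float:
    x, y = _xy(pairs)
    return float(np.mean((x - y) ** 2))


def mae(pairs: list[GeneCopyNumber]) -> float:
    x, y = _xy(pairs)
    return float(np.mean(np.abs(x - y)))


def mlre(pairs: list[GeneCopyNumber]) -> float:
    """Mean absolute log ratio between (true+1) and (predicted+1)."""
    x, y = _xy(pairs)
    return float(np.mean(np.abs(np.log((x + 1.0) / (y + 1.0)))))


def variance_of_residuals(pairs: list[GeneCopyNumber]) -> float:
    """Mean, over unique integer true CNs, of the residual variance per group.

    True copy numbers are rounded to the nearest integer to form the
    groups; the population variance of the residuals x - x̂ is computed
    within each group (a singleton group contributes 0).
    """
    x, y = _xy(pairs)
    z = x - y
    groups = np.rint(x).astype(int)
    variances = [float(np.var(z[groups == j])) for j in np.unique(groups)]
    return float(np.mean(variances))


def classify_gene(cn: float, ploidy: int = 2) -> CnClass:
    """Deletion below 1.75, amplification above 2.75 (for ploidy 2).

    The boundaries scale proportionally with the ploidy; boundary values
    themselves are normal (the inequalities are strict).
    """
    if cn < DELETION_FRACTION * ploidy:
        return CnClass.DELETION
    if cn > AMPLIFICATION_FRACTION * ploidy:
        return CnClass.AMPLIFICATION
    return CnClass.NORMAL


def confusion_micro(true_classes, pred_classes) -> dict[str, int]:
    """One-vs-rest confusion counts summed over the three classes."""
    if len(true_classes) != len(pred_classes):
        raise ValueError("class sequences must have equal length")
    tp = tn = fp = fn = 0
    for cls in CnClass:
        for t, p in zip(true_classes, pred_classes):
            if t == cls and p == cls:
                tp += 1
            elif t != cls and p != cls:
                tn += 1
            elif t != cls and p == cls:
                fp += 1
            else:
                fn += 1
    return {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def mcc_micro(true_classes, pred_classes) -> float:
    """Matthews correlation on the micro-summed confusion counts."""
    c = confusion_micro(true_classes, pred_classes)
    tp, tn, fp, fn = c["tp"], c["tn"], c["fp"], c["fn"]
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        logger.warning("MCC denominator is zero; returning 0")
        return 0.0
    return (tp * tn - fp * fn) / denom


def evaluate(
    segments: list[ConsensusSegment],
    genes: list[GeneRecord],
    truth: TruthTable,
    ploidy_model: PloidyModel = PloidyModel(),
) -> MetricsReport:
    """Full gene-level evaluation of a segment prediction against truth."""
    predicted = map_segments_to_genes(segments, genes, ploidy_model)
    pairs, missing = pair_with_truth(predicted, genes, truth)
    if not pairs:
        raise ValueError("no overlap between truth table and gene set")
    P = ploidy_model.default_ploidy
    true_cls = [classify_gene(p.true_cn, P) for p in pairs]
    pred_cls = [classify_gene(p.predicted_cn, P) for p in pairs]
    return MetricsReport(
        mse=mse(pairs),
        mae=mae(pairs),
        mlre=mlre(pairs),
        variance_of_residuals=variance_of_residuals(pairs),
        mcc=mcc_micro(true_cls, pred_cls),
        confusion=confusion_micro(true_cls, pred_cls),
        n_genes=len(pairs),
        n_unique_true_cn=len({int(round(p.true_cn)) for p in pairs}),
        missing_genes=missing,
    )
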