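"""Readers and writers for caller tracks, gene models, truth tables and results.

The three caller roles share one documented TSV layout (tab-separated,
``#`` comment lines skipped):

* coverage:  ``chrom  start  end  cn``          (absolute copy numbers)
* hybrid:    ``chrom  start  end  value``       (log2 or null-ratio scale)
* referee:   ``chrom  start  end  cn-or-class`` (class is ``deletion`` or
  ``duplication``/``amplification``)

``dialect`` selects the coordinate convention of the *input* file: ``bed``
(0-based half-open, the internal convention) or ``one_based`` (1-based
inclusive, as in GFF). Gene models are read from GFF3/GTF (via gffutils)
or a BED-style TSV ``gene_id chrom start end [strand]``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .core import (
    CallerRole,
    CallerTrack,
    CnClass,
    ConsensusSegment,
    IntervalCall,
    ValueScale,
    normalize_chrom,
    round1,
)

logger = logging.getLogger(__name__)

_REFEREE_CLASS_TOKENS = {
    "deletion": CnClass.DELETION,
    "del": CnClass.DELETION,
    "duplication": CnClass.AMPLIFICATION,
    "dup": CnClass.AMPLIFICATION,
    "amplification": CnClass.AMPLIFICATION,
    "gain": CnClass.AMPLIFICATION,
    "loss": CnClass.DELETION,
}


@dataclass(frozen=True)
class GeneRecord:
    """One gene's extent; strand is carried for provenance but never used."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: invalid extent {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthTable:
    """Per-gene true copy numbers, with an optional evaluated length in bp.

    The evaluated length restricts a gene to the part actually covered by
    the confirming truth segment when that is shorter than the gene.
    """

    true_cn: dict[str, float]
    eval_length: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [g for g, x in self.true_cn.items() if x < 0 or not math.isfinite(x)]
        if bad:
            raise ValueError(f"negative or non-finite true copy numbers for {bad[:3]}")

    def __len__(self) -> int:
        return len(self.true_cn)


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _coords(fields: list[str], dialect: str, path, lineno: int) -> tuple[str, int, int]:
    if dialect not in ("bed", "one_based"):
        raise ValueError(f"unknown dialect {dialect!r} (expected 'bed' or 'one_based')")
    try:
        chrom = normalize_chrom(fields[0])
        start, end = int(fields[1]), int(fields[2])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
    if dialect == "one_based":
        start -= 1  # 1-based inclusive start -> 0-based; inclusive end == half-open end
    if start < 0 or start >= end:
        raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
    return chrom, start, end


def _finite(token: str, path, lineno: int) -> float:
    try:
        v = float(token)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed value {token!r}") from None
    if not math.isfinite(v):
        raise ValueError(f"{path}:{lineno}: non-finite value {token!r}")
    return v


def _check_sorted(calls: list[IntervalCall], path) -> list[IntervalCall]:
    calls = sorted(calls, key=lambda c: (c.chrom, c.start))
    prev: IntervalCall | None = None
    for c in calls:
        if prev is not None and c.chrom == prev.chrom and c.start < prev.end:
            raise ValueError(
                f"{path}: overlapping intervals on {c.chrom}: "
                f"{prev.start}-{prev.end} and {c.start}-{c.end}"
            )
        prev = c
    return calls


def read_coverage_track(path: str | Path, dialect: str = "bed") -> CallerTrack:
    """Read an absolute-CN coverage track (``chrom start end cn``)."""
    calls = []
    for lineno, f in _data_lines(path):
        chrom, start, end = _coords(f, dialect, path, lineno)
        if len(f) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(f)}")
        cn = _finite(f[3], path, lineno)
        if cn < 0:
            raise ValueError(f"{path}:{lineno}: negative copy number {cn}")
        calls.append(IntervalCall(chrom, start, end, cn))
    return CallerTrack(
        CallerRole.COVERAGE, ValueScale.ABSOLUTE_CN,
        _check_sorted(calls, path), name=str(path),
    )


def read_hybrid_track(
    path: str | Path,
    dialect: str = "bed",
    value_scale: str | ValueScale = ValueScale.RATIO_VS_NULL,
) -> CallerTrack:
    """Read a hybrid-caller track; the value scale must be declared.

    Under ``ratio_vs_null`` the values are ratios against a zero-coverage
    null alignment and must be non-negative; under ``log2_vs_matched``
    negative log ratios are expected. Gaps between rows are preserved.
    """
    scale = ValueScale(value_scale)
    if scale is ValueScale.ABSOLUTE_CN:
        raise ValueError("hybrid tracks are log2_vs_matched or ratio_vs_null")
    calls = []
    for lineno, f in _data_lines(path):
        chrom, start, end = _coords(f, dialect, path, lineno)
        if len(f) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(f)}")
        v = _finite(f[3], path, lineno)
        if scale is ValueScale.RATIO_VS_NULL and v < 0:
            raise ValueError(
                f"{path}:{lineno}: negative value {v} impossible for a ratio "
                "against a zero-coverage null alignment"
            )
        calls.append(IntervalCall(chrom, start, end, v))
    return CallerTrack(CallerRole.HYBRID, scale, _check_sorted(calls, path), name=str(path))


def read_referee_track(path: str | Path, dialect: str = "bed") -> CallerTrack:
    """Read a referee track whose magnitudes are unreliable.

    The fourth column is either a copy number (kept, but flagged) or a
    call class (``deletion``/``duplication``...), stored class-only.
    """
    calls = []
    for lineno, f in _data_lines(path):
        chrom, start, end = _coords(f, dialect, path, lineno)
        if len(f) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(f)}")
        token = f[3].strip().lower()
        if token in _REFEREE_CLASS_TOKENS:
            calls.append(IntervalCall(chrom, start, end, None,
                                      cn_class=_REFEREE_CLASS_TOKENS[token]))
        else:
            cn = _finite(f[3], path, lineno)
            if cn < 0:
                raise ValueError(f"{path}:{lineno}: negative copy number {cn}")
            calls.append(IntervalCall(chrom, start, end, cn))
    if not calls:
        logger.warning("%s: empty referee track", path)
    return CallerTrack(
        CallerRole.REFEREE, ValueScale.ABSOLUTE_CN,
        _check_sorted(calls, path), name=str(path), magnitude_unreliable=True,
    )


def _write_metadata(fh, metadata: dict | None) -> None:
    for key, value in (metadata or {}).items():
        fh.write(f"## {key}: {value}\n")


def write_track(path: str | Path, track: CallerTrack, metadata: dict | None = None) -> None:
    """Write a track in its role's TSV dialect (BED-style coordinates)."""
    with open(path, "w") as fh:
        _write_metadata(fh, metadata)
        fh.write("#chrom\tstart\tend\tvalue\n")
        for c in track.calls:
            if c.value is None:
                val = "deletion" if c.cn_class is CnClass.DELETION else "duplication"
            else:
                val = repr(float(c.value))
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{val}\n")


CONSENSUS_COLUMNS = ("chrom", "start", "end", "cn_meta_1dp", "cn_meta", "error_score", "rule")


def write_consensus(
    path: str | Path,
    segments: list[ConsensusSegment],
    metadata: dict | None = None,
) -> None:
    """Write consensus segments as a BED-compatible TSV (sorted, with header)."""
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start))
    with open(path, "w") as fh:
        _write_metadata(fh, metadata)
        fh.write("#" + "\t".join(CONSENSUS_COLUMNS) + "\n")
        for s in ordered:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{round1(s.cn_meta):.1f}\t"
                f"{s.cn_meta!r}\t{s.error_score!r}\t{s.rule_id}\n"
            )


def read_consensus(path: str | Path) -> list[ConsensusSegment]:
    """Read back a consensus TSV (full-precision columns)."""
    segments = []
    for lineno, f in _data_lines(path):
        if len(f) < 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(f)}")
        chrom, start, end = _coords(f, "bed", path, lineno)
        segments.append(ConsensusSegment(
            chrom, start, end,
            _finite(f[4], path, lineno), _finite(f[5], path, lineno), f[6],
        ))
    return segments


def read_genes(path: str | Path, fmt: str | None = None) -> list[GeneRecord]:
    """Read gene records from GFF3, GTF or a BED-style TSV.

    ``fmt`` is inferred from the suffix when omitted. GFF coordinates
    (1-based inclusive) are converted to the internal 0-based half-open
    convention; duplicate gene identifiers are rejected.
    """
    p = Path(path)
    if fmt is None:
        suffix = p.suffix.lower().lstrip(".")
        fmt = {"gff": "gff3", "gff3": "gff3", "gtf": "gtf", "tsv": "tsv", "bed": "tsv"}.get(
            suffix, "tsv"
        )
    if fmt in ("gff3", "gtf"):
        genes = _read_genes_gff(p, fmt)
    elif fmt == "tsv":
        genes = []
        for lineno, f in _data_lines(p):
            if len(f) < 4:
                raise ValueError(f"{p}:{lineno}: expected >= 4 columns, got {len(f)}")
            chrom, start, end = _coords(f[1:4], "bed", p, lineno)
            strand = f[4] if len(f) > 4 else "."
            genes.append(GeneRecord(f[0], chrom, start, end, strand))
    else:
        raise ValueError(f"unknown gene format {fmt!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"{p}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def _read_genes_gff(path: Path, fmt: str) -> list[GeneRecord]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="error", disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", feat.attributes.get("ID"))
        if not gid:
            raise ValueError(
                f"{path}: gene feature at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks a gene_id/ID attribute"
            )
        genes.append(GeneRecord(
            gid[0], normalize_chrom(feat.seqid), feat.start - 1, feat.end,
            feat.strand or ".",
        ))
    return genes


def read_truth_table(path: str | Path) -> TruthTable:
    """Read a truth table TSV: ``gene_id  true_cn  [eval_length]``."""
    true_cn: dict[str, float] = {}
    eval_length: dict[str, int] = {}
    for lineno, f in _data_lines(path):
        if len(f) < 2:
            raise ValueError(f"{path}:{lineno}: expected >= 2 columns, got {len(f)}")
        gid = f[0]
        if gid in true_cn:
            raise ValueError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
        x = _finite(f[1], path, lineno)
        if x < 0:
            raise ValueError(f"{path}:{lineno}: negative true copy number {x}")
        true_cn[gid] = x
        if len(f) > 2 and f[2].strip():
            eval_length[gid] = int(f[2])
    return TruthTable(true_cn, eval_length)


def write_truth_table(path: str | Path, truth: TruthTable) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\ttrue_cn\teval_length\n")
        for gid, x in truth.true_cn.items():
            extra = str(truth.eval_length.get(gid, ""))
            fh.write(f"{gid}\t{x!r}\t{extra}\n")


def write_genes_tsv(path: str | Path, genes: list[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")
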