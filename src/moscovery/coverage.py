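"""Per-exon median sequencing depth, from alignments or imported tables.

The unit of measurement is the median per-base depth over an exon, the same
summary mosdepth reports in its per-region output.  Depth can be computed
natively from coordinate-sorted, indexed BAM/CRAM, or imported from
tab-separated per-region tables (BED4+1: chrom, start, end, name, median),
optionally gzip-compressed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ContigError, ParseError, ValidationError
from .regions import ExonRecord

logger = logging.getLogger(__name__)


@dataclass
class ReadFilter:
    """Which reads contribute to depth.

    Unmapped, secondary, supplementary and duplicate-flagged reads are always
    excluded.  ``min_mapq`` defaults to 0 (no floor).  Overlapping mate pairs
    are counted twice unless ``correct_mate_overlap`` is set.
    """

    min_mapq: int = 0
    correct_mate_overlap: bool = False

    def passes(self, read: "pysam.AlignedSegment") -> bool:
        return not (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.mapping_quality < self.min_mapq
        )


@dataclass
class CoverageTable:
    """Samples x exons matrix of per-region median depth.

    ``depth`` is a DataFrame indexed by sample id with exon-id columns;
    missing cells are NaN, never silently 0.
    """

    depth: pd.DataFrame
    kit_id: str = "unknown"
    source: str = "imported"
    unknown_regions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if ((self.depth < 0).any().any()):
            raise ValidationError("negative depth values")

    @property
    def samples(self) -> list[str]:
        return list(self.depth.index)

    @property
    def exons(self) -> list[str]:
        return list(self.depth.columns)

    def write_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.depth.rename_axis("sample_id").to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, kit_id: str = "unknown") -> "CoverageTable":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
        return cls(depth=df, kit_id=kit_id, source="imported")


def region_median_depth(
    alignment_source: str | Path | pysam.AlignmentFile,
    intervals: Sequence[ExonRecord],
    filters: ReadFilter | None = None,
    reference: str | Path | None = None,
) -> np.ndarray:
    """Median per-base depth over each interval from a BAM/CRAM file.

    The alignment must be coordinate-sorted and indexed.  For each interval
    the per-base depth over [start, end) is accumulated from the aligned
    blocks of reads passing the filters (soft-clipped and unaligned segments
    contribute nothing), and the median taken; an even-length set of values
    yields the mean of the two central ones.  Intervals with no aligned
    reads yield 0.  CRAM input requires an explicit ``reference`` path.
    """
    filters = filters or ReadFilter()
    own = False
    if not isinstance(alignment_source, pysam.AlignmentFile):
        kwargs = {}
        if reference is not None:
            kwargs["reference_filename"] = str(reference)
        alignment_source = pysam.AlignmentFile(str(alignment_source), **kwargs)
        own = True
    try:
        af = alignment_source
        if not af.has_index():
            raise OSError(f"alignment {af.filename!r} has no index (.bai/.crai)")
        known = set(af.references)
        offenders = sorted({iv.chrom for iv in intervals} - known)
        if offenders:
            raise ContigError(
                f"contigs absent from alignment header: {offenders}"
            )
        medians = np.empty(len(intervals))
        for i, iv in enumerate(intervals):
            depth = np.zeros(iv.length, dtype=np.int64)
            if filters.correct_mate_overlap:
                _accumulate_fragment_depth(af, iv, filters, depth)
            else:
                for read in af.fetch(iv.chrom, iv.start, iv.end):
                    if not filters.passes(read):
                        continue
                    for bstart, bend in read.get_blocks():
                        lo, hi = max(bstart, iv.start), min(bend, iv.end)
                        if lo < hi:
                            depth[lo - iv.start : hi - iv.start] += 1
            medians[i] = np.median(depth)
        return medians
    finally:
        if own:
            alignment_source.close()


def _accumulate_fragment_depth(af, iv, filters, depth) -> None:
    """Per-fragment depth: overlapping mate blocks are merged per read name
    so overlapping pairs count once per position."""
    by_name: dict[str, list[tuple[int, int]]] = {}
    for read in af.fetch(iv.chrom, iv.start, iv.end):
        if not filters.passes(read):
            continue
        by_name.setdefault(read.query_name, []).extend(read.get_blocks())
    for blocks in by_name.values():
        covered = np.zeros(iv.length, dtype=bool)
        for bstart, bend in blocks:
            lo, hi = max(bstart, iv.start), min(bend, iv.end)
            if lo < hi:
                covered[lo - iv.start : hi - iv.start] = True
        depth += covered


def write_regions_table(
    intervals: Sequence[ExonRecord],
    medians: Iterable[float],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write a per-region median depth table (BED4+1), single sample."""
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for iv, m in zip(intervals, medians):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene}\t{m:g}\n")


def read_regions_table(
    path: str | Path,
    panel: Sequence[ExonRecord] | None = None,
    sample_id: str | None = None,
    kit_id: str = "unknown",
) -> CoverageTable:
    """Read one sample's per-region median depth table (mosdepth-style).

    Columns: chrom, start, end, name, median depth; gzip is detected from
    the extension.  When a ``panel`` is given, regions are matched to panel
    exon ids by coordinates and unrecognized regions are reported on the
    returned table's ``unknown_regions``; panel exons absent from the file
    are NaN.
    """
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    sample_id = sample_id or path.name.split(".")[0]
    values: dict[str, float] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 tab-separated columns")
            try:
                chrom, start, end, depth = parts[0], int(parts[1]), int(parts[2]), float(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            values[f"{chrom}:{start}-{end}"] = depth

    unknown: list[str] = []
    if panel is not None:
        panel_ids = [r.exon_id for r in panel]
        unknown = sorted(set(values) - set(panel_ids))
        if unknown:
            logger.warning(
                "%s: %d regions not in the panel (e.g. %s)", path, len(unknown), unknown[0]
            )
        row = {e: values.get(e, np.nan) for e in panel_ids}
    else:
        row = values
    df = pd.DataFrame([row], index=pd.Index([sample_id], name="sample_id"))
    return CoverageTable(depth=df, kit_id=kit_id, source="imported", unknown_regions=unknown)


def coverage_from_alignments(
    alignments: dict[str, str | Path],
    panel: Sequence[ExonRecord],
    filters: ReadFilter | None = None,
    reference: str | Path | None = None,
    kit_id: str = "unknown",
) -> CoverageTable:
    """Native CoverageTable for a cohort of alignment files (sample -> path)."""
    rows = {
        sid: region_median_depth(path, panel, filters=filters, reference=reference)
        for sid, path in alignments.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[r.exon_id for r in panel])
    df.index.name = "sample_id"
    return CoverageTable(depth=df, kit_id=kit_id, source="native")


def thin_coverage(
    table: CoverageTable, keep_fraction: float, seed: int = 0
) -> CoverageTable:
    """Binomially thin every depth value, keeping ``keep_fraction`` of reads.

    A depth-level surrogate for read-level downsampling: each (rounded)
    depth d is replaced by Binomial(d, keep_fraction), so the expected
    thinned depth is keep_fraction x d.  keep_fraction = 1 returns the table
    unchanged; depth 0 stays 0.
    """
    if not (0 < keep_fraction <= 1):
        raise ValidationError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if keep_fraction == 1:
        return CoverageTable(
            depth=table.depth.copy(), kit_id=table.kit_id, source=table.source
        )
    rng = np.random.default_rng(seed)
    vals = table.depth.to_numpy(dtype=float)
    mask = np.isnan(vals)
    n = np.rint(np.where(mask, 0, vals)).astype(np.int64)
    thinned = rng.binomial(n, keep_fraction).astype(float)
    thinned[mask] = np.nan
    df = pd.DataFrame(thinned, index=table.depth.index, columns=table.depth.columns)
    return CoverageTable(depth=df, kit_id=table.kit_id, source=table.source)
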