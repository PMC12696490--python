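"""Exon panel construction for chrY coverage analysis.

Builds the two region sets the method rests on: the chrY exon panel,
restricted to single-copy genes of the X-degenerate region of the
male-specific Y (MSY), and a pool of autosomal exons matched to each chrY
exon by GC content and length via propensity scores.  Ampliconic and
X-transposed chrY genes are excluded because their copy number or
alignability would distort coverage; autosomal exons that are recurrently
gained or lost in blood are excluded because somatic copy-number events
there would contaminate the normalization baseline.

Coordinates follow the BED convention throughout: 0-based, half-open.
Strand is ignored; coverage is strand-agnostic.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .errors import (
    CapacityError,
    CohortSizeError,
    CoordinateError,
    MissingContigError,
    PanelMismatchError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: Single-copy genes of the X-degenerate MSY region, present once per chrY.
X_DEGENERATE_SINGLE_COPY_GENES: tuple[str, ...] = (
    "SRY", "RPS4Y1", "ZFY", "AMELY", "TBL1Y", "USP9Y", "DDX3Y",
    "UTY", "TMSB4Y", "NLGN4Y", "KDM5D", "EIF1AY", "RPS4Y2",
)

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$")
_CHRY_RE = re.compile(r"^(chr)?Y$", re.IGNORECASE)
_CHRX_RE = re.compile(r"^(chr)?X$", re.IGNORECASE)


def is_autosome(chrom: str) -> bool:
    return bool(_AUTOSOME_RE.match(chrom))


def is_chry(chrom: str) -> bool:
    return bool(_CHRY_RE.match(chrom))


@dataclass(frozen=True)
class ExonRecord:
    """A genomic interval with gene label, length and GC fraction.

    ``start``/``end`` are BED-style (0-based half-open).  ``gc`` is the
    fraction of G/C among non-ambiguous bases over the interval, or NaN
    before :func:`compute_exon_gc` has run (or when the interval is all N).
    ``n_frac`` is the fraction of ambiguous (non-ACGT) bases.
    """

    chrom: str
    start: int
    end: int
    gene: str = "."
    gc: float = float("nan")
    n_frac: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if not (np.isnan(self.gc) or 0.0 <= self.gc <= 1.0):
            raise ValueError(f"gc out of [0, 1]: {self.gc}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GenePanel:
    """Ordered set of gene symbols eligible for the chrY panel."""

    genes: tuple[str, ...] = X_DEGENERATE_SINGLE_COPY_GENES

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class MatchTable:
    """Mapping from each chrY exon id to its k matched autosomal exon ids.

    Matched ids are stored in rank order (rank 1 = nearest in propensity
    score).  Every chrY exon has exactly ``k`` matches.
    """

    entries: dict[str, list[str]]
    k: int = 100

    def __post_init__(self) -> None:
        for yid, matched in self.entries.items():
            if len(matched) != self.k:
                raise ValueError(
                    f"chrY exon {yid} has {len(matched)} matches, expected {self.k}"
                )

    @property
    def chry_exon_ids(self) -> list[str]:
        return list(self.entries)

    @property
    def autosomal_exon_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for matched in self.entries.values():
            for m in matched:
                seen.setdefault(m)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (yid, aid, rank)
            for yid, matched in self.entries.items()
            for rank, aid in enumerate(matched, start=1)
        ]
        return pd.DataFrame(rows, columns=["chrY_exon_id", "autosomal_exon_id", "rank"])

    def write_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MatchTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        entries: dict[str, list[str]] = {}
        for yid, grp in df.sort_values("rank").groupby("chrY_exon_id", sort=False):
            entries[yid] = grp["autosomal_exon_id"].tolist()
        ks = {len(v) for v in entries.values()}
        if len(ks) != 1:
            raise ParseError(f"inconsistent match counts per chrY exon: {sorted(ks)}")
        return cls(entries=entries, k=ks.pop())


# ---------------------------------------------------------------------------
# BED / tabular I/O


def read_bed(path: str | Path) -> list[ExonRecord]:
    """Read an exon panel from BED (4+ columns, name formatted GENE|EXONID)."""
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    records: list[ExonRecord] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            gene = parts[3].split("|")[0] if len(parts) >= 4 else "."
            records.append(ExonRecord(chrom=chrom, start=start, end=end, gene=gene))
    return records


def write_bed(records: Iterable[ExonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}|{i}\n")


def read_event_counts(path: str | Path) -> dict[str, int]:
    """Read a blacklist of mosaic gain/loss counts: 'exon_id<TAB>count'."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'exon_id<TAB>count'")
            try:
                counts[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return counts


# ---------------------------------------------------------------------------
# Operations


def compute_exon_gc(reference, intervals: Sequence[ExonRecord]) -> list[ExonRecord]:
    """Annotate intervals with GC fraction from a reference sequence source.

    ``reference`` may be a path to a FASTA file or any mapping from contig
    name to an object sliceable to a sequence string (e.g. ``pyfaidx.Fasta``).
    GC is (#G + #C) / (#A + #C + #G + #T), case-insensitive; ambiguous bases
    are excluded from numerator and denominator.  An all-ambiguous interval
    gets gc = NaN.
    """
    if isinstance(reference, (str, Path)):
        from pyfaidx import Fasta

        reference = Fasta(str(reference))
    out: list[ExonRecord] = []
    for iv in intervals:
        try:
            contig = reference[iv.chrom]
        except KeyError as exc:
            raise MissingContigError(f"contig {iv.chrom!r} not in reference") from exc
        contig_len = len(contig)
        if iv.end > contig_len:
            raise CoordinateError(
                f"{iv.exon_id} extends beyond contig end ({contig_len})"
            )
        seq = str(contig[iv.start : iv.end]).upper()
        gc_n = seq.count("G") + seq.count("C")
        at_n = seq.count("A") + seq.count("T")
        denom = gc_n + at_n
        gc = gc_n / denom if denom else float("nan")
        out.append(replace(iv, gc=gc, n_frac=1.0 - denom / iv.length))
    return out


def select_chry_exons(
    kit_exons: Sequence[ExonRecord], panel: GenePanel | None = None
) -> list[ExonRecord]:
    """Keep kit exons whose gene is in the single-copy chrY panel.

    Deduplicates on coordinates and sorts genomically.  Raises
    :class:`PanelMismatchError` if the kit captures none of the panel genes.
    """
    panel = panel or GenePanel()
    seen: dict[tuple[str, int, int], ExonRecord] = {}
    for r in kit_exons:
        if r.gene in panel:
            seen.setdefault((r.chrom, r.start, r.end), r)
    if not seen:
        raise PanelMismatchError(
            "kit captures no exon of the single-copy chrY gene panel"
        )
    return sorted(seen.values(), key=lambda r: r.sort_key)


def filter_cnv_prone(
    candidates: Sequence[ExonRecord],
    event_counts: Mapping[str, int],
    max_events: int = 10,
) -> list[ExonRecord]:
    """Drop autosomal exons with >= ``max_events`` mosaic gains+losses.

    Blacklist files enumerate only regions where events were seen, so a
    missing count is treated as 0 (eligible) and logged.
    """
    kept: list[ExonRecord] = []
    n_missing = 0
    for r in candidates:
        count = event_counts.get(r.exon_id)
        if count is None:
            n_missing += 1
            count = 0
        if count < max_events:
            kept.append(r)
    if n_missing:
        logger.info(
            "filter_cnv_prone: %d/%d exons had no event count (treated as 0)",
            n_missing, len(candidates),
        )
    return kept


def _propensity_scores(
    chry_exons: Sequence[ExonRecord], candidates: Sequence[ExonRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Linear predictor of a logistic model of chrY membership on
    standardized GC and log10(length), for panel exons and candidates."""
    gc = np.array([r.gc for r in chry_exons] + [r.gc for r in candidates])
    loglen = np.log10(
        np.array([r.length for r in chry_exons] + [r.length for r in candidates], float)
    )
    X = np.column_stack([gc, loglen])
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    y = np.r_[np.ones(len(chry_exons)), np.zeros(len(candidates))]
    # near-unpenalized, deterministic fit; a weak ridge keeps the linear
    # predictor finite under quasi-separation
    model = LogisticRegression(C=1e6, max_iter=5000, tol=1e-10)
    model.fit(X, y)
    lp = X @ model.coef_.ravel()
    return lp[: len(chry_exons)], lp[len(chry_exons):]


def match_autosomal_exons(
    chry_exons: Sequence[ExonRecord],
    candidates: Sequence[ExonRecord],
    k: int = 100,
    seed: int = 0,
) -> MatchTable:
    """Match each chrY exon to its k nearest autosomal exons in propensity
    score (GC content and length), without replacement.

    Candidates on chrX/chrY or non-primary contigs, and candidates with >50%
    ambiguous bases or undefined GC, are removed before matching.  Matching
    is greedy over chrY exons in order of decreasing length; distance ties
    break by genomic order, so the result is deterministic.  ``seed`` is
    accepted for interface symmetry; the procedure has no random step.
    """
    del seed
    eligible = [
        r for r in candidates
        if is_autosome(r.chrom) and r.n_frac <= 0.5 and not np.isnan(r.gc)
    ]
    n_dropped = len(candidates) - len(eligible)
    if n_dropped:
        logger.info("match_autosomal_exons: dropped %d ineligible candidates", n_dropped)
    needed = k * len(chry_exons)
    if len(eligible) < needed:
        raise CapacityError(
            f"need {needed} autosomal candidates for {len(chry_exons)} chrY exons "
            f"at k={k}, have {len(eligible)} (deficit {needed - len(eligible)})"
        )
    for r in chry_exons:
        if np.isnan(r.gc):
            raise ValueError(f"chrY exon {r.exon_id} has no GC annotation")

    lp_y, lp_cand = _propensity_scores(chry_exons, eligible)
    chroms = np.array([r.chrom for r in eligible])
    chrom_order = np.unique(chroms, return_inverse=True)[1]
    starts = np.array([r.start for r in eligible])
    available = np.ones(len(eligible), dtype=bool)

    order = sorted(
        range(len(chry_exons)),
        key=lambda i: (-chry_exons[i].length, chry_exons[i].sort_key),
    )
    entries: dict[str, list[str]] = {}
    for i in order:
        d = np.abs(lp_cand - lp_y[i])
        d[~available] = np.inf
        # primary key distance, ties by (chrom, start)
        pick = np.lexsort((starts, chrom_order, d))[:k]
        available[pick] = False
        entries[chry_exons[i].exon_id] = [eligible[j].exon_id for j in pick]
    # restore panel order
    entries = {r.exon_id: entries[r.exon_id] for r in chry_exons}
    return MatchTable(entries=entries, k=k)


def filter_outlier_exons(
    coverage,
    chry_exons: Sequence[ExonRecord],
    multiplier: float = 1.5,
    min_reference_samples: int = 20,
) -> list[ExonRecord]:
    """Drop chrY exons whose coverage is an outlier across reference samples.

    ``coverage`` is a :class:`~moscovery.coverage.CoverageTable` (or a
    samples x exons DataFrame) restricted to samples believed free of mosaic
    chrY loss.  Each exon's statistic is the median, across reference
    samples, of its depth normalized to that sample's autosomal median
    depth; exons falling outside median +/- ``multiplier`` x IQR of the
    per-exon statistics are removed.
    """
    df = getattr(coverage, "depth", coverage)
    if len(df) < min_reference_samples:
        raise CohortSizeError(
            f"outlier-exon filtering needs >= {min_reference_samples} reference "
            f"samples believed mLOY-free, got {len(df)}"
        )
    chry_ids = [r.exon_id for r in chry_exons]
    missing = [e for e in chry_ids if e not in df.columns]
    if missing:
        raise KeyError(f"coverage table lacks chrY exons: {missing[:5]}...")
    auto_cols = [c for c in df.columns if c not in set(chry_ids)]
    if not auto_cols:
        raise ValueError("coverage table has no autosomal exons for normalization")
    auto_median = df[auto_cols].median(axis=1)
    stat = df[chry_ids].div(auto_median, axis=0).median(axis=0)
    q1, q3 = stat.quantile([0.25, 0.75])
    iqr = q3 - q1
    med = stat.median()
    keep = (stat >= med - multiplier * iqr) & (stat <= med + multiplier * iqr)
    kept = [r for r in chry_exons if keep[r.exon_id]]
    logger.info(
        "filter_outlier_exons: kept %d/%d chrY exons", len(kept), len(chry_ids)
    )
    return kept
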