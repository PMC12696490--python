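"""Synthetic cohorts with known ground-truth mosaic chrY loss.

Generates per-exon median depth matrices (and, for end-to-end coverage
tests, miniature reference + alignment files) for a cohort in which each
carrier's true cell fraction is known.  The depth model follows the dosage
biology the estimator inverts: autosomal exons are diploid, so their
expected depth is the sample mean depth modulated by a smooth GC trend;
chrY is haploid, so a sample in which a fraction f of cells lack chrY has
expected chrY depth 0.5 * (1 - f) of the autosomal level at the same GC.
Depth noise is negative binomial (variance mu + overdispersion * mu^2),
the standard model for sequencing depth, which also supports the binomial
read-thinning surrogate used in downsampling experiments.

What this emulates: GC-dependent coverage bias, depth overdispersion,
kit/batch-level chrY coverage shifts, and the haploid dosage signal.  What
it does not: alignability artifacts, ampliconic-gene cross-mapping, CNVs in
the normalization pool, or correlated noise between neighboring exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from .coverage import CoverageTable
from .errors import ValidationError
from .regions import (
    ExonRecord,
    MatchTable,
    X_DEGENERATE_SINGLE_COPY_GENES,
    match_autosomal_exons,
)

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    ``gc_bias`` are (linear, quadratic) coefficients of the log-depth trend
    in (gc - 0.5); the default mild concave trend depresses depth at
    extreme GC, as exome capture does.  ``overdispersion`` is the
    negative-binomial excess-variance coefficient (0 = Poisson); the
    default 0.05 reflects the mild extra-Poisson variation of within-panel
    exome depth.  ``noise=False`` gives exact expected depths, for
    construction-level tests.  ``batch_shifts`` optionally maps batch id to
    a multiplicative chrY coverage bias; samples are assigned to batches
    round-robin.
    """

    n_samples: int = 500
    prevalence: float = 0.1
    cf_low: float = 0.1
    cf_high: float = 0.8
    mean_depth: float = 50.0
    overdispersion: float = 0.05
    gc_bias: tuple[float, float] = (0.0, -3.0)
    batch_shifts: dict[str, float] | None = None
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValidationError(f"prevalence outside [0, 1]: {self.prevalence}")
        if self.mean_depth <= 0:
            raise ValidationError(f"mean_depth must be > 0: {self.mean_depth}")
        if not (0 < self.cf_low <= self.cf_high <= 1):
            raise ValidationError(
                f"cell-fraction support must satisfy 0 < low <= high <= 1, "
                f"got ({self.cf_low}, {self.cf_high})"
            )
        if self.overdispersion < 0:
            raise ValidationError("overdispersion must be >= 0")


def gc_trend(gc: np.ndarray, coeffs: tuple[float, float]) -> np.ndarray:
    """Smooth multiplicative depth-vs-GC trend, exp(c1*x + c2*x^2), x = gc - 0.5."""
    x = np.asarray(gc, dtype=float) - 0.5
    return np.exp(coeffs[0] * x + coeffs[1] * x * x)


def simulate_panel(
    seed: int = 0,
    n_genes: int = 13,
    exons_per_gene: int = 13,
    n_candidates: int = 25_000,
) -> tuple[list[ExonRecord], list[ExonRecord]]:
    """A synthetic chrY exon panel plus an autosomal candidate pool.

    Defaults mirror the scale of a real single-copy chrY panel (~170 exons
    across 13 genes).  GC and length distributions of the candidates are
    slightly wider than the panel's so propensity matching has both close
    and distant material to choose from.
    """
    rng = np.random.default_rng(seed)
    genes = [
        X_DEGENERATE_SINGLE_COPY_GENES[i % len(X_DEGENERATE_SINGLE_COPY_GENES)]
        + ("" if i < len(X_DEGENERATE_SINGLE_COPY_GENES) else f"_{i}")
        for i in range(n_genes)
    ]
    chry: list[ExonRecord] = []
    pos = 2_700_000
    for gene in genes:
        for _ in range(exons_per_gene):
            length = int(np.clip(rng.lognormal(np.log(150), 0.5), 50, 5000))
            gc = float(np.clip(rng.normal(0.45, 0.08), 0.25, 0.75))
            chry.append(
                ExonRecord(chrom="chrY", start=pos, end=pos + length, gene=gene, gc=gc)
            )
            pos += length + rng.integers(500, 5000)
    candidates: list[ExonRecord] = []
    chroms = rng.integers(1, 23, size=n_candidates)
    starts = rng.integers(10_000, 200_000_000, size=n_candidates)
    lengths = np.clip(rng.lognormal(np.log(150), 0.6, size=n_candidates), 50, 8000).astype(int)
    gcs = np.clip(rng.normal(0.47, 0.10, size=n_candidates), 0.2, 0.8)
    for c, s, ln, gc in zip(chroms, starts, lengths, gcs):
        candidates.append(
            ExonRecord(chrom=f"chr{c}", start=int(s), end=int(s + ln), gene=".", gc=float(gc))
        )
    # synthetic coordinates may collide; deduplicate on exon_id
    seen: dict[str, ExonRecord] = {}
    for r in candidates:
        seen.setdefault(r.exon_id, r)
    return chry, list(seen.values())


def simulate_cohort(
    chry_exons: Sequence[ExonRecord],
    autosomal_exons: Sequence[ExonRecord],
    matches: MatchTable,
    config: SimConfig,
) -> tuple[CoverageTable, pd.DataFrame]:
    """Per-exon median depth matrix plus the ground-truth table.

    The truth table has columns ``is_mloy_true``, ``cf_true`` (0 for
    non-carriers) and ``batch``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    gc_by_id = {r.exon_id: r.gc for r in autosomal_exons}
    auto_ids = matches.autosomal_exon_ids
    missing = [a for a in auto_ids if a not in gc_by_id]
    if missing:
        raise ValidationError(f"matched exons missing from autosomal panel: {missing[:3]}...")
    chry_ids = [r.exon_id for r in chry_exons]

    n = config.n_samples
    is_carrier = rng.random(n) < config.prevalence
    cf = np.where(is_carrier, rng.uniform(config.cf_low, config.cf_high, size=n), 0.0)

    batch_ids = ["batch0"]
    chry_factor = np.ones(n)
    if config.batch_shifts:
        batch_ids = list(config.batch_shifts)
        assignment = np.arange(n) % len(batch_ids)
        chry_factor = np.array([config.batch_shifts[batch_ids[j]] for j in assignment])
        batch_col = [batch_ids[j] for j in assignment]
    else:
        batch_col = ["batch0"] * n

    trend_y = gc_trend(np.array([r.gc for r in chry_exons]), config.gc_bias)
    trend_a = gc_trend(np.array([gc_by_id[a] for a in auto_ids]), config.gc_bias)
    mu_a = config.mean_depth * np.broadcast_to(trend_a, (n, len(auto_ids))).copy()
    mu_y = (0.5 * (1 - cf) * chry_factor)[:, None] * (config.mean_depth * trend_y)[None, :]
    mu = np.concatenate([mu_y, mu_a], axis=1)

    if not config.noise:
        depth = mu
    elif config.overdispersion == 0:
        depth = rng.poisson(mu).astype(float)
    else:
        r = 1.0 / config.overdispersion
        depth = rng.negative_binomial(r, r / (r + mu)).astype(float)

    samples = [f"S{i:04d}" for i in range(n)]
    df = pd.DataFrame(depth, index=pd.Index(samples, name="sample_id"),
                      columns=chry_ids + list(auto_ids))
    truth = pd.DataFrame(
        {"is_mloy_true": is_carrier, "cf_true": cf, "batch": batch_col},
        index=pd.Index(samples, name="sample_id"),
    )
    table = CoverageTable(depth=df, kit_id="synthetic", source="native")
    return table, truth


class SimStudy(NamedTuple):
    chry_exons: list[ExonRecord]
    autosomal_exons: list[ExonRecord]
    matches: MatchTable
    coverage: CoverageTable
    truth: pd.DataFrame


def simulate_study(
    config: SimConfig | None = None,
    k: int = 100,
    n_genes: int = 13,
    exons_per_gene: int = 13,
    n_candidates: int = 25_000,
) -> SimStudy:
    """Panel + propensity matching + cohort in one call.

    Runs the real matcher on the synthetic panel, so the generated study
    exercises the same code path as a real one.
    """
    config = config or SimConfig()
    chry, candidates = simulate_panel(
        seed=config.seed, n_genes=n_genes, exons_per_gene=exons_per_gene,
        n_candidates=n_candidates,
    )
    matches = match_autosomal_exons(chry, candidates, k=k, seed=config.seed)
    coverage, truth = simulate_cohort(chry, candidates, matches, config)
    return SimStudy(chry, candidates, matches, coverage, truth)


# ---------------------------------------------------------------------------
# Miniature alignment fixtures


def _write_reference(panel: Sequence[ExonRecord], out_dir: Path, rng,
                     pad: int = 200) -> Path:
    lengths: dict[str, int] = {}
    for r in panel:
        lengths[r.chrom] = max(lengths.get(r.chrom, 0), r.end + pad)
    ref_path = out_dir / "reference.fa"
    bases = np.array(list("ACGT"))
    with open(ref_path, "w") as fh:
        for chrom, ln in lengths.items():
            fh.write(f">{chrom}\n")
            seq = "".join(rng.choice(bases, size=ln))
            for i in range(0, ln, 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(ref_path))
    return ref_path


def emit_fixture_alignments(
    panel: Sequence[ExonRecord],
    target_depths: Mapping[str, Mapping[str, float]],
    out_dir: str | Path,
    read_length: int = 100,
    uniform: bool = True,
    seed: int = 0,
) -> dict:
    """Write a miniature reference and per-sample sorted, indexed BAMs.

    ``target_depths`` maps sample id -> exon id -> target median depth.
    With ``uniform=True`` each exon gets round(depth) reads spanning it
    exactly, so the per-base depth is the target everywhere; otherwise
    reads of ``read_length`` are placed at Poisson-random positions at a
    rate giving the target depth in expectation.  An exon with target 0
    receives no reads.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ref_path = _write_reference(panel, out_dir, rng)
    contigs: dict[str, int] = {}
    with pysam.FastaFile(str(ref_path)) as fa:
        for name in fa.references:
            contigs[name] = fa.get_reference_length(name)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in contigs.items()],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    by_id = {r.exon_id: r for r in panel}

    alignments: dict[str, Path] = {}
    for sample, depths in target_depths.items():
        reads: list[tuple[int, int, int]] = []  # (tid, pos, length)
        for exon_id, depth in depths.items():
            iv = by_id[exon_id]
            if depth <= 0:
                continue
            if uniform:
                for _ in range(int(round(depth))):
                    reads.append((tid[iv.chrom], iv.start, iv.length))
            else:
                span = iv.length + read_length - 1
                n_reads = rng.poisson(depth * span / read_length)
                lo = max(0, iv.start - read_length + 1)
                starts = rng.integers(lo, iv.end, size=n_reads)
                for s in starts:
                    ln = min(read_length, contigs[iv.chrom] - s)
                    reads.append((tid[iv.chrom], int(s), int(ln)))
        reads.sort()
        bam_path = out_dir / f"{sample}.bam"
        with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
            for i, (t, pos, ln) in enumerate(reads):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"{sample}_r{i}"
                a.query_sequence = "A" * ln
                a.query_qualities = pysam.qualitystring_to_array("I" * ln)
                a.reference_id = t
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{ln}M"
                a.flag = 0
                bam.write(a)
        pysam.index(str(bam_path))
        alignments[sample] = bam_path
    return {"reference": ref_path, "alignments": alignments}
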