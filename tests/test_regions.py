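"""Panel construction, GC annotation, CNV filtering and propensity matching."""

import numpy as np
import pytest

from moscovery import (
    ExonRecord,
    GenePanel,
    MatchTable,
    compute_exon_gc,
    filter_cnv_prone,
    filter_outlier_exons,
    match_autosomal_exons,
    select_chry_exons,
)
from moscovery.errors import (
    CapacityError,
    CohortSizeError,
    CoordinateError,
    MissingContigError,
    PanelMismatchError,
)
from moscovery.regions import _propensity_scores, read_bed, write_bed

import pandas as pd


def exon(chrom="chr1", start=0, end=100, gene=".", gc=0.5):
    return ExonRecord(chrom=chrom, start=start, end=end, gene=gene, gc=gc)


# ---------------------------------------------------------------------------
# ExonRecord / GenePanel


def test_exon_record_invariants():
    r = exon(start=10, end=60)
    assert r.length == 50
    with pytest.raises(CoordinateError):
        ExonRecord(chrom="chr1", start=60, end=60)
    with pytest.raises(ValueError):
        ExonRecord(chrom="chr1", start=0, end=10, gc=1.5)


def test_default_gene_panel_is_the_13_single_copy_genes():
    panel = GenePanel()
    assert len(panel.genes) == 13
    assert "USP9Y" in panel and "RBMY1A1" not in panel


# ---------------------------------------------------------------------------
# GC computation


@pytest.fixture()
def tiny_fasta(tmp_path):
    # chr1: GGCC ATAT ATGCGCATTANN + padding A's
    path = tmp_path / "ref.fa"
    path.write_text(">chr1\nGGCCATATATGCGCATTANNAAAAAAAAAA\n>chrM\nNNNN\n")
    return path


@pytest.mark.parametrize(
    "start, end, expected",
    [
        (0, 4, 1.0),    # GGCC
        (4, 8, 0.0),    # ATAT
        # ATGCGCATTANN: 4 G/C among 10 unambiguous bases (hand count)
        (8, 20, 0.4),
    ],
)
def test_compute_exon_gc(tiny_fasta, start, end, expected):
    (rec,) = compute_exon_gc(tiny_fasta, [ExonRecord("chr1", start, end)])
    assert rec.gc == pytest.approx(expected)


def test_compute_exon_gc_n_handling_and_errors(tiny_fasta):
    (rec,) = compute_exon_gc(tiny_fasta, [ExonRecord("chr1", 16, 20)])  # TANN
    assert rec.n_frac == pytest.approx(0.5)
    (allN,) = compute_exon_gc(tiny_fasta, [ExonRecord("chrM", 0, 4)])
    assert np.isnan(allN.gc)
    with pytest.raises(CoordinateError):
        compute_exon_gc(tiny_fasta, [ExonRecord("chr1", 25, 40)])
    with pytest.raises(MissingContigError):
        compute_exon_gc(tiny_fasta, [ExonRecord("chr9", 0, 4)])


# ---------------------------------------------------------------------------
# chrY exon selection


def test_select_chry_exons_membership_dedup_sort():
    exons = [
        exon("chrY", 500, 600, "USP9Y"),
        exon("chrY", 100, 200, "USP9Y"),
        exon("chrY", 100, 200, "USP9Y"),   # duplicate coordinates
        exon("chrY", 300, 400, "RBMY1A1"),  # ampliconic, excluded
    ]
    kept = select_chry_exons(exons)
    assert [(r.start, r.end) for r in kept] == [(100, 200), (500, 600)]


def test_select_chry_exons_counts_by_construction():
    genes = ["SRY", "UTY", "KDM5D", "DDX3Y"] + ["RBMY1A1", "TSPY1", "XKRY"] * 2
    exons = [exon("chrY", 1000 * i, 1000 * i + 100, g) for i, g in enumerate(genes)]
    assert len(select_chry_exons(exons)) == 4


def test_select_chry_exons_empty_is_error():
    with pytest.raises(PanelMismatchError):
        select_chry_exons([exon("chrY", 0, 100, "TSPY1")])


# ---------------------------------------------------------------------------
# CNV-prone filtering


def test_filter_cnv_prone_threshold_and_missing():
    e9, e10 = exon(start=0, end=100), exon(start=200, end=300)
    counts = {e9.exon_id: 9, e10.exon_id: 10}
    kept = filter_cnv_prone([e9, e10], counts)
    assert kept == [e9]
    # a missing count means no events were recorded: eligible
    assert filter_cnv_prone([e9], {}) == [e9]
    assert filter_cnv_prone([], {}) == []


def test_filter_cnv_prone_count_subset_idempotent():
    exons = [exon(start=1000 * i, end=1000 * i + 100) for i in range(50)]
    counts = {r.exon_id: i for i, r in enumerate(exons)}
    kept = filter_cnv_prone(exons, counts)
    assert len(kept) == 10
    assert set(r.exon_id for r in kept) <= set(r.exon_id for r in exons)
    assert filter_cnv_prone(kept, counts) == kept


# ---------------------------------------------------------------------------
# Propensity matching


def test_matching_zero_distance_candidates_win():
    y = exon("chrY", 0, 200, "UTY", gc=0.5)
    identical = [exon("chr2", 1000 * i, 1000 * i + 200, gc=0.5) for i in range(3)]
    decoys = [exon("chr3", 10_000 * i, 10_000 * i + 2000, gc=0.9) for i in range(1, 6)]
    table = match_autosomal_exons([y], identical + decoys, k=3)
    assert set(table.entries[y.exon_id]) == {r.exon_id for r in identical}


def test_matching_agrees_with_exhaustive_pair_enumeration():
    """k=2 selection equals the pair minimizing total propensity distance."""
    from itertools import combinations

    y = exon("chrY", 0, 200, "UTY", gc=0.5)
    gcs = [0.50, 0.51, 0.30, 0.80, 0.49]
    cands = [exon("chr5", 1000 * i, 1000 * i + 200, gc=g) for i, g in enumerate(gcs)]
    table = match_autosomal_exons([y], cands, k=2)
    lp_y, lp_c = _propensity_scores([y], cands)
    best = min(
        combinations(range(5), 2),
        key=lambda pair: sum(abs(lp_c[j] - lp_y[0]) for j in pair),
    )
    assert set(table.entries[y.exon_id]) == {cands[j].exon_id for j in best}


def test_matching_k_without_replacement_and_capacity():
    rng = np.random.default_rng(3)
    ys = [exon("chrY", 1000 * i, 1000 * i + 150, "ZFY", gc=g)
          for i, g in enumerate(rng.uniform(0.35, 0.55, 5))]
    cands = [exon(f"chr{1 + i % 22}", 10_000 + 1000 * i, 10_000 + 1000 * i + 150, gc=g)
             for i, g in enumerate(rng.uniform(0.3, 0.6, 60))]
    table = match_autosomal_exons(ys, cands, k=10)
    all_matched = [a for v in table.entries.values() for a in v]
    assert all(len(v) == 10 for v in table.entries.values())
    assert len(all_matched) == len(set(all_matched))  # without replacement
    with pytest.raises(CapacityError):
        match_autosomal_exons(ys, cands[:40], k=10)


def test_matching_excludes_sex_chromosome_candidates():
    y = exon("chrY", 0, 200, "UTY", gc=0.5)
    good = [exon("chr2", 1000 * i, 1000 * i + 200, gc=0.5) for i in range(2)]
    bad = [exon("chrX", 0, 200, gc=0.5), exon("chrY", 5000, 5200, gc=0.5),
           exon("chr1_KI270706v1_random", 0, 200, gc=0.5)]
    table = match_autosomal_exons([y], good + bad, k=2)
    assert set(table.entries[y.exon_id]) == {r.exon_id for r in good}


def test_matching_deterministic(small_study):
    a = match_autosomal_exons(small_study.chry_exons, small_study.autosomal_exons, k=5, seed=1)
    b = match_autosomal_exons(small_study.chry_exons, small_study.autosomal_exons, k=5, seed=1)
    assert a.entries == b.entries


def test_matching_balances_gc_better_than_random(small_study):
    """Mean |gc_match - gc_chrY| is strictly smaller than for random picks."""
    gc_by_id = {r.exon_id: r.gc for r in small_study.autosomal_exons}
    rng = np.random.default_rng(0)
    pool = [r.exon_id for r in small_study.autosomal_exons]
    matched_err, random_err = [], []
    for y in small_study.chry_exons:
        m = small_study.matches.entries[y.exon_id]
        matched_err.append(np.mean([abs(gc_by_id[a] - y.gc) for a in m]))
        for _ in range(20):
            r = rng.choice(pool, size=len(m), replace=False)
            random_err.append(np.mean([abs(gc_by_id[a] - y.gc) for a in r]))
    assert np.mean(matched_err) < np.mean(random_err)


# ---------------------------------------------------------------------------
# Outlier-exon filtering


def _reference_coverage(chry, n_samples=25, depth=40.0, outlier_id=None, factor=10.0):
    """Reference (mLOY-free) cohort: each exon has its own capture-efficiency
    factor (uniform within +/-10%), well inside the 1.5xIQR fence, plus small
    sampling noise; the designated outlier exon sits at 10x."""
    rng = np.random.default_rng(5)
    auto_cols = {f"chr1:{i}-{i+100}": depth * 2 for i in range(0, 5000, 100)}
    efficiency = {r.exon_id: rng.uniform(0.9, 1.1) for r in chry}
    rows = []
    for _ in range(n_samples):
        row = dict(auto_cols)
        for r in chry:
            scale = factor if r.exon_id == outlier_id else efficiency[r.exon_id]
            row[r.exon_id] = depth * scale + rng.normal(0, 0.3)
        rows.append(row)
    return pd.DataFrame(rows, index=[f"S{i}" for i in range(n_samples)])


def test_filter_outlier_exons_identical_distributions_all_kept():
    chry = [exon("chrY", 1000 * i, 1000 * i + 100, "UTY", gc=0.5) for i in range(20)]
    df = _reference_coverage(chry, factor=1.0)
    df[[r.exon_id for r in chry]] = 40.0  # exactly identical chrY coverage
    assert len(filter_outlier_exons(df, chry)) == 20


def test_filter_outlier_exons_removes_10x_exon():
    chry = [exon("chrY", 1000 * i, 1000 * i + 100, "UTY", gc=0.5) for i in range(20)]
    bad = chry[7].exon_id
    df = _reference_coverage(chry, outlier_id=bad)
    kept = filter_outlier_exons(df, chry)
    assert bad not in {r.exon_id for r in kept}
    assert len(kept) == 19


def test_filter_outlier_exons_needs_reference_samples():
    chry = [exon("chrY", 0, 100, "UTY", gc=0.5)]
    df = _reference_coverage(chry, n_samples=5)
    with pytest.raises(CohortSizeError):
        filter_outlier_exons(df, chry, min_reference_samples=20)


# ---------------------------------------------------------------------------
# Serialization


def test_bed_round_trip(tmp_path):
    exons = [exon("chrY", 100, 250, "UTY"), exon("chrY", 400, 500, "SRY")]
    path = tmp_path / "panel.bed"
    write_bed(exons, path)
    back = read_bed(path)
    assert [(r.chrom, r.start, r.end, r.gene) for r in back] == [
        ("chrY", 100, 250, "UTY"), ("chrY", 400, 500, "SRY")
    ]


def test_match_table_round_trip(tmp_path, small_study):
    path = tmp_path / "matches.tsv"
    small_study.matches.write_tsv(path, header_lines=["unit test"])
    back = MatchTable.read_tsv(path)
    assert back.k == small_study.matches.k
    assert back.entries == small_study.matches.entries


def test_match_table_enforces_k():
    with pytest.raises(ValueError):
        MatchTable(entries={"chrY:0-100": ["chr1:0-100"]}, k=2)
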