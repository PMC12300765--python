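"""Per-chromosome burden statistics, relative score and aggregation."""

import pytest
from hypothesis import given, settings, strategies as st

from roifuse import (
    ChromosomePlan,
    ChromosomeReference,
    MutationTableSpec,
    VariantRecord,
    apply_hard_filters,
    chromosome_stats,
    class_median_summary,
    export_aggregate,
    gen_mutation_table,
    load_reference,
    read_aggregate,
    relative_mutation_score,
    summarize_roi,
    top_mutated_genes,
)
from roifuse.burden import ChromosomeStat


def _rec(chrom, gene, pos=1):
    return VariantRecord(roi_id="r", chromosome=chrom, position=pos,
                         gene_symbol=gene, variant_class="SNP", qual=30, depth=50)


REF = [ChromosomeReference("1", 3000, 2), ChromosomeReference("X", 1400, 1)]


def test_chromosome_stats_diploid_formulas():
    # 6 mutations over 2 distinct genes on chr1 (N=3000, c=2)
    recs = [_rec("1", "A", i) for i in range(1, 4)] + [_rec("1", "B", i) for i in range(4, 7)]
    s = {st.chromosome: st for st in chromosome_stats(recs, REF)}["1"]
    assert (s.total_mutations, s.affected_distinct_genes) == (6, 2)
    assert s.proportion_mutated == pytest.approx((2 * 2) / (3000 * 2))
    assert s.mean_mutations_per_gene == pytest.approx(6 / (2 * 2))


def test_chromosome_stats_haploid_branch():
    recs = [_rec("X", "AR", i) for i in range(1, 4)]
    s = {st.chromosome: st for st in chromosome_stats(recs, REF)}["X"]
    assert s.proportion_mutated == pytest.approx(1 / 1400)
    assert s.mean_mutations_per_gene == pytest.approx(3.0)


def test_chromosome_stats_empty_and_zero_fill():
    stats = chromosome_stats([], REF)
    assert len(stats) == 2
    assert all(s.total_mutations == 0 and s.proportion_mutated == 0.0
               and s.mean_mutations_per_gene == 0.0 for s in stats)


def test_chromosome_stats_unknown_chromosome():
    with pytest.raises(KeyError, match="17"):
        chromosome_stats([_rec("17", "TP53")], REF)


def test_missing_gene_symbol_counts_in_m_not_g(caplog):
    recs = [_rec("1", "A"), _rec("1", "", 2)]
    with caplog.at_level("WARNING"):
        s = chromosome_stats(recs, REF)[0]
    assert (s.total_mutations, s.affected_distinct_genes) == (2, 1)


def test_autosome_copy_number_cancels_in_p():
    # p = (g*2)/(N*2) must equal g/N exactly for autosomes
    recs = [_rec("1", f"G{i}", i + 1) for i in range(7)]
    s = chromosome_stats(recs, REF)[0]
    assert s.proportion_mutated == 7 / 3000


# ---------------------------------------------------------------------------
# Relative mutation score
# ---------------------------------------------------------------------------

def _stat(m, g):
    c = 2
    return ChromosomeStat("1", m, g, g / 3000 if g else 0.0, m / (g * c) if g else 0.0)


@pytest.mark.parametrize("m,g,expected", [
    (50, 50, 0.0),     # every mutation on a distinct gene
    (10, 4, 0.6),
    (100, 1, 0.99),    # all mutations on one gene: (m-1)/m
])
def test_relative_score_anchors(m, g, expected):
    assert relative_mutation_score([_stat(m, g)]) == pytest.approx(expected)


def test_relative_score_empty_convention():
    assert relative_mutation_score([_stat(0, 0)]) == 0.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 50).flatmap(
    lambda m: st.tuples(st.just(m), st.integers(1, 50).map(lambda g: min(g, m)))),
    min_size=1, max_size=24))
def test_relative_score_bounded(mg):
    stats = [_stat(m, g) for m, g in mg]
    score = relative_mutation_score(stats)
    assert 0.0 <= score <= 1.0
    if all(m == g for m, g in mg):
        assert score == 0.0


# ---------------------------------------------------------------------------
# Top genes
# ---------------------------------------------------------------------------

def _gene_records(counts):
    recs = []
    pos = 1
    for sym, n in counts.items():
        for _ in range(n):
            recs.append(_rec("1", sym, pos))
            pos += 1
    return recs


def test_top_genes_rank_and_tiebreak():
    recs = _gene_records({"TP53": 5, "KRAS": 3, "APC": 3, "TTN": 1})
    top = top_mutated_genes(recs, panel=None, k=3)
    assert [g.symbol for g in top] == ["TP53", "APC", "KRAS"]  # ties alphabetical
    assert top[0].count == 5 and len(top[0].variant_types) == 5


def test_top_genes_panel_restriction():
    recs = _gene_records({"TP53": 5, "KRAS": 3, "APC": 3, "TTN": 1})
    top = top_mutated_genes(recs, panel={"APC", "KRAS", "TTN"}, k=3)
    assert [g.symbol for g in top] == ["APC", "KRAS", "TTN"]


def test_top_genes_empty():
    assert top_mutated_genes([], panel=None, k=5) == []


# ---------------------------------------------------------------------------
# Class medians
# ---------------------------------------------------------------------------

def _summary_with_p(roi, p_values, reference):
    stats = tuple(
        ChromosomeStat(r.chromosome, 1, 1, p, 1.0) for r, p in zip(reference, p_values)
    )
    from roifuse.burden import ROISummary
    return ROISummary(roi_id=roi, per_chromosome=stats,
                      total_mutations=len(stats), total_affected_genes=len(stats),
                      relative_mutation_score=0.0)


def test_class_median_odd_even_single(reference_compat):
    n = len(reference_compat)
    s1 = _summary_with_p("a", [0.1] * n, reference_compat)
    s2 = _summary_with_p("b", [0.2] * n, reference_compat)
    s3 = _summary_with_p("c", [0.9] * n, reference_compat)
    assert class_median_summary([s1, s2, s3], "carcinoma").median_proportion[0] == 0.2
    s4 = _summary_with_p("d", [0.3] * n, reference_compat)
    assert class_median_summary([s1, s4], "native").median_proportion[0] == pytest.approx(0.2)
    single = class_median_summary([s1], "normal")
    assert single.median_proportion == tuple([0.1] * n) and single.n_rois == 1


def test_class_median_requires_input():
    with pytest.raises(ValueError):
        class_median_summary([], "normal")


def test_median_bounded_by_extremes(reference_compat):
    import numpy as np
    rng = np.random.default_rng(7)
    summaries = [_summary_with_p(f"r{i}", rng.uniform(0, 1, len(reference_compat)), reference_compat)
                 for i in range(5)]
    cs = class_median_summary(summaries, "native")
    p = np.array([[s.proportion_mutated for s in summ.per_chromosome] for summ in summaries])
    assert np.all(cs.median_proportion >= p.min(axis=0)) and np.all(cs.median_proportion <= p.max(axis=0))


# ---------------------------------------------------------------------------
# Aggregate export
# ---------------------------------------------------------------------------

def test_export_layout_and_roundtrip(tmp_path, reference):
    plan = tuple(ChromosomePlan(r.chromosome, n_genes=2, mutations_per_gene=3)
                 for r in reference)
    summaries = []
    for i in range(2):
        records, _ = gen_mutation_table(MutationTableSpec(plan=plan, seed=i, roi_id=f"roi{i}"))
        summaries.append(summarize_roi(records, reference, roi_id=f"roi{i}"))
    cs = class_median_summary(summaries, "carcinoma")
    out = tmp_path / "agg.tsv"
    export_aggregate(summaries, [cs], out)

    df = read_aggregate(out)
    assert len(df) == len(reference) == 24
    assert df.shape[1] == 2 * 4 + 2
    # bit-identical round trip of every statistic
    for summ in summaries:
        for s in summ.per_chromosome:
            assert df.loc[s.chromosome, f"{summ.roi_id}_p"] == s.proportion_mutated
            assert df.loc[s.chromosome, f"{summ.roi_id}_d"] == s.mean_mutations_per_gene
            assert df.loc[s.chromosome, f"{summ.roi_id}_m"] == s.total_mutations


def test_export_empty_is_header_only(tmp_path):
    out = tmp_path / "empty.tsv"
    export_aggregate([], [], out)
    assert out.read_text() == "chromosome\n"


# ---------------------------------------------------------------------------
# Conservation and generator round trip
# ---------------------------------------------------------------------------

def test_total_mutations_conserved(reference):
    plan = (ChromosomePlan("1", 3, (1, 2, 3)), ChromosomePlan("X", 2, 4))
    records, truth = gen_mutation_table(MutationTableSpec(plan=plan, seed=5))
    retained = apply_hard_filters(records).retained
    assert len(retained) == len(records)  # generator draws above thresholds
    summ = summarize_roi(retained, reference)
    assert summ.total_mutations == len(retained) == sum(m for m, _ in truth.values())
    by_chrom = {s.chromosome: s for s in summ.per_chromosome}
    for chrom, (m, g) in truth.items():
        assert (by_chrom[chrom].total_mutations, by_chrom[chrom].affected_distinct_genes) == (m, g)
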