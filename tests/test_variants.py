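"""Variant parsing and hard-filter behavior."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from roifuse import (
    FilterThresholds,
    VariantRecord,
    apply_hard_filters,
    gen_vcf,
    normalize_chromosome,
    parse_mutation_table,
    parse_vcf,
    qual_from_posterior,
)
from roifuse.variants import (
    BASE_QUALITY_FILTER,
    INDEL_QUAL_FILTER,
    LOD_FILTER,
    LOW_DEPTH_FILTER,
    PLOIDY_FILTER,
    SNP_QUAL_FILTER,
    SchemaError,
)


def _rec(**kw):
    base = dict(roi_id="r", chromosome="1", position=100, gene_symbol="APC",
                variant_class="SNP", qual=30.0, depth=50)
    base.update(kw)
    return VariantRecord(**base)


# ---------------------------------------------------------------------------
# TSV parsing
# ---------------------------------------------------------------------------

TSV = """chromosome\tposition\tgene_symbol\tvariant_class\tqual\tdepth
chr1\t100\tAPC\tSNP\t30\t50
chr2\t200\tTP53\tINDEL\t12\t40
chrX\t300\tAR\tSNP\t45\t60
"""


def test_parse_mutation_table_identity(tmp_path):
    p = tmp_path / "roi1.tsv"
    p.write_text(TSV)
    records = parse_mutation_table(p)
    assert len(records) == 3
    assert [r.chromosome for r in records] == ["1", "2", "X"]  # chr prefix stripped
    assert records[0].roi_id == "roi1"  # defaults to file stem
    assert records[1].variant_class == "INDEL"


def test_parse_mutation_table_skips_bad_rows(tmp_path, caplog):
    p = tmp_path / "roi.tsv"
    p.write_text(TSV + "chr3\tnot_a_number\tKRAS\tSNP\t20\t30\n")
    with caplog.at_level("WARNING"):
        records = parse_mutation_table(p)
    assert len(records) == 3
    assert any("skipping row" in m for m in caplog.messages)


def test_parse_mutation_table_missing_column(tmp_path):
    p = tmp_path / "roi.tsv"
    p.write_text("chromosome\tposition\tgene_symbol\n1\t1\tAPC\n")
    with pytest.raises(SchemaError, match="variant_class"):
        parse_mutation_table(p)


def test_parse_mutation_table_dialect(tmp_path):
    p = tmp_path / "roi.tsv"
    p.write_text("Chrom\tPos\tHUGO\tVarType\nchr7\t55\tEGFR\tsnp\n")
    recs = parse_mutation_table(p, dialect={
        "chromosome": "Chrom", "position": "Pos",
        "gene_symbol": "HUGO", "variant_class": "VarType"})
    assert recs[0].chromosome == "7" and recs[0].variant_class == "SNP"


@pytest.mark.parametrize("raw,expected", [
    ("chr1", "1"), ("chrM", "MT"), ("M", "MT"), ("x", "X"), ("22", "22"),
])
def test_normalize_chromosome(raw, expected):
    assert normalize_chromosome(raw) == expected


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------

def test_parse_vcf_variant_class_and_roundtrip(tmp_path):
    path = tmp_path / "s.vcf"
    quals = [5.0, 10.41, 25.0]
    dps = [1, 30, 12]
    classes = ["SNP", "INDEL", "SNP"]
    gen_vcf(quals, dps, classes, path, chroms=["1", "2", "MT"], lods=[None, None, 7.0])
    recs = parse_vcf(path)
    assert [r.variant_class for r in recs] == classes  # REF/ALT length rule
    assert [r.qual for r in recs] == quals
    assert [r.depth for r in recs] == dps
    assert recs[2].chromosome == "MT" and recs[2].lod == 7.0


def test_parse_vcf_empty_body(tmp_path):
    path = tmp_path / "e.vcf"
    gen_vcf([], [], [], path)
    assert parse_vcf(path) == []


# ---------------------------------------------------------------------------
# Phred transform
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,expected", [(1.0, 0.0), (0.1, 10.0), (1e-5, 50.0)])
def test_qual_from_posterior(p, expected):
    assert qual_from_posterior(p) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [0.0, -0.5, 1.0001])
def test_qual_from_posterior_domain(bad):
    with pytest.raises(ValueError):
        qual_from_posterior(bad)


# ---------------------------------------------------------------------------
# Hard filters
# ---------------------------------------------------------------------------

def _removed_reasons(report):
    return {(r.position, rs) for r, rs in report.removed}


def test_snp_qual_boundary():
    rep = apply_hard_filters([_rec(qual=10.40), _rec(position=101, qual=10.41)])
    assert len(rep.retained) == 1 and rep.retained[0].qual == 10.41
    assert _removed_reasons(rep) == {(100, (SNP_QUAL_FILTER,))}


def test_indel_qual_boundary():
    rep = apply_hard_filters([
        _rec(variant_class="INDEL", qual=7.82),
        _rec(position=101, variant_class="INDEL", qual=7.83),
    ])
    assert len(rep.retained) == 1
    assert _removed_reasons(rep) == {(100, (INDEL_QUAL_FILTER,))}


def test_low_depth_is_inclusive_at_one():
    rep = apply_hard_filters([_rec(depth=1), _rec(position=101, depth=2)])
    assert _removed_reasons(rep) == {(100, (LOW_DEPTH_FILTER,))}


def test_mitochondrial_lod_does_not_exceed():
    rep = apply_hard_filters([
        _rec(chromosome="MT", lod=6.3),
        _rec(position=101, chromosome="MT", lod=6.31),
    ])
    assert _removed_reasons(rep) == {(100, (LOD_FILTER,))}


def test_lod_ignored_off_mitochondria():
    rep = apply_hard_filters([_rec(chromosome="1", lod=0.0)])
    assert len(rep.retained) == 1


def test_base_quality_rule_and_absent_field_passes():
    rep = apply_hard_filters([
        _rec(median_base_quality=19.9),
        _rec(position=101, median_base_quality=20.0),
        _rec(position=102),  # field absent -> rule passes
    ])
    assert len(rep.retained) == 2
    assert _removed_reasons(rep) == {(100, (BASE_QUALITY_FILTER,))}


def test_ploidy_conflict_genotype_arity():
    rep = apply_hard_filters([
        _rec(chromosome="Y", genotype="0/1"),   # diploid call on haploid Y
        _rec(position=101, chromosome="Y", genotype="1"),
        _rec(position=102, chromosome="1", genotype="0/1"),
    ])
    assert _removed_reasons(rep) == {(100, (PLOIDY_FILTER,))}


def test_multiple_reasons_all_recorded():
    rep = apply_hard_filters([_rec(qual=1.0, depth=0, median_base_quality=5.0)])
    (_, reasons), = rep.removed
    assert set(reasons) == {SNP_QUAL_FILTER, LOW_DEPTH_FILTER, BASE_QUALITY_FILTER}


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(
    st.sampled_from(["SNP", "INDEL"]),
    st.floats(0, 60, allow_nan=False),
    st.integers(0, 100),
), max_size=30), st.randoms(use_true_random=False))
def test_partition_and_order_invariance(rows, rnd):
    recs = [_rec(position=i + 1, variant_class=vc, qual=q, depth=dp)
            for i, (vc, q, dp) in enumerate(rows)]
    rep = apply_hard_filters(recs)
    # partition: every input in exactly one list
    assert rep.n_input == len(recs)
    kept = {r.position for r in rep.retained}
    gone = {r.position for r, _ in rep.removed}
    assert kept | gone == {r.position for r in recs} and not (kept & gone)
    # shuffling the input yields the same sets
    shuffled = recs[:]
    rnd.shuffle(shuffled)
    rep2 = apply_hard_filters(shuffled)
    assert {r.position for r in rep2.retained} == kept


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(0, 40, allow_nan=False), st.floats(0, 40, allow_nan=False))
def test_retained_monotone_in_snp_threshold(t1, t2):
    lo, hi = sorted([t1, t2])
    recs = [_rec(position=i + 1, qual=q) for i, q in enumerate(np.linspace(0, 40, 41))]
    n_lo = len(apply_hard_filters(recs, FilterThresholds(snp_qual_min=lo)).retained)
    n_hi = len(apply_hard_filters(recs, FilterThresholds(snp_qual_min=hi)).retained)
    assert n_hi <= n_lo


def test_qual_sweep_recovers_cutoffs(tmp_path):
    """A 0.01-step QUAL grid is cut exactly at 10.41 (SNP) / 7.83 (INDEL)."""
    quals = [round(q, 2) for q in np.arange(0.0, 20.0, 0.01)]
    for vclass, cutoff in (("SNP", 10.41), ("INDEL", 7.83)):
        path = tmp_path / f"{vclass}.vcf"
        gen_vcf(quals, [30] * len(quals), [vclass] * len(quals), path)
        rep = apply_hard_filters(parse_vcf(path))
        retained_quals = sorted(r.qual for r in rep.retained)
        assert min(retained_quals) == pytest.approx(cutoff)
        assert max(r.qual for r, _ in rep.removed) == pytest.approx(cutoff - 0.01)


def test_depth_sweep_recovers_boundary(tmp_path):
    path = tmp_path / "dp.vcf"
    dps = list(range(0, 11))
    gen_vcf([30.0] * 11, dps, ["SNP"] * 11, path)
    rep = apply_hard_filters(parse_vcf(path))
    assert sorted(r.depth for r, _ in rep.removed) == [0, 1]
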