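"""Per-chromosome mutation-burden statistics and the relative mutation score.

For each sequenced ROI (a laser-microdissected cell or cell cluster),
retained variant calls are aggregated per chromosome into:

* ``m_i`` — total gene mutations on chromosome i,
* ``g_i`` — distinct affected genes on chromosome i,
* ``p_i`` — proportion of mutated genes, (g_i * c_i) / (N_i * c_i),
  where N_i is the approximate gene count of the chromosome and c_i its
  copy number (autosomes 2; X and Y in a male sample 1),
* ``d_i`` — approximate mean mutations per gene, m_i / (g_i * c_i).

The copy-number factor reflects that short-read sequencing reports the
chromosome *type* carrying a mutation, not which homolog: assuming both
homologs are equally likely to be hit, the distinct-gene count is
doubled on diploid chromosomes, and the doubling cancels in p_i but not
in d_i.

Across the chromosomes of one ROI, the relative mutation score

    C_rel = (sum_i m_i - sum_i g_i) / sum_i m_i

is 0 when every mutation hits a distinct gene and approaches 1 as
mutations concentrate on few genes; it drives the green-yellow-red
heatmap. ROIs of one tumor class (normal / native / carcinoma) are
aggregated with medians, which are robust to occasional mislabeled
cells in pathologist-assigned classes.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .variants import VariantRecord

logger = logging.getLogger(__name__)

#: chromosome index set used by the original aggregation (no 22, no MT)
PAPER_COMPAT_CHROMOSOMES = tuple(str(i) for i in range(1, 22)) + ("X", "Y")


@dataclass(frozen=True)
class ChromosomeReference:
    """Approximate gene content and copy number of one chromosome."""

    chromosome: str
    approx_gene_count: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.approx_gene_count <= 0:
            raise ValueError("approx_gene_count must be > 0")
        if self.copy_number not in (1, 2):
            raise ValueError("copy_number must be 1 or 2")


def load_reference(path: Optional[str | Path] = None, paper_compat: bool = False) -> list[ChromosomeReference]:
    """Load the chromosome gene-count reference table.

    Without ``path`` the packaged table is used (male karyotype: X and Y
    haploid). With ``paper_compat=True`` the set is restricted to
    chromosomes 1-21, X, Y — the index set of the original aggregation,
    which omits chromosome 22.
    """
    if path is None:
        src = importlib.resources.files("roifuse").joinpath("data/chromosome_genes.tsv")
        with importlib.resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", dtype={"chromosome": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    refs = [
        ChromosomeReference(str(r.chromosome), int(r.gene_count), int(r.copy_number))
        for r in df.itertuples()
    ]
    if paper_compat:
        refs = [r for r in refs if r.chromosome in PAPER_COMPAT_CHROMOSOMES]
    return refs


@dataclass(frozen=True)
class ChromosomeStat:
    """Burden statistics of one chromosome within one ROI."""

    chromosome: str
    total_mutations: int
    affected_distinct_genes: int
    proportion_mutated: float
    mean_mutations_per_gene: float

    def __post_init__(self) -> None:
        if not 0 <= self.affected_distinct_genes <= max(self.total_mutations, 0) and self.total_mutations > 0:
            raise ValueError("affected_distinct_genes must lie in [0, total_mutations]")


@dataclass(frozen=True)
class TopGene:
    """One entry of the ranked most-mutated-gene list."""

    symbol: str
    count: int
    variant_types: tuple[str, ...]
    pathways: tuple[str, ...] = ()
    drugs: tuple[str, ...] = ()
    annotated: bool = False


@dataclass(frozen=True)
class ROISummary:
    """Chromosome-level burden and derived scores for one ROI."""

    roi_id: str
    per_chromosome: tuple[ChromosomeStat, ...]
    total_mutations: int
    total_affected_genes: int
    relative_mutation_score: float
    top_genes: tuple[TopGene, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_mutation_score <= 1.0:
            raise ValueError("relative_mutation_score must be in [0, 1]")


@dataclass(frozen=True)
class ClassSummary:
    """Median burden per chromosome over the ROIs of one tumor class."""

    tumor_class: str
    chromosomes: tuple[str, ...]
    median_proportion: tuple[float, ...]
    median_mutations_per_gene: tuple[float, ...]
    n_rois: int


def chromosome_stats(
    records: Sequence[VariantRecord],
    reference: Sequence[ChromosomeReference],
) -> list[ChromosomeStat]:
    """Aggregate retained records of one ROI per chromosome.

    Every reference chromosome gets a stat; chromosomes without records
    carry zeros. Records with an empty gene symbol count toward m_i but
    not toward g_i (a warning is logged). A record on a chromosome
    absent from the reference raises ``KeyError``.
    """
    ref_by_chrom = {r.chromosome: r for r in reference}
    m: dict[str, int] = {c: 0 for c in ref_by_chrom}
    genes: dict[str, set[str]] = {c: set() for c in ref_by_chrom}
    n_unnamed = 0
    for rec in records:
        if rec.chromosome not in ref_by_chrom:
            raise KeyError(
                f"record on chromosome {rec.chromosome!r} absent from the reference table"
            )
        m[rec.chromosome] += 1
        if rec.gene_symbol:
            genes[rec.chromosome].add(rec.gene_symbol)
        else:
            n_unnamed += 1
    if n_unnamed:
        logger.warning("%d record(s) lack a gene symbol; counted in m but not g", n_unnamed)

    stats = []
    for ref in reference:
        c = ref.chromosome
        mi, gi = m[c], len(genes[c])
        if gi > ref.approx_gene_count:
            logger.warning(
                "chromosome %s: %d distinct genes exceeds reference gene count %d",
                c, gi, ref.approx_gene_count,
            )
        cn = ref.copy_number
        p = (gi * cn) / (ref.approx_gene_count * cn) if gi else 0.0
        d = mi / (gi * cn) if gi else 0.0
        stats.append(ChromosomeStat(c, mi, gi, p, d))
    return stats


def relative_mutation_score(per_chromosome: Sequence[ChromosomeStat]) -> float:
    """Relative cell mutation score (sum m - sum g) / sum m.

    Zero when every mutation hits a distinct gene; (m-1)/m when all m
    mutations hit a single gene; 0 by convention for an unsequenced
    ROI (sum m = 0).
    """
    total_m = sum(s.total_mutations for s in per_chromosome)
    total_g = sum(s.affected_distinct_genes for s in per_chromosome)
    if total_m == 0:
        return 0.0
    return (total_m - total_g) / total_m


def top_mutated_genes(
    records: Sequence[VariantRecord],
    panel: Optional[Iterable[str]] = None,
    k: int = 5,
) -> list[TopGene]:
    """Rank gene symbols by mutation count, restricted to a panel.

    ``panel`` is a set of symbols (e.g. a colon-specific gene list);
    empty or None means no restriction. Ties are broken by ascending
    alphabetical symbol; the list is truncated to ``k`` entries, each
    carrying the multiset of variant types observed on that gene.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    panel_set = {s.upper() for s in panel} if panel else None
    counts: dict[str, list[str]] = {}
    for rec in records:
        sym = rec.gene_symbol
        if not sym:
            continue
        if panel_set is not None and sym.upper() not in panel_set:
            continue
        counts.setdefault(sym, []).append(rec.variant_class)
    ranked = sorted(counts.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        TopGene(symbol=s, count=len(types), variant_types=tuple(sorted(types)))
        for s, types in ranked[:k]
    ]


def summarize_roi(
    records: Sequence[VariantRecord],
    reference: Sequence[ChromosomeReference],
    roi_id: Optional[str] = None,
    panel: Optional[Iterable[str]] = None,
    k: int = 5,
) -> ROISummary:
    """Full burden summary of one ROI from its retained records."""
    rid = roi_id if roi_id is not None else (records[0].roi_id if records else "")
    stats = chromosome_stats(records, reference)
    return ROISummary(
        roi_id=rid,
        per_chromosome=tuple(stats),
        total_mutations=sum(s.total_mutations for s in stats),
        total_affected_genes=sum(s.affected_distinct_genes for s in stats),
        relative_mutation_score=relative_mutation_score(stats),
        top_genes=tuple(top_mutated_genes(records, panel=panel, k=k)),
    )


def class_median_summary(summaries: Sequence[ROISummary], tumor_class: str) -> ClassSummary:
    """Median p_i and d_i per chromosome over the ROIs of one class.

    Even cardinality takes the arithmetic mean of the two middle order
    statistics (the usual sample median).
    """
    if not summaries:
        raise ValueError("class_median_summary requires at least one ROI summary")
    chroms = tuple(s.chromosome for s in summaries[0].per_chromosome)
    for summ in summaries[1:]:
        if tuple(s.chromosome for s in summ.per_chromosome) != chroms:
            raise ValueError("ROI summaries have inconsistent chromosome sets")
    p = np.array([[s.proportion_mutated for s in summ.per_chromosome] for summ in summaries])
    d = np.array([[s.mean_mutations_per_gene for s in summ.per_chromosome] for summ in summaries])
    return ClassSummary(
        tumor_class=tumor_class,
        chromosomes=chroms,
        median_proportion=tuple(np.median(p, axis=0).tolist()),
        median_mutations_per_gene=tuple(np.median(d, axis=0).tolist()),
        n_rois=len(summaries),
    )


# ---------------------------------------------------------------------------
# Aggregate export
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # repr gives the shortest round-tripping decimal representation
    return repr(float(x))


def export_aggregate(
    summaries: Sequence[ROISummary],
    class_summaries: Sequence[ClassSummary],
    path: str | Path,
) -> None:
    """Write the chromosome-level aggregate table as TSV.

    One row per chromosome; per ROI the four columns m, g, p, d; then
    per class the two median columns. Values are written at full
    precision with a locale-independent decimal point.
    """
    chrom_sets = [tuple(s.chromosome for s in summ.per_chromosome) for summ in summaries]
    chrom_sets += [cs.chromosomes for cs in class_summaries]
    if chrom_sets and any(c != chrom_sets[0] for c in chrom_sets):
        raise ValueError("inconsistent chromosome sets across summaries")
    chroms = chrom_sets[0] if chrom_sets else ()

    header = ["chromosome"]
    for summ in summaries:
        header += [f"{summ.roi_id}_{c}" for c in ("m", "g", "p", "d")]
    for cs in class_summaries:
        header += [f"{cs.tumor_class}_median_p", f"{cs.tumor_class}_median_d"]

    lines = ["\t".join(header)]
    for i, chrom in enumerate(chroms):
        row = [chrom]
        for summ in summaries:
            s = summ.per_chromosome[i]
            row += [
                str(s.total_mutations),
                str(s.affected_distinct_genes),
                _fmt(s.proportion_mutated),
                _fmt(s.mean_mutations_per_gene),
            ]
        for cs in class_summaries:
            row += [_fmt(cs.median_proportion[i]), _fmt(cs.median_mutations_per_gene[i])]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_aggregate(path: str | Path) -> pd.DataFrame:
    """Read back an exported aggregate table, chromosome as index."""
    return pd.read_csv(
        path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip"
    ).set_index("chromosome")
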