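"""Per-ROI variant parsing and small-variant hard filtering.

Variant calls arriving from the sequencing platform (VCF v4.2 or a
tab-separated mutation-metadata table) are parsed into
:class:`VariantRecord` objects and passed through fixed-threshold hard
filters of the kind variant callers apply to small variants: a
Phred-scaled QUAL cut (separate for SNPs and INDELs), a minimum read
depth, a genotype/ploidy consistency check, a median-base-quality cut,
and a log-odds cut for mitochondrial contigs.

QUAL is the Phred-scaled probability that the site is homozygous
reference: QUAL = -10 * log10 P(GT = 0/0 | data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: canonical chromosome names used internally (no "chr" prefix)
CANONICAL_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

#: filter reason labels, matching the variant-caller rule names
SNP_QUAL_FILTER = "DRAGENSnpHardQUAL"
INDEL_QUAL_FILTER = "DRAGENIndelHardQUAL"
LOW_DEPTH_FILTER = "LowDepth"
PLOIDY_FILTER = "PloidyConflict"
BASE_QUALITY_FILTER = "base_quality"
LOD_FILTER = "lod_fstar"

FILTER_REASONS = (
    SNP_QUAL_FILTER,
    INDEL_QUAL_FILTER,
    LOW_DEPTH_FILTER,
    PLOIDY_FILTER,
    BASE_QUALITY_FILTER,
    LOD_FILTER,
)


def normalize_chromosome(name: str) -> str:
    """Map a chromosome label onto the canonical set {1..22, X, Y, MT}.

    Strips a leading ``chr`` prefix (any case) and maps mitochondrial
    aliases (``M``, ``chrM``) to ``MT``. Unknown labels are returned
    stripped but otherwise unchanged, so downstream reference lookups
    can report them.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in ("M", "MT"):
        return "MT"
    return s.upper() if s.upper() in ("X", "Y") else s


@dataclass(frozen=True)
class VariantRecord:
    """One small-variant call belonging to a sequenced ROI.

    ``qual`` is the Phred-scaled confidence that the site is a variant;
    ``depth`` the read depth (DP); ``lod`` the log-odds score emitted
    for mitochondrial contigs only. ``filter_status`` holds the hard
    filter rules the record failed (empty tuple = PASS).
    """

    roi_id: str
    chromosome: str
    position: int
    gene_symbol: str
    variant_class: str  # "SNP" or "INDEL"
    qual: float = 0.0
    depth: int = 0
    genotype: Optional[str] = None
    median_base_quality: Optional[float] = None
    lod: Optional[float] = None
    filter_status: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.qual < 0:
            raise ValueError(f"qual must be >= 0, got {self.qual}")
        if self.variant_class not in ("SNP", "INDEL"):
            raise ValueError(f"variant_class must be SNP or INDEL, got {self.variant_class!r}")


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter cutoffs.

    Defaults are the small-variant hard-filter values of the DRAGEN
    caller: SNPs need QUAL >= 10.41 and INDELs QUAL >= 7.83; depth must
    exceed 1 (DP <= 1 removed); mitochondrial calls need LOD > 6.3.
    The median-base-quality cut has no published value; 20 Phred is the
    configurable default. ``ploidy_map`` gives the expected call arity
    per chromosome (male sample: X, Y and MT haploid).
    """

    snp_qual_min: float = 10.41
    indel_qual_min: float = 7.83
    depth_min_exclusive: int = 1
    lod_min_exclusive: float = 6.3
    base_quality_min: float = 20.0
    ploidy_map: Mapping[str, int] = field(
        default_factory=lambda: {
            **{str(i): 2 for i in range(1, 23)},
            "X": 1,
            "Y": 1,
            "MT": 1,
        }
    )

    def __post_init__(self) -> None:
        for name in ("snp_qual_min", "indel_qual_min", "lod_min_exclusive", "base_quality_min"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.depth_min_exclusive < 0:
            raise ValueError("depth_min_exclusive must be >= 0")


@dataclass
class FilterReport:
    """Partition of the input records into retained and removed.

    ``removed`` pairs each failing record with the full tuple of rules
    it failed, so filter statistics do not depend on rule order.
    """

    retained: list[VariantRecord]
    removed: list[tuple[VariantRecord, tuple[str, ...]]]

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.removed)

    def removal_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in FILTER_REASONS}
        for _, reasons in self.removed:
            for r in reasons:
                counts[r] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Flat table of all records with a PASS/reason column."""
        rows = []
        for rec in self.retained:
            rows.append(_record_row(rec, "PASS"))
        for rec, reasons in self.removed:
            rows.append(_record_row(rec, ";".join(reasons)))
        return pd.DataFrame(rows)


def _record_row(rec: VariantRecord, status: str) -> dict:
    return {
        "roi_id": rec.roi_id,
        "chromosome": rec.chromosome,
        "position": rec.position,
        "gene_symbol": rec.gene_symbol,
        "variant_class": rec.variant_class,
        "qual": rec.qual,
        "depth": rec.depth,
        "genotype": rec.genotype if rec.genotype is not None else "",
        "median_base_quality": rec.median_base_quality,
        "lod": rec.lod,
        "filter": status,
    }


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

#: default column-name map for tab-separated mutation tables
DEFAULT_DIALECT: dict[str, str] = {
    "roi_id": "roi_id",
    "chromosome": "chromosome",
    "position": "position",
    "gene_symbol": "gene_symbol",
    "variant_class": "variant_class",
    "qual": "qual",
    "depth": "depth",
    "genotype": "genotype",
    "median_base_quality": "median_base_quality",
    "lod": "lod",
}

_MANDATORY_FIELDS = ("chromosome", "position", "gene_symbol", "variant_class")


class SchemaError(ValueError):
    """A mandatory column is missing from a mutation table."""


def parse_mutation_table(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    roi_id: Optional[str] = None,
) -> list[VariantRecord]:
    """Read a tab-separated mutation-metadata table.

    The sequencing platform exports per-ROI tables with ~150 columns;
    ``dialect`` maps the internal field names (keys of
    :data:`DEFAULT_DIALECT`) to the column names actually present.
    Unknown columns are ignored. Rows whose mandatory fields cannot be
    parsed are skipped with a warning.

    Parameters
    ----------
    path:
        TSV file to read.
    dialect:
        Partial override of :data:`DEFAULT_DIALECT`.
    roi_id:
        ROI identifier used when the table has no roi_id column;
        defaults to the file stem.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)

    for fld in _MANDATORY_FIELDS:
        if colmap[fld] not in df.columns:
            raise SchemaError(
                f"mandatory column {colmap[fld]!r} (field {fld!r}) missing from {path}"
            )

    default_roi = roi_id if roi_id is not None else Path(path).stem
    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        try:
            records.append(_row_to_record(row, colmap, default_roi))
        except (ValueError, TypeError) as exc:
            logger.warning("skipping row %d of %s: %s", idx, path, exc)
    return records


def _opt_float(row: pd.Series, col: Optional[str]) -> Optional[float]:
    if col is None or col not in row.index:
        return None
    raw = row[col]
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() in ("", "."):
        return None
    return float(raw)


def _row_to_record(row: pd.Series, colmap: Mapping[str, str], default_roi: str) -> VariantRecord:
    vclass = str(row[colmap["variant_class"]]).strip().upper()
    if vclass not in ("SNP", "INDEL"):
        raise ValueError(f"unknown variant class {vclass!r}")
    qual = _opt_float(row, colmap.get("qual"))
    depth = _opt_float(row, colmap.get("depth"))
    roi_col = colmap.get("roi_id")
    roi = str(row[roi_col]) if roi_col in row.index and pd.notna(row[roi_col]) else default_roi
    gt_col = colmap.get("genotype")
    gt = str(row[gt_col]) if gt_col in row.index and pd.notna(row[gt_col]) else None
    return VariantRecord(
        roi_id=roi,
        chromosome=normalize_chromosome(row[colmap["chromosome"]]),
        position=int(row[colmap["position"]]),
        gene_symbol=str(row[colmap["gene_symbol"]]).strip(),
        variant_class=vclass,
        qual=qual if qual is not None else 0.0,
        depth=int(depth) if depth is not None else 0,
        genotype=gt,
        median_base_quality=_opt_float(row, colmap.get("median_base_quality")),
        lod=_opt_float(row, colmap.get("lod")),
    )


def parse_vcf(path: str | Path, roi_id: Optional[str] = None) -> list[VariantRecord]:
    """Read variant calls from a VCF v4.2 file.

    The variant class is derived from REF/ALT lengths: both length 1 is
    a SNP, anything else an INDEL. DP is taken from the FORMAT field of
    the first sample when present, else from INFO. Gene symbol, median
    base quality and LOD are read from the INFO keys ``GENE``, ``MBQ``
    and ``LOD`` when present.
    """
    from cyvcf2 import VCF

    def f64(x: float) -> float:
        # cyvcf2 hands back float32; re-read at the printed decimal precision
        return float(f"{x:.6g}")

    default_roi = roi_id if roi_id is not None else Path(path).stem
    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            alt = v.ALT[0] if v.ALT else ""
            vclass = "SNP" if len(v.REF) == 1 and len(alt) == 1 else "INDEL"
            depth = None
            if v.format("DP") is not None:
                depth = int(v.format("DP")[0][0])
            elif v.INFO.get("DP") is not None:
                depth = int(v.INFO.get("DP"))
            gt = None
            if v.genotypes:
                alleles = [a for a in v.genotypes[0][:-1] if a >= 0]
                if alleles:
                    sep = "|" if v.genotypes[0][-1] else "/"
                    gt = sep.join(str(a) for a in alleles)
            gene = v.INFO.get("GENE")
            mbq = v.INFO.get("MBQ")
            lod = v.INFO.get("LOD")
            records.append(
                VariantRecord(
                    roi_id=default_roi,
                    chromosome=normalize_chromosome(v.CHROM),
                    position=int(v.POS),
                    gene_symbol=str(gene) if gene is not None else "",
                    variant_class=vclass,
                    qual=f64(v.QUAL) if v.QUAL is not None else 0.0,
                    depth=depth if depth is not None else 0,
                    genotype=gt,
                    median_base_quality=f64(mbq) if mbq is not None else None,
                    lod=f64(lod) if lod is not None else None,
                )
            )
    finally:
        vcf.close()
    return records


def qual_from_posterior(p_ref: float) -> float:
    """Phred-scale a posterior homozygous-reference probability.

    QUAL = -10 * log10(p_ref), the standard Phred transform of the
    probability that the site carries no variant.
    """
    if not 0.0 < p_ref <= 1.0:
        raise ValueError(f"p_ref must be in (0, 1], got {p_ref}")
    return -10.0 * math.log10(p_ref)


# ---------------------------------------------------------------------------
# Hard filtering
# ---------------------------------------------------------------------------

def _genotype_arity(genotype: str) -> int:
    return len(genotype.replace("|", "/").split("/"))


def _failure_reasons(rec: VariantRecord, t: FilterThresholds) -> tuple[str, ...]:
    """Evaluate every rule independently; absent optional fields pass."""
    reasons = []
    if rec.variant_class == "SNP" and rec.qual < t.snp_qual_min:
        reasons.append(SNP_QUAL_FILTER)
    if rec.variant_class == "INDEL" and rec.qual < t.indel_qual_min:
        reasons.append(INDEL_QUAL_FILTER)
    if rec.depth <= t.depth_min_exclusive:
        reasons.append(LOW_DEPTH_FILTER)
    if rec.genotype is not None:
        expected = t.ploidy_map.get(rec.chromosome)
        if expected is not None and _genotype_arity(rec.genotype) != expected:
            reasons.append(PLOIDY_FILTER)
    if rec.median_base_quality is not None and rec.median_base_quality < t.base_quality_min:
        reasons.append(BASE_QUALITY_FILTER)
    if rec.chromosome == "MT" and rec.lod is not None and rec.lod <= t.lod_min_exclusive:
        reasons.append(LOD_FILTER)
    return tuple(reasons)


def apply_hard_filters(
    records: Iterable[VariantRecord],
    thresholds: Optional[FilterThresholds] = None,
) -> FilterReport:
    """Partition records into retained and removed under the hard filters.

    All rules are evaluated for every record and a failing record
    carries every reason it triggered, so the outcome is independent of
    both record order and rule order. SNP/INDEL QUAL cuts are exclusive
    below the threshold (qual == threshold is retained); depth is
    removed when DP <= ``depth_min_exclusive``; mitochondrial records
    are removed when LOD does not exceed ``lod_min_exclusive``.
    """
    t = thresholds if thresholds is not None else FilterThresholds()
    retained: list[VariantRecord] = []
    removed: list[tuple[VariantRecord, tuple[str, ...]]] = []
    for rec in records:
        reasons = _failure_reasons(rec, t)
        if reasons:
            removed.append((replace(rec, filter_status=reasons), reasons))
        else:
            retained.append(rec)
    return FilterReport(retained=retained, removed=removed)


def write_filter_report(report: FilterReport, retained_path: str | Path, removed_path: str | Path) -> None:
    """Write retained and removed records as TSV, with a reason column."""
    df = report.to_frame()
    if df.empty:
        df = pd.DataFrame(columns=list(_record_row(
            VariantRecord("r", "1", 1, "G", "SNP"), "PASS").keys()))
    df[df["filter"] == "PASS"].to_csv(retained_path, sep="\t", index=False)
    df[df["filter"] != "PASS"].to_csv(removed_path, sep="\t", index=False)
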