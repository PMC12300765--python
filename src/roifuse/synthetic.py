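"""Seeded synthetic-data generators for the full analysis surface.

Generators for mutation tables with known per-chromosome truth, VCFs
with controllable QUAL/DP/LOD fields, tissue-like images (dark nuclei
on a bright background) with ground-truth masks, and the published
segmentation benchmark counts. Every generator is deterministic given
its seed. Synthetic gene symbols use the pattern ``GENE_<chrom>_<k>``
so tests cannot accidentally depend on real gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .variants import VariantRecord


@dataclass(frozen=True)
class ChromosomePlan:
    """Plan for one chromosome: n_genes genes, mutations_per_gene each.

    ``mutations_per_gene`` is either a single int applied to every gene
    or one int per gene (each >= 1).
    """

    chromosome: str
    n_genes: int
    mutations_per_gene: int | tuple[int, ...] = 1

    def counts(self) -> list[int]:
        if isinstance(self.mutations_per_gene, int):
            c = [self.mutations_per_gene] * self.n_genes
        else:
            c = list(self.mutations_per_gene)
            if len(c) != self.n_genes:
                raise ValueError("mutations_per_gene length must equal n_genes")
        if any(x < 1 for x in c):
            raise ValueError("every listed gene needs >= 1 mutation")
        return c


@dataclass(frozen=True)
class MutationTableSpec:
    plan: tuple[ChromosomePlan, ...]
    seed: int = 0
    roi_id: str = "ROI_SYN"


def gen_mutation_table(spec: MutationTableSpec) -> tuple[list[VariantRecord], dict[str, tuple[int, int]]]:
    """Generate variant records with exact per-chromosome (m, g) truth.

    Positions are random but reproducible per seed; QUAL and DP are
    drawn above the hard-filter thresholds so the records survive
    filtering. Returns the records and ``{chromosome: (m_i, g_i)}``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[VariantRecord] = []
    truth: dict[str, tuple[int, int]] = {}
    for plan in spec.plan:
        counts = plan.counts()
        m_i = sum(counts)
        truth[plan.chromosome] = (m_i, plan.n_genes)
        for k, n_mut in enumerate(counts):
            symbol = f"GENE_{plan.chromosome}_{k}"
            for _ in range(n_mut):
                records.append(
                    VariantRecord(
                        roi_id=spec.roi_id,
                        chromosome=plan.chromosome,
                        position=int(rng.integers(1, 2**27)),
                        gene_symbol=symbol,
                        variant_class="SNP" if rng.random() < 0.8 else "INDEL",
                        qual=float(rng.uniform(15.0, 60.0)),
                        depth=int(rng.integers(10, 200)),
                    )
                )
    return records, truth


def write_mutation_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as a TSV readable by ``parse_mutation_table``."""
    cols = ("roi_id", "chromosome", "position", "gene_symbol", "variant_class",
            "qual", "depth", "genotype", "median_base_quality", "lod")
    lines = ["\t".join(cols)]
    for r in records:
        lines.append("\t".join(
            "" if getattr(r, c) is None else str(getattr(r, c)) for c in cols
        ))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF generation
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=GENE,Number=1,Type=String,Description="HUGO gene symbol">
##INFO=<ID=MBQ,Number=1,Type=Float,Description="Median base quality of alt reads">
##INFO=<ID=LOD,Number=1,Type=Float,Description="Log-odds score (mitochondrial)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE
"""


def gen_vcf(
    quals: Sequence[float],
    dps: Sequence[int],
    classes: Sequence[str],
    path: str | Path,
    chroms: Optional[Sequence[str]] = None,
    genes: Optional[Sequence[str]] = None,
    lods: Optional[Sequence[Optional[float]]] = None,
    genotypes: Optional[Sequence[str]] = None,
) -> None:
    """Write a VCF v4.2 with one record per (qual, dp, class) tuple.

    ``classes`` entries are "SNP" or "INDEL" and control REF/ALT
    lengths. Optional parallel sequences set chromosome, gene symbol,
    LOD and genotype per record. All sequences must have equal length.
    """
    n = len(quals)
    for name, seq in (("dps", dps), ("classes", classes), ("chroms", chroms),
                      ("genes", genes), ("lods", lods), ("genotypes", genotypes)):
        if seq is not None and len(seq) != n:
            raise ValueError(f"{name} length {len(seq)} != quals length {n}")
    chroms = chroms if chroms is not None else ["1"] * n
    genes = genes if genes is not None else [f"GENE_{i}" for i in range(n)]
    lods = lods if lods is not None else [None] * n
    genotypes = genotypes if genotypes is not None else ["0/1"] * n

    contig_lines = "".join(
        f"##contig=<ID={c}>\n" for c in dict.fromkeys(chroms)
    )
    lines = [_VCF_HEADER.format(contigs=contig_lines).rstrip("\n")]
    for i in range(n):
        ref, alt = ("A", "G") if classes[i] == "SNP" else ("A", "AT")
        info = [f"DP={int(dps[i])}", f"GENE={genes[i]}"]
        if lods[i] is not None:
            info.append(f"LOD={lods[i]:g}")
        lines.append("\t".join([
            chroms[i], str(1000 + i), ".", ref, alt, f"{quals[i]:g}",
            ".", ";".join(info), "GT:DP", f"{genotypes[i]}:{int(dps[i])}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tissue-like images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSpec:
    """Bright background with dark circular nuclei and Gaussian noise.

    Defaults emulate well-separated hematoxylin-stained nuclei at a
    0.24 μm/px scan: radii 15-21 px (nuclear diameters of 7-10 μm) and
    a minimum border gap of 8 px, which keeps neighboring nuclei
    resolvable under the detector's morphological dilation.
    """

    width: int = 512
    height: int = 512
    n_nuclei: int = 20
    radius_min: float = 15.0
    radius_max: float = 21.0
    background_intensity: int = 250
    nucleus_intensity: int = 60
    noise_sigma: float = 0.0
    min_separation: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.nucleus_intensity <= 255 and 0 <= self.background_intensity <= 255):
            raise ValueError("intensities must be in [0, 255]")
        if self.radius_min > self.radius_max or self.radius_min <= 0:
            raise ValueError("invalid radius range")


def gen_tissue_image(spec: ImageSpec) -> tuple[np.ndarray, np.ndarray, int]:
    """Generate (uint8 image, int32 ground-truth label mask, nucleus count).

    Disc centers are placed by rejection sampling so that disc borders
    stay at least ``min_separation`` pixels apart and discs fit in the
    frame; placement failing after bounded retries raises RuntimeError.
    """
    rng = np.random.default_rng(spec.seed)
    img = np.full((spec.height, spec.width), float(spec.background_intensity))
    mask = np.zeros((spec.height, spec.width), dtype=np.int32)

    centers: list[tuple[float, float, float]] = []  # (y, x, r)
    max_tries = 1000 * max(spec.n_nuclei, 1)
    tries = 0
    while len(centers) < spec.n_nuclei:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} nuclei at separation "
                f"{spec.min_separation} within {max_tries} attempts"
            )
        tries += 1
        r = float(rng.uniform(spec.radius_min, spec.radius_max))
        y = float(rng.uniform(r + 1, spec.height - r - 1))
        x = float(rng.uniform(r + 1, spec.width - r - 1))
        ok = all(
            np.hypot(y - cy, x - cx) >= r + cr + spec.min_separation
            for cy, cx, cr in centers
        )
        if ok:
            centers.append((y, x, r))

    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    for label, (cy, cx, r) in enumerate(centers, start=1):
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[disc] = spec.nucleus_intensity
        mask[disc] = label

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask, len(centers)


# ---------------------------------------------------------------------------
# Published segmentation benchmark counts
# ---------------------------------------------------------------------------

def table5_fixture() -> list[tuple[str, int, int, int, float]]:
    """The published per-sample segmentation counts and reported DSC.

    Rows are (sample label, detected cells, manually annotated cells,
    missed cells, reported DSC); the final row is the column total with
    the reported average DSC.
    """
    return [
        ("Sample A", 160, 207, 47, 0.872),
        ("Sample B", 261, 269, 8, 0.985),
        ("Sample C", 176, 197, 21, 0.944),
        ("Sample D", 367, 444, 77, 0.905),
        ("Sample E", 545, 706, 161, 0.871),
        ("Sample F", 716, 872, 156, 0.902),
        ("Sample G", 285, 410, 125, 0.820),
        ("Sample H", 431, 484, 53, 0.890),
        ("Sample I", 256, 288, 32, 0.889),
        ("Sample J", 89, 117, 28, 0.864),
        ("Total", 3286, 3994, 708, 0.891),
    ]
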