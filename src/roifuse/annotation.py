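"""Gene-level pathway and drug-target annotation from a local snapshot.

Mutated gene symbols are joined against a versioned local snapshot of
open pathway/drug-target databases (a TSV file), so the join is fully
reproducible and needs no network access. Annotation is pure
decoration: it never changes mutation counts or scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from .burden import ROISummary, TopGene


@dataclass(frozen=True)
class GeneAnnotation:
    symbol: str
    pathways: tuple[str, ...]
    drug_targets: tuple[str, ...]


def load_snapshot(path: str | Path) -> dict[str, GeneAnnotation]:
    """Load a snapshot TSV (columns: symbol, pathways, drugs).

    Pathways and drugs are ``;``-separated within their cells; the map
    is keyed by upper-cased symbol. Duplicate symbols are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("symbol", "pathways", "drugs"):
        if col not in df.columns:
            raise ValueError(f"snapshot missing column {col!r}")
    snapshot: dict[str, GeneAnnotation] = {}
    for r in df.itertuples():
        key = r.symbol.strip().upper()
        if key in snapshot:
            raise ValueError(f"duplicate symbol {key!r} in snapshot")
        snapshot[key] = GeneAnnotation(
            symbol=key,
            pathways=tuple(p for p in r.pathways.split(";") if p),
            drug_targets=tuple(d for d in r.drugs.split(";") if d),
        )
    return snapshot


def load_panel(path: str | Path) -> set[str]:
    """Load a gene panel (one upper-cased symbol per line, '#' comments)."""
    symbols = set()
    for line in Path(path).read_text().splitlines():
        s = line.split("#")[0].strip()
        if s:
            symbols.add(s.upper())
    return symbols


def annotate(summary: ROISummary, snapshot: Mapping[str, GeneAnnotation]) -> ROISummary:
    """Attach pathway and drug lists to the ROI's top genes.

    Symbols absent from the snapshot get empty lists and keep
    ``annotated=False`` as a flag. Counts and scores are untouched.
    """
    annotated_genes = []
    for g in summary.top_genes:
        ann = snapshot.get(g.symbol.upper())
        if ann is None:
            annotated_genes.append(replace(g, pathways=(), drugs=(), annotated=False))
        else:
            annotated_genes.append(
                replace(g, pathways=ann.pathways, drugs=ann.drug_targets, annotated=True)
            )
    return replace(summary, top_genes=tuple(annotated_genes))
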