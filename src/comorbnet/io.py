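"""Readers for the tab-separated association tables.

The tables mirror the layout of curated genetics reports: disease-gene
associations, mouse gene-phenotype associations, human-mouse ortholog
pairs, scored protein-protein links, and a protein-to-coding-gene mapping.
Column positions are configurable because real report layouts vary by
database release; `#`-prefixed comment lines are ignored everywhere.

Identifiers are kept as opaque strings within their namespace — no ontology
resolution is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path

logger = logging.getLogger(__name__)

Edge = tuple[str, str]

#: default confidence threshold for scored protein-protein links;
#: interactions scoring below this are considered unreliable and dropped
PPI_MIN_CONFIDENCE = 400


class ParseError(ValueError):
    """Raised when a table cannot yield a single valid row."""


def _iter_rows(path: str | Path):
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"association table not found: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def parse_association_table(path: str | Path, columns: tuple[int, int] = (0, 1),
                            ) -> list[Edge]:
    """Read an undirected two-column association table.

    Returns deduplicated undirected edges ``(u, v)``; the pair is canonically
    ordered so ``(a, b)`` and ``(b, a)`` collapse to one edge.  Blank or
    malformed rows (and self-pairs) are skipped and counted in the log; a
    table with zero valid rows is a fatal error.
    """
    ca, cb = columns
    edges: dict[Edge, None] = {}
    skipped = 0
    bad_rows: list[int] = []
    for lineno, fields in _iter_rows(path):
        if len(fields) <= max(ca, cb):
            skipped += 1
            bad_rows.append(lineno)
            continue
        u, v = fields[ca].strip(), fields[cb].strip()
        if not u or not v or u == v:
            skipped += 1
            bad_rows.append(lineno)
            continue
        edges[(u, v) if u <= v else (v, u)] = None
    if skipped:
        logger.warning("%s: skipped %d malformed/blank rows (lines %s%s)",
                       path, skipped, bad_rows[:10],
                       "..." if len(bad_rows) > 10 else "")
    if not edges:
        raise ParseError(
            f"{path}: zero valid rows "
            f"({skipped} rows skipped at lines {bad_rows[:20]})")
    return list(edges)


def parse_mapping_table(path: str | Path, columns: tuple[int, int] = (0, 1),
                        ) -> dict[str, str]:
    """Read a protein -> coding-gene identifier mapping (first hit wins)."""
    ca, cb = columns
    mapping: dict[str, str] = {}
    for _, fields in _iter_rows(path):
        if len(fields) <= max(ca, cb):
            continue
        prot, gene = fields[ca].strip(), fields[cb].strip()
        if prot and gene:
            mapping.setdefault(prot, gene)
    if not mapping:
        raise ParseError(f"{path}: zero valid mapping rows")
    return mapping


def parse_ppi_table(path: str | Path, mapping: dict[str, str] | None = None,
                    min_confidence: int = PPI_MIN_CONFIDENCE,
                    columns: tuple[int, int, int] = (0, 1, 2),
                    ) -> list[tuple[str, str, float]]:
    """Read scored protein-protein links and keep confident interactions.

    Rows carry ``(protein_a, protein_b, combined_score)``.  Exactly the rows
    with ``score >= min_confidence`` are retained (the threshold itself is
    kept).  Proteins are translated to their coding genes through `mapping`
    (identity if None); unmapped rows are dropped and counted.  Every
    surviving interaction becomes an unweighted edge of weight 1.0.
    """
    ca, cb, cs = columns
    edges: dict[Edge, None] = {}
    dropped_score = dropped_unmapped = dropped_bad = 0
    for lineno, fields in _iter_rows(path):
        if len(fields) <= max(ca, cb, cs):
            dropped_bad += 1
            continue
        try:
            score = float(fields[cs])
        except ValueError:
            logger.warning("%s:%d non-numeric score %r, row skipped",
                           path, lineno, fields[cs])
            dropped_bad += 1
            continue
        if score < min_confidence:
            dropped_score += 1
            continue
        pa, pb = fields[ca].strip(), fields[cb].strip()
        if mapping is not None:
            if pa not in mapping or pb not in mapping:
                dropped_unmapped += 1
                continue
            pa, pb = mapping[pa], mapping[pb]
        if not pa or not pb or pa == pb:
            dropped_bad += 1
            continue
        edges[(pa, pb) if pa <= pb else (pb, pa)] = None
    logger.info("%s: kept %d interactions (dropped %d below score %d, "
                "%d unmapped, %d malformed)", path, len(edges), dropped_score,
                min_confidence, dropped_unmapped, dropped_bad)
    if not edges:
        raise ParseError(f"{path}: zero valid rows after filtering")
    return [(u, v, 1.0) for u, v in edges]


def parse_pair_list(path: str | Path, columns: tuple[int, int] = (0, 1),
                    ) -> list[Edge]:
    """Read an unordered disease-pair list (positives)."""
    return parse_association_table(path, columns=columns)
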