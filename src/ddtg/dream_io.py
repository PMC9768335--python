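"""Readers and writers for DREAM-style steady-state expression tables.

The in-silico knockout challenges distribute two tab-delimited tables per
network: an n-row *knockout* table (row i = steady state of every gene after
deleting gene i) and a single-row *wild-type* table (the unperturbed steady
state). Gold-standard networks are 3-column edge lists ``src<TAB>dst<TAB>0|1``.
Different challenge releases optionally prepend a strain/row-label column;
both dialects are accepted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionPanel",
    "GoldStandard",
    "read_expression_panel",
    "write_expression_panel",
    "read_gold_standard",
    "write_gold_standard",
    "write_predictions",
]


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass(frozen=True)
class ExpressionPanel:
    """A wild-type steady state plus the full single-knockout design.

    Parameters
    ----------
    gene_names
        Ordered gene identifiers; this order is authoritative for both axes
        of ``knockout`` and for ``wild_type``.
    wild_type
        Length-n vector of unperturbed steady-state expression levels.
    knockout
        n x n matrix; entry ``[i, j]`` is the steady-state level of gene j
        after knockout of gene i.
    """

    gene_names: tuple[str, ...]
    wild_type: np.ndarray
    knockout: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_names", tuple(str(g) for g in self.gene_names))
        wt = np.asarray(self.wild_type, dtype=float).reshape(-1)
        ko = np.asarray(self.knockout, dtype=float)
        object.__setattr__(self, "wild_type", wt)
        object.__setattr__(self, "knockout", ko)
        n = len(self.gene_names)
        if len(set(self.gene_names)) != n:
            raise FormatError("duplicate gene names in panel header")
        if wt.shape != (n,):
            raise FormatError(
                f"wild-type vector has {wt.shape[0]} entries for {n} genes"
            )
        if ko.shape != (n, n):
            raise FormatError(
                f"knockout table is {ko.shape[0]}x{ko.shape[1]}, expected {n}x{n}"
            )
        if not np.all(np.isfinite(wt)) or not np.all(np.isfinite(ko)):
            raise FormatError("expression values must be finite")
        if np.any(wt < 0):
            raise FormatError("wild-type expression levels must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.gene_names)

    def index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"unknown gene {name!r}") from None


@dataclass(frozen=True)
class GoldStandard:
    """Directed reference network over the ordered non-self gene pairs.

    Pairs listed with label 1 are positives; every other ordered pair over
    ``gene_names`` is an implicit negative (the DREAM convention).
    """

    gene_names: tuple[str, ...]
    positives: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "positives", frozenset(self.positives))
        known = set(self.gene_names)
        for u, v in self.positives:
            if u == v:
                raise FormatError(f"self-edge {u}->{v} labelled positive")
            for g in (u, v):
                if g not in known:
                    raise FormatError(f"gold standard names unknown gene {g!r}")

    @property
    def n(self) -> int:
        return len(self.gene_names)

    @property
    def n_positive(self) -> int:
        return len(self.positives)

    @property
    def n_negative(self) -> int:
        n = self.n
        return n * (n - 1) - len(self.positives)

    def universe(self) -> Iterator[tuple[str, str]]:
        """All ordered non-self pairs, in gene order."""
        for u in self.gene_names:
            for v in self.gene_names:
                if u != v:
                    yield (u, v)

    def label(self, u: str, v: str) -> int:
        return 1 if (u, v) in self.positives else 0


def _read_rows(path) -> tuple[list[str], list[list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    rows = [ln.split("\t") for ln in lines[1:]]
    return header, rows


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _parse_table(path) -> tuple[list[str], np.ndarray]:
    """Parse one expression table, tolerating a leading row-label column."""
    header, rows = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    labelled = not _is_number(rows[0][0])
    if labelled:
        width = len(rows[0])
        # header may or may not name the label column
        if len(header) == width:
            header = header[1:]
        rows = [r[1:] for r in rows]
    genes = [h.strip() for h in header]
    values = np.empty((len(rows), len(genes)), dtype=float)
    for r, row in enumerate(rows):
        if len(row) != len(genes):
            raise FormatError(
                f"{path}: row {r + 1} has {len(row)} fields, expected {len(genes)}"
            )
        for c, cell in enumerate(row):
            try:
                values[r, c] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at data row {r + 1}, "
                    f"column {genes[c]!r}"
                ) from None
    return genes, values


def read_expression_panel(knockout_path, wildtype_path) -> ExpressionPanel:
    """Read a knockout matrix plus wild-type vector into a validated panel.

    Gene order is taken from the knockout header; the wild-type columns are
    re-mapped by name if its header lists the genes in a different order.
    """
    genes, ko = _parse_table(knockout_path)
    n = len(genes)
    if ko.shape[0] != n:
        raise FormatError(
            f"{knockout_path}: non-square knockout table: {ko.shape[0]} data rows "
            f"for {n} genes in the header"
        )
    wt_genes, wt = _parse_table(wildtype_path)
    if wt.shape[0] != 1:
        raise FormatError(
            f"{wildtype_path}: expected one wild-type row, found {wt.shape[0]}"
        )
    if wt_genes != genes:
        missing = sorted(set(genes) - set(wt_genes))
        extra = sorted(set(wt_genes) - set(genes))
        if missing or extra:
            raise FormatError(
                f"header mismatch between {knockout_path} and {wildtype_path}: "
                f"missing from wild type {missing}, unexpected {extra}"
            )
        order = [wt_genes.index(g) for g in genes]
        wt = wt[:, order]
        logger.info("wild-type columns reordered to match knockout header")
    return ExpressionPanel(gene_names=tuple(genes), wild_type=wt[0], knockout=ko)


def _fmt(x: float) -> str:
    # shortest repr that round-trips the float exactly
    return str(float(x))


def write_expression_panel(panel: ExpressionPanel, knockout_path, wildtype_path) -> None:
    """Write a panel back to the two tab-delimited tables (full precision)."""
    header = "\t".join(panel.gene_names)
    with open(knockout_path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for row in panel.knockout:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    with open(wildtype_path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        fh.write("\t".join(_fmt(v) for v in panel.wild_type) + "\n")


def read_gold_standard(path, gene_names: Sequence[str]) -> GoldStandard:
    """Read a 3-column edge list; pairs absent from the file are negatives."""
    known = set(gene_names)
    seen: dict[tuple[str, str], int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\r\n").split("\t")]
            if len(fields) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields"
                )
            u, v, lab = fields
            if lab not in ("0", "1"):
                raise FormatError(f"{path}: line {lineno}: label must be 0 or 1")
            for g in (u, v):
                if g not in known:
                    raise FormatError(f"{path}: line {lineno}: unknown gene {g!r}")
            label = int(lab)
            if u == v:
                if label == 1:
                    raise FormatError(
                        f"{path}: line {lineno}: self-edge {u}->{v} labelled 1"
                    )
                continue  # explicit self negatives are redundant
            if (u, v) in seen and seen[(u, v)] != label:
                raise FormatError(
                    f"{path}: conflicting labels for pair {u}->{v}"
                )
            seen[(u, v)] = label
    positives = frozenset(p for p, lab in seen.items() if lab == 1)
    return GoldStandard(gene_names=tuple(gene_names), positives=positives)


def write_gold_standard(gold: GoldStandard, path) -> None:
    """Write every ordered pair with its 0/1 label (positives first)."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in gold.universe():
            fh.write(f"{u}\t{v}\t{gold.label(u, v)}\n")


def _as_triple(edge) -> tuple[str, str, float]:
    if hasattr(edge, "source"):
        return (edge.source, edge.target, float(edge.confidence))
    u, v, s = edge
    return (str(u), str(v), float(s))


def write_predictions(edges: Iterable, path) -> None:
    """Write scored edges as ``src<TAB>dst<TAB>score``.

    Rows are sorted by score descending, ties broken lexicographically by
    (src, dst), so the byte output is deterministic for a given edge list.
    """
    triples = [_as_triple(e) for e in edges]
    for u, v, s in triples:
        if u == v:
            raise FormatError(f"self-edge {u}->{v} in predictions")
        if not np.isfinite(s):
            raise FormatError(f"non-finite score for {u}->{v}")
    triples.sort(key=lambda t: (-t[2], t[0], t[1]))
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, s in triples:
            fh.write(f"{u}\t{v}\t{_fmt(s)}\n")


def write_ranking(ranked: Iterable, path) -> None:
    """Write an already-ordered ranking verbatim (order is the contract)."""
    with open(path, "w", encoding="utf-8") as fh:
        for edge in ranked:
            u, v, s = _as_triple(edge)
            if u == v:
                raise FormatError(f"self-edge {u}->{v} in ranking")
            fh.write(f"{u}\t{v}\t{_fmt(s)}\n")


def read_predictions(path) -> list[tuple[str, str, float]]:
    """Read a 3-column scored edge list, preserving row order."""
    out: list[tuple[str, str, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\r\n").split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields"
                )
            u, v, s = fields
            if not _is_number(s):
                raise FormatError(f"{path}: line {lineno}: non-numeric score {s!r}")
            out.append((u, v, float(s)))
    return out
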