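"""Phyletic presence/absence/unknown matrices and their TSV format.

The matrix is taxa x gene-families over a three-valued state set.  The
third state ``unknown`` represents taxa whose data coverage is too thin
to assert absence; reconstruction treats it as missing data.

TSV format: tab-separated, UTF-8, header row of family labels with an
empty leading cell, one row per taxon, cells in ``{1, 0, ?}``.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import pandas as pd

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"
STATES = (PRESENT, ABSENT, UNKNOWN)

_CELL_TO_STATE = {"1": PRESENT, "0": ABSENT, "?": UNKNOWN}
_STATE_TO_CELL = {v: k for k, v in _CELL_TO_STATE.items()}

#: The eight ancestral eukaryotic C1A families, in canonical column order.
EIGHT_FAMILIES = (
    "cathB",
    "cathC",
    "cathX",
    "cathL",
    "cathF",
    "cathH",
    "p26_29",
    "type1_long",
)

#: Younger lineages restricted to Obazoa.
EXTRA_FAMILIES = ("cathO", "vWFA_C1")

#: Prokaryote-level generic character (any short C1A peptidase).
GENERIC_FAMILY = "C1A_generic"

DEFAULT_VOCABULARY = EIGHT_FAMILIES + EXTRA_FAMILIES + (GENERIC_FAMILY,)

__all__ = [
    "PhyleticMatrix",
    "MatrixFormatError",
    "MatrixConflictError",
    "VocabularyError",
    "read_matrix",
    "write_matrix",
    "merge",
    "matrix_from_assignments",
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "EIGHT_FAMILIES",
    "EXTRA_FAMILIES",
    "GENERIC_FAMILY",
    "DEFAULT_VOCABULARY",
]


class MatrixFormatError(ValueError):
    pass


class MatrixConflictError(ValueError):
    def __init__(self, cells: list[tuple[str, str]]):
        self.cells = cells
        listing = ", ".join(f"({t}, {f})" for t, f in cells)
        super().__init__(f"conflicting states for cells: {listing}")


class VocabularyError(KeyError):
    pass


class PhyleticMatrix:
    """Ordered taxa x families matrix over {present, absent, unknown}."""

    def __init__(self, taxa: Sequence[str], families: Sequence[str],
                 states: dict[tuple[str, str], str] | pd.DataFrame | None = None):
        taxa = list(taxa)
        families = list(families)
        if len(set(taxa)) != len(taxa):
            raise MatrixFormatError("duplicate taxon labels")
        if len(set(families)) != len(families):
            raise MatrixFormatError("duplicate family labels")
        if isinstance(states, pd.DataFrame):
            df = states.reindex(index=taxa, columns=families, fill_value=UNKNOWN)
        else:
            df = pd.DataFrame(UNKNOWN, index=taxa, columns=families, dtype=object)
            if states:
                for (taxon, family), state in states.items():
                    if state not in STATES:
                        raise MatrixFormatError(f"illegal state {state!r}")
                    df.loc[taxon, family] = state
        bad = df.map(lambda s: s not in STATES)
        if bad.to_numpy().any():
            raise MatrixFormatError("illegal state value in matrix")
        self._df = df

    # -- access ------------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self._df.index)

    @property
    def families(self) -> list[str]:
        return list(self._df.columns)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    def get(self, taxon: str, family: str) -> str:
        try:
            return self._df.loc[taxon, family]
        except KeyError as exc:
            raise KeyError(f"no cell ({taxon!r}, {family!r})") from exc

    def set(self, taxon: str, family: str, state: str) -> None:
        if state not in STATES:
            raise MatrixFormatError(f"illegal state {state!r}")
        self._df.loc[taxon, family] = state

    def column(self, family: str) -> dict[str, str]:
        if family not in self._df.columns:
            raise KeyError(f"no family {family!r}")
        return dict(self._df[family])

    def subset(self, taxa: Sequence[str] | None = None,
               families: Sequence[str] | None = None) -> "PhyleticMatrix":
        taxa = self.taxa if taxa is None else list(taxa)
        families = self.families if families is None else list(families)
        missing = [t for t in taxa if t not in self._df.index]
        missing += [f for f in families if f not in self._df.columns]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        return PhyleticMatrix(taxa, families, self._df.loc[taxa, families])

    def present_taxa(self, family: str) -> list[str]:
        col = self._df[family]
        return list(col.index[col == PRESENT])

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, PhyleticMatrix)
                and self._df.equals(other._df))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyleticMatrix({len(self.taxa)} taxa x {len(self.families)} families)"


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_matrix(source) -> PhyleticMatrix:
    """Read a phyletic matrix from a TSV path or open text handle."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise MatrixFormatError("empty file: missing header row")
    header = lines[0].split("\t")
    families = header[1:]
    taxa: list[str] = []
    cells: dict[tuple[str, str], str] = {}
    for row_no, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise MatrixFormatError(
                f"ragged row at line {row_no}: expected {len(header)} fields, "
                f"got {len(fields)}")
        taxon = fields[0]
        taxa.append(taxon)
        for family, cell in zip(families, fields[1:]):
            cell = cell.strip()
            if cell not in _CELL_TO_STATE:
                raise MatrixFormatError(
                    f"illegal cell token {cell!r} at row {taxon!r}, "
                    f"column {family!r}")
            cells[(taxon, family)] = _CELL_TO_STATE[cell]
    return PhyleticMatrix(taxa, families, cells)


def write_matrix(matrix: PhyleticMatrix, dest=None) -> str:
    """Write to TSV; returns the text (and writes to ``dest`` if given)."""
    out = io.StringIO()
    out.write("\t" + "\t".join(matrix.families) + "\n")
    df = matrix.frame
    for taxon in matrix.taxa:
        row = [taxon] + [_STATE_TO_CELL[df.loc[taxon, f]] for f in matrix.families]
        out.write("\t".join(row) + "\n")
    text = out.getvalue()
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Combination
# ---------------------------------------------------------------------------


def merge(a: PhyleticMatrix, b: PhyleticMatrix) -> PhyleticMatrix:
    """Union of taxa and families; cells defined in neither become unknown.

    A cell observed in both inputs must agree (unknown never conflicts);
    disagreement raises :class:`MatrixConflictError` listing the cells.
    """
    taxa = list(dict.fromkeys(a.taxa + b.taxa))
    families = list(dict.fromkeys(a.families + b.families))
    conflicts: list[tuple[str, str]] = []
    cells: dict[tuple[str, str], str] = {}
    for m in (a, b):
        df = m.frame
        for taxon in m.taxa:
            for family in m.families:
                state = df.loc[taxon, family]
                if state == UNKNOWN:
                    continue
                prev = cells.get((taxon, family))
                if prev is not None and prev != state:
                    conflicts.append((taxon, family))
                cells[(taxon, family)] = state
    if conflicts:
        raise MatrixConflictError(conflicts)
    return PhyleticMatrix(taxa, families, cells)


def matrix_from_assignments(
    assignments: Iterable[tuple[str, str]],
    surveyed_taxa: Sequence[str],
    families: Sequence[str] = EIGHT_FAMILIES,
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
) -> PhyleticMatrix:
    """Build a presence/absence matrix from (taxon, family) assignments.

    Surveyed taxa with no assignment for a family are scored absent;
    taxa outside ``surveyed_taxa`` that appear in assignments raise, so
    unsurveyed taxa simply do not occur (their state would be unknown).
    """
    vocab = set(vocabulary)
    surveyed = list(surveyed_taxa)
    surveyed_set = set(surveyed)
    cells = {(t, f): ABSENT for t in surveyed for f in families}
    for taxon, family in assignments:
        if family not in vocab:
            raise VocabularyError(f"unknown family label {family!r}")
        if family not in families:
            raise VocabularyError(
                f"family {family!r} not among matrix columns {list(families)}")
        if taxon not in surveyed_set:
            raise KeyError(f"assignment for unsurveyed taxon {taxon!r}")
        cells[(taxon, family)] = PRESENT
    return PhyleticMatrix(surveyed, list(families), cells)
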