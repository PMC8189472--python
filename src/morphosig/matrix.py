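"""Morphological character matrices in TNT dialect (plus a minimal NEXUS subset).

A matrix cell is a frozenset of integer states.  Polymorphic observations
(``[01]`` tokens) are kept as multi-state sets and optimised as such.  Missing
data is represented by the empty frozenset :data:`MISSING`; both ``?`` and
``-`` (gap / inapplicable) map to it, which is how TNT treats them for
unordered parsimony.  Character numbering is 1-based everywhere in the public
interface, matching the usual convention of published morphological datasets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Sentinel for a missing / inapplicable cell.
MISSING: frozenset = frozenset()


class MatrixParseError(ValueError):
    """Raised when a character-matrix file cannot be interpreted."""


class UnsupportedSettingError(MatrixParseError):
    """Raised when a file declares ordered or differentially weighted characters."""


def normalize_label(label: str) -> str:
    """Collapse whitespace in a taxon label to single underscores."""
    return "_".join(label.split())


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of state sets.

    Parameters
    ----------
    taxa:
        Ordered, unique taxon labels.
    rows:
        One list of frozensets per taxon, all of equal length.  The empty
        frozenset means missing.
    """

    taxa: list[str]
    rows: list[list[frozenset]]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if len(self.rows) != len(self.taxa):
            raise ValueError("one row per taxon required")
        if self.rows:
            n = len(self.rows[0])
            for taxon, row in zip(self.taxa, self.rows):
                if len(row) != n:
                    raise ValueError(
                        f"taxon {taxon!r} has {len(row)} cells, expected {n}"
                    )

    # -- basic queries ----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def char_ids(self) -> range:
        """1-based character numbers."""
        return range(1, self.n_chars + 1)

    def row_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in matrix") from None

    def cell(self, taxon: str, char_id: int) -> frozenset:
        return self.rows[self.row_index(taxon)][self._col(char_id)]

    def _col(self, char_id: int) -> int:
        if not 1 <= char_id <= self.n_chars:
            raise KeyError(f"character id {char_id} out of range 1..{self.n_chars}")
        return char_id - 1

    def column(self, char_id: int) -> list[frozenset]:
        c = self._col(char_id)
        return [row[c] for row in self.rows]

    def state_alphabet(self, char_id: int) -> frozenset:
        """Set of observed states for one character (empty if all missing)."""
        alph: set = set()
        for cell in self.column(char_id):
            alph |= cell
        return frozenset(alph)

    # -- derived matrices -------------------------------------------------
    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(list(self.taxa), [list(r) for r in self.rows])

    def drop_taxa(self, labels: Iterable[str]) -> "CharacterMatrix":
        drop = {normalize_label(t) for t in labels}
        unknown = drop - set(self.taxa)
        if unknown:
            raise KeyError(f"taxa not in matrix: {sorted(unknown)}")
        keep = [i for i, t in enumerate(self.taxa) if t not in drop]
        return CharacterMatrix(
            [self.taxa[i] for i in keep], [list(self.rows[i]) for i in keep]
        )

    def with_cells(
        self, updates: Mapping[tuple[str, int], frozenset]
    ) -> "CharacterMatrix":
        """Return a copy with the given (taxon, char_id) cells replaced."""
        out = self.copy()
        for (taxon, cid), value in updates.items():
            out.rows[out.row_index(taxon)][out._col(cid)] = frozenset(value)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return self.taxa == other.taxa and self.rows == other.rows


@dataclass(frozen=True)
class Partition:
    """A named subset of 1-based character ids."""

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(int(m) for m in self.members))


def default_partitions(n_chars: int = 189) -> dict[str, Partition]:
    """Postcranial / dermal / cranial partition of an 189-character matrix.

    Postcranial = characters 1-37 and 189; dermal shield = 38-46, 183, 184;
    cranial = the remaining 140 characters.
    """
    post = set(range(1, 38)) | {189}
    dermal = set(range(38, 47)) | {183, 184}
    cranial = set(range(1, n_chars + 1)) - post - dermal
    return {
        "postcranial": Partition("postcranial", frozenset(post)),
        "dermal": Partition("dermal", frozenset(dermal)),
        "cranial": Partition("cranial", frozenset(cranial)),
    }


# ---------------------------------------------------------------------------
# tokenising
# ---------------------------------------------------------------------------

_OPEN = {"[": "]", "(": ")", "{": "}"}
_STATEDATA = re.compile(r"[0-9?\-\[\]\(\)\{\}]+")


def _parse_state_tokens(
    data: str, n_expected: int | None, taxon: str, missing: str = "?", gap: str = "-"
) -> list[frozenset]:
    cells: list[frozenset] = []
    i = 0
    while i < len(data):
        ch = data[i]
        if ch.isspace():
            i += 1
            continue
        if ch in (missing, gap):
            cells.append(MISSING)
            i += 1
        elif ch.isdigit():
            cells.append(frozenset({int(ch)}))
            i += 1
        elif ch in _OPEN:
            close = _OPEN[ch]
            j = data.find(close, i + 1)
            if j < 0:
                raise MatrixParseError(
                    f"taxon {taxon!r}: unterminated polymorphism token at column "
                    f"{len(cells) + 1}"
                )
            inner = data[i + 1 : j]
            states = {int(c) for c in inner if c.isdigit()}
            if not states or any(not (c.isdigit() or c.isspace()) for c in inner):
                raise MatrixParseError(
                    f"taxon {taxon!r}: bad polymorphism token {data[i:j+1]!r} at "
                    f"column {len(cells) + 1}"
                )
            cells.append(frozenset(states))
            i = j + 1
        else:
            raise MatrixParseError(
                f"taxon {taxon!r}: unknown token {ch!r} at column {len(cells) + 1}"
            )
    if n_expected is not None and len(cells) != n_expected:
        raise MatrixParseError(
            f"taxon {taxon!r} has {len(cells)} characters, header declares "
            f"{n_expected}"
        )
    return cells


_CCODE_ORDERED = re.compile(r"[+]")
_CCODE_WEIGHT = re.compile(r"/\s*(\d+)")


def _check_ccode(body: str) -> None:
    if _CCODE_ORDERED.search(body):
        raise UnsupportedSettingError(
            "ccode declares ordered (additive) characters; only unordered, "
            "equally weighted characters are supported"
        )
    for m in _CCODE_WEIGHT.finditer(body):
        if int(m.group(1)) != 1:
            raise UnsupportedSettingError(
                "ccode declares differential character weights; only equal "
                "weights are supported"
            )


# ---------------------------------------------------------------------------
# TNT reader / writer
# ---------------------------------------------------------------------------


def parse_tnt(text: str) -> CharacterMatrix:
    """Parse an xread-style TNT matrix (or dispatch a NEXUS file).

    Accepts a leading ``xread`` keyword with an optional quoted title, a
    dimensions line ``n_chars n_taxa``, taxon rows (interleaving allowed: a
    repeated label appends states), and trailing TNT commands, which are
    ignored with a warning unless they declare character ordering or unequal
    weights (``ccode``), which raises :class:`UnsupportedSettingError`.
    """
    stripped = text.lstrip()
    if stripped[:6].upper() == "#NEXUS":
        return parse_nexus(text)

    # strip single-quoted titles/comments (TNT style)
    body = re.sub(r"'[^']*'", " ", text)
    m = re.search(r"\bxread\b", body, flags=re.IGNORECASE)
    if m:
        body = body[m.end() :]

    head = re.match(r"\s*(\d+)\s+(\d+)", body)
    if not head:
        raise MatrixParseError("could not find dimensions line 'n_chars n_taxa'")
    n_chars, n_taxa = int(head.group(1)), int(head.group(2))
    body = body[head.end() :]

    matrix_part, _, trailer = body.partition(";")

    order: list[str] = []
    chunks: dict[str, str] = {}
    for line in matrix_part.splitlines():
        line = line.strip()
        if not line or line.startswith("&"):  # interleave block marker
            continue
        parts = line.split()
        # trailing chunks made only of state tokens are data; the rest is an
        # (unquoted, possibly multi-word) taxon label
        split_at = len(parts)
        while split_at > 1 and _STATEDATA.fullmatch(parts[split_at - 1]):
            split_at -= 1
        label = normalize_label(" ".join(parts[:split_at]))
        data = "".join(parts[split_at:])
        if not data and len(parts) > 1:
            # no clean state chunk: fall back so bad tokens are reported
            label = normalize_label(parts[0])
            data = "".join(parts[1:])
        if not data:
            raise MatrixParseError(f"taxon {label!r}: row has no character data")
        if label not in chunks:
            order.append(label)
            chunks[label] = data
        else:
            chunks[label] += data

    if len(order) != n_taxa:
        raise MatrixParseError(
            f"header declares {n_taxa} taxa but {len(order)} rows were found"
        )

    taxa = order
    rows = [_parse_state_tokens(chunks[t], n_chars, t) for t in taxa]

    for command in trailer.split(";"):
        command = command.strip()
        if not command:
            continue
        word, _, rest = command.partition(" ")
        word = word.lower()
        if word == "ccode":
            _check_ccode(rest)
        elif word in {"proc", "procedure", "cnames", "comments", "nstates", "mxram"}:
            continue
        else:
            logger.warning("ignoring trailing TNT command: %s", word)

    return CharacterMatrix(taxa, rows)


def write_tnt(matrix: CharacterMatrix) -> str:
    """Serialise a matrix as a TNT xread block re-parseable by :func:`parse_tnt`."""

    def token(cell: frozenset) -> str:
        if not cell:
            return "?"
        if len(cell) == 1:
            return str(next(iter(cell)))
        return "[" + "".join(str(s) for s in sorted(cell)) + "]"

    width = max((len(t) for t in matrix.taxa), default=0) + 2
    lines = ["xread", f"{matrix.n_chars} {matrix.n_taxa}"]
    for taxon, row in zip(matrix.taxa, matrix.rows):
        lines.append(taxon.ljust(width) + "".join(token(c) for c in row))
    lines.append(";")
    lines.append("proc /;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# minimal NEXUS subset
# ---------------------------------------------------------------------------


def parse_nexus(text: str) -> CharacterMatrix:
    """Read a minimal NEXUS CHARACTERS/DATA block (MATRIX, MISSING, GAP)."""
    nt = re.search(r"NTAX\s*=\s*(\d+)", text, re.IGNORECASE)
    nc = re.search(r"NCHAR\s*=\s*(\d+)", text, re.IGNORECASE)
    if not nc:
        raise MatrixParseError("NEXUS file lacks an NCHAR declaration")
    n_chars = int(nc.group(1))
    n_taxa = int(nt.group(1)) if nt else None

    missing = "?"
    gap = "-"
    fmt = re.search(r"FORMAT\s+([^;]*);", text, re.IGNORECASE | re.DOTALL)
    if fmt:
        fm = re.search(r"MISSING\s*=\s*(\S)", fmt.group(1), re.IGNORECASE)
        gm = re.search(r"GAP\s*=\s*(\S)", fmt.group(1), re.IGNORECASE)
        if fm:
            missing = fm.group(1)
        if gm:
            gap = gm.group(1)

    mat = re.search(r"\bMATRIX\b(.*?);", text, re.IGNORECASE | re.DOTALL)
    if not mat:
        raise MatrixParseError("NEXUS file lacks a MATRIX block")

    order: list[str] = []
    chunks: dict[str, str] = {}
    for line in mat.group(1).splitlines():
        line = line.split("[")[0].strip()
        if not line:
            continue
        if line.startswith(("'", '"')):
            quote = line[0]
            end = line.find(quote, 1)
            if end < 0:
                raise MatrixParseError(f"unterminated quoted label: {line!r}")
            label = normalize_label(line[1:end])
            data = "".join(line[end + 1 :].split())
        else:
            parts = line.split()
            label = normalize_label(parts[0])
            data = "".join(parts[1:])
        if label not in chunks:
            order.append(label)
            chunks[label] = data
        else:
            chunks[label] += data

    if n_taxa is not None and len(order) != n_taxa:
        raise MatrixParseError(
            f"NTAX={n_taxa} but {len(order)} matrix rows were found"
        )
    rows = [
        _parse_state_tokens(chunks[t], n_chars, t, missing=missing, gap=gap)
        for t in order
    ]
    return CharacterMatrix(order, rows)


# ---------------------------------------------------------------------------
# auditing
# ---------------------------------------------------------------------------


def diff_matrices(
    a: CharacterMatrix, b: CharacterMatrix
) -> list[tuple[str, int, frozenset, frozenset]]:
    """All cells where two matrices over the same taxa disagree.

    Returns ``(taxon, char_id, state_a, state_b)`` tuples; the list is empty
    iff the matrices are equal under cell-wise set equality.  Taxon order may
    differ between the inputs; the output follows ``a``'s order.
    """
    if set(a.taxa) != set(b.taxa):
        sym = sorted(set(a.taxa) ^ set(b.taxa))
        raise ValueError(f"taxon sets differ; symmetric difference: {sym}")
    if a.n_chars != b.n_chars:
        raise ValueError(
            f"character counts differ: {a.n_chars} vs {b.n_chars}"
        )
    diffs = []
    for taxon in a.taxa:
        ra = a.rows[a.row_index(taxon)]
        rb = b.rows[b.row_index(taxon)]
        for col, (ca, cb) in enumerate(zip(ra, rb)):
            if ca != cb:
                diffs.append((taxon, col + 1, ca, cb))
    return diffs
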