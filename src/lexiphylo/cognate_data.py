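"""Binary cognate matrices: ingestion, validation, filtering, partitioning.

A cognate matrix records, for each documented language variety (*doculect*)
and each cognate set, whether the doculect attests a reflex of that cognate
(1), lacks it (0), or was never elicited for the cognate's meaning (missing).
Cognate sets are grouped into *meanings* (semantic slots such as "hand");
missingness operates at the meaning level: a doculect is either coded for all
cognate sets of a meaning or for none of them.

Two interchange formats are supported:

* a NEXUS DATA block (datatype=standard, symbols="01", missing=?, gap=-)
  with CHARSTATELABELS naming each column ``<meaning>_<cognate id>`` and a
  SETS block carrying one CHARSET per meaning plus a ``subcognates`` charset
  flagging sub-cognate columns;
* a tab-separated long table with columns
  ``doculect  meaning  cognate  state  subcognate`` (one row per cell;
  ``state`` in {0, 1, ?}; ``subcognate`` in {0, 1}).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CognateSet", "CognateMatrix", "PartitionScheme",
    "CognateParseError", "CognateSchemaError", "EmptyResultError",
    "read_cognate_matrix", "write_cognate_matrix",
]

MISSING = -1
ABSENT = 0
PRESENT = 1

LONG_TABLE_COLUMNS = ["doculect", "meaning", "cognate", "state", "subcognate"]


class CognateParseError(ValueError):
    """Malformed input (unknown symbol, bad dimensions)."""


class CognateSchemaError(ValueError):
    """Structurally invalid matrix (missing meaning labels, empty blocks)."""


class EmptyResultError(ValueError):
    """A filter removed everything."""


@dataclass(frozen=True)
class CognateSet:
    id: str
    meaning: str
    subcognate: bool = False


@dataclass
class CognateMatrix:
    """Doculect x cognate-set binary matrix with meaning grouping.

    ``cells`` holds -1 (missing), 0 (absent) or 1 (present), shaped
    (n_doculects, n_cognates) with rows/columns ordered as ``doculects`` /
    ``cognate_sets``.
    """

    doculects: list[str]
    cognate_sets: list[CognateSet]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.doculects), len(self.cognate_sets)):
            raise CognateSchemaError(
                f"cell block shape {self.cells.shape} does not match "
                f"{len(self.doculects)} doculects x {len(self.cognate_sets)} cognates")
        if len(set(self.doculects)) != len(self.doculects):
            raise CognateSchemaError("duplicate doculect identifiers")
        ids = [c.id for c in self.cognate_sets]
        if len(set(ids)) != len(ids):
            raise CognateSchemaError("duplicate cognate-set identifiers")
        bad = set(np.unique(self.cells)) - {MISSING, ABSENT, PRESENT}
        if bad:
            raise CognateParseError(f"invalid cell states: {sorted(bad)}")

    # ------------------------------------------------------------ properties
    # matrices are treated as immutable after construction, so the meaning
    # layout is computed once and cached (the likelihood hot path needs it)
    @property
    def meanings(self) -> list[str]:
        cache = self.__dict__.get("_meanings")
        if cache is None:
            seen: dict[str, None] = {}
            for c in self.cognate_sets:
                seen.setdefault(c.meaning, None)
            cache = self.__dict__["_meanings"] = list(seen)
        return cache

    @property
    def n_doculects(self) -> int:
        return len(self.doculects)

    @property
    def n_cognates(self) -> int:
        return len(self.cognate_sets)

    @property
    def n_meanings(self) -> int:
        return len(self.meanings)

    def columns_for_meaning(self, meaning: str) -> list[int]:
        cache = self.__dict__.get("_meaning_columns")
        if cache is None:
            cache = {}
            for j, c in enumerate(self.cognate_sets):
                cache.setdefault(c.meaning, []).append(j)
            self.__dict__["_meaning_columns"] = cache
        return cache[meaning]

    def coverage(self, meaning: str) -> np.ndarray:
        """Boolean vector over doculects: coded (non-missing) for this meaning."""
        cols = self.columns_for_meaning(meaning)
        return self.cells[:, cols[0]] != MISSING

    # ------------------------------------------------------------ validation
    def validate(self, min_doculects: int = 2, min_cognates: int = 1) -> None:
        if self.n_doculects < min_doculects or self.n_cognates < min_cognates:
            raise CognateSchemaError(
                f"matrix too small: {self.n_doculects} doculects, "
                f"{self.n_cognates} cognate sets")
        for meaning in self.meanings:
            cols = self.columns_for_meaning(meaning)
            block = self.cells[:, cols]
            missing = block == MISSING
            partial = np.any(missing, axis=1) & ~np.all(missing, axis=1)
            if np.any(partial):
                rows = [self.doculects[i] for i in np.where(partial)[0]]
                raise CognateSchemaError(
                    f"meaning {meaning!r}: doculects {rows} are partially coded "
                    "(missingness must be meaning-level)")

    # -------------------------------------------------------------- filtering
    def drop_subcognates(self) -> "CognateMatrix":
        """Remove sub-cognate columns (finer sound-change codings)."""
        keep = [j for j, c in enumerate(self.cognate_sets) if not c.subcognate]
        if not keep:
            raise EmptyResultError("all cognate sets are flagged as sub-cognates")
        return CognateMatrix(
            doculects=list(self.doculects),
            cognate_sets=[self.cognate_sets[j] for j in keep],
            cells=self.cells[:, keep].copy(),
        )

    def filter_doculects(self, min_cognates: int = 80) -> tuple["CognateMatrix", list[str]]:
        """Drop doculects with fewer than ``min_cognates`` present-state cells.

        Returns the filtered matrix and the list of cognate-set ids that are
        left without any present cell (reported, not dropped).
        """
        if min_cognates < 1:
            raise ValueError("min_cognates must be >= 1")
        counts = (self.cells == PRESENT).sum(axis=1)
        keep = np.where(counts >= min_cognates)[0]
        if keep.size == 0:
            raise EmptyResultError(
                f"no doculect has >= {min_cognates} present cognate sets")
        sub = CognateMatrix(
            doculects=[self.doculects[i] for i in keep],
            cognate_sets=list(self.cognate_sets),
            cells=self.cells[keep, :].copy(),
        )
        emptied = [c.id for j, c in enumerate(sub.cognate_sets)
                   if not np.any(sub.cells[:, j] == PRESENT)]
        return sub, emptied

    # ------------------------------------------------------------ statistics
    def empirical_state_frequencies(self) -> tuple[float, float]:
        """(f_absent, f_present) over non-missing cells."""
        observed = self.cells != MISSING
        n_obs = int(observed.sum())
        if n_obs == 0:
            raise CognateSchemaError("all cells missing; frequencies undefined")
        n_present = int((self.cells == PRESENT).sum())
        return (n_obs - n_present) / n_obs, n_present / n_obs

    def meaning_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.cognate_sets:
            out[c.meaning] = out.get(c.meaning, 0) + 1
        return out


@dataclass(frozen=True)
class PartitionScheme:
    """Meanings binned by their number of cognate sets: [1, w], [w+1, 2w], ..."""

    bins: dict[str, frozenset[str]]
    bin_width: int

    @property
    def labels(self) -> list[str]:
        return sorted(self.bins, key=lambda lab: int(lab.split("-")[0]))

    def bin_of(self, meaning: str) -> str:
        for lab, members in self.bins.items():
            if meaning in members:
                return lab
        raise KeyError(f"meaning {meaning!r} not in any bin")


def partition_by_meaning_size(matrix: CognateMatrix, bin_width: int = 10) -> PartitionScheme:
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    bins: dict[str, set[str]] = {}
    for meaning, size in matrix.meaning_sizes().items():
        k = (size - 1) // bin_width
        lab = f"{k * bin_width + 1}-{(k + 1) * bin_width}"
        bins.setdefault(lab, set()).add(meaning)
    return PartitionScheme(bins={k: frozenset(v) for k, v in bins.items()},
                           bin_width=bin_width)


# ------------------------------------------------------------------ NEXUS I/O

_STATE_FROM_SYMBOL = {"0": ABSENT, "1": PRESENT, "?": MISSING, "-": MISSING}
_SYMBOL_FROM_STATE = {ABSENT: "0", PRESENT: "1", MISSING: "?"}


def to_nexus(matrix: CognateMatrix) -> str:
    lines = ["#NEXUS", "", "BEGIN DATA;",
             f"DIMENSIONS NTAX={matrix.n_doculects} NCHAR={matrix.n_cognates};",
             'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
             "CHARSTATELABELS"]
    labels = [
        "    {} {}".format(
            j + 1,
            c.id if c.id.startswith(c.meaning + "_") else f"{c.meaning}_{c.id}")
        for j, c in enumerate(matrix.cognate_sets)
    ]
    lines.append(",\n".join(labels) + ";")
    lines.append("MATRIX")
    width = max(len(d) for d in matrix.doculects) + 2
    for i, d in enumerate(matrix.doculects):
        row = "".join(_SYMBOL_FROM_STATE[int(s)] for s in matrix.cells[i])
        lines.append(f"{d:<{width}}{row}")
    lines += [";", "END;", "", "BEGIN SETS;"]
    for meaning in matrix.meanings:
        cols = matrix.columns_for_meaning(meaning)
        idx = " ".join(str(j + 1) for j in cols)
        lines.append(f"CHARSET {meaning} = {idx};")
    subs = [j + 1 for j, c in enumerate(matrix.cognate_sets) if c.subcognate]
    if subs:
        lines.append("CHARSET subcognates = " + " ".join(map(str, subs)) + ";")
    lines += ["END;", ""]
    return "\n".join(lines)


def _parse_charset_indices(body: str) -> list[int]:
    out: list[int] = []
    for tok in body.split():
        if "-" in tok and not tok.startswith("-"):
            a, b = tok.split("-")
            out.extend(range(int(a), int(b) + 1))
        else:
            out.append(int(tok))
    return out


def from_nexus(text: str) -> CognateMatrix:
    """Parse the package's NEXUS data dialect (see module docstring)."""
    m = re.search(r"MATRIX\s*(.*?);", text, re.S | re.I)
    if m is None or not m.group(1).strip():
        raise CognateSchemaError("empty or missing MATRIX block")
    dim = re.search(r"DIMENSIONS\s+NTAX\s*=\s*(\d+)\s+NCHAR\s*=\s*(\d+)", text, re.I)
    if dim is None:
        raise CognateParseError("missing DIMENSIONS line")
    ntax, nchar = int(dim.group(1)), int(dim.group(2))
    if nchar == 0 or ntax == 0:
        raise CognateSchemaError("empty character block")

    labels: list[str] = [""] * nchar
    lab = re.search(r"CHARSTATELABELS\s*(.*?);", text, re.S | re.I)
    if lab is None:
        raise CognateSchemaError("missing CHARSTATELABELS (meaning labels required)")
    for entry in lab.group(1).split(","):
        parts = entry.split()
        if len(parts) < 2:
            continue
        labels[int(parts[0]) - 1] = parts[1]

    doculects: list[str] = []
    rows: list[list[int]] = []
    for line in m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        name, _, symbols = line.partition(" ")
        symbols = symbols.replace(" ", "")
        states = []
        for k, ch in enumerate(symbols):
            if ch not in _STATE_FROM_SYMBOL:
                raise CognateParseError(
                    f"unknown symbol {ch!r} at row {name!r}, column {k + 1}")
            states.append(_STATE_FROM_SYMBOL[ch])
        if len(states) != nchar:
            raise CognateParseError(
                f"row {name!r} has {len(states)} states, expected {nchar}")
        doculects.append(name)
        rows.append(states)
    if len(doculects) != ntax:
        raise CognateParseError(f"found {len(doculects)} rows, expected NTAX={ntax}")

    meanings: list[str] = [""] * nchar
    sub_flags = [False] * nchar
    for cm in re.finditer(r"CHARSET\s+(\S+)\s*=\s*([^;]+);", text, re.I):
        name, body = cm.group(1), cm.group(2)
        idx = _parse_charset_indices(body)
        if name.lower() == "subcognates":
            for j in idx:
                sub_flags[j - 1] = True
        else:
            for j in idx:
                meanings[j - 1] = name

    cognate_sets = []
    for j in range(nchar):
        if not meanings[j]:
            raise CognateSchemaError(
                f"column {j + 1} ({labels[j] or 'unnamed'}) has no meaning charset")
        cognate_sets.append(CognateSet(id=labels[j], meaning=meanings[j],
                                       subcognate=sub_flags[j]))
    return CognateMatrix(doculects=doculects, cognate_sets=cognate_sets,
                         cells=np.array(rows, dtype=np.int8))


# ------------------------------------------------------------- long-table I/O

def to_long_frame(matrix: CognateMatrix) -> pd.DataFrame:
    records = []
    for i, d in enumerate(matrix.doculects):
        for j, c in enumerate(matrix.cognate_sets):
            state = int(matrix.cells[i, j])
            records.append((d, c.meaning, c.id,
                            "?" if state == MISSING else str(state),
                            int(c.subcognate)))
    return pd.DataFrame.from_records(records, columns=LONG_TABLE_COLUMNS)


def from_long_frame(frame: pd.DataFrame) -> CognateMatrix:
    missing_cols = set(LONG_TABLE_COLUMNS[:4]) - set(frame.columns)
    if missing_cols:
        raise CognateSchemaError(f"long table lacks columns: {sorted(missing_cols)}")
    if "subcognate" not in frame.columns:
        frame = frame.assign(subcognate=0)
    doculects = list(dict.fromkeys(frame["doculect"]))
    cogs: dict[str, CognateSet] = {}
    for _, row in frame.drop_duplicates(["cognate"]).iterrows():
        cogs[row["cognate"]] = CognateSet(id=str(row["cognate"]),
                                          meaning=str(row["meaning"]),
                                          subcognate=bool(int(row["subcognate"])))
    meaning_of = frame.drop_duplicates(["cognate"]).set_index("cognate")["meaning"]
    conflicts = frame.groupby("cognate")["meaning"].nunique()
    if (conflicts > 1).any():
        bad = list(conflicts[conflicts > 1].index)
        raise CognateSchemaError(f"cognates mapped to multiple meanings: {bad}")
    cognate_sets = list(cogs.values())
    col_of = {c.id: j for j, c in enumerate(cognate_sets)}
    row_of = {d: i for i, d in enumerate(doculects)}
    cells = np.full((len(doculects), len(cognate_sets)), MISSING, dtype=np.int8)
    for d, cog, state in zip(frame["doculect"], frame["cognate"], frame["state"]):
        s = str(state)
        if s in ("?", "-"):
            val = MISSING
        elif s in ("0", "1"):
            val = int(s)
        else:
            raise CognateParseError(
                f"unknown state {state!r} for doculect {d!r}, cognate {cog!r}")
        cells[row_of[d], col_of[str(cog)]] = val
    return CognateMatrix(doculects=doculects, cognate_sets=cognate_sets, cells=cells)


# -------------------------------------------------------------- file plumbing

def read_cognate_matrix(path: str, format: str = "nexus_binary") -> CognateMatrix:
    """Read a cognate matrix from ``path`` in the given format.

    ``format`` is "nexus_binary" or "long_table".
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if format == "nexus_binary":
        matrix = from_nexus(text)
    elif format == "long_table":
        matrix = from_long_frame(pd.read_csv(path, sep="\t", dtype=str))
    else:
        raise ValueError(f"unknown format {format!r}")
    matrix.validate(min_doculects=2, min_cognates=1)
    return matrix


def write_cognate_matrix(matrix: CognateMatrix, path: str,
                         format: str = "nexus_binary") -> None:
    if format == "nexus_binary":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(to_nexus(matrix))
    elif format == "long_table":
        to_long_frame(matrix).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
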