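"""Dental-formula parsing and discrete character coding for Cypriniformes.

Cypriniformes bear teeth only on the paired fifth ceratobranchial (pharyngeal)
bones.  The dentition of one half-bone is summarised by a *dental formula*
listing the tooth count of each row.  The notation used here follows the
convention of the comparative literature:

* a symmetric species is written as a single comma-separated list for the
  left half-bone, **dorsal row first, ventral row last** — e.g. ``2,4,5``
  for the zebrafish (dorsal 2, mediodorsal 4, ventral 5 teeth);
* an asymmetric species appends the right half-bone in parentheses, written
  mirror-fashion **ventral row first** — e.g. ``2,3,5-(6,3,2)`` has a left
  ventral row of 5 teeth and a right ventral row of 6.

Internally both halves are stored ventral-first, so index 0 is always the
ventral row regardless of side.

Two discrete characters are derived for comparative analysis: the number of
tooth rows (0-3 in normal development) and the qualitative shape morphotype
of the (ventral-row) teeth, one of spoon, compressed, spatula, conical, saw
or molariform.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "MAX_ROWS",
    "MORPHOTYPES",
    "CLADES",
    "HalfFormula",
    "DentalFormula",
    "SpeciesRecord",
    "CharacterMatrix",
    "CharacterCoding",
    "DEFAULT_CODING",
    "SummaryStats",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "total_teeth",
    "is_asymmetric",
    "row_number_state",
    "build_character_matrix",
    "summarize",
    "load_species_table",
    "packaged_table_path",
    "MISSING",
]

#: sentinel for an unscored character state
MISSING = "?"

#: normal development shows 0-3 tooth rows; 4 is accepted for reported
#: abnormal specimens but never occurs in the packaged table
MAX_ROWS = 4

MORPHOTYPES = ("spoon", "compressed", "spatula", "conical", "saw", "molariform")

CLADES = (
    "Psilorhynchidae",
    "Rasborinae",
    "Cyprininae",
    "Cultrinae",
    "Acheilognathinae",
    "Gobioninae",
    "Tincinae",
    "Leuciscinae",
    "Catostomidae",
    "Cobitidae",
    "Gyrinocheilidae",
    "incertae-sedis",
)

SUPERFAMILIES = ("Cobitoidea", "Cyprinoidea", "outgroup")

SOURCES = ("scanned", "dissected", "literature")


class FormulaError(ValueError):
    """Raised when a dental-formula string violates the notation grammar."""


@dataclass(frozen=True)
class HalfFormula:
    """Tooth counts of one half-bone, stored ventral row first.

    ``counts[0]`` is the ventral row, the last entry the most dorsal row.
    An empty tuple denotes a toothless half-bone.
    """

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) > MAX_ROWS:
            raise FormulaError(
                f"at most {MAX_ROWS} tooth rows supported, got {len(self.counts)}"
            )
        for c in self.counts:
            if not isinstance(c, int) or c < 1:
                raise FormulaError(f"tooth counts must be positive integers, got {c!r}")

    @property
    def n_rows(self) -> int:
        return len(self.counts)

    @property
    def ventral(self) -> int | None:
        """Tooth count of the ventral row (None when toothless)."""
        return self.counts[0] if self.counts else None


@dataclass(frozen=True)
class DentalFormula:
    """Left and right half-bone formulae of one species."""

    left: HalfFormula
    right: HalfFormula
    source_string: str = ""

    @property
    def symmetric(self) -> bool:
        return self.left.counts == self.right.counts

    def __eq__(self, other: object) -> bool:  # source_string is provenance only
        if not isinstance(other, DentalFormula):
            return NotImplemented
        return self.left == other.left and self.right == other.right

    def __hash__(self) -> int:
        return hash((self.left, self.right))


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of the packaged character table."""

    taxon: str
    clade: str
    superfamily: str
    formula: DentalFormula | None = None
    row_count_only: int | None = None
    shape: str | None = None
    source: str = "literature"
    specimen_ref: str = ""

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"unknown clade {self.clade!r}; expected one of {CLADES}")
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(
                f"unknown superfamily {self.superfamily!r}; expected one of {SUPERFAMILIES}"
            )
        if self.shape is not None and self.shape not in MORPHOTYPES:
            raise ValueError(
                f"unknown morphotype {self.shape!r}; expected one of {MORPHOTYPES}"
            )
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if self.formula is None and self.row_count_only is None:
            raise ValueError(
                f"{self.taxon}: a record needs a formula or a row count "
                "(toothless taxa carry row_count_only=0)"
            )

    @property
    def toothless(self) -> bool:
        return self.formula is None and self.row_count_only == 0


_FORMULA_RE = re.compile(r"^\s*([0-9, ]+?)\s*(?:-\s*\(\s*([0-9, ]+?)\s*\))?\s*$")


def _parse_counts(part: str, *, label: str) -> tuple[int, ...]:
    tokens = [tok.strip() for tok in part.split(",")]
    counts: list[int] = []
    for tok in tokens:
        if not tok:
            raise FormulaError(f"{label}: empty row entry in {part!r}")
        if not tok.isdigit():
            raise FormulaError(f"{label}: non-integer tooth count {tok!r}")
        value = int(tok)
        if value == 0:
            raise FormulaError(f"{label}: zero tooth count {tok!r} (toothless taxa carry no formula)")
        counts.append(value)
    if len(counts) > MAX_ROWS:
        raise FormulaError(f"{label}: more than {MAX_ROWS} rows in {part!r}")
    return tuple(counts)


def parse_formula(text: str) -> DentalFormula:
    """Parse a dental-formula string into a :class:`DentalFormula`.

    The grammar is ``LEFT [ "-(" RIGHT ")" ]``.  LEFT is written dorsal
    row first (so its *last* number is the ventral row); RIGHT, when
    present, is written mirror-fashion ventral row first.  When the
    parenthesised part is absent the dentition is symmetric.

    >>> f = parse_formula("2,3,5-(6,3,2)")
    >>> f.left.ventral, f.right.ventral
    (5, 6)
    """
    m = _FORMULA_RE.match(text or "")
    if not m:
        raise FormulaError(f"malformed dental formula {text!r}")
    left_part, right_part = m.group(1), m.group(2)
    left = HalfFormula(tuple(reversed(_parse_counts(left_part, label="left half"))))
    if right_part is None:
        right = left
    else:
        right = HalfFormula(_parse_counts(right_part, label="right half"))
    if not left.counts:
        raise FormulaError(f"empty left half in {text!r}")
    return DentalFormula(left=left, right=right, source_string=text.strip())


def format_formula(f: DentalFormula) -> str:
    """Canonical table-notation string; inverse of :func:`parse_formula`."""
    if not f.left.counts or not f.right.counts:
        raise FormulaError("toothless taxa carry no formula")
    left = ",".join(str(c) for c in reversed(f.left.counts))
    if f.symmetric:
        return left
    right = ",".join(str(c) for c in f.right.counts)
    return f"{left}-({right})"


def total_teeth(h: HalfFormula) -> int:
    """Total functional teeth on one half-bone."""
    return sum(h.counts)


def is_asymmetric(f: DentalFormula) -> bool:
    """True when the two half-bones differ in any row count or row number."""
    return not f.symmetric


def row_number_state(r: SpeciesRecord) -> int | None:
    """Tooth-row-number character state of one species.

    When a bilateral formula exists the state is the larger of the two
    halves' row numbers (an asymmetric species with 2 rows on one side and
    3 on the other is scored as having three rows).  Literature records
    without a formula use their stated row count; toothless taxa score 0.
    Returns None (missing) when nothing is known.
    """
    if r.formula is not None:
        return max(r.formula.left.n_rows, r.formula.right.n_rows)
    if r.row_count_only is not None:
        return r.row_count_only
    return None


@dataclass(frozen=True)
class CharacterCoding:
    """Retained state spaces and excluded-state policy for matrix building.

    Rare states are excluded from likelihood reconstruction because with few
    species per state they would otherwise be drawn towards ancestral nodes.
    ``policy`` is either ``"treat-as-missing"`` (default; keeps the taxon on
    the tree with an uninformative state) or ``"prune-taxon"``.
    """

    row_states: tuple[int, ...] = (1, 2, 3)
    shape_states: tuple[str, ...] = ("conical", "spoon", "compressed")
    policy: str = "treat-as-missing"

    def __post_init__(self) -> None:
        if self.policy not in ("treat-as-missing", "prune-taxon"):
            raise ValueError(
                f"unknown excluded-state policy {self.policy!r}; "
                "expected 'treat-as-missing' or 'prune-taxon'"
            )


DEFAULT_CODING = CharacterCoding()


@dataclass
class CharacterMatrix:
    """Taxa x discrete characters with explicit ordered state spaces.

    ``states[name]`` is the ordered retained state space of character
    ``name``; ``data[name][taxon]`` is a state label from that space or
    :data:`MISSING`.
    """

    taxa: list[str]
    states: dict[str, list[str]]
    data: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = [t for t, n in Counter(self.taxa).items() if n > 1]
            raise ValueError(f"duplicate taxa in matrix: {dupes}")
        for name, column in self.data.items():
            space = set(self.states[name]) | {MISSING}
            for taxon, state in column.items():
                if state not in space:
                    raise ValueError(
                        f"character {name!r}: state {state!r} of {taxon} not in "
                        f"declared space {self.states[name]}"
                    )

    def tip_states(self, character: str) -> dict[str, str]:
        """Taxon -> state mapping (missing entries included as '?')."""
        return dict(self.data[character])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: pd.Series(col) for name, col in self.data.items()}
        ).reindex(self.taxa)


def build_character_matrix(
    records: Sequence[SpeciesRecord],
    coding: CharacterCoding = DEFAULT_CODING,
) -> CharacterMatrix:
    """Code the two analysis characters from species records.

    Character ``rows`` retains states {1,2,3}: the toothless state 0 is
    excluded as rare.  Character ``shape`` retains {conical, spoon,
    compressed}: the rare spatula, molariform and saw morphotypes are
    excluded.  Excluded observations become missing (default) or their
    taxon is dropped from the matrix, per ``coding.policy``.
    """
    row_space = [str(s) for s in coding.row_states]
    shape_space = list(coding.shape_states)
    for s in shape_space:
        if s not in MORPHOTYPES:
            raise ValueError(f"unknown morphotype {s!r}; expected labels from {MORPHOTYPES}")

    taxa: list[str] = []
    rows_col: dict[str, str] = {}
    shape_col: dict[str, str] = {}
    for r in records:
        row_state = row_number_state(r)
        rows_val = MISSING if row_state is None else str(row_state)
        shape_val = MISSING if r.shape is None else r.shape
        excluded = (rows_val != MISSING and rows_val not in row_space) or (
            shape_val != MISSING and shape_val not in shape_space
        )
        if excluded and coding.policy == "prune-taxon":
            continue
        if rows_val != MISSING and rows_val not in row_space:
            rows_val = MISSING
        if shape_val != MISSING and shape_val not in shape_space:
            shape_val = MISSING
        taxa.append(r.taxon)
        rows_col[r.taxon] = rows_val
        shape_col[r.taxon] = shape_val

    return CharacterMatrix(
        taxa=taxa,
        states={"rows": row_space, "shape": shape_space},
        data={"rows": rows_col, "shape": shape_col},
    )


@dataclass
class SummaryStats:
    """Descriptive statistics of a species table."""

    n_species: int
    n_by_source: dict[str, int]
    n_cyprinoidea: int
    n_cyprinoidea_with_formula: int
    n_cyprinoidea_asymmetric: int
    morphotypes_cyprinoidea: set[str]
    morphotypes_order: set[str]
    per_species_total: dict[str, int]
    per_species_max_row: dict[str, int]
    max_ventral_by_species: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_by_source": dict(self.n_by_source),
            "n_cyprinoidea": self.n_cyprinoidea,
            "n_cyprinoidea_with_formula": self.n_cyprinoidea_with_formula,
            "n_cyprinoidea_asymmetric": self.n_cyprinoidea_asymmetric,
            "n_morphotypes_cyprinoidea": len(self.morphotypes_cyprinoidea),
            "morphotypes_cyprinoidea": sorted(self.morphotypes_cyprinoidea),
            "n_morphotypes_order": len(self.morphotypes_order),
            "morphotypes_order": sorted(self.morphotypes_order),
        }


def summarize(records: Sequence[SpeciesRecord]) -> SummaryStats:
    """Descriptive statistics mirroring the survey's headline counts.

    The asymmetry cohort is the set of Cyprinoidea species with a complete
    bilateral formula: row-count-only literature records cannot be scored
    for asymmetry and are excluded from the denominator.
    """
    n_by_source = Counter(r.source for r in records)
    cyp = [r for r in records if r.superfamily == "Cyprinoidea"]
    cyp_formula = [r for r in cyp if r.formula is not None]
    asym = [r for r in cyp_formula if is_asymmetric(r.formula)]
    per_total: dict[str, int] = {}
    per_max_row: dict[str, int] = {}
    max_ventral: dict[str, int] = {}
    for r in records:
        if r.formula is None:
            continue
        f = r.formula
        per_total[r.taxon] = max(total_teeth(f.left), total_teeth(f.right))
        per_max_row[r.taxon] = max(f.left.counts + f.right.counts)
        max_ventral[r.taxon] = max(
            c for c in (f.left.ventral, f.right.ventral) if c is not None
        )
    return SummaryStats(
        n_species=len(records),
        n_by_source=dict(n_by_source),
        n_cyprinoidea=len(cyp),
        n_cyprinoidea_with_formula=len(cyp_formula),
        n_cyprinoidea_asymmetric=len(asym),
        morphotypes_cyprinoidea={r.shape for r in cyp if r.shape is not None},
        morphotypes_order={r.shape for r in records if r.shape is not None},
        per_species_total=per_total,
        per_species_max_row=per_max_row,
        max_ventral_by_species=max_ventral,
    )


def _cell(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def load_species_table(path: str | Path | None = None) -> list[SpeciesRecord]:
    """Read a UTF-8 TSV character table into species records.

    Columns: taxon / clade / superfamily / formula / row_count_only / shape /
    source / specimen_ref; empty cells denote absent values.  With no path
    the packaged survey table is loaded.
    """
    if path is None:
        path = packaged_table_path()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"taxon", "clade", "superfamily", "formula", "row_count_only", "shape", "source"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"character table is missing columns: {sorted(missing_cols)}")
    records: list[SpeciesRecord] = []
    for _, row in df.iterrows():
        formula_text = _cell(row["formula"])
        row_count = _cell(row["row_count_only"])
        shape = _cell(row["shape"])
        records.append(
            SpeciesRecord(
                taxon=_cell(row["taxon"]) or "",
                clade=_cell(row["clade"]) or "",
                superfamily=_cell(row["superfamily"]) or "",
                formula=parse_formula(formula_text) if formula_text else None,
                row_count_only=int(row_count) if row_count is not None else None,
                shape=shape.lower() if shape else None,
                source=_cell(row["source"]) or "",
                specimen_ref=_cell(row.get("specimen_ref", "")) or "",
            )
        )
    return records


def packaged_table_path() -> Path:
    """Filesystem path of the packaged survey character table."""
    return Path(str(resources.files("cyprodent").joinpath("data", "table1.tsv")))
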