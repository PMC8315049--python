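"""Domain types and tabular I/O for cartilage-secretome abundance data.

The canonical on-disk representation is long (tidy): one row per
(protein, animal, treatment, day) with a label-free summed peak-area
intensity or an explicit missing value. Wide protein-by-sample matrices
are in-memory views built downstream, never a file format, so that
missingness stays explicit per record.
"""

from __future__ import annotations

import enum
import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Culture-medium sampling days of the three-week explant time course.
DAYS: tuple[int, ...] = (4, 8, 12, 16, 20)

_ROSTER_SHA256 = "f3f386ffeb50ba63e3da9714f862b1e66b0b9e5bdf2785748cae142ff4106a0b"


class ParseError(ValueError):
    """A malformed input row; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


class IntegrityError(RuntimeError):
    """A packaged fixture is missing or fails its checksum."""


class Treatment(str, enum.Enum):
    """The eight explant culture arms.

    Codes compose three binary exposures: impact injury (I), the
    inflammatory cytokine cocktail TNFa + IL-6/sIL-6R (C), and 100 nM
    dexamethasone (D). ``N`` is the untreated control.
    """

    N = "N"
    I = "I"  # noqa: E741 - the field's single-letter code for injury
    C = "C"
    IC = "IC"
    D = "D"
    ID = "ID"
    CD = "CD"
    ICD = "ICD"

    @property
    def has_injury(self) -> bool:
        return "I" in self.value

    @property
    def has_cytokines(self) -> bool:
        return "C" in self.value

    @property
    def has_dex(self) -> bool:
        return "D" in self.value

    @classmethod
    def parse(cls, code: str) -> "Treatment":
        try:
            return cls(str(code).strip().upper())
        except ValueError:
            raise ValidationError(
                f"unknown treatment code {code!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


class Localization(str, enum.Enum):
    """UniProt-style subcellular localization stratum."""

    INTRACELLULAR = "intracellular"
    EXTRACELLULAR = "extracellular"
    BOTH = "both"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SampleKey:
    """One medium sample: animal replicate x treatment x culture day."""

    animal_id: str
    treatment: Treatment
    day: int

    def __post_init__(self) -> None:
        if self.day not in DAYS:
            raise ValidationError(
                f"invalid culture day {self.day}; sampled days are {DAYS}"
            )


@dataclass(frozen=True)
class ContrastSpec:
    """A pairwise treatment comparison, test vs. reference."""

    test: Treatment
    reference: Treatment
    label: str = ""

    def __post_init__(self) -> None:
        if self.test == self.reference:
            raise ValidationError("contrast test and reference must differ")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.test.value}|{self.reference.value}"
            )


#: The seven canonical contrasts: disease arms vs. control, and each
#: Dex arm vs. its matched non-Dex arm.
CANONICAL_CONTRASTS: tuple[ContrastSpec, ...] = tuple(
    ContrastSpec(Treatment.parse(t), Treatment.parse(r))
    for t, r in [
        ("C", "N"),
        ("IC", "N"),
        ("I", "N"),
        ("D", "N"),
        ("ID", "I"),
        ("CD", "C"),
        ("ICD", "IC"),
    ]
)

#: The three Dex contrasts entering the consistent-Dex-effect call.
DEX_CONSISTENCY_CONTRASTS: tuple[str, ...] = ("D|N", "CD|C", "ICD|IC")


_ABUNDANCE_COLUMNS = ["protein", "animal", "treatment", "day", "abundance"]


@dataclass
class AbundanceTable:
    """Long-format label-free intensities with explicit missingness.

    ``df`` columns: protein (str), animal (str), treatment (str code),
    day (int), abundance (float; NaN encodes a missing record). Every
    non-missing abundance is strictly positive on the raw scale;
    ``log2=True`` marks a log2-transformed table, where values of any
    sign are legitimate.
    """

    df: pd.DataFrame
    log2: bool = False

    def __post_init__(self) -> None:
        missing_cols = [c for c in _ABUNDANCE_COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise ValidationError(f"abundance table lacks columns {missing_cols}")
        df = self.df.loc[:, _ABUNDANCE_COLUMNS].copy()
        df["protein"] = df["protein"].astype(str)
        df["animal"] = df["animal"].astype(str)
        df["treatment"] = [Treatment.parse(t).value for t in df["treatment"]]
        df["day"] = df["day"].astype(int)
        bad_days = sorted(set(df["day"]) - set(DAYS))
        if bad_days:
            raise ValidationError(
                f"invalid culture day(s) {bad_days}; sampled days are {DAYS}"
            )
        df["abundance"] = df["abundance"].astype(float)
        if not self.log2:
            zero = df["abundance"] == 0
            if zero.any():
                logger.warning(
                    "%d abundance value(s) of exactly 0 treated as missing "
                    "(label-free intensities are positive; zero is an export artifact)",
                    int(zero.sum()),
                )
                df.loc[zero, "abundance"] = np.nan
            negative = df["abundance"] < 0
            if negative.any():
                raise ValidationError(
                    f"{int(negative.sum())} negative abundance value(s); "
                    "intensities must be positive or missing"
                )
        dup = df.duplicated(subset=["protein", "animal", "treatment", "day"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["protein", "animal", "treatment", "day"]]
            raise ValidationError(
                "duplicate record for "
                f"(protein={first['protein']}, animal={first['animal']}, "
                f"treatment={first['treatment']}, day={first['day']})"
            )
        self.df = df.reset_index(drop=True)

    # -- convenience views -------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return sorted(self.df["protein"].unique())

    @property
    def animals(self) -> list[str]:
        return sorted(self.df["animal"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.df["treatment"].unique())

    @property
    def n_missing(self) -> int:
        return int(self.df["abundance"].isna().sum())

    def observed(self) -> pd.DataFrame:
        """Rows with a quantified (non-missing) abundance."""
        return self.df[self.df["abundance"].notna()]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        a = self.df.sort_values(_ABUNDANCE_COLUMNS[:4]).reset_index(drop=True)
        b = other.df.sort_values(_ABUNDANCE_COLUMNS[:4]).reset_index(drop=True)
        if not a[_ABUNDANCE_COLUMNS[:4]].equals(b[_ABUNDANCE_COLUMNS[:4]]):
            return False
        x, y = a["abundance"].to_numpy(), b["abundance"].to_numpy()
        both_nan = np.isnan(x) & np.isnan(y)
        return bool(np.all(both_nan | np.isclose(x, y, rtol=1e-9, atol=0.0)))


@dataclass(frozen=True)
class RosterEntry:
    """One protein of the published response-profile roster.

    ``group`` is I/II/III for the 188 selected proteins and ``None`` for
    proteins listed only for their consistent dexamethasone effect.
    ``dex_direction`` is the per-protein Dex call (increase / decrease /
    no_change); ``dex_consistent`` is non-null only for proteins whose Dex
    effect held in every treatment condition.
    """

    gene_symbol: str
    group: str | None
    dex_direction: str
    dex_consistent: str | None = None


def read_abundance_tsv(path: str | Path, log2: bool = False) -> AbundanceTable:
    """Read a long-format abundance TSV into a validated table.

    Expects header columns ``protein animal treatment day abundance``;
    missing intensities are encoded as ``NA`` or an empty field.
    ``log2=True`` reads an already-transformed table, where values of
    any sign are legitimate.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"protein": str, "animal": str, "treatment": str},
            na_values=["NA"],
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing_cols = [c for c in _ABUNDANCE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: header lacks column(s) {missing_cols}")
    df["abundance"] = df["abundance"].replace("", np.nan)
    for col, caster in [("day", int), ("abundance", float)]:
        try:
            df[col] = df[col].astype(float if col == "abundance" else int)
        except (TypeError, ValueError):
            for i, value in enumerate(df[col]):
                try:
                    caster(value)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}, line {i + 2}: cannot parse {col}={value!r}"
                    ) from None
            raise
    return AbundanceTable(df, log2=log2)


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    """Write a table back to the long TSV format (missing as ``NA``)."""
    out = table.df.loc[:, _ABUNDANCE_COLUMNS].copy()
    out["abundance"] = [
        "NA" if np.isnan(v) else format(v, ".10g") for v in out["abundance"]
    ]
    out.to_csv(path, sep="\t", index=False)


def write_results_tsv(records, path: str | Path) -> None:
    """Write a homogeneous result table (dataclasses or DataFrame) as TSV.

    Floats are rendered with 10 significant digits so a read-back
    reproduces values to that precision. An empty record set is an error:
    silently writing a header-only file would mask an upstream failure.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if not records:
            raise ValidationError("refusing to write an empty result table")
        first = records[0]
        if hasattr(first, "__dataclass_fields__"):
            from dataclasses import asdict

            df = pd.DataFrame([asdict(r) for r in records])
        else:
            df = pd.DataFrame(records)
    if df.empty:
        raise ValidationError("refusing to write an empty result table")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read a protein -> subcellular-localization table.

    Columns ``protein`` and ``localization``; localization values must be
    intracellular / extracellular / both / unknown, one row per protein.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein", "localization"):
        if col not in df.columns:
            raise ParseError(f"{path}: header lacks column {col!r}")
    valid = {loc.value for loc in Localization}
    bad = sorted(set(df["localization"]) - valid)
    if bad:
        raise ValidationError(f"unknown localization value(s) {bad}")
    if df["protein"].duplicated().any():
        raise ValidationError("duplicate protein in annotation table")
    return df.reset_index(drop=True)


def load_table1_roster() -> list[RosterEntry]:
    """Load the packaged response-profile roster.

    Returns the 188 grouped proteins (32 Group I, 64 Group II, 92 Group
    III) plus the three proteins listed only in the consistent-Dex
    column, 191 entries in all; exactly 6 entries carry a non-null
    ``dex_consistent`` call. The fixture is checksummed on load.
    """
    ref = resources.files("cartisec.data").joinpath("table1_roster.tsv")
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:
        raise IntegrityError("packaged roster fixture is missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _ROSTER_SHA256:
        raise IntegrityError(
            f"roster fixture checksum mismatch: {digest} != {_ROSTER_SHA256}"
        )
    entries: list[RosterEntry] = []
    lines = raw.decode("utf-8").splitlines()
    for line in lines[1:]:
        gene, group, direction, consistent = line.rstrip("\n").split("\t")
        entries.append(
            RosterEntry(
                gene_symbol=gene,
                group=None if group == "NA" else group,
                dex_direction=direction,
                dex_consistent=None if consistent == "NA" else consistent,
            )
        )
    return entries
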