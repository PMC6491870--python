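"""Aneuploid stock panels and marker-amplification evidence matrices.

Deletion-bin mapping in hexaploid wheat rests on three classes of
cytogenetic stocks derived from the variety Chinese Spring:

* **NT** (nullisomic-tetrasomic) lines lack one chromosome pair and carry
  four copies of a homoeolog from the same group; a marker that fails to
  amplify only in the nullisomics of one chromosome maps to that chromosome.
* **Dt** (ditelosomic) lines retain a single chromosome arm; failure in the
  line retaining the *other* arm assigns the marker to an arm.
* **Del** (terminal deletion) lines retain the proximal portion of an arm up
  to a breakpoint expressed as a fraction of the arm length (FL, centromere
  = 0, telomere = 1); the pattern of presence/absence across breakpoints
  brackets the marker into a sub-arm interval.

This module holds the validated domain types for such panels and the
parsers/writers for their plain-text (CSV/TSV) representations.
"""

from __future__ import annotations

import enum
import io as _stdio
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Call",
    "StockClass",
    "AneuploidLine",
    "StockPanel",
    "AmplificationMatrix",
    "PanelError",
    "parse_stock_registry",
    "write_stock_registry",
    "parse_amplification_table",
    "write_amplification_table",
    "merge_marker_group",
    "load_cs_group7_registry",
    "load_cs_group7_matrix",
    "load_pod_primer_table",
]

_CHROMOSOME_RE = re.compile(r"^[1-7][ABD]$")
_MISSING_TOKENS = {"", "/", "NA", "N/A", "NAN", "NONE", ".", "?"}


class PanelError(ValueError):
    """Raised for malformed registries or amplification tables."""


class StockClass(str, enum.Enum):
    NT = "NT"
    DT = "Dt"
    DEL = "Del"
    EUPLOID = "euploid"


class Call(str, enum.Enum):
    """One marker x line amplification observation."""

    PRESENT = "present"
    ABSENT = "absent"
    MISSING = "missing"

    @classmethod
    def from_symbol(cls, symbol: str) -> "Call":
        s = str(symbol).strip()
        if s == "+":
            return cls.PRESENT
        if s == "-":
            return cls.ABSENT
        if s.upper() in _MISSING_TOKENS:
            return cls.MISSING
        raise PanelError(f"unrecognized amplification symbol {symbol!r}")

    @property
    def symbol(self) -> str:
        return {"present": "+", "absent": "-", "missing": "NA"}[self.value]


def normalize_chromosome(label: str) -> str:
    """Case-normalize a wheat chromosome label (``7a`` -> ``7A``)."""
    label = str(label).strip().upper()
    if not _CHROMOSOME_RE.match(label):
        raise PanelError(
            f"{label!r} is not a wheat chromosome label (group 1-7 x genome A/B/D)"
        )
    return label


def _normalize_arm(arm: str) -> str:
    arm = str(arm).strip().upper()
    if arm not in {"S", "L"}:
        raise PanelError(f"arm must be 'S' or 'L', got {arm!r}")
    return arm


@dataclass(frozen=True)
class AneuploidLine:
    """A single cytogenetic stock.

    ``chromosome``/``arm`` describe the retained arm for Dt and Del lines;
    for NT lines ``nullisomic_chromosome``/``tetrasomic_chromosome`` hold the
    missing and compensating chromosomes. ``breakpoint_fl`` is the retained
    proximal fraction arm length and is defined for Del lines only.
    """

    name: str
    stock_class: StockClass
    chromosome: str | None = None
    arm: str | None = None
    breakpoint_fl: float | None = None
    nullisomic_chromosome: str | None = None
    tetrasomic_chromosome: str | None = None

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise PanelError("stock line name must be non-empty")
        object.__setattr__(self, "stock_class", StockClass(self.stock_class))
        cls = self.stock_class
        if self.chromosome is not None:
            object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.arm is not None:
            object.__setattr__(self, "arm", _normalize_arm(self.arm))
        if cls is StockClass.NT:
            if self.nullisomic_chromosome is None or self.tetrasomic_chromosome is None:
                raise PanelError(
                    f"NT line {self.name!r} needs nullisomic and tetrasomic chromosomes"
                )
            nulli = normalize_chromosome(self.nullisomic_chromosome)
            tetra = normalize_chromosome(self.tetrasomic_chromosome)
            if nulli[0] != tetra[0]:
                raise PanelError(
                    f"NT line {self.name!r}: nullisomic {nulli} and tetrasomic {tetra} "
                    "must belong to the same homoeologous group"
                )
            if nulli == tetra:
                raise PanelError(
                    f"NT line {self.name!r}: nullisomic equals tetrasomic chromosome"
                )
            object.__setattr__(self, "nullisomic_chromosome", nulli)
            object.__setattr__(self, "tetrasomic_chromosome", tetra)
        if cls in (StockClass.DT, StockClass.DEL):
            if self.chromosome is None or self.arm is None:
                raise PanelError(f"{cls.value} line {self.name!r} needs chromosome and arm")
        if cls is StockClass.DEL:
            fl = self.breakpoint_fl
            if fl is None or not (0.0 < float(fl) < 1.0) or math.isnan(float(fl)):
                raise PanelError(
                    f"Del line {self.name!r}: breakpoint FL must lie strictly in (0, 1), "
                    f"got {fl!r}"
                )
            object.__setattr__(self, "breakpoint_fl", float(fl))
        elif self.breakpoint_fl is not None and not (
            isinstance(self.breakpoint_fl, float) and math.isnan(self.breakpoint_fl)
        ):
            raise PanelError(
                f"{cls.value} line {self.name!r} must not carry a breakpoint FL"
            )
        elif self.breakpoint_fl is not None:
            object.__setattr__(self, "breakpoint_fl", None)

    @property
    def chromosome_arm(self) -> str | None:
        """Retained arm label such as ``7DS`` (Dt/Del lines)."""
        if self.chromosome is None or self.arm is None:
            return None
        return f"{self.chromosome}{self.arm}"


@dataclass
class StockPanel:
    """An ordered, name-indexed collection of :class:`AneuploidLine`."""

    lines: list[AneuploidLine] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for line in self.lines:
            if line.name in seen:
                raise PanelError(f"duplicate stock line name {line.name!r}")
            seen.add(line.name)
        self._by_name = {line.name: line for line in self.lines}

    def __len__(self) -> int:
        return len(self.lines)

    def __iter__(self):
        return iter(self.lines)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> AneuploidLine:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no stock line named {name!r} in panel") from None

    def of_class(self, stock_class: StockClass | str) -> list[AneuploidLine]:
        stock_class = StockClass(stock_class)
        return [l for l in self.lines if l.stock_class is stock_class]

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.lines]


@dataclass
class AmplificationMatrix:
    """Marker x line presence/absence evidence.

    ``calls`` maps ``(marker, line_name)`` to :class:`Call`; every pair over
    ``markers`` x ``panel`` is defined (missing observations are explicit).
    """

    markers: list[str]
    panel: StockPanel
    calls: dict[tuple[str, str], Call]

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise PanelError("duplicate marker names in matrix")
        for marker in self.markers:
            for name in self.panel.names:
                key = (marker, name)
                if key not in self.calls:
                    raise PanelError(f"no call for marker {marker!r} x line {name!r}")
                self.calls[key] = Call(self.calls[key])
        extra = set(self.calls) - {
            (m, n) for m in self.markers for n in self.panel.names
        }
        if extra:
            raise PanelError(f"calls reference unknown marker/line pairs: {sorted(extra)}")

    def call(self, marker: str, line: str | AneuploidLine) -> Call:
        name = line.name if isinstance(line, AneuploidLine) else line
        return self.calls[(marker, name)]

    def calls_for(
        self, marker: str, stock_class: StockClass | str | None = None
    ) -> list[tuple[AneuploidLine, Call]]:
        lines = self.panel.lines if stock_class is None else self.panel.of_class(stock_class)
        return [(l, self.call(marker, l)) for l in lines]

    def to_frame(self) -> pd.DataFrame:
        """Lines as rows, markers as columns, ``+``/``-``/``NA`` cells."""
        data = {
            m: [self.call(m, n).symbol for n in self.panel.names] for m in self.markers
        }
        return pd.DataFrame(data, index=pd.Index(self.panel.names, name="line"))


# ---------------------------------------------------------------------------
# Parsing and writing


def _read_table(source) -> pd.DataFrame:
    """Read CSV or TSV from a path, file object, or literal text."""
    if isinstance(source, pd.DataFrame):
        return source.copy()
    if isinstance(source, str) and ("\n" in source or "," in source and not Path(source).exists()):
        source = _stdio.StringIO(source)
    return pd.read_csv(source, sep=None, engine="python", dtype=str, skipinitialspace=True)


def parse_stock_registry(table) -> StockPanel:
    """Parse a stock registry (columns ``line,stock_class,chromosome,arm,fl``).

    NT rows put the nullisomic chromosome in ``chromosome`` and require a
    ``tetrasomic`` column. Raises :class:`PanelError` naming the offending row
    on malformed FL values or unknown stock classes.
    """
    df = _read_table(table)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"line", "stock_class"}
    if not required.issubset(df.columns):
        raise PanelError(f"registry needs columns {sorted(required)}, got {list(df.columns)}")
    lines: list[AneuploidLine] = []
    for idx, row in df.iterrows():
        name = str(row["line"]).strip()
        raw_class = str(row["stock_class"]).strip()
        try:
            stock_class = StockClass(
                {"nt": "NT", "dt": "Dt", "del": "Del", "euploid": "euploid"}[raw_class.lower()]
            )
        except KeyError:
            raise PanelError(f"row {idx} ({name!r}): unknown stock class {raw_class!r}") from None
        chrom = row.get("chromosome")
        chrom = None if pd.isna(chrom) or not str(chrom).strip() else str(chrom).strip()
        arm = row.get("arm")
        arm = None if pd.isna(arm) or not str(arm).strip() else str(arm).strip()
        fl_raw = row.get("fl")
        fl: float | None = None
        if fl_raw is not None and not pd.isna(fl_raw) and str(fl_raw).strip() not in _MISSING_TOKENS:
            try:
                fl = float(fl_raw)
            except ValueError:
                raise PanelError(f"row {idx} ({name!r}): FL {fl_raw!r} is not a decimal") from None
        tetra = row.get("tetrasomic")
        tetra = None if tetra is None or pd.isna(tetra) or not str(tetra).strip() else str(tetra).strip()
        try:
            if stock_class is StockClass.NT:
                line = AneuploidLine(
                    name=name,
                    stock_class=stock_class,
                    nullisomic_chromosome=chrom,
                    tetrasomic_chromosome=tetra,
                )
            else:
                line = AneuploidLine(
                    name=name,
                    stock_class=stock_class,
                    chromosome=chrom,
                    arm=arm,
                    breakpoint_fl=fl,
                )
        except PanelError as exc:
            raise PanelError(f"row {idx} ({name!r}): {exc}") from None
        lines.append(line)
    return StockPanel(lines)


def write_stock_registry(panel: StockPanel, path=None, sep: str = ",") -> str:
    """Serialize a panel back to registry CSV/TSV text (inverse of parsing)."""
    rows = []
    for l in panel:
        rows.append(
            {
                "line": l.name,
                "stock_class": l.stock_class.value,
                "chromosome": l.nullisomic_chromosome if l.stock_class is StockClass.NT else l.chromosome,
                "arm": l.arm,
                "fl": "" if l.breakpoint_fl is None else f"{l.breakpoint_fl:g}",
                "tetrasomic": l.tetrasomic_chromosome,
            }
        )
    df = pd.DataFrame(rows, columns=["line", "stock_class", "chromosome", "arm", "fl", "tetrasomic"])
    if all(l.stock_class is not StockClass.NT for l in panel):
        df = df.drop(columns=["tetrasomic"])
    text = df.to_csv(path, sep=sep, index=False)
    return text


def parse_amplification_table(table, panel: StockPanel) -> AmplificationMatrix:
    """Parse a marker amplification table (lines as rows, markers as columns).

    Cells must be ``+``, ``-`` or a missing token (``NA``, ``/``, empty);
    anything else raises. Line names must exist in ``panel``; offenders are
    listed in the error.
    """
    df = _read_table(table)
    df.columns = [c.strip() for c in df.columns]
    line_col = df.columns[0]
    markers = [c for c in df.columns[1:]]
    names = [str(n).strip() for n in df[line_col]]
    unknown = [n for n in names if n not in panel]
    if unknown:
        raise PanelError(f"amplification table references unknown lines: {unknown}")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise PanelError(f"amplification table repeats lines: {dupes}")
    calls: dict[tuple[str, str], Call] = {}
    for name, (_, row) in zip(names, df.iterrows()):
        for marker in markers:
            cell = row[marker]
            cell = "" if pd.isna(cell) else str(cell)
            calls[(marker, name)] = Call.from_symbol(cell)
    # lines in the panel but not in the table are explicitly missing
    for name in panel.names:
        for marker in markers:
            calls.setdefault((marker, name), Call.MISSING)
    return AmplificationMatrix(markers=markers, panel=panel, calls=calls)


def write_amplification_table(matrix: AmplificationMatrix, path=None, sep: str = ",") -> str:
    """Serialize a matrix to CSV/TSV text; inverse of :func:`parse_amplification_table`."""
    df = matrix.to_frame().reset_index()
    return df.to_csv(path, sep=sep, index=False)


def merge_marker_group(
    matrix: AmplificationMatrix, group: Iterable[str], merged_name: str
) -> AmplificationMatrix:
    """Merge several primer sets assaying the same gene into one matrix row.

    Per line, all non-missing member calls must agree; a disagreement is
    demoted to missing with a warning (the line contributes no evidence).
    """
    group = list(group)
    for m in group:
        if m not in matrix.markers:
            raise PanelError(f"marker {m!r} not in matrix")
    calls: dict[tuple[str, str], Call] = {}
    for name in matrix.panel.names:
        observed = {matrix.call(m, name) for m in group} - {Call.MISSING}
        if len(observed) == 1:
            calls[(merged_name, name)] = next(iter(observed))
        elif len(observed) == 0:
            calls[(merged_name, name)] = Call.MISSING
        else:
            warnings.warn(
                f"line {name!r}: primer sets {group} disagree; treating as missing",
                stacklevel=2,
            )
            calls[(merged_name, name)] = Call.MISSING
    return AmplificationMatrix(markers=[merged_name], panel=matrix.panel, calls=calls)


# ---------------------------------------------------------------------------
# Packaged reference fixtures (Chinese Spring group-7 panel)


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_cs_group7_registry() -> StockPanel:
    """The packaged Chinese Spring group-7 Dt/Del stock registry (44 lines)."""
    return parse_stock_registry(_data_path("cs_group7_stocks.csv"))


def load_cs_group7_matrix(panel: StockPanel | None = None) -> AmplificationMatrix:
    """The packaged P1-P6 amplification matrix over the group-7 panel."""
    if panel is None:
        panel = load_cs_group7_registry()
    return parse_amplification_table(_data_path("cs_group7_amplification.csv"), panel)


def load_pod_primer_table() -> pd.DataFrame:
    """The packaged POD primer table (cloning sets P1-P6 and STS assays)."""
    df = pd.read_csv(_data_path("pod_primer_table.csv"))
    return df
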