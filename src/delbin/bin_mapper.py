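"""Deletion-bin inference: chromosome, arm and sub-arm interval for a marker.

The logic mirrors how aneuploid panels are read by hand:

* a marker absent in every nullisomic of chromosome *C* (and present in all
  other NT lines) sits on *C*;
* a marker absent in the ditelosomic retaining only arm *X* sits on the
  complementary arm of the same chromosome;
* on that arm, a deletion line with breakpoint FL *f* retains the proximal
  interval ``[0, f]``, so absence pushes the marker distal to *f* and
  presence pulls it proximal to (or onto) *f*. The marker bin is the
  half-open interval ``(max FL over absent lines, min FL over present
  lines]``; with no amplifying deletion line the telomere (FL 1.0) closes
  the bin, justified by presence in the whole-arm ditelosomic.

:func:`brute_force_bin` re-derives the same interval by exhaustive grid
enumeration and exists as an independent consistency oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stock_panel import (
    AmplificationMatrix,
    AneuploidLine,
    Call,
    StockClass,
    StockPanel,
    normalize_chromosome,
)

__all__ = [
    "ChromosomeAssignment",
    "ArmAssignment",
    "PhysicalBin",
    "ContradictionError",
    "assign_chromosome",
    "assign_arm",
    "infer_bin",
    "brute_force_bin",
    "count_amplified",
    "map_bins",
]


class ContradictionError(ValueError):
    """Amplification calls admit no marker position on the arm."""


@dataclass(frozen=True)
class ChromosomeAssignment:
    marker: str
    chromosome: str | None
    evidence: tuple[tuple[str, Call], ...] = ()
    diagnostic: str = ""

    @property
    def resolved(self) -> bool:
        return self.chromosome is not None


@dataclass(frozen=True)
class ArmAssignment:
    marker: str
    chromosome: str
    arm: str | None
    evidence: tuple[tuple[str, Call], ...] = ()
    diagnostic: str = ""

    @property
    def resolved(self) -> bool:
        return self.arm is not None

    @property
    def chromosome_arm(self) -> str | None:
        return None if self.arm is None else f"{self.chromosome}{self.arm}"


@dataclass(frozen=True)
class PhysicalBin:
    """A fraction-arm-length interval ``(lower_fl, upper_fl]`` on one arm."""

    marker: str
    chromosome: str
    arm: str
    lower_fl: float
    upper_fl: float
    supporting_absent: tuple[str, ...] = ()
    supporting_present: tuple[str, ...] = ()
    dropped_calls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower_fl < self.upper_fl <= 1.0):
            raise ValueError(
                f"bin bounds must satisfy 0 <= lower < upper <= 1, got "
                f"({self.lower_fl}, {self.upper_fl}]"
            )

    @property
    def distal_fraction(self) -> float | None:
        """``1 - lower_fl`` when the bin reaches the telomere, else None."""
        if self.upper_fl == 1.0:
            return round(1.0 - self.lower_fl, 12)
        return None

    @property
    def chromosome_arm(self) -> str:
        return f"{self.chromosome}{self.arm}"

    def contains(self, fl: float) -> bool:
        return self.lower_fl < fl <= self.upper_fl


def assign_chromosome(matrix: AmplificationMatrix, marker: str) -> ChromosomeAssignment:
    """Assign a chromosome from NT-line calls.

    Chromosome *C* is assigned iff the marker is absent in every NT line
    nullisomic for *C* and present in every other NT line with a non-missing
    call. Absence in nullisomics of two different chromosomes flags a
    multi-locus/contradictory pattern and yields no assignment.
    """
    nt_lines = matrix.panel.of_class(StockClass.NT)
    evidence = tuple((l.name, matrix.call(marker, l)) for l in nt_lines)
    if not nt_lines:
        return ChromosomeAssignment(marker, None, evidence, "no NT lines in panel")
    absent_chroms = sorted(
        {
            l.nullisomic_chromosome
            for l in nt_lines
            if matrix.call(marker, l) is Call.ABSENT
        }
    )
    if not absent_chroms:
        return ChromosomeAssignment(
            marker, None, evidence, "present in all NT lines: no chromosome signal"
        )
    if len(absent_chroms) > 1:
        return ChromosomeAssignment(
            marker,
            None,
            evidence,
            "multi-locus or contradictory: absent in nullisomics of "
            + ", ".join(absent_chroms),
        )
    chrom = absent_chroms[0]
    stray = [
        l.name
        for l in nt_lines
        if l.nullisomic_chromosome == chrom and matrix.call(marker, l) is Call.PRESENT
    ]
    if stray:
        return ChromosomeAssignment(
            marker,
            None,
            evidence,
            f"inconsistent: present in nullisomic-{chrom} lines {stray}",
        )
    return ChromosomeAssignment(marker, chrom, evidence)


def assign_arm(matrix: AmplificationMatrix, marker: str, chromosome: str) -> ArmAssignment:
    """Assign an arm from the chromosome's Dt lines.

    The assigned arm is the complement of the arm retained by the Dt line in
    which the marker fails to amplify: absence in the line retaining only L
    puts the marker on S, and symmetrically.
    """
    chromosome = normalize_chromosome(chromosome)
    dt_lines = [
        l for l in matrix.panel.of_class(StockClass.DT) if l.chromosome == chromosome
    ]
    evidence = tuple((l.name, matrix.call(marker, l)) for l in dt_lines)
    if not dt_lines:
        return ArmAssignment(marker, chromosome, None, evidence, "no Dt lines for chromosome")
    by_arm = {l.arm: matrix.call(marker, l) for l in dt_lines}
    s_call = by_arm.get("S", Call.MISSING)
    l_call = by_arm.get("L", Call.MISSING)
    if l_call is Call.ABSENT and s_call is Call.PRESENT:
        # missing the S-arm evidence would be ambiguous; absent-in-Dt-L alone
        # is the signature of an S-arm marker
        return ArmAssignment(marker, chromosome, "S", evidence)
    if s_call is Call.ABSENT and l_call is Call.PRESENT:
        return ArmAssignment(marker, chromosome, "L", evidence)
    return ArmAssignment(
        marker,
        chromosome,
        None,
        evidence,
        f"unresolved: Dt{chromosome}S={s_call.symbol} Dt{chromosome}L={l_call.symbol}",
    )


def _arm_del_calls(
    matrix: AmplificationMatrix, marker: str, chromosome: str, arm: str
) -> list[tuple[AneuploidLine, Call]]:
    return [
        (l, matrix.call(marker, l))
        for l in matrix.panel.of_class(StockClass.DEL)
        if l.chromosome == chromosome and l.arm == arm
    ]


def _conflicting_pairs(
    absent: list[AneuploidLine], present: list[AneuploidLine]
) -> list[tuple[str, str]]:
    return [
        (a.name, p.name)
        for a in absent
        for p in present
        if a.breakpoint_fl >= p.breakpoint_fl
    ]


def infer_bin(
    matrix: AmplificationMatrix,
    marker: str,
    chromosome: str,
    arm: str,
    tolerant: bool = False,
) -> PhysicalBin:
    """Infer the marker's FL bin on ``chromosome arm`` from Del-line calls.

    ``lower_fl`` is the largest breakpoint among absent deletion lines (0 if
    none), ``upper_fl`` the smallest among present ones. With no amplifying
    deletion line the upper bound is the telomere (1.0), which requires the
    arm's Dt line to amplify. Inconsistent panels raise
    :class:`ContradictionError` listing the conflicting line pairs; in
    ``tolerant`` mode the minimal number of calls is dropped instead
    (greedily, deterministic order by line name) and reported on the bin.

    Missing calls never contribute evidence.
    """
    chromosome = normalize_chromosome(chromosome)
    arm = arm.strip().upper()
    del_calls = _arm_del_calls(matrix, marker, chromosome, arm)
    if not del_calls:
        raise ContradictionError(
            f"marker {marker!r}: no deletion lines on {chromosome}{arm}"
        )
    absent = sorted(
        (l for l, c in del_calls if c is Call.ABSENT), key=lambda l: l.name
    )
    present = sorted(
        (l for l, c in del_calls if c is Call.PRESENT), key=lambda l: l.name
    )
    dropped: list[str] = []
    conflicts = _conflicting_pairs(absent, present)
    if conflicts and not tolerant:
        raise ContradictionError(
            f"marker {marker!r} on {chromosome}{arm}: absent/present breakpoints "
            f"conflict for line pairs {conflicts}"
        )
    while _conflicting_pairs(absent, present):
        # drop the call involved in the most conflicts; ties break by name
        counts: dict[str, int] = {}
        for a, p in _conflicting_pairs(absent, present):
            counts[a] = counts.get(a, 0) + 1
            counts[p] = counts.get(p, 0) + 1
        victim = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        absent = [l for l in absent if l.name != victim]
        present = [l for l in present if l.name != victim]
        dropped.append(victim)

    lower = max((l.breakpoint_fl for l in absent), default=0.0)
    if present:
        upper = min(l.breakpoint_fl for l in present)
    else:
        # whole-arm bound: needs the arm's ditelosomic to amplify
        dt = [
            l
            for l in matrix.panel.of_class(StockClass.DT)
            if l.chromosome == chromosome and l.arm == arm
        ]
        if not dt or matrix.call(marker, dt[0]) is not Call.PRESENT:
            raise ContradictionError(
                f"marker {marker!r} on {chromosome}{arm}: no amplifying deletion line "
                "and no amplifying ditelosomic to close the bin at the telomere"
            )
        upper = 1.0
    return PhysicalBin(
        marker=marker,
        chromosome=chromosome,
        arm=arm,
        lower_fl=lower,
        upper_fl=upper,
        supporting_absent=tuple(l.name for l in absent),
        supporting_present=tuple(l.name for l in present),
        dropped_calls=tuple(dropped),
    )


def brute_force_bin(
    matrix: AmplificationMatrix,
    marker: str,
    chromosome: str,
    arm: str,
    grid_step: float = 0.001,
) -> PhysicalBin:
    """Exhaustive-grid oracle for :func:`infer_bin`.

    Enumerates candidate positions ``p in {grid_step, 2*grid_step, ..., 1.0}``
    and keeps those consistent with every deletion-line call (present line =>
    ``p <= FL``; absent line => ``p > FL``; an amplifying ditelosomic of the
    arm acts as a present line with FL 1.0). Returns the hull of surviving
    positions; agreement with :func:`infer_bin` is exact up to the grid
    resolution. No survivor raises :class:`ContradictionError`.
    """
    if not grid_step > 0:
        raise ValueError("grid_step must be positive")
    chromosome = normalize_chromosome(chromosome)
    arm = arm.strip().upper()
    del_calls = _arm_del_calls(matrix, marker, chromosome, arm)
    constraints: list[tuple[float, Call]] = [
        (l.breakpoint_fl, c) for l, c in del_calls if c is not Call.MISSING
    ]
    for l in matrix.panel.of_class(StockClass.DT):
        if l.chromosome == chromosome and l.arm == arm:
            c = matrix.call(marker, l)
            if c is not Call.MISSING:
                constraints.append((1.0, c))
    grid = np.arange(1, int(round(1.0 / grid_step)) + 1) * grid_step
    ok = np.ones(grid.shape, dtype=bool)
    for fl, call in constraints:
        if call is Call.PRESENT:
            ok &= grid <= fl + 1e-12
        else:
            ok &= grid > fl + 1e-12
    if not ok.any():
        raise ContradictionError(
            f"marker {marker!r} on {chromosome}{arm}: no grid position consistent "
            "with all calls"
        )
    surviving = grid[ok]
    names_absent = tuple(
        l.name for l, c in del_calls if c is Call.ABSENT
    )
    names_present = tuple(
        l.name for l, c in del_calls if c is Call.PRESENT
    )
    return PhysicalBin(
        marker=marker,
        chromosome=chromosome,
        arm=arm,
        lower_fl=max(0.0, float(surviving.min() - grid_step)),
        upper_fl=float(min(1.0, surviving.max())),
        supporting_absent=names_absent,
        supporting_present=names_present,
    )


def count_amplified(
    matrix: AmplificationMatrix, marker: str, stock_class: StockClass | str
) -> int:
    """Number of lines of the given stock class in which the marker amplifies."""
    return sum(
        1 for _, c in matrix.calls_for(marker, stock_class) if c is Call.PRESENT
    )


def map_bins(
    matrix: AmplificationMatrix,
    markers: list[str] | None = None,
    tolerant: bool = False,
) -> pd.DataFrame:
    """Run arm assignment and bin inference for each marker; tabular report.

    Chromosome assignment from NT lines is attempted when the panel contains
    NT lines; otherwise the chromosome is taken from the arm signature of the
    Dt lines (the panel's Dt chromosomes are tried in sorted order and the
    unique one whose Dt pair resolves an arm wins).

    Columns: marker, chromosome, arm, lower_fl, upper_fl, distal_fraction,
    n_present, n_absent, status.
    """
    markers = list(matrix.markers) if markers is None else markers
    rows = []
    dt_chromosomes = sorted(
        {l.chromosome for l in matrix.panel.of_class(StockClass.DT)}
    )
    has_nt = bool(matrix.panel.of_class(StockClass.NT))
    for marker in markers:
        row: dict = {
            "marker": marker,
            "chromosome": None,
            "arm": None,
            "lower_fl": math.nan,
            "upper_fl": math.nan,
            "distal_fraction": math.nan,
            "n_present": 0,
            "n_absent": 0,
            "status": "",
        }
        candidates: list[str]
        if has_nt:
            ca = assign_chromosome(matrix, marker)
            if not ca.resolved:
                row["status"] = f"chromosome unresolved: {ca.diagnostic}"
                rows.append(row)
                continue
            candidates = [ca.chromosome]
        else:
            candidates = dt_chromosomes
        arm_hits = [
            aa
            for aa in (assign_arm(matrix, marker, c) for c in candidates)
            if aa.resolved
        ]
        if len(arm_hits) != 1:
            row["status"] = (
                "arm unresolved"
                if not arm_hits
                else f"ambiguous arm signal on {[a.chromosome_arm for a in arm_hits]}"
            )
            rows.append(row)
            continue
        aa = arm_hits[0]
        row["chromosome"], row["arm"] = aa.chromosome, aa.arm
        try:
            b = infer_bin(matrix, marker, aa.chromosome, aa.arm, tolerant=tolerant)
        except ContradictionError as exc:
            row["status"] = f"contradiction: {exc}"
            rows.append(row)
            continue
        row.update(
            lower_fl=b.lower_fl,
            upper_fl=b.upper_fl,
            distal_fraction=b.distal_fraction if b.distal_fraction is not None else math.nan,
            n_present=len(b.supporting_present),
            n_absent=len(b.supporting_absent),
            status="ok" if not b.dropped_calls else f"ok (dropped {list(b.dropped_calls)})",
        )
        rows.append(row)
    return pd.DataFrame(rows)
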