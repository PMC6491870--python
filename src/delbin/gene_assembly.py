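"""Amplicon merging and ATG-anchored gene models.

Coordinates follow the convention used for primer-walking tables of plant
genes: the A of the initiation ATG is +1, 5' UTR positions are negative,
and there is no position 0. A region such as (-20, 468) therefore spans
488 bases.

Overlapping PCR amplicons are merged by exact suffix/prefix matching into a
single genomic sequence, which is then partitioned into 5' UTR / ORF / 3'
UTR. ORF selection can be automatic: the 5'-most ATG in a favorable Kozak
context (purine at -3 or G at +4) that reaches an in-frame stop. Derived
gene-model statistics (translation, GC content, molecular weight) go
through Biopython.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import gc_fraction
from Bio.SeqUtils.ProtParam import ProteinAnalysis

__all__ = [
    "Amplicon",
    "GeneModel",
    "MergeError",
    "ModelError",
    "region_length",
    "coord_to_index",
    "index_to_coord",
    "merge_amplicons",
    "merge_chain",
    "build_gene_model",
    "find_orf",
    "kozak_context",
    "translate",
    "molecular_weight",
    "gc_percent",
]

_WATER_DA = 18.02
_STOPS = {"TAA", "TAG", "TGA"}
_DNA = set("ACGT")


class MergeError(ValueError):
    """No acceptable overlap between two amplicons."""


class ModelError(ValueError):
    """A sequence does not admit the requested gene model."""


def _check_coord(pos: int) -> int:
    pos = int(pos)
    if pos == 0:
        raise ValueError("position 0 does not exist in ATG-anchored coordinates")
    return pos


def region_length(start: int, end: int) -> int:
    """Length in bp of the inclusive region [start, end], skipping position 0.

    (-20, 468) -> 488; (450, 1104) -> 655; (1, 1) -> 1.
    """
    start, end = _check_coord(start), _check_coord(end)
    if start > end:
        raise ValueError(f"region start {start} must not follow end {end}")
    return end - start + 1 if (start > 0) == (end > 0) else end - start


def coord_to_index(pos: int, utr5_len: int) -> int:
    """ATG-anchored coordinate -> 0-based index in a sequence with a 5' UTR."""
    pos = _check_coord(pos)
    return utr5_len + pos - 1 if pos > 0 else utr5_len + pos


def index_to_coord(index: int, utr5_len: int) -> int:
    """0-based sequence index -> ATG-anchored coordinate (no position 0)."""
    offset = index - utr5_len
    return offset + 1 if offset >= 0 else offset


@dataclass(frozen=True)
class Amplicon:
    """A named PCR product, optionally with ATG-anchored region coordinates."""

    name: str
    sequence: str = ""
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))
        if self.start is not None and self.end is not None and self.sequence:
            declared = region_length(self.start, self.end)
            if declared != len(self.sequence):
                raise ValueError(
                    f"amplicon {self.name!r}: region ({self.start}, {self.end}) spans "
                    f"{declared} bp but sequence is {len(self.sequence)} bp"
                )

    @property
    def declared_size(self) -> int | None:
        if self.start is None or self.end is None:
            return None
        return region_length(self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    """An assembled gene partitioned into 5' UTR, ORF and 3' UTR."""

    name: str
    sequence: str
    utr5_len: int
    orf_len: int
    utr3_len: int
    protein: str
    kozak_ok: bool
    kozak_minus3: str | None
    kozak_plus4: str | None
    gc_pct: float
    mw_kda: float

    def __post_init__(self) -> None:
        if self.utr5_len + self.orf_len + self.utr3_len != len(self.sequence):
            raise ModelError("UTR5 + ORF + UTR3 must partition the sequence")
        if self.orf_len % 3:
            raise ModelError("ORF length must be divisible by 3")

    @property
    def orf(self) -> str:
        return self.sequence[self.utr5_len : self.utr5_len + self.orf_len]

    @property
    def utr5(self) -> str:
        return self.sequence[: self.utr5_len]

    @property
    def utr3(self) -> str:
        return self.sequence[self.utr5_len + self.orf_len :]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "length_bp": len(self.sequence),
            "utr5_len": self.utr5_len,
            "orf_len": self.orf_len,
            "utr3_len": self.utr3_len,
            "protein_len": len(self.protein),
            "kozak_ok": self.kozak_ok,
            "kozak_minus3": self.kozak_minus3,
            "kozak_plus4": self.kozak_plus4,
            "gc_pct": round(self.gc_pct, 1),
            "mw_kda": round(self.mw_kda, 1),
        }


# ---------------------------------------------------------------------------
# Merging


def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    best = 0
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-k:] == b[:k]:
            best = k
            break  # longest qualifying exact overlap wins
    return best


def merge_amplicons(a: Amplicon, b: Amplicon, min_overlap: int = 15) -> Amplicon:
    """Merge two amplicons by exact suffix(a)/prefix(b) overlap.

    The longest exact overlap of length >= ``min_overlap`` is used; the
    merged length is ``len(a) + len(b) - overlap``. When both amplicons carry
    region coordinates, the coordinate overlap is checked against the
    sequences and a mismatch reports the first discordant offset.
    """
    if not a.sequence or not b.sequence:
        raise MergeError("both amplicons must carry sequences")
    k = _best_overlap(a.sequence, b.sequence, min_overlap)
    if k == 0:
        if a.start is not None and b.start is not None and a.end is not None:
            if b.start <= a.end:
                expected = region_length(b.start, a.end)
                suffix = a.sequence[-expected:]
                prefix = b.sequence[:expected]
                for i, (x, y) in enumerate(zip(suffix, prefix)):
                    if x != y:
                        raise MergeError(
                            f"overlap region mismatch between {a.name!r} and "
                            f"{b.name!r} at overlap offset {i}: {x!r} != {y!r}"
                        )
        raise MergeError(
            f"no exact overlap of >= {min_overlap} bp between {a.name!r} and {b.name!r}"
        )
    merged = a.sequence + b.sequence[k:]
    start = a.start if a.start is not None else None
    end = b.end if b.end is not None else None
    if start is not None and end is not None and region_length(start, end) != len(merged):
        # coordinates inconsistent with the realized overlap: drop them
        start = end = None
    return Amplicon(name=f"{a.name}+{b.name}", sequence=merged, start=start, end=end)


def merge_chain(amplicons: list[Amplicon], min_overlap: int = 15) -> Amplicon:
    """Left-fold :func:`merge_amplicons` over an ordered amplicon chain."""
    if not amplicons:
        raise MergeError("no amplicons to merge")
    merged = amplicons[0]
    for nxt in amplicons[1:]:
        merged = merge_amplicons(merged, nxt, min_overlap=min_overlap)
    return merged


# ---------------------------------------------------------------------------
# Gene model


def kozak_context(sequence: str, atg_index: int) -> tuple[str | None, str | None, bool]:
    """Bases at -3 and +4 relative to the A of an ATG, and the lenient verdict.

    The check passes iff a purine (A/G) sits at -3 or a G at +4. A position
    falling outside the sequence contributes None and cannot pass.
    """
    minus3 = sequence[atg_index - 3] if atg_index >= 3 else None
    plus4 = sequence[atg_index + 3] if atg_index + 3 < len(sequence) else None
    ok = (minus3 in ("A", "G")) or (plus4 == "G")
    return minus3, plus4, ok


def _first_inframe_stop(sequence: str, atg_index: int) -> int | None:
    """Index of the first in-frame stop codon at/after ``atg_index``, or None."""
    for i in range(atg_index, len(sequence) - 2, 3):
        if sequence[i : i + 3] in _STOPS:
            return i
    return None


def find_orf(sequence: str, require_kozak: bool = True) -> tuple[int, int]:
    """Locate (atg_index, stop_end_index) of the 5'-most acceptable ORF.

    Scans ATGs 5'->3'; an ATG is acceptable if it has an in-frame stop and —
    when ``require_kozak`` — a favorable Kozak context. Falls back to
    ignoring the Kozak filter if no ATG passes it.
    """
    sequence = sequence.upper()
    candidates = []
    i = sequence.find("ATG")
    while i != -1:
        stop = _first_inframe_stop(sequence, i)
        if stop is not None and stop > i:
            candidates.append((i, stop + 3))
        i = sequence.find("ATG", i + 1)
    if not candidates:
        raise ModelError("no ATG with an in-frame stop codon found")
    if require_kozak:
        for atg, end in candidates:
            if kozak_context(sequence, atg)[2]:
                return atg, end
        warnings.warn("no ATG passes the Kozak check; using the 5'-most ORF")
    return candidates[0]


def build_gene_model(
    sequence: str, utr5_len: int | str = "auto", name: str = "gene"
) -> GeneModel:
    """Partition a genomic sequence into UTR5/ORF/UTR3 and derive statistics.

    With ``utr5_len='auto'`` the ORF start is chosen by :func:`find_orf`;
    with an explicit UTR length the ORF must begin with ATG at that offset
    and runs to the first in-frame stop.
    """
    sequence = sequence.upper().replace("U", "T")
    bad = set(sequence) - _DNA
    if bad:
        raise ModelError(f"non-ACGT bases in sequence: {sorted(bad)}")
    if utr5_len == "auto":
        atg, orf_end = find_orf(sequence)
    else:
        atg = int(utr5_len)
        if sequence[atg : atg + 3] != "ATG":
            raise ModelError(f"no ATG at offset {atg} (found {sequence[atg:atg + 3]!r})")
        stop = _first_inframe_stop(sequence, atg)
        if stop is None:
            raise ModelError("no in-frame stop codon downstream of the ATG")
        orf_end = stop + 3
    orf = sequence[atg:orf_end]
    protein = translate(orf)
    minus3, plus4, kozak_ok = kozak_context(sequence, atg)
    return GeneModel(
        name=name,
        sequence=sequence,
        utr5_len=atg,
        orf_len=len(orf),
        utr3_len=len(sequence) - orf_end,
        protein=protein,
        kozak_ok=kozak_ok,
        kozak_minus3=minus3,
        kozak_plus4=plus4,
        gc_pct=gc_percent(sequence),
        mw_kda=molecular_weight(protein),
    )


def translate(orf: str) -> str:
    """Translate an ORF (ATG...stop) under the standard genetic code.

    The terminal stop is required and not included; an internal stop raises
    with its codon index; protein length is ``len(orf)/3 - 1``.
    """
    orf = orf.upper().replace("U", "T")
    if len(orf) % 3:
        raise ModelError(f"ORF length {len(orf)} is not a multiple of 3")
    bad = set(orf) - _DNA
    if bad:
        raise ModelError(f"non-ACGT bases in ORF: {sorted(bad)}")
    if orf[-3:] not in _STOPS:
        raise ModelError(f"ORF does not end with a stop codon (ends {orf[-3:]!r})")
    aa = str(Seq(orf).translate())
    internal = aa[:-1].find("*")
    if internal != -1:
        raise ModelError(f"internal stop codon at codon index {internal}")
    return aa[:-1]


def molecular_weight(protein: str) -> float:
    """Average molecular weight of a peptide in kDa (residues + one water).

    The empty peptide returns the mass of water with a warning.
    """
    if not protein:
        warnings.warn("empty peptide: returning the mass of water")
        return _WATER_DA / 1000.0
    return ProteinAnalysis(protein).molecular_weight() / 1000.0


def gc_percent(sequence: str) -> float:
    """G+C content of a nucleotide sequence, in percent."""
    if not sequence:
        raise ValueError("empty sequence")
    return 100.0 * gc_fraction(sequence.upper())
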