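"""Pairwise allele comparison: alignment, SNP/InDel extraction, consequences.

Two allele sequences (genomic or ORF) are compared by optimal global
alignment with affine gap penalties. Mismatch columns become SNPs; each
maximal gap run becomes a single insertion or deletion whose bases are
left-aligned within repeat context. Positions are reported in ATG-anchored
coordinates of the reference allele (A of ATG = +1, no position 0). An
insertion's position names the reference base *after which* the new bases
sit.

Protein-level consequences are derived by codon arithmetic for individual
SNPs and by protein alignment for the overall substitution count and
inserted/deleted residues; an InDel whose length is not a multiple of three
flags the comparison as a frameshift, and consequences are left undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .gene_assembly import GeneModel, coord_to_index, index_to_coord, translate

__all__ = [
    "PairwiseAlignment",
    "Variant",
    "VariantSet",
    "ProteinConsequences",
    "global_align",
    "identity_pct",
    "call_variants",
    "apply_variants",
    "protein_consequences",
]

DEFAULT_SCORING = {"match": 2, "mismatch": -3, "gap_open": -7, "gap_extend": -2}


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment as two gapped strings plus its score."""

    aligned_a: str
    aligned_b: str
    score: float
    scoring: dict = field(default_factory=lambda: dict(DEFAULT_SCORING))

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")

    def __len__(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class Variant:
    """One difference between two alleles, on reference coordinates."""

    kind: str  # "SNP" | "insertion" | "deletion"
    position: int  # ATG-anchored; for indels, the base after which/at which
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.kind == "SNP" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("SNP must have single-base ref and alt")
        if self.kind == "insertion" and self.ref:
            raise ValueError("insertion must have empty ref")
        if self.kind == "deletion" and self.alt:
            raise ValueError("deletion must have empty alt")
        if self.kind not in ("SNP", "insertion", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")


@dataclass
class VariantSet:
    """All variants called between a reference and an alternate allele."""

    variants: list[Variant]
    identity_pct: float
    utr5_len: int = 0

    @property
    def n_snp(self) -> int:
        return sum(1 for v in self.variants if v.kind == "SNP")

    @property
    def n_indel(self) -> int:
        return sum(1 for v in self.variants if v.kind != "SNP")

    @property
    def snps(self) -> list[Variant]:
        return [v for v in self.variants if v.kind == "SNP"]

    @property
    def indels(self) -> list[Variant]:
        return [v for v in self.variants if v.kind != "SNP"]


def _make_aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # first gap base scores gap_open, each further base gap_extend
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = DEFAULT_SCORING["match"],
    mismatch: float = DEFAULT_SCORING["mismatch"],
    gap_open: float = DEFAULT_SCORING["gap_open"],
    gap_extend: float = DEFAULT_SCORING["gap_extend"],
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap scoring.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``. Among
    co-optimal alignments the first traceback is returned, which is
    deterministic for fixed inputs and parameters.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(seq_a, seq_b)[0]
    return PairwiseAlignment(
        aligned_a=str(alignment[0]),
        aligned_b=str(alignment[1]),
        score=float(alignment.score),
        scoring={
            "match": match,
            "mismatch": mismatch,
            "gap_open": gap_open,
            "gap_extend": gap_extend,
        },
    )


def identity_pct(alignment: PairwiseAlignment) -> float:
    """Percent identity: match columns over all alignment columns (gaps count)."""
    cols = len(alignment)
    if cols == 0:
        raise ValueError("empty alignment")
    matches = sum(
        1
        for x, y in zip(alignment.aligned_a, alignment.aligned_b)
        if x == y and x != "-"
    )
    return 100.0 * matches / cols


def _left_align_insertion(ref: str, anchor: int, bases: str) -> tuple[int, str]:
    """Shift an insertion (after 1-based ref position ``anchor``) left through repeats."""
    while anchor >= 1 and ref[anchor - 1] == bases[-1]:
        bases = ref[anchor - 1] + bases[:-1]
        anchor -= 1
    return anchor, bases


def _left_align_deletion(ref: str, start: int, bases: str) -> tuple[int, str]:
    """Shift a deletion (1-based ref start) left through repeats."""
    while start > 1 and ref[start - 2] == bases[-1]:
        bases = ref[start - 2] + bases[:-1]
        start -= 1
    return start, bases


def call_variants(alignment: PairwiseAlignment, utr5_len: int = 0) -> VariantSet:
    """Extract SNPs and InDels from a pairwise alignment.

    ``utr5_len`` anchors reported positions: a reference base at ungapped
    index i maps to ATG-anchored coordinate ``index_to_coord(i, utr5_len)``.
    Adjacent mismatch columns are separate SNPs; each maximal gap run is one
    InDel, left-aligned within repeat context.
    """
    ref = alignment.seq_a
    variants: list[Variant] = []
    ref_pos = 0  # 1-based position of the last consumed reference base
    ins_run: list[str] = []
    ins_anchor = 0
    del_run: list[str] = []
    del_start = 0

    def flush_runs() -> None:
        nonlocal ins_run, del_run
        if ins_run:
            anchor, bases = _left_align_insertion(ref, ins_anchor, "".join(ins_run))
            coord = index_to_coord(max(anchor - 1, 0), utr5_len)
            variants.append(Variant("insertion", coord, "", bases))
            ins_run = []
        if del_run:
            start, bases = _left_align_deletion(ref, del_start, "".join(del_run))
            coord = index_to_coord(start - 1, utr5_len)
            variants.append(Variant("deletion", coord, bases, ""))
            del_run = []

    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x == "-" and y == "-":
            continue
        if x == "-":
            if del_run:
                flush_runs()
            if not ins_run:
                ins_anchor = ref_pos
            ins_run.append(y)
            continue
        if y == "-":
            if ins_run:
                flush_runs()
            if not del_run:
                del_start = ref_pos + 1
            del_run.append(x)
            ref_pos += 1
            continue
        flush_runs()
        ref_pos += 1
        if x != y:
            variants.append(Variant("SNP", index_to_coord(ref_pos - 1, utr5_len), x, y))
    flush_runs()
    variants.sort(key=lambda v: (coord_to_index(v.position, utr5_len), v.kind))
    return VariantSet(
        variants=variants, identity_pct=identity_pct(alignment), utr5_len=utr5_len
    )


def apply_variants(ref: str, variants: list[Variant], utr5_len: int = 0) -> str:
    """Apply a called variant set to the reference allele (patch operation).

    ``apply_variants(a, call_variants(align(a, b)).variants) == b`` for any
    alignment produced by :func:`global_align`.
    """
    seq = ref

    def idx(v: Variant) -> int:
        return coord_to_index(v.position, utr5_len)

    for v in sorted(variants, key=idx, reverse=True):
        i = idx(v)
        if v.kind == "SNP":
            if seq[i] != v.ref:
                raise ValueError(f"reference mismatch at {v.position}: {seq[i]} != {v.ref}")
            seq = seq[:i] + v.alt + seq[i + 1 :]
        elif v.kind == "insertion":
            seq = seq[: i + 1] + v.alt + seq[i + 1 :]
        else:  # deletion
            if seq[i : i + len(v.ref)] != v.ref:
                raise ValueError(f"reference mismatch at deletion {v.position}")
            seq = seq[:i] + seq[i + len(v.ref) :]
    return seq


@dataclass(frozen=True)
class ProteinConsequences:
    """Protein-level summary of a variant set between two alleles."""

    protein_len_a: int
    protein_len_b: int
    aa_substitutions: int | None
    inserted_residues: str
    deleted_residues: str
    frameshift: bool
    snp_effects: tuple[tuple[int, str, str, str], ...] = ()
    # (codon number, ref AA, alt AA, "synonymous"|"missense"|"nonsense")


def _snp_codon_effects(
    variant_set: VariantSet, orf_a: str
) -> list[tuple[int, str, str, str]]:
    effects = []
    for v in variant_set.snps:
        pos = v.position  # ATG-anchored; ORF bases are 1..len(orf_a)
        if not (1 <= pos <= len(orf_a) - 3):  # skip UTRs and the stop codon
            continue
        ci = (pos - 1) // 3
        codon = orf_a[ci * 3 : ci * 3 + 3]
        offset = (pos - 1) % 3
        alt_codon = codon[:offset] + v.alt + codon[offset + 1 :]
        ref_aa = translate(codon + "TAA")
        alt_aa = "*" if alt_codon in ("TAA", "TAG", "TGA") else translate(alt_codon + "TAA")
        if alt_aa == "*":
            kind = "nonsense"
        elif alt_aa == ref_aa:
            kind = "synonymous"
        else:
            kind = "missense"
        effects.append((ci + 1, ref_aa, alt_aa, kind))
    return effects


def protein_consequences(
    variant_set: VariantSet, gene_a: GeneModel | str, gene_b: GeneModel | str
) -> ProteinConsequences:
    """Protein consequences of a variant set between two alleles.

    ``gene_a``/``gene_b`` may be gene models or bare ORF sequences. An
    in-frame insertion of 3k bases adds k residues; the overall substitution
    count comes from a protein alignment; per-SNP codon effects are computed
    on the reference ORF. Any InDel of length not divisible by three flags a
    frameshift and leaves the substitution count undefined.
    """
    orf_a = gene_a.orf if isinstance(gene_a, GeneModel) else str(gene_a).upper()
    orf_b = gene_b.orf if isinstance(gene_b, GeneModel) else str(gene_b).upper()
    prot_a = gene_a.protein if isinstance(gene_a, GeneModel) else translate(orf_a)
    prot_b = gene_b.protein if isinstance(gene_b, GeneModel) else translate(orf_b)

    frameshift = any(
        len(v.alt if v.kind == "insertion" else v.ref) % 3 for v in variant_set.indels
    )
    if frameshift:
        return ProteinConsequences(
            protein_len_a=len(prot_a),
            protein_len_b=len(prot_b),
            aa_substitutions=None,
            inserted_residues="",
            deleted_residues="",
            frameshift=True,
        )
    aln = global_align(prot_a, prot_b)
    subs = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x != y and "-" not in (x, y)
    )
    inserted = "".join(
        y for x, y in zip(aln.aligned_a, aln.aligned_b) if x == "-" and y != "-"
    )
    deleted = "".join(
        x for x, y in zip(aln.aligned_a, aln.aligned_b) if y == "-" and x != "-"
    )
    return ProteinConsequences(
        protein_len_a=len(prot_a),
        protein_len_b=len(prot_b),
        aa_substitutions=subs,
        inserted_residues=inserted,
        deleted_residues=deleted,
        frameshift=False,
        snp_effects=tuple(_snp_codon_effects(variant_set, orf_a)),
    )
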