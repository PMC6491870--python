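"""In-silico PCR with allele-specific 3'-end discrimination, and genotyping.

Allele-specific STS assays discriminate alleles through mismatches at or
near the primer 3' terminus, where *Taq* extension is intolerant of
mispairing. A primer binds a template site only if its 3'-terminal bases
match exactly (default 3) and total mismatches stay within a budget
(default 2). Products are enumerated from convergent forward/reverse site
pairs; no thermodynamic model is attempted, annealing temperatures are
metadata.

Two complementary dominant assays — each amplifying exactly one allele —
together act as a codominant genotype call: product in one assay only
identifies the allele, products in both flag ambiguity, neither is a null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "Primer",
    "MarkerAssay",
    "BindingSite",
    "PCRProduct",
    "GenotypeCall",
    "find_binding_sites",
    "insilico_pcr",
    "call_genotype",
    "genotype_template",
    "revcomp",
]

_DNA = set("ACGT")


def revcomp(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5' -> 3'."""

    name: str
    sequence: str
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq or set(seq) - _DNA:
            raise ValueError(f"primer {self.name!r}: sequence must be non-empty ACGT")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MarkerAssay:
    """A primer pair with its expected product size and diagnostic allele."""

    name: str
    forward: Primer
    reverse: Primer
    expected_size: int
    diagnostic_allele: str | None = None
    annealing_temp: float | None = None  # degrees C, metadata only

    def __post_init__(self) -> None:
        if self.expected_size <= len(self.forward) + len(self.reverse):
            raise ValueError(
                f"assay {self.name!r}: expected size {self.expected_size} must exceed "
                "the summed primer lengths"
            )


@dataclass(frozen=True)
class BindingSite:
    """A primer binding site, in plus-strand template coordinates [start, end)."""

    primer: str
    strand: str  # '+' : primer extends rightward; '-' : leftward
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class PCRProduct:
    template: str
    size: int
    start: int  # plus-strand 5' end of the leftmost primer
    end: int  # one past the plus-strand 5' end of the rightmost primer
    forward_site: BindingSite | None = None
    reverse_site: BindingSite | None = None


@dataclass(frozen=True)
class GenotypeCall:
    variety: str
    allele: str  # allele name | "ambiguous" | "null"
    evidence: dict = field(default_factory=dict)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def find_binding_sites(
    primer: Primer | str,
    template: str,
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
) -> list[BindingSite]:
    """All template sites where the primer can prime synthesis.

    Both strands are scanned. A site qualifies iff the primer's 3'-terminal
    ``three_prime_exact`` bases match exactly and total mismatches are at
    most ``max_mismatch``. On the plus strand the primer sequence is
    compared directly to the template window; on the minus strand the
    window's reverse complement is compared (the primer extends leftward on
    plus-strand coordinates).
    """
    if isinstance(primer, str):
        primer = Primer(name="primer", sequence=primer)
    template = template.upper()
    p = primer.sequence
    n, L = len(template), len(p)
    if L > n:
        return []
    k = min(three_prime_exact, L)
    sites: list[BindingSite] = []
    for start in range(n - L + 1):
        window = template[start : start + L]
        # plus strand: 3' end of the primer sits at the window's right edge
        if p[L - k :] == window[L - k :]:
            mm = _hamming(p, window)
            if mm <= max_mismatch:
                sites.append(BindingSite(primer.name, "+", start, start + L, mm))
        # minus strand: primer anneals to the plus strand shown; its 3' end
        # pairs with the window's left edge
        window_rc = revcomp(window)
        if p[L - k :] == window_rc[L - k :]:
            mm = _hamming(p, window_rc)
            if mm <= max_mismatch:
                sites.append(BindingSite(primer.name, "-", start, start + L, mm))
    return sites


def insilico_pcr(
    assay: MarkerAssay,
    template: str,
    template_name: str = "template",
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
    max_product_size: int = 5000,
) -> list[PCRProduct]:
    """Enumerate PCR products of an assay on a template.

    A product forms for every convergent pair of binding sites — one primer
    extending rightward (plus strand), the other leftward (minus strand),
    with the rightward site upstream — whose span does not exceed
    ``max_product_size``. The size is the distance between the two primers'
    5' ends, both included.
    """
    template = template.upper()
    kwargs = dict(max_mismatch=max_mismatch, three_prime_exact=three_prime_exact)
    sites = find_binding_sites(assay.forward, template, **kwargs) + find_binding_sites(
        assay.reverse, template, **kwargs
    )
    plus = [s for s in sites if s.strand == "+"]
    minus = [s for s in sites if s.strand == "-"]
    products = []
    for f in plus:
        for r in minus:
            size = r.end - f.start
            if r.start >= f.start and size <= max_product_size and size > 0:
                products.append(
                    PCRProduct(
                        template=template_name,
                        size=size,
                        start=f.start,
                        end=r.end,
                        forward_site=f,
                        reverse_site=r,
                    )
                )
    return sorted(products, key=lambda p: (p.start, p.size))


def _match_size(products, expected: int, tolerance: int, assay: str) -> bool:
    hit = False
    for p in products:
        if abs(p.size - expected) <= tolerance:
            hit = True
        else:
            warnings.warn(
                f"assay {assay}: ignoring unexpected {p.size}-bp product "
                f"(expected {expected} +/- {tolerance})",
                stacklevel=3,
            )
    return hit


def call_genotype(
    products_b_assay: list[PCRProduct],
    products_a_assay: list[PCRProduct],
    variety: str = "variety",
    allele_b: str = "TaPod-D1b",
    allele_a: str = "TaPod-D1a",
    size_b: int = 540,
    size_a: int = 640,
    size_tolerance: int = 10,
) -> GenotypeCall:
    """Genotype from the two complementary dominant assays.

    The first argument holds the products of the assay diagnostic for
    ``allele_b`` (default the 540-bp assay), the second those of the assay
    diagnostic for ``allele_a`` (default 640 bp). Exactly one expected-size
    product identifies its allele; both present flag "ambiguous"
    (heterozygosity/contamination); neither yields "null". Products of
    unexpected size are ignored with a warning.
    """
    has_b = _match_size(products_b_assay, size_b, size_tolerance, "b-assay")
    has_a = _match_size(products_a_assay, size_a, size_tolerance, "a-assay")
    if has_b and has_a:
        allele = "ambiguous"
    elif has_b:
        allele = allele_b
    elif has_a:
        allele = allele_a
    else:
        allele = "null"
    return GenotypeCall(
        variety=variety,
        allele=allele,
        evidence={
            "b_assay_sizes": [p.size for p in products_b_assay],
            "a_assay_sizes": [p.size for p in products_a_assay],
        },
    )


def genotype_template(
    template: str,
    assay_b: MarkerAssay,
    assay_a: MarkerAssay,
    variety: str = "variety",
    **pcr_kwargs,
) -> GenotypeCall:
    """Run both complementary assays on one template and call the genotype."""
    prods_b = insilico_pcr(assay_b, template, template_name=variety, **pcr_kwargs)
    prods_a = insilico_pcr(assay_a, template, template_name=variety, **pcr_kwargs)
    return call_genotype(
        prods_b,
        prods_a,
        variety=variety,
        allele_b=assay_b.diagnostic_allele or "allele_b",
        allele_a=assay_a.diagnostic_allele or "allele_a",
        size_b=assay_b.expected_size,
        size_a=assay_a.expected_size,
    )
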