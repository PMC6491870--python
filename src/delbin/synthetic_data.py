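"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of input the analysis consumes —
aneuploid stock panels with known deletion breakpoints, amplification
matrices derived from a marker's true arm position (optionally with call
errors), allele pairs with planted substitutions and one in-frame
insertion, PCR templates with planted primer-binding sites, and genotyped
variety panels with replicate enzyme activities — and returns the ground
truth alongside the data so recovery can be asserted exactly.

Defaults reproduce the dimensions of the wheat peroxidase study the
package is built around: a group-7 Chinese Spring panel, a 1121-bp allele
with a 1074-bp ORF, 21 exonic SNPs plus one 6-bp insertion ("GCTGTG"
between ORF bases 42 and 43), complementary 540/640-bp STS assays, and a
224-variety panel split 83/64 + 32/45 over two growing regions with
activities on the 650-760 U min^-1 g^-1 scale.

All randomness flows from a single integer seed (or an explicit
``numpy.random.Generator``); identical seed and configuration give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import PhenotypeRecord, replicate_cv
from .marker_toolkit import MarkerAssay, Primer, revcomp
from .stock_panel import (
    AmplificationMatrix,
    AneuploidLine,
    Call,
    StockClass,
    StockPanel,
)
from .variant_caller import Variant, VariantSet

__all__ = [
    "MarkerTruth",
    "PanelConfig",
    "AlleleConfig",
    "TemplateConfig",
    "PhenotypeConfig",
    "gen_stock_panel",
    "gen_amplification_matrix",
    "gen_allele_pair",
    "gen_pcr_template",
    "gen_variety_panel",
    "default_sts_assays",
    "WHEAT_CHROMOSOMES",
]

WHEAT_CHROMOSOMES = [f"{g}{x}" for g in range(1, 8) for x in "ABD"]
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Stock panels and amplification matrices


@dataclass(frozen=True)
class MarkerTruth:
    """The true location of a marker: chromosome, arm and FL position."""

    marker: str
    chromosome: str
    arm: str
    fl: float

    def __post_init__(self) -> None:
        if not (0.0 < self.fl <= 1.0):
            raise ValueError("true FL position must lie in (0, 1]")


@dataclass
class PanelConfig:
    """Composition of a synthetic aneuploid panel.

    ``del_breakpoints`` maps an arm label (e.g. ``7DS``) to its deletion
    breakpoints; each chromosome named there or in ``dt_chromosomes`` gets a
    Dt pair, and each chromosome in ``nt_chromosomes`` one NT line.
    """

    nt_chromosomes: list[str] = field(default_factory=lambda: list(WHEAT_CHROMOSOMES))
    dt_chromosomes: list[str] = field(default_factory=lambda: ["7A", "7B", "7D"])
    del_breakpoints: dict = field(
        default_factory=lambda: {
            "7AS": [0.89, 0.73, 0.29, 0.26, 0.59, 0.21, 0.87, 0.66, 0.45, 0.83],
            "7AL": [0.39, 0.87, 0.18, 0.80, 0.33, 0.83, 0.89, 0.49,
                    0.40, 0.31, 0.99, 0.86, 0.71, 0.90, 0.89, 0.74],
            "7BL": [0.40, 0.33, 0.86, 0.56, 0.69, 0.84, 0.48, 0.25, 0.79],
            "7DS": [0.37, 0.61, 0.36],
        }
    )


def _tetrasomic_for(chromosome: str) -> str:
    genomes = "ABD"
    group, genome = chromosome[0], chromosome[1]
    return f"{group}{genomes[(genomes.index(genome) + 1) % 3]}"


def gen_stock_panel(config: PanelConfig | None = None) -> StockPanel:
    """Build a synthetic stock panel (NT set, Dt pairs, Del lines)."""
    config = config or PanelConfig()
    lines: list[AneuploidLine] = []
    for c in config.nt_chromosomes:
        t = _tetrasomic_for(c)
        lines.append(
            AneuploidLine(
                name=f"N{c}T{t}",
                stock_class=StockClass.NT,
                nullisomic_chromosome=c,
                tetrasomic_chromosome=t,
            )
        )
    dt_chroms = sorted(set(config.dt_chromosomes) | {a[:-1] for a in config.del_breakpoints})
    for c in dt_chroms:
        for arm in "SL":
            lines.append(
                AneuploidLine(
                    name=f"Dt{c}{arm}", stock_class=StockClass.DT, chromosome=c, arm=arm
                )
            )
    for arm_label, breakpoints in sorted(config.del_breakpoints.items()):
        chromosome, arm = arm_label[:-1], arm_label[-1]
        for i, fl in enumerate(breakpoints, start=1):
            lines.append(
                AneuploidLine(
                    name=f"Del{arm_label}-{i}",
                    stock_class=StockClass.DEL,
                    chromosome=chromosome,
                    arm=arm,
                    breakpoint_fl=fl,
                )
            )
    return StockPanel(lines)


def true_call(line: AneuploidLine, truth: MarkerTruth) -> Call:
    """Error-free amplification call for one line under the deletion geometry.

    A Del line with breakpoint FL f retains the proximal interval [0, f] of
    its arm; the marker (at position p on its arm) amplifies iff retained,
    i.e. p <= f. NT lines lose the marker iff nullisomic for its chromosome;
    Dt lines iff they retain the other arm of its chromosome.
    """
    if line.stock_class is StockClass.NT:
        return (
            Call.ABSENT
            if line.nullisomic_chromosome == truth.chromosome
            else Call.PRESENT
        )
    if line.stock_class is StockClass.DT:
        if line.chromosome != truth.chromosome or line.arm == truth.arm:
            return Call.PRESENT
        return Call.ABSENT
    if line.stock_class is StockClass.DEL:
        if line.chromosome != truth.chromosome or line.arm != truth.arm:
            return Call.PRESENT
        return Call.PRESENT if truth.fl <= line.breakpoint_fl else Call.ABSENT
    return Call.PRESENT  # euploid


def gen_amplification_matrix(
    panel: StockPanel,
    truth: MarkerTruth,
    false_absent: float = 0.0,
    false_present: float = 0.0,
    seed=0,
) -> AmplificationMatrix:
    """Amplification matrix implied by a marker's true position, plus errors.

    Error-free calls follow :func:`true_call`; each call is then flipped
    independently (present -> absent with ``false_absent``, absent ->
    present with ``false_present``).
    """
    if not (0 <= false_absent <= 1 and 0 <= false_present <= 1):
        raise ValueError("error probabilities must lie in [0, 1]")
    rng = _rng(seed)
    calls: dict[tuple[str, str], Call] = {}
    for line in panel:
        call = true_call(line, truth)
        u = rng.random()
        if call is Call.PRESENT and u < false_absent:
            call = Call.ABSENT
        elif call is Call.ABSENT and u < false_present:
            call = Call.PRESENT
        calls[(truth.marker, line.name)] = call
    return AmplificationMatrix(markers=[truth.marker], panel=panel, calls=calls)


# ---------------------------------------------------------------------------
# Allele pairs


@dataclass
class AlleleConfig:
    """Shape of a synthetic allele pair.

    The reference allele has ``utr5_len + orf_len + utr3_len`` bases with a
    clean ORF (ATG ... stop, no internal stop). The alternate allele applies
    ``n_snps`` exonic substitutions (non-adjacent, sparing the start and
    stop codons) and the configured in-frame insertion. Defaults mirror the
    two peroxidase alleles this package models: a 1074-bp ORF (357
    residues), 21 SNPs, and a 6-bp "GCTGTG" insertion after ORF base 42
    which adds Ala-Val after residue 14.
    """

    utr5_len: int = 20
    orf_len: int = 1074
    utr3_len: int = 27
    n_snps: int = 21
    insertion_after: int | None = 42  # ORF base; None disables the InDel
    insertion_bases: str = "GCTGTG"
    gc: float = 0.695
    min_spacing: int = 2

    def __post_init__(self) -> None:
        if self.orf_len % 3:
            raise ValueError("ORF length must be divisible by 3")
        if not (0 < self.gc < 1):
            raise ValueError("gc must lie in (0, 1)")
        if self.insertion_after is not None and len(self.insertion_bases) == 0:
            raise ValueError("insertion bases must be non-empty")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return "".join(rng.choice(_BASES, size=n, p=p))


def _random_codon(rng: np.random.Generator, gc: float, forbid_stop: bool = True) -> str:
    while True:
        codon = _random_bases(rng, 3, gc)
        if not forbid_stop or codon not in _STOPS:
            return codon


def gen_allele_pair(
    config: AlleleConfig | None = None, seed=0
) -> tuple[str, str, VariantSet]:
    """Generate a reference/alternate allele pair and the ground truth.

    Returns ``(seq_a, seq_b, truth)`` where ``truth`` holds the planted
    variants in ATG-anchored coordinates of ``seq_a``. SNP placement avoids
    the start and stop codons, keeps a minimum spacing, stays clear of the
    insertion point, and never creates a premature stop in the alternate
    ORF. The sequence context left of the insertion point is adjusted so
    the planted insertion is already left-aligned.
    """
    config = config or AlleleConfig()
    rng = _rng(seed)
    n_codons = config.orf_len // 3
    if n_codons < 2:
        raise ValueError("ORF too short")
    codons = ["ATG"]
    codons += [_random_codon(rng, config.gc) for _ in range(n_codons - 2)]
    codons.append(str(rng.choice(["TAA", "TGA", "TAG"])))
    orf = list("".join(codons))

    ins_at = config.insertion_after
    if ins_at is not None:
        if not (3 < ins_at < config.orf_len - 3):
            raise ValueError("insertion point must be inside the ORF body")
        # keep the planted insertion left-aligned: the base before the
        # insertion point must differ from the insertion's last base
        tail = config.insertion_bases[-1]
        if orf[ins_at - 1] == tail:
            ci = (ins_at - 1) // 3
            offset = (ins_at - 1) % 3
            for b in "ACGT":
                if b == tail:
                    continue
                trial = orf[ci * 3 : ci * 3 + 3]
                trial[offset] = b
                if "".join(trial) not in _STOPS:
                    orf[ins_at - 1] = b
                    break

    utr5 = _random_bases(rng, config.utr5_len, config.gc)
    utr3 = _random_bases(rng, config.utr3_len, config.gc)
    seq_a = utr5 + "".join(orf) + utr3

    # SNP positions: ORF bases 4 .. orf_len-3, min spacing, and an 8-bp
    # exclusion flank around the insertion so the planted indel keeps a
    # unique context and the alignment cannot trade SNPs against split gaps
    forbidden: set[int] = set()
    if ins_at is not None:
        forbidden = set(range(ins_at - 7, ins_at + 9))
    candidates = [
        p for p in range(4, config.orf_len - 2) if p not in forbidden
    ]
    rng.shuffle(candidates)
    positions: list[int] = []
    for p in candidates:
        if len(positions) == config.n_snps:
            break
        if all(abs(p - q) >= config.min_spacing for q in positions):
            positions.append(p)
    if len(positions) < config.n_snps:
        raise ValueError(
            f"cannot place {config.n_snps} SNPs with spacing "
            f"{config.min_spacing} in a {config.orf_len}-bp ORF"
        )
    positions.sort()

    orf_b = list(orf)
    snvs: list[Variant] = []
    for p in positions:
        i = p - 1
        ref_base = orf[i]
        ci, offset = i // 3, i % 3
        choices = [b for b in "ACGT" if b != ref_base]
        rng.shuffle(choices)
        for alt in choices:
            codon = orf_b[ci * 3 : ci * 3 + 3]
            codon[offset] = alt
            if "".join(codon) not in _STOPS:
                orf_b[i] = alt
                snvs.append(Variant("SNP", p, ref_base, alt))
                break
        else:  # pragma: no cover - three alternatives can't all be stops
            raise RuntimeError("no stop-free substitution available")

    variants: list[Variant] = list(snvs)
    if ins_at is not None:
        orf_b = orf_b[:ins_at] + list(config.insertion_bases) + orf_b[ins_at:]
        variants.append(Variant("insertion", ins_at, "", config.insertion_bases))
    variants.sort(key=lambda v: v.position)
    seq_b = utr5 + "".join(orf_b) + utr3

    ins_len = len(config.insertion_bases) if ins_at is not None else 0
    columns = len(seq_a) + ins_len
    identity = 100.0 * (len(seq_a) - config.n_snps) / columns
    truth = VariantSet(
        variants=variants, identity_pct=identity, utr5_len=config.utr5_len
    )
    return seq_a, seq_b, truth


# ---------------------------------------------------------------------------
# PCR templates


def default_sts_assays() -> tuple[MarkerAssay, MarkerAssay]:
    """The packaged complementary STS assay pair (540-bp and 640-bp).

    Returns ``(assay_b, assay_a)``: the 540-bp assay diagnostic for the
    high-activity allele and the 640-bp assay diagnostic for the
    low-activity allele.
    """
    from .stock_panel import load_pod_primer_table

    df = load_pod_primer_table()
    assays = {}
    for _, row in df[df["kind"] == "sts"].iterrows():
        assays[row["assay"]] = MarkerAssay(
            name=row["assay"],
            forward=Primer(f"{row['assay']}-F", row["forward"], "forward"),
            reverse=Primer(f"{row['assay']}-R", row["reverse"], "reverse"),
            expected_size=int(row["expected_size"]),
            diagnostic_allele=row["diagnostic_allele"],
            annealing_temp=float(row["annealing_c"]),
        )
    return assays["POD-7D1"], assays["POD-7D6"]


@dataclass
class TemplateConfig:
    """Geometry of synthetic genotyping templates.

    Both templates share a single reverse-primer site (the two assays'
    reverse primers are near-identical, as in the real marker system) and
    carry both forward-primer sites at offsets implied by the expected
    product sizes; the non-target allele's diagnostic forward site gets a
    3'-terminal mismatch.
    """

    template_len: int = 900
    rev_margin: int = 60  # backbone retained right of the reverse site
    gc: float = 0.5


def gen_pcr_template(
    config: TemplateConfig | None = None,
    assays: tuple[MarkerAssay, MarkerAssay] | None = None,
    seed=0,
) -> tuple[dict[str, str], dict]:
    """Build one template per allele with planted primer-binding sites.

    Returns ``(templates, truth)``: templates keyed by allele name, truth
    recording planted offsets and the expected product size per (allele,
    assay). Raises if the template cannot hold the largest product.
    """
    config = config or TemplateConfig()
    assay_b, assay_a = assays or default_sts_assays()
    rng = _rng(seed)
    allele_b = assay_b.diagnostic_allele or "allele_b"
    allele_a = assay_a.diagnostic_allele or "allele_a"

    # the two reverse primers must target one shared site: one suffix of the other
    rev_a, rev_b = assay_a.reverse.sequence, assay_b.reverse.sequence
    long_rev = rev_a if len(rev_a) >= len(rev_b) else rev_b
    if not long_rev.endswith(rev_a) or not long_rev.endswith(rev_b):
        raise ValueError("reverse primers must share a common 3' site")

    rev_end = config.template_len - config.rev_margin  # one past 5' end of long rev
    starts = {}
    for assay in (assay_b, assay_a):
        # product spans from the forward 5' end to this assay's reverse 5' end
        this_rev_end = rev_end - (len(long_rev) - len(assay.reverse.sequence))
        start = this_rev_end - assay.expected_size
        if start < 0:
            raise ValueError(
                f"template of {config.template_len} bp too short for the "
                f"{assay.expected_size}-bp product of {assay.name}"
            )
        starts[assay.name] = start
    fb, fa = starts[assay_b.name], starts[assay_a.name]
    spans = sorted(
        [(fb, fb + len(assay_b.forward)), (fa, fa + len(assay_a.forward))]
    )
    if spans[0][1] > spans[1][0]:
        raise ValueError("forward-primer sites overlap; enlarge the size difference")

    def build(target_assay: MarkerAssay, off_assay: MarkerAssay) -> str:
        template = list(_random_bases(rng, config.template_len, config.gc))
        site_rev = revcomp(long_rev)
        template[rev_end - len(long_rev) : rev_end] = list(site_rev)
        for assay in (target_assay, off_assay):
            s = starts[assay.name]
            template[s : s + len(assay.forward)] = list(assay.forward.sequence)
        # kill the off-target assay at its forward 3' terminus
        mm_pos = starts[off_assay.name] + len(off_assay.forward) - 1
        current = template[mm_pos]
        template[mm_pos] = str(rng.choice([b for b in "ACGT" if b != current]))
        return "".join(template)

    templates = {
        allele_b: build(assay_b, assay_a),
        allele_a: build(assay_a, assay_b),
    }
    truth = {
        "forward_offsets": dict(starts),
        "reverse_site_end": rev_end,
        "expected": {
            (allele_b, assay_b.name): assay_b.expected_size,
            (allele_a, assay_a.name): assay_a.expected_size,
        },
    }
    return templates, truth


# ---------------------------------------------------------------------------
# Variety panels


@dataclass
class PhenotypeConfig:
    """Composition of a synthetic genotyped, phenotyped variety panel.

    Defaults reproduce the dimensions of the 224-variety association panel:
    group sizes 83/64 (region YHRVWWR) and 32/45 (region NWWR) for the
    high- and low-activity alleles, per-group mean activities on the
    650-760 U min^-1 g^-1 scale, between-variety SD 80, and duplicate
    assays with a 5% replicate CV (a third replicate is drawn whenever the
    duplicate CV exceeds the QC threshold, emulating the retest protocol).
    """

    group_sizes: dict = field(
        default_factory=lambda: {
            ("YHRVWWR", "TaPod-D1b"): 83,
            ("YHRVWWR", "TaPod-D1a"): 64,
            ("NWWR", "TaPod-D1b"): 32,
            ("NWWR", "TaPod-D1a"): 45,
        }
    )
    group_means: dict = field(
        default_factory=lambda: {
            ("YHRVWWR", "TaPod-D1b"): 689.3,
            ("YHRVWWR", "TaPod-D1a"): 654.6,
            ("NWWR", "TaPod-D1b"): 757.8,
            ("NWWR", "TaPod-D1a"): 706.7,
        }
    )
    between_sd: float = 80.0
    replicate_cv_pct: float = 5.0
    cv_threshold: float = 10.0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.between_sd < 0 or self.replicate_cv_pct < 0:
            raise ValueError("dispersions must be >= 0")
        if set(self.group_sizes) != set(self.group_means):
            raise ValueError("group_sizes and group_means must share keys")


def gen_variety_panel(
    config: PhenotypeConfig | None = None, seed=0
) -> tuple[dict[str, str], list[PhenotypeRecord], dict]:
    """Generate genotype calls and replicate phenotypes for a variety panel.

    Variety means are drawn per (region, allele) group from a normal law
    with the configured mean and between-variety SD; duplicates are drawn
    around each variety mean with the replicate CV, and a third replicate
    is added whenever the duplicate CV exceeds the QC threshold. Returns
    ``(calls, records, truth)`` with the drawn variety means in ``truth``.
    """
    config = config or PhenotypeConfig()
    rng = _rng(seed)
    calls: dict[str, str] = {}
    records: list[PhenotypeRecord] = []
    truth_means: dict[str, float] = {}
    idx = 0
    for (region, allele), n in sorted(config.group_sizes.items()):
        mu = config.group_means[(region, allele)]
        for _ in range(n):
            idx += 1
            name = f"V{idx:04d}"
            vm = float(rng.normal(mu, config.between_sd))
            vm = max(vm, 1.0)  # activities are positive
            rep_sd = config.replicate_cv_pct / 100.0 * vm
            reps = [max(float(rng.normal(vm, rep_sd)), 0.5) for _ in range(2)]
            if replicate_cv(reps) > config.cv_threshold:
                reps.append(max(float(rng.normal(vm, rep_sd)), 0.5))
            calls[name] = allele
            truth_means[name] = vm
            records.append(
                PhenotypeRecord(variety=name, region=region, replicates=tuple(reps))
            )
    truth = {
        "variety_means": truth_means,
        "group_sizes": dict(config.group_sizes),
        "group_means": dict(config.group_means),
    }
    return calls, records, truth
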