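"""Shared readers/writers and the pipeline orchestrator.

FASTA handling goes through Biopython's SeqIO; tabular formats through
pandas. Every report written by :func:`run_pipeline` starts with a header
comment carrying the tool version, the seed and a parameter hash, and a
rerun with identical configuration and seed reproduces the files byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .association import associate, parse_phenotype_table
from .bin_mapper import map_bins
from .gene_assembly import Amplicon, build_gene_model, merge_chain
from .marker_toolkit import genotype_template
from .stock_panel import parse_amplification_table, parse_stock_registry
from .synthetic_data import default_sts_assays
from .variant_caller import call_variants, global_align

__all__ = ["read_fasta", "write_fasta", "RunConfig", "run_pipeline", "report_header"]

logger = logging.getLogger("delbin")


def configure_logging(verbosity: int = 0) -> None:
    """Timestamped, stage-prefixed logging to standard error."""
    level = logging.WARNING if verbosity < 0 else (
        logging.INFO if verbosity == 0 else logging.DEBUG
    )
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(asctime)s [%(name)s] %(levelname)s: %(message)s",
        force=True,
    )


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an order-preserving ``{name: sequence}`` mapping.

    Wrapped or unwrapped lines are accepted, lowercase bases are upper-cased,
    duplicate identifiers raise.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    """Write ``{name: sequence}`` to FASTA, preserving order."""
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def report_header(seed, params: dict) -> str:
    digest = hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# delbin v{__version__} seed={seed} params={digest}\n"


@dataclass
class RunConfig:
    """Inputs and parameters of a full pipeline run."""

    registry: str | None = None
    matrix: str | None = None
    amplicons: str | None = None  # FASTA, ordered 5'->3'
    alleles: str | None = None  # FASTA with exactly two records
    templates: str | None = None  # FASTA of genotyping templates
    phenotypes: str | None = None  # CSV variety,region,rep1,rep2[,rep3]
    out_dir: str = "delbin_out"
    seed: int = 0
    utr5_len: int | str = "auto"
    min_overlap: int = 15
    alphas: tuple[float, ...] = (0.05, 0.01)
    tolerant: bool = False
    params: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write their reports.

    Stages run in method order — bin mapping, amplicon assembly, variant
    calling, genotyping, association — each only when its inputs are
    configured. Returns a dict of in-memory results keyed by stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = report_header(config.seed, {**config.params, "version": __version__})
    results: dict = {}

    if config.registry and config.matrix:
        logger.info("map-bins: %s + %s", config.registry, config.matrix)
        panel = parse_stock_registry(config.registry)
        matrix = parse_amplification_table(config.matrix, panel)
        bins = map_bins(matrix, tolerant=config.tolerant)
        with open(out / "bins.tsv", "w") as fh:
            fh.write(header)
            bins.to_csv(fh, sep="\t", index=False)
        results["bins"] = bins

    if config.amplicons:
        logger.info("assemble: %s", config.amplicons)
        seqs = read_fasta(config.amplicons)
        amplicons = [Amplicon(name=n, sequence=s) for n, s in seqs.items()]
        merged = merge_chain(amplicons, min_overlap=config.min_overlap)
        model = build_gene_model(merged.sequence, utr5_len=config.utr5_len, name=merged.name)
        write_fasta({model.name: model.sequence}, out / "gene.fasta")
        with open(out / "gene_model.json", "w") as fh:
            fh.write(header)
            json.dump(model.to_dict(), fh, indent=2)
            fh.write("\n")
        results["gene_model"] = model

    if config.alleles:
        logger.info("call-variants: %s", config.alleles)
        seqs = read_fasta(config.alleles)
        if len(seqs) != 2:
            raise ValueError("allele FASTA must contain exactly two records")
        (name_a, seq_a), (name_b, seq_b) = seqs.items()
        utr5 = 0 if config.utr5_len == "auto" else int(config.utr5_len)
        aln = global_align(seq_a, seq_b)
        vs = call_variants(aln, utr5_len=utr5)
        with open(out / "variants.tsv", "w") as fh:
            fh.write(header)
            fh.write("kind\tposition\tref\talt\n")
            for v in vs.variants:
                fh.write(f"{v.kind}\t{v.position}\t{v.ref or '.'}\t{v.alt or '.'}\n")
        results["variants"] = vs

    if config.templates:
        logger.info("genotype: %s", config.templates)
        assay_b, assay_a = default_sts_assays()
        calls = {
            name: genotype_template(seq, assay_b, assay_a, variety=name).allele
            for name, seq in read_fasta(config.templates).items()
        }
        with open(out / "genotypes.tsv", "w") as fh:
            fh.write(header)
            fh.write("variety\tallele\n")
            for name, allele in calls.items():
                fh.write(f"{name}\t{allele}\n")
        results["genotypes"] = calls

    if config.phenotypes and results.get("genotypes"):
        logger.info("associate: %s", config.phenotypes)
        records = parse_phenotype_table(config.phenotypes)
        assoc = associate(results["genotypes"], records, alphas=config.alphas)
        with open(out / "association.tsv", "w") as fh:
            fh.write(header)
            assoc.to_frame().to_csv(fh, sep="\t", index=False)
        with open(out / "association.json", "w") as fh:
            payload = {
                scope: None
                if a is None
                else {
                    "F": a.f_statistic,
                    "p": a.p_value,
                    "df": [a.df_between, a.df_within],
                    "group_sizes": list(a.group_sizes),
                    "group_means": list(a.group_means),
                }
                for scope, a in assoc.anova.items()
            }
            json.dump({"anova": payload, "n_excluded": assoc.n_excluded}, fh, indent=2)
            fh.write("\n")
        results["association"] = assoc

    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "seed": config.seed,
                "params": {k: str(v) for k, v in config.params.items()},
                "stages": sorted(results),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return results
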