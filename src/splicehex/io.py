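"""Readers and writers for the pipeline's on-disk formats.

Coordinates follow each format's convention and are converted at this
boundary: BED junction records are 0-based half-open over the intron, VCF
and FASTA are 1-based, and everything internal uses the 1-based
intron-terminal-base convention of :mod:`splicehex.genome`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import ACCEPTOR, DONOR

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- VCF

def write_vcf(variants: pd.DataFrame, dosages: pd.DataFrame, path,
              ploidy: str = "inbred") -> None:
    """VCF v4.2 with GT calls (haploid 0/1 for inbred panels, else diploid)."""
    individuals = list(dosages.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(individuals) + "\n")
        order = variants.sort_values(["chrom", "pos"]).index
        for vid in order:
            v = variants.loc[vid]
            dose = dosages.loc[vid]
            if ploidy == "inbred":
                calls = ["." if pd.isna(d) else str(int(d)) for d in dose]
            else:
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}
                calls = ["./." if pd.isna(d) else gt[int(d)] for d in dose]
            fh.write(f"{v.chrom}\t{int(v.pos)}\t{vid}\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path):
    """Parse a VCF into (variants DataFrame, dosages DataFrame).

    Haploid GT calls yield 0/1 dosages, diploid ones 0/1/2; missing calls
    become NaN.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    individuals = list(vf.header.samples)
    records, rows = [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            log.warning("skipping non-biallelic record at %s:%d", rec.chrom, rec.pos)
            continue
        dose = []
        for ind in individuals:
            alleles = rec.samples[ind].get("GT")
            if alleles is None or any(a is None for a in alleles):
                dose.append(np.nan)
            else:
                dose.append(float(sum(alleles)))
        vid = rec.id or f"{rec.chrom}:{rec.pos}"
        records.append({"variant_id": vid, "chrom": rec.chrom, "pos": rec.pos,
                        "ref": rec.ref, "alt": rec.alts[0]})
        rows.append(dose)
    variants = pd.DataFrame.from_records(records).set_index("variant_id")
    dosages = pd.DataFrame(rows, index=variants.index, columns=individuals)
    if dosages.notna().all().all() and (dosages.to_numpy() == dosages.to_numpy().astype(int)).all():
        dosages = dosages.astype(np.int8)
    return variants, dosages


# ---------------------------------------------------------------- junction BED

def write_junction_bed(junctions: pd.DataFrame, path) -> None:
    """6-column BED of introns: start/end are 0-based half-open intron bounds,
    score is the junction read count."""
    cols = ["chrom", "start", "end", "name", "count", "strand"]
    junctions[cols].to_csv(path, sep="\t", header=False, index=False)


def read_junction_bed(path, strict: bool = False) -> pd.DataFrame:
    """Parse junction records (regtools-style 6+ column BED).

    Plain 6-column records are taken as the intron interval directly; BED12
    dialects whose blocks encode anchors have the block sizes trimmed off.
    Malformed lines are reported with their line number (raised in strict
    mode, skipped with a warning otherwise).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if len(parts) < 6:
                    raise ValueError("fewer than 6 columns")
                chrom, start, end, name, count, strand = parts[:6]
                start, end, count = int(start), int(end), int(count)
                if len(parts) >= 12:  # regtools dialect: anchors in blocks
                    sizes = [int(s) for s in parts[10].rstrip(",").split(",")]
                    if len(sizes) != 2:
                        raise ValueError("junction BED12 needs two blocks")
                    start += sizes[0]
                    end -= sizes[1]
                if start >= end:
                    raise ValueError("start >= end")
                if strand not in "+-":
                    raise ValueError(f"bad strand {strand!r}")
            except ValueError as exc:
                msg = f"{path}:{ln}: {exc}"
                if strict:
                    raise ValueError(msg) from None
                log.warning("skipping malformed junction line %s", msg)
                continue
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "name": name, "count": count, "strand": strand})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "count", "strand"])


def junction_site_positions(row) -> dict[str, int]:
    """Donor/acceptor 1-based positions of a junction BED record."""
    if row["strand"] == "+":
        return {DONOR: row["start"] + 1, ACCEPTOR: row["end"]}
    return {DONOR: row["end"], ACCEPTOR: row["start"] + 1}


# ---------------------------------------------------------------- tables

def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """TSV with header, UTF-8, '.' decimal, stable column order."""
    df.to_csv(path, sep="\t", index=index)


def read_table(path, required: list[str] | None = None,
               index_col: int | str | None = 0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}")
        extra = [c for c in df.columns if c not in required]
        if extra:
            log.warning("%s: unknown column(s) %s preserved", path, extra)
    return df


# ---------------------------------------------------------------- bundles

def write_cohort(outdir, genome, sites, variants, dosages, matrix,
                 ploidy: str = "inbred") -> dict[str, str]:
    """Write a simulated cohort as FASTA/VCF/BED/TSV files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": str(outdir / "genome.fa"),
             "annotation": str(outdir / "sites.tsv"),
             "vcf": str(outdir / "variants.vcf"),
             "junction_dir": str(outdir / "junctions"),
             "crossing": str(outdir / "crossing_counts.tsv")}
    write_fasta(genome, paths["genome"])
    write_table(sites, paths["annotation"])
    write_vcf(variants, dosages, paths["vcf"], ploidy=ploidy)
    jdir = Path(paths["junction_dir"])
    jdir.mkdir(exist_ok=True)
    # intron interval per site: pair each donor with its intron's acceptor
    intervals = {}
    for d_id, d in sites[sites["site_type"] == DONOR].iterrows():
        a_id = d_id[:-2] + ".a"
        if a_id not in sites.index:
            continue
        a = sites.loc[a_id]
        lo, hi = sorted([int(d.position), int(a.position)])
        intervals[d_id] = intervals[a_id] = (d.chrom, lo - 1, hi, d.strand)
    for col, sample_id in enumerate(matrix.samples.index):
        rows = []
        for i, site_id in enumerate(matrix.sites.index):
            if site_id not in intervals:
                continue
            chrom, start, end, strand = intervals[site_id]
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "name": site_id, "count": int(matrix.alpha[i, col]),
                         "strand": strand})
        write_junction_bed(pd.DataFrame(rows), jdir / f"{sample_id}.bed")
    totals = pd.DataFrame(matrix.total, index=matrix.sites.index,
                          columns=matrix.samples.index)
    write_table(totals, paths["crossing"])
    return paths


def load_cohort(paths) -> dict:
    """Load a cohort bundle written by :func:`write_cohort`.

    Junction counts keyed by site id give alpha; beta is the crossing total
    minus alpha.  Sample metadata (genotype/replicate) is recovered from the
    ``<genotype>_r<replicate>`` file naming.
    """
    from . import sse as sse_mod

    genome = read_fasta(paths["genome"])
    sites = read_table(paths["annotation"])
    variants, dosages = read_vcf(paths["vcf"])
    totals = read_table(paths["crossing"])
    sample_ids = list(totals.columns)
    alpha = np.zeros((len(sites), len(sample_ids)), dtype=np.int64)
    site_pos = {site_id: i for i, site_id in enumerate(sites.index)}
    for col, sample_id in enumerate(sample_ids):
        bed = read_junction_bed(Path(paths["junction_dir"]) / f"{sample_id}.bed")
        for _, row in bed.iterrows():
            i = site_pos.get(row["name"])
            if i is not None:
                alpha[i, col] += int(row["count"])
    total = totals.loc[sites.index, sample_ids].to_numpy()
    beta = np.maximum(total - alpha, 0)
    genos = [s.rsplit("_r", 1)[0] for s in sample_ids]
    reps = [int(s.rsplit("_r", 1)[1]) if "_r" in s else 0 for s in sample_ids]
    samples = pd.DataFrame({"genotype": genos, "replicate": reps, "stratum": "all"},
                           index=pd.Index(sample_ids, name="sample_id"))
    matrix = sse_mod.SSEMatrix(sites=sites, samples=samples, alpha=alpha, beta=beta)
    return {"genome": genome, "sites": sites, "variants": variants,
            "dosages": dosages, "matrix": matrix}
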