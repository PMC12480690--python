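"""Synthetic genomes, cohorts and minigene libraries with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: splice-site usage is determined by the intron-terminal hexamer
(GT[N]4 for donors, [N]4AG for acceptors) through a strength map, genotypes
carry biallelic variants a configured fraction of which fall inside those
hexamers and switch the site's hexamer (hence its true strength), and
replicated junction counts add genotype-level and replicate-level noise on
the usage scale so that broad-sense heritability is well defined.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import sse as sse_mod
from .genome import ACCEPTOR, DONOR, complement, revcomp, rel_to_genomic, site_hexamer

log = logging.getLogger(__name__)

BASES = "ACGT"
HEXAMER_SPAN = 6

DONOR_HEXAMERS = tuple("GT" + "".join(p) for p in itertools.product(BASES, repeat=4))
ACCEPTOR_HEXAMERS = tuple("".join(p) + "AG" for p in itertools.product(BASES, repeat=4))

DONOR_CONSENSUS = "GTAAGT"  # complementary to the U1 snRNA binding site
ACCEPTOR_CONSENSUS = "TTGCAG"


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for the synthetic cohort."""

    n_genes: int = 100
    introns_per_gene: int = 2
    intron_length_range: tuple[int, int] = (150, 300)
    n_genotypes: int = 200
    replicates_per_genotype: int = 3
    read_depth_mean: float = 50.0
    depth_dispersion: float = 10.0
    genotype_sd: float = 0.05
    residual_sd: float = 0.05
    causal_fraction: float = 0.0
    causal_maf_range: tuple[float, float] = (0.2, 0.3)
    seed: int = 0
    # layout knobs
    exon_length_range: tuple[int, int] = (120, 180)
    intergenic_length: int = 300
    n_chromosomes: int = 2
    minus_strand_fraction: float = 0.5
    ploidy: str = "inbred"  # "inbred" (0/1 calls) or "diploid" (0/1/2 dosage)
    hexamer_weighting: str = "strength"  # or "uniform"
    donor_hexamers: tuple[str, ...] | None = None
    acceptor_hexamers: tuple[str, ...] | None = None

    def __post_init__(self):
        for name in ("n_genes", "introns_per_gene", "n_genotypes",
                     "replicates_per_genotype", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.genotype_sd < 0 or self.residual_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.causal_fraction <= 1:
            raise ValueError("causal_fraction must lie in [0, 1]")
        lo, hi = self.causal_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("causal_maf_range must lie in (0, 0.5]")
        if self.intron_length_range[0] > self.intron_length_range[1]:
            raise ValueError("intron_length_range must be (low, high)")
        if self.hexamer_weighting not in ("strength", "uniform"):
            raise ValueError("hexamer_weighting must be 'strength' or 'uniform'")
        if self.ploidy not in ("inbred", "diploid"):
            raise ValueError("ploidy must be 'inbred' or 'diploid'")


@dataclass
class TrueStrengthModel:
    """Ground-truth usage of every intron-terminal hexamer.

    ``trans_effects`` optionally lists (variant_id, multiplicative effect,
    affected site ids) triples modelling a trans-acting factor allele.
    """

    donor_map: dict[str, float]
    acceptor_map: dict[str, float]
    trans_effects: list[tuple[str, float, frozenset]] = field(default_factory=list)

    def __post_init__(self):
        for name, table, keys in (("donor_map", self.donor_map, DONOR_HEXAMERS),
                                  ("acceptor_map", self.acceptor_map, ACCEPTOR_HEXAMERS)):
            if set(table) != set(keys):
                raise ValueError(f"{name} must have exactly the 256 canonical keys")
            vals = np.fromiter(table.values(), float)
            if vals.min() < 0 or vals.max() > 1:
                raise ValueError(f"{name} strengths must lie in [0, 1]")

    def strength(self, site_type: str, hexamer: str) -> float:
        table = self.donor_map if site_type == DONOR else self.acceptor_map
        return table[hexamer]

    @classmethod
    def distance_decay(cls, seed: int = 0, decay: float = 0.45,
                       jitter: float = 0.08) -> "TrueStrengthModel":
        """Strengths decaying with p-distance from the consensus hexamer
        (GTAAGT for donors, TTGCAG for acceptors) plus seeded jitter."""
        rng = np.random.default_rng([int(seed), 0x5_7e11])

        def build(keys, consensus):
            out = {}
            for key in keys:
                d = sum(a != b for a, b in zip(key, consensus))
                s = decay ** d + jitter * rng.standard_normal()
                out[key] = float(np.clip(s, 0.01, 0.99))
            return out

        return cls(build(DONOR_HEXAMERS, DONOR_CONSENSUS),
                   build(ACCEPTOR_HEXAMERS, ACCEPTOR_CONSENSUS))


def _pick_hexamers(rng, keys, strengths, size, weighting):
    if weighting == "strength":
        w = np.asarray(strengths, float)
        w = w / w.sum()
        return rng.choice(keys, size=size, p=w)
    return rng.choice(keys, size=size)


def generate_genome(config: SynthConfig, model: TrueStrengthModel):
    """Build chromosome sequences and the splice-site annotation table.

    Returns (genome dict, sites DataFrame indexed by site_id).  Every donor
    begins GT and every acceptor ends AG on its transcribed strand; each
    site's hexamer is drawn from the strength model, weighted by strength by
    default so common hexamers are also strong ones.
    """
    min_intron = 2 * HEXAMER_SPAN + 1
    if config.intron_length_range[0] < min_intron:
        raise ValueError(
            f"introns shorter than {min_intron} bp cannot hold two hexamers")
    rng = np.random.default_rng([config.seed, 0xA1])

    donor_keys = list(config.donor_hexamers or DONOR_HEXAMERS)
    acceptor_keys = list(config.acceptor_hexamers or ACCEPTOR_HEXAMERS)
    for key in donor_keys:
        if not key.startswith("GT"):
            raise ValueError(f"donor hexamer {key!r} must start with GT")
    for key in acceptor_keys:
        if not key.endswith("AG"):
            raise ValueError(f"acceptor hexamer {key!r} must end with AG")
    d_strengths = [model.donor_map[k] for k in donor_keys]
    a_strengths = [model.acceptor_map[k] for k in acceptor_keys]

    n_introns = config.n_genes * config.introns_per_gene
    donor_hexes = _pick_hexamers(rng, donor_keys, d_strengths, n_introns,
                                 config.hexamer_weighting)
    acceptor_hexes = _pick_hexamers(rng, acceptor_keys, a_strengths, n_introns,
                                    config.hexamer_weighting)

    chrom_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)}
    chrom_len = {c: 0 for c in chrom_parts}
    records = []
    intron_i = 0
    for gi in range(config.n_genes):
        gene_id = f"gene{gi:04d}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        parts = [_random_seq(rng, rng.integers(*_hilo(config.exon_length_range)))]
        site_offsets = []  # (offset-in-transcript, site_type, hexamer, intron idx)
        for ii in range(config.introns_per_gene):
            d_hex, a_hex = donor_hexes[intron_i], acceptor_hexes[intron_i]
            length = int(rng.integers(*_hilo(config.intron_length_range)))
            interior = list(_random_seq(rng, length - 2 * HEXAMER_SPAN))
            if len(interior) >= 30:
                interior[-25] = "A"  # branch-point adenosine
            intron = d_hex + "".join(interior) + a_hex
            offset = sum(len(p) for p in parts)
            site_offsets.append((offset, DONOR, d_hex, ii))
            site_offsets.append((offset + length - 1, ACCEPTOR, a_hex, ii))
            parts.append(intron)
            parts.append(_random_seq(rng, rng.integers(*_hilo(config.exon_length_range))))
            intron_i += 1
        transcript = "".join(parts)
        chrom = f"chr{gi % config.n_chromosomes + 1}"
        start0 = chrom_len[chrom] + config.intergenic_length  # 0-based gene start
        chrom_parts[chrom].append(_random_seq(rng, config.intergenic_length))
        chrom_parts[chrom].append(transcript if strand == "+" else revcomp(transcript))
        chrom_len[chrom] = start0 + len(transcript)
        for offset, stype, hexamer, ii in site_offsets:
            if strand == "+":
                pos = start0 + offset + 1
            else:
                pos = start0 + len(transcript) - offset
            records.append({
                "site_id": f"{gene_id}.i{ii}.{stype[0]}",
                "chrom": chrom, "position": pos, "strand": strand,
                "site_type": stype, "gene_id": gene_id, "hexamer": hexamer,
                "true_strength": model.strength(stype, hexamer),
                "gene_start": start0 + 1, "gene_end": start0 + len(transcript),
            })
    for chrom in chrom_parts:
        chrom_parts[chrom].append(_random_seq(rng, config.intergenic_length))
    genome = {c: "".join(p) for c, p in chrom_parts.items()}
    sites = pd.DataFrame.from_records(records).set_index("site_id")
    for _, row in sites.iterrows():  # annotation/sequence consistency check
        assert site_hexamer(genome, row.chrom, row.position, row.strand,
                            row.site_type) == row.hexamer
    return genome, sites


def _hilo(pair):
    return pair[0], pair[1] + 1


def _random_seq(rng, length) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, int(length))])


def _hexamer_rel_offsets(site_type: str) -> np.ndarray:
    """Relative positions inside the hexamer that are free to vary."""
    return np.arange(2, 6) if site_type == DONOR else np.arange(-5, -1)


def simulate_genotypes(config: SynthConfig, sites: pd.DataFrame,
                       genome: dict[str, str], n_background: int | None = None):
    """Biallelic variants and a dosage matrix for the cohort.

    A ``causal_fraction`` of sites receives one variant inside its hexamer
    whose alternate allele switches the hexamer; the remaining variants are
    neutral background placed outside hexamers.  Returns
    (variants DataFrame indexed by variant_id, dosages DataFrame
    variants x individuals).
    """
    rng = np.random.default_rng([config.seed, 0xB2])
    individuals = [f"g{i:04d}" for i in range(config.n_genotypes)]
    max_dose = 1 if config.ploidy == "inbred" else 2

    hexamer_footprint: dict[str, set[int]] = {c: set() for c in genome}
    for _, row in sites.iterrows():
        offs = np.arange(0, 6) if row.site_type == DONOR else np.arange(-5, 1)
        for rel in offs:
            hexamer_footprint[row.chrom].add(rel_to_genomic(row.position, row.strand, int(rel)))

    records, dosage_rows = [], []
    n_causal = int(round(config.causal_fraction * len(sites)))
    causal_sites = rng.choice(sites.index.to_numpy(), size=n_causal, replace=False)
    vid = 0
    for site_id in causal_sites:
        row = sites.loc[site_id]
        rel = int(rng.choice(_hexamer_rel_offsets(row.site_type)))
        pos = rel_to_genomic(int(row.position), row.strand, rel)
        ref_fwd = genome[row.chrom][pos - 1]
        if pos not in hexamer_footprint[row.chrom]:
            raise RuntimeError("causal variant landed outside a hexamer")
        base_t = ref_fwd if row.strand == "+" else complement(ref_fwd)
        alt_t = rng.choice([b for b in BASES if b != base_t])
        alt_fwd = alt_t if row.strand == "+" else complement(alt_t)
        maf = float(rng.uniform(*config.causal_maf_range))
        dosage = _draw_dosage(rng, maf, config.n_genotypes, max_dose)
        records.append({"variant_id": f"v{vid:05d}", "chrom": row.chrom,
                        "pos": pos, "ref": ref_fwd, "alt": alt_fwd, "maf": maf,
                        "causal_site": site_id, "rel_offset": rel})
        dosage_rows.append(dosage)
        vid += 1

    if n_background is None:
        n_background = 10 * config.n_genes
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], float)
    probs = lengths / lengths.sum()
    placed = 0
    while placed < n_background:
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        pos = int(rng.integers(1, len(genome[chrom]) + 1))
        if pos in hexamer_footprint[chrom]:
            continue
        ref = genome[chrom][pos - 1]
        alt = rng.choice([b for b in BASES if b != ref])
        maf = float(rng.uniform(0.05, 0.5))
        dosage = _draw_dosage(rng, maf, config.n_genotypes, max_dose)
        records.append({"variant_id": f"v{vid:05d}", "chrom": chrom, "pos": pos,
                        "ref": ref, "alt": str(alt), "maf": maf,
                        "causal_site": None, "rel_offset": np.nan})
        dosage_rows.append(dosage)
        vid += 1
        placed += 1

    variants = pd.DataFrame.from_records(records).set_index("variant_id")
    dosages = pd.DataFrame(np.array(dosage_rows, dtype=np.int8),
                           index=variants.index, columns=individuals)
    return variants, dosages


def _draw_dosage(rng, maf, n, max_dose):
    for _ in range(100):
        if max_dose == 1:
            d = (rng.random(n) < maf).astype(np.int8)
        else:
            d = (rng.random((n, 2)) < maf).sum(axis=1).astype(np.int8)
        if 0 < d.sum() < max_dose * n:
            return d
    raise RuntimeError("could not draw a polymorphic variant")


def true_sse(sites: pd.DataFrame, model: TrueStrengthModel, genome: dict[str, str],
             variants: pd.DataFrame | None = None,
             dosages: pd.DataFrame | None = None,
             individuals: list[str] | None = None) -> pd.DataFrame:
    """Per-individual true usage: each site's strength is the model value of
    the hexamer its genotype carries (heterozygotes average both alleles)."""
    if individuals is None:
        individuals = list(dosages.columns) if dosages is not None else ["g0000"]
    base = sites.apply(
        lambda r: model.strength(r.site_type,
                                 site_hexamer(genome, r.chrom, r.position,
                                              r.strand, r.site_type)), axis=1)
    table = pd.DataFrame(np.tile(base.to_numpy()[:, None], (1, len(individuals))),
                         index=sites.index, columns=individuals)
    if variants is None or dosages is None:
        return table
    max_dose = 1 if dosages.to_numpy().max() <= 1 else 2
    causal = variants.dropna(subset=["causal_site"])
    for vid, v in causal.iterrows():
        site = sites.loc[v.causal_site]
        ref_hex = site_hexamer(genome, site.chrom, site.position, site.strand,
                               site.site_type)
        rel = int(v.rel_offset)
        idx = rel if site.site_type == DONOR else rel + 5
        alt_t = v.alt if site.strand == "+" else complement(v.alt)
        alt_hex = ref_hex[:idx] + alt_t + ref_hex[idx + 1:]
        s_ref = model.strength(site.site_type, ref_hex)
        s_alt = model.strength(site.site_type, alt_hex)
        dose = dosages.loc[vid].to_numpy(float) / max_dose
        table.loc[v.causal_site] = s_ref * (1 - dose) + s_alt * dose
    for vid, effect, affected in model.trans_effects:
        carriers = dosages.loc[vid] > 0
        for site_id in affected:
            row = table.loc[site_id].to_numpy()
            row[carriers.to_numpy()] = np.clip(row[carriers.to_numpy()] * effect, 0, 1)
            table.loc[site_id] = row
    return table


def simulate_junction_counts(truth: pd.DataFrame, config: SynthConfig,
                             sites: pd.DataFrame | None = None) -> sse_mod.SSEMatrix:
    """Replicated junction/crossing counts around the given true usage table.

    Per site, genotype and replicate the crossing total n is negative
    binomial with mean ``read_depth_mean``; supporting reads are
    Binomial(n, clamp(truth + genotype effect + replicate noise, 0, 1)) with
    the genotype effect shared across that genotype's replicates.
    """
    if ((truth.to_numpy() < 0) | (truth.to_numpy() > 1)).any():
        raise ValueError("true usage values must lie in [0, 1]")
    rng = np.random.default_rng([config.seed, 0xC3])
    n_sites, n_geno = truth.shape
    reps = config.replicates_per_genotype
    g_eff = rng.normal(0, config.genotype_sd, size=(n_sites, n_geno))
    theta = config.depth_dispersion
    p_nb = theta / (theta + config.read_depth_mean)
    alpha = np.empty((n_sites, n_geno * reps), dtype=np.int64)
    beta = np.empty_like(alpha)
    sample_ids, genos, rep_ids = [], [], []
    for r in range(reps):
        e = rng.normal(0, config.residual_sd, size=(n_sites, n_geno))
        p = np.clip(truth.to_numpy() + g_eff + e, 0.0, 1.0)
        n = rng.negative_binomial(theta, p_nb, size=(n_sites, n_geno))
        a = rng.binomial(n, p)
        for gi, g in enumerate(truth.columns):
            col = gi * reps + r
            alpha[:, col] = a[:, gi]
            beta[:, col] = n[:, gi] - a[:, gi]
    for g in truth.columns:
        for r in range(reps):
            sample_ids.append(f"{g}_r{r}")
            genos.append(g)
            rep_ids.append(r)
    samples = pd.DataFrame({"genotype": genos, "replicate": rep_ids,
                            "stratum": "all"}, index=pd.Index(sample_ids, name="sample_id"))
    site_table = sites if sites is not None else pd.DataFrame(index=truth.index)
    return sse_mod.SSEMatrix(sites=site_table.loc[truth.index] if sites is not None else site_table,
                             samples=samples, alpha=alpha, beta=beta)


def simulate_minigene_library(model: TrueStrengthModel, n_constructs: int = 500,
                              hexamers: list[str] | None = None,
                              donor_spacing: int = 40, depth: float = 200.0,
                              temperature: float = 0.2, noise_sd: float = 0.3,
                              seed: int = 0) -> pd.DataFrame:
    """Reporter constructs with two competing donors in one intron.

    Reads split between the two junctions with probability
    sigmoid((sA - sB) / temperature + noise); ``temperature=0`` is the hard
    deterministic limit, ``temperature=inf`` a fair coin.
    """
    if donor_spacing < HEXAMER_SPAN:
        raise ValueError("competing donors closer than the hexamer span")
    rng = np.random.default_rng([seed, 0xD4])
    keys = list(hexamers or DONOR_HEXAMERS)
    records = []
    for ci in range(n_constructs):
        hex_a, hex_b = rng.choice(keys, size=2, replace=True)
        s_a = model.donor_map[hex_a]
        s_b = model.donor_map[hex_b]
        exon = _random_seq(rng, 50)
        spacer = _random_seq(rng, donor_spacing - HEXAMER_SPAN)
        tail = _random_seq(rng, 60)
        acc = rng.choice(ACCEPTOR_HEXAMERS)
        seq = exon + hex_a + spacer + hex_b + tail + acc + _random_seq(rng, 30)
        pos_a = len(exon) + 1  # 1-based G of GT
        pos_b = len(exon) + donor_spacing + 1
        diff = s_a - s_b
        if temperature == 0:
            p_a = 0.5 if diff == 0 else float(diff > 0)
        else:
            z = diff / temperature + (noise_sd * rng.standard_normal() if noise_sd else 0.0)
            p_a = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        n = int(rng.poisson(depth))
        count_a = int(rng.binomial(n, p_a)) if n else 0
        count_b = n - count_a
        records.append({"construct_id": f"mg{ci:05d}", "sequence": seq,
                        "pos_a": pos_a, "pos_b": pos_b,
                        "hexamer_a": hex_a, "hexamer_b": hex_b,
                        "true_strength_a": s_a, "true_strength_b": s_b,
                        "count_a": count_a, "count_b": count_b,
                        "sse_a": count_a / n if n else np.nan,
                        "sse_b": count_b / n if n else np.nan})
    return pd.DataFrame.from_records(records).set_index("construct_id")
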