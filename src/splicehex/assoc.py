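"""Per-site genome-wide association on splice-site usage phenotypes.

Each mappable splice-site is a phenotype: its per-genotype mean SSE is
regressed on every variant's dosage (one simple linear model per variant,
optionally pre-whitened against the leading kinship components).  Peaks are
called from the per-site Manhattan profile with a minimum member count and a
noise gate: the top SNP's -log10(p) must exceed ``noise_factor`` times the
mean -log10(p) of the five best mutually spread-out SNPs in the plot.  The
winning SNP is classified cis when it lies within 1 Mb of the site.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

P_FLOOR = 1e-300
CIS_WINDOW = 1_000_000


@dataclass
class GenotypeMatrix:
    """Variant metadata plus a variants x individuals dosage frame.

    Dosages are 0/1 for inbred panels or 0/1/2 for diploids; missing calls
    may be NaN (use a float frame in that case).
    """

    variants: pd.DataFrame  # index variant_id; columns chrom, pos, ref, alt
    dosages: pd.DataFrame

    def __post_init__(self):
        if not self.variants.index.equals(self.dosages.index):
            raise ValueError("variants and dosages must share an index")

    @property
    def max_dosage(self) -> int:
        return int(np.nanmax(self.dosages.to_numpy(float)))


def associate_site(phenotype: pd.Series, genotypes: GenotypeMatrix,
                   maf_min: float = 0.05, min_n: int = 20,
                   kinship: pd.DataFrame | None = None,
                   n_kinship_components: int = 5) -> pd.DataFrame:
    """Single-variant linear associations of SSE on dosage.

    Variants with minor allele frequency below ``maf_min`` (computed on the
    analyzed individuals) are excluded; p-values are two-sided t-tests on the
    slope.  With a kinship matrix, phenotype and dosages are residualized
    against its leading eigenvectors before the per-variant fits.
    """
    y = phenotype.dropna()
    ids = y.index.intersection(genotypes.dosages.columns)
    if len(ids) < min_n:
        return _empty_records()
    y = y.loc[ids].to_numpy(float)
    X = genotypes.dosages[ids].to_numpy(float)
    if np.nanvar(y) == 0:
        warnings.warn("phenotype has zero variance; no associations computed")
        return _empty_records()

    if kinship is not None:
        K = kinship.loc[ids, ids].to_numpy(float)
        _, vecs = np.linalg.eigh(K)
        pcs = vecs[:, -n_kinship_components:]
        basis = np.column_stack([np.ones(len(ids)), pcs])
        proj = basis @ np.linalg.pinv(basis)
        y = y - proj @ y
        X = X - (proj @ np.where(np.isnan(X), 0.0, X).T).T

    max_dose = max(genotypes.max_dosage, 1)
    raw = genotypes.dosages[ids].to_numpy(float)
    mask = ~np.isnan(raw)
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        f_alt = np.nansum(raw, axis=1) / (max_dose * np.maximum(n, 1))
    maf = np.minimum(f_alt, 1 - f_alt)
    usable = (maf >= maf_min) & (n >= min_n)

    Xm = np.where(mask, X, np.nan)
    ym = np.broadcast_to(y, Xm.shape)
    n_v = mask.sum(axis=1).astype(float)
    sx = np.nansum(Xm, axis=1)
    sy = np.where(mask, ym, 0.0).sum(axis=1)
    sxx = np.nansum(Xm * Xm, axis=1)
    sxy = np.nansum(Xm * ym, axis=1)
    syy = np.where(mask, ym * ym, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Sxx = sxx - sx * sx / n_v
        Sxy = sxy - sx * sy / n_v
        Syy = syy - sy * sy / n_v
        beta = Sxy / Sxx
        df = n_v - 2
        resid = np.maximum(Syy - beta * Sxy, 0.0)
        s2 = resid / df
        se = np.sqrt(s2 / Sxx)
        t = beta / se
    usable &= (Sxx > 0) & (df > 0)
    with np.errstate(invalid="ignore"):
        p = 2 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.clip(p, P_FLOOR, 1.0)

    out = genotypes.variants.loc[usable, ["chrom", "pos"]].copy()
    out["maf"] = maf[usable]
    out["beta"] = beta[usable]
    out["se"] = se[usable]
    out["p"] = p[usable]
    out["n"] = n_v[usable].astype(int)
    return out.sort_values(["chrom", "pos"])


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "pos", "maf", "beta", "se", "p", "n"])


@dataclass
class Peak:
    """A called association peak with its representative SNPs."""

    members: pd.DataFrame
    top_snp: str
    closest_snp: str | None
    passes_noise_gate: bool

    @property
    def top(self) -> pd.Series:
        return self.members.loc[self.top_snp]


def noise_reference(records: pd.DataFrame, spread_window: int = 750_000,
                    n_ref: int = 5) -> pd.DataFrame:
    """The n_ref lowest-p SNPs with no two within spread_window of each other
    (different chromosomes never conflict)."""
    picked = []
    for vid, row in records.sort_values("p").iterrows():
        if all(row.chrom != records.loc[q, "chrom"]
               or abs(row.pos - records.loc[q, "pos"]) > spread_window
               for q in picked):
            picked.append(vid)
        if len(picked) == n_ref:
            break
    if len(picked) < n_ref:
        log.info("only %d spread-eligible SNPs for the noise reference", len(picked))
    return records.loc[picked]


def call_peaks(records: pd.DataFrame, site: pd.Series,
               sig_threshold: float, min_peak_snps: int = 50,
               merge_window: int = 100_000, noise_factor: float = 1.33,
               spread_window: int = 750_000) -> list[Peak]:
    """Group significant SNPs into peaks and gate them against plot noise.

    Neighbouring significant SNPs within ``merge_window`` bp merge into one
    peak; peaks with fewer than ``min_peak_snps`` members are dropped; a peak
    passes the noise gate iff -log10(p) of its top SNP is at least
    ``noise_factor`` times the mean -log10(p) of the genome-wide noise
    reference set.  Top-SNP ties resolve to the member nearest the site.
    """
    if records.empty:
        return []
    sig = records[records["p"] <= sig_threshold]
    if sig.empty:
        return []
    ref = noise_reference(records, spread_window=spread_window)
    noise_level = float(np.mean(-np.log10(ref["p"])))

    peaks = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        gaps = grp["pos"].diff().fillna(0)
        cluster = (gaps > merge_window).cumsum()
        for _, members in grp.groupby(cluster):
            if len(members) < min_peak_snps:
                continue
            best_p = members["p"].min()
            tied = members[members["p"] == best_p]
            top = _nearest(tied, site) if len(tied) > 1 else tied.index[0]
            closest = _nearest(members, site) if chrom == site["chrom"] else None
            gate = -np.log10(best_p) >= noise_factor * noise_level
            peaks.append(Peak(members=members, top_snp=top,
                              closest_snp=closest, passes_noise_gate=bool(gate)))
    return peaks


def _nearest(members: pd.DataFrame, site: pd.Series) -> str:
    same = members[members["chrom"] == site["chrom"]]
    pool = same if len(same) else members
    return (pool["pos"] - site["position"]).abs().idxmin()


def relative_position(variant_chrom: str, variant_pos: int, site) -> int:
    """Signed distance on the site-normalized, strand-aware axis.

    Position 0 is the intron-terminal base; for donors the intron extends to
    positive values, for acceptors to negative ones.
    """
    if variant_chrom != site["chrom"]:
        raise ValueError("relative position is undefined across chromosomes")
    d = variant_pos - int(site["position"])
    return d if site["strand"] == "+" else -d


def classify_cis_trans(variant_chrom: str, variant_pos: int, site,
                       cis_window: int = CIS_WINDOW) -> str:
    """cis iff same chromosome and within ``cis_window`` bp of the site."""
    if variant_chrom != site["chrom"]:
        return "trans"
    return "cis" if abs(variant_pos - int(site["position"])) <= cis_window else "trans"


def delta_sse(dosage: pd.Series, phenotype: pd.Series) -> float:
    """Mean SSE of minor-allele carriers minus the major-allele mean,
    weighting each individual by its minor/major allele count."""
    ids = dosage.dropna().index.intersection(phenotype.dropna().index)
    d = dosage.loc[ids].to_numpy(float)
    y = phenotype.loc[ids].to_numpy(float)
    max_dose = max(int(d.max()), 1)
    alt_count = d
    ref_count = max_dose - d
    if alt_count.sum() == 0 or ref_count.sum() == 0:
        return np.nan
    minor_is_alt = alt_count.sum() <= ref_count.sum()
    minor = alt_count if minor_is_alt else ref_count
    major = ref_count if minor_is_alt else alt_count
    return float(np.average(y, weights=minor) - np.average(y, weights=major))


def pve(beta: float, se: float, maf: float, n: int) -> float:
    """Proportion of phenotypic variance explained by one variant:
    2*b^2*f(1-f) / (2*b^2*f(1-f) + se^2 * 2N * f(1-f))."""
    num = 2 * beta**2 * maf * (1 - maf)
    den = num + se**2 * 2 * n * maf * (1 - maf)
    return float(num / den) if den > 0 else np.nan


def map_site(phenotype: pd.Series, genotypes: GenotypeMatrix, site: pd.Series,
             site_id: str | None = None, sig_threshold: float | None = None,
             maf_min: float = 0.05, min_n: int = 20,
             kinship: pd.DataFrame | None = None, **peak_kwargs) -> dict | None:
    """Run one site's GWAS end to end and summarise its best passing peak.

    ``sig_threshold`` defaults to Bonferroni 0.05 over the tested variants.
    Returns None when no peak passes; otherwise a record with the top SNP,
    its normalized distance, cis/trans label, delta-SSE and PVE.
    """
    records = associate_site(phenotype, genotypes, maf_min=maf_min,
                             min_n=min_n, kinship=kinship)
    if records.empty:
        return None
    if sig_threshold is None:
        sig_threshold = 0.05 / len(records)
        log.info("using Bonferroni significance threshold %.3g", sig_threshold)
    peaks = [p for p in call_peaks(records, site, sig_threshold, **peak_kwargs)
             if p.passes_noise_gate]
    if not peaks:
        return None
    best = min(peaks, key=lambda p: p.top["p"])
    top = best.top
    cis_trans = classify_cis_trans(top["chrom"], int(top["pos"]), site)
    distance = (relative_position(top["chrom"], int(top["pos"]), site)
                if top["chrom"] == site["chrom"] else None)
    d = delta_sse(genotypes.dosages.loc[best.top_snp], phenotype)
    return {
        "site_id": site_id, "chrom": site["chrom"], "site_pos": int(site["position"]),
        "strand": site["strand"], "site_type": site["site_type"],
        "top_snp": best.top_snp, "snp_chrom": top["chrom"], "snp_pos": int(top["pos"]),
        "p": float(top["p"]), "beta": float(top["beta"]),
        "distance": distance, "cis_trans": cis_trans, "delta_sse": d,
        "pve": pve(top["beta"], top["se"], top["maf"], int(top["n"])),
        "n_peaks": len(peaks),
    }
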