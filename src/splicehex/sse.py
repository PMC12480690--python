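"""Splice-site usage (SSE) quantification, filtering and heritability.

The splice-site strength estimate of a site in a sample is the fraction of
reads crossing the site position that actually splice at it::

    SSE = alpha / (alpha + beta)

where ``alpha`` counts junction reads using the site and ``beta`` all other
reads crossing it (continuous reads plus junctions splicing past it).  The
value is undefined (missing) when no read crosses the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "position", "strand", "site_type", "gene_id"]


def compute_sse(alpha, beta):
    """SSE = alpha / (alpha + beta); NaN where no read crosses the site."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(alpha < 0) or np.any(beta < 0):
        raise ValueError("read counts must be non-negative")
    total = alpha + beta
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, alpha / np.where(total > 0, total, 1), np.nan)
    return out if out.ndim else float(out)


@dataclass
class SSEMatrix:
    """Sites x samples usage estimates with their underlying count pairs.

    ``sites`` is indexed by site id; ``samples`` is indexed by sample id and
    carries ``genotype``, ``replicate`` and ``stratum`` columns (strata model
    the sex/tissue splits of replicated cohorts).  ``alpha``/``beta`` are
    integer arrays of shape (n_sites, n_samples).
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha)
        self.beta = np.asarray(self.beta)
        n_sites, n_samples = len(self.sites), len(self.samples)
        if self.alpha.shape != (n_sites, n_samples) or self.beta.shape != self.alpha.shape:
            raise ValueError("count matrices must be sites x samples")
        if (self.alpha < 0).any() or (self.beta < 0).any():
            raise ValueError("negative read counts")
        if "stratum" not in self.samples.columns:
            self.samples = self.samples.assign(stratum="all")

    @property
    def total(self) -> np.ndarray:
        return self.alpha + self.beta

    @property
    def values(self) -> np.ndarray:
        """SSE per site and sample, NaN where total coverage is zero."""
        return compute_sse(self.alpha, self.beta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites.index,
                            columns=self.samples.index)


def filter_sites(matrix: SSEMatrix, min_reads: int = 10, min_replicates: int = 3,
                 min_genotypes: int = 100) -> pd.Index:
    """Sites with >= min_reads coverage in >= min_replicates replicates of
    >= min_genotypes genotypes.

    Cohorts without replication should pass ``min_replicates=1``.
    """
    passing = pd.DataFrame(matrix.total >= min_reads,
                           index=matrix.sites.index, columns=matrix.samples.index)
    reps_per_geno = passing.T.groupby(matrix.samples["genotype"]).sum().T
    n_good_genotypes = (reps_per_geno >= min_replicates).sum(axis=1)
    return matrix.sites.index[n_good_genotypes >= min_genotypes]


def genotype_average(matrix: SSEMatrix, min_reads: int = 10,
                     min_passing: int = 2, stratum: str | None = None):
    """Mean SSE per genotype over replicates with >= min_reads coverage.

    A genotype is missing where fewer than ``min_passing`` replicates pass
    (use 1 for replicate-free cohorts).  Strata (e.g. sexes) are averaged
    separately: with a single stratum a sites x genotypes frame is returned,
    otherwise a dict of stratum -> frame (or one frame if ``stratum`` given).
    """
    sse = matrix.to_frame()
    passing = pd.DataFrame(matrix.total >= min_reads,
                           index=sse.index, columns=sse.columns)
    sse = sse.where(passing)

    def _one(cols: pd.Index) -> pd.DataFrame:
        sub = sse[cols]
        geno = matrix.samples.loc[cols, "genotype"]
        means = sub.T.groupby(geno).mean().T
        counts = sub.notna().T.groupby(geno).sum().T
        return means.where(counts >= min_passing)

    strata = matrix.samples["stratum"].unique()
    if stratum is not None:
        return _one(matrix.samples.index[matrix.samples["stratum"] == stratum])
    if len(strata) == 1:
        return _one(matrix.samples.index)
    return {s: _one(matrix.samples.index[matrix.samples["stratum"] == s])
            for s in strata}


def variability_metrics(genotype_table: pd.DataFrame) -> pd.DataFrame:
    """Per-site range (max - min), sample variance and genotype count."""
    n_obs = genotype_table.notna().sum(axis=1)
    rng = genotype_table.max(axis=1) - genotype_table.min(axis=1)
    var = genotype_table.var(axis=1, ddof=1)
    out = pd.DataFrame({"range": rng, "variance": var, "n_obs": n_obs})
    out.loc[n_obs < 2, ["range", "variance"]] = np.nan
    return out


def range_bins(metrics: pd.DataFrame, width: float = 0.1) -> pd.DataFrame:
    """Bin sites by usage range and report the mean variance per bin."""
    edges = np.arange(0, 1 + width, width)
    labels = pd.cut(metrics["range"], bins=edges, include_lowest=True)
    grp = metrics.groupby(labels, observed=False)
    return pd.DataFrame({"n_sites": grp.size(),
                         "mean_variance": grp["variance"].mean()})


def broad_sense_heritability(matrix: SSEMatrix, min_reads: int = 10,
                             stratum: str | None = None) -> pd.Series:
    """Broad-sense heritability per site from one-way ANOVA on genotype.

    With genotype mean squares MSB and residual MSW and harmonic-mean
    replicate count r, sigma_g^2 = (MSB - MSW) / r and
    H^2 = sigma_g^2 / (sigma_g^2 + MSW), clamped to [0, 1].  Sites without
    two genotypes having two passing replicates are NaN.
    """
    sse = matrix.to_frame()
    sse = sse.where(matrix.total >= min_reads)
    samples = matrix.samples
    if stratum is not None:
        cols = samples.index[samples["stratum"] == stratum]
        sse, samples = sse[cols], samples.loc[cols]
    geno = samples["genotype"].to_numpy()
    values = sse.to_numpy()
    h2 = np.full(len(sse), np.nan)
    geno_codes, geno_idx = np.unique(geno, return_inverse=True)
    n_geno = len(geno_codes)
    for i in range(len(sse)):
        row = values[i]
        ok = ~np.isnan(row)
        if ok.sum() < 4:
            continue
        g = geno_idx[ok]
        x = row[ok]
        counts = np.bincount(g, minlength=n_geno)
        keep = counts[g] >= 2  # groups need replication for MSW
        g, x = g[keep], x[keep]
        groups, g = np.unique(g, return_inverse=True)
        k = len(groups)
        if k < 2:
            continue
        n_i = np.bincount(g)
        sums = np.bincount(g, weights=x)
        means = sums / n_i
        grand = x.mean()
        ssb = float(np.sum(n_i * (means - grand) ** 2))
        ssw = float(np.sum((x - means[g]) ** 2))
        msb = ssb / (k - 1)
        msw = ssw / (len(x) - k)
        r_bar = len(n_i) / np.sum(1.0 / n_i)  # harmonic mean replicates
        sigma_g = (msb - msw) / r_bar
        denom = sigma_g + msw
        if denom <= 0:
            h2[i] = np.nan if msb == 0 and msw == 0 else 0.0
            continue
        h2[i] = min(max(sigma_g / denom, 0.0), 1.0)
    return pd.Series(h2, index=sse.index, name="h2")


def site_summaries(matrix: SSEMatrix, min_reads: int = 10, min_passing: int = 2,
                   replicated: bool = True, stratum: str | None = None) -> pd.DataFrame:
    """Range/variance/heritability summary per site (one stratum)."""
    table = genotype_average(matrix, min_reads=min_reads,
                             min_passing=min_passing, stratum=stratum)
    if isinstance(table, dict):
        raise ValueError("multiple strata present; pass stratum=...")
    out = variability_metrics(table)
    if replicated:
        out["h2"] = broad_sense_heritability(matrix, min_reads=min_reads,
                                             stratum=stratum)
    else:
        out["h2"] = np.nan
    return out


def select_mappable_sites(summaries: pd.DataFrame, mode: str = "replicated",
                          min_obs: int = 100) -> pd.Index:
    """Sites worth mapping: top-quartile variance (and heritability when
    replicated) with at least ``min_obs`` genotypes observed."""
    if mode not in ("replicated", "variance_only"):
        raise ValueError(f"unknown mode {mode!r}")
    var_q = summaries["variance"].quantile(0.75)
    keep = (summaries["variance"] >= var_q) & (summaries["n_obs"] >= min_obs)
    if mode == "replicated":
        h2_q = summaries["h2"].quantile(0.75)
        keep &= summaries["h2"] >= h2_q
    return summaries.index[keep.fillna(False)]
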