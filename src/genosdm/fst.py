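"""Weir–Cockerham fixation index (F_ST) from allele dosages.

Per-site variance components a (among groups), b (among individuals within
groups) and c (within individuals) follow the 1984 method-of-moments
estimator for diploid data with observed heterozygosity, generalized to r
groups. The per-site estimate is theta = a / (a + b + c); the genome-wide
summary is the ratio-of-sums weighted mean sum(a) / sum(a + b + c) over
sites with a finite denominator. Conventions mirror the common
variant-toolkit output: negative per-site values are retained and sites with
an undefined estimate are skipped in the weighted mean.
"""

from __future__ import annotations

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["fst_weir_cockerham"]


def fst_weir_cockerham(g, groups) -> tuple[np.ndarray, float]:
    """Per-site and weighted-mean Weir–Cockerham F_ST.

    Parameters
    ----------
    g : GenotypeMatrix or ndarray (individuals x sites, dosages, NaN missing)
    groups : array of per-sample group labels (at least two distinct groups)

    Returns
    -------
    per_site : ndarray of per-site theta estimates (NaN where undefined)
    weighted_mean : float, sum(a) / sum(a+b+c) over defined sites
    """
    G = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    groups = np.asarray(groups)
    if groups.shape[0] != G.shape[0]:
        raise ValueError("groups length does not match number of samples")
    labels = np.unique(groups)
    r = labels.size
    if r < 2:
        raise ValueError("F_ST requires at least two groups")

    # per-group per-site sample sizes, allele frequencies, het frequencies
    n_i = np.empty((r, G.shape[1]))
    p_i = np.empty((r, G.shape[1]))
    h_i = np.empty((r, G.shape[1]))
    for k, lab in enumerate(labels):
        sub = G[groups == lab]
        obs = np.isfinite(sub)
        n_i[k] = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.nansum(sub, axis=0) / (2.0 * n_i[k])
            h_i[k] = np.nansum(sub == 1.0, axis=0) / n_i[k]

    # sites where every group has at least one call and >1 sample overall
    valid = (n_i >= 1).all(axis=0)
    n_sum = n_i.sum(axis=0)
    valid &= n_sum > r  # nbar > 1 needed for the b component

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r
        nc = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_sum

        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        per_site = np.where(valid & (denom != 0), a / denom, np.nan)

    finite = valid & np.isfinite(denom) & (denom != 0)
    if not finite.any():
        return per_site, float("nan")
    weighted = float(a[finite].sum() / denom[finite].sum())
    return per_site, weighted
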