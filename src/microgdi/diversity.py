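"""Per-sample alpha-diversity: richness, Simpson, Shannon, rarefaction.

Simpson's index is the unbiased finite-sample form
``D = 1 - sum n(n-1) / (N(N-1))`` on absolute counts; Shannon is
``H = -sum p_i ln p_i`` in natural-log units. Rarefaction offers the exact
hypergeometric expectation of richness at a subsampled depth and a
Monte-Carlo check by subsampling reads without replacement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .otu import OtuTable


def richness(sample_counts) -> int:
    """Number of OTUs with at least one read."""
    c = np.asarray(sample_counts)
    if (c < 0).any():
        raise ValueError("negative counts")
    return int((c > 0).sum())


def simpson_index(sample_counts) -> float:
    """Simpson diversity ``1 - sum n(n-1)/(N(N-1))`` on absolute counts.

    Equals the probability that two reads drawn without replacement belong
    to different OTUs; 0 for a single-OTU sample.
    """
    c = np.asarray(sample_counts, dtype=float)
    n_total = c.sum()
    if n_total < 2:
        raise ValueError("Simpson index needs at least 2 reads")
    return float(1.0 - (c * (c - 1)).sum() / (n_total * (n_total - 1)))


def shannon_index(sample_counts) -> float:
    """Shannon entropy ``-sum p_i ln p_i`` over OTUs with positive counts."""
    c = np.asarray(sample_counts, dtype=float)
    n_total = c.sum()
    if n_total <= 0:
        raise ValueError("Shannon index needs at least 1 read")
    p = c[c > 0] / n_total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Tidy table of richness ("unique_otu"), Simpson and Shannon per sample."""
    counts = table.counts.to_numpy()
    rows = []
    for sid, row in zip(table.sample_ids, counts):
        rows.append(
            {
                "sample_id": sid,
                "unique_otu": richness(row),
                "simpson": simpson_index(row),
                "shannon": shannon_index(row),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_curve(
    sample_counts,
    depths,
    mode: str = "analytic",
    n_draws: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expected richness at each subsampling depth.

    Analytic mode is the hypergeometric expectation
    ``E[S_d] = sum_i (1 - C(N - n_i, d) / C(N, d))``; Monte-Carlo mode
    averages observed richness over ``n_draws`` subsamples of reads drawn
    without replacement.
    """
    c = np.asarray(sample_counts, dtype=np.int64)
    c = c[c > 0]
    n_total = int(c.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if (depths > n_total).any():
        raise ValueError("rarefaction depth exceeds total reads")
    if (depths < 1).any():
        raise ValueError("rarefaction depth must be positive")

    if mode == "analytic":
        exp = []
        for d in depths:
            # P(OTU i absent from a depth-d subsample) = C(N-n_i, d)/C(N, d)
            ok = (n_total - c) >= d
            log_absent = np.full(c.shape, -np.inf)
            log_absent[ok] = _log_comb(n_total - c[ok], d) - _log_comb(n_total, d)
            exp.append(float((1.0 - np.exp(log_absent)).sum()))
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        reads = np.repeat(np.arange(len(c)), c)
        exp = []
        for d in depths:
            hits = 0
            for _ in range(n_draws):
                sub = rng.choice(reads, size=int(d), replace=False)
                hits += len(np.unique(sub))
            exp.append(hits / n_draws)
    else:
        raise ValueError("mode must be 'analytic' or 'montecarlo'")

    return pd.DataFrame({"depth": depths, "expected_richness": exp})
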