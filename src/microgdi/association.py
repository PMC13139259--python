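"""Microbiome → age-trait association screen.

Early-life microbiome features (alpha-diversity, ordination scores, taxon
relative abundances) summarised to line means are correlated, per diet,
against later-life trait line means (lifespan and per-age locomotor
activity, heat knockdown time, dry weight) with Spearman's rho and
Fisher-z confidence intervals. Significance is declared when the CI
excludes zero; Benjamini–Hochberg q-values are reported as an extra column
but do not drive the flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .quantgen import phenotypic_correlation

logger = logging.getLogger("microgdi")

ALPHA_FEATURES = ("unique_otu", "simpson", "shannon")


def build_line_features(
    alpha: pd.DataFrame,
    abund: pd.DataFrame | None,
    ordination_scores: pd.DataFrame | None,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(line, diet) means of each microbiome feature over replicates.

    ``alpha`` is the per-sample alpha-diversity table; ``abund`` taxon
    percentages (columns prefixed ``taxon:``); ``ordination_scores``
    per-sample axis scores (e.g. PCA1/PCA2). All are indexed by sample id
    and averaged within (line, diet).
    """
    pieces = [alpha]
    if ordination_scores is not None:
        pieces.append(ordination_scores)
    if abund is not None:
        pieces.append(abund.add_prefix("taxon:"))
    feats = pd.concat(pieces, axis=1)
    missing = feats.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"feature samples missing metadata: {list(missing)[:5]}")
    key = meta.loc[feats.index, ["line_id", "diet"]]
    out = feats.groupby([key["line_id"], key["diet"]], observed=True).mean()
    out.index.names = ["line_id", "diet"]
    return out


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, 0, 1)
    return out


def screen(
    features: pd.DataFrame,
    traits: pd.DataFrame,
    diet: str,
    min_lines: int = 4,
) -> pd.DataFrame:
    """Correlate every feature with every (trait, age) within one diet.

    ``features``: (line_id, diet)-indexed feature means. ``traits``: tidy
    frame with columns line_id, diet, trait, age_days (NaN for ageless
    traits such as lifespan), value. Returns one row per
    (feature, trait, age) with rho, SE, Fisher-z CI, a CI-excludes-zero
    significance flag and BH q-values.
    """
    feats = features.xs(diet, level="diet")
    sub = traits[traits["diet"] == diet]
    rows = []
    for (trait, age), tsub in sub.groupby(["trait", "age_days"], observed=True, dropna=False):
        tvals = tsub.set_index("line_id")["value"]
        for feat in feats.columns:
            joined = pd.concat([feats[feat], tvals], axis=1, join="inner").dropna()
            if joined.shape[0] < min_lines:
                logger.warning(
                    "screen: %s x %s has %d shared lines (< %d), skipped",
                    feat, trait, joined.shape[0], min_lines,
                )
                continue
            est = phenotypic_correlation(joined.iloc[:, 0], joined.iloc[:, 1])
            rows.append(
                {
                    "diet": diet,
                    "feature": feat,
                    "trait": trait,
                    "age_days": age,
                    "rho": est.rho,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_lines": est.n_units,
                    "significant": bool(est.ci_low > 0 or est.ci_high < 0),
                }
            )
    if not rows:
        raise ValueError("no feature/trait pair had enough shared lines")
    out = pd.DataFrame(rows)
    # two-sided normal p on the Fisher-z scale, for the BH column only
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(out["rho"], -1 + 1e-15, 1 - 1e-15))
        zse = 1.0 / np.sqrt(out["n_lines"] - 3)
        from scipy.stats import norm

        pvals = 2 * norm.sf(np.abs(z / zse))
    out["q_value"] = _bh_qvalues(np.asarray(pvals))
    return out
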