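"""Ordination of abundance matrices: PCA, CA and diet-constrained CCA.

Supports the five presentation metrics used for compositional data —
Euclidean (raw), Chord (unit-norm rows), Aitchison (CLR with pseudocount),
Robust Aitchison (CLR over each row's nonzero support) and Chi-square (the
correspondence-analysis standardization). CCA is the classical chi-square
form: the standardized matrix is split into the part explained by a
per-sample factor (diet) and the residual, each decomposed by SVD, with
axis shares expressed against total inertia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRANSFORMS = ("euclidean", "chord", "aitchison", "robust_aitchison", "chisq")


@dataclass
class OrdinationResult:
    sample_scores: pd.DataFrame  # samples x axes
    axis_labels: list
    explained_pct: np.ndarray
    kind: str
    constrained_pct: float | None = None
    feature_loadings: pd.DataFrame | None = field(default=None, repr=False)


def _chisq_standardize(x: np.ndarray):
    total = x.sum()
    if total <= 0:
        raise ValueError("matrix with zero total")
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if (r == 0).any():
        raise ValueError("all-zero row")
    keep = c > 0
    q = (p[:, keep] - np.outer(r, c[keep])) / np.sqrt(np.outer(r, c[keep]))
    return q, r, keep


def transform_matrix(counts, method: str = "euclidean") -> pd.DataFrame:
    """Apply one of the five presentation transforms to a counts matrix."""
    df = pd.DataFrame(counts).astype(float)
    x = df.to_numpy()
    if (x < 0).any():
        raise ValueError("negative entries")
    rowsum = x.sum(axis=1)
    if method in ("chord", "aitchison", "robust_aitchison", "chisq") and (rowsum == 0).any():
        raise ValueError("all-zero row")
    if method == "euclidean":
        out = x
    elif method == "chord":
        out = x / np.linalg.norm(x, axis=1, keepdims=True)
    elif method == "aitchison":
        logx = np.log(x + 1.0)
        out = logx - logx.mean(axis=1, keepdims=True)
    elif method == "robust_aitchison":
        out = np.zeros_like(x)
        for i in range(x.shape[0]):
            nz = x[i] > 0
            lg = np.log(x[i, nz])
            out[i, nz] = lg - lg.mean()
    elif method == "chisq":
        q, _, keep = _chisq_standardize(x)
        return pd.DataFrame(q, index=df.index, columns=df.columns[keep])
    else:
        raise ValueError(f"unknown method {method!r}; choose from {TRANSFORMS}")
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _orient(u: np.ndarray, v: np.ndarray):
    """Deterministic axis signs: largest-|loading| entry of v made positive."""
    for k in range(v.shape[1]):
        j = np.argmax(np.abs(v[:, k]))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
            u[:, k] = -u[:, k]
    return u, v


def pca(matrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal component analysis by SVD of the column-centered matrix."""
    df = pd.DataFrame(matrix).astype(float)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 features")
    x = df.to_numpy()
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s[0] > 0 else 0
    if n_axes is None:
        n_axes = rank
    n_axes = max(1, min(n_axes, max(rank, 1)))
    u, v = _orient(u[:, :n_axes], vt.T[:, :n_axes])
    scores = u * s[:n_axes]
    ss_total = (s**2).sum()
    explained = 100.0 * s[:n_axes] ** 2 / ss_total if ss_total > 0 else np.zeros(n_axes)
    labels = [f"PCA{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        pd.DataFrame(scores, index=df.index, columns=labels),
        labels,
        explained,
        "pca",
        feature_loadings=pd.DataFrame(v, index=df.columns, columns=labels),
    )


def cca_constrained(matrix, constraint, n_axes: int | None = None) -> OrdinationResult:
    """Canonical correspondence analysis constrained by a per-sample factor.

    The chi-square standardized matrix is regressed (row-weighted) on the
    factor's dummy design; the SVD of the fitted part gives the constrained
    CCA axes, the SVD of the residual the unconstrained CA axes. Axis
    percentages are shares of total inertia, so the constrained share plus
    all residual shares sum to 100.
    """
    df = pd.DataFrame(matrix).astype(float)
    levels = pd.Series(np.asarray(constraint), index=df.index)
    uniq = sorted(levels.unique())
    if len(uniq) < 2:
        raise ValueError("constraint must have >= 2 levels")
    q, r, keep = _chisq_standardize(df.to_numpy())

    # row-weighted projection onto the dummy design (weights = row masses)
    d = pd.get_dummies(levels).to_numpy(float)
    w = np.sqrt(r)[:, None]
    zc = w * (d - (r @ d)[None, :])  # weighted-centered design
    g, _, _, _ = np.linalg.lstsq(zc, q, rcond=None)
    fitted = zc @ g
    resid = q - fitted

    total_inertia = (q**2).sum()
    if total_inertia <= 0:
        raise ValueError("degenerate matrix: no inertia")

    def _decompose(mat, prefix, limit):
        u, s, vt = np.linalg.svd(mat, full_matrices=False)
        rank = int((s > max(s[0], 1e-300) * 1e-9).sum())
        k = min(limit, rank) if limit else rank
        k = max(k, 0)
        u, v = _orient(u[:, :k], vt.T[:, :k])
        scores = (u * s[:k]) / w  # back to per-sample scale
        labels = [f"{prefix}{i + 1}" for i in range(k)]
        pct = 100.0 * s[:k] ** 2 / total_inertia
        return scores, labels, pct

    max_constrained = len(uniq) - 1
    c_scores, c_labels, c_pct = _decompose(fitted, "CCA", max_constrained)
    r_scores, r_labels, r_pct = _decompose(resid, "CA", n_axes)
    scores = np.hstack([c_scores, r_scores])
    labels = c_labels + r_labels
    return OrdinationResult(
        pd.DataFrame(scores, index=df.index, columns=labels),
        labels,
        np.concatenate([c_pct, r_pct]),
        "cca",
        constrained_pct=float(c_pct.sum()),
    )


def rda_constrained(matrix, constraint, n_axes: int | None = None) -> OrdinationResult:
    """Redundancy analysis: the Euclidean-metric analogue of CCA.

    Column-centered data regressed on the factor dummies with unit row
    weights; provided as an option because CCA's intrinsic metric is
    chi-square, not Euclidean.
    """
    df = pd.DataFrame(matrix).astype(float)
    levels = pd.Series(np.asarray(constraint), index=df.index)
    uniq = sorted(levels.unique())
    if len(uniq) < 2:
        raise ValueError("constraint must have >= 2 levels")
    x = df.to_numpy()
    xc = x - x.mean(axis=0, keepdims=True)
    d = pd.get_dummies(levels).to_numpy(float)
    dc = d - d.mean(axis=0, keepdims=True)
    g, _, _, _ = np.linalg.lstsq(dc, xc, rcond=None)
    fitted = dc @ g
    resid = xc - fitted
    total = (xc**2).sum()
    if total <= 0:
        raise ValueError("degenerate matrix")

    def _dec(mat, prefix, limit):
        u, s, vt = np.linalg.svd(mat, full_matrices=False)
        rank = int((s > max(s[0], 1e-300) * 1e-9).sum())
        k = min(limit, rank) if limit else rank
        u, v = _orient(u[:, :k], vt.T[:, :k])
        labels = [f"{prefix}{i + 1}" for i in range(k)]
        return u * s[:k], labels, 100.0 * s[:k] ** 2 / total

    c_scores, c_labels, c_pct = _dec(fitted, "RDA", len(uniq) - 1)
    r_scores, r_labels, r_pct = _dec(resid, "PC", n_axes)
    return OrdinationResult(
        pd.DataFrame(
            np.hstack([c_scores, r_scores]), index=df.index, columns=c_labels + r_labels
        ),
        c_labels + r_labels,
        np.concatenate([c_pct, r_pct]),
        "rda",
        constrained_pct=float(c_pct.sum()),
    )
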