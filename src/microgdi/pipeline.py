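"""End-to-end orchestration: QC → diversity/abundance → INT → variance
components, heritability, GDI and correlations → ordination → association
screen, with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import build_line_features, screen
from .diversity import alpha_diversity
from .ordination import cca_constrained, pca, transform_matrix
from .otu import (
    DIETS,
    OtuTable,
    exclude_taxon,
    filter_low_depth,
    prevalent_taxa,
    qc_report,
    read_otu_table,
    relative_abundance,
)
from .quantgen import (
    diet_effect_test,
    fit_mixed_single_diet,
    fit_mixed_two_diet,
    gdi_test,
    genetic_correlation_cross_env,
    genetic_correlation_yamada,
    heritability,
    int_transform,
    phenotypic_correlation,
)

logger = logging.getLogger("microgdi")


@dataclass
class PipelineConfig:
    """Run configuration; serialized alongside outputs."""

    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    traits_path: str | None = None
    out_dir: str = "microgdi_out"
    min_reads: int = 1000
    exclude_genus: str = "Wolbachia"
    prevalence_threshold: float = 1.0
    distance_method: str = "euclidean"
    ci_multiplier: float = 1.96
    gdi_p_method: str = "mixture"
    diversity_before_exclusion: bool = False
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            return out
        return wrapped
    return deco


@_stage("qc")
def _run_qc(table: OtuTable, cfg: PipelineConfig):
    report = qc_report(table, cfg.min_reads)
    filtered = filter_low_depth(table, cfg.min_reads)
    if filtered.counts.shape[0] == 0:
        raise StageError(
            f"stage 'qc' failed: no sample reaches min_reads={cfg.min_reads}"
        )
    cleaned = exclude_taxon(filtered, cfg.exclude_genus)
    logger.info(
        "stage qc: %d -> %d samples (min_reads=%d), %d -> %d OTUs (excluded %s)",
        table.counts.shape[0], filtered.counts.shape[0], cfg.min_reads,
        filtered.counts.shape[1], cleaned.counts.shape[1], cfg.exclude_genus,
    )
    zero = cleaned.flags.get("zero_read_samples", [])
    if zero:
        cleaned = cleaned.subset_samples(cleaned.sample_ids.difference(zero))
    return report, filtered, cleaned


def _tidy_trait(alpha_like: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    df = meta.loc[alpha_like.index, ["line_id", "diet", "replicate"]].copy()
    df["value"] = alpha_like.to_numpy(dtype=float)
    return df.reset_index(drop=True)


@_stage("quantgen")
def _run_quantgen(per_sample: pd.DataFrame, meta: pd.DataFrame, cfg: PipelineConfig):
    """Per trait: INT, two-diet REML + GDI + diet test + Yamada, per-diet
    heritability, cross-diet genetic and phenotypic correlations."""
    comp_rows, corr_rows, gdi_rows = [], [], []
    for trait in per_sample.columns:
        values = per_sample[trait]
        obs = _tidy_trait(pd.Series(int_transform(values), index=values.index), meta)
        vc2 = fit_mixed_two_diet(obs)
        g = gdi_test(obs, method=cfg.gdi_p_method)
        contrast, p_diet = diet_effect_test(obs)
        yam = genetic_correlation_yamada(vc2)
        comp_rows.append(
            {
                "trait": trait, "diet_scope": "both",
                "sigma_line": vc2.sigma_line, "sigma_lxd": vc2.sigma_lxd,
                "sigma_resid": vc2.sigma_resid,
                "h2": np.nan, "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "diet_contrast": contrast, "diet_p": p_diet,
            }
        )
        gdi_rows.append(
            {"trait": trait, "statistic": g.statistic, "p_value": g.p_value,
             "method": g.method}
        )
        line_means = {}
        for diet in DIETS:
            sub = obs[obs["diet"] == diet]
            vc1 = fit_mixed_single_diet(sub)
            h = heritability(vc1)
            comp_rows.append(
                {
                    "trait": trait, "diet_scope": diet,
                    "sigma_line": vc1.sigma_line, "sigma_lxd": np.nan,
                    "sigma_resid": vc1.sigma_resid,
                    "h2": h.h2, "se": h.se, "ci_low": h.ci_low, "ci_high": h.ci_high,
                    "diet_contrast": np.nan, "diet_p": np.nan,
                }
            )
            line_means[diet] = sub.groupby("line_id")["value"].mean()
        rg = genetic_correlation_cross_env(obs)
        lm = pd.concat(line_means, axis=1).dropna()
        rp = phenotypic_correlation(lm.iloc[:, 0], lm.iloc[:, 1])
        for est in (yam, rg, rp):
            corr_rows.append(
                {
                    "trait": trait, "kind": est.kind, "rho": est.rho, "se": est.se,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "n_units": est.n_units, "flag": est.flag,
                }
            )
    return (
        pd.DataFrame(comp_rows),
        pd.DataFrame(corr_rows),
        pd.DataFrame(gdi_rows),
    )


def run_pipeline(
    config: PipelineConfig,
    table: OtuTable | None = None,
    traits: pd.DataFrame | None = None,
) -> dict:
    """Run every stage and write one TSV per output plus a JSON manifest.

    ``table`` may be passed in-memory (e.g. from the simulator); otherwise
    the three TSV paths in the config are read. ``traits`` is an optional
    tidy line-level age-trait table enabling the association screen.
    Deterministic given (inputs, config): rerunning writes identical
    tables.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if table is None:
        if not (config.counts_path and config.metadata_path and config.taxonomy_path):
            raise StageError("stage 'input' failed: no table and no input paths")
        table = read_otu_table(
            config.counts_path, config.metadata_path, config.taxonomy_path
        )
    if traits is None and config.traits_path:
        traits = pd.read_csv(config.traits_path, sep="\t")

    results: dict = {"config": config}
    report, filtered, cleaned = _run_qc(table, config)
    results["qc_report"] = report

    diversity_input = filtered if config.diversity_before_exclusion else cleaned
    alpha = alpha_diversity(diversity_input)
    results["alpha_diversity"] = alpha

    abund_genus = relative_abundance(cleaned, rank="genus")
    prev = prevalent_taxa(abund_genus, cleaned.meta, config.prevalence_threshold)
    results["genus_abundance"] = abund_genus
    results["prevalent_genera"] = prev
    logger.info("stage abundance: %d genera, %d prevalent (>=%g%%)",
                abund_genus.shape[1], len(prev), config.prevalence_threshold)

    per_sample = alpha.join(abund_genus[prev].add_prefix("abund:"))
    comp, corr, gdi = _run_quantgen(per_sample, cleaned.meta, config)
    results["components"] = comp
    results["correlations"] = corr
    results["gdi"] = gdi

    tr = transform_matrix(cleaned.counts, config.distance_method)
    p = pca(tr, n_axes=min(10, min(tr.shape) - 1))
    c = cca_constrained(cleaned.counts, cleaned.meta["diet"], n_axes=10)
    results["pca"] = p
    results["cca"] = c
    logger.info("stage ordination: PCA1 %.1f%%, PCA2 %.1f%%; CCA1 (diet) %.1f%%",
                p.explained_pct[0], p.explained_pct[1], c.constrained_pct)

    if traits is not None:
        feats = build_line_features(
            alpha, abund_genus[prev], p.sample_scores[["PCA1", "PCA2"]], cleaned.meta
        )
        assoc = pd.concat(
            [screen(feats, traits, diet) for diet in sorted(traits["diet"].unique())],
            ignore_index=True,
        )
        results["associations"] = assoc

    _write_outputs(results, out_dir, config)
    return results


def _write_outputs(results: dict, out_dir: Path, config: PipelineConfig) -> None:
    results["qc_report"].to_csv(out_dir / "qc_report.tsv", sep="\t")
    results["alpha_diversity"].to_csv(out_dir / "alpha_diversity.tsv", sep="\t")
    results["genus_abundance"].to_csv(out_dir / "genus_abundance.tsv", sep="\t")
    results["components"].to_csv(out_dir / "components.tsv", sep="\t", index=False)
    results["correlations"].to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
    results["gdi"].to_csv(out_dir / "gdi_tests.tsv", sep="\t", index=False)
    p, c = results["pca"], results["cca"]
    scores = p.sample_scores.stack().rename("score").reset_index()
    scores.columns = ["sample_id", "axis", "score"]
    scores.to_csv(out_dir / "pca_scores.tsv", sep="\t", index=False)
    pd.DataFrame({"axis": p.axis_labels, "explained_pct": p.explained_pct}).to_csv(
        out_dir / "pca_summary.tsv", sep="\t", index=False
    )
    pd.DataFrame({"axis": c.axis_labels, "explained_pct": c.explained_pct}).to_csv(
        out_dir / "cca_summary.tsv", sep="\t", index=False
    )
    if "associations" in results:
        results["associations"].to_csv(
            out_dir / "associations.tsv", sep="\t", index=False
        )
    manifest = {
        "package": "microgdi",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "outputs": sorted(f.name for f in out_dir.glob("*.tsv")),
        "prevalent_genera": results.get("prevalent_genera", []),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
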