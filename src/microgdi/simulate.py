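"""Synthetic data with the statistical structure the estimators assume.

Two generation paths are kept separate on purpose. Trait tables are drawn
directly on the Gaussian (post-INT) scale from the mixed model
``y = mu + L + D + LxD + e`` so estimator correctness can be tested without
transformation distortion. Count tables are a Dirichlet-multinomial draw
around per-(line, diet) latent log-abundances built from a low-complexity
genus profile (one dominant lactic-acid genus near half of the community, a
second acetic-acid genus, and a tail of minor genera), with sequencing
depth negative-binomial, an endosymbiont genus spiked into infected lines,
and rare OTUs supplying singletons so coverage and depth filters have work
to do. Age-related trait tables are noise plus an adjustable coupling to a
chosen microbiome feature, so the association screen's null and power are
both constructible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .otu import DIETS, OtuTable

DEFAULT_GENUS_PROFILE = {
    "Leuconostoc": 48.0,
    "Acetobacter": 20.0,
    "Weissella": 8.0,
    "Lactobacillus": 6.0,
    "Lactiplantibacillus": 5.0,
    "Levilactobacillus": 3.0,
    "Fructobacillus": 2.5,
    "Gluconobacter": 2.0,
    "Enterococcus": 1.5,
    "Providencia": 1.0,
    "Serratia": 0.8,
    "Paenibacillus": 0.7,
    "Corynebacterium": 0.5,
    "Staphylococcus": 0.5,
    "Bacillus": 0.5,
}

AGE_DAYS = (7, 16, 25, 34)
AGE_TRAITS = ("activity", "hkdt", "dry_weight")


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults mirror the study design the pipeline targets: 88 inbred lines
    on two diets with ~3 replicate pools of 10 flies per line and diet,
    sequencing depth around 20,000 reads with a 1,000-read floor, and a
    community of ~1,200 OTUs dominated by a few genera. Trait-model
    variances are on the INT scale (total near 1). ``rho_g_target`` sets
    the implied cross-diet genetic correlation by splitting line variance:
    sigma2_line = rho * total_genetic, sigma2_lxd = (1 - rho) * total.
    """

    n_lines: int = 88
    n_reps: int = 3
    pool_size: int = 10
    depth_mean: float = 20_000.0
    depth_dispersion: float = 5.0
    min_depth: int = 1_001
    n_otus: int = 1_200
    genus_profile: dict = field(default_factory=lambda: dict(DEFAULT_GENUS_PROFILE))
    mu: float = 0.0
    diet_effect: float = 0.5
    sigma_line2: float = 0.3
    sigma_lxd2: float = 0.1
    sigma_resid2: float = 0.6
    rho_g_target: float | None = None
    coupling: float = 0.0
    wolbachia_lines: float = 0.5
    otu_log_sd: float = 1.0
    dirichlet_concentration: float = 200.0
    line_effect_sd: float = 0.4
    lxd_effect_sd: float = 0.2
    diet_target_genus: str = "Acetobacter"
    diet_log_effect: float = 0.0
    inject_low_depth: bool = False
    seed: int = 0

    def variance_triplet(self):
        if self.rho_g_target is None:
            return self.sigma_line2, self.sigma_lxd2, self.sigma_resid2
        total_g = self.sigma_line2 + self.sigma_lxd2
        rho = float(np.clip(self.rho_g_target, -1.0, 1.0))
        return rho * total_g, (1.0 - rho) * total_g, self.sigma_resid2


def _design_frame(spec: SimulationSpec) -> pd.DataFrame:
    rows = [
        {"line_id": f"line_{i + 1:03d}", "diet": diet, "replicate": rep + 1}
        for i in range(spec.n_lines)
        for diet in DIETS
        for rep in range(spec.n_reps)
    ]
    return pd.DataFrame(rows)


def simulate_trait_table(spec: SimulationSpec, trait_name: str = "trait") -> pd.DataFrame:
    """Draw a tidy trait table from the two-diet mixed model.

    Line effects L_i ~ N(0, sigma2_line), interactions (LD)_ij ~
    N(0, sigma2_lxd) independent across diets, residuals N(0, sigma2_resid);
    the diet fixed effect is added to the second diet. The implied
    cross-diet genetic correlation is sigma2_line / (sigma2_line +
    sigma2_lxd).
    """
    s_l, s_lxd, s_e = spec.variance_triplet()
    rng = np.random.default_rng(spec.seed)
    design = _design_frame(spec)
    line_idx = design["line_id"].factorize()[0]
    diet_idx = (design["diet"] == DIETS[1]).to_numpy(int)
    cell_idx = line_idx * 2 + diet_idx
    l_eff = rng.normal(0.0, np.sqrt(s_l), spec.n_lines)
    lxd_eff = rng.normal(0.0, np.sqrt(s_lxd), spec.n_lines * 2)
    resid = rng.normal(0.0, np.sqrt(s_e), len(design))
    design["value"] = (
        spec.mu
        + spec.diet_effect * diet_idx
        + l_eff[line_idx]
        + lxd_eff[cell_idx]
        + resid
    )
    design["trait"] = trait_name
    return design


def _truncated_nb_depths(rng, spec: SimulationSpec, n: int) -> np.ndarray:
    k = spec.depth_dispersion
    p = k / (k + spec.depth_mean)
    depths = rng.negative_binomial(k, p, size=n)
    low = depths < spec.min_depth
    while low.any():  # resample below-floor draws; floor keeps QC non-trivial
        depths[low] = rng.negative_binomial(k, p, size=int(low.sum()))
        low = depths < spec.min_depth
    return depths


def simulate_otu_table(spec: SimulationSpec) -> OtuTable:
    """Dirichlet-multinomial OTU counts over a low-complexity community.

    OTUs are apportioned to genera of the baseline profile (abundant genera
    get several OTUs and named species; a long tail of rare OTUs yields
    singletons). Per (line, diet) the latent genus log-abundance is
    baseline + line effect + optional diet effect on one target genus +
    line-by-diet effect; each sample then draws Dirichlet-multinomial
    counts at a negative-binomial depth. An endosymbiont (Wolbachia) genus
    is spiked into samples of infected lines. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    design = _design_frame(spec)
    n_samples = len(design)
    design["sample_id"] = [f"S{i + 1:04d}" for i in range(n_samples)]

    genera = list(spec.genus_profile)
    weights = np.array([spec.genus_profile[g] for g in genera], dtype=float)
    weights = weights / weights.sum()
    # OTUs per genus roughly proportional to sqrt(abundance), remainder rare tail
    n_core = max(len(genera), int(0.25 * spec.n_otus))
    per_genus = np.maximum(1, np.round(np.sqrt(weights) / np.sqrt(weights).sum() * n_core)).astype(int)
    otu_genus: list[str] = []
    for g, k in zip(genera, per_genus):
        otu_genus.extend([g] * int(k))
    n_tail = max(0, spec.n_otus - len(otu_genus))
    tail_genera = rng.choice(genera, size=n_tail, p=weights)
    otu_genus.extend(tail_genera.tolist())
    otu_genus = otu_genus[: spec.n_otus]
    n_otus = len(otu_genus)
    otu_ids = [f"OTU_{i + 1:05d}" for i in range(n_otus)]

    # within-genus OTU weights: first (core) OTUs abundant, tail very rare
    otu_log_base = np.empty(n_otus)
    genus_arr = np.asarray(otu_genus)
    for gi, g in enumerate(genera):
        members = np.where(genus_arr == g)[0]
        rel = rng.normal(0.0, spec.otu_log_sd, size=len(members))
        rel[np.argsort(rel)] = np.sort(rel)[::-1]  # heaviest first for readability
        is_tail = members >= (n_otus - n_tail)
        rel = rel - 6.0 * is_tail  # tail OTUs ~e^-6 down: singleton fodder
        share = np.log(weights[gi]) - np.log(len(members))
        otu_log_base[members] = share + rel

    species = []
    seen: dict[str, int] = {}
    for gi, g in enumerate(otu_genus):
        k = seen.get(g, 0)
        seen[g] = k + 1
        species.append(f"{g} synthetica {k + 1}" if k < 3 else "unknown")
    taxonomy = pd.DataFrame({"genus": otu_genus, "species": species}, index=pd.Index(otu_ids, name="otu_id"))

    # latent per-(line, diet) genus effects on the log scale
    line_eff = rng.normal(0.0, spec.line_effect_sd, size=(spec.n_lines, len(genera)))
    lxd_eff = rng.normal(0.0, spec.lxd_effect_sd, size=(spec.n_lines, 2, len(genera)))
    diet_shift = np.zeros((2, len(genera)))
    if spec.diet_log_effect and spec.diet_target_genus in genera:
        diet_shift[1, genera.index(spec.diet_target_genus)] = spec.diet_log_effect

    line_codes = design["line_id"].factorize()[0]
    diet_codes = (design["diet"] == DIETS[1]).to_numpy(int)
    depths = _truncated_nb_depths(rng, spec, n_samples)
    if spec.inject_low_depth:
        n_low = max(1, n_samples // 50)
        low_idx = rng.choice(n_samples, size=n_low, replace=False)
        depths[low_idx] = rng.integers(100, spec.min_depth - 1, size=n_low)

    genus_col = np.array([genera.index(g) for g in otu_genus])
    counts = np.zeros((n_samples, n_otus), dtype=np.int64)
    for s in range(n_samples):
        li, di = line_codes[s], diet_codes[s]
        genus_log = line_eff[li] + lxd_eff[li, di] + diet_shift[di]
        alpha_otu = np.exp(otu_log_base + genus_log[genus_col])
        alpha_otu *= spec.dirichlet_concentration / alpha_otu.sum()
        probs = rng.dirichlet(alpha_otu)
        counts[s] = rng.multinomial(depths[s], probs)

    # endosymbiont spike for infected lines
    wolb_status = rng.random(spec.n_lines) < spec.wolbachia_lines
    wolb_ids = ["OTU_WOLB_1", "OTU_WOLB_2"]
    wolb = np.zeros((n_samples, 2), dtype=np.int64)
    for s in range(n_samples):
        if wolb_status[line_codes[s]]:
            frac = rng.beta(8, 20)  # ~30% of reads in infected samples
            total = rng.binomial(depths[s], frac)
            split = rng.binomial(total, 0.8)
            wolb[s] = (split, total - split)
        elif rng.random() < 0.02:  # rare index-hopping noise
            wolb[s, 0] = rng.integers(1, 5)
    counts = np.hstack([counts, wolb])
    otu_ids = otu_ids + wolb_ids
    taxonomy = pd.concat(
        [
            taxonomy,
            pd.DataFrame(
                {"genus": ["Wolbachia", "Wolbachia"],
                 "species": ["W. pipientis", "unknown"]},
                index=pd.Index(wolb_ids, name="otu_id"),
            ),
        ]
    )

    counts_df = pd.DataFrame(counts, index=pd.Index(design["sample_id"], name="sample_id"), columns=otu_ids)
    meta = design.set_index("sample_id")[["line_id", "diet", "replicate"]]
    table = OtuTable(counts_df, meta, taxonomy)
    table.flags["wolbachia_status"] = {
        f"line_{i + 1:03d}": bool(wolb_status[i]) for i in range(spec.n_lines)
    }
    return table


def simulate_age_traits(
    features: pd.DataFrame,
    spec: SimulationSpec,
    feature_name: str = "shannon",
    traits: tuple = AGE_TRAITS,
    ages: tuple = AGE_DAYS,
) -> pd.DataFrame:
    """Line-level age-trait table with adjustable coupling to one feature.

    Each (trait, age, diet) vector is ``coupling * z(feature) +
    sqrt(1 - coupling^2) * noise`` over lines, so coupling 0 is an exact
    null and coupling 1 a deterministic monotone signal. Lifespan is
    generated once per diet without an age.
    """
    c = float(spec.coupling)
    if not -1.0 <= c <= 1.0:
        raise ValueError("coupling must be in [-1, 1]")
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for diet in features.index.get_level_values("diet").unique():
        feat = features.xs(diet, level="diet")[feature_name]
        z = (feat - feat.mean()) / (feat.std(ddof=0) or 1.0)
        specs = [("lifespan", np.nan)] + [(t, a) for t in traits for a in ages]
        for trait, age in specs:
            noise = rng.normal(size=len(z))
            vals = c * z.to_numpy() + np.sqrt(1.0 - c**2) * noise
            for line, v in zip(z.index, vals):
                rows.append(
                    {"line_id": line, "diet": diet, "trait": trait,
                     "age_days": age, "value": float(v)}
                )
    return pd.DataFrame(rows)


def recovery_experiment(
    spec: SimulationSpec, n_datasets: int, seed: int | None = None
) -> pd.DataFrame:
    """Simulate-and-refit study of the variance-component estimators.

    For each dataset: draw a trait table, fit the two-diet REML model, the
    per-diet one-way models, per-diet heritability with its delta-method CI,
    and the cross-environment genetic correlation (the Yamada plug-in is
    summarised alongside it). Returns a summary with
    truth, mean estimate, bias, rmse, Monte-Carlo SE of the mean, and CI
    coverage where an interval is defined. Fit failures are counted, not
    fatal.
    """
    from .quantgen import (
        fit_mixed_single_diet,
        fit_mixed_two_diet,
        genetic_correlation_cross_env,
        genetic_correlation_yamada,
        heritability,
    )

    if n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    s_l, s_lxd, s_e = spec.variance_triplet()
    truth = {
        "sigma_line2": s_l,
        "sigma_lxd2": s_lxd,
        "sigma_resid2": s_e,
        "h2": (s_l + s_lxd) / (s_l + s_lxd + s_e),
        "rho_g": s_l / (s_l + s_lxd) if (s_l + s_lxd) > 0 else np.nan,
        "rho_g_yamada": s_l / (s_l + s_lxd) if (s_l + s_lxd) > 0 else np.nan,
    }
    base_seed = spec.seed if seed is None else seed
    seeds = np.random.SeedSequence(base_seed).generate_state(n_datasets) % (2**31)
    est: dict[str, list] = {k: [] for k in truth}
    cover = {"h2": []}
    failures = 0
    for s in seeds:
        try:
            obs = simulate_trait_table(replace(spec, seed=int(s)))
            vc2 = fit_mixed_two_diet(obs)
            est["sigma_line2"].append(vc2.sigma_line)
            est["sigma_lxd2"].append(vc2.sigma_lxd)
            est["sigma_resid2"].append(vc2.sigma_resid)
            h2s, fits = [], []
            for diet in DIETS:
                vc1 = fit_mixed_single_diet(obs[obs["diet"] == diet])
                fits.append(vc1)
                h = heritability(vc1)
                h2s.append(h.h2)
                cover["h2"].append(h.ci_low <= truth["h2"] <= h.ci_high)
            est["h2"].append(float(np.mean(h2s)))
            rho = genetic_correlation_cross_env(obs, diets=DIETS, fits=tuple(fits))
            est["rho_g"].append(rho.rho)
            est["rho_g_yamada"].append(genetic_correlation_yamada(vc2).rho)
        except Exception:  # noqa: BLE001 - failures are tallied in the summary
            failures += 1
    rows = []
    for k, t in truth.items():
        vals = np.asarray([v for v in est[k] if np.isfinite(v)])
        n = len(vals)
        if n == 0:
            rows.append({"parameter": k, "truth": t, "n": 0})
            continue
        row = {
            "parameter": k,
            "truth": t,
            "n": n,
            "mean": vals.mean(),
            "bias": vals.mean() - t,
            "rmse": float(np.sqrt(((vals - t) ** 2).mean())),
            "mc_se": vals.std(ddof=1) / np.sqrt(n),
            "failures": failures,
        }
        if k in cover and cover[k]:
            row["ci_coverage"] = float(np.mean(cover[k]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
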