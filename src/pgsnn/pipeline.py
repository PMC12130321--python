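"""End-to-end scenario orchestration.

A scenario fixes a genetic architecture (additive, pure 4-way epistatic,
or a blend), optionally introduces the joint-tagging confound by
removing redundantly tagged causal SNPs from the observed panel, picks a
mitigation strategy, and then — per replicate — simulates data, runs the
GWAS on the 60% training split, fits the additive shrinkage PGS
baseline, trains the matched large/small x linear/nonlinear networks,
and evaluates everything on the held-out test split.  Replicates are
aggregated into the nonlinear-vs-linear gap and its paired-t
significance.

Every random draw is traceable to (base_seed, replicate index); running
the same config twice yields an identical result object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import eval_stats, nn_engine, pgs_baseline
from .genotype_sim import (
    GenotypePanel,
    LdBlockSpec,
    read_raw,
    reduce_panel_joint_tagging,
    simulate_genotypes,
)
from .nn_engine import (
    LARGE_HIDDEN,
    SMALL_HIDDEN,
    NnConfig,
    build_design_matrix,
    build_network,
    predict,
    select_network,
    train_network,
)
from .phenotype_sim import (
    CovariateTable,
    blend_phenotypes,
    draw_architecture,
    filter_phenotype_outliers,
    simulate_phenotype,
    split_samples,
)

logger = logging.getLogger("pgsnn")

MITIGATIONS = ("none", "snp_dosage_weighting", "clump_distance")

__all__ = [
    "ScenarioConfig",
    "run_scenario",
    "run_replicate",
    "run_real_data",
    "desk_scale_config",
    "test_scale_config",
    "full_scale_config",
    "table1_scenario_configs",
]


@dataclass
class ScenarioConfig:
    """Declarative description of one simulation scenario."""

    scenario: str = "additive"  # additive | epistatic | mixed
    mix_ratio: tuple[int, int] = (2, 1)  # additive:epistatic parts, mixed only
    n_samples: int = 8_000
    n_snps: int = 2_000
    block_size: int = 5
    within_block_rho: float = 0.85
    maf_range: tuple[float, float] = (0.05, 0.5)
    bp_spacing: int = 5_000
    blocks_per_chrom: int = 50
    n_causal: int = 200
    target_h2: float = 0.5
    epistasis_form: str = "dosage_product"
    joint_tagging: bool = False
    jt_r2_threshold: float = 0.25
    jt_max_removal_fraction: float = 0.5
    mitigation: str = "none"
    replicates: int = 10
    base_seed: int = 0
    split_ratios: tuple[float, float, float] = (6, 2, 2)
    model_sizes: tuple[tuple[int, ...], ...] = (LARGE_HIDDEN, SMALL_HIDDEN)
    nn_overrides: dict = field(default_factory=dict)
    ridge_window_kb: int = 250
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if self.scenario not in ("additive", "epistatic", "mixed"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.mitigation not in MITIGATIONS:
            raise ValueError(f"unknown mitigation {self.mitigation!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal exceeds n_snps")
        if not 0 < self.target_h2 <= 1:
            raise ValueError("target_h2 must be in (0, 1]")
        if self.scenario != "additive" and self.n_causal % 4 != 0:
            raise ValueError("epistatic scenarios need n_causal divisible by 4")
        LdBlockSpec(
            n_snps=self.n_snps,
            block_size=self.block_size,
            within_block_rho=self.within_block_rho,
            maf_range=tuple(self.maf_range),
            bp_spacing=self.bp_spacing,
            blocks_per_chrom=self.blocks_per_chrom,
        )

    @property
    def ld_spec(self) -> LdBlockSpec:
        return LdBlockSpec(
            n_snps=self.n_snps,
            block_size=self.block_size,
            within_block_rho=self.within_block_rho,
            maf_range=tuple(self.maf_range),
            bp_spacing=self.bp_spacing,
            blocks_per_chrom=self.blocks_per_chrom,
        )

    @property
    def epistasis_percent(self) -> float:
        if self.scenario == "additive":
            return 0.0
        if self.scenario == "epistatic":
            return 100.0
        a, b = self.mix_ratio
        return 100.0 * b / (a + b)

    def replicate_seed(self, replicate: int) -> int:
        return int((self.base_seed * 100_003 + 7_919 * replicate + 1) % (2**31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mix_ratio"] = list(d["mix_ratio"])
        d["maf_range"] = list(d["maf_range"])
        d["split_ratios"] = list(d["split_ratios"])
        d["model_sizes"] = [list(m) for m in d["model_sizes"]]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("mix_ratio", "maf_range", "split_ratios"):
            if key in d:
                d[key] = tuple(d[key])
        if "model_sizes" in d:
            d["model_sizes"] = tuple(tuple(m) for m in d["model_sizes"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def desk_scale_config(**overrides) -> ScenarioConfig:
    """Default desk-scale preset: full scenario in minutes on one CPU."""
    cfg = ScenarioConfig(
        n_samples=8_000, n_snps=2_000, n_causal=200, replicates=10
    )
    return dataclasses.replace(cfg, **overrides)


def test_scale_config(**overrides) -> ScenarioConfig:
    """Compact preset for fast qualitative checks.

    16 causal SNPs (4 four-way groups) in a 96-SNP panel at n=6,000 keep
    the per-group interaction signal large enough for the networks to
    find within a short training budget.  Because an epoch here holds
    roughly twenty times fewer gradient updates than at full scale, the
    optimizer budget is rescaled to match in *updates* rather than
    epochs: larger learning rate, more epochs, proportionally longer
    early-stopping patience.  Only the small network size is trained.
    """
    cfg = ScenarioConfig(
        n_samples=6_000,
        n_snps=96,
        block_size=4,
        within_block_rho=0.85,
        maf_range=(0.2, 0.5),
        n_causal=16,
        replicates=10,
        blocks_per_chrom=8,
        model_sizes=(SMALL_HIDDEN,),
        nn_overrides={
            "max_epochs": 400,
            "patience_epochs": 60,
            "learning_rate": 0.008,
        },
    )
    return dataclasses.replace(cfg, **overrides)


def full_scale_config(**overrides) -> ScenarioConfig:
    """The full-scale study design (not intended for desk hardware)."""
    cfg = ScenarioConfig(
        n_samples=125_000, n_snps=500_000, n_causal=2_000, replicates=20
    )
    return dataclasses.replace(cfg, **overrides)


def table1_scenario_configs(base: Optional[ScenarioConfig] = None) -> dict[str, ScenarioConfig]:
    """The eight scenario rows: (epistasis %, joint tagging, mitigation)."""
    base = base or desk_scale_config()
    rows = {
        "epistatic_none": dict(scenario="epistatic", joint_tagging=False, mitigation="none"),
        "epistatic_weighted": dict(scenario="epistatic", joint_tagging=False, mitigation="snp_dosage_weighting"),
        "additive_none": dict(scenario="additive", joint_tagging=False, mitigation="none"),
        "additive_jt_none": dict(scenario="additive", joint_tagging=True, mitigation="none"),
        "additive_jt_weighted": dict(scenario="additive", joint_tagging=True, mitigation="snp_dosage_weighting"),
        "additive_jt_clump": dict(scenario="additive", joint_tagging=True, mitigation="clump_distance"),
        "mixed_2to1_weighted": dict(scenario="mixed", mix_ratio=(2, 1), joint_tagging=False, mitigation="snp_dosage_weighting"),
        "mixed_1to2_weighted": dict(scenario="mixed", mix_ratio=(1, 2), joint_tagging=False, mitigation="snp_dosage_weighting"),
    }
    return {name: dataclasses.replace(base, **kw) for name, kw in rows.items()}


# ---------------------------------------------------------------------------
# Scenario execution
# ---------------------------------------------------------------------------

def _simulate_trait(config: ScenarioConfig, panel: GenotypePanel, seed: int):
    """Phenotype for the configured architecture (blending when mixed)."""
    if config.scenario in ("additive", "epistatic"):
        arch = draw_architecture(
            panel, config.scenario, config.n_causal, config.target_h2, seed,
            epistasis_form=config.epistasis_form,
        )
        return simulate_phenotype(panel, arch), arch
    arch_add = draw_architecture(panel, "additive", config.n_causal, config.target_h2, seed)
    arch_epi = draw_architecture(
        panel, "epistatic", config.n_causal, config.target_h2, seed + 1,
        epistasis_form=config.epistasis_form,
    )
    p_add = simulate_phenotype(panel, arch_add)
    p_epi = simulate_phenotype(panel, arch_epi)
    return blend_phenotypes(p_add, p_epi, config.mix_ratio), (arch_add, arch_epi)


def _train_pair(
    inputs: nn_engine.ModelInput,
    y: np.ndarray,
    splits: dict[str, list[str]],
    config: ScenarioConfig,
    nonlinear: bool,
    seed: int,
):
    """Train every configured model size, keep the best by validation r^2."""
    nets = []
    for size in config.model_sizes:
        nn_cfg = NnConfig(
            hidden_sizes=tuple(size),
            nonlinear=nonlinear,
            seed=seed,
            **config.nn_overrides,
        )
        net = build_network(inputs.matrix.shape[1], nn_cfg)
        nets.append(train_network(net, inputs, y, splits, nn_cfg))
    best = nets[0]
    for other in nets[1:]:
        best = select_network(best, other, inputs, y, splits["validation"])
    return best


def run_replicate(config: ScenarioConfig, replicate: int) -> dict:
    """One full replicate: simulate, baseline, train, evaluate."""
    seed = config.replicate_seed(replicate)
    panel = simulate_genotypes(config.n_samples, config.ld_spec, seed)
    pheno, _arch = _simulate_trait(config, panel, seed + 11)

    if config.scenario == "mixed":
        causal = sorted(set(_arch[0].causal_ids) | set(_arch[1].causal_ids))
    else:
        causal = _arch.causal_ids

    observed = panel
    if config.joint_tagging:
        observed, _report = reduce_panel_joint_tagging(
            panel,
            causal,
            r2_threshold=config.jt_r2_threshold,
            max_removal_fraction=config.jt_max_removal_fraction,
            seed=seed + 23,
        )

    y = pheno.y
    splits = split_samples(list(observed.sample_ids), config.split_ratios, seed + 31)

    gwas = pgs_baseline.run_gwas(observed, y, subset=splits["train"])
    sample_pos = {s: i for i, s in enumerate(observed.sample_ids)}
    val_y = y[[sample_pos[s] for s in splits["validation"]]]
    weights = pgs_baseline.fit_pgs_weights(
        gwas,
        observed,
        method="blockwise_ridge",
        hyper={"train_ids": splits["train"], "window_kb": config.ridge_window_kb},
        validation=(splits["validation"], val_y),
    )
    scores = pgs_baseline.score_pgs(observed, weights)

    test_rows = [sample_pos[s] for s in splits["test"]]
    y_test = y[test_rows]
    base_pred = scores[test_rows]
    r2_base = eval_stats.r_squared(y_test, base_pred)
    p_base = eval_stats.prediction_p_value(y_test, base_pred)

    snp_subset = None
    weighting = config.mitigation == "snp_dosage_weighting"
    if config.mitigation == "clump_distance":
        kept = pgs_baseline.ld_clump(gwas, observed)
        meta = observed.snps.set_index("snp_id")
        kept_df = pd.DataFrame(
            {
                "snp_id": kept,
                "chrom": [str(meta.at[s, "chrom"]) for s in kept],
                "pos": [int(meta.at[s, "pos"]) for s in kept],
                "p_value": [
                    float(gwas.table.set_index("snp_id").at[s, "p_value"]) for s in kept
                ],
            }
        )
        snp_subset = pgs_baseline.distance_filter(kept_df)

    inputs = build_design_matrix(
        observed,
        weights=weights if weighting else None,
        weighting_enabled=weighting,
        train_ids=splits["train"],
        snp_subset=snp_subset,
    )

    result = {"r2_baseline": r2_base, "p_baseline": p_base, "seed": seed}
    for nonlinear in (True, False):
        net = _train_pair(inputs, y, splits, config, nonlinear, seed + 41)
        pred = predict(net, inputs)[test_rows]
        key = "nonlinear" if nonlinear else "linear"
        result[f"r2_{key}"] = eval_stats.r_squared(y_test, pred)
        result[f"p_{key}"] = eval_stats.prediction_p_value(y_test, pred)
        result[f"best_epoch_{key}"] = net.best_epoch
    return result


def run_scenario(config: ScenarioConfig) -> eval_stats.ScenarioResult:
    """Run all replicates of a scenario and aggregate the comparison."""
    config.validate()
    reps = []
    failures = 0
    for r in range(config.replicates):
        try:
            rep = run_replicate(config, r)
            reps.append(rep)
            logger.info(
                "replicate %d: r2 base=%.4f lin=%.4f nl=%.4f",
                r, rep["r2_baseline"], rep["r2_linear"], rep["r2_nonlinear"],
            )
        except Exception:  # noqa: BLE001 - replicate isolation
            failures += 1
            logger.exception("replicate %d failed", r)
            if failures > config.replicates / 2:
                raise RuntimeError(
                    f"{failures} of {config.replicates} replicates failed"
                )
    result = eval_stats.ScenarioResult(
        scenario=config.scenario,
        epistasis_percent=config.epistasis_percent,
        additive_percent=100.0 - config.epistasis_percent,
        joint_tagging=config.joint_tagging,
        mitigation=config.mitigation,
        r2_nonlinear=[r["r2_nonlinear"] for r in reps],
        r2_linear=[r["r2_linear"] for r in reps],
        r2_baseline=[r["r2_baseline"] for r in reps],
        p_nonlinear=[r["p_nonlinear"] for r in reps],
        p_linear=[r["p_linear"] for r in reps],
        p_baseline=[r["p_baseline"] for r in reps],
        replicate_seeds=[r["seed"] for r in reps],
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = {"config_hash": config.config_hash(), "config": config.to_dict()}
        (out / "config.json").write_text(json.dumps(stamp, indent=2))
        pd.DataFrame(reps).to_csv(out / "replicates.tsv", sep="\t", index=False)
        pd.DataFrame([result.to_row()]).to_csv(out / "summary.tsv", sep="\t", index=False)
    return result


# ---------------------------------------------------------------------------
# Real-data workflow
# ---------------------------------------------------------------------------

def run_real_data(
    raw_path: str,
    metadata_path: str,
    phenotype_path: str,
    scoring_path: str,
    covariates_path: Optional[str] = None,
    config: Optional[ScenarioConfig] = None,
    sd_limit: float = 4.0,
    alpha: float = 0.05,
    apply_qc: bool = True,
) -> pd.DataFrame:
    """User-supplied genotypes through the full evaluation path.

    Applies the 4-SD continuous-trait outlier filter, scores the supplied
    PGS, fits the PGS(+retained covariates) regression baseline, trains
    linear and nonlinear networks on SNP-only and (when covariates are
    given) SNP+Cov inputs, and returns one row of baseline-relative
    metrics per (phenotype, input set).  Binary phenotypes (all values in
    {0,1}) use the logistic baseline and 50:50 oversampling.
    """
    config = config or desk_scale_config()
    panel = read_raw(raw_path, metadata_path)
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in pheno.columns:
        raise ValueError("phenotype TSV needs a sample_id column")
    pheno = pheno.set_index("sample_id")
    missing = set(panel.sample_ids) ^ set(pheno.index)
    if missing:
        raise ValueError(
            f"sample ids differ between genotypes ({panel.n_samples}) and "
            f"phenotypes ({len(pheno)}): {len(missing)} unmatched"
        )
    pheno = pheno.loc[panel.sample_ids]

    covariates = None
    if covariates_path is not None:
        cov_df = pd.read_csv(covariates_path, sep="\t", dtype={"sample_id": str})
        cov_df = cov_df.set_index("sample_id").loc[panel.sample_ids]
        types = {}
        for col in cov_df.columns:
            vals = cov_df[col].dropna()
            if vals.map(lambda v: isinstance(v, str)).any():
                types[col] = "factor"
            elif set(pd.unique(vals)) <= {0, 1, 0.0, 1.0}:
                types[col] = "binary"
            else:
                types[col] = "numeric"
        covariates = CovariateTable(cov_df, types)

    weights = pgs_baseline.parse_scoring_file(scoring_path)
    rows = []
    for trait in pheno.columns:
        y_all = pheno[trait].to_numpy(dtype=float)
        binary = set(np.unique(y_all[~np.isnan(y_all)])) <= {0.0, 1.0}
        keep = ~np.isnan(y_all)
        if not binary:
            keep &= filter_phenotype_outliers(
                np.where(np.isnan(y_all), np.nanmean(y_all), y_all), sd_limit
            )
        kept_ids = [s for s, k in zip(panel.sample_ids, keep) if k]
        sub_panel = panel.subset_samples(kept_ids)
        y = y_all[keep]
        sub_cov = covariates.aligned_to(kept_ids) if covariates is not None else None

        scores = pgs_baseline.score_pgs(sub_panel, weights)
        splits = split_samples(kept_ids, config.split_ratios, config.base_seed + 97)
        pos = {s: i for i, s in enumerate(kept_ids)}
        test_rows = [pos[s] for s in splits["test"]]
        train_rows = [pos[s] for s in splits["train"]]
        y_test = y[test_rows]

        input_sets: dict[str, Optional[CovariateTable]] = {"SNP": None}
        retained_cov: Optional[CovariateTable] = None
        if sub_cov is not None:
            family = "logistic" if binary else "linear"
            baseline = pgs_baseline.fit_covariate_baseline(
                scores[train_rows],
                sub_cov.aligned_to(splits["train"]),
                y[train_rows],
                splits["train"],
                family=family,
                alpha=alpha,
            )
            retained_raw = [
                name
                for name in sub_cov.column_types
                if any(c == name or c.startswith(f"{name}_") for c in baseline.retained_covariates)
            ]
            if retained_raw:
                retained_cov = CovariateTable(
                    sub_cov.data[retained_raw],
                    {k: sub_cov.column_types[k] for k in retained_raw},
                )
            pred_base = baseline.predict(scores, retained_cov, kept_ids)[test_rows]
            r2_base_cov = eval_stats.r_squared(y_test, pred_base)
            p_base_cov = eval_stats.prediction_p_value(y_test, pred_base)
            input_sets["SNP+Cov"] = retained_cov

        base_score_pred = scores[test_rows]
        r2_base_snp = eval_stats.r_squared(y_test, base_score_pred)
        p_base_snp = eval_stats.prediction_p_value(y_test, base_score_pred)

        for set_name, cov_for_input in input_sets.items():
            inputs = build_design_matrix(
                sub_panel,
                weights=weights,
                covariates=cov_for_input,
                pgs_scores=scores,
                weighting_enabled=True,
                train_ids=splits["train"],
            )
            r2s, ps = {}, {}
            for nonlinear in (True, False):
                nn_over = dict(config.nn_overrides)
                nn_over.update({"binary": binary, "oversample_binary": binary})
                sub_config = dataclasses.replace(config, nn_overrides=nn_over)
                net = _train_pair(
                    inputs, y, splits, sub_config, nonlinear, config.base_seed + 137
                )
                pred = predict(net, inputs)[test_rows]
                key = "nonlinear" if nonlinear else "linear"
                r2s[key] = eval_stats.r_squared(y_test, pred)
                ps[key] = eval_stats.prediction_p_value(y_test, pred)
            r2_base = r2_base_snp if set_name == "SNP" else r2_base_cov
            p_base = p_base_snp if set_name == "SNP" else p_base_cov
            rel = eval_stats.relative_metrics(r2s["nonlinear"], r2s["linear"], max(r2_base, 1e-12))
            rows.append(
                {
                    "phenotype": trait,
                    "input_set": set_name,
                    "binary": binary,
                    "r2_nonlinear": r2s["nonlinear"],
                    "r2_linear": r2s["linear"],
                    "r2_baseline": r2_base,
                    "p_nonlinear": ps["nonlinear"],
                    "p_linear": ps["linear"],
                    "p_baseline": p_base,
                    "fraction_of_baseline": rel["fraction_of_baseline_nl"],
                    "fraction_of_baseline_lin": rel["fraction_of_baseline_lin"],
                    "gap_percent": rel["gap_percent"],
                }
            )

    results = pd.DataFrame(rows)
    if apply_qc and len(results) > 1:
        results = eval_stats.qc_filter(results, alpha=alpha)
    return results
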