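"""Quantitative-trait simulation with additive, epistatic and environmental terms.

Phenotypes are composed as

    Y = G + E + G'xE' + G'xG' + E'xE' + eps

where G is an additive genetic term over standardized causal dosages,
G'xG' is a sum of 4-way products of standardized dosages (the canonical
multiplicative form of higher-order statistical epistasis; lower-order
interactions are statistically detectable within it), E collects
environmental main effects, and the primed cross terms are products of
standardized genetic and environmental variables.  The genetic component
is rescaled so that var(G)/var(Y) hits a target heritability, with i.i.d.
Gaussian noise supplying the remainder.

Also provides phenotype blending for mixed additive/epistatic
architectures, a liability-threshold binarizer, deterministic
train/validation/test splitting, and the single-pass 4-SD outlier filter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_sim import GenotypePanel

__all__ = [
    "TraitArchitecture",
    "PhenotypeSet",
    "CovariateTable",
    "CovariateSpec",
    "EnvEffect",
    "draw_architecture",
    "simulate_phenotype",
    "blend_phenotypes",
    "simulate_covariates",
    "binarize_liability",
    "split_samples",
    "filter_phenotype_outliers",
]

COMPONENT_NAMES = ("G_additive", "G_epistatic", "E_main", "GxE", "ExE", "noise")

SCENARIOS = ("additive", "epistatic", "mixed", "with_environment")


@dataclass
class EnvEffect:
    """One environmental contribution to the trait.

    kind 'main'  : weight x standardized covariate
    kind 'gxe'   : weight x standardized causal dosage x standardized covariate
    kind 'exe'   : weight x product of two standardized covariates
    """

    kind: str
    weight: float
    covariates: tuple[str, ...]
    snp_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("main", "gxe", "exe"):
            raise ValueError(f"unknown env effect kind {self.kind!r}")
        if self.kind == "gxe" and self.snp_id is None:
            raise ValueError("gxe effect requires a snp_id")
        if self.kind == "exe" and len(self.covariates) != 2:
            raise ValueError("exe effect requires exactly two covariates")


@dataclass
class TraitArchitecture:
    """Causal structure of a simulated trait."""

    scenario: str
    causal_ids: list[str]
    additive_weights: np.ndarray
    interaction_groups: list[tuple[str, str, str, str]]
    interaction_weights: np.ndarray
    target_h2: float
    env_spec: list[EnvEffect] = field(default_factory=list)
    mix_ratio: Optional[tuple[int, int]] = None
    epistasis_form: str = "dosage_product"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.epistasis_form not in ("dosage_product", "standardized_product"):
            raise ValueError(f"unknown epistasis form {self.epistasis_form!r}")
        if not 0.0 < self.target_h2 <= 1.0:
            raise ValueError("target_h2 must be in (0, 1]")
        flat = [s for g in self.interaction_groups for s in g]
        if len(set(flat)) != len(flat):
            raise ValueError("interaction groups must be disjoint")
        if any(len(g) != 4 for g in self.interaction_groups):
            raise ValueError("interaction groups must be 4-tuples")
        if not set(flat) <= set(self.causal_ids):
            raise ValueError("interaction groups must draw from causal_ids")

    def to_json(self) -> str:
        return json.dumps(
            {
                "scenario": self.scenario,
                "causal_ids": self.causal_ids,
                "additive_weights": list(map(float, self.additive_weights)),
                "interaction_groups": [list(g) for g in self.interaction_groups],
                "interaction_weights": list(map(float, self.interaction_weights)),
                "target_h2": self.target_h2,
                "mix_ratio": self.mix_ratio,
                "epistasis_form": self.epistasis_form,
                "seed": self.seed,
            }
        )


@dataclass
class PhenotypeSet:
    """Continuous phenotype with its named variance components.

    Invariant: y is the element-wise sum of the component vectors.
    """

    sample_ids: list[str]
    y: np.ndarray
    components: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        total = sum(self.components[name] for name in COMPONENT_NAMES)
        if not np.allclose(self.y, total, atol=1e-10):
            raise ValueError("y does not equal the sum of its components")

    @classmethod
    def from_components(cls, sample_ids: list[str], components: dict[str, np.ndarray]) -> "PhenotypeSet":
        n = len(sample_ids)
        full = {name: components.get(name, np.zeros(n)) for name in COMPONENT_NAMES}
        y = sum(full[name] for name in COMPONENT_NAMES)
        return cls(sample_ids, y, full)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "y": self.y})
        for name in COMPONENT_NAMES:
            df[name] = self.components[name]
        return df


@dataclass
class CovariateTable:
    """Sample-aligned covariates typed as numeric, binary or factor."""

    data: pd.DataFrame  # indexed by sample_id
    column_types: dict[str, str]  # name -> numeric | binary | factor

    def __post_init__(self) -> None:
        for name, kind in self.column_types.items():
            if kind not in ("numeric", "binary", "factor"):
                raise ValueError(f"column {name}: unknown type {kind!r}")
            if name not in self.data.columns:
                raise ValueError(f"typed column {name} missing from data")
            if kind == "factor":
                if self.data[name].dropna().nunique() < 2:
                    raise ValueError(f"factor column {name} has < 2 observed levels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def aligned_to(self, sample_ids: list[str]) -> "CovariateTable":
        return CovariateTable(self.data.loc[sample_ids], dict(self.column_types))


@dataclass(frozen=True)
class CovariateSpec:
    """Shape of a synthetic covariate table."""

    n_numeric: int = 3
    n_binary: int = 1
    factor_levels: tuple[int, ...] = (4,)
    missing_rate: float = 0.0
    binary_p: float = 0.5


def draw_architecture(
    panel: GenotypePanel,
    scenario: str,
    n_causal: int,
    target_h2: float,
    seed: int,
    env_spec: Optional[list[EnvEffect]] = None,
    epistasis_form: str = "dosage_product",
) -> TraitArchitecture:
    """Sample a causal architecture from the panel.

    Causal SNPs are drawn uniformly without replacement; additive weights
    are i.i.d. standard normal (total genetic variance is rescaled later).
    Under the epistatic scenario the causal set is partitioned into
    disjoint 4-tuples with i.i.d. standard-normal group weights.

    ``epistasis_form`` chooses the interaction term: centered products of
    raw {0,1,2} dosages (default; such a trait shows GWAS-visible
    additive signal, matching how epistatic variance projects onto
    additive models) or products of standardized dosages (zero additive
    projection under HWE and linkage equilibrium).
    """
    if n_causal > panel.n_snps:
        raise ValueError(f"n_causal={n_causal} exceeds panel size {panel.n_snps}")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    causal = list(rng.choice(panel.snp_ids, size=n_causal, replace=False))

    groups: list[tuple[str, str, str, str]] = []
    group_w = np.zeros(0)
    add_w = np.zeros(n_causal)
    if scenario == "epistatic":
        if n_causal % 4 != 0:
            raise ValueError("epistatic scenario requires n_causal divisible by 4")
        perm = rng.permutation(n_causal)
        groups = [
            tuple(causal[k] for k in perm[i : i + 4]) for i in range(0, n_causal, 4)
        ]
        group_w = rng.standard_normal(len(groups))
    else:
        add_w = rng.standard_normal(n_causal)

    return TraitArchitecture(
        scenario=scenario,
        causal_ids=causal,
        additive_weights=add_w,
        interaction_groups=groups,
        interaction_weights=group_w,
        target_h2=target_h2,
        env_spec=list(env_spec or []),
        epistasis_form=epistasis_form,
        seed=seed,
    )


def _standardized_causal(panel: GenotypePanel, causal_ids: list[str]) -> np.ndarray:
    cols = [panel.snp_index(c) for c in causal_ids]
    x = panel.dosages[:, cols].astype(float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [causal_ids[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"causal SNPs monomorphic in panel: {bad}")
    return (x - x.mean(axis=0)) / sd


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def simulate_phenotype(
    panel: GenotypePanel,
    arch: TraitArchitecture,
    covariates: Optional[CovariateTable] = None,
) -> PhenotypeSet:
    """Realize a phenotype under the composition model.

    The combined genetic signal (additive + epistatic) is rescaled so its
    empirical variance equals ``target_h2`` of the total phenotypic
    variance; environmental terms retain the variance implied by their
    weights; i.i.d. Gaussian noise fills the gap so that
    var(G)/var(Y) = target_h2 in expectation.  Components are stored
    separately and always sum to y.
    """
    n = panel.n_samples
    z = _standardized_causal(panel, arch.causal_ids)
    causal_pos = {c: j for j, c in enumerate(arch.causal_ids)}

    g_add = z @ arch.additive_weights if len(arch.causal_ids) else np.zeros(n)
    g_epi = np.zeros(n)
    if arch.interaction_groups:
        if arch.epistasis_form == "standardized_product":
            basis = z
        else:
            cols = [panel.snp_index(c) for c in arch.causal_ids]
            basis = panel.dosages[:, cols].astype(float)
        for w, group in zip(arch.interaction_weights, arch.interaction_groups):
            prod = np.ones(n)
            for snp in group:
                prod = prod * basis[:, causal_pos[snp]]
            g_epi += w * (prod - prod.mean())  # centered so components stay mean-zero

    genetic = g_add + g_epi
    var_g = genetic.var()
    if var_g == 0:
        raise ValueError("architecture produced zero genetic variance")

    # scale genetic variance to target_h2 on a var(Y)=1 scale
    scale = np.sqrt(arch.target_h2 / var_g)
    g_add *= scale
    g_epi *= scale

    e_main = np.zeros(n)
    gxe = np.zeros(n)
    exe = np.zeros(n)
    if arch.env_spec:
        if covariates is None:
            raise ValueError("architecture has env effects but no covariates supplied")
        cov = covariates.aligned_to(panel.sample_ids)
        z_cov = {
            name: _standardize(cov.data[name].to_numpy(dtype=float))
            for eff in arch.env_spec
            for name in eff.covariates
        }
        for eff in arch.env_spec:
            if eff.kind == "main":
                e_main += eff.weight * z_cov[eff.covariates[0]]
            elif eff.kind == "gxe":
                gxe += eff.weight * z[:, causal_pos[eff.snp_id]] * z_cov[eff.covariates[0]]
            else:
                exe += eff.weight * z_cov[eff.covariates[0]] * z_cov[eff.covariates[1]]

    # noise fills the gap to unit total variance, so var(G)/var(Y) ~ target_h2
    explained = g_add + g_epi + e_main + gxe + exe
    noise_var = max(1.0 - float(explained.var()), 0.0)
    if explained.var() > 1.0 + 1e-9:
        warnings.warn(
            "environmental variance pushes explained variance above 1; "
            "realized var(G)/var(Y) will fall below target_h2"
        )
    rng = np.random.default_rng(arch.seed + 1_000_003)
    noise = (
        rng.standard_normal(n) * np.sqrt(noise_var) if noise_var > 0 else np.zeros(n)
    )

    return PhenotypeSet.from_components(
        list(panel.sample_ids),
        {
            "G_additive": g_add,
            "G_epistatic": g_epi,
            "E_main": e_main,
            "GxE": gxe,
            "ExE": exe,
            "noise": noise,
        },
    )


def blend_phenotypes(
    p_add: PhenotypeSet, p_epi: PhenotypeSet, ratio: tuple[float, float]
) -> PhenotypeSet:
    """Mix two phenotypes in the given parts ratio.

    Both inputs are standardized to unit variance first, then combined as
    y = (a*y1 + b*y2) / (a + b); component vectors are carried through
    with the same scaling so the component-sum identity is preserved.
    """
    if p_add.sample_ids != p_epi.sample_ids:
        raise ValueError("blend requires identical sample ids in identical order")
    a, b = ratio
    if a < 0 or b < 0 or a + b == 0:
        raise ValueError("ratio parts must be non-negative and not both zero")

    def scaled(p: PhenotypeSet, part: float) -> dict[str, np.ndarray]:
        sd = p.y.std()
        if sd == 0:
            raise ValueError("cannot blend a zero-variance phenotype")
        mu = p.y.mean()
        f = part / (a + b) / sd
        comps = {name: p.components[name] * f for name in COMPONENT_NAMES}
        # remove the mean through the noise slot so components still sum to y
        comps["noise"] = comps["noise"] - mu * f
        return comps

    c1 = scaled(p_add, a)
    c2 = scaled(p_epi, b)
    merged = {name: c1[name] + c2[name] for name in COMPONENT_NAMES}
    return PhenotypeSet.from_components(list(p_add.sample_ids), merged)


def simulate_covariates(
    n_samples: int, spec: CovariateSpec, seed: int, sample_ids: Optional[list[str]] = None
) -> CovariateTable:
    """Synthetic covariate table with numeric, binary and factor columns."""
    if any(k < 2 for k in spec.factor_levels):
        raise ValueError("factor columns need >= 2 levels")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"sample{i:06d}" for i in range(n_samples)]
    cols: dict[str, object] = {}
    types: dict[str, str] = {}
    for i in range(spec.n_numeric):
        cols[f"num{i}"] = rng.standard_normal(n_samples)
        types[f"num{i}"] = "numeric"
    for i in range(spec.n_binary):
        cols[f"bin{i}"] = rng.binomial(1, spec.binary_p, n_samples).astype(float)
        types[f"bin{i}"] = "binary"
    for i, k in enumerate(spec.factor_levels):
        cols[f"fac{i}"] = pd.Categorical.from_codes(
            rng.integers(0, k, n_samples), categories=[f"L{j}" for j in range(k)]
        )
        types[f"fac{i}"] = "factor"
    df = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    if spec.missing_rate > 0:
        mask = rng.random((n_samples, df.shape[1])) < spec.missing_rate
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    return CovariateTable(df, types)


def binarize_liability(p: PhenotypeSet, prevalence: float) -> np.ndarray:
    """Case/control labels by thresholding the continuous trait.

    Cases are the samples whose y exceeds the (1 - prevalence) empirical
    quantile, so exactly round(prevalence * n) samples are cases.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    y = p.y
    if y.std() == 0:
        raise ValueError("cannot binarize a zero-variance phenotype")
    n_cases = int(round(prevalence * len(y)))
    order = np.argsort(y, kind="stable")
    labels = np.zeros(len(y), dtype=int)
    if n_cases > 0:
        labels[order[-n_cases:]] = 1
    return labels


def split_samples(
    sample_ids: list[str], ratios: tuple[float, float, float] = (6, 2, 2), seed: int = 0
) -> dict[str, list[str]]:
    """Disjoint, exhaustive train/validation/test partition by seeded shuffle."""
    if len(sample_ids) < 3:
        raise ValueError("need at least 3 samples to split")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    total = sum(ratios)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sample_ids))
    n = len(sample_ids)
    n_train = int(round(n * ratios[0] / total))
    n_val = int(round(n * ratios[1] / total))
    n_val = min(n_val, n - n_train - 1)  # keep test non-empty
    ids = np.asarray(sample_ids, dtype=object)[perm]
    return {
        "train": list(ids[:n_train]),
        "validation": list(ids[n_train : n_train + n_val]),
        "test": list(ids[n_train + n_val :]),
    }


def filter_phenotype_outliers(y: np.ndarray, sd_limit: float = 4.0) -> np.ndarray:
    """Retention mask: False where |y - mean| > sd_limit * sd.

    Mean and SD are computed once, on all values, before any removal.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 values")
    sd = y.std()
    if sd == 0:
        warnings.warn("zero-variance phenotype: retaining all samples")
        return np.ones(len(y), dtype=bool)
    return np.abs(y - y.mean()) <= sd_limit * sd
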