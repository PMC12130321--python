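"""Additive comparators: GWAS, LD clumping, shrinkage PGS and regression baselines.

This module produces everything the nonlinear models are compared
against: a per-SNP association scan, greedy LD clumping and distance
filtering (the brute-force joint-tagging mitigation), an LD-aware
shrinkage PGS built by windowed ridge regression on summary statistics
(the package's additive baseline; a deliberately simple stand-in for
Bayesian shrinkage methods, stamped into the weight-set provenance),
PLINK-style scoring, PGS-Catalog-format scoring-file I/O, and the
PGS + covariates regression baseline with p < 0.05 covariate retention.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .genotype_sim import GenotypePanel
from .phenotype_sim import CovariateTable

__all__ = [
    "GwasSummary",
    "PgsWeightSet",
    "BaselineModel",
    "run_gwas",
    "ld_clump",
    "distance_filter",
    "fit_pgs_weights",
    "score_pgs",
    "parse_scoring_file",
    "write_scoring_file",
    "fit_covariate_baseline",
]

SCORING_COLUMNS = [
    "rsID",
    "chr_name",
    "chr_position",
    "effect_allele",
    "other_allele",
    "effect_weight",
]


@dataclass
class GwasSummary:
    """Per-SNP marginal association results.

    ``table`` has one row per SNP tested: snp_id, effect_allele, beta,
    se, p_value, n_used.  SNPs monomorphic in the analysis subset carry
    NaN statistics and are excluded by downstream consumers.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "effect_allele", "beta", "se", "p_value", "n_used"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GwasSummary missing columns: {sorted(missing)}")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id rows in GWAS summary")
        ok = self.table["p_value"].dropna()
        if ((ok <= 0) | (ok > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def valid(self) -> pd.DataFrame:
        return self.table[self.table["beta"].notna()]


@dataclass
class PgsWeightSet:
    """Per-allele score weights, the in-memory image of a scoring file."""

    table: pd.DataFrame  # snp_id, effect_allele, other_allele, weight (+ chrom/pos)
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        required = {"snp_id", "effect_allele", "other_allele", "weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"PgsWeightSet missing columns: {sorted(missing)}")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_ids in weight set")
        if not np.isfinite(self.table["weight"].to_numpy(dtype=float)).all():
            raise ValueError("weights must be finite")

    def weight_of(self, snp_id: str) -> float:
        row = self.table[self.table["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        return float(row["weight"].iloc[0])


@dataclass
class BaselineModel:
    """PGS(+covariates) regression baseline after covariate screening."""

    family: str  # linear | logistic
    intercept: float
    pgs_coefficient: float
    covariate_coefficients: dict[str, float]
    retained_covariates: list[str]
    alpha: float
    r2: float  # in-family fit diagnostic on the fitting set
    model_p_value: float
    _result: object = field(default=None, repr=False)
    _design_columns: list[str] = field(default_factory=list, repr=False)

    def predict(self, pgs_scores: np.ndarray, covariates: Optional[CovariateTable], sample_ids: list[str]) -> np.ndarray:
        X = _baseline_design(pgs_scores, covariates, sample_ids, self.retained_covariates)
        X = X.reindex(columns=self._design_columns, fill_value=0.0)
        return np.asarray(self._result.predict(sm.add_constant(X, has_constant="add")))


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def run_gwas(
    panel: GenotypePanel, y: np.ndarray, subset: Optional[list[str]] = None
) -> GwasSummary:
    """Marginal scan: per SNP, simple linear regression of y on dosage.

    Closed-form simple regression with intercept, vectorized over SNPs:
    beta = Sxy/Sxx, se^2 = RSS/(n-2)/Sxx, two-sided p from t(n-2).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != panel.n_samples:
        raise ValueError("phenotype length does not match panel")
    if subset is not None:
        rows = panel.sample_rows(subset)
        X = panel.dosages[rows].astype(float)
        yy = y[rows]
    else:
        X = panel.dosages.astype(float)
        yy = y
    n = len(yy)
    if n < 3:
        raise ValueError("need at least 3 samples for a GWAS")

    xc = X - X.mean(axis=0)
    yc = yy - yy.mean()
    sxx = (xc**2).sum(axis=0)
    sxy = xc.T @ yc
    syy = float((yc**2).sum())

    mono = sxx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, np.nan, sxy / np.where(mono, 1.0, sxx))
        rss = syy - beta * sxy
        rss = np.clip(rss, 0.0, None)
        se = np.sqrt(rss / (n - 2) / np.where(mono, 1.0, sxx))
        se = np.where(mono | (se == 0), np.where(mono, np.nan, np.finfo(float).tiny), se)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p = np.where(np.isnan(beta), np.nan, p)

    table = pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "effect_allele": panel.snps["effect_allele"].to_numpy(),
            "beta": beta,
            "se": np.where(np.isnan(beta), np.nan, se),
            "p_value": p,
            "n_used": n,
        }
    )
    if mono.any():
        warnings.warn(f"{int(mono.sum())} SNPs monomorphic in GWAS subset; flagged NaN")
    return GwasSummary(table)


def write_gwas_summary(gwas: GwasSummary, path: str) -> None:
    out = gwas.table.rename(
        columns={"effect_allele": "a1", "p_value": "p", "n_used": "n"}
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clumping and distance filtering
# ---------------------------------------------------------------------------

def ld_clump(
    gwas: GwasSummary,
    panel: GenotypePanel,
    r2_threshold: float = 0.5,
    window_kb: int = 500,
) -> list[str]:
    """Greedy LD clumping: keep index SNPs, discard tagged neighbours.

    Repeatedly takes the lowest-p unassigned SNP as an index and assigns
    to it every unassigned SNP on the same chromosome within ``window_kb``
    whose dosage r^2 with the index exceeds ``r2_threshold``.  Equal
    p-values are broken by (position, snp_id) so output is deterministic.
    """
    valid = gwas.valid
    missing = [s for s in valid["snp_id"] if s not in panel._index]
    if missing:
        raise KeyError(f"GWAS SNPs absent from panel: {missing[:5]}")

    meta = panel.snps.set_index("snp_id")
    # visit order: ascending p, ties by (position, snp_id)
    v = valid.assign(
        pos=[int(meta.at[s, "pos"]) for s in valid["snp_id"]],
        chrom=[str(meta.at[s, "chrom"]) for s in valid["snp_id"]],
    ).sort_values(["p_value", "pos", "snp_id"], kind="stable")

    window_bp = window_kb * 1000
    std = {}  # standardized dosage cache

    def zcol(s: str) -> np.ndarray:
        if s not in std:
            x = panel.column(s).astype(float)
            std[s] = (x - x.mean()) / x.std()
        return std[s]

    assigned: set[str] = set()
    kept: list[str] = []
    records = list(v.itertuples())
    n = panel.n_samples
    for rec in records:
        if rec.snp_id in assigned:
            continue
        kept.append(rec.snp_id)
        assigned.add(rec.snp_id)
        zi = zcol(rec.snp_id)
        for other in records:
            if other.snp_id in assigned or other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > window_bp:
                continue
            r = float(zi @ zcol(other.snp_id)) / n
            if r * r > r2_threshold:
                assigned.add(other.snp_id)
    return kept


def distance_filter(
    snps: pd.DataFrame, min_kb: int = 500
) -> list[str]:
    """Greedy distance filter: no two kept SNPs closer than ``min_kb``.

    ``snps`` needs columns snp_id, chrom, pos, p_value.  SNPs are visited
    by ascending p (ties by position then id); a SNP is kept iff no
    already-kept SNP on its chromosome lies within ``min_kb``.
    """
    required = {"snp_id", "chrom", "pos", "p_value"}
    if missing := required - set(snps.columns):
        raise ValueError(f"distance_filter missing columns: {sorted(missing)}")
    v = snps.sort_values(["p_value", "pos", "snp_id"], kind="stable")
    min_bp = min_kb * 1000
    kept_pos: dict[str, list[int]] = {}
    kept: list[str] = []
    for rec in v.itertuples():
        positions = kept_pos.setdefault(str(rec.chrom), [])
        if all(abs(rec.pos - p) >= min_bp for p in positions):
            kept.append(rec.snp_id)
            positions.append(int(rec.pos))
    return kept


# ---------------------------------------------------------------------------
# Shrinkage PGS
# ---------------------------------------------------------------------------

DEFAULT_LAMBDA_GRID = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)


def _windows_by_position(snps: pd.DataFrame, window_kb: int) -> list[np.ndarray]:
    """Contiguous per-chromosome windows of at most ``window_kb``."""
    out = []
    window_bp = window_kb * 1000
    for _, chrom_df in snps.groupby("chrom", sort=False):
        start = None
        idx: list[int] = []
        for i, pos in zip(chrom_df.index, chrom_df["pos"]):
            if start is None or pos - start > window_bp:
                if idx:
                    out.append(np.array(idx))
                idx = []
                start = pos
            idx.append(i)
        if idx:
            out.append(np.array(idx))
    return out


def fit_pgs_weights(
    gwas: GwasSummary,
    panel: GenotypePanel,
    method: str = "blockwise_ridge",
    hyper: Optional[dict] = None,
    validation: Optional[tuple[list[str], np.ndarray]] = None,
) -> PgsWeightSet:
    """Turn marginal GWAS effects into an LD-aware per-allele weight set.

    ``blockwise_ridge`` solves w = (R + lambda I)^-1 r within contiguous
    genomic windows, where R is the training-sample dosage correlation
    matrix and r the vector of marginal phenotype-dosage correlations;
    lambda is chosen over a small grid by validation-set score r^2 when a
    ``validation`` (sample_ids, y) pair is given.  Standardized weights
    are mapped back to per-allele scale by dividing by the dosage SD.

    ``clump_threshold`` instead keeps marginal betas for clump index SNPs
    only, zeroing everything else.
    """
    hyper = dict(hyper or {})
    valid = gwas.valid
    meta = panel.snps.set_index("snp_id")

    if method == "clump_threshold":
        kept = ld_clump(
            gwas,
            panel,
            r2_threshold=hyper.get("r2_threshold", 0.5),
            window_kb=hyper.get("window_kb", 500),
        )
        keep = set(kept)
        tab = valid[valid["snp_id"].isin(keep)].copy()
        table = pd.DataFrame(
            {
                "snp_id": tab["snp_id"].to_numpy(),
                "effect_allele": tab["effect_allele"].to_numpy(),
                "other_allele": [meta.at[s, "other_allele"] for s in tab["snp_id"]],
                "weight": tab["beta"].to_numpy(dtype=float),
                "chrom": [str(meta.at[s, "chrom"]) for s in tab["snp_id"]],
                "pos": [int(meta.at[s, "pos"]) for s in tab["snp_id"]],
            }
        )
        return PgsWeightSet(table, provenance="clump_threshold marginal betas")

    if method != "blockwise_ridge":
        raise ValueError(f"unknown PGS method {method!r}")

    lambda_grid = tuple(hyper.get("lambda_grid", DEFAULT_LAMBDA_GRID))
    window_kb = hyper.get("window_kb", 250)
    train_ids = hyper.get("train_ids")

    snp_ids = list(valid["snp_id"])
    cols = np.array([panel.snp_index(s) for s in snp_ids])
    if train_ids is not None:
        rows = panel.sample_rows(train_ids)
        X = panel.dosages[np.ix_(rows, cols)].astype(float)
    else:
        X = panel.dosages[:, cols].astype(float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("monomorphic SNP reached ridge fit")
    Z = (X - X.mean(axis=0)) / sd
    n = Z.shape[0]

    # marginal correlations from the GWAS betas: r_j = beta_j * sd_j / sd_y.
    # sd_y cancels in r^2-based tuning, so work on the beta*sd scale.
    r_marg = valid["beta"].to_numpy(dtype=float) * sd

    local = valid.reset_index(drop=True).assign(
        chrom=[str(meta.at[s, "chrom"]) for s in snp_ids],
        pos=[int(meta.at[s, "pos"]) for s in snp_ids],
    )
    windows = _windows_by_position(local, window_kb)

    def solve(lmbda: float) -> np.ndarray:
        w = np.zeros(len(snp_ids))
        for idx in windows:
            Rw = Z[:, idx].T @ Z[:, idx] / n
            lam = lmbda
            for _ in range(6):
                try:
                    w[idx] = np.linalg.solve(Rw + lam * np.eye(len(idx)), r_marg[idx])
                    break
                except np.linalg.LinAlgError:
                    lam *= 10.0  # singular window despite ridge: escalate
            else:
                raise np.linalg.LinAlgError("window remained singular")
        return w

    if validation is not None and len(lambda_grid) > 1:
        val_ids, val_y = validation
        vrows = panel.sample_rows(val_ids)
        Xv = panel.dosages[np.ix_(vrows, cols)].astype(float)
        best, best_r2 = None, -np.inf
        for lam in lambda_grid:
            w_std = solve(lam)
            scores = Xv @ (w_std / sd)
            if scores.std() == 0 or np.asarray(val_y).std() == 0:
                r2 = 0.0
            else:
                r2 = float(np.corrcoef(scores, val_y)[0, 1] ** 2)
            if r2 > best_r2:
                best, best_r2, best_lam = w_std, r2, lam
        w_std = best
        chosen = best_lam
    else:
        chosen = lambda_grid[0]
        w_std = solve(chosen)

    table = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": valid["effect_allele"].to_numpy(),
            "other_allele": [meta.at[s, "other_allele"] for s in snp_ids],
            "weight": w_std / sd,
            "chrom": [str(meta.at[s, "chrom"]) for s in snp_ids],
            "pos": [int(meta.at[s, "pos"]) for s in snp_ids],
        }
    )
    return PgsWeightSet(
        table, provenance=f"blockwise_ridge(lambda={chosen}, window_kb={window_kb})"
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def aligned_weight_vector(
    panel: GenotypePanel, weights: PgsWeightSet
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-panel-SNP (weight, flip flag) aligned by snp_id and effect allele.

    Returns (w, flipped, matched_ids): w[j] is the weight applied to panel
    column j (0 when unmatched); flipped[j] marks SNPs whose scoring-file
    effect allele is the panel's other allele, which score as
    w * (2 - dosage).
    """
    w = np.zeros(panel.n_snps)
    flipped = np.zeros(panel.n_snps, dtype=bool)
    matched: list[str] = []
    meta = panel.snps
    by_id = {r.snp_id: r for r in weights.table.itertuples()}
    for j, row in enumerate(meta.itertuples()):
        rec = by_id.get(row.snp_id)
        if rec is None:
            continue
        if rec.effect_allele == row.effect_allele:
            w[j] = rec.weight
        elif rec.effect_allele == row.other_allele:
            w[j] = rec.weight
            flipped[j] = True
        else:
            continue  # allele mismatch: unmatched
        matched.append(row.snp_id)
    return w, flipped, matched


def score_pgs(panel: GenotypePanel, weights: PgsWeightSet) -> np.ndarray:
    """Polygenic score: sum over matched SNPs of weight x effect-allele dosage.

    Sum mode (PLINK --score with 'sum'); with complete hard calls this
    differs from allele-averaging only by a constant factor, which cancels
    in every r^2-based metric.  Swapped-allele entries contribute
    weight x (2 - dosage).
    """
    w, flipped, matched = aligned_weight_vector(panel, weights)
    if not matched:
        raise ValueError("no scoring-file SNP matched the panel")
    if len(matched) < len(weights.table):
        unmatched = sorted(set(weights.table["snp_id"]) - set(matched))
        warnings.warn(
            f"{len(unmatched)} scoring-file SNPs unmatched (e.g. {unmatched[:5]})"
        )
    D = panel.dosages.astype(float)
    eff = np.where(flipped, 2.0 - D, D)
    return eff @ w


# ---------------------------------------------------------------------------
# Scoring-file I/O (PGS Catalog flavour)
# ---------------------------------------------------------------------------

def write_scoring_file(weights: PgsWeightSet, path: str) -> None:
    """Serialize to the tab-separated PGS-Catalog scoring layout."""
    t = weights.table
    out = pd.DataFrame(
        {
            "rsID": t["snp_id"],
            "chr_name": t["chrom"] if "chrom" in t else "NA",
            "chr_position": t["pos"] if "pos" in t else 0,
            "effect_allele": t["effect_allele"],
            "other_allele": t["other_allele"],
            "effect_weight": t["weight"].map(lambda v: repr(float(v))),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# provenance={weights.provenance}\n")
        out.to_csv(fh, sep="\t", index=False)


def parse_scoring_file(source: str) -> PgsWeightSet:
    """Parse a PGS-Catalog-style scoring file (path or literal text).

    Requires tab-separated content with a variant id column (rsID) or
    chr_name + chr_position, an effect_allele column and an
    effect_weight column; '#'-prefixed metadata lines are skipped.
    """
    if "\n" in source or "\t" in source:
        handle: object = io.StringIO(source)
        text_lines = source.splitlines()
    else:
        handle = source
        with open(source) as fh:
            text_lines = fh.read().splitlines()

    provenance = "scoring file"
    for line in text_lines:
        if line.startswith("#") and "provenance=" in line:
            provenance = line.split("provenance=", 1)[1].strip()

    df = pd.read_csv(
        handle, sep="\t", comment="#", dtype={"chr_name": str},
        float_precision="round_trip",
    )
    if "rsID" not in df.columns and not {"chr_name", "chr_position"} <= set(df.columns):
        raise ValueError("scoring file needs an rsID or chr_name+chr_position columns")
    missing = [c for c in ("effect_allele", "effect_weight") if c not in df.columns]
    if missing:
        raise ValueError(f"scoring file missing required columns: {missing}")

    weights = pd.to_numeric(df["effect_weight"], errors="coerce")
    if weights.isna().any():
        bad = int(df.index[weights.isna()][0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"non-numeric effect_weight near line {bad}")

    snp_id = df["rsID"] if "rsID" in df.columns else (
        df["chr_name"].astype(str) + ":" + df["chr_position"].astype(str)
    )
    table = pd.DataFrame(
        {
            "snp_id": snp_id.astype(str),
            "effect_allele": df["effect_allele"].astype(str),
            "other_allele": df.get("other_allele", pd.Series(["N"] * len(df))).astype(str),
            "weight": weights.to_numpy(dtype=float),
        }
    )
    if "chr_name" in df.columns:
        table["chrom"] = df["chr_name"].astype(str)
    if "chr_position" in df.columns:
        table["pos"] = df["chr_position"].astype(int)
    return PgsWeightSet(table, provenance=provenance)


# ---------------------------------------------------------------------------
# Covariate baseline
# ---------------------------------------------------------------------------

def _expand_covariates(cov: CovariateTable) -> pd.DataFrame:
    """Numeric design block: factors dummy-coded (reference level dropped),
    numeric/binary passed through with mean imputation for missing values."""
    pieces = []
    for name, kind in cov.column_types.items():
        col = cov.data[name]
        if kind == "factor":
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            pieces.append(dummies.fillna(0.0))
        else:
            x = pd.to_numeric(col, errors="coerce")
            pieces.append(x.fillna(x.mean()).to_frame(name).astype(float))
    return pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=cov.data.index)


def _baseline_design(
    pgs_scores: np.ndarray,
    covariates: Optional[CovariateTable],
    sample_ids: list[str],
    covariate_names: Optional[list[str]] = None,
) -> pd.DataFrame:
    X = pd.DataFrame({"PGS": np.asarray(pgs_scores, dtype=float)}, index=sample_ids)
    if covariates is not None:
        expanded = _expand_covariates(covariates.aligned_to(sample_ids))
        expanded.index = X.index
        if covariate_names is not None:
            expanded = expanded[[c for c in expanded.columns if c in covariate_names]]
        X = pd.concat([X, expanded], axis=1)
    return X


def fit_covariate_baseline(
    pgs_scores: np.ndarray,
    covariates: Optional[CovariateTable],
    y: np.ndarray,
    sample_ids: list[str],
    family: str = "linear",
    alpha: float = 0.05,
) -> BaselineModel:
    """Two-stage PGS + covariates baseline with p < alpha covariate retention.

    Stage 1 regresses y on PGS plus every expanded covariate column;
    stage 2 refits keeping the PGS plus only those covariate columns
    whose stage-1 coefficient had a valid p-value below ``alpha``.  The
    retained list is what the matching network input builder reuses.
    """
    if family not in ("linear", "logistic"):
        raise ValueError("family must be 'linear' or 'logistic'")
    y = np.asarray(y, dtype=float)
    X_full = _baseline_design(pgs_scores, covariates, sample_ids)

    # drop degenerate columns up front
    degenerate = [c for c in X_full.columns if X_full[c].std() == 0 and c != "PGS"]
    if degenerate:
        warnings.warn(f"dropping constant covariate columns: {degenerate}")
        X_full = X_full.drop(columns=degenerate)

    def fit(X: pd.DataFrame):
        Xc = sm.add_constant(X, has_constant="add")
        if family == "linear":
            return sm.OLS(y, Xc).fit()
        return sm.Logit(y, Xc).fit(disp=0, maxiter=200)

    full = fit(X_full)
    retained = [
        c
        for c in X_full.columns
        if c != "PGS" and np.isfinite(full.pvalues.get(c, np.nan)) and full.pvalues[c] < alpha
    ]
    X_final = X_full[["PGS"] + retained]
    final = fit(X_final)

    if family == "linear":
        r2 = float(final.rsquared)
        model_p = float(final.f_pvalue) if np.isfinite(final.f_pvalue) else 1.0
    else:
        r2 = float(final.prsquared)
        model_p = float(final.llr_pvalue)

    coefs = {c: float(final.params[c]) for c in retained}
    return BaselineModel(
        family=family,
        intercept=float(final.params["const"]),
        pgs_coefficient=float(final.params["PGS"]),
        covariate_coefficients=coefs,
        retained_covariates=retained,
        alpha=alpha,
        r2=r2,
        model_p_value=model_p,
        _result=final,
        _design_columns=list(X_final.columns),
    )
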