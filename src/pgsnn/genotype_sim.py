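"""Diploid genotype panels with block LD structure.

Generates hard-call dosage matrices ({0,1,2} effect-allele counts) under
Hardy-Weinberg equilibrium using a latent-Gaussian (copula) scheme: within
each LD block, haplotypes are drawn from an equicorrelated multivariate
normal and thresholded at the quantile implied by each SNP's minor allele
frequency, so the block correlation parameter directly controls tagging
strength between neighbouring SNPs.  Also provides the "joint tagging"
panel reduction: causal SNPs that are redundantly tagged by other panel
SNPs are randomly dropped from the observed panel, recreating the situation
where a causal signal is missing but inferable from variants in LD with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SnpRecord",
    "LdBlockSpec",
    "GenotypePanel",
    "ReducedPanelReport",
    "simulate_genotypes",
    "pairwise_r2",
    "reduce_panel_joint_tagging",
    "write_raw",
    "write_snp_metadata",
    "write_bim",
    "read_raw",
]

SNP_METADATA_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "maf"]


@dataclass(frozen=True)
class SnpRecord:
    """Identity and frequency metadata for one biallelic SNP."""

    snp_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class LdBlockSpec:
    """Parameters of the synthetic block-LD genotype generator.

    SNPs are laid out in consecutive blocks of ``block_size``; within a
    block the latent haplotype Gaussians share pairwise correlation
    ``within_block_rho``, and blocks are mutually independent.  Positions
    advance by ``bp_spacing`` base pairs and every ``blocks_per_chrom``
    blocks a new chromosome label starts, so distance-based filters have
    something real to act on.
    """

    n_snps: int
    block_size: int = 5
    within_block_rho: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    bp_spacing: int = 5_000
    blocks_per_chrom: int = 50

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ValueError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.bp_spacing < 1 or self.blocks_per_chrom < 1:
            raise ValueError("bp_spacing and blocks_per_chrom must be >= 1")


@dataclass
class GenotypePanel:
    """Hard-call dosage matrix plus per-SNP metadata.

    ``dosages`` is samples x SNPs with entries in {0, 1, 2} counting
    effect alleles; ``snps`` is a DataFrame with one row per column of
    the matrix (columns: snp_id, chrom, pos, effect_allele, other_allele,
    maf).
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("snp_ids must be unique")
        self._index = {s: j for j, s in enumerate(self.snps["snp_id"])}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    def subset_samples(self, sample_ids: list[str]) -> "GenotypePanel":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [pos[s] for s in sample_ids]
        return GenotypePanel(list(sample_ids), self.snps.copy(), self.dosages[rows])

    def sample_rows(self, sample_ids: list[str]) -> np.ndarray:
        """Row indices of the given sample ids, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def drop_snps(self, snp_ids: list[str]) -> "GenotypePanel":
        drop = set(snp_ids)
        keep = [j for j, s in enumerate(self.snps["snp_id"]) if s not in drop]
        return GenotypePanel(
            list(self.sample_ids),
            self.snps.iloc[keep].reset_index(drop=True),
            self.dosages[:, keep],
        )


@dataclass
class ReducedPanelReport:
    """Audit trail of a joint-tagging panel reduction.

    For every removed causal SNP, ``tags`` records the (snp_id, r^2)
    pairs that justified its eligibility (each with r^2 above the
    threshold used).
    """

    removed_snp_ids: list[str]
    tags: dict[str, list[tuple[str, float]]]
    eligible_count: int
    r2_threshold: float
    max_removal_fraction: float
    removal_seed: int

    def validate(self) -> None:
        for snp in self.removed_snp_ids:
            recorded = self.tags.get(snp, [])
            if len(recorded) < 2:
                raise AssertionError(f"removed SNP {snp} has fewer than 2 recorded tags")
            if any(r2 <= self.r2_threshold for _, r2 in recorded):
                raise AssertionError(f"removed SNP {snp} has a tag at or below threshold")
        cap = self.max_removal_fraction * self.eligible_count
        if len(self.removed_snp_ids) > cap + 1e-9:
            raise AssertionError(
                f"removed {len(self.removed_snp_ids)} SNPs, exceeding "
                f"{self.max_removal_fraction:.0%} of {self.eligible_count} eligible"
            )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_MAX_MONOMORPHIC_RETRIES = 8


def _draw_block_haplotypes(
    rng: np.random.Generator, n_samples: int, width: int, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two latent haplotype Gaussians per sample for one LD block.

    Equicorrelated MVN via the one-factor construction
    z = sqrt(rho) * u + sqrt(1 - rho) * e, exact for rho in [0, 1).
    """
    out = []
    for _ in range(2):  # two haplotypes per diploid sample
        shared = rng.standard_normal((n_samples, 1))
        noise = rng.standard_normal((n_samples, width))
        out.append(np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise)
    return out[0], out[1]


def simulate_genotypes(n_samples: int, spec: LdBlockSpec, seed: int) -> GenotypePanel:
    """Simulate a hard-call diploid genotype panel with block LD.

    Per block, two haploid latent vectors per sample are drawn from an
    equicorrelated Gaussian; each coordinate is thresholded at the normal
    quantile of its SNP's MAF (allele present iff latent < quantile) and
    the two haplotype indicators are summed to a dosage in {0, 1, 2}.
    Marginally each SNP is in HWE at its MAF; within-block correlation of
    the latents induces dosage LD.  Monomorphic columns (possible at small
    n) trigger a bounded block redraw with resampled MAFs.

    Same (n_samples, spec, seed) always yields a bit-identical panel.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = spec.maf_range

    n_blocks = int(np.ceil(spec.n_snps / spec.block_size))
    dosage_cols: list[np.ndarray] = []
    mafs_all: list[np.ndarray] = []
    for b in range(n_blocks):
        width = min(spec.block_size, spec.n_snps - b * spec.block_size)
        mafs = rng.uniform(lo, hi, size=width)
        for attempt in range(_MAX_MONOMORPHIC_RETRIES + 1):
            h1, h2 = _draw_block_haplotypes(rng, n_samples, width, spec.within_block_rho)
            thresh = norm.ppf(mafs)
            block = (h1 < thresh).astype(np.int8) + (h2 < thresh).astype(np.int8)
            mono = np.array([len(np.unique(block[:, j])) < 2 for j in range(width)])
            if not mono.any():
                break
            if attempt == _MAX_MONOMORPHIC_RETRIES:
                raise RuntimeError(
                    f"block {b}: monomorphic SNP persists after "
                    f"{_MAX_MONOMORPHIC_RETRIES} MAF resamples; "
                    "increase n_samples or the lower MAF bound"
                )
            # resample frequency of the offending SNPs, biased away from rare
            mafs = np.where(mono, rng.uniform(max(lo, 0.1), hi, size=width), mafs)
        dosage_cols.append(block)
        mafs_all.append(mafs)

    dosages = np.concatenate(dosage_cols, axis=1)
    mafs_flat = np.concatenate(mafs_all)

    records = []
    for j in range(spec.n_snps):
        block_idx = j // spec.block_size
        chrom_idx = block_idx // spec.blocks_per_chrom
        within = j - chrom_idx * spec.blocks_per_chrom * spec.block_size
        records.append(
            {
                "snp_id": f"snp{j:06d}",
                "chrom": str(chrom_idx + 1),
                "pos": (within + 1) * spec.bp_spacing,
                "effect_allele": "A",
                "other_allele": "G",
                "maf": float(mafs_flat[j]),
            }
        )
    snps = pd.DataFrame.from_records(records, columns=SNP_METADATA_COLUMNS)
    sample_ids = [f"sample{i:06d}" for i in range(n_samples)]
    return GenotypePanel(sample_ids, snps, dosages)


def pairwise_r2(panel: GenotypePanel, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation between two dosage columns."""
    a = panel.column(snp_a).astype(float)
    b = panel.column(snp_b).astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("pairwise_r2 undefined for a monomorphic column")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(dosages: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray) -> np.ndarray:
    """r^2 between every column in cols_a and every column in cols_b."""
    xa = dosages[:, cols_a].astype(float)
    xb = dosages[:, cols_b].astype(float)
    xa = (xa - xa.mean(axis=0)) / xa.std(axis=0)
    xb = (xb - xb.mean(axis=0)) / xb.std(axis=0)
    r = xa.T @ xb / dosages.shape[0]
    return r**2


def reduce_panel_joint_tagging(
    panel: GenotypePanel,
    causal_ids: list[str],
    r2_threshold: float = 0.25,
    max_removal_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypePanel, ReducedPanelReport]:
    """Remove redundantly tagged causal SNPs from the observed panel.

    A causal SNP is eligible when at least two *other* panel SNPs tag it
    with r^2 above ``r2_threshold``.  Each eligible SNP is independently
    removed with probability ``max_removal_fraction`` ("up to" that
    fraction in expectation); draws exceeding the hard cap
    floor(fraction x eligible) are randomly truncated so the cap always
    holds.  Effects attached to removed SNPs are untouched — only the
    observed panel shrinks, which is what creates the joint-tagging
    confound downstream.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    if not 0.0 < max_removal_fraction <= 1.0:
        raise ValueError("max_removal_fraction must be in (0, 1]")
    missing = [c for c in causal_ids if c not in panel._index]
    if missing:
        raise KeyError(f"causal ids absent from panel: {missing}")

    causal_cols = np.array([panel.snp_index(c) for c in causal_ids], dtype=int)
    all_cols = np.arange(panel.n_snps)
    r2 = _r2_matrix(panel.dosages, causal_cols, all_cols)

    eligible: list[str] = []
    tags: dict[str, list[tuple[str, float]]] = {}
    ids = panel.snp_ids
    for i, causal in enumerate(causal_ids):
        row = r2[i].copy()
        row[causal_cols[i]] = 0.0  # a SNP does not tag itself
        hits = np.nonzero(row > r2_threshold)[0]
        if len(hits) >= 2:
            eligible.append(causal)
            tags[causal] = [(ids[j], float(row[j])) for j in hits]

    rng = np.random.default_rng(seed)
    drawn = [s for s in eligible if rng.random() < max_removal_fraction]
    cap = int(np.floor(max_removal_fraction * len(eligible)))
    if len(drawn) > cap:
        drawn = list(rng.choice(drawn, size=cap, replace=False))
    removed = sorted(drawn, key=panel.snp_index)

    report = ReducedPanelReport(
        removed_snp_ids=removed,
        tags={s: tags[s] for s in removed},
        eligible_count=len(eligible),
        r2_threshold=r2_threshold,
        max_removal_fraction=max_removal_fraction,
        removal_seed=seed,
    )
    report.validate()
    return panel.drop_snps(removed), report


# ---------------------------------------------------------------------------
# I/O: PLINK-style text formats
# ---------------------------------------------------------------------------

def write_raw(panel: GenotypePanel, path: str) -> None:
    """Write additive dosages as a PLINK .raw-style whitespace table.

    Header is ``FID IID <snp_id>_<effect_allele> ...``; FID == IID.
    """
    header = ["FID", "IID"] + [
        f"{s}_{a}" for s, a in zip(panel.snps["snp_id"], panel.snps["effect_allele"])
    ]
    with open(path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        for sid, row in zip(panel.sample_ids, panel.dosages):
            fh.write(sid + " " + sid + " " + " ".join(str(int(d)) for d in row) + "\n")


def write_snp_metadata(panel: GenotypePanel, path: str) -> None:
    """Write the per-SNP metadata TSV paired with a .raw dosage file."""
    df = panel.snps[SNP_METADATA_COLUMNS].rename(
        columns={"effect_allele": "a1", "other_allele": "a2"}
    )
    df.to_csv(path, sep="\t", index=False)


def write_bim(panel: GenotypePanel, path: str) -> None:
    """Write a PLINK .bim-compatible variant file (cM column zeroed)."""
    with open(path, "w") as fh:
        for _, s in panel.snps.iterrows():
            fh.write(
                f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\t{s.effect_allele}\t{s.other_allele}\n"
            )


def read_raw(raw_path: str, metadata_path: str) -> GenotypePanel:
    """Read a .raw-style dosage table plus its SNP metadata TSV."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"chrom": str})
    meta = meta.rename(columns={"a1": "effect_allele", "a2": "other_allele"})
    raw = pd.read_csv(raw_path, sep=r"\s+")
    snp_cols = [c for c in raw.columns if c not in ("FID", "IID")]
    expected = [
        f"{s}_{a}" for s, a in zip(meta["snp_id"], meta["effect_allele"])
    ]
    if snp_cols != expected:
        raise ValueError("dosage columns do not match SNP metadata")
    dosages = raw[snp_cols].to_numpy(dtype=np.int8)
    return GenotypePanel(list(raw["IID"].astype(str)), meta[SNP_METADATA_COLUMNS], dosages)
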