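import numpy as np
import pytest

from pgsnn import LdBlockSpec, simulate_genotypes


@pytest.fixture(scope="session")
def small_panel():
    """500 samples x 24 SNPs in blocks of 4 with moderate LD."""
    spec = LdBlockSpec(
        n_snps=24, block_size=4, within_block_rho=0.7, maf_range=(0.2, 0.5),
        blocks_per_chrom=3,
    )
    return simulate_genotypes(500, spec, seed=11)


@pytest.fixture(scope="session")
def ld_free_panel():
    """2,000 samples x 40 independent SNPs (no LD)."""
    spec = LdBlockSpec(n_snps=40, block_size=1, within_block_rho=0.0, maf_range=(0.2, 0.5))
    return simulate_genotypes(2_000, spec, seed=7)


def brute_force_clump(records, r2_table, r2_threshold, window_bp):
    """Independent greedy-clump oracle over an explicit r^2 lookup table.

    ``records``: list of (snp_id, chrom, pos, p_value).  Pure-python
    O(n^2) loops, ordered by (p, pos, id).
    """
    order = sorted(records, key=lambda r: (r[3], r[2], r[0]))
    assigned = set()
    kept = []
    for sid, chrom, pos, _p in order:
        if sid in assigned:
            continue
        kept.append(sid)
        assigned.add(sid)
        for oid, ochrom, opos, _op in order:
            if oid in assigned or ochrom != chrom:
                continue
            if abs(opos - pos) <= window_bp and r2_table[(sid, oid)] > r2_threshold:
                assigned.add(oid)
    return kept


def brute_force_distance_filter(records, min_bp):
    """Independent greedy distance-filter oracle (pure-python loops)."""
    order = sorted(records, key=lambda r: (r[3], r[2], r[0]))
    kept = []
    for sid, chrom, pos, _p in order:
        if all(k[1] != chrom or abs(k[2] - pos) >= min_bp for k in kept):
            kept.append((sid, chrom, pos))
    return [k[0] for k in kept]
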