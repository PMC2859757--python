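import numpy as np
import pytest

from lode.panel import GenotypeMatrix, SnpRecord
from lode.simulate import SimConfig, simulate_panel


def grid_search_r2(table, step=1e-4):
    """Brute-force maximum-likelihood r² for one 3x3 genotype table.

    Exhaustive grid over the single free haplotype frequency (the marginal
    allele frequencies of the ML solution equal the observed ones), kept
    deliberately independent of the EM implementation.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    idx = np.arange(3.0)
    pA = (t * idx[:, None]).sum() / (2 * n)
    pB = (t * idx[None, :]).sum() / (2 * n)
    lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)
    f = np.arange(lo, hi + step / 2, step)
    fAb, faB, fab = pA - f, pB - f, 1 - pA - pB + f
    P = np.zeros((len(f), 3, 3))
    P[:, 2, 2] = f**2
    P[:, 2, 1] = 2 * f * fAb
    P[:, 2, 0] = fAb**2
    P[:, 1, 2] = 2 * f * faB
    P[:, 1, 1] = 2 * (f * fab + fAb * faB)
    P[:, 1, 0] = 2 * fAb * fab
    P[:, 0, 2] = faB**2
    P[:, 0, 1] = 2 * faB * fab
    P[:, 0, 0] = fab**2
    ll = np.where(t[None] > 0, t[None] * np.log(np.maximum(P, 1e-300)), 0.0).sum(axis=(1, 2))
    fbest = f[np.argmax(ll)]
    d = fbest - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    return float(d * d / denom)


def random_tables(n_tables, rng, max_n=100):
    """Random 3x3 genotype tables, both loci polymorphic."""
    out = []
    while len(out) < n_tables:
        n = int(rng.integers(5, max_n + 1))
        t = rng.multinomial(n, rng.dirichlet(np.ones(9))).reshape(3, 3)
        idx = np.arange(3.0)
        pA = (t * idx[:, None]).sum() / (2 * n)
        pB = (t * idx[None, :]).sum() / (2 * n)
        if 0 < pA < 1 and 0 < pB < 1:
            out.append(t)
    return out


def tiny_panel(columns, chroms=None, positions=None, samples=None, missing=None):
    """Build a small panel from explicit dosage columns for hand-check tests."""
    dosage = np.array(columns, dtype=np.int8).T
    n, m = dosage.shape
    chroms = chroms or ["1"] * m
    positions = positions or list(range(1000, 1000 + 1000 * m, 1000))
    snps = [
        SnpRecord(snp_id=f"s{j}", status="mapped", chromosome=chroms[j], position_bp=positions[j])
        for j in range(m)
    ]
    return GenotypeMatrix(
        samples or [f"i{i}" for i in range(n)], snps, dosage, missing=missing
    )


@pytest.fixture(scope="session")
def default_panel():
    """The default simulated study panel, shared across tests."""
    return simulate_panel(SimConfig(seed=20_260_928))


@pytest.fixture(scope="session")
def default_audit(default_panel):
    """Every-10th masked-repositioning audit of the default panel."""
    from lode.qc import make_plan, run_audit

    matrix, _, _ = default_panel
    plan = make_plan([r for r in matrix.snps if r.is_mapped], scheme="every_kth", k=10)
    return run_audit(matrix, plan)
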