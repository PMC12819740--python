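import pytest

from tescope.simulate import SimulationConfig, generate_dataset, plant_ad_scenario

SMALL_CELL_TYPES = (
    ("ASC", (10, 20)),
    ("EX", (30, 50)),
    ("INH", (8, 16)),
    ("MG", (6, 12)),
    ("ODC", (35, 60)),
    ("OPC", (6, 12)),
    ("PER.END", (3, 8)),
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11, n_genes=250, n_te_loci=150, cell_types=SMALL_CELL_TYPES
    )


@pytest.fixture(scope="session")
def null_bundle(small_config):
    """Small bundle with no planted effects."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def planted_bundle(small_config):
    """Small bundle with the AD-scenario direction structure planted."""
    cfg = plant_ad_scenario(small_config, 24)
    return generate_dataset(cfg)


# ---------------------------------------------------------------------------
# independent oracles (brute force / enumeration), kept free of package code
# ---------------------------------------------------------------------------

def brute_force_pairs(te_intervals, gene_intervals, window):
    """O(n*m) scan: (te_idx, gene_idx, gap) for every pair with gap <= window."""
    out = []
    for i, (tc, ts, te) in enumerate(te_intervals):
        for j, (gc, gs, ge) in enumerate(gene_intervals):
            if tc != gc:
                continue
            gap = max(gs - te, ts - ge, 0)
            if gap <= window:
                out.append((i, j, gap))
    return out


def binom_two_sided_exact(k, n, p):
    """Minlike two-sided binomial p by full enumeration."""
    from math import comb

    pmf = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    obs = pmf[k]
    return sum(q for q in pmf if q <= obs * (1 + 1e-9))


def hypergeom_sf_exact(k, M, n, N):
    """P(X >= k) for hypergeometric(M, n, N) by tail summation."""
    from math import comb

    total = comb(M, N)
    return sum(
        comb(n, i) * comb(M - n, N - i)
        for i in range(max(k, max(0, N - (M - n))), min(n, N) + 1)
    ) / total


def fisher_two_sided_exact(table):
    """Minlike two-sided Fisher p by exhaustive hypergeometric enumeration."""
    from math import comb

    (a, b), (c, d) = table
    row1, col1, total = a + b, a + c, a + b + c + d
    denom = comb(total, row1)

    def prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > total - row1:
            return 0.0
        return comb(col1, x) * comb(total - col1, row1 - x) / denom

    obs = prob(a)
    return sum(
        p for x in range(row1 + 1) if (p := prob(x)) and p <= obs * (1 + 1e-9)
    )
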