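import numpy as np
import pandas as pd
import pytest

import scdr


@pytest.fixture(scope="session")
def toy():
    """Hand-checkable miniature cohort with closed-form expected values."""
    return scdr.make_toy_fixture()


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default-condition synthetic bulk cohort with planted truth."""
    cfg = scdr.SimulationConfig(seed=123)
    expr, responses, truth = scdr.simulate_bulk_cohort(cfg)
    return cfg, expr, responses, truth


@pytest.fixture()
def small_counts():
    """10-cell raw count matrix with 2 planted QC-failing cells.

    Cells c8 and c9 detect only 2 genes each (threshold 5); gene GLOW is
    detected only in those two cells so it dies in the gene pass.
    """
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(20)] + ["MT-1", "GLOW"]
    cells = [f"c{i}" for i in range(10)]
    counts = rng.poisson(5.0, size=(22, 10)).astype(float) + 1.0
    counts[:, 8] = 0.0
    counts[:, 9] = 0.0
    counts[0, 8] = 3.0  # c8 detects G0 and GLOW only
    counts[0, 9] = 2.0  # c9 detects G0 and GLOW only
    counts[21, :] = 0.0
    counts[21, 8] = 1.0
    counts[21, 9] = 4.0
    return scdr.ExpressionMatrix(genes, cells, counts)


def exact_rank_sum_p(r, s):
    """One-sided rank-sum p (H1: r > s) by full permutation enumeration."""
    from itertools import combinations

    r, s = list(map(float, r)), list(map(float, s))
    pooled = r + s
    n_r = len(r)
    obs = sum(sorted(pooled).index(v) + 1 for v in r)  # ranks, no ties assumed
    count = total = 0
    ranks = range(1, len(pooled) + 1)
    for combo in combinations(ranks, n_r):
        total += 1
        if sum(combo) >= obs:
            count += 1
    return count / total


def brute_force_drs(expr_values, gene_ids, signature_entries):
    """Naive triple-loop score computation used as an independent oracle."""
    n_genes, n_samples = expr_values.shape
    means = [sum(expr_values[i]) / n_samples for i in range(n_genes)]
    sds = [
        (sum((v - means[i]) ** 2 for v in expr_values[i]) / (n_samples - 1)) ** 0.5
        for i in range(n_genes)
    ]
    lut = {g: i for i, g in enumerate(gene_ids) if sds[i] > 0}
    present = [(g, fc) for g, fc in signature_entries if g in lut]
    q = len(present)
    out = []
    for m in range(n_samples):
        total = 0.0
        for g, fc in present:
            i = lut[g]
            total += fc * (expr_values[i, m] - means[i]) / sds[i]
        out.append(total / q)
    return np.array(out), q


def brute_force_cindex(auc, pred):
    """Classical concordance index by explicit pair counting."""
    lines = sorted(auc)
    num = den = 0.0
    for a in range(len(lines)):
        for b in range(a + 1, len(lines)):
            la, lb = lines[a], lines[b]
            if auc[la] == auc[lb]:
                continue
            den += 1.0
            d_pred = pred[la] - pred[lb]
            if d_pred == 0:
                num += 0.5
            elif (d_pred > 0) == (auc[la] > auc[lb]):
                num += 1.0
    return num / den
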