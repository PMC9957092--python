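"""Statistical validation of drug-response predictions.

Three layers:

* **Separation tests** — per drug, a one-sided Wilcoxon rank-sum test of
  whether resistant samples score higher than sensitive ones; p < alpha
  counts as an accurate prediction, and accuracy over a drug panel is the
  fraction of accurate drugs.
* **Cross-validation** — k-fold CV (default threefold) in which resistant
  and sensitive lines are split separately, signatures are re-derived on the
  training lines only, held-out scores are rescaled to [0,1] within each
  test, and each fold of each permutation contributes one separation test.
* **Concordance** — a weighted probabilistic concordance index (WPCI)
  between true AUC values and predicted scores, where each cell-line pair is
  weighted by the probability that its observed AUC ordering is real under
  Gaussian measurement noise; used to compare scoring methods pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SampleGrouping
from .scoring import DRSMatrix, score_samples, zscore_transform
from .signatures import ResponseLabels, derive_signature

__all__ = [
    "SeparationResult",
    "CVReport",
    "WPCIResult",
    "MethodComparison",
    "wilcoxon_separation",
    "accuracy_over_drugs",
    "min_max_rescale",
    "cross_validate",
    "wpci",
    "compare_methods",
    "group_drs_comparison",
]

# Largest per-group size for which the rank-sum null distribution is
# enumerated exactly (ties force the normal approximation regardless).
_EXACT_MAX_GROUP = 8


@dataclass
class SeparationResult:
    """One-sided rank-sum outcome for a single drug."""

    drug: str
    n_resistant: int
    n_sensitive: int
    statistic: float
    p_value: float
    accurate: bool
    alpha: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class CVReport:
    """Aggregate of all fold × permutation separation tests for one drug."""

    drug: str
    n_tests: int
    per_test: list[tuple[int, int, float]]  # (fold_id, permutation_id, p)
    accuracy_fraction: float
    n_invalid: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_fraction <= 1.0:
            raise ValueError("accuracy_fraction outside [0, 1]")


@dataclass
class WPCIResult:
    drug: str
    wpci: float
    n_pairs_weighted: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.wpci <= 1 + 1e-12:
            raise ValueError(f"WPCI {self.wpci} outside [0, 1]")
        self.wpci = float(min(max(self.wpci, 0.0), 1.0))


@dataclass
class MethodComparison:
    per_drug: pd.DataFrame  # index drug, columns wpci_a, wpci_b
    n_a_higher: int
    fraction_a_higher: float
    p_value: float  # one-sided signed-rank, H1: A > B


def wilcoxon_separation(
    scores_r,
    scores_s,
    alpha: float = 0.05,
    drug: str = "",
    alternative: str = "greater",
) -> SeparationResult:
    """One-sided Wilcoxon rank-sum test (H1: resistant > sensitive).

    The null distribution is enumerated exactly when both groups have at
    most 8 members and there are no ties; otherwise the normal approximation
    with tie and continuity corrections is used.  ``accurate`` is
    ``p < alpha``.
    """
    r = np.asarray(list(scores_r), dtype=float)
    s = np.asarray(list(scores_s), dtype=float)
    if r.size == 0 or s.size == 0:
        raise ValueError("both score groups must be nonempty")
    combined = np.concatenate([r, s])
    has_ties = np.unique(combined).size < combined.size
    method = (
        "exact"
        if not has_ties and max(r.size, s.size) <= _EXACT_MAX_GROUP
        else "asymptotic"
    )
    res = stats.mannwhitneyu(r, s, alternative=alternative, method=method)
    p = float(res.pvalue)
    return SeparationResult(
        drug=drug,
        n_resistant=int(r.size),
        n_sensitive=int(s.size),
        statistic=float(res.statistic),
        p_value=p,
        accurate=bool(p < alpha),
        alpha=alpha,
    )


def accuracy_over_drugs(results: list[SeparationResult]) -> float:
    """Fraction of drugs whose separation test was called accurate."""
    if not results:
        raise ValueError("no separation results supplied")
    return sum(r.accurate for r in results) / len(results)


def min_max_rescale(values) -> np.ndarray:
    """Map values linearly onto [0,1]; a constant vector maps to all 0.5."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values to rescale")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def _split_groups(items: list[str], folds: int, rng: np.random.Generator) -> list[list[str]]:
    shuffled = list(items)
    rng.shuffle(shuffled)
    return [list(part) for part in np.array_split(shuffled, folds)]


def cross_validate(
    expr: ExpressionMatrix,
    labels: ResponseLabels,
    folds: int = 3,
    permutations: int = 100,
    seed: int = 0,
    n_top: int = 200,
    pseudocount: float = 0.01,
    alpha: float = 0.05,
) -> CVReport:
    """K-fold cross-validation of signature-based separation for one drug.

    Per permutation, resistant and sensitive lines are shuffled and split
    separately into ``folds`` near-equal groups; fold *f* pairs the *f*-th
    resistant group with the *f*-th sensitive group as the held-out test
    set.  The signature is re-derived on the training lines only, test
    scores are rescaled to [0,1] within the test set, and a one-sided
    rank-sum test (resistant > sensitive) is run on the rescaled scores.
    Tests whose training split loses a whole class are excluded from the
    denominator and counted in ``n_invalid``.
    """
    sample_set = set(expr.sample_ids)
    r_lines = sorted(labels.resistant & sample_set)
    s_lines = sorted(labels.sensitive & sample_set)
    if len(r_lines) < folds or len(s_lines) < folds:
        raise ValueError(
            f"drug {labels.drug!r}: need >= {folds} lines per class for "
            f"{folds}-fold CV (R={len(r_lines)}, S={len(s_lines)})"
        )
    rng = np.random.default_rng(seed)
    per_test: list[tuple[int, int, float]] = []
    n_accurate = 0
    n_invalid = 0
    for perm in range(permutations):
        r_groups = _split_groups(r_lines, folds, rng)
        s_groups = _split_groups(s_lines, folds, rng)
        for fold in range(folds):
            test_r, test_s = r_groups[fold], s_groups[fold]
            train_r = [l for g in r_groups if g is not r_groups[fold] for l in g]
            train_s = [l for g in s_groups if g is not s_groups[fold] for l in g]
            if not train_r or not train_s or not test_r or not test_s:
                n_invalid += 1
                continue
            train_expr = expr.subset(samples=train_r + train_s)
            try:
                sig = derive_signature(
                    train_expr, labels, n_top=n_top, pseudocount=pseudocount
                )
                test_expr = expr.subset(samples=test_r + test_s)
                z = zscore_transform(test_expr)
                scores, _ = score_samples(z, sig)
            except ValueError:
                n_invalid += 1
                continue
            rescaled = min_max_rescale(scores)
            by_sample = dict(zip(z.sample_ids, rescaled))
            result = wilcoxon_separation(
                [by_sample[l] for l in test_r],
                [by_sample[l] for l in test_s],
                alpha=alpha,
                drug=labels.drug,
            )
            per_test.append((fold, perm, result.p_value))
            n_accurate += result.accurate
    n_tests = len(per_test)
    if n_tests == 0:
        raise ValueError(f"drug {labels.drug!r}: every CV test was invalid")
    return CVReport(
        drug=labels.drug,
        n_tests=n_tests,
        per_test=per_test,
        accuracy_fraction=n_accurate / n_tests,
        n_invalid=n_invalid,
    )


def wpci(
    true_auc: dict[str, float],
    predicted: dict[str, float],
    noise_sd: float | None = None,
    drug: str = "",
    unit_weights: bool = False,
) -> WPCIResult:
    """Weighted probabilistic concordance index between AUCs and predictions.

    Over all unordered pairs of shared cell lines with unequal AUC, a pair
    contributes weight w = Φ(|ΔAUC| / (noise_sd·√2)) — the probability that
    the observed AUC ordering is the true one when each AUC carries Gaussian
    measurement noise with standard deviation ``noise_sd`` — and concordance
    credit 1 if the predictions order the pair as the AUCs do, 0.5 on a
    prediction tie, 0 otherwise.  ``noise_sd`` defaults to 0.1 × the sample
    sd of the shared AUC values.  With ``unit_weights`` every pair gets
    weight 1 and the statistic reduces to the classical concordance index.
    """
    shared = sorted(set(true_auc) & set(predicted))
    if len(shared) < 2:
        raise ValueError("need >= 2 shared cell lines")
    auc = np.array([true_auc[l] for l in shared], dtype=float)
    pred = np.array([predicted[l] for l in shared], dtype=float)
    if np.unique(auc).size < 2:
        raise ValueError("need >= 2 distinct AUC values")
    if noise_sd is None:
        noise_sd = 0.1 * float(np.std(auc, ddof=1))
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    i, j = np.triu_indices(len(shared), k=1)
    d_auc = auc[i] - auc[j]
    keep = d_auc != 0
    i, j, d_auc = i[keep], j[keep], d_auc[keep]
    w = (
        np.ones_like(d_auc)
        if unit_weights
        else stats.norm.cdf(np.abs(d_auc) / (noise_sd * np.sqrt(2.0)))
    )
    d_pred = pred[i] - pred[j]
    credit = np.where(d_pred == 0, 0.5, (np.sign(d_pred) == np.sign(d_auc)) * 1.0)
    total_w = float(w.sum())
    return WPCIResult(drug=drug, wpci=float((w * credit).sum() / total_w),
                      n_pairs_weighted=total_w)


def compare_methods(
    true_auc: dict[str, dict[str, float]],
    method_a_scores: dict[str, dict[str, float]],
    method_b_scores: dict[str, dict[str, float]],
    noise_sd: float | None = None,
) -> MethodComparison:
    """Per-drug WPCI for two scoring methods plus a paired comparison.

    Reports the count and fraction of drugs where method A's WPCI exceeds
    method B's and a one-sided Wilcoxon signed-rank p-value (H1: A > B) on
    the paired per-drug WPCIs.
    """
    drugs = sorted(true_auc)
    if set(method_a_scores) != set(drugs) or set(method_b_scores) != set(drugs):
        raise ValueError("method score maps must cover exactly the drugs in true_auc")
    rows = {}
    for d in drugs:
        wa = wpci(true_auc[d], method_a_scores[d], noise_sd=noise_sd, drug=d)
        wb = wpci(true_auc[d], method_b_scores[d], noise_sd=noise_sd, drug=d)
        rows[d] = {"wpci_a": wa.wpci, "wpci_b": wb.wpci}
    per_drug = pd.DataFrame.from_dict(rows, orient="index")
    diff = per_drug["wpci_a"] - per_drug["wpci_b"]
    n_higher = int((diff > 0).sum())
    if np.allclose(diff, 0):
        p = 1.0  # identical methods: no evidence either way
    else:
        p = float(
            stats.wilcoxon(diff, alternative="greater", zero_method="wilcox").pvalue
        )
    return MethodComparison(
        per_drug=per_drug,
        n_a_higher=n_higher,
        fraction_a_higher=n_higher / len(drugs),
        p_value=p,
    )


def group_drs_comparison(
    drs: DRSMatrix,
    grouping: SampleGrouping,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[SeparationResult]:
    """Per-drug one-sided rank-sum test of group A scores > group B scores.

    Designed for comparing externally supplied cell clusters (e.g. putative
    intrinsic-resistant vs sensitive subgroups of untreated cells).  With
    ``adjust`` the p-values are Benjamini–Hochberg corrected across drugs
    and ``accurate`` is judged on the adjusted values.
    """
    scored = set(drs.sample_ids)
    a_cells = [c for c in grouping.members(group_a) if c in scored]
    b_cells = [c for c in grouping.members(group_b) if c in scored]
    if not a_cells or not b_cells:
        raise ValueError(
            f"no scored cells in group {group_a if not a_cells else group_b!r}"
        )
    pos = {s: i for i, s in enumerate(drs.sample_ids)}
    ai = [pos[c] for c in a_cells]
    bi = [pos[c] for c in b_cells]
    results = [
        wilcoxon_separation(drs.scores[k, ai], drs.scores[k, bi],
                            alpha=alpha, drug=drug)
        for k, drug in enumerate(drs.drugs)
    ]
    if adjust:
        adj = stats.false_discovery_control([r.p_value for r in results], method="bh")
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
            r.accurate = bool(pa < alpha)
    return results
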