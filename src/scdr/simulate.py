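"""Synthetic pharmacogenomic cohorts with planted ground truth.

The generator emulates the two data layers the pipeline consumes:

* a bulk gene × cell-line expression matrix in which a chosen set of
  "planted" signature genes is shifted up in resistant lines and down in
  sensitive lines (and vice versa for down-genes), on top of log-normal
  baseline expression with per-gene/line log-scale noise;
* an AUC table whose values are coupled to each line's planted signature
  activity, so that AUC-based labelling can recover the designed
  resistant/sensitive split, with an intermediate group exercising the
  unlabelled middle band;
* optionally, overdispersed single-cell counts per line (negative binomial
  around the line's expression profile at a per-cell library size, with
  Bernoulli dropout), the minimal standard model of 10x-style sparsity.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DrugResponseTable, ExpressionMatrix, SampleGrouping

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_bulk_cohort",
    "simulate_single_cell",
    "simulate_null_response_table",
    "make_toy_fixture",
]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic cohort generator.

    ``effect_log2fc`` is the designed log2 fold change of planted genes
    between resistant and sensitive lines (split symmetrically: +effect/2 in
    one class, −effect/2 in the other).  ``noise_sd`` is per-gene/line noise
    on the log2 scale.  ``auc_coupling`` ∈ [0,1] mixes standardized planted
    signature activity with independent Gaussian noise to form AUC values
    (1 = AUC fully determined by activity, 0 = pure noise).
    """

    n_genes: int = 2000
    n_signature_up: int = 200
    n_signature_down: int = 200
    n_resistant: int = 30
    n_sensitive: int = 30
    n_intermediate: int = 30
    effect_log2fc: float = 1.0
    noise_sd: float = 0.5
    auc_coupling: float = 0.9
    seed: int = 0
    single_cell: bool = False
    cells_per_line: int = 50
    dropout_rate: float = 0.3
    nb_dispersion: float = 2.0
    library_size: int = 5000
    drug: str = "simdrug"

    def validate(self) -> None:
        if self.n_signature_up + self.n_signature_down > self.n_genes:
            raise ValueError("planted signature larger than the gene pool")
        if self.n_resistant < 1 or self.n_sensitive < 1:
            if self.effect_log2fc > 0:
                raise ValueError(
                    "effect_log2fc > 0 requires resistant and sensitive lines"
                )
        if self.n_genes < 1 or self.cells_per_line < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.auc_coupling <= 1.0:
            raise ValueError("auc_coupling must be in [0, 1]")
        if self.effect_log2fc < 0 or self.noise_sd < 0:
            raise ValueError("effect_log2fc and noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort: planted genes and designed labels."""

    planted_up: set[str]
    planted_down: set[str]
    line_labels: dict[str, str]  # line -> "R" | "S" | "intermediate"
    true_activity: dict[str, float]

    def __post_init__(self) -> None:
        if self.planted_up & self.planted_down:
            raise ValueError("planted up/down gene sets must be disjoint")

    def lines(self, label: str) -> list[str]:
        return sorted(l for l, lab in self.line_labels.items() if lab == label)


# AUC values are mapped onto an arbitrary plausible positive range; the
# labelling step is affine-invariant so the particular scale is irrelevant.
_AUC_CENTER = 8.0
_AUC_SPREAD = 1.5


def simulate_bulk_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, DrugResponseTable, SyntheticTruth]:
    """Generate a bulk cohort: expression, AUC table and planted truth.

    Per-line *true activity* is the mean over planted genes of the gene's
    z-scored expression across lines, sign-flipped for down-genes; AUC is
    ``auc_coupling`` parts standardized activity plus ``1 − auc_coupling``
    parts independent noise, affine-mapped to a positive range.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_up, n_down = config.n_signature_up, config.n_signature_down
    n_lines = config.n_resistant + config.n_sensitive + config.n_intermediate
    if n_lines < 2:
        raise ValueError("need at least 2 cell lines")

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    lines = (
        [f"R{i:03d}" for i in range(config.n_resistant)]
        + [f"S{i:03d}" for i in range(config.n_sensitive)]
        + [f"M{i:03d}" for i in range(config.n_intermediate)]
    )
    labels = (
        ["R"] * config.n_resistant
        + ["S"] * config.n_sensitive
        + ["intermediate"] * config.n_intermediate
    )

    perm = rng.permutation(config.n_genes)
    up_idx = perm[:n_up]
    down_idx = perm[n_up : n_up + n_down]

    base_log2 = rng.normal(3.0, 1.5, size=config.n_genes)
    log2_expr = base_log2[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n_lines)
    )
    half = config.effect_log2fc / 2.0
    r_cols = np.array([lab == "R" for lab in labels])
    s_cols = np.array([lab == "S" for lab in labels])
    log2_expr[np.ix_(up_idx, r_cols)] += half
    log2_expr[np.ix_(up_idx, s_cols)] -= half
    log2_expr[np.ix_(down_idx, r_cols)] -= half
    log2_expr[np.ix_(down_idx, s_cols)] += half
    values = np.exp2(log2_expr)
    expr = ExpressionMatrix(gene_ids, lines, values, is_log_scale=False)

    planted_idx = np.concatenate([up_idx, down_idx]).astype(int)
    if planted_idx.size:
        sub = log2_expr[planted_idx]
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd
        signs = np.concatenate([np.ones(n_up), -np.ones(n_down)])
        activity = (signs[:, None] * z).mean(axis=0)
    else:
        activity = np.zeros(n_lines)

    act_sd = activity.std(ddof=1) if n_lines > 1 else 0.0
    act_std = (activity - activity.mean()) / act_sd if act_sd > 0 else np.zeros(n_lines)
    raw = config.auc_coupling * act_std + (1.0 - config.auc_coupling) * rng.standard_normal(n_lines)
    raw_sd = raw.std(ddof=1)
    raw_std = (raw - raw.mean()) / raw_sd if raw_sd > 0 else raw
    auc = _AUC_CENTER + _AUC_SPREAD * raw_std

    responses = DrugResponseTable(
        pd.DataFrame(
            {"cell_line": lines, "drug": config.drug, "auc": auc}
        )
    )
    truth = SyntheticTruth(
        planted_up={gene_ids[i] for i in up_idx},
        planted_down={gene_ids[i] for i in down_idx},
        line_labels=dict(zip(lines, labels)),
        true_activity=dict(zip(lines, activity)),
    )
    return expr, responses, truth


def simulate_single_cell(
    config: SimulationConfig,
    bulk_expr: ExpressionMatrix,
) -> tuple[ExpressionMatrix, SampleGrouping]:
    """Draw overdispersed single-cell counts around each line's bulk profile.

    Each of ``cells_per_line`` cells per line gets a log-normal library size
    around ``library_size``; gene means are the line's expression profile
    rescaled to that library size; counts are negative binomial with shape
    ``nb_dispersion`` (variance μ + μ²/dispersion), then thinned by
    Bernoulli dropout at ``dropout_rate``.
    """
    config.validate()
    if not config.single_cell:
        raise ValueError("config.single_cell must be True for single-cell simulation")
    rng = np.random.default_rng([config.seed, 0x5C])
    profile = bulk_expr.dense()
    totals = profile.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("bulk profile has lines with zero total expression")
    probs = profile / totals

    blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    assignment: dict[str, str] = {}
    theta = config.nb_dispersion
    for j, line in enumerate(bulk_expr.sample_ids):
        lib = config.library_size * np.exp(
            rng.normal(0.0, 0.3, size=config.cells_per_line)
        )
        mu = probs[:, j : j + 1] * lib[None, :]
        p = theta / (theta + mu)
        counts = rng.negative_binomial(theta, p).astype(float)
        if config.dropout_rate > 0:
            keep = rng.random(counts.shape) >= config.dropout_rate
            counts *= keep
        blocks.append(counts)
        for c in range(config.cells_per_line):
            cid = f"{line}_c{c:04d}"
            cell_ids.append(cid)
            assignment[cid] = line
    counts = np.hstack(blocks)
    return (
        ExpressionMatrix(list(bulk_expr.gene_ids), cell_ids, counts, is_log_scale=False),
        SampleGrouping(assignment),
    )


def simulate_null_response_table(
    cell_lines: list[str],
    n_drugs: int,
    seed: int = 0,
) -> DrugResponseTable:
    """AUC table for ``n_drugs`` drugs with AUCs independent of everything.

    Used for null-calibration studies: every drug's AUC vector is an i.i.d.
    Gaussian draw, so resistant/sensitive labels derived from it carry no
    information about any expression matrix.
    """
    rng = np.random.default_rng([seed, 0xA0])
    frames = []
    for d in range(n_drugs):
        frames.append(
            pd.DataFrame(
                {
                    "cell_line": cell_lines,
                    "drug": f"null{d:04d}",
                    "auc": _AUC_CENTER
                    + _AUC_SPREAD * rng.standard_normal(len(cell_lines)),
                }
            )
        )
    return DrugResponseTable(pd.concat(frames, ignore_index=True))


def make_toy_fixture() -> dict:
    """A hand-checkable miniature cohort with closed-form expected values.

    Five genes × six cell lines (2 designed resistant, 2 sensitive, 2 in the
    unlabelled band) with integer expression values chosen so that group
    means, fold changes, z-scores and scores all have closed forms.  The
    expected numbers returned here are derived from those closed forms by
    plain arithmetic, independently of the pipeline code.
    """
    genes = ["UP1", "UP2", "DN1", "DN2", "NEUT"]
    lines = ["R1", "R2", "S1", "S2", "M1", "M2"]
    values = np.array(
        [
            [4.0, 4.0, 1.0, 1.0, 2.0, 3.0],  # UP1: R-mean 4, S-mean 1
            [3.0, 1.0, 1.0, 1.0, 2.0, 1.0],  # UP2: R-mean 2, S-mean 1
            [1.0, 1.0, 4.0, 4.0, 3.0, 2.0],  # DN1: R-mean 1, S-mean 4
            [1.0, 1.0, 2.0, 2.0, 1.0, 2.0],  # DN2: R-mean 1, S-mean 2
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],  # NEUT: constant
        ]
    )
    expr = ExpressionMatrix(genes, lines, values, is_log_scale=False)
    responses = DrugResponseTable(
        pd.DataFrame(
            {
                "cell_line": lines,
                "drug": "drugX",
                "auc": [10.0, 9.0, 1.0, 2.0, 5.0, 6.0],
            }
        )
    )
    # AUC mean 5.5, sample sd sqrt(13.1); mean ± 0.8 sd = (2.6045, 8.3955):
    # R = {R1, R2}, S = {S1, S2}, M lines in the unlabelled band.
    expected_labels = {"resistant": {"R1", "R2"}, "sensitive": {"S1", "S2"}}
    # log2 fold changes of R-group vs S-group means at pseudocount 0.
    expected_log2fc = {"UP1": 2.0, "UP2": 1.0, "DN1": -2.0, "DN2": -1.0, "NEUT": 0.0}
    # Gene-wise z-scores across all six samples (sample sd):
    # UP1 devs (1.5,1.5,-1.5,-1.5,-0.5,0.5), var 1.9; UP2 var 0.7;
    # DN1 var 1.9; DN2 var 0.3; NEUT constant -> dropped.
    s19, s07, s03 = math.sqrt(1.9), math.sqrt(0.7), math.sqrt(0.3)
    expected_z = {
        "UP1": [d / s19 for d in (1.5, 1.5, -1.5, -1.5, -0.5, 0.5)],
        "UP2": [d / s07 for d in (1.5, -0.5, -0.5, -0.5, 0.5, -0.5)],
        "DN1": [d / s19 for d in (-1.5, -1.5, 1.5, 1.5, 0.5, -0.5)],
        "DN2": [d / s03 for d in (-0.5, -0.5, 0.5, 0.5, -0.5, 0.5)],
    }
    # Score per sample with weights (2, 1, -2, -1) over q = 4 genes.
    weights = {"UP1": 2.0, "UP2": 1.0, "DN1": -2.0, "DN2": -1.0}
    expected_drs = {
        line: sum(weights[g] * expected_z[g][m] for g in weights) / 4.0
        for m, line in enumerate(lines)
    }
    return {
        "expr": expr,
        "responses": responses,
        "drug": "drugX",
        "expected_labels": expected_labels,
        "expected_log2fc": expected_log2fc,
        "expected_zscores": expected_z,
        "expected_drs": expected_drs,
        "n_top": 2,
        "pseudocount": 0.0,
    }
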