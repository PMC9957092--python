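"""Drug-response scoring: z-score standardization and the weighted score.

A scored dataset is first standardized gene-wise across *its own* samples
(z = (x − mean)/sd, sample sd).  The drug-response score of sample m under a
signature is then the mean over the q signature genes present in the matrix
of (gene log2FC × the gene's z-score in m).  Higher scores predict
resistance.  Because every z row averages zero, scores for any drug average
zero over the scored samples.

Cell-level scores are aggregated to cell-line level (mDRS) by the arithmetic
mean over each line's cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ExpressionMatrix, SampleGrouping
from .signatures import DrugSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ZscoreMatrix",
    "DRSMatrix",
    "zscore_transform",
    "score_samples",
    "score_all",
    "aggregate_mdrs",
]

_ROW_BATCH = 2048  # gene rows densified per batch when the input is sparse


@dataclass
class ZscoreMatrix:
    """Gene × sample standardized expression; zero-variance genes removed."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    n_dropped_zero_variance: int = 0

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class DRSMatrix:
    """Drug × sample score matrix with the per-drug gene-intersection size q."""

    drugs: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    q_used: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.drugs), len(self.sample_ids)):
            raise ValueError("scores shape does not match drug/sample ids")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        for d, q in self.q_used.items():
            if q < 1:
                raise ValueError(f"drug {d!r}: q must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.drugs, columns=self.sample_ids)

    def row(self, drug: str) -> pd.Series:
        try:
            i = self.drugs.index(drug)
        except ValueError:
            raise KeyError(f"drug {drug!r} not scored") from None
        return pd.Series(self.scores[i], index=self.sample_ids, name=drug)


def zscore_transform(expr: ExpressionMatrix) -> ZscoreMatrix:
    """Standardize each gene across all samples of the scored dataset.

    Uses the sample standard deviation (n−1).  Genes with zero variance are
    removed (their z-score is undefined) and counted in the result.  Sparse
    input is densified in gene-row batches; the result is value-identical to
    the dense computation.
    """
    if expr.n_samples < 2:
        raise ValueError("z-score needs >= 2 samples (sd undefined for one)")
    n_genes, _ = expr.shape
    rows: list[np.ndarray] = []
    keep_mask = np.zeros(n_genes, dtype=bool)
    values = expr.values
    for start in range(0, n_genes, _ROW_BATCH):
        stop = min(start + _ROW_BATCH, n_genes)
        block = values[start:stop]
        if sp.issparse(block):
            block = np.asarray(block.todense(), dtype=float)
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        ok = (sd[:, 0] > 0)
        keep_mask[start:stop] = ok
        if ok.any():
            rows.append((block[ok] - mean[ok]) / sd[ok])
    n_dropped = int((~keep_mask).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance genes before scoring", n_dropped)
    if not keep_mask.any():
        raise ValueError("all genes have zero variance; nothing to score")
    z = np.vstack(rows)
    genes = [g for g, k in zip(expr.gene_ids, keep_mask) if k]
    return ZscoreMatrix(genes, list(expr.sample_ids), z, n_dropped)


def score_samples(z: ZscoreMatrix, signature: DrugSignature) -> tuple[np.ndarray, int]:
    """Score every sample with one signature.

    Returns the per-sample score vector and q, the number of signature genes
    found in the z-matrix.  Raises if no signature gene is present.
    """
    lut = z.gene_index()
    idx = [lut[g] for g in signature.genes if g in lut]
    if not idx:
        raise ValueError(
            f"no signature genes present in expression for drug {signature.drug!r}"
        )
    weights = np.array(
        [fc for g, fc in signature.entries if g in lut], dtype=float
    )
    q = len(idx)
    scores = weights @ z.values[idx] / q
    return scores, q


def score_all(
    expr: ExpressionMatrix,
    signatures: list[DrugSignature],
) -> DRSMatrix:
    """Score every sample against every signature, sharing one z-transform.

    Drugs whose signatures share no genes with the matrix are skipped with a
    logged report; if every drug is skipped an error is raised.
    """
    z = zscore_transform(expr)
    rows, drugs, q_used = [], [], {}
    skipped = []
    for sig in signatures:
        try:
            scores, q = score_samples(z, sig)
        except ValueError:
            skipped.append(sig.drug)
            continue
        rows.append(scores)
        drugs.append(sig.drug)
        q_used[sig.drug] = q
    if skipped:
        logger.info("skipped %d drugs with empty gene intersection: %s",
                    len(skipped), skipped[:10])
    if not rows:
        raise ValueError("every drug was skipped: no signature genes in matrix")
    return DRSMatrix(drugs, list(z.sample_ids), np.vstack(rows), q_used)


def aggregate_mdrs(drs: DRSMatrix, cell_to_line: SampleGrouping) -> DRSMatrix:
    """Average cell-level scores to one mean score (mDRS) per cell line."""
    missing = [c for c in drs.sample_ids if c not in cell_to_line.assignment]
    if missing:
        raise ValueError(f"cells missing from cell→line map: {missing[:10]}")
    lines = sorted({cell_to_line.assignment[c] for c in drs.sample_ids})
    line_pos = {ln: i for i, ln in enumerate(lines)}
    out = np.zeros((len(drs.drugs), len(lines)))
    counts = np.zeros(len(lines))
    for j, cell in enumerate(drs.sample_ids):
        i = line_pos[cell_to_line.assignment[cell]]
        out[:, i] += drs.scores[:, j]
        counts[i] += 1
    out /= counts
    return DRSMatrix(list(drs.drugs), lines, out, dict(drs.q_used))
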