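"""Resistant/sensitive labelling and drug-response-gene (DRG) derivation.

For each drug, cell lines are split on their AUC distribution: lines with
AUC above mean + k·sd are called resistant (R), below mean − k·sd sensitive
(S); the band in between stays unlabelled.  A drug's signature is then the
top-N most up- and top-N most down-regulated genes by log2 fold change of
R-group versus S-group mean expression, each gene carrying its log2FC as the
weight later used in scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DrugResponseTable, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseLabels",
    "DrugSignature",
    "classify_cell_lines",
    "derive_signature",
    "derive_all_signatures",
    "signature_overlap",
    "read_signatures",
    "write_signatures",
]


@dataclass
class ResponseLabels:
    """R/S split of cell lines for one drug, with the thresholds used."""

    drug: str
    resistant: set[str]
    sensitive: set[str]
    auc_mean: float
    auc_sd: float
    k: float

    def __post_init__(self) -> None:
        overlap = self.resistant & self.sensitive
        if overlap:
            raise ValueError(f"lines labelled both R and S: {sorted(overlap)[:5]}")


@dataclass
class DrugSignature:
    """Per-drug ordered list of (gene_id, log2FC) weights.

    Up-regulated entries (log2FC > 0) come first, most-positive first, then
    down-regulated entries, most-negative first.
    """

    drug: str
    entries: list[tuple[str, float]]
    n_up: int = field(init=False)
    n_down: int = field(init=False)

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate genes in signature for {self.drug}")
        self.n_up = sum(1 for _, fc in self.entries if fc > 0)
        self.n_down = sum(1 for _, fc in self.entries if fc < 0)
        if self.n_up + self.n_down != len(self.entries):
            raise ValueError("signature entries must have nonzero log2FC")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def weights(self) -> np.ndarray:
        return np.array([fc for _, fc in self.entries], dtype=float)

    def negated(self) -> "DrugSignature":
        return DrugSignature(self.drug, [(g, -fc) for g, fc in self.entries])


def classify_cell_lines(
    responses: DrugResponseTable,
    drug: str,
    k: float = 0.8,
    min_group_size: int = 2,
) -> ResponseLabels:
    """Label cell lines resistant/sensitive from the drug's AUC distribution.

    Mean and sd (sample sd, n−1 denominator) are taken over *all* lines with
    an AUC for the drug.  Strictly above mean + k·sd → R, strictly below
    mean − k·sd → S; boundary and in-band lines stay unlabelled.
    """
    auc = responses.auc_for_drug(drug)
    if len(auc) < 3:
        raise ValueError(f"drug {drug!r}: need >= 3 cell lines, got {len(auc)}")
    mean = float(auc.mean())
    sd = float(auc.std(ddof=1))
    if sd == 0:
        raise ValueError(f"drug {drug!r}: degenerate response distribution (sd = 0)")
    resistant = set(auc.index[auc > mean + k * sd])
    sensitive = set(auc.index[auc < mean - k * sd])
    if len(resistant) < min_group_size or len(sensitive) < min_group_size:
        raise ValueError(
            f"drug {drug!r}: insufficient group "
            f"(R={len(resistant)}, S={len(sensitive)}, need >= {min_group_size})"
        )
    return ResponseLabels(drug, resistant, sensitive, mean, sd, k)


def derive_signature(
    expr: ExpressionMatrix,
    labels: ResponseLabels,
    n_top: int = 200,
    pseudocount: float = 0.01,
    allow_log_scale: bool = False,
) -> DrugSignature:
    """Derive a drug signature by R-vs-S group-mean log2 fold change.

    Per gene, log2FC = log2((mean over R columns + pseudocount) /
    (mean over S columns + pseudocount)).  Genes with zero mean in both
    groups are dropped.  The ``n_top`` largest positive and ``n_top`` most
    negative log2FC genes form the signature; ranking ties break on gene id
    so builds are deterministic.

    Fold change is a ratio of linear-scale means; a log-scale input is
    rejected unless ``allow_log_scale`` acknowledges that group means will
    be taken on the log scale.
    """
    if expr.is_log_scale and not allow_log_scale:
        raise ValueError(
            "expression is flagged log-scale; de-log it (expm1/2**x) or pass "
            "allow_log_scale=True to take group means on the log scale"
        )
    sample_set = set(expr.sample_ids)
    r_cols = sorted(labels.resistant & sample_set)
    s_cols = sorted(labels.sensitive & sample_set)
    if not r_cols or not s_cols:
        raise ValueError(
            f"drug {labels.drug!r}: no expression columns for "
            f"{'R' if not r_cols else 'S'} lines"
        )
    lut = expr.sample_index()
    dense = expr.dense()
    mean_r = dense[:, [lut[c] for c in r_cols]].mean(axis=1)
    mean_s = dense[:, [lut[c] for c in s_cols]].mean(axis=1)
    keep = ~((mean_r == 0) & (mean_s == 0))
    genes = np.array(expr.gene_ids)[keep]
    with np.errstate(divide="ignore"):
        log2fc = np.log2(mean_r[keep] + pseudocount) - np.log2(mean_s[keep] + pseudocount)

    desc = np.lexsort((genes, -log2fc))  # fc descending, gene id breaks ties
    asc = np.lexsort((genes, log2fc))    # fc ascending, gene id breaks ties
    up_idx = [i for i in desc if log2fc[i] > 0][:n_top]
    down_idx = [i for i in asc if log2fc[i] < 0][:n_top]
    up = [(genes[i], log2fc[i]) for i in up_idx]
    down = [(genes[i], log2fc[i]) for i in down_idx]
    if len(up) < n_top or len(down) < n_top:
        logger.info(
            "drug %s: only %d up / %d down genes available (requested %d)",
            labels.drug, len(up), len(down), n_top,
        )
    entries = [(str(g), float(fc)) for g, fc in up + down]
    if not entries:
        raise ValueError(f"drug {labels.drug!r}: no genes with nonzero fold change")
    return DrugSignature(labels.drug, entries)


def derive_all_signatures(
    expr: ExpressionMatrix,
    responses: DrugResponseTable,
    k: float = 0.8,
    n_top: int = 200,
    pseudocount: float = 0.01,
    min_group_size: int = 2,
) -> tuple[list[DrugSignature], dict[str, str]]:
    """Derive one signature per drug; drugs whose R/S split fails are skipped.

    Returns the signatures plus a drug → reason map for skipped drugs.
    """
    signatures: list[DrugSignature] = []
    skipped: dict[str, str] = {}
    for drug in responses.drugs:
        try:
            labels = classify_cell_lines(responses, drug, k=k,
                                         min_group_size=min_group_size)
            signatures.append(
                derive_signature(expr, labels, n_top=n_top, pseudocount=pseudocount)
            )
        except (ValueError, KeyError) as exc:
            skipped[drug] = str(exc)
            logger.info("skipping drug %s: %s", drug, exc)
    if not signatures:
        raise ValueError(f"no drug produced a signature; reasons: {skipped}")
    return signatures, skipped


def signature_overlap(signatures: list[DrugSignature]) -> pd.DataFrame:
    """Symmetric drug × drug Jaccard-index matrix over signature gene sets."""
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures to compare overlaps")
    drugs = [s.drug for s in signatures]
    sets = [set(s.genes) for s in signatures]
    n = len(sets)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            mat[i, j] = mat[j, i] = len(sets[i] & sets[j]) / union if union else 0.0
    return pd.DataFrame(mat, index=drugs, columns=drugs)


def write_signatures(signatures: list[DrugSignature], path) -> None:
    """TSV with header drug, gene, log2fc; one row per signature entry."""
    rows = [
        {"drug": s.drug, "gene": g, "log2fc": fc}
        for s in signatures for g, fc in s.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_signatures(path) -> list[DrugSignature]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"drug", "gene", "log2fc"}
    if not required.issubset(df.columns):
        raise ValueError(f"signature file must have columns {sorted(required)}")
    out = []
    for drug, sub in df.groupby("drug", sort=True):
        out.append(DrugSignature(str(drug),
                                 list(zip(sub["gene"].astype(str),
                                          sub["log2fc"].astype(float)))))
    return out
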