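"""Core in-memory containers shared by every pipeline stage.

The pipeline moves three kinds of data around: gene × sample expression
matrices (dense or sparse-backed), long-format drug-response tables keyed by
(cell line, drug) with an AUC value, and flat sample → group assignments
(resistant/sensitive labels, cluster names, cell → cell-line maps).  All three
are thin, validated wrappers so that downstream code can rely on unique
identifiers and finite values without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["ExpressionMatrix", "DrugResponseTable", "SampleGrouping"]


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """A gene × sample expression matrix with string identifiers.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    values
        ``(n_genes, n_samples)`` array, dense ``ndarray`` or any scipy sparse
        matrix (stored as CSR).  Values must be finite, and non-negative
        unless ``is_log_scale`` is set.
    is_log_scale
        Declares whether ``values`` are log-transformed.  Fold-change
        derivation requires linear-scale input and checks this flag.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray | sp.spmatrix
    is_log_scale: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
        else:
            self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        data = self.values.data if sp.issparse(self.values) else self.values
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("expression values must be finite")
        if not self.is_log_scale and data.size and data.min() < 0:
            raise ValueError("linear-scale expression values must be >= 0")

    # -- convenience accessors -------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genes, self.n_samples)

    def dense(self) -> np.ndarray:
        """Values as a dense float array (copy only if sparse-backed)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def subset(
        self,
        genes: list[str] | None = None,
        samples: list[str] | None = None,
    ) -> "ExpressionMatrix":
        """Submatrix restricted to the given genes and/or samples (in the
        given order); unknown identifiers raise ``KeyError``."""
        gi = np.arange(self.n_genes)
        si = np.arange(self.n_samples)
        g_ids, s_ids = self.gene_ids, self.sample_ids
        if genes is not None:
            lut = self.gene_index()
            missing = [g for g in genes if g not in lut]
            if missing:
                raise KeyError(f"genes not in matrix: {missing[:10]}")
            gi = np.array([lut[g] for g in genes], dtype=int)
            g_ids = list(genes)
        if samples is not None:
            lut = self.sample_index()
            missing = [s for s in samples if s not in lut]
            if missing:
                raise KeyError(f"samples not in matrix: {missing[:10]}")
            si = np.array([lut[s] for s in samples], dtype=int)
            s_ids = list(samples)
        vals = self.values[gi][:, si]
        return ExpressionMatrix(g_ids, s_ids, vals, self.is_log_scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DrugResponseTable:
    """Long-format (cell_line, drug, auc) records, unique per pair.

    Higher AUC (area under the percent-viability curve) means more viable
    cells across doses, i.e. a more resistant line.
    """

    records: pd.DataFrame  # columns: cell_line, drug, auc

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        required = ["cell_line", "drug", "auc"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"drug-response table missing columns: {missing}")
        df = df[required].copy()
        df["cell_line"] = df["cell_line"].astype(str).str.strip()
        df["drug"] = df["drug"].astype(str).str.strip()
        df["auc"] = pd.to_numeric(df["auc"], errors="raise").astype(float)
        if not np.all(np.isfinite(df["auc"])):
            raise ValueError("AUC values must be finite")
        dup = df.duplicated(subset=["cell_line", "drug"], keep=False)
        if dup.any():
            grouped = df[dup].groupby(["cell_line", "drug"])["auc"].nunique()
            conflicts = grouped[grouped > 1]
            if len(conflicts):
                raise ValueError(
                    "conflicting AUC for pairs: "
                    + ", ".join(f"{c}/{d}" for c, d in conflicts.index[:10])
                )
            df = df.drop_duplicates(subset=["cell_line", "drug"])
        self.records = df.reset_index(drop=True)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.records["drug"].unique())

    def auc_for_drug(self, drug: str) -> pd.Series:
        """AUC values indexed by cell line for one drug."""
        sub = self.records[self.records["drug"] == drug]
        if sub.empty:
            raise KeyError(f"no response records for drug {drug!r}")
        return sub.set_index("cell_line")["auc"]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SampleGrouping:
    """Flat sample → group-label map (R/S labels, clusters, cell → line)."""

    assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignment = {
            str(k).strip(): str(v).strip() for k, v in dict(self.assignment).items()
        }

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, group in self.assignment.items():
            out.setdefault(group, []).append(sample)
        return out

    def members(self, group: str) -> list[str]:
        got = [s for s, g in self.assignment.items() if g == group]
        if not got:
            raise KeyError(f"unknown group label {group!r}")
        return got

    def __len__(self) -> int:
        return len(self.assignment)
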