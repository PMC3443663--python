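"""Normalisation, cross-dataset batch adjustment, and the ranked
expression-change vector.

The change vector is the substrate of the activity statistic: every gene in
the matrix, ordered by decreasing differential-expression statistic between a
case phenotype and a comparator phenotype.  The default statistic is the
Welch t (robust to the very unequal group sizes typical of tumor-vs-normal
compendia); a log-ratio alternative is selectable.  Ties are broken by
ascending gene id so runs are deterministic across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, FormatError, write_table


@dataclass
class ExpressionChangeVector:
    """All genes ordered by decreasing change statistic (case - comparator).

    ``genes`` and ``statistics`` are parallel, sorted by decreasing
    statistic with ties broken by ascending gene id; each gene appears once.
    """

    genes: list[str]
    statistics: np.ndarray
    case: str
    comparator: str
    statistic_name: str = "welch_t"

    def __post_init__(self) -> None:
        self.statistics = np.asarray(self.statistics, dtype=float)
        if len(self.genes) != len(self.statistics):
            raise ValueError("genes and statistics length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene in change vector")
        d = np.diff(self.statistics)
        if (d > 1e-12).any():
            raise ValueError("change vector not sorted by decreasing statistic")

    def __len__(self) -> int:
        return len(self.genes)

    def rank_of(self) -> dict[str, int]:
        """Gene id -> 0-based rank on the vector."""
        return {g: i for i, g in enumerate(self.genes)}

    def reversed(self) -> "ExpressionChangeVector":
        """Vector for the opposite contrast (statistics negated)."""
        return ExpressionChangeVector(
            list(reversed(self.genes)),
            -self.statistics[::-1],
            case=self.comparator,
            comparator=self.case,
            statistic_name=self.statistic_name,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"statistic": self.statistics}, index=pd.Index(self.genes, name="gene_id")
        )

    def write(self, path: str | Path, comments: Iterable[str] = ()) -> None:
        meta = [
            f"case={self.case}",
            f"comparator={self.comparator}",
            f"statistic={self.statistic_name}",
        ]
        write_table(self.to_frame(), path, list(comments) + meta,
                    index_label="gene_id")


def dasl_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Virtual-reference mean scaling, as used for bead-array FFPE profiles.

    Each sample is scaled by (virtual-reference mean / sample mean), where
    the virtual reference mean is the mean of the per-sample means.  After
    scaling, every sample has the same mean intensity.  Idempotent.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise FormatError("dasl_normalize expects non-negative intensities")
    sample_means = vals.mean(axis=0)
    zero = [s for s, m in zip(matrix.sample_ids, sample_means) if m == 0]
    if zero:
        raise FormatError(f"sample(s) with zero mean intensity: {zero}")
    reference = sample_means.mean()
    scaled = vals * (reference / sample_means)
    return matrix.with_values(
        pd.DataFrame(scaled, index=matrix.values.index,
                     columns=matrix.values.columns)
    )


def batch_adjust(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene location/scale matching across batches.

    For each gene, every batch is shifted so its within-batch mean equals the
    across-batch mean of batch means, and rescaled so its within-batch SD
    equals the pooled SD (square root of the unweighted mean of within-batch
    variances).  Gene/batch cells with zero variance are shifted only.  This
    is a transparent stand-in for published batch-correction methods and is
    deliberately isolated behind this one function.
    """
    batches = matrix.batch
    sizes = batches.value_counts()
    singletons = sizes[sizes < 2]
    if not singletons.empty:
        raise FormatError(
            f"batch(es) with fewer than 2 samples: {list(singletons.index)}"
        )
    vals = matrix.values.to_numpy(dtype=float).copy()
    labels = sorted(sizes.index)
    cols = {
        b: [i for i, s in enumerate(matrix.sample_ids) if batches[s] == b]
        for b in labels
    }
    means = np.stack([vals[:, cols[b]].mean(axis=1) for b in labels])
    variances = np.stack(
        [vals[:, cols[b]].var(axis=1, ddof=1) for b in labels]
    )
    grand = means.mean(axis=0)
    pooled_sd = np.sqrt(variances.mean(axis=0))
    for bi, b in enumerate(labels):
        idx = cols[b]
        centered = vals[:, idx] - means[bi][:, None]
        sd = np.sqrt(variances[bi])
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(sd > 0, pooled_sd / np.where(sd > 0, sd, 1.0), 1.0)
        vals[:, idx] = centered * scale[:, None] + grand[:, None]
    return matrix.with_values(
        pd.DataFrame(vals, index=matrix.values.index,
                     columns=matrix.values.columns)
    )


def _welch_t(case: np.ndarray, comp: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistic (case minus comparator); 0 where both
    groups have zero variance."""
    n1, n2 = case.shape[1], comp.shape[1]
    m1, m2 = case.mean(axis=1), comp.mean(axis=1)
    v1, v2 = case.var(axis=1, ddof=1), comp.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    return np.where(se2 > 0, t, 0.0)


def _log_ratio(case: np.ndarray, comp: np.ndarray) -> np.ndarray:
    return case.mean(axis=1) - comp.mean(axis=1)


_STATISTICS = {"welch_t": _welch_t, "log_ratio": _log_ratio}


def rank_expression_changes(
    matrix: ExpressionMatrix,
    case_label: str,
    comparator_label: str,
    statistic: str = "welch_t",
) -> ExpressionChangeVector:
    """Build the ranked expression-change vector between two phenotypes.

    Genes are ordered by decreasing statistic, ties broken by ascending gene
    id.  Requires at least two samples per condition.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown change statistic {statistic!r}")
    case_samples = matrix.samples_with(case_label)
    comp_samples = matrix.samples_with(comparator_label)
    for label, samples in ((case_label, case_samples),
                           (comparator_label, comp_samples)):
        if len(samples) < 2:
            raise FormatError(
                f"condition {label!r} has {len(samples)} sample(s); >=2 required"
            )
    case = matrix.values[case_samples].to_numpy(dtype=float)
    comp = matrix.values[comp_samples].to_numpy(dtype=float)
    stats = _STATISTICS[statistic](case, comp)
    genes = np.asarray(matrix.gene_ids, dtype=object)
    order = np.lexsort((genes, -stats))
    return ExpressionChangeVector(
        [str(g) for g in genes[order]],
        stats[order],
        case=case_label,
        comparator=comparator_label,
        statistic_name=statistic,
    )


def read_change_vector(path: str | Path) -> ExpressionChangeVector:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ExpressionChangeVector(
        [str(g) for g in df.index],
        df["statistic"].to_numpy(dtype=float),
        case=meta.get("case", "case"),
        comparator=meta.get("comparator", "comparator"),
        statistic_name=meta.get("statistic", "welch_t"),
    )
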