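"""miRNA activity inference from ranked expression changes.

The premise: if a miRNA is active in the case condition, its predicted target
mRNAs are repressed, so they crowd the bottom of the expression-change vector
(genes ordered by decreasing case-minus-comparator statistic); if it is
silenced they crowd the top.  The statistic is a weighted Kolmogorov–Smirnov
style running sum walked down the vector: +sqrt((N-m)/m) at each of the m
target genes, -sqrt(m/(N-m)) at each non-target, with N the vector length.
Let D be the running-sum value of largest absolute magnitude (ties resolved
to the smallest rank).  The activity score is AS = -D, so targets piled at
the bottom of the vector (repression) yield a positive AS = inferred
activation, and targets piled at the top yield a negative AS = silencing.

Significance comes from permutations of the gene labels of the expression
matrix: each permutation k reassigns which gene id carries which statistic
(one shared permutation for all miRNAs), the vector is rebuilt and every
miRNA rescored, giving the null matrix NS(x, k).  The false discovery rate
for an observed score AS* >= 0 is

    FDR(AS*) = [ #{(x,k): NS >= 0 and NS >= AS*} / #{(x,k): NS >= 0} ]
             / [ #{x: AS >= 0 and AS >= AS*}     / #{x: AS >= 0}     ]

capped at 1, and mirrored with <= for AS* < 0.  The per-miRNA empirical p is
the pseudocounted two-sided exceedance p = (1 + #{k: |NS(x,k)| >= |AS(x)|})
/ (K + 1); published analyses of this kind report p thresholds without
defining the p computation, so this definition is the package's own and is
documented as such.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .io import ExpressionMatrix, TargetSetCollection, write_table
from .preprocess import ExpressionChangeVector, rank_expression_changes

logger = logging.getLogger(__name__)

CALL_ACTIVATED = "activated"
CALL_SILENCED = "silenced"
CALL_NONE = "none"


# ---------------------------------------------------------------------------
# The running-sum score
# ---------------------------------------------------------------------------

def _score_from_ranks(target_ranks: np.ndarray, n: int) -> float:
    """Activity score given the 0-based ranks of the m targets on a length-n
    vector."""
    m = len(target_ranks)
    if m == 0:
        raise ValueError("no target ranks supplied")
    if m >= n:
        raise ValueError(f"degenerate target set: m={m} >= N={n}")
    a = np.sqrt((n - m) / m)
    b = np.sqrt(m / (n - m))
    inc = np.full(n, -b)
    inc[target_ranks] = a
    s = np.cumsum(inc)
    j = int(np.argmax(np.abs(s)))  # first occurrence = smallest rank
    return float(-s[j])


def activity_score(vector: ExpressionChangeVector,
                   target_set: Iterable[str]) -> float:
    """Score one miRNA's target set on a ranked change vector.

    Positive = inferred activation (targets concentrated among the most
    down-regulated genes), negative = silencing.  Raises if no target gene is
    on the vector or if every gene is a target.
    """
    rank = vector.rank_of()
    ranks = np.array(sorted(rank[g] for g in target_set if g in rank),
                     dtype=int)
    if len(ranks) == 0:
        raise ValueError("target set does not intersect the change vector")
    return _score_from_ranks(ranks, len(vector))


def _membership_matrix(vector: ExpressionChangeVector,
                       targets: TargetSetCollection
                       ) -> tuple[list[str], np.ndarray]:
    """Boolean (miRNA x rank) membership of targets on the vector, dropping
    (with a logged warning) miRNAs with no target on the vector."""
    rank = vector.rank_of()
    n = len(vector)
    kept: list[str] = []
    rows: list[np.ndarray] = []
    for mid in targets.mirna_ids:
        ranks = [rank[g] for g in targets[mid] if g in rank]
        if not ranks:
            logger.warning("miRNA %s: no target on the change vector; skipped",
                           mid)
            continue
        if len(ranks) == n:
            raise ValueError(
                f"miRNA {mid}: every gene on the vector is a target (degenerate)"
            )
        row = np.zeros(n, dtype=bool)
        row[ranks] = True
        kept.append(mid)
        rows.append(row)
    if not kept:
        raise ValueError("no miRNA has any target on the change vector")
    return kept, np.stack(rows)


def _score_membership(member: np.ndarray) -> np.ndarray:
    """Vectorised running-sum scores for a boolean (miRNA x rank) matrix."""
    n = member.shape[1]
    m = member.sum(axis=1).astype(float)
    a = np.sqrt((n - m) / m)
    b = np.sqrt(m / (n - m))
    inc = np.where(member, (a + b)[:, None], 0.0) - b[:, None]
    s = np.cumsum(inc, axis=1)
    j = np.argmax(np.abs(s), axis=1)
    return -s[np.arange(len(j)), j]


# ---------------------------------------------------------------------------
# Permutation null, p, FDR
# ---------------------------------------------------------------------------

@dataclass
class NullScores:
    """Null activity scores NS(x, k): miRNAs x K gene-label permutations."""

    mirna_ids: list[str]
    scores: np.ndarray  # (n_mirnas, K)
    seed: int | None
    K: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.mirna_ids), self.K):
            raise ValueError("NullScores shape mismatch")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite null scores")

    def row(self, mirna_id: str) -> np.ndarray:
        return self.scores[self.mirna_ids.index(mirna_id)]

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(self.scores,
                          index=pd.Index(self.mirna_ids, name="mirna_id"),
                          columns=[f"perm_{k}" for k in range(self.K)])
        write_table(df, path, [f"K={self.K}", f"seed={self.seed}"])


def permutation_null(
    matrix: ExpressionMatrix,
    case_label: str,
    comparator_label: str,
    targets: TargetSetCollection,
    K: int = 1000,
    seed: int | None = None,
    statistic: str = "welch_t",
) -> NullScores:
    """Null score matrix from K permutations of the matrix's gene labels.

    Permuting gene labels leaves the per-gene statistics unchanged and only
    reassigns which gene carries which value, so rebuilding the change vector
    under permutation k is equivalent to placing each miRNA's targets at the
    ranks the permutation sends them to; one shared permutation per k keeps
    the across-miRNA correlation structure of overlapping target sets.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    vector = rank_expression_changes(matrix, case_label, comparator_label,
                                     statistic)
    mirnas, member = _membership_matrix(vector, targets)
    return _null_from_membership(mirnas, member, K, seed)


def _null_from_membership(mirnas: list[str], member: np.ndarray,
                          K: int, seed: int | None) -> NullScores:
    rng = np.random.default_rng(seed)
    n = member.shape[1]
    ns = np.empty((len(mirnas), K))
    for k in range(K):
        perm = rng.permutation(n)
        ns[:, k] = _score_membership(member[:, perm])
    return NullScores(mirnas, ns, seed, K)


def empirical_p(as_score: float, null_row: np.ndarray) -> float:
    """Pseudocounted two-sided permutation p for one miRNA:
    (1 + #{k: |NS(x,k)| >= |AS|}) / (K + 1)."""
    null_row = np.asarray(null_row, dtype=float)
    if null_row.size < 1:
        raise ValueError("empty null row")
    exceed = int((np.abs(null_row) >= abs(as_score)).sum())
    return (1 + exceed) / (null_row.size + 1)


def estimate_fdr(as_scores: np.ndarray,
                 null_scores: np.ndarray | NullScores,
                 as_star: float) -> float:
    """Permutation FDR at threshold score ``as_star`` (same-signed side).

    Ratio of the null tail fraction to the observed tail fraction among the
    scores sharing the sign side of ``as_star``; capped at 1; undefined
    ratios (empty side) return 1 with a warning.
    """
    if isinstance(null_scores, NullScores):
        null_scores = null_scores.scores
    ns = np.asarray(null_scores, dtype=float).ravel()
    obs = np.asarray(as_scores, dtype=float).ravel()
    if not np.isfinite(as_star):
        raise ValueError("as_star must be finite")
    if as_star >= 0:
        ns_side = ns[ns >= 0]
        obs_side = obs[obs >= 0]
        ns_tail = (ns_side >= as_star).sum()
        obs_tail = (obs_side >= as_star).sum()
    else:
        ns_side = ns[ns <= 0]
        obs_side = obs[obs <= 0]
        ns_tail = (ns_side <= as_star).sum()
        obs_tail = (obs_side <= as_star).sum()
    if ns_side.size == 0 or obs_side.size == 0 or obs_tail == 0:
        warnings.warn("FDR undefined (empty side of the score distribution); "
                      "returning 1", stacklevel=2)
        return 1.0
    num = ns_tail / ns_side.size
    den = obs_tail / obs_side.size
    return float(min(num / den, 1.0))


def call_deregulated(results: pd.DataFrame,
                     p_threshold: float = 0.005,
                     fdr_threshold: float = 0.01
                     ) -> tuple[list[str], list[str]]:
    """Split scored miRNAs into activated / silenced lists at thresholds.

    ``results`` needs columns as_score, p_value, fdr indexed by miRNA id.
    Lists come back sorted by decreasing |AS|.
    """
    for thr, name in ((p_threshold, "p"), (fdr_threshold, "FDR")):
        if not (0 < thr <= 1):
            raise ValueError(f"{name} threshold outside (0, 1]: {thr}")
    sig = results[(results["p_value"] <= p_threshold)
                  & (results["fdr"] <= fdr_threshold)]
    sig = sig.reindex(sig["as_score"].abs().sort_values(ascending=False).index)
    activated = list(sig.index[sig["as_score"] > 0])
    silenced = list(sig.index[sig["as_score"] < 0])
    return activated, silenced


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class MiRNAActivityModel:
    """Activity of a set of miRNAs inferred from a two-condition expression
    matrix and their predicted target sets.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log-scale expression, already normalised / batch adjusted.
    targets : TargetSetCollection
        Predicted target gene sets (e.g. miRanda / TargetScan, as GMT).
    case, comparator : str
        Phenotype labels defining the contrast (case minus comparator).
    statistic : {"welch_t", "log_ratio"}
        Per-gene change statistic used to rank the vector.
    affinity_quantile : float, optional
        If target sets carry binding scores, keep only the top fraction as
        the "high affinity" subset.  Off by default.
    """

    def __init__(self, matrix: ExpressionMatrix, targets: TargetSetCollection,
                 case: str, comparator: str, statistic: str = "welch_t",
                 affinity_quantile: float | None = None) -> None:
        self.matrix = matrix
        self.targets = targets
        self.case = case
        self.comparator = comparator
        self.statistic = statistic
        self.affinity_quantile = affinity_quantile

    @classmethod
    def from_files(cls, expression_path, annotation_path, gmt_path,
                   case: str, comparator: str, **kwargs) -> "MiRNAActivityModel":
        from .io import read_expression_table, read_gmt
        return cls(read_expression_table(expression_path, annotation_path),
                   read_gmt(gmt_path), case, comparator, **kwargs)

    def _effective_targets(self) -> TargetSetCollection:
        if self.affinity_quantile is None or self.targets.scores is None:
            return self.targets
        return TargetSetCollection(
            {mid: self.targets.high_affinity(mid, self.affinity_quantile)
             for mid in self.targets.mirna_ids}
        )

    def fit(self, n_permutations: int = 1000, seed: int | None = None,
            p_threshold: float = 0.005, fdr_threshold: float = 0.01
            ) -> "MiRNAActivityResults":
        """Score every miRNA, build the permutation null, and attach p / FDR
        and activation calls at the given thresholds."""
        if n_permutations < 100:
            warnings.warn(
                f"K={n_permutations} permutations is low for discovery; "
                "p resolution is coarse", stacklevel=2)
        vector = rank_expression_changes(self.matrix, self.case,
                                         self.comparator, self.statistic)
        targets = self._effective_targets()
        mirnas, member = _membership_matrix(vector, targets)
        observed = _score_membership(member)
        null = _null_from_membership(mirnas, member, n_permutations, seed)
        p = np.array([
            empirical_p(observed[i], null.scores[i]) for i in range(len(mirnas))
        ])
        fdr = np.array([
            estimate_fdr(observed, null.scores, s) for s in observed
        ])
        df = pd.DataFrame(
            {
                "m_used": member.sum(axis=1).astype(int),
                "as_score": observed,
                "p_value": p,
                "fdr": fdr,
            },
            index=pd.Index(mirnas, name="mirna_id"),
        )
        activated, silenced = call_deregulated(df, p_threshold, fdr_threshold)
        call = pd.Series(CALL_NONE, index=df.index)
        call[activated] = CALL_ACTIVATED
        call[silenced] = CALL_SILENCED
        df["call"] = call
        return MiRNAActivityResults(self, vector, df, null, seed,
                                    p_threshold, fdr_threshold)


class MiRNAActivityResults:
    """Fitted activity scores with permutation p-values, FDR and calls.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Columns ``m_used``, ``as_score``, ``p_value``, ``fdr``, ``call``
        indexed by miRNA id.
    null_scores_ : NullScores
        NS(x, k) matrix behind the p / FDR estimates.
    vector_ : ExpressionChangeVector
        The ranked change vector scored.
    """

    def __init__(self, model: MiRNAActivityModel,
                 vector: ExpressionChangeVector, results: pd.DataFrame,
                 null: NullScores, seed: int | None,
                 p_threshold: float, fdr_threshold: float) -> None:
        self.model = model
        self.vector_ = vector
        self.results_ = results
        self.null_scores_ = null
        self.seed = seed
        self.p_threshold = p_threshold
        self.fdr_threshold = fdr_threshold

    @property
    def activated_(self) -> list[str]:
        return self.deregulated()[0]

    @property
    def silenced_(self) -> list[str]:
        return self.deregulated()[1]

    def deregulated(self, p_threshold: float | None = None,
                    fdr_threshold: float | None = None
                    ) -> tuple[list[str], list[str]]:
        """(activated, silenced) miRNA lists, optionally at new thresholds."""
        return call_deregulated(
            self.results_,
            self.p_threshold if p_threshold is None else p_threshold,
            self.fdr_threshold if fdr_threshold is None else fdr_threshold,
        )

    def to_profile(self, label: str | None = None,
                   p_threshold: float | None = None,
                   fdr_threshold: float | None = None):
        """Deregulation profile (activated/silenced/universe) for set logic."""
        from .comparisons import DeregulationProfile
        activated, silenced = self.deregulated(p_threshold, fdr_threshold)
        return DeregulationProfile(
            label or f"{self.model.case} vs {self.model.comparator}",
            frozenset(activated), frozenset(silenced),
            frozenset(self.results_.index),
        )

    def summary(self, top: int = 10) -> SimpleTable:
        """Human-readable summary table of the strongest calls."""
        df = self.results_.reindex(
            self.results_["as_score"].abs().sort_values(ascending=False).index
        ).head(top)
        act, sil = self.deregulated()
        rows = [
            [mid, f"{r.m_used:d}", f"{r.as_score:+.3f}", f"{r.p_value:.4g}",
             f"{r.fdr:.4g}", r.call]
            for mid, r in df.iterrows()
        ]
        title = (
            f"miRNA activity: {self.model.case} vs {self.model.comparator} "
            f"(K={self.null_scores_.K}, p<={self.p_threshold}, "
            f"FDR<={self.fdr_threshold}; activated={len(act)}, "
            f"silenced={len(sil)})"
        )
        return SimpleTable(
            rows,
            headers=["miRNA", "m", "AS", "p", "FDR", "call"],
            title=title,
        )

    def write(self, path: str | Path, comments: Iterable[str] = ()) -> None:
        meta = [
            f"case={self.model.case}", f"comparator={self.model.comparator}",
            f"statistic={self.model.statistic}", f"K={self.null_scores_.K}",
            f"seed={self.seed}", f"p_threshold={self.p_threshold}",
            f"fdr_threshold={self.fdr_threshold}",
        ]
        write_table(self.results_, path, list(comments) + meta)

    def plot_scores(self, ax=None):
        """Volcano-style view: AS against -log10 empirical p."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        df = self.results_
        colors = df["call"].map({CALL_ACTIVATED: "tab:red",
                                 CALL_SILENCED: "tab:blue",
                                 CALL_NONE: "0.6"})
        ax.scatter(df["as_score"], -np.log10(df["p_value"]), c=colors, s=12)
        ax.set_xlabel("activity score (AS)")
        ax.set_ylabel("-log10 permutation p")
        ax.axvline(0, color="k", lw=0.5)
        return ax
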