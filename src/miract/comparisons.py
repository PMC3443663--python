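"""Cross-phenotype set logic and supporting statistics.

Covers: hypergeometric (one-sided Fisher) overlap tests between deregulated
miRNA lists, subtype-specific miRNA extraction, pathway-switching detection
(activated under pathway-on AND silenced under pathway-off), thresholding of
pathway-activation probabilities, one-tailed Welch tests for target
transcripts, and average-linkage hierarchical clustering on correlation
distance.

The overlap "universe" is always the set of miRNAs scored in both compared
analyses; it is carried explicitly on every profile and reported in outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FormatError, PathwayProbabilities, write_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeregulationProfile:
    """Activated/silenced miRNA sets for one condition contrast, with the
    universe of miRNAs that were actually scored."""

    label: str
    activated: frozenset[str]
    silenced: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if self.activated & self.silenced:
            raise ValueError(
                f"profile {self.label!r}: miRNA(s) both activated and "
                f"silenced: {sorted(self.activated & self.silenced)}"
            )
        if not (self.activated | self.silenced) <= self.universe:
            raise ValueError(
                f"profile {self.label!r}: deregulated miRNAs outside universe"
            )

    def to_frame(self) -> pd.DataFrame:
        call = {m: "none" for m in sorted(self.universe)}
        call.update({m: "activated" for m in self.activated})
        call.update({m: "silenced" for m in self.silenced})
        return pd.DataFrame({"call": pd.Series(call)}).rename_axis("mirna_id")

    def write(self, path: str | Path, comments: Iterable[str] = ()) -> None:
        write_table(self.to_frame(), path,
                    list(comments) + [f"label={self.label}"])


def read_profile(path: str | Path) -> DeregulationProfile:
    label = Path(path).stem
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("label="):
                label = body.split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    calls = df["call"]
    return DeregulationProfile(
        label,
        frozenset(calls.index[calls == "activated"].astype(str)),
        frozenset(calls.index[calls == "silenced"].astype(str)),
        frozenset(calls.index.astype(str)),
    )


def overlap_test(set_a: Iterable[str], set_b: Iterable[str],
                 universe: Iterable[str]) -> tuple[int, float]:
    """Overlap size and one-sided (enrichment) hypergeometric p.

    p = P(overlap >= observed) drawing |B| items from a universe containing
    |A| marked items — the one-sided Fisher exact test on the 2x2 table.
    """
    a, b, u = frozenset(set_a), frozenset(set_b), frozenset(universe)
    if not u:
        raise ValueError("empty universe")
    if not a <= u or not b <= u:
        raise ValueError("sets must be contained in the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return k, min(p, 1.0)


def subtype_specific(profiles: Sequence[DeregulationProfile]
                     ) -> dict[str, dict[str, frozenset[str]]]:
    """miRNAs deregulated in exactly one condition, per direction.

    Returns {label: {"activated": set, "silenced": set}} where each set holds
    the miRNAs deregulated in that direction in that profile and in no other.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    universes = {p.universe for p in profiles}
    if len(universes) != 1:
        raise ValueError("profiles have differing universes")
    out: dict[str, dict[str, frozenset[str]]] = {}
    for p in profiles:
        others = [q for q in profiles if q is not p]
        out[p.label] = {
            "activated": p.activated - frozenset().union(
                *(q.activated for q in others)),
            "silenced": p.silenced - frozenset().union(
                *(q.silenced for q in others)),
        }
    return out


def ras_switching(profile_active: DeregulationProfile,
                  profile_inactive: DeregulationProfile
                  ) -> tuple[frozenset[str], int, float]:
    """miRNAs that flip from silenced (pathway-off) to activated (pathway-on).

    Returns (switching set, overlap count, one-sided hypergeometric p of the
    overlap within the shared universe).
    """
    universe = profile_active.universe & profile_inactive.universe
    switching = frozenset(profile_active.activated
                          & profile_inactive.silenced & universe)
    k, p = overlap_test(profile_active.activated & universe,
                        profile_inactive.silenced & universe, universe)
    return switching, k, p


def threshold_pathway(probabilities: PathwayProbabilities,
                      cutoff: float = 0.8) -> tuple[list[str], list[str]]:
    """Partition samples into pathway-active (P >= cutoff, inclusive) and
    pathway-inactive."""
    if not (0 < cutoff < 1):
        raise ValueError(f"cutoff outside (0,1): {cutoff}")
    active = [s for s, p in probabilities.probabilities.items() if p >= cutoff]
    inactive = [s for s in probabilities.probabilities if s not in set(active)]
    if not active:
        warnings.warn("no sample reaches the pathway-activation cutoff; "
                      "pathway analysis will be skipped", stacklevel=2)
    return active, inactive


def welch_one_tailed(group_a: Sequence[float], group_b: Sequence[float],
                     alternative: str = "a_less_than_b"
                     ) -> tuple[float, float, float]:
    """One-tailed Welch (heteroskedastic) t-test: (t, df, p).

    ``alternative`` is "a_less_than_b" or "a_greater_than_b".  Degenerate
    all-equal groups return p = 0.5 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if alternative not in ("a_less_than_b", "a_greater_than_b"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        warnings.warn("both groups constant and equal; p = 0.5 by convention",
                      stacklevel=2)
        return 0.0, float(len(a) + len(b) - 2), 0.5
    side = "less" if alternative == "a_less_than_b" else "greater"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=side)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Average-linkage clustering
# ---------------------------------------------------------------------------

def correlation_distance(profile_matrix: pd.DataFrame) -> np.ndarray:
    """1 - Pearson correlation between rows of ``profile_matrix``."""
    vals = profile_matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    flat = [str(profile_matrix.index[i]) for i in np.nonzero(sd == 0)[0]]
    if flat:
        raise FormatError(
            f"zero-variance item(s) under correlation distance: {flat}"
        )
    d = 1.0 - np.corrcoef(vals)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float
    new_id: int


def cluster_average_linkage(
    data: pd.DataFrame | np.ndarray,
    distance: str = "one_minus_pearson",
) -> list[Merge]:
    """Agglomerative average-linkage (UPGMA) clustering.

    ``distance`` is "one_minus_pearson" (rows of a profile matrix) or
    "precomputed" (square distance matrix).  Items are 0..n-1; merged
    clusters get ids n, n+1, ...  The merged pair is always the minimum
    inter-cluster average distance, ties broken by the smallest (left, right)
    id pair.  Average-linkage heights can decrease on non-metric
    (correlation) distances; a violation is logged, not fatal.
    """
    if distance == "one_minus_pearson":
        frame = data if isinstance(data, pd.DataFrame) else pd.DataFrame(data)
        d = correlation_distance(frame)
    elif distance == "precomputed":
        d = np.asarray(data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("precomputed distance must be a square matrix")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two items to cluster")

    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[Merge] = []
    next_id = n
    last_height = -np.inf
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (i, j), h = best
        if h < last_height - 1e-12:
            logger.warning(
                "non-monotone merge height %.6g after %.6g (non-metric "
                "distance)", h, last_height)
        last_height = max(last_height, h)
        merges.append(Merge(i, j, h, next_id))
        active -= {i, j}
        # UPGMA: size-weighted average over constituent item pairs
        for k in sorted(active):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(k, next_id)] = dnew
        del dist[(i, j)]
        sizes[next_id] = sizes[i] + sizes[j]
        active.add(next_id)
        next_id += 1
    return merges


def dendrogram_newick(merges: list[Merge],
                      labels: Sequence[str] | None = None) -> str:
    """Newick string with ultrametric branch lengths (half merge heights)."""
    n = len(merges) + 1
    labels = list(labels) if labels is not None else [str(i) for i in range(n)]
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    for m in merges:
        h = m.height / 2.0
        left = f"{node[m.left]}:{h - height[m.left]:.6g}"
        right = f"{node[m.right]}:{h - height[m.right]:.6g}"
        node[m.new_id] = f"({left},{right})"
        height[m.new_id] = h
    return node[merges[-1].new_id] + ";"


def write_subtype_report(unique: dict[str, dict[str, frozenset[str]]],
                         path: str | Path,
                         comments: Iterable[str] = ()) -> None:
    rows = [
        {"condition": label, "direction": direction, "mirna_id": mid}
        for label, dirs in unique.items()
        for direction, mirnas in dirs.items()
        for mid in sorted(mirnas)
    ]
    df = pd.DataFrame(rows, columns=["condition", "direction", "mirna_id"])
    write_table(df, path, comments, index=False)
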