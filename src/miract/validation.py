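"""Independent reference implementations and seeded validation experiments.

Every statistic with a non-trivial fast path in this package has a naive
reference implementation here — explicit loops, exhaustive enumeration,
exact tail sums — written against the definition rather than sharing code
with the production path.  The experiment functions run the package on
synthetic data under fixed study-like conditions (2000 genes, 100 miRNAs,
20 vs 20 samples, effect size 1.5 noise-SDs where effects are planted) and
measure calibration, recovery and oracle agreement.  They are what the
acceptance script and the acceptance tests execute.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats

from .activity import MiRNAActivityModel, empirical_p, estimate_fdr
from .comparisons import Merge, cluster_average_linkage, threshold_pathway
from .enrichment import ease_score
from .io import PathwayProbabilities, PrecursorSet
from .smallrna import (DELETION_IN_READ, EXACT, INSERTION_IN_READ,
                       SUBSTITUTION, map_read, phred_mean_accuracy)
from .synthetic import (SimulationSpec, SwitchProgram, generate_expression,
                        generate_pathway_probabilities)

MIR422A_PRECURSOR = "ACUGGACUUAGGGUCAGAAGGC"
MIR422A_ALTERED_READ = "ACUGGACUUGGGUCAGAAGGC"


def _child_seeds(seed: int | None, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# Reference implementations (oracles)
# ---------------------------------------------------------------------------

def fdr_brute_force(as_scores: Sequence[float], null_scores: np.ndarray,
                    as_star: float) -> float:
    """FDR ratio by explicit enumeration of every (x, k) pair."""
    ns = [float(v) for row in np.atleast_2d(null_scores) for v in row]
    obs = [float(v) for v in as_scores]
    if as_star >= 0:
        ns_side = [v for v in ns if v >= 0]
        obs_side = [v for v in obs if v >= 0]
        ns_tail = sum(1 for v in ns_side if v >= as_star)
        obs_tail = sum(1 for v in obs_side if v >= as_star)
    else:
        ns_side = [v for v in ns if v <= 0]
        obs_side = [v for v in obs if v <= 0]
        ns_tail = sum(1 for v in ns_side if v <= as_star)
        obs_tail = sum(1 for v in obs_side if v <= as_star)
    if not ns_side or not obs_side or obs_tail == 0:
        return 1.0
    return min((ns_tail / len(ns_side)) / (obs_tail / len(obs_side)), 1.0)


def activity_score_brute_force(target_ranks: Sequence[int], n: int) -> float:
    """Running-sum extremum by a plain Python walk over every rank."""
    targets = set(target_ranks)
    m = len(targets)
    up = ((n - m) / m) ** 0.5
    down = (m / (n - m)) ** 0.5
    s = 0.0
    best, best_abs = 0.0, -1.0
    for r in range(n):
        s += up if r in targets else -down
        if abs(s) > best_abs + 1e-12:
            best, best_abs = s, abs(s)
    return -best

def hypergeom_tail_exact(overlap: int, n_universe: int, n_marked: int,
                         n_drawn: int) -> float:
    """P(X >= overlap) by exact tail summation with integer binomials."""
    total = comb(n_universe, n_drawn)
    upper = min(n_marked, n_drawn)
    acc = 0
    for k in range(overlap, upper + 1):
        acc += comb(n_marked, k) * comb(n_universe - n_marked, n_drawn - k)
    return acc / total


def map_read_brute_force(read: str, precursors: PrecursorSet
                         ) -> list[tuple[str, str, int]]:
    """All best (mirna, class, offset) mappings by definitional enumeration:
    every substring of every precursor is tested against the read for each
    difference class by trying every deletion/insertion position."""
    read = read.upper().replace("U", "T")
    exact, near = [], []
    for mid in precursors:
        ref = precursors[mid]
        L = len(read)
        for off in range(len(ref) - L + 1):
            if ref[off:off + L] == read:
                exact.append((mid, EXACT, off))
        for off in range(len(ref) - L + 1):
            if sum(a != b for a, b in zip(read, ref[off:off + L])) == 1:
                near.append((mid, SUBSTITUTION, off))
        for off in range(len(ref) - (L + 1) + 1):
            window = ref[off:off + L + 1]
            if any(window[:i] + window[i + 1:] == read
                   for i in range(L + 1)):
                near.append((mid, DELETION_IN_READ, off))
        if L >= 2:
            for off in range(len(ref) - (L - 1) + 1):
                window = ref[off:off + L - 1]
                if any(read[:i] + read[i + 1:] == window for i in range(L)):
                    near.append((mid, INSERTION_IN_READ, off))
    return exact if exact else near


def upgma_brute_force(d: np.ndarray) -> list[Merge]:
    """Average-linkage agglomeration recomputing every inter-cluster average
    from the original item-level matrix at each step."""
    n = d.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[Merge] = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dist = float(np.mean(
                    [d[i, j] for i in clusters[a] for j in clusters[b]]))
                key = (dist, a, b)
                if best is None or key < best:
                    best = key
        dist, a, b = best
        merges.append(Merge(a, b, dist, next_id))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def phred_worked_example() -> float:
    """Implied base-call accuracy at mean Phred 30 (percent)."""
    return phred_mean_accuracy(30.0)


def fdr_oracle_experiment(n_instances: int = 100, seed: int | None = 0
                          ) -> dict:
    """Exact agreement of estimate_fdr with brute-force enumeration on random
    small instances (<=10 miRNAs, <=20 permutations)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n_mirnas = int(rng.integers(1, 11))
        k = int(rng.integers(1, 21))
        obs = rng.normal(0, 2, n_mirnas)
        ns = rng.normal(0, 2, (n_mirnas, k))
        as_star = float(obs[rng.integers(n_mirnas)])
        fast = estimate_fdr(obs, ns, as_star)
        slow = fdr_brute_force(obs, ns, as_star)
        agree += abs(fast - slow) < 1e-12
    return {"agreement_pct": 100.0 * agree / n_instances, "n": n_instances}


def null_calibration_experiment(n_seeds: int = 20, K: int = 200,
                                seed: int | None = 0, n_genes: int = 2000,
                                n_mirnas: int = 100, n_per_group: int = 20,
                                alpha: float = 0.005) -> dict:
    """Global-null calibration: with no planted effects, the fraction of
    miRNAs at p <= alpha should sit near alpha, and per-seed p-values should
    look uniform (KS at the 0.01 level)."""
    p_all: list[np.ndarray] = []
    ks_pass = 0
    for s in _child_seeds(seed, n_seeds):
        spec = SimulationSpec(n_genes=n_genes, n_mirnas=n_mirnas,
                              n_case=n_per_group, n_comparator=n_per_group,
                              effect_size=0.0, seed=s)
        matrix, targets, _ = generate_expression(spec)
        res = MiRNAActivityModel(matrix, targets, spec.case_label,
                                 spec.comparator_label).fit(
            n_permutations=K, seed=s)
        p = res.results_["p_value"].to_numpy()
        p_all.append(p)
        ks_pass += stats.kstest(p, "uniform").pvalue >= 0.01
    pooled = np.concatenate(p_all)
    frac = float((pooled <= alpha).mean())
    sd = np.sqrt(alpha * (1 - alpha) / pooled.size)
    return {
        "fraction_p_le_alpha": frac,
        "alpha": alpha,
        "within_3sd": bool(abs(frac - alpha) <= 3 * sd),
        "binomial_3sd": float(3 * sd),
        "ks_uniform_pass": int(ks_pass),
        "n_seeds": n_seeds,
        "n_pvalues": int(pooled.size),
    }


def planted_recovery_experiment(n_seeds: int = 10, K: int = 1000,
                                seed: int | None = 0,
                                p_threshold: float = 0.005,
                                fdr_threshold: float = 0.05) -> dict:
    """Recovery of 10 planted activated + 10 planted silenced miRNAs
    (effect 1.5 noise-SDs, 50 targets each) at the validation thresholds."""
    recovered = 0
    direction_ok = 0
    called_planted = 0
    fps: list[int] = []
    n_planted_total = 0
    for s in _child_seeds(seed, n_seeds):
        spec = SimulationSpec.with_planted(10, 10, seed=s)
        matrix, targets, truth = generate_expression(spec)
        res = MiRNAActivityModel(matrix, targets, spec.case_label,
                                 spec.comparator_label).fit(
            n_permutations=K, seed=s, p_threshold=p_threshold,
            fdr_threshold=fdr_threshold)
        act, sil = res.deregulated()
        planted_act = {m for m, v in truth.status.items() if v == "activated"}
        planted_sil = {m for m, v in truth.status.items() if v == "silenced"}
        n_planted_total += len(planted_act) + len(planted_sil)
        good = (set(act) & planted_act) | (set(sil) & planted_sil)
        bad_dir = (set(act) & planted_sil) | (set(sil) & planted_act)
        recovered += len(good)
        called_planted += len(good) + len(bad_dir)
        direction_ok += len(good)
        fps.append(len([m for m in list(act) + list(sil)
                        if truth.status[m] == "null"]))
    return {
        "recovery_pct": 100.0 * recovered / n_planted_total,
        "direction_accuracy_pct":
            100.0 * direction_ok / called_planted if called_planted else 0.0,
        "mean_false_positives_per_run": float(np.mean(fps)),
        "max_false_positives_per_run": int(np.max(fps)),
        "n_seeds": n_seeds,
    }


def switch_recovery_experiment(n_seeds: int = 10, K: int = 1000,
                               seed: int | None = 0, n_switch: int = 8,
                               p_threshold: float = 0.005,
                               fdr_threshold: float = 0.01) -> dict:
    """Recovery of a planted pathway-switch program: miRNAs whose targets
    are repressed only in pathway-active tumors must come back as exactly
    the activated(active) ∩ silenced(inactive) intersection."""
    from .comparisons import ras_switching
    exact = 0
    for s in _child_seeds(seed, n_seeds):
        mirnas = frozenset(f"miR-SIM-{i:03d}" for i in range(1, n_switch + 1))
        program = SwitchProgram(mirnas)
        spec = SimulationSpec(n_case=40, n_comparator=20,
                              switch_program=program, seed=s)
        matrix, targets, truth = generate_expression(spec)
        probs = generate_pathway_probabilities(matrix, program, seed=s)
        tumor = [x for x in matrix.sample_ids
                 if matrix.phenotype[x] != spec.comparator_label]
        active, inactive = threshold_pathway(
            PathwayProbabilities({x: probs[x] for x in tumor}), 0.8)
        comparator = matrix.samples_with(spec.comparator_label)
        profiles = {}
        for label, group in (("pathway_active", active),
                             ("pathway_inactive", inactive)):
            pheno = matrix.phenotype.copy()
            pheno[group] = label
            sub = matrix.subset_samples(group + comparator, pheno)
            res = MiRNAActivityModel(sub, targets, label,
                                     spec.comparator_label).fit(
                n_permutations=K, seed=s, p_threshold=p_threshold,
                fdr_threshold=fdr_threshold)
            profiles[label] = res.to_profile(label)
        switching, _, _ = ras_switching(profiles["pathway_active"],
                                        profiles["pathway_inactive"])
        planted = {m for m, v in truth.status.items() if v == "switching"}
        exact += switching == planted
    return {"exact_recovery_seeds": int(exact), "n_seeds": n_seeds}


def mapper_oracle_experiment(n_pairs: int = 200, seed: int | None = 0
                             ) -> dict:
    """Agreement of map_read with the definitional enumeration oracle on
    random precursor/read pairs (lengths <= 30), plus the documented
    single-deletion example read (deletion class, zero exact)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    agree = 0
    for _ in range(n_pairs):
        plen = int(rng.integers(12, 31))
        ref = "".join(rng.choice(bases, plen))
        pre = PrecursorSet({"p": ref})
        rlen = int(rng.integers(10, min(plen, 30) + 1))
        mode = rng.integers(5)
        off = int(rng.integers(0, plen - rlen + 1))
        read = ref[off:off + rlen]
        if mode == 1:  # one substitution
            i = int(rng.integers(rlen))
            read = (read[:i]
                    + str(rng.choice([b for b in "ACGT" if b != read[i]]))
                    + read[i + 1:])
        elif mode == 2 and off + rlen < plen:  # deletion in read
            i = int(rng.integers(rlen))
            read = (read + ref[off + rlen])[:i] + (read + ref[off + rlen])[i + 1:]
        elif mode == 3:  # insertion in read
            i = int(rng.integers(rlen + 1))
            read = read[:i] + str(rng.choice(bases)) + read[i:]
            read = read[:30]
        elif mode == 4:  # unrelated sequence
            read = "".join(rng.choice(bases, rlen))
        got = {(m.mirna_id, m.difference_class, m.offset)
               for m in map_read(read, pre)}
        want = set(map_read_brute_force(read, pre))
        agree += got == want
    mir422a = PrecursorSet(
        {"hsa-miR-422a": MIR422A_PRECURSOR.replace("U", "T")},
        frozenset({"hsa-miR-422a"}))
    maps = map_read(MIR422A_ALTERED_READ, mir422a)
    return {
        "agreement_pct": 100.0 * agree / n_pairs,
        "n": n_pairs,
        "mir422a_classes": sorted({m.difference_class for m in maps}),
        "mir422a_n_exact": sum(m.difference_class == EXACT for m in maps),
    }


def enrichment_property_experiment(n_tables: int = 200, seed: int | None = 0
                                   ) -> dict:
    """EASE conservativeness (ease_p >= fisher_p) and exact tail-sum
    agreement on random tables with universe size <= 30."""
    rng = np.random.default_rng(seed)
    conservative = 0
    oracle_ok = 0
    for _ in range(n_tables):
        n_u = int(rng.integers(5, 31))
        universe = [f"g{i}" for i in range(n_u)]
        hits = set(rng.choice(universe, int(rng.integers(0, n_u + 1)),
                              replace=False))
        theme = set(rng.choice(universe, int(rng.integers(1, n_u + 1)),
                               replace=False))
        ease_p, fisher_p, c = ease_score(hits, theme, universe)
        conservative += ease_p >= fisher_p - 1e-12
        if hits:
            want_f = hypergeom_tail_exact(c["overlap"], n_u, c["n_theme"],
                                          c["n_hits"])
            want_e = hypergeom_tail_exact(max(c["overlap"] - 1, 0), n_u,
                                          c["n_theme"], c["n_hits"])
        else:
            want_f = want_e = 1.0
        oracle_ok += (abs(fisher_p - want_f) < 1e-9
                      and abs(ease_p - want_e) < 1e-9)
    return {
        "conservative_pct": 100.0 * conservative / n_tables,
        "oracle_agreement_pct": 100.0 * oracle_ok / n_tables,
        "n": n_tables,
    }


def activity_closed_forms() -> dict:
    """The three closed-form running-sum scores on a 10-gene vector with 2
    targets: bottom ranks -> +4, top ranks -> -4, middle tie -> +2."""
    from .activity import _score_from_ranks
    return {
        "targets_top": _score_from_ranks(np.array([0, 1]), 10),
        "targets_bottom": _score_from_ranks(np.array([8, 9]), 10),
        "targets_middle_tie": _score_from_ranks(np.array([4, 5]), 10),
    }


def clustering_oracle_experiment(n_matrices: int = 50, n_items: int = 5,
                                 seed: int | None = 0) -> dict:
    """Merge-for-merge agreement of the incremental average-linkage
    implementation with brute-force re-averaging agglomeration."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_matrices):
        d = rng.uniform(0.1, 10.0, (n_items, n_items))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        fast = cluster_average_linkage(d, distance="precomputed")
        slow = upgma_brute_force(d)
        ok = len(fast) == len(slow) and all(
            f.left == s.left and f.right == s.right
            and abs(f.height - s.height) < 1e-9
            for f, s in zip(fast, slow))
        agree += ok
    return {"agreement_pct": 100.0 * agree / n_matrices, "n": n_matrices}
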