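"""Orchestration of full runs: discovery (activity + deregulation calls per
condition pair) and pathway-switch analysis, with declarative YAML config,
seeded reproducibility, and provenance comments on every output file.

Science parameters (thresholds, K, statistic, cutoff) live only in the
config; command-line flags select config and output locations.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .activity import MiRNAActivityModel, MiRNAActivityResults
from .comparisons import (DeregulationProfile, ras_switching,
                          threshold_pathway)
from .io import (ExpressionMatrix, PathwayProbabilities, TargetSetCollection,
                 read_expression_table, read_gmt,
                 read_pathway_probabilities, write_table)
from .preprocess import batch_adjust, dasl_normalize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    expression: str
    annotation: str
    gmt: str
    case: str
    comparator: str
    outdir: str = "miract_out"
    batch_column: str = "batch"
    phenotype_column: str = "phenotype"
    statistic: str = "welch_t"
    normalize: bool = False          # virtual-reference mean scaling first
    adjust_batches: bool = True
    n_permutations: int = 1000
    p_threshold: float = 0.005
    fdr_threshold: float = 0.01
    pathway_cutoff: float = 0.8
    seed: int | None = None
    pathway_probabilities: str | None = None

    def __post_init__(self) -> None:
        for thr, name in ((self.p_threshold, "p_threshold"),
                          (self.fdr_threshold, "fdr_threshold")):
            if not (0 < thr <= 1):
                raise ValueError(f"{name} outside (0, 1]: {thr}")
        if self.n_permutations < 100:
            warnings.warn(
                f"n_permutations={self.n_permutations} is below 100; "
                "discovery p/FDR resolution will be coarse", stacklevel=2)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    def provenance(self) -> list[str]:
        return [
            f"miract_version={__version__}",
            f"config_sha256={self.digest()}",
            f"seed={self.seed}",
            f"K={self.n_permutations}",
            f"p_threshold={self.p_threshold}",
            f"fdr_threshold={self.fdr_threshold}",
        ]


def _check_inputs(config: RunConfig) -> None:
    paths = [config.expression, config.annotation, config.gmt]
    if config.pathway_probabilities:
        paths.append(config.pathway_probabilities)
    missing = [p for p in paths if not Path(p).is_file()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")


def _load_and_preprocess(config: RunConfig
                         ) -> tuple[ExpressionMatrix, TargetSetCollection]:
    matrix = read_expression_table(config.expression, config.annotation,
                                   config.batch_column,
                                   config.phenotype_column)
    targets = read_gmt(config.gmt)
    if config.normalize:
        matrix = dasl_normalize(matrix)
    if config.adjust_batches and matrix.batch.nunique() > 1:
        matrix = batch_adjust(matrix)
    return matrix, targets


def _run_contrast(matrix: ExpressionMatrix, targets: TargetSetCollection,
                  config: RunConfig, case: str, comparator: str
                  ) -> MiRNAActivityResults:
    model = MiRNAActivityModel(matrix, targets, case, comparator,
                               statistic=config.statistic)
    return model.fit(n_permutations=config.n_permutations, seed=config.seed,
                     p_threshold=config.p_threshold,
                     fdr_threshold=config.fdr_threshold)


def run_discovery(config: RunConfig
                  ) -> tuple[DeregulationProfile, MiRNAActivityResults]:
    """Normalise -> batch adjust -> change vector -> activity/p/FDR -> calls.

    Writes the change vector, the full results table and the deregulation
    profile under ``config.outdir``, each with provenance comments.
    """
    _check_inputs(config)
    matrix, targets = _load_and_preprocess(config)
    logger.info("discovery run: %s vs %s, K=%d, seed=%s", config.case,
                config.comparator, config.n_permutations, config.seed)
    res = _run_contrast(matrix, targets, config, config.case,
                        config.comparator)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    res.vector_.write(outdir / "change_vector.tsv", prov)
    res.write(outdir / "activity_results.tsv", prov)
    profile = res.to_profile(f"{config.case} vs {config.comparator}")
    profile.write(outdir / "profile.tsv", prov)
    return profile, res


def run_switch_analysis(config: RunConfig,
                        probabilities: PathwayProbabilities | None = None):
    """Pathway-switch analysis: threshold probabilities, run the pathway-
    active and pathway-inactive contrasts against the comparator, intersect.

    Returns (switching set, profile_active, profile_inactive, overlap p) or
    None when a partition side is empty (skipped with a warning).
    """
    _check_inputs(config)
    if probabilities is None:
        if not config.pathway_probabilities:
            raise ValueError("no pathway probabilities supplied")
        probabilities = read_pathway_probabilities(
            config.pathway_probabilities)
    matrix, targets = _load_and_preprocess(config)
    tumor = [s for s in matrix.sample_ids
             if matrix.phenotype[s] != config.comparator]
    missing = [s for s in tumor if s not in probabilities.probabilities]
    if missing:
        raise ValueError(
            f"tumor sample(s) without pathway probability: {missing}")
    active, inactive = threshold_pathway(
        PathwayProbabilities(
            {s: probabilities[s] for s in tumor}),
        config.pathway_cutoff)
    if not active or not inactive:
        warnings.warn("pathway partition has an empty side; switch analysis "
                      "skipped", stacklevel=2)
        return None
    comparator_samples = matrix.samples_with(config.comparator)
    pheno = matrix.phenotype.copy()
    pheno[active] = "pathway_active"
    pheno[inactive] = "pathway_inactive"

    results = {}
    for label, group in (("pathway_active", active),
                         ("pathway_inactive", inactive)):
        sub = matrix.subset_samples(group + comparator_samples, pheno)
        results[label] = _run_contrast(sub, targets, config, label,
                                       config.comparator)
    profile_active = results["pathway_active"].to_profile("pathway_active")
    profile_inactive = results["pathway_inactive"].to_profile(
        "pathway_inactive")
    switching, k, p = ras_switching(profile_active, profile_inactive)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance() + [
        f"pathway_cutoff={config.pathway_cutoff}",
        f"n_active={len(active)}", f"n_inactive={len(inactive)}",
        f"overlap={k}", f"overlap_p={p:.4g}",
    ]
    profile_active.write(outdir / "profile_pathway_active.tsv", prov)
    profile_inactive.write(outdir / "profile_pathway_inactive.tsv", prov)
    import pandas as pd
    write_table(
        pd.DataFrame({"mirna_id": sorted(switching)}),
        outdir / "switching_mirnas.tsv", prov, index=False)
    return switching, profile_active, profile_inactive, p
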