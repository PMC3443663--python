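"""Synthetic two-condition expression data and small-RNA reads with planted
miRNA-driven structure.

The expression generator emulates the statistical skeleton of a tumor-vs-
normal microarray compendium: log-scale gene intensities around a baseline
of 8 with Gaussian noise, per-miRNA target sets drawn without replacement
(sets may overlap between miRNAs, as real prediction sets do), additive
per-batch offsets, and planted effects — for an "activated" miRNA its
targets are shifted down by delta*sigma in the case samples (repression);
for a "silenced" miRNA, up.  An optional switch program splits the case
samples into pathway-active and pathway-inactive groups in which the
program's miRNA targets are repressed and de-repressed respectively,
yielding miRNAs that flip call between the two contrasts.

The read generator emits leading-21-base windows of precursor sequences,
optionally carrying a planted single-base edit (deletion, substitution or
insertion), with Phred qualities drawn from a discretised normal.

Defaults mirror a tumor-vs-normal compendium loosely at desk scale: 2000 genes, 100
miRNAs, 50 targets each, 20 case vs 20 comparator samples, noise SD 1.0 and
effect size 1.5 noise-SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, PathwayProbabilities, PrecursorSet,
                 ReadSet, SequenceRead, TargetSetCollection)

READ_WINDOW = 21  # leading-window width, the mature-miRNA length


@dataclass(frozen=True)
class SwitchProgram:
    """miRNAs whose targets are repressed only in pathway-active case
    samples (and de-repressed in pathway-inactive ones)."""

    mirnas: frozenset[str]
    active_label: str = "RAS_active"
    inactive_label: str = "RAS_inactive"


@dataclass
class SimulationSpec:
    """Parameters of one synthetic expression experiment."""

    n_genes: int = 2000
    n_mirnas: int = 100
    targets_per_mirna: int = 50
    n_case: int = 20
    n_comparator: int = 20
    effect_size: float = 1.5      # delta, in units of noise_sd
    noise_sd: float = 1.0         # sigma of the log-scale Gaussian noise
    baseline: float = 8.0
    planted_activated: frozenset[str] = field(default_factory=frozenset)
    planted_silenced: frozenset[str] = field(default_factory=frozenset)
    batch_labels: tuple[str, ...] = ("b1",)
    batch_offsets: Mapping[str, float] = field(default_factory=dict)
    switch_program: SwitchProgram | None = None
    case_label: str = "case"
    comparator_label: str = "normal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.planted_activated & self.planted_silenced:
            raise ValueError("planted activated/silenced sets overlap")
        for n, name in ((self.n_genes, "n_genes"), (self.n_mirnas, "n_mirnas"),
                        (self.targets_per_mirna, "targets_per_mirna"),
                        (self.n_case, "n_case"),
                        (self.n_comparator, "n_comparator")):
            if n < 1:
                raise ValueError(f"{name} must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.targets_per_mirna > self.n_genes:
            raise ValueError("targets_per_mirna exceeds n_genes")

    @classmethod
    def with_planted(cls, n_activated: int = 10, n_silenced: int = 10,
                     **kwargs) -> "SimulationSpec":
        """Spec planting the first miRNAs as activated / silenced."""
        spec = cls(**kwargs)
        ids = _mirna_ids(spec.n_mirnas)
        if n_activated + n_silenced > spec.n_mirnas:
            raise ValueError("more planted miRNAs than miRNAs")
        spec.planted_activated = frozenset(ids[:n_activated])
        spec.planted_silenced = frozenset(
            ids[n_activated:n_activated + n_silenced])
        return spec


@dataclass
class GroundTruth:
    """Planted truth behind a synthetic dataset."""

    status: dict[str, str]  # miRNA -> activated | silenced | null | switching
    target_overlap_rate: float = 0.0
    read_origin: dict[str, str] = field(default_factory=dict)
    read_edit: dict[str, str] = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-SIM-{i:03d}" for i in range(1, n + 1)]


def _overlap_rate(sets: Sequence[frozenset[str]]) -> float:
    """Mean pairwise Jaccard overlap among target sets (0 if single set)."""
    if len(sets) < 2:
        return 0.0
    # Sampled estimate keeps this O(n) for large collections
    rng = np.random.default_rng(0)
    pairs = min(200, len(sets) * (len(sets) - 1) // 2)
    idx = [tuple(rng.choice(len(sets), 2, replace=False)) for _ in range(pairs)]
    jac = [len(sets[i] & sets[j]) / len(sets[i] | sets[j]) for i, j in idx]
    return float(np.mean(jac))


def generate_expression(spec: SimulationSpec
                        ) -> tuple[ExpressionMatrix, TargetSetCollection,
                                   GroundTruth]:
    """Synthesise (matrix, target sets, ground truth) for a simulation spec.

    With a switch program the case samples are split in half into
    pathway-active and pathway-inactive phenotypes; otherwise all case
    samples carry ``spec.case_label``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    mirnas = _mirna_ids(spec.n_mirnas)

    if spec.switch_program is not None:
        n_active = spec.n_case // 2
        case_phenos = ([spec.switch_program.active_label] * n_active
                       + [spec.switch_program.inactive_label]
                       * (spec.n_case - n_active))
    else:
        case_phenos = [spec.case_label] * spec.n_case
    phenos = case_phenos + [spec.comparator_label] * spec.n_comparator
    samples = [f"S{i:03d}" for i in range(1, len(phenos) + 1)]

    values = rng.normal(spec.baseline, spec.noise_sd,
                        (spec.n_genes, len(samples)))

    target_sets = {
        mid: frozenset(np.asarray(genes, dtype=object)[
            rng.choice(spec.n_genes, spec.targets_per_mirna, replace=False)
        ].tolist())
        for mid in mirnas
    }
    gene_index = {g: i for i, g in enumerate(genes)}
    pheno_arr = np.asarray(phenos, dtype=object)

    status = {mid: "null" for mid in mirnas}
    delta = spec.effect_size * spec.noise_sd

    def shift(mirna: str, columns: np.ndarray, amount: float) -> None:
        rows = [gene_index[g] for g in target_sets[mirna]]
        values[np.ix_(rows, np.nonzero(columns)[0])] += amount

    case_cols = np.isin(pheno_arr, list(set(case_phenos)))
    for mid in spec.planted_activated:
        shift(mid, case_cols, -delta)  # repression in case = activation
        status[mid] = "activated"
    for mid in spec.planted_silenced:
        shift(mid, case_cols, +delta)
        status[mid] = "silenced"

    if spec.switch_program is not None:
        active_cols = pheno_arr == spec.switch_program.active_label
        inactive_cols = pheno_arr == spec.switch_program.inactive_label
        for mid in spec.switch_program.mirnas:
            shift(mid, active_cols, -delta)
            shift(mid, inactive_cols, +delta)
            status[mid] = "switching"

    batch_cycle = [spec.batch_labels[i % len(spec.batch_labels)]
                   for i in range(len(samples))]
    for j, b in enumerate(batch_cycle):
        values[:, j] += spec.batch_offsets.get(b, 0.0)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.Series(batch_cycle, index=samples),
        pd.Series(phenos, index=samples),
    )
    truth = GroundTruth(
        status,
        target_overlap_rate=_overlap_rate(list(target_sets.values())),
    )
    return matrix, TargetSetCollection(target_sets), truth


def generate_pathway_probabilities(matrix: ExpressionMatrix,
                                   program: SwitchProgram,
                                   seed: int | None = None
                                   ) -> PathwayProbabilities:
    """Per-sample activation probabilities consistent with the planted
    switch phenotypes: active samples ~ U(0.85, 0.99), inactive ~ U(0.05,
    0.5), comparator samples ~ U(0.05, 0.5)."""
    rng = np.random.default_rng(seed)
    probs = {}
    for s in matrix.sample_ids:
        if matrix.phenotype[s] == program.active_label:
            probs[s] = float(rng.uniform(0.85, 0.99))
        else:
            probs[s] = float(rng.uniform(0.05, 0.5))
    return PathwayProbabilities(probs)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EditSpec:
    """A planted single-base edit inside the leading read window."""

    position: int
    op: str  # delete | substitute | insert
    base: str | None = None

    def __post_init__(self) -> None:
        if self.op not in ("delete", "substitute", "insert"):
            raise ValueError(f"unknown edit op {self.op!r}")
        if not (0 <= self.position < READ_WINDOW):
            raise ValueError(
                f"edit position {self.position} outside the leading "
                f"{READ_WINDOW}-base window")
        if self.op in ("substitute", "insert") and (
                self.base is None or self.base not in "ACGT"):
            raise ValueError(f"{self.op} edit needs a base in ACGT")


def _edited_read(precursor: str, edit: EditSpec) -> str:
    if len(precursor) < READ_WINDOW + 1:
        raise ValueError("precursor too short for an edited read window")
    if edit.op == "delete":
        w = precursor[:READ_WINDOW + 1]
        return w[:edit.position] + w[edit.position + 1:]
    w = precursor[:READ_WINDOW]
    if edit.op == "substitute":
        if w[edit.position] == edit.base:
            raise ValueError("substitution base equals the reference base")
        return w[:edit.position] + edit.base + w[edit.position + 1:]
    return w[:edit.position] + edit.base + w[edit.position:]  # insert


def generate_reads(precursors: PrecursorSet, reads_per_mirna: int,
                   altered: Mapping[str, EditSpec] | None = None,
                   mean_q: float = 30.0, seed: int | None = None
                   ) -> tuple[ReadSet, GroundTruth]:
    """Simulate reads as leading-21-base precursor windows.

    miRNAs named in ``altered`` emit only edited reads (their planted
    single-base alteration); all others emit exact windows.  Qualities are
    drawn per base from a discretised Normal(mean_q, 2) clipped to [2, 41],
    encoded Phred+33.
    """
    altered = dict(altered or {})
    unknown = set(altered) - set(precursors.sequences)
    if unknown:
        raise ValueError(f"altered miRNA(s) not in precursor set: "
                         f"{sorted(unknown)}")
    rng = np.random.default_rng(seed)
    reads: list[SequenceRead] = []
    origin: dict[str, str] = {}
    edits: dict[str, str] = {}
    for mid in precursors:
        seq = precursors[mid]
        if len(seq) < READ_WINDOW:
            raise ValueError(f"precursor {mid!r} shorter than the "
                             f"{READ_WINDOW}-base read window")
        if mid in altered:
            e = altered[mid]
            read_seq = _edited_read(seq, e)
            edit_desc = f"{e.op}@{e.position}" + (
                f"->{e.base}" if e.base else "")
        else:
            read_seq = seq[:READ_WINDOW]
            edit_desc = ""
        for i in range(reads_per_mirna):
            rid = f"{mid}_r{i + 1}"
            q = np.clip(np.rint(rng.normal(mean_q, 2.0, len(read_seq))),
                        2, 41).astype(int)
            reads.append(SequenceRead(
                rid, read_seq, "".join(chr(v + 33) for v in q)))
            origin[rid] = mid
            if edit_desc:
                edits[rid] = edit_desc
    truth = GroundTruth(status={}, read_origin=origin, read_edit=edits)
    return ReadSet(reads), truth


def random_precursors(n: int, length: int = 70,
                      seed: int | None = None) -> PrecursorSet:
    """Random DNA-alphabet precursor sequences for testing and simulation."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs = {
        f"pre-SIM-{i:03d}": "".join(rng.choice(bases, length))
        for i in range(1, n + 1)
    }
    return PrecursorSet(seqs)
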