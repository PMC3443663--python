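"""Domain containers and readers/writers for every format the pipeline touches.

Expression matrices travel as tab-separated tables (first column = gene id)
with a separate sample-annotation table mapping samples to batch and
phenotype.  Target sets use GMT; precursors FASTA; reads FASTQ (Phred+33);
pathway-activation probabilities a two-column TSV.  All values are assumed to
be on a log-like processed-intensity scale already — nothing here ever
exponentiates.  Gene and miRNA identifiers are opaque strings; harmonising
symbol spaces is input preparation, not this package's job.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed input file or violated container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples intensity matrix with batch and phenotype labels.

    ``values`` is a pandas DataFrame indexed by gene id with sample-id
    columns; ``batch`` and ``phenotype`` are Series indexed by sample id.
    Values must be finite; identifiers unique; every sample annotated.
    """

    values: pd.DataFrame
    batch: pd.Series
    phenotype: pd.Series

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("expression values must be finite")
        for name, ann in (("batch", self.batch), ("phenotype", self.phenotype)):
            missing = [s for s in self.values.columns if s not in ann.index]
            if missing:
                raise FormatError(
                    f"sample(s) missing from {name} annotation: {missing}"
                )
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        self.batch = self.batch.reindex(self.values.columns).rename(None)
        self.phenotype = self.phenotype.reindex(self.values.columns).rename(None)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_with(self, phenotype: str) -> list[str]:
        """Sample ids carrying the given phenotype label."""
        return [s for s in self.sample_ids if self.phenotype[s] == phenotype]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Copy carrying new values but the same annotations."""
        return ExpressionMatrix(values, self.batch.copy(), self.phenotype.copy())

    def subset_samples(self, samples: Sequence[str],
                       phenotype: pd.Series | None = None) -> "ExpressionMatrix":
        """Restrict to ``samples`` (order kept), optionally relabelling phenotype."""
        ph = self.phenotype if phenotype is None else phenotype
        return ExpressionMatrix(
            self.values[list(samples)].copy(),
            self.batch.loc[list(samples)].copy(),
            ph.loc[list(samples)].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.batch.equals(other.batch)
            and self.phenotype.equals(other.phenotype)
        )


def read_expression_table(
    path: str | Path,
    annotation_path: str | Path,
    batch_column: str = "batch",
    phenotype_column: str = "phenotype",
) -> ExpressionMatrix:
    """Read a gene x sample TSV plus a sample-annotation TSV.

    The expression table's first column holds gene ids; the annotation
    table's first column holds sample ids and must contain ``batch_column``
    and ``phenotype_column``.  Lines starting with ``#`` are comments.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                         float_precision="round_trip")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, comment="#")
    ann.index = ann.index.astype(str)
    for col in (batch_column, phenotype_column):
        if col not in ann.columns:
            raise FormatError(f"annotation table lacks column {col!r}")
    return ExpressionMatrix(
        values.astype(float),
        ann[batch_column].astype(str),
        ann[phenotype_column].astype(str),
    )


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | Path,
    annotation_path: str | Path,
    comments: Iterable[str] = (),
) -> None:
    write_table(matrix.values, path, comments, index_label="gene_id")
    ann = pd.DataFrame(
        {"batch": matrix.batch, "phenotype": matrix.phenotype}
    )
    write_table(ann, annotation_path, comments, index_label="sample_id")


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    comments: Iterable[str] = (),
    index_label: str | None = None,
    index: bool = True,
) -> None:
    """Write a TSV with leading ``#`` comment lines recording provenance."""
    buf = _stdio.StringIO()
    for line in comments:
        buf.write(f"# {line}\n")
    frame.to_csv(buf, sep="\t", index=index, index_label=index_label)
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Target sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class TargetSetCollection:
    """Per-miRNA predicted target gene sets, optionally with binding scores.

    Insertion order of ``targets`` fixes miRNA order.  Sets must be
    non-empty; target genes need not all appear in any particular expression
    matrix (the intersection is taken at analysis time).
    """

    targets: dict[str, frozenset[str]]
    scores: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        _check_unique(list(self.targets), "miRNA")
        for mid, genes in self.targets.items():
            if not genes:
                raise FormatError(f"empty target set for {mid!r}")
            self.targets[mid] = frozenset(genes)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.targets)

    def __len__(self) -> int:
        return len(self.targets)

    def __getitem__(self, mirna_id: str) -> frozenset[str]:
        return self.targets[mirna_id]

    def __iter__(self):
        return iter(self.targets)

    def high_affinity(self, mirna_id: str,
                      top_quantile: float | None = None) -> frozenset[str]:
        """Target subset used for scoring.

        With no scores, or ``top_quantile`` unset, this is the full target
        set; with scores, the genes whose binding score sits in the top
        ``top_quantile`` fraction.
        """
        genes = self.targets[mirna_id]
        if top_quantile is None or self.scores is None:
            return genes
        sc = self.scores.get(mirna_id)
        if not sc:
            return genes
        cut = np.quantile(list(sc.values()), 1.0 - top_quantile)
        keep = frozenset(g for g in genes if sc.get(g, -np.inf) >= cut)
        return keep or genes


def read_gmt(path: str | Path) -> TargetSetCollection:
    """Read a GMT file: name TAB description TAB member [TAB member ...]."""
    targets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in targets:
                raise FormatError(f"duplicate miRNA identifier: {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"GMT line {lineno}: no members for {name!r}")
            targets[name] = members
    return TargetSetCollection(targets)


def write_gmt(collection: TargetSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for mid in collection.mirna_ids:
            members = "\t".join(sorted(collection[mid]))
            fh.write(f"{mid}\t{description}\t{members}\n")


# ---------------------------------------------------------------------------
# Pathway-activation probabilities
# ---------------------------------------------------------------------------

@dataclass
class PathwayProbabilities:
    """Per-sample probability of oncogenic-pathway activation, in [0, 1]."""

    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        for s, p in self.probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise FormatError(
                    f"pathway probability for {s!r} outside [0,1]: {p}"
                )

    def __getitem__(self, sample: str) -> float:
        return self.probabilities[sample]

    def __len__(self) -> int:
        return len(self.probabilities)


def read_pathway_probabilities(path: str | Path) -> PathwayProbabilities:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    col = df.columns[0]
    return PathwayProbabilities(
        {str(s): float(p) for s, p in df[col].items()}
    )


def write_pathway_probabilities(probs: PathwayProbabilities, path: str | Path,
                                comments: Iterable[str] = ()) -> None:
    df = pd.DataFrame(
        {"probability": pd.Series(probs.probabilities)}
    )
    write_table(df, path, comments, index_label="sample_id")


# ---------------------------------------------------------------------------
# Precursor sequences (FASTA) and reads (FASTQ)
# ---------------------------------------------------------------------------

_DNA = set("ACGT")
_READ_ALPHABET = set("ACGTN")


@dataclass
class PrecursorSet:
    """miRNA precursor sequences over a single DNA alphabet.

    miRBase ships RNA-alphabet sequences; U is normalised to T at parse time
    so the mapper works over one alphabet, and ids whose input used U are
    remembered so ``display`` can show the original alphabet.
    """

    sequences: dict[str, str]
    rna_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        _check_unique(list(self.sequences), "precursor")
        for mid, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty precursor sequence for {mid!r}")
            bad = set(seq) - _DNA
            if bad:
                raise FormatError(
                    f"precursor {mid!r} has non-ACGT/U characters: {sorted(bad)}"
                )

    def __getitem__(self, mirna_id: str) -> str:
        return self.sequences[mirna_id]

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def display(self, mirna_id: str) -> str:
        seq = self.sequences[mirna_id]
        return seq.replace("T", "U") if mirna_id in self.rna_ids else seq


def read_fasta(path: str | Path) -> PrecursorSet:
    sequences: dict[str, str] = {}
    rna: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            rna.add(rec.id)
            seq = seq.replace("U", "T")
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return PrecursorSet(sequences, frozenset(rna))


def write_fasta(precursors: PrecursorSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(precursors.display(mid)), id=mid, description="")
        for mid in precursors
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class SequenceRead:
    read_id: str
    sequence: str
    quality: str  # Phred+33

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )
        bad = set(self.sequence) - _READ_ALPHABET
        if bad:
            raise FormatError(
                f"read {self.read_id!r} has unexpected characters: {sorted(bad)}"
            )

    @property
    def phred(self) -> np.ndarray:
        return np.frombuffer(self.quality.encode(), dtype=np.uint8) - 33


@dataclass
class ReadSet:
    reads: list[SequenceRead]

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def mean_phred(self) -> float:
        """Mean per-base Phred quality across all reads."""
        if not self.reads:
            raise FormatError("empty read set has no mean quality")
        return float(np.concatenate([r.phred for r in self.reads]).mean())


def read_fastq(path: str | Path) -> ReadSet:
    reads: list[SequenceRead] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(SequenceRead(rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:  # Biopython names the offending read
        raise FormatError(str(exc)) from exc
    return ReadSet(reads)


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in readset:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
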