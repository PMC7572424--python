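"""Core containers shared across the ffpeqc analysis modules.

Conventions used throughout the package:

* Coverage vectors are stored in *transcript orientation*: index 0 is the
  5'-most transcribed base, the last index is the 3'-most base, regardless
  of genomic strand.  Ingestion from genome coordinates must reverse
  minus-strand transcripts (see :mod:`ffpeqc.io`).
* Expression matrices are gene-by-sample tables of TPM values; the
  ``rescaled`` flag records whether each sample column sums to 1e6 over the
  retained genes.
* Genomic intervals are half-open, 0-based (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-")

#: sample-level quality gate: a sample is high quality iff its median
#: non-zero transcript TIN strictly exceeds this value.
TIN_GATE = 50.0


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's identity and coordinate frame for coverage scoring.

    Parameters
    ----------
    transcript_id, gene_id : str
        Identifiers; ``transcript_id`` must be unique within an annotation set.
    strand : {"+", "-"}
        Genomic strand of the transcribed RNA.
    length_nt : int
        Spliced transcript length in nucleotides (>= 1).
    canonical : bool
        Whether this isoform is the gene's designated representative; at most
        one transcript per gene may be canonical.
    """

    transcript_id: str
    gene_id: str
    strand: str
    length_nt: int
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.transcript_id}")
        if self.length_nt < 1:
            raise ValueError(f"length_nt must be >= 1, got {self.length_nt}")


def validate_annotation_set(transcripts: Sequence[TranscriptModel]) -> None:
    """Check uniqueness of transcript ids and the one-canonical-per-gene rule."""
    seen: set[str] = set()
    canon: dict[str, str] = {}
    for t in transcripts:
        if t.transcript_id in seen:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        seen.add(t.transcript_id)
        if t.canonical:
            if t.gene_id in canon:
                raise ValueError(
                    f"gene {t.gene_id!r} has multiple canonical transcripts "
                    f"({canon[t.gene_id]!r}, {t.transcript_id!r})"
                )
            canon[t.gene_id] = t.transcript_id


@dataclass
class CoverageProfile:
    """Per-base read depth along one transcript in one sample (5'->3')."""

    transcript_id: str
    sample_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError("empty profile")
        if np.any(self.depth < 0):
            raise ValueError(f"negative depth in profile {self.transcript_id}")

    @property
    def length(self) -> int:
        return int(self.depth.size)

    @property
    def total_depth(self) -> float:
        return float(self.depth.sum())

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())

    @property
    def expressed(self) -> bool:
        return self.total_depth > 0


@dataclass
class QualityRecord:
    """Per-transcript, per-sample quality scores.

    ``tin`` is 0 exactly when the transcript has no coverage (convention);
    ``tb`` is only defined for expressed transcripts and is NaN otherwise.
    """

    transcript_id: str
    sample_id: str
    tin: float
    tb: float
    mean_depth: float
    expressed: bool


@dataclass
class SampleQuality:
    """Sample-level quality summary.

    ``sample_tin`` is the median of the sample's *non-zero* transcript TINs;
    a sample with no expressed transcript has ``sample_tin`` NaN and
    ``no_expressed_transcripts`` set instead of a misleading 0.
    """

    sample_id: str
    sample_tin: float
    high_quality: bool
    median_tb: float
    n_expressed: int
    gc_content: float | None = None
    mean_template_length: float | None = None
    no_expressed_transcripts: bool = False


@dataclass
class GeneQuality:
    """Per-gene TIN: the canonical transcript's TIN when one exists."""

    gene_id: str
    sample_id: str
    gene_tin: float


@dataclass
class ExpressionMatrix:
    """Gene-by-sample TPM matrix.

    ``values`` has gene ids as the index and sample ids as columns.  When
    ``rescaled`` is true each column sums to 1e6 over the retained genes.
    """

    values: pd.DataFrame
    rescaled: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative entries")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


PAIR_TYPES = ("extraction", "library", "microdissection", "fixation")


@dataclass(frozen=True)
class ReplicatePair:
    """A pair of replicate samples differing at one protocol stage.

    ``high_tin_pair`` is true iff both samples pass the sample TIN gate.
    """

    sample_a: str
    sample_b: str
    pair_type: str
    high_tin_pair: bool = True

    def __post_init__(self) -> None:
        if self.pair_type not in PAIR_TYPES:
            raise ValueError(f"unknown pair_type {self.pair_type!r}")


@dataclass
class PairConcordance:
    """Concordance summary for one replicate pair on one gene set."""

    sample_a: str
    sample_b: str
    pair_type: str
    high_tin_pair: bool
    pearson_r: float
    n_genes: int
    divergence_p99: float
    gene_set_label: str = "whole_transcriptome"


SUCCESS_STAGES = ("extraction_to_libprep", "nonribosomal_sufficiency")


@dataclass(frozen=True)
class StageOutcome:
    """Pass/fail of one sample at one stage of the sequencing funnel."""

    sample_id: str
    stage: str
    passed: bool

    def __post_init__(self) -> None:
        if self.stage not in SUCCESS_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
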