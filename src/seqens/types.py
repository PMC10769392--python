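"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open internally; VCF 1-based positions are
converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

VALID_BASES = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ASSAY_CLASSES = ("CAGE", "DNASE_ATAC", "TF_CHIP", "HISTONE_CHIP")

# consistency categories
CONSISTENT_CORRECT = "CONSISTENT_CORRECT"
CONSISTENT_INCORRECT = "CONSISTENT_INCORRECT"
INCONSISTENT = "INCONSISTENT"
CONSISTENT_NO_TRUTH = "CONSISTENT_NO_TRUTH"
CATEGORIES = (CONSISTENT_CORRECT, INCONSISTENT, CONSISTENT_INCORRECT, CONSISTENT_NO_TRUTH)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicWindow:
    """A fixed-length sequence anchored at a genomic coordinate.

    ``anchor`` is the offset of the TSS (or variant) within the window;
    for TSS windows the anchor sits at a bin junction so that the
    "central two bins" flank it.
    """

    chrom: str
    start: int
    sequence: str
    anchor: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"window start must be >= 0, got {self.start}")
        if not (0 <= self.anchor < len(self.sequence)):
            raise ValueError(
                f"anchor {self.anchor} outside window of length {len(self.sequence)}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"non-IUPAC bases in window sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str, anchor: Optional[int] = None) -> "GenomicWindow":
        return GenomicWindow(
            chrom=self.chrom,
            start=self.start,
            sequence=sequence,
            anchor=self.anchor if anchor is None else anchor,
            strand=self.strand,
        )

    def reverse_complement(self) -> "GenomicWindow":
        n = len(self.sequence)
        return GenomicWindow(
            chrom=self.chrom,
            start=self.start,
            sequence=reverse_complement(self.sequence),
            anchor=min(n - 1, n - self.anchor),
            strand="-" if self.strand == "+" else "+",
        )


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant tied to a gene.

    ``pos`` is the 0-based offset of the variant inside its window
    (``chrom`` names the window); ``true_sign`` is +1/-1 for variants
    with a known direction of effect and ``None`` for matched negatives.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene_id: str = ""
    tss_distance: int = 0
    true_sign: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for allele in (self.ref_allele, self.alt_allele):
            if len(allele) != 1 or allele not in "ACGT":
                raise ValueError(f"SNVs only: bad allele {allele!r}")
        if self.true_sign not in (None, 1, -1):
            raise ValueError(f"true_sign must be +1, -1 or None, got {self.true_sign}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class TrackTable:
    """Per-bin nonnegative activity values for one track over one window."""

    track_id: str
    assay_class: str
    values: np.ndarray
    bin_width: int = 128

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.assay_class not in ASSAY_CLASSES:
            raise ValueError(f"unknown assay class {self.assay_class!r}")
        if np.any(self.values < 0):
            raise ValueError("track values must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[-1]


@dataclass
class PWMMotif:
    """An L x 4 probability matrix (columns A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("PWM rows must each sum to 1 (within 1e-6)")
        if np.any(self.matrix < 0):
            raise ValueError("PWM probabilities must be nonnegative")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def column_entropies(self) -> np.ndarray:
        """Shannon entropy in bits per PWM position, with 0*log0 == 0."""
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        return -terms.sum(axis=1)

    def consensus(self) -> str:
        # argmax breaks ties alphabetically because columns are in A<C<G<T order
        return "".join("ACGT"[i] for i in np.argmax(self.matrix, axis=1))


@dataclass(frozen=True)
class ConsistencyRecord:
    unit_id: str
    sign_probability: float
    category: str
    n_replicates: int
    truth: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.sign_probability <= 1.0):
            raise ValueError("sign_probability must lie in [0, 1]")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        unanimous = self.sign_probability in (0.0, 1.0)
        if (self.category != INCONSISTENT) != unanimous:
            raise ValueError("consistent categories require a unanimous ensemble")
        if self.category in (CONSISTENT_CORRECT, CONSISTENT_INCORRECT) and self.truth is None:
            raise ValueError(f"{self.category} requires ground truth")


@dataclass(frozen=True)
class MixtureMoments:
    mean: float
    variance: float


@dataclass
class PeakCallResult:
    track_id: str
    lam: float
    p_values: np.ndarray
    is_peak: np.ndarray
    fdr: float = 0.01

    @property
    def n_bins(self) -> int:
        return self.p_values.shape[0]


@dataclass
class ActivityScore:
    """Per-replicate TF activity (CANONICAL) or mutation activity (MUTATION) score."""

    motif_id: str
    track_id: str
    offset: int
    per_replicate_scores: np.ndarray
    kind: str  # CANONICAL | MUTATION

    def __post_init__(self) -> None:
        self.per_replicate_scores = np.asarray(self.per_replicate_scores, dtype=float)
        if self.offset < 1:
            raise ValueError("offset must be >= 1 bp upstream of the TSS")
        if self.kind not in ("CANONICAL", "MUTATION"):
            raise ValueError(f"kind must be CANONICAL or MUTATION, got {self.kind!r}")
        if not np.all(np.isfinite(self.per_replicate_scores)):
            raise ValueError("activity scores must be finite")


@dataclass
class VariantEffect:
    """Per-replicate signed SAD scores for one variant-gene-track triple."""

    variant: VariantRecord
    track_id: str
    per_replicate_sad: np.ndarray
    sign_probability: float = field(init=False)
    mean_abs_sad: float = field(init=False)
    category: str = field(init=False)

    def __post_init__(self) -> None:
        from . import consistency  # local import avoids a cycle

        self.per_replicate_sad = np.asarray(self.per_replicate_sad, dtype=float)
        self.sign_probability = consistency.ensemble_sign_probability(self.per_replicate_sad)
        self.mean_abs_sad = float(np.mean(np.abs(self.per_replicate_sad)))
        truth = None
        if self.variant.true_sign is not None:
            truth = 1 if self.variant.true_sign > 0 else 0
        labels = (self.per_replicate_sad > 0).astype(int)
        rec = consistency.classify_consistency(labels, truth=truth, unit_id=self.variant.variant_id)
        self.category = rec.category


@dataclass
class GeneUncertainty:
    gene_id: str
    per_replicate_rho: np.ndarray
    variance_rho: float = field(init=False)
    mean_abs_rho: float = field(init=False)
    eligible: bool = field(init=False)
    positive_count: int = field(init=False)
    uncertainty_class: str = "UNCLASSIFIED"  # HIGH | LOW | UNCLASSIFIED

    def __post_init__(self) -> None:
        rho = np.asarray(self.per_replicate_rho, dtype=float)
        self.per_replicate_rho = rho
        if rho.size < 2:
            raise ValueError("gene uncertainty needs >= 2 replicate correlations")
        if np.any(np.isnan(rho)):
            self.variance_rho = float("nan")
            self.mean_abs_rho = float("nan")
            self.eligible = False
            self.positive_count = int(np.sum(rho > 0))
            self.uncertainty_class = "UNCLASSIFIED"
        else:
            # identical replicate correlations have exactly zero variance
            # (np.var's mean-subtraction otherwise leaves ~1e-34 residue)
            self.variance_rho = (0.0 if np.all(rho == rho[0])
                                 else float(np.var(rho, ddof=1)))
            self.mean_abs_rho = float(np.mean(np.abs(rho)))
            self.eligible = self.mean_abs_rho >= 0.1
            self.positive_count = int(np.sum(rho > 0))


@dataclass(frozen=True)
class DriverRecord:
    gene_id: str
    variant: VariantRecord
    replicate_index: int
    variance_explained: float
    rank: int
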