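"""Normalized Relative Similarity (NRS) and the operations built on it.

For a target x and a reference y with relative code length C(x||y) bits,

    RS(x||y)  = |x| log2(4) - C(x||y)  =  2|x| - C(x||y)   [bits]
    NRS(x||y) = RS(x||y) / (2|x|)      =  1 - C(x||y) / (2|x|)

If the reference-trained models predict x well, C is small and NRS
approaches 1; for unrelated sequences the encoder approaches the uniform
2 bits/symbol and NRS approaches 0.  C may exceed 2|x| on adversarial
targets, so NRS is clamped to [0, 1].

This module provides per-read classification (argmax NRS over reference
bundles), sample-level composition profiling NRS(y||X) with a top-K report,
contaminant pre-filtering at threshold tau, and the genome-by-genome
inter-reference similarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .compressor import (
    MixtureConfig,
    ModelBundle,
    build_bundle,
    relative_code_length,
    relative_code_lengths,
)
from .seqio import SequenceRecord

__all__ = [
    "NRSResult",
    "ReadAssignment",
    "CompositionConfig",
    "PrefilterConfig",
    "PrefilterReport",
    "nrs_from_bits",
    "classify_reads",
    "profile_composition",
    "prefilter_reads",
    "inter_similarity_matrix",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class NRSResult:
    """Code length and similarity of one (query, reference) pair."""

    query_id: str
    reference_label: str
    bits: float
    length: int
    rs: float
    nrs: float


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    best_reference: str
    best_nrs: float
    second_best_nrs: float
    tie: bool
    status: str = "classified"


@dataclass(frozen=True)
class CompositionConfig:
    top_k: int = 20

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class PrefilterConfig:
    """tau: reads whose maximum contaminant NRS reaches tau are discarded."""

    tau: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")


@dataclass(frozen=True)
class PrefilterReport:
    n_input: int
    n_retained: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0


def nrs_from_bits(
    bits: float, length: int, query_id: str = "", reference_label: str = ""
) -> NRSResult:
    """RS = 2|x| - C and NRS = 1 - C/(2|x|) clamped to [0, 1]."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if bits < 0:
        raise ValueError("bits must be >= 0")
    rs = 2.0 * length - bits
    nrs = max(0.0, min(1.0, 1.0 - bits / (2.0 * length)))
    return NRSResult(query_id, reference_label, bits, length, rs, nrs)


def _score_one(read: SequenceRecord, bundle: ModelBundle) -> NRSResult:
    res = relative_code_length(read, bundle)
    return nrs_from_bits(res.bits, res.length, read.id, bundle.label)


def classify_reads(
    reads: Iterable[SequenceRecord],
    bundles: Sequence[ModelBundle],
    min_nrs: float = 0.0,
) -> Iterator[ReadAssignment]:
    """Assign each read to the reference bundle with the highest NRS.

    Ties break toward the lexicographically smallest reference label (and
    are flagged); reads whose best NRS falls below ``min_nrs`` are emitted
    with status "unclassified".  Reads are scored independently, so the
    output is invariant to read order.
    """
    if not bundles:
        raise ValueError("at least one reference bundle is required")
    read_list = list(reads)
    if not read_list:
        return
    # bundles sorted by label so that argmax (first maximum) realizes the
    # lexicographic tie-break
    order = sorted(range(len(bundles)), key=lambda i: bundles[i].label)
    labels = [bundles[i].label for i in order]
    lengths = np.array([r.length for r in read_list], dtype=np.float64)
    nrs = np.empty((len(read_list), len(bundles)), dtype=np.float64)
    for col, i in enumerate(order):
        bits = relative_code_lengths(read_list, bundles[i])
        nrs[:, col] = np.clip(1.0 - bits / (2.0 * lengths), 0.0, 1.0)
    for row, read in enumerate(read_list):
        scores = nrs[row]
        best_idx = int(np.argmax(scores))
        best_nrs = float(scores[best_idx])
        others = np.delete(scores, best_idx)
        second = float(others.max()) if others.size else 0.0
        tie = bool((scores == best_nrs).sum() > 1)
        status = "classified" if best_nrs >= min_nrs else UNCLASSIFIED
        yield ReadAssignment(
            read_id=read.id,
            best_reference=labels[best_idx] if status == "classified" else UNCLASSIFIED,
            best_nrs=best_nrs,
            second_best_nrs=second,
            tie=tie,
            status=status,
        )


def profile_composition(
    reads: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    config: MixtureConfig | None = None,
    top_k: int = 20,
) -> list[NRSResult]:
    """Sample composition: NRS(y||X) for each reference y under a bundle
    trained on the read sample X.

    The sample is treated as a bag of reads: model contexts reset at every
    read during training, so no artifactual cross-read contexts arise.
    Results are sorted by NRS descending (label ascending on ties) and only
    the top_k rows are kept.
    """
    CompositionConfig(top_k=top_k)
    if not reads:
        raise ValueError("empty read sample")
    if not references:
        raise ValueError("at least one reference is required")
    sample_bundle = build_bundle(reads, config, label="sample")
    results = []
    for ref in references:
        res = relative_code_length(ref, sample_bundle)
        results.append(nrs_from_bits(res.bits, res.length, ref.id, "sample"))
    results.sort(key=lambda r: (-r.nrs, r.query_id))
    return results[:top_k]


def prefilter_reads(
    reads: Iterable[SequenceRecord],
    contaminant_bundles: Sequence[ModelBundle],
    tau: float = 0.9,
) -> tuple[list[SequenceRecord], PrefilterReport]:
    """Retain reads whose maximum contaminant NRS is strictly below tau.

    tau = 1.0 retains everything (NRS never reaches 1 under smoothed
    models); tau = 0.0 retains nothing.  The recommended range for damaged,
    heavily contaminated samples is 0.6-0.7 (default 0.9).
    """
    PrefilterConfig(tau=tau)
    if not contaminant_bundles:
        raise ValueError("at least one contaminant bundle is required")
    read_list = list(reads)
    if not read_list:
        return [], PrefilterReport(n_input=0, n_retained=0)
    lengths = np.array([r.length for r in read_list], dtype=np.float64)
    worst = np.zeros(len(read_list), dtype=np.float64)
    for bundle in contaminant_bundles:
        bits = relative_code_lengths(read_list, bundle)
        nrs = np.clip(1.0 - bits / (2.0 * lengths), 0.0, 1.0)
        np.maximum(worst, nrs, out=worst)
    retained = [r for r, w in zip(read_list, worst) if w < tau]
    return retained, PrefilterReport(n_input=len(read_list), n_retained=len(retained))


def inter_similarity_matrix(
    references: Sequence[SequenceRecord],
    config: MixtureConfig | None = None,
) -> tuple[list[str], np.ndarray]:
    """Genome-by-genome similarity: M[i, j] = NRS(ref_j || ref_i-trained).

    The matrix is generally asymmetric; the diagonal is computed like any
    other cell.  Labels preserve input record order.
    """
    if len(references) < 2:
        raise ValueError("inter-reference similarity needs at least 2 references")
    labels = [r.id for r in references]
    n = len(references)
    matrix = np.zeros((n, n), dtype=np.float64)
    for i, ref_i in enumerate(references):
        bundle = build_bundle([ref_i], config, label=ref_i.id)
        for j, ref_j in enumerate(references):
            res = relative_code_length(ref_j, bundle)
            matrix[i, j] = nrs_from_bits(res.bits, res.length).nrs
    return labels, matrix
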