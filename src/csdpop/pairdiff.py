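"""Pairwise alignment and difference metrics between csd allele fragments.

The total difference between two alleles is the difference in HVR length plus
the number of amino-acid substitution columns in a global alignment of the
two fragments.  Terminal gaps are suppressed by appending identical 7-residue
sentinel anchors to both ends of both sequences before aligning — the
fragment termini are conserved and must stay aligned end to end.

Two functional-heterozygosity criteria are provided: the three-inequality
rule of Lechner and colleagues (d_HVR >= 6, d_PSD >= 1, 3*d_PSD + 2*d_e8 >= 9)
and the single minimal-HVR-difference rule (>= 5 residues difference in the
HVR, the weakest pair difference observed to direct female development).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .sequences import AlleleRecord

__all__ = [
    "AlignParams",
    "AlignmentResult",
    "PairwiseDifference",
    "align_pair",
    "count_differences",
    "pair_difference",
    "lechner_functional",
    "min_hvr_functional",
    "all_pairs",
]

#: Sentinel appended to both ends of both sequences before global alignment.
#: Anchors are identical, so they align to themselves and act as infinite
#: end-gap penalties; they are stripped from the reported alignment.
ANCHOR = "WWWWWWW"

HvrMetric = Literal["length_plus_subst", "length_only"]


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring: protein similarity matrix with affine gaps."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment of two fragments, anchors removed.

    ``aligned_a`` and ``aligned_b`` are gapped strings of equal length;
    removing the gap characters recovers the input fragments.  ``score`` is
    the alignment score of the anchored sequences.
    """

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")


@dataclass(frozen=True)
class PairwiseDifference:
    """Difference counts for one unordered allele pair.

    d_len_hvr
        absolute difference of the HVR lengths, in residues.
    n_subst
        number of alignment columns with two different residues anywhere in
        the fragment (gap columns are not substitutions).
    n_subst_hvr
        the subset of substitution columns falling inside both HVR spans.
    d_psd
        substitutions inside the potential specifying domain; the analysed
        fragment lies within the PSD, so this equals ``n_subst`` unless a
        narrower convention is imposed upstream.
    d_e8
        substitutions inside a configured exon-8 sub-span; 0 when the
        sequenced fragment ends before exon 8.
    """

    d_len_hvr: int
    n_subst: int
    n_subst_hvr: int
    d_psd: int
    d_e8: int

    def __post_init__(self) -> None:
        for name in ("d_len_hvr", "n_subst", "n_subst_hvr", "d_psd", "d_e8"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def d_total(self) -> int:
        """Total differences: HVR length difference plus substitutions."""
        return self.d_len_hvr + self.n_subst

    def hvr_difference(self, metric: HvrMetric = "length_plus_subst") -> int:
        """HVR difference under the chosen convention."""
        if metric == "length_plus_subst":
            return self.d_len_hvr + self.n_subst_hvr
        if metric == "length_only":
            return self.d_len_hvr
        raise ValueError(f"unknown HVR metric {metric!r}")


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -abs(params.gap_open)
    aligner.extend_gap_score = -abs(params.gap_extend)
    return aligner


def _fragment(x: AlleleRecord | str) -> str:
    return x.aa_seq if isinstance(x, AlleleRecord) else str(x)


def align_pair(
    a: AlleleRecord | str,
    b: AlleleRecord | str,
    params: AlignParams = AlignParams(),
) -> AlignmentResult:
    """Globally align two fragments with anchored termini.

    Deterministic for fixed parameters: of score-equivalent alignments the
    first in the aligner's canonical order is taken; gap placement inside a
    repeat tract is score-degenerate but the difference counts derived from
    the alignment do not depend on the choice.
    """
    seq_a, seq_b = _fragment(a), _fragment(b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(params)
    aln = aligner.align(ANCHOR + seq_a + ANCHOR, ANCHOR + seq_b + ANCHOR)[0]
    ga, gb = str(aln[0]), str(aln[1])
    k = len(ANCHOR)
    if ga[:k] != ANCHOR or gb[:k] != ANCHOR or ga[-k:] != ANCHOR or gb[-k:] != ANCHOR:
        raise RuntimeError("sentinel anchors failed to align to themselves")
    ga, gb = ga[k:-k], gb[k:-k]
    result = AlignmentResult(aligned_a=ga, aligned_b=gb, score=float(aln.score))
    if result.seq_a != seq_a or result.seq_b != seq_b:
        raise RuntimeError("anchor stripping did not recover the input fragments")
    return result


Span = tuple[int, int]


def _check_span(span: Span, length: int, label: str) -> None:
    s, e = span
    if not 0 <= s < e <= length:
        raise ValueError(f"{label} span {span} out of bounds for length {length}")


def count_differences(
    aln: AlignmentResult,
    hvr_span_a: Span,
    hvr_span_b: Span,
    e8_span_a: Span | None = None,
    e8_span_b: Span | None = None,
) -> PairwiseDifference:
    """Count substitution columns and the HVR length difference.

    Spans index the ungapped sequences.  A column counts as a substitution
    when both sequences contribute a residue and the residues differ; columns
    with a gap contribute to length difference, not to substitutions.
    """
    _check_span(hvr_span_a, len(aln.seq_a), "HVR a")
    _check_span(hvr_span_b, len(aln.seq_b), "HVR b")
    if e8_span_a is not None:
        _check_span(e8_span_a, len(aln.seq_a), "exon-8 a")
    if e8_span_b is not None:
        _check_span(e8_span_b, len(aln.seq_b), "exon-8 b")

    n_subst = n_subst_hvr = d_e8 = 0
    ia = ib = 0  # next ungapped position in a / b
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        pa = ia if ca != "-" else None
        pb = ib if cb != "-" else None
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if pa is None or pb is None or ca == cb:
            continue
        n_subst += 1
        if hvr_span_a[0] <= pa < hvr_span_a[1] and hvr_span_b[0] <= pb < hvr_span_b[1]:
            n_subst_hvr += 1
        if (
            e8_span_a is not None
            and e8_span_b is not None
            and e8_span_a[0] <= pa < e8_span_a[1]
            and e8_span_b[0] <= pb < e8_span_b[1]
        ):
            d_e8 += 1

    d_len_hvr = abs(
        (hvr_span_a[1] - hvr_span_a[0]) - (hvr_span_b[1] - hvr_span_b[0])
    )
    return PairwiseDifference(
        d_len_hvr=d_len_hvr,
        n_subst=n_subst,
        n_subst_hvr=n_subst_hvr,
        d_psd=n_subst,
        d_e8=d_e8,
    )


def pair_difference(
    a: AlleleRecord,
    b: AlleleRecord,
    params: AlignParams = AlignParams(),
) -> PairwiseDifference:
    """Align two allele records and count their differences."""
    aln = align_pair(a, b, params)
    return count_differences(aln, a.hvr_span, b.hvr_span)


def lechner_functional(d: PairwiseDifference) -> bool:
    """Three-inequality functional-heterozygosity rule.

    True iff d_HVR >= 6 and d_PSD >= 1 and 3*d_PSD + 2*d_e8 >= 9, where
    d_HVR is the HVR length difference.
    """
    return d.d_len_hvr >= 6 and d.d_psd >= 1 and 3 * d.d_psd + 2 * d.d_e8 >= 9


def min_hvr_functional(
    d: PairwiseDifference,
    threshold: int = 5,
    metric: HvrMetric = "length_plus_subst",
) -> bool:
    """Minimal-HVR-difference rule: HVR difference >= threshold residues."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return d.hvr_difference(metric) >= threshold


PAIR_COLUMNS = [
    "id_a",
    "id_b",
    "d_len_hvr",
    "n_subst",
    "n_subst_hvr",
    "d_total",
    "d_psd",
    "d_e8",
    "lechner_pass",
    "min_hvr_pass",
    "min_hvr_pass_length_only",
]


def all_pairs(
    alleles: Sequence[AlleleRecord],
    params: AlignParams = AlignParams(),
    min_hvr_threshold: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Difference table and summary over every unordered allele pair.

    Returns ``(table, summary)``: one row per pair (n*(n-1)/2 rows for n
    alleles) and a summary with the histogram of total differences, the
    cumulative fraction of pairs with at least n differences, and the
    fraction of pairs passing each functional-heterozygosity criterion
    (the minimal-HVR rule under both HVR-difference conventions).
    """
    rows = []
    for i in range(len(alleles)):
        for j in range(i + 1, len(alleles)):
            a, b = alleles[i], alleles[j]
            d = pair_difference(a, b, params)
            rows.append(
                {
                    "id_a": a.id,
                    "id_b": b.id,
                    "d_len_hvr": d.d_len_hvr,
                    "n_subst": d.n_subst,
                    "n_subst_hvr": d.n_subst_hvr,
                    "d_total": d.d_total,
                    "d_psd": d.d_psd,
                    "d_e8": d.d_e8,
                    "lechner_pass": lechner_functional(d),
                    "min_hvr_pass": min_hvr_functional(
                        d, min_hvr_threshold, "length_plus_subst"
                    ),
                    "min_hvr_pass_length_only": min_hvr_functional(
                        d, min_hvr_threshold, "length_only"
                    ),
                }
            )
    table = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    assert len(table) == comb(len(alleles), 2)

    if len(table):
        hist = table["d_total"].value_counts().sort_index()
        total = len(table)
        cumulative = {
            int(n): float((table["d_total"] >= n).sum() / total)
            for n in range(int(hist.index.min()), int(hist.index.max()) + 1)
        }
        summary = {
            "n_alleles": len(alleles),
            "n_pairs": total,
            "histogram": {int(k): int(v) for k, v in hist.items()},
            "cumulative_fraction_ge": cumulative,
            "fraction_lechner": float(table["lechner_pass"].mean()),
            "fraction_min_hvr": float(table["min_hvr_pass"].mean()),
            "fraction_min_hvr_length_only": float(
                table["min_hvr_pass_length_only"].mean()
            ),
        }
    else:
        summary = {
            "n_alleles": len(alleles),
            "n_pairs": 0,
            "histogram": {},
            "cumulative_fraction_ge": {},
            "fraction_lechner": None,
            "fraction_min_hvr": None,
            "fraction_min_hvr_length_only": None,
        }
    return table, summary
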