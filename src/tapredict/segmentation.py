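"""C-terminal transmembrane-domain detection and region segmentation.

Tail-anchored proteins carry a single membrane-spanning helix (TMD)
close to the C-terminus; everything C-terminal of it is the "tail" that,
together with TMD hydrophobicity, encodes the targeting signal.

The detector here is a deterministic sliding-window surrogate for the
HMM/profile servers commonly used for TM-helix annotation: among all
windows of length ``min_len``..``max_len`` whose last residue lies
within ``max_tail_len`` residues of the C-terminus, it returns the
window with the highest mean Kyte–Doolittle hydropathy, provided that
maximum reaches ``min_score``.  Ties (within 1e-9) are broken in favour
of the longer window, then the more C-terminal start, so output is
reproducible across platforms.  Dataset- or user-supplied TMD
coordinates always take precedence over detection (coordinate
passthrough); the detector is only a fallback for unannotated input.
"""

from __future__ import annotations

from dataclasses import dataclass

from .physchem import KYTE_DOOLITTLE, _check_sequence

__all__ = ["TMDSpan", "Segmentation", "find_cterm_tmd", "segment_regions"]


@dataclass(frozen=True)
class TMDSpan:
    """A candidate TMD: 1-based inclusive positions plus mean hydropathy."""

    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not 1 <= self.start < self.end:
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Segmentation:
    """Split of a sequence into context / upstream / TMD / tail.

    ``context_seq`` is whatever precedes the upstream window;
    ``context_seq + upstream_seq + tmd_seq + tail_seq`` reconstructs the
    input exactly.  The tail may be empty (TMD at the very C-terminus).
    """

    context_seq: str
    upstream_seq: str
    tmd_seq: str
    tail_seq: str

    @property
    def sequence(self) -> str:
        return self.context_seq + self.upstream_seq + self.tmd_seq + self.tail_seq


def find_cterm_tmd(
    seq: str,
    min_len: int = 17,
    max_len: int = 25,
    max_tail_len: int = 30,
    min_score: float = 1.6,
) -> TMDSpan | None:
    """Best C-terminal hydrophobic window, or ``None`` if none qualifies.

    Raises ``ValueError`` if the sequence is shorter than ``min_len``.
    """
    seq = _check_sequence(seq)
    n = len(seq)
    if n < min_len:
        raise ValueError(f"sequence length {n} is shorter than min_len={min_len}")

    # Prefix sums keep the exhaustive scan O(n * window_lengths).
    prefix = [0.0]
    for residue in seq:
        prefix.append(prefix[-1] + KYTE_DOOLITTLE[residue])

    best: tuple[float, int, int] | None = None  # (score, length, start0)
    for length in range(min_len, max_len + 1):
        for start0 in range(0, n - length + 1):
            end0 = start0 + length  # exclusive
            if n - end0 > max_tail_len:
                continue
            score = (prefix[end0] - prefix[start0]) / length
            if best is None or score > best[0] + 1e-9:
                best = (score, length, start0)
            elif abs(score - best[0]) <= 1e-9 and (length, start0) > (best[1], best[2]):
                best = (score, length, start0)
    if best is None or best[0] < min_score:
        return None
    score, length, start0 = best
    return TMDSpan(start=start0 + 1, end=start0 + length, score=score)


def segment_regions(seq: str, span: TMDSpan, upstream_len: int = 10) -> Segmentation:
    """Split *seq* around *span* into context / upstream / TMD / tail.

    The upstream window holds the (up to) ``upstream_len`` residues
    immediately N-terminal of the TMD; the tail holds everything
    C-terminal of it.
    """
    seq = _check_sequence(seq)
    if span.end > len(seq):
        raise ValueError(
            f"span ({span.start}, {span.end}) exceeds sequence length {len(seq)}"
        )
    if upstream_len < 0:
        raise ValueError("upstream_len must be >= 0")
    tmd_start0 = span.start - 1
    up_start0 = max(0, tmd_start0 - upstream_len)
    return Segmentation(
        context_seq=seq[:up_start0],
        upstream_seq=seq[up_start0:tmd_start0],
        tmd_seq=seq[tmd_start0 : span.end],
        tail_seq=seq[span.end :],
    )
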