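"""End-to-end feature extraction: sequence → segmentation → features.

Glues the detector, the coordinate passthrough and the physicochemical
calculators together.  Dataset-supplied TMD coordinates always win over
de-novo detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import DatasetEntry, ProteinRecord
from .physchem import DEFAULT_PKA, FeatureVector, PkaTable, compute_features
from .segmentation import Segmentation, TMDSpan, find_cterm_tmd, segment_regions

__all__ = ["AnalyzedRecord", "analyze_sequence", "analyze_record", "dataset_features"]


@dataclass(frozen=True)
class AnalyzedRecord:
    """Outcome of analyzing one record; ``span is None`` means no TMD."""

    id: str
    span: TMDSpan | None
    segmentation: Segmentation | None
    features: FeatureVector | None

    @property
    def has_tmd(self) -> bool:
        return self.span is not None


def analyze_sequence(
    rec_id: str,
    seq: str,
    tmd: tuple[int, int] | TMDSpan | None = None,
    *,
    upstream_len: int = 10,
    pH: float = 7.0,
    pka: PkaTable = DEFAULT_PKA,
    min_len: int = 17,
    max_len: int = 25,
    max_tail_len: int = 30,
    min_score: float = 1.6,
) -> AnalyzedRecord:
    """Segment and featurize one sequence.

    *tmd*, when given (``(start, end)`` 1-based inclusive, or a
    :class:`TMDSpan`), bypasses detection entirely.
    """
    from .physchem import gravy

    if tmd is None:
        span = find_cterm_tmd(
            seq,
            min_len=min_len,
            max_len=max_len,
            max_tail_len=max_tail_len,
            min_score=min_score,
        )
    elif isinstance(tmd, TMDSpan):
        span = tmd
    else:
        start, end = tmd
        span = TMDSpan(start=start, end=end, score=gravy(seq[start - 1 : end]))
    if span is None:
        return AnalyzedRecord(id=rec_id, span=None, segmentation=None, features=None)
    seg = segment_regions(seq, span, upstream_len=upstream_len)
    return AnalyzedRecord(
        id=rec_id,
        span=span,
        segmentation=seg,
        features=compute_features(seg, pH, pka=pka),
    )


def analyze_record(record: ProteinRecord, **kwargs) -> AnalyzedRecord:
    return analyze_sequence(record.id, record.seq, **kwargs)


def dataset_features(
    entries: Sequence[DatasetEntry],
    *,
    upstream_len: int = 10,
    pH: float = 7.0,
    pka: PkaTable = DEFAULT_PKA,
    **detector_kwargs,
) -> pd.DataFrame:
    """Feature table for a labeled dataset.

    One row per entry with columns ``id, name, location, tmd_start,
    tmd_end, tmd_gravy, tail_charge, tail_length, upstream_charge,
    upstream_gravy, status`` — status ``OK`` or ``NO_TMD`` (no detected
    TMD and no supplied coordinates; feature columns are NaN there).
    """
    rows = []
    for entry in entries:
        tmd = (entry.tmd_start, entry.tmd_end) if entry.tmd_start is not None else None
        analyzed = analyze_sequence(
            entry.id,
            entry.cterm_seq,
            tmd=tmd,
            upstream_len=upstream_len,
            pH=pH,
            pka=pka,
            **detector_kwargs,
        )
        row = {"id": entry.id, "name": entry.name, "location": entry.location}
        if analyzed.has_tmd:
            fv = analyzed.features
            row.update(
                tmd_start=analyzed.span.start,
                tmd_end=analyzed.span.end,
                tmd_gravy=fv.tmd_gravy,
                tail_charge=fv.tail_charge,
                tail_length=fv.tail_length,
                upstream_charge=fv.upstream_charge,
                upstream_gravy=fv.upstream_gravy,
                status="OK",
            )
        else:
            row["status"] = "NO_TMD"
        rows.append(row)
    columns = [
        "id", "name", "location", "tmd_start", "tmd_end", "tmd_gravy",
        "tail_charge", "tail_length", "upstream_charge", "upstream_gravy",
        "status",
    ]
    return pd.DataFrame(rows).reindex(columns=columns)
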