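"""Spike-in mock community diagnostics and tag-switching filtering.

A mock community sequenced alongside the samples gives two run-level
diagnostics: an error rate (how far recovered centroids drift from the
known references) and a tag-switching (index-bleed) rate, measured in both
directions — foreign reads appearing inside the mock sample, and mock
reads leaking out into other samples.  The measured rate then drives a
per-OTU filter: within each OTU, sample counts below that OTU's
tag-switching threshold are zeroed, counts above it are untouched.  No OTU
row is ever dropped merely for being low-abundance overall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._align import global_identity, nw_stats
from .cluster import OTU, OTUTable, flag_chimera

__all__ = [
    "MockHit",
    "MockMap",
    "BleedEstimate",
    "map_otus_to_mock",
    "error_rate",
    "estimate_bleed",
    "filter_table",
]

CLASSES = ("mock_hit", "mock_variant", "chimera_suspect", "non_mock")


@dataclass(frozen=True)
class MockHit:
    otu_id: str
    cls: str
    best_ref: Optional[str]
    identity: float
    mismatches: int  # substitutions + gap columns in the global alignment
    aligned_bp: int


@dataclass
class MockMap:
    """Per-OTU classification against a mock reference set."""

    hits: dict[str, MockHit] = field(default_factory=dict)

    def otus_of_class(self, *classes: str) -> list[str]:
        return [h.otu_id for h in self.hits.values() if h.cls in classes]

    @property
    def mock_hit_otus(self) -> list[str]:
        return self.otus_of_class("mock_hit")

    @property
    def mock_otus(self) -> list[str]:
        """OTUs removed along with the mock sample (hits and variants)."""
        return self.otus_of_class("mock_hit", "mock_variant")


@dataclass(frozen=True)
class BleedEstimate:
    rate_in: float
    rate_out: float
    applied: float
    combine: str = "max"


def map_otus_to_mock(
    otus: Sequence[OTU],
    mock_refs: Sequence[tuple[str, str]],
    hit_id: float = 0.97,
    variant_id: float = 0.90,
) -> MockMap:
    """Classify each OTU against the mock reference sequences.

    ``mock_hit``: best identity >= *hit_id*; ``mock_variant``: in
    [*variant_id*, *hit_id*) — usually an error cloud or synthesis variant
    of a mock member; ``chimera_suspect``: a two-parent crossover of mock
    references; everything else is ``non_mock`` (a genuine biological OTU,
    or bleed from other samples when the whole run is mock).
    """
    if not mock_refs:
        raise ValueError("empty mock reference set")
    ref_seqs = [seq for _, seq in mock_refs]
    out = MockMap()
    for otu in otus:
        best_ref, best_id, best_mm, best_bp = None, -1.0, 0, 0
        for name, ref in mock_refs:
            score, matches, mism, gaps, cols = nw_stats(otu.centroid, ref)
            ident = matches / cols
            if ident > best_id:
                best_ref, best_id = name, ident
                best_mm, best_bp = mism + gaps, cols
        if best_id >= hit_id:
            cls = "mock_hit"
        elif best_id >= variant_id:
            cls = "mock_variant"
        elif flag_chimera(otu.centroid, ref_seqs, full_id=hit_id):
            cls = "chimera_suspect"
        else:
            cls = "non_mock"
        out.hits[otu.otu_id] = MockHit(
            otu_id=otu.otu_id,
            cls=cls,
            best_ref=best_ref if cls != "non_mock" else None,
            identity=best_id,
            mismatches=best_mm,
            aligned_bp=best_bp,
        )
    return out


def error_rate(
    mock_map: MockMap,
    include_variants: bool = False,
) -> float:
    """Run error rate in percent: 100 x total mismatches / total aligned bp.

    Mismatches include substitutions and gap columns of each mock OTU's
    global alignment to its best reference.  Computed over ``mock_hit``
    OTUs by default; *include_variants* extends to ``mock_variant``.
    """
    classes = ("mock_hit", "mock_variant") if include_variants else ("mock_hit",)
    total_mm = 0
    total_bp = 0
    for hit in mock_map.hits.values():
        if hit.cls in classes:
            total_mm += hit.mismatches
            total_bp += hit.aligned_bp
    if total_bp == 0:
        raise ValueError("no mock OTUs to compute an error rate over")
    return 100.0 * total_mm / total_bp


def estimate_bleed(
    table: OTUTable,
    mock_sample: str,
    mock_map: MockMap,
    combine: str = "max",
) -> BleedEstimate:
    """Tag-switching rate measured through the spike-in mock sample.

    ``rate_in``  — reads inside the mock sample that belong to non-mock
    OTUs, as a fraction of all reads in the mock sample (foreign reads can
    only have arrived there by tag-switching).
    ``rate_out`` — reads of mock-hit OTUs found in non-mock samples, as a
    fraction of all mock-hit OTU reads (mock templates exist only in the
    mock sample).  Variants and chimera suspects are excluded from both
    numerators and denominators: they may be artifacts rather than
    switched reads.
    ``applied``  — the combination used for filtering; ``max`` (default,
    conservative), ``mean``, ``in`` or ``out``.
    """
    if mock_sample not in table.sample_ids:
        raise ValueError(f"mock sample {mock_sample!r} not in table")
    mock_otus = set(mock_map.mock_hit_otus) & set(table.otu_ids)
    if not mock_otus:
        raise ValueError(
            "no mock OTUs found in the table; check that the mock reference "
            "FASTA matches the spike-in actually sequenced"
        )
    non_mock_otus = [
        o for o in table.otu_ids
        if mock_map.hits.get(o) is not None and mock_map.hits[o].cls == "non_mock"
    ]
    mock_col = table.df[mock_sample]
    total_in_mock = int(mock_col.sum())
    foreign_in_mock = int(mock_col.loc[non_mock_otus].sum()) if non_mock_otus else 0
    rate_in = foreign_in_mock / total_in_mock if total_in_mock else 0.0

    mock_rows = table.df.loc[sorted(mock_otus)]
    total_mock_reads = int(mock_rows.values.sum())
    other_cols = [s for s in table.sample_ids if s != mock_sample]
    mock_outside = int(mock_rows[other_cols].values.sum()) if other_cols else 0
    rate_out = mock_outside / total_mock_reads if total_mock_reads else 0.0

    if combine == "max":
        applied = max(rate_in, rate_out)
    elif combine == "mean":
        applied = 0.5 * (rate_in + rate_out)
    elif combine == "in":
        applied = rate_in
    elif combine == "out":
        applied = rate_out
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    return BleedEstimate(rate_in=rate_in, rate_out=rate_out,
                         applied=applied, combine=combine)


def filter_table(
    table: OTUTable,
    rate: float,
    mock_map: Optional[MockMap] = None,
    mock_sample: Optional[str] = None,
    drop_mock: bool = True,
) -> OTUTable:
    """Zero out per-OTU counts attributable to tag-switching.

    For each OTU the threshold is ``ceil(rate x total reads of that OTU
    across all samples)``; cells strictly below it are set to zero, cells
    at or above it are unchanged.  Thresholds are computed once from the
    input table (never from intermediate results), which makes the filter
    idempotent.  With *drop_mock*, mock hit/variant OTU rows and the mock
    sample column are removed after filtering.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be a fraction in [0, 1]")
    counts = table.df.to_numpy().copy()
    totals = counts.sum(axis=1)
    thresholds = np.ceil(rate * totals).astype(np.int64)
    mask = (counts > 0) & (counts < thresholds[:, None])
    counts[mask] = 0
    df = table.df.copy()
    df.loc[:, :] = counts
    if drop_mock:
        if mock_map is not None:
            df = df.drop(index=[o for o in mock_map.mock_otus if o in df.index])
        if mock_sample is not None and mock_sample in df.columns:
            df = df.drop(columns=[mock_sample])
    return OTUTable(df)
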