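"""Greedy centroid OTU clustering and OTU-table construction.

The clustering stage follows the abundance-greedy centroid convention:
unique sequences are visited from most to least abundant, each either
joining the first centroid it matches at or above the identity threshold
(default 97%) or founding a new centroid.  Crucially, the OTU table is
built by mapping the *pre-quality-filter* demultiplexed reads back onto
the centroids, so expected-error filtering (which discriminates against
long amplicons) shapes only the centroid set, never the counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from ._align import global_identity, nw_stats
from .seqio import Read

__all__ = [
    "UniqueSeq",
    "OTU",
    "OTUTable",
    "global_identity",
    "dereplicate",
    "cluster_otus",
    "flag_chimera",
    "map_reads_to_otus",
    "rarefy",
]


@dataclass(frozen=True)
class UniqueSeq:
    seq: str
    size: int


@dataclass(frozen=True)
class OTU:
    otu_id: str
    centroid: str


class OTUTable:
    """Integer count matrix, rows = OTUs, columns = samples."""

    def __init__(self, df: pd.DataFrame):
        if (df.values < 0).any():
            raise ValueError("negative counts in OTU table")
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValueError("duplicate OTU or sample ids")
        self.df = df.astype(np.int64)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    def otu_totals(self) -> pd.Series:
        return self.df.sum(axis=1)

    def sample_totals(self) -> pd.Series:
        return self.df.sum(axis=0)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.index.name = "#OTU_ID"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "OTUTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def __eq__(self, other) -> bool:
        return isinstance(other, OTUTable) and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"OTUTable({len(self.df)} OTUs x {len(self.df.columns)} samples)"


def dereplicate(reads: Iterable[Read | str]) -> list[UniqueSeq]:
    """Collapse identical sequences, recording abundance.

    Output is sorted by size descending, ties broken lexicographically by
    sequence, so downstream greedy clustering is deterministic.
    """
    counts = Counter(r.seq if isinstance(r, Read) else r for r in reads)
    return [
        UniqueSeq(seq=s, size=n)
        for s, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def _segment_hits(segment: str, centroids: Sequence[str], min_id: float) -> set[int]:
    """Indices of centroids containing *segment* at >= min_id (infix match)."""
    hits = set()
    k = int(len(segment) * (1.0 - min_id)) + 1
    for i, c in enumerate(centroids):
        res = edlib.align(segment, c, mode="HW", task="distance", k=k)
        d = res["editDistance"]
        if d >= 0 and 1.0 - d / len(segment) >= min_id:
            hits.add(i)
    return hits


def flag_chimera(
    candidate: str,
    centroids: Sequence[str],
    *,
    segment_id: float = 0.99,
    full_id: float = 0.97,
    min_segment: int = 30,
) -> bool:
    """Two-parent crossover test for chimeric sequences.

    Flags *candidate* when some split point leaves its left part matching
    one centroid and its right part a different centroid (each at
    >= ``segment_id`` within the centroid) while the candidate matches no
    single centroid at >= ``full_id`` full-length identity.  This is a
    deliberately simple bipartite test, not a full chimera model: it
    catches clean two-parent PCR crossovers, which is what mock-based
    diagnostics need.
    """
    if len(centroids) < 2:
        return False
    if len(candidate) < 2 * min_segment:
        return False
    for c in centroids:
        if global_identity(candidate, c) >= full_id:
            return False
    # every split point: the 99% segment bar only clears at (or next to) the
    # true breakpoint, so a coarse grid would miss real crossovers
    for split in range(min_segment, len(candidate) - min_segment + 1):
        left = _segment_hits(candidate[:split], centroids, segment_id)
        if not left:
            continue
        right = _segment_hits(candidate[split:], centroids, segment_id)
        # any pair (i, j), i != j, with left from centroid i and right from j
        if any(i != j for i in left for j in right):
            return True
    return False


def cluster_otus(
    uniques: Sequence[UniqueSeq],
    id_threshold: float = 0.97,
    min_size: int = 2,
    chimera_check: bool = True,
) -> list[OTU]:
    """Abundance-greedy centroid clustering.

    Uniques are processed from most to least abundant; those below
    ``min_size`` never found a centroid (singleton uniques are usually
    errors) but their reads still count later via read mapping.  A
    candidate joins the first centroid at identity >= ``id_threshold``;
    otherwise, unless it looks like a two-parent chimera of existing
    centroids, it becomes a new centroid.  All centroid pairs end up below
    the threshold.
    """
    if not 0.5 < id_threshold <= 1.0:
        raise ValueError(f"id_threshold {id_threshold} outside (0.5, 1.0]")
    ordered = sorted(uniques, key=lambda u: (-u.size, u.seq))
    centroids: list[str] = []
    for uniq in ordered:
        if uniq.size < min_size:
            continue
        joined = False
        for c in centroids:
            if global_identity(uniq.seq, c) >= id_threshold:
                joined = True
                break
        if joined:
            continue
        if chimera_check and flag_chimera(uniq.seq, centroids, full_id=id_threshold):
            continue
        centroids.append(uniq.seq)
    return [OTU(otu_id=f"OTU_{i + 1}", centroid=c) for i, c in enumerate(centroids)]


def map_reads_to_otus(
    demuxed_reads: Iterable[Read],
    otus: Sequence[OTU],
    id_threshold: float = 0.97,
    sample_ids: Optional[Sequence[str]] = None,
) -> OTUTable:
    """Build the OTU table from demultiplexed (pre-filter) reads.

    Each read goes to the best centroid at identity >= ``id_threshold``
    (ties to the lowest OTU index); unmatched reads are dropped.  Reads
    must carry a sample label.  Identical sequences are aligned once.
    """
    per_seq_sample: Counter = Counter()
    samples: list[str] = list(sample_ids) if sample_ids else []
    seen = set(samples)
    for read in demuxed_reads:
        if read.sample is None:
            raise ValueError(f"read {read.id!r} has no sample label")
        if read.sample not in seen:
            seen.add(read.sample)
            samples.append(read.sample)
        per_seq_sample[(read.seq, read.sample)] += 1

    assign_cache: dict[str, Optional[int]] = {}

    def assign(seq: str) -> Optional[int]:
        if seq not in assign_cache:
            best_i, best_id = None, 0.0
            for i, otu in enumerate(otus):
                ident = global_identity(seq, otu.centroid)
                if ident >= id_threshold and ident > best_id:
                    best_i, best_id = i, ident
            assign_cache[seq] = best_i
        return assign_cache[seq]

    counts = np.zeros((len(otus), len(samples)), dtype=np.int64)
    sample_index = {s: j for j, s in enumerate(samples)}
    for (seq, sample), n in per_seq_sample.items():
        i = assign(seq)
        if i is not None:
            counts[i, sample_index[sample]] += n
    df = pd.DataFrame(counts, index=[o.otu_id for o in otus], columns=samples)
    return OTUTable(df)


def rarefy(
    table: OTUTable,
    depth: int,
    seed: int,
    return_dropped: bool = False,
):
    """Subsample every sample column to *depth* reads without replacement.

    Columns whose total is below *depth* are dropped.  Rarefaction is kept
    for comparability with common practice; read counts from amplicon
    sequencing do not track template abundance in the first place, so
    rarefied counts inherit that caveat.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    kept_cols = []
    dropped = []
    data = {}
    for sample in table.sample_ids:
        col = table.df[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append(sample)
            continue
        if total == depth:
            data[sample] = col.copy()
        else:
            data[sample] = rng.multivariate_hypergeometric(col, depth)
        kept_cols.append(sample)
    out = OTUTable(pd.DataFrame(data, index=table.otu_ids, columns=kept_cols))
    if return_dropped:
        return out, dropped
    return out
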