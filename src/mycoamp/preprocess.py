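"""Read pre-processing: demultiplexing, primer removal, length handling.

Fungal ITS amplicons vary several-fold in length, so the trimming rules
here are deliberately lossless: a long read is truncated to the length
ceiling, but a short read is kept at its native length as long as its
reverse primer was seen (proof the amplicon was sequenced through).
Discarding short reads — the classic fixed-length truncation used for 16S
— silently deletes genuinely short taxa from the final OTU set.

Defaults follow common amplicon practice: 0 mismatches in the barcode,
2 edits in the primer, 300 bp length ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib

from .seqio import Read, SampleSheet

__all__ = [
    "PrimerHit",
    "DemuxStats",
    "revcomp",
    "find_primer",
    "demux_single",
    "trim_lossless",
    "pad_to_length",
    "strip_padding",
    "merge_pairs",
    "expected_errors",
    "filter_by_ee",
]

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

# IUPAC ambiguity codes match each of their expansions at zero cost; N is a
# wildcard on either strand.
_IUPAC = {
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_EQUALITIES = [(code, base) for code, bases in _IUPAC.items() for base in bases]

_IUPAC_SETS = {c: frozenset(c) for c in "ACGT"}
_IUPAC_SETS.update({code: frozenset(bases) for code, bases in _IUPAC.items()})


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerHit:
    """Location of a primer in a read; ``end`` is exclusive (0-based)."""

    start: int
    end: int
    edits: int
    primer_name: str = "primer"


@dataclass
class DemuxStats:
    """Audit of a demultiplexing run; kept + rejected == input reads."""

    kept: dict[str, int] = field(default_factory=dict)
    rejected: dict[str, int] = field(
        default_factory=lambda: {
            "no_barcode": 0,
            "ambiguous_barcode": 0,
            "no_fwd_primer": 0,
            "too_short": 0,
            "no_rev_primer_short": 0,
        }
    )

    @property
    def n_kept(self) -> int:
        return sum(self.kept.values())

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    @property
    def total(self) -> int:
        return self.n_kept + self.n_rejected

    def to_tsv(self) -> str:
        lines = ["category\tname\tcount"]
        for name in sorted(self.kept):
            lines.append(f"kept\t{name}\t{self.kept[name]}")
        for reason, n in self.rejected.items():
            lines.append(f"rejected\t{reason}\t{n}")
        return "\n".join(lines) + "\n"


def _bases_match(primer_char: str, read_char: str) -> bool:
    if read_char == "N":
        return True
    return read_char in _IUPAC_SETS.get(primer_char, frozenset(primer_char))


def find_primer(
    read_seq: str,
    primer: str,
    max_edits: int = 2,
    *,
    primer_name: str = "primer",
    indels: bool = True,
) -> Optional[PrimerHit]:
    """Best semi-global hit of *primer* inside *read_seq*.

    The primer must align end-to-end; the read provides free flanks.  With
    ``indels=True`` (default) edits are Levenshtein edits, which is the
    right model for homopolymer-prone platforms; ``indels=False`` restricts
    the search to substitution-only (Hamming) matches.  Among equal-edit
    hits the leftmost is returned; None if nothing is within ``max_edits``.
    """
    if not primer:
        raise ValueError("empty primer")
    if indels:
        res = edlib.align(
            primer,
            read_seq,
            mode="HW",
            task="locations",
            k=max_edits,
            additionalEqualities=IUPAC_EQUALITIES,
        )
        if res["editDistance"] < 0:
            return None
        start, end = min(res["locations"], key=lambda loc: (loc[0], loc[1]))
        return PrimerHit(start=start, end=end + 1, edits=res["editDistance"],
                         primer_name=primer_name)
    best: Optional[PrimerHit] = None
    plen = len(primer)
    for start in range(len(read_seq) - plen + 1):
        window = read_seq[start : start + plen]
        mism = sum(
            not _bases_match(p, r) for p, r in zip(primer, window)
        )
        if mism <= max_edits and (best is None or mism < best.edits):
            best = PrimerHit(start=start, end=start + plen, edits=mism,
                             primer_name=primer_name)
            if mism == 0:
                break
    return best


def _match_barcode(
    seq: str, barcodes: dict[str, str], max_edits: int
) -> tuple[Optional[str], Optional[int], bool]:
    """Anchored (position 0) barcode match by edit distance.

    Returns (sample, end-of-barcode index, ambiguous).  Ambiguous means two
    or more samples tie at the best distance.
    """
    if max_edits == 0:
        for name, bc in barcodes.items():
            if seq.startswith(bc):
                return name, len(bc), False
        return None, None, False
    best_name = None
    best_dist = max_edits + 1
    best_end = None
    tied = False
    for name, bc in barcodes.items():
        res = edlib.align(bc, seq, mode="SHW", task="locations", k=max_edits)
        d = res["editDistance"]
        if d < 0:
            continue
        if d < best_dist:
            best_name, best_dist, tied = name, d, False
            best_end = res["locations"][0][1] + 1
        elif d == best_dist:
            tied = True
    if best_name is None:
        return None, None, False
    return best_name, best_end, tied


def demux_single(
    reads: Iterable[Read],
    sheet: SampleSheet,
    barcode_edits: int = 0,
    primer_edits: int = 2,
    *,
    max_len: int = 300,
    mode: str = "fulllength",
    min_len: int = 50,
    primer_indels: bool = True,
    keep_no_revprimer: bool = False,
) -> tuple[list[Read], DemuxStats]:
    """Demultiplex single-end barcoded reads (Ion Torrent / 454 layout).

    Layout expected per read: ``barcode + fwd_primer + insert +
    rc(rev_primer) [+ rev_barcode]``.  A read is kept only if its barcode
    matches a sample (anchored at position 0, ``barcode_edits`` tolerance,
    ties rejected as ambiguous) and the forward primer is found.  Barcode
    and primers are stripped; the insert is then length-processed by
    *mode*:

    - ``fulllength``: truncate longer than *max_len*, keep shorter reads
      if the reverse primer was found (lossless trimming);
    - ``pad``: truncate longer, N-pad shorter to *max_len*;
    - ``truncate``: truncate longer, discard shorter (fixed-length 16S
      convention, kept for comparison experiments).
    """
    if mode not in ("fulllength", "pad", "truncate"):
        raise ValueError(f"unknown length mode {mode!r}")
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    barcodes = {
        name: spec.fwd_barcode
        for name, spec in sheet.entries.items()
        if spec.fwd_barcode is not None
    }
    if not barcodes:
        raise ValueError("no forward barcodes in sample sheet")
    rc_rev = revcomp(sheet.rev_primer)
    stats = DemuxStats(kept={name: 0 for name in barcodes})
    out: list[Read] = []
    for read in reads:
        sample, bc_end, ambiguous = _match_barcode(read.seq, barcodes, barcode_edits)
        if sample is None:
            stats.rejected["no_barcode"] += 1
            continue
        if ambiguous:
            stats.rejected["ambiguous_barcode"] += 1
            continue
        body = read.seq[bc_end:]
        fwd_hit = find_primer(
            body, sheet.fwd_primer, primer_edits,
            primer_name="fwd", indels=primer_indels,
        )
        if fwd_hit is None:
            stats.rejected["no_fwd_primer"] += 1
            continue
        insert_start = bc_end + fwd_hit.end
        insert = read.seq[insert_start:]
        rev_hit = find_primer(
            insert, rc_rev, primer_edits, primer_name="rev", indels=primer_indels
        )
        rev_found = rev_hit is not None
        if rev_found:
            insert = insert[: rev_hit.start]
        qual = (
            read.qual[insert_start : insert_start + len(insert)]
            if read.qual is not None
            else None
        )
        if len(insert) < min_len:
            stats.rejected["too_short"] += 1
            continue
        if len(insert) > max_len:
            insert, qual = insert[:max_len], qual[:max_len] if qual else qual
        elif mode == "truncate" and len(insert) < max_len:
            stats.rejected["too_short"] += 1
            continue
        elif mode == "pad" and len(insert) < max_len:
            pad = max_len - len(insert)
            insert = insert + "N" * pad
            if qual is not None:
                qual = qual + [2] * pad
        elif mode == "fulllength" and not rev_found and not keep_no_revprimer:
            stats.rejected["no_rev_primer_short"] += 1
            continue
        stats.kept[sample] += 1
        out.append(Read(id=read.id, seq=insert, qual=qual, sample=sample))
    return out, stats


def trim_lossless(read: Read, max_len: int, rev_primer_found: bool) -> Optional[Read]:
    """Lossless length trimming of a primer-stripped read.

    Longer than *max_len*: truncated to the *max_len* prefix.  At most
    *max_len*: returned unchanged when the reverse primer was found, else
    None (without the reverse primer a short read is an artifact of
    incomplete sequencing, not a short amplicon).
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    if len(read.seq) > max_len:
        return Read(
            id=read.id,
            seq=read.seq[:max_len],
            qual=read.qual[:max_len] if read.qual is not None else None,
            sample=read.sample,
        )
    if rev_primer_found:
        return read
    return None


def pad_to_length(seq: str, L: int) -> str:
    """Force *seq* to length *L*: 3' N-padding if shorter, truncation if longer."""
    if L <= 0:
        raise ValueError("L must be positive")
    if len(seq) >= L:
        return seq[:L]
    return seq + "N" * (L - len(seq))


def strip_padding(seq: str) -> str:
    """Remove 3' N-padding added by :func:`pad_to_length`."""
    return seq.rstrip("N")


def merge_pairs(
    fwd: Read,
    rev: Read,
    min_overlap: int = 12,
    max_diff_pct: float = 5.0,
) -> Optional[Read]:
    """Merge a read pair by its best ungapped 3' overlap.

    The reverse read is reverse-complemented, then every suffix(fwd) /
    prefix(rc rev) overlap of length >= *min_overlap* is scored; overlaps
    with more than *max_diff_pct* percent mismatches are disqualified, and
    among the rest the one with the most matching bases wins (ties to the
    longer overlap).  At each disagreeing column the base with the higher
    Phred score is taken; consensus quality is the max of the two.
    """
    rc_seq = revcomp(rev.seq)
    rc_qual = rev.qual[::-1] if rev.qual is not None else None
    fq = fwd.qual
    lenf, lenr = len(fwd.seq), len(rc_seq)
    best_L = 0
    best_matches = -1
    for L in range(min_overlap, min(lenf, lenr) + 1):
        a = fwd.seq[lenf - L :]
        b = rc_seq[:L]
        mism = sum(x != y for x, y in zip(a, b))
        if 100.0 * mism / L > max_diff_pct:
            continue
        matches = L - mism
        if matches > best_matches or (matches == best_matches and L > best_L):
            best_matches, best_L = matches, L
    if best_matches < 0:
        return None
    L = best_L
    cons = []
    cons_q = []
    for k in range(L):
        fa = fwd.seq[lenf - L + k]
        fb = rc_seq[k]
        qa = fq[lenf - L + k] if fq is not None else 40
        qb = rc_qual[k] if rc_qual is not None else 40
        if fa == fb:
            cons.append(fa)
        else:
            cons.append(fa if qa >= qb else fb)
        cons_q.append(max(qa, qb))
    seq = fwd.seq[: lenf - L] + "".join(cons) + rc_seq[L:]
    if fq is not None and rc_qual is not None:
        qual = fq[: lenf - L] + cons_q + rc_qual[L:]
    else:
        qual = None
    return Read(id=fwd.id, seq=seq, qual=qual, sample=fwd.sample)


def expected_errors(qual: Sequence[int]) -> float:
    """Expected number of errors implied by Phred scores: sum of 10^(-q/10)."""
    return float(sum(10.0 ** (-q / 10.0) for q in qual))


def filter_by_ee(reads: Iterable[Read], max_ee: float = 1.0) -> list[Read]:
    """Keep reads whose expected error count is at most *max_ee*.

    Used only to pick clustering input; OTU-table counting always uses the
    unfiltered demultiplexed reads so that expected-error trimming cannot
    bias counts against longer amplicons.
    """
    out = []
    for read in reads:
        if read.qual is None or expected_errors(read.qual) <= max_ee:
            out.append(read)
    return out
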