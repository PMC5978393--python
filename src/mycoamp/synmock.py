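"""Design of non-biological ITS-like spike-in sequences (SynMock).

Each designed member has the architecture of a real fungal rRNA ITS
cassette — SSU tail, ITS1, 5.8S, ITS2, LSU head — but the ITS1/ITS2
"spacers" are random sequences not found in nature.  The conserved
anchors carry real priming sites (ITS1-F/ITS1 in the SSU tail, an
ITS2/ITS3-compatible site and fITS7 in the 5.8S, ITS4 in the LSU head),
so the members amplify and process exactly like biological ITS amplicons
while remaining unambiguous tracers of tag-switching.

Anchor layout is exact by construction: the SSU anchor ends at the last
base of the ITS1 priming site, the 5.8S anchor starts at the
reverse-complemented ITS2 site and ends at the last base of the fITS7
site, and the LSU anchor starts at the reverse-complemented ITS4 site.
Amplicon extraction between priming sites therefore recovers each random
region exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Optional, Sequence

import numpy as np

from ._align import global_identity
from .preprocess import find_primer, revcomp

__all__ = [
    "PRIMERS",
    "SSU_ANCHOR",
    "R58S_ANCHOR",
    "LSU_ANCHOR",
    "SynMockSpec",
    "HomopolymerRun",
    "design_synmock",
    "find_homopolymers",
    "extract_subregion",
    "summarize_lengths",
]

PRIMERS: dict[str, str] = {
    "ITS1-F": "CTTGGTCATTTAGAGGAAGTAA",
    "ITS1": "TCCGTAGGTGAACCTGCGG",
    "ITS2": "GCTGCGTTCTTCATCGATGC",
    "ITS3": "GCATCGATGAAGAACGCAGC",
    "fITS7": "GTGARTCATCGAATCTTTG",
    "ITS4": "TCCTCCGCTTATTGATATGC",
}

# SSU tail: ITS1-F site, a short conserved spacer, then the ITS1 site
# flush at the 3' end.
SSU_ANCHOR = PRIMERS["ITS1-F"] + "CGTAACAAGGTT" + PRIMERS["ITS1"]
# 5.8S: starts at the rc(ITS2) == ITS3 site, ends flush at the fITS7 site
# (R resolved to A so the degenerate primer still matches at 0 edits).
R58S_ANCHOR = (
    PRIMERS["ITS3"]
    + "GAAATGCGATACGTAATGTGAATTGCAGAATTCA"
    + "GTGAATCATCGAATCTTTG"
)
# LSU head: rc(ITS4) flush at the 5' end, then a conserved spacer.
LSU_ANCHOR = revcomp(PRIMERS["ITS4"]) + "CTCAAATCAGGTAGGACTACCCGCTGAACTTAAGC"


@dataclass(frozen=True)
class HomopolymerRun:
    base: str
    start: int
    length: int


@dataclass
class SynMockSpec:
    """Design constraints for a synthetic mock community.

    Lengths are spread evenly across each range so every design includes a
    short member (platforms that drop short amplicons will show it) and a
    long member near the platform ceiling.  ``planted_homopolymers`` lists
    (run length, member count) pairs: the stated number of members each
    receive one run of that length in their ITS2 region, emulating the
    homopolymer stretches real ITS databases contain; all other
    homopolymers are capped at ``max_homopolymer``.
    """

    n_members: int = 12
    its1_len_range: tuple[int, int] = (150, 300)
    its2_len_range: tuple[int, int] = (140, 360)
    gc_range: tuple[float, float] = (0.40, 0.65)
    max_homopolymer: int = 5
    planted_homopolymers: tuple[tuple[int, int], ...] = ((7, 1), (9, 1))
    min_pairwise_divergence: float = 0.10
    seed: int = 42
    ssu_anchor: str = SSU_ANCHOR
    r58s_anchor: str = R58S_ANCHOR
    lsu_anchor: str = LSU_ANCHOR
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")
        for lo, hi in (self.its1_len_range, self.its2_len_range):
            if not 0 < lo <= hi:
                raise ValueError("empty length range")
        if not 0.0 <= self.gc_range[0] <= self.gc_range[1] <= 1.0:
            raise ValueError("invalid gc_range")


def find_homopolymers(seq: str, min_len: int = 7) -> list[HomopolymerRun]:
    """All maximal single-base runs of length >= *min_len*, in order."""
    runs = []
    pos = 0
    for base, group in groupby(seq):
        n = sum(1 for _ in group)
        if n >= min_len and base in "ACGT":
            runs.append(HomopolymerRun(base=base, start=pos, length=n))
        pos += n
    return runs


def _max_run(seq: str) -> int:
    return max((sum(1 for _ in g) for _, g in groupby(seq)), default=0)


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _random_region(
    rng: np.random.Generator,
    length: int,
    gc_range: tuple[float, float],
    max_homopolymer: int,
    max_attempts: int,
) -> str:
    bases = np.array(list("ACGT"))
    for _ in range(max_attempts):
        gc_target = rng.uniform(*gc_range)
        p = np.array(
            [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
        )
        seq = "".join(rng.choice(bases, size=length, p=p))
        if not gc_range[0] <= _gc(seq) <= gc_range[1]:
            continue
        if _max_run(seq) > max_homopolymer:
            continue
        return seq
    raise RuntimeError(
        f"could not generate a {length} bp region with GC in {gc_range} and "
        f"homopolymers <= {max_homopolymer} within {max_attempts} attempts"
    )


def _plant_run(rng: np.random.Generator, region: str, run_len: int) -> str:
    """Overwrite an interior slice with a homopolymer run of *run_len*.

    The flanks are adjusted so the planted run stays exactly *run_len*
    long (no accidental extension by neighbouring identical bases).
    """
    if len(region) < run_len + 4:
        raise ValueError("region too short to plant a homopolymer run")
    base = str(rng.choice(list("ACGT")))
    start = int(rng.integers(2, len(region) - run_len - 2))
    others = [b for b in "ACGT" if b != base]
    left = region[start - 1]
    right = region[start + run_len]
    new_left = left if left != base else str(rng.choice(others))
    new_right = right if right != base else str(rng.choice(others))
    return (
        region[: start - 1]
        + new_left
        + base * run_len
        + new_right
        + region[start + run_len + 1 :]
    )


def design_synmock(spec: SynMockSpec = SynMockSpec()) -> list[tuple[str, str]]:
    """Design a synthetic mock community per *spec*.

    Returns ``(name, sequence)`` pairs, deterministic for a given seed.
    Each member is ``ssu + ITS1_i + 5.8S + ITS2_i + lsu``; random regions
    satisfy the length/GC/homopolymer constraints and all pairwise
    identities over the concatenated ITS regions are at most
    ``1 - min_pairwise_divergence``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_members
    its1_lens = np.linspace(*spec.its1_len_range, n).round().astype(int)
    its2_lens = np.linspace(*spec.its2_len_range, n).round().astype(int)
    # which members receive a planted run, longest runs first
    planted: list[Optional[int]] = [None] * n
    member = 0
    for run_len, count in sorted(spec.planted_homopolymers, reverse=True):
        for _ in range(count):
            if member < n:
                planted[member] = run_len
                member += 1
    members: list[tuple[str, str]] = []
    its_regions: list[str] = []
    for i in range(n):
        for _ in range(spec.max_attempts):
            its1 = _random_region(
                rng, int(its1_lens[i]), spec.gc_range,
                spec.max_homopolymer, spec.max_attempts,
            )
            its2 = _random_region(
                rng, int(its2_lens[i]), spec.gc_range,
                spec.max_homopolymer, spec.max_attempts,
            )
            if planted[i] is not None:
                its2 = _plant_run(rng, its2, planted[i])
                if not spec.gc_range[0] <= _gc(its2) <= spec.gc_range[1]:
                    continue
            combined = its1 + its2
            ceiling = 1.0 - spec.min_pairwise_divergence
            if any(global_identity(combined, prev) > ceiling for prev in its_regions):
                continue
            break
        else:
            raise RuntimeError(
                f"member {i + 1}: constraints unsatisfiable after "
                f"{spec.max_attempts} attempts"
            )
        its_regions.append(combined)
        seq = spec.ssu_anchor + its1 + spec.r58s_anchor + its2 + spec.lsu_anchor
        members.append((f"SynMock_{i + 1:02d}", seq))
    return members


def extract_subregion(
    seqs: Sequence[tuple[str, str]],
    fwd_primer: str,
    rev_primer: str,
    max_edits: int = 2,
) -> tuple[list[tuple[str, str]], int]:
    """Extract the region between two priming sites from each sequence.

    *rev_primer* is given in primer (sense) orientation and matched via its
    reverse complement downstream of the forward site.  Primers are
    excluded from the output.  Returns (extracted pairs, number skipped
    for lacking either site).
    """
    rc_rev = revcomp(rev_primer)
    out: list[tuple[str, str]] = []
    skipped = 0
    for name, seq in seqs:
        fwd_hit = find_primer(seq, fwd_primer, max_edits, primer_name="fwd")
        if fwd_hit is None:
            skipped += 1
            continue
        tail = seq[fwd_hit.end :]
        rev_hit = find_primer(tail, rc_rev, max_edits, primer_name="rev")
        if rev_hit is None:
            skipped += 1
            continue
        out.append((name, tail[: rev_hit.start]))
    return out, skipped


def summarize_lengths(
    seqs: Sequence[tuple[str, str]],
    hp_thresholds: Sequence[int] = (6, 8),
    long_cutoff: int = 450,
) -> dict:
    """Length and homopolymer census of a sequence set.

    Returns n, mean length (rounded to whole bp), the percentage of
    sequences containing any homopolymer run longer than each threshold,
    and the percentage longer than *long_cutoff* bp.
    """
    n = len(seqs)
    if n == 0:
        return {"n": 0, "avg_length": 0,
                **{f"pct_hp_gt_{t}": 0.0 for t in hp_thresholds},
                f"pct_gt_{long_cutoff}bp": 0.0}
    lengths = [len(seq) for _, seq in seqs]
    stats = {"n": n, "avg_length": int(round(sum(lengths) / n))}
    for t in hp_thresholds:
        with_hp = sum(
            1 for _, seq in seqs if find_homopolymers(seq, min_len=t + 1)
        )
        stats[f"pct_hp_gt_{t}"] = 100.0 * with_hp / n
    stats[f"pct_gt_{long_cutoff}bp"] = (
        100.0 * sum(1 for L in lengths if L > long_cutoff) / n
    )
    return stats
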