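"""Taxonomy assignment: global alignment, k-mer bootstrap classifier, LCA.

The default assignment is a hybrid of two signals.  When a query aligns
to a reference above 97% identity the top hit's lineage is trusted
outright; below that, a bootstrap k-mer classifier provides a
rank-resolved confidence, and where the two methods disagree the lineage
is backed off to their least common ancestor — a deliberately
conservative consensus for sequences far from any reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._align import global_identity

__all__ = [
    "RANKS",
    "Lineage",
    "RefDB",
    "top_hit_global",
    "classify_kmer_bootstrap",
    "hybrid_assign",
    "lca",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_LETTERS = "kpcofgs"


@dataclass(frozen=True)
class Lineage:
    """Seven-rank lineage (kingdom..species) with optional per-rank confidence.

    Set ranks always form a prefix: a genus is never set without its
    family.  ``method`` records which assignment path produced it.
    """

    ranks: tuple[Optional[str], ...] = (None,) * 7
    conf: Optional[tuple[Optional[float], ...]] = None
    method: str = "NA"

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise ValueError("a lineage has exactly 7 ranks")
        unset_seen = False
        for name in self.ranks:
            if name is None:
                unset_seen = True
            elif unset_seen:
                raise ValueError(f"set ranks must form a prefix: {self.ranks}")

    @property
    def depth(self) -> int:
        return sum(1 for r in self.ranks if r is not None)

    def is_empty(self) -> bool:
        return self.depth == 0

    def to_string(self) -> str:
        parts = [
            f"{letter}:{name}"
            for letter, name in zip(_RANK_LETTERS, self.ranks)
            if name is not None
        ]
        return ",".join(parts)

    @classmethod
    def from_string(cls, text: str, method: str = "NA") -> "Lineage":
        """Parse ``k:Fungi,p:...`` (SINTAX/UTAX) or ``k__Fungi;p__...`` (QIIME)."""
        names: dict[str, str] = {}
        if "__" in text:
            for chunk in text.replace(" ", "").split(";"):
                if "__" in chunk:
                    letter, _, name = chunk.partition("__")
                    if name:
                        names[letter.lower()] = name
        else:
            for chunk in text.split(","):
                if ":" in chunk:
                    letter, _, name = chunk.partition(":")
                    if name:
                        names[letter.strip().lower()] = name.strip()
        ranks = []
        for letter in _RANK_LETTERS:
            ranks.append(names.get(letter))
        # truncate at the first unset rank so set ranks form a prefix
        out: list[Optional[str]] = []
        for name in ranks:
            if name is None:
                break
            out.append(name)
        out.extend([None] * (7 - len(out)))
        return cls(ranks=tuple(out), method=method)


@dataclass
class RefDB:
    """Reference database: (id, sequence, lineage) plus a k-mer index."""

    entries: list[tuple[str, str, Lineage]]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reference ids")
        # keep entries id-sorted so every argmax tie-break is deterministic
        self.entries.sort(key=lambda e: e[0])
        self._kmer_cache: dict[int, list[frozenset]] = {}

    @classmethod
    def from_fasta(cls, path) -> "RefDB":
        """Load references whose headers carry a lineage.

        Accepted dialects (auto-detected): ``>ID;tax=k:Fungi,p:...`` and
        ``>ID k__Fungi;p__...``.
        """
        from Bio import SeqIO

        from .seqio import _normalize_seq, _open_text

        entries = []
        with _open_text(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                header = rec.description
                if ";tax=" in header:
                    rid, _, tax = header.partition(";tax=")
                elif "__" in header:
                    rid, _, tax = header.partition(" ")
                    if "__" not in tax:
                        rid, _, tax = header.partition(";")
                    if "__" not in tax:
                        raise ValueError(f"no lineage in header {header!r}")
                else:
                    raise ValueError(f"no lineage in header {header!r}")
                entries.append(
                    (rid.strip(), _normalize_seq(str(rec.seq)), Lineage.from_string(tax))
                )
        return cls(entries=entries)

    def kmer_sets(self, k: int) -> list[frozenset]:
        if k not in self._kmer_cache:
            self._kmer_cache[k] = [
                frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))
                for _, seq, _ in self.entries
            ]
        return self._kmer_cache[k]

    def lineage_of(self, ref_id: str) -> Lineage:
        for rid, _, lineage in self.entries:
            if rid == ref_id:
                return lineage
        raise KeyError(ref_id)


def top_hit_global(query: str, db: RefDB) -> tuple[str, float]:
    """Exhaustive best global-alignment hit; ties go to the smallest id."""
    if not db.entries:
        raise ValueError("empty reference database")
    best_id, best_ident = None, -1.0
    for rid, seq, _ in db.entries:  # id-sorted: first strict max wins ties
        ident = global_identity(query, seq)
        if ident > best_ident:
            best_id, best_ident = rid, ident
    return best_id, best_ident


def classify_kmer_bootstrap(
    query: str,
    db: RefDB,
    k: int = 8,
    m: int = 32,
    B: int = 100,
    seed: int = 0,
    conf_cutoff: float = 0.8,
) -> Lineage:
    """Bootstrap k-mer classifier with per-rank confidence.

    Each bootstrap draws *m* k-mers uniformly with replacement from the
    query's k-mer set and scores every reference by how many drawn k-mers
    it contains (ties to the smallest reference id).  Confidence at a rank
    is the fraction of bootstraps whose winning reference agrees with the
    overall winner at that rank, forced non-increasing down the ranks.
    The reported lineage stops at the deepest rank with confidence at
    least *conf_cutoff*.
    """
    if not db.entries:
        raise ValueError("empty reference database")
    qkmers = sorted({query[i : i + k] for i in range(len(query) - k + 1)})
    empty = Lineage(method="CLF")
    if not qkmers:
        return empty
    ref_sets = db.kmer_sets(k)
    n_refs = len(db.entries)
    membership = np.zeros((len(qkmers), n_refs), dtype=np.int32)
    for qi, kmer in enumerate(qkmers):
        for ri, rset in enumerate(ref_sets):
            if kmer in rset:
                membership[qi, ri] = 1
    full_scores = membership.sum(axis=0)
    if full_scores.max() == 0:
        return empty
    chosen = db.entries[int(full_scores.argmax())][2]  # argmax: first max, id-sorted

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(qkmers), size=(B, m))
    agree = np.zeros(7, dtype=np.int64)
    informative = 0
    for b in range(B):
        scores = membership[draws[b]].sum(axis=0)
        if scores.max() == 0:
            continue
        informative += 1
        winner = db.entries[int(scores.argmax())][2]
        for r in range(7):
            if chosen.ranks[r] is not None and winner.ranks[r] == chosen.ranks[r]:
                agree[r] += 1
    if informative == 0:
        return empty
    conf = agree / informative
    conf = np.minimum.accumulate(conf)  # enforce monotone non-increasing
    ranks: list[Optional[str]] = []
    confs: list[Optional[float]] = []
    for r in range(7):
        if chosen.ranks[r] is not None and conf[r] >= conf_cutoff:
            ranks.append(chosen.ranks[r])
            confs.append(float(conf[r]))
        else:
            break
    ranks.extend([None] * (7 - len(ranks)))
    confs.extend([None] * (7 - len(confs)))
    return Lineage(ranks=tuple(ranks), conf=tuple(confs), method="CLF")


def lca(a: Lineage, b: Lineage) -> Lineage:
    """Least common ancestor: longest common prefix of set ranks."""
    ranks: list[Optional[str]] = []
    for ra, rb in zip(a.ranks, b.ranks):
        if ra is not None and ra == rb:
            ranks.append(ra)
        else:
            break
    ranks.extend([None] * (7 - len(ranks)))
    return Lineage(ranks=tuple(ranks), method="LCA")


def hybrid_assign(
    ga: tuple[str, float],
    clf: Lineage,
    db: RefDB,
    ga_threshold: float = 0.97,
) -> Lineage:
    """Combine global-alignment and classifier assignments.

    Above *ga_threshold* identity (strictly) the alignment top hit wins.
    Otherwise the classifier lineage is used — unless it disagrees with
    the alignment lineage at some rank both have set, in which case the
    least common ancestor of the two is returned.
    """
    ref_id, identity = ga
    ga_lineage = replace(db.lineage_of(ref_id), method="GA", conf=None)
    if identity > ga_threshold:
        return ga_lineage
    disagreement = any(
        ra is not None and rb is not None and ra != rb
        for ra, rb in zip(ga_lineage.ranks, clf.ranks)
    )
    if disagreement:
        return lca(ga_lineage, clf)
    return replace(clf, method="CLF")
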