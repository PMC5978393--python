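"""Global identity, dereplication, greedy clustering, mapping, rarefaction."""

import numpy as np
import pytest

from mycoamp._align import nw_stats
from mycoamp.cluster import (
    OTU,
    OTUTable,
    cluster_otus,
    dereplicate,
    flag_chimera,
    global_identity,
    map_reads_to_otus,
    rarefy,
)
from mycoamp.seqio import Read
from mycoamp.simdata import simulate_run

from _oracles import identity_oracle, nw_oracle
from conftest import make_mock_run_spec, random_seq


class TestGlobalIdentity:
    def test_self_identity(self, rng):
        for _ in range(10):
            seq = random_seq(rng, int(rng.integers(1, 100)))
            assert global_identity(seq, seq) == 1.0

    def test_single_substitution(self):
        assert global_identity("ACGTACGT", "ACGAACGT") == pytest.approx(7 / 8)

    def test_terminal_gaps_count_in_denominator(self):
        # global alignment: a trailing overhang costs identity
        assert global_identity("ACGTACGT", "ACGTACGTCCCC") == pytest.approx(8 / 12)

    def test_symmetry(self, rng):
        for _ in range(30):
            a = random_seq(rng, int(rng.integers(5, 40)))
            b = random_seq(rng, int(rng.integers(5, 40)))
            assert global_identity(a, b) == global_identity(b, a)

    def test_matches_bruteforce_dp_oracle(self, rng):
        for _ in range(200):
            a = random_seq(rng, int(rng.integers(1, 26)))
            b = random_seq(rng, int(rng.integers(1, 26)))
            score, matches, mism, gaps, cols = nw_stats(a, b)
            o_score, o_matches, o_mism, o_gaps, o_cols = nw_oracle(a, b)
            assert score == o_score
            assert (matches, mism, gaps, cols) == (o_matches, o_mism, o_gaps, o_cols)
            assert global_identity(a, b) == pytest.approx(identity_oracle(a, b))

    def test_score_agrees_with_biopython_aligner(self, rng):
        # independent C implementation of the same scoring scheme
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        for _ in range(50):
            a = random_seq(rng, int(rng.integers(5, 120)))
            b = random_seq(rng, int(rng.integers(5, 120)))
            assert nw_stats(a, b)[0] == aligner.score(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "ACGT")


class TestDereplicate:
    def test_basic_collapse(self):
        out = dereplicate(["AAA", "AAA", "CCC"])
        assert [(u.seq, u.size) for u in out] == [("AAA", 2), ("CCC", 1)]

    def test_all_distinct(self, rng):
        seqs = {random_seq(rng, 20) for _ in range(30)}
        out = dereplicate(list(seqs))
        assert all(u.size == 1 for u in out)
        assert len(out) == len(seqs)

    def test_sizes_sum_to_input_and_match_simulation(self, synmock_its2):
        spec = make_mock_run_spec(synmock_its2, [], n_env_samples=0,
                                  reads_per_sample=200)
        reads, truth = simulate_run(spec)
        # error-free: unique sequences are exactly the templates drawn
        uniques = dereplicate([r.seq.split(FWD, 1)[1].split(RC_REV, 1)[0]
                               for r in reads])
        truth_sizes = truth.observed_matrix().sum(axis=1)
        got = {u.seq: u.size for u in uniques}
        templates = dict(spec.templates)
        for name, size in truth_sizes.items():
            if size > 0:
                assert got[templates[name]] == size
        assert sum(u.size for u in uniques) == len(reads)

    def test_tie_break_is_lexicographic(self):
        out = dereplicate(["TTT", "AAA", "CCC"])
        assert [u.seq for u in out] == ["AAA", "CCC", "TTT"]


# scaffold constants used to strip simulated reads down to their template
from mycoamp.simdata import FWD_PRIMER_SEQ as FWD  # noqa: E402
from mycoamp.preprocess import revcomp  # noqa: E402
from mycoamp.simdata import REV_PRIMER_SEQ  # noqa: E402

RC_REV = revcomp(REV_PRIMER_SEQ)


def _mutate_pct(rng, seq: str, pct: float) -> str:
    n = int(round(len(seq) * pct))
    positions = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for pos in positions:
        chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
    return "".join(chars)


class TestClusterOtus:
    def test_two_nearly_identical_sequences_one_otu(self, rng):
        a = random_seq(rng, 200)
        b = _mutate_pct(rng, a, 0.01)  # 99% identical
        otus = cluster_otus(dereplicate([a] * 5 + [b] * 3), min_size=2)
        assert len(otus) == 1

    def test_boundary_at_97_percent(self, rng):
        a = random_seq(rng, 200)
        at_97 = _mutate_pct(rng, a, 0.03)  # identity exactly 194/200 = 0.97
        below = _mutate_pct(rng, a, 0.045)  # 0.955 < 0.97
        assert global_identity(a, at_97) == pytest.approx(0.97)
        assert len(cluster_otus(dereplicate([a] * 5 + [at_97] * 3))) == 1
        assert len(cluster_otus(dereplicate([a] * 5 + [below] * 3),
                                chimera_check=False)) == 2

    def test_synmock_regions_recovered_exactly(self, synmock_its2):
        reads = [seq for _, seq in synmock_its2 for _ in range(5)]
        otus = cluster_otus(dereplicate(reads))
        assert len(otus) == len(synmock_its2) == 12
        centroids = {o.centroid for o in otus}
        assert centroids == {seq for _, seq in synmock_its2}

    def test_noisy_reads_still_recover_references(self, rng):
        refs = [random_seq(rng, 250) for _ in range(20)]
        reads = []
        for ref in refs:
            reads.append(ref)  # most-abundant unique is error-free
            reads.append(ref)
            for _ in range(8):
                reads.append(_mutate_pct(rng, ref, 0.01))
        otus = cluster_otus(dereplicate(reads))
        assert len(otus) == 20
        for ref in refs:
            assert max(global_identity(ref, o.centroid) for o in otus) >= 0.99

    def test_min_size_excludes_singletons_from_centroids(self, rng):
        a = random_seq(rng, 150)
        lone = random_seq(rng, 150)
        otus = cluster_otus(dereplicate([a, a, a, lone]))
        assert len(otus) == 1 and otus[0].centroid == a

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            cluster_otus([], id_threshold=0.4)

    def test_centroid_pairs_below_threshold(self, rng):
        reads = [random_seq(rng, 120) for _ in range(15) for _ in range(3)]
        otus = cluster_otus(dereplicate(reads))
        for i, a in enumerate(otus):
            for b in otus[i + 1 :]:
                assert global_identity(a.centroid, b.centroid) < 0.97


class TestFlagChimera:
    def test_constructed_bipartite_chimera(self, rng):
        a = random_seq(rng, 200)
        b = random_seq(rng, 200)
        chimera = a[:100] + b[100:]
        assert flag_chimera(chimera, [a, b]) is True

    def test_centroid_itself_not_flagged(self, rng):
        a = random_seq(rng, 200)
        b = random_seq(rng, 200)
        assert flag_chimera(a, [a, b]) is False

    def test_fewer_than_two_centroids(self, rng):
        assert flag_chimera(random_seq(rng, 200), [random_seq(rng, 200)]) is False

    def test_simulated_crossovers_mostly_flagged(self, synmock_its2, rng):
        refs = [seq for _, seq in synmock_its2]
        flagged = 0
        n = 50
        for _ in range(n):
            i, j = rng.choice(len(refs), size=2, replace=False)
            a, b = refs[i], refs[j]
            split_a = int(rng.integers(60, len(a) - 60))
            split_b = int(rng.integers(60, len(b) - 60))
            chimera = a[:split_a] + b[split_b:]
            if flag_chimera(chimera, refs):
                flagged += 1
        assert flagged / n >= 0.90


class TestMapReads:
    def test_error_free_run_reproduces_truth_matrix(self, synmock_its2, biomock):
        env = [m for m in biomock[:9] if len(m[1]) <= 380]
        spec = make_mock_run_spec(synmock_its2, env, reads_per_sample=250)
        reads, truth = simulate_run(spec)
        from mycoamp.preprocess import demux_single

        demuxed, _ = demux_single(reads, spec.sample_sheet(), max_len=400)
        otus = cluster_otus(dereplicate(demuxed))
        table = map_reads_to_otus(demuxed, otus,
                                  sample_ids=[s for s, _ in spec.samples])
        truth_m = truth.observed_matrix()
        by_centroid = {o.centroid: o.otu_id for o in otus}
        templates = dict(spec.templates)
        for name in truth_m.index:
            if truth_m.loc[name].sum() == 0:
                continue
            otu_id = by_centroid[templates[name]]
            assert (table.df.loc[otu_id] == truth_m.loc[name]).all()
        assert table.df.values.sum() == truth_m.values.sum()

    def test_read_below_threshold_not_counted(self, rng):
        centroid = random_seq(rng, 200)
        otus = [OTU(otu_id="OTU_1", centroid=centroid)]
        near = Read(id="a", seq=_mutate_pct(rng, centroid, 0.03), sample="S")
        far = Read(id="b", seq=_mutate_pct(rng, centroid, 0.04), sample="S")
        table = map_reads_to_otus([near, far], otus)
        assert table.df.loc["OTU_1", "S"] == 1

    def test_unlabeled_read_is_an_error(self, rng):
        with pytest.raises(ValueError, match="no sample label"):
            map_reads_to_otus([Read(id="x", seq=random_seq(rng, 50))], [])

    def test_empty_reads_give_zero_table(self, rng):
        otus = [OTU(otu_id="OTU_1", centroid=random_seq(rng, 100))]
        table = map_reads_to_otus([], otus, sample_ids=["S1", "S2"])
        assert table.df.shape == (1, 2)
        assert (table.df.values == 0).all()

    def test_column_sums_bounded_by_demux_counts(self, synmock_its2):
        spec = make_mock_run_spec(synmock_its2, [], n_env_samples=0,
                                  reads_per_sample=150, sub_rate=0.01)
        reads, _ = simulate_run(spec)
        from mycoamp.preprocess import demux_single

        demuxed, stats = demux_single(reads, spec.sample_sheet(), max_len=400)
        otus = cluster_otus(dereplicate(demuxed))
        table = map_reads_to_otus(demuxed, otus)
        for sample, total in table.sample_totals().items():
            assert total <= stats.kept[sample]


class TestRarefy:
    def _table(self):
        import pandas as pd

        return OTUTable(
            pd.DataFrame(
                {"S1": [50, 30, 20], "S2": [10, 5, 5], "S3": [400, 0, 100]},
                index=["OTU_1", "OTU_2", "OTU_3"],
            )
        )

    def test_column_at_depth_unchanged(self):
        out = rarefy(self._table(), depth=20, seed=0)
        assert (out.df["S2"] == [10, 5, 5]).all()

    def test_all_columns_sum_to_depth(self):
        out = rarefy(self._table(), depth=20, seed=1)
        assert (out.sample_totals() == 20).all()

    def test_shallow_columns_dropped_and_reported(self):
        out, dropped = rarefy(self._table(), depth=50, seed=2, return_dropped=True)
        assert dropped == ["S2"]
        assert out.sample_ids == ["S1", "S3"]

    def test_deterministic_given_seed(self):
        a = rarefy(self._table(), depth=60, seed=7)
        b = rarefy(self._table(), depth=60, seed=7)
        assert a.df.equals(b.df)

    def test_expected_counts_hypergeometric(self):
        # OTU_1 holds 80% of S3; mean subsampled count over seeds ~ 0.8*depth
        depth = 100
        vals = [
            rarefy(self._table(), depth=depth, seed=s).df.loc["OTU_1", "S3"]
            for s in range(200)
        ]
        p = 400 / 500
        se = np.sqrt(depth * p * (1 - p) * (500 - depth) / (500 - 1)) / np.sqrt(200)
        assert abs(np.mean(vals) - p * depth) <= 3 * se + 1e-9
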