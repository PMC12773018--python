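import math

import numpy as np
import pytest

from pepdev.align import pairwise_identity
from pepdev.chem import circular_fingerprint, sequence_to_smiles
from pepdev.core import Modality, PeptideRecord, PropertyDataset, get_task
from pepdev.split import (
    audit_leakage,
    cluster_sequences_by_identity,
    cluster_smiles_butina,
    cluster_split,
    distribution_matched_split,
    propagate_split,
)

from .conftest import random_aa_sequences
from .oracles import naive_butina, naive_greedy_identity_clusters


def _same_partitioning(a: dict, b: dict) -> bool:
    """Cluster maps are equal up to relabeling."""
    fwd, bwd = {}, {}
    for k in a:
        ca, cb = a[k], b[k]
        if fwd.setdefault(ca, cb) != cb or bwd.setdefault(cb, ca) != ca:
            return False
    return set(a) == set(b)


class TestIdentityClustering:
    def test_duplicates_one_cluster(self):
        ca = cluster_sequences_by_identity(["GLFDIVKKVV"] * 4)
        assert ca.n_clusters == 1

    def test_empty_input(self):
        ca = cluster_sequences_by_identity([])
        assert ca.n_clusters == 0 and ca.member_of == {}

    def test_cluster_ids_contiguous(self, rng):
        seqs = random_aa_sequences(rng, 25, 6, 12)
        ca = cluster_sequences_by_identity(seqs)
        assert sorted(set(ca.member_of.values())) == list(range(ca.n_clusters))

    def test_coverage_rule_separates_block_pair(self, rng):
        # a 10-residue block shared between a 40-mer and a 12-mer: identity
        # passes but the long sequence's coverage stays far below 0.8
        block = "WWWWWCCCCC"
        long_seq = "".join(rng.choice(list("ADEFG"), size=15)) + block + "".join(
            rng.choice(list("ADEFG"), size=15)
        )
        short_seq = "K" + block + "K"
        ident, cov_long, cov_short = pairwise_identity(long_seq, short_seq)
        assert ident >= 0.2 and cov_long < 0.8
        ca = cluster_sequences_by_identity([long_seq, short_seq], min_id=0.2, min_cov=0.8)
        assert ca.n_clusters == 2
        # dropping the coverage requirement merges them
        ca2 = cluster_sequences_by_identity([long_seq, short_seq], min_id=0.2, min_cov=0.0)
        assert ca2.n_clusters == 1

    def test_oracle_equivalence(self, rng):
        for _ in range(10):
            seqs = random_aa_sequences(rng, 20, 8, 14)
            ca = cluster_sequences_by_identity(seqs, min_id=0.3, min_cov=0.8)
            want = naive_greedy_identity_clusters(
                [(str(i), s) for i, s in enumerate(seqs)], 0.3, 0.8, pairwise_identity
            )
            assert _same_partitioning(ca.member_of, want)

    def test_rejects_smiles_modality(self):
        rec = PeptideRecord(id="a", modality=Modality.SMILES, payload="NCC(=O)O", labels={})
        with pytest.raises(ValueError, match="not AA"):
            cluster_sequences_by_identity([rec])


class TestButina:
    def _fps(self, seqs):
        return [circular_fingerprint(sequence_to_smiles(s)) for s in seqs]

    def test_all_singletons(self, rng):
        # maximally different tiny molecules fall below threshold 0.6
        fps = self._fps(["GG", "WW", "RR", "DD"])
        ca = cluster_smiles_butina(fps, sim_threshold=0.9)
        assert ca.n_clusters == 4

    def test_identical_molecules_one_cluster(self):
        fps = self._fps(["GAG"] * 5)
        ca = cluster_smiles_butina(fps, sim_threshold=0.6)
        assert ca.n_clusters == 1

    def test_oracle_equivalence_crafted(self, rng):
        from pepdev.chem import tanimoto

        for _ in range(8):
            seqs = ["".join(rng.choice(list("GAVLK"), size=rng.integers(2, 5)))
                    for _ in range(10)]
            fps = self._fps(seqs)
            n = len(fps)
            sim = np.ones((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    sim[i, j] = sim[j, i] = tanimoto(fps[i], fps[j])
            ca = cluster_smiles_butina(fps, sim_threshold=0.6)
            want = naive_butina(sim, 0.6)
            got = [ca.member_of[str(i)] for i in range(n)]
            assert _same_partitioning(
                {i: got[i] for i in range(n)}, {i: want[i] for i in range(n)}
            )

    def test_parameter_mismatch(self):
        a = circular_fingerprint("NCC(=O)O", nbits=512)
        b = circular_fingerprint("NCC(=O)O", nbits=1024)
        with pytest.raises(ValueError):
            cluster_smiles_butina([a, b])


class TestClusterSplit:
    def _ca(self, n_clusters, per=2):
        member = {f"r{c}_{k}": c for c in range(n_clusters) for k in range(per)}
        from pepdev.split import ClusterAssignment

        return ClusterAssignment(member_of=member, method="identity_greedy")

    def test_80_20_split_of_100_clusters(self):
        sa = cluster_split(self._ca(100), train_frac=0.8, seed=1)
        parts = list(sa.partition_of.values())
        assert parts.count("train") == 80 and parts.count("val") == 20

    def test_ceiling_rule(self):
        sa = cluster_split(self._ca(5), train_frac=0.8, seed=0)
        assert list(sa.partition_of.values()).count("train") == 4

    def test_deterministic(self):
        a = cluster_split(self._ca(20), seed=42)
        b = cluster_split(self._ca(20), seed=42)
        assert a.partition_of == b.partition_of

    def test_different_seeds_differ(self):
        outs = {tuple(sorted(cluster_split(self._ca(30), seed=s).partition_of.items()))
                for s in range(5)}
        assert len(outs) > 1

    def test_min_clusters(self):
        with pytest.raises(ValueError):
            cluster_split(self._ca(1))

    def test_clusters_never_straddle(self):
        sa = cluster_split(self._ca(10, per=5), seed=3)
        part = sa.record_partition
        for c in range(10):
            assert len({part[f"r{c}_{k}"] for k in range(5)}) == 1

    def test_exact_train_fraction(self):
        for n in (5, 7, 13, 100):
            sa = cluster_split(self._ca(n), train_frac=0.8, seed=0)
            got = list(sa.partition_of.values()).count("train")
            assert got == math.ceil(0.8 * n)


class TestPropagate:
    def test_partitions_preserved(self, rng):
        seqs = random_aa_sequences(rng, 12, 6, 10)
        ca = cluster_sequences_by_identity(seqs)
        if ca.n_clusters < 2:
            pytest.skip("degenerate corpus")
        sa = cluster_split(ca, seed=0)
        records = [
            PeptideRecord(id=str(i), modality=Modality.AA, payload=s,
                          labels={"hemolysis": 0.0})
            for i, s in enumerate(seqs)
        ]
        ds = PropertyDataset(task=get_task("hemolysis"), records=records)
        from pepdev.synth import convert_to_smiles

        smiles_ds = convert_to_smiles(ds)
        sa2 = propagate_split(sa, smiles_ds)
        assert sa2.record_partition == {
            r.id: sa.partition(r.id) for r in smiles_ds.records
        }

    def test_missing_id_raises(self, small_binary_dataset):
        from pepdev.split import SplitAssignment

        sa = SplitAssignment(
            cluster_of={"other": 0}, partition_of={0: "train"},
            train_frac=0.8, seed=0, method="m",
        )
        with pytest.raises(KeyError, match="r0"):
            propagate_split(sa, small_binary_dataset)

    def test_empty_converted(self):
        from pepdev.split import SplitAssignment

        sa = SplitAssignment(
            cluster_of={"a": 0}, partition_of={0: "train"},
            train_frac=0.8, seed=0, method="m",
        )
        ds = PropertyDataset(task=get_task("hemolysis"), records=[])
        assert propagate_split(sa, ds).cluster_of == {}


class TestDistributionMatchedSplit:
    def test_uniform_values_low_ks(self, rng):
        sa, ks = distribution_matched_split(rng.uniform(size=1000), n_bins=10, seed=5)
        assert ks < 0.1

    def test_identical_values(self):
        sa, ks = distribution_matched_split([3.0] * 10, seed=0)
        assert ks == 0.0

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            distribution_matched_split([1.0, 2.0, 3.0, 4.0])

    def test_moments_match_within_5pct(self, rng):
        vals = rng.normal(8.0, 2.0, size=1000)
        sa, _ = distribution_matched_split(vals, seed=3)
        part = sa.record_partition
        tr = np.array([vals[int(i)] for i in part if part[i] == "train"])
        va = np.array([vals[int(i)] for i in part if part[i] == "val"])
        assert abs(tr.mean() - va.mean()) / abs(tr.mean()) < 0.05
        assert abs(tr.var() - va.var()) / tr.var() < 0.05

    def test_deterministic(self, rng):
        vals = rng.uniform(size=100)
        a, _ = distribution_matched_split(vals, seed=9)
        b, _ = distribution_matched_split(vals, seed=9)
        assert a.record_partition == b.record_partition


class TestAuditLeakage:
    def _sim(self, a, b):
        return pairwise_identity(a, b)[0]

    def test_no_violations_by_construction(self, rng):
        seqs = list({s for s in random_aa_sequences(rng, 30, 6, 12)})
        ca = cluster_sequences_by_identity(seqs, min_id=0.5, min_cov=0.5)
        if ca.n_clusters < 2:
            pytest.skip("degenerate corpus")
        sa = cluster_split(ca, seed=0)
        report = audit_leakage(
            sa, list(zip([str(i) for i in range(len(seqs))], seqs)),
            lambda a, b: float(a == b), threshold=1.0,
        )
        assert report["n_violations"] == 0 and report["exhaustive"]

    def test_planted_leakage_detected(self):
        from pepdev.split import SplitAssignment

        seqs = ["GLFDIVKKVV"] * 6
        sa = SplitAssignment(
            cluster_of={str(i): i for i in range(6)},
            partition_of={i: ("train" if i < 3 else "val") for i in range(6)},
            train_frac=0.5, seed=0, method="random",
        )
        report = audit_leakage(
            sa, list(zip(map(str, range(6)), seqs)), self._sim, threshold=0.9
        )
        assert report["n_violations"] == 9
        assert report["worst_pairs"]

    def test_single_partition_no_cross_pairs(self):
        from pepdev.split import SplitAssignment

        sa = SplitAssignment(
            cluster_of={"a": 0, "b": 0}, partition_of={0: "train"},
            train_frac=1.0, seed=0, method="m",
        )
        report = audit_leakage(sa, [("a", "GG"), ("b", "AA")], self._sim, 0.3)
        assert report["n_violations"] == 0 and report["n_checked"] == 0
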