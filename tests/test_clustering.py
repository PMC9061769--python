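"""ANI/AF computation and genome/protein clustering."""

from __future__ import annotations

import numpy as np
import pytest

from amdvir.align import read_tabular_hits, seed_extend_hits, write_tabular_hits
from amdvir.clustering import (
    cluster_proteins,
    cluster_viral_populations,
    compute_ani_af,
    dereplicate_prokaryote_genomes,
)
from amdvir.records import GenomeRecord

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate(seq, divergence, rng):
    n = int(round(divergence * len(seq)))
    pos = rng.choice(len(seq), n, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestComputeAniAf:
    def test_identical_sequences(self, rng):
        seq = random_seq(rng, 10_000)
        a = GenomeRecord("a", seq)
        b = GenomeRecord("b", seq)
        res = compute_ani_af(a, b)
        assert res.ani == pytest.approx(100.0)
        assert res.af_smaller == pytest.approx(100.0)

    def test_three_percent_divergence(self, rng):
        """10 kb pair differing at exactly 300 positions: ANI 97, AF 100."""
        seq = random_seq(rng, 10_000)
        a = GenomeRecord("a", seq)
        b = GenomeRecord("b", mutate(seq, 0.03, rng))
        res = compute_ani_af(a, b)
        assert res.ani == pytest.approx(97.0, abs=0.2)
        assert res.af_smaller == pytest.approx(100.0, abs=0.5)

    def test_contained_contig_af_of_smaller(self, rng):
        """5 kb contig at 98% identity inside a 10 kb contig: AF is 100."""
        host = random_seq(rng, 10_000)
        inner = mutate(host[2_000:7_000], 0.02, rng)
        a = GenomeRecord("short", inner)
        b = GenomeRecord("long", host)
        res = compute_ani_af(a, b)
        assert res.ani == pytest.approx(98.0, abs=0.3)
        assert res.af_smaller == pytest.approx(100.0, abs=1.0)

    def test_no_hits_yields_zero(self, rng):
        a = GenomeRecord("a", random_seq(rng, 10_000))
        b = GenomeRecord("b", random_seq(rng, 10_000))
        res = compute_ani_af(a, b)
        assert (res.ani, res.af_smaller) == (0.0, 0.0)

    def test_symmetry(self, rng):
        seq = random_seq(rng, 12_000)
        a = GenomeRecord("a", seq[:11_000])
        b = GenomeRecord("b", mutate(seq, 0.05, rng))
        r1 = compute_ani_af(a, b)
        r2 = compute_ani_af(b, a)
        assert r1.ani == pytest.approx(r2.ani, abs=1e-9)
        assert r1.af_smaller == pytest.approx(r2.af_smaller, abs=1e-9)


class TestViralClustering:
    def test_planted_pair_plus_background(self, rng):
        seq = random_seq(rng, 12_000)
        a = GenomeRecord("A", seq)
        b = GenomeRecord("B", mutate(seq, 0.03, rng))
        c = GenomeRecord("C", random_seq(rng, 11_000))
        clusters = cluster_viral_populations([a, b, c])
        parts = {frozenset(cl.members) for cl in clusters}
        assert parts == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_both_thresholds_required(self, rng):
        """ANI ~96 but AF ~50: the pair must stay apart."""
        seq = random_seq(rng, 10_000)
        a = GenomeRecord("A", seq)
        half = mutate(seq[:5_000], 0.04, rng) + random_seq(rng, 5_000)
        b = GenomeRecord("B", half)
        res = compute_ani_af(a, b)
        assert res.ani > 95.0
        assert res.af_smaller < 85.0
        clusters = cluster_viral_populations([a, b])
        assert len(clusters) == 2

    def test_identical_genomes_one_cluster(self, rng):
        seq = random_seq(rng, 10_000)
        genomes = [GenomeRecord(f"g{i}", seq) for i in range(5)]
        clusters = cluster_viral_populations(genomes)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 5

    def test_order_invariance(self, rng):
        seq1 = random_seq(rng, 12_000)
        seq2 = random_seq(rng, 10_500)
        genomes = [
            GenomeRecord("A", seq1),
            GenomeRecord("B", mutate(seq1, 0.02, rng)),
            GenomeRecord("C", seq2),
            GenomeRecord("D", mutate(seq2, 0.04, rng)),
        ]
        ref = {frozenset(c.members) for c in cluster_viral_populations(genomes)}
        for perm in ([3, 1, 0, 2], [2, 3, 1, 0]):
            shuffled = [genomes[i] for i in perm]
            got = {frozenset(c.members) for c in cluster_viral_populations(shuffled)}
            assert got == ref

    def test_short_genome_rejected(self, rng):
        with pytest.raises(ValueError, match="below"):
            cluster_viral_populations([GenomeRecord("x", random_seq(rng, 5_000))])

    def test_empty_input(self):
        assert cluster_viral_populations([]) == []

    def test_external_hits_round_trip(self, rng, tmp_path):
        """Externally supplied tabular hits reproduce the built-in result."""
        seq = random_seq(rng, 11_000)
        genomes = [
            GenomeRecord("A", seq),
            GenomeRecord("B", mutate(seq, 0.03, rng)),
            GenomeRecord("C", random_seq(rng, 10_000)),
        ]
        hits = []
        for i, g in enumerate(genomes):
            for other in genomes[i + 1 :]:
                hits.extend(seed_extend_hits(g.id, g.sequence, other.id, other.sequence))
        path = tmp_path / "hits.tsv"
        write_tabular_hits(hits, path)
        reread = read_tabular_hits(path)
        ref = {frozenset(c.members) for c in cluster_viral_populations(genomes)}
        got = {frozenset(c.members) for c in cluster_viral_populations(genomes, hits=reread)}
        assert got == ref


class TestDereplication:
    def test_representative_by_quality_score(self, rng):
        """completeness - 4 x contamination: X scores 82, Y scores 55."""
        seq = random_seq(rng, 15_000)
        x = GenomeRecord("X", seq, kind="prokaryotic", completeness=90, contamination=2)
        y = GenomeRecord(
            "Y", mutate(seq, 0.02, rng), kind="prokaryotic", completeness=95, contamination=10
        )
        clusters = dereplicate_prokaryote_genomes([x, y])
        assert len(clusters) == 1
        assert clusters[0].representative == "X"

    def test_af_below_threshold_splits(self, rng):
        seq = random_seq(rng, 10_000)
        x = GenomeRecord("X", seq, kind="prokaryotic", completeness=90, contamination=2)
        partial = mutate(seq[:6_000], 0.02, rng) + random_seq(rng, 4_000)
        y = GenomeRecord("Y", partial, kind="prokaryotic", completeness=80, contamination=1)
        clusters = dereplicate_prokaryote_genomes([x, y])
        assert len(clusters) == 2

    def test_single_genome(self, rng):
        g = GenomeRecord("Z", random_seq(rng, 10_000), kind="prokaryotic",
                         completeness=70, contamination=3)
        clusters = dereplicate_prokaryote_genomes([g])
        assert clusters[0].representative == "Z"

    def test_missing_quality_raises(self, rng):
        g = GenomeRecord("Z", random_seq(rng, 10_000), kind="prokaryotic")
        with pytest.raises(ValueError, match="lacks"):
            dereplicate_prokaryote_genomes([g])


class TestProteinClustering:
    AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    def random_protein(self, rng, n):
        return "".join(self.AA[rng.integers(0, 20, n)])

    def test_identical_proteins_one_pc(self, rng):
        p = self.random_protein(rng, 120)
        clusters = cluster_proteins({"p1": p, "p2": p})
        assert len(clusters) == 1

    def test_half_identity_two_pcs(self, rng):
        """100-aa pair with 50 identities over the full length stays apart."""
        p = self.random_protein(rng, 100)
        q = list(p)
        pos = rng.choice(100, 50, replace=False)
        for i in pos:
            q[i] = "W" if p[i] != "W" else "Y"
        clusters = cluster_proteins({"p": p, "q": "".join(q)})
        assert len(clusters) == 2

    def test_exact_fragment_joins(self, rng):
        """A 70-aa exact fragment covers 100% of the shorter sequence."""
        p = self.random_protein(rng, 100)
        clusters = cluster_proteins({"full": p, "frag": p[10:80]})
        assert len(clusters) == 1
        assert clusters[0].representative == "full"

    def test_empty_input(self):
        assert cluster_proteins({}) == []


class TestBruteForceConsistency:
    def test_members_meet_thresholds_small_set(self, rng):
        """Every member meets both thresholds against its representative,
        verified by exhaustive pairwise ANI/AF on <= 12 genomes."""
        ancestors = [random_seq(rng, 10_000 + 500 * i) for i in range(4)]
        genomes = []
        for i, anc in enumerate(ancestors):
            genomes.append(GenomeRecord(f"c{i}.0", anc))
            genomes.append(GenomeRecord(f"c{i}.1", mutate(anc, 0.02, rng)))
            genomes.append(GenomeRecord(f"c{i}.2", mutate(anc, 0.10, rng)))
        clusters = cluster_viral_populations(genomes)
        by_id = {g.id: g for g in genomes}
        for cl in clusters:
            rep = by_id[cl.representative]
            for member in cl.members:
                if member == cl.representative:
                    continue
                res = compute_ani_af(by_id[member], rep)
                assert res.ani >= 95.0
                assert res.af_smaller >= 85.0
        # and no singleton could have joined an existing representative
        reps = [by_id[c.representative] for c in clusters]
        for cl in clusters:
            if len(cl.members) > 1:
                continue
            g = by_id[cl.representative]
            for rep in reps:
                if rep.id == g.id:
                    continue
                res = compute_ani_af(g, rep)
                assert not (res.ani >= 95.0 and res.af_smaller >= 85.0)
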