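"""Similarity search, tandem cluster detection and segmental tiers."""

import shutil
import subprocess

import numpy as np
import pytest

from plantkinome.duplication import (
    SimilarityPair,
    align_pair,
    detect_tandem_clusters,
    similarity_search,
    tier_segmental,
    unclassified_proximal,
)
from plantkinome.identify import KinaseGene


def _gene(gid, chrom="chr01", start=1, end=2_000, cds=""):
    return KinaseGene(
        gene_id=gid, protein_id=f"{gid}.t1", source_assembly="A",
        chromosome=chrom, start=start, end=end, strand="+",
        n_kinase_domains=1, subfamily="CK1_CK1", group="CK1", cds_sequence=cds,
    )


def _pair(a, b, identity=0.97, coverage=1.0, evalue=1e-50):
    return SimilarityPair(*sorted((a, b)), identity=identity,
                          coverage=coverage, evalue=evalue)


def _random_cds(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSimilaritySearch:
    def test_exact_duplicate_cds(self):
        rng = np.random.default_rng(1)
        seq = _random_cds(rng, 900)
        pairs = similarity_search({"g1": seq, "g2": seq})
        assert len(pairs) == 1
        assert pairs[0].identity == 1.0
        assert pairs[0].coverage == pytest.approx(1.0)
        assert pairs[0].evalue < 1e-100

    def test_half_length_perfect_window_fails_75pct_coverage(self):
        rng = np.random.default_rng(2)
        seq = _random_cds(rng, 1000)
        other = _random_cds(rng, 500) + seq[:500]
        result = align_pair(seq, other)
        assert result is not None
        identity, coverage, _ = result
        assert identity == pytest.approx(1.0, abs=0.01)
        assert coverage == pytest.approx(0.5, abs=0.02)
        pairs = similarity_search({"g1": seq, "g2": other}, cov_min=0.75)
        assert pairs == []

    def test_unrelated_random_sequences_produce_no_significant_pair(self):
        # the Karlin-Altschul E-value of the short chance HSPs between
        # random 1 kb sequences is far above 1e-10
        rng = np.random.default_rng(3)
        cds = {f"g{i}": _random_cds(rng, 1000) for i in range(8)}
        assert similarity_search(cds, evalue_max=1e-10) == []

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            similarity_search({"g1": "ACGT" * 100})

    def test_agrees_with_blastn_on_mutated_copies(self, tmp_path):
        """Independent cross-check of identity/coverage against BLASTn."""
        if shutil.which("blastn") is None:
            pytest.fail("blastn not on PATH; cross-check cannot run")
        rng = np.random.default_rng(4)
        seq = _random_cds(rng, 900)
        mutated = list(seq)
        for pos in rng.choice(900, size=27, replace=False):  # 3% substitutions
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        mutated = "".join(mutated)
        q, s = tmp_path / "q.fna", tmp_path / "s.fna"
        q.write_text(f">q\n{seq}\n")
        s.write_text(f">s\n{mutated}\n")
        out = subprocess.run(
            ["blastn", "-query", str(q), "-subject", str(s),
             "-outfmt", "6 pident length", "-dust", "no"],
            capture_output=True, text=True, check=True,
        ).stdout.split()
        blast_identity, blast_len = float(out[0]) / 100.0, int(out[1])
        identity, coverage, evalue = align_pair(seq, mutated)
        assert identity == pytest.approx(blast_identity, abs=0.01)
        assert coverage * 900 == pytest.approx(blast_len, rel=0.05)
        assert evalue < 1e-10


class TestTandemClusters:
    def test_close_similar_pair_forms_cluster(self):
        genes = [_gene("g1", start=1, end=2_000), _gene("g2", start=10_001, end=12_000)]
        clusters = detect_tandem_clusters(genes, [_pair("g1", "g2", identity=0.97)])
        assert len(clusters) == 1
        assert clusters[0].members == ["g1", "g2"]

    def test_single_linkage_chains_beyond_pairwise_gap(self):
        # g1-g2 and g2-g3 both at 24 kb: one cluster of 3 although the
        # g1-g3 boundary gap is 48 kb
        genes = [
            _gene("g1", start=1, end=1_000),
            _gene("g2", start=25_001, end=26_000),
            _gene("g3", start=50_001, end=51_000),
        ]
        pairs = [_pair("g1", "g2"), _pair("g2", "g3"), _pair("g1", "g3")]
        clusters = detect_tandem_clusters(genes, pairs)
        assert len(clusters) == 1
        assert clusters[0].members == ["g1", "g2", "g3"]

    def test_gap_over_25kb_is_not_tandem(self):
        genes = [_gene("g1", start=1, end=1_000), _gene("g2", start=27_001, end=28_000)]
        assert detect_tandem_clusters(genes, [_pair("g1", "g2")]) == []

    def test_different_chromosomes_never_tandem(self):
        genes = [_gene("g1"), _gene("g2", chrom="chr02")]
        assert detect_tandem_clusters(genes, [_pair("g1", "g2")]) == []

    def test_identity_below_95pct_not_tandem(self):
        genes = [_gene("g1", start=1, end=1_000), _gene("g2", start=2_001, end=3_000)]
        pairs = [_pair("g1", "g2", identity=0.94)]
        assert detect_tandem_clusters(genes, pairs) == []

    def test_unknown_gene_in_pair_is_an_error(self):
        with pytest.raises(KeyError):
            detect_tandem_clusters([_gene("g1")], [_pair("g1", "gX")])

    def test_planted_arrays_recovered_and_far_array_rejected(self, tiny_bundle):
        from plantkinome.io import read_fasta

        truth = tiny_bundle.truth
        cds_seqs = read_fasta(tiny_bundle.cds_fasta)
        from plantkinome.io import read_gene_models

        genes = read_gene_models(tiny_bundle.gff3)
        kinases = [
            _gene(
                g, chrom=genes[g].chromosome, start=genes[g].start,
                end=genes[g].end, cds=cds_seqs[truth.longest_isoform(g)],
            )
            for g in sorted(truth.kinase_genes)
        ]
        pairs = similarity_search({k.gene_id: k.cds_sequence for k in kinases})
        clusters = detect_tandem_clusters(kinases, pairs)
        detected = {frozenset(c.members) for c in clusters}
        expected = {
            frozenset(
                g for g, c in truth.tandem_cluster_membership.items() if c == cid
            )
            for cid, gap in truth.cluster_gap_bp.items()
            if gap <= 25_000
        }
        assert detected == expected
        far_genes = {
            g for g, c in truth.tandem_cluster_membership.items()
            if truth.cluster_gap_bp[c] > 25_000
        }
        assert not any(set(c.members) & far_genes for c in clusters)


class TestSegmentalTiers:
    def test_high_identity_long_range_pair_enters_all_tiers(self):
        genes = [_gene("g1", start=1, end=1_000), _gene("g2", start=201_001, end=202_000)]
        tiers = tier_segmental(genes, [_pair("g1", "g2", identity=0.92)])
        assert [len(t.pairs) for t in tiers] == [1, 1, 1]

    def test_cross_chromosome_pair_enters_tiers_below_its_identity(self):
        genes = [_gene("g1"), _gene("g2", chrom="chr02")]
        tiers = tier_segmental(genes, [_pair("g1", "g2", identity=0.80)])
        assert [len(t.pairs) for t in tiers] == [0, 1, 1]

    def test_close_pair_is_not_segmental(self):
        genes = [_gene("g1", start=1, end=1_000), _gene("g2", start=11_001, end=12_000)]
        tiers = tier_segmental(genes, [_pair("g1", "g2", identity=0.96)])
        assert all(len(t.pairs) == 0 for t in tiers)

    def test_tiers_are_nested(self):
        rng = np.random.default_rng(5)
        genes = [
            _gene(f"g{i}", chrom=f"chr{1 + i % 3:02d}", start=1 + 300_000 * i,
                  end=1_000 + 300_000 * i)
            for i in range(10)
        ]
        pairs = [
            _pair(f"g{i}", f"g{j}", identity=float(rng.uniform(0.4, 1.0)))
            for i in range(10) for j in range(i + 1, 10)
        ]
        tiers = tier_segmental(genes, pairs)
        sets = [
            {(p.gene_id_a, p.gene_id_b) for p in t.pairs} for t in tiers
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_thresholds_must_descend(self):
        with pytest.raises(ValueError):
            tier_segmental([], [], thresholds=[0.5, 0.75])

    def test_dead_zone_pairs_reported_separately(self):
        genes = [_gene("g1", start=1, end=1_000), _gene("g2", start=51_001, end=52_000)]
        pairs = [_pair("g1", "g2", identity=0.98)]
        assert detect_tandem_clusters(genes, pairs) == []
        assert all(len(t.pairs) == 0 for t in tier_segmental(genes, pairs))
        assert unclassified_proximal(genes, pairs) == pairs
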