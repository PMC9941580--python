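"""Generator contracts: determinism, planted structure, noise behaviour."""

import hashlib
import itertools
from pathlib import Path

import numpy as np
import pytest

from plantkinome.io import read_domtblout, read_fasta, read_gene_models, read_te_bed
from plantkinome.synthetic import (
    generate_domain_hits,
    generate_expression,
    generate_genome,
)


def _digest_dir(d):
    return {
        p.name: hashlib.md5(p.read_bytes()).hexdigest()
        for p in sorted(Path(d).iterdir()) if p.is_file()
    }


class TestGenerateGenome:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        for sub in ("a", "b"):
            generate_genome(3, 15, [(2, 5_000, 0.98)], 25.0, seed=4,
                            out_dir=tmp_path / sub)
        assert _digest_dir(tmp_path / "a") == _digest_dir(tmp_path / "b")

    def test_planted_array_has_requested_size_and_gaps(self, tmp_path):
        bundle = generate_genome(2, 8, [(3, 5_000, 0.98)], 0.0, seed=5,
                                 out_dir=tmp_path)
        truth = bundle.truth
        members = sorted(
            g for g, c in truth.tandem_cluster_membership.items() if c == "tde00"
        )
        assert len(members) == 3
        genes = read_gene_models(bundle.gff3)
        coords = sorted((genes[g].start, genes[g].end) for g in members)
        gaps = [s2 - e1 for (_, e1), (s2, _) in zip(coords, coords[1:])]
        assert gaps == [5_000, 5_000]
        assert len(set(genes[g].chromosome for g in members)) == 1

    def test_planted_pairwise_cds_identity_at_least_requested(self, tmp_path):
        bundle = generate_genome(2, 8, [(3, 5_000, 0.97)], 0.0, seed=6,
                                 out_dir=tmp_path)
        truth = bundle.truth
        cds = read_fasta(bundle.cds_fasta)
        members = [
            g for g, c in truth.tandem_cluster_membership.items() if c == "tde00"
        ]
        for a, b in itertools.combinations(members, 2):
            sa = cds[truth.longest_isoform(a)]
            sb = cds[truth.longest_isoform(b)]
            identity = sum(x == y for x, y in zip(sa, sb)) / len(sa)
            assert identity >= 0.97

    def test_zero_te_density_gives_empty_bed_and_no_associations(self, tmp_path):
        bundle = generate_genome(2, 6, [], 0.0, seed=7, out_dir=tmp_path)
        assert read_te_bed(bundle.te_bed) == []
        assert bundle.truth.te_associated_genes == set()

    def test_te_intervals_stay_within_chromosomes(self, tiny_bundle):
        for te in read_te_bed(tiny_bundle.te_bed):
            assert 0 <= te.start < te.end
            assert te.end <= tiny_bundle.chromosome_lengths[te.chromosome]

    def test_te_classes_ltr_dominated(self, tmp_path):
        bundle = generate_genome(3, 10, [], 80.0, seed=8, out_dir=tmp_path)
        tes = read_te_bed(bundle.te_bed)
        assert tes, "expected TEs at this density"
        ltr = sum(1 for t in tes if t.te_class.startswith("LTR"))
        assert ltr / len(tes) > 0.7

    def test_oversized_array_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="cannot fit"):
            generate_genome(2, 8, [(3, 5_000_000, 0.98)], 0.0, seed=9,
                            out_dir=tmp_path, chromosome_length=1_000_000)

    def test_invalid_specs_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_genome(0, 5, [], 0.0, seed=1, out_dir=tmp_path)
        with pytest.raises(ValueError):
            generate_genome(2, 5, [(1, 100, 0.9)], 0.0, seed=1, out_dir=tmp_path)
        with pytest.raises(ValueError):
            generate_genome(2, 5, [(2, -1, 0.9)], 0.0, seed=1, out_dir=tmp_path)
        with pytest.raises(ValueError):
            generate_genome(2, 5, [(2, 100, 1.5)], 0.0, seed=1, out_dir=tmp_path)

    def test_gff_structure_consistent(self, tiny_bundle):
        genes = read_gene_models(tiny_bundle.gff3)
        cds = read_fasta(tiny_bundle.cds_fasta)
        for gid, model in genes.items():
            for tid, tr in model.transcripts.items():
                # exon lengths sum to the CDS length written to FASTA
                assert tr.coding_length == len(cds[tid])
                starts = [e.start for e in tr.exons]
                assert starts == sorted(starts)


class TestGenerateDomainHits:
    def test_noise_free_table_has_only_planted_passing_hits(
        self, tiny_bundle, tmp_path
    ):
        from plantkinome.identify import filter_kinases

        path = generate_domain_hits(tiny_bundle, tmp_path / "h.domtbl",
                                    noise_spec=0.0, seed=1)
        hits = read_domtblout(path)
        passing = filter_kinases(hits)
        planted_isoforms = {
            iso
            for g in tiny_bundle.truth.kinase_genes
            for iso in tiny_bundle.truth.isoform_groups[g]
        }
        assert set(passing) == planted_isoforms

    def test_every_planted_hit_clears_both_thresholds(self, tiny_hits):
        hits = read_domtblout(tiny_hits)
        for h in hits:
            if h.evalue <= 1e-10 and h.model_coverage >= 0.5:
                continue
            # failing rows must belong to decoys
            assert h.score < 100

    def test_decoy_hits_always_violate_a_criterion(self, tiny_bundle, tmp_path):
        from plantkinome.identify import filter_kinases

        path = generate_domain_hits(tiny_bundle, tmp_path / "h.domtbl",
                                    noise_spec=1.0, seed=2)
        hits = read_domtblout(path)
        decoy_isoforms = {
            tiny_bundle.truth.isoform_groups[g][0]
            for g in tiny_bundle.truth.decoy_genes
        }
        decoy_hits = [h for h in hits if h.protein_id in decoy_isoforms]
        assert decoy_hits, "noise_spec=1 must produce decoy hits"
        for h in decoy_hits:
            assert h.evalue > 1e-10 or h.model_coverage < 0.5
        assert not set(filter_kinases(hits)) & decoy_isoforms

    def test_deterministic(self, tiny_bundle, tmp_path):
        p1 = generate_domain_hits(tiny_bundle, tmp_path / "h1.domtbl", 0.5, seed=3)
        p2 = generate_domain_hits(tiny_bundle, tmp_path / "h2.domtbl", 0.5, seed=3)
        assert p1.read_bytes() == p2.read_bytes()


class TestGenerateExpression:
    def _subfamily_matrix(self, bundle, counts_p, lengths_p, meta_p):
        from plantkinome.expression import (
            aggregate_subfamily,
            average_replicates,
            compute_tpm,
            read_sample_metadata,
        )
        from plantkinome.io import read_tsv_matrix

        tpm = compute_tpm(
            read_tsv_matrix(counts_p), read_tsv_matrix(lengths_p)["length"],
            read_sample_metadata(meta_p),
        )
        sub_of = {
            bundle.truth.longest_isoform(g): s
            for g, s in bundle.truth.subfamily_of_gene.items()
        }
        matrix, _ = aggregate_subfamily(average_replicates(tpm), sub_of)
        return matrix

    def test_zero_noise_blocks_correlate_perfectly(self, tiny_bundle, tmp_path):
        paths = generate_expression(
            tiny_bundle.truth, [("leaf", "control", 1)] * 20,
            block_correlation=0.9, noise_sd=0.0, seed=2, out_dir=tmp_path,
            bundle=tiny_bundle,
        )
        matrix = self._subfamily_matrix(tiny_bundle, *paths)
        block = tiny_bundle.truth.correlated_blocks[0].subfamilies
        values = matrix.values.loc[list(block)].values
        corr = np.corrcoef(values)
        off_diag = corr[np.triu_indices_from(corr, 1)]
        assert np.all(off_diag == pytest.approx(1.0, abs=1e-4))

    def test_realized_correlation_near_analytic_target(self, tiny_bundle, tmp_path):
        """Latent-factor model: within-block r approaches v/(v + sigma^2)."""
        paths = generate_expression(
            tiny_bundle.truth, [("leaf", "control", 1)] * 60,
            block_correlation=0.95, noise_sd=0.1, seed=3, out_dir=tmp_path,
            bundle=tiny_bundle,
        )
        matrix = self._subfamily_matrix(tiny_bundle, *paths)
        block = tiny_bundle.truth.correlated_blocks[0].subfamilies
        values = matrix.values.loc[list(block)].values
        corr = np.corrcoef(values)
        off_diag = corr[np.triu_indices_from(corr, 1)]
        assert np.all(off_diag > 0.7)
        assert np.mean(off_diag) == pytest.approx(0.95, abs=0.08)

    def test_counts_are_nonnegative_integers(self, tiny_bundle, tmp_path):
        counts_p, _, _ = generate_expression(
            tiny_bundle.truth, [("leaf", "control", 2)], seed=4,
            out_dir=tmp_path, bundle=tiny_bundle,
        )
        from plantkinome.io import read_tsv_matrix

        counts = read_tsv_matrix(counts_p)
        assert (counts.values >= 0).all()
        assert np.issubdtype(counts.values.dtype, np.integer)

    def test_fixed_seed_reproduces_tsvs(self, tiny_bundle, tmp_path):
        spec = [("leaf", "control", 2), ("bark", "stress:cold", 3)]
        a = generate_expression(tiny_bundle.truth, spec, seed=5,
                                out_dir=tmp_path / "a", bundle=tiny_bundle)
        b = generate_expression(tiny_bundle.truth, spec, seed=5,
                                out_dir=tmp_path / "b", bundle=tiny_bundle)
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_empty_samples_spec_rejected(self, tiny_bundle, tmp_path):
        with pytest.raises(ValueError, match="samples_spec"):
            generate_expression(tiny_bundle.truth, [], seed=1,
                                out_dir=tmp_path, bundle=tiny_bundle)

    def test_invalid_parameters_rejected(self, tiny_bundle, tmp_path):
        with pytest.raises(ValueError):
            generate_expression(tiny_bundle.truth, [("leaf", "control", 0)],
                                seed=1, out_dir=tmp_path, bundle=tiny_bundle)
        with pytest.raises(ValueError):
            generate_expression(tiny_bundle.truth, [("leaf", "control", 2)],
                                block_correlation=1.0, seed=1,
                                out_dir=tmp_path, bundle=tiny_bundle)
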