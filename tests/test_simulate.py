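import numpy as np
import pandas as pd
import pytest

from mirreg import clash
from mirreg import io as mio
from mirreg import simulate as sim


class TestGenerateTruth:
    def test_default_invariants(self):
        t = sim.generate_truth(seed=1)
        assert len(t.gene_ids) == 200 and len(t.mirna_ids) == 30
        assert len(t.conditions) == 6
        assert set(t.module_conditions) <= set(t.conditions)
        assert len(t.module_mirnas) == 4
        assert (t.edges.effect != 0).all()
        mi = t.edges[t.edges.kind == "miRNA"]
        assert (mi.effect < 0).all()  # repression

    def test_module_planted_in_requested_conditions(self):
        spec = sim.ModuleSpec(k=4, n_conditions=3)
        t = sim.generate_truth(module_spec=spec, seed=2)
        assert len(t.module_conditions) == 3
        for cancer, stage in t.module_conditions:
            sub = t.edges[(t.edges.cancer_type == cancer)
                          & (t.edges.stage == stage)
                          & (t.edges.regulator_id.isin(t.module_mirnas))]
            # every module miRNA targets module genes in each support condition
            assert set(sub.regulator_id) == set(t.module_mirnas)
            for m in t.module_mirnas:
                targets = set(sub[sub.regulator_id == m].gene_id)
                assert targets & set(t.module_genes)

    def test_different_seeds_differ(self):
        a = sim.generate_truth(seed=1)
        b = sim.generate_truth(seed=2)
        assert not a.edges.equals(b.edges)

    def test_infeasible_module_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_truth(n_mirnas=3, module_spec=sim.ModuleSpec(k=4))


@pytest.fixture(scope="module")
def truth():
    return sim.generate_truth(seed=1)


class TestBindingEvidence:

    def test_zero_depth_nothing_passes(self, truth):
        ev = sim.generate_binding_evidence(truth, depth=0.0, seed=1)
        sites = ev["sites"].drop(columns=["is_true"])
        tally = clash.tally_reads(sites, ev["mirna_singles"],
                                  ev["mrna_singles"])
        tested = clash.test_sites(sites, tally)
        assert len(clash.filter_sites(tested, 0.05)) == 0

    def test_true_pairs_pass_decoys_mostly_fail(self, truth):
        ev = sim.generate_binding_evidence(truth, seed=1)
        sites = ev["sites"]
        tally = clash.tally_reads(sites.drop(columns=["is_true"]),
                                  ev["mirna_singles"], ev["mrna_singles"])
        tested = clash.test_sites(sites.drop(columns=["is_true"]), tally)
        passed = clash.filter_sites(tested, 0.05)
        pass_pairs = set(zip(passed.mirna_id, passed.mrna_id))
        true_pairs = set(zip(sites[sites.is_true].mirna_id,
                             sites[sites.is_true].mrna_id))
        decoy_pairs = set(zip(sites[~sites.is_true].mirna_id,
                              sites[~sites.is_true].mrna_id))
        true_rate = len(true_pairs & pass_pairs) / len(true_pairs)
        decoy_rate = len(decoy_pairs & pass_pairs) / len(decoy_pairs)
        assert true_rate >= 0.9
        assert decoy_rate < 0.2

    def test_mfe_range(self, truth):
        ev = sim.generate_binding_evidence(truth, seed=1)
        mfe = ev["sites"].mfe
        assert mfe.min() >= -31.2 and mfe.max() <= -2.9


class TestExpression:
    def test_noiseless_generative_identity(self):
        """With zero residual noise, regressing a regulated gene's log2
        change on its regulators' changes plus background leaves ~zero
        residual."""
        t = sim.generate_truth(n_genes=40, n_mirnas=8, n_tfs=3,
                               n_conditions=2,
                               regulated_genes_per_condition=10,
                               module_spec=sim.ModuleSpec(
                                   k=2, n_conditions=1, n_target_genes=4),
                               seed=3)
        out = sim.generate_expression(t, samples_per_condition=15,
                                      normals_per_cancer=10, noise_sd=0.0,
                                      seed=4)
        sheet = out["sample_sheet"]
        cancer, stage = t.conditions[0]
        tum = sheet[(sheet.cancer_type == cancer) & (sheet.stage == stage)
                    & (sheet.status == "tumor")].sample_id.tolist()
        edges = t.edges[(t.edges.cancer_type == cancer)
                        & (t.edges.stage == stage)]
        gene = edges.gene_id.iloc[0]
        sub = edges[edges.gene_id == gene]
        base_gene = out["gene_expr"]
        # reconstruct the generative linear predictor per sample
        normals = sheet[(sheet.cancer_type == cancer)
                        & (sheet.status == "normal")].sample_id.tolist()
        cnv_delta = np.log2(out["cnv"].loc[gene, tum]
                            / out["cnv"].loc[gene, normals].mean())
        meth_delta = out["methylation"].loc[gene, tum] - 0.5
        resid = []
        for s in tum:
            pred = cnv_delta[s] - meth_delta[s]
            for _, e in sub.iterrows():
                src = out["mirna_expr"] if e.kind == "miRNA" else base_gene
                # regulator delta vs its baseline is encoded in the tables
                ctrl = src.loc[e.regulator_id, normals].mean()
                dreg = np.log2(src.loc[e.regulator_id, s] / ctrl)
                pred += e.effect * dreg
            ctrl_g = base_gene.loc[gene, normals].mean()
            obs = np.log2(base_gene.loc[gene, s] / ctrl_g)
            resid.append(obs - pred)
        # control-group sampling noise remains; residual must be small and
        # identical across samples up to that shared offset
        assert np.std(resid) < 0.15

    def test_sample_sheet_valid(self, tmp_path):
        t = sim.generate_truth(seed=1)
        out = sim.generate_expression(t, seed=2)
        out["sample_sheet"].to_csv(tmp_path / "s.tsv", sep="\t", index=False)
        sheet = mio.read_sample_sheet(tmp_path / "s.tsv")
        assert len(mio.conditions_from_sheet(sheet)) == 6

    def test_too_few_samples_rejected(self):
        t = sim.generate_truth(seed=1)
        with pytest.raises(ValueError):
            sim.generate_expression(t, samples_per_condition=5)


class TestPathways:
    def test_module_genes_in_module_pathways(self):
        t = sim.generate_truth(seed=1)
        pws = sim.generate_pathways(t, seed=2)
        for pw in t.module_pathways:
            assert set(t.module_genes) <= pws[pw]

    def test_gmt_round_trip(self, tmp_path):
        t = sim.generate_truth(seed=1)
        pws = sim.generate_pathways(t, n_pathways=40, seed=2)
        assert len(pws) == 40
        mio.write_gmt(pws, tmp_path / "p.gmt")
        assert mio.read_gmt(tmp_path / "p.gmt") == pws


class TestBundle:
    def test_bundle_files_pass_all_readers(self, small_bundle, tmp_path):
        sim.write_bundle(small_bundle, tmp_path)
        assert len(mio.read_binding_sites(tmp_path / "binding_sites.tsv")) \
            == len(small_bundle.sites)
        ge = mio.read_expression(tmp_path / "gene_expression.tsv")
        assert ge.shape == small_bundle.gene_expr.shape
        mio.read_expression(tmp_path / "mirna_expression.tsv")
        mio.read_signed_table(tmp_path / "cnv.tsv")
        mio.read_signed_table(tmp_path / "methylation.tsv")
        mio.read_sample_sheet(tmp_path / "sample_sheet.tsv")
        mio.read_tf_sites(tmp_path / "tf_sites.tsv")
        mio.read_mutations(tmp_path / "mutations.tsv")
        assert len(mio.read_gmt(tmp_path / "pathways.gmt")) == 40

    def test_bundle_reproducible(self):
        a = sim.generate_bundle(seed=9, samples_per_condition=10,
                                normals_per_cancer=4, n_genes=20,
                                n_mirnas=6, n_tfs=2, n_conditions=2,
                                regulated_genes_per_condition=5,
                                module_spec=sim.ModuleSpec(
                                    k=2, n_conditions=1, n_target_genes=4))
        b = sim.generate_bundle(seed=9, samples_per_condition=10,
                                normals_per_cancer=4, n_genes=20,
                                n_mirnas=6, n_tfs=2, n_conditions=2,
                                regulated_genes_per_condition=5,
                                module_spec=sim.ModuleSpec(
                                    k=2, n_conditions=1, n_target_genes=4))
        pd.testing.assert_frame_equal(a.gene_expr, b.gene_expr)
        pd.testing.assert_frame_equal(a.sites, b.sites)
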