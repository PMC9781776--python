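"""Transcriptome, proteome and metabolome operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sugarnet.config import AnalysisConfig, CONDITIONS
from sugarnet.omics import (
    OmicsDataError,
    cluster_conditions,
    correlate_genes_metabolites,
    detect_sugar_induction,
    normalize_central_tendency,
    pathway_abundance_profile,
    rollup_peptides_to_proteins,
    summarize_replicates,
)


class TestClusterConditions:
    def make(self, cols):
        return pd.DataFrame(cols)

    def test_identical_columns_merge_first_at_zero_height(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 100, 10)
        expr = self.make(
            {"a": base, "b": base, "c": rng.uniform(1, 100, 10)}
        )
        z, labels = cluster_conditions(expr)
        first = z[0]
        merged = {labels[int(first[0])], labels[int(first[1])]}
        assert merged == {"a", "b"} and first[2] == pytest.approx(0.0, abs=1e-12)

    def test_correlated_pair_merges_before_anticorrelated_third(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = self.make({"a": x, "b": 2 * x + 1, "c": -x})
        z, labels = cluster_conditions(expr)
        merged = {labels[int(z[0][0])], labels[int(z[0][1])]}
        assert merged == {"a", "b"}
        assert z[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_constant_condition_named_in_error(self):
        expr = self.make({"flat": [5.0, 5.0, 5.0], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(OmicsDataError, match="flat"):
            cluster_conditions(expr)

    def test_planted_condition_blocks_recovered_as_clades(self, scenario):
        from scipy.cluster.hierarchy import to_tree

        # condition similarity is assessed on the log2 expression scale, as
        # usual for RNA-seq profiles, so induced outlier genes do not dominate
        expr = np.log2(scenario.expression["eur"] + 1.0)
        z, labels = cluster_conditions(expr)
        clades = []

        def collect(node):
            if node.is_leaf():
                return {node.id}
            s = collect(node.left) | collect(node.right)
            clades.append(s)
            return s

        collect(to_tree(z))
        pos = {lab: i for i, lab in enumerate(labels)}
        hexoses = {pos[c] for c in ("D-glucose", "D-fructose", "D-mannose")}
        pentoses = {pos[c] for c in ("D-xylose", "L-arabinose")}
        assert hexoses in clades
        assert pentoses in clades


class TestInduction:
    def test_strong_cognate_spike_is_induced(self):
        expr = pd.DataFrame(
            [[100.0] + [1.0] * 8], index=["sp|g1"], columns=list(CONDITIONS)
        )
        out = detect_sugar_induction(expr, {"sp|g1": CONDITIONS[0]})
        assert bool(out.loc["sp|g1", "induced"]) is True
        assert out.loc["sp|g1", "fold"] == pytest.approx(100.0)

    def test_flat_row_is_not_induced(self):
        expr = pd.DataFrame(
            [[5.0] * 9], index=["sp|g1"], columns=list(CONDITIONS)
        )
        out = detect_sugar_induction(expr, {"sp|g1": CONDITIONS[3]})
        assert bool(out.loc["sp|g1", "induced"]) is False

    def test_zero_median_falls_back_to_fpkm_threshold(self):
        cols = list(CONDITIONS)
        expr = pd.DataFrame(
            [[9.0] + [0.0] * 8, [11.0] + [0.0] * 8],
            index=["sp|lo", "sp|hi"], columns=cols,
        )
        out = detect_sugar_induction(
            expr, {"sp|lo": cols[0], "sp|hi": cols[0]}
        )
        assert bool(out.loc["sp|lo", "induced"]) is False
        assert bool(out.loc["sp|hi", "induced"]) is True

    def test_unknown_cognate_condition_is_error(self):
        expr = pd.DataFrame([[1.0] * 9], index=["sp|g1"], columns=list(CONDITIONS))
        with pytest.raises(OmicsDataError, match="maltose"):
            detect_sugar_induction(expr, {"sp|g1": "maltose"})

    def test_planted_inductions_recovered_exactly(self, noiseless_scenario):
        for tag, truth in noiseless_scenario.manifest["species"].items():
            expr = noiseless_scenario.expression[tag]
            calls = detect_sugar_induction(expr, truth["cognate_map"])
            assert set(calls.index[calls["induced"]]) == set(truth["induced"])


class TestNormalization:
    def test_two_column_shift_arithmetic(self):
        m = pd.DataFrame({"a": [2.0, 4.0], "b": [4.0, 6.0]})
        out = normalize_central_tendency(m)
        assert out["a"].tolist() == [3.0, 5.0]
        assert out["b"].tolist() == [3.0, 5.0]

    def test_single_column_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        pd.testing.assert_frame_equal(normalize_central_tendency(m), m)

    def test_missing_entries_untouched(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [3.0, 5.0]})
        out = normalize_central_tendency(m)
        assert np.isnan(out.loc[1, "a"])

    def test_all_missing_column_is_error(self):
        m = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(OmicsDataError):
            normalize_central_tendency(m)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_idempotent_and_difference_preserving(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.normal(0, 3, size=(6, 4)))
        m = m.mask(rng.random(m.shape) < 0.2)
        if m.notna().sum().min() == 0:
            return
        once = normalize_central_tendency(m)
        twice = normalize_central_tendency(once)
        pd.testing.assert_frame_equal(once, twice)
        for col in m:
            d0 = m[col].diff()
            d1 = once[col].diff()
            pd.testing.assert_series_equal(d0, d1, check_exact=False)


class TestRollup:
    def peptides(self, rows, samples=("c1::r1", "c1::r2")):
        recs = []
        index = []
        for i, (protein, specific, vals) in enumerate(rows):
            recs.append([protein, specific] + list(vals))
            index.append(f"p{i}")
        return pd.DataFrame(
            recs, columns=["protein", "specific", *samples], index=index
        )

    def test_single_peptide_passes_through(self):
        # balanced columns make the final renormalization the identity
        pep = self.peptides([("P1", True, [3.0, 5.0]), ("P2", True, [5.0, 3.0])])
        out = rollup_peptides_to_proteins(pep)
        assert out.loc["P1"].tolist() == [3.0, 5.0]

    def test_two_equal_peptides_add_one_log_unit(self):
        pep = self.peptides(
            [("P1", True, [3.0, 3.0]), ("P1", True, [3.0, 3.0]),
             ("P2", True, [4.0, 4.0])]
        )
        out = rollup_peptides_to_proteins(pep)
        assert (out.loc["P1"] - out.loc["P2"]).tolist() == [0.0, 0.0]

    def test_nonspecific_peptides_contribute_nothing(self):
        pep = self.peptides(
            [("P1", True, [3.0, 3.0]), ("P1", False, [9.0, 9.0]),
             ("P2", True, [3.0, 3.0])]
        )
        out = rollup_peptides_to_proteins(pep)
        assert out.loc["P1"].tolist() == out.loc["P2"].tolist()

    def test_protein_without_specific_peptides_dropped(self):
        pep = self.peptides([("P1", True, [3.0, 3.0]), ("P2", False, [5.0, 5.0])])
        out = rollup_peptides_to_proteins(pep)
        assert list(out.index) == ["P1"]

    def test_protein_missing_only_when_all_peptides_missing(self):
        pep = self.peptides(
            [("P1", True, [np.nan, 3.0]), ("P1", True, [np.nan, np.nan]),
             ("P2", True, [2.0, 2.0])]
        )
        out = rollup_peptides_to_proteins(pep)
        assert np.isnan(out.loc["P1"].iloc[0]) and not np.isnan(out.loc["P1"].iloc[1])


class TestSummarizeReplicates:
    def table(self, rows):
        cols = pd.MultiIndex.from_tuples(
            [("c1", "r1"), ("c1", "r2"), ("c1", "r3")]
        )
        return pd.DataFrame(rows, columns=cols, index=["P1"])

    @pytest.mark.parametrize(
        "reps, expected",
        [([4.0, 6.0, 0.0], 5.0), ([0.0, 0.0, 0.0], 0.0), ([2.0, 2.0, 2.0], 2.0)],
    )
    def test_nonzero_replicate_average(self, reps, expected):
        out = summarize_replicates(self.table([reps]))
        assert out.loc["P1", "c1"] == pytest.approx(expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=3, max_size=3),
        st.floats(min_value=0.1, max_value=10),
    )
    def test_permutation_invariant_and_scale_equivariant(self, reps, scale):
        base = summarize_replicates(self.table([reps])).loc["P1", "c1"]
        perm = summarize_replicates(self.table([reps[::-1]])).loc["P1", "c1"]
        scaled = summarize_replicates(
            self.table([[scale * v for v in reps]])
        ).loc["P1", "c1"]
        assert perm == pytest.approx(base)
        assert scaled == pytest.approx(scale * base, rel=1e-9)


class TestPathwayAbundance:
    def test_detection_fraction_boundary(self, net, scenario, merged_groups):
        from sugarnet.projection import project_network

        proj = project_network(net, merged_groups, "eur")
        # two single-pathway D-galacturonic acid candidates: one protein
        # detected in 2 of 9 conditions (< 1/3, dropped), one in 3 of 9 (kept)
        vals = np.zeros((2, 9))
        vals[0, :2] = 5.0
        vals[1, :3] = 5.0
        table = pd.DataFrame(
            vals, index=["eur|gaaA_1", "eur|gaaB_1"], columns=list(CONDITIONS)
        )
        prof = pathway_abundance_profile(table, proj, net)
        gala = prof[prof.pathway == "d_galacturonic_acid"].set_index("condition")
        assert gala.loc[CONDITIONS[0], "n"] == 1  # dropped protein absent
        assert gala.loc[CONDITIONS[2], "n"] == 1
        assert gala.loc[CONDITIONS[3], "n"] == 0

    def test_galacturonate_pathway_peaks_on_its_sugar(self, net, scenario, merged_groups):
        from sugarnet.io import peptide_samples_to_multiindex
        from sugarnet.projection import project_network

        tag = "eur"
        pep = scenario.peptides[tag]
        samples = [c for c in pep.columns if c not in ("protein", "specific")]
        norm = pep.copy()
        norm[samples] = normalize_central_tendency(pep[samples])
        proteins = rollup_peptides_to_proteins(norm)
        cond = summarize_replicates(peptide_samples_to_multiindex(proteins))
        proj = project_network(net, merged_groups, tag)
        prof = pathway_abundance_profile(cond, proj, net)
        gala = prof[prof.pathway == "d_galacturonic_acid"].set_index("condition")
        assert gala["median"].idxmax() == "D-galacturonic acid"


class TestCorrelationScreen:
    def frame(self, rows, index):
        return pd.DataFrame(rows, index=index, columns=list(CONDITIONS))

    def test_identical_vectors_are_strong(self):
        v = np.arange(9, dtype=float) + 1
        recs = correlate_genes_metabolites(
            self.frame([v], ["sp|g"]), self.frame([v], ["m"])
        )
        row = recs.iloc[0]
        assert row.pcc == pytest.approx(1.0)
        assert row.passes and row.strong and row.sign == "positive"

    def test_negated_vector_passes_but_is_not_strong(self):
        v = np.arange(9, dtype=float) + 1
        neg = 2 * v.mean() - v
        recs = correlate_genes_metabolites(
            self.frame([v], ["sp|g"]), self.frame([neg], ["m"])
        )
        row = recs.iloc[0]
        assert row.pcc == pytest.approx(-1.0)
        assert row.passes and not row.strong and row.sign == "negative"

    def test_too_few_shared_conditions_is_error(self):
        e = pd.DataFrame([[1.0, 2.0, 3.0]], index=["sp|g"], columns=["a", "b", "c"])
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=["a", "b", "c"])
        with pytest.raises(OmicsDataError):
            correlate_genes_metabolites(e, m)

    def test_pcc_and_p_match_scipy_pearsonr(self):
        rng = np.random.default_rng(3)
        e = self.frame(rng.normal(size=(4, 9)), [f"sp|g{i}" for i in range(4)])
        m = self.frame(rng.normal(size=(3, 9)), [f"m{i}" for i in range(3)])
        recs = correlate_genes_metabolites(e, m).set_index(["gene", "metabolite"])
        for g in e.index:
            for mm in m.index:
                r_ref, p_ref = stats.pearsonr(e.loc[g], m.loc[mm])
                assert recs.loc[(g, mm), "pcc"] == pytest.approx(r_ref, abs=1e-12)
                assert recs.loc[(g, mm), "p"] == pytest.approx(p_ref, abs=1e-12)

    def test_pcc_invariant_under_positive_affine_transforms(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=9)
        w = rng.normal(size=9)
        base = correlate_genes_metabolites(
            self.frame([v], ["sp|g"]), self.frame([w], ["m"])
        ).iloc[0].pcc
        scaled = correlate_genes_metabolites(
            self.frame([3.0 * v + 7.0], ["sp|g"]), self.frame([0.5 * w - 2.0], ["m"])
        ).iloc[0].pcc
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_zero_variance_pairs_excluded_with_warning(self, caplog):
        e = self.frame([np.full(9, 5.0), np.arange(9.0)], ["sp|flat", "sp|g"])
        m = self.frame([np.arange(9.0)], ["m"])
        recs = correlate_genes_metabolites(e, m)
        assert set(recs["gene"]) == {"sp|g"}

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(8)
        e = self.frame(rng.normal(size=(100, 9)), [f"sp|g{i}" for i in range(100)])
        m = self.frame(rng.normal(size=(100, 9)), [f"m{i}" for i in range(100)])
        recs = correlate_genes_metabolites(e, m)
        ks = stats.kstest(recs["p"], "uniform")
        assert ks.pvalue > 1e-4

    def test_planted_correlations_recovered(self, scenario):
        for tag, truth in scenario.manifest["species"].items():
            planted = truth["planted_correlations"]
            if not planted:
                continue
            recs = correlate_genes_metabolites(
                scenario.expression[tag], scenario.metabolites[tag]
            ).set_index(["gene", "metabolite"])
            for gene, metab, rho in planted:
                row = recs.loc[(gene, metab)]
                assert row["passes"]
                assert abs(row["pcc"] - rho) < 0.15
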