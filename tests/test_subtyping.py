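"""Variant-gene selection, consensus-NMF subtyping, subgroup/control choice."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import cpdr
from cpdr import ExpressionMatrix, ScenarioConfig, simulate_cohort
from cpdr.subtyping import (
    SubtypeResult,
    consensus_subtype,
    select_controls,
    select_subgroup,
    select_variant_genes,
    subtype_similarity,
)


def _log2(data: dict, samples=None) -> ExpressionMatrix:
    df = pd.DataFrame(data).T
    if samples:
        df.columns = samples
    return ExpressionMatrix(df.astype(float), "log2")


class TestSelectVariantGenes:
    def test_dominant_gene_first(self):
        m = _log2({"gA": [0, 0, 0], "gX": [0, 5, 10], "gB": [1, 1, 1]},
                  ["s1", "s2", "s3"])
        assert select_variant_genes(m, 1) == ["gX"]

    def test_all_ties_break_lexicographically(self):
        m = _log2({"gB": [1, 1], "gA": [2, 2], "gC": [3, 3]}, ["s1", "s2"])
        assert select_variant_genes(m, 2) == ["gA", "gB"]

    def test_returned_variances_dominate_excluded(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(50, 8)),
                            index=[f"g{i:02d}" for i in range(50)],
                            columns=[f"s{i}" for i in range(8)])
        m = ExpressionMatrix(data, "log2")
        chosen = select_variant_genes(m, 20)
        var = data.var(axis=1)
        assert var[chosen].min() >= var.drop(chosen).max()

    def test_n_too_large_errors(self):
        m = _log2({"gA": [1, 2]}, ["s1", "s2"])
        with pytest.raises(ValueError):
            select_variant_genes(m, 2)

    def test_counts_units_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [1.0]}, index=["g"]), "counts")
        with pytest.raises(ValueError, match="log2"):
            select_variant_genes(m, 1)


@pytest.fixture(scope="module")
def quick_blocks():
    """Small 3-block cohort with strong separation, plus its subtyping."""
    cfg = ScenarioConfig(seed=3, n_genes=600, signature_size=50,
                        subtype_block_size=120, samples_per_subtype=12,
                        n_normals=6, noise_sd=0.5)
    cohort, normals, truth = simulate_cohort(cfg)
    log2 = cohort.to_log2()
    genes = select_variant_genes(log2, 400)
    result = consensus_subtype(log2, genes, k_range=range(2, 5), n_runs=12,
                               seed=3)
    return cohort, normals, truth, log2, genes, result


class TestConsensusSubtype:
    def test_recovers_planted_k_and_labels(self, quick_blocks):
        cohort, _, truth, _, _, result = quick_blocks
        assert result.k == 3
        ari = adjusted_rand_score([truth.labels[s] for s in cohort.samples],
                                  [result.labels[s] for s in cohort.samples])
        assert ari >= 0.9

    def test_consensus_matrix_invariants(self, quick_blocks):
        *_, result = quick_blocks
        c = result.consensus.to_numpy()
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)
        assert c.min() >= 0.0 and c.max() <= 1.0

    def test_stable_clustering_has_unit_cophenetic(self, quick_blocks):
        *_, result = quick_blocks
        # strong separation: co-clustering is near-perfectly stable at true k
        assert result.metrics[3]["cophenetic"] >= 0.99

    def test_identical_samples_get_identical_labels(self):
        rng = np.random.default_rng(8)
        base = rng.normal(5, 2, size=(60, 5))
        base[:30, :3] += 4  # two clear groups
        base[30:, 3:] += 4
        data = pd.DataFrame(base, index=[f"g{i:02d}" for i in range(60)],
                            columns=[f"s{i}" for i in range(5)])
        data["s_dup"] = data["s0"]  # exact duplicate sample
        m = ExpressionMatrix(data, "log2")
        result = consensus_subtype(m, list(m.genes), k_range=range(2, 4),
                                   n_runs=8, seed=8)
        assert result.labels["s0"] == result.labels["s_dup"]

    def test_invalid_parameters_error(self, small_log2_matrix):
        with pytest.raises(ValueError, match="k_range"):
            consensus_subtype(small_log2_matrix, small_log2_matrix.genes,
                              k_range=range(1, 3), n_runs=5)
        with pytest.raises(ValueError, match="n_runs"):
            consensus_subtype(small_log2_matrix, small_log2_matrix.genes,
                              k_range=range(2, 3), n_runs=1)


def _truth_subtype_result(cohort, labels) -> SubtypeResult:
    arr = np.array([labels[s] for s in cohort.samples])
    consensus = pd.DataFrame((arr[:, None] == arr[None, :]).astype(float),
                             index=cohort.samples, columns=cohort.samples)
    return SubtypeResult(labels=dict(labels), k=max(2, len(set(arr))),
                         metrics={}, consensus=consensus)


class TestSubtypeSimilarity:
    def _setup(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i:02d}" for i in range(30)]
        profile = rng.normal(5, 2, 30)
        cols = {}
        for i in range(3):  # subtype 1: copies of `profile`
            cols[f"a{i}"] = profile
        for i in range(3):  # subtype 2: unrelated
            cols[f"b{i}"] = rng.normal(5, 2, 30)
        cohort = ExpressionMatrix(pd.DataFrame(cols, index=genes), "log2")
        labels = {s: (1 if s.startswith("a") else 2) for s in cohort.samples}
        return genes, profile, cohort, _truth_subtype_result(cohort, labels)

    def test_identical_patient_maps_to_its_subtype(self):
        genes, profile, cohort, st_res = self._setup()
        patient = pd.Series(profile, index=genes)
        per, assigned, _ = subtype_similarity(patient, cohort, st_res, genes)
        assert per[1] == pytest.approx(1.0)
        assert assigned == 1

    def test_rank_reversed_patient_is_anticorrelated(self):
        genes, profile, cohort, st_res = self._setup()
        patient = pd.Series(-profile, index=genes)
        per, _, _ = subtype_similarity(patient, cohort, st_res, genes)
        assert per[1] == pytest.approx(-1.0)

    def test_tie_breaks_to_smaller_subtype_id(self):
        genes = ["gA", "gB", "gC"]
        profile = np.array([1.0, 2.0, 3.0])
        cohort = ExpressionMatrix(
            pd.DataFrame({"a": profile, "b": profile}, index=genes), "log2")
        st_res = _truth_subtype_result(cohort, {"a": 1, "b": 2})
        patient = pd.Series(profile, index=genes)
        _, assigned, _ = subtype_similarity(patient, cohort, st_res, genes)
        assert assigned == 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=5.0),
           st.floats(min_value=-3.0, max_value=3.0))
    def test_invariant_under_monotone_patient_transform(self, scale, shift):
        genes, profile, cohort, st_res = self._setup()
        patient = pd.Series(profile, index=genes)
        per, assigned, _ = subtype_similarity(patient, cohort, st_res, genes)
        transformed = pd.Series(scale * profile + shift, index=genes)
        per2, assigned2, _ = subtype_similarity(transformed, cohort, st_res,
                                                genes)
        assert assigned == assigned2
        for k in per:
            assert per[k] == pytest.approx(per2[k])

    def test_too_few_shared_genes_errors(self):
        genes, profile, cohort, st_res = self._setup()
        patient = pd.Series(profile[:1], index=genes[:1])
        with pytest.raises(ValueError, match="2 genes"):
            subtype_similarity(patient, cohort, st_res, genes)


class TestSelectSubgroup:
    def _result(self, n=10):
        samples = [f"s{i:02d}" for i in range(n)]
        data = pd.DataFrame(np.ones((2, n)), index=["gA", "gB"],
                            columns=samples)
        cohort = ExpressionMatrix(data, "log2")
        return _truth_subtype_result(cohort, {s: 1 for s in samples}), samples

    def test_top_n_by_rho(self):
        st_res, samples = self._result()
        rho = {s: 0.9 - 0.1 * i for i, s in enumerate(samples)}
        sg = select_subgroup("pt", rho, st_res, 1, n=3)
        assert sg.subgroup == samples[:3]

    def test_n_equals_subtype_size(self):
        st_res, samples = self._result(4)
        rho = {s: 0.5 for s in samples}
        assert select_subgroup("pt", rho, st_res, 1, n=4).subgroup == samples

    def test_n_too_large_errors(self):
        st_res, samples = self._result(4)
        with pytest.raises(ValueError, match="exceeds"):
            select_subgroup("pt", {s: 0.0 for s in samples}, st_res, 1, n=5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-1, max_value=1, allow_nan=False),
                    min_size=10, max_size=10))
    def test_growing_n_never_drops_samples(self, rhos):
        st_res, samples = self._result()
        rho = dict(zip(samples, rhos))
        previous: set = set()
        for n in range(1, 11):
            chosen = set(select_subgroup("pt", rho, st_res, 1, n=n).subgroup)
            assert previous <= chosen
            previous = chosen


class TestSelectControls:
    def test_planted_matches_found(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i:02d}" for i in range(40)]
        profile = rng.normal(6, 2, 40)
        subgroup = ExpressionMatrix(pd.DataFrame(
            {f"t{i}": profile + rng.normal(0, 0.1, 40) for i in range(3)},
            index=genes), "log2")
        pool_cols = {f"match{i}": profile + rng.normal(0, 0.1, 40)
                     for i in range(3)}
        pool_cols.update({f"noise{i}": rng.normal(6, 2, 40) for i in range(5)})
        pool = ExpressionMatrix(pd.DataFrame(pool_cols, index=genes), "log2")
        chosen = select_controls(subgroup, pool, 3, genes)
        assert sorted(chosen) == ["match0", "match1", "match2"]

    def test_n_equals_pool_size_returns_all(self):
        genes = ["gA", "gB", "gC"]
        sub = ExpressionMatrix(pd.DataFrame(
            {"t1": [1.0, 2, 3], "t2": [1.0, 2, 3]}, index=genes), "log2")
        pool = ExpressionMatrix(pd.DataFrame(
            {"n1": [3.0, 2, 1], "n2": [1.0, 3, 2]}, index=genes), "log2")
        assert sorted(select_controls(sub, pool, 2, genes)) == ["n1", "n2"]

    def test_pool_too_small_errors(self):
        genes = ["gA", "gB"]
        sub = ExpressionMatrix(pd.DataFrame({"t1": [1.0, 2]}, index=genes),
                               "log2")
        pool = ExpressionMatrix(pd.DataFrame({"n1": [1.0, 2]}, index=genes),
                                "log2")
        with pytest.raises(ValueError, match="pool"):
            select_controls(sub, pool, 2, genes)
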