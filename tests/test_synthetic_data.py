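"""Generator contracts: seeded determinism, exact planted structure,
convergence of the noise model to its nominal moments."""

import dataclasses

import numpy as np
import pytest

from comorbsig.io_formats import ValidationError
from comorbsig.synthetic_data import (
    SynthSpec,
    simulate_expression,
    simulate_gene_sets,
    simulate_interaction_network,
    simulate_network,
    simulate_regulons,
)


def test_same_seed_gives_byte_identical_matrices():
    a1, b1, _ = simulate_expression(SynthSpec(), seed=1)
    a2, b2, _ = simulate_expression(SynthSpec(), seed=1)
    for d1, d2 in zip([*a1, *b1], [*a2, *b2]):
        assert np.array_equal(d1.values, d2.values)
        assert d1.sample_ids == d2.sample_ids


def test_cohort_shapes_follow_the_study_design():
    a, b, _ = simulate_expression(SynthSpec(), seed=0)
    assert [(d.n_case, d.n_control) for d in a] == [(13, 8), (43, 29)]
    assert [(d.n_case, d.n_control) for d in b] == [(12, 24)]


def test_ground_truth_partition_sizes_match_spec_exactly():
    spec = SynthSpec()
    _, _, truth = simulate_expression(spec, seed=7)
    assert len(truth.genes_with("A", "up")) == spec.up_a
    assert len(truth.genes_with("A", "down")) == spec.down_a
    assert len(truth.genes_with("B", "up")) == spec.up_b
    assert len(truth.genes_with("B", "down")) == spec.down_b
    assert len(truth.concordant_up_genes) == spec.concordant_up == 7
    assert len(truth.concordant_down_genes) == spec.concordant_down == 21
    assert len(truth.genes_with("A", "up") & truth.genes_with("B", "down")) == 2
    assert len(truth.genes_with("A", "down") & truth.genes_with("B", "up")) == 4


def test_infeasible_overlap_counts_rejected():
    with pytest.raises(ValidationError):
        SynthSpec(up_a=5, concordant_up=7)
    with pytest.raises(ValidationError):
        SynthSpec(n_genes=100)  # planted counts exceed the universe


def test_delta_zero_plants_no_shift():
    spec = dataclasses.replace(SynthSpec(), delta=0.0)
    a, _, truth = simulate_expression(spec, seed=3)
    ds = a[1]  # largest cohort
    up = sorted(truth.genes_with("A", "up"))
    idx = [ds.gene_ids.index(g) for g in up]
    diffs = ds.case_matrix()[idx].mean(axis=1) - ds.control_matrix()[idx].mean(axis=1)
    # standardized differences should be noise-level, not ~delta
    s = np.sqrt(ds.values[idx].var(axis=1, ddof=1))
    assert np.abs(diffs / s).mean() < 0.5


def test_moments_converge_at_large_sample_size():
    # one 500v500 cohort: standardized shift estimates average to delta
    spec = dataclasses.replace(
        SynthSpec(), disease_a_datasets=((500, 500),), delta=1.2
    )
    a, _, truth = simulate_expression(spec, seed=5)
    ds = a[0]
    case, control = ds.case_matrix(), ds.control_matrix()
    sp = np.sqrt(0.5 * (case.var(axis=1, ddof=1) + control.var(axis=1, ddof=1)))
    std_effect = (case.mean(axis=1) - control.mean(axis=1)) / sp
    up = [ds.gene_ids.index(g) for g in truth.genes_with("A", "up")]
    down = [ds.gene_ids.index(g) for g in truth.genes_with("A", "down")]
    null = [ds.gene_ids.index(g) for g in truth.genes_with("A", "null")]
    assert abs(std_effect[up].mean() - spec.delta) / spec.delta < 0.05
    assert abs(std_effect[down].mean() + spec.delta) / spec.delta < 0.05
    assert abs(std_effect[null].mean()) < 0.05
    # baseline level recovered within 5%
    assert abs(ds.values.mean() - spec.baseline_mean) / spec.baseline_mean < 0.05


class TestGeneSets:
    def test_zero_terms_gives_empty_collection(self, truth):
        assert len(simulate_gene_sets(truth, n_terms=0, n_planted=0, seed=1)) == 0

    def test_fixed_size_range_gives_exact_sizes(self, truth):
        coll = simulate_gene_sets(truth, n_terms=5, term_size_range=(10, 10), n_planted=0, seed=1)
        assert all(len(coll.members(t)) == 10 for t in coll.term_ids())

    def test_planted_terms_concentrate_in_concordant_sets(self, truth):
        coll = simulate_gene_sets(truth, n_terms=10, n_planted=2, seed=2)
        planted = {t: d for t, d in truth.planted_terms.items() if t in coll.term_ids()}
        assert len(planted) == 2
        for term, direction in planted.items():
            target = (
                truth.concordant_down_genes if direction == "down" else truth.concordant_up_genes
            )
            members = coll.members(term)
            inside = len(members & target)
            assert inside >= min(0.6 * len(members), len(target)) - 1e-9

    def test_oversized_terms_rejected(self, truth):
        with pytest.raises(ValidationError):
            simulate_gene_sets(truth, n_terms=1, term_size_range=(10, 10**6), seed=1)

    def test_seeded_determinism(self, truth):
        c1 = simulate_gene_sets(truth, seed=9)
        c2 = simulate_gene_sets(truth, seed=9)
        assert {t: c1.members(t) for t in c1.term_ids()} == {
            t: c2.members(t) for t in c2.term_ids()
        }


class TestNetworkAndRegulons:
    def test_planted_hubs_dominate_degree(self, truth):
        edges = simulate_network(truth, n_hub_planted=3, seed=4)
        degree: dict[str, int] = {}
        for a, b, _ in edges.edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        non_hub = [d for n, d in degree.items() if n not in truth.planted_hubs]
        median_bg = np.median(non_hub)
        for hub in truth.planted_hubs:
            assert degree[hub] >= 3 * median_bg

    def test_empty_truth_gives_empty_edge_list(self, truth):
        from comorbsig.synthetic_data import GroundTruth

        empty = GroundTruth(genes=list(truth.genes), direction_a={g: "null" for g in truth.genes},
                            direction_b={g: "null" for g in truth.genes})
        assert len(simulate_network(empty, seed=1)) == 0

    def test_too_many_planted_hubs_rejected(self):
        with pytest.raises(ValidationError):
            simulate_interaction_network(["a", "b"], n_predicted=0, n_hub_planted=5, seed=1)

    def test_planted_regulons_target_concordant_genes(self, truth):
        table = simulate_regulons(truth, n_planted=2, seed=6)
        targets: dict[str, set] = {}
        for row in table.rows:
            targets.setdefault(row.tf, set()).add(row.target)
        for tf, direction in truth.planted_tfs.items():
            pool = (
                truth.concordant_down_genes if direction == "down" else truth.concordant_up_genes
            )
            inside = len(targets[tf] & pool)
            assert inside >= min(8, len(pool))
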