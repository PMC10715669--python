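"""Pentanucleotide clustering, group assignment, and the A3A:A3B mixture weight."""

import math

import numpy as np
import pytest

from a3sig import (
    SimulationConfig,
    a3_mixture_weight,
    annotate_contexts,
    assign_etiology,
    build_clustering_matrix,
    hierarchical_cluster,
    motif_fractions,
    simulate_clone,
)
from a3sig.etiology import ClusteringMatrix
from a3sig.synthetic_data import A3A_MOTIF, A3B_MOTIF, MotifModel


class TestClusteringMatrix:
    def test_single_mutation_channel_and_normalization(self, ctx_factory):
        m = build_clustering_matrix([ctx_factory("ATCAG", "T")])
        df = m.to_frame()
        assert df.shape == (1, 48)
        assert df.loc["s1", "AT[C>T]AG"] == 1.0
        assert df.sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_c_to_g_and_tcg_excluded(self, ctx_factory):
        with pytest.raises(ValueError):
            build_clustering_matrix(
                [ctx_factory("ATCAG", "G"), ctx_factory("ATCGA", "T")]
            )

    def test_rows_sum_to_one(self, genome_2mb):
        cfg = SimulationConfig()
        recs, _ = simulate_clone(genome_2mb, cfg, "A3A", seed=13, n_mutations=2000)
        m = build_clustering_matrix(annotate_contexts(recs, genome_2mb))
        assert np.allclose(m.frequencies.sum(axis=1), 1.0)
        assert len(m.channels) == 48

    def test_a3a_mode_mass_on_minus2_pyrimidine(self, genome_2mb):
        cfg = SimulationConfig()
        cfg.conditions["A3A"].apobec_fraction = 1.0
        cfg.conditions["A3A"].kataegis_events = 0.0
        recs, _ = simulate_clone(genome_2mb, cfg, "A3A", seed=14, n_mutations=20_000)
        m = build_clustering_matrix(annotate_contexts(recs, genome_2mb))
        y_mass = sum(
            f for ch, f in zip(m.channels, m.frequencies[0]) if ch[0] in "CT"
        )
        se = math.sqrt(0.727 * 0.273 / 20_000)
        assert abs(y_mass - 0.727) < 4 * se


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero(self):
        m = ClusteringMatrix(["a", "b"], ["x", "y"], np.array([[0.5, 0.5], [0.5, 0.5]]))
        d = hierarchical_cluster(m)
        assert d.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_euclidean_height(self):
        m = ClusteringMatrix(["a", "b"], ["x", "y"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        d = hierarchical_cluster(m)
        assert d.linkage_matrix[0, 2] == pytest.approx(math.sqrt(2))

    def test_requires_two_samples(self):
        m = ClusteringMatrix(["a"], ["x"], np.array([[1.0]]))
        with pytest.raises(ValueError):
            hierarchical_cluster(m)

    def test_newick_export_contains_all_leaves(self):
        m = ClusteringMatrix(
            ["a", "b", "c"], ["x", "y"],
            np.array([[0.0, 1.0], [1.0, 0.0], [0.5, 0.5]]),
        )
        nwk = hierarchical_cluster(m).to_newick()
        assert all(leaf in nwk for leaf in "abc") and nwk.endswith(";")


def simulate_cohort_contexts(genome, n_per_group=5, n_mut=2000, seed0=100):
    """Three simulated groups: A3A-mode, A3B-mode, and flat C>T background.

    The background group draws its mutations from the C>T class at random
    cytosines, so its pentanucleotide profile is flat at genome composition
    rather than motif-biased.
    """
    cfg = SimulationConfig()
    # all background mass on C>T so background samples populate the
    # C>T pentanucleotide matrix with a flat (composition-driven) profile
    cfg.background_class_weights = [0, 0, 1, 0, 0, 0]
    for cond in ("A3A", "A3B"):
        cfg.conditions[cond].apobec_fraction = 1.0
        cfg.conditions[cond].kataegis_events = 0.0
    by_sample = {}
    for g, cond in enumerate(("A3A", "A3B", "control")):
        for i in range(n_per_group):
            sid = f"{cond}_{i}"
            recs, _ = simulate_clone(
                genome, cfg, cond, seed=seed0 + 1000 * g + i,
                sample_id=sid, n_mutations=n_mut,
            )
            by_sample[sid] = annotate_contexts(recs, genome)
    return by_sample


class TestAssignEtiology:
    def test_three_group_recovery(self, genome_2mb):
        """k=3 cut separates A3A-mode, A3B-mode, and background samples."""
        by_sample = simulate_cohort_contexts(genome_2mb)
        all_ctx = [c for v in by_sample.values() for c in v]
        dend = hierarchical_cluster(build_clustering_matrix(all_ctx))
        anchors = {"A3A_0": "A3A", "A3B_0": "A3B", "control_0": "non-APOBEC"}
        calls = assign_etiology(dend, anchors, k=3)
        expected = {"A3A": "A3A-like", "A3B": "A3B-like", "control": "non-APOBEC"}
        for call in calls:
            cond = call.sample_id.rsplit("_", 1)[0]
            assert call.group == expected[cond], call.sample_id

    def test_order_invariance_of_groups(self, genome_2mb):
        by_sample = simulate_cohort_contexts(genome_2mb, n_per_group=3)
        anchors = {"A3A_0": "A3A", "A3B_0": "A3B", "control_0": "non-APOBEC"}
        orders = [list(by_sample), list(by_sample)[::-1]]
        results = []
        for order in orders:
            ctxs = [c for sid in order for c in by_sample[sid]]
            dend = hierarchical_cluster(build_clustering_matrix(ctxs))
            calls = assign_etiology(dend, anchors, k=3)
            results.append({c.sample_id: c.group for c in calls})
        assert results[0] == results[1]

    def test_missing_anchor_condition_rejected(self, genome_2mb):
        by_sample = simulate_cohort_contexts(genome_2mb, n_per_group=2)
        all_ctx = [c for v in by_sample.values() for c in v]
        dend = hierarchical_cluster(build_clustering_matrix(all_ctx))
        with pytest.raises(ValueError, match="missing"):
            assign_etiology(dend, {"A3A_0": "A3A", "A3B_0": "A3B"}, k=3)

    def test_fifty_fifty_mixtures_stay_in_apobec_groups(self, genome_2mb):
        """50:50 A3A/A3B mixture samples never land in the non-APOBEC group."""
        by_sample = simulate_cohort_contexts(genome_2mb, n_per_group=3)
        cfg = SimulationConfig()
        for cond in ("A3A", "A3B"):
            cfg.conditions[cond].apobec_fraction = 1.0
            cfg.conditions[cond].kataegis_events = 0.0
        for j in range(2):
            sid = f"mix_{j}"
            ctxs = []
            for cond in ("A3A", "A3B"):
                recs, _ = simulate_clone(
                    genome_2mb, cfg, cond, seed=500 + j, sample_id=sid,
                    n_mutations=1000,
                )
                ctxs.extend(annotate_contexts(recs, genome_2mb))
            by_sample[sid] = ctxs
        all_ctx = [c for v in by_sample.values() for c in v]
        dend = hierarchical_cluster(build_clustering_matrix(all_ctx))
        anchors = {"A3A_0": "A3A", "A3B_0": "A3B", "control_0": "non-APOBEC"}
        calls = {c.sample_id: c.group for c in assign_etiology(dend, anchors, k=3)}
        for j in range(2):
            assert calls[f"mix_{j}"] in ("A3A-like", "A3B-like")


class TestMixtureWeight:
    @pytest.mark.parametrize(
        "f,expected",
        [(0.472, 0.0), (0.727, 1.0), (0.5995, 0.5), (0.30, 0.0), (0.90, 1.0)],
    )
    def test_endpoints_midpoint_and_clamping(self, f, expected):
        assert a3_mixture_weight(f) == pytest.approx(expected)

    def test_monotone_in_f(self):
        fs = np.linspace(0, 1, 21)
        ws = [a3_mixture_weight(f) for f in fs]
        assert all(b >= a for a, b in zip(ws, ws[1:]))

    def test_invalid_anchors_rejected(self):
        with pytest.raises(ValueError):
            a3_mixture_weight(0.6, a_A3B=0.7, a_A3A=0.7)

    @pytest.mark.parametrize("pi", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_two_component_recovery(self, pi, genome_2mb):
        """Estimated weight within 0.05 of truth at n = 10,000 mutations."""
        cfg = SimulationConfig()
        for cond in ("A3A", "A3B"):
            cfg.conditions[cond].apobec_fraction = 1.0
            cfg.conditions[cond].kataegis_events = 0.0
        n = 10_000
        n_a = int(round(pi * n))
        ctxs = []
        if n_a:
            recs, _ = simulate_clone(
                genome_2mb, cfg, "A3A", seed=600 + int(pi * 100),
                sample_id="mix", n_mutations=n_a,
            )
            ctxs.extend(annotate_contexts(recs, genome_2mb))
        if n - n_a:
            recs, _ = simulate_clone(
                genome_2mb, cfg, "A3B", seed=700 + int(pi * 100),
                sample_id="mix", n_mutations=n - n_a,
            )
            ctxs.extend(annotate_contexts(recs, genome_2mb))
        f = motif_fractions(ctxs).f_YTCW
        assert abs(a3_mixture_weight(f) - pi) < 0.05
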