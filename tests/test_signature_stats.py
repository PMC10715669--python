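"""Spectra, motif fractions, enrichment scores, BH correction, cohort stats."""

import math

import numpy as np
import pytest

from a3sig import (
    MotifModel,
    SimulationConfig,
    annotate_contexts,
    bh_adjust,
    build_spectrum,
    cohort_summary,
    cosine_similarity,
    enrichment_score,
    motif_fractions,
    simulate_clone,
)
from a3sig.signature_stats import TRI_CHANNELS, enrichment_from_counts


class TestSpectrum:
    def test_conservation_and_channel_mapping(self, ctx_factory):
        ctxs = [
            ctx_factory("ATCAG", "T"),
            ctx_factory("ATCAG", "G"),
            ctx_factory("GTTAC", "C"),
        ]
        spec = build_spectrum(ctxs, level="tri")
        assert spec.counts.sum() == 3
        df = spec.to_frame()
        assert df.loc["s1", "T[C>T]A"] == 1
        assert df.loc["s1", "T[C>G]A"] == 1
        assert df.loc["s1", "T[T>C]A"] == 1

    def test_channel_order_is_fixed(self):
        assert len(TRI_CHANNELS) == 96
        assert TRI_CHANNELS[0] == "A[C>A]A" and TRI_CHANNELS[-1] == "T[T>G]T"

    def test_flagged_contexts_excluded(self, ctx_factory):
        spec = build_spectrum([ctx_factory("ATCAG", "T", flagged=True)])
        assert spec.counts.sum() == 0

    def test_unknown_level(self, ctx_factory):
        with pytest.raises(ValueError):
            build_spectrum([ctx_factory("ATCAG", "T")], level="hexa")

    def test_a3a_spectrum_peaks_at_tca_and_tct(self, genome_2mb):
        """Pooled A3A-mode catalogs peak at T[C>T]A and T[C>T]T."""
        cfg = SimulationConfig()
        cfg.conditions["A3A"].apobec_fraction = 1.0
        recs, _ = simulate_clone(genome_2mb, cfg, "A3A", seed=8, n_mutations=4000)
        spec = build_spectrum(annotate_contexts(recs, genome_2mb))
        totals = spec.counts.sum(axis=0)
        top2 = {spec.channels[i] for i in np.argsort(totals)[-2:]}
        assert top2 == {"T[C>T]A", "T[C>T]T"}

    def test_row_normalization(self, ctx_factory):
        spec = build_spectrum(
            [ctx_factory("ATCAG", "T"), ctx_factory("TTCTG", "G")]
        ).normalize()
        assert np.allclose(spec.normalized.sum(axis=1), 1.0)


class TestMotifFractions:
    def test_hand_constructed_fractions(self, ctx_factory):
        # four TC mutations: +1 bases A, A, T, G; -2 bases C, A, T, G
        ctxs = [
            ctx_factory("CTCAG", "T"),  # YTCW
            ctx_factory("ATCAG", "G"),  # RTCW
            ctx_factory("TTCTG", "T"),  # YTCW
            ctx_factory("GTCGA", "T"),  # TC but not TCW
        ]
        mf = motif_fractions(ctxs)
        assert mf.n_tc == 4 and mf.n_tcw == 3
        assert mf.f_plus1_A == pytest.approx(0.5)
        assert mf.f_plus1_T == pytest.approx(0.25)
        assert mf.f_W == pytest.approx(0.75)
        assert mf.f_minus2_Y == pytest.approx(0.5)
        assert mf.f_minus2_Y + mf.f_minus2_R == pytest.approx(1.0)
        assert mf.f_YTCW == pytest.approx(2 / 3)
        assert mf.f_YTCW + mf.f_RTCW == pytest.approx(1.0)

    def test_non_tc_and_ct_mutations_ignored(self, ctx_factory):
        ctxs = [
            ctx_factory("ATCAG", "T"),
            ctx_factory("AACAG", "T"),  # -1 not T
            ctx_factory("ATTAG", "C"),  # T>C, not a cytosine mutation
            ctx_factory("ATCAG", "A"),  # C>A excluded from the signature set
        ]
        assert motif_fractions(ctxs).n_tc == 1

    def test_empty_input_is_explicit_error(self, ctx_factory):
        with pytest.raises(ValueError, match="no oriented"):
            motif_fractions([ctx_factory("AACAG", "T")])

    def test_binomial_recovery_of_configured_minus2(self, genome_2mb):
        """A -2 pyrimidine probability of 0.6 is recovered within 3 SE."""
        cfg = SimulationConfig()
        cfg.conditions["A3A"].motif = MotifModel(0.6, 0.483, 0.363)
        cfg.conditions["A3A"].apobec_fraction = 1.0
        cfg.conditions["A3A"].kataegis_events = 0.0
        recs, _ = simulate_clone(genome_2mb, cfg, "A3A", seed=9, n_mutations=50_000)
        mf = motif_fractions(annotate_contexts(recs, genome_2mb))
        se = math.sqrt(0.6 * 0.4 / mf.n_tcw)
        assert abs(mf.f_YTCW - 0.6) < 3 * se


def fisher_greater_oracle(a, b, c, d):
    """One-sided (enrichment) Fisher p by direct hypergeometric summation."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    total = math.comb(n, col1)
    return sum(
        math.comb(row1, k) * math.comb(n - row1, col1 - k) / total
        for k in range(a, hi + 1)
    )


class TestEnrichment:
    def test_score_formula_on_toy_counts(self):
        e, p = enrichment_from_counts(8, 10, 20, 100)
        assert e == pytest.approx(4.0)

    def test_fisher_p_matches_hypergeometric_oracle(self):
        _, p = enrichment_from_counts(8, 10, 20, 100)
        assert p == pytest.approx(fisher_greater_oracle(8, 20, 2, 80), rel=1e-9)

    def test_undefined_counts_raise(self):
        with pytest.raises(ValueError):
            enrichment_from_counts(0, 10, 0, 100)

    def test_null_enrichment_near_one(self, genome_2mb):
        """Uniform mutations on cytosines give E ~ 1 at n = 10,000."""
        from a3sig import MutationRecord

        rng = np.random.default_rng(21)
        seq = genome_2mb.contigs["chr1"]
        cpos = np.array(
            [i for i in range(2, len(seq) - 2) if seq[i] in "CG"], dtype=np.int64
        )
        picks = rng.choice(cpos, size=10_000, replace=False)
        recs = [
            MutationRecord(
                "null", "", "chr1", int(p) + 1, seq[p], "T" if seq[p] == "C" else "A"
            )
            for p in picks
        ]
        ctxs = annotate_contexts(recs, genome_2mb)
        (res,) = enrichment_score(ctxs, genome_2mb)
        assert abs(res.E - 1.0) < 0.05

    def test_null_type_one_error_controlled(self, genome_200kb):
        """Fraction of null samples with Fisher p < 0.05 stays near 5%.

        200 simulated samples of 150 uniformly placed cytosine mutations each.
        """
        from a3sig import MutationRecord

        rng = np.random.default_rng(22)
        seq = genome_200kb.contigs["chr1"]
        cpos = np.array(
            [i for i in range(2, len(seq) - 2) if seq[i] in "CG"], dtype=np.int64
        )
        recs = []
        for s in range(200):
            for p in rng.choice(cpos, size=150, replace=False):
                recs.append(
                    MutationRecord(
                        f"null{s}", "", "chr1", int(p) + 1,
                        seq[p], "T" if seq[p] == "C" else "A",
                    )
                )
        ctxs = annotate_contexts(recs, genome_200kb)
        results = enrichment_score(ctxs, genome_200kb)
        assert len(results) == 200
        frac = np.mean([r.p < 0.05 for r in results if not r.undefined])
        # 5% nominal + 3 binomial SE tolerance
        assert frac <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 200)


def bh_oracle(ps):
    """Independent step-up implementation (sort, scale, running minimum)."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, ps[i] * m / rank)
        q[i] = prev
    return q


class TestBHAdjust:
    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(33)
        ps = rng.uniform(size=100).tolist()
        assert bh_adjust(ps) == pytest.approx(bh_oracle(ps))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCosineSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 0], [0, 1], 0.0),
            ([1, 2, 2], [2, 1, 2], 8 / 9),
        ],
    )
    def test_examples(self, a, b, expected):
        assert cosine_similarity(a, b) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])


class TestCohortSummary:
    def test_basic_statistics(self):
        out = cohort_summary({"A": [1, 2, 3], "ref": [1, 2, 3]}, reference="ref")
        a = next(s for s in out if s.condition == "A")
        assert (a.median, a.mean, a.sd) == (2.0, 2.0, 1.0)
        assert a.sem == pytest.approx(1.0 / math.sqrt(3))

    def test_welch_against_itself_is_one(self):
        out = cohort_summary({"A": [3.0, 5.0, 9.0]}, reference="A")
        assert out[0].p_vs_reference == pytest.approx(1.0)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary({"A": [], "ref": [1, 2]}, reference="ref")
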