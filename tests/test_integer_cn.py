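import numpy as np
import pytest

from pdxcna.integer_cn import (
    DiscordanceError,
    IntegerCNSample,
    int_bin_discordant,
    int_pair_discordance,
    int_sample_pass,
    ploidy_adjust,
    ploidy_rerun_policy,
    resolve_subclonal,
    round_half_away,
)


def make_sample(cn, prevalence=None, ploidy=2.0, tumor_fraction=0.5,
                sample_id="s", role="PDX"):
    cn = np.asarray(cn, dtype=float)
    prev = np.full(len(cn), np.nan) if prevalence is None else np.asarray(prevalence, float)
    return IntegerCNSample(
        sample_id=sample_id, cn=cn, prevalence=prev, ploidy=ploidy,
        tumor_fraction=tumor_fraction, meta={"role": role},
    )


class TestResolveSubclonal:
    def test_high_prevalence_becomes_clonal(self):
        s = make_sample([3, 2], prevalence=[0.95, np.nan])
        assert resolve_subclonal(s).tolist() == [3.0, 2.0]

    def test_low_prevalence_becomes_neutral_at_rounded_ploidy(self):
        s = make_sample([1, 2], prevalence=[0.05, np.nan], ploidy=2.6)
        assert resolve_subclonal(s).tolist() == [3.0, 2.0]  # round(2.6) = 3

    @pytest.mark.parametrize("prev", [0.1, 0.5, 0.9])
    def test_intermediate_prevalence_excluded_inclusive(self, prev):
        s = make_sample([3], prevalence=[prev])
        assert np.isnan(resolve_subclonal(s)[0])

    def test_prevalence_outside_unit_interval_rejected(self):
        with pytest.raises(DiscordanceError, match="prevalence"):
            make_sample([3], prevalence=[1.5])


class TestPloidyAdjust:
    @pytest.mark.parametrize(
        "cn,ploidy,expected", [(4, 2.0, 4.0), (3, 3.0, 2.0), (3, 2.5, 2.4)]
    )
    def test_rescales_to_diploid_frame(self, cn, ploidy, expected):
        assert ploidy_adjust(cn, ploidy) == pytest.approx(expected)

    def test_nonpositive_ploidy_rejected(self):
        with pytest.raises(DiscordanceError):
            ploidy_adjust(2, 0.0)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(1.5) == 2


class TestIntBinDiscordant:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (3.0, 2.0, 1),   # unique gain, gap 1.0
            (2.6, 2.2, 0),   # rounds 3 vs 2 but gap 0.4 < 0.5
            (2.0, 2.0, 0),
            (1.0, 2.0, -1),  # unique loss in a
            (3.0, 3.2, 0),   # both gain: no unique event
        ],
    )
    def test_gap_and_uniqueness_rules(self, a, b, expected):
        assert int_bin_discordant(a, b) == expected

    def test_gain_vs_loss_is_discordant(self):
        assert int_bin_discordant(3.0, 1.0) == 1


class TestSamplePass:
    def test_low_tumor_fraction_fails(self):
        s = make_sample([3] * 10 + [2] * 10, tumor_fraction=0.04)
        assert not int_sample_pass(s)

    def test_low_clonal_alteration_fails(self):
        cn = [2.0] * 97 + [3.0] * 3
        assert not int_sample_pass(make_sample(cn, tumor_fraction=0.5))

    def test_sufficient_alteration_passes(self):
        cn = [2.0] * 90 + [3.0] * 10
        assert int_sample_pass(make_sample(cn, tumor_fraction=0.5))

    def test_excluded_subclonal_bins_do_not_count_as_altered(self):
        cn = np.full(100, 2.0)
        cn[:10] = 3
        prev = np.full(100, np.nan)
        prev[:10] = 0.5  # all altered bins are intermediate-prevalence
        assert not int_sample_pass(make_sample(cn, prevalence=prev, tumor_fraction=0.5))


class TestIntPairDiscordance:
    def planted_pair(self, grid, recipient_ploidy=2.0, recipient_cn=2.0):
        n = grid.n_bins
        cn_a = np.full(n, 2.0)
        lo, hi = grid.chrom_range("1")
        arm_idx = np.flatnonzero(grid.arm == "1p")
        cn_a[arm_idx] = 3.0  # full-arm gain in a
        a = make_sample(cn_a, ploidy=2.0, sample_id="a", tumor_fraction=0.6)
        b = make_sample(np.full(n, recipient_cn), ploidy=recipient_ploidy,
                        sample_id="b", tumor_fraction=0.6)
        return a, b, arm_idx

    def test_identical_tables_fraction_zero(self, toy_grid):
        n = toy_grid.n_bins
        cn = np.full(n, 2.0)
        cn[:5] = 3.0
        a = make_sample(cn, sample_id="a")
        b = make_sample(cn.copy(), sample_id="b")
        res = int_pair_discordance(a, b, toy_grid, enforce_filters=False)
        assert res.fraction_discordant == 0.0

    def test_planted_arm_gain_fraction_and_arm_call(self, toy_grid):
        a, b, arm_idx = self.planted_pair(toy_grid)
        res = int_pair_discordance(a, b, toy_grid, enforce_filters=False,
                                   min_arm_bins=5)
        assert res.fraction_discordant == pytest.approx(len(arm_idx) / toy_grid.n_bins)
        assert ("1", "p", "a_greater") in res.discordant_arms

    def test_genome_doubled_partner_neutralizes_gain(self, toy_grid):
        # partner is uniformly cn 3 at ploidy 3: adjusted 2.0 everywhere;
        # a's arm gain is adjusted 3.0 vs 2.0 -> still discordant, but a's
        # neutral bins (adjusted 2.0) match the partner's adjusted baseline.
        a, b, arm_idx = self.planted_pair(toy_grid, recipient_ploidy=3.0,
                                          recipient_cn=3.0)
        res = int_pair_discordance(a, b, toy_grid, enforce_filters=False,
                                   min_arm_bins=5)
        assert res.fraction_discordant == pytest.approx(len(arm_idx) / toy_grid.n_bins)

    def test_ploidy_invariance_under_joint_scaling(self, toy_grid):
        rng = np.random.default_rng(11)
        n = toy_grid.n_bins
        cn_a = rng.choice([1.0, 2.0, 3.0, 4.0], size=n)
        cn_b = rng.choice([1.0, 2.0, 3.0, 4.0], size=n)
        a = make_sample(cn_a, ploidy=2.0, sample_id="a")
        b = make_sample(cn_b, ploidy=2.0, sample_id="b")
        ref = int_pair_discordance(a, b, toy_grid, enforce_filters=False)
        k = 1.5
        a2 = make_sample(cn_a * k, ploidy=2.0 * k, sample_id="a")
        b2 = make_sample(cn_b * k, ploidy=2.0 * k, sample_id="b")
        scaled = int_pair_discordance(a2, b2, toy_grid, enforce_filters=False)
        assert np.array_equal(ref.bin_status, scaled.bin_status)
        assert ref.discordant_arms == scaled.discordant_arms


class TestRerunPolicy:
    def test_converged_model_needs_no_rerun(self):
        pt = make_sample([2] * 4, ploidy=2.0, role="PT", sample_id="pt")
        pdx = make_sample([2] * 4, ploidy=2.1, role="PDX", sample_id="pdx")
        assert ploidy_rerun_policy([pt, pdx]) == []

    def test_pt_pdx_reruns_pt_at_pdx_ploidy(self):
        pt = make_sample([2] * 4, ploidy=2.0, role="PT", sample_id="pt")
        pdx = make_sample([2] * 4, ploidy=3.1, role="PDX", sample_id="pdx")
        (d,) = ploidy_rerun_policy([pt, pdx])
        assert d.sample_id == "pt"
        assert d.restricted_start_ploidy == pytest.approx(3.1)

    def test_pdx_pair_reruns_lower_tumor_fraction(self):
        p1 = make_sample([2] * 4, ploidy=2.0, tumor_fraction=0.3, sample_id="p1")
        p2 = make_sample([2] * 4, ploidy=3.0, tumor_fraction=0.6, sample_id="p2")
        (d,) = ploidy_rerun_policy([p1, p2])
        assert d.sample_id == "p1"
        assert d.restricted_start_ploidy == pytest.approx(3.0)

    def test_pdx_tie_reruns_higher_ploidy(self):
        p1 = make_sample([2] * 4, ploidy=3.0, tumor_fraction=0.5, sample_id="p1")
        p2 = make_sample([2] * 4, ploidy=2.0, tumor_fraction=0.5, sample_id="p2")
        (d,) = ploidy_rerun_policy([p1, p2])
        assert d.sample_id == "p1"

    def test_multi_sample_model_restricts_to_modal_ploidy(self):
        samples = [
            make_sample([2] * 4, ploidy=p, sample_id=f"s{i}")
            for i, p in enumerate([2.0, 2.1, 3.9])
        ]
        directives = ploidy_rerun_policy(samples)
        assert [d.sample_id for d in directives] == ["s2"]
        assert directives[0].restricted_start_ploidy == 2.0

    def test_single_sample_rejected(self):
        with pytest.raises(DiscordanceError):
            ploidy_rerun_policy([make_sample([2] * 4)])
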