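import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tgcevo import profiles as pf
from tgcevo.config import SimConfig
from tgcevo.simulate.io import simulate_all


class TestComputeLaf:
    def test_balanced(self):
        assert pf.compute_laf(50, 50) == pytest.approx(0.5)

    def test_arithmetic(self):
        assert pf.compute_laf(97, 3) == pytest.approx(0.03)

    def test_below_min_depth_is_missing(self):
        assert pf.compute_laf(5, 4) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pf.compute_laf(-1, 10)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_always_within_half(self, a, b):
        laf = pf.compute_laf(a, b, min_depth=1)
        if laf is not None:
            assert 0.0 <= laf <= 0.5


class TestAmpliconAverage:
    def test_mean(self):
        assert pf.amplicon_average([0.4, 0.5]) == pytest.approx(0.45)

    def test_identity(self):
        assert pf.amplicon_average([0.2]) == pytest.approx(0.2)

    def test_missing_excluded(self):
        assert pf.amplicon_average([0.1, None, 0.3]) == pytest.approx(0.2)

    def test_all_missing(self):
        assert pf.amplicon_average([None, float("nan")]) is None


class TestCallState:
    @pytest.mark.parametrize("laf,state", [
        (0.05, pf.LOH),
        (0.10, pf.IMBALANCE),     # boundary is strictly below
        (0.2, pf.IMBALANCE),
        (0.35, pf.BALANCED),
        (0.5, pf.BALANCED),
        (None, pf.MISSING),
    ])
    def test_thresholds(self, laf, state):
        assert pf.call_allelic_state(laf) == state

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pf.call_allelic_state(0.7)


class TestRetainedHaplotype:
    def test_majority_a(self):
        assert pf.determine_retained_haplotype(190, 10, pf.LOH) == "A"

    def test_majority_b(self):
        assert pf.determine_retained_haplotype(10, 190, pf.LOH) == "B"

    def test_non_loh_undetermined(self):
        assert pf.determine_retained_haplotype(100, 100, pf.BALANCED) \
            == pf.UNDETERMINED

    def test_tie_undetermined(self):
        assert pf.determine_retained_haplotype(5, 5, pf.LOH) == pf.UNDETERMINED


def _call(state, hap, arm="4q"):
    return pf.AllelicCall("s", arm, arm, 0.05 if state == pf.LOH else 0.4,
                          state, hap if state == pf.LOH else pf.UNDETERMINED)


class TestCompareLoh:
    def test_consistent(self):
        assert pf.compare_loh_events(_call(pf.LOH, "A"), _call(pf.LOH, "A")) \
            == pf.CONSISTENT

    def test_independent(self):
        assert pf.compare_loh_events(_call(pf.LOH, "A"), _call(pf.LOH, "B")) \
            == pf.INDEPENDENT

    def test_not_comparable(self):
        assert pf.compare_loh_events(_call(pf.LOH, "A"),
                                     _call(pf.BALANCED, None)) \
            == pf.NOT_COMPARABLE

    def test_arm_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pf.compare_loh_events(_call(pf.LOH, "A"),
                                  _call(pf.LOH, "A", arm="5p"))


class TestExpectedLaf:
    def test_examples(self):
        assert pf.expected_laf([((1, 1), 1.0)]) == pytest.approx(0.5)
        assert pf.expected_laf([((2, 0), 1.0)]) == 0.0
        assert pf.expected_laf([((1, 0), 0.8), ((1, 1), 0.2)]) \
            == pytest.approx(0.2 / 1.2)

    def test_fraction_sum_checked(self):
        with pytest.raises(ValueError):
            pf.expected_laf([((1, 1), 0.7)])

    def test_zero_copy_rejected(self):
        with pytest.raises(ValueError):
            pf.expected_laf([((0, 0), 1.0)])

    def test_monotone_in_loh_fraction(self):
        grid = np.linspace(0, 1, 21)
        vals = [pf.expected_laf([((2, 0), f), ((1, 1), 1 - f)]) for f in grid]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


def test_average_replicates():
    base = pd.DataFrame({"sample": ["s"], "amplicon": ["a1"], "arm": ["1p"],
                         "laf": [0.1], "depth": [100], "position": [5]})
    other = base.copy()
    other["laf"] = [0.3]
    avg = pf.average_replicates([base, other])
    assert avg["laf"].iloc[0] == pytest.approx(0.2)
    missing = base.copy()
    missing["laf"] = [np.nan]
    avg2 = pf.average_replicates([base, missing])
    assert avg2["laf"].iloc[0] == pytest.approx(0.1)
    ident = pf.average_replicates([base, base])
    assert ident["laf"].iloc[0] == pytest.approx(0.1)


def test_average_replicates_panel_mismatch():
    base = pd.DataFrame({"sample": ["s"], "amplicon": ["a1"], "arm": ["1p"],
                         "laf": [0.1], "depth": [100], "position": [5]})
    other = base.copy()
    other["amplicon"] = ["a2"]
    with pytest.raises(ValueError):
        pf.average_replicates([base, other])


def test_replicate_and_amplicon_averaging_commute():
    # complete data: mean over SNPs then replicates == replicates then SNPs
    rng = np.random.default_rng(0)
    lafs = rng.uniform(0, 0.5, size=(3, 4))  # replicates x SNPs
    by_amplicon_first = np.mean([np.mean(rep) for rep in lafs])
    by_replicate_first = np.mean([np.mean(lafs[:, j]) for j in range(4)])
    assert by_amplicon_first == pytest.approx(by_replicate_first)


@pytest.mark.parametrize("seed", range(8))
def test_states_match_truth_on_pure_deep_samples(seed):
    cfg = SimConfig(n_clones=5, n_samples=5, purity_range=(1.0, 1.0),
                    depth_median=100_000, depth_sigma=0.0, snv_rate=0.0,
                    n_svs=0, cna_per_edge=3.0, loh_bias=0.5,
                    seed=seed).validate()
    result = simulate_all(cfg)
    comps = {c.sample_id: c for c in result.samples}
    for comp in result.samples:
        clone = result.tree[comp.major_clone()]
        for call in pf.arm_level_calls(result.counts, comp.sample_id):
            nA, nB = clone.cn_profile[call.arm]
            if 0 in (nA, nB):
                assert call.state == pf.LOH, (call.arm, nA, nB)
                assert call.retained_haplotype == ("A" if nB == 0 else "B")
            else:
                assert call.state != pf.LOH, (call.arm, nA, nB)


def test_laf_profile_ordered_by_position():
    cfg = SimConfig(n_clones=3, n_samples=2, seed=0).validate()
    result = simulate_all(cfg)
    prof = pf.laf_profile(result.counts, "S01")
    keys = [pf.arm_sort_key(a) for a in prof["arm"]]
    assert keys == sorted(keys)
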