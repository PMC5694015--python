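"""Pattern metrics: domain calling, polarity, correlation, streak prediction."""

import itertools
import math

import numpy as np
import pytest

from axisbreak import (
    EmbryoState,
    bv_correlation,
    call_domains,
    call_domains_state,
    polarity_index,
    predict_streaks,
    summarize,
)
from axisbreak.metrics import circular_distance


def brute_force_binary_domains(profile, min_width=3, merge_gap=2):
    """Independent oracle for binary profiles: enumerate circular runs of 1s
    by doubling the string, merge across short gaps, drop narrow arcs.
    Returns a set of frozensets of member cells."""
    n = len(profile)
    if all(v == profile[0] for v in profile):
        return set()
    # mark cells above the 0.5 threshold
    above = [v > 0.5 for v in profile]
    # collect maximal circular runs
    runs = []
    for start in range(n):
        if above[start] and not above[(start - 1) % n]:
            end = start
            while above[(end + 1) % n]:
                end += 1
            runs.append((start, end))  # end may exceed n-1 (wraps)
    # merge runs separated by <= merge_gap zeros (circularly), iterate to fixpoint
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for a, b in itertools.combinations(range(len(runs)), 2):
            s1, e1 = runs[a]
            s2, e2 = runs[b]
            gap12 = (s2 - e1 - 1) % n
            gap21 = (s1 - e2 - 1) % n
            if gap12 <= merge_gap:
                runs[a] = (s1, s1 + (e2 - s1) % n)
                runs.pop(b)
                changed = True
                break
            if gap21 <= merge_gap:
                runs[b] = (s2, s2 + (e1 - s2) % n)
                runs.pop(a)
                changed = True
                break
    out = set()
    for s, e in runs:
        width = (e - s) % n + 1
        if width >= min_width:
            out.add(frozenset((s + j) % n for j in range(width)))
    return out


class TestCallDomains:
    def test_uniform_profile_has_no_domains(self):
        assert call_domains(np.ones(20)) == []
        assert call_domains(np.zeros(20)) == []

    def test_single_block(self):
        profile = np.zeros(30)
        profile[5:15] = 1.0
        doms = call_domains(profile, threshold_frac=0.5)
        assert len(doms) == 1
        assert doms[0].start == 5 and doms[0].end == 14
        assert doms[0].peak == 1.0

    def test_two_antipodal_blocks(self):
        profile = np.zeros(40)
        profile[0:6] = 1.0
        profile[20:26] = 1.0
        doms = call_domains(profile)
        assert len(doms) == 2
        sep = circular_distance(doms[0].centroid, doms[1].centroid)
        assert sep == pytest.approx(math.pi, abs=2 * math.pi / 40)

    def test_wrapped_block(self):
        profile = np.zeros(20)
        profile[18:] = 1.0
        profile[:3] = 1.0
        doms = call_domains(profile)
        assert len(doms) == 1
        assert doms[0].width == 5
        assert doms[0].start == 18 and doms[0].end == 2

    def test_narrow_arcs_dropped_and_gaps_merged(self):
        profile = np.zeros(30)
        profile[2:4] = 1.0            # width 2 < min_width -> dropped
        doms = call_domains(profile, min_width=3)
        assert doms == []
        profile = np.zeros(30)
        profile[5:9] = 1.0
        profile[11:15] = 1.0          # gap of 2 -> merged
        doms = call_domains(profile, merge_gap=2)
        assert len(doms) == 1
        assert doms[0].width == 10

    def test_flatness_rule(self):
        profile = 1.0 + 0.02 * np.sin(np.linspace(0, 2 * np.pi, 50, endpoint=False))
        assert call_domains(profile) == []

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            call_domains(np.array([]))
        with pytest.raises(ValueError):
            call_domains(np.ones(10), threshold_frac=1.5)

    def test_matches_brute_force_on_all_binary_profiles(self):
        """Exhaustive check against an independent enumeration oracle for
        every binary circular profile of length 8 and a sample of length 12."""
        for n, profiles in ((8, itertools.product([0, 1], repeat=8)),
                            (12, (tuple((s >> i) & 1 for i in range(12))
                                  for s in range(0, 4096, 7)))):
            for profile in profiles:
                arr = np.array(profile, dtype=float)
                got = {frozenset(d.indices().tolist())
                       for d in call_domains(arr, min_width=3, merge_gap=2)}
                want = brute_force_binary_domains(list(profile))
                assert got == want, f"profile {profile}"

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        profile = np.zeros(24)
        profile[3:9] = rng.uniform(1, 2, 6)
        base = call_domains(profile)
        for k in (5, 11):
            rot = call_domains(np.roll(profile, k))
            assert len(rot) == len(base)
            assert rot[0].width == base[0].width
            expect = (base[0].centroid + 2 * np.pi * k / 24) % (2 * np.pi)
            assert circular_distance(rot[0].centroid, expect) < 1e-9

    def test_scale_invariance(self):
        profile = np.zeros(30)
        profile[4:12] = np.linspace(1, 2, 8)
        a = call_domains(profile)
        b = call_domains(profile * 37.5)
        assert [(d.start, d.end) for d in a] == [(d.start, d.end) for d in b]


class TestPolarityIndex:
    def test_uniform_is_zero(self):
        assert polarity_index(np.ones(36)) == pytest.approx(0.0, abs=1e-12)

    def test_one_plus_cosine_is_half(self):
        theta = 2 * np.pi * np.arange(100) / 100
        assert polarity_index(1 + np.cos(theta)) == pytest.approx(0.5, abs=1e-12)

    def test_point_mass_is_one(self):
        profile = np.zeros(50)
        profile[13] = 4.2
        assert polarity_index(profile) == pytest.approx(1.0)

    def test_invariances(self):
        rng = np.random.default_rng(1)
        profile = rng.uniform(0, 1, 40)
        base = polarity_index(profile)
        assert polarity_index(profile * 7.7) == pytest.approx(base)
        assert polarity_index(np.roll(profile, 9)) == pytest.approx(base)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            polarity_index(np.zeros(10))


class TestBVCorrelation:
    def test_identical_profiles(self):
        theta = 2 * np.pi * np.arange(30) / 30
        v = 1 + np.cos(theta)
        state = EmbryoState(v, v.copy(), v.copy(), v.copy())
        assert bv_correlation(state) == pytest.approx(1.0)

    def test_antiphase(self):
        theta = 2 * np.pi * np.arange(30) / 30
        state = EmbryoState(1 + np.cos(theta), 1 - np.cos(theta),
                            np.ones(30), np.ones(30))
        assert bv_correlation(state) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        state = EmbryoState(np.ones(10), np.arange(10, dtype=float),
                            np.ones(10), np.ones(10))
        with pytest.raises(ValueError):
            bv_correlation(state)


class TestStreaksAndSummary:
    def test_no_v_no_streaks(self):
        theta = 2 * np.pi * np.arange(30) / 30
        state = EmbryoState(1 + np.cos(theta), np.zeros(30), np.ones(30), np.zeros(30))
        count, angles = predict_streaks(state, absolute_V_threshold=0.5)
        assert count == 0 and angles == []

    def test_streak_threshold_is_absolute(self):
        profile = np.zeros(40)
        profile[10:18] = 0.3          # below absolute threshold 0.5
        state = EmbryoState(np.zeros(40), profile, np.zeros(40), profile)
        count, _ = predict_streaks(state, absolute_V_threshold=0.5)
        assert count == 0
        count, angles = predict_streaks(state, absolute_V_threshold=0.2)
        assert count == 1

    def test_bipolar_classification(self):
        n = 60
        theta = 2 * np.pi * np.arange(n) / n
        B = np.clip(np.cos(theta), 0, None)
        V = np.clip(-np.cos(theta), 0, None)
        state = EmbryoState(B, V, B.copy(), V.copy())
        s = summarize(state, absolute_V_threshold=0.4)
        assert s.classification == "bipolar"
        assert s.centroid_separation == pytest.approx(math.pi, abs=0.1)
        assert s.bv_corr < -0.5
        assert s.predicted_streak_count == 1

    def test_uniform_classification(self):
        state = EmbryoState.homogeneous(30, (1.0, 1.0, 1.0, 1.0))
        s = summarize(state, absolute_V_threshold=0.5)
        assert s.classification == "uniform"

    def test_fragmented_domains_do_not_span_cuts(self):
        profile = np.zeros(40)
        profile[18:23] = 1.0          # block straddling a cut at 20
        state = EmbryoState(np.zeros(40), profile, np.zeros(40), profile,
                            cuts=(0, 20))
        doms = call_domains_state(state, "V", min_width=2)
        assert len(doms) == 2
        assert {d.width for d in doms} == {2, 3}
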