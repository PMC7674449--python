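import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbfmrd.fusion_mrd import (FusionJunction, NoJunctionFoundError,
                               canonical_breakpoint, count_junction_reads,
                               detection_limit, detection_probability,
                               discover_junction, log_reduction, quantify,
                               reverse_complement)

RNG = np.random.default_rng(7)
FIVE = "".join(RNG.choice(list("ACGT"), 400))
THREE = "".join(RNG.choice(list("ACGT"), 400))
BP_I, BP_J = canonical_breakpoint(FIVE, THREE, 200, 120)
FUSION = FIVE[:BP_I] + THREE[BP_J:]


def _spanning_reads(n, read_len=100, anchor=10, rng=None, error=0.0):
    rng = rng or np.random.default_rng(0)
    reads = []
    for _ in range(n):
        s = int(rng.integers(BP_I - (read_len - anchor), BP_I - anchor + 1))
        seq = list(FUSION[s : s + read_len])
        if error > 0:
            for k in range(len(seq)):
                if rng.random() < error:
                    seq[k] = rng.choice([b for b in "ACGT" if b != seq[k]])
        reads.append("".join(seq))
    return reads


class TestDiscovery:
    def test_planted_junction_recovered_exactly(self):
        reads = _spanning_reads(10)
        j = discover_junction(reads, FIVE, THREE)
        assert j.breakpoint == (BP_I, BP_J)
        assert j.support == 10

    def test_reads_without_junction_fail_explicitly(self):
        rng = np.random.default_rng(1)
        reads = [FIVE[s : s + 100]
                 for s in rng.integers(0, len(FIVE) - 100, size=30)]
        with pytest.raises(NoJunctionFoundError):
            discover_junction(reads, FIVE, THREE)

    def test_recovery_robust_to_one_percent_error(self):
        reads = _spanning_reads(30, rng=np.random.default_rng(3), error=0.01)
        j = discover_junction(reads, FIVE, THREE)
        assert j.breakpoint == (BP_I, BP_J)

    def test_reverse_complement_reads_are_found(self):
        reads = [reverse_complement(r) for r in _spanning_reads(5)]
        j = discover_junction(reads, FIVE, THREE)
        assert j.breakpoint == (BP_I, BP_J)
        assert j.support == 5

    def test_min_support_enforced(self):
        reads = _spanning_reads(1)
        with pytest.raises(NoJunctionFoundError):
            discover_junction(reads, FIVE, THREE, min_support=2)


def _junction():
    return FusionJunction(patient_id="p", five_prime_gene="A", three_prime_gene="B",
                          five_context=FIVE[BP_I - 20 : BP_I],
                          three_context=THREE[BP_J : BP_J + 20],
                          breakpoint=(BP_I, BP_J), support=10)


def _brute_force_count(reads, kmer, max_mm):
    """Independent oracle: all-window Hamming scan on both strands."""
    k = len(kmer)
    n = 0
    for read in reads:
        found = False
        for seq in (read, reverse_complement(read)):
            for off in range(len(seq) - k + 1):
                if sum(a != b for a, b in zip(seq[off : off + k], kmer)) <= max_mm:
                    found = True
                    break
            if found:
                break
        n += found
    return n


class TestCounting:
    def test_exact_kmer_counted(self):
        j = _junction()
        reads = ["T" * 30 + j.junction_kmer + "A" * 30] * 3
        assert count_junction_reads(reads, j, max_mismatch=0) == 3

    def test_two_mismatches_rejected_at_max_one(self):
        j = _junction()
        kmer = list(j.junction_kmer)
        kmer[3] = {"A": "C"}.get(kmer[3], "A")
        kmer[10] = {"A": "C"}.get(kmer[10], "A")
        read = "T" * 30 + "".join(kmer) + "A" * 30
        assert count_junction_reads([read], j, max_mismatch=1) == 0

    def test_one_mismatch_accepted(self):
        j = _junction()
        kmer = list(j.junction_kmer)
        kmer[3] = {"A": "C"}.get(kmer[3], "A")
        read = "T" * 30 + "".join(kmer) + "A" * 30
        assert count_junction_reads([read], j, max_mismatch=1) == 1

    def test_empty_read_set_counts_zero(self):
        assert count_junction_reads([], _junction()) == 0

    def test_planted_five_among_wildtype(self):
        rng = np.random.default_rng(11)
        j = _junction()
        reads = _spanning_reads(5, rng=rng)
        for _ in range(995):
            src = FIVE if rng.random() < 0.5 else THREE
            s = int(rng.integers(0, len(src) - 100))
            reads.append(src[s : s + 100])
        rng.shuffle(reads)
        assert count_junction_reads(reads, j) == 5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        j = _junction()
        reads = []
        for _ in range(200):
            kind = rng.random()
            if kind < 0.3:
                reads.append(_spanning_reads(1, rng=rng, error=0.02)[0])
            else:
                src = FIVE if kind < 0.65 else THREE
                s = int(rng.integers(0, len(src) - 80))
                reads.append(src[s : s + 80])
        for mm in (0, 1):
            assert count_junction_reads(reads, j, mm) == \
                _brute_force_count(reads, j.junction_kmer, mm)


class TestQuantAndReduction:
    def test_rpm_hand_arithmetic(self):
        assert quantify(1618, 3_010_000).rpm == pytest.approx(537.54, abs=0.01)
        assert quantify(239, 3_010_000).rpm == pytest.approx(79.40, abs=0.01)
        assert quantify(0, 1_000_000).rpm == 0.0

    def test_log_reduction_hand_example(self):
        dx = quantify(1618, 3_010_000)
        cr = quantify(2, 2_920_000, timepoint="CR")
        call = log_reduction(dx, cr)
        assert call.log_reduction == pytest.approx(2.895, abs=0.005)
        assert not call.censored and not call.achieved_3log
        assert call.detectable_at_cr

    def test_identical_samples_give_zero_reduction(self):
        dx = quantify(100, 1_000_000)
        cr = quantify(100, 1_000_000, timepoint="CR")
        assert log_reduction(dx, cr).log_reduction == 0.0

    def test_censored_zero_cr_reports_lod_bound(self):
        dx = quantify(1618, 3_010_000)
        cr = quantify(0, 2_920_000, timepoint="CR")
        call = log_reduction(dx, cr)
        assert call.censored and call.achieved_3log and not call.indeterminate
        assert call.log_reduction == pytest.approx(3.196, abs=0.002)
        assert call.report().startswith(">=")

    def test_indeterminate_when_lod_below_threshold(self):
        dx = quantify(239, 3_010_000)
        cr = quantify(0, 2_920_000, timepoint="CR")
        call = log_reduction(dx, cr)
        assert call.censored and call.indeterminate and not call.achieved_3log

    def test_zero_diagnosis_raises(self):
        with pytest.raises(ValueError, match="not quantifiable"):
            log_reduction(quantify(0, 1_000_000), quantify(0, 1_000_000))

    @given(scale=st.integers(2, 1000), jr=st.integers(1, 500),
           cr_r=st.integers(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, jr, cr_r):
        """Multiplying junction and mapped reads by a constant preserves
        the log reduction."""
        a = log_reduction(quantify(jr, 10_000), quantify(cr_r, 10_000))
        b = log_reduction(quantify(jr * scale, 10_000 * scale),
                          quantify(cr_r * scale, 10_000 * scale))
        assert a.log_reduction == pytest.approx(b.log_reduction, rel=1e-12)

    def test_monotone_in_cr_reads(self):
        dx = quantify(1000, 1_000_000)
        reds = [log_reduction(dx, quantify(c, 1_000_000)).log_reduction
                for c in (1, 2, 5, 10, 100)]
        assert all(a > b for a, b in zip(reds, reds[1:]))


class TestDetectionLimit:
    def test_published_worked_examples(self):
        dx = quantify(1618, 3_010_000)
        lod = detection_limit(dx, 2_920_000)
        assert lod == pytest.approx(3.196, abs=0.002)
        assert math.floor(lod) == 3
        dx2 = quantify(239, 3_010_000)
        lod2 = detection_limit(dx2, 2_920_000)
        assert lod2 == pytest.approx(2.365, abs=0.002)
        assert math.floor(lod2) == 2

    def test_powers_of_ten(self):
        assert detection_limit(quantify(1000, 1_000_000), 1_000_000) == pytest.approx(3.0)

    def test_detection_probability_closed_forms(self):
        assert detection_probability(0.0) == 0.0
        assert detection_probability(1.618) == pytest.approx(0.8017, abs=2e-4)
        assert detection_probability(math.log(2)) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            detection_probability(-0.1)
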