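import numpy as np
import pytest

from abekit.amplicon_quant import (
    QuantWindow,
    align_read,
    allele_table,
    classify_read,
    fit_dose_response,
    net_editing,
    summarize,
)
from abekit.seqcore import revcomp

NEG = -(10**9)


def _gotoh_best_score(x: str, y: str, match=2, mismatch=-1, open_=-5, extend=-1):
    """Exhaustive affine-gap DP oracle: best score of an alignment with free
    end gaps on both sequences (independent of the implementation's aligner)."""
    n, m = len(x), len(y)
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if x[i - 1] == y[j - 1] else mismatch
            D[i][j] = s + max(D[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0)
            Ix[i][j] = max(D[i - 1][j] + open_, Ix[i - 1][j] + extend, Iy[i - 1][j] + open_)
            Iy[i][j] = max(D[i][j - 1] + open_, Iy[i][j - 1] + extend, Ix[i][j - 1] + open_)
            best = max(best, D[i][j])
    return best


def _mutate(read, rng, n_sub=0, del_span=None):
    read = list(read)
    for p in rng.choice(len(read), size=n_sub, replace=False):
        read[p] = rng.choice([b for b in "ACGT" if b != read[p]])
    if del_span:
        start, length = del_span
        del read[start : start + length]
    return "".join(read)


class TestAlignRead:
    def test_identical_read_has_full_identity(self, pah):
        aln = align_read(pah.context, pah.context)
        assert aln.identity == 1.0
        assert aln.read_base_at_ref == list(pah.context)

    def test_single_substitution_is_one_mismatch_column(self, pah):
        read = _mutate(pah.context, np.random.default_rng(0), n_sub=1)
        aln = align_read(read, pah.context)
        diffs = [
            p for p, b in enumerate(aln.read_base_at_ref) if b != pah.context[p]
        ]
        assert len(diffs) == 1 and aln.read_base_at_ref[diffs[0]] in "ACGT"

    def test_two_nt_deletion_recovered_as_one_gap(self, pah):
        read = _mutate(pah.context, np.random.default_rng(0), del_span=(20, 2))
        aln = align_read(read, pah.context)
        gaps = [p for p, b in enumerate(aln.read_base_at_ref) if b == "-"]
        assert len(gaps) == 2 and gaps[1] == gaps[0] + 1

    @pytest.mark.parametrize("seed", range(8))
    def test_score_is_optimal_against_dp_oracle(self, pah, seed):
        rng = np.random.default_rng(seed)
        n_sub = int(rng.integers(0, 3))
        del_span = (int(rng.integers(5, 30)), int(rng.integers(1, 4))) if rng.random() < 0.5 else None
        read = _mutate(pah.context, rng, n_sub=n_sub, del_span=del_span)
        if rng.random() < 0.5:
            read = revcomp(read)
        aln = align_read(read, pah.context)
        oracle = max(
            _gotoh_best_score(pah.context, read),
            _gotoh_best_score(pah.context, revcomp(read)),
        )
        assert aln.score == oracle

    def test_empty_input_rejected(self, pah):
        with pytest.raises(ValueError):
            align_read("", pah.context)


def _read_with(pah, offsets, dele=None):
    hap = list(pah.context)
    for off in offsets:
        assert hap[off] == "T"
        hap[off] = "C"
    if dele:
        del hap[dele[0] : dele[0] + dele[1]]
    return "".join(hap)


class TestClassifyRead:
    def test_correction_only(self, pah, pah_window):
        read = _read_with(pah, [pah.variant_offset])
        cl = classify_read(align_read(read, pah.context), pah, pah_window)
        assert cl.category == "correction_only"
        assert cl.edited_offsets == {pah.variant_offset}

    def test_synonymous_coedit_stays_correction_only(self, pah, pah_window):
        read = _read_with(pah, [pah.variant_offset, pah.sense_offset_of(1)])
        cl = classify_read(align_read(read, pah.context), pah, pah_window)
        assert cl.category == "correction_only"

    def test_nonsynonymous_coedit_is_unwanted(self, pah, pah_window):
        read = _read_with(pah, [pah.variant_offset, pah.sense_offset_of(5)])
        cl = classify_read(align_read(read, pah.context), pah, pah_window)
        assert cl.category == "unwanted_bystander"

    def test_unedited_patient_read(self, pah, pah_window):
        cl = classify_read(align_read(pah.context, pah.context), pah, pah_window)
        assert cl.category == "unedited"

    def test_bystander_without_correction(self, pah, pah_window):
        read = _read_with(pah, [pah.sense_offset_of(5)])
        cl = classify_read(align_read(read, pah.context), pah, pah_window)
        assert cl.category == "bystander_only"

    def test_gap_in_window_is_indel(self, pah, pah_window):
        read = _read_with(pah, [], dele=(pah.variant_offset - 2, 2))
        cl = classify_read(align_read(read, pah.context), pah, pah_window)
        assert cl.category == "indel"

    def test_orientation_invariance(self, pah, pah_window):
        for offsets in ([pah.variant_offset], [pah.sense_offset_of(5)], []):
            read = _read_with(pah, offsets)
            fwd = classify_read(align_read(read, pah.context), pah, pah_window)
            rev = classify_read(align_read(revcomp(read), pah.context), pah, pah_window)
            assert (fwd.category, fwd.edited_offsets) == (rev.category, rev.edited_offsets)

    def test_garbage_read_is_discarded(self, pah, pah_window):
        cl = classify_read(align_read("G" * 45, pah.context), pah, pah_window)
        assert cl.category == "discarded"

    def test_read_not_covering_window_is_discarded(self, pah, pah_window):
        cl = classify_read(align_read(pah.context[:10], pah.context), pah, pah_window)
        assert cl.category == "discarded" and cl.reason == "window_uncovered"


class TestSummarize:
    def _classify_all(self, pah, pah_window, reads):
        return [
            classify_read(align_read(r, pah.context, read_id=str(i)), pah, pah_window)
            for i, r in enumerate(reads)
        ]

    def test_all_unedited(self, pah, pah_window):
        s = summarize(self._classify_all(pah, pah_window, [pah.context] * 100))
        assert s.proportions["unedited"] == 1.0 and not s.empty

    def test_planted_mixture_recovered_exactly(self, pah, pah_window):
        corrected = _read_with(pah, [pah.variant_offset])
        unwanted = _read_with(pah, [pah.variant_offset, pah.sense_offset_of(5)])
        reads = [corrected] * 60 + [unwanted] * 25 + [pah.context] * 15
        s = summarize(self._classify_all(pah, pah_window, reads))
        assert s.proportions["correction_only"] == 0.60
        assert s.proportions["unwanted_bystander"] == 0.25
        assert s.proportions["unedited"] == 0.15
        assert s.overall_corrective == pytest.approx(0.85)

    def test_proportions_sum_to_one_and_counts_conserved(self, pah, pah_window):
        reads = [pah.context] * 5 + [_read_with(pah, [pah.variant_offset])] * 5 + ["G" * 45]
        cls = self._classify_all(pah, pah_window, reads)
        s = summarize(cls)
        assert sum(s.counts.values()) == len(reads) == s.n_total
        assert sum(s.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_discarded_gives_empty_signal(self, pah, pah_window):
        s = summarize(self._classify_all(pah, pah_window, ["G" * 45] * 4))
        assert s.empty and s.proportions == {} and s.n_discarded == 4


class TestAlleleTable:
    def _table(self, pah, pah_window, reads):
        alns = [align_read(r, pah.context, read_id=str(i)) for i, r in enumerate(reads)]
        cls = [classify_read(a, pah, pah_window) for a in alns]
        return allele_table(cls, alns, pah, pah_window)

    def test_single_haplotype(self, pah, pah_window):
        df = self._table(pah, pah_window, [pah.context] * 7)
        assert len(df) == 1 and df.frequency.iloc[0] == 1.0
        assert df.amino_acids.iloc[0] == "reference"

    def test_rank_order_and_frequencies(self, pah, pah_window):
        corrected = _read_with(pah, [pah.variant_offset])
        df = self._table(pah, pah_window, [corrected] * 70 + [pah.context] * 30)
        assert list(df["count"]) == [70, 30]
        assert df.frequency.iloc[0] == pytest.approx(0.7)

    def test_corrected_haplotype_renders_trp_to_arg_at_408(self, pah, pah_window):
        corrected = _read_with(pah, [pah.variant_offset])
        df = self._table(pah, pah_window, [corrected] * 3)
        assert df.amino_acids.iloc[0] == "W408R"


class TestNetEditing:
    def test_equal_arms_give_zero(self):
        assert net_editing([0.01, 0.01], [0.01, 0.01]) == 0.0

    def test_arithmetic(self):
        assert net_editing([0.002, 0.003], [0.001, 0.001]) == pytest.approx(0.0015)

    def test_floored_at_zero(self):
        assert net_editing([0.001], [0.005]) == 0.0

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            net_editing([], [0.1])


class TestDoseResponse:
    doses = 10000 / 3.0 ** np.arange(8)

    @staticmethod
    def _truth(d, floor=0.0, ceiling=80.0, hill=1.0, ec50=750.0):
        return floor + (ceiling - floor) / (1.0 + (ec50 / d) ** hill)

    def test_noiseless_recovery(self):
        fit = fit_dose_response(self.doses, self._truth(self.doses))
        assert fit.success
        assert fit.ec50 == pytest.approx(750.0, rel=1e-6)
        assert fit.ceiling == pytest.approx(80.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(42)
        d = np.repeat(self.doses, 3)
        fit = fit_dose_response(d, self._truth(d) + rng.normal(0, 2, d.size))
        assert fit.success
        assert abs(fit.ec50 - 750.0) / 750.0 < 0.10

    def test_constant_responses_fail_with_diagnostic(self):
        fit = fit_dose_response(self.doses, np.full(8, 40.0))
        assert not fit.success and "degenerate" in fit.message

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([1, 10, 100], [0, 1, 2])

    def test_nonpositive_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([0, 1, 10, 100], [0, 1, 2, 3])


def test_quant_window_from_guide(pah, pah4_guide):
    w = QuantWindow.from_guide(pah4_guide, len(pah.context), flank=5)
    assert w.start == pah4_guide.sense_start - 5
    assert w.end == pah4_guide.sense_end + 5
    assert pah.variant_offset in w
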