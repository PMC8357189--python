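"""Quantifier tests: variant masking, conversion counting, labeled calling, rates."""

import numpy as np
import pandas as pd
import pytest

import slamwaves as sw
from slamwaves.slamquant import CONVERSION_BY_STRAND

from conftest import make_window, manual_reference


def brute_force_counts(read: str, ref: str, strand: str,
                       masked: set[int]) -> tuple[int, int, int]:
    """Independent per-base double loop: the conversion-counting oracle."""
    conv_ref = "T" if strand == "+" else "A"
    conv_alt = "C" if strand == "+" else "G"
    n_t = n_tc = n_other = 0
    for i, (rb, xb) in enumerate(zip(read, ref)):
        if i in masked or rb == "\0":
            continue
        if xb == conv_ref:
            n_t += 1
            if rb == conv_alt:
                n_tc += 1
            elif rb != xb:
                n_other += 1
        elif rb != xb:
            n_other += 1
    return n_t, n_tc, n_other


def _reads_from_strings(seqs, window):
    mat = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    return sw.WindowReads([f"r{i}" for i in range(len(seqs))], mat)


class TestVariantMask:
    def _run(self, seqs, ref_seq, threshold=0.2, min_cov=10):
        w = make_window(length=len(ref_seq))
        ref = manual_reference(ref_seq)
        rs = sw.AlignedReadSet("s1", {"g1": _reads_from_strings(seqs, w)})
        cfg = sw.QuantConfig(variant_fraction_threshold=threshold,
                             min_coverage_for_variant_call=min_cov)
        return sw.detect_variants([rs], ref, [w], cfg)

    def test_fully_altered_position_masked(self):
        ref_seq = "ACGT" * 15
        seqs = ["A" + "CGT" + "ACGT" * 14] * 12  # position 1 C->A in all reads
        seqs = [s[:1] + "A" + s[2:] for s in [ref_seq] * 12]
        mask = self._run(seqs, ref_seq)
        assert mask.masked["g1"][1]
        assert mask.positions() == {("chr1", 1)}

    @pytest.mark.parametrize("n_alt,expect_masked", [(19, False), (20, True)])
    def test_threshold_is_inclusive_at_exactly_0_2(self, n_alt, expect_masked):
        # 100 reads, n_alt carry the mismatch: fraction 0.19 vs 0.20
        ref_seq = "ACGT" * 20
        alt = ref_seq[:4] + "G" + ref_seq[5:]
        seqs = [alt] * n_alt + [ref_seq] * (100 - n_alt)
        mask = self._run(seqs, ref_seq)
        assert bool(mask.masked["g1"][4]) is expect_masked

    def test_coverage_gate(self):
        ref_seq = "ACGT" * 20
        alt = ref_seq[:4] + "G" + ref_seq[5:]
        mask = self._run([alt] * 5, ref_seq, min_cov=10)
        assert not mask.masked["g1"].any()

    def test_empty_reads_warn_and_empty_mask(self):
        w = make_window(length=60)
        with pytest.warns(UserWarning, match="empty read set"):
            mask = sw.detect_variants([], manual_reference("A" * 60), [w])
        assert not mask.masked["g1"].any()

    def test_planted_snps_recovered_exactly(self):
        """Sensitivity 1.0 and zero false positives at p_err=0, depth >= 10."""
        cfg = sw.SimConfig(n_genes=40, p_err=0.0, snp_fraction=0.3,
                           mean_depth=60, seed=21)
        truth = sw.simulate_timecourse(cfg)
        reads = sw.simulate_reads(truth, ["induced_0h_r1", "induced_4h_r1"])
        mask = sw.detect_variants(reads, truth.reference.contigs,
                                  truth.reference.windows)
        assert mask.positions() == truth.snp_positions

    def test_mask_independent_of_sample_order(self, study):
        readsets = list(study["reads"].values())
        fwd = sw.detect_variants(readsets, study["truth"].reference.contigs,
                                 study["windows"])
        rev = sw.detect_variants(readsets[::-1],
                                 study["truth"].reference.contigs,
                                 study["windows"])
        assert fwd.positions() == rev.positions()


class TestCountConversions:
    def test_reference_identical_read(self):
        ref_seq = "TTACGTTA" * 6
        w = make_window(length=len(ref_seq))
        counts = sw.count_conversions(ref_seq, w, manual_reference(ref_seq))
        assert counts == (ref_seq.count("T"), 0, 0)

    def test_two_conversions_counted(self):
        ref_seq = "TTAAGGCC" * 4
        read = "CCAAGGCC" + ref_seq[8:]   # both leading Ts read as C
        w = make_window(length=len(ref_seq))
        assert sw.count_conversions(read, w, manual_reference(ref_seq)) == \
            (ref_seq.count("T"), 2, 0)

    def test_minus_strand_counts_a_to_g(self):
        ref_seq = "AATTCCGG" * 4
        read = "GGTTCCGG" + ref_seq[8:]   # two reference As read as G
        w = make_window(length=len(ref_seq), strand="-")
        n_t, n_tc, n_other = sw.count_conversions(read, w,
                                                  manual_reference(ref_seq))
        assert (n_t, n_tc, n_other) == (ref_seq.count("A"), 2, 0)

    def test_read_outside_window_errors(self):
        w = make_window(length=20)
        with pytest.raises(ValueError, match="g1"):
            sw.count_conversions("A" * 30, w, manual_reference("A" * 20))

    def test_matches_brute_force_on_simulated_reads(self, study):
        """Oracle equivalence on >1000 simulated reads, exactly."""
        truth, mask = study["truth"], study["mask"]
        ref = truth.reference
        by_id = {g.gene_id: g for g in truth.genes}
        checked = 0
        for sid in ("induced_0.5h_r1", "control_8h_r2"):
            rs = study["reads"][sid]
            for gid, wr in rs.windows.items():
                g = by_id[gid]
                w = g.window
                ref_seq = ref.contigs[g.contig][g.window_start:g.window_end]
                masked = set(np.flatnonzero(mask.masked[gid]))
                prof = sw.quantify_window(wr, w, ref.contigs, mask)
                for i in range(wr.matrix.shape[0]):
                    read = wr.matrix[i].tobytes().decode()
                    expect = brute_force_counts(read,
                                                ref_seq.tobytes().decode(),
                                                g.strand, masked)
                    got = sw.count_conversions(wr.matrix[i], w, ref.contigs,
                                               mask)
                    assert got == expect
                    assert prof.per_read_conversions[i] == expect[1]
                    checked += 1
                if checked > 1200:
                    return
        assert checked > 1000

    def test_strand_flip_leaves_counts_unchanged(self):
        """Reverse-complementing a window and flipping strand preserves counts."""
        rng = np.random.default_rng(0)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        ref_fwd = bases[rng.integers(0, 4, 80)]
        comp = {65: 84, 84: 65, 67: 71, 71: 67}
        read_fwd = ref_fwd.copy()
        tpos = np.flatnonzero(ref_fwd == ord("T"))[:3]
        read_fwd[tpos] = ord("C")          # three T>C conversions, plus strand
        rc = np.array([comp[b] for b in ref_fwd[::-1]], dtype=np.uint8)
        read_rc = np.array([comp[b] for b in read_fwd[::-1]], dtype=np.uint8)
        w_fwd = make_window(length=80, strand="+")
        w_rev = make_window(length=80, strand="-")
        fwd = sw.count_conversions(read_fwd, w_fwd, {"chr1": ref_fwd})
        rev = sw.count_conversions(read_rc, w_rev, {"chr1": rc})
        assert fwd == rev == (len(np.flatnonzero(ref_fwd == ord("T"))), 3, 0)


class TestClassifyRead:
    @pytest.mark.parametrize("n_tc,labeled", [(0, False), (1, False),
                                              (2, True), (5, True)])
    def test_labeled_threshold_boundary(self, n_tc, labeled):
        assert sw.classify_read((30, n_tc, 0)) is labeled

    def test_masked_snp_conversion_not_counted(self):
        # conversion at a masked SNP plus one genuine one -> only 1 counted
        ref_seq = "TTAAGGCC" * 4
        w = make_window(length=len(ref_seq))
        ref = manual_reference(ref_seq)
        mask = sw.VariantMask(
            {"g1": np.array([True] + [False] * 31)},
            pd.DataFrame([{"contig": "chr1", "position": 0, "gene_id": "g1",
                           "coverage": 50, "mismatch_fraction": 1.0}]))
        read = "CCAAGGCC" + ref_seq[8:]   # conversions at offsets 0 (masked), 1
        counts = sw.count_conversions(read, w, ref, mask)
        assert counts[1] == 1
        assert not sw.classify_read(counts)

    def test_raising_threshold_never_increases_labeled_counts(self, study):
        truth, mask = study["truth"], study["mask"]
        prev = None
        for k in (1, 2, 3):
            cfg = sw.QuantConfig(min_conversions_labeled=k)
            counts = sw.build_count_matrix(
                {"induced_8h_r1": study["reads"]["induced_8h_r1"]},
                study["sheet"].query("sample_id == 'induced_8h_r1'"),
                study["windows"], truth.reference.contigs, mask, cfg)
            if prev is not None:
                assert (counts.labeled.to_numpy()
                        <= prev.labeled.to_numpy()).all()
            prev = counts


class TestUtrRate:
    def test_reference_identical_reads_rate_zero(self):
        ref_seq = "TACG" * 20
        w = make_window(length=80)
        wr = _reads_from_strings([ref_seq] * 10, w)
        assert sw.utr_conversion_rate(wr, w, manual_reference(ref_seq)) == 0.0

    def test_no_qualifying_positions_is_missing_not_zero(self):
        ref_seq = "ACGC" * 20  # no T at all on the plus strand
        w = make_window(length=80)
        wr = _reads_from_strings([ref_seq] * 5, w)
        assert np.isnan(sw.utr_conversion_rate(wr, w,
                                               manual_reference(ref_seq)))

    def test_pure_labeled_rate_recovers_p_conv(self):
        cfg = sw.SimConfig(n_genes=30, p_err=0.0, snp_fraction=0.0,
                           base_labeled_fraction=1.0, mean_depth=200, seed=31)
        truth = sw.simulate_timecourse(cfg)
        rs = sw.simulate_sample_reads(truth, "control_0h_r1")
        rates, weights = [], []
        for g in truth.genes:
            wr = rs.windows.get(g.gene_id)
            if wr is None:
                continue
            rates.append(sw.utr_conversion_rate(wr, g.window,
                                                truth.reference.contigs))
            weights.append(g.t_count * wr.matrix.shape[0])
        mean_rate = float(np.average(rates, weights=weights))
        n_obs = sum(weights)
        se = np.sqrt(0.025 * 0.975 / n_obs)
        assert abs(mean_rate - 0.025) < 3 * se

    def test_labeled_vs_no_label_regime(self):
        """After variant masking, labeled samples land in the 1.5-3.5% band
        while a no-label control stays below 0.15%."""
        import dataclasses

        def masked_rates(cfg):
            truth = sw.simulate_timecourse(cfg)
            rs = sw.simulate_sample_reads(truth, "induced_0h_r1")
            mask = sw.detect_variants([rs], truth.reference.contigs,
                                      truth.reference.windows)
            return [sw.utr_conversion_rate(rs.windows[g.gene_id], g.window,
                                           truth.reference.contigs, mask)
                    for g in truth.genes if g.gene_id in rs.windows]

        cfg = sw.SimConfig(n_genes=40, mean_depth=150, seed=32)
        assert 0.015 < np.mean(masked_rates(cfg)) < 0.035
        unlabeled = dataclasses.replace(cfg, base_labeled_fraction=0.0)
        assert np.mean(masked_rates(unlabeled)) < 0.0015


class TestCountMatrix:
    def test_all_labeled_when_threshold_zero_conversions_not_required(self):
        # a sample where every read qualifies: labeled == total
        cfg = sw.QuantConfig(min_conversions_labeled=1)
        ref_seq = "TTTT" * 20
        w = make_window(length=80)
        read = "CC" + ref_seq[2:]
        wr = _reads_from_strings([read] * 7, w)
        sheet = pd.DataFrame([{"sample_id": "s1", "arm": "induced",
                               "time_h": 0.0, "replicate": 1}])
        counts = sw.build_count_matrix(
            {"s1": sw.AlignedReadSet("s1", {"g1": wr})}, sheet, [w],
            manual_reference(ref_seq), None, cfg)
        assert counts.labeled.loc["g1", "s1"] == counts.total.loc["g1", "s1"] == 7

    def test_column_sums_conserve_read_totals(self, study):
        counts = study["counts"]
        for sid, rs in study["reads"].items():
            assert counts.total[sid].sum() == rs.n_reads

    def test_missing_sample_errors(self, study):
        sheet = study["sheet"].copy()
        sheet.loc[len(sheet)] = {"sample_id": "ghost", "arm": "induced",
                                 "time_h": 0.0, "replicate": 9}
        with pytest.raises(ValueError, match="ghost"):
            sw.build_count_matrix(study["reads"], sheet, study["windows"],
                                  study["truth"].reference.contigs,
                                  study["mask"])

    def test_labeled_tracks_planted_fraction(self, study):
        """Expected labeled fraction of reads ~ binomial given the planted
        labeled fraction times the >=2-conversion call probability."""
        from scipy import stats as st

        truth = study["truth"]
        cfg = truth.config
        counts = study["counts"]
        sid = "induced_0h_r1"
        f0 = cfg.base_labeled_fraction
        for g in truth.genes[:12]:
            tot = int(counts.total.loc[g.gene_id, sid])
            if tot < 30:
                continue
            call_p = st.binom.sf(1, g.t_count, cfg.p_conv)
            expect = f0 * call_p
            got = counts.labeled.loc[g.gene_id, sid] / tot
            se = np.sqrt(expect * (1 - expect) / tot)
            assert abs(got - expect) < 4 * se + 0.02

    def test_round_trip_via_tsv(self, study, tmp_path):
        counts = study["counts"]
        counts.write(tmp_path)
        again = sw.LabeledCountMatrix.read(tmp_path)
        pd.testing.assert_frame_equal(counts.labeled, again.labeled)
        pd.testing.assert_frame_equal(counts.total, again.total)
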