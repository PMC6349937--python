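import itertools

import numpy as np
import pandas as pd
import pytest

from crelink.iofmt import GeneRecord, GenomicInterval, PWMRecord
from crelink.tfmotif import (
    MotifHitIndex,
    Regulon,
    TFActivity,
    binarize_activity,
    build_motif_hit_index,
    build_regulons,
    call_tf_activity,
    label_active_regions,
    pwm_max_score,
    pwm_min_score,
    recovery_auc,
    scan_peak,
)

BASES = "ACGT"


def make_pwm(consensus, name="M", hit=0.91, pseudo=True):
    miss = (1 - hit) / 3
    m = np.full((len(consensus), 4), miss)
    for i, b in enumerate(consensus):
        m[i, BASES.index(b)] = hit
    return PWMRecord(name, m, 1.0 if pseudo else 0.0)


def brute_force_hits(sequence, pwm, match_fraction=0.95):
    """Independent oracle: score every window on both strands explicitly."""
    logodds = np.log2(pwm.matrix / 0.25)
    max_s = sum(max(row) for row in logodds)
    min_s = sum(min(row) for row in logodds)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(pwm)
    out = set()
    for strand in "+-":
        for off in range(len(sequence) - L + 1):
            window = sequence[off : off + L]
            if strand == "-":
                window = "".join(comp[b] for b in reversed(window) if b in comp)
                if len(window) < L:
                    continue
            if "N" in window:
                continue
            score = sum(logodds[i, BASES.index(b)] for i, b in enumerate(window))
            if (score - min_s) / (max_s - min_s) >= match_fraction:
                out.add((off, strand))
    return out


class TestRecoveryAuc:
    def _series(self, values):
        return pd.Series(values, index=[f"g{i}" for i in range(len(values))])

    def test_perfect_packing_scores_one(self):
        expr = self._series([9, 8, 7, 1, 1, 1, 1, 1, 0, 0])
        reg = Regulon("tf", frozenset({"g0", "g1", "g2"}))
        assert recovery_auc(expr, reg, top_frac=0.3) == pytest.approx(1.0)

    def test_absent_from_top_scores_zero(self):
        expr = self._series([9, 8, 7, 1, 1, 1, 1, 1, 0, 0])
        reg = Regulon("tf", frozenset({"g8", "g9"}))
        assert recovery_auc(expr, reg, top_frac=0.3) == 0.0

    def test_step_curve_hand_integration(self):
        """10 genes, top half, regulon at ranks 1 and 3: curve (1,1,2,2,2),
        max achievable (1,2,2,2,2) -> 8/9."""
        expr = self._series([10, 5, 8, 1, 1, 1, 1, 1, 0, 0])
        # ranking: g0 (10), g2 (8), g1 (5), then ties -> regulon at ranks 1,3
        reg = Regulon("tf", frozenset({"g0", "g1"}))
        assert recovery_auc(expr, reg, top_frac=0.5) == pytest.approx(8 / 9)

    def test_invariant_under_monotone_transform(self, rng):
        expr = self._series(rng.uniform(1, 10, size=40))
        reg = Regulon("tf", frozenset({"g3", "g7", "g11"}))
        before = recovery_auc(expr, reg, top_frac=0.25)
        after = recovery_auc(np.exp(expr / 2), reg, top_frac=0.25)
        assert before == pytest.approx(after)

    def test_empty_regulon_rejected(self):
        with pytest.raises(ValueError):
            Regulon("tf", frozenset())


class TestBinarizeActivity:
    def test_clean_bimodal_mixture(self, rng):
        low = rng.normal(0.1, 0.02, size=60)
        high = rng.normal(0.8, 0.02, size=40)
        auc = np.concatenate([low, high])
        thr, calls = binarize_activity(auc, seed=0)
        assert 0.2 < thr < 0.7
        np.testing.assert_array_equal(calls, (auc >= thr).astype(np.int8))
        assert calls[:60].sum() == 0 and calls[60:].sum() == 40

    def test_constant_row_all_inactive(self, caplog):
        thr, calls = binarize_activity(np.full(20, 0.5))
        assert calls.sum() == 0
        assert "constant" in caplog.text

    def test_single_outlier_marked_by_fallback(self, rng):
        auc = np.concatenate([rng.normal(0.1, 0.005, size=49), [0.9]])
        _, calls = binarize_activity(auc, seed=0)
        assert calls[-1] == 1 and calls[:-1].sum() == 0

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            binarize_activity(np.linspace(0, 1, 9))


class TestPwmScores:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWMRecord("u", np.full((4, 4), 0.25))
        assert pwm_max_score(pwm) == pytest.approx(0.0)
        assert pwm_min_score(pwm) == pytest.approx(0.0)

    def test_hand_formula_on_peaked_position(self):
        pwm = make_pwm("ACGT", hit=0.91)
        assert pwm_max_score(pwm) == pytest.approx(4 * np.log2(0.91 / 0.25))
        assert pwm_min_score(pwm) == pytest.approx(4 * np.log2(0.03 / 0.25))

    def test_max_dominates_every_enumerated_kmer(self, rng):
        m = rng.dirichlet(np.ones(4), size=5)
        pwm = PWMRecord("r", m)
        logodds = np.log2(m / 0.25)
        best = pwm_max_score(pwm)
        for kmer in itertools.product(range(4), repeat=5):
            score = sum(logodds[i, b] for i, b in enumerate(kmer))
            assert score <= best + 1e-12

    def test_zero_probability_rejected(self):
        m = np.zeros((4, 4))
        m[:, 0] = 1.0
        with pytest.raises(ValueError, match="pseudocount"):
            pwm_max_score(PWMRecord("z", m))


class TestScanPeak:
    def test_embedded_consensus_is_hit_at_offset(self, rng):
        pwm = make_pwm("ACGTAC")
        seq = "".join(rng.choice(list("ACGT"), size=60))
        seq = seq[:20] + "ACGTAC" + seq[26:]
        offsets = {(h.offset, h.strand) for h in scan_peak(seq, pwm)}
        assert (20, "+") in offsets

    def test_reverse_complement_hit_on_minus_strand(self):
        pwm = make_pwm("AAACGT")
        seq = "T" * 10 + "ACGTTT" + "T" * 10  # revcomp of AAACGT
        hits = scan_peak(seq, pwm)
        assert any(h.strand == "-" and h.offset == 10 for h in hits)

    def test_window_with_n_skipped(self):
        pwm = make_pwm("ACGTAC")
        assert scan_peak("ACGNAC", pwm) == []

    def test_short_sequence_no_hits(self):
        assert scan_peak("ACG", make_pwm("ACGTAC")) == []

    def test_matches_brute_force_oracle(self, rng):
        pwm = make_pwm("ACGTA", hit=0.7)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        seq = seq[:50] + "ACGTA" + seq[55:]
        ours = {(h.offset, h.strand) for h in scan_peak(seq, pwm, 0.9)}
        assert ours == brute_force_hits(seq, pwm, 0.9)

    def test_literal_fraction_mode(self):
        pwm = make_pwm("ACGTAC")
        hits = scan_peak("ACGTAC", pwm, match_fraction=0.999, literal_fraction=True)
        assert len(hits) == 1 and hits[0].score_fraction == pytest.approx(1.0)


class TestBuildRegulons:
    def _planted_program(self, rng, n_cells=120, n_targets=20, n_noise=60):
        activity = np.zeros(n_cells)
        activity[: n_cells // 2] = 1.0
        rows, names = [], []
        rows.append(10 + 8 * activity + rng.normal(0, 0.5, n_cells))
        names.append("TF1")
        for i in range(n_targets):
            rows.append(5 + 6 * activity + rng.normal(0, 0.8, n_cells))
            names.append(f"T{i}")
        for i in range(n_noise):
            rows.append(rng.uniform(2, 8, n_cells))
            names.append(f"X{i}")
        return pd.DataFrame(rows, index=names)

    def test_planted_program_recovered(self, rng):
        ge = self._planted_program(rng)
        (reg,) = build_regulons(ge, ["TF1"], corr_min=0.3, min_size=10)
        planted = {f"T{i}" for i in range(20)}
        assert len(planted & reg.target_gene_ids) >= 16  # >= 80%
        assert "TF1" in reg.target_gene_ids

    def test_uncorrelated_tf_builds_nothing(self, rng):
        ge = pd.DataFrame(rng.uniform(size=(30, 100)), index=[f"g{i}" for i in range(30)])
        ge.loc["TF1"] = rng.uniform(size=100)
        assert build_regulons(ge, ["TF1"], min_size=5) == []

    def test_perfect_correlation_boundary(self, rng):
        base = rng.uniform(size=50)
        ge = pd.DataFrame(
            {f"c{i}": [base[i], base[i] * 2, -base[i]] for i in range(50)},
            index=["TF1", "dup", "anti"],
        )
        (reg,) = build_regulons(ge, ["TF1"], corr_min=1.0, min_size=2)
        assert reg.target_gene_ids == frozenset({"TF1", "dup"})

    def test_absent_tf_gene_skipped_with_warning(self, rng, caplog):
        ge = pd.DataFrame(rng.uniform(size=(5, 20)), index=[f"g{i}" for i in range(5)])
        assert build_regulons(ge, ["missing"], min_size=1) == []
        assert "absent" in caplog.text

    def test_motif_context_prunes_targets(self, rng):
        ge = self._planted_program(rng, n_targets=12, n_noise=10)
        peaks = [GenomicInterval("chr1", 1000, 1200)]
        hits = MotifHitIndex()
        hits.add(0, "TF1", 1.0)
        # only T0..T5 have a TSS within 10 kb of the motif peak
        genes = [
            GeneRecord(f"T{i}", GenomicInterval("chr1", 2000 + i, 4000, "+"))
            for i in range(6)
        ] + [
            GeneRecord(f"T{i}", GenomicInterval("chr2", 2000, 4000, "+"))
            for i in range(6, 12)
        ] + [GeneRecord("TF1", GenomicInterval("chr3", 0, 1000, "+"))]
        (reg,) = build_regulons(
            ge, ["TF1"], motif_hit_index=hits, peaks=peaks, genes=genes,
            corr_min=0.3, min_size=2,
        )
        assert reg.target_gene_ids <= {"TF1"} | {f"T{i}" for i in range(6)}
        assert not reg.target_gene_ids & {f"T{i}" for i in range(6, 12)}


class TestActiveRegions:
    def _activity(self, active_cells, n_cells=6, tf="TF1"):
        auc_row = np.where(active_cells, 0.9, 0.1)
        active = active_cells.astype(np.int8)[None, :]
        return TFActivity(
            auc=pd.DataFrame(auc_row[None, :], index=[tf]),
            active=pd.DataFrame(active, index=[tf]),
            thresholds={tf: 0.5},
        )

    def test_hit_and_activity_required(self):
        peaks = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        active_cells = np.array([True, False, False, True, False, False])
        activity = self._activity(active_cells)
        hits = MotifHitIndex()
        hits.add(0, "TF1", 1.0)
        counts = np.ones((2, 6))
        mask = label_active_regions(peaks, hits, activity, counts)
        np.testing.assert_array_equal(mask[0], active_cells.astype(np.int8))
        assert mask[1].sum() == 0  # no motif

    def test_require_fragment_gates_active_calls(self):
        peaks = [GenomicInterval("chr1", 0, 100)]
        active_cells = np.array([True, True, False, False, False, False])
        activity = self._activity(active_cells)
        hits = MotifHitIndex()
        hits.add(0, "TF1", 1.0)
        counts = np.array([[0, 1, 1, 1, 1, 1]])
        mask = label_active_regions(peaks, hits, activity, counts)
        assert mask[0].tolist() == [0, 1, 0, 0, 0, 0]
        mask_nf = label_active_regions(peaks, hits, activity, counts, require_fragment=False)
        assert mask_nf[0].tolist() == [1, 1, 0, 0, 0, 0]

    def test_empty_hit_index_warns_zero_mask(self, caplog):
        peaks = [GenomicInterval("chr1", 0, 100)]
        activity = self._activity(np.array([True] * 6))
        mask = label_active_regions(peaks, MotifHitIndex(), activity, np.ones((1, 6)))
        assert mask.sum() == 0 and "empty" in caplog.text

    def test_mask_monotone_in_active_tfs(self):
        """Adding an active TF with a hit can only switch cells on."""
        peaks = [GenomicInterval("chr1", 0, 100)]
        cells_a = np.array([True, False, False, False, False, False])
        hits = MotifHitIndex()
        hits.add(0, "TF1", 1.0)
        base = label_active_regions(peaks, hits, self._activity(cells_a), np.ones((1, 6)))
        cells_b = np.array([False, False, True, False, False, False])
        both = TFActivity(
            auc=pd.DataFrame(np.vstack([np.where(cells_a, 0.9, 0.1), np.where(cells_b, 0.9, 0.1)]), index=["TF1", "TF2"]),
            active=pd.DataFrame(np.vstack([cells_a, cells_b]).astype(np.int8), index=["TF1", "TF2"]),
            thresholds={"TF1": 0.5, "TF2": 0.5},
        )
        hits.add(0, "TF2", 1.0)
        more = label_active_regions(peaks, hits, both, np.ones((1, 6)))
        assert (more >= base).all()


class TestEndToEndActivity:
    def test_activity_calls_match_planted_programs(self, rng):
        """AUC + binarization recover a two-program cell split."""
        n_cells = 80
        active = np.zeros(n_cells, dtype=bool)
        active[:40] = True
        rows, names = [], []
        for i in range(15):
            rows.append(5 + 6 * active + rng.normal(0, 0.7, n_cells))
            names.append(f"T{i}")
        rows.append(10 + 10 * active + rng.normal(0, 0.7, n_cells))
        names.append("TF1")
        for i in range(184):
            rows.append(rng.uniform(2, 8, n_cells))
            names.append(f"X{i}")
        ge = pd.DataFrame(rows, index=names, columns=[f"c{i}" for i in range(n_cells)])
        regs = build_regulons(ge, ["TF1"], corr_min=0.3, min_size=10)
        activity = call_tf_activity(ge, regs, top_frac=0.1, seed=0)
        called = activity.is_active("TF1")
        balanced = 0.5 * ((called & active).sum() / active.sum()
                          + (~called & ~active).sum() / (~active).sum())
        assert balanced >= 0.9


class TestHitIndex:
    def test_best_fraction_kept(self):
        idx = MotifHitIndex()
        idx.add(3, "TF1", 0.96)
        idx.add(3, "TF1", 0.99)
        idx.add(3, "TF2", 0.95)
        assert idx.hits[3]["TF1"] == 0.99
        assert idx.tfs_for_peak(3) == {"TF1", "TF2"}
        assert len(idx) == 2

    def test_build_from_sequences(self, rng):
        pwm = make_pwm("ACGTAC", name="TF9")
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(3)]
        seqs[1] = seqs[1][:10] + "ACGTAC" + seqs[1][16:]
        idx = build_motif_hit_index(seqs, [pwm])
        assert 1 in idx.hits and "TF9" in idx.hits[1]
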