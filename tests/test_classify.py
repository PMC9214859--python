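import numpy as np
import pandas as pd
import pytest

from circpanel.classify import (
    ClassifyError,
    FastqError,
    classify_reads,
    parse_star_chimeric,
    preprocess_reads,
)
from circpanel.simulate import SimConfig, simulate

ADAPTER = "AGATCGGAAGAGC"


def _fastq(path, records):
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


class TestPreprocess:
    def test_adapter_removed_rest_intact(self):
        insert = "ACGT" * 12
        reads, stats = preprocess_reads(
            [("r1", insert + ADAPTER + "TTTT", "I" * (len(insert) + len(ADAPTER) + 4))],
            adapter=ADAPTER,
        )
        assert reads == [("r1", insert, "I" * len(insert))]
        assert stats["adapter_trimmed"] == 1

    def test_partial_adapter_suffix_removed(self):
        insert = "ACGT" * 12
        reads, _ = preprocess_reads(
            [("r1", insert + ADAPTER[:7], "I" * (len(insert) + 7))], adapter=ADAPTER
        )
        assert reads[0][1] == insert

    def test_clean_read_unchanged(self):
        rec = ("r1", "ACGT" * 20, "I" * 80)
        reads, stats = preprocess_reads([rec], adapter=ADAPTER)
        assert reads == [rec]
        assert stats == {"input": 1, "kept": 1, "dropped_short": 0,
                         "adapter_trimmed": 0, "quality_trimmed": 0}

    def test_constructed_hundred_read_statistics(self):
        """Hand-built expectation table: 40 adapter reads, 25 with low-quality
        tails, 20 that fall below the length floor after trimming, 15 clean."""
        recs = []
        insert = "ACGT" * 15  # 60 nt
        for i in range(40):
            s = insert + ADAPTER
            recs.append((f"a{i}", s, "I" * len(s)))
        for i in range(25):
            recs.append((f"q{i}", insert + "TTTT", "I" * 60 + "#" * 4))
        for i in range(20):
            recs.append((f"s{i}", "ACGTACGTACGT" + "TTTT", "I" * 12 + "#" * 4))
        for i in range(15):
            recs.append((f"c{i}", insert, "I" * 60))
        reads, stats = preprocess_reads(recs, adapter=ADAPTER)
        assert stats == {"input": 100, "kept": 80, "dropped_short": 20,
                         "adapter_trimmed": 40, "quality_trimmed": 45}
        assert len(reads) == 80
        assert all(len(seq) == 60 for _, seq, _ in reads)

    def test_malformed_fastq_names_record(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nII\n")  # qual length mismatch
        with pytest.raises(FastqError):
            list(preprocess_reads(path))


class TestClassifier:
    def test_exact_junction_spanning_read_is_chimeric(self, heart_refs):
        ref = heart_refs[0]
        off = ref.junction_offset
        read = ref.bsj_seq[off - 40 : off + 40]
        res = classify_reads([("r1", read)], heart_refs)
        (cr,) = res.reads
        assert cr.label == "chimeric"
        assert ref.target_id in cr.target_id.split(",")
        assert cr.anchor_5 == 40 and cr.anchor_3 == 40

    def test_linear_junction_read(self, heart_refs):
        ref = heart_refs[0]
        off = ref.junction_offset
        read = ref.linear_seq[off - 50 : off + 30]
        res = classify_reads([("r1", read)], heart_refs)
        assert res.reads[0].label == "linear"

    def test_acceptor_suffix_read_is_non_junction(self, heart_refs):
        ref = max(heart_refs, key=lambda r: r.flank_D)
        assert ref.flank_D >= 30
        read = ref.bsj_seq[ref.junction_offset :]
        res = classify_reads([("r1", read)], heart_refs)
        assert res.reads[0].label == "non_junction"
        assert res.counts["n_chimeric"].sum() == 0
        assert res.counts["n_linear"].sum() == 0

    def test_short_anchor_downgraded_not_junction(self, heart_refs):
        ref = heart_refs[0]
        off = ref.junction_offset
        read = ref.bsj_seq[off - 5 : off + 40]  # only 5 nt on the 5' side
        res = classify_reads([("r1", read)], heart_refs, min_anchor=10)
        assert res.reads[0].label == "non_junction"

    def test_random_read_unassigned(self, heart_refs):
        rng = np.random.default_rng(13)
        read = "".join(rng.choice(list("ACGT"), size=80))
        res = classify_reads([("r1", read)], heart_refs)
        assert res.reads[0].label == "unassigned"

    def test_label_partition_sums_to_input(self, heart_refs):
        cfg = SimConfig(
            true_circ={heart_refs[0].target_id: 2.0, heart_refs[5].target_id: 1.0},
            true_lin={heart_refs[0].target_id: 1.0, heart_refs[5].target_id: 3.0},
            n_reads=500, seed=3,
        )
        records, _ = simulate(heart_refs, cfg)
        res = classify_reads(records, heart_refs, keep_reads=False)
        label_sum = sum(
            res.label_totals[k]
            for k in ("chimeric", "linear", "non_junction", "ambiguous", "unassigned")
        )
        assert label_sum == 500

    def test_perfect_labels_at_zero_error(self, heart_refs):
        tids = [r.target_id for r in heart_refs[:4]]
        cfg = SimConfig(
            true_circ=dict.fromkeys(tids, 1.0),
            true_lin=dict.fromkeys(tids, 1.0),
            n_reads=4000, seed=11, error_rate=0.0,
        )
        records, truth = simulate(heart_refs, cfg)
        res = classify_reads(records, heart_refs, min_anchor=10)
        by_id = {r.read_id: r for r in res.reads}
        for row in truth.per_read.itertuples():
            got = by_id[row.read_id]
            if row.spans_with_anchor:
                want = "chimeric" if row.template == "circ" else "linear"
                assert got.label == want, row.read_id
                assert row.target_id in got.target_id.split(",")
            else:
                assert got.label == "non_junction"

    def test_anchor_threshold_monotonicity(self, heart_refs):
        tids = [r.target_id for r in heart_refs[:3]]
        cfg = SimConfig(
            true_circ=dict.fromkeys(tids, 1.0), true_lin=dict.fromkeys(tids, 1.0),
            n_reads=1500, seed=5,
        )
        records, _ = simulate(heart_refs, cfg)
        prev = None
        for anchor in (5, 10, 20, 40):
            res = classify_reads(records, heart_refs, min_anchor=anchor,
                                 keep_reads=False)
            junc = res.counts["n_chimeric"].sum() + res.counts["n_linear"].sum()
            if prev is not None:
                assert junc <= prev
            prev = junc

    def test_determinism(self, heart_refs):
        tid = heart_refs[0].target_id
        cfg = SimConfig(true_circ={tid: 1.0}, true_lin={tid: 1.0},
                        n_reads=300, seed=2)
        records, _ = simulate(heart_refs, cfg)
        a = classify_reads(records, heart_refs, keep_reads=False)
        b = classify_reads(records, heart_refs, keep_reads=False)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert a.label_totals == b.label_totals

    def test_shared_linear_reference_credited_to_group(self, heart63, heart_design,
                                                       heart_refs):
        _, panel = heart63
        group = next(p for p in heart_design.primers if len(p.group_targets) == 2)
        refs = {r.target_id: r for r in heart_refs}
        ra = refs[group.group_targets[0]]
        off = ra.junction_offset
        read = ra.linear_seq[off - 40 : off + 30]
        res = classify_reads([("r1", read)], heart_refs)
        assert res.reads[0].label == "linear"
        counted = res.counts[res.counts["n_linear"] > 0]["target_id"].tolist()
        assert sorted(counted) == sorted(group.group_targets)

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ClassifyError, match="empty reference"):
            classify_reads([("r1", "ACGT" * 10)], [])


class TestStarChimericImport:
    def _write(self, path, rows):
        with open(path, "w") as fh:
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")

    @staticmethod
    def _bp(target):
        if target.strand == "+":
            return target.donor_exon.end + 1, target.acceptor_exon.start
        return target.donor_exon.start, target.acceptor_exon.end + 1

    def _row(self, chrom, donor_bp, acceptor_bp, strand, name="read1"):
        return [chrom, donor_bp, strand, chrom, acceptor_bp, strand,
                1, 0, 0, name, 1, "100M", 1, "100M"]

    def test_matching_junction_counted(self, toy2, tmp_path):
        _, panel = toy2
        t = panel.targets[0]
        donor_bp, acceptor_bp = self._bp(t)
        path = tmp_path / "Chimeric.out.junction"
        self._write(path, [
            self._row(t.chrom, donor_bp, acceptor_bp, t.strand),
            self._row(t.chrom, donor_bp + 2000, acceptor_bp + 2000, t.strand, "far"),
            self._row("chrZ", donor_bp, acceptor_bp, t.strand, "other_chrom"),
        ])
        counts = parse_star_chimeric(path, panel)
        by_target = counts.set_index("target_id")["n_chimeric"]
        assert by_target[t.target_id] == 1
        assert by_target.sum() == 1

    def test_tolerance_sweep_matches_hand_prediction(self, toy2, tmp_path):
        _, panel = toy2
        t = panel.targets[0]
        donor_bp, acceptor_bp = self._bp(t)
        path = tmp_path / "chim.junction"
        # offsets 0, 1, 3 from the true breakpoints
        self._write(path, [
            self._row(t.chrom, donor_bp, acceptor_bp, t.strand, "exact"),
            self._row(t.chrom, donor_bp + 1, acceptor_bp - 1, t.strand, "off1"),
            self._row(t.chrom, donor_bp + 3, acceptor_bp + 3, t.strand, "off3"),
        ])
        expected = {0: 1, 1: 2, 2: 2, 3: 3, 4: 3, 5: 3}
        for tol, want in expected.items():
            counts = parse_star_chimeric(path, panel, coord_tolerance=tol)
            got = counts.set_index("target_id")["n_chimeric"][t.target_id]
            assert got == want, f"tolerance {tol}"

    def test_wrong_strand_not_counted(self, toy2, tmp_path):
        _, panel = toy2
        t = panel.targets[0]
        donor_bp, acceptor_bp = self._bp(t)
        flipped = "-" if t.strand == "+" else "+"
        path = tmp_path / "chim.junction"
        self._write(path, [self._row(t.chrom, donor_bp, acceptor_bp, flipped)])
        counts = parse_star_chimeric(path, panel)
        assert counts["n_chimeric"].sum() == 0

    def test_column_count_error_names_line(self, toy2, tmp_path):
        _, panel = toy2
        path = tmp_path / "chim.junction"
        path.write_text("chr1\t100\t+\n")
        with pytest.raises(ClassifyError, match=":1"):
            parse_star_chimeric(path, panel)
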