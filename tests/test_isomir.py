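"""Mismatch alignment, end-modification classification, and profiles."""

import numpy as np
import pytest

from micromuscle import io as mio, isomir as iso, preprocess as pp
from micromuscle.core import HairpinRecord, MatureAnnotation

RNG = np.random.default_rng(55)


def _hairpin():
    # lead(6, GC-guarded tail) | arm5(21) | loop(12, guarded) | arm3(21) | tail(6, guarded)
    lead = "ATGGCC"
    arm5 = "TGAGGTAGTAGGTTGTATAGT"
    loop = "GCCGAATTCGGC"
    arm3 = "CTATACAATCTACTGTCTTTC"
    tail = "GCCGAT"
    seq = lead + arm5 + loop + arm3 + tail
    return HairpinRecord(
        "hp1",
        seq,
        matures=[
            MatureAnnotation("hp1-5p", "5p", 6, 27),
            MatureAnnotation("hp1-3p", "3p", 39, 60),
        ],
    )


class TestAlignMismatch:
    def test_exact_substring_zero_mismatches(self):
        h = _hairpin()
        hits = iso.align_mismatch(h.sequence[6:27], [h])
        exact = [x for x in hits if x.mismatches == 0]
        assert [(x.offset, x.length) for x in exact] == [(6, 21)]

    def test_three_substitutions_rejected(self):
        h = _hairpin()
        read = list(h.sequence[6:27])
        for i in (2, 9, 16):
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        hits = iso.align_mismatch("".join(read), [h])
        assert all(x.offset != 6 for x in hits)

    def test_overhang_counts_as_mismatch(self):
        h = _hairpin()
        read = h.sequence[45:] + "TT"  # 2 nt past the 3' end
        hits = iso.align_mismatch(read, [h])
        assert any(x.offset == 45 and x.mismatches == 2 for x in hits)
        read5 = h.sequence[45:] + "TTTTT"  # 5 nt: beyond the overhang allowance
        assert not any(x.offset == 45 for x in iso.align_mismatch(read5, [h]))

    def test_brute_force_oracle(self):
        """Hit sets equal an exhaustive all-offsets enumerator on random reads."""
        hairpins = []
        for hi in range(3):
            seq = "".join(RNG.choice(list("ACGT"), size=int(RNG.integers(60, 90))))
            hairpins.append(HairpinRecord(f"h{hi}", seq, matures=[]))
        for _ in range(30):
            h = hairpins[RNG.integers(3)]
            a = int(RNG.integers(0, len(h.sequence) - 20))
            read = list(h.sequence[a : a + 20])
            for _ in range(RNG.integers(0, 3)):
                i = int(RNG.integers(20))
                read[i] = str(RNG.choice(list("ACGT")))
            read = "".join(read)

            expected = set()
            for hp in hairpins:
                for off in range(len(hp.sequence) + 4 - 20 + 1):
                    mm = sum(
                        1
                        for i in range(20)
                        if off + i >= len(hp.sequence) or read[i] != hp.sequence[off + i]
                    )
                    if mm <= 2 and off + 20 <= len(hp.sequence) + 4:
                        expected.add((hp.hairpin_id, off, mm))
            got = {(x.hairpin_id, x.offset, x.mismatches) for x in iso.align_mismatch(read, hairpins)}
            assert got == expected


class TestClassify:
    def _call(self, read):
        h = _hairpin()
        return iso.classify_read(read, 1, [h])

    def test_canonical(self):
        h = _hairpin()
        call = self._call(h.sequence[6:27])
        assert call.mature_id == "hp1-5p" and call.canonical

    def test_uridylation_on_mismatching_template(self):
        h = _hairpin()
        call = self._call(h.sequence[39:60] + "TT")  # next bases are 'GC...' tail? 'AT' differs
        assert call.mature_id == "hp1-3p"
        assert call.nta3 == "TT" and call.trim3 == 0 and call.ext3_templated == 0

    def test_templated_extension(self):
        h = _hairpin()
        nxt = h.sequence[27]  # base following the 5p arm
        call = self._call(h.sequence[6:27] + nxt)
        assert call.ext3_templated == 1 and call.nta3 == ""

    def test_trimming(self):
        h = _hairpin()
        call = self._call(h.sequence[6:25])
        assert call.trim3 == 2 and call.canonical is False

    def test_trim_plus_tail(self):
        h = _hairpin()
        core = h.sequence[6:25]
        tail = "AA" if h.sequence[25] != "A" else "TT"
        call = self._call(core + tail)
        assert call.trim3 == 2 and call.nta3 == tail

    def test_internal_variant_rejected(self):
        h = _hairpin()
        read = list(h.sequence[6:27])
        read[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[10]]
        assert self._call("".join(read)) is None

    def test_decomposition_reconstructs_read(self, isomir_sim):
        """nta5 + hairpin core + nta3 reproduces every classified read exactly."""
        cfg, fasta, gff3, truth, counts, fastqs = isomir_sim
        hairpins = mio.read_hairpins(fasta, gff3)
        by_id = {h.hairpin_id: h for h in hairpins}
        hairpin_of = {m.mature_id: h.hairpin_id for h in hairpins for m in h.matures}
        params = pp.PreprocessParams(adapter=cfg.adapter, mode="isomir", flank_trim_n=4)
        sample = counts.sample_ids[0]
        reads, _ = pp.preprocess_fastq(fastqs[sample], params)
        calls = iso.classify_sample(reads, hairpins)
        assert len(calls) > 50
        for c in calls:
            h = by_id[hairpin_of[c.mature_id]]
            rebuilt = c.nta5 + h.sequence[c.core_start:c.core_end] + c.nta3
            assert rebuilt == c.sequence
            for k, base in enumerate(c.nta3):
                pos = c.core_end + k
                assert pos >= len(h.sequence) or h.sequence[pos] != base

    def test_planted_modifications_recovered(self, isomir_sim):
        """>= 99% of in-budget reads get their planted modification class back."""
        cfg, fasta, gff3, truth, counts, fastqs = isomir_sim
        hairpins = mio.read_hairpins(fasta, gff3)
        params = pp.PreprocessParams(adapter=cfg.adapter, mode="isomir", flank_trim_n=4)
        ok = tot = 0
        for sample in counts.sample_ids[:2]:
            reads, _ = pp.preprocess_fastq(fastqs[sample], params)
            calls = {c.sequence: c for c in iso.classify_sample(reads, hairpins)}
            for rid, seq, _ in mio.read_fastq(fastqs[sample]):
                mature_id, _, _, tag = rid.split("|")
                insert = seq[: len(seq) - len(cfg.adapter)][4:-4]
                if len(insert) < 12:
                    continue
                if tag.startswith("nta3=") and len(tag.split("=")[1]) > 2:
                    continue  # tail exceeds the 2-mismatch budget: out of scope
                tot += 1
                c = calls.get(insert)
                if c is None or c.mature_id != mature_id:
                    continue
                if tag == "canonical" and c.canonical:
                    ok += 1
                elif tag.startswith("trim3=") and c.trim3 == int(tag.split("=")[1]):
                    ok += 1
                elif tag.startswith("trim5=") and c.trim5 == int(tag.split("=")[1]):
                    ok += 1
                elif tag.startswith("ext3=") and c.ext3_templated == int(tag.split("=")[1]):
                    ok += 1
                elif tag.startswith("nta3=") and c.nta3 == tag.split("=")[1]:
                    ok += 1
        assert tot > 500
        assert ok / tot >= 0.99


class TestProfiles:
    def _mk_call(self, seq="A" * 22, count=5, **kw):
        base = dict(
            sequence=seq, count=count, mature_id="m", core_start=0, core_end=len(seq),
            trim5=0, trim3=0, ext5_templated=0, ext3_templated=0, nta5="", nta3="",
        )
        base.update(kw)
        return iso.IsomirCall(**base)

    def test_min_count_threshold_excludes_singletons(self):
        calls = [self._mk_call(count=1, nta3="T"), self._mk_call(count=2)]
        prof = iso.aggregate_profile(calls, min_count=2)
        assert prof["n_assigned"] == 2 and prof["f_add3"] == 0.0

    def test_all_canonical_zero_frequencies(self):
        prof = iso.aggregate_profile([self._mk_call(count=10)])
        assert prof["f_canonical"] == 1.0
        assert all(prof[c] == 0.0 for c in iso.PROFILE_CLASSES if c != "f_canonical")

    def test_frequency_arithmetic(self):
        calls = [
            self._mk_call(seq="C" * 22, count=80),
            self._mk_call(seq="G" * 22, count=20, nta3="T"),
        ]
        prof = iso.aggregate_profile(calls)
        assert prof["f_add3"] == pytest.approx(0.2)
        assert prof["f_nta3_U"] == pytest.approx(0.2)
        assert prof["f_oligoU"] == 0.0

    def test_oligo_requires_two_bases(self):
        calls = [self._mk_call(seq="C" * 22, count=5, nta3="TT"),
                 self._mk_call(seq="G" * 22, count=5, nta3="AA"),
                 self._mk_call(seq="T" * 22, count=10)]
        prof = iso.aggregate_profile(calls)
        assert prof["f_oligoU"] == pytest.approx(0.25)
        assert prof["f_oligoA"] == pytest.approx(0.25)
        assert prof["f_nta3_U"] <= prof["f_add3"]

    def test_unique_sequence_weighting_switch(self):
        calls = [self._mk_call(seq="C" * 22, count=99), self._mk_call(seq="G" * 22, count=2, nta3="T")]
        by_count = iso.aggregate_profile(calls, weight_by_count=True)
        by_seq = iso.aggregate_profile(calls, weight_by_count=False)
        assert by_count["f_add3"] == pytest.approx(2 / 101)
        assert by_seq["f_add3"] == pytest.approx(0.5)

    def test_shard_invariance(self, isomir_sim):
        """Frequencies are identical when a sample's reads arrive in two shards."""
        cfg, fasta, gff3, _, counts, fastqs = isomir_sim
        hairpins = mio.read_hairpins(fasta, gff3)
        params = pp.PreprocessParams(adapter=cfg.adapter, mode="isomir", flank_trim_n=4)
        sample = counts.sample_ids[0]
        lines = fastqs[sample].splitlines(keepends=True)
        records = ["".join(lines[i:i + 4]) for i in range(0, len(lines), 4)]
        whole, _ = pp.preprocess_fastq(fastqs[sample], params)
        half1, _ = pp.preprocess_fastq("".join(records[::2]), params)
        half2, _ = pp.preprocess_fastq("".join(records[1::2]), params)
        merged = dict(half1)
        for s, c in half2.items():
            merged[s] = merged.get(s, 0) + c
        assert merged == whole
        p1 = iso.aggregate_profile(iso.classify_sample(whole, hairpins))
        p2 = iso.aggregate_profile(iso.classify_sample(merged, hairpins))
        assert p1.equals(p2)


class TestCompareProfiles:
    def test_identical_groups(self):
        import pandas as pd
        prof = pd.DataFrame({c: [0.1, 0.1, 0.1] for c in iso.PROFILE_CLASSES})
        out = iso.compare_profiles(prof, prof)
        assert np.allclose(out["ratio_a_over_b"], 1.0)
        assert (out["pvalue"] > 0.99).all()

    def test_planted_oligou_difference_detected(self):
        """A 3x oligouridylation drop is detected and its ratio estimated."""
        import micromuscle as mm
        from micromuscle.synthetic import IsomirProfile

        detected = 0
        ratios = []
        for seed in range(6):
            profiles = {
                "WT": IsomirProfile(p_nta_u=0.15, tail_geometric_p=0.45),
                "KO": IsomirProfile(p_nta_u=0.05, tail_geometric_p=0.45),
            }
            cfg = mm.SimulationConfig(
                seed=seed, n_hairpins=8, n_clusters=0, isomir_profile=profiles,
                random_flank_n=0, baseline_mean_log_mu=4.5,
            )
            fasta, gff3, truth = mm.generate_annotation(cfg)
            cm = mm.simulate_counts(cfg, truth)
            fastqs = mm.simulate_reads(cfg, truth, cm)
            hairpins = mio.read_hairpins(fasta, gff3)
            params = pp.PreprocessParams(adapter=cfg.adapter, mode="isomir")
            tabs = {}
            for s in cm.sample_ids:
                reads, _ = pp.preprocess_fastq(fastqs[s], params)
                tabs[s] = iso.aggregate_profile(iso.classify_sample(reads, hairpins))
            tab = iso.profile_table(tabs)
            wt = tab.loc[[s for s in cm.sample_ids if s.startswith("WT")]]
            ko = tab.loc[[s for s in cm.sample_ids if s.startswith("KO")]]
            out = iso.compare_profiles(wt, ko)
            if out.loc["f_oligoU", "padj"] < 0.05:
                detected += 1
            ratios.append(out.loc["f_oligoU", "ratio_a_over_b"])
        assert detected >= 5
        assert np.median(ratios) == pytest.approx(3.0, rel=0.45)
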