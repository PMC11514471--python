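"""Generator contracts: geometry, determinism, NB moments, read conservation."""

import numpy as np
import pytest

import micromuscle as mm
from micromuscle import io as mio
from micromuscle.core import ConfigurationError
from micromuscle.synthetic import (
    IsomirProfile,
    PlantedEffect,
    simulate_timecourse,
)


def _cfg(**kw):
    base = dict(seed=5, n_hairpins=9, n_clusters=2, cluster_size=3, random_flank_n=0)
    base.update(kw)
    return mm.SimulationConfig(**base)


class TestAnnotation:
    def test_hairpin_and_arm_geometry(self):
        _, _, truth = mm.generate_annotation(_cfg(n_hairpins=20, n_clusters=3))
        for h in truth.hairpins:
            assert 60 <= len(h.sequence) <= 110
            arms = sorted(h.matures, key=lambda m: m.start)
            assert len(arms) == 2
            for m in arms:
                assert 20 <= len(m) <= 23
            assert arms[1].start - arms[0].end >= 8  # loop between arms

    def test_cluster_members_within_span(self):
        _, _, truth = mm.generate_annotation(
            _cfg(n_hairpins=3, n_clusters=1, cluster_size=3, cluster_span_bp=40_000)
        )
        loci = [h.locus for h in truth.hairpins]
        assert len({(l.chrom, l.strand) for l in loci}) == 1
        starts = [l.start for l in loci]
        assert max(starts) - min(starts) < 50_000

    def test_singletons_isolated(self):
        _, _, truth = mm.generate_annotation(_cfg(n_hairpins=6, n_clusters=1, cluster_size=2))
        singles = [h for h in truth.hairpins
                   if truth.matures.loc[h.matures[0].mature_id, "cluster_id"] == ""]
        assert len(singles) == 4
        clustered_chroms = {
            h.locus.chrom for h in truth.hairpins if h not in singles
        }
        for i, h in enumerate(singles):
            assert h.locus.chrom not in clustered_chroms
            for other in singles[i + 1:]:
                assert abs(h.locus.start - other.locus.start) > 50_000

    def test_no_clusters_yields_two_matures_per_hairpin(self):
        _, gff3, truth = mm.generate_annotation(_cfg(n_hairpins=2, n_clusters=0))
        assert gff3.count("\tmiRNA\t") == 4
        assert len(truth.matures) == 4

    def test_same_seed_identical_bytes(self):
        out1 = mm.generate_annotation(_cfg())
        out2 = mm.generate_annotation(_cfg())
        assert out1[0] == out2[0] and out1[1] == out2[1]

    def test_gff3_roundtrip(self):
        fasta, gff3, truth = mm.generate_annotation(_cfg())
        parsed = mio.read_hairpins(fasta, gff3)
        by_id = {h.hairpin_id: h for h in truth.hairpins}
        assert len(parsed) == len(by_id)
        for h in parsed:
            orig = by_id[h.hairpin_id]
            assert h.sequence == orig.sequence
            assert h.locus == orig.locus
            assert sorted((m.mature_id, m.start, m.end) for m in h.matures) == sorted(
                (m.mature_id, m.start, m.end) for m in orig.matures
            )

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_hairpins": 1, "n_clusters": 2},
            {"dispersion": -0.1},
            {"adapter": "ACGT"},
            {"groups": ()},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            _cfg(**kw)


class TestCounts:
    def test_dispersion_zero_is_poisson(self):
        cfg = _cfg(n_hairpins=2, n_clusters=0, dispersion=0.0,
                   n_samples_per_group=400, baseline_mean_log_sigma=0.0)
        _, _, truth = mm.generate_annotation(cfg)
        cm = mm.simulate_counts(cfg, truth)
        x = cm.counts.to_numpy()
        ratio = x.var(axis=1) / x.mean(axis=1)
        assert np.all(np.abs(ratio - 1) < 0.25)

    def test_nb_moments(self):
        phi = 0.2
        cfg = _cfg(n_hairpins=1, n_clusters=0, dispersion=phi, groups=("G",),
                   n_samples_per_group=10_000, baseline_mean_log_sigma=0.0,
                   baseline_mean_log_mu=5.0)
        _, _, truth = mm.generate_annotation(cfg)
        cm = mm.simulate_counts(cfg, truth)
        for mid in cm.counts.index:
            mu = truth.group_means.loc[mid, "G"]
            expected_var = mu + phi * mu**2
            assert abs(cm.counts.loc[mid].var() - expected_var) / expected_var < 0.1

    def test_no_planted_effect_log_ratio_centred(self):
        cfg = _cfg(n_hairpins=30, n_clusters=0, n_samples_per_group=10)
        _, _, truth = mm.generate_annotation(cfg)
        cm = mm.simulate_counts(cfg, truth)
        wt = cm.counts.loc[:, cm.samples["condition"] == "WT"].mean(axis=1)
        ko = cm.counts.loc[:, cm.samples["condition"] == "KO"].mean(axis=1)
        assert abs(np.log2((ko + 1) / (wt + 1)).mean()) < 0.1

    def test_planted_mirna_effect_ratio_matches_nb_oracle(self):
        """Group-mean ratios for a planted 4x effect match a direct NB simulation.

        The oracle draws the same model (mean 200 vs 800, dispersion 0.05,
        n=3/3) straight from numpy and measures how often the sample-mean
        ratio lands in [3.0, 5.3]; the generator must reproduce that
        coverage.
        """
        band = (3.0, 5.3)
        rng = np.random.default_rng(0)
        r = 1 / 0.05
        wt = rng.negative_binomial(r, r / (r + 200.0), (5000, 3)).mean(axis=1)
        ko = rng.negative_binomial(r, r / (r + 800.0), (5000, 3)).mean(axis=1)
        oracle_cov = np.mean((ko / wt >= band[0]) & (ko / wt <= band[1]))

        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            cfg = mm.SimulationConfig(
                seed=seed, n_hairpins=1, n_clusters=0, dispersion=0.05,
                baseline_mean_log_mu=float(np.log(200.0)), baseline_mean_log_sigma=0.0,
                n_samples_per_group=3, random_flank_n=0,
                planted_effects=[PlantedEffect("mirna", "sim-miR-001-5p", 2.0, ("KO",))],
            )
            _, _, truth = mm.generate_annotation(cfg)
            cm = mm.simulate_counts(cfg, truth)
            a = cm.counts.loc["sim-miR-001-5p", cm.samples["condition"] == "WT"].mean()
            b = cm.counts.loc["sim-miR-001-5p", cm.samples["condition"] == "KO"].mean()
            if band[0] <= b / a <= band[1]:
                hits += 1
        assert abs(hits / n_runs - oracle_cov) < 0.06

    def test_truth_labels_match_effect_scopes(self):
        effects = [
            PlantedEffect("cluster", "cluster_1", 1.5, ("KO",)),
            PlantedEffect("mirna", "sim-miR-009-5p", 2.0, ("KO",)),
        ]
        _, _, truth = mm.generate_annotation(_cfg(planted_effects=effects))
        labels = truth.matures["regulation_label"]
        in_c1 = truth.matures["cluster_id"] == "cluster_1"
        assert (labels[in_c1] == "transcript_level").all()
        assert labels["sim-miR-009-5p"] == "posttranscriptional"
        rest = ~in_c1 & (truth.matures.index != "sim-miR-009-5p")
        assert (labels[rest] == "null").all()


class TestReads:
    def test_clean_reads_are_mature_plus_adapter(self, clean_sim):
        cfg, _, _, truth, counts, fastqs = clean_sim
        hp = {h.hairpin_id: h for h in truth.hairpins}
        sample = counts.sample_ids[0]
        for rid, seq, quals in mio.read_fastq(fastqs[sample]):
            mature_id = rid.split("|")[0]
            h = hp[truth.matures.loc[mature_id, "hairpin_id"]]
            m = h.mature(mature_id)
            assert seq == h.sequence[m.start:m.end] + cfg.adapter
            assert set(quals) == {cfg.read_quality_q}

    def test_forced_uridylation_mismatches_template(self):
        cfg = _cfg(
            isomir_profile=IsomirProfile(p_nta_u=1.0, tail_geometric_p=1.0),
            n_hairpins=4, n_clusters=0,
        )
        _, _, truth = mm.generate_annotation(cfg)
        cm = mm.simulate_counts(cfg, truth)
        fastqs = mm.simulate_reads(cfg, truth, cm)
        hp = {h.hairpin_id: h for h in truth.hairpins}
        checked = 0
        for sample, text in fastqs.items():
            for rid, seq, _ in mio.read_fastq(text):
                insert = seq[: len(seq) - len(cfg.adapter)]
                assert insert[-1] == "T"
                mature_id = rid.split("|")[0]
                h = hp[truth.matures.loc[mature_id, "hairpin_id"]]
                m = h.mature(mature_id)
                tail = insert[m.end - m.start:]
                for k, base in enumerate(tail):
                    pos = m.end + k
                    assert pos >= len(h.sequence) or h.sequence[pos] != base
                checked += 1
        assert checked > 0

    def test_read_counts_conserve_count_matrix(self, clean_sim):
        _, _, _, truth, counts, fastqs = clean_sim
        for sample in counts.sample_ids:
            names = [rid for rid, _, _ in mio.read_fastq(fastqs[sample])]
            assert len(names) == counts.counts[sample].sum()
            per_mature = {}
            for rid in names:
                per_mature[rid.split("|")[0]] = per_mature.get(rid.split("|")[0], 0) + 1
            for mid, n in counts.counts[sample].items():
                assert per_mature.get(mid, 0) == n

    def test_same_seed_identical_fastq(self, clean_sim):
        cfg, _, _, _, _, fastqs = clean_sim
        cfg2 = mm.SimulationConfig(**{**cfg.__dict__})
        _, _, truth2 = mm.generate_annotation(cfg2)
        cm2 = mm.simulate_counts(cfg2, truth2)
        fastqs2 = mm.simulate_reads(cfg2, truth2, cm2)
        assert fastqs == fastqs2


class TestTimecourse:
    def test_monotone_template_means_increase(self):
        cfg = _cfg(n_hairpins=5, n_clusters=0, groups=("P1", "P5", "P14", "P90"),
                   dispersion=0.01, baseline_mean_log_mu=5.0)
        cm, truth = simulate_timecourse(cfg, ["monotone_up"], amplitude=3.0)
        means = truth.group_means
        assert (means.diff(axis=1).iloc[:, 1:] > 0).all().all()
        assert (truth.matures["template"] == "monotone_up").all()

    def test_determinism(self):
        cfg = _cfg(n_hairpins=4, n_clusters=0, groups=("P1", "P5", "P14"))
        cm1, _ = simulate_timecourse(cfg, ["monotone_up", "flat"])
        cm2, _ = simulate_timecourse(cfg, ["monotone_up", "flat"])
        assert cm1.counts.equals(cm2.counts)

    def test_rejects_bad_designs(self):
        with pytest.raises(ConfigurationError):
            simulate_timecourse(_cfg(groups=("P1",)), ["flat"])
        with pytest.raises(ConfigurationError):
            simulate_timecourse(_cfg(groups=("P1", "P5")), [])
        with pytest.raises(ConfigurationError):
            simulate_timecourse(_cfg(groups=("P1", "P5")), ["no_such_template"])
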