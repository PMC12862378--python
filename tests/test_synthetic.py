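"""Synthetic generator: determinism, invariants, and error-model moments."""

import numpy as np
import pytest

from epistress.synthetic import (
    ReadLengthModel,
    SyntheticConfig,
    generate_reference,
    generate_te_table,
    sample_truth,
    simulate_alignments,
    simulate_pileup,
    simulate_pretrna_lengths,
)


def read_bytes(path):
    with open(path, "rb") as fh:
        return fh.read()


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(baseline_error=0.8, mod_error_boost=0.3),       # e + delta > 1
        dict(coverage=0),
        dict(conditions={"no_stress": 2}),                    # missing IVT
        dict(conditions={"no_stress": 1, "ivt": 1}),          # 1 replicate
        dict(biotype_weights={"mRNA": 0.5, "rRNA": 0.2, "tRNA": 0.2, "ncRNA": 0.2}),
        dict(error_mix=(0.5, 0.3, 0.1)),
        dict(mrna_cds_lengths=[100]),                         # not divisible by 3
        dict(read_length_model=ReadLengthModel(immature_fraction_range=(0.8, 0.2))),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=0, **kwargs).validate()

    def test_default_config_valid(self):
        SyntheticConfig(seed=0).validate()


class TestReference:
    def test_deterministic_under_fixed_seed(self, tmp_path):
        cfg = SyntheticConfig(seed=1, n_transcripts=10)
        ref_a = generate_reference(cfg)
        ref_b = generate_reference(cfg)
        assert ref_a.sequences == ref_b.sequences
        ref_a.write_fasta(tmp_path / "a.fasta")
        ref_b.write_fasta(tmp_path / "b.fasta")
        assert read_bytes(tmp_path / "a.fasta") == read_bytes(tmp_path / "b.fasta")
        assert len(ref_a.sequences) == 10

    def test_different_seeds_differ(self):
        a = generate_reference(SyntheticConfig(seed=1))
        b = generate_reference(SyntheticConfig(seed=2))
        assert a.sequences != b.sequences

    def test_every_biotype_present(self, small_reference):
        for bt in ("mRNA", "rRNA", "tRNA", "ncRNA"):
            assert small_reference.transcripts(bt), bt

    def test_mrna_segments_consistent(self, small_reference):
        for t, (u5, cds, u3) in small_reference.mrna_segments.items():
            assert cds % 3 == 0
            assert u5 + cds + u3 == len(small_reference.sequences[t])

    def test_trnas_carry_leader_trailer(self, small_reference):
        for t, m in small_reference.trna_meta.items():
            assert m.leader_len > 0 and m.trailer_len > 0
            assert m.anticodon_start + 2 <= len(small_reference.sequences[t])


class TestTruth:
    def test_ivt_stoichiometry_zero(self, small_truth):
        ivt = small_truth.table.query("condition == 'ivt'")
        assert (ivt["stoichiometry"] == 0).all()

    def test_positions_within_transcripts(self, small_reference, small_truth):
        for r in small_truth.table.itertuples(index=False):
            assert 1 <= r.position <= len(small_reference.sequences[r.transcript])

    def test_wobble_stress_shift_clipped(self, small_reference):
        cfg = SyntheticConfig(seed=3, n_transcripts=8, stress_shift=0.3,
                              wobble_stoich_range=(0.6, 0.9))
        truth = sample_truth(small_reference, cfg)
        wob = truth.table.query("mod == 'wobble'")
        piv = wob.pivot_table(index="transcript", columns="condition",
                              values="stoichiometry")
        expected = np.clip(piv["no_stress"] + 0.3, 0, 1)
        assert np.allclose(piv["acid_stress"], expected)

    def test_rrna_truth_has_36_sites(self):
        cfg = SyntheticConfig(seed=5, n_transcripts=4,
                              biotype_weights={"mRNA": 0.25, "rRNA": 0.5,
                                               "tRNA": 0.15, "ncRNA": 0.1})
        ref = generate_reference(cfg)
        truth = sample_truth(ref, cfg)
        rrna_sites = truth.sites(ref.biotypes, "rRNA")
        assert len(rrna_sites) == 36


@pytest.fixture(scope="module")
def one_transcript():
    cfg = SyntheticConfig(seed=11, n_transcripts=4, coverage=600,
                          conditions={"no_stress": 2, "ivt": 1},
                          sites_per_transcript=1)
    ref = generate_reference(cfg)
    truth = sample_truth(ref, cfg)
    return cfg, ref, truth


class TestAlignments:
    def test_bam_deterministic(self, one_transcript, tmp_path):
        cfg, ref, truth = one_transcript
        a = simulate_alignments(ref, truth, cfg, tmp_path / "a", conditions=["ivt"])
        b = simulate_alignments(ref, truth, cfg, tmp_path / "b", conditions=["ivt"])
        assert read_bytes(a[("ivt", 1)]) == read_bytes(b[("ivt", 1)])

    def test_read_count_equals_coverage(self, one_transcript, tmp_path):
        import pysam

        cfg, ref, truth = one_transcript
        bams = simulate_alignments(ref, truth, cfg, tmp_path, conditions=["ivt"])
        with pysam.AlignmentFile(str(bams[("ivt", 1)])) as af:
            counts = {}
            for r in af.fetch(until_eof=True):
                counts[r.reference_name] = counts.get(r.reference_name, 0) + 1
        assert all(c == cfg.coverage for c in counts.values())
        assert set(counts) == set(ref.sequences)

    def test_error_rate_moments(self, one_transcript, tmp_path):
        """Empirical per-position error within 4 binomial SD of e + s*delta."""
        from epistress.profiling import compute_bcerror

        cfg, ref, truth = one_transcript
        bams = simulate_alignments(ref, truth, cfg, tmp_path / "m",
                                   conditions=["no_stress"])
        profs = compute_bcerror(str(bams[("no_stress", 1)]), ref.sequences)
        site_map = truth.for_condition("no_stress")
        e, d, n = cfg.baseline_error, cfg.mod_error_boost, cfg.coverage
        for t, prof in profs.items():
            positions, stoich = site_map.get(t, (np.empty(0, int), np.empty(0)))
            expected = np.full(prof.length, e)
            expected[positions] = e + stoich * d
            sd = np.sqrt(expected * (1 - expected) / n)
            # interior positions only: boundary deletions are re-typed
            inner = slice(1, prof.length - 1)
            dev = np.abs(prof.bcerror[inner] - expected[inner])
            assert (dev <= 4 * sd[inner] + 1e-12).mean() > 0.995
            if len(positions):
                assert np.all(
                    np.abs(prof.bcerror[positions] - expected[positions])
                    <= 4 * sd[positions])

    def test_ivt_error_rate_at_baseline(self, one_transcript, tmp_path):
        from epistress.profiling import compute_bcerror

        cfg, ref, truth = one_transcript
        bams = simulate_alignments(ref, truth, cfg, tmp_path / "ivt",
                                   conditions=["ivt"])
        profs = compute_bcerror(str(bams[("ivt", 1)]), ref.sequences)
        e = cfg.baseline_error
        sd = np.sqrt(e * (1 - e) / cfg.coverage)
        for prof in profs.values():
            assert np.nanmax(prof.bcerror) <= e + 5 * sd


class TestPileupPath:
    def test_saturated_site_rate(self):
        """s = 1 with delta 0.25 over e 0.03 gives ~0.28 error rate."""
        cfg = SyntheticConfig(seed=21, n_transcripts=4, coverage=1000,
                              sites_per_transcript=1, stoich_range=(1.0, 1.0))
        ref = generate_reference(cfg)
        truth = sample_truth(ref, cfg)
        profs = simulate_pileup(ref, truth, cfg, "no_stress", 1)
        site_map = truth.for_condition("no_stress")
        t = ref.transcripts("mRNA")[0]
        pos, stoich = site_map[t]
        rate = profs[t].bcerror[pos]
        sd = np.sqrt(0.28 * 0.72 / 1000)
        assert np.all(np.abs(rate[stoich == 1.0] - 0.28) <= 3 * sd)


class TestPreTRNA:
    def _sim(self, factor, seed=31, n_trnas=20):
        cfg = SyntheticConfig(
            seed=seed, n_transcripts=n_trnas,
            biotype_weights={"tRNA": 1.0},
            read_length_model=ReadLengthModel(immaturity_factor=factor,
                                              reads_per_trna=400))
        ref = generate_reference(cfg)
        truth = sample_truth(ref, cfg)
        return simulate_pretrna_lengths(ref, truth, cfg, "no_stress", 1)

    def test_factor_zero_blocks_immature_modification(self):
        df = self._sim(0.0)
        assert not df.loc[df["immature"], "modified"].any()
        assert df.loc[~df["immature"], "modified"].any()

    def test_factor_one_independence(self):
        df = self._sim(1.0)
        rate = df.groupby("immature")["modified"].mean()
        assert abs(rate[True] - rate[False]) < 0.08

    def test_negative_length_modification_coupling(self):
        df = self._sim(0.3)
        per = df.groupby("transcript").agg(mean_len=("length", "mean"),
                                           mod_rate=("modified", "mean"))
        r = np.corrcoef(per["mean_len"], per["mod_rate"])[0, 1]
        assert r < 0

    def test_lengths_positive_and_bounded(self):
        df = self._sim(0.3)
        assert (df["length"] > 0).all()
        assert (df["length"] <= 500).all()


class TestTETable:
    def test_empty_mrna_set(self):
        cfg = SyntheticConfig(seed=41, n_transcripts=6,
                              biotype_weights={"tRNA": 0.5, "rRNA": 0.3,
                                               "ncRNA": 0.2})
        ref = generate_reference(cfg)
        te = generate_te_table(ref, cfg)
        assert te.empty

    def test_enrichment_effect(self):
        from epistress.codons import score_cds_records

        cfg = SyntheticConfig(seed=43, n_transcripts=120,
                              biotype_weights={"mRNA": 0.94, "rRNA": 0.02,
                                               "tRNA": 0.02, "ncRNA": 0.02})
        ref = generate_reference(cfg)
        te = generate_te_table(ref, cfg, effect=2.0)
        scores = score_cds_records(
            {t: ref.cds_sequence(t) for t in ref.transcripts("mRNA")})
        merged = scores.merge(te, on="transcript")
        med = merged.groupby("te_class")["abundance"].median()
        assert med["increased"] > med["decreased"]

    def test_null_effect_classes_similar(self):
        from epistress.codons import score_cds_records

        cfg = SyntheticConfig(seed=44, n_transcripts=150,
                              biotype_weights={"mRNA": 0.94, "rRNA": 0.02,
                                               "tRNA": 0.02, "ncRNA": 0.02})
        ref = generate_reference(cfg)
        te = generate_te_table(ref, cfg, effect=0.0)
        scores = score_cds_records(
            {t: ref.cds_sequence(t) for t in ref.transcripts("mRNA")})
        merged = scores.merge(te, on="transcript")
        med = merged.groupby("te_class")["abundance"].median()
        assert abs(med["increased"] - med["decreased"]) < 0.05
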