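import numpy as np

from m5ckit import riboseq, synthetic_data as sim
from m5ckit.core_io import AlignedRead, TranscriptModel


def _model(seq=None, utr5=30, n_codons=40):
    seq = seq or ("A" * utr5 + "ATG" + "GCT" * (n_codons - 2) + "TAA" + "G" * 120)
    cds_len = 3 * n_codons
    return TranscriptModel("t", "g", "t", "+", seq, utr5, utr5 + cds_len,
                           [(utr5 + cds_len - 3, seq[utr5 + cds_len - 3 : utr5 + cds_len])])


def _read(pos, length=28, contig="t", rid="r"):
    return AlignedRead(rid, contig, pos, "+", length)


# ---------------------------------------------------------------------------
# frame filtering


def test_clean_simulation_passes_frame_filter():
    seqs, models, truth = sim.make_transcriptome(5, motif_fraction=1.0, seed=1)
    fps = sim.simulate_ribo_footprints(truth, models, expression=3, seed=2)
    kept, stats = riboseq.select_periodic_reads(fps, models)
    assert stats.n_bad_frame == 0
    assert stats.n_kept + stats.n_dropped == stats.n_input


def test_low_cds_overlap_dropped():
    m = _model()
    # 27-nt read with only 13 nt inside the CDS (< 50%)
    read = _read(m.cds_start - 14, length=27)
    kept, stats = riboseq.select_periodic_reads([read], [m], expected_frames={27: 0, 28: 0, 29: 0})
    assert not kept
    assert stats.n_low_cds_overlap == 1


def test_wrong_length_dropped():
    m = _model()
    read = _read(m.cds_start, length=33)
    kept, stats = riboseq.select_periodic_reads([read], [m])
    assert stats.n_bad_length == 1


def test_no_cds_transcript_dropped():
    m = TranscriptModel("t", "g", "t", "+", "A" * 100, 0, 0)
    kept, stats = riboseq.select_periodic_reads([_read(10)], [m])
    assert stats.n_no_cds == 1


def test_frame_shuffled_keeps_about_a_third():
    rng = np.random.default_rng(3)
    m = _model(n_codons=60)
    reads = [_read(int(rng.integers(m.cds_start, m.cds_end - 28))) for _ in range(3000)]
    kept, stats = riboseq.select_periodic_reads(reads, [m], expected_frames={28: 0})
    frac = len(kept) / len(reads)
    assert abs(frac - 1 / 3) < 0.05


# ---------------------------------------------------------------------------
# periodicity report


def test_perfect_periodicity():
    seqs, models, truth = sim.make_transcriptome(5, motif_fraction=1.0, seed=4)
    fps = sim.simulate_ribo_footprints(truth, models, expression=3, seed=5)
    rep = riboseq.periodicity_report(fps, models)
    assert set(rep["length"]) == {27, 28, 29}
    assert (rep["dominant_fraction"] == 1.0).all()
    assert (rep["dominant_frame"] == 0).all()


def test_uniform_placement_dominant_about_third():
    rng = np.random.default_rng(6)
    m = _model(n_codons=80)
    reads = [_read(int(rng.integers(m.cds_start, m.cds_end - 28))) for _ in range(6000)]
    rep = riboseq.periodicity_report(reads, [m])
    assert abs(rep["dominant_fraction"].iloc[0] - 1 / 3) < 0.05


def test_empty_input_empty_report():
    assert riboseq.periodicity_report([], [_model()]).empty


# ---------------------------------------------------------------------------
# codon profile


def test_profile_single_read_poly_aaa():
    seq = "AAA" * 30
    m = TranscriptModel("t", "g", "t", "+", seq, 0, 90)
    profile = riboseq.extract_codon_profile([_read(0, 27)], [m])
    assert profile.counts.loc["AAA"].sum() == 9
    assert (profile.counts.loc["AAA"] == 1).all()
    assert profile.counts.drop(index="AAA").to_numpy().sum() == 0


def test_profile_column_sums_equal_reads():
    seqs, models, truth = sim.make_transcriptome(4, motif_fraction=1.0, seed=7)
    fps = sim.simulate_ribo_footprints(truth, models, expression=2, seed=8)
    kept, _ = riboseq.select_periodic_reads(fps, models)
    profile = riboseq.extract_codon_profile(kept, models)
    sums = profile.counts.sum(axis=0)
    assert (sums == profile.n_reads).all()


def test_profile_short_read_skipped():
    m = _model()
    profile = riboseq.extract_codon_profile([_read(m.cds_start, 26)], [m])
    assert profile.n_skipped_short == 1
    assert profile.n_reads == 0


def test_profile_normalization_identities():
    seqs, models, truth = sim.make_transcriptome(6, motif_fraction=1.0, seed=9)
    fps = sim.simulate_ribo_footprints(truth, models, expression=2, seed=10)
    kept, _ = riboseq.select_periodic_reads(fps, models)
    profile = riboseq.extract_codon_profile(kept, models)
    frac = profile.fractions()
    assert np.allclose(frac.sum(axis=0), 1.0)
    norm = profile.normalized()
    means = norm.mean(axis=1).dropna()
    assert np.allclose(means, 1.0)


def test_terminating_footprints_have_stop_at_a_site():
    seqs, models, truth = sim.make_transcriptome(6, motif_fraction=1.0, seed=11)
    fps = sim.simulate_ribo_footprints(truth, models, expression=2, seed=12)
    by_tx = {m.transcript_id: m for m in models}
    stops = {"TAA", "TAG", "TGA"}
    n_term = 0
    for r in fps:
        m = by_tx[r.contig]
        if r.pos + 12 == m.cds_end - 6:  # terminal footprint: P-site on last sense codon
            a_site = m.sequence[r.pos + 15 : r.pos + 18]
            assert a_site in stops
            n_term += 1
    assert n_term > 0


def test_stop_psite_dwell_concentrates_at_minus_one():
    seqs, models, truth = sim.make_transcriptome(6, motif_fraction=1.0, seed=13)
    fps = sim.simulate_ribo_footprints(truth, models, expression=1, stop_psite_dwell=10, seed=14)
    kept, _ = riboseq.select_periodic_reads(fps, models)
    profile = riboseq.extract_codon_profile(kept, models)
    stop_counts = profile.counts.loc[["TAA", "TAG", "TGA"]].sum(axis=0)
    assert stop_counts.idxmax() == -1


# ---------------------------------------------------------------------------
# codon enrichment


def test_enrichment_identity_zero():
    seqs, models, truth = sim.make_transcriptome(4, motif_fraction=1.0, seed=15)
    fps = sim.simulate_ribo_footprints(truth, models, expression=2, seed=16)
    kept, _ = riboseq.select_periodic_reads(fps, models)
    profile = riboseq.extract_codon_profile(kept, models)
    enr = riboseq.codon_enrichment(profile, profile)
    assert np.nanmax(np.abs(enr.to_numpy())) == 0.0


def test_enrichment_antisymmetry():
    seqs, models, truth = sim.make_transcriptome(4, motif_fraction=1.0, seed=17)
    a_reads = sim.simulate_ribo_footprints(truth, models, expression=2, seed=18)
    b_reads = sim.simulate_ribo_footprints(truth, models, expression=2, stop_psite_dwell=6, seed=19)
    pa = riboseq.extract_codon_profile(a_reads, models)
    pb = riboseq.extract_codon_profile(b_reads, models)
    ab = riboseq.codon_enrichment(pa, pb)
    ba = riboseq.codon_enrichment(pb, pa)
    assert np.allclose(ab.to_numpy(), -ba.to_numpy(), equal_nan=True)


def test_enrichment_doubled_stop_dwell_positive_at_p_site():
    seqs, models, truth = sim.make_transcriptome(30, motif_fraction=1.0, seed=20)
    wt = sim.simulate_ribo_footprints(truth, models, expression=3, stop_psite_dwell=3, seed=21)
    ko = sim.simulate_ribo_footprints(truth, models, expression=3, stop_psite_dwell=6, seed=22)
    p_wt = riboseq.extract_codon_profile(riboseq.select_periodic_reads(wt, models)[0], models)
    p_ko = riboseq.extract_codon_profile(riboseq.select_periodic_reads(ko, models)[0], models)
    enr = riboseq.codon_enrichment(p_ko, p_wt)
    for stop in ("TAA", "TAG", "TGA"):
        assert enr.loc[stop, -1] > 0


def test_enrichment_both_zero_is_na():
    pa = riboseq.CodonProfile.empty()
    pb = riboseq.CodonProfile.empty()
    pa.counts.loc["AAA", :] = 10
    pb.counts.loc["AAA", :] = 10
    enr = riboseq.codon_enrichment(pa, pb)
    assert np.isnan(enr.loc["TTT", 0])


# ---------------------------------------------------------------------------
# P-site track


def test_track_offset_arithmetic():
    tracks = riboseq.psite_coverage_track([_read(100, 28)], offset=12)
    assert tracks["+"]["t"] == {112: 1}


def test_track_total_conservation():
    seqs, models, truth = sim.make_transcriptome(3, motif_fraction=1.0, seed=23)
    fps = sim.simulate_ribo_footprints(truth, models, expression=2, seed=24)
    tracks = riboseq.psite_coverage_track(fps)
    total = sum(sum(d.values()) for d in tracks["+"].values())
    assert total == len(fps)


def test_track_minus_strand():
    read = AlignedRead("r", "t", 100, "-", 28)
    tracks = riboseq.psite_coverage_track([read], offset=12)
    assert tracks["-"]["t"] == {100 + 27 - 12: 1}


def test_track_zero_downstream_of_stop():
    seqs, models, truth = sim.make_transcriptome(4, motif_fraction=1.0, seed=25)
    fps = sim.simulate_ribo_footprints(truth, models, expression=2, readthrough_fraction=0.0, seed=26)
    tracks = riboseq.psite_coverage_track(fps, offset=12)
    for m in models:
        per = tracks["+"].get(m.contig, {})
        assert all(pos < m.cds_end for pos in per)


def test_track_offset_beyond_read_skipped():
    tracks = riboseq.psite_coverage_track([_read(0, 10)], offset=12)
    assert tracks["+"] == {}


# ---------------------------------------------------------------------------
# motif position in footprints


def test_motif_positions_zero_without_motif():
    m = _model(seq="A" * 30 + "ATG" + "GCT" * 38 + "TAA" + "G" * 120)
    reads = [_read(35, 28)]
    counts = riboseq.motif_position_counts(reads, [m])
    assert counts["count"].sum() == 0


def test_motif_position_peak_matches_plant():
    # place CTCCA so its first base is the P-site nucleotide (read offset 12)
    seq = "A" * 50 + "CTCCA" + "A" * 50
    m = TranscriptModel("t", "g", "t", "+", seq, 0, 102)
    reads = [_read(50 - 12, 28)]
    counts = riboseq.motif_position_counts(reads, [m])
    assert counts.loc[counts["read_position"] == 13, "count"].iloc[0] == 1  # offset 12 = position 13 (1-based)


def test_motif_position_fractions_bounded():
    seqs, models, truth = sim.make_transcriptome(4, motif_fraction=1.0, seed=27)
    fps = sim.simulate_ribo_footprints(truth, models, expression=2, readthrough_fraction=1.0, seed=28)
    counts = riboseq.motif_position_counts(fps, models)
    assert (counts["fraction"] >= 0).all()
    assert counts["fraction"].max() <= 1.0


def test_compare_motif_positions_columns():
    seqs, models, truth = sim.make_transcriptome(4, motif_fraction=1.0, seed=29)
    wt = sim.simulate_ribo_footprints(truth, models, expression=2, readthrough_fraction=1.0, seed=30)
    ko = sim.simulate_ribo_footprints(truth, models, expression=2, seed=31)
    cmp_df = riboseq.compare_motif_positions(
        riboseq.motif_position_counts(wt, models),
        riboseq.motif_position_counts(ko, models),
    )
    assert {"read_position", "fraction_wt", "fraction_ko", "p", "q"} <= set(cmp_df.columns)
    assert ((cmp_df["p"] >= 0) & (cmp_df["p"] <= 1)).all()
    # BH never lowers a p-value's rank ordering
    assert (cmp_df["q"] >= cmp_df["p"] - 1e-12).all()
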