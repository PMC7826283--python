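from fractions import Fraction

import numpy as np
import pytest

from m5ckit import bsseq, synthetic_data as sim
from m5ckit._align import Hit
from m5ckit.core_io import AlignedRead, SiteRecord

REF = {"c": "AATGCCGATCGATTACGGATCCATTACGCGATAGCATTACGGAT"}


def _convert(seq, keep=()):
    return "".join(
        "C" if (b == "C" and i in keep) else ("T" if b == "C" else b)
        for i, b in enumerate(seq)
    )


# ---------------------------------------------------------------------------
# alignment


def test_fully_converted_read_aligns_zero_mismatches():
    read = _convert(REF["c"][5:30])
    aligned, unaligned = bsseq.align_bs_reads([("r", read)], REF)
    assert not unaligned
    (a,) = aligned
    assert (a.contig, a.pos, a.mismatches) == ("c", 5, 0)


def test_unconverted_c_costs_no_mismatch():
    # one C left unconverted: still 0 mismatches in collapsed space
    first_c = REF["c"].index("C", 5) - 5
    read = "".join(
        "C" if i == first_c else b for i, b in enumerate(_convert(REF["c"][5:30]))
    )
    (a,), unaligned = bsseq.align_bs_reads([("r", read)], REF)
    assert a.mismatches == 0


def test_three_true_mismatches_unaligned():
    frag = list(_convert(REF["c"][5:30]))
    # three non-C/T substitutions (true mismatches even in collapsed space)
    for i in (20, 22, 24):
        frag[i] = "G" if frag[i] != "G" else "A"
    aligned, unaligned = bsseq.align_bs_reads([("r", "".join(frag))], REF, max_mismatches=2)
    assert not aligned
    assert len(unaligned) == 1


def test_bruteforce_collapsed_space_oracle():
    # oracle: scan every offset in collapsed space and count mismatches
    rng = np.random.default_rng(0)
    ref_seq = "".join(rng.choice(list("ACGT"), size=300))
    ref = {"c": ref_seq}
    for _ in range(30):
        start = int(rng.integers(0, 260))
        frag = _convert(ref_seq[start : start + 30])
        aligned, _ = bsseq.align_bs_reads([("r", frag)], ref)
        coll_read = frag.replace("C", "T")
        coll_ref = ref_seq.replace("C", "T")
        matches = [
            (i, sum(a != b for a, b in zip(coll_read, coll_ref[i : i + 30])))
            for i in range(len(coll_ref) - 29)
        ]
        best_mm = min(m for _, m in matches)
        best = [i for i, m in matches if m == best_mm]
        if best_mm <= 2 and len(best) == 1:
            assert aligned and aligned[0].pos == best[0]
        else:
            assert not aligned


# ---------------------------------------------------------------------------
# CCA retry


TRNA_REF = {"t": "NNGGGATCGGATCGGATTACGGATCCGATTACGGATCCA" + "NN"}


def test_cca_trim_rescues_tail_read():
    body = TRNA_REF["t"][2:-5]  # reference body without the CCA tail
    read = _convert(body[-22:]) + "CCA"  # read runs into the CCA tail
    aligned, unaligned = bsseq.align_bs_reads([("r", read)], {"t": body})
    assert not aligned
    rescued, still = bsseq.retry_cca_trim(unaligned, {"t": body})
    assert len(rescued) == 1
    assert rescued[0].read_id.endswith(":ccatrim")


def test_cca_trim_both_passes_fail():
    rescued, still = bsseq.retry_cca_trim([("r", "G" * 30)], REF)
    assert not rescued
    assert still == [("r", "G" * 30)]


def test_cca_trim_short_read_discarded():
    rescued, still = bsseq.retry_cca_trim([("r", "ACGTACGTACGTACGTACGT")], REF)
    # 20 - 3 = 17 < 18: discarded entirely
    assert not rescued and not still


def test_pass_ordering_contract():
    # a read that aligns in pass 1 is never trimmed: pipeline applies retry
    # only to the unaligned output of pass 1
    read = _convert(REF["c"][5:30])
    aligned, unaligned = bsseq.align_bs_reads([("r", read)], REF)
    assert aligned and not unaligned


# ---------------------------------------------------------------------------
# artifact filter


def _read_over(ref, start, length, meth_positions):
    frag = "".join(
        "C" if (b == "C" and (start + i) in meth_positions) else ("T" if b == "C" else b)
        for i, b in enumerate(ref["c"][start : start + length])
    )
    return AlignedRead("r", "c", start, "+", length, 0, frag)


def test_artifact_filter_above_third_discarded():
    ref = {"c": "ACACACACA"}  # 4 Cs in [0, 9)
    read = _read_over(ref, 0, 9, {1, 3})  # 2/4 methylated
    kept, discarded = bsseq.filter_conversion_artifacts([read], ref)
    assert discarded == [read]


def test_artifact_filter_exactly_third_kept():
    ref = {"c": "ACACACAAA"}  # 3 Cs
    read = _read_over(ref, 0, 9, {1})  # exactly 1/3
    kept, discarded = bsseq.filter_conversion_artifacts([read], ref)
    assert kept == [read]


def test_artifact_filter_no_cytosines_kept():
    ref = {"c": "AGATAGATA"}
    read = _read_over(ref, 0, 9, set())
    kept, discarded = bsseq.filter_conversion_artifacts([read], ref)
    assert kept == [read]


def test_simulated_artifacts_all_removed():
    seqs, _, truth = sim.make_transcriptome(3, motif_fraction=1.0, seed=1)
    reads, rt = sim.simulate_bs_reads(
        truth, seqs, coverage=30, conversion_rate=0.995, artifact_fraction=0.1, seed=2
    )
    aligned, _ = bsseq.align_bs_reads(reads, seqs)
    kept, discarded = bsseq.filter_conversion_artifacts(aligned, seqs)
    kept_ids = {r.read_id for r in kept}
    artifacts = set(rt[rt.is_artifact & (rt.n_cytosines >= 2)].read_id)
    assert not (artifacts & kept_ids)
    # conservation: aligned = kept + discarded
    assert len(kept) + len(discarded) == len(aligned)


# ---------------------------------------------------------------------------
# methylation extraction


def test_extract_all_methylated():
    ref = {"c": "ACAAA"}
    reads = [_read_over(ref, 0, 5, {1}) for _ in range(10)]
    counts = bsseq.extract_methylation(reads, ref)
    cc = counts[("c", 1)]
    assert (cc.n_meth, cc.n_unmeth, cc.level) == (10, 0, 1.0)


def test_extract_binomial_level():
    rng = np.random.default_rng(3)
    ref = {"c": "ACAAA"}
    reads = [_read_over(ref, 0, 5, {1} if rng.random() < 0.5 else set()) for _ in range(1000)]
    cc = bsseq.extract_methylation(reads, ref)[("c", 1)]
    assert abs(cc.level - 0.5) < 3 * np.sqrt(0.25 / 1000)


def test_extract_uncovered_absent():
    ref = {"c": "ACAAACAAA"}
    counts = bsseq.extract_methylation([_read_over(ref, 0, 4, set())], ref)
    assert ("c", 5) not in counts


def test_extract_mismatch_not_evidence():
    ref = {"c": "ACAAA"}
    read = AlignedRead("r", "c", 0, "+", 5, 1, "AGAAA")  # G at a ref C
    counts = bsseq.extract_methylation([read], ref)
    assert ("c", 1) not in counts


# ---------------------------------------------------------------------------
# tRNA reference


def test_trna_copy_filter():
    genes = [
        bsseq.TrnaGene("tRNA-Ala-AGC-9-1", "GGGACG"),
        bsseq.TrnaGene("tRNA-Ala-AGC-9-2", "GGGACG"),
    ]
    ref = bsseq.build_trna_reference(genes)
    assert list(ref) == ["tRNA-Ala-AGC-9-1"]


def test_trna_contig_construction():
    ref = bsseq.build_trna_reference([bsseq.TrnaGene("tRNA-Gly-GCC-1-1", "GGGACG")])
    assert ref["tRNA-Gly-GCC-1-1"] == "NNGGGACGCCANN"


def test_trna_intron_splicing_length():
    gene = bsseq.TrnaGene("tRNA-Ile-AAT-1-1", "AAAGGGCCCTTT", introns=[(3, 9)])
    ref = bsseq.build_trna_reference([gene])
    # spliced exons (6) + CCA (3) + 4 Ns
    assert len(ref["tRNA-Ile-AAT-1-1"]) == 6 + 3 + 4
    assert ref["tRNA-Ile-AAT-1-1"] == "NNAAATTTCCANN"


def test_trna_malformed_name_warns_and_keeps():
    with pytest.warns(UserWarning, match="malformed"):
        ref = bsseq.build_trna_reference([bsseq.TrnaGene("weird", "ACGT")])
    assert "weird" in ref


def test_multimapper_min_mismatch_always_wins():
    hits = [Hit("a", 0, 0), Hit("b", 0, 1), Hit("c", 0, 2)]
    for seed in range(20):
        chosen = bsseq.resolve_trna_multimappers({"r": hits}, seed=seed)
        assert chosen["r"].contig == "a"


def test_multimapper_uniform_tiebreak():
    hits = [Hit("a", 0, 0), Hit("b", 0, 0)]
    n_a = sum(
        bsseq.resolve_trna_multimappers({"r": hits}, seed=s)["r"].contig == "a"
        for s in range(10_000)
    )
    assert abs(n_a - 5000) < 3 * np.sqrt(10_000 * 0.25)


def test_multimapper_single_identity():
    hits = [Hit("a", 3, 1)]
    assert bsseq.resolve_trna_multimappers({"r": hits}, seed=0)["r"] == hits[0]


# ---------------------------------------------------------------------------
# site quantification


def test_capping_preserves_fraction():
    ref = {"c": "AACAA"}
    counts = {("c", 2): bsseq.CytosineCounts("c", 2, "+", n_meth=6, n_unmeth=4)}
    sites = [SiteRecord("c", 2, "+")]
    motif_q, other_q = bsseq.quantify_site_methylation(sites, counts, ref)
    (prof,) = other_q.profiles
    m, t = prof.by_offset[0]
    assert (m, t) == (Fraction(3), Fraction(5))
    assert prof.level() == 0.6


def test_shift_and_dedup():
    ref = {"c": "AACTCCAAAAA"}  # motif C at pos 2
    sites = [SiteRecord("c", 1, "+"), SiteRecord("c", 3, "+")]
    shifted = bsseq.shift_sites_to_motif(sites, ref)
    assert len(shifted) == 1
    assert shifted[0].pos == 2


def test_quantify_partitions_by_motif():
    ref = {"c": "AACTCCAAAACAAAA"}  # motif C at 2, plain C at 10
    counts = {
        ("c", 2): bsseq.CytosineCounts("c", 2, "+", 3, 1),
        ("c", 10): bsseq.CytosineCounts("c", 10, "+", 1, 3),
    }
    sites = [SiteRecord("c", 2, "+"), SiteRecord("c", 10, "+")]
    motif_q, other_q = bsseq.quantify_site_methylation(sites, counts, ref)
    assert len(motif_q.profiles) == 1 and motif_q.profiles[0].motif
    assert len(other_q.profiles) == 1 and not other_q.profiles[0].motif
    assert len(motif_q.profiles) + len(other_q.profiles) == len(sites)


def test_no_coverage_flagged():
    ref = {"c": "AACAA"}
    motif_q, other_q = bsseq.quantify_site_methylation([SiteRecord("c", 2, "+")], {}, ref)
    (prof,) = other_q.profiles
    assert prof.no_coverage
    assert np.isnan(prof.level())


def test_capping_property_random_counts():
    # capping never changes a site's methylated fraction (exact rationals)
    rng = np.random.default_rng(4)
    for _ in range(100):
        n = int(rng.integers(1, 50))
        m = int(rng.integers(0, n + 1))
        ref = {"c": "AACAA"}
        counts = {("c", 2): bsseq.CytosineCounts("c", 2, "+", m, n - m)}
        _, other_q = bsseq.quantify_site_methylation([SiteRecord("c", 2, "+")], counts, ref)
        cm, ct = other_q.profiles[0].by_offset[0]
        assert cm / ct == Fraction(m, n)
        assert ct == min(n, 5)


def test_ko_wt_differential(small_transcriptome):
    # motif-site aggregate tracks stoichiometry in WT and ~0 in KO, while
    # non-motif background stays at 1 - conversion_rate in both
    seqs, models, truth = small_transcriptome
    site_records = [SiteRecord(s.transcript_id, s.pos, "+") for s in truth.planted_sites]
    levels = {}
    for label, override in (("wt", None), ("ko", 0.0)):
        reads, _ = sim.simulate_bs_reads(
            truth, seqs, coverage=60, conversion_rate=0.99,
            stoichiometry_override=override, seed=5,
        )
        aligned, _ = bsseq.align_bs_reads(reads, seqs)
        kept, _ = bsseq.filter_conversion_artifacts(aligned, seqs)
        counts = bsseq.extract_methylation(kept, seqs)
        motif_q, _ = bsseq.quantify_site_methylation(site_records, counts, seqs)
        levels[label] = motif_q.aggregate_site_level()
        site_keys = {(s.transcript_id, s.pos) for s in truth.planted_sites}
        bg = [c.level for k, c in counts.items() if k not in site_keys and c.total >= 20]
        assert abs(np.mean(bg) - 0.01) < 0.01
    assert levels["ko"] < 0.05
    assert abs(levels["wt"] - 0.5) < 0.1
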