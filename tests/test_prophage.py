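"""Prophage calling, palindrome scoring, dif detection, conservation, logos."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from capsidkit import prophage as pp
from capsidkit import synth

REVCOMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(REVCOMP)[::-1]


# ---------------------------------------------------------------------------
# palindrome scoring


def test_perfect_palindrome_scores_one():
    assert pp.palindrome_score("GAATTC") == 1.0
    assert pp.palindrome_score(synth.DEFAULT_DIF, spacer=(11, 6)) == 1.0


def test_poly_a_scores_zero():
    assert pp.palindrome_score("A" * 28) == 0.0


def test_ambiguity_codes_count_as_mismatch():
    assert pp.palindrome_score("GANNTC") == pytest.approx(4 / 6)


def test_spacer_positions_excluded():
    # mismatched hexamer centre is invisible when excluded
    seq = "ACGTTCGATAA" + "AAAAAA" + "TTATCGAACGT"
    assert pp.palindrome_score(seq, spacer=(11, 6)) == 1.0
    assert pp.palindrome_score(seq) < 1.0
    with pytest.raises(ValueError):
        pp.palindrome_score("ACGT", spacer=(2, 6))


def test_palindrome_reverse_complement_symmetry(rng):
    """score(s) == score(revcomp(s)) for 1000 random 28-mers."""
    for _ in range(1000):
        s = "".join(rng.choice(list("ACGT"), 28))
        assert pp.palindrome_score(s) == pytest.approx(pp.palindrome_score(revcomp(s)))


# ---------------------------------------------------------------------------
# locus calling


def _hit(query, start, end, strand="+", genome="g1"):
    return pp.HitRecord(query_id=query, genome_id=genome, start=start, end=end, strand=strand, score=50.0)


def test_rep_followed_by_mcp_makes_a_locus():
    loci = pp.call_prophage_loci([_hit("rep_initiator", 1000, 2000), _hit("mcp", 2500, 3200)])
    assert len(loci) == 1
    assert (loci[0].start, loci[0].end) == (1000, 3200)
    assert loci[0].length_flag == "short"


def test_rep_without_nearby_mcp_yields_nothing():
    assert pp.call_prophage_loci([_hit("rep_initiator", 1000, 2000)]) == []
    far = [_hit("rep_initiator", 1000, 2000), _hit("mcp", 50000, 50700)]
    assert pp.call_prophage_loci(far) == []
    wrong_strand = [_hit("rep_initiator", 1000, 2000), _hit("mcp", 2500, 3200, strand="-")]
    assert pp.call_prophage_loci(wrong_strand) == []


def test_minus_strand_synteny_reads_right_to_left():
    loci = pp.call_prophage_loci(
        [_hit("rep_initiator", 5000, 6000, "-"), _hit("mcp", 3000, 3700, "-")]
    )
    assert len(loci) == 1 and loci[0].strand == "-"


def test_overlapping_pairs_resolved_greedily_by_gap():
    hits = [
        _hit("rep_initiator", 1000, 2000),
        _hit("rep_initiator", 2100, 3100),
        _hit("mcp", 3300, 4000),
    ]
    loci = pp.call_prophage_loci(hits)
    assert len(loci) == 1
    assert loci[0].rep_hit.start == 2100  # smaller gap wins
    # input order must not matter
    assert pp.call_prophage_loci(hits[::-1]) == loci


def test_locus_calling_recovers_implanted_cassette_exactly():
    host = synth.gen_genome(60000, 0.305, circular=True, seed=11)
    genome = synth.implant_prophage(host, position=25000, seed=11)
    loci = pp.call_prophage_loci(genome.truth_hits)
    assert len(loci) == 1
    locus = pp.attach_dif_sites(genome.sequence, loci[0], min_score=0.9)
    truth = genome.truth[0]
    assert (locus.start, locus.end) == (truth["start"], truth["end"])
    assert locus.length == 7642
    assert 6021 <= locus.length <= 8407  # the observed prophage size range


# ---------------------------------------------------------------------------
# dif sites


def test_dif_pair_recovered_at_exact_positions():
    host = synth.gen_genome(50000, 0.33, circular=False, seed=2)
    genome = synth.implant_prophage(host, position=20000, seed=2)
    locus = pp.call_prophage_loci(genome.truth_hits)[0]
    up, down = pp.find_dif_sites(genome.sequence, locus, flank=9000, min_score=0.9)
    truth = genome.truth[0]
    assert up.position == truth["dif_upstream"]
    assert down.position == truth["dif_downstream"]
    assert up.sequence == down.sequence == truth["dif_seq"]
    assert len(up.sequence) == 28


def test_dif_decomposition_follows_configured_geometry():
    geometry = pp.DifGeometry()
    assert (geometry.xerc_arm, geometry.spacer, geometry.xerd_arm) == (11, 6, 11)
    host = synth.gen_genome(30000, 0.4, circular=False, seed=3)
    genome = synth.implant_prophage(host, position=10000, seed=3)
    locus = pp.attach_dif_sites(genome.sequence, pp.call_prophage_loci(genome.truth_hits)[0])
    dif = locus.dif_upstream
    assert dif.xerC_arm + dif.central_hexamer + dif.xerD_arm == dif.sequence
    assert len(dif.central_hexamer) == 6


def test_no_false_dif_pairs_in_random_genomes():
    """Empirical null: random genomes yield no high-scoring dif pair."""
    found = 0
    for seed in range(20):
        genome = synth.gen_genome(20000, 0.4, circular=False, seed=300 + seed)
        locus = pp.ProphageLocus(
            genome_id="null", start=9000, end=11000, rep_hit=None, mcp_hit=None
        )
        up, down = pp.find_dif_sites(
            genome.sequence, locus, flank=2000, min_score=0.9, min_pair_identity=0.9
        )
        found += up is not None
    assert found == 0


def test_dif_absence_is_not_an_error():
    locus = pp.ProphageLocus(genome_id="g", start=500, end=900, rep_hit=None, mcp_hit=None)
    # a homopolymer never base-pairs with itself, so no pair can exist
    assert pp.find_dif_sites("A" * 2000, locus, min_score=0.5) == (None, None)


# ---------------------------------------------------------------------------
# conservation


def test_identical_sequences_give_zero_zscores():
    msa = [("a", "MKVLA"), ("b", "MKVLA"), ("c", "MKVLA")]
    prof = pp.conservation_profile(msa, "a")
    assert np.allclose(prof.scores, 0.0)
    assert prof.column_map == {0: 1, 1: 2, 2: 3, 3: 4, 4: 5}


def test_conserved_column_has_maximal_zscore():
    msa = [("a", "MAC"), ("b", "MCA"), ("c", "MGT"), ("d", "MTG")]
    prof = pp.conservation_profile(msa, "a")
    assert np.argmax(prof.scores) == 0
    assert prof.scores.mean() == pytest.approx(0.0, abs=1e-9)
    assert prof.scores.std() == pytest.approx(1.0, abs=1e-9)


def test_reference_gaps_dropped_from_column_map():
    msa = [("ref", "MK-LA"), ("b", "MKVLA")]
    prof = pp.conservation_profile(msa, "ref")
    assert 2 not in prof.column_map
    assert prof.column_map[3] == 3  # L is reference residue 3


def test_conservation_recovers_generator_site_weights():
    """Spearman >= 0.9 between column scores and per-site substitution weights."""
    rng = np.random.default_rng(42)
    cassette = "".join(rng.choice(list("ACGT"), 200))
    family = synth.mutate_family(
        cassette, n=60, sub_rate=0.15, indel_rate=0.0, seed=42, weight_concentration=0.5
    )
    msa = [(f"s{i}", s) for i, s in enumerate(family.truth_alignment)]
    prof = pp.conservation_profile(msa, "s0")
    rho = spearmanr(prof.scores, -family.site_weights).statistic
    assert rho >= 0.9


def test_conservation_contract_errors():
    with pytest.raises(ValueError):
        pp.conservation_profile([("a", "MK")], "a")
    with pytest.raises(ValueError):
        pp.conservation_profile([("a", "MK"), ("b", "MK")], "zzz")
    with pytest.raises(ValueError):
        pp.conservation_profile([("a", "MK"), ("b", "MKV")], "a")


# ---------------------------------------------------------------------------
# structure mapping

_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CA  GLY A   2      12.685   7.004  -4.648  1.00  0.00           C
ATOM      4  CA  VAL A   3      13.715   7.894  -3.905  1.00  0.00           C
ATOM      5  CA  LEU A   9      14.715   8.894  -2.905  1.00  0.00           C
END
"""


def test_map_conservation_to_bfactor_round_trip(tmp_path):
    pdb_in = tmp_path / "model.pdb"
    pdb_in.write_text(_PDB)
    msa = [("ref", "AGV"), ("b", "AGA"), ("c", "AGT")]
    prof = pp.conservation_profile(msa, "ref")
    out = tmp_path / "mapped.pdb"
    mapped = pp.map_conservation_to_model(prof, pdb_in, "A", out)
    assert mapped == 3  # residues 1-3 mapped; residue 9 unmapped

    import gemmi

    st = gemmi.read_structure(str(out))
    b = {res.seqid.num: res[0].b_iso for res in st[0]["A"]}
    for resno in (1, 2, 3):
        assert b[resno] == pytest.approx(float(prof.scores[resno - 1]), abs=0.01)
    assert b[9] == pytest.approx(pp.UNMAPPED_BFACTOR, abs=0.01)


def test_map_conservation_missing_chain(tmp_path):
    pdb_in = tmp_path / "model.pdb"
    pdb_in.write_text(_PDB)
    prof = pp.conservation_profile([("ref", "AGV"), ("b", "AGT")], "ref")
    with pytest.raises(ValueError):
        pp.map_conservation_to_model(prof, pdb_in, "Z", tmp_path / "out.pdb")


# ---------------------------------------------------------------------------
# logos


def test_logo_information_content():
    freq, info = pp.logo_matrix(["AAGC", "AACC", "ATGC", "ATCC"])
    assert info[0] == pytest.approx(2.0)  # invariant column
    assert info[1] == pytest.approx(1.0)  # 50/50 two-letter column
    assert info[2] == pytest.approx(1.0)
    assert freq.shape == (4, 4)
    assert np.allclose(freq.sum(axis=1), 1.0)


def test_logo_equifrequent_column_is_zero_bits():
    _, info = pp.logo_matrix(["A", "C", "G", "T"])
    assert info[0] == pytest.approx(0.0)


def test_logo_rejects_ragged_input():
    with pytest.raises(ValueError):
        pp.logo_matrix(["ACGT", "ACG"])
    with pytest.raises(ValueError):
        pp.logo_matrix(["ACGT"])
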