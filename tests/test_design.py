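"""Tests for guide enumeration/selection, donor construction, in-silico HDR
and fragment assembly."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from transcreen import (
    DesignError,
    DesignRules,
    FrameshiftDonor,
    GuideCandidate,
    OrfRecord,
    UndesignableError,
    assemble_fragment,
    design_deletion_donor,
    design_frameshift_donor,
    design_library,
    enumerate_guides,
    parse_fragment,
    partition_sublibraries,
    random_cds,
    random_orfs,
    reverse_complement,
    select_guide,
    simulate_hdr_edit,
    translate,
)


def _orf(cds, gid="g1", essential=False):
    return OrfRecord(gene_id=gid, chrom="c", start=0, end=len(cds),
                     strand="+", cds_seq=cds, essential=essential)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def test_enumerate_empty_without_pam(rules):
    # A/T-only CDS contains no GG or CC dinucleotide beyond the start codon,
    # hence no NGG PAM on either strand
    cds = "ATG" + "ATA" * 20 + "TAA"
    assert enumerate_guides(_orf(cds), rules) == []


def test_enumerate_matches_sliding_window_oracle(rules):
    rng = np.random.default_rng(11)
    cds = random_cds(120, rng)
    got = {(c.strand, c.span_start, c.protospacer, c.pam)
           for c in enumerate_guides(_orf(cds), rules)}
    expected = set()
    for i in range(len(cds) - 22):
        w = cds[i:i + 23]
        if w[21] == "G" and w[22] == "G":
            expected.add(("+", i, w[:20], w[20:]))
        if w[0] == "C" and w[1] == "C":
            rc = reverse_complement(w)
            expected.add(("-", i, rc[:20], rc[20:]))
    assert got == expected


def test_gc_flag_reflects_50_percent_threshold(rules):
    rng = np.random.default_rng(12)
    cds = random_cds(600, rng)
    cands = enumerate_guides(_orf(cds), rules)
    assert any(c.gc > 0.5 for c in cands)  # fixture exercises both sides
    for c in cands:
        assert c.pass_flags["gc"] == (c.gc <= 0.5)
        assert c.pass_flags["run"] == (c.max_run <= 3)
        assert 0 <= c.position_fraction < 1


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def _cand(frac, cut, proto="ACGTACGTACGTACGTACGT", run=2, gc=0.4, off=5):
    return GuideCandidate(
        gene_id="g", protospacer=proto, pam="AGG", strand="+",
        span_start=cut - 17, cut_site=cut, position_fraction=frac, gc=gc,
        max_run=run, offtarget_min_mismatch=off,
        pass_flags={"gc": gc <= 0.5, "run": run <= 3,
                    "position_q1": frac < 0.25, "offtarget_known": True},
    )


def test_select_prefers_earlier_cut_on_equal_offtarget(rules):
    a, b = _cand(0.10, 100), _cand(0.20, 200)
    chosen = select_guide([b, a], rules)
    assert chosen.cut_site == 100 and chosen.fallback_tier == 0.25


def test_select_maximises_offtarget_distance_first(rules):
    a, b = _cand(0.20, 200, off=8), _cand(0.10, 100, off=3)
    assert select_guide([a, b], rules).cut_site == 200


def test_select_falls_back_to_first_half_when_quarter_fails(rules):
    bad_q1 = [_cand(0.10, 100, run=4), _cand(0.15, 150, run=5)]
    ok_half = _cand(0.40, 400)
    chosen = select_guide(bad_q1 + [ok_half], rules)
    assert chosen.cut_site == 400 and chosen.fallback_tier == 0.5


def test_select_reports_failing_criteria_when_undesignable(rules):
    with pytest.raises(UndesignableError, match="GC"):
        select_guide([_cand(0.1, 100, gc=0.9), _cand(0.2, 200, run=6)], rules)
    with pytest.raises(UndesignableError, match="no PAM"):
        select_guide([], rules)


# ---------------------------------------------------------------------------
# frameshift donors
# ---------------------------------------------------------------------------


def test_emitted_donors_satisfy_frameshift_ptc_and_no_recut(genome50, rules):
    orfs, _, library, _ = genome50
    by_id = {o.gene_id: o for o in orfs}
    assert len(library) > 0
    for row in library.itertuples(index=False):
        orf = by_id[row.gene_id]
        assert len(row.donor_seq) == 165
        assert len(row.replacement) == 22
        assert row.donor_seq == row.left_arm + row.replacement + row.right_arm
        assert row.left_arm in orf.cds_seq and row.right_arm in orf.cds_seq
        donor = SimpleNamespace(left_arm=row.left_arm, right_arm=row.right_arm,
                                replacement=row.replacement,
                                protospacer=row.protospacer)
        edited, report = simulate_hdr_edit(orf.cds_seq, donor)
        assert len(orf.cds_seq) - len(edited) == 1
        assert report.frameshift_bp == 1
        assert report.recut_possible is False
        # PTC strictly before half of the original protein
        assert report.ptc_codon_index is not None
        assert report.ptc_codon_index < 0.5 * len(orf.protein)
        assert report.ptc_codon_index == row.ptc_codon_index


def test_donor_ptc_verified_by_hand_translation(rules):
    rng = np.random.default_rng(13)
    cds = random_cds(300, rng)
    orf = _orf(cds)
    guide = next(
        c for c in enumerate_guides(orf, rules)
        if c.passes_hard_filters and 71 <= c.span_start <= len(cds) - 95
    )
    donor = design_frameshift_donor(orf, guide, rules)
    # oracle: splice by hand and translate the shifted frame codon by codon
    s, e = donor.replaced_span
    edited = cds[:s] + donor.replacement + cds[e:]
    aa = translate(edited)
    assert aa.index("*") == donor.ptc_codon_index
    assert len(edited) == len(cds) - 1


def test_donor_requires_flanking_context(rules):
    rng = np.random.default_rng(14)
    # try genes until one has a hard-pass guide too close to the start
    for _ in range(50):
        cds = random_cds(300, rng)
        orf = _orf(cds)
        early = [c for c in enumerate_guides(orf, rules)
                 if c.passes_hard_filters and c.span_start < 71]
        if early:
            with pytest.raises(DesignError, match="context"):
                design_frameshift_donor(orf, early[0], rules)
            return
    pytest.fail("fixture never produced an early guide")


# ---------------------------------------------------------------------------
# in-silico HDR
# ---------------------------------------------------------------------------


def test_hdr_identity_edit_is_a_noop():
    rng = np.random.default_rng(15)
    locus = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    donor = SimpleNamespace(left_arm=locus[100:140],
                            replacement=locus[140:163],
                            right_arm=locus[163:203])
    edited, report = simulate_hdr_edit(locus, donor)
    assert edited == locus and report.frameshift_bp == 0


def test_hdr_matches_string_splice_oracle_on_random_pairs():
    rng = np.random.default_rng(16)
    done = 0
    while done < 300:
        n = int(rng.integers(120, 400))
        locus = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        i = int(rng.integers(0, n - 80))
        j = int(rng.integers(i + 20, min(i + 60, n - 40)))
        left, right = locus[i:i + 20], locus[j:j + 20]
        if locus.count(left) != 1 or locus.count(right) != 1:
            continue
        repl = "".join("ACGT"[k] for k in rng.integers(0, 4, rng.integers(0, 30)))
        donor = SimpleNamespace(left_arm=left, replacement=repl, right_arm=right)
        edited, report = simulate_hdr_edit(locus, donor)
        oracle = locus[:i + 20] + repl + locus[j:]
        assert edited == oracle
        assert report.frameshift_bp == len(locus) - len(oracle)
        done += 1


def test_hdr_rejects_missing_or_repeated_arms():
    locus = "ATGC" * 50
    with pytest.raises(DesignError, match="not found"):
        simulate_hdr_edit(locus, SimpleNamespace(
            left_arm="TTTTTTTTTT", replacement="", right_arm=locus[100:120]))
    with pytest.raises(DesignError, match="times"):
        simulate_hdr_edit(locus, SimpleNamespace(
            left_arm="ATGCATGCAT", replacement="", right_arm=locus[100:120]))


# ---------------------------------------------------------------------------
# deletion donors
# ---------------------------------------------------------------------------


def _orf_in_contig(rng, cds_len=300, flank=200):
    cds = random_cds(cds_len, rng)
    up = "".join("ACGT"[i] for i in rng.integers(0, 4, flank))
    down = "".join("ACGT"[i] for i in rng.integers(0, 4, flank))
    contig = up + cds + down
    orf = OrfRecord(gene_id="g1", chrom="chr1", start=flank,
                    end=flank + cds_len, strand="+", cds_seq=cds,
                    essential=False)
    return orf, {"chr1": contig}


def test_deletion_donor_removes_orf_exactly(rules):
    rng = np.random.default_rng(17)
    orf, genome = _orf_in_contig(rng)
    donor = design_deletion_donor(orf, genome, rules)
    assert len(donor.seq) == 150
    assert len(donor.up_flank) == len(donor.down_flank) == 75
    edited, report = simulate_hdr_edit(genome["chr1"], donor)
    assert len(edited) == len(genome["chr1"]) - (orf.end - orf.start)
    assert report.frameshift_bp == orf.end - orf.start
    # the two flanks are adjacent in the edited contig (substring oracle)
    assert (donor.up_flank + donor.down_flank) in edited
    assert orf.cds_seq not in edited


def test_deletion_donor_errors_at_contig_edge(rules):
    rng = np.random.default_rng(18)
    orf, _ = _orf_in_contig(rng, flank=10)
    genome = {"chr1": ("".join("ACGT"[i] for i in rng.integers(0, 4, 10))
                       + orf.cds_seq + "ACGTACGTAC")}
    with pytest.raises(DesignError, match="context"):
        design_deletion_donor(orf, genome, rules)


# ---------------------------------------------------------------------------
# fragment assembly and library design
# ---------------------------------------------------------------------------


def test_fragment_lengths_and_roundtrip(genome50, rules):
    _, _, library, _ = genome50
    for row in library.itertuples(index=False):
        assert len(row.core_seq) == 300
        assert len(row.adaptored_seq) - len(row.core_seq) == 43
        parts = parse_fragment(row.core_seq, rules)
        assert parts["guide20"] == row.protospacer
        assert parts["donor_seq"] == row.donor_seq


def test_assemble_reports_length_arithmetic_on_bad_parts(rules, genome50):
    orfs, _, library, _ = genome50
    row = library.iloc[0]
    guide = GuideCandidate(
        gene_id=row.gene_id, protospacer=row.protospacer, pam=row.pam,
        strand=row.strand, span_start=0, cut_site=row.cut_site,
        position_fraction=row.position_fraction, gc=row.gc,
        max_run=row.max_run, offtarget_min_mismatch=None, pass_flags={})
    donor = FrameshiftDonor(
        gene_id=row.gene_id, seq=row.donor_seq, left_arm=row.left_arm,
        right_arm=row.right_arm, replacement=row.replacement,
        replaced_span=(0, 23), ptc_codon_index=row.ptc_codon_index,
        edited_protein_len=row.edited_protein_len,
        protospacer=row.protospacer)
    bad = DesignRules(scaffold_seq="GTTT")  # 4 nt scaffold cannot reach 300
    with pytest.raises(DesignError, match="expected 300"):
        assemble_fragment(guide, donor, bad)


def test_design_library_is_deterministic(small_library, rules):
    orfs, library, qc = small_library
    lib2, qc2 = design_library(orfs, rules)
    pd.testing.assert_frame_equal(library, lib2)
    pd.testing.assert_frame_equal(qc, qc2)


def test_design_library_all_essential_gives_empty_library(rules):
    rng = np.random.default_rng(19)
    orfs = random_orfs(4, rng, cds_length=300, n_essential=4)
    library, qc = design_library(orfs, rules)
    assert library.empty
    assert len(qc) == 4 and (qc["status"] == "skipped_essential").all()


def test_selected_guides_respect_hard_filters(genome50):
    _, _, library, _ = genome50
    assert (library["gc"] <= 0.50).all()
    assert (library["max_run"] <= 3).all()


# ---------------------------------------------------------------------------
# sub-library partitioning
# ---------------------------------------------------------------------------


def test_partition_reproduces_five_class_sizes():
    sizes = {"AD": 73, "SeTS-a": 79, "SeTS-b": 65, "SeTS-c": 84, "other": 60}
    rows = [dict(gene_id=f"G{i}_{cls}", transporter_class=cls)
            for cls, n in sizes.items() for i in range(n)]
    library = pd.DataFrame(rows)
    pools, manifest = partition_sublibraries(library, "transporter_class")
    assert {p: len(df) for p, df in pools.items()} == sizes
    for pool, df in pools.items():
        assert df["mixing_fraction"].sum() == pytest.approx(1.0, abs=1e-12)
    assert len(manifest) == sum(sizes.values())


def test_partition_single_class_and_unknown_label():
    library = pd.DataFrame(dict(gene_id=["a", "b"], cls=["x", "x"]))
    pools, _ = partition_sublibraries(library, "cls")
    assert list(pools) == ["x"] and len(pools["x"]) == 2
    with pytest.raises(KeyError, match="y"):
        partition_sublibraries(
            pd.DataFrame(dict(gene_id=["a"], cls=["y"])), "cls", scheme={"x": "p1"})
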