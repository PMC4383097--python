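"""Locus model: cut-site arithmetic, window construction, donor templates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliquant import (
    HdrTemplate,
    TargetLocus,
    build_reference_window,
    edited_allele,
    locate_cut_site,
    validate_hdr_template,
)
from ampliquant.locus import (
    AmbiguousTargetError,
    TemplateInconsistentError,
    WindowOutOfBoundsError,
    apply_edit,
    insert_in_window_frame,
    load_locus,
    revcomp,
)

from conftest import random_dna


def _embed(rng, offset, strand="+", total=300):
    """Random amplicon with a unique protospacer+NGG target at ``offset``
    (plus-strand coordinates of the protospacer-strand sequence)."""
    while True:
        seq = random_dna(rng, total)
        target = seq[offset : offset + 20] + seq[offset + 20] + "GG"
        seq = seq[:offset] + target + seq[offset + 23 :]
        if seq.count(target) == 1 and revcomp(seq).count(target) == 0:
            amplicon = seq if strand == "+" else revcomp(seq)
            return TargetLocus(
                name="t", protospacer=target[:20], pam=target[20:],
                amplicon=amplicon, strand=strand,
            )


def test_cut_site_is_three_bases_upstream_of_pam(rng):
    """Protospacer at 100..119 with PAM 120..122 cuts at inter-base 117."""
    locus = _embed(rng, offset=100)
    assert locate_cut_site(locus) == 117


def test_cut_site_minimal_amplicon():
    """A 23-nt amplicon (spacer 0..19, PAM 20..22) cuts at 20 - 3 = 17."""
    proto, pam = "ACGTACGTACGTACGTACGA", "TGG"
    locus = TargetLocus("mini", proto, pam, proto + pam)
    assert locate_cut_site(locus) == 17


def test_cut_site_minus_strand_maps_back_to_plus_coordinates(rng):
    """Minus-strand coordinate equals revcomp-then-locate mapped back."""
    locus = _embed(rng, offset=100, strand="-")
    plus_view = TargetLocus(
        "t", locus.protospacer, locus.pam, revcomp(locus.amplicon), "+"
    )
    assert locate_cut_site(locus) == len(locus.amplicon) - locate_cut_site(plus_view)


def test_unlocatable_or_duplicated_target_raises():
    proto, pam = "ACGTACGTACGTACGTACGA", "TGG"
    with pytest.raises(AmbiguousTargetError):
        TargetLocus("x", proto, pam, "A" * 100)
    with pytest.raises(AmbiguousTargetError):
        TargetLocus("x", proto, pam, proto + pam + "TTTT" + proto + pam)


def test_non_ngg_pam_warns_but_builds():
    proto = "ACGTACGTACGTACGTACGA"
    with pytest.warns(UserWarning, match="NGG"):
        TargetLocus("x", proto, "TAA", proto + "TAA")


@settings(deadline=None, derandomize=True, max_examples=25)
@given(flank=st.integers(min_value=0, max_value=50), offset=st.integers(60, 120),
       strand=st.sampled_from("+-"))
def test_window_length_and_cut_alignment(flank, offset, strand):
    """Window is 23+2*flank nt and window[cut] corresponds to the amplicon cut."""
    rng = np.random.default_rng(offset * 100 + flank)
    locus = _embed(rng, offset=offset, strand=strand)
    w = build_reference_window(locus, flank=flank)
    assert len(w.sequence) == 23 + 2 * flank
    assert w.cut_index == flank + 17
    # the window slice around the cut matches the protospacer-strand amplicon
    strand_seq = locus.strand_sequence()
    cut_on_strand = offset + 17
    assert strand_seq[cut_on_strand - w.cut_index : cut_on_strand - w.cut_index + len(w.sequence)] == w.sequence


def test_default_flank_gives_53nt_window(example_locus):
    w = build_reference_window(example_locus)
    assert len(w.sequence) == 53


def test_zero_flank_window_is_the_target(example_locus):
    w = build_reference_window(example_locus, flank=0)
    assert w.sequence == example_locus.target


def test_minus_strand_window_is_revcomp_of_plus_slice(rng):
    locus = _embed(rng, offset=100, strand="-")
    w = build_reference_window(locus, flank=15)
    start = revcomp(locus.amplicon).index(locus.target) - 15
    plus_slice = revcomp(locus.amplicon)[start : start + 53]
    assert w.sequence == plus_slice
    assert revcomp(revcomp(w.sequence)) == w.sequence


def test_insufficient_flank_raises(rng):
    locus = _embed(rng, offset=5)
    with pytest.raises(WindowOutOfBoundsError):
        build_reference_window(locus, flank=15)


# ---------------------------------------------------------------------------
# HDR templates


def make_template(locus, left=60, right=60, insert="AAGCTTGCTAGC", deletion=0,
                  orientation="+"):
    cut = locate_cut_site(locus)
    seq = (locus.amplicon[cut - left : cut] + insert
           + locus.amplicon[cut + deletion : cut + deletion + right])
    if orientation == "-":
        seq = revcomp(seq)
    return HdrTemplate(sequence=seq, orientation=orientation, left_arm=left,
                       right_arm=right, insert=insert, deletion_len=deletion)


def test_template_roundtrip_reports_declared_geometry(example_locus):
    tpl = make_template(example_locus, left=60, right=60, insert="AAGCTTGCTAGC")
    report = validate_hdr_template(tpl, example_locus)
    assert (report.left_arm, report.right_arm) == (60, 60)
    assert report.insert_len == 12
    cut = locate_cut_site(example_locus)
    assert report.edited_allele[cut : cut + 12] == "AAGCTTGCTAGC"
    assert report.edited_allele == edited_allele(example_locus, "AAGCTTGCTAGC")


def test_editless_template_reconstructs_the_amplicon(example_locus):
    tpl = make_template(example_locus, left=40, right=40, insert="", deletion=0)
    report = validate_hdr_template(tpl, example_locus)
    assert report.edit_len == 0
    assert report.edited_allele == example_locus.amplicon


def test_minus_orientation_template_equals_plus_report(example_locus):
    plus = make_template(example_locus, orientation="+")
    minus = make_template(example_locus, orientation="-")
    assert validate_hdr_template(plus, example_locus) == validate_hdr_template(
        minus, example_locus
    )


def test_template_with_deletion_applies_it_downstream_of_cut(example_locus):
    tpl = make_template(example_locus, insert="AAGCTT", deletion=9)
    report = validate_hdr_template(tpl, example_locus)
    cut = locate_cut_site(example_locus)
    amp = example_locus.amplicon
    assert report.edited_allele == amp[:cut] + "AAGCTT" + amp[cut + 9 :]
    assert len(report.edited_allele) == len(amp) + 6 - 9


def test_any_single_arm_corruption_fails(example_locus):
    """Every single-base arm change must be detected (exhaustive, short arms)."""
    tpl = make_template(example_locus, left=8, right=8, insert="AAGCTT")
    seq = tpl.sequence
    for pos in list(range(8)) + list(range(8 + 6, len(seq))):
        mutated = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1 :]
        bad = HdrTemplate(sequence=mutated, left_arm=8, right_arm=8, insert="AAGCTT")
        with pytest.raises(TemplateInconsistentError):
            validate_hdr_template(bad, example_locus)


def test_insert_frame_maps_through_strand(rng):
    plus = _embed(rng, offset=100, strand="+")
    minus = _embed(rng, offset=100, strand="-")
    assert insert_in_window_frame(plus, "AAGCTTGCTAGC") == "AAGCTTGCTAGC"
    assert insert_in_window_frame(minus, "AAGCTTGCTAGC") == "GCTAGCAAGCTT"


def test_load_locus_from_config_mapping(example_locus):
    spec = {
        "name": "cfg", "protospacer": example_locus.protospacer,
        "pam": example_locus.pam, "amplicon": example_locus.amplicon,
        "strand": "+", "expected_insert": "AAGCTTGCTAGC",
    }
    locus, insert = load_locus(spec)
    assert locus.target == example_locus.target
    assert insert == "AAGCTTGCTAGC"


def test_apply_edit_insert_and_delete():
    assert apply_edit("AACCGG", 3, "TTT") == "AACTTTCGG"
    assert apply_edit("AACCGG", 3, "", 2) == "AACG"
    with pytest.raises(ValueError):
        apply_edit("AACC", 3, "", 5)
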