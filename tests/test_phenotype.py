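"""Haplotype-aware antigen inference rules."""

import pytest
from hypothesis import given, settings, strategies as st

from hemotyper.glycophorin import StructuralCall
from hemotyper.io import SampleHaplotypes
from hemotyper.phenotype import (
    infer_abo,
    infer_antithetical,
    infer_duffy,
    infer_lewis,
    infer_mns,
    infer_p1,
    infer_rh_CcEe,
    infer_rh_d,
    predict_all,
)
from hemotyper.rh import RhCnvCall


def haps(sites=None, sample="s"):
    sh = SampleHaplotypes(sample=sample)
    for vid, pair in (sites or {}).items():
        sh.alleles[vid] = pair
        sh.phased[vid] = True
    return sh


def states(calls):
    return {c.antigen: c.state for c in calls}


# --- ABO ------------------------------------------------------------------

@pytest.mark.parametrize(
    "g261, g796, g803, expected",
    [
        # O frameshift in trans to the two B-defining changes -> B
        ((0, 1), (0, 1), (0, 1), {"A": "negative", "B": "positive"}),
        # all three alternates in cis: the B changes ride the O haplotype,
        # the intact haplotype types as A
        ((0, 1), (1, 0), (1, 0), {"A": "positive", "B": "negative"}),
        ((0, 0), (0, 0), (0, 0), {"A": "negative", "B": "negative"}),  # O/O
        ((1, 1), (0, 1), (0, 1), {"A": "positive", "B": "positive"}),  # A/B
    ],
)
def test_infer_abo(g261, g796, g803, expected):
    calls, _ = infer_abo(
        haps({"rs8176719": g261, "rs8176746": g796, "rs8176747": g803})
    )
    assert states(calls) == expected


def test_infer_abo_missing_genotype_no_calls():
    calls, _ = infer_abo(haps({"rs8176719": (-1, -1)}))
    assert states(calls) == {"A": "no-call", "B": "no-call"}


# --- Rh -------------------------------------------------------------------

@pytest.mark.parametrize(
    "zygosity, psi, expected",
    [
        ("homozygous", (0, 0), "positive"),
        ("null", (0, 0), "negative"),
        ("hemizygous", (0, 1), "negative"),  # the one gene copy is the pseudogene
        ("homozygous", (0, 1), "positive"),
        ("null", (1, 1), "no-call"),  # more pseudogene alleles than gene copies
        ("no-call", (0, 0), "no-call"),
    ],
)
def test_infer_rh_d(zygosity, psi, expected):
    assert infer_rh_d(zygosity, psi).state == expected


def _cnv(cc="C+c+", zyg="homozygous"):
    return RhCnvCall("s", zyg, 2.0, cc, 1.0, "modified")


@pytest.mark.parametrize(
    "g676, g602, expected_E, expected_e",
    [
        ((0, 1), (0, 0), "positive", "positive"),
        ((1, 1), (0, 0), "positive", "negative"),
        ((0, 0), (0, 1), "weak-positive", "positive"),  # weak E allele
        ((0, 0), (0, 0), "negative", "positive"),
    ],
)
def test_infer_rh_Ee(g676, g602, expected_E, expected_e):
    calls = infer_rh_CcEe(_cnv(), haps({"rs609320": g676, "rs141398055": g602}))
    s = states(calls)
    assert s["E"] == expected_E and s["e"] == expected_e
    assert s["C"] == "positive" and s["c"] == "positive"


def test_cc_no_call_propagates():
    calls = infer_rh_CcEe(_cnv(cc="no-call"), haps())
    s = states(calls)
    assert s["C"] == "no-call" and s["c"] == "no-call"


# --- antithetical pairs ---------------------------------------------------

@pytest.mark.parametrize(
    "vid, gt, ag_alt, ag_ref, expected",
    [
        ("rs1058396", (0, 1), "Jkb", "Jka", {"Jka": "positive", "Jkb": "positive"}),
        ("rs8176058", (0, 0), "K", "k", {"K": "negative", "k": "positive"}),
        ("rs28399653", (0, 0), "Lua", "Lub", {"Lua": "negative", "Lub": "positive"}),
        ("rs1058396", (1, 1), "Jkb", "Jka", {"Jka": "negative", "Jkb": "positive"}),
    ],
)
def test_infer_antithetical(vid, gt, ag_alt, ag_ref, expected):
    calls = infer_antithetical(haps({vid: gt}), vid, ag_alt, ag_ref, "alt*", "ref*")
    assert states(calls) == expected


def test_antithetical_missing_genotype():
    calls = infer_antithetical(haps({"x": (-1, -1)}), "x", "K", "k", "a", "r")
    assert states(calls) == {"K": "no-call", "k": "no-call"}


# --- Duffy ----------------------------------------------------------------

@pytest.mark.parametrize(
    "g125, gata, fs, weak, expected",
    [
        # both haplotypes Fyb with the GATA change in cis: silent on red cells
        ((1, 1), (1, 1), (0, 0), (0, 0), {"Fya": "negative", "Fyb": "negative"}),
        # Fya without GATA / Fyb with GATA -> Fy(a+b-), forced by cis-silencing
        ((0, 1), (0, 1), (0, 0), (0, 0), {"Fya": "positive", "Fyb": "negative"}),
        # weak Fyb allele in cis on the only expressing haplotype
        ((1, 1), (1, 0), (0, 0), (0, 1), {"Fya": "negative", "Fyb": "weak-positive"}),
        # frameshift null in cis
        ((1, 1), (1, 0), (0, 1), (0, 0), {"Fya": "negative", "Fyb": "negative"}),
    ],
)
def test_infer_duffy(g125, gata, fs, weak, expected):
    sh = haps(
        {"rs12075": g125, "rs2814778": gata, "rs773692057": fs, "rs34599082": weak}
    )
    assert states(infer_duffy(sh)) == expected


# --- Lewis ----------------------------------------------------------------

@pytest.mark.parametrize(
    "g461, g59, g202, g314, g1067, expected",
    [
        # secretor het, 202C/314T in trans: active FUT3 -> Le(a-b+)
        ((0, 1), (0, 0), (0, 1), (1, 0), (0, 0), {"Lea": "negative", "Leb": "positive"}),
        # both FUT3 haplotypes null (202C+314T in cis on each)
        ((0, 0), (0, 0), (1, 1), (1, 1), (0, 0), {"Lea": "negative", "Leb": "negative"}),
        # active FUT3, non-secretor (nonsense on both FUT2 haplotypes)
        ((1, 1), (0, 0), (0, 0), (0, 0), (0, 0), {"Lea": "positive", "Leb": "negative"}),
        # the second null cis pair (59G + 1067A)
        ((0, 0), (1, 1), (0, 0), (0, 0), (1, 1), {"Lea": "negative", "Leb": "negative"}),
    ],
)
def test_infer_lewis(g461, g59, g202, g314, g1067, expected):
    sh = haps(
        {
            "rs601338": g461,
            "rs28362459": g59,
            "rs812936": g202,
            "rs778986": g314,
            "rs3894326": g1067,
        }
    )
    assert states(infer_lewis(sh)) == expected


def test_infer_lewis_missing_fut2_no_calls():
    sh = haps({"rs601338": (-1, -1)})
    assert states(infer_lewis(sh)) == {"Lea": "no-call", "Leb": "no-call"}


# --- MNS ------------------------------------------------------------------

def _mns(g59=(0, 0), g71=(0, 0), g72=(0, 0), g143=(0, 0), he=(0, 0), call="none"):
    sh = haps(
        {
            "rs7682260": g59,
            "rs7687256": g71,
            "rs7658293": g72,
            "rs7683365": g143,
            "rs139511876": he,
        }
    )
    return infer_mns(sh, StructuralCall("s", call))


def test_mns_orientation_fixed_by_reference():
    s = states(_mns())
    assert s["M"] == "negative" and s["N"] == "positive"  # all hom-ref -> M-N+
    s = states(_mns(g59=(1, 1), g71=(1, 1), g72=(1, 1)))
    assert s["M"] == "positive" and s["N"] == "negative"  # all hom-alt -> M+N-


def test_mns_dantu_weak_s():
    s = states(_mns(g143=(1, 0), call="Dantu_het"))
    assert s["S"] == "positive" and s["s"] == "weak-positive"


def test_mns_gypb_deletion_and_he_silencing():
    s = states(_mns(g143=(0, 0), call="GYPB_del_het"))
    assert s["S"] == "negative" and s["s"] == "positive"
    s = states(_mns(call="GYPB_del_hom"))
    assert s["S"] == "negative" and s["s"] == "negative"
    # He(P2) haplotype carrying c.143T: genotyped S allele, silenced expression
    s = states(_mns(g143=(1, 0), he=(1, 0)))
    assert s["S"] == "negative" and s["s"] == "positive"


def test_mns_complex_structural_no_calls_Ss():
    s = states(_mns(call="complex"))
    assert s["S"] == "no-call" and s["s"] == "no-call"
    assert s["M"] == "negative" and s["N"] == "positive"


# --- P1 -------------------------------------------------------------------

def test_p1_consensus_and_alternative_predictor():
    het = haps(
        {"rs5751348": (0, 1), "rs8138197": (0, 1), "rs2143918": (0, 1),
         "rs66781836": (0, 1)}
    )
    assert infer_p1(het).state == "positive"  # one P1-associated haplotype
    hom = haps({"rs5751348": (1, 1), "rs8138197": (1, 1), "rs2143918": (1, 1)})
    assert infer_p1(hom).state == "negative"  # P2
    # the alternative single-SNV predictor runs independently
    assert infer_p1(het, predictor="rs66781836").state == "positive"
    assert infer_p1(haps({"rs66781836": (1, 1)}), predictor="rs66781836").state == "negative"


def test_p1_discordant_sites_without_majority_no_call():
    # only two called sites, voting 1-1 on each haplotype
    sh = haps({"rs5751348": (1, 0), "rs8138197": (0, 1), "rs2143918": (-1, -1)})
    assert infer_p1(sh).state == "no-call"


# --- aggregation ----------------------------------------------------------

def _ref_sample(extra=None):
    sh = haps(extra or {})
    for vid in [
        "rs8176719", "rs8176746", "rs8176747", "rs748783394", "rs609320",
        "rs141398055", "rs8176058", "rs8176059", "rs1058396", "rs12075",
        "rs2814778", "rs34599082", "rs773692057", "rs601338", "rs28362459",
        "rs812936", "rs778986", "rs3894326", "rs28399653", "rs7682260",
        "rs7687256", "rs7658293", "rs7683365", "rs139511876", "rs5751348",
        "rs8138197", "rs2143918", "rs66781836",
    ]:
        sh.alleles.setdefault(vid, (0, 0))
        sh.phased.setdefault(vid, True)
    return sh


def test_predict_all_reference_sample(panel):
    calls, assignments = predict_all(
        _ref_sample(), _cnv(cc="C-c+"), StructuralCall("s", "none"), panel
    )
    assert len(calls) == 24
    s = {c.antigen: c.state for c in calls}
    # all-reference genotypes: O, D+ (two intact copies), K-k+, Jk(a+b-),
    # Fy(a+b-), Le(a-b+), Lu(a-b+), M-N+, S-s+, P1+
    assert s["A"] == s["B"] == "negative"
    assert s["D"] == "positive" and s["K"] == "negative" and s["k"] == "positive"
    assert s["Jka"] == "positive" and s["Jkb"] == "negative"
    assert s["Fya"] == "positive" and s["Fyb"] == "negative"
    assert s["Lea"] == "negative" and s["Leb"] == "positive"
    assert s["M"] == "negative" and s["N"] == "positive"
    assert s["S"] == "negative" and s["s"] == "positive"
    assert s["P1"] == "positive"
    assert len(assignments) == 9
    for c in calls:
        if c.state != "no-call":
            assert c.provenance


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_phase_symmetry(panel, data):
    """Swapping haplotype labels never changes any antigen state."""
    sh = _ref_sample()
    for vid in list(sh.alleles):
        pair = data.draw(
            st.tuples(st.integers(0, 1), st.integers(0, 1)), label=vid
        )
        sh.alleles[vid] = pair
    cnv = _cnv(cc=data.draw(st.sampled_from(["C+c-", "C+c+", "C-c+"])))
    struct = StructuralCall("s", data.draw(st.sampled_from(["none", "Dantu_het"])))
    a, _ = predict_all(sh, cnv, struct, panel)
    b, _ = predict_all(sh.swapped(), cnv, struct, panel)
    assert {(c.antigen, c.state) for c in a} == {(c.antigen, c.state) for c in b}


def test_antithetical_consistency_on_fixture(fixture_result):
    """For the antithetical pairs without null alleles in the panel, every
    called sample is positive for at least one antigen of the pair."""
    for preds in fixture_result.predictions.values():
        for a, b in [("K", "k"), ("Kpa", "Kpb"), ("Jka", "Jkb"), ("Lua", "Lub")]:
            assert preds[a].is_positive or preds[b].is_positive
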