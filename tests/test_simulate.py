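"""Synthetic cohort generator and the published-cohort fixture."""

import hashlib
import json

import numpy as np
import pytest

import hemotyper as ht
from hemotyper.panel import allele_frequency
from hemotyper.pipeline import run_inference
from hemotyper.rh import call_rh_cnv
from hemotyper.simulate import (
    CohortConfig,
    inject_discordance,
    published_fixture,
    sample_cohort,
)

TABLE_ANTIGEN_COUNTS = {
    "A": 24, "B": 17, "D": 92, "C": 69, "c": 71, "E": 23, "e": 98,
    "K": 7, "k": 100, "Kpa": 2, "Kpb": 100, "Jka": 84, "Jkb": 56,
    "Fya": 7, "Fyb": 7, "Lea": 15, "Leb": 69, "Lua": 3, "Lub": 99,
    "M": 94, "N": 59, "S": 63, "s": 81, "P1": 79,
}


def _digests(cohort, tmp_path):
    paths = cohort.write(str(tmp_path))
    return {k: hashlib.sha256(open(p, "rb").read()).hexdigest() for k, p in paths.items()}


def test_identical_seed_and_config_give_byte_identical_outputs(panel, tmp_path):
    a = _digests(sample_cohort(CohortConfig(n=15, seed=7), panel), tmp_path / "a")
    b = _digests(sample_cohort(CohortConfig(n=15, seed=7), panel), tmp_path / "b")
    assert a == b
    c = _digests(sample_cohort(CohortConfig(n=15, seed=8), panel), tmp_path / "c")
    assert a != c


def test_fixture_is_deterministic(panel, tmp_path):
    a = _digests(published_fixture(panel), tmp_path / "a")
    b = _digests(published_fixture(panel), tmp_path / "b")
    assert a == b


def test_config_validation():
    with pytest.raises(ValueError, match="sum"):
        CohortConfig(hap_freqs={"abo": {"O": 0.5, "A": 0.2, "B": 0.2}})


def test_kell_positivity_matches_binomial_expectation(panel):
    """Observed K+ fraction at n=10000 within 3 SD of 1-(1-q)^2, q=0.035."""
    cohort = sample_cohort(CohortConfig(n=10000, seed=1), panel, with_depth=False)
    kpos = np.mean(
        [cohort.truth.phenotypes[s]["K"] == "positive" for s in cohort.samples]
    )
    p = 1 - (1 - 0.035) ** 2
    sd = np.sqrt(p * (1 - p) / 10000)
    assert abs(kpos - p) < 3 * sd


def test_allele_frequencies_recovered_at_n10000(panel):
    """Hardy-Weinberg frequency recovery: estimated AFs converge to the
    configured per-haplotype frequencies (binomial 4-SD check)."""
    cohort = sample_cohort(CohortConfig(n=10000, seed=2), panel, with_depth=False)
    for vid, expected in [
        ("rs601338", 0.405), ("rs1058396", 0.36), ("rs2814778", 0.89),
        ("rs812936", 0.725), ("rs778986", 0.735),
    ]:
        af = allele_frequency(cohort.genotypes, vid)
        sd = np.sqrt(expected * (1 - expected) / 20000)
        assert abs(af - expected) < 4 * sd, vid


def test_mismap_closed_form_ratio(panel):
    """Total mismapping with one conversion haplotype and homozygous RHD:
    the exon-2 coverage ratio lands mid C+c+ band (closed form 2/3)."""
    cohort = sample_cohort(CohortConfig(n=30, seed=5, noise=False), panel)
    hit = False
    for s in cohort.samples:
        hp = cohort.truth.hap_labels[s]
        if sum(x != "d" for x in hp["rhd"]) == 2 and sum(x == "C" for x in hp["rhce_c"]) == 1:
            call = call_rh_cnv(cohort.depth_tracks[s], panel)
            assert call.exon2_ratio == pytest.approx(2 / 3, abs=1e-6)
            assert call.cc_phenotype == "C+c+"
            hit = True
    assert hit


def test_rhd_deletion_homozygote_depth_and_class(panel):
    # deletion-enriched frequencies so del/del donors certainly occur
    freqs = {k: dict(v) for k, v in ht.simulate.DEFAULT_HAP_FREQS.items()}
    freqs["rhd"] = {"D": 0.3, "d": 0.7, "psi": 0.0}
    freqs["rhce_c"] = {"C": 0.2, "c": 0.8}
    cohort = sample_cohort(CohortConfig(n=30, seed=11, noise=False, hap_freqs=freqs), panel)
    hit = False
    for s in cohort.samples:
        if all(x == "d" for x in cohort.truth.hap_labels[s]["rhd"]):
            rh = panel.config["rh"]["rhd_locus"]
            depth = cohort.depth_tracks[s].mean_depth(rh["chrom"], rh["start"], rh["end"])
            assert depth == pytest.approx(0.0, abs=1e-9)
            assert call_rh_cnv(cohort.depth_tracks[s], panel).zygosity == "null"
            hit = True
    assert hit


def test_inject_unknown_mechanism_and_unknown_sample(panel):
    cohort = sample_cohort(CohortConfig(n=4, seed=0), panel, with_depth=False)
    with pytest.raises(ValueError, match="mechanism"):
        inject_discordance(cohort, {"mechanism": "teleportation", "sample": "S00001"})
    with pytest.raises(ValueError, match="sample"):
        inject_discordance(cohort, {"mechanism": "antigen-silencing", "sample": "nope"})


def test_empty_injection_list_leaves_outputs_identical(panel, tmp_path):
    a = _digests(
        sample_cohort(CohortConfig(n=10, seed=3, injections=[]), panel), tmp_path / "a"
    )
    b = _digests(sample_cohort(CohortConfig(n=10, seed=3), panel), tmp_path / "b")
    assert a == b


def test_genotype_miscall_injection(panel, tmp_path):
    """Flipping the VCF genotype at the ABO frameshift makes the pipeline
    predict O while the serology (from truth) stays B."""
    cohort = sample_cohort(CohortConfig(n=20, seed=13), panel)
    target = next(
        s for s in cohort.samples
        if sorted(cohort.truth.hap_labels[s]["abo"]) == ["B", "O"]
    )
    inject_discordance(
        cohort,
        {"mechanism": "genotype-miscall", "sample": target,
         "variant": "rs8176719", "genotype": (0, 0)},
    )
    paths = cohort.write(str(tmp_path))
    res = run_inference(paths["vcf"], paths["depth"], panel)
    assert res.predictions[target]["B"].state == "negative"
    assert cohort.serology.positive(target, "B")


# --- fixture content -------------------------------------------------------

def test_fixture_serology_counts_equal_reported_antigen_frequencies(fixture_serology):
    assert fixture_serology.positive_counts().to_dict() == TABLE_ANTIGEN_COUNTS


def test_fixture_allele_counts(fixture_cohort):
    gt = fixture_cohort.genotypes
    assert allele_frequency(gt, "rs8176058") == pytest.approx(0.035)  # 7 K alleles
    assert allele_frequency(gt, "rs8176719") == pytest.approx(0.21)
    assert allele_frequency(gt, "rs7683365") == pytest.approx(0.415)
    assert allele_frequency(gt, "rs2814778") == pytest.approx(0.89)
    assert allele_frequency(gt, "rs748783394") == pytest.approx(0.035)  # 7 copies
    # structural allele counts: 3 GYPB deletions, 1 Dantu, 2 He(P2)
    labels = fixture_cohort.truth.hap_labels
    assert sum(x == "del" for s in labels for x in labels[s]["gypb"]) == 3
    assert sum(x == "Dantu" for s in labels for x in labels[s]["gypb"]) == 1
    assert allele_frequency(gt, "rs139511876") == pytest.approx(0.01)


def test_fixture_printed_genotypes_of_discordant_donors(fixture_cohort):
    gt = fixture_cohort.genotypes
    i = fixture_cohort.samples.index
    # ABO miscalled donor: het at both B-defining changes, hom-ref at c.261
    assert tuple(gt["rs8176719"][i("18263X61")]) == (0, 0)
    assert sorted(gt["rs8176746"][i("18263X61")]) == [0, 1]
    # Lewis donor: secretor het, 202/314 in trans, 59 hom-ref
    assert sorted(gt["rs601338"][i("18263X9")]) == [0, 1]
    assert tuple(gt["rs28362459"][i("18263X9")]) == (0, 0)
    assert sorted(gt["rs812936"][i("18263X9")]) == [0, 1]
    assert sorted(gt["rs778986"][i("18263X9")]) == [0, 1]
    # Lutheran donor hom-ref at c.230
    assert tuple(gt["rs28399653"][i("18263X34")]) == (0, 0)
    # M/N false negatives hom-ref at the GYPA triple
    for s in ["18263X34", "18263X49", "18263X50", "18273X76", "18263X88"]:
        assert tuple(gt["rs7682260"][i(s)]) == (0, 0)
    assert tuple(gt["rs7682260"][i("18263X32")]) == (1, 1)
    # Dantu carrier het at c.143; the unresolved S/s donor hom-alt
    assert sorted(gt["rs7683365"][i("18263X66")]) == [0, 1]
    assert tuple(gt["rs7683365"][i("18263X86")]) == (1, 1)
    # P1 donor het at all three associated SNVs
    for vid in ["rs5751348", "rs8138197", "rs2143918"]:
        assert sorted(gt[vid][i("18263X75")]) == [0, 1]


def test_fixture_truth_json_round_trips(fixture_paths):
    with open(fixture_paths["truth"]) as fh:
        truth = json.load(fh)
    assert len(truth["phenotypes"]) == 100
    assert len(truth["injections"]) == 13  # 12 discordances; the Lutheran
    # donor's two adjacent candidate SNVs are planted as two records


# --- generator/phenotyper round trip ---------------------------------------

@pytest.mark.parametrize("seed", [3, 11])
def test_round_trip_identity_without_injections(panel, tmp_path, seed):
    """With no injected discordances, the pipeline reproduces generator
    truth for every antigen of every sample."""
    cohort = sample_cohort(CohortConfig(n=50, seed=seed), panel)
    paths = cohort.write(str(tmp_path / str(seed)))
    res = run_inference(paths["vcf"], paths["depth"], panel)
    for s in cohort.samples:
        for ag, call in res.predictions[s].items():
            truth_pos = cohort.truth.phenotypes[s][ag] in ("positive", "weak-positive")
            assert call.is_positive == truth_pos, (s, ag)
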