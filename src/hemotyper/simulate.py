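"""Synthetic cohort generator and the deterministic published-cohort fixture.

Two entry points:

* :func:`sample_cohort` draws a cohort under Hardy-Weinberg equilibrium from
  per-haplotype allele-class frequencies (defaults match the study
  population), with documented cis-linkage: the ABO B-defining changes ride
  one haplotype, the Duffy GATA promoter change rides Fyb haplotypes, and
  the two common FUT3 inactivating changes are anti-correlated across
  haplotypes except on the null haplotype that carries both.

* :func:`published_fixture` builds the fixed 100-donor cohort whose
  serology antigen-positive counts equal the study's antigen frequencies
  and whose 12 discordances (11 donors) are injected exactly as reported,
  including the printed genotypes of the discordant samples, the private
  triage variants (a FUT2 missense, an adjacent SNV pair in a GATA1 site,
  a 5' variant in a STAT1 site) and the copy-number carriers (three GYPB
  deletion heterozygotes, one Dantu carrier).

Depth tracks are generated directly (no read-level simulation): per-window
mean depth is copy-scaled around the configured diploid coverage (default
16x) with negative-binomial read-count noise, and reads from the exon-2
tract of RHCE*C haplotypes are reassigned to RHD exon 2 at the configured
mismap fraction (default 1.0, i.e. total).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DepthTrack, SerologyTable, tile_windows, write_depth, write_serology, write_vcf
from .panel import Panel, load_panel

__all__ = ["CohortConfig", "Cohort", "TruthSet", "sample_cohort", "published_fixture",
           "inject_discordance"]

READ_LENGTH = 150

DEFAULT_HAP_FREQS: dict[str, dict[str, float]] = {
    # per-haplotype class frequencies; each system's classes sum to 1
    "abo": {"O": 0.79, "A": 0.115, "B": 0.095},
    "rhd": {"D": 0.7724, "d": 0.19, "psi": 0.0376},
    "rhce_c": {"C": 0.46, "c": 0.54},
    "rhce_e": {"e": 0.865, "E": 0.12, "Ew": 0.015},
    "kell_k": {"k": 0.965, "K": 0.035},
    "kell_kp": {"b": 0.99, "a": 0.01},
    "kidd": {"a": 0.64, "b": 0.36},
    "duffy": {"Fya": 0.045, "Fyb": 0.045, "FybGATA": 0.89, "FybW": 0.015, "FybFS": 0.005},
    "fut3": {"null": 0.515, "A202": 0.21, "B314": 0.22, "wt": 0.055},
    "fut3_overlay": {"none": 0.81, "59": 0.125, "1067": 0.065},
    "fut2": {"G": 0.595, "A": 0.405},
    "lu": {"b": 0.985, "a": 0.015},
    "gypa": {"M": 0.62, "N59": 0.02, "N": 0.36},
    "gypb": {"S": 0.415, "s": 0.555, "del": 0.015, "He": 0.01, "Dantu": 0.005},
    "p1": {"P1": 0.575, "P2": 0.41, "P2partial": 0.015},
}

SYSTEM_FIELDS = list(DEFAULT_HAP_FREQS)


@dataclass
class CohortConfig:
    n: int = 100
    seed: int = 0
    mean_depth: float = 16.0
    depth_cv: float = 0.15  # per 1600-bp window at diploid coverage
    mismap_fraction: float = 1.0  # RHCE*C exon-2 reads reassigned to RHD exon 2
    hap_freqs: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_HAP_FREQS.items()})
    noise: bool = True
    injections: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for system, freqs in self.hap_freqs.items():
            total = sum(freqs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{system}: haplotype frequencies sum to {total}, not 1")
            if any(not 0 <= f <= 1 for f in freqs.values()):
                raise ValueError(f"{system}: frequencies must lie in [0, 1]")


@dataclass
class TruthSet:
    phenotypes: dict[str, dict[str, str]]
    copy_numbers: dict[str, dict[str, int]]
    hap_labels: dict[str, dict[str, tuple]]
    injections: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# genotype emission: haplotype class labels -> alt-allele indicators


def _fut3_sites(token_set) -> set[str]:
    m = {"202": "rs812936", "314": "rs778986", "59": "rs28362459", "1067": "rs3894326"}
    return {m[t] for t in token_set}


def _hap_alts(field_name: str, label) -> set[str]:
    """Panel variant ids carried (alt) by one haplotype of one system."""
    if field_name == "abo":
        out = set()
        if label != "O":
            out.add("rs8176719")
        if label == "B":
            out |= {"rs8176746", "rs8176747"}
        return out
    if field_name == "rhd":
        return {"rs748783394"} if label == "psi" else set()
    if field_name == "rhce_e":
        out = set()
        if label in ("E", "E2"):
            out.add("rs609320")
        if label in ("E2", "Ew"):
            out.add("rs141398055")
        return out
    if field_name == "kell_k":
        return {"rs8176058"} if label == "K" else set()
    if field_name == "kell_kp":
        return {"rs8176059"} if label == "a" else set()
    if field_name == "kidd":
        return {"rs1058396"} if label == "b" else set()
    if field_name == "duffy":
        out = set()
        if label != "Fya":
            out.add("rs12075")
        if "GATA" in label:
            out.add("rs2814778")
        if label == "FybW":
            out.add("rs34599082")
        if label == "FybFS":
            out.add("rs773692057")
        return out
    if field_name == "fut3":
        if label == "null":
            label = frozenset({"202", "314"})
        elif label == "A202":
            label = frozenset({"202"})
        elif label == "B314":
            label = frozenset({"314"})
        elif label == "wt":
            label = frozenset()
        return _fut3_sites(label)
    if field_name == "fut2":
        return {"rs601338"} if label == "A" else set()
    if field_name == "lu":
        return {"rs28399653"} if label == "a" else set()
    if field_name == "gypa":
        out = set()
        if label in ("M", "N59"):
            out.add("rs7682260")
        if label == "M":
            out |= {"rs7687256", "rs7658293"}
        return out
    if field_name == "gypb":
        out = set()
        if label in ("S", "HeT"):
            out.add("rs7683365")
        if label in ("He", "HeT"):
            out.add("rs139511876")
        return out
    if field_name == "p1":
        out = set()
        if label in ("P2", "P2partial"):
            out |= {"rs8138197", "rs2143918"}
        if label == "P2":
            out.add("rs5751348")
        return out
    if field_name == "rhce_c":
        return set()  # structural; resolved by depth
    raise KeyError(field_name)


GYPB_SNV_SITES = ("rs7683365", "rs139511876")


def _emit_genotypes(samples: Sequence[str], haps: dict[str, list[tuple]],
                    panel: Panel) -> dict[str, np.ndarray]:
    n = len(samples)
    gt = {
        v.id: np.zeros((n, 2), dtype=int)
        for v in panel.snv_indel_variants
    }
    for field_name, pairs in haps.items():
        for i, pair in enumerate(pairs):
            for h, label in enumerate(pair):
                for vid in _hap_alts(field_name, label):
                    gt[vid][i, h] = 1
        if field_name == "gypb":
            # a deleted haplotype yields no reads: the caller reports the
            # remaining haplotype's allele as a homozygous genotype
            for i, pair in enumerate(pairs):
                for h, label in enumerate(pair):
                    if label == "del":
                        other = 1 - h
                        for vid in GYPB_SNV_SITES:
                            gt[vid][i, h] = gt[vid][i, other]
    return gt


# ---------------------------------------------------------------------------
# generator-side truth phenotypes (derived from class labels, not from the
# emitted VCF, so the phenotyper round trip is a genuine cross-check)

POS, WEAK, NEG = "positive", "weak-positive", "negative"


def _truth_phenotype(hp: dict[str, tuple]) -> dict[str, str]:
    ph: dict[str, str] = {}
    abo = hp["abo"]
    ph["A"] = POS if "A" in abo else NEG
    ph["B"] = POS if "B" in abo else NEG
    ph["D"] = POS if any(x == "D" for x in hp["rhd"]) else NEG
    nC = sum(x == "C" for x in hp["rhce_c"])
    ph["C"] = POS if nC >= 1 else NEG
    ph["c"] = POS if nC <= 1 else NEG
    e = hp["rhce_e"]
    strong = any(x in ("E", "E2") for x in e)
    ph["E"] = POS if strong else (WEAK if "Ew" in e else NEG)
    ph["e"] = POS if any(x == "e" for x in e) else NEG
    ph["K"] = POS if "K" in hp["kell_k"] else NEG
    ph["k"] = POS if "k" in hp["kell_k"] else NEG
    ph["Kpa"] = POS if "a" in hp["kell_kp"] else NEG
    ph["Kpb"] = POS if "b" in hp["kell_kp"] else NEG
    ph["Jka"] = POS if "a" in hp["kidd"] else NEG
    ph["Jkb"] = POS if "b" in hp["kidd"] else NEG
    fy = hp["duffy"]
    ph["Fya"] = POS if "Fya" in fy else NEG
    ph["Fyb"] = POS if "Fyb" in fy else (WEAK if "FybW" in fy else NEG)

    def fut3_null(label) -> bool:
        if isinstance(label, frozenset):
            return {"202", "314"} <= label or {"59", "1067"} <= label
        return label == "null"

    active = not all(fut3_null(x) for x in hp["fut3"])
    secretor = "G" in hp["fut2"]
    if not active:
        ph["Lea"], ph["Leb"] = NEG, NEG
    elif secretor:
        ph["Lea"], ph["Leb"] = NEG, POS
    else:
        ph["Lea"], ph["Leb"] = POS, NEG
    ph["Lua"] = POS if "a" in hp["lu"] else NEG
    ph["Lub"] = POS if "b" in hp["lu"] else NEG
    ga = hp["gypa"]
    ph["M"] = POS if "M" in ga else NEG
    ph["N"] = POS if any(x in ("N", "N59") for x in ga) else NEG
    gb = hp["gypb"]
    ph["S"] = POS if "S" in gb else NEG
    ph["s"] = POS if "s" in gb else (WEAK if "Dantu" in gb else NEG)
    p1 = hp["p1"]
    ph["P1"] = POS if "P1" in p1 else NEG
    return ph


# ---------------------------------------------------------------------------
# depth synthesis


def _nb_depth(rng: np.random.Generator | None, mean_depth: np.ndarray, window: int,
              cv: float) -> np.ndarray:
    """Window depths with negative-binomial read-count noise (CV at diploid)."""
    mean_depth = np.asarray(mean_depth, dtype=float)
    if rng is None or cv <= 0:
        return mean_depth
    counts_mean = mean_depth * window / READ_LENGTH
    out = np.zeros_like(mean_depth)
    pos = counts_mean > 0
    m = counts_mean[pos]
    var = (cv * m) ** 2
    sampled = np.empty_like(m)
    over = var > m
    if over.any():
        r = m[over] ** 2 / (var[over] - m[over])
        p = r / (r + m[over])
        sampled[over] = rng.negative_binomial(r, p)
    if (~over).any():
        sampled[~over] = rng.poisson(m[~over])
    out[pos] = sampled * READ_LENGTH / window
    return out


def _in_span(windows: pd.DataFrame, span: dict) -> np.ndarray:
    return (
        (windows["chrom"] == span["chrom"])
        & (windows["start"] >= span["start"])
        & (windows["end"] <= span["end"])
    ).to_numpy()


def _build_depth_tracks(
    samples: Sequence[str],
    haps: dict[str, list[tuple]],
    panel: Panel,
    config: CohortConfig,
    rng: np.random.Generator | None,
) -> dict[str, DepthTrack]:
    rh = panel.config["rh"]
    g = panel.config["glycophorin"]
    window = int(g["window"])
    frames = []
    for span in (rh["rhd_locus"], rh["rhce_locus"], g["flank"], g["region"]):
        frames.append(tile_windows(span["chrom"], span["start"], span["end"], window))
    layout = pd.concat(frames, ignore_index=True)
    is_rhd = _in_span(layout, rh["rhd_locus"])
    is_rhce = _in_span(layout, rh["rhce_locus"])
    is_rhd_ex2 = _in_span(layout, rh["rhd_exon2"])
    is_rhce_ex2 = _in_span(layout, rh["rhce_exon2"])
    in_glyco = _in_span(layout, g["region"]) | _in_span(layout, g["flank"])
    in_del = _in_span(layout, g["gypb_del_span"])
    in_dantu = _in_span(layout, g["dantu_span"])

    m = config.mismap_fraction
    tracks: dict[str, DepthTrack] = {}
    for i, s in enumerate(samples):
        rhd_copies = sum(x != "d" for x in haps["rhd"][i])
        n_c = sum(x == "C" for x in haps["rhce_c"][i])
        del_copies = sum(x == "del" for x in haps["gypb"][i])
        dantu = sum(x == "Dantu" for x in haps["gypb"][i])
        copies = np.full(len(layout), 2.0)
        copies[is_rhd] = rhd_copies
        copies[is_rhd_ex2] = rhd_copies + m * n_c
        copies[is_rhce_ex2] = 2.0 - m * n_c
        copies[in_glyco & in_del] -= del_copies
        copies[in_glyco & in_dantu] += dantu
        mean = copies / 2.0 * config.mean_depth
        df = layout.copy()
        df["depth"] = _nb_depth(rng, mean, window, config.depth_cv)
        tracks[s] = DepthTrack(s, df, window)
    return tracks


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class Cohort:
    samples: list[str]
    panel: Panel
    haps: dict[str, list[tuple]]
    genotypes: dict[str, np.ndarray]
    extra_variants: list[dict]  # each: id, chrom, pos, ref, alt, gt (n,2)
    depth_tracks: dict[str, DepthTrack]
    serology: SerologyTable
    truth: TruthSet

    def vcf_records(self):
        recs = [
            (v.id, v.chrom, v.pos, v.ref, v.alt)
            for v in self.panel.snv_indel_variants
        ]
        gts = dict(self.genotypes)
        for ev in self.extra_variants:
            recs.append((ev["id"], ev["chrom"], ev["pos"], ev["ref"], ev["alt"]))
            gts[ev["id"]] = ev["gt"]
        return recs, gts

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vcf": os.path.join(outdir, "cohort.vcf"),
            "depth": os.path.join(outdir, "depth.tsv"),
            "serology": os.path.join(outdir, "serology.tsv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        recs, gts = self.vcf_records()
        write_vcf(paths["vcf"], self.samples, recs, gts)
        write_depth(paths["depth"], self.depth_tracks)
        write_serology(paths["serology"], self.serology)
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "phenotypes": self.truth.phenotypes,
                    "copy_numbers": self.truth.copy_numbers,
                    "hap_labels": {
                        s: {k: [str(x) for x in v] for k, v in d.items()}
                        for s, d in self.truth.hap_labels.items()
                    },
                    "injections": self.truth.injections,
                },
                fh,
                indent=1,
            )
        return paths


def _derive_serology(
    samples: Sequence[str],
    phenotypes: dict[str, dict[str, str]],
    antigens: Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    grades = pd.DataFrame(0, index=list(samples), columns=list(antigens), dtype=int)
    for s in samples:
        for ag in antigens:
            state = phenotypes[s][ag]
            if state == POS:
                grades.at[s, ag] = int(rng.integers(2, 5))
            elif state == WEAK:
                grades.at[s, ag] = 1
    return grades


def _assemble(
    samples: list[str],
    haps: dict[str, list[tuple]],
    panel: Panel,
    config: CohortConfig,
    depth_rng: np.random.Generator | None,
    serology_rng: np.random.Generator,
    extra_variants: list[dict] | None = None,
    with_depth: bool = True,
) -> Cohort:
    genotypes = _emit_genotypes(samples, haps, panel)
    phenotypes = {
        s: _truth_phenotype({k: haps[k][i] for k in haps}) for i, s in enumerate(samples)
    }
    copy_numbers = {
        s: {
            "rhd": sum(x != "d" for x in haps["rhd"][i]),
            "rhce_conv": sum(x == "C" for x in haps["rhce_c"][i]),
            "gypb": 2 - sum(x == "del" for x in haps["gypb"][i]),
            "dantu": sum(x == "Dantu" for x in haps["gypb"][i]),
        }
        for i, s in enumerate(samples)
    }
    tracks = (
        _build_depth_tracks(samples, haps, panel, config, depth_rng) if with_depth else {}
    )
    grades = _derive_serology(samples, phenotypes, panel.antigen_panel.antigens, serology_rng)
    truth = TruthSet(
        phenotypes=phenotypes,
        copy_numbers=copy_numbers,
        hap_labels={s: {k: haps[k][i] for k in haps} for i, s in enumerate(samples)},
    )
    return Cohort(
        samples=samples,
        panel=panel,
        haps=haps,
        genotypes=genotypes,
        extra_variants=extra_variants or [],
        depth_tracks=tracks,
        serology=SerologyTable(grades),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# random cohorts


def sample_cohort(
    config: CohortConfig, panel: Panel | None = None, with_depth: bool = True
) -> Cohort:
    """Draw a Hardy-Weinberg cohort from per-haplotype class frequencies.

    Haplotypes are sampled independently per sample and per system;
    genotypes are the haplotype pair; depth is copy-scaled negative-binomial
    noise around the configured mean; serology derives from the true
    phenotypes (grade 0 negative, 1 weak, 2-4 positive) before any
    configured discordance injections are applied.  Fully reproducible from
    the seed.
    """
    panel = panel or load_panel()
    rng = np.random.default_rng(config.seed)
    n = config.n
    samples = [f"S{i + 1:05d}" for i in range(n)]
    haps: dict[str, list[tuple]] = {}
    for field_name in SYSTEM_FIELDS:
        if field_name in ("fut3_overlay", "rhce_c"):
            continue
        freqs = config.hap_freqs[field_name]
        labels = list(freqs)
        p = np.array([freqs[l] for l in labels], dtype=float)
        draw = rng.choice(len(labels), size=(n, 2), p=p / p.sum())
        haps[field_name] = [(labels[a], labels[b]) for a, b in draw]
    # RH cis-linkage: the conversion (C) allele rides RHD-intact haplotypes
    # (the classic DCe arrangement); its conditional frequency is chosen so
    # the configured marginal frequency is preserved
    c_marg = config.hap_freqs["rhce_c"]["C"]
    p_intact = config.hap_freqs["rhd"]["D"]
    if c_marg > p_intact:
        raise ValueError(
            "inconsistent linkage spec: conversion frequency exceeds the "
            "RHD-intact haplotype frequency"
        )
    c_cond = c_marg / p_intact
    rhce_c: list[tuple] = []
    for i in range(n):
        pair = []
        for h in range(2):
            if haps["rhd"][i][h] == "D" and rng.random() < c_cond:
                pair.append("C")
            else:
                pair.append("c")
        rhce_c.append(tuple(pair))
    haps["rhce_c"] = rhce_c
    # FUT3 independent overlays (never creating a second null class)
    ofreqs = config.hap_freqs["fut3_overlay"]
    olabels = list(ofreqs)
    op = np.array([ofreqs[l] for l in olabels], dtype=float)
    odraw = rng.choice(len(olabels), size=(n, 2), p=op / op.sum())
    base_tokens = {"null": {"202", "314"}, "A202": {"202"}, "B314": {"314"}, "wt": set()}
    fut3 = []
    for i in range(n):
        pair = []
        for h in range(2):
            tokens = set(base_tokens[haps["fut3"][i][h]])
            ov = olabels[odraw[i, h]]
            if ov != "none":
                tokens.add(ov)
            pair.append(frozenset(tokens))
        fut3.append(tuple(pair))
    haps["fut3"] = fut3

    depth_rng = np.random.default_rng(config.seed + 1) if config.noise else None
    serology_rng = np.random.default_rng(config.seed + 2)
    cohort = _assemble(
        samples, haps, panel, config, depth_rng, serology_rng, with_depth=with_depth
    )
    for spec in config.injections:
        inject_discordance(cohort, spec)
    return cohort


# ---------------------------------------------------------------------------
# discordance injection


def inject_discordance(cohort: Cohort, spec: dict) -> Cohort:
    """Apply one discordance mechanism to a cohort, updating truth labels.

    Mechanisms:

    * ``genotype-miscall`` — overwrite the VCF genotype at one site
      (serology and truth untouched);
    * ``antigen-silencing`` — serology grade 0 for listed antigens;
    * ``weak-expression`` — serology grade 0 for an antigen whose predicted
      expression is weak (below assay sensitivity);
    * ``novel-variant`` — arbitrary serology grades plus a planted private
      variant;
    * ``serology-override`` — arbitrary serology grades, no candidate
      variant (unresolved discordances).
    """
    mech = spec.get("mechanism")
    sample = spec.get("sample")
    known = {"genotype-miscall", "antigen-silencing", "weak-expression",
             "novel-variant", "serology-override"}
    if mech not in known:
        raise ValueError(f"unknown discordance mechanism {mech!r}")
    if sample not in cohort.samples:
        raise ValueError(f"unknown sample {sample!r}")
    i = cohort.samples.index(sample)
    if mech == "genotype-miscall":
        vid = spec["variant"]
        cohort.genotypes[vid][i] = list(spec["genotype"])
    elif mech in ("antigen-silencing", "weak-expression"):
        for ag in spec["antigens"]:
            cohort.serology.grades.at[sample, ag] = 0
    else:
        for ag, grade in spec["grades"].items():
            cohort.serology.grades.at[sample, ag] = int(grade)
        if mech == "novel-variant" and "plant" in spec:
            plant = dict(spec["plant"])
            gt = np.zeros((len(cohort.samples), 2), dtype=int)
            for carrier, pair in plant.pop("carriers").items():
                gt[cohort.samples.index(carrier)] = list(pair)
            plant["gt"] = gt
            cohort.extra_variants.append(plant)
    cohort.truth.injections.append(dict(spec, mechanism=mech))
    return cohort


# ---------------------------------------------------------------------------
# the published-cohort fixture

FIXTURE_SEED = 18263

DISCORDANT = {
    "abo_miscall": "18263X61",
    "lewis": "18263X9",
    "lutheran": "18263X34",
    "mn_false_neg": ["18263X34", "18263X49", "18263X50", "18273X76", "18263X88"],
    "mn_false_pos": "18263X32",
    "dantu": "18263X66",
    "ss_unresolved": "18263X86",
    "p1": "18263X75",
}


def _fixture_samples() -> list[str]:
    return ["18273X76" if i == 76 else f"18263X{i}" for i in range(1, 101)]


def _place(n: int, pinned: dict[int, tuple], pool: list[tuple],
           rng: np.random.Generator) -> list[tuple]:
    """Assign a shuffled pool of hap pairs to the unpinned sample slots."""
    free = [i for i in range(n) if i not in pinned]
    if len(free) != len(pool):
        raise ValueError(f"pool size {len(pool)} != free slots {len(free)}")
    pool = list(pool)
    rng.shuffle(pool)
    out: list[tuple] = [None] * n  # type: ignore[list-item]
    for i, pair in pinned.items():
        out[i] = pair
    for i, pair in zip(free, pool):
        out[i] = pair
    return out


def published_fixture(panel: Panel | None = None) -> Cohort:
    """The deterministic 100-donor cohort mirroring the published study.

    Serology antigen-positive counts equal the reported antigen
    frequencies; panel allele counts match the reported allele frequencies
    over 200 haplotypes where those are integral; the 12 discordances are
    reproduced with the printed genotypes.  Output is byte-identical across
    runs (fixed internal seed).
    """
    panel = panel or load_panel()
    rng = np.random.default_rng(FIXTURE_SEED)
    samples = _fixture_samples()
    n = 100
    idx = {s: i for i, s in enumerate(samples)}
    haps: dict[str, list[tuple]] = {}

    # --- ABO: 24 A+, 17 B+ by serology; the miscalled donor is truly B/O
    x61 = idx[DISCORDANT["abo_miscall"]]
    pool = (
        [("A", "O")] * 22 + [("A", "B")] * 2 + [("B", "O")] * 12
        + [("B", "B")] * 2 + [("O", "O")] * 61
    )
    haps["abo"] = _place(n, {x61: ("O", "B")}, pool, rng)

    # --- Rh: 8 D-negative donors (6 del/del, 2 del/psi); C 69%, c 71%
    rh_pool = (
        [(("D", "D"), ("C", "C"))] * 29
        + [(("D", "D"), ("C", "c"))] * 26
        + [(("D", "D"), ("c", "c"))] * 8
        + [(("d", "D"), ("C", "c"))] * 12
        + [(("d", "D"), ("c", "c"))] * 12
        + [(("psi", "D"), ("C", "c"))] * 2
        + [(("psi", "D"), ("c", "c"))] * 3
        + [(("d", "d"), ("c", "c"))] * 6
        + [(("d", "psi"), ("c", "c"))] * 2
    )
    placed = _place(n, {}, rh_pool, rng)
    haps["rhd"] = [p[0] for p in placed]
    haps["rhce_c"] = [p[1] for p in placed]
    e_pool = (
        [("E", "E")] * 2 + [("E", "e")] * 18 + [("E2", "e")] * 2
        + [("Ew", "e")] * 1 + [("e", "e")] * 77
    )
    haps["rhce_e"] = _place(n, {}, e_pool, rng)

    # --- Kell, Kidd
    haps["kell_k"] = _place(n, {}, [("K", "k")] * 7 + [("k", "k")] * 93, rng)
    haps["kell_kp"] = _place(n, {}, [("a", "b")] * 2 + [("b", "b")] * 98, rng)
    haps["kidd"] = _place(
        n, {}, [("a", "a")] * 44 + [("a", "b")] * 40 + [("b", "b")] * 16, rng
    )

    # --- Duffy: 7 Fy(a+), 7 Fy(b+), pervasive GATA silencing
    fy_pool = (
        [("Fya", "Fya")] * 2 + [("Fya", "FybGATA")] * 5
        + [("Fyb", "Fyb")] * 3 + [("FybW", "FybW")] * 1 + [("FybW", "Fyb")] * 1
        + [("Fyb", "FybGATA")] * 2 + [("FybFS", "FybGATA")] * 1
        + [("FybGATA", "FybGATA")] * 85
    )
    haps["duffy"] = _place(n, {}, fy_pool, rng)

    # --- Lewis: FUT3 null haplotype = c.202C + c.314T in cis; the
    # discordant donor carries the two changes in trans (active FUT3)
    x9 = idx[DISCORDANT["lewis"]]
    f3 = frozenset
    null = f3({"202", "314"})
    a202, b314, wt = f3({"202"}), f3({"314"}), f3(())
    fut3_pool = (
        [(null, null)] * 17
        + [(null, a202)] * 34 + [(null, b314)] * 35
        + [(a202, b314)] * 7 + [(b314, wt)] * 1 + [(wt, wt)] * 5
    )
    fut3 = _place(n, {x9: (a202, b314)}, fut3_pool, rng)
    # place 25 c.59G and 13 c.1067A copies on eligible non-null haplotypes
    slots = [
        (i, h)
        for i in range(n)
        if i != x9
        for h in (0, 1)
        if fut3[i][h] != null
    ]
    rng.shuffle(slots)
    for k, (i, h) in enumerate(slots[:38]):
        token = "59" if k < 25 else "1067"
        pair = list(fut3[i])
        pair[h] = frozenset(set(pair[h]) | {token})
        fut3[i] = tuple(pair)
    haps["fut3"] = fut3
    # FUT2: the 14 non-secretors are active-FUT3 donors; X9 heterozygous
    active = [i for i in range(n) if not (fut3[i][0] >= null and fut3[i][1] >= null)]
    active_unpinned = [i for i in active if i != x9]
    rng.shuffle(active_unpinned)
    nonsec = set(active_unpinned[:14])
    others = [i for i in range(n) if i not in nonsec and i != x9]
    rng.shuffle(others)
    het = set(others[:52])
    fut2 = []
    for i in range(n):
        if i == x9 or i in het:
            fut2.append(("G", "A"))
        elif i in nonsec:
            fut2.append(("A", "A"))
        else:
            fut2.append(("G", "G"))
    haps["fut2"] = fut2

    # --- Lutheran: 3 Lu(a+) heterozygotes; discordant donor is b/b
    x34 = idx[DISCORDANT["lutheran"]]
    haps["lu"] = _place(n, {x34: ("b", "b")}, [("a", "b")] * 3 + [("b", "b")] * 96, rng)

    # --- MNS: GYPA orientation fixed by genotype-phenotype pairs
    x32 = idx[DISCORDANT["mn_false_pos"]]
    mn_pinned = {x32: ("M", "M")}
    for s in DISCORDANT["mn_false_neg"]:
        mn_pinned[idx[s]] = ("N", "N")
    gypa_pool = [("M", "M")] * 41 + [("M", "N")] * 47 + [("N", "N")] * 6
    haps["gypa"] = _place(n, mn_pinned, gypa_pool, rng)

    x66 = idx[DISCORDANT["dantu"]]
    x86 = idx[DISCORDANT["ss_unresolved"]]
    gypb_pool = (
        [("S", "S")] * 18 + [("S", "s")] * 43 + [("del", "s")] * 3
        + [("HeT", "s")] * 1 + [("He", "s")] * 1 + [("s", "s")] * 32
    )
    haps["gypb"] = _place(n, {x66: ("S", "Dantu"), x86: ("S", "S")}, gypb_pool, rng)

    # --- P1: discordant donor heterozygous at all three associated SNVs
    x75 = idx[DISCORDANT["p1"]]
    p1_pool = (
        [("P2", "P2")] * 20 + [("P1", "P2")] * 41 + [("P1", "P2partial")] * 3
        + [("P1", "P1")] * 35
    )
    haps["p1"] = _place(n, {x75: ("P1", "P2")}, p1_pool, rng)
    stat1_other = samples[[i for i in range(n) if haps["p1"][i] == ("P2", "P2")][0]]

    config = CohortConfig(n=n, seed=FIXTURE_SEED, depth_cv=0.10)
    cohort = _assemble(
        samples,
        haps,
        panel,
        config,
        depth_rng=np.random.default_rng(FIXTURE_SEED + 1),
        serology_rng=np.random.default_rng(FIXTURE_SEED + 2),
    )

    x49_grade = np.random.default_rng(FIXTURE_SEED + 3)
    injections = [
        {"mechanism": "genotype-miscall", "sample": DISCORDANT["abo_miscall"],
         "variant": "rs8176719", "genotype": (0, 0),
         "note": "reference-biased undercall of the intact allele"},
        {"mechanism": "novel-variant", "sample": DISCORDANT["lewis"],
         "grades": {"Lea": 2},
         "plant": {"id": "rs373779096", "chrom": "chr19", "pos": 48703959,
                   "ref": "G", "alt": "T",
                   "carriers": {DISCORDANT["lewis"]: (0, 1)}},
         "note": "candidate weak-secretor missense in FUT2"},
        {"mechanism": "novel-variant", "sample": DISCORDANT["lutheran"],
         "grades": {"Lua": 0, "Lub": 0},
         "plant": {"id": "rs533045163", "chrom": "chr11", "pos": 47371006,
                   "ref": "T", "alt": "A",
                   "carriers": {DISCORDANT["lutheran"]: (0, 1)}},
         "note": "adjacent GATA1-site SNVs; candidate In(Lu)"},
        {"mechanism": "novel-variant", "sample": DISCORDANT["lutheran"],
         "grades": {"Lua": 0, "Lub": 0},
         "plant": {"id": "rs184739796", "chrom": "chr11", "pos": 47371007,
                   "ref": "C", "alt": "T",
                   "carriers": {DISCORDANT["lutheran"]: (0, 1)}}},
        {"mechanism": "weak-expression", "sample": DISCORDANT["dantu"],
         "antigens": ["s"],
         "note": "Dantu weak s below assay sensitivity"},
        {"mechanism": "serology-override", "sample": DISCORDANT["ss_unresolved"],
         "grades": {"s": 1}, "note": "unresolved weak s reaction"},
        {"mechanism": "serology-override", "sample": DISCORDANT["mn_false_pos"],
         "grades": {"N": 1}, "note": "unresolved weak N reaction"},
        {"mechanism": "novel-variant", "sample": DISCORDANT["p1"],
         "grades": {"P1": 0},
         "plant": {"id": "A4GALT_5p_STAT1", "chrom": "chr22", "pos": 42721267,
                   "ref": "A", "alt": "C",
                   "carriers": {DISCORDANT["p1"]: (0, 1), stat1_other: (0, 1)}},
         "note": "candidate STAT1-site variant; AC=2"},
    ]
    for s in DISCORDANT["mn_false_neg"]:
        injections.append(
            {"mechanism": "serology-override", "sample": s,
             "grades": {"M": int(x49_grade.integers(2, 5))},
             "note": "unresolved M reaction"}
        )
    for spec in injections:
        inject_discordance(cohort, spec)

    # common (non-candidate) variants so the triage allele-count ceiling is
    # exercised against realistic background
    common_rng = np.random.default_rng(FIXTURE_SEED + 4)
    for cid, chrom, pos, ref, alt, af in [
        ("fut2_common_syn", "chr19", 48703600, "C", "T", 0.2),
        ("bcam_common_intron", "chr19", 44815000, "G", "A", 0.15),
    ]:
        gt = (common_rng.random((n, 2)) < af).astype(int)
        cohort.extra_variants.append(
            {"id": cid, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "gt": gt}
        )
    return cohort
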