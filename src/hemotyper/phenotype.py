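"""Rule engine turning phased genotypes + copy-number calls into antigen calls.

Each inference follows haplotype-resolved logic: a named allele is assigned
to each haplotype of a system and antigen states are aggregated over the
two haplotypes (an antigen is positive when at least one haplotype
expresses it; weak-positive when every expressing haplotype is a weak
allele).  No-calls propagate and are never silently converted.

Antigen states are ``positive``, ``weak-positive``, ``negative`` and
``no-call``; weak-positive counts as positive for concordance purposes.
Every non-no-call carries provenance (the allele names or rule that fired).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .glycophorin import StructuralCall
from .io import SampleHaplotypes
from .panel import Panel
from .rh import RhCnvCall

__all__ = [
    "AntigenCall",
    "HaplotypeAlleleAssignment",
    "infer_abo",
    "infer_rh_d",
    "infer_rh_CcEe",
    "infer_antithetical",
    "infer_duffy",
    "infer_lewis",
    "infer_mns",
    "infer_p1",
    "predict_all",
]

POS = "positive"
WEAK = "weak-positive"
NEG = "negative"
NO_CALL = "no-call"


@dataclass
class AntigenCall:
    sample: str
    antigen: str
    state: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.state != NO_CALL and not self.provenance:
            raise ValueError(f"{self.antigen}: provenance required for {self.state}")

    @property
    def is_positive(self) -> bool | None:
        if self.state == NO_CALL:
            return None
        return self.state in (POS, WEAK)


@dataclass
class HaplotypeAlleleAssignment:
    sample: str
    system: str
    hap1: str
    hap2: str


def _aggregate(sample: str, antigen: str, expressing: list[str], weak: list[str],
               provenance: str) -> AntigenCall:
    """Positive if any haplotype expresses; weak if only weak haplotypes do."""
    if expressing:
        return AntigenCall(sample, antigen, POS, provenance)
    if weak:
        return AntigenCall(sample, antigen, WEAK, provenance)
    return AntigenCall(sample, antigen, NEG, provenance)


# ---------------------------------------------------------------------------
# ABO

def infer_abo(haps: SampleHaplotypes) -> tuple[list[AntigenCall], HaplotypeAlleleAssignment]:
    """ABO phenotype from the O frameshift and the two B-defining changes.

    Per haplotype: the c.261 frameshift (reference allele) silences the
    transferase regardless of other changes (O); an intact haplotype with
    both B-defining substitutions in cis is B; any other intact haplotype is
    A.  The phenotype is the combination of the two haplotype alleles.
    """
    s = haps.sample
    names = []
    for h in (0, 1):
        del261 = haps.get("rs8176719")[h]
        b796 = haps.get("rs8176746")[h]
        b803 = haps.get("rs8176747")[h]
        if min(del261, b796, b803) < 0:
            names.append(None)
        elif del261 == 0:  # reference = frameshift = O
            names.append("ABO*O.01.01")
        elif b796 == 1 and b803 == 1:
            names.append("ABO*B.01")
        else:
            names.append("ABO*A1.01")
    assignment = HaplotypeAlleleAssignment(s, "ABO", names[0] or NO_CALL, names[1] or NO_CALL)
    if None in names:
        return (
            [AntigenCall(s, "A", NO_CALL), AntigenCall(s, "B", NO_CALL)],
            assignment,
        )
    prov = "+".join(sorted(set(names)))
    a = AntigenCall(s, "A", POS if "ABO*A1.01" in names else NEG, prov)
    b = AntigenCall(s, "B", POS if "ABO*B.01" in names else NEG, prov)
    return [a, b], assignment


# ---------------------------------------------------------------------------
# Rh

_ZYG_COPIES = {"null": 0, "hemizygous": 1, "homozygous": 2}


def infer_rh_d(zygosity: str, psi_genotype: tuple[int, int], sample: str = "") -> AntigenCall:
    """D antigen from RHD gene copies minus pseudogene (RHD*08N.01) alleles.

    The pseudogene carries a 37-bp exon-4 insertion introducing a premature
    stop: the gene is present by depth but expresses no D antigen.
    """
    if zygosity not in _ZYG_COPIES:
        return AntigenCall(sample, "D", NO_CALL)
    if min(psi_genotype) < 0:
        return AntigenCall(sample, "D", NO_CALL)
    functional = _ZYG_COPIES[zygosity] - sum(psi_genotype)
    if functional < 0:
        return AntigenCall(sample, "D", NO_CALL)
    if functional >= 1:
        return AntigenCall(sample, "D", POS, "RHD*01")
    prov = "RHD*08N.01" if sum(psi_genotype) else "RHD*01N.01"
    return AntigenCall(sample, "D", NEG, prov)


def infer_rh_CcEe(
    cnv: RhCnvCall, haps: SampleHaplotypes
) -> list[AntigenCall]:
    """C/c copied from the depth-ratio call; E/e from the exon-5 SNVs.

    A haplotype expresses E through c.676C (normal) or c.602C (weak E,
    reported weak-positive); e is expressed by any haplotype carrying
    neither change.
    """
    s = haps.sample
    out: list[AntigenCall] = []
    cc = cnv.cc_phenotype
    if cc == "no-call" or cnv.zygosity == "no-call":
        out += [AntigenCall(s, "C", NO_CALL), AntigenCall(s, "c", NO_CALL)]
    else:
        prov = f"{cnv.method} exon-2 ratio {cnv.exon2_ratio:.2f}"
        out.append(AntigenCall(s, "C", POS if cc.startswith("C+") else NEG, prov))
        out.append(AntigenCall(s, "c", POS if cc.endswith("c+") else NEG, prov))

    e676 = haps.get("rs609320")
    e602 = haps.get("rs141398055")
    if min(e676) < 0 or min(e602) < 0:
        out += [AntigenCall(s, "E", NO_CALL), AntigenCall(s, "e", NO_CALL)]
        return out
    strong = [h for h in (0, 1) if e676[h] == 1]
    weak = [h for h in (0, 1) if e602[h] == 1 and e676[h] == 0]
    little_e = [h for h in (0, 1) if e676[h] == 0 and e602[h] == 0]
    out.append(
        _aggregate(s, "E", [f"hap{h}" for h in strong], [f"hap{h}" for h in weak],
                   "RHCE*E" if strong else ("RHCE*Ew" if weak else "RHCE*e"))
    )
    out.append(
        AntigenCall(s, "e", POS if little_e else NEG, "RHCE*e" if little_e else "RHCE*E")
    )
    return out


# ---------------------------------------------------------------------------
# simple antithetical systems (Kell, Kidd, Lutheran)

def infer_antithetical(
    haps: SampleHaplotypes,
    vid: str,
    antigen_alt: str,
    antigen_ref: str,
    allele_alt: str,
    allele_ref: str,
) -> list[AntigenCall]:
    """Two antigen calls from one biallelic SNV with declared orientation.

    Heterozygotes are positive for both antigens; homozygotes are positive
    for one and negative for the antithetical partner.  A missing genotype
    no-calls both.
    """
    s = haps.sample
    gt = haps.get(vid)
    if min(gt) < 0:
        return [AntigenCall(s, antigen_alt, NO_CALL), AntigenCall(s, antigen_ref, NO_CALL)]
    n_alt = sum(gt)
    prov = f"{allele_alt}/{allele_ref}"
    return [
        AntigenCall(s, antigen_alt, POS if n_alt >= 1 else NEG, prov),
        AntigenCall(s, antigen_ref, POS if n_alt <= 1 else NEG, prov),
    ]


# ---------------------------------------------------------------------------
# Duffy

def infer_duffy(haps: SampleHaplotypes) -> list[AntigenCall]:
    """Fya/Fyb with cis-acting GATA silencing, frameshift null and weak allele.

    Per haplotype: antigen identity from c.125 (ref = Fya, alt = Fyb); the
    erythroid GATA promoter change in cis silences red-cell expression of
    that haplotype; the c.179_180del frameshift nulls it; c.265C in cis
    weakens it.  An antigen is positive when at least one haplotype
    expresses it.
    """
    s = haps.sample
    sites = ["rs12075", "rs2814778", "rs773692057", "rs34599082"]
    if any(min(haps.get(v)) < 0 for v in sites):
        return [AntigenCall(s, "Fya", NO_CALL), AntigenCall(s, "Fyb", NO_CALL)]
    expressing: dict[str, list[str]] = {"Fya": [], "Fyb": []}
    weak: dict[str, list[str]] = {"Fya": [], "Fyb": []}
    names = []
    for h in (0, 1):
        antigen = "Fya" if haps.get("rs12075")[h] == 0 else "Fyb"
        gata = haps.get("rs2814778")[h] == 1
        null = haps.get("rs773692057")[h] == 1
        weak_site = haps.get("rs34599082")[h] == 1
        if null:
            names.append("FY*02N.02" if antigen == "Fyb" else "FY*01N")
        elif gata:
            names.append("FY*02N.01" if antigen == "Fyb" else "FY*01N.01")
        elif weak_site:
            names.append("FY*02W.01")
            weak[antigen].append(f"hap{h}")
        else:
            names.append("FY*01" if antigen == "Fya" else "FY*02")
            expressing[antigen].append(f"hap{h}")
    prov = "+".join(names)
    return [
        _aggregate(s, "Fya", expressing["Fya"], weak["Fya"], prov),
        _aggregate(s, "Fyb", expressing["Fyb"], weak["Fyb"], prov),
    ]


# ---------------------------------------------------------------------------
# Lewis

FUT3_NULL_CIS = (("rs812936", "rs778986"), ("rs28362459", "rs3894326"))


def infer_lewis(
    haps: SampleHaplotypes,
    null_cis: tuple[tuple[str, str], ...] = FUT3_NULL_CIS,
    weak_secretor_ids: tuple[str, ...] = (),
) -> list[AntigenCall]:
    """Lewis phenotype from FUT3 haplotype activity and FUT2 secretor status.

    A FUT3 haplotype is null when it carries a configured cis pair of
    inactivating changes; FUT3 is active with at least one non-null
    haplotype.  Secretor status comes from FUT2 c.461 (the nonsense change;
    at least one intact haplotype = secretor).  Active + secretor gives
    Le(a-b+), active + non-secretor Le(a+b-), FUT3 null Le(a-b-); a weak
    secretor allele (panel extension) yields Le(a+b+).
    """
    s = haps.sample
    fut3_sites = sorted({v for pair in null_cis for v in pair})
    fut2 = haps.get("rs601338")
    if min(fut2) < 0:
        return [AntigenCall(s, "Lea", NO_CALL), AntigenCall(s, "Leb", NO_CALL)]
    if any(min(haps.get(v)) < 0 for v in fut3_sites):
        return [AntigenCall(s, "Lea", NO_CALL), AntigenCall(s, "Leb", NO_CALL)]

    def hap_null(h: int) -> bool:
        return any(all(haps.get(v)[h] == 1 for v in pair) for pair in null_cis)

    active = not (hap_null(0) and hap_null(1))
    secretor_haps = [h for h in (0, 1) if fut2[h] == 0]
    weak_secretor = bool(secretor_haps) and all(
        any(haps.get(w)[h] == 1 for w in weak_secretor_ids) for h in secretor_haps
    ) and weak_secretor_ids

    fut3_prov = "FUT3*01" if active else "FUT3 null (both haplotypes)"
    fut2_prov = "FUT2*01" if secretor_haps else "FUT2*01N.02"
    prov = f"{fut3_prov}+{fut2_prov}"
    if not active:
        return [AntigenCall(s, "Lea", NEG, prov), AntigenCall(s, "Leb", NEG, prov)]
    if not secretor_haps:
        return [AntigenCall(s, "Lea", POS, prov), AntigenCall(s, "Leb", NEG, prov)]
    if weak_secretor:
        return [
            AntigenCall(s, "Lea", POS, prov + "+weak-secretor"),
            AntigenCall(s, "Leb", POS, prov + "+weak-secretor"),
        ]
    return [AntigenCall(s, "Lea", NEG, prov), AntigenCall(s, "Leb", POS, prov)]


# ---------------------------------------------------------------------------
# MNS

def infer_mns(
    haps: SampleHaplotypes, structural: StructuralCall | None
) -> list[AntigenCall]:
    """M/N from the GYPA triple; S/s from GYPB c.143 with structural overlay.

    Orientation is fixed by observed genotype-phenotype pairs: all-reference
    GYPA haplotypes carry N, all-alternate carry M.  GYPB haplotypes express
    S (c.143 alt) or s (ref) unless silenced by the He(P2) splice change in
    cis, removed by the GYPB deletion, or replaced by the Dantu hybrid
    (which expresses s weakly).
    """
    s = haps.sample
    out: list[AntigenCall] = []
    gypa = [haps.get(v) for v in ("rs7682260", "rs7687256", "rs7658293")]
    if any(min(g) < 0 for g in gypa):
        out += [AntigenCall(s, "M", NO_CALL), AntigenCall(s, "N", NO_CALL)]
    else:
        hap_m = [all(g[h] == 1 for g in gypa) for h in (0, 1)]
        prov = "+".join("GYP*M" if m else "GYP*N" for m in hap_m)
        out.append(AntigenCall(s, "M", POS if any(hap_m) else NEG, prov))
        out.append(AntigenCall(s, "N", POS if not all(hap_m) else NEG, prov))

    call = structural.call if structural is not None else "none"
    if call == "complex":
        out += [AntigenCall(s, "S", NO_CALL), AntigenCall(s, "s", NO_CALL)]
        return out
    s143 = haps.get("rs7683365")
    he = haps.get("rs139511876")
    if min(s143) < 0 or min(he) < 0:
        out += [AntigenCall(s, "S", NO_CALL), AntigenCall(s, "s", NO_CALL)]
        return out

    if call == "GYPB_del_hom":
        out.append(AntigenCall(s, "S", NEG, "GYPB*05N.01 x2"))
        out.append(AntigenCall(s, "s", NEG, "GYPB*05N.01 x2"))
        return out

    # expressed GYPB haplotypes: drop one for a het deletion (the VCF
    # genotype at c.143 is then the remaining haplotype, called homozygous)
    hap_ids = [0, 1]
    prov_parts = []
    if call == "GYPB_del_het":
        if s143[0] != s143[1]:
            out += [AntigenCall(s, "S", NO_CALL), AntigenCall(s, "s", NO_CALL)]
            return out
        hap_ids = [0]
        prov_parts.append("GYPB*05N.01")
    expressing_S: list[str] = []
    expressing_s: list[str] = []
    weak_s: list[str] = []
    for h in hap_ids:
        if he[h] == 1:
            prov_parts.append("GYP.He(P2)")
            continue  # silences both S and s from this haplotype
        if s143[h] == 1:
            expressing_S.append(f"hap{h}")
            prov_parts.append("GYPB*S")
        else:
            expressing_s.append(f"hap{h}")
            prov_parts.append("GYPB*s")
    if call == "Dantu_het":
        # hybrid haplotype expresses s weakly; it contributes no S
        weak_s.append("Dantu")
        prov_parts.append("GYP*Dantu")
        if expressing_s:
            # the c.143-ref haplotype is the hybrid itself
            expressing_s.pop()
    prov = "+".join(prov_parts) if prov_parts else "GYPB silent"
    out.append(_aggregate(s, "S", expressing_S, [], prov))
    out.append(_aggregate(s, "s", expressing_s, weak_s, prov))
    return out


# ---------------------------------------------------------------------------
# P1

P1_CONSENSUS_SITES = ("rs5751348", "rs8138197", "rs2143918")


def infer_p1(
    haps: SampleHaplotypes, predictor: str = "consensus"
) -> AntigenCall:
    """P1 from the three associated intronic SNVs (or a single alternative).

    With the default consensus predictor a haplotype is P1-expressing when
    the majority of the three sites carry the reference (P1-associated)
    allele; P1 is positive with at least one expressing haplotype.  The
    alternative predictor (e.g. rs66781836) uses that site alone and is
    reported separately.
    """
    s = haps.sample
    if predictor == "consensus":
        gts = [haps.get(v) for v in P1_CONSENSUS_SITES]
        called = [g for g in gts if min(g) >= 0]
        if not called:
            return AntigenCall(s, "P1", NO_CALL)
        p1_hap = []
        for h in (0, 1):
            votes = [g[h] for g in called]
            n_alt = sum(votes)
            if 2 * n_alt == len(votes):  # discordant with no majority
                return AntigenCall(s, "P1", NO_CALL)
            p1_hap.append(n_alt * 2 < len(votes))
        state = POS if any(p1_hap) else NEG
        return AntigenCall(s, "P1", state, "P1PK*P1" if any(p1_hap) else "P1PK*P2")
    gt = haps.get(predictor)
    if min(gt) < 0:
        return AntigenCall(s, "P1", NO_CALL)
    return AntigenCall(
        s, "P1", POS if 0 in gt else NEG, f"{predictor} predictor"
    )


# ---------------------------------------------------------------------------
# aggregation

def assign_alleles(haps: SampleHaplotypes, panel: Panel) -> list[HaplotypeAlleleAssignment]:
    """Name the most specific matching panel allele on each haplotype."""
    out = []
    for system in panel.antigen_panel.systems:
        candidates = panel.alleles_of(system)
        names = []
        for h in (0, 1):
            hap = haps.hap(h)
            matches = [a for a in candidates if a.matches(hap)]
            if not matches:
                names.append(NO_CALL)
            else:
                names.append(max(matches, key=lambda a: len(a.requires)).name)
        out.append(HaplotypeAlleleAssignment(haps.sample, system, names[0], names[1]))
    return out


def predict_all(
    haps: SampleHaplotypes,
    rh_cnv: RhCnvCall,
    structural: StructuralCall | None,
    panel: Panel,
    p1_predictor: str = "consensus",
) -> tuple[list[AntigenCall], list[HaplotypeAlleleAssignment]]:
    """All 24 antigen calls for one sample, plus haplotype allele names.

    Deterministic aggregation of the per-system inferences; errors inside a
    system become no-calls for its antigens, never silent conversions.
    """
    abo_calls, _ = infer_abo(haps)
    calls: list[AntigenCall] = list(abo_calls)
    calls.append(infer_rh_d(rh_cnv.zygosity, haps.get("rs748783394"), haps.sample))
    calls += infer_rh_CcEe(rh_cnv, haps)
    calls += infer_antithetical(haps, "rs8176058", "K", "k", "KEL*01.01", "KEL*02")
    calls += infer_antithetical(haps, "rs8176059", "Kpa", "Kpb", "KEL*02.03", "KEL*02.04")
    calls += infer_antithetical(haps, "rs1058396", "Jkb", "Jka", "JK*02", "JK*01")
    calls += infer_duffy(haps)
    calls += infer_lewis(haps)
    calls += infer_antithetical(haps, "rs28399653", "Lua", "Lub", "LU*01", "LU*02")
    calls += infer_mns(haps, structural)
    calls.append(infer_p1(haps, predictor=p1_predictor))

    order = {ag: i for i, ag in enumerate(panel.antigen_panel.antigens)}
    calls.sort(key=lambda c: order[c.antigen])
    return calls, assign_alleles(haps, panel)
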