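"""Serology-vs-genotype concordance statistics and discordance triage.

Two accuracies are computed, with serology as truth:

* antigen prediction accuracy — the percentage of donors whose expression
  of one antigen is predicted correctly;
* blood-group (system) prediction accuracy — the percentage of donors whose
  *entire* system phenotype is correct (every tested antigen matches).

The headline figure is the unweighted mean of the nine system accuracies,
reported to one decimal.  Weak-positive counts as positive on both sides;
predicted no-calls count as incorrect.  Discordances are enumerated one per
donor-subsystem (M/N and S/s are separate subsystems within MNS) and
classified as false negatives (serology positive, genotype negative) or
false positives.

Triage scans the full VCF for rare private variants — in the discordant
system's gene bodies or in supplied regulatory intervals (e.g. erythroid
transcription-factor binding sites) — that the discordant donor carries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .io import SerologyTable, read_bed, trim_variant
from .panel import Panel
from .phenotype import AntigenCall

__all__ = [
    "Discordance",
    "ConcordanceReport",
    "TriageCandidate",
    "antigen_accuracy",
    "system_accuracy",
    "summarize",
    "triage_discordance",
]

Predictions = Mapping[str, Mapping[str, AntigenCall]]


@dataclass
class Discordance:
    sample: str
    system: str
    subsystem: str
    serology_phenotype: str
    predicted_phenotype: str
    direction: str  # false-negative | false-positive | no-call


@dataclass
class ConcordanceReport:
    n_samples: int
    antigen_accuracy: dict[str, float]
    system_accuracy: dict[str, float]
    average_system_accuracy: float
    discordances: list[Discordance] = field(default_factory=list)

    @property
    def n_discordant_samples(self) -> int:
        return len({d.sample for d in self.discordances})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": d.sample,
                "system": d.system,
                "subsystem": d.subsystem,
                "serology": d.serology_phenotype,
                "predicted": d.predicted_phenotype,
                "direction": d.direction,
            }
            for d in self.discordances
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_samples": self.n_samples,
                "antigen_accuracy": self.antigen_accuracy,
                "system_accuracy": self.system_accuracy,
                "average_system_accuracy": self.average_system_accuracy,
                "n_discordances": len(self.discordances),
                "n_discordant_samples": self.n_discordant_samples,
                "discordances": [vars(d) for d in self.discordances],
            },
            indent=2,
        )


def _round1(x: float) -> float:
    return math.floor(x * 10 + 0.5) / 10


def _match(call: AntigenCall, grade: int) -> bool:
    pred = call.is_positive
    if pred is None:  # no-call counts as incorrect
        return False
    return pred == (grade > 0)


def _overlap_samples(predictions: Predictions, serology: SerologyTable) -> list[str]:
    samples = [s for s in serology.samples if s in predictions]
    if not samples:
        raise ValueError("no overlapping samples between predictions and serology")
    return samples


def antigen_accuracy(
    predictions: Predictions, serology: SerologyTable, antigen: str
) -> float:
    """Percent of donors with this antigen's expression correctly predicted."""
    samples = _overlap_samples(predictions, serology)
    correct = sum(
        _match(predictions[s][antigen], serology.grades.at[s, antigen]) for s in samples
    )
    return 100.0 * correct / len(samples)


def system_accuracy(
    predictions: Predictions, serology: SerologyTable, system: str, panel: Panel
) -> float:
    """Percent of donors with the whole system phenotype correct."""
    antigens = panel.antigens_of(system)
    tested = [a for a in antigens if a in serology.grades.columns]
    if not tested:
        raise ValueError(f"no serology for system {system}")
    samples = _overlap_samples(predictions, serology)
    correct = 0
    for s in samples:
        if all(_match(predictions[s][a], serology.grades.at[s, a]) for a in tested):
            correct += 1
    return 100.0 * correct / len(samples)


def _phenotype_string(antigens: Sequence[str], positives: Sequence[bool | None]) -> str:
    if list(antigens) == ["A", "B"]:
        a, b = positives
        if a and b:
            return "AB"
        if a:
            return "A"
        if b:
            return "B"
        return "O"
    if list(antigens) == ["P1"]:
        return "P1" if positives[0] else "P2"
    parts = []
    for ag, p in zip(antigens, positives):
        mark = "?" if p is None else ("+" if p else "-")
        parts.append(f"{ag}{mark}")
    return "".join(parts)


def summarize(
    predictions: Predictions, serology: SerologyTable, panel: Panel
) -> ConcordanceReport:
    """Full concordance report over the nine systems.

    The average is the unweighted mean of the nine system accuracies,
    rounded to one decimal; per-antigen and per-system accuracies are
    reported unrounded.  Discordances are listed one per donor-subsystem.
    """
    samples = _overlap_samples(predictions, serology)
    systems = panel.antigen_panel.systems
    sys_acc = {
        system: system_accuracy(predictions, serology, system, panel)
        for system in systems
    }
    ag_acc = {
        ag: antigen_accuracy(predictions, serology, ag)
        for ag in panel.antigen_panel.antigens
    }
    average = _round1(sum(sys_acc.values()) / len(sys_acc))

    discordances: list[Discordance] = []
    for s in samples:
        for system in systems:
            for group in panel.antigen_panel.subsystems[system]:
                sero = [serology.grades.at[s, a] > 0 for a in group]
                pred = [predictions[s][a].is_positive for a in group]
                mism = [
                    i for i in range(len(group)) if pred[i] is None or pred[i] != sero[i]
                ]
                if not mism:
                    continue
                i = mism[0]
                if pred[i] is None:
                    direction = "no-call"
                elif pred[i] and not sero[i]:
                    direction = "false-positive"
                else:
                    direction = "false-negative"
                label = system if len(panel.antigen_panel.subsystems[system]) == 1 else (
                    f"{system} ({'/'.join(group)})"
                )
                discordances.append(
                    Discordance(
                        sample=s,
                        system=system,
                        subsystem=label,
                        serology_phenotype=_phenotype_string(group, sero),
                        predicted_phenotype=_phenotype_string(group, pred),
                        direction=direction,
                    )
                )
    return ConcordanceReport(
        n_samples=len(samples),
        antigen_accuracy=ag_acc,
        system_accuracy=sys_acc,
        average_system_accuracy=average,
        discordances=discordances,
    )


# ---------------------------------------------------------------------------
# triage


@dataclass
class TriageCandidate:
    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str
    allele_count: int
    region: str  # gene name or supplied interval name
    consequence: str  # missense | nonsense | frameshift | splice-region | regulatory-overlap


_SEVERITY = {
    "frameshift": 0,
    "nonsense": 1,
    "missense": 2,
    "splice-region": 3,
    "regulatory-overlap": 4,
}


def _classify(
    chrom: str, pos: int, ref: str, alt: str, rsid: str,
    gene: str | None, panel: Panel,
) -> str | None:
    tri = panel.config["triage"]
    if rsid in tri.get("nonsense_ids", []):
        return "nonsense"
    if gene is None:
        return None
    w = int(tri.get("splice_window", 8))
    for lo, hi in tri.get("cds", {}).get(gene, []):
        p0 = pos - 1  # 0-based
        if lo <= p0 < hi:
            return "frameshift" if len(ref) != len(alt) else "missense"
        if lo - w <= p0 < lo or hi <= p0 < hi + w:
            return "splice-region"
    return None


def triage_discordance(
    sample: str,
    system: str,
    vcf_path: str,
    panel: Panel,
    tfbs_beds: Sequence[str] | None = None,
    ac_ceiling: int | None = None,
) -> list[TriageCandidate]:
    """Rare private candidate variants for one discordant donor and system.

    Scans the cohort VCF for variants carried by the donor with cohort
    allele count at or below the ceiling (default from the panel config,
    2), lying either in the system's configured gene bodies (classified
    from the transcript annotation in the panel config) or inside supplied
    regulatory intervals (classified ``regulatory-overlap``).  Known panel
    typing sites are excluded.  Results are ordered by consequence severity,
    then allele count, then position.
    """
    tri = panel.config["triage"]
    if ac_ceiling is None:
        ac_ceiling = int(tri.get("ac_ceiling", 2))
    try:
        gene_names = tri["genes"][system]
    except KeyError:
        raise ValueError(f"no triage gene set configured for system {system!r}")
    regions = {g: panel.config["regions"][g] for g in gene_names}
    tfbs: list[tuple[str, int, int, str]] = []
    for bed in tfbs_beds or ():
        tfbs.extend(read_bed(bed))
    panel_keys = {v.key for v in panel.snv_indel_variants}

    out: list[TriageCandidate] = []
    with pysam.VariantFile(vcf_path) as vf:
        if sample not in list(vf.header.samples):
            raise ValueError(f"sample {sample!r} absent from VCF")
        n_records = 0
        for rec in vf:
            n_records += 1
            for ai, alt in enumerate(rec.alts or (), start=1):
                key = (rec.chrom, *trim_variant(rec.pos, rec.ref, alt))
                if key in panel_keys:
                    continue
                gene = next(
                    (
                        g
                        for g, r in regions.items()
                        if r["chrom"] == rec.chrom and r["start"] <= rec.pos - 1 < r["end"]
                    ),
                    None,
                )
                tf_hit = next(
                    (
                        name or f"{c}:{s}-{e}"
                        for c, s, e, name in tfbs
                        if c == rec.chrom and s <= rec.pos - 1 < e
                    ),
                    None,
                )
                if gene is None and tf_hit is None:
                    continue
                ac = 0
                carried = 0
                for sm in rec.samples.values():
                    gt = sm.get("GT") or ()
                    ac += sum(1 for g in gt if g == ai)
                carried = sum(1 for g in (rec.samples[sample].get("GT") or ()) if g == ai)
                if carried == 0 or ac > ac_ceiling:
                    continue
                if tf_hit is not None:
                    consequence: str | None = "regulatory-overlap"
                    region_label = tf_hit
                else:
                    consequence = _classify(
                        rec.chrom, rec.pos, rec.ref, alt, rec.id or "", gene, panel
                    )
                    region_label = gene
                if consequence is None:
                    continue
                out.append(
                    TriageCandidate(
                        sample=sample,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        rsid=rec.id or "",
                        allele_count=ac,
                        region=region_label,
                        consequence=consequence,
                    )
                )
        if n_records == 0:
            raise ValueError(f"no VCF records in {vcf_path}")
    out.sort(key=lambda c: (_SEVERITY[c.consequence], c.allele_count, c.chrom, c.pos))
    return out
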