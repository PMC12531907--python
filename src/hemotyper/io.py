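"""Readers and writers for the pipeline's file formats.

Formats handled:

* phased VCF 4.x restricted to the panel loci (via :mod:`pysam`);
* per-window read-depth tracks as TSV ``sample  chrom  start  end  depth``
  (0-based half-open windows), optionally computed from a BAM/SAM keeping
  reads with MAPQ > 20;
* serology tables: one row per sample, one column per antigen, grades 0-4
  (0 = clear cell button = antigen negative; 1-4 = positive);
* BED3(+name) interval sets for mappability masks and candidate regulatory
  sites.

Coordinate conventions: VCF positions are 1-based; depth windows and BED
intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .panel import Panel

__all__ = [
    "SampleHaplotypes",
    "DepthTrack",
    "SerologyTable",
    "read_phased_genotypes",
    "read_serology",
    "read_depth",
    "depth_from_bam",
    "read_bed",
    "trim_variant",
    "write_vcf",
    "write_depth",
    "write_serology",
]


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class SampleHaplotypes:
    """Phased genotypes of one sample at the panel's SNV/indel sites.

    ``alleles`` maps variant id to an ordered haplotype pair with codes
    0 (ref), 1 (alt) and -1 (missing).  ``phased`` records whether the VCF
    genotype carried phase; unphased heterozygotes are stored with the
    alternate allele on haplotype 2 (the cohort's most common cis
    configuration) and flagged through ``warnings``.
    """

    sample: str
    alleles: dict[str, tuple[int, int]] = field(default_factory=dict)
    phased: dict[str, bool] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def get(self, vid: str) -> tuple[int, int]:
        return self.alleles.get(vid, (0, 0))

    def hap(self, which: int) -> dict[str, int]:
        """Allele codes of haplotype 0 or 1 across all stored sites."""
        return {vid: pair[which] for vid, pair in self.alleles.items()}

    def swapped(self) -> "SampleHaplotypes":
        """The same sample with haplotype labels exchanged."""
        return SampleHaplotypes(
            sample=self.sample,
            alleles={vid: (b, a) for vid, (a, b) in self.alleles.items()},
            phased=dict(self.phased),
            warnings=list(self.warnings),
        )


class DepthTrack:
    """Sorted, non-overlapping windowed mean depth for one sample."""

    def __init__(self, sample: str, windows: pd.DataFrame, window_size: int | None = None):
        df = windows.reset_index(drop=True)
        expected = ["chrom", "start", "end", "depth"]
        if list(df.columns) != expected:
            df = df[expected]
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not (starts[1:] >= ends[:-1]).all():
                raise ValueError(f"depth windows overlap or are unsorted on {chrom}")
            if (ends <= starts).any():
                raise ValueError(f"empty or inverted window on {chrom}")
        if (df["depth"] < 0).any():
            raise ValueError("negative depth in track")
        self.sample = sample
        self.windows = df
        self.window_size = window_size

    def region(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        w = self.windows
        sel = (w["chrom"] == chrom) & (w["end"] > start) & (w["start"] < end)
        return w[sel]

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Overlap-weighted mean depth over a region (0-based half-open)."""
        sub = self.region(chrom, start, end)
        if sub.empty:
            raise ValueError(f"no depth windows over {chrom}:{start}-{end}")
        ov = np.minimum(sub["end"], end) - np.maximum(sub["start"], start)
        return float(np.average(sub["depth"], weights=ov))


class SerologyTable:
    """Per-sample antigen grades (0-4); grade 0 is antigen negative."""

    def __init__(self, grades: pd.DataFrame):
        bad = grades.stack()[lambda s: ~s.isin([0, 1, 2, 3, 4])]
        if len(bad):
            sample, antigen = bad.index[0]
            raise ValueError(
                f"serology grade out of range at sample {sample!r}, antigen "
                f"{antigen!r}: {bad.iloc[0]}"
            )
        self.grades = grades.astype(int)

    @property
    def samples(self) -> list[str]:
        return list(self.grades.index)

    @property
    def antigens(self) -> list[str]:
        return list(self.grades.columns)

    def positive(self, sample: str, antigen: str) -> bool:
        return bool(self.grades.at[sample, antigen] > 0)

    def positive_counts(self) -> pd.Series:
        return (self.grades > 0).sum(axis=0)


# ---------------------------------------------------------------------------
# VCF

def trim_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-trim a VCF allele pair so dialects of the same indel match.

    Shared trailing bases are removed first, then shared leading bases with
    the position advanced, always retaining at least one base on each
    allele.  SNVs are returned unchanged.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def read_phased_genotypes(
    vcf_path: str,
    panel: Panel,
    samples: Sequence[str] | None = None,
    missing_policy: str = "hom-ref",
) -> dict[str, SampleHaplotypes]:
    """Resolve every panel SNV/indel site for every sample of a VCF.

    Panel sites absent from the VCF follow ``missing_policy``: ``"hom-ref"``
    (joint-calling convention, a warning is attached) or ``"no-call"``.
    Structural-tag panel entries are never expected as VCF rows.  Raises if
    the VCF lacks GT or a requested sample is absent.
    """
    if missing_policy not in ("hom-ref", "no-call"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    want = {v.key: v.id for v in panel.snv_indel_variants}

    with pysam.VariantFile(vcf_path) as vf:
        if "GT" not in vf.header.formats:
            raise ValueError(f"{vcf_path}: no GT FORMAT defined")
        vcf_samples = list(vf.header.samples)
        if samples is None:
            samples = vcf_samples
        else:
            absent = sorted(set(samples) - set(vcf_samples))
            if absent:
                raise ValueError(f"samples absent from VCF: {absent}")

        result = {s: SampleHaplotypes(sample=s) for s in samples}
        for rec in vf:
            for alt in rec.alts or ():
                key = trim_variant(rec.pos, rec.ref, alt)
                vid = want.get((rec.chrom, *key))
                if vid is None:
                    continue
                alt_index = (rec.alts or ()).index(alt) + 1
                for s in samples:
                    call = rec.samples[s]
                    gt = call.get("GT")
                    if gt is None or all(g is None for g in gt):
                        pair = (-1, -1)
                        phased = False
                    else:
                        codes = [
                            -1 if g is None else (1 if g == alt_index else 0) for g in gt
                        ]
                        if len(codes) == 1:  # haploid record
                            codes = codes * 2
                        phased = bool(call.phased)
                        if not phased and codes[0] != codes[1]:
                            # unphased het: alt on haplotype 2 by convention
                            codes = sorted(codes)
                        pair = (codes[0], codes[1])
                    result[s].alleles[vid] = pair
                    result[s].phased[vid] = phased

    by_system: dict[str, list[str]] = {}
    for v in panel.snv_indel_variants:
        by_system.setdefault(v.system, []).append(v.id)
    for s, sh in result.items():
        for v in panel.snv_indel_variants:
            if v.id not in sh.alleles:
                if missing_policy == "hom-ref":
                    sh.alleles[v.id] = (0, 0)
                    sh.phased[v.id] = True
                    sh.warnings.append(f"{v.id}: absent from VCF, assumed hom-ref")
                else:
                    sh.alleles[v.id] = (-1, -1)
                    sh.phased[v.id] = False
        for system, vids in by_system.items():
            unphased_hets = [
                vid
                for vid in vids
                if sh.alleles[vid][0] != sh.alleles[vid][1] and not sh.phased.get(vid, False)
            ]
            if len(unphased_hets) > 1:
                sh.warnings.append(
                    f"{system}: unphased heterozygotes at {unphased_hets}; resolved "
                    "to the most common cis configuration"
                )
    return result


def write_vcf(
    path: str,
    samples: Sequence[str],
    records: Iterable[tuple[str, int, str, str, str]],
    genotypes: Mapping[str, np.ndarray],
    contigs: Sequence[str] = ("chr1", "chr4", "chr7", "chr9", "chr11", "chr18", "chr19", "chr22"),
) -> None:
    """Write a phased, sorted VCF 4.2.

    ``records`` yields (id, chrom, pos, ref, alt); ``genotypes[id]`` is an
    (n_samples, 2) array with codes 0/1/-1.  All genotypes are emitted
    phased (``|``), matching statistically phased upstream output.
    """
    order = {c: i for i, c in enumerate(contigs)}
    recs = sorted(records, key=lambda r: (order.get(r[1], 99), r[2], r[3], r[4]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hemotyper-synthetic\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for vid, chrom, pos, ref, alt in recs:
            gt = np.asarray(genotypes[vid])
            cols = [
                "./." if a < 0 or b < 0 else f"{a}|{b}" for a, b in gt
            ]
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(cols)
                + "\n"
            )


# ---------------------------------------------------------------------------
# serology

def read_serology(path: str, panel: Panel | None = None) -> SerologyTable:
    """Read a serology TSV (sample rows, antigen columns, grades 0-4)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if panel is not None:
        known = set(panel.antigen_panel.antigens)
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise ValueError(f"serology columns not in antigen panel: {unknown}")
    return SerologyTable(df)


def write_serology(path: str, table: SerologyTable) -> None:
    out = table.grades.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# depth tracks

def read_depth(path: str, window_size: int | None = None) -> dict[str, DepthTrack]:
    """Read a multi-sample depth TSV into per-sample tracks."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=0,
        dtype={"sample": str, "chrom": str, "start": int, "end": int, "depth": float},
    )
    expected = {"sample", "chrom", "start", "end", "depth"}
    if not expected.issubset(df.columns):
        raise ValueError(f"depth TSV must have columns {sorted(expected)}")
    return {
        str(s): DepthTrack(str(s), sub.drop(columns="sample"), window_size)
        for s, sub in df.groupby("sample", sort=False)
    }


def write_depth(path: str, tracks: Mapping[str, DepthTrack]) -> None:
    parts = []
    for s, t in tracks.items():
        sub = t.windows.copy()
        sub.insert(0, "sample", s)
        parts.append(sub)
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


def tile_windows(chrom: str, start: int, end: int, window: int) -> pd.DataFrame:
    """Tile complete windows of fixed size over a region."""
    n = (end - start) // window
    starts = start + window * np.arange(n)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + window, "depth": 0.0}
    )


def depth_from_bam(
    bam_path: str,
    regions: Sequence[tuple[str, int, int]],
    window: int = 1600,
    min_mapq: int = 20,
    sample: str | None = None,
) -> DepthTrack:
    """Windowed mean depth from alignments, keeping reads with MAPQ > ``min_mapq``.

    Windows with no qualifying reads report depth 0 rather than being
    omitted.  Works on SAM or BAM without requiring an index (single
    streaming pass).
    """
    frames = [tile_windows(c, s, e, window) for c, s, e in regions]
    acc = [np.zeros(len(f)) for f in frames]
    with pysam.AlignmentFile(bam_path) as af:
        name = sample or bam_path
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality <= min_mapq:
                continue
            rs, re_ = read.reference_start, read.reference_end
            if re_ is None:
                continue
            for (c, s, e), f, a in zip(regions, frames, acc):
                if read.reference_name != c or re_ <= s or rs >= e:
                    continue
                i0 = max(0, (rs - s) // window)
                i1 = min(len(f) - 1, (re_ - 1 - s) // window)
                for i in range(int(i0), int(i1) + 1):
                    ws, we = f.at[i, "start"], f.at[i, "end"]
                    ov = min(re_, we) - max(rs, ws)
                    if ov > 0:
                        a[i] += ov
    for f, a in zip(frames, acc):
        f["depth"] = a / window
    return DepthTrack(name, pd.concat(frames, ignore_index=True), window)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Read BED3(+name) intervals (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out
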