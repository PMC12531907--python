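"""RHD zygosity and C/c antigen inference from read-depth ratios.

The RHD gene is commonly deleted whole; zygosity is read from the ratio of
RHD to RHCE locus coverage scaled to a copy-number estimate (RHCE is always
diploid, so estimated RHD copies = 2 x RHD/RHCE).  The C antigen arises from
an RHCE haplotype whose exon 2 carries RHD-like sequence (a gene
conversion); short reads from that tract misalign to RHD exon 2, depleting
RHCE exon-2 coverage and inflating RHD exon-2 coverage.

Two C/c classifiers are provided:

* the *modified* (paralog-aware) method compares RHCE exon-2 coverage with
  RHD exon-2 coverage per RHD gene copy, with zygosity-specific bands —
  usable whenever RHD is present;
* the *legacy* method compares RHCE exon-2 coverage with the whole RHCE
  locus — the only option for RHD-null samples, and less reliable when RHD
  is present because the mismapped reads leave the RHCE denominator
  untouched.

Ratios falling in the gaps between classification bands yield an explicit
no-call rather than being rounded to the nearest band: the bands are
disjoint by construction and a gap value signals a QC problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import DepthTrack
from .panel import Panel

__all__ = [
    "RhThresholds",
    "RhCnvCall",
    "rhd_zygosity",
    "infer_Cc_modified",
    "infer_Cc_legacy",
    "call_rh_cnv",
]

NO_CALL = "no-call"

_DEFAULT_ZYGOSITY = {"null": (0.0, 0.5), "hemizygous": (0.6, 1.5), "homozygous": (1.6, 2.5)}
_DEFAULT_PRESENT = {"C-c+": (1.5, float("inf")), "C+c+": (0.5, 1.4), "C+c-": (float("-inf"), 0.5)}
_DEFAULT_HEMI = {"C-c+": (0.67, float("inf")), "C+c+": (0.1, 0.66), "C+c-": (float("-inf"), 0.1)}
_DEFAULT_NULL = {"C-c+": (0.75, float("inf")), "C+c+": (0.25, 0.74), "C+c-": (float("-inf"), 0.25)}


def _band_lookup(bands: Mapping[str, tuple[float, float]], value: float,
                 open_lower: frozenset[str] = frozenset()) -> str:
    """Classify a ratio against closed bands; values in gaps -> no-call.

    Bands whose printed lower bound is exclusive (e.g. ">0.67") are listed
    in ``open_lower``; unbounded sides use +/-inf.
    """
    for label, (lo, hi) in bands.items():
        lo_ok = value > lo if (label in open_lower or lo == float("-inf")) else value >= lo
        hi_ok = value < hi if hi == float("inf") or lo == float("-inf") else value <= hi
        # upper bound of the bottom band is exclusive (it is the next band's
        # closed lower bound)
        if lo == float("-inf"):
            hi_ok = value < hi
        if lo_ok and hi_ok:
            return label
    return NO_CALL


@dataclass
class RhThresholds:
    """Classification bands for RHD zygosity and the C/c ratio methods."""

    zygosity: dict = field(default_factory=lambda: dict(_DEFAULT_ZYGOSITY))
    cc_rhd_present: dict = field(default_factory=lambda: dict(_DEFAULT_PRESENT))
    cc_rhd_hemizygous: dict = field(default_factory=lambda: dict(_DEFAULT_HEMI))
    cc_rhd_null: dict = field(default_factory=lambda: dict(_DEFAULT_NULL))

    @classmethod
    def from_panel(cls, panel: Panel) -> "RhThresholds":
        raw = panel.config.get("rh", {}).get("thresholds")
        if not raw:
            return cls()
        return cls(
            zygosity={k: tuple(v) for k, v in raw["zygosity"].items()},
            cc_rhd_present={k: tuple(v) for k, v in raw["cc_rhd_present"].items()},
            cc_rhd_hemizygous={k: tuple(v) for k, v in raw["cc_rhd_hemizygous"].items()},
            cc_rhd_null={k: tuple(v) for k, v in raw["cc_rhd_null"].items()},
        )


@dataclass
class RhCnvCall:
    sample: str
    zygosity: str  # null | hemizygous | homozygous | no-call
    rhd_rhce_ratio: float
    cc_phenotype: str  # C+c- | C+c+ | C-c+ | no-call
    exon2_ratio: float
    method: str  # modified | legacy


def rhd_zygosity(
    rhd_mean: float, rhce_mean: float, thresholds: RhThresholds | None = None
) -> tuple[str, float]:
    """Classify RHD zygosity from locus coverage means.

    The ratio is scaled to an RHD copy-number estimate (2 x RHD/RHCE, since
    RHCE is invariably two-copy) and matched against the null / hemizygous /
    homozygous bands; gap values (e.g. 0.55) are no-calls.
    """
    thresholds = thresholds or RhThresholds()
    if rhce_mean <= 0:
        raise ValueError("RHCE locus depth is zero: sample-level QC failure")
    if rhd_mean < 0:
        raise ValueError("negative RHD depth")
    ratio = 2.0 * rhd_mean / rhce_mean
    return _band_lookup(thresholds.zygosity, ratio), ratio


def infer_Cc_modified(
    rhce_exon2: float,
    rhd_exon2: float,
    zygosity: str,
    thresholds: RhThresholds | None = None,
) -> tuple[str, float]:
    """Paralog-aware C/c call for RHD-present samples.

    Compares RHCE exon-2 coverage against RHD exon-2 coverage per RHD copy
    (homozygotes contribute two copies to the denominator).  Zygosity-
    specific bands are applied as configured; the hemizygous C-c+ bound is
    exclusive (ratio must exceed it), so ratios inside [0.66, 0.67] no-call.
    """
    thresholds = thresholds or RhThresholds()
    if zygosity not in ("hemizygous", "homozygous"):
        raise ValueError(
            f"modified C/c method requires RHD present, got zygosity {zygosity!r}"
        )
    if rhd_exon2 <= 0:
        raise ValueError("RHD exon-2 depth is zero for an RHD-present sample")
    copies = 2 if zygosity == "homozygous" else 1
    ratio = rhce_exon2 / (rhd_exon2 / copies)
    if zygosity == "homozygous":
        return _band_lookup(thresholds.cc_rhd_present, ratio), ratio
    return _band_lookup(thresholds.cc_rhd_hemizygous, ratio, open_lower=frozenset({"C-c+"})), ratio


def infer_Cc_legacy(
    rhce_exon2: float,
    rhce_locus_mean: float,
    thresholds: RhThresholds | None = None,
) -> tuple[str, float]:
    """Whole-locus C/c call (exon-2 depletion relative to the RHCE mean).

    The only usable method for RHD-null samples; conversion on one or both
    haplotypes removes roughly half or all of the exon-2 coverage.
    """
    thresholds = thresholds or RhThresholds()
    if rhce_locus_mean <= 0:
        raise ValueError("RHCE locus depth is zero")
    ratio = rhce_exon2 / rhce_locus_mean
    return _band_lookup(thresholds.cc_rhd_null, ratio), ratio


def call_rh_cnv(
    track: DepthTrack,
    panel: Panel,
    thresholds: RhThresholds | None = None,
    method: str = "modified",
) -> RhCnvCall:
    """Full per-sample Rh CNV call from a depth track.

    ``method="modified"`` applies the paralog-aware exon-2 comparison
    whenever RHD is present and falls back to the whole-locus method for
    RHD-null samples (which the modified method cannot handle);
    ``method="legacy"`` uses the whole-locus comparison throughout.
    """
    if method not in ("modified", "legacy"):
        raise ValueError(f"unknown method {method!r}")
    thresholds = thresholds or RhThresholds.from_panel(panel)
    rh = panel.config["rh"]

    def mean(which: str) -> float:
        r = rh[which]
        return track.mean_depth(r["chrom"], r["start"], r["end"])

    def locus_mean_excl_exon2(locus: str, exon2: str) -> float:
        # zygosity must read conversion-free coverage: the exon-2 tract is
        # copy-variable through mismapping and is excluded from the mean
        r, x = rh[locus], rh[exon2]
        win = track.region(r["chrom"], r["start"], r["end"])
        keep = (win["end"] <= x["start"]) | (win["start"] >= x["end"])
        sub = win[keep]
        if sub.empty:
            raise ValueError(f"no {locus} windows outside the exon-2 tract")
        ov = np.minimum(sub["end"], r["end"]) - np.maximum(sub["start"], r["start"])
        return float(np.average(sub["depth"], weights=ov))

    rhd_mean = locus_mean_excl_exon2("rhd_locus", "rhd_exon2")
    rhce_mean = locus_mean_excl_exon2("rhce_locus", "rhce_exon2")
    zygosity, zr = rhd_zygosity(rhd_mean, rhce_mean, thresholds)
    rhce_ex2 = mean("rhce_exon2")

    if zygosity == NO_CALL:
        return RhCnvCall(track.sample, NO_CALL, zr, NO_CALL, float("nan"), method)
    if method == "legacy" or zygosity == "null":
        # the published whole-locus comparison, denominator as printed:
        # the entire RHCE locus including its exon 2
        cc, ratio = infer_Cc_legacy(rhce_ex2, mean("rhce_locus"), thresholds)
        used = "legacy"
    else:
        cc, ratio = infer_Cc_modified(rhce_ex2, mean("rhd_exon2"), zygosity, thresholds)
        used = "modified"
    return RhCnvCall(track.sample, zygosity, zr, cc, ratio, used)
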