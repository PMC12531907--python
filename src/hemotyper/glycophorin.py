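"""Windowed-coverage copy-number segmentation over the glycophorin cluster.

The GYPE-GYPB-GYPA region (chr4) harbours common structural alleles that
silence or weaken MNS antigens: the GYPB whole-gene deletion and the Dantu
GYPB-GYPA hybrid (an expanded glycophorin copy number).  Copy number is
inferred from mean read depth in 1600-bp windows at high-mappability sites:
depth is normalized to copy units (2.0 = diploid) against a copy-number-
stable flank, then decoded with a five-state (0-4 copies) Gaussian hidden
Markov model and merged into segments.

Dantu recognition is template based — a segment of three or more copies
covering the canonical GYPB-GYPA hybrid span — not breakpoint resolved;
short-read depth cannot place hybrid breakpoints precisely.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .io import DepthTrack, read_bed
from .panel import Panel, data_path

__all__ = [
    "HmmConfig",
    "CopyNumberProfile",
    "StructuralCall",
    "estimate_diploid_mean",
    "normalize_windows",
    "viterbi_copy_number",
    "classify_structural",
    "call_glycophorin",
]


@dataclass
class HmmConfig:
    """Copy-number HMM parameters.

    State means are state/2 x the sample diploid mean, i.e. exactly the
    state value on the normalized (copy-unit) scale.  ``sigma`` is the
    emission standard deviation in copy units; when ``None`` it is estimated
    from the diploid flank windows.  ``switch_prob`` is the per-window
    probability of leaving the current state, split evenly over the other
    states.
    """

    window: int = 1600
    states: tuple[int, ...] = (0, 1, 2, 3, 4)
    switch_prob: float = 1e-4
    sigma: float | None = None
    min_sigma: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.switch_prob < 1:
            raise ValueError("switch_prob must be in (0, 1)")
        if list(self.states) != sorted(self.states):
            raise ValueError("state space must be increasing")


@dataclass
class CopyNumberProfile:
    sample: str
    windows: pd.DataFrame  # chrom, start, end, norm (copy units)
    states: np.ndarray  # Viterbi path, one entry per (unmasked) window
    segments: list[tuple[int, int, int]] = field(default_factory=list)  # start, end, copies


@dataclass
class StructuralCall:
    sample: str
    call: str  # none | GYPB_del_het | GYPB_del_hom | Dantu_het | complex
    segments: list[tuple[int, int, int]] = field(default_factory=list)


def estimate_diploid_mean(track: DepthTrack, panel: Panel) -> float:
    flank = panel.config["glycophorin"]["flank"]
    return track.mean_depth(flank["chrom"], flank["start"], flank["end"])


def _masked(win: pd.DataFrame, mask: list[tuple[str, int, int, str]]) -> np.ndarray:
    out = np.zeros(len(win), dtype=bool)
    for chrom, s, e, _name in mask:
        out |= (
            (win["chrom"] == chrom) & (win["end"] > s) & (win["start"] < e)
        ).to_numpy()
    return out


def normalize_windows(
    track: DepthTrack,
    region: tuple[str, int, int],
    mask: list[tuple[str, int, int, str]] | None,
    diploid_mean: float,
) -> pd.DataFrame:
    """Per-window coverage in copy units over a region, mask applied.

    Expected value is 2.0 at diploid windows.  Windows overlapping any mask
    interval (low mappability) are excluded from the output.
    """
    if diploid_mean <= 0:
        raise ValueError("diploid mean must be positive")
    chrom, start, end = region
    win = track.region(chrom, start, end).reset_index(drop=True)
    if win.empty:
        raise ValueError(f"no depth windows over {chrom}:{start}-{end}")
    drop = _masked(win, mask or [])
    if drop.all():
        raise ValueError("all windows masked")
    if drop.mean() > 0.5:
        _warnings.warn("more than half of the windows are masked", stacklevel=2)
    out = win[~drop].copy()
    out["norm"] = out["depth"] / diploid_mean * 2.0
    return out[["chrom", "start", "end", "norm"]].reset_index(drop=True)


def _merge_segments(win: pd.DataFrame, states: np.ndarray) -> list[tuple[int, int, int]]:
    segs: list[tuple[int, int, int]] = []
    for s, e, st in zip(win["start"], win["end"], states):
        if segs and segs[-1][2] == st and segs[-1][1] >= s:
            segs[-1] = (segs[-1][0], int(e), int(st))
        elif segs and segs[-1][2] == st:
            # contiguous state across a masked gap: extend the segment
            segs[-1] = (segs[-1][0], int(e), int(st))
        else:
            segs.append((int(s), int(e), int(st)))
    return segs


def viterbi_copy_number(
    normalized: pd.DataFrame, config: HmmConfig, sample: str = ""
) -> CopyNumberProfile:
    """Maximum-probability copy-number path over normalized windows.

    Decoding is delegated to a Gaussian HMM with fixed (not fitted)
    parameters: uniform start, symmetric switch transitions and state means
    equal to the copy-number states on the normalized scale.
    """
    norm = normalized["norm"].to_numpy(dtype=float)
    if not np.isfinite(norm).all():
        raise ValueError("non-finite normalized coverage")
    if len(norm) < 10:
        raise ValueError(f"need >= 10 unmasked windows, got {len(norm)}")
    states = np.asarray(config.states, dtype=float)
    k = len(states)
    sigma = config.sigma
    if sigma is None:
        # spread of windows attributable to noise around the diploid state
        sigma = float(np.median(np.abs(norm - 2.0)) * 1.4826)
    sigma = max(sigma, config.min_sigma)

    model = GaussianHMM(n_components=k, covariance_type="diag", init_params="")
    model.startprob_ = np.full(k, 1.0 / k)
    off = config.switch_prob / (k - 1)
    model.transmat_ = np.full((k, k), off) + np.eye(k) * (1.0 - config.switch_prob - off)
    model.means_ = states.reshape(-1, 1)
    model.covars_ = np.full((k, 1), sigma**2)
    _, path = model.decode(norm.reshape(-1, 1), algorithm="viterbi")
    copies = states[path].astype(int)

    segs = _merge_segments(normalized, copies)
    return CopyNumberProfile(sample=sample, windows=normalized, states=copies, segments=segs)


def classify_structural(profile: CopyNumberProfile, panel: Panel) -> StructuralCall:
    """Classify GYPB deletion / Dantu-like calls from a copy-number profile.

    * ``GYPB_del_het`` (``_hom``): copies 1 (0) over at least 80% of the
      unmasked GYPB windows;
    * ``Dantu_het``: a >= 3-copy state over at least 80% of the unmasked
      canonical hybrid span (GYPB through GYPA), the pattern of the known
      Dantu carrier used as template;
    * anything else with non-diploid windows beyond a 5% tolerance is
      ``complex``; otherwise ``none``.
    """
    g = panel.config["glycophorin"]
    win = profile.windows
    states = profile.states

    def frac(span: dict, pred) -> float:
        sel = (win["start"] < span["end"]) & (win["end"] > span["start"])
        sel &= (win["chrom"] == span["chrom"])
        sel = sel.to_numpy()
        if not sel.any():
            return 0.0
        return float(pred(states[sel]).mean())

    gypb = g["genes"]["GYPB"]
    dantu = g["dantu_span"]
    f_del_het = frac(gypb, lambda s: s == 1)
    f_del_hom = frac(gypb, lambda s: s == 0)
    f_dantu = frac(dantu, lambda s: s >= 3)

    if f_del_hom >= 0.8:
        call = "GYPB_del_hom"
    elif f_del_het >= 0.8:
        call = "GYPB_del_het"
    elif f_dantu >= 0.8:
        call = "Dantu_het"
    elif float((states != 2).mean()) > 0.05:
        call = "complex"
    else:
        call = "none"
    segs = [seg for seg in profile.segments if seg[2] != 2]
    return StructuralCall(sample=profile.sample, call=call, segments=segs)


def call_glycophorin(
    track: DepthTrack,
    panel: Panel,
    config: HmmConfig | None = None,
    mask: list[tuple[str, int, int, str]] | None = None,
) -> tuple[CopyNumberProfile, StructuralCall]:
    """End-to-end glycophorin CNV call for one sample."""
    g = panel.config["glycophorin"]
    if config is None:
        config = HmmConfig(
            window=g["window"],
            states=tuple(g["hmm"]["states"]),
            switch_prob=float(g["hmm"]["switch_prob"]),
        )
    if mask is None:
        mask = read_bed(data_path(g["mask_bed"]))
    region = (g["region"]["chrom"], g["region"]["start"], g["region"]["end"])
    dip = estimate_diploid_mean(track, panel)
    norm = normalize_windows(track, region, mask, dip)
    profile = viterbi_copy_number(norm, config, sample=track.sample)
    return profile, classify_structural(profile, panel)
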