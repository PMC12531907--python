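"""End-to-end inference: files in, per-sample antigen calls out."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .glycophorin import StructuralCall, call_glycophorin
from .io import DepthTrack, read_depth, read_phased_genotypes
from .panel import Panel
from .phenotype import AntigenCall, HaplotypeAlleleAssignment, predict_all
from .rh import RhCnvCall, call_rh_cnv

__all__ = ["InferenceResult", "run_inference", "infer_from_tracks", "predictions_frame"]


class InferenceResult:
    def __init__(self) -> None:
        self.predictions: dict[str, dict[str, AntigenCall]] = {}
        self.rh_calls: dict[str, RhCnvCall] = {}
        self.structural_calls: dict[str, StructuralCall] = {}
        self.assignments: dict[str, list[HaplotypeAlleleAssignment]] = {}


def infer_from_tracks(
    haplotypes: Mapping[str, "object"],
    tracks: Mapping[str, DepthTrack],
    panel: Panel,
    cc_method: str = "modified",
    p1_predictor: str = "consensus",
) -> InferenceResult:
    """Run CNV calling plus the phenotyper for every sample with a track."""
    res = InferenceResult()
    for sample, haps in haplotypes.items():
        track = tracks.get(sample)
        if track is None:
            raise ValueError(f"no depth track for sample {sample!r}")
        rh_call = call_rh_cnv(track, panel, method=cc_method)
        _, struct_call = call_glycophorin(track, panel)
        calls, assigns = predict_all(haps, rh_call, struct_call, panel,
                                     p1_predictor=p1_predictor)
        res.predictions[sample] = {c.antigen: c for c in calls}
        res.rh_calls[sample] = rh_call
        res.structural_calls[sample] = struct_call
        res.assignments[sample] = assigns
    return res


def run_inference(
    vcf_path: str,
    depth_path: str,
    panel: Panel,
    cc_method: str = "modified",
    p1_predictor: str = "consensus",
) -> InferenceResult:
    haplotypes = read_phased_genotypes(vcf_path, panel)
    tracks = read_depth(depth_path)
    return infer_from_tracks(haplotypes, tracks, panel,
                             cc_method=cc_method, p1_predictor=p1_predictor)


def predictions_frame(result: InferenceResult, panel: Panel) -> pd.DataFrame:
    """Sample x antigen table of predicted states."""
    antigens = panel.antigen_panel.antigens
    rows = {
        s: {ag: calls[ag].state for ag in antigens}
        for s, calls in result.predictions.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")[antigens]
    df.index.name = "sample"
    return df
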