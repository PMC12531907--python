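"""Declarative knowledge base of blood-group variants, alleles and antigens.

The panel ties together three layers:

* :class:`PanelVariant` — a genomic change (SNV, indel, or a structural tag
  resolved by the copy-number modules rather than by a VCF row);
* :class:`AlleleDefinition` — a named blood-group allele as a cis-combination
  of panel changes with antigen effects (express / silence / weaken);
* :class:`AntigenPanel` — the nine systems, their 24 serologically typed
  antigens and the antithetical pairs.

The builtin panel ships as YAML (``data/panel.yaml``) so users can extend it
(for example with an alternative P1 predictor or a candidate weak-secretor
allele) without touching code.  Variants are keyed by (chrom, pos, ref, alt);
rsIDs are display labels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PanelVariant",
    "AlleleDefinition",
    "AntigenPanel",
    "Panel",
    "PanelError",
    "load_panel",
    "builtin_panel_path",
]

VALID_CLASSES = {"snv", "indel", "structural-tag"}
VALID_EFFECTS = {"express", "silence", "weaken"}


class PanelError(ValueError):
    """Malformed panel configuration; the message names the offending field."""


@dataclass(frozen=True)
class PanelVariant:
    id: str
    chrom: str
    pos: int  # 1-based, GRCh38
    ref: str
    alt: str
    cdna: str
    protein: str
    system: str
    var_class: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise PanelError(f"variant {self.id}: pos must be positive, got {self.pos}")
        if self.ref == self.alt:
            raise PanelError(f"variant {self.id}: ref equals alt ({self.ref})")
        if self.var_class not in VALID_CLASSES:
            raise PanelError(f"variant {self.id}: unknown class {self.var_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_structural(self) -> bool:
        return self.var_class == "structural-tag"


@dataclass(frozen=True)
class AlleleDefinition:
    name: str
    system: str
    requires: Mapping[str, str]  # variant id -> "ref" | "alt"
    effects: Mapping[str, str]  # antigen -> express | silence | weaken

    def matches(self, hap_alleles: Mapping[str, int]) -> bool:
        """True when a haplotype (variant id -> 0/1) carries this allele."""
        for vid, which in self.requires.items():
            want = 1 if which == "alt" else 0
            if hap_alleles.get(vid, 0) != want:
                return False
        return True


@dataclass(frozen=True)
class AntigenPanel:
    systems: Sequence[str]
    antigens_by_system: Mapping[str, Sequence[str]]
    subsystems: Mapping[str, Sequence[Sequence[str]]]
    antithetical: Mapping[str, Sequence[Sequence[str]]]

    @property
    def antigens(self) -> list[str]:
        out: list[str] = []
        for system in self.systems:
            out.extend(self.antigens_by_system[system])
        return out

    def system_of(self, antigen: str) -> str:
        for system, ags in self.antigens_by_system.items():
            if antigen in ags:
                return system
        raise KeyError(f"unknown antigen {antigen!r}")


@dataclass
class Panel:
    """The loaded knowledge base plus the raw config for module sections."""

    variants: list[PanelVariant]
    alleles: list[AlleleDefinition]
    antigen_panel: AntigenPanel
    config: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {v.id: v for v in self.variants}
        self._by_key = {v.key: v for v in self.variants}

    def variant(self, vid: str) -> PanelVariant:
        try:
            return self._by_id[vid]
        except KeyError:
            raise KeyError(f"variant {vid!r} not in panel") from None

    def __contains__(self, vid: str) -> bool:
        return vid in self._by_id

    def by_key(self, chrom: str, pos: int, ref: str, alt: str) -> PanelVariant | None:
        return self._by_key.get((chrom, pos, ref, alt))

    @property
    def snv_indel_variants(self) -> list[PanelVariant]:
        return [v for v in self.variants if not v.is_structural]

    def antigens_of(self, system: str) -> list[str]:
        """Ordered antigen list of one system."""
        try:
            return list(self.antigen_panel.antigens_by_system[system])
        except KeyError:
            raise KeyError(f"unknown blood group system {system!r}") from None

    def alleles_of(self, system: str) -> list[AlleleDefinition]:
        return [a for a in self.alleles if a.system == system]

    def serialize(self) -> str:
        """Re-emit the panel as YAML; loading the result is lossless."""
        return yaml.safe_dump(self.config, sort_keys=False, allow_unicode=True)


def builtin_panel_path() -> str:
    return str(importlib.resources.files("hemotyper.data") / "panel.yaml")


def data_path(name: str) -> str:
    """Path of a packaged data file (mask / TFBS BEDs)."""
    return str(importlib.resources.files("hemotyper.data") / name)


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise PanelError(f"{where}: missing required field {key!r}")
    return mapping[key]


def load_panel(path: str | None = None) -> Panel:
    """Load a panel config; ``None`` selects the versioned builtin panel.

    Raises :class:`PanelError` naming the offending field for malformed
    configs (including an empty variant table, which is never silently
    accepted as an empty panel).
    """
    src = path or builtin_panel_path()
    with open(src) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PanelError("panel config: top level must be a mapping")

    raw_systems = _require(config, "systems", "panel config")
    raw_variants = _require(config, "variants", "panel config")
    raw_alleles = _require(config, "alleles", "panel config")
    if not raw_variants:
        raise PanelError("panel config: 'variants' is empty")
    if not raw_systems:
        raise PanelError("panel config: 'systems' is empty")

    variants: list[PanelVariant] = []
    seen_ids: set[str] = set()
    for entry in raw_variants:
        vid = _require(entry, "id", "variant entry")
        if vid in seen_ids:
            raise PanelError(f"variant id {vid!r} duplicated in panel")
        seen_ids.add(vid)
        variants.append(
            PanelVariant(
                id=vid,
                chrom=_require(entry, "chrom", f"variant {vid}"),
                pos=int(_require(entry, "pos", f"variant {vid}")),
                ref=str(_require(entry, "ref", f"variant {vid}")),
                alt=str(_require(entry, "alt", f"variant {vid}")),
                cdna=str(entry.get("cdna", "")),
                protein=str(entry.get("protein", "")),
                system=_require(entry, "system", f"variant {vid}"),
                var_class=_require(entry, "class", f"variant {vid}"),
            )
        )

    systems = list(raw_systems)
    antigens_by_system = {}
    subsystems = {}
    antithetical = {}
    for system, sc in raw_systems.items():
        antigens_by_system[system] = list(_require(sc, "antigens", f"system {system}"))
        subsystems[system] = [list(g) for g in _require(sc, "subsystems", f"system {system}")]
        antithetical[system] = [list(p) for p in sc.get("antithetical", [])]

    alleles: list[AlleleDefinition] = []
    for entry in raw_alleles:
        name = _require(entry, "name", "allele entry")
        system = _require(entry, "system", f"allele {name}")
        if system not in antigens_by_system:
            raise PanelError(f"allele {name}: unknown system {system!r}")
        requires = dict(entry.get("requires", {}))
        for vid, which in requires.items():
            if vid not in seen_ids:
                raise PanelError(f"allele {name}: requires unknown variant {vid!r}")
            if which not in ("ref", "alt"):
                raise PanelError(f"allele {name}: requires[{vid}] must be ref/alt")
        effects = dict(_require(entry, "effects", f"allele {name}"))
        for antigen, effect in effects.items():
            if antigen not in antigens_by_system[system]:
                raise PanelError(
                    f"allele {name}: effect antigen {antigen!r} not in system {system}"
                )
            if effect not in VALID_EFFECTS:
                raise PanelError(f"allele {name}: unknown effect {effect!r}")
        alleles.append(AlleleDefinition(name, system, requires, effects))

    panel = Panel(
        variants=variants,
        alleles=alleles,
        antigen_panel=AntigenPanel(systems, antigens_by_system, subsystems, antithetical),
        config=config,
    )

    # every antigen must be reachable through at least one allele effect
    touched = {ag for a in alleles for ag in a.effects}
    untouched = [ag for ag in panel.antigen_panel.antigens if ag not in touched]
    if untouched:
        raise PanelError(f"antigens with no allele effect: {untouched}")
    return panel


def allele_frequency(genotypes: Mapping[str, np.ndarray] | "pd.DataFrame", vid: str) -> float:
    """Alternate-allele frequency of a panel variant over called genotypes.

    ``genotypes`` maps variant id to an (n, 2) array of per-haplotype allele
    codes (0 ref, 1 alt, -1 missing).  Frequency = alt count / (2 x called
    samples); samples with any missing haplotype at the site are excluded.
    """
    try:
        gt = np.asarray(genotypes[vid])
    except KeyError:
        raise KeyError(f"variant {vid!r} absent from genotype matrix") from None
    if gt.ndim != 2 or gt.shape[1] != 2:
        raise ValueError("genotype matrix must have shape (n_samples, 2)")
    called = (gt >= 0).all(axis=1)
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError(f"no called genotypes at {vid}")
    return float(gt[called].sum()) / (2 * n_called)
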