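"""Hypothesis space for the six-region face-memory network.

The network comprises the inferior occipital gyrus (IOG), fusiform gyrus
(FUS), superior parietal lobule (SPL), hippocampus (HPC), amygdala (AMG)
and orbitofrontal cortex (OFC).  All models share a fully connected
endogenous backbone (every inter-regional coupling free) driven by an
"all faces" input into IOG, and differ only in how emotional valence
(negative / positive face expression) enters:

* **Bottom-up (BU) family** — valence acts as a bilinear modulator of one
  or more forward pathways {IOG, FUS, SPL, HPC, AMG} -> OFC.
* **Top-down (TD) family** — valence drives OFC directly, and OFC activity
  nonlinearly gates one or more pathways {IOG, FUS, SPL, AMG} -> HPC.

Masks are boolean selectors over the coupling matrices: ``A`` (endogenous,
6x6), one ``B`` per input (input-dependent modulation), ``C`` (driving
gains, 6x3) and one ``D`` per gating region (activity-dependent
modulation).  Self-connections are excluded from ``A`` masks and handled
as a fixed self-decay in the generative model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

REGIONS: tuple[str, ...] = ("IOG", "FUS", "SPL", "HPC", "AMG", "OFC")
INPUTS: tuple[str, ...] = ("all_faces", "negative", "positive")
N_REGIONS = len(REGIONS)
N_INPUTS = len(INPUTS)
REGION_INDEX: dict[str, int] = {r: i for i, r in enumerate(REGIONS)}
INPUT_INDEX: dict[str, int] = {u: i for i, u in enumerate(INPUTS)}

#: candidate modulated sources per family
BU_SOURCES: tuple[str, ...] = ("IOG", "FUS", "SPL", "HPC", "AMG")
TD_SOURCES: tuple[str, ...] = ("IOG", "FUS", "SPL", "AMG")

_IOG = REGION_INDEX["IOG"]
_HPC = REGION_INDEX["HPC"]
_OFC = REGION_INDEX["OFC"]
_ALL = INPUT_INDEX["all_faces"]
_NEG = INPUT_INDEX["negative"]
_POS = INPUT_INDEX["positive"]


@dataclass
class ModelSpec:
    """One connectivity hypothesis: free parameters and family label.

    Masks follow the canonical region order of :data:`REGIONS`; entry
    ``[i, j]`` of an A/B/D mask frees the coupling *from* region ``j``
    *to* region ``i``.
    """

    model_id: int
    family: str  # "BU" | "TD" | "base"
    modulated_sources: tuple[str, ...]
    A_mask: np.ndarray = field(repr=False)
    B_masks: np.ndarray = field(repr=False)  # (n_inputs, 6, 6)
    C_mask: np.ndarray = field(repr=False)   # (6, n_inputs)
    D_masks: np.ndarray = field(repr=False)  # (n_regions, 6, 6), one per gate

    def __post_init__(self) -> None:
        self.A_mask = np.asarray(self.A_mask, dtype=bool)
        self.B_masks = np.asarray(self.B_masks, dtype=bool)
        self.C_mask = np.asarray(self.C_mask, dtype=bool)
        self.D_masks = np.asarray(self.D_masks, dtype=bool)
        self.modulated_sources = tuple(self.modulated_sources)

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        if self.A_mask.shape != (N_REGIONS, N_REGIONS):
            raise ValueError("A_mask must be 6x6")
        if np.any(np.diag(self.A_mask)):
            raise ValueError("A_mask diagonal must be false (fixed self-decay)")
        if not np.all(self.A_mask[~np.eye(N_REGIONS, dtype=bool)]):
            raise ValueError("all 30 off-diagonal endogenous connections must be free")
        for src in self.modulated_sources:
            if src not in REGIONS:
                raise ValueError(f"unknown region label {src!r}")
        if self.family == "BU":
            if not self.modulated_sources:
                raise ValueError("BU model needs at least one modulated source")
            if "OFC" in self.modulated_sources:
                raise ValueError("OFC cannot be a BU source (it is the target)")
            expect = np.zeros((N_REGIONS, N_REGIONS), dtype=bool)
            for src in self.modulated_sources:
                expect[_OFC, REGION_INDEX[src]] = True
            if not (np.array_equal(self.B_masks[_NEG], expect)
                    and np.array_equal(self.B_masks[_POS], expect)):
                raise ValueError("BU B masks must free exactly source->OFC entries, "
                                 "identically for both valences")
            if self.B_masks[_ALL].any():
                raise ValueError("the driving input must not modulate")
            if self.D_masks.any():
                raise ValueError("BU models are bilinear: no D gating")
            expect_c = np.zeros((N_REGIONS, N_INPUTS), dtype=bool)
            expect_c[_IOG, _ALL] = True
            if not np.array_equal(self.C_mask, expect_c):
                raise ValueError("BU C mask must be (IOG, all_faces) only")
        elif self.family == "TD":
            if not self.modulated_sources:
                raise ValueError("TD model needs at least one gated source")
            bad = set(self.modulated_sources) - set(TD_SOURCES)
            if bad:
                raise ValueError(f"invalid TD sources {sorted(bad)}")
            if self.B_masks.any():
                raise ValueError("TD models carry no input-dependent modulation")
            expect_c = np.zeros((N_REGIONS, N_INPUTS), dtype=bool)
            expect_c[_IOG, _ALL] = True
            expect_c[_OFC, _NEG] = True
            expect_c[_OFC, _POS] = True
            if not np.array_equal(self.C_mask, expect_c):
                raise ValueError("TD C mask must drive IOG (all faces) and OFC (valences)")
            expect_d = np.zeros((N_REGIONS, N_REGIONS, N_REGIONS), dtype=bool)
            for src in self.modulated_sources:
                expect_d[_OFC, _HPC, REGION_INDEX[src]] = True
            if not np.array_equal(self.D_masks, expect_d):
                raise ValueError("TD D mask must gate source->HPC entries via OFC only")
        elif self.family == "base":
            if self.B_masks.any() or self.D_masks.any():
                raise ValueError("base model has no modulation")
        else:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def gating_regions(self) -> tuple[int, ...]:
        return tuple(int(k) for k in range(N_REGIONS) if self.D_masks[k].any())

    def n_connections(self) -> int:
        return int(self.A_mask.sum())

    # -- serialization (masks are derived, not stored) ---------------------
    def to_dict(self) -> dict:
        return {"model_id": self.model_id, "family": self.family,
                "modulated_sources": list(self.modulated_sources)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        family = d["family"]
        sources = tuple(d["modulated_sources"])
        if family == "BU":
            spec = _make_bu(d["model_id"], sources)
        elif family == "TD":
            spec = _make_td(d["model_id"], sources)
        elif family == "base":
            spec = build_base_network()
            spec.model_id = d["model_id"]
        else:
            raise ValueError(f"unknown family {family!r}")
        return spec


def _blank_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    A = ~np.eye(N_REGIONS, dtype=bool)
    B = np.zeros((N_INPUTS, N_REGIONS, N_REGIONS), dtype=bool)
    C = np.zeros((N_REGIONS, N_INPUTS), dtype=bool)
    D = np.zeros((N_REGIONS, N_REGIONS, N_REGIONS), dtype=bool)
    return A, B, C, D


def build_base_network() -> ModelSpec:
    """Fully connected endogenous backbone, faces driving IOG, no modulation."""
    A, B, C, D = _blank_masks()
    C[_IOG, _ALL] = True
    spec = ModelSpec(model_id=0, family="base", modulated_sources=(),
                     A_mask=A, B_masks=B, C_mask=C, D_masks=D)
    spec.validate()
    return spec


def _make_bu(model_id: int, sources: tuple[str, ...]) -> ModelSpec:
    A, B, C, D = _blank_masks()
    C[_IOG, _ALL] = True
    for src in sources:
        B[_NEG, _OFC, REGION_INDEX[src]] = True
        B[_POS, _OFC, REGION_INDEX[src]] = True
    spec = ModelSpec(model_id=model_id, family="BU", modulated_sources=sources,
                     A_mask=A, B_masks=B, C_mask=C, D_masks=D)
    spec.validate()
    return spec


def _make_td(model_id: int, sources: tuple[str, ...]) -> ModelSpec:
    A, B, C, D = _blank_masks()
    C[_IOG, _ALL] = True
    C[_OFC, _NEG] = True
    C[_OFC, _POS] = True
    for src in sources:
        D[_OFC, _HPC, REGION_INDEX[src]] = True
    spec = ModelSpec(model_id=model_id, family="TD", modulated_sources=sources,
                     A_mask=A, B_masks=B, C_mask=C, D_masks=D)
    spec.validate()
    return spec


def _ordered_subsets(candidates: Sequence[str]) -> list[tuple[str, ...]]:
    # by size, then lexicographically in canonical region order
    order = {r: REGION_INDEX[r] for r in candidates}
    out: list[tuple[str, ...]] = []
    for size in range(1, len(candidates) + 1):
        subs = [tuple(c) for c in combinations(candidates, size)]
        subs.sort(key=lambda s: tuple(order[r] for r in s))
        out.extend(subs)
    return out


def enumerate_bottom_up(subset_rule: str = "all_nonempty_subsets",
                        explicit_list: Iterable[Sequence[str]] | None = None,
                        start_id: int = 1) -> list[ModelSpec]:
    """Enumerate BU models, one per admitted subset of forward sources.

    ``subset_rule`` is ``"all_nonempty_subsets"`` (default; 31 models) or
    ``"explicit_list"`` with an iterable of source subsets, which allows a
    restricted published model list to be reproduced exactly.
    """
    if subset_rule == "all_nonempty_subsets":
        subsets = _ordered_subsets(BU_SOURCES)
    elif subset_rule == "explicit_list":
        if explicit_list is None:
            raise ValueError("explicit_list rule requires a model list")
        subsets = [tuple(s) for s in explicit_list]
        if not subsets:
            raise ValueError("empty model space")
        for sub in subsets:
            bad = set(sub) - set(BU_SOURCES)
            if bad:
                raise ValueError(f"invalid BU sources {sorted(bad)}")
            if not sub:
                raise ValueError("empty subset in explicit list")
    else:
        raise ValueError(f"unknown subset rule {subset_rule!r}")
    return [_make_bu(start_id + k, sub) for k, sub in enumerate(subsets)]


def enumerate_top_down(start_id: int = 1) -> list[ModelSpec]:
    """Enumerate the 15 TD models (nonempty subsets of gated sources)."""
    subsets = _ordered_subsets(TD_SOURCES)
    return [_make_td(start_id + k, sub) for k, sub in enumerate(subsets)]


def build_model_space(subset_rule: str = "all_nonempty_subsets",
                      explicit_list: Iterable[Sequence[str]] | None = None
                      ) -> list[ModelSpec]:
    """Full BU+TD space with sequential ids (BU first)."""
    bu = enumerate_bottom_up(subset_rule, explicit_list, start_id=1)
    td = enumerate_top_down(start_id=len(bu) + 1)
    return bu + td


@dataclass
class FamilyPartition:
    """Disjoint family labels over a model list, with uniform-family priors.

    Each family receives equal prior mass, split equally over its members,
    so that families of unequal size compete on even footing.
    """

    families: dict[str, tuple[int, ...]]          # label -> model_ids
    model_prior: dict[int, float]                 # model_id -> prior prob
    model_family: dict[int, str]                  # model_id -> label

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.families)

    def family_sizes(self) -> dict[str, int]:
        return {f: len(m) for f, m in self.families.items()}


def build_family_partition(models: Sequence[ModelSpec]) -> FamilyPartition:
    families: dict[str, list[int]] = {}
    for m in models:
        families.setdefault(m.family, []).append(m.model_id)
    for label, members in families.items():
        if not members:
            raise ValueError(f"family {label!r} has no members")
    n_fam = len(families)
    prior: dict[int, float] = {}
    fam_of: dict[int, str] = {}
    for label, members in families.items():
        p = 1.0 / (n_fam * len(members))
        for mid in members:
            prior[mid] = p
            fam_of[mid] = label
    return FamilyPartition(families={f: tuple(m) for f, m in families.items()},
                           model_prior=prior, model_family=fam_of)


# -- model-space files -----------------------------------------------------

def save_model_space(models: Sequence[ModelSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in models], fh, indent=1)


def load_model_space(path) -> list[ModelSpec]:
    with open(path) as fh:
        entries = json.load(fh)
    if not entries:
        raise ValueError("empty model space")
    return [ModelSpec.from_dict(d) for d in entries]
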