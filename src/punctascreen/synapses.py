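"""Query-based probabilistic synapse detection.

A target synapse is defined operationally: a candidate-antibody punctum
colocalized with, or adjacent to, puncta of one or more reference
antibodies. Each reference contributes an *association factor* — the
maximum of its punctum probability over a search neighborhood (2×2 px
in-plane for colocalization, 6×6 px and ±1 slice for adjacency). The
synapse probability is the candidate punctum probability multiplied
voxel-wise by every reference's association factor (a probabilistic AND),
and is thresholded only after this cross-channel association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from .probability import ImageVolume, ProbabilityMap
from .puncta import (
    DEFAULT_THRESHOLD,
    PunctumQuery,
    PunctumSet,
    compute_punctum_probability,
    segment_puncta,
)

__all__ = [
    "Relationship",
    "SynapseQuery",
    "SynapseSet",
    "association_factor",
    "synapse_probability",
    "detect_synapses",
]

COLOCALIZED_WINDOW = 2  # px, same-location overlap
ADJACENT_WINDOW = 6  # px, pre/postsynaptic partners ~0.1-0.3 um apart


@dataclass(frozen=True)
class Relationship:
    """Spatial relation between a candidate and one reference channel.

    ``window_xy`` is the in-plane search window side in pixels; ``z_reach``
    is how many slices the reference may be offset axially. Colocalization
    (both markers on the same side of the synapse) searches a 2×2 window in
    the same slice; adjacency (pre- vs postsynaptic partners) searches a
    6×6 window and ±1 slice.
    """

    kind: str  # "colocalized" | "adjacent"
    window_xy: int = 0  # 0 → kind default
    z_reach: int = -1  # -1 → kind default

    def __post_init__(self) -> None:
        if self.kind not in ("colocalized", "adjacent"):
            raise ValueError(f"unknown relationship kind {self.kind!r}")
        if self.window_xy == 0:
            object.__setattr__(
                self,
                "window_xy",
                COLOCALIZED_WINDOW if self.kind == "colocalized" else ADJACENT_WINDOW,
            )
        if self.z_reach < 0:
            object.__setattr__(
                self, "z_reach", 0 if self.kind == "colocalized" else 1
            )
        if self.window_xy < COLOCALIZED_WINDOW:
            raise ValueError("search window must be at least the colocalization window")

    @classmethod
    def colocalized(cls, window_xy: int = COLOCALIZED_WINDOW, z_reach: int = 0):
        return cls("colocalized", window_xy, z_reach)

    @classmethod
    def adjacent(cls, window_xy: int = ADJACENT_WINDOW, z_reach: int = 1):
        return cls("adjacent", window_xy, z_reach)


@dataclass(frozen=True)
class SynapseQuery:
    """User-defined target-synapse composition.

    The candidate channel's minimum punctum size, plus at least one
    reference channel with its own minimum size and its relationship to the
    candidate. Channel names must be distinct.
    """

    candidate: PunctumQuery
    references: tuple[tuple[PunctumQuery, Relationship], ...]
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        refs = tuple(tuple(r) for r in self.references)
        if len(refs) == 0:
            raise ValueError("query requires at least one reference")
        names = [self.candidate.channel_name] + [q.channel_name for q, _ in refs]
        if len(set(names)) != len(names):
            raise ValueError(f"query channel names must be distinct; got {names}")
        object.__setattr__(self, "references", refs)

    @property
    def channel_names(self) -> list[str]:
        return [self.candidate.channel_name] + [
            q.channel_name for q, _ in self.references
        ]


@dataclass
class SynapseSet(PunctumSet):
    """Segmented target synapses, with the query that produced them."""

    query: SynapseQuery | None = field(default=None, compare=False)


def association_factor(
    reference_prob: ProbabilityMap, rel: Relationship
) -> ProbabilityMap:
    """Per-voxel evidence that a reference punctum lies within reach.

    The maximum of the reference punctum probability over the
    relationship's search neighborhood: an in-plane window of
    ``rel.window_xy`` pixels per side and slice offsets in
    [-z_reach, +z_reach]. Even windows have no center voxel; the window
    covers in-plane offsets [-(w//2), w-1-w//2] (reach ⌈w/2⌉), consistent
    with the containing-window rule used for the 2D blob product.
    Neighborhoods are clipped at the volume border (out-of-volume treated
    as 0).
    """
    if reference_prob.stage != "punctum3d":
        raise ValueError(
            f"expected punctum3d-stage map, got {reference_prob.stage!r}"
        )
    w = int(rel.window_xy)
    nz, ny, nx = reference_prob.shape
    if w > ny or w > nx:
        raise ValueError(f"search window {w}x{w} exceeds image extent {ny}x{nx}")
    size = (2 * int(rel.z_reach) + 1, w, w)
    out = ndi.maximum_filter(reference_prob.values, size=size, mode="constant", cval=0.0)
    return ProbabilityMap(
        values=out, stage="punctum3d", channel_name=reference_prob.channel_name
    )


def synapse_probability(
    channels: Mapping[str, ImageVolume], query: SynapseQuery
) -> ProbabilityMap:
    """Per-voxel probability of belonging to a target synapse.

    Candidate punctum probability × the association factor of every
    reference (product over references). No thresholding happens here: the
    map is thresholded only after the cross-channel association, so weak
    candidate evidence can still be rescued or rejected by its context.
    """
    missing = [n for n in query.channel_names if n not in channels]
    if missing:
        raise ValueError(f"missing channels: {missing}")
    cand_vol = channels[query.candidate.channel_name]
    shapes = {n: channels[n].shape for n in query.channel_names}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"channels not aligned: shapes {shapes}")
    cand_prob = compute_punctum_probability(cand_vol, query.candidate)
    values = cand_prob.values.copy()
    for ref_query, rel in query.references:
        ref_prob = compute_punctum_probability(
            channels[ref_query.channel_name], ref_query
        )
        values *= association_factor(ref_prob, rel).values
    return ProbabilityMap(
        values=values, stage="synapse", channel_name=cand_vol.channel_name
    )


def detect_synapses(
    channels: Mapping[str, ImageVolume],
    query: SynapseQuery,
    remediate: bool = True,
) -> SynapseSet:
    """Segment target synapses for a query.

    Thresholds the synapse probability map (query threshold, default 0.9)
    and labels connected components; each component is one detected target
    synapse.
    """
    prob = synapse_probability(channels, query)
    puncta = segment_puncta(prob, threshold=query.threshold, remediate=remediate)
    return SynapseSet(
        label_volume=puncta.label_volume,
        puncta=puncta.puncta,
        threshold=puncta.threshold,
        remediated=puncta.remediated,
        channel_name=puncta.channel_name,
        query=query,
    )
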