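"""Antibody-performance measurements and screening logic.

For one candidate antibody under one synapse query, four measurements
summarize labeling quality:

* **punctum density** (puncta / μm³) — labeling abundance; unexpectedly
  sparse suggests an insensitive or over-diluted antibody, unexpectedly
  dense suggests nonspecific binding;
* **mean punctum volume ± SD** (pixels) — a large SD relative to the mean
  flags erratic labeling (giant clusters among small puncta);
* **target synapse density** (synapses / μm³) — sensitivity: how many
  target synapses the candidate labels, comparable to an expected
  biological density (~1 /μm³ excitatory, ~0.15 /μm³ inhibitory synapses
  in rodent neocortex);
* **target specificity ratio (TSR)** — synapses / candidate puncta, the
  fraction of candidate puncta that sit at target synapses (1 = fully
  synaptic labeling, 0 = none).

Screening ranks candidates by TSR (ties broken by target synapse density)
after excluding candidates whose target synapse density exceeds a
user-supplied biological maximum — an implausibly high density reflects
off-target binding, not sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .probability import ImageVolume
from .puncta import (
    PunctumSet,
    compute_punctum_probability,
    punctum_density,
    punctum_volume_stats,
    segment_puncta,
)
from .synapses import SynapseQuery, SynapseSet, segment_puncta as _segment
from .synapses import synapse_probability

__all__ = [
    "MeasurementReport",
    "ScreeningVerdict",
    "QUERY_PRESETS",
    "target_synapse_density",
    "target_specificity_ratio",
    "evaluate_antibody",
    "run_query_sweep",
    "rank_candidates",
    "reports_to_dataframe",
]

#: Named query presets varying minimum axial span (μm): (candidate, reference).
#: At 70 nm sections: Q1 = 1/1 slices, Q2 = 2/1, Q3 = 2/2, Q4 = 3/1.
QUERY_PRESETS: dict[str, tuple[float, float]] = {
    "Q1": (0.07, 0.07),
    "Q2": (0.14, 0.07),
    "Q3": (0.14, 0.14),
    "Q4": (0.21, 0.07),
}


@dataclass(frozen=True)
class MeasurementReport:
    """All performance measurements for one candidate under one query."""

    channel_name: str
    punctum_density: float  # puncta per um^3
    mean_punctum_volume: float  # pixels
    sd_punctum_volume: float  # pixels
    target_synapse_density: float  # synapses per um^3
    tsr: float | None  # None when no puncta were detected
    tsr_raw: float | None  # without split-artifact remediation
    split_artifact: bool  # raw TSR exceeded 1
    n_puncta: int
    n_synapses: int
    total_volume_um3: float
    threshold: float
    query_name: str = ""
    query: SynapseQuery | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        d = {
            "channel_name": self.channel_name,
            "query_name": self.query_name,
            "punctum_density": self.punctum_density,
            "mean_punctum_volume": self.mean_punctum_volume,
            "sd_punctum_volume": self.sd_punctum_volume,
            "target_synapse_density": self.target_synapse_density,
            "tsr": self.tsr,
            "tsr_raw": self.tsr_raw,
            "split_artifact": self.split_artifact,
            "n_puncta": self.n_puncta,
            "n_synapses": self.n_synapses,
            "total_volume_um3": self.total_volume_um3,
            "threshold": self.threshold,
        }
        return d


@dataclass(frozen=True)
class ScreeningVerdict:
    """Rank or exclusion for one candidate in a screen."""

    channel_name: str
    rank: int | None  # None for excluded candidates
    excluded: bool
    reason: str
    tsr: float | None
    target_synapse_density: float
    expected_max_density: float


def target_synapse_density(
    synapses: SynapseSet | PunctumSet,
    pixel_size_xy: float,
    slice_thickness: float,
) -> float:
    """Detected target synapses per cubic micrometer of imaged tissue."""
    return punctum_density(synapses, pixel_size_xy, slice_thickness)


def target_specificity_ratio(
    synapses: SynapseSet | PunctumSet, puncta: PunctumSet
) -> float | None:
    """Fraction of candidate puncta associated with a target synapse.

    ``n_synapses / n_puncta``. Undefined (returned as None, with a warning)
    when no candidate puncta were detected — "no signal" is distinct from
    "no specificity". Values above 1 indicate the split-punctum
    thresholding artifact; they are preserved here and flagged by
    :func:`evaluate_antibody`.
    """
    if puncta.count == 0:
        warnings.warn(
            "TSR undefined: no candidate puncta detected", stacklevel=2
        )
        return None
    return synapses.count / puncta.count


def evaluate_antibody(
    channels: Mapping[str, ImageVolume],
    query: SynapseQuery,
    remediate: bool = True,
    query_name: str = "",
) -> MeasurementReport:
    """Run the full pipeline for one candidate antibody and one query.

    Computes the candidate's punctum probability map and the synapse
    probability map once, segments both (with and without split-artifact
    remediation so the raw TSR can be reported alongside), and assembles
    the measurement report. Deterministic given its inputs; the identity
    ``tsr × punctum_density = target_synapse_density`` holds by
    construction over the shared volume.
    """
    cand_vol = channels[query.candidate.channel_name]
    cand_prob = compute_punctum_probability(cand_vol, query.candidate)
    syn_prob = synapse_probability(channels, query)

    puncta = segment_puncta(cand_prob, query.threshold, remediate=remediate)
    synapses = _segment(syn_prob, query.threshold, remediate=remediate)
    puncta_raw = segment_puncta(cand_prob, query.threshold, remediate=False)
    synapses_raw = _segment(syn_prob, query.threshold, remediate=False)

    px, dz = cand_vol.pixel_size_xy, cand_vol.slice_thickness
    stats = punctum_volume_stats(puncta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tsr = target_specificity_ratio(synapses, puncta)
        tsr_raw = target_specificity_ratio(synapses_raw, puncta_raw)
    if puncta.count == 0:
        warnings.warn("TSR undefined: no candidate puncta detected", stacklevel=2)
    return MeasurementReport(
        channel_name=cand_vol.channel_name or query.candidate.channel_name,
        punctum_density=punctum_density(puncta, px, dz),
        mean_punctum_volume=stats.mean_volume,
        sd_punctum_volume=stats.sd_volume,
        target_synapse_density=target_synapse_density(synapses, px, dz),
        tsr=tsr,
        tsr_raw=tsr_raw,
        split_artifact=(tsr_raw is not None and tsr_raw > 1.0),
        n_puncta=puncta.count,
        n_synapses=synapses.count,
        total_volume_um3=cand_vol.total_volume_um3,
        threshold=query.threshold,
        query_name=query_name,
        query=query,
    )


def _query_with_spans(
    base: SynapseQuery, cand_span_um: float, ref_span_um: float
) -> SynapseQuery:
    return SynapseQuery(
        candidate=base.candidate.with_span(cand_span_um),
        references=tuple(
            (q.with_span(ref_span_um), rel) for q, rel in base.references
        ),
        threshold=base.threshold,
    )


def run_query_sweep(
    channels: Mapping[str, ImageVolume],
    base_query: SynapseQuery,
    presets: Mapping[str, tuple[float, float]] | None = None,
    remediate: bool = True,
) -> list[MeasurementReport]:
    """Evaluate one candidate under several minimum-size presets.

    Variants differ only in the minimum axial spans (candidate, reference)
    in μm; in-plane minima, relationships and threshold come from
    ``base_query``. Defaults to the four standard stringency presets
    :data:`QUERY_PRESETS`. Counts are non-increasing in the candidate span:
    a stricter query can only lose puncta.
    """
    if presets is None:
        presets = QUERY_PRESETS
    reports = []
    for name, (cand_span, ref_span) in presets.items():
        q = _query_with_spans(base_query, cand_span, ref_span)
        reports.append(
            evaluate_antibody(channels, q, remediate=remediate, query_name=name)
        )
    return reports


def rank_candidates(
    reports: Sequence[MeasurementReport], expected_max_density: float
) -> list[ScreeningVerdict]:
    """Rank candidate antibodies for a screen.

    Candidates whose target synapse density exceeds the biologically
    plausible maximum are excluded (reason "implausible density") — a
    density far above what the tissue can contain reflects off-target
    binding. The remainder are ranked by TSR descending, ties broken by
    target synapse density descending; candidates with undefined TSR (no
    detected puncta) rank last. The result lists ranked candidates first,
    then exclusions.
    """
    included: list[MeasurementReport] = []
    verdicts: list[ScreeningVerdict] = []
    excluded: list[ScreeningVerdict] = []
    for r in reports:
        if r.target_synapse_density > expected_max_density:
            excluded.append(
                ScreeningVerdict(
                    channel_name=r.channel_name,
                    rank=None,
                    excluded=True,
                    reason="implausible density",
                    tsr=r.tsr,
                    target_synapse_density=r.target_synapse_density,
                    expected_max_density=expected_max_density,
                )
            )
        else:
            included.append(r)
    included.sort(
        key=lambda r: (
            -(r.tsr if r.tsr is not None else float("-inf")),
            -r.target_synapse_density,
            r.channel_name,
        )
    )
    for rank, r in enumerate(included, start=1):
        verdicts.append(
            ScreeningVerdict(
                channel_name=r.channel_name,
                rank=rank,
                excluded=False,
                reason="",
                tsr=r.tsr,
                target_synapse_density=r.target_synapse_density,
                expected_max_density=expected_max_density,
            )
        )
    return verdicts + excluded


def reports_to_dataframe(reports: Sequence[MeasurementReport]) -> pd.DataFrame:
    """One row per candidate per query."""
    return pd.DataFrame([r.to_dict() for r in reports])


def plot_screen(
    reports: Sequence[MeasurementReport],
    verdicts: Sequence[ScreeningVerdict] | None = None,
    path: str | None = None,
):
    """Scatter of TSR vs target synapse density, one point per candidate.

    The standard screening view: specificity on the y axis, sensitivity on
    the x axis; excluded candidates are marked. Returns the matplotlib
    figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    excluded_names = {v.channel_name for v in (verdicts or []) if v.excluded}
    fig, ax = plt.subplots(figsize=(5, 4))
    for r in reports:
        y = r.tsr if r.tsr is not None else 0.0
        color = "crimson" if r.channel_name in excluded_names else "steelblue"
        ax.scatter(r.target_synapse_density, y, color=color, s=30)
        ax.annotate(r.channel_name, (r.target_synapse_density, y), fontsize=7)
    ax.set_xlabel("target synapse density (per μm³)")
    ax.set_ylabel("target specificity ratio")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
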