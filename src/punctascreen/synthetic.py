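"""Ground-truthed synthetic array-tomography volumes.

Emulates the statistical structure the detector assumes: Gaussian
background noise, compact multi-slice immunofluorescence puncta (isotropic
in-plane Gaussian profile, flat across a few consecutive sections), and
the confounders an antibody screen must cope with — single-slice
contaminant specks (dust, random noise) and giant clusters of label
(erratic antibodies). Candidate puncta can be planted colocalized with,
adjacent to, or isolated from reference-channel puncta, so detection and
specificity measurements can be scored against exact ground truth.

Not modeled: optical point-spread blurring, section-to-section
misalignment, autofluorescence spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .probability import ImageVolume
from .puncta import PunctumSet

__all__ = [
    "SyntheticSpec",
    "TruthObject",
    "GroundTruth",
    "MatchResult",
    "generate_dataset",
    "score_against_truth",
]

CANDIDATE = "candidate"
REFERENCE = "reference"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic two-channel dataset.

    Defaults describe the standard screening condition: a 256×256×8 stack
    at 100 nm / 70 nm voxels, background N(1000, 100²), 3×3 px × 3-slice
    puncta at 10 background-SD peak amplitude (high SNR, so detection is
    limited by the query rather than the noise), and well-separated
    objects.

    ``adjacency_fraction`` / ``colocalization_fraction`` of the
    ``n_candidate`` candidate puncta receive a reference partner (offset
    by ``adjacency_offset_px`` pixels in-plane and up to
    ``adjacency_offset_slices`` slices for adjacency; zero offset for
    colocalization); the rest are isolated. ``n_reference_only`` puncta
    appear only in the reference channel.
    """

    shape: tuple[int, int, int] = (8, 256, 256)  # (z, y, x)
    pixel_size_xy: float = 100.0  # nm
    slice_thickness: float = 70.0  # nm
    background_mean: float = 1000.0
    background_sd: float = 100.0
    punctum_sigma_px: float = 1.0  # in-plane Gaussian sigma
    punctum_halfwidth_px: int = 1  # footprint = (2h+1)^2 in-plane -> 3x3
    punctum_z_extent: int = 3  # slices, flat profile
    amplitude_sd: float = 10.0  # peak amplitude in background-SD units
    n_candidate: int = 100
    adjacency_fraction: float = 0.0
    colocalization_fraction: float = 0.0
    n_reference_only: int = 20
    n_specks: int = 0  # single-slice contaminants, candidate channel
    n_giant_clusters: int = 0  # erratic-labeling blobs, candidate channel
    cluster_sigma_px: float = 6.0
    cluster_halfwidth_px: int = 12
    adjacency_offset_px: int = 2  # in-plane offset of adjacent partners
    adjacency_offset_slices: int = 1  # max |z| offset of adjacent partners
    min_separation_px: int = 14  # between unrelated object centers
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.adjacency_fraction <= 1.0):
            raise ValueError("adjacency_fraction must lie in [0, 1]")
        if not (0.0 <= self.colocalization_fraction <= 1.0):
            raise ValueError("colocalization_fraction must lie in [0, 1]")
        if self.adjacency_fraction + self.colocalization_fraction > 1.0:
            raise ValueError("paired fractions must sum to at most 1")
        for n in (
            self.n_candidate,
            self.n_reference_only,
            self.n_specks,
            self.n_giant_clusters,
        ):
            if n < 0:
                raise ValueError("object counts must be non-negative")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")


class TruthObject(NamedTuple):
    """One planted object."""

    channel: str
    center: tuple[int, int, int]  # (z, y, x)
    kind: str  # "pair-candidate" | "pair-reference" | "isolated" | "speck" | "cluster" | "reference-only"
    pair_id: int | None  # links candidate<->reference partners


@dataclass
class GroundTruth:
    """All planted objects of one dataset plus the generator seed."""

    objects: list[TruthObject]
    seed: int
    spec: SyntheticSpec = field(repr=False, default=None)

    def centers(
        self, channel: str | None = None, kinds: Sequence[str] | None = None
    ) -> np.ndarray:
        """(n, 3) array of (z, y, x) centers, optionally filtered."""
        sel = [
            o.center
            for o in self.objects
            if (channel is None or o.channel == channel)
            and (kinds is None or o.kind in kinds)
        ]
        return np.array(sel, dtype=float).reshape(-1, 3)


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int, int],
    z_margin: int,
    xy_margin: int,
    existing: list[tuple[int, int, int]],
    min_sep: float,
    max_tries_per_object: int = 2000,
) -> list[tuple[int, int, int]]:
    """Rejection-sample interior centers with a minimum in-plane separation
    from all previously placed centers (separation is enforced in-plane
    only; the stacks are thin and association neighborhoods span ±1
    slice, so in-plane distance is the relevant isolation criterion)."""
    if n == 0:
        return []
    nz, ny, nx = shape
    if ny - 2 * xy_margin <= 0 or nx - 2 * xy_margin <= 0 or nz - 2 * z_margin <= 0:
        raise ValueError("infeasible packing: volume too small for object size")
    placed = list(existing)
    out: list[tuple[int, int, int]] = []
    for _ in range(n):
        for attempt in range(max_tries_per_object):
            z = int(rng.integers(z_margin, nz - z_margin))
            y = int(rng.integers(xy_margin, ny - xy_margin))
            x = int(rng.integers(xy_margin, nx - xy_margin))
            ok = all(
                (y - py) ** 2 + (x - px) ** 2 >= min_sep**2 for _, py, px in placed
            )
            if ok:
                placed.append((z, y, x))
                out.append((z, y, x))
                break
        else:
            raise ValueError(
                "infeasible packing: cannot satisfy the separation constraint"
            )
    return out


def _add_punctum(
    img: np.ndarray,
    center: tuple[int, int, int],
    amplitude: float,
    sigma: float,
    halfwidth: int,
    z_extent: int,
) -> None:
    """Add a separable blob: truncated isotropic Gaussian in-plane, flat
    over ``z_extent`` slices centered (rounding down) on the center slice."""
    nz, ny, nx = img.shape
    z, y, x = center
    dy = np.arange(-halfwidth, halfwidth + 1)
    profile = np.exp(-(dy[:, None] ** 2 + dy[None, :] ** 2) / (2.0 * sigma**2))
    z0 = z - (z_extent - 1) // 2
    for zz in range(z0, z0 + z_extent):
        if not (0 <= zz < nz):
            continue
        ys = slice(max(0, y - halfwidth), min(ny, y + halfwidth + 1))
        xs = slice(max(0, x - halfwidth), min(nx, x + halfwidth + 1))
        py = slice(ys.start - (y - halfwidth), profile.shape[0] - ((y + halfwidth + 1) - ys.stop))
        px = slice(xs.start - (x - halfwidth), profile.shape[1] - ((x + halfwidth + 1) - xs.stop))
        img[zz, ys, xs] += amplitude * profile[py, px]


def generate_dataset(spec: SyntheticSpec) -> tuple[dict[str, ImageVolume], GroundTruth]:
    """Generate a candidate/reference channel pair with known ground truth.

    Deterministic given ``spec.seed``. Background voxels are drawn from
    N(mean, sd²) truncated at 0; every planted object adds its profile on
    top. Returns the channels keyed ``"candidate"`` / ``"reference"`` and
    the ground-truth object list.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    h = spec.punctum_halfwidth_px
    zext = spec.punctum_z_extent
    z_margin = max((zext - 1) // 2 + 1, spec.adjacency_offset_slices + 1)
    z_margin = min(z_margin, (nz - 1) // 2) or 1
    xy_margin = max(h + spec.adjacency_offset_px + 2, 6)

    n_coloc = int(round(spec.colocalization_fraction * spec.n_candidate))
    n_adj = int(round(spec.adjacency_fraction * spec.n_candidate))
    n_iso = spec.n_candidate - n_coloc - n_adj

    placed: list[tuple[int, int, int]] = []
    cand_centers = _place_centers(
        rng, spec.n_candidate, spec.shape, z_margin, xy_margin, placed, spec.min_separation_px
    )
    placed += cand_centers
    ref_only_centers = _place_centers(
        rng, spec.n_reference_only, spec.shape, z_margin, xy_margin, placed, spec.min_separation_px
    )
    placed += ref_only_centers
    speck_centers = _place_centers(
        rng, spec.n_specks, spec.shape, 0, xy_margin, placed, spec.min_separation_px
    )
    placed += speck_centers
    cluster_margin = max(xy_margin, spec.cluster_halfwidth_px + 2)
    cluster_centers = _place_centers(
        rng,
        spec.n_giant_clusters,
        spec.shape,
        z_margin,
        cluster_margin,
        placed,
        spec.min_separation_px + spec.cluster_halfwidth_px,
    )

    cand = rng.normal(spec.background_mean, spec.background_sd, size=spec.shape)
    ref = rng.normal(spec.background_mean, spec.background_sd, size=spec.shape)
    amp = spec.amplitude_sd * spec.background_sd

    objects: list[TruthObject] = []
    pair_id = 0
    for i, c in enumerate(cand_centers):
        _add_punctum(cand, c, amp, spec.punctum_sigma_px, h, zext)
        if i < n_coloc:
            _add_punctum(ref, c, amp, spec.punctum_sigma_px, h, zext)
            objects.append(TruthObject(CANDIDATE, c, "pair-candidate", pair_id))
            objects.append(TruthObject(REFERENCE, c, "pair-reference", pair_id))
            pair_id += 1
        elif i < n_coloc + n_adj:
            # offset the partner by the adjacency distance in a random
            # in-plane axis direction, plus a random axial offset
            axis = int(rng.integers(0, 4))
            dyx = [(0, 1), (0, -1), (1, 0), (-1, 0)][axis]
            dz = int(rng.integers(-spec.adjacency_offset_slices, spec.adjacency_offset_slices + 1))
            rc = (
                c[0] + dz,
                c[1] + dyx[0] * spec.adjacency_offset_px,
                c[2] + dyx[1] * spec.adjacency_offset_px,
            )
            _add_punctum(ref, rc, amp, spec.punctum_sigma_px, h, zext)
            objects.append(TruthObject(CANDIDATE, c, "pair-candidate", pair_id))
            objects.append(TruthObject(REFERENCE, rc, "pair-reference", pair_id))
            pair_id += 1
        else:
            objects.append(TruthObject(CANDIDATE, c, "isolated", None))
    for c in ref_only_centers:
        _add_punctum(ref, c, amp, spec.punctum_sigma_px, h, zext)
        objects.append(TruthObject(REFERENCE, c, "reference-only", None))
    for c in speck_centers:
        _add_punctum(cand, c, amp, spec.punctum_sigma_px, h, z_extent=1)
        objects.append(TruthObject(CANDIDATE, c, "speck", None))
    for c in cluster_centers:
        _add_punctum(
            cand, c, amp, spec.cluster_sigma_px, spec.cluster_halfwidth_px, zext
        )
        objects.append(TruthObject(CANDIDATE, c, "cluster", None))

    np.clip(cand, 0.0, None, out=cand)
    np.clip(ref, 0.0, None, out=ref)
    channels = {
        CANDIDATE: ImageVolume(
            cand, spec.pixel_size_xy, spec.slice_thickness, CANDIDATE
        ),
        REFERENCE: ImageVolume(
            ref, spec.pixel_size_xy, spec.slice_thickness, REFERENCE
        ),
    }
    return channels, GroundTruth(objects=objects, seed=spec.seed, spec=spec)


class MatchResult(NamedTuple):
    """Detection score against planted ground truth."""

    precision: float | None  # None when there are no detections
    recall: float
    n_matched: int
    n_detected: int
    n_truth: int


def score_against_truth(
    detected: PunctumSet,
    truth: GroundTruth | np.ndarray,
    match_radius: float = 2.0,
    channel: str | None = None,
    kinds: Sequence[str] | None = None,
) -> MatchResult:
    """Greedy one-to-one matching of detected centroids to planted centers.

    Candidate matches (all detection/truth pairs within ``match_radius``
    voxels, Euclidean in index space) are accepted closest-first, each
    detection and each truth object used at most once. Precision is
    matched/detected (None when nothing was detected), recall is
    matched/planted.
    """
    if match_radius < 1:
        raise ValueError("match_radius must be >= 1 voxel")
    if isinstance(truth, GroundTruth):
        centers = truth.centers(channel=channel, kinds=kinds)
    else:
        centers = np.asarray(truth, dtype=float).reshape(-1, 3)
    det = np.array([p.centroid for p in detected.puncta], dtype=float).reshape(-1, 3)
    n_det, n_truth = len(det), len(centers)
    if n_truth == 0:
        # vacuous recall; precision is 0 for any (spurious) detection
        return MatchResult(
            precision=None if n_det == 0 else 0.0,
            recall=1.0,
            n_matched=0,
            n_detected=n_det,
            n_truth=0,
        )
    if n_det == 0:
        return MatchResult(None, 0.0, 0, 0, n_truth)
    d = np.linalg.norm(det[:, None, :] - centers[None, :, :], axis=2)
    pairs = np.argwhere(d <= match_radius)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_det: set[int] = set()
    used_truth: set[int] = set()
    matched = 0
    for i, j in pairs[order]:
        if i in used_det or j in used_truth:
            continue
        used_det.add(int(i))
        used_truth.add(int(j))
        matched += 1
    return MatchResult(
        precision=matched / n_det,
        recall=matched / n_truth,
        n_matched=matched,
        n_detected=n_det,
        n_truth=n_truth,
    )
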