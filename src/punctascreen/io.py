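"""File formats and run configuration.

One grayscale multi-page TIFF per antibody channel (pages are serial
sections, in order); voxel geometry always comes from the run
configuration, never from TIFF tags, because array-tomography TIFF
metadata is unreliable. Tables are UTF-8 CSV with '.' decimals; query and
run configuration travel as YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .probability import (
    DEFAULT_PIXEL_SIZE_NM,
    DEFAULT_SLICE_THICKNESS_NM,
    ImageVolume,
    ProbabilityMap,
)
from .puncta import DEFAULT_THRESHOLD, PunctumQuery, PunctumSet
from .synapses import Relationship, SynapseQuery

__all__ = [
    "read_channel_stack",
    "write_channel_stack",
    "write_probability_map",
    "write_label_volume",
    "write_punctum_table",
    "load_config",
    "ConfigError",
    "build_synapse_query",
    "write_provenance",
]


class ConfigError(ValueError):
    """Invalid run configuration; ``problems`` lists every defect found."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))


def read_channel_stack(
    path: str | Path,
    pixel_size_xy: float = DEFAULT_PIXEL_SIZE_NM,
    slice_thickness: float = DEFAULT_SLICE_THICKNESS_NM,
    channel_name: str = "",
) -> ImageVolume:
    """Read one channel from a multi-page grayscale TIFF.

    Pages become slices in order; intensities are handled as float
    internally whatever the stored dtype. Geometry comes from the caller
    (configuration), not from TIFF tags.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) == 0:
                raise ValueError(f"{path}: TIFF contains zero pages")
            shapes = {p.shape for p in tif.pages}
            if len(shapes) > 1:
                raise ValueError(f"{path}: ragged TIFF pages with shapes {shapes}")
            data = tif.asarray()
    except (OSError, tifffile.TiffFileError) as exc:
        raise ValueError(f"{path}: unreadable TIFF ({exc})") from exc
    data = np.asarray(data)
    if data.ndim == 2:  # single page
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got shape {data.shape}")
    return ImageVolume(
        intensities=data,
        pixel_size_xy=pixel_size_xy,
        slice_thickness=slice_thickness,
        channel_name=channel_name or path.stem,
    )


def write_channel_stack(path: str | Path, volume: ImageVolume) -> None:
    """Write an intensity volume as a multi-page TIFF (dtype preserved)."""
    tifffile.imwrite(str(path), volume.intensities)


def write_probability_map(path: str | Path, prob: ProbabilityMap) -> None:
    """Write a probability map as a 32-bit float multi-page TIFF."""
    tifffile.imwrite(str(path), prob.values.astype(np.float32))


def write_label_volume(path: str | Path, puncta: PunctumSet) -> None:
    """Write a label volume as a 16-bit multi-page TIFF."""
    labels = puncta.label_volume
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot write 16-bit label map")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def write_punctum_table(path: str | Path, puncta: PunctumSet) -> None:
    """Write the punctum/synapse table (id, z, y, x, voxel_count) as CSV."""
    puncta.to_dataframe().to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration document."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _min_size_triplet(value: Any, where: str, problems: list[str]):
    """Parse a (z, y, x) minimum size in μm from a 3-list or 'ZxYxX' text."""
    if isinstance(value, str):
        parts = value.lower().split("x")
    else:
        parts = list(value) if isinstance(value, (list, tuple)) else None
    if parts is None or len(parts) != 3:
        problems.append(f"{where}: min size must be three values (z, y, x) in μm")
        return None
    try:
        z, y, x = (float(p) for p in parts)
    except (TypeError, ValueError):
        problems.append(f"{where}: min size values must be numeric")
        return None
    if min(z, y, x) <= 0:
        problems.append(f"{where}: min size values must be positive")
        return None
    return z, y, x


def build_synapse_query(cfg: Mapping[str, Any]) -> SynapseQuery:
    """Build a :class:`SynapseQuery` from a configuration mapping.

    Expected layout::

        query:
          candidate: {channel: ab1, min_size_um: [0.14, 0.2, 0.2]}
          references:
            - {channel: synapsin, kind: adjacent,
               min_size_um: [0.07, 0.2, 0.2], window: 6, z_reach: 1}
        threshold: 0.9

    Validation collects every problem before raising :class:`ConfigError`.
    """
    problems: list[str] = []
    qcfg = cfg.get("query", {})
    ccfg = qcfg.get("candidate")
    if not isinstance(ccfg, Mapping) or "channel" not in ccfg:
        problems.append("query.candidate: must give a channel name")
        ccfg = {}
    cand_size = _min_size_triplet(
        ccfg.get("min_size_um", [0.14, 0.2, 0.2]), "query.candidate", problems
    ) or (0.14, 0.2, 0.2)
    refs_cfg = qcfg.get("references", [])
    if not refs_cfg:
        problems.append("query requires at least one reference")
    references = []
    for i, rcfg in enumerate(refs_cfg):
        where = f"query.references[{i}]"
        if not isinstance(rcfg, Mapping) or "channel" not in rcfg:
            problems.append(f"{where}: must give a channel name")
            continue
        kind = rcfg.get("kind", "adjacent")
        if kind not in ("colocalized", "adjacent"):
            problems.append(f"{where}: kind must be 'colocalized' or 'adjacent'")
            continue
        size = _min_size_triplet(
            rcfg.get("min_size_um", [0.07, 0.2, 0.2]), where, problems
        ) or (0.07, 0.2, 0.2)
        rel = Relationship(
            kind=kind,
            window_xy=int(rcfg.get("window", 0)),
            z_reach=int(rcfg.get("z_reach", -1)),
        )
        references.append(
            (
                PunctumQuery(
                    channel_name=str(rcfg["channel"]),
                    min_blob_um=(size[1], size[2]),
                    min_span_um=size[0],
                ),
                rel,
            )
        )
    threshold = cfg.get("threshold", DEFAULT_THRESHOLD)
    try:
        threshold = float(threshold)
        if not (0.0 < threshold < 1.0):
            problems.append("threshold must lie in (0, 1)")
    except (TypeError, ValueError):
        problems.append("threshold must be numeric")
        threshold = DEFAULT_THRESHOLD
    if problems:
        raise ConfigError(problems)
    return SynapseQuery(
        candidate=PunctumQuery(
            channel_name=str(ccfg["channel"]),
            min_blob_um=(cand_size[1], cand_size[2]),
            min_span_um=cand_size[0],
        ),
        references=tuple(references),
        threshold=threshold,
    )


def write_provenance(path: str | Path, record: Mapping[str, Any]) -> None:
    """Write a JSON provenance record (config echo, version, seeds).

    Deterministic (sorted keys, no timestamps) so a re-run with the same
    configuration produces a byte-identical record.
    """
    from . import __version__

    payload = {"punctascreen_version": __version__, **record}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
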