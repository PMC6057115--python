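import numpy as np
import pytest

from punctascreen import (
    ImageVolume,
    PunctumQuery,
    Relationship,
    SynapseQuery,
    SyntheticSpec,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_volume(rng):
    """Pure Gaussian background, default geometry."""
    data = rng.normal(1000.0, 100.0, size=(5, 32, 32))
    return ImageVolume(np.clip(data, 0, None), channel_name="noise")


@pytest.fixture
def default_query():
    return PunctumQuery(channel_name="", min_blob_um=(0.2, 0.2), min_span_um=0.14)


@pytest.fixture
def adjacency_query():
    """Candidate 2x2x2, reference 2x2x1, adjacent relationship."""
    return SynapseQuery(
        candidate=PunctumQuery("candidate", min_span_um=0.14),
        references=(
            (PunctumQuery("reference", min_span_um=0.07), Relationship.adjacent()),
        ),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """High-SNR dataset: 50 candidates, 60% adjacent to a reference."""
    spec = SyntheticSpec(
        shape=(8, 192, 192),
        n_candidate=40,
        adjacency_fraction=0.6,
        n_reference_only=8,
        seed=7,
    )
    return generate_dataset(spec)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (per-voxel enumeration; deliberately naive)


def brute_blob2d(fg: np.ndarray, wy: int, wx: int) -> np.ndarray:
    """Max over all fully-interior wy×wx windows containing each voxel of
    the product of values in the window; 0 where no window covers."""
    nz, ny, nx = fg.shape
    out = np.zeros_like(fg)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                best = 0.0
                for ay in range(max(0, y - wy + 1), min(y, ny - wy) + 1):
                    for ax in range(max(0, x - wx + 1), min(x, nx - wx) + 1):
                        best = max(best, float(np.prod(fg[z, ay : ay + wy, ax : ax + wx])))
                out[z, y, x] = best
    return out


def brute_span(blob: np.ndarray, span: int) -> np.ndarray:
    """Max over all runs of ``span`` consecutive slices containing z of the
    per-column product across the run."""
    nz = blob.shape[0]
    out = np.zeros_like(blob)
    for z in range(nz):
        for z0 in range(max(0, z - span + 1), min(z, nz - span) + 1):
            prod = np.prod(blob[z0 : z0 + span], axis=0)
            out[z] = np.maximum(out[z], prod)
    return out


def brute_association(ref: np.ndarray, window: int, z_reach: int) -> np.ndarray:
    """Max of ref over the search neighborhood: in-plane offsets
    [-(w//2), w-1-w//2], z offsets [-z_reach, z_reach], clipped at borders."""
    nz, ny, nx = ref.shape
    lo, hi = -(window // 2), window - 1 - window // 2
    out = np.zeros_like(ref)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                best = 0.0
                for dz in range(-z_reach, z_reach + 1):
                    for dy in range(lo, hi + 1):
                        for dx in range(lo, hi + 1):
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                best = max(best, ref[zz, yy, xx])
                out[z, y, x] = best
    return out
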