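"""Association factors, synapse probability and query-based detection."""

import numpy as np
import pytest

from punctascreen import (
    ImageVolume,
    ProbabilityMap,
    PunctumQuery,
    Relationship,
    SynapseQuery,
    association_factor,
    compute_punctum_probability,
    detect_synapses,
    synapse_probability,
)
from punctascreen.synthetic import SyntheticSpec, generate_dataset

from conftest import brute_association


def ref_map(values):
    return ProbabilityMap(np.asarray(values, dtype=float), stage="punctum3d")


class TestRelationship:
    def test_kind_defaults(self):
        coloc = Relationship.colocalized()
        adj = Relationship.adjacent()
        assert (coloc.window_xy, coloc.z_reach) == (2, 0)
        assert (adj.window_xy, adj.z_reach) == (6, 1)

    def test_window_below_colocalization_rejected(self):
        with pytest.raises(ValueError):
            Relationship("adjacent", window_xy=1)

    def test_query_requires_reference(self):
        with pytest.raises(ValueError, match="at least one reference"):
            SynapseQuery(candidate=PunctumQuery("a"), references=())

    def test_query_requires_distinct_channels(self):
        with pytest.raises(ValueError, match="distinct"):
            SynapseQuery(
                candidate=PunctumQuery("a"),
                references=((PunctumQuery("a"), Relationship.adjacent()),),
            )


class TestAssociationFactor:
    def test_zero_map(self):
        out = association_factor(ref_map(np.zeros((3, 10, 10))), Relationship.adjacent())
        assert np.all(out.values == 0.0)

    def test_single_voxel_adjacency_reach(self):
        vals = np.zeros((5, 13, 13))
        vals[2, 6, 6] = 0.95
        out = association_factor(ref_map(vals), Relationship.adjacent()).values
        np.testing.assert_allclose(out, brute_association(vals, 6, 1), atol=0)
        # reach is asymmetric for an even window: +3/-2 around the source
        assert out[2, 6 + 3, 6] == 0.95 and out[2, 6 - 2, 6] == 0.95
        assert out[2, 6 + 4, 6] == 0.0 and out[2, 6 - 3, 6] == 0.0
        assert out[1, 6, 6] == 0.95 and out[3, 6, 6] == 0.95
        assert out[0, 6, 6] == 0.0 and out[4, 6, 6] == 0.0

    @pytest.mark.parametrize(
        "window,z_reach", [(2, 0), (6, 1), (3, 1), (4, 2)]
    )
    def test_matches_bruteforce(self, rng, window, z_reach):
        vals = rng.uniform(0, 1, size=(5, 12, 12))
        out = association_factor(
            ref_map(vals), Relationship("adjacent", window, z_reach)
        ).values
        np.testing.assert_allclose(
            out, brute_association(vals, window, z_reach), atol=1e-15
        )

    def test_colocalized_below_adjacent(self, rng):
        vals = rng.uniform(0, 1, size=(4, 10, 10))
        coloc = association_factor(ref_map(vals), Relationship.colocalized()).values
        adj = association_factor(ref_map(vals), Relationship.adjacent()).values
        assert np.all(coloc <= adj)

    def test_window_exceeding_extent(self):
        with pytest.raises(ValueError, match="exceeds image extent"):
            association_factor(
                ref_map(np.zeros((2, 4, 4))), Relationship("adjacent", window_xy=6)
            )


def _two_channel_fixture(offset_px, seed=3):
    """Candidate + reference channels with every candidate punctum's partner
    offset by ``offset_px`` pixels in x."""
    spec = SyntheticSpec(
        shape=(8, 160, 160),
        n_candidate=20,
        adjacency_fraction=1.0,
        adjacency_offset_px=offset_px,
        adjacency_offset_slices=0,
        n_reference_only=5,
        seed=seed,
    )
    return generate_dataset(spec)


class TestSynapseProbability:
    def test_colocalized_product_rule(self):
        spec = SyntheticSpec(
            shape=(8, 128, 128), n_candidate=10, colocalization_fraction=1.0,
            n_reference_only=0, seed=5,
        )
        channels, truth = generate_dataset(spec)
        query = SynapseQuery(
            candidate=PunctumQuery("candidate"),
            references=((PunctumQuery("reference"), Relationship.colocalized()),),
        )
        syn = synapse_probability(channels, query)
        cand = compute_punctum_probability(channels["candidate"], query.candidate)
        # product with factors in [0,1]: synapse <= candidate voxel-wise
        assert np.all(syn.values <= cand.values + 1e-12)
        for z, y, x in truth.centers("candidate").astype(int):
            p = cand.values[z, y, x]
            assert syn.values[z, y, x] == pytest.approx(p * p, abs=0.05)

    def test_distant_reference_needs_adjacency(self):
        channels, _ = _two_channel_fixture(offset_px=5)
        cand = PunctumQuery("candidate")
        ref = PunctumQuery("reference", min_span_um=0.07)
        coloc_q = SynapseQuery(cand, ((ref, Relationship.colocalized()),))
        adj_q = SynapseQuery(cand, ((ref, Relationship("adjacent", window_xy=12)),))
        assert detect_synapses(channels, coloc_q).count == 0
        assert detect_synapses(channels, adj_q).count == 20

    def test_zero_reference_annihilates(self, planted_dataset):
        channels, _ = planted_dataset
        flat = ImageVolume(
            np.abs(np.random.default_rng(0).normal(1000, 100, channels["candidate"].shape)),
            channel_name="empty_ref",
        )
        query = SynapseQuery(
            candidate=PunctumQuery("candidate"),
            references=(
                (PunctumQuery("reference", min_span_um=0.07), Relationship.adjacent()),
                (PunctumQuery("empty_ref", min_span_um=0.07), Relationship.adjacent()),
            ),
        )
        syn = detect_synapses({**channels, "empty_ref": flat}, query)
        # the pure-noise second reference suppresses (nearly) every synapse
        assert syn.count == 0

    def test_shape_mismatch(self, adjacency_query):
        a = ImageVolume(np.random.default_rng(0).uniform(0, 10, (4, 8, 8)),
                        channel_name="candidate")
        b = ImageVolume(np.random.default_rng(1).uniform(0, 10, (4, 9, 8)),
                        channel_name="reference")
        with pytest.raises(ValueError, match="not aligned"):
            synapse_probability({"candidate": a, "reference": b}, adjacency_query)


class TestDetectSynapses:
    def test_planted_adjacency_counts(self, planted_dataset, adjacency_query):
        channels, truth = planted_dataset
        syn = detect_synapses(channels, adjacency_query)
        n_paired = len(truth.centers("candidate", kinds=["pair-candidate"]))
        assert syn.count == n_paired

    def test_span_stringency_monotone(self, planted_dataset, adjacency_query):
        channels, _ = planted_dataset
        counts = []
        for span in (0.07, 0.14, 0.21):
            q = SynapseQuery(
                candidate=adjacency_query.candidate.with_span(span),
                references=adjacency_query.references,
            )
            counts.append(detect_synapses(channels, q).count)
        assert counts == sorted(counts, reverse=True)

    def test_adding_reference_never_increases(self, planted_dataset, adjacency_query):
        channels, _ = planted_dataset
        base = detect_synapses(channels, adjacency_query).count
        # second reference = same channel data under a stricter span
        chans = {**channels,
                 "reference2": ImageVolume(channels["reference"].intensities,
                                           channel_name="reference2")}
        q2 = SynapseQuery(
            candidate=adjacency_query.candidate,
            references=adjacency_query.references
            + ((PunctumQuery("reference2", min_span_um=0.14), Relationship.adjacent()),),
        )
        assert detect_synapses(chans, q2).count <= base

    def test_symmetric_swap_on_colocalized_fixture(self):
        spec = SyntheticSpec(
            shape=(8, 128, 128), n_candidate=12, colocalization_fraction=1.0,
            n_reference_only=0, seed=9,
        )
        channels, _ = generate_dataset(spec)
        forward = SynapseQuery(
            PunctumQuery("candidate"),
            ((PunctumQuery("reference"), Relationship.colocalized()),),
        )
        backward = SynapseQuery(
            PunctumQuery("reference"),
            ((PunctumQuery("candidate"), Relationship.colocalized()),),
        )
        assert (
            detect_synapses(channels, forward).count
            == detect_synapses(channels, backward).count
        )
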