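# Methods

## Problem and model

Array tomography (AT) images serial ~70 nm plastic sections of
immunolabeled brain tissue, aligned into a 3D stack with one channel per
antibody. Validating an antibody against a synaptic protein requires
deciding, for each punctum of immunofluorescence, whether it sits at a
synapse — a judgment traditionally made by eye. `punctascreen` automates it
with a probabilistic, query-based detector and a small set of summary
measurements.

### Punctum probability

Each channel is modeled as Gaussian background noise with the signal as an
outlier. The background mean μ and standard deviation σ are estimated from
*all* voxels of the channel (signal occupies a negligible fraction, so the
channel-wide statistics are background statistics to good approximation).
The population (divide-by-n) SD is used: the model treats the whole channel
as the noise population, and fixing the convention makes runs reproducible.
Constant-intensity channels are rejected (`degenerate background`) rather
than silently producing all-0.5 maps.

Three transforms follow, each mapping a probability volume to one of the
same shape with values in [0, 1]:

1. **Foreground**: p_fg(I) = Φ((I − μ)/σ), the lower-tail normal CDF —
   one minus the probability of belonging to the background. This reading
   is a design choice (an upper-tail or two-sided reading would not be
   monotone or would halve the scale); it is monotone in intensity and
   equals 0.5 at the background mean.
2. **2D blob**: for a minimum in-plane extent of w_y × w_x pixels, each
   voxel receives the maximum over all fully-interior w_y × w_x windows
   containing it of the product of foreground probabilities in the window.
   The product demands the whole minimum footprint be foreground-like; the
   containing-window maximum spreads a qualifying window's score to every
   voxel it covers, so all voxels of one blob carry the blob's probability.
   Windows must lie fully inside the slice; border voxels covered by no
   such window get 0 (a blob must have full minimum support).
3. **z-span**: the same product-then-containing-run-maximum along z over
   runs of the minimum slice count. A span of 1 is the identity.

Even-sized windows have no center voxel; the containing-window rule removes
the need to choose an anchor (both slices of a 2-slice punctum carry its
probability, all four voxels of a 2×2 blob do too). Products are computed
directly as floating-point products of shifted arrays: factors lie in
[0, 1], so overflow is impossible and underflow saturates harmlessly at 0;
the implementation is checked against per-voxel brute-force enumeration to
1e-12.

The punctum map is thresholded at 0.9 (the project-wide default, exposed as
a knob) and connected components under 26-connectivity become puncta.

### Synapse probability

A target synapse is defined by the user's query: candidate punctum
colocalized with or adjacent to puncta of one or more validated reference
antibodies. Each reference contributes an **association factor**: the
maximum of its punctum probability over a search neighborhood of each
voxel — 2×2 px in-plane with no z offset for colocalization, 6×6 px and ±1
slice for adjacency. The z-reach values are design defaults (configurable):
colocalized markers share a location on a section, while pre/postsynaptic
partners may sit on neighboring sections. For even windows the neighborhood
covers in-plane offsets [−w/2, w/2 − 1] (reach ⌈w/2⌉), matching the
containing-window convention; neighborhood maxima are clipped at the volume
border (a maximum over a partial neighborhood is well-defined, unlike the
full-support product windows).

The synapse probability is the candidate punctum probability multiplied
voxel-wise by every reference's association factor — a probabilistic AND,
the natural combination rule for a query of the form "candidate AND ref1
AND ref2". Thresholding happens only after this association. One connected
component of the thresholded map is one synapse; merged components are not
split (so two candidate puncta sharing one reference region may count as
one synapse — the simplest consistent reading).

### Measurements and screening

* punctum density = n_puncta / total volume (μm³);
* punctum volume mean and population SD (pixels) — a large SD/mean ratio
  flags erratic labeling;
* target synapse density = n_synapses / total volume;
* target specificity ratio TSR = n_synapses / n_puncta, in [0, 1] up to
  the split artifact below. TSR for zero detected puncta is reported as
  missing, not 0, distinguishing "no signal" from "no specificity".

TSR · punctum density = target synapse density holds identically (same
counts over the same volume); the test suite asserts it to rounding.

**Split artifact.** Thresholding can fragment one punctum into several
labels through a single sub-threshold voxel, inflating counts and pushing
TSR above 1. Remediation is one binary closing with a 3×3 in-plane
structuring element applied slice-wise before labeling — enough to bridge
one-voxel splits without connecting distinct puncta across sections. It is
on by default and switchable off; reports carry both the remediated and the
raw TSR plus a `split_artifact` flag when the raw value exceeds 1. The
choice of a single 3×3 slice-wise closing is a design decision; only the
purpose (repairing threshold splits) is externally fixed.

**Query presets.** Minimum sizes are physical (μm) and converted through
the voxel geometry with round-half-up, floored at 1 (0.2 μm → 2 px at
100 nm pixels; 0.14 μm → 2 slices at 70 nm sections). Four stringency
presets vary the axial spans (candidate/reference, in slices at 70 nm):
Q1 = 1/1, Q2 = 2/1, Q3 = 2/2, Q4 = 3/1. Q2 (two-section candidate) is the
recommended screening default; Q1 admits single-section specks and is known
to be unreliable.

**Ranking.** Candidates are ranked by TSR descending, ties broken by
target synapse density descending — no combined score is invented.
Candidates whose target synapse density exceeds a user-supplied plausible
maximum (tissue-dependent; ~1 /μm³ for excitatory, ~0.15 /μm³ for
inhibitory cortical synapses are typical priors) are excluded with reason
`implausible density`: density far above what the tissue can contain
reflects off-target binding. There is no formal cutoff rule in the
literature, so the threshold is always user-supplied configuration, never
a constant.

## Synthetic data

The generator emulates exactly the structure the detector assumes:
background ~ N(μ, σ²) truncated at 0, puncta as truncated isotropic
in-plane Gaussians (σ = 1 px, 3×3 px footprint) with a flat profile across
their axial extent (3 slices by default — synaptic puncta span several
sections), peak amplitude 10σ above background (the high-SNR regime where
detection is limited by the query, not the noise). Confounders: 1-slice
specks (dust/noise) and giant clusters (σ = 6 px, 25×25 px footprint)
emulating erratic antibodies. Default canvas: 8 × 256 × 256 voxels at the
standard 100 × 100 × 70 nm geometry (367 μm³) — large enough for ~100
well-separated puncta, small enough that the whole suite runs in seconds.

Planted candidate puncta are colocalized (same center), adjacent (partner
offset 2 px along one in-plane axis and up to ±1 slice — inside the 6×6/±1
adjacency reach) or isolated. Centers are rejection-sampled with a minimum
*in-plane* separation (14 px) from all unrelated objects; since the
adjacency reach is 3 px plus a 1 px blob radius, isolated puncta can never
associate by accident, so the planted adjacency fraction is exactly the
expected TSR. Separation is enforced in-plane only because the stacks are
thin and association reaches ±1 slice everywhere. Infeasible packings
(too many objects for the canvas) raise an error rather than degrading
silently. One `numpy` generator seeded once per dataset makes volumes
bit-reproducible; the seed is recorded in the ground truth.

What the generator does **not** model: optical point-spread blurring,
section misalignment, autofluorescence spectra, intensity heterogeneity
between puncta. Passing tests therefore demonstrate correctness of the
algorithmic pipeline under its own assumptions, not performance on real
tissue, where alignment quality and antibody behavior dominate.

Detection is scored against ground truth by greedy closest-first one-to-one
matching of detected centroids to planted centers within a 2-voxel radius
(index-space Euclidean distance); precision is undefined (missing) when
nothing was detected.

## Numerical and degenerate-input choices

* Thresholding uses ≥, with the threshold restricted to (0, 1).
* Empty punctum sets yield (0, 0) volume statistics with an `empty` flag
  instead of an error, so multi-candidate screens never abort.
* Probability maps validate their [0, 1] range and stage at construction.
* Voxel geometry always comes from configuration, never from TIFF tags
  (AT TIFF metadata is unreliable); defaults 100/100/70 nm.
* Provenance records contain no timestamps, so re-runs are byte-identical.

## Problem sizes

Tests and the acceptance script use 8 × 256 × 256-voxel volumes (or
smaller) with 40–100 planted puncta — the package's standard synthetic
screening condition. Measured behavior at this size: planted-punctum
precision and recall of 1.0, zero spurious noise detections, TSR equal to
the planted adjacency fraction to within one punctum.

## Known limitations

* The Gaussian background model is global per channel; slowly varying
  background (uneven illumination) will bias foreground probabilities.
  Local background estimation is deliberately out of scope.
* No handling of misaligned stacks beyond relaxing the z-span to 1 slice.
* Fluorescence bleed-through between channels can mimic colocalization and
  is not corrected.
* Merged synapse components are counted once; very dense reference
  labeling can therefore undercount synapses.
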