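# Methods

## The analysis

The package implements a resting-state MEG network analysis for placing
individual subjects on a disease spectrum spanned by two anchor groups
(pure-motor ALS and bvFTD), with an intermediate group (ALS with
cognitive/behavioral impairment, "cibi") scored against both anchors at
two timepoints. The chain is:

1. **Connectivity.** Per artifact-free epoch, region time series are
   decimated (anti-aliased FIR, default factor 4), band-pass filtered
   into six canonical bands (delta 0.5–4, theta 4–8, alpha1 8–10,
   alpha2 10–13, beta 13–30, gamma 30–48 Hz), and the corrected amplitude
   envelope correlation (AECc) computed for every region pair. AECc
   regresses each signal out of the other in the time domain before
   correlating Hilbert envelopes, removing zero-lag leakage; the two
   orthogonalization directions are averaged and negative means clipped
   to 0. Epoch matrices are averaged entrywise.
2. **Backbone.** Connectivity is converted to distance by d = 1/max(w, ε)
   (ε = 1e−6) and the minimum spanning tree extracted with Kruskal's
   algorithm — equivalently the maximum spanning tree of the similarity
   weights: the N−1 strongest connections that join all regions without
   cycles, comparable across subjects without density thresholds.
3. **Similarity.** Two reference MSTs per band and timepoint are built
   from the unweighted mean of the anchor groups' per-subject epoch-mean
   matrices (intermediate subjects never enter a reference). A subject's
   similarity to a reference is the fraction of tree edges shared,
   computed per epoch and averaged (default), or once on the MST of the
   subject's mean adjacency matrix (alternative mode). The spectrum
   coordinate of a subject is Δ = sim(bvFTD ref) − sim(motor ref).
4. **Topology.** Per tree: leaf fraction L/M (M = N−1), diameter in edges
   and normalized by M, per-node betweenness centrality normalized by
   (N−1)(N−2)/2, and tree hierarchy Th = L/(2·M·BCmax) ∈ (0, 0.5].
   Normalizations follow the MST-backbone literature (star ⇒ leaf
   fraction 1 and Th 0.5); they are a package convention, since exact
   normalizations vary across publications.
5. **Inference.** Two families of two-sided Wilcoxon signed-rank tests on
   the intermediate group: cross-sectional (motor-ref vs bvFTD-ref
   similarity, per band and timepoint) and longitudinal (baseline vs
   follow-up, per band and reference), each family BH-FDR corrected at
   q = 0.05. Zero differences are discarded; ties get average ranks; the
   null is enumerated exactly for n ≤ 15 and otherwise approximated by a
   tie-corrected normal Z without continuity correction (the convention
   of the commercial packages that report Z alongside p).

## Synthetic cohorts

Real request-only MEG cannot ship with the package, so a generator
produces cohorts with the structure the analysis assumes, giving every
claim a recoverable ground truth.

- **Archetypes.** Two networks whose planted MST backbones share at most
  a target fraction of edges (default 0.2, checked ≤ target + 0.1).
  Backbone edges carry weights U(0.6, 0.9) over background U(0.05, 0.3),
  so the archetype's MST is its planted tree. Tree pairs are drawn by
  joint rejection from uniform random labeled trees (Prüfer sequences);
  both trees are redrawn on failure because some trees (stars on 4 nodes)
  admit no edge-disjoint partner.
- **Subjects.** Each subject has a latent spectrum coordinate λ ∈ [0, 1];
  expected connectivity is the linear interpolation
  (1−λ)·W_motor + λ·W_bvftd — the simplest model under which λ is
  identifiable from MST similarity. Baseline λ is uniform per group:
  motor U(0, 0.1), cibi U(0.2, 0.5), bvftd U(0.9, 1.0) — anchors tight
  against their ends, the intermediate group nearer the motor anchor, as
  its clinical phenotype suggests. At follow-up λ shifts by a per-group
  drift (motor 0, bvftd 0, cibi +0.3, clipped to [0, 1]): the progression
  hypothesis — intermediate subjects move toward the bvFTD phenotype —
  encoded as recoverable truth.
- **Epoch noise (matrix mode).** i.i.d. Gaussian noise (sd 0.05) on the
  upper triangle, mirrored, clipped to (1e−6, 1) so weights stay
  invertible. 0.05 is small against the planted backbone gap (~0.3) but
  large enough that epoch-level trees differ.
- **Time-series mode.** Per epoch, each region gets a constant-modulus
  band-limited carrier (cosine of the instantaneous phase of narrowband
  noise) multiplied by a positive log-normal envelope exp(σ·g), σ = 0.4,
  where the slow Gaussian fields g have spatial correlation
  eigenvalue-clipped from coupling_scale·W (coupling_scale 0.8) and are
  low-passed at clip(f_lo/2, 0.25, 6) Hz — well below the carrier band
  but fast enough that one 13.1 s epoch holds a useful number of
  envelope degrees of freedom. White noise (sd 0.15 of carrier scale) is
  added broadband. The constant-modulus carrier keeps the planted
  modulator as the signal's envelope rather than confounding it with the
  Rayleigh envelope of Gaussian noise; with heavier-tailed envelopes
  (σ ≈ 0.75) occasional bursts dominate the correlation estimator and
  inflate null AECc (~0.18 mean under independence), while σ = 0.4 keeps
  the independence null near 0.04 and Spearman between planted weights
  and estimated AECc near 0.75.
- **Determinism.** Per-subject/timepoint substreams derive from the
  master seed by CRC-hashing subject id and timepoint: identical configs
  are bit-identical and adding subjects never perturbs existing ones.

**What the generator does not emulate:** anatomical leakage geometry
(leakage robustness is exercised by constructed signal mixtures instead),
1/f spectra, cross-band coupling, nonstationarity within epochs, or any
spatial organization of the 90 regions. Passing tests show the pipeline
recovers structure *of this model*; they are not evidence about effect
sizes in real MEG, whose similarity scores are an order of magnitude
lower than the synthetic ones.

## Numerical and design choices

- **Filters:** windowed-sinc (Hamming) FIR applied with filtfilt (zero
  phase); transition width 25% of each band edge, with cutoffs widened by
  half a transition so the nominal band sits in the flat passband; filter
  length capped at a third of the epoch so filtfilt padding fits, which
  widens the delta-band transition on short epochs.
- **AECc conventions:** first/last 5% of envelope samples dropped before
  correlating (filter/Hilbert transients); zero-variance residual (a
  perfectly leaked copy) contributes 0 with a logged warning; negative
  mean correlations clipped to 0, not folded — sign is not interpreted
  anywhere downstream and the MST inversion needs nonnegative weights.
- **Kruskal tie-break:** edges sorted by (distance, smaller index,
  larger index); with all-distinct weights the MST is unique, and under
  ties the result is still reproducible and permutation-consistent.
- **Degenerate guards:** leaf fraction/betweenness/hierarchy require
  N ≥ 3; a fully zero connectivity matrix still yields a tree (the
  ε floor makes the distance matrix complete) with deterministic
  tie-breaking.
- **Exact vs normal Wilcoxon:** the exact two-sided p is
  min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))) by full 2ⁿ sign enumeration.
  At n = 12 the normal approximation departs from the exact p by up to
  ~0.04 in the mid-range (p ≈ 0.6) while agreeing within 0.02 where
  decisions are made (p < 0.2).
- **FDR family:** six bands × two {timepoints|references} = 12 tests per
  family, corrected separately for the cross-sectional and longitudinal
  families — the most literal reading of a design correcting over "six
  frequency bands and two groups". Family composition is a function
  argument, not hard-coded.
- **Group averaging order:** epochs averaged within subject, then an
  unweighted mean across subjects, so each subject contributes equally
  to a reference regardless of epoch count.
- **References per timepoint:** baseline and follow-up references are
  built independently from that timepoint's data; reusing baseline
  references at follow-up is possible by passing the baseline trees
  explicitly.

## Problem sizes

Default synthetic conditions mirror the study design: 9/16/16 subjects,
two timepoints, 8 epochs × 16,384 samples at 1,250 Hz, 90 regions,
downsample factor 4. The full spectrum-recovery and type-I-error suites
run in matrix mode at these sizes (41 subjects; 20 and 50 cohort
replicates respectively). Time-series-mode properties are validated on
8–15-region cohorts, where ~100 region pairs already determine the
envelope-coupling statistics; the spectral stack is linear per region
and pair, so nothing about larger matrices changes except runtime.

## Known limitations

- The similarity scale of synthetic cohorts is far above the real-data
  regime (sparse 90-node trees overlap little by chance; the planted
  backbones dominate), so absolute score levels are not comparable to
  published values — only their ordering and statistics are.
- Tree-metric normalizations are a convention; values should not be
  compared numerically against publications that do not state theirs.
- The orthogonalization is the pairwise time-domain variant; a
  frequency-resolved variant would give different absolute AECc values.
- The Wilcoxon normal approximation is used for n > 15 regardless of tie
  structure; heavy ties at small n deserve the exact method (default).
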