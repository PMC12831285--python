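# Methods

This note documents the models, conventions and numerical choices behind
`foldguide`, what the synthetic generators do and do not emulate, and the
design decisions taken where the design was genuinely open.

## The feature container

The predictor input is a single container of query features (integer-encoded
sequence, 0-based residue index, between-segment flags), an MSA block whose
row 0 is always the gapless query, and a template stack in the fixed
37-slot heavy-atom layout.  The residue alphabet is the canonical
20-amino-acid order with X = 20; gap and mask share index 21, because
masking is performed by substitution with the gap symbol rather than a
separate channel.  Internally everything is 0-based; all user-facing
coordinates (regions, variants, reports) are 1-based chain/author
numbering.

The native on-disk format is a NumPy `.npz` archive of the integer/real
arrays plus a JSON sidecar holding strings, row labels, the assembly plan
and the append-only provenance log.  This round-trips bit-exactly for
integers and exactly for reals, independent of any single serializer.  The
stock AlphaFold2 v2.2 pickle layout (`aatype`, `residue_index`, `msa`,
`deletion_matrix_int`, `template_*`) is supported as an import/export
dialect: one-hot `aatype` decodes by argmax; MSA and template residue
numbering follow the HHblits (alphabetical) convention and are remapped.
Templates injected by hand carry `sum_prob = 1.0` unless a search score is
supplied; the weight is a documented user override.

## Multi-chain assembly

Oligomeric targets are concatenated into one query.  The default linker
policy is a residue-index gap of 200 between consecutive segments (the
established device for multimer-as-monomer prediction: the index jump tells
the predictor the segments are not covalently continuous without polluting
the sequence).  Physical linkers (default `GGGGS`) are offered as an option
and flagged in `between_segment_flags`; on disengagement they are dropped.
Chain copies expand in plan order and receive sequential output chain IDs;
each chain's author numbering restarts at its `start_offset` (e.g. 32 for a
construct whose first modeled residue is residue 32).

## MSA operations

A3M semantics are the internal convention: uppercase and `-` are match
columns, lowercase letters are insertions accumulated into the deletion
count at the next match column.  Column-aligned formats (aligned FASTA,
Stockholm) are converted by treating reference-gap columns as insertions.
Depth reduction keeps the query plus the top `n−1` rows in stored order
(assumed search ranking) or a greedy maximum–minimum-Hamming subset, seeded.
Masking sets the selected columns to gap in non-query rows only and zeroes
their deletion counts (a gap cannot carry insertions); the query row is
never altered, preserving the row-0 invariant.  Merging places harvested
blocks at their target regions, gap-pads outside, and deduplicates exact
integer rows keeping the first.  These choices favour predictability over
cleverness: no similarity clustering, no re-weighting.

## Templates

Automatic template-to-query mapping is a global alignment (BLOSUM62, gap
open −11 / extend −1) rejected below 20% identity: distant templates are
genuinely useful for state guidance but must be supplied deliberately via
an explicit residue mapping (e.g. read off a superposition onto a prior
prediction).  Relabeling rewrites only covered positions — coverage (the
set of positions with label ≠ 21) is invariant under relabel and C&beta;
truncation.  Multi-source templates keep each source's coordinate frame;
no re-superposition is applied across sources, because a source that
already contains an interface should contribute it verbatim, and relative
placement of independent sources is the user's explicit responsibility.

Template clustering (the "naive" mode's engine) compares templates over
their common covered CA positions (≥ 20 required) through the CC matrix
and embedding described below; the default is two groups — the two-state
hypothesis for transporter-like systems — with `k` user-adjustable and an
automatic mode that splits only when the largest angular gap in the
embedding exceeds 0.2 rad.

## Structural correlation and state embedding

Ensemble members are matched by (chain, author number) over CA atoms and
superposed onto an iteratively recomputed mean (first member initialises;
convergence at < 1e-6 Å mean shift or 50 iterations).  The correlation
coefficient between members is the cosine of their flattened deviation
vectors from that mean.  A member identical to the mean has no deviation
direction; it is flagged and correlated 1 with other degenerate members and
0 otherwise rather than silently assigned.

The embedding minimises `Σ_{i<j} (CC_ij − x_i·x_j)²` over vectors in the
unit ball, by penalised least squares (L-BFGS-B, quadratic penalty on
`|x|² > 1`, norms clipped afterwards) from one eigendecomposition start and
nine seeded random starts, keeping the best.  Dot products — not classical
metric MDS on distances — because the angle between vectors is the
discriminating quantity: correlated members point the same way, anticorrelated
members oppose, and noisy members shrink toward the origin.  Clustering is
complete linkage on pairwise angle, cut at the requested `k` or at the
largest merge-height gap (single cluster below 0.2 rad).  The brute-force
grid oracle in the test suite validates the optimizer, not the formula; the
CC definition itself is this package's documented dialect and is swappable
behind the `CCMatrix` contract.

## Rigid groups and hinges

Residues a, b are co-rigid when their CA distance changes by at most `tol`
(default 1.5 Å) between every pair of members (max-aggregated
difference-distance matrix).  Because the max over member pairs amplifies
the noise tail, groups are not built by a strict diameter criterion:
contiguous seed segments of ≥ 5 residues are merged agglomeratively while
the co-rigid *fraction* between groups exceeds 0.5, then boundaries are
refined to residue resolution by maximising per-residue co-rigid fractions
against the flanking group cores.  Groups may span non-adjacent segments
(lobes moving together); hinge residues are the boundaries between adjacent
groups.  `tol → ∞` collapses to a single group.  Per-group RMSD ranges are
computed after group-wise superposition onto the group mean.

## Model evaluation

* **Ramachandran**: φ/ψ from backbone dihedrals; chain breaks (numbering
  jumps or C–N > 2.5 Å) skip the flanking residues.  The allowed regions
  are coarse rectangles — general: φ∈[−180,−30] with ψ∈[−100,60] (helical)
  or ψ∈[60,180]∪[−180,−150] (sheet/PPII), plus the left-handed basin
  φ∈[20,100], ψ∈[−40,100]; proline restricted to φ∈[−110,−30]; glycine
  unrestricted.  This is a soundness heuristic, not validation-grade.
* **Compactness**: CA radius of gyration over the globular expectation
  `2.2·N^0.4` Å; ≈ 1 compact, ≫ 1 extended, 0 degenerate.
* **Interfaces**: buried area = SASA(A) + SASA(B) − SASA(AB) by
  Shrake–Rupley (probe 1.4 Å, 300 points per atom, element VdW radii).
  Hydrogen bonds are geometric: donor (nitrogens, hydroxyl oxygens) to
  acceptor (oxygens) heavy-atom distance ≤ 3.5 Å; with no hydrogens in the
  37-slot layout the donor–H–acceptor angle is not computable, so the
  distance + element rule stands alone.  Interface ΔG is never computed
  internally; an external interface-energy tool's XML can be ingested and
  is null-safe.
* **Ranking** is lexicographic: models missing a user-declared interface
  rank last regardless of confidence, then mean pLDDT (experimental models
  without confidence default to 100 so mixed ensembles rank sensibly), then
  Ramachandran outlier fraction, then |compactness − 1|, then model name as
  the deterministic tie-break.  All components are reported so users can
  re-weight; the composite order is a documented default, not a claim about
  optimal weights.

## Mosaic mode

Targets are split preferentially at chain boundaries (segments share whole
chains as anchors), falling back to overlapping intra-chain windows
(minimum overlap 30 residues).  At merge time the first segment fixes the
frame; each later segment is Kabsch-superposed on its anchor CAs onto the
growing assembly.  Overlap residues are taken from the segment with the
higher mean confidence over the overlap (earlier segment wins ties), and a
merge is refused with a diagnostic when the anchor RMSD exceeds 5 Å —
beyond domain-level flexibility, gluing disagreeing segments would be
meaningless.  Under the `best_of_previous` seed policy, later segments gain
a query-labeled template built from the anchor region of the best earlier
prediction.

## Backends and reproducibility

The predictor contract is `invoke(features, n_models, seed) → models`; a
real AlphaFold2-style backend is an external-process adapter and is never
linked in-process.  The deterministic mock backend copies the
highest-weight template's coordinates plus seeded Gaussian noise
(σ = 0.2 Å, confidence 90) at covered positions and builds uncovered
stretches as an extended chain (confidence 50).  Every run writes its
resolved configuration next to the outputs, takes all randomness from the
configured seed, avoids wall-clock timestamps in artifacts, and is
bit-reproducible from configuration + seed with the mock backend.

## Synthetic generators, and what passing tests show

Fixtures are ideal-geometry constructs: backbones built from internal
coordinates (N–CA 1.458, CA–C 1.525, C–N 1.329 Å; helix −57/−47, strand
−120/+120, extended 180/180; C&beta; at the ideal tetrahedral position),
two-block hinge proteins bent rigidly at the linker midpoint, two-state
ensembles split between bend angles θ and θ+Δ with per-coordinate Gaussian
noise, a two-helix toy dimer as an interface template, and profile-sampled
toy MSAs.  Defaults for the recovery suites — Δ = 30° (15° for the hinge
suite), σ = 0.2 Å, 6–20 members — represent a clearly two-state ensemble
with sub-Ångström thermal-scale noise.  The hydrogen-bond fixture places
backbone N···O pairs at the canonical 2.9 Å in the antiparallel ladder
pattern with exaggerated strand spacing so the count is exactly four by
construction.

These fixtures exercise the full code paths (real PDB/A3M files through the
real readers) but are geometric stand-ins: they contain no side-chain
packing, no real evolutionary signal in the MSAs, and two-state separations
far cleaner than many biological ensembles.  Passing the recovery suites
therefore demonstrates the correctness and determinism of the machinery —
not that a real predictor, guided this way, will reach a particular
accuracy on a real system; that requires a real backend, real alignments
and experimental references.

## Problem sizes

The shipped test and acceptance runs use desk-scale sizes chosen to keep
the suites quick while still exercising every stage: queries of 5–300
residues, MSAs up to 50 rows, ensembles of 6–20 members of 85 residues,
mosaic targets of 200 residues in two segments, and 20-seed recovery
sweeps.  All operations scale to realistic inputs (thousand-residue
multi-chain targets) with the same code paths.

## Known limitations

* No homology search or template retrieval: alignments and structures are
  supplied by the user or imported from harvested feature containers.
* No paired-MSA multimer features; oligomers use the
  concatenated-monomer-with-linkers route only.
* The CC/embedding dialect and the hinge algorithm are this package's
  documented constructions satisfying their stated roles; published tools
  in this space may differ in detail.
* Ramachandran regions are coarse by design; do not use the outlier
  fraction as a validation statistic.
* No energy model: interface ΔG and relaxation are external-tool hooks.
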