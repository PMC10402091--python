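# Methods

This note records the model, the defaults, the numerical choices, and what
the synthetic scenes do and do not demonstrate.

## Model and targets

The network performs semantic segmentation of protein surface atoms: each
solvent-accessible heavy atom receives a binding likelihood S_a ∈ [0, 1].
Binding-site *definition* ambiguity (atoms within some cutoff vs residues
vs meshes) is sidestepped in two ways: evaluation uses only the distance
from a predicted site center to ligand heavy atoms (DCA), which needs no
site definition, and training targets are continuous —

    t(d) = 1 / (1 + exp(s · (d − m)))

with d the distance from a surface atom to the nearest ligand heavy atom.
Midpoint m = 4.0 Å puts the 0.5 crossover at a typical protein–ligand
contact distance; steepness s = 3.0 Å⁻¹ makes targets ≈ 0 beyond 6 Å. Both
are configurable. With several ligands an atom takes its maximum target
over ligands (an atom near *any* ligand is a binding atom).

The score loss is the binary KL divergence between predicted scores and
the soft targets, i.e. cross-entropy minus the target entropy. It shares
the cross-entropy gradient but is exactly zero at a perfect fit, which
makes "loss → 0" a meaningful convergence statement for continuous targets.
The auxiliary denoising term is the mean squared error of reconstructing
the clean input features, weighted by `denoise_loss_weight` (default 0.1).

## Architecture

- Encoder: 2-layer MLP (Elu) from the 31-dimensional chemical feature
  vector to `hidden_dim`.
- Processor: `n_blocks` attention blocks. Each block runs `n_heads` (4)
  GATv2-style attention heads over the near-surface graph with self-loops;
  the attention MLP sees [x_i ‖ x_j ‖ e_ij]. Per head both the summed and
  the averaged (by in-degree) messages are kept; the 2·heads aggregates are
  concatenated, mixed by a linear layer, InstanceNorm-ed, added to the
  block input (residual) and passed through Elu. The sum/mean pair lets a
  block weigh neighbourhood density against composition per feature.
- Decoder: 2-layer MLP on the jumping-knowledge concatenation of all block
  outputs (a config switch can include the encoder output; default off, as
  the block outputs already carry a transformed copy of it through the
  residual path). A single logistic output unit produces S_a.
- Noisy Nodes: during training, Gaussian noise (σ = 0.02) is added *only*
  to the genuinely numeric input channels (formal charge, degree); one-hot
  and flag channels stay clean, since "noisy" categorical indicators would
  change the chemistry rather than perturb it. A 2-layer head on the last
  block's states reconstructs the clean features.

Self-loops need an edge feature; the paper-level formulation leaves e_ii
undefined. The inverse-distance channel uses the sentinel 1.0 (the value at
d = 1 Å), bond order and covalent flag 0 — this keeps the attention input
well-typed without colliding with any real edge (real inverse distances in
the graph are < 1 for d > 1 Å, and bonded pairs carry the covalent flag).

Defaults: hidden 64, 4 blocks, 4 heads, Adam with lr 1e-3. The toy
training runs in the tests use a smaller profile (hidden 32, 3 blocks,
lr 3e-3, 150 epochs on ~25-residue scenes) so the suite completes quickly;
these sizes are package defaults for the synthetic regime, not tuned
claims about real proteins.

The network, autodiff engine and Adam optimizer are implemented in NumPy.
Gradients of every primitive are verified against central finite
differences in the test suite.

## Geometry and numerics

- **SASA**: Shrake–Rupley sphere sampling, probe 1.4 Å, 960 golden-spiral
  points, Bondi-style vdW radii; surface iff SASA > 0.1 Å². Coordinates
  are first rotated into a deterministic principal-axes frame (axes by
  decreasing variance, signs by third moment, right-handed), which makes
  the sampled estimate — and therefore the surface classification and all
  downstream scores — exactly invariant under rigid motion of the input.
  Without canonicalization, atoms whose SASA sits within the sampling
  resolution of the cutoff could flip classification under rotation.
- **Graph**: all node pairs within 5.0 Å; buried atoms enter only within
  5.0 Å of a surface atom. Coincident atoms (< 0.01 Å) are rejected to
  guard the inverse-distance feature.
- **Bonds**: mol2 BOND records are honored (ar → order 1.5); PDB input gets
  order-1 bonds inferred from element-pair covalent radii × 1.3.
- **Clustering**: SciPy average linkage, dendrogram cut at 7.0 Å (order of
  a pocket diameter; configurable). Clusters with < 3 atoms are dropped —
  their hulls are degenerate and isolated high-scoring atoms are noise.
  The threshold comparison is strict (S_a > 0.3).
- **Site center**: volume centroid of the convex hull (tetrahedral fan
  from the vertex mean); fewer than 4 points, or coplanar/collinear sets,
  fall back to the arithmetic mean.
- **Ranking ties**: descending S_S, then larger member count, then lowest
  member atom index — fully deterministic.
- **Metrics**: DCA success is strict (< threshold). Recall matches sites to
  ligands one-to-one, greedily by site rank and then nearest ligand;
  precision counts a site as correct if it succeeds against any ligand,
  with no exclusivity, so the two metrics stay independent. Pooling is
  micro (summed counts over systems). A system with more considered sites
  than ligands can therefore score high recall and low precision at once.

## Dataset-preparation rules

- Ligand filters: name lists for water, common ions/salts and glycans
  (editable on the policy object), plus a geometric criterion of at least
  one ligand heavy atom within 4.0 Å of a protein heavy atom.
- Label augmentation: within an entry group sharing a PDB id, an unlabeled
  ligand whose element-composition multiset equals a labeled ligand's is
  promoted when buried (mean per-atom protein-contact count ≥ 5 within
  4.5 Å by default). The operation is monotone and idempotent.
- Chain splitting: a ligand is interfacial when it has heavy atoms within
  4.0 Å of more than one chain; connected components of the chain–ligand
  contact graph become subsystems, each ligand traveling with exactly one.

## Synthetic scenes

`fixtures.make_pocket_scene` builds a jittered dense atom lattice (2.2 Å
spacing) trimmed to a ball, groups consecutive atoms into 4-atom residues
with real amino-acid names, carves a spherical invagination near the
surface and balances a ring ligand inside it at a 2.4–3.6 Å closest
contact. The ground-truth pocket is the set of surface atoms strictly
within the sigmoid midpoint (4.0 Å) of the ligand, so "ground truth" and
"target > 0.5" coincide exactly. Pocket-lining residues are drawn from an
aromatic/polar subset with probability 0.8 — a deliberately learnable,
chemically plausible signal, since the featurization is coordinate-free.
Multimer arrangements place flipped copies with a controlled inter-chain
gap (14 Å, or 7 Å with a bridging interfacial ligand).

What passing tests show: the implementation honors its exact invariances
(rigid motion, permutation, attention normalization), its reductions
(frozen attention = distance-weighted reference featurizer), its
clustering and metric definitions (verified against brute-force oracles
and hand-enumerated scenarios), and that the full train→predict→evaluate
loop can recover planted pockets. What they do not show: generalization
to real protein conformations, realistic secondary structure, or
transferable learned chemistry — the scenes have no Ramachandran
geometry, no sequence context and an artificially clean pocket signal.

## Known limitations

- No hydrogen placement or protonation states; metals and cofactors are
  parsed as ligands and (by default) removed by the name filter rather
  than kept as protein context.
- The feature schema is the category-level set (element, charge, degree,
  aromaticity, residue, backbone); it is versioned so columns can be added
  without silently invalidating checkpoints.
- Average-linkage clustering is not end-to-end differentiable; clustering
  quality caps instance-segmentation performance by construction.
- Training is single-threaded full-batch-per-graph Adam; it is sized for
  desk-scale synthetic data, not database-scale corpora.
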