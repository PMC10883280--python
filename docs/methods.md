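# Methods

This note records the models, conventions and numerical choices behind
fragscore, in the order the pipeline runs.

## Structure and score input

Predicted complexes are consumed as PDB files in which the prediction engine
stores each residue's pLDDT (0–100) in the B-factor column of all of its
atoms. Parsing drops hydrogens and HETATM records, keeps the
highest-occupancy alternate-location conformer (ties: first in file order),
and preserves chain and residue order exactly as in the file — residue
identity is (chain, author residue number, insertion code), never
renumbered. Within a residue the per-atom pLDDT copies are expected to be
identical; if they are not, the mean is used and a warning logged. A
predicted model with B-factors outside [0, 100] is rejected. Native
references may also be mmCIF; mmCIF writing is not supported, and
nucleic-acid chains are skipped with a warning.

Score bundles are JSON ({iptm, ptm, model_confidence?, rank?, pae?,
pae_residues?}); pickled score files are deliberately unsupported. Missing
model confidence is recomputed as 0.8·ipTM + 0.2·pTM. A PAE matrix must be
square over the model's residues; it may be asymmetric.

## Region annotation and fragment design

Manual ordered/disordered annotations are the primary input; coiled-coil
spans are labelled ordered, and a low-pLDDT loop inside a domain may be
annotated disordered *in addition* to its membership in the ordered span.
`suggest_regions` proposes spans by thresholding a smoothed pLDDT profile,
but is only a convenience for human review: automated boundary placement
that clips residues off a folded domain can badly mislead downstream
predictions, so manual files always override suggestions.

Tiling: for each (even) window size s, a primary series steps by s from the
span start and an offset series starts at start + s/2, so consecutive
windows overlap by exactly s/2. A window that would overrun the span end is
replaced by one terminal window anchored at the end (dropped when it
duplicates an existing window) — this guarantees full coverage without
emitting sub-size fragments; the whole unfragmented span is always included,
and a region shorter than s contributes only its whole-region fragment. The
anchored-terminal rule is our choice among admissible readings of a sliding
scheme; it is what the coverage property tests pin down.

Extension schedules are cumulative pads of ±n, ±2n, ±4n, ±6n (n = minimal
motif length) for motif levels 1–4, neighbour-domain inclusion at level 5
and full length at level 6; domain levels extend through the flanking
disorder to the neighbouring domain boundary, then include the neighbour
domains, then full length. Terminal fragments extend on one side only, and
spans are clipped to [1, protein length]. A step that adds fewer than 20
residues on both termini relative to the previous step is excluded as
minimal.

## Interface metrics

All distance cutoffs are applied with strict inequality (5 Å interface,
8 Å pDockQ Cβ contacts, 3.5 Å iPAE contacts). Interface pLDDT aggregates are
plain arithmetic means over the relevant residue sets; an empty interface
makes them undefined (None), never zero, and an undefined metric makes a
model not-confident with a warning. pDockQ uses the sigmoid constants
L = 0.724, k = 0.052, x0 = 152.611, b = 0.018 frozen as named defaults from
the reference implementation, with x defined as 0 when there are no
contacts. iPAE contacts use the minimal heavy-atom residue distance, and the
median pools both PAE directions (i, j) and (j, i); whether the original
formulation uses Cα distances or a one-directional median is unresolved, so
these two choices are explicit here and covered by tests. Confidence calls:
disordered–ordered models require motif-chain interface pLDDT ≥ 70
(inclusive); ordered–ordered models require average interface pLDDT ≥ 70
(configurable to 75) and, optionally, model confidence ≥ 0.7.

## Evaluation against native structures

Superposition is an all-heavy-atom Kabsch fit over the mapped domain
residues, matching atoms strictly by name, with no outlier rejection and no
refinement cycles; atoms present on only one side are dropped and counted.
The motif RMSD is then computed over all shared heavy atoms of the mapped
motif residues in that frame. Category boundaries are upper-inclusive
(≤2 / ≤5 / ≤15 Å), resolving the "between" wording as half-open lower
bounds, and comparisons use an absolute tolerance of 1e-9 Å so that
displacement exactly on a boundary is classified into the lower category
rather than by floating-point noise. DockQ components follow the published
definition — fnat at 5 Å heavy-atom contacts, iRMS over backbone atoms of
10 Å-interface residues, LRMS of the ligand (motif) backbone after
receptor (domain) superposition, combined with the 1.5 / 8.5 Å scales — with
classes incorrect (<0.23), acceptable, medium, and high (≥0.80, inclusive).
Mean pairwise DockQ over the top ≤5 models uses the higher-ranked model of
each pair as the reference.

## Reference sets

Key motif positions are the non-wildcard elements of the class regular
expression, located by re-matching the sequence with every regex element
wrapped in a group; character classes, literals and alternation groups are
"defined", only the bare `.` is not. Miyata mutagenesis replaces each
selected key residue by the amino acid at maximal Miyata distance
(deterministic alphabetical tie-break). The 20×20 table is shipped as
static data; it is reproduced by taking Euclidean distance over polarity
and volume differences, each normalized by the standard deviation of the
190 pairwise differences, and the tests rebuild it from that formula as an
independent oracle. Which key residues to mutate when several exist is a
free choice; the default mutates the first k left-to-right, with an
all-k-subsets policy available. Shuffled pairings permute domain
assignments by seeded rejection sampling until no motif is paired with a
domain whose type intersects its class's cognate set — this also forbids
cross-class pairings that share a domain type. Sequence identity is the
optimal gap-free global alignment score (equivalently the longest common
subsequence) divided by the longer sequence length.

## Benchmark statistics

ROC/AUROC and average precision come from scikit-learn, with
lower-is-better metrics (iPAE) handled by negation; the PR curve is
step-wise, without linear interpolation. The "optimal" cutoff maximizes
Youden's J = TPR − FPR; the criterion is a package choice (the ideal-cutoff
rule is otherwise unspecified), and ties go to the more stringent
threshold. The fragmentation summary reduces per-model rows to per-PPI
flags: sensitivity counts positive PPIs with at least one confident model
whose motif RMSD is ≤5 Å; FPR counts random PPIs with at least one
confident model.

## BRET analysis

The raw BRET ratio is long-wavelength over short-wavelength luminescence
(GREEN1/BLUE1); cBRET subtracts the maximum of the two single-tag control
ratios and may be negative. Detection requires, at the configured
donor:acceptor transfection ratio (default 2:50 ng, per-pair overrides
supported), cBRET ≥ 0.05, fluorescence ≥ 500 and total luminescence
≥ 50 000, all inclusive. The acceptor/donor expression ratio is
gain_norm·(F − F_bg)/(L − L_bg); a non-positive corrected luminescence
excludes the point. Titrations are fitted with
BRET = (A/D)·BRETmax/(BRET50 + A/D) (1:1 binding) by nonlinear least
squares; standard errors are the square roots of the diagonal of the
fractional covariance matrix multiplied by the residual variance
(scipy's curve_fit applies exactly this scaling). The fit is flagged
non-converged when the optimizer fails or returns non-positive parameters,
and flagged lack-of-fit when a two-sided runs test on the sign pattern of
the residuals (ordered by A/D, n ≥ 6) rejects at α = 0.05 — the signature
of saturation behaviour that deviates from the 1:1 model. Non-saturating
titrations (max A/D ≪ BRET50) converge but report an honest, wide BRET50
standard error. Technical replicates are pooled before fitting; biological
replicates are fitted separately.

## Synthetic data

The fixture generator emulates only what the pipeline consumes: two-chain
models with shared numbering and atom names, a rigid motif displacement in
the domain frame (so the expected motif RMSD equals the displacement norm
exactly), constant or block PAE, constant per-chain pLDDT, hyperbolic
titrations with Gaussian noise, and Gaussian positive/random score sets.
Chains are rigid poly-alanine-like traces with backbone atoms N/CA/C/O plus
one pocket-facing CB per residue — enough to exercise atom-name matching,
Cβ contact logic and heavy-atom interfaces, but with no physical realism:
passing tests demonstrate the correctness of the arithmetic and the
contracts, not predictive performance on real structures. Generators are
byte-deterministic under a fixed seed, and chain layouts closer than 0.5 Å
are rejected.

Default problem sizes (12-residue domains, 5-residue motifs, ≤200-atom
brute-force oracles, 100-replicate titration simulations) are chosen so the
whole suite exercises every oracle on a single CPU in a few seconds while
keeping the Monte-Carlo checks statistically meaningful.

## Known limitations

* No sequence-alignment-based or outlier-rejecting superposition; residue
  mapping between differently numbered constructs must be supplied.
* Motif secondary-structure assignment, motif probability computation and
  coiled-coil detection are out of scope (probability is carried as an
  input field only).
* Models with more than two chains require an explicit chain pair; nucleic
  acid chains are skipped.
* The BRET expression-level scaling between instrument units and molar
  ratios is absorbed into a configurable gain factor.
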