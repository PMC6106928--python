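# Methods

## Problem and model

`nucleofit` treats side-group placement in RNA as fixed-backbone discrete
optimization, the nucleic-acid analogue of protein side-chain packing. The
sugar-phosphate backbone of the input is taken as correct and inviolable;
the conformation of each remodeled residue is chosen from a finite library
of residue geometries ("conformers", the analogue of rotamers), and the
joint choice across residues minimizes repulsive steric energy. Two scopes
are supported:

* **nucleobase mode** — fixed set P, OP1, OP2, O5′, C5′, C4′, C3′, O3′,
  O4′, C1′, C2′, O2′; only base atoms are rebuilt.
* **nucleoside mode** — fixed set P, OP1, OP2, O5′, C5′, C4′, C3′, O3′;
  the four sugar atoms O4′, C1′, C2′, O2′ are rebuilt together with the base.

Only O5′, C5′, C4′, C3′, O3′ (plus the sugar ring in nucleobase mode) are
*required*: 5′-terminal residues routinely lack the phosphate, which is kept
as fixed whenever present. Inputs need at least 3 residues; the task
sequence is case-encoded (uppercase = remodel) and must match the chain
letter by letter.

## Conformer libraries

Each conformer stores the 12 torsions (α, β, γ, δ, ε, ζ, τ₀–τ₄, χ), all
heavy-atom coordinates expressed in a canonical frame anchored on the
C5′/C4′/C3′ triad (origin at C4′, x toward C3′, C5′ in the xy-plane), and
its covalent bond lengths. Extraction accepts only residues with a complete
heavy-atom set and all 12 torsions defined — in practice interior residues
of unbroken strands; residues are considered covalently linked when the
O3′–P distance is below 2.5 Å, so concatenated multi-chain inputs do not
produce spurious inter-chain torsions.

Library construction clusters per residue type in two stages: stage 1 on
the 6-vector (α…ζ), stage 2 on χ within each group. Two algorithms are
provided:

* **neural gas** — prototypes initialized at k distinct data points;
  per-sample rank-based updates w ← w + ε·exp(−rank/λ)·Δ with Δ the wrapped
  signed angle difference, ε and λ annealed geometrically from (0.5, k/2)
  to (0.005, 0.01) over the run (default 30 epochs). The annealing
  constants are this package's choice; the originally cited formulation
  leaves them open.
* **k-medoids** — PAM-style: seeded random initialization, then the best
  improving (medoid, non-medoid) swap until a local minimum.

Distances are circular: "Euclidean" wraps each component difference into
[0, 180] before squaring (plain subtraction is meaningless at ±180°), and
MCQ is the circular mean of the per-angle differences,
atan2(mean sin dᵢ, mean cos dᵢ). Every stored prototype is the medoid of
its subcluster — a real residue with physically real coordinates and bond
lengths, not an average. Cluster counts k1/k2 are user parameters (defaults
3/2 suit the small synthetic inputs used in the tests; tens of groups per
type are appropriate for libraries built from large structure collections).

## Reconstruction geometry

Rebuilding a residue on its fixed backbone uses internal coordinates
measured on the conformer itself, so a conformer extracted from a residue
reproduces that residue exactly:

* nucleoside mode places O4′ ← (O5′, C5′, C4′), C1′ ← (C5′, C4′, O4′),
  C2′ ← (C5′, C4′, C3′) and O2′ ← (C4′, C3′, C2′) by NeRF (natural
  extension of reference frame). The five-membered ring is thus built along
  two branches; the implied C1′–C2′ bond is *checked* against the
  conformer's stored length (deviation reported as metadata, tolerance
  0.2 Å) rather than enforced, since a redundant closure constraint cannot
  be satisfied exactly by torsion-driven placement.
* the base attaches by placing the glycosidic nitrogen from the
  (C4′, O4′, C1′) frame, then the χ-defining reference atom (C4 for
  purines, C2 for pyrimidines) with the conformer's χ as the driving
  torsion; the remaining base atoms ride rigidly on the (C1′, N, C-ref)
  triad, which preserves ring planarity exactly and makes χ the single
  orientation parameter.

Fixed atoms are never copied through arithmetic — the output holds the
input's float values bit for bit.

## Steric energies and the optimizer

Energies use a 12-6 Lennard-Jones form with σ = rᵢ + rⱼ (heavy-atom van der
Waals radii C 1.70, N 1.55, O 1.52, P 1.80 Å): zero exactly at contact,
minimum −ε (ε = 1 energy unit) at 2^{1/6}σ, capped at 100 per atom pair to
tame the r⁻¹² pole, and cut off at 8 Å. Units are arbitrary; only ordering
and sign matter. Atom pairs within three covalent bonds (same residue or
across the O3′–P linkage) are excluded: 1-4 separations across the
glycosidic bond (e.g. O4′–C8 ≈ 2.78 Å in every anti purine) are dictated by
bond geometry, not packing, and counting them would assign every clean
structure a constant spurious penalty. The same ≤3-bond rule governs the
clash detector, matching contact-dot practice.

The assignment search is exact over the pruned space: Goldstein DEE to a
fixed point, committal of single-candidate residues (their pair energies
fold into the neighbours' self energies), an interaction graph with an edge
wherever some surviving candidate pair has *positive* energy, connected
components, biconnected (block-cut tree) decomposition, and depth-first
branch-and-bound per block with admissible per-node and per-pair lower
bounds. Leaf blocks are solved conditionally on each candidate of their
articulation point and collapsed; ties break toward lexicographically
smallest candidate indices everywhere, making runs bit-reproducible.

One property deserves emphasis: with signed pair energies the
positive-edge decomposition is an approximation — after DEE an edge can
lose its positive entries, leaving an attractive interaction invisible to
the decomposed search. This is inherent to the published decomposition
rule, which reads E_pair as steric overlap. The abstract packing instances
used by the oracle tests therefore draw pair energies from {0} ∪ (0, 40]
(self energies still mix signs), a regime in which the decomposition is
provably lossless and the solver must match brute-force enumeration to
1e-9; the geometric pipeline keeps the full signed potential within
components.

## Synthetic structures

The generator builds full-atom chains by torsion-driven NeRF placement from
an idealized nucleotide template: a C3′-endo ribose (pseudorotation phase
18°, amplitude 38°) fitted by least squares to standard bond lengths and
angles, planar base z-matrices measured from idealized residue geometry,
and D-ribose branch handedness (the generated helix is right-handed, twist
≈ 33°, rise ≈ 2.8 Å). The default preset is A-form-like
(α −74.4, β 179.0, γ 62.0, δ 75.2, ε −147.9, ζ −70.6, χ −156.0); its
backbone values were refined jointly, once, with the Watson-Crick pair
template (C1′–C1′ span 10.74 Å, λ angles ≈ 50–58°, propeller −6.3°) so that
a duplex built from two such strands closes all canonical hydrogen bonds to
within ≈ 0.1 Å of their standard lengths with zero steric clashes. Duplexes
place the reverse-complement strand by a single rigid superposition onto
per-pair target frames derived from the pair template.

What the fixtures emulate: correct covalent geometry, helical regularity,
canonical pairing, and injectable χ-rotation clashes. What they do not:
experimental coordinate noise, modified residues, backbone irregularity
(bulges, kinks, non-A-form suites), crystal contacts, or non-canonical
pairs. Passing the self-recovery and clash-repair tests therefore
demonstrates the machinery is correct and internally consistent — not that
remodeling accuracy on experimental structures matches any particular
published figure. Likewise the clash score counts heavy-atom overlaps
(≥ 0.4 Å past van der Waals contact, per 1000 atoms in scope) and is not
numerically comparable to hydrogen-aware MolProbity scores; only
before/after trends on the same structure are.

## Evaluation conventions

* RMSD is computed without superposition (both models share the fixed
  backbone frame). Mode-specific subsets: base heavy atoms (C2, C4, C5, C6,
  C8, N1, N2, N3, N4, N6, N7, N9, O2, O4, O6) for nucleobase comparisons,
  plus O4′, C1′, C2′, O2′, C3′, C4′ for nucleoside ones; phosphate atoms
  never enter.
* Canonical pairs (A-U, G-C, G-U wobble) are detected geometrically:
  complementary types, C1′–C1′ ∈ [8.9, 11.9] Å, the two class-defining
  donor–acceptor distances < 3.5 Å, base-plane angle < 30°; conflicts are
  resolved greedily by smallest mean H-bond distance. Only canonical INF is
  computable; non-canonical classification is out of scope.
* INF = √(PPV·STY); two empty pair sets score 1.0, exactly one empty scores
  0.0.

## Design choices on open points

* Step-1 candidate retention keeps every conformer within 15° MCQ of the
  best match (config-exposed); the source method states "most similar"
  without a cut.
* Nucleobase-mode matching adds τ₀–τ₄ to the compared angles — the sugar is
  fixed in that mode, so the ring torsions are genuine backbone signal.
* The Step-2 RMSD reference is the conformer rigidly superposed via its
  canonical C5′/C4′/C3′ frame: the score measures how much the conformer
  must distort to sit on this backbone.
* Energy minimization post-processing is accepted as a flag but is an
  external hook: the engine logs the request and skips it.
* Glycosidic bond geometry during rebuilding comes from the conformer
  record itself (bond length and angle measured on its stored coordinates).

## Known limitations

PDB is the only structure dialect (no mmCIF); modified residues and
backbone gaps are unsupported (inputs containing them are rejected or the
affected residues skipped during extraction); hydrogens are ignored
throughout; sugar pucker is handled through the five ring torsions, not a
pseudorotation (P, ν_max) parameterization; the built-in miniature library
covers ideal A-form-like geometry only and is meant for smoke tests, not
production remodeling.
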