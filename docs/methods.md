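# Methods

This note documents the models, numerical choices and limitations of
the package, in the spirit of a simulation code's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The dynamic-distance coordinate

The collective variable is

D = ( Σ_NOP (μ_ij/μ*) |r_i − r_j|² )^(1/2),  μ_ij = m_i m_j/(m_i+m_j),  μ* = Σ μ_ij,

over a set of non-overlapping atom pairs (no atom may appear twice —
enforced at construction, since a shared atom would make the pair
terms non-independent).  The square of the pair term is read as the
squared Euclidean norm of the pair vector, the only reading that gives
a scalar with distance units.  Masses are standard atomic weights
(H 1.008, N 14.007, O 15.999, Hg 200.592 amu …); no isotope convention
is applied.  The analytic gradient on atom i of pair (i, j) is
(μ_ij/(μ*·D))(r_i − r_j), zero for atoms outside the pair set, and
singular only at D = 0 (rejected).

Three pair-selection variants are defined on a duplex model:

* **EQUI** — every inter-base hydrogen bond of the regular pairs,
  detected geometrically: each donor H is matched to the nearest N/O
  acceptor of the partner base within 2.2 Å, where nitrogens carrying
  a hydrogen of their own (amino/imino donors) are excluded as
  acceptors.  On the default duplex this yields 30 pairs (3 per iG:C,
  2 per A:T).  Used by the zip-up protocol.
* **DNA** — one N···H bond per regular pair (A-N1···T-H3,
  (i)G-H1···C-N3) plus the two Hg-bridged spans εA-N7···T-O4 and
  εA-N6···T-O2: 14 pairs.  Used for dissociation runs.
* **ISO** — only the two bridged spans of the modified pair.  For an
  Hg-free, protonated modified pair the bridged spans fall back to the
  donor–acceptor pairs T-H3···εA-N7 and T-O2···εA-N6 (logged).

## 2. Coarse duplex geometry

Each base is a rigid planar template of named sites (ring/exocyclic
N and O, polar hydrogens, C1′, one backbone phosphate bead).  Full-atom
sugars are omitted: every analysis in the package measures named-site
distances and angles only.  Templates are laid out so that every
Watson–Crick hydrogen bond in the ideal fiber helix (rise 3.38 Å,
twist 36°, B-DNA fiber values; the generator the production work
delegates helix construction to does not print its values) has an
H···acceptor distance of exactly 1.88 Å.  Consequently the built
duplex starts at D_EQUI = 1.88 Å exactly — the zip-up ramp's starting
value — rather than approximately.

The construction protocol mirrors the way the parallel-stranded
experimental duplex is reasoned about:

1. antiparallel fiber duplex for strand 1 + reverse complement;
2. *parallelize*: every strand-2 base is rotated 180° about its
   pair-frame x axis (the strand is turned upside down in place) and
   strand-2 positions renumbered 5′→3′ along the new direction.  Both
   strands then run 5′→3′ in +z and strand 2 reads as the position-wise
   complement (CTCCCTATCTTTC for the default).  The flip presents the
   reverse Watson–Crick edge: A:T pairs re-form both bonds, G:C pairs
   are left with donor–donor/acceptor–acceptor clashes — the real
   reason parallel G:C DNA needs isoguanine;
3. *guanine → isoguanine*: the exocyclic O6 and N2H₂ coordinates are
   swapped (hydrogens ride along), restoring three good bonds per iG:C
   pair in parallel orientation.  The operation toggles G↔iG, making
   it an involution;
4. *modified-pair insertion* at pair 7: thymine loses H3 (base charge
   −1), the partner adenine becomes εA, and two Hg²⁺ are placed in the
   NO pattern — Hg1 bridging εA-N7/T-O4, Hg2 bridging εA-N6/T-O2 — at
   2.15 Å from each partner (the median coordinate-bond length of an
   intact Hg–N/O bond), offset within the base-pair plane.  The εA
   N7/N6 sites sit 0.72 Å behind the normal edge plane, giving
   N···O spans of 3.6 Å and an initial D_DNA ≈ 2.98 Å;
5. *neutralization*: each of the 26 units carries one phosphate bead
   (−1), which presumes 5′-terminal phosphates on both strands — the
   choice under which "26 backbone charges + (+3) modified pair → 23
   counter-cations" is exact integer arithmetic.  Ions of the sign
   opposite to the net charge are placed uniformly at random (seeded)
   outside a 3 Å exclusion shell.  Whether a hypothetical net-positive
   system receives anions is decided by the same sign rule.

Residue numbering is 1–13 (strand 1) and 14–26 (strand 2), both 5′→3′,
so the modified pair is T7:εA20.

## 3. Toy energy model

The electronic-structure engines of the production problem (DFT,
QM/MM) are replaced by a classical surface with the *qualitative*
structure the analysis machinery assumes:

| term | form | default | why |
|---|---|---|---|
| intra-unit network | harmonic, all site pairs | k = 2000 kJ/mol/Å² | near-rigid planar bases |
| backbone/stacking | harmonic C1′–C1′, P–P between neighbours | k = 200 | strand integrity without torsional detail |
| hydrogen bonds | Morse | De = 25 kJ/mol, a = 2.0 Å⁻¹, r0 = 1.88 Å | finite well so dissociation is representable |
| Hg–N/O bonds | Morse | De = 40 kJ/mol, a = 2.0 Å⁻¹, r0 = 2.15 Å | coordinate bonds stronger than H-bonds |
| LJ / Coulomb | 12-6; switched 6–8 Å cutoff | off for the duplex fixture | small non-periodic boxes, no Ewald |
| counter ions | spectators, weak positional restraint k = 10 | — | keep the box tidy; no physical claim |

Units are fixed repo-wide: Å, fs, amu, kJ/mol, K; k_B =
0.0083144621 kJ/mol/K; 1 amu·Å²/fs² ≡ 1.0e4 kJ/mol.

**Weak-spot design.** The mass-weighted constraint distributes its
force across pairs in proportion to μ_ij·d_ij, so the heavy N···O
spans of the modified pair receive ≈15× the force of any N···H pair;
with the defaults above, the Hg bonds' maximum restoring force
(De·a/2 = 40 kJ/mol/Å) is reached at ≈10× lower constraint amplitude
than the hydrogen bonds'.  The modified pair is therefore the
mechanically weakest link *by construction* — this reproduces the
qualitative behaviour of the full quantum treatment and is what the
weak-spot acceptance test verifies on this model.  A green test
establishes that the machinery detects the property, not that real
mercurated DNA has it.

**Bistable Hg fixture.** A mobile Hg1 is anchored to εA-N7 (Morse,
De = 60) and offered two competing acceptors, T-O4 ("NO" well) and
T-N3 ("NN" well), 3 Å apart.  Two deliberate choices keep the fixture
analytically transparent:

* per-acceptor Morse widths are scaled so that 2a²De is equal in both
  wells.  Minimum depths then differ by De_NO − De_NN (to within the
  ≈0.4 kJ/mol cross-well Morse tails) while basin curvatures are
  equal, so the equilibrium NO/NN occupancy ratio is the bare
  Boltzmann factor exp(−ΔDe/k_BT) without a vibrational-entropy
  correction;
* a harmonic out-of-plane restraint (k = 100 kJ/mol/Å²) on the Hg ions
  emulates the steric confinement by stacked neighbour pairs.  Without
  it a point at 2.15 Å from *all three* acceptors exists out of plane
  and would be the global minimum, destroying bistability.

A second, statically coordinated Hg2 (bridging T-O2/εA-N6) is present
so that frame classification produces well-formed NO/NN labels.

**What the generator does not emulate:** explicit solvent and its
dielectric screening, proton-transfer chemistry, charge transfer to
Hg, base-sequence-specific stacking, sugar puckers, and any
quantitative energetics.  Free energies computed on the toy duplex are
properties of the toy surface; the production-scale ΔA values
(100–200 kJ/mol) are *not* reproduced and are not targets.

## 4. Constrained integrator

RATTLE-style velocity Verlet (dt default 0.5 fs).  The single scalar
constraint makes the SHAKE system 1×1; the position-level multiplier
solves g(λ) = D(q′ + λ·(dt²/2)M⁻¹∇D(q₀)) − D_target by damped Newton
iteration with analytic dg/dλ (tol 1e-8 Å, max 50 iterations,
step-halving safeguard; non-convergence raises with the residual and
iteration count).  A velocity projection removes the component of v
along M⁻¹∇D after the second half-kick (|dD/dt| ≤ 1e-10 Å/fs).

**Sign convention.** The reported multiplier F is the amplitude with
which the constraint pushes the atoms: force = +F·∇D.  With this
convention ⟨F⟩ = dA/dD — verified exactly on the dimer, where
⟨F⟩ = U′(r) − 2k_BT/r includes the centrifugal term — and integrating
from small to large D yields a positive dissociation free energy for a
bound system.  No mass-metric (Fixman) correction is applied to ⟨F⟩;
the dimer oracle (§5) quantifies the entropic content of the raw
multiplier so the convention is transparent rather than guessed.

Thermostats:

* **Nosé–Hoover chain**, length 3, time constant 1 ps (the settings of
  the production NVT protocol this package emulates), integrated with
  a 7-point Suzuki–Yoshida decomposition.  The chain couples through a
  global velocity scale, which preserves the RATTLE condition exactly.
  Chains are poorly ergodic on few-degree-of-freedom systems (a
  constrained dimer is a 2-dof rotor), so
* **Langevin** (friction default 0.002 fs⁻¹) is the default for small
  fixtures and TI sampling; the O-step is followed by re-projection of
  the constrained velocity component.

NVE + constraint conserves energy (measured drift on the rotating
constrained dimer ≲ 1e-4 kJ/mol/ps at dt = 0.5 fs); the NHC conserved
quantity is tracked and drifts ≲ 1e-3 kJ/mol/ps.  Degrees of freedom
for the kinetic temperature: 3N_active − 1 (constraint) − 3 (COM,
except under Langevin).  NPT barostatting of explicit water is out of
toy scope; all runs are NVT/NVE on non-periodic systems.

**Protocols.** *Zip-up*: the constraint target ramps linearly from
1.88 Å to 1.56 Å over 10,000 steps (the contraction that imposes the
hydrogen-bond pattern on the high-energy initial model without letting
the strands separate); the initial configuration must lie within
0.5 Å of the ramp start.  *Annealing*: the thermostat target is
multiplied by 0.99 every 100 steps (the rescale interval is this
package's choice; only the factor is prescribed by the emulated
protocol), reaching T0·0.99^(steps/100).  *TI windows*: instantaneous
target jump, ≥1 ps sampling per window, first 20% discarded (the
emulated protocol states only "at least 1 ps" and no discard), means
and standard errors from 5 contiguous blocks, trapezoidal integration
(mixed 0.1/0.5 Å window spacings make higher-order rules awkward).
Profiles are reported relative to each run's first window, whose
absolute reference is arbitrary.

## 5. The dimer oracle

For two particles bonded by U(r) = ½k(r−r0)² with the separation held
by a holonomic constraint, the configurational density at fixed r is
proportional to r² e^{−U/k_BT} (the relative coordinate lives on a
sphere of radius r), so

A(r) = U(r) − 2 k_B T ln r + const.

Its derivative U′(r) − 2k_BT/r is exactly what the time-averaged raw
multiplier measures (the −2k_BT/r term is the average centrifugal
force ⟨μ v_⊥²⟩/r of the two transverse degrees of freedom).  The
acceptance suite requires TI to reproduce this closed form within 2%
over a 1 Å range at 300 K and forward/reverse integrations to agree
within combined 3σ.

## 6. Statistics of the bistability checks

Occupancy tests classify sampled frames (every 50 fs) with the
distance rule (cutoff 2.6 Å — between the 2.12–2.20 Å medians of
intact coordinate bonds and the 2.8 Å of a broken one; angle criteria
are implemented only as secondary evidence since no numeric angle
thresholds are prescribed), debounced with a 3-frame majority filter.
Frames bound only to the anchor (transit states) are excluded.
Standard errors come from 10 contiguous blocks of the occupancy
indicator, which absorbs the serial correlation of basin dwell times;
runs are long enough (4–8 ns, ≥ hundreds of basin transitions) for the
block estimate to be meaningful.  Equality/ratio assertions are at 3σ.

## 7. Known limitations

* The toy surface is not calibrated to any quantum-chemical data; all
  energies are synthetic.  Only *relative, qualitative* statements
  (weak-spot ordering, Boltzmann consistency, oracle agreement) are
  meaningful.
* The coarse bases are rigid planar templates: no sugar pucker,
  propeller twist, or backbone torsional physics.
* The hydrogen-bond detector is geometric; it cannot distinguish
  bifurcated bonds and takes the nearest acceptor within 2.2 Å.
* Counter ions are decorative spectators; no ionic-strength effects.
* A single scalar CV is supported — no multiple simultaneous
  constraints, path CVs, umbrella sampling or metadynamics.
* Whether reported "median distances" should span whole windows or
  final segments is ambiguous in the emulated protocol; distance
  traces therefore expose both the full-trace and tail medians.
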