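# dyndist

Constrained molecular dynamics and free-energy analysis for
metal-mediated DNA base pairs, built around the **dynamic-distance
collective variable** and exercised on a desk-scale synthetic energy
model.

## The problem

Dinuclear Hg(II)-mediated base pairs — a thymine paired with
1,N6-ethenoadenine (εA) through two bridging Hg²⁺ ions instead of
hydrogen bonds — sit inside parallel-stranded DNA duplexes whose
solution structures are unknown.  Studying their stability by
simulation needs three things: a way to *build* a chemically sensible
starting duplex, a way to *impose* a chosen hydrogen-bond pattern
without tearing the helix apart, and a way to *measure* the free
energy of pulling the structure open.  All three are provided by a
single scalar reaction coordinate, the dynamic distance

```
D = ( Σ_NOP  (μ_ij / μ*) · |r_i − r_j|² )^(1/2)
```

where the sum runs over a set of **n**on-**o**verlapping atom **p**airs
(hydrogen bonds and Hg-bridged N···O contacts), `μ_ij = m_i m_j /
(m_i + m_j)` is each pair's reduced mass and `μ* = Σ μ_ij`.  Holding D
fixed with a holonomic constraint controls the collective bonding
structure while letting individual contacts trade distance; the
time-averaged Lagrange multiplier ⟨F(D)⟩ of the constraint is the free
energy derivative, and thermodynamic integration over stepped D values
gives the dissociation free energy

```
ΔA = ∫_{Dmin}^{Dmax} ⟨F(D)⟩ dD          (blue-moon ensemble)
```

This package implements, in pure scientific Python, the full pipeline:

* **geometry** — coarse template builder for the 13-mer duplex
  5′-(iGAiGiGiGATAiGAAAiG)-3′ / 5′-d(CTCCCTATCTTTC)-3′: antiparallel
  fiber model → strand flip to parallel orientation → guanine →
  isoguanine transform → insertion of the T:εA pair with two Hg(II) in
  the NO coordination pattern → charge neutralization (23 Na⁺),
* **cv** — the dynamic distance, its analytic gradient, and the EQUI /
  DNA / ISO pair-selection variants,
* **md** — RATTLE velocity-Verlet with the scalar constraint solved by
  damped Newton iteration (|D − target| ≤ 1e-8 Å every step),
  Nosé–Hoover chains (length 3, τ = 1 ps), a Langevin option,
  simulated annealing (factor 0.99), and the "zip-up" protocol that
  contracts D_EQUI from 1.88 Å to 1.56 Å over 10,000 steps,
* **free_energy** — per-window mean constraint forces with
  equilibration discard and block-averaged errors, trapezoidal TI over
  piecewise schedules (`"2.5:3.5:0.1,3.5:8.5:0.5"`), and a closed-form
  constrained-dimer oracle for validation,
* **analysis** — NO/NN bonding-pattern classification and oscillation
  statistics, coordinate-bond and C1′···C1′ distance traces,
  amino-group pyramidalization (sp²/sp³), turnstile dihedral tracking,
* **toymodel** — the synthetic stand-in for the electronic-structure
  engine: Morse hydrogen bonds, bistable Hg coordination wells,
  Lennard-Jones/Coulomb terms (see `docs/methods.md` for what this toy
  world does and does not establish).

Electronic-structure energetics (DFT, QM/MM) are explicitly out of
scope; every algorithm is exact, but the energy surface is synthetic.

## Worked example

```python
from dyndist import build_default_duplex, select_constraint_pairs, make_toy_duplex
from dyndist.cv import dynamic_distance
from dyndist.md import zip_up, NoseHooverChain

duplex = build_default_duplex(seed=1)
topo, conf, smap = make_toy_duplex(duplex)
equi = select_constraint_pairs(duplex, "EQUI")
print(dynamic_distance(equi, conf.positions))   # 1.8800
zip_up(topo, conf, equi, 1.88, 1.56, steps=10000,
       thermostat=NoseHooverChain(300.0), seed=1)
print(dynamic_distance(equi, conf.positions))   # 1.5600
```

The built duplex reports `pairs: 13, Hg ions: 2, counter ions: 23, net
charge: 0`; the zip-up run contracts the 30-bond hydrogen-bond
coordinate from exactly 1.88 Å to 1.56 Å.  A thermodynamic-integration
run on the analytic two-particle dimer (k = 500 kJ/mol/Å², r0 = 1 Å,
300 K) prints

```
D = 1.0 A   <F> =    -4.87 kJ/mol/A   dA(TI) =     0.00   dA(exact) =     0.00
D = 1.2 A   <F> =    95.41 kJ/mol/A   dA(TI) =     9.05   dA(exact) =     9.09
D = 1.4 A   <F> =   197.20 kJ/mol/A   dA(TI) =    38.31   dA(exact) =    38.32
D = 1.6 A   <F> =   296.82 kJ/mol/A   dA(TI) =    87.72   dA(exact) =    87.66
D = 1.8 A   <F> =   397.76 kJ/mol/A   dA(TI) =   157.17   dA(exact) =   157.07
D = 2.0 A   <F> =   497.92 kJ/mol/A   dA(TI) =   246.74   dA(exact) =   246.54
```

i.e. the raw mean Lagrange multiplier integrates to the exact
constrained free energy `A(r) = ½k(r−r0)² − 2k_BT ln r` (note the
−2k_BT/r centrifugal term in ⟨F⟩ at r = r0: −4.87 ≈ −2·0.0083145·300).

A command-line interface mirrors the library:

```
dyndist build -o model.pdb            # construct + neutralize the duplex
dyndist cv-eval model.pdb --variant DNA
dyndist ti --schedule 3.0:5.8:0.2 --min-ps 1.0
dyndist pipeline --config run.yml     # build -> zip -> anneal -> TI -> analyze
dyndist validate                      # force-consistency + TI-oracle self-checks
```

## Acceptance script

`scripts/acceptance.py` rebuilds the duplex from scratch, selects the
EQUI hydrogen-bond pair set, runs the 10,000-step zip-up ramp from
1.88 Å at 300 K, evaluates the dynamic distance on the final frame and
writes the result as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
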