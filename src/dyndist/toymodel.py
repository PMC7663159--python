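"""Synthetic classical energy model standing in for the QM/MM engine.

The analysis machinery (dynamic-distance constraint, thermodynamic
integration, bonding-pattern classification) only assumes an energy
surface with hydrogen-bond wells, bistable Hg coordination and steric
repulsion.  This module provides exactly that, at desk scale:

* harmonic bonds for covalent/rigid-template connectivity,
* Morse wells for hydrogen bonds and Hg–N/O coordinate bonds (Morse
  rather than harmonic so that dissociation is representable),
* optional 12-6 Lennard-Jones and switched Coulomb terms,
* optional anisotropic harmonic positional restraints.

Parameters are synthetic and tunable; they are never the force-field or
DFT parameters of any production engine.  Units: Å, fs, amu, kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KE_COULOMB, mass_of
from . import geometry as geo

__all__ = [
    "Configuration",
    "ToyTopology",
    "energy_and_forces",
    "make_harmonic_dimer",
    "make_bistable_hg_pair",
    "make_toy_duplex",
    "make_random_cluster",
]

_MIN_SEP = 1e-8  # Å, below this interacting atoms count as coincident


@dataclass
class Configuration:
    """Positions (Å), velocities (Å/fs), masses (amu) and labels.

    ``frozen`` marks atoms excluded from integration (infinite-mass
    scaffolding of toy fixtures).
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    labels: list[str] = field(default_factory=list)
    frozen: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(n, 3)
        self.masses = np.asarray(self.masses, dtype=float).ravel()
        if len(self.masses) != n:
            raise ValueError("masses and positions shape mismatch")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")
        if self.frozen is None:
            self.frozen = np.zeros(n, dtype=bool)
        self.frozen = np.asarray(self.frozen, dtype=bool).ravel()
        if not self.labels:
            self.labels = [f"X{i}" for i in range(n)]

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(),
            self.velocities.copy(),
            self.masses.copy(),
            list(self.labels),
            self.frozen.copy(),
        )


@dataclass
class ToyTopology:
    """Term lists of the toy energy function.

    bonds      (i, j, k [kJ/mol/Å²], r0 [Å])          harmonic
    hbonds     (i, j, De [kJ/mol], a [1/Å], r0 [Å])    Morse
    hg_sites   (hg, acceptor, De, a, r0)               Morse (several
               acceptors per Hg allowed — competing coordination)
    lj         (i, j, eps [kJ/mol], sigma [Å])
    charges    per-atom partial charges, e; Coulomb acts on
               ``coulomb_pairs`` with a switched 8 Å cutoff
    restraints (i, (kx, ky, kz), (x0, y0, z0))         harmonic, per axis
    """

    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    hbonds: list[tuple[int, int, float, float, float]] = field(default_factory=list)
    hg_sites: list[tuple[int, int, float, float, float]] = field(default_factory=list)
    lj: list[tuple[int, int, float, float]] = field(default_factory=list)
    charges: np.ndarray | None = None
    coulomb_pairs: list[tuple[int, int]] = field(default_factory=list)
    restraints: list[tuple[int, tuple, tuple]] = field(default_factory=list)
    coulomb_r_on: float = 6.0
    coulomb_r_off: float = 8.0

    def __post_init__(self) -> None:
        for i, j, k, r0 in self.bonds:
            if k <= 0:
                raise ValueError("bond spring constants must be positive")
        for i, j, de, a, r0 in list(self.hbonds) + list(self.hg_sites):
            if de <= 0 or a <= 0:
                raise ValueError("Morse depth and width must be positive")
        for i, j, eps, sig in self.lj:
            if eps <= 0 or sig <= 0:
                raise ValueError("LJ parameters must be positive")
        self._compiled: dict | None = None

    # ------------------------------------------------------------------
    def _compile(self) -> dict:
        if self._compiled is None:
            morse = list(self.hbonds) + list(self.hg_sites)
            c = {
                "bond_ij": np.array([(b[0], b[1]) for b in self.bonds], int).reshape(-1, 2),
                "bond_k": np.array([b[2] for b in self.bonds], float),
                "bond_r0": np.array([b[3] for b in self.bonds], float),
                "mo_ij": np.array([(m[0], m[1]) for m in morse], int).reshape(-1, 2),
                "mo_de": np.array([m[2] for m in morse], float),
                "mo_a": np.array([m[3] for m in morse], float),
                "mo_r0": np.array([m[4] for m in morse], float),
                "lj_ij": np.array([(t[0], t[1]) for t in self.lj], int).reshape(-1, 2),
                "lj_eps": np.array([t[2] for t in self.lj], float),
                "lj_sig": np.array([t[3] for t in self.lj], float),
                "q_ij": np.array(self.coulomb_pairs, int).reshape(-1, 2),
                "re_i": np.array([r[0] for r in self.restraints], int),
                "re_k": np.array([r[1] for r in self.restraints], float).reshape(-1, 3),
                "re_x0": np.array([r[2] for r in self.restraints], float).reshape(-1, 3),
            }
            self._compiled = c
        return self._compiled

    def to_dict(self) -> dict:
        """Serializable description (documented, versioned schema)."""
        return {
            "format": "dyndist-topology",
            "version": 1,
            "bonds": [list(map(float, b)) for b in self.bonds],
            "hbonds": [list(map(float, b)) for b in self.hbonds],
            "hg_sites": [list(map(float, b)) for b in self.hg_sites],
            "lj": [list(map(float, b)) for b in self.lj],
            "charges": None if self.charges is None else list(map(float, self.charges)),
            "coulomb_pairs": [list(map(int, p)) for p in self.coulomb_pairs],
            "restraints": [
                [int(i), list(map(float, k)), list(map(float, x0))]
                for i, k, x0 in self.restraints
            ],
            "coulomb_r_on": self.coulomb_r_on,
            "coulomb_r_off": self.coulomb_r_off,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToyTopology":
        if d.get("format") != "dyndist-topology":
            raise ValueError("not a dyndist topology document")
        if d.get("version") != 1:
            raise ValueError(f"unsupported topology version {d.get('version')!r}")
        return cls(
            bonds=[(int(a), int(b), k, r0) for a, b, k, r0 in d.get("bonds", [])],
            hbonds=[
                (int(a), int(b), de, w, r0)
                for a, b, de, w, r0 in d.get("hbonds", [])
            ],
            hg_sites=[
                (int(a), int(b), de, w, r0)
                for a, b, de, w, r0 in d.get("hg_sites", [])
            ],
            lj=[(int(a), int(b), e, s) for a, b, e, s in d.get("lj", [])],
            charges=None
            if d.get("charges") is None
            else np.asarray(d["charges"], float),
            coulomb_pairs=[tuple(p) for p in d.get("coulomb_pairs", [])],
            restraints=[
                (int(i), tuple(k), tuple(x0)) for i, k, x0 in d.get("restraints", [])
            ],
            coulomb_r_on=d.get("coulomb_r_on", 6.0),
            coulomb_r_off=d.get("coulomb_r_off", 8.0),
        )


# ----------------------------------------------------------------------

def energy_and_forces(
    topo: ToyTopology, conf: Configuration | np.ndarray
) -> tuple[float, np.ndarray]:
    """Total potential energy (kJ/mol) and forces −∇E (kJ/mol/Å)."""
    pos = conf.positions if isinstance(conf, Configuration) else np.asarray(conf, float)
    c = topo._compile()
    energy = 0.0
    forces = np.zeros_like(pos)

    def _pairs(ij):
        d = pos[ij[:, 0]] - pos[ij[:, 1]]
        r = np.linalg.norm(d, axis=1)
        if len(r) and np.min(r) < _MIN_SEP:
            k = int(np.argmin(r))
            raise ValueError(
                f"coincident interacting atoms {ij[k, 0]} and {ij[k, 1]}"
            )
        return d, r

    def _accumulate(ij, dvdr, d, r):
        # dV/dr per pair -> cartesian forces
        f = -(dvdr / r)[:, None] * d
        np.add.at(forces, ij[:, 0], f)
        np.add.at(forces, ij[:, 1], -f)

    if len(c["bond_ij"]):
        d, r = _pairs(c["bond_ij"])
        dr = r - c["bond_r0"]
        energy += float(np.sum(0.5 * c["bond_k"] * dr**2))
        _accumulate(c["bond_ij"], c["bond_k"] * dr, d, r)

    if len(c["mo_ij"]):
        d, r = _pairs(c["mo_ij"])
        ex = np.exp(-c["mo_a"] * (r - c["mo_r0"]))
        energy += float(np.sum(c["mo_de"] * ((1.0 - ex) ** 2 - 1.0)))
        dvdr = 2.0 * c["mo_de"] * c["mo_a"] * (1.0 - ex) * ex
        _accumulate(c["mo_ij"], dvdr, d, r)

    if len(c["lj_ij"]):
        d, r = _pairs(c["lj_ij"])
        sr6 = (c["lj_sig"] / r) ** 6
        energy += float(np.sum(4.0 * c["lj_eps"] * (sr6**2 - sr6)))
        dvdr = 4.0 * c["lj_eps"] * (-12.0 * sr6**2 + 6.0 * sr6) / r
        _accumulate(c["lj_ij"], dvdr, d, r)

    if len(c["q_ij"]) and topo.charges is not None:
        q = np.asarray(topo.charges, float)
        ij = c["q_ij"]
        d, r = _pairs(ij)
        r_on, r_off = topo.coulomb_r_on, topo.coulomb_r_off
        qq = KE_COULOMB * q[ij[:, 0]] * q[ij[:, 1]]
        v = qq / r
        dvdr = -qq / r**2
        # CHARMM-style switching of the potential between r_on and r_off
        sw = np.ones_like(r)
        dsw = np.zeros_like(r)
        mid = (r > r_on) & (r < r_off)
        denom = (r_off**2 - r_on**2) ** 3
        rm = r[mid]
        sw[mid] = (r_off**2 - rm**2) ** 2 * (r_off**2 + 2 * rm**2 - 3 * r_on**2) / denom
        dsw[mid] = 12.0 * rm * (r_off**2 - rm**2) * (r_on**2 - rm**2) / denom
        sw[r >= r_off] = 0.0
        energy += float(np.sum(v * sw))
        _accumulate(ij, dvdr * sw + v * dsw, d, r)

    if len(c["re_i"]):
        dx = pos[c["re_i"]] - c["re_x0"]
        energy += float(np.sum(0.5 * c["re_k"] * dx**2))
        np.add.at(forces, c["re_i"], -c["re_k"] * dx)

    if not np.isfinite(energy) or not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite energy or forces")
    return energy, forces


# ----------------------------------------------------------------------
# packaged analytic / synthetic systems

def make_harmonic_dimer(
    k: float = 500.0,
    r0: float = 1.0,
    masses: tuple[float, float] = (14.007, 1.008),
) -> tuple[ToyTopology, Configuration]:
    """Two particles with a single harmonic bond.

    The constrained free-energy profile of this system is available in
    closed form (``free_energy.dimer_free_energy_oracle``), which makes
    it the package's primary validation fixture for thermodynamic
    integration.
    """
    if k <= 0:
        raise ValueError("spring constant must be positive")
    topo = ToyTopology(bonds=[(0, 1, k, r0)])
    conf = Configuration(
        positions=np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
        velocities=None,
        masses=np.array(masses, float),
        labels=["D1", "D2"],
    )
    return topo, conf


#: Site layout of the bistable fixture (pair plane z = 0, Å).
_BISTABLE_SITES = {
    "eA:N7": (0.0, 0.0, 0.0),
    "T:O4": (2.0, 1.5, 0.0),
    "T:N3": (2.0, -1.5, 0.0),
    "T:O2": (5.0, 0.0, 0.0),
    "eA:N6": (8.0, 0.0, 0.0),
}


def make_bistable_hg_pair(
    depth_NO: float = 8.0,
    depth_NN: float = 8.0,
    width: float = 2.5,
    anchor_depth: float = 60.0,
    plane_k: float = 100.0,
    hg_bond: float = geo.HG_BOND_LENGTH,
    start: str = "NO",
) -> tuple[ToyTopology, Configuration, dict[str, int]]:
    """Mobile Hg1 with two competing Morse acceptors (T-O4 vs T-N3).

    Hg1 is anchored to εA-N7 (depth ``anchor_depth``) and offered both
    T-O4 (depth ``depth_NO``) and T-N3 (depth ``depth_NN``), creating
    the NO and NN coordination minima of the dinuclear pair.  The base
    sites are frozen; a second, statically NO-coordinated Hg2 bridges
    T-O2/εA-N6 so frame classification yields proper NO/NN labels.

    Two numerical choices keep the fixture analytically transparent:

    * the Morse width of each competing acceptor is scaled so that
      2·a²·De is identical in both wells, equalizing basin curvatures —
      the equilibrium NO/NN occupancy ratio is then the bare Boltzmann
      factor exp(−(depth_NO−depth_NN)/kBT) of the depth difference;
    * a harmonic out-of-plane restraint (``plane_k``) on the Hg ions
      emulates the steric confinement by stacked neighbour pairs and
      removes a spurious out-of-plane geometry in which one Hg could
      coordinate all three acceptors at once.
    """
    if depth_NO <= 0 or depth_NN <= 0:
        raise ValueError("well depths must be positive")
    names = list(_BISTABLE_SITES) + ["Hg1", "Hg2"]
    site_map = {n: i for i, n in enumerate(names)}
    base = np.array([_BISTABLE_SITES[n] for n in _BISTABLE_SITES])

    hg1_no = _equidistant(base[0], base[1], hg_bond, away_from=base[2])
    hg1_nn = _equidistant(base[0], base[2], hg_bond, away_from=base[1])
    hg2 = _equidistant(base[3], base[4], hg_bond, away_from=np.array([6.5, -9.0, 0.0]))
    pos = np.vstack([base, hg1_no if start.upper() == "NO" else hg1_nn, hg2])

    masses = np.array(
        [mass_of(n.split(":")[1][0]) if ":" in n else mass_of("HG") for n in names]
    )
    frozen = np.array([True] * len(base) + [False, False])

    a_no = width
    a_nn = width * np.sqrt(depth_NO / depth_NN)
    i1, i2 = site_map["Hg1"], site_map["Hg2"]
    topo = ToyTopology(
        hg_sites=[
            (i1, site_map["eA:N7"], anchor_depth, width, hg_bond),
            (i1, site_map["T:O4"], depth_NO, a_no, hg_bond),
            (i1, site_map["T:N3"], depth_NN, a_nn, hg_bond),
            (i2, site_map["T:O2"], anchor_depth, width, hg_bond),
            (i2, site_map["eA:N6"], anchor_depth, width, hg_bond),
        ],
        restraints=[
            (i1, (0.0, 0.0, plane_k), tuple(hg1_no)),
            (i2, (0.0, 0.0, plane_k), tuple(hg2)),
        ],
    )
    conf = Configuration(pos, None, masses, names, frozen)
    return topo, conf, site_map


def _equidistant(
    p1: np.ndarray, p2: np.ndarray, bond: float, away_from: np.ndarray
) -> np.ndarray:
    """In-plane point at ``bond`` from p1 and p2, on the side away from
    ``away_from``."""
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    mid = 0.5 * (p1 + p2)
    half = 0.5 * np.linalg.norm(p2 - p1)
    if half > bond:
        raise ValueError("sites too far apart to bridge")
    h = np.sqrt(bond**2 - half**2)
    u = (p2 - p1) / (2 * half)
    perp = np.array([-u[1], u[0], 0.0])
    cand1, cand2 = mid + h * perp, mid - h * perp
    d1 = np.linalg.norm(cand1 - away_from)
    d2 = np.linalg.norm(cand2 - away_from)
    return cand1 if d1 >= d2 else cand2


def make_toy_duplex(
    duplex: geo.DuplexModel | None = None,
    hbond_depth: float = 25.0,
    hbond_width: float = 2.0,
    hg_depth: float = 40.0,
    hg_width: float = 2.0,
    bond_k: float = 2000.0,
    stack_k: float = 200.0,
    ion_restraint_k: float = 10.0,
    seed: int = 0,
) -> tuple[ToyTopology, Configuration, dict[str, int]]:
    """Toy energy model of the (default) mercurated parallel duplex.

    Each nucleotide is kept near-rigid by a harmonic network over all
    its intra-unit site pairs; consecutive units of a strand are tied by
    C1'–C1' and P–P bonds; inter-strand cohesion comes exclusively from
    Morse hydrogen bonds (detected geometrically) and the Hg–N/O Morse
    coordinate bonds.  Counter ions are spectators held by weak
    positional restraints.  The defaults put the maximum restoring
    force of an Hg coordinate bond (De·a/2 = 40 kJ/mol/Å) above that of
    a hydrogen bond (25 kJ/mol/Å) while the mass-weighted constraint
    pushes the heavy N···O pairs ≈ 15× harder than any N···H pair, so
    the modified pair is the mechanically weakest link of the duplex —
    the qualitative behaviour the full QM/MM treatment exhibits.
    """
    if duplex is None:
        duplex = geo.build_default_duplex(seed=seed)
    pos, masses, labels, smap = duplex.to_arrays()

    bonds: list[tuple[int, int, float, float]] = []
    units = sorted(duplex.units, key=lambda u: (u.strand_index, u.position))
    for u in units:
        idx = [smap[f"{u.label}:{s}"] for s in u.site_names]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                r0 = float(np.linalg.norm(pos[idx[a]] - pos[idx[b]]))
                bonds.append((idx[a], idx[b], bond_k, r0))
    for strand in (1, 2):
        su = [u for u in units if u.strand_index == strand]
        for u, v in zip(su, su[1:]):
            for site in ("C1'", "P"):
                i, j = smap[f"{u.label}:{site}"], smap[f"{v.label}:{site}"]
                r0 = float(np.linalg.norm(pos[i] - pos[j]))
                bonds.append((i, j, stack_k, r0))

    hbonds = [
        (smap[h], smap[a], hbond_depth, hbond_width, 1.88)
        for _, h, a in geo.hydrogen_bonds(duplex)
    ]

    hg_sites = []
    for name, xyz in duplex.hg_ions:
        i = smap[name]
        cand = sorted(
            (float(np.linalg.norm(pos[j] - xyz)), j)
            for label, j in smap.items()
            if ":" in label and label.split(":")[1][0] in ("N", "O")
        )
        for _, j in cand[:2]:
            hg_sites.append((i, j, hg_depth, hg_width, geo.HG_BOND_LENGTH))

    restraints = [
        (smap[l], (ion_restraint_k,) * 3, tuple(pos[smap[l]]))
        for l in labels
        if ":" not in l and not l.startswith("Hg")
    ]

    topo = ToyTopology(bonds=bonds, hbonds=hbonds, hg_sites=hg_sites,
                       restraints=restraints)
    conf = Configuration(pos, None, masses, labels)
    return topo, conf, smap


def make_random_cluster(
    n: int = 10, seed: int = 0
) -> tuple[ToyTopology, Configuration]:
    """Random bonded/nonbonded n-atom cluster for consistency checks."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 2.5, size=(n, 3)) + np.arange(n)[:, None] * [1.2, 0.0, 0.0]
    masses = rng.uniform(1.0, 20.0, size=n)
    bonds = [
        (i, i + 1, float(rng.uniform(100, 800)), float(rng.uniform(1.0, 2.0)))
        for i in range(n - 1)
    ]
    hbonds = [
        (0, n - 1, float(rng.uniform(5, 30)), 2.0, float(rng.uniform(2.0, 4.0)))
    ]
    lj = [(i, j, 0.5, 2.5) for i in range(n) for j in range(i + 3, n)]
    charges = rng.uniform(-0.3, 0.3, size=n)
    qpairs = [(i, j) for i in range(n) for j in range(i + 3, n)]
    topo = ToyTopology(bonds=bonds, hbonds=hbonds, lj=lj, charges=charges,
                       coulomb_pairs=qpairs)
    conf = Configuration(pos, None, masses)
    return topo, conf
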