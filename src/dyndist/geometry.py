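"""Coarse model builder for the Hg(II)-modified parallel-stranded duplex.

Each nucleotide is a rigid, planar template of its named donor/acceptor
sites plus the glycosidic carbon C1' and one backbone phosphate bead P;
full-atom sugars are out of scope because every downstream analysis
only measures named-site distances and angles.  Templates are laid out
so that in the idealized fiber helix every Watson–Crick hydrogen bond
has an H···acceptor distance of exactly 1.88 Å.

The construction protocol for the mercurated duplex is:

1. ``build_antiparallel_duplex`` — idealized B-DNA-like fiber helix
   (rise 3.38 Å, twist 36° by default) for a sequence and its
   complement.
2. ``parallelize`` — flip the second strand so both strands run 5'→3'
   in the same direction (reverse Watson–Crick edges now face each
   other; G:C pairing is broken by design, exactly as in real
   parallel-stranded DNA).
3. ``guanine_to_isoguanine`` — swap the exocyclic O and NH2 groups of
   every guanine, restoring three good hydrogen bonds per iG:C pair in
   the parallel orientation.
4. ``insert_modified_pair`` — replace the central A:T pair by the
   dinuclear-Hg pair: N3-deprotonated thymine opposite
   1,N6-ethenoadenine with Hg1 bridging εA-N7/T-O4 and Hg2 bridging
   εA-N6/T-O2 (the NO coordination pattern, Hg–N/O = 2.15 Å).
5. ``neutralize`` — add monovalent counter ions until the total system
   charge is zero.

Residue numbering follows the 5'→3' convention with strand 1 numbered
1–13 and strand 2 numbered 14–26 for the default 13-mer, so the
modified pair of the default duplex is T7:εA20.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import mass_of
from .cv import DynamicDistanceSpec

logger = logging.getLogger(__name__)

#: Default duplex sequence (strand 1, 5'→3'); its parallel complement is
#: CTCCCTATCTTTC, and position 7 holds the central T of the modified pair.
DEFAULT_SEQ1 = "GAGGGATAGAAAG"

#: B-DNA fiber helix defaults.
DEFAULT_RISE = 3.38
DEFAULT_TWIST = 36.0

#: Hg–N/O coordinate-bond length used for template placement, Å.
HG_BOND_LENGTH = 2.15

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# Planar site templates, (name, element, x, y), z = 0, for a base on
# strand 1 facing its partner in +x.  Strand-2 placement applies a 180°
# rotation about the pair y axis.  Hydrogen-bond donors protrude 1.0 Å
# from the heavy-atom edge plane at x = -1.44 so that H···acceptor
# distances across the pair come out at exactly 1.88 Å.
BASE_TEMPLATES: dict[str, list[tuple[str, str, float, float]]] = {
    "A": [
        ("N1", "N", -1.44, 0.0),
        ("C6", "C", -2.20, 0.35),
        ("N6", "N", -1.44, 1.0),
        ("H61", "H", -0.44, 1.0),
        ("H62", "H", -1.79, 1.93),
        ("N7", "N", -3.10, 1.50),
        ("N3", "N", -2.70, -1.30),
        ("C1'", "C", -4.60, -1.10),
        ("P", "P", -6.00, 0.40),
    ],
    "T": [
        ("N3", "N", -1.44, 0.0),
        ("H3", "H", -0.44, 0.0),
        ("O4", "O", -1.44, 1.0),
        ("O2", "O", -1.44, -1.0),
        ("C1'", "C", -4.60, -1.10),
        ("P", "P", -6.00, 0.40),
    ],
    "G": [
        ("N1", "N", -1.44, 0.0),
        ("H1", "H", -0.44, 0.0),
        ("O6", "O", -1.44, 1.0),
        ("N2", "N", -1.44, -1.0),
        ("H21", "H", -0.44, -1.0),
        ("H22", "H", -1.70, -1.93),
        ("C6", "C", -2.50, 0.60),
        ("C2", "C", -2.20, -0.35),
        ("N7", "N", -3.10, 1.50),
        ("N3", "N", -2.70, -1.30),
        ("C1'", "C", -4.60, -1.10),
        ("P", "P", -6.00, 0.40),
    ],
    "C": [
        ("N3", "N", -1.44, 0.0),
        ("N4", "N", -1.44, 1.0),
        ("H41", "H", -0.44, 1.0),
        ("H42", "H", -1.79, 1.93),
        ("O2", "O", -1.44, -1.0),
        ("C4", "C", -2.20, 0.35),
        ("C1'", "C", -4.60, -1.10),
        ("P", "P", -6.00, 0.40),
    ],
    # 1,N6-ethenoadenine: the two Hg-binding nitrogens N7/N6 sit 0.72 Å
    # behind the normal edge plane, giving N···O spans of 3.6 Å across
    # the mercurated pair (collective distance D_DNA ≈ 3.0 Å).
    "eA": [
        ("N7", "N", -2.16, -1.0),
        ("N6", "N", -2.16, 1.0),
        ("C6", "C", -2.90, 0.35),
        ("N1", "N", -3.30, -0.30),
        ("N3", "N", -3.60, 1.20),
        ("C1'", "C", -4.60, -1.10),
        ("P", "P", -6.00, 0.40),
    ],
}

#: Acceptor element symbols considered when detecting hydrogen bonds.
_ACCEPTOR_ELEMENTS = {"N", "O"}
_HBOND_CUTOFF = 2.2  # Å, H···acceptor detection threshold


@dataclass
class NucleotideUnit:
    """One coarse nucleotide: named sites + C1' + backbone P bead.

    ``base_charge`` excludes the phosphate; the single phosphate bead
    contributes −1, so ``net_charge`` of a normal unit is −1 and of the
    N3-deprotonated central thymine −2.
    """

    base_code: str
    strand_index: int
    position: int
    residue_number: int
    site_names: list[str]
    site_elements: list[str]
    coords: np.ndarray  # (n_sites, 3) Å
    base_charge: int = 0
    n_phosphates: int = 1

    @property
    def net_charge(self) -> int:
        return self.base_charge - self.n_phosphates

    @property
    def label(self) -> str:
        return f"{self.base_code}{self.residue_number}"

    def site(self, name: str) -> np.ndarray:
        try:
            return self.coords[self.site_names.index(name)]
        except ValueError:
            raise KeyError(f"unit {self.label} has no site {name!r}")

    def has_site(self, name: str) -> bool:
        return name in self.site_names

    def copy(self) -> "NucleotideUnit":
        new = copy.copy(self)
        new.site_names = list(self.site_names)
        new.site_elements = list(self.site_elements)
        new.coords = self.coords.copy()
        return new


@dataclass
class DuplexModel:
    """Ordered nucleotide units plus pairing topology, Hg sites and ions."""

    units: list[NucleotideUnit]
    pairing: list[tuple[int, int, str]]  # (strand1 pos, strand2 pos, class)
    orientation: str  # "antiparallel" | "parallel"
    rise: float
    twist: float
    hg_ions: list[tuple[str, np.ndarray]] = field(default_factory=list)
    counter_ions: list[tuple[str, np.ndarray, int]] = field(default_factory=list)

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        s1 = sorted(p[0] for p in self.pairing)
        s2 = sorted(p[1] for p in self.pairing)
        if len(set(s1)) != len(s1) or len(set(s2)) != len(s2):
            raise ValueError("pairing is not a bijection between strand positions")

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    @property
    def length(self) -> int:
        return max(u.position for u in self.units if u.strand_index == 1)

    def unit_at(self, strand: int, position: int) -> NucleotideUnit:
        for u in self.units:
            if u.strand_index == strand and u.position == position:
                return u
        raise KeyError(f"no unit at strand {strand} position {position}")

    def unit_by_residue(self, residue_number: int) -> NucleotideUnit:
        for u in self.units:
            if u.residue_number == residue_number:
                return u
        raise KeyError(f"no residue {residue_number}")

    def pair_units(
        self, pair: tuple[int, int, str]
    ) -> tuple[NucleotideUnit, NucleotideUnit]:
        return self.unit_at(1, pair[0]), self.unit_at(2, pair[1])

    @property
    def modified_pairs(self) -> list[tuple[int, int, str]]:
        return [p for p in self.pairing if p[2] == "modified"]

    @property
    def total_charge(self) -> int:
        q = sum(u.net_charge for u in self.units)
        q += 2 * len(self.hg_ions)
        q += sum(c for _, _, c in self.counter_ions)
        return q

    def copy(self) -> "DuplexModel":
        return DuplexModel(
            units=[u.copy() for u in self.units],
            pairing=list(self.pairing),
            orientation=self.orientation,
            rise=self.rise,
            twist=self.twist,
            hg_ions=[(n, x.copy()) for n, x in self.hg_ions],
            counter_ions=[(e, x.copy(), c) for e, x, c in self.counter_ions],
        )

    # ------------------------------------------------------------------
    def atom_table(self) -> list[tuple[str, str, np.ndarray]]:
        """Deterministic flat atom list: (label, element, xyz).

        Unit sites first (strand 1 then strand 2, 5'→3'), then Hg ions,
        then counter ions.  Labels read ``"T7:O4"``, ``"Hg1"``, ``"Na3"``.
        """
        rows: list[tuple[str, str, np.ndarray]] = []
        for u in sorted(self.units, key=lambda u: (u.strand_index, u.position)):
            for name, elem, xyz in zip(u.site_names, u.site_elements, u.coords):
                rows.append((f"{u.label}:{name}", elem, xyz))
        for name, xyz in self.hg_ions:
            rows.append((name, "HG", xyz))
        for k, (elem, xyz, _) in enumerate(self.counter_ions, start=1):
            rows.append((f"{elem.capitalize()}{k}", elem, xyz))
        return rows

    def with_coordinates(self, positions: np.ndarray) -> "DuplexModel":
        """Copy of the model with coordinates replaced from a flat array
        in :meth:`atom_table` order (e.g. an MD frame)."""
        positions = np.asarray(positions, dtype=float)
        out = self.copy()
        k = 0
        for u in sorted(out.units, key=lambda u: (u.strand_index, u.position)):
            n = len(u.site_names)
            u.coords = positions[k : k + n].copy()
            k += n
        out.hg_ions = [
            (name, positions[k + i].copy())
            for i, (name, _) in enumerate(out.hg_ions)
        ]
        k += len(out.hg_ions)
        out.counter_ions = [
            (e, positions[k + i].copy(), q)
            for i, (e, _, q) in enumerate(out.counter_ions)
        ]
        k += len(out.counter_ions)
        if k != len(positions):
            raise ValueError("position array does not match the atom table")
        return out

    def site_map(self) -> dict[str, int]:
        return {label: i for i, (label, _, _) in enumerate(self.atom_table())}

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, int]]:
        """(positions, masses, labels, site_map) for the whole system."""
        table = self.atom_table()
        pos = np.array([xyz for _, _, xyz in table], dtype=float)
        masses = np.array([mass_of(e) for _, e, _ in table], dtype=float)
        labels = [label for label, _, _ in table]
        return pos, masses, labels, {l: i for i, l in enumerate(labels)}


# ----------------------------------------------------------------------
# placement helpers

def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _pair_frame(slot: int, rise: float, twist: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and origin of the pair frame at 1-based ``slot``."""
    R = _rot_z((slot - 1) * twist)
    origin = np.array([0.0, 0.0, (slot - 1) * rise])
    return R, origin


_FLIP_Y = np.diag([-1.0, 1.0, -1.0])  # 180° about the pair y axis
_FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180° about the pair x axis


def _place_unit(
    base_code: str,
    strand: int,
    position: int,
    residue_number: int,
    slot: int,
    rise: float,
    twist: float,
    base_charge: int = 0,
    drop_sites: tuple[str, ...] = (),
    parallel: bool = False,
) -> NucleotideUnit:
    template = BASE_TEMPLATES[base_code if base_code != "iG" else "G"]
    names, elements, local = [], [], []
    for name, elem, x, y in template:
        if name in drop_sites:
            continue
        names.append(name)
        elements.append(elem)
        local.append([x, y, 0.0])
    local = np.asarray(local)
    if strand == 2:
        local = local @ _FLIP_Y.T
        if parallel:
            local = local @ _FLIP_X.T
    R, origin = _pair_frame(slot, rise, twist)
    coords = local @ R.T + origin
    return NucleotideUnit(
        base_code=base_code,
        strand_index=strand,
        position=position,
        residue_number=residue_number,
        site_names=names,
        site_elements=elements,
        coords=coords,
        base_charge=base_charge,
    )


# ----------------------------------------------------------------------
# operations

def build_antiparallel_duplex(
    seq1: str,
    rise: float = DEFAULT_RISE,
    twist: float = DEFAULT_TWIST,
) -> DuplexModel:
    """Idealized antiparallel fiber duplex for ``seq1`` (5'→3').

    The complementary strand is generated automatically; consecutive
    pairs are separated by ``rise`` along the helix axis (+z) and
    rotated by ``twist`` degrees.  Strand 1 occupies residues 1..L and
    strand 2 residues L+1..2L (both numbered 5'→3'), with strand-2
    position j paired to strand-1 position L+1−j.
    """
    seq1 = seq1.strip().upper()
    if not seq1:
        raise ValueError("sequence must be nonempty")
    for ch in seq1:
        if ch not in COMPLEMENT:
            raise ValueError(f"unknown base code {ch!r} in sequence")
    L = len(seq1)
    seq2 = "".join(COMPLEMENT[ch] for ch in reversed(seq1))  # strand 2, 5'→3'

    units = []
    for i, base in enumerate(seq1, start=1):
        units.append(_place_unit(base, 1, i, i, slot=i, rise=rise, twist=twist))
    for j, base in enumerate(seq2, start=1):
        slot = L + 1 - j
        units.append(
            _place_unit(base, 2, j, L + j, slot=slot, rise=rise, twist=twist)
        )
    pairing = [
        (i, L + 1 - i, _pair_class(seq1[i - 1])) for i in range(1, L + 1)
    ]
    return DuplexModel(units, pairing, "antiparallel", rise, twist)


def _pair_class(base1: str) -> str:
    return "AT" if base1 in ("A", "T") else "iGC"


def parallelize(duplex: DuplexModel) -> DuplexModel:
    """Flip strand 2 so both strands run 5'→3' in +z (parallel duplex).

    The second strand is turned upside down: every strand-2 unit is
    rotated 180° about the x axis of its pair frame, flipping the base
    over in place so its reverse Watson–Crick edge faces strand 1 and
    inverting the strand's backbone direction.  Strand-2 positions are
    then renumbered 5'→3' along the new direction, after which strand-2
    position i pairs strand-1 position i and strand 2 reads as the
    position-wise (parallel) complement of strand 1.
    """
    if duplex.orientation == "parallel":
        raise ValueError("duplex is already parallel-stranded")
    L = duplex.length
    out = duplex.copy()
    for u in out.units:
        if u.strand_index != 2:
            continue
        slot = L + 1 - u.position  # slot is unchanged by the flip
        R, origin = _pair_frame(slot, out.rise, out.twist)
        local = (u.coords - origin) @ R  # undo placement (R orthogonal)
        local = local @ _FLIP_X.T
        u.coords = local @ R.T + origin
        u.position = slot
        u.residue_number = L + slot
    out.pairing = [(i, i, cls) for i, _, cls in sorted(out.pairing)]
    out.orientation = "parallel"
    return out


def guanine_to_isoguanine(duplex: DuplexModel) -> DuplexModel:
    """Swap the exocyclic O6 and N2H2 groups of every guanine (G → iG).

    The O6 and N2 coordinates are exchanged and the amino hydrogens
    translate rigidly with N2.  Applied to an iG unit the same swap
    restores guanine, so the operation is an involution.
    """
    out = duplex.copy()
    for u in out.units:
        if u.base_code not in ("G", "iG"):
            continue
        i_o6 = u.site_names.index("O6")
        i_n2 = u.site_names.index("N2")
        delta = u.coords[i_o6] - u.coords[i_n2]
        u.coords[i_o6] -= delta
        u.coords[i_n2] += delta
        for h in ("H21", "H22"):
            if u.has_site(h):
                u.coords[u.site_names.index(h)] += delta
        u.base_code = "iG" if u.base_code == "G" else "G"
    return out


def insert_modified_pair(
    duplex: DuplexModel,
    position: int,
    hg: bool = True,
    protonated: bool = False,
    hg_distance: float = HG_BOND_LENGTH,
) -> DuplexModel:
    """Replace the A:T pair at ``position`` by the T:εA modified pair.

    The thymine keeps its slot; the adenine becomes 1,N6-ethenoadenine.
    With ``hg=True`` the thymine is N3-deprotonated (base charge −1)
    and two Hg(II) ions are placed in the NO pattern: Hg1 bridging
    εA-N7/T-O4 and Hg2 bridging εA-N6/T-O2 at ``hg_distance`` from each
    partner, offset within the base-pair plane.  ``hg=False,
    protonated=True`` yields the Hg-free analogue with neutral,
    protonated thymine.
    """
    pair = next((p for p in duplex.pairing if p[0] == position), None)
    if pair is None:
        raise ValueError(f"no pair at strand-1 position {position}")
    u1, u2 = duplex.pair_units(pair)
    bases = {u1.base_code, u2.base_code}
    if bases != {"A", "T"}:
        raise ValueError(
            f"pair at position {position} is {u1.base_code}:{u2.base_code}, "
            "not A:T — the modified pair replaces an A:T pair"
        )
    if hg and protonated:
        raise ValueError("the mercurated pair requires a deprotonated thymine")

    out = duplex.copy()
    parallel = out.orientation == "parallel"
    t_old, a_old = (u1, u2) if u1.base_code == "T" else (u2, u1)
    L = out.length

    def _slot(u: NucleotideUnit) -> int:
        if u.strand_index == 1 or parallel:
            return u.position
        return L + 1 - u.position

    deprotonate = hg and not protonated
    new_t = _place_unit(
        "T",
        t_old.strand_index,
        t_old.position,
        t_old.residue_number,
        _slot(t_old),
        out.rise,
        out.twist,
        base_charge=-1 if deprotonate else 0,
        drop_sites=("H3",) if deprotonate else (),
        parallel=parallel,
    )
    new_ea = _place_unit(
        "eA",
        a_old.strand_index,
        a_old.position,
        a_old.residue_number,
        _slot(a_old),
        out.rise,
        out.twist,
        parallel=parallel,
    )
    out.units = [
        new_t if (u.strand_index, u.position) == (t_old.strand_index, t_old.position)
        else new_ea if (u.strand_index, u.position) == (a_old.strand_index, a_old.position)
        else u
        for u in out.units
    ]
    out.pairing = [
        (p[0], p[1], "modified") if p[0] == position else p for p in out.pairing
    ]
    if hg:
        hg1 = _bridge_site(new_t.site("O4"), new_ea.site("N7"), hg_distance)
        hg2 = _bridge_site(new_t.site("O2"), new_ea.site("N6"), hg_distance)
        out.hg_ions = [("Hg1", hg1), ("Hg2", hg2)]
    else:
        out.hg_ions = []
    return out


def _bridge_site(p1: np.ndarray, p2: np.ndarray, bond: float) -> np.ndarray:
    """Point at distance ``bond`` from both p1 and p2, offset in-plane.

    The base-pair plane is horizontal (constant z); the offset is taken
    perpendicular to p1→p2 within that plane, directed away from the
    helix axis region (larger |xy|).
    """
    mid = 0.5 * (p1 + p2)
    d = np.linalg.norm(p2 - p1)
    if d / 2 > bond:
        raise ValueError(
            f"cannot bridge sites {d:.2f} Å apart with {bond:.2f} Å bonds"
        )
    h = np.sqrt(bond**2 - (d / 2) ** 2)
    u = p2 - p1
    perp = np.array([-u[1], u[0], 0.0])
    n = np.linalg.norm(perp)
    if n < 1e-9:  # pair vector along z — fall back to x
        perp = np.array([1.0, 0.0, 0.0])
        n = 1.0
    perp = perp / n
    cand1, cand2 = mid + h * perp, mid - h * perp
    return cand1 if np.linalg.norm(cand1[:2]) >= np.linalg.norm(cand2[:2]) else cand2


def remove_hg(duplex: DuplexModel) -> DuplexModel:
    """Hg-free analogue: delete the Hg ions and re-protonate the thymine.

    Mirrors the construction of the non-metalated control structure
    from the mercurated duplex.  Existing counter ions are kept, so a
    subsequent :func:`neutralize` adds only the ions needed to absorb
    the +3 charge removed with the metal centre (2×Hg²⁺ minus the
    restored proton).
    """
    if not duplex.hg_ions:
        raise ValueError("duplex carries no Hg ions")
    out = duplex.copy()
    out.hg_ions = []
    for pair in out.modified_pairs:
        u1, u2 = out.pair_units(pair)
        t = u1 if u1.base_code == "T" else u2
        if not t.has_site("H3"):
            i_n3 = t.site_names.index("N3")
            # re-insert H3 after N3, 1.0 Å toward the partner edge
            ea = u2 if t is u1 else u1
            direction = ea.site("N7") - t.coords[i_n3]
            direction[2] = 0.0
            direction /= np.linalg.norm(direction)
            h3 = t.coords[i_n3] + direction
            t.site_names.insert(i_n3 + 1, "H3")
            t.site_elements.insert(i_n3 + 1, "H")
            t.coords = np.insert(t.coords, i_n3 + 1, h3, axis=0)
            t.base_charge += 1
    return out


def neutralize(
    duplex: DuplexModel,
    seed: int = 0,
    exclusion: float = 3.0,
    margin: float = 8.0,
) -> DuplexModel:
    """Add monovalent counter ions until the total system charge is zero.

    Na+ for a net-negative system, Cl− for a net-positive one (the sign
    is inferred from the net charge).  Ions are placed uniformly at
    random (seeded) in the duplex bounding box plus ``margin``, at
    least ``exclusion`` Å from every existing atom and other ion.
    """
    out = duplex.copy()
    net = out.total_charge
    count = abs(net)
    if count == 0:
        out.counter_ions = list(out.counter_ions)
        return out
    element, charge = ("NA", 1) if net < 0 else ("CL", -1)
    rng = np.random.default_rng(seed)
    existing = np.array([xyz for _, _, xyz in out.atom_table()])
    lo = existing.min(axis=0) - margin
    hi = existing.max(axis=0) + margin
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < count:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("counter-ion placement failed (box too crowded)")
        x = rng.uniform(lo, hi)
        pts = existing if not placed else np.vstack([existing, placed])
        if np.min(np.linalg.norm(pts - x, axis=1)) >= exclusion:
            placed.append(x)
    out.counter_ions = list(out.counter_ions) + [
        (element, x, charge) for x in placed
    ]
    assert out.total_charge == 0
    return out


# ----------------------------------------------------------------------
# hydrogen-bond detection and constraint-pair selection

def hydrogen_bonds(
    duplex: DuplexModel, cutoff: float = _HBOND_CUTOFF
) -> list[tuple[str, str, str]]:
    """Detected inter-base hydrogen bonds, (pair_class, H label, acceptor label).

    For every hydrogen site of one base the nearest N/O site of its
    pairing partner is accepted if within ``cutoff`` Å.  Only regular
    (non-modified) pairs are scanned.
    """
    def _protonated_nitrogens(u: NucleotideUnit) -> set[str]:
        """N sites bearing an H within 1.15 Å (amino/imino donors, not
        acceptors)."""
        out = set()
        for n_name, n_elem, n_xyz in zip(u.site_names, u.site_elements, u.coords):
            if n_elem != "N":
                continue
            for h_name, h_elem, h_xyz in zip(
                u.site_names, u.site_elements, u.coords
            ):
                if h_elem == "H" and np.linalg.norm(h_xyz - n_xyz) < 1.15:
                    out.add(n_name)
                    break
        return out

    bonds = []
    for pair in duplex.pairing:
        if pair[2] == "modified":
            continue
        u1, u2 = duplex.pair_units(pair)
        for donor, acceptor in ((u1, u2), (u2, u1)):
            blocked = _protonated_nitrogens(acceptor)
            for name, elem, xyz in zip(
                donor.site_names, donor.site_elements, donor.coords
            ):
                if elem != "H":
                    continue
                best, best_d = None, cutoff
                for aname, aelem, axyz in zip(
                    acceptor.site_names, acceptor.site_elements, acceptor.coords
                ):
                    if aelem not in _ACCEPTOR_ELEMENTS or aname in blocked:
                        continue
                    d = float(np.linalg.norm(xyz - axyz))
                    if d <= best_d:
                        best, best_d = aname, d
                if best is not None:
                    bonds.append(
                        (pair[2], f"{donor.label}:{name}", f"{acceptor.label}:{best}")
                    )
    return bonds


def _central_hbond(duplex: DuplexModel, pair) -> tuple[str, str]:
    """The single N···H bond per regular pair entering the DNA variant:
    A-N1···T-H3 for A:T pairs, (i)G-H1···C-N3 for (i)G:C pairs."""
    u1, u2 = duplex.pair_units(pair)
    by_code = {u.base_code: u for u in (u1, u2)}
    if pair[2] == "AT":
        a, t = by_code["A"], by_code["T"]
        return f"{a.label}:N1", f"{t.label}:H3"
    g = by_code.get("G") or by_code.get("iG")
    c = by_code["C"]
    return f"{g.label}:H1", f"{c.label}:N3"


def _modified_pair_cv_sites(duplex: DuplexModel) -> list[tuple[str, str]]:
    """The two bridged distances of the modified pair entering D.

    With Hg present these are the εA-N7···T-O4 and εA-N6···T-O2
    nitrogen–oxygen spans; for the Hg-free analogue the corresponding
    donor–acceptor pairs (T-H3···εA-N7 and T-O2···εA-N6) are used and
    the fallback is logged.
    """
    mods = duplex.modified_pairs
    if not mods:
        raise ValueError("duplex has no modified pair")
    u1, u2 = duplex.pair_units(mods[0])
    t = u1 if u1.base_code == "T" else u2
    ea = u2 if u2.base_code == "eA" else u1
    if duplex.hg_ions:
        return [(f"{ea.label}:N7", f"{t.label}:O4"), (f"{ea.label}:N6", f"{t.label}:O2")]
    logger.info(
        "modified pair carries no Hg: falling back to the Hg-free "
        "donor-acceptor pair definition (T-H3/N3···eA-N7, T-O2···eA-N6)"
    )
    first = (f"{t.label}:H3", f"{ea.label}:N7") if t.has_site("H3") else (
        f"{t.label}:N3",
        f"{ea.label}:N7",
    )
    return [first, (f"{t.label}:O2", f"{ea.label}:N6")]


def select_constraint_pairs(duplex: DuplexModel, variant: str) -> DynamicDistanceSpec:
    """Build the dynamic-distance pair set for a duplex.

    variant ``"EQUI"``
        every detected inter-base hydrogen bond of the regular pairs
        (the zip-up coordinate).
    variant ``"DNA"``
        one N···H bond per regular pair (A-N1···T-H3 / G-H1···C-N3)
        plus the two Hg-bridged N···O spans of the modified pair
        (the dissociation coordinate).
    variant ``"ISO"``
        only the two bridged spans of the modified pair (isolated
        base-pair models).
    """
    variant = variant.upper()
    _, masses, _, smap = duplex.to_arrays()
    label_pairs: list[tuple[str, str]] = []
    if variant == "EQUI":
        label_pairs = [(h, a) for _, h, a in hydrogen_bonds(duplex)]
        if not label_pairs:
            raise ValueError("no hydrogen bonds detected for the EQUI variant")
    elif variant == "DNA":
        for pair in duplex.pairing:
            if pair[2] != "modified":
                label_pairs.append(_central_hbond(duplex, pair))
        if duplex.modified_pairs:
            label_pairs.extend(_modified_pair_cv_sites(duplex))
        elif not label_pairs:
            raise ValueError("empty duplex: no constraint pairs")
        else:
            logger.info("DNA variant on a duplex without modified pair: "
                        "using regular-pair N···H bonds only")
    elif variant == "ISO":
        label_pairs = _modified_pair_cv_sites(duplex)
    else:
        raise ValueError(f"unknown variant {variant!r} (expected EQUI/DNA/ISO)")

    idx_pairs = [(smap[a], smap[b]) for a, b in label_pairs]
    labels = [f"{a}--{b}" for a, b in label_pairs]
    return DynamicDistanceSpec.from_masses(idx_pairs, masses, variant, labels)


def build_default_duplex(
    seed: int = 0,
    hg: bool = True,
    modify_at: int = 7,
    neutralized: bool = True,
) -> DuplexModel:
    """The packaged default: parallel-stranded 13-mer with T7:εA20 pair.

    Runs the full construction protocol on :data:`DEFAULT_SEQ1`.  With
    ``hg=False`` the Hg-free analogue (protonated T7) is built instead.
    """
    d = build_antiparallel_duplex(DEFAULT_SEQ1)
    d = parallelize(d)
    d = guanine_to_isoguanine(d)
    d = insert_modified_pair(d, modify_at, hg=hg, protonated=not hg)
    if neutralized:
        d = neutralize(d, seed=seed)
    return d
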