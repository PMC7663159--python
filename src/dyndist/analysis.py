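"""Structural observables of the mercurated-base-pair trajectories.

All functions operate on plain coordinate frames ((N, 3) arrays) plus a
site map ``{"T7:O4": atom_index, ..., "Hg1": idx}`` naming atom roles.
Site labels are ``<base><residue>:<site>`` for nucleobase sites and bare
names for metal ions; base type is recovered by stripping the residue
number, so the classifiers work for any residue numbering.

Observables:

* **Bonding-pattern classification** — which acceptor sites each Hg(II)
  coordinates (within a distance cutoff), mapped to the NO/NN
  coordination isomers of the dinuclear pair, the inter-layer
  T–Hg–T cross-link, the A–Hg–εA pair, or DISSOCIATED.  The cutoff
  default of 2.6 Å sits between the 2.12–2.20 Å coordinate-bond medians
  of intact bonds and the 2.8 Å distance of a broken one.
* **Pair distance traces** with full and tail medians (supports the
  proton-transfer monitor N3···H vs N3···Hg and the C1'···C1'
  observable).
* **Amino-group pyramidalization** — the improper angle between the
  N–substituent bond and the plane of the other two substituents
  (0° for planar sp², ≈54.7° for tetrahedral sp³).
* **Turnstile dihedral** — signed, unwrapped rotation of an exocyclic
  amino group about its C–N single bond.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BondingPatternLabel",
    "classify_pattern",
    "pattern_timeseries",
    "PatternTimeseries",
    "pair_distance_trace",
    "DistanceTrace",
    "pyramidalization",
    "pyramidalization_series",
    "turnstile_dihedral",
    "dihedral",
]

#: Bonding-pattern labels, in classification priority order.
LABELS = ("NO", "NN", "CROSS_TT", "A_EA", "OTHER", "DISSOCIATED")

_SITE_RE = re.compile(r"^([A-Za-z]+)(\d*)$")


def _parse_label(label: str) -> tuple[str, str, str] | None:
    """'eA20:N7' -> (base='eA', residue='eA20', site='N7'); None for ions."""
    if ":" not in label:
        return None
    res, site = label.split(":", 1)
    m = _SITE_RE.match(res)
    if not m:
        return None
    return m.group(1), res, site


@dataclass
class BondingPatternLabel:
    """Classification of one frame's Hg coordination."""

    label: str
    coordination: dict[str, list[tuple[str, float]]]
    frame_index: int = 0


def _coordination(
    frame: np.ndarray, site_map: dict[str, int], cutoff: float
) -> dict[str, list[tuple[str, float]]]:
    hg_names = sorted(n for n in site_map if n.startswith("Hg"))
    if not hg_names:
        raise ValueError("site map names no Hg ions (labels starting 'Hg')")
    acceptors = [
        (lbl, idx)
        for lbl, idx in site_map.items()
        if (p := _parse_label(lbl)) is not None and p[2][0] in ("N", "O")
    ]
    out = {}
    for hg in hg_names:
        x = frame[site_map[hg]]
        found = [
            (lbl, float(np.linalg.norm(frame[idx] - x)))
            for lbl, idx in acceptors
        ]
        out[hg] = sorted(
            [(l, d) for l, d in found if d <= cutoff], key=lambda t: t[1]
        )
    return out


def _has(coord: list[tuple[str, float]], base: str, site: str) -> float | None:
    """Smallest distance at which (base, site) occurs in a coordination list."""
    best = None
    for lbl, d in coord:
        b, _, s = _parse_label(lbl)
        if b == base and s == site and (best is None or d < best):
            best = d
    return best


def classify_pattern(
    frame: np.ndarray,
    site_map: dict[str, int],
    cutoff: float = 2.6,
    frame_index: int = 0,
) -> BondingPatternLabel:
    """Classify one frame's Hg bonding pattern.

    Rules (coordination = base N/O sites within ``cutoff`` of an Hg):

    * ``DISSOCIATED`` — either Hg coordinates fewer than 2 base sites;
    * ``NO``   — Hg1 bound to εA-N7 and T-O4, Hg2 to εA-N6 and T-O2;
    * ``NN``   — Hg1 bound to εA-N7 and T-N3;
    * ``CROSS_TT`` — some Hg bridges the N3 of two different thymines;
    * ``A_EA`` — some Hg bridges A-N1 with εA-N6 or εA-N3;
    * ``OTHER`` otherwise.

    When several patterns match, the one with the smaller summed
    coordination distance wins.  Missing sites raise with their names.
    """
    frame = np.asarray(frame, dtype=float)
    coord = _coordination(frame, site_map, cutoff)
    hg_names = sorted(coord)
    if any(len(coord[hg]) < 2 for hg in hg_names):
        return BondingPatternLabel("DISSOCIATED", coord, frame_index)

    candidates: list[tuple[float, str]] = []
    hg1 = coord[hg_names[0]]
    hg2 = coord[hg_names[1]] if len(hg_names) > 1 else []

    d_n7, d_o4 = _has(hg1, "eA", "N7"), _has(hg1, "T", "O4")
    d_n6 = _has(hg2, "eA", "N6") if hg2 else None
    d_o2 = _has(hg2, "T", "O2") if hg2 else None
    if None not in (d_n7, d_o4) and (not hg2 or None not in (d_n6, d_o2)):
        total = d_n7 + d_o4 + ((d_n6 + d_o2) if hg2 else 0.0)
        candidates.append((total, "NO"))

    d_n3 = _has(hg1, "T", "N3")
    if None not in (d_n7, d_n3):
        candidates.append((d_n7 + d_n3, "NN"))

    for hg in hg_names:
        t_n3 = [
            (lbl, d) for lbl, d in coord[hg]
            if (p := _parse_label(lbl)) and p[0] == "T" and p[2] == "N3"
        ]
        if len({_parse_label(l)[1] for l, _ in t_n3}) >= 2:
            candidates.append((sum(d for _, d in t_n3[:2]), "CROSS_TT"))
        a_n1 = _has(coord[hg], "A", "N1")
        ea_other = [
            d for s in ("N6", "N3")
            if (d := _has(coord[hg], "eA", s)) is not None
        ]
        if a_n1 is not None and ea_other:
            candidates.append((a_n1 + min(ea_other), "A_EA"))

    if not candidates:
        return BondingPatternLabel("OTHER", coord, frame_index)
    candidates.sort()
    return BondingPatternLabel(candidates[0][1], coord, frame_index)


@dataclass
class PatternTimeseries:
    """Per-frame labels with debouncing, transitions and residence times."""

    raw_labels: list[str]
    labels: list[str]
    transitions: int
    residence: dict[str, list[int]] = field(default_factory=dict)

    def occupancy(self, label: str) -> float:
        return self.labels.count(label) / len(self.labels)


def pattern_timeseries(
    frames,
    site_map: dict[str, int],
    cutoff: float = 2.6,
    debounce: int = 3,
) -> PatternTimeseries:
    """Classify every frame and debounce with a centred majority filter.

    The 3-frame majority filter suppresses single-frame flickers at the
    cutoff boundary before transitions are counted.  Residence times are
    run lengths (in frames) of the filtered label sequence.
    """
    frames = _as_frames(frames)
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    raw = [
        classify_pattern(f, site_map, cutoff, i).label
        for i, f in enumerate(frames)
    ]
    filt = list(raw)
    half = debounce // 2
    if debounce > 1 and len(raw) >= debounce:
        for i in range(half, len(raw) - half):
            window = raw[i - half : i + half + 1]
            counts = {l: window.count(l) for l in set(window)}
            best = max(counts.values())
            winners = sorted(l for l, c in counts.items() if c == best)
            filt[i] = raw[i] if raw[i] in winners else winners[0]
    transitions = sum(1 for a, b in zip(filt, filt[1:]) if a != b)
    residence: dict[str, list[int]] = {}
    run_label, run_len = filt[0], 0
    for l in filt:
        if l == run_label:
            run_len += 1
        else:
            residence.setdefault(run_label, []).append(run_len)
            run_label, run_len = l, 1
    residence.setdefault(run_label, []).append(run_len)
    return PatternTimeseries(raw, filt, transitions, residence)


@dataclass
class DistanceTrace:
    """Per-frame distance between two named sites."""

    series: np.ndarray
    site_a: str
    site_b: str

    @property
    def median(self) -> float:
        return float(np.median(self.series))

    @property
    def tail_median(self) -> float:
        """Median over the trailing half of the trajectory."""
        return float(np.median(self.series[len(self.series) // 2 :]))

    @property
    def min(self) -> float:
        return float(np.min(self.series))

    @property
    def max(self) -> float:
        return float(np.max(self.series))


def pair_distance_trace(
    frames, site_map: dict[str, int], site_a: str, site_b: str
) -> DistanceTrace:
    """Distance series between two named sites, with medians and extrema."""
    frames = _as_frames(frames)
    for s in (site_a, site_b):
        if s not in site_map:
            raise KeyError(f"site {s!r} not present in the site map")
    ia, ib = site_map[site_a], site_map[site_b]
    series = np.array([float(np.linalg.norm(f[ia] - f[ib])) for f in frames])
    return DistanceTrace(series, site_a, site_b)


def pyramidalization(
    frame: np.ndarray,
    n_idx: int,
    sub1_idx: int,
    sub2_idx: int,
    sub3_idx: int,
) -> float:
    """Out-of-plane improper angle of a trivalent nitrogen, degrees.

    The angle between the N→sub3 bond and the plane through
    (sub1, N, sub2): 0° for planar sp², arcsin(1/√3) ≈ 54.7° for ideal
    tetrahedral sp³.  Raises when the plane atoms are collinear.
    """
    frame = np.asarray(frame, dtype=float)
    if len({n_idx, sub1_idx, sub2_idx, sub3_idx}) != 4:
        raise ValueError("the four sites must be distinct")
    n = frame[n_idx]
    a, b, c = frame[sub1_idx] - n, frame[sub2_idx] - n, frame[sub3_idx] - n
    normal = np.cross(a, b)
    nn = np.linalg.norm(normal)
    if nn < 1e-10 * (np.linalg.norm(a) * np.linalg.norm(b) + 1e-30):
        raise ValueError("plane atoms are collinear: improper angle undefined")
    s = np.dot(normal / nn, c / np.linalg.norm(c))
    return float(np.degrees(np.arcsin(np.clip(abs(s), 0.0, 1.0))))


def pyramidalization_series(
    frames,
    site_map: dict[str, int],
    n_site: str,
    substituents: tuple[str, str, str],
) -> np.ndarray:
    """Per-frame pyramidalization angle; degenerate frames become NaN."""
    frames = _as_frames(frames)
    idx = [site_map[n_site]] + [site_map[s] for s in substituents]
    out = np.empty(len(frames))
    for i, f in enumerate(frames):
        try:
            out[i] = pyramidalization(f, *idx)
        except ValueError:
            out[i] = np.nan
    return out


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC sign)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate dihedral geometry")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1 / nb1)
    return float(np.degrees(np.arctan2(y, x)))


@dataclass
class DihedralTrace:
    """Unwrapped dihedral series (degrees) about a rotation axis."""

    series: np.ndarray  # unwrapped, NaN for degenerate frames

    @property
    def total_rotation(self) -> float:
        valid = self.series[~np.isnan(self.series)]
        if len(valid) < 2:
            return 0.0
        return float(valid[-1] - valid[0])


def turnstile_dihedral(
    frames,
    site_map: dict[str, int],
    ring_site: str,
    axis_c: str,
    axis_n: str,
    reference_site: str,
) -> DihedralTrace:
    """Rotation of an amino group about its C–N single bond.

    Tracks the signed dihedral ring_site – axis_c – axis_n – reference
    (the reference is an amino H or a coordinated Hg), unwrapped so a
    continuous rotation through ±180° accumulates instead of jumping.
    Degenerate frames are masked NaN and skipped by the unwrapping.
    """
    frames = _as_frames(frames)
    idx = [site_map[s] for s in (ring_site, axis_c, axis_n, reference_site)]
    raw = np.empty(len(frames))
    for i, f in enumerate(frames):
        try:
            raw[i] = dihedral(*(f[j] for j in idx))
        except ValueError:
            raw[i] = np.nan
    valid = ~np.isnan(raw)
    out = raw.copy()
    if valid.sum() >= 2:
        out[valid] = np.degrees(np.unwrap(np.radians(raw[valid])))
    return DihedralTrace(out)


def _as_frames(frames) -> list[np.ndarray]:
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        return [frames]
    return [np.asarray(f, dtype=float) for f in frames]
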