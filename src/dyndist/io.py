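"""File formats: coarse-model PDB, XYZ trajectories, CSV traces, run config.

The coarse duplex is written as HETATM records (chains A/B for the two
strands, M for Hg ions, I for counter ions) with pairing topology,
helix parameters and per-unit charges carried in REMARK 300 lines, so a
written model round-trips losslessly (coordinates to the format's
1e-3 Å).  Reading uses Bio.PDB for the coordinate records plus a manual
scan of the REMARK header.  XYZ frames carry step/temperature/D/λ
metadata in their comment lines.
"""

from __future__ import annotations

import warnings

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from . import geometry as geo
from .geometry import DuplexModel, NucleotideUnit

_CHAIN_STRAND = {"A": 1, "B": 2}
_RESNAME = {"A": "A", "T": "T", "G": "G", "C": "C", "iG": "IG", "eA": "EA"}
_RESNAME_INV = {v: k for k, v in _RESNAME.items()}


# ----------------------------------------------------------------------
# PDB

def write_pdb(duplex: DuplexModel, path) -> None:
    """Write the coarse duplex model as a PDB file with REMARK metadata."""
    lines = [
        "REMARK 300 COARSE METAL-MEDIATED DUPLEX MODEL (dyndist)",
        f"REMARK 300 ORIENTATION {duplex.orientation.upper()}",
        f"REMARK 300 RISE {duplex.rise:.4f} TWIST {duplex.twist:.4f}",
    ]
    for s1, s2, cls in duplex.pairing:
        lines.append(f"REMARK 300 PAIR {s1} {s2} {cls}")
    for u in duplex.units:
        if u.base_charge != 0:
            lines.append(f"REMARK 300 CHARGE {u.label} {u.base_charge}")

    serial = 1

    def _atom(name, resname, chain, resseq, xyz, element):
        nonlocal serial
        name_f = name if len(name) == 4 else f" {name:<3s}"
        line = (
            f"HETATM{serial:>5d} {name_f:<4s}{'':1s}{resname:>3s} {chain}"
            f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element.upper():>2s}"
        )
        serial += 1
        return line

    for u in sorted(duplex.units, key=lambda u: (u.strand_index, u.position)):
        chain = "A" if u.strand_index == 1 else "B"
        for name, elem, xyz in zip(u.site_names, u.site_elements, u.coords):
            lines.append(
                _atom(name, _RESNAME[u.base_code], chain, u.residue_number, xyz, elem)
            )
    for k, (name, xyz) in enumerate(duplex.hg_ions, start=1):
        lines.append(_atom("HG", "HG", "M", 900 + k, xyz, "HG"))
    for k, (elem, xyz, q) in enumerate(duplex.counter_ions, start=1):
        lines.append(_atom(elem, elem, "I", 1000 + k, xyz, elem))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _validate_pdb_lines(path) -> None:
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(f"{path}: truncated atom record at line {ln}")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise ValueError(
                    f"{path}: malformed atom record at line {ln}"
                ) from None


def read_pdb(path) -> DuplexModel:
    """Read a coarse duplex model written by :func:`write_pdb`."""
    from Bio.PDB import PDBParser

    _validate_pdb_lines(path)
    orientation, rise, twist = "parallel", geo.DEFAULT_RISE, geo.DEFAULT_TWIST
    pairing: list[tuple[int, int, str]] = []
    charges: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("REMARK 300"):
                continue
            tok = line.split()
            if len(tok) < 4:
                continue
            key = tok[2]
            if key == "ORIENTATION":
                orientation = tok[3].lower()
            elif key == "RISE":
                rise, twist = float(tok[3]), float(tok[5])
            elif key == "PAIR":
                pairing.append((int(tok[3]), int(tok[4]), tok[5]))
            elif key == "CHARGE":
                charges[tok[3]] = int(tok[4])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("model", path)

    units: list[NucleotideUnit] = []
    hg_ions: list[tuple[str, np.ndarray]] = []
    counter_ions: list[tuple[str, np.ndarray, int]] = []
    n_strand1 = 0
    model = next(structure.get_models())
    for chain in model:
        cid = chain.id
        for res in chain:
            resname = res.get_resname().strip()
            if cid == "M":
                hg_ions.append(
                    (f"Hg{len(hg_ions) + 1}", _res_coords(res)[0][1].astype(float))
                )
                continue
            if cid == "I":
                q = 1 if resname == "NA" else -1
                counter_ions.append(
                    (resname, _res_coords(res)[0][1].astype(float), q)
                )
                continue
            if cid not in _CHAIN_STRAND:
                raise ValueError(f"unexpected chain {cid!r} in {path}")
            base = _RESNAME_INV.get(resname)
            if base is None:
                raise ValueError(f"unknown residue name {resname!r} in {path}")
            strand = _CHAIN_STRAND[cid]
            sites = _res_coords(res)
            resnum = res.id[1]
            units.append(
                NucleotideUnit(
                    base_code=base,
                    strand_index=strand,
                    position=resnum,  # fixed below for strand 2
                    residue_number=resnum,
                    site_names=[n for n, _ in sites],
                    site_elements=[
                        a.element.strip().upper()[:1] if a.element else n[0]
                        for (n, _), a in zip(sites, res.get_atoms())
                    ],
                    coords=np.array([c for _, c in sites], dtype=float),
                )
            )
            if strand == 1:
                n_strand1 = max(n_strand1, resnum)
    for u in units:
        if u.strand_index == 2:
            u.position = u.residue_number - n_strand1
        if u.label in charges:
            u.base_charge = charges[u.label]
    if not pairing:
        raise ValueError(f"{path}: no REMARK 300 PAIR metadata found")
    return DuplexModel(
        units=units,
        pairing=pairing,
        orientation=orientation,
        rise=rise,
        twist=twist,
        hg_ions=hg_ions,
        counter_ions=counter_ions,
    )


def _res_coords(res):
    return [(atom.get_name(), atom.get_coord()) for atom in res.get_atoms()]


# ----------------------------------------------------------------------
# XYZ

def write_xyz(path, frames, labels=None, comments=None, mode="w") -> None:
    """Write an (extended-comment) XYZ trajectory.

    ``comments`` is one string per frame, conventionally
    ``"step=... T=... D=... lambda=..."``.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    n = len(frames[0])
    if labels is None:
        labels = ["X"] * n
    if comments is None:
        comments = [""] * len(frames)
    with open(path, mode) as fh:
        for frame, comment in zip(frames, comments):
            fh.write(f"{len(frame)}\n{comment}\n")
            for lbl, (x, y, z) in zip(labels, frame):
                fh.write(f"{lbl:<8s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def read_xyz(path) -> tuple[list[np.ndarray], list[str], list[str]]:
    """Read an XYZ trajectory; returns (frames, labels, comments).

    Malformed records are rejected with their line number.
    """
    frames, comments, labels = [], [], []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(
                f"{path}: expected atom count at line {i + 1}, got "
                f"{lines[i].strip()!r}"
            ) from None
        if i + 1 + n >= len(lines) + 1:
            raise ValueError(f"{path}: truncated frame starting at line {i + 1}")
        comments.append(lines[i + 1].rstrip("\n"))
        frame = np.empty((n, 3))
        frame_labels = []
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: malformed coordinate record at line {i + 3 + k}"
                )
            frame_labels.append(parts[0])
            try:
                frame[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ValueError(
                    f"{path}: malformed coordinate record at line {i + 3 + k}"
                ) from None
        frames.append(frame)
        if not labels:
            labels = frame_labels
        i += 2 + n
    return frames, labels, comments


def write_md_traces(result, path) -> None:
    """CSV trace (step, D_target, D_measured, lambda, T, E) of an MD run."""
    import pandas as pd

    pd.DataFrame(
        {
            "step": result.steps,
            "D_target": result.d_target,
            "D_measured": result.d_measured,
            "lambda": result.lambdas,
            "T": result.temperature,
            "E_pot": result.e_pot,
            "E_kin": result.e_kin,
            "conserved": result.conserved,
        }
    ).to_csv(path, index=False)


# ----------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Structured, serializable description of one pipeline run."""

    seed: int = 0
    sequence: str = geo.DEFAULT_SEQ1
    parallel: bool = True
    isoguanine: bool = True
    modify_at: int = 7
    hg: bool = True
    neutralize: bool = True
    variant: str = "DNA"
    schedule: str = "3.0:5.8:0.2"
    dt: float = 0.5
    temperature: float = 300.0
    thermostat: str = "nhc"
    zip_steps: int = 10000
    zip_d_start: float = 1.88
    zip_d_end: float = 1.56
    anneal_steps: int = 3000
    anneal_factor: float = 0.99
    anneal_interval: int = 100
    ti_steps_per_window: int = 2000
    ti_equilibration_fraction: float = 0.2
    ti_pre_equilibration_steps: int = 1000
    pattern_cutoff: float = 2.6
    pattern_debounce: int = 3
    outdir: str = "runs/run0"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
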