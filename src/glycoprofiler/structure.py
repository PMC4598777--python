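"""Structural context of a glycosite: PDB parsing, solvent-accessible
surface area with a large (5 Å) probe, and site-to-active-site distances.

SASA uses the Shrake-Rupley method: per atom, the fraction of sphere sample
points at radius (r_vdw + probe) not buried inside any neighbour's expanded
sphere, times the sphere area. With the default 5 Å probe the per-residue
sums are accessibility *scores* in absolute arbitrary units suitable for
ranking residue exposure (e.g. methionine oxidation propensity), not for
comparison with water-probe (1.4 Å) SASA values.
"""

from __future__ import annotations

import math
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "SasaConfig",
    "VDW_RADII",
    "parse_structure",
    "sasa",
    "residue_sasa",
    "site_distance",
    "methionine_accessibility_ranking",
    "fetch_pdb",
]

#: Bondi van der Waals radii (Å); C default for unknown elements.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}

#: Side-chain atom exclusion set for the sidechain distance convention.
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    res_name: str
    res_num: int
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    radius: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("atom coordinates must be finite")
        if self.radius <= 0:
            raise ValueError("van der Waals radius must be positive")

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class SasaConfig:
    """Probe radius (Å; default the large 5 Å exposure probe), sphere
    sample-point count, and radii table name."""

    probe: float = 5.0
    n_points: int = 960
    radii: str = "bondi"

    def __post_init__(self) -> None:
        if self.probe <= 0:
            raise ValueError("probe radius must be positive")
        if self.n_points < 100:
            raise ValueError("at least 100 sphere sample points required")


def parse_structure(
    source: str | Path,
    chain: str | None = None,
    include_hetero: bool = False,
    include_hydrogens: bool = False,
) -> list[AtomRecord]:
    """Parse PDB text (or a path to it) into atom records.

    Waters and hetero groups are excluded by default; alternate locations
    are resolved to the highest-occupancy conformer; only the first model
    is read. Malformed input is rejected with the parser's diagnostics.
    """
    text: str
    path = Path(source) if not str(source).lstrip().startswith(("ATOM", "HETATM", "HEADER", "MODEL", "CRYST", "REMARK", "TITLE")) else None
    if path is not None and path.exists():
        text = path.read_text()
    else:
        text = str(source)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB input: {exc}") from exc
    if len(st) == 0:
        raise ValueError("PDB input contains no model")
    st.setup_entities()
    model = st[0]
    records: list[AtomRecord] = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.is_water():
                continue
            if not include_hetero and res.het_flag == "H" and not res.is_amino_acid():
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if not include_hydrogens and atom.element.name == "H":
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                el = atom.element.name.upper()
                records.append(
                    AtomRecord(
                        chain=ch.name,
                        res_name=res.name,
                        res_num=res.seqid.num,
                        atom_name=name,
                        element=el,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        radius=VDW_RADII.get(el, VDW_RADII["C"]),
                    )
                )
    if not records:
        raise ValueError("no atoms parsed from PDB input")
    return records


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa(atoms: Sequence[AtomRecord], config: SasaConfig | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake-Rupley."""
    if not atoms:
        raise ValueError("at least one atom required")
    config = config or SasaConfig()
    pts = _sphere_points(config.n_points)
    coords = np.array([a.coord for a in atoms])
    radii = np.array([a.radius for a in atoms]) + config.probe
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(len(atoms))
    for i, atom in enumerate(atoms):
        r_i = radii[i]
        sample = coords[i] + r_i * pts
        neighbours = [
            j for j in tree.query_ball_point(coords[i], r_i + max_r) if j != i
        ]
        exposed = np.ones(len(sample), dtype=bool)
        for j in neighbours:
            d2 = np.sum((sample - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        areas[i] = 4.0 * math.pi * r_i**2 * exposed.mean()
    return areas


def residue_sasa(
    atoms: Sequence[AtomRecord], config: SasaConfig | None = None
) -> pd.DataFrame:
    """Per-residue accessibility scores: sum of atomic SASA (arbitrary
    absolute units with a non-water probe)."""
    areas = sasa(atoms, config)
    df = pd.DataFrame(
        {
            "chain": [a.chain for a in atoms],
            "res_name": [a.res_name for a in atoms],
            "res_num": [a.res_num for a in atoms],
            "area": areas,
        }
    )
    out = (
        df.groupby(["chain", "res_num", "res_name"], as_index=False)["area"]
        .sum()
        .rename(columns={"area": "score"})
        .sort_values(["chain", "res_num"], ignore_index=True)
    )
    return out


def _select(atoms: Sequence[AtomRecord], res_num: int, sidechain: bool) -> list[AtomRecord]:
    sel = [a for a in atoms if a.res_num == res_num]
    if sidechain:
        side = [a for a in sel if a.atom_name not in BACKBONE_ATOMS]
        sel = side or sel  # Gly has no side chain: fall back to all atoms
    if not sel:
        raise ValueError(f"residue {res_num} absent from structure")
    return sel


def site_distance(
    atoms: Sequence[AtomRecord],
    residue: int,
    targets: Iterable[int],
    convention: str = "sidechain-min",
) -> tuple[float, str]:
    """Minimum distance (Å) from one residue to a residue set.

    ``sidechain-min``: minimum pairwise distance between the residue's
    side-chain heavy atoms and any atom of the targets (default);
    ``any-min``: minimum over all atoms of both. The convention used is
    returned with the value, since reported site-to-site distances are
    convention-dependent.
    """
    if convention not in ("sidechain-min", "any-min"):
        raise ValueError(f"unknown distance convention {convention!r}")
    a_atoms = _select(atoms, residue, convention == "sidechain-min")
    t_atoms = [a for t in targets for a in _select(atoms, t, False)]
    a_xyz = np.array([a.coord for a in a_atoms])
    t_xyz = np.array([a.coord for a in t_atoms])
    d = np.sqrt(((a_xyz[:, None, :] - t_xyz[None, :, :]) ** 2).sum(axis=2))
    return float(d.min()), convention


def methionine_accessibility_ranking(
    atoms: Sequence[AtomRecord], config: SasaConfig | None = None
) -> list[tuple[int, float]]:
    """Methionine residues ranked by accessibility score (descending).

    With a large-probe config this ranks Met exposure the way oxidation
    propensity tracks solvent accessibility on a folded chain.
    """
    table = residue_sasa(atoms, config)
    mets = table[table["res_name"] == "MET"]
    return list(
        mets.sort_values("score", ascending=False)[["res_num", "score"]]
        .itertuples(index=False, name=None)
    )


def fetch_pdb(pdb_id: str, dest: str | Path) -> Path:
    """Download a PDB entry (requires network access)."""
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url) as resp:
        dest.write_bytes(resp.read())
    return dest
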