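"""Protein structures: PDB parsing, van der Waals radii, residue selection.

Structures are flat atom tables (numpy arrays) rather than a hierarchy:
every atom carries element, chain, residue number + insertion code, residue
name, atom name, coordinates (Å) and a van der Waals radius. Hydrogens are
removed on loading; waters and other heteroatoms are excluded by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import CavCsgError

__all__ = [
    "Structure",
    "RadiusTable",
    "parse_structure",
    "assign_radii",
    "write_pdb",
    "residue_id_str",
    "parse_residue_id",
]

log = logging.getLogger(__name__)

ResidueId = tuple  # (chain, resseq, icode)


@dataclass
class RadiusTable:
    """Van der Waals radii by element symbol, with a default for others.

    Defaults (Å): C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, otherwise 1.70.
    """

    radii: dict[str, float] = field(
        default_factory=lambda: {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
    )
    default: float = 1.70

    def radius(self, element: str) -> float:
        el = element.strip().upper()
        if el in self.radii:
            return self.radii[el]
        log.warning("no van der Waals radius for element %r; using default %.2f", element, self.default)
        return self.default

    @classmethod
    def from_file(cls, path) -> "RadiusTable":
        """Two-column text config: element radius; a line 'default r' overrides."""
        radii: dict[str, float] = {}
        default = 1.70
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise CavCsgError(f"{path}:{lineno}: expected 'element radius'")
            key, val = parts[0], float(parts[1])
            if key.lower() == "default":
                default = val
            else:
                radii[key.upper()] = val
        return cls(radii=radii, default=default)


@dataclass
class Structure:
    """Flat atom table for one (selection of a) structure."""

    coords: np.ndarray  # (n, 3) Å
    radii: np.ndarray  # (n,) Å
    element: np.ndarray
    chain: np.ndarray
    resseq: np.ndarray
    icode: np.ndarray
    resname: np.ndarray
    atom_name: np.ndarray
    source_id: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_ids(self) -> list[ResidueId]:
        """Ordered, de-duplicated (chain, resseq, icode) identifiers."""
        seen, out = set(), []
        for ch, rs, ic in zip(self.chain, self.resseq, self.icode):
            key = (str(ch), int(rs), str(ic))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def residue_name(self, rid: ResidueId) -> str:
        mask = self._residue_mask(rid)
        names = self.resname[mask]
        return str(names[0]) if len(names) else ""

    def _residue_mask(self, rid: ResidueId) -> np.ndarray:
        ch, rs, ic = rid
        return (
            (self.chain.astype(str) == str(ch))
            & (self.resseq.astype(int) == int(rs))
            & (self.icode.astype(str) == str(ic))
        )

    def select_residues(self, rids) -> "Structure":
        mask = np.zeros(self.n_atoms, dtype=bool)
        for rid in rids:
            mask |= self._residue_mask(_normalize_rid(rid))
        if not mask.any():
            raise CavCsgError(f"no atoms matched residues {list(rids)!r}")
        return self._subset(mask)

    def select_atoms(self, mask: np.ndarray) -> "Structure":
        return self._subset(np.asarray(mask, dtype=bool))

    def _subset(self, mask: np.ndarray) -> "Structure":
        return Structure(
            coords=self.coords[mask].copy(),
            radii=self.radii[mask].copy(),
            element=self.element[mask].copy(),
            chain=self.chain[mask].copy(),
            resseq=self.resseq[mask].copy(),
            icode=self.icode[mask].copy(),
            resname=self.resname[mask].copy(),
            atom_name=self.atom_name[mask].copy(),
            source_id=self.source_id,
        )

    def transformed(self, matrix: np.ndarray) -> "Structure":
        """Apply a 4x4 rigid transform to atom coordinates."""
        m = np.asarray(matrix, dtype=float)
        out = self._subset(np.ones(self.n_atoms, dtype=bool))
        out.coords = self.coords @ m[:3, :3].T + m[:3, 3]
        return out


def _normalize_rid(rid) -> ResidueId:
    if isinstance(rid, str):
        return parse_residue_id(rid)
    if len(rid) == 2:
        return (str(rid[0]), int(rid[1]), "")
    return (str(rid[0]), int(rid[1]), str(rid[2]))


def residue_id_str(rid) -> str:
    ch, rs, ic = _normalize_rid(rid)
    return f"{ch}:{rs}{ic}"


def parse_residue_id(text: str) -> ResidueId:
    """Parse 'A:137' or 'A:137B' (chain:number[insertion-code])."""
    chain, _, rest = text.strip().partition(":")
    if not rest:
        raise CavCsgError(f"bad residue id {text!r}; expected 'chain:number'")
    num = rest
    icode = ""
    if not num[-1].isdigit():
        num, icode = num[:-1], num[-1]
    return (chain, int(num), icode)


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def parse_structure(
    path,
    model: int = 0,
    chains=None,
    altloc: str = "occupancy",
    include_het: bool = False,
    include_waters: bool = False,
    radius_table: RadiusTable | None = None,
    source_id: str | None = None,
) -> Structure:
    """Load a PDB file into a flat atom table.

    Hydrogen (and deuterium) atoms are always removed. Waters and HETATM
    records are excluded unless requested. ``altloc`` is either
    ``"occupancy"`` (keep the highest-occupancy alternate) or a specific
    altloc letter (blank always kept).
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise CavCsgError(f"no such PDB file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(source_id or path.stem, str(path))
    models = list(structure)
    if not models:
        raise CavCsgError(f"{path}: no models in PDB file")
    mdl = models[model]
    rows = []
    for chain_obj in mdl:
        if chains is not None and chain_obj.id not in chains:
            continue
        for residue in chain_obj:
            hetflag, resseq, icode = residue.id
            is_water = residue.get_resname().strip() in _WATER_NAMES
            if is_water and not include_waters:
                continue
            if hetflag.strip() and not is_water and not include_het:
                continue
            for atom in residue.get_unpacked_list() if altloc != "occupancy" else _best_altloc_atoms(residue):
                al = atom.get_altloc().strip()
                if altloc != "occupancy" and al and al != altloc:
                    continue
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                rows.append(
                    (
                        atom.coord.astype(float),
                        element,
                        chain_obj.id,
                        int(resseq),
                        icode.strip(),
                        residue.get_resname().strip(),
                        atom.get_name(),
                    )
                )
    if chains is not None and not rows:
        raise CavCsgError(f"{path}: no atoms for chain selector {chains!r}")
    if not rows:
        raise CavCsgError(f"{path}: no atoms after filtering")
    coords = np.array([r[0] for r in rows])
    st = Structure(
        coords=coords,
        radii=np.zeros(len(rows)),
        element=np.array([r[1] for r in rows], dtype=object),
        chain=np.array([r[2] for r in rows], dtype=object),
        resseq=np.array([r[3] for r in rows], dtype=int),
        icode=np.array([r[4] for r in rows], dtype=object),
        resname=np.array([r[5] for r in rows], dtype=object),
        atom_name=np.array([r[6] for r in rows], dtype=object),
        source_id=source_id or path.stem,
    )
    return assign_radii(st, radius_table or RadiusTable())


def _best_altloc_atoms(residue):
    """One atom per site: the highest-occupancy alternate."""
    best = {}
    for atom in residue.get_unpacked_list():
        name = atom.get_name()
        occ = atom.get_occupancy() or 0.0
        if name not in best or occ > (best[name].get_occupancy() or 0.0):
            best[name] = atom
    return list(best.values())


def assign_radii(structure: Structure, table: RadiusTable | None = None) -> Structure:
    """Set every atom's van der Waals radius from the table (idempotent)."""
    table = table or RadiusTable()
    structure.radii = np.array([table.radius(el) for el in structure.element])
    return structure


def write_pdb(structure: Structure, path) -> None:
    """Write a minimal, standards-conforming ATOM-record PDB file."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            name = str(structure.atom_name[i])[:4]
            if len(name) < 4:
                name = " " + name  # standard column alignment for short names
            x, y, z = structure.coords[i]
            fh.write(
                "ATOM  {serial:>5d} {name:<4s} {res:<3s} {chain:1s}{resseq:>4d}{icode:1s}"
                "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                    serial=(i + 1) % 100000,
                    name=name,
                    res=str(structure.resname[i])[:3],
                    chain=str(structure.chain[i])[:1] or "A",
                    resseq=int(structure.resseq[i]) % 10000,
                    icode=str(structure.icode[i])[:1] or " ",
                    x=x, y=y, z=z, occ=1.0, b=0.0,
                    el=str(structure.element[i])[:2],
                )
            )
        fh.write("END\n")
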