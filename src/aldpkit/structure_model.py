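"""Coordinate I/O and the uniform structure data model.

The toolkit works on a light hierarchical model (chains -> residues ->
heavy atoms, plus named ligand groups) read from PDB or mmCIF via gemmi.
Policies applied at parse time, chosen for downstream single-conformer
geometry on cryo-EM models:

* altlocs: keep the highest-occupancy conformer per atom name
  (ties broken by alphabetical altloc id);
* hydrogens dropped (heavy atoms only);
* waters stripped; other hetero groups retained as ligands;
* multi-model files: first model only, with a logged notice;
* residue numbering: author numbering as deposited, insertion codes kept.

Polymer residues lacking a C-alpha are flagged on the model, never
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np
import yaml

from .errors import (
    ChainNotFoundError,
    ComponentNotFoundError,
    EmptyModelError,
    ResidueNotFoundError,
    StructureParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class ResidueRef:
    """Identity of a residue: chain, author number, insertion code, amino acid.

    ``amino_acid`` is the 1-letter code for standard residues, otherwise the
    component code itself (ligands, modified residues without a mapping).
    """

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    amino_acid: str = "X"

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.amino_acid}{self.residue_number}{self.insertion_code}"


@dataclass
class AtomRecord:
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.atom_name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    ref: ResidueRef
    name: str  # PDB component code (3-letter for amino acids)
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")

    def heavy_atoms(self, subset: str = "all_heavy") -> list[AtomRecord]:
        if subset == "all_heavy":
            return list(self.atoms)
        if subset == "side_chain":
            return [a for a in self.atoms if a.atom_name not in BACKBONE_ATOMS]
        raise ValidationError(f"unknown atom subset {subset!r}")


@dataclass
class LigandInstance:
    component_code: str
    chain_id: str
    residue_number: int
    atoms: list[AtomRecord] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """Hierarchical coordinates plus ligand groups for one assembly."""

    entry_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[LigandInstance] = field(default_factory=list)
    assembly_symmetry: str = ""
    missing_ca: list[ResidueRef] = field(default_factory=list)

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise ChainNotFoundError(
                f"chain {chain_id!r} not in model {self.entry_id} "
                f"(available: {sorted(self.chains)})"
            ) from None

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def residue(self, chain_id: str, residue_number: int, insertion_code: str = "") -> Residue:
        for res in self.chain(chain_id):
            if (res.ref.residue_number, res.ref.insertion_code) == (residue_number, insertion_code):
                return res
        raise ResidueNotFoundError(
            f"residue {residue_number}{insertion_code} not in chain {chain_id} of {self.entry_id}"
        )

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues()) + sum(
            len(lig.atoms) for lig in self.ligands
        )

    def heavy_atom_table(self) -> tuple[np.ndarray, list[tuple[ResidueRef, AtomRecord]]]:
        """All polymer heavy atoms as an (N, 3) array plus parallel owner list."""
        owners: list[tuple[ResidueRef, AtomRecord]] = []
        for res in self.residues():
            for atom in res.atoms:
                owners.append((res.ref, atom))
        coords = np.array([a.position for _, a in owners], dtype=float).reshape(-1, 3)
        return coords, owners


@dataclass
class CaTrace:
    """Ordered C-alpha selection with the residues that had to be omitted."""

    refs: list[ResidueRef]
    coords: np.ndarray  # (N, 3)
    omitted: list[ResidueRef] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.refs)


# ---------------------------------------------------------------------------
# parsing


def _dedup_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties alphabetical."""
    by_name: dict[str, AtomRecord] = {}
    for atom in sorted(atoms, key=lambda a: (a.atom_name, -a.occupancy, a.altloc)):
        by_name.setdefault(atom.atom_name, atom)
    kept = list(by_name.values())
    for a in kept:
        a.altloc = ""
    return kept


def _one_letter(name: str) -> str:
    return THREE_TO_ONE.get(name.upper(), name)


def parse_structure(source: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file (or literal text) into a :class:`StructureModel`.

    ``source`` may be a path or the file content itself (detected by the
    presence of newlines). ``format`` is ``"pdb"`` or ``"mmcif"``; when
    omitted it is inferred from the file extension or content.
    """
    text: str | None = None
    name = "<string>"
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        path = Path(source)
        if not path.exists():
            raise StructureParseError(f"structure file not found: {path}")
        text = path.read_text()
        name = path.name
        if format is None:
            suffix = path.name.lower()
            format = "mmcif" if suffix.endswith((".cif", ".cif.gz", ".mmcif")) else "pdb"
    else:
        text = str(source)
        if format is None:
            format = "mmcif" if text.lstrip().startswith("data_") else "pdb"

    try:
        if format == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        elif format == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            raise ValidationError(f"unknown format {format!r} (expected 'pdb' or 'mmcif')")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {name} as {format}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise EmptyModelError(f"{name}: no models in file")
    if len(st) > 1:
        logger.info("%s: %d models present, using the first", name, len(st))

    model = StructureModel(entry_id=st.name or name)
    gmodel = st[0]
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name in WATER_NAMES:
                continue
            atoms = []
            for gatom in gres:
                if gatom.element.is_hydrogen:
                    continue
                atoms.append(
                    AtomRecord(
                        atom_name=gatom.name,
                        element=gatom.element.name,
                        position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=min(max(gatom.occ, 0.0), 1.0),
                        altloc=(gatom.altloc or "").strip("\x00"),
                        is_hetero=gres.het_flag == "H",
                    )
                )
            atoms = _dedup_altlocs(atoms)
            if not atoms:
                continue
            is_polymer = gres.het_flag == "A" or gres.name in THREE_TO_ONE
            icode = gres.seqid.icode.strip()
            if is_polymer:
                ref = ResidueRef(gchain.name, gres.seqid.num, icode, _one_letter(gres.name))
                res = Residue(ref=ref, name=gres.name, atoms=atoms)
                residues.append(res)
                if res.ca is None:
                    model.missing_ca.append(ref)
            else:
                model.ligands.append(
                    LigandInstance(
                        component_code=gres.name,
                        chain_id=gchain.name,
                        residue_number=gres.seqid.num,
                        atoms=atoms,
                    )
                )
        if residues:
            model.chains[gchain.name] = residues

    if not model.chains:
        raise EmptyModelError(f"{name}: no polymer residues after filtering")
    seen: set[tuple[str, int, str]] = set()
    for res in model.residues():
        key = res.ref.key()
        if key in seen:
            raise StructureParseError(f"{name}: duplicate residue identifier {res.ref}")
        seen.add(key)
    return model


# ---------------------------------------------------------------------------
# writing (fixtures are emitted as plain PDB)


def _pdb_atom_line(serial: int, atom: AtomRecord, resname: str, chain: str,
                   resnum: int, icode: str) -> str:
    record = "HETATM" if atom.is_hetero else "ATOM  "
    name = atom.atom_name
    # standard PDB name justification: element right-aligned in cols 13-14
    name_field = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
    return (
        f"{record}{serial:>5d} {name_field:<4s}{'':1s}{resname:>3s} {chain:1s}"
        f"{resnum:>4d}{icode or ' ':1s}   "
        f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
        f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a plain PDB file (fixtures, viewer export)."""
    lines: list[str] = []
    serial = 0
    for chain_id, residues in model.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                lines.append(
                    _pdb_atom_line(serial, atom, res.name, chain_id,
                                   res.ref.residue_number, res.ref.insertion_code)
                )
        lines.append(f"TER   {serial + 1:>5d}")
    for lig in model.ligands:
        for atom in lig.atoms:
            serial += 1
            rec = AtomRecord(atom.atom_name, atom.element, atom.position,
                             atom.occupancy, "", True)
            lines.append(
                _pdb_atom_line(serial, rec, lig.component_code, lig.chain_id,
                               lig.residue_number, "")
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selections


def select_ca(model: StructureModel, chain: str,
              residue_range: tuple[int, int] | None = None) -> CaTrace:
    """Ordered C-alpha trace of one chain, optionally restricted to an
    inclusive author-numbering interval. Residues lacking a CA are omitted
    and reported on the returned trace."""
    refs: list[ResidueRef] = []
    coords: list[np.ndarray] = []
    omitted: list[ResidueRef] = []
    for res in model.chain(chain):
        if residue_range is not None:
            lo, hi = residue_range
            if not lo <= res.ref.residue_number <= hi:
                continue
        ca = res.ca
        if ca is None:
            omitted.append(res.ref)
        else:
            refs.append(res.ref)
            coords.append(ca.position)
    arr = np.array(coords, dtype=float).reshape(-1, 3)
    return CaTrace(refs=refs, coords=arr, omitted=omitted)


def extract_ligand(model: StructureModel, component_code: str) -> list[LigandInstance]:
    """All instances of one hetero component, grouped per instance."""
    hits = [lig for lig in model.ligands if lig.component_code == component_code]
    if not hits:
        available = sorted({lig.component_code for lig in model.ligands})
        raise ComponentNotFoundError(
            f"component {component_code!r} not in {model.entry_id}; available: {available}"
        )
    return hits


# ---------------------------------------------------------------------------
# segment annotation

SEGMENT_NAMES = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "EH", "CH", "NBD")
TM_SEGMENTS = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6")


@dataclass
class SegmentAnnotation:
    """Named residue ranges (TM1-TM6, EH, CH, NBD) per chain.

    ``ranges`` maps segment name -> list of (chain_id, start, end) inclusive
    author-numbering intervals.
    """

    ranges: dict[str, list[tuple[str, int, int]]]

    def __post_init__(self):
        for name, spans in self.ranges.items():
            for chain, start, end in spans:
                if start > end:
                    raise ValidationError(f"{name}: start {start} > end {end} (chain {chain})")
        # distinct TM segments must not overlap within a chain
        by_chain: dict[str, list[tuple[int, int, str]]] = {}
        for name in TM_SEGMENTS:
            for chain, start, end in self.ranges.get(name, []):
                by_chain.setdefault(chain, []).append((start, end, name))
        for chain, spans in by_chain.items():
            spans.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValidationError(
                        f"overlapping TM ranges in chain {chain}: "
                        f"{n1}=({s1},{e1}) vs {n2}=({s2},{e2})"
                    )

    def segments(self) -> list[str]:
        return list(self.ranges)

    def spans(self, segment: str, chain: str | None = None) -> list[tuple[str, int, int]]:
        try:
            spans = self.ranges[segment]
        except KeyError:
            raise ValidationError(
                f"unknown segment {segment!r}; known: {sorted(self.ranges)}"
            ) from None
        if chain is not None:
            spans = [s for s in spans if s[0] == chain]
        return spans

    def contains(self, segment: str, chain: str, residue_number: int) -> bool:
        return any(
            c == chain and s <= residue_number <= e for c, s, e in self.ranges.get(segment, [])
        )

    def contains_number(self, segment: str, residue_number: int) -> bool:
        """Chain-agnostic membership (homodimer: same numbering per chain)."""
        return any(s <= residue_number <= e for _, s, e in self.ranges.get(segment, []))

    def residues_in(self, model: StructureModel, segment: str,
                    chain: str | None = None) -> list[Residue]:
        out = []
        for c, start, end in self.spans(segment, chain):
            if c not in model.chains:
                continue
            for res in model.chains[c]:
                if start <= res.ref.residue_number <= end:
                    out.append(res)
        return out


def load_segment_annotation(source: str | Path | Mapping) -> SegmentAnnotation:
    """Load segment ranges from YAML/JSON text, a path, or a mapping.

    Expected shape: ``{segment: [[chain, start, end], ...]}`` (a single
    ``[chain, start, end]`` triple is also accepted per segment).
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        if isinstance(source, Path) or "\n" not in str(source):
            text = Path(source).read_text()
        else:
            text = str(source)
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping) or not raw:
        raise ValidationError("segment annotation must be a non-empty mapping")
    ranges: dict[str, list[tuple[str, int, int]]] = {}
    for name, value in raw.items():
        if value and not isinstance(value[0], (list, tuple)):
            value = [value]
        spans = []
        for item in value:
            if len(item) != 3:
                raise ValidationError(f"{name}: expected [chain, start, end], got {item!r}")
            chain, start, end = item
            spans.append((str(chain), int(start), int(end)))
        ranges[str(name)] = spans
    return SegmentAnnotation(ranges=ranges)


def default_segment_annotation() -> SegmentAnnotation:
    """Curated default ALDP segment ranges bundled with the package.

    EH and CH bounds follow the deletion constructs (364-374 and 683-745);
    TM and NBD bounds are curated approximations, see docs/methods.md.
    """
    path = Path(__file__).parent / "data" / "aldp_segments.yaml"
    return load_segment_annotation(path)
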