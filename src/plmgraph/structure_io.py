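"""Read PDB structures into ordered residue-level records, and read/write FASTA.

Residue-level 3D graphs use the alpha carbon (CA) as each residue's
representative coordinate, so parsing keeps exactly one CA position per
residue and drops residues without one.  Only coordinate model 1 is read
by default (NMR multi-model files would otherwise duplicate every
residue).  Alternate locations are resolved to the highest-occupancy
conformer, ties going to the alphabetically first altloc identifier.
HETATM records are ignored except selenomethionine (MSE), which sits
inside polypeptide chains and is kept with the one-letter code 'X'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np
from Bio import SeqIO

from .errors import ChainNotFoundError, ModelIndexError, ParseError, ValidationError

__all__ = [
    "ResidueRecord",
    "StructureModel",
    "SequenceRecord",
    "read_structure",
    "derive_sequence",
    "read_fasta",
    "write_fasta",
    "write_ca_pdb",
    "THREE_TO_ONE",
    "AA_ALPHABET",
]

#: Standard 20 amino acids, three-letter -> one-letter.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: One-letter alphabet used for node features: 20 standard residues + 'X'.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"


@dataclass(frozen=True)
class ResidueRecord:
    """One residue observed in a structure, reduced to its CA position.

    ``res_seq``/``icode`` carry the author numbering from the PDB file and
    may be non-contiguous; positional indices used elsewhere in the
    package are 1-based ranks in the ordered record list, never author
    numbers.
    """

    chain_id: str
    res_seq: int
    icode: str
    aa: str
    ca_xyz: np.ndarray

    def __post_init__(self):
        if self.aa not in AA_ALPHABET:
            raise ValidationError(f"unknown one-letter code {self.aa!r}")
        xyz = np.asarray(self.ca_xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValidationError("ca_xyz must be a finite 3-vector")
        object.__setattr__(self, "ca_xyz", xyz)


@dataclass
class StructureModel:
    """Ordered per-chain residue records for one coordinate model."""

    chains: dict[str, list[ResidueRecord]]
    source_id: str = ""

    def __post_init__(self):
        for cid, records in self.chains.items():
            seen = set()
            for r in records:
                key = (r.res_seq, r.icode)
                if key in seen:
                    raise ValidationError(
                        f"duplicate residue {key} in chain {cid}"
                    )
                seen.add(key)

    def ca_coords(self, chain_id: str) -> np.ndarray:
        """CA coordinates of one chain as an (N, 3) array, file order."""
        if chain_id not in self.chains:
            raise ChainNotFoundError(chain_id)
        return np.array([r.ca_xyz for r in self.chains[chain_id]])


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence (uppercase, non-empty)."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValidationError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Select the CA atom of a residue under the altloc rule.

    Highest occupancy wins; occupancy ties go to the alphabetically first
    altloc identifier.  Calcium ions (atom name CA, element Ca) are not
    alpha carbons and are rejected by the element check.
    """
    candidates = [
        a for a in residue
        if a.name == "CA" and a.element.name == "C"
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda a: (-a.occ, a.altloc))


def read_structure(path: str | Path, model_index: int = 0) -> StructureModel:
    """Parse a PDB file into per-chain ordered CA records.

    Parameters
    ----------
    path
        PDB-format file (ATOM/HETATM/MODEL records, wwPDB v3.3 columns).
    model_index
        0-based coordinate model to read; files without MODEL records
        expose a single implicit model 0.

    Returns
    -------
    StructureModel
        Chains in file order, residues in file order within each chain.
        Residues lacking a CA atom are dropped with a warning.  HETATM
        residues are skipped except MSE, which maps to 'X'.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no coordinate models in {path}")
    if not 0 <= model_index < len(st):
        raise ModelIndexError(
            f"model index {model_index} out of range; file has {len(st)} model(s)"
        )
    model = st[model_index]

    chains: dict[str, list[ResidueRecord]] = {}
    for chain in model:
        records: list[ResidueRecord] = []
        seen: set[tuple[int, str]] = set()
        for res in chain:
            is_het = res.het_flag == "H"
            if is_het and res.name != "MSE":
                continue
            aa = THREE_TO_ONE.get(res.name, "X")
            atom = _pick_ca(res)
            key = (res.seqid.num, res.seqid.icode.strip())
            if atom is None:
                warnings.warn(
                    f"{path.name}: residue {res.name} {chain.name}{res.seqid.num}"
                    " has no CA atom; dropped"
                )
                continue
            if key in seen:
                warnings.warn(
                    f"{path.name}: duplicate residue {key} in chain"
                    f" {chain.name}; first occurrence kept"
                )
                continue
            seen.add(key)
            records.append(
                ResidueRecord(
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    aa=aa,
                    ca_xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                )
            )
        if records:
            chains[chain.name] = records
    return StructureModel(chains=chains, source_id=path.stem)


def derive_sequence(model: StructureModel, chain_id: str) -> SequenceRecord:
    """One-letter sequence of a chain, in record order.

    This is the *fragmentary* sequence actually observed in the
    structure; missing residues simply do not appear.  Non-standard
    residues are 'X'.
    """
    if chain_id not in model.chains or not model.chains[chain_id]:
        raise ChainNotFoundError(
            f"chain {chain_id!r} not present in {model.source_id or 'structure'}"
        )
    seq = "".join(r.aa for r in model.chains[chain_id])
    return SequenceRecord(id=f"{model.source_id}_{chain_id}", seq=seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read all records of a FASTA file, whitespace-stripped and uppercased."""
    path = Path(path)
    records = [
        SequenceRecord(id=rec.id, seq=str(rec.seq).strip().upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i:i + 60] + "\n")


def write_ca_pdb(
    seq: str,
    coords: np.ndarray,
    path: str | Path,
    chain_id: str = "A",
) -> None:
    """Write a CA-only PDB file for a single chain (synthetic fixtures).

    Residue numbering is 1..N; 'X' letters are written as the dummy
    residue name UNK.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(seq), 3):
        raise ValidationError("coords must be (len(seq), 3)")
    lines = []
    for i, (aa, (x, y, z)) in enumerate(zip(seq, coords), start=1):
        resname = ONE_TO_THREE.get(aa, "UNK")
        lines.append(
            f"ATOM  {i:5d}  CA  {resname} {chain_id}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {'C':>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
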