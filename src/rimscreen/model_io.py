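"""Reading, validating and writing predicted-structure models.

This module ingests multi-chain structure predictions in PDB or mmCIF
format following the AlphaFold output convention: the per-residue
confidence score (pLDDT, 0-100) is stored in the temperature-factor
(B-factor) column of every atom of the residue.  Hydrogens, waters and
hetero-compounds are dropped on read so that downstream distance
criteria operate on heavy atoms of amino-acid residues only, which is
deterministic across formats.

Residues are addressed internally by their 1-based ordinal within the
chain; the author numbering from the file is retained for reporting
only, because trimmed constructs renumber.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import gemmi

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "ResidueRef",
    "StructureParseError",
    "StructureValidationError",
    "ChainLookupError",
    "read_structure",
    "extract_sequence",
    "write_report",
    "read_report",
    "structure_to_gemmi",
    "write_structure",
    "read_fasta",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]


class StructureParseError(ValueError):
    """The file could not be parsed in the requested format."""


class StructureValidationError(ValueError):
    """The parsed structure violates a model invariant."""


class ChainLookupError(KeyError):
    """A requested chain is absent from the model."""


# Standard amino-acid code tables; unknown residue types map to 'X'.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Atom:
    """One heavy atom: element symbol, atom name and coordinates in A."""

    element: str
    name: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Residue:
    """One amino-acid residue with its heavy atoms and confidence.

    ``ordinal`` is the 1-based position within the chain; ``author_number``
    is the residue number as written in the file.  ``plddt`` is the
    per-residue confidence in [0, 100].
    """

    ordinal: int
    author_number: int
    aa: str
    atoms: list[Atom]
    plddt: float

    def validate(self) -> None:
        if not self.atoms:
            raise StructureValidationError(
                f"residue {self.aa}{self.author_number} has no heavy atoms"
            )
        if not (0.0 <= self.plddt <= 100.0):
            raise StructureValidationError(
                f"residue {self.aa}{self.author_number}: confidence "
                f"{self.plddt} outside [0, 100]"
            )
        for a in self.atoms:
            for c in a.xyz:
                if c != c or c in (float("inf"), float("-inf")):
                    raise StructureValidationError(
                        f"residue {self.aa}{self.author_number}: "
                        f"non-finite coordinate"
                    )


@dataclass
class Chain:
    chain_id: str
    subunit_name: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        """One-letter sequence in ordinal order."""
        return "".join(r.aa for r in self.residues)

    def validate(self) -> None:
        if not self.residues:
            raise StructureValidationError(
                f"chain {self.chain_id!r} has zero residues"
            )
        ordinals = [r.ordinal for r in self.residues]
        if any(b <= a for a, b in zip(ordinals, ordinals[1:])):
            raise StructureValidationError(
                f"chain {self.chain_id!r}: residue ordinals not strictly "
                f"increasing"
            )
        for r in self.residues:
            r.validate()


@dataclass
class StructureModel:
    """A ranked multi-chain coordinate set with per-residue confidence.

    ``rank`` follows the prediction-server convention (1 = best of the
    sampled models).  ``global_confidence`` is the model-level mean pLDDT
    in [0, 100]; ``ptm`` the predicted-TM score in [0, 1]; ``pae`` an
    optional residue-by-residue predicted aligned error matrix carried
    as an attachment (no filter in this package consumes it).
    """

    model_id: str
    rank: int
    chains: list[Chain]
    global_confidence: float | None = None
    ptm: float | None = None
    pae: Any | None = None

    def validate(self) -> None:
        if self.rank < 1:
            raise StructureValidationError(f"rank must be >= 1, got {self.rank}")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructureValidationError(f"duplicate chain ids in {ids}")
        for c in self.chains:
            c.validate()

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ChainLookupError(
            f"chain {chain_id!r} not in model {self.model_id!r} "
            f"(have {[c.chain_id for c in self.chains]})"
        )

    def residue(self, ref: "ResidueRef") -> Residue:
        chain = self.chain(ref.chain_id)
        for r in chain.residues:
            if r.ordinal == ref.ordinal:
                return r
        raise ChainLookupError(
            f"ordinal {ref.ordinal} not in chain {ref.chain_id!r}"
        )

    def mean_plddt(self) -> float:
        vals = [r.plddt for c in self.chains for r in c.residues]
        return sum(vals) / len(vals)


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Lightweight address of one residue in a model."""

    chain_id: str
    ordinal: int
    aa: str

    def to_dict(self) -> dict:
        return {"chain_id": self.chain_id, "ordinal": self.ordinal, "aa": self.aa}

    @classmethod
    def from_dict(cls, d: dict) -> "ResidueRef":
        return cls(d["chain_id"], int(d["ordinal"]), d["aa"])


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_RANK_RE = re.compile(r"rank[_\-]?0*(\d+)", re.IGNORECASE)


def _pick_altloc(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Collapse alternate locations: keep the highest-occupancy conformer
    per atom name, ties broken by first in file."""
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = a
            order.append(a.name)
        elif a.occ > by_name[a.name].occ:
            by_name[a.name] = a
    return [by_name[n] for n in order]


def read_structure(
    path: str | Path,
    format: str = "auto",
    subunit_names: Sequence[str] | None = None,
    rank: int | None = None,
) -> StructureModel:
    """Read a predicted model from PDB or mmCIF.

    Per-residue pLDDT is taken from the temperature-factor column; in
    AlphaFold output all atoms of a residue carry the same value, and if
    they do not, the mean is used and a warning recorded.  Hydrogens,
    waters and non-amino-acid residues are dropped.

    Parameters
    ----------
    path : file to read.
    format : ``pdb``, ``mmcif`` or ``auto`` (by extension).
    subunit_names : optional names for the chains in file order;
        defaults to the chain ids themselves.
    rank : model rank; if omitted, parsed from a ``rank_N`` token in the
        file name, else 1.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureParseError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {fmt}: {exc}") from exc

    st.remove_hydrogens()
    st.remove_waters()
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise StructureParseError(f"{path}: no coordinates found")

    if rank is None:
        m = _RANK_RE.search(path.name)
        rank = int(m.group(1)) if m else 1

    gmodel = st[0]
    chains: list[Chain] = []
    for ci, gchain in enumerate(gmodel):
        residues: list[Residue] = []
        ordinal = 0
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            if info is not None and not info.is_amino_acid():
                continue
            atoms_raw = _pick_altloc(list(gres))
            atoms = [
                Atom(a.element.name, a.name, a.pos.x, a.pos.y, a.pos.z)
                for a in atoms_raw
                if not a.is_hydrogen()
            ]
            if not atoms:
                continue
            bvals = [a.b_iso for a in atoms_raw if not a.is_hydrogen()]
            plddt = sum(bvals) / len(bvals)
            if max(bvals) - min(bvals) > 1e-3:
                warnings.warn(
                    f"{path.name} chain {gchain.name} residue {gres.seqid.num}: "
                    f"per-atom confidence varies; using mean {plddt:.2f}",
                    stacklevel=2,
                )
            if not (0.0 <= plddt <= 100.0):
                raise StructureValidationError(
                    f"{path.name} chain {gchain.name} residue "
                    f"{gres.seqid.num}: confidence {plddt} outside [0, 100]"
                )
            ordinal += 1
            residues.append(
                Residue(
                    ordinal=ordinal,
                    author_number=gres.seqid.num,
                    aa=THREE_TO_ONE.get(gres.name.upper(), "X"),
                    atoms=atoms,
                    plddt=plddt,
                )
            )
        if not residues:
            raise StructureValidationError(
                f"{path.name}: chain {gchain.name!r} has zero residues"
            )
        name = (
            subunit_names[ci]
            if subunit_names is not None and ci < len(subunit_names)
            else gchain.name
        )
        chains.append(Chain(chain_id=gchain.name, subunit_name=name, residues=residues))

    model = StructureModel(
        model_id=path.stem,
        rank=rank,
        chains=chains,
        global_confidence=None,
    )
    model.global_confidence = model.mean_plddt()
    model.validate()
    return model


def extract_sequence(model: StructureModel, chain_id: str) -> str:
    """One-letter sequence of a chain, in ordinal order ('X' for unknowns)."""
    return model.chain(chain_id).sequence


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Writing structures (used by the synthetic generator and for export)
# ---------------------------------------------------------------------------


def structure_to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = ONE_TO_THREE.get(res.aa, "UNK")
            gr.seqid = gemmi.SeqId(res.author_number, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
                ga.occ = 1.0
                ga.b_iso = res.plddt
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path, format: str = "auto") -> None:
    """Write a model as PDB or mmCIF with pLDDT in the B-factor column."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = structure_to_gemmi(model)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted((_to_jsonable(v) for v in obj), key=repr)
    if hasattr(obj, "item") and callable(obj.item) and getattr(obj, "shape", None) == ():
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def write_report(obj: Any, path: str | Path, format: str = "auto") -> None:
    """Serialize a pipeline result (or list of results) to TSV or JSON.

    TSV output uses a '#'-prefixed header line; JSON output round-trips
    all fields losslessly via ``read_report``.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "json" if path.suffix.lower() == ".json" else "tsv"
    data = _to_jsonable(obj)
    try:
        if fmt == "json":
            path.write_text(json.dumps(data, indent=2, sort_keys=False) + "\n")
        elif fmt == "tsv":
            _write_tsv(data, path)
        else:
            raise ValueError(f"unknown report format {format!r}")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def _flatten(d: dict, prefix: str = "") -> dict:
    out: dict = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        elif isinstance(v, (list, tuple)):
            out[key] = json.dumps(v)
        else:
            out[key] = v
    return out


def _write_tsv(data: Any, path: Path) -> None:
    rows: list[dict]
    if isinstance(data, dict):
        # A report with a per-residue/per-item table gets one row per item
        # plus trailing summary rows for the scalar fields.
        table_keys = [
            k for k, v in data.items()
            if isinstance(v, list) and v and isinstance(v[0], dict)
        ]
        if table_keys:
            key = table_keys[0]
            rows = [_flatten(r) for r in data[key]]
            scalars = _flatten({k: v for k, v in data.items() if k != key})
            lines = _tsv_lines(rows)
            for k, v in scalars.items():
                lines.append(f"# {k}\t{v}")
            path.write_text("\n".join(lines) + "\n")
            return
        rows = [_flatten(data)]
    elif isinstance(data, list):
        rows = [_flatten(r) if isinstance(r, dict) else {"value": r} for r in data]
    else:
        rows = [{"value": data}]
    path.write_text("\n".join(_tsv_lines(rows)) + "\n")


def _tsv_lines(rows: list[dict]) -> list[str]:
    cols: list[str] = []
    for r in rows:
        for k in r:
            if k not in cols:
                cols.append(k)
    lines = ["# " + "\t".join(cols) if cols else "# (empty)"]
    for r in rows:
        lines.append("\t".join(str(r.get(c, "")) for c in cols))
    return lines


def read_report(path: str | Path) -> Any:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
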