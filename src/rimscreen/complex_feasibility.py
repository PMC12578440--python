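"""Steric feasibility of pairwise interfaces on assembled complexes.

A pairwise prediction only involves two subunits; in the cell those
subunits live inside assembled complexes (e.g. an octameric filament
unit built from two copies of each of four subunits, or the octameric
tethering complex).  An interface residue found in a pairwise model is
"sterically feasible" if it is still solvent-exposed when its subunit
is embedded in the assembled complex — otherwise engaging it would
require partial disassembly or a conformational change.

Feasibility is quantified as relative solvent accessibility: the
accessible surface area (ASA) of the residue's heavy atoms in the full
complex, divided by the maximal reference ASA of that amino-acid type,
clamped to [0, 1].  ASA uses rolling-probe sphere-point sampling
(Shrake-Rupley style, Fibonacci point distribution, >=960 points per
atom) with a 1.4 A water probe.  A residue is called accessible when
its relative accessibility is at least 0.25; since complexes can carry
several copies of a subunit, a residue is feasible if accessible on at
least one copy (one partner can dock on one face of a filament).
Probe, threshold and point count are configurable and recorded in every
report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as bst
from Bio import Align

from .model_io import ResidueRef, StructureModel

__all__ = [
    "ComplexModel",
    "ResidueMapping",
    "FeasibilityReport",
    "MappingError",
    "map_to_complex",
    "relative_accessibility",
    "residue_accessibilities",
    "feasibility",
    "MAX_ASA",
]

# Theoretical maximal ASA (A^2) of residue X in an extended Gly-X-Gly
# tripeptide; Tien et al. 2013, PLOS ONE 8:e80635 (theoretical column).
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 197.0,  # median of the 20, for unknown residue types
}


class MappingError(ValueError):
    pass


@dataclass
class ComplexModel:
    """An assembled multi-subunit complex.

    ``subunit_of_chain`` maps each chain id to a subunit name; several
    chains may share a subunit name (e.g. two copies of each subunit in
    an octamer).  Every chain must be mapped.
    """

    model: StructureModel
    subunit_of_chain: dict[str, str]

    def __post_init__(self) -> None:
        missing = [
            c.chain_id for c in self.model.chains
            if c.chain_id not in self.subunit_of_chain
        ]
        if missing:
            raise MappingError(f"chains without subunit assignment: {missing}")

    def chains_of_subunit(self, subunit: str) -> list[str]:
        return [
            c.chain_id for c in self.model.chains
            if self.subunit_of_chain[c.chain_id] == subunit
        ]

    def composition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.model.chains:
            su = self.subunit_of_chain[c.chain_id]
            out[su] = out.get(su, 0) + 1
        return out


@dataclass
class ResidueMapping:
    """Where one pairwise-model interface residue lands on the complex.

    ``targets`` holds one entry per subunit copy the residue aligns to;
    an unmapped residue keeps an empty target list and ``aligned=False``
    (it is reported, never silently dropped).
    """

    source: ResidueRef
    targets: list[ResidueRef]
    aligned: bool

    def to_dict(self) -> dict:
        return {
            "source": self.source.to_dict(),
            "targets": [t.to_dict() for t in self.targets],
            "aligned": self.aligned,
        }


@dataclass
class FeasibilityReport:
    complex_label: str
    per_residue: list[tuple[ResidueRef, float, bool]]
    pct_accessible: float
    unmapped: list[ResidueRef]
    probe_radius: float
    threshold: float
    per_subunit_pct: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "complex_label": self.complex_label,
            "pct_accessible": round(self.pct_accessible, 3),
            "n_assessed": len(self.per_residue),
            "n_unmapped": len(self.unmapped),
            "probe_radius_A": self.probe_radius,
            "accessibility_threshold": self.threshold,
            "per_subunit_pct": {k: round(v, 3) for k, v in self.per_subunit_pct.items()},
            "per_residue": [
                {
                    "residue": ref.to_dict(),
                    "relative_accessibility": round(acc, 4),
                    "accessible": ok,
                }
                for ref, acc, ok in self.per_residue
            ],
            "unmapped": [r.to_dict() for r in self.unmapped],
        }


# ---------------------------------------------------------------------------
# Sequence mapping between pairwise model and complex chains
# ---------------------------------------------------------------------------


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = -1.0
    al.open_gap_score = -5.0
    al.extend_gap_score = -1.0
    return al


def _alignment_map(src: str, dst: str) -> tuple[dict[int, int], float]:
    """Map 1-based source ordinals to 1-based target ordinals through a
    global alignment; returns the map and the identity over aligned
    positions."""
    if src == dst:
        return {i: i for i in range(1, len(src) + 1)}, 1.0
    aln = _aligner().align(src, dst)[0]
    mapping: dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for k in range(a1 - a0):
            i, j = a0 + k, b0 + k
            mapping[i + 1] = j + 1
            aligned_cols += 1
            if src[i] == dst[j]:
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    return mapping, identity


def map_to_complex(
    interface: Iterable[ResidueRef],
    source_sequence: str,
    complex: ComplexModel,
    subunit_name: str,
    min_identity: float = 0.9,
    cross_species: bool = False,
) -> list[ResidueMapping]:
    """Map interface residues from a pairwise model onto a complex.

    A global alignment (match +1, mismatch -1, gap open -5, extend -1)
    is computed between the source chain sequence and each complex chain
    carrying ``subunit_name``; each interface residue maps through the
    alignment to at most one target per subunit copy.  Identical
    sequences give the identity mapping.  An alignment identity below
    ``min_identity`` raises (the wrong subunit was probably supplied)
    unless ``cross_species`` is set, in which case it only warns — the
    complex may legitimately carry an orthologue's sequence.
    """
    chain_ids = complex.chains_of_subunit(subunit_name)
    if not chain_ids:
        raise KeyError(f"subunit {subunit_name!r} not in complex "
                       f"(have {sorted(set(complex.subunit_of_chain.values()))})")
    per_chain: list[tuple[str, dict[int, int]]] = []
    for cid in chain_ids:
        dst = complex.model.chain(cid).sequence
        mapping, identity = _alignment_map(source_sequence, dst)
        if identity < min_identity:
            msg = (
                f"alignment identity {identity:.2f} < {min_identity:.2f} for "
                f"subunit {subunit_name!r} on chain {cid!r}"
            )
            if cross_species:
                warnings.warn(msg + " (cross-species mapping)", stacklevel=2)
            else:
                raise MappingError(msg + "; wrong subunit suspected")
        per_chain.append((cid, mapping))

    out: list[ResidueMapping] = []
    for ref in interface:
        targets: list[ResidueRef] = []
        for cid, mapping in per_chain:
            j = mapping.get(ref.ordinal)
            if j is not None:
                chain = complex.model.chain(cid)
                targets.append(ResidueRef(cid, j, chain.residues[j - 1].aa))
        out.append(ResidueMapping(source=ref, targets=targets, aligned=bool(targets)))
    return out


# ---------------------------------------------------------------------------
# Accessibility
# ---------------------------------------------------------------------------


def _to_atom_array(model: StructureModel) -> tuple[bst.AtomArray, dict[tuple[str, int], np.ndarray]]:
    """Flatten a model into a biotite AtomArray plus a (chain, ordinal) ->
    atom-index lookup."""
    coords = []
    elements = []
    index: dict[tuple[str, int], list[int]] = {}
    i = 0
    for chain in model.chains:
        for res in chain.residues:
            idxs = []
            for atom in res.atoms:
                coords.append(atom.xyz)
                elements.append(atom.element.upper())
                idxs.append(i)
                i += 1
            index[(chain.chain_id, res.ordinal)] = idxs
    arr = bst.AtomArray(i)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.set_annotation("element", np.asarray(elements, dtype="U2"))
    arr.set_annotation("chain_id", np.asarray(["A"] * i, dtype="U4"))
    return arr, {k: np.asarray(v) for k, v in index.items()}


def residue_accessibilities(
    complex: ComplexModel,
    probe: float = 1.4,
    point_number: int = 960,
) -> dict[tuple[str, int], float]:
    """Relative accessibility of every residue in the complex.

    Per-atom ASA is computed over the whole complex by rolling-probe
    sphere-point sampling (Fibonacci distribution, single-element van
    der Waals radii), summed per residue and divided by the maximal
    reference ASA of the residue's amino-acid type, clamped to [0, 1].
    """
    arr, index = _to_atom_array(complex.model)
    atom_sasa = bst.sasa(
        arr,
        probe_radius=probe,
        point_number=point_number,
        vdw_radii="Single",
    )
    out: dict[tuple[str, int], float] = {}
    for chain in complex.model.chains:
        for res in chain.residues:
            idxs = index[(chain.chain_id, res.ordinal)]
            asa = float(np.nansum(atom_sasa[idxs]))
            ref = MAX_ASA.get(res.aa, MAX_ASA["X"])
            out[(chain.chain_id, res.ordinal)] = min(1.0, max(0.0, asa / ref))
    return out


def relative_accessibility(
    complex: ComplexModel,
    residue: ResidueRef,
    probe: float = 1.4,
    point_number: int = 960,
) -> float:
    """Relative accessibility of one residue in the assembled complex."""
    res = complex.model.residue(residue)  # raises on unresolvable ref
    if not res.atoms:
        raise ValueError(f"residue {residue} has no atoms")
    return residue_accessibilities(complex, probe, point_number)[
        (residue.chain_id, residue.ordinal)
    ]


def feasibility(
    complex: ComplexModel,
    mapped_interface: Mapping[str, Sequence[ResidueMapping]],
    threshold: float = 0.25,
    probe: float = 1.4,
    point_number: int = 960,
    complex_label: str | None = None,
) -> FeasibilityReport:
    """Fraction of mapped interface residues still surface-accessible.

    ``mapped_interface`` holds, per subunit, the residue mappings from
    :func:`map_to_complex`.  A source residue is accessible iff the
    maximum relative accessibility over its subunit-copy targets reaches
    the threshold.  Residues that failed to map are listed separately
    and excluded from the percentage's denominator.
    """
    all_mappings = [m for ms in mapped_interface.values() for m in ms]
    if not all_mappings:
        raise ValueError("no mapped residues to assess")
    acc = residue_accessibilities(complex, probe, point_number)

    per_residue: list[tuple[ResidueRef, float, bool]] = []
    unmapped: list[ResidueRef] = []
    per_subunit_counts: dict[str, list[int]] = {}
    for subunit, mappings in mapped_interface.items():
        n_ok = 0
        n_tot = 0
        for m in mappings:
            if not m.aligned or not m.targets:
                unmapped.append(m.source)
                continue
            best = max(acc[(t.chain_id, t.ordinal)] for t in m.targets)
            ok = best >= threshold
            per_residue.append((m.source, best, ok))
            n_tot += 1
            n_ok += int(ok)
        if n_tot:
            per_subunit_counts[subunit] = [n_ok, n_tot]
    if not per_residue:
        raise ValueError("no interface residue mapped onto the complex")

    n_acc = sum(1 for _, _, ok in per_residue if ok)
    return FeasibilityReport(
        complex_label=complex_label or complex.model.model_id,
        per_residue=per_residue,
        pct_accessible=100.0 * n_acc / len(per_residue),
        unmapped=unmapped,
        probe_radius=probe,
        threshold=threshold,
        per_subunit_pct={
            su: 100.0 * k / n for su, (k, n) in per_subunit_counts.items()
        },
    )
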