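"""Synthetic fixtures with planted ground truth for every pipeline stage.

No structure models or raw images accompany the study this package
supports, so every stage is exercised on generated inputs whose correct
answer is known by construction:

* pairwise "predicted" structure models — bead-and-stick pseudo-protein
  chains (one or two heavy atoms per residue) with planted inter-chain
  contacts at exact distances and planted per-residue confidences;
* assembled complexes with known buried/exposed residues, burial being
  enforced by enclosing the residue's atom in a generated spherical
  shell of occluding atoms;
* FRAP traces following the single-exponential recovery model with
  configurable bleach depth, per-frame acquisition photobleaching and
  additive Gaussian noise;
* division-site images with rim (double-peak) versus disk (central)
  geometry.

Realism of the pseudo-protein geometry is irrelevant: only distances,
burial, confidence values and intensities matter to the pipeline.  All
generators are deterministic under a fixed seed, and each returns a
manifest sufficient to predict every downstream result without
re-deriving the geometry.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .complex_feasibility import ComplexModel
from .frap_analysis import FrapTrace, write_trace_tsv
from .intensity_profiles import IntensityImage
from .model_io import (
    Atom,
    Chain,
    Residue,
    StructureModel,
    write_structure,
)

__all__ = [
    "GenerationError",
    "StructureSpec",
    "ComplexSpec",
    "FrapSpec",
    "ImageSpec",
    "generate_pair_structures",
    "generate_pair_models",
    "generate_panel",
    "generate_complex",
    "generate_frap_trace",
    "generate_division_image",
    "generate_long_axis_pair",
    "SEPTINS",
    "EXOCYST",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
# complex chains use small/medium residue types only, so that a fully
# exposed single-atom pseudo-residue clears 0.5 relative accessibility
CPLX_AA = "ACDGINPSTV"
SEPTINS = ("Spn1", "Spn2", "Spn3", "Spn4")
EXOCYST = ("Sec3", "Sec5", "Sec6", "Sec8", "Sec10", "Sec15", "Exo70", "Exo84")

RES_SPACING = 5.0        # A between residue centers along a chain
CHAIN_GAP = 40.0         # A between non-contacting chains
FAR_OFFSET = 500.0       # A used to break an interface in one order
MIN_SEP = 2.0            # A minimum inter-atom separation everywhere
SHELL_RADIUS = 5.0       # A radius of the burial shell
SHELL_POINTS = 150


class GenerationError(ValueError):
    pass


def _random_sequence(rng: np.random.Generator, n: int, alphabet: str = AA20) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly spaced unit vectors."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - y * y)
    theta = phi * i
    return np.stack([r * np.cos(theta), y, r * np.sin(theta)], axis=1)


# ---------------------------------------------------------------------------
# Pairwise models with planted interfaces
# ---------------------------------------------------------------------------


@dataclass
class StructureSpec:
    """Recipe for one pairwise model in both input orders.

    ``planted_contacts`` are (ordinal_a, ordinal_b, distance) triples;
    each ordinal may appear once, and the planted distance becomes the
    exact minimum heavy-atom distance of that residue pair.  pLDDT
    values default to uniform in [55, 90] and can be overridden
    per-residue; ``interacting_orders`` names the orders ("AB", "BA")
    in which the interface is present — in a withheld order the second
    chain is pulled far away.
    """

    subunit_a: str = "SubA"
    subunit_b: str = "SubB"
    n_res_a: int = 30
    n_res_b: int = 30
    planted_contacts: Sequence[tuple[int, int, float]] = ()
    plddt_a: dict[int, float] = field(default_factory=dict)
    plddt_b: dict[int, float] = field(default_factory=dict)
    interacting_orders: tuple[str, ...] = ("AB", "BA")
    seed: int = 0

    def validate(self) -> None:
        a_seen: set[int] = set()
        b_seen: set[int] = set()
        for ia, ib, d in self.planted_contacts:
            if not (1 <= ia <= self.n_res_a and 1 <= ib <= self.n_res_b):
                raise GenerationError(f"planted contact ({ia},{ib}) out of range")
            if ia in a_seen or ib in b_seen:
                raise GenerationError(
                    "each residue may carry at most one planted contact "
                    "(geometry would clash otherwise)"
                )
            if d < MIN_SEP:
                raise GenerationError(
                    f"planted distance {d} violates the {MIN_SEP} A minimum "
                    "inter-atom separation"
                )
            a_seen.add(ia)
            b_seen.add(ib)
        for o in self.interacting_orders:
            if o not in ("AB", "BA"):
                raise GenerationError(f"unknown order {o!r}")


def _build_chain(
    chain_id: str,
    subunit: str,
    sequence: str,
    centers: np.ndarray,
    plddt: np.ndarray,
) -> Chain:
    residues = []
    for k, (aa, c) in enumerate(zip(sequence, centers), start=1):
        atoms = [
            Atom("C", "CA", float(c[0]), float(c[1]), float(c[2])),
            Atom("C", "CB", float(c[0]), float(c[1]), float(c[2] + 1.5)),
        ]
        residues.append(
            Residue(ordinal=k, author_number=k, aa=aa, atoms=atoms, plddt=float(plddt[k - 1]))
        )
    return Chain(chain_id=chain_id, subunit_name=subunit, residues=residues)


def generate_pair_structures(spec: StructureSpec) -> dict:
    """Build the AB- and BA-order models in memory plus the manifest.

    The manifest lists the exact expected contacts (ordinal_a,
    ordinal_b, min_distance) and the post-confidence-filter interface
    residues per side, given the default pLDDT threshold of 50.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seq_a = _random_sequence(rng, spec.n_res_a)
    seq_b = _random_sequence(rng, spec.n_res_b)
    # two decimals: the temperature-factor column's file precision
    plddt_a = np.round(rng.uniform(55.0, 90.0, spec.n_res_a), 2)
    plddt_b = np.round(rng.uniform(55.0, 90.0, spec.n_res_b), 2)
    for k, v in spec.plddt_a.items():
        plddt_a[k - 1] = v
    for k, v in spec.plddt_b.items():
        plddt_b[k - 1] = v

    centers_a = np.stack(
        [np.arange(spec.n_res_a) * RES_SPACING,
         np.zeros(spec.n_res_a), np.zeros(spec.n_res_a)], axis=1,
    )

    def b_centers(interacting: bool) -> np.ndarray:
        cb = np.stack(
            [np.arange(spec.n_res_b) * RES_SPACING,
             np.full(spec.n_res_b, CHAIN_GAP), np.zeros(spec.n_res_b)], axis=1,
        )
        if interacting:
            for ia, ib, d in spec.planted_contacts:
                cb[ib - 1] = [centers_a[ia - 1, 0], d, 0.0]
        else:
            cb[:, 1] += FAR_OFFSET
        return cb

    models = {}
    for order in ("AB", "BA"):
        interacting = order in spec.interacting_orders
        cb = b_centers(interacting)
        chain_a = _build_chain("A" if order == "AB" else "B", spec.subunit_a, seq_a, centers_a, plddt_a)
        chain_b = _build_chain("B" if order == "AB" else "A", spec.subunit_b, seq_b, cb, plddt_b)
        chains = [chain_a, chain_b] if order == "AB" else [chain_b, chain_a]
        m = StructureModel(
            model_id=f"{spec.subunit_a}_{spec.subunit_b}_{order.lower()}_rank_1_seed{spec.seed}",
            rank=1,
            chains=chains,
        )
        m.global_confidence = m.mean_plddt()
        m.validate()
        models[order] = m

    expected_contacts = sorted(
        [(ia, ib, float(d)) for ia, ib, d in spec.planted_contacts]
    )
    iface_a = sorted(ia for ia, _, _ in spec.planted_contacts if plddt_a[ia - 1] >= 50.0)
    iface_b = sorted(ib for _, ib, _ in spec.planted_contacts if plddt_b[ib - 1] >= 50.0)
    manifest = {
        "pair_label": [spec.subunit_a, spec.subunit_b],
        "seed": spec.seed,
        "sequences": {spec.subunit_a: seq_a, spec.subunit_b: seq_b},
        "expected_contacts": expected_contacts,
        "expected_interface_a": iface_a,
        "expected_interface_b": iface_b,
        "interacting_orders": list(spec.interacting_orders),
        "expected_consensus": set(spec.interacting_orders) == {"AB", "BA"}
        and bool(iface_a) and bool(iface_b),
    }
    return {"model_ab": models["AB"], "model_ba": models["BA"], "manifest": manifest}


def generate_pair_models(spec: StructureSpec, outdir: str | Path) -> dict:
    """Write both orders as PDB and mmCIF plus a JSON manifest; returns
    the file paths and the manifest.  Same seed, same bytes."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    built = generate_pair_structures(spec)
    paths = {}
    for order in ("ab", "ba"):
        model = built[f"model_{order}"]
        for ext in ("pdb", "cif"):
            p = outdir / f"{spec.subunit_a}_{spec.subunit_b}_{order}_rank_1.{ext}"
            write_structure(model, p)
            paths[f"{order}_{ext}"] = p
    manifest_path = outdir / f"{spec.subunit_a}_{spec.subunit_b}_manifest.json"
    manifest_path.write_text(json.dumps(built["manifest"], indent=2) + "\n")
    paths["manifest"] = manifest_path
    return {**paths, "manifest_data": built["manifest"]}


def generate_panel(
    seed: int = 0,
    n_interacting: int = 6,
    septins: Sequence[str] = SEPTINS,
    exocyst: Sequence[str] = EXOCYST,
    n_res: int = 30,
) -> dict:
    """A full all-against-all panel with a fixed number of planted
    bidirectional interfaces.

    All septin x exocyst combinations are generated (32 with the
    default subunit sets).  ``n_interacting`` pairs carry a consensus
    interface present in both input orders with confident residues; the
    remainder are negative by one of three mechanisms chosen in
    rotation: no contacts at all, contacts whose residues all fall
    below the confidence threshold, or an interface present in one
    input order only.
    """
    rng = np.random.default_rng(seed)
    all_pairs = [(s, e) for s in septins for e in exocyst]
    if n_interacting > len(all_pairs):
        raise GenerationError("more interacting pairs requested than pairs exist")
    idx = rng.permutation(len(all_pairs))
    positive = {all_pairs[i] for i in idx[:n_interacting]}

    panel = []
    manifest = {"seed": seed, "positive_pairs": sorted(positive), "pairs": []}
    neg_mode = 0
    for pi, (s, e) in enumerate(all_pairs):
        pair_seed = seed * 100003 + pi
        n_contacts = int(rng.integers(3, 9))
        ords_a = rng.choice(np.arange(1, n_res + 1), size=n_contacts, replace=False)
        ords_b = rng.choice(np.arange(1, n_res + 1), size=n_contacts, replace=False)
        dists = np.round(rng.uniform(2.5, 3.9, n_contacts), 2)
        contacts = [(int(a), int(b), float(d)) for a, b, d in zip(ords_a, ords_b, dists)]
        if (s, e) in positive:
            plddt_a = {int(a): float(np.round(rng.uniform(60, 95), 1)) for a, _, _ in contacts}
            plddt_b = {int(b): float(np.round(rng.uniform(60, 95), 1)) for _, b, _ in contacts}
            sp = StructureSpec(
                subunit_a=s, subunit_b=e, n_res_a=n_res, n_res_b=n_res,
                planted_contacts=contacts, plddt_a=plddt_a, plddt_b=plddt_b,
                interacting_orders=("AB", "BA"), seed=pair_seed,
            )
            mech = "bidirectional_interface"
        else:
            mech = ("no_contacts", "low_confidence", "single_order")[neg_mode % 3]
            neg_mode += 1
            if mech == "no_contacts":
                sp = StructureSpec(
                    subunit_a=s, subunit_b=e, n_res_a=n_res, n_res_b=n_res,
                    planted_contacts=(), seed=pair_seed,
                )
            elif mech == "low_confidence":
                plddt_a = {int(a): float(np.round(rng.uniform(10, 45), 1)) for a, _, _ in contacts}
                plddt_b = {int(b): float(np.round(rng.uniform(10, 45), 1)) for _, b, _ in contacts}
                sp = StructureSpec(
                    subunit_a=s, subunit_b=e, n_res_a=n_res, n_res_b=n_res,
                    planted_contacts=contacts, plddt_a=plddt_a, plddt_b=plddt_b,
                    seed=pair_seed,
                )
            else:
                plddt_a = {int(a): float(np.round(rng.uniform(60, 95), 1)) for a, _, _ in contacts}
                plddt_b = {int(b): float(np.round(rng.uniform(60, 95), 1)) for _, b, _ in contacts}
                sp = StructureSpec(
                    subunit_a=s, subunit_b=e, n_res_a=n_res, n_res_b=n_res,
                    planted_contacts=contacts, plddt_a=plddt_a, plddt_b=plddt_b,
                    interacting_orders=("AB",), seed=pair_seed,
                )
        built = generate_pair_structures(sp)
        panel.append(([built["model_ab"]], [built["model_ba"]]))
        manifest["pairs"].append(
            {
                "pair": [s, e],
                "mechanism": mech,
                "expected_consensus": built["manifest"]["expected_consensus"],
                "expected_interface_a": built["manifest"]["expected_interface_a"],
                "expected_interface_b": built["manifest"]["expected_interface_b"],
            }
        )
    return {"panel": panel, "manifest": manifest}


# ---------------------------------------------------------------------------
# Assembled complexes with planted burial
# ---------------------------------------------------------------------------


@dataclass
class ComplexSpec:
    """Recipe for an assembled complex with known burial.

    ``subunit_copies`` maps subunit name to copy count (two copies of
    each of four subunits gives an octamer).  ``buried`` lists
    (chain_id, ordinal) residues to enclose in an occluding atom shell;
    chain ids are assigned A, B, C, ... in subunit order, copies
    consecutive.  Every non-buried residue sits far from all other
    atoms and is fully exposed by construction.
    """

    subunit_copies: dict[str, int] = field(
        default_factory=lambda: {"Spn1": 2, "Spn2": 2, "Spn3": 2, "Spn4": 2}
    )
    residues_per_subunit: int = 10
    buried: Sequence[tuple[str, int]] = ()
    sequences: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def chain_layout(self) -> list[tuple[str, str]]:
        """(chain_id, subunit_name) in construction order."""
        letters = string.ascii_uppercase
        out = []
        i = 0
        for su, copies in self.subunit_copies.items():
            for _ in range(copies):
                if i >= len(letters):
                    raise GenerationError("too many chains for single-letter ids")
                out.append((letters[i], su))
                i += 1
        return out


def generate_complex(spec: ComplexSpec) -> dict:
    """Build a complex whose buried residues have relative accessibility
    < 0.05 and whose exposed residues score > 0.5, by construction.

    Each chain is a row of single-atom residues 12 A apart; chains are
    parallel rows 30 A apart.  Burial shells (Fibonacci sphere of
    occluding carbon atoms at 5 A radius) are appended as extra
    residues of the *next* chain in the layout, so deleting that
    neighbouring chain un-buries the residue — mirroring how removing a
    subunit from a complex exposes formerly occluded surface.
    """
    layout = spec.chain_layout()
    chain_ids = [cid for cid, _ in layout]
    for cid, k in spec.buried:
        if cid not in chain_ids:
            raise GenerationError(f"buried residue on unknown chain {cid!r}")
        if not (1 <= k <= spec.residues_per_subunit):
            raise GenerationError(f"buried ordinal {k} out of range")
    rng = np.random.default_rng(spec.seed)
    seqs = dict(spec.sequences)
    for su in spec.subunit_copies:
        seqs.setdefault(su, _random_sequence(rng, spec.residues_per_subunit, CPLX_AA))
        if len(seqs[su]) != spec.residues_per_subunit:
            raise GenerationError(f"sequence length mismatch for {su!r}")

    res_sp, row_gap = 12.0, 30.0
    chains: dict[str, Chain] = {}
    positions: dict[tuple[str, int], np.ndarray] = {}
    for ci, (cid, su) in enumerate(layout):
        residues = []
        for k in range(1, spec.residues_per_subunit + 1):
            pos = np.array([(k - 1) * res_sp, ci * row_gap, 0.0])
            positions[(cid, k)] = pos
            residues.append(
                Residue(
                    ordinal=k, author_number=k, aa=seqs[su][k - 1],
                    atoms=[Atom("C", "CA", *pos)],
                    plddt=90.0,
                )
            )
        chains[cid] = Chain(chain_id=cid, subunit_name=su, residues=residues)

    # burial shells on the next chain in the layout
    shell_dirs = _fibonacci_sphere(SHELL_POINTS)
    for cid, k in spec.buried:
        ci = chain_ids.index(cid)
        host = chain_ids[(ci + 1) % len(chain_ids)]
        center = positions[(cid, k)]
        pts = center + SHELL_RADIUS * shell_dirs
        host_chain = chains[host]
        next_ord = host_chain.residues[-1].ordinal + 1
        for group_start in range(0, SHELL_POINTS, 15):
            group = pts[group_start : group_start + 15]
            atoms = [
                Atom("C", f"S{j}", float(p[0]), float(p[1]), float(p[2]))
                for j, p in enumerate(group)
            ]
            host_chain.residues.append(
                Residue(
                    ordinal=next_ord, author_number=next_ord, aa="G",
                    atoms=atoms, plddt=90.0,
                )
            )
            next_ord += 1

    model = StructureModel(
        model_id=f"synthetic_complex_seed{spec.seed}",
        rank=1,
        chains=[chains[cid] for cid in chain_ids],
    )
    model.global_confidence = model.mean_plddt()
    model.validate()
    cm = ComplexModel(model=model, subunit_of_chain={cid: su for cid, su in layout})
    buried = sorted((cid, int(k)) for cid, k in spec.buried)
    exposed = sorted(
        (cid, k)
        for cid, su in layout
        for k in range(1, spec.residues_per_subunit + 1)
        if (cid, k) not in set(buried)
    )
    manifest = {
        "seed": spec.seed,
        "composition": cm.composition(),
        "sequences": seqs,
        "buried": buried,
        "exposed": exposed,
        "shell_host_of": {
            f"{cid}:{k}": chain_ids[(chain_ids.index(cid) + 1) % len(chain_ids)]
            for cid, k in buried
        },
    }
    return {"complex": cm, "manifest": manifest}


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


@dataclass
class FrapSpec:
    """Forward model for a FRAP trace.

    m1/m2/m3 parameterize the recovery on the normalized percent scale
    (m1 the plateau, m2 negative, m3 the off-rate in 1/s; the default
    m2 = -m1 starts recovery at 0%).  ``acquisition_decay`` is the
    fractional intensity loss per acquired frame applied to every
    channel; ``noise_sigma`` is additive Gaussian noise on the bleached
    channel as a fraction of the bleach dynamic range.  The bleach
    depth must satisfy the < 0.5 acceptance criterion.
    """

    m1: float = 80.0
    m2: float | None = None  # defaults to -m1
    m3: float = 0.1
    n_pre: int = 5
    n_post: int = 150
    interval: float = 0.33
    bleach_depth: float = 0.3
    acquisition_decay: float = 0.0
    noise_sigma: float = 0.0
    pre_level: float = 1000.0
    reference_level: float = 800.0
    background_level: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.bleach_depth < 0.5):
            raise GenerationError(
                f"bleach depth {self.bleach_depth} violates the < 0.5 criterion"
            )
        if self.m3 <= 0 or self.interval <= 0 or self.n_pre < 1 or self.n_post < 1:
            raise GenerationError("invalid FRAP spec")
        if not (0.0 <= self.acquisition_decay < 1.0):
            raise GenerationError("acquisition_decay must be in [0, 1)")


def generate_frap_trace(spec: FrapSpec, path: str | Path | None = None) -> dict:
    """Forward-simulate a FRAP acquisition; optionally write the TSV.

    The manifest carries the parameters the pipeline should recover
    AFTER its own normalization (identical to the planted m1/m2/m3 when
    m2 = -m1, the default; otherwise transformed so that the first
    post-bleach frame maps to 0%).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m2 = -spec.m1 if spec.m2 is None else spec.m2
    n0 = spec.m1 + m2  # planted curve's value at t=0 on the percent scale
    if n0 >= 100.0:
        raise GenerationError("recovery curve starts at or above the pre-bleach level")

    n = spec.n_pre + spec.n_post
    frames = np.arange(n)
    times = frames * spec.interval
    tau = (frames - spec.n_pre) * spec.interval  # post-bleach clock

    L = spec.pre_level
    d = spec.bleach_depth
    true = np.empty(n)
    true[: spec.n_pre] = L
    norm = spec.m1 + m2 * np.exp(-spec.m3 * tau[spec.n_pre:])
    # invert the 100%/0% normalization around depth d
    true[spec.n_pre:] = d * L + (norm - n0) / (100.0 - n0) * (L - d * L)

    decay = (1.0 - spec.acquisition_decay) ** frames
    noise_scale = spec.noise_sigma * (L - d * L)
    bleached = true * decay + spec.background_level
    if spec.noise_sigma > 0:
        bleached = bleached + rng.normal(0.0, noise_scale, n)
    reference = spec.reference_level * decay + spec.background_level
    background = np.full(n, spec.background_level)

    trace = FrapTrace(
        times=times, bleached=bleached, reference=reference,
        background=background, n_pre=spec.n_pre, interval=spec.interval,
    )
    manifest = {
        "m1_true": spec.m1,
        "m2_true": m2,
        "m3_true": spec.m3,
        "t_half_true": float(np.log(2) / spec.m3),
        "bleach_depth": d,
        "expected_fit": {
            "m1": (spec.m1 - n0) * 100.0 / (100.0 - n0),
            "m2": m2 * 100.0 / (100.0 - n0),
            "m3": spec.m3,
        },
        "seed": spec.seed,
    }
    if path is not None:
        write_trace_tsv(trace, path)
    return {"trace": trace, "manifest": manifest}


# ---------------------------------------------------------------------------
# Division-site images
# ---------------------------------------------------------------------------


@dataclass
class ImageSpec:
    """Recipe for a synthetic division-site image.

    ``geometry`` selects rim (two membrane-proximal peaks on the
    short-axis line, the double-ring localization), disk (signal spread
    across the whole division plane) or rim+center (rings plus a
    central pool).  The cell long axis is horizontal (columns); the
    division plane is the central column.
    """

    geometry: str = "rim"  # {rim, disk, rim+center}
    cell_diameter_um: float = 3.5
    pixel_size_um: float = 0.1
    amplitude: float = 500.0
    cytoplasm: float = 50.0
    noise_sigma: float = 0.0
    shape: tuple[int, int] = (60, 80)
    peak_sigma_px: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.geometry not in ("rim", "disk", "rim+center"):
            raise GenerationError(f"unknown geometry {self.geometry!r}")
        d_px = self.cell_diameter_um / self.pixel_size_um
        if d_px + 6 > self.shape[0]:
            raise GenerationError("planted peaks would fall outside the image")


def _gauss_spot(shape, row, col, sigma, amp) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-(((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2)))


def generate_division_image(spec: ImageSpec) -> dict:
    """One-channel division-site image plus ground truth.

    Truth records the division-plane column, the cell-center row, the
    planted peak rows (rim separation = cell diameter in pixels) and
    the planted signal sum above cytoplasm, so ROI correction and
    line-scan results are predictable exactly at zero noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    cy, cx = h // 2, w // 2
    d_px = spec.cell_diameter_um / spec.pixel_size_um
    half = int(round(d_px / 2))

    img = np.full((h, w), spec.cytoplasm, dtype=float)
    signal = np.zeros((h, w))
    peaks: list[tuple[int, int]] = []
    if spec.geometry in ("rim", "rim+center"):
        for row in (cy - half, cy + half):
            signal += _gauss_spot(spec.shape, row, cx, spec.peak_sigma_px, spec.amplitude)
            peaks.append((row, cx))
    if spec.geometry == "rim+center":
        signal += _gauss_spot(spec.shape, cy, cx, spec.peak_sigma_px, 0.6 * spec.amplitude)
        peaks.append((cy, cx))
    if spec.geometry == "disk":
        rr = np.arange(h)
        band = np.exp(-((np.arange(w) - cx) ** 2) / (2 * spec.peak_sigma_px**2))
        inside = ((rr >= cy - half) & (rr <= cy + half)).astype(float)
        signal += spec.amplitude * inside[:, None] * band[None, :]
        peaks.append((cy, cx))
    img += signal
    if spec.noise_sigma > 0:
        img = np.clip(img + rng.normal(0.0, spec.noise_sigma, img.shape), 0.0, None)

    image = IntensityImage(img, spec.pixel_size_um, projection="single-plane")
    truth = {
        "geometry": spec.geometry,
        "center_row": cy,
        "division_col": cx,
        "peak_rows": sorted(r for r, _ in peaks),
        "rim_separation_px": 2 * half if spec.geometry != "disk" else None,
        "signal_sum": float(signal.sum()),
        "cytoplasm": spec.cytoplasm,
        "seed": spec.seed,
    }
    return {"image": image, "truth": truth}


def generate_long_axis_pair(
    spec: ImageSpec,
    ring_half_sep_px: int = 5,
    shift_b_px: int = 0,
) -> dict:
    """Two-channel double-ring image for the long-axis colocalization
    profile: both channels show two vertical rings flanking the
    division plane; channel B can be shifted along the long axis."""
    spec.validate()
    h, w = spec.shape
    cy, cx = h // 2, w // 2
    half = int(round(spec.cell_diameter_um / spec.pixel_size_um / 2))

    def channel(shift: int) -> IntensityImage:
        img = np.full((h, w), spec.cytoplasm, dtype=float)
        rr = np.arange(h)
        inside = ((rr >= cy - half) & (rr <= cy + half)).astype(float)
        for col in (cx - ring_half_sep_px + shift, cx + ring_half_sep_px + shift):
            band = np.exp(-((np.arange(w) - col) ** 2) / (2 * spec.peak_sigma_px**2))
            img += spec.amplitude * inside[:, None] * band[None, :]
        return IntensityImage(img, spec.pixel_size_um)

    truth = {
        "center": (cy, cx),
        "peak_cols_a": [cx - ring_half_sep_px, cx + ring_half_sep_px],
        "peak_cols_b": [cx - ring_half_sep_px + shift_b_px, cx + ring_half_sep_px + shift_b_px],
        "shift_b_um": shift_b_px * spec.pixel_size_um,
    }
    return {"image_a": channel(0), "image_b": channel(shift_b_px), "truth": truth}
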