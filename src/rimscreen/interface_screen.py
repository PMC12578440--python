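"""Pairwise structure-based interaction screen.

The screen asks, for each candidate subunit pair, whether a predicted
complex model shows a credible binding interface.  Interface residues
are amino acids of the two partners whose heavy atoms come within the
contact cutoff (4 A by default, inclusive) in the best-ranked model;
residues with a per-residue confidence (pLDDT) below 50 are excluded.
Because prediction servers can give different answers depending on the
order the two sequences are supplied, each pair is predicted in both
input orders and only pairs interacting in BOTH orders are called
positive (the bidirectional consensus).

Positive calls are ranked by total union-interface size, tie-broken by
the mean pLDDT of the union-interface residues and then by pair label;
the ranking rule is recorded in every report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model_io import Chain, ResidueRef, StructureModel

__all__ = [
    "ScreenParams",
    "ContactPair",
    "InterfaceResult",
    "ConsensusCall",
    "ScreenError",
    "compute_contacts",
    "filter_by_confidence",
    "select_rank1",
    "screen_pair",
    "screen_panel",
    "merge_fragment_interfaces",
]


class ScreenError(ValueError):
    pass


@dataclass
class ScreenParams:
    """Tunable thresholds of the screen.

    contact_cutoff : heavy-atom distance defining a contact, in A.
    cutoff_inclusive : whether a pair exactly at the cutoff counts.
    plddt_min : minimum per-residue confidence; residues strictly below
        are excluded from the interface.
    n_models_expected : number of models the prediction run sampled
        (recorded as run metadata only).
    min_interface_residues_per_chain : surviving residues required on
        EACH chain for a single-order prediction to count as interacting.
    """

    contact_cutoff: float = 4.0
    cutoff_inclusive: bool = True
    plddt_min: float = 50.0
    n_models_expected: int = 5
    min_interface_residues_per_chain: int = 1

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ScreenError("contact_cutoff must be > 0")
        if not (0.0 <= self.plddt_min <= 100.0):
            raise ScreenError("plddt_min must be in [0, 100]")


@dataclass(frozen=True)
class ContactPair:
    res_a: ResidueRef
    res_b: ResidueRef
    min_distance: float

    def to_dict(self) -> dict:
        return {
            "res_a": self.res_a.to_dict(),
            "res_b": self.res_b.to_dict(),
            "min_distance": round(self.min_distance, 4),
        }


@dataclass
class InterfaceResult:
    """Filtered inter-chain interface of one ordered pairwise prediction."""

    pair_label: tuple[str, str]
    input_order: str  # "AB" or "BA"
    model_rank_used: int
    contacts_raw: list[ContactPair]
    interface_a: frozenset[ResidueRef]
    interface_b: frozenset[ResidueRef]
    is_interacting: bool

    def to_dict(self) -> dict:
        return {
            "pair_label": list(self.pair_label),
            "input_order": self.input_order,
            "model_rank_used": self.model_rank_used,
            "n_contacts_raw": len(self.contacts_raw),
            "contacts_raw": [c.to_dict() for c in self.contacts_raw],
            "interface_a": [r.to_dict() for r in sorted(self.interface_a)],
            "interface_b": [r.to_dict() for r in sorted(self.interface_b)],
            "is_interacting": self.is_interacting,
        }


@dataclass
class ConsensusCall:
    """Interaction decision for one subunit pair from its two input orders."""

    pair_label: tuple[str, str]
    result_ab: InterfaceResult
    result_ba: InterfaceResult
    consensus_interacting: bool
    union_interface: dict[str, frozenset[tuple[int, str]]]
    ranking_score: float = 0.0
    mean_interface_plddt: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "pair_label": list(self.pair_label),
            "consensus_interacting": self.consensus_interacting,
            "ranking_metric": "union_interface_size,mean_interface_plddt",
            "ranking_score": self.ranking_score,
            "mean_interface_plddt": None
            if math.isnan(self.mean_interface_plddt)
            else round(self.mean_interface_plddt, 3),
            "union_interface": {
                su: sorted([list(t) for t in refs])
                for su, refs in self.union_interface.items()
            },
            "result_ab": self.result_ab.to_dict(),
            "result_ba": self.result_ba.to_dict(),
        }


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------


def _chain_atoms(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """All heavy-atom coordinates of a chain plus per-atom residue index."""
    coords = []
    res_idx = []
    for i, res in enumerate(chain.residues):
        for atom in res.atoms:
            coords.append(atom.xyz)
            res_idx.append(i)
    return np.asarray(coords, dtype=float), np.asarray(res_idx, dtype=int)


def compute_contacts(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff: float = 4.0,
    inclusive: bool = True,
) -> list[ContactPair]:
    """All residue pairs across two chains within the contact cutoff.

    A pair is reported when the minimum heavy-atom Euclidean distance
    between the two residues is <= cutoff (or < cutoff when
    ``inclusive`` is False), together with that minimum distance.
    Output is sorted by (ordinal_a, ordinal_b).
    """
    if chain_a == chain_b:
        raise ScreenError("chain_a and chain_b must differ")
    ca = model.chain(chain_a)
    cb = model.chain(chain_b)
    xa, ia = _chain_atoms(ca)
    xb, ib = _chain_atoms(cb)

    # KD-tree candidate search with a small margin, then exact filtering,
    # so the boundary comparison is done on true distances.
    tree_a = cKDTree(xa)
    tree_b = cKDTree(xb)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff * (1 + 1e-9) + 1e-9)

    best: dict[tuple[int, int], float] = {}
    for ai, blist in enumerate(pairs):
        if not blist:
            continue
        d = np.sqrt(np.sum((xb[blist] - xa[ai]) ** 2, axis=1))
        for bj, dist in zip(blist, d):
            key = (ia[ai], ib[bj])
            if key not in best or dist < best[key]:
                best[key] = float(dist)

    out: list[ContactPair] = []
    for (ri, rj), dist in best.items():
        if (dist <= cutoff) if inclusive else (dist < cutoff):
            ra = ca.residues[ri]
            rb = cb.residues[rj]
            out.append(
                ContactPair(
                    ResidueRef(chain_a, ra.ordinal, ra.aa),
                    ResidueRef(chain_b, rb.ordinal, rb.aa),
                    dist,
                )
            )
    out.sort(key=lambda c: (c.res_a.ordinal, c.res_b.ordinal))
    return out


def filter_by_confidence(
    model: StructureModel,
    contacts: Sequence[ContactPair],
    plddt_min: float = 50.0,
) -> tuple[frozenset[ResidueRef], frozenset[ResidueRef]]:
    """Interface residue sets after the confidence filter.

    A residue enters its interface set iff it participates in at least
    one contact AND its pLDDT >= plddt_min (the exclusion criterion is
    strictly below the threshold, so a residue at exactly the threshold
    is retained).  A contact whose two residues straddle the threshold
    contributes only the passing residue.
    """
    side_a: set[ResidueRef] = set()
    side_b: set[ResidueRef] = set()
    for c in contacts:
        if model.residue(c.res_a).plddt >= plddt_min:
            side_a.add(c.res_a)
        if model.residue(c.res_b).plddt >= plddt_min:
            side_b.add(c.res_b)
    return frozenset(side_a), frozenset(side_b)


def select_rank1(models: Sequence[StructureModel]) -> StructureModel:
    """The best model: rank 1 if ranks are present, else highest mean
    confidence; ties broken by first occurrence."""
    if not models:
        raise ScreenError("no models supplied")
    ranked = [m for m in models if m.rank is not None]
    if ranked and len({m.rank for m in models}) > 1:
        return min(models, key=lambda m: m.rank)
    best = models[0]
    for m in models[1:]:
        conf = m.global_confidence if m.global_confidence is not None else m.mean_plddt()
        best_conf = (
            best.global_confidence if best.global_confidence is not None else best.mean_plddt()
        )
        if conf > best_conf:
            best = m
    return best


# ---------------------------------------------------------------------------
# Pair screening with bidirectional consensus
# ---------------------------------------------------------------------------


def _order_interface(
    models: Sequence[StructureModel],
    order: str,
    params: ScreenParams,
) -> InterfaceResult:
    model = select_rank1(models)
    if len(model.chains) < 2:
        raise ScreenError(
            f"model {model.model_id!r} has {len(model.chains)} chain(s); "
            "a pairwise prediction needs two"
        )
    first, second = model.chains[0], model.chains[1]
    contacts = compute_contacts(
        model, first.chain_id, second.chain_id,
        cutoff=params.contact_cutoff, inclusive=params.cutoff_inclusive,
    )
    iface_first, iface_second = filter_by_confidence(model, contacts, params.plddt_min)
    n = params.min_interface_residues_per_chain
    interacting = len(iface_first) >= n and len(iface_second) >= n
    if order == "AB":
        label = (first.subunit_name, second.subunit_name)
        ia, ib = iface_first, iface_second
    else:
        # in the BA file the first chain is subunit B
        label = (second.subunit_name, first.subunit_name)
        ia, ib = iface_second, iface_first
    return InterfaceResult(
        pair_label=label,
        input_order=order,
        model_rank_used=model.rank,
        contacts_raw=contacts,
        interface_a=ia,
        interface_b=ib,
        is_interacting=interacting,
    )


def screen_pair(
    models_ab: Sequence[StructureModel],
    models_ba: Sequence[StructureModel],
    params: ScreenParams | None = None,
) -> ConsensusCall:
    """Screen one subunit pair using both input orders.

    Input order can change the prediction, so a single order is never
    accepted: the call is positive only when both orders individually
    show an interface (logical AND).  The union interface pools the
    surviving residues of both orders per subunit.
    """
    params = params or ScreenParams()
    if not models_ab or not models_ba:
        raise ScreenError(
            "both input orders are required; the screen is never run on "
            "one order only"
        )
    res_ab = _order_interface(models_ab, "AB", params)
    res_ba = _order_interface(models_ba, "BA", params)
    if res_ab.pair_label != res_ba.pair_label:
        raise ScreenError(
            f"subunit labels disagree between orders: "
            f"{res_ab.pair_label} vs {res_ba.pair_label}"
        )
    sub_a, sub_b = res_ab.pair_label

    union: dict[str, frozenset[tuple[int, str]]] = {}
    plddts: list[float] = []
    model_ab = select_rank1(models_ab)
    model_ba = select_rank1(models_ba)
    for subunit, side in ((sub_a, "a"), (sub_b, "b")):
        merged: set[tuple[int, str]] = set()
        for res, model in ((res_ab, model_ab), (res_ba, model_ba)):
            refs = res.interface_a if side == "a" else res.interface_b
            for ref in refs:
                merged.add((ref.ordinal, ref.aa))
                plddts.append(model.residue(ref).plddt)
        union[subunit] = frozenset(merged)

    consensus = res_ab.is_interacting and res_ba.is_interacting
    size = sum(len(v) for v in union.values())
    return ConsensusCall(
        pair_label=(sub_a, sub_b),
        result_ab=res_ab,
        result_ba=res_ba,
        consensus_interacting=consensus,
        union_interface=union,
        ranking_score=float(size),
        mean_interface_plddt=(sum(plddts) / len(plddts)) if plddts else float("nan"),
    )


def screen_panel(
    panel: Sequence[tuple[Sequence[StructureModel], Sequence[StructureModel]]],
    params: ScreenParams | None = None,
) -> list[ConsensusCall]:
    """Screen a panel of subunit pairs and rank the positives.

    ``panel`` is a sequence of (models_ab, models_ba) entries, one per
    unordered subunit pair.  Consensus-positive calls come first, sorted
    by union-interface size (descending), then mean interface pLDDT
    (descending), then pair label; negatives follow sorted by label.
    Deterministic for fixed input.
    """
    params = params or ScreenParams()
    calls = [screen_pair(ab, ba, params) for ab, ba in panel]
    seen: set[frozenset[str]] = set()
    for c in calls:
        key = frozenset(c.pair_label)
        if key in seen:
            raise ScreenError(f"duplicate pair in panel: {sorted(key)}")
        seen.add(key)
    positives = [c for c in calls if c.consensus_interacting]
    negatives = [c for c in calls if not c.consensus_interacting]
    positives.sort(
        key=lambda c: (
            -c.ranking_score,
            -(0.0 if math.isnan(c.mean_interface_plddt) else c.mean_interface_plddt),
            c.pair_label,
        )
    )
    negatives.sort(key=lambda c: c.pair_label)
    return positives + negatives


def merge_fragment_interfaces(
    fragments: Sequence[tuple[int, Iterable[tuple[int, str]]]],
) -> frozenset[tuple[int, str]]:
    """Merge interfaces from overlapping fragments of one subunit.

    Large subunits that exceed a prediction server's input length are
    screened in overlapping fragments.  Each fragment's interface
    residues (fragment-local ordinals) are mapped to full-length
    positions via the fragment's declared offset (full-length ordinal of
    fragment position 1, minus one), and residues falling in an overlap
    are deduplicated by full-length position.
    """
    merged: dict[int, str] = {}
    for offset, residues in fragments:
        for ordinal, aa in residues:
            full = ordinal + offset
            prev = merged.get(full)
            if prev is not None and prev != aa:
                raise ScreenError(
                    f"fragment overlap disagrees at full-length position "
                    f"{full}: {prev!r} vs {aa!r} (check offsets)"
                )
            merged[full] = aa
    return frozenset(merged.items())
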