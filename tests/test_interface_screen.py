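"""Contact detection, confidence filtering and consensus logic."""

import itertools

import numpy as np
import pytest

from rimscreen.interface_screen import (
    ConsensusCall,
    ScreenError,
    ScreenParams,
    compute_contacts,
    filter_by_confidence,
    merge_fragment_interfaces,
    screen_pair,
    screen_panel,
    select_rank1,
)
from rimscreen.model_io import Atom, Chain, Residue, StructureModel
from rimscreen.synthetic_data import StructureSpec, generate_pair_structures


def brute_force_contacts(model, chain_a, chain_b, cutoff, inclusive=True):
    """Independent O(n^2) oracle: all-atom-pairs distance scan."""
    out = {}
    ca, cb = model.chain(chain_a), model.chain(chain_b)
    for ra in ca.residues:
        for rb in cb.residues:
            dmin = min(
                float(np.linalg.norm(np.subtract(a.xyz, b.xyz)))
                for a in ra.atoms
                for b in rb.atoms
            )
            ok = dmin <= cutoff if inclusive else dmin < cutoff
            if ok:
                out[(ra.ordinal, rb.ordinal)] = dmin
    return out


def _single_residue_pair(distance):
    def chain(cid, subunit, x):
        r = Residue(1, 1, "G", [Atom("C", "CA", x, 0.0, 0.0)], 90.0)
        return Chain(cid, subunit, [r])

    return StructureModel("m", 1, [chain("A", "a", 0.0), chain("B", "b", distance)])


def test_boundary_at_exactly_4A_is_inclusive():
    """A pair at exactly the 4.0 A cutoff is a contact (<= criterion)."""
    model = _single_residue_pair(4.0)
    contacts = compute_contacts(model, "A", "B", 4.0)
    assert len(contacts) == 1
    assert contacts[0].min_distance == pytest.approx(4.0)


def test_strict_comparator_excludes_the_boundary():
    model = _single_residue_pair(4.0)
    assert compute_contacts(model, "A", "B", 4.0, inclusive=False) == []
    assert compute_contacts(model, "A", "B", 4.001, inclusive=False)


def test_distant_chains_have_no_contacts():
    model = _single_residue_pair(150.0)
    assert compute_contacts(model, "A", "B", 4.0) == []


def test_same_chain_rejected(simple_pair):
    with pytest.raises(ScreenError):
        compute_contacts(simple_pair["model_ab"], "A", "A", 4.0)


def test_planted_contacts_match_manifest(simple_pair):
    model = simple_pair["model_ab"]
    contacts = compute_contacts(model, "A", "B", 4.0)
    got = sorted((c.res_a.ordinal, c.res_b.ordinal, round(c.min_distance, 3)) for c in contacts)
    assert got == simple_pair["manifest"]["expected_contacts"]


@pytest.mark.parametrize("seed", range(15))
def test_contacts_equal_brute_force_oracle(seed):
    """KD-tree contact search set-equals the all-atom-pairs scan on
    random planted structures."""
    rng = np.random.default_rng(seed)
    na, nb = int(rng.integers(20, 81)), int(rng.integers(20, 81))
    k = int(rng.integers(0, 6))
    ords_a = rng.choice(np.arange(1, na + 1), size=k, replace=False)
    ords_b = rng.choice(np.arange(1, nb + 1), size=k, replace=False)
    dists = np.round(rng.uniform(2.2, 4.0), 2)
    contacts = [
        (int(a), int(b), float(np.round(rng.uniform(2.2, 4.0), 2)))
        for a, b in zip(ords_a, ords_b)
    ]
    built = generate_pair_structures(
        StructureSpec(n_res_a=na, n_res_b=nb, planted_contacts=contacts, seed=seed)
    )
    model = built["model_ab"]
    fast = {
        (c.res_a.ordinal, c.res_b.ordinal): c.min_distance
        for c in compute_contacts(model, "A", "B", 4.0)
    }
    oracle = brute_force_contacts(model, "A", "B", 4.0)
    assert fast.keys() == oracle.keys()
    for key in fast:
        assert fast[key] == pytest.approx(oracle[key], abs=1e-9)


def test_contacts_symmetric_under_chain_swap(simple_pair):
    model = simple_pair["model_ab"]
    ab = {(c.res_a.ordinal, c.res_b.ordinal) for c in compute_contacts(model, "A", "B", 4.0)}
    ba = {(c.res_b.ordinal, c.res_a.ordinal) for c in compute_contacts(model, "B", "A", 4.0)}
    assert ab == ba


def test_cutoff_monotonicity(simple_pair):
    """Enlarging the cutoff never removes a contact."""
    model = simple_pair["model_ab"]
    prev = set()
    for cutoff in (2.5, 3.5, 4.0, 5.0, 8.0):
        cur = {(c.res_a.ordinal, c.res_b.ordinal) for c in compute_contacts(model, "A", "B", cutoff)}
        assert prev <= cur
        prev = cur


def test_plddt_threshold_is_strictly_below():
    """pLDDT 49.999 is excluded; exactly 50.0 is retained."""
    built = generate_pair_structures(
        StructureSpec(
            n_res_a=2, n_res_b=2,
            planted_contacts=[(1, 1, 3.0), (2, 2, 3.0)],
            plddt_a={1: 49.999, 2: 50.0},
            plddt_b={1: 80.0, 2: 80.0},
            seed=0,
        )
    )
    model = built["model_ab"]
    contacts = compute_contacts(model, "A", "B", 4.0)
    iface_a, iface_b = filter_by_confidence(model, contacts, 50.0)
    assert sorted(r.ordinal for r in iface_a) == [2]
    assert sorted(r.ordinal for r in iface_b) == [1, 2]


def test_filter_is_identity_when_all_confident(simple_pair):
    model = simple_pair["model_ab"]
    contacts = compute_contacts(model, "A", "B", 4.0)
    iface_a, iface_b = filter_by_confidence(model, contacts, 0.0)
    assert {r.ordinal for r in iface_a} == {c.res_a.ordinal for c in contacts}
    assert {r.ordinal for r in iface_b} == {c.res_b.ordinal for c in contacts}


def test_raising_plddt_min_never_adds_residues(simple_pair):
    model = simple_pair["model_ab"]
    contacts = compute_contacts(model, "A", "B", 4.0)
    prev_a = prev_b = None
    for thr in (0.0, 30.0, 50.0, 71.0, 100.0):
        a, b = filter_by_confidence(model, contacts, thr)
        if prev_a is not None:
            assert a <= prev_a and b <= prev_b
        prev_a, prev_b = a, b


def _model_with_rank(rank, conf):
    r = Residue(1, 1, "G", [Atom("C", "CA", 0, 0, 0)], conf)
    m = StructureModel(f"m{rank}", rank, [Chain("A", "a", [r])])
    m.global_confidence = conf
    return m


def test_select_rank1_prefers_rank():
    models = [_model_with_rank(r, 50.0 + r) for r in (3, 1, 5, 2, 4)]
    assert select_rank1(models).rank == 1


def test_select_rank1_singleton_and_unranked():
    one = _model_with_rank(2, 60.0)
    assert select_rank1([one]) is one
    a, b = _model_with_rank(1, 81.6), _model_with_rank(1, 60.0)
    assert select_rank1([b, a]) is a  # equal ranks: falls back to confidence
    with pytest.raises(ScreenError):
        select_rank1([])


@pytest.mark.parametrize(
    "orders, expected",
    [
        (("AB", "BA"), True),
        (("AB",), False),
        (("BA",), False),
        ((), False),
    ],
)
def test_consensus_truth_table(orders, expected):
    """Consensus is the AND of the two orders' interaction flags —
    all four combinations."""
    built = generate_pair_structures(
        StructureSpec(
            planted_contacts=[(3, 5, 3.2)],
            plddt_a={3: 80.0}, plddt_b={5: 80.0},
            interacting_orders=tuple(orders), seed=1,
        )
    )
    call = screen_pair([built["model_ab"]], [built["model_ba"]])
    assert call.result_ab.is_interacting == ("AB" in orders)
    assert call.result_ba.is_interacting == ("BA" in orders)
    assert call.consensus_interacting is expected
    assert call.consensus_interacting == (
        call.result_ab.is_interacting and call.result_ba.is_interacting
    )


def test_single_order_input_is_an_error(simple_pair):
    with pytest.raises(ScreenError):
        screen_pair([simple_pair["model_ab"]], [])
    with pytest.raises(ScreenError):
        screen_pair([], [simple_pair["model_ba"]])


def test_mismatched_subunit_labels_rejected(simple_pair):
    other = generate_pair_structures(
        StructureSpec(subunit_a="Spn1", subunit_b="Sec3", seed=2)
    )
    with pytest.raises(ScreenError):
        screen_pair([simple_pair["model_ab"]], [other["model_ba"]])


def test_union_interface_pools_both_orders(simple_pair):
    call = screen_pair([simple_pair["model_ab"]], [simple_pair["model_ba"]])
    # planted: residue 3 (70) passes, residue 10 (30) filtered on side A
    assert {o for o, _ in call.union_interface["Spn2"]} == {3}
    assert {o for o, _ in call.union_interface["Sec15"]} == {5, 12}


def test_empty_panel():
    assert screen_panel([]) == []


def test_duplicate_pair_in_panel_rejected(simple_pair):
    entry = ([simple_pair["model_ab"]], [simple_pair["model_ba"]])
    with pytest.raises(ScreenError):
        screen_panel([entry, entry])


def test_panel_ranking_is_deterministic_and_positive_first():
    specs = [
        StructureSpec(subunit_a="Spn1", subunit_b="Sec3",
                      planted_contacts=[(i, i, 3.0) for i in range(1, 6)],
                      plddt_a={i: 80.0 for i in range(1, 6)},
                      plddt_b={i: 80.0 for i in range(1, 6)}, seed=3),
        StructureSpec(subunit_a="Spn1", subunit_b="Sec5",
                      planted_contacts=[(1, 1, 3.0)],
                      plddt_a={1: 80.0}, plddt_b={1: 80.0}, seed=4),
        StructureSpec(subunit_a="Spn1", subunit_b="Sec6", seed=5),
    ]
    panel = []
    for sp in specs:
        built = generate_pair_structures(sp)
        panel.append(([built["model_ab"]], [built["model_ba"]]))
    calls = screen_panel(panel)
    labels = [c.pair_label for c in calls]
    # larger union interface ranks first; negative pair last
    assert labels == [("Spn1", "Sec3"), ("Spn1", "Sec5"), ("Spn1", "Sec6")]
    assert [c.consensus_interacting for c in calls] == [True, True, False]
    assert screen_panel(panel)[0].to_dict() == calls[0].to_dict()


def test_fragment_merge_maps_and_deduplicates():
    """Two overlapping fragments of one subunit merge into full-length
    coordinates with overlap residues counted once."""
    frag1 = (0, [(5, "A"), (50, "K")])     # covers 1..60 of the full chain
    frag2 = (40, [(10, "K"), (20, "M")])   # covers 41..100; 10+40 == 50
    merged = merge_fragment_interfaces([frag1, frag2])
    assert merged == frozenset({(5, "A"), (50, "K"), (60, "M")})


def test_fragment_overlap_disagreement_is_an_error():
    with pytest.raises(ScreenError):
        merge_fragment_interfaces([(0, [(50, "K")]), (40, [(10, "R")])])
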