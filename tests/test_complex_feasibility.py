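"""Interface mapping onto complexes and surface-accessibility calls."""

import numpy as np
import pytest

from rimscreen.complex_feasibility import (
    ComplexModel,
    MappingError,
    ResidueMapping,
    feasibility,
    map_to_complex,
    relative_accessibility,
    residue_accessibilities,
)
from rimscreen.model_io import Atom, Chain, Residue, ResidueRef, StructureModel
from rimscreen.synthetic_data import ComplexSpec, generate_complex


def _mapping(cm, pairs):
    """Direct 1:1 mappings onto listed (chain, ordinal) residues."""
    return [
        ResidueMapping(
            ResidueRef("src", i + 1, "G"),
            [ResidueRef(c, k, cm.model.chain(c).residues[k - 1].aa)],
            True,
        )
        for i, (c, k) in enumerate(pairs)
    ]


def _delete_chain(cm: ComplexModel, chain_id: str) -> ComplexModel:
    model = StructureModel(
        model_id=cm.model.model_id + f"_minus_{chain_id}",
        rank=cm.model.rank,
        chains=[c for c in cm.model.chains if c.chain_id != chain_id],
    )
    sub = {k: v for k, v in cm.subunit_of_chain.items() if k != chain_id}
    return ComplexModel(model=model, subunit_of_chain=sub)


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------


def test_identical_sequences_give_identity_mapping(octamer):
    cm = octamer["complex"]
    seq = octamer["manifest"]["sequences"]["Spn1"]
    refs = [ResidueRef("src", i, seq[i - 1]) for i in (1, 4, 9)]
    mappings = map_to_complex(refs, seq, cm, "Spn1")
    for m in mappings:
        assert m.aligned
        assert len(m.targets) == 2  # two copies in the octamer
        assert all(t.ordinal == m.source.ordinal for t in m.targets)


def test_trimmed_complex_chain_offsets_the_mapping():
    """Removing the first 20 source residues from the complex chain maps
    source ordinal 25 to target ordinal 5."""
    rng = np.random.default_rng(0)
    src = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
    trimmed = src[20:]
    residues = [
        Residue(k, k, aa, [Atom("C", "CA", 12.0 * k, 0, 0)], 90.0)
        for k, aa in enumerate(trimmed, start=1)
    ]
    model = StructureModel("trim", 1, [Chain("A", "SubX", residues)])
    cm = ComplexModel(model=model, subunit_of_chain={"A": "SubX"})
    mapping = map_to_complex([ResidueRef("src", 25, src[24])], src, cm, "SubX")
    assert mapping[0].aligned
    assert mapping[0].targets[0].ordinal == 5
    # a residue inside the trimmed-away region stays unmapped, not dropped
    missing = map_to_complex([ResidueRef("src", 10, src[9])], src, cm, "SubX")
    assert not missing[0].aligned and missing[0].targets == []


def test_low_identity_raises_unless_cross_species(octamer):
    cm = octamer["complex"]
    seq = octamer["manifest"]["sequences"]["Spn2"]
    rng = np.random.default_rng(1)
    mutated = "".join(
        c if rng.random() > 0.4 else rng.choice(list("ACDGINPSTV")) for c in seq
    )
    refs = [ResidueRef("src", 1, mutated[0])]
    with pytest.raises(MappingError):
        map_to_complex(refs, mutated, cm, "Spn2")
    with pytest.warns(UserWarning):
        map_to_complex(refs, mutated, cm, "Spn2", cross_species=True)


def test_unknown_subunit_is_a_lookup_error(octamer):
    with pytest.raises(KeyError):
        map_to_complex([], "AAAA", octamer["complex"], "Sec99")


# ---------------------------------------------------------------------------
# Accessibility
# ---------------------------------------------------------------------------


def test_isolated_residue_is_fully_accessible():
    """A single glycine far from every other chain scores >= 0.95."""
    far = Residue(1, 1, "G", [Atom("C", "CA", 500.0, 500.0, 500.0)], 90.0)
    other = Residue(1, 1, "G", [Atom("C", "CA", 0.0, 0.0, 0.0)], 90.0)
    model = StructureModel(
        "iso", 1, [Chain("A", "a", [far]), Chain("B", "b", [other])]
    )
    cm = ComplexModel(model=model, subunit_of_chain={"A": "a", "B": "b"})
    assert relative_accessibility(cm, ResidueRef("A", 1, "G")) >= 0.95


def test_shell_buried_residue_scores_zero(octamer):
    cm = octamer["complex"]
    acc = residue_accessibilities(cm)
    for chain_id, ordinal in octamer["manifest"]["buried"]:
        assert acc[(chain_id, ordinal)] == pytest.approx(0.0, abs=1e-9)


def test_exposed_residues_score_above_half(octamer):
    acc = residue_accessibilities(octamer["complex"])
    for chain_id, ordinal in octamer["manifest"]["exposed"]:
        assert acc[(chain_id, ordinal)] > 0.5


def test_point_count_convergence(octamer):
    """Doubling the sphere-point count moves no residue score by >= 0.02."""
    cm = octamer["complex"]
    a = residue_accessibilities(cm, point_number=960)
    b = residue_accessibilities(cm, point_number=1920)
    for key in a:
        assert abs(a[key] - b[key]) < 0.02


@pytest.mark.parametrize("seed", range(6))
def test_accessibility_monotone_under_chain_deletion(seed):
    """Removing any chain never decreases any remaining residue's
    relative accessibility."""
    rng = np.random.default_rng(seed)
    spec = ComplexSpec(
        subunit_copies={"S1": 2, "S2": 2},
        residues_per_subunit=6,
        buried=[("A", int(rng.integers(1, 7))), ("C", int(rng.integers(1, 7)))],
        seed=seed,
    )
    cm = generate_complex(spec)["complex"]
    full = residue_accessibilities(cm)
    drop = rng.choice([c.chain_id for c in cm.model.chains])
    reduced = residue_accessibilities(_delete_chain(cm, drop))
    for key, val in reduced.items():
        assert val >= full[key] - 1e-12


def test_hexamer_from_octamer_exposes_formerly_buried(octamer):
    """Deleting the shell-carrying neighbour un-buries the residue it
    occluded: accessibility can only rise when a subunit is removed."""
    cm = octamer["complex"]
    buried = octamer["manifest"]["buried"][0]
    host = octamer["manifest"]["shell_host_of"][f"{buried[0]}:{buried[1]}"]
    hexa = _delete_chain(_delete_chain(cm, host), host)  # idempotent guard
    acc = residue_accessibilities(hexa)
    assert acc[tuple(buried)] > 0.5


def test_rotation_invariance(octamer):
    """pct_accessible is invariant under rigid rotation+translation to
    sampling tolerance (0.5 percentage points)."""
    cm = octamer["complex"]
    pairs = octamer["manifest"]["exposed"][:21] + octamer["manifest"]["buried"]
    report = feasibility(cm, {"all": _mapping(cm, pairs)})

    theta = 0.7
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    ) @ np.array([[1, 0, 0], [0, np.cos(0.4), -np.sin(0.4)], [0, np.sin(0.4), np.cos(0.4)]])
    chains = []
    for c in cm.model.chains:
        residues = []
        for r in c.residues:
            atoms = [
                Atom(a.element, a.name, *(rot @ np.array(a.xyz) + [7.0, -3.0, 11.0]))
                for a in r.atoms
            ]
            residues.append(Residue(r.ordinal, r.author_number, r.aa, atoms, r.plddt))
        chains.append(Chain(c.chain_id, c.subunit_name, residues))
    rotated = ComplexModel(
        model=StructureModel("rot", 1, chains),
        subunit_of_chain=dict(cm.subunit_of_chain),
    )
    report_rot = feasibility(rotated, {"all": _mapping(rotated, pairs)})
    assert report_rot.pct_accessible == pytest.approx(report.pct_accessible, abs=0.5)


# ---------------------------------------------------------------------------
# Feasibility report
# ---------------------------------------------------------------------------


def test_planted_21_of_25_gives_84_percent(octamer):
    """21 exposed + 4 buried interface residues -> 84.0% accessible."""
    cm = octamer["complex"]
    pairs = octamer["manifest"]["exposed"][:21] + octamer["manifest"]["buried"]
    report = feasibility(cm, {"iface": _mapping(cm, pairs)})
    assert report.pct_accessible == pytest.approx(84.0)
    assert len(report.per_residue) == 25


def test_all_exposed_gives_100_percent(octamer):
    cm = octamer["complex"]
    report = feasibility(cm, {"iface": _mapping(cm, octamer["manifest"]["exposed"][:10])})
    assert report.pct_accessible == pytest.approx(100.0)


def test_multi_copy_residue_feasible_if_any_copy_accessible(octamer):
    """A residue buried on one copy but exposed on the other counts as
    accessible (max over copies)."""
    cm = octamer["complex"]
    buried_chain, buried_ord = octamer["manifest"]["buried"][0]
    # the sister copy of the same subunit, same ordinal, is exposed
    subunit = cm.subunit_of_chain[buried_chain]
    sister = [c for c in cm.chains_of_subunit(subunit) if c != buried_chain][0]
    m = ResidueMapping(
        ResidueRef("src", buried_ord, "G"),
        [
            ResidueRef(buried_chain, buried_ord, "G"),
            ResidueRef(sister, buried_ord, "G"),
        ],
        True,
    )
    report = feasibility(cm, {subunit: [m]})
    assert report.pct_accessible == pytest.approx(100.0)


def test_unmapped_residues_excluded_from_denominator(octamer):
    cm = octamer["complex"]
    mapped = _mapping(cm, octamer["manifest"]["exposed"][:4])
    mapped.append(ResidueMapping(ResidueRef("src", 99, "G"), [], False))
    report = feasibility(cm, {"iface": mapped})
    assert report.pct_accessible == pytest.approx(100.0)
    assert len(report.unmapped) == 1


def test_zero_mapped_residues_is_an_error(octamer):
    with pytest.raises(ValueError):
        feasibility(octamer["complex"], {"iface": []})
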