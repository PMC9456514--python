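"""Clade divergence classes, strong-change runs, SASA and surface enrichment."""

import math

import numpy as np
import pytest
from scipy.special import comb

from pepmap.conservation import map_columns_to_reference
from pepmap.divergence import (ColumnClass, classify_columns, compute_sasa,
                               find_strong_change_runs, FUNCTIONAL_GROUPS,
                               map_annotations_to_structure, surface_enrichment)
from pepmap.io import MultipleAlignment, Residue, StructureModel
from pepmap.synthetic import simulate_structure


def _two_clade_aln(clade_a_cols, clade_b_cols, n_each=4):
    """Alignment where clade A taxa all carry clade_a_cols, clade B likewise."""
    seq_a = "".join(clade_a_cols)
    seq_b = "".join(clade_b_cols)
    ids = [f"a{i}" for i in range(n_each)] + [f"b{i}" for i in range(n_each)]
    clades = ["A"] * n_each + ["B"] * n_each
    return MultipleAlignment(ids, clades, [seq_a] * n_each + [seq_b] * n_each)


def test_classification_basic():
    aln = _two_clade_aln("KKD", "RDD")
    classes = classify_columns(aln, aln.taxa_in_clade("A"), aln.taxa_in_clade("B"))
    # K vs R share the positive group; K vs D do not; D vs D identical
    assert [c.cls for c in classes] == ["homologous", "nonhomologous", "homologous"]


def test_majority_gap_column():
    aln = MultipleAlignment(
        ["a0", "a1", "b0", "b1", "b2", "b3"],
        ["A", "A", "B", "B", "B", "B"],
        ["K", "K", "-", "-", "-", "K"],
    )
    classes = classify_columns(aln, ["a0", "a1"], ["b0", "b1", "b2", "b3"])
    assert classes[0].cls == "gap"


def test_classes_partition_columns():
    rng = np.random.default_rng(4)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
    seqs = ["".join(rng.choice(letters, 40)) for _ in range(8)]
    aln = MultipleAlignment([f"t{i}" for i in range(8)],
                            ["A"] * 4 + ["B"] * 4, seqs)
    classes = classify_columns(aln, aln.taxa_in_clade("A"), aln.taxa_in_clade("B"))
    counts = {cls: sum(1 for c in classes if c.cls == cls)
              for cls in ("homologous", "nonhomologous", "gap")}
    assert sum(counts.values()) == aln.n_columns


def test_overlapping_clades_rejected():
    aln = _two_clade_aln("K", "K")
    with pytest.raises(ValueError, match="overlap"):
        classify_columns(aln, ["a0", "a1"], ["a1", "b0"])


def _classes_from_flags(flags):
    return [ColumnClass(i + 1, "nonhomologous" if f else "homologous",
                        "positive", "negative" if f else "positive")
            for i, f in enumerate(flags)]


class _IdentityMap:
    def __init__(self, n):
        self.mapping = {i: i for i in range(1, n + 1)}


@pytest.mark.parametrize("flags, expected", [
    ([True, True, True, False], [(1, 3)]),   # run of 3 kept
    ([True, True, False, True, True], []),   # runs of 2 discarded
    ([True] * 5, [(1, 5)]),
])
def test_strong_change_runs(flags, expected):
    runs = find_strong_change_runs(_classes_from_flags(flags),
                                   _IdentityMap(len(flags)), min_run=3)
    assert [(r.start_residue, r.end_residue) for r in runs] == expected


def test_runs_live_in_reference_residue_coordinates():
    # column 3 is a gap in the reference: it carries no residue, so the
    # flagged columns 1,2,4,5 cover the physically consecutive residues 1-4
    aln = MultipleAlignment(["ref", "o"], ["A", "A"], ["KK-KK", "KKWKK"])
    ref_map = map_columns_to_reference(aln, "ref")
    classes = _classes_from_flags([True, True, True, True, True])
    runs = find_strong_change_runs(classes, ref_map, min_run=3)
    assert [(r.start_residue, r.end_residue) for r in runs] == [(1, 4)]


def test_run_total_flagged_equals_sum_of_lengths():
    flags = [True, True, True, False, True, True, True, True]
    runs = find_strong_change_runs(_classes_from_flags(flags),
                                   _IdentityMap(len(flags)), min_run=3)
    assert sum(r.length for r in runs) == 7


def _single_atom_model():
    return StructureModel([Residue("A", 1, "ALA", {"CA": np.zeros(3)})])


def test_sasa_single_sphere_analytic():
    acc = compute_sasa(_single_atom_model(), probe_radius=1.4, n_points=960)
    analytic = 4.0 * math.pi * (1.7 + 1.4) ** 2
    assert acc.absolute[("A", 1)] == pytest.approx(analytic, rel=1e-9)


def test_sasa_distant_atoms_additive():
    model = StructureModel([
        Residue("A", 1, "ALA", {"CA": np.zeros(3)}),
        Residue("A", 2, "ALA", {"CA": np.array([100.0, 0.0, 0.0])}),
    ])
    acc = compute_sasa(model, n_points=960)
    sphere = 4.0 * math.pi * 3.1**2
    assert acc.absolute[("A", 1)] + acc.absolute[("A", 2)] == \
        pytest.approx(2 * sphere, rel=1e-9)


def _lattice27():
    residues = []
    num = 0
    for x in (-3.0, 0.0, 3.0):
        for y in (-3.0, 0.0, 3.0):
            for z in (-3.0, 0.0, 3.0):
                num += 1
                residues.append(Residue("A", num, "ALA",
                                        {"CA": np.array([x, y, z])}))
    return StructureModel(residues)


def test_sasa_lattice_center_buried_and_resolution_stable():
    model = _lattice27()
    low = compute_sasa(model, n_points=960)
    high = compute_sasa(model, n_points=4000)
    center = ("A", 14)  # the (0,0,0) atom
    assert low.relative[center] < low.exposure_threshold
    for key in low.absolute:
        # numerical agreement between sampling resolutions (3% of max area)
        assert abs(low.absolute[key] - high.absolute[key]) <= \
            0.03 * 4.0 * math.pi * 3.1**2


def test_sasa_monotone_under_added_atom():
    base = _lattice27()
    more = StructureModel(base.residues + [
        Residue("A", 28, "ALA", {"CA": np.array([4.5, 0.0, 0.0])})])
    before = compute_sasa(base, n_points=960)
    after = compute_sasa(more, n_points=960)
    for key in before.absolute:
        assert after.absolute[key] <= before.absolute[key] + 1e-9


def test_sasa_matches_biotite_on_lattice():
    """Independent numerical cross-check against biotite's Shrake-Rupley."""
    import biotite.structure as struc

    model = _lattice27()
    n = len(model.residues)
    arr = struc.AtomArray(n)
    arr.coord = np.array([r.ca for r in model.residues], dtype=np.float32)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.array([r.number for r in model.residues])
    arr.res_name = np.array(["ALA"] * n)
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    ref = struc.sasa(arr, probe_radius=1.4, point_number=1000,
                     vdw_radii="Single")
    ours = compute_sasa(model, n_points=960)
    for i, res in enumerate(model.residues):
        assert abs(ours.absolute[(res.chain_id, res.number)] - ref[i]) <= \
            0.03 * 4.0 * math.pi * 3.1**2


def test_map_annotations_and_unmapped_count():
    model, _ = simulate_structure(3, "helix")
    ann = {1: {"divergence_class": "homologous"},
           2: {"divergence_class": "nonhomologous"},
           3: {"divergence_class": "gap"}}
    assert map_annotations_to_structure(ann, model, "A") == 0
    assert model.annotations[("A", 2)]["divergence_class"] == "nonhomologous"
    model2, _ = simulate_structure(3, "helix")
    assert map_annotations_to_structure({99: {"x": 1}}, model2, "A") == 1
    model3, _ = simulate_structure(3, "helix")
    assert map_annotations_to_structure({}, model3, "A") == 0
    assert model3.annotations == {}
    with pytest.raises(KeyError, match="chain"):
        map_annotations_to_structure(ann, model, "Z")


def test_enrichment_fractions_and_degenerate_odds():
    model, truth = simulate_structure(40, "two_shell")
    access = compute_sasa(model)
    for num, exposed in truth.items():
        model.annotate("A", num,
                       divergence_class="nonhomologous" if exposed else "homologous")
    res = surface_enrichment(model, access)
    assert res.fraction_variable_exposed == 1.0
    assert res.fraction_conserved_exposed == 0.0
    assert res.odds_ratio == float("inf") and not res.degenerate


def test_enrichment_zero_margin_is_degenerate():
    # annotating only exposed residues leaves the buried column empty:
    # the odds ratio is undefined and flagged as such
    model, truth = simulate_structure(40, "two_shell")
    access = compute_sasa(model)
    exposed_ids = [n for n, e in truth.items() if e]
    for num in exposed_ids[:10]:
        model.annotate("A", num, divergence_class="nonhomologous")
    for num in exposed_ids[10:20]:
        model.annotate("A", num, divergence_class="homologous")
    res = surface_enrichment(model, access)
    assert res.degenerate and res.odds_ratio is None


def test_enrichment_exact_p_value_10_0_0_10():
    # perfectly separated 10/10 table: the exact test's two-sided p equals
    # 2 / C(20, 10) by direct hypergeometric enumeration
    model, truth = simulate_structure(40, "two_shell")
    access = compute_sasa(model)
    exposed_ids = [n for n, e in truth.items() if e][:10]
    buried_ids = [n for n, e in truth.items() if not e][:10]
    assert len(exposed_ids) == 10 and len(buried_ids) == 10
    for num in exposed_ids:
        model.annotate("A", num, divergence_class="nonhomologous")
    for num in buried_ids:
        model.annotate("A", num, divergence_class="homologous")
    res = surface_enrichment(model, access)
    assert res.table == ((10, 0), (0, 10))
    p_expected = 2.0 / comb(20, 10, exact=True)
    assert res.p_value == pytest.approx(p_expected, rel=1e-9)
    assert res.p_value == pytest.approx(1.082e-5, rel=1e-3)


def test_enrichment_recovers_planted_surface_variability():
    model, truth = simulate_structure(60, "two_shell")
    access = compute_sasa(model)
    rng = np.random.default_rng(0)
    for num, exposed in truth.items():
        if exposed:
            cls = "nonhomologous" if rng.random() < 0.8 else "homologous"
        else:
            cls = "homologous" if rng.random() < 0.8 else "nonhomologous"
        model.annotate("A", num, divergence_class=cls)
    res = surface_enrichment(model, access)
    assert res.odds_ratio is not None and res.odds_ratio > 1.0


def test_group_table_is_a_partition():
    all_members = [aa for g in FUNCTIONAL_GROUPS.values() for aa in g]
    assert len(all_members) == 20 and len(set(all_members)) == 20
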