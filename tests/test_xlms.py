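"""Crosslink records: parsing, site arithmetic, filters, graphs, distances."""

import itertools

import numpy as np
import pytest

from pepmap.io import Residue, StructureModel
from pepmap.xlms import (CrosslinkRecord, absolute_position, assess_distances,
                         build_graph, filter_records, merge_replicates,
                         parse_crosslink_table)


def _record(p1="alpha", p2="PAP5", score=50.0, pep1="ADEFGHILSK", from1=1,
            site1=("K", 10), pep2="ADEFGHILSK", from2=11, site2=("K", 10),
            replicate="r1"):
    return CrosslinkRecord(
        protein_1=p1, protein_2=p2, score=score,
        peptide_1=pep1, from_1=from1, to_1=from1 + len(pep1) - 1, site_1=site1,
        peptide_2=pep2, from_2=from2, to_2=from2 + len(pep2) - 1, site_2=site2,
        replicate_id=replicate)


class TestParsing:
    def test_bundled_table_has_12_hetero_dipeptides(self, printed_dipeptides):
        assert len(printed_dipeptides) == 12
        assert all(r.protein_1 != r.protein_2 for r in printed_dipeptides)

    def test_brackets_stripped_and_unusual_letters_kept(self, printed_dipeptides):
        assert printed_dipeptides[8].peptide_1 == "KLELVGSMGEDDDSS"  # had "[...}"
        assert "B" in printed_dipeptides[6].peptide_1  # carbamidomethyl-Cys letter

    def test_span_mismatch_flagged_not_fixed(self, printed_dipeptides):
        # printed span 602-617 (16 residues) vs 15-letter peptide
        rec = printed_dipeptides[8]
        assert "span_mismatch_1" in rec.flags
        assert rec.absolute_1 == 602  # from + relative - 1 regardless

    def test_other_rows_unflagged(self, printed_dipeptides):
        assert all(not r.flags for i, r in enumerate(printed_dipeptides) if i != 8)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert parse_crosslink_table(path) == []

    def test_canonical_headers_accepted(self, tmp_path):
        path = tmp_path / "canon.tsv"
        path.write_text(
            "protein_1\tprotein_2\tscore\tpeptide_1\tfrom_1\tto_1\tsite_1\t"
            "peptide_2\tfrom_2\tto_2\tsite_2\n"
            "alpha\tPAP5\t55.5\tGYSLK\t156\t160\tY2\tIKR\t365\t367\tK2\n")
        recs = parse_crosslink_table(path)
        assert len(recs) == 1 and recs[0].absolute_1 == 157

    def test_bad_coordinates_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "protein_1\tprotein_2\tscore\tpeptide_1\tfrom_1\tto_1\tsite_1\t"
            "peptide_2\tfrom_2\tto_2\tsite_2\n"
            "alpha\tPAP5\t55.5\tGYSLK\tabc\t160\tY2\tIKR\t365\t367\tK2\n")
        with pytest.raises(ValueError):
            parse_crosslink_table(path)

    def test_relative_site_beyond_peptide_rejected(self):
        with pytest.raises(ValueError, match="outside peptide"):
            _record(site1=("K", 11))


@pytest.mark.parametrize("from_pos, rel, expected", [
    (156, 2, 157),   # GY(157)SLK... Tyr at relative 2
    (156, 5, 160),   # ...K(160) Lys at relative 5
    (683, 1, 683),   # KNYQNER: N-terminal Lys of the peptide
])
def test_absolute_position(from_pos, rel, expected):
    assert absolute_position(from_pos, rel) == expected


def test_absolute_position_requires_one_based():
    with pytest.raises(ValueError):
        absolute_position(0, 1)


class TestFilter:
    def test_printed_table_passes_default_filter(self, printed_dipeptides):
        kept, dropped = filter_records(printed_dipeptides, min_score=30)
        assert len(kept) == 12 and not dropped

    def test_absurd_cutoff_drops_everything(self, printed_dipeptides):
        kept, _ = filter_records(printed_dipeptides, min_score=1000)
        assert kept == []

    def test_non_dsbu_site_dropped_with_reason(self):
        rec = _record(pep1="GDEFAHILSW", site1=("G", 1), from1=5)
        kept, dropped = filter_records([rec])
        assert not kept
        assert "'G'" in dropped[0][1]

    def test_protein_nterminus_allowed(self):
        # position 1 of the protein is a DSBU target even for a non-KSTY residue
        rec = _record(pep1="GDEFAHILSW", site1=("G", 1), from1=1)
        kept, _ = filter_records([rec])
        assert kept == [rec]


class TestMerge:
    def test_union_semantics(self):
        l1 = _record(from1=1, replicate="r1")
        l2 = _record(from1=21, replicate="r1", score=50.0)
        l2b = _record(from1=21, replicate="r2", score=80.0)
        l3 = _record(from1=41, replicate="r2")
        merged = merge_replicates([[l1, l2], [l2b, l3]])
        assert len(merged) == 3
        shared = [m for m in merged if m.link_key() == l2.link_key()][0]
        assert shared.replicate_ids == {"r1", "r2"}
        assert shared.score == 80.0  # max rule

    def test_idempotent(self):
        records = [_record(from1=1), _record(from1=21)]
        once = merge_replicates([records])
        twice = merge_replicates([once, once])
        assert [r.link_key() for r in once] == [r.link_key() for r in twice]
        assert [r.score for r in once] == [r.score for r in twice]


class TestGraph:
    def test_restricted_clusters_of_printed_table(self, registry, printed_dipeptides):
        g = build_graph(printed_dipeptides, registry, restrict_to_members=True)
        assert g.n_clusters == 2
        assert g.clusters[0] == ["PAP5", "PAP6/FLN2", "alpha", "beta", "beta_prime"]
        assert g.clusters[1] == ["PAP1", "PAP11", "PAP2"]

    def test_unrestricted_attaches_copurifiers(self, registry, printed_dipeptides):
        g = build_graph(printed_dipeptides, registry, restrict_to_members=False)
        assert g.n_clusters == 2
        assert "RPS2A/RPS2B" in g.cluster_of("PAP5")
        assert "SPPA" in g.cluster_of("PAP2")

    def test_empty_records_empty_graph(self, registry):
        g = build_graph([], registry)
        assert g.n_clusters == 0 and len(g.graph) == 0

    def test_clusters_invariant_under_row_permutation(self, registry,
                                                      printed_dipeptides):
        base = build_graph(printed_dipeptides, registry, restrict_to_members=True)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = list(rng.permutation(len(printed_dipeptides)))
            g = build_graph([printed_dipeptides[i] for i in perm], registry,
                            restrict_to_members=True)
            assert g.clusters == base.clusters

    def test_restriction_never_adds_nodes_or_merges_components(self, registry,
                                                               printed_dipeptides):
        free = build_graph(printed_dipeptides, registry, restrict_to_members=False)
        restricted = build_graph(printed_dipeptides, registry, restrict_to_members=True)
        assert len(restricted.graph) <= len(free.graph)
        for comp in restricted.clusters:
            # each restricted component lies inside one unrestricted component
            containers = {id(c) for node in comp for c in [free.cluster_of(node)]}
            assert len(containers) == 1

    def test_components_match_bruteforce_closure(self, registry):
        """Graph clustering vs transitive-closure enumeration on small inputs."""
        rng = np.random.default_rng(7)
        names = ["alpha", "beta", "PAP1", "PAP2", "PAP5", "PAP7", "PAP9", "PAP11"]
        for trial in range(10):
            n_edges = int(rng.integers(1, 9))
            pairs = [tuple(rng.choice(names, 2, replace=False))
                     for _ in range(n_edges)]
            records = [_record(p1=a, p2=b, from1=int(rng.integers(1, 5)) * 10 - 9)
                       for a, b in pairs]
            g = build_graph(records, registry)
            # brute force: iterate pairwise unions to a fixed point
            comps = [{a, b} for a, b in pairs]
            changed = True
            while changed:
                changed = False
                for c1, c2 in itertools.combinations(comps, 2):
                    if c1 & c2:
                        c1 |= c2
                        comps.remove(c2)
                        changed = True
                        break
            expected = sorted((sorted(c) for c in comps), key=lambda c: (-len(c), c))
            assert g.clusters == expected


class TestDistances:
    def _model(self):
        # straight chain: residue i at (4i, 0, 0)
        residues = [Residue("A", i, "ALA", {"CA": np.array([4.0 * i, 0.0, 0.0])})
                    for i in range(1, 51)]
        return StructureModel(residues)

    def test_compatible_incompatible_unmapped(self):
        model = self._model()
        chain_map = {"alpha": "A", "PAP5": "A"}
        close = _record(from1=1, site1=("K", 10), from2=3, site2=("K", 10))
        # |CA(10) - CA(12)| = 8 Å
        far = _record(from1=1, site1=("K", 10), from2=13, site2=("K", 10))
        # |CA(10) - CA(22)| = 48 Å
        off = _record(from1=991, site1=("K", 9), from2=1, site2=("K", 10))
        result = assess_distances([close, far, off], model, chain_map, 30.0)
        assert result.compatible == [True, False, None]
        assert result.distances[0] == pytest.approx(8.0)
        assert result.distances[1] == pytest.approx(48.0)
        assert (result.n_compatible, result.n_incompatible, result.n_unmapped) \
            == (1, 1, 1)

    def test_chain_absent_from_model_is_error(self):
        with pytest.raises(KeyError, match="chain"):
            assess_distances([_record()], self._model(), {"alpha": "Z"})
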