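"""Graph construction, cycle/chain enumeration, plate transforms and
platform attribution."""

import numpy as np
import pytest

from badgerqc import engine, eqtl, resolve, simulate
from badgerqc.core import (
    Correction,
    Move,
    ProvenanceEntry,
    SampleMap,
    SampleRecord,
)
from badgerqc.simulate import (
    AlienError,
    BlockReversal,
    NeighbourSwap,
    PlateRotationError,
    SimulationConfig,
)


def _scored(cohort, smap=None, eqtl_map=None):
    smap = smap or cohort.smap
    pairs = eqtl.scan_cis_associations(cohort.expr, cohort.geno, eqtl_map or cohort.truth_map)
    pairs = eqtl.fit_eqtl_set(pairs, cohort.expr, cohort.geno, eqtl_map or cohort.truth_map)
    P = engine.predict_matrix(pairs, cohort.expr)
    O = engine.observed_matrix(pairs, cohort.geno)
    sm = engine.score_matrix(P, O)
    rm = engine.rank_matrix(sm)
    return sm, rm, engine.delta_statistics(sm)


class TestMismatchGraph:
    def test_clean_cohort_graph_is_empty(self, clean_cohort):
        sm, rm, dl = _scored(clean_cohort, eqtl_map=clean_cohort.smap)
        g = resolve.build_mismatch_graph(sm, rm, clean_cohort.smap, dl)
        assert g.number_of_nodes() == 0

    def test_swapped_neighbours_form_alternating_four_cycle(self):
        c = simulate.simulate_cohort(
            SimulationConfig(seed=51, error_spec=(NeighbourSwap("genotype"),))
        )
        sm, rm, dl = _scored(c)
        g = resolve.build_mismatch_graph(sm, rm, c.smap, dl)
        assert [n for n in g if n[0] == "E"] == [("E", "E069"), ("E", "E070")]
        # the swap shows as a 4-cycle alternating intended and evidence
        # edges between the two affected pairs (extra rank-2 evidence
        # nodes may also appear)
        e1, e2, g1, g2 = ("E", "E069"), ("E", "E070"), ("G", "G069"), ("G", "G070")
        assert g[e1][g1]["intended"] and g[e2][g2]["intended"]
        assert not g[e1][g2]["intended"] and g[e1][g2]["rank"] == 1
        assert not g[e2][g1]["intended"] and g[e2][g1]["rank"] == 1

    def test_alien_is_isolated_high_score_node(self):
        c = simulate.simulate_cohort(
            SimulationConfig(seed=52, n_excluded=1, excluded_positions=(97,),
                             error_spec=(AlienError("genotype"),))
        )
        sm, rm, dl = _scored(c)
        g = resolve.build_mismatch_graph(sm, rm, c.smap, dl)
        orphans = [d for n, d in g.nodes(data=True) if n[0] == "E" and d.get("orphan")]
        aliens = [d for n, d in g.nodes(data=True) if n[0] == "G" and d.get("alien")]
        assert len(orphans) == 1 and len(aliens) == 1
        assert orphans[0]["min_score"] > g.graph["orphan_threshold"]

    def test_dot_export_mentions_every_node(self):
        c = simulate.simulate_cohort(
            SimulationConfig(seed=53, error_spec=(NeighbourSwap("genotype"),))
        )
        sm, rm, dl = _scored(c)
        g = resolve.build_mismatch_graph(sm, rm, c.smap, dl)
        dot = resolve.graph_to_dot(g)
        assert dot.startswith("graph") and dot.rstrip().endswith("}")
        for _side, arr in g.nodes:
            assert arr in dot


class TestCyclesAndChains:
    def test_planted_two_cycle_yields_one_swap(self):
        c = simulate.simulate_cohort(
            SimulationConfig(seed=54, error_spec=(NeighbourSwap("genotype"),))
        )
        sm, rm, dl = _scored(c)
        g = resolve.build_mismatch_graph(sm, rm, c.smap, dl)
        props = resolve.find_cycles_and_chains(g, c.smap, rm)
        assert len(props) == 1 and props[0].kind == "swap"

    def test_four_array_reversal_reported_as_one_correction(self):
        c = simulate.simulate_cohort(
            SimulationConfig(seed=55, error_spec=(BlockReversal(4, "genotype", start=20),))
        )
        sm, rm, dl = _scored(c)
        g = resolve.build_mismatch_graph(sm, rm, c.smap, dl)
        props = resolve.find_cycles_and_chains(g, c.smap, rm)
        assert len(props) == 1
        assert props[0].evidence.get("transform") == "block_reversal"
        assert len(props[0].affected_samples()) == 4

    def test_slippage_chain_names_aliens_from_sequence(self):
        c = simulate.simulate_cohort(
            SimulationConfig(seed=56, n_samples=96, n_excluded=2,
                             excluded_positions=(52, 56),
                             error_spec=(simulate.SlippageError(start=49, length=8),))
        )
        sm, rm, dl = _scored(c)
        g = resolve.build_mismatch_graph(sm, rm, c.smap, dl)
        props = [p for p in resolve.find_cycles_and_chains(g, c.smap, rm)
                 if p.kind == "slippage"]
        assert len(props) == 2  # one run per excluded space-holder
        named = {p.evidence.get("alien") for p in props}
        assert named == {"S052", "S056"}


class TestPlateTransforms:
    def test_identity_map_yields_no_hypothesis(self, clean_cohort):
        sm, rm, _dl = _scored(clean_cohort, eqtl_map=clean_cohort.smap)
        assert resolve.enumerate_plate_transforms(clean_cohort.smap, sm, rm) == []

    def test_planted_rotation_recovered_wholesale(self):
        c = simulate.simulate_cohort(
            SimulationConfig(seed=57, n_samples=192,
                             error_spec=(PlateRotationError("genotype", "GP2"),))
        )
        sm, rm, _dl = _scored(c)
        props = resolve.enumerate_plate_transforms(c.smap, sm, rm)
        best = props[0]
        assert best.evidence["transform"] == "rotation_180"
        assert best.evidence["plate"] == "GP2"
        assert best.evidence["gain"] == 96
        assert best.evidence["all_repaired_rank1"]


def _manual_map(geno_plates: tuple[str, str], expr_wells: tuple[str, str]):
    """Two samples adjacent (or not) per platform via explicit provenance."""
    recs = []
    for i, (gp, ew) in enumerate(zip(geno_plates, expr_wells), start=1):
        recs.append(
            SampleRecord(
                f"S{i}", f"E{i}", f"G{i}", "tumour",
                (
                    ProvenanceEntry("expression_chip", "expression", "EC1", ew, None),
                    ProvenanceEntry("genotyping", "genotype", gp, "A1", None),
                ),
            )
        )
    return SampleMap(recs)


class TestAttribution:
    def test_expression_neighbours_different_genotype_plates(self):
        # the canonical deduction: two arrays adjacent on the expression
        # chip but on different genotyping plates -> the error happened on
        # the expression side
        smap = _manual_map(("GP1", "GP7"), ("A1", "A2"))
        assert resolve.attribute_platform(smap, ["S1", "S2"]) == "expression"

    def test_neighbours_on_both_platforms_undetermined(self):
        smap = _manual_map(("GP1", "GP1"), ("A1", "A2"))
        # same genotype plate, adjacent wells on both -> cannot attribute
        smap.records[1].provenance = (
            smap.records[1].provenance[0],
            ProvenanceEntry("genotyping", "genotype", "GP1", "A2", None),
        )
        assert resolve.attribute_platform(smap, ["S1", "S2"]) == "undetermined"

    def test_expression_attribution_moves_expression_labels(self):
        smap = _manual_map(("GP1", "GP7"), ("A1", "A2"))
        corr = Correction(
            "swap",
            [Move("S1", "E1", "G2"), Move("S2", "E2", "G1")],
            evidence={"cycle_samples": ["S1", "S2"]},
        )
        (att,) = resolve.attribute_corrections([corr], smap)
        assert att.platform == "expression"
        # psi(S1)=S2 means E1 carries S2's RNA: S2 owns E1 afterwards
        assert {(m.sample_id, m.expression_array, m.genotype_array) for m in att.moves} == {
            ("S2", "E1", "G2"), ("S1", "E2", "G1")
        }


class TestAttributeAndApply:
    def test_disjoint_double_swap_both_applied(self):
        c = simulate.simulate_cohort(
            SimulationConfig(
                seed=58,
                error_spec=(NeighbourSwap("genotype", position=10),
                            NeighbourSwap("genotype", position=40)),
            )
        )
        new_map, report = resolve.attribute_and_apply(c.truth_corrections, c.smap)
        assert len(report.corrections) == 2
        assert new_map.assignment_signature() == c.truth_map.assignment_signature()

    def test_overlapping_corrections_conflict_and_nothing_applied(self, clean_cohort):
        smap = clean_cohort.smap
        s1, s2, s3 = [r.sample_id for r in smap.records[:3]]
        recs = {r.sample_id: r for r in smap.records}
        c1 = Correction("swap", [
            Move(s1, recs[s1].expression_array, recs[s2].genotype_array),
            Move(s2, recs[s2].expression_array, recs[s1].genotype_array)])
        c2 = Correction("swap", [
            Move(s2, recs[s2].expression_array, recs[s3].genotype_array),
            Move(s3, recs[s3].expression_array, recs[s2].genotype_array)])
        new_map, report = resolve.attribute_and_apply([c1, c2], smap)
        assert report.corrections == []
        assert any("conflict" in n for n in report.notes)
        assert new_map.assignment_signature() == smap.assignment_signature()
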