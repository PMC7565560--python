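"""Pathway grammar, abundance evaluator and genome completeness."""

import numpy as np
import pandas as pd
import pytest

from trenchomics.pathways import (
    MIN_OVER_STEPS,
    PathwayDef,
    PathwayParseError,
    genome_pathway_completeness,
    load_default_library,
    load_ko_symbols,
    parse_pathway_library,
    pathway_abundance,
    pathway_abundance_matrix,
    step_abundance,
)


class TestParser:
    def test_single_complex(self):
        (p,) = parse_pathway_library("nif: K02586+K02591+K02588")
        assert len(p.steps) == 1
        assert p.steps[0] == (frozenset({"K02586", "K02591", "K02588"}),)

    def test_alternative_complexes(self):
        (p,) = parse_pathway_library("dnra: K00362+K00363 | K03385+K15876")
        assert len(p.steps) == 1
        assert set(p.steps[0]) == {
            frozenset({"K00362", "K00363"}),
            frozenset({"K03385", "K15876"}),
        }

    def test_multiple_steps_and_display_name(self):
        (p,) = parse_pathway_library("x (A Name): K00001; K00002 | K00003")
        assert p.display_name == "A Name"
        assert len(p.steps) == 2

    @pytest.mark.parametrize(
        "bad",
        ["x: +K00001", "x: K1", "x:", "no_colon_here", "x: K00001;;K00002",
         "x: K00001 | ", "x (y: K00001"],
    )
    def test_malformed_definitions_raise(self, bad):
        with pytest.raises(PathwayParseError):
            parse_pathway_library(bad)

    def test_duplicate_id_rejected(self):
        with pytest.raises(PathwayParseError, match="duplicate"):
            parse_pathway_library("a: K00001\na: K00002")

    def test_error_carries_line_number(self):
        with pytest.raises(PathwayParseError, match="line 3"):
            parse_pathway_library("# c\na: K00001\nb: +K00002")


class TestAbundance:
    def test_complex_limited_by_scarcest_subunit(self):
        step = (frozenset({"K10001", "K10002", "K10003"}),)
        abund = {"K10001": 0.1, "K10002": 0.3, "K10003": 0.2}
        assert step_abundance(step, abund) == pytest.approx(0.1)

    def test_alternatives_add(self):
        step = (frozenset({"K10001"}), frozenset({"K10002"}))
        assert step_abundance(step, {"K10001": 0.1, "K10002": 0.05}) == pytest.approx(0.15)

    def test_absent_kos_count_zero(self):
        step = (frozenset({"K10001", "K10009"}),)
        assert step_abundance(step, {"K10001": 0.4}) == 0.0

    def test_pathway_mean_over_steps(self):
        (p,) = parse_pathway_library("x: K00001; K00002")
        assert pathway_abundance(p, {"K00001": 0.2, "K00002": 0.4}) == pytest.approx(0.3)
        assert pathway_abundance(
            p, {"K00001": 0.2, "K00002": 0.4}, step_reducer=MIN_OVER_STEPS
        ) == pytest.approx(0.2)

    def test_identity_for_single_ko_pathway(self):
        (p,) = parse_pathway_library("x: K00007")
        assert pathway_abundance(p, {"K00007": 0.123}) == pytest.approx(0.123)

    def test_five_pathway_fixture_matches_independent_recomputation(self, rng):
        text = "\n".join(
            [
                "p1: K00001+K00002",
                "p2: K00001 | K00003",
                "p3: K00001; K00002; K00003",
                "p4: K00001+K00002 | K00003; K00004",
                "p5: K00009",
            ]
        )
        lib = parse_pathway_library(text)
        abund = {f"K{i:05d}": float(v) for i, v in
                 enumerate(rng.uniform(0, 0.2, 5), start=1)}
        # spreadsheet-style oracle, written out term by term
        a = abund
        expected = {
            "p1": min(a["K00001"], a["K00002"]),
            "p2": a["K00001"] + a["K00003"],
            "p3": (a["K00001"] + a["K00002"] + a["K00003"]) / 3,
            "p4": (min(a["K00001"], a["K00002"]) + a["K00003"] + a["K00004"]) / 2,
            "p5": 0.0,
        }
        ko_matrix = pd.DataFrame({"s1": pd.Series(a)})
        got = pathway_abundance_matrix(lib, ko_matrix)["s1"]
        for pid, v in expected.items():
            assert got[pid] == pytest.approx(v, abs=1e-12), pid


class TestCompleteness:
    def test_fully_annotated_genome_complete(self, tiny_library_text):
        lib = parse_pathway_library(tiny_library_text)
        all_kos = {ko for p in lib for ko in p.ko_ids}
        for p in lib:
            assert genome_pathway_completeness(p, all_kos).completeness == 1.0

    def test_half_satisfied_two_step_pathway(self):
        (p,) = parse_pathway_library("x: K00001; K00002")
        assert genome_pathway_completeness(p, {"K00001"}).completeness == 0.5

    def test_partial_complex_contributes_nothing(self):
        (p,) = parse_pathway_library("x: K00001+K00002")
        assert genome_pathway_completeness(p, {"K00001"}).completeness == 0.0

    def test_alternative_complex_suffices(self):
        (p,) = parse_pathway_library("x: K00001+K00002 | K00003")
        assert genome_pathway_completeness(p, {"K00003"}).completeness == 1.0

    def test_empty_genome_all_zero(self, tiny_library_text):
        lib = parse_pathway_library(tiny_library_text)
        for p in lib:
            assert genome_pathway_completeness(p, set()).completeness == 0.0


def random_pathway(rng, ko_pool):
    steps = []
    for _ in range(rng.integers(1, 5)):
        alts = []
        for _ in range(rng.integers(1, 4)):
            size = rng.integers(1, 4)
            alts.append(frozenset(rng.choice(ko_pool, size=size, replace=False)))
        steps.append(tuple(alts))
    return PathwayDef("p", "p", tuple(steps))


class TestRandomizedProperties:
    """Monotonicity and boundedness over randomized libraries/genomes."""

    def test_monotone_and_bounded(self, rng):
        pool = np.array([f"K{i:05d}" for i in range(1, 30)])
        for _ in range(300):
            p = random_pathway(rng, pool)
            abund = {k: float(rng.uniform(0, 0.1)) for k in
                     rng.choice(pool, size=15, replace=False)}
            val = pathway_abundance(p, abund)
            step_vals = [step_abundance(s, abund) for s in p.steps]
            assert 0.0 <= val <= max(step_vals) + 1e-12  # bounded by max step
            assert max(step_vals) <= sum(abund.values()) + 1e-12
            # raising one KO never decreases the pathway value
            ko = str(rng.choice(pool))
            boosted = dict(abund)
            boosted[ko] = boosted.get(ko, 0.0) + float(rng.uniform(0, 0.1))
            assert pathway_abundance(p, boosted) >= val - 1e-12
            # adding a KO to a genome never decreases completeness
            genome = set(rng.choice(pool, size=10, replace=False))
            c0 = genome_pathway_completeness(p, genome).completeness
            c1 = genome_pathway_completeness(p, genome | {ko}).completeness
            assert 0.0 <= c0 <= c1 <= 1.0


class TestShippedLibrary:
    def test_parses_and_is_unique(self):
        lib = load_default_library()
        ids = [p.pathway_id for p in lib]
        assert len(ids) == len(set(ids))
        assert len(lib) >= 30

    def test_covers_named_marker_panels(self):
        lib = {p.pathway_id: p for p in load_default_library()}
        # glycolysis-only glk/pfk/pyk; gluconeogenesis-only fbp/pck
        assert lib["glycolysis_specific"].ko_ids == {"K00845", "K00850", "K00873"}
        assert lib["gluconeogenesis_specific"].ko_ids == {"K03841", "K01610"}
        # glyoxylate shunt = isocitrate lyase + malate synthase
        assert lib["glyoxylate_shunt"].ko_ids == {"K01637", "K01638"}
        # CBB markers RuBisCO + prk
        assert {"K01601", "K01602", "K00855"} <= lib["cbb_cycle"].ko_ids
        # rTCA aclAB / ccsAB as alternatives
        assert frozenset({"K15230", "K15231"}) in lib["rtca_cycle"].steps[0]
        assert frozenset({"K15232", "K15233"}) in lib["rtca_cycle"].steps[0]
        # 3HP mct/meh, Wood-Ljungdahl cooS/cdhAB/acsB/acsE
        assert lib["three_hp_bicycle"].ko_ids == {"K14470", "K09709"}
        assert {"K00198", "K14138", "K15023"} <= lib["wood_ljungdahl"].ko_ids
        # terminal oxidases
        for ox in ("aa3", "cbb3", "bd", "qox", "cyo"):
            assert f"oxidase_{ox}" in lib
        assert "hydrogenase_nife" in lib
        for ferm in ("lactate_fermentation", "formate_metabolism",
                     "acetate_metabolism", "ethanol_metabolism"):
            assert ferm in lib
        # N panel
        assert lib["nitrogen_fixation"].steps[0] == (
            frozenset({"K02586", "K02591", "K02588"}),
        )
        assert lib["ammonia_oxidation"].ko_ids == {"K10944", "K10945", "K10946"}
        assert lib["hydroxylamine_oxidation"].ko_ids == {"K10535"}
        assert {"K00370", "K00371", "K00374"} == lib["nitrate_reduction_nar"].ko_ids
        assert lib["nitrate_reduction_nap"].ko_ids == {"K02567", "K02568"}
        assert lib["nitrite_reduction_no"].steps[0] == (
            frozenset({"K00368"}), frozenset({"K15864"}),
        )
        assert lib["nitric_oxide_reduction"].ko_ids == {"K04561", "K02305"}
        assert lib["nitrous_oxide_reduction"].ko_ids == {"K00376"}
        # DNRA: nirBD or nrfAH
        assert set(lib["dnra"].steps[0]) == {
            frozenset({"K00362", "K00363"}), frozenset({"K03385", "K15876"}),
        }
        assert len(lib["urea_transport"].ko_ids) == 5
        # S panel
        assert {"K00958"} <= lib["dissimilatory_sulfate_reduction"].ko_ids
        assert frozenset({"K00394", "K00395"}) in [
            a for s in lib["dissimilatory_sulfate_reduction"].steps for a in s
        ]
        assert frozenset({"K11180", "K11181"}) in [
            a for s in lib["dissimilatory_sulfate_reduction"].steps for a in s
        ]
        sox = lib["sox_system"].ko_ids
        assert {"K17222", "K17223", "K17224", "K17225", "K22622",
                "K17226", "K17227"} == sox
        for s_entry in ("thiosulfate_oxidation_tsda", "thiosulfate_oxidation_dox",
                        "thiosulfate_reduction_phs", "sulfite_oxidation_soe",
                        "sulfide_oxidation_fcc", "sulfur_dioxygenase",
                        "assimilatory_sulfate_reduction"):
            assert s_entry in lib

    def test_every_library_ko_has_a_symbol(self):
        lib = load_default_library()
        symbols = set(load_ko_symbols()["ko_id"])
        missing = {ko for p in lib for ko in p.ko_ids} - symbols
        assert not missing
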