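"""Complex-calling tests on planted operon fixtures.

Fixtures come from the simulator at zero divergence, so role candidates
are exact matches of the catalog and the verdict logic is exercised in
isolation."""

import copy

import pytest

from ferroscan.records import GenomeAnnotation, ProteinRecord
from ferroscan.simulate import make_fixture
from ferroscan.synteny import (
    call_complex,
    collect_candidates,
    cohort_complex_matrix,
    find_role_candidates,
    load_complex_definitions,
)

DEFS = {d.name: d for d in load_complex_definitions()}


def _drop_protein(genome, protein_id):
    out = copy.deepcopy(genome)
    out.proteins = [p for p in out.proteins if p.protein_id != protein_id]
    return out


def _call(genome, catalog, name):
    d = DEFS[name]
    return call_complex(genome, d, collect_candidates(genome, d, catalog))


@pytest.fixture(scope="module")
def pcc3():
    return make_fixture("minimal-pcc3")


@pytest.fixture(scope="module")
def uet():
    return make_fixture("uet-no-porin")


class TestDefinitions:
    def test_shipped_definitions_parse(self):
        names = set(DEFS)
        assert {"Cyc2", "MtoAB", "MtrC", "PCC3", "Uet", "Slit_cluster"} <= names
        assert all(d.window >= 1 for d in DEFS.values())

    def test_anchor_is_first_required_mhc(self):
        assert DEFS["PCC3"].anchor_role.role_label == "PCC3-periplasmic"
        assert DEFS["Uet"].anchor_role.role_label == "UetA"


class TestRoleCandidates:
    def test_planted_undecaheme_retained(self, uet):
        genome = uet.genomes[0]
        hits = find_role_candidates(genome, "UetJ", uet.catalog)
        assert len(hits) == 1
        assert hits[0].total_hemes == 11

    def test_heme_constraint_rejects_wrong_count(self, uet):
        genome = uet.genomes[0]
        # the planted UetJ fails a deliberately impossible heme range
        assert find_role_candidates(
            genome, "UetJ", uet.catalog, min_hemes=20, max_hemes=None
        ) == []

    def test_absent_family_empty(self, uet):
        assert find_role_candidates(uet.genomes[0], "Cyc2", uet.catalog) == []

    def test_unknown_role_error(self, uet):
        with pytest.raises(KeyError, match="nonesuch"):
            find_role_candidates(uet.genomes[0], "nonesuch", uet.catalog)


class TestCallComplex:
    def test_planted_pcc3_complete(self, pcc3):
        call = _call(pcc3.genomes[0], pcc3.catalog, "PCC3")
        assert call.verdict == "complete"
        assert set(call.subunit_map) == {
            "PCC3-periplasmic", "PCC3-extracellular", "PCC3-porin",
            "PCC3-inner-membrane",
        }

    def test_porin_deletion_downgrades_to_partial(self, pcc3):
        genome = pcc3.genomes[0]
        porin_id = _call(genome, pcc3.catalog, "PCC3").subunit_map["PCC3-porin"][0]
        partial = _drop_protein(genome, porin_id)
        assert _call(partial, pcc3.catalog, "PCC3").verdict == "partial"

    def test_two_periplasmic_copies_give_variant(self, pcc3):
        genome = copy.deepcopy(pcc3.genomes[0])
        peri = next(
            p for p in genome.proteins
            if pcc3.truth.family_of.get(p.protein_id) == "PCC3-periplasmic"
        )
        extra = ProteinRecord(
            "dup_peri", genome.genome_id, "dup_peri", peri.contig_id,
            max(p.rank for p in genome.proteins) + 1, "+", peri.sequence,
        )
        genome.proteins.append(extra)
        assert _call(genome, pcc3.catalog, "PCC3").verdict == "complete-variant"

    def test_uet_complete_without_optional_porin(self, uet):
        call = _call(uet.genomes[0], uet.catalog, "Uet")
        assert call.verdict == "complete"
        assert "UetC" not in call.subunit_map

    def test_mto_fixture_with_standalone_mtrc(self):
        fx = make_fixture("mto-with-mtrc")
        genome = fx.genomes[0]
        assert _call(genome, fx.catalog, "MtoAB").verdict == "complete"
        assert _call(genome, fx.catalog, "MtrC").verdict == "complete"

    def test_absent_when_no_role_hits(self, pcc3):
        assert _call(pcc3.genomes[0], pcc3.catalog, "Uet").verdict == "absent"

    def test_deleting_genes_never_upgrades_verdict(self, pcc3):
        order = {"absent": 0, "partial": 1, "complete": 2, "complete-variant": 2}
        genome = pcc3.genomes[0]
        verdict = _call(genome, pcc3.catalog, "PCC3").verdict
        for p in list(genome.proteins):
            smaller = _drop_protein(genome, p.protein_id)
            v = _call(smaller, pcc3.catalog, "PCC3").verdict
            assert order[v] <= order[verdict]

    def test_window_monotonicity(self, pcc3):
        """Widening the rank window can only improve the verdict."""
        import dataclasses

        order = {"absent": 0, "partial": 1, "complete": 2, "complete-variant": 2}
        genome = _scatter(pcc3.genomes[0])
        verdicts = []
        for window in (1, 3, 8, 30):
            d = dataclasses.replace(DEFS["PCC3"], window=window)
            call = call_complex(genome, d, collect_candidates(genome, d, pcc3.catalog))
            verdicts.append(order[call.verdict])
        assert verdicts == sorted(verdicts)


def _scatter(genome):
    """Spread the operon out so small windows fail colocalization."""
    out = copy.deepcopy(genome)
    spread = []
    for i, p in enumerate(sorted(out.proteins, key=lambda r: r.rank)):
        spread.append(
            ProteinRecord(
                p.protein_id, p.genome_id, p.locus_tag, p.contig_id,
                i * 4, p.strand, p.sequence,
            )
        )
    out.proteins = spread
    return out


def test_cohort_matrix_counts():
    pcc3 = make_fixture("minimal-pcc3")
    table, calls = cohort_complex_matrix(
        pcc3.genomes, [DEFS["PCC3"], DEFS["Uet"]], pcc3.catalog
    )
    assert table.loc["fixture_0", "PCC3"] == "complete"
    assert table.loc["fixture_0", "Uet"] == "absent"
    assert len(calls) == 2


def test_empty_cohort_empty_table():
    pcc3 = make_fixture("minimal-pcc3")
    table, calls = cohort_complex_matrix([], [DEFS["PCC3"]], pcc3.catalog)
    assert table.empty and calls == []
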