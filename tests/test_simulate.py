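import numpy as np
import pytest

from ferroscan.hemes import profile_protein, scan_protein
from ferroscan.simulate import (
    FEOB_GROUPS,
    SimulationConfig,
    make_fixture,
    simulate_cohort,
    write_cohort,
)


def _serialize(sim):
    return (
        [(g.genome_id, g.group_label, g.completeness,
          [(p.protein_id, p.rank, p.strand, p.sequence) for p in g.proteins])
         for g in sim.genomes],
        sim.truth.marker_presence.to_dict(),
        sim.truth.complex_verdicts.to_dict(),
    )


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        cfg = dict(seed=21, n_per_group=1, n_background=8)
        a = simulate_cohort(SimulationConfig(**cfg))
        b = simulate_cohort(SimulationConfig(**cfg))
        assert _serialize(a) == _serialize(b)

    def test_write_cohort_byte_identical(self, tmp_path):
        cfg = dict(seed=22, n_per_group=1, n_background=6)
        d1 = write_cohort(simulate_cohort(SimulationConfig(**cfg)), tmp_path / "a")
        d2 = write_cohort(simulate_cohort(SimulationConfig(**cfg)), tmp_path / "b")
        for p in sorted(d1.rglob("*")):
            if p.is_file():
                q = d2 / p.relative_to(d1)
                assert p.read_bytes() == q.read_bytes(), p.name

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(seed=1, n_per_group=1, n_background=6))
        b = simulate_cohort(SimulationConfig(seed=2, n_per_group=1, n_background=6))
        assert _serialize(a) != _serialize(b)


class TestTruthConsistency:
    def test_planted_heme_counts_are_scanner_truth(self, small_cohort):
        truth = small_cohort.truth.heme_counts.set_index(
            ["genome_id", "protein_id"]
        )["total_hemes"]
        for g in small_cohort.genomes:
            for p in g.proteins:
                prof = profile_protein(p.protein_id, p.sequence)
                observed = prof.total_hemes if prof else 0
                assert observed == truth[(g.genome_id, p.protein_id)]

    def test_complete_complex_has_all_subunits(self, small_cohort):
        fam_of = small_cohort.truth.family_of
        for g in small_cohort.genomes:
            verdicts = small_cohort.truth.complex_verdicts.loc[g.genome_id]
            families = {fam_of.get(p.protein_id) for p in g.proteins}
            if verdicts["PCC3"] in {"complete", "complete-variant"}:
                assert {"PCC3-periplasmic", "PCC3-extracellular"} <= families

    def test_nob_group_lacks_big_mhcs(self, small_cohort):
        for g in small_cohort.genomes:
            if g.group_label in FEOB_GROUPS:
                continue
            for p in g.proteins:
                prof = profile_protein(p.protein_id, p.sequence)
                if prof is not None:
                    assert prof.total_hemes < 10

    def test_zero_divergence_group_members_identical(self):
        sim = simulate_cohort(
            SimulationConfig(
                seed=30, n_per_group=2, n_background=6,
                divergence_within=0.0,
            )
        )
        fam_lookup = sim.truth.heme_counts.set_index("protein_id")["family"]
        by_group = {}
        for g in sim.genomes:
            by_group.setdefault(g.group_label, []).append(g)
        for group, (g1, g2) in by_group.items():
            core1 = {fam_lookup[p.protein_id]: p.sequence for p in g1.proteins}
            core2 = {fam_lookup[p.protein_id]: p.sequence for p in g2.proteins}
            shared = set(core1) & set(core2)
            assert shared  # background families at minimum
            assert all(core1[f] == core2[f] for f in shared)


class TestConfigValidation:
    def test_bad_prevalence_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            SimulationConfig(
                seed=1,
                marker_prevalence={"Gallionella-like": {"cyc2": 1.5}},
            )


class TestFixtures:
    def test_unknown_fixture_lists_registry(self):
        with pytest.raises(ValueError, match="minimal-pcc3"):
            make_fixture("nope")

    def test_minimal_pcc3_truth(self):
        fx = make_fixture("minimal-pcc3")
        assert len(fx.genomes) == 1
        assert fx.truth.complex_verdicts.loc["fixture_0", "PCC3"] == "complete"
        families = set(fx.truth.family_of.values())
        assert {"PCC3-periplasmic", "PCC3-extracellular"} <= families

    def test_fixture_sizes_are_tiny(self):
        for name in ("minimal-pcc3", "mto-with-mtrc", "uet-no-porin"):
            fx = make_fixture(name)
            assert len(fx.genomes) <= 5
            assert sum(g.n_proteins for g in fx.genomes) <= 30

    def test_motif_count_survives_mutation(self):
        """The anchor-protection contract: heavy extra divergence never
        changes a planted motif count."""
        sim = simulate_cohort(
            SimulationConfig(seed=31, n_per_group=1, n_background=4,
                             divergence_within=0.3)
        )
        truth = sim.truth.heme_counts.set_index(["genome_id", "protein_id"])
        for g in sim.genomes:
            for p in g.proteins:
                expected = truth.loc[(g.genome_id, p.protein_id), "total_hemes"]
                assert len(scan_protein(p.sequence)) == expected
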