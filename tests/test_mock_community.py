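import numpy as np
import pytest
from Bio.Seq import Seq

from probecap._pairwise import gc_fraction, revcomp
from probecap.errors import InfeasibleTargetError, PlacementError, ValidationError
from probecap.mock_community import (
    MockDesign,
    StrainSpec,
    expected_abundance,
    mutate_cds,
    read_strains_tsv,
    read_truth_bed,
    solve_fractions,
    synth_strain,
    volume_to_mass_fractions,
    weighted_gc,
    write_strains_tsv,
    write_truth_bed,
)


def strain(name, gc, length=1_000_000, genes=None):
    return StrainSpec(name=name, length_bp=length, gc_molpercent=gc, gene_copies=genes or {})


class TestWeightedGC:
    def test_midpoint(self):
        assert weighted_gc([strain("a", 40), strain("b", 60)], [0.5, 0.5]) == 50.0

    def test_single_strain(self):
        assert weighted_gc([strain("a", 55.5)], [1.0]) == 55.5

    def test_linear_combination(self):
        got = weighted_gc(
            [strain("a", 43), strain("b", 50), strain("c", 66)], [0.2, 0.3, 0.5]
        )
        assert got == pytest.approx(56.6, abs=1e-12)

    def test_bad_fraction_sum(self):
        with pytest.raises(ValidationError):
            weighted_gc([strain("a", 50)], [0.9])


class TestSolveFractions:
    def test_two_strain_unique_solution(self):
        f = solve_fractions([strain("a", 40), strain("b", 60)], 47.0)
        np.testing.assert_allclose(f, [0.65, 0.35], atol=1e-9)

    def test_prior_attained_at_uniform_gc(self):
        strains = [strain("a", 40), strain("b", 50), strain("c", 60)]
        f = solve_fractions(strains, 50.0)
        np.testing.assert_allclose(f, [1 / 3] * 3, atol=1e-9)

    def test_infeasible_target_names_range(self):
        with pytest.raises(InfeasibleTargetError) as err:
            solve_fractions([strain("a", 40), strain("b", 60)], 70.0)
        assert err.value.lo == 40 and err.value.hi == 60

    def test_paper_targets_round_trip_on_18_strain_pool(self):
        rng = np.random.default_rng(0)
        strains = [
            strain(f"s{i}", float(g))
            for i, g in enumerate(rng.uniform(30, 70, size=18))
        ]
        for target in (47, 50, 53, 57, 60, 63):
            f = solve_fractions(strains, target)
            assert abs(f.sum() - 1) < 1e-12
            assert (f >= 0).all()
            assert weighted_gc(strains, f) == pytest.approx(target, abs=1e-9)


class TestExpectedAbundance:
    def test_single_gene(self):
        s = strain("a", 50, genes={"nifH": 2})
        assert expected_abundance([s], [1.0]) == {"nifH": 100.0}

    def test_dosage_proportional_to_copies_over_length(self):
        a = strain("a", 50, length=2_000_000, genes={"g1": 1})
        b = strain("b", 50, length=4_000_000, genes={"g2": 1})
        out = expected_abundance([a, b], [0.5, 0.5])
        assert out["g1"] == pytest.approx(200 / 3, abs=1e-9)
        assert out["g2"] == pytest.approx(100 / 3, abs=1e-9)

    def test_sums_to_100(self):
        rng = np.random.default_rng(1)
        strains = [
            strain(f"s{i}", 50, length=int(rng.integers(1, 5) * 1e6),
                   genes={f"g{j}": int(rng.integers(0, 4)) for j in range(5)})
            for i in range(6)
        ]
        f = np.full(6, 1 / 6)
        assert sum(expected_abundance(strains, f).values()) == pytest.approx(100, abs=1e-9)

    def test_invariant_under_uniform_length_scaling(self):
        strains = [
            strain("a", 50, length=1_000_000, genes={"g1": 2, "g2": 1}),
            strain("b", 50, length=3_000_000, genes={"g2": 3}),
        ]
        scaled = [
            strain("a", 50, length=7_000_000, genes={"g1": 2, "g2": 1}),
            strain("b", 50, length=21_000_000, genes={"g2": 3}),
        ]
        f = [0.4, 0.6]
        for k, v in expected_abundance(strains, f).items():
            assert expected_abundance(scaled, f)[k] == pytest.approx(v, abs=1e-9)

    def test_no_genes_rejected(self):
        with pytest.raises(ValidationError):
            expected_abundance([strain("a", 50)], [1.0])

    def test_deep_fragment_simulation_consistency(self, registry):
        # unbiased fragment truth tallies converge on the dosage formula
        # (equal gene lengths so fragment-overlap windows are comparable)
        from probecap.capture_sim import fragment_pool
        from probecap.mock_community import synth_reference_set

        refset = synth_reference_set(registry, seed=31, codon_range=(240, 241))
        fams = ["nifH", "nosZ", "mcrA"]
        strains, genomes, truth = [], {}, {}
        for i, gc in enumerate((45.0, 55.0, 62.0)):
            genes = {f: (i + 1, 0.05) for f in fams}
            spec, genome, ivs = synth_strain(
                f"s{i}", 30_000 * (i + 1), gc, genes, refset, seed=100 + i
            )
            strains.append(spec)
            genomes[spec.name] = genome
            truth[spec.name] = ivs
        design = MockDesign.from_target_gc(strains, 53.0)
        frags = fragment_pool(design, genomes, 150_000, mean_len=400, seed=5, truth=truth)
        tally = {}
        for fr in frags:
            for fam in fr.truth_families:
                tally[fam] = tally.get(fam, 0) + 1
        total = sum(tally.values())
        observed = {f: 100 * c / total for f, c in tally.items()}
        for fam, pct in design.expected_abundance.items():
            assert observed[fam] == pytest.approx(pct, abs=1.0)


class TestMutateCds:
    def test_zero_divergence_identity(self, refset):
        cds = refset["nifH"].cds
        assert mutate_cds(cds, 0.0, np.random.default_rng(0)) == cds

    def test_no_internal_stops(self, refset):
        rng = np.random.default_rng(3)
        for _ in range(20):
            mutated = mutate_cds(refset["nosZ"].cds, 0.3, rng)
            assert "*" not in str(Seq(mutated).translate())

    def test_gc_weighting_shifts_composition(self, refset):
        cds = refset["mcrA"].cds
        lo = mutate_cds(cds, 0.5, np.random.default_rng(1), gc_weight=0.2)
        hi = mutate_cds(cds, 0.5, np.random.default_rng(1), gc_weight=0.8)
        assert gc_fraction(lo) < gc_fraction(hi)


class TestSynthStrain:
    def test_background_gc_close_to_request(self, refset):
        spec, genome, truth = synth_strain("s", 100_000, 42.0, {}, refset, seed=1)
        assert truth == []
        assert abs(spec.gc_molpercent - 42.0) < 1.5
        assert len(genome) == 100_000

    def test_zero_divergence_plants_consensus(self, refset):
        spec, genome, truth = synth_strain(
            "s", 20_000, 50.0, {"nifH": (1, 0.0)}, refset, seed=2
        )
        iv = truth[0]
        planted = genome[iv.start : iv.end]
        if iv.strand == "-":
            planted = revcomp(planted)
        assert planted == refset["nifH"].cds

    def test_seed_determinism(self, refset):
        a = synth_strain("s", 20_000, 50.0, {"nifH": (2, 0.1)}, refset, seed=3)
        b = synth_strain("s", 20_000, 50.0, {"nifH": (2, 0.1)}, refset, seed=3)
        assert a[1] == b[1]
        assert a[2] == b[2]

    def test_truth_intervals_disjoint_and_translatable(self, refset):
        spec, genome, truth = synth_strain(
            "s", 40_000, 55.0,
            {"nifH": (3, 0.1), "nosZ": (2, 0.1), "mcrA": (2, 0.1)},
            refset, seed=4,
        )
        ivs = sorted((t.start, t.end) for t in truth)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2
        for t in truth:
            seq = genome[t.start : t.end]
            if t.strand == "-":
                seq = revcomp(seq)
            assert "*" not in str(Seq(seq).translate())

    def test_overcrowded_rejected(self, refset):
        with pytest.raises(PlacementError):
            synth_strain("s", 1_000, 50.0, {"nifH": (10, 0.1)}, refset, seed=5)


class TestIO:
    def test_volume_conversion(self):
        f = volume_to_mass_fractions([10, 10], [5.0, 15.0])
        np.testing.assert_allclose(f, [0.25, 0.75])

    def test_strains_tsv_round_trip(self, tmp_path):
        strains = [
            StrainSpec("a", 1000, 47.5, {"nifH": 2}, dna_concentration=12.5),
            StrainSpec("b", 2000, 60.0, {}, kind="fragment"),
        ]
        write_strains_tsv(strains, tmp_path / "s.tsv")
        loaded = read_strains_tsv(tmp_path / "s.tsv")
        assert loaded == strains

    def test_design_json_round_trip(self, tmp_path):
        strains = [strain("a", 40, genes={"g": 1}), strain("b", 60, genes={"h": 2})]
        design = MockDesign.from_target_gc(strains, 47.0)
        design.to_json(tmp_path / "d.json")
        loaded = MockDesign.from_json(tmp_path / "d.json")
        assert loaded.weighted_gc == pytest.approx(design.weighted_gc)
        np.testing.assert_allclose(loaded.mass_fractions, design.mass_fractions)
        assert loaded.expected_abundance == design.expected_abundance

    def test_truth_bed_round_trip(self, tmp_path, refset):
        _, _, truth = synth_strain("s", 20_000, 50.0, {"nifH": (2, 0.1)}, refset, seed=6)
        write_truth_bed({"s": truth}, tmp_path / "t.bed")
        loaded = read_truth_bed(tmp_path / "t.bed")
        assert loaded["s"] == truth
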