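import inspect
import math

import numpy as np
import pytest

from conftest import mutate, random_seq
from probecap._pairwise import revcomp
from probecap.capture_sim import (
    CaptureModel,
    Fragment,
    fragment_pool,
    hybridize,
    sequence_reads,
)
from probecap.mock_community import MockDesign, StrainSpec, synth_strain
from probecap.probe_design import Cluster, assemble_panel, design_probes


def two_strain_design(rng, lengths=(60_000, 60_000), gcs=(45.0, 55.0), fractions=(0.7, 0.3)):
    strains = [
        StrainSpec(name=f"s{i}", length_bp=lengths[i], gc_molpercent=gcs[i], gene_copies={})
        for i in range(2)
    ]
    genomes = {f"s{i}": random_seq(lengths[i], rng) for i in range(2)}
    design = MockDesign(
        strains=strains,
        mass_fractions=np.array(fractions),
        weighted_gc=sum(f * g for f, g in zip(fractions, gcs)),
        expected_abundance={},
    )
    return design, genomes


class TestFragmentPool:
    def test_zero_fragments(self):
        rng = np.random.default_rng(0)
        design, genomes = two_strain_design(rng)
        assert fragment_pool(design, genomes, 0) == []

    def test_default_mean_insert_630(self):
        sig = inspect.signature(fragment_pool)
        assert sig.parameters["mean_len"].default == 630.0

    def test_strain_sampling_within_binomial_bounds(self):
        rng = np.random.default_rng(1)
        design, genomes = two_strain_design(rng)
        frags = fragment_pool(design, genomes, 10_000, seed=42)
        n0 = sum(1 for f in frags if f.strain == "s0")
        expect, sd = 7000, math.sqrt(10_000 * 0.7 * 0.3)
        assert abs(n0 - expect) <= 3 * sd

    def test_fragment_sequences_match_source(self):
        rng = np.random.default_rng(2)
        design, genomes = two_strain_design(rng)
        for frag in fragment_pool(design, genomes, 50, seed=7):
            source = genomes[frag.strain][frag.start : frag.end]
            expect = source if frag.strand == "+" else revcomp(source)
            assert frag.sequence == expect
            assert len(frag) == frag.end - frag.start >= 50

    def test_truth_attachment_threshold(self, refset):
        spec, genome, truth = synth_strain(
            "s0", 30_000, 50.0, {"nifH": (3, 0.05)}, refset, seed=9
        )
        design = MockDesign(
            strains=[spec],
            mass_fractions=np.array([1.0]),
            weighted_gc=spec.gc_molpercent,
            expected_abundance={"nifH": 100.0},
        )
        frags = fragment_pool(design, {"s0": genome}, 2000, seed=3, truth={"s0": truth})
        for frag in frags:
            overlap = max(
                (min(frag.end, iv.end) - max(frag.start, iv.start) for iv in truth),
                default=0,
            )
            assert (overlap >= 50) == ("nifH" in frag.truth_families)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        design, genomes = two_strain_design(rng)
        a = fragment_pool(design, genomes, 100, seed=5)
        b = fragment_pool(design, genomes, 100, seed=5)
        assert a == b


class TestCaptureModel:
    def test_formula_oracle(self):
        model = CaptureModel()  # defaults: p_max=.95 kappa=30 x0=.8 bias on
        got = model.capture_probability(1.0, 0.5)
        expect = 0.95 * (1.0 / (1.0 + math.exp(-30.0 * (1.0 - 0.8)))) * (0.2 + 1.0 * 0.5)
        assert got == pytest.approx(expect, abs=1e-15)

    def test_bias_off_gc_term_is_one(self):
        model = CaptureModel(gc_bias_enabled=False)
        assert model.gc_term(0.1) == model.gc_term(0.9) == 1.0

    def test_gc_term_clamped(self):
        model = CaptureModel(gamma0=0.2, gamma1=1.0)
        assert model.gc_term(0.95) == 1.0
        assert CaptureModel(gamma0=-1.0).gc_term(0.1) == 0.0

    def test_monotone_in_identity_and_gc(self):
        model = CaptureModel()
        xs = np.linspace(0, 1, 21)
        ps = [model.capture_probability(x, 0.5) for x in xs]
        assert all(b >= a for a, b in zip(ps, ps[1:]))
        gs = [model.capture_probability(0.9, g) for g in xs]
        assert all(b >= a for a, b in zip(gs, gs[1:]))

    def test_perfect_match_limit(self):
        model = CaptureModel(p_max=1.0, kappa=1000.0, x0=0.8, gc_bias_enabled=False)
        assert model.capture_probability(1.0, 0.5) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_pmax(self):
        with pytest.raises(ValueError):
            CaptureModel(p_max=1.5)


def panel_from(seqs, rng):
    per_cluster = []
    for i, s in enumerate(seqs):
        per_cluster.append(
            design_probes(Cluster(f"c{i}", (f"c{i}",), 0.8), {f"c{i}": s}, family=f"f{i}")
        )
    return assemble_panel(per_cluster)


class TestHybridize:
    def test_empty_panel(self):
        rng = np.random.default_rng(0)
        frag = Fragment("f0", "s0", 0, 100, "+", random_seq(100, rng))
        assert hybridize([frag], assemble_panel([]), CaptureModel()) == []

    def test_exact_match_always_captured(self):
        rng = np.random.default_rng(1)
        gene = random_seq(300, rng)
        panel = panel_from([gene], rng)
        model = CaptureModel(p_max=1.0, kappa=1000.0, x0=0.8, gc_bias_enabled=False)
        frags = [
            Fragment(f"f{i}", "s0", 0, 400, "+", random_seq(50, rng) + gene + random_seq(50, rng))
            for i in range(20)
        ]
        captured = hybridize(frags, panel, model, seed=2)
        assert len(captured) == 20

    def test_probe_free_fragments_rarely_captured(self):
        rng = np.random.default_rng(3)
        gene = random_seq(300, rng)
        panel = panel_from([gene], rng)
        model = CaptureModel(p_max=1.0, kappa=1000.0, x0=0.8, gc_bias_enabled=False)
        frags = [
            Fragment(f"f{i}", "s0", 0, 600, "+", random_seq(600, rng)) for i in range(200)
        ]
        captured = hybridize(frags, panel, model, seed=4)
        assert len(captured) <= 2  # measurable enrichment

    def test_captured_subset_of_pool(self):
        rng = np.random.default_rng(5)
        gene = random_seq(300, rng)
        panel = panel_from([gene], rng)
        frags = [
            Fragment(f"f{i}", "s0", 0, 500, "+",
                     mutate(gene, 0.1, rng) + random_seq(200, rng))
            for i in range(30)
        ]
        captured = hybridize(frags, panel, CaptureModel(), seed=6)
        assert set(f.id for f in captured) <= set(f.id for f in frags)

    def test_reverse_strand_fragment_captured(self):
        rng = np.random.default_rng(7)
        gene = random_seq(300, rng)
        panel = panel_from([gene], rng)
        model = CaptureModel(p_max=1.0, kappa=1000.0, x0=0.8, gc_bias_enabled=False)
        frag = Fragment("f0", "s0", 0, 300, "-", revcomp(gene))
        assert len(hybridize([frag], panel, model, seed=8)) == 1

    def test_determinism(self):
        rng = np.random.default_rng(9)
        gene = random_seq(300, rng)
        panel = panel_from([gene], rng)
        frags = [
            Fragment(f"f{i}", "s0", 0, 350, "+", mutate(gene, 0.15, rng) + random_seq(50, rng))
            for i in range(40)
        ]
        a = hybridize(frags, panel, CaptureModel(), seed=10)
        b = hybridize(frags, panel, CaptureModel(), seed=10)
        assert [f.id for f in a] == [f.id for f in b]


class TestSequenceReads:
    def test_error_free_reads_are_substrings(self):
        rng = np.random.default_rng(0)
        frags = [Fragment(f"f{i}", "s0", 0, 700, "+", random_seq(700, rng)) for i in range(5)]
        readset = sequence_reads(frags, read_len=300, error_rate=0.0, seed=1)
        for pair, frag in zip(readset, frags):
            assert pair.seq1 == frag.sequence[:300]
            assert pair.seq2 == revcomp(frag.sequence)[:300]

    def test_default_read_length_300(self):
        sig = inspect.signature(sequence_reads)
        assert sig.parameters["read_len"].default == 300

    def test_short_fragment_truncated(self):
        rng = np.random.default_rng(2)
        frag = Fragment("f0", "s0", 0, 80, "+", random_seq(80, rng))
        readset = sequence_reads([frag], read_len=300)
        assert len(readset.pairs[0].seq1) == 80

    def test_error_rate_within_binomial_bounds(self):
        rng = np.random.default_rng(3)
        frags = [Fragment(f"f{i}", "s0", 0, 500, "+", random_seq(500, rng)) for i in range(200)]
        readset = sequence_reads(frags, read_len=250, error_rate=0.01, seed=4)
        mismatches = total = 0
        for pair, frag in zip(readset, frags):
            ref1 = frag.sequence[:250]
            ref2 = revcomp(frag.sequence)[:250]
            mismatches += sum(a != b for a, b in zip(pair.seq1, ref1))
            mismatches += sum(a != b for a, b in zip(pair.seq2, ref2))
            total += len(ref1) + len(ref2)
        sd = math.sqrt(total * 0.01 * 0.99)
        assert abs(mismatches - total * 0.01) <= 3 * sd

    def test_provenance_and_fastq(self, tmp_path):
        rng = np.random.default_rng(5)
        frags = [
            Fragment(f"f{i}", "s0", 0, 400, "+", random_seq(400, rng),
                     truth_families=frozenset({"nifH"}) if i % 2 else frozenset())
            for i in range(6)
        ]
        readset = sequence_reads(frags, seed=6)
        assert len(readset) == 6
        assert readset.on_target_fraction == 0.5
        r1, r2 = readset.write_fastq(tmp_path / "reads")
        from Bio import SeqIO

        reads1 = list(SeqIO.parse(str(r1), "fastq"))
        reads2 = list(SeqIO.parse(str(r2), "fastq"))
        assert len(reads1) == len(reads2) == 6
        readset.write_provenance(tmp_path / "prov.tsv")
        lines = (tmp_path / "prov.tsv").read_text().splitlines()
        assert len(lines) == 7
        frag_ids = {f.id for f in frags}
        for line in lines[1:]:
            assert line.split("\t")[1] in frag_ids
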