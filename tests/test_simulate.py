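import math

import numpy as np
import pytest

from compmap._fasta import revcomp, write_fasta
from compmap.pmd import DamageModel, damage_probability
from compmap.simulate import (
    FragmentLengthModel,
    SimConfig,
    apply_damage,
    apply_sequencing_errors,
    load_truth_tsv,
    random_genome,
    sample_fragments,
    simulate_dataset,
)


class TestSampleFragments:
    def test_n_zero(self, rng):
        genome = random_genome(rng, 1000)
        assert sample_fragments(genome, FragmentLengthModel(), 0, rng) == []

    def test_determinism(self):
        genome = random_genome(np.random.default_rng(7), 5000)
        a = sample_fragments(genome, FragmentLengthModel(), 50,
                             np.random.default_rng(42))
        b = sample_fragments(genome, FragmentLengthModel(), 50,
                             np.random.default_rng(42))
        assert a == b

    def test_fragments_are_genome_substrings(self, rng):
        genome = random_genome(rng, 5000)
        for chrom, start, end, strand, seq in sample_fragments(
            genome, FragmentLengthModel(), 100, rng
        ):
            sub = genome[chrom][start:end]
            assert seq == (sub if strand == "+" else revcomp(sub))
            assert end - start == len(seq)

    def test_median_length_matches_monte_carlo(self):
        model = FragmentLengthModel(mean_log=4.0, sd_log=0.3, min_len=30, max_len=150)
        genome = random_genome(np.random.default_rng(3), 10_000)
        frags = sample_fragments(genome, model, 10_000, np.random.default_rng(11))
        lengths = np.array([e - s for _c, s, e, _st, _seq in frags])
        # independent Monte-Carlo oracle of the truncated-lognormal median
        draws = np.random.default_rng(999).lognormal(4.0, 0.3, 400_000)
        draws = np.round(draws)
        draws = draws[(draws >= 30) & (draws <= 150)]
        oracle_median = np.median(draws)
        se = np.std(lengths) / math.sqrt(len(lengths))  # conservative scale
        assert abs(np.median(lengths) - oracle_median) <= 3 * max(se, 1.0)

    def test_genome_too_short_errors(self, rng):
        genome = {"c": "ACGT"}
        with pytest.raises(ValueError):
            sample_fragments(genome, FragmentLengthModel(min_len=30), 5, rng)


class TestApplyDamage:
    def test_null_model_identity(self, rng):
        seq = "ACGTCCGGAT" * 5
        out, n = apply_damage(seq, DamageModel(p=0.0, c=0.0), rng)
        assert out == seq
        assert n == 0

    def test_boundary_parameters(self, rng):
        out, n = apply_damage("CCCC", DamageModel(p=1.0, c=0.0), rng)
        assert out == "TCCC"
        assert n == 1

    def test_only_c_and_g_change(self, rng):
        seq = "ACGT" * 25
        out, _ = apply_damage(seq, DamageModel(p=0.9, c=0.3), rng)
        for before, after in zip(seq, out):
            if before == "A" or before == "T":
                assert after == before
            elif before == "C":
                assert after in "CT"
            else:
                assert after in "GA"

    def test_rate_calibration_z1(self):
        model = DamageModel(p=0.3, c=0.01)
        rng = np.random.default_rng(5)
        n = 20_000
        hits = 0
        for _ in range(n):
            out, _ = apply_damage("C" + "A" * 20, model, rng)
            hits += out[0] == "T"
        d1 = damage_probability(1, model)
        sd = math.sqrt(n * d1 * (1 - d1))
        assert abs(hits - n * d1) <= 3 * sd

    def test_g_damage_anchored_at_3prime(self):
        model = DamageModel(p=0.3, c=0.0)
        rng = np.random.default_rng(6)
        n = 20_000
        hits = 0
        for _ in range(n):
            out, _ = apply_damage("A" * 20 + "G", model, rng)
            hits += out[-1] == "A"
        d1 = damage_probability(1, model)
        sd = math.sqrt(n * d1 * (1 - d1))
        assert abs(hits - n * d1) <= 3 * sd


class TestApplySequencingErrors:
    def test_zero_rate(self, rng):
        seq = "ACGT" * 10
        out, quals = apply_sequencing_errors(seq, 0.0, rng)
        assert out == seq
        assert quals == [41] * 40

    def test_phred_definition(self, rng):
        _out, quals = apply_sequencing_errors("ACGT" * 10, 0.001, rng)
        assert set(quals) == {30}

    def test_binomial_calibration(self):
        rng = np.random.default_rng(8)
        seq = "A" * 1_000_000
        out, _ = apply_sequencing_errors(seq, 0.01, rng)
        n_sub = sum(1 for a, b in zip(seq, out) if a != b)
        sd = math.sqrt(1_000_000 * 0.01 * 0.99)
        assert abs(n_sub - 10_000) <= 3 * sd

    def test_substitutions_change_base(self, rng):
        seq = "ACGT" * 250
        out, _ = apply_sequencing_errors(seq, 0.2, rng)
        assert len(out) == len(seq)
        assert set(out) <= set("ACGT")


class TestSimulateDataset:
    def _config(self, tmp_path, rng, **kwargs):
        target = random_genome(rng, 10_000, chrom="chrT")
        contaminant = random_genome(rng, 10_000, chrom="chrH")
        t_path, h_path = tmp_path / "t.fa", tmp_path / "h.fa"
        write_fasta(target, t_path)
        write_fasta(contaminant, h_path)
        defaults = dict(
            target_genome=str(t_path),
            contaminant_genome=str(h_path),
            n_reads=500,
            contamination_fraction=0.1,
            seed=21,
        )
        defaults.update(kwargs)
        return SimConfig(**defaults)

    def test_contaminant_count_near_expectation(self, tmp_path, rng):
        cfg = self._config(tmp_path, rng, n_reads=2000, contamination_fraction=0.1)
        result = simulate_dataset(cfg, tmp_path / "out")
        n_cont = sum(1 for t in result.truth if t.origin == "contaminant")
        sd = math.sqrt(2000 * 0.1 * 0.9)
        assert abs(n_cont - 200) <= 3 * sd

    def test_zero_contamination(self, tmp_path, rng):
        cfg = self._config(tmp_path, rng, contamination_fraction=0.0)
        result = simulate_dataset(cfg, tmp_path / "out")
        assert all(t.origin == "target" for t in result.truth)

    def test_same_seed_byte_identical(self, tmp_path, rng):
        cfg = self._config(tmp_path, rng)
        r1 = simulate_dataset(cfg, tmp_path / "a")
        r2 = simulate_dataset(cfg, tmp_path / "b")
        for attr in ("fastq", "truth_tsv", "truth_sam", "manifest_tsv"):
            assert (getattr(r1, attr).read_bytes()
                    == getattr(r2, attr).read_bytes()), attr

    def test_fastq_names_match_truth(self, tmp_path, rng):
        cfg = self._config(tmp_path, rng, n_reads=50)
        result = simulate_dataset(cfg, tmp_path / "out")
        lines = result.fastq.read_text().splitlines()
        fastq_names = [lines[i][1:] for i in range(0, len(lines), 4)]
        assert fastq_names == [t.read_name for t in result.truth]

    def test_truth_tsv_round_trip(self, tmp_path, rng):
        cfg = self._config(tmp_path, rng, n_reads=50)
        result = simulate_dataset(cfg, tmp_path / "out")
        assert load_truth_tsv(result.truth_tsv) == result.truth

    def test_undamaged_error_free_reads_are_genome_substrings(self, tmp_path, rng):
        from compmap._fasta import read_fasta

        cfg = self._config(
            tmp_path, rng, n_reads=100, error_rate=0.0,
            damage_target=DamageModel(p=0.0, c=0.0),
            damage_contaminant=DamageModel(p=0.0, c=0.0),
        )
        result = simulate_dataset(cfg, tmp_path / "out")
        genomes = {
            "target": read_fasta(cfg.target_genome),
            "contaminant": read_fasta(cfg.contaminant_genome),
        }
        lines = result.fastq.read_text().splitlines()
        seqs = {lines[i][1:]: lines[i + 1] for i in range(0, len(lines), 4)}
        for t in result.truth:
            sub = genomes[t.origin][t.chrom][t.start : t.end]
            expected = sub if t.strand == "+" else revcomp(sub)
            assert seqs[t.read_name] == expected

    def test_truth_sam_matches_reference(self, tmp_path, rng):
        import pysam

        cfg = self._config(tmp_path, rng, n_reads=80)
        result = simulate_dataset(cfg, tmp_path / "out")
        with pysam.AlignmentFile(str(result.truth_sam)) as fh:
            names = set(fh.references)
            assert names == {"target|chrT", "human|chrH"}
            records = list(fh)
        assert len(records) == 80
        by_name = {t.read_name: t for t in result.truth}
        for rec in records:
            truth = by_name[rec.query_name]
            assert rec.reference_start == truth.start
            assert rec.mapping_quality == 60

    def test_damage_events_only_with_damage_enabled(self, tmp_path, rng):
        cfg = self._config(
            tmp_path, rng, contamination_fraction=1.0,
            damage_contaminant=DamageModel(p=0.0, c=0.0),
        )
        result = simulate_dataset(cfg, tmp_path / "out")
        assert all(t.n_damage_events == 0 for t in result.truth)

    def test_config_validation(self, tmp_path, rng):
        with pytest.raises(ValueError):
            self._config(tmp_path, rng, contamination_fraction=1.5)
        with pytest.raises(ValueError):
            self._config(tmp_path, rng, error_rate=1.0)
        with pytest.raises(ValueError):
            self._config(tmp_path, rng, n_reads=-1)

    def test_toml_config_round_trip(self, tmp_path, rng):
        cfg = self._config(tmp_path, rng)
        toml_path = tmp_path / "sim.toml"
        toml_path.write_text(
            f'target_genome = "{cfg.target_genome}"\n'
            f'contaminant_genome = "{cfg.contaminant_genome}"\n'
            "n_reads = 500\n"
            "contamination_fraction = 0.1\n"
            "seed = 21\n"
            "target_damage_p = 0.25\n"
            "target_fraglen_mean_log = 3.9\n"
        )
        loaded = SimConfig.from_toml(toml_path)
        assert loaded.n_reads == 500
        assert loaded.damage_target.p == 0.25
        assert loaded.fraglen_target.mean_log == 3.9
        assert loaded.damage_contaminant.p == 0.0

    def test_competitive_mapq_flags_shared_fragments(self, tmp_path, rng):
        import pysam

        from conftest import plant_segment
        from compmap._fasta import read_fasta

        target = random_genome(rng, 10_000, chrom="chrT")
        contaminant = random_genome(rng, 10_000, chrom="chrH")
        contaminant["chrH"] = plant_segment(
            target["chrT"], contaminant["chrH"], 2000, 5000, 1000
        )
        t_path, h_path = tmp_path / "t.fa", tmp_path / "h.fa"
        write_fasta(target, t_path)
        write_fasta(contaminant, h_path)
        cfg = SimConfig(
            target_genome=str(t_path), contaminant_genome=str(h_path),
            n_reads=400, contamination_fraction=0.0, seed=9,
            competitive_mapq=True,
        )
        result = simulate_dataset(cfg, tmp_path / "out")
        by_name = {t.read_name: t for t in result.truth}
        with pysam.AlignmentFile(str(result.truth_sam)) as fh:
            for rec in fh:
                truth = by_name[rec.query_name]
                inside_plant = 2000 <= truth.start and truth.end <= 3000
                if inside_plant:
                    assert rec.mapping_quality == 0
                elif truth.end <= 2000 or truth.start >= 3000:
                    assert rec.mapping_quality == 60

    def test_original_sam_contains_only_target_reads(self, tmp_path, rng):
        import pysam

        cfg = self._config(tmp_path, rng, contamination_fraction=0.3)
        result = simulate_dataset(cfg, tmp_path / "out", emit_original_sam=True)
        target_names = {t.read_name for t in result.truth if t.origin == "target"}
        with pysam.AlignmentFile(str(result.original_sam)) as fh:
            assert fh.references == ("chrT",)
            names = {r.query_name for r in fh}
        assert names == target_names
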