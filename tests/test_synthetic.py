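"""Synthetic locus/read generator: repair-outcome structure and round trips."""

import numpy as np
import pytest

from puftyper import (
    EmptyProfileError,
    IndelCall,
    RepairModel,
    bray_curtis,
    generate_locus,
    perturb_profile,
    profile_sample,
    sample_outcome_distribution,
    sample_puf,
    shannon_entropy,
    simulate_background_library,
)
from puftyper.errors import ConfigurationError
from puftyper.indel import DELETION, INSERTION
from puftyper.simulate import MasterDistribution
from puftyper.synthetic import emit_fastq


@pytest.fixture(scope="module")
def cg_locus():
    return generate_locus(length=120, cut_flank="CG", seed=5)


@pytest.fixture(scope="module")
def tdt_master(cg_locus):
    return sample_outcome_distribution(
        cg_locus, RepairModel.cas9_tdt(), n_unique=2000, seed=6
    )


def kind_mass(master, kind):
    return sum(
        p for k, p in zip(master.keys, master.probs)
        if IndelCall.from_key(k).kind == kind
    )


class TestGenerateLocus:
    @pytest.mark.parametrize("flank", ["CG", "AT", "CT"])
    def test_flank_dinucleotide_spans_cut(self, flank):
        locus = generate_locus(length=100, cut_flank=flank, seed=1)
        assert locus.flank_dinucleotide == flank

    def test_fixed_seed_reproducible(self):
        a = generate_locus(length=100, cut_flank="CG", seed=2)
        b = generate_locus(length=100, cut_flank="CG", seed=2)
        assert a.sequence == b.sequence

    def test_too_short_amplicon_errors(self):
        with pytest.raises(ConfigurationError):
            generate_locus(length=40)


class TestOutcomeDistribution:
    def test_tdt_insertion_mass_near_eighty_percent(self, tdt_master):
        assert kind_mass(tdt_master, INSERTION) == pytest.approx(0.80, abs=0.02)

    def test_cas9_only_deletion_mass_near_eighty_four_percent(self, cg_locus):
        with pytest.warns(UserWarning, match="unique indels"):
            master = sample_outcome_distribution(
                cg_locus, RepairModel.cas9_only(), n_unique=2000, seed=7
            )
        assert kind_mass(master, DELETION) == pytest.approx(0.84, abs=0.02)

    def test_pure_insertion_model_yields_only_insertions(self, cg_locus):
        model = RepairModel.cas9_tdt(insertion_fraction=1.0)
        master = sample_outcome_distribution(cg_locus, model, n_unique=200, seed=8)
        assert kind_mass(master, INSERTION) == pytest.approx(1.0)

    def test_top20_capture_over_thirty_percent(self, tdt_master):
        top20 = np.sort(tdt_master.probs)[::-1][:20].sum()
        assert top20 > 0.30

    def test_top_insertions_carry_flank_bases(self, tdt_master):
        """At a CG cut most frequent insertions should contain C and/or G."""
        order = np.argsort(-tdt_master.probs)
        top_ins = [
            IndelCall.from_key(tdt_master.keys[i])
            for i in order
            if IndelCall.from_key(tdt_master.keys[i]).kind == INSERTION
        ][:20]
        with_flank = sum(1 for c in top_ins if set(c.bases) & {"C", "G"})
        assert with_flank / len(top_ins) >= 0.85

    def test_deletion_windows_stay_inside_the_flexible_region(self, tdt_master):
        # left-aligned canonical windows must fit in cut +/- 20 bp
        for key in tdt_master.keys:
            call = IndelCall.from_key(key)
            if call.kind == DELETION:
                assert -20 <= call.offset
                assert call.offset + call.length <= 20


class TestEmitFastq:
    def error_free_model(self, **overrides):
        return RepairModel.cas9_tdt(error_rate=0.0, **overrides)

    def test_all_wildtype_sample_has_no_indel_reads(self, cg_locus, tmp_path):
        model = self.error_free_model(
            wt_fraction=0.98, substitution_fraction=0.01, corrupted_fraction=0.009
        )
        dist = MasterDistribution.from_dict({"I+0:GG": 1.0})
        path = emit_fastq(cg_locus, dist, model, 300, seed=0, path=tmp_path / "r.fastq")
        # ~0.1% indel reads of 300 -> none; profiling must fail cleanly
        with pytest.raises(EmptyProfileError):
            profile_sample(path, cg_locus)

    def test_generation_calling_round_trip_is_exact(self, cg_locus, tmp_path):
        """Error-free reads: the caller recovers the generating indel of
        every read, so profile counts equal the truth table exactly."""
        import csv

        from puftyper import build_read_pattern
        from puftyper.indel import canonicalize

        # keys must be canonical for this locus so generated and called
        # indels use the same representation
        pattern = build_read_pattern(cg_locus)
        weights = {}
        for key, w in {"I+0:GG": 0.5, "I+0:C": 0.3, "D-1:CG": 0.2}.items():
            canon = canonicalize(
                pattern.ref_central, IndelCall.from_key(key), pattern.cut_index
            ).key
            weights[canon] = weights.get(canon, 0.0) + w
        dist = MasterDistribution.from_dict(weights)
        model = self.error_free_model()
        fq = tmp_path / "r.fastq"
        truth = tmp_path / "truth.tsv"
        emit_fastq(cg_locus, dist, model, 2000, seed=1, path=fq, truth_path=truth)
        profile, report = profile_sample(fq, cg_locus, sample_id="s")
        with open(truth) as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        truth_counts = {}
        for row in rows:
            if row["category"] == "indel":
                truth_counts[row["indel_key"]] = truth_counts.get(row["indel_key"], 0) + 1
        assert profile.counts == truth_counts
        assert report.n_indel == sum(truth_counts.values())
        assert report.n_complex == 0

    def test_contamination_fractions_partition_reads(self, cg_locus, tmp_path):
        dist = MasterDistribution.from_dict({"I+0:GG": 1.0})
        model = self.error_free_model()
        path = emit_fastq(cg_locus, dist, model, 1000, seed=2, path=tmp_path / "r.fastq")
        _, report = profile_sample(path, cg_locus)
        assert report.n_wildtype == 300
        assert report.n_substitution_only == 20
        assert report.n_corrupted == 30
        assert report.n_indel == 650

    def test_same_seed_is_byte_identical(self, cg_locus, tmp_path):
        dist = MasterDistribution.from_dict({"I+0:GG": 0.6, "D-1:CG": 0.4})
        model = RepairModel.cas9_tdt()
        a = emit_fastq(cg_locus, dist, model, 200, seed=3, path=tmp_path / "a.fastq")
        b = emit_fastq(cg_locus, dist, model, 200, seed=3, path=tmp_path / "b.fastq")
        assert a.read_bytes() == b.read_bytes()

    def test_gzip_output(self, cg_locus, tmp_path):
        dist = MasterDistribution.from_dict({"I+0:GG": 1.0})
        path = emit_fastq(
            cg_locus, dist, self.error_free_model(), 100, seed=4,
            path=tmp_path / "r.fastq.gz",
        )
        profile, _ = profile_sample(path, cg_locus)
        assert profile.n_reads > 0


class TestEntropyContrast:
    def test_tdt_profiles_are_more_entropic_than_cas9_only(self, cg_locus):
        """Insertion-dominant repair explores a far larger outcome space
        than deletion-dominant repair, so its profiles carry more bits."""
        tdt = sample_outcome_distribution(
            cg_locus, RepairModel.cas9_tdt(), n_unique=800, seed=10
        )
        with pytest.warns(UserWarning):
            cas9 = sample_outcome_distribution(
                cg_locus, RepairModel.cas9_only(), n_unique=800, seed=10
            )
        assert tdt.support_size > cas9.support_size
        p_tdt = sample_puf(tdt, 20_000, seed=11)
        p_cas9 = sample_puf(cas9, 20_000, seed=11)
        assert shannon_entropy(p_tdt) > shannon_entropy(p_cas9)


class TestPerturbProfile:
    def test_zero_drift_is_identity(self, tdt_master):
        p = sample_puf(tdt_master, 2000, seed=12)
        assert perturb_profile(p, 0.0, tdt_master, seed=13).counts == p.counts

    def test_full_drift_is_master_sample(self, tdt_master):
        p = sample_puf(tdt_master, 2000, seed=14)
        q = perturb_profile(p, 1.0, tdt_master, seed=15)
        assert q.n_reads == p.n_reads
        assert set(q.counts) <= set(tdt_master.keys)

    def test_bcd_grows_with_drift_in_expectation(self, tdt_master):
        drifts = (0.1, 0.4, 0.8)
        means = []
        for d in drifts:
            vals = []
            for s in range(10):
                p = sample_puf(tdt_master, 2000, seed=100 + s)
                q = perturb_profile(p, d, tdt_master, seed=200 + s)
                vals.append(bray_curtis(p, q))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestBackgroundLibrary:
    def test_structure_and_shared_background(self, tdt_master):
        lib = simulate_background_library(tdt_master, n_groups=3, n_replicates=1, seed=20)
        assert len(lib.profiles) == 6
        assert len(set(lib.groups.values())) == 3
        shared = set.intersection(*(set(p.counts) for p in lib.profiles))
        order = np.argsort(-tdt_master.probs)
        background = {tdt_master.keys[i] for i in order[:30]}
        assert shared  # the high-frequency background is present everywhere
        assert shared <= background
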