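"""VCF parsing, filtering, matrix construction, and per-sample counts."""

import numpy as np
import pytest

from retrophylo import (
    MeiCallSet,
    MeiLocus,
    build_matrix,
    filter_calls,
    per_sample_counts,
    read_mei_vcf,
    write_mei_vcf,
)
from retrophylo.matrix import (
    NexusFormatError,
    PresenceAbsenceMatrix,
    read_het_sidecar,
    read_nexus,
    write_het_sidecar,
    write_nexus,
)
from retrophylo.mei_io import GT_ABSENT, GT_HET, GT_HOM, GT_MISSING

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FILTER=<ID=lc,Description="low complexity">\n'
    "##contig=<ID=chr1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


def write_vcf(tmp_path, body, name="test.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadVcf:
    def test_genotype_state_mapping(self, tmp_path):
        body = (
            "chr1\t100\t.\tN\t<INS>\t.\tPASS\t.\tGT\t0/1\t1/1\n"
            "chr1\t200\t.\tN\t<INS>\t.\tPASS\t.\tGT\t0/0\t./.\n"
            "chr1\t300\t.\tN\t<INS>\t.\tPASS\t.\tGT\t1/1\t0/1\n"
        )
        calls = read_mei_vcf(write_vcf(tmp_path, body))
        assert calls.n_loci == 3 and calls.samples == ["S1", "S2"]
        expected = [[GT_HET, GT_HOM], [GT_ABSENT, GT_MISSING], [GT_HOM, GT_HET]]
        assert calls.genotypes.tolist() == expected

    def test_phased_and_half_calls(self, tmp_path):
        body = (
            "chr1\t100\t.\tN\t<INS>\t.\tPASS\t.\tGT\t0|1\t1|1\n"
            "chr1\t200\t.\tN\t<INS>\t.\tPASS\t.\tGT\t./1\t0/.\n"
        )
        calls = read_mei_vcf(write_vcf(tmp_path, body))
        assert calls.genotypes[0].tolist() == [GT_HET, GT_HOM]
        # half-calls are conservatively treated as missing
        assert calls.genotypes[1].tolist() == [GT_MISSING, GT_MISSING]

    def test_empty_body_gives_zero_loci(self, tmp_path):
        calls = read_mei_vcf(write_vcf(tmp_path, ""))
        assert calls.n_loci == 0 and calls.n_samples == 2

    def test_roundtrip_random_callsets(self, tmp_path):
        rng = np.random.default_rng(0)
        for rep in range(5):
            gt = rng.choice(
                [GT_ABSENT, GT_HET, GT_HOM, GT_MISSING], size=(20, 3)
            ).astype(np.int8)
            calls = MeiCallSet(
                loci=[MeiLocus("chr1", 10 * (i + 1)) for i in range(20)],
                samples=["a", "b", "c"],
                genotypes=gt,
            )
            path = tmp_path / f"rt{rep}.vcf"
            write_mei_vcf(calls, path)
            back = read_mei_vcf(path)
            assert np.array_equal(back.genotypes, gt)
            assert [l.pos for l in back.loci] == [l.pos for l in calls.loci]


class TestFilter:
    def make_calls(self):
        filters = ["PASS", "lc", "PASS", "ac0", "PASS", "lc"]
        return MeiCallSet(
            loci=[MeiLocus("c", i + 1, filter=f) for i, f in enumerate(filters)],
            samples=["s"],
            genotypes=np.ones((6, 1), dtype=np.int8),
        )

    def test_pass_only(self):
        assert filter_calls(self.make_calls()).n_loci == 3

    def test_keep_all_is_identity(self):
        calls = self.make_calls()
        kept = filter_calls(calls, {"PASS", "lc", "ac0"})
        assert [l.pos for l in kept.loci] == [l.pos for l in calls.loci]

    def test_idempotent(self):
        once = filter_calls(self.make_calls())
        twice = filter_calls(once)
        assert [l.pos for l in twice.loci] == [l.pos for l in once.loci]


class TestBuildMatrix:
    def test_states_and_het_flags(self):
        calls = MeiCallSet(
            loci=[MeiLocus("c", 1)],
            samples=["x", "y", "z"],
            genotypes=np.array([[GT_HET, GT_HOM, GT_ABSENT]], dtype=np.int8),
        )
        m = build_matrix(calls)
        assert m.states[:, 0].tolist() == [1, 1, 0]
        assert m.het_flags[:, 0].tolist() == [True, False, False]
        assert m.loci_ids == ["c:1"]

    def test_monomorphic_absent_column_dropped(self):
        calls = MeiCallSet(
            loci=[MeiLocus("c", 1), MeiLocus("c", 2)],
            samples=["x", "y"],
            genotypes=np.array([[0, 0], [1, 2]], dtype=np.int8),
        )
        m = build_matrix(calls)
        assert m.loci_ids == ["c:2"]

    def test_all_present_column_kept(self):
        calls = MeiCallSet(
            loci=[MeiLocus("c", 1)],
            samples=["x", "y"],
            genotypes=np.array([[2, 2]], dtype=np.int8),
        )
        assert build_matrix(calls).n_loci == 1

    def test_missing_becomes_question(self):
        calls = MeiCallSet(
            loci=[MeiLocus("c", 1)],
            samples=["x", "y"],
            genotypes=np.array([[GT_MISSING, GT_HOM]], dtype=np.int8),
        )
        assert build_matrix(calls).states[:, 0].tolist() == [-1, 1]


class TestSampleCounts:
    def test_direct_counts_and_totals(self):
        calls = MeiCallSet(
            loci=[MeiLocus("c", 1), MeiLocus("c", 2)],
            samples=["s1", "s2"],
            genotypes=np.array([[GT_HET, GT_MISSING], [GT_HOM, GT_ABSENT]], dtype=np.int8),
        )
        counts = per_sample_counts(calls)
        assert (counts[0].n_calls, counts[0].n_het) == (2, 1)
        assert (counts[1].n_calls, counts[1].n_het) == (0, 0)
        assert counts[-1].sample == "Total"
        assert counts[-1].n_calls == 2 and counts[-1].n_het == 1

    def test_counts_match_matrix_presences(self, conflict_free_truth):
        # conservation: summed per-sample calls equal presences in the matrix
        calls = conflict_free_truth.to_call_set()
        counts = per_sample_counts(calls, totals=False)
        m = build_matrix(calls)
        for c in counts:
            i = m.taxon_index(c.sample)
            assert c.n_calls == int((m.states[i] == 1).sum())
            assert c.n_het == int(m.het_flags[i].sum())


class TestNexus:
    def make_matrix(self):
        return PresenceAbsenceMatrix(
            taxa=["tax one", "tax_two"],
            loci_ids=["c:1", "c:2"],
            states=np.array([[1, 0], [1, -1]], dtype=np.int8),
            het_flags=np.array([[True, False], [False, False]]),
        )

    def test_roundtrip_preserves_states_and_order(self, tmp_path):
        m = self.make_matrix()
        path = tmp_path / "m.nex"
        write_nexus(m, path)
        back = read_nexus(path)
        assert back.taxa == ["tax_one", "tax_two"]
        assert np.array_equal(back.states, m.states)
        assert back.loci_ids == m.loci_ids

    def test_header_arithmetic(self, tmp_path):
        path = tmp_path / "m.nex"
        write_nexus(self.make_matrix(), path)
        text = path.read_text()
        assert "NTAX=2" in text and "NCHAR=2" in text
        assert "MISSING=?" in text

    def test_het_sidecar_roundtrip(self, tmp_path):
        m = self.make_matrix()
        write_nexus(m, tmp_path / "m.nex")
        write_het_sidecar(m, tmp_path / "m.het.tsv")
        back = read_het_sidecar(read_nexus(tmp_path / "m.nex"), tmp_path / "m.het.tsv")
        assert np.array_equal(back.het_flags, m.het_flags)

    def test_malformed_nexus_raises(self, tmp_path):
        bad = tmp_path / "bad.nex"
        bad.write_text("#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2;\nEND;\n")
        with pytest.raises(NexusFormatError):
            read_nexus(bad)

    def test_unexpected_symbol_names_offender(self, tmp_path):
        bad = tmp_path / "bad.nex"
        bad.write_text(
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=1 NCHAR=2;\n"
            'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n'
            "MATRIX\nA 2X\n;\nEND;\n"
        )
        with pytest.raises(NexusFormatError, match="A"):
            read_nexus(bad)


class TestInvariants:
    def test_het_only_where_present(self):
        with pytest.raises(ValueError):
            PresenceAbsenceMatrix(
                taxa=["a"],
                loci_ids=["l"],
                states=np.array([[0]], dtype=np.int8),
                het_flags=np.array([[True]]),
            )

    def test_zero_samples_rejected(self):
        calls = MeiCallSet(loci=[], samples=[], genotypes=np.empty((0, 0), dtype=np.int8))
        with pytest.raises(ValueError):
            build_matrix(calls)

    def test_simulated_matrix_roundtrips_through_vcf(self, tmp_path, conflict_free_truth):
        calls = conflict_free_truth.to_call_set()
        path = tmp_path / "sim.vcf"
        write_mei_vcf(calls, path)
        m = build_matrix(read_mei_vcf(path))
        assert m == conflict_free_truth.matrix.drop_absent_columns()
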