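"""Alignment, tree, table and config I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pterochron.errors import (
    AlignmentError,
    ConfigError,
    FormatError,
    SchemaError,
    TreeError,
)
from pterochron.formats import (
    GeneAlignment,
    RunConfig,
    read_alignment,
    read_config,
    read_newick_dated,
    read_table,
    write_alignment,
    write_config,
    write_newick_dated,
)


class TestAlignmentIO:
    def test_fasta_parse(self, tmp_path):
        p = tmp_path / "g1.fasta"
        p.write_text(">tax1\nMKVLA\n>tax2\nMKV-A\n")
        aln = read_alignment(p, "fasta")
        assert aln.gene_id == "g1"
        assert aln.length == 5 and aln.n_taxa == 2
        assert aln.rows["tax2"] == "MKV-A"

    def test_normalisation(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">t1\nmkv.x\n")
        assert read_alignment(p).rows["t1"] == "MKV-X"

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">t1\nMKVLA\n>t2\nMKVL\n")
        with pytest.raises(AlignmentError):
            read_alignment(p)

    def test_duplicate_taxon_rejected(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">t1\nMKVLA\n>t1\nMKVLA\n")
        with pytest.raises(FormatError):
            read_alignment(p)

    def test_invalid_residue_rejected(self):
        with pytest.raises(FormatError):
            GeneAlignment("g", {"t1": "MKO"})  # O is not an amino acid

    @pytest.mark.parametrize("dialect", ["fasta", "phylip"])
    def test_roundtrip(self, tmp_path, dialect):
        aln = GeneAlignment("g", {"t1": "MKVLA-X", "t2": "MKVLAAA"})
        p = tmp_path / f"g.{dialect}"
        write_alignment(aln, p, dialect)
        back = read_alignment(p, dialect)
        assert back.rows == aln.rows

    def test_phylip_header_mismatch(self, tmp_path):
        p = tmp_path / "g.phylip"
        p.write_text("2 5\nt1  MKVLA\nt2  MKV\n")
        with pytest.raises(AlignmentError):
            read_alignment(p, "phylip")


class TestDatedTreeIO:
    def test_ages_from_durations(self):
        t = read_newick_dated("((A:1,B:1):1,C:2);")
        assert t.root_age == pytest.approx(2.0)
        inner = t.mrca({"A", "B"})
        assert t.ages[inner] == pytest.approx(1.0)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(TreeError):
            read_newick_dated("((A:1,B:2):1,C:2);")

    def test_polytomy_rejected(self):
        with pytest.raises(TreeError):
            read_newick_dated("(A:1,B:1,C:1);")

    def test_roundtrip_preserves_ages(self, tmp_path):
        t = read_newick_dated("((A:12.5,B:12.5):37.5,(C:30,D:30):20);")
        p = tmp_path / "t.nwk"
        write_newick_dated(t, p)
        back = read_newick_dated(p)
        assert back.root_age == pytest.approx(t.root_age, rel=1e-9)
        assert sorted(back.ages) == pytest.approx(sorted(t.ages), rel=1e-9)

    def test_label_emission(self):
        t = read_newick_dated("((A:1,B:1):1,C:2);")
        nwk = t.to_newick(labels={t.mrca({"A", "B"}): "n1"})
        assert "n1" in nwk

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.1, max_value=50), min_size=3, max_size=3))
    def test_roundtrip_random_cherries(self, heights):
        a, b, c = sorted(heights)
        nwk = f"((A:{a},B:{a}):{c - a + 0.1},C:{c + 0.1});"
        t = read_newick_dated(nwk)
        back = read_newick_dated(t.to_newick())
        assert np.allclose(sorted(back.ages), sorted(t.ages), rtol=1e-9)

    def test_mrca(self):
        t = read_newick_dated("((A:1,B:1):1,C:2);")
        assert t.mrca({"A", "C"}) == t.root
        assert t.mrca({"A"}) < t.n_tips  # a tip is its own MRCA


class TestTables:
    def test_transcript_schema(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "transcript_id,dataset_id,lane_id,est_count,tpm,extra\n"
            "T1,A,1,3.5,10.0,zzz\nT2,A,1,1.0,5.0,zzz\nT3,B,1,2.0,7.0,zzz\n"
        )
        df = read_table(p, "transcript")
        assert len(df) == 3 and "extra" in df.columns

    def test_missing_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("transcript_id,dataset_id,est_count,tpm\nT1,A,1,2\n")
        with pytest.raises(SchemaError):
            read_table(p, "transcript")

    def test_negative_tpm(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "transcript_id,dataset_id,lane_id,est_count,tpm\nT1,A,1,1,-1\n"
        )
        with pytest.raises(ValueError):
            read_table(p, "transcript")

    def test_occurrence_stage_preserved(self, tmp_path):
        p = tmp_path / "o.csv"
        p.write_text("species,clade,stage,status\nX,Cavolinioidea,Ypresian,accepted\n")
        df = read_table(p, "occurrence")
        assert df.loc[0, "stage"] == "Ypresian"


class TestRunConfig:
    def test_seed_mandatory(self, tmp_path):
        p = tmp_path / "c.toml"
        p.write_text('clock_model = "CIR"\n')
        with pytest.raises(ConfigError):
            read_config(p)

    def test_iterations_exceed_burnin(self):
        with pytest.raises(ConfigError):
            RunConfig(seed=1, iterations=100, burn_in=100)

    def test_roundtrip(self, tmp_path):
        cfg = RunConfig(seed=7, iterations=500, burn_in=100, thinning=2)
        p = tmp_path / "c.toml"
        write_config(cfg, p)
        back = read_config(p)
        assert back == cfg
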