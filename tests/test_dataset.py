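"""Genotype tables, allele frequencies, DUI exclusion, diploid encoding."""

import pytest
from hypothesis import given, strategies as st

from mytilus_id.dataset import (
    DatasetError,
    MarkerGenotype,
    allele_frequencies,
    encode_mito_as_diploid,
    export_genepop,
    filter_dui,
    genepop_codes,
    read_genotype_table,
    write_genotype_table,
)


def write_table(tmp_path, rows):
    path = tmp_path / "genotypes.csv"
    header = "individual_id,population,marker,allele_1,allele_2\n"
    path.write_text(header + "\n".join(rows) + "\n")
    return path


class TestReadGenotypeTable:
    def test_raw_fragment_sizes_resolve_to_haplotype(self, tmp_path):
        path = write_table(tmp_path, ["X1,MCh-1,COI,134+99,"])
        ds = read_genotype_table(path)
        assert ds.individuals[0].genotypes["COI"].alleles == ("chilensis-cut",)

    def test_duplicate_allele_collapses_to_homozygote(self, tmp_path):
        path = write_table(tmp_path, ["X2,ME-1,Me15-16,180,180"])
        ds = read_genotype_table(path)
        assert ds.individuals[0].genotypes["Me15-16"].alleles == ("180-E", "180-E")

    def test_single_nuclear_allele_means_homozygote(self, tmp_path):
        path = write_table(tmp_path, ["X2,ME-1,Me15-16,180,"])
        ds = read_genotype_table(path)
        assert ds.individuals[0].genotypes["Me15-16"].alleles == ("180-E", "180-E")

    def test_blank_alleles_mean_missing(self, tmp_path):
        path = write_table(tmp_path, ["X3,MT-1,mac-1,,"])
        ds = read_genotype_table(path)
        assert ds.individuals[0].genotypes["mac-1"].missing

    def test_more_than_two_alleles_rejected(self):
        with pytest.raises(DatasetError):
            MarkerGenotype("Me15-16", ("180-E", "168-T", "126-G"))

    def test_unknown_marker_listed_in_error(self, tmp_path):
        path = write_table(tmp_path, ["X1,ME-1,nope,180,"])
        with pytest.raises(DatasetError, match="nope"):
            read_genotype_table(path)

    def test_unresolvable_size_listed_in_error(self, tmp_path):
        path = write_table(tmp_path, ["X1,ME-1,Me15-16,999,"])
        with pytest.raises(DatasetError, match="999"):
            read_genotype_table(path)

    def test_round_trip_preserves_genotypes(self, tmp_path):
        rows = [
            "A1,ME-1,Me15-16,180,180",
            "A1,ME-1,COI,233,",
            "A1,ME-1,mac-1,255,266",
            "A2,MCh-1,Me15-16,126,",
            "A2,MCh-1,COI,134+99,",
        ]
        ds = read_genotype_table(write_table(tmp_path, rows))
        out = tmp_path / "roundtrip.csv"
        write_genotype_table(ds, out)
        ds2 = read_genotype_table(out)
        g1 = {(i.id, m): gt.alleles for i in ds.individuals for m, gt in i.genotypes.items()}
        g2 = {(i.id, m): gt.alleles for i in ds2.individuals for m, gt in i.genotypes.items()}
        assert g1 == g2


class TestAlleleFrequencies:
    def test_fixed_allele(self, make_dataset):
        rows = [(f"i{k}", "ME-1", "mac-1", ("255", "255")) for k in range(10)]
        freqs = allele_frequencies(make_dataset(rows), "mac-1")
        assert freqs.loc[0, "frequency"] == 1.0
        assert freqs.loc[0, "count"] == 20

    def test_direct_counts(self, make_dataset):
        ds = make_dataset(
            [("i1", "ME-1", "mac-1", ("255", "255")), ("i2", "ME-1", "mac-1", ("255", "266"))]
        )
        freqs = allele_frequencies(ds, "mac-1").set_index("allele")
        assert freqs.loc["255", "count"] == 3 and freqs.loc["266", "count"] == 1
        assert freqs.loc["255", "frequency"] == 0.75

    def test_mito_single_copy_vs_diploid_encoded(self, make_dataset):
        ds = make_dataset([("i1", "MCh-1", "COI", ("chilensis-cut",))])
        assert allele_frequencies(ds, "COI")["count"].sum() == 1
        assert allele_frequencies(ds, "COI", diploid_encoded=True)["count"].sum() == 2

    def test_missing_excluded_from_denominator(self, make_dataset):
        ds = make_dataset(
            [("i1", "ME-1", "mac-1", ("255", "266")), ("i2", "ME-1", "mac-1", None)]
        )
        assert allele_frequencies(ds, "mac-1")["count"].sum() == 2

    def test_empty_group_gives_empty_table(self, make_dataset):
        ds = make_dataset([("i1", "ME-1", "mac-1", None)])
        assert allele_frequencies(ds, "mac-1").empty

    @given(st.lists(st.sampled_from(["255", "266", "298"]), min_size=2, max_size=40))
    def test_frequencies_sum_to_one(self, alleles):
        from mytilus_id.markers import marker_registry
        from tests.conftest import build_dataset

        pairs = list(zip(alleles[::2], alleles[1::2]))
        rows = [
            (f"i{k}", "ME-1", "mac-1", tuple(sorted(p))) for k, p in enumerate(pairs)
        ]
        freqs = allele_frequencies(build_dataset(marker_registry(), rows), "mac-1")
        assert abs(freqs["frequency"].sum() - 1.0) < 1e-12
        assert (freqs["count"] >= 0).all()


class TestFilterDui:
    def test_whole_individual_exclusion_and_partition(self, make_dataset):
        ds = make_dataset(
            [
                ("d1", "MCh-1", "16S", ("chilensis", "edulis")),
                ("d1", "MCh-1", "COI", ("chilensis-cut",)),
                ("p1", "MCh-1", "16S", ("chilensis",)),
            ]
        )
        kept, excluded = filter_dui(ds, ["COI", "16S"])
        assert [i.id for i in excluded] == ["d1"]
        assert [i.id for i in kept.individuals] == ["p1"]
        assert len(kept) + len(excluded) == len(ds)

    def test_idempotent(self, make_dataset):
        ds = make_dataset(
            [("d1", "MCh-1", "16S", ("chilensis", "edulis")), ("p1", "MCh-1", "16S", ("chilensis",))]
        )
        once, _ = filter_dui(ds)
        twice, again = filter_dui(once)
        assert [i.id for i in twice.individuals] == [i.id for i in once.individuals]
        assert again == []

    def test_no_dui_is_identity(self, make_dataset):
        ds = make_dataset([("p1", "MCh-1", "16S", ("chilensis",))])
        kept, excluded = filter_dui(ds)
        assert excluded == [] and len(kept) == 1

    def test_two_identical_haplotypes_not_excluded(self, make_dataset):
        ds = make_dataset([("p1", "MCh-1", "16S", ("chilensis", "chilensis"))])
        _, excluded = filter_dui(ds)
        assert excluded == []


class TestEncodeMitoAsDiploid:
    def test_single_haplotype_becomes_homozygote(self):
        gt = encode_mito_as_diploid(MarkerGenotype("16S", ("edulis",)))
        assert gt.alleles == ("edulis", "edulis")

    def test_missing_passes_through(self):
        gt = MarkerGenotype("16S", (), missing=True)
        assert encode_mito_as_diploid(gt) is gt

    def test_dui_genotype_rejected(self):
        with pytest.raises(DatasetError):
            encode_mito_as_diploid(MarkerGenotype("16S", ("edulis", "chilensis")))


class TestGenepopExport:
    def test_structure_codes_and_missing(self, make_dataset, tmp_path, registry):
        ds = make_dataset(
            [
                ("a1", "ME-1", "mac-1", ("255", "255")),
                ("a2", "ME-1", "mac-1", None),
                ("b1", "MCh-1", "mac-1", ("255", "266")),
                ("b1", "MCh-1", "16S", ("chilensis",)),
            ]
        )
        path = tmp_path / "out.gen"
        export_genepop(ds, path, title="toy")
        text = path.read_text().splitlines()
        assert text.count("Pop") == 2
        codes = genepop_codes(registry["mac-1"])
        code255 = f"{codes['255']:03d}"
        assert any(line.startswith("a1 ,") and code255 * 2 in line for line in text)
        assert any(line.startswith("a2 ,") and "000000" in line for line in text)
        # mito haplotype written diploid-encoded
        b1 = next(line for line in text if line.startswith("b1 ,"))
        codes16 = genepop_codes(registry["16S"])
        assert f"{codes16['chilensis']:03d}" * 2 in b1

    def test_codes_ascend_with_fragment_size(self, registry):
        codes = genepop_codes(registry["mac-1"])
        assert codes["164"] < codes["255"] < codes["494"]
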