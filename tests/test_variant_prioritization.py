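import math
from itertools import combinations

import numpy as np
import pytest

from lopdkit.variant_prioritization import (
    BOTH_FAMILIES,
    FAMILY_SPECIFIC,
    AnnotatedVariant,
    CascadeReport,
    GenotypeMatrix,
    Pedigree,
    PedigreeEntry,
    VariantTableError,
    compound_het_genes,
    count_genotypes,
    deleteriousness_filter,
    functional_class_filter,
    load_bundled_table5,
    load_pedigree,
    load_variant_table,
    pathway_enrichment,
    phenotype_segregation,
    prioritize,
    qc_filter,
    rarity_filter,
    read_gmt,
    shared_carrier_analysis,
)


def mkvar(pos, gene="G", func="nonsynonymous_SNV", maf=None, cadd=25.0,
          ref="A", alt="T"):
    freqs = {} if maf is None else {"pop": maf}
    return AnnotatedVariant(chrom="1", pos=pos, ref=ref, alt=alt, gene=gene,
                            func_class=func, pop_freqs=freqs, cadd_phred=cadd)


@pytest.fixture()
def toy():
    """3 variants x 4 samples across two families."""
    variants = [mkvar(1), mkvar(2), mkvar(3)]
    calls = np.array([
        [1, 0, 1, 0],   # carried in both families
        [1, 1, 0, 0],   # all of F1 only
        [0, 0, 0, 0],   # monomorphic
    ], dtype=np.int8)
    gm = GenotypeMatrix([v.variant_id for v in variants],
                        ["A1", "A2", "B1", "B2"], calls)
    ped = Pedigree([
        PedigreeEntry("A1", "F1", True), PedigreeEntry("A2", "F1", True),
        PedigreeEntry("B1", "F2", True), PedigreeEntry("B2", "F2", True),
    ])
    return variants, gm, ped


class TestAnnotatedVariant:
    def test_alt_equals_ref_rejected(self):
        with pytest.raises(VariantTableError):
            mkvar(1, ref="A", alt="A")

    def test_bad_frequency_rejected(self):
        with pytest.raises(VariantTableError):
            mkvar(1, maf=1.5)

    def test_unknown_func_class_rejected(self):
        with pytest.raises(VariantTableError):
            mkvar(1, func="missense")

    def test_maf_max_over_populations(self):
        v = AnnotatedVariant(chrom="1", pos=1, ref="A", alt="T", gene="G",
                             func_class="splicing",
                             pop_freqs={"eur": 0.01, "afr": 0.12})
        assert v.maf_max == 0.12
        assert mkvar(2).maf_max is None


class TestTable5Fixture:
    def test_sixteen_rows(self):
        assert len(load_bundled_table5()) == 16

    def test_all_survive_rarity_and_deleteriousness(self):
        variants = load_bundled_table5()
        kept, _ = rarity_filter(variants)
        assert len(kept) == 16
        kept, _ = deleteriousness_filter(kept)
        assert len(kept) == 16

    def test_splicing_variant_retained_by_functional_filter(self):
        fam26f = [v for v in load_bundled_table5() if v.gene == "FAM26F"]
        assert fam26f[0].func_class == "splicing"
        kept, _ = functional_class_filter(fam26f)
        assert kept == fam26f

    def test_unscored_indel_is_the_only_missing_cadd(self):
        missing = [v for v in load_bundled_table5() if v.cadd_phred is None]
        assert [v.func_class for v in missing] == ["nonframeshift_indel"]
        assert missing[0].gene == "DCHS1"

    def test_na_maf_treated_as_novel(self):
        plin2 = [v for v in load_bundled_table5()
                 if v.gene == "PLIN2" and v.aa_change == "p.E206K"]
        assert plin2[0].maf_max is None


class TestFilters:
    def test_functional_drops_synonymous_and_other(self):
        variants = [mkvar(1), mkvar(2, func="synonymous_SNV"),
                    mkvar(3, func="other"), mkvar(4, func="splicing")]
        kept, stage = functional_class_filter(variants)
        assert [v.pos for v in kept] == [1, 4]
        assert stage.n_after == 2

    def test_rarity_boundary(self):
        variants = [mkvar(1, maf=0.04), mkvar(2, maf=0.19),
                    mkvar(3, maf=0.2), mkvar(4, maf=None)]
        kept, _ = rarity_filter(variants)
        assert [v.pos for v in kept] == [1, 2, 4]

    def test_deleteriousness_boundary_and_indel_exception(self):
        variants = [mkvar(1, cadd=23.0), mkvar(2, cadd=19.9),
                    mkvar(3, cadd=None, func="nonframeshift_indel"),
                    mkvar(4, cadd=None)]
        kept, _ = deleteriousness_filter(variants)
        assert [v.pos for v in kept] == [1, 3]

    def test_filters_idempotent(self):
        rng = np.random.default_rng(0)
        variants = [
            mkvar(i, maf=float(rng.uniform(0, 0.5)),
                  cadd=float(rng.uniform(0, 40)),
                  func=rng.choice(["nonsynonymous_SNV", "synonymous_SNV",
                                   "splicing", "other"]))
            for i in range(50)
        ]
        for filt in (functional_class_filter, rarity_filter,
                     deleteriousness_filter):
            once, _ = filt(variants)
            twice, _ = filt(once)
            assert twice == once

    def test_rarity_and_deleteriousness_commute(self):
        rng = np.random.default_rng(1)
        variants = [
            mkvar(i, maf=None if rng.random() < 0.2 else float(rng.uniform(0, 0.5)),
                  cadd=None if rng.random() < 0.2 else float(rng.uniform(0, 40)))
            for i in range(80)
        ]
        ab = deleteriousness_filter(rarity_filter(variants)[0])[0]
        ba = rarity_filter(deleteriousness_filter(variants)[0])[0]
        assert ab == ba

    def test_qc_filter(self):
        variants = [mkvar(1), mkvar(2), mkvar(3)]
        # 11 samples: v1 all-reference, v2 one missing call, v3 one het
        calls = np.zeros((3, 11), dtype=np.int8)
        calls[1, 0] = -1
        calls[1, 1] = 1
        calls[2, 0] = 1
        gm = GenotypeMatrix([v.variant_id for v in variants],
                            [f"S{i}" for i in range(11)], calls)
        kept, gm2, stage = qc_filter(variants, gm)
        assert [v.pos for v in kept] == [3]
        assert gm2.variant_ids == [variants[2].variant_id]
        assert stage.n_after == 1


class TestLoaders:
    def _write_pair(self, tmp_path, vcf_body, annot_rows):
        annot = tmp_path / "a.tsv"
        header = ("chrom\tpos\tref\talt\tgene\ttranscript\tfunc\tnt_change\t"
                  "aa_change\tfreq_pop\tcadd_phred\tsift\tpolyphen\tdbsnp\n")
        annot.write_text(header + "".join(annot_rows))
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            + vcf_body
        )
        return annot, vcf

    def _row(self, pos, maf="0.01"):
        return (f"1\t{pos}\tA\tT\tG1\tNM_1\tNSV\tc.1A>T\tp.X1Y\t{maf}\t25\t"
                "D\tD\trs1\n")

    def test_vcf_gt_encodings(self, tmp_path):
        annot, vcf = self._write_pair(
            tmp_path,
            "1\t5\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t./.\n",
            [self._row(5)],
        )
        variants, gm = load_variant_table(annot, vcf)
        assert len(variants) == 1
        assert gm.dosages(variants[0].variant_id).tolist() == [1, 2, -1]

    def test_na_frequency_absent(self, tmp_path):
        annot, vcf = self._write_pair(
            tmp_path,
            "1\t5\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n",
            [self._row(5, maf="na")],
        )
        variants, _ = load_variant_table(annot, vcf)
        assert variants[0].pop_freqs == {}

    def test_join_mismatch_errors(self, tmp_path):
        annot, vcf = self._write_pair(
            tmp_path,
            "1\t6\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n",
            [self._row(5)],
        )
        with pytest.raises(VariantTableError, match="mismatch"):
            load_variant_table(annot, vcf)

    def test_multiallelic_refused(self, tmp_path):
        annot, vcf = self._write_pair(
            tmp_path,
            "1\t5\t.\tA\tT,C\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n",
            [self._row(5)],
        )
        with pytest.raises(VariantTableError, match="multi-allelic"):
            load_variant_table(annot, vcf)

    def test_tsv_genotype_matrix(self, tmp_path):
        annot = tmp_path / "a.tsv"
        annot.write_text(
            "chrom\tpos\tref\talt\tgene\ttranscript\tfunc\tnt_change\t"
            "aa_change\tfreq_pop\tcadd_phred\tsift\tpolyphen\tdbsnp\n"
            + self._row(5)
        )
        geno = tmp_path / "g.tsv"
        geno.write_text("variant_id\tS1\tS2\tS3\n1:5:A:T\t0\t2\tna\n")
        variants, gm = load_variant_table(annot, geno)
        assert gm.dosages(variants[0].variant_id).tolist() == [0, 2, -1]

    def test_malformed_tsv_genotype(self, tmp_path):
        annot = tmp_path / "a.tsv"
        annot.write_text(
            "chrom\tpos\tref\talt\tgene\ttranscript\tfunc\tnt_change\t"
            "aa_change\tfreq_pop\tcadd_phred\tsift\tpolyphen\tdbsnp\n"
            + self._row(5)
        )
        geno = tmp_path / "g.tsv"
        geno.write_text("variant_id\tS1\tS2\tS3\n1:5:A:T\t0\t3\t1\n")
        with pytest.raises(VariantTableError, match="malformed genotype"):
            load_variant_table(annot, geno)

    def test_sample_exclusion(self, tmp_path):
        annot, vcf = self._write_pair(
            tmp_path,
            "1\t5\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\n",
            [self._row(5)],
        )
        _, gm = load_variant_table(annot, vcf, exclude_samples=["S2"])
        assert gm.samples == ["S1", "S3"]

    def test_pedigree_loader(self, tmp_path):
        p = tmp_path / "ped.tsv"
        p.write_text("sample\tfamily\taffected\nA1\tF1\t1\nB1\tF2\tyes\n")
        ped = load_pedigree(p)
        assert ped.families == ["F1", "F2"]
        assert ped.members("F2") == ["B1"]

    def test_read_bundled_gmt(self):
        from importlib import resources
        ref = resources.files("lopdkit.data").joinpath("pathways.gmt")
        with resources.as_file(ref) as p:
            sets = read_gmt(p)
        assert len(sets) == 4
        assert "RILP" in sets["autophagy_lysosomal"]


class TestSharing:
    def test_between_families(self, toy):
        variants, gm, ped = toy
        out = shared_carrier_analysis(variants, gm, ped)
        assert [s.variant.pos for s in out] == [1]
        assert out[0].label == BOTH_FAMILIES
        assert out[0].carriers == frozenset({"A1", "B1"})

    def test_within_family_keeps_family_specific(self, toy):
        variants, gm, ped = toy
        out = shared_carrier_analysis(variants, gm, ped,
                                      mode="within_family", family="F1")
        assert [s.variant.pos for s in out] == [2]
        assert out[0].label == FAMILY_SPECIFIC

    def test_within_family_subset(self, toy):
        variants, gm, ped = toy
        out = shared_carrier_analysis(variants, gm, ped,
                                      mode="within_family", family="F1",
                                      subset=["A1"])
        assert sorted(s.variant.pos for s in out) == [1, 2]

    def test_monomorphic_dropped_in_both_modes(self, toy):
        variants, gm, ped = toy
        mono = variants[2].variant_id
        for out in (
            shared_carrier_analysis(variants, gm, ped),
            shared_carrier_analysis(variants, gm, ped,
                                    mode="within_family", family="F1"),
        ):
            assert mono not in {s.variant.variant_id for s in out}

    def test_within_family_requires_family(self, toy):
        variants, gm, ped = toy
        with pytest.raises(VariantTableError, match="family"):
            shared_carrier_analysis(variants, gm, ped, mode="within_family")


class TestSegregation:
    def _gm(self, carrier_sets, samples):
        variants = [mkvar(i + 1) for i in range(len(carrier_sets))]
        calls = np.array(
            [[1 if s in cs else 0 for s in samples] for cs in carrier_sets],
            dtype=np.int8,
        )
        return variants, GenotypeMatrix(
            [v.variant_id for v in variants], samples, calls
        )

    def test_concordance_patterns(self):
        samples = [f"S{i}" for i in range(11)]
        positives = set(samples[:5])
        variants, gm = self._gm(
            [positives, set(samples), set(samples) - positives], samples
        )
        trait = {s: int(s in positives) for s in samples}
        res = phenotype_segregation(variants, gm, trait)
        by_pos = {r.variant.pos: r for r in res}
        assert by_pos[1].concordance == 1.0 and by_pos[1].perfect
        assert by_pos[2].concordance == pytest.approx(5 / 11)
        assert by_pos[3].concordance == 0.0 and by_pos[3].inverse

    def test_sorted_by_concordance(self):
        samples = ["a", "b", "c", "d"]
        variants, gm = self._gm([{"a"}, {"a", "b"}], samples)
        trait = {"a": 1, "b": 1, "c": 0, "d": 0}
        res = phenotype_segregation(variants, gm, trait)
        assert [r.variant.pos for r in res] == [2, 1]

    def test_missing_trait_errors(self):
        samples = ["a", "b"]
        variants, gm = self._gm([{"a"}], samples)
        with pytest.raises(VariantTableError, match="trait"):
            phenotype_segregation(variants, gm, {"a": 1})


class TestPathwayEnrichment:
    def test_single_draw(self):
        res = pathway_enrichment(["g1"], {"s": {"g1"}}, universe_size=10)
        assert res[0].p_upper == pytest.approx(0.1)

    def test_zero_overlap_p_one(self):
        res = pathway_enrichment(["g1"], {"s": {"g2"}}, universe_size=10)
        assert res[0].p_upper == 1.0

    def test_full_overlap_closed_form(self):
        genes = [f"g{i}" for i in range(5)]
        res = pathway_enrichment(genes, {"s": set(genes)}, universe_size=20)
        assert res[0].p_upper == pytest.approx(1 / math.comb(20, 5))

    def test_exhaustive_enumeration_oracle(self):
        # brute force: draw every n-subset of a 12-gene universe and count
        # how many overlap the set by >= k
        universe = [f"u{i}" for i in range(12)]
        gene_set = set(universe[:5])
        candidates = universe[3:7]  # overlap k = 2
        k, n = 2, len(candidates)
        hits = sum(
            1 for draw in combinations(universe, n)
            if len(set(draw) & gene_set) >= k
        )
        expected = hits / math.comb(12, n)
        res = pathway_enrichment(candidates, {"s": gene_set}, universe_size=12)
        assert res[0].overlap == k
        assert res[0].p_upper == pytest.approx(expected)

    def test_universe_too_small_errors(self):
        with pytest.raises(VariantTableError):
            pathway_enrichment(["g1", "g2"], {"s": {"g1"}}, universe_size=1)

    def test_stray_gene_warns_with_explicit_universe(self):
        with pytest.warns(UserWarning, match="absent from"):
            pathway_enrichment(["g1"], {"s": {"g1", "zz"}}, universe_size=10,
                               universe={"g1"})


class TestPrioritize:
    def test_empty_variant_table(self, toy):
        _, gm, ped = toy
        empty_gm = GenotypeMatrix([], gm.samples,
                                  np.empty((0, 4), dtype=np.int8))
        candidates, report, enrichment = prioritize([], empty_gm, ped)
        assert candidates == []
        assert all(n == 0 for n in report.counts().values())
        assert enrichment == []

    def test_toy_candidates_and_labels(self, toy):
        variants, gm, ped = toy
        trait = {"A1": 1, "A2": 1, "B1": 1, "B2": 0}
        candidates, report, _ = prioritize(variants, gm, ped,
                                           traits={"t": trait})
        by_pos = {c.variant.pos: c for c in candidates}
        assert set(by_pos) == {1, 2}
        assert by_pos[1].sharing == BOTH_FAMILIES
        assert by_pos[2].sharing == FAMILY_SPECIFIC
        assert report.counts()["sharing"] == 2

    def test_oracle_equivalence_naive_predicates(self):
        """prioritize equals a one-pass per-variant predicate evaluation."""
        rng = np.random.default_rng(42)
        samples = [f"F1S{i}" for i in range(4)] + [f"F2S{i}" for i in range(3)]
        ped = Pedigree(
            [PedigreeEntry(s, s[:2], True) for s in samples]
        )
        variants, rows = [], []
        for i in range(150):
            variants.append(mkvar(
                i + 1,
                gene=f"G{i}",
                maf=None if rng.random() < 0.1 else float(rng.uniform(0, 0.4)),
                cadd=None if rng.random() < 0.1 else float(rng.uniform(0, 40)),
                func=str(rng.choice([
                    "nonsynonymous_SNV", "synonymous_SNV", "splicing",
                    "nonframeshift_indel", "other",
                ])),
            ))
            row = rng.choice([-1, 0, 1, 2], size=7,
                             p=[0.03, 0.57, 0.3, 0.1])
            rows.append(row.astype(np.int8))
        gm = GenotypeMatrix([v.variant_id for v in variants], samples,
                            np.vstack(rows))
        candidates, _, _ = prioritize(variants, gm, ped)
        got = {c.variant.variant_id for c in candidates}

        expected = set()
        for v in variants:
            d = gm.dosages(v.variant_id)
            called = d[d >= 0]
            carriers = {s for s, x in zip(samples, d) if x >= 1}
            fams = {s[:2] for s in carriers}
            f1 = [s for s in samples if s.startswith("F1")]
            f2 = [s for s in samples if s.startswith("F2")]
            ok = (
                called.sum() > 0
                and (d >= 0).sum() / 7 >= 0.95
                and v.func_class in {"nonsynonymous_SNV", "stopgain",
                                     "stoploss", "frameshift_indel",
                                     "nonframeshift_indel", "splicing"}
                and (v.maf_max is None or v.maf_max < 0.2)
                and ((v.cadd_phred is not None and v.cadd_phred >= 20)
                     or (v.cadd_phred is None
                         and v.func_class == "nonframeshift_indel"))
                and (fams == {"F1", "F2"}
                     or all(s in carriers for s in f1)
                     or all(s in carriers for s in f2))
            )
            if ok:
                expected.add(v.variant_id)
        assert got == expected

    def test_cascade_monotonicity_enforced(self):
        report = CascadeReport()
        report.add("a", 5)
        with pytest.raises(VariantTableError):
            report.add("b", 6)

    def test_compound_het_flagging(self):
        v1, v2 = mkvar(1, gene="DCHS1"), mkvar(2, gene="DCHS1")
        from lopdkit.variant_prioritization import CandidateVariant
        candidates = [
            CandidateVariant(v1, frozenset({"a", "b"}), FAMILY_SPECIFIC, 0.5),
            CandidateVariant(v2, frozenset({"a"}), FAMILY_SPECIFIC, 0.5),
        ]
        flagged = compound_het_genes(candidates)
        assert list(flagged) == ["DCHS1"]
        assert list(flagged["DCHS1"]) == ["a"]


class TestCountGenotypes:
    def test_fokI_counts(self, table6):
        counts = count_genotypes(table6, "rs2228570")
        assert counts.genotypes == {"CC": 9, "TC": 2}
        assert counts.alleles == {"C": 20, "T": 2}

    def test_rs4588_counts(self, table6):
        counts = count_genotypes(table6, "rs4588")
        assert counts.genotypes == {"CC": 10, "CA": 1}

    def test_empty_rows_error(self):
        with pytest.raises(VariantTableError):
            count_genotypes([], "rs1")

    def test_unknown_rsid(self, table6):
        with pytest.raises(VariantTableError, match="rs999"):
            count_genotypes(table6, "rs999")
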