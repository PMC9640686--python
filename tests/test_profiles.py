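"""Annotation loading, thresholding and conservation-bin profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panstrep import (
    bgc_core_enzyme_profile,
    category_profile,
    class_count_stats,
    load_annotations,
)
from panstrep.profiles import cazy_class_of
from panstrep.stats import prevalence_bin

from conftest import make_pangenome
from oracles import tally_profile


def domains_df(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "accession", "name", "ievalue", "start", "end"]
    )


def cog_df(rows):
    return pd.DataFrame(rows, columns=["protein_id", "cog_category", "evalue"])


def cazy_df(rows):
    return pd.DataFrame(rows, columns=["protein_id", "family"])


def bgc_df(rows):
    return pd.DataFrame(rows, columns=["protein_id", "bgc_id", "bgc_type", "core_enzyme"])


class TestLoadAnnotations:
    def test_domain_threshold_strict_at_1e_1(self):
        table = load_annotations(
            {
                "domains": domains_df(
                    [
                        ("p1", "PF00001", "dom", 0.5, 1, 50),  # above threshold
                        ("p2", "PF00001", "dom", 1e-5, 1, 50),
                    ]
                )
            }
        )
        assert set(table.df["protein_id"]) == {"p2"}
        assert table.dropped["domains"] == 1

    def test_cog_threshold_at_1e_10(self):
        table = load_annotations(
            {
                "cog": cog_df(
                    [("p1", "K", 1e-12), ("p2", "K", 1e-8)]
                )
            }
        )
        assert set(table.df["protein_id"]) == {"p1"}
        assert table.dropped["cog"] == 1

    def test_kept_plus_dropped_equals_input(self):
        dom = domains_df(
            [(f"p{i}", "PF1", "d", ev, 1, 9) for i, ev in enumerate([1e-5, 0.5, 0.2, 1e-3])]
        )
        table = load_annotations({"domains": dom})
        assert len(table.df) + table.dropped["domains"] == len(dom)

    def test_duplicate_rows_deduplicated_and_counted(self):
        dom = domains_df([("p1", "PF1", "d", 1e-5, 1, 9)] * 3)
        table = load_annotations({"domains": dom})
        assert len(table.df) == 1
        assert table.n_duplicates == 2

    def test_cog_multi_letter_split_vs_first_letter(self):
        cog = cog_df([("p1", "KT", 1e-20)])
        split = load_annotations({"cog": cog})
        assert sorted(split.of_type("COG_category")["label"]) == ["K", "T"]
        single = load_annotations({"cog": cog}, cog_split=False)
        assert list(single.of_type("COG_category")["label"]) == ["K"]

    def test_cazy_rows_expand_to_family_and_class(self):
        table = load_annotations({"cazy": cazy_df([("p1", "GH13"), ("p2", "CBM2")])})
        assert set(table.of_type("CAZy_family")["label"]) == {"GH13", "CBM2"}
        assert set(table.of_type("CAZy_class")["label"]) == {"GH", "CBM"}

    def test_kegg_rollup_with_exclusions(self):
        ko = pd.DataFrame(
            [("p1", "K00001", 100.0, 50.0, 1e-20), ("p2", "K00002", 100.0, 50.0, 1e-20)],
            columns=["protein_id", "ko", "score", "threshold", "ievalue"],
        )
        mapping = pd.DataFrame(
            [
                ("K00001", "glycolysis", "metabolism"),
                ("K00002", "secondary_biosynthesis", "metabolism"),
            ],
            columns=["ko", "pathway", "category"],
        )
        table = load_annotations(
            {"ko": ko},
            kegg_mapping=mapping,
            kegg_exclusions=["secondary_biosynthesis"],
        )
        kegg = table.of_type("KEGG_category")
        assert list(kegg["protein_id"]) == ["p1"]

    def test_cazy_class_prefix(self):
        assert cazy_class_of("GH13") == "GH"
        assert cazy_class_of("AA10") == "AA"
        with pytest.raises(ValueError):
            cazy_class_of("13")


def profile_pangenome():
    """4 genomes; one strict-core group, one half-prevalence, singletons."""
    return make_pangenome(
        {
            "OG1": [(f"a{i}", f"G{i}") for i in range(4)],  # prevalence 4/4
            "OG2": [("b0", "G0"), ("b1", "G1")],  # prevalence 2/4
            "OG3": [("c0", "G0")],  # singleton
            "OG4": [("d3", "G3")],  # singleton
        }
    )


class TestCategoryProfile:
    def test_strict_core_label_in_top_bin(self):
        pangenome = profile_pangenome()
        table = load_annotations(
            {"cog": cog_df([(f"a{i}", "J", 1e-20) for i in range(4)])}
        )
        profile = category_profile(pangenome, table, "COG_category")
        assert profile.counts.loc["J", "bin_20"] == 4
        assert profile.totals["J"] == 4
        assert profile.percentages().loc["J", "bin_20"] == 100.0

    def test_planted_bin_composition_recovered(self):
        pangenome = profile_pangenome()
        table = load_annotations(
            {
                "cog": cog_df(
                    [("a0", "K", 1e-20), ("b0", "K", 1e-20), ("c0", "K", 1e-20)]
                )
            }
        )
        profile = category_profile(pangenome, table, "COG_category")
        top = prevalence_bin(1.0)
        half = prevalence_bin(0.5)
        low = prevalence_bin(0.25)
        assert profile.counts.loc["K", f"bin_{top + 1:02d}"] == 1
        assert profile.counts.loc["K", f"bin_{half + 1:02d}"] == 1
        assert profile.counts.loc["K", f"bin_{low + 1:02d}"] == 1

    def test_matches_brute_force_tally(self, medium_truth_pangenome):
        truth, pangenome = medium_truth_pangenome
        rng = np.random.default_rng(4)
        proteins = sorted(pangenome.protein_to_group)
        labelled = [(p, "COG" + "JKL"[rng.integers(3)]) for p in proteins[:200]]
        table = load_annotations(
            {"cog": cog_df([(p, lab[-1], 1e-20) for p, lab in labelled])}
        )
        profile = category_profile(pangenome, table, "COG_category")
        protein_bin = {
            p: prevalence_bin(pangenome.prevalence_fraction(pangenome.protein_to_group[p]))
            for p, _ in labelled
        }
        oracle = tally_profile([(p, lab[-1]) for p, lab in labelled], protein_bin)
        for label, bins in oracle.items():
            for b, count in bins.items():
                assert profile.counts.loc[label, f"bin_{b + 1:02d}"] == count
        assert int(profile.totals.sum()) == len(labelled)

    def test_bin_assignment_identical_across_label_types(self):
        pangenome = profile_pangenome()
        table = load_annotations(
            {
                "cog": cog_df([("b0", "K", 1e-20)]),
                "cazy": cazy_df([("b0", "GH13")]),
            }
        )
        cog_profile = category_profile(pangenome, table, "COG_category")
        cazy_profile = category_profile(pangenome, table, "CAZy_family")
        assert (
            cog_profile.counts.loc["K"].to_numpy()
            == cazy_profile.counts.loc["GH13"].to_numpy()
        ).all()

    def test_percentage_rows_sum_to_100(self):
        pangenome = profile_pangenome()
        table = load_annotations(
            {"cog": cog_df([("a0", "K", 1e-20), ("b0", "K", 1e-20), ("c0", "K", 1e-20)])}
        )
        profile = category_profile(pangenome, table, "COG_category")
        assert profile.percentages().loc["K"].sum() == pytest.approx(100.0, abs=0.2)

    def test_unknown_label_type_rejected(self):
        with pytest.raises(ValueError, match="label_type"):
            category_profile(
                profile_pangenome(), load_annotations({}), "nonsense_type"
            )

    def test_unknown_protein_rejected(self):
        table = load_annotations({"cog": cog_df([("ghost", "K", 1e-20)])})
        with pytest.raises(ValueError, match="ghost"):
            category_profile(profile_pangenome(), table, "COG_category")


class TestClassCountStats:
    def test_identical_counts_have_zero_cv(self):
        pangenome = profile_pangenome()
        table = load_annotations(
            {"cazy": cazy_df([(f"a{i}", "GH13") for i in range(4)])}
        )
        stats = class_count_stats(table, pangenome)
        assert stats.summary.loc["GH", "cv"] == 0.0

    def test_cv_uses_population_sd(self):
        # per-genome counts 1, 2, 3 -> population SD sqrt(2/3), CV = SD / 2
        pangenome = make_pangenome(
            {
                "OG1": [("a1", "G1")],
                "OG2": [("b1", "G2"), ("b2", "G2")],
                "OG3": [("c1", "G3"), ("c2", "G3"), ("c3", "G3")],
            }
        )
        table = load_annotations(
            {"cazy": cazy_df([(p, "PL1") for p in ["a1", "b1", "b2", "c1", "c2", "c3"]])}
        )
        stats = class_count_stats(table, pangenome)
        expected_sd = np.sqrt(((1 - 2) ** 2 + 0 + (3 - 2) ** 2) / 3)
        assert stats.summary.loc["PL", "sd"] == pytest.approx(expected_sd)
        assert stats.summary.loc["PL", "cv"] == pytest.approx(expected_sd / 2)
        assert stats.totals["G3"] == 3

    def test_absent_class_cv_missing(self):
        pangenome = profile_pangenome()
        table = load_annotations({"cazy": cazy_df([])})
        stats = class_count_stats(table, pangenome)
        assert stats.per_genome.empty or stats.summary["cv"].isna().all()


class TestBgcCoreEnzymeProfile:
    def test_singleton_core_enzymes_all_in_lowest_bin(self):
        # 40 genomes: a singleton's prevalence (1/40 = 2.5%) falls in (0, 0.05]
        genome_ids = tuple(f"G{i}" for i in range(40))
        pangenome = make_pangenome(
            {
                "OG1": [(f"a{i}", f"G{i}") for i in range(40)],  # strict core
                "OG2": [("b0", "G0"), ("b1", "G1")],
                "OG3": [("c0", "G0")],
                "OG4": [("d3", "G3")],
            },
            n_genomes=40,
            genome_ids=genome_ids,
        )
        table = load_annotations(
            {
                "bgc": bgc_df(
                    [
                        ("c0", "bgc1", "butyrolactone", True),
                        ("d3", "bgc2", "butyrolactone", True),
                        ("a0", "bgc3", "ectoine", True),
                        ("b0", "bgc4", "butyrolactone", False),  # not a core enzyme
                    ]
                )
            }
        )
        profile = bgc_core_enzyme_profile(pangenome, table)
        assert profile.counts.loc["butyrolactone", "bin_01"] == 2
        assert profile.totals["butyrolactone"] == 2  # non-core row excluded
        assert profile.percentages().loc["butyrolactone", "bin_01"] == 100.0
        assert profile.counts.loc["ectoine", "bin_20"] == 1

    def test_empty_bgc_table_gives_empty_profile(self):
        profile = bgc_core_enzyme_profile(
            profile_pangenome(), load_annotations({"bgc": bgc_df([])})
        )
        assert profile.counts.empty
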