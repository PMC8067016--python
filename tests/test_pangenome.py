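"""Presence-matrix analytics: group rules, enrichment, Venn, CAZy, Wilcoxon."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bdellocomp import (
    SimConfig,
    build_presence_matrix,
    call_group_specific,
    cazy_class_counts,
    count_group_specific,
    enrichment_table,
    group_presence,
    make_fixture,
    peptidase_venn,
    simulate_annotations,
    source_tally,
    wilcoxon_copy_test,
)
from bdellocomp.io import ANNOTATION_COLUMNS
from bdellocomp.util import GROUPS

from _oracles import rank_sum_enumeration


def _ann(rows):
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def _meta(rows):
    return pd.DataFrame(rows, columns=["genome_id", "group", "environment"])


class TestBuildPresenceMatrix:
    def test_empty_table_gives_all_false(self):
        pm = build_presence_matrix(_ann([]), genomes=["g1", "g2"])
        assert pm.presence.shape == (0, 2)
        assert not pm.presence.any().any()

    def test_duplicate_rows_sum_copies(self):
        pm = build_presence_matrix(
            _ann([("g", "KEGG", "K00001", 2), ("g", "KEGG", "K00001", 1)])
        )
        assert pm.copies.at["K00001", "g"] == 3
        assert bool(pm.presence.at["K00001", "g"])

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError, match="negative copy"):
            build_presence_matrix(_ann([("g", "KEGG", "K1", -1)]))

    def test_long_form_round_trip(self, fixture_w1, fixture_w1_matrix):
        long = fixture_w1_matrix.to_long()
        pm2 = build_presence_matrix(
            long, genomes=list(fixture_w1.metadata["genome_id"])
        )
        pd.testing.assert_frame_equal(fixture_w1_matrix.copies, pm2.copies)
        pd.testing.assert_series_equal(
            fixture_w1_matrix.namespace, pm2.namespace
        )

    def test_unknown_genome_in_annotations_rejected(self):
        with pytest.raises(ValueError, match="unknown genomes"):
            build_presence_matrix(_ann([("gX", "KEGG", "K1", 1)]), genomes=["g1"])


class TestGroupPresence:
    def test_cheb_fraction_in_group2(self):
        f = make_fixture("W3_cheB")
        pm = build_presence_matrix(f.annotations, genomes=list(f.metadata["genome_id"]))
        gp = group_presence(pm, f.metadata)
        row = gp[(gp["gene_id"] == "cheB") & (gp["group"] == "Bdello-group2")].iloc[0]
        assert row["n_present"] == 41 and row["n_group"] == 46
        assert row["fraction"] == pytest.approx(41 / 46)
        assert bool(row["present"])

    @pytest.mark.parametrize(
        "n_present,n_total,flag", [(2, 4, True), (4999, 10000, False), (1, 2, True)]
    )
    def test_at_least_half_rule_is_inclusive(self, n_present, n_total, flag):
        meta = _meta(
            [(f"g{i}", "Oligoflexia", "marine") for i in range(n_total)]
        )
        pm = build_presence_matrix(
            _ann([(f"g{i}", "KEGG", "K1", 1) for i in range(n_present)]),
            genomes=list(meta["genome_id"]),
        )
        gp = group_presence(pm, meta)
        assert bool(gp.iloc[0]["present"]) is flag

    def test_empty_group_rejected(self):
        meta = _meta([("g1", "Oligoflexia", "marine")])
        pm = build_presence_matrix(_ann([("g1", "KEGG", "K1", 1)]))
        with pytest.raises(ValueError, match="no genomes"):
            group_presence(pm, meta, groups=["Bacteriovoracia"])


class TestGroupSpecific:
    def _gp(self, fractions):
        return pd.DataFrame(
            {
                "gene_id": ["K1"] * 4,
                "group": list(GROUPS),
                "fraction": fractions,
            }
        )

    @pytest.mark.parametrize(
        "fractions,expected",
        [
            ((0.6, 0.2, 0.1, 0.0), "Oligoflexia"),
            ((0.6, 0.6, 0.1, 0.0), None),  # two groups exceed
            ((0.5, 0.2, 0.2, 0.2), None),  # strict > 0.5
            ((0.51, 0.5, 0.5, 0.5), "Oligoflexia"),  # others at most 0.5
        ],
    )
    def test_strictly_more_than_half_in_exactly_one_group(self, fractions, expected):
        assert call_group_specific(self._gp(fractions), "K1") == expected

    def test_counts_match_planted_specificity(self):
        # one gene specific to each group, one gene shared by all groups
        meta_rows, ann_rows = [], []
        for gi, group in enumerate(GROUPS):
            for i in range(4):
                gid = f"grp{gi}_{i}"
                meta_rows.append((gid, group, "marine"))
                ann_rows.append((gid, "KEGG", "Kshared", 1))
                if i < 3:  # 75% of own group
                    ann_rows.append((gid, "KEGG", f"Kspec{gi}", 1))
        meta = _meta(meta_rows)
        pm = build_presence_matrix(_ann(ann_rows), genomes=list(meta["genome_id"]))
        counts = count_group_specific(pm, meta, "KEGG")
        assert counts == {g: 1 for g in GROUPS}

    def test_no_gene_above_half_gives_zero_counts(self):
        meta = _meta([(f"g{i}", "Oligoflexia", "marine") for i in range(4)]
                     + [(f"h{i}", "Bdello-group2", "marine") for i in range(4)])
        pm = build_presence_matrix(
            _ann([("g0", "KEGG", "K1", 1), ("h0", "KEGG", "K1", 1)]),
            genomes=list(meta["genome_id"]),
        )
        counts = count_group_specific(pm, meta, "KEGG")
        assert set(counts.values()) == {0}


class TestEnrichment:
    def test_w1_reference_rows(self, fixture_w1, fixture_w1_matrix):
        et = enrichment_table(fixture_w1_matrix, fixture_w1.metadata, "Bacteriovoracia")
        row = et[et["gene_id"] == "K02168"].iloc[0]
        assert row["marine_pct"] == 77.78
        assert row["nonmarine_pct"] == 21.05
        et2 = enrichment_table(fixture_w1_matrix, fixture_w1.metadata, "Bdello-group2")
        row2 = et2[et2["gene_id"] == "K02168"].iloc[0]
        assert row2["nonmarine_pct"] == 0.0 and row2["nonmarine_pct_display"] == 0.0

    def test_percentages_recompute_from_counts(self, fixture_w1, fixture_w1_matrix):
        from bdellocomp.util import pct_exact

        for group in GROUPS:
            et = enrichment_table(fixture_w1_matrix, fixture_w1.metadata, group)
            for row in et.itertuples(index=False):
                assert row.marine_pct == pct_exact(row.marine_present, row.marine_n)
                assert row.nonmarine_pct == pct_exact(
                    row.nonmarine_present, row.nonmarine_n
                )

    def test_all_marine_group_flags_undefined_side(self):
        meta = _meta([("g1", "Oligoflexia", "marine"), ("g2", "Oligoflexia", "marine")])
        pm = build_presence_matrix(
            _ann([("g1", "KEGG", "K1", 1)]), genomes=["g1", "g2"]
        )
        et = enrichment_table(pm, meta, "Oligoflexia")
        assert np.isnan(et.iloc[0]["nonmarine_pct"])
        assert et.iloc[0]["marine_pct"] == 50.0

    def test_unknown_group_rejected(self, fixture_w1, fixture_w1_matrix):
        with pytest.raises(ValueError, match="unknown or empty"):
            enrichment_table(fixture_w1_matrix, fixture_w1.metadata, "Nope")

    def test_planted_enrichment_ranks_top(self):
        # strong marine enrichment must surface at the top of the table
        cfg = SimConfig(
            seed=17,
            group_sizes={"Bdello-group2": (50, 50)},
            gene_probs={
                ("Kplant", "Bdello-group2", "marine"): 0.9,
                ("Kplant", "Bdello-group2", "non-marine"): 0.1,
                ("Kflat", "Bdello-group2", "marine"): 0.5,
                ("Kflat", "Bdello-group2", "non-marine"): 0.5,
            },
            background_rate=0.3,
            n_background_genes=30,
        )
        bundle, _ = simulate_annotations(cfg)
        pm = build_presence_matrix(
            bundle.annotations, genomes=list(bundle.metadata["genome_id"])
        )
        et = enrichment_table(pm, bundle.metadata, "Bdello-group2")
        et = et.assign(gap=et["marine_pct"] - et["nonmarine_pct"])
        assert et.sort_values("gap", ascending=False).iloc[0]["gene_id"] == "Kplant"


class TestWilcoxon:
    def test_identical_vectors_p1(self):
        w, p = wilcoxon_copy_test([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_extreme_separation_exact_p(self):
        w, p = wilcoxon_copy_test([1, 2, 3, 4], [10, 11, 12, 13])
        assert w == 10.0  # minimal possible rank sum for n=4
        assert p == pytest.approx(2 / 70)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wilcoxon_copy_test([], [1, 2])

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_exact_p_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1, 2 * n + 1, dtype=float))
            a, b = pooled[:n], pooled[n:]
            w, p = wilcoxon_copy_test(a, b)
            w_ref, p_ref = rank_sum_enumeration(a, b)
            assert w == w_ref
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_large_sample_close_to_permutation(self):
        rng = np.random.default_rng(99)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.8, 1.0, 12)
        _, p = wilcoxon_copy_test(a, b)
        # Monte-Carlo permutation oracle
        pooled = np.concatenate([a, b])
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        w_obs = ranks[:12].sum()
        mu = ranks.sum() * 12 / 24
        count = 0
        n_perm = 20000
        for i in range(n_perm):
            perm = rng.permutation(24)
            w = ranks[perm[:12]].sum()
            if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
                count += 1
        assert p == pytest.approx(count / n_perm, abs=0.01)


class TestVennAndCazy:
    def test_six_family_core_and_uniques(self):
        f = make_fixture("W4_peptidases")
        pm = build_presence_matrix(f.annotations, genomes=list(f.metadata["genome_id"]))
        venn = peptidase_venn(pm, f.metadata)
        assert venn.count(GROUPS) == 6
        for group in GROUPS:
            assert venn.count([group]) >= 1

    def test_region_counts_conserve_families(self):
        f = make_fixture("W4_peptidases")
        pm = build_presence_matrix(f.annotations, genomes=list(f.metadata["genome_id"]))
        venn = peptidase_venn(pm, f.metadata)
        gp = group_presence(pm, f.metadata)
        merops = [g for g in pm.genes if pm.namespace[g] == "MEROPS"]
        with_signature = {
            g for g in merops
            if gp[(gp["gene_id"] == g) & gp["present"]].shape[0] > 0
        }
        assert venn.total == len(with_signature)

    def test_venn_invariant_to_genome_order(self):
        f = make_fixture("W4_peptidases")
        shuffled = f.annotations.sample(frac=1.0, random_state=0)
        pm1 = build_presence_matrix(f.annotations, genomes=list(f.metadata["genome_id"]))
        pm2 = build_presence_matrix(shuffled, genomes=list(f.metadata["genome_id"][::-1]))
        v1 = peptidase_venn(pm1, f.metadata)
        v2 = peptidase_venn(pm2, f.metadata.iloc[::-1])
        assert v1.regions == v2.regions

    def test_cazy_copy_sums_and_group_means(self):
        meta = _meta(
            [("g1", "Oligoflexia", "marine"), ("g2", "Oligoflexia", "marine")]
        )
        ann = _ann(
            [
                ("g1", "CAZy", "GT2", 3),
                ("g1", "CAZy", "GT4", 1),
                ("g2", "CAZy", "GT2", 2),
            ]
        )
        pm = build_presence_matrix(ann, genomes=["g1", "g2"])
        counts = cazy_class_counts(pm, meta)
        assert counts.loc[counts["group"] == "Oligoflexia", "GT"].iloc[0] == 3.0

    def test_unrecognized_class_prefix_warns_and_excludes(self):
        meta = _meta([("g1", "Oligoflexia", "marine")])
        ann = _ann([("g1", "CAZy", "ZZ9", 1), ("g1", "CAZy", "GH18", 2)])
        pm = build_presence_matrix(ann, genomes=["g1"])
        with pytest.warns(UserWarning, match="ZZ9"):
            counts = cazy_class_counts(pm, meta)
        assert counts["GH"].iloc[0] == 2.0

    def test_planted_gt_excess_recovered(self):
        meta_rows, ann_rows = [], []
        for group, gt_copies in zip(GROUPS, (6, 2, 2, 2)):
            for i in range(3):
                gid = f"{group[:2]}{i}"
                meta_rows.append((gid, group, "marine"))
                ann_rows.append((gid, "CAZy", "GT2", gt_copies))
        pm = build_presence_matrix(_ann(ann_rows))
        counts = cazy_class_counts(pm, _meta(meta_rows)).set_index("group")
        assert counts["GT"].idxmax() == "Oligoflexia"


class TestSourceTally:
    def test_w2_marine_fractions(self):
        f = make_fixture("W2_sources")
        tally = source_tally(f.metadata)
        marine = tally[tally["environment"] == "marine"].set_index("group")
        assert marine.at["Bacteriovoracia", "pct"] == 43.40
        assert marine.at["Bdello-group2", "pct"] == 46.81

    def test_single_genome_group_is_100pct(self):
        tally = source_tally(_meta([("g1", "Oligoflexia", "ground water")]))
        assert tally.iloc[0]["pct"] == 100.0

    def test_percentages_sum_to_100_before_rounding(self):
        f = make_fixture("W2_sources")
        tally = source_tally(f.metadata)
        sums = tally.groupby("group").apply(
            lambda s: s["n"].sum() / s["n_group"].iloc[0], include_groups=False
        )
        assert (sums == 1.0).all()


@given(st.data())
def test_group_specific_consistent_with_presence_flag(data):
    """A group-level present flag can only coexist with specificity to that
    group (or no specificity at all), never to another group."""
    fractions = data.draw(
        st.tuples(*[st.sampled_from([0.0, 0.25, 0.5, 0.51, 0.75, 1.0])] * 4)
    )
    gp = pd.DataFrame(
        {"gene_id": ["K1"] * 4, "group": list(GROUPS), "fraction": fractions}
    )
    label = call_group_specific(gp, "K1")
    for group, frac in zip(GROUPS, fractions):
        if frac >= 0.5 and label is not None and label != group:
            # the other group must exceed strictly while this one sits at <= 0.5
            assert frac <= 0.5
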