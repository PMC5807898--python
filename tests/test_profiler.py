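import io

import numpy as np
import pytest

from viromass.profiler import (
    UNASSIGNED,
    BlastHitRecord,
    TaxonomicProfile,
    assign_reads,
    build_profile,
    collapse_minor,
    filter_hits,
    lca_assign,
    parse_blast_tab,
    read_subject_map,
)
from viromass.taxonomy import TaxonomyTree

from conftest import random_tree


def make_hit(query="r1", subject="FamA", evalue=1e-10, bitscore=100.0):
    return BlastHitRecord(
        query_id=query, subject=subject, percent_identity=90.0,
        alignment_length=80, mismatches=8, gap_opens=0,
        qstart=1, qend=80, sstart=1, send=80, evalue=evalue, bitscore=bitscore,
    )


def tab_line(query="r1", subject="FamA", evalue="1e-10", bitscore="100"):
    return "\t".join(
        [query, subject, "90.0", "80", "8", "0", "1", "80", "1", "80", evalue, bitscore]
    )


class TestParseBlastTab:
    def test_empty_stream(self):
        result = parse_blast_tab(io.StringIO(""))
        assert result.hits == () and result.malformed == ()

    def test_three_lines_preserve_order(self):
        text = "\n".join(tab_line(query=f"r{i}") for i in range(3)) + "\n"
        result = parse_blast_tab(io.StringIO(text))
        assert [h.query_id for h in result.hits] == ["r0", "r1", "r2"]

    def test_malformed_lines_collected_not_fatal(self):
        lines = [tab_line("r1"), "only\televen" + "\tx" * 9, tab_line("r2"),
                 tab_line("r3", evalue="notanumber")]
        result = parse_blast_tab(io.StringIO("\n".join(lines) + "\n"))
        assert [h.query_id for h in result.hits] == ["r1", "r2"]
        assert [m.lineno for m in result.malformed] == [2, 4]

    def test_comments_and_blanks_skipped(self):
        text = "# BLASTX\n\n" + tab_line("r1") + "\n"
        result = parse_blast_tab(io.StringIO(text))
        assert len(result.hits) == 1 and not result.malformed


class TestFilterHits:
    def test_boundary_is_strict(self):
        hits = [make_hit(evalue=1e-5), make_hit(evalue=0.99e-5)]
        kept = filter_hits(hits, 1e-5)
        assert kept == [hits[1]]

    def test_all_above_threshold(self):
        assert filter_hits([make_hit(evalue=1.0)], 1e-5) == []

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(11)
        hits = [make_hit(query=f"r{i}", evalue=float(10.0 ** rng.uniform(-30, 1)))
                for i in range(200)]
        threshold = 1e-5
        assert filter_hits(hits, threshold) == [h for h in hits if h.evalue < threshold]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_hits([], 0.0)


class TestLcaAssign:
    def test_single_hit_identity(self, tiny_tree):
        a = lca_assign([make_hit(subject="FamA")], tiny_tree)
        assert a.assigned_taxon == "FamA" and a.n_hits_used == 1

    def test_two_families_meet_at_clade(self, tiny_tree):
        hits = [make_hit(subject="FamA"), make_hit(subject="FamB")]
        assert lca_assign(hits, tiny_tree).assigned_taxon == "ssDNA viruses"

    def test_cross_type_families_meet_at_superkingdom(self, tiny_tree):
        hits = [make_hit(subject="FamA"), make_hit(subject="FamC")]
        assert lca_assign(hits, tiny_tree).assigned_taxon == "Viruses"

    def test_weak_hits_dropped_by_min_bitscore(self, tiny_tree):
        hits = [make_hit(subject="FamA", bitscore=100.0),
                make_hit(subject="FamC", bitscore=40.0)]
        assert lca_assign(hits, tiny_tree).assigned_taxon == "FamA"

    def test_top_percent_window(self, tiny_tree):
        hits = [make_hit(subject="FamA", bitscore=100.0),
                make_hit(subject="FamB", bitscore=89.0)]  # below 90% of best
        assert lca_assign(hits, tiny_tree, top_percent=10.0).assigned_taxon == "FamA"
        # at exactly the window edge the hit is retained
        hits[1] = make_hit(subject="FamB", bitscore=90.0)
        assert lca_assign(hits, tiny_tree, top_percent=10.0).assigned_taxon == "ssDNA viruses"

    def test_no_retained_hits_unassigned(self, tiny_tree):
        a = lca_assign([make_hit(bitscore=10.0)], tiny_tree)
        assert a.assigned_taxon == UNASSIGNED and a.n_hits_used == 0

    def test_unknown_subject_skipped_with_warning(self, tiny_tree):
        hits = [make_hit(subject="FamA"), make_hit(subject="NotATaxon")]
        with pytest.warns(UserWarning, match="absent from"):
            a = lca_assign(hits, tiny_tree)
        assert a.assigned_taxon == "FamA" and a.n_unresolved_subjects == 1

    def test_subject_map_resolution(self, tiny_tree):
        mapping = read_subject_map(io.StringIO("gi|123\tFamA\n"))
        a = lca_assign([make_hit(subject="gi|123")], tiny_tree, subject_map=mapping)
        assert a.assigned_taxon == "FamA"

    def test_mixed_reads_rejected(self, tiny_tree):
        with pytest.raises(ValueError, match="multiple reads"):
            lca_assign([make_hit("r1"), make_hit("r2")], tiny_tree)

    def test_equals_ancestor_intersection_oracle(self):
        """LCA placement equals a brute-force oracle (intersect the full
        ancestor sets of retained hits' taxa, take the deepest shared node)
        on >= 1000 randomized tree/hit-set instances."""
        rng = np.random.default_rng(123)
        n_checked = 0
        for _ in range(250):
            tree = random_tree(rng, int(rng.integers(3, 60)))
            names = list(tree)
            for _ in range(4):
                n_hits = int(rng.integers(1, 21))
                hits = [
                    make_hit(
                        subject=names[rng.integers(0, len(names))],
                        bitscore=float(rng.uniform(20, 200)),
                    )
                    for _ in range(n_hits)
                ]
                got = lca_assign(hits, tree, min_bitscore=50.0, top_percent=10.0)
                # oracle: same retention rule, then deepest common ancestor by
                # set intersection instead of path-prefix walking
                strong = [h for h in hits if h.bitscore >= 50.0]
                if strong:
                    best = max(h.bitscore for h in strong)
                    retained = [h for h in strong if h.bitscore >= 0.9 * best]
                else:
                    retained = []
                if not retained:
                    assert got.assigned_taxon == UNASSIGNED
                else:
                    common = set.intersection(
                        *(set(tree.ancestors(h.subject, include_self=True))
                          for h in retained)
                    )
                    expected = max(common, key=tree.depth)
                    assert got.assigned_taxon == expected
                n_checked += 1
        assert n_checked >= 1000


class TestProfiles:
    def test_single_family_profile(self, tiny_tree):
        hits = [make_hit(query=f"r{i}", subject="FamB") for i in range(5)]
        profile = build_profile(assign_reads(hits, tiny_tree), tiny_tree)
        assert profile.counts == {"FamB": 5}
        assert profile.viral_reads == 5

    def test_genus_rolls_up_to_family(self, tiny_tree):
        hits = [make_hit(subject="GenB")]
        profile = build_profile(assign_reads(hits, tiny_tree), tiny_tree)
        assert profile.counts == {"FamB": 1}

    def test_na_type_scheme_split(self, tiny_tree):
        hits = [make_hit(query="r1", subject="FamA"),
                make_hit(query="r2", subject="FamA"),
                make_hit(query="r3", subject="FamC")]
        profile = build_profile(assign_reads(hits, tiny_tree), tiny_tree,
                                scheme="na_type")
        assert profile.counts == {"ssDNA": 2, "dsDNA": 1}

    def test_count_conservation(self, tiny_tree):
        rng = np.random.default_rng(5)
        subjects = ["FamA", "FamB", "FamC", "GenB"]
        hits = [
            make_hit(query=f"r{i}", subject=subjects[rng.integers(0, 4)],
                     bitscore=float(rng.uniform(20, 200)))
            for i in range(300)
        ]
        assignments = assign_reads(hits, tiny_tree)
        for scheme in ("family", "na_type", "superkingdom"):
            profile = build_profile(assignments, tiny_tree, scheme=scheme)
            assert sum(profile.counts.values()) == len(assignments)

    def test_hit_order_permutation_invariance(self, tiny_tree):
        rng = np.random.default_rng(9)
        subjects = ["FamA", "FamB", "FamC"]
        hits = [
            make_hit(query=f"r{rng.integers(0, 40)}",
                     subject=subjects[rng.integers(0, 3)],
                     bitscore=float(rng.uniform(40, 200)))
            for _ in range(200)
        ]
        base = build_profile(assign_reads(hits, tiny_tree), tiny_tree)
        for seed in range(3):
            perm = list(hits)
            np.random.default_rng(seed).shuffle(perm)
            shuffled = build_profile(assign_reads(perm, tiny_tree), tiny_tree)
            assert shuffled.counts == base.counts

    def test_unknown_scheme_rejected(self, tiny_tree):
        with pytest.raises(ValueError, match="scheme"):
            build_profile([], tiny_tree, scheme="genus")


class TestCollapseMinor:
    def profile(self, counts, tree):
        viral = sum(counts.values())
        return TaxonomicProfile("lib", counts, viral, viral)

    def test_exact_threshold_retained(self, tiny_tree):
        # FamC at exactly 2.0% of viral reads survives a 2% threshold
        profile = self.profile({"FamA": 98, "FamC": 2}, tiny_tree)
        collapsed = collapse_minor(profile, 2.0, tiny_tree)
        assert collapsed.counts == {"FamA": 98, "FamC": 2}

    def test_below_threshold_collapsed_by_type(self, tiny_tree):
        profile = self.profile({"FamA": 980, "FamB": 10, "FamC": 10}, tiny_tree)
        collapsed = collapse_minor(profile, 2.0, tiny_tree)
        assert collapsed.counts == {
            "FamA": 980, "other ssDNA viruses": 10, "other dsDNA viruses": 10
        }

    def test_zero_threshold_identity(self, tiny_tree):
        profile = self.profile({"FamA": 1, "FamC": 999}, tiny_tree)
        assert collapse_minor(profile, 0.0, tiny_tree) is profile

    def test_full_collapse_conserves_total(self, tiny_tree):
        profile = self.profile({"FamA": 30, "FamB": 30, "FamC": 40}, tiny_tree)
        collapsed = collapse_minor(profile, 100.0, tiny_tree)
        assert set(collapsed.counts) <= {
            "other ssDNA viruses", "other dsDNA viruses", "others"
        }
        assert sum(collapsed.counts.values()) == 100

    def test_unassigned_untouched(self, tiny_tree):
        profile = TaxonomicProfile("lib", {"FamA": 99, UNASSIGNED: 100, "FamC": 1},
                                   200, 100)
        collapsed = collapse_minor(profile, 2.0, tiny_tree)
        assert collapsed.counts[UNASSIGNED] == 100
        assert collapsed.counts["other dsDNA viruses"] == 1

    def test_invalid_threshold(self, tiny_tree):
        with pytest.raises(ValueError):
            collapse_minor(self.profile({"FamA": 1}, tiny_tree), 101.0, tiny_tree)
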