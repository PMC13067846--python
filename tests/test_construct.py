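import dataclasses

import numpy as np
import pytest

from pistolkit.construct import (
    build_construct,
    arm_length_series,
    make_inactive_mutant,
    parse_dot_bracket,
    render_dot_bracket,
    simulate_cleavage,
)
from pistolkit.errors import (
    ConfigError,
    CoordinateError,
    NoSiteError,
    ScaffoldIntegrityError,
)
from pistolkit.scaffold import PistolScaffold, load_scaffold
from pistolkit.scanner import CleavageSite, find_gu_sites
from pistolkit.seq_io import Transcript
from pistolkit import synthetic
from oracles import naive_reverse_complement

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def site_at(target, position, frame="transcript"):
    return CleavageSite(transcript_id=target.id, position=position, frame=frame)


@pytest.fixture(scope="module")
def target():
    return synthetic.make_transcript(length=300, planted_gu=(150,), seed=42,
                                     with_cds=False)


class TestBuildConstruct:
    def test_lead_design_has_sixteen_p3_pairs(self, scaffold, target):
        c = build_construct(scaffold, target, site_at(target, 150), p3_len=16)
        assert c.name == "PS150-16"
        assert c.p3_length == 16
        pairs = parse_dot_bracket(c.predicted_duplex)
        n_r = len(c.full_sequence)
        p3_region = set(range(n_r - 16, n_r))
        intermolecular = [(i, j) for i, j in pairs if i < n_r <= j]
        p3_pairs = [(i, j) for i, j in intermolecular if i in p3_region]
        assert len(p3_pairs) == 16
        assert len(intermolecular) == c.p1_length + 16

    def test_arms_are_reverse_complements_of_footprints(self, scaffold, target):
        rng = np.random.default_rng(9)
        sites = find_gu_sites(target)
        for site in rng.choice(sites, size=5, replace=False):
            if site.position < 20 or site.position > 280:
                continue
            c = build_construct(scaffold, target, site, p1_len=6, p3_len=12)
            p = site.position
            upstream = target.sequence[p - 12 : p]
            downstream = target.sequence[p : p + 6]
            assert c.p3_arm == naive_reverse_complement(upstream)
            assert c.p1_arm == naive_reverse_complement(downstream)
            # per-position complementarity, independent of reverse_complement
            for arm, footprint in ((c.p3_arm, upstream), (c.p1_arm, downstream)):
                for a, b in zip(arm, reversed(footprint)):
                    assert (a, b) in WC

    def test_zero_length_arm_rejected(self, scaffold, target):
        with pytest.raises(ConfigError):
            build_construct(scaffold, target, site_at(target, 150), p1_len=0)

    def test_footprint_beyond_end_is_boundary_error(self, scaffold):
        t = Transcript("short", "AAAGUAAAA")
        with pytest.raises(CoordinateError):
            build_construct(scaffold, t, site_at(t, 4), p3_len=16)

    def test_position_without_gu_rejected(self, scaffold, target):
        bad = next(p for p in range(50, 250)
                   if target.sequence[p - 1 : p + 1] != "GU")
        with pytest.raises(NoSiteError):
            build_construct(scaffold, target, site_at(target, bad))

    def test_pure_function(self, scaffold, target):
        a = build_construct(scaffold, target, site_at(target, 150))
        b = build_construct(scaffold, target, site_at(target, 150))
        assert a == b


class TestArmLengthSeries:
    def test_cardinality_and_names(self, scaffold, target):
        series = arm_length_series(scaffold, target, site_at(target, 150), (14, 18))
        assert [c.name for c in series] == [f"PS150-{n}" for n in range(14, 19)]

    def test_shared_core_across_series(self, scaffold, target):
        series = arm_length_series(scaffold, target, site_at(target, 150), (14, 18))
        assert {c.core for c in series} == {scaffold.core}

    def test_each_length_gives_that_many_p3_pairs(self, scaffold, target):
        for c in arm_length_series(scaffold, target, site_at(target, 150), (14, 18)):
            pairs = parse_dot_bracket(c.predicted_duplex)
            n_r = len(c.full_sequence)
            count = sum(1 for i, j in pairs if n_r - c.p3_length <= i < n_r <= j)
            assert count == c.p3_length

    def test_empty_range_empty_list(self, scaffold, target):
        assert arm_length_series(scaffold, target, site_at(target, 150), (16, 15)) == []


class TestInactiveMutant:
    def test_differs_at_exactly_two_catalytic_positions(self, scaffold, target):
        c = build_construct(scaffold, target, site_at(target, 150))
        m5 = make_inactive_mutant(c, scaffold)
        diff = [i for i, (a, b) in enumerate(zip(c.full_sequence, m5.full_sequence))
                if a != b]
        expected = [c.p1_length + scaffold.catalytic_g - 1,
                    c.p1_length + scaffold.catalytic_c - 1]
        assert diff == expected
        assert (c.full_sequence[diff[0]], m5.full_sequence[diff[0]]) == ("G", "U")
        assert (c.full_sequence[diff[1]], m5.full_sequence[diff[1]]) == ("C", "A")
        assert (m5.p1_arm, m5.p3_arm) == (c.p1_arm, c.p3_arm)

    def test_hamming_two_for_every_series_member(self, scaffold, target):
        for c in arm_length_series(scaffold, target, site_at(target, 150), (14, 18)):
            m5 = make_inactive_mutant(c, scaffold)
            assert sum(a != b for a, b in zip(c.full_sequence, m5.full_sequence)) == 2

    def test_mutating_a_mutant_rejected(self, scaffold, target):
        m5 = make_inactive_mutant(
            build_construct(scaffold, target, site_at(target, 150)), scaffold)
        with pytest.raises(ConfigError):
            make_inactive_mutant(m5, scaffold)

    def test_scaffold_mismatch_is_integrity_error(self, scaffold, target):
        c = build_construct(scaffold, target, site_at(target, 150))
        wrong = dataclasses.replace(scaffold, catalytic_g=scaffold.catalytic_g,
                                    catalytic_c=scaffold.catalytic_c)
        corrupted = dataclasses.replace(
            c, full_sequence=c.full_sequence[: c.p1_length + scaffold.catalytic_g - 1]
            + "A" + c.full_sequence[c.p1_length + scaffold.catalytic_g :])
        with pytest.raises(ScaffoldIntegrityError):
            make_inactive_mutant(corrupted, wrong)


class TestSimulateCleavage:
    def test_46nt_substrate_cut_into_29_and_17(self, scaffold, target):
        # register a 46-nt window so the G of the site is its 29th base
        p = 150
        substrate = target.sequence[p - 29 : p - 29 + 46]
        c = build_construct(scaffold, target, site_at(target, p), p1_len=8, p3_len=16)
        out = simulate_cleavage(c, substrate)
        assert out.cleaved
        assert (len(out.products.fragment5), len(out.products.fragment3)) == (29, 17)
        assert out.products.end5_chemistry == "2',3'-cyclic phosphate"
        assert out.products.end3_chemistry == "5'-hydroxyl"

    def test_cleavage_conserves_length_and_content(self, scaffold, target):
        rng = np.random.default_rng(3)
        for site in rng.choice(find_gu_sites(target)[5:-5], size=6, replace=False):
            if not 30 < site.position < 270:
                continue
            c = build_construct(scaffold, target, site, p1_len=6, p3_len=8)
            lo = max(0, site.position - 25)
            substrate = target.sequence[lo : site.position + 20]
            out = simulate_cleavage(c, substrate)
            assert out.products.fragment5 + out.products.fragment3 == substrate

    def test_m5_gives_explicit_no_cleavage(self, scaffold, target):
        c = build_construct(scaffold, target, site_at(target, 150))
        m5 = make_inactive_mutant(c, scaffold)
        substrate = target.sequence[120:180]
        out = simulate_cleavage(m5, substrate)
        assert not out.cleaved
        assert out.products is None
        assert "dead" in out.reason

    def test_absent_footprint_raises(self, scaffold, target):
        c = build_construct(scaffold, target, site_at(target, 150))
        with pytest.raises(NoSiteError):
            simulate_cleavage(c, "A" * 60)


class TestDotBracket:
    def test_round_trip_parse(self, scaffold, target):
        c = build_construct(scaffold, target, site_at(target, 150))
        substrate = target.sequence[125:180]
        text = render_dot_bracket(c, substrate, scaffold)
        pairs = parse_dot_bracket(text)
        n_r = len(c.full_sequence)
        expected_intra = {
            (c.p1_length + i - 1, c.p1_length + j - 1)
            for i, j in scaffold.p2_pairs + scaffold.pseudoknot_pairs
        }
        assert {p for p in pairs if p[1] < n_r} == expected_intra
        n_inter = sum(1 for i, j in pairs if i < n_r <= j)
        assert n_inter == c.p1_length + c.p3_length

    def test_mismatched_substrate_renders_arms_unpaired(self, scaffold, target):
        c = build_construct(scaffold, target, site_at(target, 150))
        text = render_dot_bracket(c, "A" * 40, scaffold)
        pairs = parse_dot_bracket(text)
        n_r = len(c.full_sequence)
        inter = [(i, j) for i, j in pairs if i < n_r <= j]
        # only arm positions complementary to A (i.e. U) may pair
        assert all(c.full_sequence[i] == "U" for i, _ in inter)

    def test_unbalanced_annotation_rejected(self):
        with pytest.raises(ConfigError):
            parse_dot_bracket("ACGU\n(()")


class TestScaffoldFiles:
    def test_bundled_scaffold_declarations_hold(self, scaffold):
        assert scaffold.core[scaffold.catalytic_g - 1] == "G"
        assert scaffold.core[scaffold.catalytic_c - 1] == "C"
        assert set(scaffold.stems) == {"P2"}

    def test_catalytic_positions_at_40_41_with_default_arm(self, scaffold, target):
        c = build_construct(scaffold, target, site_at(target, 150))
        assert c.p1_length + scaffold.catalytic_g == 40
        assert c.p1_length + scaffold.catalytic_c == 41

    def test_corrupt_scaffold_file_rejected(self, tmp_path, scaffold):
        bad = tmp_path / "bad.txt"
        bad.write_text(
            "name: bad\ncore: AAAAGGGG\ncatalytic_g: 5\ncatalytic_c: 6\n")
        with pytest.raises(ScaffoldIntegrityError):
            load_scaffold(bad)  # position 6 is G, not C

    def test_overlapping_pairs_rejected(self):
        with pytest.raises(ScaffoldIntegrityError):
            PistolScaffold(name="x", core="GGGGAAAACCCC",
                           p2_pairs=((1, 12), (1, 11)), pseudoknot_pairs=(),
                           conserved=(), catalytic_g=1, catalytic_c=9)
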