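"""Read-to-event conversion, duplicate removal, and contact profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fourcat import (
    FragmentMap,
    SimConfig,
    dedup_by_sonication_site,
    profile_from_events,
    reads_to_ligations,
    simulate_library,
)
from fourcat.errors import ConfigError, CoordinateError
from fourcat.ligation import READ_COLUMNS


@pytest.fixture()
def tiny_map():
    return FragmentMap(chrom="c", recognition_site="GATC", bounds=[0, 96, 400, 500])


def reads_frame(rows):
    return pd.DataFrame(rows, columns=READ_COLUMNS)


class TestReadsToLigations:
    def test_forward_read_breakpoint_is_read_end(self, tiny_map):
        events = reads_to_ligations(reads_frame([("c", 100, 180, "+", "B1")]), tiny_map)
        assert events.iloc[0]["fragment"] == 1
        assert events.iloc[0]["breakpoint"] == 180

    def test_reverse_read_breakpoint_is_read_start(self, tiny_map):
        events = reads_to_ligations(reads_frame([("c", 120, 400, "-", "B1")]), tiny_map)
        assert events.iloc[0]["fragment"] == 1  # 5'-most base is end - 1 = 399
        assert events.iloc[0]["breakpoint"] == 120

    def test_straddling_read_assigned_by_five_prime_base(self, tiny_map):
        fwd = reads_to_ligations(reads_frame([("c", 390, 420, "+", "B1")]), tiny_map)
        rev = reads_to_ligations(reads_frame([("c", 390, 420, "-", "B1")]), tiny_map)
        assert fwd.iloc[0]["fragment"] == 1
        assert rev.iloc[0]["fragment"] == 2

    def test_off_chromosome_read_rejected(self, tiny_map):
        with pytest.raises(CoordinateError):
            reads_to_ligations(reads_frame([("other", 10, 20, "+", "B1")]), tiny_map)

    def test_unknown_viewpoint_rejected(self, tiny_map):
        with pytest.raises(ConfigError):
            reads_to_ligations(
                reads_frame([("c", 10, 20, "+", "B9")]), tiny_map, known_viewpoints={"B1"}
            )

    def test_events_match_generator_truth(self, study_fmap, study):
        """Every extracted (fragment, breakpoint) equals the identity the
        generator assigned to that record's molecule."""
        sim = SimConfig(seed=17, n_events=10_000, duplication_rate=0.3)
        lib = simulate_library(
            study_fmap,
            study["viewpoints"]["B1"],
            study["model"],
            study["scenarios"]["naive"],
            sim,
        )
        events = reads_to_ligations(lib.records, study_fmap)
        truth = lib.truth_unique.iloc[lib.records["molecule"].to_numpy()]
        np.testing.assert_array_equal(
            events["fragment"].to_numpy(), truth["fragment"].to_numpy()
        )
        np.testing.assert_array_equal(
            events["breakpoint"].to_numpy(), truth["breakpoint"].to_numpy()
        )


class TestDedup:
    def test_distinct_keys_kept(self):
        events = pd.DataFrame(
            {
                "viewpoint": ["B1"] * 3,
                "fragment": [1, 2, 3],
                "breakpoint": [10, 10, 10],
                "multiplicity": [1, 1, 1],
            }
        )
        assert len(dedup_by_sonication_site(events)) == 3

    def test_key_collapse_records_multiplicity(self):
        events = pd.DataFrame(
            {
                "viewpoint": ["B1"] * 3,
                "fragment": [5, 5, 5],
                "breakpoint": [12100, 12100, 12160],
                "multiplicity": [1, 1, 1],
            }
        )
        out = dedup_by_sonication_site(events)
        assert len(out) == 2
        assert list(out["breakpoint"]) == [12100, 12160]
        assert list(out["multiplicity"]) == [2, 1]

    def test_idempotent(self, study_fmap, study):
        sim = SimConfig(seed=5, n_events=5_000, duplication_rate=0.4)
        lib = simulate_library(
            study_fmap,
            study["viewpoints"]["B1"],
            study["model"],
            study["scenarios"]["naive"],
            sim,
        )
        once = dedup_by_sonication_site(reads_to_ligations(lib.records, study_fmap))
        twice = dedup_by_sonication_site(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_recovers_generator_unique_set_exactly(self, study_fmap, study):
        """Dedup returns the generator's pre-duplication molecule set."""
        sim = SimConfig(seed=6, n_events=100_000, duplication_rate=0.3)
        lib = simulate_library(
            study_fmap,
            study["viewpoints"]["B1"],
            study["model"],
            study["scenarios"]["naive"],
            sim,
        )
        out = dedup_by_sonication_site(reads_to_ligations(lib.records, study_fmap))
        got = set(zip(out["fragment"], out["breakpoint"]))
        want = set(zip(lib.truth_unique["fragment"], lib.truth_unique["breakpoint"]))
        assert got == want

    def test_profile_invariant_under_read_order(self, study_fmap, study):
        sim = SimConfig(seed=7, n_events=5_000, duplication_rate=0.3)
        lib = simulate_library(
            study_fmap,
            study["viewpoints"]["B1"],
            study["model"],
            study["scenarios"]["naive"],
            sim,
        )
        shuffled = lib.records.sample(frac=1.0, random_state=1).reset_index(drop=True)
        kwargs = dict(
            condition="naive",
            bait_position=study["viewpoints"]["B1"].anchor,
            exclusion_halfwidth=2,
        )
        p1 = profile_from_events(
            dedup_by_sonication_site(reads_to_ligations(lib.records, study_fmap)),
            study_fmap,
            **kwargs,
        )
        p2 = profile_from_events(
            dedup_by_sonication_site(reads_to_ligations(shuffled, study_fmap)),
            study_fmap,
            **kwargs,
        )
        np.testing.assert_array_equal(p1.counts, p2.counts)


class TestProfileFromEvents:
    def test_empty_events_give_zero_profile(self, tiny_map):
        events = pd.DataFrame(
            columns=["viewpoint", "fragment", "breakpoint", "multiplicity"]
        )
        profile = profile_from_events(events, tiny_map, condition="naive")
        assert profile.n == 0
        assert np.all(profile.counts == 0)

    def test_one_event_per_fragment(self):
        fmap = FragmentMap(chrom="c", recognition_site="GATC", bounds=range(0, 110, 10))
        events = pd.DataFrame(
            {
                "viewpoint": ["B1"] * 10,
                "fragment": range(10),
                "breakpoint": range(5, 105, 10),
                "multiplicity": [1] * 10,
            }
        )
        profile = profile_from_events(events, fmap, condition="naive")
        assert profile.n == 10
        assert np.all(profile.counts == 1)

    def test_bait_exclusion_zeroes_counts_and_shrinks_n(self):
        fmap = FragmentMap(chrom="c", recognition_site="GATC", bounds=range(0, 110, 10))
        events = pd.DataFrame(
            {
                "viewpoint": ["B1"] * 10,
                "fragment": range(10),
                "breakpoint": range(5, 105, 10),
                "multiplicity": [1] * 10,
            }
        )
        profile = profile_from_events(
            events, fmap, condition="naive", bait_position=45, exclusion_halfwidth=2
        )
        assert np.all(profile.counts[2:7] == 0)
        assert profile.n == 5
        assert profile.excluded_range() == (2, 7)

    def test_counts_match_multinomial_expectation(self, study_fmap, study):
        """Binned dedup counts pass a goodness-of-fit test against the
        generator's probability vector (alpha = 0.01, fixed seed)."""
        sim = SimConfig(seed=13, n_events=50_000, duplication_rate=0.0)
        lib = simulate_library(
            study_fmap,
            study["viewpoints"]["B1"],
            study["model"],
            study["scenarios"]["naive"],
            sim,
        )
        out = dedup_by_sonication_site(reads_to_ligations(lib.records, study_fmap))
        profile = profile_from_events(out, study_fmap, condition="naive")
        nbins = 150
        edges = np.linspace(0, study_fmap.n_fragments, nbins + 1).astype(int)
        observed = np.add.reduceat(profile.counts, edges[:-1])
        expected = np.add.reduceat(lib.truth_probabilities, edges[:-1]) * profile.n
        keep = expected >= 5
        _, p = stats.chisquare(observed[keep], expected[keep] * observed[keep].sum()
                               / expected[keep].sum())
        assert p > 0.01

    def test_sam_round_trip_preserves_reads(self, study_fmap, study, tmp_path):
        from fourcat.ligation import read_reads_sam, write_reads_sam

        sim = SimConfig(seed=19, n_events=500, duplication_rate=0.0)
        lib = simulate_library(
            study_fmap,
            study["viewpoints"]["B1"],
            study["model"],
            study["scenarios"]["naive"],
            sim,
        )
        path = tmp_path / "reads.sam"
        write_reads_sam(lib.records, path, study_fmap)
        back = read_reads_sam(path)
        for col in ("chrom", "start", "end", "strand", "viewpoint"):
            assert list(back[col]) == list(lib.records[col])

    def test_round_trip_through_bedgraph(self, study_fmap, study, tmp_path):
        sim = SimConfig(seed=14, n_events=5_000)
        lib = simulate_library(
            study_fmap,
            study["viewpoints"]["B1"],
            study["model"],
            study["scenarios"]["naive"],
            sim,
        )
        out = dedup_by_sonication_site(reads_to_ligations(lib.records, study_fmap))
        profile = profile_from_events(
            out,
            study_fmap,
            condition="naive",
            bait_position=study["viewpoints"]["B1"].anchor,
        )
        profile.write(tmp_path / "p.bedgraph", tmp_path / "p.json")
        from fourcat.ligation import ContactProfile

        back = ContactProfile.read(tmp_path / "p.bedgraph", tmp_path / "p.json", study_fmap)
        np.testing.assert_array_equal(back.counts, profile.counts)
        assert back.condition == "naive" and back.viewpoint == "B1"
        assert back.n == profile.n
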