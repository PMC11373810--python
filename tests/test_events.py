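"""Event parsing, bout derivation, and session-table round-trips."""

import numpy as np
import pytest

from nestcoord.core import (
    Bout,
    BoutSequence,
    Category,
    SESSION_48H,
    SessionRecord,
    Stage,
    ValidationError,
)
from nestcoord.events import (
    EventKind,
    EventRecord,
    bouts_to_events,
    derive_bouts,
    read_event_log,
    read_session_table,
    write_event_log,
    write_session_table,
)
from nestcoord.simulate import SyntheticConfig, session_events, simulate_pair_session

HEADER = "session_id,pair_id,year,stage,phase,individual_id,sex,t_seconds,kind,food_load\n"


def _ev(t, kind, food=False):
    return EventRecord(t=t, kind=EventKind(kind), individual_id="A", food_load=food)


class TestReadEventLog:
    def test_basic_parse_sorts_and_groups(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(
            HEADER
            + "S1,P1,2019,INCUBATION,15,A,F,3600,vanish,false\n"
            + "S1,P1,2019,INCUBATION,15,A,F,0,appear,false\n"
        )
        (sess,) = read_event_log(p)
        assert list(sess.events) == ["A"]
        assert [e.t for e in sess.events["A"]] == [0, 3600]
        assert sess.sex["A"] == "F"

    def test_alternation_violation_names_individual(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(
            HEADER
            + "S1,P1,2019,INCUBATION,15,B,M,100,nest_enter,false\n"
            + "S1,P1,2019,INCUBATION,15,B,M,200,nest_enter,false\n"
        )
        with pytest.raises(ValidationError, match="B.*nest_enter"):
            read_event_log(p)

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(HEADER)
        assert read_event_log(p) == []

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(HEADER + "S1,P1,2019,INCUBATION,15,A,F,notanumber,appear,false\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_event_log(p)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(ValidationError, match="header"):
            read_event_log(p)

    def test_timestamp_outside_session_rejected(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(HEADER + f"S1,P1,2019,INCUBATION,15,A,F,{SESSION_48H + 5},appear,false\n")
        with pytest.raises(ValidationError, match="outside"):
            read_event_log(p)


class TestDeriveBouts:
    def test_long_absence_is_foraging(self):
        # colony 0-1000, away 1000-8200 (2 h >= 1 h), colony to end
        events = [_ev(1000, "vanish"), _ev(8200, "appear")]
        seq, _ = derive_bouts(events, Stage.INCUBATION, 10000)
        assert [(b.category, b.start, b.end) for b in seq] == [
            (Category.COLONY, 0, 1000),
            (Category.FORAGING, 1000, 8200),
            (Category.COLONY, 8200, 10000),
        ]

    def test_short_absence_bridged_as_colony(self):
        events = [_ev(1000, "vanish"), _ev(2800, "appear")]  # 1800 s < 1 h
        seq, _ = derive_bouts(events, Stage.INCUBATION, 5000)
        assert len(seq) == 1 and seq[0].category is Category.COLONY

    def test_food_return_is_foraging_regardless_of_length(self):
        events = [_ev(1000, "vanish"), _ev(3000, "appear", food=True)]  # 2000 s < 1 h
        seq, _ = derive_bouts(events, Stage.CHICK_REARING, 5000)
        forage = [b for b in seq if b.category is Category.FORAGING]
        assert forage == [Bout(Category.FORAGING, 1000, 3000, True)]

    def test_long_absence_without_food_flagged_nonprovisioning(self):
        events = [_ev(1000, "vanish"), _ev(9000, "appear", food=False)]
        seq, _ = derive_bouts(events, Stage.CHICK_REARING, 10000)
        (forage,) = [b for b in seq if b.category is Category.FORAGING]
        assert forage.food is False

    def test_nest_time(self):
        events = [_ev(100, "nest_enter"), _ev(5000, "nest_exit")]
        seq, extrap = derive_bouts(events, Stage.INCUBATION, 6000)
        assert seq.time_in(Category.NEST) == 4900
        assert extrap  # leading span before the first event was inferred

    def test_event_beyond_duration_errors(self):
        with pytest.raises(ValidationError, match="beyond"):
            derive_bouts([_ev(100, "vanish"), _ev(9000, "appear")], Stage.INCUBATION, 5000)

    def test_empty_events_error(self):
        with pytest.raises(ValidationError):
            derive_bouts([], Stage.INCUBATION, 100)

    @pytest.mark.parametrize("stage", [Stage.INCUBATION, Stage.CHICK_REARING])
    def test_tiling_and_merging_invariants(self, stage):
        cfg = SyntheticConfig(stage=stage, kappa=0.4)
        for seed in range(5):
            s = simulate_pair_session(cfg, rng=seed)
            for seq in (s.bouts_f, s.bouts_m):
                assert sum(b.length for b in seq) == s.duration
                for a, b in zip(seq, seq.bouts[1:]):
                    assert a.category is not b.category

    @pytest.mark.parametrize("stage", [Stage.INCUBATION, Stage.CHICK_REARING])
    def test_round_trip_bouts_events_bouts(self, stage):
        """bouts -> synthetic events -> bouts is the identity."""
        cfg = SyntheticConfig(stage=stage, kappa=0.6)
        for seed in range(8):
            s = simulate_pair_session(cfg, rng=seed)
            for seq in (s.bouts_f, s.bouts_m):
                events = bouts_to_events(seq, stage, "X")
                back, _ = derive_bouts(events, stage, s.duration)
                assert back == seq


class TestSessionTable:
    def _session(self, seed=0):
        return simulate_pair_session(
            SyntheticConfig(stage=Stage.CHICK_REARING, kappa=0.3),
            rng=seed,
            session_id=f"S{seed}",
            pair_id="P07",
            year=2020,
            phase="MID",
        )

    def test_round_trip(self, tmp_path):
        s = self._session()
        write_session_table([s], tmp_path / "bouts.csv")
        (back,) = read_session_table(tmp_path / "bouts.csv")
        assert back.bouts_f == s.bouts_f and back.bouts_m == s.bouts_m
        assert (back.pair_id, back.year, back.stage, back.phase) == (
            s.pair_id,
            s.year,
            s.stage,
            s.phase,
        )

    def test_zero_sessions_header_only(self, tmp_path):
        write_session_table([], tmp_path / "bouts.csv")
        assert read_session_table(tmp_path / "bouts.csv") == []
        header = (tmp_path / "bouts.csv").read_text().splitlines()[0]
        assert header.startswith("session_id,individual_id,category")

    def test_refuses_invalid_session(self, tmp_path):
        s = self._session()
        s.bouts_m = BoutSequence([Bout(Category.COLONY, 0, 100)], 100)  # wrong span
        with pytest.raises(ValidationError):
            write_session_table([s], tmp_path / "bouts.csv")

    def test_event_log_round_trip(self, tmp_path):
        s = simulate_pair_session(
            SyntheticConfig(stage=Stage.INCUBATION, kappa=0.5), rng=4, phase=12.0
        )
        write_event_log([session_events(s)], tmp_path / "ev.csv")
        (sess,) = read_event_log(tmp_path / "ev.csv")
        fid = f"{s.pair_id}-F"
        seq, _ = derive_bouts(sess.events[fid], sess.stage, sess.duration)
        assert seq == s.bouts_f


class TestSessionRecordValidation:
    def test_phase_coherence(self):
        s = simulate_pair_session(SyntheticConfig(stage=Stage.INCUBATION), rng=0)
        with pytest.raises(ValidationError, match="phase"):
            SessionRecord(
                session_id="X",
                pair_id="P",
                year=2019,
                stage=Stage.INCUBATION,
                phase="EARLY",  # days-before-hatching required for incubation
                duration=s.duration,
                bouts_f=s.bouts_f,
                bouts_m=s.bouts_m,
            )
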