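"""Event-log parsing, transition reconstruction, visits and sessions."""

import io

import numpy as np
import pandas as pd
import pytest

from colonytrack.events import (
    EventLog,
    EventLogError,
    ScheduleError,
    SessionSchedule,
    Topology,
    TopologyError,
    Tube,
    assign_sessions,
    build_visits,
    read_event_log,
    reconstruct_transitions,
    split_visits_by_session,
    write_event_log,
)

TOY = Topology(
    compartments=("NC", "CC", "FC"),
    tubes=(Tube("ant3", "ant4", "CC", "NC"), Tube("ant5", "ant6", "CC", "FC")),
    floor_antennas={"f1": "NC"},
)


def _log(rows):
    return EventLog(
        pd.DataFrame(
            rows, columns=["timestamp", "mouse_id", "sensor_id", "sensor_kind", "extra"]
        )
    )


class TestReadEventLog:
    HEADER = "timestamp\tmouse_id\tsensor_id\tsensor_kind\textra\n"

    def test_sorted_roundtrip(self, tmp_path):
        text = self.HEADER + (
            "1000\tm1\tant3\ttube_antenna\t\n"
            "1600\tm1\tant4\ttube_antenna\t\n"
            "2000\tm2\tf1\tfloor_antenna\t\n"
        )
        log = read_event_log(io.StringIO(text), topology=TOY)
        assert len(log) == 3
        assert list(log.data["timestamp"]) == [1000, 1600, 2000]
        out = tmp_path / "events.tsv"
        write_event_log(log, out)
        assert out.read_text() == text  # bit-exact canonical round-trip

    def test_out_of_order_rows_are_stably_resorted(self):
        text = self.HEADER + (
            "2000\tm2\tf1\tfloor_antenna\t\n"
            "1000\tm1\tant3\ttube_antenna\t\n"
        )
        log = read_event_log(io.StringIO(text))
        assert list(log.data["timestamp"]) == [1000, 2000]

    def test_same_millisecond_total_order(self):
        # simultaneous detections ordered by (timestamp, sensor_id, mouse_id)
        text = self.HEADER + (
            "1000\tm1\tant4\ttube_antenna\t\n"
            "1000\tm1\tant3\ttube_antenna\t\n"
        )
        log = read_event_log(io.StringIO(text))
        assert list(log.data["sensor_id"]) == ["ant3", "ant4"]

    def test_unknown_sensor_named_in_error(self):
        text = self.HEADER + "1000\tm1\tant99\ttube_antenna\t\n"
        with pytest.raises(EventLogError, match="ant99"):
            read_event_log(io.StringIO(text), topology=TOY)

    def test_unparseable_timestamp_reports_line(self):
        text = self.HEADER + "1000\tm1\tant3\ttube_antenna\t\nnope\tm1\tant4\ttube_antenna\t\n"
        with pytest.raises(EventLogError, match="line 3"):
            read_event_log(io.StringIO(text))

    def test_malformed_rows_counted_not_dropped_silently(self):
        text = self.HEADER + "1000\tm1\tant3\ttube_antenna\t\nshort\n"
        log = read_event_log(io.StringIO(text))
        assert len(log) == 1
        assert len(log.malformed) == 1 and log.malformed[0][0] == 3

    def test_custom_dialect_column_order(self):
        text = "m1,ant3,1000,tube_antenna\n"
        log = read_event_log(
            io.StringIO(text),
            dialect={"mouse_id": 0, "sensor_id": 1, "timestamp": 2, "sensor_kind": 3},
            sep=",",
            header=False,
        )
        assert log.data.loc[0, "sensor_id"] == "ant3"


class TestTopology:
    def test_shared_antenna_rejected(self):
        with pytest.raises(TopologyError, match="shared"):
            Topology(
                compartments=("A", "B", "C"),
                tubes=(Tube("x", "y", "A", "B"), Tube("y", "z", "B", "C")),
            )

    def test_disconnected_graph_rejected(self):
        with pytest.raises(TopologyError, match="connected"):
            Topology(
                compartments=("A", "B", "C", "D"),
                tubes=(Tube("x", "y", "A", "B"),),
            )

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "topo.yaml"
        p.write_text(
            "compartments: [NC, CC]\n"
            "tubes:\n  - [ant3, ant4, CC, NC]\n"
            "floor_antennas: {f1: NC}\n"
        )
        topo = Topology.from_yaml(p)
        assert topo.tube_antennas == {"ant3", "ant4"}


class TestReconstructTransitions:
    def test_hand_traced_pair(self):
        log = _log([(1000, "m1", "ant3", "tube_antenna", ""),
                    (1600, "m1", "ant4", "tube_antenna", "")])
        tr, rep = reconstruct_transitions(log, TOY)
        assert len(tr) == 1 and rep.total == 0
        row = tr.iloc[0]
        assert (row.from_compartment, row.to_compartment) == ("CC", "NC")
        assert (row.t_start, row.t_end) == (1000, 1600)

    def test_reverse_direction(self):
        log = _log([(1000, "m1", "ant4", "tube_antenna", ""),
                    (1600, "m1", "ant3", "tube_antenna", "")])
        tr, _ = reconstruct_transitions(log, TOY)
        assert (tr.iloc[0].from_compartment, tr.iloc[0].to_compartment) == ("NC", "CC")

    def test_back_out_same_antenna(self):
        log = _log([(1000, "m1", "ant3", "tube_antenna", ""),
                    (1500, "m1", "ant3", "tube_antenna", "")])
        tr, rep = reconstruct_transitions(log, TOY)
        assert len(tr) == 0
        assert rep.counts["same_antenna_repeat"] == 1

    def test_empty_log(self):
        tr, rep = reconstruct_transitions(_log([]), TOY)
        assert len(tr) == 0 and rep.total == 0

    def test_cross_tube_orphan(self):
        # detection on ant3 then ant5 (different tube): ant3 is orphaned
        log = _log([(1000, "m1", "ant3", "tube_antenna", ""),
                    (2000, "m1", "ant5", "tube_antenna", ""),
                    (2500, "m1", "ant6", "tube_antenna", "")])
        tr, rep = reconstruct_transitions(log, TOY)
        assert len(tr) == 1
        assert rep.counts["unpaired_detection"] == 1
        assert tr.iloc[0].to_compartment == "FC"

    def test_inconsistent_origin_resynchronised(self):
        # CC->NC, then (impossibly) CC->FC without returning: trust antennas
        log = _log([(1000, "m1", "ant3", "tube_antenna", ""),
                    (1600, "m1", "ant4", "tube_antenna", ""),
                    (3000, "m1", "ant5", "tube_antenna", ""),
                    (3600, "m1", "ant6", "tube_antenna", "")])
        tr, rep = reconstruct_transitions(log, TOY)
        assert len(tr) == 2
        assert rep.counts["inconsistent_origin"] == 1
        assert tr.iloc[1].to_compartment == "FC"


class TestBuildVisits:
    def test_hand_trace(self):
        tr = pd.DataFrame(
            [("m1", "CC", "NC", 1000, 1600), ("m1", "NC", "FC", 9000, 9600)],
            columns=["mouse_id", "from_compartment", "to_compartment", "t_start", "t_end"],
        )
        v = build_visits(tr)
        assert len(v) == 1
        assert (v.iloc[0].compartment, v.iloc[0].t_enter, v.iloc[0].t_exit) == (
            "NC", 1600, 9600,
        )

    def test_single_transition_yields_no_visit(self):
        tr = pd.DataFrame(
            [("m1", "CC", "NC", 1000, 1600)],
            columns=["mouse_id", "from_compartment", "to_compartment", "t_start", "t_end"],
        )
        assert len(build_visits(tr)) == 0
        tail = build_visits(tr, include_tail=True, log_end=5000)
        assert len(tail) == 1 and tail.iloc[0].t_exit == 5000

    def test_conservation_on_simulated_colony(self, small_colony):
        from colonytrack.events import reconstruct_transitions as rt

        tr, _ = rt(small_colony.events, small_colony.config.topology)
        visits = build_visits(tr)
        for m, g in tr.groupby("mouse_id"):
            v = visits[visits.mouse_id == m]
            tracked = g.t_end.max() - g.t_end.min()
            assert (v.t_exit - v.t_enter).sum() == tracked


class TestSessions:
    SCHED = SessionSchedule([("S1", 0, 1000), ("S2", 1000, 2000)])

    def test_labels_and_halfopen_boundary(self):
        df = pd.DataFrame({"timestamp": [500, 1000, 2500]})
        out = assign_sessions(df, self.SCHED)
        assert list(out.session) == ["S1", "S2", "none"]

    def test_overlap_is_config_error(self):
        with pytest.raises(ScheduleError, match="overlap"):
            SessionSchedule([("S1", 0, 1000), ("S2", 500, 2000)])

    def test_visit_split_at_boundary(self):
        visits = pd.DataFrame(
            [("m1", "NC", 500, 1500)],
            columns=["mouse_id", "compartment", "t_enter", "t_exit"],
        )
        out = split_visits_by_session(visits, self.SCHED)
        assert len(out) == 2
        assert list(out.t_enter) == [500, 1000]
        assert list(out.session) == ["S1", "S2"]
        # split conserves total duration
        assert (out.t_exit - out.t_enter).sum() == 1000
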