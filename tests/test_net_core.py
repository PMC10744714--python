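"""Structure validation, incidence construction, and format round-trips."""

import json

import numpy as np
import pytest

from atheronet.net import (Arc, NetFormatError, PetriNet, Place, Transition,
                           build_incidence_matrix, incidence_to_tsv, read_net,
                           validate_structure, write_net)
from conftest import random_nets


def test_incidence_of_two_place_cycle(cycle2):
    inc = build_incidence_matrix(cycle2)
    assert inc.row_ids == ["p0", "p1"] and inc.col_ids == ["t0", "t1"]
    assert inc.column("t0").tolist() == [-1, 1]
    assert inc.column("t1").tolist() == [1, -1]


def test_incidence_with_weighted_production(fork_net):
    inc = build_incidence_matrix(fork_net)
    assert inc.column("t0").tolist() == [-1, 2]


def test_incidence_is_insertion_order_stable(cycle2):
    shuffled = PetriNet(cycle2.places, cycle2.transitions,
                        list(reversed(cycle2.arcs)))
    a = build_incidence_matrix(cycle2)
    b = build_incidence_matrix(shuffled)
    assert np.array_equal(a.entries, b.entries)


def test_column_sums_match_weight_balance():
    for net in random_nets(25):
        inc = build_incidence_matrix(net)
        for j, tid in enumerate(inc.col_ids):
            out_w = sum(a.weight for a in net.arcs if a.source == tid)
            in_w = sum(a.weight for a in net.arcs if a.target == tid)
            assert inc.entries[:, j].sum() == out_w - in_w


@pytest.mark.parametrize("mutate,needle", [
    (lambda n: n.arcs.append(Arc("p0", "p1")), "bipartiteness"),
    (lambda n: n.transitions.append(Transition("t0")), "duplicate transition"),
    (lambda n: n.arcs.append(Arc("p0", "t_missing")), "dangling"),
    (lambda n: n.arcs.append(Arc("p1", "t0", 0)), "non-positive weight"),
])
def test_validation_flags_structural_violations(cycle2, mutate, needle):
    assert validate_structure(cycle2).ok
    mutate(cycle2)
    report = validate_structure(cycle2)
    assert not report.ok
    assert any(needle in v for v in report)


def test_logical_places_collapse_before_analysis():
    net = PetriNet(
        [Place("p0"), Place("p0__1", is_logical=True), Place("p1")],
        [Transition("t0"), Transition("t1")],
        [Arc("p0", "t0"), Arc("t0", "p1"), Arc("p1", "t1"), Arc("t1", "p0__1")],
    )
    inc = build_incidence_matrix(net)
    assert inc.row_ids == ["p0", "p1"]
    assert inc.column("t1").tolist() == [1, -1]


@pytest.mark.parametrize("fmt", ["native-json", "pnml"])
def test_round_trip_identity_on_random_nets(tmp_path, fmt):
    suffix = ".json" if fmt == "native-json" else ".pnml"
    for i, net in enumerate(random_nets(100)):
        path = tmp_path / f"net{i}{suffix}"
        write_net(net, path, fmt)
        back = read_net(path, fmt)
        assert [p.id for p in back.places] == [p.id for p in net.places]
        assert [t.id for t in back.transitions] == [t.id for t in net.transitions]
        assert {(a.source, a.target, a.weight) for a in back.arcs} == \
               {(a.source, a.target, a.weight) for a in net.arcs}
        assert {p.id: p.initial_tokens for p in back.places} == \
               {p.id: p.initial_tokens for p in net.places}


def test_pnml_missing_inscription_defaults_to_weight_one(tmp_path, cycle2):
    path = tmp_path / "c.pnml"
    write_net(cycle2, path, "pnml")  # unit weights carry no inscription element
    text = path.read_text()
    assert "inscription" not in text
    back = read_net(path)
    assert all(a.weight == 1 for a in back.arcs)


def test_read_errors_carry_context(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(NetFormatError, match="line"):
        read_net(bad)
    with pytest.raises(NetFormatError, match="unsupported"):
        read_net(bad, "sbml")
    notpt = tmp_path / "notpt.pnml"
    notpt.write_text('<pnml xmlns="http://www.pnml.org/version-2009/grammar/pnml">'
                     '<net id="n" type="http://example.org/colored"/></pnml>')
    with pytest.raises(NetFormatError, match="PT nets"):
        read_net(notpt)


def test_incidence_tsv_layout(cycle2):
    tsv = incidence_to_tsv(build_incidence_matrix(cycle2))
    lines = tsv.splitlines()
    assert lines[0].split("\t") == ["", "t0", "t1"]
    assert lines[1].split("\t") == ["p0", "-1", "1"]
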