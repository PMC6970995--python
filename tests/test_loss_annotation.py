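"""Neutral-loss matching, the loss library, and fragment-graph construction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isofrag.loss_annotation import (
    LossLibraryError,
    build_fragment_graph,
    load_loss_library,
    match_loss,
    save_loss_library,
)
from isofrag.spectrum_io import IonSpecies, Peak, PrecursorIon, Spectrum

REQUIRED_LOSSES = {
    "NH3", "CH5N", "C2H7N", "CH4O", "CH4", "CH2O", "CO", "CH3", "H2O",
    "CO2", "C2H4", "C2H5N", "H2", "C3H6O", "C4H8O",
}


def _spec(prec, peaks, species=IonSpecies.PROTONATED):
    return Spectrum(
        precursor=PrecursorIon(prec, species),
        peaks=tuple(Peak(mz, i) for mz, i in peaks),
        identifier="t",
    )


def test_default_library_contents_and_masses(library, oracle):
    names = {e.name for e in library}
    assert REQUIRED_LOSSES <= names
    by_name = {e.name: e for e in library}
    assert round(by_name["NH3"].mass, 4) == 17.0265
    assert round(by_name["C2H7N"].mass, 4) == 45.0578
    for e in library:  # every stored mass equals brute-force elemental summation
        assert e.mass == pytest.approx(oracle["neutral"](dict(e.formula.counts)), abs=1e-6)
    assert by_name["CH3"].radical and not by_name["CH4"].radical


def test_library_round_trip_and_corruption_check(tmp_path, library):
    path = tmp_path / "lib.tsv"
    save_loss_library(library, path)
    back = load_loss_library(path)
    assert {(e.name, e.formula.hill(), e.radical) for e in back} == {
        (e.name, e.formula.hill(), e.radical) for e in library
    }
    # corrupt one stored mass -> load error
    text = path.read_text().replace("17.0265", "17.0465")
    bad = tmp_path / "bad.tsv"
    bad.write_text(text)
    with pytest.raises(LossLibraryError, match="NH3"):
        load_loss_library(bad)


def test_match_loss_worked_examples(library):
    # high-abundance amine loss: 286.1445 -> 269.1180 is an NH3 loss
    top = match_loss(286.1445, 269.1180, library, 10.0)
    assert top and top[0][0].name == "NH3"
    # the suspected methylamine loss rejected at ~76 ppm
    assert match_loss(336.1226, 305.1039, library, 20.0) == []
    # constructed exact difference matches at ~0 ppm
    hits = match_loss(400.0, 400.0 - 17.02654910, library, 10.0)
    assert hits[0][0].name == "NH3"
    assert abs(hits[0][1]) < 1e-6


def test_match_loss_contract():
    with pytest.raises(ValueError):
        match_loss(100.0, 200.0, [], 10.0)


def test_graph_finds_printed_chelidonine_chain(library):
    s = _spec(354.1313, [(336.1210, 80), (305.0785, 40), (275.0683, 60), (247.0737, 30)])
    g = build_fragment_graph(s, library, 10.0)
    labelled = {(round(e.parent_mz, 4), round(e.child_mz, 4), e.loss_name) for e in g.edges}
    assert {(354.1313, 336.1210, "H2O"),
            (305.0785, 275.0683, "CH2O"),
            (275.0683, 247.0737, "CO")} <= labelled


def test_graph_single_methanol_loss(library):
    s = _spec(300.0, [(300.0 - 32.02621474, 10.0)])
    g = build_fragment_graph(s, library, 10.0)
    assert len(g.edges) == 1 and g.edges[0].loss_name == "CH4O"
    assert g.edges[0].parent_is_precursor


def test_unrelated_peaks_stay_unmatched(library):
    # peaks chosen, then verified exhaustively, to be >10 ppm from every
    # library loss for every pair difference
    peaks = [101.3, 168.9, 212.71, 267.13]
    prec = 411.57
    masses = [e.mass for e in library]
    for pm in [prec] + peaks:
        for cm in peaks:
            if cm >= pm:
                continue
            for m in masses:
                expected = pm - m
                if expected > 0:
                    assert abs((cm - expected) / expected * 1e6) > 10.0
    g = build_fragment_graph(_spec(prec, [(p, 5.0) for p in peaks]), library, 10.0)
    assert g.edges == ()
    assert {p.mz for p in g.unmatched} == set(peaks)


def test_graph_edges_respect_tolerance_invariant(library):
    s = _spec(354.1313, [(336.1210, 80), (305.0785, 40), (275.0683, 60), (247.0737, 30)])
    g = build_fragment_graph(s, library, 10.0)
    for e in g.edges:
        expected = e.parent_mz - e.entry.mass
        assert abs((e.child_mz - expected) / expected * 1e6) <= 10.0
        assert e.parent_mz > e.child_mz


@given(st.permutations([(336.1210, 80.0), (305.0785, 40.0), (275.0683, 60.0), (247.0737, 30.0)]))
def test_graph_is_invariant_to_peak_order(library, order):
    reference = build_fragment_graph(_spec(354.1313, order), library, 10.0)
    again = build_fragment_graph(
        _spec(354.1313, list(reversed(order))), library, 10.0
    )
    key = lambda g: [(e.parent_mz, e.child_mz, e.loss_name, e.ppm) for e in g.edges]
    assert key(reference) == key(again)


@given(st.integers(0, 2**31 - 1))
def test_widening_tolerance_never_removes_edges(library, seed):
    rng = np.random.default_rng(seed)
    prec = float(rng.uniform(250, 600))
    peaks = [(float(rng.uniform(60, prec - 1)), float(rng.uniform(1, 100))) for _ in range(8)]
    s = _spec(prec, peaks)
    narrow = build_fragment_graph(s, library, 5.0)
    wide = build_fragment_graph(s, library, 25.0)
    edge_key = lambda g: {(e.parent_mz, e.child_mz, e.loss_name) for e in g.edges}
    assert edge_key(narrow) <= edge_key(wide)
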