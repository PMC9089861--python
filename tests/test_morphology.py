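"""Morphology container, SWC round trips and the reduced-morphology generator."""

import math

import numpy as np
import pytest

from ca3burst.morphology import (
    Morphology,
    MorphologyError,
    MorphoSpec,
    Section,
    SWCParseError,
    athorny_spec,
    generate_reduced_morphology,
    read_swc,
    replace_axon,
    thorny_spec,
    write_swc,
)


def _oblique_roots(morph):
    return [s for s in morph.by_region("oblique")
            if morph.section(s.parent_id).region != "oblique"]


class TestSWC:
    def test_minimal_three_point_file(self, tmp_path):
        p = tmp_path / "tiny.swc"
        p.write_text(
            "# comment\n"
            "1 1 0 0 0 10 -1\n"
            "2 3 0 -30 0 1 1\n"
        )
        m = read_swc(p)
        assert len(m.sections) == 2
        child = m.sections[1]
        assert child.parent_id == m.root.id
        assert child.region == "basal"
        assert child.length == pytest.approx(30.0)

    def test_round_trip_preserves_file(self, tmp_path):
        src = tmp_path / "cell.swc"
        src.write_text(
            "1 1 0 0 0 8 -1\n"
            "2 4 0 50 0 2 1\n"
            "3 4 0 100 0 1.5 2\n"
            "4 4 40 120 0 0.5 3\n"
            "5 4 -35 130 0 0.4 3\n"
            "6 2 0 -20 0 1 1\n"
        )
        m = read_swc(src)
        out = tmp_path / "out.swc"
        write_swc(m, out)
        body = [l.split() for l in out.read_text().splitlines()
                if l.strip() and not l.startswith("#")]
        orig = [l.split() for l in src.read_text().splitlines() if l.strip()]
        for a, b in zip(orig, body):
            assert a[0] == b[0] and a[1] == b[1] and a[6] == b[6]
            assert np.allclose([float(x) for x in a[2:6]],
                               [float(x) for x in b[2:6]])

    def test_round_trip_preserves_path_distance(self, tmp_path):
        m = generate_reduced_morphology(thorny_spec(seed=3))
        f = tmp_path / "gen.swc"
        write_swc(m, f)
        m2 = read_swc(f)
        d1 = sorted(s.path_distance_from_soma for s in m.sections)
        d2 = sorted(s.path_distance_from_soma for s in m2.sections)
        assert np.allclose(d1, d2, atol=1e-9)

    def test_forward_parent_reference_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 10 -1\n2 3 0 10 0 1 5\n")
        with pytest.raises(SWCParseError):
            read_swc(p)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 10 -1\n2 3 zero 10 0 1 1\n")
        with pytest.raises(SWCParseError) as exc:
            read_swc(p)
        assert exc.value.line == 2

    def test_apical_sublabels_inferred(self, tmp_path):
        # trunk -> bifurcation -> one side branch off the trunk continues, the
        # other unbranched path to a tip becomes terminal
        p = tmp_path / "apical.swc"
        p.write_text(
            "1 1 0 0 0 8 -1\n"
            "2 4 0 50 0 2 1\n"
            "3 4 0 100 0 2 2\n"
            "4 4 30 130 0 0.6 3\n"
            "5 4 -30 130 0 0.6 3\n"
            "6 4 -60 160 0 0.5 5\n"
        )
        m = read_swc(p)
        regions = {s.id: s.region for s in m.sections}
        assert regions[2] == regions[3] == "apical_trunk"
        assert regions[4] == "terminal"  # unbranched path to a tip
        assert regions[5] == regions[6] == "terminal"


class TestGenerator:
    def test_thorny_oblique_branch_count(self):
        m = generate_reduced_morphology(thorny_spec(n_oblique_or_terminal=5))
        assert len(_oblique_roots(m)) == 5
        assert len(m.by_region("terminal")) == 0

    def test_athorny_has_no_obliques(self):
        m = generate_reduced_morphology(athorny_spec())
        assert len(m.by_region("oblique")) == 0
        assert len(m.by_region("terminal")) > 0

    def test_determinism_under_fixed_seed(self):
        a = generate_reduced_morphology(thorny_spec(seed=11))
        b = generate_reduced_morphology(thorny_spec(seed=11))
        for s, t in zip(a.sections, b.sections):
            assert (s.id, s.parent_id, s.region) == (t.id, t.parent_id, t.region)
            assert s.length == t.length
            assert s.diameter_proximal == t.diameter_proximal

    def test_seed_changes_geometry(self):
        a = generate_reduced_morphology(thorny_spec(seed=1))
        b = generate_reduced_morphology(thorny_spec(seed=2))
        assert any(s.length != t.length for s, t in zip(a.sections, b.sections))

    def test_athorny_dendrites_thicker_by_default(self):
        assert athorny_spec().branch_diameter > thorny_spec().branch_diameter
        assert athorny_spec().basal_diameter > thorny_spec().basal_diameter

    def test_path_distance_nondecreasing_root_to_tip(self):
        m = generate_reduced_morphology(athorny_spec(seed=4))
        for s in m.sections:
            if s.parent_id is None:
                continue
            parent = m.section(s.parent_id)
            if parent.region == "soma":
                continue
            assert s.path_distance_from_soma >= parent.path_distance_from_soma

    def test_zero_branches_rejected(self):
        with pytest.raises(MorphologyError):
            thorny_spec(n_oblique_or_terminal=0)

    def test_generated_morphology_passes_validator(self):
        m = generate_reduced_morphology(thorny_spec(seed=9))
        m.validate()  # raises on any structural defect


class TestReplaceAxon:
    def test_existing_axon_replaced_by_two_stub_sections(self):
        m = generate_reduced_morphology(thorny_spec())
        # graft extra axon sections to emulate a detailed reconstruction
        nid = max(s.id for s in m.sections) + 1
        last = [s for s in m.sections if s.region == "axon"][-1].id
        extra = [Section(nid + k, last + k if k else last, "axon", 15.0, 0.8, 0.8)
                 for k in range(8)]
        for k, s in enumerate(extra):
            s.parent_id = last if k == 0 else extra[k - 1].id
        detailed = Morphology(m.sections + extra, cell_type=m.cell_type)
        assert len(detailed.by_region("axon")) == 10

        replaced = replace_axon(detailed)
        axon = replaced.by_region("axon")
        assert len(axon) == 2
        assert all(s.length == pytest.approx(30.0) for s in axon)
        assert sum(s.length for s in axon) == pytest.approx(60.0)
        assert replaced.section(axon[0].parent_id).region == "soma"

    def test_axonless_input_gains_stub(self):
        m = Morphology([
            Section(1, None, "soma", 20.0, 20.0, 20.0),
            Section(2, 1, "basal", 100.0, 1.0, 0.8),
        ])
        out = replace_axon(m)
        assert len(out.by_region("axon")) == 2

    def test_non_axon_sections_untouched(self):
        m = generate_reduced_morphology(athorny_spec(seed=2))
        out = replace_axon(m)
        before = {s.id: (s.length, s.diameter_proximal, s.diameter_distal)
                  for s in m.sections if s.region != "axon"}
        after = {s.id: (s.length, s.diameter_proximal, s.diameter_distal)
                 for s in out.sections if s.region != "axon"}
        assert before == after


class TestValidation:
    def test_two_roots_rejected(self):
        with pytest.raises(MorphologyError):
            Morphology([
                Section(1, None, "soma", 20.0, 20.0, 20.0),
                Section(2, None, "soma", 20.0, 20.0, 20.0),
            ])

    def test_child_before_parent_rejected(self):
        with pytest.raises(MorphologyError):
            Morphology([
                Section(1, None, "soma", 20.0, 20.0, 20.0),
                Section(3, 2, "basal", 10.0, 1.0, 1.0),
                Section(2, 1, "basal", 10.0, 1.0, 1.0),
            ])

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(MorphologyError):
            Morphology([Section(1, None, "soma", 0.0, 20.0, 20.0)])
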