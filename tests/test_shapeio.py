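import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trilokit.shapeio import (
    CEPHALON,
    PYGIDIUM,
    LandmarkConfiguration,
    ShapeParseError,
    TpsParseError,
    read_metadata,
    read_references,
    read_stereomorph,
    read_tps,
    resolve_structure_suffix,
    write_stereomorph,
    write_tps,
)


# -- tps -----------------------------------------------------------------


class TestReadTps:
    def test_scale_multiplication(self, tmp_path):
        f = tmp_path / "a_C.tps"
        f.write_text("LM=2\n0 0\n3 4\nSCALE=2.0\n")
        (cfg,) = read_tps(f)
        np.testing.assert_allclose(cfg.landmarks, [[0, 0], [6, 8]])
        assert cfg.scale == 2.0
        assert not cfg.unscaled
        assert cfg.structure == CEPHALON

    def test_missing_as_negative(self, tmp_path):
        f = tmp_path / "a_C.tps"
        f.write_text("LM=1\n-1 -1\n")
        (cfg,) = read_tps(f, missing_as_negative=True)
        assert cfg.missing_mask.tolist() == [True]
        (cfg,) = read_tps(f, missing_as_negative=False)
        assert cfg.missing_mask.tolist() == [False]
        np.testing.assert_allclose(cfg.landmarks, [[-1, -1]])

    def test_unscaled_flagged(self, tmp_path):
        f = tmp_path / "a_C.tps"
        f.write_text("LM=1\n1 2\n")
        (cfg,) = read_tps(f)
        assert cfg.unscaled

    def test_curves_and_id(self, tmp_path):
        f = tmp_path / "a_P.tps"
        f.write_text(
            "LM=1\n1 1\nCURVES=2\nPOINTS=2\n0 0\n1 0\nPOINTS=3\n0 0\n1 1\n2 2\nID=spec9\n"
        )
        (cfg,) = read_tps(f)
        assert cfg.specimen_id == "spec9"
        assert [len(c) for c in cfg.curves] == [2, 3]

    def test_multiple_records(self, tmp_path):
        f = tmp_path / "multi_C.tps"
        f.write_text("LM=1\n1 1\nID=a\nLM=1\n2 2\nID=b\n")
        cfgs = read_tps(f)
        assert [c.specimen_id for c in cfgs] == ["a", "b"]

    def test_lm_count_mismatch(self, tmp_path):
        f = tmp_path / "a_C.tps"
        f.write_text("LM=3\n0 0\n1 1\nID=x\n")
        with pytest.raises(TpsParseError, match="line"):
            read_tps(f)

    def test_points_count_mismatch(self, tmp_path):
        f = tmp_path / "a_C.tps"
        f.write_text("LM=1\n0 0\nCURVES=1\nPOINTS=3\n0 0\n1 1\nID=x\n")
        with pytest.raises(TpsParseError, match="line"):
            read_tps(f)

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "a_C.tps"
        f.write_text("LM=1\nnot coordinates here\n")
        with pytest.raises(TpsParseError, match="line 2"):
            read_tps(f)


class TestWriteTps:
    def test_round_trip(self, tmp_path, base_cephalon):
        f = tmp_path / "rt_C.tps"
        write_tps([base_cephalon], f)
        (back,) = read_tps(f)
        np.testing.assert_allclose(back.landmarks, base_cephalon.landmarks, atol=1e-9)
        assert len(back.curves) == len(base_cephalon.curves)
        for a, b in zip(back.curves, base_cephalon.curves):
            np.testing.assert_allclose(a, b, atol=1e-9)
        assert back.scale == base_cephalon.scale

    def test_round_trip_missing_landmark(self, tmp_path, base_cephalon):
        cfg = base_cephalon
        cfg.landmarks[7] = np.nan
        f = tmp_path / "rt_C.tps"
        write_tps([cfg], f)
        (back,) = read_tps(f)
        assert back.missing_mask[7]
        assert back.missing_mask.sum() == 1

    def test_header_layout(self, tmp_path):
        cfg = LandmarkConfiguration("s1", CEPHALON, [[0, 1], [2, 3]],
                                    curves=[np.zeros((12, 2)) + [1, 2], np.ones((20, 2))])
        f = tmp_path / "h_C.tps"
        write_tps([cfg], f)
        text = f.read_text()
        assert "LM=2" in text
        assert "CURVES=2" in text
        assert "POINTS=12" in text
        assert "POINTS=20" in text

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="nothing to write"):
            write_tps([], tmp_path / "x.tps")

    def test_mixed_structures_rejected(self, tmp_path):
        a = LandmarkConfiguration("a", CEPHALON, [[0, 1], [2, 3]])
        b = LandmarkConfiguration("b", PYGIDIUM, [[0, 1], [2, 3]])
        with pytest.raises(ValueError, match="mixed structures"):
            write_tps([a, b], tmp_path / "x.tps")


def test_scale_equivariance(tmp_path):
    body = "LM=2\n1 2\n3 4\nSCALE={s}\n"
    f1, f2 = tmp_path / "a_C.tps", tmp_path / "b_C.tps"
    f1.write_text(body.format(s=1.5))
    f2.write_text(body.format(s=3.0))
    (c1,), (c2,) = read_tps(f1), read_tps(f2)
    np.testing.assert_allclose(c2.landmarks, 2.0 * c1.landmarks)


@settings(max_examples=25, deadline=None)
@given(
    n_lm=st.integers(1, 10),
    curve_lens=st.lists(st.integers(2, 8), max_size=3),
    seed=st.integers(0, 2**31),
)
def test_parser_never_invents_points(tmp_path_factory, n_lm, curve_lens, seed):
    rng = np.random.default_rng(seed)
    cfg = LandmarkConfiguration(
        "x",
        CEPHALON,
        rng.uniform(0, 10, size=(n_lm, 2)),
        curves=[rng.uniform(0, 10, size=(k, 2)) for k in curve_lens],
        scale=float(rng.uniform(0.5, 2.0)),
    )
    f = tmp_path_factory.mktemp("tps") / "p_C.tps"
    write_tps([cfg], f)
    (back,) = read_tps(f)
    assert back.n_landmarks == n_lm
    assert [len(c) for c in back.curves] == curve_lens
    np.testing.assert_allclose(back.landmarks, cfg.landmarks, atol=1e-9)


# -- tag-block (StereoMorph-style) ---------------------------------------


class TestStereomorph:
    def test_full_cephalon(self, tmp_path, base_cephalon, cephalon_template):
        f = tmp_path / "s1_C.txt"
        write_stereomorph(base_cephalon, f, cephalon_template)
        cfg = read_stereomorph(f)
        assert cfg.n_landmarks == 16
        assert len(cfg.curves) == 4
        np.testing.assert_allclose(cfg.landmarks, base_cephalon.landmarks, atol=1e-9)
        for a, b in zip(cfg.curves, base_cephalon.curves):
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_absent_names_flagged_missing(self, tmp_path, base_cephalon, cephalon_template):
        cfg = base_cephalon
        cfg.landmarks[[7, 8, 13]] = np.nan  # LM8, LM9, LM14
        f = tmp_path / "blind_C.txt"
        write_stereomorph(cfg, f, cephalon_template)
        back = read_stereomorph(f)
        assert back.missing_mask[[7, 8, 13]].all()
        assert back.missing_mask.sum() == 3

    def test_ruler_scaling(self, tmp_path):
        f = tmp_path / "r_C.txt"
        f.write_text(
            "<landmarks.pixel>\nLM1\t10\t20\nLM2\t30\t40\n</landmarks.pixel>\n"
            "<ruler.pixel>100.0</ruler.pixel>\n<ruler.interval>50.0</ruler.interval>\n"
        )
        cfg = read_stereomorph(f)
        assert cfg.scale == 0.5
        np.testing.assert_allclose(cfg.landmarks[0], [5, 10])
        np.testing.assert_allclose(cfg.landmarks[1], [15, 20])

    def test_unknown_block_warns(self, tmp_path):
        f = tmp_path / "w_C.txt"
        f.write_text(
            "<landmarks.pixel>\nLM1\t1\t2\n</landmarks.pixel>\n"
            "<mystery.block>\nstuff\n</mystery.block>\n"
        )
        with pytest.warns(UserWarning, match="mystery.block"):
            cfg = read_stereomorph(f)
        assert not cfg.missing_mask[0]

    def test_no_landmark_block_is_error(self, tmp_path):
        f = tmp_path / "e_C.txt"
        f.write_text("<curves.pixel>\nglabella.0001\t1\t2\n</curves.pixel>\n")
        with pytest.raises(ShapeParseError, match="no landmark block"):
            read_stereomorph(f)

    def test_pygidium_round_trip(self, tmp_path, base_pygidium):
        f = tmp_path / "p1_P.txt"
        write_stereomorph(base_pygidium, f)
        back = read_stereomorph(f)
        assert back.structure == PYGIDIUM
        assert back.n_landmarks == 7
        assert len(back.curves) == 3
        np.testing.assert_allclose(back.landmarks, base_pygidium.landmarks, atol=1e-9)


# -- naming convention ---------------------------------------------------


@pytest.mark.parametrize(
    "name,expected",
    [
        ("CEGH-UNC_7316_C.txt", ("CEGH-UNC_7316", CEPHALON)),
        ("X_12_P.tps", ("X_12", PYGIDIUM)),
        ("a_b_c_p.TPS", ("a_b_c", PYGIDIUM)),
        ("lower_c.txt", ("lower", CEPHALON)),
    ],
)
def test_resolve_structure_suffix(name, expected):
    assert resolve_structure_suffix(name) == expected


@pytest.mark.parametrize("name", ["X_12.tps", "plain.txt", "_C.tps", ""])
def test_resolve_structure_suffix_rejects(name):
    with pytest.raises(ValueError):
        resolve_structure_suffix(name)


# -- metadata ------------------------------------------------------------


GOOD_ENTRY = """
SPEC-1:
  ref.pic: "Author 1999 pl. 2"
  enter.metadata: AB
  enter.landmark: AB
  taxonomy:
    orig_genus: Paradoxides
    genus: Paradoxides
    sp: Paradoxides davidis
  morphology:
    cephalon: true
    cranidium: false
    pygidium: false
    eyes: true
    ontogeny: Holaspis
  geography:
    locality: Somewhere
    lat: -31.5
    long: -64.2
  stratigraphy:
    min_age: Givetian
    max_age: Eifelian
"""


class TestReadMetadata:
    def test_complete_entry_has_no_violations(self, tmp_path):
        f = tmp_path / "meta.yaml"
        f.write_text(GOOD_ENTRY)
        (rec,) = read_metadata(f)
        assert rec.id == "SPEC-1"
        assert rec.violations == []
        assert rec.taxonomy.genus == "Paradoxides"
        assert rec.stratigraphy.max_age == "Eifelian"

    def test_missing_mandatory_species(self, tmp_path):
        f = tmp_path / "meta.yaml"
        f.write_text(GOOD_ENTRY.replace("    sp: Paradoxides davidis\n", ""))
        (rec,) = read_metadata(f)
        assert "missing mandatory field taxonomy.sp" in rec.violations

    def test_lat_out_of_range(self, tmp_path):
        f = tmp_path / "meta.yaml"
        f.write_text(GOOD_ENTRY.replace("lat: -31.5", "lat: 123.0"))
        (rec,) = read_metadata(f)
        assert "lat out of range" in rec.violations

    def test_no_structure_flag(self, tmp_path):
        f = tmp_path / "meta.yaml"
        f.write_text(GOOD_ENTRY.replace("cephalon: true", "cephalon: false"))
        (rec,) = read_metadata(f)
        assert "no digitised structure flagged true" in rec.violations

    def test_two_entries(self, tmp_path):
        f = tmp_path / "meta.yaml"
        f.write_text(GOOD_ENTRY + GOOD_ENTRY.replace("SPEC-1", "SPEC-2"))
        records = read_metadata(f)
        assert [r.id for r in records] == ["SPEC-1", "SPEC-2"]

    def test_unparseable_document(self, tmp_path):
        f = tmp_path / "meta.yaml"
        f.write_text("- just\n- a list\n")
        with pytest.raises(ValueError, match="map specimen ids"):
            read_metadata(f)


def test_read_references(tmp_path):
    f = tmp_path / "refs.csv"
    f.write_text("ref_id,citation\nR1,Someone 1999\nR2,Other 2001\n")
    refs = read_references(f)
    assert [r.ref_id for r in refs] == ["R1", "R2"]
    f.write_text("ref_id,citation\nR1,a\nR1,b\n")
    with pytest.raises(ValueError, match="duplicate ref_id"):
        read_references(f)
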