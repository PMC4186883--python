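import json

import numpy as np
import pytest

from dscape.geometry import Conformation, build_cartesian
from dscape.pdb_disulfide import (
    ClassSummary,
    DisulfideGeometry,
    PdbParseError,
    PdbStructure,
    ResidueKey,
    classify,
    find_disulfides,
    measure_disulfide,
    parse_pdb,
    summarize_class,
    survey,
)
from dscape.synthetic import write_disulfide_pdb


def _inline_structure(chi1, chi2, chi3):
    """Exact in-memory two-cysteine structure at prescribed dihedrals."""
    from dscape.synthetic import _fragment_model, _fragment_conformation, _ATOM_MAP

    m = _fragment_model()
    s = build_cartesian(m, _fragment_conformation(chi1, chi2, chi3))
    atoms = {ResidueKey("A", 1): {}, ResidueKey("A", 2): {}}
    for (ires, name), xyz in zip(_ATOM_MAP, s.coords):
        atoms[ResidueKey("A", ires + 1)][name] = xyz.copy()
    return PdbStructure(pdb_id="inline", atoms=atoms,
                        res_names={k: "CYS" for k in atoms})


def _two_cys_pdb(path, sg_gap):
    """Two CYS residues whose SG atoms sit sg_gap apart; no SSBOND record."""
    lines = []
    serial = 0
    for ires, x0 in ((1, 0.0), (2, sg_gap)):
        for name, dx, dy in (("CA", 0.0, 2.8), ("CB", 0.0, 1.4), ("SG", 0.0, 0.0)):
            serial += 1
            x = x0 + dx + (0.3 if name != "SG" else 0.0) * ires
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} CYS A{ires:4d}    "
                f"{x:8.3f}{dy:8.3f}{float(ires):8.3f}  1.00  0.00           {name[0]:>2s}"
            )
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def test_parse_round_trip_with_writer(tmp_path):
    path = write_disulfide_pdb(150.0, 280.0, 100.0, tmp_path / "one.pdb")
    st, decls = parse_pdb(path)
    assert len(decls) == 1
    cys = [k for k, n in st.res_names.items() if n == "CYS"]
    assert len(cys) == 2
    assert all(set(st.atoms[k]) >= {"CA", "CB", "SG"} for k in cys)


def test_parse_without_ssbond(tmp_path):
    path = write_disulfide_pdb(60.0, 60.0, 90.0, tmp_path / "a.pdb")
    text = "\n".join(l for l in path.read_text().splitlines() if not l.startswith("SSBOND"))
    stripped = tmp_path / "nossbond.pdb"
    stripped.write_text(text + "\n")
    st, decls = parse_pdb(stripped)
    assert decls == []
    assert len(find_disulfides(st, decls)) == 1  # geometric detection still works


def test_parse_truncated_line_names_line_number(tmp_path):
    bad = tmp_path / "trunc.pdb"
    bad.write_text("ATOM      1  CA  CYS A   1      12.3\nEND\n")
    with pytest.raises(PdbParseError, match="line 1"):
        parse_pdb(bad)


def test_parse_empty_structure(tmp_path):
    empty = tmp_path / "empty.pdb"
    empty.write_text("HEADER    NOTHING\nEND\n")
    with pytest.raises(PdbParseError, match="no ATOM"):
        parse_pdb(empty)


def test_parse_missing_file():
    with pytest.raises(FileNotFoundError):
        parse_pdb("/nonexistent/file.pdb")


def test_find_disulfides_geometric_cutoff(tmp_path):
    st, _ = parse_pdb(_two_cys_pdb(tmp_path / "near.pdb", sg_gap=2.05))
    assert len(find_disulfides(st, [])) == 1
    st_far, _ = parse_pdb(_two_cys_pdb(tmp_path / "far.pdb", sg_gap=6.0))
    assert find_disulfides(st_far, []) == []


def test_find_disulfides_deduplicates_declared_and_geometric(tmp_path):
    path = write_disulfide_pdb(180.0, 180.0, 90.0, tmp_path / "dup.pdb")
    st, decls = parse_pdb(path)
    assert len(decls) == 1
    assert len(find_disulfides(st, decls + decls)) == 1


def test_find_disulfides_excludes_incomplete_residues(tmp_path, caplog):
    path = _two_cys_pdb(tmp_path / "m.pdb", sg_gap=2.05)
    text = "\n".join(l for l in path.read_text().splitlines() if " CB  CYS A   2" not in l)
    path.write_text(text + "\n")
    st, _ = parse_pdb(path)
    import logging

    with caplog.at_level(logging.WARNING):
        pairs = find_disulfides(st, [])
    assert pairs == []
    assert "missing" in caplog.text


@pytest.mark.parametrize(
    "chi,expected",
    [(180.0, "closed"), (60.0, "open"), (130.0, "closed"), (230.0, "closed"),
     (129.9, "open"), (230.1, "open"), (-180.0, "closed")],
)
def test_classify_band(chi, expected):
    assert classify(chi) == expected
    assert classify(chi + 360.0) == expected


def test_measure_recovers_prescribed_dihedrals_exactly():
    st = _inline_structure(60.0, 180.0, 90.0)
    rec = measure_disulfide(st, (ResidueKey("A", 1), ResidueKey("A", 2)))
    assert rec.chi1 == pytest.approx(60.0, abs=1e-4)
    assert rec.chi2 == pytest.approx(180.0, abs=1e-4)
    assert rec.chi3 == pytest.approx(90.0, abs=1e-4)
    assert rec.joint_state == "open/closed"
    assert not rec.interchain


def test_measure_pair_order_invariance():
    st = _inline_structure(150.0, 300.0, 95.0)
    a, b = ResidueKey("A", 1), ResidueKey("A", 2)
    r1 = measure_disulfide(st, (a, b))
    r2 = measure_disulfide(st, (b, a))
    assert (r1.chi1, r1.chi2, r1.chi3, r1.d_calpha) == (r2.chi1, r2.chi2, r2.chi3, r2.d_calpha)
    # residue a supplies chi1, residue b chi2
    from dscape.geometry import dihedral

    atoms = st.atoms
    assert r1.chi2 == pytest.approx(
        dihedral(atoms[b]["CA"], atoms[b]["CB"], atoms[b]["SG"], atoms[a]["SG"])
    )


def test_measure_invariant_under_rigid_motion():
    st = _inline_structure(200.0, 100.0, 265.0)
    base = measure_disulfide(st, (ResidueKey("A", 1), ResidueKey("A", 2)))
    rng = np.random.default_rng(8)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.normal(size=3) * 20
    moved = PdbStructure(
        pdb_id="moved",
        atoms={k: {n: v @ q.T + shift for n, v in d.items()} for k, d in st.atoms.items()},
        res_names=st.res_names,
    )
    rec = measure_disulfide(moved, (ResidueKey("A", 1), ResidueKey("A", 2)))
    for attr in ("chi1", "chi2", "chi3", "d_calpha", "ss_length"):
        assert getattr(rec, attr) == pytest.approx(getattr(base, attr), abs=1e-8)


def test_measure_missing_atom_names_residue():
    st = _inline_structure(180.0, 180.0, 90.0)
    del st.atoms[ResidueKey("A", 2)]["CB"]
    with pytest.raises(KeyError, match="A/2 missing atom CB"):
        measure_disulfide(st, (ResidueKey("A", 1), ResidueKey("A", 2)))


def test_summarize_class_statistics():
    def rec(d, joint):
        sa, sb = joint.split("/")
        return DisulfideGeometry("A", 1, "A", 2, 180, 180, 90, d, 2.05, sa, sb, joint, False)

    recs = [rec(4.0, "closed/closed"), rec(6.0, "open/closed")]
    s = summarize_class(recs, "demo")
    assert s.mean_d_calpha == pytest.approx(5.0)
    assert s.fraction_closed_closed == pytest.approx(0.5)
    all_closed = summarize_class([rec(5.0, "closed/closed")] * 3, "x")
    assert all_closed.fraction_closed_closed == 1.0
    with pytest.raises(ValueError):
        summarize_class([], "empty")


def test_full_pipeline_on_shipped_fixtures(fixtures_dir):
    """write -> parse -> find -> measure recovers every fixture's prescribed
    dihedrals to 1e-3 degrees and its joint state exactly."""
    out, manifest = fixtures_dir
    for entry in manifest["pdb_files"]:
        st, decls = parse_pdb(out / entry["file"])
        pairs = find_disulfides(st, decls)
        assert len(pairs) == 1
        rec = measure_disulfide(st, pairs[0])
        for got, want in ((rec.chi1, entry["chi1"]), (rec.chi2, entry["chi2"]), (rec.chi3, entry["chi3"])):
            err = abs(got - want) % 360.0
            assert min(err, 360.0 - err) <= 1e-3
        assert rec.joint_state == entry["joint_state"]


def test_survey_aggregates_classes(fixtures_dir):
    out, manifest = fixtures_dir
    paths = [out / e["file"] for e in manifest["pdb_files"]]
    table, summary = survey(paths)
    assert len(table) == 12
    assert set(table.joint_state) <= {"open/open", "open/closed", "closed/closed"}
    assert summary.loc[summary.class_label == "intrachain", "n"].item() == 12
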