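import numpy as np
import pytest

import knotfiber as kf
from knotfiber.knot_id import ALEXANDER_COEFFS, SIGNATURE_TABLE, _eval


EXPECTED_SIGNATURES = {
    # evaluated from the standard tabulated Alexander polynomials
    "3_1": (3, 7),
    "4_1": (5, 11),
    "5_1": (5, 31),
    "5_2": (7, 16),
    "6_1": (9, 20),
    "3_1#3_1": (9, 49),
    "3_1#4_1": (15, 77),
}


class TestSignatureTable:
    @pytest.mark.parametrize("label,sig", sorted(EXPECTED_SIGNATURES.items()))
    def test_tabulated_signatures(self, label, sig):
        coeffs = ALEXANDER_COEFFS[label]
        assert (abs(_eval(coeffs, -1)), abs(_eval(coeffs, -2))) == sig
        assert SIGNATURE_TABLE[sig] == label

    def test_all_determinants_odd(self):
        for label, coeffs in ALEXANDER_COEFFS.items():
            assert abs(_eval(coeffs, -1)) % 2 == 1, label

    def test_composite_signature_is_product_of_factors(self):
        t31 = EXPECTED_SIGNATURES["3_1"]
        t41 = EXPECTED_SIGNATURES["4_1"]
        assert EXPECTED_SIGNATURES["3_1#3_1"] == (t31[0] ** 2, t31[1] ** 2)
        assert EXPECTED_SIGNATURES["3_1#4_1"] == (t31[0] * t41[0],
                                                  t31[1] * t41[1])


class TestProjectDiagram:
    def test_planar_polygon_has_no_crossings(self):
        conf = kf.make_fixture("planar", 25)
        diag = kf.project_diagram(conf, [0.0, 0.0, 1.0])
        assert diag.crossing_count == 0

    def test_opposite_directions_same_crossing_count(self, fixture_curves):
        d = np.array([0.3, 0.5, 0.81])
        a = kf.project_diagram(fixture_curves["torus_2_3"], d)
        b = kf.project_diagram(fixture_curves["torus_2_3"], -d)
        assert a.crossing_count == b.crossing_count

    def test_each_crossing_visited_twice(self, fixture_curves):
        diag = kf.project_diagram(fixture_curves["5_2"], [0.2, 0.3, 0.93])
        ids = [c for c, _ in diag.events]
        assert all(ids.count(c) == 2 for c in set(ids))
        overs = {}
        for cid, over in diag.events:
            overs.setdefault(cid, []).append(over)
        assert all(sorted(v) == [0, 1] for v in overs.values())

    def test_torus_projection_reduces_to_three_crossings(self, fixture_curves):
        # along the torus axis the (2,3) curve shows its minimal diagram
        diag = kf.project_diagram(fixture_curves["torus_2_3"],
                                  [0.01, 0.02, 0.9995])
        red = kf.reduce_diagram(diag)
        assert red.crossing_count == 3
        assert kf.alexander_signature(red).as_tuple() == (3, 7)

    def test_dt_code_structure(self, fixture_curves):
        diag = kf.project_diagram(fixture_curves["torus_2_3"],
                                  [0.01, 0.02, 0.9995])
        code = kf.reduce_diagram(diag).dt_code()
        assert len(code) == 3
        assert all(abs(e) % 2 == 0 for e in code)


class TestReduceDiagram:
    def test_already_reduced_trefoil_is_fixed_point(self, fixture_curves):
        diag = kf.project_diagram(fixture_curves["torus_2_3"],
                                  [0.01, 0.02, 0.9995])
        red = kf.reduce_diagram(diag)
        assert kf.reduce_diagram(red).events == red.events

    def test_reduction_preserves_signature(self, ens_small):
        rng = np.random.default_rng(3)
        checked = 0
        for i in range(0, ens_small.n, 25):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            try:
                diag = kf.project_diagram(ens_small.coords[i], d)
            except kf.errors.DegenerateProjectionError:
                continue
            sig_full = kf.alexander_signature(diag)
            sig_red = kf.alexander_signature(kf.reduce_diagram(diag))
            assert sig_full == sig_red
            checked += 1
        assert checked >= 10


class TestAlexanderSignature:
    def test_empty_diagram_is_unknot(self):
        diag = kf.CrossingDiagram(events=(), signs=())
        assert kf.alexander_signature(diag).as_tuple() == (1, 1)

    @pytest.mark.parametrize("kind,sig", [
        ("torus_2_3", (3, 7)), ("figure_eight", (5, 11)),
        ("torus_2_5", (5, 31)), ("5_2", (7, 16)), ("6_1", (9, 20)),
    ])
    def test_fixture_signatures(self, fixture_curves, kind, sig):
        kt = kf.classify(fixture_curves[kind], seed=11)
        assert kt.signature.as_tuple() == sig

    def test_connected_sum_multiplicativity(self, fixture_curves):
        sig = kf.classify(fixture_curves["granny"], seed=11).signature
        t31 = kf.classify(fixture_curves["torus_2_3"], seed=11).signature
        assert sig.d1 == t31.d1 ** 2
        assert sig.d2 == t31.d2 ** 2


class TestClassify:
    def test_oracle_suite_fully_correct(self, fixture_curves):
        for kind, expected in kf.FIXTURE_KNOTS.items():
            kt = kf.classify(fixture_curves[kind], seed=5)
            assert kt.label == expected, kind
            assert kt.crossing_number == (
                0 if expected == "0_1"
                else sum(int(f.split("_")[0]) for f in expected.split("#")))

    def test_projection_independence(self, ens_047_20k):
        # random plus strongly compacted conformations, many seeds
        order = np.argsort(ens_047_20k.rg)
        pick = np.concatenate([order[:15], order[::737][:15]])
        for i in pick:
            labels = {kf.classify(ens_047_20k.coords[i], seed=s).label
                      for s in range(5)}
            assert len(labels) == 1

    def test_rigid_motion_and_scale_invariance(self, fixture_curves, rng):
        curve = fixture_curves["5_2"]
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = 3.7 * (curve @ q) + np.array([1.0, -2.0, 0.5])
        assert kf.classify(moved, seed=4).label == "5_2"

    def test_batch_agrees_with_per_conformation_path(self, ens_047_20k):
        idx = np.arange(0, ens_047_20k.n, 97)
        coords = ens_047_20k.coords[idx]
        labels, d1, d2, _ = kf.classify_batch(coords, seed=13)
        for row, i in enumerate(idx):
            kt = kf.classify(ens_047_20k.coords[i], seed=int(1000 + i))
            assert kt.label == labels[row]

    def test_unresolved_signature_not_in_table(self):
        # a signature outside the shipped table maps to "unresolved"
        from knotfiber.knot_id import _lookup
        kt = _lookup((3, 217), 0)   # 3_1 # 5_1 composite, deliberately absent
        assert kt.label == "unresolved"
        assert kt.is_knotted
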