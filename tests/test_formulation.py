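import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tabcal.errors import (
    InfeasibleConstraintsError,
    InfeasibleRecipeError,
    InvalidGeometryError,
)
from tabcal.formulation import (
    PAPER_CONSTRAINTS,
    PLACEBO_LUBRICANT_PCT,
    CrushTest,
    ExcipientComposition,
    MixtureConstraints,
    TabletRecipe,
    component_masses,
    derive_placebo,
    extreme_vertices_design,
    make_recipe,
    polygon_vertices,
    reference_design,
    tensile_strength,
)

TABLE2 = {
    "Rp.1": (0.0, 10.0, 90.0),
    "Rp.2": (17.5, 17.5, 65.0),
    "Rp.3": (0.0, 35.0, 65.0),
    "Rp.4": (60.0, 0.0, 40.0),
    "Rp.5": (10.0, 0.0, 90.0),
    "Rp.6": (35.0, 0.0, 65.0),
    "Rp.7": (30.0, 30.0, 40.0),
    "Rp.8": (0.0, 60.0, 40.0),
    "Rp.9": (5.0, 5.0, 90.0),
}


class TestComposition:
    def test_sum_enforced(self):
        with pytest.raises(ValueError):
            ExcipientComposition(30, 30, 30)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ExcipientComposition(-1, 11, 90)

    def test_from_xy(self):
        c = ExcipientComposition.from_xy(10, 0)
        assert c.mcc == 90.0
        assert c.xy == (10.0, 0.0)


class TestTensileStrength:
    def test_zero_force(self):
        assert tensile_strength(CrushTest(0, 8, 4)) == 0.0

    def test_hand_value(self):
        # 2*100 / (pi * 8 * 4) = 1.98944 MPa
        assert tensile_strength(CrushTest(100, 8, 4)) == pytest.approx(1.98944, abs=5e-6)

    def test_linearity_in_force(self):
        ts1 = tensile_strength(CrushTest(50, 8, 4))
        ts2 = tensile_strength(CrushTest(100, 8, 4))
        assert ts2 == pytest.approx(2 * ts1, rel=1e-12)

    @given(
        F=st.floats(0.1, 1e4),
        d=st.floats(0.1, 100),
        t=st.floats(0.1, 100),
        k=st.floats(0.1, 10),
    )
    def test_homogeneity(self, F, d, t, k):
        base = tensile_strength(CrushTest(F, d, t))
        assert tensile_strength(CrushTest(k * F, d, t)) == pytest.approx(k * base, rel=1e-9)
        assert tensile_strength(CrushTest(F, k * d, t)) == pytest.approx(base / k, rel=1e-9)
        assert tensile_strength(CrushTest(F, d, k * t)) == pytest.approx(base / k, rel=1e-9)

    def test_invalid_geometry(self):
        with pytest.raises(InvalidGeometryError):
            CrushTest(10, 0, 4)
        with pytest.raises(InvalidGeometryError):
            CrushTest(10, 8, -1)


class TestComponentMasses:
    def test_rp1_10pct_api(self):
        r = make_recipe("Rp.1", ExcipientComposition(0, 10, 90), api_id="ACE", drug_load=10)
        m = component_masses(r)
        assert round(m["api"], 2) == 20.00
        assert round(m["cs"], 2) == 17.88
        assert round(m["mcc"], 2) == 160.92
        assert round(m["lubricant"], 2) == 1.20

    def test_rp1_placebo(self):
        r = make_recipe("Rp.1", ExcipientComposition(0, 10, 90))
        m = component_masses(r)
        assert round(m["cs"], 2) == 19.87
        assert round(m["mcc"], 2) == 178.80
        assert round(m["lubricant"], 2) == 1.33
        assert round(r.lubricant, 2) == 0.67

    def test_rp8_10pct_api(self):
        # arithmetic oracle: base = 178.8; 0.60*178.8 and 0.40*178.8
        r = make_recipe("Rp.8", ExcipientComposition(0, 60, 40), api_id="ACE", drug_load=10)
        m = component_masses(r)
        assert m["cs"] == pytest.approx(107.28, abs=1e-9)
        assert m["mcc"] == pytest.approx(71.52, abs=1e-9)

    @given(
        lac=st.floats(0, 100),
        frac=st.floats(0, 1),
        drug=st.floats(0, 60),
    )
    def test_masses_sum_to_tablet_mass(self, lac, frac, drug):
        cs = (100.0 - lac) * frac
        comp = ExcipientComposition(lac, cs, max(100.0 - lac - cs, 0.0))
        r = make_recipe("x", comp, api_id="ACE", drug_load=drug)
        assert sum(component_masses(r).values()) == pytest.approx(200.0, abs=1e-6)

    def test_infeasible_recipe(self):
        r = TabletRecipe("x", ExcipientComposition(0, 10, 90), "ACE", 60.0, lubricant=40.0)
        with pytest.raises(InfeasibleRecipeError):
            component_masses(r)


class TestDerivePlacebo:
    def test_paper_masses(self):
        r = make_recipe("Rp.1", ExcipientComposition(0, 10, 90), api_id="ACE", drug_load=10)
        p = derive_placebo(r)
        m = component_masses(p)
        assert (round(m["cs"], 2), round(m["mcc"], 2), round(m["lubricant"], 2)) == (
            19.87,
            178.80,
            1.33,
        )

    def test_idempotent(self):
        r = make_recipe("Rp.5", ExcipientComposition(10, 0, 90), api_id="PYH", drug_load=40)
        assert derive_placebo(derive_placebo(r)) == derive_placebo(r)

    def test_composition_unchanged(self):
        r = make_recipe("Rp.5", ExcipientComposition(10, 0, 90), api_id="PYH", drug_load=40)
        p = derive_placebo(r)
        assert p.composition == r.composition
        assert p.api_id == "none" and p.drug_load == 0.0
        assert p.lubricant == PLACEBO_LUBRICANT_PCT


def _shapely_vertices(constraints):
    """Independent constraint-polygon oracle via shapely half-plane clipping."""
    from shapely.geometry import Polygon

    L = 2000.0
    box = Polygon([(-L, -L), (L, -L), (L, L), (-L, L)])
    (l_lo, l_hi), (c_lo, c_hi) = constraints.lac, constraints.cs
    s_lo, s_hi = 100.0 - constraints.mcc[1], 100.0 - constraints.mcc[0]
    halves = [
        Polygon([(l_lo, -L), (L, -L), (L, L), (l_lo, L)]),  # x >= l_lo
        Polygon([(-L, -L), (l_hi, -L), (l_hi, L), (-L, L)]),  # x <= l_hi
        Polygon([(-L, c_lo), (L, c_lo), (L, L), (-L, L)]),  # y >= c_lo
        Polygon([(-L, -L), (L, -L), (L, c_hi), (-L, c_hi)]),  # y <= c_hi
        Polygon([(s_hi + L, -L), (-L, s_hi + L), (-L, -L)]),  # x + y <= s_hi
        Polygon([(s_lo + L, -L), (-L, s_lo + L), (L, L)]),  # x + y >= s_lo
    ]
    poly = box
    for h in halves:
        poly = poly.intersection(h)
    coords = list(poly.simplify(1e-9).exterior.coords)[:-1]
    return {(round(x, 6), round(y, 6)) for x, y in coords}


class TestExtremeVerticesDesign:
    def test_matches_table2(self):
        pts = extreme_vertices_design(PAPER_CONSTRAINTS)
        got = {tuple(round(v, 6) for v in p.as_tuple()) for p in pts}
        assert got == set(TABLE2.values())
        assert len(pts) == 9

    def test_duplicate_centroid_gives_ten_runs(self):
        pts = extreme_vertices_design(PAPER_CONSTRAINTS, duplicate_centroid=True)
        assert len(pts) == 10
        assert pts[-1] == pts[-2] == ExcipientComposition(17.5, 17.5, 65.0)

    def test_unconstrained_simplex_vertices_are_pure_components(self):
        pts = extreme_vertices_design(MixtureConstraints())
        verts = {tuple(p.as_tuple()) for p in pts[:3]}
        assert verts == {(100.0, 0.0, 0.0), (0.0, 100.0, 0.0), (0.0, 0.0, 100.0)}

    @pytest.mark.parametrize(
        "cons",
        [
            PAPER_CONSTRAINTS,
            MixtureConstraints(),
            MixtureConstraints(lac=(5, 50), cs=(10, 70), mcc=(10, 80)),
            MixtureConstraints(lac=(0, 30), cs=(20, 60), mcc=(30, 70)),
            MixtureConstraints(lac=(0, 100), cs=(0, 100), mcc=(25, 25.5)),
        ],
    )
    def test_vertices_match_halfplane_oracle(self, cons):
        got = {(round(x, 6), round(y, 6)) for x, y in polygon_vertices(cons)}
        assert got == _shapely_vertices(cons)

    @pytest.mark.parametrize(
        "cons",
        [
            PAPER_CONSTRAINTS,
            MixtureConstraints(lac=(5, 50), cs=(10, 70), mcc=(10, 80)),
        ],
    )
    def test_all_points_satisfy_constraints(self, cons):
        for p in extreme_vertices_design(cons, duplicate_centroid=True):
            assert cons.contains(p, tol=1e-7)

    def test_empty_region_raises(self):
        with pytest.raises(InfeasibleConstraintsError):
            MixtureConstraints(lac=(0, 10), cs=(0, 10), mcc=(0, 10))
        with pytest.raises(InfeasibleConstraintsError):
            # single feasible point -> degenerate polygon
            polygon_vertices(MixtureConstraints(lac=(0, 0), cs=(0, 0), mcc=(100, 100)))


class TestReferenceDesign:
    def test_labels_and_order(self):
        rows = reference_design()
        assert len(rows) == 10
        assert [rid for rid, _ in rows] == [
            "Rp.1", "Rp.2", "Rp.2", "Rp.3", "Rp.4",
            "Rp.5", "Rp.6", "Rp.7", "Rp.8", "Rp.9",
        ]
        for rid, comp in rows:
            assert tuple(round(v, 6) for v in comp.as_tuple()) == TABLE2[rid]
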