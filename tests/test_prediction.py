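"""Naive-Bayes scoring, ranking with tie averaging, and evaluation on
planted sites."""

import numpy as np
import pytest

from iondist import (
    PlantedIonModel, accumulate, build_frame, neighbor_context, rank_ions,
    score_ion,
)
from iondist.ion_prediction import evaluate, predict, score_all
from iondist.local_geometry import from_local, geometry_center
from iondist.pair_statistics import ProbabilityModel, StatsDB
from iondist.structure_io import Structure
from iondist import synthetic as syn


def _db_with_counts(pair_counts, octant_counts=None):
    db = StatsDB()
    db.n_pair = dict(pair_counts)
    db.n_pair_octant = dict(octant_counts or {})
    if not db.n_pair_octant:
        # put everything in octant 0 so both tables are consistent
        db.n_pair_octant = {k + (0,): v for k, v in db.n_pair.items()}
    return db


class TestNeighborContext:
    def test_query_at_gc_has_r_zero(self):
        res = syn.make_residue("HIS")
        st = Structure("s", [res], [])
        gc = geometry_center(res.atoms)
        ctx = neighbor_context(st, gc)
        assert len(ctx) == 1
        assert ctx.neighbors[0][1].r == pytest.approx(0.0, abs=1e-12)

    def test_far_query_gives_empty_context(self):
        res = syn.make_residue("HIS")
        st = Structure("s", [res], [])
        gc = geometry_center(res.atoms)
        ctx = neighbor_context(st, gc + np.array([7.0, 0, 0]))
        assert len(ctx) == 0

    def test_matches_bruteforce_scan(self, rng):
        residues = [
            syn.make_residue(
                str(rng.choice(syn.CANONICAL_AA)),
                syn.RigidTransform.random(rng, translation_scale=6.0),
                seq_id=i + 1)
            for i in range(8)
        ]
        st = Structure("s", residues, [])
        query = rng.uniform(-4, 4, size=3)
        ctx = neighbor_context(st, query)
        expected = sum(
            np.linalg.norm(query - geometry_center(r.atoms)) <= 6.0
            for r in residues
        )
        assert len(ctx) == expected


class TestScoreIon:
    def test_independence_case_scores_zero(self):
        # counts chosen so p(ALA,Zn)=0.2, p(ALA)=0.5, p(Zn)=0.4 exactly
        db = _db_with_counts({
            ("ALA", "Zn2+"): 2, ("ALA", "Ca2+"): 3,
            ("GLY", "Zn2+"): 2, ("GLY", "Ca2+"): 3,
        })
        model = ProbabilityModel.from_statsdb(db, alpha=0.0)
        res = syn.make_residue("ALA")
        st = Structure("s", [res], [])
        ctx = neighbor_context(st, geometry_center(res.atoms) + 1.0)
        assert score_ion(model, ctx, "Zn2+") == pytest.approx(0.0, abs=1e-12)

    def test_empty_context_scores_all_ions_equally(self):
        db = _db_with_counts({("ALA", "Zn2+"): 5, ("CYS", "Ca2+"): 3})
        model = ProbabilityModel.from_statsdb(db)
        from iondist.ion_prediction import NeighborContext

        ctx = NeighborContext(position=np.zeros(3))
        scores = score_all(model, ctx, ("Zn2+", "Ca2+"))
        assert scores["Zn2+"] == scores["Ca2+"] == 0.0

    def test_matches_direct_product_oracle(self, rng):
        counts = {
            (aa, ion): int(rng.integers(1, 50))
            for aa in ("ALA", "CYS", "HIS")
            for ion in ("Zn2+", "Ca2+")
        }
        db = _db_with_counts(counts)
        alpha = 1.0
        model = ProbabilityModel.from_statsdb(db, alpha=alpha)
        residues = [
            syn.make_residue(
                aa, syn.RigidTransform.random(rng, translation_scale=2.0),
                seq_id=i + 1)
            for i, aa in enumerate(("ALA", "CYS", "HIS"))
        ]
        # query within reach of all three residues: average of the GCs
        query = np.mean([geometry_center(r.atoms) for r in residues], axis=0)
        st = Structure("s", residues, [])
        ctx = neighbor_context(st, query)
        assert len(ctx) == 3
        # oracle: explicit product of smoothed table ratios
        ions = model.ion_labels
        joint = np.full((20, len(ions)), alpha)
        for (aa, ion), v in counts.items():
            joint[model.aa_index(aa), model.ion_index(ion)] += v
        p = joint / joint.sum()
        p_aa, p_ion = p.sum(axis=1), p.sum(axis=0)
        for ion in ("Zn2+", "Ca2+"):
            prod = 1.0
            for res, _ in ctx.neighbors:
                ai, ii = model.aa_index(res.aa_type), model.ion_index(ion)
                prod *= p[ai, ii] / (p_aa[ai] * p_ion[ii])
            assert np.exp(score_ion(model, ctx, ion)) == pytest.approx(
                prod, rel=1e-12)

    def test_octant_mode_uses_query_octant(self, rng):
        # Zn sits in octant 0 of ALA frames, Ca in octant 7; a query in
        # octant 0 must then favor Zn under octant mode
        db = _db_with_counts(
            {("ALA", "Zn2+"): 10, ("ALA", "Ca2+"): 10},
            {("ALA", "Zn2+", 0): 10, ("ALA", "Ca2+", 7): 10},
        )
        model = ProbabilityModel.from_statsdb(db)
        res = syn.make_residue("ALA")
        frame = build_frame(res)
        st = Structure("s", [res], [])
        query = from_local(frame, np.array([1.5, 1.5, 1.5]))  # octant 0
        ctx = neighbor_context(st, query)
        assert score_ion(model, ctx, "Zn2+", mode="pair") == pytest.approx(
            score_ion(model, ctx, "Ca2+", mode="pair"))
        assert (score_ion(model, ctx, "Zn2+", mode="octant")
                > score_ion(model, ctx, "Ca2+", mode="octant"))

    def test_unknown_ion_lists_candidates(self):
        db = _db_with_counts({("ALA", "Zn2+"): 1})
        model = ProbabilityModel.from_statsdb(db)
        from iondist.ion_prediction import NeighborContext

        with pytest.raises(KeyError, match="candidates"):
            score_ion(model, NeighborContext(position=np.zeros(3)), "Xx9+")

    def test_neighbor_order_invariance(self, rng):
        db = _db_with_counts({
            ("ALA", "Zn2+"): 4, ("CYS", "Zn2+"): 9, ("ALA", "Ca2+"): 2,
        })
        model = ProbabilityModel.from_statsdb(db)
        residues = [syn.make_residue(aa, seq_id=i + 1)
                    for i, aa in enumerate(("ALA", "CYS"))]
        st_fwd = Structure("s", residues, [])
        st_rev = Structure("s", residues[::-1], [])
        q = geometry_center(residues[0].atoms)
        s1 = score_ion(model, neighbor_context(st_fwd, q), "Zn2+")
        s2 = score_ion(model, neighbor_context(st_rev, q), "Zn2+")
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_favorable_neighbor_increases_score(self):
        # CYS-Zn is enriched above independence; adding a CYS neighbor
        # must strictly increase the Zn score
        db = _db_with_counts({
            ("CYS", "Zn2+"): 30, ("CYS", "Ca2+"): 1,
            ("ALA", "Zn2+"): 1, ("ALA", "Ca2+"): 30,
        })
        model = ProbabilityModel.from_statsdb(db)
        res1 = syn.make_residue("CYS", seq_id=1)
        res2 = syn.make_residue("CYS", syn.RigidTransform(
            np.eye(3), np.array([3.0, 0, 0])), seq_id=2)
        q = geometry_center(res1.atoms) + np.array([1.5, 0, 0])
        one = neighbor_context(Structure("s", [res1], []), q)
        two = neighbor_context(Structure("s", [res1, res2], []), q)
        assert len(one) == 1 and len(two) == 2
        assert (score_ion(model, two, "Zn2+")
                > score_ion(model, one, "Zn2+"))


class TestRankIons:
    def test_clear_winner(self):
        result = rank_ions({"Zn2+": 3.0, "Ca2+": 1.0}, truth="Zn2+")
        assert result.rank_of_truth == 1.0
        assert result.ranking[0] == "Zn2+"

    def test_all_tied_over_eleven(self):
        from iondist import DEFAULT_CANDIDATES

        result = rank_ions({ion: 0.0 for ion in DEFAULT_CANDIDATES})
        assert all(r == 6.0 for r in result.ranks.values())

    def test_matches_sort_oracle_with_tie_averaging(self, rng):
        for _ in range(20):
            vals = rng.integers(0, 5, size=7).astype(float)
            ions = [f"i{k}" for k in range(7)]
            scores = dict(zip(ions, vals))
            result = rank_ions(scores)
            for ion, v in scores.items():
                greater = sum(w > v for w in vals)
                ties = sum(w == v for w in vals)
                expected = greater + (ties + 1) / 2
                assert result.ranks[ion] == pytest.approx(expected)


class TestEvaluate:
    def test_perfectly_specific_sites_rank_first(self):
        db = _db_with_counts({
            ("CYS", "Zn2+"): 50, ("ASP", "Ca2+"): 50,
        })
        model = ProbabilityModel.from_statsdb(db)
        sites = []
        for aa, ion in (("CYS", "Zn2+"), ("ASP", "Ca2+")):
            for k in range(5):
                res = syn.make_residue(aa)
                q = geometry_center(res.atoms) + np.array([1.0 + 0.2 * k,
                                                           0.5, 0.5])
                sites.append((Structure("s", [res], []), q, ion))
        report = evaluate(model, sites, candidates=("Zn2+", "Ca2+"))
        assert np.all(report.per_ion.mean_rank == 1.0)
        assert np.all(report.per_ion.std_rank == 0.0)
        # CDF ends at 1 and is non-decreasing
        for col in report.rank_cdf:
            vals = report.rank_cdf[col].to_numpy()
            assert vals[-1] == 1.0
            assert np.all(np.diff(vals) >= 0)

    def test_planted_preference_recovered_quickly(self, rng):
        model = PlantedIonModel()
        db = accumulate(model.sample_training_structures(60, rng))
        sites = model.sample_sites(22, rng)
        pm = ProbabilityModel.from_statsdb(db, ions=model.candidates)
        report = evaluate(pm, sites, mode="octant",
                          candidates=model.candidates)
        overall = np.average(report.per_ion.mean_rank,
                             weights=report.per_ion.n_sites)
        assert overall < 2.0

    def test_predict_end_to_end(self, rng):
        model = PlantedIonModel()
        db = accumulate(model.sample_training_structures(30, rng))
        st, query, truth = model.sample_site(model.candidates[0], rng)
        result = predict(db, st, query, mode="octant",
                         candidates=model.candidates)
        assert sorted(result.ranking) == sorted(model.candidates)
        assert result.ranks[truth] <= 4.0
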