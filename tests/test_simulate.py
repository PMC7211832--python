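import numpy as np
import pandas as pd
import pytest

from roostnet.association import build_gbi, simple_ratio_index, social_differentiation
from roostnet.records import filter_dataset, read_captures, read_relatedness, read_roosts
from roostnet.simulate import (
    Pedigree,
    SimulationConfig,
    pedigree_relatedness,
    sample_captures,
    simulate_dataset,
    simulate_pedigree,
    simulate_roosting,
)


def small_cfg(**kw):
    base = dict(
        seed=1, n_founders=16, n_years=2, days_per_year=15,
        n_roosts_per_population=4, groups_per_day=2,
        capture_events_per_year=10, male_immigrants_per_year=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestPedigree:
    def test_full_dispersal_removes_locally_born_males(self):
        cfg = small_cfg(male_dispersal_prob=1.0, n_years=4, pup_rate=0.8)
        ped = simulate_pedigree(cfg)
        for year in range(2, cfg.n_years):
            adults = ped.present_adults(year, cfg.maturity_years)
            local_males = adults[(adults["sex"] == "male") & adults["mother_id"].notna()]
            assert len(local_males) == 0

    def test_zero_pup_rate_gives_founders_only(self):
        cfg = small_cfg(pup_rate=0.0)
        ped = simulate_pedigree(cfg)
        assert len(ped.table) == cfg.n_founders
        assert ped.table["mother_id"].isna().all()

    def test_sex_ratio_at_birth_binomial(self):
        cfg = SimulationConfig(
            seed=3, n_founders=80, n_years=4, pup_rate=0.9,
            days_per_year=1, male_dispersal_prob=0.0, adult_survival=1.0,
            male_immigrants_per_year=0.0,
        )
        ped = simulate_pedigree(cfg)
        born = ped.table[ped.table["mother_id"].notna()]
        n = len(born)
        assert n > 100
        frac_female = (born["sex"] == "female").mean()
        # binomial(n, 0.5): allow 4 standard errors
        assert abs(frac_female - 0.5) < 4 * 0.5 / np.sqrt(n)

    def test_parentage_invariants_enforced(self):
        bad = pd.DataFrame(
            [
                dict(id="a", sex="male", mother_id=None, father_id=None,
                     birth_year=0, population="p", death_year=np.nan,
                     dispersal_year=np.nan, arrival_year=np.nan),
                dict(id="b", sex="female", mother_id="a", father_id=None,
                     birth_year=1, population="p", death_year=np.nan,
                     dispersal_year=np.nan, arrival_year=np.nan),
            ]
        )
        with pytest.raises(ValueError, match="wrong sex"):
            Pedigree(bad)


class TestPedigreeRelatedness:
    def _family(self):
        rows = [
            dict(id="mom", sex="female", mother_id=None, father_id=None, birth_year=-1),
            dict(id="dad", sex="male", mother_id=None, father_id=None, birth_year=-1),
            dict(id="sire2", sex="male", mother_id=None, father_id=None, birth_year=-1),
            dict(id="kid1", sex="female", mother_id="mom", father_id="dad", birth_year=0),
            dict(id="kid2", sex="male", mother_id="mom", father_id="dad", birth_year=0),
            dict(id="half", sex="female", mother_id="mom", father_id="sire2", birth_year=1),
        ]
        for r in rows:
            r.update(population="p", death_year=np.nan, dispersal_year=np.nan,
                     arrival_year=np.nan)
        return Pedigree(pd.DataFrame(rows))

    def test_analytic_relationships(self):
        rel = pedigree_relatedness(self._family())
        f = rel.to_frame()
        assert f.at["mom", "kid1"] == pytest.approx(0.5)  # parent-offspring
        assert f.at["kid1", "kid2"] == pytest.approx(0.5)  # full siblings
        assert f.at["kid1", "half"] == pytest.approx(0.25)  # half siblings
        assert f.at["mom", "dad"] == 0.0
        assert f.at["dad", "half"] == 0.0

    def test_noise_clamped_and_symmetric(self):
        rel = pedigree_relatedness(self._family(), noise_sd=0.2,
                                   rng=np.random.default_rng(0))
        assert (rel.r >= 0).all() and (rel.r <= 1).all()
        np.testing.assert_array_equal(rel.r, rel.r.T)

    @pytest.mark.parametrize("trial", range(6))
    def test_matches_path_counting_oracle(self, trial):
        # Wright's path-counting method, written independently of the
        # tabular recurrence: sum (1/2)^(n1+n2) * (1 + F_A) over pairs of
        # ancestor paths meeting only at the common ancestor A
        cfg = SimulationConfig(
            seed=500 + trial, n_founders=6, n_years=3, pup_rate=0.9,
            days_per_year=1, male_dispersal_prob=0.2, adult_survival=1.0,
            male_immigrants_per_year=0.0,
        )
        ped = simulate_pedigree(cfg)
        table = ped.table.iloc[:20]
        ped = Pedigree(table[
            table["mother_id"].isin(list(table["id"]) + [None])
            & table["father_id"].isin(list(table["id"]) + [None])
        ])
        parents = {
            r["id"]: (r["mother_id"], r["father_id"])
            for _, r in ped.table.iterrows()
        }

        def ancestor_paths(x):
            out = [[x]]
            for p in parents.get(x, (None, None)):
                if isinstance(p, str):
                    out.extend([[x] + path for path in ancestor_paths(p)])
            return out

        inbreeding_cache = {}

        def inbreeding(a):
            if a not in inbreeding_cache:
                m, f = parents[a]
                inbreeding_cache[a] = (
                    relationship(m, f) / 2
                    if isinstance(m, str) and isinstance(f, str)
                    else 0.0
                )
            return inbreeding_cache[a]

        def relationship(i, j):
            total = 0.0
            for p1 in ancestor_paths(i):
                for p2 in ancestor_paths(j):
                    if p1[-1] != p2[-1]:
                        continue
                    if set(p1) & set(p2) != {p1[-1]}:
                        continue
                    total += 0.5 ** (len(p1) + len(p2) - 2) * (1 + inbreeding(p1[-1]))
            return total

        rel = pedigree_relatedness(ped)
        ids = ped.ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                want = min(1.0, relationship(ids[i], ids[j]))
                assert rel.r[i, j] == pytest.approx(want, abs=1e-12)


class TestRoosting:
    def test_null_assembly_uniform_co_roosting(self):
        cfg = SimulationConfig(
            seed=9, n_founders=12, n_years=1, days_per_year=400,
            n_roosts_per_population=6, groups_per_day=3,
            pup_rate=0.0, male_immigrants_per_year=0.0, adult_survival=1.0,
        ).null()
        ped = simulate_pedigree(cfg)
        truth = simulate_roosting(ped, cfg)
        C = truth.co_roost_days
        ids = truth.bat_ids
        pop = ped.table.set_index("id")["population"]
        idx = [k for k, b in enumerate(ids) if pop[b] == "west"]
        rates = C[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)] / 400
        # each dyad co-roosts with probability 1/groups_per_day
        se = np.sqrt((1 / 3) * (2 / 3) / 400)
        assert abs(rates.mean() - 1 / 3) < 4 * se
        assert np.all(np.abs(rates - 1 / 3) < 6 * se)

    def test_partner_preference_raises_true_association_cv(self):
        base = dict(
            seed=11, n_founders=12, n_years=1, days_per_year=150,
            n_roosts_per_population=6, groups_per_day=3, pup_rate=0.0,
            male_immigrants_per_year=0.0, kin_bias_strength=0.0,
            male_avoidance=0.0, adult_survival=1.0,
        )
        null_cfg = SimulationConfig(**base, partner_preference_strength=0.0)
        pref_cfg = SimulationConfig(**base, partner_preference_strength=4.0)

        def true_cv(cfg):
            ped = simulate_pedigree(cfg)
            truth = simulate_roosting(ped, cfg)
            rates = truth.co_roost_days[
                np.triu_indices(len(truth.bat_ids), 1)
            ] / (cfg.days_per_year * cfg.n_years)
            # within-population dyads only (cross-population rates are 0)
            rates = rates[rates > 0]
            return rates.std() / rates.mean()

        assert true_cv(pref_cfg) > 1.5 * true_cv(null_cfg)

    def test_single_roost_everyone_together(self):
        cfg = small_cfg(
            n_roosts_per_population=1, groups_per_day=1, detection_prob=1.0,
            pup_rate=0.0, adult_survival=1.0,
        )
        ped = simulate_pedigree(cfg)
        truth = simulate_roosting(ped, cfg)
        rng = np.random.default_rng(0)
        ds = sample_captures(truth, ped, cfg, rng)
        assoc = simple_ratio_index(build_gbi(ds))
        pop = ped.table.set_index("id")["population"]
        for i, a in enumerate(assoc.bats):
            for j in range(i + 1, len(assoc.bats)):
                if pop[a] == pop[assoc.bats[j]]:
                    assert assoc.sri[i, j] == 1.0


class TestCaptureSampling:
    def test_perfect_detection_records_true_groups(self):
        cfg = small_cfg(detection_prob=1.0)
        bundle = simulate_dataset(cfg)
        members = bundle.dataset.event_members()
        for _, row in bundle.sampled_truth.iterrows():
            eid = f"{row['date'].date()}@{row['roost_id']}"
            assert members[eid] == frozenset(row["members"])

    def test_half_detection_halves_group_sizes(self):
        cfg = SimulationConfig(
            seed=21, n_founders=40, n_years=2, days_per_year=30,
            capture_events_per_year=30, groups_per_day=2,
            n_roosts_per_population=4, detection_prob=0.5,
            male_immigrants_per_year=0.0,
        )
        bundle = simulate_dataset(cfg)
        true_sizes = bundle.sampled_truth["members"].map(len)
        rec_sizes = bundle.sampled_truth["detected"].map(len)
        ratio = rec_sizes.sum() / true_sizes.sum()
        n = true_sizes.sum()
        assert abs(ratio - 0.5) < 4 * 0.5 / np.sqrt(n)

    def test_bundle_roundtrips_through_readers(self, small_bundle, tmp_path):
        small_bundle.write(tmp_path)
        reg = read_roosts(tmp_path / "roosts.csv")
        ds = read_captures(tmp_path / "captures.csv", registry=reg)
        pd.testing.assert_frame_equal(ds.records, small_bundle.dataset.records)
        rel = read_relatedness(tmp_path / "relatedness.csv")
        assert rel.ids == small_bundle.relatedness.ids
        np.testing.assert_allclose(rel.r, small_bundle.relatedness.r, atol=1e-12)
        assert (tmp_path / "truth.json").exists()

    def test_seed_reproducibility(self):
        cfg = small_cfg(seed=33)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a.dataset.records, b.dataset.records)
        np.testing.assert_array_equal(a.relatedness.r, b.relatedness.r)


class TestEmergentStructure:
    def test_female_philopatry_span_variance(self):
        # locally born males disperse at maturity, so female
        # juvenile-to-adult recapture spans vary more than male spans
        from roostnet.univariate import juvenile_recapture_spans

        spans_f, spans_m = [], []
        for seed in (101, 102, 103):
            cfg = SimulationConfig(seed=seed, n_years=5, days_per_year=40)
            bundle = simulate_dataset(cfg)
            spans = juvenile_recapture_spans(bundle.dataset)
            spans_f += list(spans.loc[spans["sex"] == "female", "span_days"])
            spans_m += list(spans.loc[spans["sex"] == "male", "span_days"])
        assert len(spans_f) >= 5 and len(spans_m) >= 2
        assert np.var(spans_f, ddof=1) > np.var(spans_m, ddof=1)
        assert max(spans_f) > max(spans_m)

    def test_kin_bias_raises_female_kin_co_roosting(self):
        base = dict(
            seed=7, n_founders=30, n_years=4, days_per_year=40,
            n_roosts_per_population=6, groups_per_day=3,
            male_immigrants_per_year=1.0, partner_preference_strength=0.0,
            male_avoidance=0.0, adult_survival=1.0, pup_rate=0.8,
            male_dispersal_prob=0.9,
        )
        def female_kin_assortment(kappa):
            cfg = SimulationConfig(**base, kin_bias_strength=kappa)
            ped = simulate_pedigree(cfg)
            rel = pedigree_relatedness(ped)
            truth = simulate_roosting(ped, cfg, relatedness=rel)
            C = truth.co_roost_days
            ids = truth.bat_ids
            sex = ped.sex_of()
            pop = ped.table.set_index("id")["population"]
            fem = [k for k, b in enumerate(ids) if sex[b] == "female"]
            num = den = 0.0
            for a in range(len(fem)):
                for b in range(a + 1, len(fem)):
                    i, j = fem[a], fem[b]
                    if pop[ids[i]] != pop[ids[j]] or C[i, j] == 0:
                        continue
                    num += C[i, j] * rel.r[i, j]
                    den += C[i, j]
            return num / den

        assert female_kin_assortment(8.0) > 1.5 * female_kin_assortment(0.0)
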