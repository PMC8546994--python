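import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longdbn.constraints import (ConstraintMatrix, augmented_constraints,
                                 skeleton_constraints)
from longdbn.core_io.types import SLICE_T, SLICE_T1, DBNModel, Edge, NodeRef
from longdbn.dbn import (GriddedSubject, ObservationTable, bic_score,
                         bootstrap_network, build_observations, cpd_loglik,
                         fit_cpd, learn_structure, max_edges_single_network,
                         normalized_weight, overlap_percent,
                         per_slice_node_count, summarize_network)


def N(kind, feature, slice_=SLICE_T1):
    return NodeRef(kind, feature, slice_)


class TestConstraints:
    def test_skeleton_cells(self):
        c = skeleton_constraints()
        assert not c.is_allowed(N("gene", "g", SLICE_T1), N("taxon", "t"),
                                "intra")
        assert c.is_allowed(N("metabolite", "m", SLICE_T), N("taxon", "t"),
                            "inter")
        assert not c.is_allowed(N("env", "w", SLICE_T), N("env", "w"), "inter")
        assert c.is_allowed(N("env", "w", SLICE_T1), N("taxon", "t"), "intra")
        assert c.is_allowed(N("host_gene", "h", SLICE_T1), N("taxon", "t"),
                            "intra")
        assert c.is_allowed(N("taxon", "t", SLICE_T1), N("gene", "g"), "intra")
        assert c.is_allowed(N("gene", "g", SLICE_T1), N("metabolite", "m"),
                            "intra")

    def test_self_loops_only_for_same_feature(self):
        c = skeleton_constraints()
        assert c.is_allowed(N("taxon", "t", SLICE_T), N("taxon", "t"), "inter")
        assert not c.is_allowed(N("taxon", "u", SLICE_T), N("taxon", "t"),
                                "inter")

    def test_augmented_adds_taxon_metabolite(self):
        sk, aug = skeleton_constraints(), augmented_constraints()
        tm = (N("taxon", "t", SLICE_T1), N("metabolite", "m"), "intra")
        assert aug.is_allowed(*tm) and not sk.is_allowed(*tm)
        assert sk.issubset(aug)

    def test_no_incoming_to_env_or_host(self):
        aug = augmented_constraints()
        with pytest.raises(ValueError):
            ConstraintMatrix(frozenset({("taxon", "env", "intra", "all")}))
        assert not aug.is_allowed(N("taxon", "t", SLICE_T),
                                  N("host_gene", "h"), "inter")

    def test_file_round_trip(self, tmp_path):
        aug = augmented_constraints()
        aug.to_file(tmp_path / "c.json")
        back = ConstraintMatrix.from_file(tmp_path / "c.json")
        assert back.allowed == aug.allowed and back.name == "augmented"


def _table_from_columns(columns: dict[NodeRef, np.ndarray]) -> ObservationTable:
    df = pd.DataFrame({str(n): v for n, v in columns.items()})
    return ObservationTable(df, list(columns), np.array(["s"] * len(df)))


class TestBuildObservations:
    def _subject(self, name, n_points, rng):
        times = 14.0 * np.arange(n_points)
        dyn = {("taxon", "A"): rng.normal(size=n_points),
               ("gene", "g"): rng.normal(size=n_points)}
        return GriddedSubject(name, times, dyn, {("host_gene", "h"): 0.7})

    def test_row_count_n_minus_one(self):
        rng = np.random.default_rng(0)
        tab = build_observations([self._subject("s", 5, rng)])
        assert tab.n_rows == 4

    def test_row_count_arithmetic(self):
        rng = np.random.default_rng(0)
        subs = [self._subject(f"s{i}", 25, rng) for i in range(50)]
        assert build_observations(subs).n_rows == 1200

    def test_values_match_lookup_oracle(self):
        rng = np.random.default_rng(3)
        gs = self._subject("s", 6, rng)
        tab = build_observations([gs])
        series = gs.dynamic[("taxon", "A")]
        np.testing.assert_array_equal(tab.col(N("taxon", "A", SLICE_T)),
                                      series[:-1])
        np.testing.assert_array_equal(tab.col(N("taxon", "A", SLICE_T1)),
                                      series[1:])

    def test_static_repeated_both_slices(self):
        rng = np.random.default_rng(1)
        tab = build_observations([self._subject("s", 5, rng)])
        assert (tab.col(N("host_gene", "h", SLICE_T)) == 0.7).all()
        assert (tab.col(N("host_gene", "h", SLICE_T1)) == 0.7).all()

    def test_week_env_node(self):
        rng = np.random.default_rng(1)
        tab = build_observations([self._subject("s", 3, rng)])
        np.testing.assert_allclose(tab.col(N("env", "week", SLICE_T1)),
                                   [2.0, 4.0])


class TestFitCpd:
    def test_noiseless_self_loop(self):
        x = np.linspace(-2, 2, 50)
        tab = _table_from_columns({N("taxon", "A", SLICE_T): x,
                                   N("taxon", "A"): x})
        cpd = fit_cpd(N("taxon", "A"), [N("taxon", "A", SLICE_T)], tab)
        assert cpd.beta0 == pytest.approx(0.0, abs=1e-10)
        assert cpd.betas[0] == pytest.approx(1.0)
        assert cpd.sigma2 == pytest.approx(1e-9)  # floor

    def test_zero_parent_fit_is_mean_and_population_variance(self):
        rng = np.random.default_rng(5)
        y = rng.normal(2.0, 1.5, size=200)
        tab = _table_from_columns({N("taxon", "A"): y})
        cpd = fit_cpd(N("taxon", "A"), [], tab)
        assert cpd.beta0 == pytest.approx(y.mean())
        assert cpd.sigma2 == pytest.approx(y.var())  # divisor n, the MLE

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 3))
        y = 0.5 + X @ [1.0, -2.0, 0.3] + rng.normal(0, 0.1, 200)
        parents = [N("taxon", f"p{i}", SLICE_T) for i in range(3)]
        cols = {p: X[:, i] for i, p in enumerate(parents)}
        cols[N("taxon", "y")] = y
        tab = _table_from_columns(cols)
        cpd = fit_cpd(N("taxon", "y"), parents, tab)
        # independent oracle: closed-form normal equations
        design = np.column_stack([np.ones(200), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert cpd.beta0 == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(cpd.betas, beta[1:], atol=1e-8)
        resid = y - design @ beta
        assert cpd.sigma2 == pytest.approx(np.mean(resid ** 2), abs=1e-10)

    def test_rank_deficient_raises(self):
        x = np.ones(50)
        tab = _table_from_columns({N("taxon", "p", SLICE_T): x,
                                   N("taxon", "A"): x * 2})
        with pytest.raises(np.linalg.LinAlgError):
            fit_cpd(N("taxon", "A"), [N("taxon", "p", SLICE_T)], tab)


class TestBicScore:
    def _model(self, tab, parent_map):
        cpds = {c: fit_cpd(c, p, tab) for c, p in parent_map.items()}
        edges = [Edge(p, c, "inter" if p.slice_ == SLICE_T else "intra")
                 for c, ps in parent_map.items() for p in ps]
        return DBNModel(set(tab.nodes), edges, cpds)

    def test_three_node_toy_hand_computed(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=40)
        b = 0.8 * a + rng.normal(0, 0.3, 40)
        c = rng.normal(size=40)
        nodes = {N("taxon", "a", SLICE_T): a, N("taxon", "b"): b,
                 N("metabolite", "c"): c}
        tab = _table_from_columns(nodes)
        model = self._model(tab, {N("taxon", "b"): [N("taxon", "a", SLICE_T)],
                                  N("metabolite", "c"): []})
        # brute-force density oracle: sum of per-row Gaussian log-pdfs
        expected_ll = 0.0
        cpd_b = model.cpds[N("taxon", "b")]
        mu = cpd_b.beta0 + cpd_b.betas[0] * a
        expected_ll += stats.norm.logpdf(b, mu, math.sqrt(cpd_b.sigma2)).sum()
        cpd_c = model.cpds[N("metabolite", "c")]
        expected_ll += stats.norm.logpdf(c, cpd_c.beta0,
                                         math.sqrt(cpd_c.sigma2)).sum()
        n_params = 3 + 2
        expected = expected_ll - 0.5 * n_params * math.log(40)
        assert bic_score(model, tab) == pytest.approx(expected, rel=1e-12)

    def test_penalty_is_one_at_e_squared_rows(self):
        n = int(round(math.e ** 2))  # |D| ~ e^2 -> log|D|/2 ~ 1
        assert 0.5 * math.log(math.e ** 2) == pytest.approx(1.0)

    def test_null_parent_costs_half_log_n(self):
        # adding an unrelated parent changes BIC by about -log(n)/2
        rng = np.random.default_rng(13)
        deltas = []
        for _ in range(40):
            y = rng.normal(size=400)
            x = rng.normal(size=400)
            tab = _table_from_columns({N("taxon", "x", SLICE_T): x,
                                       N("taxon", "y"): y})
            base = self._model(tab, {N("taxon", "y"): []})
            extended = self._model(tab,
                                   {N("taxon", "y"): [N("taxon", "x", SLICE_T)]})
            deltas.append(bic_score(extended, tab) - bic_score(base, tab))
        assert np.mean(deltas) == pytest.approx(-0.5 * math.log(400) + 0.5,
                                                abs=0.35)


def _independent_noise_subjects(n_subjects, n_points, seed):
    rng = np.random.default_rng(seed)
    subs = []
    for i in range(n_subjects):
        times = 14.0 * np.arange(n_points)
        dyn = {("taxon", "T0"): rng.normal(size=n_points),
               ("taxon", "T1"): rng.normal(size=n_points),
               ("gene", "G0"): rng.normal(size=n_points),
               ("metabolite", "M0"): rng.normal(size=n_points)}
        subs.append(GriddedSubject(f"s{i}", times, dyn))
    return subs


class TestLearnStructure:
    def test_self_loops_always_present(self):
        subs = _independent_noise_subjects(10, 11, seed=0)
        tab = build_observations(subs, include_week=False)
        model = learn_structure(tab, skeleton_constraints())
        for child in tab.children():
            assert child.at(SLICE_T) in model.parents_of(child)

    def test_independent_noise_rarely_adds_edges(self):
        # |D| = 500; false-positive additions <= 5% of children over 20 seeds
        extra = total = 0
        for seed in range(20):
            subs = _independent_noise_subjects(10, 51, seed=seed)
            tab = build_observations(subs, include_week=False)
            assert tab.n_rows == 500
            model = learn_structure(tab, skeleton_constraints())
            for child in tab.children():
                total += 1
                extra += len(model.parents_of(child)) - 1
        assert extra / total <= 0.05

    def test_planted_inter_edge_recovered(self):
        rng = np.random.default_rng(42)
        subs = []
        for i in range(10):
            n = 51
            m = np.zeros(n)
            t = np.zeros(n)
            for j in range(n - 1):
                m[j + 1] = 0.5 * m[j] + rng.normal(0, 0.1)
                t[j + 1] = 0.4 * t[j] + 0.9 * m[j] + rng.normal(0, 0.1)
            dyn = {("metabolite", "M"): m, ("taxon", "T"): t,
                   ("gene", "G"): rng.normal(size=n)}
            subs.append(GriddedSubject(f"s{i}", 14.0 * np.arange(n), dyn))
        tab = build_observations(subs, include_week=False)
        model = learn_structure(tab, skeleton_constraints())
        assert ("metabolite", "M", "taxon", "T", "inter") in model.edge_keys()
        edge = [e for e in model.edges
                if e.key == ("metabolite", "M", "taxon", "T", "inter")][0]
        assert edge.coefficient == pytest.approx(0.9, abs=0.1)

    def test_greedy_never_beats_exhaustive(self):
        # 4 dynamic nodes, max_parents=2, against full parent-set enumeration
        rng = np.random.default_rng(17)
        subs = []
        for i in range(8):
            n = 20
            t0 = rng.normal(size=n)
            g0 = np.zeros(n)
            m0 = np.zeros(n)
            m1 = np.zeros(n)
            for j in range(n - 1):
                g0[j + 1] = 0.5 * g0[j] + 0.8 * t0[j + 1] + rng.normal(0, 0.1)
                m0[j + 1] = 0.4 * m0[j] - 0.7 * g0[j + 1] + rng.normal(0, 0.1)
                m1[j + 1] = 0.5 * m1[j] + rng.normal(0, 0.1)
            dyn = {("taxon", "T0"): t0, ("gene", "G0"): g0,
                   ("metabolite", "M0"): m0, ("metabolite", "M1"): m1}
            subs.append(GriddedSubject(f"s{i}", 14.0 * np.arange(n), dyn))
        tab = build_observations(subs, include_week=False)
        constraints = skeleton_constraints()
        model = learn_structure(tab, constraints, max_parents=2)
        greedy_bic = bic_score(model, tab)

        # oracle: per-child exhaustive enumeration of allowed parent sets
        half_log_n = 0.5 * math.log(tab.n_rows)
        exhaustive = 0.0
        for child in tab.children():
            allowed = []
            for lag in ("intra", "inter"):
                s = SLICE_T1 if lag == "intra" else SLICE_T
                for node in tab.variables(s):
                    if node != child and constraints.is_allowed(node, child, lag):
                        allowed.append(node)
            best = -np.inf
            for r in range(0, 3):
                for combo in itertools.combinations(allowed, r):
                    try:
                        cpd = fit_cpd(child, list(combo), tab)
                    except np.linalg.LinAlgError:
                        continue
                    score = cpd_loglik(cpd, tab) - (r + 2) * half_log_n
                    best = max(best, score)
            exhaustive += best
        assert greedy_bic <= exhaustive + 1e-9

    def test_bic_monotone_along_greedy_path(self):
        # starting model (self-loops) must never outscore the final model
        subs = _independent_noise_subjects(8, 21, seed=2)
        tab = build_observations(subs, include_week=False)
        constraints = skeleton_constraints()
        final = learn_structure(tab, constraints)
        start_cpds = {c: fit_cpd(c, [c.at(SLICE_T)], tab)
                      for c in tab.children()}
        start = DBNModel(set(tab.nodes),
                         [Edge(c.at(SLICE_T), c, "inter")
                          for c in tab.children()], start_cpds)
        assert bic_score(final, tab) >= bic_score(start, tab)

    def test_empty_table_error(self):
        df = pd.DataFrame({str(N("taxon", "A")): []})
        tab = ObservationTable(df, [N("taxon", "A")], np.array([]))
        with pytest.raises(ValueError, match="empty"):
            learn_structure(tab, skeleton_constraints())

    def test_parent_cap_respected(self, default_truth):
        _, truth = default_truth
        tab = build_observations(truth.latent, include_week=False)
        model = learn_structure(tab, truth.constraints, max_parents=3)
        for child in tab.children():
            assert len(model.parents_of(child)) <= 3

    def test_constraint_compliance(self, small_truth):
        _, truth = small_truth
        tab = build_observations(truth.latent, include_week=False)
        model = learn_structure(tab, truth.constraints)
        for e in model.edges:
            assert truth.constraints.is_allowed(e.parent, e.child, e.lag)


class TestNormalizedWeight:
    def test_standardized_parent_child(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=500)
        x = (x - x.mean()) / x.std()
        y = rng.normal(size=500)
        y = (y - y.mean()) / y.std()
        tab = _table_from_columns({N("taxon", "p", SLICE_T): x,
                                   N("taxon", "c"): y})
        nw = normalized_weight(0.37, N("taxon", "p", SLICE_T),
                               N("taxon", "c"), tab)
        assert nw == pytest.approx(0.37)

    def test_parent_scaling_invariance(self):
        rng = np.random.default_rng(29)
        x = rng.normal(size=300)
        y = 0.5 * x + rng.normal(0, 0.1, 300)
        parent, child = N("taxon", "p", SLICE_T), N("taxon", "c")
        tab = _table_from_columns({parent: x, child: y})
        cpd = fit_cpd(child, [parent], tab)
        nw1 = normalized_weight(float(cpd.betas[0]), parent, child, tab)
        tab10 = _table_from_columns({parent: 10 * x, child: y})
        cpd10 = fit_cpd(child, [parent], tab10)
        nw2 = normalized_weight(float(cpd10.betas[0]), parent, child, tab10)
        assert nw1 == pytest.approx(nw2, rel=1e-9)

    def test_zero_child_variance_error(self):
        tab = _table_from_columns({N("taxon", "p", SLICE_T): np.arange(10.0),
                                   N("taxon", "c"): np.ones(10)})
        with pytest.raises(ValueError, match="variance"):
            normalized_weight(1.0, N("taxon", "p", SLICE_T),
                              N("taxon", "c"), tab)


class TestBootstrap:
    def test_identity_resample_matches_single_run(self, small_truth):
        _, truth = small_truth
        net = bootstrap_network(truth.latent, truth.constraints, n_reps=1,
                                seed=0, include_week=False,
                                resample_subjects=False)
        tab = build_observations(truth.latent, include_week=False)
        single = learn_structure(tab, truth.constraints)
        assert net.edge_keys() == single.edge_keys()
        assert all(e.bootstrap_support == 1.0 for e in net.edges)

    def test_union_at_least_single_rep(self, small_truth):
        _, truth = small_truth
        net = bootstrap_network(truth.latent, truth.constraints, n_reps=5,
                                seed=4, include_week=False)
        tab = build_observations(truth.latent, include_week=False)
        single = learn_structure(tab, truth.constraints)
        assert len(net.edges) >= len(single.edges)

    def test_same_seed_identical(self, small_truth):
        _, truth = small_truth
        kwargs = dict(n_reps=5, seed=123, include_week=False)
        n1 = bootstrap_network(truth.latent, truth.constraints, **kwargs)
        n2 = bootstrap_network(truth.latent, truth.constraints, **kwargs)
        assert [(e.key, e.bootstrap_support, e.coefficient)
                for e in n1.edges] == [(e.key, e.bootstrap_support,
                                        e.coefficient) for e in n2.edges]

    def test_support_calibration(self, small_truth):
        # planted edges should carry higher support than other allowed edges
        _, truth = small_truth
        net = bootstrap_network(truth.latent, truth.constraints, n_reps=10,
                                seed=6, include_week=False)
        planted = truth.model.edge_keys()
        sup_true = [e.bootstrap_support for e in net.edges
                    if e.key in planted]
        sup_false = [e.bootstrap_support for e in net.edges
                     if e.key not in planted]
        assert np.mean(sup_true) > (np.mean(sup_false) if sup_false else 0.0)


class TestSummaries:
    def test_per_slice_node_count(self):
        sizes = {"taxa": 101, "genes": 72, "metabolites": 70,
                 "host_genes": 40, "env": 1}
        assert per_slice_node_count(sizes) == 284

    def test_max_edges_bound(self):
        assert max_edges_single_network(284, 3) == 852

    def _edges(self, n_inter, n_intra, n_negative):
        edges = []
        for i in range(n_inter + n_intra):
            lag = "inter" if i < n_inter else "intra"
            parent_slice = SLICE_T if lag == "inter" else SLICE_T1
            coef = -1.0 if i < n_negative else 1.0
            edges.append(Edge(NodeRef("metabolite", f"m{i}", parent_slice),
                              NodeRef("taxon", f"t{i}"), lag,
                              coefficient=coef))
        return edges

    def test_lag_breakdown_total(self):
        summary = summarize_network(self._edges(470, 607, 0))
        assert summary.n_edges == 1077
        assert summary.n_inter == 470 and summary.n_intra == 607

    def test_negative_percent_floor(self):
        summary = summarize_network(self._edges(470, 607, 362))
        assert summary.n_negative == 362
        assert summary.negative_percent == 33

    def test_overlap_percent(self):
        a = self._edges(300, 371, 0)
        b = a[:372] + self._edges(0, 50, 0)[:0]
        other = [Edge(NodeRef("taxon", f"x{i}", SLICE_T),
                      NodeRef("taxon", f"x{i}"), "inter")
                 for i in range(100)]
        assert overlap_percent(a, a[:372] + other) == 55
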