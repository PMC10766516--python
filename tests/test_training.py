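"""Loss, fitting, range-parameter scan and the supervised loop."""

import numpy as np
import pytest

from cf22d.database import Database, DataSet, ReactionRecord, SpeciesEntry
from cf22d.model import (
    Promotion,
    TrainingConfig,
    TrainingLoopError,
    TrainingProblem,
    regularization_terms,
)
from cf22d.synthetic import (
    SyntheticSpec,
    make_database,
    make_dimer_scan,
    make_species_pool,
    random_parameters,
    default_dispersion_params,
)
from cf22d.xc.descriptors import DescriptorVector
from cf22d.xc.params import XCParameters, write_parameter_file


def lam0(seed=0, **kw):
    kw.setdefault("n_starts", 1)
    return TrainingConfig(lambda_=0.0, seed=seed, **kw)


# ---------------------------------------------------------------------------
# regularization worked values
# ---------------------------------------------------------------------------

class TestRegularization:
    def test_constant_blocks_vanish(self):
        params = XCParameters(17.0, np.full(40, 0.7), np.full(9, -1.2), np.full(9, 3.0))
        assert regularization_terms(params) == (0.0, 0.0, 0.0)

    def test_single_unit_difference(self):
        b = np.zeros(9)
        b[0] = 1.0
        params = XCParameters(0.0, np.zeros(40), b, np.zeros(9))
        assert regularization_terms(params)[1] == 1.0

    def test_arithmetic_ramp(self):
        params = XCParameters(0.0, np.zeros(40), np.arange(9.0), np.zeros(9))
        assert regularization_terms(params)[1] == 8.0

    def test_a_term_couples_only_adjacent_k(self):
        # a_{0,0,5} has no successor in k: changing it alone contributes one
        # difference (against a_{0,0,4}), not two
        a = np.zeros(40)
        a[5] = 2.0  # lexicographic position of (0,0,5)
        params = XCParameters(0.0, a, np.zeros(9), np.zeros(9))
        assert regularization_terms(params)[0] == 4.0


# ---------------------------------------------------------------------------
# hand-built miniature databases
# ---------------------------------------------------------------------------

def zero_species(sid):
    return SpeciesEntry(
        sid, DescriptorVector(np.zeros(40), np.zeros(9), np.zeros(9), 0.0)
    )


def constant_error_database(set_specs):
    """Sets whose per-record references ARE the errors of the zero model."""
    species = {"s0": zero_species("s0")}
    datasets = []
    for sid, errors, role, panel in set_specs:
        records = tuple(ReactionRecord({"s0": 1.0}, e, relative=False) for e in errors)
        datasets.append(DataSet(sid, records, 1.0, role, "TC", panel))
    return Database(species, tuple(datasets))


class TestPredictedValue:
    def test_identity_reaction_is_exactly_zero(self, noiseless_database, planted_params, dispersion_params):
        # A -> A, written with a clone of A so coefficients +1/-1 cancel exactly
        sid = next(iter(noiseless_database.species))
        entry = noiseless_database.species[sid]
        clone = SpeciesEntry("clone", entry.descriptors, entry.geometry)
        db = Database({**noiseless_database.species, "clone": clone}, noiseless_database.datasets)
        prob = TrainingProblem(db, dispersion_params, lam0())
        rec = ReactionRecord({sid: 1.0, "clone": -1.0}, 0.0)
        assert prob.predicted_value(rec, planted_params, 1.53) == 0.0

    def test_zero_params_no_dispersion_gives_zero(self, noiseless_database):
        prob = TrainingProblem(noiseless_database, None, lam0())
        ds = noiseless_database.datasets[0]
        assert prob.predicted_value(ds.records[0], XCParameters.zeros(), 1.53) == 0.0

    def test_three_species_stoichiometric_sum(self, noiseless_database, planted_params, dispersion_params):
        from cf22d.units import KCALMOL_PER_HARTREE
        from cf22d.dispersion.energy import dispersion_energy

        prob = TrainingProblem(noiseless_database, dispersion_params, lam0())
        sids = list(noiseless_database.species)[:3]
        coeffs = {sids[0]: 1.0, sids[1]: -2.0, sids[2]: 1.0}
        rec = ReactionRecord(coeffs, 0.0)
        theta = planted_params.to_vector()
        oracle = 0.0
        for sid, nu in coeffs.items():
            sp = noiseless_database.species[sid]
            e_df = float(sp.descriptors.stacked() @ theta)
            e_disp = dispersion_energy(sp.geometry, dispersion_params)
            oracle += nu * (e_df + e_disp)
        oracle *= KCALMOL_PER_HARTREE
        assert prob.predicted_value(rec, planted_params, 1.53) == pytest.approx(oracle, abs=1e-9)

    def test_unknown_species_named(self, noiseless_database, planted_params):
        prob = TrainingProblem(noiseless_database, None, lam0())
        with pytest.raises(KeyError, match="ghost"):
            prob.predicted_value(ReactionRecord({"ghost": 1.0}, 0.0), planted_params, 1.53)


class TestLoss:
    def test_perfect_predictions_zero_loss(self, noiseless_database, planted_params, dispersion_params):
        prob = TrainingProblem(noiseless_database, dispersion_params, lam0())
        # planted params have nonzero regularization, so lambda = 0 isolates the data term
        assert prob.loss(planted_params, 1.53) == pytest.approx(0.0, abs=1e-9)

    def test_single_record_loss_is_abs_error(self):
        db = constant_error_database([("s", [3.0], "training", None)])
        prob = TrainingProblem(db, None, lam0())
        assert prob.loss(XCParameters.zeros(), 1.53) == pytest.approx(3.0, abs=1e-12)

    def test_doubling_inverse_weights_halves_data_term(self, noiseless_database, dispersion_params):
        rng = np.random.default_rng(2)
        theta = XCParameters.from_vector(rng.normal(size=59))
        prob = TrainingProblem(noiseless_database, dispersion_params, lam0())
        l1 = prob.loss(theta, 1.53)
        doubled = Database(
            noiseless_database.species,
            tuple(
                DataSet(ds.id, ds.records, 2 * ds.inverse_weight, ds.role,
                        ds.property_class, ds.reference_mue_mean)
                for ds in noiseless_database.datasets
            ),
        )
        l2 = prob.loss(theta, 1.53, doubled)
        assert l2 == pytest.approx(l1 / 2.0, rel=1e-12)

    def test_permutation_invariance(self, noiseless_database, dispersion_params):
        rng = np.random.default_rng(4)
        theta = XCParameters.from_vector(rng.normal(size=59))
        prob = TrainingProblem(noiseless_database, dispersion_params, lam0())
        l1 = prob.loss(theta, 1.53)
        shuffled = Database(
            noiseless_database.species,
            tuple(reversed([
                DataSet(ds.id, tuple(reversed(ds.records)), ds.inverse_weight,
                        ds.role, ds.property_class, ds.reference_mue_mean)
                for ds in noiseless_database.datasets
            ])),
        )
        prob2 = TrainingProblem(shuffled, dispersion_params, lam0())
        assert prob2.loss(theta, 1.53) == pytest.approx(l1, rel=1e-12)

    def test_no_training_sets_rejected(self):
        db = constant_error_database([("s", [1.0], "test", None)])
        prob = TrainingProblem(db, None, lam0())
        with pytest.raises(ValueError, match="training"):
            prob.loss(XCParameters.zeros(), 1.53)


class TestFitParameters:
    def test_planted_recovery_noiseless(self, noiseless_database, planted_params, dispersion_params):
        prob = TrainingProblem(noiseless_database, dispersion_params, lam0(seed=3))
        theta = prob.fit_parameters(1.53)
        dev = np.max(np.abs(theta.to_vector() - planted_params.to_vector()))
        assert dev < 1e-6

    def test_huge_lambda_flattens_blocks(self, noiseless_database):
        # zero-mean targets: references replaced by zeros; dispersion off so
        # the data term carries no offsets
        flat = Database(
            noiseless_database.species,
            tuple(
                DataSet(
                    ds.id,
                    tuple(ReactionRecord(r.species, 0.0, r.relative) for r in ds.records),
                    ds.inverse_weight, ds.role, ds.property_class, ds.reference_mue_mean,
                )
                for ds in noiseless_database.datasets
            ),
        )
        cfg = TrainingConfig(lambda_=1e9, seed=0, n_starts=1)
        prob = TrainingProblem(flat, None, cfg)
        theta = prob.fit_parameters(1.53)
        for block in (theta.a, theta.b, theta.c):
            assert np.max(np.abs(block - block.mean())) < 1e-6

    def test_fixed_point_at_optimum(self, noiseless_database, planted_params, dispersion_params):
        prob = TrainingProblem(noiseless_database, dispersion_params, lam0(seed=3))
        theta = prob.fit_parameters(1.53, theta_init=planted_params)
        assert prob.loss(theta, 1.53) <= prob.loss(planted_params, 1.53) + 1e-15

    def test_nested_model_loss_non_increasing(self, noiseless_database, dispersion_params):
        """Adding parameters never worsens the fitted loss (lambda = 0)."""
        noisy = Database(
            noiseless_database.species,
            tuple(
                DataSet(
                    ds.id,
                    tuple(
                        ReactionRecord(r.species, r.reference_kcal + 0.5 * (i % 3 - 1), r.relative)
                        for i, r in enumerate(ds.records)
                    ),
                    ds.inverse_weight, ds.role, ds.property_class, ds.reference_mue_mean,
                )
                for ds in noiseless_database.datasets
            ),
        )
        prob = TrainingProblem(noisy, dispersion_params, lam0(seed=5))
        # restricted model: X only (a = b = c = 0), solved by 1-d least squares
        blocks = [prob._dataset_design(ds) for ds in noisy.by_role("training")]
        col = np.concatenate([A[:, 0] for A, _ in blocks])
        tgt = np.concatenate(
            [y - prob._dataset_offsets(ds, 1.53) for (A, y), ds in zip(blocks, noisy.by_role("training"))]
        )
        x_only = float(col @ tgt / (col @ col))
        restricted = XCParameters(x_only, np.zeros(40), np.zeros(9), np.zeros(9))
        full = prob.fit_parameters(1.53, theta_init=restricted)
        assert prob.loss(full, 1.53) <= prob.loss(restricted, 1.53) + 1e-12

    def test_noise_scaling_one_over_sqrt_n(self, species_pool, planted_params, dispersion_params):
        """Fitted-parameter error shrinks roughly like 1/sqrt(N)."""
        spec, pool = species_pool
        sizes = (40, 160, 640)
        all_errs = []
        for seed in (31, 77, 123):
            errs = []
            for size in sizes:
                s = SyntheticSpec(seed=seed, n_sets=4, set_size=size, noise_sigma=1.0)
                db = make_database(s, pool, planted_params, sr6=1.53, dispersion=dispersion_params)
                prob = TrainingProblem(db, dispersion_params, lam0(seed=1))
                theta = prob.fit_parameters(1.53)
                errs.append(np.linalg.norm(theta.to_vector() - planted_params.to_vector()))
            all_errs.append(errs)
        mean = np.mean(all_errs, axis=0)
        # over a 16x growth in N the error should shrink about 4x; allow a
        # generous stochastic band
        assert mean[0] > mean[1] > mean[2]
        assert 2.0 < mean[0] / mean[2] < 10.0


class TestScanSr6:
    def test_planted_sr6_recovery(self):
        db, _ = make_dimer_scan(("C", "Ar"), 1.53, np.linspace(3.0, 7.0, 25))
        prob = TrainingProblem(db, default_dispersion_params(), lam0(maxiter_opt=60))
        sr6, _ = prob.scan_sr6()
        assert abs(sr6 - 1.53) < 0.01

    def test_flat_objective_returns_lower_bound(self, noiseless_database):
        # no dispersion geometries used: the objective cannot depend on sr6
        db, _ = make_dimer_scan(("C", "Ar"), 1.53, np.linspace(3.0, 7.0, 10))
        # strip geometries so every candidate is equivalent
        from cf22d.database import SpeciesEntry as SE

        stripped = Database(
            {sid: SE(sid, sp.descriptors, None) for sid, sp in db.species.items()},
            db.datasets,
        )
        prob = TrainingProblem(stripped, default_dispersion_params(), lam0(maxiter_opt=30))
        sr6, _ = prob.scan_sr6()
        assert sr6 == pytest.approx(1.2, abs=1e-9)

    def test_result_within_bounds(self):
        db, _ = make_dimer_scan(("C", "Ar"), 1.53, np.linspace(3.0, 7.0, 12))
        cfg = TrainingConfig(lambda_=0.0, sr6_min=1.6, sr6_max=2.0, seed=0, n_starts=1, maxiter_opt=30)
        prob = TrainingProblem(db, default_dispersion_params(), cfg)
        sr6, _ = prob.scan_sr6()
        assert 1.6 - 1e-9 <= sr6 <= 2.0 + 1e-9


class TestSupervisedUpdate:
    def make_problem(self, mues_panels):
        specs = [("train0", [0.0, 0.1], "training", None)]
        for i, (m, p) in enumerate(mues_panels):
            specs.append((f"val{i}", [m], "validation", p))
        db = constant_error_database(specs)
        return TrainingProblem(db, None, lam0()), db

    def test_threshold_arithmetic(self):
        prob, db = self.make_problem([(1.4, 1.0)])
        promos, _ = prob.supervised_update(XCParameters.zeros(), 1.53, db)
        assert [p.set_id for p in promos] == ["val0"]

    def test_boundary_is_strict(self):
        prob, db = self.make_problem([(1.3, 1.0)])
        promos, _ = prob.supervised_update(XCParameters.zeros(), 1.53, db)
        assert promos == []

    def test_exactly_two_of_three_promoted(self):
        prob, db = self.make_problem([(0.5, 1.0), (2.0, 1.0), (1.31, 1.0)])
        promos, new_db = prob.supervised_update(XCParameters.zeros(), 1.53, db)
        assert [p.set_id for p in promos] == ["val1", "val2"]
        assert new_db.dataset("val1").role == "training"
        assert new_db.dataset("val1").inverse_weight == 1.0  # the panel statistic

    def test_promotion_monotone_in_trigger(self):
        for lo, hi in [(0.1, 0.3), (0.3, 0.9)]:
            prob_lo, db = self.make_problem([(0.5, 1.0), (2.0, 1.0), (1.31, 1.0)])
            prob_lo.config = TrainingConfig(lambda_=0.0, trigger=lo)
            n_lo = len(prob_lo.supervised_update(XCParameters.zeros(), 1.53, db)[0])
            prob_hi, db2 = self.make_problem([(0.5, 1.0), (2.0, 1.0), (1.31, 1.0)])
            prob_hi.config = TrainingConfig(lambda_=0.0, trigger=hi)
            n_hi = len(prob_hi.supervised_update(XCParameters.zeros(), 1.53, db2)[0])
            assert n_hi <= n_lo

    def test_missing_panel_statistic_rejected(self):
        prob, db = self.make_problem([(1.4, None)])
        with pytest.raises(ValueError, match="panel"):
            prob.supervised_update(XCParameters.zeros(), 1.53, db)


@pytest.fixture(scope="module")
def hard_set_scenario(species_pool, planted_params):
    spec, pool = species_pool
    s = SyntheticSpec(
        seed=2, n_sets=6, set_size=20,
        roles=("training", "training", "training", "training", "validation", "validation"),
        hard_sets=("set05",), hard_set_bias=5.0, panel_factor=20.0,
    )
    return make_database(s, pool, planted_params, sr6=1.53)


class TestTrainingLoop:

    def test_no_validation_terminates_after_one_iteration(self, noiseless_database, dispersion_params):
        prob = TrainingProblem(noiseless_database, dispersion_params, lam0(seed=3))
        res = prob.fit(sr6=1.53)
        assert res.n_iterations == 1
        assert res.promotion_log == ()

    def test_planted_hard_set_is_promoted_and_loop_reconverges(self, hard_set_scenario):
        prob = TrainingProblem(hard_set_scenario, None, lam0(seed=3))
        res = prob.fit(sr6=1.53)
        assert [p.set_id for p in res.promotion_log] == ["set05"]
        assert res.database.dataset("set05").role == "training"
        assert res.database.dataset("set04").role == "validation"

    def test_same_seed_reproduces_log_and_parameter_file(self, hard_set_scenario, tmp_path):
        res1 = TrainingProblem(hard_set_scenario, None, lam0(seed=3)).fit(sr6=1.53)
        res2 = TrainingProblem(hard_set_scenario, None, lam0(seed=3)).fit(sr6=1.53)
        assert res1.promotion_log == res2.promotion_log
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_parameter_file(p1, res1.params, res1.sr6)
        write_parameter_file(p2, res2.params, res2.sr6)
        assert p1.read_bytes() == p2.read_bytes()

    def test_iteration_cap_raises_with_state(self, hard_set_scenario):
        cfg = TrainingConfig(lambda_=0.0, seed=3, n_starts=1, max_iter=1)
        with pytest.raises(TrainingLoopError) as exc:
            TrainingProblem(hard_set_scenario, None, cfg).fit(sr6=1.53)
        assert exc.value.state.iteration == 1

    def test_summary_mentions_promotions(self, hard_set_scenario):
        res = TrainingProblem(hard_set_scenario, None, lam0(seed=3)).fit(sr6=1.53)
        text = res.summary()
        assert "set05" in text
        assert "training MUE" in text
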