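"""MCMC machinery: likelihood, prior recovery, reproducibility, unit layout."""

import math

import numpy as np
import pytest
from scipy import stats

from paleoselect.coat_genetics import Genotype, default_rules
from paleoselect.cohort import AgePrior, AncientSample, PeriodGrid
from paleoselect.mcmc import (
    ChainConfig,
    Priors,
    build_problem,
    run_chain,
    run_inference,
    sample_log_likelihood,
)
from paleoselect.wfsim import AlleleOrigin, Demography, Trajectory

import toys


def _traj(freqs_by_locus, g=10.0, start=100.0):
    names = list(freqs_by_locus)
    arr = np.column_stack([freqs_by_locus[n] for n in names])
    ages = start - g * np.arange(arr.shape[0])
    return Trajectory(ages_bp=ages, freqs=arr, locus_names=names, generation_time=g)


def _sample(sid, dosages, age=100.0):
    rules = default_rules()
    g = {n: None for n in rules.locus_names}
    g.update(dosages)
    return AncientSample(sid, "s", "c", "Toy", AgePrior("uniform", (age - 0.4, age + 0.4)),
                        Genotype(g))


class TestLikelihood:
    def test_heterozygote_at_half(self):
        traj = _traj({"KIT_tobiano": np.full(3, 0.5)})
        ll = sample_log_likelihood([_sample("a", {"KIT_tobiano": 1})], traj, [100.0])
        assert ll == pytest.approx(math.log(0.5))

    def test_observed_allele_at_zero_frequency_impossible(self):
        traj = _traj({"KIT_tobiano": np.zeros(3)})
        ll = sample_log_likelihood([_sample("a", {"KIT_tobiano": 2})], traj, [100.0])
        assert ll == -math.inf

    def test_additivity_across_samples_and_loci(self):
        traj = _traj({"KIT_tobiano": np.full(3, 0.3), "TRPM1_LP": np.full(3, 0.7)})
        samples = [_sample("a", {"KIT_tobiano": 1, "TRPM1_LP": 0}),
                   _sample("b", {"KIT_tobiano": 2, "TRPM1_LP": 1})]
        ll = sample_log_likelihood(samples, traj, [100.0, 100.0])
        expected = (math.log(2 * 0.3 * 0.7) + math.log(0.3 ** 2)
                    + math.log(0.3 ** 2) + math.log(2 * 0.7 * 0.3))
        assert ll == pytest.approx(expected)

    def test_missing_contributes_nothing(self):
        traj = _traj({"KIT_tobiano": np.full(3, 0.3)})
        ll = sample_log_likelihood([_sample("a", {})], traj, [100.0])
        assert ll == 0.0


def _flat_unit():
    """A unit whose data are entirely missing: the posterior is the prior."""
    counts = [3, 3, 3]
    samples = toys.toy_samples(counts)
    # asymmetric model prior so the jump move accepts stochastically and its
    # stationary distribution is informative about correctness
    priors = Priors(demography=toys.TOY_DEMO, origin_prob_standing=0.7)
    (unit,) = build_problem(samples, loci=["KIT_tobiano"], period_grid=toys.TOY_GRID,
                            priors=priors, window_start_bp=toys.TOY_WINDOW)
    unit.dosages[:] = -1
    unit.fd_low[:] = unit.window_end_bp  # no detections constrain the mutation age
    return unit


@pytest.fixture(scope="module")
def flat_draws():
    """Thinned draws from a flat-likelihood chain (posterior == prior)."""
    cfg = ChainConfig(n_chains=1, n_steps=15_000, burn_in=0.2, thin=10, seed=0,
                      s_scale=0.5, n_age_updates=0)
    return run_chain(_flat_unit(), cfg, seed=123)


class TestPriorRecovery:
    """With a flat likelihood every posterior equals its prior."""

    def test_selection_posterior_is_uniform_prior(self, flat_draws):
        s = flat_draws["s[tobiano|Toy]"]
        ks = stats.kstest(s, "uniform", args=(-1.0, 2.0))
        assert ks.pvalue > 0.01

    def test_model_indicator_matches_prior_odds(self, flat_draws):
        # P(new_mutation) prior is 0.3 in the flat unit
        assert abs(flat_draws["model[KIT_tobiano]"].mean() - 0.3) < 0.08

    def test_p0_posterior_is_uniform_prior(self, flat_draws):
        p0 = flat_draws["p0[KIT_tobiano]"]
        p0 = p0[np.isfinite(p0)]  # recorded only while in the standing model
        ks = stats.kstest(p0, "uniform")
        assert ks.pvalue > 0.01

    def test_mutation_age_posterior_is_uniform_prior(self, flat_draws):
        t = flat_draws["t_mut[KIT_tobiano]"]
        t = t[np.isfinite(t)]
        ks = stats.kstest(t, "uniform", args=(0.0, toys.TOY_WINDOW))
        assert ks.pvalue > 0.01


class TestSamplerBasics:
    def test_reproducible_draws(self):
        counts = toys.toy_generate_counts(0.2, seed=5)
        samples = toys.toy_samples(counts)
        (unit,) = build_problem(samples, loci=["KIT_tobiano"],
                                period_grid=toys.TOY_GRID,
                                priors=Priors(demography=toys.TOY_DEMO),
                                window_start_bp=toys.TOY_WINDOW,
                                fixed_origins=toys.TOY_FIXED_ORIGIN)
        cfg = ChainConfig(n_chains=1, n_steps=400, burn_in=0.5, thin=1, seed=0,
                          n_age_updates=0, enable_model_jump=False)
        a = run_chain(unit, cfg, seed=77)
        b = run_chain(unit, cfg, seed=77)
        for k in a:
            assert np.array_equal(a[k], b[k], equal_nan=True)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_problem([])

    def test_all_wildtype_cohort_rejected(self):
        samples = [_sample("a", {"KIT_tobiano": 0})]
        with pytest.warns(UserWarning, match="no derived alleles"):
            with pytest.raises(ValueError):
                build_problem(samples, loci=["KIT_tobiano"],
                              period_grid=toys.TOY_GRID,
                              window_start_bp=toys.TOY_WINDOW)

    def test_unit_partition_joint_base_and_singleton_spotting(self):
        samples = [
            _sample("a", {"MC1R": 2, "ASIP": 1, "PMEL17": 1, "KIT_tobiano": 1}),
            _sample("b", {"MC1R": 0, "ASIP": 2, "PMEL17": 0, "KIT_tobiano": 0}),
        ]
        units = build_problem(samples, period_grid=toys.TOY_GRID,
                              window_start_bp=toys.TOY_WINDOW)
        names = [tuple(u.loci) for u in units]
        assert ("MC1R", "ASIP", "PMEL17") in names
        assert ("KIT_tobiano",) in names
        joint = units[names.index(("MC1R", "ASIP", "PMEL17"))]
        classes = {c for c, _ in joint.cells}
        # bay is the fitness reference and gets no coefficient
        assert classes == {"black", "chestnut", "silver"}

    def test_mutation_age_draws_respect_first_detection(self):
        samples, _ = toys.recovery_cohort(
            {("tobiano", "P4"): 0.6, ("tobiano", "P5"): 0.6},
            AlleleOrigin("new_mutation", t_mut=1150.0), seed=41)
        (unit,) = build_problem(samples, loci=["KIT_tobiano"],
                                period_grid=toys.RECOVERY_GRID,
                                priors=Priors(demography=toys.RECOVERY_DEMO))
        cfg = ChainConfig(n_chains=1, n_steps=800, burn_in=0.5, thin=1, seed=3,
                          n_age_updates=3)
        out = run_chain(unit, cfg, seed=11)
        t_mut = out["t_mut[KIT_tobiano]"]
        t_mut = t_mut[np.isfinite(t_mut)]
        if t_mut.size:  # only recorded while in the new-mutation model
            assert (t_mut >= unit.fd_low[0]).all()

    def test_joint_unit_runs_through_general_simulator(self):
        """ASIP+MC1R(+silver) exercise the multi-locus epistatic path."""
        rng = np.random.default_rng(4)
        samples = []
        for i, age in enumerate([1900, 1000, 100] * 6):
            mc1r = int(rng.integers(0, 3))
            asip = int(rng.integers(0, 3))
            samples.append(_sample(f"j{i}", {"MC1R": mc1r, "ASIP": asip},
                                   age=float(age)))
        # ensure both derived alleles are observed
        samples.append(_sample("jx", {"MC1R": 2, "ASIP": 2}, age=500.0))
        units = build_problem(samples, loci=["MC1R", "ASIP"],
                              period_grid=toys.RECOVERY_GRID,
                              priors=Priors(demography=toys.RECOVERY_DEMO))
        (unit,) = units
        assert not unit.singleton_groups()
        cfg = ChainConfig(n_chains=1, n_steps=120, burn_in=0.5, thin=1, seed=0,
                          n_age_updates=2)
        out = run_chain(unit, cfg, seed=2)
        assert np.isfinite(out["loglik"]).all()
        assert any(k.startswith("s[chestnut") for k in out)


class TestRunInference:
    def test_summary_and_diagnostics_layout(self):
        samples, _ = toys.recovery_cohort({}, AlleleOrigin("standing", p0=0.4),
                                          seed=8)
        cfg = ChainConfig(n_chains=2, n_steps=400, thin=4, seed=1, n_age_updates=2)
        res = run_inference(samples, config=cfg, loci=["KIT_tobiano"],
                            period_grid=toys.RECOVERY_GRID,
                            priors=Priors(demography=toys.RECOVERY_DEMO))
        summ = res.summary
        assert {"parameter", "mean", "q2.5", "q97.5"} <= set(summ.columns)
        s_rows = summ[summ.parameter.str.startswith("s[")]
        assert len(s_rows) == 5 and s_rows["P(s>0)"].between(0, 1).all()
        unit = res.unit_for("KIT_tobiano")
        assert 0.0 <= unit.draws.model_probability("KIT_tobiano") <= 1.0
        assert "rhat_flags" in unit.diagnostics
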