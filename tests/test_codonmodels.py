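"""Codon site models: pruning oracle, simulation round trips, LRT logic."""

import numpy as np
import pytest
from scipy import stats

from rosaslocus.codonmodels import (ClassMatrices, LrtResult, N_CODONS, SiteModelParams,
                                    TreeIndex, beb_positive_posterior, call_positive_sites,
                                    discretize_beta, encode_alignment,
                                    equal_codon_frequencies, fit_branch_lengths_m0,
                                    fit_site_model, lrt, simulate_codon_alignment)
from rosaslocus.phylo import Alignment
from rosaslocus.synthetic import random_tree


# ---------------------------------------------------------------------------
# Parameter handling
# ---------------------------------------------------------------------------

def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        SiteModelParams(model="M9")
    with pytest.raises(ValueError):
        SiteModelParams(model="M2a", p0=0.8, p1=0.5)
    with pytest.raises(ValueError):
        SiteModelParams(model="M7", beta_p=-1.0)
    with pytest.raises(ValueError):
        SiteModelParams(model="M0", omega=-0.5)
    with pytest.raises(ValueError):
        SiteModelParams(model="M0", kappa=0.0)


def test_class_proportions_sum_to_one():
    for params in (
        SiteModelParams(model="M1a", p0=0.3),
        SiteModelParams(model="M2a", p0=0.5, p1=0.3),
        SiteModelParams(model="M7", beta_p=0.4, beta_q=1.3),
        SiteModelParams(model="M8", beta_p=0.4, beta_q=1.3, p0=0.8, omega_s=3.0),
    ):
        omegas, props = params.class_distribution()
        assert props.sum() == pytest.approx(1.0)
        assert (omegas >= 0).all()


def test_beta_discretization_preserves_the_mean():
    for p, q in [(0.5, 0.5), (2.0, 5.0), (0.2, 1.7)]:
        cats = discretize_beta(p, q, 10)
        assert cats.mean() == pytest.approx(p / (p + q), rel=1e-3)
        assert ((cats > 0) & (cats < 1)).all()
        assert (np.diff(cats) >= 0).all()


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def test_simulation_is_deterministic():
    tree = random_tree(4, seed=1)
    params = SiteModelParams(model="M0", omega=0.3)
    a1, c1 = simulate_codon_alignment(tree, params, 50, seed=9)
    a2, c2 = simulate_codon_alignment(tree, params, 50, seed=9)
    assert a1.rows == a2.rows
    assert (c1 == c2).all()


def test_simulation_degenerate_inputs():
    tree = random_tree(4, seed=1)
    params = SiteModelParams(model="M0")
    with pytest.raises(ValueError):
        simulate_codon_alignment(tree, params, 0, seed=1)


def test_omega_zero_forbids_nonsynonymous_change():
    """omega=0 freezes the protein: every tip translates identically.

    (Pathway-based counting can still attribute fractional non-synonymous
    steps to synonymous codons two changes apart, so the process-level
    invariant is checked on the translations, not on NG86 output.)
    """
    from rosaslocus.candidates import translate_cds
    from rosaslocus.evolstats import ng86_counts

    tree = random_tree(4, seed=2, min_branch=0.3, max_branch=0.6)
    params = SiteModelParams(model="M0", omega=0.0)
    aln, _ = simulate_codon_alignment(tree, params, 300, seed=3)
    peptides = {translate_cds(row)[0] for row in aln.rows}
    assert len(peptides) == 1
    counts = ng86_counts(aln.rows[0], aln.rows[1])
    assert counts.Sd > 0.0


# ---------------------------------------------------------------------------
# Likelihood: pruning vs brute-force enumeration
# ---------------------------------------------------------------------------

def brute_force_loglik(aln, tree, params):
    """Sum over all internal-node state assignments (4-taxon toys only)."""
    from rosaslocus.codonmodels import _site_class_likelihoods  # noqa: F401

    states, _ = encode_alignment(aln)
    tindex = TreeIndex(tree, aln.ids)
    pi = equal_codon_frequencies()
    omegas, props = params.class_distribution()
    mats = ClassMatrices(omegas, props, params.kappa, pi)
    lengths = np.array(tindex.edge_lengths)

    internal = [i for i, (ch, tip, _s) in enumerate(tindex.nodes) if tip < 0]
    n_sites = states.shape[1]
    total = 0.0
    for site in range(n_sites):
        site_like = 0.0
        for k, (w, pk) in enumerate(zip(omegas, props)):
            pmats = {slot: mats.transition(k, t) for slot, t in enumerate(lengths)}

            def assign(level, chosen, k=k, pmats=pmats, site=site):
                if level == len(internal):
                    prob = 1.0
                    root = tindex.root_index
                    prob *= pi[chosen[root]]
                    for idx, (children, tip, _slot) in enumerate(tindex.nodes):
                        for cidx, slot in children:
                            child_tip = tindex.nodes[cidx][1]
                            child_state = (states[child_tip, site] if child_tip >= 0
                                           else chosen[cidx])
                            prob *= pmats[slot][chosen[idx], child_state]
                    return prob
                acc = 0.0
                for s in range(N_CODONS):
                    chosen[internal[level]] = s
                    acc += assign(level + 1, chosen)
                return acc

            site_like += pk * assign(0, {})
        total += np.log(site_like)
    return total


def test_pruning_matches_enumeration_on_toy():
    tree = random_tree(4, seed=5, min_branch=0.1, max_branch=0.4)
    params = SiteModelParams(model="M2a", p0=0.4, p1=0.4, omega0=0.2, omega2=3.0)
    aln, _ = simulate_codon_alignment(tree, params, 3, seed=6)

    from rosaslocus.codonmodels import _mixture_loglik, _site_class_likelihoods

    states, _ = encode_alignment(aln)
    tindex = TreeIndex(tree, aln.ids)
    omegas, props = params.class_distribution()
    mats = ClassMatrices(omegas, props, params.kappa, equal_codon_frequencies())
    log_class = _site_class_likelihoods(states, tindex,
                                        np.array(tindex.edge_lengths), mats, len(omegas))
    lnl, post = _mixture_loglik(log_class, props)
    assert lnl == pytest.approx(brute_force_loglik(aln, tree, params), abs=1e-8)
    assert np.allclose(post.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def m0_data():
    tree = random_tree(6, seed=3)
    params = SiteModelParams(model="M0", omega=0.2, kappa=2.0)
    aln, _ = simulate_codon_alignment(tree, params, 500, seed=7)
    return tree, aln


def test_m0_recovers_omega(m0_data):
    tree, aln = m0_data
    _, fit = fit_branch_lengths_m0(aln, tree, seed=1)
    assert fit.params.omega == pytest.approx(0.2, abs=0.05)
    assert 1.0 < fit.params.kappa < 4.0


def test_nested_models_keep_likelihood_ordering(m0_data):
    tree, aln = m0_data
    fitted, fit0 = fit_branch_lengths_m0(aln, tree, seed=1)
    f1 = fit_site_model(aln, fitted, "M1a", seed=1, n_starts=2, init_from=fit0)
    f2 = fit_site_model(aln, fitted, "M2a", seed=1, n_starts=2, init_from=f1)
    assert f2.lnL >= f1.lnL - 1e-6
    res = lrt(f1, f2)
    assert res.statistic >= 0.0
    assert 0.0 <= res.p_value <= 1.0
    # purifying data: the positive-selection class finds no support
    assert res.p_value > 0.01
    assert np.allclose(f1.site_posteriors.sum(axis=1), 1.0)
    assert np.allclose(f2.site_posteriors.sum(axis=1), 1.0)


def test_no_signal_data_gives_zero_lrt():
    tree = random_tree(4, seed=8, min_branch=0.05, max_branch=0.1)
    aln = Alignment([f"t{i+1}" for i in range(4)], ["ATGAAATTTGGGCCCCTG" * 5] * 4, "codon")
    fitted, fit0 = fit_branch_lengths_m0(aln, tree, seed=2)
    f1 = fit_site_model(aln, fitted, "M1a", seed=2, n_starts=1, init_from=fit0)
    f2 = fit_site_model(aln, fitted, "M2a", seed=2, n_starts=1, init_from=f1)
    res = lrt(f1, f2)
    assert res.statistic == pytest.approx(0.0, abs=0.05)
    assert res.p_value > 0.9


def test_lrt_chi2_reference():
    a = LrtResult("M1a", "M2a", 5.99, 2, stats.chi2.sf(5.99, 2))
    assert a.p_value == pytest.approx(0.05, abs=0.001)


def test_stop_codons_in_alignment_rejected():
    aln = Alignment(["a", "b", "c"], ["ATGTAAAAA"] * 3, "codon")
    with pytest.raises(ValueError, match="stop codon"):
        encode_alignment(aln)


def test_call_positive_sites_threshold_validation(m0_data):
    tree, aln = m0_data
    fitted, fit0 = fit_branch_lengths_m0(aln, tree, seed=1)
    f1 = fit_site_model(aln, fitted, "M1a", seed=1, n_starts=1, init_from=fit0)
    with pytest.raises(ValueError):
        call_positive_sites(f1, f1, f1, f1, threshold=1.5)
    with pytest.raises(ValueError):
        call_positive_sites(f1, f1, f1, f1, rule="nonsense")


@pytest.fixture(scope="module")
def m2a_scan():
    """One positive-selection data set with all four fits."""
    tree = random_tree(6, seed=30)
    truth = SiteModelParams(model="M2a", p0=0.5, p1=0.3, omega0=0.1, omega2=5.0)
    aln, classes = simulate_codon_alignment(tree, truth, 300, seed=31)
    fitted, fit0 = fit_branch_lengths_m0(aln, tree, seed=1)
    f1 = fit_site_model(aln, fitted, "M1a", seed=1, init_from=fit0)
    f2 = fit_site_model(aln, fitted, "M2a", seed=1, init_from=f1)
    f7 = fit_site_model(aln, fitted, "M7", seed=1, init_from=fit0)
    f8 = fit_site_model(aln, fitted, "M8", seed=1, init_from=f7)
    return aln, classes, fitted, f1, f2, f7, f8


def test_positive_selection_detected_by_both_comparisons(m2a_scan):
    _aln, _classes, _tree, f1, f2, f7, f8 = m2a_scan
    assert lrt(f1, f2).p_value < 0.001
    assert lrt(f7, f8).p_value < 0.001
    assert f2.params.omega2 > 2.0


def test_site_calls_recover_planted_sites(m2a_scan):
    aln, classes, tree, f1, f2, f7, f8 = m2a_scan
    calls = call_positive_sites(f1, f2, f7, f8, aln=aln, reference_id=aln.ids[0],
                                threshold=0.9, rule="NEB_only")
    called = {c.column for c in calls}
    planted = {i for i, k in enumerate(classes) if k == 2}
    neutral = set(range(len(classes))) - planted
    assert len(called & planted) / len(planted) > 0.4
    assert len(called & neutral) / len(neutral) < 0.05
    # reference-residue mapping is 1-based and gap-free here
    assert all(c.reference_position == c.column + 1 for c in calls)


def test_beb_posteriors_track_planted_sites(m2a_scan):
    aln, classes, tree, _f1, f2, _f7, _f8 = m2a_scan
    beb = beb_positive_posterior(aln, tree, f2, grid=6)
    assert beb.shape == (f2.n_sites,)
    assert ((beb >= 0) & (beb <= 1)).all()
    planted = classes == 2
    assert beb[planted].mean() > beb[~planted].mean() + 0.2
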